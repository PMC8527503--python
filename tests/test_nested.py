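"""Nested intronic gene detection: brute-force oracle equivalence,
tolerance boundary, intron exclusion arithmetic, census, TE flanks."""
from __future__ import annotations

from fractions import Fraction

import numpy as np
import pytest

from ctenokit.model import GenomicInterval, ValidationError
from ctenokit.nested import (
    detect_nested_genes,
    extract_and_filter_introns,
    summarize_nested,
    te_flanking,
)
from ctenokit.simulate import simulate_nested_annotation

from conftest import make_annotation, make_gene, random_annotation


# ---------------------------------------------------------------------------
# Brute-force oracle: exact-rational containment over all triples
# ---------------------------------------------------------------------------

def oracle_nested(annotation, introns, tolerance: Fraction):
    """Quadratic oracle: test every (gene, transcript, intron) triple with
    exact rational arithmetic; returns {nested_id: (host_id, intron key)}
    choosing the minimal-span qualifying intron per gene."""
    out = {}
    for g in annotation.genes:
        candidates = []
        for t in g.transcripts:
            span = t.end - t.start
            for rec in introns:
                if rec.host_gene_id == g.gene_id:
                    continue
                iv = rec.interval
                if t.seqid != iv.seqid:
                    continue
                left = max(0, iv.start - t.start)
                right = max(0, t.end - iv.end)
                if Fraction(left) > tolerance * span:
                    continue
                if Fraction(right) > tolerance * span:
                    continue
                if left > rec.left_exon_length:
                    continue
                if right > rec.right_exon_length:
                    continue
                candidates.append(
                    ((rec.length, iv.seqid, iv.start, iv.end,
                      rec.host_gene_id), rec)
                )
        if candidates:
            _, best = min(candidates, key=lambda c: c[0])
            out[g.gene_id] = (best.host_gene_id,
                              (best.interval.seqid, best.interval.start,
                               best.interval.end))
    return out


def test_oracle_equivalence_on_random_annotations():
    """On 100 random small annotations the detector matches the exact
    rational brute-force oracle, gene for gene and host for host."""
    rng = np.random.default_rng(99)
    for trial in range(100):
        ann = random_annotation(rng, int(rng.integers(5, 51)))
        introns = extract_and_filter_introns(ann, 0.005)
        records = detect_nested_genes(ann, introns, 0.15)
        got = {
            r.nested_gene_id: (
                r.host_gene_id,
                (r.host_intron.interval.seqid, r.host_intron.interval.start,
                 r.host_intron.interval.end),
            )
            for r in records
        }
        want = oracle_nested(ann, introns, Fraction(15, 100))
        assert got == want, f"trial {trial}"


def test_overlap_tolerance_boundary_150_vs_151():
    """On a 1000-bp nested transcript, 150 bp of host-exon overlap is
    allowed and 151 bp is rejected at the default 15% tolerance."""
    def build(overlap):
        host = make_gene("host", "c1", [(0, 1_000), (10_000, 11_000)])
        nested = make_gene("ni", "c1",
                           [(1_000 - overlap, 1_400 - overlap),
                            (1_600 - overlap, 2_000 - overlap)])
        return make_annotation([host, nested])

    for overlap, expected in [(150, 1), (151, 0)]:
        ann = build(overlap)
        introns = extract_and_filter_introns(ann, 0.0)
        host_introns = [r for r in introns if r.host_gene_id == "host"]
        records = detect_nested_genes(ann, host_introns, 0.15)
        assert len(records) == expected, f"overlap {overlap}"
        if records:
            assert records[0].five_prime_overlap == 150


def test_intron_exclusion_ceiling():
    """With 1000 introns and fraction 0.005, exactly the 5 longest are
    excluded."""
    genes = []
    for i in range(1000):
        base = i * 30_000
        intron_len = 1_000 + i  # strictly increasing
        genes.append(make_gene(
            f"g{i:04d}", "c1",
            [(base, base + 100), (base + 100 + intron_len,
                                  base + 200 + intron_len)]))
    ann = make_annotation(genes, {"c1": 1000 * 30_000 + 10_000})
    introns = extract_and_filter_introns(ann, 0.005)
    assert len(introns) == 995
    assert max(r.length for r in introns) == 1_000 + 994


def test_single_exon_genes_yield_no_introns():
    ann = make_annotation([make_gene("g1", "c1", [(0, 500)]),
                           make_gene("g2", "c1", [(1000, 1500)])])
    assert extract_and_filter_introns(ann) == []


def test_fig_like_fixture_four_nested_two_doubly():
    """One host carrying four NI genes, two of which are doubly nested."""
    ann, truth = simulate_nested_annotation(1, n_host_genes=1,
                                            n_singly_nested=2,
                                            n_doubly_nested=2)
    introns = extract_and_filter_introns(ann, 0.0)
    records = detect_nested_genes(ann, introns)
    assert len(records) == 4
    assert sum(1 for r in records if r.nesting_depth == 2) == 2
    got = {(r.host_gene_id, r.nested_gene_id, r.nesting_depth)
           for r in records}
    want = {(h, n, d) for h, n, d, _f in truth.itertuples(index=False)}
    assert got == want


def test_planted_truth_recovery_with_overlap_fractions():
    """Planted overlap fractions <= tolerance are detected; fractions
    above it are excluded."""
    ann, truth = simulate_nested_annotation(
        5, n_host_genes=6, n_singly_nested=6,
        overlap_fractions=(0.0, 0.10, 0.15, 0.20, 0.30, 0.05),
        nested_gene_length=1_000)
    introns = extract_and_filter_introns(ann, 0.0)
    records = detect_nested_genes(ann, introns, 0.15)
    detected = {r.nested_gene_id for r in records}
    for row in truth.itertuples():
        if row.overlap_fraction <= 0.15:
            assert row.nested_gene_id in detected
        else:
            assert row.nested_gene_id not in detected


def test_tolerance_monotonicity(rng):
    """Raising the tolerance never shrinks the NI set; excluding more
    introns never grows it."""
    ann = random_annotation(rng, 40)
    introns = extract_and_filter_introns(ann, 0.0)
    prev = -1
    for tol in (0.0, 0.05, 0.15, 0.30, 0.45):
        n = len(detect_nested_genes(ann, introns, tol))
        assert n >= prev
        prev = n
    prev = 10**9
    for frac in (0.0, 0.05, 0.2, 0.5):
        filtered = extract_and_filter_introns(ann, frac)
        n = len(detect_nested_genes(ann, filtered, 0.15))
        assert n <= prev
        prev = n


def test_tolerance_validation():
    ann = make_annotation([make_gene("g", "c1", [(0, 100)])])
    with pytest.raises(ValidationError):
        detect_nested_genes(ann, [], 0.6)


# ---------------------------------------------------------------------------
# Census
# ---------------------------------------------------------------------------

def test_summary_no_ni_genes():
    ann = make_annotation([make_gene("g1", "c1", [(0, 500)])])
    s = summarize_nested(ann, [])
    assert s.percent_exonic_in_ni == 0.0
    assert s.exonic_bp_total == 500


def test_summary_percent_exonic_hand_case():
    """NI exon union 120 bp of a 1000 bp total union -> 12.0%."""
    host = make_gene("host", "c1", [(0, 440), (10_000, 10_440)])
    ni = make_gene("ni", "c1", [(1_000, 1_060), (2_000, 2_060)])
    ann = make_annotation([host, ni])
    introns = extract_and_filter_introns(ann, 0.0)
    records = detect_nested_genes(ann, introns)
    assert [r.nested_gene_id for r in records] == ["ni"]
    s = summarize_nested(ann, records)
    assert (s.exonic_bp_total, s.exonic_bp_ni) == (1_000, 120)
    assert s.percent_exonic_in_ni == pytest.approx(12.0)


def test_summary_invariant_under_transcript_duplication():
    host = make_gene("host", "c1", [(0, 440), (10_000, 10_440)])
    ni = make_gene("ni", "c1", [(1_000, 1_060), (2_000, 2_060)])
    host_dup = make_gene("host", "c1", [(0, 440), (10_000, 10_440)],
                         n_transcripts=3)
    ni_dup = make_gene("ni", "c1", [(1_000, 1_060), (2_000, 2_060)],
                       n_transcripts=2)
    for genes in ([host, ni], [host_dup, ni_dup]):
        ann = make_annotation(genes)
        records = detect_nested_genes(
            ann, extract_and_filter_introns(ann, 0.0))
        s = summarize_nested(ann, records)
        assert s.percent_exonic_in_ni == pytest.approx(12.0)


# ---------------------------------------------------------------------------
# TE flanking
# ---------------------------------------------------------------------------

def _flank_fixture():
    host = make_gene("host", "c1", [(0, 500), (10_000, 10_500)])
    ni = make_gene("ni", "c1", [(4_000, 4_400), (4_600, 5_000)])
    ann = make_annotation([host, ni])
    records = detect_nested_genes(ann, extract_and_filter_introns(ann, 0.0))
    assert len(records) == 1
    return ann, records


def test_te_flank_one_side():
    ann, records = _flank_fixture()
    tes = [GenomicInterval("c1", 500, 4_000)]  # exactly the 5' flank
    flags = te_flanking(records, ann, tes)
    assert flags["ni"] == (True, False)
    s = summarize_nested(ann, records, tes)
    assert (s.n_te_flanked_one_side, s.n_te_flanked_both_sides) == (1, 0)


def test_te_flank_both_sides_counted_in_both_tallies():
    ann, records = _flank_fixture()
    tes = [GenomicInterval("c1", 3_000, 3_500),
           GenomicInterval("c1", 6_000, 6_500)]
    s = summarize_nested(ann, records, tes)
    assert (s.n_te_flanked_one_side, s.n_te_flanked_both_sides) == (1, 1)


def test_te_flank_none():
    ann, records = _flank_fixture()
    s = summarize_nested(ann, records, [])
    assert (s.n_te_flanked_one_side, s.n_te_flanked_both_sides) == (0, 0)


def test_te_outside_host_intron_does_not_flank():
    ann, records = _flank_fixture()
    tes = [GenomicInterval("c1", 12_000, 13_000)]
    flags = te_flanking(records, ann, tes)
    assert flags["ni"] == (False, False)
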