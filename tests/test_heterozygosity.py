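"""Depth-conditioned heterozygosity estimator: classification rules,
conservation, parameter recovery, and the half-depth dip."""
from __future__ import annotations

import numpy as np
import pytest

from ctenokit.heterozygosity import (
    CLASS_HET_INDEL,
    CLASS_HET_SNP,
    CLASS_HOM_ALT,
    CLASS_HOM_REF,
    CLASS_OTHER,
    HetBandConfig,
    as_pileup_frame,
    assign_region_classes,
    build_allele_balance_2d,
    build_depth_histogram,
    classify_site,
    estimate_heterozygosity,
    stratified_heterozygosity,
)
from ctenokit.model import PileupSite, ValidationError
from ctenokit.simulate import SimulationConfig, simulate_diploid_pileup

from conftest import make_annotation, make_gene


def site(depth, ref, snp=0, indel=0, pos=0, seqid="c1"):
    return PileupSite(seqid, pos, depth, ref, snp, indel)


# ---------------------------------------------------------------------------
# Depth histogram
# ---------------------------------------------------------------------------

def test_histogram_tally_and_mode():
    hist = build_depth_histogram([site(5, 5, pos=0), site(5, 5, pos=1),
                                  site(7, 7, pos=2)])
    assert hist.counts == {5: 2, 7: 1}
    assert hist.modal_depth == 5
    assert hist.total() == 3


def test_histogram_tie_breaks_to_lowest_depth():
    hist = build_depth_histogram(
        [site(4, 4, pos=0), site(4, 4, pos=1),
         site(6, 6, pos=2), site(6, 6, pos=3)])
    assert hist.modal_depth == 4


def test_histogram_empty_stream_errors():
    with pytest.raises(ValidationError):
        build_depth_histogram([])


# ---------------------------------------------------------------------------
# Site classification
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("s,expected", [
    (site(178, 178), CLASS_HOM_REF),
    (site(178, 89, snp=89), CLASS_HET_SNP),
    (site(178, 90, snp=3, indel=85), CLASS_HET_INDEL),
    (site(178, 0, snp=178), CLASS_HOM_ALT),
    (site(178, 40, snp=138), CLASS_HOM_ALT),    # f = 0.225 <= 1 - upper
    (site(10, 5, snp=2, indel=2), CLASS_HET_SNP),  # subtype tie -> snp
])
def test_classify_site_band_rules(s, expected):
    assert classify_site(s) == expected


def test_classify_site_other_zone_with_asymmetric_band():
    """With lower > 1 - upper a gap zone exists between hom_alt and the
    heterozygous band; sites there are 'other' but stay in denominators."""
    band = HetBandConfig(lower=0.40, upper=0.70)
    s = site(178, 60, snp=118)  # f = 0.337: above 0.30, below 0.40
    assert classify_site(s, band) == CLASS_OTHER
    est = estimate_heterozygosity([s], 178, band)
    assert (est.sites_total, est.sites_het) == (1, 0)


def test_classify_frame_matches_scalar(rng):
    sites = []
    for i in range(500):
        d = int(rng.integers(1, 200))
        r = int(rng.integers(0, d + 1))
        rest = d - r
        sn = int(rng.integers(0, rest + 1))
        sites.append(site(d, r, snp=sn, indel=rest - sn, pos=i))
    df = as_pileup_frame(sites)
    from ctenokit.heterozygosity import classify_frame
    vec = classify_frame(df)
    assert vec.tolist() == [classify_site(s) for s in sites]


# ---------------------------------------------------------------------------
# Estimation
# ---------------------------------------------------------------------------

def test_estimate_brute_force_small_case():
    sites = [site(20, 10, snp=10, pos=i) for i in range(2)] + \
            [site(20, 20, pos=i) for i in range(2, 10)]
    est = estimate_heterozygosity(sites, 20)
    assert (est.sites_total, est.sites_het) == (10, 2)
    assert est.heterozygosity == 0.2


def test_estimate_all_homozygous_is_zero():
    sites = [site(30, 30, pos=i) for i in range(50)]
    assert estimate_heterozygosity(sites, 30).heterozygosity == 0.0


def test_estimate_errors_when_no_sites_at_mode():
    with pytest.raises(ValidationError, match="99"):
        estimate_heterozygosity([site(30, 30)], 99)


def test_estimate_recovers_planted_rates():
    """Combined estimate within 3 binomial SEs of the planted 3.2%."""
    cfg = SimulationConfig(seed=42, length=400_000, snp_rate=0.02,
                           indel_rate=0.012, error_rate=0.002,
                           mean_depth=178)
    _, pu = simulate_diploid_pileup(cfg)
    hist = build_depth_histogram(pu)
    est = estimate_heterozygosity(pu, hist.modal_depth)
    h = 0.032
    se = np.sqrt(h * (1 - h) / est.sites_total)
    assert abs(est.heterozygosity - h) < 3 * se


def test_band_widening_never_decreases_het_sites():
    cfg = SimulationConfig(seed=8, length=50_000, mean_depth=60)
    _, pu = simulate_diploid_pileup(cfg)
    hist = build_depth_histogram(pu)
    prev = -1
    for lo, hi in [(0.45, 0.55), (0.40, 0.60), (0.30, 0.70), (0.20, 0.80)]:
        est = estimate_heterozygosity(
            pu, hist.modal_depth, HetBandConfig(lower=lo, upper=hi))
        assert est.sites_het >= prev
        prev = est.sites_het


def test_half_depth_heterozygosity_dips():
    """At D*/2 (single-haplotype sites) the apparent heterozygosity is far
    below the value at D*."""
    cfg = SimulationConfig(seed=15, length=300_000, snp_rate=0.02,
                           indel_rate=0.012, error_rate=0.002,
                           mean_depth=178)
    _, pu = simulate_diploid_pileup(cfg)
    # emulate collapsed regions: halve depth by keeping one haplotype's
    # reads (ref reads at het sites; het sites become pure-ref)
    half = pu.copy()
    half["depth"] = half["ref_count"]
    half["snp_alt_count"] = 0
    half["indel_alt_count"] = 0
    hist = build_depth_histogram(pu)
    at_mode = estimate_heterozygosity(pu, hist.modal_depth).heterozygosity
    at_half = estimate_heterozygosity(
        half[half["depth"] >= 1], hist.modal_depth // 2).heterozygosity
    assert at_half < at_mode / 5


def test_band_config_validation():
    with pytest.raises(ValidationError):
        HetBandConfig(lower=0.6, upper=0.7)
    with pytest.raises(ValidationError):
        HetBandConfig(lower=0.3, upper=0.4)


# ---------------------------------------------------------------------------
# Stratification
# ---------------------------------------------------------------------------

def _toy_annotation():
    # exon [0, 100), intron [100, 200), exon [200, 300); intergenic beyond
    g = make_gene("g1", "c1", [(0, 100), (200, 300)])
    return make_annotation([g], {"c1": 1000})


def test_region_assignment_precedence():
    ann = _toy_annotation()
    df = as_pileup_frame([site(10, 10, pos=50), site(10, 10, pos=150),
                          site(10, 10, pos=500)])
    regions = assign_region_classes(df, ann)
    assert regions.tolist() == ["exonic", "intronic", "intergenic"]


def test_region_exon_wins_over_other_genes_intron():
    """A base in gene A's exon and gene B's intron counts as exonic."""
    a = make_gene("gA", "c1", [(100, 200)])
    b = make_gene("gB", "c1", [(0, 50), (400, 500)])  # intron [50, 400)
    ann = make_annotation([a, b], {"c1": 1000})
    df = as_pileup_frame([site(10, 10, pos=150)])
    assert assign_region_classes(df, ann).tolist() == ["exonic"]


def test_stratified_conservation_and_unknown_seqid():
    cfg = SimulationConfig(seed=21, length=2_000, mean_depth=40, seqid="c1")
    _, pu = simulate_diploid_pileup(cfg)
    ann = make_annotation([make_gene("g1", "c1", [(0, 500), (1500, 2000)])],
                          {"c1": 2_000})
    hist = build_depth_histogram(pu)
    ests = stratified_heterozygosity(pu, ann, hist.modal_depth)
    per_region = {
        (e.region_class): e.sites_total
        for e in ests
        if e.seqid == "all" and e.variant_class == "combined"
        and e.region_class != "genome"
    }
    genome_total = next(
        e.sites_total for e in ests
        if e.seqid == "all" and e.region_class == "genome"
        and e.variant_class == "combined"
    )
    assert sum(per_region.values()) == genome_total
    assert genome_total == hist.counts[hist.modal_depth]

    bad = pu.copy()
    bad["seqid"] = "unknown"
    with pytest.raises(ValidationError):
        stratified_heterozygosity(bad, ann, hist.modal_depth)


def test_stratified_whole_sequence_exonic_leaves_other_strata_empty():
    ann = make_annotation([make_gene("g1", "c1", [(0, 3000)])], {"c1": 3000})
    cfg = SimulationConfig(seed=2, length=3_000, mean_depth=40, seqid="c1")
    _, pu = simulate_diploid_pileup(cfg)
    hist = build_depth_histogram(pu)
    ests = stratified_heterozygosity(pu, ann, hist.modal_depth)
    regions = {e.region_class for e in ests}
    assert "intronic" not in regions and "intergenic" not in regions


def test_stratified_indel_direction_follows_planted_rates():
    """Higher planted indel rate in intergenic than exonic regions gives a
    higher intergenic indel estimate."""
    rng = np.random.default_rng(3)
    # gene covers [0, 5000); intergenic [5000, 50000)
    ann = make_annotation([make_gene("g1", "c1", [(0, 5_000)])],
                          {"c1": 50_000})
    cfg_ex = SimulationConfig(seed=31, length=5_000, indel_rate=0.004,
                              snp_rate=0.0, mean_depth=100, seqid="c1")
    cfg_ig = SimulationConfig(seed=32, length=45_000, indel_rate=0.03,
                              snp_rate=0.0, mean_depth=100, seqid="c1")
    _, pu_ex = simulate_diploid_pileup(cfg_ex)
    _, pu_ig = simulate_diploid_pileup(cfg_ig)
    pu_ig["pos"] += 5_000
    import pandas as pd
    pu = pd.concat([pu_ex, pu_ig], ignore_index=True)
    hist = build_depth_histogram(pu)
    ests = stratified_heterozygosity(pu, ann, hist.modal_depth,
                                     HetBandConfig(depth_window=3))
    by_key = {(e.region_class, e.variant_class): e.heterozygosity
              for e in ests if e.seqid == "all"}
    assert by_key[("intergenic", "indel")] > by_key[("exonic", "indel")]


# ---------------------------------------------------------------------------
# 2D allele balance
# ---------------------------------------------------------------------------

def test_allele_balance_2d_single_site_and_marginal():
    ab = build_allele_balance_2d([site(10, 5, snp=5)])
    assert ab.counts == {(10, 5): 1}

    cfg = SimulationConfig(seed=9, length=20_000, mean_depth=30)
    _, pu = simulate_diploid_pileup(cfg)
    ab = build_allele_balance_2d(pu)
    hist = build_depth_histogram(pu)
    assert ab.depth_marginal() == hist.counts
    assert ab.total() == len(pu)


def test_allele_balance_2d_het_mass_near_half_depth():
    cfg = SimulationConfig(seed=10, length=100_000, snp_rate=0.05,
                           indel_rate=0.0, error_rate=0.0, mean_depth=178)
    truth, pu = simulate_diploid_pileup(cfg)
    ab = build_allele_balance_2d(pu)
    # among sites at depth 178 with intermediate balance, the modal
    # ref_count is near 89
    at178 = {r: n for (d, r), n in ab.counts.items()
             if d == 178 and 40 <= r <= 140}
    mode_ref = max(at178, key=at178.get)
    assert abs(mode_ref - 89) <= 5
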