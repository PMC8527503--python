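"""Nested intronic (NI) gene detection and census.

An NI gene is a gene whose transcript lies within the boundaries of a
single intron of another (host) gene, with limited overlap into the
host's flanking exons at either end. Doubly nested genes are NI genes
sitting inside another NI gene's intron. The census reports the fraction
of exonic bases contributed by NI genes and how many NI genes are flanked
by transposable elements inside their host intron.

Geometric definition (shared by the detector and the brute-force test
oracle): transcript T of candidate gene G nests in filtered intron I of a
transcript of host H (G != H) iff the part of T extending left of I
(``left overhang``) and the part extending right of I are each at most
``tolerance`` x T's genomic span, and each overhang fits inside the
host exon immediately flanking that side of the intron. The very long
intron tail (introns created by trans-spliced leader first exons) is
excluded before detection.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from intervaltree import IntervalTree

from .model import Annotation, GeneModel, GenomicInterval, Transcript, ValidationError


@dataclass(frozen=True)
class IntronRecord:
    interval: GenomicInterval
    host_gene_id: str
    host_transcript_id: str
    # lengths of the exons immediately flanking this intron in its transcript
    left_exon_length: int
    right_exon_length: int

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass(frozen=True)
class NestedGeneRecord:
    nested_gene_id: str
    host_gene_id: str
    host_intron: IntronRecord
    five_prime_overlap: int
    three_prime_overlap: int
    orientation: str  # parallel | antiparallel
    nesting_depth: int  # 1 = NI, 2 = doubly nested


@dataclass(frozen=True)
class NestedSummary:
    n_host_genes: int
    n_ni_genes: int
    n_doubly_nested: int
    exonic_bp_total: int
    exonic_bp_ni: int
    n_te_flanked_one_side: int
    n_te_flanked_both_sides: int

    @property
    def percent_exonic_in_ni(self) -> float:
        if self.exonic_bp_total == 0:
            return 0.0
        return 100.0 * self.exonic_bp_ni / self.exonic_bp_total


# ---------------------------------------------------------------------------
# Introns
# ---------------------------------------------------------------------------

def extract_and_filter_introns(
    annotation: Annotation,
    exclude_top_fraction: float = 0.005,
) -> list[IntronRecord]:
    """Per-transcript introns, deduplicated by coordinates within each
    gene, with the longest ceil(fraction * N) introns removed genome-wide.

    Single-exon transcripts yield no introns. The returned list is sorted
    by (seqid, start).
    """
    if not (0 <= exclude_top_fraction < 1):
        raise ValidationError("exclude_top_fraction must lie in [0, 1)")
    records: list[IntronRecord] = []
    for g in annotation.genes:
        seen: set[tuple[str, int, int]] = set()
        for t in g.transcripts:
            for i in range(len(t.exons) - 1):
                a, b = t.exons[i], t.exons[i + 1]
                if b.start <= a.end:
                    continue
                key = (t.seqid, a.end, b.start)
                if key in seen:
                    continue
                seen.add(key)
                records.append(IntronRecord(
                    interval=GenomicInterval(t.seqid, a.end, b.start, t.strand),
                    host_gene_id=g.gene_id,
                    host_transcript_id=t.transcript_id,
                    left_exon_length=a.length,
                    right_exon_length=b.length,
                ))
    n_drop = math.ceil(exclude_top_fraction * len(records))
    if n_drop > 0:
        by_len = sorted(
            records,
            key=lambda r: (-r.length, r.interval.seqid, r.interval.start),
        )
        dropped = set(id(r) for r in by_len[:n_drop])
        records = [r for r in records if id(r) not in dropped]
    records.sort(key=lambda r: (r.interval.seqid, r.interval.start,
                                r.interval.end))
    return records


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def transcript_fits_intron(t: Transcript, intron: IntronRecord,
                           tolerance: float) -> tuple[int, int] | None:
    """Apply the shared nesting definition to one (transcript, intron)
    pair; returns (left overhang, right overhang) bp, or None."""
    iv = intron.interval
    if t.seqid != iv.seqid:
        return None
    span = t.end - t.start
    left_over = max(0, iv.start - t.start)
    right_over = max(0, t.end - iv.end)
    # integer bp allowance; the epsilon guards against binary representation
    # of tolerances like 0.15 (0.15 * 1000 must allow exactly 150 bp)
    allowed = math.floor(tolerance * span + 1e-9)
    if left_over > allowed or right_over > allowed:
        return None
    if left_over > intron.left_exon_length:
        return None
    if right_over > intron.right_exon_length:
        return None
    return left_over, right_over


def detect_nested_genes(
    annotation: Annotation,
    introns: Sequence[IntronRecord],
    end_overlap_tolerance: float = 0.15,
) -> list[NestedGeneRecord]:
    """Find all NI genes in an annotation against a filtered intron set.

    A gene qualifies when at least one of its transcripts fits one intron
    of another gene under the overlap tolerance. Each NI gene is reported
    once, with its minimal-span qualifying host intron; nesting depth is 2
    when that intron belongs to a gene that is itself NI (capped at 2).
    """
    if not (0 <= end_overlap_tolerance < 0.5):
        raise ValidationError("end_overlap_tolerance must lie in [0, 0.5)")
    trees: dict[str, IntervalTree] = {}
    for idx, rec in enumerate(introns):
        iv = rec.interval
        trees.setdefault(iv.seqid, IntervalTree()).addi(iv.start, iv.end, idx)

    chosen: dict[str, tuple[IntronRecord, int, int]] = {}
    for g in annotation.genes:
        best: tuple | None = None
        for t in g.transcripts:
            tree = trees.get(t.seqid)
            if tree is None:
                continue
            span = t.end - t.start
            pad = int(end_overlap_tolerance * span) + 1
            for hit in tree.overlap(t.start - pad, t.end + pad):
                rec = introns[hit.data]
                if rec.host_gene_id == g.gene_id:
                    continue
                fit = transcript_fits_intron(t, rec, end_overlap_tolerance)
                if fit is None:
                    continue
                key = (rec.length, rec.interval.seqid, rec.interval.start,
                       rec.interval.end, rec.host_gene_id)
                if best is None or key < best[0]:
                    best = (key, rec, fit)
        if best is not None:
            _key, rec, (left, right) = best
            chosen[g.gene_id] = (rec, left, right)

    ni_ids = set(chosen)
    out: list[NestedGeneRecord] = []
    for g in annotation.genes:
        if g.gene_id not in chosen:
            continue
        rec, left, right = chosen[g.gene_id]
        if g.strand == "-":
            five, three = right, left
        else:
            five, three = left, right
        host_gene = annotation.gene(rec.host_gene_id)
        orientation = ("parallel" if g.strand == host_gene.strand
                       else "antiparallel")
        depth = 2 if rec.host_gene_id in ni_ids else 1
        out.append(NestedGeneRecord(
            nested_gene_id=g.gene_id,
            host_gene_id=rec.host_gene_id,
            host_intron=rec,
            five_prime_overlap=five,
            three_prime_overlap=three,
            orientation=orientation,
            nesting_depth=depth,
        ))
    out.sort(key=lambda r: r.nested_gene_id)
    return out


# ---------------------------------------------------------------------------
# Summary
# ---------------------------------------------------------------------------

def _union_bp(intervals: list[tuple[str, int, int]]) -> int:
    intervals.sort()
    total = 0
    cur_seq, cur_s, cur_e = None, 0, -1
    for seqid, s, e in intervals:
        if seqid != cur_seq or s > cur_e:
            if cur_seq is not None:
                total += cur_e - cur_s
            cur_seq, cur_s, cur_e = seqid, s, e
        else:
            cur_e = max(cur_e, e)
    if cur_seq is not None:
        total += cur_e - cur_s
    return total


def _gene_exons(g: GeneModel) -> list[tuple[str, int, int]]:
    return [(e.seqid, e.start, e.end)
            for t in g.transcripts for e in t.exons]


def summarize_nested(
    annotation: Annotation,
    records: Sequence[NestedGeneRecord],
    te_intervals: Sequence[GenomicInterval] | None = None,
) -> NestedSummary:
    """Census of the NI gene set.

    Exonic bp are sizes of strand-collapsed exon unions: the genome-wide
    union over all genes, and the union over NI genes only — so the
    percentage is invariant under transcript duplication.
    """
    ni_ids = {r.nested_gene_id for r in records}
    all_exons: list[tuple[str, int, int]] = []
    ni_exons: list[tuple[str, int, int]] = []
    for g in annotation.genes:
        ex = _gene_exons(g)
        all_exons.extend(ex)
        if g.gene_id in ni_ids:
            ni_exons.extend(ex)
    one_side = both_sides = 0
    if te_intervals is not None:
        flags = te_flanking(records, annotation, te_intervals)
        one_side = sum(1 for f5, f3 in flags.values() if f5 or f3)
        both_sides = sum(1 for f5, f3 in flags.values() if f5 and f3)
    return NestedSummary(
        n_host_genes=len({r.host_gene_id for r in records}),
        n_ni_genes=len(records),
        n_doubly_nested=sum(1 for r in records if r.nesting_depth == 2),
        exonic_bp_total=_union_bp(all_exons),
        exonic_bp_ni=_union_bp(ni_exons),
        n_te_flanked_one_side=one_side,
        n_te_flanked_both_sides=both_sides,
    )


def te_flanking(
    records: Sequence[NestedGeneRecord],
    annotation: Annotation,
    te_intervals: Sequence[GenomicInterval],
) -> dict[str, tuple[bool, bool]]:
    """Which NI genes have a transposable element in a flank segment.

    The flank segments are bounded by the host intron: from the intron
    start to the nested gene start, and from the nested gene end to the
    intron end. A side counts as flanked when at least one TE interval
    overlaps that segment by >= 1 bp; zero-length segments are not
    flanked.
    """
    tree: dict[str, IntervalTree] = {}
    for te in te_intervals:
        tree.setdefault(te.seqid, IntervalTree()).addi(te.start, te.end)

    def seg_flanked(seqid: str, s: int, e: int) -> bool:
        if e <= s:
            return False
        t = tree.get(seqid)
        return bool(t is not None and t.overlap(s, e))

    out: dict[str, tuple[bool, bool]] = {}
    for r in records:
        gene = annotation.gene(r.nested_gene_id)
        iv = r.host_intron.interval
        left = seg_flanked(iv.seqid, iv.start, gene.interval.start)
        right = seg_flanked(iv.seqid, gene.interval.end, iv.end)
        out[r.nested_gene_id] = (left, right)
    return out
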