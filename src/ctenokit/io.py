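"""Readers and writers for the standard formats the pipeline touches.

GFF3, BED, FASTA/FASTQ, a 6-column TSV pileup contract, and 12-column
blast-style hit tables. Also two small arithmetic utilities that belong to
no analysis stage: physical coverage and global pairwise percent identity.

A pileup TSV can be produced from ``samtools mpileup`` output by emitting,
per site: seqid, 1-based position, depth, reads matching the reference
base, reads supporting the most common substitution allele, and reads
supporting the most common insertion/deletion allele.
"""
from __future__ import annotations

import math
from typing import Iterable, Iterator, Sequence

from Bio import Align, SeqIO

from .model import (
    Annotation,
    CoverageRecord,
    GeneModel,
    GenomicInterval,
    HitRecord,
    PileupSite,
    Transcript,
    ValidationError,
)


class ParseError(ValueError):
    """A file violates its format contract."""


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _parse_attributes(col9: str) -> dict[str, str]:
    out = {}
    for part in col9.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


_GENE_TYPES = {"gene"}
_TRANSCRIPT_TYPES = {"mRNA", "transcript"}
_EXON_TYPES = {"exon"}


def parse_gff3(path: str, fasta: str | None = None) -> Annotation:
    """Read a GFF3 file into an :class:`Annotation`.

    Expects gene / mRNA (or transcript) / exon features linked by ``Parent``
    attributes. Coordinates are converted from 1-based inclusive to the
    internal 0-based half-open convention. Unknown feature types are
    ignored; features whose parent is unknown, and genes that end up with
    no exons, are skipped and counted in ``Annotation.n_skipped``.

    Sequence lengths come from ``##sequence-region`` directives, or from
    ``fasta`` when given (FASTA takes precedence).
    """
    seq_lengths: dict[str, int] = {}
    genes_raw: dict[str, tuple[str, int, int, str]] = {}
    gene_order: list[str] = []
    tx_raw: dict[str, tuple[str, str, int, int, str]] = {}  # id -> (gene, seqid, s, e, strand)
    exons_raw: dict[str, list[tuple[int, int, str, str]]] = {}  # tx -> [(s, e, strand, seqid)]
    n_skipped = 0

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    seq_lengths[parts[1]] = int(parts[3])
                continue
            if line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, "
                    f"got {len(cols)}"
                )
            seqid, _src, ftype, start1, end1, _score, strand, _phase, attrs = cols
            if ftype not in _GENE_TYPES | _TRANSCRIPT_TYPES | _EXON_TYPES:
                continue
            try:
                start = int(start1) - 1
                end = int(end1)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            att = _parse_attributes(attrs)
            if ftype in _GENE_TYPES:
                gid = att.get("ID")
                if gid is None:
                    n_skipped += 1
                    continue
                genes_raw[gid] = (seqid, start, end, strand)
                gene_order.append(gid)
            elif ftype in _TRANSCRIPT_TYPES:
                tid, parent = att.get("ID"), att.get("Parent")
                if tid is None or parent not in genes_raw:
                    n_skipped += 1
                    continue
                tx_raw[tid] = (parent, seqid, start, end, strand)
            else:  # exon
                parent = att.get("Parent")
                if parent not in tx_raw:
                    n_skipped += 1
                    continue
                exons_raw.setdefault(parent, []).append((start, end, strand, seqid))

    if fasta is not None:
        for rec in SeqIO.parse(fasta, "fasta"):
            seq_lengths[rec.id] = len(rec.seq)

    tx_by_gene: dict[str, list[Transcript]] = {}
    for tid, (gid, seqid, ts, te, strand) in tx_raw.items():
        ex = exons_raw.get(tid)
        if not ex:
            n_skipped += 1
            continue
        ex.sort()
        for es, ee, _estrand, eseq in ex:
            if eseq != seqid or es < ts or ee > te:
                raise ValidationError(
                    f"exon {eseq}:{es + 1}-{ee} lies outside transcript {tid}"
                )
        exons = tuple(
            GenomicInterval(seqid, es, ee, strand) for es, ee, _s, _q in ex
        )
        tx_by_gene.setdefault(gid, []).append(Transcript(tid, exons))

    genes: list[GeneModel] = []
    for gid in gene_order:
        seqid, gs, ge, strand = genes_raw[gid]
        txs = tx_by_gene.get(gid)
        if not txs:
            n_skipped += 1
            continue
        genes.append(
            GeneModel(gid, GenomicInterval(seqid, gs, ge, strand), tuple(txs))
        )
    return Annotation(genes=genes, seq_lengths=seq_lengths, n_skipped=n_skipped)


def write_gff3(annotation: Annotation, path: str) -> None:
    """Serialize an Annotation back to GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for seqid in sorted(annotation.seq_lengths):
            fh.write(
                f"##sequence-region {seqid} 1 {annotation.seq_lengths[seqid]}\n"
            )
        for g in annotation.genes:
            iv = g.interval
            fh.write(
                f"{iv.seqid}\tctenokit\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\tID={g.gene_id}\n"
            )
            for t in g.transcripts:
                fh.write(
                    f"{t.seqid}\tctenokit\tmRNA\t{t.start + 1}\t{t.end}\t.\t"
                    f"{t.strand}\t.\tID={t.transcript_id};Parent={g.gene_id}\n"
                )
                for e in t.exons:
                    fh.write(
                        f"{e.seqid}\tctenokit\texon\t{e.start + 1}\t{e.end}\t.\t"
                        f"{e.strand}\t.\tParent={t.transcript_id}\n"
                    )


# ---------------------------------------------------------------------------
# Pileup TSV
# ---------------------------------------------------------------------------

def parse_pileup(path: str) -> Iterator[PileupSite]:
    """Stream a 6-column pileup TSV as validated :class:`PileupSite` records.

    Columns: seqid, position (1-based), depth, reads matching the reference
    base, reads supporting a substitution allele, reads supporting an
    insertion/deletion allele. Positions become 0-based internally.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 6:
                raise ParseError(
                    f"{path}:{lineno}: expected 6 columns, got {len(cols)}"
                )
            try:
                site = PileupSite(
                    cols[0],
                    int(cols[1]) - 1,
                    int(cols[2]),
                    int(cols[3]),
                    int(cols[4]),
                    int(cols[5]),
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer field") from exc
            yield site.validate()


def write_pileup(sites: Iterable[PileupSite], path: str) -> None:
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                f"{s.seqid}\t{s.pos + 1}\t{s.depth}\t{s.ref_count}\t"
                f"{s.snp_alt_count}\t{s.indel_alt_count}\n"
            )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def parse_bed(path: str) -> list[GenomicInterval]:
    """Read BED3/BED6 intervals (already 0-based half-open)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 BED columns")
            strand = cols[5] if len(cols) >= 6 and cols[5] in "+-" else "."
            out.append(GenomicInterval(cols[0], int(cols[1]), int(cols[2]), strand))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str,
              names: Sequence[str] | None = None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else f"iv{i}"
            fh.write(
                f"{iv.seqid}\t{iv.start}\t{iv.end}\t{name}\t0\t"
                f"{iv.strand if iv.strand != '.' else '+'}\n"
            )


# ---------------------------------------------------------------------------
# Blast-style tabular hits (outfmt 6)
# ---------------------------------------------------------------------------

def parse_hit_table(path: str) -> list[HitRecord]:
    """Read a 12-column blast-style hit table (qseqid sseqid pident length
    mismatch gapopen qstart qend sstart send evalue bitscore)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise ParseError(
                    f"{path}:{lineno}: expected 12 columns, got {len(cols)}"
                )
            out.append(
                HitRecord(
                    cols[0], cols[1], float(cols[2]),
                    float(cols[11]), float(cols[10]),
                ).validate()
            )
    return out


def write_hit_table(hits: Iterable[HitRecord], path: str) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.percent_identity:.1f}\t"
                f"100\t0\t0\t1\t100\t1\t100\t{h.evalue:g}\t{h.bitscore:g}\n"
            )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(seqs: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Arithmetic utilities
# ---------------------------------------------------------------------------

def physical_coverage(records: Sequence[CoverageRecord]) -> float:
    """Fold coverage: sum over libraries of sequenced bases / genome size.

    All records must share the same genome size. Reported to one decimal,
    the convention used for per-library coverage tables.
    """
    if not records:
        return 0.0
    sizes = {r.validate().genome_size for r in records}
    if len(sizes) != 1:
        raise ValidationError(f"records mix genome sizes: {sorted(sizes)}")
    total = sum(r.total_bases / r.genome_size for r in records)
    return round(total, 1)


def pairwise_percent_identity(
    seq_a: str,
    seq_b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_extend: float = -0.5,
) -> float:
    """Global end-to-end percent identity between two nucleotide sequences.

    Needleman-Wunsch with affine gaps (defaults: match +1, mismatch -1,
    gap open -2, gap extend -0.5); identity = identical columns / total
    alignment columns x 100, rounded to one decimal. Gap columns count
    against identity.
    """
    if not seq_a or not seq_b:
        raise ValidationError("sequences must be non-empty")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    aln = aligner.align(seq_a.upper(), seq_b.upper())[0]
    counts = aln.counts()
    return round(100.0 * counts.identities / aln.length, 1)


def derive_introns(annotation: Annotation) -> list[GenomicInterval]:
    """All per-transcript introns of an annotation, in genomic order."""
    out = []
    for g in annotation.genes:
        for t in g.transcripts:
            out.extend(t.introns())
    out.sort(key=lambda iv: (iv.seqid, iv.start, iv.end))
    return out


def ceil_fraction(n: int, fraction: float) -> int:
    """ceil(fraction * n) — used for "exclude the top X%" style rules."""
    return int(math.ceil(fraction * n))
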