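"""Core genomic data model shared by all analysis modules.

All coordinates are 0-based, half-open, everywhere inside the package.
GFF3 (1-based inclusive) and pileup positions (1-based) are converted at
the I/O boundary; BED is already 0-based half-open.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

VALID_STRANDS = ("+", "-", ".")


class ValidationError(ValueError):
    """An object violates one of the model invariants."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open interval [start, end) on a named sequence."""

    seqid: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.seqid:
            raise ValidationError("seqid must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.seqid}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.seqid == other.seqid
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.seqid != other.seqid:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.seqid == other.seqid
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class Transcript:
    """An ordered chain of exons belonging to one gene."""

    transcript_id: str
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValidationError(f"transcript {self.transcript_id} has no exons")
        seqids = {e.seqid for e in self.exons}
        if len(seqids) != 1:
            raise ValidationError(
                f"transcript {self.transcript_id} spans multiple sequences"
            )
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValidationError(
                    f"exons of transcript {self.transcript_id} overlap or are "
                    "unsorted"
                )

    @property
    def seqid(self) -> str:
        return self.exons[0].seqid

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.seqid, self.start, self.end, self.strand)

    def introns(self) -> Iterator[GenomicInterval]:
        """Gaps between consecutive exons, in genomic order."""
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                yield GenomicInterval(self.seqid, a.end, b.start, self.strand)


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    interval: GenomicInterval
    transcripts: tuple[Transcript, ...]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValidationError(f"gene {self.gene_id} has no transcripts")
        for t in self.transcripts:
            if t.strand != self.interval.strand:
                raise ValidationError(
                    f"transcript {t.transcript_id} strand differs from gene "
                    f"{self.gene_id}"
                )
            if not self.interval.contains(t.span):
                raise ValidationError(
                    f"transcript {t.transcript_id} extends outside gene "
                    f"{self.gene_id}"
                )

    @property
    def seqid(self) -> str:
        return self.interval.seqid

    @property
    def strand(self) -> str:
        return self.interval.strand


@dataclass
class Annotation:
    """A gene -> transcript -> exon hierarchy plus sequence lengths."""

    genes: list[GeneModel] = field(default_factory=list)
    seq_lengths: dict[str, int] = field(default_factory=dict)
    n_skipped: int = 0

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate gene identifiers: {dup[:5]}")

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def genes_by_seqid(self) -> dict[str, list[GeneModel]]:
        out: dict[str, list[GeneModel]] = {}
        for g in self.genes:
            out.setdefault(g.seqid, []).append(g)
        for lst in out.values():
            lst.sort(key=lambda g: (g.interval.start, g.interval.end, g.gene_id))
        return out

    def __len__(self) -> int:
        return len(self.genes)


class PileupSite(NamedTuple):
    """Per-position read support: the atom of heterozygosity estimation.

    ``ref_count`` reads match the reference base, ``snp_alt_count`` support a
    substitution allele and ``indel_alt_count`` support an insertion/deletion
    allele. The three need not sum to ``depth`` (multi-allelic remainder is
    allowed) but each must not exceed it.
    """

    seqid: str
    pos: int
    depth: int
    ref_count: int
    snp_alt_count: int
    indel_alt_count: int

    def validate(self) -> "PileupSite":
        for name in ("depth", "ref_count", "snp_alt_count", "indel_alt_count"):
            v = getattr(self, name)
            if v < 0:
                raise ValidationError(
                    f"{self.seqid}:{self.pos}: negative {name} ({v})"
                )
        for name in ("ref_count", "snp_alt_count", "indel_alt_count"):
            if getattr(self, name) > self.depth:
                raise ValidationError(
                    f"{self.seqid}:{self.pos}: {name} exceeds depth"
                )
        return self


class HitRecord(NamedTuple):
    """One row of a blast-style tabular hit file (subset of columns)."""

    query_id: str
    subject_id: str
    percent_identity: float
    bitscore: float
    evalue: float

    def validate(self) -> "HitRecord":
        if self.bitscore < 0 or self.evalue < 0:
            raise ValidationError(
                f"hit {self.query_id}->{self.subject_id}: negative score"
            )
        if not (0 <= self.percent_identity <= 100):
            raise ValidationError(
                f"hit {self.query_id}->{self.subject_id}: identity out of range"
            )
        return self


class CoverageRecord(NamedTuple):
    """Sequenced bases of one library relative to a genome size."""

    library_name: str
    total_bases: float
    genome_size: float

    def validate(self) -> "CoverageRecord":
        if self.total_bases < 0:
            raise ValidationError(f"{self.library_name}: negative total_bases")
        if self.genome_size <= 0:
            raise ValidationError(f"{self.library_name}: genome_size must be > 0")
        return self
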