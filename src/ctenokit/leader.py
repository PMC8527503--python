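"""Trans-spliced leader analysis.

Many ctenophore mRNAs receive a short leader RNA at their 5' end by
splicing in trans. In a genome assembly the leader shows up as a short
shared "first exon" reused by clusters of otherwise distinct genes, and
on full-length transcript reads as a common 5' prefix. This module
locates leader-like motif occurrences in genomic sequence, measures the
fraction of reads carrying the leader as a prefix, groups genes sharing a
leader-like first exon, and tallies transcript start dinucleotides (the
splice-acceptor AG is expected to dominate).
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Union

import edlib
from Bio import SeqIO

from .model import Annotation, GenomicInterval, ValidationError

#: 44-bp spliced-leader motif used as the default query.
DEFAULT_LEADER = "GAGTTTCAAACTTTTCAACACTACTTTAAACAAATTAATTTGAG"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class LeaderConfig:
    """Motif, identity threshold, and length window for leader scanning."""

    motif: str = DEFAULT_LEADER
    min_identity: float = 0.90
    min_len: int = 35
    max_len: int = 48
    both_strands: bool = True

    def __post_init__(self) -> None:
        if len(self.motif) < 10:
            raise ValidationError("motif shorter than 10 bp: identity "
                                  "threshold is meaningless")
        if not (0.5 < self.min_identity <= 1):
            raise ValidationError("min_identity must lie in (0.5, 1]")
        if self.min_len > self.max_len:
            raise ValidationError("min_len must be <= max_len")

    @property
    def max_edits(self) -> int:
        """Edit-distance ceiling implied by the identity threshold."""
        return int((1 - self.min_identity) * self.max_len)


@dataclass(frozen=True)
class LeaderMatch:
    """A located, scored motif occurrence on the genome."""

    interval: GenomicInterval
    identity: float
    matched_length: int

    @property
    def strand(self) -> str:
        return self.interval.strand


GenomeLike = Union[str, Path, dict]


def _as_seq_dict(genome: GenomeLike) -> dict[str, str]:
    if isinstance(genome, dict):
        return {k: v.upper() for k, v in genome.items()}
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(genome), "fasta")}


def _cigar_stats(cigar: str) -> tuple[int, int]:
    """(match columns, total columns) from an extended cigar (= X I D)."""
    matches = columns = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            n = int(num)
            num = ""
            columns += n
            if ch == "=":
                matches += n
    return matches, columns


def _align_stats(motif: str, segment: str) -> tuple[float, int]:
    """Global identity of motif vs segment: (identity, columns)."""
    res = edlib.align(motif, segment, mode="NW", task="path")
    matches, columns = _cigar_stats(res["cigar"])
    return matches / columns, columns


def _scan_one_strand(motif: str, seq: str, config: LeaderConfig
                     ) -> list[tuple[int, int, float]]:
    """All candidate loci on one strand as (start, end, identity).

    Iterative best-hit extraction: edlib's infix search returns every
    location achieving the current optimal edit distance; those loci are
    scored exactly (identity over alignment columns), masked out, and the
    search repeats until the optimal distance exceeds the ceiling implied
    by the identity threshold.
    """
    work = bytearray(seq.encode())
    k = config.max_edits
    out: list[tuple[int, int, float]] = []
    while True:
        res = edlib.align(motif, bytes(work).decode(), mode="HW",
                          task="locations", k=k)
        dist = res["editDistance"]
        if dist == -1:
            break
        for s, e in res["locations"]:
            end = e + 1
            segment = seq[s:end]
            identity, _cols = _align_stats(motif, segment)
            span = end - s
            if identity >= config.min_identity and \
                    config.min_len <= span <= config.max_len:
                out.append((s, end, identity))
            work[s:end] = b"N" * (end - s)
    return out


def scan_leader_motif(genome: GenomeLike,
                      config: LeaderConfig | None = None) -> list[LeaderMatch]:
    """Locate leader-motif occurrences on a genome.

    Semi-global alignment (free end-gaps on the genome side); a candidate
    is kept when identity = matching columns / alignment columns >=
    ``min_identity`` and the aligned genomic span lies in
    [``min_len``, ``max_len``]. Overlapping candidates are reduced to the
    highest-identity non-overlapping set (ties -> leftmost). Both strands
    are scanned unless disabled.
    """
    config = config or LeaderConfig()
    seqs = _as_seq_dict(genome)
    if not seqs or all(len(s) == 0 for s in seqs.values()):
        raise ValidationError("genome is empty")
    matches: list[LeaderMatch] = []
    for seqid, seq in seqs.items():
        candidates: list[tuple[int, int, float, str]] = []
        for s, e, ident in _scan_one_strand(config.motif, seq, config):
            candidates.append((s, e, ident, "+"))
        if config.both_strands:
            rc = revcomp(seq)
            for s, e, ident in _scan_one_strand(config.motif, rc, config):
                candidates.append((len(seq) - e, len(seq) - s, ident, "-"))
        # greedy non-overlap resolution: identity desc, then leftmost
        candidates.sort(key=lambda c: (-c[2], c[0], c[3]))
        taken: list[tuple[int, int]] = []
        for s, e, ident, strand in candidates:
            if any(s < te and ts < e for ts, te in taken):
                continue
            taken.append((s, e))
            matches.append(
                LeaderMatch(GenomicInterval(seqid, s, e, strand),
                            identity=ident, matched_length=e - s)
            )
    matches.sort(key=lambda m: (m.interval.seqid, m.interval.start))
    return matches


# ---------------------------------------------------------------------------
# Read-prefix detection
# ---------------------------------------------------------------------------

def _read_carries_leader(read: str, motif: str, min_identity: float,
                         min_suffix: int) -> bool:
    read = read.upper()
    for L in range(min(len(motif), len(read)), min_suffix - 1, -1):
        suffix = motif[-L:]
        prefix = read[:L]
        budget = int((1 - min_identity) * L)
        mism = 0
        for a, b in zip(suffix, prefix):
            if a != b:
                mism += 1
                if mism > budget:
                    break
        else:
            return True
    return False


def leader_read_fraction(reads: Union[str, Path, Iterable[str]],
                         config: LeaderConfig | None = None,
                         min_suffix: int = 15) -> float:
    """Fraction of reads carrying the leader as a 5' prefix.

    A read carries the leader when some suffix of the motif of length >=
    ``min_suffix`` matches the read's 5' end with a mismatch fraction <=
    (1 - min_identity). Reads are also tested reverse-complemented. The
    suffix rule tolerates 5' shearing of full-length cDNA reads.
    """
    config = config or LeaderConfig()
    if isinstance(reads, (str, Path)):
        p = str(reads)
        fmt = "fastq" if p.endswith((".fastq", ".fq")) else "fasta"
        seqs = [str(rec.seq) for rec in SeqIO.parse(p, fmt)]
    else:
        seqs = list(reads)
    if not seqs:
        raise ValidationError("no reads supplied")
    n_carry = 0
    for read in seqs:
        if _read_carries_leader(read, config.motif, config.min_identity,
                                min_suffix) or \
           _read_carries_leader(revcomp(read), config.motif,
                                config.min_identity, min_suffix):
            n_carry += 1
    return n_carry / len(seqs)


# ---------------------------------------------------------------------------
# Shared first exons and start dinucleotides
# ---------------------------------------------------------------------------

def shared_first_exon_clusters(annotation: Annotation, genome: GenomeLike,
                               config: LeaderConfig | None = None
                               ) -> list[dict]:
    """Group genes whose first exon matches the leader motif at the same
    genomic locus.

    The first exon is taken in transcript orientation (genomic last exon
    for minus-strand transcripts); it is tested against the motif with the
    scan rules, and genes are clustered by the exact genomic interval of
    the matching region. Returns a list of
    ``{"locus": GenomicInterval, "genes": [gene_ids]}``.
    """
    config = config or LeaderConfig()
    seqs = _as_seq_dict(genome)
    clusters: dict[tuple[str, int, int], set[str]] = {}
    loci: dict[tuple[str, int, int], GenomicInterval] = {}
    exon_cfg = replace(config, both_strands=False)
    for gene in annotation.genes:
        for t in gene.transcripts:
            exon = t.exons[0] if t.strand != "-" else t.exons[-1]
            seq = seqs.get(exon.seqid, "")[exon.start:exon.end]
            if not seq:
                continue
            if t.strand == "-":
                seq = revcomp(seq)
            hits = _scan_one_strand(config.motif, seq, exon_cfg)
            if not hits:
                continue
            s, e, _ident = max(hits, key=lambda h: (h[2], -h[0]))
            if t.strand == "-":
                g_start, g_end = exon.end - e, exon.end - s
            else:
                g_start, g_end = exon.start + s, exon.start + e
            key = (exon.seqid, g_start, g_end)
            clusters.setdefault(key, set()).add(gene.gene_id)
            loci.setdefault(
                key, GenomicInterval(exon.seqid, g_start, g_end, t.strand)
            )
            break  # one qualifying transcript suffices
    return [
        {"locus": loci[k], "genes": sorted(genes)}
        for k, genes in sorted(clusters.items())
    ]


def start_dinucleotide_census(transcript_seqs: Iterable[str]) -> dict[str, float]:
    """Frequencies of the first two bases over valid transcripts.

    Valid = length >= 2 with unambiguous leading bases; fractions sum to 1
    over the valid set.
    """
    counts: dict[str, int] = {}
    total = 0
    for seq in transcript_seqs:
        seq = seq.upper()
        if len(seq) < 2:
            continue
        dinuc = seq[:2]
        if any(b not in "ACGT" for b in dinuc):
            continue
        counts[dinuc] = counts.get(dinuc, 0) + 1
        total += 1
    if total == 0:
        return {}
    return {k: v / total for k, v in sorted(counts.items())}
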