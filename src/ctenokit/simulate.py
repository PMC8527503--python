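"""Synthetic-data generators with recorded ground truth.

Each generator emulates the statistical structure one analysis stage
assumes — diploid pileups with planted SNP/indel heterozygosity under a
Poisson depth model, annotations with nested and doubly-nested genes,
ortholog gene orders related by rearrangements, sequences with planted
partially diverged leader motifs, and TAD landscapes with a controlled
boundary-to-gene offset distribution — so every downstream stage is
testable without external downloads. All randomness in one invocation
flows from a single seeded generator; identical seed and configuration
give identical output.

Default parameters mirror the study conditions the estimators were built
for: mean mapping depth 178x, SNP heterozygosity 2%, combined SNP+indel
heterozygosity 3.2%, a 44-bp leader motif at >=90% identity, TADs with a
60-kb median length.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .leader import DEFAULT_LEADER, revcomp
from .model import (
    Annotation,
    GeneModel,
    GenomicInterval,
    HitRecord,
    Transcript,
    ValidationError,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.choice(_BASES, size=length)


# ---------------------------------------------------------------------------
# Diploid pileup
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    """Parameters for the diploid-pileup generator.

    Rates are per-bp probabilities; ``mean_depth`` is the Poisson mean
    (fold coverage); ``error_rate`` is the per-read-base probability that
    a read's support is flipped to a random wrong allele category.
    ``overdispersion`` > 0 switches the depth model to a negative binomial
    with that dispersion parameter (variance = mean + mean^2/k).
    """

    seed: int
    length: int = 1_000_000
    snp_rate: float = 0.02
    indel_rate: float = 0.012
    mean_depth: float = 178.0
    error_rate: float = 0.002
    overdispersion: float | None = None
    seqid: str = "sim1"

    def __post_init__(self) -> None:
        for name in ("snp_rate", "indel_rate", "error_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.snp_rate + self.indel_rate >= 1:
            raise ValidationError("snp_rate + indel_rate must be < 1")
        if self.length <= 0:
            raise ValidationError("length must be > 0")


@dataclass
class DiploidTruth:
    """Planted variants and realized rates for one simulated genome."""

    reference: str
    variants: pd.DataFrame  # pos, type, ref_allele, alt_allele
    snp_heterozygosity: float
    indel_heterozygosity: float
    config: SimulationConfig = field(repr=False, default=None)


def simulate_diploid_pileup(
    config: SimulationConfig,
) -> tuple[DiploidTruth, pd.DataFrame]:
    """Simulate a per-site pileup of a diploid genome against a composite
    reference.

    Every position gets depth ~ Poisson(mean); at planted heterozygous
    positions each read is drawn from either haplotype with probability
    1/2; sequencing errors flip a read's support to one of the two wrong
    categories, chosen uniformly. Indel variants are planted as
    single-position pileup signals (reads supporting an indel allele)
    because the estimator consumes pileups only.

    Returns the truth table and a pileup frame with columns
    seqid, pos, depth, ref_count, snp_alt_count, indel_alt_count.
    """
    rng = np.random.default_rng(config.seed)
    L = config.length
    ref = _random_sequence(rng, L)

    u = rng.random(L)
    is_snp = u < config.snp_rate
    is_indel = (~is_snp) & (u < config.snp_rate + config.indel_rate)

    if config.overdispersion:
        k = config.overdispersion
        p = k / (k + config.mean_depth)
        depth = rng.negative_binomial(k, p, size=L)
    else:
        depth = rng.poisson(config.mean_depth, size=L)

    ref_count = depth.copy()
    snp_alt = np.zeros(L, dtype=np.int64)
    indel_alt = np.zeros(L, dtype=np.int64)
    err = config.error_rate

    def split_errors(total: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        a = rng.binomial(total, 0.5)
        return a, total - a

    hom = ~(is_snp | is_indel)
    if err > 0:
        e_hom = rng.binomial(depth[hom], err)
        to_snp, to_indel = split_errors(e_hom)
        ref_count[hom] -= e_hom
        snp_alt[hom] += to_snp
        indel_alt[hom] += to_indel

    for mask, alt_is_indel in ((is_snp, False), (is_indel, True)):
        d = depth[mask]
        h_ref = rng.binomial(d, 0.5)
        h_alt = d - h_ref
        if err > 0:
            e_ref = rng.binomial(h_ref, err)   # flips to the two non-ref cats
            e_alt = rng.binomial(h_alt, err)   # flips to ref or the other alt
            r_to_a, r_to_other = split_errors(e_ref)
            a_to_ref, a_to_other = split_errors(e_alt)
        else:
            e_ref = e_alt = r_to_a = r_to_other = a_to_ref = a_to_other = 0
        rc = h_ref - e_ref + a_to_ref
        ac = h_alt - e_alt + r_to_a
        other = r_to_other + a_to_other
        ref_count[mask] = rc
        if alt_is_indel:
            indel_alt[mask] = ac
            snp_alt[mask] = other
        else:
            snp_alt[mask] = ac
            indel_alt[mask] = other

    # truth table
    pos_snp = np.flatnonzero(is_snp)
    pos_indel = np.flatnonzero(is_indel)
    ref_str = ref.tobytes().decode()
    rows = []
    alt_choices = rng.integers(1, 4, size=len(pos_snp))  # offset to a != base
    for p, off in zip(pos_snp, alt_choices):
        base = ref_str[p]
        alt = "ACGT"[("ACGT".index(base) + off) % 4]
        rows.append((int(p), "snp", base, alt))
    ins_mask = rng.random(len(pos_indel)) < 0.5
    ins_base = rng.choice(list("ACGT"), size=len(pos_indel))
    for p, is_ins, b in zip(pos_indel, ins_mask, ins_base):
        base = ref_str[p]
        if is_ins:
            rows.append((int(p), "insertion", base, base + b))
        else:
            rows.append((int(p), "deletion", base, ""))
    variants = pd.DataFrame(rows, columns=["pos", "type", "ref_allele",
                                           "alt_allele"])
    truth = DiploidTruth(
        reference=ref_str,
        variants=variants,
        snp_heterozygosity=len(pos_snp) / L,
        indel_heterozygosity=len(pos_indel) / L,
        config=config,
    )
    pileup = pd.DataFrame({
        "seqid": config.seqid,
        "pos": np.arange(L, dtype=np.int64),
        "depth": depth.astype(np.int64),
        "ref_count": ref_count.astype(np.int64),
        "snp_alt_count": snp_alt,
        "indel_alt_count": indel_alt,
    })
    return truth, pileup


# ---------------------------------------------------------------------------
# Nested annotation
# ---------------------------------------------------------------------------

def simulate_nested_annotation(
    seed: int,
    n_host_genes: int,
    n_singly_nested: int = 0,
    n_doubly_nested: int = 0,
    overlap_fractions: Sequence[float] = (0.0,),
    host_intron_length: int = 30_000,
    host_exon_length: int = 500,
    nested_gene_length: int = 2_000,
    doubly_gene_length: int = 600,
    seqid: str = "nchr1",
) -> tuple[Annotation, pd.DataFrame]:
    """Emit an annotation with planted nested-intronic (NI) genes and the
    truth table of nesting relations.

    Each host gene has two exons around one large intron; singly nested
    genes are placed side by side inside host introns, extended at their
    genomic-left (5', plus-strand) end into the host's flanking exon by
    the requested overlap fraction of their own length. Doubly nested
    genes sit inside the intron of a singly nested carrier gene. The
    truth table lists (host_gene_id, nested_gene_id, depth,
    overlap_fraction).
    """
    for f in overlap_fractions:
        if not (0 <= f < 0.5):
            raise ValidationError("overlap fractions must lie in [0, 0.5)")
    if n_doubly_nested > 0 and n_singly_nested == 0:
        raise ValidationError("doubly nested genes need a singly nested "
                              "carrier")
    rng = np.random.default_rng(seed)
    genes: list[GeneModel] = []
    truth_rows: list[tuple[str, str, int, float]] = []

    host_span = 2 * host_exon_length + host_intron_length
    gap_between_hosts = 5_000
    margin = 200

    # distribute singly nested genes round-robin over hosts
    per_host: list[list[int]] = [[] for _ in range(n_host_genes)]
    for k in range(n_singly_nested):
        if n_host_genes == 0:
            raise ValidationError("cannot nest genes without hosts")
        per_host[k % n_host_genes].append(k)

    # carriers: the first min(n_singly, n_doubly-needed) singly nested genes
    carriers_needed = min(n_singly_nested, n_doubly_nested)
    doubly_per_carrier: list[list[int]] = [[] for _ in range(max(carriers_needed, 1))]
    for k in range(n_doubly_nested):
        doubly_per_carrier[k % max(carriers_needed, 1)].append(k)

    fracs = [overlap_fractions[k % len(overlap_fractions)]
             for k in range(n_singly_nested)]

    cursor = 1_000
    singly_counter = 0
    for h in range(n_host_genes):
        hs = cursor
        intron_start = hs + host_exon_length
        intron_end = intron_start + host_intron_length
        he = intron_end + host_exon_length
        host_id = f"host{h:03d}"
        host = GeneModel(
            host_id,
            GenomicInterval(seqid, hs, he, "+"),
            (Transcript(f"{host_id}.t1", (
                GenomicInterval(seqid, hs, intron_start, "+"),
                GenomicInterval(seqid, intron_end, he, "+"),
            )),),
        )
        genes.append(host)

        inner_cursor = intron_start + margin
        for k in per_host[h]:
            frac = fracs[k]
            is_carrier = singly_counter < carriers_needed
            glen = nested_gene_length
            overlap_bp = int(round(frac * glen))
            if overlap_bp > host_exon_length:
                raise ValidationError(
                    f"overlap {overlap_bp} bp exceeds host exon length"
                )
            if overlap_bp > 0:
                gs = intron_start - overlap_bp
            else:
                gs = inner_cursor
            ge = gs + glen
            if ge > intron_end - margin:
                raise ValidationError(
                    f"host intron too short for nested gene of {glen} bp"
                )
            nid = f"ni{singly_counter:03d}"
            if is_carrier:
                # two short exons around a wide inner intron that can host
                # doubly nested genes
                ex1 = GenomicInterval(seqid, gs, gs + 150, "+")
                ex2 = GenomicInterval(seqid, ge - 150, ge, "+")
                inner_intron = (gs + 150, ge - 150)
            else:
                mid = gs + glen // 2
                ex1 = GenomicInterval(seqid, gs, mid - 50, "+")
                ex2 = GenomicInterval(seqid, mid + 50, ge, "+")
                inner_intron = None
            strand = "+" if overlap_bp > 0 else rng.choice(["+", "-"])
            if strand == "-":
                gene = GeneModel(nid, GenomicInterval(seqid, gs, ge, "-"),
                                 (Transcript(f"{nid}.t1", (
                                     GenomicInterval(seqid, ex1.start, ex1.end, "-"),
                                     GenomicInterval(seqid, ex2.start, ex2.end, "-"),
                                 )),))
            else:
                gene = GeneModel(nid, GenomicInterval(seqid, gs, ge, "+"),
                                 (Transcript(f"{nid}.t1", (ex1, ex2)),))
            genes.append(gene)
            truth_rows.append((host_id, nid, 1, frac))

            if is_carrier and doubly_per_carrier[singly_counter]:
                ii_s, ii_e = inner_intron
                d_cursor = ii_s + 100
                for dk in doubly_per_carrier[singly_counter]:
                    dlen = doubly_gene_length
                    ds, de = d_cursor, d_cursor + dlen
                    if de > ii_e - 100:
                        raise ValidationError(
                            "carrier intron too short for doubly nested gene"
                        )
                    did = f"dni{dk:03d}"
                    dmid = ds + dlen // 2
                    genes.append(GeneModel(
                        did, GenomicInterval(seqid, ds, de, "+"),
                        (Transcript(f"{did}.t1", (
                            GenomicInterval(seqid, ds, dmid - 20, "+"),
                            GenomicInterval(seqid, dmid + 20, de, "+"),
                        )),),
                    ))
                    truth_rows.append((nid, did, 2, 0.0))
                    d_cursor = de + 100
            inner_cursor = max(inner_cursor, ge) + margin
            singly_counter += 1
        cursor = he + gap_between_hosts

    ann = Annotation(
        genes=genes,
        seq_lengths={seqid: cursor + 1_000},
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["host_gene_id", "nested_gene_id", "depth", "overlap_fraction"],
    )
    return ann, truth


# ---------------------------------------------------------------------------
# Ortholog tables
# ---------------------------------------------------------------------------

Rearrangement = tuple[str, int, int]  # kind, first index, last index (incl.)


def _single_exon_gene(gene_id: str, seqid: str, start: int, length: int,
                      strand: str = "+") -> GeneModel:
    iv = GenomicInterval(seqid, start, start + length, strand)
    return GeneModel(gene_id, iv, (Transcript(f"{gene_id}.t1", (iv,)),))


def simulate_ortholog_tables(
    seed: int,
    n_genes: int,
    rearrangements: Sequence[Rearrangement] = (),
    gene_length: int = 1_000,
    gene_spacing: int = 16_000,
    n_decoys: int = 0,
) -> tuple[Annotation, Annotation, list[HitRecord], list[HitRecord], list[dict]]:
    """Two genomes whose gene orders differ by planted rearrangements,
    plus mutual hit tables and the implied truth blocks.

    Genome B is genome A's gene order transformed by the rearrangements:
    an ``("inversion", i, j)`` reverses genes i..j in place; a
    ``("relocation", i, j)`` moves each of genes i..j to its own separate
    sequence, so relocated genes cannot form blocks. The default
    start-to-start spacing (16 kb) is chosen so that, under a 30-kb gap
    rule, chains can only join genes consecutive on both genomes — which
    makes the construction-implied truth blocks unambiguous. Truth blocks
    (>= 2 genes) are returned as ``{"a_genes", "b_genes", "orientation"}``.
    """
    rng = np.random.default_rng(seed)
    spans = sorted((int(i), int(j), kind) for kind, i, j in rearrangements)
    last = -1
    for i, j, kind in spans:
        if not (0 <= i <= j < n_genes):
            raise ValidationError(f"rearrangement span ({i}, {j}) outside "
                                  f"gene range 0..{n_genes - 1}")
        if i <= last:
            raise ValidationError("rearrangement spans overlap")
        if kind not in ("inversion", "relocation"):
            raise ValidationError(f"unknown rearrangement kind {kind!r}")
        last = j

    a_ids = [f"ga{i:04d}" for i in range(n_genes)]
    b_ids = [f"gb{i:04d}" for i in range(n_genes)]
    genes_a = [
        _single_exon_gene(a_ids[i], "A_chr1", 1_000 + i * gene_spacing,
                          gene_length)
        for i in range(n_genes)
    ]

    # build B order and truth segments
    order: list[int] = []
    relocated: list[int] = []
    segments: list[tuple[list[int], str]] = []
    cursor = 0
    for i, j, kind in spans:
        if cursor < i:
            segments.append((list(range(cursor, i)), "forward"))
            order.extend(range(cursor, i))
        if kind == "inversion":
            segments.append((list(range(i, j + 1)), "reverse"))
            order.extend(range(j, i - 1, -1))
        else:
            relocated.extend(range(i, j + 1))
        cursor = j + 1
    if cursor < n_genes:
        segments.append((list(range(cursor, n_genes)), "forward"))
        order.extend(range(cursor, n_genes))

    genes_b = [
        _single_exon_gene(b_ids[orig], "B_chr1", 1_000 + k * gene_spacing,
                          gene_length,
                          "-" if _inverted(orig, spans) else "+")
        for k, orig in enumerate(order)
    ]
    for r, orig in enumerate(relocated):
        genes_b.append(
            _single_exon_gene(b_ids[orig], f"B_reloc{r}", 1_000, gene_length)
        )

    ann_a = Annotation(
        genes=genes_a,
        seq_lengths={"A_chr1": 2_000 + n_genes * gene_spacing},
    )
    b_lengths = {"B_chr1": 2_000 + max(len(order), 1) * gene_spacing}
    for r in range(len(relocated)):
        b_lengths[f"B_reloc{r}"] = 10_000
    ann_b = Annotation(genes=genes_b, seq_lengths=b_lengths)

    hits_ab = [HitRecord(a_ids[i], b_ids[i], 95.0, 500.0, 1e-100)
               for i in range(n_genes)]
    hits_ba = [HitRecord(b_ids[i], a_ids[i], 95.0, 500.0, 1e-100)
               for i in range(n_genes)]
    for _ in range(n_decoys):
        qi = int(rng.integers(n_genes))
        si = int(rng.integers(n_genes))
        hits_ab.append(HitRecord(a_ids[qi], b_ids[si], 40.0, 50.0, 1e-5))
        hits_ba.append(HitRecord(b_ids[si], a_ids[qi], 40.0, 50.0, 1e-5))

    truth_blocks = [
        {
            "a_genes": [a_ids[i] for i in seg],
            "b_genes": [b_ids[i] for i in seg],
            "orientation": orient,
        }
        for seg, orient in segments
        if len(seg) >= 2
    ]
    return ann_a, ann_b, hits_ab, hits_ba, truth_blocks


def _inverted(idx: int, spans: list[tuple[int, int, str]]) -> bool:
    return any(i <= idx <= j and kind == "inversion" for i, j, kind in spans)


# ---------------------------------------------------------------------------
# Leader insertions
# ---------------------------------------------------------------------------

def simulate_leader_sequences(
    seed: int,
    length: int,
    n_insertions: int,
    divergence: float = 0.0,
    leader: str = DEFAULT_LEADER,
    seqid: str = "lchr1",
    max_attempts_factor: int = 200,
    interior_margin: int = 0,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Plant mutated leader copies into uniform random background sequence.

    Each copy is independently mutated at ceil(divergence * |leader|)
    distinct positions (substitutions to a different base), placed at a
    non-overlapping uniform random locus, on a random strand. With
    ``interior_margin`` > 0 the mutated positions avoid the first and last
    ``interior_margin`` bases of the motif — substitutions at the motif
    edges leave a shorter, still-high-identity window that a windowed
    scanner rightly accepts, so threshold experiments plant interior
    mutations. Returns the sequence dict and a truth table
    (start, end, strand, n_mutations, identity).
    """
    if not (0 <= divergence <= 0.3):
        raise ValidationError("divergence must lie in [0, 0.3]")
    if n_insertions < 0:
        raise ValidationError("n_insertions must be >= 0")
    rng = np.random.default_rng(seed)
    m = len(leader)
    if n_insertions * m > length:
        raise ValidationError("insertions cannot be placed without overlap")
    seq = _random_sequence(rng, length)
    n_mut = math.ceil(divergence * m)
    mut_lo, mut_hi = interior_margin, m - interior_margin
    if n_mut > mut_hi - mut_lo:
        raise ValidationError("interior_margin leaves too few mutable "
                              "positions")

    placed: list[tuple[int, int]] = []
    rows = []
    attempts = 0
    max_attempts = max_attempts_factor * max(n_insertions, 1)
    while len(placed) < n_insertions:
        if attempts > max_attempts:
            raise ValidationError("insertions cannot be placed without overlap")
        attempts += 1
        s = int(rng.integers(0, length - m + 1))
        if any(s < e and ps < s + m for ps, e in placed):
            continue
        copy = list(leader)
        mut_pos = mut_lo + rng.choice(mut_hi - mut_lo, size=n_mut,
                                      replace=False)
        for p in mut_pos:
            base = copy[p]
            copy[p] = "ACGT"[("ACGT".index(base)
                              + int(rng.integers(1, 4))) % 4]
        copy_str = "".join(copy)
        strand = "+" if rng.random() < 0.5 else "-"
        planted = copy_str if strand == "+" else revcomp(copy_str)
        seq[s:s + m] = np.frombuffer(planted.encode(), dtype="S1")
        placed.append((s, s + m))
        rows.append((s, s + m, strand, n_mut, (m - n_mut) / m))
    truth = pd.DataFrame(
        rows, columns=["start", "end", "strand", "n_mutations", "identity"]
    ).sort_values("start").reset_index(drop=True)
    return {seqid: seq.tobytes().decode()}, truth


# ---------------------------------------------------------------------------
# TAD landscape
# ---------------------------------------------------------------------------

OffsetSpec = Union[int, Sequence[int], tuple]


def simulate_tad_landscape(
    seed: int,
    chrom_sizes: dict[str, int],
    n_tads: int,
    tad_length: Union[int, Sequence[int]] = 60_000,
    boundary_offset: OffsetSpec = 0,
    gene_length: int = 2_000,
    gene_period: int = 10_000,
) -> tuple[list[GenomicInterval], Annotation, dict]:
    """A gene-dense landscape with TAD start boundaries planted at
    controlled offsets from gene ends.

    Genes tile every chromosome with period ``gene_period``; each TAD is
    anchored so its start boundary sits ``offset`` bp downstream of a gene
    end. ``boundary_offset`` may be a constant, a sequence of length
    ``n_tads``, or ``("uniform", lo, hi)``. The truth median is the median
    of the sampled offsets.
    """
    rng = np.random.default_rng(seed)
    intergenic = gene_period - gene_length
    if intergenic <= 0:
        raise ValidationError("gene_period must exceed gene_length")

    genes: list[GeneModel] = []
    anchor_pool: list[tuple[str, int]] = []  # (seqid, gene end)
    for seqid, size in sorted(chrom_sizes.items()):
        n = (size - gene_period) // gene_period
        for i in range(n):
            s = 1_000 + i * gene_period
            g = _single_exon_gene(f"{seqid}_g{i:05d}", seqid, s, gene_length)
            genes.append(g)
            anchor_pool.append((seqid, s + gene_length))
    ann = Annotation(genes=genes, seq_lengths=dict(chrom_sizes))

    if isinstance(tad_length, int):
        lengths = np.full(n_tads, tad_length, dtype=np.int64)
    else:
        lengths = np.asarray(tad_length, dtype=np.int64)
        if len(lengths) != n_tads:
            raise ValidationError("tad_length sequence must have n_tads items")

    if isinstance(boundary_offset, tuple) and boundary_offset \
            and boundary_offset[0] == "uniform":
        _tag, lo, hi = boundary_offset
        offsets = rng.integers(int(lo), int(hi) + 1, size=n_tads)
    elif isinstance(boundary_offset, int):
        offsets = np.full(n_tads, boundary_offset, dtype=np.int64)
    else:
        offsets = np.asarray(boundary_offset, dtype=np.int64)
        if len(offsets) != n_tads:
            raise ValidationError("boundary_offset sequence must have "
                                  "n_tads items")
    if (offsets < 0).any():
        raise ValidationError("offsets must be >= 0")
    if (offsets > intergenic).any():
        raise ValidationError(
            f"offset exceeds intergenic space ({intergenic} bp)"
        )

    anchor_idx = rng.choice(len(anchor_pool), size=n_tads,
                            replace=n_tads > len(anchor_pool))
    tads: list[GenomicInterval] = []
    for k in range(n_tads):
        seqid, gene_end = anchor_pool[int(anchor_idx[k])]
        start = gene_end + int(offsets[k])
        end = start + int(lengths[k])
        if end > chrom_sizes[seqid]:
            # deterministic fallback: re-anchor to the earliest gene that fits
            placed = False
            for aseq, aend in anchor_pool:
                cand_end = aend + int(offsets[k]) + int(lengths[k])
                if cand_end <= chrom_sizes[aseq]:
                    seqid, start = aseq, aend + int(offsets[k])
                    end = cand_end
                    placed = True
                    break
            if not placed:
                raise ValidationError("TAD does not fit in any chromosome")
        tads.append(GenomicInterval(seqid, start, end))
    truth = {
        "offsets": offsets.tolist(),
        "median_offset": float(np.median(offsets)) if n_tads else float("nan"),
    }
    return tads, ann, truth
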