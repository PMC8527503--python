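"""Reciprocal best hits, collinear block chaining, and macrosynteny.

Orthologs between two genomes are approximated by reciprocal best hits
(RBH) from mutual all-vs-all protein searches. Runs of orthologs in
conserved order — forward or inverted — are chained into microsynteny
blocks under three limits: a minimum number of genes per block, a maximum
number of intervening genes between consecutive members, and a maximum
genomic distance (start-to-start) to the next member. The macrosynteny
summary assigns each sequence of genome A its plurality partner sequence
in genome B and emits Oxford dot-plot coordinates.

Chaining semantics: a chain is a subsequence of ortholog pairs strictly
increasing in A gene order and strictly monotone in B gene order
(orientation fixed by the first step), where every consecutive step obeys
the intervening-gene and distance limits on BOTH genomes. Blocks are
extracted longest-first; among equally long chains the one whose A-side
ordinal tuple is lexicographically smallest wins (forward preferred on an
exact tie), and the pairs of a chosen block cannot be reused.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .model import Annotation, HitRecord, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GenePos:
    gene_id: str
    seqid: str
    start: int
    end: int
    ordinal: int  # rank by start within its sequence


@dataclass(frozen=True)
class OrthologPair:
    gene_a: GenePos
    gene_b: GenePos
    bitscore: float


@dataclass(frozen=True)
class SyntenyConfig:
    min_block: int = 3
    max_intervening: int = 5
    max_gap: int = 30_000

    def __post_init__(self) -> None:
        if self.min_block < 2:
            raise ValidationError("min_block must be >= 2")
        if self.max_intervening < 0:
            raise ValidationError("max_intervening must be >= 0")
        if self.max_gap <= 0:
            raise ValidationError("max_gap must be > 0")


@dataclass(frozen=True)
class SyntenyBlock:
    pairs: tuple[OrthologPair, ...]
    orientation: str  # forward | reverse

    @property
    def n_genes(self) -> int:
        return len(self.pairs)

    @property
    def span_a(self) -> int:
        return (max(p.gene_a.end for p in self.pairs)
                - min(p.gene_a.start for p in self.pairs))

    @property
    def span_b(self) -> int:
        return (max(p.gene_b.end for p in self.pairs)
                - min(p.gene_b.start for p in self.pairs))

    @property
    def a_gene_ids(self) -> tuple[str, ...]:
        return tuple(p.gene_a.gene_id for p in self.pairs)

    @property
    def b_gene_ids(self) -> tuple[str, ...]:
        return tuple(p.gene_b.gene_id for p in self.pairs)


# ---------------------------------------------------------------------------
# Reciprocal best hits
# ---------------------------------------------------------------------------

def _dedupe(hits: Sequence[HitRecord]) -> list[HitRecord]:
    best: dict[tuple[str, str], HitRecord] = {}
    n_dup = 0
    for h in hits:
        key = (h.query_id, h.subject_id)
        prev = best.get(key)
        if prev is None:
            best[key] = h
        else:
            n_dup += 1
            if h.bitscore > prev.bitscore:
                best[key] = h
    if n_dup:
        logger.info("dropped %d duplicate (query, subject) hit rows", n_dup)
    return list(best.values())


def _best_per_query(hits: Sequence[HitRecord]) -> dict[str, str]:
    """Highest bitscore wins; ties broken by lower e-value, then
    lexicographically smaller subject id."""
    best: dict[str, HitRecord] = {}
    for h in hits:
        prev = best.get(h.query_id)
        if prev is None or (-h.bitscore, h.evalue, h.subject_id) < \
                (-prev.bitscore, prev.evalue, prev.subject_id):
            best[h.query_id] = h
    return {q: h.subject_id for q, h in best.items()}


def reciprocal_best_hits(
    hits_ab: Sequence[HitRecord],
    hits_ba: Sequence[HitRecord],
) -> list[tuple[str, str, float]]:
    """Mutual-best pairs (a_id, b_id, bitscore of the a->b best hit)."""
    if not hits_ab or not hits_ba:
        raise ValidationError("hit tables must be non-empty")
    ab = _dedupe(hits_ab)
    best_ab = _best_per_query(ab)
    best_ba = _best_per_query(_dedupe(hits_ba))
    score_ab = {(h.query_id, h.subject_id): h.bitscore for h in ab}
    out = []
    for a, b in sorted(best_ab.items()):
        if best_ba.get(b) == a:
            out.append((a, b, score_ab[(a, b)]))
    return out


# ---------------------------------------------------------------------------
# Gene ordinals
# ---------------------------------------------------------------------------

def gene_positions(annotation: Annotation) -> dict[str, GenePos]:
    """Gene id -> position with per-sequence ordinal (rank by start,
    ties by end then id)."""
    out: dict[str, GenePos] = {}
    for seqid, genes in annotation.genes_by_seqid().items():
        for i, g in enumerate(genes):
            out[g.gene_id] = GenePos(
                g.gene_id, seqid, g.interval.start, g.interval.end, i
            )
    return out


def build_pairs(
    rbh: Sequence[tuple[str, str, float]],
    ann_a: Annotation,
    ann_b: Annotation,
) -> list[OrthologPair]:
    pos_a = gene_positions(ann_a)
    pos_b = gene_positions(ann_b)
    out = []
    for a, b, score in rbh:
        if a not in pos_a:
            raise ValidationError(f"gene {a!r} absent from annotation A")
        if b not in pos_b:
            raise ValidationError(f"gene {b!r} absent from annotation B")
        out.append(OrthologPair(pos_a[a], pos_b[b], score))
    seen_a = [p.gene_a.gene_id for p in out]
    seen_b = [p.gene_b.gene_id for p in out]
    if len(set(seen_a)) != len(seen_a) or len(set(seen_b)) != len(seen_b):
        raise ValidationError("ortholog pairs are not one-to-one")
    return out


# ---------------------------------------------------------------------------
# Collinear chaining
# ---------------------------------------------------------------------------

def _step_ok(p: OrthologPair, q: OrthologPair, cfg: SyntenyConfig) -> int | None:
    """Direction (+1/-1) of a valid chain step p -> q, else None."""
    a1, a2, b1, b2 = p.gene_a, q.gene_a, p.gene_b, q.gene_b
    if a1.seqid != a2.seqid or b1.seqid != b2.seqid:
        return None
    if a2.ordinal <= a1.ordinal or b1.ordinal == b2.ordinal:
        return None
    if a2.ordinal - a1.ordinal - 1 > cfg.max_intervening:
        return None
    if abs(b2.ordinal - b1.ordinal) - 1 > cfg.max_intervening:
        return None
    if abs(a2.start - a1.start) > cfg.max_gap:
        return None
    if abs(b2.start - b1.start) > cfg.max_gap:
        return None
    return 1 if b2.ordinal > b1.ordinal else -1


def _best_chain(pairs: list[OrthologPair], cfg: SyntenyConfig
                ) -> tuple[list[int], int] | None:
    """Longest valid chain over the given pairs.

    Returns (indices into ``pairs``, direction). Among maximal-length
    chains, picks the one with the lexicographically smallest sequence of
    A-side positions, preferring forward on a tie."""
    n = len(pairs)
    if n == 0:
        return None
    order = sorted(range(n), key=lambda i: (pairs[i].gene_a.seqid,
                                            pairs[i].gene_a.ordinal))
    # F[i][s] = longest chain starting at order-position i with direction s
    F = [{1: 1, -1: 1} for _ in range(n)]
    edges: list[dict[int, list[int]]] = [{1: [], -1: []} for _ in range(n)]
    for ii in range(n - 1, -1, -1):
        p = pairs[order[ii]]
        for jj in range(ii + 1, n):
            q = pairs[order[jj]]
            if q.gene_a.seqid != p.gene_a.seqid:
                break
            if q.gene_a.ordinal - p.gene_a.ordinal - 1 > cfg.max_intervening:
                break
            s = _step_ok(p, q, cfg)
            if s is None:
                continue
            edges[ii][s].append(jj)
            F[ii][s] = max(F[ii][s], 1 + F[jj][s])
    best_len = max(max(f.values()) for f in F)
    if best_len < 2:
        return None
    # greedy front-to-back reconstruction of the lexicographically smallest
    # maximal chain (forward preferred on ties)
    start = min(
        (ii, -s) for ii in range(n) for s in (1, -1) if F[ii][s] == best_len
    )
    ii, s = start[0], -start[1]
    chain = [order[ii]]
    remaining = best_len - 1
    while remaining:
        nxt = min(jj for jj in edges[ii][s] if F[jj][s] == remaining)
        chain.append(order[nxt])
        ii = nxt
        remaining -= 1
    return chain, s


def collinear_blocks(
    pairs: Sequence[OrthologPair],
    config: SyntenyConfig | None = None,
) -> list[SyntenyBlock]:
    """Chain ortholog pairs into microsynteny blocks.

    Blocks are extracted longest-first until no chain reaches
    ``min_block``; each pair belongs to at most one block. See the module
    docstring for the full chaining semantics.
    """
    cfg = config or SyntenyConfig()
    pool = list(pairs)
    blocks: list[SyntenyBlock] = []
    while True:
        found = _best_chain(pool, cfg)
        if found is None:
            break
        chain_idx, s = found
        if len(chain_idx) < cfg.min_block:
            break
        chain_pairs = tuple(pool[i] for i in chain_idx)
        blocks.append(SyntenyBlock(
            pairs=chain_pairs,
            orientation="forward" if s == 1 else "reverse",
        ))
        drop = set(chain_idx)
        pool = [p for i, p in enumerate(pool) if i not in drop]
    blocks.sort(key=lambda b: (b.pairs[0].gene_a.seqid,
                               b.pairs[0].gene_a.ordinal))
    return blocks


def blocks_from_annotations(
    rbh: Sequence[tuple[str, str, float]],
    ann_a: Annotation,
    ann_b: Annotation,
    config: SyntenyConfig | None = None,
) -> list[SyntenyBlock]:
    """Convenience: attach positions then chain."""
    return collinear_blocks(build_pairs(rbh, ann_a, ann_b), config)


# ---------------------------------------------------------------------------
# Macrosynteny
# ---------------------------------------------------------------------------

def macrosynteny_summary(
    pairs: Sequence[OrthologPair],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-A-sequence plurality partner and Oxford dot-plot coordinates.

    Partner table columns: a_seqid, partner_b_seqid, n_pairs (to the
    partner), n_total, fraction, ambiguous (plurality tie, resolved to
    the lexicographically smallest B sequence). Dot-plot table columns:
    a_seqid, a_pos, b_seqid, b_pos (gene start coordinates).
    """
    if not pairs:
        raise ValidationError("no ortholog pairs")
    dots = pd.DataFrame(
        [
            {
                "a_seqid": p.gene_a.seqid, "a_pos": p.gene_a.start,
                "b_seqid": p.gene_b.seqid, "b_pos": p.gene_b.start,
            }
            for p in pairs
        ]
    ).sort_values(["a_seqid", "a_pos"]).reset_index(drop=True)
    rows = []
    for a_seqid, sub in dots.groupby("a_seqid"):
        counts = sub["b_seqid"].value_counts()
        top = counts.max()
        winners = sorted(counts[counts == top].index)
        rows.append({
            "a_seqid": a_seqid,
            "partner_b_seqid": winners[0],
            "n_pairs": int(top),
            "n_total": int(len(sub)),
            "fraction": float(top / len(sub)),
            "ambiguous": len(winners) > 1,
        })
    partners = pd.DataFrame(rows).sort_values("a_seqid").reset_index(drop=True)
    return partners, dots
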