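"""Shared builders for compact gene models used across the suite."""
from __future__ import annotations

import numpy as np
import pytest

from ctenokit.model import Annotation, GeneModel, GenomicInterval, Transcript


def make_gene(gene_id: str, seqid: str, exon_coords: list[tuple[int, int]],
              strand: str = "+", n_transcripts: int = 1) -> GeneModel:
    """A gene whose (single) transcript has the given exon coordinates."""
    exons = tuple(GenomicInterval(seqid, s, e, strand) for s, e in exon_coords)
    txs = tuple(
        Transcript(f"{gene_id}.t{i + 1}", exons) for i in range(n_transcripts)
    )
    start, end = exon_coords[0][0], exon_coords[-1][1]
    return GeneModel(gene_id, GenomicInterval(seqid, start, end, strand), txs)


def make_annotation(genes: list[GeneModel],
                    seq_lengths: dict[str, int] | None = None) -> Annotation:
    if seq_lengths is None:
        seq_lengths = {}
        for g in genes:
            seq_lengths[g.seqid] = max(seq_lengths.get(g.seqid, 0),
                                       g.interval.end + 1000)
    return Annotation(genes=genes, seq_lengths=seq_lengths)


def random_annotation(rng: np.random.Generator, n_genes: int,
                      seqids: tuple[str, ...] = ("rchr1", "rchr2"),
                      chrom_len: int = 200_000) -> Annotation:
    """Random small annotation with overlapping genes and varied exon
    structures — adversarial input for containment detectors."""
    genes = []
    for i in range(n_genes):
        seqid = seqids[int(rng.integers(len(seqids)))]
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(1, 5))
        start = int(rng.integers(0, chrom_len - 20_000))
        coords = []
        pos = start
        for _ in range(n_exons):
            elen = int(rng.integers(50, 2_000))
            coords.append((pos, pos + elen))
            pos += elen + int(rng.integers(50, 5_000))
        genes.append(make_gene(f"rg{i:03d}", seqid, coords, strand))
    return make_annotation(genes, {s: chrom_len + 25_000 for s in seqids})


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_917)
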