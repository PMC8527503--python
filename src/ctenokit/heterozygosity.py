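"""Depth-conditioned heterozygosity estimation from read pileups.

In a composite (both-haplotypes-collapsed) diploid assembly, sites where
reads from both haplotypes map cluster at the modal mapping depth D*,
while collapsed single-haplotype sites sit near D*/2. Restricting to
sites at exactly D* and classifying them by allele balance gives a
heterozygosity estimate that is robust to assembly errors and to variant
callers: a site is called heterozygous when roughly half its reads match
the reference allele.

The allele-balance band (default [0.30, 0.70]) operationalizes "half the
reads"; exact halves are impossible at odd depths. Sites at D* whose
reference fraction falls outside both the band and the homozygous zones
stay in the denominator — the estimate divides by all sites at that depth.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Union

import numpy as np
import pandas as pd

from .model import Annotation, PileupSite, ValidationError

PILEUP_COLUMNS = ["seqid", "pos", "depth", "ref_count", "snp_alt_count",
                  "indel_alt_count"]

SitesLike = Union[pd.DataFrame, Iterable[PileupSite]]

REGION_EXONIC = "exonic"
REGION_INTRONIC = "intronic"
REGION_INTERGENIC = "intergenic"
REGION_GENOME = "genome"


def as_pileup_frame(sites: SitesLike) -> pd.DataFrame:
    """Normalize a PileupSite stream or DataFrame to a canonical frame."""
    if isinstance(sites, pd.DataFrame):
        missing = [c for c in PILEUP_COLUMNS if c not in sites.columns]
        if missing:
            raise ValidationError(f"pileup frame missing columns {missing}")
        return sites
    return pd.DataFrame(list(sites), columns=PILEUP_COLUMNS)


@dataclass(frozen=True)
class DepthHistogram:
    """Number of sites observed at each mapping depth, and the mode D*."""

    counts: dict[int, int]
    modal_depth: int

    def total(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class HetBandConfig:
    """Allele-balance band and depth window for site classification.

    ``lower``/``upper`` bound the reference-allele fraction of a
    heterozygous call; ``depth_window`` widens the depth restriction to
    D* +/- window (0 = exactly D*).
    """

    lower: float = 0.30
    upper: float = 0.70
    depth_window: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.lower < 0.5 < self.upper < 1):
            raise ValidationError(
                f"band must satisfy 0 < lower < 0.5 < upper < 1, "
                f"got [{self.lower}, {self.upper}]"
            )
        if self.depth_window < 0:
            raise ValidationError("depth_window must be >= 0")


@dataclass(frozen=True)
class HetEstimate:
    depth_used: int
    variant_class: str  # snp | indel | combined
    region_class: str   # genome | exonic | intronic | intergenic
    seqid: str          # seqid or "all"
    sites_total: int
    sites_het: int

    @property
    def heterozygosity(self) -> float:
        return self.sites_het / self.sites_total

    def __post_init__(self) -> None:
        if not (0 <= self.sites_het <= self.sites_total):
            raise ValidationError("sites_het must lie in [0, sites_total]")


@dataclass(frozen=True)
class AlleleBalance2D:
    """2D tally of (depth, ref_count) over all sites."""

    counts: dict[tuple[int, int], int] = field(default_factory=dict)

    def total(self) -> int:
        return sum(self.counts.values())

    def depth_marginal(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for (d, _r), n in self.counts.items():
            out[d] = out.get(d, 0) + n
        return out


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def build_depth_histogram(sites: SitesLike) -> DepthHistogram:
    """Tally sites per depth; D* is the smallest depth >= 1 attaining the
    maximum count (deterministic tie-break towards lower depth)."""
    df = as_pileup_frame(sites)
    if df.empty:
        raise ValidationError("cannot build a depth histogram from zero sites")
    vc = df["depth"].value_counts()
    counts = {int(k): int(v) for k, v in vc.items()}
    positive = {d: n for d, n in counts.items() if d >= 1}
    if not positive:
        raise ValidationError("no sites with depth >= 1")
    best = max(positive.values())
    modal = min(d for d, n in positive.items() if n == best)
    return DepthHistogram(counts=counts, modal_depth=modal)


CLASS_HOM_REF = "hom_ref"
CLASS_HOM_ALT = "hom_alt"
CLASS_HET_SNP = "het_snp"
CLASS_HET_INDEL = "het_indel"
CLASS_OTHER = "other"


def classify_site(site: PileupSite, band: HetBandConfig | None = None) -> str:
    """Classify one site by its reference-allele balance f = ref/depth.

    f >= upper -> hom_ref; f <= 1-upper -> hom_alt; lower <= f <= upper ->
    heterozygous, subtyped het_indel when indel-supporting reads outnumber
    substitution-supporting reads (ties -> het_snp); anything else -> other.
    """
    band = band or HetBandConfig()
    if site.depth < 1:
        raise ValidationError(f"{site.seqid}:{site.pos}: depth must be >= 1")
    f = site.ref_count / site.depth
    if f >= band.upper:
        return CLASS_HOM_REF
    if f <= 1 - band.upper:
        return CLASS_HOM_ALT
    if band.lower <= f <= band.upper:
        if site.indel_alt_count > site.snp_alt_count:
            return CLASS_HET_INDEL
        return CLASS_HET_SNP
    return CLASS_OTHER


def classify_frame(df: pd.DataFrame, band: HetBandConfig | None = None) -> pd.Series:
    """Vectorized :func:`classify_site` over a pileup frame (depth >= 1)."""
    band = band or HetBandConfig()
    depth = df["depth"].to_numpy()
    if (depth < 1).any():
        raise ValidationError("classify_frame requires depth >= 1 at all sites")
    f = df["ref_count"].to_numpy() / depth
    indel_major = df["indel_alt_count"].to_numpy() > df["snp_alt_count"].to_numpy()
    out = np.full(len(df), CLASS_OTHER, dtype=object)
    het = (f >= band.lower) & (f <= band.upper)
    out[het & ~indel_major] = CLASS_HET_SNP
    out[het & indel_major] = CLASS_HET_INDEL
    out[f >= band.upper] = CLASS_HOM_REF
    out[f <= 1 - band.upper] = CLASS_HOM_ALT
    return pd.Series(out, index=df.index)


def _depth_mask(df: pd.DataFrame, modal_depth: int, band: HetBandConfig) -> pd.Series:
    return (df["depth"] - modal_depth).abs() <= band.depth_window


def _het_mask(classes: pd.Series, variant_class: str) -> pd.Series:
    if variant_class == "snp":
        return classes == CLASS_HET_SNP
    if variant_class == "indel":
        return classes == CLASS_HET_INDEL
    if variant_class == "combined":
        return classes.isin([CLASS_HET_SNP, CLASS_HET_INDEL])
    raise ValidationError(f"unknown variant class {variant_class!r}")


def estimate_heterozygosity(
    sites: SitesLike,
    modal_depth: int,
    band: HetBandConfig | None = None,
    variant_class: str = "combined",
    region_class: str = REGION_GENOME,
    seqid: str = "all",
) -> HetEstimate:
    """Heterozygous fraction among all sites at the modal depth.

    Denominator: sites with |depth - D*| <= depth_window. Numerator: those
    classified het_snp (class "snp"), het_indel ("indel"), or either
    ("combined")."""
    band = band or HetBandConfig()
    if modal_depth < 1:
        raise ValidationError("modal depth must be >= 1")
    df = as_pileup_frame(sites)
    at_mode = df[_depth_mask(df, modal_depth, band)]
    if at_mode.empty:
        raise ValidationError(f"no sites at depth {modal_depth}")
    classes = classify_frame(at_mode, band)
    n_het = int(_het_mask(classes, variant_class).sum())
    return HetEstimate(
        depth_used=modal_depth,
        variant_class=variant_class,
        region_class=region_class,
        seqid=seqid,
        sites_total=len(at_mode),
        sites_het=n_het,
    )


def _region_arrays(annotation: Annotation, seqid: str) -> tuple[np.ndarray, np.ndarray]:
    """Merged exon union and merged gene-span union for one sequence, as
    (starts, ends) arrays usable with searchsorted membership tests."""
    exons, spans = [], []
    for g in annotation.genes:
        if g.seqid != seqid:
            continue
        spans.append((g.interval.start, g.interval.end))
        for t in g.transcripts:
            exons.extend((e.start, e.end) for e in t.exons)
    return _merge(exons), _merge(spans)


def _merge(ivs: list[tuple[int, int]]) -> np.ndarray:
    if not ivs:
        return np.empty((0, 2), dtype=np.int64)
    ivs.sort()
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged, dtype=np.int64)


def _membership(pos: np.ndarray, merged: np.ndarray) -> np.ndarray:
    """Boolean: does each position fall inside any merged interval."""
    if merged.size == 0:
        return np.zeros(len(pos), dtype=bool)
    idx = np.searchsorted(merged[:, 0], pos, side="right") - 1
    ok = idx >= 0
    inside = np.zeros(len(pos), dtype=bool)
    inside[ok] = pos[ok] < merged[idx[ok], 1]
    return inside


def assign_region_classes(df: pd.DataFrame, annotation: Annotation) -> pd.Series:
    """Assign exactly one region class per site.

    Precedence exonic > intronic > intergenic: a base exonic in any
    transcript of any gene is exonic; a base inside any gene span but not
    exonic is intronic; the rest is intergenic."""
    out = pd.Series(REGION_INTERGENIC, index=df.index, dtype=object)
    for seqid, sub in df.groupby("seqid", sort=False):
        if seqid not in annotation.seq_lengths:
            raise ValidationError(
                f"pileup sequence {seqid!r} absent from annotation lengths"
            )
        exon_u, span_u = _region_arrays(annotation, str(seqid))
        pos = sub["pos"].to_numpy()
        in_exon = _membership(pos, exon_u)
        in_span = _membership(pos, span_u)
        vals = np.full(len(sub), REGION_INTERGENIC, dtype=object)
        vals[in_span & ~in_exon] = REGION_INTRONIC
        vals[in_exon] = REGION_EXONIC
        out.loc[sub.index] = vals
    return out


def stratified_heterozygosity(
    sites: SitesLike,
    annotation: Annotation,
    modal_depth: int,
    band: HetBandConfig | None = None,
) -> list[HetEstimate]:
    """Per-(seqid, region, variant-class) heterozygosity at the modal depth.

    Emits an estimate for every stratum with >= 1 site at D*, plus "all"
    aggregates per region and a ("all", "genome") overall row."""
    band = band or HetBandConfig()
    df = as_pileup_frame(sites)
    at_mode = df[_depth_mask(df, modal_depth, band)].copy()
    if at_mode.empty:
        raise ValidationError(f"no sites at depth {modal_depth}")
    at_mode["region"] = assign_region_classes(at_mode, annotation)
    at_mode["cls"] = classify_frame(at_mode, band)

    out: list[HetEstimate] = []

    def emit(sub: pd.DataFrame, region: str, seqid: str) -> None:
        if sub.empty:
            return
        for vc in ("snp", "indel", "combined"):
            out.append(
                HetEstimate(
                    depth_used=modal_depth, variant_class=vc,
                    region_class=region, seqid=seqid,
                    sites_total=len(sub),
                    sites_het=int(_het_mask(sub["cls"], vc).sum()),
                )
            )

    for (seqid, region), sub in at_mode.groupby(["seqid", "region"], sort=True):
        emit(sub, str(region), str(seqid))
    for region, sub in at_mode.groupby("region", sort=True):
        emit(sub, str(region), "all")
    emit(at_mode, REGION_GENOME, "all")
    return out


def build_allele_balance_2d(sites: SitesLike) -> AlleleBalance2D:
    """Exact 2D tally of (depth, ref_count); its depth marginal equals the
    depth histogram."""
    df = as_pileup_frame(sites)
    if df.empty:
        raise ValidationError("cannot tally zero sites")
    grouped = df.groupby(["depth", "ref_count"]).size()
    return AlleleBalance2D(
        counts={(int(d), int(r)): int(n) for (d, r), n in grouped.items()}
    )


def estimates_to_frame(estimates: list[HetEstimate]) -> pd.DataFrame:
    rows = [
        {
            "seqid": e.seqid, "region": e.region_class,
            "variant_class": e.variant_class, "depth": e.depth_used,
            "sites_total": e.sites_total, "sites_het": e.sites_het,
            "heterozygosity": e.heterozygosity,
        }
        for e in estimates
    ]
    return pd.DataFrame(rows)
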