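"""Small-RNA profiling: size classes, RPM, categories, miRNA families.

sRNA accumulation is quantified per locus and per read-length class
(18-28 nt) and normalized to reads per million of genome-matching 18-28 nt
sRNAs.  Reads are categorized sequentially against genes, miRNAs, TEs,
rRNA and tRNA; miRNA families and sRNA abundance at arbitrary regions
(typically DMRs) are tested for differential accumulation with the same
negative-binomial engine used for mRNA differential expression, with
library totals supplying the size factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .expression import de_test

__all__ = [
    "SRNAProfile",
    "rpm_normalize",
    "size_distribution",
    "categorize",
    "mirna_family_de",
    "crossref_mirna_targets",
    "srna_at_regions",
    "assign_regions_to_loci",
]

SIZE_CLASSES = tuple(range(18, 29))  # 18..28 nt inclusive
#: the analysis window; reads below 16 nt are removed upstream
MIN_READ_LENGTH = 16


@dataclass
class SRNAProfile:
    """Locus x size-class x sample sRNA counts with per-sample library totals.

    ``counts`` carries a (locus, size) MultiIndex and one column per
    sample; ``loci`` holds the locus intervals (chrom/start/end/name,
    half-open).  ``rpm`` is filled by :func:`rpm_normalize`.
    """

    counts: pd.DataFrame
    library_totals: pd.Series
    loci: pd.DataFrame | None = None
    rpm: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self):
        sizes = self.counts.index.get_level_values("size")
        if (sizes < MIN_READ_LENGTH).any():
            raise ValueError("reads below the 16-nt floor must be removed upstream")
        bad = set(sizes) - set(SIZE_CLASSES)
        if bad:
            raise ValueError(f"size classes outside the 18-28 nt window: {sorted(bad)}")


def rpm_normalize(profile: SRNAProfile) -> SRNAProfile:
    """Fill ``profile.rpm`` = counts / library_total x 1e6 per sample.

    Raw counts are preserved.  A zero library total is an error.
    """
    totals = profile.library_totals.reindex(profile.counts.columns)
    if totals.isna().any() or (totals <= 0).any():
        raise ValueError("every sample needs a positive 18-28 nt library total")
    profile.rpm = profile.counts / totals * 1e6
    return profile


def size_distribution(profile: SRNAProfile, groups: dict[str, str]) -> pd.DataFrame:
    """Mean +- SD of per-sample summed RPM per size class and group.

    ``groups`` maps sample id -> group label (e.g. light condition).
    """
    if profile.rpm is None:
        rpm_normalize(profile)
    per_sample = profile.rpm.groupby(level="size").sum()  # size x sample
    rows = []
    for group in sorted(set(groups.values())):
        cols = [s for s, g in groups.items() if g == group and s in per_sample.columns]
        if not cols:
            raise ValueError(f"group {group!r} has no samples in the profile")
        sub = per_sample[cols]
        for size in sub.index:
            rows.append(
                dict(
                    size=int(size),
                    group=group,
                    mean_rpm=float(sub.loc[size].mean()),
                    sd_rpm=float(sub.loc[size].std(ddof=1)) if len(cols) > 1 else 0.0,
                    n=len(cols),
                )
            )
    return pd.DataFrame(rows)


DEFAULT_PRIORITY = ("genes", "miRNAs", "TEs", "rRNA", "tRNA")


def categorize(
    read_assignments: pd.DataFrame,
    priority: tuple[str, ...] = DEFAULT_PRIORITY,
    *,
    independent: bool = False,
) -> pd.DataFrame:
    """Category totals from per-read (or per-read-class) index matches.

    ``read_assignments`` has one boolean column per category plus a
    ``count`` column (collapsed identical reads).  In priority mode each
    read is counted once toward the first category it matches, unmatched
    reads toward ``other``; the counts partition the total.  With
    ``independent=True`` overlapping totals per category are reported
    instead (no ``other`` row, no partition property).
    """
    missing = [c for c in priority if c not in read_assignments.columns]
    if missing:
        raise ValueError(f"read_assignments misses category columns {missing}")
    counts = read_assignments["count"].to_numpy(dtype=float)
    rows = []
    if independent:
        for cat in priority:
            rows.append(dict(category=cat, count=float(counts[read_assignments[cat].to_numpy(bool)].sum())))
    else:
        unassigned = np.ones(len(read_assignments), dtype=bool)
        for cat in priority:
            hit = read_assignments[cat].to_numpy(bool) & unassigned
            rows.append(dict(category=cat, count=float(counts[hit].sum())))
            unassigned &= ~hit
        rows.append(dict(category="other", count=float(counts[unassigned].sum())))
    out = pd.DataFrame(rows)
    total = counts.sum()
    out["fraction"] = out["count"] / total if total > 0 else 0.0
    return out


def _library_size_factors(library_totals: pd.Series, samples) -> pd.Series:
    totals = library_totals.reindex(samples)
    return totals / np.exp(np.log(totals).mean())


def mirna_family_de(
    family_counts: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    contrast: tuple[str, str],
    library_totals: pd.Series,
    *,
    alpha: float = 0.05,
    lfc_min: float = 1.5,
) -> pd.DataFrame:
    """Differential accumulation of miRNA families (counts summed over
    members) using the NB engine with library-total size factors."""
    factors = _library_size_factors(library_totals, family_counts.columns)
    return de_test(
        family_counts,
        sample_sheet,
        contrast,
        alpha=alpha,
        lfc_min=lfc_min,
        factors=factors,
    )


def crossref_mirna_targets(
    family_de: pd.DataFrame,
    fr_degs: pd.Series,
    target_map: pd.DataFrame,
    *,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Cross-reference differential miRNA families with their FR-DEG targets.

    ``fr_degs`` maps gene -> expression direction; ``target_map`` has
    columns ``family`` and ``gene_id``.  For every differential family the
    targets inside the FR-DEG set are listed with both directions and an
    ``inverse`` flag (miRNA up with target down, or vice versa) — the
    signature of miRNA-guided repression.
    """
    rows = []
    de_families = family_de[family_de["status"] != "ns"]
    targets_by_family = target_map.groupby("family")["gene_id"].agg(set)
    for family, res in de_families.iterrows():
        fam_dir = res["status"]
        for gene in sorted(targets_by_family.get(family, set()) & set(fr_degs.index)):
            gene_dir = fr_degs[gene]
            rows.append(
                dict(
                    family=family,
                    family_direction=fam_dir,
                    gene_id=gene,
                    gene_direction=gene_dir,
                    inverse=(fam_dir == "up") != (gene_dir == "up"),
                )
            )
    return pd.DataFrame(rows, columns=["family", "family_direction", "gene_id", "gene_direction", "inverse"])


def assign_regions_to_loci(regions: pd.DataFrame, loci: pd.DataFrame) -> dict[str, list[str]]:
    """Map each region (e.g. a DMR) to the sRNA loci it overlaps by >= 1 bp.

    Both frames need chrom/start/end plus an id column (``dmr_id`` or
    ``name``).  Returns region id -> list of locus names.
    """
    trees: dict[str, IntervalTree] = {}
    for locus in loci.itertuples(index=False):
        trees.setdefault(locus.chrom, IntervalTree()).addi(locus.start, locus.end, locus.name)
    region_id_col = "dmr_id" if "dmr_id" in regions.columns else "name"
    out: dict[str, list[str]] = {}
    for region in regions.itertuples(index=False):
        hits = trees.get(region.chrom, IntervalTree()).overlap(region.start, region.end)
        out[getattr(region, region_id_col)] = sorted(h.data for h in hits)
    return out


def srna_at_regions(
    profile: SRNAProfile,
    regions: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    contrast: tuple[str, str],
    *,
    sizes: tuple[int, ...] = (21, 22, 24),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-region, per-size-class differential sRNA accumulation (FR vs R).

    Region counts are sums over the loci each region overlaps (>= 1 bp).
    Each size class is tested independently with the NB engine
    (library-total size factors) and BH-corrected across regions within
    the size class.  Regions with zero counts everywhere come back ``ns``.
    Direction is up/down where q <= alpha, else ns.
    """
    if profile.loci is None:
        raise ValueError("profile has no locus intervals to overlap regions with")
    mapping = assign_regions_to_loci(regions, profile.loci)
    factors = _library_size_factors(profile.library_totals, profile.counts.columns)
    region_ids = list(mapping)
    frames = []
    for size in sizes:
        sub = profile.counts.xs(size, level="size")
        mat = pd.DataFrame(
            {
                rid: sub.reindex(mapping[rid]).fillna(0).sum(axis=0)
                for rid in region_ids
            }
        ).T
        mat.index.name = "region_id"
        res = de_test(mat.round().astype(int), sample_sheet, contrast, alpha=alpha, factors=factors)
        res = res.rename_axis("region_id").reset_index()
        res.insert(1, "size", size)
        frames.append(res)
    out = pd.concat(frames, ignore_index=True)
    out["direction"] = np.where(
        out["q"] <= alpha, np.where(out["log2fc"] > 0, "up", "down"), "ns"
    )
    return out
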