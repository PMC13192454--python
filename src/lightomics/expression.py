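"""Normalization and differential expression for the light time course.

The experiment contrasts *Cuscuta campestris* shoots under red- (R) and
far-red-enriched (FR) light against untreated shoots (Ctrl), at one and
three days of treatment.  This module provides:

* median-of-ratios size factors (DESeq-style) and TPM normalization;
* a per-gene negative-binomial Wald test on size-factor-normalized counts
  with a moment-based dispersion estimate -- a deliberately simple,
  calibration-tested engine rather than a shrinkage estimator;
* the DEG gates used throughout (FDR <= 0.05 and |log2 FC| >= 1.5);
* Venn partitioning of per-contrast DEG sets and construction of the
  FR-DEG set from cluster direction labels.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import bh_adjust

__all__ = [
    "size_factors",
    "tpm",
    "de_test",
    "venn_partition",
    "define_fr_degs",
    "group_samples",
]

#: gates from the study design: FDR cut-off and minimum |log2 fold change|
DEFAULT_ALPHA = 0.05
DEFAULT_LFC_MIN = 1.5


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factor per sample (column).

    The reference is the gene-wise geometric mean over genes with strictly
    positive counts in every sample; each sample's factor is the median of
    its count/reference ratios over those genes.
    """
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has positive counts in every sample; supply a "
            "pseudo-reference (e.g. add a pseudocount) before computing "
            "size factors"
        )
    logs = np.log(mat[positive])
    ref = logs.mean(axis=1)  # log geometric mean per gene
    factors = np.exp(np.median(logs - ref[:, None], axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per kilobase million; every nonzero column sums to 1e6."""
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every gene needs a positive length in bp")
    rate = counts.div(lengths / 1e3, axis=0)
    colsum = rate.sum(axis=0)
    zero_cols = colsum == 0
    if zero_cols.any():
        warnings.warn(
            f"samples with zero total counts get all-zero TPM columns: "
            f"{list(counts.columns[zero_cols])}",
            stacklevel=2,
        )
        colsum = colsum.replace(0, 1.0)
    return rate.div(colsum, axis=1) * 1e6


def group_samples(sample_sheet: pd.DataFrame, group: str) -> list[str]:
    """Sample ids belonging to a ``condition_timepoint`` group label."""
    labels = sample_sheet["condition"].astype(str) + "_" + sample_sheet["timepoint"].astype(str)
    hits = sample_sheet.loc[labels == group, "sample_id"].tolist()
    if not hits:
        raise ValueError(f"no samples in group {group!r}; known groups: {sorted(set(labels))}")
    return hits


def _moment_dispersion(mat: np.ndarray, floor: float) -> np.ndarray:
    """Method-of-moments NB dispersion per gene from one group's counts."""
    mu = mat.mean(axis=1)
    s2 = mat.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (s2 - mu) / mu**2
    alpha[~np.isfinite(alpha)] = floor
    return np.maximum(alpha, floor)


def de_test(
    counts: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    contrast: tuple[str, str],
    *,
    alpha: float = DEFAULT_ALPHA,
    lfc_min: float = DEFAULT_LFC_MIN,
    factors: pd.Series | None = None,
    dispersion_floor: float = 1e-8,
) -> pd.DataFrame:
    """Per-gene NB Wald test of ``contrast = (test_group, ref_group)``.

    log2 fold changes are test over reference on size-factor-normalized
    group means.  The Wald statistic uses the delta-method variance of the
    log mean with a per-gene method-of-moments dispersion (floored at
    ``dispersion_floor``, averaged over the two groups) and is referred to a
    t distribution with Welch-Satterthwaite degrees of freedom -- the
    small-sample reference that keeps the raw-p type-I rate at nominal
    level for n = 4 replicates.

    Returns a DataFrame indexed by gene with columns ``base_mean``,
    ``log2fc``, ``p``, ``q`` (BH over all genes) and ``status`` in
    {up, down, ns} per the FDR and |log2 FC| gates.  Genes with zero counts
    in both groups get p = 1 and status ns.
    """
    test_group, ref_group = contrast
    test_ids = group_samples(sample_sheet, test_group)
    ref_ids = group_samples(sample_sheet, ref_group)
    if len(test_ids) < 2 or len(ref_ids) < 2:
        raise ValueError("each group in the contrast needs >= 2 replicates")
    if factors is None:
        factors = size_factors(counts)
    norm = counts.div(factors, axis=1)
    A = norm[ref_ids].to_numpy(dtype=float)
    B = norm[test_ids].to_numpy(dtype=float)
    nA, nB = A.shape[1], B.shape[1]
    mA, mB = A.mean(axis=1), B.mean(axis=1)

    disp = 0.5 * (_moment_dispersion(A, dispersion_floor) + _moment_dispersion(B, dispersion_floor))

    # Stabilize zero-mean groups with half a normalized count so the SE and
    # the fold change stay finite; exact ratios are preserved when both
    # group means are positive.
    zero_either = (mA == 0) | (mB == 0)
    mA_adj = np.where(zero_either, mA + 0.5, mA)
    mB_adj = np.where(zero_either, mB + 0.5, mB)

    log2fc = np.log2(mB_adj / mA_adj)
    # delta-method variance of ln(mean) per group
    uA = (mA_adj + disp * mA_adj**2) / (nA * mA_adj**2)
    uB = (mB_adj + disp * mB_adj**2) / (nB * mB_adj**2)
    se = np.sqrt(uA + uB)
    with np.errstate(divide="ignore", invalid="ignore"):
        df = (uA + uB) ** 2 / (uA**2 / (nA - 1) + uB**2 / (nB - 1))
    df = np.clip(np.nan_to_num(df, nan=1.0), 1.0, None)
    z = log2fc * np.log(2) / se
    p = 2.0 * stats.t.sf(np.abs(z), df)

    both_zero = (mA == 0) & (mB == 0)
    p[both_zero] = 1.0
    log2fc[both_zero] = 0.0

    q = bh_adjust(p)
    status = np.where(
        (q <= alpha) & (np.abs(log2fc) >= lfc_min),
        np.where(log2fc > 0, "up", "down"),
        "ns",
    )
    return pd.DataFrame(
        {
            "base_mean": norm.mean(axis=1).to_numpy(),
            "log2fc": log2fc,
            "p": p,
            "q": q,
            "status": status,
        },
        index=counts.index,
    )


def all_pairwise_contrasts(sample_sheet: pd.DataFrame) -> list[tuple[str, str]]:
    """Every unordered pair of condition_timepoint groups, deterministic order."""
    labels = sorted(
        set(sample_sheet["condition"].astype(str) + "_" + sample_sheet["timepoint"].astype(str))
    )
    return [(b, a) for a, b in combinations(labels, 2)]


def venn_partition(deg_sets: dict[str, set]) -> dict[tuple[str, ...], int]:
    """Exclusive-region counts of a Venn diagram over named gene sets.

    Keys are sorted tuples of the set names a region belongs to; values are
    the number of genes exactly in those sets.  Region counts sum to the
    size of the union.
    """
    names = sorted(deg_sets)
    out: dict[tuple[str, ...], int] = {}
    for gene in set().union(*deg_sets.values()) if deg_sets else set():
        key = tuple(n for n in names if gene in deg_sets[n])
        out[key] = out.get(key, 0) + 1
    return out


def define_fr_degs(
    assignments: pd.DataFrame,
    cluster_labels: dict[int, str],
) -> pd.Series:
    """FR-DEG set: members of clusters labelled FR-up or FR-down.

    ``assignments`` is the retained hard assignment table from the
    clustering module (index gene, column ``cluster``); ``cluster_labels``
    maps cluster index to {"FR-up", "FR-down", "other"}.  Returns a Series
    gene -> direction ("up"/"down"); genes of unlabelled clusters are
    excluded.  Hard assignment guarantees the set sizes add up.
    """
    directions = {}
    for gene, cluster in assignments["cluster"].items():
        label = cluster_labels.get(int(cluster), "other")
        if label == "FR-up":
            directions[gene] = "up"
        elif label == "FR-down":
            directions[gene] = "down"
    return pd.Series(directions, dtype=object, name="direction").sort_index()
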