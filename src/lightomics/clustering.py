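"""Soft clustering of DEG expression profiles (Mfuzz-style fuzzy c-means).

Differentially expressed genes are z-scored on log2(TPM + 1) and grouped
into ``c`` soft clusters; only genes whose maximum cluster membership
reaches 0.7 are retained, giving a disjoint hard assignment.  Cluster
centroids are then labelled by their far-red response (FR-up / FR-down /
other) and redundant clusters with correlated centroids are merged — the
FR-labelled clusters define the FR-DEG set used by every downstream stage.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

__all__ = [
    "select_cluster_input",
    "zscore",
    "fuzzy_cmeans",
    "estimate_fuzzifier",
    "label_cluster_direction",
    "merge_redundant_clusters",
    "ClusterModel",
]


def select_cluster_input(
    norm_counts: pd.DataFrame,
    pairwise_results: dict[str, pd.DataFrame],
    *,
    min_count: float = 5.0,
    min_samples: int = 3,
) -> list[str]:
    """Genes eligible for clustering.

    A gene qualifies when it (i) is differentially expressed (status not
    ``ns``) in at least one of the supplied pairwise contrasts and (ii) has
    at least ``min_count`` size-factor-normalized counts in at least
    ``min_samples`` samples, regardless of treatment.
    """
    de_any = pd.Series(False, index=norm_counts.index)
    for res in pairwise_results.values():
        de_any |= res["status"].reindex(norm_counts.index, fill_value="ns") != "ns"
    expressed = (norm_counts >= min_count).sum(axis=1) >= min_samples
    return sorted(norm_counts.index[de_any & expressed])


def zscore(mat: pd.DataFrame) -> pd.DataFrame:
    """Per-gene standardization: subtract the row mean, divide by the row
    sample SD (ddof=1).  Zero-variance rows are dropped with a warning."""
    mean = mat.mean(axis=1)
    sd = mat.std(axis=1, ddof=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(f"dropping {int(flat.sum())} constant-expression rows", stacklevel=2)
        mat, mean, sd = mat[~flat], mean[~flat], sd[~flat]
    return mat.sub(mean, axis=0).div(sd, axis=0)


def estimate_fuzzifier(n_genes: int, n_dims: int) -> float:
    """Empirical fuzzifier rule of Schwaemmle & Jensen (2010).

    m = 1 + (1418/N + 22.05) D^-2 + (12.33/N + 0.243) D^(-0.0406 ln N - 0.1134)
    with N genes and D dimensions (samples).
    """
    N, D = float(n_genes), float(n_dims)
    return (
        1.0
        + (1418.0 / N + 22.05) * D**-2
        + (12.33 / N + 0.243) * D ** (-0.0406 * math.log(N) - 0.1134)
    )


@dataclass
class ClusterModel:
    """Fitted fuzzy c-means model over z-scored profiles."""

    centroids: pd.DataFrame  # c x T, z-space
    membership: pd.DataFrame  # N x c, rows sum to 1
    m: float
    objective: float
    objective_path: list[float] = field(repr=False)
    assignments: pd.DataFrame = None  # retained genes: cluster, membership
    membership_min: float = 0.7


def _kmeanspp_init(X: np.ndarray, c: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++-style centroid seeding from data points."""
    n = X.shape[0]
    idx = [int(rng.integers(n))]
    d2 = ((X - X[idx[0]]) ** 2).sum(axis=1)
    for _ in range(1, c):
        total = d2.sum()
        if total <= 0:
            idx.append(int(rng.integers(n)))
        else:
            idx.append(int(rng.choice(n, p=d2 / total)))
        d2 = np.minimum(d2, ((X - X[idx[-1]]) ** 2).sum(axis=1))
    return X[idx].copy()


def _memberships(d2: np.ndarray, m: float) -> np.ndarray:
    """Membership update: u_ij proportional to d_ij^(-2/(m-1)); a point
    coinciding with a centroid gets membership 1 there (limit convention,
    ties split equally)."""
    exp = 1.0 / (m - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = d2 ** -exp
        U = inv / inv.sum(axis=1, keepdims=True)
    zero_rows = (d2 == 0).any(axis=1)
    if zero_rows.any():
        U[zero_rows] = 0.0
        hits = d2[zero_rows] == 0
        U[zero_rows] = hits / hits.sum(axis=1, keepdims=True)
    return U


def fuzzy_cmeans(
    z: pd.DataFrame,
    c: int = 10,
    m: float | None = None,
    *,
    tol: float = 1e-6,
    max_iter: int = 300,
    seed: int = 0,
    n_init: int = 10,
    membership_min: float = 0.7,
) -> ClusterModel:
    """Fuzzy c-means with k-means++ seeding and multi-restart.

    The alternating membership/centroid updates provably never increase the
    objective J = sum_ij u_ij^m ||x_i - v_j||^2; this is asserted every
    iteration.  Genes are processed in sorted-id order so permuting the
    input permutes the output identically.  Retained hard assignments keep
    genes whose maximum membership is at least ``membership_min``, ties
    broken toward the lowest cluster index.
    """
    if c < 2:
        raise ValueError("need at least two clusters")
    z = z.sort_index()
    X = z.to_numpy(dtype=float)
    N = X.shape[0]
    if N <= c:
        raise ValueError(f"need more genes ({N}) than clusters ({c})")
    if m is None:
        m = estimate_fuzzifier(N, X.shape[1])
    if m <= 1:
        raise ValueError("fuzzifier m must exceed 1")

    best = None
    for restart in range(n_init):
        rng = np.random.default_rng([seed, restart])
        V = _kmeanspp_init(X, c, rng)
        path: list[float] = []
        prev = np.inf
        for _ in range(max_iter):
            d2 = cdist(X, V, "sqeuclidean")
            U = _memberships(d2, m)
            Um = U**m
            V_new = (Um.T @ X) / Um.sum(axis=0)[:, None]
            obj = float((Um * cdist(X, V_new, "sqeuclidean")).sum())
            if obj > prev + 1e-9 * max(1.0, abs(prev)):  # alternating updates cannot ascend
                raise AssertionError("fuzzy c-means objective increased")
            path.append(obj)
            shift = np.abs(V_new - V).max()
            V = V_new
            prev = obj
            if shift < tol:
                break
        if best is None or prev < best[0]:
            best = (prev, V, path)

    obj, V, path = best
    U = _memberships(cdist(X, V, "sqeuclidean"), m)
    centroids = pd.DataFrame(V, index=range(c), columns=z.columns)
    membership = pd.DataFrame(U, index=z.index, columns=range(c))
    top = np.argmax(U, axis=1)  # argmax takes the lowest index on ties
    top_u = U[np.arange(N), top]
    keep = top_u >= membership_min
    assignments = pd.DataFrame(
        {"cluster": top[keep], "membership": top_u[keep]}, index=z.index[keep]
    )
    return ClusterModel(
        centroids=centroids,
        membership=membership,
        m=m,
        objective=obj,
        objective_path=path,
        assignments=assignments,
        membership_min=membership_min,
    )


def label_cluster_direction(
    centroids: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    *,
    delta: float = 0.5,
    day1: str = "23",
    day3: str = "71",
) -> dict[int, str]:
    """Label clusters by far-red response of their centroid.

    For each day the FR-minus-R centroid mean difference (in z units) is
    computed; a cluster is FR-up if the difference exceeds ``delta`` on day
    1, day 3 or both (and never drops below ``-delta``), FR-down in the
    mirrored case, otherwise "other".
    """
    sheet = sample_sheet.set_index("sample_id")
    labels = {}
    for cl, centroid in centroids.iterrows():
        diffs = []
        for day in (day1, day3):
            fr = [s for s in centroids.columns if str(sheet.loc[s, "condition"]) == "FR" and str(sheet.loc[s, "timepoint"]) == day]
            r = [s for s in centroids.columns if str(sheet.loc[s, "condition"]) == "R" and str(sheet.loc[s, "timepoint"]) == day]
            if fr and r:
                diffs.append(centroid[fr].mean() - centroid[r].mean())
        up = any(d > delta for d in diffs)
        down = any(d < -delta for d in diffs)
        if up and not down:
            labels[int(cl)] = "FR-up"
        elif down and not up:
            labels[int(cl)] = "FR-down"
        else:
            labels[int(cl)] = "other"
    return labels


def merge_redundant_clusters(
    centroids: pd.DataFrame,
    *,
    r_min: float = 0.8,
    alpha: float = 0.05,
) -> list[list[int]]:
    """Group clusters with an overall similar centroid pattern.

    Single-linkage (transitive) grouping over the graph that connects
    cluster pairs whose centroid Pearson correlation is at least ``r_min``
    with a correlation-test p below ``alpha``.  Returns sorted groups of
    cluster indices.
    """
    if len(centroids) < 2:
        raise ValueError("need at least two clusters to merge")
    G = nx.Graph()
    G.add_nodes_from(int(i) for i in centroids.index)
    idx = list(centroids.index)
    for i, a in enumerate(idx):
        for b in idx[i + 1 :]:
            r, p = stats.pearsonr(centroids.loc[a], centroids.loc[b])
            if r >= r_min and p < alpha:
                G.add_edge(int(a), int(b))
    return sorted(sorted(comp) for comp in nx.connected_components(G))
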