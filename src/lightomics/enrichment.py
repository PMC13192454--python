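"""Functional-bin over-representation analysis.

Gene sets (clusters, DMR-associated genes, network neighbourhoods) are
tested against a gene -> functional-bin map (Mercator/MapMan-style TSV)
with a hypergeometric upper-tail test; p-values are corrected with the
Benjamini-Hochberg step-up procedure and bins with FDR <= 0.05 are called
enriched.

``bh_adjust`` is the shared multiple-testing utility used by every other
module (differential expression, DMR calling, sRNA tests).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["bh_adjust", "hypergeom_upper_tail", "enrich", "EnrichmentResult"]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values).

    q_(i) = min_{j >= i} ( p_(j) * m / j ), capped at 1 and mapped back to
    the input order.  Accepts any 1-d sequence; returns a float array of the
    same length.  An empty input yields an empty array.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("bh_adjust expects a 1-d vector of p-values")
    if p.size == 0:
        return np.empty(0, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    N genes in the universe, K of them in the bin, n drawn (the query set),
    k observed in the bin.  k = 0 gives 1 by convention (the full tail).
    """
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"need 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need K <= N and n <= N; got K={K}, n={n}, N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


@dataclass
class EnrichmentResult:
    """One tested bin: k of n query genes hit a bin covering K of N genes."""

    bin_id: str
    bin_name: str
    k: int
    K: int
    n: int
    N: int
    gene_ratio: float  # k / K: query genes with the term over universe genes with it
    p: float
    q: float
    enriched: bool


def enrich(
    gene_set,
    bin_map: pd.DataFrame,
    universe=None,
    *,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric enrichment of ``gene_set`` against every annotated bin.

    Parameters
    ----------
    gene_set
        Iterable of gene ids; must be a subset of the universe.
    bin_map
        Long-format table with columns ``gene_id``, ``bin_id`` and optionally
        ``bin_name`` (genes may carry several bins).
    universe
        Background gene ids. Defaults to all genes with at least one bin
        annotation.
    alpha
        FDR gate for the ``enriched`` flag.

    Returns a DataFrame sorted by q then p with one row per tested bin
    (bins without universe members are skipped); BH correction is applied
    across the tested bins of this one query set.
    """
    required = {"gene_id", "bin_id"}
    if not required.issubset(bin_map.columns):
        raise ValueError(f"bin_map needs columns {sorted(required)}")
    genes = set(gene_set)
    if universe is None:
        universe = set(bin_map["gene_id"])
    else:
        universe = set(universe)
    stray = genes - universe
    if stray:
        raise ValueError(
            f"{len(stray)} query genes absent from the universe "
            f"(e.g. {sorted(stray)[:3]}); the universe must be the annotated "
            "transcriptome"
        )
    bm = bin_map[bin_map["gene_id"].isin(universe)]
    names = (
        bm.drop_duplicates("bin_id").set_index("bin_id")["bin_name"]
        if "bin_name" in bm.columns
        else pd.Series(dtype=object)
    )
    N, n = len(universe), len(genes)
    rows = []
    for bin_id, members in bm.groupby("bin_id")["gene_id"]:
        member_set = set(members)
        K = len(member_set)
        if K == 0:
            continue
        k = len(genes & member_set)
        p = hypergeom_upper_tail(k, K, n, N)
        rows.append(
            dict(
                bin_id=bin_id,
                bin_name=names.get(bin_id, str(bin_id)),
                k=k,
                K=K,
                n=n,
                N=N,
                gene_ratio=k / K,
                p=p,
            )
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out.reindex(
            columns=["bin_id", "bin_name", "k", "K", "n", "N", "gene_ratio", "p", "q", "enriched"]
        )
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["enriched"] = out["q"] <= alpha
    return out.sort_values(["q", "p", "bin_id"]).reset_index(drop=True)
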