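"""Co-expression networks around phytochrome hub genes.

Pairwise Pearson correlations of replicate-level log2(TPM+1) profiles are
variance-stabilized with Fisher's Z transform (atanh), standardized over
all gene pairs, and thresholded at a normal quantile (default 0.945,
i.e. standardized Z >= 1.5982) together with a hard PCC floor (0.98 for the
FR-upregulated set, 0.97 for the downregulated set).  The resulting graph
is queried for first-/second-level hub neighbourhoods and for shortest
paths back to the hubs (phytochrome B1b/B2a/B2b, FHY1/FHL).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "pcc_matrix",
    "fisher_z",
    "build_adjacency",
    "hub_neighborhood",
    "shortest_paths_to_hubs",
    "CoexprNetwork",
]


def pcc_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation of rows (genes) over columns (samples).

    Requires at least three observations; zero-variance genes must be
    excluded upstream (they yield NaN rows).
    """
    if expr.shape[1] < 3:
        raise ValueError("need >= 3 observations per gene for correlations")
    R = np.corrcoef(expr.to_numpy(dtype=float))
    return pd.DataFrame(R, index=expr.index, columns=expr.index)


def fisher_z(r) -> np.ndarray | float:
    """Fisher's Z transform, z = atanh(r) = 0.5 ln((1+r)/(1-r)).

    Correlations at or beyond +-1 (collinear synthetic genes) are clamped
    to 1 - 1e-12 in magnitude with a warning.
    """
    arr = np.asarray(r, dtype=float)
    clip = 1.0 - 1e-12
    if np.any(np.abs(arr) >= 1):
        warnings.warn("clamping |r| >= 1 before the Fisher transform", stacklevel=2)
        arr = np.clip(arr, -clip, clip)
    out = np.arctanh(arr)
    return out if out.ndim else float(out)


@dataclass
class CoexprNetwork:
    """Thresholded co-expression graph plus edge bookkeeping."""

    graph: nx.Graph
    edges: pd.DataFrame  # gene_a, gene_b, pcc, fisher_z, std_z
    hubs: list[str]
    levels: dict[str, int]  # node -> BFS depth from the nearest hub (hubs: 0)
    retained_fraction_quantile: float  # quantile filter alone
    retained_fraction: float  # combined quantile + PCC floor
    quantile: float
    pcc_floor: float
    effective_pcc_threshold: float = field(default=float("nan"))


def build_adjacency(
    expr: pd.DataFrame,
    *,
    quantile: float = 0.945,
    pcc_floor: float = -1.0,
    positive_only: bool = True,
    hubs: tuple[str, ...] = (),
) -> CoexprNetwork:
    """Build the thresholded co-expression network for one gene set.

    All pairwise Fisher-Z values are standardized (mean subtracted, sample
    SD divided); an edge is kept when its standardized Z reaches the normal
    quantile cut-off AND its raw PCC reaches ``pcc_floor``.  With
    ``positive_only`` (default) anticorrelated pairs never form edges.
    The fraction of pairs surviving the quantile step alone and the
    combined filter are both recorded, as is the smallest PCC among
    quantile-retained pairs (the PCC threshold the quantile implies).
    """
    genes = list(expr.index)
    n = len(genes)
    n_pairs = n * (n - 1) // 2
    if n_pairs <= 2:
        raise ValueError("need more than two gene pairs to standardize Z values")
    R = pcc_matrix(expr).to_numpy()
    iu = np.triu_indices(n, k=1)
    r = R[iu]
    zv = np.asarray(fisher_z(r))
    sd = zv.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("degenerate Fisher-Z distribution: all pairs identical")
    std_z = (zv - zv.mean()) / sd
    cut = stats.norm.ppf(quantile)
    pass_quantile = std_z >= cut
    keep = pass_quantile & (r >= pcc_floor)
    if positive_only:
        keep &= r > 0
    eff_thr = float(r[pass_quantile].min()) if pass_quantile.any() else float("nan")

    ga = np.asarray(genes, dtype=object)[iu[0]][keep]
    gb = np.asarray(genes, dtype=object)[iu[1]][keep]
    edges = pd.DataFrame(
        {
            "gene_a": ga,
            "gene_b": gb,
            "pcc": r[keep],
            "fisher_z": zv[keep],
            "std_z": std_z[keep],
        }
    ).sort_values(["gene_a", "gene_b"], ignore_index=True)

    G = nx.Graph()
    G.add_nodes_from(genes)
    for row in edges.itertuples(index=False):
        G.add_edge(row.gene_a, row.gene_b, pcc=row.pcc, fisher_z=row.fisher_z, std_z=row.std_z)

    present_hubs = [h for h in hubs if h in G]
    for h in hubs:
        if h not in G:
            warnings.warn(f"hub {h!r} absent from the network; skipped", stacklevel=2)
    levels = _hub_levels(G, present_hubs)
    return CoexprNetwork(
        graph=G,
        edges=edges,
        hubs=present_hubs,
        levels=levels,
        retained_fraction_quantile=float(pass_quantile.mean()),
        retained_fraction=float(keep.mean()),
        quantile=quantile,
        pcc_floor=pcc_floor,
        effective_pcc_threshold=eff_thr,
    )


def _hub_levels(G: nx.Graph, hubs: list[str]) -> dict[str, int]:
    levels: dict[str, int] = {}
    for h in hubs:
        for node, d in nx.single_source_shortest_path_length(G, h).items():
            if node not in levels or d < levels[node]:
                levels[node] = d
    return levels


def hub_neighborhood(network: CoexprNetwork, hubs=None, max_level: int = 2) -> nx.Graph:
    """Induced subgraph of nodes within ``max_level`` BFS steps of any hub,
    with each node's depth stored as the ``level`` attribute."""
    G = network.graph
    if hubs is None:
        present = network.hubs
    else:
        present = [h for h in hubs if h in G]
        for h in hubs or ():
            if h not in G:
                warnings.warn(f"hub {h!r} absent from the network; skipped", stacklevel=2)
    levels = _hub_levels(G, present)
    nodes = [v for v, d in levels.items() if d <= max_level]
    sub = G.subgraph(nodes).copy()
    nx.set_node_attributes(sub, {v: levels[v] for v in sub}, "level")
    return sub


def shortest_paths_to_hubs(network: CoexprNetwork, hubs=None) -> dict[str, list[str]]:
    """Unweighted shortest path from every reachable node to its nearest hub.

    Ties are broken deterministically: the nearest hub with the
    lexicographically smallest id wins, and among equal-length paths the
    lexicographically smallest node sequence is returned.  Unreachable
    nodes are absent from the result; hubs map to the single-node path.
    """
    G = network.graph
    hub_list = sorted(network.hubs if hubs is None else [h for h in hubs if h in G])
    dist_from: dict[str, dict[str, int]] = {
        h: nx.single_source_shortest_path_length(G, h) for h in hub_list
    }
    out: dict[str, list[str]] = {}
    for node in G.nodes:
        dists = [dist_from[h][node] for h in hub_list if node in dist_from[h]]
        if not dists:
            continue
        d_min = min(dists)
        candidates = []
        for hub in hub_list:
            if dist_from[hub].get(node) != d_min:
                continue
            # walk greedily: always step to the smallest neighbour one closer
            # to the hub; this yields the lexicographically smallest shortest
            # path to that hub
            path = [node]
            cur = node
            while cur != hub:
                nxt = min(
                    nb
                    for nb in G.neighbors(cur)
                    if dist_from[hub].get(nb, -1) == dist_from[hub][cur] - 1
                )
                path.append(nxt)
                cur = nxt
            candidates.append(path)
        out[node] = min(candidates)
    return out
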