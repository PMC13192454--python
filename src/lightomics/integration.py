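"""Joining methylation, sRNA and expression evidence per gene.

Under RNA-directed DNA methylation, small RNAs guide de novo cytosine
methylation, so increased methylation is expected to move together with
sRNA accumulation and opposite to the target gene's expression (and vice
versa for losses).  This module joins called DMRs to FR-DEGs through
promoter/exon/intron overlap, attaches the per-size-class differential
sRNA verdicts at each DMR, applies the consistency rule, and produces the
Sankey-style path tallies plus a per-gene candidate evidence report.
"""

from __future__ import annotations

import warnings

import pandas as pd

__all__ = [
    "associate_dmrs_with_degs",
    "attach_srna",
    "rddm_verdict",
    "tally_sankey",
    "candidate_report",
    "RDDM_SIZES",
]

#: size classes whose differential accumulation can satisfy the rule
RDDM_SIZES = (21, 22, 24)

_FEATURE_PRIORITY = {"promoter": 0, "exon": 1, "intron": 2}


def associate_dmrs_with_degs(
    dmrs: pd.DataFrame,
    fr_degs: pd.Series,
    feature_assignments: pd.DataFrame,
) -> pd.DataFrame:
    """One record per (FR-DEG gene, DMR) pair linked by >= 1 bp overlap
    with the gene's promoter, exon or intron.

    ``feature_assignments`` is the long DMR-feature overlap table from the
    methylome module.  When a DMR touches several features of one gene the
    record keeps the feature with the largest overlap (ties resolved
    promoter > exon > intron).
    """
    dmr_info = dmrs.set_index("dmr_id")
    hits = feature_assignments[
        feature_assignments["ftype"].isin(_FEATURE_PRIORITY)
        & feature_assignments["parent"].isin(fr_degs.index)
    ].copy()
    if hits.empty:
        return pd.DataFrame(
            columns=["gene_id", "dmr_id", "context", "feature", "meth_direction", "expr_direction"]
        )
    hits["rank"] = hits["ftype"].map(_FEATURE_PRIORITY)
    hits = hits.sort_values(["parent", "dmr_id", "overlap_bp", "rank"],
                            ascending=[True, True, False, True])
    best = hits.drop_duplicates(["parent", "dmr_id"], keep="first")
    records = pd.DataFrame(
        {
            "gene_id": best["parent"].to_numpy(),
            "dmr_id": best["dmr_id"].to_numpy(),
            "context": dmr_info.loc[best["dmr_id"], "context"].to_numpy(),
            "feature": best["ftype"].to_numpy(),
            "meth_direction": dmr_info.loc[best["dmr_id"], "direction"].to_numpy(),
            "expr_direction": fr_degs.reindex(best["parent"]).to_numpy(),
        }
    )
    return records.sort_values(["gene_id", "dmr_id"], ignore_index=True)


def attach_srna(records: pd.DataFrame, srna_results: pd.DataFrame) -> pd.DataFrame:
    """Attach per-size-class sRNA directions (up/down where q passed the
    gate, else ns) to every record; DMRs absent from the sRNA results get
    all-ns with a warning."""
    records = records.copy()
    by_key = srna_results.set_index(["region_id", "size"])["direction"]
    missing = set(records["dmr_id"]) - set(srna_results["region_id"])
    if missing:
        warnings.warn(
            f"{len(missing)} DMRs have no sRNA quantification; their sRNA "
            "directions are set to 'ns'",
            stacklevel=2,
        )
    for size in RDDM_SIZES:
        records[f"srna_{size}"] = [
            by_key.get((dmr, size), "ns") for dmr in records["dmr_id"]
        ]
    return records


def rddm_verdict(meth_direction: str, srna_directions: dict[int, str], expr_direction: str) -> bool:
    """The RdDM-consistency rule for one (gene, DMR) evidence triple.

    Consistent iff methylation gain comes with sRNA gain in at least one of
    the 21/22/24-nt classes and expression loss — or the fully mirrored
    triple.  A non-significant sRNA class never supports consistency.
    """
    dirs = [srna_directions.get(s, "ns") for s in RDDM_SIZES]
    if meth_direction == "hyper":
        return expr_direction == "down" and "up" in dirs
    if meth_direction == "hypo":
        return expr_direction == "up" and "down" in dirs
    raise ValueError(f"unknown methylation direction {meth_direction!r}")


def apply_verdicts(records: pd.DataFrame) -> pd.DataFrame:
    """Add the per-record ``rddm_consistent`` flag."""
    records = records.copy()
    records["rddm_consistent"] = [
        rddm_verdict(
            row.meth_direction,
            {s: getattr(row, f"srna_{s}") for s in RDDM_SIZES},
            row.expr_direction,
        )
        for row in records.itertuples(index=False)
    ]
    return records


def consistent_genes(records: pd.DataFrame) -> list[str]:
    """Genes with at least one RdDM-consistent (gene, DMR) record."""
    if records.empty:
        return []
    flagged = records.loc[records["rddm_consistent"], "gene_id"]
    return sorted(set(flagged))


def tally_sankey(records: pd.DataFrame) -> pd.DataFrame:
    """Path counts (meth_direction -> sRNA direction -> expr_direction) per
    size class, over records whose sRNA class is not ns.  Path weights sum
    to the number of contributing records per size class."""
    rows = []
    for size in RDDM_SIZES:
        col = f"srna_{size}"
        sub = records[records[col] != "ns"] if not records.empty else records
        if sub.empty:
            continue
        grouped = (
            sub.groupby(["meth_direction", col, "expr_direction"]).size().reset_index(name="count")
        )
        grouped = grouped.rename(columns={col: "srna_direction"})
        grouped.insert(0, "size", size)
        rows.append(grouped)
    if not rows:
        return pd.DataFrame(
            columns=["size", "meth_direction", "srna_direction", "expr_direction", "count"]
        )
    return pd.concat(rows, ignore_index=True)


def candidate_report(
    records: pd.DataFrame,
    hub_networks: dict[str, set] | None = None,
) -> pd.DataFrame:
    """Per-gene evidence table for the RdDM candidate genes.

    One row per consistent gene listing all of its DMR records — including
    those without significant sRNA accumulation, which are flagged — and
    the hub neighbourhoods (e.g. phytochrome networks) containing the gene.
    """
    hub_networks = hub_networks or {}
    rows = []
    for gene in consistent_genes(records):
        sub = records[records["gene_id"] == gene]
        nets = sorted(h for h, members in hub_networks.items() if gene in members)
        rows.append(
            dict(
                gene_id=gene,
                expr_direction=sub["expr_direction"].iloc[0],
                n_dmrs=len(sub),
                consistent_dmrs=",".join(sub.loc[sub["rddm_consistent"], "dmr_id"]),
                silent_dmrs=",".join(sub.loc[~sub["rddm_consistent"], "dmr_id"]),
                networks=",".join(nets),
            )
        )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "expr_direction", "n_dmrs", "consistent_dmrs", "silent_dmrs", "networks"],
    )
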