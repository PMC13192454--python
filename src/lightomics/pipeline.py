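"""Stage orchestration: one call runs the whole integrative analysis.

Stages run in dependency order — simulate (or load), differential
expression, soft clustering, co-expression networks, enrichment, methylome
(DMRs), sRNA, integration — and each writes its tables plus a timestamp-
free JSON provenance block, so identical configs and seeds reproduce
byte-identical output trees.  A stage subset can be requested; upstream
results are then loaded from an earlier run's data directory.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import clustering, enrichment, expression, integration, methylome, network, srna
from .io import (
    read_cytosine_report,
    read_counts,
    read_gff3,
    read_sample_sheet,
    write_bed6,
    write_provenance,
)
from .simulate import GroundTruth, SimulatedExperiment, SimulationConfig, simulate_all
from .srna import SRNAProfile

__all__ = ["run_pipeline", "STAGES"]

STAGES = ["simulate", "de", "cluster", "network", "enrich", "methylome", "srna", "integrate"]


def _jaccard(a: set, b: set) -> float:
    return len(a & b) / len(a | b) if (a or b) else 1.0


class PipelineState:
    """In-memory bundle passed between stages."""

    def __init__(self, outdir: Path, seed: int, config: dict):
        self.outdir = outdir
        self.seed = seed
        self.config = config
        self.data: SimulatedExperiment | None = None
        self.truth: GroundTruth | None = None
        self.annotation = None
        self.sample_sheet = None
        self.counts = None
        self.lengths = None
        self.factors = None
        self.tpm = None
        self.de_results: dict[str, pd.DataFrame] = {}
        self.cluster_model = None
        self.cluster_labels = None
        self.fr_degs = None
        self.networks: dict[str, network.CoexprNetwork] = {}
        self.dmrs = None
        self.dmr_features = None
        self.dmr_classes = None
        self.srna_profile: SRNAProfile | None = None
        self.srna_results = None
        self.records = None
        self.summary: dict = {}


def _load_data(state: PipelineState) -> None:
    """Load simulate-stage outputs from disk for partial runs."""
    data_dir = Path(state.config.get("data_dir", state.outdir / "data"))
    if not data_dir.exists():
        raise FileNotFoundError(
            f"missing upstream data directory {data_dir}; run the simulate stage first"
        )
    state.annotation = read_gff3(data_dir / "annotation.gff3")
    state.sample_sheet = read_sample_sheet(data_dir / "samples.tsv")
    state.counts, state.lengths = read_counts(data_dir / "counts.tsv")
    state._data_dir = data_dir
    truth_path = data_dir / "truth.json"
    if truth_path.exists():
        state.truth = GroundTruth.from_json(truth_path)


def stage_simulate(state: PipelineState) -> None:
    sim_cfg = dict(state.config.get("simulate", {}))
    sim_cfg.setdefault("seed", state.seed)
    cfg = SimulationConfig(**sim_cfg)
    data_dir = state.outdir / "data"
    exp = simulate_all(cfg, outdir=data_dir)
    state.data = exp
    state.truth = exp.truth
    state.annotation = exp.annotation
    state.sample_sheet = exp.sample_sheet
    state.counts, state.lengths = exp.counts, exp.lengths
    state._data_dir = data_dir
    write_provenance(
        data_dir / "provenance.json",
        stage="simulate",
        params={k: str(v) for k, v in sim_cfg.items()},
        seed=cfg.seed,
    )


def stage_de(state: PipelineState) -> None:
    out = state.outdir / "de"
    out.mkdir(parents=True, exist_ok=True)
    state.factors = expression.size_factors(state.counts)
    state.tpm = expression.tpm(state.counts, state.lengths)
    contrasts = expression.all_pairwise_contrasts(state.sample_sheet)
    sets = {}
    for test, ref in contrasts:
        name = f"{test}_vs_{ref}"
        res = expression.de_test(
            state.counts, state.sample_sheet, (test, ref), factors=state.factors
        )
        state.de_results[name] = res
        res.to_csv(out / f"de_{name}.tsv", sep="\t", index_label="gene_id")
        if ref == "Ctrl_0":
            sets[name] = set(res.index[res["status"] != "ns"])
    venn = expression.venn_partition(sets)
    with open(out / "venn.json", "w", encoding="utf-8") as fh:
        json.dump({"+".join(k): v for k, v in sorted(venn.items())}, fh, indent=2, sort_keys=True)
        fh.write("\n")
    state.summary["n_deg_union"] = len(set().union(*sets.values())) if sets else 0
    state.summary["deg_counts_vs_ctrl"] = {k: len(v) for k, v in sorted(sets.items())}
    write_provenance(out / "provenance.json", stage="de",
                     params={"alpha": 0.05, "lfc_min": 1.5}, seed=state.seed)


def stage_cluster(state: PipelineState) -> None:
    out = state.outdir / "cluster"
    out.mkdir(parents=True, exist_ok=True)
    cfg = state.config.get("cluster", {})
    norm = state.counts.div(state.factors, axis=1)
    genes = clustering.select_cluster_input(norm, state.de_results)
    # z-profiles use median-of-ratios-normalized counts: per-gene z-scoring
    # cancels gene length anyway, and size factors resist the composition
    # bias that per-sample total scaling (TPM) suffers when a large gene
    # fraction is regulated
    log_expr = np.log2(norm.loc[genes] + 1.0)
    z = clustering.zscore(log_expr)
    model = clustering.fuzzy_cmeans(
        z,
        c=int(cfg.get("c", 10)),
        m=cfg.get("m"),
        seed=state.seed,
        membership_min=float(cfg.get("membership_min", 0.7)),
    )
    labels = clustering.label_cluster_direction(
        model.centroids, state.sample_sheet, delta=float(cfg.get("delta", 0.5))
    )
    groups = clustering.merge_redundant_clusters(model.centroids)
    state.cluster_model = model
    state.cluster_labels = labels
    state.fr_degs = expression.define_fr_degs(model.assignments, labels)
    model.membership.to_csv(out / "membership.tsv", sep="\t", index_label="gene_id")
    model.assignments.to_csv(out / "assignments.tsv", sep="\t", index_label="gene_id")
    model.centroids.to_csv(out / "centroids.tsv", sep="\t", index_label="cluster")
    state.fr_degs.to_csv(out / "fr_degs.tsv", sep="\t", index_label="gene_id")
    with open(out / "labels.json", "w", encoding="utf-8") as fh:
        json.dump({"labels": {str(k): v for k, v in labels.items()},
                   "merged_groups": groups, "fuzzifier": model.m}, fh, indent=2, sort_keys=True)
        fh.write("\n")
    state.summary["n_clustered_genes"] = int(len(model.assignments))
    state.summary["n_fr_degs"] = int(len(state.fr_degs))
    state.summary["n_fr_up"] = int((state.fr_degs == "up").sum())
    state.summary["n_fr_down"] = int((state.fr_degs == "down").sum())
    if state.truth is not None:
        truth_fr = state.truth.fr_deg_truth()
        state.summary["frdeg_jaccard_vs_truth"] = _jaccard(
            set(state.fr_degs.index), set(truth_fr)
        )
    write_provenance(out / "provenance.json", stage="cluster",
                     params={"c": int(cfg.get("c", 10)), "membership_min": 0.7},
                     seed=state.seed)


def stage_network(state: PipelineState) -> None:
    out = state.outdir / "network"
    out.mkdir(parents=True, exist_ok=True)
    cfg = state.config.get("network", {})
    hubs = list(cfg.get("hubs") or (state.truth.hub_genes if state.truth else []))
    floors = {"up": float(cfg.get("pcc_floor_up", 0.98)),
              "down": float(cfg.get("pcc_floor_down", 0.97))}
    log_expr = np.log2(state.counts.div(state.factors, axis=1) + 1.0)
    for direction, floor in floors.items():
        members = state.fr_degs.index[state.fr_degs == direction]
        if len(members) < 4:
            continue
        expr = log_expr.loc[members]
        expr = expr[expr.std(axis=1) > 0]
        net = network.build_adjacency(
            expr,
            quantile=float(cfg.get("quantile", 0.945)),
            pcc_floor=floor,
            hubs=tuple(h for h in hubs if h in expr.index),
        )
        state.networks[direction] = net
        net.edges.to_csv(out / f"edges_{direction}.tsv", sep="\t", index=False)
        pd.Series(net.levels, name="level").sort_index().to_csv(
            out / f"levels_{direction}.tsv", sep="\t", index_label="gene_id"
        )
        nx.write_graphml(net.graph, out / f"network_{direction}.graphml")
        state.summary[f"retained_edge_fraction_{direction}"] = net.retained_fraction
        state.summary[f"retained_edge_fraction_quantile_{direction}"] = (
            net.retained_fraction_quantile
        )
    write_provenance(out / "provenance.json", stage="network",
                     params={"quantile": 0.945, **floors}, seed=state.seed)


def stage_enrich(state: PipelineState) -> None:
    out = state.outdir / "enrich"
    out.mkdir(parents=True, exist_ok=True)
    bin_path = Path(state.config.get("bin_map", state._data_dir / "bins.tsv"))
    if not bin_path.exists():
        return
    bin_map = pd.read_csv(bin_path, sep="\t")
    universe = set(bin_map["gene_id"])
    for direction in ("up", "down"):
        members = set(state.fr_degs.index[state.fr_degs == direction]) & universe
        if not members:
            continue
        res = enrichment.enrich(members, bin_map, universe)
        res.to_csv(out / f"enrichment_fr_{direction}.tsv", sep="\t", index=False)
        state.summary[f"n_enriched_bins_fr_{direction}"] = int(res["enriched"].sum())
    write_provenance(out / "provenance.json", stage="enrich",
                     params={"alpha": 0.05}, seed=state.seed)


def stage_methylome(state: PipelineState) -> None:
    out = state.outdir / "methylome"
    out.mkdir(parents=True, exist_ok=True)
    cfg = state.config.get("methylome", {})
    if state.data is not None:
        rec_R, rec_FR = state.data.records_R, state.data.records_FR
    else:
        rec_R = read_cytosine_report(state._data_dir / "cytosines_R.tsv")
        rec_FR = read_cytosine_report(state._data_dir / "cytosines_FR.tsv")
    covered_R = rec_R[rec_R["count_methylated"] + rec_R["count_unmethylated"] > 0]
    covered_FR = rec_FR[rec_FR["count_methylated"] + rec_FR["count_unmethylated"] > 0]
    state.summary["global_methylation_R"] = methylome.global_methylation(covered_R)
    state.summary["global_methylation_FR"] = methylome.global_methylation(covered_FR)
    meta = methylome.metagene_profile(covered_FR, state.annotation)
    meta.to_csv(out / "metagene_FR.tsv", sep="\t", index=False)
    dmr_frames = []
    for context in ("CG", "CHG", "CHH"):
        dmrs = methylome.call_dmrs(
            rec_R, rec_FR, context,
            max_gap=int(cfg.get("max_gap", 300)),
            min_c=int(cfg.get("min_c", 6)),
            min_diff=float(cfg.get("min_diff", 0.1)),
            alpha=float(cfg.get("alpha", 0.05)),
        )
        dmr_frames.append(dmrs)
    state.dmrs = pd.concat(dmr_frames, ignore_index=True)
    state.dmr_features, state.dmr_classes = methylome.overlap_features(
        state.dmrs, state.annotation
    )
    state.dmrs.to_csv(out / "dmrs.tsv", sep="\t", index=False)
    if len(state.dmrs):
        write_bed6(
            state.dmrs.rename(columns={"dmr_id": "name"})[["chrom", "start", "end", "name"]],
            out / "dmrs.bed",
        )
    state.dmr_features.to_csv(out / "dmr_features.tsv", sep="\t", index=False)
    state.dmr_classes.to_csv(out / "dmr_classes.tsv", sep="\t", index=False)
    state.summary["n_dmrs"] = int(len(state.dmrs))
    state.summary["n_dmrs_by_context"] = (
        state.dmrs["context"].value_counts().sort_index().to_dict() if len(state.dmrs) else {}
    )
    state.summary["n_dmrs_by_direction"] = (
        state.dmrs["direction"].value_counts().sort_index().to_dict() if len(state.dmrs) else {}
    )
    if state.truth is not None:
        state.summary.update(_dmr_recovery(state.dmrs, state.truth))
    write_provenance(out / "provenance.json", stage="methylome",
                     params={"max_gap": 300, "min_c": 6, "min_diff": 0.1, "alpha": 0.05},
                     seed=state.seed)


def _dmr_recovery(dmrs: pd.DataFrame, truth: GroundTruth) -> dict:
    """Planted-DMR sensitivity and empirical FDR by interval+context match."""
    planted = [
        (d["chrom"], d["start"], d["end"], d["context"], d["direction"])
        for d in truth.dmr_intervals
    ]
    hit = set()
    n_false = 0
    for dmr in dmrs.itertuples(index=False):
        matched = False
        for i, (chrom, start, end, ctx, direction) in enumerate(planted):
            if (
                dmr.chrom == chrom
                and dmr.context == ctx
                and dmr.start < end
                and dmr.end > start
                and dmr.direction == direction
            ):
                hit.add(i)
                matched = True
        if not matched:
            n_false += 1
    n_called = len(dmrs)
    return {
        "dmr_sensitivity": len(hit) / len(planted) if planted else float("nan"),
        "dmr_fdr": n_false / n_called if n_called else 0.0,
    }


def stage_srna(state: PipelineState) -> None:
    out = state.outdir / "srna"
    out.mkdir(parents=True, exist_ok=True)
    if state.data is not None:
        profile = state.data.srna
        mirna_counts = state.data.mirna_counts
        targets = state.data.mirna_targets
    else:
        loci = pd.read_csv(
            state._data_dir / "srna_loci.bed", sep="\t", header=None,
            names=["chrom", "start", "end", "name", "score", "strand"],
        )
        long = pd.read_csv(state._data_dir / "srna_counts.tsv", sep="\t")
        counts = long.set_index(["locus", "size"])
        profile = SRNAProfile(counts=counts, library_totals=counts.sum(axis=0), loci=loci)
        mirna_counts = pd.read_csv(state._data_dir / "mirna_counts.tsv", sep="\t", index_col=0)
        targets = pd.read_csv(state._data_dir / "mirna_targets.tsv", sep="\t")
    srna.rpm_normalize(profile)
    groups = {
        row["sample_id"]: f"{row['condition']}_{row['timepoint']}"
        for _, row in state.sample_sheet.iterrows()
        if row["sample_id"] in profile.counts.columns
    }
    dist = srna.size_distribution(profile, groups)
    dist.to_csv(out / "size_distribution.tsv", sep="\t", index=False)
    state.srna_profile = profile

    contrast = ("FR_71", "R_71")
    if state.dmrs is not None and len(state.dmrs) and state.fr_degs is not None:
        deg_dmrs = integration.associate_dmrs_with_degs(
            state.dmrs, state.fr_degs, state.dmr_features
        )
        test_dmrs = state.dmrs[state.dmrs["dmr_id"].isin(set(deg_dmrs["dmr_id"]))]
        if len(test_dmrs):
            state.srna_results = srna.srna_at_regions(
                profile, test_dmrs, state.sample_sheet, contrast
            )
            state.srna_results.to_csv(out / "srna_at_dmrs.tsv", sep="\t", index=False)
            sig = state.srna_results[state.srna_results["direction"] != "ns"]
            state.summary["n_srna_differential_dmrs"] = int(sig["region_id"].nunique())

    fam_de = srna.mirna_family_de(
        mirna_counts, state.sample_sheet, contrast, profile.library_totals
        if set(mirna_counts.columns) <= set(profile.library_totals.index)
        else mirna_counts.sum(axis=0),
    )
    fam_de.to_csv(out / "mirna_family_de.tsv", sep="\t", index_label="family")
    state.summary["n_differential_mirna_families"] = int((fam_de["status"] != "ns").sum())
    if state.fr_degs is not None:
        xref = srna.crossref_mirna_targets(fam_de, state.fr_degs, targets)
        xref.to_csv(out / "mirna_target_xref.tsv", sep="\t", index=False)
        state.summary["n_mirna_fr_deg_targets"] = int(xref["gene_id"].nunique())
    write_provenance(out / "provenance.json", stage="srna",
                     params={"contrast": "FR_71_vs_R_71"}, seed=state.seed)


def stage_integrate(state: PipelineState) -> None:
    out = state.outdir / "integrate"
    out.mkdir(parents=True, exist_ok=True)
    if state.dmrs is None or state.fr_degs is None:
        raise RuntimeError("integrate needs the methylome and cluster stages")
    records = integration.associate_dmrs_with_degs(
        state.dmrs, state.fr_degs, state.dmr_features
    )
    state.summary["n_fr_degs_with_dmrs"] = int(records["gene_id"].nunique())
    if state.srna_results is not None:
        records = integration.attach_srna(records, state.srna_results)
    else:
        for size in integration.RDDM_SIZES:
            records[f"srna_{size}"] = "ns"
    records = integration.apply_verdicts(records)
    state.records = records
    records.to_csv(out / "integration.tsv", sep="\t", index=False)
    sankey = integration.tally_sankey(records)
    sankey.to_csv(out / "sankey.tsv", sep="\t", index=False)
    hub_nets = {
        f"{direction}_hub_network": set(net.levels)
        for direction, net in state.networks.items()
    }
    report = integration.candidate_report(records, hub_nets)
    report.to_csv(out / "candidates.tsv", sep="\t", index=False)
    found = set(integration.consistent_genes(records))
    state.summary["n_rddm_consistent_genes"] = len(found)
    if state.truth is not None:
        planted = set(state.truth.rddm_genes)
        state.summary["rddm_sensitivity"] = (
            len(found & planted) / len(planted) if planted else float("nan")
        )
        state.summary["rddm_false_positives"] = len(found - planted)
    write_provenance(out / "provenance.json", stage="integrate",
                     params={"sizes": list(integration.RDDM_SIZES)}, seed=state.seed)


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "de": stage_de,
    "cluster": stage_cluster,
    "network": stage_network,
    "enrich": stage_enrich,
    "methylome": stage_methylome,
    "srna": stage_srna,
    "integrate": stage_integrate,
}

_REQUIRES = {
    "de": [],
    "cluster": ["de"],
    "network": ["cluster"],
    "enrich": ["cluster"],
    "methylome": [],
    "srna": [],
    "integrate": ["methylome", "cluster"],
}


def run_pipeline(
    config: dict | None = None,
    outdir="lightomics_out",
    *,
    seed: int = 0,
    stages: list[str] | None = None,
) -> dict:
    """Run the requested stages (default: all) and return the summary dict.

    ``config`` may carry per-stage parameter blocks (``simulate``,
    ``cluster``, ``network``, ``methylome``) and a ``data_dir`` pointing at
    a previous simulate stage when that stage is skipped.
    """
    config = config or {}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    requested = list(STAGES) if stages is None else [s for s in STAGES if s in set(stages)]
    unknown = set(stages or []) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}; valid: {STAGES}")
    state = PipelineState(outdir, seed, config)
    if "simulate" not in requested:
        _load_data(state)
    for stage in requested:
        for dep in _REQUIRES.get(stage, []):
            if dep not in requested:
                raise RuntimeError(
                    f"stage {stage!r} needs upstream stage {dep!r}; include it in --stages"
                )
        _STAGE_FUNCS[stage](state)
    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(state.summary, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
    return state.summary
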