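"""Synthetic multi-omics experiment with machine-readable planted truth.

The generator emulates the far-red-light haustorium-induction study design
entirely in silico so every downstream stage is testable without
sequencing data: a single chromosome carrying non-overlapping gene bodies
and transposable elements, negative-binomial RNA-seq counts with planted
temporally patterned DEG archetypes, per-cytosine binomial methylation
calls with planted context-specific DMRs, per-size-class sRNA locus counts
with planted shifts in the 21/22/24-nt classes, and a set of genes planted
to jointly satisfy the RdDM-consistency rule (methylation and sRNA move
together, opposite to expression).

Genome layout
-------------
The chromosome is a lattice of *units*: an A/T-only spacer (default 400 bp,
longer than the DMR caller's maximum intra-region gap) followed by a
random-ACGT *cytosine island* (default 150 bp).  Cytosines therefore occur
only inside islands, so the islands are exactly the candidate regions the
DMR caller will form, and planted DMRs/sRNA loci align with them by
construction.  Gene bodies span a few consecutive units (their terminal
islands are the exons), strands alternate, and TEs may overlap gene bodies.

Every generator draws from its own RNG stream derived from the master seed
by a fixed offset, so adding a generator never perturbs the others; a
fixed seed makes all outputs byte-for-byte reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    AnnotationSet,
    FEATURE_COLUMNS,
    write_bed6,
    write_counts,
    write_cytosine_report,
    write_fasta,
    write_gff3,
    write_sample_sheet,
)
from .srna import SIZE_CLASSES, SRNAProfile

__all__ = ["SimulationConfig", "GroundTruth", "SimulatedExperiment", "simulate_all",
           "simulate_annotation", "simulate_counts", "simulate_methylome", "simulate_srna",
           "cytosine_sites", "ARCHETYPES", "ARCHETYPE_FR_DIRECTION"]

# RNG stream offsets per generator (fixed; see module docstring)
_STREAM_ANNOTATION = 1
_STREAM_COUNTS = 2
_STREAM_METHYLOME = 3
_STREAM_SRNA = 4
_STREAM_MIRNA = 5
_STREAM_BINS = 6
_STREAM_TRUTH = 10

#: temporal archetypes: group -> log2FC multiplier, over the five sequenced
#: groups (Ctrl_0, R_23, FR_23, R_71, FR_71).  They cover far-red up/down at
#: day 1, day 3 and both, red-specific regulation, and light-general
#: regulation with no R/FR contrast.
ARCHETYPES: list[dict[str, int]] = [
    {"FR_23": +1},
    {"FR_71": +1},
    {"FR_23": +1, "FR_71": +1},
    {"FR_23": -1},
    {"FR_71": -1},
    {"FR_23": -1, "FR_71": -1},
    {"R_23": +1, "R_71": +1},
    {"R_23": -1, "R_71": -1},
    {"R_23": +1, "FR_23": +1, "R_71": +1, "FR_71": +1},
    {"R_23": -1, "FR_23": -1, "R_71": -1, "FR_71": -1},
]
#: FR response of each archetype relative to R light (the direction the
#: cluster-labelling rule recovers); None = no R/FR contrast.
ARCHETYPE_FR_DIRECTION: list[str | None] = [
    "up", "up", "up", "down", "down", "down", "down", "up", None, None,
]


@dataclass
class SimulationConfig:
    """Parameters of the in-silico experiment.

    Methylation base levels are arbitrary plumbing defaults per context,
    not empirical estimates.  ``planted_log2fc_range`` must stay above the
    DEG |log2FC| gate (1.5) so planted DEGs are recoverable by
    construction.
    """

    seed: int = 0
    n_genes: int = 200
    n_te: int = 60
    chrom_length: int | None = None  # None: derived from the packing
    n_samples_per_group: int = 4
    groups: tuple[tuple[str, str], ...] = (
        ("Ctrl", "0"), ("R", "23"), ("FR", "23"), ("R", "71"), ("FR", "71"),
    )
    nb_dispersion: float = 0.05
    base_meth: dict[str, float] = field(
        default_factory=lambda: {"CG": 0.7, "CHG": 0.5, "CHH": 0.1}
    )
    meth_coverage: float = 20.0
    planted_deg_frac: float = 0.3
    planted_log2fc_range: tuple[float, float] = (2.0, 3.0)
    n_planted_dmrs: int = 200
    dmr_effect: float = 0.4
    n_rddm_genes: int = 12
    #: with False, planted non-RdDM DMRs keep clear of every gene's body and
    #: promoter (a noise-controlled background: the only DMRs at FR-DEGs are
    #: the planted RdDM ones)
    background_dmrs_at_degs: bool = True
    # genome layout
    island_len: int = 150
    spacer_len: int = 400
    gene_units: int = 3
    gap_units: int = 5
    n_extra_units: int = 600
    # sRNA layout
    srna_shift_fold: float = 4.0
    srna_dispersion: float = 0.1
    n_mirna_families: int = 16
    n_bins: int = 30

    def validate(self) -> None:
        if self.planted_log2fc_range[0] < 1.5:
            raise ValueError("planted_log2fc_range lower bound must be >= the DEG gate (1.5)")
        if not 0 <= self.planted_deg_frac <= 1:
            raise ValueError("planted_deg_frac must lie in [0, 1]")
        if not 0 < self.dmr_effect <= 1:
            raise ValueError("dmr_effect must lie in (0, 1]")
        for ctx in ("CG", "CHG", "CHH"):
            if not 0 <= self.base_meth.get(ctx, -1) <= 1:
                raise ValueError(f"base_meth[{ctx}] must lie in [0, 1]")
        if self.nb_dispersion <= 0 or self.srna_dispersion <= 0:
            raise ValueError("dispersions must be positive")
        if not self.groups:
            raise ValueError("at least one sample group is required")
        if self.spacer_len <= 300:
            raise ValueError("spacer_len must exceed the DMR caller's default max_gap (300)")
        needed = self.required_length()
        if self.chrom_length is not None and self.chrom_length < needed:
            raise ValueError(
                f"chrom_length={self.chrom_length} cannot pack {self.n_genes} genes "
                f"(need >= {needed} bp); refusing to truncate"
            )

    @property
    def unit_len(self) -> int:
        return self.spacer_len + self.island_len

    @property
    def n_units(self) -> int:
        base = self.n_genes * (self.gene_units + self.gap_units) + self.n_extra_units
        if self.chrom_length is not None:
            return max(base, self.chrom_length // self.unit_len)
        return base

    def required_length(self) -> int:
        return (self.n_genes * (self.gene_units + self.gap_units) + self.n_extra_units) * self.unit_len

    def group_labels(self) -> list[str]:
        return [f"{c}_{t}" for c, t in self.groups]


@dataclass
class GroundTruth:
    """Planted signals, keyed by generated identifiers only."""

    deg_labels: dict[str, dict]  # gene -> {direction, archetype, log2fc}
    dmr_intervals: list[dict]  # chrom/start/end/context/direction/effect/island
    srna_shifts: dict[str, dict[int, str]]  # island -> {size: up/down}
    rddm_genes: dict[str, dict]  # gene -> {meth, srna, expr, dmr_index}
    hub_genes: list[str]
    mirna_de: dict[str, str] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["srna_shifts"] = {
            k: {str(s): d for s, d in v.items()} for k, v in self.srna_shifts.items()
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        payload["srna_shifts"] = {
            k: {int(s): d for s, d in v.items()} for k, v in payload["srna_shifts"].items()
        }
        return cls(**payload)

    def fr_deg_truth(self) -> dict[str, str]:
        """Genes with a genuine FR-vs-R response and its direction."""
        return {
            g: lab["direction"]
            for g, lab in self.deg_labels.items()
            if lab["direction"] in ("up", "down")
        }


# ---------------------------------------------------------------------------
# annotation + genome


def simulate_annotation(config: SimulationConfig):
    """Build the island-lattice chromosome, gene models and TEs.

    Returns ``(annotation, genome, islands)`` where ``islands`` is a frame
    of the cytosine-island intervals (the DMR candidate lattice).
    """
    config.validate()
    rng = np.random.default_rng([config.seed, _STREAM_ANNOTATION])
    L, n_units = config.unit_len, config.n_units
    chrom = "chr1"
    chrom_len = n_units * L

    # genome: A/T spacers + random-ACGT islands
    bases = np.empty(chrom_len, dtype="<U1")
    spacer_pool = np.array(list("AT"))
    island_pool = np.array(list("ACGT"))
    for u in range(n_units):
        s0 = u * L
        bases[s0 : s0 + config.spacer_len] = spacer_pool[
            rng.integers(0, 2, config.spacer_len)
        ]
        bases[s0 + config.spacer_len : s0 + L] = island_pool[
            rng.integers(0, 4, config.island_len)
        ]
    genome = {chrom: "".join(bases)}

    islands = pd.DataFrame(
        {
            "name": [f"island_{u:05d}" for u in range(n_units)],
            "chrom": chrom,
            "start": [u * L + config.spacer_len for u in range(n_units)],
            "end": [(u + 1) * L for u in range(n_units)],
        }
    )[["chrom", "start", "end", "name"]]

    rows = []
    stride = config.gene_units + config.gap_units
    for g in range(config.n_genes):
        gid = f"gene_{g:04d}"
        single_exon = g % 5 == 4
        n_body_units = 1 if single_exon else config.gene_units
        u0 = g * stride + config.gap_units
        start = u0 * L + config.spacer_len
        end = (u0 + n_body_units - 1) * L + config.spacer_len + config.island_len
        strand = "+" if g % 2 == 0 else "-"
        rows.append(dict(feature_id=gid, chrom=chrom, start=start, end=end,
                         strand=strand, ftype="gene", parent=None))
        if single_exon:
            rows.append(dict(feature_id=f"{gid}.exon1", chrom=chrom, start=start, end=end,
                             strand=strand, ftype="exon", parent=gid))
        else:
            rows.append(dict(feature_id=f"{gid}.exon1", chrom=chrom, start=start,
                             end=start + config.island_len, strand=strand, ftype="exon", parent=gid))
            rows.append(dict(feature_id=f"{gid}.exon2", chrom=chrom,
                             start=end - config.island_len, end=end, strand=strand,
                             ftype="exon", parent=gid))
    gene_spans = [(r["start"], r["end"]) for r in rows if r["ftype"] == "gene"]
    for t in range(config.n_te):
        length = int(rng.integers(300, 801))
        if t % 2 == 0 and gene_spans:  # overlap a gene body to exercise "both"
            gs, ge = gene_spans[int(rng.integers(len(gene_spans)))]
            start = int(rng.integers(gs, max(gs + 1, ge - 50)))
        else:
            start = int(rng.integers(0, chrom_len - length))
        rows.append(dict(feature_id=f"te_{t:03d}", chrom=chrom, start=start,
                         end=min(start + length, chrom_len), strand="+",
                         ftype="TE", parent=None))
    features = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    annotation = AnnotationSet.build(features, {chrom: chrom_len})
    return annotation, genome, islands


_COMP = str.maketrans("ACGT", "TGCA")


def cytosine_sites(genome: dict[str, str]) -> pd.DataFrame:
    """All cytosines in the genome (both strands) with context and
    trinucleotide, vectorized.  Bases beyond a contig end count as H."""
    frames = []
    for chrom in sorted(genome):
        seq = genome[chrom]
        arr = np.frombuffer(seq.encode(), dtype="S1")
        for strand in "+-":
            if strand == "+":
                idx = np.flatnonzero(arr == b"C")
                b1 = np.full(idx.shape, b"N", dtype="S1")
                b2 = np.full(idx.shape, b"N", dtype="S1")
                ok1, ok2 = idx + 1 < len(arr), idx + 2 < len(arr)
                b1[ok1] = arr[idx[ok1] + 1]
                b2[ok2] = arr[idx[ok2] + 2]
                is_g1, is_g2 = b1 == b"G", b2 == b"G"
                tri = [seq[i : i + 3].ljust(3, "N") for i in idx]
            else:
                idx = np.flatnonzero(arr == b"G")
                b1 = np.full(idx.shape, b"N", dtype="S1")
                b2 = np.full(idx.shape, b"N", dtype="S1")
                ok1, ok2 = idx - 1 >= 0, idx - 2 >= 0
                b1[ok1] = arr[idx[ok1] - 1]
                b2[ok2] = arr[idx[ok2] - 2]
                is_g1, is_g2 = b1 == b"C", b2 == b"C"  # complement of C is G
                tri = [
                    seq[max(i - 2, 0) : i + 1].rjust(3, "N")[::-1].translate(_COMP)
                    for i in idx
                ]
            context = np.where(is_g1, "CG", np.where(is_g2, "CHG", "CHH"))
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": idx,
                        "strand": strand,
                        "context": context,
                        "trinucleotide": tri,
                    }
                )
            )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["chrom", "pos", "strand"], ignore_index=True)


# ---------------------------------------------------------------------------
# truth planting


def _island_context_counts(sites: pd.DataFrame, islands: pd.DataFrame) -> pd.DataFrame:
    """Per-island site counts per context (islands are non-overlapping)."""
    edges = islands["start"].to_numpy()
    pos = sites["pos"].to_numpy()
    unit = np.searchsorted(edges, pos, side="right") - 1
    inside = (unit >= 0) & (pos < islands["end"].to_numpy()[np.clip(unit, 0, None)])
    tab = (
        pd.DataFrame({"island": islands["name"].to_numpy()[unit[inside]],
                      "context": sites["context"].to_numpy()[inside]})
        .value_counts()
        .unstack(fill_value=0)
    )
    return tab.reindex(islands["name"], fill_value=0)


def make_truth(
    config: SimulationConfig,
    annotation: AnnotationSet,
    islands: pd.DataFrame,
    genome: dict[str, str],
) -> GroundTruth:
    """Plant DEG archetypes, DMRs, sRNA shifts and RdDM-consistent genes."""
    rng = np.random.default_rng([config.seed, _STREAM_TRUTH])
    genes = annotation.genes()
    gene_ids = list(genes.index)

    # --- DEGs: archetypes assigned round-robin over a shuffled gene sample
    n_deg = int(round(config.planted_deg_frac * config.n_genes))
    deg_genes = sorted(rng.choice(gene_ids, size=n_deg, replace=False))
    order = rng.permutation(n_deg)
    lo, hi = config.planted_log2fc_range
    deg_labels = {}
    for rank, gi in enumerate(order):
        arch = rank % len(ARCHETYPES)
        deg_labels[deg_genes[gi]] = dict(
            direction=ARCHETYPE_FR_DIRECTION[arch],
            archetype=arch,
            log2fc=float(rng.uniform(lo, hi)),
        )

    sites = cytosine_sites(genome)
    counts_tab = _island_context_counts(sites, islands)
    island_iv = islands.set_index("name")

    def islands_overlapping(start: int, end: int) -> list[str]:
        sel = (island_iv["start"] < end) & (island_iv["end"] > start)
        return list(island_iv.index[sel])

    promoters = annotation.of_type("promoter").set_index("parent")

    # --- RdDM genes: expression down + hypermethylated DMR + sRNA up, or
    #     the mirrored triple.  Drawn from genuinely FR-responsive archetypes.
    down_pool = sorted(g for g, l in deg_labels.items() if l["archetype"] in (3, 4, 5))
    up_pool = sorted(g for g, l in deg_labels.items() if l["archetype"] in (0, 1, 2))
    n_hyper = config.n_rddm_genes // 2
    n_hypo = config.n_rddm_genes - n_hyper
    if len(down_pool) < n_hyper or len(up_pool) < n_hypo:
        raise ValueError("not enough planted FR-responsive genes to host RdDM signals")
    rddm_spec = [(g, "hyper") for g in down_pool[:n_hyper]] + [
        (g, "hypo") for g in up_pool[:n_hypo]
    ]

    context_pool = np.array(["CHH", "CG", "CHG"])
    context_w = np.array([0.8, 0.1, 0.1])
    min_sites = 8

    # islands touched by each gene's body or promoter; RdDM islands must be
    # private to their gene so the planted (gene, DMR) pair is unambiguous
    island_hosts: dict[str, set[str]] = {}
    for gid in gene_ids:
        g = genes.loc[gid]
        touched = set(islands_overlapping(int(g["start"]), int(g["end"])))
        if gid in promoters.index:
            prom = promoters.loc[gid]
            touched |= set(islands_overlapping(int(prom["start"]), int(prom["end"])))
        for isl in touched:
            island_hosts.setdefault(isl, set()).add(gid)

    used_islands: set[str] = set()
    dmr_intervals: list[dict] = []
    srna_shifts: dict[str, dict[int, str]] = {}
    rddm_genes: dict[str, dict] = {}

    def effective_effect(context: str, direction: str) -> float:
        base = config.base_meth[context]
        shifted = min(1.0, max(0.0, base + config.dmr_effect))
        eff = shifted - base
        return eff if direction == "hyper" else -eff

    def pick_context(island: str) -> str:
        for ctx in rng.choice(context_pool, size=3, replace=False, p=context_w):
            if counts_tab.loc[island, ctx] >= min_sites:
                return str(ctx)
        return "CHH"

    for gene, direction in rddm_spec:
        cand = [
            c
            for c in sorted(isl for isl, hosts in island_hosts.items() if hosts == {gene})
            if c not in used_islands and counts_tab.loc[c, "CHH"] >= min_sites
        ]
        if not cand:
            raise ValueError(f"no free cytosine island near RdDM gene {gene}")
        island = cand[int(rng.integers(len(cand)))]
        used_islands.add(island)
        ctx = pick_context(island)
        iv = island_iv.loc[island]
        dmr_intervals.append(
            dict(chrom=iv["chrom"], start=int(iv["start"]), end=int(iv["end"]),
                 context=ctx, direction=direction,
                 effect=effective_effect(ctx, direction), island=island)
        )
        srna_dir = "up" if direction == "hyper" else "down"
        srna_shifts[island] = {21: srna_dir, 22: srna_dir, 24: srna_dir}
        rddm_genes[gene] = dict(
            meth=direction,
            srna=srna_dir,
            expr=deg_labels[gene]["direction"],
            dmr_index=len(dmr_intervals) - 1,
        )

    # --- remaining planted DMRs on free islands (anywhere by default;
    #     intergenic-only under the noise-controlled background)
    n_left = config.n_planted_dmrs - len(dmr_intervals)
    free = [
        c for c in islands["name"]
        if c not in used_islands
        and counts_tab.loc[c, "CHH"] >= min_sites
        and (config.background_dmrs_at_degs or c not in island_hosts)
    ]
    if len(free) < n_left:
        raise ValueError("not enough free islands for the requested planted DMRs")
    chosen = rng.choice(free, size=n_left, replace=False)
    for island in chosen:
        used_islands.add(island)
        ctx = pick_context(island)
        direction = "hyper" if rng.random() < 0.5 else "hypo"
        iv = island_iv.loc[island]
        dmr_intervals.append(
            dict(chrom=iv["chrom"], start=int(iv["start"]), end=int(iv["end"]),
                 context=ctx, direction=direction,
                 effect=effective_effect(ctx, direction), island=island)
        )

    # a few decoy sRNA shifts away from genes and planted DMRs
    decoys = [c for c in islands["name"] if c not in used_islands and c not in island_hosts][:5]
    for island in decoys:
        srna_shifts[island] = {24: "up"}

    # --- hub genes: one planted FR-up, one planted FR-down
    hub_genes = []
    if up_pool:
        hub_genes.append(up_pool[-1])
    if down_pool:
        hub_genes.append(down_pool[-1])

    return GroundTruth(
        deg_labels=deg_labels,
        dmr_intervals=dmr_intervals,
        srna_shifts=srna_shifts,
        rddm_genes=rddm_genes,
        hub_genes=hub_genes,
    )


# ---------------------------------------------------------------------------
# counts


def make_sample_sheet(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for cond, tp in config.groups:
        for r in range(config.n_samples_per_group):
            rows.append(dict(sample_id=f"{cond}{tp}_r{r + 1}", condition=cond,
                             timepoint=str(tp), replicate=r + 1))
    return pd.DataFrame(rows)


def _nb(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + np.asarray(mean, dtype=float)))


def simulate_counts(
    config: SimulationConfig,
    annotation: AnnotationSet,
    truth: GroundTruth,
):
    """Negative-binomial gene counts per sample.

    Planted DEGs scale their group means by 2^(+-log2fc) following their
    archetype; non-DEGs share one mean across groups.  Planted genes draw
    their baseline from a narrower, higher-expression distribution so the
    planted effect is recoverable at the study's replicate number.
    Returns ``(counts, lengths, sample_sheet)``.
    """
    rng = np.random.default_rng([config.seed, _STREAM_COUNTS])
    genes = annotation.genes()
    gene_ids = list(genes.index)
    exons = annotation.of_type("exon")
    lengths = (
        (exons["end"] - exons["start"]).groupby(exons["parent"]).sum().reindex(gene_ids)
    ).rename("length")

    base = rng.lognormal(np.log(100.0), 1.0, len(gene_ids))
    sheet = make_sample_sheet(config)
    cols = {}
    for _, sample in sheet.iterrows():
        group = f"{sample['condition']}_{sample['timepoint']}"
        mu = base.copy()
        for i, gid in enumerate(gene_ids):
            lab = truth.deg_labels.get(gid)
            if lab is None:
                continue
            mu[i] = max(mu[i], 50.0)  # recoverable baseline for planted genes
            coef = ARCHETYPES[lab["archetype"]].get(group, 0)
            mu[i] *= 2.0 ** (coef * lab["log2fc"])
        cols[sample["sample_id"]] = _nb(rng, mu, config.nb_dispersion)
    counts = pd.DataFrame(cols, index=gene_ids)
    return counts, lengths, sheet


# ---------------------------------------------------------------------------
# methylome


def simulate_methylome(
    config: SimulationConfig,
    genome: dict[str, str],
    truth: GroundTruth,
):
    """Per-cytosine reports for the pooled R and FR groups (day-3).

    Coverage is Poisson(meth_coverage) per condition; methylated counts are
    Binomial(coverage, level).  Inside a planted DMR the shifted condition
    (FR for hyper, R for hypo — so hypomethylation under FR has headroom in
    every context) moves by the clipped effect, for the DMR's context only.
    Zero-coverage sites are emitted as 0/0.  Returns ``(records_R,
    records_FR)``.
    """
    rng = np.random.default_rng([config.seed, _STREAM_METHYLOME])
    sites = cytosine_sites(genome)
    n = len(sites)
    base = sites["context"].map(config.base_meth).to_numpy(dtype=float)
    level_R = base.copy()
    level_FR = base.copy()
    pos = sites["pos"].to_numpy()
    chroms = sites["chrom"].to_numpy()
    ctx = sites["context"].to_numpy()
    for dmr in truth.dmr_intervals:
        mask = (
            (chroms == dmr["chrom"])
            & (pos >= dmr["start"])
            & (pos < dmr["end"])
            & (ctx == dmr["context"])
        )
        if dmr["direction"] == "hyper":
            level_FR[mask] = np.clip(level_FR[mask] + abs(dmr["effect"]), 0.0, 1.0)
        else:
            level_R[mask] = np.clip(level_R[mask] + abs(dmr["effect"]), 0.0, 1.0)

    out = []
    for level in (level_R, level_FR):
        cov = rng.poisson(config.meth_coverage, n)
        meth = rng.binomial(cov, level)
        rec = sites.copy()
        rec["count_methylated"] = meth
        rec["count_unmethylated"] = cov - meth
        out.append(rec[["chrom", "pos", "strand", "count_methylated",
                        "count_unmethylated", "context", "trinucleotide"]])
    return out[0], out[1]


# ---------------------------------------------------------------------------
# sRNAs


#: per-size-class baseline abundance weights (arbitrary units) peaking at
#: 24 nt with secondary 21/22-nt classes, as in plant sRNA libraries
SIZE_WEIGHTS = {18: 4, 19: 4, 20: 6, 21: 15, 22: 12, 23: 6, 24: 30, 25: 8, 26: 5, 27: 4, 28: 4}


def simulate_srna(
    config: SimulationConfig,
    islands: pd.DataFrame,
    truth: GroundTruth,
    sample_sheet: pd.DataFrame,
) -> SRNAProfile:
    """Per-locus, per-size-class sRNA counts for the day-3 R and FR samples.

    Loci are the cytosine islands.  Islands flagged in the planted shift
    labels scale their FR means by the shift fold (up) or its inverse
    (down) in the 21/22/24-nt classes.  Library totals are the per-sample
    column sums, so category/locus counts conserve the library total by
    construction.
    """
    rng = np.random.default_rng([config.seed, _STREAM_SRNA])
    day3 = sample_sheet[
        (sample_sheet["timepoint"] == "71") & sample_sheet["condition"].isin(["R", "FR"])
    ]
    if day3.empty:
        raise ValueError("sRNA simulation needs day-3 (71 h) R and FR samples")
    names = islands["name"].tolist()
    scale = rng.lognormal(0.0, 0.5, len(names))
    index = pd.MultiIndex.from_product([names, SIZE_CLASSES], names=["locus", "size"])
    cols = {}
    for _, sample in day3.iterrows():
        mu = np.empty(len(index))
        k = 0
        for i, locus in enumerate(names):
            shifts = truth.srna_shifts.get(locus, {})
            for size in SIZE_CLASSES:
                m = SIZE_WEIGHTS[size] * scale[i]
                d = shifts.get(size)
                if d and sample["condition"] == "FR":
                    m *= config.srna_shift_fold if d == "up" else 1.0 / config.srna_shift_fold
                mu[k] = m
                k += 1
        cols[sample["sample_id"]] = _nb(rng, mu, config.srna_dispersion)
    counts = pd.DataFrame(cols, index=index)
    return SRNAProfile(
        counts=counts,
        library_totals=counts.sum(axis=0),
        loci=islands.copy(),
    )


# ---------------------------------------------------------------------------
# miRNA families, targets and functional bins (auxiliary inputs)


def simulate_mirna(
    config: SimulationConfig,
    truth: GroundTruth,
    sample_sheet: pd.DataFrame,
):
    """Family-level miRNA counts, a family->target map, and planted
    differential families (mostly down under FR, a couple up)."""
    rng = np.random.default_rng([config.seed, _STREAM_MIRNA])
    n_fam = config.n_mirna_families
    families = [f"miRfam_{i:02d}" for i in range(n_fam)]
    conserved = {fam: i < int(0.7 * n_fam) for i, fam in enumerate(families)}
    day3 = sample_sheet[
        (sample_sheet["timepoint"] == "71") & sample_sheet["condition"].isin(["R", "FR"])
    ]
    n_de = min(6, n_fam)
    de_dirs = {families[i]: ("down" if i % 3 else "up") for i in range(n_de)}
    base = rng.lognormal(np.log(300.0), 0.5, n_fam)
    cols = {}
    for _, sample in day3.iterrows():
        mu = base.copy()
        for i, fam in enumerate(families):
            d = de_dirs.get(fam)
            if d and sample["condition"] == "FR":
                mu[i] *= 4.0 if d == "up" else 0.25
        cols[sample["sample_id"]] = _nb(rng, mu, config.nb_dispersion)
    counts = pd.DataFrame(cols, index=families)

    fr_truth = truth.fr_deg_truth()
    fr_up = sorted(g for g, d in fr_truth.items() if d == "up")
    fr_down = sorted(g for g, d in fr_truth.items() if d == "down")
    rows = []
    for i, fam in enumerate(families):
        d = de_dirs.get(fam)
        if d == "down" and fr_up:
            rows.append(dict(family=fam, gene_id=fr_up[i % len(fr_up)]))
        elif d == "up" and fr_down:
            rows.append(dict(family=fam, gene_id=fr_down[i % len(fr_down)]))
        rows.append(dict(family=fam, gene_id=f"gene_{int(rng.integers(0, config.n_genes)):04d}"))
    targets = pd.DataFrame(rows).drop_duplicates(ignore_index=True)
    truth.mirna_de = de_dirs
    meta = pd.DataFrame({"family": families, "conserved": [conserved[f] for f in families]})
    return counts, targets, meta


def simulate_bins(config: SimulationConfig, truth: GroundTruth) -> pd.DataFrame:
    """Synthetic gene -> functional-bin map with one bin enriched among the
    planted FR-upregulated genes."""
    rng = np.random.default_rng([config.seed, _STREAM_BINS])
    gene_ids = [f"gene_{i:04d}" for i in range(config.n_genes)]
    bins = [f"bin_{i:02d}" for i in range(config.n_bins)]
    rows = []
    for gid in gene_ids:
        for b in rng.choice(config.n_bins, size=int(rng.integers(1, 3)), replace=False):
            rows.append(dict(gene_id=gid, bin_id=bins[b], bin_name=f"category {b}", level=1))
    fr_up = sorted(g for g, d in truth.fr_deg_truth().items() if d == "up")
    planted_bin = "bin_photomorphogenesis"
    for gid in fr_up:
        if rng.random() < 0.7:
            rows.append(dict(gene_id=gid, bin_id=planted_bin, bin_name="photomorphogenesis", level=1))
    for gid in gene_ids:
        if gid not in fr_up and rng.random() < 0.02:
            rows.append(dict(gene_id=gid, bin_id=planted_bin, bin_name="photomorphogenesis", level=1))
    return pd.DataFrame(rows).drop_duplicates(["gene_id", "bin_id"], ignore_index=True)


# ---------------------------------------------------------------------------
# bundle


@dataclass
class SimulatedExperiment:
    """Everything one in-silico experiment produced, plus its truth."""

    config: SimulationConfig
    annotation: AnnotationSet
    genome: dict[str, str]
    islands: pd.DataFrame
    truth: GroundTruth
    sample_sheet: pd.DataFrame
    counts: pd.DataFrame
    lengths: pd.Series
    records_R: pd.DataFrame
    records_FR: pd.DataFrame
    srna: SRNAProfile
    mirna_counts: pd.DataFrame
    mirna_targets: pd.DataFrame
    mirna_meta: pd.DataFrame
    bin_map: pd.DataFrame

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome, out / "genome.fa")
        write_gff3(self.annotation, out / "annotation.gff3")
        write_sample_sheet(self.sample_sheet, out / "samples.tsv")
        write_counts(self.counts, self.lengths, out / "counts.tsv")
        write_cytosine_report(self.records_R, out / "cytosines_R.tsv")
        write_cytosine_report(self.records_FR, out / "cytosines_FR.tsv")
        write_bed6(self.islands, out / "srna_loci.bed")
        srna_long = self.srna.counts.reset_index().sort_values(["locus", "size"])
        srna_long.to_csv(out / "srna_counts.tsv", sep="\t", index=False)
        self.mirna_counts.sort_index().to_csv(out / "mirna_counts.tsv", sep="\t", index_label="family")
        self.mirna_targets.sort_values(["family", "gene_id"]).to_csv(
            out / "mirna_targets.tsv", sep="\t", index=False
        )
        self.mirna_meta.to_csv(out / "mirna_families.tsv", sep="\t", index=False)
        self.bin_map.sort_values(["gene_id", "bin_id"]).to_csv(out / "bins.tsv", sep="\t", index=False)
        self.truth.to_json(out / "truth.json")


def simulate_all(config: SimulationConfig | None = None, outdir=None) -> SimulatedExperiment:
    """Run every generator in its fixed stream order and optionally write
    the full experiment to ``outdir``."""
    config = config or SimulationConfig()
    config.validate()
    annotation, genome, islands = simulate_annotation(config)
    truth = make_truth(config, annotation, islands, genome)
    counts, lengths, sheet = simulate_counts(config, annotation, truth)
    records_R, records_FR = simulate_methylome(config, genome, truth)
    srna = simulate_srna(config, islands, truth, sheet)
    mirna_counts, mirna_targets, mirna_meta = simulate_mirna(config, truth, sheet)
    bin_map = simulate_bins(config, truth)
    exp = SimulatedExperiment(
        config=config, annotation=annotation, genome=genome, islands=islands,
        truth=truth, sample_sheet=sheet, counts=counts, lengths=lengths,
        records_R=records_R, records_FR=records_FR, srna=srna,
        mirna_counts=mirna_counts, mirna_targets=mirna_targets,
        mirna_meta=mirna_meta, bin_map=bin_map,
    )
    if outdir is not None:
        exp.write(outdir)
    return exp
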