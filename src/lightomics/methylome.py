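"""DNA methylome analysis: contexts, profiles and DMR calling.

Methylation level of a cytosine is methylated/(methylated+unmethylated)
reads; contexts are CG, CHG and CHH (H = A, C or T), read 5'->3' on the
cytosine's strand.  Differentially methylated regions between the R and FR
light treatments are called on gap-bounded runs of covered same-context
cytosines: per-cytosine levels (replicate-pooled per condition) are
compared with a Mann-Whitney U test, BH-corrected across candidate regions
per context, and a region is reported as a DMR only when it has more than
5 cytosines, an absolute pooled methylation difference above 0.1 and
q < 0.05.  The direction convention is fixed: hypermethylated means higher
methylation under FR than under R light.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .enrichment import bh_adjust
from .io import AnnotationSet

__all__ = [
    "assign_context",
    "methylation_level",
    "global_methylation",
    "metagene_profile",
    "call_dmrs",
    "classify_direction",
    "overlap_features",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def assign_context(genome: dict[str, str], chrom: str, pos: int, strand: str) -> tuple[str, bool]:
    """Methylation context of the cytosine at (chrom, pos, strand).

    Returns ``(context, ambiguous)``.  The context comes from the two bases
    downstream of the cytosine on its own strand: CG if the next base is G,
    CHG if the next is H and the second G, else CHH.  Near a contig end the
    context is derived from the available bases: CG is decidable from one
    base; otherwise CHH is returned flagged ambiguous.
    """
    seq = genome[chrom]
    if strand == "+":
        if seq[pos] != "C":
            raise ValueError(f"{chrom}:{pos}(+) is {seq[pos]}, not C")
        b1 = seq[pos + 1] if pos + 1 < len(seq) else None
        b2 = seq[pos + 2] if pos + 2 < len(seq) else None
    elif strand == "-":
        if seq[pos] != "G":
            raise ValueError(f"{chrom}:{pos}(-) is {seq[pos]}, not G (C on minus strand)")
        b1 = seq[pos - 1].translate(_COMPLEMENT) if pos - 1 >= 0 else None
        b2 = seq[pos - 2].translate(_COMPLEMENT) if pos - 2 >= 0 else None
    else:
        raise ValueError(f"unknown strand {strand!r}")
    if b1 == "G":
        return "CG", False
    if b1 is None:
        return "CHH", True
    if b2 == "G":
        return "CHG", False
    if b2 is None:
        return "CHH", True
    return "CHH", False


def methylation_level(m, u):
    """m/(m+u); NaN (missing) when the site has no coverage."""
    m = np.asarray(m, dtype=float)
    u = np.asarray(u, dtype=float)
    cov = m + u
    with np.errstate(divide="ignore", invalid="ignore"):
        lev = np.where(cov > 0, m / np.where(cov > 0, cov, 1.0), np.nan)
    return float(lev) if lev.ndim == 0 else lev


def global_methylation(records: pd.DataFrame, context: str | None = None):
    """Pooled-count global methylation: sum(m) / sum(m+u) over covered
    cytosines, per context (dict) or for one requested context (float)."""
    if context is not None:
        sub = records[records["context"] == context]
        cov = sub["count_methylated"] + sub["count_unmethylated"]
        total = int(cov.sum())
        if total == 0:
            raise ValueError(f"no covered cytosines in context {context}")
        return float(sub["count_methylated"].sum() / total)
    return {ctx: global_methylation(records, ctx) for ctx in sorted(records["context"].unique())}


def metagene_profile(
    records: pd.DataFrame,
    annotation: AnnotationSet,
    *,
    flank: int = 2000,
    bins_per_segment: int = 20,
) -> pd.DataFrame:
    """Pooled metagene methylation profile (upstream / body / downstream).

    Each gene body is rescaled to ``bins_per_segment`` bins; the 2-kb
    flanks are binned at fixed width.  Minus-strand genes are mirrored so
    bin 0 is always the far upstream end.  Per (bin, context) the pooled
    level sum(m)/sum(cov) over all genes is reported.  Genes shorter than
    ``bins_per_segment`` bp are skipped; their count is stored in
    ``df.attrs['n_skipped']``.
    """
    B = bins_per_segment
    contexts = sorted(records["context"].unique())
    ctx_index = {c: i for i, c in enumerate(contexts)}
    m_acc = np.zeros((len(contexts), 3 * B))
    cov_acc = np.zeros((len(contexts), 3 * B))

    by_chrom = {}
    for chrom, sub in records.groupby("chrom"):
        sub = sub.sort_values("pos")
        by_chrom[chrom] = (
            sub["pos"].to_numpy(),
            sub["count_methylated"].to_numpy(float),
            (sub["count_methylated"] + sub["count_unmethylated"]).to_numpy(float),
            np.array([ctx_index[c] for c in sub["context"]]),
        )

    n_skipped = 0
    for gid, gene in annotation.genes().iterrows():
        length = int(gene["end"] - gene["start"])
        if length < B:
            n_skipped += 1
            continue
        if gene["chrom"] not in by_chrom:
            continue
        pos, m, cov, ctx = by_chrom[gene["chrom"]]
        lo = np.searchsorted(pos, gene["start"] - flank)
        hi = np.searchsorted(pos, gene["end"] + flank)
        if lo == hi:
            continue
        p = pos[lo:hi].astype(np.int64)
        if gene["strand"] == "-":
            # mirror so that the profile is strand-symmetric bit for bit
            p = (gene["start"] - flank) + (gene["end"] + flank - 1 - p)
        rel = p - (gene["start"] - flank)
        seg_bins = np.empty(rel.shape, dtype=np.int64)
        upstream = rel < flank
        body = (rel >= flank) & (rel < flank + length)
        downstream = rel >= flank + length
        seg_bins[upstream] = rel[upstream] * B // flank
        seg_bins[body] = B + (rel[body] - flank) * B // length
        seg_bins[downstream] = 2 * B + (rel[downstream] - flank - length) * B // flank
        np.add.at(m_acc, (ctx[lo:hi], np.clip(seg_bins, 0, 3 * B - 1)), m[lo:hi])
        np.add.at(cov_acc, (ctx[lo:hi], np.clip(seg_bins, 0, 3 * B - 1)), cov[lo:hi])

    rows = []
    segments = ["upstream"] * B + ["body"] * B + ["downstream"] * B
    for c, ctx_name in enumerate(contexts):
        for b in range(3 * B):
            level = m_acc[c, b] / cov_acc[c, b] if cov_acc[c, b] > 0 else np.nan
            rows.append(dict(context=ctx_name, bin=b, segment=segments[b], level=level))
    out = pd.DataFrame(rows)
    out.attrs["n_skipped"] = n_skipped
    return out


def _pooled_level(m: np.ndarray, u: np.ndarray) -> float:
    cov = m.sum() + u.sum()
    return float(m.sum() / cov) if cov > 0 else float("nan")


def call_dmrs(
    records_R: pd.DataFrame,
    records_FR: pd.DataFrame,
    context: str,
    *,
    max_gap: int = 300,
    min_c: int = 6,
    min_diff: float = 0.1,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Call differentially methylated regions for one context.

    Candidate regions are maximal runs of cytosines of the requested
    context covered in both conditions, with inter-cytosine gaps of at
    most ``max_gap`` bp.  Regions with at least ``min_c`` cytosines are
    tested (per-site FR vs R levels, two-sided Mann-Whitney U) and
    BH-corrected; reported DMRs additionally satisfy
    |pooled level difference| > ``min_diff`` and q < ``alpha``.
    diff is FR - R; direction "hyper" means diff > 0.
    """
    key = ["chrom", "pos", "strand"]
    r = records_R[records_R["context"] == context]
    f = records_FR[records_FR["context"] == context]
    merged = r.merge(f, on=key, suffixes=("_r", "_f"))
    merged = merged[
        (merged["count_methylated_r"] + merged["count_unmethylated_r"] > 0)
        & (merged["count_methylated_f"] + merged["count_unmethylated_f"] > 0)
    ].sort_values(["chrom", "pos"], kind="mergesort")
    if merged.empty:
        return _empty_dmr_frame()

    chroms = merged["chrom"].to_numpy()
    pos = merged["pos"].to_numpy()
    new_run = np.ones(len(merged), dtype=bool)
    new_run[1:] = (chroms[1:] != chroms[:-1]) | (np.diff(pos) > max_gap)
    run_id = np.cumsum(new_run)

    mr = merged["count_methylated_r"].to_numpy(float)
    ur = merged["count_unmethylated_r"].to_numpy(float)
    mf = merged["count_methylated_f"].to_numpy(float)
    uf = merged["count_unmethylated_f"].to_numpy(float)
    lev_r = mr / (mr + ur)
    lev_f = mf / (mf + uf)

    rows = []
    order = pd.DataFrame({"run": run_id}).groupby("run").indices
    for run, idx in order.items():
        if len(idx) < min_c:
            continue
        lr, lf = lev_r[idx], lev_f[idx]
        if np.all(lr == lf) or (np.unique(np.concatenate([lr, lf])).size == 1):
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(lf, lr, alternative="two-sided").pvalue)
        diff = _pooled_level(mf[idx], uf[idx]) - _pooled_level(mr[idx], ur[idx])
        rows.append(
            dict(
                chrom=chroms[idx[0]],
                start=int(pos[idx[0]]),
                end=int(pos[idx[-1]]) + 1,
                context=context,
                n_cytosines=len(idx),
                mean_level_R=_pooled_level(mr[idx], ur[idx]),
                mean_level_FR=_pooled_level(mf[idx], uf[idx]),
                diff=diff,
                p=p,
            )
        )
    if not rows:
        return _empty_dmr_frame()
    cand = pd.DataFrame(rows)
    cand["q"] = bh_adjust(cand["p"].to_numpy())
    dmrs = cand[
        (cand["n_cytosines"] > min_c - 1)
        & (cand["diff"].abs() > min_diff)
        & (cand["q"] < alpha)
    ].copy()
    dmrs["direction"] = np.where(dmrs["diff"] > 0, "hyper", "hypo")
    dmrs = dmrs.sort_values(["chrom", "start"], ignore_index=True)
    dmrs.insert(0, "dmr_id", [f"dmr_{context}_{i:05d}" for i in range(len(dmrs))])
    dmrs.attrs["n_candidates"] = len(cand)
    return dmrs


def _empty_dmr_frame() -> pd.DataFrame:
    out = pd.DataFrame(
        columns=[
            "dmr_id",
            "chrom",
            "start",
            "end",
            "context",
            "n_cytosines",
            "mean_level_R",
            "mean_level_FR",
            "diff",
            "p",
            "q",
            "direction",
        ]
    )
    out.attrs["n_candidates"] = 0
    return out


def classify_direction(diff: float) -> str:
    """hyper iff FR - R methylation difference is positive."""
    if diff == 0:
        raise ValueError("direction undefined at zero difference")
    return "hyper" if diff > 0 else "hypo"


def overlap_features(
    dmrs: pd.DataFrame,
    annotation: AnnotationSet,
    min_overlap: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign every DMR its overlapping genomic features (>= 1 bp).

    Returns ``(assignments, classes)``: a long table with one row per
    (DMR, feature) overlap, and a per-DMR classification in
    {gene-only, TE-only, both, neither} based on gene-body vs TE overlap
    (a DMR may carry several feature labels).
    """
    trees = annotation.interval_tree("gene", "exon", "intron", "promoter", "TE")
    assign_rows = []
    class_rows = []
    for dmr in dmrs.itertuples(index=False):
        hits = trees.get(dmr.chrom, IntervalTree()).overlap(dmr.start, dmr.end)
        touches_gene = False
        touches_te = False
        for hit in hits:
            feat = hit.data
            ov = min(dmr.end, feat.end) - max(dmr.start, feat.start)
            if ov < min_overlap:
                continue
            if feat.ftype == "gene":
                touches_gene = True
            if feat.ftype == "TE":
                touches_te = True
            assign_rows.append(
                dict(
                    dmr_id=dmr.dmr_id,
                    feature_id=feat.feature_id,
                    ftype=feat.ftype,
                    parent=feat.parent if feat.parent else feat.feature_id,
                    overlap_bp=ov,
                )
            )
        cls = {
            (True, False): "gene-only",
            (False, True): "TE-only",
            (True, True): "both",
            (False, False): "neither",
        }[(touches_gene, touches_te)]
        class_rows.append(dict(dmr_id=dmr.dmr_id, feature_class=cls))
    assignments = pd.DataFrame(
        assign_rows, columns=["dmr_id", "feature_id", "ftype", "parent", "overlap_bp"]
    ).sort_values(["dmr_id", "feature_id"], ignore_index=True)
    classes = pd.DataFrame(class_rows, columns=["dmr_id", "feature_class"])
    return assignments, classes
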