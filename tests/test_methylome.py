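"""Context assignment, methylation levels, metagene profiles and DMRs."""

import numpy as np
import pandas as pd
import pytest

from lightomics.io import AnnotationSet
from lightomics.methylome import (
    assign_context,
    call_dmrs,
    classify_direction,
    global_methylation,
    metagene_profile,
    methylation_level,
    overlap_features,
)


class TestContext:
    def test_plus_strand_cg(self):
        assert assign_context({"c": "ACGTT"}, "c", 1, "+") == ("CG", False)

    def test_plus_strand_chg(self):
        assert assign_context({"c": "CAGTT"}, "c", 0, "+") == ("CHG", False)

    def test_minus_strand_reads_reverse_complement(self):
        # G at index 2 of ACGTT: minus-strand C whose downstream reads CG
        assert assign_context({"c": "ACGTT"}, "c", 2, "-") == ("CG", False)

    def test_contig_end_is_ambiguous_chh(self):
        ctx, ambiguous = assign_context({"c": "AAC"}, "c", 2, "+")
        assert ctx == "CHH" and ambiguous

    def test_cg_decidable_with_one_base(self):
        assert assign_context({"c": "ACG"}, "c", 1, "+") == ("CG", False)

    def test_non_cytosine_raises(self):
        with pytest.raises(ValueError):
            assign_context({"c": "AAA"}, "c", 0, "+")


class TestLevels:
    def test_simple_ratio_and_edge_cases(self):
        assert methylation_level(3, 7) == pytest.approx(0.3)
        assert methylation_level(5, 0) == pytest.approx(1.0)
        assert np.isnan(methylation_level(0, 0))

    def test_global_is_pooled_not_mean_of_levels(self):
        rec = pd.DataFrame({
            "context": ["CHH", "CHH"],
            "count_methylated": [1, 90],
            "count_unmethylated": [9, 10],
        })
        # pooled 91/110, while the mean of per-site levels would be 0.5
        assert global_methylation(rec, "CHH") == pytest.approx(91 / 110)
        rec2 = rec.assign(count_methylated=[1, 9], count_unmethylated=[9, 1])
        assert global_methylation(rec2, "CHH") == pytest.approx(0.5)

    def test_global_matches_bernoulli_truth(self):
        rng = np.random.default_rng(5)
        n = 4000
        cov = rng.poisson(10, n)
        m = rng.binomial(cov, 0.3)
        rec = pd.DataFrame({
            "context": "CHH", "count_methylated": m, "count_unmethylated": cov - m,
        })
        se = np.sqrt(0.3 * 0.7 / cov.sum())
        assert abs(global_methylation(rec, "CHH") - 0.3) < 3 * se


def _uniform_records(genome_len, level, seed=0, chrom="chr1", every=3):
    """Cytosine-like records every ``every`` bp at a fixed Bernoulli level."""
    rng = np.random.default_rng(seed)
    pos = np.arange(0, genome_len, every)
    cov = rng.poisson(20, len(pos))
    m = rng.binomial(cov, level)
    return pd.DataFrame({
        "chrom": chrom, "pos": pos, "strand": "+",
        "count_methylated": m, "count_unmethylated": cov - m,
        "context": "CHH", "trinucleotide": "CTT",
    })


def _gene_annotation(genes):
    rows = []
    for gid, (start, end, strand) in genes.items():
        rows.append(dict(feature_id=gid, chrom="chr1", start=start, end=end,
                         strand=strand, ftype="gene", parent=None))
        rows.append(dict(feature_id=f"{gid}.e", chrom="chr1", start=start, end=end,
                         strand=strand, ftype="exon", parent=gid))
    return AnnotationSet.build(pd.DataFrame(rows), {"chr1": 10**7})


class TestMetagene:
    def test_uniform_methylome_is_flat(self):
        rec = _uniform_records(120_000, 0.3)
        ann = _gene_annotation({f"g{i}": (10_000 + 20_000 * i, 14_000 + 20_000 * i, "+")
                                for i in range(5)})
        prof = metagene_profile(rec, ann)
        assert np.all(np.abs(prof["level"] - 0.3) < 0.02)

    def test_strand_reversal_symmetry_is_exact(self):
        """A minus-strand gene over the mirrored methylome yields the exact
        profile of the equivalent plus-strand gene."""
        L = 30_000
        rec = _uniform_records(L, 0.3, seed=3)
        # bias methylation toward low coordinates
        bias = rec["pos"] < 12_000
        rec.loc[bias, "count_methylated"] += 5
        mirrored = rec.copy()
        mirrored["pos"] = L - 1 - mirrored["pos"]
        plus = metagene_profile(rec, _gene_annotation({"g": (10_000, 14_000, "+")}))
        minus = metagene_profile(
            mirrored, _gene_annotation({"g": (L - 14_000, L - 10_000, "-")})
        )
        assert np.allclose(plus["level"], minus["level"], equal_nan=True)

    def test_short_genes_are_skipped_and_counted(self):
        rec = _uniform_records(1000, 0.3)
        ann = _gene_annotation({"tiny": (100, 110, "+"), "ok": (200, 400, "+")})
        prof = metagene_profile(rec, ann)
        assert prof.attrs["n_skipped"] == 1


def _sites(levels, cov, start=0, spacing=10, rng=None, exact=False):
    rows = []
    for i, level in enumerate(levels):
        c = cov if np.isscalar(cov) else cov[i]
        m = round(level * c) if exact else rng.binomial(c, level)
        rows.append(dict(chrom="chr1", pos=start + i * spacing, strand="+",
                         count_methylated=int(m), count_unmethylated=int(c - m),
                         context="CHH", trinucleotide="CAT"))
    return pd.DataFrame(rows)


class TestCallDMRs:
    def test_strong_shift_yields_one_hyper_dmr(self):
        rng = np.random.default_rng(0)
        rec_R = _sites([0.1] * 6, 50, rng=rng)
        rec_F = _sites([0.5] * 6, 50, rng=rng)
        dmrs = call_dmrs(rec_R, rec_F, "CHH")
        assert len(dmrs) == 1
        assert dmrs.iloc[0]["direction"] == "hyper"
        assert dmrs.iloc[0]["n_cytosines"] == 6

    def test_five_cytosines_never_reported(self):
        rec_R = _sites([0.0] * 5, 50, exact=True)
        rec_F = _sites([1.0] * 5, 50, exact=True)
        assert call_dmrs(rec_R, rec_F, "CHH").empty

    def test_small_difference_fails_min_diff(self):
        rec_R = _sites([0.50] * 10, 1000, exact=True)
        rec_F = _sites([0.55] * 10, 1000, exact=True)
        assert call_dmrs(rec_R, rec_F, "CHH").empty

    def test_identical_groups_yield_nothing(self):
        rng = np.random.default_rng(1)
        rec = _sites([0.3] * 20, 30, rng=rng)
        assert call_dmrs(rec, rec.copy(), "CHH").empty

    def test_gap_splits_candidate_regions(self):
        rng = np.random.default_rng(2)
        left_R = _sites([0.1] * 8, 40, start=0, rng=rng)
        right_R = _sites([0.1] * 8, 40, start=5000, rng=rng)
        left_F = _sites([0.6] * 8, 40, start=0, rng=rng)
        right_F = _sites([0.6] * 8, 40, start=5000, rng=rng)
        dmrs = call_dmrs(pd.concat([left_R, right_R]), pd.concat([left_F, right_F]), "CHH")
        assert len(dmrs) == 2

    def test_absent_context_gives_empty_list(self):
        rec = _sites([0.3] * 6, 30, exact=True)
        assert call_dmrs(rec, rec, "CG").empty

    def test_direction_is_sign_of_difference(self):
        assert classify_direction(0.4) == "hyper"
        assert classify_direction(-0.4) == "hypo"
        with pytest.raises(ValueError):
            classify_direction(0.0)


class TestOverlap:
    @staticmethod
    def _ann():
        rows = [
            dict(feature_id="g", chrom="chr1", start=100, end=400, strand="+",
                 ftype="gene", parent=None),
            dict(feature_id="g.e", chrom="chr1", start=150, end=300, strand="+",
                 ftype="exon", parent="g"),
            dict(feature_id="te", chrom="chr1", start=600, end=700, strand="+",
                 ftype="TE", parent=None),
        ]
        return AnnotationSet.build(pd.DataFrame(rows), {"chr1": 10000})

    def _dmrs(self, intervals):
        return pd.DataFrame([
            dict(dmr_id=f"d{i}", chrom="chr1", start=s, end=e)
            for i, (s, e) in enumerate(intervals)
        ])

    def test_partial_overlap_is_assigned(self):
        assigns, classes = overlap_features(self._dmrs([(100, 200)]), self._ann())
        assert "g.e" in set(assigns["feature_id"])
        assert classes.iloc[0]["feature_class"] == "gene-only"

    def test_half_open_abutment_is_no_overlap(self):
        assigns, classes = overlap_features(self._dmrs([(400, 500)]), self._ann())
        hit_types = set(assigns["ftype"])
        assert "gene" not in hit_types and "exon" not in hit_types
        assert classes.iloc[0]["feature_class"] == "neither"

    def test_te_and_gene_overlap_classifies_both(self):
        assigns, classes = overlap_features(self._dmrs([(350, 650)]), self._ann())
        assert classes.iloc[0]["feature_class"] == "both"

    def test_matches_quadratic_scan(self):
        rng = np.random.default_rng(13)
        rows = []
        for i in range(200):
            start = int(rng.integers(0, 20000))
            ftype = ["gene", "TE"][i % 2]
            rows.append(dict(feature_id=f"f{i}", chrom="chr1", start=start,
                             end=start + int(rng.integers(1, 500)), strand="+",
                             ftype=ftype, parent=None))
        ann = AnnotationSet(features=pd.DataFrame(rows), chrom_sizes={"chr1": 25000})
        dmrs = self._dmrs([
            (int(s), int(s) + int(rng.integers(1, 400)))
            for s in rng.integers(0, 20000, size=100)
        ])
        assigns, _ = overlap_features(dmrs, ann)
        got = set(zip(assigns["dmr_id"], assigns["feature_id"]))
        expected = {
            (d["dmr_id"], r["feature_id"])
            for _, d in dmrs.iterrows()
            for r in rows
            if min(d["end"], r["end"]) - max(d["start"], r["start"]) >= 1
        }
        assert got == expected
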