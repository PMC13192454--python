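"""The synthetic-data generator: determinism, planted-signal fidelity and
internal consistency of the ground truth."""

import numpy as np
import pandas as pd
import pytest

from lightomics.integration import rddm_verdict
from lightomics.methylome import assign_context
from lightomics.simulate import (
    ARCHETYPES,
    GroundTruth,
    SimulationConfig,
    cytosine_sites,
    make_sample_sheet,
    make_truth,
    simulate_annotation,
    simulate_counts,
    simulate_methylome,
)

from conftest import small_config


class TestConfig:
    def test_low_fold_change_floor_rejected(self):
        with pytest.raises(ValueError, match="1.5"):
            SimulationConfig(planted_log2fc_range=(1.0, 2.0)).validate()

    def test_infeasible_packing_is_an_explicit_error(self):
        with pytest.raises(ValueError, match="pack"):
            SimulationConfig(chrom_length=10_000).validate()

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(planted_deg_frac=1.5).validate()
        with pytest.raises(ValueError):
            SimulationConfig(base_meth={"CG": 1.2, "CHG": 0.5, "CHH": 0.1}).validate()


class TestAnnotation:
    def test_determinism_bit_for_bit(self, tmp_path):
        from lightomics.io import write_gff3

        cfg = small_config(seed=7)
        for run in ("a", "b"):
            ann, genome, _ = simulate_annotation(cfg)
            write_gff3(ann, tmp_path / f"{run}.gff3")
        assert (tmp_path / "a.gff3").read_bytes() == (tmp_path / "b.gff3").read_bytes()

    def test_gene_bodies_do_not_overlap(self, small_exp):
        genes = small_exp.annotation.genes().sort_values("start")
        assert (genes["start"].to_numpy()[1:] >= genes["end"].to_numpy()[:-1]).all()

    def test_single_exon_genes_have_no_introns(self, small_exp):
        ann = small_exp.annotation
        single = {
            gid for gid, grp in ann.of_type("exon").groupby("parent") if len(grp) == 1
        }
        intron_parents = set(ann.of_type("intron")["parent"])
        assert single and not (single & intron_parents)

    def test_minus_strand_promoters_extend_rightward(self, small_exp):
        ann = small_exp.annotation
        genes = ann.genes()
        for _, prom in ann.of_type("promoter").iterrows():
            gene = genes.loc[prom["parent"]]
            if gene["strand"] == "-":
                assert prom["start"] == gene["end"]
            else:
                assert prom["end"] == gene["start"]

    def test_all_contexts_on_both_strands(self, small_exp):
        sites = cytosine_sites(small_exp.genome)
        combos = set(zip(sites["context"], sites["strand"]))
        assert combos == {(c, s) for c in ("CG", "CHG", "CHH") for s in "+-"}

    def test_site_contexts_match_single_site_rule(self, small_exp):
        sites = cytosine_sites(small_exp.genome).sample(200, random_state=0)
        for row in sites.itertuples(index=False):
            ctx, _ = assign_context(small_exp.genome, row.chrom, row.pos, row.strand)
            assert ctx == row.context


class TestCounts:
    def test_same_seed_identical_matrices(self, small_exp):
        cfg = small_config()
        counts2, _, _ = simulate_counts(cfg, small_exp.annotation, small_exp.truth)
        pd.testing.assert_frame_equal(small_exp.counts, counts2)

    def test_no_planted_degs_means_equal_group_means(self):
        cfg = small_config(seed=3, planted_deg_frac=0.0, n_rddm_genes=0)
        ann, genome, islands = simulate_annotation(cfg)
        truth = make_truth(cfg, ann, islands, genome)
        assert truth.deg_labels == {}

    def test_planted_fold_change_recovered_within_sampling_error(self, default_exp):
        """Planted FR-day-3 genes show the planted FR/Ctrl mean count ratio."""
        sheet = default_exp.sample_sheet
        fr = sheet[(sheet["condition"] == "FR") & (sheet["timepoint"] == "71")]["sample_id"]
        ctrl = sheet[sheet["condition"] == "Ctrl"]["sample_id"]
        checked = 0
        for gene, lab in default_exp.truth.deg_labels.items():
            coef = ARCHETYPES[lab["archetype"]].get("FR_71", 0)
            if coef != 1 or lab["log2fc"] > 2.3:
                continue
            mean_fr = default_exp.counts.loc[gene, fr].mean()
            mean_ctrl = default_exp.counts.loc[gene, ctrl].mean()
            expected = 2.0 ** lab["log2fc"]
            # 3-SE band for the ratio of NB means at n=4
            se = expected * np.sqrt(2 * (1 / mean_ctrl + 0.05) / 4)
            assert abs(mean_fr / mean_ctrl - expected) < 3 * se
            checked += 1
        assert checked >= 3


class TestMethylome:
    def test_same_seed_identical_reports(self, small_exp):
        cfg = small_config()
        r2, f2 = simulate_methylome(cfg, small_exp.genome, small_exp.truth)
        pd.testing.assert_frame_equal(small_exp.records_R, r2)
        pd.testing.assert_frame_equal(small_exp.records_FR, f2)

    def test_hyper_dmr_levels_hit_base_plus_effect(self, default_exp):
        truth = default_exp.truth
        rec = default_exp.records_FR
        for dmr in truth.dmr_intervals:
            if not (dmr["context"] == "CHH" and dmr["direction"] == "hyper"):
                continue
            sub = rec[(rec["pos"] >= dmr["start"]) & (rec["pos"] < dmr["end"])
                      & (rec["context"] == "CHH")]
            cov = (sub["count_methylated"] + sub["count_unmethylated"]).sum()
            level = sub["count_methylated"].sum() / cov
            target = 0.1 + dmr["effect"]
            assert abs(level - target) < 3 * np.sqrt(target * (1 - target) / cov)
            break

    def test_background_levels_match_between_conditions(self, default_exp):
        planted = {(d["start"], d["end"]) for d in default_exp.truth.dmr_intervals}
        outside = np.ones(len(default_exp.records_R), bool)
        pos = default_exp.records_R["pos"].to_numpy()
        for s, e in planted:
            outside &= ~((pos >= s) & (pos < e))
        for rec_name in ("records_R", "records_FR"):
            rec = getattr(default_exp, rec_name)[outside]
            chh = rec[rec["context"] == "CHH"]
            cov = (chh["count_methylated"] + chh["count_unmethylated"]).sum()
            level = chh["count_methylated"].sum() / cov
            assert abs(level - 0.1) < 3 * np.sqrt(0.1 * 0.9 / cov)

    def test_zero_coverage_sites_are_emitted(self):
        cfg = small_config(seed=5, meth_coverage=0.7)
        ann, genome, islands = simulate_annotation(cfg)
        truth = make_truth(cfg, ann, islands, genome)
        rec_R, _ = simulate_methylome(cfg, genome, truth)
        cov = rec_R["count_methylated"] + rec_R["count_unmethylated"]
        assert (cov == 0).any()


class TestSRNA:
    def test_planted_shift_ratio(self, default_exp):
        """A planted 24-nt up-shift shows a ~4x FR/R RPM ratio."""
        truth = default_exp.truth
        prof = default_exp.srna
        sheet = default_exp.sample_sheet
        fr = [s for s in prof.counts.columns
              if sheet.set_index("sample_id").loc[s, "condition"] == "FR"]
        r = [s for s in prof.counts.columns if s not in fr]
        island = next(i for i, shifts in truth.srna_shifts.items()
                      if shifts.get(24) == "up")
        row = prof.counts.xs(island, level="locus").loc[24]
        ratio = row[fr].mean() / row[r].mean()
        se = 4.0 * np.sqrt(2 * (1 / row[r].mean() + 0.1) / 4)
        assert abs(ratio - 4.0) < 3 * se

    def test_unshifted_regions_match_across_groups(self, default_exp):
        truth = default_exp.truth
        prof = default_exp.srna
        shifted = set(truth.srna_shifts)
        quiet = [l for l in prof.loci["name"] if l not in shifted][:200]
        sheet = default_exp.sample_sheet.set_index("sample_id")
        fr = [s for s in prof.counts.columns if sheet.loc[s, "condition"] == "FR"]
        r = [s for s in prof.counts.columns if s not in fr]
        sub = prof.counts.loc[quiet]
        tot_fr, tot_r = sub[fr].to_numpy().sum(), sub[r].to_numpy().sum()
        se = np.sqrt(tot_fr + tot_r)  # Poisson-scale error on the difference
        assert abs(tot_fr - tot_r) < 4 * se * np.sqrt(1 + 0.1 * 30)

    def test_library_totals_are_column_sums(self, small_exp):
        assert (small_exp.srna.library_totals == small_exp.srna.counts.sum(axis=0)).all()


class TestTruth:
    def test_round_trip_json(self, small_exp, tmp_path):
        path = tmp_path / "truth.json"
        small_exp.truth.to_json(path)
        back = GroundTruth.from_json(path)
        assert back == small_exp.truth

    def test_rddm_triples_satisfy_consistency_rule(self, small_exp):
        for gene, triple in small_exp.truth.rddm_genes.items():
            assert rddm_verdict(
                triple["meth"], {21: triple["srna"]}, triple["expr"]
            )

    def test_rddm_dmrs_touch_their_gene(self, small_exp):
        genes = small_exp.annotation.genes()
        promoters = small_exp.annotation.of_type("promoter").set_index("parent")
        for gene, triple in small_exp.truth.rddm_genes.items():
            dmr = small_exp.truth.dmr_intervals[triple["dmr_index"]]
            g = genes.loc[gene]
            spans = [(g["start"], g["end"])]
            if gene in promoters.index:
                p = promoters.loc[gene]
                spans.append((p["start"], p["end"]))
            assert any(dmr["start"] < e and dmr["end"] > s for s, e in spans)

    def test_sample_sheet_layout(self):
        sheet = make_sample_sheet(small_config())
        assert sheet["sample_id"].is_unique
        assert len(sheet) == 5 * 4
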