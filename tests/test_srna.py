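"""sRNA size-class profiling, categorization and differential accumulation."""

import numpy as np
import pandas as pd
import pytest

from lightomics.srna import (
    SIZE_CLASSES,
    SRNAProfile,
    assign_regions_to_loci,
    categorize,
    crossref_mirna_targets,
    rpm_normalize,
    size_distribution,
    srna_at_regions,
)


def _profile(counts_by_locus, samples=("s1", "s2"), loci=None):
    index = pd.MultiIndex.from_product(
        [list(counts_by_locus), SIZE_CLASSES], names=["locus", "size"]
    )
    data = {}
    for s in samples:
        col = []
        for locus in counts_by_locus:
            col.extend(counts_by_locus[locus].get(s, [0] * len(SIZE_CLASSES)))
        data[s] = col
    counts = pd.DataFrame(data, index=index)
    return SRNAProfile(counts=counts, library_totals=counts.sum(axis=0), loci=loci)


class TestProfileAndRPM:
    def test_size_window_enforced(self):
        index = pd.MultiIndex.from_arrays([["l1"], [15]], names=["locus", "size"])
        with pytest.raises(ValueError, match="16-nt"):
            SRNAProfile(counts=pd.DataFrame({"s": [1]}, index=index),
                        library_totals=pd.Series({"s": 1}))

    def test_simple_rpm_value(self):
        index = pd.MultiIndex.from_arrays([["l1"], [24]], names=["locus", "size"])
        prof = SRNAProfile(counts=pd.DataFrame({"s": [50]}, index=index),
                           library_totals=pd.Series({"s": 2_000_000}))
        rpm_normalize(prof)
        assert prof.rpm.iloc[0, 0] == pytest.approx(25.0)

    def test_million_library_is_identity(self):
        index = pd.MultiIndex.from_arrays([["l1"], [24]], names=["locus", "size"])
        prof = SRNAProfile(counts=pd.DataFrame({"s": [123]}, index=index),
                           library_totals=pd.Series({"s": 1_000_000}))
        rpm_normalize(prof)
        assert prof.rpm.iloc[0, 0] == pytest.approx(123.0)

    def test_zero_total_is_an_error(self):
        index = pd.MultiIndex.from_arrays([["l1"], [24]], names=["locus", "size"])
        prof = SRNAProfile(counts=pd.DataFrame({"s": [0]}, index=index),
                           library_totals=pd.Series({"s": 0}))
        with pytest.raises(ValueError):
            rpm_normalize(prof)

    def test_rpm_conservation_identity(self):
        """Sum of RPM equals 1e6 x assigned/library per sample."""
        rng = np.random.default_rng(0)
        counts = {f"l{i}": {"s1": rng.integers(0, 50, len(SIZE_CLASSES)).tolist(),
                            "s2": rng.integers(0, 50, len(SIZE_CLASSES)).tolist()}
                  for i in range(5)}
        prof = _profile(counts)
        prof.library_totals = prof.library_totals + 1000  # some unassigned reads
        rpm_normalize(prof)
        for s in ("s1", "s2"):
            assigned = prof.counts[s].sum()
            assert prof.rpm[s].sum() == pytest.approx(1e6 * assigned / prof.library_totals[s])

    def test_rescaling_totals_divides_rpm(self):
        rng = np.random.default_rng(1)
        counts = {"l1": {"s1": rng.integers(1, 50, len(SIZE_CLASSES)).tolist()}}
        prof = _profile(counts, samples=("s1",))
        rpm_normalize(prof)
        base = prof.rpm.copy()
        prof.library_totals = prof.library_totals * 7
        rpm_normalize(prof)
        assert np.allclose(prof.rpm, base / 7)


class TestSizeDistribution:
    def test_single_mass_at_24(self):
        counts = {"l1": {"s1": [0] * len(SIZE_CLASSES)}}
        counts["l1"]["s1"][SIZE_CLASSES.index(24)] = 10
        prof = _profile(counts, samples=("s1",))
        dist = size_distribution(prof, {"s1": "FR"})
        nonzero = dist[dist["mean_rpm"] > 0]
        assert list(nonzero["size"]) == [24]

    def test_duplicated_sample_has_zero_sd(self):
        counts = {"l1": {"s1": [3] * len(SIZE_CLASSES), "s2": [3] * len(SIZE_CLASSES)}}
        prof = _profile(counts)
        dist = size_distribution(prof, {"s1": "FR", "s2": "FR"})
        assert np.allclose(dist["sd_rpm"], 0.0)

    def test_matches_manual_aggregation(self):
        rng = np.random.default_rng(4)
        counts = {f"l{i}": {s: rng.integers(0, 30, len(SIZE_CLASSES)).tolist()
                            for s in ("s1", "s2", "s3")} for i in range(4)}
        prof = _profile(counts, samples=("s1", "s2", "s3"))
        groups = {"s1": "R", "s2": "R", "s3": "FR"}
        dist = size_distribution(prof, groups).set_index(["group", "size"])
        rpm = prof.rpm.groupby(level="size").sum()
        for size in SIZE_CLASSES:
            assert dist.loc[("R", size), "mean_rpm"] == pytest.approx(
                rpm.loc[size, ["s1", "s2"]].mean()
            )
            assert dist.loc[("FR", size), "mean_rpm"] == pytest.approx(rpm.loc[size, "s3"])


class TestCategorize:
    @staticmethod
    def _reads():
        return pd.DataFrame({
            "count": [10, 5, 2, 8],
            "genes": [True, False, False, False],
            "miRNAs": [False, True, False, False],
            "TEs": [True, True, False, False],
            "rRNA": [False, False, False, False],
            "tRNA": [False, False, False, False],
        })

    def test_priority_assignment(self):
        out = categorize(self._reads()).set_index("category")["count"]
        assert out["genes"] == 10  # gene+TE read goes to genes
        assert out["miRNAs"] == 5
        assert out["TEs"] == 0
        assert out["other"] == 10  # two unmatched read classes

    def test_partition_sums_to_total(self):
        out = categorize(self._reads())
        assert out["count"].sum() == self._reads()["count"].sum()
        assert out["fraction"].sum() == pytest.approx(1.0)

    def test_independent_mode_counts_overlaps(self):
        out = categorize(self._reads(), independent=True).set_index("category")["count"]
        assert out["genes"] == 10 and out["TEs"] == 15


class TestCrossref:
    def test_inverse_flag_and_empty_families(self):
        fam_de = pd.DataFrame(
            {"status": ["down", "up", "ns"]}, index=["famA", "famB", "famC"]
        )
        fr = pd.Series({"g1": "up", "g2": "down", "g3": "up"})
        targets = pd.DataFrame([
            ("famA", "g1"), ("famB", "g3"), ("famC", "g2"), ("famA", "not_deg"),
        ], columns=["family", "gene_id"])
        out = crossref_mirna_targets(fam_de, fr, targets)
        byfam = out.set_index(["family", "gene_id"])
        assert byfam.loc[("famA", "g1"), "inverse"]  # family down, target up
        assert not byfam.loc[("famB", "g3"), "inverse"]  # both up: not inverse
        assert "famC" not in out["family"].values  # ns family ignored
        assert "not_deg" not in out["gene_id"].values

    def test_overlap_counts_match_set_intersection(self):
        rng = np.random.default_rng(6)
        genes = [f"g{i}" for i in range(40)]
        fr = pd.Series("up", index=rng.choice(genes, 15, replace=False))
        fam_de = pd.DataFrame({"status": ["down"] * 3}, index=["fA", "fB", "fC"])
        targets = pd.DataFrame(
            [(f, g) for f in fam_de.index for g in rng.choice(genes, 8, replace=False)],
            columns=["family", "gene_id"],
        )
        out = crossref_mirna_targets(fam_de, fr, targets)
        for fam in fam_de.index:
            expected = set(targets[targets["family"] == fam]["gene_id"]) & set(fr.index)
            assert set(out[out["family"] == fam]["gene_id"]) == expected


class TestAtRegions:
    @staticmethod
    def _sheet():
        rows = []
        for cond in ("R", "FR"):
            for r in range(4):
                rows.append(dict(sample_id=f"{cond}71_r{r}", condition=cond,
                                 timepoint="71", replicate=r))
        return pd.DataFrame(rows)

    def _planted_profile(self, fold=6.0, seed=0):
        rng = np.random.default_rng(seed)
        loci = pd.DataFrame({
            "chrom": "chr1",
            "start": np.arange(20) * 1000,
            "end": np.arange(20) * 1000 + 200,
            "name": [f"l{i:02d}" for i in range(20)],
        })
        samples = [f"{c}71_r{r}" for c in ("R", "FR") for r in range(4)]
        index = pd.MultiIndex.from_product(
            [loci["name"], SIZE_CLASSES], names=["locus", "size"]
        )
        mu = np.full((len(index), len(samples)), 30.0)
        for j, s in enumerate(samples):
            if s.startswith("FR"):
                # plant a 24-nt shift in locus l00
                k = list(index).index(("l00", 24))
                mu[k, j] *= fold
        counts = pd.DataFrame(
            rng.poisson(mu), index=index, columns=samples
        )
        return SRNAProfile(counts=counts, library_totals=counts.sum(axis=0), loci=loci)

    def test_planted_shift_detected_with_direction(self):
        prof = self._planted_profile()
        regions = pd.DataFrame({
            "chrom": "chr1", "start": [0, 5000], "end": [150, 5100],
            "dmr_id": ["dmrA", "dmrB"],
        })
        res = srna_at_regions(prof, regions, self._sheet(), ("FR_71", "R_71"))
        hit = res[(res["region_id"] == "dmrA") & (res["size"] == 24)].iloc[0]
        assert hit["direction"] == "up"
        null = res[res["region_id"] == "dmrB"]
        assert (null["direction"] == "ns").all()

    def test_region_totals_match_overlap_scan(self):
        prof = self._planted_profile(seed=2)
        regions = pd.DataFrame({
            "chrom": "chr1", "start": [100, 950, 8000], "end": [1100, 2200, 8050],
            "dmr_id": ["a", "b", "c"],
        })
        mapping = assign_regions_to_loci(regions, prof.loci)
        for region in regions.itertuples(index=False):
            expected = sorted(
                l.name for l in prof.loci.itertuples(index=False)
                if l.start < region.end and l.end > region.start
            )
            assert mapping[region.dmr_id] == expected
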