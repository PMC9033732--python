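"""TPM arithmetic, correlation distances, clustering QC and averaging."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import squareform

from anchorcoex import (CompendiumConfig, SampleMeta, cluster_and_flag_replicates,
                        correlation_distance_matrix, linkage_merges, prune_and_average,
                        simulate_compendium, tpm_from_counts)
from anchorcoex.examples import BTR_MEIOSIS_TPM

from conftest import make_compendium


def counts_df(values, genes=None, samples=None):
    values = np.asarray(values)
    genes = genes or [f"g{i + 1}" for i in range(values.shape[0])]
    samples = samples or [f"S{i + 1}" for i in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=samples)


class TestTpm:
    def test_equal_lengths_proportional(self):
        comp = tpm_from_counts(counts_df([[10], [30]]), {"g1": 100, "g2": 100})
        assert comp.values["S1"].tolist() == [250000.0, 750000.0]

    def test_single_gene_normalises_to_a_million(self):
        comp = tpm_from_counts(counts_df([[7]]), {"g1": 421})
        assert comp.values.iloc[0, 0] == pytest.approx(1e6)

    def test_hand_computed_three_gene_case(self):
        # rates 0.1 / 0.05 / 0.025 over total 0.175
        comp = tpm_from_counts(counts_df([[10], [10], [10]]),
                               {"g1": 100, "g2": 200, "g3": 400})
        got = comp.values["S1"].round(2).tolist()
        assert got == [571428.57, 285714.29, 142857.14]

    def test_columns_sum_to_a_million_on_random_matrices(self, rng):
        for _ in range(20):
            shape = (int(rng.integers(2, 30)), int(rng.integers(1, 6)))
            counts = rng.integers(0, 1000, size=shape)
            counts[0] += 1  # keep every column non-zero
            lengths = {f"g{i + 1}": int(rng.integers(100, 5000)) for i in range(shape[0])}
            comp = tpm_from_counts(counts_df(counts), lengths)
            sums = comp.values.sum(axis=0).to_numpy()
            assert np.allclose(sums, 1e6, rtol=1e-6)

    def test_zero_length_gene_rejected(self):
        with pytest.raises(ValueError, match="g1"):
            tpm_from_counts(counts_df([[1]]), {"g1": 0})

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValueError, match="S2"):
            tpm_from_counts(counts_df([[1, 0], [2, 0]]), {"g1": 10, "g2": 10})


class TestCorrelationDistance:
    def test_identical_columns_have_zero_distance(self):
        comp = make_compendium([[1, 1], [5, 5], [2, 2]])
        d = correlation_distance_matrix(comp)
        assert d.loc["S1", "S2"] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_columns_have_distance_two(self):
        comp = make_compendium([[1, 3], [2, 2], [3, 1]])
        d = correlation_distance_matrix(comp)
        assert d.loc["S1", "S2"] == pytest.approx(2.0)

    def test_published_anchor_profiles_distance(self):
        # the two anchor TPM vectors as sample columns: d = 1 - 0.99 = 0.01
        mat = np.column_stack([BTR_MEIOSIS_TPM["Btr1-like-a"],
                               BTR_MEIOSIS_TPM["Btr2-like-a"]])
        comp = make_compendium(mat, sample_ids=["btr1", "btr2"])
        d = correlation_distance_matrix(comp)
        assert round(float(d.loc["btr1", "btr2"]), 2) == 0.01

    def test_zero_variance_sample_named(self):
        comp = make_compendium([[1, 4], [2, 4], [3, 4]])
        with pytest.raises(ValueError, match="S2"):
            correlation_distance_matrix(comp)


class TestLinkage:
    def test_average_linkage_matches_scipy_on_random_matrices(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 7))
            a = rng.random((n, n))
            d = (a + a.T) / 2
            np.fill_diagonal(d, 0)
            labels = [f"L{i}" for i in range(n)]
            mine = linkage_merges(pd.DataFrame(d, index=labels, columns=labels))
            Z = scipy_linkage(squareform(d), method="average")
            clusters = {i: frozenset([labels[i]]) for i in range(n)}
            for k, (m, row) in enumerate(zip(mine, Z)):
                ref = clusters[int(row[0])] | clusters[int(row[1])]
                clusters[n + k] = ref
                assert m.members == ref
                assert m.height == pytest.approx(row[2], abs=1e-12)

    def test_unknown_method_rejected(self):
        d = pd.DataFrame(np.zeros((2, 2)), index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError):
            linkage_merges(d, "ward")


def _two_group_distance(cross=0.9, within=0.01):
    ids = ["a1", "a2", "b1", "b2"]
    d = np.full((4, 4), cross)
    d[0, 1] = d[1, 0] = within
    d[2, 3] = d[3, 2] = within
    np.fill_diagonal(d, 0)
    return pd.DataFrame(d, index=ids, columns=ids)


def _metas(groups):
    return [SampleMeta(sid, "p", "t", "s", g) for sid, g in groups]


class TestReplicateFlagging:
    def test_coherent_groups_not_flagged(self):
        report = cluster_and_flag_replicates(
            _two_group_distance(), _metas([("a1", "A"), ("a2", "A"), ("b1", "B"), ("b2", "B")]))
        assert report.flagged_replicate_groups == []
        assert report.removed_sample_ids == []
        assert set(report.kept_sample_ids) == {"a1", "a2", "b1", "b2"}

    def test_split_group_flagged_and_fully_removed(self):
        # a2's profile resembles the B group, so A cannot form a subtree
        d = _two_group_distance()
        d.loc["a2", ["b1", "b2"]] = 0.02
        d.loc[["b1", "b2"], "a2"] = 0.02
        d.loc["a1", "a2"] = d.loc["a2", "a1"] = 0.9
        report = cluster_and_flag_replicates(
            d, _metas([("a1", "A"), ("a2", "A"), ("b1", "B"), ("b2", "B")]))
        flagged = [g for g, _ in report.flagged_replicate_groups]
        assert flagged == ["A"]
        assert sorted(report.removed_sample_ids) == ["a1", "a2"]

    def test_singleton_groups_exempt(self):
        report = cluster_and_flag_replicates(
            _two_group_distance(), _metas([("a1", "A"), ("a2", "A"), ("b1", "B"), ("b2", "C")]))
        assert report.flagged_replicate_groups == []

    def test_partition_conserves_samples(self, default_synthetic):
        comp, _ = default_synthetic
        report = cluster_and_flag_replicates(
            correlation_distance_matrix(comp), comp.samples)
        assert len(report.removed_sample_ids) + len(report.kept_sample_ids) == comp.shape[1]

    def test_planted_outliers_flagged_across_seeds(self):
        for seed in range(20):
            comp, truth = simulate_compendium(CompendiumConfig(seed=seed))
            report = cluster_and_flag_replicates(
                correlation_distance_matrix(comp), comp.samples)
            flagged = {g for g, _ in report.flagged_replicate_groups}
            outlier_groups = {s.replicate_group for s in comp.samples
                              if s.sample_id in set(truth.outlier_sample_ids)}
            assert outlier_groups <= flagged
            assert set(truth.outlier_sample_ids) <= set(report.removed_sample_ids)


class TestPruneAndAverage:
    def _germination_comp(self):
        stages = ["0h", "8h", "16h", "24h", "32h", "40h", "48h"]
        samples, cols = [], {}
        rng = np.random.default_rng(0)
        for st in stages:
            for r in (1, 2):
                sid = f"germ.{st}.r{r}"
                samples.append(SampleMeta(sid, "germination", "scutellum", st, f"germ.{st}"))
                cols[sid] = rng.random(5)
        from anchorcoex import ExpressionCompendium
        return ExpressionCompendium(values=pd.DataFrame(cols), samples=samples)

    def test_replicates_average_to_their_mean(self):
        comp = make_compendium([[1.0, 3.0]], sample_ids=["r1", "r2"], group="G")
        avg = prune_and_average(comp)
        assert avg.sample_ids == ["G"]
        assert avg.values.loc["g1", "G"] == pytest.approx(2.0)

    def test_deny_rule_keeps_only_8h_and_48h(self):
        comp = self._germination_comp()
        avg = prune_and_average(comp, {"deny": [{"stage": "0h,16h,24h,32h,40h"}]})
        assert [m.stage for m in avg.samples] == ["8h", "48h"]

    def test_averaging_is_idempotent(self, default_synthetic):
        comp, _ = default_synthetic
        once = prune_and_average(comp)
        twice = prune_and_average(once)
        assert twice.values.equals(once.values)
        assert twice.samples == once.samples

    def test_unknown_field_in_rules_rejected(self):
        comp = make_compendium([[1.0, 2.0]])
        with pytest.raises(ValueError, match="flavour"):
            prune_and_average(comp, {"deny": [{"flavour": "x"}]})
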