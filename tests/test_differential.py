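"""Normalization, DEG calling, Ward clustering, PC1-pathology tests."""

import numpy as np
import pandas as pd
import pytest

from cernaflow import differential, scoring
from cernaflow.errors import ConstantInputError, MissingGroupError, ValidationError
from cernaflow.io import ExpressionMatrix
from cernaflow.synthetic import SimulationConfig, simulate_dataset

from conftest import null_config


def _matrix(values: dict, groups: dict, index=None, layer="mRNA"):
    df = pd.DataFrame(values, index=index)
    df.index.name = "feature_id"
    return ExpressionMatrix(
        layer=layer, values=df, design=pd.Series(groups, name="group")
    )


class TestCpm:
    def test_single_feature_is_million(self):
        m = _matrix({"S1": [7], "S2": [123]}, {"S1": "NC", "S2": "OC"}, index=["f1"])
        assert (differential.cpm(m).to_numpy() == 1e6).all()

    def test_equal_counts_split_evenly(self):
        m = _matrix({"S1": [50, 50]}, {"S1": "NC"}, index=["f1", "f2"])
        assert differential.cpm(m)["S1"].tolist() == [5e5, 5e5]

    def test_scale_invariance(self):
        m1 = _matrix({"S1": [10, 30, 60]}, {"S1": "NC"}, index=list("abc"))
        m2 = _matrix({"S1": [20, 60, 120]}, {"S1": "NC"}, index=list("abc"))
        pd.testing.assert_frame_equal(differential.cpm(m1), differential.cpm(m2))

    def test_all_zero_sample_rejected(self):
        m = _matrix({"S1": [0, 0]}, {"S1": "NC"}, index=["f1", "f2"])
        with pytest.raises(ValidationError):
            differential.cpm(m)

    def test_columns_sum_to_million(self, default_dataset):
        sums = differential.cpm(default_dataset.mrna).sum(axis=0)
        assert np.allclose(sums, 1e6)


class TestCallDegs:
    def test_identical_groups_all_ns(self, small_matrix):
        values = small_matrix.values
        dup = pd.concat(
            [values[["A_1", "A_2", "A_3"]], values[["A_1", "A_2", "A_3"]]], axis=1
        )
        dup.columns = ["A_1", "A_2", "A_3", "B_1", "B_2", "B_3"]
        m = _matrix(
            {c: dup[c].tolist() for c in dup.columns},
            {c: c.split("_")[0] for c in dup.columns},
            index=list(values.index),
        )
        out = differential.call_degs(m, "A", "B")
        assert (out["call"] == "ns").all()
        assert np.allclose(out["fold_change"], 1.0)

    def test_planted_feature_called_up(self, small_matrix):
        out = differential.call_degs(small_matrix, "A", "B").set_index("feature")
        assert out.at["gUP", "call"] == "up"
        assert out.at["g2", "call"] == "ns"

    def test_fc_below_threshold_is_ns_despite_small_p(self):
        # 1.2-fold with almost no noise: tiny p but fails the 1.5 bound
        rng = np.random.default_rng(3)
        base = 1000 + rng.normal(0, 1, 3)
        m = _matrix(
            {
                "A_1": [base[0], 500],
                "A_2": [base[1], 500],
                "A_3": [base[2], 500],
                "B_1": [base[0] * 1.2, 500],
                "B_2": [base[1] * 1.2, 500],
                "B_3": [base[2] * 1.2, 500],
            },
            {f"{g}_{i}": g for g in "AB" for i in range(1, 4)},
            index=["f_mild", "f_anchor"],
        )
        out = differential.call_degs(m, "A", "B").set_index("feature")
        # normalization maps the 1.2-fold shift onto both features; neither
        # passes the 1.5 fold-change bound whatever its p-value
        assert (out["call"] == "ns").all()

    def test_fold_change_reciprocal_under_contrast_swap(self, default_dataset):
        ab = differential.call_degs(default_dataset.mrna, "NC", "OC")
        ba = differential.call_degs(default_dataset.mrna, "OC", "NC")
        assert np.allclose(ab["fold_change"] * ba["fold_change"], 1.0)
        assert np.allclose(ab["p_value"], ba["p_value"], equal_nan=True)

    def test_order_invariance(self, default_dataset):
        m = default_dataset.mrna
        shuffled_rows = m.values.iloc[::-1]
        m2 = ExpressionMatrix(layer="mRNA", values=shuffled_rows, design=m.design)
        a = differential.call_degs(m, "NC", "OC").set_index("feature")
        b = differential.call_degs(m2, "NC", "OC").set_index("feature")
        pd.testing.assert_frame_equal(a.sort_index(), b.sort_index())

    def test_missing_group(self, small_matrix):
        with pytest.raises(MissingGroupError):
            differential.call_degs(small_matrix, "A", "Z")

    def test_planted_effects_recovered(self):
        """Planted |log2FC|=2 mRNAs are called with the correct direction."""
        hits = total = 0
        for seed in range(5):
            ds = simulate_dataset(SimulationConfig(seed=200 + seed))
            table = differential.call_degs(ds.mrna, "NC", "OC").set_index("feature")
            for feat, direction in ds.manifest.de_features["mRNA"].items():
                hits += table.at[feat, "call"] == direction
                total += 1
        assert hits / total >= 0.9


class TestDegCounts:
    def test_symmetry_and_ordering(self, default_dataset):
        counts = differential.deg_counts(default_dataset.mrna)
        pd.testing.assert_frame_equal(counts, counts.T)
        # dose profile: model (OC) farthest from normal, high-dose nearest
        assert counts.loc["NC", "OC"] == max(
            counts.loc["NC", g] for g in ["OC", "LK", "HK", "LOS"]
        )
        assert counts.loc["NC", "HK"] == min(
            counts.loc["NC", g] for g in ["OC", "LK", "HK", "LOS"]
        )

    def test_missing_group(self, default_dataset):
        with pytest.raises(MissingGroupError):
            differential.deg_counts(default_dataset.mrna, ["NC", "XX"])


class TestWardCluster:
    def test_two_samples_single_merge(self):
        df = pd.DataFrame({"S1": [0.0, 0.0], "S2": [3.0, 4.0]}, index=["a", "b"])
        tree = differential.ward_cluster(df)
        assert tree.linkage.shape == (1, 4)
        assert tree.linkage[0, 2] == pytest.approx(5.0)  # Euclidean distance

    def test_duplicates_merge_first_at_zero(self):
        df = pd.DataFrame(
            {"S1": [1.0, 2.0], "S2": [1.0, 2.0], "S3": [9.0, 9.0]}, index=["a", "b"]
        )
        tree = differential.ward_cluster(df)
        assert tree.linkage[0, 2] == pytest.approx(0.0)
        assert set(tree.linkage[0, :2]) == {0.0, 1.0}

    def test_single_sample_rejected(self):
        df = pd.DataFrame({"S1": [1.0, 2.0]}, index=["a", "b"])
        with pytest.raises(ValidationError):
            differential.ward_cluster(df)

    def test_newick_contains_all_leaves(self, default_dataset):
        log = differential.log2_cpm(default_dataset.mrna)
        tree = differential.ward_cluster(log)
        nwk = tree.to_newick()
        assert nwk.endswith(";")
        for sample in log.columns:
            assert sample in nwk

    def test_groups_recovered_at_five_clusters(self):
        """Cutting the dendrogram at 5 clusters recovers the treatment groups."""
        from sklearn.metrics import adjusted_rand_score

        aris = []
        for seed in range(5):
            ds = simulate_dataset(SimulationConfig(seed=300 + seed))
            log = differential.log2_cpm(ds.mrna)
            tree = differential.ward_cluster(log)
            labels = tree.cut(5)
            truth = [ds.mrna.design[s] for s in labels.index]
            aris.append(adjusted_rand_score(truth, labels.to_numpy()))
        assert np.mean(aris) >= 0.8


class TestPc1Pathology:
    def test_perfect_correlation_with_own_coords(self, default_dataset):
        log = differential.log2_cpm(default_dataset.mrna)
        first = differential.pc1_pathology(
            log,
            pd.Series(1.0, index=log.columns)
            + pd.Series(range(len(log.columns)), index=log.columns),
            default_dataset.mrna.design,
        )
        res = differential.pc1_pathology(log, first.coords, default_dataset.mrna.design)
        assert res.r == pytest.approx(1.0)
        negated = differential.pc1_pathology(
            log, -first.coords, default_dataset.mrna.design
        )
        assert negated.r == pytest.approx(-1.0)

    def test_constant_scores_rejected(self, default_dataset):
        log = differential.log2_cpm(default_dataset.mrna)
        with pytest.raises(ConstantInputError):
            differential.pc1_pathology(
                log, pd.Series(2.0, index=log.columns), default_dataset.mrna.design
            )

    def test_sign_convention_oc_positive(self, default_dataset):
        log = differential.log2_cpm(default_dataset.mrna)
        scores = scoring.score_histology(default_dataset.histology).set_index("animal")
        res = differential.pc1_pathology(log, scores["gsi"], default_dataset.mrna.design)
        oc = [s for s in log.columns if default_dataset.mrna.design[s] == "OC"]
        assert res.coords[oc].mean() > 0

    def test_pathology_correlation_strong(self, default_dataset):
        log = differential.log2_cpm(default_dataset.mrna)
        scores = scoring.score_histology(default_dataset.histology).set_index("animal")
        res = differential.pc1_pathology(log, scores["gsi"], default_dataset.mrna.design)
        assert res.r >= 0.7


def test_null_p_values_uniform_rate():
    """Without planted effects the t-test keeps its nominal type-I rate."""
    fp = tot = 0
    for seed in range(10):
        ds = simulate_dataset(null_config(700 + seed))
        table = differential.call_degs(ds.mrna, "NC", "OC")
        fp += int((table["p_value"] < 0.05).sum())
        tot += len(table)
    assert fp / tot == pytest.approx(0.05, abs=0.012)
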