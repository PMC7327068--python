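"""Correlation, thresholded edges, and ceRNA triad inference."""

import numpy as np
import pandas as pd
import pytest

from cernaflow import differential, networks
from cernaflow.errors import SampleMismatchError, ValidationError
from cernaflow.io import ExpressionMatrix, TargetMap
from cernaflow.synthetic import SimulationConfig, simulate_dataset


def covariance_oracle(x, y):
    """Two-pass product-moment correlation, independent of the fast path."""
    mx = sum(x) / len(x)
    my = sum(y) / len(y)
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    dx = sum((a - mx) ** 2 for a in x) ** 0.5
    dy = sum((b - my) ** 2 for b in y) ** 0.5
    return num / (dx * dy)


def bh_oracle(pvals):
    """Brute-force BH step-up by sorting and cumulative minimum from the top."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adj[i] = running
    return adj


def _df(rows, samples=None):
    df = pd.DataFrame(rows).T if isinstance(rows, dict) else pd.DataFrame(rows)
    if samples:
        df.columns = samples
    return df


class TestCorrelate:
    def test_perfect_positive_and_negative(self):
        df = pd.DataFrame(
            [[1, 2, 3], [2, 4, 6], [6, 4, 2]], index=["a", "b", "c"], dtype=float
        )
        corr = networks.correlate(df)
        assert corr.r.at["a", "b"] == pytest.approx(1.0)
        assert corr.r.at["a", "c"] == pytest.approx(-1.0)
        assert (np.diag(corr.r) == 1.0).all()

    def test_zero_correlation_p_one(self):
        # orthogonal to a constant-free pattern: r = 0 exactly
        df = pd.DataFrame(
            [[1, -1, 1, -1, 1, -1, 1, -1, 1, -1], [1, 1, -1, -1, 1, 1, -1, -1, 1, 1]],
            index=["a", "b"],
            dtype=float,
        )
        corr = networks.correlate(df)
        assert corr.r.at["a", "b"] == pytest.approx(0.0, abs=1e-12)
        assert corr.p.at["a", "b"] == pytest.approx(1.0)

    def test_matches_covariance_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            data = rng.normal(size=(10, 10))
            df = pd.DataFrame(data, index=[f"f{i}" for i in range(10)])
            corr = networks.correlate(df)
            for i in range(10):
                for j in range(i + 1, 10):
                    expected = covariance_oracle(data[i], data[j])
                    assert corr.r.iat[i, j] == pytest.approx(expected, abs=1e-12)

    def test_too_few_samples(self):
        df = pd.DataFrame([[1, 2], [3, 4]], index=["a", "b"], dtype=float)
        with pytest.raises(ValidationError):
            networks.correlate(df)

    def test_constant_feature_excluded_with_warning(self):
        df = pd.DataFrame(
            [[1, 2, 3, 4], [5, 5, 5, 5]], index=["a", "const"], dtype=float
        )
        with pytest.warns(UserWarning):
            corr = networks.correlate(df)
        assert corr.row_features == ["a"]

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(6, 8)))
        corr = networks.correlate(df)
        assert np.allclose(corr.r, corr.r.T)
        assert (np.abs(corr.r.to_numpy()) <= 1).all()
        assert ((corr.p.to_numpy() >= 0) & (corr.p.to_numpy() <= 1)).all()

    def test_mismatched_samples_rejected(self):
        rng = np.random.default_rng(8)
        a = pd.DataFrame(rng.normal(size=(2, 4)), columns=list("wxyz"))
        b = pd.DataFrame(rng.normal(size=(2, 4)), columns=list("wxyq"))
        with pytest.raises(SampleMismatchError):
            networks.correlate(a, b)


class TestBhAdjust:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        for size in (1, 7, 100):
            p = rng.uniform(size=size)
            assert np.allclose(networks.bh_adjust(p), bh_oracle(list(p)))

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=50)
        assert (networks.bh_adjust(p) >= p - 1e-15).all()


def _corr_from_r(rmat, features, n=10):
    """Build a CorrelationMatrix directly from an r matrix for edge tests."""
    r = pd.DataFrame(rmat, index=features, columns=features, dtype=float)
    p = pd.DataFrame(
        networks._corr_p(r.to_numpy(), n), index=features, columns=features
    )
    return networks.CorrelationMatrix(
        r=r, p=p, p_adj=p, n_samples=n, symmetric=True
    )


class TestCoexpressionEdges:
    def test_inclusive_threshold(self):
        corr = _corr_from_r(
            [[1.0, 0.8, -0.79], [0.8, 1.0, 0.0], [-0.79, 0.0, 1.0]], list("abc")
        )
        edges = networks.coexpression_edges(corr, threshold=0.8)
        assert len(edges) == 1  # r=0.8 kept, r=-0.79 dropped
        assert edges.at[0, "r"] == pytest.approx(0.8)
        assert edges.at[0, "adjacency"] == pytest.approx(0.8)

    def test_negative_kept_under_abs_rule(self):
        corr = _corr_from_r([[1.0, -0.9], [-0.9, 1.0]], list("ab"))
        edges = networks.coexpression_edges(corr, threshold=0.8)
        assert len(edges) == 1 and edges.at[0, "r"] == pytest.approx(-0.9)

    def test_power_beta(self):
        corr = _corr_from_r([[1.0, -0.9], [-0.9, 1.0]], list("ab"))
        edges = networks.coexpression_edges(corr, threshold=0.8, beta=2.0)
        assert edges.at[0, "adjacency"] == pytest.approx(0.81)

    def test_invalid_threshold(self):
        corr = _corr_from_r([[1.0, 0.5], [0.5, 1.0]], list("ab"))
        for bad in (0.0, 1.5, -0.2):
            with pytest.raises(ValidationError):
                networks.coexpression_edges(corr, threshold=bad)

    def test_null_edge_count_matches_tail_mass(self):
        """Independent features produce |r|>=0.8 edges at the theoretical rate."""
        from scipy import stats

        n_feat, n_samp, reps = 50, 15, 30
        rng = np.random.default_rng(99)
        observed = 0
        for _ in range(reps):
            df = pd.DataFrame(rng.normal(size=(n_feat, n_samp)))
            corr = networks.correlate(df)
            observed += len(networks.coexpression_edges(corr, threshold=0.8))
        pairs = reps * n_feat * (n_feat - 1) // 2
        expected = pairs * stats.beta.sf(0.64, 0.5, (n_samp - 2) / 2)
        assert abs(observed - expected) <= 6 * np.sqrt(expected) + 3


class TestMirnaTargetEdges:
    def _logs(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=12)
        mi = pd.DataFrame(
            {"mir1": z, "mir2": rng.normal(size=12)},
            index=[f"s{i}" for i in range(12)],
        ).T
        tg = pd.DataFrame(
            {
                "g_anti": -z + 0.1 * rng.normal(size=12),  # strongly negative r
                "g_null": rng.normal(size=12),
            },
            index=[f"s{i}" for i in range(12)],
        ).T
        return mi, tg

    def test_map_and_sign_filters(self):
        mi, tg = self._logs()
        tmap = TargetMap.from_pairs([("mir1", "g_anti", "mRNA"), ("mir1", "g_null", "mRNA")])
        edges = networks.mirna_target_edges(mi, tg, tmap)
        assert edges["target"].tolist() == ["g_anti"]
        assert edges.at[0, "r"] <= -0.8

    def test_strong_negative_but_unmapped_excluded(self):
        mi, tg = self._logs()
        tmap = TargetMap.from_pairs([("mir2", "g_null", "mRNA")])
        edges = networks.mirna_target_edges(mi, tg, tmap)
        assert len(edges) == 0

    def test_empty_intersection_warns_not_raises(self):
        mi, tg = self._logs()
        tmap = TargetMap.from_pairs([("mirX", "gX", "mRNA")])
        with pytest.warns(UserWarning):
            edges = networks.mirna_target_edges(mi, tg, tmap)
        assert len(edges) == 0


class TestBuildCerna:
    def test_planted_triads_recovered_no_decoys(self, default_dataset):
        ds = default_dataset
        net = networks.build_cerna(ds.lncrna, ds.mirna, ds.mrna, ds.target_map)
        planted = set(ds.manifest.sponge_triads)
        assert planted <= net.triad_tuples
        decoys = set(ds.manifest.decoy_pairs)
        assert all((m, g) not in decoys for (_, m, g) in net.triad_tuples)

    def test_empty_target_map_no_triads(self, default_dataset):
        ds = default_dataset
        with pytest.warns(UserWarning):
            net = networks.build_cerna(
                ds.lncrna, ds.mirna, ds.mrna, TargetMap.from_pairs([])
            )
        assert len(net.triads) == 0

    def test_triad_count_monotone_in_threshold(self, default_dataset):
        ds = default_dataset
        counts = [
            len(
                networks.build_cerna(
                    ds.lncrna, ds.mirna, ds.mrna, ds.target_map, threshold=t
                ).triads
            )
            for t in (0.7, 0.8, 0.9, 0.99)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_null_couplings_no_triads(self):
        ds = simulate_dataset(
            SimulationConfig(
                seed=55,
                repression_coupling=0.0,
                pair_latent_sd=0.0,
                n_mrna=200,
                n_mirna=60,
                n_lncrna=60,
                n_de_mrna=0,
            )
        )
        net = networks.build_cerna(ds.lncrna, ds.mirna, ds.mrna, ds.target_map)
        assert len(net.triads) == 0

    def test_sample_mismatch_rejected(self, default_dataset):
        ds = default_dataset
        values = ds.mirna.values.iloc[:, ::-1]
        reordered = ExpressionMatrix(layer="miRNA", values=values, design=ds.mirna.design)
        with pytest.raises(SampleMismatchError):
            networks.build_cerna(ds.lncrna, reordered, ds.mrna, ds.target_map)

    def test_triad_edges_exist_with_required_signs(self, default_dataset):
        ds = default_dataset
        net = networks.build_cerna(ds.lncrna, ds.mirna, ds.mrna, ds.target_map)
        assert (net.triads["r_lm"] <= -0.8).all()
        assert (net.triads["r_mg"] <= -0.8).all()
        assert (net.triads["r_lg"] >= 0.8).all()
        assert (net.edges["weight"] >= 0).all()

    def test_filtered_view_subsets_edges(self, default_dataset):
        ds = default_dataset
        net = networks.build_cerna(ds.lncrna, ds.mirna, ds.mrna, ds.target_map)
        sig = net.filtered(0.05)
        assert len(sig.edges) <= len(net.edges)
        assert (sig.edges["p_adj"] < 0.05).all()
        assert sig.triad_tuples <= net.triad_tuples

    def test_feature_reordering_invariance(self, default_dataset):
        ds = default_dataset
        net1 = networks.build_cerna(ds.lncrna, ds.mirna, ds.mrna, ds.target_map)
        shuffled = ExpressionMatrix(
            layer="lncRNA", values=ds.lncrna.values.iloc[::-1], design=ds.lncrna.design
        )
        net2 = networks.build_cerna(shuffled, ds.mirna, ds.mrna, ds.target_map)
        assert net1.triad_tuples == net2.triad_tuples

    def test_to_networkx_roundtrip(self, default_dataset):
        ds = default_dataset
        net = networks.build_cerna(ds.lncrna, ds.mirna, ds.mrna, ds.target_map)
        g = net.to_networkx()
        assert g.number_of_edges() == len(net.edges)
        layers = {d["layer"] for _, d in g.nodes(data=True)}
        assert layers <= {"mRNA", "miRNA", "lncRNA"}
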