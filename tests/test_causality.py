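"""The directing cascade: Pearson gate, unit roots, cointegration, Granger tests."""

import numpy as np
import pytest
from scipy import stats

from grangersift import (
    SyntheticSpec,
    TimeSeriesMatrix,
    TypedEdgeList,
    direct_edge,
    direct_network,
    simulate_interactions,
    simulate_var_timeseries,
)
from grangersift.causality import (
    cointegration_test,
    granger_test,
    pearson_test,
    unit_root_test,
)
from grangersift.network import build_network


def _ts(arrays, genes=None):
    arrays = np.atleast_2d(np.asarray(arrays, dtype=float))
    genes = genes or tuple(f"g{i}" for i in range(arrays.shape[0]))
    return TimeSeriesMatrix(
        gene_ids=genes,
        time_points=tuple(float(t) for t in range(arrays.shape[1])),
        values=arrays,
    )


class TestPearson:
    def test_perfect_linear_dependence(self, rng):
        x = rng.standard_normal(30)
        r, p = pearson_test(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-20

    def test_perfect_anticorrelation(self, rng):
        x = rng.standard_normal(30)
        r, _ = pearson_test(x, -x)
        assert r == pytest.approx(-1.0)

    def test_p_matches_t_transform(self, rng):
        # textbook r -> t -> p closed form as the oracle
        n = 26
        x = rng.standard_normal(n)
        y = 0.5 * x + np.sqrt(1 - 0.25) * rng.standard_normal(n)
        r, p = pearson_test(x, y)
        assert abs(r - 0.5) < 0.3
        t = r * np.sqrt((n - 2) / (1 - r**2))
        expected = 2 * stats.t.sf(abs(t), df=n - 2)
        assert p == pytest.approx(expected, rel=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            pearson_test(np.ones(10), np.arange(10.0))


class TestUnitRoot:
    def test_stationary_ar1_order_zero(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            e = rng.standard_normal(200)
            x = np.empty(200)
            x[0] = e[0]
            for t in range(1, 200):
                x[t] = 0.3 * x[t - 1] + e[t]
            if unit_root_test(x)[2] == 0:
                hits += 1
        assert hits >= 95

    def test_random_walk_order_one(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            x = np.cumsum(rng.standard_normal(200))
            if unit_root_test(x)[2] == 1:
                hits += 1
        assert hits >= 90

    def test_constant_series_not_testable(self):
        assert unit_root_test(np.ones(50))[2] is None

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            unit_root_test(np.arange(5.0))


class TestCointegration:
    def test_planted_cointegrated_pair(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = np.cumsum(rng.standard_normal(200))
            y = x + 0.5 * rng.standard_normal(200)
            if cointegration_test(x, y) < 0.05:
                hits += 1
        assert hits >= 90

    def test_independent_walks_near_nominal(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(5000 + seed)
            x = np.cumsum(rng.standard_normal(200))
            y = np.cumsum(rng.standard_normal(200))
            if cointegration_test(x, y) < 0.05:
                hits += 1
        assert hits <= 15

    def test_identical_walks_perfectly_cointegrated(self, rng):
        x = np.cumsum(rng.standard_normal(100))
        assert cointegration_test(x, x.copy()) == 0.0


def _nested_ols_granger_p(x, y, lag):
    """Independent oracle: restricted vs unrestricted OLS F-test via lstsq."""
    n = len(y)
    rows = n - lag
    y_resp = y[lag:]
    X_r = np.column_stack(
        [np.ones(rows)] + [y[lag - k : n - k] for k in range(1, lag + 1)]
    )
    X_u = np.column_stack(
        [X_r] + [x[lag - k : n - k] for k in range(1, lag + 1)]
    )
    rss_r = np.sum((y_resp - X_r @ np.linalg.lstsq(X_r, y_resp, rcond=None)[0]) ** 2)
    rss_u = np.sum((y_resp - X_u @ np.linalg.lstsq(X_u, y_resp, rcond=None)[0]) ** 2)
    df_denom = rows - X_u.shape[1]
    f = (rss_r - rss_u) / lag / (rss_u / df_denom)
    return stats.f.sf(f, lag, df_denom)


class TestGranger:
    @pytest.mark.parametrize("lag", [1, 2])
    def test_matches_nested_ols_oracle(self, rng, lag):
        x = rng.standard_normal(80)
        y = 0.5 * np.r_[0.0, x[:-1]] + rng.standard_normal(80)
        assert granger_test(x, y, lag) == pytest.approx(
            _nested_ols_granger_p(x, y, lag), rel=1e-8
        )

    def test_planted_direction_power_and_reverse_null(self):
        fwd = rev = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal(200)
            y = 0.9 * np.r_[0.0, x[:-1]] + rng.standard_normal(200)
            fwd += granger_test(x, y, 1) < 0.01
            rev += granger_test(y, x, 1) < 0.05
        assert fwd >= 95
        assert rev <= 10

    def test_type_i_error_near_nominal(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(7000 + seed)
            x = rng.standard_normal(200)
            y = rng.standard_normal(200)
            hits += granger_test(x, y, 1) < 0.05
        assert hits <= 10

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            granger_test(np.arange(6.0), np.arange(6.0), 2)


class TestDirectEdge:
    def test_planted_var_pair_directed_correctly(self):
        spec = SyntheticSpec(
            n_genes=2, n_timepoints=200, planted_causal_edges={("G000", "G001"): 0.9}, seed=3
        )
        ts, _ = simulate_var_timeseries(spec)
        res = direct_edge(("G000", "G001"), ts)
        assert res.verdict == "a_causes_b"
        assert res.granger_p_ab < 0.05

    def test_uncorrelated_pair_gated_before_granger(self):
        spec = SyntheticSpec(n_genes=2, n_timepoints=200, seed=11)
        ts, _ = simulate_var_timeseries(spec)
        res = direct_edge(("G000", "G001"), ts)
        assert res.verdict == "not_correlated"
        assert np.isnan(res.granger_p_ab) and np.isnan(res.granger_p_ba)

    def test_symmetric_coupling_yields_bidirectional(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            A = np.array([[0.4, 0.4], [0.4, 0.4]])
            x = np.zeros((2, 260))
            e = rng.standard_normal((2, 260))
            for t in range(1, 260):
                x[:, t] = A @ x[:, t - 1] + e[:, t]
            res = direct_edge(("a", "b"), _ts(x[:, 60:], genes=("a", "b")))
            if res.verdict == "bidirectional":
                return
        raise AssertionError("no bidirectional verdict across 5 planted two-way seeds")

    def test_swap_antisymmetry(self):
        spec = SyntheticSpec(
            n_genes=2, n_timepoints=150, planted_causal_edges={("G000", "G001"): 0.7}, seed=5
        )
        ts, _ = simulate_var_timeseries(spec)
        ab = direct_edge(("G000", "G001"), ts)
        ba = direct_edge(("G001", "G000"), ts)
        mirror = ab.swapped()
        import dataclasses

        for field, value in dataclasses.asdict(ba).items():
            expected = getattr(mirror, field)
            if isinstance(value, float) and np.isnan(value):
                assert np.isnan(expected)
            else:
                assert value == expected, field

    def test_constant_series_not_testable(self):
        vals = np.vstack([np.ones(30), np.arange(30.0)])
        res = direct_edge(("g0", "g1"), _ts(vals))
        assert res.verdict == "not_testable"


class TestDirectNetwork:
    def test_empty_feature_net(self):
        spec = SyntheticSpec(n_genes=3, n_timepoints=50, seed=0)
        ts, _ = simulate_var_timeseries(spec)
        net = build_network({"G000", "G001"}, TypedEdgeList.build([]))
        report = direct_network(net, ts)
        assert len(report.network.directed_edges) == 0
        assert report.network.nodes == {"G000", "G001"}

    def test_planted_structure_recovery(self):
        genes = [f"G{i:03d}" for i in range(20)]
        planted = {(genes[i], genes[10 + i]): 0.7 for i in range(10)}
        spec = SyntheticSpec(
            n_genes=20, n_timepoints=150, planted_causal_edges=planted, seed=42
        )
        ts, _ = simulate_var_timeseries(spec)
        interactions = simulate_interactions(spec, edge_density=0.1)
        net = build_network(set(genes), interactions)
        report = direct_network(net, ts)
        directed_pairs = report.network.edge_pairs()
        recovered = sum(1 for p in planted if p in directed_pairs)
        false_dirs = len({(s, t) for s, t in directed_pairs if (s, t) not in planted})
        assert recovered >= 7
        assert false_dirs <= 3

    def test_per_type_counts_partition_causal_edges(self):
        genes = [f"G{i:03d}" for i in range(10)]
        planted = {(genes[i], genes[5 + i]): 0.8 for i in range(5)}
        spec = SyntheticSpec(n_genes=10, n_timepoints=150, planted_causal_edges=planted, seed=7)
        ts, _ = simulate_var_timeseries(spec)
        net = build_network(set(genes), simulate_interactions(spec, 0.2))
        report = direct_network(net, ts)
        assert sum(c for c, _ in report.per_type_counts.values()) == len(
            report.network.directed_edges
        )
        assert sum(n for _, n in report.per_type_counts.values()) == net.n_edges

    def test_missing_gene_skipped_and_counted(self):
        spec = SyntheticSpec(n_genes=2, n_timepoints=50, seed=1)
        ts, _ = simulate_var_timeseries(spec)
        edges = TypedEdgeList.build(
            [("G000", "G001", "physical"), ("G000", "zz", "physical")]
        )
        net = build_network({"G000", "G001", "zz"}, edges)
        report = direct_network(net, ts)
        assert report.n_pairs_skipped == 1
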