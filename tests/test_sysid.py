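"""Regression construction, constrained estimation and AIC order detection."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

import gwgen
from gwgen.io import ExpressionDataset
from gwgen.network import make_node_table
from gwgen.sysid import (
    RegressionProblem,
    aic_value,
    build_regression,
    detect_order,
    estimate_parameters,
    exhaustive_best_subset,
)


def _dataset(rows: dict, samples=None) -> ExpressionDataset:
    cols = samples or [f"s{i}" for i in range(len(next(iter(rows.values()))))]
    df = pd.DataFrame(rows, index=cols).T
    df.index.name = "node_id"
    return ExpressionDataset(df, pd.Series("q", index=df.columns))


def _linear_problem(y, X, bounds=None):
    n, q = X.shape
    design = np.column_stack([X, np.ones(n)])
    meta = [(f"r{j}", "linear") for j in range(q)] + [("", "basal")]
    lo = np.full(q + 1, -np.inf)
    hi = np.full(q + 1, np.inf)
    if bounds:
        for j, (a, b) in bounds.items():
            lo[j], hi[j] = a, b
    return RegressionProblem("y", "GRN", np.asarray(y, float), design, meta, lo, hi)


class TestBuildRegression:
    def test_ppi_product_column(self):
        nodes = make_node_table([("A", "protein"), ("B", "protein")])
        net = gwgen.CandidateNetwork(nodes, pd.DataFrame(
            [("A", "B", "PPI")], columns=["source", "target", "edge_class"]))
        data = _dataset({"A": [1.0, 2.0], "B": [3.0, 4.0]})
        prob = build_regression("A", "PPIN", net, data)
        assert prob.design.shape == (2, 2)
        assert np.allclose(prob.design[:, 0], [3.0, 8.0])

    def test_mirna_repression_column_is_target_times_mirna(self):
        nodes = make_node_table([("G", "protein"), ("K", "miRNA")])
        net = gwgen.CandidateNetwork(nodes, pd.DataFrame(
            [("K", "G", "M-G")], columns=["source", "target", "edge_class"]))
        data = _dataset({"G": [2.0, 1.0], "K": [1.0, 3.0]})
        prob = build_regression("G", "GRN", net, data)
        assert np.allclose(prob.design[:, 0], [2.0, 3.0])
        assert prob.upper[0] == 0.0 and prob.lower[0] == -np.inf

    def test_no_regulators_gives_basal_only_design(self):
        nodes = make_node_table([("A", "protein")])
        net = gwgen.CandidateNetwork(nodes)
        data = _dataset({"A": [5.0, 5.0, 5.0]})
        prob = build_regression("A", "GRN", net, data)
        assert prob.design.shape == (3, 1)
        assert np.allclose(prob.design[:, 0], 1.0)

    def test_missing_regulator_named_in_error(self):
        nodes = make_node_table([("A", "protein"), ("B", "protein")])
        net = gwgen.CandidateNetwork(nodes, pd.DataFrame(
            [("A", "B", "PPI")], columns=["source", "target", "edge_class"]))
        data = _dataset({"A": [1.0, 2.0]})
        with pytest.raises(KeyError, match="'B'"):
            build_regression("B", "PPIN", net, data)


class TestEstimateParameters:
    def test_unconstrained_recovers_ols_solution(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 2))
        y = 2.0 * X[:, 0] - 1.0 * X[:, 1] + 0.5
        theta, rv = estimate_parameters(_linear_problem(y, X))
        assert np.allclose(theta, [2.0, -1.0, 0.5], atol=1e-8)
        assert rv < 1e-16

    def test_sign_violating_column_clamped_at_zero(self):
        # response truly increases with the bounded column -> estimate at bound
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        y = 1.5 * x + rng.normal(scale=0.01, size=30)
        prob = _linear_problem(y, x[:, None], bounds={0: (-np.inf, 0.0)})
        theta, _ = estimate_parameters(prob)
        # independent oracle: NNLS on the negated column
        from scipy.optimize import nnls

        design = np.column_stack([-x, np.ones(30), -np.ones(30)])
        sol, _ = nnls(design, y)
        assert theta[0] == 0.0
        assert np.isclose(-sol[0], theta[0], atol=1e-10)

    def test_constant_response_basal_only(self):
        prob = _linear_problem(np.full(5, 3.25), np.empty((5, 0)))
        theta, rv = estimate_parameters(prob)
        assert np.isclose(theta[-1], 3.25)
        assert rv < 1e-20


class TestDetectOrder:
    def test_aic_formula_hand_value(self):
        # N=10, RSS=1.0, Y=2 -> ln(0.1) + 6/10
        assert np.isclose(aic_value(1.0, 10, 2), np.log(0.1) + 0.6)
        assert np.isclose(aic_value(1.0, 10, 2), -1.70259, atol=1e-5)

    def test_noiseless_true_order_recovered(self):
        rng = np.random.default_rng(42)
        X = 8 + rng.normal(size=(40, 6))
        y = 1.2 * X[:, 1] - 0.7 * X[:, 4] + 3.0
        m = detect_order(_linear_problem(y, X))
        assert m.selected_order == 2
        assert set(m.coefficients) == {"r1", "r4"}
        assert np.isclose(m.coefficients["r1"], 1.2)
        # agrees with the exhaustive best-subset oracle
        k, subset = exhaustive_best_subset(_linear_problem(y, X))
        assert (k, set(subset)) == (2, {1, 4})

    def test_rss_monotone_along_trace(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 5))
        y = X[:, 0] + rng.normal(size=30)
        m = detect_order(_linear_problem(y, X))
        rss = [np.exp(a - 2 * (o + 1) / 30) for o, a in m.aic_trace if np.isfinite(a)]
        assert all(b <= a + 1e-12 for a, b in zip(rss, rss[1:]))

    def test_perfect_fit_gets_sentinel_and_stops(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        y = 2.0 * X[:, 0]
        m = detect_order(_linear_problem(y, X))
        assert m.aic_trace[-1][1] == -np.inf
        assert m.selected_order == 1

    def test_order_capped_at_n_minus_2(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(6, 10))
        y = rng.normal(size=6)
        m = detect_order(_linear_problem(y, X))
        assert max(o for o, _ in m.aic_trace) <= 4

    def test_greedy_matches_exhaustive_on_null_responses(self):
        """Pure-noise responses: greedy and exhaustive AIC select the same
        order; order 0 is not the majority outcome because retaining one null
        regressor only requires the best of q chi-square(1) drops to beat 2."""
        rng = np.random.default_rng(2024)
        agree = 0
        order0 = 0
        for _ in range(50):
            X = 8 + rng.normal(size=(100, 5))
            y = 8 + rng.normal(size=100)
            prob = _linear_problem(y, X)
            m = detect_order(prob)
            k, _ = exhaustive_best_subset(prob)
            agree += m.selected_order == k
            order0 += m.selected_order == 0
        assert agree >= 48
        # oracle-computed frequency band: P(select 0) ~ (1 - 0.157)^5 ~ 0.43
        assert 10 <= order0 <= 35


class TestIdentifyGWGEN:
    def test_truth_candidate_noiseless_recovers_exact_edge_set(self):
        # regulator classes are kept exogenous: with zero noise a regulated
        # regulator is an exact linear function of its own parents, making
        # the edge set non-identifiable (a perfect fit exists without it)
        cfg = gwgen.SimulationConfig(
            node_counts={"TF": 8, "lncRNA": 3, "miRNA": 4, "receptor": 4, "protein": 20},
            source_fraction={"TF": 1.0, "lncRNA": 1.0, "miRNA": 1.0,
                             "receptor": 0.5, "protein": 0.2},
            seed=21, noise_sd=0.0)
        truth = gwgen.generate_ground_truth(cfg)
        data = gwgen.simulate_expression(truth, 40, "quiet")
        cand = gwgen.corrupt_candidate(truth, 0.0, seed=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            real = gwgen.identify_gwgen(cand, data, "quiet")
        scores = gwgen.recovery_scores(truth, real)
        assert scores["fp"] == 0 and scores["fn"] == 0

    def test_real_edges_subset_of_candidates(self, small_candidate, small_real):
        from gwgen.sysid import _edge_key_set

        assert _edge_key_set(small_real.edges) <= _edge_key_set(small_candidate.edges)
        assert len(small_real.edges) <= len(small_candidate.edges)

    def test_repression_estimates_exactly_nonnegative(self, small_real):
        for m in small_real.models.values():
            for reg, term in m.terms.items():
                if term == "repression":
                    assert m.coefficients[reg] >= 0.0

    def test_stage_independence(self, small_truth, small_candidate):
        """Permuting another stage's samples leaves this stage's network identical."""
        rng = np.random.default_rng(0)
        a = gwgen.simulate_expression(small_truth, 20, "quiet")
        b = gwgen.simulate_expression(small_truth, 20, "exacerbation")
        both = a.concat(b)
        perm = list(b.values.columns)
        rng.shuffle(perm)
        b_perm = ExpressionDataset(b.values[perm], b.stages[perm])
        both2 = a.concat(b_perm)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r1 = gwgen.identify_gwgen(small_candidate, both, "quiet")
            r2 = gwgen.identify_gwgen(small_candidate, both2, "quiet")
        pd.testing.assert_frame_equal(r1.edges, r2.edges)

    def test_missing_node_dropped_with_warning(self, small_candidate, small_data):
        trimmed = ExpressionDataset(small_data.values.iloc[:-2], small_data.stages)
        with pytest.warns(UserWarning, match="absent"):
            real = gwgen.identify_gwgen(small_candidate, trimmed, "quiet")
        dropped = set(small_data.values.index[-2:])
        assert not (set(real.nodes["node_id"]) & dropped)

    def test_save_load_round_trip(self, tmp_path, small_real):
        gwgen.save_real_gwgen(small_real, tmp_path / "net", aic_trace=True)
        back = gwgen.load_real_gwgen(tmp_path / "net")
        assert set(back.models) == set(small_real.models)
        for key, m in small_real.models.items():
            assert back.models[key].coefficients == pytest.approx(m.coefficients)
            assert back.models[key].basal == pytest.approx(m.basal)
        assert len(back.edges) == len(small_real.edges)


class TestParameterRecovery:
    def test_rmse_shrinks_with_noise(self):
        """Coefficient RMSE on retained true edges tends to zero as noise does."""
        import dataclasses

        base = gwgen.SimulationConfig(
            node_counts={"TF": 10, "lncRNA": 3, "miRNA": 5, "receptor": 5, "protein": 25},
            seed=8)
        rmses = []
        for noise in (0.3, 0.01):
            cfg = dataclasses.replace(base, noise_sd=noise)
            truth = gwgen.generate_ground_truth(cfg)
            data = gwgen.simulate_expression(truth, 60, "quiet")
            cand = gwgen.corrupt_candidate(truth, 0.0, seed=4)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                real = gwgen.identify_gwgen(cand, data, "quiet")
            rmses.append(gwgen.coefficient_rmse(truth, real)["rmse"])
        assert rmses[1] < rmses[0]
        assert rmses[1] < 0.01
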