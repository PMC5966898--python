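"""Weighted NMF engine: recovery, invariances, sweeps, consensus."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linear_sum_assignment

from omicspatterns import (
    RobustnessSweep,
    SimConfig,
    UncertaintyMatrix,
    fit,
    fit_amplitudes,
    generate_time_course,
    parallel_sets_consensus,
    select_dimensionality,
    sweep_dimensions,
    uncertainty_for,
)
from omicspatterns.factorization import _svd_init, _objective, greedy_match


def hungarian_cosines(P_fit, P_true):
    Pf = np.asarray(P_fit, float)
    Pt = np.asarray(P_true, float)
    C = (Pf / np.linalg.norm(Pf, axis=1, keepdims=True)) @ (
        Pt / np.linalg.norm(Pt, axis=1, keepdims=True)
    ).T
    r, c = linear_sum_assignment(-C)
    return C[r, c]


def constant_sigma(df, value=1.0):
    return UncertaintyMatrix(sigma=pd.DataFrame(value, index=df.index, columns=df.columns))


class TestFit:
    def test_rank1_noiseless_recovery(self):
        rng = np.random.default_rng(0)
        a = rng.gamma(2, 1, 40)
        p = rng.uniform(0.1, 1, 8)
        D = pd.DataFrame(np.outer(a, p))
        F = fit(D, constant_sigma(D), 1, n_restarts=2, seed=1)
        R = F.reconstruct().to_numpy()
        assert np.linalg.norm(R - D.to_numpy()) / np.linalg.norm(D.to_numpy()) < 1e-6
        assert hungarian_cosines(F.P, p[None, :])[0] > 0.9999

    def test_three_pattern_noiseless_recovery(self):
        expr, *_ , truth = generate_time_course(
            SimConfig(n_genes=300, p_expr=3, seed=5, noise_scale=0.0)
        )
        F = fit(expr, uncertainty_for(expr), 3, n_restarts=2, seed=2)
        cos = hungarian_cosines(F.P, truth.P_true["expression"])
        assert (cos >= 0.99).all()

    def test_column_permutation_equivariance(self):
        expr, *_ , _ = generate_time_course(SimConfig(n_genes=150, seed=8))
        sigma = uncertainty_for(expr)
        F = fit(expr.values, sigma.sigma, 3, n_restarts=1, seed=3)
        perm = list(np.random.default_rng(1).permutation(list(expr.values.columns)))
        F2 = fit(expr.values[perm], sigma.sigma[perm], 3, n_restarts=1, seed=3)
        pd.testing.assert_frame_equal(F.A, F2.A, atol=1e-8, rtol=1e-6)
        pd.testing.assert_frame_equal(F.P[perm], F2.P, atol=1e-8, rtol=1e-6)

    def test_bit_identical_under_seed(self, sim_default):
        expr, *_ = sim_default
        sigma = uncertainty_for(expr)
        F1 = fit(expr, sigma, 4, n_restarts=2, seed=9)
        F2 = fit(expr, sigma, 4, n_restarts=2, seed=9)
        assert F1.A.equals(F2.A) and F1.P.equals(F2.P) and F1.chi2 == F2.chi2

    def test_nonnegativity_and_row_normalization(self, sim_default):
        expr, *_ = sim_default
        F = fit(expr, uncertainty_for(expr), 5, n_restarts=1, seed=0)
        assert (F.A.to_numpy() >= 0).all() and (F.P.to_numpy() >= 0).all()
        assert np.allclose(F.P.max(axis=1), 1.0)
        assert np.isfinite(F.chi2)

    def test_objective_beats_svd_initialization(self, sim_default):
        expr, *_ = sim_default
        sigma = uncertainty_for(expr)
        F = fit(expr, sigma, 4, n_restarts=2, seed=1)
        D = expr.values.to_numpy()
        W = 1.0 / sigma.sigma.to_numpy() ** 2
        A0, P0 = _svd_init(D, 4, np.random.default_rng(0))
        assert F.chi2 <= _objective(D, W, A0, P0, 0.0)

    def test_sigma_rescaling_leaves_argmin_unchanged(self, sim_default):
        expr, *_ = sim_default
        sigma = uncertainty_for(expr)
        doubled = UncertaintyMatrix(sigma=2.0 * sigma.sigma)
        F1 = fit(expr, sigma, 3, n_restarts=1, seed=4, sparsity=0.0)
        F2 = fit(expr, doubled, 3, n_restarts=1, seed=4, sparsity=0.0)
        pd.testing.assert_frame_equal(F1.A, F2.A, atol=1e-7, rtol=1e-5)
        assert F2.chi2 == pytest.approx(F1.chi2 / 4.0, rel=1e-6)

    def test_objective_trace_monotone_after_init(self, sim_default):
        expr, *_ = sim_default
        F = fit(expr, uncertainty_for(expr), 3, n_restarts=1, seed=2, sparsity=0.0)
        trace = np.array(F.objective_trace)
        assert (np.diff(trace) <= 1e-8 * np.abs(trace[:-1])).all()

    def test_invalid_p_rejected(self, sim_default):
        expr, *_ = sim_default
        with pytest.raises(ValueError):
            fit(expr, uncertainty_for(expr), 25, seed=0)
        with pytest.raises(ValueError):
            fit(expr, uncertainty_for(expr), 0, seed=0)

    def test_missing_entries_get_zero_weight(self):
        rng = np.random.default_rng(3)
        D = pd.DataFrame(np.outer(rng.gamma(2, 1, 30), rng.uniform(0.1, 1, 10)))
        sig = pd.DataFrame(1.0, index=D.index, columns=D.columns)
        D_miss = D.copy()
        D_miss.iloc[0, 0] = np.nan
        F = fit(D_miss, sig, 1, n_restarts=1, seed=0)
        # reconstruction of observed entries unaffected by the missing one
        R = F.reconstruct().to_numpy()
        mask = ~np.isnan(D_miss.to_numpy())
        assert np.abs((R - D.to_numpy())[mask]).max() < 1e-4


class TestSweepAndSelection:
    def test_noiseless_rank2_similarity_ordering(self):
        rng = np.random.default_rng(1)
        A = np.zeros((200, 2))
        half = 100
        A[:half, 0] = rng.gamma(2, 1, half) + 0.5
        A[half:, 1] = rng.gamma(2, 1, half) + 0.5
        P = rng.uniform(0.05, 1, (2, 12))
        D = pd.DataFrame(A @ P + rng.normal(0, 0.01, (200, 12)))
        sw = sweep_dimensions(D, constant_sigma(D, 0.05), range(1, 5),
                              n_restarts=3, seed=0)
        assert sw.min_similarity[2] > 0.95
        assert sw.min_similarity[2] > sw.min_similarity[3]
        assert sw.min_similarity[2] > sw.min_similarity[4]

    def test_single_p_and_single_restart_contracts(self):
        rng = np.random.default_rng(2)
        D = pd.DataFrame(rng.gamma(2, 1, (40, 8)))
        sw = sweep_dimensions(D, constant_sigma(D), [2], n_restarts=1, seed=0)
        assert list(sw.similarity) == [2]
        assert sw.similarity[2] is None
        with pytest.raises(ValueError):
            select_dimensionality(sw)

    def test_selection_rule_and_fallback(self):
        sw = RobustnessSweep(similarity={}, min_similarity={2: 0.99, 3: 0.97, 4: 0.6},
                             chi2={})
        assert select_dimensionality(sw, threshold=0.85) == (3, True)
        sw_bad = RobustnessSweep(similarity={}, min_similarity={2: 0.5, 3: 0.4}, chi2={})
        with pytest.warns(RuntimeWarning):
            p, ok = select_dimensionality(sw_bad, threshold=0.85)
        assert (p, ok) == (2, False)

    def test_rebound_above_threshold_not_selected(self):
        sw = RobustnessSweep(similarity={},
                             min_similarity={2: 0.99, 3: 0.95, 4: 0.5, 5: 0.9},
                             chi2={})
        assert select_dimensionality(sw, threshold=0.85) == (3, True)


class TestParallelSetsConsensus:
    def test_noiseless_consensus_matches_truth(self):
        expr, *_ , truth = generate_time_course(
            SimConfig(n_genes=400, p_expr=3, seed=6, noise_scale=0.0)
        )
        F = parallel_sets_consensus(expr, uncertainty_for(expr), 3, n_sets=2, seed=1)
        cos = hungarian_cosines(F.P, truth.P_true["expression"])
        assert (cos >= 0.99).all()

    def test_single_set_rejected(self, sim_default):
        expr, *_ = sim_default
        with pytest.raises(ValueError):
            parallel_sets_consensus(expr, uncertainty_for(expr), 3, n_sets=1, seed=0)

    def test_partition_seed_stability(self, sim_default):
        expr, *_ = sim_default
        sigma = uncertainty_for(expr)
        F1 = parallel_sets_consensus(expr, sigma, 3, n_sets=2, seed=1)
        F2 = parallel_sets_consensus(expr, sigma, 3, n_sets=2, seed=2)
        cos = hungarian_cosines(F1.P, F2.P)
        assert (cos >= 0.95).all()

    def test_fit_amplitudes_with_fixed_patterns(self, sim_noiseless):
        expr, *_ , truth = sim_noiseless
        A = fit_amplitudes(expr, uncertainty_for(expr), truth.P_true["expression"])
        # with the true patterns fixed, amplitudes reproduce the data
        R = A.to_numpy() @ truth.P_true["expression"].to_numpy()
        assert np.abs(R - expr.values.to_numpy()).max() < 1e-6


def test_greedy_match_prefers_best_pairs():
    C = np.array([[0.9, 0.2], [0.85, 0.8]])
    pairs = greedy_match(C)
    assert (0, 0, 0.9) in [(i, j, round(s, 2)) for i, j, s in pairs]
    assert {j for _, j, _ in pairs} == {0, 1}
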