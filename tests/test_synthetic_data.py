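import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bandcorr.core_model import ConstantRates
from bandcorr.synthetic_data import (
    MArray,
    SimulationConfig,
    annual_probabilities,
    cell_probabilities,
    draw_generating_params,
    simulate_effects,
    simulate_marray,
)


class TestGeneratingParams:
    def test_hyperprior_means(self):
        cfg = SimulationConfig()
        rng = np.random.default_rng(0)
        draws = np.array(
            [draw_generating_params(cfg, rng) for _ in range(100_000)]
        )
        # gamma(20, 80) mean 0.25; uniform(-0.9, 0) mean -0.45
        assert draws[:, 0].mean() == pytest.approx(0.25, abs=0.002)
        assert draws[:, 1].mean() == pytest.approx(0.25, abs=0.002)
        assert draws[:, 2].mean() == pytest.approx(-0.45, abs=0.003)
        assert draws[:, 2].min() >= -0.9 and draws[:, 2].max() <= 0.0

    def test_degenerate_rho_interval(self):
        cfg = SimulationConfig(rho_range=(-0.5, -0.5))
        rng = np.random.default_rng(1)
        for _ in range(5):
            assert draw_generating_params(cfg, rng)[2] == -0.5

    def test_seeded_determinism(self):
        cfg = SimulationConfig()
        a = draw_generating_params(cfg, np.random.default_rng(3))
        b = draw_generating_params(cfg, np.random.default_rng(3))
        assert a == b


class TestSimulateEffects:
    def test_vanishing_scale_collapses_to_zero(self):
        eps = simulate_effects(1e-12, 1e-12, -0.5, 50, np.random.default_rng(0))
        assert np.max(np.abs(eps)) < 1e-10

    def test_sample_covariance_matches_target(self):
        n = 100_000
        eps = simulate_effects(0.3, 0.2, -0.9, n, np.random.default_rng(5))
        cov = np.cov(eps.T)
        assert cov[0, 0] == pytest.approx(0.09, rel=0.02)
        assert cov[1, 1] == pytest.approx(0.04, rel=0.02)
        assert cov[0, 1] == pytest.approx(-0.9 * 0.3 * 0.2, rel=0.02)
        r = np.corrcoef(eps.T)[0, 1]
        assert r == pytest.approx(-0.9, abs=3 / math.sqrt(n))

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            simulate_effects(0.3, 0.2, -1.5, 10, np.random.default_rng(0))


class TestAnnualProbabilities:
    def test_zero_effects_reference_year(self):
        # with all effects zero, every year has hazards e^-1 each, so
        # S = exp(-2/e) and f = kappa * (1-c) * b
        cfg = SimulationConfig(T=5)
        S, f = annual_probabilities(cfg, np.zeros((5, 2)))
        h = math.exp(-1)
        S_expected = math.exp(-2 * h)
        kappa = (1 - S_expected) / 2
        assert np.allclose(S, S_expected, atol=1e-14)
        assert np.allclose(f, kappa * 0.8 * 0.5, atol=1e-14)
        assert S_expected == pytest.approx(0.4791, abs=5e-5)

    def test_extreme_negative_hunting_effect_kills_recovery(self):
        cfg = SimulationConfig(T=2)
        eps = np.array([[-19.0, 0.0], [-19.0, 0.0]])
        _, f = annual_probabilities(cfg, eps)
        assert np.all(f < 1e-8)

    def test_effects_beyond_clip_are_guarded(self, caplog):
        cfg = SimulationConfig(T=2)
        eps = np.array([[50.0, 0.0], [0.0, 0.0]])
        with caplog.at_level("WARNING"):
            S, f = annual_probabilities(cfg, eps)
        assert np.all(np.isfinite(S)) and np.all(np.isfinite(f))

    def test_consistent_relabelling_permutes_outputs(self):
        cfg = SimulationConfig(T=6)
        rng = np.random.default_rng(2)
        eps = rng.normal(0, 0.3, (6, 2))
        S, f = annual_probabilities(cfg, eps)
        perm = np.array([3, 1, 5, 0, 2, 4])
        S2, f2 = annual_probabilities(cfg, eps[perm])
        np.testing.assert_allclose(S2, S[perm])
        np.testing.assert_allclose(f2, f[perm])


class TestCellProbabilities:
    def test_two_year_enumeration(self):
        # fate enumeration with S=(0.5, 0.5), f=(0.1, 0.1):
        # cohort 1: recovered yr1 0.1; survive then recovered yr2 0.5*0.1;
        # otherwise 0.85.  cohort 2: 0.1 / 0.9.
        P = cell_probabilities([0.5, 0.5], [0.1, 0.1])
        np.testing.assert_allclose(P, [[0.1, 0.05, 0.85], [0.0, 0.1, 0.9]])

    def test_no_recovery_means_never_column_is_one(self):
        P = cell_probabilities([0.7, 0.6, 0.5], [0.0, 0.0, 0.0])
        np.testing.assert_allclose(P[:, -1], 1.0)

    @given(st.integers(2, 8), st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_rows_sum_to_one_with_structural_zeros(self, T, seed):
        rng = np.random.default_rng(seed)
        S = rng.uniform(0.2, 0.95, T)
        f = rng.uniform(0, 0.2, T)
        P = cell_probabilities(S, f)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(P[np.tril_indices(T, k=-1)] == 0)
        np.testing.assert_allclose(np.diag(P[:, :T]), f)


class TestSimulateMArray:
    def test_rows_conserve_releases_and_structural_zeros(self):
        cfg = SimulationConfig(T=12, releases=777)
        marray, _ = simulate_marray(cfg, np.random.default_rng(0))
        assert np.all(marray.counts.sum(axis=1) == 777)
        tri = np.tril_indices(12, k=-1)
        assert np.all(marray.counts[:, :12][tri] == 0)

    def test_counts_match_expected_cell_frequencies(self):
        """Mean of replicate m-arrays at fixed truth approaches releases x P."""
        cfg = SimulationConfig(T=4, releases=1000, rho_range=(-0.5, -0.5))
        rng = np.random.default_rng(8)
        _, truth = simulate_marray(cfg, rng)
        P = cell_probabilities(truth.S, truth.f)
        total = np.zeros_like(P)
        n_rep = 1000
        for _ in range(n_rep):
            for t in range(cfg.T):
                total[t] += rng.multinomial(1000, P[t])
        mean = total / n_rep
        # 4 MC standard errors entrywise
        se = np.sqrt(np.maximum(P * (1 - P), 1e-12) * 1000 / n_rep)
        assert np.all(np.abs(mean - 1000 * P) < 4 * se + 1e-9)

    def test_fixed_seed_bit_identical(self):
        cfg = SimulationConfig(T=10)
        m1, t1 = simulate_marray(cfg, np.random.default_rng(123))
        m2, t2 = simulate_marray(cfg, np.random.default_rng(123))
        np.testing.assert_array_equal(m1.counts, m2.counts)
        assert t1.rho == t2.rho

    def test_realized_rho_recomputable_from_stored_effects(self):
        cfg = SimulationConfig(T=20)
        _, truth = simulate_marray(cfg, np.random.default_rng(3))
        hazard_corr = np.corrcoef(
            np.exp(truth.epsilon[:, 0]), np.exp(truth.epsilon[:, 1])
        )[0, 1]
        assert truth.realized_rho == pytest.approx(hazard_corr, abs=1e-12)
        log_corr = np.corrcoef(truth.epsilon[:, 0], truth.epsilon[:, 1])[0, 1]
        assert truth.realized_rho_log == pytest.approx(log_corr, abs=1e-12)
        assert -1 <= truth.realized_rho <= 1

    def test_realized_hazard_correlation_attenuates_toward_zero(self):
        """Log-normal transform weakens the correlation: on average the
        hazard-scale realized correlation sits slightly nearer zero than the
        log-scale one."""
        cfg = SimulationConfig(T=36)
        rng = np.random.default_rng(11)
        diffs = []
        for _ in range(200):
            _, truth = simulate_marray(
                SimulationConfig(T=36, releases=10), rng
            )
            diffs.append(truth.realized_rho - truth.realized_rho_log)
        assert np.mean(diffs) > 0.005  # attenuation toward zero (rho < 0)

    def test_shared_probabilities_when_scale_vanishes(self):
        cfg = SimulationConfig(T=6, releases=200_000,
                               sigma_hyper=(20.0, 2e6), rho_range=(-0.5, -0.5))
        marray, truth = simulate_marray(cfg, np.random.default_rng(4))
        assert np.ptp(truth.f) < 1e-3
        diag = np.diag(marray.counts[:, :6]) / 200_000
        assert np.allclose(diag, truth.f.mean(), atol=4 * np.sqrt(0.075 / 200_000) + 1e-3)


class TestMArrayValidation:
    def test_row_sum_violation_names_row(self):
        counts = np.array([[1, 1, 8], [0, 2, 8]])
        with pytest.raises(ValueError, match="row 1"):
            MArray(counts=counts, releases=np.array([11, 10]))

    def test_subdiagonal_nonzero_rejected(self):
        counts = np.array([[1, 1, 8], [1, 2, 7]])
        with pytest.raises(ValueError, match="before release"):
            MArray(counts=counts, releases=np.array([10, 10]))

    def test_negative_count_rejected(self):
        counts = np.array([[-1, 1, 10], [0, 2, 8]])
        with pytest.raises(ValueError, match="negative"):
            MArray(counts=counts, releases=np.array([10, 10]))


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(T=1)
    with pytest.raises(ValueError):
        SimulationConfig(rho_range=(0.5, -0.5))
    with pytest.raises(ValueError):
        SimulationConfig(sigma_hyper=(0.0, 80.0))
    with pytest.raises(ValueError):
        SimulationConfig(releases=0)
    assert ConstantRates(0.2, 0.5).c == 0.2
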