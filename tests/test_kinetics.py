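"""Forward model and rate estimators."""

import numpy as np
import pytest

from rnacycle.kinetics import (
    ConvergenceError,
    ExpressionProfiles,
    PhaseGrid,
    RateProfiles,
    estimate_rates_full,
    estimate_rates_simplified,
    phase_shift,
    predict_mature_profiles,
    predict_with_constant_rate,
    simulate_labeled_profiles,
    simulate_mature_only,
    simulate_simplified_profiles,
    simulate_total_profiles,
    solve_gamma_quadratic,
)
from rnacycle.synthetic import SineTarget, rates_case1


def _const_rates(grid, alpha, beta, gamma):
    n = grid.n_points
    return RateProfiles(grid, alpha=np.full(n, alpha), beta=np.full(n, beta),
                        gamma=np.full(n, gamma))


def _steady_state_full_profiles(grid, a, b, g, t):
    """Exact short-labeling closed forms at steady state (constant rates)."""
    n = grid.n_points
    p0, m0 = a / b, a / g
    pu = p0 * np.exp(-t * b)
    pl = (a / b) * (1 - np.exp(-t * b))
    mu = b * p0 / (g - b) * np.exp(-t * b) + (m0 - b * p0 / (g - b)) * np.exp(-t * g)
    ml = a / g - a / (g - b) * np.exp(-t * b) + a * b / (g * (g - b)) * np.exp(-t * g)
    return ExpressionProfiles(
        grid, t,
        pu=np.full(n, pu), mu=np.full(n, mu), pl=np.full(n, pl), ml=np.full(n, ml),
    )


class TestPhaseGrid:
    def test_omega_times_period_is_two_pi(self):
        grid = PhaseGrid(100, 19.33)
        assert grid.omega * grid.period_hours == pytest.approx(2 * np.pi)

    def test_phases_uniform(self):
        grid = PhaseGrid(64, 10.0)
        assert np.allclose(np.diff(grid.phases), grid.spacing)

    def test_phase_shift_wraps(self):
        grid = PhaseGrid(100, 19.33)
        vals = np.sin(grid.phases)
        shifted = phase_shift(vals, grid, -0.7)
        assert np.allclose(shifted, np.sin(grid.phases - 0.7), atol=1e-6)


class TestTotalSimulation:
    def test_constant_rates_reach_steady_state(self, grid500):
        rates = _const_rates(grid500, 10.0, 12.0, 0.5)
        p, m, n_cycles = simulate_total_profiles(rates, grid500)
        assert np.allclose(p, 10.0 / 12.0, rtol=1e-9)
        assert np.allclose(m, 20.0, rtol=1e-9)
        assert n_cycles <= 2

    def test_case1_reproduces_target_quickly(self, grid500, sine_target):
        rates = rates_case1(sine_target, beta=12.0, gamma=0.5, grid=grid500)
        p, m, n_cycles = simulate_total_profiles(rates, grid500, rel_tol=1e-6)
        target = sine_target.m(grid500.phases)
        assert np.max(np.abs(m - target) / target) < 1e-3
        assert n_cycles <= 10

    def test_nonconvergence_raises(self, grid500, sine_target):
        rates = rates_case1(sine_target, beta=12.0, gamma=0.5, grid=grid500)
        with pytest.raises(ConvergenceError):
            simulate_total_profiles(rates, grid500, rel_tol=1e-6, max_cycles=1)


class TestLabeledSimulation:
    def test_zero_labeling_time(self, grid500, sine_target):
        rates = rates_case1(sine_target, beta=12.0, gamma=0.5, grid=grid500)
        p, m, _ = simulate_total_profiles(rates, grid500)
        prof = simulate_labeled_profiles(rates, p, m, 0.0, grid500)
        assert np.array_equal(prof.pl, np.zeros_like(p))
        assert np.array_equal(prof.ml, np.zeros_like(m))
        assert np.array_equal(prof.pu, p)
        assert np.array_equal(prof.mu, m)

    def test_labeling_beyond_period_rejected(self, grid500, sine_target):
        rates = rates_case1(sine_target, beta=12.0, gamma=0.5, grid=grid500)
        p, m, _ = simulate_total_profiles(rates, grid500)
        with pytest.raises(ValueError):
            simulate_labeled_profiles(rates, p, m, 20.0, grid500)

    def test_constant_rates_match_closed_forms(self, grid500):
        a, b, g, t = 10.0, 12.0, 0.5, 1.0
        rates = _const_rates(grid500, a, b, g)
        p, m, _ = simulate_total_profiles(rates, grid500)
        prof = simulate_labeled_profiles(rates, p, m, t, grid500)
        expected = _steady_state_full_profiles(grid500, a, b, g, t)
        for name in ("pu", "mu", "pl", "ml"):
            assert np.allclose(getattr(prof, name), getattr(expected, name), rtol=1e-7)

    def test_conservation_under_dynamic_rates(self, dynamic_full_rates, grid500):
        p, m, _ = simulate_total_profiles(dynamic_full_rates, grid500)
        prof = simulate_labeled_profiles(dynamic_full_rates, p, m, 1.0, grid500)
        assert np.max(np.abs(prof.p - p) / p) < 1e-6
        assert np.max(np.abs(prof.m - m) / m) < 1e-6

    def test_labeled_species_vanish_as_t_to_zero(self, dynamic_full_rates, grid500):
        p, m, _ = simulate_total_profiles(dynamic_full_rates, grid500)
        pl_means, ml_means = [], []
        for t in (0.008, 0.004, 0.002):
            prof = simulate_labeled_profiles(dynamic_full_rates, p, m, t, grid500)
            pl_means.append(np.mean(prof.pl))
            ml_means.append(np.mean(prof.ml))
        # labeled precursors vanish linearly in t (halving t halves pl);
        # labeled matures vanish faster (they require splicing first)
        assert pl_means[0] / pl_means[1] == pytest.approx(2.0, rel=0.05)
        assert pl_means[1] / pl_means[2] == pytest.approx(2.0, rel=0.05)
        assert ml_means[0] > ml_means[1] > ml_means[2] > 0
        assert ml_means[0] / ml_means[1] > 2.0


class TestFullModelEstimation:
    def test_steady_state_alpha_beta(self, grid200):
        prof = _steady_state_full_profiles(grid200, 8.0, 2.0, 0.4, 0.25)
        est = estimate_rates_full(prof)
        assert np.allclose(est.beta, 2.0, rtol=1e-10)
        assert np.allclose(est.alpha, 8.0, rtol=1e-10)

    def test_gamma_quadratic_steady_state_root(self, grid200):
        prof = _steady_state_full_profiles(grid200, 8.0, 2.0, 0.4, 0.25)
        gamma = solve_gamma_quadratic(prof, np.full(grid200.n_points, 2.0))
        assert np.allclose(gamma, 0.4, rtol=1e-9)

    def test_no_splicing_gives_zero_beta(self, grid200):
        n = grid200.n_points
        p = np.full(n, 4.0)
        prof = ExpressionProfiles(grid200, 0.25, pu=p.copy(), mu=np.full(n, 20.0),
                                  pl=np.full(n, 1e-9), ml=np.full(n, 1e-9))
        est = estimate_rates_full(prof)
        assert np.allclose(est.beta, 0.0, atol=1e-8)

    def test_dynamic_recovery_short_labeling(self, dynamic_full_rates, grid500):
        p, m, _ = simulate_total_profiles(dynamic_full_rates, grid500)
        prof = simulate_labeled_profiles(dynamic_full_rates, p, m, 0.1, grid500)
        est = estimate_rates_full(prof)
        for name in ("alpha", "beta", "gamma"):
            err = np.median(
                np.abs(getattr(est, name) - getattr(dynamic_full_rates, name))
                / getattr(dynamic_full_rates, name)
            )
            assert err < 0.05, name


class TestSimplifiedEstimation:
    def test_steady_state_recovery(self, grid200):
        n = grid200.n_points
        a, g, t = 10.0, 0.5, 1.0
        m = np.full(n, a / g)
        mu = m * np.exp(-g * t)
        ml = (a / g) * (1 - np.exp(-g * t))
        alpha_hat, gamma_hat = estimate_rates_simplified(mu, ml, m, t, grid200)
        assert np.allclose(gamma_hat, 0.5, rtol=1e-10)
        assert np.allclose(alpha_hat, 10.0, rtol=1e-10)

    def test_no_decay_limit(self, grid200):
        n = grid200.n_points
        m = np.full(n, 20.0)
        ml = np.full(n, 3.0)
        alpha_hat, gamma_hat = estimate_rates_simplified(m.copy(), ml, m, 1.0, grid200)
        assert np.allclose(gamma_hat, 0.0)
        assert np.allclose(alpha_hat, 3.0)  # ml / t

    def test_noise_guard_floors_gamma(self, grid200):
        n = grid200.n_points
        m = np.full(n, 20.0)
        mu = np.full(n, 21.0)  # more unlabeled than the onset total: noise
        ml = np.full(n, 1.0)
        _alpha, gamma_hat = estimate_rates_simplified(mu, ml, m, 1.0, grid200)
        assert np.all(gamma_hat == 0.0)

    def test_closed_form_profiles_inverted_exactly(self, grid500):
        ph = grid500.phases
        rates = RateProfiles(
            grid500,
            alpha=10.0 * (1.0 + 0.3 * np.sin(ph)),
            beta=np.full(grid500.n_points, 12.0),
            gamma=0.5 * (1.0 + 0.3 * np.sin(ph + 1.0)),
        )
        m = simulate_mature_only(rates.alpha, rates.gamma, grid500)
        mu, ml = simulate_simplified_profiles(rates, m, 1.0, grid500)
        alpha_hat, gamma_hat = estimate_rates_simplified(mu, ml, m, 1.0, grid500)
        assert np.median(np.abs(gamma_hat - rates.gamma) / rates.gamma) < 1e-10
        assert np.median(np.abs(alpha_hat - rates.alpha) / rates.alpha) < 1e-10


class TestPrediction:
    def test_constant_rate_closed_form(self, grid200):
        n = grid200.n_points
        a, g, t = 10.0, 0.5, 1.0
        m = np.full(n, a / g)
        mu_pred, ml_pred, m_pred = predict_mature_profiles(
            np.full(n, a), np.full(n, g), m, t, grid200
        )
        assert np.allclose(mu_pred, (a / g) * np.exp(-g * t), rtol=1e-8)
        assert np.allclose(ml_pred, (a / g) * (1 - np.exp(-g * t)), rtol=1e-5)

    def test_zero_gamma_preserves_unlabeled(self, grid200):
        n = grid200.n_points
        m = 20.0 + 5.0 * np.sin(grid200.phases)
        mu_pred, _ml, _m = predict_mature_profiles(
            np.full(n, 3.0), np.zeros(n), m, 1.0, grid200
        )
        onset = phase_shift(m, grid200, -grid200.omega * 1.0)
        assert np.allclose(mu_pred, onset, rtol=1e-9)

    def test_constant_rate_prediction_idempotent_when_already_constant(self, grid200):
        n = grid200.n_points
        a, g, t = 10.0, 0.5, 0.5
        m = np.full(n, a / g)
        dyn = predict_mature_profiles(np.full(n, a), np.full(n, g), m, t, grid200)
        for which in ("transcription", "degradation"):
            const = predict_with_constant_rate(
                np.full(n, a), np.full(n, g), m, t, grid200, which
            )
            for d, c in zip(dyn, const):
                assert np.allclose(d, c, rtol=1e-6)

    def test_roundtrip_self_consistency_short_labeling(self, grid500):
        ph = grid500.phases
        rates = RateProfiles(
            grid500,
            alpha=10.0 * (1.0 + 0.1 * np.sin(ph)),
            beta=np.full(grid500.n_points, 12.0),
            gamma=0.5 * (1.0 + 0.1 * np.sin(ph + 1.0)),
        )
        m = simulate_mature_only(rates.alpha, rates.gamma, grid500)
        t = 0.05
        mu, ml = simulate_simplified_profiles(rates, m, t, grid500, method="characteristics")
        alpha_hat, gamma_hat = estimate_rates_simplified(mu, ml, mu + ml, t, grid500)
        preds = predict_mature_profiles(alpha_hat, gamma_hat, mu + ml, t, grid500)
        for pred, obs in zip(preds, (mu, ml, mu + ml)):
            assert np.mean(np.abs(pred - obs) / obs) < 1e-3
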