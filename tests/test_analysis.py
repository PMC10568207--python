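"""Normalization, peaks, deviations, modes, bootstrap and downsampling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import sparse

from rnacycle.analysis import (
    MODE_BOTH,
    MODE_DYNAMIC_DEGRADATION,
    MODE_DYNAMIC_TRANSCRIPTION,
    MODE_OTHER,
    PeakCall,
    analyze_gene_profiles,
    binomial_thin,
    bootstrap_rates,
    classify_cycling,
    classify_kinetic_mode,
    deviation,
    downsample_validity,
    find_peaks,
    max_deviation,
    mean_half_life,
    normalize_cpm,
    tpr_table,
)
from rnacycle.kinetics import simulate_mature_only, simulate_simplified_profiles, simulate_total_profiles
from rnacycle.smoothing import SmoothProfile
from rnacycle.synthetic import marker_housekeeping_panel

TWO_PI = 2 * np.pi


class TestCpm:
    def test_single_entry(self):
        mat = np.array([[5.0]])
        out, kept = normalize_cpm(mat, per_cell_totals=[10_000])
        assert out[0, 0] == 500.0

    def test_columns_sum_to_one_million(self):
        rng = np.random.default_rng(0)
        mat = rng.poisson(5, size=(20, 30)).astype(float)
        mat[:, 0] = 0.0  # zero-total cell dropped
        out, kept = normalize_cpm(mat)
        assert kept.size == 29
        assert np.allclose(out.sum(axis=0), 1e6)

    def test_sparse_matches_dense(self):
        rng = np.random.default_rng(1)
        dense = rng.poisson(3, size=(15, 25)).astype(float)
        sp_out, _ = normalize_cpm(sparse.csr_matrix(dense))
        d_out, _ = normalize_cpm(dense)
        assert np.allclose(sp_out.toarray(), d_out)


class TestPeaks:
    def test_constant_profile_not_peaking(self):
        call = find_peaks(lambda x: np.full_like(x, 3.0))
        assert not call.is_peaking and call.n_peaks == 0

    def test_single_sine_peak(self):
        call = find_peaks(lambda x: 2.0 + np.sin(x))
        assert call.is_peaking
        assert call.n_peaks == 1
        assert call.peak_phases[0] == pytest.approx(np.pi / 2, abs=0.02)
        assert call.fc_global == pytest.approx(3.0, rel=1e-6)

    def test_subthreshold_fold_change_not_peaking(self):
        call = find_peaks(lambda x: 10.0 + np.sin(x))  # fc = 11/9 < 1.5
        assert not call.is_peaking and call.n_peaks == 0

    @staticmethod
    def _bruteforce_peaks(f, n=4000, fc_threshold=1.5, frac=0.25):
        ph = np.linspace(0, TWO_PI, n, endpoint=False)
        v = f(ph)
        if v.max() / v.min() < fc_threshold:
            return 0
        nxt, prv = np.roll(v, -1), np.roll(v, 1)
        maxima = np.flatnonzero((v > prv) & (v > nxt))
        minima = np.flatnonzero((v < prv) & (v < nxt))
        diff = v.max() - v.min()
        gidx = maxima[np.argmax(v[maxima])]
        count = 1
        for idx in maxima:
            if idx == gidx:
                continue
            pos = np.searchsorted(minima, idx)
            left = minima[pos - 1]
            right = minima[pos % len(minima)]
            if v[idx] - max(v[left], v[right]) >= frac * diff:
                count += 1
        return count

    @pytest.mark.parametrize("h", [0.05, 0.2, 0.35, 0.5, 0.8, 1.1])
    def test_two_bump_family_matches_bruteforce(self, h):
        f = lambda x: 2.0 + np.cos(x) + h * np.cos(2 * x)
        call = find_peaks(f, n_grid=2000)
        assert call.n_peaks == self._bruteforce_peaks(f)

    def test_secondary_peak_appears_exactly_at_quarter_prominence(self):
        # family with a secondary bump of tunable prominence
        def family(h):
            return lambda x: 2.0 + np.cos(x) + h * np.cos(2 * x)

        hs = np.linspace(0.05, 1.2, 120)
        ours = np.array([find_peaks(family(h), n_grid=2000).n_peaks for h in hs])
        brute = np.array([self._bruteforce_peaks(family(h)) for h in hs])
        assert np.array_equal(ours, brute)
        assert set(ours) == {1, 2}  # the family crosses the threshold
        # single transition point
        assert (np.diff(ours) != 0).sum() == 1


class TestCyclingAndModes:
    def test_classify_cycling(self):
        assert classify_cycling(PeakCall(True, 1))
        assert not classify_cycling(PeakCall(True, 2))
        assert not classify_cycling(PeakCall(False, 0))

    @pytest.mark.parametrize(
        "dev_a,dev_g,mode",
        [
            (0.5, 0.05, MODE_DYNAMIC_TRANSCRIPTION),
            (0.05, 0.5, MODE_DYNAMIC_DEGRADATION),
            (0.4, 0.6, MODE_BOTH),
            (0.05, 0.05, MODE_OTHER),
            (0.2, 0.2, MODE_OTHER),  # boundary is inclusive on the quiet side
        ],
    )
    def test_mode_table(self, dev_a, dev_g, mode):
        assert classify_kinetic_mode(dev_a, dev_g) == mode


class TestDeviation:
    def test_identical_is_zero(self):
        assert deviation(np.ones(5), np.ones(5)) == 0.0

    def test_twenty_percent_boundary(self):
        obs = np.array([1.0, 2.0, 5.0])
        assert deviation(1.2 * obs, obs) == pytest.approx(0.2)

    def test_matches_bruteforce_loop(self):
        rng = np.random.default_rng(3)
        pred = rng.uniform(1, 10, 50)
        obs = rng.uniform(1, 10, 50)
        expected = sum(abs(p - o) / o for p, o in zip(pred, obs)) / 50
        assert deviation(pred, obs) == pytest.approx(expected)

    @settings(max_examples=50, derandomize=True)
    @given(scale=st.floats(1e-3, 1e3))
    def test_scale_invariance(self, scale):
        rng = np.random.default_rng(7)
        pred = rng.uniform(1, 10, 20)
        obs = rng.uniform(1, 10, 20)
        assert deviation(pred * scale, obs * scale) == pytest.approx(
            deviation(pred, obs), rel=1e-9
        )

    def test_max_over_species(self):
        obs = np.ones(4)
        preds = (obs * 1.1, obs * 1.3, obs)
        assert max_deviation(preds, (obs, obs, obs)) == pytest.approx(0.3)


class TestHalfLife:
    def test_log_two_per_hour(self):
        assert mean_half_life(np.full(10, np.log(2.0))) == pytest.approx(1.0)

    def test_doubling_gamma_halves_half_life(self):
        g = np.full(10, 0.25)
        assert mean_half_life(2 * g) == pytest.approx(mean_half_life(g) / 2)

    def test_sinusoidal_profile_uses_cycle_mean(self):
        ph = np.linspace(0, TWO_PI, 1000, endpoint=False)
        gamma = 0.347 + 0.1 * np.sin(ph)
        assert mean_half_life(gamma) == pytest.approx(np.log(2) / np.mean(gamma))

    def test_nonpositive_mean_is_missing(self):
        assert np.isnan(mean_half_life(np.zeros(5)))


@pytest.fixture(scope="module")
def case_results(three_cases, three_case_totals, grid500):
    out = {}
    for name, rates in three_cases.items():
        _p, m, _ = three_case_totals[name]
        mu, ml = simulate_simplified_profiles(
            rates, m, 1.0, grid500, method="characteristics"
        )
        out[name] = analyze_gene_profiles(name, mu, ml, mu + ml, 1.0, grid500)
    return out


class TestThreeCaseClassification:

    def test_constant_gamma_case_has_negligible_gamma_dev(self, case_results):
        assert case_results["I"].dev_c_gamma < 0.05
        assert case_results["I"].dev_c_alpha > 0.2

    def test_constant_alpha_case_mirrors(self, case_results):
        assert case_results["II"].dev_c_alpha < 0.05
        assert case_results["II"].dev_c_gamma > 0.2

    def test_case3_exceeds_both_thresholds(self, case_results):
        assert case_results["III"].dev_c_alpha > 0.2
        assert case_results["III"].dev_c_gamma > 0.2

    def test_modes(self, case_results):
        assert case_results["I"].mode == MODE_DYNAMIC_TRANSCRIPTION
        assert case_results["II"].mode == MODE_DYNAMIC_DEGRADATION
        assert case_results["III"].mode == MODE_BOTH

    def test_recovered_constant_rate_is_constant(self, case_results):
        gamma = case_results["I"].gamma_hat
        assert np.std(gamma) / np.mean(gamma) < 0.05
        alpha = case_results["II"].alpha_hat
        assert np.std(alpha) / np.mean(alpha) < 0.05

    def test_all_cases_well_predicted_and_robust(self, case_results):
        for res in case_results.values():
            assert res.well_predicted
            assert res.is_cycling
            assert res.robust_cycling  # implies well_predicted and cycling


@pytest.fixture(scope="module")
def noisy_gene(grid200):
    from rnacycle.kinetics import PeriodicSpline, RateProfiles

    ph = grid200.phases
    rates = RateProfiles(
        grid200,
        alpha=10.0 * (1.0 + 0.3 * np.sin(ph)),
        beta=np.full(grid200.n_points, 12.0),
        gamma=0.5 * (1.0 + 0.3 * np.sin(ph + 1.0)),
    )
    m = simulate_mature_only(rates.alpha, rates.gamma, grid200)
    mu, ml = simulate_simplified_profiles(rates, m, 1.0, grid200)
    rng = np.random.default_rng(5)
    phases = rng.uniform(0, TWO_PI, 1000)
    mu_c = rng.poisson(PeriodicSpline(ph, mu)(phases))
    ml_c = rng.poisson(PeriodicSpline(ph, ml)(phases))
    return rates, phases, mu_c, ml_c


class TestBootstrap:

    def test_same_seed_identical_bands(self, noisy_gene, grid200):
        _r, phases, mu_c, ml_c = noisy_gene
        a = bootstrap_rates(phases, mu_c, ml_c, 1.0, grid200, B=10, seed=9)
        b = bootstrap_rates(phases, mu_c, ml_c, 1.0, grid200, B=10, seed=9)
        assert np.array_equal(a["gamma_bands"], b["gamma_bands"])
        assert np.array_equal(a["alpha_bands"], b["alpha_bands"])

    def test_minimum_replicates_enforced(self, noisy_gene, grid200):
        _r, phases, mu_c, ml_c = noisy_gene
        with pytest.raises(ValueError):
            bootstrap_rates(phases, mu_c, ml_c, 1.0, grid200, B=1)


class TestDownsampling:
    def test_fraction_one_is_identity(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(5, size=(4, 30))
        assert np.array_equal(binomial_thin(counts, 1.0, rng), counts)

    def test_fraction_out_of_range_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            binomial_thin(np.ones((2, 2), dtype=int), 0.0, rng)
        with pytest.raises(ValueError):
            binomial_thin(np.ones((2, 2), dtype=int), 1.2, rng)

    def test_thinning_mean(self):
        rng = np.random.default_rng(1)
        counts = np.full((1, 10_000), 10)
        thinned = binomial_thin(counts, 0.3, rng)
        se = np.sqrt(10 * 0.3 * 0.7 / 10_000)
        assert thinned.mean() == pytest.approx(3.0, abs=3 * se)

    def test_marker_survives_thinning_housekeeping_never_called(self):
        counts, phases, names, truth = marker_housekeeping_panel(
            400, seed=2, noise="none", marker_fold_changes=(3.0,)
        )
        val = downsample_validity(
            counts, phases, names, fractions=(0.8, 1.0), iters=10, seed=3
        )
        marker = val[val["gene"] == "marker_fc3"]
        assert marker["is_marker"].all()
        house = val[~val["gene"].map(truth)]
        assert not house["is_marker"].any()

    def test_tpr_table_counts(self):
        val = pd.DataFrame(
            {
                "gene": ["a", "b", "c", "d"],
                "fraction": [0.5] * 4,
                "dropout_rate": [0.1] * 4,
                "marker_rate": [1.0, 0.5, 1.0, 0.0],
                "is_marker": [True, False, True, False],
            }
        )
        truth = {"a": True, "b": True, "c": False, "d": False}
        tab = tpr_table(val, truth)
        assert tab.loc[0, "TP"] == 1 and tab.loc[0, "FN"] == 1
        assert tab.loc[0, "FP"] == 1 and tab.loc[0, "TN"] == 1
        assert tab.loc[0, "TPR"] == pytest.approx(0.5)
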