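import numpy as np
import pytest

import swntpore as sp


def _grid_sample(geometry, k_ads, k_des, t_drift, n, seed):
    mu = geometry.length**2 / t_drift
    params = sp.TransportParams(mu, 1.0, k_ads=k_ads, k_des=k_des)
    return sp.DwellSample(sp.sample_dwell_times(geometry, params, n, seed=seed))


class TestSplitDistribution:
    def test_no_adsorption_peak_at_drift(self, geometry):
        sample = _grid_sample(geometry, 0.0, 1.0, 0.010, 100, 0)
        t_peak, tail_start = sp.split_distribution(sample)
        assert t_peak == pytest.approx(0.010, rel=0.05)
        assert tail_start > t_peak

    def test_peak_near_drift_with_adsorption(self, geometry):
        sample = _grid_sample(geometry, 50.0, 100.0, 0.010, 5000, 1)
        t_peak, tail_start = sp.split_distribution(sample)
        assert t_peak == pytest.approx(0.010, rel=0.15)
        assert tail_start > t_peak

    def test_too_few_dwells_rejected(self):
        sample = sp.DwellSample(np.linspace(0.01, 0.02, 20))
        with pytest.raises(sp.InsufficientDataError):
            sp.split_distribution(sample)
        with pytest.warns(UserWarning):
            sp.split_distribution(sample, allow_small=True)


class TestTailFit:
    def test_pure_exponential_rate_recovery(self):
        """MLE on exact exponential draws recovers the dopamine-like rate."""
        rate = 53.6
        rng = np.random.default_rng(10)
        sample = sp.DwellSample(rng.exponential(1.0 / rate, 50_000))
        fit = sp.fit_tail_exponential(sample, tail_start=0.0, n_boot=200)
        assert fit.tau == pytest.approx(1.0 / rate, rel=0.02)
        assert fit.ci_low < fit.tau < fit.ci_high

    def test_shift_invariance(self):
        rng = np.random.default_rng(11)
        dwells = rng.exponential(0.02, 2000) + 0.005
        a = sp.fit_tail_exponential(sp.DwellSample(dwells), 0.005, n_boot=50)
        c = 0.5
        b = sp.fit_tail_exponential(sp.DwellSample(dwells + c), 0.005 + c, n_boot=50)
        assert b.tau == pytest.approx(a.tau, rel=1e-9)

    def test_degenerate_tail_rejected(self):
        dwells = np.concatenate([np.linspace(0.001, 0.002, 50), np.full(15, 0.05)])
        with pytest.raises(sp.SwntPoreError):
            sp.fit_tail_exponential(sp.DwellSample(dwells), tail_start=0.01)

    def test_insufficient_tail_rejected(self):
        dwells = np.linspace(0.001, 0.002, 100)
        with pytest.raises(sp.InsufficientDataError):
            sp.fit_tail_exponential(sp.DwellSample(dwells), tail_start=0.00195)


class TestRateEstimates:
    def test_kdes_is_inverse_tau(self):
        fit = sp.TailFit(tail_start=0.05, tau=0.01866, n_tail=100,
                         ci_low=0.015, ci_high=0.023)
        est = sp.estimate_kdes(fit)
        assert est.value == pytest.approx(53.6, rel=0.01)
        assert est.ci_low == pytest.approx(1 / 0.023)
        assert est.ci_high == pytest.approx(1 / 0.015)

    def test_kdes_scaling(self):
        tau = sp.TailFit(0.0, 1.0, 50, 0.9, 1.1)
        half = sp.TailFit(0.0, 0.5, 50, 0.45, 0.55)
        assert sp.estimate_kdes(half).value == 2 * sp.estimate_kdes(tau).value

    def test_kads_limits(self):
        rng = np.random.default_rng(12)
        t_drift = 0.01
        # mean dwell == t_drift -> k_ads == 0 (constant sample, clamped cleanly)
        const = sp.DwellSample(np.full(100, t_drift))
        est0 = sp.estimate_kads(const, t_drift, k_des=50.0, n_boot=50)
        assert est0.value == 0.0
        # mean dwell == 2 t_drift -> k_ads == k_des
        doubled = sp.DwellSample(np.full(100, 2 * t_drift))
        est1 = sp.estimate_kads(doubled, t_drift, k_des=50.0, n_boot=50)
        assert est1.value == pytest.approx(50.0)

    def test_kads_clamped_with_warning(self):
        sample = sp.DwellSample(np.full(100, 0.009))
        with pytest.warns(sp.NegativeKadsWarning):
            est = sp.estimate_kads(sample, t_drift=0.010, k_des=50.0, n_boot=50)
        assert est.value == 0.0

    def test_forward_inverse_identity(self):
        t_drift, k_ads, k_des = 0.010, 27.5, 53.6
        mean = sp.mean_dwell_forward(t_drift, k_ads, k_des)
        sample = sp.DwellSample(np.full(100, mean))
        est = sp.estimate_kads(sample, t_drift, k_des, n_boot=50)
        assert est.value == pytest.approx(k_ads, rel=1e-9)


class TestMeanDwellForward:
    def test_values(self):
        assert sp.mean_dwell_forward(0.5, 0.0, 10.0) == 0.5
        # sodium-like rate pair at unit drift time
        assert sp.mean_dwell_forward(1.0, 41.3, 52.5) == pytest.approx(1.787, abs=5e-4)

    def test_invalid_kdes(self):
        with pytest.raises(sp.ParameterError):
            sp.mean_dwell_forward(1.0, 10.0, 0.0)


class TestBootstrap:
    def test_constant_data_zero_width(self):
        lo, hi = sp.bootstrap_ci(np.full(30, 2.5), np.mean, n_boot=100, seed=0)
        assert lo == hi == 2.5

    def test_reproducible(self):
        rng = np.random.default_rng(13)
        data = rng.exponential(1.0, 100)
        a = sp.bootstrap_ci(data, np.mean, n_boot=200, seed=5)
        b = sp.bootstrap_ci(data, np.mean, n_boot=200, seed=5)
        assert a == b

    def test_coverage_for_exponential_mean(self):
        """Percentile intervals cover the true mean at ~95% nominal rate."""
        rng = np.random.default_rng(14)
        hits = 0
        reps = 300
        for i in range(reps):
            data = rng.exponential(1.0, 60)
            lo, hi = sp.bootstrap_ci(data, np.mean, n_boot=300, seed=i)
            hits += lo <= 1.0 <= hi
        assert 0.88 <= hits / reps <= 0.985


class TestEstimateKinetics:
    def test_low_adsorption_recovery(self, geometry):
        """At modest adsorption load the tail estimator recovers both rates."""
        sample = _grid_sample(geometry, 10.0, 100.0, 0.010, 5000, 21)
        est = sp.estimate_kinetics(sample, n_boot=200, seed=0)
        assert est.k_des.value == pytest.approx(100.0, rel=0.15)
        assert est.k_ads.value == pytest.approx(10.0, rel=0.35)

    def test_kads_ci_covers_truth(self, geometry):
        """Mean-dwell inversion with known k_des and drift time covers the
        generating k_ads in >= 90% of repeated draws."""
        covered = 0
        for seed in range(10):
            sample = _grid_sample(geometry, 27.5, 53.6, 0.0438, 5000, 100 + seed)
            est = sp.estimate_kads(sample, t_drift=0.0438, k_des=53.6,
                                   n_boot=300, seed=seed)
            covered += est.ci_low <= 27.5 <= est.ci_high
        assert covered >= 9

    def test_eq1_self_consistency(self, geometry):
        """Forward mean from fitted rates reproduces the sample mean."""
        sample = _grid_sample(geometry, 50.0, 100.0, 0.010, 5000, 22)
        est = sp.estimate_kinetics(sample, n_boot=100, seed=1)
        forward = sp.mean_dwell_forward(est.t_drift_used, est.k_ads.value,
                                        est.k_des.value)
        assert forward == pytest.approx(float(sample.dwells.mean()), rel=1e-6)

    def test_mean_dwell_monotone_in_kads(self, geometry):
        """More adsorption at fixed desorption lengthens dwells (paired seeds)."""
        means = []
        for k_ads in (10.0, 50.0, 250.0):
            sample = _grid_sample(geometry, k_ads, 100.0, 0.010, 4000, 55)
            means.append(float(sample.dwells.mean()))
        assert means[0] < means[1] < means[2]

    def test_deterministic(self, geometry):
        sample = _grid_sample(geometry, 27.5, 53.6, 0.0438, 2000, 33)
        a = sp.estimate_kinetics(sample, n_boot=100, seed=2)
        b = sp.estimate_kinetics(sample, n_boot=100, seed=2)
        assert a == b
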