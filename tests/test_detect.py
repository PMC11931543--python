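import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import swntpore as sp
from swntpore.simulate import render_trace


def _trace(samples, rate=25_000.0):
    return sp.CurrentTrace(np.asarray(samples, dtype=float), rate)


class TestBoxcarFilter:
    def test_constant_signal_fixed_point(self):
        trace = _trace(np.full(1000, 3.7))
        out = sp.boxcar_filter(trace, 99)
        assert np.allclose(out.samples, 3.7)
        assert out.n == trace.n

    def test_unit_impulse_kernel(self):
        x = np.zeros(501)
        x[250] = 1.0
        out = sp.boxcar_filter(_trace(x), 99).samples
        window = out[250 - 49 : 250 + 50]
        assert np.allclose(window, 1.0 / 99)
        assert out[250 - 50] == 0.0 and out[250 + 50] == 0.0

    def test_white_noise_variance_reduction(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0.0, 3.0, size=1_000_000)
        out = sp.boxcar_filter(_trace(x), 99).samples
        interior = out[99:-99]  # full-width windows only
        assert interior.std() == pytest.approx(3.0 / np.sqrt(99), rel=0.05)

    def test_even_width_rejected(self):
        with pytest.raises(sp.ParameterError):
            sp.boxcar_filter(_trace(np.zeros(100)), 10)
        with pytest.raises(sp.ParameterError):
            sp.boxcar_filter(_trace(np.zeros(10)), 99)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(
        a=st.floats(-5, 5, allow_nan=False),
        b=st.floats(-100, 100, allow_nan=False),
        seed=st.integers(0, 2**16),
    )
    def test_linearity(self, a, b, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 400)
        fx = sp.boxcar_filter(_trace(x), 33).samples
        fax = sp.boxcar_filter(_trace(a * x + b), 33).samples
        assert np.allclose(fax, a * fx + b, atol=1e-9)


class TestHistogramAndLevels:
    def test_identical_samples_single_bin(self):
        edges, counts = sp.current_histogram(_trace(np.full(10, 5.0)), bin_width=1.0)
        assert counts.sum() == 10
        assert (counts > 0).sum() == 1

    def test_counts_conserved(self, small_sim):
        edges, counts = sp.current_histogram(small_sim["filtered"])
        assert counts.sum() == small_sim["filtered"].n

    def test_two_gaussian_modes_recovered(self):
        rng = np.random.default_rng(1)
        x = np.concatenate(
            [rng.normal(100.0, 2.0, 35_000), rng.normal(80.0, 2.0, 15_000)]
        )
        hist = sp.current_histogram(_trace(x))
        bin_width = hist[0][1] - hist[0][0]
        levels = sp.find_two_states(hist)
        assert levels.open_level == pytest.approx(100.0, abs=bin_width)
        assert levels.closed_level == pytest.approx(80.0, abs=bin_width)
        assert levels.n_modes_found == 2

    def test_unimodal_raises(self):
        rng = np.random.default_rng(2)
        hist = sp.current_histogram(_trace(rng.normal(100.0, 2.0, 20_000)))
        with pytest.raises(sp.NoClosedStateError):
            sp.find_two_states(hist)

    def test_three_levels_warn(self):
        rng = np.random.default_rng(3)
        x = np.concatenate(
            [
                rng.normal(100.0, 1.5, 20_000),
                rng.normal(85.0, 1.5, 10_000),
                rng.normal(70.0, 1.5, 10_000),
            ]
        )
        with pytest.warns(sp.MultiStateWarning):
            levels = sp.find_two_states(sp.current_histogram(_trace(x)))
        assert levels.n_modes_found == 3
        assert levels.open_level > levels.closed_level


class TestDetectEvents:
    def test_noiseless_single_event(self):
        config = sp.TraceConfig(
            duration=0.1, baseline_current=1000.0, pbc_depth=20.0,
            sampling_rate=250_000.0, noise_sd=0.0, seed=0,
        )
        event = sp.GroundTruthEvent(0.04, 0.05, 0.01, 20.0, 0)
        trace = render_trace([event], config)
        levels = sp.StateLevels(1000.0, 980.0, 2)
        table = sp.detect_events(trace, levels, noise_sd=0.0)
        assert len(table) == 1
        rec = table.events[0]
        assert rec.dwell == pytest.approx(0.010, abs=1 / 250_000.0)
        assert rec.pbc == pytest.approx(20.0, abs=1e-9)

    def test_flat_noisy_baseline_empty(self):
        rng = np.random.default_rng(4)
        trace = _trace(1000.0 + rng.normal(0, 2.0, 50_000))
        levels = sp.StateLevels(1000.0, 970.0, 2)
        table = sp.detect_events(trace, levels, noise_sd=2.0)
        assert len(table) == 0

    def test_inverted_levels_rejected(self):
        with pytest.raises(sp.ParameterError):
            sp.StateLevels(970.0, 1000.0, 2)

    def test_round_trip_against_ground_truth(self, small_sim):
        """Idealization recovers each simulated event, dwell to <= 2 samples
        and PBC within its per-event noise bound (depth/noise = 15)."""
        table, truth = small_sim["table"], small_sim["truth"]
        config = small_sim["config"]
        rate = config.sampling_rate
        matched = 0
        pbc_ok = 0
        for gt in truth:
            hit = next(
                (e for e in table.events if e.start < gt.end and e.end > gt.start),
                None,
            )
            if hit is None:
                continue
            matched += 1
            assert abs(hit.dwell - gt.dwell) <= 2.0 / rate
            bound = 3 * config.noise_sd / np.sqrt(gt.dwell * rate)
            pbc_ok += abs(hit.pbc - gt.depth) <= bound
        assert matched / len(truth) >= 0.95
        assert matched / len(table) >= 0.95
        # 3-sigma bound: allow the expected ~0.3% of exceedances
        assert pbc_ok / matched >= 0.95

    def test_noise_sd_estimate(self, small_sim):
        sd = sp.estimate_noise_sd(small_sim["trace"], small_sim["levels"])
        assert sd == pytest.approx(2.0, rel=0.1)


class TestQC:
    @staticmethod
    def _table(n):
        events = [
            sp.EventRecord(start=i * 0.1, end=i * 0.1 + 0.01, dwell=0.01, pbc=30.0)
            for i in range(n)
        ]
        return sp.EventTable(events, baseline=1000.0)

    def test_minimum_event_rule_boundary(self):
        assert not sp.qc_condition(self._table(49)).min_events_ok
        assert sp.qc_condition(self._table(50)).min_events_ok

    def test_two_state_purity_on_simulated_trace(self, small_sim):
        qc = sp.qc_condition(
            small_sim["table"],
            trace=small_sim["trace"],
            levels=small_sim["levels"],
        )
        assert qc.purity is not None and qc.purity >= 0.99
        assert qc.two_state_ok

    def test_baseline_and_pbc_concentration_invariance(self, geometry):
        """Baseline and PBC do not track a nominal concentration tag."""
        params = sp.TransportParams(2.76e-5, 1.0, k_ads=27.5, k_des=53.6,
                                    entry_rate=5.0)
        results = []
        for seed, conc in [(101, 0.1), (202, 1.0)]:
            config = sp.TraceConfig(duration=5.0, sampling_rate=25_000.0,
                                    pbc_depth=30.0, noise_sd=2.0, seed=seed)
            trace, _ = sp.simulate_trace(geometry, params, config)
            trace.metadata["concentration_m"] = conc
            filtered = sp.boxcar_filter(trace, 99)
            levels = sp.find_two_states(sp.current_histogram(filtered))
            table = sp.detect_events(filtered, levels, raw_trace=trace)
            results.append((table.baseline, table.pbcs.mean()))
        (b1, p1), (b2, p2) = results
        assert abs(b1 - b2) < 3 * 2.0 / np.sqrt(1000)  # well within noise
        assert abs(p1 - p2) < 1.0
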