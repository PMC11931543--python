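"""Synthetic two-state Coulter trace generation.

The dwell-time model is a first-passage decomposition: an ion crosses the
pore in a deterministic drift time t_drift = L^2 / (mu0 * V) and, along the
way, sticks to the wall N ~ Poisson(k_ads * t_drift) times, each sojourn
lasting Exp(k_des).  The total dwell is

    t = t_drift + sum_{i=1..N} tau_i,

which has mean t_drift * (1 + k_ads / k_des) and an exponential-like long
tail controlled by k_des.  Traces are rendered as a noisy open-pore baseline
with rectangular blockades of depth equal to the pore-blocking current.
"""

from __future__ import annotations

import warnings

import numpy as np

from .core import (
    CurrentTrace,
    DeviceGeometry,
    GroundTruthEvent,
    InvalidKineticsError,
    ParameterError,
    TraceConfig,
    TransportParams,
)

__all__ = [
    "drift_time",
    "sample_dwell_times",
    "simulate_trace",
    "render_trace",
    "pbc_voltage_model",
]


def drift_time(geometry: DeviceGeometry, params: TransportParams) -> float:
    """Field-driven transit time L^2 / (mu0 * V) in seconds.

    Raises
    ------
    ParameterError
        If the voltage or intrinsic mobility is zero (drift undefined).
    """
    if params.voltage <= 0:
        raise ParameterError("drift time undefined at V <= 0")
    if params.mobility_intrinsic <= 0:
        raise ParameterError("drift time undefined at mu0 <= 0")
    return geometry.length**2 / (params.mobility_intrinsic * params.voltage)


def _dwells_with_counts(
    t_drift: float, params: TransportParams, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n dwell times plus the adsorption count behind each."""
    if params.k_ads > 0 and params.k_des <= 0:
        raise InvalidKineticsError("k_des must be > 0 when k_ads > 0")
    if params.k_ads == 0:
        return np.full(n, t_drift), np.zeros(n, dtype=int)
    counts = rng.poisson(params.k_ads * t_drift, size=n)
    # sum of N iid Exp(k_des) sojourns == Gamma(N, 1/k_des)
    adsorbed = np.zeros(n)
    pos = counts > 0
    if pos.any():
        adsorbed[pos] = rng.gamma(counts[pos], 1.0 / params.k_des)
    return t_drift + adsorbed, counts


def sample_dwell_times(
    geometry: DeviceGeometry,
    params: TransportParams,
    n: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Sample ``n`` dwell times from the drift + adsorption/desorption model.

    Every dwell is at least the drift time; the sample mean converges to
    t_drift * (1 + k_ads / k_des).  Reproducible for a fixed seed.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dwells, _ = _dwells_with_counts(drift_time(geometry, params), params, n, rng)
    return dwells


def pbc_voltage_model(depth_per_volt: float, voltage: float) -> float:
    """Linear-through-origin pore-blocking current, pA = depth_per_volt * V.

    The blockade depth grows with driving voltage; only monotonicity is
    physically established, so the simplest monotone form is used.
    """
    if depth_per_volt <= 0:
        raise ParameterError("depth_per_volt must be > 0")
    if voltage < 0:
        raise ParameterError("voltage must be >= 0")
    return depth_per_volt * voltage


def _place_events(
    duration: float,
    t_drift: float,
    params: TransportParams,
    config: TraceConfig,
    rng_arrivals: np.random.Generator,
    rng_dwells: np.random.Generator,
    max_tries: int = 100,
    gap_samples: int = 100,
) -> list[GroundTruthEvent]:
    """Poisson arrivals with non-overlap enforced by bounded re-sampling.

    Events are kept isolated: neighbours must be separated by at least
    ``gap_samples`` sample periods, so that blockades remain resolvable
    after the downstream 99-point smoothing.  This defines the
    non-overlap regime the generator operates in.
    """
    n_arrivals = rng_arrivals.poisson(params.entry_rate * duration)
    dwells, counts = _dwells_with_counts(t_drift, params, max(n_arrivals, 1), rng_dwells)
    dt = 1.0 / config.sampling_rate
    gap = gap_samples * dt
    accepted: list[tuple[float, float, int]] = []  # (start, end, n_ads)
    for i in range(n_arrivals):
        dwell = dwells[i]
        for _ in range(max_tries):
            start = rng_arrivals.uniform(0.0, duration)
            end = start + dwell
            if end >= duration - gap or start <= gap:
                continue
            if all(end + gap < s or start > e + gap for s, e, _ in accepted):
                accepted.append((start, end, int(counts[i])))
                break
    accepted.sort()
    events = []
    for start, end, n_ads in accepted:
        # snap to the sample grid so trace and ground truth agree exactly
        i0 = int(round(start * config.sampling_rate))
        i1 = int(round(end * config.sampling_rate))
        if i1 <= i0:
            i1 = i0 + 1
        events.append(
            GroundTruthEvent(
                start=i0 * dt,
                end=i1 * dt,
                dwell=(i1 - i0) * dt,
                depth=config.pbc_depth,
                n_adsorptions=n_ads,
            )
        )
    return events


def render_trace(
    events: list[GroundTruthEvent],
    config: TraceConfig,
    metadata: dict | None = None,
    rng: np.random.Generator | None = None,
) -> CurrentTrace:
    """Render a baseline + rectangular-blockade trace from explicit events.

    Separated from :func:`simulate_trace` so tests can force exact event
    placements (e.g. a single noiseless 10 ms blockade).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_samples
    samples = np.full(n, config.baseline_current)
    if config.noise_sd > 0:
        samples = samples + rng.normal(0.0, config.noise_sd, size=n)
    for ev in events:
        i0 = int(round(ev.start * config.sampling_rate))
        i1 = int(round(ev.end * config.sampling_rate))
        samples[i0:i1] -= ev.depth
    return CurrentTrace(samples, config.sampling_rate, dict(metadata or {}))


def simulate_trace(
    geometry: DeviceGeometry,
    params: TransportParams,
    config: TraceConfig,
) -> tuple[CurrentTrace, list[GroundTruthEvent]]:
    """Simulate one Coulter trace and its ground-truth event list.

    Below the threshold voltage no blockades occur and the trace is pure
    baseline.  Otherwise event starts follow a homogeneous Poisson process
    (overlaps re-sampled), dwells come from :func:`sample_dwell_times`, and
    the rendered signal has exactly two noiseless levels.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_arr, rng_dwell, rng_noise = (np.random.default_rng(s) for s in ss.spawn(3))

    metadata = {
        "voltage_v": params.voltage,
        "sampling_rate_hz": config.sampling_rate,
        "length_m": geometry.length,
        "diameter_m": geometry.diameter,
        "baseline_pa": config.baseline_current,
    }

    if params.voltage < params.threshold_voltage or params.voltage <= 0:
        events: list[GroundTruthEvent] = []
    else:
        t_drift = drift_time(geometry, params)
        if config.duration < t_drift * (1 + params.k_ads / max(params.k_des, 1e-300)):
            warnings.warn(
                "trace duration is shorter than one expected dwell", UserWarning
            )
        events = _place_events(
            config.duration, t_drift, params, config, rng_arr, rng_dwell
        )
    trace = render_trace(events, config, metadata, rng_noise)
    return trace, events
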