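"""Trace idealization: filtering, two-state level finding, event extraction.

The analysis chain mirrors standard resistive-pulse practice: boxcar
smoothing, an all-points current histogram, mode finding to locate the
open and blocked levels, then threshold-crossing event extraction at the
level midpoint with a hysteresis depth requirement.  A histogram with more
than two comparable modes is flagged — on these devices that pattern
indicates leak transport through the elastomer seal rather than through
the nanotube.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .core import (
    CurrentTrace,
    EventRecord,
    EventTable,
    MultiStateWarning,
    NoClosedStateError,
    ParameterError,
    StateLevels,
)

__all__ = [
    "boxcar_filter",
    "current_histogram",
    "find_two_states",
    "detect_events",
    "estimate_noise_sd",
    "qc_condition",
    "QCReport",
]


def boxcar_filter(trace: CurrentTrace, n_points: int = 99) -> CurrentTrace:
    """Centered moving average of odd width ``n_points``.

    Output length equals input length; near the edges the window shrinks to
    the available samples, so constant signals are exact fixed points and
    the filter is affine-equivariant: boxcar(a*x + b) = a*boxcar(x) + b.
    """
    if n_points % 2 == 0 or n_points < 1:
        raise ParameterError("n_points must be odd and positive")
    if n_points > trace.n:
        raise ParameterError("n_points exceeds trace length")
    x = trace.samples
    half = n_points // 2
    csum = np.concatenate(([0.0], np.cumsum(x)))
    idx = np.arange(x.size)
    lo = np.clip(idx - half, 0, None)
    hi = np.clip(idx + half + 1, None, x.size)
    out = (csum[hi] - csum[lo]) / (hi - lo)
    meta = dict(trace.metadata)
    meta["boxcar_points"] = n_points
    return CurrentTrace(out, trace.sampling_rate, meta)


def _fd_bin_width(x: np.ndarray) -> float:
    """Freedman-Diaconis width, with a sane fallback for zero-IQR data."""
    q75, q25 = np.percentile(x, [75, 25])
    width = 2.0 * (q75 - q25) / x.size ** (1.0 / 3.0)
    if width <= 0:
        span = np.ptp(x)
        width = span / 50.0 if span > 0 else 1.0
    return float(width)


def current_histogram(
    trace: CurrentTrace, bin_width: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """All-points histogram (edges, counts) of the current values."""
    x = trace.samples
    if x.size == 0:
        raise ParameterError("cannot histogram an empty trace")
    if bin_width is None:
        bin_width = _fd_bin_width(x)
    if bin_width <= 0:
        raise ParameterError("bin_width must be > 0")
    lo, hi = float(np.min(x)), float(np.max(x))
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, edges = np.histogram(x, bins=edges if n_bins > 1 else 1)
    return edges, counts


def find_two_states(
    histogram: tuple[np.ndarray, np.ndarray],
    prominence_frac: float = 0.05,
) -> StateLevels:
    """Locate open (higher-current) and closed levels from histogram modes.

    Modes are peaks with prominence at least ``prominence_frac`` of the
    tallest bin.  The open level is the dominant high-current mode; the
    closed level the tallest remaining mode below it.  More than two modes
    raises :class:`MultiStateWarning` (leak-transport diagnostic); a
    unimodal histogram raises :class:`NoClosedStateError`.
    """
    edges, counts = histogram
    centers = 0.5 * (edges[:-1] + edges[1:])
    # light smoothing + a minimum peak separation suppress plateau wiggles
    kernel = np.ones(3) / 3.0
    smooth = np.convolve(counts.astype(float), kernel, mode="same")
    padded = np.concatenate(([0.0], smooth, [0.0]))
    peaks, _ = find_peaks(
        padded, prominence=prominence_frac * smooth.max(), distance=4
    )
    peaks -= 1  # undo padding offset
    n_modes = int(peaks.size)
    if n_modes < 2:
        raise NoClosedStateError(
            f"found {n_modes} mode(s); need an open and a closed state"
        )
    if n_modes > 2:
        warnings.warn(
            f"{n_modes} comparable current modes found; more than two states "
            "suggests non-SWNT (leak) transport",
            MultiStateWarning,
        )
    # dominant mode overall, then the relationship decides which is open
    order = peaks[np.argsort(counts[peaks])[::-1]]
    top_two = sorted(order[:2], key=lambda p: centers[p])
    closed_p, open_p = top_two[0], top_two[-1]
    # closed = tallest mode strictly below the open one
    below = [p for p in peaks if centers[p] < centers[open_p]]
    closed_p = max(below, key=lambda p: counts[p])

    def refine(p: int) -> float:
        # sub-bin mode by parabolic interpolation through the peak bin
        if 0 < p < counts.size - 1:
            y0, y1, y2 = (float(c) for c in smooth[p - 1 : p + 2])
            denom = y0 - 2.0 * y1 + y2
            if denom < 0:
                delta = np.clip(0.5 * (y0 - y2) / denom, -0.5, 0.5)
                return float(centers[p] + delta * (centers[1] - centers[0]))
        return float(centers[p])

    return StateLevels(
        open_level=refine(open_p),
        closed_level=refine(closed_p),
        n_modes_found=n_modes,
    )


def estimate_noise_sd(trace: CurrentTrace, levels: StateLevels) -> float:
    """Robust open-state noise: scaled MAD of samples nearer the open level."""
    mid = 0.5 * (levels.open_level + levels.closed_level)
    open_samples = trace.samples[trace.samples > mid]
    if open_samples.size < 2:
        raise ParameterError("no open-state samples above the level midpoint")
    mad = np.median(np.abs(open_samples - np.median(open_samples)))
    return float(1.4826 * mad)


def detect_events(
    trace: CurrentTrace,
    levels: StateLevels,
    min_dwell_samples: int = 3,
    noise_sd: float | None = None,
    edge_margin: int = 0,
    raw_trace: CurrentTrace | None = None,
) -> EventTable:
    """Extract blockade events by midpoint threshold crossing.

    An event is a maximal run of samples below the open/closed midpoint
    that (i) lasts at least ``min_dwell_samples`` samples and (ii) dips
    below midpoint - noise_sd (hysteresis band, rejecting shallow noise
    excursions).  PBC is open_level minus the in-event mean; when
    ``edge_margin`` > 0 that mean excludes the filter-ramp samples at each
    end of sufficiently long events.  Runs touching the trace boundaries
    are censored and discarded.

    When ``trace`` is a smoothed copy, pass the unfiltered record as
    ``raw_trace``: event boundaries found on the smooth trace are then
    refined against the raw midpoint crossings (removing the filter-ramp
    jitter) and the PBC is measured on the raw samples.
    """
    if levels.open_level <= levels.closed_level:
        raise ParameterError("levels inverted")
    if min_dwell_samples < 1:
        raise ParameterError("min_dwell_samples must be >= 1")
    if raw_trace is not None and raw_trace.n != trace.n:
        raise ParameterError("raw_trace must match trace length")
    if noise_sd is None:
        noise_sd = estimate_noise_sd(trace, levels)
    mid = 0.5 * (levels.open_level + levels.closed_level)
    deep = mid - noise_sd
    x = trace.samples
    below = x < mid
    # run boundaries of the below-threshold indicator
    d = np.diff(below.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if below[0]:
        starts = np.concatenate(([0], starts))
    if below[-1]:
        ends = np.concatenate((ends, [x.size]))
    rate = trace.sampling_rate
    raw = raw_trace.samples if raw_trace is not None else None
    bounds: list[tuple[int, int, float]] = []  # (i0, i1, in-event mean)
    for i0, i1 in zip(starts, ends):
        if i0 == 0 or i1 == x.size:
            continue  # boundary-censored
        if i1 - i0 < min_dwell_samples:
            continue
        seg = x[i0:i1]
        if seg.min() >= deep:
            continue  # never left the hysteresis band
        if raw is not None:
            # refine boundaries against raw midpoint crossings
            while i0 > 0 and raw[i0 - 1] < mid:
                i0 -= 1
            while i0 < i1 - 1 and raw[i0] >= mid:
                i0 += 1
            while i1 < x.size and raw[i1] < mid:
                i1 += 1
            while i1 > i0 + 1 and raw[i1 - 1] >= mid:
                i1 -= 1
            if i0 == 0 or i1 == x.size or i1 - i0 < min_dwell_samples:
                continue
            seg = raw[i0:i1]
        elif edge_margin > 0 and i1 - i0 > 2 * edge_margin + min_dwell_samples:
            seg = seg[edge_margin:-edge_margin]
        # boundary refinement can, rarely, make neighbours collide; keep first
        if bounds and i0 < bounds[-1][1]:
            continue
        bounds.append((i0, i1, float(seg.mean())))

    baseline = levels.open_level
    if raw is not None:
        # unbiased baseline: raw open-state samples outside every event
        open_mask = np.ones(x.size, dtype=bool)
        for i0, i1, _ in bounds:
            open_mask[max(i0 - 1, 0) : min(i1 + 1, x.size)] = False
        open_mask &= raw > mid
        if open_mask.sum() >= 2:
            baseline = float(raw[open_mask].mean())

    records = [
        EventRecord(start=i0 / rate, end=i1 / rate, dwell=(i1 - i0) / rate,
                    pbc=baseline - seg_mean)
        for i0, i1, seg_mean in bounds
        if baseline - seg_mean > 0
    ]
    return EventTable(records, baseline=baseline, metadata=dict(trace.metadata))


@dataclass(frozen=True)
class QCReport:
    """Per-condition quality-control summary."""

    n_events: int
    min_events_ok: bool
    baseline_pa: float
    noise_sd_pa: float | None
    purity: float | None
    two_state_ok: bool | None
    n_modes_found: int | None

    def to_dict(self) -> dict:
        return {
            "n_events": self.n_events,
            "min_events_ok": self.min_events_ok,
            "baseline_pa": self.baseline_pa,
            "noise_sd_pa": self.noise_sd_pa,
            "purity": self.purity,
            "two_state_ok": self.two_state_ok,
            "n_modes_found": self.n_modes_found,
        }


def qc_condition(
    table: EventTable,
    trace: CurrentTrace | None = None,
    levels: StateLevels | None = None,
    noise_sd: float | None = None,
    min_events: int = 50,
    purity_threshold: float = 0.99,
) -> QCReport:
    """Apply the inclusion rules used for per-condition reporting.

    Flags whether at least ``min_events`` blockades were collected, and —
    when the trace and levels are supplied — the two-state purity: the
    fraction of samples within 4 noise-sd of either level.
    """
    n = len(table)
    purity = None
    two_state_ok = None
    n_modes = levels.n_modes_found if levels is not None else None
    if trace is not None and levels is not None:
        if noise_sd is None:
            noise_sd = estimate_noise_sd(trace, levels)
        x = trace.samples
        near_open = np.abs(x - levels.open_level) <= 4 * noise_sd
        near_closed = np.abs(x - levels.closed_level) <= 4 * noise_sd
        purity = float(np.mean(near_open | near_closed))
        two_state_ok = purity >= purity_threshold
    return QCReport(
        n_events=n,
        min_events_ok=n >= min_events,
        baseline_pa=table.baseline,
        noise_sd_pa=noise_sd,
        purity=purity,
        two_state_ok=two_state_ok,
        n_modes_found=n_modes,
    )
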