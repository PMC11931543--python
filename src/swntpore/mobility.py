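"""Electrophoretic mobility estimation and pH-trend summarization.

For a pore of length L the inverse dwell time is linear in voltage,
1/t = mu * V / L^2, so the mobility is the slope of 1/<t> against V scaled
by L^2.  When blockades appear at only one voltage the same relation is
solved directly, mu = L^2 / (V * <t>).  The module also determines the
threshold voltage (smallest bias with any blockades), evaluates the
effective mobility predicted by the adsorption/desorption model,

    mu_eff = mu0 / (1 + k_ads / k_des),

and fits a Langmuir-type saturation curve to mobility vs [H+] data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Any, Mapping, Sequence

import numpy as np
import statsmodels.api as sm
from scipy.optimize import curve_fit

from .core import (
    DeviceGeometry,
    InsufficientDataError,
    NonphysicalSlopeError,
    ParameterError,
)

__all__ = [
    "VoltageCondition",
    "MobilityEstimate",
    "SaturationFit",
    "mobility_from_regression",
    "mobility_single_point",
    "threshold_voltage",
    "eq3_mobility_ratio",
    "saturation_fit",
]


@dataclass(frozen=True)
class VoltageCondition:
    """Per-voltage dwell and PBC summary statistics."""

    voltage: float
    mean_dwell: float
    sd_dwell: float = 0.0
    n: int = 1
    pbc_mean: float = np.nan
    pbc_sd: float = np.nan

    def __post_init__(self) -> None:
        if not self.voltage > 0:
            raise ParameterError("voltage must be > 0")
        if not self.mean_dwell > 0:
            raise ParameterError("mean_dwell must be > 0")


@dataclass(frozen=True)
class MobilityEstimate:
    """Electrophoretic mobility (m^2 V^-1 s^-1) with its standard error."""

    mu: float
    stderr: float
    method: str  # "regression" | "single_voltage"
    intercept: float = np.nan  # diagnostic; expected ~ 0 for regression
    intercept_stderr: float = np.nan
    condition: dict[str, Any] | None = None


@dataclass(frozen=True)
class SaturationFit:
    """Langmuir-type fit mu(c) = mu_low + delta_mu * c / (K + c)."""

    mu_low: float
    delta_mu: float
    half_sat: float  # K, mol/L
    c95: float  # concentration at 95% of the plateau = 19*K
    delta_mu_ci: tuple[float, float]
    no_saturation: bool


def mobility_from_regression(
    conditions: Sequence[VoltageCondition],
    geometry: DeviceGeometry,
    weighted: bool = False,
) -> MobilityEstimate:
    """Mobility from OLS of mean inverse dwell on voltage: mu = slope * L^2.

    The intercept is retained as a diagnostic (threshold effects can offset
    the line) rather than forced through the origin.  ``weighted`` switches
    to WLS with weights 1/SE^2 of the inverse dwell.
    """
    if len({c.voltage for c in conditions}) < 3:
        raise InsufficientDataError("need >= 3 distinct voltages for regression")
    v = np.array([c.voltage for c in conditions])
    inv_t = np.array([1.0 / c.mean_dwell for c in conditions])
    X = sm.add_constant(v)
    if weighted:
        # delta method: se(1/t) = se(t) / t^2
        se = np.array(
            [c.sd_dwell / max(np.sqrt(c.n), 1.0) / c.mean_dwell**2 for c in conditions]
        )
        if np.any(se <= 0):
            raise ParameterError("weighted regression needs positive dwell SEs")
        res = sm.WLS(inv_t, X, weights=1.0 / se**2).fit()
    else:
        res = sm.OLS(inv_t, X).fit()
    slope = float(res.params[1])
    if slope <= 1e-12 * float(np.mean(np.abs(inv_t))):
        raise NonphysicalSlopeError(
            f"inverse dwell does not increase with voltage (slope={slope:g})"
        )
    L2 = geometry.length**2
    return MobilityEstimate(
        mu=slope * L2,
        stderr=float(res.bse[1]) * L2,
        method="regression",
        intercept=float(res.params[0]),
        intercept_stderr=float(res.bse[0]),
    )


def mobility_single_point(
    voltage: float,
    mean_dwell: float,
    geometry: DeviceGeometry,
    sd_dwell: float = 0.0,
    n: int = 1,
) -> MobilityEstimate:
    """Mobility from one voltage by direct inversion, mu = L^2 / (V * <t>).

    Used when blockades appear only at a single voltage (e.g. an ion whose
    threshold equals the largest applicable bias).  The standard error
    comes from the dwell SE by the delta method.
    """
    if voltage <= 0 or mean_dwell <= 0:
        raise ParameterError("voltage and mean_dwell must be > 0")
    mu = geometry.length**2 / (voltage * mean_dwell)
    se_t = sd_dwell / np.sqrt(max(n, 1))
    return MobilityEstimate(
        mu=mu,
        stderr=mu * se_t / mean_dwell,
        method="single_voltage",
    )


def threshold_voltage(scan: Mapping[float, int]) -> float | None:
    """Smallest voltage in a scan with at least one blockade event.

    Returns None when no voltage produced events (a no-transport result,
    not an error).
    """
    if len(scan) < 2:
        raise ParameterError("scan must cover >= 2 voltages")
    with_events = sorted(v for v, count in scan.items() if count >= 1)
    return with_events[0] if with_events else None


def eq3_mobility_ratio(mu_intrinsic: float, k_ads: float, k_des: float) -> float:
    """Effective mobility mu0 / (1 + k_ads/k_des) under wall adsorption.

    Equals mu0 exactly when k_ads = 0, and is constant in pH whenever the
    ratio k_ads/k_des is pH-independent.
    """
    if k_des <= 0:
        raise ParameterError("k_des must be > 0")
    if mu_intrinsic <= 0 or k_ads < 0:
        raise ParameterError("mu_intrinsic must be > 0 and k_ads >= 0")
    return mu_intrinsic / (1.0 + k_ads / k_des)


def saturation_fit(
    points: Sequence[tuple[float, float, float]],
    z: float = 1.96,
) -> SaturationFit:
    """Weighted Langmuir-type fit of mobility against [H+].

    ``points`` are (concentration mol/L, mobility, mobility error) triples.
    Flags ``no_saturation`` when the plateau rise delta_mu is statistically
    indistinguishable from zero, and warns when the fitted trend decreases.
    """
    if len(points) < 4:
        raise InsufficientDataError("need >= 4 concentration points")
    c = np.array([p[0] for p in points], dtype=float)
    mu = np.array([p[1] for p in points], dtype=float)
    err = np.array([p[2] for p in points], dtype=float)
    if np.any(err <= 0):
        err = np.full_like(mu, max(1e-3 * np.ptp(mu), 1e-30))

    def model(x, mu_low, delta_mu, K):
        return mu_low + delta_mu * x / (K + x)

    p0 = (float(mu.min()), float(mu.max() - mu.min()) or float(mu.mean()) * 0.1,
          float(np.median(c)))
    popt, pcov = curve_fit(
        model, c, mu, p0=p0, sigma=err, absolute_sigma=True, maxfev=20000,
        bounds=([-np.inf, -np.inf, 1e-12], [np.inf, np.inf, np.inf]),
    )
    mu_low, delta_mu, K = (float(x) for x in popt)
    se_delta = float(np.sqrt(pcov[1, 1]))
    ci = (delta_mu - z * se_delta, delta_mu + z * se_delta)
    no_sat = ci[0] <= 0.0 <= ci[1]
    if delta_mu < 0:
        warnings.warn("mobility decreases with [H+]; delta_mu < 0", UserWarning)
    return SaturationFit(
        mu_low=mu_low,
        delta_mu=delta_mu,
        half_sat=K,
        c95=19.0 * K,
        delta_mu_ci=ci,
        no_saturation=no_sat,
    )
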