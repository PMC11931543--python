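"""Shared domain types for SWNT nanopore transport analysis.

Units are SI internally (m, s, V) except currents, which are kept in pA
throughout because every instrument-facing quantity (baseline, noise,
pore-blocking current) is reported in pA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd


class SwntPoreError(Exception):
    """Base class for all package errors."""


class ParameterError(SwntPoreError, ValueError):
    """An argument violates an operation's preconditions."""


class InvalidKineticsError(ParameterError):
    """Adsorption requested with a non-positive desorption rate."""


class NoClosedStateError(SwntPoreError):
    """Current histogram is unimodal: no blocked-pore state found."""


class InsufficientDataError(SwntPoreError):
    """Too few observations for the requested inference."""


class NonphysicalSlopeError(SwntPoreError):
    """Inverse-dwell vs voltage regression produced a non-positive slope."""


class TraceFormatError(SwntPoreError):
    """A trace or event file is malformed."""


class MultiStateWarning(UserWarning):
    """More than two comparable Coulter states: transport may not be SWNT."""


class NegativeKadsWarning(UserWarning):
    """Mean dwell below drift time; adsorption rate clamped to zero."""


@dataclass(frozen=True)
class DeviceGeometry:
    """Cylindrical nanopore geometry.

    Parameters
    ----------
    length : float
        Pore length in metres (the SWNT span between reservoirs).
    diameter : float
        Inner diameter in metres.
    """

    length: float
    diameter: float

    def __post_init__(self) -> None:
        if not self.length > 0:
            raise ParameterError(f"length must be > 0, got {self.length}")
        if not self.diameter > 0:
            raise ParameterError(f"diameter must be > 0, got {self.diameter}")
        if not self.diameter < self.length:
            raise ParameterError("diameter must be smaller than length")


#: The 1.01 nm diameter, 1.1 mm long device studied throughout.
DEFAULT_GEOMETRY = DeviceGeometry(length=1.1e-3, diameter=1.01e-9)


@dataclass(frozen=True)
class TransportParams:
    """Physical parameters of the drift + adsorption/desorption model.

    ``mobility_intrinsic`` is the free-drift electrophoretic mobility mu0
    (m^2 V^-1 s^-1); wall adsorption at rate ``k_ads`` (s^-1) and release at
    ``k_des`` (s^-1) lengthen the transit.  ``threshold_voltage`` is the
    minimum bias at which blockade events appear; ``entry_rate`` the Poisson
    arrival rate of ions at the pore mouth (events/s).
    """

    mobility_intrinsic: float
    voltage: float
    k_ads: float = 0.0
    k_des: float = 1.0
    threshold_voltage: float = 0.0
    entry_rate: float = 5.0

    def __post_init__(self) -> None:
        if not self.mobility_intrinsic > 0:
            raise ParameterError("mobility_intrinsic must be > 0")
        if self.voltage < 0:
            raise ParameterError("voltage must be >= 0")
        if self.k_ads < 0 or self.entry_rate < 0 or self.threshold_voltage < 0:
            raise ParameterError("rates and threshold voltage must be >= 0")
        if self.k_ads > 0 and not self.k_des > 0:
            raise InvalidKineticsError(
                "k_des must be > 0 when adsorption (k_ads > 0) is enabled"
            )


@dataclass(frozen=True)
class TraceConfig:
    """Rendering parameters for a synthetic current trace."""

    duration: float
    baseline_current: float = 1000.0
    pbc_depth: float = 30.0
    sampling_rate: float = 250_000.0
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.duration > 0 or not self.sampling_rate > 0:
            raise ParameterError("duration and sampling_rate must be > 0")
        if not self.pbc_depth > 0:
            raise ParameterError("pbc_depth must be > 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))


@dataclass(frozen=True)
class GroundTruthEvent:
    """A simulated blockade with its generative bookkeeping."""

    start: float
    end: float
    dwell: float
    depth: float
    n_adsorptions: int

    def __post_init__(self) -> None:
        if abs((self.end - self.start) - self.dwell) > 1e-12 * max(1.0, self.dwell):
            raise ParameterError("end - start must equal dwell")
        if self.n_adsorptions < 0:
            raise ParameterError("n_adsorptions must be >= 0")


@dataclass
class CurrentTrace:
    """Uniformly sampled current record in pA."""

    samples: np.ndarray
    sampling_rate: float
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ParameterError("trace needs at least 2 samples")
        if not self.sampling_rate > 0:
            raise ParameterError("sampling_rate must be > 0")

    @property
    def n(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        return self.n / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n) / self.sampling_rate


@dataclass(frozen=True)
class StateLevels:
    """Open/blocked current levels from the two-state histogram."""

    open_level: float
    closed_level: float
    n_modes_found: int

    def __post_init__(self) -> None:
        if not self.open_level > self.closed_level:
            raise ParameterError("open_level must exceed closed_level")


@dataclass(frozen=True)
class EventRecord:
    """One idealized blockade event."""

    start: float
    end: float
    dwell: float
    pbc: float

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ParameterError("end must exceed start")
        if abs((self.end - self.start) - self.dwell) > 1e-12 * max(1.0, self.dwell):
            raise ParameterError("dwell must equal end - start")
        if not self.pbc > 0:
            raise ParameterError("pbc must be > 0")


@dataclass
class EventTable:
    """Time-ordered, non-overlapping blockade events for one condition."""

    events: list[EventRecord]
    baseline: float
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for prev, cur in zip(self.events, self.events[1:]):
            if cur.start < prev.end:
                raise ParameterError("events must be time-ordered, non-overlapping")

    def __len__(self) -> int:
        return len(self.events)

    @property
    def dwells(self) -> np.ndarray:
        return np.array([e.dwell for e in self.events], dtype=float)

    @property
    def pbcs(self) -> np.ndarray:
        return np.array([e.pbc for e in self.events], dtype=float)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "event_id": np.arange(len(self.events)),
                "start_s": [e.start for e in self.events],
                "end_s": [e.end for e in self.events],
                "dwell_s": [e.dwell for e in self.events],
                "pbc_pa": [e.pbc for e in self.events],
            }
        )
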