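"""Closed-form physicochemical calculators for the nanopore device.

Back-of-envelope physics used when interpreting transport data: the number
of ions resident in the pore at a given bulk concentration, the wall
surface-charge density those ions would neutralize, the Raman radial-
breathing-mode (RBM) to diameter conversion, and the fractional velocity
gain of a heavy ion struck by a thermal proton.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.constants import Avogadro, elementary_charge

from .core import DeviceGeometry, ParameterError

__all__ = [
    "IonSpecies",
    "KNOWN_IONS",
    "HYDROGEN_MOLAR_MASS",
    "RBM_CONSTANT",
    "ions_in_pore",
    "surface_charge_density",
    "rbm_to_diameter",
    "collision_velocity_gain",
]

#: Molar mass of atomic hydrogen, g/mol.
HYDROGEN_MOLAR_MASS = 1.008

#: RBM relation constant A in d = A/omega, cm^-1 nm, for isolated SWNTs on SiO2.
RBM_CONSTANT = 248.0


@dataclass(frozen=True)
class IonSpecies:
    """A transported cation: name, molar mass (g/mol), charge (e units)."""

    name: str
    molar_mass: float
    charge: int = 1

    def __post_init__(self) -> None:
        if not self.molar_mass > 0:
            raise ParameterError("molar_mass must be > 0")
        if self.charge == 0:
            raise ParameterError("transported ions must carry charge")


#: Cations studied with this device (cation masses, g/mol).
KNOWN_IONS = {
    "sodium": IonSpecies("sodium", 22.99),
    "choline": IonSpecies("choline", 104.17),
    "acetylcholine": IonSpecies("acetylcholine", 146.21),
    "dopamine": IonSpecies("dopamine", 154.19),
    "aniline": IonSpecies("aniline", 94.13),
}


def ions_in_pore(concentration: float, geometry: DeviceGeometry) -> float:
    """Expected ion count inside the pore at bulk concentration c (mol/L).

    Assumes the in-pore concentration equals the bulk:
    count = c * N_A * pi * (d/2)^2 * L, with c converted to mol/m^3.
    """
    if concentration < 0:
        raise ParameterError("concentration must be >= 0")
    volume_m3 = np.pi * (geometry.diameter / 2.0) ** 2 * geometry.length
    return concentration * 1000.0 * Avogadro * volume_m3


def surface_charge_density(n_ions: float, geometry: DeviceGeometry) -> float:
    """Charge density (C/m^2) if n monovalent ions coat the lateral wall.

    Uses the cylindrical (lateral) area pi * d * L only.
    """
    if n_ions < 0:
        raise ParameterError("n_ions must be >= 0")
    area = np.pi * geometry.diameter * geometry.length
    return n_ions * elementary_charge / area


def rbm_to_diameter(omega: float, a: float = RBM_CONSTANT) -> float:
    """SWNT diameter (nm) from the RBM Raman shift omega (cm^-1): d = A/omega."""
    if omega <= 0:
        raise ParameterError("omega must be > 0")
    return a / omega


def collision_velocity_gain(ion: IonSpecies) -> float:
    """Percent velocity gain of an ion after complete momentum transfer
    from one thermal proton: 100 * sqrt(m_H / m_ion).

    Both species move at their thermal speeds (v ~ 1/sqrt(m)), so a proton
    of momentum m_H * v_H delivers a fractional velocity boost
    m_H v_H / (m v) = sqrt(m_H / m).  Note: this convention reproduces the
    conventionally quoted gains for sodium (21%) and choline (10%) but
    gives 8.3% for the acetylcholine cation where 7.1% is sometimes quoted;
    the mass convention behind that figure is not documented, so the value
    computed here is reported unreconciled.
    """
    return 100.0 * float(np.sqrt(HYDROGEN_MOLAR_MASS / ion.molar_mass))
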