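"""Electrochemical potential-scale arithmetic.

Everything in this package is carried internally in volts vs SHE (standard
hydrogen electrode); the RHE (reversible hydrogen electrode) scale is a
pH-dependent view of the same number,

    E_RHE = E_SHE - E_eq(pH, p_H2),

where ``E_eq`` is the equilibrium potential of the H+/H2 couple.  By
convention the Nernstian pH slope defaults to a rounded 60 mV/pH, which is
what electrochemists use when quoting values such as "-0.42 V vs SHE at
pH 7"; the physically exact slope 2.303*R*T/F is available by passing
``slope_mV_per_pH=None`` together with a temperature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "R",
    "F",
    "PotentialValue",
    "RedoxCouple",
    "nernst_slope_mV",
    "h2_equilibrium_potential",
    "convert_reference",
    "mediator_overpotential",
    "nernst_from_ratio",
]

R = 8.31446261815324  # J mol^-1 K^-1
F = 96485.33212  # C mol^-1

_SCALES = ("SHE", "RHE")


def nernst_slope_mV(temperature: float = 298.15) -> float:
    """Physically exact Nernstian slope 2.303*R*T/F in mV per pH unit."""
    return 1000.0 * math.log(10.0) * R * temperature / F


@dataclass(frozen=True)
class PotentialValue:
    """A potential with an explicit reference scale and pH context.

    Parameters
    ----------
    value:
        Potential in volts.
    scale:
        ``"SHE"`` or ``"RHE"``.
    pH:
        Solution pH; required whenever the value is on the RHE scale or a
        scale conversion is requested.
    temperature:
        Kelvin; only used when the exact Nernstian slope is requested.
    """

    value: float
    scale: str = "SHE"
    pH: float | None = None
    temperature: float = 298.15

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError("potential must be finite")
        if self.scale not in _SCALES:
            raise ValueError(f"scale must be one of {_SCALES}, got {self.scale!r}")
        if self.pH is not None and not (0.0 <= self.pH <= 14.0):
            raise ValueError(f"pH must lie in [0, 14], got {self.pH}")
        if self.scale == "RHE" and self.pH is None:
            raise ValueError("RHE-scale potentials require a pH")

    @property
    def mV(self) -> float:
        return 1000.0 * self.value


@dataclass(frozen=True)
class RedoxCouple:
    """A redox couple with standard potential ``e0`` in volts vs SHE."""

    e0: float
    n_electrons: int = 1
    label: str = ""

    def __post_init__(self) -> None:
        if self.n_electrons < 1:
            raise ValueError("n_electrons must be a positive integer")
        if not math.isfinite(self.e0):
            raise ValueError("e0 must be finite")


def _slope_volts(slope_mV_per_pH: float | None, temperature: float) -> float:
    if slope_mV_per_pH is None:
        return nernst_slope_mV(temperature) / 1000.0
    return slope_mV_per_pH / 1000.0


def h2_equilibrium_potential(
    pH: float,
    p_h2: float = 1.0,
    slope_mV_per_pH: float | None = 60.0,
    temperature: float = 298.15,
) -> PotentialValue:
    """Equilibrium potential of the H+/H2 couple, in volts vs SHE.

    E_eq = -slope*pH - (slope/2)*log10(p_H2); the half power of p(H2)
    follows from the two-electron stoichiometry H2 = 2H+ + 2e-.  At
    p_H2 = 1 bar and pH 7 with the conventional 60 mV/pH slope this is
    -0.42 V vs SHE.
    """
    if p_h2 <= 0:
        raise ValueError(f"p_h2 must be positive, got {p_h2}")
    s = _slope_volts(slope_mV_per_pH, temperature)
    value = -s * pH - (s / 2.0) * math.log10(p_h2)
    return PotentialValue(value, scale="SHE", pH=pH, temperature=temperature)


def convert_reference(
    p: PotentialValue,
    target_scale: str,
    slope_mV_per_pH: float | None = 60.0,
    p_h2: float = 1.0,
) -> PotentialValue:
    """Convert a potential between the SHE and RHE scales.

    E_RHE = E_SHE - E_eq(pH); the round trip is the identity.  The pH must
    be carried by the input value.
    """
    if target_scale not in _SCALES:
        raise ValueError(f"target scale must be one of {_SCALES}")
    if p.scale == target_scale:
        return p
    if p.pH is None:
        raise ValueError("scale conversion requires a pH")
    e_eq = h2_equilibrium_potential(
        p.pH, p_h2=p_h2, slope_mV_per_pH=slope_mV_per_pH, temperature=p.temperature
    ).value
    if target_scale == "RHE":
        value = p.value - e_eq
    else:
        value = p.value + e_eq
    return PotentialValue(value, scale=target_scale, pH=p.pH, temperature=p.temperature)


def mediator_overpotential(
    couple: RedoxCouple,
    pH: float,
    p_h2: float = 1.0,
    slope_mV_per_pH: float | None = 60.0,
    temperature: float = 298.15,
) -> float:
    """E0 - E_eq(pH, p_H2) in millivolts.

    Positive means the mediator couple is more oxidizing than the H+/H2
    couple under the stated conditions.
    """
    e_eq = h2_equilibrium_potential(
        pH, p_h2=p_h2, slope_mV_per_pH=slope_mV_per_pH, temperature=temperature
    ).value
    return 1000.0 * (couple.e0 - e_eq)


def nernst_from_ratio(
    couple: RedoxCouple,
    ratio_ox_over_red: float,
    temperature: float = 298.15,
) -> PotentialValue:
    """Nernst potential E = E0 + (RT/nF) ln([ox]/[red]), in volts vs SHE."""
    if ratio_ox_over_red <= 0:
        raise ValueError(
            "the Nernst potential is undefined at fully oxidized/reduced poles; "
            f"ratio must be positive, got {ratio_ox_over_red}"
        )
    value = couple.e0 + (R * temperature / (couple.n_electrons * F)) * math.log(
        ratio_ox_over_red
    )
    return PotentialValue(value, scale="SHE", temperature=temperature)
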