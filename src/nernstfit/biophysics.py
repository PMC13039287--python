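"""Closed-form membrane electrochemistry.

Goldman-Hodgkin-Katz (GHK) and Nernst potentials for the K+/Na+/Cl- system,
and the voltage <-> equilibrium-constant conversions that tie a membrane
potential to the forward/reverse rate constants of a monovalent lipophilic
cation (z = +1) crossing that membrane.  All public voltages are in mV with
the physiological sign convention: a polarized membrane (inside negative)
is a negative number.  Internally voltages are converted to volts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "GAS_CONSTANT",
    "FARADAY",
    "BODY_TEMPERATURE_K",
    "TC99M_HALF_LIFE_H",
    "PhysicalConstants",
    "IonConditions",
    "VoltageSegment",
    "ghk_voltage",
    "nernst_voltage",
    "equilibrium_constant",
    "reverse_rate",
    "steady_state_ratios",
    "decay_rate_constant",
    "time_averaged_potential",
]

#: Universal gas constant, J mol^-1 K^-1.
GAS_CONSTANT = 8.314
#: Faraday constant, C mol^-1.
FARADAY = 96485.0
#: Default absolute temperature, K (mammalian body temperature).
BODY_TEMPERATURE_K = 310.0
#: Half-life of Tc-99m, hours.
TC99M_HALF_LIFE_H = 6.006


@dataclass(frozen=True)
class PhysicalConstants:
    """Thermodynamic constants used throughout the package."""

    R: float = GAS_CONSTANT
    F: float = FARADAY
    T: float = BODY_TEMPERATURE_K

    def __post_init__(self) -> None:
        for name in ("R", "F", "T"):
            if getattr(self, name) <= 0:
                raise ValueError(f"PhysicalConstants.{name} must be > 0")

    @property
    def thermal_voltage(self) -> float:
        """RT/F in volts."""
        return self.R * self.T / self.F


def _thermal_voltage(temperature_k: float) -> float:
    if temperature_k <= 0:
        raise ValueError("temperature must be > 0 K")
    return GAS_CONSTANT * temperature_k / FARADAY


@dataclass(frozen=True)
class IonConditions:
    """Intra-/extracellular concentrations (mM) and relative permeabilities.

    Covers the three dominant permeant species of excitable membranes:
    K+, Na+ and Cl-.  Permeabilities are relative (dimensionless); only
    their ratios matter in the GHK voltage equation.
    """

    k_out: float
    k_in: float
    na_out: float
    na_in: float
    cl_out: float
    cl_in: float
    p_k: float = 1.0
    p_na: float = 0.01
    p_cl: float = 0.1

    def __post_init__(self) -> None:
        for name in ("k_out", "k_in", "na_out", "na_in", "cl_out", "cl_in"):
            if getattr(self, name) <= 0:
                raise ValueError(f"IonConditions.{name} must be > 0 mM")
        perms = (self.p_k, self.p_na, self.p_cl)
        if any(p < 0 for p in perms):
            raise ValueError("permeabilities must be >= 0")
        if all(p == 0 for p in perms):
            raise ValueError("at least one permeability must be > 0")

    @classmethod
    def cardiac_rest(cls, k_out: float = 4.9) -> "IonConditions":
        """Typical resting cardiac-tissue conditions.

        ``k_out`` may be varied to model hyperkalaemic buffers; all other
        values are the standard resting concentrations/permeabilities.
        """
        return cls(
            k_out=k_out, k_in=115.0,
            na_out=140.0, na_in=15.0,
            cl_out=115.0, cl_in=15.0,
            p_k=1.0, p_na=0.01, p_cl=0.1,
        )


@dataclass(frozen=True)
class VoltageSegment:
    """One phase of a periodic voltage waveform (e.g. the cardiac cycle)."""

    voltage_mv: float
    duration_ms: float

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("VoltageSegment.duration_ms must be > 0")


def ghk_voltage(ions: IonConditions, temperature_k: float = BODY_TEMPERATURE_K) -> float:
    """GHK voltage for the K+/Na+/Cl- system, in mV.

    Em = (RT/F) ln[(P_K[K]o + P_Na[Na]o + P_Cl[Cl]i) /
                   (P_K[K]i + P_Na[Na]i + P_Cl[Cl]o)]

    The chloride terms swap sides because Cl- is an anion.
    """
    num = ions.p_k * ions.k_out + ions.p_na * ions.na_out + ions.p_cl * ions.cl_in
    den = ions.p_k * ions.k_in + ions.p_na * ions.na_in + ions.p_cl * ions.cl_out
    if num <= 0:
        raise ValueError(
            "GHK numerator P_K[K]out + P_Na[Na]out + P_Cl[Cl]in is non-positive"
        )
    if den <= 0:
        raise ValueError(
            "GHK denominator P_K[K]in + P_Na[Na]in + P_Cl[Cl]out is non-positive"
        )
    return _thermal_voltage(temperature_k) * math.log(num / den) * 1000.0


def nernst_voltage(
    c_out: float,
    c_in: float,
    z: int = 1,
    temperature_k: float = BODY_TEMPERATURE_K,
) -> float:
    """Nernst equilibrium potential E = (RT/zF) ln(c_out/c_in), in mV."""
    if z == 0:
        raise ValueError("ionic charge z must be non-zero")
    if c_out <= 0 or c_in <= 0:
        raise ValueError("concentrations must be > 0")
    return _thermal_voltage(temperature_k) / z * math.log(c_out / c_in) * 1000.0


def equilibrium_constant(e_mv: float, temperature_k: float = BODY_TEMPERATURE_K) -> float:
    """Equilibrium constant of a monovalent cation across a membrane at ``e_mv``.

    K = exp(-F E / RT) with E in volts; K > 1 for an inside-negative
    (polarized) membrane, i.e. the cation accumulates inside.
    """
    if not math.isfinite(e_mv):
        raise ValueError("membrane potential must be finite")
    return math.exp(-FARADAY * (e_mv / 1000.0) / (GAS_CONSTANT * temperature_k))


def reverse_rate(
    k_fwd: float,
    e_mv: float,
    temperature_k: float = BODY_TEMPERATURE_K,
) -> float:
    """Reverse rate constant implied by the Nernst relation.

    k_rev = k_fwd * exp(F E / RT), so that k_fwd / k_rev equals
    :func:`equilibrium_constant`.
    """
    if k_fwd < 0:
        raise ValueError("forward rate constant must be >= 0")
    return k_fwd * math.exp(FARADAY * (e_mv / 1000.0) / (GAS_CONSTANT * temperature_k))


def steady_state_ratios(
    em_mv: float,
    dpsi_mv: float,
    temperature_k: float = BODY_TEMPERATURE_K,
    rounded: bool = False,
) -> tuple[float, float, float]:
    """Relative steady-state tracer concentrations plasma : cytosol : mitochondria.

    Returns (1, K1, K1*K2) where K1 and K2 are the equilibrium constants
    across the sarcolemmal and mitochondrial membranes.  With
    ``rounded=True`` each K is rounded to the nearest integer before the
    product is taken (the conventional back-of-envelope presentation).
    """
    k1 = equilibrium_constant(em_mv, temperature_k)
    k2 = equilibrium_constant(dpsi_mv, temperature_k)
    if rounded:
        k1r, k2r = round(k1), round(k2)
        return (1.0, float(k1r), float(k1r * k2r))
    return (1.0, k1, k1 * k2)


def decay_rate_constant(half_life_hours: float = TC99M_HALF_LIFE_H) -> float:
    """First-order radioactive decay rate constant, s^-1, from a half-life in hours."""
    if half_life_hours <= 0:
        raise ValueError("half-life must be > 0")
    return math.log(2.0) / (half_life_hours * 3600.0)


def time_averaged_potential(segments: Iterable[VoltageSegment] | Sequence[tuple]) -> float:
    """Duration-weighted mean voltage over a waveform, in mV.

    Accepts :class:`VoltageSegment` instances or plain ``(voltage_mv,
    duration_ms)`` tuples.  Used e.g. to average diastolic and systolic
    sarcolemmal potentials over the cardiac cycle.
    """
    segs = [
        s if isinstance(s, VoltageSegment) else VoltageSegment(*s)
        for s in segments
    ]
    if not segs:
        raise ValueError("at least one voltage segment is required")
    total = sum(s.duration_ms for s in segs)
    return sum(s.voltage_mv * s.duration_ms for s in segs) / total
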