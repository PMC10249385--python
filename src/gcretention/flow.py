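"""Carrier-gas flow physics for open-tubular GC columns.

Compressible laminar (Hagen–Poiseuille) flow of an ideal gas through a
cylindrical capillary: the pressure profile obeys
p(z)² = p_i² − (p_i² − p_o²)·z/L and the holdup (void) time — the transit
time of an unretained species — has the closed form

    tM = (128 η L² / (3 d²)) · (p_i³ − p_o³) / (p_i² − p_o²)²,

with η the dynamic viscosity of the carrier gas at the column temperature.
All quantities in SI (m, Pa, s); pressures are absolute.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "ColumnSpec",
    "FlowConditions",
    "GasProperties",
    "GAS_PROPERTIES",
    "UnsupportedGasError",
    "NoFlowError",
    "viscosity",
    "holdup_time",
    "outlet_flow",
    "inlet_pressure_for_flow",
    "GeometryEstimate",
    "estimate_geometry",
    "STANDARD_T",
    "STANDARD_P",
]

#: Reference state for volumetric flow specifications (25 °C, 1 atm).
STANDARD_T = 298.15  # K
STANDARD_P = 101325.0  # Pa


class UnsupportedGasError(ValueError):
    pass


class NoFlowError(ValueError):
    pass


@dataclass(frozen=True)
class GasProperties:
    """Power-law viscosity model η(T) = eta_ref · (T / T_ref)^zeta."""

    name: str
    eta_ref: float  # [Pa s] at T_ref
    T_ref: float  # [K]
    zeta: float  # dimensionless exponent


# Reference data: helium anchored to Kestin, Ro & Wakeham,
# J. Chem. Phys. 56 (1972) 4119: eta(He, 298.15 K) = 19.86 uPa s.
# Exponents chosen so the power law tracks tabulated viscosities over the
# GC-relevant 300-600 K range to within ~2%.
GAS_PROPERTIES: Dict[str, GasProperties] = {
    "helium": GasProperties("helium", 19.86e-6, 298.15, 0.694),
    "hydrogen": GasProperties("hydrogen", 8.90e-6, 298.15, 0.670),
    "nitrogen": GasProperties("nitrogen", 17.80e-6, 298.15, 0.730),
}
_ALIASES = {"he": "helium", "h2": "hydrogen", "n2": "nitrogen"}


def _gas(gas) -> GasProperties:
    if isinstance(gas, GasProperties):
        return gas
    key = str(gas).strip().lower()
    key = _ALIASES.get(key, key)
    try:
        return GAS_PROPERTIES[key]
    except KeyError:
        raise UnsupportedGasError(
            f"unsupported carrier gas {gas!r}; known: {sorted(GAS_PROPERTIES)}"
        ) from None


@dataclass(frozen=True)
class ColumnSpec:
    """Wall-coated cylindrical column geometry (SI units).

    The phase ratio β = d/(4·df) relates to the dimensionless film
    thickness φ0 = df/d = 1/(4β).
    """

    L: float  # length [m]
    d: float  # internal diameter [m]
    df: float  # film thickness [m]
    phase: str = ""

    def __post_init__(self):
        if self.L <= 0 or self.d <= 0 or self.df <= 0:
            raise ValueError("L, d, df must all be positive")
        if self.d <= 2 * self.df:
            raise ValueError("film thickness too large: need d > 2*df")

    @property
    def beta(self) -> float:
        return self.d / (4.0 * self.df)

    @property
    def phi0(self) -> float:
        return 1.0 / (4.0 * self.beta)


@dataclass(frozen=True)
class FlowConditions:
    """Carrier-gas operating point.

    mode "flow": ``flow`` is the volumetric flow [m³/s] referred to
    (``ref_T``, ``ref_p``); the inlet pressure is recomputed from viscosity
    at each column temperature.  mode "pressure": ``p_i`` is held constant.
    """

    gas: str = "helium"
    mode: str = "flow"
    flow: Optional[float] = None  # [m^3/s] at (ref_T, ref_p)
    p_i: Optional[float] = None  # [Pa] absolute
    p_o: float = STANDARD_P  # [Pa] absolute
    ref_T: float = STANDARD_T
    ref_p: float = STANDARD_P

    def __post_init__(self):
        if self.p_o <= 0:
            raise ValueError("outlet pressure must be positive (absolute)")
        if self.mode == "flow":
            if self.flow is None or self.flow <= 0:
                raise ValueError("flow mode requires flow > 0")
        elif self.mode == "pressure":
            if self.p_i is None or self.p_i <= 0:
                raise ValueError("pressure mode requires p_i > 0")
        else:
            raise ValueError(f"unknown flow mode {self.mode!r}")

    def inlet_pressure(self, col: "ColumnSpec", T: float) -> float:
        """Inlet pressure [Pa] at column temperature T under these conditions."""
        if self.mode == "pressure":
            return float(self.p_i)
        return inlet_pressure_for_flow(
            col, T, self.flow, self.p_o, self.gas, ref_T=self.ref_T, ref_p=self.ref_p
        )


def viscosity(gas, T) -> float:
    """Dynamic viscosity [Pa s] of the carrier gas at temperature T [K]."""
    g = _gas(gas)
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive (kelvin)")
    out = g.eta_ref * (T / g.T_ref) ** g.zeta
    return out if out.ndim else float(out)


def holdup_time(col: ColumnSpec, T: float, p_i: float, p_o: float, gas="helium") -> float:
    """Holdup (void) time tM [s] for compressible laminar flow."""
    if p_o <= 0 or p_i <= p_o:
        raise NoFlowError("need p_i > p_o > 0 for forward flow")
    eta = viscosity(gas, T)
    num = p_i**3 - p_o**3
    den = (p_i**2 - p_o**2) ** 2
    return (128.0 * eta * col.L**2 / (3.0 * col.d**2)) * num / den


def outlet_flow(
    col: ColumnSpec,
    T: float,
    p_i: float,
    p_o: float,
    gas="helium",
    ref_T: float = STANDARD_T,
    ref_p: float = STANDARD_P,
) -> float:
    """Volumetric flow [m³/s] at the reference state (molar-flow conserved)."""
    if p_o <= 0 or p_i <= p_o:
        raise NoFlowError("need p_i > p_o > 0 for forward flow")
    eta = viscosity(gas, T)
    # F_ref = (pi d^4 / 256 eta L) * (p_i^2 - p_o^2) * ref_T / (ref_p * T)
    return (
        math.pi
        * col.d**4
        / (256.0 * eta * col.L)
        * (p_i**2 - p_o**2)
        * ref_T
        / (ref_p * T)
    )


def inlet_pressure_for_flow(
    col: ColumnSpec,
    T: float,
    flow: float,
    p_o: float,
    gas="helium",
    ref_T: float = STANDARD_T,
    ref_p: float = STANDARD_P,
) -> float:
    """Inlet pressure [Pa] sustaining a given reference-state volumetric flow.

    The compressible-flow relation is quadratic in p_i² and inverts in
    closed form; the zero-flow limit returns p_o.
    """
    if flow < 0:
        raise NoFlowError("flow must be non-negative")
    eta = viscosity(gas, T)
    rhs = flow * 256.0 * eta * col.L * ref_p * T / (math.pi * col.d**4 * ref_T)
    return math.sqrt(p_o**2 + rhs)


@dataclass(frozen=True)
class GeometryEstimate:
    """L/d estimate from void-time measurements.

    Standard errors are ``None`` (absent) when only one measurement is
    available — a single observation carries no dispersion information.
    """

    L_over_d: float
    L_over_d_err: Optional[float]
    L: float
    L_err: Optional[float]
    d: float
    per_measurement: Tuple[float, ...]


def estimate_geometry(
    measurements: Iterable[Tuple[float, float, float, float]],
    d: float,
    gas="helium",
    df: Optional[float] = None,
) -> GeometryEstimate:
    """Estimate the L/d ratio of a column from measured void times.

    ``measurements`` — iterable of (tM [s], T [K], p_i [Pa], p_o [Pa]).
    Each measurement is inverted through the closed-form holdup relation
    (tM ∝ L² at fixed d and conditions); the estimate is the mean across
    measurements with its standard error.
    """
    rows = list(measurements)
    if not rows:
        raise ValueError("need at least one void-time measurement")
    if d <= 0:
        raise ValueError("diameter must be positive")
    ratios = []
    for tM, T, p_i, p_o, *_ in rows:
        if p_i <= p_o or p_o <= 0:
            raise NoFlowError("need p_i > p_o > 0 in every measurement")
        if tM <= 0:
            raise ValueError("void time must be positive")
        eta = viscosity(gas, T)
        num = p_i**3 - p_o**3
        den = (p_i**2 - p_o**2) ** 2
        L = math.sqrt(tM * 3.0 * d**2 * den / (128.0 * eta * num))
        ratios.append(L / d)
    ratios_arr = np.asarray(ratios)
    mean = float(ratios_arr.mean())
    if len(ratios) > 1:
        sem = float(ratios_arr.std(ddof=1) / math.sqrt(len(ratios)))
        L_err = sem * d
    else:
        sem = None
        L_err = None
    return GeometryEstimate(
        L_over_d=mean,
        L_over_d_err=sem,
        L=mean * d,
        L_err=L_err,
        d=d,
        per_measurement=tuple(ratios),
    )
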