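"""Retention models and their pairwise conversions.

Three equivalent temperature-independent parameterizations of gas-liquid
partition retention are supported:

``ABCParams``
    Clarke–Glew three-parameter form.  The coefficients parameterize the
    distribution coefficient,

        ln K(T) = A + B/T + C·ln(T/T1),   T1 = 1 K,

    and the retention factor on a column with phase ratio β follows from
    K = k·β:

        ln k(T) = A + B/T + C·ln(T/T1) − ln β.

    ``beta0`` is the nominal phase ratio the parameters were determined at;
    with β0 = 1 the two expressions coincide.

``KCentricParams``
    Distribution-centric form of Blumberg with a direct chromatographic
    interpretation: the characteristic temperature Tchar is where ln k = 0
    (solute evenly split between the phases), the characteristic thermal
    constant θchar is the inverse declining slope of ln k(T) there (a θchar
    rise in temperature around Tchar cuts k by a factor of e), and ΔCp is
    the change of the isobaric molar heat capacity:

        ln k(T) = (ΔCp/R + Tchar/θchar)·(Tchar/T − 1)
                  + (ΔCp/R)·ln(T/Tchar).

``ThermoParams``
    Enthalpy ΔHref and entropy ΔSref of transfer from the stationary into
    the mobile phase at a reference temperature Tref, plus ΔCp:

        ΔH(T) = ΔHref + ΔCp·(T − Tref)
        ΔS(T) = ΔSref + ΔCp·ln(T/Tref)
        ln K(T) = −ΔH(T)/(R·T) + ΔS(T)/R.

All conversions are exact algebra except ABC → K-centric, which requires the
real −1 branch of the Lambert W function to locate Tchar.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy.special import lambertw

from .constants import R_GAS, T1_K

__all__ = [
    "ABCParams",
    "KCentricParams",
    "ThermoParams",
    "LambertArgument",
    "DomainError",
    "ConversionDomainError",
    "lnk_abc",
    "lnk_kcentric",
    "lnk_thermo",
    "retention_factor",
    "abc_to_thermo",
    "thermo_to_abc",
    "abc_to_kcentric",
    "kcentric_to_abc",
    "kcentric_to_thermo",
    "thermo_to_kcentric",
]


class DomainError(ValueError):
    """Input outside the physical domain of a retention model."""


class ConversionDomainError(DomainError):
    """A parameter conversion has no valid solution.

    Raised e.g. when the Lambert-W argument of the ABC → K-centric
    conversion falls outside (−1/e, 0): the ln k(T) curve then never
    crosses zero and no characteristic temperature exists.  Entries
    hitting this must be flagged, never silently repaired.
    """

    def __init__(self, message: str, x: float | None = None):
        super().__init__(message)
        self.x = x


@dataclass(frozen=True)
class ABCParams:
    """Clarke–Glew coefficients (see module docstring for the convention).

    A is dimensionless, B has units of K, C is dimensionless.  ``beta0`` is
    the phase ratio the parameters refer to.
    """

    A: float
    B: float
    C: float
    beta0: float = 1.0
    err_A: Optional[float] = None
    err_B: Optional[float] = None
    err_C: Optional[float] = None

    def __post_init__(self):
        if not math.isfinite(self.B):
            raise DomainError("B must be finite")
        if self.beta0 <= 0:
            raise DomainError("phase ratio beta0 must be positive")


@dataclass(frozen=True)
class KCentricParams:
    """K-centric parameters (internal units: K, J/mol/K)."""

    Tchar: float  # [K]
    thetachar: float  # [K]
    dCp: float  # [J mol^-1 K^-1]
    beta0: float = 1.0
    err_Tchar: Optional[float] = None
    err_thetachar: Optional[float] = None
    err_dCp: Optional[float] = None

    def __post_init__(self):
        if self.Tchar <= 0:
            raise DomainError("Tchar must be positive (kelvin)")
        if self.beta0 <= 0:
            raise DomainError("phase ratio beta0 must be positive")


@dataclass(frozen=True)
class ThermoParams:
    """Transfer enthalpy/entropy at a reference temperature Tref [K]."""

    dHref: float  # [J mol^-1]
    dSref: float  # [J mol^-1 K^-1]
    dCp: float  # [J mol^-1 K^-1]
    Tref: float  # [K]
    err_dHref: Optional[float] = None
    err_dSref: Optional[float] = None

    def __post_init__(self):
        if self.Tref <= 0:
            raise DomainError("Tref must be positive (kelvin)")


@dataclass(frozen=True)
class LambertArgument:
    """Diagnostics of the Lambert-W step of an ABC → K-centric conversion.

    For an acceptable conversion the argument satisfies −1/e < x < 0 and the
    real −1 branch is used, so W(x) < −1.
    """

    x: float
    branch: int = -1
    w: float = field(default=float("nan"))


def _check_T(T):
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise DomainError("temperature must be positive (kelvin)")
    return T


def lnk_abc(T, p: ABCParams):
    """ln k(T) of the Clarke–Glew model at the parameter set's own β0.

    With β0 = 1 this is exactly A + B/T + C·ln(T/T1).
    """
    T = _check_T(T)
    out = p.A + p.B / T + p.C * np.log(T / T1_K) - math.log(p.beta0)
    return out if out.ndim else float(out)


def lnk_kcentric(T, p: KCentricParams, beta1: Optional[float] = None):
    """ln k(T) of the K-centric model.

    ``beta1`` — phase ratio of the column the prediction is for.  If given
    and different from the β0 the parameters were determined at, the result
    is shifted by ln(β0/β1) (K = k·β is invariant under β changes).
    """
    if p.thetachar == 0:
        raise DomainError("thetachar must be nonzero")
    T = _check_T(T)
    c = p.dCp / R_GAS
    out = (c + p.Tchar / p.thetachar) * (p.Tchar / T - 1.0) + c * np.log(T / p.Tchar)
    if beta1 is not None:
        if beta1 <= 0:
            raise DomainError("phase ratio beta1 must be positive")
        out = out + math.log(p.beta0 / beta1)
    return out if out.ndim else float(out)


def lnk_thermo(T, p: ThermoParams, beta: float):
    """ln k(T) from the thermodynamic parameterization on a column with phase ratio β."""
    if beta <= 0:
        raise DomainError("phase ratio beta must be positive")
    T = _check_T(T)
    dH = p.dHref + p.dCp * (T - p.Tref)
    dS = p.dSref + p.dCp * np.log(T / p.Tref)
    out = -dH / (R_GAS * T) + dS / R_GAS - math.log(beta)
    return out if out.ndim else float(out)


def retention_factor(tR: float, tM: float) -> float:
    """Retention factor k = (tR − tM)/tM from retention and void time (same units)."""
    if tM <= 0:
        raise DomainError("void time tM must be positive")
    if tR < tM:
        raise DomainError(
            f"retention time {tR} before void time {tM}: negative retention"
        )
    return (tR - tM) / tM


def abc_to_thermo(p: ABCParams, Tref: float) -> ThermoParams:
    """Convert Clarke–Glew coefficients to (ΔHref, ΔSref, ΔCp) at Tref [K].

    ΔCp = C·R;  ΔHref = C·R·Tref − B·R;  ΔSref = A·R + C·R·(1 + ln(Tref/T1)).
    """
    if Tref <= 0:
        raise DomainError("Tref must be positive (kelvin)")
    dCp = p.C * R_GAS
    dHref = dCp * Tref - p.B * R_GAS
    dSref = p.A * R_GAS + dCp * (1.0 + math.log(Tref / T1_K))
    return ThermoParams(dHref=dHref, dSref=dSref, dCp=dCp, Tref=Tref)


def thermo_to_abc(p: ThermoParams, beta0: float = 1.0) -> ABCParams:
    """Exact inverse of :func:`abc_to_thermo` at the same Tref."""
    C = p.dCp / R_GAS
    B = C * p.Tref - p.dHref / R_GAS
    A = p.dSref / R_GAS - C * (1.0 + math.log(p.Tref / T1_K))
    return ABCParams(A=A, B=B, C=C, beta0=beta0)


#: |C| below this is treated as the two-parameter (ΔCp = 0) model, where the
#: Lambert form is singular and the root is analytic.
_TWO_PARAM_C_TOL = 1e-12


def abc_to_kcentric(
    p: ABCParams, allow_two_param_fallback: bool = False
) -> Tuple[KCentricParams, Optional[LambertArgument]]:
    """Convert Clarke–Glew coefficients to K-centric parameters.

    Tchar solves ln k(Tchar) = 0, obtained in closed form on the real −1
    branch of the Lambert W function:

        x = −(B/C)·exp((A − ln β0)/C) / T1,   Tchar = −(B/C)/W₋₁(x),

    and θchar = Tchar² / (B − C·Tchar) (the inverse negative slope of
    ln k at Tchar).  Returns the K-centric parameters together with a
    :class:`LambertArgument` record (``None`` on the two-parameter branch).

    Raises
    ------
    ConversionDomainError
        If x falls outside (−1/e, 0) — the curve never crosses ln k = 0 —
        or if C < 0 and ``allow_two_param_fallback`` is False.
    """
    a_eff = p.A - math.log(p.beta0)  # ln k intercept

    if abs(p.C) < _TWO_PARAM_C_TOL or (p.C < 0 and allow_two_param_fallback):
        # two-parameter model: ln k = a_eff + B/T
        if a_eff >= 0 or p.B <= 0:
            raise ConversionDomainError(
                "two-parameter model has no positive root of ln k = 0"
            )
        Tchar = -p.B / a_eff
        thetachar = Tchar**2 / p.B
        return (
            KCentricParams(Tchar=Tchar, thetachar=thetachar, dCp=0.0, beta0=p.beta0),
            None,
        )

    if p.C < 0:
        raise ConversionDomainError(
            "C < 0: curvature has the wrong sign for the W_-1 branch; "
            "pass allow_two_param_fallback=True to ignore the curvature term"
        )

    x = -(p.B / p.C) * math.exp(a_eff / p.C) / T1_K
    if not (-1.0 / math.e < x < 0.0):
        raise ConversionDomainError(
            f"Lambert-W argument x = {x:.6g} outside (-1/e, 0): "
            "ln k(T) never crosses zero, no characteristic temperature exists",
            x=x,
        )
    w = float(lambertw(x, -1).real)
    Tchar = -(p.B / p.C) / w
    thetachar = Tchar**2 / (p.B - p.C * Tchar)
    kc = KCentricParams(
        Tchar=Tchar, thetachar=thetachar, dCp=p.C * R_GAS, beta0=p.beta0
    )
    return kc, LambertArgument(x=x, branch=-1, w=w)


def kcentric_to_abc(p: KCentricParams) -> ABCParams:
    """Convert K-centric parameters to Clarke–Glew coefficients.

    Exact algebra (inverse of :func:`abc_to_kcentric`); the nominal phase
    ratio β0 enters the A coefficient because A parameterizes ln K while
    Tchar/θchar are defined on ln k.
    """
    if p.thetachar == 0:
        raise DomainError("thetachar must be nonzero")
    C = p.dCp / R_GAS
    s = C + p.Tchar / p.thetachar
    B = s * p.Tchar
    A = math.log(p.beta0) - s - C * math.log(p.Tchar / T1_K)
    return ABCParams(A=A, B=B, C=C, beta0=p.beta0)


def kcentric_to_thermo(p: KCentricParams, Tref: float) -> ThermoParams:
    """Enthalpy/entropy at Tref from K-centric parameters.

    With Tref = Tchar this yields the characteristic enthalpy and entropy
    ΔHchar, ΔSchar.
    """
    return abc_to_thermo(kcentric_to_abc(p), Tref)


def thermo_to_kcentric(
    p: ThermoParams, beta0: float
) -> Tuple[KCentricParams, Optional[LambertArgument]]:
    """K-centric parameters from thermodynamic data on a column with phase ratio β0."""
    return abc_to_kcentric(thermo_to_abc(p, beta0=beta0))
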