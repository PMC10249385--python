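"""Synthetic isothermal series and synthetic databases.

The generator emulates the standardized determination workflow: isothermal
measurements on a 60–300 °C grid in 10 °C increments, ln k computed from
retention and void times, and Gaussian noise on ln k (measurement noise in
retention times is small and multiplicative, so additive noise on ln k is
the natural idealization).  All randomness flows through explicit seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .constants import celsius_to_kelvin
from .dbio import DatabaseEntry, complete_entry
from .fitting import IsothermalSeries, LNK_RANGE
from .models import KCentricParams, kcentric_to_abc, lnk_kcentric

__all__ = [
    "SynthSpec",
    "DEFAULT_T_GRID_C",
    "generate_isothermal",
    "generate_isothermal_set",
    "generate_database",
    "CategoryTemplate",
]

#: Default isothermal temperature grid [°C]: 60–300 °C in 10 °C increments.
DEFAULT_T_GRID_C: Tuple[float, ...] = tuple(float(t) for t in range(60, 301, 10))


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for one synthetic isothermal series."""

    params: KCentricParams
    T_grid_C: Tuple[float, ...] = DEFAULT_T_GRID_C
    sigma: float = 0.0
    seed: int = 0
    compound: str = "synthetic"
    truncate_to_range: bool = False
    heteroscedastic: bool = False

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("noise sigma must be non-negative")
        if not self.T_grid_C:
            raise ValueError("temperature grid must be non-empty")


def generate_isothermal(
    spec: SynthSpec, rng: Optional[np.random.Generator] = None
) -> IsothermalSeries:
    """Generate one isothermal (T, ln k) series from known true parameters.

    lnk_i = lnk_kcentric(T_i; params) + ε_i with ε_i ~ N(0, σ²) (or
    σ·|lnk_i| heteroscedastic noise in stress mode).  With
    ``truncate_to_range`` the series keeps only points inside the acceptable
    ln k window, emulating the range criterion applied to real data.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    T = celsius_to_kelvin(np.asarray(spec.T_grid_C, dtype=float))
    lnk = np.asarray(lnk_kcentric(T, spec.params), dtype=float)
    if spec.sigma > 0:
        scale = spec.sigma * np.abs(lnk) if spec.heteroscedastic else spec.sigma
        lnk = lnk + rng.normal(0.0, 1.0, size=lnk.shape) * scale
    if spec.truncate_to_range:
        keep = (lnk >= LNK_RANGE[0]) & (lnk <= LNK_RANGE[1])
        T, lnk = T[keep], lnk[keep]
    return IsothermalSeries(
        compound=spec.compound,
        T=tuple(T),
        lnk=tuple(lnk),
        beta0=spec.params.beta0,
        provenance=f"synthetic (sigma={spec.sigma}, seed={spec.seed})",
    )


def generate_isothermal_set(
    params: Dict[str, KCentricParams],
    T_grid_C: Sequence[float] = DEFAULT_T_GRID_C,
    sigma: float = 0.0,
    seed: int = 0,
    **kwargs,
) -> List[IsothermalSeries]:
    """Generate series for several compounds from one master seed."""
    rng = np.random.default_rng(seed)
    out = []
    for name, p in params.items():
        spec = SynthSpec(
            params=p, T_grid_C=tuple(T_grid_C), sigma=sigma, compound=name, **kwargs
        )
        out.append(generate_isothermal(spec, rng=rng))
    return out


@dataclass(frozen=True)
class CategoryTemplate:
    """Mean and spread of (Tchar [K], θchar [K], ΔCp [J/mol/K]) for one
    substance category, e.g. n-alkanes vs PAHs occupying distinct regions of
    the K-centric parameter space."""

    Tchar_mean: float
    Tchar_sd: float
    thetachar_mean: float
    thetachar_sd: float
    dCp_mean: float
    dCp_sd: float
    beta0: float = 250.0
    phase: str = "SynthPhase"


def generate_database(
    n_per_category: int,
    templates: Dict[str, CategoryTemplate],
    seed: int = 0,
) -> List[DatabaseEntry]:
    """Draw synthetic database entries per category and complete all three
    parameterizations self-consistently."""
    rng = np.random.default_rng(seed)
    entries: List[DatabaseEntry] = []
    for category in sorted(templates):
        tpl = templates[category]
        for i in range(n_per_category):
            kc = KCentricParams(
                Tchar=float(rng.normal(tpl.Tchar_mean, tpl.Tchar_sd)),
                thetachar=float(rng.normal(tpl.thetachar_mean, tpl.thetachar_sd)),
                dCp=float(rng.normal(tpl.dCp_mean, tpl.dCp_sd)),
                beta0=tpl.beta0,
            )
            entry = DatabaseEntry(
                name=f"{category}-{i + 1:03d}",
                phase=tpl.phase,
                phi0=1.0 / (4.0 * tpl.beta0),
                abc=kcentric_to_abc(kc),
                kcentric=kc,
                N=len(DEFAULT_T_GRID_C),
                categories=[category],
                source="synthetic",
            )
            entries.append(complete_entry(entry))
    return entries
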