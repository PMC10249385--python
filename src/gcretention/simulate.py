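"""Temperature-programmed GC separation simulation.

A solute migrates through the column at the local carrier velocity slowed by
its instantaneous retention factor:

    dz/dt = u(z, t) / (1 + k(T(t))),

with u(z, t) from the compressible laminar pressure profile and k evaluated
from the solute's temperature-independent retention parameters at the
program temperature T(t).  The column temperature is spatially uniform.
Integration runs over position (dt/dz = (1 + k)/u) so the domain [0, L] is
fixed; retention time is t(L) and the elution temperature is T(tR).

In constant-flow mode the inlet pressure is recomputed from the carrier
viscosity at T(t) at every step (quasi-static assumption).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import quad, solve_ivp

from .constants import celsius_to_kelvin, kelvin_to_celsius, minutes_to_seconds, seconds_to_minutes
from .flow import ColumnSpec, FlowConditions, viscosity
from .models import KCentricParams, lnk_kcentric

__all__ = [
    "TemperatureProgram",
    "PeakResult",
    "SimulationResult",
    "temperature_at",
    "simulate_retention",
    "simulate_chromatogram",
    "compare_to_measured",
    "ComparisonResult",
]


@dataclass(frozen=True)
class TemperatureProgram:
    """Piecewise linear-with-holds oven program.

    ``segments`` is a list of (ramp rate [°C/min], target T [°C],
    hold time [min]).  The final temperature is held indefinitely, so T(t)
    is defined for all t ≥ 0.
    """

    T_init_C: float
    segments: Tuple[Tuple[float, float, float], ...] = ()

    def __post_init__(self):
        T = self.T_init_C
        for rate, target, hold in self.segments:
            if rate <= 0:
                raise ValueError("ramp rates must be positive")
            if hold < 0:
                raise ValueError("hold times must be non-negative")
            T = target
        object.__setattr__(self, "segments", tuple(tuple(s) for s in self.segments))

    def span_min(self) -> float:
        """Total programmed duration [min] (ramps + holds)."""
        t = 0.0
        T = self.T_init_C
        for rate, target, hold in self.segments:
            t += abs(target - T) / rate + hold
            T = target
        return t


def temperature_at(prog: TemperatureProgram, t_min) -> float:
    """Oven temperature [°C] at time t [min]; continuous and piecewise linear."""
    t = np.asarray(t_min, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    out = np.full_like(t, prog.T_init_C)
    t_seg = np.zeros_like(t)  # start time of the current segment
    T_seg = prog.T_init_C
    for rate, target, hold in prog.segments:
        ramp = abs(target - T_seg) / rate
        sgn = 1.0 if target >= T_seg else -1.0
        dt = t - t_seg
        in_ramp = dt > 0
        out = np.where(in_ramp, np.minimum(np.abs(dt) * rate, abs(target - T_seg)) * sgn + T_seg, out)
        t_seg = t_seg + ramp + hold
        T_seg = target
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class PeakResult:
    name: str
    tR_min: float
    Telu_C: float
    k_elution: float
    eluted: bool = True


@dataclass(frozen=True)
class SimulationResult:
    """Per-compound retention times of a simulated separation.

    ``peaks`` is sorted by retention time; compounds that failed to elute
    within the time limit appear at the end with ``eluted = False``.
    """

    peaks: Tuple[PeakResult, ...]
    diagnostics: Dict[str, dict] = field(default_factory=dict)

    def peak_table(self) -> List[dict]:
        return [
            {
                "name": p.name,
                "tR_min": p.tR_min,
                "Telu_C": p.Telu_C,
                "k_elu": p.k_elution,
                "eluted": p.eluted,
            }
            for p in self.peaks
        ]

    def plot(self, n_plates: float = 1e5, ax=None, label_peaks: bool = True):
        """Render the simulated chromatogram (Gaussian peak shapes)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t, y = simulate_chromatogram(self, n_plates=n_plates)
        ax.plot(t, y, "-")
        if label_peaks:
            for p in self.peaks:
                if p.eluted:
                    ax.annotate(
                        p.name,
                        (p.tR_min, y[np.abs(t - p.tR_min).argmin()]),
                        rotation=90,
                        fontsize=8,
                        ha="center",
                        va="bottom",
                    )
        ax.set_xlabel("time [min]")
        ax.set_ylabel("signal")
        return ax


def _velocity_profile(col: ColumnSpec, p_i: float, p_o: float, eta: float):
    """Local velocity u(z) [m/s] for the parabolic pressure-squared profile."""
    dp2 = p_i**2 - p_o**2

    def u(z):
        p = math.sqrt(max(p_i**2 - dp2 * z / col.L, p_o**2 * 1e-12))
        return (col.d**2 / (32.0 * eta)) * dp2 / (2.0 * col.L * p)

    return u


def simulate_retention(
    params: Dict[str, KCentricParams],
    col: ColumnSpec,
    prog: TemperatureProgram,
    flow: FlowConditions,
    rtol: float = 1e-8,
    max_time_factor: float = 10.0,
    max_time_min: Optional[float] = None,
) -> SimulationResult:
    """Simulate retention times for a set of compounds.

    ``params`` maps compound names to K-centric parameters; each is
    phase-ratio corrected from its own β0 to the column's β = d/(4·df).
    Compounds not eluted within ``max_time_min`` (default
    ``max_time_factor`` × the program span, or × 60 min for an isothermal
    program with no ramps) are flagged rather than raising.
    """
    if max_time_min is None:
        max_time_min = max_time_factor * max(prog.span_min(), 60.0)
    t_max_s = minutes_to_seconds(max_time_min)
    peaks: List[PeakResult] = []
    diagnostics: Dict[str, dict] = {}

    for name, p in params.items():
        def rhs(z, t):
            t_min = seconds_to_minutes(t[0])
            T_C = temperature_at(prog, t_min)
            T = celsius_to_kelvin(T_C)
            k = math.exp(lnk_kcentric(T, p, beta1=col.beta))
            p_i = flow.inlet_pressure(col, T)
            u = _velocity_profile(col, p_i, flow.p_o, viscosity(flow.gas, T))(z)
            return [(1.0 + k) / u]

        def overtime(z, t):
            return t[0] - t_max_s

        overtime.terminal = True
        sol = solve_ivp(
            rhs,
            (0.0, col.L),
            [0.0],
            method="RK45",
            rtol=rtol,
            atol=1e-6,
            events=overtime,
            dense_output=False,
        )
        if not sol.success and sol.status != 1:
            raise RuntimeError(f"solver failure for {name!r}: {sol.message}")
        eluted = sol.status != 1 and sol.t[-1] >= col.L
        diagnostics[name] = {
            "steps": int(sol.t.size),
            "solver_status": int(sol.status),
        }
        if not eluted:
            peaks.append(PeakResult(name, float("inf"), float("nan"), float("nan"), False))
            continue
        tR_s = float(sol.y[0, -1])
        tR_min = seconds_to_minutes(tR_s)
        Telu_C = float(temperature_at(prog, tR_min))
        k_elu = math.exp(lnk_kcentric(celsius_to_kelvin(Telu_C), p, beta1=col.beta))
        peaks.append(PeakResult(name, tR_min, Telu_C, k_elu, True))

    peaks.sort(key=lambda pk: pk.tR_min)
    return SimulationResult(peaks=tuple(peaks), diagnostics=diagnostics)


def simulate_chromatogram(
    result: SimulationResult,
    n_plates: float = 1e5,
    abundances: Optional[Dict[str, float]] = None,
    n_points: int = 5000,
    pad_min: float = 0.5,
) -> Tuple[np.ndarray, np.ndarray]:
    """Render a synthetic chromatogram trace from simulated peaks.

    Gaussian peaks with σ_t = tR/√n_plates, unit area each unless
    ``abundances`` is given.  Returns (time [min], signal) arrays.
    Presentation aid only — no physical peak-shape model is implied.
    """
    eluted = [p for p in result.peaks if p.eluted]
    if not eluted:
        t = np.linspace(0.0, 1.0, n_points)
        return t, np.zeros_like(t)
    t_end = max(p.tR_min for p in eluted) + pad_min
    t = np.linspace(0.0, t_end, n_points)
    signal = np.zeros_like(t)
    for p in eluted:
        sigma = p.tR_min / math.sqrt(n_plates)
        area = abundances.get(p.name, 1.0) if abundances else 1.0
        signal += area / (sigma * math.sqrt(2 * math.pi)) * np.exp(
            -0.5 * ((t - p.tR_min) / sigma) ** 2
        )
    return t, signal


@dataclass(frozen=True)
class ComparisonResult:
    rmse_min: float
    deviations_pct: Dict[str, float]
    matched: Tuple[str, ...]
    unmatched: Tuple[str, ...]


def compare_to_measured(
    predicted: Dict[str, float], measured: Dict[str, float]
) -> ComparisonResult:
    """Root-mean-square error [min] and per-compound % deviation between
    predicted and measured retention times, matched by compound name.

    Compounds present in only one list are reported and excluded from the
    rmse.
    """
    matched = sorted(set(predicted) & set(measured))
    unmatched = sorted(set(predicted) ^ set(measured))
    if not matched:
        return ComparisonResult(float("nan"), {}, (), tuple(unmatched))
    diffs = np.array([predicted[n] - measured[n] for n in matched])
    rmse = float(np.sqrt(np.mean(diffs**2)))
    dev = {
        n: 100.0 * abs(predicted[n] - measured[n]) / measured[n] for n in matched
    }
    return ComparisonResult(rmse, dev, tuple(matched), tuple(unmatched))
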