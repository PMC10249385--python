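"""Estimation of K-centric retention parameters from isothermal measurements.

The measurement model is ln k(T) from the K-centric parameterization plus
additive noise on ln k.  Because the ABC form is linear in its coefficients,
the (weighted) least-squares optimum can be found exactly in ABC space; the
nonlinear K-centric fit is seeded from that solution and its Jacobian-based
covariance yields standard errors directly on (Tchar, θchar, ΔCp).

The module exposes a statsmodels-style pair —
:class:`IsothermalRetentionModel` (built from data, ``fit()`` /
``fit_robust()``) and :class:`RetentionFitResults` (estimates, standard
errors, residuals, outlier indices, ``summary()``) — plus thin functional
wrappers :func:`fit_kcentric` and :func:`robust_fit`.

Robust fitting is a least-trimmed-squares style search: for each candidate
number of outliers m the best size-(n−m) subset is located (exhaustively for
n ≤ 12, by seeded random starts with concentration steps beyond), and the
smallest m whose retained residuals pass a MAD-studentized size test is
selected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .constants import R_GAS, celsius_to_kelvin, T1_K
from .models import (
    ABCParams,
    ConversionDomainError,
    KCentricParams,
    abc_to_kcentric,
    lnk_kcentric,
    retention_factor,
)

__all__ = [
    "IsothermalSeries",
    "FitResult",
    "RetentionFitResults",
    "IsothermalRetentionModel",
    "InsufficientDataError",
    "fit_kcentric",
    "robust_fit",
    "filter_lnk_range",
    "read_isothermal",
    "LNK_RANGE",
]

#: Acceptable ln k range for fitting; points outside are associated with
#: overly broad peaks (high k) or solvent-peak interference (low k).
#: Boundaries inclusive.
LNK_RANGE = (-2.0, 3.5)


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class IsothermalSeries:
    """Per-compound isothermal (T, ln k) measurements.

    Temperatures in kelvin, sorted ascending; ``beta0`` is the phase ratio
    of the column the measurements were made on.
    """

    compound: str
    T: Tuple[float, ...]
    lnk: Tuple[float, ...]
    beta0: float
    cas: str = ""
    phase: str = ""
    provenance: str = ""

    def __post_init__(self):
        if len(self.T) != len(self.lnk):
            raise ValueError("T and lnk must have equal length")
        if len(self.T) < 1:
            raise ValueError("series needs at least one point")
        if any(t <= 0 for t in self.T):
            raise ValueError("temperatures must be positive (kelvin)")
        if self.beta0 <= 0:
            raise ValueError("phase ratio beta0 must be positive")
        if any(b < a for a, b in zip(self.T, self.T[1:])):
            order = np.argsort(np.asarray(self.T), kind="stable")
            object.__setattr__(self, "T", tuple(np.asarray(self.T)[order]))
            object.__setattr__(self, "lnk", tuple(np.asarray(self.lnk)[order]))

    def __len__(self):
        return len(self.T)


def filter_lnk_range(
    series: IsothermalSeries, lo: float = LNK_RANGE[0], hi: float = LNK_RANGE[1]
) -> Tuple[IsothermalSeries, List[int]]:
    """Remove points with ln k outside [lo, hi] (boundaries inclusive).

    Returns the filtered series and the indices (into the input series) of
    the excluded points.
    """
    lnk = np.asarray(series.lnk)
    keep = (lnk >= lo) & (lnk <= hi)
    excluded = [int(i) for i in np.flatnonzero(~keep)]
    if not excluded:
        return series, []
    filtered = replace(
        series,
        T=tuple(np.asarray(series.T)[keep]),
        lnk=tuple(lnk[keep]),
    )
    return filtered, excluded


def _linear_abc_solve(T, lnk, beta0, weights=None) -> ABCParams:
    """Exact (weighted) least-squares solution in the linear ABC basis."""
    T = np.asarray(T, dtype=float)
    y = np.asarray(lnk, dtype=float) + math.log(beta0)  # back to ln K
    X = np.column_stack([np.ones_like(T), 1.0 / T, np.log(T / T1_K)])
    if weights is not None:
        sw = np.sqrt(np.asarray(weights, dtype=float))
        X = X * sw[:, None]
        y = y * sw
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return ABCParams(A=float(coef[0]), B=float(coef[1]), C=float(coef[2]), beta0=beta0)


def _init_kcentric(T, lnk, beta0) -> KCentricParams:
    """Heuristic start: Tchar from the ln k = 0 crossing, θchar = 30 K,
    ΔCp = 100 J/(mol K)."""
    T = np.asarray(T, dtype=float)
    lnk = np.asarray(lnk, dtype=float)
    sign = np.sign(lnk)
    crossing = np.flatnonzero(sign[:-1] * sign[1:] <= 0)
    if crossing.size:
        i = int(crossing[0])
        t0, t1 = T[i], T[i + 1]
        y0, y1 = lnk[i], lnk[i + 1]
        Tchar0 = t0 if y0 == y1 else t0 + (0.0 - y0) * (t1 - t0) / (y1 - y0)
    else:
        Tchar0 = float(T[np.argmin(np.abs(lnk))])
    return KCentricParams(Tchar=float(Tchar0), thetachar=30.0, dCp=100.0, beta0=beta0)


@dataclass
class RetentionFitResults:
    """Results of an isothermal retention fit.

    ``params`` carries the point estimates with the series' β0;
    ``std_errors`` maps parameter names to Jacobian-based standard errors.
    """

    params: KCentricParams
    std_errors: dict
    cov_params: np.ndarray
    residuals: np.ndarray
    N: int
    outliers: List[int] = field(default_factory=list)
    range_excluded: List[int] = field(default_factory=list)
    converged: bool = True
    rss: float = 0.0
    compound: str = ""
    model: Optional["IsothermalRetentionModel"] = None

    @property
    def bse(self) -> dict:
        return self.std_errors

    @property
    def nobs(self) -> int:
        return self.N

    def fittedvalues(self, T) -> np.ndarray:
        return np.asarray(lnk_kcentric(T, self.params))

    def conf_int(self, nsigma: float = 3.0) -> dict:
        est = {
            "Tchar": self.params.Tchar,
            "thetachar": self.params.thetachar,
            "dCp": self.params.dCp,
        }
        return {
            k: (v - nsigma * self.std_errors[k], v + nsigma * self.std_errors[k])
            for k, v in est.items()
        }

    def summary(self) -> str:
        lines = [
            "K-centric retention fit" + (f": {self.compound}" if self.compound else ""),
            f"  N = {self.N}  (range-excluded: {len(self.range_excluded)}, "
            f"outliers: {len(self.outliers)})",
            f"  RSS = {self.rss:.6g}   converged = {self.converged}",
            f"  {'parameter':<12}{'estimate':>14}{'std err':>12}",
        ]
        units = {"Tchar": "K", "thetachar": "K", "dCp": "J/mol/K"}
        for name, value in (
            ("Tchar", self.params.Tchar),
            ("thetachar", self.params.thetachar),
            ("dCp", self.params.dCp),
        ):
            se = self.std_errors.get(name, float("nan"))
            lines.append(f"  {name:<12}{value:>14.4f}{se:>12.4g}  [{units[name]}]")
        lines.append(f"  beta0 = {self.params.beta0:g}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Measured ln k points, the fitted curve, and flagged outliers."""
        import matplotlib.pyplot as plt

        if self.model is None:
            raise ValueError("results carry no model reference to plot from")
        if ax is None:
            _, ax = plt.subplots()
        T_all, y_all = self.model.T, self.model.lnk
        mask = np.ones(len(T_all), dtype=bool)
        mask[self.outliers] = False
        ax.plot(T_all[mask], y_all[mask], "o", label="used")
        if self.outliers:
            ax.plot(T_all[~mask], y_all[~mask], "x", color="crimson", label="outlier")
        grid = np.linspace(T_all.min(), T_all.max(), 200)
        ax.plot(grid, self.fittedvalues(grid), "-", label="K-centric fit")
        ax.set_xlabel("T [K]")
        ax.set_ylabel("ln k")
        if self.compound:
            ax.set_title(self.compound)
        ax.legend()
        return ax


#: Backwards-friendly alias used by the functional interface.
FitResult = RetentionFitResults


class IsothermalRetentionModel:
    """Model object for K-centric retention fits (statsmodels-style).

    Parameters
    ----------
    T, lnk : array-like
        Isothermal measurements: temperatures [K] and ln retention factors.
    beta0 : float
        Phase ratio of the column.
    weights : array-like, optional
        Least-squares weights (default uniform).
    apply_range_filter : bool
        Drop points outside the acceptable ln k range before fitting.
    """

    XTOL = 1e-10
    MAX_NFEV = 800  # ~200 iterations of the trust-region step

    def __init__(
        self,
        T,
        lnk,
        beta0: float,
        weights=None,
        apply_range_filter: bool = True,
        compound: str = "",
    ):
        T = np.asarray(T, dtype=float)
        lnk = np.asarray(lnk, dtype=float)
        if T.shape != lnk.shape or T.ndim != 1:
            raise ValueError("T and lnk must be 1-D arrays of equal length")
        order = np.argsort(T, kind="stable")
        T, lnk = T[order], lnk[order]
        if weights is not None:
            weights = np.asarray(weights, dtype=float)[order]
        self.range_excluded: List[int] = []
        if apply_range_filter:
            keep = (lnk >= LNK_RANGE[0]) & (lnk <= LNK_RANGE[1])
            self.range_excluded = [int(i) for i in np.flatnonzero(~keep)]
            T, lnk = T[keep], lnk[keep]
            if weights is not None:
                weights = weights[keep]
        if len(T) < 3:
            raise InsufficientDataError(
                f"need at least 3 usable points, got {len(T)}"
            )
        self.T = T
        self.lnk = lnk
        self.beta0 = float(beta0)
        self.weights = weights
        self.compound = compound

    @classmethod
    def from_series(cls, series: IsothermalSeries, **kwargs) -> "IsothermalRetentionModel":
        return cls(
            series.T, series.lnk, series.beta0, compound=series.compound, **kwargs
        )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        beta0: Optional[float] = None,
        temperature: str = "T_C",
        lnk: str = "lnk",
        **kwargs,
    ) -> "IsothermalRetentionModel":
        """Build from a dataframe with a temperature column in °C and either
        an ``lnk`` column or (tR_min, tM_min) columns."""
        T = celsius_to_kelvin(df[temperature].to_numpy(dtype=float))
        if lnk in df.columns:
            y = df[lnk].to_numpy(dtype=float)
        elif {"tR_min", "tM_min"} <= set(df.columns):
            y = np.log(
                [
                    retention_factor(tr, tm)
                    for tr, tm in zip(df["tR_min"], df["tM_min"])
                ]
            )
        else:
            raise ValueError("dataframe needs an 'lnk' or 'tR_min'/'tM_min' columns")
        if beta0 is None:
            if "beta0" not in df.columns:
                raise ValueError("beta0 must be given or present as a column")
            beta0 = float(df["beta0"].iloc[0])
        return cls(T, y, beta0, **kwargs)

    # -- plain least squares ------------------------------------------------

    def _residual_fn(self, T, lnk, weights):
        sw = np.sqrt(weights) if weights is not None else None

        def resid(x):
            p = KCentricParams(
                Tchar=x[0], thetachar=x[1], dCp=x[2], beta0=self.beta0
            )
            r = np.asarray(lnk_kcentric(T, p)) - lnk
            return r * sw if sw is not None else r

        return resid

    def _fit_subset(self, idx: Optional[np.ndarray] = None) -> RetentionFitResults:
        if idx is None:
            idx = np.arange(len(self.T))
        T, lnk = self.T[idx], self.lnk[idx]
        w = self.weights[idx] if self.weights is not None else None
        n = len(T)
        if n < 3:
            raise InsufficientDataError("subset too small for a 3-parameter fit")

        try:
            x0p, _ = abc_to_kcentric(_linear_abc_solve(T, lnk, self.beta0, w))
        except ConversionDomainError:
            x0p = _init_kcentric(T, lnk, self.beta0)
        x0 = np.array([x0p.Tchar, x0p.thetachar, x0p.dCp])

        sol = least_squares(
            self._residual_fn(T, lnk, w),
            x0,
            xtol=self.XTOL,
            ftol=self.XTOL,
            gtol=None,
            x_scale=[100.0, 10.0, 100.0],
            max_nfev=self.MAX_NFEV,
        )
        converged = sol.status > 0
        rss = float(2.0 * sol.cost)
        dof = n - 3
        s2 = rss / dof if dof > 0 else 0.0
        JtJ = sol.jac.T @ sol.jac
        try:
            cov = s2 * np.linalg.inv(JtJ)
        except np.linalg.LinAlgError:
            cov = np.full((3, 3), np.nan)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        params = KCentricParams(
            Tchar=float(sol.x[0]),
            thetachar=float(sol.x[1]),
            dCp=float(sol.x[2]),
            beta0=self.beta0,
            err_Tchar=float(se[0]),
            err_thetachar=float(se[1]),
            err_dCp=float(se[2]),
        )
        resid = np.asarray(lnk_kcentric(T, params)) - lnk
        return RetentionFitResults(
            params=params,
            std_errors={"Tchar": float(se[0]), "thetachar": float(se[1]), "dCp": float(se[2])},
            cov_params=cov,
            residuals=resid,
            N=n,
            range_excluded=list(self.range_excluded),
            converged=converged,
            rss=float(resid @ resid),
            compound=self.compound,
            model=self,
        )

    def fit(self) -> RetentionFitResults:
        """Weighted least squares on ln k; standard errors from the Jacobian
        covariance at the optimum."""
        return self._fit_subset()

    # -- robust (trimmed) fit ------------------------------------------------

    #: A subset size is accepted when its residual scale is within this
    #: factor of the best scale over all candidate trim counts.  Trimming
    #: pure noise shrinks the scale only mildly (~0.8x), while removing a
    #: genuine outlier collapses it, so a factor-2 band separates the two.
    SCALE_RATIO = 2.0
    #: Absolute scale floor below which fits are considered exact, so that
    #: noiseless data never triggers spurious trimming.
    SCALE_FLOOR = 1e-8

    def _subset_rss(self, keep: np.ndarray) -> float:
        T, lnk = self.T[keep], self.lnk[keep]
        w = self.weights[keep] if self.weights is not None else None
        abc = _linear_abc_solve(T, lnk, self.beta0, w)
        r = abc.A - math.log(self.beta0) + abc.B / T + abc.C * np.log(T) - lnk
        if w is not None:
            r = r * np.sqrt(w)
        return float(r @ r)

    def _best_subset(self, m: int, rng: np.random.Generator, n_starts: int):
        n = len(self.T)
        keep_size = n - m
        if m == 0:
            return np.arange(n)
        if n <= 12:
            best, best_rss = None, np.inf
            for drop in combinations(range(n), m):
                keep = np.setdiff1d(np.arange(n), drop)
                rss = self._subset_rss(keep)
                if rss < best_rss:
                    best, best_rss = keep, rss
            return best
        # FAST-LTS style: random elemental starts + concentration steps
        best, best_rss = None, np.inf
        for _ in range(n_starts):
            idx = rng.choice(n, size=3, replace=False)
            keep = np.sort(idx)
            for _ in range(25):
                T0, y0 = self.T[keep], self.lnk[keep]
                abc = _linear_abc_solve(T0, y0, self.beta0)
                r_all = (
                    abc.A
                    - math.log(self.beta0)
                    + abc.B / self.T
                    + abc.C * np.log(self.T)
                    - self.lnk
                )
                new_keep = np.sort(np.argsort(np.abs(r_all), kind="stable")[:keep_size])
                if new_keep.size == keep.size and np.array_equal(new_keep, keep):
                    break
                keep = new_keep
            if keep.size >= 3:
                rss = self._subset_rss(keep)
                if rss < best_rss:
                    best, best_rss = keep, rss
        return best

    def fit_robust(
        self,
        max_outliers: Optional[int] = None,
        seed: int = 0,
        n_starts: int = 100,
    ) -> RetentionFitResults:
        """Least-trimmed-squares style fit with outlier identification.

        For every candidate trim count m = 0..max_outliers (default ⌊n/4⌋)
        the best size-(n−m) subset is located — by exhaustive enumeration for
        n ≤ 12, by seeded random starts with concentration steps above — and
        its unbiased residual scale s_m = sqrt(RSS/(n−m−3)) recorded.  The
        smallest m whose scale falls within ``SCALE_RATIO`` of the best
        (or below the absolute floor) is selected: genuine outliers collapse
        the scale when removed, trimming mere noise does not.
        """
        n = len(self.T)
        if n < 4:
            raise InsufficientDataError(
                "robust fitting needs at least 4 points for redundancy"
            )
        if max_outliers is None:
            max_outliers = n // 4
        max_outliers = min(max_outliers, n - 4)
        rng = np.random.default_rng(seed)

        candidates = []  # (m, keep, scale)
        for m in range(max_outliers + 1):
            keep = self._best_subset(m, rng, n_starts)
            if keep is None or len(keep) < 4:
                continue
            rss = self._subset_rss(np.asarray(keep))
            scale = math.sqrt(rss / (len(keep) - 3))
            candidates.append((m, np.asarray(keep), scale))
        if not candidates:
            chosen = np.arange(n)
        else:
            best_scale = min(s for _, _, s in candidates)
            limit = max(self.SCALE_RATIO * best_scale, self.SCALE_FLOOR)
            chosen = next(k for _, k, s in candidates if s <= limit)
        res = self._fit_subset(np.asarray(chosen))
        res.outliers = [int(i) for i in np.setdiff1d(np.arange(n), chosen)]
        return res


# -- functional interface ----------------------------------------------------


def fit_kcentric(
    series: IsothermalSeries,
    weights=None,
    apply_range_filter: bool = True,
) -> RetentionFitResults:
    """Weighted least-squares K-centric fit of an isothermal series."""
    model = IsothermalRetentionModel.from_series(
        series, weights=weights, apply_range_filter=apply_range_filter
    )
    return model.fit()


def robust_fit(
    series: IsothermalSeries,
    max_outliers: Optional[int] = None,
    seed: int = 0,
    apply_range_filter: bool = True,
    n_starts: int = 100,
) -> RetentionFitResults:
    """Robust (trimmed) K-centric fit with outlier identification."""
    model = IsothermalRetentionModel.from_series(
        series, apply_range_filter=apply_range_filter
    )
    return model.fit_robust(max_outliers=max_outliers, seed=seed, n_starts=n_starts)


def read_isothermal(path) -> List[IsothermalSeries]:
    """Read isothermal measurements from delimited text.

    Required columns: compound, T_C and either lnk or (tR_min, tM_min);
    optional: CAS, phase, beta0.  One row per measurement; rows are grouped
    by (compound, phase).
    """
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"compound", "T_C"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"isothermal file missing columns: {sorted(missing)}")
    if "lnk" not in df.columns and not {"tR_min", "tM_min"} <= set(df.columns):
        raise ValueError("isothermal file needs 'lnk' or 'tR_min'+'tM_min' columns")
    out = []
    group_cols = ["compound"] + (["phase"] if "phase" in df.columns else [])
    for key, grp in df.groupby(group_cols, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        T = celsius_to_kelvin(grp["T_C"].to_numpy(dtype=float))
        if "lnk" in grp.columns:
            y = grp["lnk"].to_numpy(dtype=float)
        else:
            y = np.log(
                [
                    retention_factor(float(tr), float(tm))
                    for tr, tm in zip(grp["tR_min"], grp["tM_min"])
                ]
            )
        out.append(
            IsothermalSeries(
                compound=str(key[0]),
                T=tuple(T),
                lnk=tuple(y),
                beta0=float(grp["beta0"].iloc[0]) if "beta0" in grp.columns else 1.0,
                cas=(
                    str(grp["CAS"].iloc[0])
                    if "CAS" in grp.columns and pd.notna(grp["CAS"].iloc[0])
                    else ""
                ),
                phase=str(key[1]) if len(key) > 1 else "",
                provenance=str(path),
            )
        )
    return out
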