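"""Quality criteria for database entries and PCA-based quality control.

An entry is acceptable when all of the following hold:

(a) the fit used at least three measurement points;
(b) the fitted ln k values lie in [-2.0, 3.5] (evaluated at fit time; the
    min/max actually used are recorded on the entry);
(c) 0 < θchar < 100 K — a negative θchar would mean retention *grows* with
    temperature, and empirically θchar stays below 100;
(d) Tchar above absolute zero;
(e) C > 0 — non-positive curvature puts the conversion on the wrong
    Lambert-W branch;
(f) A < 0;
(g) the Lambert-W argument of the ABC → K-centric conversion satisfies
    −1/e < x < 0 with W(x) < −1 (the W₋₁ branch).

Failures are collected without short-circuiting; entries are flagged, never
modified or dropped.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .constants import kelvin_to_celsius
from .fitting import LNK_RANGE
from .dbio import DatabaseEntry
from .models import ConversionDomainError, abc_to_kcentric

__all__ = [
    "ValidationReport",
    "IncompleteEntryError",
    "validate_entry",
    "filter_database",
    "pca_qc",
    "PCAResult",
]


class IncompleteEntryError(ValueError):
    pass


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of validating one entry: ``passed`` iff ``failures`` empty."""

    entry_id: str
    failures: Tuple[Tuple[str, str, float], ...] = ()

    @property
    def passed(self) -> bool:
        return not self.failures

    def letters(self) -> List[str]:
        return [f[0] for f in self.failures]


def validate_entry(entry: DatabaseEntry) -> ValidationReport:
    """Evaluate criteria (a)-(g) on a database entry.

    Requires the ABC and K-centric parameterizations to be populated (use
    :func:`gcretention.dbio.complete_entry` first); K-centric parameters may
    legitimately be absent when the conversion itself failed, which counts
    as a criterion (g) failure.
    """
    if entry.abc is None:
        raise IncompleteEntryError(f"entry {entry.name!r} has no ABC parameters")
    failures: List[Tuple[str, str, float]] = []

    if entry.N is not None and entry.N < 3:
        failures.append(("a", f"only {entry.N} measurement points (minimum 3)", entry.N))

    if entry.lnk_min is not None and entry.lnk_min < LNK_RANGE[0]:
        failures.append(("b", f"ln k minimum {entry.lnk_min:.3g} below {LNK_RANGE[0]}", entry.lnk_min))
    if entry.lnk_max is not None and entry.lnk_max > LNK_RANGE[1]:
        failures.append(("b", f"ln k maximum {entry.lnk_max:.3g} above {LNK_RANGE[1]}", entry.lnk_max))

    kc = entry.kcentric
    if kc is not None:
        if not (0.0 < kc.thetachar < 100.0):
            failures.append(
                ("c", f"thetachar = {kc.thetachar:.4g} K outside (0, 100)", kc.thetachar)
            )
        if kc.Tchar <= 0:
            failures.append(
                ("d", f"Tchar = {kelvin_to_celsius(kc.Tchar):.4g} C at or below absolute zero", kc.Tchar)
            )

    if entry.abc.C <= 0:
        failures.append(("e", f"C = {entry.abc.C:.4g} not positive", entry.abc.C))
    if entry.abc.A >= 0:
        failures.append(("f", f"A = {entry.abc.A:.4g} not negative", entry.abc.A))

    # (g): recompute the conversion diagnostics from the (converted,
    # post-roundtrip) ABC coefficients.
    try:
        _, lam = abc_to_kcentric(entry.abc)
        if lam is not None and not (-1.0 / math.e < lam.x < 0.0 and lam.w < -1.0):
            failures.append(("g", f"Lambert-W argument x = {lam.x:.4g} invalid", lam.x))
    except ConversionDomainError as exc:
        failures.append(("g", str(exc), exc.x if exc.x is not None else float("nan")))

    return ValidationReport(entry_id=f"{entry.name}|{entry.phase}", failures=tuple(failures))


def filter_database(
    entries: Sequence[DatabaseEntry],
) -> Tuple[List[Tuple[DatabaseEntry, ValidationReport]], Counter]:
    """Validate every entry; flag failures in place, delete nothing.

    Returns the (entry, report) pairs and a Counter of failures per
    criterion letter.
    """
    counts: Counter = Counter()
    out = []
    for e in entries:
        report = validate_entry(e)
        if not report.passed:
            reasons = "; ".join(f"({letter}) {msg}" for letter, msg, _ in report.failures)
            if reasons not in e.flag_reason:
                e.add_flag(reasons)
            counts.update(report.letters())
        out.append((e, report))
    return out, counts


@dataclass(frozen=True)
class PCAResult:
    explained_variance_ratio: np.ndarray
    scores: np.ndarray
    components: np.ndarray


def pca_qc(X, standardize: bool = True) -> PCAResult:
    """Principal-component QC of a parameter matrix (rows = entries).

    Columns are standardized to zero mean / unit variance by default —
    required when mixing parameters with incommensurate units such as
    (Tchar, θchar, ΔCp).  Explained-variance fractions sum to one.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least two rows")
    if np.isnan(X).any():
        raise ValueError("missing values not allowed")
    Xc = X - X.mean(axis=0)
    if standardize:
        sd = Xc.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("zero-variance column: degenerate input for PCA")
        Xc = Xc / sd
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    return PCAResult(
        explained_variance_ratio=var / var.sum(),
        scores=U * s,
        components=Vt,
    )
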