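"""Reading, writing, merging, and categorizing retention-parameter databases.

Canonical file format: UTF-8 CSV, comma-separated, period decimal, one
header row.  The reader additionally accepts tab-separated input and
tolerates typographic artifacts common in published tables: Unicode
minus/en-dash signs and thousands separators inside numbers.  Temperatures
(Tchar, Tref) are stored in °C in files and converted to kelvin at the
boundary.

Entries are never deleted on failure — validation problems are recorded in
the ``flag``/``flag_reason`` columns.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .constants import R_GAS, celsius_to_kelvin, kelvin_to_celsius
from .models import (
    ABCParams,
    ConversionDomainError,
    KCentricParams,
    ThermoParams,
    abc_to_kcentric,
    abc_to_thermo,
)

__all__ = [
    "DatabaseEntry",
    "SchemaError",
    "MergeConflictError",
    "DB_COLUMNS",
    "DEFAULT_TREF_C",
    "read_db",
    "write_db",
    "merge_datasets",
    "categorize",
    "complete_entry",
    "entries_to_dataframe",
    "example_db_path",
]

#: Canonical column order of a database file.
DB_COLUMNS = [
    "name",
    "CAS",
    "phase",
    "phi0",
    "A",
    "err_A",
    "B",
    "err_B",
    "C",
    "err_C",
    "Tchar_C",
    "err_Tchar",
    "thetachar",
    "err_thetachar",
    "dCp",
    "err_dCp",
    "dHref",
    "err_dHref",
    "dSref",
    "err_dSref",
    "Tref_C",
    "N",
    "category",
    "source",
    "flag",
    "flag_reason",
]

MANDATORY_COLUMNS = ["name", "phase", "phi0", "A", "B", "C"]

#: Default reference temperature for the thermodynamic parameterization,
#: matching the convention of published retention databases.
DEFAULT_TREF_C = 90.0

_CAS_RE = re.compile(r"^\d{2,7}-\d{2}-\d$")


class SchemaError(ValueError):
    pass


class MergeConflictError(ValueError):
    pass


@dataclass
class DatabaseEntry:
    """One compound/stationary-phase record of the retention database.

    φ0 = 1/(4β) is the dimensionless film thickness; the three
    parameterizations (ABC, K-centric, thermodynamic) describe the same
    ln k(T) curve and are kept mutually consistent by
    :func:`complete_entry`.
    """

    name: str
    phase: str
    phi0: float
    abc: Optional[ABCParams] = None
    kcentric: Optional[KCentricParams] = None
    thermo: Optional[ThermoParams] = None
    cas: str = ""
    N: Optional[int] = None
    categories: List[str] = field(default_factory=list)
    source: str = ""
    flag: bool = False
    flag_reason: str = ""
    lnk_min: Optional[float] = None
    lnk_max: Optional[float] = None

    def __post_init__(self):
        if self.phi0 <= 0:
            raise ValueError("phi0 must be positive")
        if self.cas and not _CAS_RE.match(self.cas):
            raise ValueError(f"malformed CAS number: {self.cas!r}")

    @property
    def beta0(self) -> float:
        return 1.0 / (4.0 * self.phi0)

    def add_flag(self, reason: str) -> None:
        self.flag = True
        self.flag_reason = (
            f"{self.flag_reason}; {reason}" if self.flag_reason else reason
        )

    def key(self) -> Tuple[str, str, float]:
        return (self.cas or self.name, self.phase, self.phi0)


def complete_entry(entry: DatabaseEntry, Tref_C: float = DEFAULT_TREF_C) -> DatabaseEntry:
    """Fill in missing parameterizations from the ABC coefficients.

    Conversion failures (no characteristic temperature exists) flag the
    entry rather than raising; the entry is never modified silently in any
    other way.
    """
    if entry.abc is None:
        raise ValueError("entry has no ABC parameters to complete from")
    if entry.thermo is None:
        entry.thermo = abc_to_thermo(entry.abc, celsius_to_kelvin(Tref_C))
    if entry.kcentric is None:
        try:
            entry.kcentric, _ = abc_to_kcentric(entry.abc)
        except ConversionDomainError as exc:
            entry.add_flag(f"K-centric conversion failed: {exc}")
    return entry


# -- parsing helpers ----------------------------------------------------------

_MINUS_CHARS = "−–—"  # minus sign, en dash, em dash


def _clean_number(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, (int, float)):
        return float(value)
    s = str(value).strip()
    if not s or s.lower() in {"nan", "na", ""}:
        return None
    for ch in _MINUS_CHARS:
        s = s.replace(ch, "-")
    s = s.replace(",", "").replace(" ", "").replace(" ", "")
    return float(s)


def _fmt(value) -> str:
    """Deterministic 6-significant-digit ASCII formatting."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ""
    if isinstance(value, bool):
        return str(value)
    if isinstance(value, int):
        return str(value)
    return f"{value:.6g}"


def read_db(path) -> List[DatabaseEntry]:
    """Read a retention database from delimited text (CSV or TSV)."""
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    df.columns = [c.strip() for c in df.columns]
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"database file missing mandatory columns: {missing}")

    entries: List[DatabaseEntry] = []
    for _, row in df.iterrows():
        def num(col):
            return _clean_number(row[col]) if col in df.columns else None

        parse_warning = ""
        phi0 = None
        try:
            phi0 = num("phi0")
            A, B, C = num("A"), num("B"), num("C")
            if phi0 is None or A is None or B is None or C is None:
                raise ValueError("missing mandatory numeric field")
            beta0 = 1.0 / (4.0 * phi0)
            abc = ABCParams(
                A=A, B=B, C=C, beta0=beta0,
                err_A=num("err_A"), err_B=num("err_B"), err_C=num("err_C"),
            )
        except (ValueError, TypeError) as exc:
            parse_warning = f"parse warning: {exc}"
            abc = None
            if phi0 is None or phi0 <= 0:
                phi0 = 1.0

        kc = None
        th = None
        try:
            tchar_c = num("Tchar_C")
            theta = num("thetachar")
            dcp = num("dCp")
            if tchar_c is not None and theta is not None and dcp is not None:
                kc = KCentricParams(
                    Tchar=celsius_to_kelvin(tchar_c),
                    thetachar=theta,
                    dCp=dcp,
                    beta0=1.0 / (4.0 * phi0),
                    err_Tchar=num("err_Tchar"),
                    err_thetachar=num("err_thetachar"),
                    err_dCp=num("err_dCp"),
                )
            dh, ds = num("dHref"), num("dSref")
            tref_c = num("Tref_C")
            if dh is not None and ds is not None and tref_c is not None:
                th = ThermoParams(
                    dHref=dh, dSref=ds,
                    dCp=dcp if dcp is not None else (abc.C * R_GAS if abc else 0.0),
                    Tref=celsius_to_kelvin(tref_c),
                    err_dHref=num("err_dHref"), err_dSref=num("err_dSref"),
                )
        except (ValueError, TypeError) as exc:
            parse_warning = (
                f"{parse_warning}; {exc}" if parse_warning else f"parse warning: {exc}"
            )

        cas = str(row["CAS"]).strip() if "CAS" in df.columns else ""
        cats = (
            [c.strip() for c in str(row["category"]).split(";") if c.strip()]
            if "category" in df.columns
            else []
        )
        n_raw = num("N")
        entry = DatabaseEntry(
            name=str(row["name"]).strip(),
            phase=str(row["phase"]).strip(),
            phi0=phi0,
            abc=abc,
            kcentric=kc,
            thermo=th,
            cas=cas if _CAS_RE.match(cas) else "",
            N=int(n_raw) if n_raw is not None else None,
            categories=cats,
            source=str(row["source"]).strip() if "source" in df.columns else "",
            flag=str(row.get("flag", "")).strip().lower() in {"true", "1", "yes"},
            flag_reason=str(row.get("flag_reason", "")).strip(),
        )
        if parse_warning:
            entry.add_flag(parse_warning)
        entries.append(entry)
    return entries


def entries_to_dataframe(entries: Sequence[DatabaseEntry]) -> pd.DataFrame:
    rows = []
    for e in entries:
        abc = e.abc
        kc = e.kcentric
        th = e.thermo
        rows.append(
            {
                "name": e.name,
                "CAS": e.cas,
                "phase": e.phase,
                "phi0": _fmt(e.phi0),
                "A": _fmt(abc.A) if abc else "",
                "err_A": _fmt(abc.err_A) if abc else "",
                "B": _fmt(abc.B) if abc else "",
                "err_B": _fmt(abc.err_B) if abc else "",
                "C": _fmt(abc.C) if abc else "",
                "err_C": _fmt(abc.err_C) if abc else "",
                "Tchar_C": _fmt(kelvin_to_celsius(kc.Tchar)) if kc else "",
                "err_Tchar": _fmt(kc.err_Tchar) if kc else "",
                "thetachar": _fmt(kc.thetachar) if kc else "",
                "err_thetachar": _fmt(kc.err_thetachar) if kc else "",
                "dCp": _fmt(kc.dCp) if kc else (_fmt(th.dCp) if th else ""),
                "err_dCp": _fmt(kc.err_dCp) if kc else "",
                "dHref": _fmt(th.dHref) if th else "",
                "err_dHref": _fmt(th.err_dHref) if th else "",
                "dSref": _fmt(th.dSref) if th else "",
                "err_dSref": _fmt(th.err_dSref) if th else "",
                "Tref_C": _fmt(kelvin_to_celsius(th.Tref)) if th else "",
                "N": _fmt(e.N),
                "category": ";".join(e.categories),
                "source": e.source,
                "flag": str(e.flag),
                "flag_reason": e.flag_reason,
            }
        )
    df = pd.DataFrame(rows, columns=DB_COLUMNS)
    return df.sort_values(["phase", "name"], kind="stable").reset_index(drop=True)


def write_db(entries: Sequence[DatabaseEntry], path) -> None:
    """Write entries as canonical CSV: deterministic column order and
    formatting (ASCII minus, no thousands separators, 6 significant digits),
    stable-sorted by (phase, name)."""
    df = entries_to_dataframe(entries)
    df.to_csv(path, index=False, lineterminator="\n")


def merge_datasets(
    datasets: Sequence[Sequence[DatabaseEntry]],
    policy: str = "keep-all-with-source-suffix",
) -> List[DatabaseEntry]:
    """Merge entry sets, resolving duplicates keyed by (CAS-or-name, phase, phi0).

    policy "keep-all-with-source-suffix": duplicates are all retained, their
    names suffixed " A", " B", ... in input order.  policy "prefer-larger-N":
    the entry with the largest N wins; a duplicate group whose members
    disagree on Tref cannot be ranked meaningfully and raises
    :class:`MergeConflictError`.
    """
    if policy not in {"keep-all-with-source-suffix", "prefer-larger-N"}:
        raise ValueError(f"unknown merge policy {policy!r}")
    groups: Dict[Tuple, List[DatabaseEntry]] = {}
    order: List[Tuple] = []
    for ds in datasets:
        for e in ds:
            k = e.key()
            if k not in groups:
                groups[k] = []
                order.append(k)
            groups[k].append(e)

    merged: List[DatabaseEntry] = []
    for k in order:
        group = groups[k]
        if len(group) == 1:
            merged.append(group[0])
            continue
        if policy == "keep-all-with-source-suffix":
            for i, e in enumerate(group):
                suffix = chr(ord("A") + i)
                merged.append(replace_name(e, f"{e.name} {suffix}"))
        else:  # prefer-larger-N
            trefs = {
                round(e.thermo.Tref, 6) for e in group if e.thermo is not None
            }
            if len(trefs) > 1:
                raise MergeConflictError(
                    f"conflicting Tref values {sorted(trefs)} in merge group {k}"
                )
            merged.append(max(group, key=lambda e: (e.N if e.N is not None else -1)))
    return merged


def replace_name(entry: DatabaseEntry, name: str) -> DatabaseEntry:
    out = DatabaseEntry(
        name=name,
        phase=entry.phase,
        phi0=entry.phi0,
        abc=entry.abc,
        kcentric=entry.kcentric,
        thermo=entry.thermo,
        cas=entry.cas,
        N=entry.N,
        categories=list(entry.categories),
        source=entry.source,
        flag=entry.flag,
        flag_reason=entry.flag_reason,
        lnk_min=entry.lnk_min,
        lnk_max=entry.lnk_max,
    )
    return out


def categorize(
    entries: Sequence[DatabaseEntry], rules: Sequence[Tuple[str, str]]
) -> List[DatabaseEntry]:
    """Attach category labels by regex rules on name or CAS.

    ``rules`` — sequence of (pattern, label); patterns are case-insensitive
    regexes matched against the compound name and CAS.  Multiple labels per
    entry are allowed; existing labels are kept.
    """
    compiled = [(re.compile(pat, re.IGNORECASE), label) for pat, label in rules]
    for e in entries:
        for rx, label in compiled:
            if (rx.search(e.name) or (e.cas and rx.search(e.cas))) and label not in e.categories:
                e.categories.append(label)
    return list(entries)


def example_db_path() -> Path:
    """Path of the bundled example retention database (allergenic
    fragrances, triglycerides, PCBs, and PAHs on three columns)."""
    return Path(__file__).parent / "data" / "example_retention_db.csv"
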