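"""Multi-domain trial data model: lossless CSV I/O and a structural diff.

A :class:`Study` is a named collection of domain tables (in the style of
CDISC SDTM domains such as DM, AE, VS, LB) that share a subject key.  All
cell values are held as text so that reading and re-writing a study is an
exact round trip; declared value kinds (``integer``, ``decimal``,
``calendar-date``, ``partial-date``) are used for validation and by the
transform rules, never for silent coercion.  Missing is the empty string.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "VALUE_KINDS",
    "Table",
    "Study",
    "ChangeRecord",
    "StudyError",
    "read_study",
    "write_study",
    "diff_studies",
    "parse_iso_date",
    "is_partial_date",
]

#: Recognised per-variable value kinds.
VALUE_KINDS = ("text", "integer", "decimal", "calendar-date", "partial-date")

_PARTIAL_DATE_RE = re.compile(r"^\d{4}(-\d{2})?$")
_FULL_DATE_RE = re.compile(r"^\d{4}-\d{2}-\d{2}$")


class StudyError(ValueError):
    """Structural error in a study or its configuration."""


def parse_iso_date(value: str) -> _dt.date | None:
    """Parse ``YYYY-MM-DD`` into a date, or None if not a valid calendar date."""
    if not _FULL_DATE_RE.match(value or ""):
        return None
    try:
        return _dt.date.fromisoformat(value)
    except ValueError:
        return None


def is_partial_date(value: str) -> bool:
    """True for ``YYYY`` or ``YYYY-MM`` strings (month 01-12)."""
    if not _PARTIAL_DATE_RE.match(value or ""):
        return False
    if len(value) == 7:
        return 1 <= int(value[5:7]) <= 12
    return True


@dataclass
class Table:
    """One domain table: an ordered set of variables and text-valued records."""

    name: str
    df: pd.DataFrame
    kinds: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cols = list(self.df.columns)
        if len(cols) != len(set(cols)):
            raise StudyError(f"table {self.name!r}: duplicate variable names")
        # normalise to string cells, missing -> ""
        self.df = self.df.astype(object).fillna("").astype(str)
        for var in cols:
            self.kinds.setdefault(var, "text")
        unknown = set(self.kinds) - set(cols)
        if unknown:
            raise StudyError(
                f"table {self.name!r}: kinds declared for unknown variables {sorted(unknown)}"
            )
        bad_kinds = {k: v for k, v in self.kinds.items() if v not in VALUE_KINDS}
        if bad_kinds:
            raise StudyError(f"table {self.name!r}: invalid value kinds {bad_kinds}")

    @property
    def variables(self) -> list[str]:
        return list(self.df.columns)

    @property
    def n_records(self) -> int:
        return len(self.df)

    def values(self, variable: str) -> list[str]:
        return self.df[variable].tolist()

    def copy(self) -> "Table":
        return Table(self.name, self.df.copy(), dict(self.kinds))

    def equals(self, other: "Table") -> bool:
        return (
            self.name == other.name
            and self.variables == other.variables
            and self.df.reset_index(drop=True).equals(other.df.reset_index(drop=True))
        )


@dataclass
class Study:
    """A collection of domain tables sharing a subject key.

    Parameters
    ----------
    tables
        Mapping domain-name -> :class:`Table`.
    subject_key
        Variable naming the subject code; must exist in the subject table.
    subject_table
        Domain holding one row per subject (typically ``DM``).
    site_key
        Variable naming the site code, or None.
    reference_date
        Optional ``(table, variable)`` designating the per-subject reference
        date (for example first-dose date ``("DM", "RFSTDTC")``).
    provenance
        Free-form metadata (source paths, load timestamp, config fingerprint).
    """

    tables: dict[str, Table]
    subject_key: str
    subject_table: str = "DM"
    site_key: str | None = None
    reference_date: tuple[str, str] | None = None
    provenance: dict = field(default_factory=dict)

    def validate(self) -> None:
        """Raise :class:`StudyError` on any violated structural invariant."""
        if self.subject_table not in self.tables:
            raise StudyError(f"subject table {self.subject_table!r} not present")
        subj_tab = self.tables[self.subject_table]
        if self.subject_key not in subj_tab.variables:
            raise StudyError(
                f"subject key {self.subject_key!r} missing from table {self.subject_table!r}"
            )
        known = set(subj_tab.values(self.subject_key))
        if len(known) != subj_tab.n_records:
            raise StudyError(
                f"subject table {self.subject_table!r} has duplicate {self.subject_key!r} values"
            )
        for name, tab in self.tables.items():
            if name == self.subject_table or self.subject_key not in tab.variables:
                continue
            orphans = set(tab.values(self.subject_key)) - known
            if orphans:
                raise StudyError(
                    f"table {name!r} has subjects absent from {self.subject_table!r}: "
                    f"{sorted(orphans)[:5]}"
                )
        if self.reference_date is not None:
            rt, rv = self.reference_date
            if rt not in self.tables or rv not in self.tables[rt].variables:
                raise StudyError(f"reference date variable {rt}.{rv} not present")

    @property
    def subjects(self) -> list[str]:
        return self.tables[self.subject_table].values(self.subject_key)

    def subject_tables(self) -> list[str]:
        """Names of tables that carry the subject key."""
        return [n for n, t in self.tables.items() if self.subject_key in t.variables]

    def copy(self) -> "Study":
        return Study(
            tables={n: t.copy() for n, t in self.tables.items()},
            subject_key=self.subject_key,
            subject_table=self.subject_table,
            site_key=self.site_key,
            reference_date=self.reference_date,
            provenance=dict(self.provenance),
        )

    def equals(self, other: "Study") -> bool:
        if set(self.tables) != set(other.tables):
            return False
        return all(self.tables[n].equals(other.tables[n]) for n in self.tables)


@dataclass(frozen=True)
class ChangeRecord:
    """One structural difference between two studies, at (table, variable)."""

    table: str
    variable: str
    kind: str  # removed | added | unchanged-values-differ


def _check_kind(value: str, kind: str) -> bool:
    """Does a non-missing text value conform to its declared kind?"""
    if value == "" or kind == "text":
        return True
    if kind == "integer":
        return bool(re.match(r"^[+-]?\d+$", value))
    if kind == "decimal":
        try:
            float(value)
            return True
        except ValueError:
            return False
    if kind == "calendar-date":
        return parse_iso_date(value) is not None
    if kind == "partial-date":
        return is_partial_date(value) or parse_iso_date(value) is not None
    return True


def read_study(
    paths: Iterable[str | Path],
    config: Mapping,
    warnings_out: list[str] | None = None,
) -> Study:
    """Load CSV domain files into a validated :class:`Study`.

    ``config`` declares at minimum ``subject_key``; optionally
    ``subject_table``, ``site_key``, ``reference_date: {table, variable}``
    and per-domain variable kinds under ``domains: {NAME: {kinds: {...}}}``.
    Domain names are the upper-cased file stems.  Values that fail their
    declared kind are kept verbatim as text and reported in
    ``warnings_out``, never silently coerced.
    """
    if "subject_key" not in config:
        raise StudyError("config must declare subject_key")
    domains_cfg = config.get("domains", {}) or {}
    tables: dict[str, Table] = {}
    src_paths = []
    for path in paths:
        path = Path(path)
        name = path.stem.upper()
        if name in tables:
            raise StudyError(f"duplicate domain name {name!r}")
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        kinds = dict((domains_cfg.get(name, {}) or {}).get("kinds", {}) or {})
        tables[name] = Table(name, df, kinds)
        src_paths.append(str(path))

    subject_key = config["subject_key"]
    subject_table = config.get("subject_table") or _default_subject_table(tables, subject_key)
    for name, tab in tables.items():
        if name == subject_table and subject_key not in tab.variables:
            raise StudyError(f"subject-key column {subject_key!r} missing from table {name!r}")

    study = Study(
        tables=tables,
        subject_key=subject_key,
        subject_table=subject_table,
        site_key=config.get("site_key"),
        reference_date=_ref_tuple(config.get("reference_date")),
        provenance={"source_paths": src_paths},
    )
    study.validate()

    if warnings_out is not None:
        for name, tab in tables.items():
            for var in tab.variables:
                kind = tab.kinds[var]
                if kind == "text":
                    continue
                for i, val in enumerate(tab.values(var)):
                    if not _check_kind(val, kind):
                        warnings_out.append(
                            f"{name}.{var} row {i}: value {val!r} is not a valid {kind}; kept as text"
                        )
    return study


def _default_subject_table(tables: Mapping[str, Table], subject_key: str) -> str:
    if "DM" in tables:
        return "DM"
    for name, tab in tables.items():
        if subject_key in tab.variables and len(set(tab.values(subject_key))) == tab.n_records:
            return name
    raise StudyError(f"no table qualifies as subject table for key {subject_key!r}")


def _ref_tuple(spec) -> tuple[str, str] | None:
    if spec is None:
        return None
    if isinstance(spec, (tuple, list)):
        return (spec[0], spec[1])
    return (spec["table"], spec["variable"])


def write_study(study: Study, out_dir: str | Path, overwrite: bool = False) -> list[Path]:
    """Write one RFC 4180 CSV per table; returns the written paths.

    ``read_study(write_study(s), ...)`` reproduces ``s`` table for table,
    value for value.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, tab in study.tables.items():
        path = out_dir / f"{name}.csv"
        if path.exists() and not overwrite:
            raise StudyError(f"refusing to overwrite existing file {path}")
        tab.df.to_csv(path, index=False, lineterminator="\n")
        written.append(path)
    return written


def diff_studies(before: Study, after: Study) -> list[ChangeRecord]:
    """Variable-level structural diff used by the quality-control step.

    A ``(table, variable)`` pair appears exactly once iff the variable was
    removed, added, or any of its values differ between the two studies.
    """
    if set(before.tables) != set(after.tables):
        only_before = sorted(set(before.tables) - set(after.tables))
        only_after = sorted(set(after.tables) - set(before.tables))
        raise StudyError(
            f"domain sets differ: only in before={only_before}, only in after={only_after}"
        )
    changes: list[ChangeRecord] = []
    for name in before.tables:
        b, a = before.tables[name], after.tables[name]
        bvars, avars = set(b.variables), set(a.variables)
        for var in b.variables:
            if var not in avars:
                changes.append(ChangeRecord(name, var, "removed"))
        for var in a.variables:
            if var not in bvars:
                changes.append(ChangeRecord(name, var, "added"))
        for var in b.variables:
            if var in avars:
                if b.n_records != a.n_records or b.values(var) != a.values(var):
                    changes.append(ChangeRecord(name, var, "unchanged-values-differ"))
    return changes
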