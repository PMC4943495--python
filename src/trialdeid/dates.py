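"""Date transforms: study days, per-subject offsets, age derivation, season.

Patient-related calendar dates are among the most identifying elements of
trial data.  The default transform replaces each date with its study day
relative to a per-subject reference date under the CDISC SDTM ``--DY``
convention: day 1 is the reference date itself, days before it are
negative and there is no day 0.  The alternative keeps calendar dates but
shifts each subject's dates by one random offset, which preserves every
within-subject interval exactly.  Date of birth is replaced by age in
completed years.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np

from .study import Study, StudyError, is_partial_date, parse_iso_date

__all__ = [
    "ReferenceDateSpec",
    "OffsetPlan",
    "study_day",
    "apply_study_days",
    "offset_dates",
    "derive_age",
    "retain_season",
    "STUDY_DAY_SUFFIX",
]

#: Variables renamed after study-day conversion: ``--DTC`` becomes ``--DY``
#: (the SDTM convention); anything else gains this suffix.
STUDY_DAY_SUFFIX = "_DY"

SEASONS = {12: "DJF", 1: "DJF", 2: "DJF", 3: "MAM", 4: "MAM", 5: "MAM",
           6: "JJA", 7: "JJA", 8: "JJA", 9: "SON", 10: "SON", 11: "SON"}


@dataclass
class ReferenceDateSpec:
    """Where each subject's reference date comes from.

    ``mode="per-subject"`` points at a table+variable (e.g. first-dose date
    in DM); ``mode="trial-level"`` uses one fixed date for everyone.
    ``fallback`` decides what happens when a subject lacks the reference
    date: ``"error"`` aborts, ``"drop-subject-dates"`` blanks that
    subject's dates (logged by callers).
    """

    mode: str = "per-subject"
    table: str | None = None
    variable: str | None = None
    fixed_date: str | None = None
    fallback: str = "error"

    def resolve(self, study: Study) -> dict[str, _dt.date]:
        """Map each subject code to its reference date (absent if missing)."""
        if self.mode == "trial-level":
            d = parse_iso_date(self.fixed_date or "")
            if d is None:
                raise StudyError(f"trial-level reference date {self.fixed_date!r} invalid")
            return {s: d for s in study.subjects}
        if not self.table or not self.variable:
            raise StudyError("per-subject reference needs table and variable")
        tab = study.tables.get(self.table)
        if tab is None or self.variable not in tab.variables:
            raise StudyError(f"reference variable {self.table}.{self.variable} not present")
        out: dict[str, _dt.date] = {}
        for subj, val in zip(tab.values(study.subject_key), tab.values(self.variable)):
            d = parse_iso_date(val)
            if d is not None:
                out[subj] = d
        missing = set(study.subjects) - set(out)
        if missing and self.fallback == "error":
            raise StudyError(
                f"subjects lack a reference date: {sorted(missing)[:5]} "
                "(fallback policy is 'error')"
            )
        return out


@dataclass
class OffsetPlan:
    """Per-subject random day offsets actually applied, plus bookkeeping."""

    offsets: dict[str, int]
    bounds: tuple[int, int]
    constrain_to_trial_range: bool
    seed_fingerprint: str
    fallback_subjects: list[str] = field(default_factory=list)
    trial_range: tuple[str, str] | None = None


def study_day(date: _dt.date | str, reference: _dt.date | str) -> int:
    """Signed study day under the SDTM --DY convention (day 1 = reference,
    no day 0)."""
    d = _coerce_date(date, "date")
    r = _coerce_date(reference, "reference")
    delta = (d - r).days
    return delta + 1 if delta >= 0 else delta


def _coerce_date(value, what: str) -> _dt.date:
    if isinstance(value, _dt.date):
        return value
    if is_partial_date(str(value)):
        raise StudyError(
            f"{what} {value!r} is a partial date; route it through the "
            "partial-date policy, not study_day"
        )
    d = parse_iso_date(str(value))
    if d is None:
        raise StudyError(f"{what} {value!r} is not a valid ISO calendar date")
    return d


def derive_age(dob: _dt.date | str, reference: _dt.date | str) -> int:
    """Age in completed years at the reference date.

    Leap-day births: the birthday is deemed reached on Feb 28 of non-leap
    years.
    """
    b = _coerce_date(dob, "date of birth")
    r = _coerce_date(reference, "reference")
    if b > r:
        raise StudyError(f"date of birth {b} is after reference {r}")
    bm, bd = b.month, b.day
    if bm == 2 and bd == 29 and not _is_leap(r.year):
        bd = 28
    age = r.year - b.year
    if (r.month, r.day) < (bm, bd):
        age -= 1
    return age


def _is_leap(year: int) -> bool:
    return year % 4 == 0 and (year % 100 != 0 or year % 400 == 0)


def _day_variable_name(var: str) -> str:
    if var.upper().endswith("DTC") and len(var) > 3:
        return var[:-3] + "DY"
    return var + STUDY_DAY_SUFFIX


def _impute_partial(value: str, policy: str) -> str | None:
    """Resolve a partial date under the declared imputation policy.

    Returns a full ISO date string, or None when the value must be dropped.
    """
    if policy == "none" or policy == "conservative-drop":
        return None
    if policy == "month-midpoint":
        if len(value) == 7:  # YYYY-MM
            return f"{value}-15"
        if len(value) == 4:  # YYYY -> mid-year
            return f"{value}-07-01"
    raise StudyError(f"unknown partial-date policy {policy!r}")


def apply_study_days(
    study: Study,
    ref: ReferenceDateSpec,
    date_variables: dict[str, list[str]],
    partial_policy: str = "none",
    keep: set[tuple[str, str]] | None = None,
    log: list[dict] | None = None,
) -> Study:
    """Replace calendar-date variables with integer study-day variables.

    ``date_variables`` maps table name -> variables to transform; pairs in
    ``keep`` are left untouched (keep-by-config).  Original date values are
    absent from the output; the new variable takes the SDTM-style ``--DY``
    name.  Partial dates go through ``partial_policy`` and every imputation
    or drop is appended to ``log``.
    """
    keep = keep or set()
    refs = ref.resolve(study)
    out = study.copy()
    for tname, variables in date_variables.items():
        tab = out.tables.get(tname)
        if tab is None:
            raise StudyError(f"table {tname!r} not present")
        if study.subject_key not in tab.variables:
            raise StudyError(f"table {tname!r} lacks subject key; cannot resolve references")
        for var in variables:
            if var not in tab.variables or (tname, var) in keep:
                continue
            subjects = tab.values(study.subject_key)
            new_vals: list[str] = []
            n_imputed = n_dropped = 0
            for subj, val in zip(subjects, tab.values(var)):
                if val == "":
                    new_vals.append("")
                    continue
                if is_partial_date(val):
                    imputed = _impute_partial(val, partial_policy)
                    if imputed is None:
                        new_vals.append("")
                        n_dropped += 1
                        continue
                    val = imputed
                    n_imputed += 1
                d = parse_iso_date(val)
                if d is None or subj not in refs:
                    new_vals.append("")  # unparseable or no reference: blank
                    n_dropped += 1
                    continue
                new_vals.append(str(study_day(d, refs[subj])))
            new_name = _day_variable_name(var)
            tab.df[var] = new_vals
            tab.df.rename(columns={var: new_name}, inplace=True)
            tab.kinds[new_name] = "integer"
            tab.kinds.pop(var, None)
            if log is not None:
                log.append(
                    {
                        "table": tname,
                        "variable": var,
                        "rule": "dates.study_day",
                        "renamed_to": new_name,
                        "imputed_partials": n_imputed,
                        "dropped_values": n_dropped,
                    }
                )
    return out


def offset_dates(
    study: Study,
    seed: int,
    bounds: tuple[int, int],
    date_variables: dict[str, list[str]],
    constrain_to_trial_range: bool = False,
    exclude_zero: bool = True,
    ref: ReferenceDateSpec | None = None,
    log: list[dict] | None = None,
) -> tuple[Study, OffsetPlan]:
    """Shift each subject's dates by one random offset drawn from ``bounds``.

    All of a subject's dates shift identically, so within-subject intervals
    are preserved exactly.  With ``constrain_to_trial_range`` the offset is
    drawn from the exact feasible set keeping every shifted date inside the
    original trial [min, max]; a subject with an empty feasible set falls
    back to the study-day method (when ``ref`` is given) or blanking, with
    a warning, and is listed in the plan.
    """
    lo, hi = bounds
    if lo > hi:
        raise StudyError(f"offset bounds [{lo}, {hi}] are empty")
    rng = np.random.default_rng(seed)

    # collect every subject's parseable dates across targeted variables
    subject_dates: dict[str, list[_dt.date]] = {s: [] for s in study.subjects}
    all_dates: list[_dt.date] = []
    for tname, variables in date_variables.items():
        tab = study.tables[tname]
        for var in variables:
            if var not in tab.variables:
                continue
            for subj, val in zip(tab.values(study.subject_key), tab.values(var)):
                d = parse_iso_date(val)
                if d is not None and subj in subject_dates:
                    subject_dates[subj].append(d)
                    all_dates.append(d)
    trial_lo, trial_hi = (min(all_dates), max(all_dates)) if all_dates else (None, None)

    refs = ref.resolve(study) if ref is not None else {}
    offsets: dict[str, int] = {}
    fallback: list[str] = []
    for subj in sorted(subject_dates):
        dates = subject_dates[subj]
        if not dates:
            continue
        flo, fhi = lo, hi
        if constrain_to_trial_range:
            flo = max(flo, (trial_lo - min(dates)).days)
            fhi = min(fhi, (trial_hi - max(dates)).days)
        choices = [k for k in range(flo, fhi + 1) if not (exclude_zero and k == 0)]
        if not choices:
            warnings.warn(
                f"subject {subj}: no feasible nonzero offset in [{lo},{hi}] "
                "within the trial date range; falling back",
                stacklevel=2,
            )
            fallback.append(subj)
            continue
        offsets[subj] = int(choices[int(rng.integers(0, len(choices)))])

    out = study.copy()
    for tname, variables in date_variables.items():
        tab = out.tables[tname]
        for var in variables:
            if var not in tab.variables:
                continue
            new_vals = []
            for subj, val in zip(tab.values(study.subject_key), tab.values(var)):
                d = parse_iso_date(val)
                if d is None:
                    new_vals.append(val if val == "" else "")
                elif subj in offsets:
                    new_vals.append((d + _dt.timedelta(days=offsets[subj])).isoformat())
                elif subj in refs:  # fallback: study day
                    new_vals.append(str(study_day(d, refs[subj])))
                else:
                    new_vals.append("")
            tab.df[var] = new_vals
            if log is not None:
                log.append({"table": tname, "variable": var, "rule": "dates.offset"})

    plan = OffsetPlan(
        offsets=offsets,
        bounds=(lo, hi),
        constrain_to_trial_range=constrain_to_trial_range,
        seed_fingerprint=hashlib.sha256(f"trialdeid-seed:{seed}".encode()).hexdigest()[:16],
        fallback_subjects=fallback,
        trial_range=(trial_lo.isoformat(), trial_hi.isoformat()) if all_dates else None,
    )
    return out, plan


def retain_season(
    study: Study, table: str, variable: str, granularity: str = "month"
) -> Study:
    """Derive a month (1-12) or meteorological season (DJF/MAM/JJA/SON)
    column from a date variable, for seasonal diseases where calendar
    timing carries scientific value.  The raw date remains subject to the
    date policy separately.
    """
    if granularity not in ("month", "season"):
        raise StudyError(f"unknown granularity {granularity!r}")
    out = study.copy()
    tab = out.tables.get(table)
    if tab is None or variable not in tab.variables:
        raise StudyError(f"variable {table}.{variable} not present")
    new_name = f"{variable}_{granularity.upper()}"
    vals = []
    for val in tab.values(variable):
        month = None
        d = parse_iso_date(val)
        if d is not None:
            month = d.month
        elif is_partial_date(val) and len(val) == 7:
            month = int(val[5:7])
        if month is None:
            vals.append("")
        elif granularity == "month":
            vals.append(str(month))
        else:
            vals.append(SEASONS[month])
    tab.df[new_name] = vals
    tab.kinds[new_name] = "integer" if granularity == "month" else "text"
    return out
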