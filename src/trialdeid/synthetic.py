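"""Synthetic multi-domain trial generator with a ground-truth manifest.

Emulates the data landscape every transform must handle — DM demographics
with planted direct identifiers (names, emails, phone numbers, SSN-like
codes, dates of birth, ZIP codes), AE adverse events pairing free-text
verbatims with dictionary-coded terms, VS/LB visit measurements on a
fixed grid with jitter, and DS disposition including death dates for a
configurable fraction.  The manifest records exactly what was planted
where, so scanner recall, transform completeness and risk metrics are all
checkable against ground truth.  Ages are uniform over 18-95 to exercise
the >89 top-code; fixtures aim at rule boundaries, not clinical realism.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _words as W
from .study import Study, StudyError, Table

__all__ = ["GenOptions", "GroundTruth", "generate_study", "inject_identifiers",
           "default_declarations"]

_TRIAL_START = _dt.date(2020, 1, 1)


@dataclass
class GenOptions:
    """Generation knobs; defaults define the standard fixture conditions."""

    phi_rate: float = 0.1
    phi_families: tuple[str, ...] = ("email", "phone", "ssn-like")
    rare_events: dict[str, int] = field(default_factory=dict)
    death_fraction: float = 0.1
    mean_aes: float = 2.0
    n_visits: int = 4
    pre_reference_history: bool = False


@dataclass
class GroundTruth:
    """What the generator planted, for oracle-style verification."""

    planted: list[tuple[str, str, int, str]] = field(default_factory=list)
    covariates: pd.DataFrame | None = None
    reference_dates: dict[str, str] = field(default_factory=dict)
    rare_event_plan: dict[str, int] = field(default_factory=dict)


def _rand_date(rng, lo: _dt.date, hi: _dt.date) -> _dt.date:
    span = (hi - lo).days
    return lo + _dt.timedelta(days=int(rng.integers(0, span + 1)))


def _make_plant(family: str, rng: np.random.Generator) -> str:
    first = W.FIRST_NAMES[int(rng.integers(0, len(W.FIRST_NAMES)))]
    last = W.LAST_NAMES[int(rng.integers(0, len(W.LAST_NAMES)))]
    if family == "email":
        return f"{first.lower()}.{last.lower()}@example.com"
    if family == "phone":
        return f"({rng.integers(200, 999)}) {rng.integers(100, 999)}-{rng.integers(1000, 9999)}"
    if family == "ssn-like":
        return f"{rng.integers(100, 999)}-{rng.integers(10, 99)}-{rng.integers(1000, 9999)}"
    if family == "date-like":
        return _rand_date(rng, _dt.date(1950, 1, 1), _dt.date(2019, 12, 31)).isoformat()
    if family == "name-like":
        return f"Dr. {first} {last}"
    if family == "url":
        return f"www.clinic-{last.lower()}.example.com"
    if family == "ip":
        return ".".join(str(int(rng.integers(1, 255))) for _ in range(4))
    if family == "zip":
        return f"{rng.integers(10000, 99999)}-{rng.integers(1000, 9999)}"
    raise StudyError(f"unknown plant family {family!r}")


def generate_study(
    n_subjects: int,
    n_sites: int,
    seed: int,
    options: GenOptions | None = None,
) -> tuple[Study, GroundTruth]:
    """Generate a deterministic multi-domain trial with planted identifiers.

    Returns the study (domains DM, AE, VS, LB, DS) and its ground-truth
    manifest.  Identical arguments reproduce identical studies.
    """
    if n_subjects < 1 or n_sites < 1:
        raise StudyError("need at least one subject and one site")
    if n_sites > n_subjects:
        warnings.warn("more sites than subjects; truncating site list", stacklevel=2)
        n_sites = n_subjects
    opts = options or GenOptions()
    rng = np.random.default_rng(seed)

    subjects = [f"P{1001 + i}" for i in range(n_subjects)]
    sites = [f"{101 + j}" for j in range(n_sites)]
    site_country = {s: W.COUNTRIES[j % len(W.COUNTRIES)] for j, s in enumerate(sites)}
    # skew site sizes so pooling rules have rare sites to find
    site_weights = rng.dirichlet(np.ones(n_sites) * 0.8)
    subj_site = [sites[int(i)] for i in rng.choice(n_sites, n_subjects, p=site_weights)]

    ages = rng.integers(18, 96, n_subjects)  # uniform 18-95, exercises the >89 cap
    sexes = rng.choice(["M", "F"], n_subjects)
    races = rng.choice(len(W.RACES), n_subjects, p=[0.55, 0.15, 0.15, 0.05, 0.05, 0.05])
    ethnics = rng.choice(len(W.ETHNICITIES), n_subjects)
    arms = rng.choice(len(W.ARMS), n_subjects)
    heights = np.round(rng.normal(170, 10, n_subjects), 1)
    weights = np.round(rng.normal(75, 15, n_subjects), 1)

    ref_dates = [_rand_date(rng, _TRIAL_START, _dt.date(2020, 6, 30)) for _ in subjects]
    dm_rows = []
    refs: dict[str, str] = {}
    for i, subj in enumerate(subjects):
        ref = ref_dates[i]
        refs[subj] = ref.isoformat()
        dob = ref - _dt.timedelta(days=int(ages[i]) * 365 + int(rng.integers(0, 365)))
        first = W.FIRST_NAMES[int(rng.integers(0, len(W.FIRST_NAMES)))]
        last = W.LAST_NAMES[int(rng.integers(0, len(W.LAST_NAMES)))]
        dm_rows.append(
            {
                "SUBJID": subj,
                "SITEID": subj_site[i],
                "COUNTRY": site_country[subj_site[i]],
                "SUBJNAME": f"{first} {last}",
                "EMAIL": f"{first.lower()}.{last.lower()}@example.com",
                "PHONE": f"({rng.integers(200, 999)}) {rng.integers(100, 999)}-{rng.integers(1000, 9999)}",
                "SSN": f"{rng.integers(100, 999)}-{rng.integers(10, 99)}-{rng.integers(1000, 9999)}",
                "ZIPCODE": f"{rng.integers(10000, 99999)}",
                "BRTHDTC": dob.isoformat(),
                "SEX": str(sexes[i]),
                "RACE": W.RACES[int(races[i])],
                "ETHNIC": W.ETHNICITIES[int(ethnics[i])],
                "HEIGHT": str(heights[i]),
                "WEIGHT": str(weights[i]),
                "ARM": W.ARMS[int(arms[i])],
                "RFSTDTC": ref.isoformat(),
            }
        )

    ae_rows = []
    for i, subj in enumerate(subjects):
        n_ae = int(rng.poisson(opts.mean_aes))
        for k in range(n_ae):
            term_i = int(rng.integers(0, len(W.AE_TERMS)))
            coded, verbatim = W.AE_TERMS[term_i]
            sev = W.SEVERITIES[int(rng.integers(0, len(W.SEVERITIES)))]
            if opts.pre_reference_history and rng.random() < 0.2:
                start = ref_dates[i] - _dt.timedelta(days=int(rng.integers(1, 30)))
            else:
                start = ref_dates[i] + _dt.timedelta(days=int(rng.integers(0, 91)))
            end = start + _dt.timedelta(days=int(rng.integers(0, 15)))
            ae_rows.append(
                {
                    "SUBJID": subj,
                    "AESEQ": str(k + 1),
                    "AETERM": f"{sev} {verbatim}",
                    "AEDECOD": coded,
                    "AESTDTC": start.isoformat(),
                    "AEENDTC": end.isoformat(),
                }
            )
    # planted rare coded terms with exact distinct-subject counts
    for term, count in sorted((opts.rare_events or {}).items()):
        if count > n_subjects:
            raise StudyError(f"rare event {term!r} wants {count} subjects of {n_subjects}")
        chosen = rng.choice(n_subjects, size=count, replace=False)
        for i in sorted(int(c) for c in chosen):
            start = ref_dates[i] + _dt.timedelta(days=int(rng.integers(0, 91)))
            ae_rows.append(
                {
                    "SUBJID": subjects[i],
                    "AESEQ": "99",
                    "AETERM": f"severe reaction ({term.lower()})",
                    "AEDECOD": term,
                    "AESTDTC": start.isoformat(),
                    "AEENDTC": (start + _dt.timedelta(days=7)).isoformat(),
                }
            )

    visit_grid = [0, 14, 28, 56, 84, 112, 140][: opts.n_visits]
    vs_rows, lb_rows = [], []
    for i, subj in enumerate(subjects):
        for v, day in enumerate(visit_grid, start=1):
            jitter = int(rng.integers(-2, 3))
            vdate = ref_dates[i] + _dt.timedelta(days=max(day + jitter, 0))
            vs_rows.append(
                {
                    "SUBJID": subj,
                    "VISITNUM": str(v),
                    "VSDTC": vdate.isoformat(),
                    "VSTESTCD": "SYSBP",
                    "VSORRES": str(int(rng.normal(122, 14))),
                }
            )
            lb_rows.append(
                {
                    "SUBJID": subj,
                    "VISITNUM": str(v),
                    "LBDTC": vdate.isoformat(),
                    "LBTESTCD": "ALT",
                    "LBORRES": str(round(float(np.exp(rng.normal(3.2, 0.4))), 1)),
                }
            )

    ds_rows = []
    died = rng.random(n_subjects) < opts.death_fraction
    for i, subj in enumerate(subjects):
        if died[i]:
            when = ref_dates[i] + _dt.timedelta(days=int(rng.integers(30, 150)))
            ds_rows.append(
                {"SUBJID": subj, "DSTERM": "death", "DSDECOD": "DEATH", "DSSTDTC": when.isoformat()}
            )
        else:
            when = ref_dates[i] + _dt.timedelta(days=int(rng.integers(140, 200)))
            ds_rows.append(
                {"SUBJID": subj, "DSTERM": "completed study", "DSDECOD": "COMPLETED",
                 "DSSTDTC": when.isoformat()}
            )

    date_kinds = {"BRTHDTC": "calendar-date", "RFSTDTC": "calendar-date"}
    tables = {
        "DM": Table("DM", pd.DataFrame(dm_rows), {**date_kinds, "HEIGHT": "decimal",
                                                  "WEIGHT": "decimal"}),
        "AE": Table("AE", pd.DataFrame(ae_rows, columns=["SUBJID", "AESEQ", "AETERM",
                                                         "AEDECOD", "AESTDTC", "AEENDTC"]),
                    {"AESTDTC": "calendar-date", "AEENDTC": "calendar-date", "AESEQ": "integer"}),
        "VS": Table("VS", pd.DataFrame(vs_rows), {"VSDTC": "calendar-date",
                                                  "VISITNUM": "integer", "VSORRES": "decimal"}),
        "LB": Table("LB", pd.DataFrame(lb_rows), {"LBDTC": "calendar-date",
                                                  "VISITNUM": "integer", "LBORRES": "decimal"}),
        "DS": Table("DS", pd.DataFrame(ds_rows), {"DSSTDTC": "calendar-date"}),
    }
    study = Study(
        tables=tables,
        subject_key="SUBJID",
        subject_table="DM",
        site_key="SITEID",
        reference_date=("DM", "RFSTDTC"),
        provenance={"generator": "trialdeid.synthetic", "seed": seed},
    )
    study.validate()

    truth = GroundTruth(
        covariates=pd.DataFrame(
            {
                "SUBJID": subjects,
                "age": [int(a) for a in ages],
                "sex": [str(s) for s in sexes],
                "race": [W.RACES[int(r)] for r in races],
                "site": subj_site,
                "country": [site_country[s] for s in subj_site],
                "arm": [W.ARMS[int(a)] for a in arms],
            }
        ),
        reference_dates=refs,
        rare_event_plan=dict(opts.rare_events or {}),
    )

    if opts.phi_rate > 0 and len(ae_rows) > 0:
        study, delta = inject_identifiers(
            study, opts.phi_rate, list(opts.phi_families), seed=seed + 1
        )
        truth.planted.extend(delta)
    return study, truth


def inject_identifiers(
    study: Study,
    rate: float,
    families: list[str],
    seed: int,
    table: str = "AE",
    variable: str = "AETERM",
) -> tuple[Study, list[tuple[str, str, int, str]]]:
    """Plant identifier-like strings into free-text cells at the given rate.

    Each selected cell gets one plant from a cycling choice of families;
    the returned delta lists the exact (table, variable, row, family)
    coordinates for ground-truth checks.
    """
    if not 0 <= rate <= 1:
        raise StudyError(f"rate must be in [0, 1], got {rate}")
    tab = study.tables.get(table)
    if tab is None or variable not in tab.variables:
        raise StudyError(f"no free-text variable {table}.{variable} to inject into")
    rng = np.random.default_rng(seed)
    out = study.copy()
    vals = out.tables[table].values(variable)
    delta: list[tuple[str, str, int, str]] = []
    for i in range(len(vals)):
        if rng.random() >= rate:
            continue
        family = families[int(rng.integers(0, len(families)))]
        plant = _make_plant(family, rng)
        vals[i] = f"{vals[i]}, contact {plant}" if vals[i] else f"contact {plant}"
        delta.append((table, variable, i, family))
    out.tables[table].df[variable] = vals
    return out, delta


def default_declarations() -> dict:
    """Variable-role declarations matching the generated study layout."""
    return {
        "SUBJID": "subject-identifier",
        "SITEID": "site-identifier",
        "COUNTRY": "quasi-identifier",
        "SUBJNAME": {"role": "other", "registry_code": "A"},
        "EMAIL": {"role": "other", "registry_code": "F"},
        "PHONE": {"role": "other", "registry_code": "D"},
        "SSN": {"role": "other", "registry_code": "G"},
        "ZIPCODE": {"role": "other", "registry_code": "B", "retain_policy": "transform"},
        "BRTHDTC": "date-of-birth",
        "SEX": "quasi-identifier",
        "RACE": "quasi-identifier",
        "ETHNIC": {"role": "quasi-identifier", "retain_policy": "remove"},
        "HEIGHT": "measurement",
        "WEIGHT": "measurement",
        "ARM": "other",
        "RFSTDTC": "calendar-date",
        "AETERM": "verbatim-text",
        "AEDECOD": "coded-term",
        "AESTDTC": "calendar-date",
        "AEENDTC": "calendar-date",
        "VSDTC": "calendar-date",
        "LBDTC": "calendar-date",
        "DSTERM": "verbatim-text",
        "DSDECOD": "coded-term",
        "DSSTDTC": "calendar-date",
        "AESEQ": "other",
        "VISITNUM": "other",
        "VSTESTCD": "coded-term",
        "VSORRES": "measurement",
        "LBTESTCD": "coded-term",
        "LBORRES": "measurement",
    }
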