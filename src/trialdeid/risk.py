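"""Residual re-identification risk metrics.

Subjects are partitioned into equivalence classes by exact equality on a
declared quasi-identifier tuple (age band, sex, site, ...); the minimum
class size is the k-anonymity of the release and size-1 classes are
uniques.  Small-cell screening follows the published rule of thumb:
quasi-identifier cells with population below 100 (small denominators) and
event terms carried by fewer than 3 subjects (small numerators) are
flagged.  Flags are reported, never auto-remediated — blanket removal of
rare events would gut the scientific value of safety data.

Missingness is a category of its own when partitioning: missingness
patterns can themselves identify, so they must be counted, deterministically.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .study import Study, StudyError

__all__ = [
    "QuasiIdentifierSet",
    "RiskReport",
    "SmallCellFlag",
    "equivalence_classes",
    "k_anonymity",
    "flag_small_cells",
    "build_risk_report",
    "DENOM_THRESHOLD",
    "NUMER_THRESHOLD",
]

#: Small-denominator rule: flag quasi-identifier cells with population < 100.
DENOM_THRESHOLD = 100
#: Small-numerator rule: flag event terms carried by 1 or 2 subjects (< 3).
NUMER_THRESHOLD = 3

_MISSING = "<missing>"


@dataclass
class QuasiIdentifierSet:
    """Ordered quasi-identifier variables, each addressed as (table, variable).

    Variables on event-level tables must reduce to one value per subject;
    ``reduce="unique"`` (the default) demands the per-subject value be
    constant and errors otherwise, ``reduce="first"`` takes the first
    occurrence in table order.
    """

    variables: list[tuple[str, str]]
    reduce: str = "unique"

    def project(self, study: Study) -> dict[str, tuple]:
        """One quasi-identifier tuple per subject (missing -> its own value)."""
        subjects = study.subjects
        rows: dict[str, list] = {s: [] for s in subjects}
        for tname, var in self.variables:
            tab = study.tables.get(tname)
            if tab is None or var not in tab.variables:
                raise StudyError(f"quasi-identifier {tname}.{var} not present")
            if study.subject_key not in tab.variables:
                raise StudyError(f"table {tname!r} lacks the subject key")
            per_subj: dict[str, str] = {}
            for subj, val in zip(tab.values(study.subject_key), tab.values(var)):
                val = val if val != "" else _MISSING
                if subj in per_subj:
                    if self.reduce == "first":
                        continue
                    if per_subj[subj] != val:
                        raise StudyError(
                            f"{tname}.{var} is event-level (subject {subj!r} has "
                            "multiple values); declare a reduction rule"
                        )
                per_subj[subj] = val
            for s in subjects:
                rows[s].append(per_subj.get(s, _MISSING))
        return {s: tuple(vals) for s, vals in rows.items()}


@dataclass(frozen=True)
class SmallCellFlag:
    """One flagged small cell, with the observed count and threshold used."""

    kind: str  # "denominator" | "numerator"
    cell: str
    observed: int
    threshold: int


@dataclass
class RiskReport:
    """Equivalence-class profile plus small-cell flags for one release."""

    qi_variables: list[tuple[str, str]]
    class_sizes: list[int]
    k: int
    uniques: int
    n_subjects: int
    flags: list[SmallCellFlag] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "quasi_identifiers": [f"{t}.{v}" for t, v in self.qi_variables],
            "n_subjects": self.n_subjects,
            "n_classes": len(self.class_sizes),
            "class_sizes": sorted(self.class_sizes),
            "k_anonymity": self.k,
            "uniques": self.uniques,
            "flags": [
                {
                    "kind": f.kind,
                    "cell": f.cell,
                    "observed": f.observed,
                    "threshold": f.threshold,
                }
                for f in self.flags
            ],
        }


def equivalence_classes(study: Study, qi: QuasiIdentifierSet) -> list[int]:
    """Sizes of the equivalence classes induced by the quasi-identifier set.

    Subjects with identical quasi-identifier tuples share a class; the
    sizes always sum to the number of subjects.  An empty set yields a
    single class of size n (the vacuous partition).
    """
    proj = qi.project(study)
    return sorted(Counter(proj.values()).values())


def k_anonymity(study: Study, qi: QuasiIdentifierSet) -> int:
    """Minimum equivalence-class size; k=1 means at least one subject is
    unique on the declared quasi-identifiers."""
    if not study.subjects:
        raise StudyError("k-anonymity is undefined for zero subjects")
    return min(equivalence_classes(study, qi))


def flag_small_cells(
    study: Study,
    qi: QuasiIdentifierSet,
    event_vars: list[tuple[str, str]] | None = None,
    denom_threshold: int = DENOM_THRESHOLD,
    numer_threshold: int = NUMER_THRESHOLD,
) -> list[SmallCellFlag]:
    """Flag small denominators and small numerators.

    A denominator flag marks every quasi-identifier combination whose
    subject count is strictly below ``denom_threshold``; a numerator flag
    marks every event term (e.g. a coded adverse-event term) carried by a
    nonzero number of subjects strictly below ``numer_threshold``.
    Counting is distinct subjects, not rows.
    """
    if denom_threshold < 1 or numer_threshold < 1:
        raise StudyError("thresholds must be >= 1")
    flags: list[SmallCellFlag] = []
    proj = qi.project(study)
    for combo, count in sorted(Counter(proj.values()).items()):
        if count < denom_threshold:
            flags.append(
                SmallCellFlag("denominator", "=".join(map(str, combo)) or "<all>", count, denom_threshold)
            )
    for tname, var in event_vars or []:
        tab = study.tables.get(tname)
        if tab is None or var not in tab.variables:
            raise StudyError(f"event variable {tname}.{var} not present")
        term_subjects: dict[str, set] = {}
        for subj, term in zip(tab.values(study.subject_key), tab.values(var)):
            if term != "":
                term_subjects.setdefault(term, set()).add(subj)
        for term, subjs in sorted(term_subjects.items()):
            if 0 < len(subjs) < numer_threshold:
                flags.append(
                    SmallCellFlag("numerator", f"{tname}.{var}={term}", len(subjs), numer_threshold)
                )
    return flags


def build_risk_report(
    study: Study,
    qi: QuasiIdentifierSet,
    event_vars: list[tuple[str, str]] | None = None,
    denom_threshold: int = DENOM_THRESHOLD,
    numer_threshold: int = NUMER_THRESHOLD,
) -> RiskReport:
    """Full risk profile: class sizes, k, uniques, and small-cell flags."""
    sizes = equivalence_classes(study, qi)
    return RiskReport(
        qi_variables=list(qi.variables),
        class_sizes=sizes,
        k=min(sizes) if sizes else 0,
        uniques=sum(1 for s in sizes if s == 1),
        n_subjects=len(study.subjects),
        flags=flag_small_cells(study, qi, event_vars, denom_threshold, numer_threshold),
    )
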