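"""Value-level generalisation rules.

Age top-coding (ages above 89 collapse into a single ``>89`` category, per
the Safe Harbor date rule), fixed-width binning for ages and anthropometry,
race mapping onto the five FDA categories, pooling of rare sites/countries
by distinct-subject count, and ZIP truncation to three leading digits.
These reduce quasi-identifier resolution while keeping analytic utility.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass
from importlib import resources as _res

import yaml

from .study import StudyError, Table

__all__ = [
    "BinSpec",
    "PoolingRule",
    "cap_age",
    "bin_value",
    "map_race",
    "load_race_map",
    "pool_rare_categories",
    "truncate_zip",
    "AGE_CAP",
    "AGE_CAP_LABEL",
    "DEFAULT_MIN_COUNT",
]

#: Safe Harbor age top-code: ages above this collapse to one category.
AGE_CAP = 89
AGE_CAP_LABEL = ">89"
#: Alternative wording for the same set, available via config.
AGE_CAP_LABEL_ALT = "90 or older"
#: Default minimum distinct-subject count below which a category is pooled.
#: No authoritative default exists; 5 is disclosed in every report.
DEFAULT_MIN_COUNT = 5
#: Default age-bin width in years.
DEFAULT_AGE_BIN_WIDTH = 5

_ZIP_RE = re.compile(r"^\d{5}(-?\d{4})?$")


@dataclass
class BinSpec:
    """Fixed-width, left-closed right-open bins over the real line.

    ``label_template`` may use ``{lo}``, ``{hi}`` (exclusive upper edge),
    ``{hi_incl}`` (``hi - 1``, for integer variables) and ``{hi_dec}``
    (``hi - 0.1``, for one-decimal measurements).
    """

    width: float
    anchor: float = 0.0
    label_template: str = "{lo}-{hi_incl}"

    def __post_init__(self) -> None:
        if not (self.width > 0):
            raise StudyError(f"bin width must be positive, got {self.width}")

    def label(self, value: float) -> str:
        k = math.floor((value - self.anchor) / self.width)
        lo = self.anchor + k * self.width
        hi = lo + self.width
        return self.label_template.format(
            lo=_fmt(lo), hi=_fmt(hi), hi_incl=_fmt(hi - 1), hi_dec=_fmt(round(hi - 0.1, 10))
        )


def _fmt(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else str(x)


@dataclass
class PoolingRule:
    """Pool categories observed in fewer than ``min_count`` distinct subjects."""

    variable: str
    min_count: int = DEFAULT_MIN_COUNT
    pooled_label: str = "POOLED"

    def __post_init__(self) -> None:
        if self.min_count < 1:
            raise StudyError("min_count must be >= 1")


def cap_age(age: int | str, cap: int = AGE_CAP, label: str = AGE_CAP_LABEL):
    """Top-code an age: values at or below ``cap`` pass through unchanged,
    values above collapse to ``label``.  Idempotent (an already-capped
    label passes through)."""
    if isinstance(age, str):
        if age == label or age == "":
            return age
        if not re.match(r"^\d+$", age):
            raise StudyError(f"age {age!r} is not a non-negative integer")
        age = int(age)
    if age < 0:
        raise StudyError(f"age must be non-negative, got {age}")
    return age if age <= cap else label


def bin_value(value, spec: BinSpec):
    """Assign a numeric value to its fixed-width bin label.

    Non-finite/unparseable values map to missing (the caller logs them);
    already-binned labels are passed through unchanged rather than
    re-binned."""
    if isinstance(value, str):
        if value == "":
            return ""
        try:
            value = float(value)
        except ValueError:
            return value  # already a label; do not re-bin
    if not math.isfinite(value):
        return ""
    return spec.label(value)


def load_race_map() -> dict:
    text = _res.files("trialdeid.resources").joinpath("race_map.yaml").read_text("utf-8")
    return yaml.safe_load(text)


def map_race(
    value: str,
    mapping: dict | None = None,
    review_out: list[str] | None = None,
) -> str:
    """Map a collected race term onto the five FDA categories (or the
    configured Other/Multiple bucket).  Unmapped terms become missing and
    are appended to the review list — never guessed."""
    mapping = mapping or load_race_map()
    if value == "":
        return ""
    target = mapping["map"].get(value.strip().upper())
    if target is None:
        if review_out is not None:
            review_out.append(value)
        return ""
    return target


def pool_rare_categories(
    table: Table,
    rule: PoolingRule,
    subject_key: str,
) -> tuple[Table, dict[str, str]]:
    """Replace categories held by fewer than ``min_count`` distinct subjects
    with the pooled label.

    Counting is over distinct subjects, not rows: re-identification risk
    attaches to people.  Returns the new table and the total mapping
    old-category -> final-category.
    """
    if rule.variable not in table.variables:
        raise StudyError(f"pooling variable {rule.variable!r} absent from {table.name!r}")
    if subject_key not in table.variables:
        raise StudyError(f"subject key {subject_key!r} absent from {table.name!r}")
    counts: dict[str, set] = {}
    for subj, cat in zip(table.values(subject_key), table.values(rule.variable)):
        counts.setdefault(cat, set()).add(subj)
    mapping = {
        cat: (rule.pooled_label if len(subjs) < rule.min_count else cat)
        for cat, subjs in sorted(counts.items())
    }
    if len(counts) == 1 and list(mapping.values())[0] == rule.pooled_label:
        warnings.warn(
            f"{table.name}.{rule.variable}: pooling the sole category is vacuous",
            stacklevel=2,
        )
    out = table.copy()
    out.df[rule.variable] = [mapping[c] for c in table.values(rule.variable)]
    return out, mapping


def truncate_zip(zip_code: str, retention_permitted: bool, log: list[str] | None = None) -> str:
    """Apply the three-digit ZIP rule: when retention is permitted the first
    three digits are kept and the remainder masked (``021**``); otherwise,
    or for malformed values, the whole value is removed (missing)."""
    if zip_code == "":
        return ""
    if not _ZIP_RE.match(zip_code):
        if log is not None:
            log.append(f"malformed ZIP {zip_code!r} removed")
        return ""
    if not retention_permitted:
        return ""
    return zip_code[:3] + "**"
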