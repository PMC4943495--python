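"""Safe Harbor identifier registry, variable classification, cell scanner.

Classification is declaration-first: the data holder declares each
variable's role and the scanner flags identifier-like values it finds
anywhere, for human review.  The scanner never reclassifies or mutates
data; a conservative bias (prefer a false positive in the review list over
a miss) is deliberate.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources as _res
from typing import Mapping

import yaml

from .study import Study, StudyError, Table

__all__ = [
    "ROLES",
    "RETAIN_POLICIES",
    "RegistryEntry",
    "VariableMeta",
    "ScanFinding",
    "Classification",
    "builtin_registry",
    "safe_harbor_condition",
    "classify_variables",
    "scan_free_values",
    "PATTERN_FAMILIES",
]

ROLES = (
    "subject-identifier",
    "site-identifier",
    "calendar-date",
    "date-of-birth",
    "verbatim-text",
    "coded-term",
    "quasi-identifier",
    "measurement",
    "other",
)

RETAIN_POLICIES = ("remove", "recode", "transform", "generalise", "blank", "keep")

# role -> (hipaa_class, registry_code, default retain policy)
_ROLE_DEFAULTS: dict[str, tuple[str, str | None, str]] = {
    "subject-identifier": ("direct", "R", "recode"),
    "site-identifier": ("indirect", None, "recode"),
    "date-of-birth": ("direct", "C", "transform"),
    "calendar-date": ("direct", "C", "transform"),
    "verbatim-text": ("indirect", None, "remove"),
    "coded-term": ("none", None, "keep"),
    "quasi-identifier": ("indirect", None, "generalise"),
    "measurement": ("none", None, "keep"),
    "other": ("none", None, "keep"),
}


@dataclass(frozen=True)
class RegistryEntry:
    """One Safe Harbor identifier class (codes A-R)."""

    code: str
    label: str
    detection: str  # pattern family or "none"


def _load_registry_resource() -> dict:
    text = _res.files("trialdeid.resources").joinpath("registry.yaml").read_text("utf-8")
    return yaml.safe_load(text)


_REGISTRY_DATA = _load_registry_resource()
_REGISTRY: tuple[RegistryEntry, ...] = tuple(
    RegistryEntry(e["code"], e["label"], e.get("detection", "none"))
    for e in _REGISTRY_DATA["identifiers"]
)


def builtin_registry() -> list[RegistryEntry]:
    """The eighteen Safe Harbor direct-identifier classes, codes A through R."""
    return list(_REGISTRY)


def safe_harbor_condition() -> str:
    """The no-actual-knowledge condition (item S), recorded as an attestation."""
    return _REGISTRY_DATA["safe_harbor_condition"]


@dataclass
class VariableMeta:
    """Role, HIPAA classification and retention policy for one variable."""

    name: str
    role: str = "other"
    hipaa_class: str = "none"  # direct | indirect | none
    registry_code: str | None = None
    retain_policy: str = "keep"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise StudyError(f"variable {self.name!r}: unknown role {self.role!r}")
        if self.retain_policy not in RETAIN_POLICIES:
            raise StudyError(
                f"variable {self.name!r}: unknown retain policy {self.retain_policy!r}"
            )
        if self.registry_code is not None and self.hipaa_class != "direct":
            raise StudyError(
                f"variable {self.name!r}: registry code implies a direct identifier"
            )
        if self.hipaa_class == "direct" and self.retain_policy not in (
            "remove",
            "recode",
            "transform",
        ):
            raise StudyError(
                f"variable {self.name!r}: direct identifiers must be removed, "
                f"recoded or transformed, not {self.retain_policy!r}"
            )


@dataclass
class Classification:
    """Total classification of a study's variables plus the manual-review set."""

    meta: dict[str, VariableMeta]
    needs_review: set[str] = field(default_factory=set)

    def __getitem__(self, name: str) -> VariableMeta:
        return self.meta[name]

    def __contains__(self, name: str) -> bool:
        return name in self.meta

    def __len__(self) -> int:
        return len(self.meta)

    def by_policy(self, policy: str) -> list[VariableMeta]:
        return [m for m in self.meta.values() if m.retain_policy == policy]

    def by_role(self, role: str) -> list[VariableMeta]:
        return [m for m in self.meta.values() if m.role == role]


def classify_variables(study: Study, declarations: Mapping) -> Classification:
    """Assign a :class:`VariableMeta` to every variable in the study.

    ``declarations`` maps variable name to either a role string or a dict
    with keys ``role`` and optional ``registry_code`` / ``retain_policy``
    overrides.  Undeclared variables default to role ``other`` with policy
    ``keep`` and are listed in the needs-manual-review set, since automated
    preparation always leaves some element of manual review to catch
    unexpected identifiers.
    """
    all_vars: dict[str, None] = {}
    for tab in study.tables.values():
        for v in tab.variables:
            all_vars.setdefault(v)
    missing = [v for v in declarations if v not in all_vars]
    if missing:
        raise StudyError(f"declarations name variables not in the study: {sorted(missing)}")

    meta: dict[str, VariableMeta] = {}
    review: set[str] = set()
    for var in all_vars:
        decl = declarations.get(var)
        if decl is None:
            meta[var] = VariableMeta(var)
            review.add(var)
            continue
        if isinstance(decl, str):
            decl = {"role": decl}
        role = decl.get("role", "other")
        if role not in ROLES:
            raise StudyError(f"variable {var!r}: unknown role {role!r}")
        hipaa, code, policy = _ROLE_DEFAULTS[role]
        if "registry_code" in decl and decl["registry_code"] is not None:
            code = str(decl["registry_code"]).upper()
            if code not in {e.code for e in _REGISTRY}:
                raise StudyError(f"variable {var!r}: unknown registry code {code!r}")
            hipaa = "direct"
            if policy not in ("remove", "recode", "transform"):
                policy = "remove"
        policy = decl.get("retain_policy", policy)
        meta[var] = VariableMeta(var, role, hipaa, code, policy)
    return Classification(meta, review)


# --- cell-level scanner -----------------------------------------------------

@dataclass(frozen=True)
class ScanFinding:
    """An identifier-like value detected inside a cell."""

    table: str
    variable: str
    record_index: int
    pattern_family: str
    span: tuple[int, int]
    registry_code: str
    matched_text: str


# Pattern families are conservative, documented regular expressions.  A fax
# number is textually indistinguishable from a telephone number, so both
# plants map to the phone family (registry code D).
PATTERN_FAMILIES: dict[str, tuple[str, re.Pattern]] = {
    "email": ("F", re.compile(r"[A-Za-z0-9._%+-]+@[A-Za-z0-9.-]+\.[A-Za-z]{2,}")),
    "phone": (
        "D",
        re.compile(r"(?<![\d-])(?:\+?1[-.\s])?\(?\d{3}\)?[-.\s]\d{3}[-.\s]\d{4}(?![\d-])"),
    ),
    "url": ("N", re.compile(r"(?:https?://|www\.)[^\s,;\"']+")),
    "ip": ("O", re.compile(r"(?<![\d.])(?:\d{1,3}\.){3}\d{1,3}(?![\d.])")),
    "ssn-like": ("G", re.compile(r"(?<![\d-])\d{3}-\d{2}-\d{4}(?![\d-])")),
    "zip": ("B", re.compile(r"(?<![\d-])\d{5}-\d{4}(?![\d-])|^\d{5}$")),
    "date-like": ("C", re.compile(r"(?<![\d-])\d{4}-\d{2}-\d{2}(?![\d-])")),
}


def scan_free_values(table: Table, variables: list[str] | None = None) -> list[ScanFinding]:
    """Test every cell against the detection pattern families.

    Deterministic for fixed input: variables in table order, rows in order,
    families in registry order.  The scanner reports; it never mutates.
    """
    findings: list[ScanFinding] = []
    cols = table.variables if variables is None else variables
    for var in cols:
        for i, cell in enumerate(table.values(var)):
            if not cell:
                continue
            claimed: list[tuple[int, int]] = []
            for family, (code, pat) in PATTERN_FAMILIES.items():
                for m in pat.finditer(cell):
                    span = m.span()
                    if any(span[0] < e and s < span[1] for s, e in claimed):
                        continue  # earlier family already claimed this text
                    claimed.append(span)
                    findings.append(
                        ScanFinding(table.name, var, i, family, span, code, m.group())
                    )
    return findings


def findings_to_rows(findings: list[ScanFinding]) -> list[dict]:
    """Flatten findings for CSV/JSON export (review list)."""
    return [
        {
            "table": f.table,
            "variable": f.variable,
            "record_index": f.record_index,
            "pattern_family": f.pattern_family,
            "start": f.span[0],
            "end": f.span[1],
            "registry_code": f.registry_code,
            "matched_text": f.matched_text,
        }
        for f in findings
    ]
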