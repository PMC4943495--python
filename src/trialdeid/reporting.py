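"""Transformation report and the adversarial quality-control step.

The report documents, per table, the variables removed or altered and how
— researchers receive it in place of the original dataset specification.
QC is deliberately separate from the transform: it compares input to
output directly (never trusting the log), verifies every rule family took
effect, and verifies the log covers every observed change (no silent
edits).  Any ``fail`` finding must make the run exit nonzero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .registry import Classification, scan_free_values, safe_harbor_condition
from .risk import RiskReport
from .study import Study, diff_studies, parse_iso_date

__all__ = ["TransformLog", "QCFinding", "build_report", "render_markdown", "qc_verify"]


@dataclass
class TransformLog:
    """Ordered, machine-readable record of every rule applied."""

    entries: list[dict] = field(default_factory=list)

    def add(self, table: str, variable: str, rule: str, **details) -> None:
        self.entries.append({"table": table, "variable": variable, "rule": rule, **details})

    def extend(self, entries: list[dict]) -> None:
        self.entries.extend(entries)

    def covered_pairs(self) -> set[tuple[str, str]]:
        """(table, variable) pairs the log accounts for, including renames
        and whole-table entries (variable ``*``)."""
        pairs: set[tuple[str, str]] = set()
        for e in self.entries:
            pairs.add((e["table"], e["variable"]))
            if e.get("renamed_to"):
                pairs.add((e["table"], e["renamed_to"]))
            if e.get("derived"):
                pairs.add((e["table"], e["derived"]))
        return pairs

    def rules_for(self, table: str, variable: str) -> list[str]:
        return [
            e["rule"]
            for e in self.entries
            if e["table"] == table and e["variable"] in (variable, "*")
        ]


@dataclass(frozen=True)
class QCFinding:
    check_id: str
    severity: str  # fail | warn | info
    message: str
    location: str = ""


def build_report(
    log: TransformLog,
    risk: RiskReport | None = None,
    subset_note: str | None = None,
    meta: dict | None = None,
    timestamp: str = "",
) -> dict:
    """Assemble the machine-readable transformation report.

    Deterministic for a fixed log (timestamps are pinned by the caller).
    The Markdown rendering (:func:`render_markdown`) derives from the same
    object, so the two forms can never disagree.
    """
    by_table: dict[str, list[dict]] = {}
    for e in log.entries:
        by_table.setdefault(e["table"], []).append(
            {k: v for k, v in e.items() if k != "table"}
        )
    report = {
        "generated": timestamp,
        "n_transformations": len(log.entries),
        "tables": by_table,
        "risk": risk.to_dict() if risk is not None else None,
        "subset_note": subset_note,
        "meta": meta or {},
        "attestation": safe_harbor_condition(),
        "warnings": [] if log.entries else ["empty run: zero transformations applied"],
    }
    return report


def render_markdown(report: dict) -> str:
    """Human-readable rendering of :func:`build_report` output."""
    lines = ["# De-identification report", ""]
    if report.get("generated"):
        lines.append(f"Generated: {report['generated']}")
        lines.append("")
    for w in report.get("warnings", []):
        lines.append(f"> **Warning:** {w}")
        lines.append("")
    lines.append(f"Total transformations applied: {report['n_transformations']}")
    lines.append("")
    for table, entries in report["tables"].items():
        lines.append(f"## Table {table}")
        lines.append("")
        for e in entries:
            detail = ", ".join(
                f"{k}={v}" for k, v in e.items() if k not in ("variable", "rule") and v not in (None, "")
            )
            lines.append(f"- `{e['variable']}` — {e['rule']}" + (f" ({detail})" if detail else ""))
        lines.append("")
    risk = report.get("risk")
    if risk:
        lines.append("## Residual risk")
        lines.append("")
        lines.append(
            f"Quasi-identifiers: {', '.join(risk['quasi_identifiers'])} — "
            f"{risk['n_subjects']} subjects in {risk['n_classes']} classes; "
            f"k-anonymity = {risk['k_anonymity']}, uniques = {risk['uniques']}."
        )
        if risk["flags"]:
            lines.append("")
            lines.append("Small-cell flags (reported, not auto-remediated):")
            for f in risk["flags"]:
                lines.append(
                    f"- {f['kind']}: {f['cell']} (observed {f['observed']} < {f['threshold']})"
                )
        lines.append("")
    if report.get("subset_note"):
        lines.append("## Subset of data shared")
        lines.append("")
        lines.append(report["subset_note"])
        lines.append("")
    meta = report.get("meta") or {}
    if meta:
        lines.append("## Parameters")
        lines.append("")
        for k, v in meta.items():
            lines.append(f"- {k}: {json.dumps(v) if not isinstance(v, str) else v}")
        lines.append("")
    lines.append("## Attestation")
    lines.append("")
    lines.append(report["attestation"])
    lines.append("")
    return "\n".join(lines)


def qc_verify(
    original: Study,
    deidentified: Study,
    classification: Classification,
    log: TransformLog,
) -> list[QCFinding]:
    """Adversarial verification that the de-identification took effect.

    Checks: (a) no direct identifier survives unchanged; (b) no raw
    calendar dates remain in study-day-transformed variables; (c) subject
    codes are fully recoded (zero overlap with originals); (d) verbatim
    targets are absent, blank, or scanner-clean after review; (e) every
    observed difference is covered by the log.  Findings, not exceptions.
    """
    findings: list[QCFinding] = []

    # restrict to shared domains; dropped domains must be logged
    shared = set(original.tables) & set(deidentified.tables)
    for name in set(original.tables) - shared:
        if (name, "*") not in log.covered_pairs():
            findings.append(
                QCFinding("e", "fail", f"table {name} dropped but not logged", name)
            )

    def _orig_sub(names):
        return {n: original.tables[n] for n in names}

    # (a) direct identifiers must not survive unchanged
    n_a = 0
    for meta in classification.meta.values():
        if meta.hipaa_class != "direct":
            continue
        for tname in shared:
            otab, dtab = original.tables[tname], deidentified.tables[tname]
            if meta.name not in otab.variables:
                continue
            if meta.name in dtab.variables and any(v != "" for v in otab.values(meta.name)):
                if otab.values(meta.name) == dtab.values(meta.name):
                    n_a += 1
                    findings.append(
                        QCFinding(
                            "a",
                            "fail",
                            f"direct identifier {meta.name} survives unchanged",
                            f"{tname}.{meta.name}",
                        )
                    )
    if n_a == 0:
        findings.append(QCFinding("a", "info", "no direct identifier survives unchanged"))

    # (b) no raw ISO dates in study-day-transformed variables
    n_b = 0
    for e in log.entries:
        if e["rule"] != "dates.study_day":
            continue
        tname, new_var = e["table"], e.get("renamed_to", e["variable"])
        dtab = deidentified.tables.get(tname)
        if dtab is None:
            continue
        if e["variable"] in dtab.variables and e["variable"] != new_var:
            n_b += 1
            findings.append(
                QCFinding("b", "fail", f"original date variable still present", f"{tname}.{e['variable']}")
            )
        if new_var in dtab.variables:
            bad = [v for v in dtab.values(new_var) if parse_iso_date(v) is not None]
            if bad:
                n_b += 1
                findings.append(
                    QCFinding(
                        "b",
                        "fail",
                        f"{len(bad)} raw calendar dates remain after study-day transform",
                        f"{tname}.{new_var}",
                    )
                )
    # date-classified variables never transformed at all
    for meta in classification.meta.values():
        if meta.role not in ("calendar-date", "date-of-birth"):
            continue
        for tname in shared:
            dtab = deidentified.tables[tname]
            if meta.name in dtab.variables and not log.rules_for(tname, meta.name):
                if any(parse_iso_date(v) is not None for v in dtab.values(meta.name)):
                    n_b += 1
                    findings.append(
                        QCFinding(
                            "b",
                            "fail",
                            f"date variable {meta.name} left untransformed",
                            f"{tname}.{meta.name}",
                        )
                    )
    if n_b == 0:
        findings.append(QCFinding("b", "info", "no raw dates remain in transformed variables"))

    # (c) subject codes fully recoded
    old_codes = set(original.subjects)
    n_c = 0
    for tname in shared:
        dtab = deidentified.tables[tname]
        key = deidentified.subject_key
        if key in dtab.variables:
            overlap = old_codes & set(dtab.values(key))
            if overlap:
                n_c += 1
                findings.append(
                    QCFinding(
                        "c",
                        "fail",
                        f"{len(overlap)} original subject codes remain (e.g. {sorted(overlap)[:3]})",
                        f"{tname}.{key}",
                    )
                )
    if n_c == 0:
        findings.append(QCFinding("c", "info", "subject codes fully recoded"))

    # (d) verbatim targets absent, blank, or scanner-clean
    n_d = 0
    for meta in classification.by_role("verbatim-text"):
        for tname in shared:
            otab, dtab = original.tables[tname], deidentified.tables[tname]
            if meta.name not in otab.variables or meta.name not in dtab.variables:
                continue
            nonblank = any(v != "" for v in dtab.values(meta.name))
            reviewed = any(r == "scrub.review" for r in log.rules_for(tname, meta.name))
            if nonblank and not reviewed:
                n_d += 1
                findings.append(
                    QCFinding(
                        "d",
                        "fail",
                        f"verbatim variable {meta.name} still populated",
                        f"{tname}.{meta.name}",
                    )
                )
            elif nonblank and reviewed:
                leftover = scan_free_values(dtab, [meta.name])
                if leftover:
                    n_d += 1
                    findings.append(
                        QCFinding(
                            "d",
                            "fail",
                            f"{len(leftover)} scanner findings survive review scrub",
                            f"{tname}.{meta.name}",
                        )
                    )
    if n_d == 0:
        findings.append(QCFinding("d", "info", "verbatim targets absent, blank or clean"))

    # (e) every observed change covered by the log
    sub_orig = Study(
        tables=_orig_sub(shared),
        subject_key=original.subject_key,
        subject_table=original.subject_table,
        site_key=original.site_key,
    )
    sub_deid = Study(
        tables={n: deidentified.tables[n] for n in shared},
        subject_key=deidentified.subject_key,
        subject_table=deidentified.subject_table,
        site_key=deidentified.site_key,
    )
    covered = log.covered_pairs()
    n_e = 0
    for change in diff_studies(sub_orig, sub_deid):
        if (change.table, change.variable) not in covered and (change.table, "*") not in covered:
            n_e += 1
            findings.append(
                QCFinding(
                    "e",
                    "fail",
                    f"unlogged change ({change.kind})",
                    f"{change.table}.{change.variable}",
                )
            )
    if n_e == 0:
        findings.append(QCFinding("e", "info", "every observed change is covered by the log"))

    return findings
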