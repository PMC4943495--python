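"""Verbatim free-text scrubbing.

Free-text fields (adverse-event verbatims, medical history, general
comments) can carry names, dates and other personal information, so by
default they are dropped outright while their dictionary-coded
counterparts (e.g. the MedDRA preferred term) are retained untouched.
``blank-values`` keeps the column shape; ``review`` is the conservative
middle ground — run the cell scanner and blank only the cells with
findings, emitting a review report.
"""

from __future__ import annotations

from dataclasses import dataclass

from .registry import ScanFinding, scan_free_values
from .study import StudyError, Table

__all__ = ["ScrubPolicy", "scrub_verbatim"]

MODES = ("drop-variable", "blank-values", "review")


@dataclass
class ScrubPolicy:
    """How one verbatim variable is scrubbed.

    ``coded_counterpart`` names the dictionary-coded variable that must be
    retained; naming one that does not exist is a hard error so the only
    usable term is never lost.
    """

    mode: str = "drop-variable"
    coded_counterpart: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise StudyError(f"unknown scrub mode {self.mode!r}")


def scrub_verbatim(
    table: Table,
    targets: dict[str, ScrubPolicy],
    log: list[dict] | None = None,
    review_out: list[ScanFinding] | None = None,
) -> Table:
    """Apply scrub policies to a table's verbatim variables.

    Coded counterparts are verified present and pass through byte-identical.
    Every action (including per-cell blanking in review mode) is appended
    to ``log``.
    """
    for var, policy in targets.items():
        if var not in table.variables:
            raise StudyError(f"scrub target {var!r} absent from table {table.name!r}")
        if policy.coded_counterpart and policy.coded_counterpart not in table.variables:
            raise StudyError(
                f"coded counterpart {policy.coded_counterpart!r} of {var!r} absent "
                f"from table {table.name!r} — refusing to drop the only usable term"
            )
    out = table.copy()
    for var, policy in targets.items():
        if policy.mode == "drop-variable":
            out.df.drop(columns=[var], inplace=True)
            out.kinds.pop(var, None)
            action = {"action": "dropped", "n_affected": table.n_records}
        elif policy.mode == "blank-values":
            n = sum(1 for v in out.values(var) if v != "")
            out.df[var] = ""
            action = {"action": "blanked", "n_affected": n}
        else:  # review: blank only cells with scanner findings
            findings = scan_free_values(table, [var])
            if review_out is not None:
                review_out.extend(findings)
            rows = sorted({f.record_index for f in findings})
            vals = out.values(var)
            for i in rows:
                vals[i] = ""
            out.df[var] = vals
            action = {"action": "review-blanked", "n_affected": len(rows)}
        if log is not None:
            log.append(
                {
                    "table": table.name,
                    "variable": var,
                    "rule": f"scrub.{policy.mode}",
                    "coded_counterpart": policy.coded_counterpart,
                    **action,
                }
            )
    return out
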