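"""Consistent random re-coding of subject and site identifiers.

New codes are drawn as a uniformly random injection into a template space
(never derived from the old code — hashed codes are dictionary-attackable
and would make the new identifier depend on record content).  The mapping
is applied consistently to every table carrying the key, so links across
domains and extension studies survive.  The code key is the only route
back to the originals; it is stored where the caller designates, or
destroyed, with an attestation either way.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .study import Study, StudyError

__all__ = ["CodeKey", "remap_subjects", "remap_sites", "destroy_key"]

DEFAULT_SUBJECT_TEMPLATE = "S#####"
DEFAULT_SITE_TEMPLATE = "SITE###"


def _fingerprint(seed: int) -> str:
    return hashlib.sha256(f"trialdeid-seed:{seed}".encode()).hexdigest()[:16]


def _utcnow() -> str:
    return _dt.datetime.now(_dt.timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")


@dataclass
class CodeKey:
    """Old-code -> new-code mapping with lifecycle status and attestation."""

    scope: str  # "subject" | "site"
    entries: dict[str, str]
    seed_fingerprint: str
    status: str = "active"  # active | destroyed
    attestation: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.status == "destroyed":
            if self.entries:
                raise StudyError("destroyed code key must have no entries")
            return
        news = list(self.entries.values())
        if len(set(news)) != len(news):
            raise StudyError("code key entries must be injective")
        overlap = set(self.entries) & set(news)
        if overlap:
            raise StudyError(f"new codes collide with old codes: {sorted(overlap)[:5]}")

    def to_dict(self) -> dict:
        return {
            "scope": self.scope,
            "entries": dict(self.entries),
            "seed_fingerprint": self.seed_fingerprint,
            "status": self.status,
            "attestation": list(self.attestation),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n", "utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "CodeKey":
        d = json.loads(Path(path).read_text("utf-8"))
        return cls(d["scope"], d["entries"], d["seed_fingerprint"], d["status"], d["attestation"])


def _template_size(template: str) -> int:
    n_digits = template.count("#")
    if n_digits == 0:
        raise StudyError(f"code template {template!r} has no '#' slots")
    return 10 ** n_digits


def _render(template: str, number: int) -> str:
    digits = f"{number:0{template.count('#')}d}"
    out, i = [], 0
    for ch in template:
        if ch == "#":
            out.append(digits[i])
            i += 1
        else:
            out.append(ch)
    return "".join(out)


def _draw_codes(
    old_codes: list[str],
    template: str,
    rng: np.random.Generator,
    extra_forbidden: set[str] | None = None,
) -> dict[str, str]:
    """Uniform random injection old -> template space, avoiding old codes."""
    space = _template_size(template)
    forbidden = set(old_codes) | (extra_forbidden or set())
    n = len(old_codes)
    # count forbidden codes that live inside the template space
    n_forbidden_in_space = sum(1 for c in forbidden if _in_space(c, template))
    if n > space - n_forbidden_in_space:
        raise StudyError(
            f"code template {template!r} offers {space} codes for {n} entries; "
            "use a template with more '#' slots"
        )
    chosen: set[str] = set()
    out: dict[str, str] = {}
    for old in sorted(old_codes):
        while True:
            code = _render(template, int(rng.integers(0, space)))
            if code not in chosen and code not in forbidden:
                chosen.add(code)
                out[old] = code
                break
    return out


def _in_space(code: str, template: str) -> bool:
    if len(code) != len(template):
        return False
    return all(
        (t == "#" and c.isdigit()) or (t != "#" and c == t)
        for c, t in zip(code, template)
    )


def _apply_mapping(study: Study, key_var: str, mapping: dict[str, str]) -> Study:
    out = study.copy()
    for tab in out.tables.values():
        if key_var in tab.variables:
            tab.df[key_var] = [mapping.get(v, v) for v in tab.values(key_var)]
    return out


def remap_subjects(
    study: Study,
    seed: int,
    template: str = DEFAULT_SUBJECT_TEMPLATE,
    prior_key: CodeKey | None = None,
    timestamp: str | None = None,
) -> tuple[Study, CodeKey]:
    """Replace every subject code, in every table, with a random new code.

    The same old code maps to the same new code everywhere; the assignment
    is a uniformly random injection given the seed and carries no
    information from the records.  A ``prior_key`` (e.g. from the parent of
    an extension study) pins codes already mapped; only new subjects draw
    fresh codes.
    """
    if study.subject_key is None:
        raise StudyError("study has no subject key")
    old = study.subjects
    if any(c == "" for c in old):
        raise StudyError("missing subject codes cannot be re-coded")
    return _remap(study, study.subject_key, "subject", old, seed, template, prior_key, timestamp)


def remap_sites(
    study: Study,
    seed: int,
    template: str = DEFAULT_SITE_TEMPLATE,
    prior_key: CodeKey | None = None,
    timestamp: str | None = None,
) -> tuple[Study, CodeKey]:
    """As :func:`remap_subjects`, at site scope.  Pooling of small sites is a
    separate generalisation step; this only randomises the codes."""
    if study.site_key is None:
        raise StudyError("study has no site key")
    old: list[str] = []
    for tab in study.tables.values():
        if study.site_key in tab.variables:
            for v in tab.values(study.site_key):
                if v and v not in old:
                    old.append(v)
    return _remap(study, study.site_key, "site", old, seed, template, prior_key, timestamp)


def _remap(study, key_var, scope, old_codes, seed, template, prior_key, timestamp):
    if prior_key is not None:
        if prior_key.status != "active":
            raise StudyError("prior code key has been destroyed and cannot seed a remap")
        if prior_key.scope != scope:
            raise StudyError(f"prior key scope {prior_key.scope!r} != {scope!r}")
    rng = np.random.default_rng(seed)
    mapping: dict[str, str] = {}
    fresh = []
    for c in old_codes:
        if prior_key is not None and c in prior_key.entries:
            mapping[c] = prior_key.entries[c]
        else:
            fresh.append(c)
    drawn = _draw_codes(
        fresh, template, rng, extra_forbidden=set(mapping.values()) | set(old_codes)
    )
    mapping.update(drawn)
    key = CodeKey(
        scope=scope,
        entries=mapping,
        seed_fingerprint=_fingerprint(seed),
        attestation=[{"event": "created", "timestamp": timestamp or _utcnow()}],
    )
    return _apply_mapping(study, key_var, mapping), key


def destroy_key(key: CodeKey, timestamp: str | None = None) -> CodeKey:
    """Erase the mapping, keeping only the attestation trail.

    Destroying an already-destroyed key is a warned no-op.
    """
    if key.status == "destroyed":
        warnings.warn("code key already destroyed; no-op", stacklevel=2)
        return key
    return CodeKey(
        scope=key.scope,
        entries={},
        seed_fingerprint=key.seed_fingerprint,
        status="destroyed",
        attestation=key.attestation + [{"event": "destroyed", "timestamp": timestamp or _utcnow()}],
    )
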