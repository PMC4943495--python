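"""Config-driven orchestration of the full de-identification sequence.

Stage order is fixed and documented: classification, direct-identifier
removal, subject/site recoding, date transforms, generalisation, verbatim
scrubbing, subset selection, risk assessment, reporting, and finally the
adversarial QC comparison of input against output.  Recoding precedes the
date transforms so that all logs and derived columns reference the new
codes; risk is computed on the data exactly as it will be shared (after
subsetting).  Whether to share all tables or a subset is a mandatory
config field — the trade-off (full data is more useful but riskier) is
never decided silently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as _field
from pathlib import Path
from typing import Literal, Optional

from pydantic import BaseModel, Field

from . import dates as D
from . import generalise as G
from .pseudonym import CodeKey, destroy_key, remap_sites, remap_subjects
from .registry import Classification, classify_variables
from .reporting import QCFinding, TransformLog, build_report, qc_verify, render_markdown
from .risk import QuasiIdentifierSet, RiskReport, build_risk_report
from .scrub import ScrubPolicy, scrub_verbatim
from .study import Study, StudyError, parse_iso_date, read_study, write_study

__all__ = ["PipelineConfig", "PipelineResult", "run_deidentify", "default_config"]

#: Canonical stage order.
STAGES = (
    "classify",
    "remove_direct",
    "recode_subjects",
    "recode_sites",
    "derive_age",
    "dates",
    "generalise",
    "scrub",
    "subset",
    "risk",
    "report",
)


class ReferenceCfg(BaseModel):
    mode: Literal["per-subject", "trial-level"] = "per-subject"
    table: Optional[str] = None
    variable: Optional[str] = None
    fixed_date: Optional[str] = None
    fallback: Literal["error", "drop-subject-dates"] = "error"


class OffsetCfg(BaseModel):
    lo: int = -30
    hi: int = 30
    exclude_zero: bool = True
    constrain_to_trial_range: bool = True


class DatesCfg(BaseModel):
    method: Literal["study_day", "offset"] = "study_day"
    reference: ReferenceCfg = ReferenceCfg()
    offset: OffsetCfg = OffsetCfg()
    partial_policy: Literal["none", "month-midpoint", "conservative-drop"] = "none"
    retain_season: list[dict] = Field(default_factory=list)
    keep: list[list[str]] = Field(default_factory=list)


class PseudonymCfg(BaseModel):
    seed: int
    subject_template: str = "S#####"
    site_template: str = "SITE###"
    prior_subject_key: Optional[str] = None
    prior_site_key: Optional[str] = None
    key_disposition: Literal["store", "destroy"]  # mandatory: never defaulted


class AgeCfg(BaseModel):
    cap: int = G.AGE_CAP
    label: str = G.AGE_CAP_LABEL
    bin_width: Optional[int] = None


class PoolingCfg(BaseModel):
    table: str
    variable: str
    min_count: int = G.DEFAULT_MIN_COUNT
    pooled_label: str = "POOLED"


class AnthroCfg(BaseModel):
    table: str
    variable: str
    width: float
    anchor: float = 0.0
    label_template: str = "{lo}-{hi_dec}"


class ZipCfg(BaseModel):
    table: str
    variable: str
    retention_permitted: bool = False


class GeneraliseCfg(BaseModel):
    age: AgeCfg = AgeCfg()
    race_variable: Optional[str] = None
    race_table: str = "DM"
    pooling: list[PoolingCfg] = Field(default_factory=list)
    anthropometry: list[AnthroCfg] = Field(default_factory=list)
    zip: Optional[ZipCfg] = None


class ScrubTargetCfg(BaseModel):
    mode: Literal["drop-variable", "blank-values", "review"] = "drop-variable"
    coded_counterpart: Optional[str] = None


class RiskCfg(BaseModel):
    qi: list[list[str]] = Field(default_factory=list)
    events: list[list[str]] = Field(default_factory=list)
    denom_threshold: int = 100
    numer_threshold: int = 3


class SubsetCfg(BaseModel):
    mode: Literal["all", "subset"]  # mandatory: never defaulted
    tables: list[str] = Field(default_factory=list)


class ReportCfg(BaseModel):
    timestamp: str = ""


class PipelineConfig(BaseModel):
    """Everything one run needs, schema-validated."""

    layout: dict = Field(default_factory=dict)
    classification: dict = Field(default_factory=dict)
    pseudonym: PseudonymCfg
    dates: DatesCfg = DatesCfg()
    generalise: GeneraliseCfg = GeneraliseCfg()
    scrub: dict[str, ScrubTargetCfg] = Field(default_factory=dict)
    risk: RiskCfg = RiskCfg()
    subset: SubsetCfg
    report: ReportCfg = ReportCfg()
    disable: list[str] = Field(default_factory=list)  # stages to skip (QC will object)


@dataclass
class PipelineResult:
    study: Study
    original: Study
    classification: Classification
    log: TransformLog
    risk: RiskReport | None
    code_keys: dict[str, CodeKey]
    report: dict
    report_md: str
    qc_findings: list[QCFinding]
    exit_code: int
    review: dict = _field(default_factory=dict)


def default_config(seed: int = 0, **overrides) -> PipelineConfig:
    """Best-practice configuration for the generated synthetic layout."""
    from .synthetic import default_declarations

    base = {
        "classification": default_declarations(),
        "pseudonym": {"seed": seed, "key_disposition": "store"},
        "dates": {
            "method": "study_day",
            "reference": {"mode": "per-subject", "table": "DM", "variable": "RFSTDTC"},
        },
        "generalise": {
            "age": {"cap": 89, "label": ">89"},
            "race_variable": "RACE",
            "pooling": [
                {"table": "DM", "variable": "SITEID", "min_count": 5},
                {"table": "DM", "variable": "COUNTRY", "min_count": 5},
            ],
            "zip": {"table": "DM", "variable": "ZIPCODE", "retention_permitted": True},
        },
        "scrub": {
            "AETERM": {"mode": "drop-variable", "coded_counterpart": "AEDECOD"},
            "DSTERM": {"mode": "drop-variable", "coded_counterpart": "DSDECOD"},
        },
        "risk": {
            "qi": [["DM", "AGE"], ["DM", "SEX"], ["DM", "SITEID"], ["DM", "COUNTRY"]],
            "events": [["AE", "AEDECOD"]],
        },
        "subset": {"mode": "all"},
        "report": {"timestamp": "pinned"},
    }
    base.update(overrides)
    return PipelineConfig(**base)


def _enabled(config: PipelineConfig, stage: str) -> bool:
    return stage not in config.disable


def run_deidentify(
    config: PipelineConfig,
    study: Study | None = None,
    in_paths: list | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full best-practice sequence and the closing QC step.

    The input study is either passed directly or read from ``in_paths``
    using ``config.layout``.  When ``out_dir`` is given, the de-identified
    CSVs, code keys (per the mandatory disposition), report.json,
    report.md and qc_findings.json are written there.  Exit code 2 on any
    QC fail, 0 otherwise.
    """
    if study is None:
        if not in_paths:
            raise StudyError("provide a study or input paths")
        study = read_study(in_paths, config.layout)
    original = study.copy()
    study = study.copy()  # never mutate the caller's object
    log = TransformLog()
    review: dict = {}
    ts = config.report.timestamp or None

    classification = classify_variables(study, config.classification)
    review["needs_manual_review"] = sorted(classification.needs_review)

    # --- remove declared direct identifiers (and anything policy=remove)
    if _enabled(config, "remove_direct"):
        for meta in classification.by_policy("remove"):
            if meta.role == "verbatim-text":
                continue  # verbatim text is the scrub stage's responsibility
            for tname, tab in study.tables.items():
                if meta.name in tab.variables:
                    tab.df.drop(columns=[meta.name], inplace=True)
                    tab.kinds.pop(meta.name, None)
                    log.add(tname, meta.name, "remove.direct",
                            action="removed", registry_code=meta.registry_code)

    # --- consistent random recoding
    code_keys: dict[str, CodeKey] = {}
    if _enabled(config, "recode_subjects"):
        prior = (
            CodeKey.load(config.pseudonym.prior_subject_key)
            if config.pseudonym.prior_subject_key
            else None
        )
        study, skey = remap_subjects(
            study, config.pseudonym.seed, config.pseudonym.subject_template,
            prior_key=prior, timestamp=ts,
        )
        code_keys["subject"] = skey
        for tname in study.subject_tables():
            log.add(tname, study.subject_key, "pseudonym.recode",
                    action="recoded", scope="subject",
                    seed_fingerprint=skey.seed_fingerprint)
    if _enabled(config, "recode_sites") and study.site_key:
        prior = (
            CodeKey.load(config.pseudonym.prior_site_key)
            if config.pseudonym.prior_site_key
            else None
        )
        study, ckey = remap_sites(
            study, config.pseudonym.seed + 1, config.pseudonym.site_template,
            prior_key=prior, timestamp=ts,
        )
        code_keys["site"] = ckey
        for tname, tab in study.tables.items():
            if study.site_key in tab.variables:
                log.add(tname, study.site_key, "pseudonym.recode",
                        action="recoded", scope="site",
                        seed_fingerprint=ckey.seed_fingerprint)

    # --- season retention must see the raw dates
    if _enabled(config, "dates"):
        for item in config.dates.retain_season:
            study = D.retain_season(
                study, item["table"], item["variable"], item.get("granularity", "month")
            )
            log.add(item["table"], item["variable"], "dates.retain_season",
                    derived=f"{item['variable']}_{item.get('granularity', 'month').upper()}")

    # --- date of birth -> age
    ref_spec = D.ReferenceDateSpec(
        mode=config.dates.reference.mode,
        table=config.dates.reference.table,
        variable=config.dates.reference.variable,
        fixed_date=config.dates.reference.fixed_date,
        fallback=config.dates.reference.fallback,
    )
    if _enabled(config, "derive_age"):
        dob_vars = classification.by_role("date-of-birth")
        if dob_vars:
            refs = ref_spec.resolve(study)
            for meta in dob_vars:
                for tname, tab in study.tables.items():
                    if meta.name not in tab.variables:
                        continue
                    ages = []
                    for subj, val in zip(tab.values(study.subject_key), tab.values(meta.name)):
                        d = parse_iso_date(val)
                        if d is None or subj not in refs:
                            ages.append("")
                        else:
                            ages.append(str(D.derive_age(d, refs[subj])))
                    tab.df.drop(columns=[meta.name], inplace=True)
                    tab.kinds.pop(meta.name, None)
                    tab.df["AGE"] = ages
                    tab.kinds["AGE"] = "integer"
                    log.add(tname, meta.name, "dates.derive_age",
                            action="replaced-by-age", derived="AGE")

    # --- remaining patient-related dates
    if _enabled(config, "dates"):
        date_vars: dict[str, list[str]] = {}
        for meta in classification.by_role("calendar-date"):
            for tname, tab in study.tables.items():
                if meta.name in tab.variables:
                    date_vars.setdefault(tname, []).append(meta.name)
        keep = {tuple(pair) for pair in config.dates.keep}
        stage_log: list[dict] = []
        if config.dates.method == "study_day":
            study = D.apply_study_days(
                study, ref_spec, date_vars, config.dates.partial_policy, keep, stage_log
            )
        else:
            study, plan = D.offset_dates(
                study,
                config.pseudonym.seed + 2,
                (config.dates.offset.lo, config.dates.offset.hi),
                date_vars,
                constrain_to_trial_range=config.dates.offset.constrain_to_trial_range,
                exclude_zero=config.dates.offset.exclude_zero,
                ref=ref_spec,
                log=stage_log,
            )
            review["offset_fallback_subjects"] = plan.fallback_subjects
        log.extend(stage_log)

    # --- generalisation
    if _enabled(config, "generalise"):
        gcfg = config.generalise
        # age cap (and optional binning)
        for tname, tab in study.tables.items():
            if "AGE" not in tab.variables:
                continue
            cap, label = gcfg.age.cap, gcfg.age.label
            spec = G.BinSpec(gcfg.age.bin_width) if gcfg.age.bin_width else None
            new_vals = []
            for v in tab.values("AGE"):
                capped = G.cap_age(v, cap, label) if v != "" else ""
                if spec is not None and capped not in ("", label):
                    capped = G.bin_value(capped, spec)
                new_vals.append(str(capped))
            tab.df["AGE"] = new_vals
            log.add(tname, "AGE", "generalise.age_cap", cap=cap, label=label,
                    bin_width=gcfg.age.bin_width)
        if gcfg.race_variable:
            tab = study.tables.get(gcfg.race_table)
            if tab is not None and gcfg.race_variable in tab.variables:
                unmapped: list[str] = []
                mapping = G.load_race_map()
                tab.df[gcfg.race_variable] = [
                    G.map_race(v, mapping, unmapped) for v in tab.values(gcfg.race_variable)
                ]
                review["unmapped_race_values"] = sorted(set(unmapped))
                log.add(gcfg.race_table, gcfg.race_variable, "generalise.race_map",
                        action="mapped-to-fda-categories", unmapped=len(set(unmapped)))
        for rule_cfg in gcfg.pooling:
            tab = study.tables.get(rule_cfg.table)
            if tab is None or rule_cfg.variable not in tab.variables:
                continue
            rule = G.PoolingRule(rule_cfg.variable, rule_cfg.min_count, rule_cfg.pooled_label)
            new_tab, mapping = G.pool_rare_categories(tab, rule, study.subject_key)
            study.tables[rule_cfg.table] = new_tab
            n_pooled = sum(1 for k, v in mapping.items() if v != k)
            if n_pooled:
                log.add(rule_cfg.table, rule_cfg.variable, "generalise.pool",
                        min_count=rule_cfg.min_count, pooled_label=rule_cfg.pooled_label,
                        n_categories_pooled=n_pooled)
        for a in gcfg.anthropometry:
            tab = study.tables.get(a.table)
            if tab is None or a.variable not in tab.variables:
                continue
            spec = G.BinSpec(a.width, a.anchor, a.label_template)
            tab.df[a.variable] = [str(G.bin_value(v, spec)) for v in tab.values(a.variable)]
            tab.kinds[a.variable] = "text"
            log.add(a.table, a.variable, "generalise.bin", width=a.width, anchor=a.anchor)
        if gcfg.zip is not None:
            tab = study.tables.get(gcfg.zip.table)
            if tab is not None and gcfg.zip.variable in tab.variables:
                zlog: list[str] = []
                tab.df[gcfg.zip.variable] = [
                    G.truncate_zip(v, gcfg.zip.retention_permitted, zlog)
                    for v in tab.values(gcfg.zip.variable)
                ]
                review["malformed_zips"] = zlog
                log.add(gcfg.zip.table, gcfg.zip.variable, "generalise.zip_truncate",
                        retention_permitted=gcfg.zip.retention_permitted)

    # --- verbatim text
    if _enabled(config, "scrub"):
        scrub_findings: list = []
        for tname in list(study.tables):
            tab = study.tables[tname]
            targets = {
                var: ScrubPolicy(cfg.mode, cfg.coded_counterpart)
                for var, cfg in config.scrub.items()
                if var in tab.variables
            }
            if not targets:
                continue
            stage_log = []
            study.tables[tname] = scrub_verbatim(tab, targets, stage_log, scrub_findings)
            log.extend(stage_log)
        if scrub_findings:
            review["scrub_review_findings"] = [
                f"{f.table}.{f.variable}[{f.record_index}]: {f.pattern_family}"
                for f in scrub_findings
            ]

    # --- subset selection (last, so risk sees the data as shared)
    subset_note = None
    if config.subset.mode == "subset" and _enabled(config, "subset"):
        keep_tables = set(config.subset.tables)
        unknown = keep_tables - set(study.tables)
        if unknown:
            raise StudyError(f"subset names unknown tables {sorted(unknown)}")
        for tname in sorted(set(study.tables) - keep_tables):
            del study.tables[tname]
            log.add(tname, "*", "subset.drop-table", action="table-not-shared")
        subset_note = (
            "Only a subset of the study tables is shared for this request: "
            + ", ".join(sorted(keep_tables))
            + ". Tables not listed were withheld entirely."
        )

    # --- residual risk on the data as shared
    risk_report = None
    if _enabled(config, "risk") and config.risk.qi:
        qi = QuasiIdentifierSet([tuple(p) for p in config.risk.qi], reduce="unique")
        events = [tuple(p) for p in config.risk.events
                  if p[0] in study.tables and p[1] in study.tables[p[0]].variables]
        qi_present = [p for p in qi.variables if p[0] in study.tables]
        risk_report = build_risk_report(
            Study(tables=study.tables, subject_key=study.subject_key,
                  subject_table=study.subject_table, site_key=study.site_key),
            QuasiIdentifierSet(qi_present, reduce="unique"),
            events,
            config.risk.denom_threshold,
            config.risk.numer_threshold,
        )

    # --- key disposition (mandatory, explicit)
    if config.pseudonym.key_disposition == "destroy":
        code_keys = {scope: destroy_key(k, timestamp=ts) for scope, k in code_keys.items()}

    # --- report + adversarial QC
    meta = {
        "stage_order": [s for s in STAGES if _enabled(config, s)],
        "key_disposition": config.pseudonym.key_disposition,
        "seed_fingerprints": {s: k.seed_fingerprint for s, k in code_keys.items()},
        "date_method": config.dates.method,
        "pooling_min_counts": {
            f"{p.table}.{p.variable}": p.min_count for p in config.generalise.pooling
        },
        "risk_thresholds": {
            "denominator": config.risk.denom_threshold,
            "numerator": config.risk.numer_threshold,
        },
    }
    report = build_report(log, risk_report, subset_note, meta,
                          timestamp=config.report.timestamp)
    report_md = render_markdown(report)
    qc = qc_verify(original, study, classification, log)
    exit_code = 2 if any(f.severity == "fail" for f in qc) else 0

    result = PipelineResult(
        study=study, original=original, classification=classification, log=log,
        risk=risk_report, code_keys=code_keys, report=report, report_md=report_md,
        qc_findings=qc, exit_code=exit_code, review=review,
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir), config)
    return result


def _write_outputs(result: PipelineResult, out_dir: Path, config: PipelineConfig) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_study(result.study, out_dir / "data", overwrite=True)
    (out_dir / "report.json").write_text(
        json.dumps(result.report, indent=2, default=str) + "\n", "utf-8"
    )
    (out_dir / "report.md").write_text(result.report_md, "utf-8")
    (out_dir / "qc_findings.json").write_text(
        json.dumps(
            [
                {"check": f.check_id, "severity": f.severity,
                 "message": f.message, "location": f.location}
                for f in result.qc_findings
            ],
            indent=2,
        )
        + "\n",
        "utf-8",
    )
    key_dir = out_dir / "keys"
    key_dir.mkdir(exist_ok=True)
    for scope, key in result.code_keys.items():
        key.save(key_dir / f"{scope}_key.json")
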