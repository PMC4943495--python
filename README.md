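# trialdeid

De-identification of patient-level clinical trial datasets for sharing
with third-party researchers.

Sponsors and academic trial units that share individual participant data
must first transform it so that patients are no longer identifiable while
the data remains scientifically usable. `trialdeid` implements the
Safe Harbor-based best-practice sequence for multi-domain trial datasets
(CDISC SDTM-style tables such as DM, AE, VS, LB, DS):

- **Direct identifiers** — a built-in registry of the eighteen HIPAA Safe
  Harbor identifier classes (names, geography below state, dates,
  telephone/fax, email, SSN, record/account numbers, URLs, IPs,
  biometrics, photographs, other unique codes), declaration-driven
  variable classification, and a regex cell scanner that flags
  identifier-like values anywhere in the data for review.
- **Pseudonymisation** — subject and site codes are replaced by uniformly
  random new codes, consistently across every table and (via a prior code
  key) extension studies. New codes carry no information from the records;
  the code key is stored or destroyed, with an attestation either way.
- **Dates** — every patient-related date is replaced by its study day
  relative to a per-subject reference date under the SDTM `--DY`
  convention (day 1 = reference, no day 0), or optionally by offset dates:
  one random per-subject shift that preserves all within-subject intervals
  and can be constrained to the original trial date range. Date of birth
  becomes age in completed years; month/season can be retained for
  seasonal indications.
- **Generalisation** — age top-coding (`>89`), optional fixed-width
  binning, race mapped to the five FDA categories, ethnicity removal,
  pooling of sites/countries with few patients (distinct-subject counts),
  anthropometry grouping, and three-digit ZIP truncation.
- **Free text** — verbatim fields are dropped or blanked while their
  dictionary-coded terms (e.g. MedDRA preferred terms) are retained
  byte-identical; a review mode blanks only scanner-flagged cells.
- **Risk assessment** — equivalence classes over declared
  quasi-identifiers, k-anonymity (k = minimum class size; k = 1 means
  someone is unique), and small-cell screening: populations below 100 and
  event terms carried by fewer than 3 subjects are flagged — reported,
  never auto-deleted.
- **Reporting & QC** — a machine- and human-readable transformation
  report, plus a separate adversarial QC step that compares input against
  output and fails the run (exit code 2) if any rule did not take effect
  or any change is unlogged.

A synthetic-trial generator with a ground-truth manifest (planted emails,
phone numbers, SSN-like codes, rare adverse events, ages beyond the
top-code boundary) makes the whole pipeline testable without any real
data.

## Worked example

```python
import trialdeid as td

study, truth = td.generate_study(n_subjects=100, n_sites=6, seed=42)
print("domains:", {n: t.n_records for n, t in study.tables.items()})

findings = td.scan_free_values(study.tables["AE"], ["AETERM"])
print("scanner findings in AE verbatims:", len(findings), "| planted:", len(truth.planted))

res = td.run_deidentify(td.default_config(seed=7), study=study)
print("transformations applied:", res.report["n_transformations"])
print("QC:", *[f"{f.check_id}:{f.severity}" for f in res.qc_findings])
print("k-anonymity of release:", res.risk.k, "| uniques:", res.risk.uniques)
print("DM variables after:", res.study.tables["DM"].variables)
```

prints

```
domains: {'DM': 100, 'AE': 223, 'VS': 400, 'LB': 400, 'DS': 100}
scanner findings in AE verbatims: 23 | planted: 23
transformations applied: 25
QC: a:info b:info c:info d:info e:info
k-anonymity of release: 1 | uniques: 80
DM variables after: ['SUBJID', 'SITEID', 'COUNTRY', 'ZIPCODE', 'SEX', 'RACE',
                     'HEIGHT', 'WEIGHT', 'ARM', 'RFSTDY', 'AGE']
```

The scanner found all 23 planted identifiers (and nothing else); the
pipeline applied 25 logged transformations; all five QC checks — direct
identifiers gone, no raw dates, subject codes fully recoded, verbatims
scrubbed, every change logged — passed at severity `info`. Name, email,
phone, SSN, ethnicity and date-of-birth columns are gone from DM; the
subject and site codes are random (`S94490`, `SITE326`), the reference
date collapsed to study day 1, age is derived and top-coded, ZIP is
truncated to three digits (`453**`). k = 1 with 80 unique subjects over
(AGE, SEX, SITEID, COUNTRY) is typical for a 100-subject trial and is
exactly what the risk report is for: the data holder decides whether to
generalise further (e.g. five-year age bins) or rely on controlled access
and the data sharing agreement.

The same machinery is scriptable from the shell:

```sh
trialdeid simulate -n 100 -k 6 -s 42 --out raw/
trialdeid run --config config.yaml --in raw/ --out deid/   # exit 2 on QC fail
trialdeid assess-risk --in deid/data --qi DM.AGE,DM.SEX,DM.SITEID --events AE.AEDECOD
```

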