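# Methods

## The de-identification model

`trialdeid` adopts the Safe Harbor route to de-identification — removal
of the eighteen enumerated direct-identifier classes — extended with
generalisation and masking of indirect identifiers, rather than Expert
Determination or diversity/closeness models (l-diversity, t-closeness).
The latter are deliberately not implemented: clinical trial data are
high-dimensional relative to their subject count, and enforcing
non-uniqueness across that many attributes destroys most of the analytic
value (rare adverse events, which are scientifically critical, are
inherently unique). The package therefore *measures* residual risk
(k-anonymity, small cells) and reports it, leaving the acceptable-risk
threshold to the data holder, who also controls the complementary legal
and access safeguards.

The unit of operation is a `Study`: a set of domain tables sharing a
subject key, in the style of CDISC SDTM (DM demographics, AE adverse
events, VS vitals, LB labs, DS disposition). All cells are carried as
text; declared value kinds (integer, decimal, calendar-date,
partial-date) drive validation and the transforms but never silent
coercion, which makes CSV round trips exact and QC diffs trustworthy.

## Stage order

classification → direct-identifier removal → subject/site recoding →
date transforms → generalisation → verbatim scrubbing → subset selection
→ risk assessment → report → QC.

Recoding precedes the date transforms so every log entry and derived
column references the new codes; subsetting comes last before risk so
the risk metrics describe the data exactly as shared. Two fields are
mandatory in every config, with no default: the code-key disposition
(store or destroy) and the all-tables-vs-subset choice — both are
genuine governance decisions that must never be made silently.

## Key conventions and parameters

- **Registry.** The eighteen identifier classes carry codes A–R. The
  closing "no actual knowledge" condition of the Safe Harbor rule is a
  governance attestation, not a computable rule; it is emitted as an
  attestation line in every report rather than pretending to be a check.
- **Classification is declaration-first.** The data holder declares each
  variable's role; undeclared variables default to *keep* but land in a
  needs-manual-review list, because automated preparation always leaves
  some element of manual review. The cell scanner (documented regexes for
  email, phone/fax, URL, IP, SSN-like, ZIP+4, ISO dates; conservatively
  biased toward false positives) feeds a review list and never deletes or
  reclassifies anything itself. Name detection is deliberately
  heuristic-free: names are handled by role declaration and verbatim
  policy, not NER, which would be unreliable without training data and
  give false confidence.
- **Pseudonymisation.** New codes are a uniformly random injection into a
  digit-template space (`S#####` subjects, `SITE###` sites by default),
  never a hash of the old code — hashed codes are dictionary-attackable
  and would make the new identifier depend on record content. The seed is
  mandatory and recorded only as a SHA-256 fingerprint. Extension-study
  consistency comes from passing the prior code key: mapped codes are
  reused, new subjects draw fresh codes. Destroying a key erases the
  entries and keeps the timestamped attestation trail.
- **Study day** follows the SDTM `--DY` rule: day 1 is the reference
  date, the day before is −1, there is no day 0. Study day is the default
  date method because it retains most of the scientific value of dates
  while avoiding the residual risk of shifted calendar dates; offsets are
  opt-in. The reference date is configurable per subject (e.g. first
  dose) or trial-level; which anchor to use is data-holder preference.
- **Offsets** are per-subject (one draw shifts all of a subject's dates,
  so intervals are exact) with zero excluded by default, since a zero
  offset leaks true dates. Under the trial-range constraint the offset is
  drawn uniformly from the *exact* feasible set — the intersection of the
  bounds with `[trial_min − subj_min, trial_max − subj_max]` — rather
  than by rejection sampling; a subject with an empty feasible set falls
  back to study days (or blanking if no reference is configured), is
  warned about, and is listed in the offset plan.
- **Ages.** Age is completed years at the reference date; leap-day births
  are deemed to reach their birthday on Feb 28 of non-leap years (a
  convention had to be fixed; this one is the commoner legal rule). The
  top-code is `>89` (the equivalent "90 or older" wording is available
  via config — the two label the same set). Optional binning uses
  left-closed right-open fixed-width bins, default width 5 years.
- **Pooling** counts *distinct subjects*, not rows — re-identification
  risk attaches to people. The minimum count has no authoritative
  default; the package uses 5, config-overridable, and always disclosed
  in the report.
- **Partial dates** (`YYYY`, `YYYY-MM`) are pervasive in trial data. They
  are resolved by a declared policy — `none` / `conservative-drop` (blank,
  logged) or `month-midpoint` (the 15th; mid-year for year-only) — and
  every imputation is logged; they are never silently fed to date
  arithmetic.
- **Risk.** Missing is its own category when partitioning subjects:
  missingness patterns can identify, and the choice must be
  deterministic. Small-denominator (< 100 subjects per quasi-identifier
  cell) and small-numerator (< 3 subjects per event term) flags use
  strict inequality and are reported, never auto-remediated — removing
  every rare event would gut safety analyses.
- **QC** is adversarial by design: a separate pass that re-derives the
  input→output diff and checks (a) no direct identifier survives
  unchanged, (b) no raw calendar dates survive a study-day transform,
  (c) zero overlap between old and new subject codes, (d) verbatim
  targets absent/blank/scanner-clean, (e) every observed change is
  covered by the transformation log. Any failure exits with code 2.
  Generalisation rules without a dedicated check (race mapping, pooling)
  are still guarded by check (e), which catches their absence only if
  data changed unlogged; their correctness is covered by unit tests.

## The synthetic-trial generator

The generator emulates the data landscape the rules must survive, not a
clinically realistic trial: ages uniform on 18–95 so the `>89` cap is
always exercised; Dirichlet-skewed site sizes so pooling always has rare
sites to find; a fixed visit grid (days 0/14/28/56, ±2 days jitter);
reference dates spread over six months of 2020; ~10% deaths in DS;
Poisson(2) adverse events per subject pairing clean free-text verbatims
with dictionary-coded terms. Identifier plants (emails, phone numbers,
SSN-like codes, dates, names, from a small in-package word list) are
injected into verbatims at a configurable rate, and rare coded terms are
planted with exact distinct-subject counts. Every plant's coordinates go
into the ground-truth manifest, so scanner recall/precision and the risk
metrics are checked against truth, not against the implementation.

What passing these tests does *not* show: performance on real legacy
data with inconsistent spellings, free text whose PHI does not match any
regex family (misspelled emails, prose names), non-Gregorian or
malformed date formats beyond ISO 8601, and multi-study consistency at
scale. The manual-review list and the scanner's conservative bias exist
precisely because the automated pass is not sufficient on such data.

## Problem sizes

The test suite and the acceptance script run on generated trials of
50–500 subjects (200 subjects / 8 sites in the acceptance run, plus 200
random studies of up to 200 subjects for the brute-force oracle
comparisons), which exercises every rule boundary while keeping the
whole suite around ten seconds. All randomness is seed-derived;
reported seeds are fingerprinted, never echoed.

## Known limitations

- No XPT/Dataset-XML ingestion, database back ends, or out-of-core
  tables: CSV in, CSV out.
- Review-mode scrubbing blanks whole cells with findings; it does not
  excise the matched span surgically.
- No probabilistic attacker models or population-registry linkage
  estimation; k-anonymity and small-cell flags are descriptive.
- Key storage is written in plaintext to a caller-designated location
  with an attestation; encryption at rest is a deployment concern.
- Genetic data are out of scope entirely: a genome is unique per subject
  and no tabular generalisation makes it otherwise.
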