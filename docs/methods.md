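# Methods

## Scope and model

pvdispro screens spontaneous adverse-event reporting for two
lack-of-efficacy conditions — drug resistance and drug ineffectiveness —
each defined by a fixed set of MedDRA Preferred Terms (2 and 11 terms
respectively, shipped in `src/pvdispro/data/meddra_pt_dictionary.csv`).
The inferential core is the reporting odds ratio of a target drug against
a comparator:

* 2×2 table: `a` evaluated-condition reactions / `b` other reactions for
  the target; `c` / `d` likewise for the comparator. Cells are counts of
  ADR rows (reported reactions), not cases — the "other reactions" margin
  is defined per reaction, so the evaluated count must be too. Distinct
  case counts (`n_icsrs`) are carried separately for the
  reactions-per-case descriptive.
* `ROR = (a·d)/(b·c)`; log-scale Woolf standard error
  `SE = √(1/a + 1/b + 1/c + 1/d)`; Wald interval `exp(ln ROR ± z·SE)`.
* Signal rule (EMA screening practice): `a ≥ min_reports` (default 5)
  **and** lower CI bound strictly greater than 1. Both parameters are
  exposed (`min_reports`, `z`) for sensitivity analyses; `z` defaults to
  the conventional 1.96 rather than a re-derived quantile, because that
  is the constant regulatory calculators print.
* The two-sided p-value `2(1 − Φ(|ln ROR|/SE))` is reported for
  convenience (it reconstructs the significance stars of forest plots)
  but never enters signal classification.

The ROR is a measure of *reporting* disproportion, not of risk: it
conditions on a report having been made and inherits every reporting bias
of the source database (stimulated reporting, drug age, indication
channeling). Results are screening signals, not effect estimates.

### Assumptions and numerical choices

* **Zero cells.** Any zero cell leaves the ROR or its SE undefined; the
  result is flagged `defined=False`, carries no numeric fields, and never
  signals. No Haldane–Anscombe or other continuity correction is applied:
  screening practice drops such pairs, and a correction would silently
  manufacture signals from sparse cells.
* **No multiplicity adjustment** across a comparator panel; standard in
  screening but a caveat for interpretation (documented, deliberate).
* **Rounding.** All reported descriptive ratios and percentages round
  half-up to 2 decimals (`decimal`-based, so 2.105 → 2.11); ROR and CI
  bounds are reported at 4 decimals in tables. Raw values are always
  recomputable from the integer counts.
* **Drug names** are normalized (trim, lower-case, collapse internal
  whitespace); slash-joined combination products stay one token.
* **PT classification** matches by MedDRA code first, then by
  case-insensitive exact name; a code/name conflict resolves to the code
  with a logged warning. No fuzzy matching — a misspelled PT classifies
  as `other`, which is conservative for the evaluated conditions.

## Synthetic data generator

Spontaneous-reporting exports cannot be redistributed, so all testing and
the reference analysis run on generated line listings.

* **Exact mode** reproduces every target count precisely:
  `aggregate(generate(spec))` equals the spec. PT counts within a
  condition come from the user's weights via largest-remainder
  (Hamilton) allocation; outcome labels are expanded in a fixed enum
  order and paired with the PT stream positionally, satisfying both
  margins. Reactions are dealt to cases round-robin, so the number of
  distinct cases is exactly `n_icsrs` and reactions-per-case is as
  uniform as possible. This is the mode used for the reference analysis:
  every quantity derived from it is arithmetic on the encoded counts, not
  a simulation estimate.
* **Sample mode** keeps each drug's reaction total fixed and draws the
  composition (condition, PT, outcome) multinomially from the target
  proportions, from a single `numpy` generator seeded by the spec — equal
  spec + seed gives byte-identical output files.

### The reference study spec

`reference_study_spec()` encodes the published EudraVigilance aggregates
(data lock 1 December 2024) for bevacizumab and panitumumab in colorectal
cancer: ICSR/ADR totals (59,693 / 107,085 and 7,178 / 15,051), condition
counts (resistance 91 / 18, ineffectiveness 1,414 / 328), the published
PT splits ("Drug resistance" 82 / 17; "Drug ineffective" 768 / 60;
"Therapy partial responder" 179 / 172; "Therapy non-responder" 136 / 14;
"Therapeutic product effect incomplete" 112 / 52) and the
unfavorable-outcome breakdowns (resistance: 10 unfavorable of which 8
fatal / 1 of 1; ineffectiveness: 181 of which 92 fatal / 16 of which 4).

What the source tables leave unstated is filled deterministically and
flagged here:

* The residual PT mass within a condition (219 ineffectiveness reactions
  for bevacizumab, 30 for panitumumab; 9 and 1 resistance reactions,
  which can only be "Multiple drug resistance") is spread uniformly over
  the unnamed dictionary PTs by largest remainder in dictionary order.
  Only condition totals and the named PTs affect any reported statistic.
* Outcomes other than the published unfavorable counts are split 50/50
  between favorable and unknown (odd remainder to favorable; within
  favorable, recovered before recovering). This split is **arbitrary** —
  favorable-vs-unknown proportions are never published for these cases —
  and no computed statistic depends on it: unfavorable and fatal counts
  are pinned, and the favorable/unknown distinction enters no table cell.
* One published inconsistency: the source states 0.53% unfavorable for
  panitumumab resistance alongside n = 1 of 18 reactions; 1/18 = 5.56%,
  and no denominator reproduces 0.53. The package reports 5.56 from the
  raw counts.

What the generator does *not* emulate: reporting dynamics over calendar
time, duplicate reports, report-level covariates (age, sex, region,
reporter type), within-case PT correlation beyond the round-robin deal,
and comparator-drug condition counts (not published; comparator panels
are exercised with synthetic counts and property-based checks only).
Passing tests therefore demonstrate the arithmetic and its invariants on
realistic count structures, not robustness to real-data messiness.

## Pipeline and reproducibility

`RunConfig` names exactly one input source — synthetic spec, line-listing
CSV, or a long-form aggregate table (for entering printed counts
directly) — plus targets, comparators, conditions, `min_reports`, `z`,
seed and output directory. Stages (`simulate`, `aggregate`, `describe`,
`dispro`) compose on disk through documented CSV schemas; a JSON manifest
records seed, package version, row counts and the SHA-256 of the PT
dictionary so a changed term set is visible downstream. Identical config
and seed give byte-identical tables. Existing outputs are only
overwritten with `force`.

Problem sizes: the reference analysis generates 122,136 reaction rows and
runs in about two seconds; property-based suites use hundreds of random
small listings (≤ 60 rows) and random feasible generator specs, plus one
10⁵-draw sample-mode convergence check (within 3 standard errors).

## Known limitations

* Only the ROR is implemented; PRR, IC/BCPNN and EBGM shrinkage
  estimators are out of scope, as is any duplicate-report detection.
* The MedDRA hierarchy (SOC/HLGT/HLT) is not modelled — only the 13-term
  PT dictionary, which users can replace with their own CSV.
* Real EudraVigilance export dialects (HTML/XLSX, E2B XML) are not
  parsed; inputs are the package's documented CSV schemas.
* A case reporting the same drug on multiple rows contributes each row;
  no deduplication rule is applied (aggregates in the source system are
  row-based).
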