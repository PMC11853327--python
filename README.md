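# pvdispro

Disproportionality analysis of spontaneous adverse-event reports:
reporting odds ratios (ROR) with Wald confidence intervals and EMA-style
signal screening for MedDRA-coded Individual Case Safety Report (ICSR)
data, plus the descriptive reporting statistics that accompany such an
analysis and a seeded synthetic-data generator so the whole pipeline runs
without access to a regulatory database.

The package is built for pharmacovigilance analysts studying
*lack-of-efficacy* reporting — drug resistance and drug ineffectiveness —
for targeted cancer therapies such as bevacizumab and panitumumab in
colorectal cancer, where spontaneous reports in EudraVigilance are coded
under a small fixed set of MedDRA Preferred Terms (2 resistance PTs,
11 ineffectiveness PTs; shipped as packaged data).

## The statistic

For a target drug and a comparator, reactions of the evaluated condition
form a 2×2 table: *a* evaluated / *b* other reactions for the target, *c*
evaluated / *d* other for the comparator. Then

    ROR        = (a·d) / (b·c)
    SE{ln ROR} = √(1/a + 1/b + 1/c + 1/d)          (Woolf)
    95% CI     = exp( ln ROR ± 1.96 · SE{ln ROR} )  (Wald)

A pair is screened as a **disproportionality signal** when the evaluated
reaction has at least 5 reports for the target drug *and* the lower 95%
CI bound exceeds 1 (strict). Tables with a zero cell are flagged
undefined rather than continuity-corrected, and never signal. A two-sided
p-value from the Wald z statistic is carried as a convenience output; it
plays no part in the signal rule.

Counting unit throughout is the ADR row (one reported reaction), not the
case; `n_icsrs` counts distinct case identifiers.

## Worked example

The packaged reference spec encodes the published EudraVigilance
aggregates for bevacizumab (59,693 ICSRs / 107,085 ADRs; 91 resistance and
1,414 ineffectiveness reactions) and panitumumab (7,178 / 15,051; 18 and
328), including the dominant PT splits and unfavorable-outcome counts.

```python
from pvdispro import (Condition, DisproportionalityModel, aggregate,
                      adrs_per_icsr, generate, reference_study_spec)

dataset = generate(reference_study_spec())          # 122,136 synthetic reactions
aggs = aggregate(dataset)

bev = next(a for a in aggs if a.drug == "bevacizumab")
print(adrs_per_icsr(bev))                           # 1.79 reactions per case

model = DisproportionalityModel(aggs, "panitumumab", ["bevacizumab"],
                                [Condition.INEFFECTIVENESS])
print(model.fit().summary())
```

```
1.79
Reporting odds ratio panel
  target:      panitumumab
  condition:   ineffectiveness
  z:           1.96   min reports: 5

  comparator                   a       ROR              95% CI         p  signal
  bevacizumab                328    1.6649    (1.4746, 1.8797)    0.0000  yes
```

Ineffectiveness is reported for panitumumab 1.66 times more often than
for bevacizumab (per reported reaction, against each drug's own reporting
base); the interval excludes 1 and *a* = 328 ≥ 5, so the pair screens as
a signal. The same comparison restricted to the resistance PTs gives
ROR 1.4078 with CI (0.8489, 2.3348) — the interval spans 1, no signal.

The same run from a shell:

```sh
pvdispro all --config examples/reference_config.json --out out/
```

or stage by stage (`simulate`, `aggregate`, `describe`, `dispro`), each
stage reading and writing plain CSV so stages compose on disk. Outputs:
`line_listing.csv`, `aggregates.csv`, `descriptives.csv`
(reactions/case, condition percentages, unfavorable and fatal outcome
breakdowns per drug), `pt_distribution.csv`, `signals_<target>.csv`
(columns `target,comparator,condition,a,b,c,d,ror,ci_low,ci_high,
p_value,n_reports,signal,defined` — forest-plot ready), and a
`manifest.json` recording seed, versions, row counts and the PT
dictionary checksum.

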