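# pvsignal

Disproportionality-based signal detection for spontaneous adverse-event
reports, built around the workflow used in FAERS pharmacovigilance studies:
case-level 2×2 contingency construction, the three workhorse statistics —
reporting odds ratio (ROR), proportional reporting ratio (PRR) with
chi-squared, and the BCPNN information component — and a triple-positive
signal rule with exclusion filtering and system-organ-class (SOC)
aggregation.

It is written for pharmacoepidemiologists and drug-safety analysts who want
a scriptable, testable version of the screen that published FAERS analyses
(such as the ticagrelor safety profile study this package reproduces)
perform with web tools like OpenVigil.

## The statistics

Each deduplicated case contributes to exactly one cell of a 2×2 table per
(drug, event) pair, with exposure meaning the drug holds the
primary-suspect role:

|                 | event | no event |
|-----------------|-------|----------|
| drug (PS)       | a     | b        |
| all other cases | c     | d        |

with N = a+b+c+d. The three methods and their signal criteria:

- **ROR** = (a·d)/(b·c), 95% CI = exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d));
  positive when a > 3 and the CI lower bound > 1.
- **PRR** = [a/(a+b)]/[c/(c+d)] with the Yates-corrected chi-squared
  χ² = (|ad−bc| − N/2)²·N / [(a+b)(c+d)(a+c)(b+d)];
  positive when a > 3, PRR > 2 and χ² > 4.
- **BCPNN**: information component IC = log₂[aN/((a+b)(a+c))] with
  posterior moments E(IC), V(IC) under the priors α₁=β₁=γ₁₁=1, α=β=2
  (Bate et al. 1998); positive when a > 3 and
  IC025 = E(IC) − 2·√V(IC) > 0.

A pair is a **signal** when all three methods are positive and the
preferred term is not struck by the exclusion list (terms with no
pharmacovigilance reference value, disease-of-indication terms,
medication-error terms).

## Worked example

Generate a synthetic spontaneous-report dataset with five planted
drug-event associations (relative reporting rate 10), deduplicate the
report versions into cases, and screen:

```python
from pvsignal import (SyntheticConfig, VocabularyMap, generate_cases,
                      generate_vocabulary, deduplicate_to_cases,
                      DisproportionalityAnalysis)

cfg = SyntheticConfig.example(n_cases=5000, seed=1)
reports, manifest = generate_cases(cfg)
cases = deduplicate_to_cases(reports)
model = DisproportionalityAnalysis(cases, "ticagrelor",
                                   vocab=VocabularyMap(generate_vocabulary(cfg)))
res = model.fit()
print(res.summary(top=5))
```

```
Disproportionality screen
=========================
drug:                 ticagrelor
cases (universe N):   5,000
drug-exposed cases:   233
PT tables built:      34
triple-positive PTs:  5
excluded positives:   0
final signals:        5

PT                               reports      ROR            95% CI     PRR       chi2     IC   IC025
Planted event 01                      21     7.64      (4.57-12.79)    7.04      77.63   2.46    1.46
Planted event 00                      20     8.04      (4.74-13.67)    7.44      78.05   2.52    1.47
Planted event 04                      20     6.69      (3.98-11.24)    6.20      63.92   2.32    1.33
Planted event 02                      18     5.31       (3.12-9.05)    4.98      43.51   2.07    1.08
Planted event 03                      17     5.44       (3.14-9.41)    5.11      42.35   2.10    1.07
```

All five planted events — and none of the thirty null events — pass the
triple-positive rule: each row shows its ROR with Wald CI, PRR with
Yates-corrected χ², the raw information component and its lower bound
IC025. `res.to_frame()` returns the full per-PT table,
`res.soc_summary()` aggregates signals by organ class (here 2 cardiac,
1 respiratory, 1 gastrointestinal, 1 nervous-system), and
`res.save(outdir)` writes `results.csv`, `soc_summary.csv`, ranked top-N
tables and `run_log.json`.

The same pipeline is exposed as a CLI:

```bash
pvsignal simulate --n-cases 5000 --seed 1 --out sim/
pvsignal analyze --input sim/reports.csv --drug ticagrelor \
    --vocab sim/vocabulary.csv --out analysis/
pvsignal reconstruct --rows printed_rows.csv --out tables.csv
```

## Layout

- `pvsignal.io` — report parsing (flat CSV and dollar-delimited
  quarterly-extract layouts), case deduplication, PT→SOC vocabulary.
- `pvsignal.contingency` — case-level 2×2 tables.
- `pvsignal.disproportionality` — ROR/PRR/χ²/BCPNN and the signal rule.
- `pvsignal.screen` — pipeline, exclusions, SOC aggregation, rankings.
- `pvsignal.model` — `DisproportionalityAnalysis` / `SignalScreenResults`.
- `pvsignal.reconstruction` — printed-row inversion oracle.
- `pvsignal.synthetic` — ground-truth report generator and
  operating-characteristics simulation.
- `pvsignal.datasets` — curated subgroup PT lists (bleeding, respiratory,
  cardiac) and a starter exclusion list.

See `docs/methods.md` for the statistical model, the generator's design
and the package's numerical conventions.
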