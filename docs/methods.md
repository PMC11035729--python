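# Methods

## Scope and counting conventions

The package screens one study drug against the whole case universe of a
spontaneous-report database. The unit of counting is the *case* (a
patient-event episode), not the report: report versions are deduplicated
first, and a drug-event pair present in **any** version of a case counts
for that case. This follows the convention that an entire case contributes
when at least one of its reports carries the relationship; demographics are
taken from the latest version (highest version sequence, ties by latest
receipt date, then greatest report id).

Drug exposure defaults to the **primary-suspect (PS)** role: b = exposed
cases without the event, so the drug margin a+b is the PS case count and is
constant across events. This choice is what makes published per-PT
statistics recomputable from printed margins (see Reconstruction below);
an any-role definition is available via `ps_only=False`. The comparator is
all other cases in the universe — no active-comparator restriction. Each
case contributes at most 1 to any cell: duplicate PTs within a report, and
repeated reports within a case, collapse.

Within one report a drug named with several role codes keeps the
highest-precedence one (PS > SS > C > I). Drug names and PTs are matched
case-insensitively after whitespace normalisation; free-text drug-name
mapping is out of scope (inputs are assumed to carry normalised generic
names; a synonym table can be layered on by the caller).

## Statistics

All three methods are evaluated on the same 2×2 table (rows = exposure,
columns = event).

**ROR.** (a·d)/(b·c) with the Wald interval
exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)). Undefined when any cell is zero;
the optional Haldane correction (add 0.5 to every cell) is opt-in and
marks the result `corrected`. 1.96 is used literally (the print
convention), not the exact 97.5% normal quantile; the difference is below
print precision and is covered by a tolerance in the statsmodels
cross-check.

**PRR and χ².** PRR = [a/(a+b)]/[c/(c+d)], undefined when the exposure
margin is empty or no comparator case has the event. The chi-squared
statistic applies the **Yates continuity correction by default**:
(max(|ad−bc| − N/2, 0))²·N / [(a+b)(c+d)(a+c)(b+d)]. Published screens of
this design print χ² values that match the corrected statistic (verified
on reconstructed tables to better than 0.01% at large counts), even where
the formula is typeset without the correction term; the uncorrected form
is available through `continuity_correction=False`. The correction term
floors at zero before squaring.

**BCPNN.** Posterior moments of the information component under the
standard priors α₁=β₁=γ₁₁=1, α=β=2, with the joint prior weight
γ = γ₁₁(N+α)(N+β)/((a+b+α₁)(a+c+β₁)) that centres the prior IC at 0:

    E(IC) = log₂[(a+γ₁₁)(N+α)(N+β) / ((N+γ)(a+b+α₁)(a+c+β₁))]
    V(IC) = (1/ln²2)·[(N−a+γ−γ₁₁)/((a+γ₁₁)(1+N+γ))
                     + (N−(a+b)+α−α₁)/((a+b+α₁)(1+N+α))
                     + (N−(a+c)+β−β₁)/((a+c+β₁)(1+N+β))]

IC025 is the normal approximation E(IC) − 2·√V(IC), not an exact posterior
quantile. The raw maximum-likelihood IC = log₂[aN/((a+b)(a+c))] is exposed
alongside (`ic_raw`): the two agree as counts grow (E(IC) → raw IC under
table scaling, checked numerically) but diverge at small a, where the
priors shrink E(IC) toward 0. Published tables of this workflow print the
**raw IC** in their IC column while their IC025 column is the posterior
normal bound — both are therefore carried in every output, and consumers
choose which column to compare against.

**Signal rule.** All criteria are strict inequalities: a > 3; ROR CI lower
bound > 1; PRR > 2 and χ² > 4; IC025 > 0. A pair is a combined signal when
all three methods are positive. Undefined statistics make a method
negative (zero-cell policy: no signal without evidence in every route).
Signal **intensity** is graded on E(IC) against two ascending cut-points
(defaults 1.5 and 3.0 bits → "+", "++", "+++"). The cut-points are
configuration, not science: published grade columns of this workflow are
internally inconsistent between tables with identical statistics, so no
default can reproduce them and the grading is deliberately kept
descriptive.

**Exclusions.** The exclusion list (no-reference-value terms,
disease-of-indication terms, medication-error terms) only removes terms
from the *signal set*; excluded rows keep their statistics and remain in
the output with an `excluded` marker, so exclusion never changes a number,
only membership. SOC aggregation sums the a-cell over signal PTs per SOC
and counts them; a case reported under several PTs of one SOC is counted
once per PT (the sum-over-PTs reading of per-SOC report totals).

No multiple-comparison adjustment is applied across PTs — deliberate, as
is conventional for hypothesis-generating disproportionality screens.
Stratified/shrinkage variants (MGPS, EBGM) are out of scope.

## Reconstruction of published rows

For a published row (PT, a, ROR, PRR) with known margins (drug total a+b,
universe N), b is fixed and c is seeded by inverting the PRR,

    c₀ = a·(N−(a+b)) / ((a+b)·PRR),

then refined by integer search over a ±2% window minimising the squared
relative deviation of the recomputed (ROR, PRR) from the printed pair. The
winner must reproduce both printed values under half-up rounding at the
printed precision (2 decimals), else an inconsistency error names the
residuals. Identifiability: c is recovered exactly (±1) when a unit step
in c moves the PRR by more than the print resolution (PRR/c > 0.005 —
true for strong signals with small comparator counts); otherwise c is
pinned to the rounding band, whose relative half-width 0.005/PRR is
far below the tolerance of any downstream statistic. Round-tripping
unrounded statistics recovers c exactly.

## Synthetic-report generator

The generator emulates the case/report structure of FAERS-like data with
known ground truth; its default `example()` configuration defines the
conditions under which the pipeline's operating characteristics are
measured:

- 20,000 cases; study drug exposed with marginal probability 0.05 and
  primary-suspect probability 0.9 given exposure (≈900 PS cases); a
  background comedication at marginal 0.9 (PS probability 0.05) so nearly
  every case names a drug, as real reports do;
- 30 null events with baseline per-case rates geometrically spaced over
  0.002–0.03 across four organ classes, and 5 planted events at baseline
  0.004 with relative reporting rate ρ = 10 under the study drug, giving
  expected a ≈ 36 per planted pair (≥ 30, comfortably detectable);
- event probability given an exposure pattern is min(1, λ·Πρ) — the
  multiplicative model keeps ρ interpretable as an approximate PRR at low
  baselines;
- cases realising no event, or no exposed drug, are redrawn (spontaneous
  reports by construction name at least one drug and one event); redraw
  counts are logged in the manifest;
- 20% of cases emit extra report versions (truncated-geometric count,
  capped at 3) that repeat the full case content, so deduplication
  correctness is testable independently of content;
- demographics (sex, age band, country, year) are drawn from categorical
  distributions shaped like the published ticagrelor cohort summary
  (57% male, US-dominant, 2016 reporting peak).

The manifest's **expected** counts are computed exactly under this model:
exposure patterns are enumerated (conditioned on ≥1 exposed drug), the
primary-suspect winner probability is computed combinatorially, and the
at-least-one-event conditioning is applied as P(e | any event) =
p_e / (1 − Π(1−p_f)). This conditioning matters — it enriches every event
rate by roughly 2–3× at the default configuration — and the naive
unconditional product is used only as a fallback beyond 12 drugs, where
pattern enumeration becomes too wide. **Realised** counts are tallied from
the actually generated exposure/event draws, and the pipeline
(deduplication → table construction) is required to match them exactly.

What the generator does **not** emulate: drug co-prescription correlation,
masking/competition bias between signals, reporting-rate drift over time,
conflicting duplicate content across report versions, and free-text drug
names. Passing tests therefore show the pipeline's correctness and the
rule's operating characteristics under clean conditions, not robustness to
those real-data pathologies.

Operating characteristics run the honest full pipeline per replicate
(generate → deduplicate → enumerate tables → all three statistics); at the
default 20,000 cases × 100 replicates this takes about a minute. The
conjunction rule's flag count is asserted ≤ each single method's, and its
sensitivity on the planted pairs is required to reach 0.9.

## Numerical conventions and degenerate inputs

- Half-up rounding at 2 decimals is the assumed print convention when
  matching published values.
- Empty case universe → all-zero table, valid but degenerate; N = 0 is an
  error for BCPNN (priors cannot regularise a nonexistent universe).
- Table enumeration keys PTs by first-seen spelling with case-insensitive
  matching; outputs are deterministically ordered (report count
  descending, then PT), and identical inputs yield byte-identical CSVs.
- Ranking tie-breaks: by-reports ranks on a then ROR then PT; by-strength
  on ROR then a then PT; undefined ROR sorts last.
- Seeds: every stochastic routine takes an explicit seed; replicate seeds
  are derived as (seed·1,000,003 + rep) mod 2³¹.

## Problem sizes

Unit and property tests run at 1,000–20,000 synthetic cases; the
operating-characteristics check uses 20,000 cases × 100 replicates (its
planted-pair expected count of ≈36 is what the sensitivity claim is about);
published-row reconstruction works on the printed margins (N ≈ 9.7M) at
negligible cost since only an integer search over c is involved.
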