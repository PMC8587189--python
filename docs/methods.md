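# Methods

## Problem setting

Published evidence on allogeneic HCT for sickle cell disease is aggregate:
per-cohort counts by transplant factor, outcome probabilities at one
follow-up horizon (25–48 months depending on the cohort), and hazard ratios
from multivariable survival models. No patient-level data are available to
the engine. The task is therefore *aggregate-data survival decomposition*:
reconstruct subgroup-specific outcome probabilities that (a) honor the
published between-level contrasts and (b) aggregate back exactly to the
published cohort value.

## Decomposition

Let *r* be the cohort event probability for one outcome at follow-up,
*f_j* the fraction of the cohort at level *j* of a factor, and *h_j* the
level's hazard ratio (reference = 1). Both modes enforce the mixture
constraint; they differ in which scale the hazard ratio is matched on.

- **relative_risk** (default): ratios of event probabilities between levels
  equal the hazard ratios, held constant over follow-up. Closed form
  `r_j = r * h_j / sum_k f_k h_k`. At high baseline risks the linear algebra
  can push a level past 1; the value is clamped and the output carries a
  `clamped` flag — never silently. The mixture is conserved to 1e-12
  pre-clamp.
- **proportional_hazards**: survival at level *j* is
  `S_ref ** h_j`, with `S_ref` the root of `sum_j f_j S_ref**h_j = 1 - r`.
  The left side is strictly increasing on [0, 1] so the root is unique;
  Brent's method with `xtol=1e-15` gives residuals ≤ 1e-10 (the module's
  hard tolerance). Endpoints `S ∈ {0, 1}` are returned exactly rather than
  bracketed. This mode never clamps and is exact under the simulator's
  data-generating process.

The default mode matches the published description of hazard ratios being
interpreted as relative risks; the proportional-hazards mode is provided
because it respects survival-scale hazard semantics and behaves at extreme
risks. The mixture-conserving normalization (dividing by `sum f_k h_k`) was
chosen over anchoring the reference level at the cohort value: only the
former reproduces the cohort probability when levels are re-aggregated. The
anchored variant is deliberately not implemented.

Multi-factor combinations assume **independence of factor distributions** —
joint fractions simply do not exist in aggregate tables. In relative-risk
mode the per-factor multipliers multiply; in proportional-hazards mode the
reference survival is solved against the full product mixture over all level
combinations and the combination's exponent is the product of its hazard
ratios. The simulator draws factors independently as well, so its recovery
tests isolate algebraic errors from violations of this assumption; a
correlated-factors study would quantify the approximation error but is out
of scope here.

Missing hazard ratios (registry studies omit non-significant factors) are
treated as 1 with a logged warning.

Outcome orientation: OS and EFS are stored as survival probabilities (as the
source tables print them); graft failure and GVHD as event probabilities.
The decomposition operates on event probabilities and converts at its
boundary, so a hazard ratio above 1 worsens every outcome consistently.

## Age handling

Published age bins (e.g. 0–5, 6–15, >15 years) are treated as uniform within
their bounds. Open-ended bins resolve to a configurable cap, default 25
years — the approximate upper bound of pediatric registry inclusion; the
sources do not state a maximum. A bin's representative age is its midpoint
(the mean under uniformity). Splitting a range into 2 or 3 subsets uses
equal widths with counts apportioned by largest-remainder rounding, ties to
the younger bin: deterministic and exactly sum-preserving.

Age-specific baselines are carried as optional per-bin outcome probabilities
on the cohort table (filled by user config or by the simulator's
aggregation). A bin without one falls back to the cohort-level baseline,
giving a flat age profile. This was chosen over modelling age as an extra
hazard-ratio factor: it keeps the factor algebra two-level-clean and mirrors
how age-stratified outcome rows actually appear in published tables.

## Regression and model selection

Per (factor combination, outcome), the decomposed per-bin probabilities form
2–3 points at the bin midpoints. Four two-parameter families are fitted by
least squares in their linearizing space (exponential and power on
log-values; +1 age offsets admit age 0), and compared by R² computed on the
**original probability scale** — log-scale R² values are not comparable
across families. Zero-variance data score R² = 1 for a perfect fit and −inf
otherwise. Ties within 1e-9 go to the exponential family (the family the
source analysis found best), then to list order; with only two points every
family interpolates, so the fit is marked non-informative (`interpolatory`).
Weighting by subset counts is available but off by default — the source
procedure states none.

Predictions clamp to [0, 1] (flagged) and *refuse* ages above the model's
valid domain (default: the source cohort's resolved age range, optionally
overridden by a per-donor-type cap). The hard refusal mirrors the source
tool's restriction of older ages, where extrapolated pediatric curves gave
implausibly poor outcomes.

## Predictor

The five-question profile selects one grid entry per outcome; estimates are
evaluated at the patient's age, the cohort's follow-up horizon is attached
(horizons differ across donor types and are surfaced, not harmonized — there
is no defensible way to re-project aggregate probabilities to a common
horizon), and EFS ≤ OS is enforced by lowering EFS with a
`consistency_adjusted` flag. The delayed-transplant comparison evaluates the
same grid at age + delay (default range 0–10 years, configurable) and
reports signed deltas. Output is deterministic: the same grid and profile
give byte-identical JSON. GVHD is reported without severity grades — the
aggregate schema has none.

## Synthetic registry

The simulator emulates the registry cohorts the engine was built for:
uniform ages on a configurable range (default 0–25 years), independent
factor levels at configured fractions, exponential event times with rate
`baseline_rate × Π (true hazard ratio of drawn levels)` — constant hazards
matching the "held constant over follow-up" interpretation and giving
closed-form oracles — and administrative censoring at the follow-up horizon.
One event type per run; competing risks are out of scope. All draws come
from a seeded `numpy` PCG64 generator.

Aggregation reverses the published-table construction: counts, level
fractions, overall and per-age-subset event-free proportions, and hazard
tables holding either the true ratios (oracle mode) or incidence-rate ratios
(events per person-time versus the reference level — the maximum-likelihood
contrast for exponential data, so no Cox partial likelihood is needed; an
event-free reference level is a signalled error).

What passing recovery tests show: with 20,000 patients, two binary factors
(true hazard ratios 1.5 and 2.0) and a cohort event risk of 0.12 at 36
months, the full simulate → aggregate → decompose → fit → predict pipeline
reproduces every subgroup's event-free probability within ±0.02 of the
empirical value in both modes (proportional-hazards is exact up to Monte
Carlo noise; relative-risk carries a small linearization bias, ≈0.005 at
this risk level). What they do not show: performance under correlated
factors, non-constant hazards, era effects, or any patient-level covariate
(comorbidity index, disease severity, quality of life) — none of which exist
in aggregate registry data.

## Questionnaire statistics

Evaluation data for the kind of decision-support tool this engine feeds are
Likert questionnaires (a 4-point/mixed-scale acceptability instrument and
the 18-item, 7-point mHealth usability questionnaire) and "k of n (p%)"
tallies. Conventions implemented: per-item mean and sample SD (n−1; absent,
not zero, for a single respondent, likewise for items with no responses);
an overall summary over per-participant means — the published fractional
range bounds (e.g. a minimum of 4.2 on an integer 1–7 scale) are only
attainable on participant means, which fixes this otherwise ambiguous
convention; and integer percentages by round-half-up in exact integer
arithmetic, which reproduces every recorded count/percent pair in the
shipped tally fixture.

## Numerical and degenerate-input choices

- Percent-consistency tolerance for printed age-table percentages: 0.05
  percentage points (half the last printed digit).
- Fraction sums checked to 1e-9; mixture conservation to 1e-12 (risk scale)
  and 1e-10 (survival scale).
- Baseline event probability 0 (or survival 1) short-circuits to exact
  limits in both modes.
- Cohort fractions computed from data are renormalized to sum exactly to 1
  before table validation.
- Problem sizes in the test and acceptance runs (20,000-patient recovery
  cohort, 1,000 mixture instances, 500 randomized-grid determinism cases)
  were chosen so Monte Carlo noise sits well inside the stated tolerances.

## Known limitations

- Independence across factors and hazard ratios constant over follow-up are
  modelling assumptions inherited from the aggregate data, not testable
  within it.
- Relative-risk mode is biased upward at high baseline risks and may clamp;
  use proportional-hazards mode when cohort risks are large.
- With two age subsets all fitted curves are interpolations; R² carries no
  evidence about the family.
- Estimates carry no uncertainty intervals: the aggregate inputs publish
  none to propagate.
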