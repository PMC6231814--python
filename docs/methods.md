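# Methods

This note records the models, estimators, numerical choices, and known
limitations behind `promval`.

## Estimands and estimators

### Change score and anchor dichotomization

All three instruments score higher = worse, so the change score is
Δ = baseline − follow-up and improvement is positive. The 7-category
transition rating is dichotomized with categories 1–2 ("completely
recovered", "much improved") as improved and 3–7 as not improved. A
change pair enters an analysis only if baseline score, follow-up score,
and the period's transition rating are all present; exclusion is
per-analysis (pairwise), not listwise, so one missing rating removes a
participant only from the analyses that need it.

### Responsiveness (ROC AUC)

The AUC is the exact rank-sum (Mann–Whitney) concordance probability
with ties counted ½ — no binormal smoothing. The standard error is the
moment approximation SE² = [A(1−A) + (n₁−1)(Q₁−A²) + (n₀−1)(Q₂−A²)]
/ (n₁n₀) with Q₁ = A/(2−A), Q₂ = 2A²/(1+A), and the CI is A ± 1.96·SE.
This normal-approximation interval was chosen over DeLong because it is
the same arithmetic that underlies the package's design-stage precision
calculator (±0.12 at A = 0.8 with 25/25), keeping planning and analysis
consistent. The CI is deliberately not clipped to [0, 1]: a bound past
the scale edge is a legible small-sample warning.

### MIC cut-point

Candidate thresholds are the observed distinct change values (integer,
given the instrument grids), evaluated as "Δ ≥ c ⇒ test-positive". The
MIC is the candidate minimizing (1−sensitivity)² + (1−specificity)².
Exact ties are broken toward the smallest threshold — the most
sensitive cut — and each tie is logged. The percent-of-baseline form is
100·MIC / mean baseline of the analysed pairs, rounded to an integer.

### Bootstrap precision and the convergence sweep

The resampling unit is the participant pair, drawn jointly (cases and
controls together), preserving the sampling variability of the case
mix. Replicates that lose an entire anchor class are discarded and
counted; more than 10% discarded raises a result-level warning. The SE
is the SD of replicate cut-points and the CI is symmetric,
point ± 1.96·SE — a percentile interval on a coarse bounded grid
collapses onto a few grid values and cannot express the sign-crossing
lower bounds that small samples genuinely produce. CI endpoints are
additionally reported snapped to the instrument grid (half-up).

Within each replicate the candidate set is that replicate's observed
values, so the replicate estimator is identical to the point estimator.
Implementation: change values are mapped to their value set once, each
replicate is reduced to two histograms (improved / not-improved) over
that set, and suffix/prefix sums give sensitivity and specificity at
every candidate simultaneously; values absent from a replicate are
masked out before the argmin. This makes a full sweep (sum of 20…6000
replications ≈ 9·10⁵ replicates) run in seconds.

The sweep computes an independent bootstrap SE at each grid point
(300 points, 20…6000 step 20) and reports `converged_at`: the first
grid point after which the coefficient of variation of the SE over the
next 10 grid points is below 2%. Because the sampling noise of an SE
estimate shrinks like 1/√B, this rule typically fires in the high
hundreds to low thousands of replications; the package default of 5000
replications sits comfortably beyond it. Visual assessment is available
via `ConvergenceSweep.plot`.

### Reliability

The ICC is two-way random effects, single measure, absolute agreement —
ICC(A,1). Agreement (not consistency) is the only defensible form for
test-retest purposes, since consistency forgives systematic
occasion shifts and overestimates reliability; the consistency ICC is
computed alongside and exposed on the result for comparison, never
reported as the headline. The CI uses the F-based method with
Satterthwaite degrees of freedom. Variance components come from the
expected mean squares (σ²_subject = (MS_S−MS_E)/2,
σ²_occasion = (MS_O−MS_E)/n, σ²_error = MS_E); negative estimates —
likely at the n≈15 sizes these analyses often face — are truncated to
zero and flagged on the result. SEM uses the agreement-consistent
components form √(σ²_occasion + σ²_error) rather than SD·√(1−ICC); the
consistency SEM (√MS_E) is also exposed. MDC₉₅ = 1.96·√2·SEM is an
exact identity on every result.

Stable-participant selection: `per_protocol` keeps transition = 4 ("no
change") only; `about_the_same` keeps 3–5, the wider definition used
when strict stability yields too few observations.

### Anchor validity

Pearson correlations of the numeric 1–7 rating with baseline and
follow-up scores, and nested OLS models
(rating ~ follow-up, then + baseline) compared by the likelihood-ratio
statistic n·ln(RSS₀/RSS₁) on χ²(1). Treating the ordinal rating as
numeric matches standard practice for this diagnostic; an
ordinal-aware variant is out of scope. The nested-OLS likelihood-ratio
reading is this package's interpretation of the significance test for
the added baseline term; survival-style log-rank machinery has no
object in this setting. Near-collinear baseline/follow-up columns are
flagged (condition number > 10¹⁰) with the statistic still returned
when computable.

### Precision calculators

ICC: half-width = 1.96·(1−ρ²)·√(2/(k(k−1)n)) — the large-sample SE of
an intraclass correlation with k replicates. AUC: 1.96 times the
moment-approximation SE above. Both reproduce the conventional design
figures (±0.14 at ρ = 0.7, ±0.10 at ρ = 0.8, ±0.12 at A = 0.8, all at
n = 50).

## Cohort handling

The wide CSV schema (see `cohort_schema.md`) carries an explicit
per-timepoint submission marker because the disability-questionnaire
zero-imputation rules are conditional on a submission having been made,
which a blank cell alone cannot encode. The rules: before the "none of
the above" box existed, (a) a blank baseline questionnaire with a
baseline submission is imputed 0; (b) a blank follow-up questionnaire
with a follow-up submission is imputed 0 only when baseline > 0. An
untouched pain slider submits an explicit 0 and is kept as valid; the
0–10 rating is a required field and never imputed — a missing value
despite a submission is logged as a data anomaly rather than raised as
an error, since real platforms produce such rows. Imputation is
idempotent and every event is logged. Missingness is a first-class
state distinct from 0.

Flow percentages are displayed half-up: 1 decimal for
inclusion/enrolment, 0 decimals for recovery summaries. Cumulative
recoveries sum the per-period recovery counts, with all included
baseline participants as the percentage denominator. Score summaries
are median (IQR) with linear-interpolation quartiles.

## The synthetic cohort generator

The generator defines the study conditions under which the pipeline is
exercised. Each participant carries a shared latent severity
z ~ N(0,1); instrument baselines are mean_i + sd_i·(0.7z + √(1−0.7²)ε),
with defaults (5, 4.5), (41, 22), (5, 2.6) for the 0–24, 0–100, and
0–10 scales, chosen so baseline medians/IQRs land near a typical
community low back pain cohort (0–10 median 5, IQR ≈ 4). Observed
scores add instrument measurement error (SDs 1.5, 10, 1.0) and
clip-and-round to the grid.

True improvement over a period, in severity-SD units, is
δ = μ[chronicity, period] + γ·z + 0.7·u with γ = 1 by default and u
sharing a component across periods. γ = 1 means follow-up severity is
independent of baseline severity (full regression to the mean); this is
what lets the generator reproduce the well-documented empirical
finding that a transition rating correlates with follow-up score but
not with baseline score. Default change means: acute/subacute 1.15 (1
week) and 1.90 (6 weeks); chronic 0.35 and 0.75 — acute back pain
mostly recovers, chronic improves modestly.

The anchor latent is a = w_f·(−z_fup)/s_f + w_c·δ/s_c + w_n·ε with
defaults w_f = 0.6, w_c = 0.2, w_n = 0.2: predominantly follow-up
state, weak change component, noise. The components are scaled by their
population SDs but not centered, so the improved fraction is monotone
in the true-change mean. Six ascending thresholds cut a into the 7
categories. The default thresholds (−0.819, −0.415, −0.060, 0.299,
0.724, 1.542) were frozen from a single large-sample calibration at the
default parameter set, targeting category shares of 20/34/18/12/8/5/3%
(top to bottom) at 1 week — i.e. ≈54% improved among respondents, ≈12%
"no change" — with chronic share among the broadly stable near 63%
under the default 45% chronic mix, and ≈76% improved at 6 weeks.
Attrition is independent per period (58% by 1 week, 80% by 6 weeks),
and 76.9% of enrollees carry the low-back-pain inclusion flag. With
575 enrolled this yields ≈190 1-week change pairs per instrument.

Test-retest mode (`generate_test_retest`) draws two occasions with no
true change: between-subject SD σ_b from the instrument baseline and
error SD σ_b·√((1−ρ)/ρ), so the latent population ICC equals the
`icc_target` by construction. Grid rounding and bound clipping
attenuate the realized ICC slightly — negligible on the 0–100 scale
(parameter recovery lands within 0.02 of the target at n = 2000),
worth a percentage point or two on the coarse 0–10 grid.

What the generator does *not* emulate, hence what passing tests do not
show about real data: platform/device effects; informative attrition
(dropout is independent of severity and improvement); item-level
response processes (only summed scores exist); floor-effect skew beyond
what clipping a normal produces; and recall or panel-conditioning
effects between occasions. One consequence worth knowing: participants
selected as anchor-"stable" in the full generator still carry residual
true change (the anchor is mostly follow-up state plus noise), so ICCs
computed on those subsets understate the instruments' intrinsic
reliability — by design, that bias direction matches the caveat that
treatment-embedded test-retest designs rest on the anchor's stability
classification being valid. The dedicated test-retest mode is the
clean reliability benchmark.

## Numerical and degenerate-input choices

- Half-up rounding everywhere a displayed value is rounded (so 76.85 →
  76.9, not banker's rounding).
- AUC/MIC require both anchor classes; single-class inputs raise a
  distinct `DegenerateClassError` (the pipeline converts it to a skip
  reason rather than aborting).
- Zero total variance makes the ICC undefined (error); roundoff-scale
  negative variance components are clamped without flagging, genuinely
  negative estimates are clamped and flagged.
- MIC objective ties: smallest threshold, logged.
- Pipeline block seeds are derived deterministically from the single
  config seed, so reruns are byte-identical (timestamps excluded).

## Problem sizes

Default analyses run at the generator's cohort scale (575 enrolled,
≈190 1-week pairs) with 5000 bootstrap replications; the test suite
uses 200–2000-replication bootstraps, a 1000-cohort Monte-Carlo for CI
calibration at n = 50, n = 2000 for ICC parameter recovery, and 10⁴
observations for the MIC consistency check — sizes at which the checked
quantities are stable to well within their asserted tolerances.
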