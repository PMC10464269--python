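# Methods

This note records the statistical model, the processing conventions, the
synthetic-cohort design and the numerical choices behind `actimet`, in
enough detail to re-derive every default.

## 1. Accelerometer processing

**Input.** One label per 5-second epoch per participant, from a fixed
vocabulary: six activities (`lying`, `sitting`, `standing`, `walking`,
`running`, `cycling`) plus `nonwear`. Streams must start on a whole minute
and contain whole minutes (12 epochs each); ragged input is an error, not
silently padded.

**Minute smoothing.** Each minute takes the majority label of its 12
epochs. Ties go to the label of the earliest epoch among the tied labels —
a deterministic rule that makes the vote order-dependent only in the tied
case, and which the validation suite checks exhaustively against a
brute-force counting oracle over all 12-epoch multisets on 3 labels
(including shuffled orders).

**Day selection.** The first and last calendar dates are removed
(attachment/detachment artefacts); fewer than three distinct dates
therefore leaves nothing and warns. Only complete 1440-minute days are
kept. If a day contains more than 60 minutes of non-wear, that day *and
all following days* are excluded (the monitor is treated as no longer
reliably worn from that point on); exactly 60 minutes is still acceptable.
A participant enters analysis with at least one weekday and one weekend
day (strict variant: at least three weekdays and one weekend day).
Every exclusion is recorded with a reason in the participant-flow table.

**MET minutes.** Daily MET minutes per label are minutes × MET value with
lying 1.0, sitting 1.3, standing 1.8, walking 2.8, running 7.0,
cycling 4.0; `nonwear` contributes zero. A walking value of 3.3 (the IPAQ
convention) is available as a variant for sensitivity analyses. Categories
sum labels: sedentary = lying + sitting; on feet = standing + walking +
running + cycling; on the move = walking + running + cycling;
running/cycling = running + cycling — so the last three nest, an invariant
the tests enforce. Weekly values are 7 × daily means. Guideline
compliance is daily running/cycling MET minutes ≥ 600/7 ≈ 85.7 (the
600 MET min/week recommendation spread evenly over the week).

## 2. Questionnaire scoring

**IPAQ short form.** Weekly MET minutes per category are
MET × days × minutes/day with walking 3.3, moderate 4.0, vigorous 8.0.
A response is *invalid* when total reported activity exceeds 960 min/day
or activity plus sitting exceeds 1440 min/day; *incomplete* when a
days/minutes pair is partially missing. Invalid responses are never
scored; incomplete ones are scored only in an explicit partial mode that
treats missing categories as zero. The low/moderate/high classification
implements the protocol criteria (high: ≥3 vigorous days and
≥1500 MET min/week, or ≥7 combined days and ≥3000; moderate: ≥3 vigorous
days of ≥20 min, or ≥5 walking/moderate days of ≥30 min, or ≥5 combined
days and ≥600 MET min/week), with combined days capped at 7. The
classifier is validated against an independently written criteria
evaluator on the exhaustive grid of days 0–7 × minutes
{0, 10, 20, 30, 60, 120} per category (110,592 cases), and by a
monotonicity property: more reported activity never lowers the level.

**SF-36.** Items are recoded to "higher = better", summed per domain and
linearly transformed to 0–100. A domain is scored when at least half its
items are answered, missing items imputed with the person's domain mean
(the half-scale rule); otherwise it is missing. Component summaries are
T-scores, 50 + 10 × Σ coefficient × z(domain). The bundled norm means,
SDs and factor coefficients are *illustrative* values with the standard
qualitative structure (physical domains load on PCS, mental on MCS); the
licensed population weights are not redistributable. Studies with their
own norms pass a `NormCoefficients` object.

## 3. Inference

**Estimands.** Group differences are the group coefficient of OLS
`outcome ~ group + sex (+ optional covariates)`, i.e. SGA minus control
adjusted for sex; categorical covariates (month of assessment) enter as
indicator sets, continuous ones (weekly work hours) as-is, with listwise
deletion logged per variable. Activity–HRQoL associations fit
`PA ~ SF36 + group + sex + SF36×group`; the reported group-specific slopes
are in MET minutes per SF-36 point (the PA category is the dependent
variable), and the interaction coefficient tests whether the slopes
differ.

**BCa bootstrap.** Uncertainty comes from case resampling: participants
are resampled within group (preserving group sizes) B times (default
2000) and the full regression is refit per resample. The bias correction
z0 is the normal quantile of the fraction of bootstrap replicates below
the point estimate (ties counted half, clamped to [1/(B+1), B/(B+1)]);
the acceleration is the jackknife skewness estimate
a = Σd³ / (6 (Σd²)^{3/2}) with d the jackknife deviations. Interval
endpoints are quantiles of the bootstrap distribution at the adjusted
levels. Quantiles use numpy's `median_unbiased` method: with small B the
default linear interpolation gives systematically too-narrow tails, which
measurably inflated the type-I error (≈6.9% → ≈5.4% at B=200 in paired
simulation). P-values invert the interval over a fixed alpha grid
(0.001–0.999, step 0.001): p is the smallest grid alpha whose (1−alpha)
interval excludes the null value, so "p < alpha" and "interval excludes
0" can never disagree — an invariant the tests check directly. Degenerate
(zero-variance) bootstrap distributions yield a zero-width interval with
a warning rather than an error.

**Calibration (measured, not assumed).** At the default design scale
(groups of 40 and 48) the machinery achieves: 95% BCa coverage of a
Gaussian mean 93.9% (1000 replicates, B=1000); type-I error of the
adjusted group test 5.4–6.8% across seeds (3000 replicates, B=200) —
mildly anti-conservative, a known small-sample property of
percentile-type bootstrap tests that worsens markedly below ~20 per group
(≈8–9%); CI coverage ≥90% for an injected −50 MET min/day group effect
and a 4.0 MET min/PCS-point interaction slope (100 replicates, B=500).
These studies are reproducible via `actimet.calibration` and
`scripts/acceptance.py`.

**Classical tests.** Two proportions are compared by Pearson chi-square
without continuity correction (flag available); Spearman correlations via
mid-ranks; ordinal descriptive variables by a permutation Mann–Whitney
test (exhaustive enumeration when total n ≤ 12, else seeded Monte-Carlo
with 100,000 permutations); continuous descriptives by Student's t-test.
The minimum detectable standardized difference is
(z_{1−α/2} + z_{power})·√(1/n₁ + 1/n₂) in the normal approximation (0.469
for groups of 64 and 81 at α=0.05, power 0.80), with an exact
noncentral-t mode that gives slightly larger values.

## 4. Synthetic cohort

**Activity.** Each participant has an expected daily minute budget per
label, summing to 1440, anchored to group-level budgets chosen so the
default cohorts land near published-scale category MET means (sedentary
≈1240/1260, on feet ≈710/680, on the move ≈220/230, running/cycling
≈46/37 MET min/day for SGA/control). Running/cycling volume is strongly
right-skewed between people, so each participant's running/cycling MET
minutes are drawn from an exponential with the group-budget mean (the
group mean is preserved; the spread makes realistic guideline-compliance
fractions possible at all). Days realize the budget with truncated-normal
day-to-day noise (SD 25 min), lay labels out as exponential-length bouts
(walking mean 7 min, so bouts straddle the questionnaire's 10-minute
threshold), and force a 23:00–07:00 lying block. Non-wear episodes arrive
as a Poisson process (default 0.2/day) with lognormal durations; a heavy
tail occasionally produces the >60 min gaps that exercise the exclusion
rule.

**Activity–HRQoL coupling.** PCS and MCS are drawn exogenously
(mean 50, SD 10). The participant's walking budget is then adjusted so
that expected on-the-move MET minutes equal
baseline + group_effect + β_group·(PCS − 50) + N(0, 100²). Putting the
noise on the activity side (rather than generating PCS from activity)
keeps the configured slope recoverable by the regression without
errors-in-variables attenuation — the design choice that makes parameter
recovery a fair test of the estimator.

**Self-report coupling.** Reported walking equals true walking in bouts
of ≥10 minutes plus large recall noise (SD 60 min); reported
moderate/vigorous activity equals true cycling/running times an
overestimation factor (default 1.5) with a third of the noise. This
reproduces the field's pattern: self-report correlates poorly with
device-measured walking and much better with running/cycling, and
overstates MVPA. Configurable fractions of responses are made incomplete
(30%) or implausible (2%); 2% of SF-36 forms lose a domain.

**Reproducibility.** Every draw comes from
`SeedSequence(master_seed, spawn_key=crc32(names))` substreams keyed by
stage and participant id, so any participant can be regenerated in
isolation and whole cohorts are byte-identical under a fixed seed. A fast
path (`materialize_epochs=False`) skips the 5-second streams and emits
only daily truth minutes, two orders of magnitude faster, for simulation
studies.

## 5. Pipeline conventions

Outputs are delimited text with floats at `%.6g`, no timestamps, and a
SHA-256 content hash over all tables recorded in the report — so
identical config + seed implies byte-identical artefacts. Flow accounting
(recorded → trimmed → non-wear rule → inclusion) is monotone
non-increasing and every excluded participant carries a reason. Default
problem sizes (40/48 participants, 7 days, B=2000) are package choices
matching the emulated design scale; the demo pipeline completes in a few
seconds on one CPU.

## 6. Limitations and open choices

- The SF-36 component coefficients are illustrative; absolute PCS/MCS
  values are not comparable to licensed-scoring studies (slopes per point
  are, approximately, because the T-score scale is preserved).
- The group test is mildly anti-conservative at small n (see §3);
  analyses with fewer than ~20 per group should increase B and interpret
  p-values near 0.05 cautiously.
- The bootstrap p-value's resolution is bounded by the alpha grid floor
  (0.001) and by B; values at the floor mean "at or below".
- The generator models weekly structure only through the
  weekday/weekend day labels, not through different weekday/weekend
  budgets; seasonal effects enter only via the month-of-assessment
  covariate being available for adjustment, not via true seasonal
  activity variation.
- Non-goals: mixed models, survival analysis, multiple imputation,
  multiplicity adjustment, plotting beyond the text report.
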