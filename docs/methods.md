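# Methods

## The problem

When the same questionnaire is administered through different channels —
here internet self-completion versus a telephone interview — two things can
move the observed scores apart: *selection* (different kinds of people
respond in each arm) and the *mode effect proper* (an interviewer tends to
elicit rosier answers).  The package separates the two by comparing scores
before and after propensity-score matching of responders across arms: if
the matched (covariate-comparable) difference remains close to the
unmatched one, selection on the observed covariates explains little, and
the residual difference is attributed to the mode of administration.

## SF-36 scoring

Each of the 36 precoded answers is recoded to a calibrated value; 35 items
form 8 scales (PF 10, RP 4, BP 2, GH 5, VT 4, SF 2, RE 3, MH 5 items), and
the health-transition item (item 2 in the standard v1 ordering) enters no
score.  A scale's raw sum is normalised to 0–100 by its attainable range.
Validity follows the half-scale rule: a scale is scored only when at least
`ceil(k/2)` of its k items are answered (so 2 of 3 for an odd scale, the
strictest reading of "at least half"); missing items are then imputed with
the respondent's mean over the answered items of that scale, which is
algebraically equivalent to rescaling the mean of the answered items.
The component summaries are norm-based factor scores,
`50 + 10·Σ w·z`, with z-scores against general-population norms.

All numeric tables live in `data/sf36_v1_default.yaml`: item–scale
assignments, recode tables (including the standard reverse-coded items and
the two empirically recalibrated ones — the general-health rating and pain
intensity), scale ranges, the 1990 US general-population norm means/SDs
and the PCS/MCS factor-score coefficients.  Every table can be overridden
from a user YAML, e.g. to substitute French norms.  Two deliberate
conventions:

* **Pain interference (item 22).** The scoring manual's recode for this
  item conditions on the pain-intensity answer.  The package's
  `ScoringSpec` is a declarative per-item table (a total map from codes to
  values), so the unconditional variant (6, 4.75, 3.5, 2.25, 1 — the
  manual's own rule when pain intensity is missing) is shipped as the
  default.  The difference only affects respondents reporting no pain at
  all but some pain interference, an uncommon and arguably inconsistent
  pattern.
* **Full precision.** Scores are computed in floating precision; rounding
  to 2 decimals happens only in reports.

## Reliability

Cronbach's α per scale on complete cases (listwise deletion per scale),
sample variances (n−1).  The acceptability gate is strict: α > .7.
Zero-variance items are retained with a warning; a zero-variance total
raises an error since α is then undefined.

## Propensity matching

The propensity of being an internet responder (rather than a telephone
responder) is modelled by maximum-likelihood logistic regression on age,
length of stay, education, employment, income, relationship status,
insurance, plus the three exact-match variables (sex, type of
hospitalization, ward).  Categorical covariates use indicator coding with
the most frequent level as reference; income's "no response" is kept as
its own level rather than dropping those subjects; age and length of stay
enter linearly.  The fit is delegated to statsmodels' IRLS
(`GLM(..., Binomial)`, tol 1e-10, 100 iterations).  A handful of
boundary propensities (quasi-separation on a rare covariate pattern) is
tolerated with a warning; more than 5% of subjects at the boundary, or
complete separation, raises an error advising covariate coarsening.

Matching is greedy 1:1 nearest-neighbour on the propensity score, without
replacement and without caliper: treated subjects in decreasing propensity
order, ties broken by smallest id; eligible controls must agree exactly on
sex, type of hospitalization and ward.  A treated subject with no eligible
control is recorded unmatched with a warning rather than failing the run.
These determinism rules make re-runs bit-identical.

Balance is diagnosed with standardized mean differences:
`(mean_t − mean_c)/sd_ref`, with `sd_ref = sqrt((s_t² + s_c²)/2)` for
continuous terms and the pooled binomial SD for indicators, both computed
**before** matching and held fixed afterwards so post-matching SMDs
isolate mean movement.  The headline "global distance" SMD is computed on
the propensity scale (the linear-predictor version is also reported), and
the balance improvement is `100·(|before| − |after|)/|before|`.

## Group comparison

For each of the 10 measures: medians/IQRs, means/SDs, a bootstrap
percentile CI of the mean (10,000 resamples, seeded — chosen because the
reported intervals of such tables are asymmetric around the mean, which a
normal-theory CI cannot produce), the telephone-minus-internet mean
difference, a two-sided Wilcoxon–Mann–Whitney test, Cohen's effect size,
and the 5-point relevance flag (strictly greater than 5).

* **Rank test.** Exact permutation enumeration of the rank-sum
  distribution whenever n₁+n₂ ≤ 20 — computed on midranks, so ties are
  handled exactly; two-sided p is twice the smaller tail, capped at 1.
  Larger samples use the normal approximation with tie-corrected variance
  and continuity correction.  Empirical type-I error at n=245 per arm is
  ≈0.048 at nominal 0.05 (checked in the test suite over 5,000 null
  simulations).
* **Effect size.** `d = (m₂ − m₁) / ((s₁ + s₂)/2)` — the arithmetic mean
  of the group SDs as denominator.  With similar SDs this is numerically
  close to the root-mean-square pooled SD, and it is the convention that
  reproduces published matched-comparison tables of this design exactly at
  2 decimals; the test suite pins all ten worked examples.
* **Proportions.** Response rates are compared with the chi-square test of
  independence without continuity correction when all expected cells are
  ≥ 5, otherwise Fisher's exact test.
* **Multiplicity.** No multiple-testing adjustment is applied across the
  10 measures, mirroring the design this pipeline reproduces; the run log
  notes this.

## Synthetic cohorts

The generator emulates the structure the analysis assumes — it is the
package's testbed, not a model fitted to any dataset.

* **Covariates.** Drawn independently per subject from configurable
  marginals (`data/table1_like.yaml` defaults: the pooled baseline
  frequencies of a 1,680-patient two-arm posthospitalization cohort from
  5 wards); age is rounded truncated normal (47 ± 15), length of stay
  rounded lognormal (median ≈ 1.6 days, long right tail).  Both arms share
  the same covariate distribution, as in a randomized trial.
* **Nonresponse.** A logistic model in the covariates with per-arm
  intercepts *calibrated on the realized cohort* (scalar root-finding) so
  each arm's expected response rate hits its target — defaults 0.292
  (internet) and 0.75 (telephone).  Covariate coefficients create
  selection bias; setting them to zero gives a no-selection world.
* **Latent scores.** Per scale s:
  `T = μ_s + loadings·x + σ_s·(√ρ·u + √(1−ρ)·e) + δ_s·1[telephone]`,
  truncated to [0, 100], with a shared person factor u (ρ = 0.6) so the 8
  scales correlate as real profiles do.  The interviewer effect δ_s is
  additive on the latent 0–100 scale *before* item generation, so it must
  survive the full scoring pipeline to be recovered.  The default δ vector
  (4.57, 9.39, 4.56, 0.04, 0.82, 7.96, 9.93, 5.01) is a realistic preset
  patterned on observed matched telephone–internet differences; it is a
  preset, not ground truth.
* **Items.** Each item's calibrated values are placed on [0, 1]; the
  jittered latent position `u = clip((T + ε)/100)` (ε ~ N(0, 6)) is mapped
  to an answer by *stochastic rounding* between the two adjacent
  categories.  This makes the reported value conditionally unbiased for
  the latent position, hence the scored scale conditionally unbiased for
  T — the property that lets an injected shift pass through scoring
  undistorted.  Answered items are blanked at rate 0.01.

Two structural limits are worth knowing.  First, binary-item scales (RP,
RE) are intrinsically coarse: any conditionally unbiased binary item is
Bernoulli, so its variance is irreducible.  The default latent SDs for
RP/RE (62/58) place realistic mass at the scale bounds — reproducing the
bimodal role-score distributions and observed SDs (≈ 41/40) of real data
and keeping all 8 α values above .7 — but latent-score recovery
correlations are ≈ 0.91/0.87 there versus ≈ 0.94–0.96 for the polytomous
scales (the suite asserts a mean over scales > 0.9).  Second, truncation
at [0, 100] attenuates an injected shift in proportion to the mass at the
bounds; with the wide role-scale defaults a 9–10 point δ is visibly
compressed.  Recovery *experiments* therefore use mid-range settings
(means 55, SDs 18), where the matched estimate recovers a 5-point shift
to within 0.5 points averaged over 100 replicates at 840 per arm — the
problem size used throughout, matching the emulated trial's arms.  The
generator draws everything from a single numpy Generator, so identical
config + seed reproduces cohorts bit-identically.

What passing tests show — and don't.  The generator's world is ignorable
selection through *observed* covariates, independent item noise and an
additive mode shift; real mixed-mode data may violate any of these
(latent-driven nonresponse, differential item functioning, non-additive
interviewer effects), and the matched comparison identifies the mode
effect only under the observed-selection assumption.

## Pipeline and reproducibility

`run_pipeline` chains simulate/ingest → score → reliability → match →
compare, writes each artifact as CSV (UTF-8, comma-separated, blank/`NA`
missing), logs one structured line per stage with counts, and records
seed, config hash and version in `run_log.json`.  All randomness flows
from the single configured seed; inputs are never mutated.  Stage
failures abort with a stage-tagged message (exit 1 for user errors, 2 for
internal ones in the CLI).
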