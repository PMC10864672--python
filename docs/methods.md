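# Methods note

This note documents the statistical model behind `runiei`, the parameter
defaults and why they were chosen, what the synthetic cohort generator does
and does not emulate, and the numerical decisions that affect results.

## 1. ST-IAT G-Score

**Task structure.** Five blocks: B1 (24 trials, affective categories only,
12 smiley / 12 frowny), B2 and B4 (44 trials, 12:12:20
smiley:frowny:runner), B3 and B5 (84 trials, 24:24:36). B2/B3 pair the
target (running) with negative stimuli, B4/B5 with positive stimuli. Trial
timing constants (700 ms fixation, 1200 ms inter-trial interval) are
recorded as metadata only.

**Scoring** (`runiei.stiat`):

1. Participants with strictly more than 10 % of their 256 scored (B2–B5)
   trials faster than 300 ms are excluded (`g = NaN`); fast trials of
   retained participants are kept.
2. B1 is dropped; error trials are retained untreated (the rank transform
   rather than an error penalty handles atypical responses).
3. Pooled RTs are winsorized at 10 % per tail; quantiles use linear
   interpolation between order statistics.
4. Fractional (average-tie) ranks are converted to mid-rank percentiles
   `p = (rank − 0.5)/N` and mapped through `Φ⁻¹`. The mid-rank offset keeps
   extreme deviates finite. An alternative `"zscore"` convention
   (z-standardized percentiles) is available for sensitivity analyses.
5. `G = mean(deviates | negative condition) − mean(deviates | positive
   condition)`; positive G = positive implicit association.

**Reliability.** Stratified Monte-Carlo split-half: within each stratum
(association condition × stimulus type) trials are split into two disjoint
random halves (an odd trial joins a half at random; a bootstrap scheme that
draws both halves with replacement is available), each half is scored
through the full pipeline, half-scores are correlated across participants
(Pearson by default), and the replication correlations are averaged with
**no Spearman–Brown correction** — the estimate describes half-length
tests, matching the reference analysis. Library default is 10 000
replications; the pipeline default uses 500 (r_mean stabilizes to ±0.01
well below that; the SD across replications is reported).

## 2. IEC / IED components

`runiei.iei` z-standardizes (sample SD, ddof = 1) the G-Scores and explicit
ratings of the *analyzed* sample (ST-IAT exclusions dropped listwise) and
eigendecomposes their 2×2 correlation matrix. Components are identified by
loading pattern, not eigenvalue order: same-sign loadings → concordance
(IEC), opposite-sign → discrepancy (IED), oriented so IEC loads positively
on both inputs and IED positively on the explicit input. Scores are
divided by the component SD, so both have mean 0 / SD 1 in the fitted
sample; they are sample-relative quantities by construction. Degenerate
inputs (constant columns, |ρ| ≥ 1, missing values) raise.

## 3. Clustering

`runiei.clustering` provides, on the (IEC, IED) plane:

- a Ward linkage tree (cluster-number diagnostic; within-cluster sum of
  squares per k = 1…9 is exported for the elbow inspection),
- crisp k-means (scikit-learn backend, best of `n_starts`),
- fuzzy c-means, implemented in-package (no maintained fuzzy-clustering
  dependency is available): m = 2.0, k = 4, 25 random membership
  initializations, ≤ 1000 iterations per start, convergence when the
  maximum membership change is below 1e-9. Memberships at zero distance
  are handled exactly.
- diagnostics: Rand index between fuzzy-hard and crisp partitions, optimal
  fuzzy→crisp relabeling (Hungarian assignment on the confusion matrix),
  row-percentage overlap table, mean-membership-by-cluster table, and the
  unclear-assignment flag (max membership < 0.5).

Pattern labels for k = 4: largest IED center → *positive discrepant*,
smallest IED → *negative discrepant*; of the remaining two, larger IEC →
*positive non-discrepant*, smaller → *negative non-discrepant*.

## 4. Group comparisons

`runiei.compare`:

- Kruskal–Wallis with tie correction (χ² approximation, df = k − 1); the
  effect size is the rank η² `(H − k + 1)/(n − k)`, clipped at 0. An
  all-constant pooled sample is defined as H = 0, p = 1.
- Pairwise two-sided Mann-Whitney tests with Bonferroni adjustment over
  k(k−1)/2 pairs. The exact null distribution is used when the pooled pair
  is tie-free and both groups have ≤ 25 observations; otherwise the normal
  approximation with tie and continuity corrections. (The approximation
  errs by up to ~0.04 at n = 3 and ~0.01 at n = 8, so small untied samples
  need the exact path.)
- Fisher exact test for r×c tables: full enumeration of the fixed-margins
  table space summing probabilities of all tables no more probable than the
  observed one (probability comparisons use a 1e-7 log tolerance). When
  the enumeration would exceed `max_tables` (default 10⁶) candidate
  tables, a Monte-Carlo estimate over Patefield draws is used with the
  add-one estimator `p = (1 + hits)/(n_mc + 1)`. The Pearson χ² statistic
  is reported alongside. Zero rows/columns are dropped first.

## 5. Questionnaires

`runiei.questionnaires`: SSK subscale means (3 items each on 1–6;
intrinsic, identified, introjected, extrinsic; the item→subscale map is
configurable) and the self-concordance index
`(intrinsic + identified) − (introjected + extrinsic)`; 8-item EHI
laterality quotient `100·Σw/16` with classes left ≤ −50 / right ≥ +50 /
ambidextrous between; running-behavior categories (0 runs/week = non,
< 1 = irregular, ≥ 1 = regular); Cronbach's α; moment descriptives with
sample SD, moment skewness `m₃/m₂^1.5` and non-excess kurtosis `m₄/m₂²`
(normal ≈ 3).

## 6. Synthetic cohort generator

No public data accompany the reference cohort, so `runiei.simulate` plants
a known structure and every downstream claim is tested as parameter
recovery.

**RT model.** Ex-Gaussian, `rt = μ + σ·N(0,1) + Exp(τ)` with defaults
μ = 450 ms, σ = 80 ms, τ = 150 ms and a 180 ms floor — a standard
positively skewed RT family with realistic IAT-scale latencies. A 5 %
error rate marks trials incorrect (errors are retained in scoring, so they
need no RT penalty). An optional `fast_guess_rate` replaces trials with
uniform 150–299 ms guesses to exercise the exclusion rule.

**Condition effect.** The implicit association is a pure location shift
between conditions, applied as *slowing of the association-incongruent
condition only* (a positive planted G slows the negative condition, never
speeds the other). A symmetric ± shift/2 scheme would push the speeded
condition under 300 ms at large planted |G| and spuriously trigger the
fast-responder rule; with slowing-only, uncontaminated sessions always
pass it.

**Shift calibration.** The rank transform admits no closed form for
E[G | shift], so a `ShiftCalibration` object estimates the map empirically:
200 base sessions are drawn once (common random numbers) and rescored under
each candidate shift on a 33-point grid over ±800 ms. Under common random
numbers the curve is smooth and increasing but saturates near ±1.51 (G is
bounded once the conditions separate completely) and the RT floor makes the
saturated tails wobble slightly, so only the contiguous strictly increasing
run around zero shift is kept. Planted values are inverted by bisection
(single targets) or grid interpolation (whole cohorts); targets outside the
achievable range raise. The zero-shift SD across calibration sessions
(≈ 0.12) is recorded as the scoring measurement SD.

**Population.** Four latent profiles with sizes 36/16/20/17 (n = 89).
Per-profile means/SDs of the implicit and explicit association, the four
SSK subscales, intention and effort, plus running-behavior and
past-experience category frequencies, are calibrated to the printed
per-cluster summaries of the reference cohort. Because those implicit SDs
describe *observed* (scored) G values, latent planted values are drawn with
variance `max(sd_obs² − σ_meas², (0.25·sd_obs)²)` — the measurement
variance of the scoring procedure is deconvolved, with a floor so the
latent SD never collapses. Questionnaire responses are normal draws
discretized and clamped to their scales (SSK items add item-level noise of
SD 0.5 around the subscale latent); `runs_per_week` is drawn consistently
with the behavior category; EHI item patterns are rejection-sampled to
match the drawn handedness class; age, occupation, main exercise and
handedness frequencies are cohort-level.

A `separation_scale` factor widens each profile's implicit/explicit mean
deviation from the size-weighted grand mean (explicit means clipped to
0–10); the parameter-recovery tests use a tripled separation, where the
fuzzy partition recovers the planted labels essentially perfectly.

**What is not emulated:** response processes beyond a location shift
(no speed–accuracy trade-off, practice, or fatigue effects; block order is
fixed, not counterbalanced), within-session RT autocorrelation,
item-level stimulus effects, and any missing-data mechanisms. Simulated
questionnaire items are conditionally independent given the profile, so
between-variable correlations arise only through the profile structure.

## 7. Problem sizes and runtime defaults

- Cohort: 89 participants × 280 trials (≈ 25 000 rows); generation ≈ 1 s.
- Reliability: 500 replications (pipeline default) ≈ 10 s for 89
  participants; the library default of 10 000 matches the reference
  procedure when runtime is not a concern.
- Fuzzy clustering: 89 × 2 points, 25 starts — milliseconds.
- Fisher tests: the 4×3 running-behavior table enumerates exactly; larger
  tables (e.g. 4×5 past experience) typically fall back to Monte-Carlo
  with 100 000 draws (pipeline default).

## 8. Reproducibility

A single master seed fans out to per-stage seeds via
`numpy.random.SeedSequence([master, stage_index])` with the fixed stage
order simulate = 0, reliability = 1, clustering = 2, comparison = 3; stages
are therefore independently rerunnable. `manifest.json` records the
configuration, stage seeds and SHA-256 checksums of all artifacts; reruns
with an identical configuration are byte-identical.

## 9. Limitations

- IEC/IED (and hence cluster structure) are sample-relative; scores from
  different samples are not directly comparable.
- The η² formula is the standard rank-based estimator; it can exceed the
  "variance explained" of specific group patterns under heavy ties.
- Monte-Carlo Fisher p-values carry resampling error of order
  `1/sqrt(n_mc)`; the add-one estimator never returns exactly 0.
- The simulator is calibrated to printed summary statistics, not raw data;
  quantities the summaries do not constrain (e.g. within-profile response
  correlations) are conventions and are documented as such.
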