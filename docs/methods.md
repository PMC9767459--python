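# Methods

This note documents the models the package implements, the defaults it
ships, what the synthetic-data generator does and does not emulate, and
the numerical and design choices a maintainer should know about.

## mtDNA copy number estimation

The estimator is the diploid-normalized coverage ratio,
`copies/cell = 2·(mean mtDNA depth)/(mean autosomal depth)`. It operates
on per-sample coverage summaries; extracting mean depths from alignments
(including duplicate filtering and NUMT handling) is upstream-tool
territory and out of scope. Whole-blood estimates are inflated by
platelets, which contribute mtDNA but no nuclear genome; following common
practice the estimate itself is left uncorrected and platelet count and
WBC parameters are instead included as covariates in every association
model. Samples with non-positive autosomal coverage cannot be normalized
and are excluded with a logged reason. The estimator is exactly linear in
mitochondrial depth and invariant to rescaling both depths by a common
factor.

## Association models

Both outcome (mtDNAcn) and each continuous predictor are z-scored with
the n−1 denominator, so trait effects are in SD of mtDNAcn per SD of
trait and comparable across cohorts of different depth and demography.
Binary predictors (sex, CES-D cutoff indicators) stay on their 0/1
coding: their coefficients are per-category differences, which is why
cutoff effects are several times larger than per-SD effects. The default
adjustment set is age, sex, sequence coverage (mean autosomal depth),
platelet count, WBC count, and percent neutrophils, lymphocytes,
basophils, and eosinophils. Percent monocytes is excluded by default
(only marginally related to mtDNAcn in the motivating screen, and
dropping one of the five percentages — which sum to 100 — keeps the
design full rank); the covariate list is a plain argument everywhere.
Missingness is handled by listwise deletion; p-values use the t
distribution with residual degrees of freedom. `percent_difference`
converts a standardized effect into percent change of mtDNAcn via the
SD/mean ratio.

## Meta-analysis and FDR

Cohorts are pooled with the DerSimonian–Laird random-effects estimator:
fixed weights w=1/se² give the fixed-effect mean and Cochran's Q;
τ² = max(0,(Q−(k−1))/(Σw−Σw²/Σw)); random weights w*=1/(se²+τ²) give the
pooled effect, its SE, a Wald 95% CI, and a two-sided normal p;
I² = max(0,(Q−df)/Q)·100. When Q ≤ k−1 (the homogeneous regime), τ²
truncates to zero and the pooled estimate equals fixed-effect pooling, so
with k=2 concordant cohorts the choice of τ² estimator is immaterial.
`se_from_beta_p` inverts a two-sided normal Wald test (se = |β|/z(p/2))
so published per-cohort (β, p) pairs can be pooled without raw data; the
printed-precision rounding of p propagates into the recovered SE at the
third decimal, which is why pooled values are reported at two decimals.
BH-FDR (via statsmodels) is applied over the family of exactly 35
personality traits; CES-D and PMI associations are reported unadjusted.

## Personality-mortality index

One point each for vulnerability strictly below its cohort median and
activity, self-discipline, and competence strictly above theirs; the
index is their sum (0–4). Ties at a median score zero — the scoring rule
is strictly directional, and continuous T-scores make exact ties rare.
Medians are computed within the analyzed cohort, making the index
invariant to cohort-wide monotone transforms; with independent continuous
facets it is Binomial(4, ½). The 2×2 vulnerability/self-discipline
classification uses the same strict splits, with LVHD (low vulnerability,
high self-discipline) as the reference group.

## Survival analysis

`fit_cox` maximizes the Cox partial likelihood with Breslow tie handling
by Newton–Raphson from β=0, halving any step that decreases the
likelihood; convergence is declared when max|score| < 1e−8 or the
relative log-likelihood change is below 1e−10. SEs come from the inverse
observed information. Covariates are centered internally for
conditioning (coefficients are unchanged). Monotone likelihoods (perfect
separation) are detected as non-convergence or a runaway coefficient
(|β| > 15, hazard ratio ≈ 3×10⁶) and raise an error naming the covariate.
Breslow is the simplest consistent tie convention and coincides with
Efron when event times are distinct, which is how the hand-rolled fitter
is cross-checked against lifelines in the tests; tiny fixtures are
checked against brute-force grid + golden-section maximization of an
independently coded partial likelihood. Follow-up time is time since
entry with age as a covariate. Kaplan–Meier curves use the lifelines
product-limit estimator, returned as per-group step functions (time, at
risk, events, survival).

## Mediation

The three-model linear decomposition: c from outcome~exposure+covariates,
a from mediator~exposure+covariates, and (c′, b) from
outcome~exposure+mediator+covariates, all by least squares with the same
covariates (age and sex by default), so c = c′ + a·b holds to machine
precision as an algebraic identity. The binary death indicator is
modeled as a linear probability: that is the only link under which the
additive decomposition is exact, and it keeps all paths in probability
units (the identity fails for logistic links). Exposure and mediator
stay on native scales (PMI points, mtDNAcn copies). The bootstrap
resamples participants with replacement, refits the mediator and outcome
models per resample, and reports the percentile 95% CI of a·b, a
sign-based p-value 2·min(#{a·b ≤ 0}+1, #{a·b ≥ 0}+1)/(B+1), a
normal-approximation z-test on the bootstrap SE, and bootstrap SEs for
each path. Degenerate resamples are redrawn and counted. The default is
5000 resamples; inference is deterministic given the seed.

## Synthetic cohorts

The generator emulates the joint structure the analysis assumes, one
cohort per `SimConfig`:

- **Traits**: 35 NEO-PI-R scores (5 domains, 30 facets) drawn
  multivariate normal on the T-score scale (defaults mean 50, SD 10).
  The published facet intercorrelations are not available, so the
  default correlation is block-structured: r=0.5 within a domain (domain
  plus its six facets), r=0.2 between domains — positive definite by
  construction and qualitatively faithful to the inventory. Because of
  these correlations, planting an effect on one trait induces attenuated
  marginal associations on its neighbors, which is the realistic
  behavior; single-trait recovery checks therefore plant one effect at a
  time. An optional measurement-error SD with a visit-averaging factor
  (0.5 for a four-visit average) emulates multi-visit trait averaging as
  reduced observation noise.
- **Demographics and blood**: age is normal (defaults 74.88 ± 10.86
  years for the older-cohort preset, 57.28 ± 13.24 for the younger);
  sex is Bernoulli with the configured female proportion (0=female,
  1=male, so the lower male mtDNAcn carries a negative sign). CES-D is a
  rounded Gamma matched to configured moments (defaults 5.47 ± 5.66),
  clipped to 0–60. The leukocyte differential is Dirichlet over five
  classes with physiological means (neutrophils 60, lymphocytes 30,
  monocytes 7, eosinophils 2.5, basophils 0.5 percent; precision 120),
  summing to 100 by construction; WBC and platelet counts are truncated
  normals. None of the blood variables affect mtDNAcn in the generator —
  they exist so the adjustment machinery has realistic covariates to
  chew on, and the tests verify the screen's null calibration on them.
- **mtDNAcn**: built on the standardized scale as
  mean + sd·(Σβ_t·z_t + β_age(age−mean) + β_male·1[male] + ε), ε~N(0,1),
  so the marginal SD equals `mtdnacn_sd` when all effects are zero, plus
  `path_a·(PMI−2)` in copies. Defaults 150 ± 41.7 copies/cell: the
  SD/mean ratio 0.278 is back-solved from the equivalence "0.014 SD per
  year ⇔ 3.89% per decade" and the mean is a typical buffy-coat value.
  Copy numbers are floored at 1 (blood always carries some mtDNA) and
  stored at single precision.
- **Coverage**: autosomal depth is Gamma around the configured mean
  (35.8× / 3.8× presets, CV 0.05 by default); mitochondrial depth is
  (mtDNAcn/2)·autosomal·η with η lognormal, mean 1, configurable CV.
  Depths and copy numbers are quantized to 24-bit mantissas, so with
  zero noise the product entering the estimator is exact in double
  precision and the round trip reproduces planted copy numbers *bit for
  bit* — the round-trip contract is exact, not approximate.
- **Mortality**: death probability is the linear mechanism
  p = baseline + c′·(PMI−2) + b·(mtDNAcn−mean), clipped to [0,1] (a
  warning fires if more than half the cohort clips); the event time is
  exponential with the per-person rate solved so P(T ≤ follow-up) = p,
  and times beyond follow-up are censored. The binary indicator and the
  survival times are therefore mutually consistent, and the indicator is
  exactly Bernoulli(p) as the mediation model assumes. For planted
  log-hazard-ratio simulations, `exponential_survival` provides a
  proportional-hazards generator instead. How the real cohorts censor
  administratively is unknown; `followup_years` (default 15) is the
  knob.

With the trait-scale mtDNAcn SD of 41.7 copies, a mediator→outcome path
of −0.02 probability per copy would push most probabilities outside
[0,1]; the planted-mediation preset (`mediation_scenario`) therefore
uses a residual mediator SD of 4 copies (baseline 0.5, a=5, b=−0.02,
c′=−0.05), under which clipping is below 1% and the linear-probability
mechanism genuinely holds. This is a property of the path magnitudes
themselves, not of the implementation. `SimConfig` defaults all path
coefficients to zero — mediation structure is opted into per scenario —
because a nonzero b at trait-scale SD would make the default generator
internally inconsistent.

What the generator does **not** emulate: item-level NEO-PI-R responses,
relatedness/pedigree structure, ancestry stratification, longitudinal
visit schedules, informative censoring, real platelet-driven bias in the
coverage ratio, or any dependence of blood composition on traits.
Passing tests therefore demonstrate that the statistical machinery
recovers what was planted under the stated mechanism — not that the
mechanism is how nature generated any real cohort.

## Problem sizes and determinism

Every stochastic step takes an integer seed (numpy Generator); same seed
means byte-identical output tables. The test suite exercises planted
recovery at n=50,000 (association) and n=20,000 with 1000 bootstrap
resamples (mediation), calibration at 200 replicates (type-I error of
the adjusted association; bootstrap CI coverage under a null indirect
effect at n=400 with 200 resamples each), and replicate-level properties
(CI coverage of a planted β over 50 cohorts; Kaplan–Meier curve ordering
over 40 cohorts of 4000). The analysis scripts use the published cohort
sizes (722 and 587) and 5000 bootstrap resamples.

## Known limitations

- The linear-probability outcome can clip at extreme covariate values;
  the generator warns, and users fitting real data with rare or
  near-certain death should prefer a survival model for inference and
  regard the mediation decomposition as an approximation.
- DerSimonian–Laird with k=2 estimates τ² very noisily; this is benign
  in the homogeneous regime (every headline row here) but pooled SEs
  with k=2 heterogeneous cohorts deserve skepticism.
- SE recovery from printed p-values inherits rounding at the printed
  precision; recovered SEs are accurate to roughly 1%, which is why
  pooled results are compared at two decimals.
- The Cox fitter implements Breslow ties only; heavily tied data
  (discretized follow-up) would warrant Efron weighting, which is a
  non-goal here.
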