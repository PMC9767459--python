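# mitopersona

Blood mitochondrial DNA copy number (mtDNAcn), personality, and mortality:
a tested, reusable analysis pipeline.

## The scientific problem

Mitochondria carry their own genome, and the number of mtDNA copies per
cell in blood is an accessible (if imperfect) proxy for mitochondrial mass
and energetic health. Epidemiological cohorts with whole-genome sequencing
can estimate it essentially for free: sequencing depth is proportional to
template copy number, and each cell carries two copies of the nuclear
genome, so

```
mtDNAcn = 2 · (mean mtDNA coverage) / (mean autosomal coverage)
```

This package implements the full analysis chain that links that estimate
to psychological traits and mortality in two-cohort studies of aging:

1. **Estimation** of mtDNAcn from per-sample coverage summaries, with a
   single-covariate screen (age, sex, sequence coverage, platelet count,
   WBC count, leukocyte percentages) that motivates the adjustment set.
2. **Association**: OLS of z-scored mtDNAcn on each z-scored NEO-PI-R
   trait (5 domains, 30 facets) and on CES-D depressive symptoms
   (continuous and the clinical cutoffs 16/20), adjusting for age, sex,
   sequence coverage, platelet count, and WBC parameters. Effects are in
   SD of mtDNAcn per SD of trait.
3. **Meta-analysis**: DerSimonian–Laird random-effects pooling across
   cohorts (fixed weights w=1/se², Q, τ², I² = max(0,(Q−df)/Q)·100) with
   Benjamini–Hochberg FDR over the 35-trait family, plus recovery of
   standard errors from printed (β, p) pairs so published per-cohort
   results can be pooled without raw data.
4. **Personality-mortality index (PMI)**: one point each for
   below-median vulnerability and above-median activity, self-discipline,
   and competence (0–4), with the 2×2 vulnerability/self-discipline
   cross-classification (LVHD … HVLD).
5. **Survival**: Cox proportional hazards (Newton–Raphson on the Breslow
   partial likelihood, observed-information SEs) and Kaplan–Meier curves
   per PMI level.
6. **Mediation**: the three-model linear decomposition
   c = c′ + a·b — outcome~exposure (total c), mediator~exposure (a),
   outcome~exposure+mediator (c′, b) — with death as a linear-probability
   outcome and percentile bootstrap inference on the indirect effect a·b.

Individual-level data of this kind are access-restricted, so the package
ships a synthetic-cohort generator (`mitopersona.synthdata`) that emulates
the full data structure — correlated T-score traits, blood-cell
composition, coverage at deep (~35.8×) and low-pass (~3.8×) depths, age
and sex effects on mtDNAcn, and a configurable PMI→mtDNAcn→mortality
mediation mechanism — so every stage is testable end to end with known
planted truths.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
cohorts shaped like the published design (n=722 at 35.8× and n=587 at
3.8×), with a −0.11 SD/SD Neuroticism effect planted on mtDNAcn:

```
cd analysis
python 01_simulate_cohorts.py
python 02_estimate_mtdnacn.py
python 03_trait_associations.py
python 04_meta_analysis.py
python 05_pmi_survival.py
python 06_mediation.py
```

Script 04 prints the pooled association table (all outputs land under
`results/`):

```
35 traits in the FDR family; 1 significant at FDR 0.01
      trait  pooled_beta  pooled_se         p    p_fdr  I2    p_Q
neuroticism      -0.1076    0.02731 8.182e-05 0.002864   0 0.6932
```

The planted −0.11 is recovered (−0.108 ± 0.027), survives FDR correction
over 35 traits, and shows no between-cohort heterogeneity (I²=0) — while
its correlated facets show the expected weaker, non-significant echoes.
Script 06 fits the mediation model on a cohort with planted paths
a=4.89 copies/point and b=−0.02 probability/copy:

```
total effect c       = -0.147 per PMI point
direct effect c'     = -0.045
path a (PMI->mtDNAcn)= +4.90 copies/point
path b (mtDNAcn->death) = -0.0209 per copy
indirect a*b         = -0.103 [-0.111, -0.095] (bootstrap p = 0.0003999, 5000 resamples)
```

The same stages are available as a single executable
(`mitopersona run-all --config config.yaml --out results/run`) or as
library calls; see `mitopersona --help`.

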