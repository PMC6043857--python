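# eduslope

Does education change the *rate* of age-related cognitive decline, or only
the *level* of cognitive performance?  `eduslope` implements the full
Bayesian workflow for answering that question from cohort-sequential
(accelerated longitudinal) data: a hierarchical growth model fitted by
MCMC, and Savage-Dickey Bayes factors that can quantify evidence **for**
the null hypothesis of no effect — something classical significance tests
cannot do.

Because the motivating cohort data (the Betula study: two population
samples followed over five waves at 5-year intervals, birth cohorts
1909–1959) are not publicly deposited, the package ships a synthetic-data
generator that emulates that design with configurable ground-truth
parameters, so the entire pipeline is testable end to end.

## The model

For person *i* at occasion *t*, with age decomposed into a linear term and
an orthogonalised quadratic term, the outcome (a T-standardised cognitive
score) follows

    Y_ti = β0_i + β1_i · age_ti + β2_i · age²_ti + ε_ti

with person-level coefficients

    β0_i = γ00 + γ01·cohort + γ02·edu + γ03·sex + γ04·sample
         + γ05·cohort·edu + γ06·cohort·sex + γ07·edu·sex
         + γ08·cohort·edu·sex + u0_i
    β1_i = γ10 + γ11·cohort + γ12·edu + γ13·sex + γ14·cohort·edu
         + γ15·cohort·sex + γ16·edu·sex + γ17·cohort·edu·sex + u1_i
    β2_i = γ20 + … + γ27·cohort·edu·sex          (no random component)

where (u0, u1) are bivariate normal with SDs σ_u0, σ_u1 and correlation ρ,
and ε ~ Normal(0, σ_e).  Covariates are centred (age at 62.9 years, birth
cohort at 1933, education at 10.2 years by default).  The focal parameter
is **γ12**, the change in annual rate of decline per extra year of
education: γ12 = 0 is the "passive reserve" null hypothesis.

Priors: Normal(50, 20) on the intercept, Normal(0, 3) on other
coefficients, half-Cauchy(0, 10) on the three scales, LKJ(1) on ρ, and a
focal prior γ12 ~ Normal(0, σ) with σ equal to 1×, 2× or 4× a literature
effect size (0.002 for visuospatial ability, 0.004 for semantic knowledge,
0.017 for episodic memory) — the 1×/2×/4× grid doubles as a prior
sensitivity analysis.  The Bayes factor is the Savage-Dickey density
ratio, BF01 = p(γ12 = 0 | data) / p(γ12 = 0), computed from a posterior
sampled under the matching focal prior.

The random effects are integrated out analytically (each person's
observations are jointly normal), and sampling uses a blocked scheme:
exact conjugate draws for the 25 regression coefficients given the
variance components, adaptive random-walk Metropolis for the variance
block.  Convergence is checked with split-chain R̂ < 1.01 on 4 chains of
2,000 post-warmup draws.

## Worked example

```python
import eduslope as es

# a Betula-like synthetic cohort with a known null truth (gamma12 = 0)
design = es.StudyDesign(cohort_birth_years=(1919, 1929, 1939, 1949),
                        persons_per_cell=50, dropout_hazard=0.1,
                        education_min=6)
truth = es.betula_like_truth("em")            # episodic-memory profile
data = es.generate(design, truth, seed=1)

prep = es.prepare(data, outcome="em",
                  cfg=es.PrepConfig(recompute_centers_from_data=True))

model = es.BayesianGrowthModel(n_chains=4, n_draws=2000, random_state=2)
model.fit_prepared(prep)
print(model.converged_, float(model.rhat_.max()))
print(model.summary_.loc["LS x education", ["map", "hdi_low", "hdi_high"]])

grid = es.SensitivityGrid.for_outcome("em")   # sigmas 0.017, 0.034, 0.068
sens = es.run_sensitivity(prep, grid, n_draws=2000, seed=3)
print(es.sensitivity_table(sens))
```

Output of this exact run:

```
True 1.0022861995416343
map        -0.002241
hdi_low    -0.014033
hdi_high    0.009355
Name: LS x education, dtype: float64
  outcome  prior_sigma       map   hdi_low  hdi_high      bf01      bf10
0      em        0.017 -0.003247 -0.013653  0.008518  2.631638  0.379991
1      em        0.034 -0.003544 -0.014472  0.008799  4.991481  0.200341
2      em        0.068 -0.003713 -0.014650  0.008811  9.892284  0.101089
3      em        3.000 -0.003639 -0.014728  0.008897       NaN       NaN
```

All R̂ are below 1.01 (the fit reports `converged_ = True` with a maximum
R̂ of 1.002); the focal MAP is essentially zero and nearly identical under
every prior width, its 95% HDI covers zero, and BF01 grows with the prior
width — evidence in favour of the null that education does not alter the
rate of decline.  (The generating truth used the published episodic-memory
profile, whose education-by-slope effect is 0.006 T-units — tiny, which is
exactly what the Bayes factors report.)

The same workflow is scriptable from the shell:

```bash
eduslope simulate --seed 1 --out cohort.csv
eduslope fit --input cohort.csv --outcome em --seed 2 \
             --recompute-centers --out-prefix em_fit
eduslope bf  --input cohort.csv --outcome em --seed 3 \
             --recompute-centers --out bf_em.csv
eduslope report --seed 4 --outdir out/
```

## Layout

| module | contents |
| --- | --- |
| `eduslope.simulate` | `StudyDesign`, `TrueParameters`, `generate`, `attrition`, `truth_table` |
| `eduslope.prepare` | exclusion filters, T-standardisation, orthogonal age basis, 25-column design matrix, `GrowthDataPreparer` |
| `eduslope.model` | marginalized likelihood, priors, blocked-Gibbs sampler, `BayesianGrowthModel`, R̂/HDI/MAP summaries |
| `eduslope.bayes_factors` | `SensitivityGrid`, Savage-Dickey ratios, `run_sensitivity` |
| `eduslope.pipeline` / `eduslope.cli` | end-to-end orchestration, report tables, implied trajectories, `eduslope` CLI |

See `docs/methods.md` for modelling assumptions, conventions and
limitations.
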