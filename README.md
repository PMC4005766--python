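# hr2ee — heart-rate → energy-expenditure calibration models

Heart rate is the cheapest wearable proxy for energy expenditure, but the
heart-rate/VO2 line differs substantially between people — especially in
older adults, where resting heart rate varies widely with cardiovascular
fitness. `hr2ee` implements the full modelling pipeline for quantifying how
much individual calibration data is needed before a population regression
equation becomes individually accurate:

1. **Synthetic cohorts** (`hr2ee.cohort`): seed-reproducible long-format
   tables of older adults measured at five exertion levels (rest, slow walk,
   customary walk, peak sustained walk, maximal exertion), with realistic
   covariate distributions, correlated within-subject heart rates, and
   energy expenditure generated from a random-intercept/random-slope model.
2. **Linear mixed models** (`hr2ee.lmm`): for subject *i* at measurement *j*,

       y_ij = x_ij' β + b_0i + b_1i · HR_ij + W_ij,
       (b_0i, b_1i) ~ N(0, G),   W_ij ~ N(0, σ²),

   with either a stratified fixed-effect design (four sex/age groups,
   "model 1") or a continuous-age design with sex and an age×HR interaction
   ("model 2"). Fitting is written from scratch: profile likelihood over a
   log-Cholesky parameterization of G/σ² (β and σ² concentrated out in
   closed form), ML or REML, multi-start quasi-Newton plus simplex polish.
   Verified against statsmodels `MixedLM` and a brute-force multivariate
   normal density.
3. **Subject calibration** (`hr2ee.calibrate`): best linear unbiased
   prediction (BLUP) of a subject's (b_0i, b_1i) from k calibration
   measurements by conditional-normal computation, prediction of energy
   expenditure at any heart rate with prediction variance, and conversion to
   kcal/min at 5 kcal per litre of O2.
4. **Cross-validation** (`hr2ee.crossval`): subject-level 80/20 splits
   (stratified for the stratified model), training-set fits, and pooled
   validation errors in kcal/min under four calibration scenarios — none,
   rest only, rest + peak walk, all five levels — summarised by their SD and
   kernel density estimates.

It is intended for methodologists studying heart-rate-based energy
expenditure assessment and for reproducing/extending the calibration
hierarchy analysis on simulated data.

## Worked example

```python
from hr2ee import (GeneratorConfig, simulate_cohort, fit_lmm, ModelSpec,
                   run_scenarios, mean_scenario_sds)

cohort = simulate_cohort(GeneratorConfig(seed=1))      # 290 subjects x 5 levels
fit = fit_lmm(cohort, ModelSpec("m2"), method="ML")
print(dict(zip(fit.names, fit.fixed.round(3))))
print(fit.vc)

reps = run_scenarios(cohort, "m2", seed=1, replicates=5, with_density=False)
print({k: round(v, 2) for k, v in mean_scenario_sds(reps).items()})
```

prints (exactly, for this seed):

```
{'intercept': np.float64(-21.623), 'hr': np.float64(0.344), 'male': np.float64(2.356), 'age': np.float64(0.08), 'age:hr': np.float64(-0.001)}
VarianceComponents(sd_b0=4.04579803026645, sd_b1=0.06513912001009772, corr_b=-0.8825925983338337, sd_resid=2.726056603185008)
{'all_five': 0.95, 'none': 2.01, 'rest_only': 1.8, 'rest_peak': 1.22}
```

The fitted fixed effects and variance components recover the generating
values (intercept −23.05, HR slope 0.339, sd(b0) 3.966, sd(b1) 0.062,
corr −0.874, sd(W) 2.787) up to single-cohort sampling noise. The scenario
SDs show the calibration hierarchy: predicting with the population equation
alone leaves ~2 kcal/min of error SD, a single resting calibration
measurement trims it, two points (rest + peak walk) remove most of the
subject-level heterogeneity, and all five leave mainly residual noise.

The same pipeline is available from the shell:

```bash
hr2ee simulate --n 290 --seed 7 --out cohort.csv
hr2ee fit --model m2 --in cohort.csv --out fit.json
hr2ee predict --fit fit.json --calib calib.csv --at queries.csv --out pred.csv
hr2ee crossval --model m2 --in cohort.csv --replicates 20 --seed 11 --out cv.json
hr2ee run --seed 3 --out results_dir     # full experiment + report
```

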