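# longmed

Power analysis and sample-size determination for **longitudinal mediation
studies** under a two-level (1-1-1) random-intercept mediation model.

When planning a study that asks *"does X affect Y through the mediator M?"*
with repeated measures per subject, no closed-form sample-size formula
exists: the test statistic is a product of two regression coefficients whose
distribution is skewed, and the repeated measures are correlated within
subjects. `longmed` answers the planning question by Monte-Carlo simulation:
it generates data from the assumed model, fits the mediation paths by maximum
likelihood, applies a mediation test, and searches for the smallest number of
subjects that reaches a target power (80% by default).

## Model

For measurement *i* of subject *j*:

```
M_ij = gamma_3 + u3_j + beta_a * X_ij + e3_ij        (a-path)
Y_ij = gamma_2 + u2_j + beta_c' * X_ij + beta_b * M_ij + e2_ij   (b-path)
```

with subject-level random intercepts `u2_j ~ N(0, tau^2)`, `u3_j ~ N(0, tau^2)`
and occasion-level errors `e_ij ~ N(0, sigma^2)`.  The mediation (indirect)
effect is `beta_a * beta_b`, estimated by the product of the ML path
estimates.  The within-subject correlation is controlled by a single `icc`
parameter that sets `tau^2 = icc` (see `docs/methods.md` for the two
supported variance conventions).  With `n_measures = 1` the model reduces to
the classical single-level mediation model fitted by OLS.

Three tests of `H0: beta_a * beta_b = 0` are implemented, each as a
confidence interval that rejects when it excludes zero:

* **Sobel** — delta-method interval `ab ± z * sqrt(se_a^2 b^2 + se_b^2 a^2)`;
* **Distribution of the product** — asymmetric interval with Monte-Carlo
  critical values from the distribution of a product of two normals centered
  at the standardized path estimates;
* **Percentile cases bootstrap** — resample whole subjects with replacement
  (lower level kept intact), refit, take empirical percentiles of the
  bootstrap indirect-effect estimates.

Estimation uses a closed-form profiled likelihood for the balanced
compound-symmetry model, vectorized across simulation replicates and
bootstrap resamples, so full-scale runs (1000 replicates; 300x300 bootstrap)
complete in seconds to minutes on one CPU.

## Worked example

How many subjects are needed to detect a small a-path (0.14) and medium
b-path (0.39) with 4 repeated measures, within-subject correlation parameter
0.2, using the distribution-of-the-product test?

```bash
mediate-n --beta-a 0.14 --beta-b 0.39 --icc 0.2 --n-measures 4 \
          --method product --reps 1000 --seed 21
```

```json
{
  "n_required": 180,
  "achieved_power": 0.807,
  "target_power": 0.8,
  "method": "product",
  "trace": [{"n": 194, "power": 0.82}, {"n": 97, "power": 0.571},
            {"n": 145, "power": 0.703}, {"n": 169, "power": 0.77},
            {"n": 181, "power": 0.804}, {"n": 175, "power": 0.776},
            {"n": 178, "power": 0.784}, {"n": 179, "power": 0.79},
            {"n": 180, "power": 0.807}]
}
```

`n_required` is the number of subjects whose estimated power (rejection
proportion over 1000 simulated datasets) is nearest 80%; the `trace` lists
every (n, power) the search evaluated.  Power at a fixed sample size:

```bash
mediate-power --beta-a 0.14 --beta-b 0.39 --icc 0.2 --n-measures 4 \
              --n-subjects 191 --method sobel --reps 1000 --seed 21
# -> {"power": 0.798, "mc_se": 0.0127, ...}
```

Applying the tests to your own long-format CSV (columns
`subject,measure,x,m,y`, balanced design):

```bash
mediate-test --data study.csv --method bootstrap --boot-b 500 --seed 1
```

Batch tables over an effect-size grid (letters S=0.14, H=0.26, M=0.39,
L=0.59 for the a- and b-paths):

```bash
mediate-tables --profile smoke --cells SS,SM,MM,LL --icc 0.1,0.2 --m 2,3,4 \
               --methods sobel,product --out-dir tables_out --seed 3
```

The same functionality is available as a library (`longmed.simulate_dataset`,
`longmed.fit_mediation`, `longmed.estimate_power`, `longmed.find_sample_size`,
`longmed.run_grid`).

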