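# vacalib

Country-specific verbal-autopsy (VA) misclassification modelling and
modular calibration of cause-specific mortality fractions (CSMFs).

## The problem

In settings without medical certification of deaths, computer-coded VA
algorithms assign causes of death from caregiver interviews.  Against
reference diagnoses they misclassify often, so the raw VA cause
distribution q̂ is a biased estimate of the true CSMF p.  The two are
linked through the misclassification matrix Φ (rows = reference cause,
columns = VA-predicted cause, rows sum to one):

    q = Φᵀ p .

vacalib is for analysts who (a) hold limited paired reference/VA cause
data from several countries and want uncertainty-quantified,
country-specific estimates of Φ, or (b) hold only VA-predicted cause
counts and want calibrated CSMFs using *stored* misclassification
estimates — no access to the paired data required.

Φ is modelled through two latent mechanisms per algorithm: **intrinsic
accuracy** a_i (probability of identifying true cause i by design) and
**pull** b (where predictions land on failure, regardless of the true
cause): φ_ij = a_i·1{i=j} + (1−a_i)·b_j.  Country deviations enter on
logit/log scales under a horseshoe (global–local) shrinkage prior, so
countries with little data shrink toward the pooled estimate and an
explicit *other-country* predictive covers countries absent from the
paired data.  Calibration then treats the stored posterior of Φ as an
informative prior in p ~ Dirichlet(1), x ~ Multinomial(n, Φᵀp), sampled by
an exact data-augmentation Gibbs scheme; single-algorithm and
multi-algorithm (ensemble) modes are provided.  See `docs/methods.md` for
the full model.

## Worked example

```python
import numpy as np
from vacalib import (ScenarioConfig, simulate_scenario, FitSettings,
                     fit_country_specific, build_informative_prior,
                     calibrate_single, CalibrationSettings)

# synthetic multi-country study: 4 causes, 4 countries, strong
# cross-country heterogeneity, 5000 VA-only records from country 1
cfg = ScenarioConfig(cause_map="custom4", n_countries=4, n_per_row=500,
                     heterogeneity=1.0, n_va_records=5000, seed=20260923)
truth = simulate_scenario(cfg)

post = fit_country_specific(truth.paired[0], FitSettings(seed=20260924))
prior = build_informative_prior(post.country_draws[:, 0],
                                cause_map=cfg.cause_map)
res = calibrate_single(truth.va_only[0], prior,
                       CalibrationSettings(seed=20260925))
```

Running the equivalent scripted analysis (`analysis/01_simulate.py` …
`analysis/04_evaluate.py`) prints:

```
cause            true   uncalibrated  calibrated [95% CI]
cause_1         0.400   0.462         0.399 [0.370, 0.427]
cause_2         0.300   0.407         0.291 [0.264, 0.319]
cause_3         0.200   0.080         0.190 [0.140, 0.238]
cause_4         0.100   0.052         0.120 [0.082, 0.164]
MAE vs truth: calibrated 0.0098, uncalibrated 0.0842
condition number of posterior-mean Phi^T: 6.86
```

The raw VA fractions overstate the leading causes and miss rare ones by up
to 12 percentage points; calibration through the fitted misclassification
prior recovers the true CSMF to within about one point, with intervals
that are honestly wider than the (overconfident) raw ones.  The evaluation
step scores the country-specific model against the homogeneous
(one-matrix-for-all-countries) alternative on observed rates:

```
avg absolute loss: country-specific 0.0058 vs homogeneous 0.0894 (93.5% reduction)
share of cells improved: 93.8%
interval score: 0.047 vs 3.191 (98.5% reduction)
```

## Command line

```bash
vacalib simulate      --out-dir demo --seed 1 --cause-map custom4
vacalib fit-misclass  --paired demo/paired_algo_1.csv --cause-map custom4 \
                      --out demo/inventory.json --seed 2
vacalib calibrate     --inventory demo/inventory.json \
                      --va-counts demo/va_counts.csv \
                      --country country_1 --out-dir demo --seed 3
vacalib evaluate      --paired demo/paired_algo_1.csv --cause-map custom4 \
                      --inventory-a demo/inv_country.json \
                      --inventory-b demo/inv_pooled.json --out-dir demo
```

or drive all stages from one YAML config with `vacalib run --config
pipeline.yaml`.  Cause-map presets `neonate6` (six broad neonatal causes,
0–27 days) and `child9` (nine causes, 1–59 months) are built in; the
residual 'other' category is excluded from calibration with the matrix
renormalized accordingly.

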