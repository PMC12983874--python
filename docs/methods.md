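# Methods

## Problem

Computer-coded verbal autopsy (CCVA) algorithms assign a cause of death
(COD) from caregiver interviews.  Compared against reference diagnoses
(e.g. minimally invasive tissue sampling reviewed by an expert panel), they
misclassify frequently, so the raw VA-predicted cause distribution
q̂_j = x_j / n is a biased estimate of the true cause-specific mortality
fraction (CSMF) p.  The two distributions are linked by the calibration
equation

    q_j = Σ_i φ_ij p_i,        q = Φᵀ p,

where Φ = (φ_ij) is the row-stochastic *misclassification matrix*: φ_ij is
the probability the algorithm predicts cause j when the reference cause is
i (diagonal = sensitivity, off-diagonal = false-negative rates).  vacalib
implements the two halves of the resulting workflow:

1. **Misclassification estimation** — a hierarchical Bayesian model of
   country-specific Φ from limited paired (reference, VA) counts.
2. **Modular calibration** — Bayesian recovery of p from VA-only counts,
   using stored posterior draws of Φ as an informative prior, so that the
   paired data themselves never need to be shared.

## The accuracy/pull misclassification model

Each row of Φ is generated by two latent mechanisms:

* **intrinsic accuracy** a_i ∈ [0, 1] — the probability the algorithm
  identifies true cause i by design;
* **pull** b, a probability vector over causes — where predictions land
  when the algorithm fails, independent of the true cause.

Default parameterization:

    φ_ij = a_i · 1{i = j} + (1 − a_i) · b_j ,

so rows sum to one identically and the sensitivity is a_i + (1 − a_i) b_i
(the pull may land on the true cause).  A variant that renormalizes the
pull over the off-diagonal causes (`parameterization="pull_off_diagonal"`,
sensitivity exactly a_i) is available; the default was chosen because pull
is defined as a cause preference *regardless* of the true cause.  With C
causes the mechanism has 2C − 1 free parameters per matrix instead of
C(C − 1), which is what makes estimation workable at the sample sizes
typical of paired COD data (tens of deaths per cause per country).

A pull equal to the uniform vector (1/C, e.g. 1/6 for the six-cause
neonatal grouping) means no systematic cause preference; deviations from
uniform diagnose over- or under-prediction of specific causes.

### Country-specific extension and shrinkage

With countries s = 1..S:

    logit(a_si) = α_i + u_si ,     b_s = softmax(β + v_s),   β_C = v_sC = 0,

and a horseshoe (global–local continuous shrinkage) prior on the country
deviations:

    u_si ~ N(0, (λ_a ψ_si)²),   v_sj ~ N(0, (λ_b ω_sj)²),
    λ_a, λ_b, ψ_si, ω_sj ~ half-Cauchy(0, 1),
    α_i, β_j ~ N(0, 1.5²).

The global scales λ adapt the model's complexity to the evidence: with
homogeneous data they collapse toward zero and every country shrinks to the
pooled matrix; the heavy-tailed local scales let individual deviations
escape when a country's data demand it.  Independence of accuracy and pull
deviations across causes is assumed.  Rows of the paired count matrix are
multinomial given the reference cause; reference causes never observed in a
country contribute no likelihood, so their rows are hierarchy-driven (not
an error).

The *homogeneous* model is the S = 1 special case fitted to counts summed
over countries.  The *other-country* predictive draws a new country's
deviations per posterior draw (fresh half-Cauchy locals, standard-normal
raw deviations scaled by that draw's λ): it is centred on the pooled
matrix with spread that grows with the fitted heterogeneity, and is the
estimate used for countries absent from the paired data.

A consequence worth knowing: because the local scales are Cauchy-tailed,
the predictive *spread* for a new country exceeds the pooled-draw spread
even when the fitted λ is small, and under strongly heterogeneous fits the
predictive *mean* can deviate from the pooled mean by a few percentage
points (heavy tails push expectations through the logit/softmax links
toward flatter matrices).  The tests therefore check centring of the
predictive mean under moderate heterogeneity and monotone growth of the
spread, not equality of spreads.

### Sampling

Posteriors are explored with an affine-invariant ensemble MCMC (emcee),
using differential-evolution and snooker moves over a non-centered
parameterization (raw deviations ũ ~ N(0, 1) scaled inside the model by
λ·ψ) with local/global scales sampled on the log scale.  Defaults: walkers
≈ 2 × dimension (minimum 48), 2000 steps with the first 1000 discarded,
1000 parameter vectors subsampled from the retained ensemble; the starting
cloud is centred on moment-style estimates from the pooled counts.  Split
R-hat and bulk ESS are computed over the retained ensemble (walkers folded
into four pseudo-chains); values outside the gates (R-hat < 1.01,
ESS > 400) raise a warning, never a silent failure — posterior means are
far less demanding than full-distribution summaries, and the parameter-
recovery suite verifies their accuracy directly.  The model-based estimate
φ̃ is the posterior mean of the draws; all intervals are equal-tailed.

An independent dense-grid numerical posterior over (a₁, a₂, b₁) for the
two-cause pooled model is used as an oracle in the test suite; the sampler
agrees with it to < 0.005 on posterior means.

## Modular calibration

Model for VA-only counts x (one algorithm):

    p ~ Dirichlet(1, ..., 1),   Φ ~ prior,   x ~ Multinomial(n, Φᵀp).

The prior on Φ comes from the stored misclassification posterior in one of
three forms:

* `dirichlet_rows` (default) — each row's Dirichlet prior is moment-matched
  to the stored draws: mean m equals the draw mean, concentration
  α₀ = mean over causes of m_j(1 − m_j)/Var_j − 1, capped to [1, 10⁶]
  (identical draws hit the cap with a warning).  Smooth and conjugate.
* `draw_resampling` — the stored draws themselves, preserving cross-cell
  dependence.
* `point_mass` — a single fixed matrix.

Inference is an exact data-augmentation Gibbs sampler: each VA death with
predicted cause j receives a latent true cause i with probability ∝
p_i φ_ij; given latent counts, p and each Dirichlet row of Φ are conjugate.
Stored-draw priors update Φ by independence Metropolis proposing uniformly
from the bank.  Defaults: 4000 sweeps, 1000 burn-in, 2000 kept draws of p.
No gradients or tuning parameters are involved, and with Φ = I the sampler
reduces *exactly* to the Dirichlet-multinomial conjugate posterior.

Calibration is well posed only when Φ is non-singular.  The condition
number of the posterior-mean Φᵀ is reported; above 10³ a warning is issued,
above 10⁸ (or for a singular point-mass prior) calibration refuses to run.

The residual 'other' category mixes different causes on the VA and
reference sides and is not calibrated: deaths VA-classified as 'other' are
*excluded* (not redistributed) and Φ's 'other' row/column removed with row
renormalization; calibrated CSMFs are reported over the remaining causes.
The uncalibrated comparator is the empirical fraction with equal-tailed
Dirichlet(1 + x)-multinomial intervals over the same reduced cause set.

**Ensemble calibration** shares one p across K algorithms, each with its
own prior and an independent Multinomial(n_k, Φ_kᵀp) working likelihood
over aggregate counts (individual-level agreement between algorithms is not
modelled).  This hedges against relying on a single inaccurate algorithm;
with identical algorithms it reproduces the single-algorithm posterior with
a narrower interval.

Calibration typically *widens* intervals relative to the raw estimate —
the price of acknowledging misclassification uncertainty — while removing
the bias, which the synthetic studies show is the dominant error.

## Evaluation metrics

* **Average absolute loss** Σ_sij |φ̃_sij − φ̂_sij| / Obs against observed
  row-conditional rates φ̂, where a row (s, i) is observed iff its paired
  total is ≥ 1 and Obs counts all C cells of observed rows (a row-level
  alternative is exposed by flag in the comparison report).
* **Interval score** — the proper (Winkler) score at α = 0.05:
  width + (2/α)·(distance outside the interval).
* **Model comparison** — percent loss reduction, share of observed cells
  with strictly smaller absolute error (ties count as not improved), and
  average interval-score reduction.
* **ci_coverage** — fraction of simulation replicates whose interval
  contains the truth; used by the coverage suite.

## Synthetic data

Generators mirror the estimation model's assumptions: global accuracy/pull
per algorithm; country deviations N(0, η²) applied on the same link scales
(η = 0 ⇒ identical matrices); paired rows multinomial given the reference
cause; VA-only deaths draw a true cause from p and each algorithm's
prediction from its matrix row, conditionally independently — so VA margins
obey q = Φᵀp and the ensemble working likelihood is exact on this
generator.  Defaults (4 causes, 4 countries, 500 deaths per reference-cause
row, 5000 VA-only records, η = 0.3, accuracy spanning 0.2–0.8 with a
moderately biased decreasing pull and decreasing true CSMF) describe a
mid-sized multi-country study in which sensitivities span the low range
where calibration matters most; η ∈ {0, 0.3, 1} brackets homogeneous to
strongly heterogeneous regimes.  One master seed expands into per-stage
substreams.

What the generator does *not* emulate: questionnaire/symptom data,
missingness, multiple causes per death, temporal drift of
misclassification, or non-transportability between the paired and VA-only
populations.  Passing tests therefore demonstrate internal consistency and
correct inversion under the model's assumptions — not that those
assumptions hold in any particular surveillance system.

## Problem sizes and numerical choices

Replicated studies in the test and acceptance suites use 4 causes ×
4 countries × 500 deaths per row with 1200–2500 sampler steps — sizes at
which the fits' posterior means carry ~6–10× margins over the thresholds
they are tested against.  Row-stochasticity is enforced to 1e-9 in
containers and 1e-6 on inventory files read back from disk; matrix
probabilities are floored at 1e-300 inside log-likelihoods; degenerate
latent-assignment weights fall back to uniform.  Posterior-mean matrices
are renormalized row-wise before reporting to remove accumulated floating-
point drift.

## Known limitations

* Ensemble calibration uses aggregate counts; per-death concordance across
  algorithms is ignored.
* Convergence gates (R-hat 1.01, ESS 400) are conservative for an ensemble
  sampler's short chains; warnings are common at the reduced problem sizes
  even when posterior means are accurate.
* The horseshoe's heavy tails make the other-country predictive mean drift
  from the pooled mean under strong fitted heterogeneity (see above).
* Exact zeros in a stored draw bank can make `draw_resampling` acceptance
  rates very low when the latent counts contradict them; `dirichlet_rows`
  is the robust default.
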