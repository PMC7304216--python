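# Methods

## Model

The outcome is an unordered four-category illness count per child (0 = none
of diarrhea/fever/cough, 1/2/3 = that many concurrently). A
baseline-category logit fixes the category-0 predictor at zero; each
non-reference category l gets its own structured additive predictor

η_l = H β_l + f_l(age) + f_str,l(region) + f_unstr,l(region)

with any subset of terms active (model forms M1–M6). Probabilities are
π_l = exp(η_l) / (1 + Σ_k exp(η_k)), computed with a max-shift so
predictors up to |η| ≈ 700 stay finite.

**Fixed effects.** Dummy coding, reference levels contribute no column,
intercept first, deterministic column order (schema order, then level
order). The default prior is the improper uniform (numerically realised as
a N(0, 10⁸) ridge, far below the information in any dataset of interest);
an optional N(0, sd²) prior is available and is used wherever a proper
prior is required.

**Age smooth.** Cubic B-splines on equidistant knots spanning the observed
age range, 20 interior knots by default (m = 24 basis functions; both
config-overridable). The coefficient prior is a second-order random walk,
equivalently the penalty K = D₂ᵀD₂ of rank m − 2: constants and linear
trends are unpenalized, curvature is shrunk with variance τ².

**Spatial effects.** The structured term uses the intrinsic CAR prior on
the region adjacency graph: precision structure K_str with N_s on the
diagonal and −1 between neighbours, so fᵀK_str f is the sum of squared
neighbour differences and each region's conditional variance is τ²_str/N_s.
The unstructured term is iid Gaussian with variance τ²_unstr. Each variance
has an IG(a, b) hyperprior; a = 1, b = 0.005 by default (a = b = 0.001 is
the conventional alternative).

**Identifiability.** RW2 is flat in the constant and linear coefficient
directions, ICAR in the constant direction. The smooth's fitted values and
both region-effect vectors are therefore recentred to mean zero at every
sweep, with the removed constants absorbed into the category intercept (the
linear component of the smooth stays inside the smooth). The predictor is
unchanged by this reparameterisation; stored effect vectors sum to zero to
1e−10.

## Sampling

The multinomial likelihood, viewed as a function of category l's predictor
only, is a Bernoulli likelihood for the indicator 1{y = l} with logit
η_l − log(1 + Σ_{k≠l} exp η_k). Each sweep, per category: draw Polya-Gamma
latent variables ω_i ~ PG(1, ψ_i) at the current tilt, then draw each
coefficient block from its exact Gaussian full conditional
(precision XᵀΩX + K/τ², one Cholesky per block; region-indicator blocks use
per-region sums instead of dense matmuls), then recentre. Variances follow
as IG(a + rank(K)/2, b + βᵀKβ/2). This is a pure Gibbs scheme — no
tuning, no rejections.

PG(1, z) is sampled exactly by the alternating-series (Devroye-type)
method: a two-piece proposal (truncated inverse-Gaussian below t = 0.64,
truncated exponential above) accepted against the partial sums of the
Jacobi series density; the implementation is numba-compiled and draws
sequentially from a single `numpy.random.Generator`, so runs are
bit-reproducible for a fixed seed. Validation: closed-form mean
tanh(z/2)/(2z), the Laplace transform cosh(z/2)/cosh(√(z²/4 + t/2)), exact
conjugate oracles (intercept-only posterior vs empirical logit; 2×4-table
log cross-product ratios), and a successive-conditional prior-recovery run.

A metropolized IWLS alternative (`method="iwls"`) proposes each block from
the Gaussian IWLS approximation at the current state and corrects by
Metropolis-Hastings; it passes the same conjugate oracles and exists mainly
as a cross-check of the PG scheme.

**Prior-recovery ("getting it right") design.** The check alternates
"simulate data given parameters" with a few sampler sweeps, so the
stationary marginal of every parameter must equal its prior. Improper
priors cannot be simulated from, so the check runs the identical code path
with proper variants: ridge-augmented penalties (K + 0.3·I, full rank),
Gaussian fixed effects (sd 1.5), IG(3, 2) variances, centring off, at
n = 40, m = 6 basis functions, 3 regions. Because the data at n = 40 are
weakly informative, consecutive cycles are strongly autocorrelated whatever
the sweep count; the Kolmogorov-Smirnov test is therefore run on every 25th
of 2500 cycles (near-independent samples) and required to exceed p = 0.01
for a fixed coefficient against its Gaussian prior and for each variance
against its inverse gamma.

**Chain defaults.** 12 000 iterations, 2 000 burn-in, thinning 10 (stored
draws = ⌈(iterations − burn-in)/thinning⌉). The validation experiments use
deliberately shorter chains (300–1 500 iterations) and the test suite uses
reduced replicate counts where a full-size run would add nothing but wall
time; problem sizes are stated with each experiment below. Divergent states
abort with the iteration index; a non-finite predictor is refused up front.

## Model comparison

Per-draw deviance −2 Σ log π_{y_i} is stored during sampling (observed-
category probabilities clamped at 1e−300 with a warning). DIC uses the
classic plug-in form: pD = D̄ − D(θ̄) with θ̄ the posterior mean of the
coefficients (not of the probabilities), DIC = D̄ + pD. Both D̄ and D(θ̄)
are reported, since published tables are often ambiguous about which
"deviance" column they show. The comparison table flags the DIC minimum but
leaves selection to the analyst — near-ties between the full model and the
model without the unstructured term are expected, because the unstructured
term adds little once the structured term is in.

## Hotspots

Cluster value: mean illness count per child (alternatives: proportion with
≥1 or ≥2 illnesses). Weights: binary k-nearest-neighbour (k = 8) by
haversine distance with self-weight 1 — Gi\* requires including the focal
cluster; k-NN copes with the uneven cluster density of DHS designs, and a
fixed distance band is available. z_i follows the standard Gi\* form with
the global (population) SD; all-equal inputs return z = 0 by convention
(with a warning). Two-sided Gaussian p-values, α = 0.05, no
multiple-testing correction by default (an optional Benjamini-Hochberg
switch exists). Gi\* is affine-invariant in the values and is checked
against a brute-force double-loop oracle to 1e−10.

## Synthetic generator

The generator emulates: 8742 children; 11 regions with the published
region labels on a synthetic lattice map (abstract grid cells, not real
boundaries); 643 clusters allocated per published per-region counts with
uniform coordinates inside each region's cell; covariates drawn
independently from the published margins; age uniform on 0–59 months; a
true age curve that is a mean-centred Gaussian bump peaking at 12 months
(width 6 months — a clearly identifiable maximum inside the 10–15-month
window), with per-category amplitudes (1.1, 1.1, 1.45) calibrated so that
adding the smooth to the fixed-effects model improves DIC by roughly 200
units at n = 8742, the scale the published model comparison reports; structured effects drawn from the sum-to-zero intrinsic MRF via
its eigendecomposition (variance τ²_str per reciprocal eigenvalue) and iid
unstructured effects (defaults τ²_str = 0.1, τ²_unstr = 0.03, giving
region effects of a few tenths on the log-odds scale, matching the spread
of published residual risk maps); true fixed effects of plausible published
magnitude (e.g. −0.17 for female/one illness, +0.50 for working
mother/three illnesses). Category intercepts are calibrated by root-finding
so the expected outcome margins over the realised covariates equal the
published margins (0.7315/0.1444/0.0908/0.0333).

What the generator does **not** emulate: DHS two-stage sampling weights,
stratification and nonresponse; within-region cluster geography (the
lattice is a stand-in); covariate dependence (margins are independent);
household/mother clustering of children. Passing recovery tests therefore
demonstrates the estimator works under the model's own assumptions at the
study's size and signal strength — not that the published estimates
themselves are reproduced, which would require the restricted microdata.

## Validation experiments and sizes

* **Interval coverage** — 100 replicates, n = 8742, fixed-effects truth and
  fit (M1), chains 320/100/2; pooled 95%-interval coverage over all 51
  coefficient-category pairs must fall in 88–99%.
* **Age-peak recovery** — 10 replicates, n = 8742, fixed+smooth truth and
  fit (M2), chains 600/200/4; the argmax of the posterior-mean curve must
  land in [10, 15] months in ≥ 8 of 10.
* **DIC model recovery** — 10 seeds, n = 3000, fixed+smooth+structured
  truth, all six models fitted (chains 450/150/3); the DIC minimum must
  contain smooth + structured terms in ≥ 8 of 10.
* **Planted hotspot** — 10 seeds, one region's structured effect raised by
  +1.0; the majority of significant "high" clusters must sit in that region
  in ≥ 9 of 10.
* **Prior recovery** — 1500 cycles of the successive-conditional simulator
  as above.

## Known limitations

* The intrinsic-MRF constraint is handled by recentring, which is exact
  under flat intercept priors but approximate under a proper Gaussian
  intercept prior (hence the prior-recovery check disables centring).
* Fixed effects with unobserved or near-separated levels under the flat
  prior can drift; tiny datasets with empty outcome categories are not
  protected beyond the non-finite-state guard.
* The IWLS method's acceptance rate degrades for large blocks; it is a
  cross-check, not the recommended sampler.
* Printed descriptive tables from survey-weighted analyses need not match
  unweighted Pearson chi-square recomputations; three published rows (sex,
  breastfeeding, toilet type) disagree with the unweighted statistic
  computed from their own printed counts and are reported as computed.
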