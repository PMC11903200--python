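# Methods

`fasdiet` estimates the diet composition of a predator from its fatty-acid
(FA) signature: the vector of K FA proportions (summing to one) measured in
its lipid stores. Some dietary FAs are deposited in a predator's adipose
tissue with little modification, so a predator's signature resembles a
convex mixture of the signatures of its prey. This note records the models
implemented, the tunable parameters that matter, the numerical choices, and
what the synthetic-data generator does and does not emulate.

## Data model

A *prey library* holds FA signatures of sampled prey individuals grouped
into R species. Per-species arithmetic means of the (subset-renormalized)
individual signatures, re-closed to the simplex, are the mixture
components. Two per-unit corrections connect predator and prey spaces:

* **Calibration coefficients (CCs)** `c`, one positive constant per FA,
  describing how metabolism inflates or deflates each FA between ingestion
  and deposition. Predator signatures are divided componentwise by `c` and
  re-closed before any fitting ("prey space"). Unit CCs are the identity.
* **Fat content** `f`, one positive value per species. Fitted diet
  proportions are biomass (lipid) shares; dividing by `f` and re-closing
  converts them to shares of prey individuals consumed. Applied after
  optimization, never inside the objective.

Signatures are accepted as proportions or percentages: raw sums in
[90, 110] are divided by 100, sums in [0.9, 1.1] are re-closed with a
warning, anything else is rejected. These bands reflect how rounded
laboratory exports actually circulate.

### Zero handling

Log-ratio machinery needs strictly positive parts. The default replacement
is multiplicative with `eps = 1e-5`: zeros become `eps` and the nonzero
parts are scaled by `1 - z*eps` (z = number of zeros), preserving the unit
sum exactly. `eps = 1e-5` sits safely below the smallest FA proportions
that are typically reported (~1e-4). The public function enforces
`eps < min positive part`; inside the estimators the constant is shrunk to
`min_positive/10` when a signature is sparser than that, so a fit never
aborts on an unusually small part.

## Distances

Three compositional distances are selectable everywhere (`x` = predator in
prey space, `y` = modeled mixture):

* **KL** (symmetrized Kullback–Leibler): `sum_k (x_k - y_k) ln(x_k/y_k)`.
* **AIT** (Aitchison): `||clr(x) - clr(y)||_2`, with
  `clr_k(x) = ln x_k - mean_j ln x_j`. A metric on the simplex, invariant
  under perturbation.
* **CS** (chi-square type): with `u = x^g / sum(x^g)` (power `g = gamma`,
  default 1), `(1/g) sqrt(2 sum_k (u_k - v_k)^2 / (u_k + v_k))`, dropping
  components where both parts are zero — hence usable on zero-laden data
  with no replacement.

The estimators minimize the *additive* form of each distance (KL itself,
squared AIT, squared CS), whose per-FA addends are reported as the
contribution of each FA to the fit; the metric-scale value is reported
alongside. The argmin is unchanged by the monotone transform.

## Distance-minimization estimation

For each predator, the diet `alpha` minimizes the chosen objective between
the calibrated predator signature and `sum_i alpha_i m_i` over the simplex.
Numerics: SLSQP on the sum-to-one + box constraints, analytic gradients for
KL, AIT and CS (gamma = 1), `ftol = 1e-12`, and a seeded multistart
(uniform diet plus Dirichlet(1) draws, 10 starts by default) because the
KL/CS objectives are not convex in general. Ties are broken first-found; a
start achieving objective < 1e-16 short-circuits the rest. When R exceeds
K the solution need not be unique and a warning is emitted. Batch runs give
each predator an independent seeded stream, so results are reproducible and
order-independent.

## Likelihood models

On the clr scale the prey-means MLE assumes
`clr(x_j) ~ N(clr(sum_i alpha_ji m_i), V)` with `V = sigma^2 I` or
`diag(sigma_k^2)`. With isotropic variance, profiling `sigma^2` reduces the
per-predator problem to minimizing the squared clr residual — exactly the
AIT fit — which is the equivalence the acceptance suite asserts. The
per-FA model alternates weighted diet fits with closed-form variance
updates from an isotropic start, so its likelihood can only improve on the
isotropic fit. Variances are floored at 1e-12. Diets are per-predator by
default (a shared-diet option exists); the likelihood is joint with one
shared variance.

**MUFASA** replaces the species means with latent species effects
`z_i ~ N(clr(mean_i), S_i/n_i)` (`S_i` = within-species clr covariance,
diagonal by default, ridge 1e-8), acknowledging that the predator did not
eat the sampled individuals; observations are
`clr(x_j) ~ N(clr(sum_i alpha_ji clr_inv(z_i)), sigma_eps^2 I)`. The exact
random-effects structure of the published variants is not in the public
record, so this generative model is declared normative here, and it is
exactly what the parametric pseudo-predator generator simulates — making
the recovery tests internally valid while saying nothing about other error
structures. The marginal likelihood is approximated by Laplace: diets,
latent effects and (profiled) error variance are maximized jointly with
analytic gradients (L-BFGS-B), and the Gaussian curvature correction
`-(1/2) log det H_zz` is evaluated at the optimum. As `S_i -> 0` the
latent effects pin to the prey means and the fit collapses to the MLE
(verified at a 1e-6 scaling).

## Prey-type selection

Both stepwise searches wrap the isotropic MLE. The criterion for species
set S is `-2 loglik + k (n_pred (|S|-1) + 1)` — per-predator diets plus one
shared variance — with `k = 2` (AIC) by default. Backward elimination
protects any species reaching proportion `cutoff = 0.1` in *any* predator,
re-evaluating protection each round, and commits the best drop when its
criterion does not exceed the current one (ties favour the smaller model).
Forward selection seeds from the best single-species criterion when no
start set is given and forces IC-best additions until `min_spec = 5`
species are included. Candidate order follows the library's species order,
so the whole path is deterministic.

## Calibration-coefficient estimation

With the sum constraint `sum_k c_k = K` (mean CC 1) resolving the joint
scale indeterminacy:

* **Alternating distance minimization**: per-predator AIT diet fits given
  `c`, then the exact c-step — in clr coordinates the calibration division
  is a subtraction, so the optimal `clr(c)` is the mean residual
  `mean_j (clr(x_j) - clr(mix_j))`. The objective is therefore monotone
  non-increasing; iteration stops when the relative decrease falls below
  `tol = 1e-8` or at `max_iter = 100`. Diet steps after the first warm-start
  from the previous iterate. At least two predators (with distinct diets)
  are needed for identifiability.
* **Common-diet likelihood (SMUFASA)**: one diet for the whole predator
  sample and `c` enter the MUFASA-type Laplace likelihood jointly
  (`clr(c)` is an unconstrained centred vector in the optimizer); the
  estimated CCs are then typically passed back into any per-predator
  estimator.

## Inference

**Simultaneous confidence intervals** for the true common diet of a
predator sample: the common estimate is the columnwise mean of the diet
matrix; B parametric-bootstrap replicates regenerate `n_pred`
pseudo-predators from it (bootstrap-mean resampling, `preysize = 2`),
re-estimate, and record the replicate means. Per-species endpoints are
taken at the Bonferroni-adjusted level `1 - (1 - level)/R` for familywise
coverage, shifted by the bootstrap bias estimate, and truncated to [0, 1].
Numerical choice: when the adjusted tail is deeper than the bootstrap can
resolve (`B * tail < 1` — e.g. the 0.5% tail with B = 50, whose sample
extremes only reach the ~2% tail), the endpoint quantiles are estimated by
the normal approximation `mean* ± z sd*` at the same nominal level;
otherwise plain percentiles are used. Bonferroni remains the simultaneity
device; the exact construction in the source literature is encapsulated
behind this one function.

**Two-sample permutation test**: the statistic is the mean cross-sample
distance (CS by default, because signatures carry zeros) minus the pooled
within-sample mean with V-statistic normalization, which is exactly zero
for identical multisets and location-free. The null relabels the pooled
sample; p-values use the add-one rule `(1 + #{>= observed})/(1 + n_perm)`
(the raw proportion is also reported). The test is exact under
exchangeability, which the type-I acceptance check verifies.

## Repeatability

Repeated diet estimates (individuals x occasions) are decomposed with the
Gower identity applied to squared pairwise distances: among/within sums of
squares for the individual and occasion groupings give two-way pseudo mean
squares (`df_ind = n-1`, `df_occ = T-1`, `df_res = N-n-T+1`), combined in
the two-way agreement ICC with `k0 = T` when balanced and
`k0 = (N - sum n_i^2/N)/(n-1)` otherwise; missing cells are simply absent
rows. The raw measure is biased; individuals (with their occasion sets)
are bootstrapped (B = 100 default) and the standard reversal
`2 r - mean(r*)` is reported, with a percentile CI of the bias-corrected
bootstrap distribution on request. Perfect-repeat layouts give exactly 1
(the residual SS vanishes identically).

## Diagnostics

Species mean signatures are clustered agglomeratively (scipy linkage;
average by default, KL distance by default) and exported to newick with
branch lengths equal to merge-height differences. The leave-one-prey-out
matrix treats every prey individual as a predator with unit CCs and no fat
rescaling, recomputing only its own species' mean without it; rows are the
per-species average estimated diets. Single-individual species cannot be
their own candidate and are skipped with a warning.

## Synthetic libraries and pseudo-predators

The generator emulates the shape of a working marine prey library — by
default 11 species, 39 FAs, 10–50 individuals per species. Species base
profiles are Dirichlet(concentration = 1) draws; their clr deviations from
the across-species centre are scaled by `separation` (default 1, giving
clearly but not perfectly distinguishable species, in line with published
leave-one-out matrices whose diagonals span ~0.66–0.98); individuals add
centred logistic-normal noise with `within_sd = 0.15` per clr coordinate,
a moderate within-species dispersion. All ground truth (means, CC, fat,
covariances) is returned.

Nonparametric pseudo-predators mix one random individual (`preysize = 1`)
or a per-species bootstrap mean (`preysize = 2`, default) per supported
species; mixing weights are proportional to `diet_i * fat_i`, the unique
choice that makes estimation followed by fat rescaling invert the
construction exactly; CCs multiply the final signature. Every supported
species contributes exactly one summary signature — diet-proportional
*counts* of sampled individuals are not drawn, because the bootstrap-mean
mode already realises the "average sampled prey" mechanics.
Parametric pseudo-predators draw species signatures from the clr-normal
with pooled within-species covariance — the MUFASA observation model.

What the generator does **not** emulate: real FA chemistry (named FAs,
biochemical correlation structure), predator-specific metabolic variation
beyond the CC vector, measurement rounding, or structural zeros. Passing
tests therefore demonstrate internal correctness and the stated operating
characteristics under logistic-normal variation, not field performance.

## Problem sizes

The shipped checks use deliberately scaled-down designs chosen to exercise
every code path at desk scale: 3–11 species, 8–39 FAs, 5–20 predators,
B = 50 bootstrap replicates, 199–999 permutations, 20–200 replicates per
operating characteristic. Larger designs change run time, not code paths.

## Known limitations

* The MUFASA/SMUFASA error structure is a declared stand-in (see above);
  its Laplace approximation is evaluated at a jointly optimized mode rather
  than with a nested inner solve per outer step.
* Simultaneous intervals are assessed only for the distance-minimization
  estimators; likelihood-based diets would need their own calibration.
* The alternating CC estimator inherits the identifiability limits of the
  problem: predators with identical diets confound CCs with the shared
  mixture, and the sum-K constraint is a convention.
* CS distance with `gamma < 1` falls back to numerical gradients.
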