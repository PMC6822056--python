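# Methods

## The sampling situation

Camera-trap surveys for naturally marked species place two opposed cameras at
each of `J` stations so that both flanks of a passing animal can be
photographed over `K` occasions. Because cameras misfire, many capture
histories are recorded by only one of the two detectors, and the
correspondence between left-flank and right-flank histories is unknown unless
the animal was photographed by both cameras simultaneously at least once
(which requires metadata such as capture times). The package models such
*bilateral* data: two binary arrays `Y1`, `Y2` of shape `M x J x K` after
zero-augmentation to `M` pseudo-individuals, a set of known links between
detector-1 and detector-2 rows, and a latent permutation `L` aligning the
remaining (partial-identity) rows.

## The four competing models

All four models share the data-augmentation skeleton: inclusion indicators
`z_i ~ Bernoulli(psi)` (population size `N = sum z`), activity centers
`s_i ~ Uniform(V)` on a rectangular state space, a uniform prior on the
permutation `L` (restricted to the known links), and optionally a sex
indicator `u_i ~ Bernoulli(theta)` that selects a sex-specific movement
scale.

* **Entry-detection models (M1 sexed, M3 sexless).** An individual enters
  trap `j` on an occasion with probability
  `eta_j(s_i) = omega0 * exp(-d(s_i, x_j)^2 / (2 sigma^2))`, and given entry
  each detector fires independently with probability `phi`. Writing `n_ij`
  for the number of occasions with at least one detection at trap `j` and
  `y_i..` for the total detection count, the per-individual likelihood is a
  zero-inflated Bernoulli pair: `phi^{y_i..} (1-phi)^{2 n_i. - y_i..}
  prod_j eta_j^{n_ij} [(1-eta_j) + eta_j (1-phi)^2]^{K - n_ij}`, raised to
  `z_i`.
* **Direct-detection models (M2 sexed, M4 sexless).** Movement is folded
  into the observation process: each detector fires with probability
  `p_j(s_i) = p0 * exp(-d^2/(2 sigma^2))`, giving `2K` independent Bernoulli
  trials per trap.

Priors are `U(0,1)` for all probability parameters and `U(0,R)` for the
movement scales, with `R = 10` spatial units by default (configurable; it
only needs to comfortably exceed plausible movement). The sex-prior factor
`theta^{u_i} (1-theta)^{1-u_i}` applies to all `M` augmented rows — the sex
indicator is defined for every pseudo-individual — while the `z_i` exponent
covers only the detection factor. A row with observed detections and
`z_i = 0` has density zero (the implementation returns `-inf`).

## Posterior sampling

`run_chain` is a Metropolis-within-Gibbs sampler with a fixed update order
per sweep: transformed-scale random-walk Metropolis for each scalar (logit
for probabilities, logit of `sigma/R` for scales; default proposal s.d. 0.1,
optional Robbins-Monro adaptation during burn-in, off by default for
reproducibility); a random-walk update with boundary reflection for the
activity centers of included individuals and a prior refresh for excluded
ones (valid as a Gibbs step because their likelihood is flat); a Bernoulli
full-conditional Gibbs update of `z_i` for undetected rows (odds
`psi f0 : 1 - psi`, with `f0` the probability of an all-zero history); a
two-point Gibbs update of the missing sex indicators; and `M` swap proposals
for the identity permutation.

Permutation proposals pick one free detector-2 row and one free target slot
uniformly; known links are never disturbed. The proposal is symmetric, so
acceptance uses the likelihood ratio of the two affected rows only. Observed
sexes travel with their rows: a sexed detector-2 row pins the sex of the slot
it is currently assigned to, swaps deterministically carry the pins, and a
swap that would put two different observed sexes on one slot is rejected
(density zero). Swapping two all-zero detector-2 rows leaves the posterior
invariant and is accepted without likelihood evaluation.

Initial states use a link- and sex-consistent greedy assignment for `L`,
activity centers at each individual's mean capture location, `z = 1` for all
detected rows, and scalars drawn from their priors. A single seeded
generator drives the whole chain; fixed seeds give bit-identical output.

## Marginal-likelihood estimators

The Gelfand-Dey estimator averages `g(mu) / [f(Y|mu) pi(mu)]` over posterior
draws, with a tuning density `g` fitted on the transformed (unconstrained)
scale so its support is the whole space; the prior then carries the logit
Jacobians. Nine tuning variants are provided: multivariate normal,
multivariate t with 10/100/500/1000/10000 degrees of freedom (scale shrunk
by `(df-2)/df` so the fitted variance matches the sample covariance), and
normal truncated to the Mahalanobis ellipsoid of confidence 0.90/0.95/0.99
with the retained mass renormalized. Draws falling outside a truncated
density's ellipsoid are legitimate zero summands and are kept in the
denominator; only non-computable (`+inf`/`nan`) summands are dropped, with
the count reported.

Two approximations handle the high-dimensional latents:

* **MAP approximation.** The latents are fixed at an iteratively improved
  MAP estimate: starting from the best joint retained draw, the search
  alternately rescans all scalar draws at the fixed latents and all latent
  snapshots at the fixed scalars, accepting only improvements; the kernel
  sequence is therefore monotone and ends at least as high as the best joint
  draw. The denominator couples the complete-data likelihood at the fixed
  latents with the latent prior — i.e. the joint density
  `f(Y, mu_s_hat | mu_p)` — so that every scalar dimension (including `psi`,
  which enters only through the `z` prior) is informative.
* **Integrated likelihood.** `z` and the missing sex indicators are summed
  out analytically and the activity centers are integrated by a Riemann sum
  over a regular grid on `V` (default cell about 0.1 x 0.1 at full scale;
  a refinement check doubles the grid and compares). The permutation keeps
  its posterior draw; choosing `g(mu_p, L) = g(mu_p)/M!` cancels the uniform
  permutation prior exactly. Inter-dependencies among the integrated latents
  are ignored, so the integrated likelihood factorizes over individuals
  given `L`.

Setting `g` equal to the prior yields the harmonic-mean estimator, computed
from the complete-data log-likelihood of every retained draw.

## Information criteria and predictive loss

DIC uses the MAP estimate (not the posterior mean) for the plug-in deviance,
because the binary latents and the permutation make the posterior mean
meaningless; `p_DIC1 = 2(log f(Y|mu_hat) - mean_d log f(Y|mu^(d)))` and
`p_DIC2 = 2 Var_d log f(Y|mu^(d))` (denominator `N_iter`; always
nonnegative). WAIC partitions the data by augmented individual `i = 1..M`
(including all-zero rows) with three penalties: the lppd gap (`p_WAIC1`),
the pointwise posterior variance (`p_WAIC2`), and twice the pointwise
posterior mean absolute deviation (`p_WAIC3`) — the absolute-error analogue
of `p_WAIC2`. The posterior predictive loss `D_inf` simulates one replicate
data set per stored draw from the fitted model (entry-then-detection for
M1/M3, direct Bernoulli for M2/M4), maps the replicate's detector-2 rows
back to observed row order through that draw's permutation, and sums squared
bias plus predictive variance over the `2 M J K` binary cells. Evidence
methods select the largest log-marginal, the criteria the smallest value;
exact ties go to the model with fewer scalar parameters and are reported as
ties (split fractionally in selection proportions).

## The synthetic-data generator

The simulator reproduces the study design: a 5 x 7 state space with a 1-unit
buffer, a 10 x 16 grid (J = 160; spacing 0.3 on X, 0.3125 on Y — traps sit
at the cell centers of the buffered interior, which is what those printed
spacings imply), K = 50 occasions, N = 100 individuals with exactly 40 males
(the fixed design of the study, not a Binomial draw), M = 400, and twelve
(omega0, phi, sigma_m, sigma_f) scenarios. Detections follow the
entry-then-detection mechanism with conditionally independent detectors;
individuals with at least one simultaneous capture are fully identified,
the rest contribute unlinked single-detector rows, detector-2 row order is
shuffled so no identity leaks through labels, and sex is revealed for every
captured individual. What the generator does *not* emulate: behavioural
response to traps, occasion heterogeneity, misidentification, non-rectangular
habitat — so passing tests demonstrate correctness of the machinery under
the model's own assumptions, not robustness to their violation.

## Problem sizes used by the test surface

Fitting all four models to one full-scale data set takes days per chain, so
the package's tests and the acceptance script run a scaled-down preset:
7 x 7 traps, K = 15, N = 30 (12 male), M = 100, chains of 5,000 iterations
with 1,000 burn-in. The preset's geometry is a 1.4 x 1.4 state space with a
0.2 buffer (trap spacing 0.143). That choice deliberately restores the
full design's information content: cutting K from 50 to 15 at the full
design's relative spacing would leave a captured female with about one
expected detection per detector, making `sigma_f` (and through it `N`)
poorly identified — the same `N`-`theta`/`N`-`sigma_f` confounding the
low-information scenarios exhibit. At spacing 0.143 a captured female
expects about three detections per detector and roughly 85% of individuals
are captured, matching the high-information full-design scenarios.

## Numerical choices

* All densities and estimators work in log space with `logsumexp`;
  `xlogy`-style helpers make `0 * log 0 = 0` exact, and structural zeros
  (detections with zero probability) return `-inf` rather than underflowing.
* Transform round-trips are exact to 1e-12; the transformed-scale prior was
  verified against a finite-difference change-of-variables check.
* The tuning-density fit adds a 1e-8 ridge (with a warning) if the draw
  covariance is singular.
* Ties in `select_model` are exact floating-point ties; the tie rule exists
  for degenerate fixtures, not as a numerical tolerance.

## Known limitations

* Single-session, closed-population, binary detectors only.
* The permutation sampler conditions on `z` when proposing swaps; a row swap
  onto an excluded slot is rejected rather than jointly proposing `z`, which
  can slow identity mixing when `psi` is small and few augmented rows are
  switched on. At the preset's information levels this is immaterial (most
  captured individuals are fully identified).
* GD-IL is expensive at full scale (one Riemann integration per retained
  draw); `draw_stride` subsamples draws, which remains a valid Monte Carlo
  average at reduced precision.
* The update order (scalars, centers, inclusion, sexes, permutation) is one
  fixed valid choice; the original analysis's exact proposal mechanisms are
  not documented, so acceptance rates are not comparable.
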