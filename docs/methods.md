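# Methods

## Measurement model

Responses to item *j* with K_j ordered categories (default K = 5, codes
0..K−1) follow the graded response model. Cumulative category curves are
logistic,

P\*_jk(θ) = Pr(X_j ≥ k | θ) = 1 / (1 + exp(−a_j (θ − b_jk))),  k = 1..K−1,

with slope a_j > 0 and strictly ascending thresholds b_j1 < … < b_j,K−1;
category probabilities are adjacent differences P_jk = P\*_jk − P\*_j,k+1
(P\*_j0 = 1, P\*_jK = 0). The logistic metric carries **no 1.7 scaling
constant**; slopes from normal-ogive-scaled calibrations must be divided by
1.7 before use. Items are conditionally independent given θ, there are no
missing responses, and item parameters are treated as known calibrated
inputs throughout — the package never estimates them.

Expected Fisher information per item is I_j(θ) = Σ_k (P′_jk)² / P_jk with
P′_jk = a_j [P\*_jk(1−P\*_jk) − P\*_j,k+1(1−P\*_j,k+1)]; for the GRM this
equals the expected negated curvature of the log-likelihood because the
second-derivative terms cancel in expectation. Test information is the sum
over items. All standard errors of the point estimators use *expected*
(not observed) information.

## Trait estimators

All optimizing estimators search θ ∈ [−6, 6] by coarse-grid bracketing plus
bounded Brent refinement (tolerance 1e−7), with a 12,001-point grid as a
fallback on optimizer failure.

* **ML** maximizes log L(θ); SE = I(θ̂)^(−1/2). All-minimum / all-maximum
  patterns have monotone likelihoods: the estimate is clamped to the search
  bound and flagged `converged=False` rather than raising.
* **WML** maximizes log L(θ) + ½ log I(θ). Warm's original bias correction
  is dichotomous; the ½ log I penalty with expected polytomous information
  is adopted here as the standard generalization, and it keeps every
  pattern's estimate finite because the penalty diverges to −∞ in the
  tails. SE = I(θ̂)^(−1/2).
* **EAP** is the posterior mean under a Gaussian prior; its SE is the
  posterior SD. Quadrature uses 101 equally spaced nodes on prior mean ± 6
  prior SDs with weights proportional to the prior density, renormalized.
  Equally spaced trapezoid-type rules are spectrally accurate for these
  smooth, rapidly decaying integrands: the default grid agrees with a
  10,001-node reference to ~1e−15 on test banks, and recentring the grid on
  the prior keeps shifted priors (e.g. mean −0.8) fully covered.
* **MAP** maximizes the log-posterior; its SE comes from a central
  finite-difference curvature (h = 1e−3) at the mode.
* **Summed-score EAP** builds the score likelihood L(s | θ) by the
  Lord–Wingersky item-by-item convolution, then reports E(θ | X₊ = s),
  SD(θ | X₊ = s), and the marginal score probability P(s). The table is the
  practical "look-up" interface for clinicians who only record sum scores.

Batch scoring vectorizes the same objectives over persons on a step-0.01
grid with parabolic refinement of the argmax; it matches the scalar
optimizers to ~2e−5, far inside the reporting precision of any trait
estimate, and is what the simulation study uses.

Category probabilities are floored at 1e−10 only where logarithms are
taken, so probabilities still sum to one exactly while likelihoods stay
finite for any pattern.

## Reliable change

The CTT statistic divides the sum-score difference by a constant
SE_d = √2 · SD(X) · √(1 − α) (coefficient α reliability, N−1 variances), or
by the pooled √(SE²_pre + SE²_post) when per-occasion SEs are supplied. The
IRT statistic divides the trait-estimate difference by the root sum of
squared occasion SEs. Both are referred to N(0,1); testing is two-sided by
default (one-sided rules are available) and a statistic landing exactly on
the critical value is retained. Negative changes encode improvement, since
the instruments modeled here measure symptom severity.

## Empirical prior for the post-test

With item parameters fixed on the pre-test N(0,1) metric (the
identification convention), the post-test responses identify the moments of
g(θ_post) = N(μ_post, σ²_post). The fit maximizes the marginal
log-likelihood Σ_i log ∫ L_i(θ) φ(θ; μ, σ²) dθ by direct numerical
optimization — bounded scalar search over μ ∈ [−5, 5] with σ² fixed at 1 by
default (every study prior has unit variance), or Nelder–Mead over
(μ, log σ²) when variance estimation is requested. The quadrature grid is
re-centered on the candidate prior at every evaluation; EM brings nothing
at this problem size and direct search is trivially verifiable against a
fine grid. The asymptotic SE of μ̂ is taken from the finite-difference
curvature of the profile log-likelihood at the optimum.

The augmented pipeline scores the pre-test with EAP under N(0,1), fits
g(θ_post) (or accepts a fixed prior), scores the post-test with EAP under
the fitted prior, and applies the IRT statistic. Everything downstream of
the simulated data is deterministic.

## Simulation study

The Monte Carlo design crosses test length J ∈ {5, 10, 20}, true change
Δθ ∈ {0, −0.5, −1, −1.5}, a conditional θ grid on [−2.5, 3.5], two item
designs, and the estimator arms (WML; EAP with post-test priors N(0,1),
N(−0.2,1), N(−0.5,1), N(−0.8,1), pre-test always N(0,1); optional CTT).
Item designs: homogeneous — slopes U[1.5, 2.5], thresholds (−1, −0.5, 0.5,
1) + b̄; heterogeneous — slopes U[1, 2.5], thresholds (−0.5, −0.2, 0.2,
0.5) + b̄ — with the shift b̄ drawn per item from U[0, 1.25] and
U[−1.5, 2.5] respectively (a common per-item shift preserves threshold
order). A fresh bank is sampled in every replication. The CTT arm draws its
SE_d from a calibration sample simulated from the clinical population
θ ~ N(1/2, 1); this deliberately reproduces the original design's scale
mismatch between the CTT and IRT arms, and can be recentred by passing a
different population.

Within a replication, at each grid θ, N independent pre/post pattern pairs
are simulated (pre at θ, post at θ + Δθ) and shared across estimator arms.
The per-θ reading of the design — N pairs *at each* conditional θ — is
adopted because it yields well-defined conditional rejection rates; cell
summaries are the empirical two-sided rejection rate at α = .10 and the
bias and RMSD of Δθ̂ (RMSD ≥ |bias| by Jensen's inequality, checked).
Marginal summaries average cell biases and pool squared deviations over the
grid and replications.

Two profiles fix the problem sizes. The full profile mirrors the original
design (grid step .05, R = 100 replications, N = 5000 pairs, n_cal =
100,000) and is long-running. The desk profile — grid step 0.5, R = 20,
N = 500 — is the package's default and what the packaged checks run; at
this scale a conditional rate has Monte Carlo SE ≈ 0.003–0.013, small
enough for the bound- and ordering-style conclusions the study makes
(conservative Type I error; power gains from informative priors; RMSD
reductions), though not for point-reproducing full rate surfaces. Packaged
ordering checks use the homogeneous design. Reproducibility comes from a
single master seed whose per-(replication, cell) children are spawned
deterministically, so any cell can be regenerated in isolation.

The population reliability of the sampled test forms is computed by
averaging coefficient α over 50 freshly sampled banks with 100,000
simulated clinical-population respondents each; the bank-to-bank SE of the
average is ~0.002–0.006, well inside the ±0.02 band used to compare against
the design's printed values. The number of bank draws behind the original
printed reliabilities is not stated; 50 makes the sampling error of the
average negligible at this tolerance.

## What the generator does and does not emulate

Synthetic data are exactly GRM-conformant: correctly specified response
functions, Gaussian latent traits, invariant item parameters across
occasions, complete data, and independent persons. Passing tests therefore
demonstrate the estimators' and indices' behavior *under the model*; they
say nothing about robustness to DIF, non-Gaussian latent shapes,
multidimensionality, missingness, or item-parameter estimation error —
all of which are out of scope (item parameters are inputs here).

## Known limitations and numerical notes

* The WML variant for polytomous items (½ log I with expected information)
  is an assumption; other generalizations exist.
* Marginal bias over the full θ grid mixes shrinkage with floor/ceiling
  attenuation: at θ beyond the items' threshold range both occasions yield
  near-extreme patterns and every estimator's Δθ̂ is pulled toward zero.
  In Δθ < 0 conditions this adds a positive offset to all marginal biases,
  which can make the most informative prior's *marginal* |bias| smaller
  than the truth-matched prior's even though the matched prior minimizes
  conditional bias in the well-measured range.
* EAP/MAP priors are Gaussian only; empirical-histogram or mixture priors
  are not implemented.
* The decision rule treats boundary statistics as retained; with short
  tests the discrete pattern space makes empirical rates slightly
  conservative near the nominal level.
* Search bounds [−6, 6] cap ML divergence for extreme patterns; WML/EAP/MAP
  never reach the bounds in practice.
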