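# Methods

This note records the conventions, numerical choices and open design
decisions behind `fmblaw`, and what the synthetic generators do and do
not emulate.

## Conventions that make the identities exact

The Price partition and its FMB re-expression are *identities*, not
approximations, but only under a specific set of conventions, which the
package enforces rather than documents away:

- **Initial-weight population moments.** Every covariance and
  expectation is weighted by the initial frequencies `q` and uses
  population normalization (no `m/(m−1)` correction).  The selection
  term equals `Cov_q(w, θ)` and the transmission term `E_q(wΔθ)` only
  under this convention.
- **Relative fitness.** Fitness is normalized so `q·w = 1`; the
  constructor derives `w` from updated weights (or vice versa) and
  validates consistency to 1e−12.  `Population.from_performance`
  renormalizes raw performance values and keeps the raw vector for
  reporting.
- **Strictly interior simplex.** Zero frequencies are rejected
  everywhere (`Δq/q`, `log(q′/q)` and the Shahshahani metric all divide
  by `q`).  Extinct classes must be pruned upstream.
- **Regression with intercept.** The force `f` is the coefficient
  vector of the q-weighted least-squares regression of `w` on `θ`
  *with* an intercept.  The intercept is required for the identity
  `Cov_q(w, θ) = Cov_q(θ, θ) f` when predictors are uncentered, which is
  the identity every `Mf = selection` test relies on.
- **Singular metrics are surfaced, not hidden.** A rank-deficient
  centered covariance switches the solve to the Moore–Penrose
  minimum-norm solution and sets an explicit `singular` flag.  The
  reconstruction `Mf = Cov(w, θ)` remains exact because the covariance
  vector always lies in the column space of the covariance matrix.
- **Maximization is primary.** Performance `U` is maximized; a
  `minimize` orientation negates `U`, flipping the gradient and the
  Hessian sign convention in one place.

Identity tolerances are 1e−10 absolute / 1e−8 relative throughout the
validation checks; the partition itself is asserted at 1e−10.

## Information geometry

All logarithms are natural.  The squared Fisher–Rao step
`F = Σ(Δq)²/q`, the fitness variance `Var_q(w)`, and the Shahshahani
form `aᵀS⁻¹a` (with `S = diag(1/q)`, `a = Δq/q`) are three computations
of the same number and are tested against each other, not against a
stored constant.

The small-step limits `F/‖Δr‖² → 4` (square-root coordinates) and
`F/D(q′‖q) → 2` are evaluated by `limit_ratio_suite` on a ladder of
decreasing step scales.  Numerics matter here: at ε = 1e−6 the naive
KL sum loses ~4 digits to cancellation, so the suite computes `Δq`
exactly as `ε·direction`, `Δr` by the conjugate identity
`Δq/(√q′ + √q)`, and the KL via `log1p` of the exact relative change.
A linear Richardson step from the two smallest scales supplies the
`scale = 0` row (the raw 0/0 ratio is undefined there).

The d'Alembert balance is a continuous-time statement; the discrete
counterpart implemented here splits a step into two half-steps with
per-half Malthusian parameters `m1, m2` and reports `|m1·Δq_half + q·(m2 − m1)|`, using `q·Δm` for the inertial
work (the exact finite-difference analogue of the continuous identity
`q·dm = dq·dlog m`, and well defined when components of `m` are
negative).  This residual is O(ε³) and is tested by halving.  The exact
discrete conservation laws — the normalized-likelihood telescope
(`Δq·L + q′·ΔL = 0`) and the variational bracket identity — carry the
hard assertions at 1e−12/1e−10.

## Bayes and variational choices

The variational family parameter is identified with the candidate
distribution itself: the ELBO, its Price decomposition into
`Δq·log L̃ − D(q̂‖q)`, and the free-energy change need nothing more.  A
concrete mean-field family (product of independent marginals over a
factored state space) exists so that constrained optima are exercisable;
`variational_project` runs coordinate ascent with a deterministic sweep
order, each factor update being the exact coordinatewise ELBO maximizer,
so the ELBO trace is monotone.  Convergence is declared when a sweep
improves the ELBO by less than 1e−10.  Expected-free-energy policy
selection over actions is out of scope.

## Optimizer zoo

Every optimizer returns an `FMBStep` whose fields reconstruct the step
bit-for-bit (`audit_residual` ≤ 1e−12); the audit is part of the public
contract, not a debug aid.

- **Adam, as printed.** The implemented metric divides by `vₜ + c`
  directly — no square root, no bias correction — matching the printed
  identity `Δθₜ = Mf + Cβ = η mₜ/((1−u)(vₜ+c))`, which the tests check
  against the decomposition on random tuples.  Conventional
  `√vₜ` scaling is available behind `standard_sqrt=True` for comparison
  only.
- **BFGS.** The standard inverse-Hessian secant update is used, with
  updates skipped (and flagged) when the curvature condition fails.  On a quadratic with
  exact line searches the estimate reaches the true inverse curvature in
  `n` steps, which is the convergence property tested.
- **Boltzmann–Fisher metric.** `G = −E_q[H]` under `q ∝ exp(b·U)` with
  inverse temperature `b = 1` by default, evaluated over a supplied
  grid or sample cloud with optional quadrature weights.  For quadratic
  `U` the Hessian is constant and `G` is exact, which makes the
  natural-gradient step equal the Newton step — the tested equivalence.
- **Langevin noise.** `ξ = √(2η)·M^{1/2}ε` with the *symmetric*
  eigendecomposition square root (not Cholesky), one standard-normal
  vector consumed per call in documented order, so runs are reproducible
  from the seed.  `Cov[ξ] = 2ηM` is verified empirically at 10⁵ draws
  within 3 standard errors.
- **Minibatch noise.** `sgd_split` separates the full-data mean
  gradient from the batch deviation.  Sampling without replacement gives
  the finite-population variance law `(1/B)(1 − B/N)·σ²`;
  with-replacement batches give the pure `1/B` law used for the log-log
  slope test.
- Newton and natural-gradient steps default to unit step size; zero
  gradient with zero momentum yields the zero step (no stochastic
  restarts).

## Population methods

The evolution strategy is deliberately minimal: Gaussian sampling about
the current mean, fitness normalized to mean 1 over the uniform sample,
and a mean shift that *is* the Price selection term of the sampled
population — asserted every generation.  The sampling covariance blends
toward the fitness-weighted outer products of deviations at rate
α = 0.3 (rank-μ style).  Evolution paths, step-size control and other
full covariance-matrix-adaptation machinery are intentionally absent.
Nonpositive performance is handled by a shift-to-positive transform
(default) or exponential ranking; truncation selection is optional.
The closed-form check uses a linear 1-D performance `U = a + bθ` with
Gaussian sampling: the expected mean shift of the population-moment
estimator is `(1 − 1/m)·bσ²/U(μ)` up to `O((bσ/a)²/m)` ratio terms,
compared at 3 standard errors over 2000 generations (m = 50, a = 10,
b = 2, σ² = 0.25).

The Gaussian-process update concerns the training-input mean only:
`Δḡ = (K⁻¹ + σ⁻²I)⁻¹ σ⁻²(y − μ₀)`, tested as a matrix identity against
`K(K + σ²I)⁻¹(y − μ₀)` at N = 30.  Ill-conditioned kernels receive a
diagonal jitter of 1e−10 times the baseline variance, with a flag.
Kernel hyperparameters are fixed per run.

The Kalman filter renames the dynamics matrix to `A` and the observation
map to avoid collisions with the Fisher–Rao symbol and the Hessian.  The
posterior covariance uses the Joseph form, chosen because it preserves
symmetry and positive semidefiniteness over long runs.  The mean update is exposed as
`M = P⁻`, `f = HᵀS⁻¹ν` and tested against the gain form each step.

## Hierarchy

Group expectations use group weights `q_g`; within-group moments use
`q_{j|g}`; the flattened weight is the product — the only convention
under which the two-level recursion is exact.  Member populations carry
raw within-group fitness (group mean `w̄_g ≠ 1`), with the global
`q_g`-weighted mean validated to 1; the `Population` constructor exposes
`unit_mean_fitness=False` for exactly this case.  The between-group bias
is centered as `b_B = E_g(b_g)` so the residuals `b̃_g` average to zero.
Only two levels are implemented; deeper recursion is an extension point.

The Baldwin demonstration defines a learning trial as independent
per-bit flips with probability `flip_prob`, success being any trial
matching the target — chosen because the hit probability has the closed
form `1 − (1 − p^d(1−p)^(L−d))^G`, computed via `log1p`/`expm1` so it
stays monotone in the Hamming distance `d` all the way to underflow.
Fitness is `1 + bonus·hit` (Bernoulli draw or its expectation), only
seed strings are transmitted, and selection is multinomial resampling
proportional to fitness.  With no mutation of seeds, the demonstration
shows the selection response — declining mean distance — not an
open-ended search.

The lookahead wrapper blends `θ_slow ← θ_slow + α(θ_fast − θ_slow)`
after each run of `k` inner steps; `α = 1, k = 1` reduces to the bare
inner optimizer.  It is the single representative of two-timescale
single-vector methods; meta-learning and weight-averaging algorithms are
out of scope.

## Synthetic data

`generate_population` draws `q` from a symmetric Dirichlet(5), Gaussian
traits, and fitness from a linear map plus Gaussian noise (shifted
positive and renormalized), a constant, or a Boltzmann weighting of a
concave quadratic.  Trait updates are either a shared constant (pure
`γ` bias) or fitness-correlated (nonzero `Cβ`).  These fixtures exercise
every identity, but they are identities — exact for *any* valid
population — so passing tests certify the algebra and the numerics, not
any claim about real biological or training data: the generators have no
linkage, no heritability structure, no heavy tails, and no
model misspecification.  The surface catalog (random-rotation quadratics
with controlled condition number, a 1-D quartic, a concave
positive-orthant surface) provides closed-form gradients and Hessians,
self-checked against central finite differences at 1e−5 relative.

Problem sizes used by the test suite and acceptance script: 1000 random
populations (m ∈ [5, 25), n ∈ [1, 4)) for the identity sweep, 10⁷ draws
for the bit-string match bound, 10⁵ Langevin draws, 2000 resamples per
batch size for the minibatch variance law, and 2000 generations for the
evolution-strategy expectation — chosen so each stochastic check resolves
its target at 3 standard errors while the whole suite stays at
desk scale.

## Known limitations

- Sampling error of `f` and `M` is not estimated; population quantities
  are treated as exact.
- No genetic bookkeeping (alleles, ploidy, linkage); traits are abstract
  real vectors.
- The continuous-time balance law is exercised only through its discrete
  counterparts and the small-step residual.
- The statistical (dimension-reducing) reading of the Fisher matrix is
  noted but not implemented; only the diagonal Shahshahani form is used.
- No line searches or trust-region logic; the BFGS test supplies its own
  exact quadratic line search.
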