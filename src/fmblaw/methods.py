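"""Population methods reduced to metric-times-force form.

Three spatially extended algorithms whose mean update is exactly Mf:

* a simplified evolution strategy whose mean shift *is* the Price
  selection term Cov(w, θ) of the sampled batch;
* the Gaussian-process posterior-mean update, Δḡ = Mf with
  M = (K⁻¹ + σ⁻²I)⁻¹ the inverse total Fisher information and
  f = σ⁻²(y − μ₀) the data force — algebraically equal to the textbook
  K(K + σ²I)⁻¹(y − μ₀);
* the Kalman filter, Δx̂ = P⁻HᵀS⁻¹ν with the prior covariance P⁻ as the
  metric and the information-weighted innovation as the force.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np
import scipy.linalg

from .optim import FMBStep, MetricNotPD, PerformanceSurface, _require_pd
from .price import Population, price_partition

__all__ = [
    "ESState",
    "GPModel",
    "KalmanModel",
    "squared_exponential_kernel",
    "es_generation",
    "gp_mean_update",
    "kalman_update",
]


@dataclass(frozen=True)
class ESState:
    """Evolution-strategy search state: target mean, sampling covariance,

    the last sampled batch as a :class:`~fmblaw.price.Population`, and the
    generation counter."""

    mean: np.ndarray
    sampling_cov: np.ndarray
    population: Optional[Population] = None
    generation: int = 0

    def __post_init__(self):
        mu = np.asarray(self.mean, dtype=float)
        C = np.asarray(self.sampling_cov, dtype=float)
        object.__setattr__(self, "mean", mu)
        object.__setattr__(self, "sampling_cov", _require_pd(C, "sampling covariance"))


def _positive_fitness(u: np.ndarray, transform: str) -> np.ndarray:
    if np.all(u > 0) or transform == "none":
        if np.any(u <= 0):
            raise ValueError(
                "nonpositive performance; enable a fitness transform "
                "('shift' or 'exp_rank')"
            )
        return u
    if transform == "shift":
        span = float(u.max() - u.min())
        return u - u.min() + (0.1 * span if span > 0 else 1.0)
    if transform == "exp_rank":
        order = np.argsort(np.argsort(-u))  # 0 = best
        return np.exp(-order / max(1, u.size - 1))
    raise ValueError(f"unknown fitness transform {transform!r}")


def es_generation(
    state: ESState,
    surface: PerformanceSurface,
    pop_size: int,
    rng: np.random.Generator,
    alpha: float = 0.3,
    transform: str = "shift",
    truncation: Optional[float] = None,
) -> ESState:
    """One evolution-strategy generation as an explicit Price update.

    Samples ``pop_size`` points from N(mean, sampling_cov), normalizes
    performance to mean-1 fitness over the uniform sample, and moves the
    mean by the sample's Price selection term Cov(w, θ).  The sampling
    covariance blends toward the fitness-weighted outer products of the
    selected deviations at rate ``alpha`` (rank-μ style; no evolution
    paths or step-size control).  ``truncation`` keeps only the top
    fraction before weighting, when given.
    """
    if pop_size < 2:
        raise ValueError("pop_size must be at least 2")
    X = rng.multivariate_normal(state.mean, state.sampling_cov, size=pop_size)
    u = np.array([surface.signed_value(x) for x in X])
    if truncation is not None:
        cutoff = np.quantile(u, 1.0 - truncation)
        keep = u >= cutoff
        X, u = X[keep], u[keep]
    u_pos = _positive_fitness(u, transform)
    m = X.shape[0]
    q = np.full(m, 1.0 / m)
    pop = Population.from_performance(q, X, u_pos)
    selection, _ = price_partition(pop)
    new_mean = state.mean + selection
    dev = X - state.mean
    weighted_outer = (pop.fitness[:, None] * dev).T @ dev / m
    new_cov = (1 - alpha) * state.sampling_cov + alpha * weighted_outer
    return ESState(
        mean=new_mean,
        sampling_cov=new_cov,
        population=pop,
        generation=state.generation + 1,
    )


def squared_exponential_kernel(sigma_g2: float, length_scale: float
                               ) -> Callable[[np.ndarray, np.ndarray], float]:
    """k(x, x̃) = σ_g²·exp(−‖x − x̃‖²/(2ℓ²))."""
    if sigma_g2 <= 0 or length_scale <= 0:
        raise ValueError("sigma_g2 and length_scale must be positive")

    def k(x, xt):
        x = np.atleast_1d(np.asarray(x, float))
        xt = np.atleast_1d(np.asarray(xt, float))
        return sigma_g2 * float(np.exp(-np.sum((x - xt) ** 2) / (2 * length_scale**2)))

    return k


@dataclass(frozen=True)
class GPModel:
    """Gaussian-process prior over function values at N training inputs."""

    kernel: Callable[[np.ndarray, np.ndarray], float]
    inputs: np.ndarray
    noise_var: float
    prior_mean: np.ndarray
    K: np.ndarray = None
    jittered: bool = field(default=False, compare=False)

    def __post_init__(self):
        X = np.asarray(self.inputs, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        mu0 = np.asarray(self.prior_mean, dtype=float)
        if mu0.size != X.shape[0]:
            raise ValueError("prior_mean must have one entry per input")
        if self.noise_var <= 0:
            raise ValueError("noise_var must be positive")
        if self.K is None:
            N = X.shape[0]
            K = np.empty((N, N))
            for i in range(N):
                for j in range(i, N):
                    K[i, j] = K[j, i] = self.kernel(X[i], X[j])
        else:
            K = np.asarray(self.K, dtype=float)
        jittered = False
        K = 0.5 * (K + K.T)
        scale = float(np.max(np.diag(K))) if K.size else 1.0
        if np.linalg.eigvalsh(K).min() < 1e-12 * scale:
            # conditioning rescue: tiny diagonal jitter scaled to the baseline variance
            K = K + 1e-10 * scale * np.eye(K.shape[0])
            jittered = True
        object.__setattr__(self, "inputs", X)
        object.__setattr__(self, "prior_mean", mu0)
        object.__setattr__(self, "K", 0.5 * (K + K.T))
        object.__setattr__(self, "jittered", jittered)


def gp_mean_update(model: GPModel, observations) -> np.ndarray:
    """Posterior-mean change at the training inputs, Δḡ = Mf.

    M = (K⁻¹ + σ⁻²I)⁻¹ is the inverse of the total Fisher information
    (prior precision plus data precision) and f = σ⁻²(y − μ₀) the force of
    the data; equal to the standard K(K + σ²I)⁻¹(y − μ₀).
    """
    y = np.asarray(observations, dtype=float)
    if y.size != model.prior_mean.size:
        raise ValueError("observations must have one entry per input")
    N = y.size
    K, s2 = model.K, model.noise_var
    f = (y - model.prior_mean) / s2
    precision = np.linalg.inv(K) + np.eye(N) / s2
    M = np.linalg.inv(precision)
    return M @ f


@dataclass(frozen=True)
class KalmanModel:
    """Linear-Gaussian state-space model and its current belief.

    The paper-facing symbols F (dynamics) and H (observation) are renamed
    ``dynamics``/``observation`` to avoid clashing with the Fisher–Rao
    step length and the Hessian elsewhere in the package.
    """

    dynamics: np.ndarray          # state transition A
    process_noise_cov: np.ndarray  # Q, PSD
    observation: np.ndarray       # measurement map (k×n)
    obs_noise_cov: np.ndarray     # R, PD
    state_mean: np.ndarray        # x̂
    state_cov: np.ndarray         # P, PSD

    def __post_init__(self):
        A = np.asarray(self.dynamics, float)
        Q = np.asarray(self.process_noise_cov, float)
        Hm = np.atleast_2d(np.asarray(self.observation, float))
        R = np.asarray(self.obs_noise_cov, float)
        x = np.asarray(self.state_mean, float)
        P = np.asarray(self.state_cov, float)
        for M, name in ((Q, "process_noise_cov"), (P, "state_cov")):
            if not np.allclose(M, M.T, atol=1e-10 * max(1.0, np.abs(M).max())):
                raise ValueError(f"{name} must be symmetric")
            if np.any(np.linalg.eigvalsh(M) < -1e-10):
                raise ValueError(f"{name} must be positive semidefinite")
        _require_pd(R, "obs_noise_cov")
        object.__setattr__(self, "dynamics", A)
        object.__setattr__(self, "process_noise_cov", 0.5 * (Q + Q.T))
        object.__setattr__(self, "observation", Hm)
        object.__setattr__(self, "obs_noise_cov", 0.5 * (R + R.T))
        object.__setattr__(self, "state_mean", x)
        object.__setattr__(self, "state_cov", 0.5 * (P + P.T))


def kalman_update(model: KalmanModel, observation) -> tuple[KalmanModel, FMBStep]:
    """One predict–update cycle, with the mean update exposed in Mf form.

    Predict: x̂⁻ = A·x̂, P⁻ = A·P·Aᵀ + Q.  The innovation ν = y − H·x̂⁻ has
    covariance S = H·P⁻·Hᵀ + R; the mean moves by Δx̂ = P⁻·Hᵀ·S⁻¹·ν, i.e.
    metric M = P⁻ (prior covariance = inverse curvature of the estimate
    error) times force f = Hᵀ·S⁻¹·ν (the innovation weighted by its
    information content).  The posterior covariance uses the Joseph form,
    which preserves symmetry and positive semidefiniteness.
    """
    y = np.atleast_1d(np.asarray(observation, dtype=float))
    A, Q = model.dynamics, model.process_noise_cov
    Hm, R = model.observation, model.obs_noise_cov
    x_prior = A @ model.state_mean
    P_prior = A @ model.state_cov @ A.T + Q
    P_prior = 0.5 * (P_prior + P_prior.T)
    nu = y - Hm @ x_prior
    S = Hm @ P_prior @ Hm.T + R
    try:
        S_chol = scipy.linalg.cho_factor(S)
    except scipy.linalg.LinAlgError:
        raise MetricNotPD("innovation covariance is singular (R must be PD)")
    f = Hm.T @ scipy.linalg.cho_solve(S_chol, nu)
    n = x_prior.size
    step = FMBStep(
        metric=P_prior,
        force=f,
        bias_metric_part=np.zeros(n),
        intrinsic_bias=np.zeros(n),
        noise=np.zeros(n),
        step=P_prior @ f,
    )
    gain = P_prior @ Hm.T @ scipy.linalg.cho_solve(S_chol, np.eye(y.size))
    I_KH = np.eye(n) - gain @ Hm
    P_post = I_KH @ P_prior @ I_KH.T + gain @ R @ gain.T
    new_model = replace(
        model,
        state_mean=x_prior + step.step,
        state_cov=0.5 * (P_post + P_post.T),
    )
    return new_model, step
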