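"""Single-vector update algorithms, each audited against its FMB decomposition.

Every optimizer here returns an :class:`FMBStep` whose fields reproduce the
parameter step exactly:

    Δθ = M f + Cβ + γ + ξ,

with M the metric (identity scaled by the step size, inverse Hessian,
inverse Fisher matrix, mirror-potential inverse Hessian, or Adam's
running-average diagonal), f the performance gradient, Cβ + γ the bias
(momentum, regularization shrinkage), and ξ the exploration noise
(Langevin draws, minibatch sampling error).

Sign convention: performance U is maximized.  A surface flagged
``minimize`` is handled by negating U, which flips both the gradient and
the Hessian sign — same algorithms, different signs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "FMBStep",
    "OptimizerState",
    "PerformanceSurface",
    "MirrorPotential",
    "MetricNotPD",
    "quadratic_potential",
    "entropy_potential",
    "gd_step",
    "newton_step",
    "quadratic_model_gain",
    "bfgs_metric_update",
    "natural_gradient_step",
    "boltzmann_fisher",
    "mirror_step_first_order",
    "mirror_step_exact",
    "regularized_gd_step",
    "polyak_step",
    "adam_paper_step",
    "sgld_step",
    "sgd_split",
]


class MetricNotPD(ValueError):
    """Raised when a candidate metric fails to be positive definite."""


@dataclass(frozen=True)
class FMBStep:
    """One parameter update and its exact force–metric–bias–noise split."""

    metric: np.ndarray            # M (n×n PSD)
    force: np.ndarray             # f
    bias_metric_part: np.ndarray  # Cβ (as a vector contribution)
    intrinsic_bias: np.ndarray    # γ
    noise: np.ndarray             # ξ (zero for deterministic methods)
    step: np.ndarray              # Δθ = Mf + Cβ + γ + ξ

    def audit_residual(self) -> float:
        """Max abs deviation of step from its own decomposition."""
        recon = (
            self.metric @ self.force
            + self.bias_metric_part
            + self.intrinsic_bias
            + self.noise
        )
        return float(np.max(np.abs(self.step - recon)))


def _deterministic_step(metric, force, bias_metric_part=None, intrinsic_bias=None,
                        noise=None) -> FMBStep:
    metric = np.asarray(metric, dtype=float)
    force = np.asarray(force, dtype=float)
    n = force.size
    cb = np.zeros(n) if bias_metric_part is None else np.asarray(bias_metric_part, float)
    gamma = np.zeros(n) if intrinsic_bias is None else np.asarray(intrinsic_bias, float)
    xi = np.zeros(n) if noise is None else np.asarray(noise, float)
    return FMBStep(metric, force, cb, gamma, xi, metric @ force + cb + gamma + xi)


@dataclass(frozen=True)
class OptimizerState:
    """Evolving per-algorithm quantities for iterated single-vector updates."""

    position: np.ndarray
    momentum: np.ndarray = None
    second_moment: np.ndarray = None
    inverse_metric_estimate: np.ndarray = None
    step_index: int = 0
    rng: Optional[np.random.Generator] = field(default=None, compare=False)
    skipped_update: bool = False

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        object.__setattr__(self, "position", pos)
        n = pos.size
        if self.momentum is None:
            object.__setattr__(self, "momentum", np.zeros(n))
        else:
            object.__setattr__(self, "momentum", np.asarray(self.momentum, float))
        if self.second_moment is None:
            object.__setattr__(self, "second_moment", np.zeros(n))
        else:
            sm = np.asarray(self.second_moment, float)
            if np.any(sm < 0):
                raise ValueError("second_moment must be elementwise nonnegative")
            object.__setattr__(self, "second_moment", sm)
        if self.inverse_metric_estimate is None:
            object.__setattr__(self, "inverse_metric_estimate", np.eye(n))
        else:
            B = np.asarray(self.inverse_metric_estimate, float)
            if not np.allclose(B, B.T, atol=1e-10 * max(1.0, np.abs(B).max())):
                raise ValueError("inverse_metric_estimate must be symmetric")
            object.__setattr__(self, "inverse_metric_estimate", B)


@dataclass(frozen=True)
class PerformanceSurface:
    """A performance function with closed-form gradient and Hessian.

    ``orientation`` is ``"maximize"`` (default) or ``"minimize"``; all
    algorithms internally maximize the signed performance.
    """

    evaluate: Callable[[np.ndarray], float]
    gradient: Callable[[np.ndarray], np.ndarray]
    hessian: Callable[[np.ndarray], np.ndarray]
    orientation: str = "maximize"
    name: str = ""

    def __post_init__(self):
        if self.orientation not in ("maximize", "minimize"):
            raise ValueError("orientation must be 'maximize' or 'minimize'")

    @property
    def sign(self) -> float:
        return 1.0 if self.orientation == "maximize" else -1.0

    def signed_value(self, theta) -> float:
        return self.sign * float(self.evaluate(np.asarray(theta, float)))

    def signed_gradient(self, theta) -> np.ndarray:
        return self.sign * np.asarray(self.gradient(np.asarray(theta, float)), float)

    def signed_hessian(self, theta) -> np.ndarray:
        return self.sign * np.asarray(self.hessian(np.asarray(theta, float)), float)

    def check_gradient(self, theta, rel_tol: float = 1e-5, h: float = 1e-6) -> float:
        """Central finite-difference self-check of the gradient at θ.

        Returns the relative error; raises if it exceeds ``rel_tol``."""
        theta = np.asarray(theta, dtype=float)
        g = np.asarray(self.gradient(theta), float)
        fd = np.empty_like(g)
        for i in range(theta.size):
            e = np.zeros_like(theta)
            e[i] = h
            fd[i] = (self.evaluate(theta + e) - self.evaluate(theta - e)) / (2 * h)
        scale = max(1.0, float(np.linalg.norm(g)))
        err = float(np.linalg.norm(fd - g)) / scale
        if err > rel_tol:
            raise ValueError(f"gradient self-check failed: rel error {err:.2e}")
        return err


def _require_pd(M: np.ndarray, what: str) -> np.ndarray:
    """Cholesky-based positive-definiteness gate."""
    M = np.asarray(M, dtype=float)
    try:
        np.linalg.cholesky(0.5 * (M + M.T))
    except np.linalg.LinAlgError:
        raise MetricNotPD(f"{what} is not positive definite")
    return 0.5 * (M + M.T)


# ---------------------------------------------------------------------------
# deterministic force–metric steps


def gd_step(surface: PerformanceSurface, theta, eta: float) -> FMBStep:
    """Plain gradient ascent: M = ηI, f = ∇U, Δθ = η∇U (sign per orientation)."""
    if eta <= 0:
        raise ValueError("step size eta must be positive")
    f = surface.signed_gradient(theta)
    return _deterministic_step(eta * np.eye(f.size), f)


def newton_step(surface: PerformanceSurface, theta, damping: float = 0.0) -> FMBStep:
    """Newton update with M = (−H)⁻¹ on the maximize scale.

    Indefinite curvature raises :class:`MetricNotPD` unless a damping λ > 0
    is supplied, in which case M = (−H + λI)⁻¹.
    """
    f = surface.signed_gradient(theta)
    Ht = -surface.signed_hessian(theta)
    if damping:
        Ht = Ht + damping * np.eye(f.size)
    Ht = _require_pd(Ht, "negated Hessian (plus damping)")
    return _deterministic_step(np.linalg.inv(Ht), f)


def quadratic_model_gain(surface: PerformanceSurface, theta, delta) -> float:
    """Second-order predicted performance gain fᵀΔθ − Δθᵀ(−H)Δθ/2.

    Exact on quadratics; the Newton direction maximizes it among steps of
    equal metric length Δθᵀ(−H)Δθ."""
    delta = np.asarray(delta, dtype=float)
    f = surface.signed_gradient(theta)
    Ht = _require_pd(-surface.signed_hessian(theta), "negated Hessian")
    return float(f @ delta - 0.5 * delta @ Ht @ delta)


def bfgs_metric_update(state: OptimizerState, delta_theta, delta_grad,
                       orientation: str = "maximize") -> OptimizerState:
    """Secant (BFGS) update of the running inverse-metric estimate.

    With s = Δθ and y the curvature pair (−Δ∇U for maximization, +Δ∇U for
    minimization so that y approximates H̃s for the positive-definite H̃),
    the updated estimate B satisfies By = s exactly and stays symmetric
    positive definite whenever s·y > 0.  When the curvature condition
    fails, the update is skipped and ``skipped_update`` is set.
    """
    s = np.asarray(delta_theta, dtype=float)
    y = np.asarray(delta_grad, dtype=float)
    if orientation == "maximize":
        y = -y
    sy = float(s @ y)
    B = state.inverse_metric_estimate
    if sy <= 1e-12 * max(1.0, float(np.linalg.norm(s) * np.linalg.norm(y))):
        return replace(state, skipped_update=True)
    if np.allclose(B @ y, s, rtol=0, atol=1e-14 * max(1.0, np.abs(s).max())):
        return replace(state, skipped_update=False)
    rho = 1.0 / sy
    n = s.size
    V = np.eye(n) - rho * np.outer(s, y)
    B_new = V @ B @ V.T + rho * np.outer(s, s)
    B_new = 0.5 * (B_new + B_new.T)
    return replace(state, inverse_metric_estimate=B_new, skipped_update=False)


def natural_gradient_step(surface: PerformanceSurface, theta, fisher) -> FMBStep:
    """Natural-gradient update Δθ = G⁻¹∇U with the Fisher matrix G as curvature."""
    G = _require_pd(fisher, "Fisher matrix")
    f = surface.signed_gradient(theta)
    return _deterministic_step(np.linalg.inv(G), f)


def boltzmann_fisher(surface: PerformanceSurface, points, inv_temp: float = 1.0,
                     base_weights=None) -> np.ndarray:
    """Fisher matrix G = −E_q[H(θ)] under Boltzmann weights q(θ) ∝ exp(b·U(θ)).

    ``points`` is a P×n array of quadrature/sample locations; optional
    ``base_weights`` carry quadrature cell volumes (uniform by default).
    For a strictly concave U the result is symmetric positive definite; a
    quadratic U returns its (constant) negated Hessian exactly.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    u = np.array([surface.signed_value(p) for p in pts])
    logw = inv_temp * u
    if base_weights is not None:
        bw = np.asarray(base_weights, dtype=float)
        if np.any(bw <= 0) or bw.shape[0] != pts.shape[0]:
            raise ValueError("base_weights must be positive, one per point")
        logw = logw + np.log(bw)
    logw -= logw.max()
    qw = np.exp(logw)
    z = qw.sum()
    if not np.isfinite(z) or z <= 0:
        raise ValueError("Boltzmann normalizer diverged on the supplied points")
    qw /= z
    n = pts.shape[1]
    G = np.zeros((n, n))
    for p, qi in zip(pts, qw):
        G -= qi * surface.signed_hessian(p)
    return 0.5 * (G + G.T)


# ---------------------------------------------------------------------------
# mirror geometry


@dataclass(frozen=True)
class MirrorPotential:
    """Strictly convex potential φ defining the mirror geometry.

    ``grad_inverse`` maps a dual vector back to the primal domain, i.e.
    inverts ∇φ; required for the exact mirror step.
    """

    value: Callable[[np.ndarray], float]
    grad: Callable[[np.ndarray], np.ndarray]
    hess: Callable[[np.ndarray], np.ndarray]
    grad_inverse: Optional[Callable[[np.ndarray], np.ndarray]] = None
    name: str = ""


quadratic_potential = MirrorPotential(
    value=lambda t: 0.5 * float(t @ t),
    grad=lambda t: t,
    hess=lambda t: np.eye(t.size),
    grad_inverse=lambda z: z,
    name="quadratic",
)

entropy_potential = MirrorPotential(
    value=lambda t: float(np.sum(t * np.log(t))),
    grad=lambda t: 1.0 + np.log(t),
    hess=lambda t: np.diag(1.0 / t),
    grad_inverse=lambda z: np.exp(z - 1.0),
    name="negative entropy",
)


def mirror_step_first_order(surface: PerformanceSurface, theta,
                            potential: MirrorPotential, eta: float) -> FMBStep:
    """First-order mirror ascent: M = η·Hφ⁻¹, a Newton-like step in the

    mirror geometry mapped back to the primal coordinates."""
    if eta <= 0:
        raise ValueError("step size eta must be positive")
    theta = np.asarray(theta, dtype=float)
    Hphi = _require_pd(potential.hess(theta), "mirror potential Hessian")
    f = surface.signed_gradient(theta)
    return _deterministic_step(eta * np.linalg.inv(Hphi), f)


def mirror_step_exact(surface: PerformanceSurface, theta,
                      potential: MirrorPotential, eta: float) -> np.ndarray:
    """Exact mirror ascent: solve ∇φ(θ') = ∇φ(θ) + η∇U(θ); returns θ'.

    Differs from the first-order step by O(η²)."""
    if eta <= 0:
        raise ValueError("step size eta must be positive")
    if potential.grad_inverse is None:
        raise ValueError("potential has no invertible gradient map")
    theta = np.asarray(theta, dtype=float)
    dual = potential.grad(theta) + eta * surface.signed_gradient(theta)
    return np.asarray(potential.grad_inverse(dual), dtype=float)


# ---------------------------------------------------------------------------
# bias: regularization and momentum


def regularized_gd_step(surface: PerformanceSurface, theta, eta: float,
                        lam: float, prior_point=None) -> FMBStep:
    """Gradient ascent with shrinkage toward a prior point.

    M = ηI, f = ∇U, γ = −ηλ(θ − θ_prior); the fixed point balances the
    performance force against the prior pull, ∇U = λ(θ − θ_prior).
    """
    if eta <= 0 or lam <= 0:
        raise ValueError("eta and lam must be positive")
    theta = np.asarray(theta, dtype=float)
    prior = np.zeros_like(theta) if prior_point is None else np.asarray(prior_point, float)
    f = surface.signed_gradient(theta)
    gamma = -eta * lam * (theta - prior)
    return _deterministic_step(eta * np.eye(theta.size), f, intrinsic_bias=gamma)


def polyak_step(state: OptimizerState, surface: PerformanceSurface, eta: float,
                u: float) -> tuple[OptimizerState, FMBStep]:
    """Heavy-ball momentum: m_t = (1−u)g_t + u·m_{t−1}, Δθ = η·m_t.

    FMB split: M = η(1−u)I carries the fresh gradient g_t; the momentum
    carry-over η·u·m_{t−1} is performance-independent bias γ.
    """
    if not (0 <= u < 1) or eta <= 0:
        raise ValueError("require 0 ≤ u < 1 and eta > 0")
    g = surface.signed_gradient(state.position)
    m_new = (1 - u) * g + u * state.momentum
    gamma = eta * u * state.momentum
    step = _deterministic_step(eta * (1 - u) * np.eye(g.size), g, intrinsic_bias=gamma)
    new_state = replace(
        state,
        position=state.position + step.step,
        momentum=m_new,
        step_index=state.step_index + 1,
    )
    return new_state, step


def adam_paper_step(state: OptimizerState, surface: PerformanceSurface, eta: float,
                    u: float, s: float, c: float,
                    standard_sqrt: bool = False) -> tuple[OptimizerState, FMBStep]:
    """Momentum plus adaptive diagonal metric from squared-gradient averages.

    m_t = (1−u)g_t + u·m_{t−1},  v_t = (1−s)g_t² + s·v_{t−1},
    M = diag(η/(v_t + c)),  f = g_t,  Cβ = M·u·m_{t−1}/(1−u),
    so Δθ = Mf + Cβ = η·m_t / ((1−u)(v_t + c)) elementwise — the momentum
    update rescaled by the adaptive metric.  The metric divides by v_t + c
    directly (no square root, no bias correction); ``standard_sqrt=True``
    switches to the conventional √v_t + c denominator for comparison runs.
    """
    if not (0 <= u < 1 and 0 <= s < 1) or c <= 0 or eta <= 0:
        raise ValueError("require 0 ≤ u,s < 1, c > 0, eta > 0")
    g = surface.signed_gradient(state.position)
    m_new = (1 - u) * g + u * state.momentum
    v_new = (1 - s) * g**2 + s * state.second_moment
    denom = (np.sqrt(v_new) if standard_sqrt else v_new) + c
    M = np.diag(eta / denom)
    if u > 0:
        cbeta = M @ (u * state.momentum / (1 - u))
    else:
        cbeta = np.zeros_like(g)
    step = _deterministic_step(M, g, bias_metric_part=cbeta)
    new_state = replace(
        state,
        position=state.position + step.step,
        momentum=m_new,
        second_moment=v_new,
        step_index=state.step_index + 1,
    )
    return new_state, step


# ---------------------------------------------------------------------------
# noise: Langevin and minibatch sampling


def _sym_sqrt(M: np.ndarray) -> np.ndarray:
    """Symmetric PSD square root via eigendecomposition."""
    vals, vecs = np.linalg.eigh(0.5 * (M + M.T))
    if np.any(vals < -1e-12 * max(1.0, vals.max())):
        raise MetricNotPD("matrix has negative eigenvalues")
    return (vecs * np.sqrt(np.clip(vals, 0, None))) @ vecs.T


def sgld_step(surface: PerformanceSurface, theta, metric, eta: float,
              rng: np.random.Generator) -> FMBStep:
    """Langevin exploration step Δθ = ηM∇U + √(2η)·M^{1/2}·ε, ε ~ N(0, I).

    The noise ξ has mean zero and covariance 2ηM: fluctuations scale with
    the inverse-curvature metric, exploring widest where the surface is
    flattest.  One length-n standard-normal vector is consumed per call.
    """
    if eta < 0:
        raise ValueError("eta must be nonnegative")
    M = _require_pd(metric, "Langevin metric")
    f = surface.signed_gradient(theta)
    if eta == 0:
        return _deterministic_step(0.0 * M, f)
    eps = rng.standard_normal(f.size)
    xi = np.sqrt(2 * eta) * (_sym_sqrt(M) @ eps)
    return _deterministic_step(eta * M, f, noise=xi)


def sgd_split(per_datum_gradients, batch_indices) -> tuple[np.ndarray, np.ndarray]:
    """Split a minibatch gradient into signal and sampling noise.

    signal is the full-data mean gradient (the true force direction);
    noise is the batch mean minus the signal.  Over uniform random batches
    the noise has mean zero with componentwise variance
    (1/B)(1 − B/N)·population variance for without-replacement batches, or
    a pure 1/B law with replacement.
    """
    grads = np.asarray(per_datum_gradients, dtype=float)
    if grads.ndim == 1:
        grads = grads[:, None]
    idx = np.asarray(batch_indices, dtype=int)
    if idx.size == 0:
        raise ValueError("batch must be nonempty")
    if idx.min() < 0 or idx.max() >= grads.shape[0]:
        raise ValueError("batch indices out of range")
    signal = grads.mean(axis=0)
    noise = grads[idx].mean(axis=0) - signal
    return signal, noise
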