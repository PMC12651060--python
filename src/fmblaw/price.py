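"""Exact Price-equation partitioning of change in a weighted population.

The Price equation splits the change in a weighted mean trait vector,

    Δθ̄ = q'·θ' − q·θ = Δq·θ + q'·Δθ = Cov_q(w, θ) + E_q(w Δθ),

into a *selection* term driven by frequency change and a *transmission*
term driven by within-type trait change.  Re-expressing each term through
a q-weighted least-squares regression of fitness on traits gives the
force–metric–bias (FMB) form

    Δθ̄ = M f + (C β + γ),

with M = Cov_q(θ, θ) the trait covariance (metric), f the partial
regression of relative fitness w on θ (force), C = Cov_q(Δθ, Δθ),
β the regression of w on Δθ, and γ = E_q(Δθ) the intrinsic bias.

All moments are population moments weighted by the *initial* frequencies
q (no sample-size correction); the identities are exact only under this
convention.  Fitness is relative: q·w = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Population",
    "RegressionFit",
    "FMBDecomposition",
    "PopulationError",
    "weighted_mean",
    "weighted_cov",
    "weighted_regression",
    "delta_mean",
    "price_partition",
    "fmb_decompose",
    "expected_gain",
    "covariance_from_deviations",
]

SIMPLEX_TOL = 1e-12
IDENTITY_ATOL = 1e-10
IDENTITY_RTOL = 1e-8


class PopulationError(ValueError):
    """Invalid population input (simplex, consistency, or shape violation)."""

    def __init__(self, code: str, message: str):
        self.code = code
        super().__init__(f"[{code}] {message}")


def _as_simplex(v, name: str, tol: float = SIMPLEX_TOL) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.ndim != 1:
        raise PopulationError("shape", f"{name} must be a 1-D vector")
    if np.any(v <= 0):
        raise PopulationError("positivity", f"{name} entries must be strictly positive")
    s = v.sum()
    if abs(s - 1.0) > max(tol, 1e-9 * v.size):
        raise PopulationError("simplex", f"{name} sums to {s!r}, expected 1")
    return v


@dataclass(frozen=True)
class Population:
    """A weighted population of trait vectors, the Price equation's substrate.

    Parameters
    ----------
    weights
        Initial frequencies q, strictly positive, summing to 1.
    traits
        m×n matrix of trait values θ (a 1-D vector is treated as one trait).
    fitness
        Relative fitness w with q·w = 1, or ``None`` if ``updated_weights``
        is given (then w = q'/q).
    updated_weights
        Updated frequencies q' = q∘w; derived from fitness if omitted.
    updated_traits
        Optional θ'; when absent, Δθ ≡ 0.
    labels
        Optional row identifiers.
    unit_mean_fitness
        When True (default) enforce q·w = 1 and that q' is a simplex.  Groups
        inside a hierarchy carry raw within-group fitness whose mean is the
        group fitness w̄_g ≠ 1; they are built with ``unit_mean_fitness=False``.
    raw_performance
        Optional record of unnormalized performance values U(θ_i) when the
        fitness was produced by ``from_performance``.
    """

    weights: np.ndarray
    traits: np.ndarray
    fitness: np.ndarray
    updated_weights: np.ndarray
    updated_traits: Optional[np.ndarray] = None
    labels: Optional[Sequence] = None
    unit_mean_fitness: bool = True
    raw_performance: Optional[np.ndarray] = field(default=None, compare=False)

    def __init__(
        self,
        weights,
        traits,
        fitness=None,
        updated_weights=None,
        updated_traits=None,
        labels=None,
        unit_mean_fitness: bool = True,
        raw_performance=None,
    ):
        q = _as_simplex(weights, "weights")
        theta = np.asarray(traits, dtype=float)
        if theta.ndim == 1:
            theta = theta[:, None]
        if theta.ndim != 2 or theta.shape[0] != q.size:
            raise PopulationError(
                "shape",
                f"traits must be m×n with m={q.size} rows, got shape {theta.shape}",
            )
        if fitness is None and updated_weights is None:
            raise PopulationError("missing", "supply fitness or updated_weights")
        if fitness is not None:
            w = np.asarray(fitness, dtype=float)
            if w.shape != q.shape:
                raise PopulationError("shape", "fitness must match weights in length")
            if np.any(w <= 0):
                raise PopulationError("positivity", "fitness must be strictly positive")
            qp_derived = q * w
            if updated_weights is not None:
                qp = np.asarray(updated_weights, dtype=float)
                if not np.allclose(qp, qp_derived, rtol=0, atol=1e-12):
                    i = int(np.argmax(np.abs(qp - qp_derived)))
                    raise PopulationError(
                        "consistency",
                        f"updated_weights inconsistent with q*w at row {i}: "
                        f"{qp[i]!r} vs {qp_derived[i]!r}",
                    )
            qp = qp_derived
        else:
            qp = np.asarray(updated_weights, dtype=float)
            if qp.shape != q.shape:
                raise PopulationError("shape", "updated_weights must match weights")
            if np.any(qp <= 0):
                raise PopulationError(
                    "positivity", "updated_weights must be strictly positive"
                )
            w = qp / q
        if unit_mean_fitness:
            wbar = float(q @ w)
            if abs(wbar - 1.0) > max(SIMPLEX_TOL, 1e-9):
                raise PopulationError(
                    "mean_fitness", f"mean fitness q·w = {wbar!r}, expected 1"
                )
            _as_simplex(qp, "updated_weights")
        if updated_traits is not None:
            tp = np.asarray(updated_traits, dtype=float)
            if tp.ndim == 1:
                tp = tp[:, None]
            if tp.shape != theta.shape:
                raise PopulationError("shape", "updated_traits must match traits shape")
        else:
            tp = None
        object.__setattr__(self, "weights", q)
        object.__setattr__(self, "traits", theta)
        object.__setattr__(self, "fitness", w)
        object.__setattr__(self, "updated_weights", qp)
        object.__setattr__(self, "updated_traits", tp)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "unit_mean_fitness", unit_mean_fitness)
        object.__setattr__(
            self,
            "raw_performance",
            None if raw_performance is None else np.asarray(raw_performance, float),
        )

    @classmethod
    def from_performance(cls, weights, traits, performance, updated_traits=None,
                         labels=None) -> "Population":
        """Build a population from raw performance U(θ_i), renormalized so q·w = 1."""
        q = _as_simplex(np.asarray(weights, dtype=float), "weights")
        u = np.asarray(performance, dtype=float)
        if np.any(u <= 0):
            raise PopulationError("positivity", "performance must be strictly positive")
        w = u / (q @ u)
        return cls(q, traits, fitness=w, updated_traits=updated_traits,
                   labels=labels, raw_performance=u)

    @property
    def m(self) -> int:
        return self.weights.size

    @property
    def n(self) -> int:
        return self.traits.shape[1]

    @property
    def delta_traits(self) -> np.ndarray:
        """Δθ = θ' − θ (zero when no updated traits were supplied)."""
        if self.updated_traits is None:
            return np.zeros_like(self.traits)
        return self.updated_traits - self.traits

    @property
    def delta_weights(self) -> np.ndarray:
        return self.updated_weights - self.weights


@dataclass(frozen=True)
class RegressionFit:
    """q-weighted least-squares fit of a response on predictor columns.

    ``coefficients`` are the partial regression slopes, ``intercept`` the
    fitted constant, ``residuals`` the errors ζ (q-orthogonal to each
    centered predictor), ``singular`` flags a rank-deficient centered
    predictor covariance (minimum-norm solution used).
    """

    coefficients: np.ndarray
    intercept: float
    residuals: np.ndarray
    singular: bool = False


@dataclass(frozen=True)
class FMBDecomposition:
    """Selection/transmission partition of one update and its Mf + Cβ + γ form."""

    metric: np.ndarray            # M = Cov_q(θ, θ)
    force: np.ndarray             # f: regression of w on θ
    bias_metric: np.ndarray       # C = Cov_q(Δθ, Δθ)
    bias_slope: np.ndarray        # β: regression of w on Δθ
    intrinsic_bias: np.ndarray    # γ = E_q(Δθ)
    selection_term: np.ndarray    # Δq·θ = Cov_q(w, θ)
    transmission_term: np.ndarray  # q'·Δθ = E_q(w Δθ)
    total: np.ndarray             # Δθ̄
    singular_metric: bool = False
    singular_bias_metric: bool = False

    @property
    def bias(self) -> np.ndarray:
        """b = Cβ + γ, the transmission term in FMB form."""
        return self.bias_metric @ self.bias_slope + self.intrinsic_bias


def weighted_mean(values: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """q-weighted mean over rows."""
    return np.asarray(weights) @ np.asarray(values)


def weighted_cov(x: np.ndarray, y: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """q-weighted population covariance Cov_q(x, y) between column sets."""
    q = np.asarray(weights, dtype=float)
    x = np.atleast_2d(np.asarray(x, dtype=float).T).T
    y = np.atleast_2d(np.asarray(y, dtype=float).T).T
    xc = x - q @ x
    yc = y - q @ y
    return (xc * q[:, None]).T @ yc


def weighted_regression(response, predictors, weights) -> RegressionFit:
    """q-weighted least squares of ``response`` on ``predictors`` with intercept.

    Solves the centered normal equations Cov_q(X, X) b = Cov_q(X, y).  When the
    centered predictor covariance is singular, the minimum-norm solution is
    returned and ``singular`` is set; the fitted covariance identity
    Cov_q(y, X) = Cov_q(X, X) b still holds because the right-hand side lies in
    the column space of the covariance.
    """
    q = _as_simplex(np.asarray(weights, dtype=float), "weights")
    y = np.asarray(response, dtype=float)
    X = np.asarray(predictors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != q.size or y.shape != q.shape:
        raise PopulationError("shape", "regression inputs must share m rows")
    cxx = weighted_cov(X, X, q)
    cxy = weighted_cov(X, y, q)[:, 0]
    # rank of the centered covariance decides the solve path
    rank = np.linalg.matrix_rank(cxx, tol=1e-12 * max(1.0, np.abs(cxx).max()))
    singular = rank < X.shape[1]
    if singular:
        coef = np.linalg.pinv(cxx, rcond=1e-12) @ cxy
    else:
        coef = np.linalg.solve(cxx, cxy)
    intercept = float(q @ y - (q @ X) @ coef)
    resid = y - intercept - X @ coef
    return RegressionFit(coef, intercept, resid, singular)


def delta_mean(pop: Population) -> np.ndarray:
    """Δθ̄ = q'·θ' − q·θ (θ' = θ when no updated traits)."""
    theta_p = pop.traits if pop.updated_traits is None else pop.updated_traits
    return pop.updated_weights @ theta_p - pop.weights @ pop.traits


def price_partition(pop: Population) -> tuple[np.ndarray, np.ndarray]:
    """The two Price terms: (Δq·θ, q'·Δθ) = (Cov_q(w,θ), E_q(wΔθ)).

    Their sum equals :func:`delta_mean` exactly (an algebraic identity)."""
    selection = pop.delta_weights @ pop.traits
    transmission = pop.updated_weights @ pop.delta_traits
    return selection, transmission


def fmb_decompose(pop: Population) -> FMBDecomposition:
    """Full FMB decomposition Δθ̄ = Mf + Cβ + γ of one population update."""
    q, w = pop.weights, pop.fitness
    selection, transmission = price_partition(pop)
    fit_f = weighted_regression(w, pop.traits, q)
    metric = weighted_cov(pop.traits, pop.traits, q)
    dtheta = pop.delta_traits
    if np.allclose(dtheta, 0.0):
        n = pop.n
        bias_metric = np.zeros((n, n))
        bias_slope = np.zeros(n)
        gamma = np.zeros(n)
        singular_bias = False
    else:
        fit_b = weighted_regression(w, dtheta, q)
        bias_metric = weighted_cov(dtheta, dtheta, q)
        bias_slope = fit_b.coefficients
        gamma = weighted_mean(dtheta, q)
        singular_bias = fit_b.singular
    return FMBDecomposition(
        metric=metric,
        force=fit_f.coefficients,
        bias_metric=bias_metric,
        bias_slope=bias_slope,
        intrinsic_bias=gamma,
        selection_term=selection,
        transmission_term=transmission,
        total=delta_mean(pop),
        singular_metric=fit_f.singular,
        singular_bias_metric=singular_bias,
    )


def expected_gain(M: np.ndarray, f: np.ndarray) -> float:
    """Expected partial fitness gain fᵀMf ≥ 0 from a force f under metric M."""
    M = np.asarray(M, dtype=float)
    f = np.asarray(f, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise PopulationError("shape", "metric must be square")
    if not np.allclose(M, M.T, atol=1e-12 * max(1.0, np.abs(M).max())):
        raise PopulationError("symmetry", "metric must be symmetric")
    return float(f @ M @ f)


def covariance_from_deviations(pop: Population) -> np.ndarray:
    """Trait covariance via JᵀS⁻¹J with J the centered traits and S = diag(1/q).

    The frequency-space Fisher (Shahshahani) metric S pulls back to the trait
    covariance: JᵀS⁻¹J = Σ_i q_i (θ_i − θ̄)(θ_i − θ̄)ᵀ = Cov_q(θ, θ).
    """
    q = pop.weights
    J = pop.traits - q @ pop.traits
    return J.T @ (q[:, None] * J)
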