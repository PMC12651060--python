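"""Bayesian updating as selection, and variational Bayes as constrained selection.

A discrete Bayes update is a Price-equation frequency change: the normalized
likelihood L = L̃/(q·L̃) plays the role of relative fitness (q·L = 1) and the
posterior is q' = q∘L.  The partial gain in mean likelihood from frequency
change, Δq·L, equals the squared Fisher–Rao step of the update.

For a candidate posterior q̂ the evidence lower bound is

    ELBO(q̂) = E_q̂ log L̃ − D(q̂‖q) = log p(D) − D(q̂‖q'),

so the ELBO is maximized, and the variational free energy D(q̂‖q')
minimized, exactly at the true posterior.  The Price equation partitions
the ELBO change from prior to candidate into a direct likelihood-force
term Δq·log L̃ and an opposing context (prior-inertia) term −D(q̂‖q).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .infogeom import FrequencyChange, fisher_rao_sq, kl_divergence
from .price import PopulationError, _as_simplex

__all__ = [
    "DiscreteBayes",
    "VariationalState",
    "bayes_update",
    "likelihood_gain",
    "elbo",
    "elbo_price_decomposition",
    "free_energy_change",
    "dalembert_balance",
    "variational_project",
]


@dataclass(frozen=True)
class DiscreteBayes:
    """A discrete Bayes problem: prior, likelihood, posterior, log evidence."""

    prior: np.ndarray
    unnorm_likelihood: np.ndarray
    norm_likelihood: np.ndarray
    posterior: np.ndarray
    log_evidence: float

    @property
    def change(self) -> FrequencyChange:
        """The prior → posterior frequency change."""
        return FrequencyChange(self.prior, self.posterior)


@dataclass(frozen=True)
class VariationalState:
    """A candidate posterior with its ELBO and divergence from the truth."""

    candidate: np.ndarray
    elbo: float
    kl_to_posterior: float
    free_energy: float  # = D(q̂‖q') = log_evidence − elbo


def bayes_update(prior, unnorm_likelihood) -> DiscreteBayes:
    """One discrete Bayes update q' = q∘L with L = L̃/(q·L̃)."""
    q = _as_simplex(prior, "prior")
    lt = np.asarray(unnorm_likelihood, dtype=float)
    if lt.shape != q.shape:
        raise PopulationError("shape", "likelihood must match prior in length")
    if np.any(lt <= 0):
        raise PopulationError("positivity", "likelihood must be strictly positive")
    evidence = float(q @ lt)
    L = lt / evidence
    posterior = q * L
    return DiscreteBayes(
        prior=q,
        unnorm_likelihood=lt,
        norm_likelihood=L,
        posterior=posterior,
        log_evidence=float(np.log(evidence)),
    )


def likelihood_gain(db: DiscreteBayes) -> float:
    """Direct gain in mean likelihood, Δq·L; equals the squared Fisher–Rao step."""
    return float((db.posterior - db.prior) @ db.norm_likelihood)


def _candidate(db: DiscreteBayes, candidate) -> np.ndarray:
    qh = _as_simplex(candidate, "candidate")
    if qh.shape != db.prior.shape:
        raise PopulationError("shape", "candidate must match prior in length")
    return qh


def elbo(db: DiscreteBayes, candidate) -> VariationalState:
    """ELBO(q̂) = E_q̂ log L̃ − D(q̂‖q), with the q̂-independent identity

    ELBO(q̂) + D(q̂‖q') = log p(D)."""
    qh = _candidate(db, candidate)
    value = float(qh @ np.log(db.unnorm_likelihood)) - kl_divergence(qh, db.prior)
    kl_post = kl_divergence(qh, db.posterior)
    return VariationalState(
        candidate=qh, elbo=value, kl_to_posterior=kl_post, free_energy=kl_post
    )


def elbo_price_decomposition(db: DiscreteBayes, candidate) -> tuple[float, float]:
    """Price split of ELBO(q̂) − ELBO(q) into (direct, context) terms.

    direct = Δq·log L̃ is the work of the data's likelihood force over the
    frequency move Δq = q̂ − q; context = −D(q̂‖q) is the inertial cost of
    leaving the prior.  Their sum telescopes to the ELBO difference since
    ELBO(q) = E_q log L̃.
    """
    qh = _candidate(db, candidate)
    direct = float((qh - db.prior) @ np.log(db.unnorm_likelihood))
    context = -kl_divergence(qh, db.prior)
    return direct, context


def free_energy_change(db: DiscreteBayes, candidate) -> float:
    """Variational free-energy change ΔF = D(q̂‖q) − Δq·log L̃ = −ΔELBO.

    Negative whenever the candidate improves on the prior; minimal (most
    negative) at the true posterior."""
    direct, context = elbo_price_decomposition(db, candidate)
    return -(direct + context)


def dalembert_balance(
    db: DiscreteBayes, candidate, displacements: Sequence
) -> float:
    """Static balance of likelihood, prior-inertia and residual forces.

    For any zero-sum virtual displacement δ, the bracket
    log L̃ − log(q̂/q) − log(q'/q̂) is a constant vector (the log normalizer),
    so its virtual work vanishes.  Returns the maximum absolute work over
    the supplied displacements (≤ 1e−10 up to roundoff).
    """
    qh = _candidate(db, candidate)
    bracket = (
        np.log(db.unnorm_likelihood)
        - np.log(qh / db.prior)
        - np.log(db.posterior / qh)
    )
    worst = 0.0
    for delta in displacements:
        d = np.asarray(delta, dtype=float)
        if d.shape != qh.shape:
            raise PopulationError("shape", "displacement must match state length")
        if abs(d.sum()) > 1e-10 * max(1.0, np.abs(d).max()):
            raise PopulationError("zero_sum", "displacement must sum to zero")
        worst = max(worst, float(abs(bracket @ d)))
    return worst


def _marginals(joint: np.ndarray) -> list[np.ndarray]:
    dims = joint.ndim
    return [
        joint.sum(axis=tuple(a for a in range(dims) if a != k)) for k in range(dims)
    ]


def variational_project(
    db: DiscreteBayes,
    shape: Sequence[int],
    steps: int = 200,
    tol: float = 1e-10,
) -> tuple[VariationalState, list[float]]:
    """Mean-field projection of the posterior onto a product of marginals.

    The state space is the Cartesian product with the given ``shape``
    (C-order flattening matches the problem vectors).  Coordinate ascent on
    the ELBO over independent marginals: each factor update sets
    log m_k ∝ E_{others}[log(q∘L̃)], the exact coordinatewise maximizer, so
    the ELBO trace is monotone nondecreasing.  Returns the final
    variational state and the ELBO trace (one entry per sweep, including
    the start).
    """
    shape = tuple(int(s) for s in shape)
    if int(np.prod(shape)) != db.prior.size:
        raise PopulationError(
            "family", f"state space {shape} does not factor the {db.prior.size}-vector"
        )
    log_joint = (np.log(db.prior) + np.log(db.unnorm_likelihood)).reshape(shape)
    k = len(shape)
    # start from the true posterior's marginals
    post = db.posterior.reshape(shape)
    marg = [m / m.sum() for m in _marginals(post)]

    def product(ms: list[np.ndarray]) -> np.ndarray:
        out = np.ones(shape)
        for axis, m in enumerate(ms):
            sl = [None] * k
            sl[axis] = slice(None)
            out = out * m[tuple(sl)]
        return out

    def current_elbo(ms) -> float:
        return elbo(db, product(ms).reshape(-1)).elbo

    trace = [current_elbo(marg)]
    for _ in range(steps):
        for axis in range(k):
            weight = product(
                [marg[a] if a != axis else np.ones(shape[axis]) for a in range(k)]
            )
            # E over the other factors of the joint log-weight
            axes = tuple(a for a in range(k) if a != axis)
            expect = (weight * log_joint).sum(axis=axes)
            expect -= expect.max()
            new = np.exp(expect)
            marg[axis] = new / new.sum()
        trace.append(current_elbo(marg))
        if trace[-1] - trace[-2] < tol:
            break
    qh = product(marg).reshape(-1)
    qh = qh / qh.sum()
    return elbo(db, qh), trace
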