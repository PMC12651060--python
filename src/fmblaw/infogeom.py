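"""Information geometry of a discrete frequency update q → q'.

The squared Fisher–Rao step F = Σ(Δq_i)²/q_i equals the fitness variance
Var_q(w) and the Shahshahani quadratic form aᵀS⁻¹a in the average excess
a = Δq/q.  The Jeffreys divergence equals the Price selection term for
the Malthusian trait m = log(q'/q).  In the small-step limit F → 4‖Δr‖²
in square-root coordinates r = √q, and F → 2·D(q'‖q).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .price import PopulationError, _as_simplex

__all__ = [
    "FrequencyChange",
    "fisher_rao_sq",
    "kl_divergence",
    "jeffreys_divergence",
    "sqrt_coordinates",
    "shahshahani_form",
    "limit_ratio_suite",
    "conserved_likelihood_check",
]


@dataclass(frozen=True)
class FrequencyChange:
    """A pair of strictly positive simplex vectors q → q' and derived fields.

    ``malthusian`` is m = log(q'/q) (so q·exp(m) = 1) and ``average_excess``
    is a = Δq/q = w − 1 (so q·a = 0).
    """

    before: np.ndarray
    after: np.ndarray
    malthusian: np.ndarray
    average_excess: np.ndarray

    def __init__(self, before, after):
        q = _as_simplex(before, "before")
        qp = _as_simplex(after, "after")
        if q.shape != qp.shape:
            raise PopulationError("shape", "before and after must share length")
        object.__setattr__(self, "before", q)
        object.__setattr__(self, "after", qp)
        object.__setattr__(self, "malthusian", np.log(qp / q))
        object.__setattr__(self, "average_excess", qp / q - 1.0)

    @property
    def delta(self) -> np.ndarray:
        return self.after - self.before

    @property
    def fitness(self) -> np.ndarray:
        """Relative fitness w = q'/q, mean 1 under q."""
        return self.after / self.before


def fisher_rao_sq(change: FrequencyChange) -> float:
    """Discrete squared Fisher–Rao step length F = Σ(Δq_i)²/q_i = Var_q(w)."""
    return float(np.sum(change.delta**2 / change.before))


def kl_divergence(p, q) -> float:
    """Kullback–Leibler divergence D(p‖q) = Σ p_i log(p_i/q_i), natural log."""
    p = _as_simplex(p, "p")
    q = _as_simplex(q, "q")
    if p.shape != q.shape:
        raise PopulationError("shape", "p and q must share length")
    return float(np.sum(p * np.log(p / q)))


def jeffreys_divergence(change: FrequencyChange) -> float:
    """Symmetrized KL divergence; equals the Price term Δq·m for m = log w."""
    return kl_divergence(change.after, change.before) + kl_divergence(
        change.before, change.after
    )


def sqrt_coordinates(q) -> np.ndarray:
    """Square-root coordinates r = √q, a unit vector on the positive orthant sphere."""
    return np.sqrt(_as_simplex(q, "q"))


def shahshahani_form(change: FrequencyChange) -> float:
    """aᵀS⁻¹a with S = diag(1/q): the Fisher metric quadratic form in the

    average excess.  Equals the squared Fisher–Rao step F identically."""
    a = change.average_excess
    return float(np.sum(change.before * a**2))


def _dalembert_residual(q: np.ndarray, dq: np.ndarray) -> float:
    """Two-sub-step discrete residual of the d'Alembert balance.

    Splits q → q + Δq into halves through the midpoint, with per-sub-step
    Malthusian parameters m1, m2.  The direct virtual work m1·Δq_half is
    balanced by the inertial work q·(m2 − m1); their sum vanishes at third
    order in the step size.
    """
    half = 0.5 * dq
    m1 = np.log1p(half / q)
    m2 = np.log1p(half / (q + half))
    return float(abs(m1 @ half + q @ (m2 - m1)))


def limit_ratio_suite(q, direction, scales) -> pd.DataFrame:
    """Small-step limit ratios for q' = q + ε·direction over a ladder of ε.

    Reports, per scale, F/‖Δr‖² (→ 4), F/D(q'‖q) (→ 2) and the d'Alembert
    two-sub-step residual (→ 0 at order ε³).  A final ``extrapolated`` row
    carries the Richardson limits from the last two scales, covering the
    otherwise-undefined ε = 0 ratios.
    """
    q = _as_simplex(q, "q")
    d = np.asarray(direction, dtype=float)
    if d.shape != q.shape:
        raise PopulationError("shape", "direction must match q in length")
    if abs(d.sum()) > 1e-12 * max(1.0, np.abs(d).max()):
        raise PopulationError("zero_sum", "direction must sum to zero")
    scales = np.asarray(scales, dtype=float)
    if np.any(scales <= 0) or np.any(np.diff(scales) >= 0):
        raise PopulationError("scales", "scales must be positive and decreasing")
    rows = []
    r = np.sqrt(q)
    for eps in scales:
        dq = eps * d
        qp = q + dq
        if np.any(qp <= 0):
            raise PopulationError(
                "interior", f"step ε={eps} leaves the simplex interior"
            )
        # cancellation-free forms: Δq is exact, Δr via the conjugate identity,
        # and the KL sum via log1p of the exact relative change
        F = float(np.sum(dq**2 / q))
        dr = dq / (np.sqrt(qp) + r)
        dr2 = float(np.sum(dr**2))
        D = float(np.sum(qp * np.log1p(dq / q)))
        rows.append(
            {
                "scale": eps,
                "ratio_sqrt": F / dr2,
                "ratio_kl": F / D,
                "dalembert_residual": _dalembert_residual(q, dq),
            }
        )
    out = pd.DataFrame(rows)
    if len(out) >= 2:
        # error is O(ε): linear Richardson step from the two smallest scales
        a, b = out.iloc[-2], out.iloc[-1]
        t = a["scale"] / b["scale"]
        extrap = {
            "scale": 0.0,
            "ratio_sqrt": (t * b["ratio_sqrt"] - a["ratio_sqrt"]) / (t - 1.0),
            "ratio_kl": (t * b["ratio_kl"] - a["ratio_kl"]) / (t - 1.0),
            "dalembert_residual": 0.0,
        }
        out = pd.concat([out, pd.DataFrame([extrap])], ignore_index=True)
    return out


def conserved_likelihood_check(q, unnorm_likelihood) -> tuple[float, float, float]:
    """Conservation of mean normalized likelihood across one Bayes update.

    With L normalized so q·L = 1 and posterior q' = q∘L, the re-normalized
    posterior likelihood L' satisfies ΔL̄ = Δq·L + q'·(L'−L) = 0: the direct
    gain from frequency change is exactly cancelled by the inertial decay
    from re-normalization.  Returns (direct, inertial, total).
    """
    q = _as_simplex(q, "q")
    lt = np.asarray(unnorm_likelihood, dtype=float)
    if lt.shape != q.shape:
        raise PopulationError("shape", "likelihood must match q in length")
    if np.any(lt <= 0):
        raise PopulationError("positivity", "likelihood must be strictly positive")
    L = lt / (q @ lt)
    qp = q * L
    Lp = lt / (qp @ lt)
    direct = float((qp - q) @ L)
    inertial = float(qp @ (Lp - L))
    return direct, inertial, direct + inertial
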