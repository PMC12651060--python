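"""Two-level (multilevel-selection) Price recursion and hierarchical FMB law.

For a population split into groups g with group frequencies q_g, member
frequencies q_{j|g} and member fitness w_{j|g} (global mean fitness 1),

    Δθ̄ = Cov_g(w̄_g, θ̄_g) + E_g(w̄_g Δθ̄_g),

and each group term expands by the one-level Price equation, so the
between + within partition reconstructs the flat change on the flattened
population (absolute weight q_g·q_{j|g}) exactly.  The FMB re-expression
splits metric and force by level: M = M_B + E(M_g) (law of total
covariance) and the composite force M⁻¹(M_B f_B + E(M_g f_g)) equals the
flat pooled regression force when M is nonsingular.

The module also carries two algorithmic demonstrations of hierarchy:
a Baldwin-effect simulation (nonheritable within-lifetime learning
smooths the fitness surface seen by selection) and a generic
two-timescale lookahead wrapper for single-vector optimizers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .price import (
    Population,
    PopulationError,
    _as_simplex,
    delta_mean,
    weighted_cov,
    weighted_regression,
)

__all__ = [
    "GroupedPopulation",
    "HierarchicalFMB",
    "hierarchical_partition",
    "hierarchical_fmb",
    "baldwin_hit_probability",
    "baldwin_simulation",
    "lookahead_wrap",
]


@dataclass(frozen=True)
class GroupedPopulation:
    """Two-level nesting of populations for the recursive Price equation.

    Member populations carry raw within-group fitness (group mean w̄_g, not
    1); the globally q_g-weighted mean fitness must be 1.
    """

    group_weights: np.ndarray
    members: tuple[Population, ...]

    def __init__(self, group_weights, members: Sequence[Population]):
        qg = _as_simplex(group_weights, "group_weights")
        members = tuple(members)
        if len(members) != qg.size:
            raise PopulationError("shape", "one member population per group weight")
        n = members[0].n
        if any(p.n != n for p in members):
            raise PopulationError("shape", "all groups must share the trait dimension")
        wbar_global = float(qg @ np.array([p.weights @ p.fitness for p in members]))
        if abs(wbar_global - 1.0) > 1e-9:
            raise PopulationError(
                "mean_fitness", f"global mean fitness {wbar_global!r}, expected 1"
            )
        object.__setattr__(self, "group_weights", qg)
        object.__setattr__(self, "members", members)

    @property
    def n(self) -> int:
        return self.members[0].n

    @property
    def group_fitness(self) -> np.ndarray:
        """w̄_g = Σ_j q_{j|g} w_{j|g}."""
        return np.array([p.weights @ p.fitness for p in self.members])

    @property
    def group_means(self) -> np.ndarray:
        """Initial group trait means θ̄_g (one row per group)."""
        return np.vstack([p.weights @ p.traits for p in self.members])

    def flatten(self) -> Population:
        """Pool members with absolute weights q_g·q_{j|g} into one population."""
        qg = self.group_weights
        q = np.concatenate([g * p.weights for g, p in zip(qg, self.members)])
        theta = np.vstack([p.traits for p in self.members])
        w = np.concatenate([p.fitness for p in self.members])
        has_tp = any(p.updated_traits is not None for p in self.members)
        tp = (
            np.vstack([
                p.traits if p.updated_traits is None else p.updated_traits
                for p in self.members
            ])
            if has_tp
            else None
        )
        return Population(q, theta, fitness=w, updated_traits=tp)


@dataclass(frozen=True)
class HierarchicalFMB:
    """Per-level metrics, forces and biases of the two-level FMB law."""

    between_metric: np.ndarray
    between_force: np.ndarray
    between_bias: np.ndarray            # b_B = E_g(b_g)
    within_metrics: tuple[np.ndarray, ...]
    within_forces: tuple[np.ndarray, ...]
    within_bias_residuals: tuple[np.ndarray, ...]  # b̃_g = b_g − b_B
    total_metric: np.ndarray            # M_B + E_g(M_g)
    composite_force: np.ndarray         # M⁻¹(M_B f_B + E(M_g f_g))
    total: np.ndarray                   # flat Δθ̄
    singular: bool = False

    def reconstruct(self, group_weights: np.ndarray) -> np.ndarray:
        """M_B f_B + b_B + E_g(M_g f_g + b̃_g)."""
        qg = np.asarray(group_weights, float)
        within = sum(
            g * (M @ f + bt)
            for g, M, f, bt in zip(
                qg, self.within_metrics, self.within_forces,
                self.within_bias_residuals,
            )
        )
        return (
            self.between_metric @ self.between_force + self.between_bias + within
        )


def _group_terms(pop: Population) -> tuple[np.ndarray, np.ndarray]:
    """Raw within-group Price terms (Cov_j(w,θ), E_j(wΔθ)) for one group."""
    q, w = pop.weights, pop.fitness
    cov_wt = weighted_cov(w, pop.traits, q)[0]
    trans = q @ (w[:, None] * pop.delta_traits)
    return cov_wt, trans


def hierarchical_partition(gpop: GroupedPopulation) -> tuple[np.ndarray, np.ndarray]:
    """(between, within) = (Cov_g(w̄_g, θ̄_g), E_g(w̄_g Δθ̄_g)).

    Each within-group term is expanded by the one-level Price equation,
    w̄_g Δθ̄_g = Cov_j(w, θ) + E_j(wΔθ); the two parts sum to the flat
    change Δθ̄ of the flattened population (global w̄ = 1)."""
    qg = gpop.group_weights
    between = weighted_cov(gpop.group_fitness, gpop.group_means, qg)[0]
    within = np.zeros(gpop.n)
    for g, pop in zip(qg, gpop.members):
        cov_wt, trans = _group_terms(pop)
        within += g * (cov_wt + trans)
    return between, within


def hierarchical_fmb(gpop: GroupedPopulation) -> HierarchicalFMB:
    """Two-level FMB law Δθ̄ = M_B f_B + b_B + E_g(M_g f_g + b̃_g).

    The between-group bias b_B is the q_g-weighted mean of the group
    transmission terms b_g = E_j(wΔθ), so that the within residuals b̃_g
    average to zero.  Singular centered covariances at either level fall
    back to the minimum-norm (pseudoinverse) force with ``singular`` set;
    the reconstruction stays exact because each covariance vector lies in
    the column space of its metric.
    """
    qg = gpop.group_weights
    n = gpop.n
    wbar = gpop.group_fitness
    means = gpop.group_means
    M_B = weighted_cov(means, means, qg)
    fit_B = weighted_regression(wbar, means, qg)
    f_B = fit_B.coefficients
    singular = fit_B.singular
    within_M, within_f, b_gs = [], [], []
    for pop in gpop.members:
        M_g = weighted_cov(pop.traits, pop.traits, pop.weights)
        fit_g = weighted_regression(pop.fitness, pop.traits, pop.weights)
        singular = singular or fit_g.singular
        _, b_g = _group_terms(pop)
        within_M.append(M_g)
        within_f.append(fit_g.coefficients)
        b_gs.append(b_g)
    b_B = sum(g * b for g, b in zip(qg, b_gs))
    residuals = [b - b_B for b in b_gs]
    total_metric = M_B + sum(g * M for g, M in zip(qg, within_M))
    mixed = M_B @ f_B + sum(g * M @ f for g, M, f in zip(qg, within_M, within_f))
    rank = np.linalg.matrix_rank(
        total_metric, tol=1e-12 * max(1.0, np.abs(total_metric).max())
    )
    if rank < n:
        composite = np.linalg.pinv(total_metric, rcond=1e-12) @ mixed
        singular = True
    else:
        composite = np.linalg.solve(total_metric, mixed)
    return HierarchicalFMB(
        between_metric=M_B,
        between_force=f_B,
        between_bias=b_B,
        within_metrics=tuple(within_M),
        within_forces=tuple(within_f),
        within_bias_residuals=tuple(residuals),
        total_metric=total_metric,
        composite_force=composite,
        total=delta_mean(gpop.flatten()),
        singular=singular,
    )


def baldwin_hit_probability(d: int, L: int, flip_prob: float, trials: int) -> float:
    """Probability that ≥1 of ``trials`` independent all-bit-flip rounds hits

    the target from Hamming distance d: 1 − (1 − p^d(1−p)^(L−d))^G.  Strictly
    decreasing in d for flip_prob < 1/2, which is what turns a needle-in-a-
    haystack fitness function into a graded surface selection can climb."""
    log_p_match = d * np.log(flip_prob) + (L - d) * np.log1p(-flip_prob)
    # -expm1(G·log1p(-p)) stays accurate when the match probability underflows 1 − p
    return float(-np.expm1(trials * np.log1p(-np.exp(log_p_match))))


def baldwin_simulation(
    L: int,
    pop_size: int,
    flip_prob: float,
    trials_G: int,
    bonus: float,
    generations: int,
    rng: np.random.Generator,
    expectation_mode: bool = True,
) -> pd.DataFrame:
    """Baldwin-effect demonstration: selection on seeds, learning in lifetimes.

    Each individual inherits a bit string (the seed).  During its lifetime
    it runs ``trials_G`` learning trials, each an independent per-bit flip
    with probability ``flip_prob``; hitting the all-zeros target in any
    trial earns effective fitness 1 + bonus (in ``expectation_mode`` the
    analytic hit probability replaces the Bernoulli draw).  Selection
    resamples *seed* strings in proportion to effective fitness — the
    learned (mutated) strings are never transmitted.  Returns a per-
    generation trace of mean Hamming distance to target and the maximum
    effective fitness.
    """
    if L < 1:
        raise ValueError("L must be at least 1")
    if not (0 < flip_prob < 0.5):
        raise ValueError("flip_prob must lie in (0, 1/2)")
    if trials_G < 0 or bonus < 0:
        raise ValueError("trials_G and bonus must be nonnegative")
    seeds = rng.integers(0, 2, size=(pop_size, L))
    rows = []
    for gen in range(generations):
        dist = seeds.sum(axis=1)  # Hamming distance to the all-zeros target
        if trials_G == 0:
            hit = (dist == 0).astype(float)
        elif expectation_mode:
            hit = np.array(
                [baldwin_hit_probability(int(d), L, flip_prob, trials_G) for d in dist]
            )
        else:
            hit = np.zeros(pop_size)
            for i in range(pop_size):
                for _ in range(trials_G):
                    mutated = seeds[i] ^ (rng.random(L) < flip_prob)
                    if not mutated.any():
                        hit[i] = 1.0
                        break
        fitness = 1.0 + bonus * hit
        rows.append(
            {
                "generation": gen,
                "mean_distance": float(dist.mean()),
                "max_fitness": float(fitness.max()),
            }
        )
        parents = rng.choice(pop_size, size=pop_size, p=fitness / fitness.sum())
        seeds = seeds[parents]
    return pd.DataFrame(rows)


def lookahead_wrap(
    inner_step: Callable[[np.ndarray], np.ndarray],
    theta0,
    inner_steps_k: int,
    blend_alpha: float,
    outer_steps: int,
) -> np.ndarray:
    """Two-timescale wrapper: k fast inner steps, then a slow blended update.

    θ_slow ← θ_slow + α(θ_fast − θ_slow) after each inner run; the fast
    loop restarts from the new slow point.  α = 1 with k = 1 reduces to
    the bare inner optimizer.  Returns the (outer_steps+1)×n trajectory of
    slow iterates.
    """
    if not (0 < blend_alpha <= 1):
        raise ValueError("blend_alpha must lie in (0, 1]")
    if inner_steps_k < 1 or outer_steps < 1:
        raise ValueError("inner_steps_k and outer_steps must be positive")
    slow = np.asarray(theta0, dtype=float)
    traj = [slow.copy()]
    for _ in range(outer_steps):
        fast = slow.copy()
        for _ in range(inner_steps_k):
            fast = np.asarray(inner_step(fast), dtype=float)
        slow = slow + blend_alpha * (fast - slow)
        traj.append(slow.copy())
    return np.vstack(traj)
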