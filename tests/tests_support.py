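"""Shared helpers for the test suite."""

import numpy as np

from fmblaw.hierarchy import GroupedPopulation
from fmblaw.optim import PerformanceSurface
from fmblaw.price import Population


def flat_surface(n, gradient_value):
    """Surface with a constant gradient and zero curvature."""
    g = np.asarray(gradient_value, float)
    return PerformanceSurface(
        evaluate=lambda t: float(g @ t),
        gradient=lambda t: g,
        hessian=lambda t: np.zeros((n, n)),
    )


def random_grouped_population(seed, n_groups=3, members=4, n=2):
    """Seeded random two-level population with trait updates, globally normalized."""
    gen = np.random.default_rng(seed)
    qg = gen.dirichlet(np.full(n_groups, 3.0))
    raw = []
    for _ in range(n_groups):
        qj = gen.dirichlet(np.full(members, 3.0))
        theta = gen.standard_normal((members, n))
        w = gen.random(members) + 0.5
        raw.append((qj, theta, w))
    mean_w = sum(g * (qj @ w) for g, (qj, _, w) in zip(qg, raw))
    pops = [
        Population(
            qj, theta, fitness=w / mean_w,
            updated_traits=theta + 0.2 * gen.standard_normal(theta.shape),
            unit_mean_fitness=False,
        )
        for qj, theta, w in raw
    ]
    return GroupedPopulation(qg, pops)
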