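"""Delimited-text population I/O and seeded synthetic generators.

Population tables are TSV (default) or CSV with a header row: required
columns ``q`` and one of ``w``/``q_prime``; trait columns ``theta_1..n``;
optional ``theta_prime_1..n``, ``group`` and ``id``.  A ``group`` column
switches the reader to the two-level grouped format (within-group weights
renormalized, group weights proportional to summed raw ``q``).

The generators produce the random populations and performance surfaces
used throughout the identity test suites; every draw comes from a caller-
supplied seeded generator, so identical (config, seed) pairs reproduce
byte-identical outputs.
"""

from __future__ import annotations

from typing import Optional, Union

import numpy as np
import pandas as pd

from .hierarchy import GroupedPopulation
from .optim import PerformanceSurface
from .price import Population, PopulationError

__all__ = [
    "read_population",
    "write_population",
    "generate_population",
    "generate_surface",
    "SURFACE_CATALOG",
]

_FLOAT_FMT = "%.12g"  # 12 significant digits round-trips our identity checks


def _sniff_sep(path: str, dialect: Optional[str]) -> str:
    if dialect == "csv":
        return ","
    if dialect == "tsv":
        return "\t"
    if str(path).endswith(".csv"):
        return ","
    return "\t"


def read_population(path, dialect: Optional[str] = None
                    ) -> Union[Population, GroupedPopulation]:
    """Read and validate a population table; grouped if a ``group`` column exists."""
    try:
        df = pd.read_csv(path, sep=_sniff_sep(path, dialect))
    except FileNotFoundError:
        raise PopulationError("io", f"no such file: {path}")
    except Exception as exc:
        raise PopulationError("parse", f"cannot parse {path}: {exc}")
    if df.isna().any().any():
        row = int(df[df.isna().any(axis=1)].index[0])
        raise PopulationError("ragged", f"missing value at row {row}")
    cols = set(df.columns)
    if "q" not in cols:
        raise PopulationError("missing", "required column 'q' not found")
    theta_cols = sorted(
        (c for c in cols if c.startswith("theta_") and not c.startswith("theta_prime")),
        key=lambda c: int(c.split("_")[-1]),
    )
    if not theta_cols:
        raise PopulationError("missing", "no trait columns theta_1..theta_n found")
    prime_cols = sorted(
        (c for c in cols if c.startswith("theta_prime_")),
        key=lambda c: int(c.split("_")[-1]),
    )
    if prime_cols and len(prime_cols) != len(theta_cols):
        raise PopulationError("shape", "theta_prime columns must match theta columns")
    if "w" not in cols and "q_prime" not in cols:
        raise PopulationError("missing", "need a 'w' or 'q_prime' column")

    def build(sub: pd.DataFrame, unit_mean: bool) -> Population:
        q = sub["q"].to_numpy(float)
        theta = sub[theta_cols].to_numpy(float)
        tp = sub[prime_cols].to_numpy(float) if prime_cols else None
        labels = sub["id"].tolist() if "id" in cols else None
        kwargs = dict(updated_traits=tp, labels=labels, unit_mean_fitness=unit_mean)
        if "w" in cols and "q_prime" in cols:
            w = sub["w"].to_numpy(float)
            qp = sub["q_prime"].to_numpy(float)
            bad = np.abs(qp - q * w) > 1e-12
            if bad.any():
                row = int(sub.index[bad][0])
                raise PopulationError(
                    "consistency",
                    f"row {row}: q_prime={qp[bad][0]!r} disagrees with "
                    f"q*w={(q * w)[bad][0]!r}",
                )
            return Population(q, theta, fitness=w, **kwargs)
        if "w" in cols:
            return Population(q, theta, fitness=sub["w"].to_numpy(float), **kwargs)
        return Population(
            q, theta, updated_weights=sub["q_prime"].to_numpy(float), **kwargs
        )

    if "group" not in cols:
        return build(df, unit_mean=True)

    raw_q = df["q"].to_numpy(float)
    if np.any(raw_q <= 0):
        row = int(np.argmax(raw_q <= 0))
        raise PopulationError("positivity", f"nonpositive weight at row {row}")
    group_keys = list(dict.fromkeys(df["group"].tolist()))  # first-appearance order
    qg, members = [], []
    for key in group_keys:
        sub = df[df["group"] == key].copy()
        qg.append(sub["q"].sum())
        sub["q"] = sub["q"] / sub["q"].sum()
        if "q_prime" in cols:
            raise PopulationError(
                "unsupported",
                "grouped tables must supply 'w' (within-group weights are "
                "renormalized, so q_prime is ambiguous)",
            )
        members.append(build(sub, unit_mean=False))
    qg = np.asarray(qg, float)
    return GroupedPopulation(qg / qg.sum(), members)


def write_population(pop: Population, path, dialect: Optional[str] = None) -> None:
    """Write a population table; value-identical on round-trip at 12 digits."""
    data = {"q": pop.weights, "w": pop.fitness}
    for j in range(pop.n):
        data[f"theta_{j + 1}"] = pop.traits[:, j]
    if pop.updated_traits is not None:
        for j in range(pop.n):
            data[f"theta_prime_{j + 1}"] = pop.updated_traits[:, j]
    if pop.labels is not None:
        data["id"] = list(pop.labels)
    df = pd.DataFrame(data)
    df.to_csv(path, sep=_sniff_sep(path, dialect), index=False,
              float_format=_FLOAT_FMT)


def generate_population(
    m: int,
    n: int,
    rng: np.random.Generator,
    fitness_model: str = "linear",
    noise: float = 0.1,
    delta_model: Optional[str] = None,
    slope: Optional[np.ndarray] = None,
) -> Population:
    """Random valid population: Dirichlet q, Gaussian θ, model-driven fitness.

    fitness_model:
        ``linear`` — w from a linear map of θ plus Gaussian noise, shifted
        positive and renormalized to q·w = 1 (zero noise lets the FMB force
        recover the slope); ``constant`` — w ≡ 1; ``boltzmann`` — w ∝
        exp(−½‖θ‖²), a concave quadratic performance.
    delta_model:
        ``None`` — no trait update; ``gamma_only`` — a shared constant Δθ
        (pure frame-of-reference bias, C = 0); ``w_correlated`` — Δθ with a
        component aligned with fitness (nonzero Cβ).
    """
    if m < 2:
        raise PopulationError("shape", "need at least two population classes")
    q = rng.dirichlet(np.full(m, 5.0))
    theta = rng.standard_normal((m, n))
    if fitness_model == "constant":
        u = np.ones(m)
    elif fitness_model == "linear":
        b = slope if slope is not None else rng.standard_normal(n)
        raw = theta @ np.asarray(b, float) + noise * rng.standard_normal(m)
        span = float(np.ptp(raw))
        u = raw - raw.min() + 0.5 * (span if span > 0 else 1.0)
    elif fitness_model == "boltzmann":
        u = np.exp(-0.5 * np.sum(theta**2, axis=1))
    else:
        raise PopulationError("model", f"unknown fitness_model {fitness_model!r}")
    w = u / (q @ u)
    if delta_model is None:
        tp = None
    elif delta_model == "gamma_only":
        tp = theta + rng.standard_normal(n)
    elif delta_model == "w_correlated":
        dtheta = 0.1 * rng.standard_normal((m, n)) + 0.2 * np.outer(w - 1, np.ones(n))
        tp = theta + dtheta
    else:
        raise PopulationError("model", f"unknown delta_model {delta_model!r}")
    return Population(q, theta, fitness=w, updated_traits=tp)


def _quadratic_surface(n: int, rng: np.random.Generator, condition: float = 4.0,
                       shift: Optional[np.ndarray] = None) -> PerformanceSurface:
    eigs = np.geomspace(1.0, condition, n)
    Qrot = np.linalg.qr(rng.standard_normal((n, n)))[0] if n > 1 else np.eye(1)
    A = Qrot @ np.diag(eigs) @ Qrot.T
    mu = np.zeros(n) if shift is None else np.asarray(shift, float)
    return PerformanceSurface(
        evaluate=lambda t: -0.5 * float((t - mu) @ A @ (t - mu)),
        gradient=lambda t: -A @ (t - mu),
        hessian=lambda t: -A,
        name="quadratic",
    )


def _quartic1d(n: int, rng: np.random.Generator) -> PerformanceSurface:
    if n != 1:
        raise PopulationError("shape", "quartic1d is one-dimensional")
    a = 0.5 + rng.random()
    return PerformanceSurface(
        evaluate=lambda t: float(-(t[0] ** 4) - a * t[0] ** 2),
        gradient=lambda t: np.array([-4 * t[0] ** 3 - 2 * a * t[0]]),
        hessian=lambda t: np.array([[-12 * t[0] ** 2 - 2 * a]]),
        name="quartic1d",
    )


def _entropy_domain(n: int, rng: np.random.Generator) -> PerformanceSurface:
    # concave on the positive orthant, maximized at θ_i = a_i
    a = 1.0 + rng.random(n)
    return PerformanceSurface(
        evaluate=lambda t: float(np.sum(a * np.log(t) - t)),
        gradient=lambda t: a / t - 1.0,
        hessian=lambda t: np.diag(-a / t**2),
        name="entropy_domain",
    )


SURFACE_CATALOG = {
    "quadratic": _quadratic_surface,
    "shifted_quadratic": lambda n, rng: _quadratic_surface(
        n, rng, shift=rng.standard_normal(n)
    ),
    "quartic1d": _quartic1d,
    "entropy_domain": _entropy_domain,
}


def generate_surface(name: str, n: int, rng: np.random.Generator,
                     self_check: bool = True) -> PerformanceSurface:
    """Build a catalog surface with closed-form gradient and Hessian.

    Runs the finite-difference gradient self-check at 5 random probes
    (positive-orthant probes for the entropy surface)."""
    if name not in SURFACE_CATALOG:
        raise PopulationError(
            "model", f"unknown surface {name!r}; catalog: {sorted(SURFACE_CATALOG)}"
        )
    surf = SURFACE_CATALOG[name](n, rng)
    if self_check:
        for _ in range(5):
            probe = (
                0.5 + rng.random(n) if name == "entropy_domain"
                else rng.standard_normal(n)
            )
            surf.check_gradient(probe)
    return surf
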