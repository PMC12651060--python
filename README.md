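# fmblaw

Exact Price-equation decomposition of selection and learning updates into
**force, metric, bias and noise** — with the information-geometric
quantities, Bayesian/variational updates, an audited optimizer zoo,
population methods (evolution strategy, Gaussian process, Kalman filter)
and the two-level multilevel-selection recursion that all follow from the
same identity.

## The core identity

For a population of `m` parameter (trait) vectors `θᵢ` with frequencies
`q` (Σq = 1), relative fitness `w = q′/q` (mean 1), and optional trait
updates `θ′`, the change in the weighted mean trait is exactly

```
Δθ̄ = q′·θ′ − q·θ = Δq·θ + q′·Δθ = Cov_q(w, θ) + E_q(w Δθ)
```

— a *selection* term from frequency change and a *transmission* term from
within-type change.  Writing the q-weighted regression of fitness on
traits (`f`) and on trait changes (`β`) turns this into the
force–metric–bias (FMB) form

```
Δθ̄ = M f + (C β + γ) + ξ
```

with `M = Cov_q(θ, θ)` the trait covariance acting as a metric,
`C = Cov_q(Δθ, Δθ)`, `γ = E_q(Δθ)`, and `ξ` the exploration noise.  The
same structure describes Newton's method (`M = (−H)⁻¹`), the natural
gradient (`M = G⁻¹`), mirror descent (`M = Hφ⁻¹`), Adam
(`M = diag(η/(vₜ+c))` plus a momentum bias), Langevin search
(`ξ ~ N(0, 2ηM)`), Bayesian updating (`w = L`, the normalized
likelihood), the Gaussian-process posterior-mean update
(`M = (K⁻¹+σ⁻²I)⁻¹`, `f = σ⁻²(y−μ₀)`), and the Kalman filter
(`M = P⁻`, `f = HᵀS⁻¹ν`).  Every algorithm in the package returns its
step together with this decomposition, and the decomposition is audited
to reproduce the step exactly.

Derived quantities come along for free: the squared Fisher–Rao step
`F = Σ(Δq)²/q = Var_q(w)`, the Jeffreys divergence as the Price term of
the Malthusian parameter `m = log w`, the ELBO's split into a direct
likelihood force and a prior-inertia cost, and the d'Alembert-style
balance of those forces at stationarity.

## Worked example

```python
import numpy as np
from fmblaw.price import Population, fmb_decompose

pop = Population(
    weights=[0.5, 0.5],
    traits=[[0.0], [1.0]],
    updated_weights=[0.25, 0.75],     # fitness w = (0.5, 1.5) derived
    updated_traits=[[0.2], [1.0]],
)
dec = fmb_decompose(pop)
print("selection   ", dec.selection_term)     # [0.25]
print("transmission", dec.transmission_term)  # [0.05]
print("total       ", dec.total)              # [0.3]
print("M, f        ", dec.metric[0, 0], dec.force[0])  # 0.25 1.0
print("Mf + b      ", dec.metric @ dec.force + dec.bias)  # [0.3]
```

Output:

```
selection    [0.25]
transmission [0.05]
total        [0.3]
M, f         0.25 1.0
Mf + b       [0.3]
```

The mean trait rose by 0.3: 0.25 of it because the fitter type doubled
its frequency share (`Mf` with trait variance 0.25 and selection
gradient 1), and 0.05 because the first type's own trait drifted up
(transmission bias `b`).

The same decomposition is available from the shell:

```
fmblaw decompose population.tsv --format json
fmblaw optimize --algo adam --surface quadratic --steps 20 --seed 1
fmblaw bayes --prior 0.5,0.5 --likelihood 2,1
```

## Layout

- `fmblaw.price` — populations, weighted regression, the Price partition
  and FMB decomposition.
- `fmblaw.infogeom` — Fisher–Rao step, KL/Jeffreys divergences,
  square-root coordinates, small-step limit ratios, conservation checks.
- `fmblaw.bayes` — discrete Bayes as selection, ELBO identities,
  mean-field variational projection.
- `fmblaw.optim` — gradient/Newton/quasi-Newton/natural-gradient/mirror/
  regularized/momentum/Adam/Langevin/minibatch steps, each with its FMB
  audit.
- `fmblaw.methods` — evolution strategy, Gaussian-process mean update,
  Kalman filter, all in Mf form with textbook cross-checks.
- `fmblaw.hierarchy` — two-level Price recursion, hierarchical FMB law,
  Baldwin-effect demo, lookahead wrapper.
- `fmblaw.io` / `fmblaw.cli` — TSV/CSV population tables, seeded
  synthetic generators, the `fmblaw` command.

See `docs/methods.md` for the modelling choices, conventions and
limitations.
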