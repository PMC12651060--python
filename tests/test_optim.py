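"""Optimizer steps, their FMB audits, and the stochastic noise contracts."""

import numpy as np
import pytest

from fmblaw.io import generate_surface
from fmblaw.optim import (
    MetricNotPD,
    OptimizerState,
    PerformanceSurface,
    adam_paper_step,
    bfgs_metric_update,
    boltzmann_fisher,
    entropy_potential,
    gd_step,
    mirror_step_exact,
    mirror_step_first_order,
    natural_gradient_step,
    newton_step,
    polyak_step,
    quadratic_model_gain,
    quadratic_potential,
    regularized_gd_step,
    sgd_split,
    sgld_step,
)


def quadratic_surface(A, a=None, orientation="maximize"):
    """U(θ) = −½θᵀAθ + aᵀθ (or its negation for minimize surfaces)."""
    A = np.asarray(A, float)
    a = np.zeros(A.shape[0]) if a is None else np.asarray(a, float)
    return PerformanceSurface(
        evaluate=lambda t: float(-0.5 * t @ A @ t + a @ t),
        gradient=lambda t: -A @ t + a,
        hessian=lambda t: -A,
        orientation=orientation,
    )


def random_concave_quadratic(seed, n=3):
    gen = np.random.default_rng(seed)
    B = gen.standard_normal((n, n))
    A = B @ B.T + n * np.eye(n)
    return quadratic_surface(A, gen.standard_normal(n)), A


class TestGDStep:
    def test_zero_gradient_zero_step(self):
        surf = quadratic_surface(np.eye(2))
        assert np.allclose(gd_step(surf, np.zeros(2), 0.1).step, 0.0)

    def test_negative_quadratic_example(self):
        surf = quadratic_surface(np.eye(2))  # U = −½‖θ‖²
        step = gd_step(surf, np.array([1.0, 0.0]), 0.1)
        assert np.allclose(step.step, [-0.1, 0.0])
        assert step.audit_residual() == 0.0

    def test_minimize_orientation_flips_sign(self):
        # minimizing cost ½‖θ‖² descends toward the origin too
        cost = PerformanceSurface(
            evaluate=lambda t: 0.5 * float(t @ t),
            gradient=lambda t: t,
            hessian=lambda t: np.eye(t.size),
            orientation="minimize",
        )
        assert np.allclose(gd_step(cost, np.array([1.0, 0.0]), 0.1).step, [-0.1, 0.0])


class TestNewton:
    def test_one_step_exact_on_concave_quadratic(self):
        surf = quadratic_surface(np.eye(2), a=np.array([3.0, -1.0]))
        step = newton_step(surf, np.zeros(2))
        assert np.allclose(step.step, [3.0, -1.0])
        # the landing point is the maximizer: gradient vanishes there
        assert np.allclose(surf.gradient(step.step), 0.0, atol=1e-12)

    def test_zero_step_at_maximizer(self):
        surf, A = random_concave_quadratic(0)
        theta_star = np.linalg.solve(A, surf.gradient(np.zeros(3)))  # ∇U(θ*) = 0
        assert np.allclose(newton_step(surf, theta_star).step, 0.0, atol=1e-10)

    def test_convex_region_raises_metric_not_pd(self):
        convex = quadratic_surface(-np.eye(2))  # U = +½‖θ‖², convex
        with pytest.raises(MetricNotPD):
            newton_step(convex, np.ones(2))
        # damping restores a usable metric
        step = newton_step(convex, np.ones(2), damping=3.0)
        assert np.isfinite(step.step).all()


class TestQuadraticModelGain:
    def test_newton_step_gain_is_exact_on_quadratic(self):
        surf, _ = random_concave_quadratic(1)
        theta = np.array([0.5, -1.0, 2.0])
        delta = newton_step(surf, theta).step
        predicted = quadratic_model_gain(surf, theta, delta)
        actual = surf.evaluate(theta + delta) - surf.evaluate(theta)
        assert predicted == pytest.approx(actual, abs=1e-10)
        assert quadratic_model_gain(surf, theta, np.zeros(3)) == 0.0

    def test_newton_direction_beats_equal_length_alternatives(self):
        surf, A = random_concave_quadratic(2)
        theta = np.array([1.0, 0.3, -0.7])
        newton = newton_step(surf, theta).step
        length = newton @ A @ newton  # metric length Δθᵀ(−H)Δθ
        best = quadratic_model_gain(surf, theta, newton)
        gen = np.random.default_rng(7)
        for _ in range(200):
            d = gen.standard_normal(3)
            d *= np.sqrt(length / (d @ A @ d))  # rescale to equal metric length
            assert quadratic_model_gain(surf, theta, d) <= best + 1e-12


class TestBFGS:
    def test_estimate_converges_on_quadratic_with_line_search(self):
        surf, A = random_concave_quadratic(3)
        state = OptimizerState(position=np.array([2.0, -1.0, 0.5]))
        for _ in range(3):
            g = surf.signed_gradient(state.position)
            d = state.inverse_metric_estimate @ g
            # exact line search along d on the quadratic: t* = gᵀd / dᵀAd
            t = float(g @ d) / float(d @ A @ d)
            s = t * d
            new_pos = state.position + s
            y = surf.signed_gradient(new_pos) - g
            state = bfgs_metric_update(state, s, y)
            state = OptimizerState(
                position=new_pos,
                inverse_metric_estimate=state.inverse_metric_estimate,
            )
        assert np.allclose(state.inverse_metric_estimate, np.linalg.inv(A), atol=1e-6)

    def test_secant_equation_holds_after_update(self):
        surf, A = random_concave_quadratic(4)
        state = OptimizerState(position=np.zeros(3))
        s = np.array([0.2, -0.1, 0.4])
        y = -(surf.signed_gradient(s) - surf.signed_gradient(np.zeros(3)))  # = A s
        new = bfgs_metric_update(state, s, -y)  # pass Δgrad, sign handled inside
        assert np.allclose(new.inverse_metric_estimate @ y, s, atol=1e-10)
        B = new.inverse_metric_estimate
        assert np.allclose(B, B.T)
        assert np.all(np.linalg.eigvalsh(B) > 0)

    def test_flat_direction_skips_update_with_flag(self):
        state = OptimizerState(position=np.zeros(2))
        new = bfgs_metric_update(state, np.array([1.0, 0.0]), np.zeros(2))
        assert new.skipped_update
        assert np.allclose(new.inverse_metric_estimate, state.inverse_metric_estimate)

    def test_satisfied_secant_leaves_estimate_unchanged(self):
        state = OptimizerState(position=np.zeros(2))
        s = np.array([0.5, -0.2])
        # choose Δgrad so that B·y = s already (B = I): y = s
        new = bfgs_metric_update(state, s, -s)
        assert np.allclose(new.inverse_metric_estimate, np.eye(2), atol=1e-12)


class TestNaturalGradient:
    def test_identity_fisher_reduces_to_gd(self):
        surf, _ = random_concave_quadratic(5)
        theta = np.ones(3)
        ng = natural_gradient_step(surf, theta, np.eye(3))
        assert np.allclose(ng.step, gd_step(surf, theta, 1.0).step)

    def test_diagonal_fisher_scales_inversely(self):
        surf = PerformanceSurface(
            evaluate=lambda t: float(t.sum()),
            gradient=lambda t: np.ones(t.size),
            hessian=lambda t: np.zeros((t.size, t.size)),
        )
        step = natural_gradient_step(surf, np.zeros(2), np.diag([2.0, 0.5]))
        assert np.allclose(step.step, [0.5, 2.0])

    def test_boltzmann_fisher_makes_natgrad_newton_on_quadratic(self):
        surf, A = random_concave_quadratic(6)
        gen = np.random.default_rng(11)
        G = boltzmann_fisher(surf, gen.standard_normal((100, 3)))
        assert np.allclose(G, A, atol=1e-10)  # constant Hessian: exact
        theta = np.array([0.4, -0.2, 1.0])
        assert np.allclose(
            natural_gradient_step(surf, theta, G).step,
            newton_step(surf, theta).step,
            atol=1e-6,
        )

    def test_non_pd_fisher_rejected(self):
        surf, _ = random_concave_quadratic(7)
        with pytest.raises(MetricNotPD):
            natural_gradient_step(surf, np.zeros(3), -np.eye(3))


class TestBoltzmannFisher:
    def test_quartic_grid_refinement_agrees(self):
        gen = np.random.default_rng(8)
        surf = generate_surface("quartic1d", 1, gen)
        coarse = boltzmann_fisher(surf, np.linspace(-3, 3, 401)[:, None])
        fine = boltzmann_fisher(surf, np.linspace(-3, 3, 801)[:, None])
        assert abs(coarse[0, 0] - fine[0, 0]) < 1e-4

    def test_high_inverse_temperature_approaches_curvature_at_argmax(self):
        gen = np.random.default_rng(9)
        surf = generate_surface("quartic1d", 1, gen)  # argmax at 0
        grid = np.linspace(-1, 1, 2001)[:, None]
        G = boltzmann_fisher(surf, grid, inv_temp=200.0)
        assert G[0, 0] == pytest.approx(-surf.hessian(np.zeros(1))[0, 0], rel=0.1)


class TestMirror:
    def test_quadratic_potential_equals_gd(self):
        surf, _ = random_concave_quadratic(10)
        theta = np.array([0.3, 0.1, -0.4])
        mirror = mirror_step_first_order(surf, theta, quadratic_potential, 0.2)
        assert np.allclose(mirror.step, gd_step(surf, theta, 0.2).step)
        exact = mirror_step_exact(surf, theta, quadratic_potential, 0.2)
        assert np.allclose(exact - theta, mirror.step, atol=1e-14)

    def test_entropy_potential_examples(self):
        surf = PerformanceSurface(
            evaluate=lambda t: float(0.1 * t[0] - 0.1 * t[1]),
            gradient=lambda t: np.array([0.1, -0.1]),
            hessian=lambda t: np.zeros((2, 2)),
        )
        theta = np.array([1.0, 2.0])
        first = mirror_step_first_order(surf, theta, entropy_potential, 1.0)
        assert np.allclose(first.step, [0.1, -0.2])
        exact = mirror_step_exact(surf, theta, entropy_potential, 1.0)
        assert np.allclose(exact, theta * np.exp([0.1, -0.1]))
        assert np.allclose(exact, [1.1052, 1.8097], atol=1e-4)

    def test_discrepancy_is_second_order_in_step_size(self):
        gen = np.random.default_rng(13)
        surf = generate_surface("entropy_domain", 3, gen)
        theta = 0.5 + gen.random(3)
        gaps = []
        for eta in (0.2, 0.1, 0.05):
            first = theta + mirror_step_first_order(
                surf, theta, entropy_potential, eta
            ).step
            exact = mirror_step_exact(surf, theta, entropy_potential, eta)
            gaps.append(np.linalg.norm(exact - first))
        assert gaps[0] / gaps[1] == pytest.approx(4.0, rel=0.25)
        assert gaps[1] / gaps[2] == pytest.approx(4.0, rel=0.25)


class TestRegularizedGD:
    def test_pure_shrinkage_without_gradient(self):
        flat = PerformanceSurface(
            evaluate=lambda t: 0.0,
            gradient=lambda t: np.zeros(t.size),
            hessian=lambda t: np.zeros((t.size, t.size)),
        )
        theta = np.array([2.0, -1.0])
        step = regularized_gd_step(flat, theta, eta=0.1, lam=1.0)
        assert np.allclose(step.step, -0.1 * theta)

    def test_iterates_converge_to_force_balance(self):
        surf = quadratic_surface(np.eye(1), a=np.array([2.0]))  # U = −½(θ−2)² + const
        theta = np.array([0.0])
        for _ in range(400):
            theta = theta + regularized_gd_step(surf, theta, 0.1, 1.0).step
        # fixed point of ∇U = λθ: 2 − θ = θ  ⇒  θ = 1
        assert theta[0] == pytest.approx(1.0, abs=1e-8)


class TestPolyak:
    def test_no_momentum_reduces_to_gd(self):
        surf, _ = random_concave_quadratic(14)
        state = OptimizerState(position=np.ones(3))
        _, step = polyak_step(state, surf, 0.1, 0.0)
        assert np.allclose(step.step, gd_step(surf, np.ones(3), 0.1).step)

    def test_momentum_coasting_with_zero_gradient(self):
        flat = PerformanceSurface(
            evaluate=lambda t: 0.0,
            gradient=lambda t: np.zeros(t.size),
            hessian=lambda t: np.zeros((t.size, t.size)),
        )
        state = OptimizerState(position=np.zeros(2), momentum=np.array([0.0, 1.0]))
        _, step = polyak_step(state, flat, 0.1, 0.9)
        assert np.allclose(step.step, [0.0, 0.09])

    def test_mixed_gradient_and_momentum_example(self):
        surf = PerformanceSurface(
            evaluate=lambda t: float(t[0]),
            gradient=lambda t: np.array([1.0, 0.0]),
            hessian=lambda t: np.zeros((2, 2)),
        )
        state = OptimizerState(position=np.zeros(2), momentum=np.array([0.0, 1.0]))
        new_state, step = polyak_step(state, surf, 0.1, 0.9)
        assert np.allclose(step.step, [0.01, 0.09])
        assert step.audit_residual() == 0.0
        assert np.allclose(new_state.momentum, [0.1, 0.9])


class TestAdam:
    def test_zero_history_zero_gradient(self):
        flat = PerformanceSurface(
            evaluate=lambda t: 0.0,
            gradient=lambda t: np.zeros(t.size),
            hessian=lambda t: np.zeros((t.size, t.size)),
        )
        state = OptimizerState(position=np.zeros(2))
        _, step = adam_paper_step(state, flat, 0.1, 0.9, 0.999, 1e-8)
        assert np.allclose(step.step, 0.0)

    def test_first_step_matches_closed_form(self):
        surf = PerformanceSurface(
            evaluate=lambda t: float(t[0]),
            gradient=lambda t: np.array([1.0]),
            hessian=lambda t: np.zeros((1, 1)),
        )
        state = OptimizerState(position=np.zeros(1))
        _, step = adam_paper_step(state, surf, 0.1, 0.9, 0.999, 1e-8)
        v1 = (1 - 0.999) * 1.0
        m1 = (1 - 0.9) * 1.0
        closed = 0.1 * m1 / ((1 - 0.9) * (v1 + 1e-8))
        assert step.step[0] == pytest.approx(closed, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_decomposition_equals_closed_form_randomized(self, seed):
        gen = np.random.default_rng(seed)
        for _ in range(200):
            n = 3
            g = gen.standard_normal(n)
            surf = PerformanceSurface(
                evaluate=lambda t: 0.0,
                gradient=lambda t, g=g: g,
                hessian=lambda t: np.zeros((n, n)),
            )
            m_prev = gen.standard_normal(n)
            v_prev = gen.random(n)
            eta, u, s = gen.random() + 0.01, gen.random() * 0.98, gen.random() * 0.98
            c = 10.0 ** gen.uniform(-8, -2)
            state = OptimizerState(position=np.zeros(n), momentum=m_prev,
                                   second_moment=v_prev)
            _, step = adam_paper_step(state, surf, eta, u, s, c)
            v_new = (1 - s) * g**2 + s * v_prev
            m_new = (1 - u) * g + u * m_prev
            closed = eta * m_new / ((1 - u) * (v_new + c))
            assert np.allclose(step.step, closed, atol=1e-12)
            assert step.audit_residual() <= 1e-12


class TestSGLD:
    def test_zero_step_size(self):
        surf, _ = random_concave_quadratic(15)
        step = sgld_step(surf, np.ones(3), np.eye(3), 0.0,
                         np.random.default_rng(0))
        assert np.allclose(step.step, 0.0)

    def test_seeded_reproducibility(self):
        surf, _ = random_concave_quadratic(16)
        s1 = sgld_step(surf, np.ones(3), np.eye(3), 0.05, np.random.default_rng(42))
        s2 = sgld_step(surf, np.ones(3), np.eye(3), 0.05, np.random.default_rng(42))
        assert np.allclose(s1.step, s2.step)
        assert np.allclose(s1.noise, s2.noise)

    def test_noise_covariance_matches_2_eta_M(self):
        flat = PerformanceSurface(
            evaluate=lambda t: 0.0,
            gradient=lambda t: np.zeros(t.size),
            hessian=lambda t: np.zeros((t.size, t.size)),
        )
        M = np.diag([1.0, 4.0])
        eta = 0.05
        gen = np.random.default_rng(2024)
        n_draws = 100_000
        draws = np.empty((n_draws, 2))
        for i in range(n_draws):
            draws[i] = sgld_step(flat, np.zeros(2), M, eta, gen).noise
        target = 2 * eta * np.diag(M)  # (0.1, 0.4)
        sample_var = draws.var(axis=0)
        se_var = target * np.sqrt(2.0 / n_draws)
        assert np.all(np.abs(sample_var - target) < 3 * se_var)
        se_mean = np.sqrt(target / n_draws)
        assert np.all(np.abs(draws.mean(axis=0)) < 3 * se_mean)


class TestSGDSplit:
    def test_full_batch_has_no_noise(self, rng):
        grads = rng.standard_normal((50, 3))
        _, noise = sgd_split(grads, np.arange(50))
        assert np.allclose(noise, 0.0)

    def test_single_datum_batch(self, rng):
        grads = rng.standard_normal((50, 3))
        signal, noise = sgd_split(grads, [7])
        assert np.allclose(signal + noise, grads[7])

    def test_empty_batch_rejected(self, rng):
        with pytest.raises(ValueError):
            sgd_split(rng.standard_normal((10, 2)), [])

    def test_variance_halves_when_batch_quadruples(self):
        # without replacement: Var = (1/B)(1 − B/N)·population variance
        gen = np.random.default_rng(5)
        N = 1000
        grads = gen.standard_normal((N, 1)) * 2.0
        pop_var = grads.var(axis=0)[0]
        resamples = 5000
        out = {}
        for B in (10, 40):
            vs = np.empty(resamples)
            for r in range(resamples):
                idx = gen.choice(N, size=B, replace=False)
                vs[r] = sgd_split(grads, idx)[1][0]
            out[B] = vs.var()
        expected = {B: pop_var / B * (1 - B / N) for B in out}
        ratio = out[10] / out[40]
        expected_ratio = expected[10] / expected[40]
        se = expected_ratio * np.sqrt(4.0 / resamples)  # ratio of two variance estimates
        assert abs(ratio - expected_ratio) < 3 * se
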