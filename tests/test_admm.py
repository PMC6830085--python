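"""Block updates of the augmented Lagrangian, checked against independent
oracles: closed forms, numerical gradients, generic solvers and brute force."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from momf import admm
from momf.admm import (
    ADMMState,
    kl_divergence,
    objective_value,
    primal_residuals,
    project_nonnegative,
    update_duals,
    update_factors,
    update_mu,
    update_signature,
)

from conftest import random_state, residual_free_state


def _copy(state: ADMMState) -> ADMMState:
    import copy

    return copy.deepcopy(state)


def _numeric_grad(fun, arr, h=1e-4):
    g = np.zeros_like(arr)
    it = np.nditer(arr, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = arr[idx]
        arr[idx] = orig + h
        fp = fun()
        arr[idx] = orig - h
        fm = fun()
        arr[idx] = orig
        g[idx] = (fp - fm) / (2 * h)
    return g


class TestObjective:
    def test_zero_at_residual_free_point(self, tiny_dataset):
        state, mu_y, mu_x, H = residual_free_state(tiny_dataset)
        # data equal to their rates makes both KL terms vanish too
        assert objective_value(state, mu_y, mu_x, H) == pytest.approx(0.0, abs=1e-10)

    def test_scalar_kl_toy(self):
        # single entry Y=2 against rate 1, every other term zero
        one = np.ones((1, 1))
        state = ADMMState(
            mu_y=one.copy(), mu_x=one.copy(), Psi=one.copy(), Lambda=one.copy(),
            W=one.copy(), Psi_plus=one.copy(), Lambda_plus=one.copy(),
            U_y=np.zeros((1, 1)), U_x=np.zeros((1, 1)), U_Psi=np.zeros((1, 1)),
            U_Lambda=np.zeros((1, 1)), U_W=np.zeros((1, 1)), rho=2.0,
        )
        Y = np.array([[2.0]])
        X = np.array([[1.0]])
        H = np.array([[1.0]])
        assert objective_value(state, Y, X, H) == pytest.approx(2 * np.log(2) - 1)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(0)
        state = random_state(rng, ny=4, nx=3, p=6, C=2)
        Y = rng.poisson(3.0, (4, 6)).astype(float)
        X = rng.poisson(3.0, (3, 6)).astype(float)
        H = rng.uniform(0.1, 1.0, (2, 6))
        base = objective_value(state, Y, X, H)
        perm = np.array([2, 0, 3, 1])
        permuted = _copy(state)
        for name in ("mu_y", "Psi", "Psi_plus", "U_y", "U_Psi"):
            setattr(permuted, name, getattr(state, name)[perm])
        assert objective_value(permuted, Y[perm], X, H) == pytest.approx(base)

    def test_nonpositive_rate_rejected(self):
        rng = np.random.default_rng(1)
        state = random_state(rng)
        state.mu_y[0, 0] = 0.0
        Y = np.ones_like(state.mu_y)
        X = np.ones_like(state.mu_x)
        H = np.ones_like(state.W)
        with pytest.raises(ValueError, match="positive"):
            objective_value(state, Y, X, H)

    def test_kl_zero_count_convention(self):
        # entries with y=0 contribute exactly x
        assert kl_divergence(np.array([[0.0]]), np.array([[3.5]])) == pytest.approx(3.5)


class TestUpdateMu:
    def test_closed_form_example(self):
        rng = np.random.default_rng(2)
        state = random_state(rng, ny=1, nx=1, p=1, C=1, rho=2.0)
        state.Psi[:] = 1.0
        state.W[:] = 1.0
        state.U_y[:] = 0.0
        Y = np.array([[0.0]])
        X = np.array([[1.0]])
        update_mu(state, Y, X)
        assert state.mu_y[0, 0] == pytest.approx(0.5)

    def test_scalar_stationarity(self):
        # 1 - Y/mu + U + rho (mu - a) = 0 for every entry with a count
        rng = np.random.default_rng(3)
        for _ in range(5):
            state = random_state(rng, ny=4, nx=5, p=7, C=3)
            Y = rng.poisson(4.0, (4, 7)).astype(float) + 1.0
            X = rng.poisson(4.0, (5, 7)).astype(float) + 1.0
            update_mu(state, Y, X)
            a = state.Psi @ state.W
            resid = 1 - Y / state.mu_y + state.U_y + state.rho * (state.mu_y - a)
            assert np.max(np.abs(resid)) < 1e-8
            ax = state.Lambda @ state.W
            resid_x = 1 - X / state.mu_x + state.U_x + state.rho * (state.mu_x - ax)
            assert np.max(np.abs(resid_x)) < 1e-8

    def test_elementwise_gene_permutation_commutes(self):
        rng = np.random.default_rng(4)
        state = random_state(rng, ny=3, nx=4, p=6, C=2)
        Y = rng.poisson(3.0, (3, 6)).astype(float)
        X = rng.poisson(3.0, (4, 6)).astype(float)
        perm = np.array([5, 2, 0, 1, 4, 3])
        direct = update_mu(_copy(state), Y, X)
        permuted = _copy(state)
        for name in ("mu_y", "mu_x", "W", "U_y", "U_x", "U_W"):
            setattr(permuted, name, getattr(state, name)[:, perm])
        update_mu(permuted, Y[:, perm], X[:, perm])
        np.testing.assert_allclose(permuted.mu_y, direct.mu_y[:, perm])
        np.testing.assert_allclose(permuted.mu_x, direct.mu_x[:, perm])

    def test_rho_must_be_positive(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValueError, match="rho"):
            random_state(rng, rho=-1.0)


class TestUpdateFactors:
    def test_zeroes_numerical_gradient(self):
        rng = np.random.default_rng(6)
        state = random_state(rng, ny=3, nx=3, p=4, C=2)
        Y = rng.poisson(3.0, (3, 4)).astype(float)
        X = rng.poisson(3.0, (3, 4)).astype(float)
        H = rng.uniform(0.1, 1.0, (2, 4))
        fun = lambda: objective_value(state, Y, X, H)
        g_before = np.linalg.norm(_numeric_grad(fun, state.Psi))
        update_factors(state)
        g_after = np.linalg.norm(_numeric_grad(fun, state.Psi))
        assert g_after / max(g_before, 1.0) < 1e-6
        g_lam = np.linalg.norm(_numeric_grad(fun, state.Lambda))
        assert g_lam < 1e-6 * max(np.linalg.norm(state.Lambda), 1.0)

    def test_penalty_only_solution(self):
        rng = np.random.default_rng(7)
        state = random_state(rng)
        state.W[:] = 0.0
        for name in ("U_y", "U_x", "U_Psi", "U_Lambda"):
            getattr(state, name)[:] = 0.0
        update_factors(state)
        np.testing.assert_allclose(state.Psi, state.Psi_plus)
        np.testing.assert_allclose(state.Lambda, state.Lambda_plus)

    def test_matches_generic_linear_solver(self):
        rng = np.random.default_rng(8)
        state = random_state(rng, ny=4, nx=5, p=6, C=3)
        rhs = (
            state.mu_y @ state.W.T
            + state.Psi_plus
            + (state.U_y @ state.W.T - state.U_Psi) / state.rho
        )
        gram = state.W @ state.W.T + np.eye(3)
        expected, *_ = np.linalg.lstsq(gram.T, rhs.T, rcond=None)
        update_factors(state)
        np.testing.assert_allclose(state.Psi, expected.T, atol=1e-10)

    def test_nonfinite_rejected(self):
        rng = np.random.default_rng(9)
        state = random_state(rng)
        state.mu_y[0, 0] = np.nan
        with pytest.raises(FloatingPointError):
            update_factors(state)


class TestUpdateSignature:
    def test_anchor_only_solution(self):
        rng = np.random.default_rng(10)
        state = random_state(rng)
        state.Psi[:] = 0.0
        state.Lambda[:] = 0.0
        state.U_W[:] = 0.0
        H = rng.uniform(0.1, 1.0, state.W.shape)
        update_signature(state, H)
        np.testing.assert_allclose(state.W, H)

    def test_zeroes_numerical_gradient(self):
        rng = np.random.default_rng(11)
        state = random_state(rng, ny=2, nx=3, p=3, C=2)
        Y = rng.poisson(3.0, (2, 3)).astype(float)
        X = rng.poisson(3.0, (3, 3)).astype(float)
        H = rng.uniform(0.1, 1.0, (2, 3))
        fun = lambda: objective_value(state, Y, X, H)
        g_before = np.linalg.norm(_numeric_grad(fun, state.W))
        update_signature(state, H)
        g_after = np.linalg.norm(_numeric_grad(fun, state.W))
        assert g_after / max(g_before, 1.0) < 1e-6

    def test_residual_free_fixed_point_independent_of_rho(self, tiny_dataset):
        state, mu_y, mu_x, H = residual_free_state(tiny_dataset, rho=2.0)
        doubled, *_ = residual_free_state(tiny_dataset, rho=4.0)
        update_signature(state, H)
        update_signature(doubled, H)
        np.testing.assert_allclose(state.W, H, atol=1e-10)
        np.testing.assert_allclose(doubled.W, H, atol=1e-10)


class TestProjection:
    def test_clipping_examples(self):
        rng = np.random.default_rng(12)
        state = random_state(rng, ny=1, nx=1, p=2, C=2)
        state.Psi = np.array([[-1.0, 2.0]])
        state.U_Psi = np.zeros((1, 2))
        project_nonnegative(state)
        np.testing.assert_allclose(state.Psi_plus, [[0.0, 2.0]])

    def test_identity_on_feasible_points(self):
        rng = np.random.default_rng(13)
        state = random_state(rng)
        state.Psi = np.abs(state.Psi)
        state.Lambda = np.abs(state.Lambda)
        state.U_Psi[:] = 0.0
        state.U_Lambda[:] = 0.0
        project_nonnegative(state)
        np.testing.assert_allclose(state.Psi_plus, state.Psi)
        np.testing.assert_allclose(state.Lambda_plus, state.Lambda)

    def test_brute_force_sign_enumeration(self):
        # Psi_plus minimizes (rho/2)||Psi - Z||^2 + <U_Psi, Psi - Z> over
        # Z >= 0; enumerate all active sets of a 2x2 instance
        rng = np.random.default_rng(14)
        state = random_state(rng, ny=2, nx=2, p=3, C=2)
        rho, Psi, U = state.rho, state.Psi, state.U_Psi

        def value(Z):
            return 0.5 * rho * np.sum((Psi - Z) ** 2) + np.sum(U * (Psi - Z))

        best, best_val = None, np.inf
        unconstrained = Psi + U / rho
        for pattern in itertools.product([0, 1], repeat=4):
            Z = np.where(np.array(pattern).reshape(2, 2), unconstrained, 0.0)
            if np.any(Z < 0):
                continue
            if value(Z) < best_val:
                best, best_val = Z, value(Z)
        project_nonnegative(state)
        assert value(state.Psi_plus) <= best_val + 1e-12
        np.testing.assert_allclose(state.Psi_plus, best, atol=1e-12)


class TestUpdateDuals:
    def test_zero_residual_fixed_point(self, tiny_dataset):
        state, mu_y, mu_x, H = residual_free_state(tiny_dataset)
        before = {n: getattr(state, n).copy() for n in ("U_y", "U_x", "U_Psi", "U_Lambda", "U_W")}
        update_duals(state, H)
        for name, val in before.items():
            np.testing.assert_allclose(getattr(state, name), val, atol=1e-12)

    def test_single_step_from_zero_gives_rho_times_residual(self):
        rng = np.random.default_rng(15)
        state = random_state(rng)
        for n in ("U_y", "U_x", "U_Psi", "U_Lambda", "U_W"):
            getattr(state, n)[:] = 0.0
        H = rng.uniform(0.1, 1.0, state.W.shape)
        R = state.mu_y - state.Psi @ state.W
        update_duals(state, H)
        np.testing.assert_allclose(state.U_y, state.rho * R)
        np.testing.assert_allclose(state.U_W, state.rho * (state.W - H))

    def test_commutes_with_bulk_row_permutation(self):
        rng = np.random.default_rng(16)
        state = random_state(rng, ny=4)
        H = rng.uniform(0.1, 1.0, state.W.shape)
        perm = np.array([3, 1, 0, 2])
        permuted = _copy(state)
        for name in ("mu_y", "Psi", "Psi_plus", "U_y", "U_Psi"):
            setattr(permuted, name, getattr(state, name)[perm])
        update_duals(state, H)
        update_duals(permuted, H)
        np.testing.assert_allclose(permuted.U_y, state.U_y[perm])
        np.testing.assert_allclose(permuted.U_Psi, state.U_Psi[perm])


class TestResiduals:
    def test_finite_on_random_states(self):
        rng = np.random.default_rng(17)
        state = random_state(rng)
        H = rng.uniform(0.1, 1.0, state.W.shape)
        res = primal_residuals(state, H)
        assert set(res) == {"mu_y", "mu_x", "Psi", "Lambda", "W"}
        assert all(np.isfinite(v) for v in res.values())


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    y=st.integers(min_value=1, max_value=200),
    a=st.floats(min_value=-5, max_value=5, allow_nan=False),
    u=st.floats(min_value=-3, max_value=3, allow_nan=False),
    rho=st.floats(min_value=0.1, max_value=10, allow_nan=False),
)
def test_mu_root_stationarity_property(y, a, u, rho):
    """The quadratic root solves 1 - y/mu + u + rho (mu - a) = 0 for y > 0."""
    b = rho * a - u - 1.0
    mu = (b + np.sqrt(b * b + 4 * rho * y)) / (2 * rho)
    assert mu > 0
    assert 1 - y / mu + u + rho * (mu - a) == pytest.approx(0.0, abs=1e-8)
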