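"""ADMM block updates for joint Poisson matrix factorization.

The solver minimizes, over Poisson rate matrices mu_y (ny x p) and mu_x
(nx x p), factor matrices Psi (ny x C), Lambda (nx x C), signature W (C x p)
and their non-negative copies Psi_plus, Lambda_plus, the augmented
Lagrangian

    L = D(Y|mu_y) + D(X|mu_x)
      + <U_y, mu_y - Psi W>      + (rho/2) ||mu_y - Psi W||_F^2
      + <U_x, mu_x - Lambda W>   + (rho/2) ||mu_x - Lambda W||_F^2
      + <U_Psi, Psi - Psi_plus>  + (rho/2) ||Psi - Psi_plus||_F^2
      + <U_L, Lambda - Lambda_plus> + (rho/2) ||Lambda - Lambda_plus||_F^2
      + <U_W, W - H>             + (rho/2) ||W - H||_F^2

where D(y|x) = y log(y/x) - y + x is the elementwise KL divergence (the
Bregman divergence of the Poisson log-likelihood) and H is the single-cell
reference panel. The dual ascent on U_* enforces, at convergence,
mu_y = Psi W, mu_x = Lambda W, Psi = Psi_plus >= 0, Lambda = Lambda_plus >= 0
and W = H; the quadratic W-anchor shapes the path of W between its data-driven
value and the reference panel.

Each block update below solves its subproblem exactly: the mu updates are
the positive root of an elementwise quadratic, the factor and signature
updates are ridge-regularized normal equations, and the non-negative copies
are Euclidean projections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ADMMState",
    "initialize_state",
    "objective_value",
    "update_mu",
    "update_factors",
    "update_signature",
    "project_nonnegative",
    "update_duals",
    "primal_residuals",
    "kl_divergence",
]

# floor for Poisson rates inside logarithms / after the mu update; keeps the
# KL domain valid when a count is zero and the quadratic root collapses to 0
MU_FLOOR = 1e-12


@dataclass
class ADMMState:
    """All primal and dual blocks of the splitting, plus rho and a counter."""

    mu_y: np.ndarray
    mu_x: np.ndarray
    Psi: np.ndarray
    Lambda: np.ndarray
    W: np.ndarray
    Psi_plus: np.ndarray
    Lambda_plus: np.ndarray
    U_y: np.ndarray
    U_x: np.ndarray
    U_Psi: np.ndarray
    U_Lambda: np.ndarray
    U_W: np.ndarray
    rho: float
    iteration: int = 0
    # penalty on the W-anchor block; equals rho unless the caller re-weights
    # the anchor by the estimated single-cell uncertainty (rho / sigma^2)
    rho_w: float | None = None

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise ValueError(f"rho must be positive, got {self.rho}")
        if self.rho_w is None:
            self.rho_w = self.rho
        if self.rho_w <= 0:
            raise ValueError(f"rho_w must be positive, got {self.rho_w}")
        ny, p = self.mu_y.shape
        nx, C = self.Lambda.shape
        expected = {
            "mu_y": (ny, p), "mu_x": (nx, p), "Psi": (ny, C), "Lambda": (nx, C),
            "W": (C, p), "Psi_plus": (ny, C), "Lambda_plus": (nx, C),
            "U_y": (ny, p), "U_x": (nx, p), "U_Psi": (ny, C),
            "U_Lambda": (nx, C), "U_W": (C, p),
        }
        for name, shape in expected.items():
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")

    @property
    def shapes(self) -> tuple[int, int, int, int]:
        """(ny, nx, p, C)."""
        ny, p = self.mu_y.shape
        nx, C = self.Lambda.shape
        return ny, nx, p, C


def kl_divergence(counts: np.ndarray, rates: np.ndarray) -> float:
    """Sum of elementwise D(y|x) = y log(y/x) - y + x, with 0 log 0 = 0."""
    if np.any(rates < 0):
        raise ValueError("KL divergence undefined for negative rates")
    rates = np.maximum(rates, MU_FLOOR)
    y = np.asarray(counts, dtype=float)
    pos = y > 0
    out = float(rates.sum() - y.sum())
    out += float((y[pos] * np.log(y[pos] / rates[pos])).sum())
    return out


def initialize_state(
    Y: np.ndarray,
    X: np.ndarray,
    H: np.ndarray,
    cell_type_index: np.ndarray,
    rho: float,
    rng: np.random.Generator,
    rho_w: float | None = None,
) -> ADMMState:
    """Structure-aware initialization.

    W starts at the reference panel H; Lambda starts one-hot on the known
    cell-type memberships scaled by each cell's total count relative to its
    type's mean; Psi rows start uniform on the simplex (seeded); the Poisson
    rates start at the counts floored at 0.5; all duals start at zero.
    """
    ny, p = Y.shape
    nx = X.shape[0]
    C = H.shape[0]
    Psi = rng.uniform(size=(ny, C))
    Psi /= Psi.sum(axis=1, keepdims=True)
    Lambda = np.zeros((nx, C))
    depths = X.sum(axis=1).astype(float)
    for c in range(C):
        members = cell_type_index == c
        if members.any():
            mean_depth = depths[members].mean()
            Lambda[members, c] = depths[members] / mean_depth if mean_depth > 0 else 1.0
    return ADMMState(
        mu_y=np.maximum(Y.astype(float), 0.5),
        mu_x=np.maximum(X.astype(float), 0.5),
        Psi=Psi,
        Lambda=Lambda,
        W=H.copy(),
        Psi_plus=Psi.copy(),
        Lambda_plus=Lambda.copy(),
        U_y=np.zeros((ny, p)),
        U_x=np.zeros((nx, p)),
        U_Psi=np.zeros((ny, C)),
        U_Lambda=np.zeros((nx, C)),
        U_W=np.zeros((C, p)),
        rho=float(rho),
        rho_w=float(rho_w) if rho_w is not None else None,
    )


def objective_value(state: ADMMState, Y: np.ndarray, X: np.ndarray, H: np.ndarray) -> float:
    """Evaluate the augmented Lagrangian L at the current state."""
    if np.any(state.mu_y <= 0) or np.any(state.mu_x <= 0):
        raise ValueError("Poisson rates must be strictly positive")
    rho = state.rho
    val = kl_divergence(Y, state.mu_y) + kl_divergence(X, state.mu_x)
    for U, resid, pen in (
        (state.U_y, state.mu_y - state.Psi @ state.W, rho),
        (state.U_x, state.mu_x - state.Lambda @ state.W, rho),
        (state.U_Psi, state.Psi - state.Psi_plus, rho),
        (state.U_Lambda, state.Lambda - state.Lambda_plus, rho),
        (state.U_W, state.W - H, state.rho_w),
    ):
        val += float((U * resid).sum()) + 0.5 * pen * float((resid * resid).sum())
    if not np.isfinite(val):
        raise FloatingPointError("non-finite objective")
    return val


def _mu_root(counts: np.ndarray, anchor: np.ndarray, U: np.ndarray, rho: float) -> np.ndarray:
    # positive root of rho*mu^2 + (1 + U - rho*anchor)*mu - counts = 0,
    # the stationarity condition 1 - counts/mu + U + rho*(mu - anchor) = 0
    b = rho * anchor - U - 1.0
    mu = (b + np.sqrt(b * b + 4.0 * rho * counts)) / (2.0 * rho)
    return np.maximum(mu, MU_FLOOR)


def update_mu(state: ADMMState, Y: np.ndarray, X: np.ndarray) -> ADMMState:
    """Exact elementwise minimization of L in the Poisson-rate blocks."""
    state.mu_y = _mu_root(Y, state.Psi @ state.W, state.U_y, state.rho)
    state.mu_x = _mu_root(X, state.Lambda @ state.W, state.U_x, state.rho)
    return state


def _factor_solve(rhs: np.ndarray, gram: np.ndarray) -> np.ndarray:
    # right-multiplication by (gram)^-1 via a symmetric solve
    return np.linalg.solve(gram, rhs.T).T


def update_factors(state: ADMMState) -> ADMMState:
    """Ridge normal equations for Psi and Lambda (exact block minimizers)."""
    for arr in (state.mu_y, state.mu_x, state.W, state.Psi_plus, state.Lambda_plus):
        if not np.all(np.isfinite(arr)):
            raise FloatingPointError("non-finite input to factor update")
    W = state.W
    rho = state.rho
    gram = W @ W.T + np.eye(W.shape[0])
    state.Psi = _factor_solve(
        state.mu_y @ W.T + state.Psi_plus + (state.U_y @ W.T - state.U_Psi) / rho, gram
    )
    state.Lambda = _factor_solve(
        state.mu_x @ W.T + state.Lambda_plus + (state.U_x @ W.T - state.U_Lambda) / rho, gram
    )
    return state


def update_signature(state: ADMMState, H: np.ndarray) -> ADMMState:
    """Ridge normal equations for the shared signature W."""
    for arr in (state.Psi, state.Lambda, state.mu_y, state.mu_x):
        if not np.all(np.isfinite(arr)):
            raise FloatingPointError("non-finite input to signature update")
    rho = state.rho
    w_weight = state.rho_w / rho
    gram = (
        state.Psi.T @ state.Psi
        + state.Lambda.T @ state.Lambda
        + w_weight * np.eye(state.W.shape[0])
    )
    rhs = (
        state.Psi.T @ state.mu_y
        + state.Lambda.T @ state.mu_x
        + w_weight * H
        + (state.Psi.T @ state.U_y + state.Lambda.T @ state.U_x - state.U_W) / rho
    )
    state.W = np.linalg.solve(gram, rhs)
    return state


def project_nonnegative(state: ADMMState) -> ADMMState:
    """Euclidean projection of the split copies onto the non-negative orthant."""
    state.Psi_plus = np.maximum(state.Psi + state.U_Psi / state.rho, 0.0)
    state.Lambda_plus = np.maximum(state.Lambda + state.U_Lambda / state.rho, 0.0)
    return state


def update_duals(state: ADMMState, H: np.ndarray) -> ADMMState:
    """Dual ascent on every constraint residual."""
    rho = state.rho
    state.U_y = state.U_y + rho * (state.mu_y - state.Psi @ state.W)
    state.U_x = state.U_x + rho * (state.mu_x - state.Lambda @ state.W)
    state.U_W = state.U_W + state.rho_w * (state.W - H)
    state.U_Psi = state.U_Psi + rho * (state.Psi - state.Psi_plus)
    state.U_Lambda = state.U_Lambda + rho * (state.Lambda - state.Lambda_plus)
    return state


def primal_residuals(state: ADMMState, H: np.ndarray) -> dict[str, float]:
    """Frobenius norms of the five constraint violations."""
    return {
        "mu_y": float(np.linalg.norm(state.mu_y - state.Psi @ state.W)),
        "mu_x": float(np.linalg.norm(state.mu_x - state.Lambda @ state.W)),
        "Psi": float(np.linalg.norm(state.Psi - state.Psi_plus)),
        "Lambda": float(np.linalg.norm(state.Lambda - state.Lambda_plus)),
        "W": float(np.linalg.norm(state.W - H)),
    }
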