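import numpy as np
import pytest

from momf import simulate_dataset
from momf.admm import ADMMState
from momf.reference import build_reference_panel


@pytest.fixture
def tiny_dataset():
    """C=2 dataset small enough for exhaustive/numeric oracles."""
    return simulate_dataset(C=2, p=8, ny=4, nx=6, seed=5)


@pytest.fixture
def small_dataset():
    """C=3 dataset small enough to fit in a few seconds."""
    return simulate_dataset(C=3, p=300, ny=30, nx=90, seed=17)


def random_state(rng, ny=3, nx=4, p=5, C=2, rho=2.0, scale=1.0):
    """A random (feasible-domain) ADMM state for update-rule checks."""
    return ADMMState(
        mu_y=rng.uniform(0.2, 3.0, (ny, p)) * scale,
        mu_x=rng.uniform(0.2, 3.0, (nx, p)) * scale,
        Psi=rng.normal(1.0, 0.5, (ny, C)),
        Lambda=rng.normal(1.0, 0.5, (nx, C)),
        W=rng.uniform(0.1, 2.0, (C, p)),
        Psi_plus=rng.uniform(0.0, 2.0, (ny, C)),
        Lambda_plus=rng.uniform(0.0, 2.0, (nx, C)),
        U_y=rng.normal(0.0, 0.3, (ny, p)),
        U_x=rng.normal(0.0, 0.3, (nx, p)),
        U_Psi=rng.normal(0.0, 0.3, (ny, C)),
        U_Lambda=rng.normal(0.0, 0.3, (nx, C)),
        U_W=rng.normal(0.0, 0.3, (C, p)),
        rho=rho,
    )


def residual_free_state(dataset, rho=2.0):
    """A state where every constraint residual vanishes and the data equal
    their Poisson rates, so the augmented Lagrangian is exactly zero."""
    panel = build_reference_panel(dataset.sc)
    H = panel.values
    ny = dataset.bulk.n_individuals
    nx = dataset.sc.n_cells
    C = H.shape[0]
    rng = np.random.default_rng(0)
    Psi = rng.uniform(0.5, 2.0, (ny, C))
    Lam = rng.uniform(0.5, 2.0, (nx, C))
    mu_y = Psi @ H
    mu_x = Lam @ H
    state = ADMMState(
        mu_y=mu_y, mu_x=mu_x, Psi=Psi, Lambda=Lam, W=H.copy(),
        Psi_plus=Psi.copy(), Lambda_plus=Lam.copy(),
        U_y=np.zeros_like(mu_y), U_x=np.zeros_like(mu_x),
        U_Psi=np.zeros_like(Psi), U_Lambda=np.zeros_like(Lam),
        U_W=np.zeros_like(H), rho=rho,
    )
    return state, mu_y, mu_x, H
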