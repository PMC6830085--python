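"""Synthetic bulk + single-cell datasets with known cell-type proportions.

The generator mirrors the model's own data-generating process: a shared
signature W with Gamma(shape, rate) entries, mixing matrices Psi (bulk
proportions on the simplex, scaled to sequencing depth) and Lambda
(block-structured single-cell loadings, one type per cell), expected counts
E(Y) = Psi_scaled W and E(X) = Lambda W, and Poisson-sampled observations.
Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .data import BulkCountMatrix, SingleCellCountMatrix

__all__ = ["SyntheticDataset", "simulate_dataset", "default_benchmark_grid"]


@dataclass
class SyntheticDataset:
    """A simulated bulk/single-cell pair plus its generating truth."""

    bulk: BulkCountMatrix
    sc: SingleCellCountMatrix
    true_proportions: pd.DataFrame
    true_loadings: np.ndarray
    true_signature: np.ndarray
    seed: int
    params: dict

    def write(self, outdir: str | os.PathLike) -> None:
        """Write bulk.csv, sc.csv, labels.csv, truth_proportions.csv, params.json."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            self.bulk.values, index=self.bulk.individual_ids, columns=self.bulk.gene_ids
        ).to_csv(outdir / "bulk.csv")
        pd.DataFrame(
            self.sc.values, index=self.sc.cell_ids, columns=self.sc.gene_ids
        ).to_csv(outdir / "sc.csv")
        pd.DataFrame(
            {"cell_id": self.sc.cell_ids, "cell_type": self.sc.cell_type_labels}
        ).to_csv(outdir / "labels.csv", index=False, header=False)
        self.true_proportions.to_csv(outdir / "truth_proportions.csv")
        with open(outdir / "params.json", "w") as fh:
            json.dump({**self.params, "seed": self.seed}, fh, indent=2)


def simulate_dataset(
    C: int,
    p: int,
    ny: int,
    nx: int,
    seed: int,
    gamma_shape: float = 2.0,
    gamma_rate: float = 2.0,
    depth_scale: float = 50.0,
    proportion_source: str = "dirichlet",
    proportions: "pd.DataFrame | np.ndarray | None" = None,
) -> SyntheticDataset:
    """Simulate one benchmark dataset.

    Parameters
    ----------
    C, p, ny, nx
        Cell types, genes, bulk individuals, single cells. Cells are split
        as evenly as possible across types (every type gets at least one).
    gamma_shape, gamma_rate
        Signature entries W[c, j] ~ Gamma(shape, rate); the default
        (2, rate 2) gives mean 1 per gene per type.
    depth_scale
        Bulk rows of the true proportion matrix are multiplied by this
        factor before forming E(Y) = Psi_scaled W, so the average expected
        count per gene per individual is about ``depth_scale * mean(W)``.
    proportion_source
        ``"dirichlet"`` draws each individual's proportions from a flat
        Dirichlet; ``"user_matrix"`` uses the supplied ``proportions``
        (ny x C, e.g. estimates from a real cohort), renormalized per row.
    """
    if C < 1:
        raise ValueError("C must be >= 1")
    if p < C:
        raise ValueError("p must be >= C")
    if ny < 2:
        raise ValueError("ny must be >= 2")
    if nx < C:
        raise ValueError(f"need at least one cell per type: nx={nx} < C={C}")
    if gamma_shape <= 0 or gamma_rate <= 0:
        raise ValueError("gamma_shape and gamma_rate must be positive")
    if depth_scale <= 0:
        raise ValueError("depth_scale must be positive")

    rng = np.random.default_rng(seed)
    types = [f"type{c + 1}" for c in range(C)]

    W = rng.gamma(shape=gamma_shape, scale=1.0 / gamma_rate, size=(C, p))

    if proportion_source == "dirichlet":
        Psi = rng.dirichlet(np.ones(C), size=ny) if C > 1 else np.ones((ny, 1))
    elif proportion_source == "user_matrix":
        if proportions is None:
            raise ValueError("proportion_source='user_matrix' requires `proportions`")
        Psi = np.asarray(proportions, dtype=float)
        if Psi.shape != (ny, C):
            raise ValueError(f"proportions must have shape ({ny}, {C}), got {Psi.shape}")
        if np.any(Psi < 0):
            raise ValueError("proportions must be non-negative")
        Psi = Psi / Psi.sum(axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown proportion_source {proportion_source!r}")

    # cells split across types as evenly as possible, one Gamma magnitude each
    cells_per_type = np.full(C, nx // C)
    cells_per_type[: nx % C] += 1
    type_index = np.repeat(np.arange(C), cells_per_type)
    Lambda = np.zeros((nx, C))
    Lambda[np.arange(nx), type_index] = rng.gamma(
        shape=gamma_shape, scale=1.0 / gamma_rate, size=nx
    )

    mean_y = (depth_scale * Psi) @ W
    mean_x = Lambda @ W
    Y = rng.poisson(mean_y)
    X = rng.poisson(mean_x)

    bulk = BulkCountMatrix(
        Y,
        [f"ind{i + 1}" for i in range(ny)],
        [f"gene{j + 1}" for j in range(p)],
    )
    sc = SingleCellCountMatrix(
        X,
        [f"cell{k + 1}" for k in range(nx)],
        list(bulk.gene_ids),
        [types[c] for c in type_index],
    )
    params = {
        "C": C,
        "p": p,
        "ny": ny,
        "nx": nx,
        "gamma_shape": gamma_shape,
        "gamma_rate": gamma_rate,
        "depth_scale": depth_scale,
        "proportion_source": proportion_source,
    }
    return SyntheticDataset(
        bulk=bulk,
        sc=sc,
        true_proportions=pd.DataFrame(Psi, index=bulk.individual_ids, columns=types),
        true_loadings=Lambda,
        true_signature=W,
        seed=seed,
        params=params,
    )


def default_benchmark_grid() -> list[dict]:
    """The benchmark configurations: 10,000-gene runs at C in {2, 3, 5},
    plus 2,000-gene desk-scale variants sized to finish in minutes.

    Each record carries the simulate_dataset keyword arguments plus a
    ``scaled_down`` flag.
    """
    grid = []
    for C in (2, 3, 5):
        grid.append(
            {"C": C, "p": 10_000, "ny": 590, "nx": 359, "depth_scale": 50.0,
             "scaled_down": False}
        )
    for C in (2, 3, 5):
        grid.append(
            {"C": C, "p": 2_000, "ny": 100, "nx": 100 * C, "depth_scale": 50.0,
             "scaled_down": True}
        )
    return grid
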