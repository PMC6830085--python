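"""Model front end: :class:`MOMF` and :class:`MOMFResults`.

MOMF (multi-omics matrix factorization) estimates the cell-type composition
of bulk RNA-seq individuals by jointly factorizing the bulk count matrix Y
(individuals x genes) and a labeled single-cell count matrix X (cells x
genes) under Poisson observation models with a shared cell-type signature
W::

    Y_ij ~ Poisson((Psi W)_ij)        Psi: individuals x cell types
    X_kj ~ Poisson((Lambda W)_kj)     Lambda: cells x cell types

W is anchored at the empirical reference panel H built from the labeled
cells. Estimation is by ADMM on the augmented Lagrangian (see
:mod:`momf.admm`); the estimated proportions are the rows of the
non-negative factor Psi_plus rescaled to the unit simplex.

Typical use::

    model = MOMF(bulk, sc)          # gene-aligned count containers
    res = model.fit(rho=2.0, iterations=5000, seed=1)
    res.proportions                 # DataFrame, individuals x cell types
    print(res.summary())
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from . import admm
from .data import BulkCountMatrix, SignaturePanel, SingleCellCountMatrix, align_genes
from .reference import build_reference_panel, estimate_sigma2

logger = logging.getLogger("momf")

__all__ = ["MOMF", "MOMFResults", "fit_momf", "proportions_from_psi"]


def proportions_from_psi(psi_plus: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map the non-negative bulk factor onto the unit simplex, row by row.

    Rows summing to zero (an individual with no attributable signal) fall
    back to the uniform composition 1/C; the boolean mask of such rows is
    returned alongside.
    """
    psi_plus = np.asarray(psi_plus, dtype=float)
    C = psi_plus.shape[1]
    row_sums = psi_plus.sum(axis=1)
    zero_rows = row_sums <= 0
    out = np.empty_like(psi_plus)
    out[zero_rows] = 1.0 / C
    out[~zero_rows] = psi_plus[~zero_rows] / row_sums[~zero_rows, None]
    return out, zero_rows


@dataclass
class MOMFResults:
    """Deconvolution fit: estimates, diagnostics and solver configuration.

    Attributes
    ----------
    proportions : pandas.DataFrame
        Individuals x cell types, rows on the unit simplex (rows of
        ``raw_psi`` divided by their sums).
    raw_psi : pandas.DataFrame
        Un-normalized non-negative bulk factor Psi_plus, on the scale that
        absorbs sequencing depth; kept so users can apply an alternative
        normalization.
    loadings : pandas.DataFrame
        Cells x cell types non-negative single-cell factor Lambda_plus.
    signature : SignaturePanel
        Fitted shared signature W (cell types x genes).
    reference_panel : SignaturePanel
        Empirical anchor H the signature was shrunk toward.
    objective_trace, primal_residuals
        Augmented-Lagrangian values (recorded every ``trace_every``
        iterations) and per-constraint Frobenius residual traces.
    converged : bool
        Whether every primal residual fell below the tolerance before the
        iteration cap.
    sigma2 : float
        Pooled single-cell variance around the panel (diagnostic).
    config : dict
        Solver parameters of the run (rho, iterations, seed, tol, ...).
    """

    proportions: pd.DataFrame
    raw_psi: pd.DataFrame
    loadings: pd.DataFrame
    signature: SignaturePanel
    reference_panel: SignaturePanel
    objective_trace: list[float]
    trace_iterations: list[int]
    primal_residuals: dict[str, list[float]]
    converged: bool
    n_iterations: int
    sigma2: float
    config: dict[str, Any] = field(default_factory=dict)

    @property
    def cell_types(self) -> list[str]:
        return list(self.proportions.columns)

    def summary(self) -> str:
        """Plain-text fit summary in the spirit of statsmodels results."""
        prop = self.proportions
        lines = [
            "MOMF deconvolution results",
            "=" * 60,
            f"individuals: {prop.shape[0]}    cell types: {prop.shape[1]}"
            f"    genes: {len(self.signature.gene_ids)}",
            f"rho: {self.config.get('rho')}    iterations run: {self.n_iterations}"
            f"    converged: {self.converged}",
            f"seed: {self.config.get('seed')}    sigma^2 (panel uncertainty): "
            f"{self.sigma2:.4g}",
            "-" * 60,
            f"{'cell type':<24}{'mean':>9}{'sd':>9}{'min':>9}{'max':>9}",
        ]
        for ct in prop.columns:
            col = prop[ct]
            lines.append(
                f"{ct:<24}{col.mean():>9.4f}{col.std():>9.4f}"
                f"{col.min():>9.4f}{col.max():>9.4f}"
            )
        lines.append("-" * 60)
        if self.objective_trace:
            lines.append(f"final objective: {self.objective_trace[-1]:.6g}")
        res = {k: v[-1] for k, v in self.primal_residuals.items() if v}
        if res:
            lines.append(
                "final primal residuals: "
                + "  ".join(f"{k}={v:.3g}" for k, v in res.items())
            )
        return "\n".join(lines)

    def diagnostics_dict(self) -> dict[str, Any]:
        """JSON-serializable record of the run (for ``diagnostics.json``)."""
        return {
            "config": self.config,
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "sigma2": self.sigma2,
            "objective_trace": self.objective_trace,
            "trace_iterations": self.trace_iterations,
            "primal_residuals": self.primal_residuals,
        }


class MOMF:
    """Joint Poisson factorization model for bulk deconvolution.

    Parameters
    ----------
    bulk : BulkCountMatrix
    sc : SingleCellCountMatrix
        Gene-aligned raw counts (see :func:`momf.align_genes`; the
        constructor aligns automatically when the gene lists differ).
    panel_mode : {"counts", "mean"}
        How the reference panel H is built from the labeled cells.
    sigma_weighted : bool
        When True, the W-anchor penalty is strengthened to
        rho_W = rho / max(sigma^2, 1e-8) so a tighter single-cell panel pulls
        W harder; default False uses the plain objective with a single rho.
    """

    def __init__(
        self,
        bulk: BulkCountMatrix,
        sc: SingleCellCountMatrix,
        panel_mode: str = "counts",
        sigma_weighted: bool = False,
    ):
        if bulk.gene_ids != sc.gene_ids:
            bulk, sc = align_genes(bulk, sc)
        self.bulk = bulk
        self.sc = sc
        self.panel_mode = panel_mode
        self.sigma_weighted = sigma_weighted
        self.reference_panel = build_reference_panel(sc, mode=panel_mode)
        self.sigma2 = estimate_sigma2(sc, self.reference_panel) if sc.n_cells >= 2 else 0.0

    @classmethod
    def from_dataframes(
        cls,
        bulk: pd.DataFrame,
        sc: pd.DataFrame,
        cell_type_labels: "pd.Series | list[str] | dict[str, str]",
        **kwargs: Any,
    ) -> "MOMF":
        """Build the model from samples-by-genes DataFrames.

        ``cell_type_labels`` may be a list aligned with ``sc`` rows, a Series
        indexed by cell id, or a dict mapping cell id to type.
        """
        if isinstance(cell_type_labels, dict):
            labels = [cell_type_labels[str(c)] for c in sc.index]
        elif isinstance(cell_type_labels, pd.Series):
            labels = [cell_type_labels.loc[c] for c in sc.index]
        else:
            labels = list(cell_type_labels)
        bulk_m = BulkCountMatrix(
            bulk.to_numpy(), [str(i) for i in bulk.index], [str(g) for g in bulk.columns]
        )
        sc_m = SingleCellCountMatrix(
            sc.to_numpy(), [str(i) for i in sc.index], [str(g) for g in sc.columns], labels
        )
        return cls(bulk_m, sc_m, **kwargs)

    def fit(
        self,
        rho: float = 2.0,
        iterations: int = 5000,
        seed: int = 0,
        tol: float | None = None,
        trace_every: int = 25,
    ) -> MOMFResults:
        """Run the ADMM block updates and extract proportions.

        ``iterations`` is a hard cap (default 5000); the loop stops early
        when every primal residual drops below ``tol`` (default
        ``1e-6 * ||Y||_F``). ``seed`` fixes the random initialization of
        Psi; everything else is deterministic.
        """
        if iterations < 1:
            raise ValueError("iterations must be >= 1")
        Y = np.asarray(self.bulk.values, dtype=float)
        X = np.asarray(self.sc.values, dtype=float)
        H = self.reference_panel.values
        types = self.reference_panel.cell_type_labels
        type_to_idx = {t: c for c, t in enumerate(types)}
        cell_type_index = np.asarray([type_to_idx[t] for t in self.sc.cell_type_labels])
        if tol is None:
            tol = 1e-6 * float(np.linalg.norm(Y))

        rng = np.random.default_rng(seed)
        # tighter single-cell panels (small sigma^2) pull W harder when the
        # sigma-weighted anchor is requested; plain objective otherwise
        rho_w = rho / max(self.sigma2, 1e-8) if self.sigma_weighted else rho
        state = admm.initialize_state(Y, X, H, cell_type_index, rho, rng, rho_w=rho_w)

        obj_trace: list[float] = []
        trace_iters: list[int] = []
        res_trace: dict[str, list[float]] = {k: [] for k in ("mu_y", "mu_x", "Psi", "Lambda", "W")}
        converged = False
        it = 0
        for it in range(1, iterations + 1):
            state = admm.update_mu(state, Y, X)
            state = admm.update_factors(state)
            state = admm.update_signature(state, H)
            state = admm.project_nonnegative(state)
            state = admm.update_duals(state, H)
            state.iteration = it
            resid = admm.primal_residuals(state, H)
            for k, v in resid.items():
                if not np.isfinite(v):
                    raise FloatingPointError(f"non-finite {k} residual at iteration {it}")
            if it % trace_every == 0 or it == iterations or it == 1:
                obj = admm.objective_value(state, Y, X, H)
                if not np.isfinite(obj):
                    raise FloatingPointError(f"non-finite objective at iteration {it}")
                obj_trace.append(obj)
                trace_iters.append(it)
                for k, v in resid.items():
                    res_trace[k].append(v)
            if max(resid.values()) < tol:
                converged = True
                if trace_iters and trace_iters[-1] != it:
                    obj_trace.append(admm.objective_value(state, Y, X, H))
                    trace_iters.append(it)
                    for k, v in resid.items():
                        res_trace[k].append(v)
                break

        psi_plus = state.Psi_plus
        C = len(types)
        proportions, zero_rows = proportions_from_psi(psi_plus)
        if zero_rows.any():
            logger.warning(
                "%d individual(s) with all-zero proportion estimates; set to uniform 1/%d",
                int(zero_rows.sum()), C,
            )

        ids = self.bulk.individual_ids
        config = {
            "rho": rho,
            "rho_w": rho_w,
            "iterations": iterations,
            "seed": seed,
            "tol": tol,
            "trace_every": trace_every,
            "panel_mode": self.panel_mode,
            "sigma_weighted": self.sigma_weighted,
            "n_genes": self.bulk.n_genes,
        }
        return MOMFResults(
            proportions=pd.DataFrame(proportions, index=ids, columns=types),
            raw_psi=pd.DataFrame(psi_plus, index=ids, columns=types),
            loadings=pd.DataFrame(state.Lambda_plus, index=self.sc.cell_ids, columns=types),
            signature=SignaturePanel(
                np.maximum(state.W, 0.0), types, list(self.bulk.gene_ids)
            ),
            reference_panel=self.reference_panel,
            objective_trace=obj_trace,
            trace_iterations=trace_iters,
            primal_residuals=res_trace,
            converged=converged,
            n_iterations=it,
            sigma2=self.sigma2,
            config=config,
        )


def fit_momf(
    bulk: BulkCountMatrix,
    sc: SingleCellCountMatrix,
    rho: float = 2.0,
    iterations: int = 5000,
    seed: int = 0,
    tol: float | None = None,
    **model_kwargs: Any,
) -> MOMFResults:
    """Convenience wrapper: build the :class:`MOMF` model and fit it."""
    return MOMF(bulk, sc, **model_kwargs).fit(
        rho=rho, iterations=iterations, seed=seed, tol=tol
    )
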