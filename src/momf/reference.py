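"""Reference signature panel H from labeled single-cell counts.

For gene j and cell type c with cell set Omega_c, the panel entry is the
fraction of all single-cell reads for that gene contributed by that type:

    h[c, j] = sum_{k in Omega_c} X[k, j] / sum_{k=1..nx} X[k, j]

so informative gene columns sum to 1 across types. Note this weights cells
by their read counts: doubling one cell's depth changes H. The alternative
``mode="mean"`` averages depth-normalized expression per type instead, which
is robust to cell-type abundance in the reference but is not the default.

The fitted signature W is anchored at H during optimization; the scalar
sigma^2 returned by :func:`estimate_sigma2` quantifies how variable
individual cells are around their type's panel value and is reported as a
diagnostic (optionally re-weighting the anchor strength).
"""

from __future__ import annotations

import numpy as np

from .data import SignaturePanel, SingleCellCountMatrix

__all__ = ["build_reference_panel", "estimate_sigma2"]


def _type_indices(sc: SingleCellCountMatrix) -> dict[str, np.ndarray]:
    labels = np.asarray(sc.cell_type_labels)
    groups = {t: np.flatnonzero(labels == t) for t in sc.cell_types}
    for t, idx in groups.items():
        if idx.size == 0:
            raise ValueError(f"cell type {t!r} has no cells")
    return groups


def build_reference_panel(sc: SingleCellCountMatrix, mode: str = "counts") -> SignaturePanel:
    """Build the C x p reference panel H; rows ordered by sorted type label.

    ``mode="counts"`` (default) is the count-weighted fraction defined above.
    ``mode="mean"`` first divides each cell by its total count, then averages
    within type and renormalizes each gene column to sum to 1.

    Genes with zero total count carry no information and get the uniform
    column 1/C, keeping shapes aligned with the bulk matrix.
    """
    X = np.asarray(sc.values, dtype=float)
    if X.sum() == 0:
        raise ValueError("single-cell matrix is all zero")
    groups = _type_indices(sc)
    types = sc.cell_types
    C, p = len(types), sc.n_genes
    H = np.empty((C, p))
    if mode == "counts":
        totals = X.sum(axis=0)
        informative = totals > 0
        for c, t in enumerate(types):
            with np.errstate(invalid="ignore"):
                H[c] = np.where(informative, X[groups[t]].sum(axis=0) / np.where(informative, totals, 1.0), 1.0 / C)
    elif mode == "mean":
        depths = X.sum(axis=1, keepdims=True)
        R = np.divide(X, depths, out=np.zeros_like(X), where=depths > 0)
        for c, t in enumerate(types):
            H[c] = R[groups[t]].mean(axis=0)
        colsum = H.sum(axis=0)
        informative = colsum > 0
        H = np.where(informative, H / np.where(informative, colsum, 1.0), 1.0 / C)
    else:
        raise ValueError(f"unknown panel mode {mode!r}")
    return SignaturePanel(H, types, list(sc.gene_ids))


def estimate_sigma2(sc: SingleCellCountMatrix, panel: SignaturePanel) -> float:
    """Pooled variance of per-cell normalized contributions around the panel.

    Each cell's contribution to gene j is r[k, j] = X[k, j] / sum_k X[k, j].
    Within type c these have mean h[c, j] / |Omega_c|; sigma^2 pools the
    unbiased within-type variance of r over all informative genes and types.
    Returned as a single scalar, logged in run metadata; types with a single
    cell contribute no degrees of freedom (all-singleton references give 0).
    """
    if sc.n_cells < 2:
        raise ValueError("sigma^2 needs at least 2 cells")
    X = np.asarray(sc.values, dtype=float)
    totals = X.sum(axis=0)
    informative = totals > 0
    if not informative.any():
        raise ValueError("single-cell matrix is all zero")
    R = X[:, informative] / totals[informative]
    groups = _type_indices(sc)
    ss = 0.0
    dof = 0
    for t, idx in groups.items():
        if idx.size < 2:
            continue
        sub = R[idx]
        ss += float(((sub - sub.mean(axis=0)) ** 2).sum())
        dof += (idx.size - 1) * sub.shape[1]
    return ss / dof if dof else 0.0
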