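"""Count-matrix containers shared by the solver, simulator and I/O layers.

Bulk data are individuals x genes; single-cell data are cells x genes with a
per-cell type label. Both are raw (unnormalized) read/UMI counts: the model
is a Poisson factorization of the counts themselves, so any library-size or
log normalization upstream would change its meaning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger("momf")

__all__ = [
    "BulkCountMatrix",
    "SingleCellCountMatrix",
    "SignaturePanel",
    "align_genes",
]


def _validate_counts(values: np.ndarray, what: str) -> np.ndarray:
    values = np.asarray(values)
    if values.ndim != 2:
        raise ValueError(f"{what}: expected a 2-D matrix, got ndim={values.ndim}")
    if values.size == 0:
        raise ValueError(f"{what}: matrix is empty")
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError(f"{what}: non-numeric entries")
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{what}: non-finite entries")
    if np.any(values < 0):
        i, j = np.argwhere(values < 0)[0]
        raise ValueError(f"{what}: negative count at row {i}, column {j}")
    if not np.allclose(values, np.round(values)):
        i, j = np.argwhere(~np.isclose(values, np.round(values)))[0]
        raise ValueError(f"{what}: fractional count at row {i}, column {j}")
    return np.asarray(np.round(values), dtype=np.int64)


def _check_gene_ids(gene_ids: list[str], n_cols: int, what: str) -> list[str]:
    gene_ids = [str(g) for g in gene_ids]
    if len(gene_ids) != n_cols:
        raise ValueError(f"{what}: {len(gene_ids)} gene ids for {n_cols} columns")
    if len(set(gene_ids)) != len(gene_ids):
        seen, dup = set(), None
        for g in gene_ids:
            if g in seen:
                dup = g
                break
            seen.add(g)
        raise ValueError(f"{what}: duplicate gene id {dup!r}")
    return gene_ids


@dataclass
class BulkCountMatrix:
    """Raw bulk RNA-seq counts, individuals x genes."""

    values: np.ndarray
    individual_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = _validate_counts(self.values, "bulk counts")
        self.individual_ids = [str(s) for s in self.individual_ids]
        if len(self.individual_ids) != self.values.shape[0]:
            raise ValueError(
                f"bulk counts: {len(self.individual_ids)} individual ids for "
                f"{self.values.shape[0]} rows"
            )
        self.gene_ids = _check_gene_ids(self.gene_ids, self.values.shape[1], "bulk counts")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, gene_ids: list[str]) -> "BulkCountMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        cols = [idx[g] for g in gene_ids]
        return BulkCountMatrix(self.values[:, cols], list(self.individual_ids), list(gene_ids))


@dataclass
class SingleCellCountMatrix:
    """Raw single-cell counts, cells x genes, with per-cell type labels."""

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    cell_type_labels: list[str]

    def __post_init__(self) -> None:
        self.values = _validate_counts(self.values, "single-cell counts")
        self.cell_ids = [str(s) for s in self.cell_ids]
        self.cell_type_labels = [str(s) for s in self.cell_type_labels]
        nx = self.values.shape[0]
        if len(self.cell_ids) != nx:
            raise ValueError(f"single-cell counts: {len(self.cell_ids)} cell ids for {nx} rows")
        if len(self.cell_type_labels) != nx:
            raise ValueError(
                f"single-cell counts: {len(self.cell_type_labels)} labels for {nx} cells"
            )
        if any(lab == "" for lab in self.cell_type_labels):
            raise ValueError("single-cell counts: empty cell-type label")
        self.gene_ids = _check_gene_ids(self.gene_ids, self.values.shape[1], "single-cell counts")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def cell_types(self) -> list[str]:
        """Distinct cell-type labels in lexicographic order."""
        return sorted(set(self.cell_type_labels))

    @property
    def n_cell_types(self) -> int:
        return len(set(self.cell_type_labels))

    def subset_genes(self, gene_ids: list[str]) -> "SingleCellCountMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        cols = [idx[g] for g in gene_ids]
        return SingleCellCountMatrix(
            self.values[:, cols],
            list(self.cell_ids),
            list(gene_ids),
            list(self.cell_type_labels),
        )

    def filter_genes(self, min_total_count: int = 0, min_cells_expressed: int = 0):
        """Drop genes by total count and number of expressing cells.

        Both thresholds default to 0, i.e. no filtering; filtering rules vary
        per dataset so nothing is dropped silently.
        """
        totals = self.values.sum(axis=0)
        n_expressed = (self.values > 0).sum(axis=0)
        keep = (totals > min_total_count) & (n_expressed >= min_cells_expressed)
        kept = [g for g, k in zip(self.gene_ids, keep) if k]
        if not kept:
            raise ValueError("gene filter removed every gene")
        logger.info("gene filter kept %d of %d genes", len(kept), self.n_genes)
        return self.subset_genes(kept)


@dataclass
class SignaturePanel:
    """Cell-type x gene expression panel.

    Holds either the empirical reference panel H (per-gene fractions of
    single-cell reads attributable to each type; informative gene columns sum
    to 1) or a fitted signature W on the expression scale.
    """

    values: np.ndarray
    cell_type_labels: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("signature panel must be 2-D")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("signature panel entries must be finite and non-negative")
        self.cell_type_labels = [str(s) for s in self.cell_type_labels]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if len(self.cell_type_labels) != self.values.shape[0]:
            raise ValueError("signature panel: label/row mismatch")
        if len(self.gene_ids) != self.values.shape[1]:
            raise ValueError("signature panel: gene/column mismatch")

    @property
    def n_cell_types(self) -> int:
        return self.values.shape[0]


def align_genes(
    bulk: BulkCountMatrix, sc: SingleCellCountMatrix
) -> tuple[BulkCountMatrix, SingleCellCountMatrix]:
    """Restrict both matrices to their shared genes, in a common column order.

    Gene identifiers are matched verbatim (no case folding or prefix
    stripping); the shared set keeps the bulk matrix's column order so the
    operation is idempotent. Raises if the intersection is empty.
    """
    sc_set = set(sc.gene_ids)
    shared = [g for g in bulk.gene_ids if g in sc_set]
    if not shared:
        raise ValueError(
            "no shared gene identifiers between bulk and single-cell data; "
            "harmonize identifiers (e.g. map transcripts to a common gene "
            "annotation) before deconvolution"
        )
    logger.info(
        "align_genes: %d shared genes (bulk %d, single-cell %d)",
        len(shared), bulk.n_genes, sc.n_genes,
    )
    return bulk.subset_genes(shared), sc.subset_genes(shared)
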