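# momf

Cell-type deconvolution of bulk RNA-seq data by **M**ulti-**O**mics **M**atrix
**F**actorization: a joint Poisson factorization of a bulk count matrix and a
labeled single-cell RNA-seq count matrix, solved with ADMM.

## The problem

Bulk RNA-seq measures tissue-averaged expression, hiding the cellular
composition of each sample. Given a bulk count matrix **Y** (n<sub>y</sub>
individuals × p genes) and a single-cell count matrix **X** (n<sub>x</sub>
cells × p genes) with known per-cell type labels, `momf` estimates the
proportion of each of C cell types in every bulk individual. It works
directly on raw counts — no CPM/log normalization, which distorts sparse
count data (a single read at library depth 3000 already jumps to
log₂ 334 ≈ 8.4 on the logCPM scale while zeros stay at 0).

## The model

Both matrices are Poisson with low-rank rates sharing one signature matrix
**W** (C × p, cell-type-specific expression):

    Y_ij ~ Poisson((Ψ W)_ij)          Ψ : n_y × C   cell-type proportions
    X_kj ~ Poisson((Λ W)_kj)          Λ : n_x × C   per-cell loadings

**W** is anchored at the empirical reference panel **H**, where
h<sub>cj</sub> is the fraction of all single-cell reads for gene j that come
from cells of type c (columns sum to 1). The solver minimizes an augmented
Lagrangian combining the two Poisson KL-divergence fits, the W−H anchor, and
non-negativity constraints on Ψ and Λ via split variables, using exact ADMM
block updates (closed-form Poisson-rate roots, ridge normal equations,
orthant projections, dual ascent). Estimated proportions are the rows of the
non-negative factor Ψ⁺ rescaled to the unit simplex. See
[docs/methods.md](docs/methods.md) for the full objective, update equations
and numerical choices.

## Worked example

Simulate a three-cell-type benchmark (2,000 genes, 100 bulk individuals, 300
labeled cells, signature entries Gamma(2, 2), Dirichlet proportions, Poisson
counts) and deconvolute it:

```python
import momf

ds = momf.simulate_dataset(C=3, p=2000, ny=100, nx=300, seed=101)
res = momf.fit_momf(ds.bulk, ds.sc, rho=2.0, iterations=1000, seed=11)
print(res.summary())
rep = momf.compare_proportions(res.proportions, ds.true_proportions)
print(f"recovery vs truth: R = {rep.pearson_r:.4f}, MSE = {rep.mse:.4f}")
```

prints

```
MOMF deconvolution results
============================================================
individuals: 100    cell types: 3    genes: 2000
rho: 2.0    iterations run: 1000    converged: False
seed: 11    sigma^2 (panel uncertainty): 2.05e-05
------------------------------------------------------------
cell type                    mean       sd      min      max
type1                      0.3357   0.2283   0.0000   0.8841
type2                      0.3758   0.2405   0.0070   0.9316
type3                      0.2885   0.2221   0.0000   0.7949
------------------------------------------------------------
final objective: 584307
final primal residuals: mu_y=0.0116  mu_x=0.136  Psi=0.0112  Lambda=0.0948  W=9.6

recovery vs truth: R = 0.9979, MSE = 0.0002
```

Each proportion row is one bulk individual's estimated composition (rows sum
to 1); `R` is the flattened Pearson correlation between the estimated and
generating proportions and `MSE` their mean squared difference. The
`converged: False` flag means the fixed iteration budget stopped the run
before every ADMM constraint residual crossed the tolerance — the slow
direction is the W−H anchor — while the proportion estimates themselves are
already stable (see the methods note on stopping).

The same workflow is available from a shell:

```sh
momf simulate --cell-types 3 --genes 2000 --individuals 100 --cells 300 --seed 101 --out sim/
momf fit --bulk sim/bulk.csv --sc sim/sc.csv --labels sim/labels.csv \
         --rho 2 --iters 1000 --seed 11 --out fit/
momf evaluate --estimated fit/proportions.csv --truth sim/truth_proportions.csv
```

`momf fit` accepts CSV/TSV or MatrixMarket input (`.mtx` plus
`<stem>_rows.txt` / `<stem>_cols.txt` sidecars), an explicit
`--orientation`, optional gene filters (`--min-total-count`,
`--min-cells-expressed`), and a YAML `--config` whose values are overridden
by explicit flags. Outputs are `proportions.csv`, `loadings.csv`,
`signature.csv` and `diagnostics.json`.

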