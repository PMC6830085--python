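# Methods

## Model

`momf` models raw read counts from both assays as Poisson with shared
low-rank structure:

    Y_ij ~ Poisson(mu^y_ij),   mu^y = Psi W      (bulk: n_y individuals x p genes)
    X_kj ~ Poisson(mu^x_kj),   mu^x = Lambda W   (single cell: n_x cells x p genes)

* **Psi** (n_y × C) carries each bulk individual's cell-type composition;
* **Lambda** (n_x × C) carries each cell's loading on its type;
* **W** (C × p) is the cell-type-specific expression signature shared by the
  two assays, which is what lets the bulk and single-cell data constrain
  each other within a single fit rather than being processed in two stages
  (signature estimation, then regression).

Modelling counts directly keeps the Poisson mean–variance coupling that
normalized/log-transformed pipelines discard; any over-dispersion beyond
Poisson is absorbed by the splitting below, in which the rate matrices are
free blocks penalized toward their factorizations rather than equal to them
at every iteration.

The signature is tied to the data through the empirical **reference panel**
H built from the labeled cells,

    h_cj = ( sum_{k in Omega_c} X_kj ) / ( sum_k X_kj ),

the fraction of all single-cell reads for gene j contributed by type c
(Omega_c = cells labeled c). Columns of H sum to 1 for every gene with any
single-cell signal. This formula weights cells by their sequencing depth; a
deeper cell pulls its type's fraction up. That is deliberate (it is the
maximum-likelihood allocation of reads) but sensitive to the cell-type
abundance of the reference, so `panel_mode="mean"` offers the
depth-normalized per-type mean profile (renormalized per gene column) as an
alternative. Genes with zero single-cell total are uninformative and get the
uniform column 1/C, keeping shapes aligned with the bulk matrix instead of
silently dropping genes.

The scatter of individual cells around their type's panel value is
summarized by a single pooled variance sigma^2 of the per-cell normalized
contributions X_kj / sum_k X_kj about their within-type mean h_cj/|Omega_c|
(unbiased, pooled over informative genes and all types with >= 2 cells).
It is reported as a diagnostic of panel uncertainty; with
`sigma_weighted=True` it also rescales the W-anchor penalty to
rho_W = rho / max(sigma^2, 1e-8), so a tighter panel pulls W harder. The
default leaves the anchor at the single penalty rho because the plain
objective needs no extra assumption about how uncertainty should enter.

## Optimization

The fit minimizes the augmented Lagrangian

    L = D(Y|mu^y) + D(X|mu^x)
      + <U_y,  mu^y - Psi W>          + (rho/2)||mu^y - Psi W||_F^2
      + <U_x,  mu^x - Lambda W>       + (rho/2)||mu^x - Lambda W||_F^2
      + <U_Psi, Psi - Psi+>           + (rho/2)||Psi - Psi+||_F^2
      + <U_Lam, Lambda - Lambda+>     + (rho/2)||Lambda - Lambda+||_F^2
      + <U_W,  W - H>                 + (rho_W/2)||W - H||_F^2

with D(y|x) = y log(y/x) − y + x the elementwise KL divergence (the Bregman
divergence matching the Poisson log-likelihood), Psi+ and Lambda+ the
non-negative split copies, and U_* dual variables. One ADMM sweep applies,
in order:

1. **Rates.** Minimizing L in each mu entry gives the quadratic
   rho*mu^2 + (1 + U − rho*a)*mu − y = 0 (a = the matching entry of Psi W or
   Lambda W); the update takes its positive root, which satisfies the
   stationarity condition 1 − y/mu + U + rho(mu − a) = 0 exactly.
2. **Factors.** Psi ← (mu^y Wᵀ + Psi+ + (U_y Wᵀ − U_Psi)/rho)(W Wᵀ + I)⁻¹
   and the analogous Lambda update — the exact ridge normal equations of L;
   (W Wᵀ + I) is always invertible. Note the data enter only through the KL
   term, which the rate update already handled, so these equations contain
   mu, not Y or X, and the C×C inverse applies from the right (it must, by
   shape).
3. **Signature.** W ← (PsiᵀPsi + LambdaᵀLambda + w·I)⁻¹ (Psiᵀmu^y +
   Lambdaᵀmu^x + w·H + (PsiᵀU_y + LambdaᵀU_x − U_W)/rho), w = rho_W/rho.
4. **Projection.** Psi+ = max(Psi + U_Psi/rho, 0), likewise Lambda+ — the
   exact minimizer of L over the non-negative orthant. Exact zeros stay
   zero (unambiguous tie-break, noted for bit-reproducibility).
5. **Dual ascent** on all five residuals, including U_Psi and U_Lambda;
   without those two the non-negativity constraints would never bind at
   convergence.

Each update is verified in the test suite against an independent oracle:
central-difference gradients of L, a generic linear solver, exhaustive
active-set enumeration for the projection, and (end to end) an L-BFGS-B
multistart on a tiny instance.

At a fixed point the dual ascent enforces mu^y = Psi W, mu^x = Lambda W,
Psi = Psi+ ≥ 0, Lambda = Lambda+ ≥ 0 and W = H: the limit problem is the
KL fit of Y and X onto the panel under non-negativity, and the anchoring
variance only shapes the path W takes toward H. This is confirmed
empirically on small instances, where the converged objective matches a
20-restart bound-constrained optimizer for exactly that constrained problem
to well under 1%.

**Proportions.** Rows of Psi+ absorb sequencing depth, so the reported
composition is each row divided by its sum (simplex projection by scaling).
A row summing to zero — an individual with no attributable signal — falls
back to the uniform 1/C with a logged warning. The un-normalized Psi+ is
kept on the results object for users who prefer a different normalization
(e.g. cell-size corrections, which this model does not attempt).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `rho` | 2.0 | ADMM penalty; one value for all constraint blocks (unitless) |
| `iterations` | 5000 | hard cap on ADMM sweeps |
| `tol` | 1e-6·‖Y‖_F | early stop when every primal residual is below this |
| `seed` | 0 | seeds the random simplex initialization of Psi |
| `panel_mode` | `"counts"` | H as read fractions, or `"mean"` per-type profile |
| `sigma_weighted` | False | rescale the W anchor by 1/sigma^2 |
| `trace_every` | 25 | iterations between objective/residual recordings |

Initialization exploits the known structure: W⁰ = H, Lambda⁰ one-hot on the
cell labels scaled by each cell's depth relative to its type mean, Psi⁰
uniform on the simplex (the seeded component), mu⁰ = max(counts, 0.5),
duals zero.

## Stopping, and why the benchmark uses 1000 iterations

The constraint blocks equilibrate at very different speeds. The rate and
projection residuals fall within a few hundred sweeps, and the proportion
estimates are already stable there. The W = H block is the stiff direction:
its dual must grow to balance a count-scale gradient (the panel lives on a
reads-fraction scale, the data on a counts scale), which takes far longer
than the default budget, and — as is known for ADMM with a fixed penalty on
nonconvex problems — the long-horizon dual equilibration is not guaranteed
to converge monotonically: on desk-scale problems the W residual drifts and
can oscillate after roughly 1500 sweeps before settling, transiently
degrading the estimates, although on small instances the iteration does
reach the constrained fixed point. The benchmark protocol therefore runs
1000 sweeps (2000 for the two-seed stability comparison), inside the window
where the rate residuals have flattened; the residual traces on the results
object make this visible for any run, and the `converged` flag reports
honestly whether the tolerance was reached. Users fitting much larger
problems can simply raise the cap; the per-sweep cost is a handful of
n·C·p matrix products.

## Numerical conventions

* KL terms use 0·log 0 = 0 (a zero count contributes exactly its rate);
  rates are floored at 1e-12 inside logarithms and after the rate update,
  which also covers the boundary case y = 0 where the quadratic root
  collapses to zero.
* The linear solves use `numpy.linalg.solve` on symmetric positive-definite
  C×C systems; no explicit inverses.
* Proportion rows are guaranteed to sum to 1 within 1e-8 and entries to lie
  in [0, 1]; tables are written with sorted cell-type columns and matched by
  label, never by position, when compared.
* Renaming cell types permutes the proportion columns identically up to
  solver tolerance, not bitwise: the random Psi⁰ is drawn per sorted column
  position, so a label permutation changes which draw a type receives; the
  data-driven solution is label-equivariant, the initialization is not.

## Simulator

`simulate_dataset` draws W_cj ~ Gamma(shape 2, rate 2) (mean 1; "rate" is
the inverse scale), per-individual proportions from a flat Dirichlet (or a
user-supplied matrix, e.g. compositions estimated from a real cohort),
scales them by `depth_scale` (default 50, giving realistic bulk counts of
~50·mean(W) per gene), assigns cells to types in near-equal blocks with a
single Gamma(2, 2) magnitude each (expected single-cell library ~p·mean(W),
a realistic UMI depth), and samples Y and X from Poisson at their expected
values. `default_benchmark_grid()` lists the benchmark configurations:
full-scale runs at 10,000 genes for C ∈ {2, 3, 5} (590 individuals, 359
cells — the dimensions of the colorectal-cancer cohorts such compositions
are typically estimated from) and desk-scale variants (2,000 genes, 100
individuals, 100·C cells) flagged `scaled_down`, sized to fit in minutes on
one CPU.

What the simulator does **not** emulate: over-dispersion (negative-binomial
noise), dropout beyond Poisson sparsity, batch effects between the bulk and
single-cell assays, shared-individual structure, or unequal/correlated
cell-type abundances in the reference. Recovery results on this generator
therefore demonstrate correctness of the estimator under its own model
(identifiability, solver quality, calibration of the panel anchor), not
robustness to the misspecifications real cohorts bring; the flat-Dirichlet
mixing is also better conditioned than compositions estimated from real
tumors, so simulated accuracy at C = 5 is appreciably higher than what
should be expected on tissue data.

## Limitations

* Cell-type labels for the reference are required; unlabeled references
  must be clustered/annotated upstream.
* C is fixed by the labels; there is no model selection over C.
* The Poisson model has no explicit over-dispersion parameter; severely
  over-dispersed data will widen the rate residuals rather than the
  reported uncertainty (the fit reports no standard errors on proportions).
* The count-weighted panel is sensitive to reference composition; use
  `panel_mode="mean"` when the reference's cell-type abundances are
  arbitrary.
* Fixed-penalty ADMM carries no global convergence guarantee on this
  nonconvex problem; monitor the residual traces for long runs.
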