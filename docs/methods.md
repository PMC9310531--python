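# Methods

## Model

`lmmgmm` fits a linear mixed model for a continuous outcome measured on $n$
individuals with multi-layer omics predictors grouped into $R$ regions
(genes or pathways):

$$
Y = X_d\beta_d + \sum_{i=1}^{R} E_i\gamma_i
  + \sum_{i=1}^{R} g_i + \sum_{i=1}^{R} m_i + \sum_{i=1}^{R} o_i + \epsilon ,
$$

where $X_d$ are demographic covariates (an intercept is always added),
$E_i$ is the per-region expression value with fixed effect $\gamma_i$, and
$g_i \sim N(0, K_{g,i}\sigma^2_{g,i})$,
$m_i \sim N(0, K_{m,i}\sigma^2_{m,i})$,
$o_i \sim N(0, (K_{g,i}\circ K_{m,i})\,\sigma^2_{\mathrm{int},i})$ are
region-level random effects for the genomic layer, the methylation layer
and (optionally) their Hadamard-product interaction;
$\epsilon \sim N(0, \sigma_0^2 I)$.  Expression enters the fixed part
because it is summarised one value per region, where a one-dimensional
random effect would be wasteful.

Kernels default to the linear (gBLUP) convention
$K = X_s X_s^\top / p$ with column-standardized features $X_s$ (train-learned
mean/scale, reapplied verbatim to test samples; constant columns are
centered only).  Standardization makes the $\sigma^2$ comparable across
regions with different feature counts and feature scales.  Gaussian
($\exp(-\lVert x-x'\rVert^2/(p\,h))$, bandwidth $h$, default 1) and
polynomial ($(1+\langle x,x'\rangle/p)^d$, default degree 2) kernels are
available for nonlinear effects.  Kernel order is deterministic — genomic
regions in annotation order, then methylation, then interactions — so
variance-component vectors are reproducible.

## Estimation

Parameters are estimated by alternating two convex problems until the
maximum relative parameter change falls below `outer_tol` (default 1e-4,
at most `outer_max_iter` = 50 rounds; non-convergence returns the model
with a warning flag rather than raising).

**Variance components (method of moments).**  Given the fixed-effect
residual $Z$, the components solve

$$
\min_{\sigma^2 \ge 0}\;
\tfrac12\bigl\lVert ZZ^\top - \textstyle\sum_k K_k\sigma_k^2 - \sigma_0^2 I
\bigr\rVert_F^2
+ \lambda_1 \textstyle\sum_k \sigma_k^2 ,
$$

with $\sigma_0^2$ unpenalized.  Because the loss is quadratic, the problem
reduces to non-negative penalized least squares on the Gram matrix
$C_{jk} = \langle K_j, K_k\rangle_F$ and moment vector $b_k = Z^\top K_k Z$.
$C$ is computed once per fit; each solve is cyclic projected coordinate
descent at $O(K^2)$ per sweep (tolerance 1e-8, max 10 000 sweeps), never
touching the $n\times n$ residual inside the loop — this is what makes many
random effects affordable where REML is not.  Inactive components are exact
zeros (the update is a projected soft shrink), so "selected region" needs
no epsilon threshold.  For linear kernels the quadratic forms
$Z^\top K Z$ are evaluated through the low-rank factors
($\lVert F^\top Z\rVert^2$ with $K = FF^\top$;
$\lVert F_g^\top \mathrm{diag}(Z) F_m\rVert_F^2$ for interactions).

**Fixed effects (penalized GLS).**  With $\Sigma = \sum_k K_k\hat\sigma_k^2
+ \hat\sigma_0^2 I$ held fixed, maximizing the penalized Gaussian
log-likelihood in $(\beta_d,\gamma)$ is a lasso on whitened data
($L^{-1}$ for the Cholesky factor of $\Sigma$; the $\log\lvert\Sigma\rvert$
term is constant in this step and dropped).  The unpenalized $\beta_d$ is
profiled out exactly, leaving a lasso in $\gamma$ on the whitened data
projected off the whitened covariates, solved by coordinate-wise
soft-thresholding on the projected Gram matrix (tolerance 1e-10).
Expression columns are standardized before penalization so $\lambda_2$ acts
evenly; coefficients are reported on the original scale with exact zeros
preserved.  $\sigma_0^2$ is floored at $10^{-6}\,\mathrm{var}(Y)$ before
factorization (noiseless fits can return $\sigma_0^2 = 0$); a small jitter
ladder guards the Cholesky.

**Initialization and order.**  $\beta_d$ starts at OLS, $\gamma = 0$; each
round updates the variance components first, then the fixed effects.

**Penalty selection.**  Grids default to 7 log-spaced points per penalty
from a data-derived maximum (the smallest value that nulls every term) down
to $10^{-3}$ times it.  `internal_validation` holds out 20% of the training
samples (seeded), fits every grid pair on the remainder with warm starts,
scores validation MSE, and refits the winner on the full training set; ties
break toward larger penalties.  Grid-selection fits use a looser outer
tolerance (1e-3) than the final refit, since they only rank candidate
pairs.  The tuning procedure is a package choice — configurable and logged —
as is everything about the grids.

**Prediction** is the conditional mean under the fitted Gaussian model:
$\hat Y_p = X_{d,p}\hat\beta_d + E_p\hat\gamma +
\Sigma_{po}\Sigma_{oo}^{-1}(Y - X_d\hat\beta_d - E\hat\gamma)$, with
$\Sigma_{po}$ assembled from the cross-kernels of strictly positive
components only, using the training-estimated covariance (standard BLUP;
no re-estimation on test data).  Because centered linear kernels annihilate
the constant vector, the intercept carries the outcome mean and the
random-effect part smooths mean-zero structure.

## Synthetic data

The simulator generates cohorts with $R$ regions, each carrying `p_g` = 30
biallelic dosages (Binomial(2, MAF), MAF ~ Uniform(0.05, 0.5) per SNP,
monomorphic columns redrawn), `p_m` = 30 methylation levels and one
expression value, methylation and expression Uniform(0, 1).  The first
`n_assoc` = 3 regions are associative.  Outcomes are drawn from the exact
multivariate normal the model implies, with components activated by one of
eight disease models (expression-only, genomic-only, methylation-only,
interaction-only, and their combinations); the interaction-only model draws
directly from the Hadamard-kernel covariance and so has no marginal
main-effect variance.  Kernels use the same standardized linear convention
as the estimator.

What it does **not** emulate: linkage disequilibrium within regions
(genotype columns are i.i.d.; the outcome law conditions on realized
kernels, so this changes kernel spectra but not the generative model),
methylation beta-value biology, population structure/relatedness, and
covariate effects (simulated cohorts have no demographic covariates).
Passing tests therefore demonstrate correctness of the estimator under its
own model assumptions, not robustness to real-data artifacts.

**Effect sizes.**  Defaults live in `src/lmmgmm/data/scenario_effects.json`
and were fixed once: residual variance $\sigma_0^2 = 2$ and total
associative signal 2.65, so the associative share of $\mathrm{var}(Y)$ is
~0.57.  In the three-layer scenario that splits as $\gamma_i = 2$ per
associative region (expression contributes $3\cdot 4/12 = 1.0$) and
$\sigma_{g,i}^2 = \sigma_{m,i}^2 = 0.275$ (1.65); the seven disease models
reallocate the same 2.65 budget evenly across their active layers.  Two
consequences worth knowing: (i) the best achievable test Pearson under this
budget is ~0.65 at $n = 500$, $R = 10$ (true-parameter BLUP), not
$\sqrt{0.57} = 0.755$, because the random-effect part is only partially
predictable at finite $n$; (ii) the interaction-only model is intentionally
hard — the Hadamard product of standardized kernels from independent layers
is close to the identity at $p = 30$, so its variance component is nearly
confounded with noise and selection sensitivity is intrinsically limited at
this effect size.

## Baseline

The kriging comparator pools all features of each layer into one
whole-layer standardized linear kernel, mixes layers with equal weights,
models $Y \sim N(\mu 1, \tau^2(S + \delta I))$, estimates $(\tau^2,\delta)$
by profile likelihood on a 41-point log grid in $\delta \in [10^{-4},10^4]$
(one eigendecomposition, then $O(n)$ per grid point), and predicts
$\mu + S_{po}(S_{oo}+\delta I)^{-1}(Y-\mu)$.  It selects no variables.
This is a from-scratch implementation of the standard multi-omic kriging
recipe, not a wrapper around any existing package.

## Experiment scale

The replicated-scenario runner derives per-replicate seeds from a base seed
(`SeedSequence`), simulates, splits 70/30, fits, and reports means with
Monte-Carlo standard errors; failed replicates are logged and counted.
Desk-scale problem sizes used by the shipped experiments: Scenario I
(noise-region sweep, $n = 500$) at 100 replicates for $R = 10$ and 20 for
$R = 100$; Scenario II ($R = 50$) at 30 replicates for the methylation-only
and interaction-only models; `scripts/acceptance.py` uses 60/20/30/30.
Full-scale runs are available through `lmmgmm reproduce-scenario --reps`.

## Numerical choices and edge cases

- Convergence metric: $\max_\theta |\theta^{t+1}-\theta^t|/(1+|\theta^t|)$.
- Zero kernels (constant features) are fixed at $\sigma^2 = 0$ with a warning.
- Degenerate residual $Z = 0$ yields all-zero components; the $\sigma_0^2$
  floor keeps $\Sigma$ SPD downstream.
- Train/test splitting shuffles the canonically sorted sample ids, so the
  partition is invariant to input row order.
- Sample alignment across files is by id intersection with logged drops;
  missing values are rejected, never imputed.

## Known limitations

Continuous outcomes only (no GLMM extension); no screening rules for
ultra-high-dimensional regions; kernels are materialized densely
($O(Rn^2)$ memory); expression must be one column per region; the
multi-probe-per-pathway case is rejected rather than guessed at.
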