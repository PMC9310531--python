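# lmmgmm

Penalized multi-kernel linear mixed models for risk prediction from
multi-layer omics data, with variance components estimated by a
method-of-moments (Frobenius-loss) criterion.

## The problem

Risk prediction from genome, methylome and transcriptome data jointly faces
two obstacles: far more predictors than samples, and the fact that most
measured regions are noise.  Mixed-model (gBLUP-style) predictors handle
dimensionality by modelling region-level similarity kernels instead of
per-variant effects, but classical REML estimation becomes computationally
prohibitive with many random effects, and without selection the noise
regions dilute the kernels and degrade prediction.

`lmmgmm` addresses both.  The outcome is modelled as

    Y = X_d β_d + Σ_i E_i γ_i + Σ_i g_i + Σ_i m_i + Σ_i o_i + ε,

with one random effect per region per omics layer,
g_i ~ N(0, K_{g,i} σ²_{g,i}), m_i ~ N(0, K_{m,i} σ²_{m,i}), an optional
Hadamard-product interaction kernel o_i ~ N(0, (K_{g,i}∘K_{m,i}) σ²_{int,i}),
per-region expression as penalized fixed effects γ, and ε ~ N(0, σ₀² I).
Estimation alternates two convex steps:

1. **variance components** minimize
   ½‖ZZᵀ − Σ_k K_k σ²_k − σ₀² I‖²_F + λ₁ Σ_k σ²_k over σ² ≥ 0
   (residual variance unpenalized) — a non-negative penalized least-squares
   problem on Frobenius inner products, solved by projected coordinate
   descent in O(K²) per sweep;
2. **fixed effects** maximize the L1-penalized Gaussian log-likelihood at
   fixed Σ — a lasso on whitened data with unpenalized covariates.

Both penalties produce exact zeros, so the strictly positive components
*are* the selected regions.  Prediction for new samples is the conditional
(BLUP/kriging) mean Σ_po Σ_oo⁻¹ applied to the training residual plus the
fixed part.  A whole-layer kriging baseline without selection, a synthetic
multi-omics simulator with known ground truth, and a replicated-scenario
runner are included.  See `docs/methods.md` for the full model account.

Intended users: statistical geneticists and biostatisticians evaluating
multi-omics prediction methods, and anyone needing a fast
variance-component selector over many kernels.

## Worked example

Simulate a 300-sample cohort with 10 regions (3 associative, all three
layers active), fit, and predict:

```
$ lmmgmm simulate --n 300 --regions 10 --seed 11 --out demo/data
wrote n=300, R=10 dataset to demo/data

$ lmmgmm fit --data demo/data --seed 1 --out demo/model.npz
fitted: lambdas=(365.430632, 0.029588), selected={"expression": ["region_01", "region_02", "region_03", "region_04", "region_05", "region_06", "region_07", "region_08", "region_09", "region_10"], "genomic": ["region_01", "region_02", "region_03"], "methylation": ["region_01", "region_02", "region_03", "region_04", "region_05", "region_09"], "interaction": []}

$ lmmgmm predict --model demo/model.npz --data demo/data --out demo/pred.tsv
wrote 300 predictions to demo/pred.tsv

$ lmmgmm evaluate --predictions demo/pred.tsv --data demo/data
pearson=0.8992 mse=1.1710
```

The fit line reports the penalty pair chosen by internal validation and the
selected regions per layer.  The genomic layer recovers exactly the three
truly associative regions; methylation keeps them plus three false
positives; the chosen λ₂ is small, so all expression columns stay in the
fixed part (their three true effects dominate the coefficients).  Every
unselected variance component is exactly zero.  The in-sample Pearson of
0.90 reflects the BLUP smoother; out-of-sample accuracy is what the
scenario runner measures on held-out 30% splits.

The same pipeline is callable as a library: `lmmgmm.simulate_dataset`,
`lmmgmm.fit`, `lmmgmm.predict`, `lmmgmm.kriging_baseline`,
`lmmgmm.run_scenario`.

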