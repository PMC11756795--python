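# transptlr

Robust transfer learning for high-dimensional linear regression with
t-distributed errors.

## The problem

Gene-expression studies often need to fit a sparse linear model on a small
*target* dataset (say, one brain tissue) while related *source* datasets
(other tissues) are plentiful but systematically different. Two things go
wrong with the obvious approaches: pooling everything ignores between-source
heterogeneity, and expression data are heavy-tailed and outlier-prone, which
breaks least-squares-based estimators. `transptlr` addresses both at once:

- **Robust fitting (PtLR).** The l1-penalized linear model
  `y_i = x_i'β + ε_i` with `ε_i ~ t(0, σ², ν)` is fitted by an EM algorithm
  on the gamma-normal representation of the t-distribution: latent precision
  weights `τ_i = (ν+1)/(ν + r_i²/σ²)` down-weight outlying observations, the
  β-update is a weighted lasso solved by coordinate descent, σ² has a
  closed-form update, and the degrees of freedom ν are estimated from the
  data (so each dataset can have its own tail weight).
- **Three-step transfer.** For each transferable source *s*: (1) fit β̂⁽ˢ⁾
  on the source; (2) estimate the sparse contrast δ̂⁽ˢ⁾ = argmax
  L(β̂⁽ˢ⁾+δ; target) − λ‖δ‖₁ on the target; (3) jointly maximize
  L(β; target) + Σₛ L(β − δ̂⁽ˢ⁾; source_s) − λ‖β‖₁ over β, each dataset
  keeping its own (σ², ν). Every penalty level is chosen by 5-fold
  cross-validation.
- **Transferable-source detection.** The target is split in half; for every
  source the three-step estimator is run on (training half, source) and
  compared with the target-only fit by validation log-likelihood under a
  common scale: `T̂_s = L(β̂₀) − L(β̂_s)`. Sources with
  `T̂_s ≤ t·max(|L(β̂₀)|, 0.01)` (default threshold t = 0.1) are kept,
  guarding against negative transfer from unrelated sources.

Gaussian-error counterparts (PNLR / Trans-PNLR, i.e. the standard lasso and
its transfer variant) are provided as baselines, and a simulation engine
generates the multi-source study designs (AR(1)-correlated predictors,
sparse coefficients, four error families: normal, t₅, contaminated normal,
skew-t) with full metrics (estimation error, prediction error,
variable-selection precision/recall).

## Worked example

```python
import numpy as np
import transptlr as tp

# one replication of the simulation design: n0=150 target rows, 10 sources
# of 100 rows each, p=500, 16 true coefficients of 0.5, t5 errors, all ten
# sources transferable with small coefficient shifts
cfg = tp.SimulationConfig(error_family="t", n_transferable=10, seed=5)
target, sources, truth = tp.gen_multidata(cfg)

# target-only robust fit with cross-validated penalty
lam, fit, _ = tp.cv_select_lambda(target, tp.desk_emconfig(), family="t")
print("PtLR:     nu=%.1f  est.err=%.3f  precision=%.2f" % (
    fit.nu, np.sum((fit.beta - truth.beta0) ** 2),
    tp.precision_recall(fit.beta, truth.beta0)[0]))

# full pipeline: detect transferable sources, then three-step transfer
res = tp.trans_fit(target, sources,
                   tp.TransferConfig(em=tp.desk_transfer_emconfig(), seed=5))
print("detected: %s" % res.detected_set)
print("TransPtLR: est.err=%.3f  precision=%.2f" % (
    np.sum((res.beta_TL - truth.beta0) ** 2),
    tp.precision_recall(res.beta_TL, truth.beta0)[0]))
```

Output:

```
PtLR:     nu=100.0  est.err=0.426  precision=0.73
detected: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
TransPtLR: est.err=0.103  precision=1.00
```

Detection keeps all ten genuinely transferable sources, and borrowing them
cuts the squared estimation error ‖β̂ − β‖₂² by roughly 4× while removing
every false positive from the selected support. (At a strongly shrunk
cross-validated penalty the residuals are dominated by Gaussian-shaped
shrinkage bias, so ν̂ sits at its near-Gaussian upper bound; unpenalized
fits recover the true ν ≈ 5 — see the parameter-recovery test.)

A command-line interface mirrors the library: `transptlr fit`,
`transptlr transfer`, `transptlr simulate`, and `transptlr benchmark`
(see `transptlr --help`).

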