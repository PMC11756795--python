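# Methods

## Model

Each dataset (one target, S sources) follows a sparse linear model
`y_i = x_i'β⁽ˢ⁾ + ε_i` with errors from a scaled t-distribution
`t(0, σ², ν)`. The t family is handled through its gamma-normal hierarchy:
conditional on a latent precision multiplier `τ_i ~ Gamma(ν/2, ν/2)`,
`y_i | τ_i` is normal with variance `σ²/τ_i`. The conditional expectations
are available in closed form,

    E[τ_i | data]     = (ν+1) / (ν + r_i²/σ²),        r_i = y_i − x_i'β,
    E[log τ_i | data] = ψ((ν+1)/2) − log((ν + r_i²/σ²)/2),

so maximum penalized likelihood is computable by EM: observations with large
residuals receive small weights `τ̂_i`, which is what makes the fit robust to
outliers and heavy tails. With `ν → ∞` the weights become 1 and the model is
the Gaussian linear model; the Gaussian baseline (PNLR) is literally the same
code path with unit weights.

## Penalty calibration (a deliberate reformulation)

The textbook objective `L(β, σ², ν) − λ‖β‖₁` is **degenerate** whenever
p ≥ n: an interpolating β exists, so residuals can be driven to zero,
σ² → 0, and the log-likelihood to +∞ while the penalty stays bounded. Both
the t-family EM and the Gaussian alternation genuinely cascade into this
solution (hundreds of active coefficients, σ² ≈ 1e-20) for most of the λ
path at the study scale (n₀ = 150, p = 500).

`transptlr` therefore calibrates the penalty on the weighted-least-squares
scale: the β-step solves

    min_β  ½ Σ_i τ̂_i (σ₀²/σ²_g(i)) r_i²  +  λ‖β‖₁ ,

with λ held fixed on this scale (relative to the likelihood this equals the
penalty λ‖β‖₁/σ₀² at the current target scale σ₀²). Because the E-step
weights τ̂ are bounded, the degenerate cascade cannot occur, the estimator
is equivariant under rescaling of y, and for Gaussian errors the criterion
is exactly the standard lasso (λ comparable to n times a glmnet `alpha`;
verified against scikit-learn's solver in the test suite). Group scales are
floored at 1e-3 of their null variance so cross-group weight ratios stay
finite. `λ_max = max_j |Σ_i x_ij z_i|` and the default grid is 50 log-spaced
values down to 0.001·λ_max (the experiment runner uses shorter desk-scale
grids, below).

## The EM loop

Per iteration: E-step weights at θ^(u−1); β by cyclic coordinate descent
with soft-thresholding on the weighted surrogate (warm-started, a few passes
per reweighting — a generalized-EM step); σ²_g by its weighted MLE
`Σ τ̂ r²/n_g` per dataset; ν_g by the ECME variant — maximizing the observed
per-dataset log-likelihood by golden-section on [1, 100] — because the exact
Q-function root (which the public `m_step_nu` implements and the tests
verify) approaches its fixed point by a crawl of hundreds of iterations when
ν is weakly informed. Convergence is declared when the L1 change of
θ = (β, σ², ν) falls below `tol` (1e-6 by default). After convergence the
returned β is polished by alternating reweighting with full-accuracy
coordinate descent so that the lasso KKT conditions hold at the weights
recomputed from the returned coefficients (certified at 1e-6 relative to
the gradient scale in the tests).

Monotonicity: the β and ν steps never decrease the observed penalized
objective, and with (σ², ν) held fixed — or with λ = 0 — the whole loop is
exact (EC)M(E), which is what the ascent tests assert. The σ² recalibration
step re-scales the effective penalty, so monotonicity of the combined
objective across a full update cycle is not guaranteed termwise; in practice
the fits converge in tens of iterations.

Initialization: β from a Gaussian-lasso fit at the same λ, σ² from its
residual variance, ν = 5. Cross-validation paths are warm-started from the
previous grid point.

## Penalty selection

λ is chosen by 5-fold cross-validation on held-out squared prediction error.
The held-out *log-likelihood* was rejected after measurement: it plugs in the
training-fold σ², which shrinks as the fit overfits, systematically
rewarding smaller λ (selected supports tripled in size). By default the
one-standard-error rule picks the largest λ within one SE of the best score
— the convention of `cv.glmnet`'s `coef()` — with the plain minimizer
available via `cv_rule="min"`. Folds are seeded and reproducible.

## Transfer (three steps) and detection

Step 1 fits each source with its own cross-validated λ. Step 2 estimates the
contrast δ̂⁽ˢ⁾ by a penalized fit on the target with the source prediction as
a fixed offset. Step 3 stacks the target with the offset-corrected sources
(`z = y_s + X_s δ̂⁽ˢ⁾`, shared β, per-dataset σ² and ν — tails differ across
tissues, so nuisance parameters are not pooled) and selects λ by CV over
target rows only.

Detection splits the target into halves by a seeded permutation (⌈n/2⌉
training, the rest validation; the same split serves all sources). For each
source the three-step estimator runs on (training half, source); candidates
are compared by validation log-likelihood `T̂_s = L(β̂₀) − L(β̂_s)` under a
**common** (σ², ν) estimated once from the target-only training fit.
Re-estimating the nuisances per candidate — a natural alternative — was
rejected after measurement: a badly predicting candidate inflates its scale
and drops its ν, flattening its likelihood until even pure-noise sources
outscore the target-only fit. A source is kept when
`T̂_s ≤ t·max(|L(β̂₀)|, 0.01)`, default t = 0.1; the final refit runs the
three steps on the full target with the detected set (step-1 source fits are
cached between detection and refit).

Two properties of this implementation are worth knowing. First, because the
δ̂-correction absorbs mild coefficient shifts, sources perturbed by only
h/100 ∈ {0.1, 0.2} remain *net-beneficial* even when they perturb the true
support, so detection — correctly, by its own validation criterion — retains
them and naive (all-source) transfer performs on par with detected transfer
at these heterogeneity levels. Negative transfer, and rejection by the
detector, appears for grossly shifted or unrelated sources (verified with
shift 1.0 and with pure-noise responses). Second, the t-family and
Gaussian-family *transfer* estimators perform at parity in the heavy-tailed
simulation cells even though the single-dataset robust fit clearly beats the
Gaussian lasso there (contaminated-normal errors especially): in the joint
fit most rows are source rows whose residuals carry δ̂-estimation error on
top of the noise, the shrinkage bias is shared by both families, and the
remaining tail-robustness gain is about the size of the extra
(σ², ν)-estimation variance. The outlier downweighting itself is verifiably
active in the joint fits (per-group ν̂ ≈ 4–7 under contamination, minimum
weights below 0.1).

## Simulation engine

The generator reproduces the study design: target n₀ = 150, S = 10 sources
of n_s = 100, p = 500 predictors drawn from N(0, Σ) with AR(1) correlation
Σ_ij = 0.7^|i−j| (sampled exactly via the Markov construction), target
coefficients 0.5 on the first k = 16 coordinates, per-source shifts of
−h/100 on a random 50-subset H⁽ˢ⁾ of the null coordinates (transferable
sources) plus the full support (non-transferable sources), h ∈ {10, 20}.
Error families: N(0,1); t(0,1,5); the contaminated normal
0.9·N(0,1)+0.1·N(0,10) with per-draw component selection; and a skew-t with
location 0, scale 1, df 5 and slant 1 in the Azzalini parameterization
(sampled as a skew-normal divided by √(χ²₅/5)) — the parameterization is a
choice, and the qualitative conclusions are insensitive to modest variants.
Metrics: squared estimation error ‖β̂−β⁽⁰⁾‖₂², 5-fold mean prediction error
(retraining the full pipeline per fold), and variable-selection
precision/recall of the nonzero pattern (precision of an empty selection is
defined as 0 so averages exist). One root seed spawns independent child
seeds per grid cell and replication.

What the generator does *not* emulate about real expression data: gene-gene
correlation beyond AR(1), batch structure, non-linear regulation, and
feature sets that differ across sources. Passing tests demonstrate correct
behaviour of the estimators under the stated design, not performance on any
particular real dataset.

## Desk-scale settings

Library defaults follow the conventions above (50-point grid, tol 1e-6).
The experiment runner and the acceptance script use documented desk-scale
settings chosen for a single CPU: single-dataset fits a 20-point grid down
to 0.01·λ_max (`desk_emconfig`); the transfer pipeline — which solves ~40
cross-validated sub-problems per replication — a 12-point grid down to
0.02·λ_max with CV-fold EM capped at 30 iterations at tolerance 2e-3 and
final fits at 1e-5 (`desk_transfer_emconfig`). No-transfer cells run 100
replications; transfer cells 25; trend comparisons in the test suite run
8–25 replications with common random numbers across methods (paired
comparisons, which need far fewer replications than independent ones for
the same power).

## Degenerate and edge inputs

Constant predictor columns under standardization are pinned at coefficient
zero and excluded from coordinate descent; all-zero residuals raise a
degenerate-scale error; CV requires at least 5 training rows per fold;
ν updates are bracketed on [1, 100] and the upper bound is reported as
near-Gaussian; λ = 0 with p < n reproduces the unpenalized MLE (checked
against OLS on Gaussian data).

## Known limitations

Only the l1 penalty is supported (no elastic net or l2), there is no
intercept/missing-data handling beyond simple standardization flags, all
sources must share the target's predictor set, and the detection statistic
inherits the variance of a single half-split rather than averaging several
splits. The negative-transfer behaviour discussed above means the detector
should be viewed as a guard against harmful sources rather than a recoverer
of the design's transferable-set labels.
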