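"""Three-step transfer estimation and transferable-source detection.

Step 1 fits each candidate source on its own data; step 2 measures the
coefficient contrast delta between each source fit and the target on target
data; step 3 jointly maximizes the summed penalized likelihood of the target
and the offset-corrected sources. Detection splits the target in half, runs
the three-step estimator with each single source on the training half, and
keeps the sources whose validation log-likelihood does not degrade beyond a
threshold, guarding against negative transfer.

Every sub-problem selects its own penalty by cross-validation on the data it
is fitted to, and each dataset (target and each source) carries its own
scale and degrees of freedom throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _engine
from .data import Dataset
from .ptlr import (
    GAUSSIAN_NU,
    DegenerateScaleError,
    EMConfig,
    TModelFit,
    _e_step_resid,
    _select_lambda_index,
    cv_select_lambda,
    m_step_nu,
    observed_loglik,
)


@dataclass
class TransferConfig:
    """Settings for the transfer pipeline.

    threshold_t scales the tolerated validation log-likelihood loss when
    deciding whether a source is transferable; split_fraction is the share of
    target rows used as the detection training half; `em` parameterizes every
    sub-fit; family selects t or Gaussian errors throughout.
    """

    threshold_t: float = 0.1
    split_fraction: float = 0.5
    seed: int = 0
    em: EMConfig = field(default_factory=EMConfig)
    family: str = "t"

    def __post_init__(self) -> None:
        if self.threshold_t < 0:
            raise ValueError("threshold_t must be nonnegative")
        if not (0 < self.split_fraction < 1):
            raise ValueError("split_fraction must lie in (0, 1)")
        if self.family not in ("t", "gaussian"):
            raise ValueError("family must be 't' or 'gaussian'")


@dataclass
class SourceOffset:
    source_id: int
    delta_hat: np.ndarray
    lambda_delta: float


@dataclass
class TransferResult:
    beta_TL: np.ndarray
    detected_set: list[int]
    stats: pd.DataFrame | None
    offsets: list[SourceOffset]
    source_fits: list[TModelFit]
    target_only_fit: TModelFit
    joint_fit: TModelFit | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        return X @ self.beta_TL


# ---------------------------------------------------------------------------
# stacked multi-dataset fit (Algorithm 2, step 3)
# ---------------------------------------------------------------------------


def _stack(target: Dataset, sources: list[Dataset], offsets: list[SourceOffset]):
    """Row-stack target and offset-corrected sources.

    Source responses are shifted by +x_i' delta_hat so that every group shares
    the common coefficient beta (the source model is beta - delta)."""
    Xs = [target.X]
    zs = [target.y]
    groups = [np.zeros(target.n, dtype=np.int64)]
    for g, (src, off) in enumerate(zip(sources, offsets), start=1):
        if off.delta_hat.shape[0] != src.p:
            raise ValueError("offset dimension mismatch")
        Xs.append(src.X)
        zs.append(src.y + src.X @ off.delta_hat)
        groups.append(np.full(src.n, g, dtype=np.int64))
    X = np.asfortranarray(np.vstack(Xs))
    z = np.concatenate(zs)
    group = np.concatenate(groups)
    return X, z, group


def _run_stacked_em(X, z, group, lam, em: EMConfig, family: str, state,
                    tol, max_iter, track_obj: bool = False,
                    polish: bool = False):
    beta, sigma2, nu = state
    pf = np.ones(X.shape[1])
    active = np.ones(X.shape[1], dtype=np.bool_)
    obj = np.empty(max_iter if track_obj else 1)
    n_iter, converged, status = _engine._em_fit(
        X, z, group, beta, sigma2, nu, lam, pf, active,
        family == "t", em.estimate_nu and family == "t",
        em.nu_bounds[0], em.nu_bounds[1], tol, max_iter,
        em.inner_tol, em.max_pass, obj, track_obj, em.estimate_scale,
        em.cd_passes, polish,
    )
    if status == _engine.STATUS_DEGENERATE_SCALE:
        raise DegenerateScaleError("degenerate scale in joint fit")
    return (beta, sigma2, nu), n_iter, converged


def _init_state(X, z, group, lam, em: EMConfig, family: str):
    G = int(group.max()) + 1
    sigma2 = np.array([max(float(np.mean(z[group == g] ** 2)), 1e-12)
                       for g in range(G)])
    beta = np.zeros(X.shape[1])
    nu = np.full(G, GAUSSIAN_NU)
    state = (beta, sigma2, nu)
    state, *_ = _run_stacked_em(X, z, group, lam, em, "gaussian", state, 1e-6, 50)
    if family == "t":
        state = (state[0], state[1], np.full(G, 5.0))
    return state


def _joint_cv_fit(target: Dataset, sources, offsets, config: TransferConfig):
    """CV over lambda for the stacked fit; folds over target rows only."""
    em = config.em
    X, z, group = _stack(target, sources, offsets)
    n0 = target.n
    # grid from the stacked problem under initial weights
    sigma20 = np.array([max(float(np.mean(z[group == g] ** 2)), 1e-12)
                        for g in range(int(group.max()) + 1)])
    w0 = sigma20[0] / sigma20[group]
    lmax = float(np.max(np.abs(X.T @ (w0 * z))))
    grid = (np.sort(np.unique(em.lambda_grid))[::-1] if em.lambda_grid is not None
            else np.geomspace(lmax, lmax * em.lambda_min_ratio, em.n_lambda))

    rng = np.random.default_rng(em.seed)
    perm = rng.permutation(n0)
    folds = [perm[f::em.cv_folds] for f in range(em.cv_folds)]
    scores = np.zeros((len(grid), len(folds)))
    for fi, hold in enumerate(folds):
        keep = np.ones(X.shape[0], dtype=bool)
        keep[hold] = False
        Xf = np.asfortranarray(X[keep])
        zf, gf = z[keep], group[keep]
        Xv, zv = X[hold], z[hold]
        state = _init_state(Xf, zf, gf, grid[0], em, config.family)
        for li, lam in enumerate(grid):
            state, *_ = _run_stacked_em(
                Xf, zf, gf, lam, em, config.family, state, em.cv_tol, em.cv_max_iter)
            beta = state[0]
            scores[li, fi] = -float(np.mean((zv - Xv @ beta) ** 2))
    mean_scores = scores.mean(axis=1)
    best = _select_lambda_index(mean_scores, scores, em.cv_rule)
    lam_best = float(grid[best])
    state = _init_state(X, z, group, lam_best, em, config.family)
    state, n_iter, converged = _run_stacked_em(
        X, z, group, lam_best, em, config.family, state, em.tol, em.max_iter,
        polish=True)
    beta, sigma2, nu = state
    nu0 = float(nu[0]) if config.family == "t" else GAUSSIAN_NU
    ll = observed_loglik(target, beta, float(sigma2[0]), nu0)
    fit = TModelFit(
        beta=beta, sigma2=float(sigma2[0]), nu=nu0, lam=lam_best,
        loglik=ll,
        penalized_obj=ll - lam_best * float(np.sum(np.abs(beta)))
        / float(sigma2[0]),
        n_iter=n_iter, converged=converged,
    )
    table = pd.DataFrame({"lambda": grid, "mean_score": mean_scores})
    return fit, table


# ---------------------------------------------------------------------------
# Algorithm 2: the three steps
# ---------------------------------------------------------------------------


def fit_source_models(sources: list[Dataset], config: TransferConfig) -> list[TModelFit]:
    """Step 1: penalized fit on each source with its own CV-chosen lambda."""
    fits = []
    for s, src in enumerate(sources, start=1):
        try:
            _, fit, _ = cv_select_lambda(src, config.em, family=config.family)
        except Exception as exc:  # noqa: BLE001 - annotate with source id
            raise RuntimeError(f"source {s} fit failed: {exc}") from exc
        fits.append(fit)
    return fits


def estimate_offset(target: Dataset, beta_s: np.ndarray,
                    config: TransferConfig, source_id: int = 0) -> SourceOffset:
    """Step 2: delta maximizing the penalized target likelihood at beta_s + delta.

    Implemented as a penalized fit on the target with the source prediction
    x_i' beta_s as a fixed offset, so delta takes the role of beta."""
    beta_s = np.asarray(beta_s, dtype=float)
    if beta_s.shape[0] != target.p:
        raise ValueError("beta_s dimension mismatch")
    off = target.X @ beta_s
    lam, fit, _ = cv_select_lambda(target, config.em, offset=off, family=config.family)
    return SourceOffset(source_id=source_id, delta_hat=fit.beta, lambda_delta=lam)


def joint_estimate(target: Dataset, sources: list[Dataset],
                   offsets: list[SourceOffset], config: TransferConfig) -> TModelFit:
    """Step 3: joint estimation over target and offset-corrected sources.

    Maximizes L(beta; target) + sum_s L(beta - delta_s; source_s) - lam ||beta||_1
    with per-dataset (sigma2, nu) and lambda chosen by CV on the target."""
    if target.n == 0:
        raise ValueError("empty target")
    if len(offsets) != len(sources):
        raise ValueError("offsets must align one-to-one with sources")
    if not sources:
        _, fit, _ = cv_select_lambda(target, config.em, family=config.family)
        return fit
    fit, _ = _joint_cv_fit(target, sources, offsets, config)
    return fit


def transfer_fit_known(target: Dataset, sources: list[Dataset],
                       T: list[int], config: TransferConfig | None = None,
                       source_fits: dict[int, TModelFit] | None = None,
                       target_fit: TModelFit | None = None) -> TransferResult:
    """Three-step transfer with a known transferable index set T (1-based).

    With T empty the result is the target-only fit. `source_fits` may carry
    cached step-1 fits keyed by source index; `target_fit` a cached
    target-only CV fit."""
    config = config or TransferConfig()
    S = len(sources)
    T = sorted(set(int(s) for s in T))
    if any(s < 1 or s > S for s in T):
        raise ValueError(f"transferable indices must lie in 1..{S}")
    if target_fit is None:
        _, target_fit, _ = cv_select_lambda(target, config.em, family=config.family)
    if not T:
        return TransferResult(
            beta_TL=target_fit.beta, detected_set=[], stats=None, offsets=[],
            source_fits=[], target_only_fit=target_fit,
        )
    fits = []
    for s in T:
        if source_fits is not None and s in source_fits:
            fits.append(source_fits[s])
        else:
            fits.append(fit_source_models([sources[s - 1]], config)[0])
    offsets = [estimate_offset(target, f.beta, config, source_id=s)
               for s, f in zip(T, fits)]
    joint = joint_estimate(target, [sources[s - 1] for s in T], offsets, config)
    return TransferResult(
        beta_TL=joint.beta, detected_set=T, stats=None, offsets=offsets,
        source_fits=fits, target_only_fit=target_fit, joint_fit=joint,
    )


# ---------------------------------------------------------------------------
# Algorithm 3: detection
# ---------------------------------------------------------------------------


def _scale_df_mle(r: np.ndarray, family: str, nu_bounds, max_iter: int = 200):
    """ML estimates of (sigma2, nu) for t residuals with the location fixed."""
    sigma2 = float(np.mean(r * r))
    if sigma2 <= 0:
        raise DegenerateScaleError("zero residuals in scale re-estimation")
    if family == "gaussian":
        return sigma2, GAUSSIAN_NU
    nu = 5.0
    for _ in range(max_iter):
        lw = _e_step_resid(r, sigma2, nu)
        s_new = float(np.mean(lw.tau_hat * r * r))
        nu_new = m_step_nu(lw, nu_bounds)
        d = abs(s_new - sigma2) + abs(nu_new - nu)
        sigma2, nu = s_new, nu_new
        if d < 1e-8:
            break
    return sigma2, nu


def _valid_loglik(beta, d_va: Dataset, sigma2: float, nu: float) -> float:
    """Validation log-likelihood of beta under common nuisance parameters.

    (sigma2, nu) are estimated once, from the target-only training fit, and
    shared by every candidate: per-candidate re-estimation lets a badly
    predicting beta inflate its scale (and drop nu), flattening its
    likelihood until even noise sources score above the target-only fit.
    Under a common scale the comparison is a genuine robust prediction loss."""
    return observed_loglik(d_va, beta, sigma2, nu)


def detect_transferable(target: Dataset, sources: list[Dataset],
                        config: TransferConfig | None = None,
                        source_fits: dict[int, TModelFit] | None = None):
    """Detect the transferable source set by a seeded half-split of the target.

    Fits beta0 on the training half, then for each source runs the three-step
    estimator on (training half, source) and compares validation
    log-likelihoods: T_hat_s = L(beta0) - L(beta_s) on the validation half.
    Sources with T_hat_s <= t * max(|L(beta0)|, 0.01) are kept (negative
    values mean the source improved validation fit).

    Returns (detected 1-based index list, stats DataFrame, step-1 fit cache).
    """
    config = config or TransferConfig()
    if target.n < 4:
        raise ValueError("target too small to split for detection")
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(target.n)
    n_tr = int(math.ceil(target.n * config.split_fraction))
    d_tr = target.subset(perm[:n_tr])
    d_va = target.subset(perm[n_tr:])

    _, fit0, _ = cv_select_lambda(d_tr, config.em, family=config.family)
    # common nuisance parameters for every candidate's validation likelihood
    r0_tr = d_tr.y - d_tr.X @ fit0.beta
    sigma2_va, nu_va = _scale_df_mle(r0_tr, config.family, config.em.nu_bounds)
    L0 = _valid_loglik(fit0.beta, d_va, sigma2_va, nu_va)
    bound = config.threshold_t * max(abs(L0), 0.01)

    if source_fits is None:
        source_fits = {s: f for s, f in
                       enumerate(fit_source_models(sources, config), start=1)}
    rows = []
    for s in range(1, len(sources) + 1):
        res = transfer_fit_known(d_tr, sources, [s], config,
                                 source_fits=source_fits, target_fit=fit0)
        Ls = _valid_loglik(res.beta_TL, d_va, sigma2_va, nu_va)
        T_hat = L0 - Ls
        rows.append({"source": s, "T_hat": T_hat, "bound": bound,
                     "L_valid": Ls, "L0_valid": L0,
                     "detected": T_hat <= bound})
    stats = pd.DataFrame(rows)
    detected = [int(r["source"]) for r in rows if r["detected"]]
    return detected, stats, source_fits


def trans_fit(target: Dataset, sources: list[Dataset],
              config: TransferConfig | None = None) -> TransferResult:
    """Full pipeline: detect the transferable set, then refit on the whole
    target with the detected sources (Trans-PtLR / Trans-PNLR)."""
    config = config or TransferConfig()
    detected, stats, cache = detect_transferable(target, sources, config)
    result = transfer_fit_known(target, sources, detected, config,
                                source_fits=cache)
    result.stats = stats
    result.detected_set = detected
    return result
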