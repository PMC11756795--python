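"""Synthetic multi-source designs, evaluation metrics, and the experiment grid.

The generator draws AR(1)-correlated Gaussian predictors, a sparse target
coefficient vector (k leading coefficients equal to beta_val), per-source
coefficient perturbations of magnitude h/100 on random index subsets, and
errors from one of four families: standard normal (N), scaled t with 5
degrees of freedom (t), a contaminated-normal outlier mixture (CN), and an
Azzalini skew-t (St). Transferable sources are perturbed only outside the
true support; non-transferable sources are additionally perturbed on the
full support, which is what makes them harmful to borrow from.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .data import Dataset
from .gaussian import naive_transfer
from .ptlr import EMConfig, cv_select_lambda
from .transfer import TransferConfig, trans_fit

ERROR_FAMILIES = ("N", "t", "CN", "St")


@dataclass
class SimulationConfig:
    """Study design parameters (defaults are the simulation conditions)."""

    n0: int = 150
    n_s: int = 100
    S: int = 10
    p: int = 500
    rho: float = 0.7
    k: int = 16
    beta_val: float = 0.5
    h: int = 10
    n_transferable: int = 0
    H_size: int = 50
    error_family: str = "N"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k >= self.p:
            raise ValueError("k must be smaller than p")
        if self.H_size > self.p - self.k:
            raise ValueError("H_size cannot exceed p - k")
        if self.n_transferable > self.S:
            raise ValueError("n_transferable cannot exceed S")
        if self.error_family not in ERROR_FAMILIES:
            raise ValueError(f"unknown error family {self.error_family!r}")


@dataclass
class SimulationTruth:
    beta0: np.ndarray
    betas: list[np.ndarray]
    transferable_set: list[int]
    H_sets: list[np.ndarray]


@dataclass
class MetricsReport:
    estimation_error: float
    precision: float
    recall: float
    mpe: float | None = None
    relative_pe: float | None = None


def make_ar1_cov(p: int, rho: float) -> np.ndarray:
    """First-order autoregressive covariance Sigma_ij = rho^|i-j|."""
    if not -1 < rho < 1:
        raise ValueError("|rho| must be < 1")
    idx = np.arange(p)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def _ar1_sample(n: int, p: int, rho: float, rng: np.random.Generator) -> np.ndarray:
    """Draw n rows from N(0, AR1(rho)) via the Markov construction."""
    e = rng.standard_normal((n, p))
    X = np.empty((n, p))
    X[:, 0] = e[:, 0]
    c = np.sqrt(1.0 - rho * rho)
    for j in range(1, p):
        X[:, j] = rho * X[:, j - 1] + c * e[:, j]
    return X


def gen_coefficients(config: SimulationConfig,
                     rng: np.random.Generator) -> SimulationTruth:
    """True target and source coefficients.

    beta0 has beta_val on the first k coordinates. The transferable sources
    (a random size-n_transferable subset of 1..S) are shifted by -h/100 on a
    random 50-subset H(s) of the null coordinates; the rest are additionally
    shifted on the whole true support.
    """
    p, k = config.p, config.k
    beta0 = np.zeros(p)
    beta0[:k] = config.beta_val
    order = rng.permutation(config.S) + 1
    transferable = sorted(order[: config.n_transferable].tolist())
    shift = config.h / 100.0
    betas, H_sets = [], []
    for s in range(1, config.S + 1):
        H = rng.choice(np.arange(k, p), size=config.H_size, replace=False)
        H_sets.append(np.sort(H))
        b = beta0.copy()
        b[H] -= shift
        if s not in transferable:
            b[:k] -= shift
        betas.append(b)
    return SimulationTruth(beta0=beta0, betas=betas,
                           transferable_set=transferable, H_sets=H_sets)


def gen_errors(family: str, n: int, rng: np.random.Generator) -> np.ndarray:
    """Sample n errors from one of the four study families.

    N: standard normal. t: t(0, 1, 5). CN: 0.9 N(0,1) + 0.1 N(0,10) with
    per-draw component selection. St: Azzalini skew-t, location 0, scale 1,
    df 5, slant 1.
    """
    if family == "N":
        return rng.standard_normal(n)
    if family == "t":
        return rng.standard_t(5, size=n)
    if family == "CN":
        outlier = rng.random(n) < 0.1
        sd = np.where(outlier, np.sqrt(10.0), 1.0)
        return sd * rng.standard_normal(n)
    if family == "St":
        alpha = 1.0
        delta = alpha / np.sqrt(1.0 + alpha * alpha)
        w0 = np.abs(rng.standard_normal(n))
        w1 = rng.standard_normal(n)
        z = delta * w0 + np.sqrt(1.0 - delta * delta) * w1  # skew-normal
        v = rng.chisquare(5, size=n)
        return z / np.sqrt(v / 5.0)
    raise ValueError(f"unknown error family {family!r}")


def gen_multidata(config: SimulationConfig,
                  rng: np.random.Generator | None = None):
    """Generate (target, sources, truth) for one replication."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    truth = gen_coefficients(config, rng)
    X0 = _ar1_sample(config.n0, config.p, config.rho, rng)
    y0 = X0 @ truth.beta0 + gen_errors(config.error_family, config.n0, rng)
    target = Dataset(X0, y0, role="target")
    sources = []
    for s in range(1, config.S + 1):
        Xs = _ar1_sample(config.n_s, config.p, config.rho, rng)
        ys = Xs @ truth.betas[s - 1] + gen_errors(
            config.error_family, config.n_s, rng)
        sources.append(Dataset(Xs, ys, role=f"source:{s}"))
    return target, sources, truth


def precision_recall(beta_hat: np.ndarray, beta_true: np.ndarray):
    """Variable-selection precision and recall of the nonzero pattern.

    precision = |selected ∩ true| / |selected| (0 when nothing is selected);
    recall = |selected ∩ true| / |true|.
    """
    beta_hat = np.asarray(beta_hat)
    beta_true = np.asarray(beta_true)
    if beta_hat.shape != beta_true.shape:
        raise ValueError("length mismatch")
    true = beta_true != 0
    if not true.any():
        raise ValueError("recall undefined: beta_true has no nonzero entries")
    sel = beta_hat != 0
    hits = int(np.sum(sel & true))
    precision = hits / int(sel.sum()) if sel.any() else 0.0
    recall = hits / int(true.sum())
    return precision, recall


def prediction_error_cv(target: Dataset,
                        method: Callable[[Dataset], np.ndarray],
                        folds: int = 5,
                        rng: np.random.Generator | None = None) -> float:
    """5-fold mean squared prediction error on the target.

    The method (including any transfer machinery it closes over) is retrained
    on each set of held-in folds and scored on the held-out fold; the fold
    means are averaged.
    """
    if target.n < folds:
        raise ValueError("not enough rows for the requested folds")
    rng = rng or np.random.default_rng(0)
    perm = rng.permutation(target.n)
    fold_idx = [perm[f::folds] for f in range(folds)]
    errs = []
    for f, hold in enumerate(fold_idx):
        train = np.setdiff1d(np.arange(target.n), hold)
        try:
            beta = method(target.subset(train))
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"method failed in fold {f}: {exc}") from exc
        pred = target.X[hold] @ beta
        errs.append(float(np.mean((pred - target.y[hold]) ** 2)))
    return float(np.mean(errs))


# ---------------------------------------------------------------------------
# experiment grid
# ---------------------------------------------------------------------------

METHODS = ("PtLR", "PNLR", "Trans-PtLR", "Trans-PNLR",
           "Naive-Trans-PtLR", "Naive-Trans-PNLR")


def desk_emconfig(**kwargs) -> EMConfig:
    """EM settings used by the experiment runner: a 20-point lambda path down
    to 0.01 * lambda_max with 5-fold CV, and slightly relaxed EM tolerances
    for the fold fits (see the methods note)."""
    defaults = dict(n_lambda=20, lambda_min_ratio=0.01, cv_tol=1e-3,
                    cv_max_iter=50, tol=1e-5, max_iter=200)
    defaults.update(kwargs)
    return EMConfig(**defaults)


def desk_transfer_emconfig(**kwargs) -> EMConfig:
    """EM settings for the transfer pipeline's many sub-fits: a 12-point
    lambda path down to 0.02 * lambda_max with capped CV iterations."""
    defaults = dict(n_lambda=12, lambda_min_ratio=0.02, cv_tol=2e-3,
                    cv_max_iter=30, tol=1e-5, max_iter=200)
    defaults.update(kwargs)
    return EMConfig(**defaults)


def make_method(name: str, sources: list[Dataset], threshold_t: float = 0.1,
                em: EMConfig | None = None, seed: int = 0,
                ) -> Callable[[Dataset], np.ndarray]:
    """Build a `target -> beta_hat` callable for one of the six methods.

    When `em` is omitted, single-dataset fits use desk_emconfig() and the
    transfer pipelines desk_transfer_emconfig().
    """

    def run(target: Dataset) -> np.ndarray:
        family = "t" if "PtLR" in name else "gaussian"
        if name in ("PtLR", "PNLR"):
            _, fit, _ = cv_select_lambda(target, em or desk_emconfig(),
                                         family=family)
            return fit.beta
        cfg = TransferConfig(threshold_t=threshold_t, seed=seed,
                             em=em or desk_transfer_emconfig(), family=family)
        if name.startswith("Naive"):
            return naive_transfer(target, sources, cfg).beta_TL
        return trans_fit(target, sources, cfg).beta_TL

    return run


def run_experiment(
    h_values: Sequence[int] = (10,),
    T_values: Sequence[int] = (0, 10),
    families: Sequence[str] = ("N",),
    methods: Sequence[str] = ("PtLR", "PNLR"),
    reps: int = 1,
    seed: int = 0,
    threshold_t: float = 0.1,
    em: EMConfig | None = None,
    compute_prediction_error: bool = False,
    base: SimulationConfig | None = None,
) -> pd.DataFrame:
    """Run the simulation grid; one tidy row per cell x replication x method.

    Every cell/replication gets an independently spawned seed, so any row is
    reproducible in isolation. Failures are recorded in the `error` column
    and the run continues.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    base = base or SimulationConfig()
    root = np.random.SeedSequence(seed)
    rows = []
    for h in h_values:
        for n_tr in T_values:
            for fam in families:
                cell_ss = root.spawn(1)[0]
                rep_seeds = cell_ss.generate_state(reps) % (2**31)
                for rep in range(reps):
                    rep_seed = int(rep_seeds[rep])
                    cfg = replace(base, h=h, n_transferable=n_tr,
                                  error_family=fam, seed=rep_seed)
                    rng = np.random.default_rng(rep_seed)
                    target, sources, truth = gen_multidata(cfg, rng)
                    for m in methods:
                        em_m = em if em is not None else (
                            desk_emconfig() if m in ("PtLR", "PNLR")
                            else desk_transfer_emconfig())
                        em_rep = replace(em_m, seed=rep_seed)
                        row = {"h": h, "n_transferable": n_tr, "family": fam,
                               "rep": rep, "method": m, "seed": rep_seed,
                               "error": ""}
                        try:
                            fn = make_method(m, sources, threshold_t,
                                             em_rep, seed=rep_seed)
                            beta = fn(target)
                            prec, rec = precision_recall(beta, truth.beta0)
                            row.update(
                                estimation_error=float(
                                    np.sum((beta - truth.beta0) ** 2)),
                                precision=prec, recall=rec,
                            )
                            if compute_prediction_error:
                                row["mpe"] = prediction_error_cv(
                                    target, fn, folds=5,
                                    rng=np.random.default_rng(rep_seed + 1))
                        except Exception as exc:  # noqa: BLE001
                            row["error"] = str(exc)
                        rows.append(row)
    table = pd.DataFrame(rows)
    if compute_prediction_error and "mpe" in table.columns:
        # relative prediction error: each method's MPE over PNLR's, per rep
        def _rel(g):
            ref = g.loc[g.method == "PNLR", "mpe"]
            if len(ref) == 1 and np.isfinite(ref.iloc[0]):
                g["relative_pe"] = g["mpe"] / ref.iloc[0]
            return g
        table = table.groupby(
            ["h", "n_transferable", "family", "rep"], group_keys=False,
        )[table.columns].apply(_rel)
    return table


def aggregate(table: pd.DataFrame) -> pd.DataFrame:
    """Mean metrics per grid cell and method."""
    metrics = [c for c in ("estimation_error", "precision", "recall",
                           "mpe", "relative_pe") if c in table.columns]
    ok = table[table["error"] == ""]
    return (ok.groupby(["h", "n_transferable", "family", "method"])[metrics]
            .mean().reset_index())
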