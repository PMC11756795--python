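"""Penalized normal-error linear regression (PNLR) and naive transfer.

These are the Gaussian-family comparators: the same coordinate-descent engine
with unit latent weights (equivalently the t-family loop with nu fixed at
infinity), and Algorithm-2 transfer applied to *all* sources without
detection ("naive" transfer).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import Dataset
from .ptlr import GAUSSIAN_NU, EMConfig, TModelFit, cv_select_lambda, fit_ptlr


@dataclass
class GaussianFit:
    beta: np.ndarray
    sigma2: float
    lam: float
    loglik: float
    n_iter: int
    converged: bool
    intercept: float = 0.0

    @property
    def nu(self) -> float:
        return GAUSSIAN_NU

    def predict(self, X: np.ndarray) -> np.ndarray:
        return X @ self.beta + self.intercept


def _from_tfit(fit: TModelFit) -> GaussianFit:
    return GaussianFit(
        beta=fit.beta,
        sigma2=fit.sigma2,
        lam=fit.lam,
        loglik=fit.loglik,
        n_iter=fit.n_iter,
        converged=fit.converged,
        intercept=fit.intercept,
    )


def fit_pnlr(data: Dataset, lam: float, config: EMConfig | None = None,
             offset: np.ndarray | None = None) -> GaussianFit:
    """Gaussian lasso: minimize (1/(2 sigma2)) RSS + lam ||beta||_1.

    Coordinate descent alternates with the sigma2 MLE (RSS/n) until the joint
    fixed point, sharing the EM engine of the t-family fit.
    """
    return _from_tfit(fit_ptlr(data, lam, config, offset=offset, family="gaussian"))


def cv_fit_pnlr(data: Dataset, config: EMConfig | None = None,
                offset: np.ndarray | None = None):
    """Cross-validated PNLR; returns (lambda, GaussianFit, cv table)."""
    lam, fit, table = cv_select_lambda(data, config, offset=offset, family="gaussian")
    return lam, _from_tfit(fit), table


def naive_transfer(target: Dataset, sources: list[Dataset], config=None):
    """Algorithm-2 transfer using every source, skipping detection.

    Family (t or Gaussian) follows config.family; with a small number of
    genuinely transferable sources this demonstrates negative transfer.
    """
    from .transfer import TransferConfig, transfer_fit_known

    config = config or TransferConfig()
    if len(sources) < 1:
        raise ValueError("naive transfer needs at least one source")
    return transfer_fit_known(target, sources, list(range(1, len(sources) + 1)), config)
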