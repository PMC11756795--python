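"""Dataset readers and report writers for the command-line tools."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import Dataset
from .gaussian import GaussianFit
from .ptlr import TModelFit
from .transfer import TransferResult


class DataFormatError(ValueError):
    pass


def read_dataset(path: str | Path, response_column: str,
                 role: str = "target") -> Dataset:
    """Read a delimited text file (header required) into a Dataset.

    Every column other than `response_column` is a predictor. Non-numeric or
    missing cells are reported with their row and column.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[0] == 0:
        raise DataFormatError(f"{path}: no data rows")
    if response_column not in df.columns:
        raise DataFormatError(
            f"{path}: response column {response_column!r} not found "
            f"(columns: {list(df.columns)[:8]}...)")
    num = df.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(num.isna().to_numpy())
    if bad.size:
        r, c = bad[0]
        raise DataFormatError(
            f"{path}: non-numeric or missing value at row {r + 2} "
            f"(1-based incl. header), column {df.columns[c]!r}")
    y = num[response_column].to_numpy(float)
    Xdf = num.drop(columns=[response_column])
    return Dataset(Xdf.to_numpy(float), y, role=role,
                   columns=list(Xdf.columns))


def write_dataset(data: Dataset, path: str | Path,
                  response_column: str = "y") -> None:
    cols = data.columns or [f"x{j + 1}" for j in range(data.p)]
    df = pd.DataFrame(data.X, columns=cols)
    df.insert(0, response_column, data.y)
    df.to_csv(path, index=False)


def _sig12(x: float) -> float:
    """Round to 12 significant digits for byte-stable JSON output."""
    return float(f"{x:.12g}")


def _sparse_beta(beta: np.ndarray) -> list[list]:
    return [[int(j), _sig12(float(b))] for j, b in enumerate(beta) if b != 0.0]


def _fit_payload(fit: TModelFit | GaussianFit) -> dict:
    return {
        "beta": _sparse_beta(fit.beta),
        "p": int(fit.beta.shape[0]),
        "intercept": _sig12(float(getattr(fit, "intercept", 0.0))),
        "sigma2": _sig12(fit.sigma2),
        "nu": None if not np.isfinite(fit.nu) else _sig12(fit.nu),
        "lambda": _sig12(fit.lam),
        "loglik": _sig12(fit.loglik),
        "n_iter": int(fit.n_iter),
        "converged": bool(fit.converged),
    }


def write_report(result, path: str | Path, config_echo: dict | None = None,
                 seed: int | None = None) -> None:
    """Serialize a fit, transfer result, or results table.

    Model objects become JSON (sparse coefficient encoding); tables become
    CSV. The JSON echoes the run configuration, seed, and package version.
    """
    from . import __version__

    path = Path(path)
    if isinstance(result, pd.DataFrame):
        result.to_csv(path, index=False)
        return
    meta = {"package": "transptlr", "version": __version__, "seed": seed,
            "config": config_echo or {}}
    if isinstance(result, (TModelFit, GaussianFit)):
        payload = {"type": "fit", **meta, "fit": _fit_payload(result)}
    elif isinstance(result, TransferResult):
        payload = {
            "type": "transfer",
            **meta,
            "beta_TL": _sparse_beta(result.beta_TL),
            "p": int(result.beta_TL.shape[0]),
            "detected_set": list(result.detected_set),
            "offsets": [
                {"source": o.source_id,
                 "delta": _sparse_beta(o.delta_hat),
                 "lambda_delta": _sig12(o.lambda_delta)}
                for o in result.offsets
            ],
            "target_only_fit": _fit_payload(result.target_only_fit),
            "detection": (None if result.stats is None
                          else json.loads(result.stats.to_json(orient="records"))),
        }
    else:
        raise TypeError(f"cannot serialize {type(result).__name__}")
    path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def dense_beta(sparse: list[list], p: int) -> np.ndarray:
    beta = np.zeros(p)
    for j, v in sparse:
        beta[j] = v
    return beta
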