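"""Dataset container shared by every fitting routine."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

TARGET = "target"


@dataclass
class Dataset:
    """A predictor matrix with an aligned response vector.

    Parameters
    ----------
    X : (n, p) array of real predictors.
    y : (n,) response vector.
    role : "target" or "source:<s>"; purely informational.
    """

    X: np.ndarray
    y: np.ndarray
    role: str = TARGET
    columns: list[str] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.X = np.ascontiguousarray(np.asarray(self.X, dtype=np.float64))
        self.y = np.asarray(self.y, dtype=np.float64).ravel()
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError(
                f"X has {self.X.shape[0]} rows but y has {self.y.shape[0]} entries"
            )
        if self.X.shape[0] < 2:
            raise ValueError("need at least 2 observations")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains non-finite entries")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("y contains non-finite entries")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def subset(self, idx: np.ndarray) -> "Dataset":
        return Dataset(self.X[idx], self.y[idx], role=self.role, columns=self.columns)


def source(X: np.ndarray, y: np.ndarray, s: int) -> Dataset:
    """Convenience constructor for the s-th source dataset."""
    return Dataset(X, y, role=f"source:{s}")
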