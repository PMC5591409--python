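"""Column scaling for chemometric models.

Pareto scaling — centering each variable and dividing by the square root of
its standard deviation — is the conventional compromise for NMR bucket
tables: it damps the dominance of the most intense buckets without inflating
noise-only buckets the way unit-variance scaling does.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import BinMatrix

__all__ = ["ParetoScaler", "pareto_scale"]


@dataclass
class ParetoScaler:
    """Per-column mean and SD captured from a training matrix.

    Columns with zero variance are centered only (divisor 1) and flagged, so
    applying the scaler never divides by zero.
    """

    means: np.ndarray
    sds: np.ndarray
    zero_variance: np.ndarray  # boolean mask
    mode: str = "pareto"

    @classmethod
    def fit(cls, x: np.ndarray) -> "ParetoScaler":
        x = np.asarray(x, dtype=float)
        if x.ndim != 2 or x.shape[0] < 2:
            raise ValueError("need a 2-D matrix with at least 2 rows")
        means = x.mean(axis=0)
        sds = x.std(axis=0, ddof=1)
        zero = sds == 0.0
        return cls(means=means, sds=sds, zero_variance=zero)

    @property
    def divisors(self) -> np.ndarray:
        d = np.sqrt(self.sds)
        d[self.zero_variance] = 1.0
        return d

    def transform(self, x: np.ndarray) -> np.ndarray:
        """Scale new data with the *training* means/SDs."""
        x = np.asarray(x, dtype=float)
        if x.shape[-1] != self.means.size:
            raise ValueError(
                f"column count {x.shape[-1]} does not match scaler ({self.means.size})"
            )
        return (x - self.means) / self.divisors


def pareto_scale(matrix: BinMatrix | np.ndarray) -> tuple[np.ndarray, ParetoScaler]:
    """Fit a Pareto scaler on a matrix and return (scaled values, scaler)."""
    x = matrix.values if isinstance(matrix, BinMatrix) else np.asarray(matrix, float)
    scaler = ParetoScaler.fit(x)
    return scaler.transform(x), scaler
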