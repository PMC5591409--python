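"""Principal components analysis with Hotelling-T² outlier screening.

Used as the unsupervised first look at a scaled bucket table: the scores plot
and the T² limit identify samples that sit implausibly far from the rest of
the cohort before any supervised modelling. Flagging is report-only; nothing
is removed automatically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["PCA", "PCAResults"]


class PCA:
    """PCA model on an already centered/scaled matrix.

    Computed by singular-value decomposition (numerically safer than NIPALS;
    a NIPALS routine is kept for cross-checking).

    Parameters
    ----------
    x : (n, p) array, centered (e.g. Pareto-scaled) data
    n_comp : number of components; must be <= min(n - 1, p)
    """

    def __init__(self, x: np.ndarray, n_comp: int):
        x = np.asarray(x, dtype=float)
        if x.ndim != 2:
            raise ValueError("x must be 2-D")
        n, p = x.shape
        if not 1 <= n_comp <= min(n - 1, p):
            raise ValueError(f"n_comp must be in [1, {min(n - 1, p)}]")
        self.x = x
        self.n_comp = n_comp

    def fit(self) -> "PCAResults":
        u, s, vt = np.linalg.svd(self.x, full_matrices=False)
        a = self.n_comp
        # deterministic sign: largest-magnitude loading entry positive
        for k in range(a):
            j = np.argmax(np.abs(vt[k]))
            if vt[k, j] < 0:
                vt[k] *= -1
                u[:, k] *= -1
        scores = u[:, :a] * s[:a]
        total_ss = float((self.x**2).sum())
        explained = (s[:a] ** 2) / total_ss if total_ss > 0 else np.zeros(a)
        return PCAResults(
            model=self,
            scores=scores,
            loadings=vt[:a].T,
            explained=explained,
        )


@dataclass
class PCAResults:
    model: PCA
    scores: np.ndarray  # (n, A)
    loadings: np.ndarray  # (p, A), orthonormal columns
    explained: np.ndarray  # per-component fraction of total X sum of squares

    @property
    def n_comp(self) -> int:
        return self.scores.shape[1]

    def hotelling_t2(self) -> np.ndarray:
        """Per-sample T² = sum_a t_ia² / s_ta² over the retained components."""
        var = self.scores.var(axis=0, ddof=1)
        if np.any(var == 0):
            raise ValueError("degenerate component with zero score variance")
        return (self.scores**2 / var).sum(axis=1)

    def t2_limit(self, alpha: float = 0.05) -> float:
        """Critical T² limit A(N²-1)/(N(N-A)) * F_{1-alpha}(A, N-A)."""
        n = self.scores.shape[0]
        a = self.n_comp
        if n <= a:
            raise ValueError("need more samples than components")
        f_crit = stats.f.ppf(1.0 - alpha, a, n - a)
        return a * (n**2 - 1) / (n * (n - a)) * f_crit

    def outlier_flags(self, alpha: float = 0.05) -> np.ndarray:
        """Report-only boolean mask of samples beyond the T² limit."""
        return self.hotelling_t2() > self.t2_limit(alpha)

    def reconstruct(self) -> np.ndarray:
        return self.scores @ self.loadings.T


def _nipals_pca(x: np.ndarray, n_comp: int, tol: float = 1e-12,
                max_iter: int = 2000) -> tuple[np.ndarray, np.ndarray]:
    """Reference NIPALS PCA (scores, loadings) used to cross-check the SVD path."""
    x = np.asarray(x, dtype=float).copy()
    n, p = x.shape
    scores = np.zeros((n, n_comp))
    loadings = np.zeros((p, n_comp))
    for a in range(n_comp):
        t = x[:, np.argmax(x.var(axis=0))].copy()
        for _ in range(max_iter):
            pvec = x.T @ t / (t @ t)
            pvec /= np.linalg.norm(pvec)
            t_new = x @ pvec
            if np.linalg.norm(t_new - t) < tol * max(np.linalg.norm(t_new), 1e-300):
                t = t_new
                break
            t = t_new
        j = np.argmax(np.abs(pvec))
        if pvec[j] < 0:
            pvec, t = -pvec, -t
        scores[:, a], loadings[:, a] = t, pvec
        x = x - np.outer(t, pvec)
    return scores, loadings
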