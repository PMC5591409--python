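"""Model validation: label-permutation diagnostics and CV-ANOVA.

Permutation test
----------------
The class labels are shuffled ``n_perm`` times; for each shuffle the model is
refit with the identical component specification and cross-validation, and
the triple (r, R²Y, Q²) is recorded, where r is the absolute Pearson
correlation between the permuted and original (centered) y. Least-squares
lines of R²Y-versus-r and Q²-versus-r are fitted through all permuted records
plus the unpermuted anchor at r = 1; their intercepts at r = 0 diagnose
overfitting (a valid model has a low R² intercept and a Q² intercept near or
below zero). Empirical p-values P(R²_perm ≥ R²_model) and
P(Q²_perm ≥ Q²_model) use the add-one rule (1 + #exceed)/(1 + n_perm).

By default the refits use PLS-DA with the same *total* component count as
the OPLS-DA under validation (the convention of the originating software's
validate plot); ``mode="oplsda"`` refits the OPLS-DA itself instead.

CV-ANOVA
--------
An F-test comparing the cross-validated predictive sum of squares
(SS_total − PRESS) against the predictive residuals:
F = ((SS − PRESS)/A) / (PRESS/(N − 1 − A)) with A total components and N
samples; p is the upper tail of F(A, N − 1 − A). PRESS larger than SS (a
model worse than the mean) gives a negative F and is reported as p = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .opls import (
    CVResult,
    OPLSDAResults,
    assign_folds,
    cross_validate_q2,
    fit_oplsda_core,
    nipals_pls1,
)
from .preprocess import BinMatrix
from .scale import pareto_scale

__all__ = [
    "PermutationSummary",
    "CVANOVAResult",
    "permutation_test",
    "cv_anova",
]


@dataclass
class PermutationSummary:
    """Permutation records plus the fitted intercept diagnostics."""

    records: pd.DataFrame      # columns perm_idx, r, R2Y, Q2 (perm_idx 0 = anchor)
    r2_slope: float
    r2_intercept: float
    q2_slope: float
    q2_intercept: float
    p_r2: float                # empirical P(R2_perm >= R2_model)
    p_q2: float                # empirical P(Q2_perm >= Q2_model)
    n_perm: int
    seed: int
    mode: str

    @property
    def anchor(self) -> pd.Series:
        return self.records.iloc[0]

    def passes_heuristic(self) -> bool:
        """Report-only rule of thumb: R² intercept < 0.4 and Q² intercept < 0.05."""
        return self.r2_intercept < 0.4 and self.q2_intercept < 0.05

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False, float_format="%.6g")

    def plot(self, ax=None):
        """Validate plot: R²Y and Q² of every refit against its label
        correlation r, with the fitted regression lines."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        r = self.records["r"]
        ax.scatter(r, self.records["R2Y"], marker="s", label="R2Y")
        ax.scatter(r, self.records["Q2"], marker="o", label="Q2")
        grid = np.linspace(0, 1, 2)
        ax.plot(grid, self.r2_intercept + self.r2_slope * grid, lw=1)
        ax.plot(grid, self.q2_intercept + self.q2_slope * grid, lw=1)
        ax.set_xlabel("|corr(y_perm, y)|")
        ax.set_ylabel("R2Y / Q2")
        ax.legend()
        return ax


def _fit_r2_q2(
    x_raw: np.ndarray,
    y: np.ndarray,
    n_orth: int,
    folds: int,
    mode: str,
    sample_ids: list[str] | None,
) -> tuple[float, float]:
    """(R²Y, Q²) of one refit under the requested scheme."""
    x_scaled, _ = pareto_scale(x_raw)
    if mode == "oplsda":
        core = fit_oplsda_core(x_scaled, y, n_orth=n_orth)
        r2y = core.r2y
    elif mode == "plsda":
        pls = nipals_pls1(x_scaled, y, n_comp=1 + n_orth)
        r2y = pls.r2y
    else:
        raise ValueError(f"unknown mode {mode!r}")
    cv = cross_validate_q2(
        x_raw, y, n_orth=n_orth, folds=folds, model=mode, sample_ids=sample_ids
    )
    return r2y, cv.q2


def permutation_test(
    x_raw: np.ndarray | BinMatrix,
    y: np.ndarray,
    n_orth: int = 1,
    n_perm: int = 500,
    seed: int = 0,
    folds: int = 7,
    mode: str = "plsda",
    sample_ids: list[str] | None = None,
    fitted: OPLSDAResults | None = None,
) -> PermutationSummary:
    """Run the label-permutation validation of a two-class model.

    ``y`` is the 0/1 class coding. Permutations are drawn uniformly (with the
    given seed); duplicates are allowed. Permutations that put a single class
    in some training fold are redrawn (they cannot be cross-validated).
    """
    if isinstance(x_raw, BinMatrix):
        if sample_ids is None:
            sample_ids = x_raw.sample_ids
        x_raw = x_raw.values
    x_raw = np.asarray(x_raw, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if np.unique(y).size < 2:
        raise ValueError("constant y cannot be permuted meaningfully")
    if n_perm < 1:
        raise ValueError("need n_perm >= 1")

    rng = np.random.default_rng(seed)
    yc = y - y.mean()
    y_norm = float(np.sqrt(yc @ yc))

    # anchor: the unpermuted model under the same refit scheme
    r2_model, q2_model = _fit_r2_q2(x_raw, y, n_orth, folds, mode, sample_ids)
    rows = [(0, 1.0, r2_model, q2_model)]

    exceed_r2 = 0
    exceed_q2 = 0
    for i in range(1, n_perm + 1):
        for _attempt in range(1000):
            y_perm = rng.permutation(y)
            try:
                assign_folds(y_perm, folds, sample_ids)
                r2p, q2p = _fit_r2_q2(x_raw, y_perm, n_orth, folds, mode, sample_ids)
                break
            except ValueError:
                continue
        else:  # pragma: no cover - only with pathological class imbalance
            raise RuntimeError("could not draw a cross-validatable permutation")
        ypc = y_perm - y_perm.mean()
        r = abs(float(ypc @ yc)) / (y_norm * float(np.sqrt(ypc @ ypc)))
        rows.append((i, r, r2p, q2p))
        exceed_r2 += r2p >= r2_model
        exceed_q2 += q2p >= q2_model

    records = pd.DataFrame(rows, columns=["perm_idx", "r", "R2Y", "Q2"])
    r_all = records["r"].to_numpy()
    design = np.column_stack([np.ones_like(r_all), r_all])
    beta_r2, *_ = np.linalg.lstsq(design, records["R2Y"].to_numpy(), rcond=None)
    beta_q2, *_ = np.linalg.lstsq(design, records["Q2"].to_numpy(), rcond=None)

    return PermutationSummary(
        records=records,
        r2_slope=float(beta_r2[1]),
        r2_intercept=float(beta_r2[0]),
        q2_slope=float(beta_q2[1]),
        q2_intercept=float(beta_q2[0]),
        p_r2=(1 + exceed_r2) / (1 + n_perm),
        p_q2=(1 + exceed_q2) / (1 + n_perm),
        n_perm=n_perm,
        seed=seed,
        mode=mode,
    )


@dataclass
class CVANOVAResult:
    ss_total: float
    press: float
    df_regression: int
    df_residual: int
    F: float
    p: float

    @property
    def ss_regression(self) -> float:
        return self.ss_total - self.press


def cv_anova(cv: CVResult, n_components: int, n_samples: int) -> CVANOVAResult:
    """CV-ANOVA significance test on a cross-validation result.

    ``n_components`` is the total component count A of the model (predictive
    plus orthogonal); requires N > A + 1.
    """
    a = int(n_components)
    n = int(n_samples)
    if n <= a + 1:
        raise ValueError("need N > A + 1 samples for CV-ANOVA")
    if not np.isfinite(cv.press):
        raise ValueError("PRESS undefined: run cross-validation first")
    df_reg = a
    df_res = n - 1 - a
    f = ((cv.ss - cv.press) / df_reg) / (cv.press / df_res)
    p = float(stats.f.sf(f, df_reg, df_res)) if f > 0 else 1.0
    return CVANOVAResult(
        ss_total=cv.ss, press=cv.press, df_regression=df_reg,
        df_residual=df_res, F=float(f), p=p,
    )
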