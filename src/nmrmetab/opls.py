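"""Two-class OPLS-DA (orthogonal projections to latent structures,
discriminant analysis) with cross-validated prediction quality.

The model splits the scaled bucket matrix X into a single predictive
component — the direction correlated with class membership — and ``n_orth``
orthogonal components carrying structured variation uncorrelated with class.
Class membership is coded as a centered 0/1 dummy (two-class case). With
``n_orth = 0`` the fit reduces exactly to one-component NIPALS PLS1.

Algorithm (orthogonal filtering)
--------------------------------
w  ∝ Xᵀy, normalized. For each orthogonal component:
    t = X w,  p = Xᵀt/(tᵀt),
    w_o = p − (wᵀp) w, normalized;  t_o = X w_o,  p_o = Xᵀt_o/(t_oᵀt_o);
    X ← X − t_o p_oᵀ
then one predictive component (t, p, c) on the filtered X.

Goodness of fit R²Y = 1 − ‖y − t c‖²/‖y‖² (y centered); R²X(cum) sums the
explained X sum-of-squares over predictive and orthogonal components.
Goodness of prediction Q² = 1 − PRESS/SS comes from k-fold cross-validation
in which each training split is re-scaled from scratch (no leakage).

The public surface is the statsmodels-style pair :class:`OPLSDA` (model,
built from a bin matrix and class labels) and :class:`OPLSDAResults`
(estimates, diagnostics, ``summary()``); the module-level functions are the
building blocks and are used directly by the validation and test code.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import BinMatrix
from .scale import ParetoScaler, pareto_scale

__all__ = [
    "OPLSDA",
    "OPLSDAResults",
    "OPLSCore",
    "PLS1Model",
    "CVResult",
    "fit_oplsda_core",
    "predict_oplsda_core",
    "nipals_pls1",
    "assign_folds",
    "cross_validate_q2",
]


# ---------------------------------------------------------------------------
# core fits on already-scaled matrices
# ---------------------------------------------------------------------------

@dataclass
class OPLSCore:
    """Weights/scores/loadings of a fitted OPLS-DA on a scaled matrix."""

    w: np.ndarray          # predictive weight, unit norm (p,)
    t: np.ndarray          # predictive score (n,)
    p: np.ndarray          # predictive X-loading (p,)
    c: float               # y-loading
    w_orth: np.ndarray     # (p, n_orth)
    t_orth: np.ndarray     # (n, n_orth)
    p_orth: np.ndarray     # (p, n_orth)
    y_mean: float          # mean of the 0/1 y coding on the training data
    r2x_cum: float
    r2y: float

    @property
    def n_orth(self) -> int:
        return self.w_orth.shape[1]

    @property
    def component_spec(self) -> str:
        return f"1P + {self.n_orth}O"


def fit_oplsda_core(x: np.ndarray, y: np.ndarray, n_orth: int = 1) -> OPLSCore:
    """Fit OPLS-DA on a scaled matrix ``x`` and a numeric two-class ``y``
    (0/1 coding; centered internally)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if x.shape[0] != y.size:
        raise ValueError("x and y length mismatch")
    levels = np.unique(y)
    if levels.size != 2:
        raise ValueError(f"need exactly 2 classes in y, got {levels.size}")
    if min((y == lv).sum() for lv in levels) < 2:
        raise ValueError("each class needs at least 2 samples")
    if n_orth < 0:
        raise ValueError("n_orth must be >= 0")

    y_mean = float(y.mean())
    yc = y - y_mean
    x0_ss = float((x**2).sum())
    xr = x.copy()

    w = xr.T @ yc
    w_norm = np.linalg.norm(w)
    if w_norm == 0:
        raise ValueError("degenerate y: zero covariance with X")
    w = w / w_norm

    w_os, t_os, p_os = [], [], []
    for _ in range(n_orth):
        t = xr @ w
        p = xr.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        n_wo = np.linalg.norm(w_o)
        if n_wo < 1e-12 * max(np.linalg.norm(p), 1.0):
            break  # no y-orthogonal structure left
        w_o = w_o / n_wo
        t_o = xr @ w_o
        p_o = xr.T @ t_o / (t_o @ t_o)
        xr = xr - np.outer(t_o, p_o)
        w_os.append(w_o)
        t_os.append(t_o)
        p_os.append(p_o)

    t = xr @ w
    tt = float(t @ t)
    p = xr.T @ t / tt
    c = float(yc @ t / tt)

    expl_x = tt * float(p @ p) + sum(
        float(t_o @ t_o) * float(p_o @ p_o) for t_o, p_o in zip(t_os, p_os)
    )
    r2x = expl_x / x0_ss if x0_ss > 0 else 0.0
    resid = yc - t * c
    yss = float(yc @ yc)
    r2y = 1.0 - float(resid @ resid) / yss if yss > 0 else 0.0

    n_k = len(w_os)
    pdim = x.shape[1]
    return OPLSCore(
        w=w,
        t=t,
        p=p,
        c=c,
        w_orth=np.column_stack(w_os) if n_k else np.zeros((pdim, 0)),
        t_orth=np.column_stack(t_os) if n_k else np.zeros((x.shape[0], 0)),
        p_orth=np.column_stack(p_os) if n_k else np.zeros((pdim, 0)),
        y_mean=y_mean,
        r2x_cum=r2x,
        r2y=r2y,
    )


def predict_oplsda_core(
    core: OPLSCore, x_new: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Apply the stored orthogonal filtering to new scaled data and score it.

    Returns (predictive scores, predicted y on the 0/1 scale, class calls by
    0.5 threshold). Deterministic.
    """
    x_new = np.asarray(x_new, dtype=float)
    if x_new.ndim == 1:
        x_new = x_new[None, :]
    if x_new.shape[1] != core.w.size:
        raise ValueError("column count does not match fitted model")
    xr = x_new.copy()
    for k in range(core.n_orth):
        t_o = xr @ core.w_orth[:, k]
        xr = xr - np.outer(t_o, core.p_orth[:, k])
    t = xr @ core.w
    y_hat = t * core.c + core.y_mean
    calls = (y_hat >= 0.5).astype(int)
    return t, y_hat, calls


@dataclass
class PLS1Model:
    """Multi-component NIPALS PLS1 (single y), used for the permutation
    refits (and, with one component, as the n_orth = 0 reference)."""

    W: np.ndarray  # (p, A) weights, unit norm
    T: np.ndarray  # (n, A) scores
    P: np.ndarray  # (p, A) loadings
    c: np.ndarray  # (A,) y-loadings
    y_mean: float
    r2x_cum: float
    r2y: float


def nipals_pls1(x: np.ndarray, y: np.ndarray, n_comp: int) -> PLS1Model:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    y_mean = float(y.mean())
    yc = y - y_mean
    x0_ss = float((x**2).sum())
    yss = float(yc @ yc)
    xr = x.copy()
    yr = yc.copy()
    Ws, Ts, Ps, cs = [], [], [], []
    for _ in range(n_comp):
        w = xr.T @ yr
        nw = np.linalg.norm(w)
        if nw == 0:
            break
        w = w / nw
        t = xr @ w
        tt = float(t @ t)
        if tt == 0:
            break
        p = xr.T @ t / tt
        ca = float(yr @ t / tt)
        xr = xr - np.outer(t, p)
        yr = yr - t * ca
        Ws.append(w)
        Ts.append(t)
        Ps.append(p)
        cs.append(ca)
    if not Ws:
        raise ValueError("PLS1: no component could be extracted")
    W = np.column_stack(Ws)
    T = np.column_stack(Ts)
    P = np.column_stack(Ps)
    expl_x = sum(float(T[:, a] @ T[:, a]) * float(P[:, a] @ P[:, a])
                 for a in range(T.shape[1]))
    return PLS1Model(
        W=W,
        T=T,
        P=P,
        c=np.array(cs),
        y_mean=y_mean,
        r2x_cum=expl_x / x0_ss if x0_ss > 0 else 0.0,
        r2y=1.0 - float(yr @ yr) / yss if yss > 0 else 0.0,
    )


def predict_pls1(model: PLS1Model, x_new: np.ndarray) -> np.ndarray:
    """Predicted y (0/1 scale) for new scaled data, by sequential deflation."""
    x_new = np.asarray(x_new, dtype=float)
    if x_new.ndim == 1:
        x_new = x_new[None, :]
    xr = x_new.copy()
    y_hat = np.full(x_new.shape[0], model.y_mean)
    for a in range(model.W.shape[1]):
        t = xr @ model.W[:, a]
        xr = xr - np.outer(t, model.P[:, a])
        y_hat = y_hat + t * model.c[a]
    return y_hat


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    folds: np.ndarray        # fold index per sample
    y_pred: np.ndarray       # out-of-fold prediction per sample (0/1 scale)
    press: float
    ss: float

    @property
    def q2(self) -> float:
        return 1.0 - self.press / self.ss


def assign_folds(y: np.ndarray, folds: int, sample_ids: list[str] | None = None
                 ) -> np.ndarray:
    """Deterministic interleaved fold assignment: samples ordered by
    (class, id) take folds 0, 1, 2, ... cyclically. Seed-free."""
    y = np.asarray(y)
    n = y.size
    if folds < 2:
        raise ValueError("need folds >= 2")
    if folds > n:
        raise ValueError("more folds than samples")
    ids = sample_ids if sample_ids is not None else [f"{i:06d}" for i in range(n)]
    order = sorted(range(n), key=lambda i: (str(y[i]), str(ids[i])))
    assignment = np.empty(n, dtype=int)
    for pos, i in enumerate(order):
        assignment[i] = pos % folds
    return assignment


def cross_validate_q2(
    x_raw: np.ndarray | BinMatrix,
    y: np.ndarray,
    n_orth: int = 1,
    folds: int = 7,
    model: str = "oplsda",
    sample_ids: list[str] | None = None,
    fold_assignment: np.ndarray | None = None,
) -> CVResult:
    """k-fold cross-validated Q² = 1 − PRESS/SS.

    For every fold the scaler is re-fit on the training rows only, the model
    (OPLS-DA ``1P + n_orth O``, or PLS-DA with ``1 + n_orth`` components when
    ``model="plsda"``) is fit on the scaled training rows, and the held-out
    rows are predicted with the training scaler. Every sample is predicted
    exactly once; SS is the total corrected sum of squares of y.
    """
    if isinstance(x_raw, BinMatrix):
        if sample_ids is None:
            sample_ids = x_raw.sample_ids
        x_raw = x_raw.values
    x_raw = np.asarray(x_raw, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    assignment = (
        np.asarray(fold_assignment)
        if fold_assignment is not None
        else assign_folds(y, folds, sample_ids)
    )
    y_pred = np.full(y.size, np.nan)
    for k in np.unique(assignment):
        test = assignment == k
        train = ~test
        y_train = y[train]
        if np.unique(y_train).size < 2:
            raise ValueError(f"fold {k}: training split contains a single class")
        scaler = ParetoScaler.fit(x_raw[train])
        x_tr = scaler.transform(x_raw[train])
        x_te = scaler.transform(x_raw[test])
        if model == "oplsda":
            core = fit_oplsda_core(x_tr, y_train, n_orth=n_orth)
            _, y_hat, _ = predict_oplsda_core(core, x_te)
        elif model == "plsda":
            pls = nipals_pls1(x_tr, y_train, n_comp=1 + n_orth)
            y_hat = predict_pls1(pls, x_te)
        else:
            raise ValueError(f"unknown model kind {model!r}")
        y_pred[test] = y_hat
    press = float(((y - y_pred) ** 2).sum())
    ss = float(((y - y.mean()) ** 2).sum())
    return CVResult(folds=assignment, y_pred=y_pred, press=press, ss=ss)


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class OPLSDA:
    """Two-class OPLS-DA model on an (unscaled) bucket matrix.

    Parameters
    ----------
    matrix : BinMatrix or (n, p) array of normalized bucket areas
    labels : class label per sample (taken from the BinMatrix groups if absent)
    classes : pair (negative_class, positive_class); y is coded 0/1 in this
        order. Defaults to the two labels in sorted order.
    n_orth : number of orthogonal components (default 1, i.e. "1P + 1O")
    """

    def __init__(
        self,
        matrix: BinMatrix | np.ndarray,
        labels: list[str] | None = None,
        classes: tuple[str, str] | None = None,
        n_orth: int = 1,
    ):
        if isinstance(matrix, BinMatrix):
            self.matrix = matrix
            self.x_raw = matrix.values
            self.sample_ids = list(matrix.sample_ids)
            labels = labels if labels is not None else [str(g) for g in matrix.groups]
            self.bin_names = matrix.grid.column_names()
        else:
            self.matrix = None
            self.x_raw = np.asarray(matrix, dtype=float)
            self.sample_ids = [f"s{i:04d}" for i in range(self.x_raw.shape[0])]
            self.bin_names = [f"x{j}" for j in range(self.x_raw.shape[1])]
            if labels is None:
                raise ValueError("labels are required with a plain array")
        self.labels = [str(l) for l in labels]
        present = sorted(set(self.labels))
        if classes is None:
            if len(present) != 2:
                raise ValueError(f"need exactly 2 classes, found {present}")
            classes = (present[0], present[1])
        unknown = set(self.labels) - set(classes)
        if unknown:
            raise ValueError(f"labels outside {classes}: {sorted(unknown)}")
        self.classes = classes
        self.y = np.array([1.0 if l == classes[1] else 0.0 for l in self.labels])
        if min((self.y == 0).sum(), (self.y == 1).sum()) < 2:
            raise ValueError("each class needs at least 2 samples")
        self.n_orth = int(n_orth)

    def fit(self, folds: int = 7, cv: bool = True) -> "OPLSDAResults":
        x_scaled, scaler = pareto_scale(self.x_raw)
        core = fit_oplsda_core(x_scaled, self.y, n_orth=self.n_orth)
        cv_res = (
            cross_validate_q2(
                self.x_raw, self.y, n_orth=self.n_orth, folds=folds,
                model="oplsda", sample_ids=self.sample_ids,
            )
            if cv
            else None
        )
        return OPLSDAResults(
            model=self, scaler=scaler, x_scaled=x_scaled, core=core, cv=cv_res
        )


@dataclass
class OPLSDAResults:
    """Fitted OPLS-DA: weights/scores/loadings, fit and prediction summaries."""

    model: OPLSDA
    scaler: ParetoScaler
    x_scaled: np.ndarray
    core: OPLSCore
    cv: CVResult | None = None
    _extras: dict = field(default_factory=dict, repr=False)

    # -- basic accessors ----------------------------------------------------
    @property
    def r2x_cum(self) -> float:
        return self.core.r2x_cum

    @property
    def r2y_cum(self) -> float:
        return self.core.r2y

    @property
    def q2_cum(self) -> float | None:
        return self.cv.q2 if self.cv is not None else None

    @property
    def component_spec(self) -> str:
        return self.core.component_spec

    @property
    def n_components(self) -> int:
        """Total components (predictive + orthogonal), the A of CV-ANOVA."""
        return 1 + self.core.n_orth

    def predict(self, new_matrix: BinMatrix | np.ndarray):
        """Scale new (raw) data with the training scaler, filter, and score."""
        x = new_matrix.values if isinstance(new_matrix, BinMatrix) else new_matrix
        return predict_oplsda_core(self.core, self.scaler.transform(x))

    def scores_frame(self) -> pd.DataFrame:
        """Scores table (sample_id, group, t_pred, t_orth1, ...) for plotting."""
        df = pd.DataFrame(
            {"sample_id": self.model.sample_ids, "group": self.model.labels,
             "t_pred": self.core.t}
        )
        for k in range(self.core.n_orth):
            df[f"t_orth{k + 1}"] = self.core.t_orth[:, k]
        return df

    # -- diagnostics (delegate to sibling modules) --------------------------
    def permutation_test(self, n_perm: int = 500, seed: int = 0,
                         mode: str = "plsda"):
        from .validation import permutation_test

        return permutation_test(
            self.model.x_raw, self.model.y, n_orth=self.core.n_orth,
            n_perm=n_perm, seed=seed, mode=mode,
            sample_ids=self.model.sample_ids, fitted=self,
        )

    def cv_anova(self):
        from .validation import cv_anova

        if self.cv is None:
            raise ValueError("fit with cv=True before CV-ANOVA")
        return cv_anova(self.cv, self.n_components, len(self.model.y))

    def s_plot(self) -> pd.DataFrame:
        from .biomarkers import compute_s_plot

        return compute_s_plot(self, self.x_scaled)

    def vip(self, include_orthogonal: bool = True) -> pd.DataFrame:
        from .biomarkers import compute_vip

        return compute_vip(self, include_orthogonal=include_orthogonal)

    def plot_scores(self, ax=None):
        """Predictive-vs-first-orthogonal scores plot, colored by class."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t2 = (self.core.t_orth[:, 0] if self.core.n_orth
              else np.zeros_like(self.core.t))
        for marker, cls in zip(("o", "^"), self.model.classes):
            mask = np.array(self.model.labels) == cls
            ax.scatter(self.core.t[mask], t2[mask], label=cls, marker=marker)
        ax.axvline(0.0, lw=0.5, color="grey")
        ax.set_xlabel("t (predictive)")
        ax.set_ylabel("t_orth 1" if self.core.n_orth else "0")
        ax.legend()
        return ax

    # -- report -------------------------------------------------------------
    def summary(self) -> str:
        neg, pos = self.model.classes
        q2 = self.q2_cum
        lines = [
            "OPLS-DA summary",
            "===============",
            f"comparison:   {neg} vs {pos}  "
            f"(n = {int((self.model.y == 0).sum())} vs {int((self.model.y == 1).sum())})",
            f"components:   {self.component_spec}",
            f"R2X(cum):     {self.r2x_cum:.3f}",
            f"R2Y(cum):     {self.r2y_cum:.3f}",
            f"Q2(cum):      {q2:.3f}" if q2 is not None else "Q2(cum):      n/a",
        ]
        if self.scaler.zero_variance.any():
            nz = int(self.scaler.zero_variance.sum())
            lines.append(f"note:         {nz} zero-variance bin(s) centered only")
        return "\n".join(lines)
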