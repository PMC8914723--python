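"""PCA diagnostics and PLS-DA classification with a 0.5 decision baseline.

The discriminant model is a NIPALS PLS1 regression of the 0/1 class code on
the (centered, optionally autoscaled) absorbance matrix:

    y = X β + e,     X = T Pᵀ + E_x,     y = sum_a q_a t_a + e_y

with unit-norm weight vectors W, scores T = X W(PᵀW)⁻¹ and y-loadings q.
A sample is called a foreign material when its predicted score ŷ is at or
above the 0.5 midpoint between the class targets 0 (vegetable) and 1 (FM).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold

from .core import (
    ConfusionCounts,
    SpectraSet,
    confusion_counts,
    metrics,
)

__all__ = [
    "PCAResult",
    "PLSDAModel",
    "ModelReport",
    "DECISION_THRESHOLD",
    "fit_pca",
    "fit_plsda",
    "predict_plsda",
    "choose_n_lv",
    "evaluate_model",
]

DECISION_THRESHOLD = 0.5
_TOL = 1e-12


@dataclass
class PCAResult:
    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    mean_spectrum: np.ndarray


def fit_pca(S: SpectraSet, n_components: int) -> PCAResult:
    """Column-mean-centered PCA via SVD (scikit-learn, full solver)."""
    bound = min(S.n_samples - 1, S.n_wavelengths)
    if not 1 <= n_components <= bound:
        raise ValueError(f"n_components must be in [1, {bound}]")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(S.absorbance)
    return PCAResult(
        scores=scores,
        loadings=pca.components_.T,
        explained_variance_ratio=pca.explained_variance_ratio_,
        mean_spectrum=pca.mean_,
    )


@dataclass
class PLSDAModel:
    """Fitted NIPALS PLS1 discriminant model (see module docstring)."""

    n_lv: int
    wavelengths: np.ndarray
    W: np.ndarray  # unit-norm X-weights, (J, n_lv)
    T: np.ndarray  # calibration X-scores, (n, n_lv)
    P: np.ndarray  # X-loadings, (J, n_lv)
    U: np.ndarray  # y-score vectors (response residual per component)
    q: np.ndarray  # y-loadings, (n_lv,)
    beta: np.ndarray  # regression vector on the *raw* variable scale
    intercept: float
    x_mean: np.ndarray
    y_mean: float
    x_scale: np.ndarray | None  # per-variable divisor when autoscaled
    Ex: np.ndarray  # X residual after deflation
    Ey: np.ndarray  # y residual after deflation
    threshold: float = DECISION_THRESHOLD

    @property
    def beta_scaled(self) -> np.ndarray:
        """β on the centered/scaled working variables (the 'weighted' β)."""
        return self.beta if self.x_scale is None else self.beta * self.x_scale

    def to_json(self) -> str:
        payload = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in asdict(self).items()
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "PLSDAModel":
        raw = json.loads(text)
        for key in ("wavelengths", "W", "T", "P", "U", "q", "beta",
                    "x_mean", "x_scale", "Ex", "Ey"):
            if raw[key] is not None:
                raw[key] = np.asarray(raw[key], dtype=float)
        return cls(**raw)


def _nipals_pls1(
    X: np.ndarray, y: np.ndarray, n_lv: int, min_components: int = 1
) -> tuple[np.ndarray, ...]:
    """Core NIPALS loop on pre-centered data; truncates on rank exhaustion."""
    n, J = X.shape
    Xc = X.copy()
    yc = y.copy()
    W, T, P, U, q = [], [], [], [], []
    for a in range(n_lv):
        w = Xc.T @ yc
        norm = np.linalg.norm(w)
        if norm < 1e-10:
            if a < min_components:
                raise ValueError("degenerate deflation: zero-norm weight vector")
            break
        w /= norm
        t = Xc @ w
        tt = float(t @ t)
        if tt < _TOL:
            if a < min_components:
                raise ValueError("degenerate deflation: zero-variance score")
            break
        p = Xc.T @ t / tt
        q_a = float(yc @ t) / tt
        U.append(yc.copy())
        Xc -= np.outer(t, p)
        yc = yc - q_a * t
        W.append(w)
        T.append(t)
        P.append(p)
        q.append(q_a)
    return (
        np.column_stack(W), np.column_stack(T), np.column_stack(P),
        np.column_stack(U), np.asarray(q), Xc, yc,
    )


def _pls1_beta(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> np.ndarray:
    return W @ np.linalg.solve(P.T @ W, q)


def fit_plsda(
    S: SpectraSet, n_lv: int, autoscale: bool = False
) -> PLSDAModel:
    """Fit a PLS-DA model of the 0/1 class code on the absorbance matrix.

    ``autoscale=True`` divides each centered variable by its standard
    deviation before fitting — required when the β vector is read as the
    *weighted* regression coefficient for waveband selection.
    """
    y = S.labels.astype(float)
    if len(np.unique(S.labels)) < 2:
        raise ValueError("both classes must be present to fit PLS-DA")
    bound = min(S.n_samples - 1, S.n_wavelengths)
    if not 1 <= n_lv <= bound:
        raise ValueError(f"n_lv must be in [1, {bound}]")
    X = S.absorbance
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    x_scale = None
    if autoscale:
        x_scale = X.std(axis=0, ddof=1)
        if np.any(x_scale < _TOL):
            raise ValueError("constant variable cannot be autoscaled")
        Xc = Xc / x_scale
    W, T, P, U, q, Ex, Ey = _nipals_pls1(Xc, y - y_mean, n_lv)
    beta_work = _pls1_beta(W, P, q)
    beta = beta_work / x_scale if autoscale else beta_work
    intercept = y_mean - float(x_mean @ beta)
    return PLSDAModel(
        n_lv=W.shape[1],
        wavelengths=S.grid.values.copy(),
        W=W, T=T, P=P, U=U, q=q,
        beta=beta, intercept=intercept,
        x_mean=x_mean, y_mean=y_mean, x_scale=x_scale,
        Ex=Ex, Ey=Ey,
    )


def predict_plsda(
    m: PLSDAModel, S: SpectraSet
) -> tuple[np.ndarray, np.ndarray]:
    """Predicted scores ŷ and hard classes (FM iff ŷ >= threshold)."""
    if S.n_wavelengths != m.wavelengths.size or not np.allclose(
        S.grid.values, m.wavelengths
    ):
        raise ValueError("wavelength grid does not match the fitted model")
    y_hat = m.intercept + S.absorbance @ m.beta
    classes = (y_hat >= m.threshold).astype(int)
    return y_hat, classes


# --- cross-validation helpers (shared with band selection) ------------------


def _fit_predict_raw(
    X_tr: np.ndarray, y_tr: np.ndarray, X_te: np.ndarray, n_lv: int
) -> np.ndarray:
    """Fast path: fit on raw arrays (centering only) and score a test block."""
    x_mean = X_tr.mean(axis=0)
    y_mean = float(y_tr.mean())
    n_lv = min(n_lv, max(1, min(X_tr.shape[0] - 1, X_tr.shape[1])))
    W, T, P, U, q, _, _ = _nipals_pls1(X_tr - x_mean, y_tr - y_mean, n_lv)
    beta = _pls1_beta(W, P, q)
    return y_mean + (X_te - x_mean) @ beta


def cv_misclassification(
    X: np.ndarray,
    y: np.ndarray,
    n_lv: int,
    folds: int,
    seed: int,
) -> tuple[float, float]:
    """Stratified k-fold CV error fraction and mean decision margin.

    The margin of a prediction is its signed distance from the 0.5 baseline
    toward the correct class; the mean margin breaks ties between candidate
    variable sets that all reach the same (often zero) error.
    """
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    errors = 0
    margin_sum = 0.0
    for train, test in skf.split(X, y):
        y_hat = _fit_predict_raw(X[train], y[train].astype(float), X[test], n_lv)
        pred = (y_hat >= DECISION_THRESHOLD).astype(int)
        errors += int(np.sum(pred != y[test]))
        signs = np.where(y[test] == 1, 1.0, -1.0)
        margin_sum += float(np.sum((y_hat - DECISION_THRESHOLD) * signs))
    return errors / y.size, margin_sum / y.size


def choose_n_lv(
    S: SpectraSet, max_lv: int, folds: int = 10, seed: int = 0
) -> int:
    """Smallest LV count minimising stratified k-fold CV misclassification."""
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if max_lv < 1:
        raise ValueError("max_lv must be >= 1")
    counts = np.bincount(S.labels, minlength=2)
    if folds > counts.min():
        raise ValueError("more folds than samples in the smaller class")
    X, y = S.absorbance, S.labels
    errors = [
        cv_misclassification(X, y, lv, folds, seed)[0]
        for lv in range(1, max_lv + 1)
    ]
    return int(np.argmin(errors)) + 1  # argmin returns the first (smallest) LV


@dataclass
class ModelReport:
    """Confusion counts plus the derived percentages for one data partition."""

    counts: ConfusionCounts
    sensitivity: float
    specificity: float
    accuracy: float
    n_lv: int
    partition: str

    def row(self) -> dict:
        """Flat summary row (counts first, metrics at 2 d.p. presentation)."""
        c = self.counts
        return {
            "partition": self.partition,
            "n_samples": c.total,
            "correct_vegetables": c.tp,
            "correct_fms": c.tn,
            "sensitivity_pct": round(self.sensitivity, 2),
            "specificity_pct": round(self.specificity, 2),
            "accuracy_pct": round(self.accuracy, 2),
            "n_lv": self.n_lv,
        }


def evaluate_model(
    m: PLSDAModel, S: SpectraSet, partition_tag: str = "validation"
) -> ModelReport:
    """Predict a partition and report Tp/Fn/Tn/Fp with the derived metrics."""
    if S.n_samples == 0:
        raise ValueError("cannot evaluate on an empty set")
    _, pred = predict_plsda(m, S)
    c = confusion_counts(S.labels, pred)
    sens, spec, acc = metrics(c)
    return ModelReport(
        counts=c, sensitivity=sens, specificity=spec, accuracy=acc,
        n_lv=m.n_lv, partition=partition_tag,
    )
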