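"""PCA, PLS regression and PLS-DA with cross-validated component selection.

Modelling objects follow the statsmodels convention: a model is constructed
from data, ``fit()`` returns a results object carrying the estimates, and the
results object predicts and summarises.  Thin functional wrappers
(:func:`pca_fit`, :func:`pls_fit`, ...) are provided for pipeline use.

PLS latent variables are extracted by NIPALS with deflation (the classic
PLS1/PLS2 algorithm, via scikit-learn's implementation); with all components
retained on full-rank data it coincides with ordinary least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression as _SkPLS
from sklearn.model_selection import KFold

from .grid import SpectraSet, Spectrum

__all__ = [
    "PCAResults",
    "pca_fit",
    "pca_transform",
    "PLSModel",
    "PLSResults",
    "pls_fit",
    "pls_predict",
    "select_components_cv",
]


def _matrix(X) -> np.ndarray:
    if isinstance(X, SpectraSet):
        return X.X
    if isinstance(X, Spectrum):
        return X.absorbance[None, :]
    return np.asarray(X, dtype=float)


# ---------------------------------------------------------------------------
# PCA

@dataclass
class PCAResults:
    """Mean-centred SVD principal components.

    ``loadings`` is k x p with orthonormal rows; each row's
    largest-magnitude element is forced positive (sign convention) so that
    loadings are reproducible across SVD implementations.
    """

    mean_: np.ndarray
    loadings: np.ndarray
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]

    def transform(self, X) -> np.ndarray:
        return (_matrix(X) - self.mean_) @ self.loadings.T

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        return np.asarray(scores) @ self.loadings + self.mean_

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "component": np.arange(1, self.n_components + 1),
            "explained_variance": self.explained_variance,
            "explained_variance_ratio": self.explained_variance_ratio,
        })


def pca_fit(X, k: int) -> PCAResults:
    """Fit a k-component PCA by SVD of the mean-centred matrix."""
    M = _matrix(X)
    n, p = M.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 samples")
    if not (1 <= k <= min(n - 1, p)):
        raise ValueError(f"k must be in [1, {min(n - 1, p)}], got {k}")
    mean = M.mean(axis=0)
    U, s, Vt = np.linalg.svd(M - mean, full_matrices=False)
    var = s**2 / (n - 1)
    total = var.sum()
    loadings = Vt[:k].copy()
    # sign convention: largest-|.| element of each loading positive
    for row in loadings:
        j = int(np.argmax(np.abs(row)))
        if row[j] < 0:
            row *= -1.0
    ratio = var[:k] / total if total > 0 else np.zeros(k)
    return PCAResults(mean, loadings, var[:k], ratio)


def pca_transform(results: PCAResults, X) -> np.ndarray:
    return results.transform(X)


# ---------------------------------------------------------------------------
# PLS

@dataclass
class PLSResults:
    """Fitted PLS estimates; prediction is reproducible from the
    coefficients alone (yhat = X @ coef + intercept)."""

    mode: str
    n_components: int
    coef_: np.ndarray              # p x q
    intercept_: np.ndarray         # q
    x_weights_: np.ndarray
    x_loadings_: np.ndarray
    y_loadings_: np.ndarray
    x_scores_: np.ndarray
    classes_: Optional[np.ndarray] = None

    def predict_raw(self, X) -> np.ndarray:
        return _matrix(X) @ self.coef_ + self.intercept_

    def predict(self, X) -> np.ndarray:
        """Fractions (regression) or class labels via argmax (discriminant)."""
        raw = self.predict_raw(X)
        if self.mode == "discriminant":
            return self.classes_[np.argmax(raw, axis=1)]
        return raw[:, 0] if raw.shape[1] == 1 else raw

    def summary(self) -> pd.DataFrame:
        rows = [
            ("mode", self.mode),
            ("n_components", self.n_components),
            ("n_features", self.coef_.shape[0]),
            ("n_targets", self.coef_.shape[1]),
            ("coef_norm", float(np.linalg.norm(self.coef_))),
        ]
        return pd.DataFrame(rows, columns=["quantity", "value"])


class PLSModel:
    """Partial least squares model (regression or discriminant).

    Parameters
    ----------
    X : SpectraSet or (n, p) array
    y : responses; for ``mode="discriminant"`` integer class labels that are
        one-hot encoded internally, for ``mode="regression"`` real targets.
    """

    def __init__(self, X, y=None, mode: str = "regression"):
        if isinstance(X, SpectraSet) and y is None:
            y = X.labels
            mode = "discriminant" if X.label_kind == "origin" else "regression"
        if mode not in ("regression", "discriminant"):
            raise ValueError(f"unknown mode {mode!r}")
        self.X = _matrix(X)
        self.mode = mode
        y = np.asarray(y)
        if mode == "discriminant":
            self.classes_ = np.unique(y)
            if self.classes_.size < 2:
                raise ValueError("discriminant mode needs >= 2 classes")
            self.Y = (y[:, None] == self.classes_[None, :]).astype(float)
        else:
            self.classes_ = None
            self.Y = y.astype(float).reshape(len(y), -1)

    def fit(self, n_components: int) -> PLSResults:
        n, p = self.X.shape
        if not (1 <= n_components <= min(n - 1, p)):
            raise ValueError(
                f"n_components must be in [1, {min(n - 1, p)}], got {n_components}")
        sk = _SkPLS(n_components=n_components, scale=False)
        sk.fit(self.X, self.Y)
        coef = sk.coef_.T.copy()                      # p x q
        # fold the centring into an explicit intercept so that
        # yhat = X @ coef + intercept reproduces the fit exactly
        intercept = self.Y.mean(axis=0) - self.X.mean(axis=0) @ coef
        return PLSResults(
            mode=self.mode,
            n_components=n_components,
            coef_=coef,
            intercept_=np.atleast_1d(intercept).copy(),
            x_weights_=sk.x_weights_.copy(),
            x_loadings_=sk.x_loadings_.copy(),
            y_loadings_=sk.y_loadings_.copy(),
            x_scores_=sk.x_scores_.copy(),
            classes_=self.classes_,
        )


def pls_fit(X, y, n_components: int, mode: str = "regression") -> PLSResults:
    return PLSModel(X, y, mode=mode).fit(n_components)


def pls_predict(results: PLSResults, X) -> np.ndarray:
    return results.predict(X)


# ---------------------------------------------------------------------------
# Cross-validated component selection

def select_components_cv(X, y, folds: int = 10, max_k: int = 15,
                         mode: str = "regression", seed: int = 0) -> int:
    """Pick the PLS component count by k-fold cross-validation.

    Scores RMSECV (regression) or accuracy (discriminant) for k = 1..max_k
    and applies the one-standard-error rule: the smallest k whose mean CV
    score is within one standard error of the best.  Fold assignment is
    deterministic given ``seed``.
    """
    M = _matrix(X)
    y = np.asarray(y)
    n = M.shape[0]
    if n < folds:
        raise ValueError(f"need at least {folds} samples for {folds}-fold CV")
    max_k = int(min(max_k, M.shape[1], n - np.ceil(n / folds) - 1))
    if max_k < 1:
        raise ValueError("no admissible component count")
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(kf.split(M))
    scores = np.empty((max_k, folds))
    for ki, k in enumerate(range(1, max_k + 1)):
        for fi, (tr, te) in enumerate(splits):
            try:
                res = PLSModel(M[tr], y[tr], mode=mode).fit(k)
            except ValueError:
                scores[ki, fi] = np.inf if mode == "regression" else -np.inf
                continue
            pred = res.predict(M[te])
            if mode == "regression":
                scores[ki, fi] = float(np.sqrt(np.mean((pred - y[te]) ** 2)))
            else:
                scores[ki, fi] = float(np.mean(pred == y[te]))
    mean = scores.mean(axis=1)
    se = scores.std(axis=1, ddof=1) / np.sqrt(folds)
    if mode == "regression":
        best = int(np.argmin(mean))
        ok = mean <= mean[best] + se[best]
    else:
        best = int(np.argmax(mean))
        ok = mean >= mean[best] - se[best]
    return int(np.nonzero(ok)[0][0]) + 1


class PLSDAClassifier:
    """fit/predict adapter over discriminant PLS for the evaluation harness.

    ``n_components`` may be an integer or ``"cv"`` to select by 10-fold
    cross-validation on the training block.
    """

    def __init__(self, n_components=10, seed: int = 0, max_k: int = 15):
        self.n_components = n_components
        self.seed = seed
        self.max_k = max_k
        self.results_: Optional[PLSResults] = None

    def fit(self, X, y):
        if self.n_components == "cv":
            k = select_components_cv(X, y, mode="discriminant",
                                     max_k=self.max_k, seed=self.seed)
        else:
            k = int(self.n_components)
        k = min(k, _matrix(X).shape[0] - 1)
        self.results_ = PLSModel(X, y, mode="discriminant").fit(k)
        return self

    def predict(self, X):
        return self.results_.predict(X)
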