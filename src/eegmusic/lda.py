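"""Fisher-criterion linear discriminant analysis, built from scatter matrices.

The projection maximises the Fisher criterion
``J(w) = (w^T S_b w) / (w^T S_w w)`` where ``S_w = sum_i S_i`` is the
pooled within-class scatter (``S_i = sum_{x in X_i} (x - m_i)(x - m_i)^T``)
and ``S_b = sum_i N_i (m_i - m)(m_i - m)^T`` the between-class scatter.
The optimal directions are the leading generalized eigenvectors of
``(S_b, S_w + reg*I)``; at most c-1 carry a nonzero criterion, so six
emotion classes yield a 5-dimensional embedding.

When the feature dimension exceeds the sample count (wavelet family),
``S_w`` is singular; a ridge term ``reg*I`` regularises it, and the
eigenproblem is solved in the span of the centred data (where every
direction with nonzero between-class scatter lives), which keeps the
solve O(n^3) instead of O(d^3).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.linalg
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y


class SingularScatterError(np.linalg.LinAlgError):
    """S_w is singular and no regularisation was requested."""


def scatter_matrices(X: np.ndarray, y: np.ndarray):
    """(S_w, S_b, class_means, global_mean, class_counts, classes)."""
    classes, counts = np.unique(y, return_counts=True)
    if np.any(counts < 2):
        raise ValueError("every class needs at least 2 rows")
    d = X.shape[1]
    m = X.mean(axis=0)
    Sw = np.zeros((d, d))
    Sb = np.zeros((d, d))
    means = np.empty((len(classes), d))
    for i, c in enumerate(classes):
        Xi = X[y == c]
        mi = Xi.mean(axis=0)
        means[i] = mi
        Z = Xi - mi
        Sw += Z.T @ Z
        diff = (mi - m)[:, None]
        Sb += len(Xi) * (diff @ diff.T)
    return Sw, Sb, means, m, counts, classes


def fisher_criterion(w: np.ndarray, Sw: np.ndarray, Sb: np.ndarray) -> float:
    """J(w) for a single direction."""
    w = np.asarray(w, dtype=float).ravel()
    return float((w @ Sb @ w) / (w @ Sw @ w))


class FisherLDA(TransformerMixin, BaseEstimator):
    """Supervised projection maximising between/within scatter ratio.

    Parameters
    ----------
    n_components : int, default 5
        Output dimensions; must be <= n_classes - 1.
    reg : float or "auto", default "auto"
        Ridge added to S_w as ``reg * I``.  "auto" uses
        ``1e-4 * trace(S_w) / d``; 0 requires a nonsingular S_w.
    standardize : bool, default True
        Scale columns to zero mean / unit variance before the solve
        (an invertible affine map, so the criterion is unchanged, but
        the default ridge becomes scale-free).
    """

    def __init__(self, n_components: int = 5, reg: float | str = "auto",
                 standardize: bool = True):
        self.n_components = n_components
        self.reg = reg
        self.standardize = standardize

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        classes = np.unique(y)
        c = len(classes)
        if c < 2:
            raise ValueError("need at least 2 classes")
        if self.n_components > c - 1:
            raise ValueError(
                f"n_components={self.n_components} exceeds n_classes-1={c - 1}"
            )
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0) if self.standardize else np.ones(X.shape[1])
        self.scale_[self.scale_ == 0] = 1.0
        Xs = (X - self.mean_) / self.scale_

        n, d = Xs.shape
        if d > n:
            # solve inside the span of the centred data: S_w and S_b map
            # the span to itself, and every direction with w^T S_b w > 0
            # lies in it, so the restriction is exact
            U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
            rank = int(np.sum(s > s[0] * 1e-12))
            basis = Vt[:rank]
            Z = Xs @ basis.T
            W_small, evals, Sw, Sb, _ = self._solve(Z, y)
            W = basis.T @ W_small
            means = np.vstack([Xs[y == k].mean(axis=0) for k in classes])
        else:
            W, evals, Sw, Sb, means = self._solve(Xs, y)
        # sign convention: largest-magnitude component positive
        for j in range(W.shape[1]):
            k = np.argmax(np.abs(W[:, j]))
            if W[k, j] < 0:
                W[:, j] = -W[:, j]
        self.classes_ = classes
        self.scalings_ = W
        self.eigenvalues_ = evals
        self.Sw_ = Sw
        self.Sb_ = Sb
        self.class_means_ = means
        self.class_counts_ = np.array([np.sum(y == k) for k in classes])
        self.n_features_in_ = d
        return self

    def _solve(self, X, y):
        Sw, Sb, means, m, counts, _ = scatter_matrices(X, y)
        d = X.shape[1]
        if self.reg == "auto":
            reg = 1e-4 * np.trace(Sw) / d
        else:
            reg = float(self.reg)
        A = Sw + reg * np.eye(d)
        if reg == 0:
            cond = np.linalg.cond(Sw)
            if not np.isfinite(cond) or cond > 1e12:
                raise SingularScatterError(
                    "within-class scatter is singular; set reg > 0"
                )
        evals, evecs = scipy.linalg.eigh(Sb, A)
        order = np.argsort(evals)[::-1][: self.n_components]
        return evecs[:, order], evals[order], Sw, Sb, means

    def transform(self, X):
        check_is_fitted(self, "scalings_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, model expects {self.n_features_in_}"
            )
        return ((X - self.mean_) / self.scale_) @ self.scalings_


def fit_lda(X, y, k: int = 5, reg: float | str = "auto",
            standardize: bool = True) -> FisherLDA:
    """Functional wrapper over :class:`FisherLDA`."""
    return FisherLDA(n_components=k, reg=reg, standardize=standardize).fit(X, y)


def transform(model: FisherLDA, X) -> np.ndarray:
    return model.transform(X)


def scatter_plot_data(model: FisherLDA, X, y) -> pd.DataFrame:
    """First two discriminant coordinates plus labels, for plotting."""
    if model.scalings_.shape[1] < 2:
        raise ValueError("need at least 2 discriminant components")
    Z = model.transform(X)
    return pd.DataFrame({"ld1": Z[:, 0], "ld2": Z[:, 1], "label": np.asarray(y)})
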