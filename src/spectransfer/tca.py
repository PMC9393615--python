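"""Transfer Component Analysis, primal (linear feature-space) variant.

TCA learns a projection W (d features -> m components) that shrinks the
maximum mean discrepancy (MMD) between a source and a target feature
distribution while preserving pooled variance.  With stacked data
X ((n_s + n_t) x d), MMD block matrix L (1/n_s^2 within source, 1/n_t^2
within target, -1/(n_s n_t) across) and centring matrix H = I - 11'/n, the
primal components are the top-m eigenvectors of

    (X'LX + mu I)^{-1} X'HX

— the numerator rewards retained variance, the denominator penalizes
domain mean discrepancy, and mu regularizes.  "Primal" means the projection
acts on the d raw feature columns rather than on an n x n kernel matrix;
with 16 index features and hundreds of samples this is the natural form.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator, TransformerMixin


def mmd_linear(Xs: np.ndarray, Xt: np.ndarray) -> float:
    """Squared Euclidean distance between domain column-mean vectors."""
    Xs = np.atleast_2d(np.asarray(Xs, dtype=float))
    Xt = np.atleast_2d(np.asarray(Xt, dtype=float))
    if Xs.shape[1] != Xt.shape[1]:
        raise ValueError("source/target feature dimensions differ")
    if Xs.shape[0] == 0 or Xt.shape[0] == 0:
        raise ValueError("empty domain matrix")
    diff = Xs.mean(axis=0) - Xt.mean(axis=0)
    return float(diff @ diff)


def _mmd_block(n_s: int, n_t: int) -> np.ndarray:
    n = n_s + n_t
    L = np.empty((n, n))
    L[:n_s, :n_s] = 1.0 / n_s**2
    L[n_s:, n_s:] = 1.0 / n_t**2
    L[:n_s, n_s:] = L[n_s:, :n_s] = -1.0 / (n_s * n_t)
    return L


class TransferComponentAnalysis(BaseEstimator, TransformerMixin):
    """Primal TCA as an sklearn-style transformer.

    Parameters
    ----------
    n_components : int, default 5
        Embedding dimensionality m (must be <= number of features).
    mu : float, default 1.0
        Ridge regularizer on the MMD term; must be > 0 unless X'LX is
        full rank.

    Attributes
    ----------
    W_ : (d, m) array — projection with unit-norm columns, sign fixed so
        each column's largest-magnitude entry is positive.
    eigenvalues_ : (m,) array — retained eigenvalues, descending.
    """

    def __init__(self, n_components: int = 5, mu: float = 1.0):
        self.n_components = n_components
        self.mu = mu

    def fit(self, X_source: np.ndarray, X_target: np.ndarray | None = None):
        if X_target is None:
            raise ValueError("TCA requires both source and target matrices")
        Xs = np.atleast_2d(np.asarray(X_source, dtype=float))
        Xt = np.atleast_2d(np.asarray(X_target, dtype=float))
        if Xs.shape[1] != Xt.shape[1]:
            raise ValueError("source/target feature dimensions differ")
        n_s, n_t = Xs.shape[0], Xt.shape[0]
        if n_s < 2 or n_t < 2:
            raise ValueError("each domain needs >= 2 samples")
        d = Xs.shape[1]
        m = self.n_components
        if not 1 <= m <= d:
            raise ValueError(f"n_components must be in [1, {d}], got {m}")

        X = np.vstack([Xs, Xt])
        n = n_s + n_t
        L = _mmd_block(n_s, n_t)
        H = np.eye(n) - np.ones((n, n)) / n
        A = X.T @ L @ X + self.mu * np.eye(d)
        B = X.T @ H @ X
        try:
            M = np.linalg.solve(A, B)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "X'LX + mu*I is singular; increase mu"
            ) from exc
        eigvals, eigvecs = np.linalg.eig(M)
        # complex parts are numerical artifacts of the non-symmetric product
        order = np.argsort(-eigvals.real)[:m]
        vals = eigvals.real[order]
        W = eigvecs[:, order].real
        # re-orthonormalize and fix signs for determinism
        W, _ = np.linalg.qr(W)
        for col in range(W.shape[1]):
            peak = np.argmax(np.abs(W[:, col]))
            if W[peak, col] < 0:
                W[:, col] = -W[:, col]
        self.W_ = W
        self.eigenvalues_ = vals
        self.n_features_in_ = d
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.W_.shape[0]:
            raise ValueError(
                f"X has {X.shape[1]} features, model expects {self.W_.shape[0]}"
            )
        return X @ self.W_

    def fit_transform_pair(
        self, X_source: np.ndarray, X_target: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        self.fit(X_source, X_target)
        return self.transform(X_source), self.transform(X_target)


def fit_tca_primal(
    Xs: np.ndarray, Xt: np.ndarray, m: int = 5, mu: float = 1.0
) -> TransferComponentAnalysis:
    """Functional wrapper over :class:`TransferComponentAnalysis`."""
    return TransferComponentAnalysis(n_components=m, mu=mu).fit(Xs, Xt)


def tca_eigensystem_oracle(
    Xs: np.ndarray, Xt: np.ndarray, mu: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Independent route: generalized eigenproblem B v = lambda A v.

    Solved directly with scipy's generalized solver (no explicit inverse);
    used to cross-check the fitted components.  Returns (eigenvalues,
    eigenvectors) sorted descending by real part.
    """
    Xs = np.atleast_2d(np.asarray(Xs, dtype=float))
    Xt = np.atleast_2d(np.asarray(Xt, dtype=float))
    X = np.vstack([Xs, Xt])
    n_s, n_t = Xs.shape[0], Xt.shape[0]
    n = n_s + n_t
    d = X.shape[1]
    A = X.T @ _mmd_block(n_s, n_t) @ X + mu * np.eye(d)
    B = X.T @ (np.eye(n) - np.ones((n, n)) / n) @ X
    vals, vecs = scipy.linalg.eig(B, A)
    order = np.argsort(-vals.real)
    return vals.real[order], vecs[:, order].real
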