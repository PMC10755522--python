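"""Relevance vector regression (sparse Bayesian kernel regression).

A scikit-learn-compatible implementation of Tipping-style relevance vector
regression: a linear model over kernel basis functions centred on the
training points, with an independent Gaussian prior precision per weight.
Evidence maximisation drives most precisions to infinity, pruning their
basis functions; the survivors are the "relevance vectors".

Only what the brain-age pipeline needs is implemented: linear and RBF
kernels, deterministic fitting, and mean prediction.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["RVR"]

_PRUNE_ALPHA = 1e9
_BETA_MAX = 1e8  # noise-precision cap; keeps the posterior solvable on noiseless data


def _posterior_factor(phi_a: np.ndarray, a_a: np.ndarray, beta: float):
    """Cholesky factor of the posterior precision, with escalating jitter
    if round-off pushes it off the positive-definite cone."""
    H = beta * (phi_a.T @ phi_a)
    H[np.diag_indices_from(H)] += a_a
    scale = np.trace(H) / len(a_a)
    for jitter in (0.0, 1e-10, 1e-8, 1e-6, 1e-4):
        try:
            Hj = H if jitter == 0.0 else H + jitter * scale * np.eye(len(a_a))
            return cho_factor(Hj, lower=True)
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError("posterior precision not positive definite")


class RVR(BaseEstimator, RegressorMixin):
    """Relevance vector regression.

    Parameters
    ----------
    kernel : 'linear' or 'rbf'
    gamma : RBF width; None means 1 / (n_features * X.var()), matching the
        'scale' convention of the SVR it competes against.
    max_iter : cap on evidence-maximisation sweeps.
    tol : convergence threshold on the largest change in log alpha.
    """

    def __init__(
        self,
        kernel: str = "linear",
        gamma: float | None = None,
        max_iter: int = 300,
        tol: float = 1e-3,
    ):
        self.kernel = kernel
        self.gamma = gamma
        self.max_iter = max_iter
        self.tol = tol

    def _kernel_matrix(self, A: np.ndarray, B: np.ndarray) -> np.ndarray:
        if self.kernel == "linear":
            return A @ B.T
        if self.kernel == "rbf":
            g = self.gamma_
            sq = (
                np.sum(A * A, axis=1)[:, None]
                + np.sum(B * B, axis=1)[None, :]
                - 2.0 * A @ B.T
            )
            return np.exp(-g * np.maximum(sq, 0.0))
        raise ValueError(f"unknown kernel {self.kernel!r}")

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n = X.shape[0]
        self.X_train_ = X
        if self.kernel == "rbf":
            var = X.var()
            self.gamma_ = self.gamma if self.gamma is not None else 1.0 / (X.shape[1] * var if var > 0 else X.shape[1])
        else:
            self.gamma_ = None
        self._y_mean = float(y.mean())
        t = y - self._y_mean

        K = self._kernel_matrix(X, X)
        phi = np.concatenate([np.ones((n, 1)), K], axis=1)  # bias + basis per point
        m = phi.shape[1]

        active = np.arange(m)
        alpha = np.full(m, 1e-4)
        t_var = t.var()
        beta = 1.0 / max(t_var, 1e-8)  # noise precision init

        mu_active = np.zeros(m)
        for _ in range(self.max_iter):
            phi_a = phi[:, active]
            a_a = alpha[active]
            chol = _posterior_factor(phi_a, a_a, beta)
            mu_active = beta * cho_solve(chol, phi_a.T @ t)
            sigma_diag = np.diag(cho_solve(chol, np.eye(len(a_a))))

            gamma_i = 1.0 - a_a * sigma_diag
            new_alpha = np.where(
                mu_active**2 > 1e-12, np.maximum(gamma_i, 1e-12) / np.maximum(mu_active**2, 1e-12), _PRUNE_ALPHA * 10
            )
            resid = t - phi_a @ mu_active
            denom = max(float(resid @ resid), 1e-12)
            beta = min(max(n - float(gamma_i.sum()), 1e-3) / denom, _BETA_MAX)

            delta = np.max(np.abs(np.log(new_alpha) - np.log(a_a)))
            alpha[active] = new_alpha
            keep = new_alpha < _PRUNE_ALPHA
            if not keep.any():  # pathological: keep the best basis function
                keep[np.argmin(new_alpha)] = True
            active = active[keep]
            if delta < self.tol:
                break

        self.active_ = active
        self.weights_ = np.zeros(m)
        phi_a = phi[:, active]
        a_a = alpha[active]
        chol = _posterior_factor(phi_a, a_a, beta)
        self.weights_[active] = beta * cho_solve(chol, phi_a.T @ t)
        self.beta_ = beta
        return self

    def predict(self, X):
        check_is_fitted(self, "weights_")
        X = np.asarray(X, dtype=float)
        out = np.full(X.shape[0], self._y_mean)
        act = self.active_
        if len(act) == 0:
            return out
        has_bias = act[0] == 0
        basis_idx = act[1:] - 1 if has_bias else act - 1
        if has_bias:
            out = out + self.weights_[0]
        if len(basis_idx):
            K = self._kernel_matrix(X, self.X_train_[basis_idx])
            out = out + K @ self.weights_[act[1:]] if has_bias else out + K @ self.weights_[act]
        return out
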