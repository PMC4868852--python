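"""Independent brute-force oracles used by the tests.

These deliberately take different computational routes from the package:
CCA by explicit whitening + SVD of the full covariance blocks (the package
reduces via an economy SVD and solves a generalized eigenproblem), the SVM
by a direct QP solve of the soft-margin dual, and dense-descriptor
histograms by a per-pixel Python loop.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def cca_correlations_oracle(X: np.ndarray, Y: np.ndarray, eps: float = 0.0):
    """Canonical correlations by regularized whitening + SVD."""
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    S11 = Xc.T @ Xc / (n - 1) + eps * np.eye(X.shape[1])
    S22 = Yc.T @ Yc / (n - 1) + eps * np.eye(Y.shape[1])
    S12 = Xc.T @ Yc / (n - 1)

    def inv_sqrt(S):
        w, V = np.linalg.eigh(S)
        return V @ np.diag(1.0 / np.sqrt(w)) @ V.T

    M = inv_sqrt(S11) @ S12 @ inv_sqrt(S22)
    return np.clip(np.linalg.svd(M, compute_uv=False), 0.0, 1.0)


def sample_cca_leading_correlation(X: np.ndarray, Y: np.ndarray) -> float:
    """Leading sample canonical correlation (tiny ridge for conditioning)."""
    return float(cca_correlations_oracle(X, Y, eps=1e-8)[0])


def svm_dual_objective_oracle(X: np.ndarray, y: np.ndarray, C: float) -> float:
    """Optimal soft-margin linear-SVM objective via a direct dual QP solve.

    maximize  Σα − ½ ΣΣ α_i α_j y_i y_j ⟨x_i, x_j⟩
    s.t.      0 ≤ α ≤ C,  Σ α_i y_i = 0.

    By strong duality the optimum equals the primal objective
    ½‖w‖² + C Σ hinge.
    """
    y = y.astype(float)
    Q = (y[:, None] * y[None, :]) * (X @ X.T)
    n = len(y)

    def neg_dual(alpha):
        return -(alpha.sum() - 0.5 * alpha @ Q @ alpha)

    def neg_dual_grad(alpha):
        return -(np.ones(n) - Q @ alpha)

    res = minimize(
        neg_dual,
        np.full(n, min(C, 1.0) / 2),
        jac=neg_dual_grad,
        bounds=[(0.0, C)] * n,
        constraints=[{"type": "eq", "fun": lambda a: a @ y,
                      "jac": lambda a: y}],
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-14},
    )
    assert res.success, res.message
    return float(-res.fun)


def svm_primal_objective(model, X: np.ndarray, y: np.ndarray, C: float) -> float:
    """Primal objective of a fitted linear SVM."""
    w = model.coef_.ravel()
    margins = y * (X @ w + model.intercept_[0])
    return float(0.5 * w @ w + C * np.maximum(0.0, 1.0 - margins).sum())


def dense_patch_histogram_oracle(img: np.ndarray, r0: int, c0: int,
                                 patch: int, spatial_bins: int,
                                 orientation_bins: int) -> np.ndarray:
    """Per-pixel loop computing one patch's descriptor, pre-normalization."""
    gy, gx = np.gradient(img.astype(float))
    mag = np.hypot(gx, gy)
    ang = np.mod(np.arctan2(gy, gx), 2 * np.pi)
    edges = np.round(np.linspace(0, patch, spatial_bins + 1)).astype(int)
    desc = np.zeros((spatial_bins, spatial_bins, orientation_bins))
    for r in range(r0, r0 + patch):
        for c in range(c0, c0 + patch):
            bi = np.searchsorted(edges, r - r0, side="right") - 1
            bj = np.searchsorted(edges, c - c0, side="right") - 1
            bi = min(bi, spatial_bins - 1)
            bj = min(bj, spatial_bins - 1)
            ob = min(
                int(ang[r, c] / (2 * np.pi / orientation_bins)),
                orientation_bins - 1,
            )
            desc[bi, bj, ob] += mag[r, c]
    return desc.ravel()


def normalize_clamp(vec: np.ndarray, clamp: float = 0.2) -> np.ndarray:
    """Standard dense-SIFT post-processing: l2, clamp, l2."""
    out = vec.astype(float).copy()
    n = np.linalg.norm(out)
    if n > 1e-12:
        out /= n
    out = np.minimum(out, clamp)
    n = np.linalg.norm(out)
    if n > 1e-12:
        out /= n
    return out
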