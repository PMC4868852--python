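"""Two-view canonical correlation analysis and the augmented representation.

Given paired feature matrices ``X1, X2`` (one row per subject), CCA finds
projection bases ``B1, B2`` maximizing the correlation of the projected
views in a common space, subject to unit regularized variance:

    max  b1' S12 b2   s.t.  b1'(S11 + eps I)b1 = b2'(S22 + eps I)b2 = 1,

solved by generalized eigen-decomposition of the (reduced) covariance
blocks.  Because imaging feature dimensions typically exceed the subject
count, the fit first reduces each view to its row space via an economy SVD
of the centered data; with a ridge ``eps > 0`` the canonical directions
provably lie in that span, so the reduction is exact, and with ``eps = 0``
a rank-deficient view raises a :class:`~neurofuse.exceptions.NumericalError`
instructing the caller to regularize.

The augmented representation stacks original and projected features per
subject, ``F = [X1; X2; Z1; Z2]``, so a downstream classifier sees both the
modality-specific and the shared information.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import ConfigurationError, InputDataError, NumericalError

__all__ = ["CCAFusion", "AugmentedFeature", "fit_cca", "project_cca",
           "augment_features", "save_cca", "load_cca"]

_MODEL_FORMAT_VERSION = 1
_RANK_RTOL = 1e-10


class CCAFusion(BaseEstimator, TransformerMixin):
    """Regularized two-view CCA.

    Parameters
    ----------
    n_components : int or None
        Number of canonical pairs.  None keeps ``min(rank1, rank2, n-1)``
        components and then drops those with correlation below
        ``min_correlation``.
    epsilon : float or "auto"
        Ridge added to each view's covariance diagonal.  "auto" uses
        ``1e-3 ×`` the mean diagonal of the pooled covariance; 0 requires
        both views to have full column rank.
    min_correlation : float
        Truncation threshold used only when ``n_components`` is None.

    Attributes
    ----------
    B1_, B2_ : (d, c) projection bases, columns ordered by descending
        canonical correlation and normalized to unit regularized variance.
    correlations_ : (c,) canonical correlations in [0, 1].
    mean1_, mean2_ : training column means.
    epsilon_ : the ridge actually used.
    """

    def __init__(self, n_components: int | None = None,
                 epsilon: float | str = "auto", min_correlation: float = 0.01):
        self.n_components = n_components
        self.epsilon = epsilon
        self.min_correlation = min_correlation

    # ------------------------------------------------------------------
    def fit(self, X: np.ndarray, Y: np.ndarray) -> "CCAFusion":
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
            # Unequal feature dimensions are fine mathematically, but the
            # subject counts must agree.
            raise InputDataError(
                f"views must be 2-D with equal subject counts, got "
                f"{X.shape} and {Y.shape}"
            )
        n = X.shape[0]
        if n < 3:
            raise InputDataError(f"need at least 3 subjects, got {n}")
        if isinstance(self.epsilon, str):
            if self.epsilon != "auto":
                raise ConfigurationError(f"epsilon must be a float or 'auto', got {self.epsilon!r}")
        elif self.epsilon < 0:
            raise ConfigurationError(f"epsilon must be >= 0, got {self.epsilon}")

        self.mean1_ = X.mean(axis=0)
        self.mean2_ = Y.mean(axis=0)
        Xc = X - self.mean1_
        Yc = Y - self.mean2_
        denom = n - 1

        if self.epsilon == "auto":
            pooled_diag = (np.sum(Xc**2) + np.sum(Yc**2)) / (
                denom * (X.shape[1] + Y.shape[1])
            )
            eps = 1e-3 * pooled_diag
        else:
            eps = float(self.epsilon)
        self.epsilon_ = eps

        # Economy SVD of each centered view: row-space coordinates.
        U1, s1, V1t = np.linalg.svd(Xc, full_matrices=False)
        U2, s2, V2t = np.linalg.svd(Yc, full_matrices=False)
        r1 = int(np.sum(s1 > _RANK_RTOL * max(s1[0], 1e-300)))
        r2 = int(np.sum(s2 > _RANK_RTOL * max(s2[0], 1e-300)))
        if eps == 0.0 and (r1 < X.shape[1] or r2 < Y.shape[1]):
            raise NumericalError(
                "a view's covariance is singular (rank-deficient data with "
                "epsilon=0); set epsilon > 0 to regularize"
            )
        U1, s1, V1 = U1[:, :r1], s1[:r1], V1t[:r1].T
        U2, s2, V2 = U2[:, :r2], s2[:r2], V2t[:r2].T

        # Reduced covariance blocks (r1 and r2 dimensional).
        R11 = np.diag(s1**2 / denom + eps)
        R22 = np.diag(s2**2 / denom + eps)
        R12 = (s1[:, None] * (U1.T @ U2) * s2[None, :]) / denom

        A = np.zeros((r1 + r2, r1 + r2))
        A[:r1, r1:] = R12
        A[r1:, :r1] = R12.T
        B = np.zeros_like(A)
        B[:r1, :r1] = R11
        B[r1:, r1:] = R22
        try:
            w, V = scipy.linalg.eigh(A, B)
        except scipy.linalg.LinAlgError as exc:  # pragma: no cover
            raise NumericalError(
                "generalized eigen-decomposition failed; set epsilon > 0"
            ) from exc

        c_max = min(r1, r2, n - 1)
        order = np.argsort(w)[::-1][:c_max]
        a_red = V[:r1, order]
        b_red = V[r1:, order]
        # Rescale to unit regularized variance per view (eigh normalizes
        # the concatenated vector instead).
        a_norm = np.sqrt(np.einsum("ij,ii,ij->j", a_red, R11, a_red))
        b_norm = np.sqrt(np.einsum("ij,ii,ij->j", b_red, R22, b_red))
        a_norm[a_norm < 1e-300] = 1.0
        b_norm[b_norm < 1e-300] = 1.0
        a_red = a_red / a_norm
        b_red = b_red / b_norm
        corr = np.einsum("ij,ik,kj->j", a_red, R12, b_red)
        # Flip signs so correlations are nonnegative.
        flip = corr < 0
        b_red[:, flip] *= -1
        corr = np.abs(corr)
        corr = np.clip(corr, 0.0, 1.0)
        # Deterministic sign convention: the largest-magnitude entry of each
        # view-1 basis column is positive (the pair (a, b) is otherwise only
        # determined up to a joint sign).
        B1_full = V1 @ a_red
        signs = np.sign(B1_full[np.argmax(np.abs(B1_full), axis=0),
                                np.arange(B1_full.shape[1])])
        signs[signs == 0] = 1.0
        a_red *= signs
        b_red *= signs

        if self.n_components is not None:
            if self.n_components < 1:
                raise ConfigurationError(
                    f"n_components must be >= 1, got {self.n_components}"
                )
            c = min(self.n_components, c_max)
        else:
            keep = corr >= self.min_correlation
            c = max(1, int(keep.sum())) if corr.size else 0
        self.B1_ = V1 @ a_red[:, :c]
        self.B2_ = V2 @ b_red[:, :c]
        self.correlations_ = corr[:c]
        self.n_components_ = c
        return self

    # ------------------------------------------------------------------
    def transform(self, X: np.ndarray, Y: np.ndarray):
        """Project both views: ``Z = (X − mean) B``, shape (m, c) each."""
        if not hasattr(self, "B1_"):
            raise InputDataError("CCA model is not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        if X.shape[1] != self.B1_.shape[0] or Y.shape[1] != self.B2_.shape[0]:
            raise InputDataError(
                f"feature dimensions ({X.shape[1]}, {Y.shape[1]}) do not "
                f"match fitted ({self.B1_.shape[0]}, {self.B2_.shape[0]})"
            )
        Z1 = (X - self.mean1_) @ self.B1_
        Z2 = (Y - self.mean2_) @ self.B2_
        return Z1, Z2

    def fit_transform(self, X, Y):
        return self.fit(X, Y).transform(X, Y)


@dataclass
class AugmentedFeature:
    """Augmented per-subject representation ``F = [X1; X2; Z1; Z2]``.

    ``F`` stacks the blocks feature-wise (columns, since subjects are
    rows); ``blocks`` records each block's column slice so any original
    block can be recovered exactly.
    """

    F: np.ndarray
    blocks: dict[str, slice]

    def block(self, name: str) -> np.ndarray:
        return self.F[:, self.blocks[name]]


def augment_features(X1, X2, Z1, Z2) -> AugmentedFeature:
    """Stack original and canonical features in the order X1, X2, Z1, Z2.

    No rescaling is applied; the first block equals ``X1`` exactly.
    """
    mats = [np.atleast_2d(np.asarray(m, dtype=float)) for m in (X1, X2, Z1, Z2)]
    counts = {m.shape[0] for m in mats}
    if len(counts) != 1:
        raise InputDataError(
            f"blocks must agree on the subject count, got {[m.shape[0] for m in mats]}"
        )
    blocks = {}
    start = 0
    for name, m in zip(("X1", "X2", "Z1", "Z2"), mats):
        blocks[name] = slice(start, start + m.shape[1])
        start += m.shape[1]
    return AugmentedFeature(F=np.hstack(mats), blocks=blocks)


# ---------------------------------------------------------------------------
# Thin functional wrappers and persistence.

def fit_cca(X1, X2, n_components=None, epsilon="auto") -> CCAFusion:
    return CCAFusion(n_components=n_components, epsilon=epsilon).fit(X1, X2)


def project_cca(model: CCAFusion, X1, X2):
    return model.transform(X1, X2)


def save_cca(model: CCAFusion, path: str | Path) -> None:
    """Serialize a fitted model; reload reproduces it exactly."""
    if not hasattr(model, "B1_"):
        raise InputDataError("cannot save an unfitted CCA model")
    np.savez(
        path,
        version=np.array([_MODEL_FORMAT_VERSION]),
        B1=model.B1_,
        B2=model.B2_,
        correlations=model.correlations_,
        mean1=model.mean1_,
        mean2=model.mean2_,
        epsilon=np.array([model.epsilon_]),
    )


def load_cca(path: str | Path) -> CCAFusion:
    data = np.load(path, allow_pickle=False)
    version = int(data["version"][0])
    if version != _MODEL_FORMAT_VERSION:
        raise InputDataError(f"unsupported CCA model format version {version}")
    model = CCAFusion()
    model.B1_ = data["B1"]
    model.B2_ = data["B2"]
    model.correlations_ = data["correlations"]
    model.mean1_ = data["mean1"]
    model.mean2_ = data["mean2"]
    model.epsilon_ = float(data["epsilon"][0])
    model.n_components_ = model.B1_.shape[1]
    return model
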