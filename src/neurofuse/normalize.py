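"""Feature normalization: power (signed root), lp, and L2A/L2AL2W.

Encoded histogram vectors vary both across subjects (cohort-level scale of
each histogram bin) and within subjects (overall vector magnitude).  Power
normalization ``x ← sign(x)|x|^ρ`` suppresses bursty components before the
linear classifier; the two-step L2AL2W scheme first scales every feature
dimension by its l2 norm over the *training* subjects (across-subject step,
whose divisors are reused unchanged for test subjects to avoid leakage) and
then scales every subject vector to unit l2 norm (within-subject step).
The two steps do not commute.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import ConfigurationError, InputDataError

__all__ = [
    "NormalizationConfig",
    "power_normalize",
    "lp_normalize",
    "vector_normalize",
    "normalize_cohort_l2al2w",
    "PowerNormalizer",
    "L2AL2W",
]

_EPS = 1e-12


@dataclass(frozen=True)
class NormalizationConfig:
    """A sequence of normalization schemes applied in order.

    Valid scheme names: ``none, l1, l2, sqrt`` (power with exponent
    ``rho``), ``L2A``, ``L2AL2W``.  The cohort-level schemes (L2A, L2AL2W)
    cannot be applied through :func:`vector_normalize`; they need training
    statistics and go through :class:`L2AL2W`.
    """

    order: tuple[str, ...] = ("sqrt", "L2AL2W")
    rho: float = 0.5

    def __post_init__(self):
        valid = {"none", "l1", "l2", "sqrt", "L2A", "L2AL2W"}
        for scheme in self.order:
            if scheme not in valid:
                raise ConfigurationError(
                    f"unknown normalization scheme {scheme!r}; valid: {sorted(valid)}"
                )
        if not 0.0 <= self.rho <= 1.0:
            raise ConfigurationError(f"rho must be in [0, 1], got {self.rho}")


def _check_finite(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise InputDataError("input contains non-finite values")
    return v


def power_normalize(v: np.ndarray, rho: float = 0.5) -> np.ndarray:
    """Element-wise signed power ``sign(x)|x|^rho`` (rho=0.5: signed sqrt)."""
    if not 0.0 <= rho <= 1.0:
        raise ConfigurationError(f"rho must be in [0, 1], got {rho}")
    v = _check_finite(v)
    return np.sign(v) * np.abs(v) ** rho


def lp_normalize(v: np.ndarray, p: int = 2) -> np.ndarray:
    """Scale to unit lp norm along the last axis; zero vectors pass through."""
    v = _check_finite(v)
    norm = np.linalg.norm(v, ord=p, axis=-1, keepdims=True)
    return np.divide(v, norm, out=v.copy(), where=norm > _EPS)


def vector_normalize(v: np.ndarray, cfg: NormalizationConfig) -> np.ndarray:
    """Apply the per-vector schemes of ``cfg.order`` in sequence."""
    out = _check_finite(v)
    for scheme in cfg.order:
        if scheme == "none":
            continue
        if scheme == "l1":
            out = lp_normalize(out, 1)
        elif scheme == "l2":
            out = lp_normalize(out, 2)
        elif scheme == "sqrt":
            out = power_normalize(out, cfg.rho)
        else:
            raise ConfigurationError(
                f"scheme {scheme!r} needs cohort statistics; use the L2AL2W "
                "transformer instead"
            )
    return out


class PowerNormalizer(BaseEstimator, TransformerMixin):
    """Stateless signed-power transformer (default rho = 0.5)."""

    def __init__(self, rho: float = 0.5):
        self.rho = rho

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return power_normalize(X, self.rho)


class L2AL2W(BaseEstimator, TransformerMixin):
    """Inter-subject (A) then intra-subject (W) l2 normalization.

    ``fit`` stores per-dimension l2 norms over the training subjects;
    ``transform`` divides each column by that norm (zero-norm dimensions
    pass through unscaled) and then scales each row to unit l2 norm (zero
    rows pass through).  Set ``within=False`` for the plain L2A scheme.
    """

    def __init__(self, within: bool = True):
        self.within = within

    def fit(self, X: np.ndarray, y=None) -> "L2AL2W":
        X = _check_finite(np.atleast_2d(X))
        self.column_norms_ = np.linalg.norm(X, axis=0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "column_norms_"):
            raise InputDataError("L2AL2W is not fitted")
        X = _check_finite(np.atleast_2d(X))
        if X.shape[1] != self.column_norms_.size:
            raise InputDataError(
                f"feature dimension {X.shape[1]} does not match fitted "
                f"{self.column_norms_.size}"
            )
        out = np.divide(
            X, self.column_norms_, out=X.copy(),
            where=self.column_norms_ > _EPS,
        )
        if self.within:
            out = lp_normalize(out, 2)
        return out


def normalize_cohort_l2al2w(
    train: np.ndarray, test: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None]:
    """Functional L2AL2W: fit on ``train``, apply to both matrices."""
    model = L2AL2W().fit(train)
    train_out = model.transform(train)
    test_out = model.transform(test) if test is not None else None
    return train_out, test_out
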