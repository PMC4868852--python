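"""Explicit feature maps so a linear SVM can emulate additive kernels.

For a homogeneous additive kernel ``k(x, y) = Σ_i k0(x_i, y_i)`` with
``k0(x, y) = sqrt(xy) · K(log(y/x))``, the finite-dimensional map of
Vedaldi & Zisserman samples the kernel signature's spectrum ``κ(ω)`` on a
regular grid of period ``L``: each nonnegative scalar ``x`` maps to the
``2n+1`` values

    [ sqrt(L κ(0) x),
      sqrt(2 L κ(jL) x) cos(jL log x),
      sqrt(2 L κ(jL) x) sin(jL log x) ]   for j = 1..n,

so that ``Ψ(x)·Ψ(y) ≈ k0(x, y)``.  Supported kinds:

- ``linear``    — identity (no map);
- ``hellinger`` — element-wise square root, exact:
  ``Ψ(x)·Ψ(y) = Σ sqrt(x_i y_i)``;
- ``kchi2``     — chi-square kernel ``Σ 2 x y / (x + y)``,
  spectrum ``κ(ω) = sech(πω)``;
- ``kjs``       — Jensen–Shannon kernel, spectrum
  ``κ(ω) = (2 / log 4) · sech(πω) / (1 + 4ω²)``.

The sampled maps require nonnegative inputs (they are meant for normalized
histograms); zeros map to zero blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import ConfigurationError, InputDataError

__all__ = [
    "KernelMapConfig",
    "apply_kernel_map",
    "HomogeneousKernelMap",
    "chi2_kernel_exact",
    "js_kernel_exact",
]

_KINDS = ("linear", "hellinger", "kchi2", "kjs")


@dataclass(frozen=True)
class KernelMapConfig:
    """Kind plus sampling parameters of the approximate map.

    ``order_n`` is the number of spectrum samples per side (output length
    is ``2·order_n + 1`` per input dimension for kchi2/kjs); ``period``
    is the sampling period L.  When None it is chosen from ``order_n``
    (0.8 / 0.5 / 0.4 for n = 1 / 2 / 3, then 2.4/(n+2)): the period must
    shrink as the order grows, otherwise the approximation saturates at
    the aliasing floor of the periodicized kernel instead of converging.
    """

    kind: str = "hellinger"
    order_n: int = 3
    period: float | None = None

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ConfigurationError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if self.kind in ("kchi2", "kjs") and self.order_n < 1:
            raise ConfigurationError(
                f"order_n must be >= 1 for {self.kind}, got {self.order_n}"
            )
        if self.period is not None and self.period <= 0:
            raise ConfigurationError(f"period must be > 0, got {self.period}")

    def resolved_period(self) -> float:
        if self.period is not None:
            return self.period
        return {1: 0.8, 2: 0.5, 3: 0.4}.get(self.order_n, 2.4 / (self.order_n + 2))


def _spectrum(kind: str, omega: np.ndarray) -> np.ndarray:
    sech = 1.0 / np.cosh(np.pi * omega)
    if kind == "kchi2":
        return sech
    if kind == "kjs":
        return (2.0 / np.log(4.0)) * sech / (1.0 + 4.0 * omega**2)
    raise ConfigurationError(f"no spectrum for kind {kind!r}")


def _check_nonnegative(X: np.ndarray, kind: str) -> None:
    neg = np.flatnonzero(X.ravel() < 0)
    if neg.size:
        raise InputDataError(
            f"{kind} kernel map requires nonnegative entries; first "
            f"offending flat index: {int(neg[0])}"
        )


def apply_kernel_map(v: np.ndarray, cfg: KernelMapConfig) -> np.ndarray:
    """Map a vector (or matrix of row vectors) through the explicit map."""
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise InputDataError("input contains non-finite values")
    if cfg.kind == "linear":
        return v.copy()
    if cfg.kind == "hellinger":
        return np.sign(v) * np.sqrt(np.abs(v))

    _check_nonnegative(v, cfg.kind)
    squeeze = v.ndim == 1
    X = np.atleast_2d(v)
    n, L = cfg.order_n, cfg.resolved_period()
    j = np.arange(1, n + 1)
    kappa0 = float(_spectrum(cfg.kind, np.zeros(1))[0])
    kappaj = _spectrum(cfg.kind, j * L)

    out = np.zeros((X.shape[0], X.shape[1], 2 * n + 1))
    pos = X > 0
    logx = np.where(pos, np.log(np.where(pos, X, 1.0)), 0.0)
    out[:, :, 0] = np.sqrt(L * kappa0 * X)
    for jj in range(1, n + 1):
        w = np.sqrt(2.0 * L * kappaj[jj - 1] * X)
        theta = jj * L * logx
        out[:, :, 2 * jj - 1] = w * np.cos(theta)
        out[:, :, 2 * jj] = w * np.sin(theta)
    out[~pos, :] = 0.0
    flat = out.reshape(X.shape[0], -1)
    return flat[0] if squeeze else flat


class HomogeneousKernelMap(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer over :func:`apply_kernel_map`."""

    def __init__(self, kind: str = "hellinger", order_n: int = 3,
                 period: float | None = None):
        self.kind = kind
        self.order_n = order_n
        self.period = period

    def _cfg(self) -> KernelMapConfig:
        return KernelMapConfig(self.kind, self.order_n, self.period)

    def fit(self, X, y=None):
        self._cfg()  # validate
        return self

    def transform(self, X):
        return apply_kernel_map(X, self._cfg())


def chi2_kernel_exact(x: np.ndarray, y: np.ndarray) -> float:
    """Closed-form additive chi-square kernel ``Σ 2 x y / (x + y)``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    s = x + y
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(s > 0, 2.0 * x * y / np.where(s > 0, s, 1.0), 0.0)
    return float(terms.sum())


def js_kernel_exact(x: np.ndarray, y: np.ndarray) -> float:
    """Closed-form Jensen–Shannon kernel with 0·log terms defined as 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    s = x + y

    def _term(a):
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(a > 0, s / np.where(a > 0, a, 1.0), 1.0)
            return np.where(a > 0, (a / 2.0) * np.log2(ratio), 0.0)

    return float((_term(x) + _term(y)).sum())
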