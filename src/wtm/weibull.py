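"""Truncated, rescaled Weibull proxies and KL-divergence fitting.

The two-parameter Weibull density

    h_W(b; λ, k) = (k/λ) (b/λ)^{k-1} exp(-(b/λ)^k),    b ≥ 0, λ > 0, k > 0

is a smooth unimodal family whose scale λ tracks the peak position
("brightness") and whose shape k tracks the spread ("contrast") of a
brightness histogram.  For image work the support is truncated at b = 2.55 —
beyond which the distributions of interest carry no appreciable mass — and the
axis divided by 2.55 so proxies live on [0, 1].  The truncated proxy is
renormalised by the retained mass T(2.55) so it is a proper distribution.

Fitting is an exhaustive grid search minimising the KL divergence of the
observed 256-bin brightness pdf from the proxy, over λ ∈ {0.1, …, 3.0} and
k ∈ {0.1, …, 15.0} in steps of 0.1 (4500 candidate pairs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .core import DEFAULT_BINS, _validate_pdf

TRUNCATION = 2.55
GRID_STEP = 0.1
LAMBDA_MAX = 3.0
K_MAX = 15.0
_KL_FLOOR = 1e-12

__all__ = [
    "WeibullParams",
    "WeibullFit",
    "weibull_pdf_discrete",
    "weibull_cdf",
    "weibull_icdf",
    "kl_divergence",
    "fit_weibull",
    "fitting_grid",
]


@dataclass(frozen=True)
class WeibullParams:
    """Scale/shape pair (λ, k) of a truncated, rescaled Weibull proxy."""

    lam: float
    k: float

    def __post_init__(self) -> None:
        if not (self.lam > 0.0 and self.k > 0.0):
            raise ValueError(f"Weibull parameters must be positive, got {self}")

    def to_dict(self) -> dict:
        return {"lambda": self.lam, "k": self.k}


@dataclass(frozen=True)
class WeibullFit:
    """A fitted proxy: the grid-minimising parameters and their KL divergence (nats)."""

    params: WeibullParams
    kl: float

    def to_dict(self) -> dict:
        return {**self.params.to_dict(), "kl": self.kl}


def _raw_cdf(x, lam: float, k: float):
    """Untruncated Weibull CDF T(x) = 1 - exp(-(x/λ)^k) on the raw axis."""
    x = np.asarray(x, dtype=np.float64)
    with np.errstate(over="ignore", under="ignore"):
        return -np.expm1(-np.power(x / lam, k))


def weibull_cdf(b, params: WeibullParams):
    """Truncation-renormalised CDF on the rescaled [0, 1] brightness axis.

    Returns T(2.55·b) / T(2.55); strictly increasing, 0 at b=0 and 1 at b=1.
    """
    b = np.asarray(b, dtype=np.float64)
    if np.any(b < 0.0) or np.any(b > 1.0):
        raise ValueError("brightness must lie in [0, 1]")
    z = _raw_cdf(TRUNCATION, params.lam, params.k)
    out = _raw_cdf(TRUNCATION * b, params.lam, params.k) / z
    return out if out.ndim else float(out)


def weibull_icdf(p, params: WeibullParams):
    """Closed-form inverse of :func:`weibull_cdf`.

    De-renormalises the probability (q = p·T(2.55)) and inverts the raw CDF:
    b = λ·(-log(1-q))^{1/k} / 2.55.
    """
    p = np.asarray(p, dtype=np.float64)
    if np.any(p < 0.0) or np.any(p > 1.0):
        raise ValueError("probability must lie in [0, 1]")
    z = _raw_cdf(TRUNCATION, params.lam, params.k)
    with np.errstate(divide="ignore", over="ignore"):
        raw = params.lam * np.power(-np.log1p(-p * z), 1.0 / params.k)
    out = np.clip(raw / TRUNCATION, 0.0, 1.0)
    return out if out.ndim else float(out)


def weibull_pdf_discrete(params: WeibullParams, n_bins: int = DEFAULT_BINS) -> np.ndarray:
    """Discrete proxy pdf: renormalised CDF differences at the N bin edges."""
    if int(n_bins) < 2:
        raise ValueError("n_bins must be >= 2")
    edges = np.linspace(0.0, 1.0, int(n_bins) + 1)
    return np.diff(weibull_cdf(edges, params))


def kl_divergence(h: np.ndarray, g: np.ndarray) -> float:
    """KL(h ‖ g) in nats, with 0·log(0/·) = 0 and g floored at 1e-12.

    Non-negative by Gibbs' inequality; zero iff the distributions coincide.
    """
    h = _validate_pdf(h)
    g = _validate_pdf(g)
    if h.shape != g.shape:
        raise ValueError("distributions must have the same number of bins")
    g = np.maximum(g, _KL_FLOOR)
    g = g / g.sum()
    mask = h > 0.0
    return float(np.sum(h[mask] * np.log(h[mask] / g[mask])))


def fitting_grid() -> tuple[np.ndarray, np.ndarray]:
    """The (λ, k) search grid: steps of 0.1, zero excluded (pdf undefined there)."""
    lams = np.round(np.arange(1, int(round(LAMBDA_MAX / GRID_STEP)) + 1) * GRID_STEP, 10)
    ks = np.round(np.arange(1, int(round(K_MAX / GRID_STEP)) + 1) * GRID_STEP, 10)
    return lams, ks


@lru_cache(maxsize=4)
def _grid_log_pdfs(n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Pre-computed (pairs, log-proxy) matrices for the full 4500-pair grid."""
    lams, ks = fitting_grid()
    pairs = np.array([(lam, k) for lam in lams for k in ks])
    logg = np.empty((pairs.shape[0], n_bins))
    for i, (lam, k) in enumerate(pairs):
        g = weibull_pdf_discrete(WeibullParams(lam, k), n_bins)
        g = np.maximum(g, _KL_FLOOR)
        logg[i] = np.log(g / g.sum())
    return pairs, logg


def fit_weibull(h: np.ndarray) -> WeibullFit:
    """Exhaustive KL grid search for the closest Weibull proxy to ``h``.

    Evaluates all 4500 (λ, k) pairs and returns the global minimiser; ties are
    broken by the smallest λ then the smallest k (the enumeration order).
    """
    h = _validate_pdf(h)
    if h[0] >= 1.0 - 1e-12:
        warnings.warn(
            "degenerate histogram (all mass at the darkest bin); "
            "returning the best grid fit anyway",
            stacklevel=2,
        )
    pairs, logg = _grid_log_pdfs(h.shape[0])
    mask = h > 0.0
    self_term = float(np.sum(h[mask] * np.log(h[mask])))
    kls = self_term - logg[:, mask] @ h[mask]
    best = int(np.argmin(kls))  # first minimum == lexicographic (λ, k) tie-break
    lam, k = pairs[best]
    return WeibullFit(WeibullParams(float(lam), float(k)), max(float(kls[best]), 0.0))
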