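"""Tone-curve constructors.

Histogram equalisation (HE) uses the input brightness CDF as the tone curve;
contrast-limited HE (CLHE) equalises against a proxy histogram whose
cumulative has slopes bounded in [m, M]; Weibull tone mapping (WTM) composes
the CDF of the input's Weibull proxy with the inverse CDF of a target proxy,
t(b) = t_out⁻¹(t_in(b)); and the control-point constructor interpolates six
fixed-abscissa points with a monotone piecewise-cubic (PCHIP, the
Fritsch–Carlson scheme).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from .core import (
    DEFAULT_BINS,
    _validate_pdf,
    apply_tonecurve,
    compute_pdf,
    cumulative,
    extract_brightness,
)
from .weibull import WeibullFit, WeibullParams, fit_weibull, weibull_cdf, weibull_icdf

CONTROL_ABSCISSAE = np.array([0.0, 0.2, 0.4, 0.6, 0.8, 1.0])

__all__ = [
    "SlopeBounds",
    "ControlPointSet",
    "he_tonecurve",
    "clhe_proxy",
    "clhe_tonecurve",
    "wtm_tonecurve",
    "wtm_enhance",
    "wtm_approximate",
    "pchip_tonecurve",
    "CONTROL_ABSCISSAE",
]


@dataclass(frozen=True)
class SlopeBounds:
    """Minimum/maximum tone-curve slope for CLHE (defaults m=0.5, M=2)."""

    m: float = 0.5
    M: float = 2.0

    def __post_init__(self) -> None:
        if not (0.0 < self.m <= 1.0 <= self.M):
            raise ValueError(
                f"infeasible slope bounds {self}: need 0 < m <= 1 <= M "
                "for a bounded-slope pdf to sum to 1"
            )


@dataclass(frozen=True)
class ControlPointSet:
    """Six output-brightness ordinates at fixed abscissae {0, 0.2, …, 1}."""

    ordinates: tuple[float, ...]

    def __post_init__(self) -> None:
        y = np.asarray(self.ordinates, dtype=np.float64)
        if y.shape != (6,):
            raise ValueError("exactly 6 control-point ordinates are required")
        if y.min() < 0.0 or y.max() > 1.0:
            raise ValueError("ordinates must lie in [0, 1]")
        if np.any(np.diff(y) <= 0.0):
            raise ValueError("ordinates must be strictly increasing (monotone tone map)")
        object.__setattr__(self, "ordinates", tuple(float(v) for v in y))


def he_tonecurve(pdf: np.ndarray) -> np.ndarray:
    """Histogram-equalisation tone curve: the cumulative of the brightness pdf."""
    return cumulative(pdf)


def clhe_proxy(pdf: np.ndarray, bounds: SlopeBounds = SlopeBounds()) -> np.ndarray:
    """Slope-limited proxy histogram: least-squares projection of ``pdf``.

    Returns the Euclidean projection of the pdf onto
    ``{h' : m/N <= h'_j <= M/N, Σ h' = 1}`` — the unique closest histogram
    whose cumulative tone curve has every slope in [m, M].  The projection is
    a uniform shift clipped to the box, h'_j = clip(h_j + τ, m/N, M/N), with
    the shift τ chosen so the result sums to one.
    """
    pdf = _validate_pdf(pdf)
    n = pdf.shape[0]
    lo, hi = bounds.m / n, bounds.M / n

    def excess(tau: float) -> float:
        return float(np.clip(pdf + tau, lo, hi).sum() - 1.0)

    t_lo = lo - float(pdf.max())
    t_hi = hi - float(pdf.min())
    if excess(t_lo) > 0.0 or excess(t_hi) < 0.0:  # pragma: no cover - guarded by bounds
        raise ValueError("no bounded-slope histogram sums to 1 under these bounds")
    tau = brentq(excess, t_lo, t_hi, xtol=1e-16)
    proxy = np.clip(pdf + tau, lo, hi)
    # absorb residual rounding in the interior bins, keeping the box exact
    residual = 1.0 - proxy.sum()
    interior = (proxy > lo) & (proxy < hi)
    if abs(residual) > 0.0 and interior.any():
        proxy[interior] += residual / interior.sum()
        proxy = np.clip(proxy, lo, hi)
    return proxy


def clhe_tonecurve(pdf: np.ndarray, bounds: SlopeBounds = SlopeBounds()) -> np.ndarray:
    """Contrast-limited HE curve: cumulative of the slope-limited proxy."""
    return cumulative(clhe_proxy(pdf, bounds))


def wtm_tonecurve(
    fit_in: WeibullParams, target: WeibullParams, n_bins: int = DEFAULT_BINS
) -> np.ndarray:
    """Weibull tone map t = t_out⁻¹ ∘ t_in sampled at the N node abscissae."""
    xs = np.arange(1, int(n_bins) + 1, dtype=np.float64) / n_bins
    curve = weibull_icdf(weibull_cdf(xs, fit_in), target)
    # the composition is monotone analytically; enforce it against float noise
    return np.clip(np.maximum.accumulate(curve), 0.0, 1.0)


def wtm_enhance(
    image: np.ndarray, target: WeibullParams, n_bins: int = DEFAULT_BINS
) -> tuple[np.ndarray, np.ndarray, WeibullFit]:
    """Two-parameter WTM enhancement of an image.

    Fits the Weibull proxy of the image's brightness histogram, builds the
    tone curve onto the user-chosen target proxy (λ ≈ brightness, k ≈
    contrast — a *lower* k widens the histogram and raises contrast), and
    applies it.  Returns (enhanced image, tone curve, input fit).
    """
    fit = fit_weibull(compute_pdf(extract_brightness(image), n_bins))
    curve = wtm_tonecurve(fit.params, target, n_bins)
    return apply_tonecurve(image, curve), curve, fit


def wtm_approximate(
    input_img: np.ndarray, output_img: np.ndarray, n_bins: int = DEFAULT_BINS
) -> tuple[np.ndarray, np.ndarray, WeibullFit, WeibullFit]:
    """Closest-WTM approximation of an arbitrary tonal adjustment.

    Fits Weibull proxies to the brightness histograms of the input and of the
    (user-)adjusted output, composes their tone map and applies it to the
    input.  Returns (WTM image, tone curve, input fit, output fit).
    """
    if np.shape(input_img)[:2] != np.shape(output_img)[:2]:
        raise ValueError("input and output images must share dimensions")
    fit_in = fit_weibull(compute_pdf(extract_brightness(input_img), n_bins))
    fit_out = fit_weibull(compute_pdf(extract_brightness(output_img), n_bins))
    curve = wtm_tonecurve(fit_in.params, fit_out.params, n_bins)
    return apply_tonecurve(input_img, curve), curve, fit_in, fit_out


def pchip_tonecurve(cps: ControlPointSet, n_bins: int = DEFAULT_BINS) -> np.ndarray:
    """Monotone PCHIP interpolant through the six control points.

    Shape-preserving piecewise-cubic Hermite interpolation (Fritsch–Carlson
    derivative limiting) sampled at the N node abscissae; passes through every
    control point exactly and never overshoots between knots.
    """
    interp = PchipInterpolator(CONTROL_ABSCISSAE, np.asarray(cps.ordinates))
    xs = np.arange(1, int(n_bins) + 1, dtype=np.float64) / n_bins
    return np.clip(interp(xs), 0.0, 1.0)
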