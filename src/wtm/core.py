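"""Image and brightness primitives.

Images are H×W×3 float arrays with channel values in [0, 1] (8-bit files are
rescaled by 1/255 on load).  Brightness is defined as the per-pixel maximum of
R, G and B — the HSV value channel.  Using the maximum rather than the mean
means that any tone-mapped brightness can be pushed back into the colour image
by pure per-pixel scaling without ever leaving the display range.

A tone curve is a 256-element monotone non-decreasing vector ``s`` where
``s[j-1]`` is the output brightness for input brightness ``j/N``; between the
nodes the curve is evaluated by linear interpolation with an implied (0, 0)
anchor.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_BINS = 256

__all__ = [
    "DEFAULT_BINS",
    "validate_image",
    "extract_brightness",
    "compute_pdf",
    "cumulative",
    "curve_slopes",
    "validate_curve",
    "identity_curve",
    "reconstruct_color",
    "apply_tonecurve",
    "load_image",
    "save_image",
    "save_curve",
    "load_curve",
]


def validate_image(image: np.ndarray) -> np.ndarray:
    """Check RGB-image invariants and return the array as float64.

    Raises ``ValueError`` for non-H×W×3 shapes, non-finite entries or values
    outside [0, 1].
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an H×W×3 RGB array, got shape {image.shape}")
    if image.shape[0] < 1 or image.shape[1] < 1:
        raise ValueError("image must contain at least one pixel")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    if image.min() < 0.0 or image.max() > 1.0:
        raise ValueError("channel values must lie in [0, 1]")
    return image


def extract_brightness(image: np.ndarray) -> np.ndarray:
    """Per-pixel brightness L(x, y) = max(R, G, B)."""
    image = validate_image(image)
    return image.max(axis=2)


def compute_pdf(brightness: np.ndarray, n_bins: int = DEFAULT_BINS) -> np.ndarray:
    """Normalised brightness histogram over ``n_bins`` half-open bins.

    Bin j (1-based) covers ((j-1)/N, j/N]; exact zeros are counted in bin 1 so
    that fully black pixels are not dropped.
    """
    brightness = np.asarray(brightness, dtype=np.float64)
    if brightness.size == 0:
        raise ValueError("empty brightness map")
    if int(n_bins) < 2:
        raise ValueError("n_bins must be >= 2")
    n_bins = int(n_bins)
    if brightness.min() < 0.0 or brightness.max() > 1.0:
        raise ValueError("brightness values must lie in [0, 1]")
    # v in ((j-1)/N, j/N]  <=>  ceil(v*N) == j ; zeros fold into bin 1
    idx = np.ceil(brightness.ravel() * n_bins).astype(np.int64) - 1
    np.clip(idx, 0, n_bins - 1, out=idx)
    counts = np.bincount(idx, minlength=n_bins).astype(np.float64)
    return counts / counts.sum()


def cumulative(pdf: np.ndarray) -> np.ndarray:
    """Running sum s_j = Σ_{i<=j} h_i — the discrete CDF, a valid tone curve."""
    pdf = _validate_pdf(pdf)
    curve = np.cumsum(pdf)
    # guard against float drift past 1
    return np.clip(curve, 0.0, 1.0)


def curve_slopes(curve: np.ndarray) -> np.ndarray:
    """Slope of the tone curve at each node: (s_j - s_{j-1}) * N with s_0 = 0.

    For a curve that is the cumulative of a pdf h this equals N*h exactly.
    """
    curve = np.asarray(curve, dtype=np.float64)
    n = curve.shape[0]
    return np.diff(curve, prepend=0.0) * n


def identity_curve(n_bins: int = DEFAULT_BINS) -> np.ndarray:
    """The null tone curve s_j = j/N (a 45° line)."""
    return np.arange(1, n_bins + 1, dtype=np.float64) / n_bins


def validate_curve(curve: np.ndarray, atol: float = 1e-12) -> np.ndarray:
    """Check tone-curve invariants (monotone non-decreasing, values in [0,1])."""
    curve = np.asarray(curve, dtype=np.float64)
    if curve.ndim != 1 or curve.shape[0] < 2:
        raise ValueError("tone curve must be a 1-D vector of >= 2 values")
    if not np.all(np.isfinite(curve)):
        raise ValueError("tone curve contains non-finite values")
    if curve.min() < -atol or curve.max() > 1.0 + atol:
        raise ValueError("tone-curve values must lie in [0, 1]")
    if np.any(np.diff(curve) < -atol):
        raise ValueError("tone curve must be monotone non-decreasing")
    return np.clip(curve, 0.0, 1.0)


def reconstruct_color(
    image: np.ndarray, l_in: np.ndarray, l_out: np.ndarray
) -> np.ndarray:
    """Rebuild a colour image from adjusted brightness by per-pixel scaling.

    Every channel is multiplied by L_out/L_in, which preserves the R:G:B
    chromatic ratios; pixels with L_in = 0 stay black.  ``l_in`` must be the
    max-channel brightness of ``image``.
    """
    image = validate_image(image)
    l_in = np.asarray(l_in, dtype=np.float64)
    l_out = np.asarray(l_out, dtype=np.float64)
    if l_in.shape != image.shape[:2] or l_out.shape != image.shape[:2]:
        raise ValueError("brightness maps must match the image dimensions")
    if not np.allclose(l_in, image.max(axis=2), atol=1e-12):
        raise ValueError("l_in is not the max-channel brightness of image")
    if l_out.min() < 0.0 or l_out.max() > 1.0:
        raise ValueError("l_out must lie in [0, 1]")
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(l_in > 0.0, l_out / np.where(l_in > 0.0, l_in, 1.0), 0.0)
    out = image * scale[..., None]
    return np.clip(out, 0.0, 1.0)


def _eval_curve(brightness: np.ndarray, curve: np.ndarray) -> np.ndarray:
    n = curve.shape[0]
    xs = np.concatenate(([0.0], np.arange(1, n + 1) / n))
    ys = np.concatenate(([0.0], curve))
    return np.interp(brightness, xs, ys)


def apply_tonecurve(image: np.ndarray, curve: np.ndarray) -> np.ndarray:
    """Tone-map an image: L_out = t(L_in), colour rebuilt by Eq.-of-ratios scaling."""
    image = validate_image(image)
    curve = validate_curve(curve)
    l_in = image.max(axis=2)
    l_out = _eval_curve(l_in, curve)
    return reconstruct_color(image, l_in, l_out)


# ---------------------------------------------------------------------------
# I/O

def load_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit PNG/JPEG/TIFF as a float image in [0, 1]; alpha dropped."""
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim == 3 and arr.shape[2] == 4:
        logger.warning("dropping alpha channel of %s", path)
        arr = arr[:, :, :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"unsupported image shape {arr.shape} in {path}")
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    return validate_image(arr)


def save_image(image: np.ndarray, path: str | Path) -> None:
    """Write a [0, 1] float image as 8-bit, rounding to the nearest level."""
    image = validate_image(image)
    iio.imwrite(Path(path), np.rint(image * 255.0).astype(np.uint8))


def save_curve(curve: np.ndarray, path: str | Path) -> None:
    """Serialise a tone curve to JSON ({"n", "values"}) or single-column CSV."""
    curve = validate_curve(curve)
    path = Path(path)
    if path.suffix.lower() == ".csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            for v in curve:
                writer.writerow([repr(float(v))])
    else:
        payload = {"n": int(curve.shape[0]), "values": [float(v) for v in curve]}
        path.write_text(json.dumps(payload))


def load_curve(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        with open(path, newline="") as fh:
            values = [float(row[0]) for row in csv.reader(fh) if row]
        curve = np.asarray(values, dtype=np.float64)
    else:
        payload = json.loads(path.read_text())
        curve = np.asarray(payload["values"], dtype=np.float64)
        if "n" in payload and int(payload["n"]) != curve.shape[0]:
            raise ValueError("curve length does not match declared n")
    return validate_curve(curve)


def _validate_pdf(pdf: np.ndarray, atol: float = 1e-9) -> np.ndarray:
    pdf = np.asarray(pdf, dtype=np.float64)
    if pdf.ndim != 1 or pdf.shape[0] < 2:
        raise ValueError("pdf must be a 1-D vector of >= 2 bins")
    if pdf.min() < 0.0:
        raise ValueError("pdf bins must be non-negative")
    if abs(pdf.sum() - 1.0) > atol:
        raise ValueError("pdf must sum to 1")
    return pdf
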