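"""Seeded generators for artificially lit seafloor test imagery.

Real benthic survey frames are dominated by a bright central light cone with
radial falloff into a dark periphery, Weibull-distributed brightness texture
from the substrate, and low-saturation substrate colour.  The generator
emulates exactly those statistical features — an i.i.d. truncated-Weibull
brightness field, multiplied by a Gaussian illumination cone, coloured by a
fixed substrate chromaticity — and nothing of the optics (no scattering,
wavelength attenuation or blur).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .core import validate_image
from .tonemap import ControlPointSet, pchip_tonecurve, wtm_enhance
from .weibull import WeibullParams, weibull_icdf

__all__ = [
    "SceneSpec",
    "sample_weibull_brightness",
    "generate_seafloor_image",
    "generate_user_adjustment",
    "write_scene",
]


@dataclass(frozen=True)
class SceneSpec:
    """Recipe for a synthetic artificially lit seafloor frame.

    The texture parameters set the substrate brightness distribution; the
    cone centre/radius are fractions of the frame (radius relative to the
    half-diagonal) and the gain sets how dark the periphery falls relative to
    the centre (0 = no cone).
    """

    height: int = 128
    width: int = 128
    texture: WeibullParams = field(default_factory=lambda: WeibullParams(1.2, 3.0))
    cone_centre: tuple[float, float] = (0.5, 0.5)
    cone_radius: float = 0.45
    cone_gain: float = 0.5
    substrate_hue: float = 0.10
    substrate_saturation: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 16 or self.width < 16:
            raise ValueError("scene dimensions must be at least 16 px")
        if not 0.0 <= self.cone_gain <= 1.0:
            raise ValueError("cone gain must lie in [0, 1]")
        if not 0.0 <= self.substrate_saturation <= 1.0:
            raise ValueError("saturation must lie in [0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["texture"] = self.texture.to_dict()
        return d


def sample_weibull_brightness(params: WeibullParams, n: int, seed: int) -> np.ndarray:
    """Inverse-CDF samples from the truncated, rescaled Weibull distribution.

    Deterministic for a fixed seed; all values lie in (0, 1].
    """
    if n < 1:
        raise ValueError("need at least one sample")
    rng = np.random.default_rng(seed)
    u = 1.0 - rng.random(n)  # in (0, 1]: keeps the samples strictly positive
    return np.asarray(weibull_icdf(u, params))


def _substrate_chromaticity(hue: float, saturation: float) -> np.ndarray:
    """Unit-brightness RGB of the substrate colour (HSV with V = 1)."""
    h = (hue % 1.0) * 6.0
    i = int(h) % 6
    f = h - int(h)
    p, q, t = 1.0 - saturation, 1.0 - saturation * f, 1.0 - saturation * (1.0 - f)
    table = [(1, t, p), (q, 1, p), (p, 1, t), (p, q, 1), (t, p, 1), (1, p, q)]
    return np.array(table[i], dtype=np.float64)


def generate_seafloor_image(spec: SceneSpec) -> np.ndarray:
    """Render a synthetic seafloor frame from a scene recipe.

    Brightness = Weibull texture × Gaussian light cone (1 at the centre,
    1 − gain in the far periphery); colour = brightness × substrate
    chromaticity, so the max channel equals the brightness field exactly.
    """
    rng_seed = spec.seed
    texture = sample_weibull_brightness(
        spec.texture, spec.height * spec.width, rng_seed
    ).reshape(spec.height, spec.width)

    yy, xx = np.mgrid[0 : spec.height, 0 : spec.width]
    cy, cx = spec.cone_centre[0] * (spec.height - 1), spec.cone_centre[1] * (spec.width - 1)
    half_diag = 0.5 * np.hypot(spec.height, spec.width)
    r2 = ((yy - cy) ** 2 + (xx - cx) ** 2) / (spec.cone_radius * half_diag) ** 2
    cone = (1.0 - spec.cone_gain) + spec.cone_gain * np.exp(-0.5 * r2)

    brightness = np.clip(texture * cone, 0.0, 1.0)
    chroma = _substrate_chromaticity(spec.substrate_hue, spec.substrate_saturation)
    return validate_image(brightness[..., None] * chroma[None, None, :])


def generate_user_adjustment(
    image: np.ndarray,
    kind: str,
    params=None,
    seed: int = 0,
) -> np.ndarray:
    """Stand-in for an observer's enhancement of an image.

    ``kind="wtm"`` applies a two-parameter WTM enhancement (``params`` a
    (λ, k) target, or a random on-grid target for ``params=None``);
    ``kind="pchip"`` applies a monotone control-point curve (``params`` six
    increasing ordinates, or a gentle random monotone perturbation of the
    identity).
    """
    from .core import apply_tonecurve

    rng = np.random.default_rng(seed)
    if kind == "wtm":
        if params is None:
            lam = round(rng.integers(8, 21) * 0.1, 1)
            k = round(rng.integers(20, 61) * 0.1, 1)
            target = WeibullParams(lam, k)
        elif isinstance(params, WeibullParams):
            target = params
        else:
            target = WeibullParams(*params)
        enhanced, _, _ = wtm_enhance(image, target)
        return enhanced
    if kind == "pchip":
        if params is None:
            knots = np.array([0.0, 0.2, 0.4, 0.6, 0.8, 1.0])
            jitter = rng.uniform(-0.06, 0.06, size=6)
            jitter[0] = abs(jitter[0])
            jitter[-1] = -abs(jitter[-1])
            y = np.clip(knots + jitter, 0.0, 1.0)
            y = np.maximum.accumulate(y + np.arange(6) * 1e-3)  # enforce strict increase
            y = np.clip(y / max(y[-1], 1.0), 0.0, 1.0)
            params = y
        cps = params if isinstance(params, ControlPointSet) else ControlPointSet(tuple(params))
        return apply_tonecurve(image, pchip_tonecurve(cps))
    raise ValueError(f"unknown adjustment kind {kind!r}")


def write_scene(spec: SceneSpec, path: str | Path) -> np.ndarray:
    """Render a scene to an 8-bit PNG with a JSON sidecar echoing the recipe."""
    from .core import save_image

    image = generate_seafloor_image(spec)
    path = Path(path)
    save_image(image, path)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(spec.to_dict(), indent=2))
    return image
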