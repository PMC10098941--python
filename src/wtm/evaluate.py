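"""Quantitative evaluation: CIELAB colour difference and observer statistics.

Two images are compared by the mean ΔE*ab — the per-pixel Euclidean distance
in CIELAB (sRGB working space, D65 white point) averaged over the frame.  A
ΔE*ab of ~1 is a just-noticeable difference; a mean below 5 across an image
pair reads as visually identical, which is the similarity verdict reported
here.

Observer-session statistics summarise repeated enhancements of the same image:
the agreement proportion (same tool chosen on both viewings), the coefficient
of variation CV = σ/μ of a chosen parameter within an image pair, and the MCV,
its mean across image pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import color as skcolor

SIMILARITY_THRESHOLD = 5.0

WTM_TOOL = "wtm"
CONTROL_TOOL = "control-point"

__all__ = [
    "DeltaEReport",
    "mean_delta_e",
    "agreement",
    "coefficient_of_variation",
    "mcv",
    "load_sessions",
    "SIMILARITY_THRESHOLD",
]


@dataclass
class DeltaEReport:
    """Mean ΔE*ab between two images plus the per-pixel difference map."""

    mean_delta_e: float
    delta_map: np.ndarray = field(repr=False)
    fraction_below_1: float
    similar: bool
    threshold: float = SIMILARITY_THRESHOLD

    def to_dict(self) -> dict:
        return {
            "mean_delta_e": self.mean_delta_e,
            "fraction_below_1": self.fraction_below_1,
            "similar": self.similar,
            "threshold": self.threshold,
        }


def mean_delta_e(img_a: np.ndarray, img_b: np.ndarray) -> DeltaEReport:
    """Per-pixel CIELAB distance between two images, averaged over the frame.

    Both images are converted sRGB → XYZ (D65) → L*a*b*; the report's verdict
    is "similar" iff the mean distance is below 5.
    """
    from .core import validate_image

    img_a = validate_image(img_a)
    img_b = validate_image(img_b)
    if img_a.shape != img_b.shape:
        raise ValueError("images must share dimensions")
    lab_a = skcolor.rgb2lab(img_a)
    lab_b = skcolor.rgb2lab(img_b)
    delta = np.sqrt(np.sum((lab_a - lab_b) ** 2, axis=2))
    mean = float(delta.mean())
    return DeltaEReport(
        mean_delta_e=mean,
        delta_map=delta,
        fraction_below_1=float((delta < 1.0).mean()),
        similar=bool(mean < SIMILARITY_THRESHOLD),
    )


# ---------------------------------------------------------------------------
# Observer-session statistics

_SESSION_COLUMNS = ["observer", "image", "repeat", "tool", "p1", "p2", "p3", "p4", "p5", "p6"]


def load_sessions(path: str | Path) -> pd.DataFrame:
    """Read an observer-session table (CSV: observer,image,repeat,tool,p1..p6)."""
    df = pd.read_csv(path)
    missing = [c for c in _SESSION_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"session table is missing columns {missing}")
    return df


def _paired(sessions: pd.DataFrame) -> pd.DataFrame:
    """Keep (observer, image) groups with exactly two repeats; warn and skip others."""
    if len(sessions) == 0:
        raise ValueError("empty session table")
    sizes = sessions.groupby(["observer", "image"])["repeat"].transform("size")
    if (sizes != 2).any():
        bad = sessions.loc[sizes != 2, ["observer", "image"]].drop_duplicates()
        warnings.warn(
            f"skipping {len(bad)} observer/image groups without exactly 2 repeats",
            stacklevel=3,
        )
    return sessions[sizes == 2]


def agreement(sessions: pd.DataFrame) -> dict:
    """Proportion of images on which each observer chose the same tool twice.

    Returns per-observer proportions plus their mean and population std.
    """
    paired = _paired(sessions)
    if len(paired) == 0:
        raise ValueError("no complete repeat pairs in session table")
    per_observer = {}
    for obs, grp in paired.groupby("observer"):
        matches = grp.groupby("image")["tool"].nunique() == 1
        per_observer[obs] = float(matches.mean())
    values = np.array(list(per_observer.values()))
    return {
        "per_observer": per_observer,
        "mean": float(values.mean()),
        "std": float(values.std()),
    }


def coefficient_of_variation(values, population: bool = True) -> float:
    """CV = σ/μ, the standard deviation normalised by the mean.

    Uses the population σ by default (``population=False`` applies the Bessel
    correction).  Zero iff all values are equal; scale-invariant.
    """
    arr = np.asarray(values, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("CV of an empty sequence")
    if np.any(arr < 0.0):
        raise ValueError("CV is defined here for non-negative values")
    mu = arr.mean()
    if mu == 0.0:
        raise ValueError("CV undefined for zero mean")
    sigma = arr.std(ddof=0 if population else 1)
    return float(sigma / mu)


def mcv(
    sessions: pd.DataFrame,
    tool: str,
    per_observer: bool = True,
    population: bool = True,
) -> dict:
    """Mean coefficient of variation of tool parameters across image pairs.

    For WTM pairs the CV of λ and of k are averaged separately across image
    pairs (MCV_λ, MCV_k); for control-point pairs the six per-ordinate CVs are
    first averaged within each pair, then across pairs (MCV_c).  Observers who
    never used the tool are reported as None — the "-" convention.
    """
    paired = _paired(sessions)
    results: dict = {}
    groups = paired.groupby("observer") if per_observer else [(None, paired)]
    for obs, grp in groups:
        both = grp.groupby("image").filter(lambda g: (g["tool"] == tool).all())
        if len(both) == 0:
            results[obs] = None
            continue
        if tool == WTM_TOOL:
            cv_lam, cv_k = [], []
            for _, pair in both.groupby("image"):
                cv_lam.append(coefficient_of_variation(pair["p1"], population))
                cv_k.append(coefficient_of_variation(pair["p2"], population))
            results[obs] = {
                "mcv_lambda": float(np.mean(cv_lam)),
                "mcv_k": float(np.mean(cv_k)),
            }
        else:
            cv_c = []
            for _, pair in both.groupby("image"):
                cvs = [
                    coefficient_of_variation(pair[f"p{i}"], population)
                    for i in range(1, 7)
                ]
                cv_c.append(float(np.mean(cvs)))
            results[obs] = {"mcv_control": float(np.mean(cv_c))}
    return results if per_observer else results[None]
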