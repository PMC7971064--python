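"""Morphometry of stained liver sections by HSV color gating.

Collagen proportional area (CPA) is the fraction of Sirius-red-positive
pixels over tissue; lipid vacuolization (LV) is the fraction of unstained
vacuole pixels over tissue on H&E.  Tissue is separated from the slide
background by a saturation gate followed by hole filling, so that unstained
vacuoles *inside* the section count as tissue area (and as the LV
numerator) while the slide outside the section counts as neither.

Gate parameters are plain module-level defaults recorded in every result
for provenance.  No shape filtering (e.g. vacuole circularity) is applied
by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_fill_holes
from skimage.color import rgb2hsv

from .phantom.stains import StainImage

__all__ = ["MorphometryResult", "cpa", "lv", "measure_stain"]

# Default HSV gates. Hue in [0, 1); red wraps around 0.
GATES = {
    "tissue_saturation_min": 0.15,
    "sirius_red": {"hue_max": 0.06, "hue_min_wrap": 0.90, "saturation_min": 0.30},
    "h_and_e": {"saturation_max": 0.15, "value_min": 0.85},
}


@dataclass
class MorphometryResult:
    positive_frac: float
    positive_pixels: int
    total_tissue_pixels: int
    stain: str
    threshold_params: dict = field(default_factory=dict)

    @property
    def positive_pct(self) -> float:
        return 100.0 * self.positive_frac


def _rgb_array(image: StainImage | np.ndarray) -> np.ndarray:
    rgb = image.pixels if isinstance(image, StainImage) else np.asarray(image)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("expected an RGB raster (H, W, 3)")
    return rgb


def _tissue_region(hsv: np.ndarray) -> np.ndarray:
    """Stained pixels, holes filled, so intra-tissue vacuoles are tissue."""
    stained = hsv[..., 1] > GATES["tissue_saturation_min"]
    return binary_fill_holes(stained)


def measure_stain(image: StainImage | np.ndarray, stain: str) -> MorphometryResult:
    """Positive-pixel fraction over tissue for the given stain chemistry."""
    if stain not in ("sirius_red", "h_and_e"):
        raise ValueError(f"unknown stain {stain!r}")
    rgb = _rgb_array(image)
    hsv = rgb2hsv(rgb)
    tissue = _tissue_region(hsv)
    n_tissue = int(tissue.sum())
    if n_tissue == 0:
        raise ValueError("no tissue detected in image")

    hue, sat, val = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    if stain == "sirius_red":
        g = GATES["sirius_red"]
        positive = ((hue <= g["hue_max"]) | (hue >= g["hue_min_wrap"])) \
            & (sat >= g["saturation_min"]) & tissue
        params = {"tissue_saturation_min": GATES["tissue_saturation_min"], **g}
    else:
        g = GATES["h_and_e"]
        positive = (sat <= g["saturation_max"]) & (val >= g["value_min"]) & tissue
        params = {"tissue_saturation_min": GATES["tissue_saturation_min"], **g}

    n_pos = int(positive.sum())
    return MorphometryResult(n_pos / n_tissue, n_pos, n_tissue, stain, params)


def cpa(image: StainImage) -> MorphometryResult:
    """Collagen proportional area from a Sirius-red section."""
    if image.stain != "sirius_red":
        raise ValueError(f"cpa requires a sirius_red image, got {image.stain!r}")
    return measure_stain(image, "sirius_red")


def lv(image: StainImage) -> MorphometryResult:
    """Lipid vacuolization from an H&E section."""
    if image.stain != "h_and_e":
        raise ValueError(f"lv requires an h_and_e image, got {image.stain!r}")
    return measure_stain(image, "h_and_e")
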