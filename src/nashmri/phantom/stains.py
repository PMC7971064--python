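"""Synthetic histology renders with exact pixel-level ground truth.

Two stain styles are emulated on an elliptical tissue section over a bright
slide background:

* ``sirius_red`` — yellow counterstained parenchyma with red collagen
  strands (thin, elongated, branching), the substrate for collagen
  proportional area (CPA) morphometry;
* ``h_and_e`` — eosin-pink parenchyma with round unstained lipid vacuoles,
  the substrate for lipid vacuolization (LV) morphometry.

The renderer places blobs until the positive-pixel fraction over the tissue
region slightly exceeds the target, then trims randomly chosen positive
pixels so the truth mask hits the target count exactly.  Colors are flat
(no anti-aliasing), so color-gate morphometry can be validated against the
truth mask pixel for pixel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt
from skimage.draw import disk, ellipse, line
from skimage.morphology import dilation, disk as disk_se

__all__ = ["StainImage", "STAIN_COLORS", "render_stain_image"]

# Flat RGB colors (uint8) used by the renderer; morphometry gates are set
# in HSV space and do not reference these values directly.
STAIN_COLORS = {
    "slide_background": (245, 245, 245),
    "sirius_red": {"tissue": (225, 195, 95), "positive": (185, 40, 45)},
    "h_and_e": {"tissue": (205, 120, 150), "positive": (242, 242, 244)},
}

_MIN_SIDE = 32


@dataclass
class StainImage:
    """RGB stain raster with exact ground truth."""

    pixels: np.ndarray          # (H, W, 3) uint8
    stain: str                  # sirius_red | h_and_e
    truth_mask: np.ndarray      # bool, positive pixels
    tissue_mask: np.ndarray     # bool, tissue section extent
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        if self.pixels.shape[:2] != self.truth_mask.shape:
            raise ValueError("truth_mask shape must match pixels")
        if self.pixels.shape[:2] != self.tissue_mask.shape:
            raise ValueError("tissue_mask shape must match pixels")

    @property
    def truth_positive_frac(self) -> float:
        """Ground-truth positive fraction over tissue pixels."""
        return float(self.truth_mask.sum() / self.tissue_mask.sum())


def _tissue_ellipse(shape: tuple[int, int]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    rr, cc = ellipse(shape[0] / 2, shape[1] / 2,
                     shape[0] * 0.42, shape[1] * 0.45, shape=shape)
    mask[rr, cc] = True
    return mask


def _collagen_strand(shape: tuple[int, int], tissue: np.ndarray,
                     depth: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """A jittered polyline dilated to a thin fibrous strand."""
    h, w = shape
    blob = np.zeros(shape, dtype=bool)
    seeds = np.argwhere(tissue)
    r, c = seeds[rng.integers(len(seeds))]
    angle = rng.uniform(0, 2 * np.pi)
    n_seg = rng.integers(4, 10)
    step = rng.uniform(0.02, 0.06) * min(h, w)
    for _ in range(n_seg):
        angle += rng.normal(0, 0.6)
        r2 = int(np.clip(r + step * np.sin(angle), 0, h - 1))
        c2 = int(np.clip(c + step * np.cos(angle), 0, w - 1))
        rr, cc = line(int(r), int(c), r2, c2)
        blob[rr, cc] = True
        r, c = r2, c2
    width = int(rng.integers(1, max(2, min(h, w) // 200 + 2)))
    return dilation(blob, disk_se(width)) & tissue


def _vacuole(shape: tuple[int, int], tissue: np.ndarray,
             depth: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """A round lipid vacuole, kept strictly interior to the section.

    Vacuoles touching the section rim would read as bays of slide
    background rather than holes in tissue, so centers are drawn only
    where the distance to the rim exceeds the vacuole radius.
    """
    h, w = shape
    blob = np.zeros(shape, dtype=bool)
    radius = max(1.5, rng.lognormal(np.log(0.012 * min(h, w)), 0.45))
    interior = depth > radius + 1.5
    seeds = np.argwhere(interior if interior.any() else depth == depth.max())
    r, c = seeds[rng.integers(len(seeds))]
    rr, cc = disk((r, c), radius, shape=shape)
    blob[rr, cc] = True
    return blob & tissue


def render_stain_image(target_positive_frac: float, stain: str,
                       shape: tuple[int, int] = (1024, 1024),
                       seed: int = 0,
                       pixel_size_um: float = 1.0) -> StainImage:
    """Render a stain image whose positive fraction over tissue is exact.

    Parameters
    ----------
    target_positive_frac
        Desired positive-pixel fraction over the tissue region, in [0, 1].
    stain
        ``sirius_red`` (collagen strands) or ``h_and_e`` (lipid vacuoles).
    shape
        Raster shape; each side must be at least 32 pixels so a non-zero
        target is representable to the construction tolerance.

    The returned image's ``truth_mask`` has exactly
    ``round(target · n_tissue_pixels)`` positive pixels.
    """
    if not 0.0 <= target_positive_frac <= 1.0:
        raise ValueError("target_positive_frac must be in [0, 1]")
    if stain not in ("sirius_red", "h_and_e"):
        raise ValueError(f"unknown stain {stain!r}")
    if min(shape) < _MIN_SIDE:
        raise ValueError(
            f"raster sides must be ≥ {_MIN_SIDE} px to place blobs at the "
            "requested fractional accuracy")

    rng = np.random.default_rng(seed)
    tissue = _tissue_ellipse(shape)
    depth = distance_transform_edt(tissue)
    n_tissue = int(tissue.sum())
    target_count = int(round(target_positive_frac * n_tissue))

    positive = np.zeros(shape, dtype=bool)
    make_blob = _collagen_strand if stain == "sirius_red" else _vacuole
    stall = 0
    while positive.sum() < target_count and stall < 20_000:
        before = positive.sum()
        positive |= make_blob(shape, tissue, depth, rng)
        stall = stall + 1 if positive.sum() == before else 0
    deficit = target_count - int(positive.sum())
    if deficit > 0:  # pathological stall: fill with interior tissue pixels
        free = np.argwhere((depth > 2.5) & ~positive)
        pick = free[rng.choice(len(free), size=deficit, replace=False)]
        positive[pick[:, 0], pick[:, 1]] = True

    excess = int(positive.sum()) - target_count
    if excess > 0:  # trim randomly so the truth count is exact
        pos = np.argwhere(positive)
        drop = pos[rng.choice(len(pos), size=excess, replace=False)]
        positive[drop[:, 0], drop[:, 1]] = False

    colors = STAIN_COLORS[stain]
    img = np.empty(shape + (3,), dtype=np.uint8)
    img[...] = STAIN_COLORS["slide_background"]
    img[tissue] = colors["tissue"]
    img[positive] = colors["positive"]
    return StainImage(img, stain, positive, tissue, pixel_size_um)
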