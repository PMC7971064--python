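"""Two-point Dixon fat-fraction computation.

Under the water-dominant convention (fat fraction ≤ 0.5, valid for mouse
liver) the in-phase (IP = W + F) and opposed-phase (OP = |W − F|) magnitude
images give the fat signal fraction FF = (IP − OP) / (2·IP).  Magnitude
two-point Dixon cannot distinguish fat- from water-dominant voxels — the
pool swap (W, F) → (F, W) leaves (IP, OP) unchanged — so values are clamped
to [0, 0.5].  Noise occasionally drives OP above IP; those voxels are
clamped to FF = 0 (and counted) rather than masked, which keeps low-fat ROI
means close to unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import ImageSeries, ROIMask

__all__ = ["FatFractionMap", "dixon_fat_fraction", "roi_fat_percent"]


@dataclass
class FatFractionMap:
    """Voxelwise fat signal fraction in [0, 0.5]."""

    values: np.ndarray          # FF, NaN where unevaluable
    valid: np.ndarray           # bool, voxels above the noise floor
    n_clamped_low: int          # voxels with raw FF < 0 (clamped to 0)
    n_clamped_high: int         # voxels with raw FF > 0.5 (clamped)
    noise_floor: float

    @property
    def n_voxels(self) -> int:
        return int(self.valid.sum())


def _as_raster(x) -> np.ndarray:
    if isinstance(x, ImageSeries):
        if x.n_frames != 1:
            raise ValueError("Dixon input series must have a single frame")
        return x.frames[0]
    return np.asarray(x, dtype=float)


def dixon_fat_fraction(in_phase, opposed_phase,
                       noise_sigma: float = 0.0) -> FatFractionMap:
    """Compute FF = (IP − OP)/(2·IP) with noise-floor masking and clamping.

    ``in_phase`` and ``opposed_phase`` are rasters (or single-frame
    ``ImageSeries``).  Voxels whose in-phase signal is below ``3·noise_sigma``
    (or non-positive) are marked invalid and set to NaN.
    """
    ip = _as_raster(in_phase)
    op = _as_raster(opposed_phase)
    if ip.shape != op.shape:
        raise ValueError(f"shape mismatch: {ip.shape} vs {op.shape}")

    floor = 3.0 * noise_sigma
    valid = (ip > floor) & (ip > 0)
    values = np.full(ip.shape, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = (ip - op) / (2.0 * ip)
    n_low = int(np.sum(valid & (raw < 0)))
    n_high = int(np.sum(valid & (raw > 0.5)))
    values[valid] = np.clip(raw[valid], 0.0, 0.5)
    return FatFractionMap(values, valid, n_low, n_high, floor)


def roi_fat_percent(ff_map: FatFractionMap, mask: ROIMask) -> float:
    """ROI fat percentage: 100 × mean fat fraction over valid masked voxels."""
    if mask.voxels.shape != ff_map.values.shape:
        raise ValueError("mask shape must match fat-fraction map")
    effective = mask.voxels & ff_map.valid
    if not effective.any():
        raise ValueError("mask is empty after noise-floor exclusion")
    return float(100.0 * ff_map.values[effective].mean())
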