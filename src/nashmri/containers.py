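"""Shared in-memory containers for image series and regions of interest.

All rasters are ``(row, col)`` ndarrays, 0-based; series stack frames on the
leading axis as ``(frame, row, col)``.  Physical geometry (field of view,
pixel size) travels in acquisition metadata, never in the arrays themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["ImageSeries", "ROIMask"]


@dataclass
class ROIMask:
    """Boolean voxel mask with provenance.

    Parameters
    ----------
    voxels
        Boolean raster, shape ``(rows, cols)``.
    label
        One of ``liver``, ``muscle``, ``background``, ``vessel``.
    n_excluded_vessel
        Number of voxels removed from an initial seed mask by vessel
        exclusion (0 for masks that never went through segmentation).
    threshold_used
        Signal threshold applied during vessel exclusion, if any.
    """

    voxels: np.ndarray
    label: str
    n_excluded_vessel: int = 0
    threshold_used: float | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.ndim != 2:
            raise ValueError("ROIMask.voxels must be a 2-D raster")
        if self.n_excluded_vessel < 0:
            raise ValueError("n_excluded_vessel must be non-negative")

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    def __bool__(self) -> bool:  # truthiness == non-empty
        return bool(self.voxels.any())


@dataclass
class ImageSeries:
    """A stack of 2-D magnitude frames with per-frame acquisition metadata.

    ``frame_axis_values`` carries the quantity that varies along the frame
    axis: inversion time (ms) for IR, echo time (ms) for multi-echo GRE, or
    post-injection time (min) for DCE.  ``meta`` holds simulation ground
    truth and phantom masks when the series was generated synthetically.
    """

    frames: np.ndarray
    kind: str
    frame_axis_values: np.ndarray
    params: Any = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.frame_axis_values = np.asarray(self.frame_axis_values, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("ImageSeries.frames must be (frame, row, col)")
        if len(self.frame_axis_values) != self.frames.shape[0]:
            raise ValueError("frame_axis_values length must match frame count")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]  # type: ignore[return-value]

    def roi_means(self, mask: ROIMask) -> np.ndarray:
        """Mean signal inside ``mask`` for every frame."""
        if not mask:
            raise ValueError("mask is empty")
        return self.frames[:, mask.voxels].mean(axis=1)
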