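"""Disk formats: NIfTI series with JSON sidecars, PNG stain images, CSV tables.

Each simulated series is written as a ``.nii.gz`` volume (frames on the
third axis) with a JSON sidecar carrying the acquisition parameters and, for
synthetic data, the ground-truth tissue state.  Stain images are PNG with
the truth mask as a paired ``*_truth.png`` (and tissue mask as
``*_tissue.png``).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np

from .containers import ImageSeries
from .phantom.stains import StainImage
from .phantom.trajectory import Diet, TissueState

__all__ = ["save_series", "load_series", "save_stain_image", "load_stain_image"]


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Diet):
        return obj.value
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    return obj


def save_series(series: ImageSeries, path: str | Path) -> Path:
    """Write a series as NIfTI (+ ``.json`` sidecar); returns the NIfTI path."""
    path = Path(path)
    if path.suffixes[-2:] != [".nii", ".gz"]:
        path = path.with_suffix(".nii.gz")
    # (row, col, frame) voxel order; pixel size from FOV when available.
    vol = np.moveaxis(series.frames, 0, -1)
    affine = np.eye(4)
    if series.params is not None and getattr(series.params, "fov_cm", None):
        fov = series.params.fov_cm
        affine[0, 0] = 10.0 * fov[0] / series.frame_shape[0]  # mm
        affine[1, 1] = 10.0 * fov[1] / series.frame_shape[1]
    nib.save(nib.Nifti1Image(vol, affine), str(path))

    sidecar = {
        "kind": series.kind,
        "frame_axis_values": series.frame_axis_values.tolist(),
        "params": _jsonable(series.params),
        "ground_truth": _jsonable(series.meta.get("state")),
    }
    sidecar_path = path.with_name(path.name.removesuffix(".nii.gz") + ".json")
    sidecar_path.write_text(json.dumps(sidecar, indent=2, ensure_ascii=False))
    return path


def load_series(path: str | Path) -> ImageSeries:
    """Read a NIfTI series written by :func:`save_series`."""
    path = Path(path)
    img = nib.load(str(path))
    frames = np.moveaxis(np.asarray(img.dataobj, dtype=float), -1, 0)
    sidecar_path = path.with_name(path.name.removesuffix(".nii.gz") + ".json")
    meta: dict = {}
    kind = "UNKNOWN"
    axis = np.arange(frames.shape[0], dtype=float)
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        kind = sidecar.get("kind", kind)
        axis = np.asarray(sidecar.get("frame_axis_values", axis), dtype=float)
        meta["sidecar"] = sidecar
    return ImageSeries(frames, kind, axis, params=None, meta=meta)


def save_stain_image(image: StainImage, path: str | Path) -> Path:
    """Write a stain render as PNG with paired truth/tissue mask PNGs."""
    path = Path(path).with_suffix(".png")
    iio.imwrite(path, image.pixels)
    stem = path.with_suffix("")
    iio.imwrite(stem.with_name(stem.name + "_truth.png"),
                (image.truth_mask * np.uint8(255)))
    iio.imwrite(stem.with_name(stem.name + "_tissue.png"),
                (image.tissue_mask * np.uint8(255)))
    return path


def load_stain_image(path: str | Path, stain: str) -> StainImage:
    """Read a stain PNG (with its paired masks) back into a StainImage."""
    path = Path(path)
    pixels = np.asarray(iio.imread(path))[..., :3]
    stem = path.with_suffix("")
    truth = np.asarray(iio.imread(stem.with_name(stem.name + "_truth.png"))) > 127
    tissue = np.asarray(iio.imread(stem.with_name(stem.name + "_tissue.png"))) > 127
    return StainImage(pixels, stain, truth, tissue)
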