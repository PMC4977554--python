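"""Cell and nucleus segmentation.

Absorption volumes (hematoxylin-stained, optical-CT convention: denser
material = higher value) are segmented in two stages: the whole cell
against the background, then the nucleus as the high-absorption class
within the cell.  Fluorescence (DAPI) stacks segment the nucleus directly.

The default recipe is deliberately parameter-light: Gaussian smoothing
(sigma in µm, so anisotropic grids are handled correctly), Otsu
thresholding, largest 26-connected component, morphological closing with a
physical-radius ball, and hole filling.  It is exactly equivariant under
axis-aligned 90° rotations and reflections on isotropic grids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_multiotsu, threshold_otsu

from .errors import SegmentationError
from .volume import LabelMask, Volume3D

_STRUCT26 = np.ones((3, 3, 3), dtype=int)


@dataclass
class SegmentationParams:
    """Tunables for the threshold-based segmentation recipe.

    ``smoothing_sigma_um`` — Gaussian pre-smoothing scale (µm).
    ``threshold`` — "otsu" (default) or "fixed" with ``fixed_threshold``.
    ``min_object_volume_um3`` — components below this are discarded.
    ``closing_radius_um`` — ball radius for morphological closing (µm).
    """

    smoothing_sigma_um: float = 0.25
    threshold: str = "otsu"
    fixed_threshold: float | None = None
    min_object_volume_um3: float = 5.0
    closing_radius_um: float = 0.7

    def __post_init__(self) -> None:
        if self.smoothing_sigma_um < 0 or self.min_object_volume_um3 < 0:
            raise ValueError("sigma and min object volume must be >= 0")
        if self.threshold not in ("otsu", "fixed"):
            raise ValueError(f"unknown threshold method {self.threshold!r}")
        if self.threshold == "fixed" and self.fixed_threshold is None:
            raise ValueError("fixed threshold method requires fixed_threshold")


def _smooth(volume: Volume3D, sigma_um: float) -> np.ndarray:
    data = volume.data.astype(np.float32)
    if sigma_um <= 0:
        return data
    sigma_vox = sigma_um / np.asarray(volume.voxel_size, dtype=float)
    return ndimage.gaussian_filter(data, sigma=sigma_vox)


def _anisotropic_ball(radius_um: float, voxel_size) -> np.ndarray | None:
    """Ball footprint of physical radius in (possibly anisotropic) voxels."""
    vs = np.asarray(voxel_size, dtype=float)
    half = np.floor(radius_um / vs).astype(int)
    if np.all(half < 1):
        return None
    axes = [np.arange(-h, h + 1) * v for h, v in zip(half, vs)]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    return (zz**2 + yy**2 + xx**2) <= radius_um**2 + 1e-9


def _threshold_value(values: np.ndarray, params: SegmentationParams) -> float:
    if params.threshold == "fixed":
        return float(params.fixed_threshold)  # type: ignore[arg-type]
    if values.size == 0 or np.ptp(values) == 0:
        raise SegmentationError("no intensity contrast: cannot threshold")
    return float(threshold_otsu(values))


def _intermedian_refine(vals: np.ndarray, thr: float, max_iter: int = 50) -> float:
    """Iterate thr → midpoint of the class *medians*.

    Medians of the two classes sit on the intensity plateaus, unaffected by
    smoothed edge-transition voxels or by small bright outliers (dense
    clumps), so the fixed point is the plateau midpoint — where the smoothed
    boundary crosses at zero offset.
    """
    for _ in range(max_iter):
        lo = vals[vals < thr]
        hi = vals[vals >= thr]
        if lo.size == 0 or hi.size == 0:
            return thr
        new = 0.5 * (float(np.median(lo)) + float(np.median(hi)))
        if abs(new - thr) < 1e-6:
            return new
        thr = new
    return thr


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask, structure=_STRUCT26)
    if n == 0:
        raise SegmentationError("empty foreground after thresholding")
    counts = np.bincount(labels.ravel())[1:]
    return labels == (int(counts.argmax()) + 1)


def _postprocess(mask: np.ndarray, volume: Volume3D, params: SegmentationParams) -> np.ndarray:
    mask = _largest_component(mask)
    ball = _anisotropic_ball(params.closing_radius_um, volume.voxel_size)
    if ball is not None:
        mask = ndimage.binary_closing(mask, structure=ball)
    mask = ndimage.binary_fill_holes(mask)
    mask = _largest_component(mask)  # closing cannot split, but be safe
    if mask.sum() * volume.voxel_volume < params.min_object_volume_um3:
        raise SegmentationError("largest object below minimum volume")
    return mask


def segment_cell(volume: Volume3D, params: SegmentationParams | None = None) -> LabelMask:
    """Segment the single cell against the background.

    Returns the largest connected supra-Otsu component after smoothing,
    closed and hole-filled, as a single-label mask.

    Raises :class:`SegmentationError` on contrast-free input or empty
    foreground.
    """
    params = params or SegmentationParams()
    smooth = _smooth(volume, params.smoothing_sigma_um)
    if params.threshold == "otsu":
        # absorption volumes are trimodal (background / cytoplasm / nucleus):
        # the lower of the two 3-class Otsu thresholds separates cell from
        # background at the edge midpoint, which plain 2-class Otsu misses
        vals = smooth.ravel()
        if np.ptp(vals) == 0:
            raise SegmentationError("no intensity contrast: cannot threshold")
        try:
            thr = float(threshold_multiotsu(vals, classes=3)[0])
        except ValueError:
            thr = float(threshold_otsu(vals))
    else:
        thr = _threshold_value(smooth.ravel(), params)
    mask = _postprocess(smooth > thr, volume, params)
    return LabelMask(mask.astype(np.uint8), volume.voxel_size, role="cell")


def segment_nucleus(
    volume: Volume3D, cell_mask: LabelMask, params: SegmentationParams | None = None
) -> LabelMask:
    """Segment the nucleus as the high-absorption class within the cell.

    Otsu is recomputed on the smoothed intensities *inside the cell mask*,
    separating dense nuclear material from cytoplasm.  The result is the
    largest component, closed, hole-filled, and clipped to the cell so
    nucleus ⊆ cell always holds.
    """
    params = params or SegmentationParams()
    cell_mask.check_aligned(volume)
    cell = cell_mask.foreground()
    if not cell.any():
        raise SegmentationError("cell mask is empty")
    smooth = _smooth(volume, params.smoothing_sigma_um)
    thr = _threshold_value(smooth[cell], params)
    if params.threshold == "otsu":
        thr = _intermedian_refine(smooth[cell], thr)
    mask = _postprocess((smooth > thr) & cell, volume, params) & cell
    if not mask.any():
        raise SegmentationError("nucleus segmentation empty")
    return LabelMask(mask.astype(np.uint8), volume.voxel_size, role="nucleus")


def segment_nucleus_fluorescence(
    dapi_volume: Volume3D, params: SegmentationParams | None = None
) -> LabelMask:
    """Segment the nucleus directly from a DAPI channel (no cell mask)."""
    params = params or SegmentationParams()
    smooth = _smooth(dapi_volume, params.smoothing_sigma_um)
    thr = _threshold_value(smooth.ravel(), params)
    if params.threshold == "otsu":
        thr = _intermedian_refine(smooth.ravel(), thr)
    mask = _postprocess(smooth > thr, dapi_volume, params)
    return LabelMask(mask.astype(np.uint8), dapi_volume.voxel_size, role="nucleus")
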