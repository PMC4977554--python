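"""FISH spot detection, relative radial distance (RRD), and colocalization.

The RRD of a locus expresses its position between the nuclear periphery and
the geometric nuclear center: 0 at the periphery, 1 at the center.  For a
spot at position ``s`` in a nucleus with centroid ``c``, a ray is cast from
``c`` through ``s``; if ``b`` is the first boundary crossing of the nuclear
mask along that ray beyond the spot, then

    RRD = 1 - |s - c| / |b - c|

For a sphere of radius R this reduces to the analytic 1 - r/R.  The boundary
crossing is located at sub-voxel precision by marching the ray in
quarter-voxel steps through a trilinearly interpolated signed distance field
of the mask (positive inside, negative outside) and linearly interpolating
the zero crossing.

All positions handled here are in physical µm, in nucleus-local (volume)
coordinates with axis order (z, y, x); voxel index ``i`` maps to physical
coordinate ``i * voxel_size`` (voxel centers).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import NucmorphError, SegmentationError
from .volume import LabelMask, Volume3D

logger = logging.getLogger(__name__)


@dataclass
class SpotMeasurement:
    """One FISH allele: centroid (µm, volume coordinates, z/y/x) and its RRD."""

    cell_id: str
    allele: int
    centroid_um: tuple[float, float, float]
    rrd: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.rrd <= 1.0:
            raise ValueError(f"rrd must lie in [0, 1], got {self.rrd}")


@dataclass
class ColocalizationResult:
    """Whole-nucleus Pearson correlation between two channels."""

    cell_id: str
    pearson_r: float
    n_voxels: int

    def __post_init__(self) -> None:
        if not -1.0 <= self.pearson_r <= 1.0 + 1e-12:
            raise ValueError(f"pearson_r out of [-1, 1]: {self.pearson_r}")
        if self.n_voxels < 10:
            raise ValueError(f"colocalization needs >= 10 voxels, got {self.n_voxels}")


# ---------------------------------------------------------------------------
# Signed distance and ray casting


def signed_distance_field(mask: np.ndarray, voxel_size: tuple[float, float, float]) -> np.ndarray:
    """Signed Euclidean distance to the mask boundary in µm, positive inside."""
    fg = mask > 0
    inside = ndimage.distance_transform_edt(fg, sampling=voxel_size)
    outside = ndimage.distance_transform_edt(~fg, sampling=voxel_size)
    return inside - outside


def _interp(field: np.ndarray, point_vox: np.ndarray) -> float:
    """Trilinear sample of ``field`` at a fractional voxel coordinate."""
    return float(
        ndimage.map_coordinates(
            field, point_vox.reshape(3, 1), order=1, mode="nearest"
        )[0]
    )


def ray_boundary_distance(
    sdf: np.ndarray,
    voxel_size: tuple[float, float, float],
    origin_um: np.ndarray,
    direction: np.ndarray,
    start_um: float = 0.0,
) -> float:
    """Distance (µm) from ``origin_um`` to the first mask boundary crossing
    along unit vector ``direction``, searching outward from ``start_um``.

    ``sdf`` is the signed distance field of the mask (µm, positive inside).
    Marches in quarter-voxel steps; the zero crossing is refined by linear
    interpolation between the bracketing samples.
    """
    vs = np.asarray(voxel_size, dtype=float)
    step = 0.25 * float(vs.min())
    shape_um = (np.array(sdf.shape) - 1) * vs
    max_t = float(np.linalg.norm(shape_um)) + step  # cannot leave the grid further

    t_prev = start_um
    p_prev = (origin_um + t_prev * direction) / vs
    d_prev = _interp(sdf, p_prev)
    if d_prev <= 0:
        # already outside at the start: boundary is at/behind the start point
        d_prev = max(d_prev, 0.0)

    t = t_prev
    while t < max_t:
        t = t_prev + step
        p = (origin_um + t * direction) / vs
        d = _interp(sdf, p)
        if d <= 0.0 < d_prev:
            frac = d_prev / (d_prev - d) if d_prev != d else 0.5
            return t_prev + frac * step
        t_prev, d_prev = t, d
    raise NucmorphError("ray never crossed the mask boundary inside the grid")


def _count_crossings_beyond(
    sdf: np.ndarray,
    voxel_size: tuple[float, float, float],
    origin_um: np.ndarray,
    direction: np.ndarray,
    t_boundary: float,
    extra_um: float,
) -> int:
    """Count re-entries of the mask shortly beyond the first crossing."""
    vs = np.asarray(voxel_size, dtype=float)
    step = 0.25 * float(vs.min())
    reentries = 0
    prev_inside = False
    t = t_boundary + step
    while t < t_boundary + extra_um:
        p = (origin_um + t * direction) / vs
        inside = _interp(sdf, p) > 0
        if inside and not prev_inside:
            reentries += 1
        prev_inside = inside
        t += step
    return reentries


def mask_centroid_um(mask: LabelMask | np.ndarray, voxel_size=None) -> np.ndarray:
    """Geometric centroid of the mask foreground in µm (z, y, x)."""
    if isinstance(mask, LabelMask):
        data, vs = mask.foreground(), np.asarray(mask.voxel_size)
    else:
        data, vs = np.asarray(mask) > 0, np.asarray(voxel_size, dtype=float)
    if not data.any():
        raise SegmentationError("empty mask has no centroid")
    com = np.array(ndimage.center_of_mass(data))
    return com * vs


def rrd(
    spot_centroid_um,
    nucleus_mask: LabelMask,
    sdf: np.ndarray | None = None,
) -> float:
    """Relative radial distance of a spot in [0, 1].

    0 = nuclear periphery, 1 = geometric nuclear center.  A spot within half
    a voxel of the centroid returns exactly 1 by convention.  For non-convex
    masks the first boundary crossing beyond the spot is used; later
    re-entries of the ray are logged.

    Raises
    ------
    NucmorphError
        If the spot lies outside the nucleus mask.
    """
    vs = np.asarray(nucleus_mask.voxel_size, dtype=float)
    spot = np.asarray(spot_centroid_um, dtype=float)
    if sdf is None:
        sdf = signed_distance_field(nucleus_mask.data, nucleus_mask.voxel_size)
    # half-voxel tolerance: a centroid on the digitized boundary is in-mask
    if _interp(sdf, spot / vs) < -0.5 * float(vs.min()):
        raise NucmorphError(f"spot at {spot} µm lies outside the nucleus mask")

    center = mask_centroid_um(nucleus_mask)
    offset = spot - center
    r = float(np.linalg.norm(offset))
    if r < 0.5 * float(vs.min()):
        return 1.0
    direction = offset / r
    t_b = ray_boundary_distance(sdf, nucleus_mask.voxel_size, center, direction, start_um=r)
    extra = _count_crossings_beyond(sdf, nucleus_mask.voxel_size, center, direction, t_b, 8 * vs.min())
    if extra:
        logger.debug(
            "ray from nucleus center re-enters mask %d time(s) beyond first crossing "
            "at spot %s; first crossing used", extra, spot,
        )
    return float(np.clip(1.0 - r / t_b, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Spot detection


def detect_spots(
    fish_volume: Volume3D,
    nucleus_mask: LabelMask,
    min_spot_volume_um3: float = 0.05,
    k_sigma: float = 3.0,
    spot_sigma_um: float = 0.3,
    cell_id: str = "cell",
) -> list[tuple[float, float, float]]:
    """Detect FISH spots inside the nucleus; returns intensity-weighted
    centroids in µm (z, y, x).

    Blob enhancement is a Laplacian-of-Gaussian filter (negated so spots are
    bright) at scale ``spot_sigma_um``; the detection threshold is
    mean + ``k_sigma``·sd of the enhanced signal within the nucleus, and
    26-connected components smaller than ``min_spot_volume_um3`` are
    discarded.  Two or more spots per nucleus are expected and supported
    (aneuploid loci).  Zero detections return an empty list with a warning.
    """
    nucleus_mask.check_aligned(fish_volume)
    vs = np.asarray(fish_volume.voxel_size, dtype=float)
    fg = nucleus_mask.foreground()
    if not fg.any():
        raise SegmentationError("nucleus mask is empty")

    sigma_vox = spot_sigma_um / vs
    enhanced = -ndimage.gaussian_laplace(fish_volume.data.astype(np.float32), sigma=sigma_vox)
    inside = enhanced[fg]
    thr = float(inside.mean() + k_sigma * inside.std())
    candidate = (enhanced > thr) & fg

    labels, n = ndimage.label(candidate, structure=np.ones((3, 3, 3), dtype=int))
    if n == 0:
        logger.warning("%s: no FISH spots detected", cell_id)
        return []
    voxel_vol = float(np.prod(vs))
    counts = np.bincount(labels.ravel())[1:]
    keep = np.flatnonzero(counts * voxel_vol >= min_spot_volume_um3) + 1
    if keep.size == 0:
        logger.warning("%s: all candidate spots below min volume", cell_id)
        return []
    intensity = np.clip(fish_volume.data.astype(np.float64), 0, None)
    coms = ndimage.center_of_mass(intensity, labels, keep)
    return [tuple(np.asarray(c) * vs) for c in coms]


def measure_spots(
    fish_volume: Volume3D,
    nucleus_mask: LabelMask,
    cell_id: str = "cell",
    **detect_kwargs,
) -> list[SpotMeasurement]:
    """Detect spots and compute each allele's RRD."""
    centroids = detect_spots(fish_volume, nucleus_mask, cell_id=cell_id, **detect_kwargs)
    sdf = signed_distance_field(nucleus_mask.data, nucleus_mask.voxel_size)
    out = []
    for i, c in enumerate(centroids):
        out.append(
            SpotMeasurement(
                cell_id=cell_id,
                allele=i,
                centroid_um=tuple(float(x) for x in c),
                rrd=rrd(c, nucleus_mask, sdf=sdf),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Colocalization


def pearson_colocalization(
    fish_volume: Volume3D,
    h3k9ac_volume: Volume3D,
    nucleus_mask: LabelMask,
    cell_id: str = "cell",
) -> ColocalizationResult:
    """Pearson correlation of the two channels over all nuclear voxels.

    No intensity thresholding or Costes masking is applied: the statistic is
    the plain sample correlation of voxel intensities within the nucleus, so
    it is invariant to affine rescaling of either channel.

    Raises
    ------
    NucmorphError
        If either channel is constant inside the nucleus (undefined r).
    """
    nucleus_mask.check_aligned(fish_volume)
    nucleus_mask.check_aligned(h3k9ac_volume)
    fg = nucleus_mask.foreground()
    a = fish_volume.data[fg].astype(np.float64)
    b = h3k9ac_volume.data[fg].astype(np.float64)
    if a.std() == 0 or b.std() == 0:
        raise NucmorphError("constant channel inside nucleus: Pearson undefined")
    r = float(np.corrcoef(a, b)[0, 1])
    return ColocalizationResult(cell_id=cell_id, pearson_r=float(np.clip(r, -1, 1)), n_voxels=int(a.size))
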