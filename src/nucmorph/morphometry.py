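"""Per-cell 3D nuclear morphometry.

Four diagnostically relevant parameters are computed per cell from the
segmented masks and the absorption volume:

* nuclear volume (µm³) — foreground voxel count × voxel volume;
* nuclear-cytoplasmic (NC) ratio — V_nucleus / (V_cell − V_nucleus), the
  classical karyoplasmic ratio with a cytoplasm-only denominator;
* nuclear shape concavity (%) — volume deficit of the nucleus relative to
  its voxelized 3D convex hull, 100·(V_hull − V_nucleus)/V_hull; convex
  bodies score ≈ 0 and surface invaginations raise it monotonically;
* dense clump count — number of 26-connected supra-threshold components of
  the absorption signal inside the nucleus, with a per-nucleus adaptive
  threshold mean + k·sd (robust to per-cell staining variation).

All four are exactly invariant under axis-aligned 90° rotations and integer
translations of the input grids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import convex_hull_image

from .errors import NucmorphError, SegmentationError
from .volume import FeatureTable, LabelMask, Volume3D

logger = logging.getLogger(__name__)

_STRUCT26 = np.ones((3, 3, 3), dtype=int)


@dataclass
class MorphometryRecord:
    """The four morphometric parameters for one cell."""

    cell_id: str
    nuclear_volume_um3: float
    nc_ratio: float
    concavity_pct: float
    clump_count: int

    def __post_init__(self) -> None:
        if self.nuclear_volume_um3 <= 0:
            raise ValueError("nuclear volume must be > 0")
        if self.nc_ratio <= 0:
            raise ValueError("NC ratio must be > 0")
        if not 0.0 <= self.concavity_pct < 100.0:
            raise ValueError(f"concavity out of [0, 100): {self.concavity_pct}")
        if self.clump_count < 0:
            raise ValueError("clump count must be >= 0")

    def as_rows(self, condition: str) -> list[dict]:
        """Long-format rows for a :class:`FeatureTable`."""
        return [
            {"cell_id": self.cell_id, "condition": condition, "feature": "nuclear_volume",
             "value": self.nuclear_volume_um3, "unit": "um3"},
            {"cell_id": self.cell_id, "condition": condition, "feature": "nc_ratio",
             "value": self.nc_ratio, "unit": ""},
            {"cell_id": self.cell_id, "condition": condition, "feature": "concavity_pct",
             "value": self.concavity_pct, "unit": "%"},
            {"cell_id": self.cell_id, "condition": condition, "feature": "clump_count",
             "value": float(self.clump_count), "unit": "count"},
        ]


def nuclear_volume(nucleus_mask: LabelMask) -> float:
    """Nuclear volume in µm³.  Raises on an empty mask."""
    n = int(np.count_nonzero(nucleus_mask.data))
    if n == 0:
        raise SegmentationError("nucleus mask is empty")
    return n * nucleus_mask.voxel_volume


def nc_ratio(nucleus_mask: LabelMask, cell_mask: LabelMask) -> float:
    """Nuclear-cytoplasmic ratio V_n / (V_cell − V_n).

    Requires nucleus ⊆ cell and a cell strictly larger than its nucleus.
    """
    nucleus_mask.check_aligned(cell_mask)
    nuc = nucleus_mask.foreground()
    cell = cell_mask.foreground()
    if not nuc.any() or not cell.any():
        raise SegmentationError("empty mask in NC ratio")
    if (nuc & ~cell).any():
        raise NucmorphError("nucleus mask is not contained in the cell mask")
    v_n = nuc.sum() * nucleus_mask.voxel_volume
    v_c = cell.sum() * cell_mask.voxel_volume
    if v_c <= v_n:
        raise NucmorphError("cell volume equals nuclear volume: cytoplasm is empty")
    return float(v_n / (v_c - v_n))


def _hull_volume_voxels(mask: np.ndarray) -> int:
    """Voxel count of the voxelized 3D convex hull of a binary mask."""
    fg = mask > 0
    coords = np.argwhere(fg)
    if coords.shape[0] < 4 or np.linalg.matrix_rank(coords - coords[0]) < 3:
        raise NucmorphError("convex hull needs >= 4 non-coplanar foreground voxels")
    # crop to the bounding box: hull cannot exceed it and it keeps hulling cheap
    lo = coords.min(axis=0)
    hi = coords.max(axis=0) + 1
    sub = fg[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    # voxel-center coordinates (no half-voxel offset): the hull of a convex
    # digital body is then the body itself, so convex shapes score ~0
    return int(convex_hull_image(sub, offset_coordinates=False).sum())


def concavity_index(nucleus_mask: LabelMask) -> float:
    """Nuclear shape concavity in percent: hull volume deficit.

    100 × (V_hull − V_mask) / V_hull with the hull voxelized on the same
    grid as the mask, so convex digital bodies return ≈ 0 (small
    discretization residue only).
    """
    v_mask = int(np.count_nonzero(nucleus_mask.data))
    if v_mask == 0:
        raise SegmentationError("nucleus mask is empty")
    v_hull = _hull_volume_voxels(nucleus_mask.data)
    if v_hull <= 0:
        raise NucmorphError("degenerate convex hull")
    return 100.0 * max(v_hull - v_mask, 0) / v_hull


def count_dense_clumps(
    volume: Volume3D,
    nucleus_mask: LabelMask,
    k_sigma: float = 2.0,
    min_clump_volume_um3: float = 0.5,
) -> int:
    """Number of dense intra-nuclear clumps.

    Threshold T = mean + ``k_sigma``·sd of the absorption intensities within
    the nucleus; 26-connected components of supra-threshold nuclear voxels
    smaller than ``min_clump_volume_um3`` are discarded.  Returns 0 when
    nothing passes.
    """
    nucleus_mask.check_aligned(volume)
    fg = nucleus_mask.foreground()
    if not fg.any():
        raise SegmentationError("nucleus mask is empty")
    vals = volume.data[fg].astype(np.float64)
    thr = vals.mean() + k_sigma * vals.std()
    cand = (volume.data > thr) & fg
    labels, n = ndimage.label(cand, structure=_STRUCT26)
    if n == 0:
        return 0
    counts = np.bincount(labels.ravel())[1:]
    min_vox = min_clump_volume_um3 / volume.voxel_volume
    return int(np.count_nonzero(counts >= min_vox))


def analyze_cell(
    volume: Volume3D,
    cell_mask: LabelMask,
    nucleus_mask: LabelMask,
    cell_id: str = "cell",
    k_sigma: float = 2.0,
    min_clump_volume_um3: float = 0.5,
) -> MorphometryRecord:
    """All four morphometric parameters for one segmented cell."""
    return MorphometryRecord(
        cell_id=cell_id,
        nuclear_volume_um3=nuclear_volume(nucleus_mask),
        nc_ratio=nc_ratio(nucleus_mask, cell_mask),
        concavity_pct=concavity_index(nucleus_mask),
        clump_count=count_dense_clumps(volume, nucleus_mask, k_sigma, min_clump_volume_um3),
    )


@dataclass
class MorphometryRun:
    """Result of a cohort run: feature table plus per-cell failures."""

    table: FeatureTable
    errors: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["cell_id", "condition", "stage", "error"])
    )


def run_morphometry(
    cells: "Iterable[tuple[str, str, Volume3D, LabelMask | None, LabelMask | None]]",
    seg_params=None,
    k_sigma: float = 2.0,
    min_clump_volume_um3: float = 0.5,
) -> MorphometryRun:
    """Run morphometry over a cohort.

    ``cells`` yields (cell_id, condition, volume, cell_mask, nucleus_mask);
    masks may be None, in which case the cell is segmented here with
    ``seg_params``.  Per-cell failures are collected into an error report —
    never silently dropped — and the remaining cells are still returned.
    """
    from .segmentation import SegmentationParams, segment_cell, segment_nucleus

    params = seg_params or SegmentationParams()
    rows: list[dict] = []
    errs: list[dict] = []
    for cell_id, condition, volume, cmask, nmask in cells:
        try:
            if cmask is None:
                cmask = segment_cell(volume, params)
            if nmask is None:
                nmask = segment_nucleus(volume, cmask, params)
            rec = analyze_cell(volume, cmask, nmask, cell_id, k_sigma, min_clump_volume_um3)
        except NucmorphError as exc:
            logger.warning("morphometry failed for %s (%s): %s", cell_id, condition, exc)
            errs.append({"cell_id": cell_id, "condition": condition,
                         "stage": "morphometry", "error": str(exc)})
            continue
        rows.extend(rec.as_rows(condition))
    run = MorphometryRun(table=FeatureTable(pd.DataFrame(rows, columns=list(FeatureTable().df.columns))
                                            if rows else FeatureTable().df))
    if errs:
        run.errors = pd.DataFrame(errs)
    return run


def run_morphometry_dir(cohort_dir: str | Path, seg_params=None, **kwargs) -> MorphometryRun:
    """Run morphometry over a simulated cohort directory (manifest.json)."""
    import json

    from .volume import read_stack

    cohort_dir = Path(cohort_dir)
    manifest = json.loads((cohort_dir / "manifest.json").read_text())

    def gen():
        for entry in manifest["cells"]:
            vol = read_stack(cohort_dir / entry["volume"])
            yield entry["cell_id"], entry["condition"], vol, None, None

    return run_morphometry(gen(), seg_params=seg_params, **kwargs)
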