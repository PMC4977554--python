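"""Volumetric containers and file I/O with explicit physical units.

All image data in nucmorph lives in a :class:`Volume3D` (scalar intensities)
or a :class:`LabelMask` (integer labels), both with axis order (Z, Y, X) and
a per-axis voxel size in micrometres.  Downstream code never works in pixel
units: every volume, distance and threshold that leaves this module is in
µm / µm³.

Volumes round-trip through multi-page TIFF; the voxel size and intensity
convention are stored as JSON in the TIFF ImageDescription tag so that a
file read back without external configuration still knows its units.
Feature tables round-trip through plain CSV (RFC 4180, header row).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError, ShapeError, UnitError

IntensityConvention = Literal["absorption", "fluorescence"]
MaskRole = Literal["cell", "nucleus", "clump", "spot"]

_MIN_AXIS = 8

_TABLE_COLUMNS = ["cell_id", "condition", "feature", "value", "unit"]


def _validate_voxel_size(voxel_size: Sequence[float]) -> tuple[float, float, float]:
    vs = tuple(float(v) for v in voxel_size)
    if len(vs) != 3:
        raise UnitError(f"voxel_size must have 3 components (dz, dy, dx), got {vs!r}")
    if not all(np.isfinite(v) and v > 0 for v in vs):
        raise UnitError(f"voxel_size components must be finite and > 0, got {vs!r}")
    return vs


@dataclass
class Volume3D:
    """A 3D scalar grid with physical voxel size.

    Parameters
    ----------
    data
        3D array, axis order (Z, Y, X), at least 8 voxels per axis.
    voxel_size
        (dz, dy, dx) in µm; all components strictly positive.
    intensity_convention
        ``"absorption"`` — higher value = denser material (optical-CT,
        hematoxylin stain); ``"fluorescence"`` — higher value = more signal.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    intensity_convention: IntensityConvention = "absorption"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ShapeError(f"Volume3D requires 3 axes, got {self.data.ndim}")
        if min(self.data.shape) < _MIN_AXIS:
            raise ShapeError(
                f"Volume3D requires >= {_MIN_AXIS} voxels per axis, got {self.data.shape}"
            )
        self.voxel_size = _validate_voxel_size(self.voxel_size)
        if self.intensity_convention not in ("absorption", "fluorescence"):
            raise ValueError(f"unknown intensity convention {self.intensity_convention!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³."""
        dz, dy, dx = self.voxel_size
        return dz * dy * dx


@dataclass
class LabelMask:
    """Integer label grid aligned to a parent :class:`Volume3D`.

    Value 0 is background.  ``role`` says what the foreground delineates.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    role: MaskRole = "nucleus"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ShapeError(f"LabelMask requires 3 axes, got {self.data.ndim}")
        if not np.issubdtype(self.data.dtype, np.integer):
            if np.issubdtype(self.data.dtype, np.bool_):
                self.data = self.data.astype(np.uint8)
            else:
                raise ShapeError(f"LabelMask requires integer data, got {self.data.dtype}")
        if self.data.size and self.data.min() < 0:
            raise ShapeError("LabelMask values must be nonnegative")
        self.voxel_size = _validate_voxel_size(self.voxel_size)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        dz, dy, dx = self.voxel_size
        return dz * dy * dx

    def foreground(self) -> np.ndarray:
        """Boolean foreground (any nonzero label)."""
        return self.data > 0

    def volume_um3(self) -> float:
        """Foreground volume in µm³ (voxel count × voxel volume)."""
        return float(np.count_nonzero(self.data)) * self.voxel_volume

    def check_aligned(self, other: "Volume3D | LabelMask") -> None:
        if self.shape != other.shape:
            raise ShapeError(f"mask shape {self.shape} != parent shape {other.shape}")


@dataclass
class FeatureTable:
    """Long-format per-cell feature table.

    One row per (cell, condition, feature) with a numeric value and a unit
    string.  This is the table every cohort summary (mean ± SEM) and group
    comparison is computed from.
    """

    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=_TABLE_COLUMNS))

    def __post_init__(self) -> None:
        missing = [c for c in _TABLE_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"feature table missing columns {missing}")
        self.df = self.df[_TABLE_COLUMNS].reset_index(drop=True)
        dup = self.df.duplicated(subset=["cell_id", "condition", "feature"])
        if dup.any():
            pairs = self.df.loc[dup, ["cell_id", "condition", "feature"]].values[:3]
            raise FormatError(f"duplicate (cell_id, condition, feature) rows, e.g. {pairs}")

    @classmethod
    def from_records(cls, records: Iterable[dict]) -> "FeatureTable":
        return cls(pd.DataFrame(list(records), columns=_TABLE_COLUMNS))

    def values(self, feature: str, condition: str | None = None) -> np.ndarray:
        sel = self.df["feature"] == feature
        if condition is not None:
            sel &= self.df["condition"] == condition
        return self.df.loc[sel, "value"].to_numpy(dtype=float)

    def conditions(self) -> list[str]:
        return sorted(self.df["condition"].unique())

    def features(self) -> list[str]:
        return sorted(self.df["feature"].unique())

    def __len__(self) -> int:
        return len(self.df)


# ---------------------------------------------------------------------------
# TIFF I/O


def _metadata_json(voxel_size: Sequence[float], convention: str, role: str | None) -> str:
    meta = {"voxel_size_um": list(voxel_size), "intensity_convention": convention}
    if role is not None:
        meta["mask_role"] = role
    return json.dumps(meta)


def write_stack(volume: Volume3D | LabelMask, path: str | Path) -> Path:
    """Write a volume or mask as a multi-page TIFF.

    Voxel size (µm) and convention/role are recorded as JSON in the
    ImageDescription tag; integer and 32-bit float data round-trip
    losslessly.
    """
    path = Path(path)
    if isinstance(volume, LabelMask):
        desc = _metadata_json(volume.voxel_size, "label", volume.role)
        data = volume.data
    else:
        desc = _metadata_json(volume.voxel_size, volume.intensity_convention, None)
        data = volume.data
    if data.dtype == np.float64:
        data = data.astype(np.float32)
    try:
        tifffile.imwrite(path, data, description=desc, metadata=None)
    except OSError as exc:
        raise OSError(f"cannot write TIFF to {path}: {exc}") from exc
    return path


def _read_tiff(path: Path) -> tuple[np.ndarray, dict]:
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description or ""
    meta: dict = {}
    if desc:
        try:
            parsed = json.loads(desc)
            if isinstance(parsed, dict):
                meta = parsed
        except json.JSONDecodeError:
            pass
    return data, meta


def read_stack(
    path: str | Path,
    voxel_size_override: Sequence[float] | None = None,
    intensity_convention: IntensityConvention | None = None,
) -> Volume3D:
    """Read a multi-page TIFF as a :class:`Volume3D`.

    The voxel size must come from the file's metadata or from
    ``voxel_size_override``; there is no silent pixel-unit default.

    Raises
    ------
    UnitError
        If no voxel size is available.
    ShapeError
        If the file is not a 3D stack.
    """
    data, meta = _read_tiff(Path(path))
    if data.ndim != 3:
        raise ShapeError(f"{path}: expected a 3D stack, got {data.ndim} axes")
    if voxel_size_override is not None:
        vs = _validate_voxel_size(voxel_size_override)
    elif "voxel_size_um" in meta:
        vs = _validate_voxel_size(meta["voxel_size_um"])
    else:
        raise UnitError(
            f"{path}: no voxel size in TIFF metadata and no override given; "
            "physical units are required"
        )
    conv = intensity_convention or meta.get("intensity_convention", "absorption")
    if conv == "label":
        conv = "absorption"
    return Volume3D(data=data, voxel_size=vs, intensity_convention=conv)  # type: ignore[arg-type]


def read_mask(
    path: str | Path,
    voxel_size_override: Sequence[float] | None = None,
    role: MaskRole | None = None,
) -> LabelMask:
    """Read a label mask TIFF (integer data)."""
    data, meta = _read_tiff(Path(path))
    if data.ndim != 3:
        raise ShapeError(f"{path}: expected a 3D mask, got {data.ndim} axes")
    if voxel_size_override is not None:
        vs = _validate_voxel_size(voxel_size_override)
    elif "voxel_size_um" in meta:
        vs = _validate_voxel_size(meta["voxel_size_um"])
    else:
        raise UnitError(f"{path}: no voxel size metadata and no override")
    return LabelMask(data=data, voxel_size=vs, role=role or meta.get("mask_role", "nucleus"))


# ---------------------------------------------------------------------------
# Feature-table I/O


def write_feature_table(table: FeatureTable, path: str | Path) -> Path:
    """Write a feature table as CSV (header ``cell_id,condition,feature,value,unit``)."""
    path = Path(path)
    table.df.to_csv(path, index=False)
    return path


def read_feature_table(path: str | Path) -> FeatureTable:
    """Read a feature table CSV written by :func:`write_feature_table`.

    Raises :class:`FormatError` on a malformed header.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"cell_id": str, "condition": str, "feature": str, "unit": str})
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if len(df):
        df["value"] = df["value"].astype(float)
    return FeatureTable(df)
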