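"""Synthetic single-cell phantoms with planted ground truth.

This module generates every input the analysis pipeline consumes, with a
ground-truth manifest so each stage is testable by parameter recovery:

* absorption-convention optical-CT-like volumes of one cell — an ellipsoidal
  cytoplasm containing a denser ellipsoidal nucleus, optional dense
  spherical chromatin clumps inside the nucleus, and optional surface
  invaginations (spherical bites removed from the nuclear surface) that
  produce a known convex-hull volume deficit;
* confocal-like multi-channel fluorescence stacks (DAPI / FISH / H3K9ac)
  with FISH spots planted at requested relative radial distances and an
  H3K9ac channel built to a requested Pearson correlation with the FISH
  channel;
* viability tables drawn from the four-parameter logistic law; and
* qPCR Ct tables consistent with efficiency-corrected amplification.

Ground-truth volumes, NC ratios, concavity and clump counts are computed
from the *generated masks themselves* (voxel counts, hull deficits,
connected components), never from the analytic shape parameters, so
discretization is shared with the pipeline under test.

The noise model is additive Gaussian only; tomographic reconstruction
artifacts and point-spread blurring are deliberately not modelled.
All generation is reproducible: same seed, bit-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import NucmorphError, PlacementError
from .gene_position import mask_centroid_um, ray_boundary_distance, rrd, signed_distance_field
from .morphometry import concavity_index
from .volume import FeatureTable, LabelMask, Volume3D, write_feature_table, write_stack

_STRUCT26 = np.ones((3, 3, 3), dtype=int)


@dataclass
class CellPhantomSpec:
    """Geometry, intensity and noise parameters of one cell phantom.

    Lengths in µm; intensities in arbitrary absorption units.  The clump
    contrast multiplies the nuclear base intensity (default 1.8, well above
    the default mean+2·sd detection threshold); invaginations are spherical
    bites centred on the nuclear surface.
    """

    cell_semiaxes_um: tuple[float, float, float] = (7.2, 7.2, 7.2)
    nucleus_semiaxes_um: tuple[float, float, float] = (5.0, 5.0, 5.0)
    nucleus_offset_um: tuple[float, float, float] = (0.0, 0.0, 0.0)
    n_clumps: int = 0
    clump_radius_um: float = 0.7
    clump_contrast: float = 1.8
    clump_separation_factor: float = 2.0  # min center distance in clump diameters
    n_invaginations: int = 0
    invagination_radius_um: float = 2.0
    background_intensity: float = 0.05
    cytoplasm_intensity: float = 0.40
    nucleus_intensity: float = 0.80
    noise_sd: float = 0.0
    voxel_size_um: tuple[float, float, float] = (0.35, 0.35, 0.35)
    margin_um: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        cs = np.asarray(self.cell_semiaxes_um, dtype=float)
        ns = np.asarray(self.nucleus_semiaxes_um, dtype=float)
        off = np.abs(np.asarray(self.nucleus_offset_um, dtype=float))
        if np.any(ns + off > cs + 1e-9):
            raise NucmorphError("nucleus (with offset) does not fit inside the cell")
        if self.n_clumps < 0 or self.n_invaginations < 0:
            raise NucmorphError("object counts must be >= 0")
        if self.n_clumps and self.clump_contrast <= 1.0:
            raise NucmorphError("clump contrast must exceed 1")
        if not self.nucleus_intensity > self.cytoplasm_intensity > self.background_intensity:
            raise NucmorphError("require nucleus > cytoplasm > background intensity")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        cs = np.asarray(self.cell_semiaxes_um, dtype=float)
        vs = np.asarray(self.voxel_size_um, dtype=float)
        n = np.ceil(2 * (cs + self.margin_um) / vs).astype(int)
        return tuple(int(max(v, 8)) for v in n)


@dataclass
class GroundTruth:
    """Planted truths, all measured from the emitted masks."""

    nuclear_volume_um3: float
    cell_volume_um3: float
    nc_ratio: float
    concavity_pct: float
    clump_count: int
    spot_rrds: list[float] = field(default_factory=list)
    requested_spot_rrds: list[float] = field(default_factory=list)
    spot_centroids_um: list[tuple[float, float, float]] = field(default_factory=list)
    params: dict = field(default_factory=dict)


def _coordinate_grids(shape, voxel_size):
    vs = np.asarray(voxel_size, dtype=float)
    axes = [np.arange(n) * vs[i] for i, n in enumerate(shape)]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid_mask(shape, voxel_size, center_um, semiaxes_um) -> np.ndarray:
    zz, yy, xx = _coordinate_grids(shape, voxel_size)
    c = np.asarray(center_um, dtype=float)
    s = np.asarray(semiaxes_um, dtype=float)
    q = ((zz - c[0]) / s[0]) ** 2 + ((yy - c[1]) / s[1]) ** 2 + ((xx - c[2]) / s[2]) ** 2
    return q <= 1.0


def _ball_at(shape, voxel_size, center_um, radius_um) -> np.ndarray:
    return _ellipsoid_mask(shape, voxel_size, center_um, (radius_um,) * 3)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n < 1e-12:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


def _place_clumps(
    rng: np.random.Generator,
    nucleus_mask: np.ndarray,
    voxel_size,
    n_clumps: int,
    radius_um: float,
    separation_factor: float = 2.0,
    max_retries: int = 2000,
) -> list[np.ndarray]:
    """Sample clump centers inside the nucleus, min center separation
    ``separation_factor`` clump diameters, each ball fully inside the mask."""
    if n_clumps == 0:
        return []
    sdf = signed_distance_field(nucleus_mask, tuple(voxel_size))
    valid = np.argwhere(sdf >= radius_um + 0.5 * min(voxel_size))
    if valid.shape[0] == 0:
        raise PlacementError("nucleus too small for requested clump radius")
    min_sep = separation_factor * 2.0 * radius_um
    vs = np.asarray(voxel_size, dtype=float)
    # random sequential placement with full restarts: a greedy run can wedge
    # itself even when a feasible configuration exists
    for _ in range(20):
        centers: list[np.ndarray] = []
        tries = 0
        while len(centers) < n_clumps and tries < max_retries:
            tries += 1
            cand = valid[rng.integers(valid.shape[0])] * vs
            if all(np.linalg.norm(cand - c) >= min_sep for c in centers):
                centers.append(cand)
        if len(centers) == n_clumps:
            return centers
    raise PlacementError(
        f"placed only {len(centers)}/{n_clumps} clumps after bounded retries "
        f"(separation {min_sep:.2f} µm in this nucleus)"
    )


def make_cell_phantom(
    spec: CellPhantomSpec,
) -> tuple[Volume3D, LabelMask, LabelMask, GroundTruth]:
    """Generate one absorption-convention cell phantom.

    Returns the noisy volume, the true cell mask, the true nucleus mask
    (after invaginations) and the ground truth measured from those masks.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.grid_shape
    vs = spec.voxel_size_um
    center = (np.array(shape) - 1) * np.asarray(vs) / 2.0

    cell = _ellipsoid_mask(shape, vs, center, spec.cell_semiaxes_um)
    nuc_center = center + np.asarray(spec.nucleus_offset_um)
    nucleus = _ellipsoid_mask(shape, vs, nuc_center, spec.nucleus_semiaxes_um)

    # invaginations: spherical bites centred on the nuclear surface
    for _ in range(spec.n_invaginations):
        u = _random_unit(rng)
        surf = nuc_center + u * np.asarray(spec.nucleus_semiaxes_um)
        nucleus &= ~_ball_at(shape, vs, surf, spec.invagination_radius_um)
    if not nucleus.any():
        raise PlacementError("invaginations removed the entire nucleus")
    # keep the largest component: a bite could in principle split the mask
    labels, n = ndimage.label(nucleus, structure=_STRUCT26)
    if n > 1:
        nucleus = labels == (np.bincount(labels.ravel())[1:].argmax() + 1)

    intensity = np.full(shape, spec.background_intensity, dtype=np.float32)
    intensity[cell] = spec.cytoplasm_intensity
    intensity[nucleus] = spec.nucleus_intensity

    clump_mask = np.zeros(shape, dtype=bool)
    if spec.n_clumps:
        centers = _place_clumps(rng, nucleus, vs, spec.n_clumps, spec.clump_radius_um,
                                separation_factor=spec.clump_separation_factor)
        for c in centers:
            clump_mask |= _ball_at(shape, vs, c, spec.clump_radius_um)
        clump_mask &= nucleus
        intensity[clump_mask] = spec.clump_contrast * spec.nucleus_intensity

    if spec.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, spec.noise_sd, size=shape).astype(np.float32)

    volume = Volume3D(intensity.astype(np.float32), vs, "absorption")
    cell_mask = LabelMask(cell.astype(np.uint8), vs, role="cell")
    nucleus_mask = LabelMask(nucleus.astype(np.uint8), vs, role="nucleus")

    vv = volume.voxel_volume
    v_n = float(nucleus.sum()) * vv
    v_c = float(cell.sum()) * vv
    truth = GroundTruth(
        nuclear_volume_um3=v_n,
        cell_volume_um3=v_c,
        nc_ratio=v_n / (v_c - v_n),
        concavity_pct=concavity_index(nucleus_mask),
        clump_count=int(ndimage.label(clump_mask, structure=_STRUCT26)[1]),
        params=asdict(spec),
    )
    return volume, cell_mask, nucleus_mask, truth


# ---------------------------------------------------------------------------
# FISH phantoms


def _gaussian_random_field(rng, shape, sigma_vox: float = 1.5) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.normal(size=shape), sigma_vox)
    f -= f.mean()
    sd = f.std()
    return f / sd if sd > 0 else f


def make_fish_phantom(
    spec: CellPhantomSpec,
    spot_rrds: Sequence[float],
    coloc_rho: float = 0.5,
    seed: int | None = None,
    z_step_um: float | None = None,
    spot_sigma_um: float = 0.3,
    spot_amplitude: float = 1.0,
    independent_noise_sd: float = 1.0,
    min_spot_separation_um: float = 1.5,
) -> tuple[dict[str, Volume3D], LabelMask, GroundTruth]:
    """Generate a confocal-like DAPI / FISH / H3K9ac stack.

    Each requested spot is placed on a random ray from the nucleus centroid
    at the fractional radial position that yields the requested RRD under
    the centroid-ray definition.  The H3K9ac channel mixes the standardized
    FISH signal with an independent Gaussian random field so the
    whole-nucleus Pearson correlation with the FISH channel targets
    ``coloc_rho`` (with ``independent_noise_sd=0`` and ``coloc_rho=1`` the
    two nuclear signals are identical up to an affine map).

    ``z_step_um`` switches to an anisotropic grid (e.g. 0.25 µm axial step)
    while x/y keep the spec's lateral voxel size.
    """
    for r in spot_rrds:
        if not 0.0 <= r <= 1.0:
            raise NucmorphError(f"requested RRD {r} outside [0, 1]")
    if not -1.0 <= coloc_rho <= 1.0:
        raise NucmorphError("coloc_rho must lie in [-1, 1]")
    rng = np.random.default_rng(spec.seed if seed is None else seed)

    vs = np.asarray(spec.voxel_size_um, dtype=float)
    if z_step_um is not None:
        vs = np.array([z_step_um, vs[1], vs[2]])
    ns = np.asarray(spec.nucleus_semiaxes_um, dtype=float)
    shape = tuple(int(max(v, 8)) for v in np.ceil(2 * (ns + spec.margin_um) / vs).astype(int))
    center = (np.array(shape) - 1) * vs / 2.0

    nucleus = _ellipsoid_mask(shape, tuple(vs), center, ns)
    nucleus_mask = LabelMask(nucleus.astype(np.uint8), tuple(vs), role="nucleus")
    sdf = signed_distance_field(nucleus, tuple(vs))
    centroid = mask_centroid_um(nucleus, tuple(vs))

    dapi = np.full(shape, 0.02, dtype=np.float32)
    dapi[nucleus] = 0.8
    fish = np.full(shape, 0.0, dtype=np.float32)

    zz, yy, xx = _coordinate_grids(shape, tuple(vs))
    placed: list[tuple[float, float, float]] = []
    for req in spot_rrds:
        # resample the ray direction until spots are separated enough to be
        # individually resolvable (close alleles merge under any detector)
        pos = None
        for _ in range(200):
            u = _random_unit(rng)
            t_b = ray_boundary_distance(sdf, tuple(vs), centroid, u, start_um=0.0)
            # keep boundary spots (RRD→0) half a voxel inside the mask
            radial = min((1.0 - req) * t_b, t_b - 0.5 * float(vs.min()))
            cand = centroid + max(radial, 0.0) * u
            if all(np.linalg.norm(cand - np.asarray(p)) >= min_spot_separation_um
                   for p in placed):
                pos = cand
                break
        if pos is None:
            raise PlacementError(
                f"could not separate {len(spot_rrds)} spots by "
                f"{min_spot_separation_um} µm in this nucleus"
            )
        placed.append(tuple(float(p) for p in pos))
        d2 = (zz - pos[0]) ** 2 + (yy - pos[1]) ** 2 + (xx - pos[2]) ** 2
        fish += spot_amplitude * np.exp(-d2 / (2 * spot_sigma_um**2)).astype(np.float32)
    if spec.noise_sd > 0:
        fish = fish + rng.normal(0.0, spec.noise_sd, size=shape).astype(np.float32)
        dapi = dapi + rng.normal(0.0, spec.noise_sd, size=shape).astype(np.float32)

    # H3K9ac: rho·standardized(FISH | nucleus) + sqrt(1-rho²)·independent field
    h3 = rng.normal(0.0, 0.05, size=shape).astype(np.float32)
    fvals = fish[nucleus].astype(np.float64)
    fsd = fvals.std()
    zf = (fvals - fvals.mean()) / fsd if fsd > 0 else np.zeros_like(fvals)
    indep = rng.normal(size=zf.shape) * independent_noise_sd
    isd = indep.std()
    if isd > 0:
        indep = indep / isd
    mix = coloc_rho * zf + np.sqrt(max(0.0, 1.0 - coloc_rho**2)) * indep
    h3[nucleus] = (0.5 + 0.15 * mix).astype(np.float32)

    channels = {
        "dapi": Volume3D(dapi, tuple(vs), "fluorescence"),
        "fish": Volume3D(fish.astype(np.float32), tuple(vs), "fluorescence"),
        "h3k9ac": Volume3D(h3, tuple(vs), "fluorescence"),
    }
    measured = [rrd(p, nucleus_mask, sdf=sdf) for p in placed]
    vv = float(np.prod(vs))
    v_n = float(nucleus.sum()) * vv
    truth = GroundTruth(
        nuclear_volume_um3=v_n,
        cell_volume_um3=v_n,
        nc_ratio=1.0,
        concavity_pct=concavity_index(nucleus_mask),
        clump_count=0,
        spot_rrds=measured,
        requested_spot_rrds=[float(r) for r in spot_rrds],
        spot_centroids_um=placed,
        params={"coloc_rho": coloc_rho, "z_step_um": z_step_um, **asdict(spec)},
    )
    return channels, nucleus_mask, truth


# ---------------------------------------------------------------------------
# Cohorts


@dataclass
class CohortSpec:
    """Population parameters for one experimental condition.

    Nuclear volumes are drawn Normal(mean, sd) (truncated > 8 µm³) and
    converted to sphere radii; the NC ratio target sets the cell radius;
    clump counts are Poisson; a fraction of cells carries surface
    invaginations.  Defaults are at the scale of an adenocarcinoma line
    under vehicle: mean nuclear volume ≈ 670 µm³, NC ≈ 0.65, ≈ 6 clumps.
    """

    condition: str = "DMSO"
    nuclear_volume_mean_um3: float = 672.7
    nuclear_volume_sd_um3: float = 323.9  # SEM 22.9 at n=200
    nc_mean: float = 0.65
    nc_sd: float = 0.05
    clump_count_mean: float = 6.1
    clump_radius_um: float = 0.6
    clump_contrast: float = 1.8
    clump_separation_factor: float = 2.0
    invagination_prob: float = 0.3
    n_invaginations: int = 2
    invagination_radius_um: float = 1.5
    noise_sd: float = 0.02
    voxel_size_um: tuple[float, float, float] = (0.35, 0.35, 0.35)
    margin_um: float = 1.0


def sample_cohort_specs(n_cells: int, pop: CohortSpec, seed: int) -> list[CellPhantomSpec]:
    """Draw per-cell phantom specs from the population; deterministic."""
    if n_cells < 1:
        raise NucmorphError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n_cells):
        v = -1.0
        while v < 8.0:
            v = rng.normal(pop.nuclear_volume_mean_um3, pop.nuclear_volume_sd_um3)
        r_nuc = (3.0 * v / (4.0 * np.pi)) ** (1.0 / 3.0)
        nc = max(rng.normal(pop.nc_mean, pop.nc_sd), 0.05)
        r_cell = r_nuc * (1.0 + 1.0 / nc) ** (1.0 / 3.0)
        # cap the Poisson draw at what random sequential placement can fit
        r_valid = r_nuc - pop.clump_radius_um - 0.5 * min(pop.voxel_size_um)
        min_sep = pop.clump_separation_factor * 2.0 * pop.clump_radius_um
        cap = int(0.25 * ((2.0 * max(r_valid, 0.0) + min_sep) / min_sep) ** 3)
        n_clumps = min(int(rng.poisson(pop.clump_count_mean)), max(cap, 0))
        invag = rng.random() < pop.invagination_prob
        offset_mag = rng.uniform(0.0, max(0.0, 0.5 * (r_cell - r_nuc)))
        offset = _random_unit(rng) * offset_mag
        specs.append(
            CellPhantomSpec(
                cell_semiaxes_um=(r_cell,) * 3,
                nucleus_semiaxes_um=(r_nuc,) * 3,
                nucleus_offset_um=tuple(offset),
                n_clumps=n_clumps,
                clump_radius_um=pop.clump_radius_um,
                clump_contrast=pop.clump_contrast,
                clump_separation_factor=pop.clump_separation_factor,
                n_invaginations=pop.n_invaginations if invag else 0,
                invagination_radius_um=min(pop.invagination_radius_um, 0.8 * r_nuc),
                noise_sd=pop.noise_sd,
                voxel_size_um=pop.voxel_size_um,
                margin_um=pop.margin_um,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return specs


def iter_cohort(specs: Sequence[CellPhantomSpec], condition: str, id_prefix: str = "cell"):
    """Yield (cell_id, condition, volume, cell_mask, nucleus_mask, truth)."""
    for i, spec in enumerate(specs):
        vol, cmask, nmask, truth = make_cell_phantom(spec)
        yield f"{id_prefix}_{condition}_{i:04d}", condition, vol, cmask, nmask, truth


def make_cohort(
    n_cells: int,
    pop: CohortSpec,
    seed: int,
    out_dir: str | Path | None = None,
) -> tuple[list[CellPhantomSpec], FeatureTable]:
    """Generate a cohort; return per-cell specs and the ground-truth table.

    With ``out_dir`` set, volumes/masks are written as TIFFs together with
    ``ground_truth.csv`` and ``manifest.json``.
    """
    specs = sample_cohort_specs(n_cells, pop, seed)
    rows: list[dict] = []
    manifest: list[dict] = []
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
    for cell_id, condition, vol, cmask, nmask, truth in iter_cohort(specs, pop.condition):
        rows.extend(_truth_rows(cell_id, condition, truth))
        if out_dir is not None:
            vpath = f"{cell_id}.tif"
            write_stack(vol, out_dir / vpath)
            write_stack(cmask, out_dir / f"{cell_id}_cell_mask.tif")
            write_stack(nmask, out_dir / f"{cell_id}_nucleus_mask.tif")
            manifest.append({"cell_id": cell_id, "condition": condition, "volume": vpath,
                             "cell_mask": f"{cell_id}_cell_mask.tif",
                             "nucleus_mask": f"{cell_id}_nucleus_mask.tif"})
    truth_table = FeatureTable(pd.DataFrame(rows))
    if out_dir is not None:
        write_feature_table(truth_table, out_dir / "ground_truth.csv")
        (out_dir / "manifest.json").write_text(
            json.dumps({"condition": pop.condition, "n_cells": n_cells, "seed": seed,
                        "cells": manifest}, indent=1)
        )
    return specs, truth_table


def _truth_rows(cell_id: str, condition: str, truth: GroundTruth) -> list[dict]:
    return [
        {"cell_id": cell_id, "condition": condition, "feature": "nuclear_volume",
         "value": truth.nuclear_volume_um3, "unit": "um3"},
        {"cell_id": cell_id, "condition": condition, "feature": "nc_ratio",
         "value": truth.nc_ratio, "unit": ""},
        {"cell_id": cell_id, "condition": condition, "feature": "concavity_pct",
         "value": truth.concavity_pct, "unit": "%"},
        {"cell_id": cell_id, "condition": condition, "feature": "clump_count",
         "value": float(truth.clump_count), "unit": "count"},
    ]


# ---------------------------------------------------------------------------
# Viability and qPCR tables


def default_dose_series(top_dose_um: float = 100.0, n_points: int = 10, fold: float = 3.0) -> np.ndarray:
    """The assay's serial dilution: ``n_points`` doses, ``fold``-fold steps
    down from ``top_dose_um`` (µM)."""
    return top_dose_um / fold ** np.arange(n_points)


def four_param_logistic(x: np.ndarray, top: float, bottom: float, logic50: float, hillslope: float):
    """Response at X = log10(dose): Bottom + (Top−Bottom)/(1 + 10^((LogIC50−X)·HillSlope))."""
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((logic50 - np.asarray(x, dtype=float)) * hillslope))


def make_viability_table(
    params: tuple[float, float, float, float],
    doses_um: Sequence[float] | None = None,
    n_reps: int = 6,
    noise_sd: float = 3.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a viability plate: (dose_uM, replicate, response) rows.

    ``params`` is (Top, Bottom, LogIC50, HillSlope) on a 0–100 viability
    scale; the default dose series is the 10-point, 3-fold dilution from
    100 µM with 6 replicates per dose and Gaussian noise sd 3.
    """
    doses = np.asarray(default_dose_series() if doses_um is None else doses_um, dtype=float)
    if np.any(doses <= 0):
        raise NucmorphError("doses must be strictly positive (µM)")
    top, bottom, logic50, hillslope = params
    rng = np.random.default_rng(seed)
    rows = []
    for d in doses:
        y = four_param_logistic(np.log10(d), top, bottom, logic50, hillslope)
        for rep in range(n_reps):
            rows.append({"dose_uM": d, "replicate": rep,
                         "response": float(y + rng.normal(0.0, noise_sd) if noise_sd > 0 else y)})
    return pd.DataFrame(rows)


def make_qpcr_table(
    efficiencies: dict[str, float],
    fold_changes: dict[str, float],
    ref_gene: str = "ACTB",
    n_reps: int = 3,
    base_ct: float = 24.0,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a Ct table for Pfaffl analysis.

    For a gene with amplification efficiency E and a treated/control
    template fold change f, Ct_treated = Ct_control − log_E(f); the
    reference gene has fold change 1.  Columns: gene, condition
    (control/treated), replicate, ct.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for gene, eff in efficiencies.items():
        if not 1.0 < eff <= 2.0:
            raise NucmorphError(f"efficiency for {gene} must lie in (1, 2], got {eff}")
        fold = 1.0 if gene == ref_gene else float(fold_changes.get(gene, 1.0))
        ct_control = base_ct + rng.uniform(-2.0, 2.0)
        ct_treated = ct_control - np.log(fold) / np.log(eff)
        for cond, ct in (("control", ct_control), ("treated", ct_treated)):
            for rep in range(n_reps):
                rows.append({"gene": gene, "condition": cond, "replicate": rep,
                             "ct": float(ct + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0))})
    return pd.DataFrame(rows)
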