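import numpy as np
import pytest
from scipy.spatial import Delaunay

from conftest import rot90_mask
from nucmorph.errors import NucmorphError, SegmentationError
from nucmorph.morphometry import (
    MorphometryRecord,
    analyze_cell,
    concavity_index,
    count_dense_clumps,
    nc_ratio,
    nuclear_volume,
    run_morphometry,
)
from nucmorph.phantoms import (
    CellPhantomSpec,
    CohortSpec,
    iter_cohort,
    make_cell_phantom,
    sample_cohort_specs,
)
from nucmorph.segmentation import segment_cell, segment_nucleus
from nucmorph.volume import LabelMask, Volume3D


def hull_deficit_oracle(mask: np.ndarray) -> float:
    """Brute-force concavity oracle: Delaunay-test every voxel center against
    the convex hull of the foreground voxel centers."""
    pts = np.argwhere(mask > 0).astype(float)
    tri = Delaunay(pts)
    grid = np.argwhere(np.ones_like(mask, dtype=bool)).astype(float)
    inside = tri.find_simplex(grid) >= 0
    v_hull = int(inside.sum())
    v_mask = int((mask > 0).sum())
    return 100.0 * (v_hull - v_mask) / v_hull


class TestNuclearVolume:
    def test_count_times_voxel_volume(self):
        data = np.zeros((12, 12, 12), np.uint8)
        data[1:11, 1:11, 1:11] = 1  # 1000 voxels
        assert nuclear_volume(LabelMask(data, (0.5, 0.5, 0.5))) == pytest.approx(125.0)

    def test_digital_ball_matches_analytic_sphere(self, sphere_mask_5um):
        assert nuclear_volume(sphere_mask_5um) == pytest.approx(523.6, rel=0.03)

    def test_rotation_invariance_exact(self, sphere_mask_5um):
        assert nuclear_volume(rot90_mask(sphere_mask_5um)) == nuclear_volume(sphere_mask_5um)

    def test_empty_mask_raises(self):
        with pytest.raises(SegmentationError):
            nuclear_volume(LabelMask(np.zeros((8, 8, 8), np.uint8), (1, 1, 1)))


class TestNCRatio:
    @staticmethod
    def _nested(cell_vox: int, nuc_vox: int):
        cell = np.zeros((20, 20, 20), np.uint8)
        nuc = np.zeros_like(cell)
        cell.ravel()[:cell_vox] = 1
        nuc.ravel()[:nuc_vox] = 1
        return (LabelMask(nuc, (1, 1, 1)), LabelMask(cell, (1, 1, 1)))

    def test_cytoplasm_denominator(self):
        nuc, cell = self._nested(4000, 1000)
        assert nc_ratio(nuc, cell) == pytest.approx(1000 / 3000)

    def test_half_cell_nucleus_gives_unit_ratio(self):
        nuc, cell = self._nested(2000, 1000)
        assert nc_ratio(nuc, cell) == pytest.approx(1.0)

    def test_cell_equal_nucleus_raises(self):
        nuc, cell = self._nested(1000, 1000)
        with pytest.raises(NucmorphError):
            nc_ratio(nuc, cell)

    def test_planted_nc_recovered_within_5pct(self):
        # FLO-1 DMSO scale: planted NC ~0.65
        spec = CellPhantomSpec(cell_semiaxes_um=(6.86, 6.86, 6.86),
                               nucleus_semiaxes_um=(5.0, 5.0, 5.0), noise_sd=0.0, seed=9)
        vol, _, _, gt = make_cell_phantom(spec)
        cmask = segment_cell(vol)
        nmask = segment_nucleus(vol, cmask)
        est = nc_ratio(nmask, cmask)
        assert abs(est - gt.nc_ratio) / gt.nc_ratio <= 0.05


class TestConcavity:
    def test_digital_ball_is_nearly_convex(self, sphere_mask_5um):
        assert concavity_index(sphere_mask_5um) <= 2.0

    def test_agrees_with_brute_force_hull_oracle(self):
        # ball r=20 voxels minus a surface-centered ball r=10
        n = 48
        zz, yy, xx = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
        c = (n - 1) / 2
        ball = (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= 20**2
        bite = (zz - c) ** 2 + (yy - c) ** 2 + (xx - (c + 20)) ** 2 <= 10**2
        mask = (ball & ~bite).astype(np.uint8)
        ours = concavity_index(LabelMask(mask, (1, 1, 1)))
        oracle = hull_deficit_oracle(mask)
        assert ours == pytest.approx(oracle, abs=0.5)

    def test_planted_hull_deficit_recovered_within_3pp(self):
        # CP-A post-drug scale (~27% deficit)
        spec = CellPhantomSpec(n_invaginations=2, invagination_radius_um=4.5,
                               noise_sd=0.02, seed=11)
        vol, _, _, gt = make_cell_phantom(spec)
        assert gt.concavity_pct > 20.0
        rec = analyze_cell(vol, segment_cell(vol), segment_nucleus(vol, segment_cell(vol)))
        assert abs(rec.concavity_pct - gt.concavity_pct) <= 3.0

    def test_monotone_in_invagination_radius(self):
        values = []
        for r_inv in (1.5, 2.5, 3.5, 4.5):
            spec = CellPhantomSpec(n_invaginations=2, invagination_radius_um=r_inv,
                                   noise_sd=0.0, seed=17)
            _, _, nmask, _ = make_cell_phantom(spec)
            values.append(concavity_index(nmask))
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_too_few_voxels_raise(self):
        data = np.zeros((8, 8, 8), np.uint8)
        data[0, 0, :3] = 1  # collinear
        with pytest.raises(NucmorphError):
            concavity_index(LabelMask(data, (1, 1, 1)))


class TestClumpCount:
    @pytest.mark.parametrize("planted", [0, 5, 6])
    def test_planted_clumps_recovered_exactly(self, planted):
        spec = CellPhantomSpec(n_clumps=planted, noise_sd=0.02, seed=23 + planted)
        vol, _, _, gt = make_cell_phantom(spec)
        assert gt.clump_count == planted
        nmask = segment_nucleus(vol, segment_cell(vol))
        assert count_dense_clumps(vol, nmask) == planted

    def test_recovery_up_to_10pct_noise(self):
        # quantified recovery: separation >= 2 diameters, contrast 1.8,
        # noise up to 10% of the nuclear base intensity
        spec = CellPhantomSpec(n_clumps=5, noise_sd=0.08, seed=31)
        vol, _, nmask, gt = make_cell_phantom(spec)
        assert count_dense_clumps(vol, nmask) == gt.clump_count == 5

    def test_translation_invariance_exact(self, noisy_clump_phantom):
        vol, _, nmask, _ = noisy_clump_phantom
        shifted_vol = Volume3D(np.roll(vol.data, 2, axis=0), vol.voxel_size)
        shifted_mask = LabelMask(np.roll(nmask.data, 2, axis=0), nmask.voxel_size)
        assert (count_dense_clumps(shifted_vol, shifted_mask)
                == count_dense_clumps(vol, nmask))


class TestRecordAndCohort:
    def test_record_validation(self):
        with pytest.raises(ValueError):
            MorphometryRecord("c", -1.0, 0.5, 1.0, 2)
        with pytest.raises(ValueError):
            MorphometryRecord("c", 100.0, 0.5, 120.0, 2)

    def test_all_features_rotation_invariant(self, noisy_clump_phantom):
        vol, cmask, nmask, _ = noisy_clump_phantom
        a = analyze_cell(vol, cmask, nmask)
        b = analyze_cell(rot90_volume_all(vol), rot90_mask(cmask), rot90_mask(nmask))
        assert a.nuclear_volume_um3 == b.nuclear_volume_um3
        assert a.nc_ratio == b.nc_ratio
        assert a.concavity_pct == pytest.approx(b.concavity_pct, abs=1e-9)
        assert a.clump_count == b.clump_count

    def test_cohort_run_counts_and_determinism(self):
        pop = CohortSpec(nuclear_volume_mean_um3=220.0, nuclear_volume_sd_um3=40.0,
                         voxel_size_um=(0.5, 0.5, 0.5))
        specs = sample_cohort_specs(8, pop, seed=3)

        def cells():
            for cid, cond, vol, _c, _n, _t in iter_cohort(specs, "DMSO"):
                yield cid, cond, vol, None, None

        run1 = run_morphometry(cells())
        run2 = run_morphometry(cells())
        assert len(run1.table.df) == 8 * 4
        assert len(run1.errors) == 0
        assert run1.table.df.equals(run2.table.df)

    def test_failures_collected_not_dropped(self):
        flat = Volume3D(np.full((16, 16, 16), 0.3, np.float32), (0.5, 0.5, 0.5))
        good_vol, good_c, good_n, _ = make_cell_phantom(
            CellPhantomSpec(voxel_size_um=(0.5, 0.5, 0.5), seed=2))
        run = run_morphometry([
            ("bad", "DMSO", flat, None, None),
            ("good", "DMSO", good_vol, good_c, good_n),
        ])
        assert list(run.errors.cell_id) == ["bad"]
        assert set(run.table.df.cell_id) == {"good"}


def rot90_volume_all(vol: Volume3D) -> Volume3D:
    return Volume3D(np.rot90(vol.data, k=1, axes=(1, 2)).copy(), vol.voxel_size,
                    vol.intensity_convention)
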