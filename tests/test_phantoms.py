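"""Generator correctness: planted truths must be measurable from the emitted
masks and all generation must be reproducible under its seed."""

import numpy as np
import pytest
from scipy import ndimage

from nucmorph.errors import NucmorphError, PlacementError
from nucmorph.gene_position import mask_centroid_um, pearson_colocalization, signed_distance_field
from nucmorph.phantoms import (
    CellPhantomSpec,
    CohortSpec,
    default_dose_series,
    four_param_logistic,
    make_cell_phantom,
    make_cohort,
    make_fish_phantom,
    make_qpcr_table,
    make_viability_table,
    sample_cohort_specs,
)


class TestCellPhantom:
    def test_sphere_volume_matches_analytic(self):
        spec = CellPhantomSpec(seed=1)  # nucleus radius 5 µm, 0.35 µm voxels
        _, _, nmask, gt = make_cell_phantom(spec)
        analytic = 4.0 / 3.0 * np.pi * 5.0**3
        assert gt.nuclear_volume_um3 == pytest.approx(analytic, rel=0.03)
        # truth equals voxel count x voxel volume exactly
        assert gt.nuclear_volume_um3 == pytest.approx(
            np.count_nonzero(nmask.data) * nmask.voxel_volume, abs=1e-9)

    def test_convex_nucleus_has_near_zero_concavity(self):
        _, _, _, gt = make_cell_phantom(CellPhantomSpec(seed=2))
        assert 0.0 <= gt.concavity_pct <= 2.0

    def test_planted_clump_count_matches_components(self):
        vol, _, nmask, gt = make_cell_phantom(CellPhantomSpec(n_clumps=5, seed=3))
        assert gt.clump_count == 5
        # independent recount from the intensity image itself
        bright = vol.data > 1.2 * 0.80  # above nucleus base, below clump level x contrast
        n = ndimage.label(bright & nmask.foreground().astype(bool),
                          structure=np.ones((3, 3, 3), int))[1]
        assert n == 5

    def test_intensity_ordering_nucleus_cytoplasm_background(self):
        vol, cmask, nmask, _ = make_cell_phantom(CellPhantomSpec(seed=4))
        nuc = vol.data[nmask.foreground()].mean()
        cyto = vol.data[cmask.foreground() & ~nmask.foreground()].mean()
        bg = vol.data[~cmask.foreground()].mean()
        assert nuc > cyto > bg

    def test_invaginations_raise_concavity_monotonically(self):
        last = -1.0
        for r_inv in (0.0, 2.0, 3.0, 4.0):
            spec = CellPhantomSpec(n_invaginations=2 if r_inv else 0,
                                   invagination_radius_um=max(r_inv, 1.0), seed=7)
            _, _, _, gt = make_cell_phantom(spec)
            assert gt.concavity_pct > last or r_inv == 0.0
            last = gt.concavity_pct

    def test_same_seed_bit_identical(self):
        spec = CellPhantomSpec(n_clumps=3, noise_sd=0.05, seed=11)
        v1, c1, n1, g1 = make_cell_phantom(spec)
        v2, c2, n2, g2 = make_cell_phantom(spec)
        np.testing.assert_array_equal(v1.data, v2.data)
        np.testing.assert_array_equal(n1.data, n2.data)
        assert g1.clump_count == g2.clump_count

    def test_nucleus_must_fit_in_cell(self):
        with pytest.raises(NucmorphError):
            CellPhantomSpec(cell_semiaxes_um=(5, 5, 5), nucleus_semiaxes_um=(5, 5, 5),
                            nucleus_offset_um=(1, 0, 0))

    def test_infeasible_clump_packing_raises(self):
        spec = CellPhantomSpec(n_clumps=60, clump_radius_um=1.2, seed=5)
        with pytest.raises(PlacementError):
            make_cell_phantom(spec)


class TestFishPhantom:
    SPEC = CellPhantomSpec(nucleus_semiaxes_um=(4, 4, 4), cell_semiaxes_um=(5.5, 5.5, 5.5))

    def test_center_spot_lands_at_centroid(self):
        channels, nmask, gt = make_fish_phantom(self.SPEC, [1.0], seed=9)
        centroid = mask_centroid_um(nmask)
        assert np.linalg.norm(np.asarray(gt.spot_centroids_um[0]) - centroid) <= 0.35
        assert gt.spot_rrds[0] == 1.0

    def test_boundary_spot_lands_within_one_voxel_of_mask_edge(self):
        _, nmask, gt = make_fish_phantom(self.SPEC, [0.0], seed=9)
        sdf = signed_distance_field(nmask.data, nmask.voxel_size)
        pos_vox = np.asarray(gt.spot_centroids_um[0]) / np.asarray(nmask.voxel_size)
        dist_to_edge = ndimage.map_coordinates(sdf, pos_vox.reshape(3, 1), order=1)[0]
        assert abs(dist_to_edge) <= 0.35

    def test_spot_placement_inverts_rrd_operator(self):
        requested = list(np.round(np.arange(0.1, 1.0, 0.1), 2))
        for seed in (100, 101):
            _, _, gt = make_fish_phantom(self.SPEC, requested, seed=seed,
                                         min_spot_separation_um=1.0)
            for req, got in zip(requested, gt.spot_rrds):
                assert abs(got - req) <= 0.05

    def test_perfect_colocalization_when_no_independent_noise(self):
        channels, nmask, _ = make_fish_phantom(self.SPEC, [0.5], coloc_rho=1.0,
                                               independent_noise_sd=0.0, seed=3)
        r = pearson_colocalization(channels["fish"], channels["h3k9ac"], nmask).pearson_r
        assert r == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("rho", [0.0, 0.3, 0.6, 0.9])
    def test_coloc_rho_targets_hit(self, rho):
        channels, nmask, _ = make_fish_phantom(self.SPEC, [0.4, 0.7], coloc_rho=rho, seed=21)
        r = pearson_colocalization(channels["fish"], channels["h3k9ac"], nmask).pearson_r
        assert r == pytest.approx(rho, abs=0.05)

    def test_empty_spot_list_is_noop(self):
        channels, nmask, gt = make_fish_phantom(self.SPEC, [], seed=5)
        assert gt.spot_rrds == []
        assert channels["fish"].data[nmask.foreground()].max() < 0.5

    def test_anisotropic_z_step(self):
        _, nmask, _ = make_fish_phantom(self.SPEC, [0.5], seed=6, z_step_um=0.25)
        assert nmask.voxel_size[0] == pytest.approx(0.25)
        assert nmask.voxel_size[2] == pytest.approx(0.35)


class TestCohort:
    POP = CohortSpec(nuclear_volume_mean_um3=250.0, nuclear_volume_sd_um3=50.0,
                     voxel_size_um=(0.5, 0.5, 0.5))

    def test_cohort_size_and_determinism(self):
        specs1, gt1 = make_cohort(6, self.POP, seed=42)
        specs2, gt2 = make_cohort(6, self.POP, seed=42)
        assert len(specs1) == 6
        assert gt1.df.equals(gt2.df)

    def test_cohort_writes_manifest_and_truth(self, tmp_path):
        make_cohort(2, self.POP, seed=1, out_dir=tmp_path)
        assert (tmp_path / "manifest.json").exists()
        assert (tmp_path / "ground_truth.csv").exists()
        assert len(list(tmp_path.glob("cell_*.tif"))) == 6  # volume + 2 masks per cell

    def test_planted_population_mean_recovered(self):
        # population at Table-1 scale: mean 672.7, sd tuned for SEM~22.9 at n=200;
        # run n=60 and check the sample mean within 3 SEM of the plant
        pop = CohortSpec()
        n = 60
        _, gt = make_cohort(n, pop, seed=202)
        vols = gt.values("nuclear_volume", "DMSO")
        sem = pop.nuclear_volume_sd_um3 / np.sqrt(n)
        assert abs(vols.mean() - 672.7) <= 3 * sem


class TestViabilityTable:
    def test_midpoint_at_logic50(self):
        t = make_viability_table((80.0, 20.0, 0.0, -1.0), doses_um=[1.0], n_reps=1, noise_sd=0)
        assert t["response"].iloc[0] == pytest.approx(50.0)  # (Top+Bottom)/2

    def test_low_dose_asymptote_is_top_for_negative_hill(self):
        y = four_param_logistic(-12.0, 100.0, 5.0, 0.0, -1.0)
        assert y == pytest.approx(100.0, abs=1e-9)
        y_hi = four_param_logistic(12.0, 100.0, 5.0, 0.0, -1.0)
        assert y_hi == pytest.approx(5.0, abs=1e-9)

    def test_default_series_is_ten_point_threefold_from_100(self):
        d = default_dose_series()
        assert len(d) == 10
        assert d[0] == 100.0
        np.testing.assert_allclose(d[:-1] / d[1:], 3.0)

    def test_six_replicates_over_ten_doses_gives_60_rows(self):
        t = make_viability_table((100, 0, 0, -1), n_reps=6, seed=1)
        assert len(t) == 60

    def test_nonpositive_dose_rejected(self):
        with pytest.raises(NucmorphError):
            make_viability_table((100, 0, 0, -1), doses_um=[1.0, 0.0])


class TestQpcrTable:
    def test_unit_fold_change_gives_equal_delta_cts(self):
        t = make_qpcr_table({"MGMT": 2.0, "ACTB": 2.0}, {"MGMT": 1.0}, noise_sd=0, seed=1)
        for gene in ("MGMT", "ACTB"):
            g = t[t.gene == gene]
            dct = g[g.condition == "control"].ct.mean() - g[g.condition == "treated"].ct.mean()
            assert dct == pytest.approx(0.0, abs=1e-9)

    def test_twelve_fold_gives_log2_12_delta_ct_difference(self):
        t = make_qpcr_table({"MGMT": 2.0, "ACTB": 2.0}, {"MGMT": 12.0}, noise_sd=0, seed=1)
        def dct(gene):
            g = t[t.gene == gene]
            return g[g.condition == "control"].ct.mean() - g[g.condition == "treated"].ct.mean()
        assert dct("MGMT") - dct("ACTB") == pytest.approx(np.log2(12.0), abs=1e-9)

    def test_deterministic_under_seed(self):
        kw = dict(efficiencies={"MGMT": 1.9, "ACTB": 2.0}, fold_changes={"MGMT": 5.0}, seed=8)
        assert make_qpcr_table(**kw).equals(make_qpcr_table(**kw))

    def test_efficiency_outside_range_rejected(self):
        with pytest.raises(NucmorphError):
            make_qpcr_table({"MGMT": 2.5, "ACTB": 2.0}, {"MGMT": 2.0})
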