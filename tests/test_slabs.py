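"""Rotation, slicing, hydration bookkeeping and the slab profile."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rborient.slabs import (
    AdsorptionState,
    Orientation,
    PackingError,
    SliceConfig,
    assemble_profile,
    bulk_sld,
    penetrated_fraction,
    rho_total_from_gamma,
    rotate_model,
    rotation_matrix,
    slice_protein,
)
from rborient.synthetic import default_contrasts

NRW = default_contrasts()[0]


def z_rotation(psi_deg):
    p = np.radians(psi_deg)
    c, s = np.cos(p), np.sin(p)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


class TestRotationMatrix:
    def test_zero_angles_identity(self):
        np.testing.assert_allclose(rotation_matrix(Orientation(0, 0)),
                                   np.eye(3), atol=1e-15)

    def test_full_turn_identity(self):
        np.testing.assert_allclose(rotation_matrix(Orientation(360, 360)),
                                   np.eye(3), atol=1e-12)

    def test_right_handed_active_convention(self):
        # theta = 90 about x maps +z to -y
        out = rotation_matrix(Orientation(90, 0)) @ np.array([0.0, 0.0, 1.0])
        np.testing.assert_allclose(out, [0.0, -1.0, 0.0], atol=1e-12)

    def test_zy_mode_first_rotation_about_z(self):
        out = rotation_matrix(Orientation(90, 0, mode="ZY")) @ np.array(
            [1.0, 0.0, 0.0])
        np.testing.assert_allclose(out, [0.0, 1.0, 0.0], atol=1e-12)

    @given(st.floats(-180, 180), st.floats(-180, 180))
    @settings(deadline=None, max_examples=50)
    def test_orthonormal_with_unit_determinant(self, theta, phi):
        rot = rotation_matrix(Orientation(theta, phi))
        np.testing.assert_allclose(rot @ rot.T, np.eye(3), atol=1e-12)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-12)


class TestSliceProtein:
    def test_single_bead_single_nonzero_slice(self, residue_table):
        gly = residue_table["GLY"]
        _, v, sld = slice_protein(np.array([0.0]), np.array([gly.volume]),
                                  np.array([gly.b_h]), SliceConfig(10))
        assert np.count_nonzero(v) == 1
        assert v.sum() == pytest.approx(gly.volume)
        assert sld.max() == pytest.approx(gly.b_h / gly.volume * 1e6)

    def test_volume_conserved_over_orientations(self, ellipsoid_model):
        total = ellipsoid_model.total_volume()
        rng = np.random.default_rng(0)
        for _ in range(20):
            state = Orientation(rng.uniform(-180, 180), rng.uniform(-180, 180))
            z = rotate_model(ellipsoid_model, state)[:, 2]
            _, v, _ = slice_protein(z, ellipsoid_model.volumes,
                                    ellipsoid_model.b_h, SliceConfig(50))
            assert v.sum() == pytest.approx(total, rel=1e-12)

    def test_fine_slicing_aggregates_to_coarse(self, ellipsoid_model):
        z = rotate_model(ellipsoid_model, Orientation(33, -71))[:, 2]
        vols = ellipsoid_model.volumes
        b = ellipsoid_model.b_h
        _, coarse, _ = slice_protein(z, vols, b, SliceConfig(50))
        _, fine, _ = slice_protein(z, vols, b, SliceConfig(5000))
        aggregated = fine.reshape(50, 100).sum(axis=1)
        assert np.abs(aggregated - coarse).max() <= vols.max() + 1e-9

    def test_empty_slices_have_zero_sld(self, residue_table):
        gly = residue_table["GLY"]
        z = np.array([0.0, 100.0])
        _, v, sld = slice_protein(z, np.full(2, gly.volume),
                                  np.full(2, gly.b_h), SliceConfig(20))
        assert np.all(sld[v == 0] == 0.0)


class TestBulkSLD:
    def test_zero_penetration_all_solvent(self):
        edges = np.linspace(0.0, 50.0, 11)
        bulk = bulk_sld(edges, edges[0], sld_solvent=6.35, sld_substrate=0.0)
        np.testing.assert_allclose(bulk, 6.35)

    def test_interface_at_slice_midpoint_mixes_half(self):
        edges = np.array([0.0, 10.0])
        bulk = bulk_sld(edges, 5.0, sld_solvent=6.0, sld_substrate=2.0)
        assert bulk[0] == pytest.approx(4.0)

    def test_matches_fine_subslicing_oracle(self):
        edges = np.linspace(-20.0, 30.0, 51)
        z_int = 3.3
        coarse = bulk_sld(edges, z_int, 6.35, -0.56)
        fine_edges = np.linspace(-20.0, 30.0, 5001)
        fine = bulk_sld(fine_edges, z_int, 6.35, -0.56)
        aggregated = fine.reshape(50, 100).mean(axis=1)
        np.testing.assert_allclose(coarse, aggregated, atol=0.005 * 6.91)

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError):
            bulk_sld(np.array([1.0, 0.0]), 0.5, 6.35, 0.0)


class TestRhoTotal:
    def test_dimensional_oracle(self):
        # 2 mg/m^2 = 2e-7 g/cm^2; 50 A = 5e-7 cm; / 1.38 g/cm^3
        expected = 2e-7 / (1.38 * 5e-7)
        assert rho_total_from_gamma(2.0, 1.38, 50.0) == pytest.approx(expected)
        assert expected == pytest.approx(0.29, abs=0.005)

    def test_linear_in_gamma(self):
        assert rho_total_from_gamma(0.0, 1.4, 50.0) == 0.0
        assert rho_total_from_gamma(2.0, 1.4, 50.0) == pytest.approx(
            2 * rho_total_from_gamma(1.0, 1.4, 50.0))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            rho_total_from_gamma(1.0, 0.0, 50.0)
        with pytest.raises(ValueError):
            rho_total_from_gamma(1.0, 1.4, -1.0)


class TestAssembleProfile:
    def test_volume_conservation_and_occupancy_bounds(self, ellipsoid_model):
        state = AdsorptionState(orientation=Orientation(25, 140), z_pen=5,
                                gamma=1.5)
        prof = assemble_profile(ellipsoid_model, state, SliceConfig(),
                                NRW.solvent, NRW.substrate_sld)
        assert prof.v_slice_prot.sum() == pytest.approx(
            ellipsoid_model.total_volume(), rel=1e-12)
        occ = prof.rho_norm * prof.rho_slice
        assert np.all(occ >= 0) and np.all(occ <= 1 + 1e-9)

    def test_empty_slice_equals_bulk(self, residue_table):
        from conftest import model_from_positions
        # two clusters far apart leave empty slices between them
        pos = np.vstack([np.random.default_rng(1).normal(0, 2, (20, 3)),
                         np.random.default_rng(2).normal(0, 2, (20, 3)) +
                         np.array([0, 0, 60.0])])
        model = model_from_positions(pos, residue_table)
        state = AdsorptionState(gamma=0.5)
        prof = assemble_profile(model, state, SliceConfig(), NRW.solvent,
                                NRW.substrate_sld)
        empty = prof.v_slice_prot == 0
        assert empty.any()
        np.testing.assert_allclose(prof.sld_slice[empty], prof.sld_bulk[empty])

    def test_unphysical_gamma_raises_packing_error(self, ellipsoid_model):
        state = AdsorptionState(orientation=Orientation(0, 0), gamma=30.0)
        with pytest.raises(PackingError, match="slice"):
            assemble_profile(ellipsoid_model, state, SliceConfig(),
                             NRW.solvent, NRW.substrate_sld)

    def test_z_rotation_leaves_profile_unchanged(self, ellipsoid_model):
        state = AdsorptionState(orientation=Orientation(47, -12), z_pen=8,
                                gamma=2.0)
        ref = assemble_profile(ellipsoid_model, state, SliceConfig(),
                               NRW.solvent, NRW.substrate_sld)
        rot = assemble_profile(ellipsoid_model, state, SliceConfig(),
                               NRW.solvent, NRW.substrate_sld,
                               extra_rotation=z_rotation(73.0))
        np.testing.assert_allclose(rot.sld_slice, ref.sld_slice, atol=1e-10)

    def test_gauge_image_gives_identical_profile(self, y_model):
        state = AdsorptionState(orientation=Orientation(30, 45), z_pen=10,
                                gamma=2.0)
        a = assemble_profile(y_model, state, SliceConfig(), NRW.solvent,
                             NRW.substrate_sld)
        b = assemble_profile(y_model, state.gauge_image(), SliceConfig(),
                             NRW.solvent, NRW.substrate_sld)
        np.testing.assert_allclose(b.sld_slice, a.sld_slice, atol=1e-9)

    def test_pair_map_reverses_profile_for_mirror_model(self, mirror_model):
        state = AdsorptionState(orientation=Orientation(28, 61), gamma=1.0)
        a = assemble_profile(mirror_model, state, SliceConfig(), NRW.solvent,
                             NRW.substrate_sld)
        b = assemble_profile(mirror_model, state.symmetric_image(),
                             SliceConfig(), NRW.solvent, NRW.substrate_sld)
        np.testing.assert_allclose(b.sld_slice, a.sld_slice[::-1], atol=1e-9)

    def test_spherical_model_rotation_invariant(self):
        # a finite bead sample only approximates a sphere, so compare
        # smoothed profiles of a dense sample at the sampling-noise scale
        from scipy.ndimage import gaussian_filter1d

        from rborient.synthetic import SyntheticSpec, make_bead_protein
        model = make_bead_protein(SyntheticSpec(
            shape="sphere", n_beads=1200, extents=(80.0, 80.0, 80.0), seed=6))
        ref = None
        rng = np.random.default_rng(8)
        for _ in range(4):
            state = AdsorptionState(
                orientation=Orientation(rng.uniform(-180, 180),
                                        rng.uniform(-180, 180)), gamma=1.5)
            prof = assemble_profile(model, state, SliceConfig(),
                                    NRW.solvent, NRW.substrate_sld)
            smooth = gaussian_filter1d(prof.sld_slice, 2.0)
            if ref is None:
                ref = smooth
            else:
                # tolerance set by bead-sampling noise (~1/sqrt(beads/window))
                assert np.abs(smooth - ref).max() < 0.2 * np.abs(ref).max()

    def test_cumulative_volume_converges_with_slice_count(self, ellipsoid_model):
        # whole-residue binning concentrates each residue into one slice,
        # so the pointwise occupancy profile cannot converge as slices
        # shrink; the cumulative volume distribution along z does
        z_res = rotate_model(ellipsoid_model, Orientation(30, 45))[:, 2]
        vols = ellipsoid_model.volumes
        b = ellipsoid_model.b_h
        z_grid = np.linspace(z_res.min(), z_res.max(), 500)
        dists = []
        edges_ref, v_ref, _ = slice_protein(z_res, vols, b, SliceConfig(4000))
        ref = np.interp(z_grid, edges_ref[1:], np.cumsum(v_ref))
        for n in (10, 50, 400):
            edges, v, _ = slice_protein(z_res, vols, b, SliceConfig(n))
            cur = np.interp(z_grid, edges[1:], np.cumsum(v))
            dists.append(np.sqrt(np.mean((cur - ref) ** 2)))
        assert dists[0] > dists[1] > dists[2]


class TestPenetratedFraction:
    def test_no_penetration_zero_fraction(self, ellipsoid_model):
        state = AdsorptionState(orientation=Orientation(10, 20), z_pen=0.0,
                                gamma=1.0)
        assert penetrated_fraction(ellipsoid_model, state) == 0.0

    def test_full_penetration_unity(self, ellipsoid_model):
        state = AdsorptionState(orientation=Orientation(10, 20), z_pen=500.0,
                                gamma=1.0)
        assert penetrated_fraction(ellipsoid_model, state) == 1.0

    def test_median_plane_counting_oracle(self, residue_table):
        from conftest import model_from_positions
        z = np.concatenate([np.linspace(-10, -1, 50), np.linspace(1, 10, 50)])
        pos = np.column_stack([np.random.default_rng(0).normal(size=100),
                               np.random.default_rng(1).normal(size=100), z])
        model = model_from_positions(pos, residue_table)
        state = AdsorptionState(z_pen=10.001, gamma=1.0)  # interface ~ z=0
        assert penetrated_fraction(model, state) == pytest.approx(0.5)
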