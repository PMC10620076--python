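"""Phantom geometry: shells, electrodes, ROIs, electrode-sphere placement."""

import numpy as np
import pytest

import tidose
from tidose.errors import (ConfigurationError, InfeasibleROIError,
                           UnknownElectrodeError)
from tidose.phantom import (AIR, GRAY, PhantomConfig, TARGET, WHITE,
                            build_phantom, electrode_patch,
                            electrode_positions, make_roi_set,
                            sphere_under_electrode)


class TestBuildPhantom:
    def test_brain_volume_matches_analytic_sphere(self, default_phantom):
        ph = default_phantom
        vox = ph.brain_mask.sum() * ph.voxel_volume_mm3
        r = ph.layer_radii_mm["brain"]
        analytic = 4.0 / 3.0 * np.pi * r ** 3
        # voxelization error bounded by two surface shells of voxels
        bound = 2 * 4.0 * np.pi * r ** 2 * ph.spacing_mm
        assert abs(vox - analytic) < bound
        # the actual error is far smaller than the bound
        assert abs(vox - analytic) / analytic < 0.01

    def test_non_nested_radii_rejected(self):
        with pytest.raises(ConfigurationError):
            build_phantom(PhantomConfig(skull_radius_mm=95.0))  # > scalp 92

    def test_spacing_out_of_range_rejected(self):
        with pytest.raises(ConfigurationError):
            build_phantom(PhantomConfig(spacing_mm=0.5))

    def test_labels_agree_across_resolutions_on_shared_centers(self):
        """Geometry is analytic, so common voxel centers get equal labels."""
        fine = build_phantom(PhantomConfig(spacing_mm=2.0))
        coarse = build_phantom(PhantomConfig(spacing_mm=4.0))
        xs_f = fine.origin_mm[0] + fine.spacing_mm * np.arange(fine.shape[0])
        xs_c = coarse.origin_mm[0] + coarse.spacing_mm * np.arange(coarse.shape[0])
        in_f = np.isin(xs_f, xs_c)
        in_c = np.isin(xs_c, xs_f)
        sub_f = fine.labels[np.ix_(in_f, in_f, in_f)]
        sub_c = coarse.labels[np.ix_(in_c, in_c, in_c)]
        assert sub_f.shape == sub_c.shape and sub_f.size > 0
        assert np.array_equal(sub_f, sub_c)

    def test_mirror_symmetry_is_voxel_exact(self, default_phantom):
        lab = default_phantom.labels
        assert np.array_equal(lab, lab[::-1, :, :])

    def test_determinism(self):
        a = build_phantom(PhantomConfig(spacing_mm=4.0))
        b = build_phantom(PhantomConfig(spacing_mm=4.0))
        assert np.array_equal(a.labels, b.labels)

    def test_air_outside_scalp_and_tissue_inside(self, coarse_phantom):
        r = coarse_phantom.radius_volume_mm()
        scalp = coarse_phantom.layer_radii_mm["scalp"]
        tissue = coarse_phantom.labels != AIR
        assert np.all(r[tissue] < scalp)
        assert np.all(r[~tissue] >= scalp)

    def test_conductivities(self, coarse_phantom):
        table = coarse_phantom.conductivity_table
        assert table[AIR] == 0.0
        assert all(s > 0 for code, s in table.items() if code != AIR)

    def test_brain_mask_inside_csf_shell(self, coarse_phantom):
        r = coarse_phantom.radius_volume_mm()
        brain = coarse_phantom.brain_mask.astype(bool)
        assert brain.any()
        assert np.all(r[brain] < coarse_phantom.layer_radii_mm["csf"])

    def test_volume_convergence_under_refinement(self):
        """Halving the spacing shrinks the volume error within the
        single-shell surface-voxel bound."""
        for label, attr in [(GRAY, "brain")]:
            fine = build_phantom(PhantomConfig(spacing_mm=2.0))
            coarse = build_phantom(PhantomConfig(spacing_mm=4.0))
            r = fine.layer_radii_mm["brain"]
            analytic = 4 / 3 * np.pi * r ** 3
            for ph in (fine, coarse):
                vox = ph.brain_mask.sum() * ph.voxel_volume_mm3
                bound = 4 * np.pi * r ** 2 * ph.spacing_mm
                assert abs(vox - analytic) < bound


class TestElectrodes:
    def test_cz_is_vertex(self, coarse_phantom):
        (cz,) = electrode_positions(["Cz"], coarse_phantom)
        assert np.allclose(cz.direction, (0.0, 0.0, 1.0), atol=1e-12)

    @pytest.mark.parametrize("left,right", [("F3", "F4"), ("TP7", "TP8"),
                                            ("AF3", "AF4"), ("C3", "C4")])
    def test_homologs_mirror_about_midsagittal(self, coarse_phantom, left, right):
        l, r = electrode_positions([left, right], coarse_phantom)
        dl, dr = l.direction_arr, r.direction_arr
        assert abs(dl[2] - dr[2]) < 1e-9           # equal polar angle
        assert abs(dl[0] + dr[0]) < 1e-9           # mirrored laterally
        assert abs(dl[1] - dr[1]) < 1e-9

    def test_unknown_label_raises_listing_known(self, coarse_phantom):
        with pytest.raises(UnknownElectrodeError, match="Cz"):
            electrode_positions(["XX9"], coarse_phantom)

    def test_patches_nonempty(self, coarse_phantom):
        for e in electrode_positions(["F3", "F4", "TP7", "TP8", "Cz"],
                                     coarse_phantom):
            assert electrode_patch(coarse_phantom, e).sum() > 0


class TestROISet:
    def test_bilateral_targets_equal_counts(self, coarse_phantom):
        rois = make_roi_set(coarse_phantom)
        assert rois["target_left"].sum() == rois["target_right"].sum() > 0

    def test_target_masks_inside_brain(self, coarse_phantom):
        rois = make_roi_set(coarse_phantom)
        brain = rois["brain"].astype(bool)
        for name in ("target_left", "target_right", "target",
                     "cortical_control"):
            assert not (rois[name].astype(bool) & ~brain).any()

    def test_tiny_target_is_single_voxel(self, coarse_phantom):
        h = coarse_phantom.spacing_mm
        rois = make_roi_set(coarse_phantom, target_radius_mm=0.5 * h,
                            target_centers_mm=[np.zeros(3)])
        assert rois["target_left"].sum() == 1

    def test_roi_at_scalp_is_clipped_with_reported_fraction(self, coarse_phantom):
        center = np.array([0.0, 0.0, coarse_phantom.layer_radii_mm["brain"]])
        rois = make_roi_set(coarse_phantom, target_radius_mm=10.0,
                            target_centers_mm=[center])
        assert rois.clipped_fraction["target_left"] > 0


class TestSphereUnderElectrode:
    def test_cz_sphere_depth_matches_bruteforce(self, default_phantom):
        """Shallowest containing depth equals an independent 0.1-mm scan."""
        ph = default_phantom
        (cz,) = electrode_positions(["Cz"], ph)
        mask = sphere_under_electrode(ph, cz, radius_mm=10.0)
        # center of mass of the returned sphere -> depth along +z
        idx = np.argwhere(mask.astype(bool))
        center_mm = ph.origin_mm + ph.spacing_mm * idx.mean(axis=0)
        depth_found = ph.layer_radii_mm["scalp"] - center_mm[2]

        # independent brute force: scan center positions, voxelize, check
        brain = ph.brain_mask.astype(bool)
        x = ph.origin_mm[0] + ph.spacing_mm * np.arange(ph.shape[0])
        scalp_r = ph.layer_radii_mm["scalp"]
        expected_depth = None
        for depth in np.arange(10.0, scalp_r, 0.1):
            c = np.array([0.0, 0.0, scalp_r - depth])
            d2 = ((x - c[0])[:, None, None] ** 2
                  + (x - c[1])[None, :, None] ** 2
                  + (x - c[2])[None, None, :] ** 2)
            m = d2 <= 100.0
            if m.any() and not (m & ~brain).any():
                expected_depth = depth
                break
        assert expected_depth is not None
        # analytic: center radius = brain radius - sphere radius
        analytic_depth = scalp_r - (ph.layer_radii_mm["brain"] - 10.0)
        assert abs(expected_depth - analytic_depth) <= ph.spacing_mm
        assert abs(depth_found - expected_depth) <= ph.spacing_mm

    def test_sphere_volume_near_analytic(self, default_phantom):
        ph = default_phantom
        (cz,) = electrode_positions(["Cz"], ph)
        mask = sphere_under_electrode(ph, cz, radius_mm=10.0)
        vox = mask.sum() * ph.voxel_volume_mm3
        analytic = 4 / 3 * np.pi * 10.0 ** 3
        bound = 2 * 4 * np.pi * 10.0 ** 2 * ph.spacing_mm
        assert abs(vox - analytic) < bound

    def test_oversized_sphere_infeasible(self, coarse_phantom):
        (cz,) = electrode_positions(["Cz"], coarse_phantom)
        with pytest.raises(InfeasibleROIError):
            sphere_under_electrode(coarse_phantom, cz,
                                   radius_mm=coarse_phantom.layer_radii_mm["brain"])
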