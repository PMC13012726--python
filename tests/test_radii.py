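"""Deconvolution, orthogonal planes, boundary detection, vertex radii."""

import numpy as np
import pytest
from scipy import ndimage
from scipy.signal import fftconvolve

from mvgraph import (BinaryMask, ImageVolume, PhantomSpec, PSFModel,
                     SphereSpec, TubeSpec, VascularGraph, deconvolve,
                     detect_boundary_profiles, estimate_vertex_radii,
                     extract_orthogonal_plane, generate_phantom,
                     neuron_distance, prior_radius_dt, smooth_and_tangents)
from mvgraph.radii import PlaneImage, RadiusEstimationError, spoke_length_um

VS = (0.99, 0.99, 0.99)


def _blurred_disk_plane(radius_um=5.0, size=41, spacing=0.99, center=None,
                        fg=600.0, bg=150.0, blur_px=0.6):
    if center is None:
        center = ((size - 1) / 2.0, (size - 1) / 2.0)
    rr, cc = np.mgrid[:size, :size].astype(float)
    dist = np.hypot(rr - center[0], cc - center[1]) * spacing
    img = np.where(dist < radius_um, fg, bg)
    return PlaneImage(ndimage.gaussian_filter(img, blur_px), spacing)


class TestDeconvolve:
    def test_delta_psf_is_identity(self, straight_tube):
        vol = straight_tube.volumes[0]["vascular"]
        out = deconvolve(vol, PSFModel.delta(), iterations=5)
        assert np.allclose(out.voxels, vol.voxels, rtol=1e-6)

    def test_zero_iterations_is_identity(self, straight_tube, psf):
        vol = straight_tube.volumes[0]["vascular"]
        out = deconvolve(vol, psf, iterations=0)
        assert np.array_equal(out.voxels, vol.voxels)

    def test_sharpens_blurred_bead_edge(self, psf):
        spec = PhantomSpec((31, 31, 31),
                           beads=[SphereSpec([15 * 0.99] * 3, 4.0, 600.0)])
        data = generate_phantom(spec)
        vol = data.volumes[0]["vascular"]
        blurred = vol.copy_with(fftconvolve(vol.voxels, psf.kernel, mode="same"))
        decon = deconvolve(blurred, psf, iterations=10)
        # gradient magnitude at the true boundary strictly increases
        grad_b = np.linalg.norm(np.gradient(blurred.voxels), axis=0)
        grad_d = np.linalg.norm(np.gradient(decon.voxels), axis=0)
        shell = ndimage.binary_dilation(data.masks[0]["vascular"].voxels) \
            ^ ndimage.binary_erosion(data.masks[0]["vascular"].voxels)
        assert grad_d[shell].mean() > grad_b[shell].mean()

    def test_total_intensity_approximately_conserved(self, straight_tube, psf):
        vol = straight_tube.volumes[0]["vascular"]
        blurred = vol.copy_with(fftconvolve(vol.voxels, psf.kernel, mode="same"))
        out = deconvolve(blurred, psf, iterations=10)
        assert out.voxels.sum() == pytest.approx(blurred.voxels.sum(), rel=0.01)

    def test_negative_image_rejected(self, psf):
        vol = ImageVolume(np.full((8, 8, 8), -1.0), VS)
        with pytest.raises(ValueError):
            deconvolve(vol, psf)


class TestExtractOrthogonalPlane:
    def test_axis_aligned_tangent_equals_xy_slice(self, straight_tube):
        vol = straight_tube.volumes[0]["vascular"]
        pos = np.array([30 * 0.99, 20 * 0.99, 20 * 0.99])
        plane = extract_orthogonal_plane(vol, pos, np.array([1.0, 0, 0]),
                                         half_width_um=10.0)
        n = plane.image.shape[0] // 2
        sub = vol.voxels[30, 20 - n:20 + n + 1, 20 - n:20 + n + 1]
        assert np.allclose(plane.image, sub, atol=1e-9)

    def test_tilted_tube_cross_section_is_circular(self):
        # a tube tilted 30° from z still yields a disk of the true radius
        ext = np.array([59, 59, 43]) * 0.99
        direction = np.array([np.cos(np.deg2rad(30)), np.sin(np.deg2rad(30)), 0.0])
        c = ext / 2
        spec = PhantomSpec((60, 60, 44),
                           tubes=[TubeSpec([c - 26 * direction, c + 26 * direction],
                                           4.0)])
        data = generate_phantom(spec)
        plane = extract_orthogonal_plane(data.volumes[0]["vascular"], c,
                                         direction, half_width_um=12.0)
        prof = detect_boundary_profiles(
            PlaneImage(ndimage.gaussian_filter(plane.image, 0.7), 0.99), 1.8)
        assert prof.radius == pytest.approx(4.0, rel=0.05)

    def test_degenerate_tangent_rejected(self, straight_tube):
        vol = straight_tube.volumes[0]["vascular"]
        with pytest.raises(ValueError):
            extract_orthogonal_plane(vol, np.zeros(3), np.zeros(3), 5.0)

    def test_out_of_volume_samples_counted(self, straight_tube):
        vol = straight_tube.volumes[0]["vascular"]
        plane = extract_orthogonal_plane(vol, np.array([1.0, 1.0, 1.0]),
                                         np.array([1.0, 0, 0]), 15.0)
        assert plane.filled_fraction > 0.25


class TestDetectBoundaryProfiles:
    def test_noiseless_disk_recovered(self):
        prof = detect_boundary_profiles(_blurred_disk_plane(5.0), 2.0)
        assert prof.radius == pytest.approx(5.0, abs=0.5)
        assert prof.outlier_flags.sum() == 0

    def test_corrupted_spoke_flagged_and_excluded(self):
        plane = _blurred_disk_plane(5.0, size=41)
        # a thin bright streak pushes the 90° (column) spoke's boundary far
        # outward; the outlier gate must reject it and leave the radius alone
        img = plane.image.copy()
        img[20, 24:41] = 600.0
        prof = detect_boundary_profiles(PlaneImage(img, 0.99), 2.0)
        assert prof.outlier_flags[9]  # the 90° spoke
        clean = detect_boundary_profiles(plane, 2.0)
        assert prof.radius == pytest.approx(clean.radius, abs=0.15)

    def test_offset_disk_recentered(self):
        off = _blurred_disk_plane(5.0, center=(17.0, 23.0))
        prof = detect_boundary_profiles(off, 2.0)
        assert np.hypot(prof.center_px[0] - 17, prof.center_px[1] - 23) <= 1.0
        centered = detect_boundary_profiles(_blurred_disk_plane(5.0), 2.0)
        assert prof.radius == pytest.approx(centered.radius, abs=0.3)

    def test_scale_equivariance_noiseless(self):
        base = _blurred_disk_plane(4.0, size=61)
        r0 = detect_boundary_profiles(base, 1.8).radius
        for s in (0.6, 1.5, 2.0):
            img = ndimage.zoom(base.image, s, order=3)
            r = detect_boundary_profiles(PlaneImage(img, 0.99), 1.8 * s).radius
            assert r == pytest.approx(s * r0, rel=0.02)

    def test_too_many_outliers_rejected(self):
        rng = np.random.default_rng(0)
        noise = PlaneImage(rng.random((41, 41)), 0.99)
        # pure noise planes either fail or return *something*; force failure
        # through the half-spokes gate by requiring 36 retained of 36
        with pytest.raises((RadiusEstimationError, ValueError)):
            detect_boundary_profiles(noise, -1.0)

    def test_spoke_count_and_geometry(self):
        prof = detect_boundary_profiles(_blurred_disk_plane(5.0), 2.0)
        assert prof.angles_deg.shape == (36,)
        assert np.all(np.diff(prof.angles_deg) == 10.0)
        assert prof.boundary_distances.shape == (36,)


class TestPriorRadius:
    def _tube_graph(self, data):
        return smooth_and_tangents(VascularGraph(data.graph, VS))

    def test_cylinder_prior_near_third_of_radius(self):
        radius = 6.0
        ext = 40 * 0.99
        spec = PhantomSpec((41, 31, 31),
                           tubes=[TubeSpec([[2, 15 * 0.99, 15 * 0.99],
                                            [ext - 2, 15 * 0.99, 15 * 0.99]],
                                           radius)])
        data = generate_phantom(spec)
        vg = self._tube_graph(data)
        priors = prior_radius_dt(data.masks[0]["vascular"], vg)
        # analytic mean of (R - r) over the disk is R/3; discretization adds
        # about half a voxel because distances run to background voxel centers
        assert radius / 3 < priors[0] < radius / 3 + 0.8

    def test_centerline_prior_near_full_radius(self):
        radius = 4.0
        ext = 40 * 0.99
        spec = PhantomSpec((41, 31, 31),
                           tubes=[TubeSpec([[2, 15 * 0.99, 15 * 0.99],
                                            [ext - 2, 15 * 0.99, 15 * 0.99]],
                                           radius)])
        data = generate_phantom(spec)
        vg = self._tube_graph(data)
        priors = prior_radius_dt(data.masks[0]["vascular"], vg,
                                 over="centerline")
        assert priors[0] == pytest.approx(radius, abs=0.8)

    def test_parallel_identical_tubes_get_equal_priors(self):
        ext = 40 * 0.99
        spec = PhantomSpec((41, 41, 41),
                           tubes=[TubeSpec([[2, 10 * 0.99, 12 * 0.99],
                                            [ext - 2, 10 * 0.99, 12 * 0.99]], 3.0),
                                  TubeSpec([[2, 30 * 0.99, 28 * 0.99],
                                            [ext - 2, 30 * 0.99, 28 * 0.99]], 3.0)])
        data = generate_phantom(spec)
        vg = self._tube_graph(data)
        priors = prior_radius_dt(data.masks[0]["vascular"], vg)
        assert priors[0] == pytest.approx(priors[1], rel=0.02)


class TestEstimateVertexRadii:
    def test_tube_radius_recovered_and_modulation_tracked(self, straight_tube,
                                                          psf):
        from mvgraph import apply_psf_and_noise
        vols = []
        for t in range(2):
            noisy = apply_psf_and_noise(
                straight_tube.volumes[t]["vascular"], psf, target_snr=6.9,
                seed=11 + t, foreground_mask=straight_tube.masks[t]["vascular"])
            vols.append(deconvolve(noisy, psf, 10))
        vg = smooth_and_tangents(VascularGraph(straight_tube.graph, VS))
        priors = prior_radius_dt(straight_tube.masks[0]["vascular"], vg)
        table = estimate_vertex_radii(vols, vg, priors)
        interior = table[(table.vertex > 5) & (table.vertex < table.vertex.max() - 5)]
        mean0 = interior["radius_t0"].mean()
        mean1 = interior["radius_t1"].mean()
        assert mean0 == pytest.approx(3.0, abs=0.3)
        # prescribed ×1.10 dilation recovered as +10 ± 3 %
        assert 100 * (mean1 - mean0) / mean0 == pytest.approx(10.0, abs=3.0)
        # homogeneous tube: intra-edge spread well below the radius
        assert interior["radius_t0"].std() < 0.1 * mean0


class TestNeuronDistance:
    def test_radius_subtracted_distance(self):
        import pandas as pd
        vox = np.zeros((40, 40, 40), bool)
        zz, yy, xx = np.mgrid[:40, :40, :40].astype(float) * 0.99
        soma_center = np.array([20, 20, 30]) * 0.99
        soma_r = 5.0
        vox[(zz - soma_center[0])**2 + (yy - soma_center[1])**2
            + (xx - soma_center[2])**2 < soma_r**2] = True
        mask = BinaryMask(vox, VS, label="neuron")
        # vessel axis 20 μm from the soma surface, radius 2 μm
        axis_pos = soma_center - np.array([0.0, 0.0, soma_r + 20.0])
        records = pd.DataFrame([{"edge": 0, "vertex": 0,
                                 "z": axis_pos[0], "y": axis_pos[1],
                                 "x": axis_pos[2], "radius_t0": 2.0}])
        out = neuron_distance(mask, records)
        assert out["neuron_distance"].iloc[0] == pytest.approx(18.0, abs=0.8)

    def test_touching_wall_clips_to_zero(self):
        import pandas as pd
        vox = np.zeros((20, 20, 20), bool)
        vox[8:12, 8:12, 8:12] = True
        mask = BinaryMask(vox, VS, label="neuron")
        records = pd.DataFrame([{"edge": 0, "vertex": 0, "z": 9.9, "y": 9.9,
                                 "x": 5.0, "radius_t0": 10.0}])
        out = neuron_distance(mask, records)
        assert out["neuron_distance"].iloc[0] == 0.0

    def test_empty_mask_gives_infinity(self):
        import pandas as pd
        mask = BinaryMask(np.zeros((5, 5, 5), bool), VS, label="neuron")
        records = pd.DataFrame([{"edge": 0, "vertex": 0, "z": 1.0, "y": 1.0,
                                 "x": 1.0, "radius_t0": 1.0}])
        out = neuron_distance(mask, records)
        assert np.isinf(out["neuron_distance"].iloc[0])


class TestRotationInvariance:
    def test_bead_estimate_independent_of_plane_normal(self, psf):
        spec = PhantomSpec((35, 35, 35),
                           beads=[SphereSpec([17 * 0.99] * 3, 7.32 / 2, 600.0)])
        data = generate_phantom(spec)
        vol = data.volumes[0]["vascular"]
        blurred = vol.copy_with(fftconvolve(vol.voxels, psf.kernel, mode="same"))
        decon = deconvolve(blurred, psf, 10)
        center = np.array([17 * 0.99] * 3)
        prior = 1.4
        hw = spoke_length_um(prior) + 2
        rng = np.random.default_rng(5)
        radii = []
        for _ in range(8):
            v = rng.standard_normal(3)
            v /= np.linalg.norm(v)
            plane = extract_orthogonal_plane(decon, center, v, hw)
            radii.append(detect_boundary_profiles(plane, prior).radius)
        radii = np.array(radii)
        assert np.ptp(radii) / radii.mean() < 0.05
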