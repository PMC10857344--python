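"""Centerline smoothing, rotation-minimizing frames, volume resampling."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from lumenfit.sections import (
    Centerline,
    Volume3D,
    extract_cross_section,
    extract_sections,
    frenet_frames,
    load_centerline_csv,
    normalize_ct,
    rotation_minimizing_frames,
    save_centerline_csv,
    smooth_centerline,
)


def helix(n=200, r=5.0, pitch=2.0, turns=2.0):
    th = np.linspace(0, 2 * np.pi * turns, n)
    return np.stack([r * np.cos(th), r * np.sin(th), pitch * th], axis=1)


def tube_volume(radius=3.0, spacing=0.5, nx=41, nz=30, a=0.1, b=0.25, blur_mm=0.65):
    """Straight z-aligned tube with anti-aliased cross-section and Gaussian blur."""
    ss = 4
    xf = (np.arange(nx * ss) + 0.5) / ss * spacing - nx * spacing / 2
    Xf, Yf = np.meshgrid(xf, xf, indexing="xy")
    disk = (np.hypot(Xf, Yf) <= radius).astype(float)
    disk = disk.reshape(nx, ss, nx, ss).mean(axis=(1, 3))
    section = a + b * disk
    data = np.broadcast_to(section, (nz, nx, nx)).copy()
    data = gaussian_filter(data, [0.0, blur_mm / spacing, blur_mm / spacing])
    origin = [-nx * spacing / 2 + spacing / 2] * 2 + [0.0]
    return Volume3D(data, [spacing] * 3, origin)


class TestSmoothCenterline:
    def test_collinear_input_stays_collinear(self):
        t = np.linspace(0, 9, 25)
        pts = np.stack([t, 2 * t, -t], axis=1)
        cl = smooth_centerline(pts, 0.0, spacing=0.5)
        direction = np.array([1.0, 2.0, -1.0]) / np.sqrt(6)
        assert np.allclose(cl.tangents, direction, atol=1e-9)
        offsets = cl.points - cl.points[0]
        cross = np.linalg.norm(np.cross(offsets[1:], direction), axis=1)
        assert cross.max() < 1e-9

    def test_zero_smoothing_interpolates(self):
        pts = helix(60)
        cl = smooth_centerline(pts, 0.0, spacing=0.1)
        # every original point must lie on the resampled curve (nearest
        # sample within half a resampling step plus curvature sag)
        from scipy.spatial import cKDTree

        d, _ = cKDTree(cl.points).query(pts)
        assert d.max() < 0.06

    def test_smoothing_denoises_helix(self, rng):
        pts = helix(150)
        noisy = pts + rng.normal(0.0, 0.15, pts.shape)
        cl = smooth_centerline(noisy, smoothing=150 * 3 * 0.15**2, spacing=0.5)
        from scipy.spatial import cKDTree

        dense = helix(3000)
        d, _ = cKDTree(dense).query(cl.points)
        rms = np.sqrt(np.mean(d**2))
        noise_rms = np.sqrt(np.mean(rng.normal(0.0, 0.15, 10000) ** 2))
        assert rms < noise_rms

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            smooth_centerline(np.zeros((3, 3)) + np.arange(3)[:, None])

    def test_arc_length_spacing(self):
        cl = smooth_centerline(helix(200), 0.0, spacing=0.5)
        steps = np.linalg.norm(np.diff(cl.points, axis=0), axis=1)
        assert np.abs(steps - 0.5).max() < 0.02


class TestFrames:
    def test_straight_line_frames_constant(self):
        t = np.linspace(0, 10, 30)
        cl = smooth_centerline(np.stack([t, 0 * t, 0 * t], 1), 0.0)
        fr = rotation_minimizing_frames(cl)
        assert np.abs(fr.normals - fr.normals[0]).max() < 1e-12
        assert np.abs(fr.binormals - fr.binormals[0]).max() < 1e-12

    def test_planar_arc_normals_stay_in_plane(self):
        th = np.linspace(0, np.pi / 2, 60)
        arc = np.stack([20 * np.cos(th), 20 * np.sin(th), 0 * th], 1)
        cl = smooth_centerline(arc, 0.0, spacing=0.5)
        fr = rotation_minimizing_frames(cl, initial_normal=[0, 0, 1])
        assert np.abs(np.abs(fr.normals[:, 2]) - 1.0).max() < 1e-6

    def test_orthonormal_right_handed(self):
        cl = smooth_centerline(helix(), 0.0, spacing=0.5)
        fr = rotation_minimizing_frames(cl)
        assert np.abs(np.einsum("ij,ij->i", fr.normals, fr.tangents)).max() < 1e-9
        assert np.abs(np.linalg.norm(fr.normals, axis=1) - 1.0).max() < 1e-9
        handed = np.einsum("ij,ij->i", np.cross(fr.tangents, fr.normals), fr.binormals)
        assert handed.min() > 1.0 - 1e-9

    def test_less_twist_than_frenet_on_helix(self):
        cl = smooth_centerline(helix(), 0.0, spacing=0.5)
        rmf = rotation_minimizing_frames(cl)
        fre = frenet_frames(cl)
        assert rmf.twist().sum() < fre.twist().sum()

    def test_parallel_initial_normal_rejected(self):
        t = np.linspace(0, 10, 30)
        cl = smooth_centerline(np.stack([t, 0 * t, 0 * t], 1), 0.0)
        with pytest.raises(ValueError):
            rotation_minimizing_frames(cl, initial_normal=[1, 0, 0])


class TestExtract:
    def test_constant_volume_gives_constant_image(self):
        vol = Volume3D(np.full((20, 20, 20), 0.37), [1, 1, 1], [0, 0, 0])
        img = extract_cross_section(vol, [10, 10, 10], [1, 0, 0], [0, 1, 0], N=4)
        assert np.allclose(img.intensities, 0.37)

    def test_frame_rotation_rotates_image(self):
        rng = np.random.default_rng(0)
        vol = Volume3D(rng.random((30, 30, 30)), [1, 1, 1], [0, 0, 0])
        img1 = extract_cross_section(vol, [15, 15, 15], [1, 0, 0], [0, 1, 0], N=5)
        # rotating the frame 90 deg about the tangent: normal->binormal
        img2 = extract_cross_section(vol, [15, 15, 15], [0, 1, 0], [-1, 0, 0], N=5)
        assert np.allclose(img2.intensities, np.rot90(img1.intensities), atol=1e-12)

    def test_linearity_in_intensity(self, rng):
        d1 = rng.random((20, 20, 20))
        d2 = rng.random((20, 20, 20))
        geom = dict(spacing=[0.7, 0.7, 0.7], origin=[0, 0, 0])
        args = ([7, 7, 7], [1, 0, 0], [0, 1, 0])
        s1 = extract_cross_section(Volume3D(d1, **geom), *args, N=3, delta_s=0.7)
        s2 = extract_cross_section(Volume3D(d2, **geom), *args, N=3, delta_s=0.7)
        s12 = extract_cross_section(Volume3D(2 * d1 + 3 * d2, **geom), *args,
                                    N=3, delta_s=0.7)
        assert np.allclose(s12.intensities,
                           2 * s1.intensities + 3 * s2.intensities, atol=1e-9)

    def test_tube_section_matches_forward_render(self):
        # perpendicular section of a blurred straight tube must agree with
        # the forward model's rendering of the matching circular contour
        from lumenfit.fit import fit_image

        vol = tube_volume()
        img = extract_cross_section(vol, [0, 0, 7.5], [1, 0, 0], [0, 1, 0],
                                    N=7, delta_s=1.0)
        res = fit_image(img, R=11.0, w=0.65)
        from lumenfit.forward import ImageFormationParams, render
        from lumenfit.geometry import ContourSpline

        model = render(ImageFormationParams(
            spline=ContourSpline(d=res.d_hat, R=11.0),
            a=res.a_hat, b=res.b_hat, w=0.65))
        assert np.abs(model.intensities - img.intensities).max() < 0.03 * 0.25

    def test_out_of_volume_plane_rejected(self):
        vol = Volume3D(np.zeros((10, 10, 10)), [1, 1, 1], [0, 0, 0])
        with pytest.raises(ValueError):
            extract_cross_section(vol, [100, 100, 100], [1, 0, 0], [0, 1, 0], N=3)

    def test_validity_mask_flags_outside_samples(self):
        vol = Volume3D(np.ones((10, 10, 10)), [1, 1, 1], [0, 0, 0])
        img = extract_cross_section(vol, [1, 4.5, 4.5], [1, 0, 0], [0, 1, 0], N=4)
        assert img.valid_mask is not None
        assert not img.valid_mask.all()
        assert img.valid_mask.any()


class TestNormalizeCT:
    def test_clip_endpoints_and_midpoint(self):
        data = np.array([[[-500.0, -300.0, 250.0, 800.0, 1200.0]]])
        vol = normalize_ct(Volume3D(data, [1, 1, 1], [0, 0, 0]))
        assert np.allclose(vol.data[0, 0], [0.0, 0.0, 0.5, 1.0, 1.0])

    def test_bad_window_rejected(self):
        vol = Volume3D(np.zeros((2, 2, 2)), [1, 1, 1], [0, 0, 0])
        with pytest.raises(ValueError):
            normalize_ct(vol, 100.0, 100.0)


class TestEndToEnd:
    def test_tube_phantom_radius_recovery(self):
        # full chain: volume -> centerline -> frames -> sections -> LS fit
        from lumenfit.fit import fit_image
        from lumenfit.geometry import ContourSpline, evaluate_contour, polygon_area

        radius = 3.0
        vol = tube_volume(radius=radius)
        axis_pts = np.stack([np.zeros(12), np.zeros(12),
                             np.linspace(2.0, 12.0, 12)], axis=1)
        cl = smooth_centerline(axis_pts, 0.0, spacing=1.0)
        images = extract_sections(vol, cl, N=7, delta_s=1.0)
        for img in images[3:6]:
            res = fit_image(img, R=11.0, w=0.65)
            area = polygon_area(evaluate_contour(
                ContourSpline(d=res.d_hat, R=11.0), 1000))
            r_est = np.sqrt(area / np.pi)
            assert abs(r_est - radius) / radius < 0.05


class TestIO:
    def test_centerline_csv_roundtrip(self, tmp_path):
        pts = helix(15)
        path = tmp_path / "cl.csv"
        save_centerline_csv(path, pts)
        assert np.allclose(load_centerline_csv(path), pts, atol=1e-8)

    def test_volume_reader_nifti(self, tmp_path, rng):
        import SimpleITK as sitk

        from lumenfit.sections import load_volume

        arr = rng.random((8, 9, 10)).astype(np.float32)
        img = sitk.GetImageFromArray(arr)
        img.SetSpacing((0.4, 0.5, 0.6))
        img.SetOrigin((1.0, 2.0, 3.0))
        path = str(tmp_path / "vol.nii.gz")
        sitk.WriteImage(img, path)
        vol = load_volume(path)
        assert vol.data.shape == (8, 9, 10)
        assert np.allclose(vol.spacing, [0.4, 0.5, 0.6])
        assert np.allclose(vol.origin, [1.0, 2.0, 3.0])
        assert np.allclose(vol.data, arr, atol=1e-6)

    def test_volume_reader_metaimage(self, tmp_path, rng):
        import SimpleITK as sitk

        from lumenfit.sections import load_volume

        arr = rng.random((5, 6, 7)).astype(np.float32)
        img = sitk.GetImageFromArray(arr)
        img.SetSpacing((0.32, 0.32, 0.4))
        path = str(tmp_path / "vol.mhd")
        sitk.WriteImage(img, path)
        vol = load_volume(path)
        assert vol.data.shape == (5, 6, 7)
        assert np.allclose(vol.spacing, [0.32, 0.32, 0.4])
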