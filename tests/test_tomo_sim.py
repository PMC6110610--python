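"""Rasterization, projection, noise, WBP and wedge masks."""

import numpy as np
import pytest

from centriotome import tomo_sim as ts


def point_volume(n=48, voxel=2.0, pos=None, sigma=2.0):
    pos = [0.0, 0.0, 0.0] if pos is None else pos
    blobs = (np.array([pos]), np.array([sigma]), np.array([1.0]))
    origin = -voxel * np.array([n, n, n]) / 2.0
    return ts.rasterize(blobs, voxel, (n, n, n), origin=origin)


class TestRasterize:
    def test_single_blob_argmax_at_center(self):
        vol = point_volume(n=49)  # odd box: centre falls on a voxel centre
        assert np.unravel_index(np.argmax(vol.grid), vol.grid.shape) == (24, 24, 24)

    def test_integral_equals_mass(self):
        vol = point_volume()
        integral = vol.grid.sum() * vol.voxel_size**3
        assert abs(integral - 1.0) < 0.01

    def test_linearity_two_blobs(self):
        blobs = (np.array([[-8.0, 0, 0], [8.0, 0, 0]]), np.array([2.0, 2.0]),
                 np.array([1.0, 1.0]))
        vol = ts.rasterize(blobs, 2.0, (48, 48, 48),
                           origin=-2.0 * np.array([24.0, 24, 24]))
        assert abs(vol.grid.sum() * 8.0 - 2.0) < 0.02

    def test_nonpositive_voxel_error(self):
        with pytest.raises(ValueError):
            point_volume(voxel=0.0)

    def test_model_confined_to_envelope(self, tiny_model):
        pos, _, _ = tiny_model.all_blobs()
        r_blob = np.linalg.norm(pos[:, :2], axis=1).max()
        vol = ts.rasterize(tiny_model, 2.0, (144, 64, 144), mount=True)
        g = vol.grid
        nx, ny, nz = g.shape
        xs, zs = np.indices((nx, nz))
        r = np.hypot((xs - (nx - 1) / 2), (zs - (nz - 1) / 2)) * 2.0
        outside = r > r_blob + 8.0
        dens = g.max(axis=1)
        assert dens[outside].max() < 0.05 * dens.max()


class TestProjection:
    def test_zero_tilt_is_axial_sum(self):
        vol = point_volume()
        series = ts.project_tilt_series(vol, [0.0])
        assert np.allclose(series.images[0], vol.grid.sum(axis=2) * vol.voxel_size,
                           atol=1e-5)

    def test_default_scheme_has_121_images(self):
        vol = point_volume(n=16)
        series = ts.project_tilt_series(vol, ts.default_tilt_angles())
        assert len(series.images) == 121
        assert series.tilt_angles[0] == 60.0 and series.tilt_angles[-1] == -60.0

    def test_point_on_tilt_axis_is_fixed(self):
        vol = point_volume(n=33, voxel=2.0)  # odd box: centre on a voxel
        series = ts.project_tilt_series(vol, [-40.0, 0.0, 40.0])
        for img in series.images:
            assert np.unravel_index(np.argmax(img), img.shape) == (16, 16)

    def test_projection_linearity(self):
        v1 = point_volume(pos=[-6, 0, 4])
        v2 = point_volume(pos=[8, 2, -6])
        combo = ts.DensityVolume(2.0 * v1.grid + 3.0 * v2.grid, 2.0, v1.origin)
        p1 = ts.project_tilt_series(v1, [25.0]).images[0]
        p2 = ts.project_tilt_series(v2, [25.0]).images[0]
        pc = ts.project_tilt_series(combo, [25.0]).images[0]
        assert np.allclose(pc, 2.0 * p1 + 3.0 * p2, atol=1e-4 * pc.max())

    def test_empty_angle_list_raises(self):
        with pytest.raises(ValueError):
            ts.project_tilt_series(point_volume(n=8), [])

    def test_matches_skimage_radon_single_slice(self):
        """Cross-check the projector against skimage's radon transform.

        The two tools differ in rotation sense, projection-axis label and
        centre convention, so the comparison registers the 1-D profiles
        (orientation and sub-pixel offset) before correlating.
        """
        from skimage.transform import radon

        rng = np.random.default_rng(0)
        n = 32
        img = np.zeros((n, n))
        img[10:22, 12:20] = rng.random((12, 8))
        vol = ts.DensityVolume(np.repeat(img[:, None, :], 3, axis=1), 1.0,
                               np.zeros(3))
        theta = 30.0
        mine = ts.project_tilt_series(vol, [theta]).images[0][:, 1]
        best = -1.0
        for sk_theta in (90 + theta, 90 - theta):
            sk = radon(img, theta=[sk_theta], circle=False, preserve_range=True)
            pad = (sk.shape[0] - n) // 2
            for flip in (1, -1):
                skp = sk[pad - 2 : pad + n + 2, 0][::flip]
                for off in range(0, 5):
                    cand = skp[off : off + n]
                    cc = np.corrcoef(mine, cand)[0, 1]
                    best = max(best, cc)
        assert best > 0.98


class TestNoise:
    def test_noiseless_limit(self):
        vol = point_volume()
        series = ts.project_tilt_series(vol, [0.0, 30.0])
        noisy = ts.add_noise(series, ts.NoiseSpec(snr=1e9, seed=1))
        rms = np.sqrt(np.mean((noisy.images - series.images) ** 2))
        assert rms < 1e-3 * np.sqrt(np.mean(series.images**2))

    def test_determinism(self):
        vol = point_volume()
        series = ts.project_tilt_series(vol, [0.0])
        a = ts.add_noise(series, ts.NoiseSpec(snr=0.5, seed=7))
        b = ts.add_noise(series, ts.NoiseSpec(snr=0.5, seed=7))
        assert np.array_equal(a.images, b.images)

    def test_variance_ratio(self):
        rng = np.random.default_rng(3)
        img = rng.random((96, 96)).astype(np.float32) + 0.5
        series = ts.TiltSeries(img[None], np.array([0.0]), 1.0)
        noisy = ts.add_noise(series, ts.NoiseSpec(snr=0.5, seed=2, mask_fraction=0.0))
        noise = noisy.images[0] - img
        ratio = img.var() / noise.var()
        assert abs(ratio - 0.5) / 0.5 < 0.05

    def test_invalid_snr(self):
        with pytest.raises(Exception):
            ts.NoiseSpec(snr=0.0)


class TestWBP:
    def test_point_source_recovered_full_range(self):
        vol = point_volume(n=33)
        angles = np.linspace(89, -89, 179)
        series = ts.project_tilt_series(vol, angles)
        rec = ts.reconstruct_wbp(series, 33)
        assert np.unravel_index(np.argmax(rec.grid), rec.grid.shape) == (16, 16, 16)

    def test_missing_wedge_elongation(self):
        vol = point_volume(n=33)
        series = ts.project_tilt_series(vol, ts.default_tilt_angles(2.0, 60.0))
        rec = ts.reconstruct_wbp(series, 33).grid

        def spread(p):
            p = np.clip(p - p.max() * 0.05, 0, None)
            x = np.arange(len(p)) - 16.0
            return np.sqrt(np.sum(p * x**2) / np.sum(p))

        elong = spread(rec[16, 16, :]) / spread(rec[:, 16, 16])
        assert elong > 1.1  # point-spread elongated along the beam (z)

    def test_zero_images_raises(self):
        with pytest.raises(ValueError):
            ts.reconstruct_wbp(
                ts.TiltSeries(np.zeros((0, 4, 4)), np.zeros(0), 1.0), 4
            )

    def test_wedge_restricted_fidelity(self, wedge60):
        """Masked correlation of a noiseless reconstruction with its source,
        inside the sampled Fourier region, is high."""
        rng = np.random.default_rng(5)
        blobs = (rng.uniform(-20, 20, (12, 3)), np.full(12, 2.5), np.ones(12))
        vol = ts.rasterize(blobs, 2.0, (32, 32, 32), origin=-np.array([32.0, 32, 32]))
        series = ts.project_tilt_series(vol, ts.default_tilt_angles(1.0, 60.0))
        rec = ts.reconstruct_wbp(series, 32)
        m = wedge60.mask_array((32, 32, 32))
        m[0, 0, 0] = False
        fa = np.fft.fftn(vol.grid)[m]
        fb = np.fft.fftn(rec.grid)[m]
        cc = np.real(np.vdot(fa, fb)) / np.sqrt(
            (np.abs(fa) ** 2).sum() * (np.abs(fb) ** 2).sum()
        )
        assert cc > 0.95

    def test_matches_skimage_iradon_single_slice(self):
        """Cross-check WBP against skimage's filtered back-projection.

        Both reconstruct the same slice from the same sinogram; the
        comparison registers the 2-D outputs (axis order/sense and a
        1-voxel centre offset) before correlating.
        """
        from skimage.transform import iradon

        rng = np.random.default_rng(1)
        n = 32
        img = np.zeros((n, n))
        img[8:24, 10:22] = rng.random((16, 12))
        from scipy.ndimage import gaussian_filter

        img = gaussian_filter(img, 1.0)
        vol = ts.DensityVolume(np.repeat(img[:, None, :], 3, axis=1), 1.0)
        angles = np.linspace(85, -85, 86)
        series = ts.project_tilt_series(vol, angles)
        rec = ts.reconstruct_wbp(series, n).grid[:, 1, :]
        sino = np.stack([series.images[i][:, 1] for i in range(len(angles))],
                        axis=1)
        best = -1.0
        for theta in (90 - angles, 90 + angles):
            sk = iradon(sino, theta=theta, filter_name="ramp",
                        output_size=n, circle=False)
            for cand in (sk, sk.T, sk[::-1], sk[:, ::-1], sk.T[::-1],
                         sk.T[:, ::-1], sk[::-1, ::-1], sk.T[::-1, ::-1]):
                for dx in (-1, 0, 1):
                    for dy in (-1, 0, 1):
                        shifted = np.roll(np.roll(cand, dx, 0), dy, 1)
                        cc = np.corrcoef(rec[2:-2, 2:-2].ravel(),
                                         shifted[2:-2, 2:-2].ravel())[0, 1]
                        best = max(best, cc)
        assert best > 0.95


class TestWedgeMask:
    def test_full_range_all_ones(self):
        m = ts.wedge_mask(-90.0, 90.0, 16)
        assert m.all()

    def test_sixty_degree_fraction(self):
        """Sampled solid-angle fraction is (theta range)/180 for a
        single-axis scheme, evaluated inside the in-plane Nyquist disc
        (the cube's corners over-weight diagonal directions)."""
        n = 64
        m = ts.wedge_mask(-60.0, 60.0, n)
        fx = np.fft.fftfreq(n)[:, None, None]
        fz = np.fft.fftfreq(n)[None, None, :]
        disc = np.broadcast_to(np.hypot(fx, fz) <= 0.5, m.shape)
        frac = m[disc].mean()
        assert abs(frac - 2.0 / 3.0) < 0.03

    def test_friedel_symmetry(self):
        m = ts.wedge_mask(-50.0, 50.0, 17)
        flipped = m[::-1, ::-1, ::-1]
        # conjugate inversion about the DC term (roll to align fftfreq grid)
        flipped = np.roll(flipped, 1, axis=(0, 1, 2))
        assert np.array_equal(m, flipped)

    def test_rotated_mask_matches_rotated_directions(self, wedge60):
        from scipy.spatial.transform import Rotation

        r = Rotation.from_euler("ZYZ", [30, 40, 10], degrees=True).as_matrix()
        m = wedge60.mask_array((16, 16, 16), rotation=r)
        fx = np.fft.fftfreq(16)
        v = r @ np.array([fx[3], fx[5], fx[7]])
        expect = wedge60.passes(np.array(v[0]), 0.0, np.array(v[2]))
        assert m[3, 5, 7] == expect
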