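"""Constrained correlation, alignment, averaging, FSC, periodicity."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from centriotome import sta
from centriotome.errors import AmbiguousPeriodError, EmptySetError
from centriotome.picking import Particle
from centriotome.studies import _particles_from_frames
from centriotome.tomo_sim import WedgeMask, apply_wedge, simulate_segments
from conftest import rotation_distance_deg


def random_volume(seed, n=32):
    return np.random.default_rng(seed).normal(size=(n, n, n))


def realspace_cc_oracle(a, b, mask_region):
    """Brute-force oracle: plain normalized correlation of mask-filtered
    copies in real space."""
    region = mask_region.copy()
    region[0, 0, 0] = False
    fa = np.fft.ifftn(np.fft.fftn(a) * region).real
    fb = np.fft.ifftn(np.fft.fftn(b) * region).real
    fa -= fa.mean()
    fb -= fb.mean()
    return float(np.sum(fa * fb) / np.sqrt(np.sum(fa**2) * np.sum(fb**2)))


class TestConstrainedCC:
    def test_self_correlation_is_one(self):
        x = random_volume(0)
        assert sta.constrained_cc(x, x) == pytest.approx(1.0, abs=1e-6)

    def test_anticorrelation_is_minus_one(self):
        x = random_volume(1)
        assert sta.constrained_cc(x, -x) == pytest.approx(-1.0, abs=1e-6)

    @pytest.mark.parametrize("seed", range(20))
    def test_equals_realspace_oracle_under_wedge(self, seed, wedge60):
        a = random_volume(seed)
        b = random_volume(seed + 100)
        region = wedge60.mask_array(a.shape)
        got = sta.constrained_cc(a, b, wedge_a=region)
        want = realspace_cc_oracle(a, b, region)
        assert got == pytest.approx(want, abs=1e-3)

    def test_empty_overlap_raises(self):
        a = random_volume(2)
        with pytest.raises(Exception):
            sta.constrained_cc(a, a, wedge_a=np.zeros(a.shape, bool))


class TestAlignment:
    def test_known_misrotation_recovered(self, blade_reference, wedge60):
        g = blade_reference.grid.astype(float)
        voxel = blade_reference.voxel_size
        truth = Rotation.from_euler("ZYZ", [4.0, 0.0, -2.0], degrees=True)
        sub = sta.resample_residual(g, truth.as_matrix().T, np.zeros(3))
        p = Particle(particle_id=0, rod_id=1, s=12.0, center0=np.zeros(3),
                     euler0=np.zeros(3))
        params = sta.AlignmentParams((8.0, 8.0, 8.0), 2.0, shift_range=0.0,
                                     shift_step=voxel, lowpass=4.0)
        q = sta.align_particle(sub, g, p, params, voxel_size=voxel)
        got = q.residual_rotation()
        # sub(x) = ref(R^-1 x), so the recovered residual is R itself
        assert rotation_distance_deg(got, truth.as_matrix()) <= 2.0

    def test_zero_ranges_returns_unchanged(self, blade_reference):
        g = blade_reference.grid.astype(float)
        p = Particle(particle_id=0, rod_id=1, s=12.0, center0=np.zeros(3),
                     euler0=np.array([10.0, 5.0, -3.0]))
        params = sta.AlignmentParams((0.0, 0.0, 0.0), 2.0, shift_range=0.0,
                                     shift_step=1.0, lowpass=None)
        q = sta.align_particle(g, g, p, params, voxel_size=1.75)
        assert np.allclose(q.euler, p.euler)
        assert q.score == pytest.approx(1.0, abs=1e-6)

    def test_majority_recovery_at_snr_half(self, blade_reference, wedge60):
        """>= 90% of SNR 0.5 segments recover pose within one grid step."""
        n = 40
        subvols, frames, true = simulate_segments(
            blade_reference, n, 0.5, wedge60, seed=11,
            angle_jitter=(3.0, 2.0, 3.0), shift_jitter=1.5,
        )
        particles = _particles_from_frames(frames)
        params = [sta.AlignmentParams((4.0, 2.0, 4.0), 2.0, shift_range=2.0,
                                      shift_step=1.75, lowpass=4.0)] * 2
        avg, refined, scores = sta.run_alignment(
            particles, subvols, params, wedge60, blade_reference.voxel_size,
            reference0=blade_reference.grid.astype(float), seed=3,
        )
        ok = 0
        for p, t in zip(refined, true):
            want = Rotation.from_euler(
                "ZYZ", [t["rot"], t["tilt"], t["psi"]], degrees=True
            ).as_matrix()
            err = rotation_distance_deg(p.residual_rotation(), want)
            shift_err = np.linalg.norm(p.shift - np.array([t["sx"], t["sy"], t["sz"]]))
            if err <= 2.0 * np.sqrt(3) and shift_err <= 2.0:
                ok += 1
        assert ok / n >= 0.9

    def test_score_invariant_to_global_rotation(self, blade_reference, wedge60):
        """Rotating pose and content together leaves the score unchanged."""
        g = blade_reference.grid.astype(float)
        voxel = blade_reference.voxel_size
        p0 = Particle(particle_id=0, rod_id=1, s=12.0, center0=np.zeros(3),
                      euler0=np.zeros(3))
        params = sta.AlignmentParams((0.0, 0.0, 0.0), 2.0, shift_range=0.0,
                                     shift_step=voxel, lowpass=4.0)
        q0 = sta.align_particle(g, g, p0, params, wedge=wedge60, voxel_size=voxel)
        # rotate the content and carry the inverse rotation in the pose:
        # the aligner resamples by the residual, so the score is unchanged
        rot = Rotation.from_euler("ZYZ", [0.0, 0.0, 90.0], degrees=True)
        g_rot = sta.resample_residual(g, rot.as_matrix(), np.zeros(3))
        p1 = Particle(particle_id=0, rod_id=1, s=12.0, center0=np.zeros(3),
                      euler0=np.zeros(3))
        p1.euler = np.array([0.0, 0.0, -90.0])
        q1 = sta.align_particle(g_rot, g, p1, params, wedge=wedge60,
                                voxel_size=voxel)
        assert q1.score == pytest.approx(q0.score, abs=0.05)


class TestAveraging:
    def test_identical_copies_average_to_copy(self, blade_reference):
        g = blade_reference.grid.astype(float)
        full = WedgeMask(-90.0, 90.0)
        particles = [
            Particle(particle_id=i, rod_id=1, s=12.0, center0=np.zeros(3),
                     euler0=np.zeros(3), half_set=i % 2)
            for i in range(4)
        ]
        avg = sta.average_particles(particles, [g] * 4, full, 1.75)
        rms = np.sqrt(np.mean((avg.grid - g) ** 2)) / g.std()
        assert rms < 1e-3

    def test_complementary_wedges_fill_coverage(self, blade_reference):
        g = blade_reference.grid.astype(float)
        wedge = WedgeMask(-60.0, 60.0)
        r90 = Rotation.from_euler("ZYZ", [0.0, 0.0, 90.0], degrees=True)
        p0 = Particle(particle_id=0, rod_id=1, s=12.0, center0=np.zeros(3),
                      euler0=np.zeros(3), half_set=0)
        p1 = Particle(particle_id=1, rod_id=1, s=12.0, center0=np.zeros(3),
                      euler0=np.array([0.0, 0.0, 90.0]), half_set=1)
        m0 = wedge.mask_array(g.shape, rotation=p0.rotation(), rfft=True)
        m1 = wedge.mask_array(g.shape, rotation=r90.as_matrix(), rfft=True)
        union = m0 | m1
        assert union.sum() > m0.sum() and union.sum() > m1.sum()

    def test_zero_particles_raises(self):
        with pytest.raises(EmptySetError):
            sta.average_particles([], [], WedgeMask(-60, 60), 1.0)

    def test_average_recovers_reference_under_noise(self, blade_reference, wedge60):
        subvols, frames, _ = simulate_segments(
            blade_reference, 60, 0.25, wedge60, seed=4,
            angle_jitter=(0.0, 0.0, 0.0), shift_jitter=0.0,
        )
        particles = _particles_from_frames(frames)
        avg = sta.average_particles(particles, subvols, wedge60,
                                    blade_reference.voxel_size)
        sig = blade_reference.grid > 0.1 * blade_reference.grid.max()
        cc = np.corrcoef(avg.grid[sig], blade_reference.grid[sig])[0, 1]
        assert cc > 0.9


class TestRunAlignment:
    def test_fixed_point_at_ground_truth(self, blade_reference, wedge60):
        subvols, frames, _ = simulate_segments(
            blade_reference, 12, 1e6, wedge60, seed=5,
            angle_jitter=(0.0, 0.0, 0.0), shift_jitter=0.0,
        )
        particles = _particles_from_frames(frames)
        params = sta.AlignmentParams((2.0, 2.0, 2.0), 2.0, shift_range=0.0,
                                     shift_step=1.75, lowpass=4.0,
                                     n_iterations=2)
        avg, refined, scores = sta.run_alignment(
            particles, subvols, params, wedge60, blade_reference.voxel_size,
            reference0=None, seed=0, gold_standard=False,
        )
        # already at the optimum: the first-pass mean score is high and a
        # second pass does not improve it
        assert scores[0] > 0.95
        assert abs(scores[1] - scores[0]) < 1e-3

    def test_single_particle_average_is_wedge_filtered_input(
        self, blade_reference, wedge60
    ):
        g = blade_reference.grid.astype(float)
        p = Particle(particle_id=0, rod_id=1, s=12.0, center0=np.zeros(3),
                     euler0=np.zeros(3), half_set=0)
        gw = apply_wedge(g, wedge60)
        avg = sta.average_particles([p], [gw], wedge60, 1.75)
        cc = np.corrcoef(avg.grid.ravel(), gw.ravel())[0, 1]
        assert cc > 0.999

    def test_half_set_balance(self, blade_reference, wedge60):
        subvols, frames, _ = simulate_segments(
            blade_reference, 11, 1.0, wedge60, seed=6,
            angle_jitter=(0.0, 0.0, 0.0), shift_jitter=0.0,
        )
        particles = _particles_from_frames(frames)
        sta.assign_half_sets(particles, seed=1)
        counts = np.bincount([p.half_set for p in particles])
        assert abs(counts[0] - counts[1]) <= 1


class TestFSC:
    def test_identical_half_maps_give_unity(self, blade_reference):
        g = blade_reference.grid.astype(float)
        curve = sta.compute_fsc(g, g, 1.75)
        assert np.allclose(curve.fsc, 1.0, atol=1e-9)

    def test_independent_noise_is_insignificant(self):
        rng = np.random.default_rng(8)
        a = rng.normal(size=(32, 32, 32))
        b = rng.normal(size=(32, 32, 32))
        curve = sta.compute_fsc(a, b, 1.0)
        counts = sta.shell_voxel_counts((32, 32, 32))
        sig = 3.0 / np.sqrt(counts)
        frac = np.mean(np.abs(curve.fsc) < sig)
        assert frac >= 0.95

    def test_band_limited_resolution(self):
        rng = np.random.default_rng(9)
        voxel = 1.0
        n = 48
        base = rng.normal(size=(n, n, n))
        fx = np.fft.fftfreq(n)[:, None, None]
        fy = np.fft.fftfreq(n)[None, :, None]
        fz = np.fft.fftfreq(n)[None, None, :]
        f = np.sqrt(fx**2 + fy**2 + fz**2)
        keep = f <= 1.0 / 4.0  # band limit 4 nm
        src = np.fft.ifftn(np.fft.fftn(base) * keep).real
        a = src + 0.05 * rng.normal(size=src.shape)
        b = src + 0.05 * rng.normal(size=src.shape)
        curve = sta.compute_fsc(a, b, voxel)
        res = curve.resolution_at(0.143)
        shell_width = 1.0 / (n * voxel)
        assert res <= 1.0 / (1.0 / 4.0 - shell_width) + 1e-6

    def test_small_box_rejected(self):
        with pytest.raises(ValueError):
            sta.compute_fsc(np.zeros((4, 4, 4)), np.zeros((4, 4, 4)), 1.0)


class TestPeriodicity:
    def test_no_decoration_is_ambiguous(self):
        g = np.zeros((32, 32, 32))
        with pytest.raises(AmbiguousPeriodError):
            sta.decoration_periodicity(g, g, 1.6)


class TestCounting:
    def test_ideal_triplet_counts(self, blade_reference, tubule_centers):
        for label, annulus, want in (
            ("A", (11.0, 14.5), 13),
            ("B", (10.0, 13.5), 10),
            ("C", (10.0, 13.5), 10),
        ):
            c = tubule_centers[label]
            got = sta.count_protofilaments(
                blade_reference.grid, (c[0], c[1]), annulus, voxel_size=1.75
            )
            assert got == want, label

    def test_uniform_annulus_counts_zero(self):
        g = np.ones((32, 32, 32))
        assert sta.count_protofilaments(g, (0, 0), (5.0, 10.0), voxel_size=1.0) == 0

    def test_invariant_to_inplane_rotation(self, blade_reference, tubule_centers):
        g = blade_reference.grid.astype(float)
        rot = Rotation.from_euler("ZYZ", [0.0, 0.0, 25.0], degrees=True).as_matrix()
        g_rot = sta.resample_residual(g, rot, np.zeros(3))
        c = tubule_centers["A"]
        c_rot = rot[:2, :2].T @ np.asarray(c)
        n0 = sta.count_protofilaments(g, tuple(c), (11.0, 14.5), voxel_size=1.75)
        n1 = sta.count_protofilaments(g_rot, tuple(c_rot), (11.0, 14.5),
                                      voxel_size=1.75)
        assert n0 == n1 == 13

    def test_empty_annulus_rejected(self, blade_reference):
        with pytest.raises(ValueError):
            sta.count_protofilaments(blade_reference.grid, (0, 0), (10.0, 5.0),
                                     voxel_size=1.75)
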