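"""Refitting, ellipse fits, symmetrization and ensemble measurements."""

import numpy as np
import pytest

from centriotome import geometry as geo, model_builder as mb
from centriotome.errors import FitDegenerateError
from centriotome.picking import Particle
from centriotome.studies import _reference_volume


def ellipse_points(a, b, n=36, theta=0.0, center=(0.0, 0.0), noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = np.stack([a * np.cos(t), b * np.sin(t)], axis=1)
    c, s = np.cos(theta), np.sin(theta)
    pts = pts @ np.array([[c, s], [-s, c]])
    pts += np.asarray(center)
    if noise:
        pts += rng.normal(0, noise, pts.shape)
    return pts


class TestFitEllipse:
    def test_exact_circle(self):
        fit = geo.fit_ellipse(ellipse_points(100.0, 100.0, n=9))
        assert fit.a == pytest.approx(100.0, abs=1e-6)
        assert fit.b == pytest.approx(100.0, abs=1e-6)
        assert fit.ellipticity_percent == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("a,b,theta", [(110, 90, 0.0), (50, 30, 0.7),
                                           (80, 75, -1.1)])
    def test_exact_ellipse_recovery(self, a, b, theta):
        fit = geo.fit_ellipse(ellipse_points(a, b, theta=theta, center=(3, -2)))
        assert fit.a == pytest.approx(a, rel=1e-6)
        assert fit.b == pytest.approx(b, rel=1e-6)
        assert fit.center == pytest.approx([3, -2], abs=1e-6)

    def test_noisy_ellipticity_recovery(self):
        pts = ellipse_points(110.0, 90.0, n=72, noise=1.0, seed=4)
        fit = geo.fit_ellipse(pts)
        want = 100.0 * (110.0 - 90.0) / 110.0
        assert abs(fit.ellipticity_percent - want) < 1.0

    def test_five_points_rejected(self):
        with pytest.raises(FitDegenerateError):
            geo.fit_ellipse(ellipse_points(10, 8)[:5])

    def test_collinear_rejected(self):
        pts = np.stack([np.arange(8.0), 2 * np.arange(8.0)], axis=1)
        with pytest.raises(FitDegenerateError):
            geo.fit_ellipse(pts)


def closed_form_segment_centers(preset, domain, e):
    """Independent closed form: squash the blade-centre circle, re-tangent
    rigid blades, add the segment-centre lever arm."""
    R = preset.radius_of(domain)
    alpha = np.deg2rad(preset.tilt_of(domain))
    off = preset.center_offset
    a, b = R * (1 + e), R / (1 + e)
    out = []
    for phi in np.deg2rad(40.0 * np.arange(9)):
        p = np.array([a * np.cos(phi), b * np.sin(phi)])
        t = np.array([-a * np.sin(phi), b * np.cos(phi)])
        t /= np.linalg.norm(t)
        n = np.array([t[1], -t[0]])
        if np.dot(n, p) < 0:
            n = -n
        xb = np.cos(alpha) * t + np.sin(alpha) * n
        out.append(p + off * xb)
    return np.array(out)


def synthetic_cross_section_particles(model):
    """Particles at ground-truth poses of an assembled model (model frame)."""
    parts = []
    for i, row in model.ground_truth.iterrows():
        parts.append(
            Particle(
                particle_id=i, rod_id=int(row.rod_id), s=row.s_nm,
                center0=np.array([row.x_nm, row.y_nm, row.z_nm]),
                euler0=np.array([row.rot_deg, row.tilt_deg, row.psi_deg]),
                domain=row.domain,
            )
        )
    return parts


class TestRefitPositions:
    def test_unflattened_rods_equidistant(self, tiny_model):
        parts = [p for p in synthetic_cross_section_particles(tiny_model)
                 if p.domain == "proximal"]
        cs = geo.refit_positions(parts)
        r = np.linalg.norm(geo.rod_mean_points(cs), axis=1)
        assert np.ptp(r) < 2.0

    def test_flattened_axis_ratio(self, cho_preset):
        e = 0.25
        model = mb.assemble_centriole(cho_preset, mb.FlatteningSpec(e), seed=3)
        parts = [p for p in synthetic_cross_section_particles(model)
                 if p.domain == "proximal"]
        cs = geo.refit_positions(parts)
        r = np.sort(np.linalg.norm(geo.rod_mean_points(cs), axis=1))
        want = np.sort(np.linalg.norm(
            closed_form_segment_centers(cho_preset, "proximal", e), axis=1))
        assert np.abs(r - want).max() < 0.5
        # the measured spread reflects the (1+e)^2 blade-centre squash
        assert abs(r.max() / r.min() - want.max() / want.min()) < 0.02

    def test_too_few_rods_rejected(self):
        parts = [
            Particle(particle_id=i, rod_id=i % 2, s=12.0 * i,
                     center0=np.array([i * 1.0, 0, 0]), euler0=np.zeros(3))
            for i in range(10)
        ]
        with pytest.raises(FitDegenerateError):
            geo.refit_positions(parts)


class TestSymmetrize:
    @pytest.fixture(scope="class")
    def proximal_ensemble(self, blade_reference, cho_preset):
        params = geo.SymmetryParams(
            blade_radius=cho_preset.radius_proximal,
            blade_tilt=cho_preset.blade_tilt_proximal,
            domain="proximal",
            center_offset=cho_preset.center_offset,
        )
        return geo.symmetrize(blade_reference, params, box=(160, 160, 24))

    def test_ninefold_rotation_invariance(self, proximal_ensemble):
        from scipy.ndimage import rotate

        g = proximal_ensemble.volume.grid
        mid = g[:, :, g.shape[2] // 2]
        rot = rotate(mid, 40.0, reshape=False, order=3)
        sel = mid > 0.1 * mid.max()
        rms = np.sqrt(np.mean((rot[sel] - mid[sel]) ** 2))
        assert rms < 0.1 * mid[sel].std() + 0.05 * mid.max() * 0.1 + 1e-12 \
            or np.corrcoef(rot[sel], mid[sel])[0, 1] > 0.98

    def test_measured_tilt_matches_params(self, proximal_ensemble, cho_preset):
        t = geo.measure_blade_tilt(proximal_ensemble)
        assert t == pytest.approx(cho_preset.blade_tilt_proximal, abs=1e-6)

    def test_blade_too_big_rejected(self, blade_reference, cho_preset):
        params = geo.SymmetryParams(blade_radius=70.0, blade_tilt=50.0)
        with pytest.raises(ValueError):
            geo.symmetrize(blade_reference, params, box=(16, 16, 16))

    def test_proximal_diameter(self, proximal_ensemble):
        d = geo.measure_diameter(proximal_ensemble)
        assert abs(d - 235.0) / 235.0 < 0.05


class TestDiameterMonotone:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_monotone_in_radius(self, blade_reference, seed):
        rng = np.random.default_rng(seed)
        jitter = rng.uniform(-1.0, 1.0)
        diams = []
        for radius in (55.0, 70.0, 82.0):
            params = geo.SymmetryParams(blade_radius=radius + jitter,
                                        blade_tilt=50.0)
            ens = geo.symmetrize(blade_reference, params, box=(176, 176, 24))
            diams.append(geo.measure_diameter(ens))
        assert diams[0] < diams[1] < diams[2]


class TestMapEllipticity:
    @staticmethod
    def _shared_wall_arc(centers):
        a, b = centers["A"], centers["B"]
        bang = np.rad2deg(np.arctan2(b[1] - a[1], b[0] - a[0]))
        return ((bang - 35.0) % 360.0, (bang + 35.0) % 360.0)

    def test_circular_tubule_near_zero(self, blade_reference, tubule_centers):
        c = tubule_centers["A"]
        e = geo.measure_map_ellipticity(
            blade_reference, tuple(c), (10.0, 15.5),
            exclude_arc=self._shared_wall_arc(tubule_centers),
        )
        assert e < 2.0

    def test_distorted_tubule_recovered(self, cho_preset, proximal_gamma):
        spec = mb.blade_spec_for(cho_preset, "proximal", a_ellipticity=10.0)
        blade = mb.build_blade(spec, 48.0, seed=3)
        ref = _reference_volume(blade, proximal_gamma,
                                cho_preset.center_offset, 1.75, 48)
        centers = mb.tubule_centers_in_reference(
            blade, proximal_gamma, cho_preset.center_offset)
        e = geo.measure_map_ellipticity(
            ref, tuple(centers["A"]), (10.0, 15.5),
            exclude_arc=self._shared_wall_arc(centers),
        )
        assert abs(e - 10.0) < 2.0

    def test_annulus_without_wall_rejected(self):
        g = np.zeros((32, 32, 32), np.float32)
        with pytest.raises(FitDegenerateError):
            geo.measure_map_ellipticity(g, (0, 0), (5.0, 10.0), voxel_size=1.0)


class TestTiltChange:
    def test_same_ensemble_zero_change(self, blade_reference, cho_preset):
        params = geo.SymmetryParams(blade_radius=70.0, blade_tilt=50.0,
                                    center_offset=cho_preset.center_offset)
        ens = geo.symmetrize(blade_reference, params, box=(160, 160, 24))
        assert geo.tilt_change(ens, ens) == pytest.approx(0.0, abs=1e-9)

    def test_generator_presets_give_15_degrees(self, cho_preset):
        assert (cho_preset.blade_tilt_proximal - cho_preset.blade_tilt_distal
                ) == pytest.approx(15.0)

    def test_cross_section_recovery_from_truth_poses(self, cho_preset):
        """Blade tilt measured from refit poses matches the generator."""
        model = mb.assemble_centriole(cho_preset, mb.FlatteningSpec(0.2), seed=5)
        parts = synthetic_cross_section_particles(model)
        tilts = {}
        for domain in ("proximal", "distal"):
            sel = [p for p in parts if p.domain == domain]
            params = geo.SymmetryParams(
                blade_radius=cho_preset.radius_of(domain),
                blade_tilt=cho_preset.tilt_of(domain),
                domain=domain,
                center_offset=cho_preset.center_offset,
            )
            delta = geo.blade_axis_reference(params.gamma())
            cs = geo.refit_positions(sel, blade_axis_ref=delta,
                                     point_offset_ref=params.a_center_in_reference())
            tilts[domain] = geo.measure_blade_tilt(cs)
        change = geo.tilt_change(tilts["proximal"], tilts["distal"])
        assert abs(change - 15.0) < 2.0


class TestRebuildComposite:
    def test_single_class_composite_and_runs(self, blade_reference):
        parts = []
        for i in range(4):
            p = Particle(particle_id=i, rod_id=1 + i % 2, s=12.0 + 24 * (i // 2),
                         center0=np.array([32.0, 32.0, 16.0 + 24 * (i // 2)]),
                         euler0=np.zeros(3))
            p.class_label = 0
            parts.append(p)
        g = blade_reference.grid.astype(np.float32)
        vol, runs = geo.rebuild_composite(parts, {0: g}, (64, 64, 48), 1.75)
        assert vol.grid.shape == (64, 64, 48)
        assert set(runs.rod_id) == {1, 2}
        assert (runs.run_length == 2).all()

    def test_rod_level_clustering_statistic(self):
        parts = []
        pid = 0
        for rod in range(1, 10):
            label = 1 if rod in (3, 7) else 0
            for k in range(9):
                p = Particle(particle_id=pid, rod_id=rod, s=12.0 + 24 * k,
                             center0=np.zeros(3), euler0=np.zeros(3))
                p.class_label = label
                parts.append(p)
                pid += 1
        g = np.zeros((8, 8, 8), np.float32)
        vol, runs = geo.rebuild_composite(parts, {0: g, 1: g}, (16, 16, 16), 2.0)
        partial_runs = runs[runs.class_label == 1]
        assert (partial_runs.run_length == 9).all()
        assert len(partial_runs) == 2

    def test_unclassified_particle_rejected(self):
        p = Particle(particle_id=0, rod_id=1, s=12.0, center0=np.zeros(3),
                     euler0=np.zeros(3))
        with pytest.raises(ValueError):
            geo.rebuild_composite([p], {0: np.zeros((4, 4, 4))}, (8, 8, 8), 1.0)
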