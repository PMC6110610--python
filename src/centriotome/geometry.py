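"""Geometric reconstruction: refitting, flattening quantification,
9-fold symmetrization and ensemble measurements.

Flattened centrioles cannot be symmetrized from their own data, so the
symmetry parameters (blade radius and blade tilt per axial domain) are
*inputs*, mirroring the use of externally determined geometry from
resin-embedded centrioles; the pipeline measures what the symmetrized
ensemble then looks like (outer diameter, blade tilt) and what the raw
refitted cross-sections reveal (flattening, per-domain blade rotation).

Sign conventions: blade tilt is the angle between the blade long axis
(A->C, or A->B for doublets) and the local tangent, positive when the
outer end rotates away from the axis; the proximal->distal tilt change is
reported inward-positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.measure import EllipseModel

from .errors import FitDegenerateError
from .model_builder import particle_frame_gamma
from .sta import AverageMap
from .tomo_sim import DensityVolume

# ---------------------------------------------------------------------------
# cross sections
# ---------------------------------------------------------------------------


@dataclass
class CrossSection:
    """Per-particle positions/orientations projected onto the plane
    perpendicular to the fitted centriole axis."""

    axis_point: np.ndarray
    axis_dir: np.ndarray
    e1: np.ndarray  # in-plane basis
    e2: np.ndarray
    rod_ids: np.ndarray
    s: np.ndarray
    points: np.ndarray  # (n, 2) nm
    blade_angles: np.ndarray  # in-plane blade long-axis direction, degrees
    domains: np.ndarray


def blade_axis_reference(gamma_deg: float) -> np.ndarray:
    """Blade long-axis direction in the reference frame.

    ``gamma_deg`` is the in-plane blade angle of the frame convention
    (see :func:`centriotome.model_builder.particle_frame_gamma`).
    """
    g = np.deg2rad(gamma_deg)
    return np.array([np.cos(g), np.sin(g), 0.0])


def refit_positions(
    particles,
    blade_axis_ref: np.ndarray | None = None,
    point_offset_ref: np.ndarray | None = None,
) -> CrossSection:
    """Project refined particle poses into the axis-normal plane.

    The axis is the first principal direction of the particle centres;
    the in-plane blade orientation is the projected direction of
    ``blade_axis_ref`` (default: reference x axis) under each particle's
    refined rotation.  ``point_offset_ref`` (reference-frame nm, e.g. the
    A-tubule centre measured in the average map) shifts each projected
    point from the segment centre to that anchor, so tangents are
    evaluated where the blade attaches to the 9-fold ring.
    """
    particles = list(particles)
    rods = {p.rod_id for p in particles}
    if len(particles) < 9 or len(rods) < 3:
        raise FitDegenerateError("need >= 9 particles spanning >= 3 rods")
    if point_offset_ref is None:
        centers = np.array([p.center for p in particles])
    else:
        off = np.asarray(point_offset_ref, float)
        centers = np.array([p.center + p.rotation() @ off for p in particles])
    mean = centers.mean(axis=0)
    # axis = mean of per-rod line directions (each rod runs along the
    # centriole axis); a global principal direction would tip into the
    # cross-section plane whenever the 9-fold ring is wider than the
    # sampled length
    rod_ids = np.array([p.rod_id for p in particles])
    dirs = []
    for rid in np.unique(rod_ids):
        pts = centers[rod_ids == rid]
        if len(pts) < 2:
            continue
        _, sv, vt = np.linalg.svd(pts - pts.mean(axis=0), full_matrices=False)
        if sv[0] > 1e-9:
            d = vt[0]
            # orient consistently along increasing s
            s_order = np.array([p.s for p in particles])[rod_ids == rid]
            if np.dot(pts[np.argmax(s_order)] - pts[np.argmin(s_order)], d) < 0:
                d = -d
            dirs.append(d)
    if dirs:
        axis = np.mean(dirs, axis=0)
    else:
        _, sv, vt = np.linalg.svd(centers - mean, full_matrices=False)
        if sv[0] < 1e-9 or sv[1] < 1e-9:
            raise FitDegenerateError("degenerate particle configuration")
        axis = vt[0]
    n = np.linalg.norm(axis)
    if n < 1e-9:
        raise FitDegenerateError("degenerate particle configuration")
    axis = axis / n
    spread = np.linalg.norm(
        (centers - mean) - np.outer((centers - mean) @ axis, axis), axis=1
    )
    if spread.max() < 1e-9:
        raise FitDegenerateError("particle centres are collinear")
    # deterministic in-plane basis
    seed_vec = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(seed_vec, axis)) > 0.9:
        seed_vec = np.array([0.0, 1.0, 0.0])
    e1 = seed_vec - np.dot(seed_vec, axis) * axis
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    delta = blade_axis_ref if blade_axis_ref is not None else np.array([1.0, 0.0, 0.0])
    pts, angles = [], []
    for p, c in zip(particles, centers):
        rel = c - mean
        pts.append([np.dot(rel, e1), np.dot(rel, e2)])
        d_world = p.rotation() @ delta
        angles.append(
            np.rad2deg(np.arctan2(np.dot(d_world, e2), np.dot(d_world, e1)))
        )
    return CrossSection(
        axis_point=mean,
        axis_dir=axis,
        e1=e1,
        e2=e2,
        rod_ids=np.array([p.rod_id for p in particles]),
        s=np.array([p.s for p in particles]),
        points=np.array(pts),
        blade_angles=np.array(angles),
        domains=np.array([p.domain or "" for p in particles]),
    )


def rod_mean_points(cs: CrossSection) -> np.ndarray:
    """Mean in-plane point per rod (one blade-centre sample each)."""
    out = []
    for rid in np.unique(cs.rod_ids):
        out.append(cs.points[cs.rod_ids == rid].mean(axis=0))
    return np.array(out)


# ---------------------------------------------------------------------------
# ellipse fitting
# ---------------------------------------------------------------------------


@dataclass
class EllipseFit:
    center: np.ndarray
    a: float  # semi-major, nm
    b: float  # semi-minor
    orientation_deg: float

    @property
    def ellipticity_percent(self) -> float:
        """100 * (a - b) / a."""
        return 100.0 * (self.a - self.b) / self.a

    @property
    def axis_ratio_percent(self) -> float:
        """Alternative convention: 100 * (a/b - 1)."""
        return 100.0 * (self.a / self.b - 1.0)

    def tangent_at(self, point: np.ndarray) -> np.ndarray:
        """Unit tangent of the ellipse at the parameter nearest ``point``
        (counter-clockwise orientation)."""
        th = np.deg2rad(self.orientation_deg)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        q = rot.T @ (np.asarray(point, float) - self.center)
        t_par = np.arctan2(q[1] / self.b, q[0] / self.a)
        t = rot @ np.array([-self.a * np.sin(t_par), self.b * np.cos(t_par)])
        return t / np.linalg.norm(t)

    def normal_at(self, point: np.ndarray) -> np.ndarray:
        t = self.tangent_at(point)
        n = np.array([t[1], -t[0]])
        rel = np.asarray(point, float) - self.center
        return n if np.dot(n, rel) > 0 else -n


def fit_ellipse(points: np.ndarray) -> EllipseFit:
    """Direct least-squares conic fit constrained to ellipses."""
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 6:
        raise FitDegenerateError("ellipse fit needs >= 6 planar points")
    # collinearity check
    rel = pts - pts.mean(axis=0)
    sv = np.linalg.svd(rel, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        raise FitDegenerateError("points are collinear")
    model = EllipseModel.from_estimate(pts)
    if not model:
        raise FitDegenerateError("ellipse estimation failed")
    (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
    if b > a:
        a, b = b, a
        theta += np.pi / 2.0
    theta = (theta + np.pi / 2.0) % np.pi - np.pi / 2.0
    if a <= 0 or b <= 0 or not np.isfinite([xc, yc, a, b, theta]).all():
        raise FitDegenerateError("degenerate ellipse parameters")
    return EllipseFit(
        center=np.array([xc, yc]), a=float(a), b=float(b),
        orientation_deg=float(np.rad2deg(theta)),
    )


def measure_map_ellipticity(
    average,
    center_xy_nm: tuple[float, float],
    annulus: tuple[float, float],
    voxel_size: float | None = None,
    axial_extent: float = 24.0,
    n_theta: int = 120,
    exclude_arc: tuple[float, float] | None = None,
) -> float:
    """A-tubule wall ellipticity (percent) from a sub-volume average.

    The per-angle radial position of the wall-density maximum is
    extracted over the central ``axial_extent`` and an ellipse fitted to
    the wall points; returns ``100 (a - b) / a``.  ``exclude_arc``
    (degrees, measured at the tubule centre) masks out a sector -- the
    shared wall with an attached tubule hides the host wall there.
    """
    if isinstance(average, (AverageMap, DensityVolume)):
        grid = average.grid
        voxel_size = average.voxel_size
    else:
        grid = np.asarray(average)
        if voxel_size is None:
            raise ValueError("voxel_size required for a bare array")
    r_lo, r_hi = annulus
    nx, ny, nz = grid.shape
    half = int(round(axial_extent / voxel_size / 2))
    sect = grid[:, :, max(nz // 2 - half, 0) : min(nz // 2 + half, nz)].mean(axis=2)
    cx = (nx - 1) / 2.0 + center_xy_nm[0] / voxel_size
    cy = (ny - 1) / 2.0 + center_xy_nm[1] / voxel_size
    thetas = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    radii = np.arange(r_lo, r_hi + 1e-9, voxel_size / 4.0)
    xs = cx + (radii[None, :] / voxel_size) * np.cos(thetas)[:, None]
    ys = cy + (radii[None, :] / voxel_size) * np.sin(thetas)[:, None]
    prof = ndimage.map_coordinates(
        sect.astype(float), np.stack([xs, ys]), order=1, mode="constant",
        cval=float(sect.min()),
    )
    if np.ptp(prof) < 1e-12:
        raise FitDegenerateError("no wall density inside the annulus")
    j = np.argmax(prof, axis=1)
    r_wall = radii[j]
    # parabolic sub-sample refinement of the wall-maximum radius
    step = radii[1] - radii[0] if len(radii) > 1 else 0.0
    inner = (j > 0) & (j < prof.shape[1] - 1)
    rows = np.flatnonzero(inner)
    f0 = prof[rows, j[rows]]
    fm = prof[rows, j[rows] - 1]
    fp = prof[rows, j[rows] + 1]
    den = fm - 2 * f0 + fp
    ok = den < 0
    r_wall[rows[ok]] += step * np.clip(0.5 * (fm - fp)[ok] / den[ok], -0.5, 0.5)
    if exclude_arc is not None:
        lo, hi = exclude_arc
        deg = np.rad2deg(thetas)
        span = (hi - lo) % 360.0
        inside = ((deg - lo) % 360.0) <= span
        thetas = thetas[~inside]
        r_wall = r_wall[~inside]
    # luminal MIP tails and seam gaps produce sparse inward/outward
    # outliers: keep only radii near the median wall radius before fitting
    med = np.median(r_wall)
    near = np.abs(r_wall - med) <= 1.8
    if near.sum() >= 6:
        thetas = thetas[near]
        r_wall = r_wall[near]
    pts = np.stack([r_wall * np.cos(thetas), r_wall * np.sin(thetas)], axis=1)
    # robust two-pass fit against remaining outliers
    fit = fit_ellipse(pts)
    th = np.deg2rad(fit.orientation_deg)
    rot = np.array([[np.cos(th), np.sin(th)], [-np.sin(th), np.cos(th)]])
    q = (pts - fit.center) @ rot.T
    ang = np.arctan2(q[:, 1] / fit.b, q[:, 0] / fit.a)
    model_r = np.hypot(fit.a * np.cos(ang), fit.b * np.sin(ang))
    resid = np.abs(np.hypot(q[:, 0], q[:, 1]) - model_r)
    keep = resid <= np.quantile(resid, 0.85)
    if keep.sum() >= 6:
        fit = fit_ellipse(pts[keep])
    return fit.ellipticity_percent


# ---------------------------------------------------------------------------
# symmetrization
# ---------------------------------------------------------------------------


@dataclass
class SymmetryParams:
    """Externally supplied 9-fold geometry for one axial domain."""

    blade_radius: float  # axis -> A-tubule centre, nm
    blade_tilt: float  # degrees from the local tangent, outward positive
    domain: str = "proximal"
    n: int = 9
    center_offset: float = 22.0  # A-tubule centre -> segment centre, nm

    def __post_init__(self):
        if self.n != 9:
            raise ValueError("centriole symmetry is 9-fold")
        if self.blade_radius <= 0:
            raise ValueError("blade radius must be positive")

    def gamma(self) -> float:
        """In-plane blade angle of the reference frame (degrees)."""
        return particle_frame_gamma(
            self.blade_radius, self.blade_tilt, self.center_offset
        )

    def azimuth_offset(self) -> float:
        """Segment-centre azimuth ahead of the A-centre azimuth (degrees)."""
        return (90.0 - self.blade_tilt) - self.gamma()

    def a_center_in_reference(self) -> np.ndarray:
        """Position of the A-tubule centre in the reference frame."""
        g = np.deg2rad(self.gamma())
        return -self.center_offset * np.array([np.cos(g), np.sin(g), 0.0])


@dataclass
class EnsembleModel:
    """Symmetrized whole-centriole density with its blade poses."""

    volume: DensityVolume
    params: SymmetryParams
    blade_centers: np.ndarray  # (9, 3) segment-centre positions, nm
    blade_frames: np.ndarray  # (9, 3, 3) reference -> ensemble rotations
    blade_axis_angles: np.ndarray  # (9,) world angle of the blade long axis


def symmetrize(
    blade_average,
    params: SymmetryParams,
    box: int | tuple[int, int, int] = 144,
    voxel_size: float | None = None,
) -> EnsembleModel:
    """Place the blade average at nine 40-degree azimuths.

    The blade (in its reference frame, x outward radial) is positioned so
    its A-tubule centre sits at ``blade_radius`` and summed into an
    axis-centred volume; the result is invariant under 40-degree rotation
    by construction.
    """
    if isinstance(blade_average, (AverageMap, DensityVolume)):
        grid = np.asarray(blade_average.grid, float)
        bv = blade_average.voxel_size
    else:
        grid = np.asarray(blade_average, float)
        bv = voxel_size
        if bv is None:
            raise ValueError("voxel_size required for a bare array")
    box = (box, box, box) if np.isscalar(box) else tuple(box)
    out_voxel = bv
    if max(grid.shape) * bv > max(box) * out_voxel:
        raise ValueError("blade box larger than the ensemble box")
    vol = np.zeros(box, np.float32)
    bc = (np.array(grid.shape) - 1) / 2.0
    oc = (np.array(box) - 1) / 2.0
    centers, frames, axes = [], [], []
    a_ref = params.a_center_in_reference()
    dphi = np.deg2rad(params.azimuth_offset())
    for kk in range(params.n):
        phi = np.deg2rad(40.0 * kk)
        psi = phi + dphi  # reference-frame azimuth at the segment centre
        rk = np.array(
            [
                [np.cos(psi), -np.sin(psi), 0.0],
                [np.sin(psi), np.cos(psi), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        p_a = params.blade_radius * np.array([np.cos(phi), np.sin(phi), 0.0])
        p_part = p_a - rk @ a_ref
        # ensemble(w) += blade(R^-1 (w - p)); sampling matrix R^-1
        mat = rk.T
        offset = bc - mat @ (oc + p_part / out_voxel)
        vol += ndimage.affine_transform(
            grid, mat, offset=offset, order=1, mode="constant", cval=0.0,
            output_shape=box,
        ).astype(np.float32)
        centers.append(p_part)
        frames.append(rk)
        axes.append(np.rad2deg(phi) + 90.0 - params.blade_tilt)
    return EnsembleModel(
        volume=DensityVolume(vol, out_voxel,
                             origin=-out_voxel * np.array(box) / 2.0),
        params=params,
        blade_centers=np.array(centers),
        blade_frames=np.array(frames),
        blade_axis_angles=np.array(axes),
    )


def measure_diameter(ensemble: EnsembleModel, threshold_fraction: float = 0.2) -> float:
    """Outer-envelope diameter of the symmetrized ensemble.

    The density is averaged along the axis (z-uniform blades, so this
    also suppresses noise), lightly smoothed, thresholded at
    ``threshold_fraction * max``, and the diameter of the circumscribing
    circle (twice the maximal above-threshold radial extent) is returned.
    With odd 9-fold symmetry no diameter chord joins two blade tips, so
    the circumscribing circle is the natural tip-to-tip envelope measure.
    """
    grid = ensemble.volume.grid
    voxel = ensemble.volume.voxel_size
    proj = ndimage.gaussian_filter(grid.mean(axis=2).astype(float), 1.0)
    thr = threshold_fraction * proj.max()
    if not (proj > thr).any():
        raise ValueError("thresholded density is empty")
    nx, ny = proj.shape
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    thetas = np.deg2rad(np.arange(0.0, 360.0, 1.0))
    radii = np.arange(0.0, min(cx, cy), 0.25)
    xs = cx + radii[None, :] * np.cos(thetas)[:, None]
    ys = cy + radii[None, :] * np.sin(thetas)[:, None]
    vals = ndimage.map_coordinates(
        proj, np.stack([xs, ys]), order=1, mode="constant", cval=0.0
    )
    above_r = vals > thr
    r_out = np.where(above_r.any(axis=1),
                     radii[above_r.shape[1] - 1 - np.argmax(above_r[:, ::-1], axis=1)],
                     0.0)
    return float(2.0 * r_out.max() * voxel)


# ---------------------------------------------------------------------------
# blade tilt
# ---------------------------------------------------------------------------


def measure_blade_tilt(obj, points: np.ndarray | None = None) -> float:
    """Mean blade-tilt angle (degrees from the local tangent).

    For an :class:`EnsembleModel` the tilt follows from the stored blade
    axis directions and azimuths.  For a :class:`CrossSection` the local
    tangent comes from an ellipse fitted to the rod-mean points, so the
    measurement is meaningful on flattened centrioles too.
    """
    if isinstance(obj, EnsembleModel):
        tilts = []
        for kk in range(obj.params.n):
            phi = 40.0 * kk
            tilts.append(90.0 + phi - obj.blade_axis_angles[kk])
        t = np.array(tilts)
        t = (t + 180.0) % 360.0 - 180.0
        return float(t.mean())
    cs: CrossSection = obj
    pts = rod_mean_points(cs) if points is None else points
    fit = fit_ellipse(pts)
    tilts = []
    for p, ang in zip(cs.points, cs.blade_angles):
        t = fit.tangent_at(p)
        n = fit.normal_at(p)
        d = np.array([np.cos(np.deg2rad(ang)), np.sin(np.deg2rad(ang))])
        if np.dot(d, t) < 0:  # blade axis direction is tangent-aligned
            d = -d
        tilt = np.rad2deg(np.arctan2(np.dot(d, n), np.dot(d, t)))
        tilts.append(tilt)
    return float(np.mean(tilts))


def tilt_change(proximal, distal) -> float:
    """Inward-positive blade-tilt change from proximal to distal.

    Arguments may be measured tilt angles (outward positive) or objects
    accepted by :func:`measure_blade_tilt`.
    """
    tp = proximal if np.isscalar(proximal) else measure_blade_tilt(proximal)
    td = distal if np.isscalar(distal) else measure_blade_tilt(distal)
    return float(tp - td)


# ---------------------------------------------------------------------------
# composite rebuild
# ---------------------------------------------------------------------------


def rebuild_composite(
    particles,
    class_maps: dict,
    tomo_shape: tuple[int, int, int],
    voxel_size: float,
    origin=None,
):
    """Fit each particle's class map back at its refined pose.

    Overlaps are averaged; returns ``(DensityVolume, runs)`` where runs is
    a DataFrame of consecutive same-class segment runs per rod.
    """
    import pandas as pd

    origin = np.zeros(3) if origin is None else np.asarray(origin, float)
    out = np.zeros(tomo_shape, np.float32)
    wsum = np.zeros(tomo_shape, np.float32)
    for p in particles:
        if p.class_label is None:
            raise ValueError(f"particle {p.particle_id} is unclassified")
        if p.class_label not in class_maps:
            raise ValueError(f"missing class map for label {p.class_label}")
        cmap = np.asarray(class_maps[p.class_label], np.float32)
        box = np.array(cmap.shape)
        r = p.rotation()
        c_vox = (np.asarray(p.center, float) - origin) / voxel_size - 0.5
        half = int(np.ceil(box.max() * np.sqrt(3) / 2.0))
        lo = np.maximum(np.floor(c_vox).astype(int) - half, 0)
        hi = np.minimum(np.floor(c_vox).astype(int) + half + 1, np.array(tomo_shape))
        if np.any(hi <= lo):
            continue
        ii = np.indices(tuple(hi - lo)).reshape(3, -1).astype(float)
        ii += lo[:, None]
        rel = ii - c_vox[:, None]
        coords = r.T @ rel + (box[:, None] - 1) / 2.0
        vals = ndimage.map_coordinates(cmap, coords, order=1, mode="constant", cval=0.0)
        wts = ndimage.map_coordinates(
            np.ones(cmap.shape, np.float32), coords, order=1, mode="constant", cval=0.0
        )
        sl = tuple(slice(a, b) for a, b in zip(lo, hi))
        out[sl] += (vals * wts).reshape(tuple(hi - lo))
        wsum[sl] += wts.reshape(tuple(hi - lo))
    with np.errstate(invalid="ignore"):
        comp = np.where(wsum > 1e-6, out / np.maximum(wsum, 1e-6), 0.0)
    rows = []
    for rid in sorted({p.rod_id for p in particles}):
        rod_parts = sorted([p for p in particles if p.rod_id == rid], key=lambda q: q.s)
        run_label, run_len, run_start = None, 0, 0.0
        for p in rod_parts:
            if p.class_label == run_label:
                run_len += 1
            else:
                if run_label is not None:
                    rows.append(dict(rod_id=rid, class_label=run_label,
                                     run_length=run_len, start_s=run_start))
                run_label, run_len, run_start = p.class_label, 1, p.s
        rows.append(dict(rod_id=rid, class_label=run_label,
                         run_length=run_len, start_s=run_start))
    runs = pd.DataFrame(rows)
    return DensityVolume(comp.astype(np.float32), voxel_size, origin=origin), runs
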