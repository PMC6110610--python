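"""Rod tracing and disc sub-volume extraction.

Particles are 24 nm discs extracted along each microtubule rod.  The
extraction frame puts the rod tangent on the particle z axis and the
outward radial direction from the centriole axis on the particle x axis;
orientations are intrinsic ZYZ Euler angles (rot, tilt, psi, degrees)
mapping the reference frame into the tomogram frame.  Pose refinements
are stored as a residual rotation/shift relative to the extraction pose,
so raw sub-volumes never need re-extraction during iterative alignment.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation
from skimage.feature import peak_local_max

from .errors import (
    OrientationDegenerateError,
    OutOfBoundsError,
    RodDeficitError,
)
from .tomo_sim import MOUNT_ROTATION, DensityVolume


# ---------------------------------------------------------------------------
# rods
# ---------------------------------------------------------------------------


@dataclass
class Rod:
    """Polyline trace of one microtubule rod (tomogram frame, nm)."""

    rod_id: int
    control_points: np.ndarray  # (n, 3)
    centriole_id: int = 0

    def __post_init__(self):
        self.control_points = np.atleast_2d(np.asarray(self.control_points, float))
        if len(self.control_points) < 2:
            raise ValueError("a rod needs at least two control points")

    def _arclengths(self) -> np.ndarray:
        d = np.linalg.norm(np.diff(self.control_points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(d)])

    @property
    def length(self) -> float:
        return float(self._arclengths()[-1])

    def point_at(self, s: float) -> np.ndarray:
        t = self._arclengths()
        return np.array(
            [np.interp(s, t, self.control_points[:, k]) for k in range(3)]
        )

    def tangent_at(self, s: float) -> np.ndarray:
        t = self._arclengths()
        i = int(np.clip(np.searchsorted(t, s) - 1, 0, len(t) - 2))
        d = self.control_points[i + 1] - self.control_points[i]
        n = np.linalg.norm(d)
        if n == 0:
            raise OrientationDegenerateError("zero-length rod segment")
        return d / n


# ---------------------------------------------------------------------------
# particles
# ---------------------------------------------------------------------------


@dataclass
class Particle:
    """One disc sub-volume's metadata and pose.

    ``euler0``/``center0`` are the extraction pose; ``euler``/``center``
    the current refined pose with ``shift`` the particle-frame residual
    translation (nm), so ``center = center0 + R0 @ shift``.
    """

    particle_id: int
    rod_id: int
    s: float  # axial position (nm) from the proximal end
    center0: np.ndarray
    euler0: np.ndarray  # ZYZ degrees, reference -> tomogram
    centriole_id: int = 0
    euler: np.ndarray | None = None
    shift: np.ndarray = field(default_factory=lambda: np.zeros(3))
    score: float | None = None
    class_label: int | None = None
    half_set: int = -1
    domain: str | None = None  # carried ground-truth labels, if known
    partial_b: bool = False

    def __post_init__(self):
        self.center0 = np.asarray(self.center0, float)
        self.euler0 = np.asarray(self.euler0, float)
        self.shift = np.asarray(self.shift, float)
        if self.euler is None:
            self.euler = self.euler0.copy()
        self.euler = np.asarray(self.euler, float)

    # pose algebra -----------------------------------------------------
    def rotation0(self) -> np.ndarray:
        return Rotation.from_euler("ZYZ", self.euler0, degrees=True).as_matrix()

    def rotation(self) -> np.ndarray:
        return Rotation.from_euler("ZYZ", self.euler, degrees=True).as_matrix()

    def residual_rotation(self) -> np.ndarray:
        """S with R = R0 @ S (identity before any refinement)."""
        return self.rotation0().T @ self.rotation()

    @property
    def center(self) -> np.ndarray:
        return self.center0 + self.rotation0() @ self.shift

    def with_refinement(self, angle_offset, shift_nm, score) -> "Particle":
        """Compose a grid-search result (relative to the current pose)."""
        q = self.copy()
        s_cur = self.residual_rotation()
        d_s = Rotation.from_euler("ZYZ", angle_offset, degrees=True).as_matrix()
        s_new = s_cur @ d_s
        q.euler = Rotation.from_matrix(self.rotation0() @ s_new).as_euler(
            "ZYZ", degrees=True
        )
        q.shift = self.shift + s_cur @ np.asarray(shift_nm, float)
        q.score = score
        return q

    def copy(self) -> "Particle":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# rod tracing
# ---------------------------------------------------------------------------


def rods_from_truth(truth, centriole_id: int = 0) -> list[Rod]:
    """Rebuild rods exactly from a ground-truth segment table.

    Truth coordinates are model-frame nm; rods are returned in the
    tomogram frame (model mounted with its axis along the tilt axis).
    The polyline is extended by half the segment spacing at both ends so
    arc-length sampling reproduces the table's s positions.
    """
    rods = []
    for rod_id, grp in truth.groupby("rod_id"):
        grp = grp.sort_values("s_nm")
        pts_model = grp[["x_nm", "y_nm", "z_nm"]].to_numpy()
        if len(pts_model) >= 2:
            half = float(grp.s_nm.iloc[0])
            t0 = pts_model[1] - pts_model[0]
            t0 = t0 / np.linalg.norm(t0)
            t1 = pts_model[-1] - pts_model[-2]
            t1 = t1 / np.linalg.norm(t1)
            pts_model = np.vstack(
                [pts_model[0] - half * t0, pts_model, pts_model[-1] + half * t1]
            )
        pts = pts_model @ MOUNT_ROTATION.T
        rods.append(Rod(rod_id=int(rod_id), control_points=pts, centriole_id=centriole_id))
    return rods


def trace_rods(
    tomogram: DensityVolume,
    mode: str = "auto",
    truth=None,
    n_expected: int = 9,
    lowpass_nm: float = 10.0,
    slab_nm: float = 24.0,
    min_separation_nm: float = 25.0,
    max_link_nm: float = 16.0,
) -> list[Rod]:
    """Trace the nine microtubule rods of a centriole.

    ``from_truth`` rebuilds rods from the ground-truth table.  ``auto``
    low-passes the tomogram, thresholds at mean + 2 SD, finds blade peaks
    in cross-section slabs along the tilt axis (the centriole axis in the
    mounting convention), links them into tracks and keeps the
    ``n_expected`` longest; fewer tracks raise :class:`RodDeficitError`.
    """
    if mode == "from_truth":
        if truth is None:
            raise ValueError("from_truth mode requires a ground-truth table")
        return rods_from_truth(truth)
    if mode != "auto":
        raise ValueError(f"unknown tracing mode {mode!r}")
    g = np.asarray(tomogram.grid, float)
    if g.size == 0 or not np.any(g != g.flat[0]):
        raise RodDeficitError(0, n_expected)
    voxel = tomogram.voxel_size
    sigma = lowpass_nm / 2.355 / voxel  # FWHM ~ lowpass
    sm = ndimage.gaussian_filter(g, sigma)
    slab = max(int(round(slab_nm / voxel)), 1)
    ny = g.shape[1]
    # seeds: blade peaks of the whole-length projection (rods are roughly
    # axis-parallel, so the projection concentrates each blade)
    glob = sm.mean(axis=1)
    thr = glob.mean() + 2.0 * glob.std()
    min_sep = max(int(round(min_separation_nm / voxel)), 1)
    peaks = peak_local_max(glob, min_distance=min_sep, threshold_abs=thr,
                           exclude_border=False)
    if len(peaks) < n_expected:
        raise RodDeficitError(len(peaks), n_expected)
    vals = glob[peaks[:, 0], peaks[:, 1]]
    seeds = peaks[np.argsort(vals)[::-1][:n_expected]].astype(float)
    # per slab: follow each seed by the local maximum in a window around
    # the track's previous position (tolerates curvature and flattening)
    win = max(int(round(max_link_nm / voxel)), 2)
    tracks = [[] for _ in range(n_expected)]
    last = [s.copy() for s in seeds]
    for y0 in range(0, ny - slab + 1, slab):
        sect = sm[:, y0 : y0 + slab, :].max(axis=1)
        s_thr = sect.mean() + 1.0 * sect.std()
        ymid = y0 + (slab - 1) / 2.0
        for k in range(n_expected):
            x0, z0 = last[k]
            xl = int(np.clip(round(x0) - win, 0, sect.shape[0] - 1))
            xh = int(np.clip(round(x0) + win + 1, 1, sect.shape[0]))
            zl = int(np.clip(round(z0) - win, 0, sect.shape[1] - 1))
            zh = int(np.clip(round(z0) + win + 1, 1, sect.shape[1]))
            local = sect[xl:xh, zl:zh]
            j = np.unravel_index(np.argmax(local), local.shape)
            if local[j] < s_thr:
                continue  # rod not visible in this slab
            pos = np.array([xl + j[0], zl + j[1]], float)
            last[k] = pos
            tracks[k].append(np.array([pos[0], ymid, pos[1]]))
    n_slabs = (ny - slab) // slab + 1
    good = [t for t in tracks if len(t) >= max(2, int(0.6 * n_slabs))]
    if len(good) < n_expected:
        raise RodDeficitError(len(good), n_expected)
    # order rods by azimuth around the traced centre for stable ids
    centers = [np.mean(t, axis=0) for t in good]
    cx = np.mean([c[0] for c in centers])
    cz = np.mean([c[2] for c in centers])
    azim = [np.arctan2(c[2] - cz, c[0] - cx) for c in centers]
    rods = []
    for rid, i in enumerate(np.argsort(azim), start=1):
        pts_nm = tomogram.origin + (np.array(good[i]) + 0.5) * voxel
        rods.append(Rod(rod_id=rid, control_points=pts_nm))
    return rods


# ---------------------------------------------------------------------------
# segment sampling and orientations
# ---------------------------------------------------------------------------


def sample_segments(rod: Rod, step: float = 24.0):
    """Arc-length sample every ``step`` nm starting at ``step/2``.

    Returns a list of ``(s, centre, tangent)``; empty if the rod is
    shorter than one step.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    length = rod.length
    out = []
    s = step / 2.0
    while s < length and length >= step:
        out.append((s, rod.point_at(s), rod.tangent_at(s)))
        s += step
    return out


def orientation_from_geometry(center, tangent, axis_point, axis_dir,
                              radial: np.ndarray | None = None):
    """Reference->tomogram rotation: z on the tangent, x outward radial.

    ``radial`` overrides the axis-derived radial direction (e.g. the
    outward normal of an ellipse fitted to flattened rod positions).
    """
    z = np.asarray(tangent, float)
    z = z / np.linalg.norm(z)
    if radial is None:
        v = np.asarray(center, float) - np.asarray(axis_point, float)
        ad = np.asarray(axis_dir, float)
        ad = ad / np.linalg.norm(ad)
        v = v - np.dot(v, ad) * ad  # radial component
    else:
        v = np.asarray(radial, float)
    x = v - np.dot(v, z) * z
    n = np.linalg.norm(x)
    if n < 1e-6 or np.linalg.norm(v) < 1e-6:
        raise OrientationDegenerateError("tangent parallel to radial direction")
    x = x / n
    y = np.cross(z, x)
    return np.stack([x, y, z], axis=1)


def flattening_aware_radial(rods, axis_point, axis_dir):
    """Per-point radial-direction function from the rod-centroid ellipse.

    Fits an ellipse to the in-plane rod centroids; the returned callable
    maps a 3-D point to the outward ellipse normal at its in-plane
    position -- on flattened centrioles this tracks the blade frames far
    better than the axis-radial direction, and reduces exactly to it on
    circular ones.  Returns ``None`` when there are too few rods to fit.
    """
    from .geometry import fit_ellipse  # local import; no cycle at module load

    ad = np.asarray(axis_dir, float)
    ad = ad / np.linalg.norm(ad)
    seed = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(seed, ad)) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    e1 = seed - np.dot(seed, ad) * ad
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(ad, e1)
    pts = []
    for rod in rods:
        c = rod.control_points.mean(axis=0) - np.asarray(axis_point, float)
        pts.append([np.dot(c, e1), np.dot(c, e2)])
    pts = np.array(pts)
    if len(pts) < 6:
        return None
    try:
        fit = fit_ellipse(pts)
    except Exception:
        return None

    def radial(point3d):
        rel = np.asarray(point3d, float) - np.asarray(axis_point, float)
        p2 = np.array([np.dot(rel, e1), np.dot(rel, e2)])
        n2 = fit.normal_at(p2)
        return n2[0] * e1 + n2[1] * e2

    return radial


def initial_orientations(rod: Rod, axis_point, axis_dir, step: float = 24.0,
                         radial_fn=None):
    """ZYZ Euler angles (degrees, in [-180, 180)) for each segment."""
    eulers = []
    for s, c, t in sample_segments(rod, step):
        radial = radial_fn(c) if radial_fn is not None else None
        r = orientation_from_geometry(c, t, axis_point, axis_dir, radial=radial)
        e = Rotation.from_matrix(r).as_euler("ZYZ", degrees=True)
        e = (e + 180.0) % 360.0 - 180.0
        eulers.append((s, c, e))
    return eulers


def make_particles(
    rods: list[Rod],
    axis_point,
    axis_dir,
    step: float = 24.0,
    centriole_id: int = 0,
    truth=None,
    flattening_aware: bool = True,
) -> list[Particle]:
    """Build the particle table from traced rods.

    With ``flattening_aware`` the initial x axes follow the outward
    normals of an ellipse fitted to the rod centroids instead of the
    straight axis-radial direction (identical for circular centrioles).
    If a ground-truth table is given, each particle inherits the domain
    and partial-B labels of the matching (rod, s) row.
    """
    radial_fn = (
        flattening_aware_radial(rods, axis_point, axis_dir)
        if flattening_aware
        else None
    )
    particles = []
    pid = 0
    for rod in rods:
        for s, c, e in initial_orientations(rod, axis_point, axis_dir, step,
                                            radial_fn=radial_fn):
            p = Particle(
                particle_id=pid,
                rod_id=rod.rod_id,
                s=s,
                center0=c,
                euler0=e,
                centriole_id=centriole_id,
            )
            if truth is not None:
                m = truth[
                    (truth.rod_id == rod.rod_id) & (np.abs(truth.s_nm - s) < step / 2)
                ]
                if len(m):
                    p.domain = m.iloc[0]["domain"]
                    p.partial_b = bool(m.iloc[0]["partial_b"])
            particles.append(p)
            pid += 1
    return particles


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------


def extract_subvolume(
    tomogram: DensityVolume,
    center_nm,
    euler,
    box: int | tuple[int, int, int],
    voxel_size: float | None = None,
) -> np.ndarray:
    """Resample the tomogram into the particle frame by trilinear
    interpolation; out-of-bounds voxels are filled with the tomogram mean.

    ``subvol(x) = tomo(center + R x)`` with R the ZYZ rotation; the rod
    axis therefore lies along the sub-volume z axis.
    """
    box = (box, box, box) if np.isscalar(box) else tuple(box)
    vs = voxel_size or tomogram.voxel_size
    center_vox = tomogram.nm_to_voxel(center_nm)
    if np.any(center_vox < -0.5) or np.any(
        center_vox > np.array(tomogram.grid.shape) - 0.5
    ):
        raise OutOfBoundsError(f"center {center_nm} outside the tomogram")
    r = Rotation.from_euler("ZYZ", np.asarray(euler, float), degrees=True).as_matrix()
    bc = (np.array(box) - 1) / 2.0
    ii = np.indices(box).reshape(3, -1).astype(float)
    rel = (ii - bc[:, None]) * vs  # particle-frame nm
    coords = (r @ rel) / tomogram.voxel_size + center_vox[:, None]
    vals = ndimage.map_coordinates(
        np.asarray(tomogram.grid, np.float32),
        coords,
        order=1,
        mode="constant",
        cval=float(tomogram.grid.mean()),
    )
    return vals.reshape(box).astype(np.float32)


def extract_particles(tomogram, particles, box, voxel_size=None):
    """Extract all particle sub-volumes at their extraction poses."""
    return np.stack(
        [
            extract_subvolume(tomogram, p.center0, p.euler0, box, voxel_size)
            for p in particles
        ]
    )


# ---------------------------------------------------------------------------
# curation
# ---------------------------------------------------------------------------


def _circular_median(angles_deg: np.ndarray) -> float:
    """Deterministic circular median: the sample minimizing the summed
    circular distance (first such sample on ties)."""
    a = np.asarray(angles_deg, float)
    d = np.abs((a[:, None] - a[None, :] + 180.0) % 360.0 - 180.0)
    return float(a[int(np.argmin(d.sum(axis=1)))])


def circular_distance(a, b):
    return np.abs((np.asarray(a) - np.asarray(b) + 180.0) % 360.0 - 180.0)


def curate_consistency(
    particles: list[Particle],
    max_angle_dev: float = 15.0,
    max_shift_dev: float = 6.0,
):
    """Reject particles deviating from their rod's median pose.

    Per rod, the circular median of each Euler angle and the median shift
    are computed; particles whose angular deviation exceeds
    ``max_angle_dev`` (any angle) or whose shift deviates by more than
    ``max_shift_dev`` (vector norm) are rejected.  Returns
    ``(kept, rejected)``.
    """
    kept, rejected = [], []
    by_rod: dict[int, list[Particle]] = {}
    for p in particles:
        by_rod.setdefault((p.centriole_id, p.rod_id), []).append(p)
    for group in by_rod.values():
        eulers = np.array([g.euler for g in group])
        shifts = np.array([g.shift for g in group])
        med_e = np.array([_circular_median(eulers[:, k]) for k in range(3)])
        med_s = np.median(shifts, axis=0)
        for g, e, s in zip(group, eulers, shifts):
            ang_dev = circular_distance(e, med_e).max()
            shift_dev = np.linalg.norm(s - med_s)
            if ang_dev > max_angle_dev or shift_dev > max_shift_dev:
                rejected.append(g)
            else:
                kept.append(g)
    return kept, rejected
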