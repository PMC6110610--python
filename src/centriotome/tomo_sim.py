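"""Tomographic simulation: rasterization, tilt series, WBP, wedge masks.

Geometry conventions (fixed once, used everywhere):

* Volume arrays are indexed ``(x, y, z)``; the tilt axis is the second
  array axis (y) and the untilted beam runs along the third (z).
* A tilt series rotates the specimen right-handedly about +y; the image at
  tilt ``theta`` is the beam-direction line integral of the rotated volume.
* In Fourier space a single-axis scheme over ``[theta_min, theta_max]``
  samples the directions whose Friedel-folded in-plane angle
  ``-atan2(fz, fx)`` lies inside the tilt range (the tilted central
  sections are perpendicular to the beam); the unsampled complement
  around the beam axis is the missing wedge.
* Models are built with the centriole axis along model-z; when mounted
  into a tomogram the model is rotated so its axis lies along the tilt
  axis (ice-sheet geometry, axis perpendicular to the beam).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .errors import InvalidSpecError
from .model_builder import BladeModel, CentrioleModel

#: model frame -> tomogram frame: -90 deg about x maps the model axis (z)
#: onto the tomogram tilt axis (y)
MOUNT_ROTATION = Rotation.from_euler("x", -90, degrees=True).as_matrix()


def default_tilt_angles(step: float = 1.0, max_tilt: float = 60.0) -> np.ndarray:
    """Single-axis scheme +max..-max, descending, inclusive."""
    n = int(round(2 * max_tilt / step)) + 1
    return np.linspace(max_tilt, -max_tilt, n)


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------


@dataclass
class DensityVolume:
    """Scalar density on a regular grid; voxel size in nm.

    ``origin`` is the nm offset of the corner of voxel (0, 0, 0) from the
    model frame origin; the centre of voxel ``i`` is at
    ``origin + (i + 0.5) * voxel_size``.
    """

    grid: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        if self.voxel_size <= 0:
            raise ValueError("voxel size must be positive")
        self.origin = np.asarray(self.origin, float)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.grid.shape

    def center_nm(self) -> np.ndarray:
        return self.origin + self.voxel_size * np.asarray(self.grid.shape) / 2.0

    def nm_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        return (np.asarray(xyz, float) - self.origin) / self.voxel_size - 0.5


def _as_blobs(model, mount: bool = False):
    if isinstance(model, CentrioleModel):
        pos, sig, mas = model.all_blobs()
    elif isinstance(model, BladeModel):
        pos, sig, mas = model.positions, model.sigmas, model.masses
    else:
        pos, sig, mas = model
        pos = np.asarray(pos, float)
        sig = np.asarray(sig, float)
        mas = np.asarray(mas, float)
    if mount:
        pos = pos @ MOUNT_ROTATION.T
    return pos, sig, mas


def rasterize(
    model,
    voxel_size: float,
    box: tuple[int, int, int],
    origin: np.ndarray | None = None,
    mount: bool = False,
) -> DensityVolume:
    """Render Gaussian blobs onto a grid.

    Each blob contributes an analytic isotropic Gaussian (unit integral
    times its mass, in density units of mass/nm^3) evaluated on voxel
    centres within 4 sigma.  ``model`` may be a CentrioleModel, BladeModel
    or a ``(positions, sigmas, masses)`` tuple; ``mount=True`` applies the
    model->tomogram mounting rotation first.  If no origin is given the
    blob centroid bounding box is centred in the grid; blobs outside are
    clipped with a warning.
    """
    if voxel_size <= 0:
        raise ValueError("voxel size must be positive")
    box = tuple(int(b) for b in box)
    pos, sig, mas = _as_blobs(model, mount=mount)
    if origin is None:
        lo = pos.min(axis=0)
        hi = pos.max(axis=0)
        center = (lo + hi) / 2.0
        origin = center - voxel_size * np.asarray(box) / 2.0
        if np.any(hi - lo > voxel_size * np.asarray(box)):
            warnings.warn("box does not contain the whole model; clipping")
    origin = np.asarray(origin, float)
    grid = np.zeros(box, dtype=np.float32)
    # voxel-centre coordinate of index 0 along each axis
    base = origin + 0.5 * voxel_size
    inv = 1.0 / voxel_size
    for p, s, m in zip(pos, sig, mas):
        half = 4.0 * s
        i0 = np.maximum(np.ceil((p - half - base) * inv), 0).astype(int)
        i1 = np.minimum(np.floor((p + half - base) * inv), np.array(box) - 1).astype(int)
        if np.any(i1 < i0):
            continue
        amp = m / ((2.0 * np.pi) ** 1.5 * s**3)
        gs = []
        for ax in range(3):
            c = base[ax] + voxel_size * np.arange(i0[ax], i1[ax] + 1)
            gs.append(np.exp(-((c - p[ax]) ** 2) / (2.0 * s**2)))
        blob = amp * gs[0][:, None, None] * gs[1][None, :, None] * gs[2][None, None, :]
        grid[i0[0] : i1[0] + 1, i0[1] : i1[1] + 1, i0[2] : i1[2] + 1] += blob
    return DensityVolume(grid=grid, voxel_size=voxel_size, origin=origin)


# ---------------------------------------------------------------------------
# tilt series
# ---------------------------------------------------------------------------


@dataclass
class TiltSeries:
    """Projection images (one per tilt angle) with fixed in-plane tilt axis."""

    images: np.ndarray  # (n_angles, nx, ny)
    tilt_angles: np.ndarray  # degrees
    pixel_size: float  # nm

    def __post_init__(self):
        self.images = np.asarray(self.images)
        self.tilt_angles = np.asarray(self.tilt_angles, float)
        if len(self.images) != len(self.tilt_angles):
            raise ValueError("one image per tilt angle required")


def _tilt_matrix(theta_deg: float) -> np.ndarray:
    c = np.cos(np.deg2rad(theta_deg))
    s = np.sin(np.deg2rad(theta_deg))
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def project_tilt_series(volume: DensityVolume, angles) -> TiltSeries:
    """Line-integral projections of the volume along the tilted beam.

    The image at angle theta is the z-sum (times voxel size) of the volume
    rotated by -theta about the y axis, sampled with linear interpolation;
    theta = 0 reduces to the plain axial sum.
    """
    angles = np.atleast_1d(np.asarray(angles, float))
    if angles.size == 0:
        raise ValueError("empty tilt-angle list")
    if np.any(np.abs(angles) >= 90.0):
        raise ValueError("tilt angles must lie in (-90, 90)")
    g = np.ascontiguousarray(volume.grid, dtype=np.float32)
    nx, ny, nz = g.shape
    center = (np.array([nx, ny, nz]) - 1) / 2.0
    images = np.empty((len(angles), nx, ny), dtype=np.float32)
    for i, th in enumerate(angles):
        if abs(th) < 1e-12:
            images[i] = g.sum(axis=2) * volume.voxel_size
            continue
        rot = _tilt_matrix(-th)  # lab -> specimen sampling matrix
        offset = center - rot @ center
        rotated = ndimage.affine_transform(
            g, rot, offset=offset, order=1, mode="constant", cval=0.0
        )
        images[i] = rotated.sum(axis=2) * volume.voxel_size
    return TiltSeries(images=images, tilt_angles=angles, pixel_size=volume.voxel_size)


@dataclass
class NoiseSpec:
    """Additive white Gaussian image noise at a given signal-to-noise ratio.

    ``snr`` is the ratio of signal variance (over pixels inside the signal
    mask, pooled across the stack) to the added noise variance.
    """

    snr: float
    seed: int = 0
    mask_fraction: float = 0.05  # |pixel| > fraction * max defines the signal mask

    def __post_init__(self):
        if self.snr <= 0:
            raise InvalidSpecError("snr must be positive")


def add_noise(series: TiltSeries, noise: NoiseSpec) -> TiltSeries:
    """Add seeded white Gaussian noise scaled to the requested SNR."""
    rng = np.random.default_rng(noise.seed)
    imgs = series.images.astype(np.float32)
    mask = np.abs(imgs) > noise.mask_fraction * np.abs(imgs).max()
    signal_var = float(imgs[mask].var()) if mask.any() else float(imgs.var())
    sigma = np.sqrt(signal_var / noise.snr)
    noisy = imgs + rng.normal(0.0, sigma, imgs.shape).astype(np.float32)
    return TiltSeries(noisy, series.tilt_angles.copy(), series.pixel_size)


def reconstruct_wbp(series: TiltSeries, box_z: int, origin=None) -> DensityVolume:
    """Weighted back-projection with an exact ramp (|f|) filter.

    Projections are ramp-filtered along the axis perpendicular to the tilt
    axis and smeared back along their beam directions with linear
    interpolation.  The ramp zeroes each cross-section's 2-D DC term, so
    the per-slice means (the tilt-axis Fourier line, which every
    projection samples) are restored afterwards from the projections'
    column sums.  A noiseless point source reconstructs to a peak within
    one voxel of its true position.
    """
    if len(series.images) == 0:
        raise ValueError("tilt series has no images")
    shapes = {im.shape for im in series.images}
    if len(shapes) != 1:
        raise ValueError("mismatched image sizes in tilt series")
    n_ang = len(series.tilt_angles)
    nx, ny = series.images[0].shape
    nz = int(box_z)
    # ramp filter along x', zero-padded to avoid circular-convolution wrap
    npad = 2 * nx
    freqs = np.fft.rfftfreq(npad)
    padded = np.zeros((n_ang, npad, ny), dtype=np.float32)
    padded[:, :nx] = series.images
    fimgs = np.fft.irfft(
        np.fft.rfft(padded, axis=1) * freqs[None, :, None], n=npad, axis=1
    )[:, :nx].astype(np.float32)
    cx, cz = (nx - 1) / 2.0, (nz - 1) / 2.0
    xs = np.arange(nx) - cx
    zs = np.arange(nz) - cz
    X, Z = np.meshgrid(xs, zs, indexing="ij")  # (nx, nz)
    out = np.zeros((nx, ny, nz), dtype=np.float32)
    for img, th in zip(fimgs, series.tilt_angles):
        c = np.cos(np.deg2rad(th))
        s = np.sin(np.deg2rad(th))
        xl = c * X + s * Z + cx  # lab-frame detector coordinate
        i0 = np.floor(xl).astype(int)
        w = (xl - i0).astype(np.float32)
        valid0 = (i0 >= 0) & (i0 <= nx - 1)
        valid1 = (i0 + 1 >= 0) & (i0 + 1 <= nx - 1)
        i0c = np.clip(i0, 0, nx - 1)
        i1c = np.clip(i0 + 1, 0, nx - 1)
        # (nx, nz, ny) contributions via fancy indexing on the image rows
        contrib = (
            img[i0c] * ((1.0 - w) * valid0)[..., None]
            + img[i1c] * (w * valid1)[..., None]
        )
        out += contrib.transpose(0, 2, 1)
    out *= np.pi / (2.0 * n_ang)
    # restore per-slice means: the slice mass is the column sum of any
    # projection (take the average over the stack for noise suppression)
    mass_y = series.images.sum(axis=1).mean(axis=0) / series.pixel_size
    out += (mass_y / (nx * nz))[None, :, None] - out.mean(axis=(0, 2))[None, :, None]
    if origin is None:
        origin = np.zeros(3)
    return DensityVolume(out, series.pixel_size, origin=np.asarray(origin, float))


# ---------------------------------------------------------------------------
# wedge masks
# ---------------------------------------------------------------------------


@dataclass
class WedgeMask:
    """Fourier-domain sampling region of a single-axis tilt scheme.

    Evaluated analytically: a frequency direction passes iff its
    Friedel-folded (fx, fz) angle lies within [theta_min, theta_max].  An
    optional rotation (particle frame -> tomogram frame) re-orients the
    wedge into a particle's own frame without mask resampling.
    """

    theta_min: float = -60.0
    theta_max: float = 60.0

    def __post_init__(self):
        if self.theta_min >= self.theta_max:
            raise ValueError("theta_min must be below theta_max")

    @property
    def full(self) -> bool:
        return self.theta_min <= -90.0 and self.theta_max >= 90.0

    def passes(self, fx, fy, fz) -> np.ndarray:
        """Boolean pass condition for frequency components (tomogram frame).

        The central section at tilt theta is perpendicular to the beam
        ``(sin theta, 0, cos theta)``, so a direction is sampled iff
        ``fx sin(theta) + fz cos(theta) = 0`` for some theta in range,
        i.e. iff the Friedel-folded angle ``-atan2(fz, fx)`` lies inside
        ``[theta_min, theta_max]``; the unsampled complement around the
        beam axis is the missing wedge.
        """
        if self.full:
            return np.ones(np.broadcast(fx, fz).shape, dtype=bool)
        phi = np.rad2deg(np.arctan2(-np.asarray(fz), np.asarray(fx)))
        phi = np.where(phi > 90.0, phi - 180.0, phi)
        phi = np.where(phi <= -90.0, phi + 180.0, phi)
        ok = (phi >= self.theta_min) & (phi <= self.theta_max)
        # the pure tilt-axis line (fx = fz = 0) is always sampled
        return ok | ((np.asarray(fx) == 0) & (np.asarray(fz) == 0))

    def mask_array(
        self,
        shape: tuple[int, int, int],
        rotation: np.ndarray | None = None,
        rfft: bool = False,
    ) -> np.ndarray:
        """Binary mask on the (r)fft frequency grid of ``shape``.

        ``rotation`` maps particle-frame vectors into the tomogram frame
        (v_tomo = R @ u); the mask is evaluated at the rotated directions.
        """
        nx, ny, nz = shape
        fx = np.fft.fftfreq(nx)[:, None, None]
        fy = np.fft.fftfreq(ny)[None, :, None]
        fz = (np.fft.rfftfreq(nz) if rfft else np.fft.fftfreq(nz))[None, None, :]
        if rotation is None:
            gx = np.broadcast_to(fx, (nx, ny, fz.shape[2]))
            gz = np.broadcast_to(fz, (nx, ny, fz.shape[2]))
            return self.passes(gx, 0.0, gz)
        r = np.asarray(rotation, float)
        vx = r[0, 0] * fx + r[0, 1] * fy + r[0, 2] * fz
        vz = r[2, 0] * fx + r[2, 1] * fy + r[2, 2] * fz
        return self.passes(vx, 0.0, vz)


def wedge_mask(theta_min: float, theta_max: float, box) -> np.ndarray:
    """Binary full-FFT wedge mask array for a box (convenience wrapper)."""
    wm = WedgeMask(theta_min, theta_max)
    box = (box, box, box) if np.isscalar(box) else tuple(box)
    return wm.mask_array(box)


def apply_wedge(
    grid: np.ndarray,
    wedge: WedgeMask,
    rotation: np.ndarray | None = None,
) -> np.ndarray:
    """Zero the missing-wedge Fourier components of a real-space volume."""
    f = np.fft.rfftn(grid)
    m = wedge.mask_array(grid.shape, rotation=rotation, rfft=True)
    return np.fft.irfftn(f * m, s=grid.shape, axes=(0, 1, 2)).astype(grid.dtype, copy=False)


# ---------------------------------------------------------------------------
# segment dataset simulation
# ---------------------------------------------------------------------------


def simulate_segments(
    reference: DensityVolume,
    n: int,
    snr: float,
    wedge: WedgeMask,
    seed: int = 0,
    angle_jitter: tuple[float, float, float] = (3.0, 2.0, 3.0),
    shift_jitter: float = 2.0,
    azimuths: np.ndarray | None = None,
):
    """Simulate extracted disc sub-volumes of a blade reference.

    Each segment gets an extraction frame whose tomogram orientation is a
    rod-azimuth frame (rods perpendicular to the beam, wedge orientation
    varying with azimuth as it does around a real centriole), a small
    uniform true pose offset (ZYZ jitter in degrees, shift in nm), the
    azimuth-dependent missing wedge, and white noise at the requested SNR.

    Returns ``(subvols, frames, true_offsets)`` where ``frames`` is the
    (n, 3, 3) extraction rotation (particle frame -> tomogram) and
    ``true_offsets`` a record array with the jitter each alignment should
    recover (ZYZ degrees ``rot/tilt/psi`` and particle-frame shift nm).
    """
    rng = np.random.default_rng(seed)
    g = reference.grid.astype(np.float32)
    shape = g.shape
    center = (np.array(shape) - 1) / 2.0
    if azimuths is None:
        azimuths = rng.uniform(0.0, 360.0, n)
    subvols = np.empty((n,) + shape, dtype=np.float32)
    frames = np.empty((n, 3, 3))
    recs = []
    aj = np.asarray(angle_jitter, float)
    sig_mask = g > 0.1 * g.max()
    sig_var = float(g[sig_mask].var())
    noise_sigma = np.sqrt(sig_var / snr)
    for i in range(n):
        frame_model = Rotation.from_euler("ZYZ", [azimuths[i], 0.0, 0.0], degrees=True)
        r0 = MOUNT_ROTATION @ frame_model.as_matrix()
        d_ang = rng.uniform(-aj, aj)
        d_shift = rng.uniform(-shift_jitter, shift_jitter, 3)
        delta = Rotation.from_euler("ZYZ", d_ang, degrees=True).as_matrix()
        # subvol(x) = rho(delta^-1 (x - d)); sample coords = delta^-1 (x - d)
        mat = delta.T
        offset = center - mat @ (center + d_shift / reference.voxel_size)
        content = ndimage.affine_transform(
            g, mat, offset=offset, order=3, mode="constant", cval=0.0
        ).astype(np.float32)
        r_true = r0 @ delta
        filtered = apply_wedge(content, wedge, rotation=r_true)
        noisy = filtered + rng.normal(0.0, noise_sigma, shape).astype(np.float32)
        subvols[i] = noisy
        frames[i] = r0
        recs.append((d_ang[0], d_ang[1], d_ang[2], *d_shift))
    true_offsets = np.array(
        recs,
        dtype=[("rot", float), ("tilt", float), ("psi", float),
               ("sx", float), ("sy", float), ("sz", float)],
    )
    return subvols, frames, true_offsets
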