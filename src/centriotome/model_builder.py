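"""Parametric ground-truth centriole models.

A centriole is modelled as nine rigid microtubule *blades* (triplet, doublet
or partial-doublet) arranged with 9-fold symmetry around a straight axis.
Each blade is a set of Gaussian-blob density primitives: two blobs per
tubulin dimer per protofilament on a cylindrical lattice, plus a small set
of non-tubulin decorations (pinhead, A-C linker halves, A-A hinge, MIPs,
L-shaped linker, A09 foot) anchored to named protofilaments.

Coordinate conventions
----------------------
* Blade frame: ``z`` along the centriole axis (proximal -> distal), ``x``
  along the blade long axis (A-tubule -> C-tubule), ``y = z x x``.
  The A-tubule wall-centre circle is centred at the blade-frame origin.
* Reference (particle) frame: ``z`` along the rod, ``x`` along the outward
  radial direction from the centriole axis.  A blade whose long axis makes
  an angle ``tilt`` with the local tangent appears in the reference frame
  rotated in-plane by ``90 - tilt`` degrees.
* All physical coordinates are in nanometres.

The ground-truth segment table records, for every 24 nm disc along every
rod, the segment centre, its reference-frame orientation as intrinsic ZYZ
Euler angles (degrees, reference -> world), the axial domain label and the
partial-B flag.  It is the oracle against which picking, alignment and
geometry recovery are tested.
"""

from __future__ import annotations

import copy
import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy.spatial.transform import Rotation

from .errors import InvalidSpecError

# ---------------------------------------------------------------------------
# lattice / tubule / decoration specifications
# ---------------------------------------------------------------------------

DIMER_REPEAT_NM = 8.0
MONOMER_OFFSET_NM = 4.0

#: wall-centre radii (nm); chosen so a triplet spans ~60-65 nm
A_TUBULE_RADIUS_NM = 12.5
BC_TUBULE_RADIUS_NM = 11.5
#: wall overlap between attached tubules (nm)
WALL_OVERLAP_NM = 3.5
#: particle (segment) centre offset from the A-tubule centre, along the
#: blade long axis, so a box centred there covers the whole blade
BLADE_CENTER_OFFSET_NM = 22.0


@dataclass
class LatticeSpec:
    """Cylindrical protofilament lattice of one tubule."""

    n_pf: int
    tubule_radius: float
    dimer_repeat: float = DIMER_REPEAT_NM
    monomer_offset: float = MONOMER_OFFSET_NM
    rise_per_pf: float | None = None  # default: 3-start, 3*monomer_offset/n_pf
    seam_between: tuple[int, int] | None = None
    seam_extra_gap: float = 0.0  # degrees
    blob_sigma: float = 1.5

    def __post_init__(self):
        if self.n_pf < 1:
            raise InvalidSpecError(f"n_pf must be >= 1, got {self.n_pf}")
        if self.dimer_repeat <= 0:
            raise InvalidSpecError("dimer_repeat must be positive")
        if self.rise_per_pf is None:
            self.rise_per_pf = 3.0 * self.monomer_offset / self.n_pf
        if self.seam_between is not None:
            i, j = self.seam_between
            if not (1 <= i <= self.n_pf and 1 <= j <= self.n_pf):
                raise InvalidSpecError("seam_between indices out of range")
            if (j - i) % self.n_pf != 1:
                raise InvalidSpecError("seam_between must name adjacent protofilaments")

    def pf_angles(self, phase_deg: float = 0.0) -> np.ndarray:
        """Angular position (deg) of each protofilament, pf 1..n.

        Equal angular gaps, except an enlarged gap at the seam; the gap sum
        is exactly 360 degrees.  Angles decrease with protofilament index
        (protofilament numbering runs clockwise in the blade frame).
        """
        g = self.seam_extra_gap if self.seam_between else 0.0
        step = (360.0 - g) / self.n_pf
        ang = phase_deg - step * np.arange(self.n_pf, dtype=float)
        if self.seam_between:
            i, _ = self.seam_between
            # widen the gap *between* pf i and pf i+1
            ang[i:] -= g
        return ang


@dataclass
class TubuleSpec:
    """One tubule of a blade: label A/B/C, its lattice, and attachment."""

    label: str
    lattice: LatticeSpec
    attachment: tuple[str, tuple[int, int]] | None = None
    present_pfs: tuple[int, ...] | None = None  # None = all
    ellipticity_percent: float = 0.0  # area-preserving in-plane distortion
    ellipse_axis_deg: float = 0.0

    def __post_init__(self):
        if self.label not in ("A", "B", "C"):
            raise InvalidSpecError(f"unknown tubule label {self.label!r}")
        if self.label == "A" and self.attachment is not None:
            raise InvalidSpecError("A-tubule must not have an attachment")
        if self.label in ("B", "C") and self.attachment is None:
            raise InvalidSpecError(f"{self.label}-tubule requires an attachment")
        if self.present_pfs is not None:
            pfs = tuple(self.present_pfs)
            if len(pfs) == 0:
                raise InvalidSpecError("present_pfs must be non-empty")
            if not _cyclic_contiguous(pfs, self.lattice.n_pf):
                raise InvalidSpecError("present_pfs must be contiguous in cyclic order")
            self.present_pfs = pfs

    @property
    def pfs(self) -> tuple[int, ...]:
        if self.present_pfs is None:
            return tuple(range(1, self.lattice.n_pf + 1))
        return self.present_pfs


def _cyclic_contiguous(pfs: tuple[int, ...], n: int) -> bool:
    s = set(pfs)
    if len(s) != len(pfs) or not all(1 <= p <= n for p in pfs):
        return False
    if len(s) == n:
        return True
    # contiguous iff exactly one cyclic gap between successive present pfs
    present = sorted(s)
    gaps = 0
    for a, b in zip(present, present[1:] + [present[0] + n]):
        if b - a > 1:
            gaps += 1
    return gaps <= 1


@dataclass
class DecorationSpec:
    """A non-tubulin density anchored to protofilaments of one tubule.

    ``blob_offsets`` are expressed in the anchor-local frame
    (outward-radial from the tubule centre, tangential, axial); each row is
    one Gaussian blob of the instance.  Instances repeat axially with
    ``axial_period`` and are kept independently with probability
    ``occupancy``.
    """

    name: str
    anchor: tuple[str, tuple[int, ...]]
    blob_offsets: np.ndarray  # (m, 3) nm, anchor-local
    blob_sigmas: np.ndarray  # (m,) nm
    axial_period: float = 8.0
    occupancy: float = 1.0
    mass: float = 1.0

    def __post_init__(self):
        self.blob_offsets = np.atleast_2d(np.asarray(self.blob_offsets, float))
        self.blob_sigmas = np.atleast_1d(np.asarray(self.blob_sigmas, float))
        if self.blob_offsets.shape[0] != self.blob_sigmas.shape[0]:
            raise InvalidSpecError("blob_offsets and blob_sigmas length mismatch")
        if self.axial_period not in (4.0, 8.0, 16.0, 24.0):
            raise InvalidSpecError("axial_period must be one of 4, 8, 16, 24 nm")
        if not 0.0 <= self.occupancy <= 1.0:
            raise InvalidSpecError("occupancy must lie in [0, 1]")


@dataclass
class BladeSpec:
    """One blade: its tubules, decorations and axial-domain identity."""

    tubules: list[TubuleSpec]
    decorations: list[DecorationSpec] = field(default_factory=list)
    domain: str = "proximal"  # proximal | distal | fly
    partial_b: bool = False

    def tubule(self, label: str) -> TubuleSpec | None:
        for t in self.tubules:
            if t.label == label:
                return t
        return None


@dataclass
class FlatteningSpec:
    """Area-preserving elliptical remap of the blade-centre circle.

    ``factor`` e >= 0 is the squash factor: one in-plane axis is
    stretched by (1+e) and the other compressed by 1/(1+e), so the
    blade-centre circle of radius R maps to an ellipse with a·b = R² and
    largest-to-smallest centre distance ratio (1+e)².  Blades stay rigid
    and are re-tangented to the ellipse.
    """

    factor: float = 0.0
    squash_axis_deg: float = 0.0  # direction of the long (a) semi-axis

    def __post_init__(self):
        if self.factor < 0:
            raise InvalidSpecError("flattening factor must be >= 0")

    def semi_axes(self, radius: float) -> tuple[float, float]:
        s = 1.0 + self.factor
        return radius * s, radius / s


@dataclass
class CentriolePreset:
    """Named whole-centriole geometry (cho triplet or s2 doublet)."""

    name: str
    n_blades: int = 9
    length: float = 440.0
    domain_boundary: float | None = 200.0  # None: single domain (fly)
    radius_proximal: float = 70.0
    radius_distal: float = 70.0
    blade_tilt_proximal: float = 50.0
    blade_tilt_distal: float = 35.0
    segment_step: float = 24.0
    center_offset: float = BLADE_CENTER_OFFSET_NM
    a11_mip_domain: str = "proximal"  # which CHO domain carries the A11 MIP
    blade_overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_blades != 9:
            raise InvalidSpecError("centrioles have 9 blades")
        if self.domain_boundary is not None and not (
            0.0 <= self.domain_boundary <= self.length
        ):
            raise InvalidSpecError("domain boundary must lie within the length")

    def domain_of(self, s: float) -> str:
        if self.name == "s2":
            return "fly"
        if self.domain_boundary is None or s < self.domain_boundary:
            return "proximal"
        return "distal"

    def radius_of(self, domain: str) -> float:
        return self.radius_distal if domain == "distal" else self.radius_proximal

    def tilt_of(self, domain: str) -> float:
        return self.blade_tilt_distal if domain == "distal" else self.blade_tilt_proximal


# ---------------------------------------------------------------------------
# blade construction
# ---------------------------------------------------------------------------


@dataclass
class BladeModel:
    """Realized blade density: Gaussian blobs in the blade frame."""

    spec: BladeSpec
    length: float
    positions: np.ndarray  # (n, 3) nm
    sigmas: np.ndarray  # (n,)
    masses: np.ndarray  # (n,)
    tubule_centers: dict  # label -> (2,) xy
    tubule_phases: dict  # label -> phase deg
    decoration_termini: dict  # name -> (3,) blade frame

    @property
    def n_blobs(self) -> int:
        return len(self.sigmas)


def _tubule_geometry(spec: BladeSpec) -> tuple[dict, dict]:
    """Place tubule circles: centres and protofilament phases (blade frame)."""
    centers: dict[str, np.ndarray] = {}
    phases: dict[str, float] = {}
    for tub in spec.tubules:
        lat = tub.lattice
        if tub.label == "A":
            centers["A"] = np.zeros(2)
            # phase chosen so the B-attachment face (between A10 and A11 for
            # a 13-pf tubule) points along +x, toward the rest of the blade
            g = lat.seam_extra_gap if lat.seam_between else 0.0
            step = (360.0 - g) / lat.n_pf
            phases["A"] = 9.5 * step + g if lat.n_pf == 13 else 0.0
        else:
            parent_label, pair = tub.attachment
            if parent_label not in centers:
                raise InvalidSpecError(
                    f"{tub.label}-tubule attaches to missing parent {parent_label}"
                )
            parent = spec.tubule(parent_label)
            p_ang = parent.lattice.pf_angles(phases[parent_label])
            i, j = pair
            a1, a2 = np.deg2rad(p_ang[i - 1]), np.deg2rad(p_ang[j - 1])
            mid = np.arctan2(
                np.sin(a1) + np.sin(a2), np.cos(a1) + np.cos(a2)
            )
            u = np.array([np.cos(mid), np.sin(mid)])
            dist = parent.lattice.tubule_radius + lat.tubule_radius - WALL_OVERLAP_NM
            centers[tub.label] = centers[parent_label] + dist * u
            # the gap between child pf 1 and pf n faces the parent
            back = np.rad2deg(mid) + 180.0
            phases[tub.label] = back - (360.0 / lat.n_pf) / 2.0
    return centers, phases


def build_tubule(
    spec: TubuleSpec,
    length: float,
    center: np.ndarray | None = None,
    phase_deg: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Emit one Gaussian blob per tubulin monomer on the lattice cylinder.

    Returns (positions (n,3), sigmas (n,), masses (n,)); z in [0, length)
    up to the helical rise.  Monomer count is exactly
    ``len(present_pfs) * 2 * floor(length / dimer_repeat)``.
    """
    lat = spec.lattice
    if length < lat.dimer_repeat:
        raise InvalidSpecError("tubule length must be at least one dimer repeat")
    center = np.zeros(2) if center is None else np.asarray(center, float)
    angles = lat.pf_angles(phase_deg)
    n_dimers = int(np.floor(length / lat.dimer_repeat))
    pos = []
    for k in spec.pfs:
        th = np.deg2rad(angles[k - 1])
        x = center[0] + lat.tubule_radius * np.cos(th)
        y = center[1] + lat.tubule_radius * np.sin(th)
        z0 = (k - 1) * lat.rise_per_pf
        for d in range(n_dimers):
            for m in (0.0, lat.monomer_offset):
                pos.append((x, y, z0 + d * lat.dimer_repeat + m))
    pos = np.array(pos, float).reshape(-1, 3)
    if spec.ellipticity_percent:
        pos = _distort_ellipse(
            pos, center, spec.ellipticity_percent, spec.ellipse_axis_deg
        )
    sig = np.full(len(pos), lat.blob_sigma)
    mas = np.ones(len(pos))
    return pos, sig, mas


def _distort_ellipse(pos, center, percent, axis_deg):
    """Area-preserving elliptical remap of tubule xy about its centre."""
    b_over_a = 1.0 - percent / 100.0
    a = 1.0 / np.sqrt(b_over_a)
    b = np.sqrt(b_over_a)
    th = np.deg2rad(axis_deg)
    c, s = np.cos(th), np.sin(th)
    rot = np.array([[c, -s], [s, c]])
    xy = (pos[:, :2] - center) @ rot  # into ellipse-axis frame
    xy = xy * np.array([a, b])
    pos = pos.copy()
    pos[:, :2] = xy @ rot.T + center
    return pos


def build_blade(
    spec: BladeSpec,
    length: float,
    seed: int | np.random.Generator = 0,
) -> BladeModel:
    """Realize a blade: tubule lattices plus occupancy-drawn decorations."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    centers, phases = _tubule_geometry(spec)
    all_pos, all_sig, all_mas = [], [], []
    for tub in spec.tubules:
        p, s, m = build_tubule(tub, length, centers[tub.label], phases[tub.label])
        all_pos.append(p)
        all_sig.append(s)
        all_mas.append(m)
    termini = {}
    for deco in spec.decorations:
        label, anchor_pfs = deco.anchor
        tub = spec.tubule(label)
        if tub is None:
            raise InvalidSpecError(f"decoration {deco.name} anchored to missing tubule {label}")
        missing = [k for k in anchor_pfs if k not in tub.pfs]
        if missing:
            raise InvalidSpecError(
                f"decoration {deco.name} anchored to absent protofilament(s) {missing}"
            )
        ang = tub.lattice.pf_angles(phases[label])
        base_angles = np.deg2rad([ang[k - 1] for k in anchor_pfs])
        mid = np.arctan2(np.sin(base_angles).mean(), np.cos(base_angles).mean())
        radial = np.array([np.cos(mid), np.sin(mid)])
        tangential = np.array([-radial[1], radial[0]])
        base = centers[label] + tub.lattice.tubule_radius * radial
        # anchor-local -> blade frame
        off = deco.blob_offsets
        xy = base[None, :] + off[:, :1] * radial[None, :] + off[:, 1:2] * tangential[None, :]
        world_off = np.concatenate([xy, off[:, 2:3]], axis=1)  # z filled per instance
        far = world_off[np.argmax(np.linalg.norm(off, axis=1))]
        termini[deco.name] = far.copy()
        z = deco.axial_period / 2.0
        while z < length:
            if rng.random() < deco.occupancy:
                inst = world_off.copy()
                inst[:, 2] += z
                all_pos.append(inst)
                all_sig.append(deco.blob_sigmas.copy())
                all_mas.append(np.full(len(inst), deco.mass))
            z += deco.axial_period
    return BladeModel(
        spec=spec,
        length=length,
        positions=np.concatenate(all_pos, axis=0),
        sigmas=np.concatenate(all_sig),
        masses=np.concatenate(all_mas),
        tubule_centers=centers,
        tubule_phases=phases,
        decoration_termini=termini,
    )


def make_partial_b(blade: BladeSpec) -> BladeSpec:
    """Restrict the B-tubule to the two flanking stubs B01-B02 and B07-B10.

    The stubs keep the complete-B lattice radius (same curvature).  The
    operation is idempotent; decorations anchored to removed protofilaments
    are dropped.
    """
    b = blade.tubule("B")
    if b is None:
        raise InvalidSpecError("blade has no B-tubule")
    keep = (1, 2, 7, 8, 9, 10)
    new = copy.deepcopy(blade)
    for tub in new.tubules:
        if tub.label == "B":
            tub.present_pfs = keep
    new.decorations = [
        d
        for d in new.decorations
        if not (d.anchor[0] == "B" and any(k not in keep for k in d.anchor[1]))
    ]
    new.partial_b = True
    return new


def particle_frame_gamma(
    radius: float, tilt_deg: float, center_offset: float
) -> float:
    """In-plane angle (degrees) of the blade long axis in the reference frame.

    The reference x axis is the outward radial direction *at the segment
    centre*, which sits ``center_offset`` along the blade long axis from
    the A-tubule centre; the lever arm advances the segment's azimuth by
    ``dphi = atan2(off cos(tilt), R + off sin(tilt))`` relative to the
    A-centre ring, so the blade appears rotated by ``90 - tilt - dphi``.
    """
    al = np.deg2rad(tilt_deg)
    dphi = np.arctan2(center_offset * np.cos(al), radius + center_offset * np.sin(al))
    return 90.0 - tilt_deg - np.rad2deg(dphi)


def blade_to_reference(
    blade: BladeModel, gamma_deg: float, center_offset: float | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Express blade blobs in the reference (particle) frame.

    ``gamma_deg`` is the in-plane angle of the blade long axis in the
    reference frame (see :func:`particle_frame_gamma`).  The frame origin
    is the segment centre (A-tubule centre + ``center_offset`` along the
    blade long axis), with z centred on the blade mid-height.
    """
    if center_offset is None:
        center_offset = BLADE_CENTER_OFFSET_NM
    gamma = np.deg2rad(gamma_deg)
    c, s = np.cos(gamma), np.sin(gamma)
    rot = np.array([[c, -s], [s, c]])
    pos = blade.positions.copy()
    pos[:, 2] -= blade.length / 2.0
    pos[:, :2] -= np.array([center_offset, 0.0])
    pos[:, :2] = pos[:, :2] @ rot.T
    return pos, blade.sigmas.copy(), blade.masses.copy()


def tubule_centers_in_reference(
    blade: BladeModel, gamma_deg: float, center_offset: float | None = None
) -> dict:
    """Tubule-centre xy positions in the reference (particle) frame."""
    if center_offset is None:
        center_offset = BLADE_CENTER_OFFSET_NM
    gamma = np.deg2rad(gamma_deg)
    c, s = np.cos(gamma), np.sin(gamma)
    rot = np.array([[c, -s], [s, c]])
    out = {}
    for label, xy in blade.tubule_centers.items():
        out[label] = rot @ (np.asarray(xy, float) - np.array([center_offset, 0.0]))
    return out


# ---------------------------------------------------------------------------
# preset blade specs
# ---------------------------------------------------------------------------


def _a_lattice(ellipticity: float = 0.0) -> LatticeSpec:
    return LatticeSpec(
        n_pf=13,
        tubule_radius=A_TUBULE_RADIUS_NM,
        seam_between=(9, 10),
        seam_extra_gap=5.0,
    )


def _bc_lattice() -> LatticeSpec:
    return LatticeSpec(n_pf=10, tubule_radius=BC_TUBULE_RADIUS_NM)


def _deco(name, anchor, offsets, sigmas, period, occupancy, mass=1.2):
    return DecorationSpec(
        name=name,
        anchor=anchor,
        blob_offsets=np.asarray(offsets, float),
        blob_sigmas=np.asarray(sigmas, float),
        axial_period=float(period),
        occupancy=float(occupancy),
        mass=mass,
    )


def _mip(name, label, pfs, period=8.0, occupancy=0.9):
    # single blob just inside the wall, straddling the anchor pfs
    return _deco(name, (label, tuple(pfs)), [[-4.0, 0.0, 0.0]], [1.8], period, occupancy)


def proximal_cho_blade_spec(
    a_ellipticity: float = 0.0, a11_mip: bool = True
) -> BladeSpec:
    """CHO proximal triplet: A(13)+B(10)+C(10), pinhead, A-C linker, 4 MIPs."""
    a = TubuleSpec("A", _a_lattice(), ellipticity_percent=a_ellipticity)
    b = TubuleSpec("B", _bc_lattice(), attachment=("A", (10, 11)))
    c = TubuleSpec("C", _bc_lattice(), attachment=("B", (6, 7)))
    decorations = [
        # pinhead: extends from A03 toward the centriole lumen
        _deco(
            "pinhead",
            ("A", (3,)),
            [[3.0, 0.0, 0.0], [7.5, 1.5, 0.0], [11.5, 3.0, 0.0]],
            [2.0, 2.0, 2.2],
            8.0,
            0.7,
        ),
        # both halves of the canonical A-C linker (A09 <-> neighbour C08/C09)
        _deco(
            "ac_linker_a",
            ("A", (9,)),
            [[3.5, 0.0, 0.0], [8.0, -2.0, 0.0]],
            [2.0, 2.2],
            8.0,
            0.7,
        ),
        _deco(
            "ac_linker_c",
            ("C", (8, 9)),
            [[3.5, 0.0, 0.0], [8.0, 2.0, 0.0]],
            [2.0, 2.2],
            8.0,
            0.7,
        ),
        _mip("mip_a09a10", "A", (9, 10), 8.0, 0.95),
        _mip("mip_b01b02", "B", (1, 2), 8.0, 0.9),
        _mip("mip_c01c02", "C", (1, 2), 8.0, 0.9),
    ]
    if a11_mip:
        decorations.append(_mip("mip_a11", "A", (11,), 16.0, 0.8))
    return BladeSpec(tubules=[a, b, c], decorations=decorations, domain="proximal")


def distal_cho_blade_spec(
    a_ellipticity: float = 0.0, a11_mip: bool = False
) -> BladeSpec:
    """CHO distal: partial C (C01-C08), no pinhead / canonical A-C linker;
    L-shaped inner-AB-junction linker and the A09 foot instead."""
    a = TubuleSpec("A", _a_lattice(), ellipticity_percent=a_ellipticity)
    b = TubuleSpec("B", _bc_lattice(), attachment=("A", (10, 11)))
    c = TubuleSpec(
        "C", _bc_lattice(), attachment=("B", (6, 7)), present_pfs=tuple(range(1, 9))
    )
    decorations = [
        # L-shaped linker from the inner AB-junction toward the lumen
        _deco(
            "l_linker",
            ("A", (1, 2)),
            [[3.0, 0.0, 0.0], [7.0, 3.0, 0.0], [10.0, 7.5, 0.0]],
            [2.0, 2.0, 2.2],
            8.0,
            0.7,
        ),
        # foot-like appendage from A09 toward the neighbour's C07/C08
        _deco(
            "a09_foot",
            ("A", (9,)),
            [[3.5, 0.0, 0.0], [8.0, -2.5, 0.0]],
            [2.0, 2.2],
            8.0,
            0.7,
        ),
        _mip("mip_a09a10", "A", (9, 10), 8.0, 0.95),
        _mip("mip_b01b02", "B", (1, 2), 8.0, 0.9),
        _mip("mip_c01c02", "C", (1, 2), 8.0, 0.9),
    ]
    if a11_mip:
        decorations.append(_mip("mip_a11", "A", (11,), 16.0, 0.8))
    return BladeSpec(tubules=[a, b, c], decorations=decorations, domain="distal")


def fly_blade_spec(a_ellipticity: float = 0.0) -> BladeSpec:
    """S2 doublet: A(13)+B(10), elaborated pinhead, A-A hinge, wishbone,
    seam MIP only (no B01/B02 MIP in the fly)."""
    a = TubuleSpec("A", _a_lattice(), ellipticity_percent=a_ellipticity)
    b = TubuleSpec("B", _bc_lattice(), attachment=("A", (10, 11)))
    decorations = [
        # elaborated pinhead: A03 with extra contacts toward A02 / inner AB
        _deco(
            "pinhead",
            ("A", (3,)),
            [[3.0, 0.0, 0.0], [7.5, 1.5, 0.0], [11.5, 3.0, 0.0], [6.0, -4.0, 0.0]],
            [2.0, 2.0, 2.2, 1.8],
            8.0,
            0.8,
        ),
        # hinge-shaped density on A05/A06, one half of the A-A linker
        _deco(
            "aa_hinge",
            ("A", (5, 6)),
            [[3.5, 0.0, 0.0], [8.5, -2.0, 0.0]],
            [2.0, 2.2],
            8.0,
            0.7,
        ),
        # wishbone / hollow-cone density, weak connection to A08
        _deco(
            "wishbone",
            ("A", (8,)),
            [[4.0, 0.0, 0.0], [8.0, 3.0, 0.0], [8.0, -3.0, 0.0]],
            [2.0, 2.2, 2.2],
            16.0,
            0.5,
        ),
        _mip("mip_a09a10", "A", (9, 10), 8.0, 0.95),
    ]
    return BladeSpec(tubules=[a, b], decorations=decorations, domain="fly")


def blade_spec_for(preset: CentriolePreset, domain: str, **kw) -> BladeSpec:
    a11 = preset.a11_mip_domain
    over = dict(preset.blade_overrides)
    over.update(kw)
    if domain == "proximal":
        return proximal_cho_blade_spec(a11_mip=(a11 == "proximal"), **over)
    if domain == "distal":
        return distal_cho_blade_spec(a11_mip=(a11 == "distal"), **over)
    if domain == "fly":
        return fly_blade_spec(**over)
    raise InvalidSpecError(f"unknown blade domain {domain!r}")


# ---------------------------------------------------------------------------
# preset loading
# ---------------------------------------------------------------------------


def load_preset(name: str) -> CentriolePreset:
    """Load a named preset (``cho`` or ``s2``) from the shipped YAML configs."""
    try:
        ref = importlib.resources.files("centriotome.presets").joinpath(f"{name}.yaml")
        text = ref.read_text()
    except FileNotFoundError as exc:
        raise InvalidSpecError(f"unknown preset {name!r}") from exc
    cfg = yaml.safe_load(text)
    return preset_from_dict(cfg)


def preset_from_dict(cfg: dict) -> CentriolePreset:
    known = {
        "name",
        "n_blades",
        "length",
        "domain_boundary",
        "radius_proximal",
        "radius_distal",
        "blade_tilt_proximal",
        "blade_tilt_distal",
        "segment_step",
        "center_offset",
        "a11_mip_domain",
        "blade_overrides",
    }
    unknown = set(cfg) - known
    if unknown:
        raise InvalidSpecError(f"unknown preset keys: {sorted(unknown)}")
    return CentriolePreset(**cfg)


# ---------------------------------------------------------------------------
# whole-centriole assembly
# ---------------------------------------------------------------------------


@dataclass
class BladePlacement:
    """One axial section of one rod: a blade model plus its rigid pose."""

    rod_id: int  # 1..9
    domain: str
    blade: BladeModel
    a_center_xy: np.ndarray  # world xy of the A-tubule centre
    blade_angle_deg: float  # world angle of the blade long axis
    z_lo: float
    z_hi: float

    def world_blobs(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        th = np.deg2rad(self.blade_angle_deg)
        c, s = np.cos(th), np.sin(th)
        rot = np.array([[c, -s], [s, c]])
        pos = self.blade.positions.copy()
        pos[:, :2] = pos[:, :2] @ rot.T + self.a_center_xy
        pos[:, 2] += self.z_lo
        keep = pos[:, 2] < self.z_hi + 1e-9
        return pos[keep], self.blade.sigmas[keep], self.blade.masses[keep]


@dataclass
class CentrioleModel:
    """Nine-bladed centriole: placements, preset, and ground-truth table."""

    preset: CentriolePreset
    flattening: FlatteningSpec
    placements: list[BladePlacement]
    ground_truth: pd.DataFrame
    length: float

    def all_blobs(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        ps, ss, ms = [], [], []
        for pl in self.placements:
            p, s, m = pl.world_blobs()
            ps.append(p)
            ss.append(s)
            ms.append(m)
        return np.concatenate(ps), np.concatenate(ss), np.concatenate(ms)


def _ellipse_point_tangent(radius, flat: FlatteningSpec, phi):
    """Blade-centre position, outward normal and tangent on the (possibly
    flattened) blade-centre ellipse at parameter angle phi (radians)."""
    a, b = flat.semi_axes(radius)
    th = np.deg2rad(flat.squash_axis_deg)
    c, s = np.cos(th), np.sin(th)
    rot = np.array([[c, -s], [s, c]])
    p = rot @ np.array([a * np.cos(phi), b * np.sin(phi)])
    t = rot @ np.array([-a * np.sin(phi), b * np.cos(phi)])
    t = t / np.linalg.norm(t)
    n = np.array([t[1], -t[0]])  # rotate tangent by -90 deg
    if np.dot(n, p) < 0:
        n = -n
    # orient the tangent counter-clockwise (2-D cross product n x t > 0)
    if n[0] * t[1] - n[1] * t[0] < 0:
        t = -t
    return p, n, t


def _frame_from_blade_angle(blade_angle_deg: float, tilt_deg: float):
    """Reference-frame axes for a blade at a given world in-plane angle.

    The reference x axis is the blade long axis rotated by -(90 - tilt):
    on an unflattened circle this is exactly the outward radial direction.
    """
    ang = np.deg2rad(blade_angle_deg - (90.0 - tilt_deg))
    x = np.array([np.cos(ang), np.sin(ang), 0.0])
    z = np.array([0.0, 0.0, 1.0])
    y = np.cross(z, x)
    return np.stack([x, y, z], axis=1)  # columns: reference -> world


def assemble_centriole(
    preset: CentriolePreset,
    flattening: FlatteningSpec | None = None,
    seed: int = 0,
    partial_b_rods: tuple[int, ...] = (),
    a_ellipticity: float = 0.0,
) -> CentrioleModel:
    """Assemble nine blades at 40-degree azimuths, flatten the ensemble,
    and fill the ground-truth segment table.

    ``partial_b_rods`` lists rod ids whose blades get the incomplete
    (B01-B02 / B07-B10) B-tubule; ``a_ellipticity`` applies the in-plane
    A-tubule distortion (percent) to every blade.
    """
    flat = flattening or FlatteningSpec(0.0)
    rng = np.random.default_rng(seed)
    domains = (
        ["fly"]
        if preset.name == "s2"
        else (["proximal", "distal"] if preset.domain_boundary not in (None, 0.0) else ["proximal"])
    )
    placements: list[BladePlacement] = []
    rows = []
    for k in range(preset.n_blades):
        phi = np.deg2rad(40.0 * k)
        rod_id = k + 1
        partial = rod_id in partial_b_rods
        for domain in domains:
            if preset.name == "s2" or len(domains) == 1:
                z_lo, z_hi = 0.0, preset.length
            elif domain == "proximal":
                z_lo, z_hi = 0.0, preset.domain_boundary
            else:
                z_lo, z_hi = preset.domain_boundary, preset.length
            if z_hi - z_lo < DIMER_REPEAT_NM:
                continue
            spec = blade_spec_for(preset, domain, a_ellipticity=a_ellipticity)
            if partial:
                spec = make_partial_b(spec)
            blade = build_blade(spec, z_hi - z_lo, rng)
            radius = preset.radius_of(domain)
            tilt = preset.tilt_of(domain)
            p, n, t = _ellipse_point_tangent(radius, flat, phi)
            al = np.deg2rad(tilt)
            xblade = np.cos(al) * t + np.sin(al) * n
            blade_angle = np.rad2deg(np.arctan2(xblade[1], xblade[0]))
            placements.append(
                BladePlacement(
                    rod_id=rod_id,
                    domain=domain,
                    blade=blade,
                    a_center_xy=p,
                    blade_angle_deg=blade_angle,
                    z_lo=z_lo,
                    z_hi=z_hi,
                )
            )
    # ground-truth segment table at the segment step
    step = preset.segment_step
    for pl in placements:
        s = step / 2.0 + np.floor(pl.z_lo / step + 0.5) * step
        # enumerate segment centres s in [z_lo, z_hi)
        s_vals = np.arange(step / 2.0, preset.length, step)
        s_vals = s_vals[(s_vals >= pl.z_lo) & (s_vals < pl.z_hi)]
        tilt = preset.tilt_of(pl.domain)
        th = np.deg2rad(pl.blade_angle_deg)
        xblade = np.array([np.cos(th), np.sin(th)])
        cxy = pl.a_center_xy + preset.center_offset * xblade
        # model frames keep z along the axis: the ZYZ decomposition is the
        # pure in-plane angle (tilt = psi = 0), computed directly to avoid
        # the gimbal-lock ambiguity.  The frame x axis is the outward
        # radial at the segment centre (gamma convention), carried rigidly
        # with the blade under flattening.
        gamma0 = particle_frame_gamma(
            preset.radius_of(pl.domain), tilt, preset.center_offset
        )
        rot = pl.blade_angle_deg - gamma0
        rot = (rot + 180.0) % 360.0 - 180.0
        tl, psi = 0.0, 0.0
        for s in s_vals:
            rows.append(
                dict(
                    rod_id=pl.rod_id,
                    s_nm=s,
                    x_nm=cxy[0],
                    y_nm=cxy[1],
                    z_nm=s,
                    rot_deg=rot,
                    tilt_deg=tl,
                    psi_deg=psi,
                    domain=pl.domain,
                    partial_b=pl.blade.spec.partial_b,
                )
            )
    truth = pd.DataFrame(rows).sort_values(["rod_id", "s_nm"]).reset_index(drop=True)
    return CentrioleModel(
        preset=preset,
        flattening=flat,
        placements=placements,
        ground_truth=truth,
        length=preset.length,
    )
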