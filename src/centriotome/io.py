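"""File formats: MRC volumes, particle tables (TSV / STAR dialect),
tilt-angle files, FSC curves and YAML run configs.

MRC files store mode-2 floats with the voxel size in the header in
Angstrom (nm x 10).  The STAR dialect uses RELION-style column names
(rlnCoordinate{X,Y,Z}, rlnAngle{Rot,Tilt,Psi}) plus custom columns for
rod id, axial position, class label and half-set.
"""

from __future__ import annotations

from pathlib import Path

import mrcfile
import numpy as np
import pandas as pd
import yaml

from .picking import Particle
from .tomo_sim import DensityVolume, TiltSeries

# ---------------------------------------------------------------------------
# MRC
# ---------------------------------------------------------------------------


def write_mrc(path, volume: DensityVolume | np.ndarray, voxel_size: float | None = None):
    """Write a volume as MRC mode 2 (float32); voxel size and origin are
    stored in the header in Angstrom (nm x 10)."""
    origin = np.zeros(3)
    if isinstance(volume, DensityVolume):
        grid = volume.grid
        voxel_size = volume.voxel_size
        origin = volume.origin
    else:
        grid = np.asarray(volume)
        if voxel_size is None:
            raise ValueError("voxel_size required for a bare array")
    with mrcfile.new(str(path), overwrite=True) as m:
        m.set_data(np.ascontiguousarray(grid, dtype=np.float32))
        m.voxel_size = voxel_size * 10.0  # nm -> Angstrom
        m.header.origin.x = origin[0] * 10.0
        m.header.origin.y = origin[1] * 10.0
        m.header.origin.z = origin[2] * 10.0


def read_mrc(path) -> DensityVolume:
    with mrcfile.open(str(path), permissive=True) as m:
        grid = np.asarray(m.data, np.float32).copy()
        vs = float(m.voxel_size.x) / 10.0  # Angstrom -> nm
        origin = np.array([float(m.header.origin.x), float(m.header.origin.y),
                           float(m.header.origin.z)]) / 10.0
    if vs <= 0:
        vs = 1.0
    return DensityVolume(grid=grid, voxel_size=vs, origin=origin)


# ---------------------------------------------------------------------------
# tilt series
# ---------------------------------------------------------------------------


def write_tlt(path, angles):
    Path(path).write_text("".join(f"{a:.2f}\n" for a in np.asarray(angles, float)))


def read_tlt(path) -> np.ndarray:
    return np.array([float(x) for x in Path(path).read_text().split()], float)


def write_tilt_series(stem, series: TiltSeries):
    """Write images as <stem>.mrc (stack) and angles as <stem>.tlt."""
    stem = Path(stem)
    with mrcfile.new(str(stem.with_suffix(".mrc")), overwrite=True) as m:
        m.set_data(np.ascontiguousarray(series.images, np.float32))
        m.voxel_size = series.pixel_size * 10.0
    write_tlt(stem.with_suffix(".tlt"), series.tilt_angles)


def read_tilt_series(stem) -> TiltSeries:
    stem = Path(stem)
    with mrcfile.open(str(stem.with_suffix(".mrc")), permissive=True) as m:
        images = np.asarray(m.data, np.float32).copy()
        px = float(m.voxel_size.x) / 10.0
    angles = read_tlt(stem.with_suffix(".tlt"))
    return TiltSeries(images=images, tilt_angles=angles, pixel_size=px or 1.0)


# ---------------------------------------------------------------------------
# particle tables
# ---------------------------------------------------------------------------

_TSV_COLUMNS = [
    "particle_id", "centriole_id", "rod_id", "s_nm",
    "x0_nm", "y0_nm", "z0_nm", "rot0_deg", "tilt0_deg", "psi0_deg",
    "rot_deg", "tilt_deg", "psi_deg", "sx_nm", "sy_nm", "sz_nm",
    "score", "class_label", "half_set", "domain", "partial_b",
]


def particles_to_frame(particles: list[Particle]) -> pd.DataFrame:
    rows = []
    for p in particles:
        rows.append(
            dict(
                particle_id=p.particle_id,
                centriole_id=p.centriole_id,
                rod_id=p.rod_id,
                s_nm=p.s,
                x0_nm=p.center0[0], y0_nm=p.center0[1], z0_nm=p.center0[2],
                rot0_deg=p.euler0[0], tilt0_deg=p.euler0[1], psi0_deg=p.euler0[2],
                rot_deg=p.euler[0], tilt_deg=p.euler[1], psi_deg=p.euler[2],
                sx_nm=p.shift[0], sy_nm=p.shift[1], sz_nm=p.shift[2],
                score=np.nan if p.score is None else p.score,
                class_label=-1 if p.class_label is None else p.class_label,
                half_set=p.half_set,
                domain="" if p.domain is None else p.domain,
                partial_b=bool(p.partial_b),
            )
        )
    return pd.DataFrame(rows, columns=_TSV_COLUMNS)


def frame_to_particles(df: pd.DataFrame) -> list[Particle]:
    out = []
    for _, r in df.iterrows():
        p = Particle(
            particle_id=int(r.particle_id),
            centriole_id=int(r.centriole_id),
            rod_id=int(r.rod_id),
            s=float(r.s_nm),
            center0=np.array([r.x0_nm, r.y0_nm, r.z0_nm], float),
            euler0=np.array([r.rot0_deg, r.tilt0_deg, r.psi0_deg], float),
        )
        p.euler = np.array([r.rot_deg, r.tilt_deg, r.psi_deg], float)
        p.shift = np.array([r.sx_nm, r.sy_nm, r.sz_nm], float)
        p.score = None if np.isnan(r.score) else float(r.score)
        p.class_label = None if int(r.class_label) < 0 else int(r.class_label)
        p.half_set = int(r.half_set)
        p.domain = None if r.domain in ("", None) or pd.isna(r.domain) else str(r.domain)
        p.partial_b = bool(r.partial_b)
        out.append(p)
    return out


def write_particles_tsv(path, particles: list[Particle]):
    particles_to_frame(particles).to_csv(path, sep="\t", index=False)


def read_particles_tsv(path) -> list[Particle]:
    return frame_to_particles(pd.read_csv(path, sep="\t", keep_default_na=True,
                                          dtype={"domain": str}, na_values=[]))


# ---------------------------------------------------------------------------
# STAR dialect
# ---------------------------------------------------------------------------

_STAR_MAP = [
    ("rlnCoordinateX", "x0_nm"),
    ("rlnCoordinateY", "y0_nm"),
    ("rlnCoordinateZ", "z0_nm"),
    ("rlnAngleRot", "rot_deg"),
    ("rlnAngleTilt", "tilt_deg"),
    ("rlnAnglePsi", "psi_deg"),
    ("rlnOriginX", "sx_nm"),
    ("rlnOriginY", "sy_nm"),
    ("rlnOriginZ", "sz_nm"),
    ("particleID", "particle_id"),
    ("centrioleID", "centriole_id"),
    ("rodID", "rod_id"),
    ("sNm", "s_nm"),
    ("angleRot0", "rot0_deg"),
    ("angleTilt0", "tilt0_deg"),
    ("anglePsi0", "psi0_deg"),
    ("score", "score"),
    ("classLabel", "class_label"),
    ("halfSet", "half_set"),
]


def write_particles_star(path, particles: list[Particle]):
    """Minimal STAR loop_ block with RELION-style coordinate/angle names."""
    df = particles_to_frame(particles)
    lines = ["data_particles", "", "loop_"]
    for i, (star, _) in enumerate(_STAR_MAP, start=1):
        lines.append(f"_{star} #{i}")
    for _, r in df.iterrows():
        vals = []
        for _, col in _STAR_MAP:
            v = r[col]
            if isinstance(v, float):
                vals.append(f"{v:.6f}")
            else:
                vals.append(str(v))
        lines.append(" ".join(vals))
    Path(path).write_text("\n".join(lines) + "\n")


def read_particles_star(path) -> pd.DataFrame:
    """Parse the STAR loop_ block back into a column-named DataFrame."""
    names, rows = [], []
    in_loop = False
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("data_"):
            continue
        if line == "loop_":
            in_loop = True
            names = []
            continue
        if line.startswith("_"):
            if in_loop:
                names.append(line.split()[0].lstrip("_"))
            continue
        if in_loop and names:
            rows.append(line.split())
    df = pd.DataFrame(rows, columns=names)
    for c in df.columns:
        try:
            df[c] = pd.to_numeric(df[c])
        except (ValueError, TypeError):
            pass
    return df


# ---------------------------------------------------------------------------
# misc tables / configs
# ---------------------------------------------------------------------------


def write_truth_tsv(path, truth: pd.DataFrame):
    cols = ["rod_id", "s_nm", "x_nm", "y_nm", "z_nm",
            "rot_deg", "tilt_deg", "psi_deg", "domain", "partial_b"]
    truth[cols].to_csv(path, sep="\t", index=False)


def read_truth_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_fsc_tsv(path, curve):
    pd.DataFrame({"freq_inv_nm": curve.freq, "fsc": curve.fsc}).to_csv(
        path, sep="\t", index=False
    )


def load_config(path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def save_config(path, cfg: dict):
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))
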