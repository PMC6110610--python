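"""End-to-end runs: simulate -> pick -> align -> classify -> geometry.

Every stage persists its outputs (MRC volumes, TSV/STAR particle tables,
FSC curves, a JSON report) under the run's output directory, and every
random draw flows from a named seed in the config, so re-running an
identical config reproduces all tables bit-identically.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import io
from .classify import AxialBinning, axial_bin_average, masked_classify, select_class, split_proximal_distal
from .errors import ConfigError
from .geometry import (
    SymmetryParams,
    measure_blade_tilt,
    measure_diameter,
    rebuild_composite,
    refit_positions,
    symmetrize,
    tilt_change,
)
from .model_builder import (
    FlatteningSpec,
    assemble_centriole,
    blade_spec_for,
    build_blade,
    blade_to_reference,
    load_preset,
    tubule_centers_in_reference,
)
from .picking import extract_particles, make_particles, trace_rods
from .sta import AlignmentParams, compute_fsc, run_alignment
from .tomo_sim import (
    DensityVolume,
    NoiseSpec,
    WedgeMask,
    add_noise,
    default_tilt_angles,
    project_tilt_series,
    rasterize,
    reconstruct_wbp,
)

log = logging.getLogger("centriotome.pipeline")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    preset: str = "cho"
    flattening: float = 0.0
    snr: float = 0.5
    seed_model: int = 1
    seed_noise: int = 2
    seed_halves: int = 3
    seed_classify: int = 4
    voxel_size: float = 2.0
    subvolume_box: int = 40
    tilt_max: float = 60.0
    tilt_step: float = 1.0
    picking_mode: str = "from_truth"
    segment_step: float = 24.0
    shift_range: float = 3.0
    lowpass: float = 5.0
    # angular schedule: (rot, tilt, psi) range and step per iteration; the
    # first pass searches psi widely to absorb the flattening-induced
    # in-plane offset between the radial picking frame and the blade
    angular_schedule: list = field(
        default_factory=lambda: [
            ((0.0, 0.0, 21.0), 3.0),
            ((4.0, 4.0, 4.0), 2.0),
            ((4.0, 4.0, 4.0), 2.0),
        ]
    )
    bin_width: float = 100.0
    partial_b_rods: tuple = ()
    classify_partial_b: bool = False
    a_ellipticity: float = 0.0
    out_dir: str | None = None

    def validate(self):
        if self.preset not in ("cho", "s2"):
            raise ConfigError(f"unknown preset {self.preset!r}")
        if self.flattening < 0:
            raise ConfigError("flattening must be >= 0")
        if self.snr <= 0:
            raise ConfigError("snr must be positive")
        for name in ("seed_model", "seed_noise", "seed_halves", "seed_classify"):
            if not float(getattr(self, name)).is_integer():
                raise ConfigError(f"{name} must be an integer")
        return self


def config_from_dict(d: dict) -> RunConfig:
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(d) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**d)
    if isinstance(cfg.partial_b_rods, list):
        cfg.partial_b_rods = tuple(cfg.partial_b_rods)
    return cfg.validate()


def _alignment_schedule(cfg: RunConfig) -> list[AlignmentParams]:
    out = []
    for ranges, step in cfg.angular_schedule:
        out.append(
            AlignmentParams(
                angular_range=tuple(ranges),
                angular_step=step,
                shift_range=cfg.shift_range,
                shift_step=cfg.voxel_size,
                lowpass=cfg.lowpass,
                n_iterations=1,
            )
        )
    return out


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def simulate_stage(cfg: RunConfig, out: Path | None = None):
    """Model -> density -> tilt series (+noise) -> WBP tomogram."""
    preset = load_preset(cfg.preset)
    model = assemble_centriole(
        preset,
        FlatteningSpec(cfg.flattening),
        seed=cfg.seed_model,
        partial_b_rods=tuple(cfg.partial_b_rods),
        a_ellipticity=cfg.a_ellipticity,
    )
    pos, sig, mas = model.all_blobs()
    lo = pos.min(axis=0) - 10.0
    hi = pos.max(axis=0) + 10.0
    # mount: model (x, y, z) -> tomogram (x, z, -y)
    ext = np.array([hi[0] - lo[0], hi[2] - lo[2], hi[1] - lo[1]])
    box = tuple(int(np.ceil(e / cfg.voxel_size / 8.0)) * 8 for e in ext)
    volume = rasterize(model, cfg.voxel_size, box, mount=True)
    angles = default_tilt_angles(cfg.tilt_step, cfg.tilt_max)
    series = project_tilt_series(volume, angles)
    series = add_noise(series, NoiseSpec(cfg.snr, seed=cfg.seed_noise))
    tomo = reconstruct_wbp(series, box[2], origin=volume.origin)
    if out is not None:
        io.write_tilt_series(out / "tilt_series", series)
        io.write_mrc(out / "tomogram.mrc", tomo)
        io.write_truth_tsv(out / "ground_truth.tsv", model.ground_truth)
    return model, volume, series, tomo


def pick_stage(cfg: RunConfig, tomo: DensityVolume, model, out: Path | None = None):
    preset = model.preset
    rods = trace_rods(
        tomo,
        mode=cfg.picking_mode,
        truth=model.ground_truth if cfg.picking_mode == "from_truth" else None,
    )
    axis_point = np.array([0.0, preset.length / 2.0, 0.0])
    axis_dir = np.array([0.0, 1.0, 0.0])
    if cfg.picking_mode == "auto":
        pts = np.concatenate([r.control_points for r in rods])
        axis_point = pts.mean(axis=0)
    particles = make_particles(
        rods, axis_point, axis_dir, step=cfg.segment_step,
        truth=model.ground_truth,
    )
    if out is not None:
        io.write_particles_tsv(out / "particles_picked.tsv", particles)
        io.write_particles_star(out / "particles_picked.star", particles)
    return rods, particles, (axis_point, axis_dir)


def align_stage(cfg: RunConfig, tomo, particles, wedge, out: Path | None = None,
                tag: str = "all"):
    from .picking import curate_consistency
    from .sta import average_particles

    subvols = extract_particles(tomo, particles, cfg.subvolume_box)
    schedule = _alignment_schedule(cfg)
    avg, refined, scores = run_alignment(
        particles, subvols, schedule, wedge, cfg.voxel_size,
        reference0=None, seed=cfg.seed_halves,
    )
    # automated angular/translational consistency curation along each rod
    kept, rejected = curate_consistency(refined)
    if rejected and len(kept) >= max(9, len(refined) // 2):
        log.info("curation (%s): rejected %d of %d particles",
                 tag, len(rejected), len(refined))
        keep_ids = {p.particle_id for p in kept}
        idx = [i for i, p in enumerate(refined) if p.particle_id in keep_ids]
        refined = [refined[i] for i in idx]
        subvols = subvols[idx]
        avg = average_particles(refined, subvols, wedge, cfg.voxel_size)
    fsc = None
    if avg.half_grids is not None:
        fsc = compute_fsc(avg.half_grids[0], avg.half_grids[1], cfg.voxel_size)
    if out is not None:
        io.write_mrc(out / f"average_{tag}.mrc", avg.grid, cfg.voxel_size)
        io.write_particles_tsv(out / f"particles_{tag}.tsv", refined)
        io.write_particles_star(out / f"particles_{tag}.star", refined)
        if fsc is not None:
            io.write_fsc_tsv(out / f"fsc_{tag}.tsv", fsc)
    return avg, refined, scores, subvols, fsc


def _blade_axis_from_average(
    avg,
    params: SymmetryParams,
    d_ab: float = 20.5,
    search_nm: float = 5.0,
    step_nm: float = 0.5,
    theta_range: float = 20.0,
    radius_a: float = 12.5,
    radius_b: float = 11.5,
):
    """Blade long-axis direction and A-tubule centre, measured in the map.

    A rigid two-ring template (A- and B-tubule walls at their known
    spacing) is matched against the central cross-section over a grid of
    A-centre offsets and in-plane blade angles; each score integrates the
    density along both walls, which is robust on noisy averages.  Returns
    ``(delta, a_ref)`` as reference-frame 3-vectors (z = 0): the measured
    A->B direction and the measured A-tubule centre.
    """
    grid = np.asarray(avg.grid, float)
    voxel = avg.voxel_size
    nz = grid.shape[2]
    half = max(int(round(12.0 / voxel)), 1)
    sect = grid[:, :, nz // 2 - half : nz // 2 + half].mean(axis=2)
    nxy = np.array(sect.shape)
    mid = (nxy - 1) / 2.0
    a_guess = params.a_center_in_reference()[:2]
    theta_guess = params.gamma()

    ring_t = np.deg2rad(np.arange(0.0, 360.0, 5.0))
    ring = np.stack([np.cos(ring_t), np.sin(ring_t)])  # (2, 72)
    offs = np.arange(-search_nm, search_nm + 1e-9, step_nm)
    dx, dy = np.meshgrid(offs, offs, indexing="ij")
    cand = np.stack([dx.ravel(), dy.ravel()], axis=1) + a_guess  # (nc, 2)
    thetas = theta_guess + np.arange(-theta_range, theta_range + 1e-9, 1.0)

    def ring_scores(centers_nm, radius):
        coords = (centers_nm[:, :, None] / voxel + mid[None, :, None]
                  + radius / voxel * ring[None, :, :])
        vals = ndimage.map_coordinates(
            sect, coords.transpose(1, 0, 2).reshape(2, -1), order=1,
            mode="constant", cval=float(sect.min()),
        )
        return vals.reshape(len(centers_nm), -1).mean(axis=1)

    def search(centers, theta_list):
        score_a = ring_scores(centers, radius_a)
        best = (-np.inf, centers[0], theta_list[0])
        for th in theta_list:
            u2 = np.array([np.cos(np.deg2rad(th)), np.sin(np.deg2rad(th))])
            tot = score_a + ring_scores(centers + d_ab * u2, radius_b)
            j = int(np.argmax(tot))
            if tot[j] > best[0]:
                best = (float(tot[j]), centers[j], th)
        return best

    _, a, th = search(cand, thetas)
    # fine stage around the coarse optimum
    f_offs = np.arange(-0.5, 0.5 + 1e-9, 0.125)
    fdx, fdy = np.meshgrid(f_offs, f_offs, indexing="ij")
    fine = np.stack([fdx.ravel(), fdy.ravel()], axis=1) + a
    _, a, th = search(fine, th + np.arange(-1.0, 1.0 + 1e-9, 0.25))
    u = np.array([np.cos(np.deg2rad(th)), np.sin(np.deg2rad(th)), 0.0])
    return u, np.array([a[0], a[1], 0.0])


def geometry_stage(cfg: RunConfig, preset, domain_results: dict, out: Path | None = None):
    """Symmetrize per-domain averages with the preset parameters and
    measure diameters and the blade-tilt change."""
    report = {}
    ens_box = int(np.ceil((2 * preset.radius_proximal + 140.0) / cfg.voxel_size / 8)) * 8
    tilts = {}
    for domain, (avg, refined) in domain_results.items():
        params = SymmetryParams(
            blade_radius=preset.radius_of(domain),
            blade_tilt=preset.tilt_of(domain),
            domain=domain,
            center_offset=preset.center_offset,
        )
        ens = symmetrize(avg, params, box=(ens_box, ens_box, cfg.subvolume_box // 2))
        diam = measure_diameter(ens)
        report[f"diameter_{domain}_nm"] = diam
        delta, a_ref = _blade_axis_from_average(avg, params)
        cs = refit_positions(refined, blade_axis_ref=delta,
                             point_offset_ref=a_ref)
        tilts[domain] = measure_blade_tilt(cs)
        report[f"blade_angle_{domain}_deg"] = tilts[domain]
        if out is not None:
            io.write_mrc(out / f"ensemble_{domain}.mrc", ens.volume)
    if "proximal" in tilts and "distal" in tilts:
        report["tilt_change_deg"] = tilt_change(tilts["proximal"], tilts["distal"])
    if out is not None:
        import pandas as pd

        row = {"centriole_id": 0}
        for k in ("diameter_proximal_nm", "diameter_distal_nm",
                  "diameter_fly_nm", "tilt_change_deg"):
            if k in report:
                row[k] = report[k]
        pd.DataFrame([row]).to_csv(out / "geometry_report.tsv", sep="\t",
                                   index=False)
    return report


# ---------------------------------------------------------------------------
# whole run
# ---------------------------------------------------------------------------


def run_pipeline(cfg: RunConfig, out_dir=None) -> dict:
    """Execute all stages; returns the run report (also written as JSON)."""
    cfg.validate()
    t0 = time.time()
    out = Path(out_dir or cfg.out_dir) if (out_dir or cfg.out_dir) else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": asdict(cfg)}
    if out is not None:
        io.save_config(out / "config.yaml", _jsonable(asdict(cfg)))
    wedge = WedgeMask(-cfg.tilt_max, cfg.tilt_max)
    preset = load_preset(cfg.preset)

    log.info("stage simulate: preset=%s e=%.2f snr=%.2f", cfg.preset, cfg.flattening, cfg.snr)
    model, volume, series, tomo = simulate_stage(cfg, out)
    log.info("stage pick: mode=%s", cfg.picking_mode)
    rods, particles, axis = pick_stage(cfg, tomo, model, out)
    report["n_rods"] = len(rods)
    report["n_particles"] = len(particles)

    domain_results = {}
    if cfg.preset == "cho":
        proximal, distal = split_proximal_distal(particles, preset.domain_boundary)
        report["n_proximal"] = len(proximal)
        report["n_distal"] = len(distal)
        groups = {"proximal": proximal, "distal": distal}
    else:
        groups = {"fly": particles}
    all_refined = []
    all_subvols = []
    for domain, group in groups.items():
        log.info("stage align: domain=%s n=%d", domain, len(group))
        avg, refined, scores, subvols, fsc = align_stage(
            cfg, tomo, group, wedge, out, tag=domain
        )
        report[f"mean_cc_{domain}"] = scores
        if fsc is not None:
            report[f"fsc_resolution_{domain}_nm"] = fsc.resolution_at(0.143)
        domain_results[domain] = (avg, refined)
        all_refined.extend(refined)
        all_subvols.extend(subvols)

    # axial bin averages (block maps along the proximal-distal axis)
    if cfg.bin_width and cfg.preset == "cho":
        edges = np.arange(0.0, preset.length - preset.segment_step, cfg.bin_width)
        edges = np.append(edges, edges[-1] + cfg.bin_width)
        binning = AxialBinning(edges)
        bins = axial_bin_average(all_refined, all_subvols, binning, wedge, cfg.voxel_size)
        report["axial_bins"] = [
            {"label": lbl, "n": (avg.n_particles if avg is not None else 0)}
            for lbl, avg in bins
        ]
        if out is not None:
            for lbl, avg in bins:
                if avg is not None:
                    io.write_mrc(out / f"bin_{lbl}.mrc", avg.grid, cfg.voxel_size)

    log.info("stage geometry")
    report.update(geometry_stage(cfg, preset, domain_results, out))

    if cfg.classify_partial_b and cfg.preset == "s2":
        log.info("stage classify: partial-B, k=2")
        avg, refined = domain_results["fly"]
        mask = _b_stub_mask(cfg, preset)
        cm = masked_classify(
            all_refined, all_subvols, mask, k=2, wedge=wedge,
            voxel_size=cfg.voxel_size, seed=cfg.seed_classify,
        )
        cidx, members, lowconf = select_class(cm, "min_mask_density")
        for i, p in enumerate(all_refined):
            p.class_label = int(cm.assignments[i])
        truth_partial = np.array([p.partial_b for p in all_refined])
        pred_partial = cm.assignments == cidx
        agree = float(np.mean(truth_partial == pred_partial))
        report["classify"] = {
            "class_sizes": [int(x) for x in np.bincount(cm.assignments, minlength=2)],
            "partial_class": int(cidx),
            "low_confidence": bool(lowconf),
            "rounds": cm.n_rounds_run,
            "label_agreement": max(agree, 1.0 - agree),
        }
        comp, runs = rebuild_composite(
            all_refined,
            {c: cm.averages[c].grid for c in range(cm.k)},
            tomo.grid.shape,
            cfg.voxel_size,
            origin=tomo.origin,
        )
        report["class_runs"] = runs.to_dict("records")
        if out is not None:
            import pandas as pd

            io.write_mrc(out / "composite.mrc", comp)
            io.write_particles_tsv(out / "particles_classified.tsv", all_refined)
            pd.DataFrame(
                {
                    "round": np.arange(1, len(cm.mean_cc_history) + 1),
                    "mean_cc": cm.mean_cc_history,
                    "class_sizes": [str(s) for s in cm.class_sizes],
                }
            ).to_csv(out / "classification_report.tsv", sep="\t", index=False)

    report["runtime_s"] = round(time.time() - t0, 1)
    if out is not None:
        (out / "report.json").write_text(json.dumps(_jsonable(report), indent=2))
    return report


def _b_stub_mask(cfg: RunConfig, preset) -> np.ndarray:
    """Soft spherical mask over the B03-B06 region of the reference frame."""
    from .model_builder import particle_frame_gamma

    blade = build_blade(blade_spec_for(preset, "fly"), 24.0, seed=0)
    gamma = particle_frame_gamma(
        preset.radius_of("fly"), preset.tilt_of("fly"), preset.center_offset
    )
    centers = tubule_centers_in_reference(blade, gamma, preset.center_offset)
    # B03-B06 sit on the far side of the B circle from the A attachment
    b = centers["B"]
    a = centers["A"]
    d = b - a
    d = d / np.linalg.norm(d)
    target = b + 11.5 * d  # outer B wall, away from A
    box = cfg.subvolume_box
    bc = (box - 1) / 2.0
    xs, ys, zs = np.indices((box, box, box))
    r2 = (
        (xs - bc - target[0] / cfg.voxel_size) ** 2
        + (ys - bc - target[1] / cfg.voxel_size) ** 2
    )
    r_soft = 14.0 / cfg.voxel_size
    mask = np.exp(-np.clip(np.sqrt(r2) - r_soft, 0, None) ** 2 / (2 * (2.0 / cfg.voxel_size) ** 2))
    zmask = np.exp(-np.clip(np.abs(zs - bc) - 12.0 / cfg.voxel_size, 0, None) ** 2
                   / (2 * (2.0 / cfg.voxel_size) ** 2))
    return (mask * zmask).astype(np.float32)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


def make_fixtures(scale: str = "tiny", seed: int = 0) -> dict:
    """Deterministic test fixtures.

    ``tiny``: a 96 nm CHO stub (36 particles) with its noiseless tomogram;
    ``standard``: full-length CHO and S2 models (no tomogram).
    """
    if scale == "tiny":
        preset = load_preset("cho")
        preset.length = 96.0
        preset.domain_boundary = 48.0
        model = assemble_centriole(preset, FlatteningSpec(0.0), seed=seed)
        pos, sig, mas = model.all_blobs()
        lo, hi = pos.min(axis=0) - 8, pos.max(axis=0) + 8
        ext = np.array([hi[0] - lo[0], hi[2] - lo[2], hi[1] - lo[1]])
        box = tuple(int(np.ceil(e / 2.0 / 8.0)) * 8 for e in ext)
        vol = rasterize(model, 2.0, box, mount=True)
        return {"preset": preset, "model": model, "volume": vol}
    if scale == "standard":
        cho = assemble_centriole(load_preset("cho"), FlatteningSpec(0.0), seed=seed)
        s2 = assemble_centriole(load_preset("s2"), FlatteningSpec(0.0), seed=seed + 1)
        return {"cho": cho, "s2": s2}
    raise ConfigError(f"unknown fixture scale {scale!r}")
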