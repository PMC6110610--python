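"""Axial binning and masked hard-assignment classification.

Classification follows the averaging model: orientations stay fixed (no
alignment inside), class membership is re-estimated each round by the
wedge-constrained correlation between the particle and each class average
inside a tight real-space mask.  Initialization is k-means on the top
principal components of wedge-filled, masked voxel vectors -- the missing
wedge of each particle is filled from the current global average so the
wedge orientation itself cannot drive the clustering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .errors import EmptySetError
from .sta import AverageMap, average_particles, resample_residual, _lowpass_mask, _rfft_weights
from .tomo_sim import WedgeMask

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# axial binning
# ---------------------------------------------------------------------------


@dataclass
class AxialBinning:
    """Half-open axial bins [lo, hi) along the proximal-distal axis."""

    edges: np.ndarray  # nm, strictly increasing
    labels: list[str] | None = None

    def __post_init__(self):
        self.edges = np.asarray(self.edges, float)
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if self.labels is None:
            self.labels = [
                f"{self.edges[i]:g}-{self.edges[i+1]:g}nm"
                for i in range(len(self.edges) - 1)
            ]
        if len(self.labels) != len(self.edges) - 1:
            raise ValueError("one label per bin required")

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    def assign(self, s: np.ndarray) -> np.ndarray:
        """Bin index per value; -1 flags out-of-range."""
        s = np.asarray(s, float)
        idx = np.searchsorted(self.edges, s, side="right") - 1
        idx[(s < self.edges[0]) | (s >= self.edges[-1])] = -1
        return idx


def axial_bin_average(
    particles, subvols, binning: AxialBinning, wedge: WedgeMask, voxel_size: float
):
    """One wedge-weighted average per non-empty axial bin.

    Returns a list of ``(label, AverageMap | None)``; ``None`` marks an
    empty bin.
    """
    idx = binning.assign(np.array([p.s for p in particles]))
    out = []
    for b in range(binning.n_bins):
        members = [i for i in range(len(particles)) if idx[i] == b]
        if not members:
            out.append((binning.labels[b], None))
            continue
        avg = average_particles(
            [particles[i] for i in members],
            [subvols[i] for i in members],
            wedge,
            voxel_size,
        )
        out.append((binning.labels[b], avg))
    return out


def split_proximal_distal(particles, boundary: float = 200.0):
    """Particles with s < boundary are proximal; s >= boundary distal."""
    if boundary <= 0:
        return [], list(particles)
    proximal = [p for p in particles if p.s < boundary]
    distal = [p for p in particles if p.s >= boundary]
    return proximal, distal


# ---------------------------------------------------------------------------
# masked classification
# ---------------------------------------------------------------------------


@dataclass
class ClassModel:
    """Result of masked hard-assignment classification."""

    k: int
    assignments: np.ndarray  # (n,) class index per particle
    averages: list[AverageMap]
    mask: np.ndarray
    n_rounds_run: int
    mean_cc_history: list[float] = field(default_factory=list)
    class_sizes: list[tuple[int, ...]] = field(default_factory=list)


def _masked_cc(f_a, f_b, region, weights):
    num = float(np.sum(weights * region * np.real(np.conj(f_a) * f_b)))
    da = float(np.sum(weights * region * np.abs(f_a) ** 2))
    db = float(np.sum(weights * region * np.abs(f_b) ** 2))
    if da <= 0 or db <= 0:
        return 0.0
    return num / np.sqrt(da * db)


def masked_classify(
    particles,
    subvols,
    mask: np.ndarray,
    k: int,
    wedge: WedgeMask,
    voxel_size: float,
    n_rounds: int = 100,
    seed: int = 0,
    lowpass: float | None = None,
) -> ClassModel:
    """Classify fixed-pose particles into ``k`` stable classes.

    The per-round objective (mean within-class masked constrained CC) is
    non-decreasing; iteration stops early once assignments are stable.
    An emptied class is re-seeded from the particle most distant from all
    classes (logged).  Deterministic for a given seed.
    """
    n = len(particles)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError("more classes than particles")
    if n == 0:
        raise EmptySetError("no particles to classify")
    mask = np.asarray(mask, float)
    shape = np.asarray(subvols[0]).shape
    # residual-resampled (aligned) copies, particle wedge regions
    aligned = [
        resample_residual(np.asarray(sv, float), p.residual_rotation(), p.shift / voxel_size)
        for p, sv in zip(particles, subvols)
    ]
    regions = [
        wedge.mask_array(shape, rotation=p.rotation(), rfft=True) for p in particles
    ]
    weights = _rfft_weights(shape)
    lp = _lowpass_mask(shape, voxel_size, lowpass, rfft=True)
    if lp is not None:
        regions = [r & lp for r in regions]
    f_parts = []
    for sv in aligned:
        f = np.fft.rfftn(sv * mask)
        f[0, 0, 0] = 0.0
        f_parts.append(f)
    # --- initialization: PCA on wedge-filled masked voxels, then k-means
    glob = average_particles(particles, subvols, wedge, voxel_size)
    f_glob = np.fft.rfftn(glob.grid.astype(float))
    sel = mask > 0.5 * mask.max()
    feats = np.empty((n, int(sel.sum())), np.float32)
    for i, sv in enumerate(aligned):
        f = np.fft.rfftn(sv)
        filled = np.fft.irfftn(np.where(regions[i], f, f_glob), s=shape, axes=(0, 1, 2))
        feats[i] = filled[sel]
    if k == 1:
        assign = np.zeros(n, int)
    else:
        n_comp = int(min(10, n - 1, feats.shape[1]))
        pcs = PCA(n_components=n_comp, random_state=seed).fit_transform(feats)
        assign = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(pcs)
    history, sizes = [], []
    rounds_run = 0
    for rnd in range(n_rounds):
        rounds_run = rnd + 1
        averages = []
        for c in range(k):
            members = np.flatnonzero(assign == c)
            if len(members) == 0:
                averages.append(None)
                continue
            averages.append(
                average_particles(
                    [particles[i] for i in members],
                    [subvols[i] for i in members],
                    wedge,
                    voxel_size,
                )
            )
        f_cls = []
        for avg in averages:
            if avg is None:
                f_cls.append(None)
                continue
            f = np.fft.rfftn(avg.grid.astype(float) * mask)
            f[0, 0, 0] = 0.0
            f_cls.append(f)
        scores = np.full((n, k), -np.inf)
        for i in range(n):
            for c in range(k):
                if f_cls[c] is None:
                    continue
                scores[i, c] = _masked_cc(f_cls[c], f_parts[i], regions[i], weights)
        new_assign = np.argmax(scores, axis=1)
        # re-seed emptied classes from the least well explained particle
        for c in range(k):
            if not np.any(new_assign == c):
                worst = int(np.argmin(np.max(scores, axis=1)))
                new_assign[worst] = c
                log.info("class %d emptied; re-seeded from particle %d", c, worst)
        history.append(float(np.mean(scores[np.arange(n), new_assign])))
        sizes.append(tuple(int(np.sum(new_assign == c)) for c in range(k)))
        if np.array_equal(new_assign, assign) and rnd > 0:
            break
        assign = new_assign
    averages = []
    for c in range(k):
        members = np.flatnonzero(assign == c)
        averages.append(
            average_particles(
                [particles[i] for i in members],
                [subvols[i] for i in members],
                wedge,
                voxel_size,
            )
        )
    return ClassModel(
        k=k,
        assignments=assign,
        averages=averages,
        mask=mask,
        n_rounds_run=rounds_run,
        mean_cc_history=history,
        class_sizes=sizes,
    )


def select_class(model: ClassModel, criterion: str = "min_mask_density"):
    """Pick the class with extreme mean density inside the mask.

    Returns ``(class_index, particle_indices, low_confidence)``; the
    selection is flagged low-confidence when the between-class density
    contrast is small compared with the in-mask map variation.
    """
    if criterion not in ("min_mask_density", "max_mask_density"):
        raise ValueError(f"unknown criterion {criterion!r}")
    sel = model.mask > 0.5 * model.mask.max()
    dens = np.array([float(avg.grid[sel].mean()) for avg in model.averages])
    c = int(np.argmin(dens) if criterion == "min_mask_density" else np.argmax(dens))
    spread = float(np.ptp(dens))
    scale = float(np.mean([avg.grid[sel].std() for avg in model.averages])) or 1.0
    low_confidence = spread < 0.2 * scale
    members = np.flatnonzero(model.assignments == c)
    return c, members, low_confidence
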