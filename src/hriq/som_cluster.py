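"""Self-organizing-map cluster analysis and hepatorenal-index computation.

Each ROI's pixel intensities (normalized to [0, 1]) are clustered by a small
two-dimensional Kohonen map: for every sample the most similar node
(minimum squared distance) wins and every node within the neighbourhood
radius of the winner moves a fraction ``alpha`` toward the sample.  After a
fixed number of passes the learning rate is decayed multiplicatively and the
radius shrunk; training stops once ``alpha`` falls below its floor or the
radius is no longer positive.

Trained node weights are then quantized into fixed-width intensity bins —
nodes sharing a bin merge into one cluster, which absorbs the ultrasound
distractions (speckle, faint vessels) that would otherwise split a tissue
field across nodes.  The ROI's representative intensity is the mean of the
pixels in the largest cluster, and the hepatorenal index difference
(HRI-diff) is the liver representative minus the kidney representative.
A brighter-than-kidney liver indicates steatosis; default severity bands are
the midpoints between representative class means observed clinically
(normal/mild boundary 5.113, mild/moderate boundary 15.230 intensity units).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SOMConfig",
    "SOMGrid",
    "ClusterStats",
    "HRIReport",
    "DEFAULT_SEVERITY_BANDS",
    "find_winner",
    "update_weights",
    "train_som",
    "quantize_clusters",
    "representative_intensity",
    "compute_hri",
    "quantify_roi",
]

#: normal/mild and mild/moderate HRI-diff boundaries (8-bit intensity units)
DEFAULT_SEVERITY_BANDS: tuple[float, float] = (5.113, 15.230)


@dataclass
class SOMConfig:
    grid_rows: int = 4
    grid_cols: int = 4
    alpha0: float = 0.9
    alpha_decay: float = 0.9
    r0: float = 2.0
    r_decrement: float = 1.0
    epochs_per_stage: int = 5
    alpha_stop: float = 0.2
    seed: int = 0
    #: training subsample ceiling; larger ROIs are subsampled (seeded) for
    #: the sequential updates, then assigned in full when clustering
    max_samples: int = 4096

    def __post_init__(self):
        if self.grid_rows * self.grid_cols < 2:
            raise ValueError("SOM grid needs at least 2 nodes")
        if not (0 < self.alpha0 <= 1):
            raise ValueError("alpha0 must be in (0, 1]")
        if not (0 < self.alpha_decay < 1):
            raise ValueError("alpha_decay must be in (0, 1)")
        if self.alpha_stop >= self.alpha0:
            raise ValueError("alpha_stop must be below alpha0")


@dataclass
class SOMGrid:
    weights: np.ndarray | None = None  # (grid_rows, grid_cols), normalized units
    trained: bool = False


@dataclass
class ClusterStats:
    quantized_level: int
    pixel_count: int
    mean_intensity: float
    member_nodes: list[tuple[int, int]] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["member_nodes"] = [list(n) for n in self.member_nodes]
        return d


@dataclass
class HRIReport:
    liver_rep: float
    kidney_rep: float
    liver_cluster_count: int
    kidney_cluster_count: int
    hri_diff: float
    severity: str
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def find_winner(grid: SOMGrid, x: float) -> tuple[int, int]:
    """Node minimizing the squared distance to ``x``; ties go to the first
    node in row-major order."""
    if grid.weights is None:
        raise RuntimeError("SOM grid is not initialized")
    d2 = (grid.weights - x) ** 2
    flat = int(np.argmin(d2))  # first minimum in C order == row-major tie-break
    return flat // grid.weights.shape[1], flat % grid.weights.shape[1]


def update_weights(
    grid: SOMGrid, winner: tuple[int, int], x: float, alpha: float, r: float
) -> SOMGrid:
    """Move every node within Chebyshev radius ``r`` of the winner a fraction
    ``alpha`` toward ``x`` (in place); a radius of 0 updates only the winner."""
    if grid.weights is None:
        raise RuntimeError("SOM grid is not initialized")
    i, j = winner
    ri = int(r)
    rows, cols = grid.weights.shape
    r0, r1 = max(0, i - ri), min(rows, i + ri + 1)
    c0, c1 = max(0, j - ri), min(cols, j + ri + 1)
    w = grid.weights[r0:r1, c0:c1]
    w += alpha * (x - w)
    return grid


def train_som(intensities, cfg: SOMConfig) -> SOMGrid:
    """Train a map on scalar samples (normalized units, typically [0, 1]).

    Weights start as seeded uniform draws over the sample range; samples are
    presented in a freshly shuffled order each pass.  Every update is a
    convex combination of the old weight and the sample, so trained weights
    never leave the sample range.
    """
    x = np.asarray(intensities, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("cannot train a SOM on an empty sample set")
    rng = np.random.default_rng(cfg.seed)
    if x.size > cfg.max_samples:
        x = rng.choice(x, size=cfg.max_samples, replace=False)
    lo, hi = float(x.min()), float(x.max())
    grid = SOMGrid(weights=rng.uniform(lo, hi, size=(cfg.grid_rows, cfg.grid_cols)))

    n = x.size
    alpha, r = cfg.alpha0, cfg.r0
    while alpha >= cfg.alpha_stop and r > 0:
        for _ in range(cfg.epochs_per_stage):
            for idx in rng.permutation(n):
                xv = x[idx]
                update_weights(grid, find_winner(grid, xv), xv, alpha, r)
        alpha *= cfg.alpha_decay
        r -= cfg.r_decrement
    grid.trained = True
    return grid


def quantize_clusters(
    grid: SOMGrid, intensities, bin_width: int = 8
) -> list[ClusterStats]:
    """Assign pixels to winner nodes, merge nodes by intensity bin.

    ``intensities`` are on the 0–255 scale; assignment happens in normalized
    units.  Node weights are mapped back to 0–255 and binned at ``bin_width``
    levels; nodes in one bin form one cluster.  Only nonempty clusters are
    returned, sorted by quantized level, and their pixel counts sum to the
    ROI size.
    """
    if not grid.trained:
        raise RuntimeError("SOM grid is not trained")
    x = np.asarray(intensities, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("no pixels to cluster")
    w = grid.weights
    xn = x / 255.0
    d2 = (w.reshape(-1, 1) - xn.reshape(1, -1)) ** 2
    winners = np.argmin(d2, axis=0)  # first minimum == row-major tie-break

    node_levels = np.clip(np.rint(w.ravel() * 255.0), 0, 255).astype(int)
    node_bins = node_levels // int(bin_width)
    ncols = w.shape[1]

    clusters: dict[int, ClusterStats] = {}
    for flat_node in range(w.size):
        members = winners == flat_node
        count = int(members.sum())
        if count == 0:
            continue
        b = int(node_bins[flat_node])
        node_rc = (flat_node // ncols, flat_node % ncols)
        if b in clusters:
            cs = clusters[b]
            total = cs.pixel_count + count
            cs.mean_intensity = (
                cs.mean_intensity * cs.pixel_count + float(x[members].sum())
            ) / total
            cs.pixel_count = total
            cs.member_nodes.append(node_rc)
        else:
            clusters[b] = ClusterStats(
                quantized_level=b,
                pixel_count=count,
                mean_intensity=float(x[members].mean()),
                member_nodes=[node_rc],
            )
    return [clusters[b] for b in sorted(clusters)]


def representative_intensity(stats: list[ClusterStats]) -> float:
    """Mean intensity of the largest cluster (ties: lower quantized level)."""
    if not stats:
        raise ValueError("no clusters to summarize")
    best = min(stats, key=lambda s: (-s.pixel_count, s.quantized_level))
    return float(best.mean_intensity)


def compute_hri(
    liver_rep: float,
    kidney_rep: float,
    bands: tuple[float, float] = DEFAULT_SEVERITY_BANDS,
    liver_cluster_count: int = 0,
    kidney_cluster_count: int = 0,
    meta: dict | None = None,
) -> HRIReport:
    """HRI-diff = liver representative − kidney representative, with severity.

    Severity bands are configurable thresholds on HRI-diff; a negative
    difference (kidney brighter than liver) is graded normal with a note.
    """
    lo, hi = bands
    if not lo < hi:
        raise ValueError("severity bands must be strictly increasing")
    hri = float(liver_rep) - float(kidney_rep)
    if hri < 0:
        logger.info("HRI-diff %.3f is negative; graded normal", hri)
        severity = "normal"
    elif hri < lo:
        severity = "normal"
    elif hri < hi:
        severity = "mild"
    else:
        severity = "moderate"
    return HRIReport(
        liver_rep=float(liver_rep),
        kidney_rep=float(kidney_rep),
        liver_cluster_count=liver_cluster_count,
        kidney_cluster_count=kidney_cluster_count,
        hri_diff=hri,
        severity=severity,
        meta=meta or {},
    )


def quantify_roi(
    img, mask, cfg: SOMConfig, bin_width: int = 8
) -> tuple[float, int, list[ClusterStats]]:
    """Representative intensity and cluster count of one ROI.

    Trains the map on the ROI's normalized pixel intensities, quantizes, and
    returns (representative, nonempty-cluster count, cluster table).
    """
    a = np.asarray(img)
    m = np.asarray(mask, dtype=bool)
    vals = a[m].astype(np.float64)
    if vals.size == 0:
        raise ValueError("ROI mask selects no pixels")
    grid = train_som(vals / 255.0, cfg)
    stats = quantize_clusters(grid, vals, bin_width=bin_width)
    return representative_intensity(stats), len(stats), stats
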