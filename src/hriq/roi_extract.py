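"""ROI extraction: binarization, edge-tracking labeling, and mask logic.

The extractor isolates the two parenchyma fields whose brightness the
hepatorenal index compares.  On the contrast-enhanced scan it (1) thresholds
at the positive-pixel mean, (2) labels connected bright objects with an
edge-tracking tracer, (3) discards objects too small or too large to be
anatomy, (4) restores the liver–kidney limiting membrane if the enhancement
fragmented it, and (5) carves the liver field out of the band between the
fascia and the membrane, and the renal-cortex field out of the interior of
the perirenal-fat annulus — in both cases as the complement ("reverse
binarization") of the bright structures AND-ed with the inter-landmark band.

Region membership uses 8-connectivity.  The boundary tracer rotates its
probe clockwise in 45-degree steps from the direction it came from; along a
convex stretch this consults at most a five-heading, 180-degree fan around
the current heading.  The trace closes when it returns to its start pixel
about to repeat its first move.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_fill_holes
from skimage.morphology import closing, disk

logger = logging.getLogger(__name__)

__all__ = [
    "ExtractionError",
    "LabeledRegion",
    "RegionSet",
    "ROIPair",
    "average_binarize",
    "trace_and_label",
    "filter_noise",
    "restore_boundaries",
    "extract_rois",
    "identify_landmarks",
]

MIN_OBJECT_AREA = 200
MAX_OBJECT_AREA = 20000

# headings clockwise from East; index k -> (drow, dcol)
_OFFSETS = ((0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1))
_NEIGHBOURS_8 = _OFFSETS


class ExtractionError(RuntimeError):
    """Raised when an anatomical landmark cannot be identified; names the stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"{stage}: {message}")


@dataclass
class LabeledRegion:
    """A connected bright object: its pixels, closed boundary circuit, and stats."""

    label: int
    pixels: np.ndarray  # (n, 2) array of (row, col)
    boundary_path: list[tuple[int, int]]

    @property
    def area(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def pixel_set(self) -> set[tuple[int, int]]:
        return {(int(r), int(c)) for r, c in self.pixels}

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        """(top, left, bottom, right), half-open."""
        r = self.pixels[:, 0]
        c = self.pixels[:, 1]
        return (int(r.min()), int(c.min()), int(r.max()) + 1, int(c.max()) + 1)

    @property
    def width(self) -> int:
        b = self.bbox
        return b[3] - b[1]

    @property
    def mean_row(self) -> float:
        return float(self.pixels[:, 0].mean())

    @property
    def centroid_col(self) -> float:
        return float(self.pixels[:, 1].mean())

    def to_dict(self) -> dict:
        return {"label": self.label, "area": self.area, "bbox": list(self.bbox)}


@dataclass
class RegionSet:
    """Labeled connected objects plus the dimensions of their source raster."""

    regions: list[LabeledRegion]
    source_dims: tuple[int, int]  # (height, width)

    def __len__(self) -> int:
        return len(self.regions)

    def mask(self, regions=None) -> np.ndarray:
        """Union binary mask of the given regions (default: all)."""
        m = np.zeros(self.source_dims, dtype=bool)
        for reg in (self.regions if regions is None else regions):
            m[reg.pixels[:, 0], reg.pixels[:, 1]] = True
        return m

    def to_json(self) -> list[dict]:
        return [r.to_dict() for r in self.regions]


@dataclass
class ROIPair:
    liver_mask: np.ndarray
    kidney_mask: np.ndarray
    landmarks: dict = field(default_factory=dict)


def average_binarize(img) -> np.ndarray:
    """Threshold at the mean of strictly positive pixels.

    Pixels at 0 (the stretched-away dark background) never count, neither
    toward the threshold nor the foreground.  A pixel exactly at the
    threshold is foreground.  An image with no positive pixel yields an
    all-zero mask.
    """
    a = np.asarray(img)
    if a.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    pos = a > 0
    if not pos.any():
        return np.zeros_like(a, dtype=bool)
    t = a[pos].mean(dtype=np.float64)
    return pos & (a >= t)


def _bfs_fill(mask: np.ndarray, visited: np.ndarray, r0: int, c0: int) -> np.ndarray:
    """Collect the 8-connected component containing (r0, c0)."""
    H, W = mask.shape
    out = [(r0, c0)]
    visited[r0, c0] = True
    q = deque(out)
    while q:
        r, c = q.popleft()
        for dr, dc in _NEIGHBOURS_8:
            nr, nc = r + dr, c + dc
            if 0 <= nr < H and 0 <= nc < W and mask[nr, nc] and not visited[nr, nc]:
                visited[nr, nc] = True
                out.append((nr, nc))
                q.append((nr, nc))
    return np.array(out, dtype=np.intp)


def _trace_boundary(mask: np.ndarray, r0: int, c0: int, area: int) -> list | None:
    """Boundary follower from the region's top-left pixel.

    At each step the continuation is probed in 45-degree clockwise rotations
    starting just clockwise of the backtrack direction (the pixel we came
    from), so the trace hugs the region's outer boundary; on a convex
    stretch at most five probes — a 180-degree fan around the heading — are
    consulted.  The circuit closes when the tracer stands on the start pixel
    about to repeat its first move.  Returns the closed path
    (first == last), or None if the step bound is exceeded without closure
    (divergent; the region is then discarded).
    """
    H, W = mask.shape
    start = (r0, c0)
    path = [start]
    cur = start
    backtrack = 4  # West: row above and left neighbour of the start are background
    first_move = None
    bound = max(4 * (H + W), 8 * area + 8)
    steps = 0
    closed = False
    while steps < bound:
        d = None
        for k in range(1, 9):
            cand = (backtrack + k) % 8
            nr = cur[0] + _OFFSETS[cand][0]
            nc = cur[1] + _OFFSETS[cand][1]
            if 0 <= nr < H and 0 <= nc < W and mask[nr, nc]:
                d = cand
                break
        if d is None:  # isolated pixel
            closed = True
            break
        if cur == start:
            if first_move is None:
                first_move = d
            elif d == first_move:  # back where we began, same move next: closed
                closed = True
                break
        cur = (nr, nc)
        path.append(cur)
        backtrack = (d + 4) % 8
        steps += 1
    if not closed and not (steps < bound):
        return None
    if path[-1] != start:
        path.append(start)
    return path


def trace_and_label(mask) -> RegionSet:
    """Label every 8-connected foreground component and trace its boundary.

    Components are discovered in raster order, so each region's trace starts
    at its top-most then left-most pixel with an initial East heading.  A
    region whose boundary trace diverges (fails to close within its step
    bound) is discarded with a warning; this is defensive only — a valid
    8-connected component always closes.
    """
    m = np.ascontiguousarray(np.asarray(mask).astype(bool))
    if m.ndim != 2:
        raise ValueError("expected a 2-D binary mask")
    visited = np.zeros_like(m)
    regions: list[LabeledRegion] = []
    label = 0
    for r0, c0 in np.argwhere(m):
        if visited[r0, c0]:
            continue
        pixels = _bfs_fill(m, visited, int(r0), int(c0))
        path = _trace_boundary(m, int(r0), int(c0), pixels.shape[0])
        if path is None:
            logger.warning(
                "edge tracking diverged for region at (%d, %d), area %d; discarded",
                r0, c0, pixels.shape[0],
            )
            continue
        label += 1
        regions.append(LabeledRegion(label=label, pixels=pixels, boundary_path=path))
    return RegionSet(regions=regions, source_dims=m.shape)


def filter_noise(
    rs: RegionSet,
    min_area: int = MIN_OBJECT_AREA,
    max_area: int = MAX_OBJECT_AREA,
) -> RegionSet:
    """Keep regions whose area lies in [min_area, max_area]; rest is noise."""
    kept = [r for r in rs.regions if min_area <= r.area <= max_area]
    return RegionSet(regions=kept, source_dims=rs.source_dims)


def _find_fascia(rs: RegionSet, fascia_width_frac: float) -> LabeledRegion:
    W = rs.source_dims[1]
    wide = [r for r in rs.regions if r.width >= fascia_width_frac * W]
    if not wide:
        raise ExtractionError("fascia", "no retained bright region spans "
                              f">= {fascia_width_frac:.0%} of the image width")
    return min(wide, key=lambda r: r.mean_row)


def _find_kidney_fat(rs: RegionSet, fascia: LabeledRegion, right_frac: float) -> LabeledRegion:
    W = rs.source_dims[1]
    cands = [
        r for r in rs.regions
        if r is not fascia and r.mean_row > fascia.mean_row
        and r.centroid_col >= right_frac * W
    ]
    if not cands:
        raise ExtractionError("kidney fat", "no bright region below the fascia "
                              "in the right half of the image")
    return max(cands, key=lambda r: r.mean_row)


def identify_landmarks(
    rs: RegionSet,
    fascia_width_frac: float = 0.4,
    right_frac: float = 0.5,
) -> dict:
    """Assign anatomical roles to the retained bright regions.

    fascia: top-most wide region; kidney fat: bottom-most region in the
    right half; membrane: wide region(s) whose mean row lies strictly
    between the two (falling back to any in-between region when no wide one
    exists).  Raises ExtractionError naming the missing landmark.
    """
    fascia = _find_fascia(rs, fascia_width_frac)
    kidney_fat = _find_kidney_fat(rs, fascia, right_frac)
    between = [
        r for r in rs.regions
        if r not in (fascia, kidney_fat)
        and fascia.mean_row < r.mean_row < kidney_fat.mean_row
    ]
    W = rs.source_dims[1]
    wide_between = [r for r in between if r.width >= fascia_width_frac * W]
    membrane = wide_between or between
    if not membrane:
        raise ExtractionError("limiting membrane", "no bright region between "
                              "the fascia and the kidney-fat area")
    return {"fascia": fascia, "membrane": membrane, "kidney_fat": kidney_fat}


def _corridor_rows(fascia: LabeledRegion, kidney_fat: LabeledRegion,
                   dims: tuple[int, int]) -> tuple[int, int]:
    top = fascia.bbox[2]           # first row below the fascia
    bottom = kidney_fat.bbox[0]    # first row of the kidney-fat area
    if bottom <= top:
        raise ExtractionError("boundary restoration",
                              "fascia and kidney-fat areas are not vertically ordered")
    return top, bottom


def restore_boundaries(
    img,
    rs: RegionSet,
    closing_radius: int = 5,
    fascia_width_frac: float = 0.4,
    right_frac: float = 0.5,
    min_area: int = MIN_OBJECT_AREA,
    max_area: int = MAX_OBJECT_AREA,
) -> RegionSet:
    """Reconnect a limiting membrane lost to enhancement and noise filtering.

    The membrane is the faintest landmark and may fragment into sub-threshold
    pieces.  If a membrane candidate already exists between the fascia and
    the kidney-fat area the set is returned unchanged.  Otherwise the
    corridor between those two landmarks is re-binarized at its own
    positive-pixel mean, the result is morphologically bridged (closing with
    a disk) together with the retained bright regions, and the corridor part
    of the bridged image is merged back, relabeled and re-filtered.
    """
    a = np.asarray(img)
    if len(rs.regions) < 2:
        raise ExtractionError("boundary restoration",
                              "fewer than 2 bright landmark candidates survive filtering")
    fascia = _find_fascia(rs, fascia_width_frac)
    kidney_fat = _find_kidney_fat(rs, fascia, right_frac)
    try:
        identify_landmarks(rs, fascia_width_frac, right_frac)
        return rs  # membrane already connected; nothing to restore
    except ExtractionError:
        pass

    top, bottom = _corridor_rows(fascia, kidney_fat, rs.source_dims)
    corridor = np.zeros(rs.source_dims, dtype=bool)
    corridor[top:bottom, :] = True

    bright = rs.mask()
    corridor_fg = average_binarize(np.where(corridor, a, 0))
    bridged = closing(bright | corridor_fg, disk(closing_radius)).astype(bool)
    final = bright | (bridged & corridor)

    out = filter_noise(trace_and_label(final), min_area, max_area)
    restored = [
        r for r in out.regions
        if top <= r.bbox[0] and r.bbox[2] <= bottom
    ]
    if not restored:
        raise ExtractionError("limiting membrane",
                              "no membrane signal found in the corridor between "
                              "the fascia and the kidney-fat area")
    return out


def extract_rois(
    rs: RegionSet,
    img,
    fascia_width_frac: float = 0.4,
    right_frac: float = 0.5,
) -> ROIPair:
    """Carve the liver and renal-cortex parenchyma fields from the landmarks.

    The liver field is the band strictly between the fascia's lower envelope
    and the membrane's upper envelope (per column); the renal cortex is the
    field enclosed by the perirenal-fat annulus, below the membrane's lower
    envelope.  Both are AND-ed with the complement of every retained bright
    region (reverse binarization), so the masks never touch a bright object.
    """
    H, W = rs.source_dims
    lm = identify_landmarks(rs, fascia_width_frac, right_frac)
    fascia: LabeledRegion = lm["fascia"]
    kidney_fat: LabeledRegion = lm["kidney_fat"]
    membrane_mask = rs.mask(lm["membrane"])
    bright_all = rs.mask()

    if not (fascia.mean_row < kidney_fat.mean_row):
        raise ExtractionError("landmark ordering",
                              "fascia does not lie above the kidney-fat area")

    rows = np.arange(H)[:, None]

    # fascia lower envelope per column (bbox bottom where the column is empty)
    fa_mask = rs.mask([fascia])
    fa_any = fa_mask.any(axis=0)
    fa_low = np.where(
        fa_any,
        (rows * fa_mask).max(axis=0),
        fascia.bbox[2] - 1,
    )

    mem_any = membrane_mask.any(axis=0)
    if not mem_any.any():
        raise ExtractionError("limiting membrane", "membrane mask is empty")
    big = H + 1
    mem_up = np.where(mem_any, np.where(membrane_mask, rows, big).min(axis=0), -1)
    mem_global_low = int(np.argwhere(membrane_mask)[:, 0].max())
    mem_low = np.where(mem_any, (rows * membrane_mask).max(axis=0), mem_global_low)

    liver = (
        mem_any[None, :]
        & (rows > fa_low[None, :])
        & (rows < mem_up[None, :])
        & ~bright_all
    )

    kf_mask = rs.mask([kidney_fat])
    kidney = (
        binary_fill_holes(kf_mask)
        & ~kf_mask
        & (rows > mem_low[None, :])
        & ~bright_all
    )

    if not liver.any():
        raise ExtractionError("liver parenchyma",
                              "no pixels between the fascia and the limiting membrane")
    if not kidney.any():
        raise ExtractionError("renal parenchyma",
                              "no pixels enclosed by the kidney-fat area below the membrane")
    return ROIPair(liver_mask=liver, kidney_mask=kidney,
                   landmarks={"fascia": fascia.to_dict(),
                              "kidney_fat": kidney_fat.to_dict(),
                              "membrane": [m.to_dict() for m in lm["membrane"]]})
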