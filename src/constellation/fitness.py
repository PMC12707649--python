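"""Structural fitness: how well a candidate image's edges fit the dots.

The score of a candidate is the number of constellation dots that
(a) lie within a pixel tolerance (default 3 px, strict ``<``) of the
candidate's traced edge contours, and (b) are linked to an adjacent
matched dot along the same contour by less than a path-length threshold
(default 40 px).  Rule (b) stops the search from rewarding arbitrarily
long, unrealistic drawings that sweep through dots without connecting
them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from skimage.feature import canny as _canny

from .data import ConstellationImage, DotSet
from .errors import ContractError
from .imageops import resize_bilinear, to_grey01

# 4-neighbours first, then diagonals; fixed order keeps tracing deterministic
_NEIGHBOUR_OFFSETS = ((0, 1), (1, 0), (0, -1), (-1, 0),
                      (1, 1), (1, -1), (-1, 1), (-1, -1))


@dataclass
class Contour:
    """An ordered 8-connected pixel polyline."""

    points: np.ndarray          # (n, 2) float, columns (x, y)
    closed: bool

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        self._cum = None

    @property
    def arc_positions(self) -> np.ndarray:
        """Cumulative arc length at each point (0 at the first point)."""
        if self._cum is None:
            if len(self.points) < 2:
                self._cum = np.zeros(len(self.points))
            else:
                seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
                self._cum = np.concatenate([[0.0], np.cumsum(seg)])
        return self._cum

    @property
    def length(self) -> float:
        """Total arc length (including the closing segment if closed)."""
        base = float(self.arc_positions[-1]) if len(self.points) else 0.0
        if self.closed and len(self.points) >= 2:
            base += float(np.linalg.norm(self.points[-1] - self.points[0]))
        return base


@dataclass
class ContourSet:
    contours: list[Contour] = field(default_factory=list)

    def __len__(self):
        return len(self.contours)

    def all_points(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Concatenate points -> (points (M,2), contour ids, point indices)."""
        if not self.contours:
            z = np.zeros(0, dtype=int)
            return np.zeros((0, 2)), z, z
        pts = np.vstack([c.points for c in self.contours])
        cids = np.concatenate([np.full(len(c.points), i, dtype=int)
                               for i, c in enumerate(self.contours)])
        pidx = np.concatenate([np.arange(len(c.points))
                               for c in self.contours])
        return pts, cids, pidx


@dataclass
class FitnessConfig:
    """Tolerances of the structural fitness.

    `edge_threshold` — max dot-to-edge distance for a dot to match (px).
    `link_threshold` — max gap between adjacent matched dots on one
    contour for them to contribute (px).  `link_metric` selects whether
    the gap is measured along the contour ("arc", default) or as the
    Euclidean distance between the dots ("euclidean").
    Canny thresholds are on an 8-bit intensity scale.
    """

    edge_threshold: float = 3.0
    link_threshold: float = 40.0
    canny_low: float = 100.0
    canny_high: float = 200.0
    canny_sigma: float = 1.0
    link_metric: str = "arc"

    def __post_init__(self):
        if self.edge_threshold <= 0:
            raise ContractError("edge_threshold must be > 0")
        if self.link_threshold <= self.edge_threshold:
            raise ContractError("link_threshold must exceed edge_threshold")
        if self.link_metric not in ("arc", "euclidean"):
            raise ContractError(f"unknown link_metric {self.link_metric!r}")


@dataclass
class DotMatch:
    """Per-dot nearest-contour assignment."""

    dot_index: int
    contour_id: int
    point_index: int
    distance: float
    arc_position: float


@dataclass
class FitnessResult:
    score: int
    matched: np.ndarray         # dot indices within edge_threshold
    contributing: np.ndarray    # matched dots surviving the link rule
    per_dot: list[DotMatch]

    def to_dict(self) -> dict:
        return {
            "score": int(self.score),
            "matched": [int(i) for i in self.matched],
            "contributing": [int(i) for i in self.contributing],
        }


# ---------------------------------------------------------------------------
# Edge detection and contour tracing
# ---------------------------------------------------------------------------

def trace_pixel_chains(edge_mask: np.ndarray) -> ContourSet:
    """Order the pixels of a binary edge map into 8-connected chains.

    Chains start at degree-1 pixels when one exists (open curves) and at
    the lowest scan-order pixel otherwise (loops); junctions split the
    edge set into several chains, each pixel used once.  Deterministic.
    """
    mask = np.asarray(edge_mask, dtype=bool)
    remaining = {(int(r), int(c)) for r, c in zip(*np.nonzero(mask))}
    contours: list[Contour] = []
    while remaining:
        # prefer an endpoint (<=1 unused neighbour); ties by scan order
        best = None
        best_key = None
        for p in remaining:
            deg = sum((p[0] + dr, p[1] + dc) in remaining
                      for dr, dc in _NEIGHBOUR_OFFSETS)
            key = (deg > 1, p)
            if best_key is None or key < best_key:
                best, best_key = p, key
        path = [best]
        remaining.discard(best)
        cur = best
        while True:
            nxt = None
            for dr, dc in _NEIGHBOUR_OFFSETS:
                cand = (cur[0] + dr, cur[1] + dc)
                if cand in remaining:
                    nxt = cand
                    break
            if nxt is None:
                break
            path.append(nxt)
            remaining.discard(nxt)
            cur = nxt
        pts = np.array([[c, r] for r, c in path], dtype=float)
        closed = (len(path) >= 3
                  and max(abs(path[0][0] - path[-1][0]),
                          abs(path[0][1] - path[-1][1])) <= 1)
        contours.append(Contour(points=pts, closed=closed))
    return ContourSet(contours=contours)


def detect_edges(image: np.ndarray, cfg: FitnessConfig | None = None) -> ContourSet:
    """Canny edge detection traced into ordered pixel polylines."""
    cfg = cfg or FitnessConfig()
    grey = to_grey01(image) * 255.0
    if grey.size == 0 or grey.max() == grey.min():
        return ContourSet([])
    edges = _canny(grey, sigma=cfg.canny_sigma,
                   low_threshold=cfg.canny_low, high_threshold=cfg.canny_high)
    if edges.any():
        # thin doubled pixels so traced chains are 1 px wide; otherwise
        # staircase duplicates inflate arc lengths
        from skimage.morphology import skeletonize
        edges = skeletonize(edges)
    return trace_pixel_chains(edges)


# ---------------------------------------------------------------------------
# Dot matching and the contour-link rule
# ---------------------------------------------------------------------------

def match_dots(contours: ContourSet, dots: DotSet,
               edge_threshold: float) -> list[DotMatch]:
    """Match each dot to its nearest contour point; keep dots with
    distance strictly below `edge_threshold`.  Ties go to the lowest
    contour index (then lowest point index)."""
    if edge_threshold <= 0:
        raise ContractError("edge_threshold must be > 0")
    pts, cids, pidx = contours.all_points()
    if len(pts) == 0 or len(dots) == 0:
        return []
    d = cdist(dots.coords, pts)
    matches = []
    for i in range(len(dots)):
        j = int(np.argmin(d[i]))   # first minimum -> lowest contour id
        if d[i, j] < edge_threshold:
            cid = int(cids[j])
            matches.append(DotMatch(
                dot_index=i, contour_id=cid, point_index=int(pidx[j]),
                distance=float(d[i, j]),
                arc_position=float(
                    contours.contours[cid].arc_positions[pidx[j]])))
    return matches


def connectivity_filter(matches: list[DotMatch], contours: ContourSet,
                        link_threshold: float, dots: DotSet | None = None,
                        link_metric: str = "arc") -> np.ndarray:
    """Keep matched dots whose gap to an adjacent matched dot on the same
    contour is strictly below `link_threshold`.

    Dots on one contour are ordered by arc position; for closed contours
    the gap wraps around.  A contour's sole matched dot never contributes.
    Returns the contributing dot indices, sorted.
    """
    if link_metric == "euclidean" and dots is None:
        raise ContractError("euclidean link metric needs the dot coordinates")
    by_contour: dict[int, list[DotMatch]] = {}
    for m in matches:
        by_contour.setdefault(m.contour_id, []).append(m)
    contributing: list[int] = []
    for cid, group in by_contour.items():
        if len(group) < 2:
            continue
        group = sorted(group, key=lambda m: (m.arc_position, m.dot_index))
        contour = contours.contours[cid]
        n = len(group)
        gaps = np.full(n + 1, np.inf)   # gaps[i] between group[i-1], group[i]
        for i in range(1, n):
            gaps[i] = _gap(group[i - 1], group[i], contour, dots, link_metric)
        if contour.closed:
            wrap = _wrap_gap(group[0], group[-1], contour, dots, link_metric)
            gaps[0] = gaps[n] = wrap
        for i, m in enumerate(group):
            if min(gaps[i], gaps[i + 1]) < link_threshold:
                contributing.append(m.dot_index)
    return np.array(sorted(contributing), dtype=int)


def _gap(a: DotMatch, b: DotMatch, contour: Contour,
         dots: DotSet | None, metric: str) -> float:
    if metric == "arc":
        return abs(b.arc_position - a.arc_position)
    return float(np.linalg.norm(dots.coords[b.dot_index]
                                - dots.coords[a.dot_index]))


def _wrap_gap(first: DotMatch, last: DotMatch, contour: Contour,
              dots: DotSet | None, metric: str) -> float:
    if metric == "arc":
        return contour.length - (last.arc_position - first.arc_position)
    return float(np.linalg.norm(dots.coords[first.dot_index]
                                - dots.coords[last.dot_index]))


def fitness(candidate: np.ndarray, dots: DotSet,
            cfg: FitnessConfig | None = None) -> FitnessResult:
    """Full pipeline: edges -> dot matching -> contour-link rule -> score.

    The candidate must already be at the constellation's resolution.
    """
    cfg = cfg or FitnessConfig()
    contours = detect_edges(candidate, cfg)
    matches = match_dots(contours, dots, cfg.edge_threshold)
    contributing = connectivity_filter(matches, contours, cfg.link_threshold,
                                       dots=dots, link_metric=cfg.link_metric)
    matched = np.array(sorted(m.dot_index for m in matches), dtype=int)
    return FitnessResult(score=int(len(contributing)), matched=matched,
                         contributing=contributing, per_dot=matches)


def score_candidate(image: np.ndarray, stimulus: ConstellationImage,
                    cfg: FitnessConfig | None = None) -> FitnessResult:
    """Score a generator-resolution candidate against a stimulus
    (greyscale conversion and bilinear upscaling included)."""
    grey = to_grey01(image)
    h, w = stimulus.size
    if grey.shape != (h, w):
        grey = resize_bilinear(grey, h, w)
    return fitness(grey, stimulus.dots, cfg)
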