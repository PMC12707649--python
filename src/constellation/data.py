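"""Constellation stimuli: dotted object outlines among distractor dots.

A constellation image hides an object by sampling dots at a fixed arc
spacing along its outline and scattering additional noise dots.  The
spacing is the difficulty level: the wider the spacing, the sparser the
evidence and the harder the stimulus.  Stimuli are single-channel rasters
(default 160x160) with a JSON sidecar holding the exact dot coordinates;
the raster is authoritative for pixels, the sidecar for coordinates.

Coordinates are (x, y) = (column, row), 0-based, origin top-left, stored
as floats and rendered by rounding to the nearest pixel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import CapacityError, ContractError, DegenerateShapeError

CONTOUR = "contour"
DISTRACTOR = "distractor"

DEFAULT_SIZE = 160
DEFAULT_SPACING = 11.0   # difficulty level of the main experiments
DEFAULT_NOISE_RATIO = 0.5
DEFAULT_DOT_RADIUS = 1.5


@dataclass
class DotSet:
    """Dot centres with per-dot roles (contour vs distractor)."""

    coords: np.ndarray          # (n, 2) float, columns (x, y)
    roles: np.ndarray           # (n,) of {"contour", "distractor"}

    def __post_init__(self):
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if self.coords.size == 0:
            self.coords = self.coords.reshape(0, 2)
        self.roles = np.asarray(self.roles, dtype=object)
        if self.coords.shape[0] != self.roles.shape[0]:
            raise ContractError("coords and roles length mismatch")

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def contour_indices(self) -> np.ndarray:
        return np.flatnonzero(self.roles == CONTOUR)

    @property
    def distractor_indices(self) -> np.ndarray:
        return np.flatnonzero(self.roles == DISTRACTOR)

    @classmethod
    def empty(cls) -> "DotSet":
        return cls(np.zeros((0, 2)), np.zeros((0,), dtype=object))

    def to_records(self) -> list[dict]:
        return [{"x": float(x), "y": float(y), "role": str(r)}
                for (x, y), r in zip(self.coords, self.roles)]

    @classmethod
    def from_records(cls, records: list[dict]) -> "DotSet":
        if not records:
            return cls.empty()
        coords = np.array([[r["x"], r["y"]] for r in records], dtype=float)
        roles = np.array([r["role"] for r in records], dtype=object)
        return cls(coords, roles)


@dataclass
class OutlineShape:
    """Object outline as ordered vertex chains; closed chains wrap around."""

    polylines: list[tuple[np.ndarray, bool]]   # [(vertices (n,2), closed), ...]
    label: str = ""

    def __post_init__(self):
        cleaned = []
        for verts, closed in self.polylines:
            verts = np.asarray(verts, dtype=float)
            if closed and verts.shape[0] < 3:
                raise ContractError("closed polyline needs >= 3 vertices")
            cleaned.append((verts, bool(closed)))
        self.polylines = cleaned

    def total_length(self) -> float:
        return float(sum(_polyline_length(v, c) for v, c in self.polylines))


@dataclass
class ConstellationImage:
    """A dot-pattern stimulus: raster + coordinates + provenance."""

    raster: np.ndarray          # (H, W) uint8
    dots: DotSet
    label: str = ""
    difficulty: float = DEFAULT_SPACING   # inter-dot arc spacing, pixels
    source_id: str = ""
    seed: int | None = None

    def __post_init__(self):
        self.raster = np.asarray(self.raster)
        if self.raster.ndim != 2:
            raise ContractError("raster must be single-channel (2-D)")

    @property
    def size(self) -> tuple[int, int]:
        return self.raster.shape  # (H, W)


# ---------------------------------------------------------------------------
# Outline -> dots
# ---------------------------------------------------------------------------

def _polyline_length(verts: np.ndarray, closed: bool) -> float:
    if verts.shape[0] < 2:
        return 0.0
    pts = np.vstack([verts, verts[:1]]) if closed else verts
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def _point_at_arc(pts: np.ndarray, cum: np.ndarray, s: float) -> np.ndarray:
    """Point at arc length `s` along the vertex chain `pts`."""
    i = int(np.searchsorted(cum, s, side="right") - 1)
    i = min(max(i, 0), len(pts) - 2)
    seg = cum[i + 1] - cum[i]
    t = 0.0 if seg <= 0 else (s - cum[i]) / seg
    return pts[i] + t * (pts[i + 1] - pts[i])


def sample_contour_dots(shape: OutlineShape, spacing: float) -> DotSet:
    """Place dots at equal arc-length steps along each polyline.

    Per polyline the dot count is ``floor(length / spacing)``; sampling is
    deterministic.  Raises :class:`DegenerateShapeError` when any polyline
    cannot carry at least two dots.
    """
    if spacing <= 0:
        raise ContractError("spacing must be positive")
    all_pts = []
    for verts, closed in shape.polylines:
        length = _polyline_length(verts, closed)
        count = int(np.floor(length / spacing))
        if count < 2:
            raise DegenerateShapeError(
                f"polyline of length {length:.2f} is too short for two dots "
                f"at spacing {spacing}")
        pts = np.vstack([verts, verts[:1]]) if closed else verts
        cum = np.concatenate(
            [[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
        for i in range(count):
            all_pts.append(_point_at_arc(pts, cum, i * spacing))
    coords = np.array(all_pts, dtype=float)
    roles = np.array([CONTOUR] * len(all_pts), dtype=object)
    return DotSet(coords, roles)


def add_distractors(dots: DotSet, n_distractors: int, min_separation: float,
                    bounds: tuple[int, int], seed: int,
                    max_attempts_per_dot: int = 2000) -> DotSet:
    """Add uniformly placed noise dots at least `min_separation` from all
    other dots.  `bounds` is (H, W).  Reproducible under `seed`."""
    if n_distractors < 0:
        raise ContractError("n_distractors must be >= 0")
    if n_distractors == 0:
        return DotSet(dots.coords.copy(), dots.roles.copy())
    h, w = bounds
    rng = np.random.default_rng(seed)
    placed = list(dots.coords)
    new_pts = []
    for _ in range(n_distractors):
        for attempt in range(max_attempts_per_dot):
            cand = np.array([rng.uniform(0, w), rng.uniform(0, h)])
            if not placed:
                break
            d = np.linalg.norm(np.asarray(placed) - cand, axis=1)
            if np.all(d >= min_separation):
                break
        else:
            raise CapacityError(
                f"could not place distractor {len(new_pts) + 1} of "
                f"{n_distractors} with min_separation={min_separation}")
        placed.append(cand)
        new_pts.append(cand)
    coords = np.vstack([dots.coords, np.asarray(new_pts)]) if len(dots) else \
        np.asarray(new_pts)
    roles = np.concatenate(
        [dots.roles, np.array([DISTRACTOR] * n_distractors, dtype=object)])
    return DotSet(coords, roles)


# ---------------------------------------------------------------------------
# Rendering and dot extraction
# ---------------------------------------------------------------------------

def render_constellation(dots: DotSet, size: tuple[int, int] = (DEFAULT_SIZE, DEFAULT_SIZE),
                         dot_radius: float = DEFAULT_DOT_RADIUS,
                         **meta) -> ConstellationImage:
    """Render dots as filled discs on a black background."""
    h, w = size
    if len(dots):
        if (np.any(dots.coords[:, 0] < 0) or np.any(dots.coords[:, 0] >= w)
                or np.any(dots.coords[:, 1] < 0) or np.any(dots.coords[:, 1] >= h)):
            raise ContractError("dot out of image bounds")
    raster = np.zeros((h, w), dtype=np.uint8)
    r = int(np.floor(dot_radius))
    offs = [(dx, dy) for dy in range(-r - 1, r + 2) for dx in range(-r - 1, r + 2)
            if dx * dx + dy * dy <= dot_radius * dot_radius]
    for x, y in dots.coords:
        cx, cy = int(round(x)), int(round(y))
        for dx, dy in offs:
            px, py = cx + dx, cy + dy
            if 0 <= px < w and 0 <= py < h:
                raster[py, px] = 255
    return ConstellationImage(raster=raster, dots=dots, **meta)


def extract_dots(raster: np.ndarray) -> DotSet:
    """Recover dot centres as centroids of connected foreground components."""
    from scipy import ndimage
    raster = np.asarray(raster)
    if raster.ndim != 2:
        raise ContractError("raster must be single-channel (2-D)")
    mask = raster > 0
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return DotSet.empty()
    centroids = ndimage.center_of_mass(mask, labels, index=range(1, n + 1))
    coords = np.array([[c, r] for r, c in centroids], dtype=float)  # -> (x, y)
    roles = np.array([CONTOUR] * n, dtype=object)
    return DotSet(coords, roles)


# ---------------------------------------------------------------------------
# High-level stimulus construction
# ---------------------------------------------------------------------------

def make_constellation(shape: OutlineShape, spacing: float = DEFAULT_SPACING,
                       noise_ratio: float = DEFAULT_NOISE_RATIO,
                       min_separation: float | None = None,
                       size: tuple[int, int] = (DEFAULT_SIZE, DEFAULT_SIZE),
                       dot_radius: float = DEFAULT_DOT_RADIUS,
                       seed: int = 0, source_id: str = "") -> ConstellationImage:
    """Outline -> contour dots -> distractors -> raster, in one call.

    The distractor count is ``round(noise_ratio * n_contour_dots)``;
    `min_separation` defaults to half the spacing.
    """
    if min_separation is None:
        min_separation = spacing / 2.0
    dots = sample_contour_dots(shape, spacing)
    n_noise = int(round(noise_ratio * len(dots)))
    # Keep noise inside bounds with a small margin so discs stay in-frame
    dots = add_distractors(dots, n_noise, min_separation,
                           (size[0] - 1, size[1] - 1), seed)
    return render_constellation(dots, size=size, dot_radius=dot_radius,
                                label=shape.label, difficulty=spacing,
                                source_id=source_id, seed=seed)


def outline_from_raster(image: np.ndarray, level: float = 0.5,
                        label: str = "") -> OutlineShape:
    """Trace iso-level outlines of a greyscale raster into an OutlineShape.

    Useful for planting a generator-made shape in a constellation or for
    thresholding-and-tracing ordinary object images.
    """
    from skimage import measure
    image = np.asarray(image, dtype=float)
    contours = measure.find_contours(image, level=level)
    polylines = []
    for c in contours:
        if c.shape[0] < 3:
            continue
        closed = bool(np.allclose(c[0], c[-1]))
        verts = c[:-1] if closed else c
        polylines.append((verts[:, ::-1].copy(), closed))  # (row,col)->(x,y)
    if not polylines:
        raise DegenerateShapeError("no iso-level contours found in raster")
    return OutlineShape(polylines=polylines, label=label)


# ---------------------------------------------------------------------------
# Serialization: <id>.png + <id>.json sidecar
# ---------------------------------------------------------------------------

def save_constellation(stim: ConstellationImage, directory: str | Path,
                       stem: str) -> tuple[Path, Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    png_path = directory / f"{stem}.png"
    json_path = directory / f"{stem}.json"
    Image.fromarray(stim.raster.astype(np.uint8), mode="L").save(png_path)
    sidecar = {
        "label": stim.label,
        "difficulty": stim.difficulty,
        "dots": stim.dots.to_records(),
        "source_id": stim.source_id,
        "seed": stim.seed,
    }
    json_path.write_text(json.dumps(sidecar, indent=1))
    return png_path, json_path


def load_constellation(png_path: str | Path) -> ConstellationImage:
    png_path = Path(png_path)
    raster = np.asarray(Image.open(png_path).convert("L"))
    json_path = png_path.with_suffix(".json")
    if json_path.exists():
        meta = json.loads(json_path.read_text())
        dots = DotSet.from_records(meta.get("dots", []))
        return ConstellationImage(
            raster=raster, dots=dots, label=meta.get("label", ""),
            difficulty=meta.get("difficulty", DEFAULT_SPACING),
            source_id=meta.get("source_id", ""), seed=meta.get("seed"))
    # No sidecar: fall back to component centroids
    return ConstellationImage(raster=raster, dots=extract_dots(raster))


# -- simple parametric outlines (used by examples and tests) ----------------

def square_outline(cx: float, cy: float, side: float, label: str = "square") -> OutlineShape:
    h = side / 2.0
    verts = np.array([[cx - h, cy - h], [cx + h, cy - h],
                      [cx + h, cy + h], [cx - h, cy + h]])
    return OutlineShape([(verts, True)], label=label)


def circle_outline(cx: float, cy: float, radius: float, n_vertices: int = 720,
                   label: str = "circle") -> OutlineShape:
    t = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    verts = np.stack([cx + radius * np.cos(t), cy + radius * np.sin(t)], axis=1)
    return OutlineShape([(verts, True)], label=label)
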