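"""Drawing-overlap and behavioural-comparison metrics.

Two solutions of the same constellation (a human drawing, a model
solution, or the ground-truth outline) are each reduced to the set of
stimulus dots their strokes pass within a margin of (default 3 px), and
compared by intersection-over-union on those dot sets.  ``IOU(mistakes)``
repeats the comparison after removing the ground-truth contour dots, so
only the errors are compared.  Confusion matrices of two solvers are
compared by Pearson correlation over the cells that are nonzero in at
least one matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial.distance import cdist

from .data import DotSet
from .errors import ContractError, UndefinedCorrelationError
from .fitness import ContourSet
from .imageops import to_grey01

DEFAULT_MARGIN = 3.0
OTHERS = "Others"


@dataclass
class CoverageSet:
    """The dot indices of one stimulus covered by one solution."""

    covered: frozenset[int]
    stimulus_id: str = ""
    source: str = "model_solution"   # human_drawing | model_solution | ground_truth
    margin: float = DEFAULT_MARGIN

    def __post_init__(self):
        self.covered = frozenset(int(i) for i in self.covered)

    def __len__(self):
        return len(self.covered)


def _drawing_points(drawing, skeletonize_raster: bool) -> np.ndarray:
    """Stroke point set of a drawing given as raster or ContourSet."""
    if isinstance(drawing, ContourSet):
        pts, _, _ = drawing.all_points()
        return pts
    raster = to_grey01(np.asarray(drawing))
    mask = raster > 0
    if skeletonize_raster and mask.any():
        from skimage.morphology import skeletonize
        mask = skeletonize(mask)
    rr, cc = np.nonzero(mask)
    return np.stack([cc, rr], axis=1).astype(float)   # (x, y)


def dots_covered(drawing, dots: DotSet, margin: float = DEFAULT_MARGIN,
                 stimulus_id: str = "", source: str = "model_solution",
                 skeletonize_raster: bool = True) -> CoverageSet:
    """Dots lying strictly within `margin` of the drawing's strokes.

    Raster drawings are skeletonized to 1-px strokes first so stroke
    width does not inflate coverage.  No contour-connectivity rule is
    applied here (unlike the structural fitness).
    """
    if margin <= 0:
        raise ContractError("margin must be > 0")
    pts = _drawing_points(drawing, skeletonize_raster)
    if len(pts) == 0 or len(dots) == 0:
        return CoverageSet(frozenset(), stimulus_id, source, margin)
    d = cdist(dots.coords, pts).min(axis=1)
    covered = frozenset(int(i) for i in np.flatnonzero(d < margin))
    return CoverageSet(covered, stimulus_id, source, margin)


def _check_same_stimulus(a: CoverageSet, b: CoverageSet):
    if a.stimulus_id != b.stimulus_id:
        raise ContractError(
            f"coverage sets refer to different stimuli: "
            f"{a.stimulus_id!r} vs {b.stimulus_id!r}")


def iou_dots(a: CoverageSet, b: CoverageSet) -> float:
    """|A n B| / |A u B|; both-empty counts as perfect agreement (1.0)."""
    _check_same_stimulus(a, b)
    union = a.covered | b.covered
    if not union:
        return 1.0
    return len(a.covered & b.covered) / len(union)


def iou_mistakes(a: CoverageSet, b: CoverageSet,
                 ground_truth: CoverageSet) -> float | None:
    """IOU of the two error sets (coverage minus ground-truth dots).

    Returns ``None`` (undefined, excluded from averages) when neither
    solution makes a mistake.
    """
    _check_same_stimulus(a, b)
    _check_same_stimulus(a, ground_truth)
    a_err = a.covered - ground_truth.covered
    b_err = b.covered - ground_truth.covered
    if not a_err and not b_err:
        return None
    union = a_err | b_err
    return len(a_err & b_err) / len(union)


# ---------------------------------------------------------------------------
# Confusion matrices
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    """category x (category + Others) trial counts.

    Predictions of ``None`` or outside the category list land in the
    trailing ``Others`` column.
    """

    counts: np.ndarray
    row_labels: list[str]
    col_labels: list[str]

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ContractError("counts shape does not match labels")
        if np.any(self.counts < 0):
            raise ContractError("counts must be non-negative")


def confusion_matrix(trials: list[tuple[str, str | None]],
                     categories: list[str]) -> ConfusionMatrix:
    """Count (true label, predicted label) pairs; unknown or missing
    predictions aggregate into the Others column."""
    cols = list(categories) + [OTHERS]
    counts = np.zeros((len(categories), len(cols)), dtype=int)
    row_of = {c: i for i, c in enumerate(categories)}
    col_of = {c: i for i, c in enumerate(cols)}
    for true, pred in trials:
        if true not in row_of:
            raise ContractError(f"true label {true!r} not in categories")
        j = col_of.get(pred, col_of[OTHERS]) if pred is not None \
            else col_of[OTHERS]
        counts[row_of[true], j] += 1
    return ConfusionMatrix(counts, list(categories), cols)


def pearson_nonzero(m1: ConfusionMatrix, m2: ConfusionMatrix) -> float:
    """Pearson correlation over cells that are nonzero in at least one of
    the two matrices (cells zero in both are dropped)."""
    if m1.counts.shape != m2.counts.shape \
            or m1.row_labels != m2.row_labels \
            or m1.col_labels != m2.col_labels:
        raise ContractError("confusion matrices are not comparable")
    a = m1.counts.ravel().astype(float)
    b = m2.counts.ravel().astype(float)
    keep = ~((a == 0) & (b == 0))
    a, b = a[keep], b[keep]
    if a.size < 2:
        raise UndefinedCorrelationError(
            "fewer than 2 retained cells after zero-exclusion")
    if np.std(a) == 0 or np.std(b) == 0:
        raise UndefinedCorrelationError(
            "zero variance in retained cells")
    r, _ = stats.pearsonr(a, b)
    return float(r)
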