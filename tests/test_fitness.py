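"""Structural fitness: edge tracing, 3-px matching, 40-px link rule.

The reference implementation here (`brute_force_score`) recomputes the
score with plain Python loops — every dot-to-edge-pixel distance, an
explicit per-contour arc sort, and the adjacency-gap rule — and is kept
deliberately independent of the vectorised pipeline it checks.
"""

import math

import numpy as np
import pytest

from constellation.data import DotSet
from constellation.errors import ContractError
from constellation.fitness import (Contour, ContourSet, FitnessConfig,
                                   connectivity_filter, detect_edges, fitness,
                                   match_dots, trace_pixel_chains)


def _dotset(points):
    pts = np.asarray(points, dtype=float)
    return DotSet(pts, np.array(["contour"] * len(pts), dtype=object))


def brute_force_score(candidate, dots, cfg):
    """Loop-based oracle for the full fitness pipeline (shares only the
    traced contours with the implementation under test)."""
    contours = detect_edges(candidate, cfg)
    # nearest contour point per dot, ties to lowest (contour, point) index
    assignments = {}
    for di, (dx, dy) in enumerate(dots.coords):
        best = None
        for ci, contour in enumerate(contours.contours):
            cum = 0.0
            prev = None
            for pi, (px, py) in enumerate(contour.points):
                if prev is not None:
                    cum += math.hypot(px - prev[0], py - prev[1])
                prev = (px, py)
                d = math.hypot(px - dx, py - dy)
                if best is None or d < best[0] - 1e-12:
                    best = (d, ci, pi, cum)
        if best is not None and best[0] < cfg.edge_threshold:
            assignments[di] = best
    # explicit per-contour arc sort + adjacency gaps
    contributing = set()
    for ci, contour in enumerate(contours.contours):
        group = sorted(((a[3], di) for di, a in assignments.items()
                        if a[1] == ci))
        if len(group) < 2:
            continue
        total = contour.length
        for idx, (arc, di) in enumerate(group):
            gaps = []
            if idx > 0:
                gaps.append(arc - group[idx - 1][0])
            if idx < len(group) - 1:
                gaps.append(group[idx + 1][0] - arc)
            if contour.closed:
                wrap = total - (group[-1][0] - group[0][0])
                if idx == 0 or idx == len(group) - 1:
                    gaps.append(wrap)
            if gaps and min(gaps) < cfg.link_threshold:
                contributing.add(di)
    return len(contributing)


# ---------------------------------------------------------------------------
# Edge detection / tracing
# ---------------------------------------------------------------------------

class TestDetectEdges:
    def test_blank_image_gives_empty_contour_set(self):
        assert len(detect_edges(np.zeros((64, 64)))) == 0

    def test_disc_perimeter_traced_within_fifteen_percent(self):
        yy, xx = np.mgrid[0:160, 0:160]
        disc = (((xx - 80) ** 2 + (yy - 80) ** 2) <= 30 ** 2).astype(float)
        contours = detect_edges(disc, FitnessConfig())
        longest = max(contours.contours, key=lambda c: c.length)
        assert longest.closed
        expected = 2 * np.pi * 30
        assert abs(longest.length - expected) / expected < 0.15

    def test_chains_are_eight_connected(self, toy_generator, rng):
        img = toy_generator.generate(rng.standard_normal(8))
        contours = detect_edges(img, FitnessConfig())
        for c in contours.contours:
            if len(c.points) > 1:
                steps = np.linalg.norm(np.diff(c.points, axis=0), axis=1)
                assert steps.max() <= math.sqrt(2) + 1e-9

    def test_tracing_uses_every_edge_pixel_once(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5, 2:15] = True            # open segment
        mask[10:15, 10] = True          # second segment
        cs = trace_pixel_chains(mask)
        n_points = sum(len(c.points) for c in cs.contours)
        assert n_points == mask.sum()


# ---------------------------------------------------------------------------
# Matching and connectivity on constructed contours
# ---------------------------------------------------------------------------

def _line_contour(length, y=50.0, closed=False):
    """Horizontal pixel chain from (0, y) to (length, y)."""
    xs = np.arange(0.0, length + 1.0)
    pts = np.stack([xs, np.full_like(xs, y)], axis=1)
    return ContourSet([Contour(points=pts, closed=closed)])


class TestMatchDots:
    def test_dot_on_contour_matches_at_distance_zero(self):
        cs = _line_contour(100)
        m = match_dots(cs, _dotset([(30, 50)]), 3.0)
        assert len(m) == 1 and m[0].distance == 0.0

    def test_three_pixel_tolerance_is_strict(self):
        cs = _line_contour(100)
        assert len(match_dots(cs, _dotset([(30, 52.9)]), 3.0)) == 1
        assert len(match_dots(cs, _dotset([(30, 53.0)]), 3.0)) == 0

    def test_far_dot_unmatched(self):
        cs = _line_contour(100)
        assert len(match_dots(cs, _dotset([(30, 55)]), 3.0)) == 0

    def test_tie_goes_to_lowest_contour_index(self):
        pts = np.stack([np.arange(0.0, 11.0), np.full(11, 40.0)], axis=1)
        cs = ContourSet([Contour(pts, False), Contour(pts + [0, 20], False)])
        m = match_dots(cs, _dotset([(5, 50)]), 11.0)   # equidistant (10 px)
        assert m[0].contour_id == 0

    def test_arc_position_recorded(self):
        cs = _line_contour(100)
        m = match_dots(cs, _dotset([(42, 50)]), 3.0)
        assert m[0].arc_position == pytest.approx(42.0)


class TestConnectivityFilter:
    def _run(self, xs, link=40.0, length=200, closed=False):
        cs = _line_contour(length, closed=closed)
        dots = _dotset([(x, 50) for x in xs])
        m = match_dots(cs, dots, 3.0)
        return set(connectivity_filter(m, cs, link, dots=dots).tolist())

    def test_gap_thirty_both_contribute(self):
        assert self._run([10, 40]) == {0, 1}

    def test_gap_fifty_neither_contributes(self):
        assert self._run([10, 60]) == set()

    def test_three_dots_mixed_gaps(self):
        # arc positions 0, 30, 100: gaps 30 and 70 -> first two contribute
        assert self._run([0, 30, 100]) == {0, 1}

    def test_sole_matched_dot_never_contributes(self):
        assert self._run([10]) == set()

    def test_closed_contour_wraps_arc_gap(self):
        # ring of radius 30: two dots at opposite ends of a short arc
        t = np.linspace(0, 2 * np.pi, 400, endpoint=False)
        pts = np.stack([80 + 30 * np.cos(t), 80 + 30 * np.sin(t)], axis=1)
        cs = ContourSet([Contour(pts, True)])
        # dots at angles 0 and 2pi*0.9: forward arc ~ 170 px, wrap arc ~ 19 px
        a = (80 + 30 * np.cos(0.0), 80 + 30 * np.sin(0.0))
        b = (80 + 30 * np.cos(2 * np.pi * 0.9), 80 + 30 * np.sin(2 * np.pi * 0.9))
        dots = _dotset([a, b])
        m = match_dots(cs, dots, 3.0)
        got = set(connectivity_filter(m, cs, 40.0, dots=dots).tolist())
        assert got == {0, 1}

    def test_euclidean_variant_uses_straight_line_distance(self):
        # U-shaped contour: dots close in space, far along the arc
        xs = np.arange(0.0, 61.0)
        down = np.stack([np.zeros(31), np.arange(0.0, 31.0)], axis=1)
        across = np.stack([np.arange(1.0, 61.0), np.full(60, 30.0)], axis=1)
        up = np.stack([np.full(30, 60.0), np.arange(29.0, -1.0, -1.0)], axis=1)
        pts = np.vstack([down, across, up])
        cs = ContourSet([Contour(pts, False)])
        dots = _dotset([(0, 0), (60, 0)])   # arc gap ~120, Euclidean 60
        m = match_dots(cs, dots, 3.0)
        assert set(connectivity_filter(m, cs, 70.0, dots=dots,
                                       link_metric="arc").tolist()) == set()
        assert set(connectivity_filter(
            m, cs, 70.0, dots=dots,
            link_metric="euclidean").tolist()) == {0, 1}


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

class TestFitnessPipeline:
    def test_blank_candidate_scores_zero(self, planted_square):
        stim, _ = planted_square
        res = fitness(np.zeros(stim.size), stim.dots)
        assert res.score == 0

    def test_exact_outline_recovers_all_contour_dots(self, planted_circle_clean,
                                                     toy_generator):
        stim, z = planted_circle_clean
        from constellation.fitness import score_candidate
        res = score_candidate(toy_generator.generate(z), stim)
        assert res.score == len(stim.dots.contour_indices)

    def test_result_sets_are_nested_and_bounded(self, planted_square,
                                                toy_generator, rng):
        stim, _ = planted_square
        from constellation.fitness import score_candidate
        for _ in range(5):
            res = score_candidate(toy_generator.generate(rng.standard_normal(8)),
                                  stim)
            assert set(res.contributing) <= set(res.matched)
            assert 0 <= res.score <= len(stim.dots)
            assert res.score == len(res.contributing)

    def test_score_non_decreasing_in_tolerances(self, planted_square,
                                                toy_generator, rng):
        stim, _ = planted_square
        from constellation.fitness import score_candidate
        z = rng.standard_normal(8)
        img = toy_generator.generate(z)
        prev = -1
        for et in (1.0, 2.0, 3.0, 5.0):
            s = score_candidate(img, stim, FitnessConfig(edge_threshold=et)).score
            assert s >= prev
            prev = s
        prev = -1
        for lt in (10.0, 25.0, 40.0, 80.0):
            s = score_candidate(img, stim,
                                FitnessConfig(link_threshold=lt)).score
            assert s >= prev
            prev = s

    def test_pipeline_matches_brute_force_on_random_candidates(
            self, toy_generator):
        from constellation.benchmark import planted_toy_stimulus
        from constellation.imageops import resize_bilinear
        cfg = FitnessConfig()
        rng = np.random.default_rng(2024)
        cats = ["circle", "square", "ellipse", "trefoil", "clover"]
        for k in range(10):
            stim, _ = planted_toy_stimulus(
                cats[k % 5], seed=100 + k, noise_ratio=0.5 if k % 2 else 0.0)
            for _ in range(2):
                z = rng.standard_normal(8) * 2.0
                img = np.asarray(resize_bilinear(toy_generator.generate(z),
                                                 *stim.size))
                assert fitness(img, stim.dots, cfg).score == \
                    brute_force_score(img, stim.dots, cfg)

    def test_invalid_config_rejected(self):
        with pytest.raises(ContractError):
            FitnessConfig(edge_threshold=0)
        with pytest.raises(ContractError):
            FitnessConfig(edge_threshold=5, link_threshold=4)
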