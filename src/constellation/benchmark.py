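"""End-to-end toy benchmark: plant a known shape, solve, compare methods.

A planted stimulus is built by rendering a toy-family shape, tracing its
outline at the stimulus resolution, sampling contour dots at a fixed
spacing and (optionally) adding distractors.  Both solvers then get the
same stimulus, and the report collects per-method identification
accuracy, mean dots covered, and mean IOU(dots) of the solution drawing
against the ground-truth contour dots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import ConstellationImage, make_constellation, outline_from_raster
from .fitness import FitnessConfig, detect_edges
from .generators import (TOY_CATEGORY_LATENTS, NearestTemplateClassifier,
                         ToyShapeGenerator)
from .genetic import GAConfig, run_gensearch
from .gradient import GradConfig, run_gradsearch
from .imageops import resize_bilinear, to_grey01
from .metrics import CoverageSet, dots_covered, iou_dots

TOY_SPACING = 10.0


#: Default within-category gene jitter of planted shapes, in gene units
#: (0.25 tanh units of shape variability at the generator's gene scale).
DEFAULT_JITTER = 0.25 * ToyShapeGenerator.GENE_SCALE


def planted_toy_stimulus(category: str, seed: int, spacing: float = TOY_SPACING,
                         noise_ratio: float = 0.0, jitter: float = 0.0,
                         size: int = 160,
                         generator: ToyShapeGenerator | None = None,
                         ensure_category: bool = True,
                         max_jitter_attempts: int = 50
                         ) -> tuple[ConstellationImage, np.ndarray]:
    """Build a constellation whose hidden object is a toy-family shape.

    `jitter` perturbs the category's canonical genes (standard deviation
    in gene units) so repeated stimuli are not identical.  Because large
    jitter can carry a latent across a category boundary (a heavily
    deformed circle may genuinely be a trefoil), jittered draws are by
    default re-sampled until the rendered shape still classifies as its
    nominal category — the stimulus must actually depict the label it is
    scored against.  Returns the stimulus and the planted latent.
    """
    generator = generator or ToyShapeGenerator()
    rng = np.random.default_rng(seed)
    base = TOY_CATEGORY_LATENTS[category].copy()
    z = base
    if jitter > 0:
        checker = (NearestTemplateClassifier.for_toy_generator(generator)
                   if ensure_category else None)
        for _ in range(max_jitter_attempts):
            z = base + rng.normal(0.0, jitter, size=base.shape)
            if checker is None or \
                    checker.classify(generator.generate(z))[0] == category:
                break
        else:
            z = base    # fall back to the canonical latent
    img = generator.generate(z)
    up = resize_bilinear(img, size, size)
    shape = outline_from_raster(up, level=0.5, label=category)
    stim = make_constellation(shape, spacing=spacing, noise_ratio=noise_ratio,
                              size=(size, size), seed=int(rng.integers(2**31)),
                              source_id=f"toy/{category}")
    return stim, z


def solution_coverage(image: np.ndarray, stimulus: ConstellationImage,
                      margin: float = 3.0, stimulus_id: str = "",
                      fcfg: FitnessConfig | None = None) -> CoverageSet:
    """Dots covered by a solution image's edge contours (no link rule)."""
    grey = to_grey01(image)
    h, w = stimulus.size
    if grey.shape != (h, w):
        grey = resize_bilinear(grey, h, w)
    contours = detect_edges(grey, fcfg or FitnessConfig())
    return dots_covered(contours, stimulus.dots, margin=margin,
                        stimulus_id=stimulus_id, source="model_solution")


def ground_truth_coverage(stimulus: ConstellationImage,
                          stimulus_id: str = "") -> CoverageSet:
    return CoverageSet(frozenset(int(i) for i in stimulus.dots.contour_indices),
                       stimulus_id=stimulus_id, source="ground_truth")


@dataclass
class BenchmarkReport:
    rows: list[dict] = field(default_factory=list)
    summary: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"summary": self.summary, "per_image": self.rows}


def _method_summary(rows: list[dict], method: str) -> dict:
    sel = [r for r in rows if r["method"] == method]
    if not sel:
        return {"n": 0}
    return {
        "n": len(sel),
        "accuracy": float(np.mean([r["correct"] for r in sel])),
        "mean_dots_covered": float(np.mean([r["dots_covered"] for r in sel])),
        "mean_fitness": float(np.mean([r["fitness"] for r in sel])),
        "mean_iou_dots_vs_truth":
            float(np.mean([r["iou_dots_vs_truth"] for r in sel])),
    }


def run_toy_benchmark(n_images: int, seed: int = 0,
                      ga_cfg: GAConfig | None = None,
                      grad_cfg: GradConfig | None = None,
                      fcfg: FitnessConfig | None = None,
                      spacing: float = TOY_SPACING,
                      noise_ratio: float = 0.0,
                      jitter: float = DEFAULT_JITTER,
                      methods: tuple[str, ...] = ("genetic", "gradient"),
                      ) -> BenchmarkReport:
    """Desk-scale comparison of the two search variants on planted shapes.

    Categories cycle through the toy families; every stimulus and every
    solver run is seeded from `seed`, so the report is reproducible.
    The default genetic setting (population 200, 40 parents) is the
    benchmark's reduced problem size; all other knobs keep their tuned
    defaults.
    """
    fcfg = fcfg or FitnessConfig()
    generator = ToyShapeGenerator()
    classifier = NearestTemplateClassifier.for_toy_generator(generator)
    categories = list(TOY_CATEGORY_LATENTS.keys())
    rng = np.random.default_rng(seed)

    report = BenchmarkReport()
    for i in range(n_images):
        category = categories[i % len(categories)]
        stim_seed = int(rng.integers(2**31))
        run_seed = int(rng.integers(2**31))
        stim, _ = planted_toy_stimulus(category, stim_seed, spacing=spacing,
                                       noise_ratio=noise_ratio, jitter=jitter,
                                       generator=generator)
        sid = f"toy-{i:03d}"
        truth = ground_truth_coverage(stim, stimulus_id=sid)
        for method in methods:
            if method == "genetic":
                cfg = ga_cfg or GAConfig(population_size=200, n_parents=40)
                cfg = GAConfig(**{**cfg.__dict__, "seed": run_seed})
                res = run_gensearch(stim, generator, classifier, cfg, fcfg)
            elif method == "gradient":
                cfg = grad_cfg or GradConfig()
                cfg = GradConfig(**{**cfg.__dict__, "seed": run_seed})
                res = run_gradsearch(stim, generator, classifier, cfg, fcfg)
            else:
                raise ValueError(f"unknown method {method!r}")
            cov = solution_coverage(res.best_image, stim, stimulus_id=sid,
                                    fcfg=fcfg)
            report.rows.append({
                "stimulus": sid,
                "category": category,
                "method": method,
                "label_pred": res.label,
                "correct": bool(res.label == category),
                "fitness": int(res.fitness),
                "dots_covered": len(cov),
                "iou_dots_vs_truth": iou_dots(cov, truth),
                "n_dots": len(stim.dots),
                "n_contour_dots": int(len(stim.dots.contour_indices)),
            })
    report.summary = {m: _method_summary(report.rows, m) for m in methods}
    report.summary["n_images"] = n_images
    report.summary["seed"] = seed
    return report
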