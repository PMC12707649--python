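"""Gradient-descent ablation of the latent-space search.

Instead of evolving a population, a single latent vector is optimised by
gradient descent on a differentiable surrogate of the dot-fitting
objective: the candidate image is turned into a Sobel edge-magnitude map
E(x, y), the stimulus dots into a Gaussian heatmap

    H(x, y) = sum_i exp(-((x - x_i)^2 + (y - y_i)^2) / (2 sigma^2)),

and the loss is the negative masked dot product

    L = - sum_{H > eps} H(x, y) * E(x, y),

so edges are pulled toward dot neighbourhoods (sigma defaults to 3 px).
The learning rate follows a triangular schedule (linear warm-up to the
peak over the first half of the run, linear decay back).  For
comparability with the evolutionary solver, the final solution is always
re-scored with the non-differentiable structural fitness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .data import ConstellationImage, DotSet
from .errors import CapabilityError, ContractError
from .fitness import FitnessConfig, score_candidate
from .generators import ClassifierHandle, GeneratorHandle
from .genetic import SearchTrace, SolveResult
from .imageops import to_grey01


@dataclass
class HeatmapField:
    values: np.ndarray          # (H, W) non-negative
    sigma: float
    dots: DotSet


@dataclass
class GradConfig:
    sigma: float = 3.0
    iterations: int = 300
    base_lr: float = 0.01
    max_lr: float = 0.1
    schedule: str = "triangular"
    mask_epsilon: float = 1e-4
    restarts: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.iterations < 0:
            raise ContractError("iterations must be >= 0")
        if not (0 < self.base_lr <= self.max_lr):
            raise ContractError("need 0 < base_lr <= max_lr")
        if self.schedule != "triangular":
            raise ContractError(f"unknown schedule {self.schedule!r}")


def build_heatmap(dots: DotSet, sigma: float,
                  size: tuple[int, int]) -> HeatmapField:
    """Sum-of-Gaussians heatmap of the dot coordinates at pixel centres."""
    if sigma <= 0:
        raise ContractError("sigma must be > 0")
    h, w = size
    field = np.zeros((h, w), dtype=float)
    if len(dots):
        ys, xs = np.mgrid[0:h, 0:w]
        for x, y in dots.coords:
            field += np.exp(-((xs - x) ** 2 + (ys - y) ** 2)
                            / (2.0 * sigma * sigma))
    return HeatmapField(values=field, sigma=float(sigma), dots=dots)


_SOBEL_X = np.array([[1.0, 0.0, -1.0],
                     [2.0, 0.0, -2.0],
                     [1.0, 0.0, -1.0]])
_SOBEL_Y = _SOBEL_X.T


def sobel_edge_map(image):
    """Gradient-magnitude field sqrt(Gx^2 + Gy^2) from 3x3 Sobel kernels.

    Accepts a plain array or an autodiff tensor; in the latter case the
    map is differentiable w.r.t. the image intensities.  Zero padding, so
    statements about responses refer to the image interior.
    """
    img4 = ad.reshape(image, (1, 1) + tuple(image.shape))
    gx = ad.conv2d(img4, _SOBEL_X.reshape(1, 1, 3, 3), stride=1, pad=1)
    gy = ad.conv2d(img4, _SOBEL_Y.reshape(1, 1, 3, 3), stride=1, pad=1)
    mag = ad.sqrt(gx * gx + gy * gy)
    return ad.reshape(mag, tuple(image.shape))


def masked_similarity_loss(heatmap: HeatmapField, edge_field,
                           mask_epsilon: float = 1e-4):
    """L = - sum over pixels with H > mask_epsilon of H * E."""
    target = heatmap.values
    shape = edge_field.shape if not isinstance(edge_field, ad.Tensor) \
        else edge_field.data.shape
    if tuple(shape) != target.shape:
        raise ContractError("heatmap / edge field shape mismatch")
    mask = (target > mask_epsilon).astype(float)
    return -ad.tensor_sum(edge_field * (target * mask))


def triangular_lr(iteration: int, total: int, base_lr: float,
                  max_lr: float) -> float:
    """Linear warm-up to `max_lr` over the first half, linear decay back."""
    if total <= 1:
        return max_lr
    half = (total - 1) / 2.0
    t = iteration / half if iteration <= half else (total - 1 - iteration) / half
    return base_lr + (max_lr - base_lr) * t


def latent_loss(z: np.ndarray | ad.Tensor, generator: GeneratorHandle,
                heatmap: HeatmapField, mask_epsilon: float = 1e-4):
    """Differentiable loss of a latent: generate, upscale, Sobel, match."""
    field = generator.render_field(z)
    h, w = heatmap.values.shape
    if field.shape != (h, w):
        field = ad.bilinear_resize(field, h, w)
    edges = sobel_edge_map(field)
    return masked_similarity_loss(heatmap, edges, mask_epsilon)


def run_gradsearch(stimulus: ConstellationImage, generator: GeneratorHandle,
                   classifier: ClassifierHandle | None,
                   cfg: GradConfig | None = None,
                   fcfg: FitnessConfig | None = None) -> SolveResult:
    """Optimise a single latent by gradient descent on the masked
    edge-heatmap loss; best restart (lowest final loss) wins.

    The returned result carries the loss trajectory of the winning
    restart in ``loss_history`` and the structural-fitness score of the
    final image, so genetic and gradient runs compare on the same metric.
    """
    cfg = cfg or GradConfig()
    fcfg = fcfg or FitnessConfig()
    if not getattr(generator, "differentiable", False) \
            or not hasattr(generator, "render_field"):
        raise CapabilityError("generator does not support gradients")

    h, w = stimulus.size
    heatmap = build_heatmap(stimulus.dots, cfg.sigma, (h, w))
    rng = np.random.default_rng(cfg.seed)
    # The raw loss scales with the stimulus's total heatmap mass; dividing
    # the gradient by that mass makes the learning-rate schedule scale-free
    # (a unit learning rate then moves genes by order-one amounts).
    mask = heatmap.values > cfg.mask_epsilon
    step_scale = float(heatmap.values[mask].sum()) or 1.0

    best = None
    for restart in range(max(1, cfg.restarts)):
        z = generator.sample_latents(1, rng)[0]
        losses = []
        lrs = []
        for it in range(cfg.iterations):
            zt = ad.Tensor(z, requires_grad=True)
            loss = latent_loss(zt, generator, heatmap, cfg.mask_epsilon)
            loss.backward()
            lr = triangular_lr(it, cfg.iterations, cfg.base_lr, cfg.max_lr)
            z = z - lr * zt.grad / step_scale
            losses.append(float(loss.data))
            lrs.append(lr)
        final_loss = float(latent_loss(z, generator, heatmap,
                                       cfg.mask_epsilon))
        losses.append(final_loss)
        if best is None or final_loss < best[0]:
            best = (final_loss, z, losses, lrs)

    _, z, losses, lrs = best
    image = generator.generate(z)
    fres = score_candidate(image, stimulus, fcfg)
    label, score = (None, 0.0)
    if classifier is not None:
        label, score = classifier.classify(image)
    result = SolveResult(best_latent=np.asarray(z), best_image=image,
                         label=label, label_score=score, fitness=fres.score,
                         fitness_result=fres, trace=SearchTrace(
                             records=[], termination="iterations"),
                         method="gradient")
    result.loss_history = np.asarray(losses)
    result.lr_history = np.asarray(lrs)
    return result
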