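"""Latent-space image generators and category classifiers.

The search algorithms are generator-agnostic: anything exposing the
:class:`GeneratorHandle` contract (fixed latent dimension, deterministic
latent -> single-channel [0, 1] image mapping) can be searched.  Two
generators ship with the package:

* :class:`ToyShapeGenerator` — a deterministic 8-gene parametric renderer
  of superellipse blobs with boundary harmonics.  It is differentiable,
  needs no training, and makes the whole pipeline self-testing.
* a convolutional (DCGAN-style) generator trained on user-supplied images
  (see :mod:`constellation.dcgan`), latent dimension 256, output 64x64.

Generated images are produced at the generator's native resolution and
upscaled (bilinear by default) to the stimulus resolution before edge
detection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .errors import ContractError

TOY_LATENT_DIM = 8


class GeneratorHandle:
    """Contract: deterministic mapping from latent vectors to images.

    Subclasses implement :meth:`_render` mapping a 1-D latent array to a
    single-channel float image in [0, 1].
    """

    latent_dim: int
    output_size: int
    differentiable: bool = False

    def sample_latents(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw `n` latents from the prior (standard normal per gene)."""
        return rng.standard_normal((n, self.latent_dim))

    def generate(self, z: np.ndarray) -> np.ndarray:
        """Generate one image from one latent vector."""
        z = np.asarray(z, dtype=float).ravel()
        if z.shape[0] != self.latent_dim:
            raise ContractError(
                f"latent dim {z.shape[0]} != generator dim {self.latent_dim}")
        img = self._render(z)
        return np.clip(np.asarray(img, dtype=float), 0.0, 1.0)

    def generate_batch(self, zs: np.ndarray) -> np.ndarray:
        zs = np.atleast_2d(np.asarray(zs, dtype=float))
        return np.stack([self.generate(z) for z in zs])

    def _render(self, z: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def generate_image(generator: GeneratorHandle, z: np.ndarray) -> np.ndarray:
    """Functional form of :meth:`GeneratorHandle.generate`."""
    return generator.generate(z)


# ---------------------------------------------------------------------------
# Toy parametric generator
# ---------------------------------------------------------------------------

class ToyShapeGenerator(GeneratorHandle):
    """Deterministic 8-gene renderer of filled superellipse blobs.

    Genes (each squashed internally, so any real value is valid):

    ======  =======================================================
    z[0:2]  centre (x, y), tanh-squashed around the image centre
    z[2:4]  log-radii of the two principal axes
    z[4]    rotation angle
    z[5]    squareness exponent of the superellipse (z=0 -> ellipse)
    z[6:8]  amplitudes of 3-fold and 4-fold boundary harmonics
    ======  =======================================================

    ``z = 0`` renders a centred circle of the mid-range radius.  The
    mapping is continuous (smooth sigmoid boundary) and differentiable,
    which the gradient-descent solver relies on.

    Genes pass through ``tanh(z / GENE_SCALE)``; the scale sets how fast
    the rendered shape changes per gene unit.  It is chosen so that a
    perturbation of one gene unit moves boundary pixels by roughly the
    edge-matching tolerance of the structural fitness, which keeps
    unit-sized search moves meaningful at the stimulus resolution.
    """

    latent_dim = TOY_LATENT_DIM
    differentiable = True

    MID_RADIUS = 14.0
    RADIUS_SPREAD = 0.45     # log-spread of radii around MID_RADIUS
    CENTRE_SPREAD = 12.0     # max offset of the centre from image centre
    MAX_HARMONIC = 0.35      # max relative boundary modulation per harmonic
    SHARPNESS = 1.5          # sigmoid steepness of the filled boundary, 1/px
    GENE_SCALE = 3.0         # gene units per tanh unit

    def __init__(self, output_size: int = 64):
        self.output_size = int(output_size)
        c = (self.output_size - 1) / 2.0
        xs = np.arange(self.output_size, dtype=float)
        self._X, self._Y = np.meshgrid(xs, xs)  # _X varies along columns
        self._centre = c

    def _render(self, z):
        return self.render_field(z)

    def render_field(self, z):
        """Render the image; works on plain arrays or autodiff tensors.

        When `z` is an :class:`autodiff.Tensor` of shape (8,), the returned
        field is a Tensor and gradients flow back to the genes.
        """
        g = [z[i] * (1.0 / self.GENE_SCALE) for i in range(self.latent_dim)]
        cx = self._centre + self.CENTRE_SPREAD * ad.tanh(g[0])
        cy = self._centre + self.CENTRE_SPREAD * ad.tanh(g[1])
        ra = self.MID_RADIUS * ad.exp(self.RADIUS_SPREAD * ad.tanh(g[2]))
        rb = self.MID_RADIUS * ad.exp(self.RADIUS_SPREAD * ad.tanh(g[3]))
        rot = (np.pi / 2.0) * ad.tanh(g[4])
        n_exp = 2.0 * ad.exp(0.8 * ad.tanh(g[5]))
        a3 = self.MAX_HARMONIC * ad.tanh(g[6])
        a4 = self.MAX_HARMONIC * ad.tanh(g[7])

        dx = self._X - cx
        dy = self._Y - cy
        rho = ad.sqrt(dx * dx + dy * dy + 1e-9)
        theta = ad.atan2(dy, dx) - rot

        # superellipse boundary radius in the rotated frame
        eps = 1e-9
        ct = ad.absolute(ad.cos(theta)) + eps
        st = ad.absolute(ad.sin(theta)) + eps
        # (ct/ra)^n + (st/rb)^n, with a tensor-valued exponent via exp/log
        term_a = ad.exp(n_exp * (ad.log(ct) - ad.log(ra)))
        term_b = ad.exp(n_exp * (ad.log(st) - ad.log(rb)))
        r0 = ad.exp((-1.0 / 1.0) * ad.log(term_a + term_b) / n_exp)

        modulation = 1.0 + a3 * ad.cos(3.0 * theta) + a4 * ad.cos(4.0 * theta)
        r_boundary = r0 * modulation
        return ad.sigmoid(self.SHARPNESS * (r_boundary - rho))

    def boundary_radius(self, z: np.ndarray, theta: np.ndarray) -> np.ndarray:
        """Analytic boundary radius r(theta) in image coordinates (for tests)."""
        z = np.asarray(z, dtype=float) / self.GENE_SCALE
        ra = self.MID_RADIUS * np.exp(self.RADIUS_SPREAD * np.tanh(z[2]))
        rb = self.MID_RADIUS * np.exp(self.RADIUS_SPREAD * np.tanh(z[3]))
        rot = (np.pi / 2.0) * np.tanh(z[4])
        n_exp = 2.0 * np.exp(0.8 * np.tanh(z[5]))
        a3 = self.MAX_HARMONIC * np.tanh(z[6])
        a4 = self.MAX_HARMONIC * np.tanh(z[7])
        th = np.asarray(theta, dtype=float) - rot
        ct = np.abs(np.cos(th)) + 1e-9
        st = np.abs(np.sin(th)) + 1e-9
        r0 = (np.power(ct / ra, n_exp) + np.power(st / rb, n_exp)) ** (-1.0 / n_exp)
        return r0 * (1.0 + a3 * np.cos(3.0 * np.asarray(theta))
                     + a4 * np.cos(4.0 * np.asarray(theta)))

    # -- serialization (JSON only: the generator is purely parametric) ------
    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {"arch": "toy", "latent_dim": self.latent_dim,
                "output_size": self.output_size}
        path = directory / "generator.json"
        path.write_text(json.dumps(meta, indent=1))
        return path

    @classmethod
    def load(cls, directory: str | Path) -> "ToyShapeGenerator":
        meta = json.loads((Path(directory) / "generator.json").read_text())
        if meta.get("arch") != "toy":
            raise ContractError(f"not a toy generator checkpoint: {meta}")
        return cls(output_size=meta["output_size"])


# ---------------------------------------------------------------------------
# Classifiers
# ---------------------------------------------------------------------------

class ClassifierHandle:
    """Contract: image -> (argmax label, per-category probability scores)."""

    categories: list[str]

    def scores(self, image: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def classify(self, image: np.ndarray) -> tuple[str, float]:
        s = self.scores(image)
        i = int(np.argmax(s))
        return self.categories[i], float(s[i])


def classify_solution(classifier: ClassifierHandle,
                      image: np.ndarray) -> tuple[str, float]:
    """Classify the generated greyscale image (not its edge map)."""
    return classifier.classify(image)


# Canonical latent codes of the toy shape families (in gene units, i.e.
# before the generator's internal tanh squash).  The five categories
# exercise each part of the gene space: squareness, aspect ratio and the
# two boundary harmonics.
_S = ToyShapeGenerator.GENE_SCALE
TOY_CATEGORY_LATENTS: dict[str, np.ndarray] = {
    "circle":   np.zeros(TOY_LATENT_DIM),
    "square":   _S * np.array([0., 0., 0.3, 0.3, 0., 2.5, 0., 0.]),
    "ellipse":  _S * np.array([0., 0., 2.0, -2.0, 0., 0., 0., 0.]),
    "trefoil":  _S * np.array([0., 0., 0., 0., 0., 0., 3.0, 0.]),
    "clover":   _S * np.array([0., 0., 0.2, 0.2, 0., 0., 0., 3.0]),
}


class NearestTemplateClassifier(ClassifierHandle):
    """Classify by pixel-space distance to a bank of template images.

    Scores are a softmax over negative squared distances; an exact template
    match scores 1.0.  This mirrors "off-the-shelf classifier" usage for
    the toy family without any training.
    """

    def __init__(self, templates: dict[str, np.ndarray], tau: float | None = None):
        if not templates:
            raise ContractError("need at least one template")
        self.categories = list(templates.keys())
        self._bank = np.stack([np.asarray(templates[c], dtype=float)
                               for c in self.categories])
        if tau is None:
            # distance scale: a fraction of the mean inter-template distance
            if len(self.categories) > 1:
                d = [np.sum((a - b) ** 2)
                     for i, a in enumerate(self._bank)
                     for b in self._bank[i + 1:]]
                tau = 0.25 * float(np.mean(d))
            else:
                tau = 1.0
        self.tau = float(tau)

    @classmethod
    def for_toy_generator(cls, generator: ToyShapeGenerator | None = None
                          ) -> "NearestTemplateClassifier":
        generator = generator or ToyShapeGenerator()
        templates = {name: generator.generate(z)
                     for name, z in TOY_CATEGORY_LATENTS.items()}
        return cls(templates)

    def scores(self, image: np.ndarray) -> np.ndarray:
        image = np.asarray(image, dtype=float)
        if image.shape != self._bank.shape[1:]:
            from .imageops import resize_bilinear
            image = resize_bilinear(image, *self._bank.shape[1:])
        d2 = np.array([np.sum((image - t) ** 2) for t in self._bank])
        if np.min(d2) == 0.0:
            out = np.zeros(len(d2))
            out[int(np.argmin(d2))] = 1.0
            return out
        logits = -d2 / self.tau
        logits -= logits.max()
        p = np.exp(logits)
        return p / p.sum()


def load_generator(directory: str | Path) -> GeneratorHandle:
    """Open a generator checkpoint directory (toy or convolutional)."""
    meta = json.loads((Path(directory) / "generator.json").read_text())
    arch = meta.get("arch")
    if arch == "toy":
        return ToyShapeGenerator.load(directory)
    if arch == "dcgan":
        from .dcgan import DCGANGenerator
        return DCGANGenerator.load(directory)
    raise ContractError(f"unknown generator arch {arch!r}")
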