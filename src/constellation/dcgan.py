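"""Convolutional generative adversarial generator (DCGAN family).

A four-deconvolution-layer generator (latent dim 256 by default, 64x64
single-channel output) trained against a four-convolution-layer
discriminator with one-sided label smoothing on the real targets.  The
implementation runs on the package's autodiff core, so a trained
generator is differentiable and can be searched by both the evolutionary
and the gradient-descent solvers.

Training here is meant for desk-scale experiments (small image banks,
few epochs); sample quality at full dataset scale is out of scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .errors import ContractError, InputError
from .generators import GeneratorHandle


@dataclass
class DCGANConfig:
    latent_dim: int = 256
    output_size: int = 64          # fixed by the 4-layer upsampling stack
    base_channels: int = 32        # discriminator/generator channel width
    epochs: int = 1
    batch_size: int = 32
    lr: float = 2e-4
    beta1: float = 0.5
    beta2: float = 0.999
    label_smooth: float = 0.9      # target for real samples in D's loss

    def __post_init__(self):
        if self.output_size != 64:
            raise ContractError("the 4-layer stack generates 64x64 images")
        if self.latent_dim < 1 or self.base_channels < 1:
            raise ContractError("latent_dim and base_channels must be >= 1")


# ---------------------------------------------------------------------------
# Parameters and layers
# ---------------------------------------------------------------------------

class _Params:
    """Named parameter store: Tensors for training, arrays for eval."""

    def __init__(self):
        self.tensors: dict[str, ad.Tensor] = {}
        self.buffers: dict[str, np.ndarray] = {}   # batch-norm running stats

    def add(self, name: str, value: np.ndarray):
        self.tensors[name] = ad.Tensor(value, requires_grad=True)

    def get(self, name: str, train: bool):
        t = self.tensors[name]
        return t if train else t.data

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {k: v.data.copy() for k, v in self.tensors.items()}
        out.update({f"buf::{k}": v.copy() for k, v in self.buffers.items()})
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for k, v in state.items():
            if k.startswith("buf::"):
                self.buffers[k[5:]] = np.asarray(v, dtype=float)
            else:
                self.add(k, np.asarray(v, dtype=float))


def _batchnorm(x, params: _Params, name: str, train: bool,
               momentum: float = 0.1, eps: float = 1e-5):
    gamma = params.get(f"{name}.gamma", train)
    beta = params.get(f"{name}.beta", train)
    c = params.tensors[f"{name}.gamma"].data.shape[0]
    shape = (1, c, 1, 1)
    if train:
        mu = ad.mean(x, axis=(0, 2, 3), keepdims=True)
        var = ad.mean((x - mu) * (x - mu), axis=(0, 2, 3), keepdims=True)
        rm, rv = params.buffers[f"{name}.mean"], params.buffers[f"{name}.var"]
        params.buffers[f"{name}.mean"] = \
            (1 - momentum) * rm + momentum * mu.data.reshape(c)
        params.buffers[f"{name}.var"] = \
            (1 - momentum) * rv + momentum * var.data.reshape(c)
    else:
        mu = params.buffers[f"{name}.mean"].reshape(shape)
        var = params.buffers[f"{name}.var"].reshape(shape)
    xhat = (x - mu) / ad.sqrt(var + eps)
    return xhat * ad.reshape(gamma, shape) + ad.reshape(beta, shape)


def _bce_with_logits(logits, target: float):
    """Mean of softplus(l) - target * l (binary cross-entropy on logits)."""
    n = logits.data.size if isinstance(logits, ad.Tensor) else logits.size
    return (ad.tensor_sum(ad.softplus(logits)) -
            target * ad.tensor_sum(logits)) * (1.0 / float(n))


class _Adam:
    def __init__(self, tensors: list[ad.Tensor], lr: float,
                 beta1: float, beta2: float, eps: float = 1e-8):
        self.tensors = tensors
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(t.data) for t in tensors]
        self.v = [np.zeros_like(t.data) for t in tensors]
        self.t = 0

    def step(self):
        self.t += 1
        for i, p in enumerate(self.tensors):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.tensors:
            p.grad = None


# ---------------------------------------------------------------------------
# Generator
# ---------------------------------------------------------------------------

class DCGANGenerator(GeneratorHandle):
    """Latent -> 64x64 single-channel image in [0, 1], deterministic."""

    differentiable = True

    def __init__(self, cfg: DCGANConfig, params: _Params | None = None,
                 seed: int = 0):
        self.cfg = cfg
        self.latent_dim = cfg.latent_dim
        self.output_size = cfg.output_size
        self.seed = seed
        self.params = params if params is not None \
            else _init_generator_params(cfg, np.random.default_rng(seed))

    def forward(self, z, train: bool = False):
        """(B, latent) -> (B, 1, 64, 64); Tensor in, Tensor out."""
        p = self.params
        f = self.cfg.base_channels
        b = z.shape[0] if not isinstance(z, ad.Tensor) else z.data.shape[0]
        h = _matmul_t(z, p.get("g.fc.w", train)) + p.get("g.fc.b", train)
        h = ad.reshape(h, (b, 8 * f, 4, 4))
        h = ad.relu(_batchnorm(h, p, "g.bn0", train))
        for i, cout in enumerate((4 * f, 2 * f, f)):
            h = ad.conv_transpose2d(h, p.get(f"g.ct{i}.w", train),
                                    stride=2, pad=1)
            h = ad.relu(_batchnorm(h, p, f"g.bn{i + 1}", train))
        h = ad.conv_transpose2d(h, p.get("g.ct3.w", train), stride=2, pad=1)
        return (ad.tanh(h) + 1.0) * 0.5

    def _render(self, z: np.ndarray) -> np.ndarray:
        out = self.forward(z.reshape(1, -1), train=False)
        out = out.data if isinstance(out, ad.Tensor) else out
        return out.reshape(self.output_size, self.output_size)

    def render_field(self, z):
        """Differentiable single-image forward (for gradient search)."""
        if isinstance(z, ad.Tensor):
            z2 = ad.reshape(z, (1, z.data.size))
            out = self.forward(z2, train=False)
            return ad.reshape(out, (self.output_size, self.output_size))
        return self._render(np.asarray(z, dtype=float))

    # -- serialization ------------------------------------------------------
    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {"arch": "dcgan", "latent_dim": self.cfg.latent_dim,
                "output_size": self.cfg.output_size,
                "base_channels": self.cfg.base_channels, "seed": self.seed}
        (directory / "generator.json").write_text(json.dumps(meta, indent=1))
        np.savez(directory / "weights.npz", **self.params.state_dict())
        return directory / "generator.json"

    @classmethod
    def load(cls, directory: str | Path) -> "DCGANGenerator":
        directory = Path(directory)
        meta = json.loads((directory / "generator.json").read_text())
        cfg = DCGANConfig(latent_dim=meta["latent_dim"],
                          output_size=meta["output_size"],
                          base_channels=meta["base_channels"])
        params = _Params()
        with np.load(directory / "weights.npz") as npz:
            state = {k: npz[k] for k in npz.files
                     if k.startswith(("g.", "buf::g."))}
        params.load_state_dict(state)
        return cls(cfg, params=params, seed=meta.get("seed", 0))


def _matmul_t(z, w):
    """z @ w.T for Tensor or ndarray operands."""
    if isinstance(z, ad.Tensor) or isinstance(w, ad.Tensor):
        zt = z if isinstance(z, ad.Tensor) else ad.Tensor(z)
        return zt @ ad.transpose(w)
    return z @ np.swapaxes(w, -1, -2)


def _init_generator_params(cfg: DCGANConfig,
                           rng: np.random.Generator) -> _Params:
    f = cfg.base_channels
    p = _Params()
    p.add("g.fc.w", rng.normal(0, 0.02, (8 * f * 16, cfg.latent_dim)))
    p.add("g.fc.b", np.zeros(8 * f * 16))
    chain = [(8 * f, 4 * f), (4 * f, 2 * f), (2 * f, f), (f, 1)]
    for i, (cin, cout) in enumerate(chain):
        p.add(f"g.ct{i}.w", rng.normal(0, 0.02, (cin, cout, 4, 4)))
    for i, c in enumerate((8 * f, 4 * f, 2 * f, f)):
        p.add(f"g.bn{i}.gamma", np.ones(c))
        p.add(f"g.bn{i}.beta", np.zeros(c))
        p.buffers[f"g.bn{i}.mean"] = np.zeros(c)
        p.buffers[f"g.bn{i}.var"] = np.ones(c)
    return p


def _init_discriminator_params(cfg: DCGANConfig,
                               rng: np.random.Generator) -> _Params:
    f = cfg.base_channels
    p = _Params()
    chain = [(1, f), (f, 2 * f), (2 * f, 4 * f), (4 * f, 8 * f)]
    for i, (cin, cout) in enumerate(chain):
        p.add(f"d.c{i}.w", rng.normal(0, 0.02, (cout, cin, 4, 4)))
    for i, c in [(1, 2 * f), (2, 4 * f), (3, 8 * f)]:
        p.add(f"d.bn{i}.gamma", np.ones(c))
        p.add(f"d.bn{i}.beta", np.zeros(c))
        p.buffers[f"d.bn{i}.mean"] = np.zeros(c)
        p.buffers[f"d.bn{i}.var"] = np.ones(c)
    p.add("d.fc.w", rng.normal(0, 0.02, (1, 8 * f * 16)))
    p.add("d.fc.b", np.zeros(1))
    return p


def _discriminate(x, p: _Params, cfg: DCGANConfig, train: bool):
    f = cfg.base_channels
    h = ad.leaky_relu(ad.conv2d(x, p.get("d.c0.w", train), stride=2, pad=1))
    for i in range(1, 4):
        h = ad.conv2d(h, p.get(f"d.c{i}.w", train), stride=2, pad=1)
        h = ad.leaky_relu(_batchnorm(h, p, f"d.bn{i}", train))
    b = h.data.shape[0] if isinstance(h, ad.Tensor) else h.shape[0]
    h = ad.reshape(h, (b, 8 * f * 16))
    return _matmul_t(h, p.get("d.fc.w", train)) + p.get("d.fc.b", train)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def train_dcgan(images: np.ndarray, config: DCGANConfig | None = None,
                seed: int = 0, out_dir: str | Path | None = None,
                verbose: bool = False) -> DCGANGenerator:
    """Adversarial training on a bank of single-channel rasters.

    `images` is (n, 64, 64) with intensities in [0, 1] (or 0..255).
    Real targets are smoothed to `label_smooth`; fake targets are 0.
    All randomness comes from `seed`, so two runs on the same platform
    produce bit-identical checkpoints.
    """
    config = config or DCGANConfig()
    images = np.asarray(images, dtype=float)
    if images.ndim != 3 or images.shape[0] == 0:
        raise InputError("need a non-empty (n, H, W) image array")
    if images.shape[1:] != (config.output_size, config.output_size):
        raise ContractError(
            f"images must be {config.output_size}x{config.output_size}")
    if images.max() > 1.0:
        images = images / 255.0
    images = images * 2.0 - 1.0            # tanh range

    rng = np.random.default_rng(seed)
    gen = DCGANGenerator(config, seed=seed)
    gen.params = _init_generator_params(config, rng)
    dparams = _init_discriminator_params(config, rng)

    g_opt = _Adam(list(gen.params.tensors.values()),
                  config.lr, config.beta1, config.beta2)
    d_opt = _Adam(list(dparams.tensors.values()),
                  config.lr, config.beta1, config.beta2)

    n = images.shape[0]
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            real = images[idx][:, None, :, :]
            b = real.shape[0]

            # -- discriminator step
            z = rng.standard_normal((b, config.latent_dim))
            fake = gen.forward(z, train=True)
            fake_img = (fake.data if isinstance(fake, ad.Tensor) else fake)
            fake_img = fake_img * 2.0 - 1.0    # detach: D sees arrays
            d_opt.zero_grad()
            d_real = _discriminate(ad.Tensor(real), dparams, config, True)
            d_fake = _discriminate(ad.Tensor(fake_img), dparams, config, True)
            d_loss = _bce_with_logits(d_real, config.label_smooth) \
                + _bce_with_logits(d_fake, 0.0)
            d_loss.backward()
            d_opt.step()

            # -- generator step
            z = rng.standard_normal((b, config.latent_dim))
            g_opt.zero_grad()
            fake = gen.forward(ad.Tensor(z), train=True)
            logits = _discriminate(fake * 2.0 - 1.0, dparams, config, True)
            g_loss = _bce_with_logits(logits, 1.0)
            g_loss.backward()
            # only generator parameters are updated here
            g_opt.step()
            d_opt.zero_grad()
            if verbose:
                print(f"epoch {epoch} step {start // config.batch_size}: "
                      f"d_loss={float(d_loss.data):.4f} "
                      f"g_loss={float(g_loss.data):.4f}")

    if out_dir is not None:
        gen.save(out_dir)
    return gen
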