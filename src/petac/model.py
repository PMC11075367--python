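"""Conditional-GAN networks for NAC-to-AC PET translation.

Generator: 2-D U-Net encoder-decoder with skip connections between
corresponding levels, kernel-4 / stride-2 / pad-1 convolutions,
instance normalization, LeakyReLU down / ReLU up, sigmoid output so the
(0, 1) scaled-SUV contract holds by construction.  Channels double per
level from ``base_channels``, capped at ``8 * base_channels``.

Discriminator: PatchGAN — three stride-2 conv blocks (kernel 4, pad 1)
plus a 1-channel head, conditioned on the NAC slice by channel
concatenation.  Patch responses pass through a sigmoid and are averaged
to one scalar score per image, so a 256x256 input yields a 32x32 patch
map before pooling.

Losses: binary cross-entropy adversarial terms plus an L1
reconstruction term weighted by ``lambda_l1`` (default 100, the usual
Pix-2-Pix setting).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn as _nn
from .nn import (
    Adam,
    Conv2d,
    ConvTranspose2d,
    InstanceNorm2d,
    Layer,
    LeakyReLU,
    Param,
    ReLU,
    Sequential,
    Sigmoid,
)

__all__ = [
    "GeneratorConfig", "DiscriminatorConfig", "LossWeights",
    "UNetGenerator", "PatchDiscriminator",
    "bce", "discriminator_loss", "generator_loss", "generator_loss_grads",
]

_EPS = 1e-7


@dataclass
class GeneratorConfig:
    in_size: int = 256
    depth: int = 8
    base_channels: int = 64
    out_activation: str = "sigmoid"
    #: initial bias of the final (pre-sigmoid) layer.  Scaled PET slices
    #: are mostly background near zero, so starting the sigmoid output
    #: low (e.g. -2.5 -> ~0.08) skips the long transient in which an
    #: untrained net emits ~0.5 everywhere.
    out_bias: float = 0.0

    def __post_init__(self) -> None:
        if self.in_size % (2 ** self.depth) != 0:
            raise ValueError(
                f"in_size {self.in_size} must be divisible by 2^depth={2 ** self.depth}"
            )
        if self.out_activation not in ("sigmoid", "clamp"):
            raise ValueError("out_activation must be 'sigmoid' or 'clamp'")

    @classmethod
    def small(cls) -> "GeneratorConfig":
        """Desk-scale preset: 64x64 input, 4 levels."""
        return cls(in_size=64, depth=4, base_channels=16, out_bias=-2.5)

    @property
    def level_channels(self) -> list[int]:
        return [min(self.base_channels * 2 ** i, 8 * self.base_channels)
                for i in range(self.depth)]


@dataclass
class DiscriminatorConfig:
    n_layers: int = 3
    kernel: int = 4
    stride: int = 2
    padding: int = 1
    base_channels: int = 64

    @classmethod
    def small(cls) -> "DiscriminatorConfig":
        return cls(base_channels=16)


@dataclass
class LossWeights:
    lambda_l1: float = 100.0

    def __post_init__(self) -> None:
        if self.lambda_l1 < 0:
            raise ValueError("lambda_l1 must be >= 0")


class _Clamp(Layer):
    def forward(self, x):
        self._mask = (x > 0) & (x < 1)
        return np.clip(x, 0.0, 1.0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0)


class _UNetBlock(Layer):
    """One U-Net level: down -> submodule -> up, with skip concat."""

    def __init__(self, down: Sequential, sub: Layer | None, up: Sequential,
                 outermost: bool):
        self.down, self.sub, self.up = down, sub, up
        self.outermost = outermost

    def params(self):
        ps = self.down.params() + self.up.params()
        if self.sub is not None:
            ps += self.sub.params()
        return ps

    def forward(self, x):
        d = self.down.forward(x)
        m = self.sub.forward(d) if self.sub is not None else d
        u = self.up.forward(m)
        if self.outermost:
            return u
        self._cx = x.shape[1]
        return np.concatenate([x, u], axis=1)

    def backward(self, dy):
        if self.outermost:
            du = dy
            dskip = 0.0
        else:
            dskip = dy[:, : self._cx]
            du = dy[:, self._cx :]
        dm = self.up.backward(du)
        dd = self.sub.backward(dm) if self.sub is not None else dm
        return dskip + self.down.backward(dd)


class UNetGenerator:
    """2-D U-Net generator mapping a scaled NAC slice to a scaled AC slice."""

    def __init__(self, config: GeneratorConfig | None = None, seed: int = 0):
        self.config = config or GeneratorConfig()
        rng = np.random.default_rng(seed)
        ch = self.config.level_channels
        d = self.config.depth

        # innermost level
        block = _UNetBlock(
            down=Sequential(LeakyReLU(0.2), Conv2d(ch[d - 2], ch[d - 1], rng=rng)),
            sub=None,
            up=Sequential(ReLU(), ConvTranspose2d(ch[d - 1], ch[d - 2], rng=rng),
                          InstanceNorm2d(ch[d - 2])),
            outermost=False,
        )
        for lvl in range(d - 2, 0, -1):
            block = _UNetBlock(
                down=Sequential(LeakyReLU(0.2), Conv2d(ch[lvl - 1], ch[lvl], rng=rng),
                                InstanceNorm2d(ch[lvl])),
                sub=block,
                up=Sequential(ReLU(), ConvTranspose2d(2 * ch[lvl], ch[lvl - 1], rng=rng),
                              InstanceNorm2d(ch[lvl - 1])),
                outermost=False,
            )
        out_act = Sigmoid() if self.config.out_activation == "sigmoid" else _Clamp()
        out_conv = ConvTranspose2d(2 * ch[0], 1, rng=rng)
        out_conv.b.value[...] = self.config.out_bias
        self.net = _UNetBlock(
            down=Sequential(Conv2d(1, ch[0], rng=rng)),
            sub=block,
            up=Sequential(ReLU(), out_conv, out_act),
            outermost=True,
        )

    def params(self) -> list[Param]:
        return self.net.params()

    @property
    def n_params(self) -> int:
        return sum(p.value.size for p in self.params())

    def _check(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=_nn.DTYPE)
        if x.ndim == 2:
            x = x[None, None]
        elif x.ndim == 3:
            x = x[:, None]
        if x.shape[-2:] != (self.config.in_size, self.config.in_size):
            raise ValueError(
                f"expected {self.config.in_size}x{self.config.in_size} input, "
                f"got {x.shape[-2]}x{x.shape[-1]} (no silent resampling)"
            )
        return x

    def forward(self, x: np.ndarray) -> np.ndarray:
        """(B, 1, H, W), (B, H, W) or (H, W) in [0,1] -> (B, 1, H, W) in [0,1]."""
        return self.net.forward(self._check(x))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.net.backward(dy)

    def state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, v in zip(self.params(), state, strict=True):
            p.value[...] = v


class PatchDiscriminator:
    """Conditional PatchGAN scoring (NAC, candidate-AC) slice pairs."""

    def __init__(self, config: DiscriminatorConfig | None = None, seed: int = 1):
        self.config = cfg = config or DiscriminatorConfig()
        rng = np.random.default_rng(seed)
        b = cfg.base_channels
        layers: list[Layer] = [
            Conv2d(2, b, k=cfg.kernel, stride=cfg.stride, pad=cfg.padding, rng=rng),
            LeakyReLU(0.2),
        ]
        c = b
        for _ in range(cfg.n_layers - 1):
            layers += [
                Conv2d(c, 2 * c, k=cfg.kernel, stride=cfg.stride, pad=cfg.padding, rng=rng),
                InstanceNorm2d(2 * c),
                LeakyReLU(0.2),
            ]
            c *= 2
        # 1-channel head preserving the patch-map size, then per-patch sigmoid
        layers += [Conv2d(c, 1, k=1, stride=1, pad=0, rng=rng), Sigmoid()]
        self.net = Sequential(*layers)

    def params(self) -> list[Param]:
        return self.net.params()

    @staticmethod
    def _stack(cond: np.ndarray, cand: np.ndarray) -> np.ndarray:
        cond = np.asarray(cond, dtype=_nn.DTYPE)
        cand = np.asarray(cand, dtype=_nn.DTYPE)
        if cond.shape != cand.shape:
            raise ValueError(
                f"conditioning and candidate slices differ in shape: "
                f"{cond.shape} vs {cand.shape}"
            )
        if cond.ndim == 2:
            cond, cand = cond[None, None], cand[None, None]
        elif cond.ndim == 3:
            cond, cand = cond[:, None], cand[:, None]
        return np.concatenate([cond, cand], axis=1)

    def patch_map(self, cond: np.ndarray, cand: np.ndarray) -> np.ndarray:
        """Sigmoid patch-response map, shape (B, 1, h, w)."""
        return self.net.forward(self._stack(cond, cand))

    def forward(self, cond: np.ndarray, cand: np.ndarray) -> np.ndarray:
        """Scalar score per image in (0, 1): mean over sigmoid patch responses."""
        pm = self.patch_map(cond, cand)
        self._pm_shape = pm.shape
        return pm.mean(axis=(1, 2, 3))

    def backward_scores(self, dscores: np.ndarray) -> np.ndarray:
        """Backprop from per-image score grads; returns grad w.r.t. candidate."""
        b, c, h, w = self._pm_shape
        dpm = np.broadcast_to(
            np.asarray(dscores).reshape(b, 1, 1, 1) / (c * h * w), self._pm_shape
        )
        dx = self.net.backward(np.ascontiguousarray(dpm))
        return dx[:, 1:2]  # candidate channel

    def state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, v in zip(self.params(), state, strict=True):
            p.value[...] = v


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def bce(p, target) -> float:
    """Mean binary cross-entropy of probabilities against a 0/1 target."""
    p = np.clip(np.asarray(p, dtype=np.float64), _EPS, 1.0 - _EPS)
    t = np.broadcast_to(np.asarray(target, dtype=np.float64), p.shape)
    return float(np.mean(-(t * np.log(p) + (1.0 - t) * np.log(1.0 - p))))


def bce_grad(p, target) -> np.ndarray:
    """Gradient of mean BCE w.r.t. the probabilities."""
    p = np.clip(np.asarray(p, dtype=np.float64), _EPS, 1.0 - _EPS)
    t = np.broadcast_to(np.asarray(target, dtype=np.float64), p.shape)
    return (p - t) / (p * (1.0 - p)) / p.size


def discriminator_loss(score_real, score_fake) -> float:
    """BCE(real -> 1) + BCE(fake -> 0)."""
    return bce(score_real, 1.0) + bce(score_fake, 0.0)


def generator_loss(score_fake, gen, target, weights: LossWeights | None = None) -> float:
    """BCE(fake -> 1) + lambda_l1 * mean|gen - target|."""
    w = weights or LossWeights()
    gen = np.asarray(gen, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if gen.shape != target.shape:
        raise ValueError(f"shape mismatch: {gen.shape} vs {target.shape}")
    return bce(score_fake, 1.0) + w.lambda_l1 * float(np.mean(np.abs(gen - target)))


def generator_loss_grads(score_fake, gen, target, weights: LossWeights | None = None):
    """Grads of the generator loss w.r.t. (scores, generated image)."""
    w = weights or LossWeights()
    gen = np.asarray(gen, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    dscore = bce_grad(score_fake, 1.0)
    dgen = w.lambda_l1 * np.sign(gen - target) / gen.size
    return dscore, dgen
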