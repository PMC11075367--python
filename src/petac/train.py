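"""GAN training loop, checkpoint selection, and volume-level inference.

Training follows the slice-based regimen: studies are visited in a
(seeded) random order each epoch; within a study the slices are fed in
consecutive batches of at most ``batch_size``; batch losses are
aggregated per study and averaged across studies into the epoch loss.
After each epoch every validation scan is translated and its NMSE
against the target recorded; the checkpoint minimizing the configured
criterion (median per-scan validation NMSE by default, mean by config)
is kept as the final model.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .metrics import nmse
from .model import (
    DiscriminatorConfig,
    GeneratorConfig,
    LossWeights,
    PatchDiscriminator,
    UNetGenerator,
    bce_grad,
    discriminator_loss,
    generator_loss,
    generator_loss_grads,
)
from .nn import Adam
from .volume import PETVolume

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "EpochLog", "TrainLog", "Checkpoint",
           "train_model", "infer_volume", "save_checkpoint", "load_checkpoint"]


@dataclass
class TrainConfig:
    batch_size: int = 25
    lr: float = 2e-4
    epochs: int = 25
    seed: int = 0
    strategy: str = "v1"
    checkpoint_criterion: str = "median_nmse"
    lambda_l1: float = 100.0
    drop_empty_slices: bool = False

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.strategy not in ("v1", "v2"):
            raise ValueError("strategy must be 'v1' or 'v2'")
        if self.checkpoint_criterion not in ("median_nmse", "mean_nmse"):
            raise ValueError("checkpoint_criterion must be median_nmse or mean_nmse")


@dataclass
class EpochLog:
    epoch: int
    train_loss: float
    val_nmse: list[float]
    criterion: float
    selected: bool = False


@dataclass
class TrainLog:
    epochs: list[EpochLog] = field(default_factory=list)

    @property
    def selected_epoch(self) -> int:
        sel = [e.epoch for e in self.epochs if e.selected]
        if len(sel) != 1:
            raise ValueError(f"expected exactly one selected epoch, got {sel}")
        return sel[0]


@dataclass
class Checkpoint:
    gen_config: GeneratorConfig
    gen_state: list[np.ndarray]
    epoch: int
    criterion: float
    train_config: TrainConfig | None = None

    def generator(self) -> UNetGenerator:
        g = UNetGenerator(self.gen_config)
        g.load_state(self.gen_state)
        return g


def _slices(item) -> np.ndarray:
    arr = item.voxels if isinstance(item, PETVolume) else np.asarray(item, dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[None]
    return arr


def batch_partition(n_slices: int, batch_size: int) -> list[slice]:
    """Consecutive batches of at most batch_size slices."""
    return [slice(i, min(i + batch_size, n_slices))
            for i in range(0, n_slices, batch_size)]


def train_model(
    train_set: list[tuple],
    val_set: list[tuple],
    config: TrainConfig | None = None,
    gen_config: GeneratorConfig | None = None,
    disc_config: DiscriminatorConfig | None = None,
) -> tuple[Checkpoint, TrainLog]:
    """Train the conditional GAN on paired preprocessed (NAC, AC) studies.

    Each element of ``train_set`` / ``val_set`` is a ``(nac, ac)`` pair of
    (0, 1)-scaled volumes (PETVolume or array, slices on axis 0).
    Returns the best checkpoint and the full per-epoch log.
    """
    config = config or TrainConfig()
    gen_config = gen_config or GeneratorConfig()
    disc_config = disc_config or DiscriminatorConfig()
    if not train_set or not val_set:
        raise ValueError("train_set and val_set must be non-empty")

    rng = np.random.default_rng(config.seed)
    weights = LossWeights(lambda_l1=config.lambda_l1)
    gen = UNetGenerator(gen_config, seed=int(rng.integers(2 ** 31)))
    disc = PatchDiscriminator(disc_config, seed=int(rng.integers(2 ** 31)))
    opt_g = Adam(gen.params(), lr=config.lr)
    opt_d = Adam(disc.params(), lr=config.lr)

    studies = []
    for nac, ac in train_set:
        xs, ys = _slices(nac), _slices(ac)
        if xs.shape != ys.shape:
            raise ValueError(f"paired volumes differ in shape: {xs.shape} vs {ys.shape}")
        if config.drop_empty_slices:
            keep = xs.reshape(xs.shape[0], -1).max(axis=1) > 0
            xs, ys = xs[keep], ys[keep]
        if xs.shape[0] == 0:
            logger.warning("skipping study with 0 slices")
            continue
        studies.append((xs, ys))
    if not studies:
        raise ValueError("no non-empty training studies")

    log = TrainLog()
    best: Checkpoint | None = None
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(len(studies))
        study_losses = []
        for si in order:
            xs, ys = studies[si]
            batch_losses = []
            for sl in batch_partition(xs.shape[0], config.batch_size):
                x = xs[sl][:, None]  # (B, 1, H, W)
                y = ys[sl][:, None]

                # --- discriminator update ---
                fake = gen.forward(x)
                opt_d.zero_grad()
                s_real = disc.forward(x[:, 0], y[:, 0])
                disc.backward_scores(bce_grad(s_real, 1.0))
                s_fake = disc.forward(x[:, 0], fake[:, 0])
                disc.backward_scores(bce_grad(s_fake, 0.0))
                d_loss = discriminator_loss(s_real, s_fake)
                opt_d.step()

                # --- generator update (fresh D pass; D grads discarded) ---
                opt_g.zero_grad()
                s_fake2 = disc.forward(x[:, 0], fake[:, 0])
                dscore, dgen = generator_loss_grads(s_fake2, fake, y, weights)
                dfake_adv = disc.backward_scores(dscore)
                gen.backward(dfake_adv + dgen)
                opt_g.step()
                g_loss = generator_loss(s_fake2, fake, y, weights)

                if not np.isfinite(g_loss) or not np.isfinite(d_loss):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch} (G={g_loss}, D={d_loss})"
                    )
                batch_losses.append(g_loss)
            study_losses.append(float(np.mean(batch_losses)))
        train_loss = float(np.mean(study_losses))

        val_scores = []
        for nac, ac in val_set:
            xs, ys = _slices(nac), _slices(ac)
            pred = _forward_stack(gen, xs, config.batch_size)
            val_scores.append(nmse(pred, ys))
        crit = (float(np.median(val_scores))
                if config.checkpoint_criterion == "median_nmse"
                else float(np.mean(val_scores)))
        log.epochs.append(EpochLog(epoch, train_loss, val_scores, crit))
        logger.info("epoch %d: train loss %.4f, val %s %.3f%%",
                    epoch, train_loss, config.checkpoint_criterion, crit)

        if best is None or crit < best.criterion:
            best = Checkpoint(gen_config, gen.state(), epoch, crit, config)

    for e in log.epochs:
        e.selected = e.epoch == best.epoch
    return best, log


def _forward_stack(gen: UNetGenerator, xs: np.ndarray, batch_size: int) -> np.ndarray:
    out = np.empty_like(xs)
    for sl in batch_partition(xs.shape[0], batch_size):
        out[sl] = gen.forward(xs[sl])[:, 0]
    return out


def infer_volume(model, nac_volume: PETVolume, batch_size: int = 25,
                 suv_scale: float = 100.0) -> PETVolume:
    """Translate a preprocessed NAC volume to a generated AC volume in SUV.

    ``model`` may be a Checkpoint, a generator, or any object with a
    slice-batch ``forward``.  Each axial slice passes through the
    generator; the output stack is multiplied by ``suv_scale`` (the clip
    threshold) to return to SUV space, geometry copied from the input.
    """
    gen = model.generator() if isinstance(model, Checkpoint) else model
    xs = _slices(nac_volume)
    out = np.empty_like(xs)
    for sl in batch_partition(xs.shape[0], batch_size):
        pred = np.asarray(gen.forward(xs[sl]))
        if pred.ndim == 4:
            pred = pred[:, 0]
        if pred.shape != xs[sl].shape:
            raise ValueError(
                f"generator output shape {pred.shape} does not match "
                f"input slices {xs[sl].shape}"
            )
        out[sl] = pred
    out = out * suv_scale
    if isinstance(nac_volume, PETVolume):
        return PETVolume(out, spacing=nac_volume.spacing,
                         value_space="SUV", origin=nac_volume.origin)
    return PETVolume(out, value_space="SUV")


def save_checkpoint(ckpt: Checkpoint, path) -> None:
    """Persist config + weights (+ selection state) to an .npz file."""
    header = {
        "gen_config": ckpt.gen_config.__dict__,
        "epoch": ckpt.epoch,
        "criterion": ckpt.criterion,
        "train_config": ckpt.train_config.__dict__ if ckpt.train_config else None,
        "n_arrays": len(ckpt.gen_state),
    }
    arrays = {f"w{i}": a for i, a in enumerate(ckpt.gen_state)}
    np.savez(path, header=json.dumps(header), **arrays)


def load_checkpoint(path) -> Checkpoint:
    with np.load(path, allow_pickle=False) as z:
        header = json.loads(str(z["header"]))
        state = [z[f"w{i}"] for i in range(header["n_arrays"])]
    tc = TrainConfig(**header["train_config"]) if header["train_config"] else None
    return Checkpoint(
        gen_config=GeneratorConfig(**header["gen_config"]),
        gen_state=state,
        epoch=header["epoch"],
        criterion=header["criterion"],
        train_config=tc,
    )
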