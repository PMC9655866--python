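"""Alternating adversarial training protocol, splitting and inference.

Protocol: Adam (beta1=0.5, beta2=0.999), learning rate 0.002 held for the
first 200 epochs then linearly attenuated to 0 at epoch 500; batch size 4;
augmentation by random cropping plus a random transverse-plane rotation of
90/180/270 degrees; one discriminator update followed by one generator
update per batch; every epoch checkpointed.  Desk-scale runs shrink the
volumes, crop and network widths but keep the protocol unchanged.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .grid import DoseDistribution, VolumeGrid
from .losses import (
    LossReport,
    LossWeights,
    avd_loss,
    discriminator_loss,
    generator_adversarial_loss,
    l1_term,
    total_generator_loss,
)
from .networks import (
    DISCRIMINATOR_IN_CHANNELS,
    GENERATOR_IN_CHANNELS,
    Discriminator,
    DiscriminatorSpec,
    Generator,
    GeneratorSpec,
)
from .preprocess import ChannelStack, denormalize_affine, dose_range


@dataclass
class TrainConfig:
    scheme: str = "A"
    epochs: int = 500
    lr0: float = 0.002
    decay_start: int = 200
    betas: tuple[float, float] = (0.5, 0.999)
    batch_size: int = 4
    crop_size: int = 96
    seed: int = 0
    checkpoint_dir: str | None = None
    width_mult: float = 1.0
    loss_weights: LossWeights = field(default_factory=LossWeights)
    reduction: str = "mean"
    augment: bool = True
    log_csv: str | None = None

    def __post_init__(self):
        if self.decay_start >= self.epochs and self.epochs > 0:
            if self.decay_start > self.epochs:
                # a plateau-only schedule is fine for short desk-scale runs
                pass
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")


@dataclass
class SplitPlan:
    """Held-out test ids plus per-fold train/validation id lists."""

    test_ids: list
    folds: list[tuple[list, list]]  # (train_ids, validation_ids) per fold
    seed: int = 0

    def __post_init__(self):
        trainval = set()
        for tr, va in self.folds:
            trainval |= set(tr) | set(va)
        if trainval & set(self.test_ids):
            raise ValueError("test ids overlap the train/validation pool")


def learning_rate_at(epoch: int, config: TrainConfig) -> float:
    """Plateau at lr0 up to ``decay_start``, then linear decay to 0."""
    if epoch < 0 or epoch > config.epochs:
        raise ValueError(f"epoch {epoch} outside [0, {config.epochs}]")
    if epoch <= config.decay_start:
        return config.lr0
    span = config.epochs - config.decay_start
    return config.lr0 * (config.epochs - epoch) / span


def make_split(case_ids, n_test: int, seed: int = 0, n_folds: int = 7) -> SplitPlan:
    """Seeded test split plus k-fold train/validation rotation (ratio 6:1)."""
    ids = list(case_ids)
    if n_test >= len(ids):
        raise ValueError("n_test must leave cases for training")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    test_ids = order[:n_test]
    pool = order[n_test:]
    folds = []
    for f in range(n_folds):
        val = pool[f::n_folds]
        train = [c for c in pool if c not in set(val)]
        folds.append((train, val))
    return SplitPlan(test_ids, folds, seed)


def rotate_transverse(stack_values: np.ndarray, quarter_turns: int) -> np.ndarray:
    """Rotate a (C, D, H, W) array in the transverse (row, column) plane."""
    return np.rot90(stack_values, k=quarter_turns % 4, axes=(2, 3))


def augment_sample(stack: ChannelStack, seed=None, crop_size: int = 96,
                   rng: np.random.Generator | None = None) -> ChannelStack:
    """Random crop to ``crop_size``^3 plus random 90/180/270-degree rotation.

    The same window and rotation apply to every channel; rotation acts in
    the transverse plane only, so masks stay binary and axial anatomy stays
    consistent.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    c, d, h, w = stack.channels.shape
    if min(d, h, w) < crop_size:
        raise ValueError(
            f"input {(d, h, w)} smaller than crop size {crop_size}"
        )
    off = [int(rng.integers(0, n - crop_size + 1)) for n in (d, h, w)]
    window = stack.channels[
        :, off[0] : off[0] + crop_size, off[1] : off[1] + crop_size,
        off[2] : off[2] + crop_size,
    ]
    k = int(rng.integers(1, 4))  # 90, 180 or 270 degrees
    window = rotate_transverse(window, k)
    return ChannelStack(
        stack.scheme, np.ascontiguousarray(window), stack.names,
        stack.prescription, stack.spacing, stack.origin, stack.has_dose,
    )


def _batched(indices, batch_size):
    for i in range(0, len(indices), batch_size):
        yield indices[i : i + batch_size]


def save_checkpoint(path, generator: Generator, discriminator: Discriminator,
                    epoch: int) -> None:
    arrays = {}
    for i, a in enumerate(generator.state_arrays()):
        arrays[f"g_{i}"] = a
    for i, a in enumerate(discriminator.state_arrays()):
        arrays[f"d_{i}"] = a
    arrays["epoch"] = np.array(epoch)
    np.savez(path, **arrays)


def load_checkpoint(path, generator: Generator,
                    discriminator: Discriminator | None = None) -> int:
    data = np.load(path)
    n_g = len(generator.state_arrays())
    generator.load_state_arrays([data[f"g_{i}"] for i in range(n_g)])
    if discriminator is not None:
        n_d = len(discriminator.state_arrays())
        discriminator.load_state_arrays([data[f"d_{i}"] for i in range(n_d)])
    return int(data["epoch"])


def build_models(config: TrainConfig, seed_g: int, seed_d: int):
    gspec = GeneratorSpec(
        in_channels=GENERATOR_IN_CHANNELS[config.scheme],
        width_mult=config.width_mult,
    )
    dspec = DiscriminatorSpec(
        in_channels=DISCRIMINATOR_IN_CHANNELS[config.scheme],
        width_mult=config.width_mult,
    )
    return Generator(gspec, seed=seed_g), Discriminator(dspec, seed=seed_d)


def train_adversarial(stacks: list[ChannelStack], config: TrainConfig):
    """Alternating generator/discriminator optimisation.

    ``stacks`` are training samples *with* the clinical dose channel.
    Returns ``(generator, discriminator, history)`` where ``history`` is a
    list of per-epoch :class:`LossReport`.  All epochs are checkpointed
    when ``config.checkpoint_dir`` is set.
    """
    if not stacks:
        raise ValueError("no training samples")
    master = np.random.SeedSequence(config.seed)
    seed_g, seed_d, seed_aug, seed_order = (
        int(s.generate_state(1)[0] % (2**31)) for s in master.spawn(4)
    )
    gen, disc = build_models(config, seed_g, seed_d)
    opt_g = nn.Adam(gen.parameters(), lr=config.lr0, betas=config.betas)
    opt_d = nn.Adam(disc.parameters(), lr=config.lr0, betas=config.betas)
    aug_rng = np.random.default_rng(seed_aug)
    order_rng = np.random.default_rng(seed_order)
    w = config.loss_weights
    red = config.reduction

    ckpt_dir = Path(config.checkpoint_dir) if config.checkpoint_dir else None
    if ckpt_dir:
        ckpt_dir.mkdir(parents=True, exist_ok=True)
        save_checkpoint(ckpt_dir / "epoch_0000.npz", gen, disc, 0)

    history: list[LossReport] = []
    for epoch in range(1, config.epochs + 1):
        lr = learning_rate_at(epoch, config)
        opt_g.lr = opt_d.lr = lr
        order = order_rng.permutation(len(stacks))
        sums = np.zeros(len(LossReport.FIELDS))
        n_batches = 0
        for batch_ids in _batched(order, config.batch_size):
            samples = []
            for i in batch_ids:
                s = stacks[i]
                if config.augment:
                    s = augment_sample(s, crop_size=config.crop_size, rng=aug_rng)
                samples.append(s)
            real = np.stack([s.channels for s in samples]).astype(np.float32)
            x = real[:, 1:]       # conditioning channels (no dose)
            gt = real[:, :1]      # normalised clinical dose

            # --- discriminator step (generator output detached) -----------
            with nn.no_grad():
                gen.train(True)
                fake_dose = gen(x).data
            opt_d.zero_grad()
            disc.train(True)
            logits_real = disc(real)
            fake_in = np.concatenate([fake_dose, x], axis=1)
            logits_fake = disc(fake_in)
            l_gt, l_pre, l_d = discriminator_loss(logits_real, logits_fake)
            l_d.backward()
            opt_d.step()

            # --- generator step -------------------------------------------
            opt_g.zero_grad()
            opt_d.zero_grad()  # discard discriminator grads from the G pass
            pred = gen(nn.Var(x, requires_grad=False))
            logits = disc(nn.concat([pred, nn.Var(x, requires_grad=False)], axis=1))
            l_adv = generator_adversarial_loss(logits)
            l_avd = avd_loss(gt, pred, reduction=red)
            l_l1 = l1_term(gt, pred, reduction=red)
            l_g = total_generator_loss(l_adv, l_avd, l_l1, w)
            l_g.backward()
            opt_g.step()
            opt_d.zero_grad()

            vals = (
                float(l_gt.data), float(l_pre.data), float(l_d.data),
                float(l_adv.data), float(l_avd.data), float(l_l1.data),
                float(l_g.data),
            )
            if not all(np.isfinite(v) for v in vals):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {n_batches}: {vals}"
                )
            sums += vals
            n_batches += 1
        report = LossReport(*(sums / n_batches))
        history.append(report)
        if ckpt_dir:
            save_checkpoint(ckpt_dir / f"epoch_{epoch:04d}.npz", gen, disc, epoch)
    if config.log_csv:
        write_loss_log(config.log_csv, history)
    return gen, disc, history


def write_loss_log(path, history: list[LossReport]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(("epoch",) + LossReport.FIELDS)
        for i, rep in enumerate(history, start=1):
            writer.writerow([i] + [rep.as_dict()[k] for k in LossReport.FIELDS])


def predict_dose(generator: Generator, stack: ChannelStack,
                 prescription: float | None = None) -> DoseDistribution:
    """Forward pass plus denormalisation of the tanh output to cGy."""
    x = stack.without_dose()
    rx = prescription if prescription is not None else x.prescription
    generator.train(False)
    with nn.no_grad():
        out = generator(x.channels[None].astype(np.float32))
    dose = denormalize_affine(out.data[0, 0], dose_range(rx))
    dose = np.clip(dose, 0.0, None)
    grid = VolumeGrid(dose.astype(np.float32), x.spacing, x.origin)
    return DoseDistribution(grid, rx)
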