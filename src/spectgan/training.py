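"""Alternating adversarial training of the conditional generator pair.

Each step follows the alternating scheme: (i) synthesize a batch with
the generator; (ii) score augmented real slices and accumulate the hinge
loss on real logits plus the self-supervised reconstruction loss;
(iii) score the generated batch for the fake hinge loss; (iv) sum the
discriminator losses; (v) compute the generator loss; (vi) update both
networks with Adam (beta1=0.9, beta2=0.999, lr=2e-4 by default).  Both
gradients are taken against the pre-update networks, then the two
optimizers step.

Real slices are max-normalized, augmented (neighbor weighted average,
anteroposterior translation, selective horizontal flip) and mapped from
[0, 1] to the tanh range [-1, 1] before entering the discriminator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .augment import augment_hflip, augment_translate, augment_weighted_average
from .conditioning import Variant, condition_image, encode_condition
from .discriminator import (
    Discriminator,
    DiscriminatorConfig,
    build_discriminator,
    crop_image_like,
    crop_regional,
)
from .evaluation import lr_ratio, mean_counts
from .generator import (
    Generator,
    GeneratorConfig,
    build_generator,
    sample_images,
    sample_latent,
)
from .losses import (
    loss_discriminator_total,
    loss_fake,
    loss_generator,
    loss_real,
    loss_recon,
)
from .nn import Adam, Tensor
from .nn import concat as tensor_concat
from .slices import Level, Pattern, SpectSlice, normalize_slice

__all__ = [
    "TrainingConfig",
    "TrainingError",
    "LossBreakdown",
    "Checkpoint",
    "TrainResult",
    "train",
    "select_epoch",
    "save_checkpoint",
    "load_checkpoint",
]


class TrainingError(ValueError):
    pass


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 2e-4
    beta1: float = 0.9
    beta2: float = 0.999
    epochs: int = 1000
    batch_size: int = 4
    variant: Variant = Variant.A
    seed: int = 0
    checkpoint_every: int = 25
    # network widths; defaults follow the full-size design
    g_base_channels: int = 256
    d_base_channels: int = 32
    flip_probability: float = 0.5
    max_steps: Optional[int] = None  # early stop for scaled-down runs


@dataclass(frozen=True)
class LossBreakdown:
    l_g: float
    l_real: float
    l_fake: float
    l_recon: float
    l_d_total: float


@dataclass
class Checkpoint:
    epoch: int
    g_state: list
    d_state: list
    g_config: GeneratorConfig
    d_config: DiscriminatorConfig

    def generator(self) -> Generator:
        g = build_generator(self.g_config)
        g.load_state_arrays(self.g_state)
        return g

    def discriminator(self) -> Discriminator:
        d = build_discriminator(self.d_config)
        d.load_state_arrays(self.d_state)
        return d


@dataclass
class TrainResult:
    generator: Generator
    discriminator: Discriminator
    checkpoints: list[Checkpoint]
    log: pd.DataFrame
    config: TrainingConfig = field(repr=False, default=None)


def _prepare_real(
    s: SpectSlice, rng: np.random.Generator, flip_probability: float
) -> np.ndarray:
    """Normalize and augment one real slice; returns pixels in [0, 1]."""
    x = normalize_slice(s)
    if s.neighbor is not None:
        nb = normalize_slice(s.neighbor)
        x = augment_weighted_average(x, nb, float(rng.uniform(0.0, 1.0)))
    x = augment_translate(x, int(rng.integers(-2, 3)))
    if s.pattern != Pattern.UNILATERAL and rng.random() < flip_probability:
        x = augment_hflip(x)
    return np.clip(x.pixels, 0.0, 1.0)


def train(
    dataset: Sequence[SpectSlice],
    config: TrainingConfig,
    progress: Optional[Callable[[int, int, LossBreakdown], None]] = None,
) -> TrainResult:
    """Train generator and discriminator on a labelled slice dataset.

    Variant 'B' restricts the dataset to cortical slices.  Returns the
    final networks, checkpoints every ``checkpoint_every`` epochs (plus the
    last), and a per-step loss log.
    """
    data = list(dataset)
    if config.variant is Variant.B:
        data = [s for s in data if s.level == Level.COR]
    if not data:
        raise TrainingError("empty training dataset")

    root = np.random.SeedSequence(config.seed)
    ss_init, ss_aug, ss_latent, ss_shuffle, ss_crop = root.spawn(5)
    init_seed = int(ss_init.generate_state(1)[0] % (2**31))
    g_config = GeneratorConfig(
        variant=config.variant, base_channels=config.g_base_channels, seed=init_seed
    )
    d_config = DiscriminatorConfig(
        variant=config.variant, base_channels=config.d_base_channels, seed=init_seed + 1
    )
    g = build_generator(g_config)
    d = build_discriminator(d_config)
    opt_g = Adam(g.parameters(), config.learning_rate, config.beta1, config.beta2)
    opt_d = Adam(d.parameters(), config.learning_rate, config.beta1, config.beta2)
    d_params = list(d.parameters())
    g_params = list(g.parameters())

    aug_rng = np.random.default_rng(ss_aug)
    latent_rng = np.random.default_rng(ss_latent)
    shuffle_rng = np.random.default_rng(ss_shuffle)
    crop_rng = np.random.default_rng(ss_crop)

    conds = {
        (s.level, s.pattern): encode_condition(s.level, s.pattern, config.variant)
        for s in data
    }

    rows: list[dict] = []
    checkpoints: list[Checkpoint] = []
    n = len(data)
    step = 0
    stop = False
    for epoch in range(1, config.epochs + 1):
        order = shuffle_rng.permutation(n)
        for start in range(0, n, config.batch_size):
            batch = [data[i] for i in order[start : start + config.batch_size]]
            bs = len(batch)
            real01 = np.stack(
                [_prepare_real(s, aug_rng, config.flip_probability) for s in batch]
            )
            real = Tensor(2.0 * real01[:, None] - 1.0)
            y = np.stack([conds[(s.level, s.pattern)].as_array() for s in batch])
            cond_imgs = np.stack(
                [
                    condition_image(conds[(s.level, s.pattern)], 64, 64)
                    for s in batch
                ]
            )

            # (i) synthesize
            z = sample_latent(bs, latent_rng, g_config.latent_dim)
            fake = g(z, y)

            # (ii)+(iii) one batched discriminator pass over [real; fake],
            # fakes detached: this pass only trains the discriminator
            both = tensor_concat([real, fake.detach()], axis=0)
            both_cond = np.concatenate([cond_imgs, cond_imgs], axis=0)
            logits, b1, b2 = d(both, both_cond)
            real_logits = logits[:bs]
            fake_logits = logits[bs:]
            l_real = loss_real(real_logits)
            l_fake = loss_fake(fake_logits)
            # reconstruction losses are evaluated on real images only
            cropped, loc = crop_regional(b1[:bs], crop_rng)
            reg_recon = d.decoder_regional(cropped)
            reg_target = crop_image_like(real01[:, None], loc, b1.shape[2])
            glob_recon = d.decoder_global(b2[:bs])
            l_recon = loss_recon(reg_recon, reg_target, glob_recon, real01[:, None])

            # (iv) total discriminator loss, then its update
            l_d = loss_discriminator_total(l_real, l_fake, l_recon)
            if not np.isclose(
                l_d.item(),
                l_real.item() + l_fake.item() + l_recon.item(),
                rtol=1e-5,
                atol=1e-6,
            ):
                raise TrainingError("discriminator loss additivity violated")
            for p in d_params:
                p.zero_grad()
            l_d.backward()
            opt_d.step()

            # (v) generator loss against the freshly updated discriminator,
            # (vi) generator update — the alternating scheme
            gen_logits, _, _ = d(fake, cond_imgs)
            l_g = loss_generator(gen_logits)
            for p in g_params + d_params:
                p.zero_grad()
            l_g.backward()
            opt_g.step()
            breakdown = LossBreakdown(
                l_g.item(), l_real.item(), l_fake.item(), l_recon.item(), l_d.item()
            )

            step += 1
            rows.append(
                {
                    "epoch": epoch,
                    "step": step,
                    "l_g": breakdown.l_g,
                    "l_real": breakdown.l_real,
                    "l_fake": breakdown.l_fake,
                    "l_recon": breakdown.l_recon,
                    "l_d_total": breakdown.l_d_total,
                }
            )
            if progress is not None:
                progress(epoch, step, breakdown)
            if config.max_steps is not None and step >= config.max_steps:
                stop = True
                break
        if epoch % config.checkpoint_every == 0 or epoch == config.epochs or stop:
            checkpoints.append(
                Checkpoint(epoch, g.state_arrays(), d.state_arrays(), g_config, d_config)
            )
        if stop:
            break
    return TrainResult(g, d, checkpoints, pd.DataFrame(rows), config)


def select_epoch(
    checkpoints: Sequence[Checkpoint],
    real_dataset: Sequence[SpectSlice],
    samples_per_class: int = 25,
    seed: int = 0,
) -> int:
    """Pick the checkpoint epoch whose samples best match real statistics.

    The criterion is the sum over observed (level, pattern) classes of the
    absolute differences between real and generated per-class mean MC and
    mean LR (on max-normalized images).  Ties break toward the later epoch.
    """
    checkpoints = list(checkpoints)
    if not checkpoints:
        raise TrainingError("no checkpoints to select from")
    variant = checkpoints[0].g_config.variant
    data = list(real_dataset)
    if variant is Variant.B:
        data = [s for s in data if s.level == Level.COR]
    classes: dict[tuple[Level, Pattern], list[np.ndarray]] = {}
    for s in data:
        classes.setdefault((s.level, s.pattern), []).append(
            normalize_slice(s).pixels
        )
    real_stats = {
        key: (
            float(np.mean([mean_counts(p) for p in imgs])),
            float(np.mean([lr_ratio(p) for p in imgs])),
        )
        for key, imgs in classes.items()
    }
    best_epoch, best_score = None, np.inf
    for ckpt in sorted(checkpoints, key=lambda c: c.epoch):
        gen = ckpt.generator()
        rng = np.random.default_rng(seed)
        score = 0.0
        for (level, pattern), (mc_real, lr_real) in real_stats.items():
            imgs = sample_images(gen, level, pattern, samples_per_class, rng)
            mc_gen = float(np.mean([mean_counts(im) for im in imgs]))
            lr_gen = float(np.mean([lr_ratio(im) for im in imgs]))
            score += abs(mc_gen - mc_real) + abs(lr_gen - lr_real)
        if score <= best_score:
            best_epoch, best_score = ckpt.epoch, score
    return best_epoch


def save_checkpoint(path: str | Path, ckpt: Checkpoint) -> Path:
    """Persist a checkpoint as .npz (parameters) + sidecar JSON (config)."""
    path = Path(path)
    arrays = {f"g_{i:03d}": a for i, a in enumerate(ckpt.g_state)}
    arrays.update({f"d_{i:03d}": a for i, a in enumerate(ckpt.d_state)})
    np.savez(path, **arrays)
    meta = {
        "epoch": ckpt.epoch,
        "variant": ckpt.g_config.variant.value,
        "g_base_channels": ckpt.g_config.base_channels,
        "g_seed": ckpt.g_config.seed,
        "latent_dim": ckpt.g_config.latent_dim,
        "embed_dim": ckpt.g_config.embed_dim,
        "d_base_channels": ckpt.d_config.base_channels,
        "d_seed": ckpt.d_config.seed,
    }
    meta_path = path.with_suffix(".json")
    meta_path.write_text(json.dumps(meta, indent=2))
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_checkpoint(path: str | Path) -> Checkpoint:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    meta = json.loads(path.with_suffix(".json").read_text())
    with np.load(path) as data:
        g_state = [data[k] for k in sorted(data.files) if k.startswith("g_")]
        d_state = [data[k] for k in sorted(data.files) if k.startswith("d_")]
    g_config = GeneratorConfig(
        variant=Variant(meta["variant"]),
        latent_dim=meta["latent_dim"],
        embed_dim=meta["embed_dim"],
        base_channels=meta["g_base_channels"],
        seed=meta["g_seed"],
    )
    d_config = DiscriminatorConfig(
        variant=Variant(meta["variant"]),
        base_channels=meta["d_base_channels"],
        seed=meta["d_seed"],
    )
    return Checkpoint(meta["epoch"], g_state, d_state, g_config, d_config)
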