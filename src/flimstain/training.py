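"""Training loop for the virtual-staining GAN.

Implements the full objective alpha * L_adv + beta * L1 + lambda * DISTS
with Adam (beta1 = 0.5, beta2 = 0.999), a learning rate initialised at
1e-4 and divided by 10 every 60 epochs, and optional horizontal-flip /
±15° rotation augmentation. Training alternates one discriminator and one
generator update per batch. All randomness (shuffling, flips, rotation
angles, dropout) derives from a single integer seed, so a run is exactly
reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .coregister import PatchPair
from .dists import DISTSWeights, FeatureExtractor, desk_extractor, dists
from .eval_metrics import mssim
from .gan_model import (LossWeights, PatchDiscriminator, UNetGenerator,
                        adversarial_losses, l1_loss, make_optimisers)
from .nn import Tensor

log = logging.getLogger(__name__)


def learning_rate(epoch: int, init: float = 1e-4, decay_every: int = 60,
                  factor: float = 10.0) -> float:
    """Step schedule: lr(1..60) = init, lr(61..120) = init/10, ..."""
    if epoch < 1:
        raise ValueError("epochs are 1-based")
    return init / factor ** ((epoch - 1) // decay_every)


def pairs_to_arrays(pairs: list[PatchPair]) -> tuple[np.ndarray, np.ndarray]:
    """Stack PatchPairs into (N, C, H, W) input / (N, 3, H, W) target arrays."""
    if not pairs:
        raise ValueError("empty patch set")
    x = np.stack([p.input_patch.pixels.transpose(2, 0, 1) for p in pairs])
    y = np.stack([p.target_patch.transpose(2, 0, 1) for p in pairs])
    return x.astype(np.float32), y.astype(np.float32)


def _augment(x: np.ndarray, y: np.ndarray, rng: np.random.Generator,
             flip: bool, rotate: bool, max_angle: float = 15.0,
             ) -> tuple[np.ndarray, np.ndarray]:
    x, y = x.copy(), y.copy()
    for i in range(x.shape[0]):
        if flip and rng.random() < 0.5:
            x[i] = x[i, :, :, ::-1]
            y[i] = y[i, :, :, ::-1]
        if rotate:
            ang = rng.uniform(-max_angle, max_angle)
            x[i] = ndimage.rotate(x[i], ang, axes=(1, 2), reshape=False,
                                  order=1, mode="reflect")
            y[i] = ndimage.rotate(y[i], ang, axes=(1, 2), reshape=False,
                                  order=1, mode="reflect")
    return x, y


@dataclass
class TrainResult:
    generator: UNetGenerator
    discriminator: PatchDiscriminator
    history: list[dict] = field(default_factory=list)


def evaluate_generator(gen: UNetGenerator, pairs: list[PatchPair]) -> float:
    """Mean MSSIM of the generator's output against the true H&E patches."""
    scores = [mssim(p.target_patch, gen.generate(p.input_patch.pixels))
              for p in pairs]
    return float(np.mean(scores))


def train_gan(pairs: list[PatchPair],
              epochs: int = 20,
              batch_size: int = 4,
              weights: LossWeights = LossWeights(),
              lr_init: float = 1e-4,
              lr_decay_every: int = 60,
              levels: int = 3,
              base: int = 16,
              dropout: float = 0.0,
              augment_flip: bool = True,
              augment_rotate: bool = False,
              extractor: FeatureExtractor | None = None,
              seed: int = 0,
              generator: UNetGenerator | None = None,
              start_epoch: int = 1,
              ) -> TrainResult:
    """Train (or fine-tune, via ``generator``/``start_epoch``) the GAN.

    Returns the trained networks and a per-epoch loss log with the mean
    adversarial, L1 and DISTS components.
    """
    if not pairs:
        raise ValueError("training requires at least one patch pair")
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    x_all, y_all = pairs_to_arrays(pairs)
    n, c_in = x_all.shape[:2]
    if generator is not None and generator.in_channels != c_in:
        raise ValueError(
            f"checkpoint expects {generator.in_channels} input channels but "
            f"the dataset has {c_in}")
    gen = generator or UNetGenerator(c_in, levels=levels, base=base,
                                     dropout=dropout, seed=seed)
    disc = PatchDiscriminator(c_in, base=base, levels=levels, seed=seed + 1)
    opt_g, opt_d = make_optimisers(gen, disc, lr=lr_init)
    if weights.lam > 0:
        extractor = extractor or desk_extractor()
        dw = DISTSWeights.for_extractor(extractor)
    rng = np.random.default_rng(seed + 17)

    result = TrainResult(gen, disc)
    for epoch in range(start_epoch, start_epoch + epochs):
        lr = learning_rate(epoch, init=lr_init, decay_every=lr_decay_every)
        opt_g.lr = opt_d.lr = lr
        order = rng.permutation(n)
        sums = {"loss_d": 0.0, "loss_g_adv": 0.0, "loss_l1": 0.0,
                "loss_dists": 0.0}
        n_batches = 0
        for lo in range(0, n, batch_size):
            idx = order[lo:lo + batch_size]
            xb, yb = x_all[idx], y_all[idx]
            if augment_flip or augment_rotate:
                xb, yb = _augment(xb, yb, rng, augment_flip, augment_rotate)
            x = Tensor(xb)
            y = Tensor(yb)

            s = gen(x)

            # discriminator update (synthetic detached)
            opt_d.zero_grad()
            d_real = disc(y, x)
            d_fake = disc(s.detach(), x)
            loss_d, _ = adversarial_losses(d_real, d_fake)
            (weights.alpha * loss_d).backward()
            opt_d.step()

            # generator update through a fresh discriminator pass
            opt_g.zero_grad()
            _, loss_g_adv = adversarial_losses(d_real.detach(), disc(s, x))
            loss_l1 = l1_loss(y, s)
            total = weights.alpha * loss_g_adv + weights.beta * loss_l1
            if weights.lam > 0:
                loss_dists = dists(y, s, extractor, dw)
                total = total + weights.lam * loss_dists
                sums["loss_dists"] += loss_dists.item()
            total.backward()
            opt_g.step()

            sums["loss_d"] += loss_d.item()
            sums["loss_g_adv"] += loss_g_adv.item()
            sums["loss_l1"] += loss_l1.item()
            n_batches += 1

        row = {"epoch": epoch, "lr": lr}
        row.update({k: v / n_batches for k, v in sums.items()})
        result.history.append(row)
        log.info("epoch %d lr %.2g D %.4f Gadv %.4f L1 %.4f DISTS %.4f",
                 epoch, lr, row["loss_d"], row["loss_g_adv"], row["loss_l1"],
                 row["loss_dists"])
    return result


def stain_field(gen: UNetGenerator, pixels: np.ndarray) -> np.ndarray:
    """Whole-field inference with pad-infer-crop for arbitrary sizes.

    The input is reflect-padded up to a multiple of the generator's
    downsampling factor, inferred in one pass (no patch seams) and cropped
    back to the original extent.
    """
    h, w = pixels.shape[:2]
    f = gen.downsample_factor
    ph, pw = (-h) % f, (-w) % f
    padded = np.pad(pixels, ((0, ph), (0, pw), (0, 0)), mode="reflect")
    out = gen.generate(padded)
    return out[:h, :w]
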