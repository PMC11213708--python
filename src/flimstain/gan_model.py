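"""Conditional generator/discriminator and the adversarial + L1 objectives.

The virtual-staining network is a conditional image-to-image GAN in the
pix2pix mould: a U-Net generator G maps a FLIM-derived input f (1, 3 or 4
channels) to an H&E RGB image s = G(f) in [0, 1], and a patch-based
discriminator D scores (candidate, condition) channel concatenations with a
grid of realism probabilities. The discriminator is trained to label real
H&E as 1 and synthetic as 0 under the standard conditional cross-entropy;
the generator combines the adversarial term with an L1 reconstruction term,
alpha * L_adv + beta * L1 (a perceptual structure/texture term is added by
the DISTS module).
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .nn import (Adam, Conv2d, Dropout, InstanceNorm2d, LeakyReLU, Module,
                 ReLU, Sequential, Tensor, concat)

_LOG_EPS = 1e-8


@dataclass(frozen=True)
class LossWeights:
    """Objective weights: alpha (adversarial), beta (L1), lam (DISTS)."""

    alpha: float = 0.1
    beta: float = 1.0
    lam: float = 5.0

    def __post_init__(self):
        if min(self.alpha, self.beta, self.lam) < 0:
            raise ValueError("loss weights must be non-negative")
        if self.alpha == self.beta == self.lam == 0:
            raise ValueError("at least one loss weight must be positive")


class UNetGenerator(Module):
    """U-Net image-to-image map with a [0, 1]-bounded output.

    ``levels`` stride-2 4x4 conv encoders (features doubling from ``base``,
    capped at 8x), mirrored by 3x3 conv + pixel-shuffle (depth-to-space)
    decoders with skip concatenation, finished by a 1x1 conv and a scaled
    tanh. Dropout in the decoder is the train-time stochasticity source.
    """

    def __init__(self, in_channels: int, levels: int = 3, base: int = 16,
                 dropout: float = 0.0, seed: int = 0, dtype=np.float32):
        super().__init__()
        if in_channels not in (1, 3, 4):
            raise ValueError("in_channels must be 1, 3 or 4")
        rng = np.random.default_rng(seed)
        self.in_channels = in_channels
        self.levels = levels
        feats = [min(base * 2**i, base * 8) for i in range(levels)]
        self.enc_convs: list[Module] = []
        self.enc_norms: list[Module] = []
        ch = in_channels
        for i, f in enumerate(feats):
            self.enc_convs.append(Conv2d(ch, f, 4, stride=2, padding=1,
                                         rng=rng, dtype=dtype))
            self.enc_norms.append(InstanceNorm2d(f, dtype=dtype) if i > 0
                                  else _Identity())
            ch = f
        self.dec_convs: list[Module] = []
        self.dec_norms: list[Module] = []
        self.dec_drops: list[Module] = []
        for i in reversed(range(levels)):
            skip = feats[i - 1] if i > 0 else 0
            out_f = feats[i - 1] if i > 0 else base
            # conv on the coarse grid to 4x channels, then pixel shuffle
            self.dec_convs.append(Conv2d(ch, out_f * 4, 3, stride=1,
                                         padding=1, rng=rng, dtype=dtype))
            self.dec_norms.append(InstanceNorm2d(out_f, dtype=dtype))
            self.dec_drops.append(Dropout(dropout, rng=np.random.default_rng(
                seed + 1000 + i)) if dropout > 0 else _Identity())
            ch = out_f + skip
        self.head = Conv2d(ch, 3, 1, rng=rng, dtype=dtype)
        # bias the initial output toward white: H&E fields are dominated by
        # bright background, so starting near the data mean speeds training
        self.head.weight.data *= 0.2
        self.head.bias.data += 1.2

    @property
    def downsample_factor(self) -> int:
        return 2 ** self.levels

    def forward(self, x: Tensor) -> Tensor:
        skips: list[Tensor] = []
        for conv, norm in zip(self.enc_convs, self.enc_norms):
            x = norm(conv(x)).leaky_relu(0.2)
            skips.append(x)
        for i, (conv, norm, drop) in enumerate(
                zip(self.dec_convs, self.dec_norms, self.dec_drops)):
            x = drop(norm(conv(x).depth_to_space(2)).relu())
            skip_idx = self.levels - 2 - i
            if skip_idx >= 0:  # matching encoder stage is at this resolution
                x = concat([x, skips[skip_idx]], axis=1)
        y = self.head(x)
        return (y.tanh() + 1.0) * 0.5  # bound output to [0, 1]

    def generate(self, pixels: np.ndarray) -> np.ndarray:
        """Inference on one (H, W, C) input; returns (H, W, 3) in [0, 1]."""
        self.eval()
        x = Tensor(np.ascontiguousarray(
            pixels.transpose(2, 0, 1)[None], dtype=np.float32))
        out = self.forward(x)
        self.train()
        return out.data[0].transpose(1, 2, 0).astype(np.float64)


class _Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class PatchDiscriminator(Module):
    """Patch-based conditional realism classifier.

    The candidate H&E and the conditioning input are concatenated on the
    channel axis and reduced by strided 4x4 convs to a score grid squashed
    to (0, 1) by a sigmoid.
    """

    def __init__(self, cond_channels: int, base: int = 16, levels: int = 3,
                 seed: int = 1, dtype=np.float32):
        super().__init__()
        rng = np.random.default_rng(seed)
        ch = 3 + cond_channels
        layers: list[Module] = []
        for i in range(levels):
            f = base * 2**i
            layers.append(Conv2d(ch, f, 4, stride=2, padding=1, rng=rng,
                                 dtype=dtype))
            if i > 0:
                layers.append(InstanceNorm2d(f, dtype=dtype))
            layers.append(LeakyReLU(0.2))
            ch = f
        layers.append(Conv2d(ch, 1, 4, stride=1, padding=1, rng=rng,
                             dtype=dtype))
        self.net = Sequential(*layers)

    def forward(self, candidate: Tensor, condition: Tensor) -> Tensor:
        return self.net(concat([candidate, condition], axis=1)).sigmoid()


# ------------------------------------------------------------------- losses

def adversarial_losses(d_real: Tensor, d_fake: Tensor,
                       d_fake_for_g: Tensor | None = None,
                       ) -> tuple[Tensor, Tensor]:
    """Conditional-GAN cross-entropy from precomputed score grids.

    ``d_real`` = D(h | f), ``d_fake`` = D(G(f).detach() | f) and
    ``d_fake_for_g`` = D(G(f) | f) with gradients attached to G (defaults
    to ``d_fake``). Real images carry label 1:

        loss_D = -[mean log D(h|f) + mean log(1 - D(s|f))]
        loss_G_adv = -mean log D(s|f)

    Scores of exactly 0 or 1 are guarded by an epsilon inside the logs.
    """
    if d_fake_for_g is None:
        d_fake_for_g = d_fake
    loss_d = -((d_real + _LOG_EPS).log().mean()
               + (1.0 - d_fake + _LOG_EPS).log().mean())
    loss_g = -(d_fake_for_g + _LOG_EPS).log().mean()
    return loss_d, loss_g


def l1_loss(h: Tensor | np.ndarray, s: Tensor | np.ndarray) -> Tensor:
    """Mean absolute difference over all pixels and channels."""
    h = h if isinstance(h, Tensor) else Tensor(h)
    s = s if isinstance(s, Tensor) else Tensor(s)
    if h.shape != s.shape:
        raise ValueError(f"shape mismatch: {h.shape} vs {s.shape}")
    return (h - s).abs().mean()


def combine_gan_objective(loss_g_adv: Tensor | float, loss_l1: Tensor | float,
                          w: LossWeights) -> Tensor | float:
    """alpha * adversarial + beta * L1 (the DISTS term is added separately)."""
    return w.alpha * loss_g_adv + w.beta * loss_l1


# --------------------------------------------------------------- checkpoints

def save_checkpoint(path: str | Path, generator: UNetGenerator,
                    meta: dict) -> None:
    """Single-file archive: parameter tensors + a JSON header."""
    state = generator.state_dict()
    header = dict(meta)
    header.update({"in_channels": generator.in_channels,
                   "levels": generator.levels,
                   "base": int(generator.enc_convs[0].weight.shape[0])})
    buf = io.BytesIO()
    np.savez(buf, __header__=np.frombuffer(
        json.dumps(header).encode(), dtype=np.uint8), **state)
    Path(path).write_bytes(buf.getvalue())


def load_checkpoint(path: str | Path) -> tuple[UNetGenerator, dict]:
    with np.load(Path(path)) as archive:
        header = json.loads(bytes(archive["__header__"]).decode())
        state = {k: archive[k] for k in archive.files if k != "__header__"}
    gen = UNetGenerator(header["in_channels"], levels=header["levels"],
                        base=header["base"])
    gen.load_state_dict(state)
    return gen, header


def make_optimisers(generator: Module, discriminator: Module,
                    lr: float = 1e-4, beta1: float = 0.5, beta2: float = 0.999,
                    ) -> tuple[Adam, Adam]:
    return (Adam(generator.parameters(), lr=lr, beta1=beta1, beta2=beta2),
            Adam(discriminator.parameters(), lr=lr, beta1=beta1, beta2=beta2))
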