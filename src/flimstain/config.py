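"""Pipeline configuration with YAML round-trip and named profiles.

The ``full`` profile is the full-scale training recipe (256x256
patches, 300 epochs, Adam with beta1 0.5 / beta2 0.999, learning rate 1e-4
divided by 10 every 60 epochs, horizontal flips and ±15° rotations, loss
weights alpha = 0.1, beta = 1, lambda = 5). The ``desk`` profile is a
CPU-scale variant for demos and tests: 64x64 patches, a 3-level U-Net with
16 base features, 20 epochs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from pathlib import Path

import yaml

from .gan_model import LossWeights
from .stain_formats import FormatTag


@dataclass(frozen=True)
class PipelineConfig:
    # paths
    flim_dir: str = "flim"
    he_dir: str = "he"
    out_dir: str = "out"
    colormap_path: str | None = None
    # input construction
    format_tag: str = FormatTag.IW_FLIM.value
    lifetime_range: tuple[float, float] = (1.0, 5.0)
    pixel_size_flim: float = 0.455       # µm
    pixel_size_he: float = 0.22          # µm
    # patching
    patch_size: int = 256
    stride: int = 128
    eval_stride: int = 256
    background_threshold: float = 0.05
    # objective / optimiser
    alpha: float = 0.1
    beta: float = 1.0
    lam: float = 5.0
    adam_beta1: float = 0.5
    adam_beta2: float = 0.999
    lr_init: float = 1e-4
    lr_decay_every: int = 60
    epochs: int = 300
    batch_size: int = 4
    # architecture
    unet_levels: int = 8
    unet_base: int = 64
    dropout: float = 0.5
    # augmentation
    augment_flip: bool = True
    augment_rotate: bool = True
    # reproducibility
    seed: int = 0

    def loss_weights(self) -> LossWeights:
        return LossWeights(self.alpha, self.beta, self.lam)

    def tag(self) -> FormatTag:
        return FormatTag(self.format_tag)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["lifetime_range"] = list(self.lifetime_range)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "lifetime_range" in d:
            d["lifetime_range"] = tuple(d["lifetime_range"])
        return cls(**d)


DESK_OVERRIDES = dict(patch_size=64, stride=64, eval_stride=64, epochs=20,
                      batch_size=2, unet_levels=3, unet_base=16, dropout=0.0,
                      augment_rotate=False)


def profile_config(profile: str = "full", **overrides) -> PipelineConfig:
    if profile == "full":
        return replace(PipelineConfig(), **overrides)
    if profile == "desk":
        merged = {**DESK_OVERRIDES, **overrides}
        return replace(PipelineConfig(), **merged)
    raise ValueError(f"unknown profile '{profile}' (expected full|desk)")
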