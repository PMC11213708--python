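"""The three candidate network-input formats built from a FLIM field.

A virtual-staining network can be conditioned on (a) the greyscale
autofluorescence intensity alone, inverted so tissue is dark on a white
background; (b) the false-colour lifetime image with normalised intensity
appended as a fourth alpha channel (α-FLIM); or (c) the false-colour
lifetime image multiplied pixelwise by normalised intensity as a soft
weight (IW-FLIM). Lifetime is colour-mapped over a fixed [1.0, 5.0] ns
display range regardless of the data range, so hue is comparable across
fields; sub-range lifetimes saturate at the map ends.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .flim_core import FLIMField, NormalisationContext, normalise_intensity

DEFAULT_LIFETIME_RANGE = (1.0, 5.0)  # ns, fixed display range

# blue→cyan→green→yellow→red anchors, sampled to a 256-entry table
_ANCHORS = np.array([
    [0.0, 0.0, 1.0],
    [0.0, 1.0, 1.0],
    [0.0, 1.0, 0.0],
    [1.0, 1.0, 0.0],
    [1.0, 0.0, 0.0],
])


def default_colormap() -> np.ndarray:
    """The built-in 256x3 blue→green→red lookup table, values in [0, 1]."""
    u = np.linspace(0.0, 1.0, 256)
    pos = u * (len(_ANCHORS) - 1)
    lo = np.minimum(pos.astype(int), len(_ANCHORS) - 2)
    frac = (pos - lo)[:, None]
    return _ANCHORS[lo] * (1 - frac) + _ANCHORS[lo + 1] * frac


def load_colormap(path: str | Path) -> np.ndarray:
    """Load a 256-row CSV of R,G,B values in [0, 1]."""
    table = np.loadtxt(path, delimiter=",")
    if table.shape != (256, 3):
        raise ValueError(f"colour table must be 256x3, got {table.shape}")
    if table.min() < 0 or table.max() > 1:
        raise ValueError("colour-table entries must lie in [0, 1]")
    return table


class FormatTag(str, Enum):
    INTENSITY = "intensity"
    ALPHA_FLIM = "alpha_flim"
    IW_FLIM = "iw_flim"


N_CHANNELS = {FormatTag.INTENSITY: 1, FormatTag.ALPHA_FLIM: 4, FormatTag.IW_FLIM: 3}


@dataclass(frozen=True)
class StainInput:
    """A network-ready raster in one of the three input formats."""

    pixels: np.ndarray            # (H, W, C) in [0, 1]
    format_tag: FormatTag
    colormap_name: str = "builtin-bgr"
    lifetime_range: tuple[float, float] = DEFAULT_LIFETIME_RANGE

    def __post_init__(self):
        c = self.pixels.shape[-1] if self.pixels.ndim == 3 else 1
        if self.pixels.ndim != 3 or c != N_CHANNELS[self.format_tag]:
            raise ValueError(
                f"{self.format_tag.value} requires "
                f"{N_CHANNELS[self.format_tag]} channels, got shape "
                f"{self.pixels.shape}")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("StainInput channels must lie in [0, 1]")
        if not self.lifetime_range[0] < self.lifetime_range[1]:
            raise ValueError("lifetime_range must satisfy lo < hi")

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[-1]


def lifetime_to_rgb(lifetime: np.ndarray,
                    colormap: np.ndarray | None = None,
                    lifetime_range: tuple[float, float] = DEFAULT_LIFETIME_RANGE,
                    ) -> np.ndarray:
    """False-colour a lifetime raster over a fixed ns display range.

    The map position is u = clip((tau - lo) / (hi - lo), 0, 1); the 256-entry
    table is sampled with linear interpolation, so the range endpoints hit
    the first and last entries exactly.
    """
    lo, hi = lifetime_range
    if lo >= hi:
        raise ValueError(f"lifetime_range lo must be < hi, got ({lo}, {hi})")
    cmap = default_colormap() if colormap is None else np.asarray(colormap)
    u = np.clip((np.asarray(lifetime, dtype=float) - lo) / (hi - lo), 0.0, 1.0)
    pos = u * (len(cmap) - 1)
    idx = np.minimum(pos.astype(int), len(cmap) - 2)
    frac = (pos - idx)[..., None]
    return cmap[idx] * (1 - frac) + cmap[idx + 1] * frac


def make_intensity_input(field: FLIMField,
                         ctx: NormalisationContext | None = None) -> StainInput:
    """Inverted normalised intensity: tissue dark on a white background."""
    inv = 1.0 - normalise_intensity(field, ctx)
    return StainInput(inv[..., None], FormatTag.INTENSITY)


def make_alpha_flim(field: FLIMField,
                    ctx: NormalisationContext | None = None,
                    colormap: np.ndarray | None = None,
                    lifetime_range: tuple[float, float] = DEFAULT_LIFETIME_RANGE,
                    ) -> StainInput:
    """False-colour lifetime RGB with normalised intensity as alpha (4ch)."""
    rgb = lifetime_to_rgb(field.lifetime, colormap, lifetime_range)
    alpha = normalise_intensity(field, ctx)
    pixels = np.concatenate([rgb, alpha[..., None]], axis=-1)
    return StainInput(pixels, FormatTag.ALPHA_FLIM, lifetime_range=lifetime_range)


def make_iw_flim(field: FLIMField,
                 ctx: NormalisationContext | None = None,
                 colormap: np.ndarray | None = None,
                 lifetime_range: tuple[float, float] = DEFAULT_LIFETIME_RANGE,
                 ) -> StainInput:
    """Intensity-weighted FLIM: RGB scaled pixelwise by normalised intensity."""
    rgb = lifetime_to_rgb(field.lifetime, colormap, lifetime_range)
    weight = normalise_intensity(field, ctx)
    return StainInput(rgb * weight[..., None], FormatTag.IW_FLIM,
                      lifetime_range=lifetime_range)


def build_stain_input(field: FLIMField, tag: FormatTag,
                      ctx: NormalisationContext | None = None,
                      colormap: np.ndarray | None = None,
                      lifetime_range: tuple[float, float] = DEFAULT_LIFETIME_RANGE,
                      ) -> StainInput:
    if tag is FormatTag.INTENSITY:
        return make_intensity_input(field, ctx)
    if tag is FormatTag.ALPHA_FLIM:
        return make_alpha_flim(field, ctx, colormap, lifetime_range)
    return make_iw_flim(field, ctx, colormap, lifetime_range)


def save_stain_input_png(si: StainInput, path: str | Path) -> None:
    """8-bit PNG for inspection (RGBA for α-FLIM, greyscale for intensity)."""
    arr = np.round(si.pixels * 255).astype(np.uint8)
    if arr.shape[-1] == 1:
        arr = arr[..., 0]
    iio.imwrite(Path(path), arr, extension=".png")
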