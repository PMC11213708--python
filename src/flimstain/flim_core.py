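"""FLIM data model and raw-range post-processing.

A FLIM acquisition exports two co-located single-channel rasters per field:
photon-count intensity and fitted lifetime in nanoseconds. Instrument
exports are clamped to fixed display ranges — intensity to [0, 2000] counts
and lifetime to [0.0, 5.0] ns — before any downstream formatting, and
intensity is normalised globally per cohort (e.g. per TMA core), never per
patch, so that brightness is comparable across fields.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import tifffile

log = logging.getLogger(__name__)

INTENSITY_CLAMP = (0.0, 2000.0)
LIFETIME_CLAMP = (0.0, 5.0)


@dataclass(frozen=True)
class FLIMField:
    """A registered pair of intensity and lifetime rasters.

    Attributes
    ----------
    intensity : (H, W) float array of photon counts, >= 0 after clamping.
    lifetime : (H, W) float array of fitted lifetimes in ns.
    pixel_size : physical pixel edge in micrometres.
    field_id : opaque identifier used in logs and manifests.
    """

    intensity: np.ndarray
    lifetime: np.ndarray
    pixel_size: float
    field_id: str = "field"

    def __post_init__(self):
        if self.intensity.shape != self.lifetime.shape:
            raise ValueError(
                f"intensity {self.intensity.shape} and lifetime "
                f"{self.lifetime.shape} shapes differ")
        if self.intensity.ndim != 2:
            raise ValueError("rasters must be 2-D")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape


@dataclass(frozen=True)
class NormalisationContext:
    """Per-cohort intensity bounds for global normalisation."""

    intensity_min: float = INTENSITY_CLAMP[0]
    intensity_max: float = INTENSITY_CLAMP[1]

    def __post_init__(self):
        if not (self.intensity_max > self.intensity_min >= 0):
            raise ValueError(
                f"require intensity_max > intensity_min >= 0, got "
                f"({self.intensity_min}, {self.intensity_max})")

    @classmethod
    def from_fields(cls, fields: list[FLIMField]) -> "NormalisationContext":
        """Cohort bounds from the pooled intensity range of ``fields``."""
        lo = min(float(f.intensity.min()) for f in fields)
        hi = max(float(f.intensity.max()) for f in fields)
        return cls(lo, hi)


def _read_single_channel(path: str | Path, page: int | None = None) -> np.ndarray:
    path = Path(path)
    try:
        if page is None:
            arr = tifffile.imread(path)
        else:
            arr = tifffile.imread(path, key=page)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read raster {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel 2-D raster, "
                         f"got shape {arr.shape}")
    return arr.astype(np.float64)


def read_flim_field(intensity_path: str | Path, lifetime_path: str | Path,
                    pixel_size: float, field_id: str | None = None) -> FLIMField:
    """Read an intensity/lifetime TIFF pair into an (unclamped) FLIMField.

    NaN lifetime pixels — exponential-fit failures — are replaced by 0 ns
    and counted in a log record; 0 ns renders as background downstream.
    """
    intensity = _read_single_channel(intensity_path)
    lifetime = _read_single_channel(lifetime_path)
    if intensity.shape != lifetime.shape:
        raise ValueError(
            f"shape mismatch: {intensity_path} is {intensity.shape}, "
            f"{lifetime_path} is {lifetime.shape}")
    nan_mask = np.isnan(lifetime)
    if nan_mask.any():
        log.info("field %s: %d NaN lifetime pixels (fit failures) set to 0 ns",
                 field_id or "?", int(nan_mask.sum()))
        lifetime = np.where(nan_mask, 0.0, lifetime)
    if np.isnan(intensity).any():
        raise ValueError(f"{intensity_path}: NaN values in intensity raster")
    return FLIMField(intensity, lifetime, pixel_size,
                     field_id or Path(intensity_path).stem)


def read_flim_field_twopage(path: str | Path, pixel_size: float,
                            field_id: str | None = None) -> FLIMField:
    """Two-page TIFF dialect: page 0 = intensity, page 1 = lifetime."""
    intensity = _read_single_channel(path, page=0)
    lifetime = _read_single_channel(path, page=1)
    nan_mask = np.isnan(lifetime)
    if nan_mask.any():
        log.info("field %s: %d NaN lifetime pixels set to 0 ns",
                 field_id or "?", int(nan_mask.sum()))
        lifetime = np.where(nan_mask, 0.0, lifetime)
    return FLIMField(intensity, lifetime, pixel_size,
                     field_id or Path(path).stem)


def write_flim_field(field: FLIMField, intensity_path: str | Path,
                     lifetime_path: str | Path,
                     sidecar_path: str | Path | None = None) -> None:
    """Write the pair as 32-bit float TIFFs plus a JSON metadata sidecar."""
    tifffile.imwrite(intensity_path, field.intensity.astype(np.float32))
    tifffile.imwrite(lifetime_path, field.lifetime.astype(np.float32))
    if sidecar_path is not None:
        meta = {
            "field_id": field.field_id,
            "pixel_size_um": field.pixel_size,
            "intensity_clamp": list(INTENSITY_CLAMP),
            "lifetime_clamp_ns": list(LIFETIME_CLAMP),
        }
        Path(sidecar_path).write_text(json.dumps(meta, indent=2))


def clamp_flim(field: FLIMField) -> FLIMField:
    """Clip intensity to [0, 2000] counts and lifetime to [0, 5] ns.

    Idempotent; values already inside the ranges pass through unchanged.
    """
    return replace(
        field,
        intensity=np.clip(field.intensity, *INTENSITY_CLAMP),
        lifetime=np.clip(field.lifetime, *LIFETIME_CLAMP),
    )


def normalise_intensity(field: FLIMField,
                        ctx: NormalisationContext | None = None) -> np.ndarray:
    """Linearly rescale intensity by the cohort bounds, clipped to [0, 1].

    ``ctx`` defaults to the clamp bounds (0, 2000) so results are
    reproducible when no cohort statistics are available.
    """
    ctx = ctx or NormalisationContext()
    span = ctx.intensity_max - ctx.intensity_min
    out = (field.intensity - ctx.intensity_min) / span
    return np.clip(out, 0.0, 1.0)
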