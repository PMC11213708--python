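"""H&E preparation, FLIM↔H&E affine co-registration, and patch extraction.

Tissue processing between FLIM acquisition and H&E staining preserves the
underlying structure, so a global 6-parameter affine is sufficient to map
the bright-field H&E raster onto the FLIM pixel grid. Registration drives a
mutual-information similarity (robust across the two modalities) over a
3-level multi-resolution pyramid with dense sampling, which makes the
estimate deterministic for a given input pair. A control-point
least-squares mode is available as a fallback when landmarks are known.

Training patches are cut on a regular grid; a patch whose background
fraction exceeds 0.75 (strictly) carries too little tissue and is dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import SimpleITK as sitk
from scipy import ndimage
from skimage.color import rgb2gray
from skimage.transform import resize

from .stain_formats import StainInput

PATCH_SIZE = 256
BACKGROUND_FRACTION_MAX = 0.75  # strict: drop iff fraction > 0.75
BACKGROUND_INTENSITY_THRESHOLD = 0.05  # normalised counts below this = background

_SWAP = np.array([[0.0, 1.0], [1.0, 0.0]])


class RegistrationError(RuntimeError):
    """Raised when the affine optimiser fails to find overlap."""

    def __init__(self, message: str, similarity: float | None = None):
        super().__init__(message)
        self.similarity = similarity


@dataclass(frozen=True)
class AffineTransform:
    """2x3 matrix mapping moving (H&E) pixel (row, col) to fixed (FLIM) pixel."""

    matrix: np.ndarray  # shape (2, 3), row-major

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (2, 3):
            raise ValueError(f"affine matrix must be 2x3, got {m.shape}")
        if abs(np.linalg.det(m[:, :2])) < 1e-12:
            raise ValueError("affine linear part is singular")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))

    @classmethod
    def from_params(cls, rotation_deg: float = 0.0, shift: tuple[float, float] = (0, 0),
                    scale: float = 1.0, center: tuple[float, float] = (0, 0),
                    ) -> "AffineTransform":
        """Rotation (about ``center``) + isotropic scale + (row, col) shift."""
        th = np.deg2rad(rotation_deg)
        lin = scale * np.array([[np.cos(th), -np.sin(th)],
                                [np.sin(th), np.cos(th)]])
        c = np.asarray(center, dtype=float)
        off = c - lin @ c + np.asarray(shift, dtype=float)
        return cls(np.column_stack([lin, off]))

    @property
    def linear(self) -> np.ndarray:
        return self.matrix[:, :2]

    @property
    def offset(self) -> np.ndarray:
        return self.matrix[:, 2]

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        """Map (n, 2) (row, col) points."""
        return np.asarray(pts, dtype=float) @ self.linear.T + self.offset

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.linear)
        return AffineTransform(np.column_stack([inv, -inv @ self.offset]))

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """self ∘ other: apply ``other`` first."""
        lin = self.linear @ other.linear
        off = self.linear @ other.offset + self.offset
        return AffineTransform(np.column_stack([lin, off]))

    def corner_error(self, truth: "AffineTransform", shape: tuple[int, int]) -> float:
        """Mean displacement (px) of the image corners between two affines."""
        h, w = shape
        corners = np.array([[0, 0], [0, w - 1], [h - 1, 0], [h - 1, w - 1]], float)
        return float(np.linalg.norm(
            self.apply_points(corners) - truth.apply_points(corners), axis=1).mean())

    def to_json(self, path: str | Path | None = None) -> str:
        s = json.dumps([float(v) for v in self.matrix.ravel()])
        if path is not None:
            Path(path).write_text(s)
        return s

    @classmethod
    def from_json(cls, source: str | Path) -> "AffineTransform":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        vals = json.loads(text)
        return cls(np.asarray(vals, dtype=float).reshape(2, 3))


@dataclass(frozen=True)
class PatchPair:
    """One co-registered (network input, H&E target) training patch."""

    input_patch: StainInput
    target_patch: np.ndarray        # (P, P, 3) in [0, 1]
    background_fraction: float
    origin: tuple[int, int]         # (row, col) of the patch in field coords
    field_id: str = "field"

    def __post_init__(self):
        p = self.input_patch.pixels.shape[:2]
        if p != self.target_patch.shape[:2]:
            raise ValueError("input and target patch shapes differ")
        if not 0.0 <= self.background_fraction <= 1.0:
            raise ValueError("background_fraction must lie in [0, 1]")


# --------------------------------------------------------------- preparation

def prepare_he_for_registration(he_rgb: np.ndarray) -> np.ndarray:
    """Greyscale H&E, contrast-stretched so the 1st/99th percentiles hit 0/1."""
    grey = rgb2gray(np.asarray(he_rgb, dtype=float))
    lo, hi = np.percentile(grey, [1.0, 99.0])
    if hi - lo < 1e-12:
        raise ValueError("H&E image has no dynamic range (constant image)")
    return np.clip((grey - lo) / (hi - lo), 0.0, 1.0)


def downsample_he(he_rgb: np.ndarray, src_pixel_size: float,
                  dst_pixel_size: float) -> np.ndarray:
    """Bicubic resample of the finer H&E grid onto the FLIM pixel size."""
    if src_pixel_size <= 0 or dst_pixel_size <= 0:
        raise ValueError("pixel sizes must be positive")
    factor = src_pixel_size / dst_pixel_size
    if factor == 1.0:
        return np.asarray(he_rgb, dtype=float).copy()
    h, w = he_rgb.shape[:2]
    out_shape = (max(1, round(h * factor)), max(1, round(w * factor)))
    out = resize(np.asarray(he_rgb, dtype=float), out_shape + he_rgb.shape[2:],
                 order=3, anti_aliasing=factor < 1, preserve_range=True)
    return np.clip(out, 0.0, 1.0)


# --------------------------------------------------------------- registration

def _sitk_to_affine(tx: sitk.AffineTransform) -> AffineTransform:
    """Convert the (fixed→moving, x-y) SimpleITK result to moving→fixed row-col."""
    m_xy = np.asarray(tx.GetMatrix(), dtype=float).reshape(2, 2)
    c = np.asarray(tx.GetCenter(), dtype=float)
    t = np.asarray(tx.GetTranslation(), dtype=float)
    off_xy = t + c - m_xy @ c
    m_rc = _SWAP @ m_xy @ _SWAP
    off_rc = off_xy[::-1]
    fixed_to_moving = AffineTransform(np.column_stack([m_rc, off_rc]))
    return fixed_to_moving.inverse()


def _affine_to_sitk(t: AffineTransform) -> sitk.AffineTransform:
    inv = t.inverse()  # fixed→moving for the resampling convention
    m_xy = _SWAP @ inv.linear @ _SWAP
    tx = sitk.AffineTransform(2)
    tx.SetMatrix(m_xy.ravel())
    tx.SetTranslation(tuple(inv.offset[::-1]))
    return tx


def _register_once(f_img: sitk.Image, m_img: sitk.Image,
                   initial: sitk.Transform, n_bins: int, n_iterations: int,
                   shrink: list[int], sigmas: list[float],
                   ) -> tuple[AffineTransform, float]:
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=n_bins)
    reg.SetMetricSamplingStrategy(reg.NONE)  # dense → deterministic
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=2.0, minStep=1e-5, numberOfIterations=n_iterations,
        relaxationFactor=0.6, gradientMagnitudeTolerance=1e-7)
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel(shrink)
    reg.SetSmoothingSigmasPerLevel(sigmas)
    reg.SetInitialTransform(initial, inPlace=False)
    result = reg.Execute(f_img, m_img)
    concrete = result.Downcast()
    if isinstance(concrete, sitk.CompositeTransform):
        concrete = concrete.GetNthTransform(0).Downcast()
    return _sitk_to_affine(concrete), reg.GetMetricValue()


def estimate_affine(moving: np.ndarray, fixed: np.ndarray,
                    init: AffineTransform | None = None,
                    n_bins: int = 50, n_iterations: int = 300,
                    init_rotations_deg: tuple[float, ...] = (
                        0., -5., 5., -10., 10., -15., 15.),
                    ) -> AffineTransform:
    """Estimate the moving→fixed affine by mutual-information maximisation.

    Dense (non-sampled) Mattes mutual information over a 3-level pyramid
    (shrink factors 4/2/1) with gradient descent and physical-shift
    parameter scaling; fully deterministic (no stochastic metric sampling).

    Repetitive cellular texture makes the similarity surface multi-modal,
    so unless ``init`` is given the optimiser is first multi-started from a
    grid of initial rotations about the image centre on the coarse pyramid
    level only; the start with the best coarse similarity is then refined
    through the full pyramid.
    """
    f_img = sitk.GetImageFromArray(np.ascontiguousarray(fixed, dtype=np.float32))
    m_img = sitk.GetImageFromArray(np.ascontiguousarray(moving, dtype=np.float32))

    last_error: Exception | None = None
    if init is not None:
        start = _affine_to_sitk(init)
    else:
        centre = ((moving.shape[0] - 1) / 2.0, (moving.shape[1] - 1) / 2.0)
        best_coarse: tuple[AffineTransform, float] | None = None
        for angle in init_rotations_deg:
            initial = _affine_to_sitk(
                AffineTransform.from_params(rotation_deg=angle, center=centre))
            try:
                t, metric = _register_once(f_img, m_img, initial, n_bins,
                                           n_iterations, [4, 2], [2.0, 1.0])
            except RuntimeError as exc:
                last_error = exc
                continue
            if best_coarse is None or metric < best_coarse[1]:  # MI negated
                best_coarse = (t, metric)
        if best_coarse is None:
            raise RegistrationError(
                f"affine optimiser failed for every start: {last_error}")
        start = _affine_to_sitk(best_coarse[0])

    try:
        t, final_metric = _register_once(f_img, m_img, start, n_bins,
                                         n_iterations, [4, 2, 1],
                                         [2.0, 1.0, 0.0])
    except RuntimeError as exc:
        raise RegistrationError(f"affine optimiser failed: {exc}") from exc
    if final_metric > -1e-3:
        raise RegistrationError(
            f"registration found no mutual information "
            f"(final similarity {final_metric:.6f})", similarity=final_metric)
    return t


def estimate_affine_from_points(moving_pts: np.ndarray, fixed_pts: np.ndarray,
                                ) -> AffineTransform:
    """Least-squares affine from ≥3 matched (row, col) control points."""
    mv = np.asarray(moving_pts, dtype=float)
    fx = np.asarray(fixed_pts, dtype=float)
    if mv.shape != fx.shape or mv.shape[0] < 3:
        raise ValueError("need >= 3 matched control-point pairs")
    design = np.column_stack([mv, np.ones(len(mv))])
    sol, *_ = np.linalg.lstsq(design, fx, rcond=None)
    return AffineTransform(sol.T)


def apply_affine(image: np.ndarray, t: AffineTransform,
                 out_shape: tuple[int, int], fill: float = 0.0) -> np.ndarray:
    """Inverse-warp ``image`` onto the fixed grid with bilinear sampling.

    ``fill`` is the out-of-domain value: 1.0 (white) for H&E, 0 for intensity.
    """
    inv = t.inverse()
    image = np.asarray(image, dtype=float)

    def _warp(chan: np.ndarray) -> np.ndarray:
        return ndimage.affine_transform(
            chan, inv.linear, offset=inv.offset, output_shape=out_shape,
            order=1, mode="constant", cval=fill)

    if image.ndim == 2:
        return _warp(image)
    return np.stack([_warp(image[..., c]) for c in range(image.shape[-1])],
                    axis=-1)


# ---------------------------------------------------------------- patching

def background_mask_from_intensity(norm_intensity: np.ndarray,
                                   threshold: float = BACKGROUND_INTENSITY_THRESHOLD,
                                   ) -> np.ndarray:
    """Background = pixels whose normalised photon intensity is < threshold."""
    return np.asarray(norm_intensity) < threshold


def extract_patches(input_image: StainInput, target_image: np.ndarray,
                    background_mask: np.ndarray, patch: int = PATCH_SIZE,
                    stride: int | None = None, field_id: str = "field",
                    ) -> list[PatchPair]:
    """Cut co-registered patches on a regular grid and filter by background.

    Partial edge patches are dropped; a patch is retained iff its mean
    background fraction is <= 0.75 (strictly-greater patches are dropped).
    """
    h, w = input_image.pixels.shape[:2]
    if target_image.shape[:2] != (h, w) or background_mask.shape != (h, w):
        raise ValueError("input, target and mask must share the same grid")
    if patch > h or patch > w:
        raise ValueError(f"patch size {patch} exceeds image shape {(h, w)}")
    stride = stride or patch
    pairs: list[PatchPair] = []
    for r in range(0, h - patch + 1, stride):
        for c in range(0, w - patch + 1, stride):
            frac = float(background_mask[r:r + patch, c:c + patch].mean())
            if frac > BACKGROUND_FRACTION_MAX:
                continue
            crop = StainInput(input_image.pixels[r:r + patch, c:c + patch],
                              input_image.format_tag,
                              input_image.colormap_name,
                              input_image.lifetime_range)
            pairs.append(PatchPair(crop,
                                   target_image[r:r + patch, c:c + patch],
                                   frac, (r, c), field_id))
    return pairs
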