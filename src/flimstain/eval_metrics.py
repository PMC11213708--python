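"""Similarity metrics between virtual and true H&E images.

Four full-reference metrics with pinned conventions:

* NRMSE — Euclidean error normalised by the reference norm,
  ||ref - test||_2 / ||ref||_2 (lower is better).
* NMI — normalised mutual information (H1 + H2) / H12 from a 256-bin joint
  histogram of greyscale intensities; 1 = independent, 2 = identical
  (higher is better).
* PSNR — 10 log10(peak^2 / MSE) in dB with peak 1.0 on normalised images;
  identical images report +inf (higher is better).
* MSSIM — mean structural similarity with a Gaussian 11x11 window
  (sigma 1.5), K1 = 0.01, K2 = 0.03, data range 1.0; RGB images are scored
  per channel and averaged (higher is better).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.color import rgb2gray
from skimage.metrics import normalized_mutual_information
from skimage.metrics import structural_similarity

from .stain_formats import FormatTag

NMI_BINS = 256


def _check_pair(ref: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.asarray(ref, dtype=float)
    test = np.asarray(test, dtype=float)
    if ref.shape != test.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {test.shape}")
    return ref, test


def nrmse(ref: np.ndarray, test: np.ndarray) -> float:
    """Euclidean-norm-normalised RMS error over all pixels and channels."""
    ref, test = _check_pair(ref, test)
    denom = np.linalg.norm(ref.ravel())
    if denom == 0:
        raise ValueError("reference image is identically zero")
    return float(np.linalg.norm((ref - test).ravel()) / denom)


def nmi(ref: np.ndarray, test: np.ndarray, bins: int = NMI_BINS) -> float:
    """Normalised mutual information (H1 + H2) / H12 on greyscale images."""
    ref, test = _check_pair(ref, test)
    if ref.ndim == 3:
        ref, test = rgb2gray(ref), rgb2gray(test)
    if np.ptp(ref) == 0 or np.ptp(test) == 0:
        raise ValueError("NMI is undefined for constant images")
    return float(normalized_mutual_information(ref, test, bins=bins))


def psnr(ref: np.ndarray, test: np.ndarray, peak: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; identical images give +inf."""
    ref, test = _check_pair(ref, test)
    mse = float(np.mean((ref - test) ** 2))
    if mse == 0:
        return float("inf")
    return float(10.0 * np.log10(peak**2 / mse))


def mssim(ref: np.ndarray, test: np.ndarray) -> float:
    """Mean SSIM, Gaussian window 11/sigma 1.5; RGB averaged per channel."""
    ref, test = _check_pair(ref, test)
    if min(ref.shape[:2]) < 11:
        raise ValueError("image smaller than the 11x11 SSIM window")
    kwargs = dict(win_size=11, gaussian_weights=True, sigma=1.5,
                  use_sample_covariance=False, K1=0.01, K2=0.03,
                  data_range=1.0)
    if ref.ndim == 2:
        return float(structural_similarity(ref, test, **kwargs))
    vals = [structural_similarity(ref[..., c], test[..., c], **kwargs)
            for c in range(ref.shape[-1])]
    return float(np.mean(vals))


def all_metrics(ref: np.ndarray, test: np.ndarray) -> dict[str, float]:
    return {"nrmse": nrmse(ref, test), "nmi": nmi(ref, test),
            "psnr": psnr(ref, test), "mssim": mssim(ref, test)}


# ------------------------------------------------------------------ reports

#: metric → True when larger values mean more similar images
HIGHER_IS_BETTER = {"nrmse": False, "nmi": True, "psnr": True, "mssim": True}


@dataclass
class MetricReport:
    """Per-field and aggregate metric values for one input format."""

    format_tag: FormatTag
    field_ids: list[str]
    per_field: dict[str, dict[str, float]] = field(default_factory=dict)

    @classmethod
    def from_pairs(cls, format_tag: FormatTag,
                   pairs: dict[str, tuple[np.ndarray, np.ndarray]],
                   ) -> "MetricReport":
        """``pairs``: field_id → (true H&E, virtual H&E)."""
        report = cls(format_tag, sorted(pairs))
        for fid in report.field_ids:
            ref, test = pairs[fid]
            report.per_field[fid] = all_metrics(ref, test)
        return report

    def aggregate(self) -> dict[str, float]:
        out = {}
        for m in HIGHER_IS_BETTER:
            out[m] = float(np.mean([self.per_field[f][m]
                                    for f in self.field_ids]))
        return out

    def to_tsv(self, path: str | Path) -> None:
        cols = list(HIGHER_IS_BETTER)
        lines = ["field_id\t" + "\t".join(cols)]
        for fid in self.field_ids:
            lines.append(fid + "\t" + "\t".join(
                f"{self.per_field[fid][m]:.6g}" for m in cols))
        Path(path).write_text("\n".join(lines) + "\n")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"format": self.format_tag.value, "aggregate": self.aggregate(),
             "per_field": self.per_field}, indent=2))


def compare_formats(reports: list[MetricReport]) -> dict[str, list[tuple[str, float, bool]]]:
    """Rank input formats per metric; best first, ties flagged.

    Returns metric → list of (format, aggregate value, is_best); every
    report must cover the same field set.
    """
    if not reports:
        raise ValueError("no reports to compare")
    field_sets = {tuple(r.field_ids) for r in reports}
    if len(field_sets) > 1:
        raise ValueError("reports cover different field sets")
    table: dict[str, list[tuple[str, float, bool]]] = {}
    for m, higher in HIGHER_IS_BETTER.items():
        scored = [(r.format_tag.value, r.aggregate()[m]) for r in reports]
        scored.sort(key=lambda kv: kv[1], reverse=higher)
        best = scored[0][1]
        table[m] = [(name, val, np.isclose(val, best, rtol=0, atol=1e-12))
                    for name, val in scored]
    return table


def format_comparison_grid(table: dict[str, list[tuple[str, float, bool]]]) -> str:
    """Human-readable grid: one row per format, one column per metric."""
    formats = [name for name, _, _ in next(iter(table.values()))]
    formats = sorted(set(formats))
    lines = ["format    " + "".join(f"{m:>12}" for m in table)]
    for fmt in formats:
        cells = []
        for m in table:
            for name, val, best in table[m]:
                if name == fmt:
                    mark = "*" if best else " "
                    cells.append(f"{val:>11.4g}{mark}")
        lines.append(f"{fmt:<10}" + "".join(cells))
    lines.append("(* best per metric; NRMSE lower-is-better, others higher)")
    return "\n".join(lines)
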