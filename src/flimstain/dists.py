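"""Deep Image Structure and Texture Similarity (DISTS) loss.

DISTS compares two RGB images through a hierarchy of convolutional feature
maps. Stage 0 is the image itself; deeper stages come from a pluggable
feature extractor. For every feature map j of stage i the *texture* term
compares global means,

    T_ij = (2 mu_r mu_s + c1) / (mu_r^2 + mu_s^2 + c1),

and the *structure* term compares global (co)variances,

    S_ij = (2 sigma_rs + c2) / (sigma_r^2 + sigma_s^2 + c2).

The loss is 1 - sum_ij (eta_ij T_ij + theta_ij S_ij) with non-negative map
weights normalised to sum(eta + theta) = 1, so identical images score 0.
Everything runs on the autodiff engine, making the loss differentiable with
respect to the synthetic image.

Two extractors ship with the package: a tiny fixed two-map extractor used
by the correctness oracle, and a VGG16-topology extractor with fixed-seed
orthogonal weights that works fully offline. Both are deterministic.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .gan_model import LossWeights
from .nn import Tensor

DEFAULT_C1 = 1e-6
DEFAULT_C2 = 1e-6


# ------------------------------------------------------------- term formulas

def texture_term(r_map: np.ndarray, s_map: np.ndarray,
                 c1: float = DEFAULT_C1) -> float:
    """Global-mean similarity of two feature maps (symmetric, 1 if equal)."""
    if r_map.shape != s_map.shape:
        raise ValueError("feature maps must share a shape")
    mu_r, mu_s = float(np.mean(r_map)), float(np.mean(s_map))
    return (2 * mu_r * mu_s + c1) / (mu_r**2 + mu_s**2 + c1)


def structure_term(r_map: np.ndarray, s_map: np.ndarray,
                   c2: float = DEFAULT_C2) -> float:
    """Global-covariance similarity of two feature maps."""
    if r_map.shape != s_map.shape:
        raise ValueError("feature maps must share a shape")
    r, s = np.asarray(r_map, float).ravel(), np.asarray(s_map, float).ravel()
    var_r = float(np.mean(r**2) - np.mean(r) ** 2)
    var_s = float(np.mean(s**2) - np.mean(s) ** 2)
    cov = float(np.mean(r * s) - np.mean(r) * np.mean(s))
    return (2 * cov + c2) / (var_r + var_s + c2)


# --------------------------------------------------------------- extractors

class FeatureExtractor:
    """Base: maps an (N, 3, H, W) Tensor to feature stages.

    ``extract`` returns a list of Tensors, one per stage, each of shape
    (N, n_i, H_i, W_i); stage 0 is always the input image itself.
    """

    def extract(self, x: Tensor) -> list[Tensor]:
        raise NotImplementedError

    def n_maps(self, image_channels: int = 3) -> list[int]:
        """Number of feature maps per stage, for weight validation."""
        probe = Tensor(np.zeros((1, image_channels, 16, 16)))
        return [int(s.shape[1]) for s in self.extract(probe)]


class TinyMeanExtractor(FeatureExtractor):
    """One stage of two fixed 2x2-mean maps — the oracle-testable extractor.

    Map 1 is the plain 2x2 spatial mean of the channel average; map 2 is a
    2x2 mean with a fixed asymmetric channel mixing. Stride 2, no padding.
    """

    def __init__(self, dtype=np.float64):
        k1 = np.full((3, 2, 2), 1.0 / 12.0)
        mix = np.array([0.6, 0.3, 0.1])
        k2 = np.repeat(mix[:, None, None], 2, axis=1)
        k2 = np.repeat(k2, 2, axis=2) / 4.0
        self.weight = Tensor(np.stack([k1, k2]).astype(dtype))

    def extract(self, x: Tensor) -> list[Tensor]:
        return [x, x.conv2d(self.weight, stride=2, padding=0)]


class RandomVGGExtractor(FeatureExtractor):
    """VGG16-topology extractor with fixed-seed orthogonal kernels.

    Five stages of 3x3 conv blocks (channel widths 64/128/256/512/512 by
    default, configurable) with ReLU and 2x2 average pooling between
    blocks; the stage output is the last conv of each block. Weights are
    orthogonally initialised from a Philox stream, so the extractor is
    identical on every platform and needs no downloaded weights.
    """

    VGG16_PLAN = ((64, 2), (128, 2), (256, 3), (512, 3), (512, 3))

    def __init__(self, plan=VGG16_PLAN, seed: int = 7, dtype=np.float32):
        rng = np.random.Generator(np.random.Philox(seed))
        self.plan = tuple(plan)
        self.weights: list[list[Tensor]] = []
        in_ch = 3
        for width, n_convs in self.plan:
            stage = []
            for _ in range(n_convs):
                w = self._orthogonal(rng, width, in_ch * 9).reshape(
                    width, in_ch, 3, 3)
                stage.append(Tensor(w.astype(dtype)))
                in_ch = width
            self.weights.append(stage)

    @staticmethod
    def _orthogonal(rng, rows: int, cols: int) -> np.ndarray:
        a = rng.normal(size=(max(rows, cols), min(rows, cols)))
        q, r = np.linalg.qr(a)
        q = q * np.sign(np.diag(r))  # deterministic sign convention
        return (q if rows >= cols else q.T) * np.sqrt(2.0)

    def extract(self, x: Tensor) -> list[Tensor]:
        stages = [x]
        h = x
        for i, stage_weights in enumerate(self.weights):
            if i > 0:
                h = h.avg_pool2d(2)
            for w in stage_weights:
                h = h.conv2d(w, stride=1, padding=1).relu()
            stages.append(h)
        return stages


def desk_extractor(seed: int = 7) -> RandomVGGExtractor:
    """A lightweight 3-stage extractor for CPU-scale training runs."""
    return RandomVGGExtractor(plan=((8, 1), (16, 1), (32, 1)), seed=seed)


# ------------------------------------------------------------------ weights

class DISTSWeights:
    """Non-negative per-map texture (eta) / structure (theta) weights.

    The weights satisfy sum(eta) + sum(theta) = 1 so that DISTS of an image
    with itself is exactly zero.
    """

    def __init__(self, eta: list[np.ndarray], theta: list[np.ndarray]):
        self.eta = [np.asarray(e, dtype=float) for e in eta]
        self.theta = [np.asarray(t, dtype=float) for t in theta]
        if len(self.eta) != len(self.theta):
            raise ValueError("eta and theta must have the same stage count")
        total = sum(e.sum() for e in self.eta) + sum(t.sum() for t in self.theta)
        if any((e < 0).any() for e in self.eta) or \
           any((t < 0).any() for t in self.theta):
            raise ValueError("DISTS weights must be non-negative")
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"sum(eta) + sum(theta) must equal 1, got {total}")

    @classmethod
    def uniform(cls, n_maps: list[int]) -> "DISTSWeights":
        total = 2 * sum(n_maps)
        return cls([np.full(n, 1.0 / total) for n in n_maps],
                   [np.full(n, 1.0 / total) for n in n_maps])

    @classmethod
    def for_extractor(cls, extractor: FeatureExtractor) -> "DISTSWeights":
        return cls.uniform(extractor.n_maps())

    def validate_against(self, stages: list[Tensor]) -> None:
        shapes = [int(s.shape[1]) for s in stages]
        ours = [len(e) for e in self.eta]
        if shapes != ours:
            raise ValueError(
                f"weight stage structure {ours} does not match extractor "
                f"stages {shapes}")

    def to_json(self, path: str | Path) -> None:
        payload = {str(i): {"eta": e.tolist(), "theta": t.tolist()}
                   for i, (e, t) in enumerate(zip(self.eta, self.theta))}
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "DISTSWeights":
        payload = json.loads(Path(path).read_text())
        stages = sorted(payload, key=int)
        return cls([np.asarray(payload[s]["eta"]) for s in stages],
                   [np.asarray(payload[s]["theta"]) for s in stages])


# --------------------------------------------------------------------- loss

def _to_nchw_tensor(img) -> Tensor:
    if isinstance(img, Tensor):
        x = img
    else:
        arr = np.asarray(img, dtype=float)
        if arr.ndim == 2:
            arr = arr[..., None]
        if arr.ndim == 3:
            arr = arr.transpose(2, 0, 1)[None]
        x = Tensor(arr)
    if x.shape[1] == 1:  # replicate grey to RGB for the extractor
        from .nn import concat
        x = concat([x, x, x], axis=1)
    return x


def dists(r, s, extractor: FeatureExtractor | None = None,
          weights: DISTSWeights | None = None,
          c1: float = DEFAULT_C1, c2: float = DEFAULT_C2) -> Tensor:
    """DISTS between a reference and a candidate image (0 = identical).

    Accepts (H, W, 3) arrays or (N, 3, H, W) Tensors; returns a scalar
    Tensor (mean over the batch) that backpropagates into ``s`` when ``s``
    is part of an autodiff graph.
    """
    extractor = extractor or RandomVGGExtractor()
    xr = _to_nchw_tensor(r)
    xs = _to_nchw_tensor(s)
    if xr.shape != xs.shape:
        raise ValueError(f"image shapes differ: {xr.shape} vs {xs.shape}")
    stages_r = extractor.extract(xr)
    stages_s = extractor.extract(xs)
    weights = weights or DISTSWeights.uniform(
        [int(st.shape[1]) for st in stages_r])
    weights.validate_against(stages_r)

    n = xr.shape[0]
    score = Tensor(np.zeros(n, dtype=xr.dtype))
    for fr, fs, eta, theta in zip(stages_r, stages_s, weights.eta,
                                  weights.theta):
        mu_r = fr.mean(axis=(2, 3))                      # (N, n_i)
        mu_s = fs.mean(axis=(2, 3))
        var_r = (fr * fr).mean(axis=(2, 3)) - mu_r * mu_r
        var_s = (fs * fs).mean(axis=(2, 3)) - mu_s * mu_s
        cov = (fr * fs).mean(axis=(2, 3)) - mu_r * mu_s
        t_term = (2.0 * mu_r * mu_s + c1) / (mu_r**2 + mu_s**2 + c1)
        s_term = (2.0 * cov + c2) / (var_r + var_s + c2)
        w_eta = Tensor(np.broadcast_to(eta, t_term.shape).astype(t_term.dtype))
        w_theta = Tensor(np.broadcast_to(theta, s_term.shape).astype(s_term.dtype))
        score = score + (w_eta * t_term + w_theta * s_term).sum(axis=1)
    return (1.0 - score).mean()


def full_objective(loss_g_adv, loss_l1, dists_value, w: LossWeights):
    """alpha * L_adv + beta * L1 + lambda * DISTS — the training objective."""
    return w.alpha * loss_g_adv + w.beta * loss_l1 + w.lam * dists_value
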