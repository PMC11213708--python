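import numpy as np
import pytest
from scipy import ndimage

from flimstain.dists import (DISTSWeights, RandomVGGExtractor,
                             TinyMeanExtractor, desk_extractor, dists,
                             full_objective, structure_term, texture_term)
from flimstain.gan_model import LossWeights
from flimstain.nn import Tensor


def brute_force_dists(r, s, extractor, c1=1e-6, c2=1e-6):
    """Independent oracle: per-map means/variances/covariances by hand."""
    stages_r = [t.data[0] for t in extractor.extract(
        Tensor(r.transpose(2, 0, 1)[None]))]
    stages_s = [t.data[0] for t in extractor.extract(
        Tensor(s.transpose(2, 0, 1)[None]))]
    n_maps = sum(st.shape[0] for st in stages_r)
    w = 1.0 / (2 * n_maps)  # uniform eta = theta
    total = 0.0
    for fr, fs in zip(stages_r, stages_s):
        for j in range(fr.shape[0]):
            a, b = fr[j].ravel(), fs[j].ravel()
            mu_a, mu_b = a.mean(), b.mean()
            t_term = (2 * mu_a * mu_b + c1) / (mu_a**2 + mu_b**2 + c1)
            cov = (a * b).mean() - mu_a * mu_b
            s_term = (2 * cov + c2) / (a.var() + b.var() + c2)
            total += w * t_term + w * s_term
    return 1.0 - total


class TestTermFormulas:
    def test_texture_identity_and_symmetry(self, rng):
        m = rng.random((4, 4))
        n = rng.random((4, 4))
        assert texture_term(m, m) == pytest.approx(1.0)
        assert texture_term(m, n) == pytest.approx(texture_term(n, m))

    def test_texture_disjoint_means(self):
        ones, zeros = np.ones((4, 4)), np.zeros((4, 4))
        assert texture_term(ones, zeros, c1=1e-6) == pytest.approx(1e-6, rel=1e-3)

    def test_structure_identity_and_anticorrelation(self, rng):
        m = rng.random((6, 6))
        m -= m.mean()
        assert structure_term(m, m) == pytest.approx(1.0)
        assert structure_term(m, -m) == pytest.approx(-1.0, abs=1e-4)

    def test_structure_of_constant_maps_is_one(self):
        a = np.full((4, 4), 0.3)
        b = np.full((4, 4), 0.9)
        assert structure_term(a, b) == pytest.approx(1.0)


class TestWeights:
    def test_normalisation_enforced(self):
        with pytest.raises(ValueError, match="equal 1"):
            DISTSWeights([np.array([0.5])], [np.array([0.6])])
        with pytest.raises(ValueError, match="non-negative"):
            DISTSWeights([np.array([-0.5, 1.0])], [np.array([0.25, 0.25])])

    def test_uniform_sums_to_one(self):
        w = DISTSWeights.uniform([3, 2])
        total = sum(e.sum() for e in w.eta) + sum(t.sum() for t in w.theta)
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_json_roundtrip_and_structure_validation(self, tmp_path, rng):
        ext = TinyMeanExtractor()
        w = DISTSWeights.for_extractor(ext)
        w.to_json(tmp_path / "w.json")
        back = DISTSWeights.from_json(tmp_path / "w.json")
        x = rng.random((8, 8, 3))
        assert dists(x, x, ext, back).item() == pytest.approx(0.0, abs=1e-12)
        wrong = DISTSWeights.uniform([3, 5])
        with pytest.raises(ValueError, match="stage structure"):
            dists(x, x, ext, wrong)


class TestDistsValue:
    def test_identity_and_symmetry_tiny(self, rng):
        ext = TinyMeanExtractor()
        for _ in range(5):
            x, y = rng.random((8, 8, 3)), rng.random((8, 8, 3))
            assert dists(x, x, ext).item() == pytest.approx(0.0, abs=1e-12)
            assert dists(x, y, ext).item() == pytest.approx(
                dists(y, x, ext).item(), abs=1e-12)

    def test_oracle_equivalence(self, rng):
        ext = TinyMeanExtractor()
        for _ in range(10):
            x, y = rng.random((8, 8, 3)), rng.random((8, 8, 3))
            assert dists(x, y, ext).item() == pytest.approx(
                brute_force_dists(x, y, ext), abs=1e-10)

    def test_bounds_with_uniform_weights(self, rng):
        ext = TinyMeanExtractor()
        for _ in range(10):
            x, y = rng.random((8, 8, 3)), rng.random((8, 8, 3))
            assert 0.0 - 1e-12 <= dists(x, y, ext).item() <= 2.0

    def test_gradient_matches_finite_differences(self, rng):
        ext = TinyMeanExtractor()
        x = rng.random((8, 8, 3))
        y = rng.random((8, 8, 3))
        s = Tensor(y.transpose(2, 0, 1)[None].copy(), requires_grad=True)
        val = dists(Tensor(x.transpose(2, 0, 1)[None]), s, ext)
        val.backward()
        analytic = s.grad[0, 1, 3, 4]
        eps = 1e-6
        yp, ym = y.copy(), y.copy()
        yp[3, 4, 1] += eps
        ym[3, 4, 1] -= eps
        fd = (dists(x, yp, ext).item() - dists(x, ym, ext).item()) / (2 * eps)
        assert analytic == pytest.approx(fd, rel=1e-4)

    def test_monotone_blur_degradation(self, phantom_sample):
        ext = desk_extractor()
        img = phantom_sample.he[:64, :64]
        scores = []
        for sigma in (0.5, 1.5, 3.0):
            blurred = np.stack([ndimage.gaussian_filter(img[..., c], sigma)
                                for c in range(3)], axis=-1)
            scores.append(dists(img, blurred, ext).item())
        assert scores == sorted(scores)

    def test_default_extractor_identity(self, rng):
        ext = RandomVGGExtractor(plan=((16, 1), (32, 1)), seed=7)
        x = rng.random((16, 16, 3))
        assert dists(x, x, ext).item() == pytest.approx(0.0, abs=1e-6)


class TestFullObjective:
    def test_defaults_arithmetic(self):
        w = LossWeights(0.1, 1.0, 5.0)
        assert full_objective(0.6931, 0.2, 0.05, w) == pytest.approx(0.51931)

    def test_lambda_zero_reduces_to_gan_objective(self):
        from flimstain.gan_model import combine_gan_objective
        w = LossWeights(0.3, 0.7, 0.0)
        assert full_objective(0.5, 0.2, 0.9, w) == pytest.approx(
            combine_gan_objective(0.5, 0.2, w))

    def test_zero_components(self):
        assert full_objective(0.0, 0.0, 0.0, LossWeights()) == 0.0
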