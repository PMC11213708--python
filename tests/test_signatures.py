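import numpy as np
import pytest

from flimstain.flim_core import FLIMField
from flimstain.phantom import PhantomSpec, generate_phantom
from flimstain.signatures import (CellAnnotation, cell_histogram,
                                  read_annotation, signature_from_histogram,
                                  signature_for_label, summarise_cell_types,
                                  write_annotation, signatures_to_tsv)


def _field_with(lifetimes: np.ndarray) -> FLIMField:
    return FLIMField(np.ones_like(lifetimes, dtype=float),
                     np.asarray(lifetimes, dtype=float), 1.0)


def _annot(mask, labels):
    return CellAnnotation(np.asarray(mask), labels)


class TestCellHistogram:
    def test_delta_distribution(self):
        lt = np.zeros((4, 4))
        lt[:2, :] = 2.0
        mask = np.zeros((4, 4), int)
        mask[:2, :] = 1
        counts, edges = cell_histogram(_field_with(lt), _annot(mask, {1: "t"}), 1)
        assert counts.sum() == 8
        centre_bin = np.argmax(counts)
        assert counts[centre_bin] == 8
        assert edges[centre_bin] <= 2.0 <= edges[centre_bin + 1]

    def test_two_valued_tally(self):
        lt = np.zeros((1, 8))
        lt[0, :5] = 1.01
        lt[0, 5:] = 3.01
        mask = np.ones((1, 8), int)
        counts, edges = cell_histogram(_field_with(lt), _annot(mask, {1: "t"}), 1)
        centres = 0.5 * (edges[:-1] + edges[1:])
        assert counts[np.argmin(np.abs(centres - 1.025))] == 5
        assert counts[np.argmin(np.abs(centres - 3.025))] == 3
        assert counts.sum() == 8

    def test_mass_conserved_for_any_bin_width(self):
        rng = np.random.default_rng(3)
        lt = rng.uniform(0, 5, (16, 16))
        mask = (rng.random((16, 16)) < 0.4).astype(int)
        annot = _annot(mask, {1: "t"})
        for bw in (0.01, 0.05, 0.5, 1.0):
            counts, _ = cell_histogram(_field_with(lt), annot, 1, bin_width=bw)
            assert counts.sum() == mask.sum()

    def test_unknown_label_and_empty_region(self):
        field = _field_with(np.zeros((4, 4)))
        with pytest.raises(KeyError):
            cell_histogram(field, _annot(np.zeros((4, 4), int), {}), 3)
        mask = np.zeros((4, 4), int)
        mask[0, 0] = 1
        annot = CellAnnotation(mask, {1: "t", 2: "ghost"})
        with pytest.raises(ValueError, match="no annotated pixels"):
            cell_histogram(field, annot, 2)


class TestSignatureFromHistogram:
    def test_delta_peak_and_mean(self):
        edges = np.linspace(0, 5, 101)
        counts = np.zeros(100)
        counts[40] = 10  # bin [2.0, 2.05) → centre 2.025
        sig = signature_from_histogram(counts, edges, "t")
        assert sig.peak_lifetime == pytest.approx(2.025)
        assert sig.mean_lifetime == pytest.approx(2.025)
        assert sig.n_pixels == 10

    def test_weighted_mean(self):
        edges = np.array([0.5, 1.5, 2.5, 3.5])
        counts = np.array([5, 0, 3])  # centres 1.0, 2.0, 3.0
        sig = signature_from_histogram(counts, edges, "t")
        assert sig.peak_lifetime == 1.0
        assert sig.mean_lifetime == pytest.approx((5 * 1 + 3 * 3) / 8)

    def test_tie_breaks_toward_lower_lifetime(self):
        edges = np.array([0.5, 1.5, 2.5, 3.5])
        sig = signature_from_histogram(np.array([4, 0, 4]), edges, "t")
        assert sig.peak_lifetime == 1.0

    def test_empty_histogram_rejected(self):
        with pytest.raises(ValueError):
            signature_from_histogram(np.zeros(10), np.linspace(0, 5, 11), "t")


class TestSummarise:
    def test_phantom_type_means_and_ordering(self):
        sample = generate_phantom(PhantomSpec(image_size=(256, 256), seed=5))
        per_type, per_cell = summarise_cell_types(sample.flim, sample.annot)
        truth = {ct.name: ct.mean_lifetime for ct in sample.spec.cell_types}
        means = [s.mean_lifetime for s in per_type]
        assert means == sorted(means)
        recovered_order = [s.cell_type for s in per_type]
        true_order = sorted(truth, key=truth.get)
        assert recovered_order == true_order
        for s in per_type:
            assert s.mean_lifetime == pytest.approx(truth[s.cell_type],
                                                    abs=0.05)
        assert len(per_cell) == len(sample.annot.labels)

    def test_pooled_mean_is_pixel_weighted_mean_of_cells(self):
        lt = np.zeros((4, 4))
        lt[0, :2] = 1.01   # cell 1, 2 px
        lt[1, :4] = 3.01   # cell 2, 4 px
        mask = np.zeros((4, 4), int)
        mask[0, :2] = 1
        mask[1, :4] = 2
        annot = _annot(mask, {1: "t", 2: "t"})
        field = _field_with(lt)
        per_type, per_cell = summarise_cell_types(field, annot)
        assert len(per_type) == 1
        cell_means = {s.n_pixels: s.mean_lifetime for s in per_cell}
        expected = (2 * cell_means[2] + 4 * cell_means[4]) / 6
        assert per_type[0].mean_lifetime == pytest.approx(expected)

    def test_single_type_and_no_annotations(self):
        field = _field_with(np.full((4, 4), 2.0))
        mask = np.zeros((4, 4), int)
        mask[1, 1] = 1
        per_type, _ = summarise_cell_types(field, _annot(mask, {1: "only"}))
        assert len(per_type) == 1
        with pytest.raises(ValueError):
            summarise_cell_types(field, _annot(np.zeros((4, 4), int), {}))


class TestAnnotationIO:
    def test_mask_roundtrip(self, tmp_path):
        mask = np.zeros((8, 8), int)
        mask[2:4, 2:4] = 1
        mask[5:7, 5:7] = 2
        annot = _annot(mask, {1: "tumour", 2: "rbc"})
        write_annotation(annot, tmp_path / "m.tif", tmp_path / "m.json")
        back = read_annotation(tmp_path / "m.tif", tmp_path / "m.json")
        np.testing.assert_array_equal(back.mask, mask)
        assert back.labels == {1: "tumour", 2: "rbc"}

    def test_unlabelled_mask_value_rejected(self):
        mask = np.zeros((4, 4), int)
        mask[0, 0] = 5
        with pytest.raises(ValueError, match="without a type name"):
            CellAnnotation(mask, {1: "t"})

    def test_tsv_export(self, tmp_path):
        field = _field_with(np.full((4, 4), 2.0))
        mask = np.zeros((4, 4), int)
        mask[1:3, 1:3] = 1
        per_type, _ = summarise_cell_types(field, _annot(mask, {1: "tumour"}))
        signatures_to_tsv(per_type, tmp_path / "sig.tsv")
        text = (tmp_path / "sig.tsv").read_text()
        assert "tumour" in text and "mean_lifetime_ns" in text


def test_signature_for_label_convenience():
    lt = np.zeros((4, 4))
    lt[0, :3] = 1.2
    mask = np.zeros((4, 4), int)
    mask[0, :3] = 7
    field = _field_with(lt)
    sig = signature_for_label(field, _annot(mask, {7: "plasma"}), 7)
    assert sig.cell_type == "plasma"
    assert sig.n_pixels == 3
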