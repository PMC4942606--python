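"""Image-to-signal reduction, normalization, areas and image enhancement."""

import numpy as np
import pytest

from snomchemo import (
    SpectrumLikeSignal,
    TransmissionImage,
    average_replicates,
    build_area_table,
    delta_area_percent,
    enhance_image,
    image_to_signal,
    normalize_signal,
    signal_area,
)
from snomchemo.snom_signal import AlreadyNormalizedError, auto_interval


def _image(pixels, **kw):
    defaults = dict(wavelength_um=6.06, biomarker="amide_I", cell_id="c1",
                    class_label="normal", scan_size_um=400.0)
    defaults.update(kw)
    return TransmissionImage(pixels=np.asarray(pixels, float), **defaults)


def _signal(values, axis=None, normalized=False, biomarker="amide_I"):
    values = np.asarray(values, float)
    if axis is None:
        axis = np.arange(len(values), dtype=float)
    return SpectrumLikeSignal(values=values, spatial_axis_um=np.asarray(axis, float),
                              biomarker=biomarker, source_cell_id="c1",
                              normalized=normalized)


def brute_force_column_means(X):
    """Independent double-loop oracle for the image reduction."""
    m, c = X.shape
    out = np.empty(c)
    for j in range(c):
        acc = 0.0
        for i in range(m):
            acc += X[i, j]
        out[j] = acc / m
    return out


class TestImageToSignal:
    def test_constant_image_gives_constant_signal(self):
        sig = image_to_signal(_image(np.ones((150, 150))))
        assert sig.values.shape == (150,)
        np.testing.assert_array_equal(sig.values, np.ones(150))
        assert not sig.normalized

    def test_explicit_small_matrix(self):
        X = np.array([[1, 2, 3], [4, 5, 6], [7, 8, 9], [10, 11, 12]], float)
        sig = image_to_signal(_image(X))
        np.testing.assert_allclose(sig.values, [5.5, 6.5, 7.5], rtol=0, atol=0)

    def test_constant_columns_reproduced_exactly(self, rng):
        v = rng.normal(size=7)
        X = np.tile(v, (5, 1))
        np.testing.assert_allclose(image_to_signal(_image(X)).values, v, rtol=1e-15)

    def test_matches_double_loop_oracle_on_fuzzed_matrices(self, rng):
        for _ in range(50):
            m, c = rng.integers(2, 21, size=2)
            X = rng.normal(size=(m, c)) * 10
            sig = image_to_signal(_image(X))
            np.testing.assert_allclose(sig.values, brute_force_column_means(X),
                                       atol=1e-12)

    def test_linearity_and_permutation_invariance(self, rng):
        X, Y = rng.normal(size=(2, 6, 9))
        a, b = 2.5, -1.25
        lhs = image_to_signal(_image(a * X + b * Y)).values
        rhs = a * image_to_signal(_image(X)).values + b * image_to_signal(_image(Y)).values
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)
        row_perm = rng.permutation(6)
        np.testing.assert_allclose(
            image_to_signal(_image(X[row_perm])).values,
            image_to_signal(_image(X)).values, atol=1e-12)
        col_perm = rng.permutation(9)
        np.testing.assert_allclose(
            image_to_signal(_image(X[:, col_perm])).values,
            image_to_signal(_image(X)).values[col_perm], atol=1e-12)

    def test_spatial_axis_spans_scan_size(self):
        sig = image_to_signal(_image(np.zeros((4, 8)), scan_size_um=400.0))
        np.testing.assert_allclose(sig.spatial_axis_um, np.arange(8) * 50.0)


class TestNormalize:
    @pytest.mark.parametrize(
        "values,expected",
        [([1, 1, 1], [0, 0, 0]), ([0, 2], [1, 1]), ([1, 2, 6], [2, 1, 3])],
    )
    def test_examples(self, values, expected):
        out = normalize_signal(_signal(values))
        np.testing.assert_allclose(out.values, expected, atol=1e-12)
        assert out.normalized

    def test_centred_vector_has_zero_mean_and_output_nonnegative(self, rng):
        v = rng.normal(size=40) * 5 + 3
        assert abs((v - v.mean()).mean()) < 1e-12
        out = normalize_signal(_signal(v))
        assert (out.values >= 0).all()

    def test_double_normalization_forbidden(self):
        out = normalize_signal(_signal([1, 2, 6]))
        with pytest.raises(AlreadyNormalizedError):
            normalize_signal(out)


class TestAverageReplicates:
    def test_identical_signals_average_to_themselves(self):
        s = _signal([1, 2, 3])
        out = average_replicates([s, s, s])
        np.testing.assert_array_equal(out.values, s.values)

    def test_pointwise_mean_and_single_signal(self):
        out = average_replicates([_signal([0, 0]), _signal([2, 4])])
        np.testing.assert_array_equal(out.values, [1, 2])
        single = average_replicates([_signal([5, 7])])
        np.testing.assert_array_equal(single.values, [5, 7])

    def test_mixed_biomarkers_or_lengths_rejected(self):
        with pytest.raises(ValueError, match="biomarker"):
            average_replicates([_signal([1, 2]), _signal([1, 2], biomarker="dna")])
        with pytest.raises(ValueError, match="length"):
            average_replicates([_signal([1, 2]), _signal([1, 2, 3])])


class TestSignalArea:
    @pytest.mark.parametrize(
        "values,axis,interval,expected",
        [
            ([1, 1], [0, 1], (0, 1), 1.0),
            ([0, 1, 0], [0, 1, 2], (0, 2), 1.0),
            ([0, 1, 0], [0, 1, 2], (0, 1), 0.5),
        ],
    )
    def test_examples(self, values, axis, interval, expected):
        sig = _signal(values, axis, normalized=True)
        assert signal_area(sig, interval) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_interval_rejected(self):
        sig = _signal([1, 1], [0, 1], normalized=True)
        with pytest.raises(ValueError, match="degenerate"):
            signal_area(sig, (1, 0))

    def test_unnormalized_signal_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            signal_area(_signal([1, 1], [0, 1]), (0, 1))

    def test_enlarging_interval_never_decreases_area(self, rng):
        values = np.abs(rng.normal(size=30))
        axis = np.arange(30, dtype=float)
        sig = _signal(values, axis, normalized=True)
        areas = [signal_area(sig, (10.0 - w, 15.0 + w)) for w in range(0, 10, 2)]
        assert all(a2 >= a1 - 1e-12 for a1, a2 in zip(areas, areas[1:]))


class TestDeltaArea:
    @pytest.mark.parametrize(
        "area,ref,expected", [(2.0, 2.0, 0.0), (4.0, 2.0, 100.0), (1.0, 2.0, -50.0)]
    )
    def test_examples(self, area, ref, expected):
        assert delta_area_percent(area, ref) == pytest.approx(expected)

    def test_degenerate_reference_rejected(self):
        with pytest.raises(ValueError):
            delta_area_percent(1.0, 0.0)


class TestBuildAreaTable:
    def _grouped(self, factors):
        """One cell per class; each biomarker profile scaled per class."""
        base = np.concatenate([np.zeros(5), np.ones(10), np.zeros(5)])
        axis = np.arange(20, dtype=float)
        grouped = {}
        for cls, f in factors.items():
            for bm in ("lipids", "amide_I", "amide_II", "dna"):
                grouped[(cls, bm)] = [
                    SpectrumLikeSignal(values=f * base, spatial_axis_um=axis,
                                       biomarker=bm, source_cell_id=cls)
                    for _ in range(3)
                ]
        return grouped

    def test_identical_classes_give_zero_delta(self):
        grouped = self._grouped({"normal": 1.0, "abnormal": 1.0})
        records = build_area_table(grouped)
        for r in records:
            if r.class_label != "normal":
                assert r.delta_area_pct == pytest.approx(0.0, abs=1e-9)

    def test_record_count_and_normal_rows(self):
        grouped = self._grouped(dict.fromkeys(
            ["normal", "a", "b", "c", "d"], 1.0))
        records = build_area_table(grouped)
        assert len(records) == 20
        assert sum(r.delta_area_pct is None for r in records) == 4

    def test_scaling_recovered_as_delta_percent(self):
        records = build_area_table(self._grouped({"normal": 1.0, "up": 2.0}))
        ups = [r for r in records if r.class_label == "up"]
        assert all(r.delta_area_pct == pytest.approx(100.0, abs=1e-9) for r in ups)

    def test_missing_normal_or_biomarker_rejected(self):
        grouped = self._grouped({"a": 1.0, "b": 2.0})
        with pytest.raises(ValueError, match="normal"):
            build_area_table(grouped)
        grouped = self._grouped({"normal": 1.0, "b": 2.0})
        del grouped[("b", "dna")]
        with pytest.raises(ValueError, match="dna"):
            build_area_table(grouped)


class TestAutoInterval:
    def test_contains_the_peak_region(self):
        values = np.zeros(100)
        values[40:60] = 1.0
        sig = _signal(values, np.arange(100.0), normalized=True)
        lo, hi = auto_interval(sig)
        assert lo <= 40 and hi >= 59

    def test_flat_signal_falls_back_to_full_axis(self):
        sig = _signal(np.zeros(10), np.arange(10.0), normalized=True)
        assert auto_interval(sig) == (0.0, 9.0)


class TestEnhanceImage:
    def test_constant_image_is_a_fixed_point(self):
        img = _image(np.full((16, 16), 3.7))
        out = enhance_image(img, 0.5)
        np.testing.assert_allclose(out.pixels, img.pixels, atol=1e-10)
        assert out.presentation_only

    def test_offset_row_realigned_to_common_median(self, rng):
        px = rng.normal(size=(12, 12)) * 0.01
        px[4] += 5.0
        out = enhance_image(_image(px), 1.0)
        medians = np.median(out.pixels, axis=1)
        assert np.ptp(medians) < 0.1  # the +5 offset is gone

    def test_full_band_cutoff_only_realigns_rows(self, rng):
        px = rng.normal(size=(10, 14))
        aligned = px - np.median(px, axis=1)[:, None] + np.median(np.median(px, axis=1))
        out = enhance_image(_image(px), 1.0)
        np.testing.assert_allclose(out.pixels, aligned, atol=1e-10)

    def test_cutoff_out_of_range_rejected(self):
        img = _image(np.zeros((4, 4)))
        for bad in (0.0, -0.5, 1.5):
            with pytest.raises(ValueError):
                enhance_image(img, bad)
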