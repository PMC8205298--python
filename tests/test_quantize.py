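"""Quantizer unit and property tests.

The reference implementations here apply the transition-level definitions
literally, pixel by pixel, and stay independent of the vectorized package
code they check.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

from triq.quantize import (GlobalTriqQuantizer, Histogram, HistogramEqualizer,
                           TriqParams, TriqQuantizer, ZeroMemoryQuantizer,
                           black_level_threshold, compute_histogram,
                           count_operations, global_triq, histogram_equalize,
                           triq_quantize, triq_threshold, zero_memory_quantize)

# ---------------------------------------------------------------------------
# reference (per-pixel, literal) implementations used as oracles


def map_levels_literal(value, transitions):
    """Level 0 iff f <= t_1; k iff t_k < f <= t_{k+1}; top iff f > t_last."""
    if value <= transitions[0]:
        return 0
    for k in range(1, len(transitions)):
        if transitions[k - 1] < value <= transitions[k]:
            return k
    return len(transitions)


def zero_memory_literal(a, n):
    lo, hi = a.min(), a.max()
    w = (hi - lo) / n
    transitions = [lo + k * w for k in range(1, n)]
    return np.array([[map_levels_literal(v, transitions) for v in row]
                     for row in a])


def triq_literal(a, q, n, cdf_bins):
    lo, hi = a.min(), a.max()
    edges = np.linspace(lo, hi, cdf_bins + 1)
    counts = np.zeros(cdf_bins, dtype=int)
    for v in a.ravel():  # first bin closed at lo, then (e_i, e_{i+1}]
        placed = False
        for i in range(cdf_bins):
            if (i == 0 and v <= edges[1]) or (edges[i] < v <= edges[i + 1]):
                counts[i] += 1
                placed = True
                break
        if not placed:
            counts[-1] += 1
    cum = 0.0
    for k in range(cdf_bins):
        cum += counts[k] / a.size
        if cum >= q:
            T = edges[k + 1]
            break
    w = (T - lo) / (n - 1)
    transitions = [lo + k * w for k in range(1, n)]
    levels = np.array([[map_levels_literal(v, transitions) for v in row]
                       for row in a])
    return levels, T


positive_images = arrays(
    dtype=float,
    shape=st.tuples(st.integers(2, 12), st.integers(2, 12)),
    elements=st.floats(0.0, 1e6, allow_nan=False, allow_infinity=False),
)


# ---------------------------------------------------------------------------
# histogram


class TestComputeHistogram:
    def test_left_open_convention(self):
        # 0 and 1 share the first (closed) bin; 2 and 3 the second
        h = compute_histogram(np.array([[0.0, 1.0, 2.0, 3.0]]), bins=2,
                              lo=0.0, hi=3.0)
        assert h.counts.tolist() == [2, 2]

    def test_constant_image_single_bin(self):
        h = compute_histogram(np.full((4, 4), 3.0), bins=5, lo=0.0, hi=10.0)
        assert h.n_pixels == 16
        assert h.counts.sum() == 16
        assert np.count_nonzero(h.counts) == 1

    def test_matches_brute_force_binning(self, rng):
        a = rng.uniform(0, 100, size=(17, 13))
        bins = 11
        h = compute_histogram(a, bins, 0.0, 100.0)
        edges = h.edges
        brute = np.zeros(bins, dtype=int)
        for v in a.ravel():
            for i in range(bins):
                if (i == 0 and v <= edges[1]) or (edges[i] < v <= edges[i + 1]):
                    brute[i] += 1
                    break
        assert np.array_equal(h.counts, brute)

    def test_out_of_range_values_clamped(self):
        h = compute_histogram(np.array([[0.0, 500.0]]), bins=4, lo=10.0, hi=20.0)
        assert h.counts.tolist() == [1, 0, 0, 1]
        assert h.n_pixels == 2

    def test_bad_range_rejected(self):
        with pytest.raises(ValueError):
            compute_histogram(np.ones((2, 2)), bins=4, lo=5.0, hi=5.0)


# ---------------------------------------------------------------------------
# zero-memory quantizer


class TestZeroMemory:
    def test_hand_example(self):
        qr = zero_memory_quantize(np.array([[0.0, 10.0, 20.0, 30.0]]), n=3)
        # w = 10; 10 <= t_1 = 10 so it stays at level 0
        assert qr.levels.tolist() == [[0, 0, 1, 2]]
        assert qr.bin_width == pytest.approx(10.0)

    def test_constant_image_all_zero(self):
        qr = zero_memory_quantize(np.full((3, 5), 42.0), n=8)
        assert np.all(qr.levels == 0)

    def test_skew_collapses_to_lowest_levels(self, skewed_image):
        # heavy right skew: with 256 levels almost everything lands in the
        # first few bins, the pathology TrIQ corrects
        qr = zero_memory_quantize(skewed_image, n=256)
        assert np.mean(qr.levels < 4) > 0.99

    @given(img=positive_images, n=st.integers(2, 40))
    @settings(max_examples=60, deadline=None)
    def test_matches_literal_reference(self, img, n):
        qr = zero_memory_quantize(img, n=n)
        assert np.array_equal(qr.levels, zero_memory_literal(img, n))

    def test_rejects_negative_intensities(self):
        with pytest.raises(ValueError):
            zero_memory_quantize(np.array([[-1.0, 2.0]]), n=4)


# ---------------------------------------------------------------------------
# threshold selection


class TestTriqThreshold:
    def test_hand_cdf(self):
        counts = np.zeros(100, dtype=int)
        counts[0], counts[99] = 98, 2
        h = Histogram(counts=counts, edges=np.linspace(0, 1000, 101))
        T, k_hit = triq_threshold(h, 0.98)
        assert T == pytest.approx(10.0)
        assert k_hit == 0

    def test_full_mass_returns_last_edge(self, rng):
        a = rng.uniform(0, 50, (10, 10))
        h = compute_histogram(a, 16)
        T, k_hit = triq_threshold(h, 1.0)
        assert T >= a.max()
        assert T == pytest.approx(h.edges[-1])

    def test_monotone_in_q(self, skewed_image):
        h = compute_histogram(skewed_image, 100)
        thresholds = [triq_threshold(h, q)[0]
                      for q in np.linspace(0.05, 1.0, 25)]
        assert np.all(np.diff(thresholds) >= 0)

    def test_empty_histogram_rejected(self):
        h = Histogram(counts=np.zeros(4, dtype=int), edges=np.linspace(0, 1, 5))
        with pytest.raises(ValueError):
            triq_threshold(h, 0.5)


class TestBlackLevel:
    def test_hand_cdf(self):
        counts = np.zeros(10, dtype=int)
        counts[0], counts[9] = 50, 50
        h = Histogram(counts=counts, edges=np.linspace(0, 10, 11))
        assert black_level_threshold(h, 0.5) == pytest.approx(1.0)

    def test_small_q_black_gives_first_occupied_edge(self, skewed_image):
        h = compute_histogram(skewed_image, 50)
        B = black_level_threshold(h, 1e-9)
        first = np.argmax(h.counts > 0)
        assert B == pytest.approx(h.edges[first + 1])

    def test_black_level_zeroes_background_fraction(self, rng):
        # noisy background + bright blob; requesting q_black must zero at
        # least that fraction of pixels
        a = rng.gamma(2.0, 10.0, (40, 40))
        a[10:20, 10:20] += 5000.0
        q_black = 0.5
        qr = triq_quantize(a, q=0.98, n=32, q_black=q_black)
        assert np.mean(qr.levels == 0) >= q_black

    def test_all_mass_below_black_level_rejected(self):
        a = np.concatenate([np.full(99, 1.0), [1.001]]).reshape(10, 10)
        with pytest.raises(ValueError, match="black level"):
            triq_quantize(a, q=0.5, n=16, cdf_bins=2, q_black=0.49)


# ---------------------------------------------------------------------------
# TrIQ quantizer


class TestTriqQuantize:
    def test_outlier_lands_on_top_level(self, rng):
        a = rng.uniform(0, 100, (50, 50))
        a[0, 0] = 1e6  # single huge outlier
        # a fine CDF search grid is needed to pull T close to the bulk when
        # one pixel stretches the range by four orders of magnitude
        qr = triq_quantize(a, q=0.98, n=32, cdf_bins=20000)
        assert qr.levels[0, 0] == 31
        assert qr.threshold < 1e6
        # remaining pixels use the whole scale rather than collapsing
        assert len(np.unique(qr.levels)) > 16

    def test_constant_image(self):
        qr = triq_quantize(np.full((4, 4), 9.0))
        assert np.all(qr.levels == 0)
        assert qr.threshold == qr.black_level == 9.0

    def test_q_one_saturates_only_top_bin(self, rng):
        a = rng.uniform(0, 100, (30, 30))
        qr = triq_quantize(a, q=1.0, n=10)
        assert qr.threshold >= a.max()
        assert np.mean(qr.levels == 9) <= np.mean(
            a > qr.transition_levels[-1]) + 1e-12

    def test_coverage_at_least_q(self, skewed_image):
        for q in (0.90, 0.95, 0.98):
            qr = triq_quantize(skewed_image, q=q, n=64)
            assert np.mean(skewed_image <= qr.threshold) >= q

    def test_transition_levels_equally_spaced(self, skewed_image):
        qr = triq_quantize(skewed_image, q=0.98, n=100)
        gaps = np.diff(qr.transition_levels)
        assert np.allclose(gaps, qr.bin_width, rtol=1e-9)

    @given(img=positive_images, q=st.floats(0.5, 1.0), n=st.integers(2, 30))
    @settings(max_examples=60, deadline=None)
    def test_matches_literal_reference(self, img, q, n):
        if img.min() == img.max():
            return  # degenerate covered elsewhere
        qr = triq_quantize(img, q=q, n=n, cdf_bins=n)
        ref_levels, ref_T = triq_literal(img, q, n, cdf_bins=n)
        assert qr.threshold == pytest.approx(ref_T)
        assert np.array_equal(qr.levels, ref_levels)

    @given(img=positive_images)
    @settings(max_examples=40, deadline=None)
    def test_order_preserving(self, img):
        qr = triq_quantize(img, q=0.9, n=16)
        flat = img.ravel()
        order = np.argsort(flat, kind="stable")
        assert np.all(np.diff(qr.levels.ravel()[order]) >= 0)

    def test_params_validation(self):
        with pytest.raises(ValueError):
            TriqParams(q=0.0)
        with pytest.raises(ValueError):
            TriqParams(q=1.5)
        with pytest.raises(ValueError):
            TriqParams(n=1)
        with pytest.raises(ValueError):
            TriqParams(q=0.9, q_black=0.9)

    def test_sklearn_protocol(self, skewed_image):
        est = TriqQuantizer(q=0.95, n_levels=25)
        assert est.get_params()["q"] == 0.95
        est.set_params(q=0.9)
        levels = est.fit_transform(skewed_image)
        assert levels.shape == skewed_image.shape
        assert est.threshold_ < skewed_image.max()
        # fitted scale applies unchanged to new data
        other = skewed_image * 0.5
        assert levels.max() >= est.transform(other).max()


# ---------------------------------------------------------------------------
# global TrIQ


class TestGlobalTriq:
    def test_singleton_equals_single_image(self, skewed_image):
        single = triq_quantize(skewed_image, q=0.95, n=32)
        [from_set] = global_triq([skewed_image], q=0.95, n=32)
        assert from_set.threshold == pytest.approx(single.threshold)
        assert np.array_equal(from_set.levels, single.levels)

    def test_duplicate_images_idempotent(self, skewed_image):
        r1, r2 = global_triq([skewed_image, skewed_image], q=0.95, n=32)
        assert r1.threshold == r2.threshold
        assert np.array_equal(r1.levels, r2.levels)

    def test_shared_threshold_is_max(self, skewed_image):
        imgs = [skewed_image, skewed_image * 2.0, skewed_image * 0.5]
        est = GlobalTriqQuantizer(q=0.95, n_levels=32).fit(imgs)
        assert est.threshold_ == pytest.approx(est.per_image_thresholds_.max())
        results = global_triq(imgs, q=0.95, n=32)
        assert len({r.threshold for r in results}) == 1

    def test_same_intensity_same_level_everywhere(self, skewed_image):
        imgs = [skewed_image, skewed_image * 3.0]
        est = GlobalTriqQuantizer(q=0.95, n_levels=32).fit(imgs)
        probe = np.linspace(skewed_image.min(), skewed_image.max() * 3,
                            200).reshape(8, 25)
        l1 = est.transform([probe])[0]
        l2 = est.transform([probe])[0]
        assert np.array_equal(l1, l2)
        # and a brighter copy never maps below the dimmer one
        la, lb = est.transform([skewed_image, skewed_image * 3.0])
        assert np.all(lb >= la)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            global_triq([], q=0.9, n=8)

    def test_q_black_rejected_in_global_mode(self, skewed_image):
        with pytest.raises(ValueError, match="q_black"):
            GlobalTriqQuantizer(q=0.9, n_levels=8, q_black=0.1).fit(
                [skewed_image])


# ---------------------------------------------------------------------------
# histogram equalization baseline


class TestHistogramEqualize:
    def test_uniform_histogram_identity(self):
        a = np.arange(256, dtype=float).reshape(16, 16)
        qr = histogram_equalize(a, 256)
        assert np.array_equal(qr.levels, a.astype(int))

    def test_constant_image_single_level(self):
        qr = histogram_equalize(np.full((5, 5), 3.0), 64)
        assert np.all(qr.levels == 0)

    def test_gray_level_loss_on_skewed_image(self, skewed_image):
        # the equalizer's occupied output levels collapse below the request,
        # while TrIQ at the same depth keeps its full scale usable
        n = 256
        qr = histogram_equalize(skewed_image, n)
        assert len(np.unique(qr.levels)) < n
        assert qr.method == "equalized"
        assert qr.transition_levels is None

    @given(img=positive_images)
    @settings(max_examples=40, deadline=None)
    def test_order_preserving(self, img):
        qr = histogram_equalize(img, 32)
        flat = img.ravel()
        order = np.argsort(flat, kind="stable")
        assert np.all(np.diff(qr.levels.ravel()[order]) >= 0)


# ---------------------------------------------------------------------------
# complexity


class TestComplexity:
    def test_operation_count_scales_linearly(self):
        rng = np.random.default_rng(5)
        sizes = [2500, 5000, 10000, 20000, 40000]
        ops = []
        for s in sizes:
            a = rng.gamma(2.0, 50.0, size=(s // 50, 50))
            _, n_ops = count_operations(triq_quantize, a, q=0.98, n=100)
            ops.append(n_ops)
        ratios = [b / a for a, b in zip(ops, ops[1:])]
        # doubling the pixels doubles the work
        assert all(1.9 <= r <= 2.1 for r in ratios)
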