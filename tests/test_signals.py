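"""Derivative enhancement and per-segment normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppgarr.exceptions import InvalidInputError
from ppgarr.signals import (
    PPGSegment,
    backward_difference,
    compute_apg,
    compute_vpg,
    enhance,
    enhance_batch,
    zscore,
)


def loop_backward_difference(x, boundary_mode):
    """Element-by-element oracle, written independently of the vectorized path."""
    out = [0.0] * len(x)
    for i in range(1, len(x)):
        out[i] = x[i] - x[i - 1]
    if boundary_mode == "extrapolate_continuous":
        out[0] = x[1] - x[0]
    else:
        out[0] = x[0] - (x[1] - x[0])
    return np.array(out)


class TestBackwardDifference:
    def test_constant_vector_has_zero_derivative(self):
        assert np.array_equal(backward_difference(np.full(4, 5.0)), np.zeros(4))

    @pytest.mark.parametrize("mode,expected", [
        ("extrapolate_continuous", [2, 2, 2, 2]),
        ("literal_eq1", [-2, 2, 2, 2]),
    ])
    def test_linear_ramp_boundary_modes(self, mode, expected):
        out = backward_difference(np.array([0.0, 2, 4, 6]), mode)
        assert np.array_equal(out, expected)

    @pytest.mark.parametrize("mode", ["extrapolate_continuous", "literal_eq1"])
    def test_matches_loop_oracle_on_random_vector(self, rng, mode):
        x = rng.standard_normal(1000)
        out = backward_difference(x, mode)
        oracle = loop_backward_difference(x, mode)
        # interior indices must agree exactly (0 ulp), boundary too
        assert np.array_equal(out[1:], oracle[1:])
        assert out[0] == oracle[0]

    def test_length_preserved(self, rng):
        for n in (2, 3, 17, 1000):
            assert backward_difference(rng.standard_normal(n)).shape == (n,)

    @pytest.mark.parametrize("bad", [np.array([1.0]), np.array([1.0, np.nan]),
                                     np.array([1.0, np.inf])])
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(InvalidInputError):
            backward_difference(bad)

    def test_unknown_boundary_mode_rejected(self):
        with pytest.raises(InvalidInputError):
            backward_difference(np.arange(4.0), "nearest")

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 2**31 - 1), st.floats(-3, 3), st.floats(-3, 3))
    def test_linearity(self, seed, a, b):
        rng = np.random.default_rng(seed)
        x, y = rng.standard_normal((2, 32))
        for mode in ("extrapolate_continuous", "literal_eq1"):
            lhs = backward_difference(a * x + b * y, mode)
            rhs = (a * backward_difference(x, mode)
                   + b * backward_difference(y, mode))
            np.testing.assert_allclose(lhs, rhs, atol=1e-9)


class TestDerivatives:
    def test_vpg_preserves_length_and_equals_difference(self, rng):
        seg = PPGSegment(rng.standard_normal(1000))
        vpg = compute_vpg(seg)
        assert vpg.shape == (1000,)
        assert np.array_equal(vpg, backward_difference(seg.samples))

    def test_vpg_of_sine_tracks_analytic_derivative(self):
        fs, f = 100.0, 1.0
        t = np.arange(1000) / fs
        x = np.sin(2 * np.pi * f * t)
        seg = PPGSegment(x, fs=fs)
        vpg = compute_vpg(seg) * fs  # scale sample difference to d/dt
        analytic = 2 * np.pi * f * np.cos(2 * np.pi * f * t)
        h = 1 / fs
        bound = h * np.max(np.abs((2 * np.pi * f) ** 2 * x)) + 1e-9
        # backward difference approximates the derivative at midpoint; the
        # worst-case error is bounded by h * max|x''|
        assert np.max(np.abs(vpg[1:] - analytic[1:])) < bound

    def test_apg_is_double_difference(self, rng):
        seg = PPGSegment(rng.standard_normal(500))
        expected = backward_difference(backward_difference(seg.samples))
        assert np.array_equal(compute_apg(seg), expected)

    def test_apg_of_linear_is_zero_and_quadratic_is_constant(self):
        ramp = PPGSegment(np.arange(10.0))
        assert np.allclose(compute_apg(ramp), 0)
        quad = PPGSegment(np.arange(10.0) ** 2)
        assert np.allclose(compute_apg(quad)[2:], 2.0)

    def test_apg_needs_three_samples(self):
        with pytest.raises(InvalidInputError):
            compute_apg(PPGSegment(np.array([1.0, 2.0])))


class TestZscore:
    def test_two_point_example(self):
        out, stats = zscore(np.array([0.0, 2.0]))
        assert np.allclose(out, [-1, 1])
        assert stats.mu == 1.0 and stats.sigma == 1.0 and not stats.degenerate

    def test_constant_segment_flagged_degenerate(self):
        out, stats = zscore(np.full(100, 3.7))
        assert np.array_equal(out, np.zeros(100))
        assert stats.degenerate

    def test_moments_against_independent_summation(self, rng):
        x = rng.standard_normal(1000) * 3 + 5
        out, stats = zscore(x)
        # two-pass summation oracle
        mu = sum(x) / len(x)
        sigma = (sum((v - mu) ** 2 for v in x) / len(x)) ** 0.5
        assert abs(stats.mu - mu) < 1e-10
        assert abs(stats.sigma - sigma) < 1e-9
        assert abs(np.mean(out)) < 1e-10
        assert abs(np.std(out) - 1.0) < 1e-10

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 2**31 - 1), st.floats(-100, 100),
           st.floats(-5, 5).filter(lambda c: abs(c) > 1e-3))
    def test_shift_and_scale_invariance(self, seed, shift, scale):
        x = np.random.default_rng(seed).standard_normal(64)
        base, _ = zscore(x)
        shifted, _ = zscore(x + shift)
        scaled, _ = zscore(scale * x)
        np.testing.assert_allclose(shifted, base, atol=1e-8)
        np.testing.assert_allclose(scaled, np.sign(scale) * base, atol=1e-8)


class TestEnhance:
    def test_produces_3xL_stack_with_unit_moments(self, rng):
        seg = PPGSegment(rng.standard_normal(1000))
        mv = enhance(seg)
        assert mv.channels.shape == (3, 1000)
        assert mv.normalized
        assert np.allclose(mv.channels.mean(axis=1), 0, atol=1e-6)
        assert np.allclose(mv.channels.std(axis=1), 1, atol=1e-4)

    def test_first_row_equals_zscore_of_raw(self, rng):
        """Dropping the derivative rows must recover the PPG-only input."""
        seg = PPGSegment(rng.standard_normal(1000))
        mv = enhance(seg)
        expected, _ = zscore(seg.samples)
        np.testing.assert_allclose(mv.channels[0], expected, atol=1e-12)

    def test_derivatives_computed_from_raw_segment(self, rng):
        seg = PPGSegment(rng.standard_normal(200) * 50 + 100)
        mv = enhance(seg, normalize_each_channel=False)
        np.testing.assert_array_equal(mv.channels[1], compute_vpg(seg))
        np.testing.assert_array_equal(mv.channels[2], compute_apg(seg))

    def test_batch_enhancement_matches_per_segment(self, rng):
        mat = rng.standard_normal((5, 200))
        batch = enhance_batch(mat, dtype=np.float64)
        for i in range(5):
            single = enhance(PPGSegment(mat[i])).channels
            np.testing.assert_allclose(batch[i], single, atol=1e-10)

    def test_batch_single_channel_is_zscored_ppg(self, rng):
        mat = rng.standard_normal((4, 100))
        batch = enhance_batch(mat, channels=1, dtype=np.float64)
        assert batch.shape == (4, 1, 100)
        np.testing.assert_allclose(batch[0, 0], zscore(mat[0])[0], atol=1e-10)
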