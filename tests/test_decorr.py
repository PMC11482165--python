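"""Sliding-window L1 decorrelation against hand computations and a brute-force oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octa.core_io import BScanBlock
from octa.decorr import (
    DecorrParams,
    ParameterError,
    make_label,
    pairwise_l1,
    windowed_decorrelation,
)


def brute_force_windowed(frames, n_frames, wz, wx):
    """Nested-loop reference: adjacent-pair L1 then boxcar with reflect padding.

    Window anchoring: output pixel (z, x) averages rows z-wz//2+1 .. z+wz//2
    for even sizes (z-wz//2 .. z+wz//2 for odd), mirroring at the borders.
    """
    d = np.zeros(frames.shape[1:])
    for t in range(n_frames - 1):
        d += np.abs(frames[t] - frames[t + 1])
    d /= n_frames - 1
    h, w = d.shape

    def reflect(i, n):
        while i < 0 or i >= n:
            i = -i - 1 if i < 0 else 2 * n - 1 - i
        return i

    lo_z = wz // 2 - (1 - wz % 2)
    lo_x = wx // 2 - (1 - wx % 2)
    out = np.zeros_like(d)
    for z in range(h):
        for x in range(w):
            acc = 0.0
            for dz in range(-lo_z, wz - lo_z):
                for dx in range(-lo_x, wx - lo_x):
                    acc += d[reflect(z + dz, h), reflect(x + dx, w)]
            out[z, x] = acc / (wz * wx)
    return out


class TestPairwiseL1:
    def test_identical_frames_zero(self):
        block = BScanBlock(frames=np.tile(np.random.default_rng(0).random((1, 8, 8)), (5, 1, 1)))
        assert pairwise_l1(block, 5).values.max() == 0.0

    def test_two_frame_hand_value(self):
        block = BScanBlock(frames=np.array([[[0.2]], [[0.7]]]))
        np.testing.assert_allclose(pairwise_l1(block, 2).values, [[0.5]])

    def test_three_frame_hand_value(self):
        block = BScanBlock(frames=np.array([[[0.0]], [[1.0]], [[0.0]]]))
        # (|0-1| + |1-0|) / 2 = 1
        np.testing.assert_allclose(pairwise_l1(block, 3).values, [[1.0]])

    def test_uses_only_first_n_frames(self, random_block):
        sub = BScanBlock(frames=random_block.frames[:3])
        np.testing.assert_array_equal(
            pairwise_l1(random_block, 3).values, pairwise_l1(sub, 3).values
        )

    @pytest.mark.parametrize("n", [0, 1, 11])
    def test_bad_n_frames(self, random_block, n):
        with pytest.raises(ParameterError):
            pairwise_l1(random_block, n)


class TestWindowedDecorrelation:
    def test_constant_pairwise_gives_constant_map(self):
        # two frames differing by a constant -> pairwise map constant c
        base = np.random.default_rng(1).random((12, 12))
        block = BScanBlock(frames=np.stack([base, base + 0.3]))
        out = windowed_decorrelation(block, DecorrParams(n_frames=2))
        np.testing.assert_allclose(out.values, 0.3)

    @pytest.mark.parametrize("wz,wx", [(6, 6), (5, 3), (1, 1), (4, 7)])
    def test_matches_brute_force_oracle(self, rng, wz, wx):
        frames = rng.random((2, 12, 12))
        block = BScanBlock(frames=frames)
        out = windowed_decorrelation(block, DecorrParams(window_x=wx, window_z=wz, n_frames=2))
        expected = brute_force_windowed(frames, 2, wz, wx)
        np.testing.assert_allclose(out.values, expected, rtol=1e-12, atol=1e-14)

    def test_interior_pixel_is_window_mean(self, rng):
        frames = rng.random((2, 12, 12))
        block = BScanBlock(frames=frames)
        out = windowed_decorrelation(block, DecorrParams(n_frames=2))
        d = np.abs(frames[0] - frames[1])
        # 6x6 window anchored at rows z-2..z+3, cols x-2..x+3
        assert out.values[6, 6] == pytest.approx(d[4:10, 4:10].mean(), rel=1e-12)

    def test_crop_policy_shrinks_output(self, random_block):
        out = windowed_decorrelation(
            random_block, DecorrParams(n_frames=2, edge_policy="crop")
        )
        assert out.values.shape == (24 - 5, 20 - 5)

    def test_shrink_window_matches_reflect_interior(self, random_block):
        a = windowed_decorrelation(random_block, DecorrParams(n_frames=2)).values
        b = windowed_decorrelation(
            random_block, DecorrParams(n_frames=2, edge_policy="shrink-window")
        ).values
        np.testing.assert_allclose(a[3:-3, 3:-3], b[3:-3, 3:-3], rtol=1e-12)

    def test_window_larger_than_image_rejected(self, rng):
        block = BScanBlock(frames=rng.random((2, 4, 4)))
        with pytest.raises(ParameterError):
            windowed_decorrelation(block, DecorrParams(window_x=6, window_z=6, n_frames=2))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3), seed=st.integers(0, 2**31 - 1))
    def test_homogeneity(self, scale, seed):
        """Scaling intensities by k scales every decorrelation value by k."""
        frames = np.random.default_rng(seed).random((3, 10, 10))
        p = DecorrParams(n_frames=3)
        base = windowed_decorrelation(BScanBlock(frames=frames), p).values
        scaled = windowed_decorrelation(BScanBlock(frames=frames * scale), p).values
        np.testing.assert_allclose(scaled, base * scale, rtol=1e-9)


class TestLabel:
    def test_zero_for_static_block(self):
        frames = np.tile(np.random.default_rng(2).random((1, 10, 10)), (10, 1, 1))
        label = make_label(BScanBlock(frames=frames))
        assert label.values.max() == 0.0
        assert label.source == "label10"

    def test_equals_windowed_n10(self, random_block):
        label = make_label(random_block)
        direct = windowed_decorrelation(random_block, DecorrParams(n_frames=10))
        np.testing.assert_array_equal(label.values, direct.values)
        assert label.n_used == 10

    def test_requires_ten_frames(self, rng):
        with pytest.raises(ParameterError):
            make_label(BScanBlock(frames=rng.random((9, 12, 12))))


class TestVarianceReduction:
    def test_std_decreases_with_n_and_follows_dependent_pair_theory(self):
        """More frames -> lower estimator noise, at the 1-dependent-pair rate.

        The N-1 adjacent |L1| terms share frames, so the N=2 vs N=10 std
        ratio is sqrt(81 / (9 + 16*rho1)) with rho1 = corr(|d_t|, |d_t+1|)
        (~2.5 for additive half-normal noise), not the independent-pair
        value of 3.
        """
        rng = np.random.default_rng(42)
        reps, h, w = 300, 8, 8
        base = rng.random((h, w)) + 0.5
        stds = {}
        for n in (2, 4, 10):
            est = []
            for _ in range(reps):
                frames = base[None] + 0.2 * np.abs(rng.standard_normal((10, h, w)))
                block = BScanBlock(frames=frames)
                est.append(
                    windowed_decorrelation(block, DecorrParams(n_frames=n)).values
                )
            stds[n] = np.std(np.stack(est), axis=0).mean()
        assert stds[2] > stds[4] > stds[10]
        ratio = stds[2] / stds[10]
        assert 2.2 < ratio < 2.9
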