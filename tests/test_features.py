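"""Subpatch descriptors and parent aggregation against oracles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lymphopatch.config import LBPConfig
from lymphopatch.features import (
    aggregate_parent,
    gray_stats,
    lab_color_histogram,
    subpatch_lbp_features,
    ulbp_histogram,
    uniform_code_table,
)

from .oracles import oracle_ulbp_histogram


class TestUlbp:
    def test_histogram_length_is_59_for_p8(self, rng):
        h = ulbp_histogram(rng.integers(0, 256, (10, 10)).astype(np.uint8), 1)
        assert len(h) == 8 * 7 + 3 == 59

    def test_constant_patch_is_one_hot_all_ones_pattern(self):
        # with the >= convention every neighbor ties the center, so every
        # interior pixel gets the all-ones code (the last uniform bin)
        h = ulbp_histogram(np.full((9, 9), 42, dtype=np.uint8), 1)
        table = uniform_code_table(8)
        assert h[table[255]] == 1.0 and h.sum() == 1.0

    def test_constant_patch_under_strict_gt_is_all_zero_pattern(self):
        h = ulbp_histogram(np.full((9, 9), 42, dtype=np.uint8), 1, strict_gt=True)
        table = uniform_code_table(8)
        assert h[table[0]] == 1.0

    @pytest.mark.parametrize("radius", [1, 2])
    def test_matches_bruteforce_oracle_on_random_patches(self, radius, rng):
        for _ in range(25):
            patch = rng.integers(0, 256, (8, 8)).astype(np.uint8)
            np.testing.assert_array_equal(
                ulbp_histogram(patch, radius), oracle_ulbp_histogram(patch, radius)
            )

    def test_small_patch_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            ulbp_histogram(np.zeros((4, 4), dtype=np.uint8), 2)

    def test_concatenated_radii_match_single_radius_oracles(self, rng):
        cfg = LBPConfig()
        patch = rng.integers(0, 256, (12, 12)).astype(np.uint8)
        vec = subpatch_lbp_features(patch, cfg)
        assert len(vec) == 118
        expected = np.concatenate(
            [oracle_ulbp_histogram(patch, r) for r in cfg.radii]
        )
        np.testing.assert_allclose(vec, expected, atol=1e-12)


class TestGrayStats:
    def test_constant_patch(self):
        out = gray_stats(np.full((50, 50), 7.0))
        np.testing.assert_allclose(out, [7, 7, 2500 * 7, 7, 0, 7, 7, 7, 0])

    def test_hand_computed_small_patch(self):
        out = gray_stats(np.array([[1.0, 2.0], [3.0, 4.0]]))
        # Q1/Q3 by linear interpolation between order statistics
        np.testing.assert_allclose(out, [4, 1, 10, 2.5, np.sqrt(1.25), 2.5, 1.75, 3.25, 1.5])

    def test_iqr_is_q3_minus_q1(self, rng):
        out = gray_stats(rng.integers(0, 256, (30, 30)))
        assert out[8] == pytest.approx(out[7] - out[6])


class TestLabHistogram:
    def test_default_length_is_170(self, rng):
        patch = rng.uniform(-100, 100, (10, 10, 3))
        assert len(lab_color_histogram(patch)) == 170

    def test_constant_color_is_one_hot_per_channel(self):
        patch = np.zeros((6, 6, 3))
        patch[..., 1], patch[..., 2] = -50.0, 30.0
        h = lab_color_histogram(patch)
        a, b = h[:85], h[85:]
        assert a.max() == 1.0 and b.max() == 1.0
        assert a.sum() == pytest.approx(1) and b.sum() == pytest.approx(1)

    def test_each_half_normalized_and_clipping_applied(self, rng):
        patch = rng.uniform(-400, 400, (8, 8, 3))  # far outside [-128, 127]
        h = lab_color_histogram(patch)
        assert h[:85].sum() == pytest.approx(1.0)
        assert h[85:].sum() == pytest.approx(1.0)


class TestAggregateParent:
    def test_lbp_block_reaches_472(self, rng):
        subs = [rng.dirichlet(np.ones(118)) for _ in range(49)]
        assert len(aggregate_parent(subs)) == 472

    def test_identical_subvectors_have_zero_dispersion(self):
        v = np.array([1.0, 2.0, 3.0])
        out = aggregate_parent([v, v, v])
        np.testing.assert_allclose(out, np.concatenate([v, np.zeros(3), v, v]))

    def test_hand_computed_two_point_case(self):
        out = aggregate_parent([np.array([0.0]), np.array([10.0])])
        np.testing.assert_allclose(out, [5.0, 5.0, 1.0, 9.0])

    def test_empty_and_ragged_inputs_rejected(self):
        with pytest.raises(ValueError):
            aggregate_parent([])
        with pytest.raises(ValueError, match="ragged"):
            aggregate_parent([np.zeros(3), np.zeros(4)])

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_commutes_with_dimension_permutation(self, seed):
        rng = np.random.default_rng(seed)
        n, k = 5, 6
        subs = rng.normal(size=(k, n))
        perm = rng.permutation(n)
        direct = aggregate_parent(subs[:, perm])
        permuted_blocks = np.concatenate(
            [block[perm] for block in aggregate_parent(subs).reshape(4, n)]
        )
        np.testing.assert_allclose(direct, permuted_blocks)
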