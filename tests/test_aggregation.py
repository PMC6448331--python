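"""MV/MS/DMW aggregation and the C1-C5 combination modes."""

from __future__ import annotations

import numpy as np
import pytest

from lymphopatch.aggregation import (
    PatchScores,
    dmw_image_score,
    dmw_weights,
    fuse_image_scores,
    fuse_patch_scores,
    majority_vote,
    mean_score,
    run_combination_mode,
)
from lymphopatch.config import FusionConfig

from .oracles import oracle_dmw_weights


def random_simplex(rng, m):
    return rng.dirichlet(np.ones(3), size=m)


class TestMajorityVote:
    def test_strict_majority(self):
        assert majority_vote([0, 0, 1]) == 0

    def test_single_patch(self):
        assert majority_vote([1]) == 1

    def test_tie_resolved_by_lowest_class_index(self):
        assert majority_vote([0, 1]) == 0
        assert majority_vote([2, 1]) == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            majority_vote([])

    def test_equals_argmax_of_mean_score_for_one_hot_scores(self, rng):
        for _ in range(20):
            labels = rng.integers(0, 3, size=11)
            counts = np.bincount(labels, minlength=3)
            if np.sum(counts == counts.max()) > 1:
                continue  # untied cases only
            assert majority_vote(labels) == int(np.argmax(mean_score(np.eye(3)[labels])))


class TestMeanScore:
    def test_identical_scores_pass_through(self):
        v = np.array([0.2, 0.5, 0.3])
        np.testing.assert_allclose(mean_score(np.tile(v, (4, 1))), v)

    def test_symmetric_two_patch_case(self):
        s = np.array([[1.0, 0, 0], [0, 1.0, 0]])
        np.testing.assert_allclose(mean_score(s), [0.5, 0.5, 0])

    def test_equals_dmw_when_distances_are_uniform(self, rng):
        # equilateral simplex vertices: all pairwise distances equal
        feats = np.eye(3)
        scores = random_simplex(rng, 3)
        w = dmw_weights(feats)
        np.testing.assert_allclose(dmw_image_score(scores, w), mean_score(scores), atol=1e-12)


class TestDmwWeights:
    def test_two_patches_split_evenly(self, rng):
        w = dmw_weights(rng.normal(size=(2, 5)))
        np.testing.assert_allclose(w, [0.5, 0.5], atol=1e-12)

    def test_worked_colinear_three_patch_case(self):
        w = dmw_weights(np.array([[0.0], [1.0], [3.0]]))
        np.testing.assert_allclose(w, [15 / 47, 20 / 47, 12 / 47], atol=1e-9)

    def test_identical_patches_fall_back_to_uniform(self):
        w = dmw_weights(np.ones((4, 3)))
        np.testing.assert_allclose(w, 0.25)

    def test_single_patch_degenerates_to_unit_weight(self):
        np.testing.assert_array_equal(dmw_weights(np.ones((1, 7))), [1.0])

    def test_matches_bruteforce_oracle(self, rng):
        for m in (2, 3, 5, 8):
            feats = rng.normal(size=(m, 4))
            np.testing.assert_allclose(
                dmw_weights(feats), oracle_dmw_weights(feats), atol=1e-12
            )

    def test_simplex_and_permutation_equivariance(self, rng):
        feats = rng.normal(size=(6, 10))
        w = dmw_weights(feats)
        assert np.all(w >= 0) and w.sum() == pytest.approx(1.0, abs=1e-9)
        perm = rng.permutation(6)
        np.testing.assert_allclose(dmw_weights(feats[perm]), w[perm], atol=1e-12)

    def test_scale_invariance(self, rng):
        feats = rng.normal(size=(5, 4))
        np.testing.assert_allclose(dmw_weights(feats), dmw_weights(1000.0 * feats), atol=1e-9)

    def test_outlier_patch_gets_smallest_weight(self):
        feats = np.vstack([np.zeros((4, 2)) + np.arange(4)[:, None] * 0.01,
                           [[50.0, 50.0]]])
        w = dmw_weights(feats)
        assert np.argmin(w) == 4
        assert w[4] < w[:4].min()

    def test_ragged_input_rejected(self):
        with pytest.raises(ValueError):
            dmw_weights(np.array([[1, 2], [3]], dtype=object))


class TestScoreCombination:
    def test_uniform_weights_reproduce_mean_score(self, rng):
        s = random_simplex(rng, 5)
        np.testing.assert_allclose(
            dmw_image_score(s, np.full(5, 0.2)), mean_score(s), atol=1e-12
        )

    def test_one_hot_weight_selects_that_patch(self, rng):
        s = random_simplex(rng, 4)
        w = np.array([0.0, 0.0, 1.0, 0.0])
        np.testing.assert_allclose(dmw_image_score(s, w), s[2])

    def test_weighted_sum_hand_case(self):
        s = np.array([[1.0, 0, 0], [0, 1.0, 0]])
        np.testing.assert_allclose(dmw_image_score(s, [0.75, 0.25]), [0.75, 0.25, 0])

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            dmw_image_score(random_simplex(rng, 3), [0.5, 0.5])


class TestFusion:
    def test_patch_fusion_endpoints_and_hand_case(self):
        s1 = np.array([[1.0, 0, 0]])
        s2 = np.array([[0, 0, 1.0]])
        np.testing.assert_allclose(fuse_patch_scores(s1, s2, 1.0), s1)
        np.testing.assert_allclose(fuse_patch_scores(s1, s2, 0.0), s2)
        np.testing.assert_allclose(fuse_patch_scores(s1, s2, 0.7), [[0.7, 0, 0.3]])

    def test_patch_fusion_mismatched_m_rejected(self):
        with pytest.raises(ValueError):
            fuse_patch_scores(np.zeros((2, 3)), np.zeros((3, 3)), 0.5)

    def test_image_fusion_cases(self):
        a, b = np.array([1.0, 0, 0]), np.array([0, 1.0, 0])
        np.testing.assert_allclose(fuse_image_scores(a, b, 0.5), [0.5, 0.5, 0])
        np.testing.assert_allclose(fuse_image_scores(a, b, 1.0), a)
        np.testing.assert_allclose(fuse_image_scores(a, a, 0.123), a)


class TestCombinationModes:
    @pytest.fixture
    def paths(self, rng):
        m = 6
        return {
            "F1": PatchScores(scores=random_simplex(rng, m), features=rng.normal(size=(m, 8))),
            "F2": PatchScores(scores=random_simplex(rng, m), features=rng.normal(size=(m, 12))),
            "deep": PatchScores(scores=random_simplex(rng, 4), features=rng.normal(size=(4, 16))),
        }

    def test_c1_single_patch_returns_its_score(self, rng):
        s = random_simplex(rng, 1)
        paths = {"F1": PatchScores(scores=s, features=rng.normal(size=(1, 5)))}
        np.testing.assert_allclose(
            run_combination_mode("C1", paths, FusionConfig()), s[0]
        )

    def test_c3_with_full_patch_weight_equals_c1_on_shared_features(self, rng):
        # when both paths carry the same DMW features, w_P=1 reduces C3 to C1
        m = 5
        feats = rng.normal(size=(m, 7))
        s1 = random_simplex(rng, m)
        paths = {
            "F1": PatchScores(scores=s1, features=feats),
            "F2": PatchScores(scores=random_simplex(rng, m), features=feats),
        }
        cfg = FusionConfig(w_P=1.0)
        np.testing.assert_allclose(
            run_combination_mode("C3", paths, cfg),
            run_combination_mode("C1", paths, cfg),
            atol=1e-12,
        )

    def test_c5_with_full_image_weight_equals_c3(self, paths):
        cfg = FusionConfig(w_I=1.0)
        np.testing.assert_allclose(
            run_combination_mode("C5", paths, cfg),
            run_combination_mode("C3", paths, cfg),
            atol=1e-12,
        )

    @pytest.mark.parametrize("mode", ["C1", "C2", "C3", "C4", "C5"])
    def test_all_modes_stay_on_the_simplex(self, mode, paths):
        out = run_combination_mode(mode, paths, FusionConfig())
        assert np.all(out >= -1e-12)
        assert out.sum() == pytest.approx(1.0, abs=1e-9)

    def test_missing_path_named_in_error(self, paths):
        del paths["deep"]
        with pytest.raises(KeyError, match="deep"):
            run_combination_mode("C4", paths, FusionConfig())
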