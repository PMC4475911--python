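"""ROC-hull predictive power, cross-validation machinery, and null controls."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import spikefield as sf
from spikefield import (
    BinnedSpikeTrain,
    CVConfig,
    CVResult,
    FeatureBlock,
    block_shuffle,
    chance_level,
    compare_feature_sets,
    nested_cv_fit,
    roc_hull_pp,
)
from spikefield.evaluation import _make_folds, evaluate_population
from spikefield.core import DELTA_S


class TestRocHullPP:
    def test_perfect_prediction(self):
        assert roc_hull_pp([1, 0, 1, 0], [1, 0, 1, 0]) == 1.0

    def test_constant_score_is_chance(self):
        assert roc_hull_pp([0.3] * 6, [1, 0, 1, 0, 0, 0]) == 0.0

    def test_worked_example_with_hull_gain(self):
        # raw AUC 0.75; convex hull AUC 0.875; PP = 2*0.875 - 1
        assert abs(roc_hull_pp([0.9, 0.8, 0.7, 0.1], [1, 0, 1, 0]) - 0.75) < 1e-12

    def test_degenerate_labels_rejected(self):
        with pytest.raises(ValueError):
            roc_hull_pp([0.1, 0.2], [0, 0])
        with pytest.raises(ValueError):
            roc_hull_pp([0.1, 0.2], [1, 1])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(3, 40), st.integers(0, 10**6))
    def test_pp_in_unit_interval(self, n, seed):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, n)
        if y.sum() in (0, n):
            y[0] = 1 - y[0]
            if y.sum() in (0, n):
                y[1] = 1 - y[1]
        pp = roc_hull_pp(rng.random(n), y)
        assert 0.0 <= pp <= 1.0


class TestFolds:
    def test_contiguous_partition(self):
        folds = _make_folds(1000, CVConfig(seed=0))
        joined = np.sort(np.concatenate(folds))
        assert np.array_equal(joined, np.arange(1000))
        assert len(folds) == 10

    def test_random_partition(self):
        folds = _make_folds(1000, CVConfig(seed=0, fold_scheme="random"))
        joined = np.sort(np.concatenate(folds))
        assert np.array_equal(joined, np.arange(1000))

    def test_grid_validation(self):
        with pytest.raises(ValueError):
            CVConfig(alpha_grid=(1e-3, 1e-2))
        with pytest.raises(ValueError):
            CVConfig(alpha_grid=tuple(np.logspace(-9, 2, 11)))  # no zero


class TestBlockShuffle:
    def test_multiset_preserved_and_deterministic(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(1050, 3))
        a = block_shuffle(x, 100, seed=5)
        b = block_shuffle(x, 100, seed=5)
        assert np.array_equal(a, b)
        assert np.allclose(np.sort(a, axis=0), np.sort(x, axis=0))
        assert not np.allclose(a, x)

    def test_single_chunk_warns(self):
        x = np.arange(50.0).reshape(-1, 1)
        with pytest.warns(UserWarning):
            out = block_shuffle(x, 100, seed=0)
        assert np.array_equal(out, x)

    def test_autocorrelation_kept_alignment_destroyed(self):
        # slow common drive: x predicts y at lag 0 before shuffling
        rng = np.random.default_rng(1)
        drive = np.convolve(rng.normal(size=6000), np.ones(200) / 14.0,
                            mode="same")
        x = drive + 0.1 * rng.normal(size=6000)
        y = drive + 0.1 * rng.normal(size=6000)
        xs = block_shuffle(x.reshape(-1, 1), 100, seed=2)[:, 0]
        assert abs(np.corrcoef(x, y)[0, 1]) > 0.9
        assert abs(np.corrcoef(xs, y)[0, 1]) < 0.2
        # within-chunk structure (lag-1 autocorrelation) preserved
        def lag1(v):
            return np.corrcoef(v[:-1], v[1:])[0, 1]
        assert lag1(xs) > 0.9


def _driven_unit(T=60000, seed=0):
    """A unit driven by a slow latent signal, plus informative features."""
    rng = np.random.default_rng(seed)
    drive = np.convolve(rng.normal(size=T), np.ones(400) / 20.0, mode="same")
    lam_delta = np.exp(np.log(25 * DELTA_S) + 0.8 * drive / drive.std())
    y = (rng.random(T) < np.minimum(lam_delta, 1)).astype(int)
    feats = np.column_stack(
        [np.roll(drive, k) for k in (-50, 0, 50)]
    ) / drive.std()
    good = FeatureBlock(feats, ["d-50", "d0", "d+50"], "kin")
    noise = FeatureBlock(rng.normal(size=(T, 3)), ["n0", "n1", "n2"], "lfp")
    return good, noise, BinnedSpikeTrain(y)


class TestNestedCV:
    @pytest.fixture(scope="class")
    def driven(self):
        return _driven_unit()

    def test_informative_features_beat_chance(self, driven):
        good, noise, Y = driven
        cfg = CVConfig(seed=3)
        res = nested_cv_fit([good], Y, cfg, "drive", unit="u0")
        thr, nulls = chance_level([noise], Y, cfg, 20, alpha=1e-2)
        assert res.pp_pooled > thr
        assert res.pp_pooled > 0.1
        assert len(res.pp_per_fold) == 10
        assert np.all((0 <= res.pp_per_fold) & (res.pp_per_fold <= 1))

    def test_noise_features_below_chance_threshold(self, driven):
        good, noise, Y = driven
        cfg = CVConfig(seed=3)
        res = nested_cv_fit([noise], Y, cfg, "noise", unit="u0")
        thr, nulls = chance_level([noise], Y, cfg, 20, alpha=1e-2)
        assert res.pp_pooled <= thr
        # null distribution centred near zero
        assert abs(np.median(nulls)) < thr

    def test_population_path_matches_reference(self, driven):
        good, noise, Y = driven
        cfg = CVConfig(seed=3)
        ref = nested_cv_fit([good], Y, cfg, "kin", unit=Y.label)
        pop = evaluate_population(good, None, None, [Y], cfg, ladders=("kin",))
        got = pop["kin"][0]
        assert abs(got.pp_pooled - ref.pp_pooled) < 2e-3
        assert got.selected_alphas == ref.selected_alphas

    def test_chance_requires_enough_permutations(self, driven):
        good, noise, Y = driven
        with pytest.raises(ValueError):
            chance_level([noise], Y, CVConfig(seed=0), 5)


class TestCompare:
    def _results(self, pps_a, pps_b):
        def mk(name, pps):
            return [
                CVResult(name, np.full(10, p), p, [0.01], unit=f"u{i}")
                for i, p in enumerate(pps)
            ]
        return {"a": mk("a", pps_a), "b": mk("b", pps_b)}

    def test_identical_results_degenerate_p(self):
        pps = list(np.linspace(0.1, 0.4, 8))
        res = self._results(pps, pps)
        cmp_ = compare_feature_sets(res, "a", "b", n_tests=3)
        assert cmp_.p_value == 1.0
        assert cmp_.median_delta == 0.0
        assert not cmp_.significant

    def test_consistent_gain_significant(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(0.1, 0.3, 12)
        ext = base + rng.uniform(0.05, 0.1, 12)
        cmp_ = compare_feature_sets(self._results(base, ext), "a", "b", 3)
        assert cmp_.median_delta > 0.04
        assert cmp_.significant

    def test_too_few_units_rejected(self):
        res = self._results([0.1] * 4, [0.2] * 4)
        with pytest.raises(ValueError):
            compare_feature_sets(res, "a", "b", 1)

    def test_mismatched_units_rejected(self):
        res = self._results([0.1] * 8, [0.2] * 8)
        res["b"] = res["b"][::-1]
        with pytest.raises(ValueError):
            compare_feature_sets(res, "a", "b", 1)
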