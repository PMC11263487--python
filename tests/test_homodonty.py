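import itertools
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from odontomech import (
    ValidationError,
    bootstrap_null,
    classify,
    kmedoids_threshold,
    residual_stress,
    run_homodonty,
    two_medoids,
)
from odontomech import synthetic as syn
from odontomech.homodonty import _two_medoids_sorted


def brute_force_two_medoids(values):
    """Independent oracle: exhaustive search over all medoid pairs."""
    v = np.asarray(values, dtype=float)
    best = None
    for i, j in itertools.combinations(range(len(v)), 2):
        cost = np.minimum(np.abs(v - v[i]), np.abs(v - v[j])).sum()
        if best is None or cost < best[0] - 1e-12:
            best = (cost, tuple(sorted((v[i], v[j]))))
    return best


class TestResiduals:
    def test_hand_median(self):
        np.testing.assert_allclose(residual_stress([1, 2, 3, 4, 5]),
                                   [1 / 3, 2 / 3, 1, 4 / 3, 5 / 3])

    def test_all_equal_gives_ones(self):
        np.testing.assert_array_equal(residual_stress([0.7] * 6), np.ones(6))

    def test_median_residual_is_one_for_odd_n(self):
        rng = np.random.default_rng(0)
        r = residual_stress(rng.lognormal(0, 0.5, size=11))
        assert np.median(r) == pytest.approx(1.0, abs=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(c=st.floats(min_value=1e-6, max_value=1e6,
                       allow_nan=False, allow_infinity=False))
    def test_scale_invariance(self, c):
        s = np.array([0.2, 0.5, 1.1, 2.0, 3.3])
        np.testing.assert_allclose(residual_stress(c * s), residual_stress(s),
                                   rtol=1e-12)

    def test_non_positive_rejected(self):
        with pytest.raises(ValidationError):
            residual_stress([1.0, -2.0, 3.0])


class TestBootstrap:
    def test_all_equal_pool_is_all_ones(self):
        pool = bootstrap_null([2.0] * 8, reps=50, seed=0)
        np.testing.assert_array_equal(pool, np.ones(50 * 4))

    def test_pool_size_and_determinism(self):
        s = np.arange(1.0, 11.0)
        a = bootstrap_null(s, reps=100, seed=123)
        b = bootstrap_null(s, reps=100, seed=123)
        assert a.shape == (100 * 5,)
        np.testing.assert_array_equal(a, b)

    def test_pool_median_near_one(self):
        rng = np.random.default_rng(7)
        stresses = rng.lognormal(0, 0.25, size=20)
        pool = bootstrap_null(stresses, reps=10_000, seed=7)
        assert np.median(pool) == pytest.approx(1.0, abs=0.05)

    def test_too_few_teeth_rejected(self):
        with pytest.raises(ValidationError):
            bootstrap_null([1.0, 2.0, 3.0], reps=10, seed=0)


class TestKMedoids:
    def test_bimodal_pool_threshold_exactly_one(self):
        pool = np.array([0.5] * 2500 + [1.5] * 2500)
        upper, lower = kmedoids_threshold(pool, subsample=5000, seed=0)
        assert upper == 1.0
        assert lower == 1.0  # mirror_log: 1/1

    def test_two_medoids_bimodal(self):
        assert two_medoids([0.5] * 10 + [1.5] * 10) == (0.5, 1.5)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        for size in (2, 3, 5, 8, 12):
            v = np.round(rng.lognormal(0, 0.5, size=size), 4)
            cost_oracle, _ = brute_force_two_medoids(v)
            _, cost = _two_medoids_sorted(np.sort(v)[None, :])
            assert cost[0] == pytest.approx(cost_oracle, abs=1e-9)

    def test_full_pool_subsample_repeats_equivalent(self):
        rng = np.random.default_rng(3)
        pool = rng.lognormal(0, 0.3, size=400)
        one = kmedoids_threshold(pool, subsample=400, repeats=1, seed=0)
        hundred = kmedoids_threshold(pool, subsample=400, repeats=100, seed=1)
        assert one == hundred

    def test_degenerate_pool_collapses(self):
        with pytest.warns(UserWarning, match="degenerate"):
            upper, lower = kmedoids_threshold(np.ones(100), seed=0)
        assert upper == lower == 1.0

    def test_reciprocal_mode_lower_from_inverted_pool(self):
        pool = np.array([0.5] * 2500 + [1.5] * 2500)
        upper, lower = kmedoids_threshold(pool, subsample=5000, seed=0,
                                          two_sided="reciprocal")
        # reciprocal pool {2, 2/3}: medoids mean 4/3, lower = 3/4
        assert upper == 1.0
        assert lower == pytest.approx(0.75, rel=1e-12)


class TestClassify:
    def test_all_within_band(self):
        classes, avg_sq, prop = classify([0.9, 1.0, 1.1], 1.5, 0.5)
        assert list(classes) == ["homodont"] * 3
        assert prop == 0.0

    def test_outliers_both_sides(self):
        classes, _, prop = classify([0.2, 1.0, 3.0], 1.5, 0.5)
        assert list(classes) == ["heterodont", "homodont", "heterodont"]
        assert prop == pytest.approx(2 / 3)

    def test_avg_squared_residual_baseline(self):
        _, avg_sq, _ = classify([1.0, 1.0, 1.0], 1.5, 0.5)
        assert avg_sq == 1.0
        _, centered, _ = classify([1.0, 1.0, 1.0], 1.5, 0.5, center="one")
        assert centered == 0.0


class TestRunHomodonty:
    def _outlier_truth(self, factor=5.0, index=3, n=20):
        spec = syn.inject_outlier(
            syn.JawSpec(n_teeth=n, jaw_length=3.0 * n), index, factor)
        return syn.ground_truth(spec)

    def test_homodont_jaw_has_zero_heterodont(self):
        spec = syn.calibrate_homodont(syn.JawSpec(n_teeth=12, jaw_length=40.0))
        truth = syn.ground_truth(spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = run_homodonty(truth, seed=1)["all"]
        assert r.proportion_heterodont == 0.0
        assert r.degenerate

    def test_outlier_recovered_across_seeds(self):
        truth = self._outlier_truth(5.0)
        hits = 0
        for seed in range(11):
            r = run_homodonty(truth, reps=2000, subsample=1000, repeats=20,
                              seed=seed)["all"]
            hits += r.classes[3] == "heterodont"
        assert hits >= 10  # majority vote

    def test_low_stress_outlier_flagged_below(self):
        truth = self._outlier_truth(0.2, index=10)
        r = run_homodonty(truth, reps=2000, subsample=1000, repeats=20,
                          seed=0)["all"]
        assert r.residuals[10] < r.lower_threshold
        assert r.classes[10] == "heterodont"

    def test_seeded_determinism(self):
        truth = self._outlier_truth(5.0)
        a = run_homodonty(truth, reps=500, subsample=500, repeats=10, seed=9)["all"]
        b = run_homodonty(truth, reps=500, subsample=500, repeats=10, seed=9)["all"]
        np.testing.assert_array_equal(a.pool, b.pool)
        assert (a.upper_threshold, a.lower_threshold) == \
               (b.upper_threshold, b.lower_threshold)
        np.testing.assert_array_equal(a.classes, b.classes)

    def test_scale_invariance_of_whole_pipeline(self):
        truth = self._outlier_truth(5.0)
        scaled = truth.copy()
        scaled["stress"] = truth["stress"] * 4.0  # power of two: exact
        a = run_homodonty(truth, reps=500, subsample=500, repeats=10, seed=2)["all"]
        b = run_homodonty(scaled, reps=500, subsample=500, repeats=10, seed=2)["all"]
        np.testing.assert_array_equal(a.residuals, b.residuals)
        assert a.upper_threshold == b.upper_threshold
        np.testing.assert_array_equal(a.classes, b.classes)
        assert a.avg_squared_residual == b.avg_squared_residual

    def test_small_jaw_skipped_with_warning(self):
        import pandas as pd

        df = pd.DataFrame({"stress": [1.0, 1.1, 0.9],
                           "jaw_id": ["J1"] * 3})
        with pytest.warns(UserWarning, match="skipped"):
            results = run_homodonty(df, seed=0)
        assert results == {}

    def test_groups_are_independent_of_each_other(self):
        import pandas as pd

        rng = np.random.default_rng(5)
        j1 = rng.lognormal(0, 0.3, 10)
        j2 = rng.lognormal(0, 0.3, 12)
        both = pd.DataFrame({
            "stress": np.concatenate([j1, j2]),
            "jaw_id": ["J1"] * 10 + ["J2"] * 12})
        only = pd.DataFrame({"stress": j1, "jaw_id": ["J1"] * 10})
        ra = run_homodonty(both, reps=500, subsample=500, repeats=10, seed=4)
        rb = run_homodonty(only, reps=500, subsample=500, repeats=10, seed=4)
        assert ra["J1"].upper_threshold == rb["J1"].upper_threshold
        np.testing.assert_array_equal(ra["J1"].classes, rb["J1"].classes)

    def test_threshold_stable_across_seeds(self):
        rng = np.random.default_rng(11)
        import pandas as pd

        truth = pd.DataFrame({"stress": rng.lognormal(0, 0.25, size=30)})
        uppers = [run_homodonty(truth, seed=s)["all"].upper_threshold
                  for s in range(10)]
        cv = np.std(uppers) / np.mean(uppers)
        assert cv < 0.02
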