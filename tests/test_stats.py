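"""Statistical kernel: Welch test, Spearman, critical values, contrast."""

import math
from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from splicedrift.stats import (
    PRESET_RHO_THRESHOLD,
    normalized_contrast,
    spearman_critical,
    spearman_rho,
    welch_t,
    welch_t_from_summary,
)


class TestWelch:
    def test_hand_computed_example(self):
        # means 2 vs 5, unit variances: t = -3 / sqrt(2/3), df = 4
        res = welch_t([1, 2, 3], [4, 5, 6])
        assert res.t == pytest.approx(-3.6742, abs=1e-3)
        assert res.df == pytest.approx(4.0)
        assert res.p == pytest.approx(0.0213, abs=2e-3)

    def test_from_summary_published_serum_comparison(self):
        # 43.9 (SD 7.1, n=6) vs 23.0 (SD 9.3, n=6): reported as p < 0.04
        res = welch_t_from_summary(43.9, 7.1, 6, 23.0, 9.3, 6)
        assert res.p < 0.04
        assert res.t == pytest.approx(4.375, abs=5e-3)
        assert res.p == pytest.approx(0.0016, abs=3e-4)

    def test_identical_groups(self):
        res = welch_t([5, 5, 5], [5, 5, 5])
        assert res.t == 0.0 and res.p == 1.0 and not res.degenerate

    def test_zero_variance_unequal_means_is_degenerate(self):
        res = welch_t([1, 1, 1], [2, 2, 2])
        assert res.p == 0.0 and res.degenerate

    def test_equal_variance_equal_n_gives_pooled_df(self):
        res = welch_t([1, 2, 3, 4], [10, 11, 12, 13])
        assert res.df == pytest.approx(6.0)

    def test_group_size_below_two_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            welch_t_from_summary(1, 1, 1, 2, 1, 3)

    @given(
        a=st.lists(st.floats(-50, 50), min_size=2, max_size=8),
        b=st.lists(st.floats(-50, 50), min_size=2, max_size=8),
    )
    @settings(derandomize=True, max_examples=60)
    def test_antisymmetry(self, a, b):
        r1 = welch_t(a, b)
        r2 = welch_t(b, a)
        assert r1.t == pytest.approx(-r2.t, rel=1e-9, abs=1e-12) or (
            math.isinf(r1.t) and math.isinf(r2.t)
        )
        assert r1.p == pytest.approx(r2.p, rel=1e-9, abs=1e-12)

    def test_matches_scipy_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            na, nb = rng.integers(2, 10, size=2)
            a = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), na)
            b = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), nb)
            res = welch_t(a, b)
            t, p = sps.ttest_ind(a, b, equal_var=False)
            assert res.t == pytest.approx(t, rel=1e-9)
            assert res.p == pytest.approx(p, rel=1e-9)

    def test_null_rate_is_conservative_at_n3(self):
        """With 3 vs 3 samples the Welch test rejects at *below* the nominal
        level on null data — the basis for reporting raw p-values with no
        multiplicity correction downstream."""
        rng = np.random.default_rng(7)
        a = rng.normal(1.0, 0.1, size=(10000, 3))
        b = rng.normal(1.0, 0.1, size=(10000, 3))
        _, p = sps.ttest_ind(a, b, axis=1, equal_var=False)
        frac_scipy = float((p < 0.05).mean())
        # spot-check our implementation agrees with the vectorized oracle
        sub = [welch_t(a[i], b[i]).p for i in range(300)]
        assert np.allclose(sub, p[:300])
        sigma = math.sqrt(0.05 * 0.95 / 10000)
        assert 0.02 <= frac_scipy <= 0.05 + 2 * sigma


class TestSpearman:
    def test_hand_ranked_example(self):
        assert spearman_rho([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)

    def test_monotone_transform_gives_one(self):
        xs = [1.0, 2.5, 4.0, 7.0]
        assert spearman_rho(xs, [x ** 2 for x in xs]) == pytest.approx(1.0)

    def test_reversal_negates(self):
        xs = [1, 2, 3, 4, 5]
        ys = [3, 1, 4, 5, 2]
        assert spearman_rho(xs, ys) == pytest.approx(-spearman_rho(xs, ys[::-1]))

    def test_constant_vector_undefined(self):
        assert math.isnan(spearman_rho([1, 1, 1, 1], [1, 2, 3, 4]))

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = int(rng.integers(3, 30))
            xs = rng.integers(0, 5, n).astype(float)  # heavy ties
            ys = rng.normal(size=n)
            if np.ptp(xs) == 0:
                continue
            expected = sps.spearmanr(xs, ys).statistic
            assert spearman_rho(xs, ys) == pytest.approx(expected, abs=1e-12)

    @given(st.lists(st.integers(-1000, 1000), min_size=4, max_size=20, unique=True))
    @settings(derandomize=True, max_examples=40)
    def test_invariant_under_increasing_transform(self, xs):
        rng = np.random.default_rng(len(xs))
        ys = list(rng.normal(size=len(xs)))
        if np.ptp(ys) == 0:
            return
        transformed = [math.exp(x / 1000) for x in xs]
        assert spearman_rho(xs, ys) == pytest.approx(
            spearman_rho(transformed, ys), abs=1e-12
        )


class TestSpearmanCritical:
    def test_published_scale_n571(self):
        # one-tailed t-approximation at the published event count
        assert spearman_critical(571, 0.05, "one") == pytest.approx(0.069, abs=1e-3)
        # the published preset differs; both must be available
        assert PRESET_RHO_THRESHOLD == 0.0655

    def test_small_n_two_tailed(self):
        assert spearman_critical(5, 0.05, "two") == pytest.approx(0.878, abs=1e-3)

    def test_alpha_to_one_threshold_to_zero(self):
        assert spearman_critical(30, 0.999, "one") < 0.01

    def test_exact_permutation_tail_at_n5(self):
        """Enumerating all 5! rank permutations: the one-tailed exact tail
        probability at the t-approximation threshold stays below alpha."""
        base = [1, 2, 3, 4, 5]
        rhos = [spearman_rho(base, list(p)) for p in permutations(base)]
        thr = spearman_critical(5, 0.05, "one")
        tail = sum(r >= thr for r in rhos) / len(rhos)
        assert tail <= 0.05

    def test_bad_alpha_rejected(self):
        with pytest.raises(ValueError):
            spearman_critical(10, 1.5)


class TestContrast:
    def test_arithmetic(self):
        assert normalized_contrast([0.25], [0.75]) == pytest.approx(-0.5)

    def test_symmetry_zero(self):
        assert normalized_contrast([2, 2], [2, 2]) == 0.0

    def test_saturation_edges(self):
        assert normalized_contrast([0.3, 0.5], [0.0, 0.0]) == 1.0
        assert normalized_contrast([0.0, 0.0], [0.1, 0.2]) == -1.0

    def test_both_zero_undefined(self):
        assert math.isnan(normalized_contrast([0.0], [0.0]))

    @given(
        a=st.lists(st.floats(0, 100), min_size=1, max_size=6),
        b=st.lists(st.floats(0, 100), min_size=1, max_size=6),
        k=st.floats(1e-3, 1e3),
    )
    @settings(derandomize=True, max_examples=60)
    def test_scale_invariance_and_bounds(self, a, b, k):
        x = normalized_contrast(a, b)
        if math.isnan(x):
            return
        assert -1.0 <= x <= 1.0
        xs = normalized_contrast([k * v for v in a], [k * v for v in b])
        assert xs == pytest.approx(x, rel=1e-9, abs=1e-12)
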