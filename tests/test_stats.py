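import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu as scipy_mwu

from flymuscle.stats import (
    aggregate_population,
    compare_genotypes,
    mann_whitney_u,
    neg_log10,
    plot_comparison,
)


def enumeration_oracle(x, y):
    """Exact two-sided Mann-Whitney p by brute force over all labelings,
    computing U from pairwise comparisons (independent of rank formulas)."""
    pooled = list(x) + list(y)
    n1 = len(x)

    def u_stat(sample1, sample2):
        u1 = sum(1 for a in sample1 for b in sample2 if a > b)
        return min(u1, len(sample1) * len(sample2) - u1)

    observed = u_stat(list(x), list(y))
    count = total = 0
    idx = range(len(pooled))
    for combo in itertools.combinations(idx, n1):
        s1 = [pooled[i] for i in combo]
        s2 = [pooled[i] for i in idx if i not in combo]
        if u_stat(s1, s2) <= observed:
            count += 1
        total += 1
    return observed, count / total


def feature_frame(rows):
    return pd.DataFrame(rows, columns=["stack_name", "genotype", "hours_ahe", "diam"])


class TestAggregatePopulation:
    def test_linear_interpolation_percentiles(self):
        df = feature_frame([(f"a{i}", "g", 0.0, v) for i, v in enumerate((10, 20, 30))])
        s = aggregate_population(df, "diam", np.array([0.0]))
        assert s.median[0] == 20
        assert s.p25[0] == 15
        assert s.p75[0] == 25
        assert s.n[0] == 3

    def test_single_value_collapses_band(self):
        df = feature_frame([("a", "g", 0.0, 42.0)])
        s = aggregate_population(df, "diam", np.array([0.0]))
        assert s.median[0] == s.p25[0] == s.p75[0] == 42.0

    def test_constant_population_zero_width_band(self):
        df = feature_frame([(f"a{i}", "g", 0.0, 7.0) for i in range(12)])
        s = aggregate_population(df, "diam", np.array([0.0]))
        assert s.p75[0] - s.p25[0] == 0.0

    def test_empty_grid_point_is_missing_not_error(self):
        df = feature_frame([("a", "g", 0.0, 1.0)])
        s = aggregate_population(df, "diam", np.array([0.0, 50.0]))
        assert np.isnan(s.median[1])
        assert s.n[1] == 0

    def test_order_invariance(self, rng):
        rows = [(f"a{i}", "g", 0.0, float(v)) for i, v in enumerate(rng.normal(50, 5, 15))]
        s1 = aggregate_population(feature_frame(rows), "diam", np.array([0.0]))
        s2 = aggregate_population(feature_frame(rows[::-1]), "diam", np.array([0.0]))
        assert s1.median[0] == s2.median[0]


class TestMannWhitney:
    def test_worked_example(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_samples_p_one(self):
        _, p = mann_whitney_u([3.0, 3.0, 3.0], [3.0, 3.0, 3.0])
        assert p == 1.0

    def test_exact_matches_enumeration_oracle_small_n(self, rng):
        # exhaustive sweep over all tie-free rank patterns with n1, n2 <= 5
        for n1 in range(1, 6):
            for n2 in range(1, 6):
                for combo in itertools.combinations(range(n1 + n2), n1):
                    vals = np.arange(1.0, n1 + n2 + 1)
                    x = vals[list(combo)]
                    y = np.delete(vals, list(combo))
                    u_impl, p_impl = mann_whitney_u(x, y)
                    u_or, p_or = enumeration_oracle(x, y)
                    assert u_impl == u_or
                    assert p_impl == pytest.approx(p_or, abs=1e-12)

    def test_random_values_match_oracle_n6(self, rng):
        for _ in range(30):
            x = rng.normal(0, 1, 6)
            y = rng.normal(0.5, 1, 6)
            u_impl, p_impl = mann_whitney_u(x, y)
            u_or, p_or = enumeration_oracle(x, y)
            assert u_impl == u_or
            assert p_impl == pytest.approx(p_or)

    def test_approximation_close_to_scipy(self, rng):
        for _ in range(50):
            x = rng.normal(0, 1, 15)
            y = rng.normal(0.8, 1, 14)
            _, p = mann_whitney_u(x, y)
            p_ref = scipy_mwu(x, y, alternative="two-sided", method="asymptotic").pvalue
            assert p == pytest.approx(p_ref, abs=0.01)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        x=st.lists(st.integers(-1000, 1000), min_size=2, max_size=6, unique=True),
        y=st.lists(st.integers(-1000, 1000), min_size=2, max_size=6, unique=True),
        shift=st.floats(-10, 10),
        scale=st.floats(0.1, 10),
    )
    def test_invariant_under_joint_monotone_transform(self, x, y, shift, scale):
        _, p1 = mann_whitney_u(x, y)
        _, p2 = mann_whitney_u(
            [scale * v + shift for v in x], [scale * v + shift for v in y]
        )
        assert p1 == pytest.approx(p2)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestNegLog10:
    @pytest.mark.parametrize("p,expected", [(0.01, 2.0), (1.0, 0.0), (0.05, 1.3010)])
    def test_values(self, p, expected):
        assert neg_log10(p) == pytest.approx(expected, abs=1e-4)

    def test_invalid_p_rejected(self):
        for p in (0.0, -0.5, 1.5):
            with pytest.raises(ValueError):
                neg_log10(p)


class TestCompareGenotypes:
    def _two_cohorts(self, rng, effect_after=None, n=10):
        rows = []
        grid = np.arange(0.0, 30.0, 5.0)
        for g in ("a", "b"):
            for animal in range(n):
                for t in grid:
                    v = rng.normal(50, 3)
                    if g == "b" and effect_after is not None and t >= effect_after:
                        v += 20
                    rows.append((f"{g}{animal}", g, t, v))
        return feature_frame(rows), grid

    def test_identical_populations_not_significant(self, rng):
        df, grid = self._two_cohorts(rng)
        res = compare_genotypes(df, "a", "b", "diam", grid)
        assert np.all(res.p_two_sided >= 0.01)

    def test_divergence_detected_after_onset(self, rng):
        df, grid = self._two_cohorts(rng, effect_after=15.0)
        res = compare_genotypes(df, "a", "b", "diam", grid)
        assert np.all(res.p_two_sided[grid >= 15.0] < 0.01)
        assert np.all(res.p_two_sided[grid < 15.0] >= 0.01)

    def test_symmetric_in_genotype_order(self, rng):
        df, grid = self._two_cohorts(rng, effect_after=10.0)
        p_ab = compare_genotypes(df, "a", "b", "diam", grid).p_two_sided
        p_ba = compare_genotypes(df, "b", "a", "diam", grid).p_two_sided
        np.testing.assert_allclose(p_ab, p_ba)

    def test_absent_genotype_rejected(self, rng):
        df, grid = self._two_cohorts(rng)
        with pytest.raises(KeyError):
            compare_genotypes(df, "a", "zzz", "diam", grid)


class TestPlotComparison:
    def test_writes_nonempty_file(self, tmp_path, rng):
        rows = []
        grid = np.arange(0.0, 20.0, 5.0)
        for g in ("a", "b"):
            for animal in range(6):
                for t in grid:
                    rows.append((f"{g}{animal}", g, t, rng.normal(40 if g == "a" else 60, 3)))
        df = feature_frame(rows)
        res = compare_genotypes(df, "a", "b", "diam", grid)
        series = tuple(aggregate_population(df, "diam", grid, genotype=g) for g in ("a", "b"))
        out = plot_comparison(res, series, tmp_path / "cmp.png")
        assert out.exists() and out.stat().st_size > 0

    def test_mismatched_grids_rejected(self, rng):
        rows = [(f"a{i}", "a", 0.0, 1.0 * i) for i in range(5)]
        rows += [(f"b{i}", "b", 0.0, 2.0 * i) for i in range(5)]
        df = feature_frame(rows)
        res = compare_genotypes(df, "a", "b", "diam", np.array([0.0]))
        s_a = aggregate_population(df, "diam", np.array([0.0]), genotype="a")
        s_b = aggregate_population(df, "diam", np.array([0.0, 5.0]), genotype="b")
        with pytest.raises(ValueError):
            plot_comparison(res, (s_a, s_b), "unused.png")
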