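"""Septal spacing, stage assignment, ANOVA, Tukey-Kramer, hatching detection."""

import logging
from types import SimpleNamespace

import numpy as np
import pytest
from scipy import stats as sps

from nautimorph import (
    anova_oneway,
    assign_stage,
    hatching_chamber,
    pairwise_comparisons,
    select_stage_points,
    septal_angles,
)


def record(diameters, chambers=None, positions=None):
    d = np.asarray(diameters, float)
    n = d.size
    return SimpleNamespace(
        diameters_at_chamber=d,
        chamber_numbers=np.arange(2, n + 2) if chambers is None else np.asarray(chambers),
        septal_positions=positions,
    )


class TestSeptalAngles:
    def test_differences_of_positions(self):
        rec = record([10, 20, 30], positions=np.array([0.0, 25.0, 50.0]))
        assert np.allclose(septal_angles(rec), [25.0, 25.0])

    def test_constant_spacing(self):
        rec = record([1] * 5, positions=np.arange(0.0, 150.0, 30.0))
        assert np.allclose(septal_angles(rec), 30.0)

    def test_non_monotone_positions_rejected(self):
        rec = record([1, 2], positions=np.array([0.0, 25.0, 20.0]))
        with pytest.raises(ValueError, match="strictly"):
            septal_angles(rec)


class TestAssignStage:
    def test_small_diameter_mid_series_is_pre_hatching(self):
        st = assign_stage(record([10, 20, 29.9, 35, 40, 45]))
        assert st.stages[2] == "pre_hatching"

    def test_boundary_30mm_is_juvenile(self):
        st = assign_stage(record([10, 20, 30.0, 35, 40, 45]))
        assert st.stages[2] == "juvenile_submature"

    def test_last_two_chambers_are_mature_even_if_small(self):
        st = assign_stage(record([10, 12, 14, 16, 18, 20]))
        assert st.stages[-2:] == ["mature", "mature"]
        assert st.stages[-3] == "pre_hatching"

    def test_every_chamber_gets_exactly_one_stage(self):
        diam = np.linspace(15.0, 120.0, 25)
        st = assign_stage(record(diam))
        assert len(st.stages) == 25
        assert sum(st.counts().values()) == 25

    def test_fewer_than_four_chambers_undefined(self):
        with pytest.raises(ValueError, match="fewer than 4"):
            assign_stage(record([10, 20, 30]))


class TestSelectStagePoints:
    def test_two_closest_to_target(self):
        i, j = select_stage_points([18.2, 19.5, 21.0, 33.0], 20.0)
        assert (i, j) == (1, 2)

    def test_maturity_returns_last_two(self):
        assert select_stage_points([10, 20, 30, 40], "max") == (2, 3)
        assert select_stage_points([10, 20, 30, 40], None) == (2, 3)

    def test_tie_broken_toward_smaller_diameter(self):
        # |19-20| == |21-20|; third point is farther
        i, j = select_stage_points([19.0, 21.0, 40.0], 20.0)
        assert (i, j) == (0, 1)
        i, j = select_stage_points([19.0, 21.0, 20.5], 20.0)  # 20.5 is closest
        assert (i, j) == (0, 2)


class TestAnova:
    def test_identical_groups_give_f_zero_p_one(self):
        res = anova_oneway({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert res.F == 0.0
        assert res.p_value == 1.0

    def test_two_group_example_matches_scipy(self):
        g = {"a": np.array([1.0, 2.0, 3.0]), "b": np.array([4.0, 5.0, 6.0])}
        res = anova_oneway(g)
        F, p = sps.f_oneway(g["a"], g["b"])
        assert res.F == pytest.approx(F, rel=1e-12)
        assert res.p_value == pytest.approx(p, rel=1e-12)
        # hand computation: SSB = 13.5, MSW = 1 -> F = 13.5 on df (1, 4)
        assert res.F == pytest.approx(13.5, abs=1e-12)
        assert (res.df_between, res.df_within) == (1, 4)

    def test_matches_scipy_on_random_unbalanced_groups(self, rng):
        for _ in range(20):
            groups = {
                f"g{i}": rng.normal(loc=rng.normal(), size=rng.integers(2, 9))
                for i in range(rng.integers(2, 6))
            }
            res = anova_oneway(groups)
            F, p = sps.f_oneway(*groups.values())
            assert res.F == pytest.approx(F, rel=1e-10)
            assert res.p_value == pytest.approx(p, rel=1e-8)

    def test_null_p_values_uniform(self, rng):
        """Permutation-free null check: equal-mean groups give uniform p."""
        n_rep, k, n = 2000, 4, 8
        data = rng.normal(size=(n_rep, k, n))
        ps = []
        for r in range(n_rep):
            ps.append(anova_oneway({f"g{i}": data[r, i] for i in range(k)}).p_value)
        stat = sps.kstest(ps, "uniform").pvalue
        assert stat > 0.01

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            anova_oneway({"a": [1, 2, 3]})


class TestPairwise:
    def test_identical_groups_nothing_significant(self):
        g = {"a": [5.0, 5.1, 4.9], "b": [5.0, 5.1, 4.9], "c": [5.0, 5.1, 4.9]}
        comps = pairwise_comparisons(g, alpha=0.05)
        assert len(comps) == 3
        for c in comps:
            assert not c.significant
            assert c.adjusted_p > 0.99

    def test_two_groups_reduce_to_pooled_t_test(self, rng):
        a = rng.normal(size=9)
        b = rng.normal(loc=0.8, size=12)
        (comp,) = pairwise_comparisons({"a": a, "b": b}, alpha=0.05)
        t_p = sps.ttest_ind(a, b, equal_var=True).pvalue
        assert comp.adjusted_p == pytest.approx(t_p, abs=1e-6)

    def test_shifted_group_is_the_significant_one(self, rng):
        base = rng.normal(size=10)
        g = {"a": base, "b": base + rng.normal(scale=0.01, size=10), "far": base + 50.0}
        comps = pairwise_comparisons(g, alpha=0.05)
        sig = {tuple(sorted((c.group_a, c.group_b))) for c in comps if c.significant}
        assert sig == {("a", "far"), ("b", "far")}

    def test_interval_consistent_with_significance(self, rng):
        groups = {f"g{i}": rng.normal(loc=i * 0.7, size=8) for i in range(4)}
        for c in pairwise_comparisons(groups, alpha=0.05):
            lo, hi = c.adjusted_interval
            excludes_zero = lo > 0 or hi < 0
            assert c.significant == excludes_zero
            assert c.significant == (c.adjusted_p < 0.05)

    def test_singleton_group_excluded_with_warning(self, rng, caplog):
        g = {"a": rng.normal(size=5), "b": rng.normal(size=6), "solo": [1.0]}
        with caplog.at_level(logging.WARNING, logger="nautimorph.septal"):
            comps = pairwise_comparisons(g)
        assert {frozenset((c.group_a, c.group_b)) for c in comps} == {frozenset(("a", "b"))}
        assert any("solo" in m for m in caplog.messages)

    def test_matches_statsmodels_tukeyhsd_loosely(self, rng):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        groups = {f"g{i}": rng.normal(loc=0.5 * i, size=10) for i in range(3)}
        vals = np.concatenate(list(groups.values()))
        labs = np.repeat(list(groups), [len(v) for v in groups.values()])
        sm = pairwise_tukeyhsd(vals, labs, alpha=0.05)
        ours = {tuple(sorted((c.group_a, c.group_b))): c.adjusted_p
                for c in pairwise_comparisons(groups)}
        for row, p in zip(sm.summary().data[1:], sm.pvalues):
            key = tuple(sorted((str(row[0]), str(row[1]))))
            assert ours[key] == pytest.approx(p, abs=2e-3)


class TestHatchingDetection:
    def test_monotone_series_not_detected(self):
        assert hatching_chamber(np.linspace(10, 40, 15)) is None

    def test_synthetic_drop_at_known_chamber(self):
        # rise over chambers 2..6, drop >= 20% at chamber 7
        series = np.array([12.0, 18, 24, 30, 36, 25, 25, 26, 24, 25, 25, 25])
        assert hatching_chamber(series) == 7

    def test_drop_beyond_search_window_ignored(self):
        series = np.concatenate([np.linspace(10, 40, 12), [10.0, 10.0]])
        assert hatching_chamber(series) is None

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="10"):
            hatching_chamber([30.0, 20.0, 10.0])
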