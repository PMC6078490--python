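"""Community metrics, rank ANOVA, Monte-Carlo Dunnett and duration labels."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import dungfauna as df
from dungfauna.community import _group_by_day, _per_pat_totals


def rec(pat, day, taxon, count, order=df.DIPTERA, week=2, colonizer=False):
    return df.EmergenceRecord(pat, day, order, taxon, week, count, colonizer=colonizer)


class TestHillDiversity:
    def test_even_community_equals_richness(self):
        m = df.community_metrics(
            [rec("p", 0, t, 10) for t in ("A", "B", "C", "D")]
        )
        assert (m.abundance, m.richness) == (40, 4)
        assert m.hill_1d == pytest.approx(4.0)

    def test_single_taxon_pat(self):
        m = df.community_metrics([rec("p", 0, "A", 17)])
        assert (m.richness, m.hill_1d) == (1, pytest.approx(1.0))

    def test_worked_two_taxon_value(self):
        # counts {8, 2}: H' = -(0.8 ln 0.8 + 0.2 ln 0.2) = 0.500402,
        # so 1D = exp(H') = 1.649385 (direct evaluation of the formula)
        m = df.community_metrics([rec("p", 0, "A", 8), rec("p", 0, "B", 2)])
        assert m.hill_1d == pytest.approx(1.6493, abs=1e-4)

    def test_empty_pat_is_missing_not_error(self):
        m = df.community_metrics([rec("p", 0, "A", 0)])
        assert (m.abundance, m.richness) == (0, 0)
        assert np.isnan(m.hill_1d)

    @given(
        counts=st.lists(st.integers(min_value=1, max_value=200), min_size=1, max_size=8),
        factor=st.integers(min_value=2, max_value=50),
    )
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance_and_richness_bound(self, counts, factor):
        d1 = df.hill_diversity(counts)
        d2 = df.hill_diversity([c * factor for c in counts])
        assert d1 == pytest.approx(d2, rel=1e-12)
        assert 1.0 - 1e-9 <= d1 <= len(counts) + 1e-9
        if len(set(counts)) > 1:
            assert d1 < len(counts)


class TestRankTransform:
    @pytest.mark.parametrize(
        "values,expected",
        [([3, 1, 2], [3, 1, 2]), ([5, 5, 7], [1.5, 1.5, 3])],
    )
    def test_midrank_convention(self, values, expected):
        assert list(df.rank_transform(values)) == expected

    @given(st.lists(st.floats(-1e6, 1e6, allow_nan=False), min_size=1, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_rank_sum_identity(self, values):
        n = len(values)
        assert df.rank_transform(values).sum() == pytest.approx(n * (n + 1) / 2)


class TestAnovaOnRanks:
    def test_matches_textbook_computation_on_separated_groups(self):
        # ranks of [1,2,3 | 4,5,6] are themselves; classic one-way F by hand:
        # SSB = 2*3*(1.5)^2/... check against scipy on the ranks instead
        res = df.anova_on_ranks([np.array([1, 2, 3]), np.array([4, 5, 6])])
        f_ref, p_ref = stats.f_oneway([1.0, 2, 3], [4.0, 5, 6])
        assert res.f_statistic == pytest.approx(f_ref)
        assert res.p_value == pytest.approx(p_ref)
        assert (res.df_between, res.df_within) == (1, 4)

    def test_degenerate_constant_data(self):
        res = df.anova_on_ranks([np.array([2.0, 2.0]), np.array([2.0, 2.0])])
        assert res.f_statistic == 0.0
        assert res.p_value == 1.0

    def test_oracle_agreement_on_random_data(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            k = rng.integers(2, 6)
            groups = [rng.normal(size=rng.integers(3, 12)) for _ in range(k)]
            pooled = stats.rankdata(np.concatenate(groups))
            sizes = np.cumsum([g.size for g in groups])[:-1]
            ranked_groups = np.split(pooled, sizes)
            f_ref, p_ref = stats.f_oneway(*ranked_groups)
            res = df.anova_on_ranks(groups)
            assert res.f_statistic == pytest.approx(f_ref, rel=1e-10)
            assert res.p_value == pytest.approx(p_ref, rel=1e-10)

    def test_type_one_error_near_nominal(self):
        # 8 groups from one null distribution; rejection rate ~ alpha
        rng = np.random.default_rng(12)
        n_sims, rejections = 4000, 0
        for _ in range(n_sims):
            groups = [rng.normal(size=10) for _ in range(8)]
            rejections += df.anova_on_ranks(groups).p_value < 0.05
        assert 0.04 <= rejections / n_sims <= 0.06


class TestDunnett:
    def test_k1_matches_one_sided_pooled_t(self):
        rng = np.random.default_rng(2)
        control = rng.normal(0, 1, 12)
        treated = rng.normal(-0.8, 1, 10)
        cfg = df.AnalysisConfig(mc_draws=100_000, seed=9)
        res = df.dunnett_many_to_one(control, {7: treated}, cfg)
        p_ref = stats.ttest_ind(treated, control, alternative="less").pvalue
        mc_se = np.sqrt(p_ref * (1 - p_ref) / cfg.mc_draws)
        assert abs(res.p_adjusted[0] - p_ref) < 3 * mc_se + 1e-4

    def test_agrees_with_scipy_dunnett(self):
        rng = np.random.default_rng(3)
        control = rng.normal(0, 1, 12)
        groups = {7: rng.normal(-1, 1, 10), 14: rng.normal(-0.5, 1, 11),
                  28: rng.normal(0.2, 1, 10)}
        cfg = df.AnalysisConfig(mc_draws=200_000, seed=17)
        res = df.dunnett_many_to_one(control, groups, cfg)
        ref = stats.dunnett(*[groups[d] for d in sorted(groups)],
                            control=control, alternative="less")
        assert np.allclose(res.p_adjusted, ref.pvalue, atol=0.005)

    def test_identical_data_never_significant(self):
        vals = np.array([3.0, 4.0, 5.0, 6.0])
        cfg = df.AnalysisConfig(mc_draws=20_000, seed=1)
        res = df.dunnett_many_to_one(vals, {7: vals.copy(), 14: vals.copy()}, cfg)
        assert not any(res.significant)

    def test_large_effect_detected(self):
        rng = np.random.default_rng(8)
        control = rng.poisson(30, 10).astype(float)
        zeros = np.zeros(10)
        cfg = df.AnalysisConfig(mc_draws=50_000, seed=2)
        ranked_c = df.rank_transform(np.concatenate([control, zeros]))
        res = df.dunnett_many_to_one(
            ranked_c[:10], {7: ranked_c[10:]}, cfg,
            unranked_control=control, unranked_treatments={7: zeros},
        )
        assert res.significant[0]
        assert res.means[0] == 0.0 and res.control_mean == pytest.approx(control.mean())

    def test_adjusted_p_monotone_under_multiplicity(self):
        rng = np.random.default_rng(5)
        control = rng.normal(0, 1, 10)
        t1 = rng.normal(-0.7, 1, 10)
        cfg = df.AnalysisConfig(mc_draws=100_000, seed=21)
        single = df.dunnett_many_to_one(control, {7: t1}, cfg)
        multi = df.dunnett_many_to_one(
            control, {7: t1, 14: rng.normal(0, 1, 10), 28: rng.normal(0, 1, 10)}, cfg
        )
        assert multi.p_adjusted[0] >= single.p_adjusted[0] - 0.003

    def test_empty_treatments_rejected(self):
        with pytest.raises(df.ValidationError):
            df.dunnett_many_to_one(np.ones(5), {}, df.AnalysisConfig())

    def test_undefined_pooled_variance_rejected(self):
        with pytest.raises(df.ValidationError):
            df.dunnett_many_to_one(np.array([1.0]), {7: np.array([2.0])},
                                   df.AnalysisConfig(mc_draws=100))


class TestDurationOfEffect:
    def _result(self, flags, days=(7, 14, 28, 56, 84, 112, 140)):
        k = len(days)
        return df.DunnettResult(
            days=tuple(days), means=(0.0,) * k, ses=(0.0,) * k,
            control_mean=1.0, control_se=0.1, statistics=(0.0,) * k,
            p_adjusted=tuple(0.01 if f else 0.5 for f in flags),
            significant=tuple(flags), alpha=0.05, sidedness="less",
        )

    def test_suppressed_through_final_day(self, design):
        label = df.duration_of_effect(self._result([True] * 7), design)
        assert label.label == "≥ 140 d"

    def test_no_day_significant(self, design):
        label = df.duration_of_effect(self._result([False] * 7), design)
        assert label.label == "no effect"

    def test_bounded_interval(self, design):
        flags = [True, True, True, True, True, True, False]
        label = df.duration_of_effect(self._result(flags), design)
        assert label.label == "112–140 d"

    def test_noncontiguous_uses_last_significant_day(self, design):
        flags = [True, False, True, False, False, False, False]
        label = df.duration_of_effect(self._result(flags), design)
        assert label.label == "28–56 d"


class TestColonizerBalance:
    def test_identical_counts_give_p_one(self, design):
        records = []
        for day in design.sampling_days:
            for p in range(3):
                records.append(rec(f"d{day}p{p}", day, "Hydrophilidae", 2,
                                   order=df.COLEOPTERA, week=1, colonizer=True))
        res = df.colonizer_balance_check(records)
        assert res.p_value == 1.0

    def test_no_colonizers_is_an_error(self):
        with pytest.raises(df.ValidationError):
            df.colonizer_balance_check([rec("p", 0, "A", 1)])

    def test_type_one_error_and_power(self, design):
        # counts independent of day -> rarely significant;
        # strong day effect -> almost always significant
        rng = np.random.default_rng(6)
        null_sig = effect_sig = 0
        n_runs = 200
        for _ in range(n_runs):
            null_records, effect_records = [], []
            for j, day in enumerate(design.sampling_days):
                for p in range(10):
                    null_records.append(
                        rec(f"d{day}p{p}", day, "H", int(rng.poisson(3)),
                            order=df.COLEOPTERA, week=1, colonizer=True))
                    effect_records.append(
                        rec(f"d{day}p{p}", day, "H", int(rng.poisson(1 + 3 * j)),
                            order=df.COLEOPTERA, week=1, colonizer=True))
            null_sig += df.colonizer_balance_check(null_records).p_value < 0.05
            effect_sig += df.colonizer_balance_check(effect_records).p_value < 0.05
        assert null_sig / n_runs <= 0.10
        assert effect_sig / n_runs >= 0.90


class TestPipelineHelpers:
    def test_roster_keeps_absent_taxa_as_zero(self):
        records = [rec("p1", 0, "A", 4), rec("p2", 0, "B", 2),
                   rec("p3", 7, "A", 1)]
        totals = _per_pat_totals([r for r in records])
        assert totals[("p2", 0)] == 2
        by_day = _group_by_day(totals)
        assert sorted(by_day[0]) == [2, 4]

    def test_community_metrics_table_excludes_colonizers(self):
        records = [
            rec("p1", 0, "A", 4),
            rec("p1", 0, "H", 10, order=df.COLEOPTERA, week=1, colonizer=True),
        ]
        table = df.community_metrics_table(records)
        assert table.loc[0, "abundance"] == 4
        assert table.loc[0, "richness"] == 1

    def test_normality_diagnostic_flags_skew_but_changes_nothing(self, design):
        rng = np.random.default_rng(14)
        skewed = {0: rng.exponential(1, 40) ** 3, 7: rng.normal(size=40),
                  14: np.ones(5), 28: np.arange(2.0)}
        ps = df.normality_diagnostic(skewed)
        assert ps[0] < 0.05  # strongly non-normal group detected
        assert ps[7] > 0.05
        assert np.isnan(ps[14]) and np.isnan(ps[28])  # constant / too small

    def test_omnibus_gate_skips_post_hoc(self, design):
        rng = np.random.default_rng(9)
        by_day = {d: rng.normal(size=10) for d in design.sampling_days}
        cfg = df.AnalysisConfig(alpha=1e-6, mc_draws=1000, seed=0)
        res = df.many_to_one_analysis(by_day, cfg, design)
        assert res["dunnett"] is None
        assert res["duration"].label == "no effect"
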