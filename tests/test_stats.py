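import warnings

import numpy as np
import pytest
from scipy import stats as sps

from mwlkit import (
    AlignmentError,
    DegenerateDataError,
    FusionWeights,
    IndexSeries,
    ParameterError,
    align_series,
    correlation_table,
    fuse_series,
    make_phase_schedule,
    minmax_normalize,
    oneway_anova,
    pearson_cc,
    tukey_hsd,
    zscore_phase_means,
)


def series(values, step=5.0, t0=0.0, label="x", flagged=None):
    values = np.asarray(values, dtype=float)
    t = t0 + np.arange(values.size) * step
    return IndexSeries(t, values, step, label, flagged)


class TestMinMaxNormalize:
    def test_linear_rescaling(self):
        out = minmax_normalize(series([2, 4, 6]))
        assert np.allclose(out.values, [0, 0.5, 1])

    def test_idempotent_on_unit_range(self):
        out = minmax_normalize(series([0, 0.25, 1]))
        assert np.allclose(out.values, [0, 0.25, 1])

    def test_flagged_points_excluded_from_range(self):
        s = series([2, 4, 100], flagged=[False, False, True])
        out = minmax_normalize(s)
        assert np.allclose(out.values[:2], [0, 1])
        assert out.flagged[2]

    def test_constant_series_rejected(self):
        with pytest.raises(DegenerateDataError):
            minmax_normalize(series([3, 3, 3]))


class TestAlignSeries:
    def test_identical_grids_pass_through(self):
        a = series([1, 2, 3, 4])
        b = series([5, 6, 7, 8], label="y")
        aa, bb = align_series(a, b)
        assert np.array_equal(aa.values, a.values)
        assert np.array_equal(bb.values, b.values)

    def test_coarse_bins_expand_by_locf(self):
        a = series(np.arange(48), step=5.0)  # 240 s at 5 s
        b = series([10.0, 20.0], step=120.0, label="clicks")
        aa, bb = align_series(a, b)
        assert len(bb) == 48
        assert np.all(bb.values[:24] == 10.0)
        assert np.all(bb.values[24:] == 20.0)

    def test_flagged_stamps_dropped_pairwise(self):
        a = series([1, 2, 3, 4], flagged=[False, True, False, False])
        b = series([4, 3, 2, 1], label="y")
        aa, bb = align_series(a, b)
        assert len(aa) == len(bb) == 3
        assert 5.0 not in aa.t_s

    def test_disjoint_spans_rejected(self):
        a = series([1, 2, 3], t0=0.0)
        b = series([1, 2, 3], t0=1000.0)
        with pytest.raises(AlignmentError):
            align_series(a, b)


class TestFuseSeries:
    def test_degenerate_weight_returns_first_input(self):
        a, b = series([0.0, 1.0]), series([1.0, 0.0])
        out = fuse_series(a, b, FusionWeights(1.0, 0.0))
        assert np.allclose(out.values, a.values)

    @pytest.mark.parametrize(
        "w,expected",
        [((0.5, 0.5), [0.5, 0.5]), ((0.7, 0.3), [0.7, 0.3]), ((0.3, 0.7), [0.3, 0.7])],
    )
    def test_weighted_sum(self, w, expected):
        a, b = series([1.0, 0.0]), series([0.0, 1.0])
        out = fuse_series(a, b, FusionWeights(*w))
        assert np.allclose(out.values, expected)

    def test_convex_fusion_stays_in_unit_interval(self, rng):
        a = series(rng.random(50))
        b = series(rng.random(50))
        out = fuse_series(a, b, FusionWeights(0.3, 0.7))
        assert np.all((out.values >= 0) & (out.values <= 1))

    def test_unaligned_inputs_rejected(self):
        a, b = series([1.0, 0.0]), series([0.0, 1.0], t0=2.5)
        with pytest.raises(AlignmentError):
            fuse_series(a, b, FusionWeights(0.5, 0.5))

    def test_invalid_weights_rejected(self):
        with pytest.raises(ParameterError):
            FusionWeights(0.7, 0.7)


class TestPearsonCC:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        assert pearson_cc(x, x) == pytest.approx(1.0)
        assert pearson_cc(x, -x) == pytest.approx(-1.0)

    def test_known_value_from_formula(self):
        assert pearson_cc([1, 2, 3], [1, 2, 4]) == pytest.approx(0.9820, abs=1e-4)

    def test_matches_scipy_on_random_inputs(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 40))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            assert pearson_cc(x, y) == pytest.approx(
                sps.pearsonr(x, y).statistic, abs=1e-10
            )

    def test_affine_invariance_and_antisymmetry(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        cc = pearson_cc(x, y)
        assert pearson_cc(3.0 * x + 7.0, y) == pytest.approx(cc, abs=1e-12)
        assert pearson_cc(-x, y) == pytest.approx(-cc, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ParameterError):
            pearson_cc([1, 2], [1, 2])
        with pytest.raises(DegenerateDataError):
            pearson_cc([1, 1, 1], [1, 2, 3])


class TestZScorePhaseMeans:
    def test_unit_spaced_means_map_to_unit_z(self):
        sched = make_phase_schedule((10, 10, 10, 10, 10))
        vals = np.concatenate([np.full(2, v) for v in [5.0, 1.0, 2.0, 3.0, 5.0]])
        s = IndexSeries(np.arange(10) * 5.0, vals, 5.0)
        summ = zscore_phase_means(s, sched, ("Phase1", "Phase2", "Phase3"))
        assert np.allclose(summ.raw_means, [1, 2, 3])
        assert np.allclose(summ.z_means, [-1, 0, 1])

    def test_full_session_z_scores_standardized(self):
        sched = make_phase_schedule((10, 10, 10, 10, 10))
        rng = np.random.default_rng(5)
        s = IndexSeries(np.arange(10) * 5.0, rng.normal(size=10), 5.0)
        summ = zscore_phase_means(s, sched)
        assert summ.z_means.mean() == pytest.approx(0.0, abs=1e-12)
        assert summ.z_means.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_equal_means_yield_zeros_with_warning(self):
        sched = make_phase_schedule((10, 10, 10, 10, 10))
        s = IndexSeries(np.arange(10) * 5.0, np.ones(10), 5.0)
        with pytest.warns(UserWarning):
            summ = zscore_phase_means(s, sched)
        assert np.allclose(summ.z_means, 0.0)

    def test_phase_without_valid_points_rejected(self):
        sched = make_phase_schedule((10, 10, 10, 10, 10))
        flags = np.zeros(10, dtype=bool)
        flags[2:4] = True  # all of Phase1 flagged
        s = IndexSeries(np.arange(10) * 5.0, np.ones(10), 5.0, flagged=flags)
        with pytest.raises(DegenerateDataError):
            zscore_phase_means(s, sched)


class TestOneWayAnova:
    def test_hand_computed_sum_of_squares(self):
        groups = [[1, 2, 3], [2, 3, 4], [3, 4, 5]]
        res = oneway_anova(groups)
        # oracle: SSB = 6, SSW = 6, df (2, 6) -> F = 3
        assert res.F == pytest.approx(3.0, abs=1e-12)
        assert (res.df_between, res.df_within) == (2, 6)
        assert np.allclose(res.group_means, [2, 3, 4])

    def test_equal_means_give_zero_f(self):
        res = oneway_anova([[1, 2, 3], [3, 2, 1], [2, 2, 2]])
        assert res.F == pytest.approx(0.0, abs=1e-12)

    def test_shift_invariance(self, rng):
        groups = [rng.normal(size=6) for _ in range(3)]
        f0 = oneway_anova(groups).F
        f1 = oneway_anova([g + 100.0 for g in groups]).F
        assert f1 == pytest.approx(f0, rel=1e-9)

    def test_matches_scipy_on_random_groups(self, rng):
        for _ in range(100):
            k = int(rng.integers(2, 5))
            groups = [rng.normal(size=int(rng.integers(2, 10))) for _ in range(k)]
            res = oneway_anova(groups)
            ref = sps.f_oneway(*groups)
            assert res.F == pytest.approx(ref.statistic, abs=1e-10)
            assert res.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_no_within_variance_rejected(self):
        with pytest.raises(DegenerateDataError):
            oneway_anova([[1, 1], [2, 2]])


class TestTukeyHSD:
    def test_widely_separated_groups_all_significant(self, rng):
        groups = [rng.normal(m, 0.1, size=5) for m in (0.0, 10.0, 20.0)]
        res = tukey_hsd(groups)
        assert len(res.significant_pairs()) == 3

    def test_identical_groups_not_significant(self, rng):
        g = rng.normal(size=8)
        res = tukey_hsd([g, g + 1e-6, g - 1e-6])
        assert res.significant_pairs() == []

    def test_small_overlapping_groups_not_significant(self):
        res = tukey_hsd([[1, 2, 3], [2, 3, 4], [3, 4, 5]])
        assert res.significant_pairs() == []

    def test_decisions_match_scipy(self, rng):
        for _ in range(50):
            k = int(rng.integers(3, 5))
            n = int(rng.integers(4, 8))
            groups = [rng.normal(rng.uniform(-2, 2), 1.0, size=n) for _ in range(k)]
            mine = tukey_hsd(groups)
            ref = sps.tukey_hsd(*groups)
            for c in mine.comparisons:
                assert c.p_adj == pytest.approx(
                    ref.pvalue[c.group_a, c.group_b], abs=1e-8
                )


class TestCorrelationTable:
    def test_cross_participant_mean_and_sample_sd(self):
        # construct two participants whose (x, y) correlations are 0.6, 0.8
        def pair_with_cc(rho, rng):
            z1 = rng.normal(size=4000)
            z2 = rng.normal(size=4000)
            return z1, rho * z1 + np.sqrt(1 - rho**2) * z2

        summaries = correlation_table(
            {
                "p1": dict(zip("xy", pair_with_cc(0.6, np.random.default_rng(1)))),
                "p2": dict(zip("xy", pair_with_cc(0.8, np.random.default_rng(2)))),
            }
        )
        s = summaries[0]
        ccs = np.array(list(s.per_participant.values()))
        assert s.mean == pytest.approx(ccs.mean())
        assert s.sd == pytest.approx(ccs.std(ddof=1))
        # sample-SD convention: for exact CCs .6/.8 this would be 0.1414
        assert np.std([0.6, 0.8], ddof=1) == pytest.approx(0.1414, abs=1e-4)

    def test_feature_against_itself_is_one(self, rng):
        x = rng.normal(size=100)
        out = correlation_table({"p1": {"a": x, "b": x}})
        assert out[0].per_participant["p1"] == pytest.approx(1.0)

    def test_single_participant_sd_undefined(self, rng):
        out = correlation_table({"p1": {"a": rng.normal(size=50), "b": rng.normal(size=50)}})
        assert np.isnan(out[0].sd)

    def test_missing_feature_omitted_with_warning(self, rng):
        feats = {
            "p1": {"a": rng.normal(size=50), "b": rng.normal(size=50)},
            "p2": {"a": rng.normal(size=50)},
        }
        with pytest.warns(UserWarning, match="p2"):
            out = correlation_table(feats)
        assert list(out[0].per_participant) == ["p1"]
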