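"""Behavioral statistics: normalization, peak fits, cohort summaries, ANOVA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import timingnet as tn
from timingnet.behavior import (
    BehavioralCurve,
    PeakStats,
    cohort_summary,
    double_sigmoid,
    fit_peak_function,
    normalize_curve,
    pivot_measure,
    posthoc_pairwise,
    rm_anova,
)


def curve_from_family(n_pre=20, n_stim=80, **params):
    tau = np.arange(n_stim) + 0.5
    y = double_sigmoid(tau, **params)
    base = params.get("baseline", 0.0)
    return BehavioralCurve(np.concatenate([np.full(n_pre, base), y]))


class TestNormalize:
    def test_max_becomes_one(self):
        c = BehavioralCurve(np.linspace(0, 2.0, 100))
        out = normalize_curve(c)
        assert out.rate.max() == pytest.approx(1.0) and out.normalized

    def test_idempotent(self):
        c = normalize_curve(BehavioralCurve(np.linspace(0, 2.0, 100)))
        again = normalize_curve(c)
        np.testing.assert_array_equal(c.rate, again.rate)

    def test_constant_curve_all_ones(self):
        out = normalize_curve(BehavioralCurve(np.full(100, 0.37)))
        assert np.all(out.rate == 1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            normalize_curve(BehavioralCurve(np.zeros(100)))


class TestPeakFunctionFit:
    def test_round_trip_parameter_recovery(self):
        """Noiseless symmetric member of the model family is recovered."""
        true = dict(amplitude=1.0, center=30.0, width=20.0,
                    s_rise=3.0, s_fall=3.0, baseline=0.05)
        fit = fit_peak_function(curve_from_family(**true))
        assert fit.valid and fit.r_squared > 0.999
        for k, v in true.items():
            assert fit.params[k] == pytest.approx(v, abs=1e-4), k

    def test_flat_curve_flagged_invalid(self):
        fit = fit_peak_function(BehavioralCurve(np.full(100, 0.5)))
        assert not fit.valid
        with pytest.raises(ValueError):
            fit.peak_stats()

    def test_known_argmax_recovered(self):
        """Noiseless asymmetric curve with argmax 30 on the dense grid."""
        true = dict(amplitude=1.0, center=31.0, width=22.0,
                    s_rise=2.0, s_fall=6.0, baseline=0.02)
        tau = np.arange(0, 80, 0.001)
        argmax_true = tau[np.argmax(double_sigmoid(tau, **true))]
        fit = fit_peak_function(curve_from_family(**true))
        assert fit.peak_stats().peak_time == pytest.approx(argmax_true, abs=0.1)

    def test_width_matches_half_crossing_geometry(self):
        true = dict(amplitude=1.0, center=30.0, width=20.0,
                    s_rise=3.0, s_fall=3.0, baseline=0.0)
        fit = fit_peak_function(curve_from_family(**true))
        t, f = fit.grid()
        half = f.max() / 2
        above = t[f >= half]
        expected = above[-1] - above[0]
        assert fit.peak_stats().width50 == pytest.approx(expected, abs=0.05)

    def test_right_edge_clamped_when_no_crossing(self):
        # very wide fall: function never drops to half peak before 80 s
        true = dict(amplitude=1.0, center=60.0, width=80.0,
                    s_rise=4.0, s_fall=20.0, baseline=0.0)
        fit = fit_peak_function(curve_from_family(**true), r2_threshold=0.3)
        if fit.valid:
            ps = fit.peak_stats()
            t, f = fit.grid()
            assert ps.width50 <= 80.0

    def test_scale_invariance_of_peak_stats(self):
        true = dict(amplitude=0.8, center=25.0, width=15.0,
                    s_rise=2.0, s_fall=4.0, baseline=0.03)
        a = fit_peak_function(curve_from_family(**true)).peak_stats()
        scaled = curve_from_family(**{**true, "amplitude": 4.0, "baseline": 0.15})
        b = fit_peak_function(scaled).peak_stats()
        assert a.peak_time == pytest.approx(b.peak_time, abs=0.05)
        assert a.width50 == pytest.approx(b.width50, abs=0.2)


class TestPeakStats:
    def test_printed_per_rat_values_reproduce_ratio_and_cv(self):
        """Tone rat 1: PT 5.93, W-50 10.38 -> ratio ~0.5711 (printed) and
        flash rat 1 -> CV 2.308."""
        tone1 = PeakStats(peak_time=5.93, width50=10.38)
        assert tone1.ratio == pytest.approx(0.5711, abs=3e-4)
        flash1 = PeakStats(peak_time=21.75, width50=50.19)
        assert flash1.cv == pytest.approx(2.308, abs=1e-3)

    @given(pt=st.floats(0.5, 70), w=st.floats(0.5, 80))
    def test_ratio_times_cv_is_one(self, pt, w):
        ps = PeakStats(pt, w)
        assert ps.ratio * ps.cv == pytest.approx(1.0, abs=1e-12)

    def test_positivity_enforced(self):
        with pytest.raises(ValueError):
            PeakStats(0.0, 5.0)


class TestCohortTable:
    def test_reference_averages_reproduced(self, peak_table):
        """Cohort means recomputed from the transcribed per-rat values match
        every printed average to +/-0.01."""
        s = cohort_summary(peak_table)
        expected_pt = {"tone": 4.72, "flash": 26.14, "compound": 16.21}
        expected_w = {"tone": 9.13, "flash": 40.60, "compound": 35.90}
        expected_cv = {"tone": 1.95, "flash": 1.57, "compound": 2.26}
        for t in expected_pt:
            assert s.loc[t, ("mean", "peak_time")] == pytest.approx(
                expected_pt[t], abs=0.01)
            assert s.loc[t, ("mean", "width50")] == pytest.approx(
                expected_w[t], abs=0.01)
            assert s.loc[t, ("mean", "cv")] == pytest.approx(
                expected_cv[t], abs=0.01)

    def test_listwise_exclusion_of_incomplete_rat(self, peak_table):
        wide = pivot_measure(peak_table, "peak_time")
        assert wide.shape == (15, 3)  # 16 rats, one lacks flash/compound fits
        assert 5 not in wide.index

    def test_summary_needs_two_complete_rats(self, peak_table):
        tiny = peak_table[peak_table.rat_id == 1]
        with pytest.raises(ValueError):
            cohort_summary(tiny)


class TestRmAnova:
    def test_hand_computed_sums_of_squares(self):
        """3x3 matrix against an explicit SS decomposition done longhand."""
        m = np.array([[1.0, 2.0, 4.0], [2.0, 3.0, 3.0], [0.0, 2.0, 5.0]])
        # longhand oracle with explicit loops
        n, k = m.shape
        grand = m.sum() / m.size
        ss_cond = sum(n * (m[:, j].mean() - grand) ** 2 for j in range(k))
        ss_subj = sum(k * (m[i, :].mean() - grand) ** 2 for i in range(n))
        ss_err = sum(
            (m[i, j] - m[i, :].mean() - m[:, j].mean() + grand) ** 2
            for i in range(n) for j in range(k)
        )
        f_oracle = (ss_cond / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))
        res = rm_anova(m)
        assert res.F == pytest.approx(f_oracle, rel=1e-12)
        assert (res.df1, res.df2) == (2, 4)

    def test_reference_peak_times_give_published_df(self, peak_table):
        res = rm_anova(pivot_measure(peak_table, "peak_time"))
        assert (res.df1, res.df2) == (2, 28)

    def test_identical_conditions_give_zero_f(self):
        col = np.array([1.0, 2.0, 3.0, 2.5])
        res = rm_anova(np.column_stack([col, col, col]))
        assert res.F == 0.0

    def test_invariant_to_per_subject_constants(self, peak_table):
        wide = pivot_measure(peak_table, "peak_time").to_numpy()
        shifted = wide + np.arange(wide.shape[0])[:, None] * 3.7
        assert rm_anova(shifted).F == pytest.approx(rm_anova(wide).F, abs=1e-9)

    def test_agrees_with_pingouin(self, peak_table):
        pingouin = pytest.importorskip("pingouin")
        wide = pivot_measure(peak_table, "peak_time")
        long = wide.reset_index().melt(id_vars="rat_id", value_name="pt")
        aov = pingouin.rm_anova(data=long, dv="pt", within="trial_type",
                                subject="rat_id")
        assert rm_anova(wide).F == pytest.approx(float(aov["F"][0]), rel=1e-9)

    def test_missing_cells_rejected(self):
        m = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError):
            rm_anova(m)


class TestPosthoc:
    def test_peak_time_ordering(self, peak_table):
        res = posthoc_pairwise(pivot_measure(peak_table, "peak_time"))
        assert res.ordering == ["flash", "compound", "tone"]
        assert res.all_significant

    def test_cv_ordering(self, peak_table):
        res = posthoc_pairwise(pivot_measure(peak_table, "cv"))
        assert res.ordering == ["compound", "tone", "flash"]
        # Bonferroni-paired-t leaves only the widest CV gap significant
        sig = res.table.set_index(["a", "b"])["significant"]
        assert sig[("flash", "compound")]

    def test_identical_columns_nothing_significant(self):
        col = np.array([1.0, 2.0, 3.0, 2.0, 1.5])
        res = posthoc_pairwise(np.column_stack([col, col, col]))
        assert not res.table["significant"].any()
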