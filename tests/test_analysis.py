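"""Log-scale summaries, AUC windows, thresholds and significance tests."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from drainknee.analysis import (
    ThresholdBand,
    auc_table,
    combined_concentration,
    exposure_summary,
    log_difference,
    students_t,
    summarize_log,
    time_above_threshold,
    trapezoid_auc,
    ttest_table,
)
from drainknee.depots import TOBRAMYCIN, VANCOMYCIN
from drainknee.flow import CLINICAL_SAMPLING_TIMES_H


def make_dataset(records):
    return pd.DataFrame(records, columns=["arm", "replicate", "time_h", "antibiotic",
                                          "conc_ug_ml", "censored"])


class TestSummarizeLog:
    def test_geometric_mean_of_1_and_100_is_10(self):
        ds = make_dataset([
            ("a", 1, 1.0, VANCOMYCIN, 1.0, 0),
            ("a", 2, 1.0, VANCOMYCIN, 100.0, 0),
        ])
        out = summarize_log(ds)
        assert out["log10_mean"].iloc[0] == pytest.approx(1.0)

    def test_all_censored_group_reports_minus_point_01(self):
        ds = make_dataset([
            ("a", r, 2.0, VANCOMYCIN, 0.98, 1) for r in (1, 2, 3)
        ])
        out = summarize_log(ds)
        assert round(out["log10_mean"].iloc[0], 2) == -0.01
        assert out["log10_se"].iloc[0] == 0.0

    def test_single_replicate_flagged_with_zero_se(self):
        ds = make_dataset([("a", 1, 1.0, VANCOMYCIN, 10.0, 0)])
        out = summarize_log(ds)
        assert out["n"].iloc[0] == 1
        assert not out["se_estimable"].iloc[0]
        assert out["log10_se"].iloc[0] == 0.0

    def test_values_below_lod_are_floored_before_logging(self):
        ds = make_dataset([("a", 1, 1.0, VANCOMYCIN, 0.0, 1)])
        out = summarize_log(ds)
        assert out["log10_mean"].iloc[0] == pytest.approx(np.log10(0.98))


class TestTrapezoidAuc:
    def test_constant_series_gives_rectangle_from_first_sample(self):
        t = np.asarray(CLINICAL_SAMPLING_TIMES_H)
        v = np.full(t.size, 10.0)
        assert trapezoid_auc(t, v, 2.0) == pytest.approx(10.0 * (2.0 - 5.0 / 60.0))

    def test_windows_are_monotone_in_length(self):
        rng = np.random.default_rng(1)
        t = np.asarray(CLINICAL_SAMPLING_TIMES_H)
        v = rng.uniform(0, 50, t.size)
        aucs = [trapezoid_auc(t, v, w) for w in (2.0, 12.0, 24.0, 48.0)]
        assert np.all(np.diff(aucs) >= 0)

    def test_additive_over_adjacent_windows(self):
        t = np.asarray(CLINICAL_SAMPLING_TIMES_H)
        v = np.linspace(5.0, 80.0, t.size)
        full = trapezoid_auc(t, v, 12.0)
        first = trapezoid_auc(t, v, 2.0)
        inner = t[(t >= 2.0) & (t <= 12.0)]
        tail = np.trapezoid(np.interp(inner, t, v), inner)
        assert full == pytest.approx(first + tail)

    def test_window_beyond_last_sample_rejected(self):
        with pytest.raises(ValueError):
            trapezoid_auc([0.1, 1.0], [1.0, 1.0], 2.0)

    def test_agrees_with_fine_quadrature_for_smooth_arms(self, arm_results, sampling_times):
        # sampling-grid trapezoid vs dense-grid integral of the simulated curve
        for arm in ("spacer_only", "csb_plus_spacer"):
            series = arm_results[arm].series
            sampled = series.interp(VANCOMYCIN, sampling_times)
            for w in (2.0, 12.0, 24.0, 48.0):
                coarse = trapezoid_auc(sampling_times, sampled, w)
                grid = series.times_h
                mask = (grid >= sampling_times[0]) & (grid <= w)
                fine = np.trapezoid(series.concentrations_ug_ml[VANCOMYCIN][mask], grid[mask])
                assert coarse == pytest.approx(fine, rel=0.10)


@given(st.data())
@settings(max_examples=40, deadline=None)
def test_auc_monotone_for_any_nonnegative_series(data):
    t = np.asarray(CLINICAL_SAMPLING_TIMES_H)
    v = np.array(data.draw(st.lists(
        st.floats(min_value=0.0, max_value=1e4), min_size=t.size, max_size=t.size)))
    aucs = [trapezoid_auc(t, v, w) for w in (2.0, 12.0, 24.0, 48.0)]
    assert aucs[0] >= 0
    assert np.all(np.diff(aucs) >= -1e-9)


class TestLogDifference:
    def _summary(self, arm, scale):
        ds = make_dataset([
            (arm, r, t, VANCOMYCIN, scale * (10 + t), 0)
            for r in (1, 2) for t in (1.0, 2.0)
        ])
        return summarize_log(ds)

    def test_identical_arms_give_zero(self):
        a = self._summary("a", 1.0)
        b = self._summary("b", 1.0)
        out = log_difference(a, b)
        assert np.allclose(out["log10_difference"], 0.0)

    def test_hundredfold_ratio_gives_two(self):
        out = log_difference(self._summary("a", 100.0), self._summary("b", 1.0))
        assert np.allclose(out["log10_difference"], 2.0)

    def test_invariant_to_common_rescaling(self):
        d1 = log_difference(self._summary("a", 5.0), self._summary("b", 1.0))
        d2 = log_difference(self._summary("a", 50.0), self._summary("b", 10.0))
        assert np.allclose(d1["log10_difference"], d2["log10_difference"])

    def test_grid_mismatch_rejected(self):
        a = self._summary("a", 1.0)
        b = self._summary("b", 1.0).iloc[:1]
        with pytest.raises(ValueError):
            log_difference(a, b)

    def test_combined_arm_never_below_spacer_alone(self, noise_free_dataset):
        summary = summarize_log(noise_free_dataset)
        diff = log_difference(
            summary[summary["arm"] == "csb_plus_spacer"],
            summary[summary["arm"] == "spacer_only"],
        )
        van = diff[diff["antibiotic"] == VANCOMYCIN]
        assert np.all(van["log10_difference"].to_numpy() >= -1e-9)


class TestTimeAboveThreshold:
    band = ThresholdBand(100.0, 750.0, 24.0)

    def test_constant_above_band_satisfies(self):
        t = np.linspace(5 / 60, 48.0, 50)
        hours, ok = time_above_threshold(t, np.full(t.size, 200.0), self.band)
        assert ok
        assert hours == pytest.approx(t[-1] - t[0])

    def test_constant_below_band_fails(self):
        t = np.linspace(5 / 60, 48.0, 50)
        hours, ok = time_above_threshold(t, np.full(t.size, 50.0), self.band)
        assert hours == 0.0 and not ok

    def test_bolus_crossing_matches_closed_form(self):
        # exponential washout at constant flow crosses `low` at V ln(C0/low) / Q
        V, Q, C0 = 75.0, 3.5 * 60.0, 13333.33
        t = np.linspace(0.0, 48.0, 20000)
        c = C0 * np.exp(-Q * t / V)
        t_star = V / Q * np.log(C0 / 100.0)
        hours, ok = time_above_threshold(t, c, self.band)
        assert hours == pytest.approx(t_star, rel=1e-3)
        assert not ok

    def test_series_not_reaching_requirement_cannot_satisfy(self):
        t = np.linspace(5 / 60, 12.0, 20)
        _, ok = time_above_threshold(t, np.full(t.size, 500.0), self.band)
        assert not ok

    def test_band_validation(self):
        with pytest.raises(ValueError):
            ThresholdBand(750.0, 100.0, 24.0)


class TestStudentsT:
    def test_identical_groups_t_zero_p_one(self):
        t, p = students_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_matches_pooled_variance_formula(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.0, 0.1, 3)
        b = rng.normal(1.0, 0.1, 3)
        t, p = students_t(a, b)
        na, nb = len(a), len(b)
        sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
        t_manual = (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / na + 1 / nb))
        p_manual = 2 * stats.t.sf(abs(t_manual), na + nb - 2)
        assert t == pytest.approx(t_manual, abs=1e-10)
        assert p == pytest.approx(p_manual, abs=1e-10)

    def test_swapping_groups_negates_t_keeps_p(self):
        a, b = [0.1, 0.3, 0.2], [0.6, 0.8, 0.9]
        t1, p1 = students_t(a, b)
        t2, p2 = students_t(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_degenerate_and_undersized_inputs(self):
        with pytest.raises(ValueError):
            students_t([1.0, 1.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            students_t([1.0], [1.0, 2.0])

    def test_type_i_error_at_nominal_level_under_null(self):
        """Equal lognormal arms: the rejection rate should sit near 5%."""
        rng = np.random.default_rng(2024)
        n_sim, n = 1000, 3
        a = rng.normal(1.0, 0.15, size=(n_sim, n))
        b = rng.normal(1.0, 0.15, size=(n_sim, n))
        _, p = stats.ttest_ind(a, b, axis=1, equal_var=True)
        frac = np.mean(p < 0.05)
        assert 0.03 <= frac <= 0.08


class TestDatasetLevelTables:
    def test_auc_table_covers_all_groups(self, default_dataset):
        table = auc_table(default_dataset)
        vp = table[table["arm"] == "vp_bolus"]
        assert set(vp["antibiotic"]) == {VANCOMYCIN}
        assert set(table["window_h"]) == {2.0, 12.0, 24.0, 48.0}
        assert (table["auc_ug_h_ml"] >= 0).all()

    def test_ttest_table_and_holm_flag(self, default_dataset):
        plain = ttest_table(default_dataset, "csb_plus_spacer", "spacer_only")
        assert not plain.attrs["multiplicity_adjusted"]
        assert "p_holm" not in plain.columns
        holm = ttest_table(default_dataset, "csb_plus_spacer", "spacer_only", holm=True)
        assert holm.attrs["multiplicity_adjusted"]
        ok = holm["p_value"].notna()
        assert (holm.loc[ok, "p_holm"] >= holm.loc[ok, "p_value"] - 1e-12).all()

    def test_combined_concentration_sums_agents(self):
        ds = make_dataset([
            ("a", 1, 1.0, VANCOMYCIN, 30.0, 0),
            ("a", 1, 1.0, TOBRAMYCIN, 12.0, 0),
        ])
        out = combined_concentration(ds)
        assert out["combined_ug_ml"].iloc[0] == 42.0

    def test_exposure_summary_bundle(self, default_dataset):
        summary = exposure_summary(default_dataset)
        assert summary.log_diff is not None
        assert summary.tests is not None
        assert set(summary.threshold["arm"]) == set(default_dataset["arm"])
        text = summary.report()
        assert "Geometric-mean AUC" in text
        # only the combined arm sustains the eradication band for 24 h
        sat = summary.threshold.groupby("arm")["satisfied"].all()
        assert sat["csb_plus_spacer"]
        assert not sat["vp_bolus"]
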