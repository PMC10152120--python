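"""Cohort-level STP-vs-MTP comparison: PDs, Bland–Altman, coverage,
window coverage, and inter-cycle half-life change."""

import math

import numpy as np
import pandas as pd
import pytest

from stpdosim.compare import (
    bland_altman_summary,
    bland_altman_table,
    compare_cohort,
    coverage_table,
    half_life_change_stats,
    percent_difference,
    records_to_frame,
    window_coverage_table,
)
from stpdosim.errors import (
    DomainError,
    InsufficientDataError,
    ValidationError,
)
from stpdosim.stp import stp_h_relative_error
from stpdosim.tac import MTP_REF, STP_H, STP_PRIOR, TiaEstimate

from conftest import exact_curve


def est(value, method=STP_H, t=48.0, voi=None):
    return TiaEstimate(value, method, None if method == MTP_REF else t, voi)


class TestPercentDifference:
    @pytest.mark.parametrize(
        "stp,ref,expected,tol",
        [(110.0, 100.0, 10.0, 1e-12), (100.0, 100.0, 0.0, 1e-12),
         (6924.9, 4688.8, 47.69, 0.05)],
    )
    def test_arithmetic(self, stp, ref, expected, tol):
        pd_ = percent_difference(est(stp), est(ref, MTP_REF))
        assert pd_ == pytest.approx(expected, abs=tol)

    def test_identity_checks(self):
        with pytest.raises(ValidationError):
            percent_difference(est(1.0), est(1.0, STP_H))  # ref not MTP
        with pytest.raises(DomainError):
            percent_difference(est(1.0), est(0.0, MTP_REF))
        a = est(1.0, STP_H, voi=("P1", 2, "v1"))
        b = est(1.0, MTP_REF, voi=("P1", 2, "v2"))
        with pytest.raises(ValidationError):
            percent_difference(a, b)


class TestCompareCohort:
    def test_noiseless_single_voi_composition(self):
        """One VOI, same kinetics both cycles: STP_prior PDs are 0 and
        STP_H PDs equal 100*err(t/T) at every nominal time."""
        curves = [
            exact_curve(cycle=1, times=(24.0, 48.0, 72.0)),
            exact_curve(cycle=2, times=(24.0, 48.0, 72.0)),
        ]
        records = compare_cohort(curves)
        assert len(records) == 6
        for r in records:
            if r.method == STP_PRIOR:
                assert r.pd_percent == pytest.approx(0.0, abs=1e-9)
            else:
                expected = 100.0 * stp_h_relative_error(r.time_used_h / 32.5)
                assert r.pd_percent == pytest.approx(expected, abs=1e-9)

    def test_empty_dataset(self):
        assert compare_cohort([]) == []

    def test_record_counting(self):
        """2 patients x 2 kidneys x 3 times x 2 methods = 24 records."""
        curves = []
        for pid in ("P1", "P2"):
            for voi, vtype in (("kidney_left", "kidney_left"),
                               ("kidney_right", "kidney_right")):
                for cycle in (1, 2):
                    curves.append(
                        exact_curve(patient=pid, cycle=cycle, voi_id=voi,
                                    voi_type=vtype)
                    )
        assert len(compare_cohort(curves)) == 24

    def test_missing_prior_cycle_degrades_to_hanscheid(self, caplog):
        curves = [exact_curve(cycle=2)]
        with caplog.at_level("WARNING", logger="stpdosim"):
            records = compare_cohort(curves)
        assert {r.method for r in records} == {STP_H}
        assert any("STP_prior skipped" in m for m in caplog.messages)

    def test_time_tolerance_skips_missing_nominal(self, caplog):
        curves = [exact_curve(cycle=1, times=(24.0, 48.0)),
                  exact_curve(cycle=2, times=(24.0, 48.0))]
        with caplog.at_level("WARNING", logger="stpdosim"):
            records = compare_cohort(curves, stp_times=(24.0, 48.0, 72.0),
                                     time_tolerance_h=6.0)
        times = {r.nominal_time_h for r in records}
        assert times == {24.0, 48.0}
        assert any("no sample within" in m for m in caplog.messages)

    def test_measured_not_predicted_activity_used(self):
        """STP input is the measured sample nearest the nominal time."""
        c2 = exact_curve(cycle=2, times=(26.0, 50.0, 70.0))
        records = compare_cohort([c2], stp_times=(48.0,))
        (rec,) = records
        assert rec.time_used_h == 50.0


class TestBlandAltman:
    def test_hand_computed_summary(self):
        ba = bland_altman_summary([10.0, -10.0, 0.0])
        assert ba.mean_diff_percent == pytest.approx(0.0, abs=1e-12)
        assert ba.sd_diff_percent == pytest.approx(10.0, rel=1e-12)
        assert ba.loa_low_percent == pytest.approx(-19.6, rel=1e-12)
        assert ba.loa_high_percent == pytest.approx(19.6, rel=1e-12)

    @pytest.mark.parametrize("vals,mean,sd", [
        ([5.0, 5.0, 5.0], 5.0, 0.0),
        ([0.0, 0.0], 0.0, 0.0),
    ])
    def test_degenerate(self, vals, mean, sd):
        ba = bland_altman_summary(vals)
        assert ba.mean_diff_percent == pytest.approx(mean)
        assert ba.sd_diff_percent == pytest.approx(sd)
        assert ba.loa_low_percent == pytest.approx(mean)
        assert ba.loa_high_percent == pytest.approx(mean)

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            bland_altman_summary([1.0])

    def test_symmetry_invariant_and_mean_consistency(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(2.0, 8.0, 40)
        ba = bland_altman_summary(vals)
        assert ba.loa_high_percent - ba.mean_diff_percent == pytest.approx(
            ba.mean_diff_percent - ba.loa_low_percent, rel=1e-9
        )
        assert ba.mean_diff_percent == pytest.approx(float(vals.mean()))

    def test_table_matches_per_stratum_summary(self):
        curves = [exact_curve(cycle=1), exact_curve(cycle=2)]
        records = compare_cohort(curves)
        table = bland_altman_table(records)
        # one VOI => n = 1 per stratum, below the n >= 2 threshold
        assert table.empty


class TestCoverage:
    def make_records(self, pds):
        curves = []  # build via compare on synthetic values is overkill here
        from stpdosim.compare import ComparisonRecord

        return [
            ComparisonRecord("P1", 2, f"v{i}", "lesion", STP_H, 48.0, 48.0,
                             100.0 + p, 100.0, p, True)
            for i, p in enumerate(pds)
        ]

    def test_counting(self):
        table = coverage_table(self.make_records([5.0, -15.0, 25.0]))
        row = table.iloc[0]
        assert row["n"] == 3
        assert row["frac_within_10"] == pytest.approx(1 / 3)
        assert row["frac_within_20"] == pytest.approx(2 / 3)

    def test_all_zero(self):
        table = coverage_table(self.make_records([0.0, 0.0]))
        assert table.iloc[0]["frac_within_10"] == 1.0
        assert table.iloc[0]["frac_within_20"] == 1.0

    def test_inclusive_boundaries(self):
        table = coverage_table(self.make_records([10.0, -10.0, 20.0, -20.0]))
        row = table.iloc[0]
        assert row["frac_within_10"] == pytest.approx(0.5)
        assert row["frac_within_20"] == pytest.approx(1.0)

    def test_permutation_invariance_and_additivity(self):
        pds = [3.0, 12.0, -25.0, 8.0, 19.0]
        t1 = coverage_table(self.make_records(pds))
        t2 = coverage_table(self.make_records(pds[::-1]))
        pd.testing.assert_frame_equal(t1, t2)
        # additivity over disjoint strata: counts add up
        recs_a = self.make_records(pds[:2])
        recs_b = [
            r for r in self.make_records(pds[2:])
        ]
        both = coverage_table(recs_a + recs_b)
        assert both.iloc[0]["n"] == 5

    def test_empty_records(self):
        assert coverage_table([]).empty


class TestWindowCoverage:
    def test_direct_evaluation_of_window_rule(self):
        """T = {10, 30, 100} h at t = 24: exactly T=10 and T=30 in window."""
        fits = pd.DataFrame(
            {
                "voi_type": ["lesion"] * 3,
                "cycle": [1] * 3,
                "half_life_eff_h": [10.0, 30.0, 100.0],
            }
        )
        table = window_coverage_table(fits, times=(24.0,))
        row = table.iloc[0]
        assert row["n"] == 3
        assert row["n_in_window"] == 2
        assert row["pct_in_window"] == 67

    def test_all_kidneys_in_window_at_48(self):
        rng = np.random.default_rng(0)
        fits = pd.DataFrame(
            {
                "voi_type": ["kidney_left"] * 37,
                "cycle": [2] * 37,
                "half_life_eff_h": rng.uniform(19.2, 64.0, 37),
            }
        )
        table = window_coverage_table(fits, times=(48.0,))
        assert table.iloc[0]["pct_in_window"] == 100

    def test_long_half_life_excluded_at_24(self):
        fits = pd.DataFrame(
            {"voi_type": ["lesion"], "cycle": [1], "half_life_eff_h": [69.0]}
        )
        table = window_coverage_table(fits, times=(24.0,))
        assert table.iloc[0]["n_in_window"] == 0

    def test_nondecaying_rows_excluded(self):
        fits = pd.DataFrame(
            {
                "voi_type": ["lesion", "lesion"],
                "cycle": [1, 1],
                "half_life_eff_h": [30.0, -12.0],
            }
        )
        table = window_coverage_table(fits, times=(48.0,))
        assert table.iloc[0]["n"] == 1


class TestHalfLifeChange:
    def test_boundary_rule_strictly_greater_than_20(self):
        c1 = {("P1", "a"): 50.0, ("P1", "b"): 50.0, ("P1", "c"): 50.0}
        c2 = {("P1", "a"): 40.0, ("P1", "b"): 39.0, ("P1", "c"): 50.0}
        stats = half_life_change_stats(c1, c2)
        changes = dict(
            zip(stats.frame["voi_id"], stats.frame["change_percent"])
        )
        assert changes["a"] == pytest.approx(-20.0)
        assert changes["b"] == pytest.approx(-22.0)
        assert changes["c"] == pytest.approx(0.0)
        assert stats.n_exceeding_20 == 1  # only b: exactly -20 not counted

    def test_unmatched_vois_skipped(self, caplog):
        with caplog.at_level("WARNING", logger="stpdosim"):
            stats = half_life_change_stats(
                {("P1", "a"): 50.0}, {("P1", "b"): 40.0}
            )
        assert stats.n == 0
        assert math.isnan(stats.fraction_exceeding_20)
        assert any("only one cycle" in m for m in caplog.messages)
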