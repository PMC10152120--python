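"""Synthetic cohort generator: determinism, calibration, noise model,
and parameter recovery."""

import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from stpdosim.cohort import (
    CohortParams,
    TruncNormSpec,
    generate_cohort,
    simulate_measurements,
)
from stpdosim.compare import compare_cohort, records_to_frame
from stpdosim.errors import ValidationError
from stpdosim.tac import STP_PRIOR, fit_monoexponential

from conftest import monoexp


class TestSimulateMeasurements:
    def test_noiseless_equals_model(self):
        samples = simulate_measurements(100.0, 32.5, [24.0, 48.0, 72.0], 0.0, 0)
        acts = [s.activity_MBq for s in samples]
        assert acts == pytest.approx([59.94, 35.92, 21.53], abs=0.01)

    def test_noise_cv_calibration(self):
        """Empirical CV of 10^4 replicates at one time matches noise_cv."""
        rng = np.random.default_rng(123)
        vals = np.array(
            [
                simulate_measurements(100.0, 32.5, [48.0], 0.05, rng)[0].activity_MBq
                for _ in range(10_000)
            ]
        )
        cv = vals.std(ddof=1) / vals.mean()
        assert 0.045 <= cv <= 0.055
        # mean-unbiased on the linear scale
        assert vals.mean() == pytest.approx(monoexp(100.0, 32.5, 48.0), rel=0.01)

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            simulate_measurements(100.0, 32.5, [24.0], -0.1, 0)
        with pytest.raises(ValidationError):
            simulate_measurements(100.0, 32.5, [-1.0], 0.05, 0)


class TestTruncNormSpec:
    def test_range_must_contain_mean(self):
        with pytest.raises(ValidationError):
            TruncNormSpec(10.0, 1.0, 20.0, 30.0)

    def test_sampling_respects_truncation(self):
        spec = TruncNormSpec(32.5, 7.0, 17.8, 51.9)
        u = np.random.default_rng(0).uniform(size=5000)
        vals = spec.ppf(u)
        assert vals.min() >= 17.8
        assert vals.max() <= 51.9


class TestGenerateCohort:
    def test_determinism_same_seed(self):
        a = generate_cohort(CohortParams(seed=7))
        b = generate_cohort(CohortParams(seed=7))
        assert a.curves == b.curves
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_different_seeds_differ(self):
        a = generate_cohort(CohortParams(seed=1))
        b = generate_cohort(CohortParams(seed=2))
        ta = a.truth["half_life_h"].dropna()
        tb = b.truth["half_life_h"].dropna()
        assert ta.mean() != pytest.approx(tb.mean(), rel=1e-12)

    def test_structure(self):
        cohort = generate_cohort(CohortParams(n_patients=30, seed=3))
        truth = cohort.truth
        per_patient = truth[truth["cycle"] == 1].groupby("patient_id")
        for _, sub in per_patient:
            kidneys = sub[sub["voi_type"].str.startswith("kidney")]
            lesions = sub[sub["voi_type"] == "lesion"]
            assert len(kidneys) in (1, 2)
            assert 0 <= len(lesions) <= 6
        # some patients single-kidney, some lesion-free, at default rates
        n_single = sum(
            len(sub[sub["voi_type"].str.startswith("kidney")]) == 1
            for _, sub in per_patient
        )
        assert 0 < n_single < 30

    def test_halflives_within_truncation(self):
        cohort = generate_cohort(CohortParams(n_patients=100, seed=5))
        t = cohort.truth
        kid1 = t[(t["voi_type"].str.startswith("kidney")) & (t["cycle"] == 1)]
        les2 = t[(t["voi_type"] == "lesion") & (t["cycle"] == 2)]
        assert kid1["half_life_h"].between(17.8, 51.9).all()
        assert les2["half_life_h"].between(19.7, 216.2).all()

    def test_kidney_population_mean_recovered(self):
        """Cycle-1 kidney half-life sample mean is within 3 SE of 32.5 h."""
        cohort = generate_cohort(CohortParams(n_patients=200, seed=11))
        t = cohort.truth
        kid = t[(t["voi_type"].str.startswith("kidney")) & (t["cycle"] == 1)]
        vals = kid["half_life_h"]
        se = vals.std(ddof=1) / math.sqrt(len(vals))
        assert abs(vals.mean() - 32.5) < 3 * se + 1e-9

    def test_tbfov_is_sum_of_lesions(self):
        """Conservation: the TB_FOV curve equals the sum of the patient's
        lesion measurement curves at every time."""
        cohort = generate_cohort(CohortParams(n_patients=10, seed=9))
        by_key = {c.key: c for c in cohort.curves}
        checked = 0
        for (pid, cycle, voi_id), curve in by_key.items():
            if voi_id != "tb_fov":
                continue
            lesions = [
                c for c in cohort.curves
                if c.patient_id == pid and c.cycle == cycle
                and c.voi_type == "lesion"
            ]
            total = np.sum([c.activities_MBq for c in lesions], axis=0)
            assert curve.activities_MBq == pytest.approx(total, rel=1e-12)
            assert curve.times_h == pytest.approx(lesions[0].times_h)
            checked += 1
        assert checked > 0

    def test_noiseless_fit_recovers_truth(self):
        """Fitting noiseless generated curves returns the sampled
        half-lives to 1e-9 relative error."""
        params = CohortParams(n_patients=5, noise_cv=0.0, seed=2)
        cohort = generate_cohort(params)
        truth = cohort.truth.set_index(["patient_id", "cycle", "voi_id"])
        for curve in cohort.curves:
            if curve.voi_id == "tb_fov":
                continue  # derived, no single truth half-life
            fit = fit_monoexponential(curve)
            row = truth.loc[curve.key]
            assert fit.half_life_eff_h == pytest.approx(
                row["half_life_h"], rel=1e-9
            )
            assert fit.A0_MBq == pytest.approx(row["A0_MBq"], rel=1e-9)

    def test_exactness_path_stp_prior_zero_pd(self):
        """noise=0, identical cycle marginals, correlation 1: every
        STP_prior percentage difference is exactly zero."""
        k = TruncNormSpec(32.5, 7.0, 17.8, 51.9)
        l = TruncNormSpec(69.0, 40.0, 20.1, 249.7)
        params = CohortParams(
            n_patients=8,
            noise_cv=0.0,
            intercycle_correlation=1.0,
            kidney_half_life_h=(k, k),
            lesion_half_life_h=(l, l),
            uptake_intercycle_cv=0.0,
            seed=4,
        )
        cohort = generate_cohort(params)
        non_tb = [c for c in cohort.curves if c.voi_id != "tb_fov"]
        records = compare_cohort(non_tb)
        prior = [r for r in records if r.method == STP_PRIOR]
        assert prior
        for r in prior:
            assert r.pd_percent == pytest.approx(0.0, abs=1e-9)

    def test_lesion_halflife_change_calibration_target(self):
        """At the default correlation, the share of lesions changing by
        more than ±20% between cycles sits near the 46% calibration target."""
        cohort = generate_cohort(CohortParams(n_patients=300, seed=8))
        t = cohort.truth
        les = t[t["voi_type"] == "lesion"].pivot_table(
            index=["patient_id", "voi_id"], columns="cycle",
            values="half_life_h",
        )
        change = 100.0 * (les[2] - les[1]) / les[1]
        frac = (change.abs() > 20.0).mean()
        assert 0.31 <= frac <= 0.61

    def test_infeasible_truncation_rejected(self):
        with pytest.raises(ValidationError):
            CohortParams(
                kidney_half_life_h=(
                    TruncNormSpec(32.5, 7.0, 40.0, 51.9),  # mean below range
                    TruncNormSpec(31.7, 6.4, 21.6, 45.7),
                )
            )

    def test_biexponential_truth_option(self):
        from stpdosim.cohort import BiexpComponent

        params = CohortParams(
            n_patients=3, noise_cv=0.0,
            second_component=BiexpComponent(0.2, 200.0), seed=6,
        )
        cohort = generate_cohort(params)
        curve = next(c for c in cohort.curves if c.voi_id != "tb_fov")
        truth = cohort.truth.set_index(["patient_id", "cycle", "voi_id"])
        row = truth.loc[curve.key]
        fit = fit_monoexponential(curve)
        # mono fit of a biexp truth must overestimate the fast half-life
        assert fit.half_life_eff_h > row["half_life_h"]
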