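"""Preprocessing: relative days, detection-limit imputation, albumin
plausibility filter, eligibility rule and daily-mean aggregation."""
import datetime
import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bsikinetics import (
    Biomarker,
    Measurement,
    MicrobialGroup,
    PatientRecord,
    assign_relative_day,
    daily_means,
    exclude_implausible_pa,
    generate_cohort,
    impute_below_lod,
    select_cohort,
    select_cohort_both,
)
from conftest import CRP_KIN, make_scenario


def crp(pid, day, value, below=False):
    return Measurement(pid, Biomarker.CRP, day, value, below)


def pa(pid, day, value):
    return Measurement(pid, Biomarker.PA, day, value)


@pytest.mark.parametrize(
    "specimen, index, expected",
    [
        ("2004-03-10", "2004-03-10", 0),
        ("2004-03-07", "2004-03-10", -3),
        ("2004-03-11", "2004-03-10", 1),
        (datetime.date(2005, 1, 2), datetime.date(2004, 12, 31), 2),
    ],
)
def test_assign_relative_day(specimen, index, expected):
    assert assign_relative_day(specimen, index) == expected


class TestImputeBelowLod:
    def test_flagged_values_drawn_from_discrete_uniform_0_to_9(self):
        flagged = [crp("a", d, 10.0, below=True) for d in range(-20, 0)]
        out = impute_below_lod(flagged, rng=0)
        assert all(m.value in set(range(10)) for m in out)
        assert all(not m.below_lod for m in out)

    def test_values_at_or_above_limit_pass_through(self):
        m = crp("a", -5, 57.0)
        assert impute_below_lod([m], rng=0) == [m]

    def test_empirical_mean_matches_uniform_law(self):
        """10,000 imputations: mean within 3 SE of the uniform{0..9} mean 4.5."""
        flagged = [crp("a", -1, 10.0, below=True)] * 10_000
        values = [m.value for m in impute_below_lod(flagged, rng=1)]
        se = np.sqrt(np.var(range(10)) / len(values))
        assert abs(np.mean(values) - 4.5) <= 3 * se

    def test_continuous_mode_stays_below_limit(self):
        flagged = [crp("a", -1, 10.0, below=True)] * 200
        values = [m.value for m in impute_below_lod(flagged, rng=2,
                                                    mode="continuous")]
        assert all(0 <= v < 10 for v in values)
        assert any(v != int(v) for v in values)

    def test_albumin_rejected(self):
        with pytest.raises(ValueError, match="CRP only"):
            impute_below_lod([pa("a", -1, 30.0)], rng=0)

    def test_reproducible_under_fixed_seed(self):
        flagged = [crp("a", d, 10.0, below=True) for d in range(-9, 0)]
        assert impute_below_lod(flagged, rng=11) == impute_below_lod(flagged, rng=11)

    @given(st.lists(st.floats(min_value=0, max_value=500,
                              allow_nan=False), max_size=30))
    @settings(max_examples=25, derandomize=True)
    def test_only_flagged_values_change(self, values):
        ms = [crp("a", -1, v, below=v < 10) for v in values]
        out = impute_below_lod(ms, rng=3)
        for before, after in zip(ms, out):
            if before.below_lod:
                assert 0 <= after.value <= 9
            else:
                assert after.value == before.value


class TestExcludeImplausiblePa:
    def test_strict_boundary(self):
        ms = [pa("a", -1, 10.9), pa("a", -1, 11.0), pa("a", 0, 28.0)]
        assert [m.value for m in exclude_implausible_pa(ms)] == [11.0, 28.0]

    def test_empty_input(self):
        assert exclude_implausible_pa([]) == []

    def test_count_matches_direct_filter(self, rng):
        values = rng.uniform(5, 45, size=100)
        ms = [pa("a", -1, v) for v in values]
        kept = exclude_implausible_pa(ms)
        assert len(kept) == int(np.sum(values >= 11.0))


class TestSelectCohort:
    def test_pre_and_diagnosis_day_measurements_required(self):
        eligible = PatientRecord("a", MicrobialGroup.UNKNOWN,
                                 [crp("a", -5, 50.0), crp("a", 0, 80.0)])
        only_pre = PatientRecord("b", MicrobialGroup.UNKNOWN,
                                 [crp("b", -5, 50.0)])
        assert select_cohort([eligible, only_pre], Biomarker.CRP) == [eligible]

    def _random_cohort(self, n=50, seed=0):
        r = random.Random(seed)
        cohort = []
        for i in range(n):
            ms = []
            for bm in Biomarker:
                for _ in range(r.randint(0, 4)):
                    ms.append(Measurement(f"p{i}", bm, r.randint(-30, 1),
                                          r.uniform(12, 90)))
            cohort.append(PatientRecord(f"p{i}", MicrobialGroup.UNKNOWN, ms))
        return cohort

    def test_matches_brute_force_rule(self):
        cohort = self._random_cohort()
        for bm in Biomarker:
            expected = [
                p.patient_id
                for p in cohort
                if any(-30 <= m.relative_day <= -1 for m in p.measurements
                       if m.biomarker == bm)
                and any(m.relative_day in (0, 1) for m in p.measurements
                        if m.biomarker == bm)
            ]
            assert [p.patient_id for p in select_cohort(cohort, bm)] == expected
        both = select_cohort_both(cohort)
        ids = {p.patient_id for p in both}
        assert ids == (
            {p.patient_id for p in select_cohort(cohort, Biomarker.CRP)}
            & {p.patient_id for p in select_cohort(cohort, Biomarker.PA)}
        )

    def test_idempotent_and_order_independent(self):
        cohort = self._random_cohort(seed=4)
        once = select_cohort(cohort, Biomarker.CRP)
        assert select_cohort(once, Biomarker.CRP) == once
        shuffled = cohort[::-1]
        assert {p.patient_id for p in select_cohort(shuffled, Biomarker.CRP)} \
            == {p.patient_id for p in once}


class TestDailyMeans:
    def test_hand_computed_mean_and_count(self):
        p = PatientRecord("a", MicrobialGroup.UNKNOWN,
                          [crp("a", -7, 10), crp("a", -7, 20), crp("a", -7, 30),
                           crp("a", 0, 100)])
        series = daily_means([p], Biomarker.CRP)
        assert series.days.tolist() == [-7, 0]
        assert series.means.tolist() == [20.0, 100.0]
        assert series.counts.tolist() == [3, 1]

    def test_same_day_duplicates_pool_as_separate_specimens(self):
        p = PatientRecord("a", MicrobialGroup.UNKNOWN,
                          [crp("a", -3, 5), crp("a", -3, 15)])
        series = daily_means([p], Biomarker.CRP)
        assert series.means.tolist() == [10.0]
        assert series.counts.tolist() == [2]

    def test_zero_noise_cohort_reproduces_true_curve(self, zero_noise_cohort):
        series = daily_means(zero_noise_cohort, Biomarker.CRP)
        np.testing.assert_allclose(series.means, CRP_KIN.mean_at(series.days),
                                   atol=1e-12)

    def test_counts_conserve_measurements(self):
        cohort = generate_cohort(make_scenario(n_patients=25, sampling_p=0.5,
                                               crp_noise_sd_log=0.3, seed=8))
        for bm in Biomarker:
            series = daily_means(cohort, bm)
            n_meas = sum(m.biomarker == bm for p in cohort
                         for m in p.measurements)
            assert series.counts.sum() == n_meas
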