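"""Grade assignment, deviation scores, and report assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ivdquant.grading import (AGE_BANDS, BaselineLookupError, BaselineTable,
                              GradingCriteria, assign_grade, beta_deviation,
                              build_report, collapse_percentage, grade_delta,
                              synthetic_baseline, synthetic_criteria)


@pytest.fixture(scope="module")
def criteria():
    return GradingCriteria(mu=[150, 120, 90, 60, 30], sigma=[10] * 5)


class TestGradeDelta:
    def test_at_grade_mean(self, criteria):
        # ΔSI = μ_i, equal σ, μ gap 30 → Δ = 30/10 − 0 = 3
        assert grade_delta(150.0, criteria, 1) == pytest.approx(3.0)

    def test_at_next_grade_mean_negative(self, criteria):
        assert grade_delta(120.0, criteria, 1) == pytest.approx(-3.0)

    def test_zero_at_midpoint(self, criteria):
        assert grade_delta(135.0, criteria, 1) == pytest.approx(0.0)

    def test_invalid_index(self, criteria):
        with pytest.raises(ValueError):
            grade_delta(100.0, criteria, 5)


class TestAssignGrade:
    def test_at_first_mean(self, criteria):
        assert assign_grade(150.0, criteria) == 1

    def test_midpoint_tie_breaks_severe(self, criteria):
        # midpoint of grades 2 and 3 at equal sigma
        assert assign_grade(105.0, criteria) == 3

    def test_sweep_non_decreasing(self, criteria):
        grades = [assign_grade(s, criteria)
                  for s in np.linspace(160.0, 20.0, 561)]
        assert all(b >= a for a, b in zip(grades, grades[1:]))

    def test_step_boundaries_at_adjacent_mu_midpoints(self, criteria):
        sweep = np.linspace(20.0, 160.0, 14001)
        grades = np.array([assign_grade(s, criteria) for s in sweep])
        plateaus = len(np.unique(grades))
        assert plateaus == criteria.n_grades
        jumps = sweep[1:][np.diff(grades) != 0]
        expected = [(150 + 120) / 2, (120 + 90) / 2, (90 + 60) / 2,
                    (60 + 30) / 2]
        assert len(jumps) == 4
        for j, e in zip(sorted(jumps), sorted(expected)):
            assert abs(j - e) <= 0.02

    def test_sign_change_equivalence(self, criteria, rng):
        # assigned grade g means Δ_i >= 0 for i < g and Δ_i < 0 for i >= g
        for dsi in rng.uniform(10, 170, 100):
            g = assign_grade(dsi, criteria)
            deltas = [grade_delta(dsi, criteria, i) for i in range(1, 5)]
            oracle = 1 + sum(d <= 0 for d in deltas)
            assert g == oracle or any(abs(d) < 1e-9 for d in deltas)

    def test_invariant_to_joint_affine_rescaling(self, criteria, rng):
        a, b = 2.7, 13.0
        scaled = GradingCriteria(mu=a * criteria.mu + b,
                                 sigma=a * criteria.sigma)
        for dsi in rng.uniform(20, 160, 50):
            assert assign_grade(dsi, criteria) == assign_grade(a * dsi + b,
                                                               scaled)


@settings(max_examples=60, derandomize=True)
@given(dsi=st.floats(0, 300),
       top=st.floats(50, 250),
       sigma=st.floats(1, 40))
def test_grade_never_decreases_when_delta_si_grows(dsi, top, sigma):
    crit = GradingCriteria(mu=np.linspace(top, top / 10, 5),
                           sigma=[sigma] * 5)
    g_here = assign_grade(dsi, crit)
    g_brighter = assign_grade(dsi + 5.0, crit)
    assert g_brighter <= g_here


class TestDeviations:
    def test_beta_zero_at_mean(self):
        assert beta_deviation(10.0, 10.0, 2.0) == 0.0

    def test_beta_two_sigma_below(self):
        assert beta_deviation(6.0, 10.0, 2.0) == -2.0

    def test_beta_monotone_in_x(self, rng):
        xs = np.sort(rng.uniform(-5, 5, 50))
        bs = [beta_deviation(x, 1.0, 0.7) for x in xs]
        assert all(b2 > b1 for b1, b2 in zip(bs, bs[1:]))

    def test_beta_requires_positive_sigma(self):
        with pytest.raises(ValueError):
            beta_deviation(1.0, 0.0, 0.0)

    def test_collapse_percentage(self):
        assert collapse_percentage(10.0, 10.0) == (0.0, False)
        assert collapse_percentage(5.0, 10.0) == (50.0, False)
        pct, above = collapse_percentage(11.0, 10.0)
        assert pct == 0.0 and above

    def test_collapse_needs_positive_baseline(self):
        with pytest.raises(ValueError):
            collapse_percentage(5.0, 0.0)


class TestCriteriaTables:
    def test_mu_must_decrease(self):
        with pytest.raises(ValueError):
            GradingCriteria(mu=[100, 110, 90], sigma=[1, 1, 1])

    def test_csv_roundtrip(self, tmp_path, criteria):
        p = tmp_path / "crit.csv"
        criteria.to_csv(p)
        back = GradingCriteria.from_csv(p)
        np.testing.assert_allclose(back.mu, criteria.mu)
        np.testing.assert_allclose(back.sigma, criteria.sigma)

    def test_baseline_requires_all_segments(self):
        tb = synthetic_baseline().table
        broken = tb[~((tb.gender == 0) & (tb.age_band == AGE_BANDS[0])
                      & (tb.segment == "DISC_L3L4"))]
        with pytest.raises(ValueError, match="five segments"):
            BaselineTable(broken)

    def test_baseline_csv_roundtrip(self, tmp_path):
        base = synthetic_baseline()
        p = tmp_path / "base.csv"
        base.to_csv(p)
        back = BaselineTable.from_csv(p)
        pd.testing.assert_frame_equal(back.table, base.table)


class TestBuildReport:
    def _measures(self, sample):
        from ivdquant.geometry import measure_spine
        return measure_spine(sample.image, sample.mask)

    def test_healthy_phantom_grade1_beta_small(self, healthy_sample):
        measures = self._measures(healthy_sample)
        truth_dsi = healthy_sample.truth["DISC_L3L4"].delta_si
        crit = GradingCriteria(mu=np.linspace(truth_dsi, 10, 5),
                               sigma=[10] * 5)
        rep = build_report(measures, crit, synthetic_baseline(),
                           {"gender": 0, "age": 35})
        for d in rep.discs:
            assert d.grade == 1
            assert abs(d.beta_dhi) < 2.0
            assert abs(d.beta_hdr) < 2.0

    def test_collapsed_endpoint_highest_grade(self):
        from ivdquant.phantom import degeneration_series, healthy_spec
        end = degeneration_series(healthy_spec(), 2)[-1]
        measures = self._measures(end)
        crit = synthetic_criteria()
        rep = build_report(measures, crit, synthetic_baseline(),
                           {"gender": 1, "age": 62})
        for d in rep.discs:
            assert d.grade == crit.n_grades
            assert d.beta_dhi < 0
            assert d.beta_hdr < 0
            assert d.collapse_percent > 30

    def test_unknown_gender_raises(self, healthy_sample):
        measures = self._measures(healthy_sample)
        with pytest.raises(BaselineLookupError):
            build_report(measures, synthetic_criteria(), synthetic_baseline(),
                         {"gender": "x", "age": 40})

    def test_no_baseline_skips_deviations(self, healthy_sample):
        measures = self._measures(healthy_sample)
        rep = build_report(measures, synthetic_criteria(), None, {})
        for d in rep.discs:
            assert d.grade is not None
            assert d.beta_dhi is None
            assert d.collapse_percent is None
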