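"""Wear-time filtering, MET conversion, prevalence and per-type summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bodytyper.bodytype import label_types
from bodytyper.health import (activity_by_type, bmi_age_slope,
                              cross_type_correlation, filter_valid_wear_days,
                              lifestyle_summary, medication_frequency,
                              met_to_oxygen, participant_activity_summary,
                              prevalence)


def _days(rows):
    return pd.DataFrame(rows, columns=["id", "day_type", "wear_hours",
                                       "steps", "met"])


# ----------------------------------------------------------------------
@pytest.mark.parametrize("day_type,wear,valid", [
    ("weekday", 18.0, True),    # boundary inclusive
    ("weekday", 17.99, False),
    ("weekday", 24.0, True),
    ("weekend", 20.0, True),    # boundary inclusive
    ("weekend", 19.5, False),
    ("weekend", 18.0, False),   # enough for a weekday, not a weekend
])
def test_wear_day_validity_rules(day_type, wear, valid):
    days = _days([("p1", day_type, wear, 5000, 1.3)])
    valid_days, _ = filter_valid_wear_days(days)
    assert (len(valid_days) == 1) is valid


def test_eligibility_needs_mix_of_day_types():
    """8 valid days as 4+4 weekday/weekend: eligible; 8 weekdays: not."""
    mixed = _days([("p1", "weekday", 20.0, 1, 1.0)] * 4
                  + [("p1", "weekend", 21.0, 1, 1.0)] * 4)
    _, eligible = filter_valid_wear_days(mixed)
    assert eligible.loc["p1"]
    weekdays_only = _days([("p2", "weekday", 20.0, 1, 1.0)] * 8)
    _, eligible2 = filter_valid_wear_days(weekdays_only)
    assert not eligible2.loc["p2"]


def test_eligibility_needs_eight_valid_days():
    seven = _days([("p1", "weekday", 20.0, 1, 1.0)] * 6
                  + [("p1", "weekend", 21.0, 1, 1.0)])
    _, eligible = filter_valid_wear_days(seven)
    assert not eligible.loc["p1"]


def test_invalid_days_do_not_count():
    rows = ([("p1", "weekday", 20.0, 1, 1.0)] * 4
            + [("p1", "weekend", 21.0, 1, 1.0)] * 4
            + [("p1", "weekend", 10.0, 1, 1.0)] * 5)
    valid, eligible = filter_valid_wear_days(_days(rows))
    assert len(valid) == 8 and eligible.loc["p1"]


def test_wear_time_out_of_range_rejected():
    with pytest.raises(ValueError, match="p1"):
        filter_valid_wear_days(_days([("p1", "weekday", 25.0, 1, 1.0)]))


@given(st.lists(
    st.tuples(st.sampled_from(["weekday", "weekend"]),
              st.floats(min_value=0, max_value=24)),
    min_size=1, max_size=20))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_filter_monotone_in_thresholds(day_specs):
    """Raising wear-time thresholds never enlarges the valid-day set."""
    days = _days([("p", t, w, 0, 1.0) for t, w in day_specs])
    loose, _ = filter_valid_wear_days(days, weekday_min=16, weekend_min=18)
    strict, _ = filter_valid_wear_days(days, weekday_min=20, weekend_min=22)
    assert set(strict.index) <= set(loose.index)


# ----------------------------------------------------------------------
def test_met_oxygen_conversion():
    assert met_to_oxygen(1.0) == pytest.approx(3.5)
    assert met_to_oxygen(0.0) == 0.0
    assert met_to_oxygen(2.0) == pytest.approx(7.0)
    with pytest.raises(ValueError):
        met_to_oxygen(-0.1)


@pytest.mark.parametrize("affected,total,expected", [
    (192, 4766, 4.0),
    (59, 5234, 1.1),
    (0, 100, 0.0),
    (1089, 4766, 22.8),
    (1, 1600, 0.1),
])
def test_prevalence_values(affected, total, expected):
    assert prevalence(affected, total) == expected


def test_prevalence_contract():
    with pytest.raises(ValueError):
        prevalence(1, 0)
    with pytest.raises(ValueError):
        prevalence(5, 4)


@given(st.integers(min_value=0, max_value=1000),
       st.integers(min_value=1, max_value=1000))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_prevalence_bounds_and_complement(affected, total):
    affected = min(affected, total)
    p = prevalence(affected, total)
    q = prevalence(total - affected, total)
    assert 0.0 <= p <= 100.0
    assert p + q == pytest.approx(100.0, abs=0.11)  # rounding slack


# ----------------------------------------------------------------------
def test_summary_uses_valid_days_only():
    """One valid 9000-step day + one invalid 0-step day -> mean 9000."""
    rows = ([("p1", "weekday", 20.0, 9000, 1.5)]
            + [("p1", "weekday", 5.0, 0, 0.2)]
            + [("p1", "weekday", 20.0, 9000, 1.5)] * 3
            + [("p1", "weekend", 21.0, 9000, 1.5)] * 4)
    summary = participant_activity_summary(_days(rows))
    assert summary.loc["p1", "mean_steps"] == pytest.approx(9000.0)


def _toy_assignment(n_per_type=60, shift=0.0, seed=0):
    """Two female types aged alike; type T2 optionally less active."""
    rng = np.random.default_rng(seed)
    ids = [f"p{i}" for i in range(2 * n_per_type)]
    part = pd.DataFrame({"sex": "F", "age": rng.uniform(50, 60, len(ids))},
                        index=ids)
    clusters = pd.Series([0] * n_per_type + [1] * n_per_type, index=ids)
    assignment = label_types(clusters, part)
    rows = []
    for i, pid in enumerate(ids):
        met = 1.5 + (shift if i >= n_per_type else 0.0) \
            + 0.05 * rng.standard_normal()
        for d in range(8):
            day_type = "weekend" if d >= 6 else "weekday"
            rows.append((pid, day_type, 23.0, 8000, max(met, 0.1)))
    return assignment, part, _days(rows)


def test_activity_marks_planted_low_met_type():
    assignment, part, days = _toy_assignment(n_per_type=200, shift=-0.6,
                                             seed=1)
    out = activity_by_type(assignment, days, part)
    low = out.loc[out["median_met"].idxmin()]
    assert low["met_mark"] == "−−−"


def test_activity_no_mark_when_identical_to_reference():
    assignment, part, days = _toy_assignment(shift=0.0, seed=2)
    out = activity_by_type(assignment, days, part)
    assert (out["met_p"] > 0.1).all()


# ----------------------------------------------------------------------
def test_cross_type_correlation_perfect_line():
    bmi = pd.Series({"A": 22.0, "B": 26.0, "C": 30.0})
    met = pd.Series({"A": 1.6, "B": 1.4, "C": 1.2})
    assert cross_type_correlation(bmi, met) == pytest.approx(-1.0)


def test_cross_type_correlation_noise_monotone():
    rng = np.random.default_rng(0)
    bmi = pd.Series(np.linspace(22, 32, 12), index=range(12))
    rs = []
    for noise in (0.0, 0.1, 0.4):
        met = pd.Series(2.0 - 0.03 * bmi.to_numpy()
                        + noise * rng.standard_normal(12), index=bmi.index)
        rs.append(cross_type_correlation(bmi, met))
    assert rs[0] == pytest.approx(-1.0)
    assert rs[0] <= rs[1] <= rs[2] < 0.5


def test_cross_type_correlation_degenerate_and_small():
    bmi = pd.Series({"A": 22.0, "B": 26.0, "C": 30.0})
    assert np.isnan(cross_type_correlation(bmi, pd.Series(
        {"A": 1.4, "B": 1.4, "C": 1.4})))
    with pytest.raises(ValueError):
        cross_type_correlation(bmi.iloc[:2], bmi.iloc[:2])


# ----------------------------------------------------------------------
def _summary_df(rows):
    return pd.DataFrame(rows).set_index("label")


def test_bmi_age_slope_two_point():
    s = _summary_df([{"label": "F1", "mean_age": 45.0, "mean_bmi": 24.0},
                     {"label": "F2", "mean_age": 65.0, "mean_bmi": 29.0}])
    assert bmi_age_slope(s) == pytest.approx(0.25)


def test_bmi_age_slope_flat():
    s = _summary_df([{"label": "M1", "mean_age": 45.0, "mean_bmi": 26.0},
                     {"label": "M2", "mean_age": 60.0, "mean_bmi": 26.0}])
    assert bmi_age_slope(s) == pytest.approx(0.0)


def test_bmi_age_slope_outlier_exclusion():
    """An off-line obese type at an extreme age bends the fit; excluding
    it restores the planted slope."""
    rows = [{"label": f"F{i}", "mean_age": 45.0 + 5 * i,
             "mean_bmi": 24.0 + 0.25 * 5 * i} for i in range(5)]
    rows.append({"label": "F9", "mean_age": 70.0, "mean_bmi": 36.0})
    s = _summary_df(rows)
    assert abs(bmi_age_slope(s) - 0.25) > 0.02
    assert bmi_age_slope(s, exclude=["F9"]) == pytest.approx(0.25)


def test_bmi_age_slope_needs_two_points():
    s = _summary_df([{"label": "F1", "mean_age": 45.0, "mean_bmi": 24.0}])
    with pytest.raises(ValueError):
        bmi_age_slope(s)


# ----------------------------------------------------------------------
def _health_frame(ids, **cols):
    df = pd.DataFrame(cols, index=ids)
    df.index.name = "id"
    return df


def test_medication_frequency_limits_and_planted_rate():
    assignment, part, _ = _toy_assignment(n_per_type=500, seed=3)
    ids = part.index
    rng = np.random.default_rng(3)
    t2 = assignment.members(assignment.labels.iloc[-1])
    flags = pd.Series(False, index=ids)
    flags.loc[t2] = rng.uniform(size=len(t2)) < 0.30
    health = _health_frame(ids, atc_C=flags, atc_G=False, atc_H=True,
                           smoking="never", alcohol_g_day=0.0)
    freq = medication_frequency(assignment, health, "C")
    lab2 = assignment.labels.iloc[-1]
    se = 100 * np.sqrt(0.3 * 0.7 / len(t2))
    assert abs(freq[lab2] - 30.0) < 3 * se
    assert freq[assignment.labels.iloc[0]] == 0.0
    assert (medication_frequency(assignment, health, "H") == 100.0).all()
    with pytest.raises(ValueError, match="ATC"):
        medication_frequency(assignment, health, "Z")


def test_medication_counts_aggregate_to_cohort_total():
    assignment, part, _ = _toy_assignment(n_per_type=100, seed=4)
    rng = np.random.default_rng(4)
    health = _health_frame(part.index,
                           atc_C=rng.uniform(size=len(part)) < 0.25,
                           smoking="never", alcohol_g_day=0.0)
    freq = medication_frequency(assignment, health, "C")
    counts = sum(round(freq[lab] / 100 * len(assignment.members(lab, view=True)))
                 for lab in freq.index)
    assert counts == int(health.atc_C.sum())


def test_lifestyle_smoker_definition():
    """1089 current + 1715 former of 4766 -> 58.8% smokers, 22.8% current."""
    n = 4766
    smoking = np.array(["current"] * 1089 + ["former"] * 1715
                       + ["never"] * (n - 1089 - 1715))
    ids = [f"p{i}" for i in range(n)]
    part = pd.DataFrame({"sex": "M", "age": 55.0}, index=ids)
    assignment = label_types(pd.Series(0, index=ids), part)
    health = _health_frame(ids, smoking=smoking, alcohol_g_day=10.0,
                           atc_C=False)
    out = lifestyle_summary(assignment, health)
    assert out["smoker_pct"].iloc[0] == 58.8
    assert out["current_smoker_pct"].iloc[0] == 22.8
    assert out["alcohol_mean_g_day"].iloc[0] == pytest.approx(10.0)


def test_lifestyle_all_never_smokers():
    ids = ["a", "b", "c"]
    part = pd.DataFrame({"sex": "F", "age": 50.0}, index=ids)
    assignment = label_types(pd.Series(0, index=ids), part)
    health = _health_frame(ids, smoking="never", alcohol_g_day=0.0)
    out = lifestyle_summary(assignment, health)
    assert out["smoker_pct"].iloc[0] == 0.0
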