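"""Age-dependence analyses: correlations, bodygrams, incidence, smoothing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bodytyper.aging import (IncidenceCurves, bodygram, delta_bodygram,
                             incidence_by_age, metameasure_age_correlation,
                             net_incidence_change, smoothed_index_curve)


def _aged_meta(n=2000, slope_per_decade=0.4, noise=1.0, seed=0):
    rng = np.random.default_rng(seed)
    ages = pd.Series(rng.uniform(40, 80, n))
    girth = slope_per_decade * (ages - 60) / 10 + noise * rng.standard_normal(n)
    flat = rng.standard_normal(n)
    meta = pd.DataFrame({"B": girth, "H": -girth, "X": flat})
    sexes = pd.Series(np.where(np.arange(n) % 2 == 0, "F", "M"))
    return meta, ages, sexes


def test_age_correlation_recovers_planted_trend():
    meta, ages, sexes = _aged_meta()
    r = metameasure_age_correlation(meta, ages, sexes)
    # analytic r = slope*sd_age / sqrt(slope^2 sd_age^2 + noise^2)
    sd_dec = np.sqrt((80 - 40) ** 2 / 12) / 10
    expected = 0.4 * sd_dec / np.hypot(0.4 * sd_dec, 1.0)
    for sex in ("F", "M"):
        assert r.loc[sex, "B"] == pytest.approx(expected, abs=0.1)
        assert r.loc[sex, "H"] < 0          # planted decrease
        assert abs(r.loc[sex, "X"]) < 0.05  # null axis


def test_age_correlation_needs_three_participants():
    meta = pd.DataFrame({"B": [0.0, 1.0]})
    with pytest.raises(ValueError):
        metameasure_age_correlation(meta, pd.Series([40.0, 50.0]),
                                    pd.Series(["F", "F"]))


# ----------------------------------------------------------------------
def test_whole_cohort_bodygram_is_zero(meta_default):
    assert np.abs(bodygram(meta_default)).max() < 1e-9


def test_single_participant_bodygram_identity(meta_default):
    pid = meta_default.index[3]
    pd.testing.assert_series_equal(bodygram(meta_default, pd.Index([pid])),
                                   meta_default.loc[pid], check_names=False)


def test_bodygram_linearity(meta_default):
    """Union bodygram equals the size-weighted mean of part bodygrams."""
    ids = meta_default.index
    a, b = ids[:100], ids[100:350]
    union = bodygram(meta_default, a.union(b))
    weighted = (len(a) * bodygram(meta_default, a)
                + len(b) * bodygram(meta_default, b)) / (len(a) + len(b))
    pd.testing.assert_series_equal(union, weighted, atol=1e-12)


def test_bodygram_empty_group_rejected(meta_default):
    with pytest.raises(ValueError):
        bodygram(meta_default, pd.Index([]))


def test_delta_bodygram_identical_groups_zero(meta_default):
    ids = meta_default.index[:50]
    dg = delta_bodygram(meta_default, ids, ids)
    assert np.allclose(dg["delta"], 0.0)
    assert not dg["flagged"].any()


def test_delta_bodygram_antisymmetry(meta_default):
    a, b = meta_default.index[:80], meta_default.index[80:200]
    d1 = delta_bodygram(meta_default, a, b)["delta"]
    d2 = delta_bodygram(meta_default, b, a)["delta"]
    pd.testing.assert_series_equal(d1, -d2)


def test_delta_bodygram_flags_planted_effect():
    """A +0.3 Z / 30 y girth drift flags the girth axis, negative H shows
    a negative delta."""
    meta, ages, _ = _aged_meta(n=2000, slope_per_decade=0.3, seed=2)
    young = meta.index[(ages >= 40) & (ages < 50)]
    old = meta.index[(ages >= 70) & (ages <= 80)]
    dg = delta_bodygram(meta, young, old, flag_threshold=0.2)
    assert dg.loc["B", "flagged"] and dg.loc["B", "delta"] > 0.2
    assert dg.loc["H", "delta"] < 0
    assert not dg.loc["X", "flagged"]


# ----------------------------------------------------------------------
def test_incidence_single_type_flat_100():
    n = 200
    rng = np.random.default_rng(0)
    ages = pd.Series(rng.uniform(40, 80, n))
    labels = pd.Series(["T1"] * n)
    sexes = pd.Series(["F"] * n)
    curves = incidence_by_age(labels, ages, sexes)
    vals = curves.curves["F"]["T1"].dropna()
    assert np.allclose(vals, 100.0)


def test_incidence_even_split_is_flat_50():
    n = 400
    rng = np.random.default_rng(1)
    ages = pd.Series(np.repeat(rng.uniform(40, 80, n // 2), 2))
    labels = pd.Series(["X", "Y"] * (n // 2))
    sexes = pd.Series(["M"] * n)
    curves = incidence_by_age(labels, ages, sexes)
    df = curves.curves["M"].dropna()
    assert np.allclose(df["X"], 50.0) and np.allclose(df["Y"], 50.0)


def test_incidence_conservation(assignment_default, default_cohort):
    curves = incidence_by_age(assignment_default.sex_view,
                              default_cohort.ages, default_cohort.sexes)
    for df in curves.curves.values():
        sums = df.dropna(how="all").sum(axis=1)
        assert np.allclose(sums, 100.0, atol=1e-6)


def test_incidence_age_linked_mixture_monotone():
    """Mixture weight drifting from X to Y with age yields a falling X
    curve and a rising Y curve."""
    rng = np.random.default_rng(3)
    n = 6000
    ages = pd.Series(rng.uniform(40, 80, n))
    p_y = (ages - 40) / 40
    labels = pd.Series(np.where(rng.uniform(size=n) < p_y, "Y", "X"))
    sexes = pd.Series(["F"] * n)
    df = incidence_by_age(labels, ages, sexes, bin_width=10.0).curves["F"]
    x = df["X"].dropna().to_numpy()
    y = df["Y"].dropna().to_numpy()
    assert np.all(np.diff(x) < 0) and np.all(np.diff(y) > 0)


def test_net_change_worked_example():
    """A: 30->20, B: 10->20, C flat -> net +/-10%."""
    df = pd.DataFrame({"A": [30.0, 20.0], "B": [10.0, 20.0],
                       "C": [60.0, 60.0]}, index=[40.0, 75.0])
    curves = IncidenceCurves(curves={"F": df}, bin_width=5.0)
    net = net_incidence_change(curves)
    assert net["F"]["net_percent"] == pytest.approx(10.0)
    assert net["F"]["per_type"]["A"] == pytest.approx(-10.0)


def test_net_change_flat_curves_zero():
    df = pd.DataFrame({"A": [40.0, 40.0], "B": [60.0, 60.0]},
                      index=[40.0, 75.0])
    net = net_incidence_change(IncidenceCurves(curves={"M": df}, bin_width=5))
    assert net["M"]["net_percent"] == pytest.approx(0.0)


@given(st.lists(st.floats(min_value=0.1, max_value=100.0), min_size=2,
                max_size=8))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_net_change_balance_property(shares):
    """Sum of positive changes equals |sum of negative changes| whenever
    per-bin percentages sum to 100."""
    shares = np.asarray(shares)
    first = 100.0 * shares / shares.sum()
    rolled = np.roll(shares, 1)
    last = 100.0 * rolled / rolled.sum()
    df = pd.DataFrame([first, last], index=[40.0, 75.0],
                      columns=[f"T{i}" for i in range(len(shares))])
    net = net_incidence_change(IncidenceCurves(curves={"F": df}, bin_width=5))
    assert net["F"]["net_percent"] == pytest.approx(
        -net["F"]["negative_sum"], abs=1e-6)


# ----------------------------------------------------------------------
def test_smoother_constant_input():
    rng = np.random.default_rng(0)
    ages = pd.Series(rng.uniform(40, 80, 60))
    vals = pd.Series(np.full(60, 27.3), index=ages.index)
    cur = smoothed_index_curve(vals, ages)
    assert np.allclose(cur["value"], 27.3, atol=1e-9)


def test_smoother_exact_on_linear_input():
    rng = np.random.default_rng(1)
    ages = pd.Series(np.sort(rng.uniform(40, 80, 120)))
    vals = pd.Series(0.25 * ages + 10.0, index=ages.index)
    cur = smoothed_index_curve(vals, ages)
    interior = cur[(cur.age > 45) & (cur.age < 75)]
    assert np.allclose(interior["value"], 0.25 * interior["age"] + 10.0,
                       atol=1e-6)


def test_smoother_requires_span_and_size():
    ages = pd.Series([50.0] * 20)
    vals = pd.Series(np.ones(20))
    with pytest.raises(ValueError, match="span"):
        smoothed_index_curve(vals, ages)
    with pytest.raises(ValueError, match="few"):
        smoothed_index_curve(vals.iloc[:5], pd.Series([40, 50, 60, 70, 80.0]))


def test_type_curves_flat_while_pooled_rises():
    """Age-independent per-type BMI with an aging mixture: each type's
    smoothed curve stays flat although the pooled mean rises with age."""
    rng = np.random.default_rng(5)
    n = 3000
    ages = pd.Series(rng.uniform(40, 80, n))
    p_fat = (ages - 40) / 40
    types = pd.Series(np.where(rng.uniform(size=n) < p_fat, "fat", "lean"))
    bmi = pd.Series(np.where(types == "fat", 31.0, 23.0)
                    + 0.5 * rng.standard_normal(n))
    for t, level in (("lean", 23.0), ("fat", 31.0)):
        cur = smoothed_index_curve(bmi[types == t], ages[types == t])
        assert np.allclose(cur["value"], level, atol=0.3)
    pooled = smoothed_index_curve(bmi, ages)
    assert pooled["value"].iloc[-1] - pooled["value"].iloc[0] > 4.0
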