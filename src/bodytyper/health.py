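"""Physical activity, infarction history, medication and lifestyle by type.

Activity records are day-level accelerometer summaries (wear time,
steps, MET).  Before any statistic, days are filtered by wear-time
validity (>= 18 h on weekdays, >= 20 h on weekend days) and participants
by eligibility (>= 8 valid days including >= 4 weekdays and >= 1 weekend
day).  Health records carry the self-reported infarction history (PMI),
ATC medication-group flags (C, G, H), smoking status and alcohol intake.
"""

from __future__ import annotations

import logging
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .bodytype import BodyTypeAssignment, compare_to_reference

log = logging.getLogger(__name__)

WEEKDAY_MIN_HOURS = 18.0
WEEKEND_MIN_HOURS = 20.0
MIN_VALID_DAYS = 8
MIN_WEEKDAYS = 4
MIN_WEEKEND_DAYS = 1

#: 1 MET = 3.5 ml O2 per kg body weight per minute (resting consumption)
ML_O2_PER_KG_MIN_PER_MET = 3.5

ATC_GROUPS = ("C", "G", "H")


def filter_valid_wear_days(activity: pd.DataFrame,
                           weekday_min: float = WEEKDAY_MIN_HOURS,
                           weekend_min: float = WEEKEND_MIN_HOURS
                           ) -> tuple[pd.DataFrame, pd.Series]:
    """Valid day records and per-participant eligibility.

    A day is valid iff (weekday and wear >= 18 h) or (weekend and wear
    >= 20 h), boundaries inclusive.  A participant is eligible iff they
    have >= 8 valid days of which >= 4 weekdays and >= 1 weekend day.
    Returns (valid day records, eligibility Series by participant id).
    """
    required = {"id", "day_type", "wear_hours"}
    missing = required - set(activity.columns)
    if missing:
        raise ValueError(f"activity records lack columns {sorted(missing)}")
    wear = activity["wear_hours"].astype(float)
    if ((wear < 0) | (wear > 24)).any():
        bad = activity.loc[(wear < 0) | (wear > 24), "id"].iloc[0]
        raise ValueError(f"wear time outside [0, 24] h (participant {bad})")
    bad_type = ~activity["day_type"].isin(["weekday", "weekend"])
    if bad_type.any():
        raise ValueError(
            f"unknown day types: {sorted(activity.loc[bad_type, 'day_type'].unique())}")
    is_weekend = activity["day_type"] == "weekend"
    valid = np.where(is_weekend, wear >= weekend_min, wear >= weekday_min)
    valid_days = activity[valid]

    counts = valid_days.groupby("id")["day_type"].agg(
        n="count",
        n_weekday=lambda s: int((s == "weekday").sum()),
        n_weekend=lambda s: int((s == "weekend").sum()))
    eligible = ((counts["n"] >= MIN_VALID_DAYS)
                & (counts["n_weekday"] >= MIN_WEEKDAYS)
                & (counts["n_weekend"] >= MIN_WEEKEND_DAYS))
    eligible = eligible.reindex(activity["id"].unique(), fill_value=False)
    eligible.index.name = "id"
    return valid_days, eligible.rename("eligible")


def met_to_oxygen(met):
    """Oxygen consumption (ml O2 / kg / min) for a MET level (met x 3.5)."""
    arr = np.asarray(met, dtype=float)
    if np.any(arr < 0):
        raise ValueError("MET must be >= 0")
    out = arr * ML_O2_PER_KG_MIN_PER_MET
    return out.item() if np.isscalar(met) else out


def prevalence(affected: int, total: int) -> float:
    """Percentage affected/total, rounded half-up to one decimal."""
    if total <= 0:
        raise ValueError("total must be > 0")
    if not 0 <= affected <= total:
        raise ValueError("need 0 <= affected <= total")
    pct = Decimal(100 * affected) / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def participant_activity_summary(activity: pd.DataFrame) -> pd.DataFrame:
    """Mean steps and MET over each eligible participant's valid days."""
    valid_days, eligible = filter_valid_wear_days(activity)
    keep = eligible.index[eligible]
    days = valid_days[valid_days["id"].isin(keep)]
    out = days.groupby("id")[["steps", "met"]].mean()
    out.columns = ["mean_steps", "mean_met"]
    return out


def activity_by_type(assignment: BodyTypeAssignment, activity: pd.DataFrame,
                     participants: pd.DataFrame,
                     window_years: float = 10.0) -> pd.DataFrame:
    """Median steps/day and MET per body type with significance marks.

    Participant values are means over valid days (eligible participants
    only); each type's medians are compared against its age-matched
    same-sex reference group by rank-sum test.  Types without eligible
    members are reported missing with a warning.
    """
    summ = participant_activity_summary(activity)
    rows = []
    for label in sorted(assignment.sex_view.unique()):
        members = assignment.members(label, view=True)
        have = members.intersection(summ.index)
        if len(have) == 0:
            log.warning("WARN type %s has no eligible activity data", label)
            continue
        from .bodytype import build_reference_group
        ref = build_reference_group(assignment, label, participants,
                                    window_years, view=True)
        ref_have = ref.intersection(summ.index)
        row = {"type": label, "n_eligible": len(have)}
        for col, name in (("mean_steps", "steps"), ("mean_met", "met")):
            row[f"median_{name}"] = float(summ.loc[have, col].median())
            if len(ref_have):
                mark = compare_to_reference(summ.loc[have, col].to_numpy(),
                                            summ.loc[ref_have, col].to_numpy())
                row[f"{name}_mark"] = mark.mark
                row[f"{name}_p"] = mark.p
                row[f"ref_median_{name}"] = float(summ.loc[ref_have, col].median())
        rows.append(row)
    return pd.DataFrame(rows).set_index("type") if rows else pd.DataFrame()


def cross_type_correlation(mean_bmi: pd.Series, mean_met: pd.Series) -> float:
    """Pearson r across types of mean MET against mean BMI.

    Requires >= 3 types; degenerate (constant) inputs yield NaN with a
    warning.
    """
    common = mean_bmi.index.intersection(mean_met.index)
    if len(common) < 3:
        raise ValueError("need at least 3 types")
    x = mean_bmi.loc[common].astype(float)
    y = mean_met.loc[common].astype(float)
    tol = 1e-12
    if x.std(ddof=0) <= tol * max(1.0, abs(x.mean())) \
            or y.std(ddof=0) <= tol * max(1.0, abs(y.mean())):
        log.warning("WARN constant type means; correlation undefined")
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def bmi_age_slope(summary: pd.DataFrame, exclude: list[str] | None = None,
                  sex: str | None = None) -> float:
    """OLS slope of per-type mean BMI on per-type mean age (kg/m^2 / year).

    ``exclude`` drops outlier types (e.g. the obese ones) from the fit;
    ``sex`` restricts to labels of one family via their first letter
    ("F" also matches the female views of mixed types, "M" the male).
    """
    df = summary.copy()
    if exclude:
        df = df.drop(index=[t for t in exclude if t in df.index])
    if sex is not None:
        fam = df.index.str.match(rf"{sex}\d") | df.index.str.match(rf"B\d{sex}")
        df = df[fam]
    if len(df) < 2:
        raise ValueError("need at least 2 types for a slope")
    x = df["mean_age"].to_numpy(dtype=float)
    y = df["mean_bmi"].to_numpy(dtype=float)
    return float(np.polyfit(x, y, 1)[0])


def medication_frequency(assignment: BodyTypeAssignment, health: pd.DataFrame,
                         atc_group: str) -> pd.Series:
    """Percentage of each body type taking drugs of one ATC group."""
    if atc_group not in ATC_GROUPS:
        raise ValueError(f"unknown ATC group {atc_group!r}; expected one of "
                         f"{ATC_GROUPS}")
    col = f"atc_{atc_group}"
    if col not in health.columns:
        raise ValueError(f"health records lack column {col!r}")
    out = {}
    for label in sorted(assignment.sex_view.unique()):
        members = assignment.members(label, view=True)
        flags = health.loc[health.index.intersection(members), col].astype(bool)
        if len(flags) == 0:
            continue
        out[label] = prevalence(int(flags.sum()), len(flags))
    return pd.Series(out, name=col)


def lifestyle_summary(assignment: BodyTypeAssignment,
                      health: pd.DataFrame) -> pd.DataFrame:
    """Per-type smoker percentage and mean alcohol intake.

    "Smoker" subsumes current and former smoking; the current-only rate
    is reported alongside.  Alcohol is the arithmetic mean in g/day.
    """
    rows = []
    for label in sorted(assignment.sex_view.unique()):
        members = assignment.members(label, view=True)
        sub = health.loc[health.index.intersection(members)]
        if len(sub) == 0:
            continue
        smoking = sub["smoking"].astype(str)
        n = len(sub)
        rows.append({
            "type": label, "n": n,
            "smoker_pct": prevalence(
                int(smoking.isin(["current", "former"]).sum()), n),
            "current_smoker_pct": prevalence(int((smoking == "current").sum()), n),
            "alcohol_mean_g_day": float(sub["alcohol_g_day"].mean()),
        })
    return pd.DataFrame(rows).set_index("type") if rows else pd.DataFrame()
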