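"""Age dependence of body shape: correlations, bodygrams, incidence curves.

A "bodygram" is the polar profile of a group's mean meta-measure values
in Z units; Δ-bodygrams contrast two age strata axis by axis, flagging
pronounced differences (|ΔZ| > 0.2 by default).  Incidence curves track
the percentage share of each body type within age bins per sex, and the
net incidence change summarizes the total redistribution of body types
between the earliest and latest bin.  Smoothed per-type index curves
(LOESS) expose how classical indices develop with age within a type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from statsmodels.nonparametric.smoothers_lowess import lowess

log = logging.getLogger(__name__)


def metameasure_age_correlation(meta: pd.DataFrame, ages: pd.Series,
                                sexes: pd.Series) -> pd.DataFrame:
    """Pearson correlation of each meta-measure with age, per sex.

    Zero-variance meta-measures are reported as missing with a warning.
    """
    out: dict[str, dict[str, float]] = {}
    for sex in sexes.unique():
        ids = sexes.index[sexes == sex]
        if len(ids) < 3:
            raise ValueError(f"need >=3 participants of sex {sex!r}")
        sub = meta.loc[ids]
        a = ages.loc[ids]
        row: dict[str, float] = {}
        for col in meta.columns:
            if sub[col].std(ddof=0) == 0 or a.std(ddof=0) == 0:
                log.warning("WARN zero variance for %s (%s); correlation "
                            "undefined", col, sex)
                row[col] = np.nan
            else:
                row[col] = float(pearsonr(sub[col], a)[0])
        out[sex] = row
    return pd.DataFrame(out).T


def bodygram(meta: pd.DataFrame, members: pd.Index | None = None) -> pd.Series:
    """Mean meta-measure profile of a group (whole cohort when None)."""
    sub = meta if members is None else meta.loc[members]
    if len(sub) == 0:
        raise ValueError("empty group")
    return sub.mean(axis=0)


def delta_bodygram(meta: pd.DataFrame, young: pd.Index, old: pd.Index,
                   flag_threshold: float = 0.2) -> pd.DataFrame:
    """Axis-wise mean(old) - mean(young) with |Δ| > threshold flags."""
    if len(young) == 0 or len(old) == 0:
        raise ValueError("both age strata must be nonempty")
    delta = bodygram(meta, old) - bodygram(meta, young)
    return pd.DataFrame({"delta": delta,
                         "flagged": delta.abs() > flag_threshold})


def age_stratum(participants: pd.DataFrame, lo: float, hi: float,
                sex: str | None = None, closed_right: bool = False) -> pd.Index:
    """Participants with age in [lo, hi) (or [lo, hi] if closed_right)."""
    a = participants["age"]
    mask = (a >= lo) & ((a <= hi) if closed_right else (a < hi))
    if sex is not None:
        mask &= participants["sex"] == sex
    return participants.index[mask]


# ----------------------------------------------------------------------
@dataclass
class IncidenceCurves:
    """Per-sex body-type incidence by age bin, in percent.

    ``curves[sex]`` is a DataFrame bins x type labels whose rows each sum
    to 100 (missing bins are NaN rows).  Bin labels are the half-open
    interval lower edges.
    """
    curves: dict[str, pd.DataFrame]
    bin_width: float

    def net_change(self) -> dict[str, pd.Series]:
        """Per type: incidence(latest bin) - incidence(earliest bin)."""
        out = {}
        for sex, df in self.curves.items():
            valid = df.dropna(how="all")
            if len(valid) < 2:
                raise ValueError(f"need >=2 age bins for sex {sex!r}")
            out[sex] = valid.iloc[-1] - valid.iloc[0]
        return out


def incidence_by_age(labels: pd.Series, ages: pd.Series, sexes: pd.Series,
                     bin_width: float = 5.0) -> IncidenceCurves:
    """Percentage of participants per body type within each sex/age bin.

    Bins are half-open ``[lo, lo + width)`` anchored at the floor of the
    minimum age; the maximum age is included in the last bin.  Empty bins
    are recorded as missing rows, not zeros.
    """
    lo = np.floor(ages.min() / bin_width) * bin_width
    hi = ages.max()
    edges = np.arange(lo, hi + bin_width, bin_width)
    if edges[-1] <= hi:
        edges = np.append(edges, edges[-1] + bin_width)
    curves: dict[str, pd.DataFrame] = {}
    for sex in sorted(sexes.unique()):
        ids = sexes.index[sexes == sex]
        sub_lab, sub_age = labels.loc[ids], ages.loc[ids]
        types = sorted(sub_lab.unique())
        rows = {}
        for i in range(len(edges) - 1):
            in_bin = (sub_age >= edges[i]) & (sub_age < edges[i + 1])
            n = int(in_bin.sum())
            if n == 0:
                rows[edges[i]] = pd.Series(np.nan, index=types)
            else:
                counts = sub_lab[in_bin].value_counts()
                rows[edges[i]] = 100.0 * counts.reindex(types, fill_value=0) / n
        df = pd.DataFrame(rows).T
        df.index.name = "age_bin"
        curves[sex] = df
    return IncidenceCurves(curves=curves, bin_width=bin_width)


def net_incidence_change(curves: IncidenceCurves) -> dict[str, dict]:
    """Net redistribution of body types between the earliest and latest bin.

    For each sex: the per-type signed change and the total ±X% (sum of
    positive changes, which equals the absolute sum of negative changes
    because per-bin percentages sum to 100).
    """
    out: dict[str, dict] = {}
    for sex, delta in curves.net_change().items():
        pos = float(delta[delta > 0].sum())
        neg = float(delta[delta < 0].sum())
        out[sex] = {"per_type": delta, "net_percent": pos,
                    "negative_sum": neg}
    return out


# ----------------------------------------------------------------------
def smoothed_index_curve(values: pd.Series, ages: pd.Series,
                         span: float = 0.5, grid_step: float = 1.0,
                         min_members: int = 10,
                         min_span_years: float = 10.0,
                         name: str = "") -> pd.DataFrame:
    """LOESS curve of an index against age on a 1-year grid.

    Locally weighted linear regression (span = fraction of points per
    local fit) evaluated over the observed age range.  Requires at least
    ``min_members`` observations spanning ``min_span_years`` years.
    """
    ids = values.index.intersection(ages.index)
    v = values.loc[ids].astype(float)
    a = ages.loc[ids].astype(float)
    ok = v.notna() & a.notna()
    v, a = v[ok], a[ok]
    if len(v) < min_members:
        raise ValueError(
            f"too few members for a smoothed curve ({len(v)} < {min_members})"
            + (f" for type {name}" if name else ""))
    if a.max() - a.min() < min_span_years:
        raise ValueError(
            f"age span {a.max() - a.min():.1f} y too short"
            + (f" for type {name}" if name else ""))
    grid = np.arange(np.ceil(a.min()), np.floor(a.max()) + 0.5, grid_step)
    smoothed = lowess(v.to_numpy(), a.to_numpy(), frac=span, it=1,
                      xvals=grid)
    return pd.DataFrame({"age": grid, "value": smoothed})


def per_type_index_curves(assignment_labels: pd.Series, index_values: pd.Series,
                          ages: pd.Series, span: float = 0.5) -> pd.DataFrame:
    """Tidy table of smoothed index curves for every body type."""
    frames = []
    for lab in sorted(assignment_labels.unique()):
        ids = assignment_labels.index[assignment_labels == lab]
        try:
            cur = smoothed_index_curve(index_values.loc[ids], ages.loc[ids],
                                       span=span, name=lab)
        except ValueError as exc:
            log.warning("WARN skipping curve: %s", exc)
            continue
        cur.insert(0, "type", lab)
        frames.append(cur)
    if not frames:
        return pd.DataFrame(columns=["type", "age", "value"])
    return pd.concat(frames, ignore_index=True)
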