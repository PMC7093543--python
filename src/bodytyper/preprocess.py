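"""Normalization of scanner measures and classical body indices.

The preprocessing chain mirrors standard scanner-anthropometry practice:
restrict to the retained measure set, divide each length/girth measure by
the participant's body height (making measures proportions of stature),
then Z-normalize each column so different measures become comparable.
Classical indices (BMI, waist-to-hip, waist-to-height, ABSI) and the WHO
BMI categories are computed alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import (HEIGHT_NORMALIZED, RAW, Z_SCORED, Cohort, MeasureMatrix)

log = logging.getLogger(__name__)

#: WHO BMI category boundaries (kg/m^2), half-open intervals
#: [0, 18.5) underweight, [18.5, 25) normal, [25, 30) overweight, [30, inf) obese.
BMI_EDGES = (18.5, 25.0, 30.0)
BMI_CATEGORIES = ("underweight", "normal", "overweight", "obese")


def select_measures(matrix: MeasureMatrix, retained: list[str]) -> MeasureMatrix:
    """Restrict the matrix to the retained measure set, order preserved.

    Raises ``KeyError`` listing any retained name absent from the matrix.
    """
    missing = [m for m in retained if m not in matrix.data.columns]
    if missing:
        raise KeyError(f"retained measures not present in matrix: {missing}")
    cols = [c for c in matrix.data.columns if c in set(retained)]
    dropped = matrix.data[cols].isna().any(axis=1)
    data = matrix.data[cols]
    if dropped.any():
        log.warning("WARN dropping %d rows with missing retained measures",
                    int(dropped.sum()))
        data = data.loc[~dropped]
    return matrix.with_data(data)


def height_normalize(matrix: MeasureMatrix, heights_cm: pd.Series) -> MeasureMatrix:
    """Divide every length/girth column by the participant's body height.

    Dimensionless index columns (bmi, whtr) are kept as they are.
    Heights must be positive and in the same unit as the measures (cm).
    """
    matrix.require_state(RAW, "height_normalize")
    heights = heights_cm.reindex(matrix.data.index)
    if heights.isna().any():
        missing = list(matrix.data.index[heights.isna()])[:5]
        raise ValueError(f"no height for participants {missing}")
    bad = heights <= 0
    if bad.any():
        raise ValueError(
            "non-positive height for participants "
            f"{list(matrix.data.index[bad])[:5]}")
    data = matrix.data.copy()
    keep = [c for c in data.columns if c in matrix.dimensionless]
    scale_cols = [c for c in data.columns if c not in matrix.dimensionless]
    data[scale_cols] = data[scale_cols].div(heights, axis=0)
    if keep:
        log.debug("height_normalize: %d index columns kept raw: %s",
                  len(keep), keep)
    return matrix.with_data(data, HEIGHT_NORMALIZED)


def z_normalize(matrix: MeasureMatrix, by_sex: pd.Series | None = None) -> MeasureMatrix:
    """Z-score each column: subtract mean, divide by population sd (ddof=0).

    By default the normalization pools both sexes (the sex contrast stays
    visible in the Z values); pass ``by_sex`` to normalize within sex.
    Requires at least 2 participants; a zero-variance column is an error.
    """
    matrix.require_state(HEIGHT_NORMALIZED, "z_normalize")
    if len(matrix.data) < 2:
        raise ValueError("z_normalize needs at least 2 participants")

    def _z(df: pd.DataFrame) -> pd.DataFrame:
        sd = df.std(ddof=0)
        zero = sd[sd == 0]
        if len(zero):
            raise ValueError(
                f"zero-variance column(s): {list(zero.index)}")
        return (df - df.mean()) / sd

    if by_sex is None:
        data = _z(matrix.data)
    else:
        groups = by_sex.reindex(matrix.data.index)
        parts = [_z(matrix.data.loc[groups == g]) for g in groups.unique()]
        data = pd.concat(parts).reindex(matrix.data.index)
    return matrix.with_data(data, Z_SCORED)


def normalize_cohort(cohort: Cohort, retained: list[str] | None = None,
                     per_sex: bool = False) -> MeasureMatrix:
    """Full chain select -> height-normalize -> Z-score for a cohort."""
    from .measures import retained_names
    retained = retained_names() if retained is None else retained
    retained = [m for m in retained if m in cohort.measures.data.columns]
    mm = select_measures(cohort.measures, retained)
    mm = height_normalize(mm, cohort.heights_cm)
    return z_normalize(mm, cohort.sexes if per_sex else None)


# ----------------------------------------------------------------------
@dataclass
class BodyIndexSet:
    """Classical body indices for one participant or an aligned vector.

    BMI kg/m^2; WTH and WHtR dimensionless; ABSI in m^(11/6) kg^(-2/3).
    """
    bmi: float | np.ndarray
    wth: float | np.ndarray
    whtr: float | np.ndarray
    absi: float | np.ndarray

    @property
    def bmi_category(self):
        return bmi_category(self.bmi)


def _check_positive(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError(f"{name} must be positive and finite")
    return arr


def compute_body_indices(weight_kg, height_m, waist_m, hip_m) -> BodyIndexSet:
    """BMI, waist-to-hip, waist-to-height and ABSI from metric inputs.

    ABSI = waist / (BMI^(2/3) * height^(1/2)) with waist and height in
    meters -- waist circumference normalized for the girth expected at a
    given BMI and stature.
    """
    w = _check_positive("weight", weight_kg)
    h = _check_positive("height", height_m)
    waist = _check_positive("waist", waist_m)
    hip = _check_positive("hip", hip_m)
    bmi = w / h ** 2
    return BodyIndexSet(
        bmi=bmi, wth=waist / hip, whtr=waist / h,
        absi=waist / (bmi ** (2.0 / 3.0) * np.sqrt(h)))


def cohort_body_indices(cohort: Cohort,
                        waist_col: str = "waist_girth",
                        hip_col: str = "hip_girth") -> pd.DataFrame:
    """Index table for a cohort (heights and girths converted cm -> m)."""
    idx = compute_body_indices(
        cohort.weights_kg.to_numpy(),
        cohort.heights_cm.to_numpy() / 100.0,
        cohort.measures.data[waist_col].to_numpy() / 100.0,
        cohort.measures.data[hip_col].to_numpy() / 100.0)
    out = pd.DataFrame({"bmi": idx.bmi, "wth": idx.wth, "whtr": idx.whtr,
                        "absi": idx.absi}, index=cohort.participants.index)
    out["bmi_category"] = bmi_category(out["bmi"].to_numpy())
    return out


def bmi_category(bmi):
    """WHO category: underweight <18.5, normal [18.5, 25), overweight
    [25, 30), obese >=30.  Accepts scalars or arrays; BMI must be > 0."""
    arr = np.asarray(bmi, dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError("BMI must be positive and finite")
    cats = np.select(
        [arr < BMI_EDGES[0], arr < BMI_EDGES[1], arr < BMI_EDGES[2]],
        BMI_CATEGORIES[:3], default=BMI_CATEGORIES[3])
    return cats.item() if np.isscalar(bmi) else cats
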