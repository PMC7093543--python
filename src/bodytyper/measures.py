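"""Catalog of scanner-derived body measures.

A whole-body laser scanner reports on the order of 150 length and girth
measures per participant.  The analysis pipeline groups the retained
measures into 13 blocks of mutually correlated measures (labeled A..M),
each of which later becomes one "meta-measure".  This module defines the
default catalog: measure names, block membership, per-sex location/scale
used by the synthetic-cohort generator, and which measures are retained
for analysis.

The named measures follow the standard scanner nomenclature (shoulder
width, chest girth, inseam length, ...).  Each block additionally carries
a few auxiliary channels (``*_auxNN``) standing in for the scanner's many
minor variants of the same dimension, so that the retained set has the
realistic size of 134 columns.  A further 21 ``scanner_extra_*`` channels
are emitted but flagged as not retained.
"""

from __future__ import annotations

from dataclasses import dataclass

BLOCK_LABELS = list("ABCDEFGHIJKLM")

BLOCK_TITLES = {
    "A": "Shoulder width",
    "B": "Upper body girths",
    "C": "Thigh girth",
    "D": "Head circumference",
    "E": "Shoulder angle",
    "F": "Sideseam length",
    "G": "Inseam length",
    "H": "Upper body lengths",
    "I": "Arm length",
    "J": "Neck length",
    "K": "Neck girth",
    "L": "Arm girth",
    "M": "Torso length",
}

#: Measures that are dimensionless indices rather than cm-scale dimensions.
#: They are exempt from height normalization.
INDEX_MEASURES = ("bmi", "whtr")


@dataclass(frozen=True)
class MeasureDef:
    """One scanner measure: name, block, distribution parameters.

    ``mean_male``/``mean_female`` are cm (degrees for angles); ``cv`` is the
    coefficient of variation of the within-sex marginal.  ``kind`` selects
    the generator's marginal family: ``girth`` measures are log-normal
    (positive, right-skewed), ``length``/``angle`` are normal, ``index``
    columns are derived from weight/height/waist and carry no parameters
    of their own.
    """

    name: str
    block: str | None
    kind: str  # length | girth | angle | index | extra
    mean_male: float = 0.0
    mean_female: float = 0.0
    cv: float = 0.05
    retained: bool = True


# (name, kind, mean_male, mean_female, cv) per block; from published
# population anthropometry, rounded.  Waist girth is calibrated explicitly
# to the study's reported marginal (101 +/- 12 men, 91 +/- 13 women).
_NAMED: dict[str, list[tuple]] = {
    "A": [
        ("shoulder_width", "length", 46.0, 41.0, 0.050),
        ("width_of_armpits", "length", 40.0, 36.0, 0.055),
        ("cross_shoulder_length", "length", 48.0, 43.0, 0.050),
    ],
    "B": [
        ("chest_girth", "girth", 106.0, 99.0, 0.080),
        ("waist_girth", "girth", 101.0, 91.0, 0.11881, ),  # sd 12 / 13 cm
        ("hip_girth", "girth", 105.0, 108.0, 0.075),
        ("belly_circumference", "girth", 103.0, 95.0, 0.095),
        ("bmi", "index", 0.0, 0.0, 0.0),
        ("whtr", "index", 0.0, 0.0, 0.0),
    ],
    "C": [
        ("thigh_girth_left", "girth", 57.0, 60.0, 0.090),
        ("thigh_girth_right", "girth", 57.0, 60.0, 0.090),
    ],
    "D": [
        ("head_circumference", "girth", 57.5, 55.5, 0.025),
        ("crotch_length", "length", 78.0, 74.0, 0.070),
    ],
    "E": [
        ("shoulder_angle_left", "angle", 22.0, 23.0, 0.150),
        ("shoulder_angle_right", "angle", 22.0, 23.0, 0.150),
    ],
    "F": [
        ("sideseam_length_left", "length", 110.0, 104.0, 0.040),
        ("sideseam_length_right", "length", 110.0, 104.0, 0.040),
        ("ankle_height_sideseam_left", "length", 7.5, 7.0, 0.100),
        ("ankle_height_sideseam_right", "length", 7.5, 7.0, 0.100),
        ("head_height", "length", 23.0, 22.0, 0.060),
    ],
    "G": [
        ("inseam_length_left", "length", 82.0, 78.0, 0.050),
        ("inseam_length_right", "length", 82.0, 78.0, 0.050),
        ("ankle_height_inseam_left", "length", 7.0, 6.6, 0.100),
        ("ankle_height_inseam_right", "length", 7.0, 6.6, 0.100),
        ("crotch_height", "length", 83.0, 79.0, 0.050),
    ],
    "H": [
        ("distance_neck_to_hip", "length", 64.0, 58.0, 0.050),
        ("distance_neck_to_knee", "length", 107.0, 99.0, 0.040),
        ("distance_waist_to_knee", "length", 60.0, 56.0, 0.050),
    ],
    "I": [
        ("arm_length_left", "length", 62.0, 57.0, 0.040),
        ("arm_length_right", "length", 62.0, 57.0, 0.040),
        ("up_arm_length_left", "length", 37.0, 34.0, 0.050),
        ("up_arm_length_right", "length", 37.0, 34.0, 0.050),
    ],
    "J": [
        ("neck_length", "length", 9.5, 9.0, 0.120),
    ],
    "K": [
        ("neck_girth_base", "girth", 43.0, 37.0, 0.060),
        ("neck_girth_middle", "girth", 40.0, 34.0, 0.060),
    ],
    "L": [
        ("forearm_girth_left", "girth", 29.0, 25.5, 0.070),
        ("forearm_girth_right", "girth", 29.0, 25.5, 0.070),
        ("up_arm_girth_left", "girth", 32.0, 30.0, 0.090),
        ("up_arm_girth_right", "girth", 32.0, 30.0, 0.090),
        ("elbow_girth_left", "girth", 27.0, 25.0, 0.070),
        ("elbow_girth_right", "girth", 27.0, 25.0, 0.070),
        ("ankle_girth_left", "girth", 23.0, 22.0, 0.070),
        ("ankle_girth_right", "girth", 23.0, 22.0, 0.070),
    ],
    "M": [
        ("neck_to_waist_left", "length", 47.0, 43.0, 0.050),
        ("neck_to_waist_right", "length", 47.0, 43.0, 0.050),
        ("neck_to_waist_central", "length", 47.0, 43.0, 0.050),
    ],
}

# Auxiliary channels per block bring the retained set to 134 columns.
_N_AUX = {"A": 7, "B": 7, "C": 6, "D": 6, "E": 6, "F": 7, "G": 7,
          "H": 7, "I": 7, "J": 7, "K": 7, "L": 7, "M": 7}

_AUX_SLUG = {
    "A": "shoulder_width", "B": "upper_body_girth", "C": "thigh_girth",
    "D": "head", "E": "shoulder_angle", "F": "sideseam", "G": "inseam",
    "H": "upper_body_length", "I": "arm_length", "J": "neck_length",
    "K": "neck_girth", "L": "arm_girth", "M": "torso_length",
}

N_EXTRA = 21  # emitted but not retained


#: Scanner measures scale isometrically with body height in the generator;
#: each measure's total cv must therefore exceed the height cv (~0.04).
MIN_CV = 0.055


def default_catalog() -> list[MeasureDef]:
    """Build the default 155-measure catalog (134 retained + 21 extras)."""
    defs: list[MeasureDef] = []
    for block in BLOCK_LABELS:
        for name, kind, mm, mf, cv in _NAMED[block]:
            cv = cv if kind == "index" else max(cv, MIN_CV)
            defs.append(MeasureDef(name, block, kind, mm, mf, cv))
        # auxiliary channels: variants of the block's first named measure
        base = _NAMED[block][0]
        _, kind, mm, mf, cv = base
        cv = max(cv, MIN_CV)
        for i in range(_N_AUX[block]):
            factor = 0.82 + 0.04 * i
            defs.append(MeasureDef(
                f"{_AUX_SLUG[block]}_aux{i + 1:02d}", block, kind,
                round(mm * factor, 2), round(mf * factor, 2), cv))
    for i in range(N_EXTRA):
        defs.append(MeasureDef(
            f"scanner_extra_{i + 1:02d}", None, "extra",
            30.0 + 2.0 * i, 28.0 + 2.0 * i, 0.08, retained=False))
    return defs


def catalog_names(defs: list[MeasureDef] | None = None) -> list[str]:
    defs = default_catalog() if defs is None else defs
    return [d.name for d in defs]


def retained_names(defs: list[MeasureDef] | None = None) -> list[str]:
    defs = default_catalog() if defs is None else defs
    return [d.name for d in defs if d.retained]


def block_members(defs: list[MeasureDef] | None = None,
                  include_indices: bool = True) -> dict[str, list[str]]:
    """Mapping block label -> member measure names, in catalog order."""
    defs = default_catalog() if defs is None else defs
    out: dict[str, list[str]] = {b: [] for b in BLOCK_LABELS}
    for d in defs:
        if d.block is None:
            continue
        if d.kind == "index" and not include_indices:
            continue
        out[d.block].append(d.name)
    return out
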