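"""In-memory cohort container and the measure matrix with normalization state.

A :class:`Cohort` bundles the participant table (id, sex, age, height,
weight), the scanner measure matrix (cm), day-level activity records and
health/lifestyle records, together with the generator config and seed
that produced it (provenance).

A :class:`MeasureMatrix` wraps a participants x measures DataFrame plus an
explicit normalization state: ``raw`` (cm) -> ``height_normalized``
(divided by body height) -> ``z_scored``.  State transitions are enforced
by the preprocessing operations; skipping a state is an error.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
import yaml

if TYPE_CHECKING:  # pragma: no cover
    from .config import GeneratorConfig

RAW = "raw"
HEIGHT_NORMALIZED = "height_normalized"
Z_SCORED = "z_scored"
_STATES = (RAW, HEIGHT_NORMALIZED, Z_SCORED)


class StateError(ValueError):
    """A normalization step was applied in the wrong state."""


@dataclass
class MeasureMatrix:
    """Participants x measures with an explicit normalization state.

    ``dimensionless`` names columns exempt from height normalization
    (index columns such as bmi and whtr).
    """

    data: pd.DataFrame                 # index: participant id
    state: str = RAW
    dimensionless: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.state not in _STATES:
            raise ValueError(f"unknown normalization state {self.state!r}")

    @property
    def participant_ids(self) -> pd.Index:
        return self.data.index

    @property
    def measure_names(self) -> list[str]:
        return list(self.data.columns)

    def require_state(self, state: str, op: str) -> None:
        if self.state != state:
            raise StateError(
                f"{op} requires state {state!r}, matrix is {self.state!r}")

    def with_data(self, data: pd.DataFrame, state: str | None = None) -> "MeasureMatrix":
        return replace(self, data=data, state=self.state if state is None else state)


@dataclass
class Cohort:
    """A (synthetic or loaded) cohort with all participant-level tables."""

    participants: pd.DataFrame          # id-indexed: sex, age, height_cm, weight_kg [, archetype]
    measures: MeasureMatrix             # raw scanner measures, cm
    activity: pd.DataFrame | None = None   # id, day, day_type, wear_hours, steps, met
    health: pd.DataFrame | None = None     # id-indexed: pmi, atc_C/G/H, smoking, alcohol_g_day
    config: "GeneratorConfig | None" = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.measures.data.index.equals(self.participants.index):
            raise ValueError("measure rows do not match the participant table")

    @property
    def n(self) -> int:
        return len(self.participants)

    @property
    def sexes(self) -> pd.Series:
        return self.participants["sex"]

    @property
    def ages(self) -> pd.Series:
        return self.participants["age"]

    @property
    def heights_cm(self) -> pd.Series:
        return self.participants["height_cm"]

    @property
    def weights_kg(self) -> pd.Series:
        return self.participants["weight_kg"]

    # ------------------------------------------------------------------
    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write the cohort as CSV tables plus a YAML provenance sidecar."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        measures = pd.concat([self.participants, self.measures.data], axis=1)
        paths["measures"] = out / "measures.csv"
        measures.to_csv(paths["measures"], index_label="id", float_format="%.6g")

        if self.activity is not None:
            paths["activity"] = out / "activity.csv"
            self.activity.to_csv(paths["activity"], index=False, float_format="%.6g")
        if self.health is not None:
            paths["health"] = out / "health.csv"
            self.health.to_csv(paths["health"], index_label="id", float_format="%.6g")

        sidecar = {"seed": self.seed, "n": self.n,
                   "measure_state": self.measures.state}
        if self.config is not None:
            sidecar["generator"] = self.config.to_dict()
        paths["sidecar"] = out / "cohort.yaml"
        with open(paths["sidecar"], "w") as fh:
            yaml.safe_dump(sidecar, fh, sort_keys=False)
        return paths


def body_mass_index(weight_kg, height_cm):
    """BMI in kg/m^2 from weight (kg) and height (cm); vectorized."""
    h = np.asarray(height_cm, dtype=float) / 100.0
    return np.asarray(weight_kg, dtype=float) / h ** 2
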