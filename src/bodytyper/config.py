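"""Configuration objects for the synthetic-cohort generator and the pipeline.

The generator emulates a population-based adult cohort (ages 40-80, both
sexes) as characterized by whole-body scanner anthropometry:

* per-sex marginals for height, weight, waist, daily steps, MET and
  alcohol intake, calibrated to the study population's summary table;
* 13 blocks of mutually correlated scanner measures (the later
  meta-measures A..M), with configurable within/cross-block correlation;
* a mixture of 15 body-shape archetypes (6 female, 7 male, 2 mixed) whose
  mean-offset vectors in block space encode qualitative shape descriptors
  (e.g. "massive body, big girths" = large positive offsets on the girth
  blocks); the offsets are design defaults, not measured values;
* linear age drift per block in Z-units per decade (girths increase,
  upper-body lengths and thigh girth decrease);
* physical activity anti-correlated with adiposity and age, and Bernoulli
  health outcomes (infarction history, medication, smoking).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

from .measures import (BLOCK_LABELS, MeasureDef, block_members,
                       default_catalog)


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class Marginal:
    """Target (mean, sd) of a per-sex marginal distribution."""
    mean: float
    sd: float

    def validate(self, name: str) -> None:
        if not self.sd > 0:
            raise ConfigError(f"marginal {name!r}: sd must be > 0, got {self.sd}")


@dataclass
class SexMarginals:
    height: Marginal   # cm
    weight: Marginal   # kg
    waist: Marginal    # cm
    steps: Marginal    # steps/day
    met: Marginal      # multiples of resting metabolic rate
    alcohol: Marginal  # g/day

    def validate(self, sex: str) -> None:
        for f in dataclasses.fields(self):
            getattr(self, f.name).validate(f"{sex}.{f.name}")


@dataclass
class BlockSpec:
    """One block of correlated measures.

    Cross-block correlation between two blocks is the geometric mean of
    their ``cross_corr`` values (all members share a common factor with
    loading sqrt(cross_corr)).
    """
    label: str
    members: list[str]
    within_corr: float = 0.8
    cross_corr: float = 0.2

    def validate(self) -> None:
        if not self.members:
            raise ConfigError(f"block {self.label!r} has no members")
        if not 0.0 <= self.cross_corr < 1.0 or not 0.0 <= self.within_corr < 1.0:
            raise ConfigError(
                f"block {self.label!r}: correlations must lie in [0, 1); got "
                f"within={self.within_corr}, cross={self.cross_corr}")
        if self.cross_corr > self.within_corr:
            raise ConfigError(
                f"block {self.label!r}: cross-block correlation "
                f"{self.cross_corr} exceeds within-block correlation "
                f"{self.within_corr} (implied covariance not positive definite)")


@dataclass
class ArchetypeSpec:
    """One body-shape archetype of the planted mixture.

    ``offsets`` live in block (meta-measure) space, in Z units.  ``sex``
    is "F", "M" or "mixed"; mixed archetypes recruit both sexes and are
    androgynous: their members' sex-specific measure levels are shrunk
    toward the mid-sex mean by ``androgyny`` (1 = fully androgynous).
    ``age_mean``/``age_sd`` tilt the mixture weight with member age,
    giving archetypes distinct age profiles while the cohort age marginal
    stays uniform.
    """
    label: str
    sex: str                       # "F" | "M" | "mixed"
    weight: float                  # mixing weight within the sex
    offsets: dict[str, float] = field(default_factory=dict)
    age_mean: float | None = None
    age_sd: float = 12.0
    androgyny: float = 0.0

    def validate(self) -> None:
        if self.sex not in ("F", "M", "mixed"):
            raise ConfigError(f"archetype {self.label!r}: sex must be F/M/mixed")
        if self.weight < 0:
            raise ConfigError(f"archetype {self.label!r}: negative weight")
        bad = set(self.offsets) - set(BLOCK_LABELS)
        if bad:
            raise ConfigError(
                f"archetype {self.label!r}: offsets refer to unknown blocks {sorted(bad)}")
        if not 0.0 <= self.androgyny <= 1.0:
            raise ConfigError(f"archetype {self.label!r}: androgyny outside [0, 1]")


def _default_marginals() -> dict[str, SexMarginals]:
    # Study-population summary values (male / female).
    return {
        "M": SexMarginals(
            height=Marginal(176.0, 7.0), weight=Marginal(86.0, 14.0),
            waist=Marginal(101.0, 12.0), steps=Marginal(9683.0, 4011.0),
            met=Marginal(1.41, 0.25), alcohol=Marginal(18.8, 21.7)),
        "F": SexMarginals(
            height=Marginal(165.0, 7.0), weight=Marginal(71.0, 14.0),
            waist=Marginal(91.0, 13.0), steps=Marginal(9903.0, 3682.0),
            met=Marginal(1.35, 0.24), alcohol=Marginal(5.9, 10.0)),
    }


def default_blocks(catalog: list[MeasureDef] | None = None,
                   within_corr: float = 0.8,
                   cross_corr: float = 0.2) -> list[BlockSpec]:
    members = block_members(catalog, include_indices=True)
    return [BlockSpec(label, members[label], within_corr, cross_corr)
            for label in BLOCK_LABELS]


def default_archetypes() -> list[ArchetypeSpec]:
    """The 15 default archetypes (6 F, 7 M, 2 mixed).

    Offset patterns translate the qualitative shape descriptors into
    block-space Z offsets; amplitudes are chosen so that archetypes form
    separable clusters in meta-measure space (a design requirement of the
    generator, needed for planted-structure recovery tests).  Age means
    stagger the types along the 40-80 year range.
    """
    A = [
        # --- mixed ---
        ArchetypeSpec("B1", "mixed", 0.06, age_mean=46.0, androgyny=0.85,
                      offsets={"F": 3.0, "G": 2.0, "H": 3.0, "B": -3.0,
                               "L": -2.0, "D": -2.0, "M": 2.0}),
        ArchetypeSpec("B2", "mixed", 0.06, age_mean=62.0, androgyny=0.85,
                      offsets={"B": 3.0, "A": 2.5, "G": -3.0, "F": -2.5,
                               "J": 2.0, "D": 2.0, "K": -1.0, "M": -1.5}),
        # --- female ---
        ArchetypeSpec("F-slim", "F", 0.1467, age_mean=48.0,
                      offsets={"B": -3.0, "K": -2.5, "L": -2.5, "A": -2.5,
                               "C": -2.0, "E": -2.0}),
        ArchetypeSpec("F-small-arms-long-chest", "F", 0.1467, age_mean=52.0,
                      offsets={"L": -3.0, "I": -2.5, "M": 3.0, "J": 2.5,
                               "H": 1.5, "B": -1.0}),
        ArchetypeSpec("F-big-upper-big-thighs", "F", 0.1467, age_mean=56.0,
                      offsets={"B": 2.5, "A": 2.0, "C": 3.5, "M": 2.0, "H": 1.5}),
        ArchetypeSpec("F-massive", "F", 0.1467, age_mean=58.0,
                      offsets={"B": 3.5, "K": 3.0, "L": 3.0, "C": 1.0,
                               "D": 2.0, "E": 1.0, "M": 1.5}),
        ArchetypeSpec("F-short-upper-body", "F", 0.1467, age_mean=64.0,
                      offsets={"H": -3.5, "M": -3.0, "J": -2.5, "B": 1.0, "F": -1.5}),
        ArchetypeSpec("F-drooping-shoulders", "F", 0.1465, age_mean=68.0,
                      offsets={"E": 3.5, "A": 3.0, "H": -1.0, "L": -1.5,
                               "C": -1.5, "K": -1.0}),
        # --- male ---
        ArchetypeSpec("M-slim-long-extremities", "M", 0.1257, age_mean=48.0,
                      offsets={"B": -2.5, "I": 3.5, "G": 3.0, "F": 1.5,
                               "K": -2.5, "J": -2.0, "C": 1.0}),
        ArchetypeSpec("M-long-upper-body", "M", 0.1257, age_mean=52.0,
                      offsets={"H": 3.5, "M": 3.0, "J": 2.0, "B": -1.5,
                               "I": 1.0, "E": -2.0}),
        ArchetypeSpec("M-big-arms-neck", "M", 0.1257, age_mean=55.0,
                      offsets={"L": 3.5, "K": 2.5, "I": 1.5, "E": -2.0,
                               "J": 1.5, "C": 1.5}),
        ArchetypeSpec("M-broad-neck-short-legs", "M", 0.1257, age_mean=58.0,
                      offsets={"K": 3.5, "G": -3.0, "F": -2.5, "J": -1.5, "D": 1.5}),
        ArchetypeSpec("M-massive-upper-body", "M", 0.1257, age_mean=60.0,
                      offsets={"B": 3.5, "A": 3.0, "K": 1.5, "L": 2.0,
                               "C": -1.0, "D": 1.5, "E": -1.5}),
        ArchetypeSpec("M-long-body-short-extremities", "M", 0.1257, age_mean=62.0,
                      offsets={"M": 2.5, "H": 2.5, "I": -3.0, "G": -2.5,
                               "D": 2.0, "E": 1.5}),
        ArchetypeSpec("M-broad-neck-thin-legs", "M", 0.1258, age_mean=66.0,
                      offsets={"K": 3.0, "C": -3.5, "J": 2.0, "E": 2.5, "A": 1.5}),
    ]
    return A


def default_age_effect() -> dict[str, float]:
    """Linear age drift per block, Z-units per decade.

    Girth blocks drift upward with age; upper-body lengths (H) and thigh
    girth (C) drift downward.
    """
    return {"A": 0.10, "B": 0.25, "C": -0.15, "D": 0.05, "E": 0.20,
            "F": -0.05, "G": -0.05, "H": -0.20, "I": 0.10, "J": 0.10,
            "K": 0.20, "L": 0.20, "M": 0.10}


@dataclass
class GeneratorConfig:
    """Full parameterization of the synthetic cohort."""

    n_male: int = 4766
    n_female: int = 5234
    age_min: float = 40.0
    age_max: float = 80.0
    marginals: dict[str, SexMarginals] = field(default_factory=_default_marginals)
    height_weight_corr: float = 0.5
    adiposity_loading: float = 0.75   # loading of log-weight on the girth-block factor
    #: Scale of the continuous per-participant block factor relative to the
    #: template's block-shared variance.  1.0 reproduces the correlation
    #: template exactly (no archetypes); the default < 1 concentrates the
    #: block-level variance in the archetype mixture instead, making the
    #: planted body-shape clusters separable in meta-measure space.
    individuality: float = 0.5
    blocks: list[BlockSpec] = field(default_factory=default_blocks)
    archetypes: list[ArchetypeSpec] = field(default_factory=default_archetypes)
    age_effect: dict[str, float] = field(default_factory=default_age_effect)
    catalog: list[MeasureDef] = field(default_factory=default_catalog)
    # activity
    activity_fraction: dict[str, float] = field(
        default_factory=lambda: {"M": 0.277, "F": 0.210})
    n_days: int = 10
    invalid_day_fraction: float = 0.15
    met_bmi_slope: float = -0.030     # MET per kg/m^2
    met_age_slope: float = -0.005     # MET per year
    steps_bmi_slope: float = -150.0   # steps/day per kg/m^2
    steps_age_slope: float = -60.0    # steps/day per year
    # health
    pmi_rate: dict[str, float] = field(
        default_factory=lambda: {"M": 0.040, "F": 0.011})
    smoking_current: dict[str, float] = field(
        default_factory=lambda: {"M": 0.228, "F": 0.194})
    smoking_former: dict[str, float] = field(
        default_factory=lambda: {"M": 0.360, "F": 0.208})
    alcohol_zero_fraction: dict[str, float] = field(
        default_factory=lambda: {"M": 0.25, "F": 0.45})
    medication_rates: dict[str, dict[str, float]] = field(
        default_factory=lambda: {"C": {"M": 0.28, "F": 0.30},
                                 "G": {"M": 0.02, "F": 0.12},
                                 "H": {"M": 0.04, "F": 0.09}})
    seed: int = 0

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if self.n_male < 0 or self.n_female < 0:
            raise ConfigError("participant counts must be non-negative")
        if not self.age_min < self.age_max:
            raise ConfigError("age_min must be below age_max")
        for sex in ("M", "F"):
            self.marginals[sex].validate(sex)
        if not -1 < self.height_weight_corr < 1:
            raise ConfigError("height_weight_corr must lie in (-1, 1)")
        if self.height_weight_corr ** 2 + self.adiposity_loading ** 2 >= 1:
            raise ConfigError(
                "height_weight_corr^2 + adiposity_loading^2 must be < 1")
        if not 0 < self.individuality <= 1:
            raise ConfigError("individuality must lie in (0, 1]")
        seen: set[str] = set()
        for b in self.blocks:
            b.validate()
            dup = seen & set(b.members)
            if dup:
                raise ConfigError(
                    f"measures {sorted(dup)} appear in more than one block "
                    f"(second occurrence in block {b.label!r})")
            seen |= set(b.members)
        names = {d.name for d in self.catalog}
        missing = seen - names
        if missing:
            raise ConfigError(f"block members missing from catalog: {sorted(missing)}")
        for a in self.archetypes:
            a.validate()
        for sex in ("M", "F"):
            tot = sum(a.weight for a in self.archetypes
                      if a.sex in (sex, "mixed"))
            if abs(tot - 1.0) > 1e-6:
                raise ConfigError(
                    f"archetype mixing weights for sex {sex} sum to {tot:.6f}, not 1")
        for sex, r in self.pmi_rate.items():
            if not 0 <= r <= 1:
                raise ConfigError(f"PMI rate for {sex} outside [0, 1]: {r}")
        for grp, rates in self.medication_rates.items():
            for sex, r in rates.items():
                if not 0 <= r <= 1:
                    raise ConfigError(
                        f"medication rate {grp}/{sex} outside [0, 1]: {r}")
        for sex in ("M", "F"):
            p_c = self.smoking_current[sex]
            p_f = self.smoking_former[sex]
            if min(p_c, p_f) < 0 or p_c + p_f > 1:
                raise ConfigError(f"smoking probabilities invalid for sex {sex}")
        if not 0 <= self.invalid_day_fraction <= 1:
            raise ConfigError("invalid_day_fraction outside [0, 1]")
        if self.n_days < 1:
            raise ConfigError("n_days must be >= 1")

    # ------------------------------------------------------------------
    @classmethod
    def blocks_only(cls, n: int = 2000, seed: int = 0,
                    within_corr: float = 0.8,
                    cross_corr: float = 0.2) -> "GeneratorConfig":
        """Structure-recovery profile: the pure 13-block covariance template.

        Archetype offsets, age drift and sex dimorphism of the scanner
        measures are switched off so that the generated measure
        correlations equal the planted template.  Used to exercise
        correlation-block recovery in isolation.
        """
        catalog = [dataclasses.replace(d, mean_female=d.mean_male)
                   for d in default_catalog()]
        arch = [dataclasses.replace(a, offsets={}, age_mean=None)
                for a in default_archetypes()]
        cfg = cls(
            n_male=n // 2, n_female=n - n // 2, seed=seed,
            blocks=default_blocks(catalog, within_corr, cross_corr),
            archetypes=arch,
            age_effect={b: 0.0 for b in BLOCK_LABELS},
            catalog=catalog, individuality=1.0)
        cfg.marginals["F"] = dataclasses.replace(cfg.marginals["M"])
        return cfg

    # ------------------------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["catalog"] = [dataclasses.asdict(m) for m in self.catalog]
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "GeneratorConfig":
        d = dict(d)
        if "marginals" in d:
            d["marginals"] = {
                sex: SexMarginals(**{k: Marginal(**v) for k, v in m.items()})
                for sex, m in d["marginals"].items()}
        if "blocks" in d:
            d["blocks"] = [BlockSpec(**b) for b in d["blocks"]]
        if "archetypes" in d:
            d["archetypes"] = [ArchetypeSpec(**a) for a in d["archetypes"]]
        if "catalog" in d:
            d["catalog"] = [MeasureDef(**m) for m in d["catalog"]]
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ----------------------------------------------------------------------
@dataclass
class LinkRule:
    """Selection rule for "most similar" participant pairs.

    ``knn``: each participant's ``m`` nearest neighbours; a pair is a link
    if either side selects the other.  ``quantile``: all pairs whose
    distance falls below the given quantile of cross-type distances.
    Distance ties break deterministically by participant-id order.
    """
    method: str = "knn"
    m: int = 3
    quantile: float = 0.01

    def validate(self) -> None:
        if self.method not in ("knn", "quantile"):
            raise ConfigError(f"unknown link rule {self.method!r}")
        if self.method == "knn" and self.m < 1:
            raise ConfigError("link rule: m must be >= 1")
        if self.method == "quantile" and not 0 < self.quantile < 1:
            raise ConfigError("link rule: quantile must lie in (0, 1)")


@dataclass
class PipelineConfig:
    """End-to-end pipeline parameters (defaults are the analysis defaults)."""

    generator: GeneratorConfig | None = None   # None -> read input tables
    input_dir: str | None = None
    k_metameasures: int = 13
    k_bodytypes: int = 15
    auto_k_metameasures: bool = False
    auto_k_bodytypes: bool = False
    window_years: float = 10.0
    incidence_bin_years: float = 5.0
    bodygram_bin_years: float = 10.0
    link_rule: LinkRule = field(default_factory=LinkRule)
    smoother_span: float = 0.5
    sex_purity_threshold: float = 0.9
    include_indices_in_blocks: bool = True
    delta_flag_threshold: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.generator is None and self.input_dir is None:
            raise ConfigError("either a generator config or input_dir is required")
        if self.generator is not None:
            self.generator.validate()
        if self.k_metameasures < 2 or self.k_bodytypes < 2:
            raise ConfigError("cluster counts must be >= 2")
        if not 0 < self.smoother_span <= 1:
            raise ConfigError("smoother_span must lie in (0, 1]")
        if not 0.5 <= self.sex_purity_threshold <= 1:
            raise ConfigError("sex_purity_threshold must lie in [0.5, 1]")
        self.link_rule.validate()

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        if self.generator is not None:
            d["generator"] = self.generator.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        if d.get("generator") is not None:
            d["generator"] = GeneratorConfig.from_dict(d["generator"])
        if "link_rule" in d and isinstance(d["link_rule"], dict):
            d["link_rule"] = LinkRule(**d["link_rule"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
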