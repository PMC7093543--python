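"""End-to-end orchestration, table I/O and the run manifest.

``run_pipeline`` executes the full analysis -- simulate (optional) ->
preprocess -> meta-measures -> body types -> aging -> trajectory ->
health -- writing every stage output as plain CSV/TSV plus a YAML
manifest that records the config snapshot, seed, library versions and
per-stage row counts, sufficient to reproduce the run bit for bit.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aging import (age_stratum, bodygram, delta_bodygram, incidence_by_age,
                    metameasure_age_correlation, net_incidence_change,
                    per_type_index_curves)
from .bodytype import (BodyTypeAssignment, assign_body_types,
                       auto_select_k_types, compare_type_feature, label_types)
from .cohort import Cohort, MeasureMatrix
from .config import PipelineConfig
from .health import (activity_by_type, lifestyle_summary,
                     medication_frequency, prevalence)
from .measures import INDEX_MEASURES
from .metameasure import (MetaMeasureDefinition, auto_select_k,
                          derive_metameasures, score_metameasures)
from .preprocess import cohort_body_indices, normalize_cohort
from .synthetic import simulate
from .trajectory import count_similarity_links, transition_graph

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunManifest:
    config: dict
    seed: int
    versions: dict[str, str]
    row_counts: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    timings_s: dict[str, float] = field(default_factory=dict)

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"config": self.config, "seed": self.seed,
                 "versions": self.versions, "row_counts": self.row_counts,
                 "warnings": self.warnings, "outputs": self.outputs,
                 "timings_s": {k: round(v, 3) for k, v in self.timings_s.items()}},
                fh, sort_keys=False)


@dataclass
class PipelineResult:
    cohort: Cohort
    z_matrix: MeasureMatrix
    indices: pd.DataFrame
    definition: MetaMeasureDefinition
    meta: pd.DataFrame
    assignment: BodyTypeAssignment
    age_correlations: pd.DataFrame
    bodygrams: pd.DataFrame
    delta_bodygrams: pd.DataFrame
    incidence: dict
    net_change: dict
    index_curves: pd.DataFrame
    links: dict[str, object]
    transitions: dict[str, pd.DataFrame]
    type_marks: pd.DataFrame
    activity_summary: pd.DataFrame | None
    health_summary: pd.DataFrame | None
    medication: pd.DataFrame | None
    pmi_by_type: pd.Series | None
    manifest: RunManifest


# ----------------------------------------------------------------------
def read_cohort_tables(input_dir: str | Path) -> Cohort:
    """Load a cohort from ``measures.csv`` (+ optional activity/health).

    Schema violations -- missing columns, duplicate ids, non-numeric
    measures (e.g. comma decimal separators) -- raise with row context.
    """
    d = Path(input_dir)
    mpath = d / "measures.csv"
    if not mpath.exists():
        raise FileNotFoundError(f"missing {mpath}")
    df = pd.read_csv(mpath)
    if "id" not in df.columns:
        raise ValueError("measures.csv lacks an 'id' column")
    dup = df["id"][df["id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate participant id {dup.iloc[0]!r} in measures.csv")
    df = df.set_index("id")
    required = ["sex", "age", "height_cm", "weight_kg"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"measures.csv lacks columns {missing}")
    bad_sex = ~df["sex"].isin(["F", "M"])
    if bad_sex.any():
        raise ValueError(
            f"sex must be 'F' or 'M'; offending rows: "
            f"{list(df.index[bad_sex])[:5]}")
    part_cols = required + (["archetype"] if "archetype" in df.columns else [])
    measure_cols = [c for c in df.columns if c not in part_cols]
    meas = df[measure_cols]
    for col in measure_cols + ["age", "height_cm", "weight_kg"]:
        series = df[col]
        if series.dtype == object:
            sample = series.astype(str).str.contains(",", regex=False)
            if sample.any():
                raise ValueError(
                    f"column {col!r} contains comma decimal separators "
                    f"(row {series.index[sample][0]!r}); re-export the table "
                    "with '.' as the decimal mark (C locale)")
            raise ValueError(f"column {col!r} is not numeric")
    activity = health = None
    if (d / "activity.csv").exists():
        activity = pd.read_csv(d / "activity.csv")
    if (d / "health.csv").exists():
        health = pd.read_csv(d / "health.csv").set_index("id")
    return Cohort(
        participants=df[part_cols],
        measures=MeasureMatrix(meas.astype(float), dimensionless=INDEX_MEASURES),
        activity=activity, health=health)


# ----------------------------------------------------------------------
def _write_tsv(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", float_format="%.8g", **kw)


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None
                 ) -> PipelineResult:
    """Execute the full pipeline; write stage outputs when ``out_dir`` set."""
    config.validate()
    seed = config.seed
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=config.to_dict(), seed=seed,
        versions={"bodytyper": __version__, "numpy": np.__version__,
                  "pandas": pd.__version__})
    failed_marker = (out / "FAILED") if out is not None else None

    def _stage(name: str):
        class _Ctx:
            def __enter__(self):
                self.t0 = time.perf_counter()
                log.info("stage %s ...", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                manifest.timings_s[name] = time.perf_counter() - self.t0
                if exc is not None:
                    if failed_marker is not None:
                        failed_marker.write_text(f"stage {name} failed: {exc}\n")
                    raise PipelineError(name, exc) from exc
                return False
        return _Ctx()

    # --- input ---------------------------------------------------------
    with _stage("simulate" if config.generator is not None else "load"):
        if config.generator is not None:
            cohort = simulate(config.generator, seed)
        else:
            cohort = read_cohort_tables(config.input_dir)
    manifest.row_counts["participants"] = cohort.n

    # --- preprocess ----------------------------------------------------
    with _stage("preprocess"):
        z = normalize_cohort(cohort)
        indices = cohort_body_indices(cohort)
    manifest.row_counts["measures_retained"] = len(z.measure_names)

    # --- metameasure ---------------------------------------------------
    with _stage("metameasure"):
        if config.auto_k_metameasures:
            k_meta = auto_select_k(z)
        else:
            k_meta = config.k_metameasures
        definition = derive_metameasures(z, k=k_meta, seed=seed)
        meta = score_metameasures(z, definition)
    manifest.row_counts["metameasures"] = definition.k

    # --- bodytype ------------------------------------------------------
    with _stage("bodytype"):
        if config.auto_k_bodytypes:
            k_types = auto_select_k_types(meta, seed=seed)
        else:
            k_types = config.k_bodytypes
        clusters = assign_body_types(meta, k=k_types, seed=seed)
        assignment = label_types(clusters, cohort.participants, indices,
                                 purity_threshold=config.sex_purity_threshold)
        marks = []
        for label in sorted(assignment.sex_view.unique()):
            for feat_name, feat in (("bmi", indices["bmi"]),
                                    ("wth", indices["wth"]),
                                    ("age", cohort.ages)):
                mark = compare_type_feature(
                    assignment, label, feat, cohort.participants,
                    window_years=config.window_years)
                marks.append({"type": label, "feature": feat_name,
                              "p": mark.p, "mark": mark.mark})
        type_marks = pd.DataFrame(marks)
    manifest.row_counts["body_types"] = len(assignment.summary)

    # --- aging ---------------------------------------------------------
    with _stage("aging"):
        age_corr = metameasure_age_correlation(meta, cohort.ages, cohort.sexes)
        grams = {}
        for sex in ("F", "M"):
            grams[f"{sex}_all"] = bodygram(
                meta, cohort.participants.index[cohort.sexes == sex])
            for lo in np.arange(config.generator.age_min if config.generator
                                else cohort.ages.min() // 10 * 10,
                                cohort.ages.max(), config.bodygram_bin_years):
                ids = age_stratum(cohort.participants, lo,
                                  lo + config.bodygram_bin_years, sex=sex)
                if len(ids):
                    grams[f"{sex}_{int(lo)}"] = bodygram(meta, ids)
        bodygrams = pd.DataFrame(grams).T
        deltas = {}
        for sex in ("F", "M"):
            young = age_stratum(cohort.participants, 40, 50, sex=sex)
            old = age_stratum(cohort.participants, 70, 80, sex=sex,
                              closed_right=True)
            if len(young) and len(old):
                dg = delta_bodygram(meta, young, old,
                                    config.delta_flag_threshold)
                deltas[sex] = dg["delta"]
                deltas[f"{sex}_flag"] = dg["flagged"]
        delta_bodygrams = pd.DataFrame(deltas).T
        incidence = incidence_by_age(assignment.sex_view, cohort.ages,
                                     cohort.sexes, config.incidence_bin_years)
        net = net_incidence_change(incidence)
        curves = per_type_index_curves(
            assignment.sex_view, indices["bmi"], cohort.ages,
            span=config.smoother_span)

    # --- trajectory ----------------------------------------------------
    with _stage("trajectory"):
        links, transitions = {}, {}
        view_summary = assignment.view_summary(cohort.participants, indices)
        for sex in ("F", "M"):
            ids = cohort.participants.index[cohort.sexes == sex]
            min_n = config.link_rule.m + 1 if config.link_rule.method == "knn" else 2
            if len(ids) < min_n:
                continue
            lm = count_similarity_links(meta.loc[ids],
                                        assignment.sex_view.loc[ids],
                                        config.link_rule)
            links[sex] = lm
            transitions[sex] = transition_graph(
                lm, view_summary.loc[lm.counts.index])

    # --- health --------------------------------------------------------
    with _stage("health"):
        act_summary = health_summary = medication = pmi_by_type = None
        if cohort.activity is not None and len(cohort.activity):
            act_summary = activity_by_type(assignment, cohort.activity,
                                           cohort.participants,
                                           config.window_years)
        if cohort.health is not None and len(cohort.health):
            health_summary = lifestyle_summary(assignment, cohort.health)
            medication = pd.DataFrame({
                g: medication_frequency(assignment, cohort.health, g)
                for g in ("C", "G", "H")})
            pmi = {}
            for label in sorted(assignment.sex_view.unique()):
                members = assignment.members(label, view=True)
                flags = cohort.health.loc[
                    cohort.health.index.intersection(members), "pmi"]
                if len(flags):
                    pmi[label] = prevalence(int(flags.astype(bool).sum()),
                                            len(flags))
            pmi_by_type = pd.Series(pmi, name="pmi_pct")

    # --- outputs -------------------------------------------------------
    if out is not None:
        with _stage("write"):
            cohort.write(out / "cohort")
            definition.to_yaml(out / "metameasures.yaml")
            _write_tsv(meta, out / "meta_scores.tsv", index_label="id")
            _write_tsv(pd.DataFrame({"body_type": assignment.labels,
                                     "view": assignment.sex_view}),
                       out / "body_types.tsv", index_label="id")
            _write_tsv(assignment.summary, out / "type_summary.tsv")
            _write_tsv(view_summary, out / "type_summary_by_sex.tsv")
            _write_tsv(type_marks, out / "type_marks.tsv", index=False)
            _write_tsv(age_corr, out / "age_correlations.tsv",
                       index_label="sex")
            _write_tsv(bodygrams, out / "bodygrams.tsv", index_label="group")
            _write_tsv(delta_bodygrams, out / "delta_bodygrams.tsv",
                       index_label="group")
            for sex, df in incidence.curves.items():
                _write_tsv(df, out / f"incidence_{sex}.tsv")
            _write_tsv(pd.DataFrame(
                {sex: {"net_percent": v["net_percent"]}
                 for sex, v in net.items()}).T,
                out / "net_incidence_change.tsv", index_label="sex")
            _write_tsv(curves, out / "bmi_curves.tsv", index=False)
            for sex, lm in links.items():
                _write_tsv(lm.counts, out / f"links_{sex}.tsv")
                _write_tsv(transitions[sex], out / f"transitions_{sex}.tsv",
                           index=False)
            if act_summary is not None and len(act_summary):
                _write_tsv(act_summary, out / "activity_by_type.tsv")
            if health_summary is not None and len(health_summary):
                _write_tsv(health_summary, out / "lifestyle_by_type.tsv")
            if medication is not None:
                _write_tsv(medication, out / "medication_by_type.tsv",
                           index_label="type")
            if pmi_by_type is not None:
                _write_tsv(pmi_by_type.to_frame(), out / "pmi_by_type.tsv",
                           index_label="type")
            manifest.outputs = sorted(
                str(p.relative_to(out)) for p in out.rglob("*") if p.is_file())
            manifest.write(out / "manifest.yaml")

    return PipelineResult(
        cohort=cohort, z_matrix=z, indices=indices, definition=definition,
        meta=meta, assignment=assignment, age_correlations=age_corr,
        bodygrams=bodygrams, delta_bodygrams=delta_bodygrams,
        incidence=incidence, net_change=net, index_curves=curves,
        links=links, transitions=transitions, type_marks=type_marks,
        activity_summary=act_summary, health_summary=health_summary,
        medication=medication, pmi_by_type=pmi_by_type, manifest=manifest)
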