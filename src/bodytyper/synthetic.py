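"""Synthetic anthropometric cohort generator.

The generator produces cohorts with the statistical structure the
downstream analysis assumes, so the whole pipeline is testable without
access to the original (non-public) study data:

* Scanner measures follow a latent block-factor model: every measure of
  block ``b`` is ``sqrt(c_b)*u_g + sqrt(w_b - c_b)*u_b + s_b + sqrt(1 -
  w_b)*eps`` with a cohort-wide factor ``u_g``, a per-participant block
  factor ``u_b`` and idiosyncratic noise, giving within-block correlation
  ``w_b`` and cross-block correlation ``sqrt(c_b * c_b')``.
* ``s_b`` is the structural block signal: the participant's archetype
  offset (including the androgyny correction for mixed types) plus a
  linear age drift in Z-units per decade.
* Raw measures are mapped from latent Z scale to cm: log-normal for
  girths (positive, right-skewed), normal for lengths and angles, both
  scaled isometrically with the participant's body height (so that
  dividing by height -- the pipeline's normalization step -- removes the
  shared size variance and exposes the block structure, as in real
  anthropometry).  The mapping is calibrated analytically -- via the
  moment-generating function of the latent signal -- so that each
  configured per-sex (mean, sd) is matched exactly in expectation,
  archetype mixture, age drift and height scaling included.
* Weight loads on height and on the girth-block factor ("adiposity"),
  which propagates body-volume archetypes into BMI; BMI and
  waist-to-height columns are derived, not drawn.
* Day-level activity (wear time, steps, MET) decreases with BMI and age
  per configured slopes; a configurable fraction of days violates the
  wear-time validity rules.  Health records are Bernoulli/categorical
  per configured sex-specific rates.

A single integer seed drives everything; per-stage sub-streams are
spawned deterministically from it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cohort import Cohort, MeasureMatrix, body_mass_index
from .config import ConfigError, GeneratorConfig
from .measures import INDEX_MEASURES, MeasureDef

_AGE_GRID = 401  # resolution of the (archetype, age) joint used for calibration


# ----------------------------------------------------------------------
# latent signal distribution per (sex, block)
# ----------------------------------------------------------------------
@dataclass
class _SignalDist:
    """Distribution of the structural block signal s_b for one sex.

    Carries the joint probability of (archetype, age) on a grid and the
    matching signal values, from which exact moments and the mgf are
    computed for marginal calibration.
    """

    probs: np.ndarray   # (K, G) joint probabilities, sums to 1
    values: np.ndarray  # (K, G) signal values

    @property
    def mean(self) -> float:
        return float(np.sum(self.probs * self.values))

    @property
    def var(self) -> float:
        m = self.mean
        return float(np.sum(self.probs * (self.values - m) ** 2))

    def mgf(self, t: float) -> float:
        return float(np.sum(self.probs * np.exp(t * self.values)))


class _SexModel:
    """Calibration state for one sex: mixture geometry and signal dists."""

    def __init__(self, cfg: GeneratorConfig, sex: str):
        self.cfg = cfg
        self.sex = sex
        self.marg = cfg.marginals[sex]
        self.archetypes = [a for a in cfg.archetypes if a.sex in (sex, "mixed")]
        wsum = sum(a.weight for a in self.archetypes)
        self.base_weights = np.array([a.weight / wsum for a in self.archetypes])
        self.age_mid = 0.5 * (cfg.age_min + cfg.age_max)
        self.age_grid = np.linspace(cfg.age_min, cfg.age_max, _AGE_GRID)
        # P(k | age) on the grid
        w = np.repeat(self.base_weights[:, None], _AGE_GRID, axis=1)
        for i, a in enumerate(self.archetypes):
            if a.age_mean is not None:
                w[i] *= np.exp(-0.5 * ((self.age_grid - a.age_mean) / a.age_sd) ** 2)
        self.cond_weights = w / w.sum(axis=0, keepdims=True)
        self.joint = self.cond_weights / _AGE_GRID
        self._andro_gap = _androgyny_gaps(cfg)
        self._signals: dict[str, _SignalDist] = {}

    def effective_offset(self, arch_idx: int, block: str) -> float:
        a = self.archetypes[arch_idx]
        off = a.offsets.get(block, 0.0)
        if a.androgyny:
            off -= a.androgyny * self._andro_gap[self.sex].get(block, 0.0)
        return off

    def signal(self, block: str) -> _SignalDist:
        if block not in self._signals:
            beta = self.cfg.age_effect.get(block, 0.0)
            age_term = beta * (self.age_grid - self.age_mid) / 10.0
            vals = np.empty_like(self.joint)
            for i in range(len(self.archetypes)):
                vals[i] = self.effective_offset(i, block) + age_term
            self._signals[block] = _SignalDist(self.joint, vals)
        return self._signals[block]

    def signal_values(self, block: str, arch_idx: np.ndarray,
                      ages: np.ndarray) -> np.ndarray:
        beta = self.cfg.age_effect.get(block, 0.0)
        offs = np.array([self.effective_offset(i, block)
                         for i in range(len(self.archetypes))])
        return offs[arch_idx] + beta * (ages - self.age_mid) / 10.0

    def sample_archetypes(self, ages: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        w = np.repeat(self.base_weights[:, None], len(ages), axis=1)
        for i, a in enumerate(self.archetypes):
            if a.age_mean is not None:
                w[i] *= np.exp(-0.5 * ((ages - a.age_mean) / a.age_sd) ** 2)
        w /= w.sum(axis=0, keepdims=True)
        cum = np.cumsum(w, axis=0)
        u = rng.uniform(size=len(ages))
        return (u[None, :] > cum).sum(axis=0)


def _androgyny_gaps(cfg: GeneratorConfig) -> dict[str, dict[str, float]]:
    """Per-sex, per-block standardized gap from the sex mean to the
    mid-sex ("neutral") mean of height-normalized measures.

    Mixed archetypes subtract ``androgyny * gap`` from their block
    offsets, which moves their members toward the neutral region of the
    pooled Z space regardless of sex.
    """
    hbar = {s: cfg.marginals[s].height.mean for s in ("M", "F")}
    cv_h = {s: cfg.marginals[s].height.sd / cfg.marginals[s].height.mean
            for s in ("M", "F")}
    by_block: dict[str, list[MeasureDef]] = {}
    for d in cfg.catalog:
        if d.block is not None and d.kind != "index":
            by_block.setdefault(d.block, []).append(d)
    gaps: dict[str, dict[str, float]] = {"M": {}, "F": {}}
    for block, defs in by_block.items():
        for sex in ("M", "F"):
            g = []
            for d in defs:
                mm, mf = _measure_means(cfg, d)
                hn = {"M": mm / hbar["M"], "F": mf / hbar["F"]}
                neutral = 0.5 * (hn["M"] + hn["F"])
                sd = hn[sex] * math.sqrt(d.cv ** 2 + cv_h[sex] ** 2)
                g.append((hn[sex] - neutral) / sd if sd > 0 else 0.0)
            gaps[sex][block] = float(np.mean(g))
    return gaps


def _measure_means(cfg: GeneratorConfig, d: MeasureDef) -> tuple[float, float]:
    """(male mean, female mean) with the waist marginal override."""
    if d.name == "waist_girth":
        return cfg.marginals["M"].waist.mean, cfg.marginals["F"].waist.mean
    return d.mean_male, d.mean_female


def _measure_cv(cfg: GeneratorConfig, d: MeasureDef, sex: str) -> float:
    if d.name == "waist_girth":
        m = cfg.marginals[sex].waist
        return m.sd / m.mean
    return d.cv


# ----------------------------------------------------------------------
# scale calibration
# ----------------------------------------------------------------------
def _calibrate_lognormal(mean: float, cv: float, mgf) -> tuple[float, float]:
    """Find (sigma, scale) so scale*exp(sigma*z) has the target mean, cv.

    ``mgf(t)`` is the moment-generating function of the standardized
    latent z.  cv^2(sigma) = mgf(2 sigma)/mgf(sigma)^2 - 1 is increasing
    in sigma; solved by bracketing.
    """
    def g(s: float) -> float:
        return mgf(2 * s) / mgf(s) ** 2 - 1 - cv ** 2

    hi = 1.0
    while g(hi) < 0 and hi < 16:
        hi *= 2
    sigma = brentq(g, 1e-9, hi, xtol=1e-12)
    return sigma, mean / mgf(sigma)


def _std_mgf(sig: _SignalDist, cont_var: float):
    """mgf of the standardized latent (continuous N(0, cont_var) + signal)."""
    m = sig.mean
    st = math.sqrt(cont_var + sig.var)

    def mgf(t: float) -> float:
        u = t / st
        return math.exp(-u * m + 0.5 * cont_var * u ** 2) * sig.mgf(u)

    return mgf, m, st


# ----------------------------------------------------------------------
# main entry points
# ----------------------------------------------------------------------
def plant_block_structure(config: GeneratorConfig) -> pd.DataFrame:
    """Correlation template implied by the block spec.

    Entries: 1 on the diagonal, ``within_corr`` inside a block,
    ``sqrt(cross_b * cross_b')`` between blocks.  The template describes
    the height-normalized measures (raw measures additionally share the
    isometric height factor).  It is realized exactly by the
    ``blocks_only`` profile (``individuality=1``, no archetypes); the
    default archetype mixture adds structured covariance on top.  Index
    columns (bmi, whtr) are derived measures and are excluded.
    """
    config.validate()
    kinds = {d.name: d.kind for d in config.catalog}
    names: list[str] = []
    block_of: dict[str, str] = {}
    for b in config.blocks:
        for m in b.members:
            if kinds.get(m) == "index":
                continue
            names.append(m)
            block_of[m] = b.label
    spec = {b.label: b for b in config.blocks}
    n = len(names)
    out = np.empty((n, n))
    for i, a in enumerate(names):
        for j, c in enumerate(names):
            if i == j:
                out[i, j] = 1.0
            elif block_of[a] == block_of[c]:
                out[i, j] = spec[block_of[a]].within_corr
            else:
                out[i, j] = math.sqrt(spec[block_of[a]].cross_corr
                                      * spec[block_of[c]].cross_corr)
    return pd.DataFrame(out, index=names, columns=names)


def generate_cohort(config: GeneratorConfig, seed: int | None = None) -> Cohort:
    """Generate the participant table and raw scanner measures.

    Deterministic under fixed (config, seed); ``seed=None`` uses
    ``config.seed``.  Activity and health tables are added by
    :func:`generate_activity` / :func:`generate_health` (or use
    :func:`simulate` for everything at once).
    """
    config.validate()
    seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence([int(seed), 101])
    rng_demo, rng_latent, rng_eps, rng_weight = (
        np.random.default_rng(s) for s in ss.spawn(4))

    frames = []
    mframes = []
    for sex, n in (("M", config.n_male), ("F", config.n_female)):
        part, meas = _generate_sex(config, sex, n, rng_demo, rng_latent,
                                   rng_eps, rng_weight)
        frames.append(part)
        mframes.append(meas)
    participants = pd.concat(frames) if frames else pd.DataFrame()
    measures = pd.concat(mframes) if mframes else pd.DataFrame()
    if len(participants):
        participants.index = [f"P{i + 1:06d}" for i in range(len(participants))]
        measures.index = participants.index
    participants.index.name = "id"
    measures.index.name = "id"
    mm = MeasureMatrix(measures, dimensionless=INDEX_MEASURES)
    return Cohort(participants=participants, measures=mm,
                  config=config, seed=seed)


def _generate_sex(config: GeneratorConfig, sex: str, n: int,
                  rng_demo, rng_latent, rng_eps, rng_weight
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    model = _SexModel(config, sex)
    marg = model.marg
    ages = rng_demo.uniform(config.age_min, config.age_max, size=n)
    arch = model.sample_archetypes(ages, rng_demo)
    arch_labels = np.array([a.label for a in model.archetypes])[arch] \
        if n else np.array([], dtype=str)

    heights = marg.height.mean + marg.height.sd * rng_demo.standard_normal(n)
    h_std = (heights - marg.height.mean) / marg.height.sd

    # latent factors
    u_g = rng_latent.standard_normal(n)
    u_b = {b.label: rng_latent.standard_normal(n) for b in config.blocks}
    spec = {b.label: b for b in config.blocks}
    block_of = {m: b.label for b in config.blocks for m in b.members}

    gamma = config.individuality

    # block-B factor drives adiposity -> weight
    girth_block = "B" if "B" in spec else config.blocks[0].label
    sigB = model.signal(girth_block)
    wB, cB = spec[girth_block].within_corr, spec[girth_block].cross_corr
    a_raw = gamma * (math.sqrt(cB) * u_g
                     + math.sqrt(wB - cB) * u_b[girth_block]) \
        + model.signal_values(girth_block, arch, ages)
    mgf_a, mA, sA = _std_mgf(sigB, gamma ** 2 * wB)
    a_std = (a_raw - mA) / sA

    w1 = config.height_weight_corr
    w2 = config.adiposity_loading
    w3 = math.sqrt(max(1.0 - w1 ** 2 - w2 ** 2, 0.0))
    cv_w = marg.weight.sd / marg.weight.mean

    def mgf_w(t: float) -> float:
        return math.exp(0.5 * t ** 2 * (w1 ** 2 + w3 ** 2)) * mgf_a(w2 * t)

    sig_w, scale_w = _calibrate_lognormal(marg.weight.mean, cv_w, mgf_w)
    lw = sig_w * (w1 * h_std + w2 * a_std + w3 * rng_weight.standard_normal(n))
    weights = scale_w * np.exp(lw)

    # scanner measures: isometric height scaling x calibrated latent scale
    cv_h = marg.height.sd / marg.height.mean
    h_fac = heights / marg.height.mean
    cols: dict[str, np.ndarray] = {}
    mgf_cache: dict[str, tuple] = {}
    for d in config.catalog:
        if d.kind == "index":
            continue
        mean = _measure_means(config, d)[0 if sex == "M" else 1]
        cv = _measure_cv(config, d, sex)
        if cv <= cv_h:
            raise ConfigError(
                f"measure {d.name!r}: cv {cv} must exceed the height cv "
                f"{cv_h:.4f} (isometric height scaling)")
        # residual cv once the height factor is taken out
        cv_eff = math.sqrt((1 + cv ** 2) / (1 + cv_h ** 2) - 1)
        if d.block is None:
            z_std = rng_eps.standard_normal(n)
            mgf = lambda t: math.exp(0.5 * t ** 2)  # noqa: E731
        else:
            b = spec[d.block]
            if d.block not in mgf_cache:
                cont_var = gamma ** 2 * b.within_corr + (1.0 - b.within_corr)
                mgf_cache[d.block] = (
                    _std_mgf(model.signal(d.block), cont_var),
                    model.signal_values(d.block, arch, ages))
            (mgf, m_b, s_b), sig_vals = mgf_cache[d.block]
            z = (gamma * (math.sqrt(b.cross_corr) * u_g
                          + math.sqrt(b.within_corr - b.cross_corr) * u_b[d.block])
                 + math.sqrt(1.0 - b.within_corr) * rng_eps.standard_normal(n)
                 + sig_vals)
            z_std = (z - m_b) / s_b
        if d.kind == "girth":
            sigma, scale = _calibrate_lognormal(mean, cv_eff, mgf)
            cols[d.name] = h_fac * scale * np.exp(sigma * z_std)
        else:
            cols[d.name] = h_fac * (mean + mean * cv_eff * z_std)

    # derived index columns
    bmi = body_mass_index(weights, heights)
    for name in INDEX_MEASURES:
        if name == "bmi":
            cols[name] = bmi
        elif name == "whtr":
            cols[name] = cols["waist_girth"] / heights

    order = [d.name for d in config.catalog]
    measures = pd.DataFrame({k: cols[k] for k in order})
    participants = pd.DataFrame({
        "sex": sex, "age": ages, "height_cm": heights,
        "weight_kg": weights, "archetype": arch_labels})
    return participants, measures


# ----------------------------------------------------------------------
def generate_activity(cohort: Cohort, config: GeneratorConfig | None = None,
                      seed: int | None = None) -> pd.DataFrame:
    """Day-level activity records for a random subcohort.

    Steps and MET decrease with BMI and age per the configured slopes; a
    configurable fraction of days violates the wear-time validity rules.
    """
    config = cohort.config if config is None else config
    if config is None:
        raise ValueError("an explicit GeneratorConfig is required")
    config.validate()
    seed = (cohort.seed if cohort.seed is not None else config.seed) \
        if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 202]))

    rows = []
    bmi_all = body_mass_index(cohort.weights_kg, cohort.heights_cm)
    for sex in ("M", "F"):
        mask = cohort.sexes == sex
        ids = cohort.participants.index[mask]
        if len(ids) == 0:
            continue
        n_sub = int(round(config.activity_fraction[sex] * len(ids)))
        sub = rng.choice(ids, size=min(n_sub, len(ids)), replace=False)
        sub = pd.Index(sorted(sub))
        ages = cohort.ages.loc[sub].to_numpy()
        bmi = pd.Series(bmi_all, index=cohort.participants.index).loc[sub].to_numpy()
        marg = config.marginals[sex]

        def latent(target, b_bmi, b_age, floor):
            sd2 = target.sd ** 2
            if len(sub) > 1:
                resid = sd2 - b_bmi ** 2 * bmi.var() - b_age ** 2 * ages.var() \
                    - 2 * b_bmi * b_age * np.cov(bmi, ages)[0, 1]
            else:
                resid = sd2
            resid = math.sqrt(max(resid, 0.05 * sd2))
            lat = (target.mean + b_bmi * (bmi - bmi.mean())
                   + b_age * (ages - ages.mean())
                   + resid * rng.standard_normal(len(sub)))
            return np.maximum(lat, floor)

        steps_lat = latent(marg.steps, config.steps_bmi_slope,
                           config.steps_age_slope, 200.0)
        met_lat = latent(marg.met, config.met_bmi_slope,
                         config.met_age_slope, 0.2)

        nd = config.n_days
        day_idx = np.arange(nd)
        weekend = (day_idx % 7) >= 5
        for i, pid in enumerate(sub):
            invalid = rng.uniform(size=nd) < config.invalid_day_fraction
            wear = np.where(weekend, rng.uniform(20.0, 23.5, nd),
                            rng.uniform(18.0, 23.5, nd))
            bad = np.where(weekend, rng.uniform(4.0, 19.9, nd),
                           rng.uniform(4.0, 17.9, nd))
            wear = np.where(invalid, bad, wear)
            day_steps = steps_lat[i] * np.exp(
                0.12 * rng.standard_normal(nd) - 0.0072)
            day_met = np.maximum(met_lat[i] + 0.06 * rng.standard_normal(nd), 0.05)
            for j in range(nd):
                rows.append((pid, j + 1,
                             "weekend" if weekend[j] else "weekday",
                             wear[j], max(float(np.round(day_steps[j])), 0.0),
                             day_met[j]))
    return pd.DataFrame(
        rows, columns=["id", "day", "day_type", "wear_hours", "steps", "met"])


def generate_health(cohort: Cohort, config: GeneratorConfig | None = None,
                    seed: int | None = None) -> pd.DataFrame:
    """Health and lifestyle records: PMI, ATC medication flags, smoking,
    alcohol (zero-inflated log-normal, calibrated to the configured
    per-sex mean/sd of the overall marginal)."""
    config = cohort.config if config is None else config
    if config is None:
        raise ValueError("an explicit GeneratorConfig is required")
    config.validate()
    seed = (cohort.seed if cohort.seed is not None else config.seed) \
        if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 303]))

    frames = []
    for sex in ("M", "F"):
        mask = cohort.sexes == sex
        ids = cohort.participants.index[mask]
        n = len(ids)
        if n == 0:
            continue
        pmi = rng.uniform(size=n) < config.pmi_rate[sex]
        atc = {g: rng.uniform(size=n) < config.medication_rates[g][sex]
               for g in config.medication_rates}
        u = rng.uniform(size=n)
        p_cur = config.smoking_current[sex]
        p_for = config.smoking_former[sex]
        smoking = np.where(u < p_cur, "current",
                           np.where(u < p_cur + p_for, "former", "never"))
        alcohol = _zero_inflated_lognormal(
            config.marginals[sex].alcohol.mean, config.marginals[sex].alcohol.sd,
            config.alcohol_zero_fraction[sex], n, rng)
        frames.append(pd.DataFrame({
            "pmi": pmi,
            **{f"atc_{g}": v for g, v in atc.items()},
            "smoking": smoking, "alcohol_g_day": alcohol}, index=ids))
    out = pd.concat(frames) if frames else pd.DataFrame(
        columns=["pmi", "atc_C", "atc_G", "atc_H", "smoking", "alcohol_g_day"])
    out.index.name = "id"
    return out.loc[cohort.participants.index] if len(out) else out


def _zero_inflated_lognormal(mean: float, sd: float, p_zero: float,
                             n: int, rng: np.random.Generator) -> np.ndarray:
    """Zero-inflated log-normal with overall (mean, sd) as configured."""
    if not 0 <= p_zero < 1:
        raise ConfigError(f"zero fraction outside [0, 1): {p_zero}")
    mp = mean / (1 - p_zero)
    second = (sd ** 2 + mean ** 2) / (1 - p_zero)
    vp = second - mp ** 2
    if vp <= 0:
        raise ConfigError(
            "alcohol marginal incompatible with zero fraction "
            f"(positive-part variance {vp:.3g} <= 0)")
    s2 = math.log(1 + vp / mp ** 2)
    mu = math.log(mp) - s2 / 2
    vals = np.exp(mu + math.sqrt(s2) * rng.standard_normal(n))
    zero = rng.uniform(size=n) < p_zero
    return np.where(zero, 0.0, vals)


def simulate(config: GeneratorConfig, seed: int | None = None) -> Cohort:
    """Generate a complete cohort: measures + activity + health."""
    cohort = generate_cohort(config, seed)
    cohort.activity = generate_activity(cohort, config, cohort.seed)
    cohort.health = generate_health(cohort, config, cohort.seed)
    return cohort
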