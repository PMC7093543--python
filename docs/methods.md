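# Methods

This note documents the models and numerical choices behind
`bodytyper`: the synthetic-cohort generator, the normalization and
clustering pipeline, the aging and trajectory statistics, and the known
limitations of each.

## Synthetic cohort model

### Demographics and marginals

Ages are uniform on [40, 80] years per sex; sexes are generated at the
configured counts (defaults 4766 men, 5234 women). Per-sex target
marginals (mean ± sd) default to published summary statistics of a
large middle-European adult cohort:

| quantity | men | women |
|---|---|---|
| height (cm) | 176 ± 7 | 165 ± 7 |
| weight (kg) | 86 ± 14 | 71 ± 14 |
| waist girth (cm) | 101 ± 12 | 91 ± 13 |
| steps/day | 9683 ± 4011 | 9903 ± 3682 |
| MET | 1.41 ± 0.25 | 1.35 ± 0.24 |
| alcohol (g/day) | 18.8 ± 21.7 | 5.9 ± 10.0 |

BMI is **not** a generator parameter; it emerges from the height and
weight models (≈ 28 kg/m² for men, ≈ 26 for women), which is used as a
joint calibration check of generator plus index code.

### Latent measure model

Each of the 155 scanner measures belongs to one of 13 correlation
blocks A–M (21 auxiliary channels are emitted but flagged non-retained,
mirroring the usual practice of analyzing ~134 of the reported
channels). The latent Z value of measure *i* in block *b* is

    z_i = γ·( √c_b·u_g + √(w_b − c_b)·u_b ) + s_b + √(1 − w_b)·ε_i

with a cohort-wide factor `u_g`, a per-participant block factor `u_b`,
idiosyncratic noise ε, and the structural signal
`s_b = δ(archetype, b) + β_b·(age − 60)/10`. With `γ = 1` and no
archetypes the within-block correlation is exactly `w_b` (default 0.8)
and the cross-block correlation `√(c_b c_b')` (default 0.2) — the
**template profile** (`GeneratorConfig.blocks_only`) used for
correlation-structure recovery checks. In the default profile
`γ = 0.5` (the `individuality` parameter): half of the template's
shared standard deviation remains continuous individual variation,
and the archetype mixture supplies the complementary block-level
variance. This is the design decision that makes the planted body-shape
clusters separable; with γ = 1 the continuous block variance swamps any
realistic offset pattern and no clustering method could (or should)
recover the mixture.

Raw measures scale **isometrically with body height**:
`raw = (h/h̄)·scale(z)`, log-normal for girths (positivity,
right skew) and normal for lengths and angles. Dividing by height —
the pipeline's first normalization step — therefore *removes* the
shared size variance, exactly as intended in real scanner anthropometry.
A consequence is that each measure's total cv must exceed the height cv
(~0.04); the catalog floors cvs at 0.055, which slightly inflates the
spread of naturally tight measures such as head circumference.

Scale calibration is analytic: the moment-generating function of the
standardized latent (normal continuous part × discrete archetype
mixture × uniform age drift) is evaluated on a (archetype, age) grid,
and the log-normal σ is solved by bracketing so that each configured
per-sex (mean, sd) is matched in expectation — archetype offsets, age
drift, androgyny correction and height scaling all included. Sample
moments then match targets to within ordinary sampling error (the test
suite asserts 3 standard errors).

### Archetypes

The 15 body-shape archetypes (6 female, 7 male, 2 mixed) are design
config, not measured values: their offset vectors encode qualitative
shape descriptors ("massive body, big girths" → large positive offsets
on the girth blocks B, K, L; "long/slim body and legs" → positive
F, G, H and negative B, L; …) with amplitudes of roughly 2–3.5 latent-Z
units on 4–8 axes each. Amplitudes were chosen by centroid-geometry
analysis so that the planted clusters are separable in meta-measure
space (silhouette > 0, k-means recovery, silhouette-selected k equal to
the planted count); after pooled Z-normalization the *emergent* type
separations are ~1–2 Z, i.e. on the scale of realistic bodygram
contrasts. Each archetype carries a Gaussian age tilt (means staggered
46–68 years, sd 12) so types acquire distinct age profiles while the
cohort age marginal stays uniform.

Mixed types (B1, B2) are androgynous: their members' block offsets are
shifted toward the mid-sex mean by an `androgyny` factor (default
0.85), computed per block from the standardized sex gap of the
height-normalized member measures. This keeps the per-sex marginal
calibration exact while letting male and female members of a mixed type
occupy the same region of pooled Z space.

Age drift per block (`age_effect`, Z/decade): girths positive
(B +0.25, K/L/E +0.2, A/I/J/M +0.05…0.1), upper-body lengths negative
(H −0.2) and thigh girth negative (C −0.15), plus mild negative drifts
on the leg lengths.

### Weight, activity, health

Log-weight loads on standardized height (loading = configured
height–weight correlation, default 0.5) and on the girth-block
"adiposity" factor (default loading 0.75), so body-volume archetypes
propagate into weight, BMI and waist. The BMI and waist-to-height
columns among the scanner measures are derived, not drawn, and join
girth block B with realistic correlation ~0.7–0.95.

Activity is generated for a subcohort (defaults 27.7% of men, 21.0% of
women, matching the published activity-subcohort fractions). Per
participant, 10 days are simulated on a Monday-anchored calendar (8
weekdays, 2 weekend days); a configurable fraction (default 0.15) of
days violates the wear-time rules to exercise the validity filter.
Participant-level steps and MET decrease linearly with BMI and age
(defaults: −150 steps and −0.030 MET per kg/m²; −60 steps and −0.005
MET per year), with residual noise scaled so the per-sex marginal sd is
preserved; covariate terms are centered on sample means so marginal
means calibrate exactly.

Health records: infarction history (PMI) is Bernoulli per sex (defaults
4.0% men, 1.1% women), ATC medication flags C/G/H are Bernoulli per
sex, smoking is categorical per sex (current/former/never at the
published rates), and alcohol is zero-inflated log-normal whose
zero fraction (0.25 men / 0.45 women) and positive part are solved so
the *overall* per-sex (mean, sd) matches the configured marginal.

### Determinism

A single integer seed drives everything. Stage-level RNG sub-streams
are spawned from it (`SeedSequence([seed, stage])`), so the same
(config, seed) reproduces the cohort bit for bit; generation is
vectorized within stages.

## Pipeline

* **Normalization.** Retained measures (134) are divided by body height
  (the dimensionless index columns bmi/whtr are exempt) and then
  Z-scored with the population (n) sd convention, pooled across both
  sexes by default so the sex contrast remains visible in Z units; a
  per-sex option exists. Zero-variance columns and state-skipping are
  errors, not warnings.
* **Indices.** BMI = w/h² (kg/m²); WTH = waist/hip; WHtR = waist/h;
  ABSI = waist/(BMI^(2/3)·√h) with waist and height in meters. WHO BMI
  categories use half-open boundaries: underweight < 18.5 ≤ normal
  < 25 ≤ overweight < 30 ≤ obese.
* **Meta-measures.** Default route: an 8×8 batch self-organizing map
  (100 epochs, Gaussian neighbourhood with linearly decaying radius,
  deterministic PCA-plane initialization) is trained on the measure
  profiles; the occupied codebook is cut into k groups by average-link
  agglomerative clustering under correlation distance, and measures
  inherit their best-matching unit's group. The direct hierarchical
  route (average linkage, 1 − Pearson r between measure columns) is the
  deterministic fallback and must produce the same partition on
  separable block data (property-tested). Automatic k maximizes the
  mean silhouette of the measure partition under correlation distance
  over the requested range (hierarchical candidates; ties → smallest
  k). Scores are unweighted means of member Z values; recovered
  clusters are labeled A–M by maximal-overlap assignment against the
  default blocks, with numeric labels for leftovers.
* **Body types.** k-means (25 restarts, fixed seed) on the meta-measure
  scores; automatic k by silhouette over k-means partitions (evaluated
  on a fixed-seed subsample of 2000 when the cohort is larger, for
  O(n²) containment). Sex-purity threshold for F/M labels is 0.9;
  indices follow increasing mean age; mixed types are split into
  per-sex views (B1F, B1M, …) for every downstream statistic.
  Reference groups take all same-sex participants in a 10-year
  half-open window centered on the type's *median* member age (the
  centering rule is a package choice; a per-member pooled alternative
  was considered and rejected as harder to reason about). Rank-sum
  comparisons are two-sided; no multiple-testing correction is applied
  by default (raw tiers are reported, as is conventional for this kind
  of descriptive stratification).
* **Aging.** Incidence bins are 5 years (half-open), bodygram strata
  decades, and the Δ-bodygram contrasts [40, 50) against [70, 80] with
  |ΔZ| > 0.2 flagged. Net incidence change reports the sum of positive
  per-type changes between the earliest and latest bin (equal to the
  absolute sum of negative changes, since per-bin percentages sum
  to 100); the signed per-type changes are returned alongside. The
  smoother is LOESS, degree 1, span 0.5, one robustifying iteration,
  evaluated on a 1-year grid — exact on linear input, which the tests
  exploit.
* **Trajectories.** "Most similar" defaults to the union of each
  participant's m = 3 nearest neighbours (a pair links if either side
  selects the other); distance ties break by participant order. A
  distance-quantile alternative is exposed. Within-type links populate
  the diagonal but are excluded from transition reporting. Expected
  counts under random mixing are proportional to the number of
  unordered pairs per type pair (n_a·n_b off-diagonal, n_a(n_a−1)/2
  diagonal), which calibrates the null (property-tested by χ²
  goodness-of-fit over 100 random splits). Transition edges keep
  off-diagonal cells at or above the median nonzero count and run from
  lower to higher mean age, ties toward higher mean BMI.
* **Health.** Day validity: weekday ≥ 18 h, weekend ≥ 20 h, boundaries
  inclusive; eligibility: ≥ 8 valid days, ≥ 4 weekdays, ≥ 1 weekend
  day. Participant activity is the mean over valid days (a package
  choice), summarized per type by medians. Percentages are rounded
  half-up to one decimal. "Smoker" subsumes current and former smoking;
  the current-only rate is reported alongside.

## What the generator does and does not emulate

The generator reproduces the *structure* the analysis needs — block
correlations, separable shape archetypes, sex dimorphism, age drifts,
activity–adiposity coupling, outcome rates — with defaults calibrated
to published summary statistics. It does **not** attempt the real joint
distribution of scanner measures: archetypes are idealized Gaussian
clusters (real body-type boundaries are fuzzier; accordingly,
cross-type similarity links are sparse on default data, and the
trajectory stage is exercised by overlapping-mixture constructions in
the tests), measure skewness beyond log-normality, missing data,
measurement error and device drift are absent, and health outcomes are
independent Bernoulli given sex (no age or BMI gradient in PMI).
Passing tests therefore demonstrate correctness of the *procedures*
under controlled conditions, not reproduction of any real cohort's
findings. Magnitudes of link-differential profiles are attenuated
toward the cluster-overlap region by construction (nearest-neighbour
selection); the tests assert sign and axis patterns, and treat the
magnitude as qualitative.

## Problem sizes

Structure-recovery checks run at n = 2000 (measure clustering, 13
blocks) and n = 4000 (body typing, 15 archetypes); marginal-calibration
checks at the full default cohort size (n = 10 000). These sizes give
comfortable statistical margins (k-means recovery of the default
mixture is exact at n = 4000) while keeping a full test-suite run
within a few minutes on one CPU.
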