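# Methods

This note documents the models, rules and numerical conventions behind
`glaucoprev`, the choices made where the published survey methodology leaves
the design open, and what the synthetic cohorts do and do not establish
about behaviour on real data.

## Case definition

The ISGEO epidemiological case definition trades clinical nuance for
comparability: an eye is a case when the *evidence* reaches one of four
levels.

| Category | Structure | Function | Other |
|---|---|---|---|
| 1 | VCDR or VCDR asymmetry ≥ 97.5th percentile | typical field defect | |
| 2 | VCDR or asymmetry ≥ 99.5th percentile | field unusable/absent | |
| 2b | disc seen, VCDR < 97.5th percentile | field unusable or "unlikely" (or typical) | IOP ≥ 99.5th percentile **and** RAPD or corneal oedema |
| 3 | disc not seen | field not possible | acuity worse than 3/60 with IOP ≥ 99.5th percentile, or glaucoma surgery/diagnosis history |

Structural criteria are evaluated on the scale they were measured on:
photographic (image) grades against the image-scale percentiles, direct
ophthalmoscopy (clinical) grades against the clinical-scale ones, with the
photographic grade taking precedence when both exist. Category 2
deliberately requires the field result to be *unusable or absent*, not
merely normal: a large cup with a reliably normal field is not a case.
A person is a case if either eye is; the person's category is the best eye
category under the ordering 1 > 2 > 2b > 3 (descending directness of
evidence), with ties broken toward the eye with the larger cup.

Interpretive choices made here, where the source methodology is ambiguous:

- A field graded "possible" counts as a typical defect for category 1
  (the published level-1 tallies include definite, probable and possible
  defects).
- VCDR asymmetry between eyes measured on *different* scales is compared
  against the wider clinical-scale cut-offs and flagged
  (`mixed_scale_asymmetry`) — a conservative reading.
- Category 3's history clause accepts either prior surgery or a prior
  diagnosis/treatment; the two are distinguishable through
  `evidence_basis`.
- Category 2b makes the classifier non-monotone in VCDR by construction
  (a pressure-evidence case with a modest cup can lose its category when
  the cup grows past the 97.5th percentile without the field or the
  99.5th criterion following). The property tests treat 2b as the
  documented exception to monotonicity.

## FDT field grading

The C-20 pattern is modelled as 17 zones: a 4×4 grid (two superior rows,
two inferior) plus a central zone. The device documentation does not define
zone adjacency or edge membership, so the geometry is an explicit constant
(`C20_GEOMETRY`): *edge* = touching the outer boundary of the grid,
*adjacency* = side-sharing within a hemifield, the central zone belongs to
no hemifield and is excluded from hemifield-restricted counts.

All counts are cumulative over probability levels (a p<0.5% defect also
counts at p<5%), rows are minimum thresholds, and the grade is the most
severe satisfied row. Two singleton rules overlap at the deepest levels
(a single p<1% or p<0.5% defect): a *non-edge* singleton takes the
hemifield-restricted "probable" row, an *edge or central* p<0.5% singleton
the unrestricted "definite" row — the more specific row wins. The
"unlikely" grade fires when the TDP plot is strictly better (lower total
severity score) than the PDP plot, or when the PDP matches no abnormal row
while the TDP is diffusely shaded (more than half the zones flagged) — the
signature of media opacity rather than glaucoma. Screening reliability is
≤1 fixation error *and* ≤1 false positive (failing either index makes the
test unreliable); threshold reliability allows ≤2 of each. The two
published phrasings of threshold-test normality conflict; both are exposed
(`threshold_normal(..., variant="strict"|"lenient")`, default strict: no
defect at p<1% or deeper).

## Percentile thresholds

Nearest-rank percentiles (value at rank ⌈p/100·n⌉), no interpolation:
VCDR is recorded on a 0.05 grid and IOP in whole mmHg, so interpolated
cut-offs would be unobservable values. Derivation uses participants
flagged as the systematic 1-in-7 normative subsample, after a single-pass
exclusion of persons who meet any case category under the default cut set
(so diseased eyes do not drag the "normal" percentiles). Image and
clinical scales are parallel distributions; each scale's asymmetry comes
from same-scale pairs of eyes.

## Survey estimators

Clusters are the primary sampling units. Prevalence is the ratio estimator
with Taylor-linearised between-cluster variance, a normal-approximation CI
truncated to [0, 100]%, and deff = design variance / SRS variance. The
exact CI method behind published survey intervals is rarely stated, so CI
endpoints are treated as approximately — not exactly — reproducible.
Subgroup contrasts use a Rao–Scott-style correction: the Pearson chi-square
deflated by the mean level-specific design effect, with a
Satterthwaite-type degrees-of-freedom adjustment for heterogeneous design
effects. Direct standardisation weights band rates by an external standard
population; the packaged `standard_population_synthetic.csv` is a synthetic
approximation of a national 40+ age structure shipped so examples run —
real analyses must substitute official census counts. Ethnic groups with
fewer than 200 members pool as "Others"; rows with a missing factor value
are excluded and counted.

## Agreement statistics

Within-tolerance kappa is provided in two variants because published
"agreement within δ" kappas rarely state their dichotomisation: the default
bins values into δ-width bins and applies Cohen's kappa to the binned
table; the alternative (`method="tolerance"`) chance-corrects the event
|a−b| ≤ δ directly under independent-rater margins. Bland–Altman limits are
bias ± 1.96·SD of the paired differences. Landis–Koch verbal labels are
attached in reports only.

## Synthetic cohort generator

The generator emulates the study conditions of a national cluster survey;
its defaults are the conditions, not tuning knobs:

- **Design**: 305 clusters × 45 examined persons aged ≥40; age structure
  36.0/26.3/20.4/12.2/5.1% across the five 10-year bands.
- **Disease**: true prevalence 1.9/3.6/6.4/10.8/14.7% by band (marginal
  5.0%); a logit-normal cluster effect (SD 0.7) calibrated to a design
  effect near 2 at 45 persons per cluster, with per-band offsets solved by
  Gauss–Hermite quadrature so the *marginal* prevalence matches the band
  values despite the random effect. 39% of cases bilateral; types
  secondary 7.8%, and 14% of primary angle-closure.
- **Measurements**: normal-eye IOP ~ N(14, 4) with a 2% ocular-hypertension
  component at N(24, 4) — giving the observed ≈4% of non-glaucomatous eyes
  above 21 mmHg once recorded to whole mmHg — against a trimodal mixture in
  glaucomatous eyes (12/28/50 mmHg, SDs 3/5/6, weights 0.50/0.35/0.15,
  mean ≈23). Normal-eye VCDR is an explicit discrete distribution on the
  0.05 grid whose nearest-rank percentiles sit exactly at the published
  cut-offs (image 0.70/0.75, clinical 0.60/0.70), so threshold derivation
  from the simulated normative subsample reproduces the default cut set;
  glaucomatous eyes draw 0.65 + 0.35·Beta(3,1) with a 2% low-cup
  ("pressure-dominant") tail that only the 2b path can catch. Eyes within
  a person share a Gaussian-copula factor (share 0.95), calibrated so the
  normative image-scale asymmetry 97.5th percentile lands at 0.10; an
  eye's clinical grade is a noisier copy of the same latent (share 0.85)
  plus digit preference, which yields non-trivial clinical-vs-image
  agreement statistics.
- **Acuity and blindness**: healthy logMAR drifts with age; a person-level
  cataract mixture produces ≈3% bilateral blindness among non-cases; among
  bilateral cases 51% are end-stage (both eyes blind) and other case eyes
  go blind with probability 0.20 — targeting roughly one in five cases
  blind and somewhat over a third of case eyes worse than 3/60.
- **Missingness**: detailed-exam eyes keep a photographic grade with
  probability 0.66, fall back to a clinical grade with 0.205 and lose disc
  grading entirely with 0.135; censoring is correlated within person
  (camera/electricity failures hit both eyes) and elevated for blind eyes
  (dense media opacity), with the non-blind rate solved so the marginal
  stays at 13.5%. Reason codes follow the field mix (cataract, corneal
  opacity, camera faults, …) and eye-disease reasons co-occur with poor
  acuity. Fields are absent for 40% of eyes that need them — except in the
  normative subsample, whose protocol was complete — ≈10% of performed
  tests are unreliable, and profoundly blind eyes are usually untestable
  (which is what populates category 3). Gonioscopy is performed only where
  indicated and lost in 58% of indicated eyes (field humidity damage),
  calibrated to the observed share of type-unclassifiable cases. IOP and
  Van Herick grading thin at 14.2% / 8.9%.

All draws flow from `numpy.random.default_rng` seeded from the config, with
deterministic substreams for the censoring and field-generation stages;
cohorts are byte-identical across processes and hash seeds.

**What the synthetic cohorts do not capture**: no spatial or
geopolitical-zone structure beyond cluster labels, no ethnicity- or
sex-specific risk (subgroup differences in simulated output are sampling
noise), independence between IOP mixture component and cup size within
cases, Gaussian copula tails (the derived 99.5th asymmetry percentiles come
out one grid step below the published 0.20/0.30), and no modelling of the
inter-*observer* repeat-grading study (the pipeline's agreement table
compares the clinical and photographic *methods*). Passing tests therefore
establish the correctness of the rules and estimators and the internal
consistency of the pipeline — not the epidemiology of any real population.

## Problem sizes used

The default test suite and the acceptance script scale the simulations to
keep runs snappy while leaving percentile and coverage margins comfortable:
the main acceptance run uses 150 clusters × 45 persons (≈6 750 persons),
threshold derivation a 280-cluster cohort (≈1 700 normative persons after
exclusions), CI coverage 1 000 replicates of 120 clusters, parameter
recovery 100 replicates of 40-cluster surveys, and the exhaustive field
oracle a reduced 8-zone grid (5⁸ = 390 625 maps). At these sizes the
derived image-scale VCDR cut-offs are stable; the 99.5th percentiles would
flip occasionally below ~1 000 normative eyes.

## Known limitations

- The classifier is faithful to the evidence hierarchy, which has imperfect
  specificity: normal eyes with a 99.5th-percentile cup and no usable field
  are counted (category 2), as in the source design — so a zero-prevalence
  cohort does not yield zero diagnoses.
- CI endpoints, the Rao–Scott p-values and the derived IOP cut-off (which
  lands at 27 rather than 28 mmHg under the configured normal-IOP mixture)
  are approximate reproductions; they are not exact-match quantities.
- The reduced-grid field oracle exercises every rule except the 17-zone
  central-zone conventions, which are covered by example-based tests.
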