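# glaucoprev

Analysis machinery for population-based glaucoma prevalence surveys that use
the ISGEO (International Society of Geographical and Epidemiological
Ophthalmology) case definition — the design used by national blindness
surveys in which adults aged 40+ are sampled in clusters, screened with
frequency-doubling technology (FDT) perimetry, and classified as glaucoma
cases from optic-disc structure, visual function and pressure evidence.

It is written for epidemiologists and biostatisticians who need the full
chain from raw person/eye-level survey tables to publishable prevalence
tables, and for methodologists who want to stress-test that chain on
synthetic cohorts with known truth.

## What it implements

- **FDT C-20 field grading** (`glaucoprev.vf`): screening/threshold
  reliability rules, the threshold-test trigger (≥3 defects at p<1% or ≥2
  at p<0.5%), and grading of the pattern-deviation probability (PDP) map
  against the total-deviation (TDP) map into
  normal / possible / probable / definite / unlikely.
- **Population percentile thresholds** (`glaucoprev.thresholds`):
  nearest-rank 97.5th/99.5th percentiles of VCDR (vertical cup:disc ratio),
  VCDR asymmetry and IOP in a normative 1-in-7 subsample, plus the published
  cut set (image scale 0.70/0.75 VCDR, 0.10/0.20 asymmetry; clinical scale
  0.60/0.70 and 0.20/0.30; IOP 28 mmHg) as a constant.
- **ISGEO classification** (`glaucoprev.isgeo`): per-eye categories —
  1 (structural ≥97.5th percentile + typical field defect),
  2 (structural ≥99.5th percentile, field unusable),
  2b (modest cup but IOP ≥99.5th percentile with RAPD/corneal oedema),
  3 (disc not seen, perimetry impossible: blindness + high IOP, or glaucoma
  history) — person-level aggregation by highest evidence, and glaucoma type
  (POAG / PACG by gonioscopy, secondary, unclassified).
- **Cluster-survey statistics** (`glaucoprev.survey`): ratio-estimated
  prevalence with Taylor-linearised cluster-robust 95% CIs and design
  effects, age-specific and subgroup tables, Rao–Scott-corrected group
  tests, direct age standardisation with burden projection, and blindness
  summaries.
- **Agreement statistics** (`glaucoprev.agreement`): Cohen's kappa,
  within-tolerance kappa for continuous grades, Bland–Altman limits of
  agreement, percent agreement.
- **Synthetic survey generator** (`glaucoprev.simulate`): cluster-sampled
  cohorts with age-rising prevalence, calibrated measurement distributions
  and realistic missingness, plus a truth table — so the whole pipeline is
  testable without any restricted data.

At its statistical core the prevalence estimator is the ratio estimator
p̂ = Σᵢyᵢ / Σᵢnᵢ over clusters i, with design-based variance
v(p̂) = k/(k−1) · Σᵢ(yᵢ − p̂nᵢ)² / N² and design effect
deff = v(p̂) / [p̂(1−p̂)/N]; the age-standardised rate is
Σ_b r_b·W_b / Σ_b W_b for band rates r_b and standard population W_b.

## Worked example

```python
from glaucoprev import RunConfig, SimulationConfig, run_pipeline

bundle = run_pipeline(RunConfig(
    simulation=SimulationConfig(n_clusters=60, persons_per_cluster=45,
                                seed=42)))
print(bundle.crude.as_dict())
print(bundle.flow_counts["persons_by_category"])
```

prints

```
{'numerator': 137, 'denominator': 2700, 'prevalence_pct': 5.07,
 'ci_low_pct': 4.23, 'ci_high_pct': 5.92, 'design_effect': 1.049,
 'n_clusters': 60}
{'1': 44, '2': 84, '2b': 1, '3': 8}
```

Reading: of 2700 simulated persons in 60 clusters, 137 were classified as
glaucoma — a crude prevalence of 5.07% with a cluster-robust 95% CI of
4.23–5.92%. Of the cases, 44 carried level-1 evidence (large cup plus a
glaucomatous field), 84 level-2 (advanced cupping with no usable field),
1 level-2b and 8 level-3 (end-stage surrogate). The same bundle holds
age-specific and subgroup tables, the age-standardised rate (5.08%, a
projected 1.24 million affected adults under the packaged synthetic
standard population), blindness summaries (23.4% of cases blind;
36.8% of case eyes with acuity worse than 3/60) and agreement statistics.

The same pipeline runs from the shell:

```bash
glaucoprev simulate --out data/ --seed 42 --clusters 60
glaucoprev report --out report/ --seed 42 --clusters 60
glaucoprev derive-thresholds data/participants.csv data/eyes.csv --out thresholds.yaml
```

To analyse real survey tables instead, point `RunConfig` (or the
`grade-vf` / `classify` / `prevalence` subcommands) at your own
`participants.csv`, `eyes.csv` and `vf.csv` in the documented schema, and
supply an official census `standard_population.csv` in place of the
packaged synthetic one.

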