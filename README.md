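# phenoval

Validation machinery for **claims-based trial-eligibility phenotypes**:
synthetic longitudinal claims with known latent truth, a computable
eligibility phenotype over diagnosis/procedure/lab/vital tables, stratified
index-claim sampling, simulated chart abstraction with two-expert
adjudication, and exact positive-predictive-value (PPV) statistics.

## The problem

Pragmatic clinical trials increasingly recruit patients found by running a
rule set — a *computable phenotype* — over administrative claims. Before
trusting such an algorithm, one validates it against the gold standard of
medical-record review: sample algorithm-positive patients, retrieve their
charts, and measure how many the record actually confirms. The motivating
design here is the eligibility algorithm of a large aspirin-dosing trial in
patients with atherosclerotic cardiovascular disease: a patient qualifies
with a prior AMI, PCI, CABG, or chronic CAD, **plus** at least one of 11
risk-enrichment factors, and **no** bleeding-related exclusion. Chart
review of 185 retrieved records confirmed 168, a PPV of

```
PPV = k/n = 168/185 = 0.908,  exact 95% CI (Clopper–Pearson): (0.857, 0.946)
```

This package re-implements that whole validation pipeline as reusable,
fully testable code. Because no real claims can ship with it, the
`synth` module generates cohorts whose latent truth is known, and exposes
the **closed-form expected PPV** implied by its coding-error mixture — so
the end-to-end pipeline can be checked against an analytic oracle, not
just against itself.

## Core statistics

* **PPV** `k/n` with exact Clopper–Pearson limits from beta quantiles:
  lower = `B(α/2; k, n−k+1)`, upper = `B(1−α/2; k+1, n−k)`.
* **PPV ratios** between subgroups (strata, sex, age bands) via the Katz
  log method: `exp(log r ± z·SE)`, `SE = sqrt((n1−k1)/(k1·n1) + (n2−k2)/(k2·n2))`,
  with a parametric-bootstrap percentile interval as an alternative.
* **Expected PPV** of the generator: exact enumeration of the finite
  mixture (event eras, coding sensitivity, history re-mentions,
  false-positive codes, claims-invisible exclusions, abstraction misses
  and expert recovery) — see `docs/methods.md`.

## Worked example

Replay the packaged printed review tallies through the consensus
arithmetic and interval machinery:

```bash
phenoval replay-paper
```

```
Phenotype validation: positive predictive values
================================================================
Records: 185 obtained of 300 requested (retrieval rate 61.7%)
All patients - abstractor                          158/185 = 0.854 (0.795, 0.902)
All patients, after expert review (main result)    168/185 = 0.908 (0.857, 0.946)
Sensitivity analysis: CAD-only counted confirmed   172/185 = 0.93 (0.883, 0.962)
AMI stratum (stratum 1)                            97/107 = 0.907 (0.835, 0.954)
PCI/CABG stratum (stratum 2)                       71/78 = 0.91 (0.824, 0.963)
Aged < 65 years                                    34/35 = 0.971 (0.851, 0.999)
Aged >= 65 years                                   134/150 = 0.893 (0.833, 0.938)
Female patients                                    62/70 = 0.886 (0.787, 0.949)
Male patients                                      106/115 = 0.922 (0.857, 0.964)
----------------------------------------------------------------
PPV ratio strata_ami_over_pci_cabg                 0.996 (0.908, 1.092)
PPV ratio sex_male_over_female                     1.041 (0.942, 1.15)
PPV ratio age_ge65_over_lt65                       0.92 (0.85, 0.995)
```

Reading it: the abstractor alone confirmed 158/185 records; expert review
reversed ten non-confirmed records (mostly events documented in the
distant past), lifting the PPV to 0.908; counting CAD-only records as
confirmed (the sensitivity analysis) gives 0.930. The stratum ratio 0.996
says patients flagged by AMI codes validate as well as those flagged by
PCI/CABG codes.

The same numbers are available as a library:

```python
from phenoval import ValidationStudy, clopper_pearson, ppv_ratio

results = ValidationStudy.from_paper_fixture().fit()
results.overall            # 168/185 = 0.908 (0.857, 0.946)
clopper_pearson(168, 185)  # (0.8569..., 0.9455...)
ppv_ratio(97, 107, 71, 78).ratio  # 0.9959...
```

A fully synthetic end-to-end run — generate a cohort whose closed-form
expected PPV is calibrated to 0.91, phenotype it, draw the two-stratum
sample, simulate retrieval/abstraction/review, and report:

```python
from phenoval import default_pipeline_config, run_pipeline
config = default_pipeline_config(seed=42, n_patients=5000)
results = run_pipeline(config, "runs/demo")
print(results.overall)   # e.g. 89/96 = 0.927 (0.856, 0.97)
```

Every artifact (cohort CSVs, eligibility flags, sampling frame, review
outcomes, report, manifest) lands in the run directory, byte-identical
for a fixed seed. The same pipeline is scriptable stage by stage via the
CLI subcommands `generate`, `phenotype`, `sample`, `adjudicate`,
`report`, `run`, and `replay-paper`.

## Layout

```
src/phenoval/registry.py      codeset registry (ICD-9-CM / ICD-10-CM / CPT)
src/phenoval/cohort.py        claims tables, CSV round trip, invariants
src/phenoval/synth.py         synthetic cohorts + closed-form expected PPV
src/phenoval/phenotype.py     the eligibility phenotype
src/phenoval/sampling.py      index claims, regulatory filter, strata
src/phenoval/adjudication.py  abstraction, expert review, printed-tally replay
src/phenoval/valstats.py      PPV / intervals / ratios, ValidationStudy
src/phenoval/pipeline.py      end-to-end orchestration, manifest
src/phenoval/cli.py           command-line front end
docs/methods.md               models, assumptions, parameter choices
```
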