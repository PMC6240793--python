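# Methods

## The eligibility phenotype

A patient is study-eligible at an `as_of` date when all three hold:

1. **Qualifying cardiac history** — at least one claim code mapping to
   AMI, PCI, CABG, or chronic CAD/ischemic heart disease. Codes count in
   *any* claim position, any care setting (facility or professional), and
   with *no lookback limit*: the design deliberately admits prevalent
   cases, e.g. a bypass graft from 2007.
2. **At least one of 11 enrichment factors** — age ≥ 65 at `as_of`;
   creatinine ≥ 1.5 mg/dL (any time); LDL ≥ 130 mg/dL and systolic BP
   ≥ 140 mmHg restricted to the trailing 365 days; LVEF < 50 % (strict);
   current smoking (most recent observation); and five diagnosis-coded
   conditions (diabetes, cerebrovascular disease, peripheral arterial
   disease, heart failure, three-vessel CAD) with unrestricted lookback.
3. **No claims-coded exclusion** — significant bleeding or a GI-bleed
   condition. Aspirin allergy also excludes a patient from the trial but
   has no claims representation, so the phenotype cannot see it; this
   asymmetry is the main structural source of false positives that no
   coding improvement can remove.

Window arithmetic: dates are ISO-8601 calendar dates; every window is a
closed interval in days; "past 12 months" is `[as_of − 365 d, as_of]`.
Thresholds are inclusive ("at least") except LVEF, which is strictly
below 50. Age uses calendar-year arithmetic (born 1952-04-01 turns 65 on
2017-04-01, inclusive).

Code matching is prefix-based for ICD families (`I21` matches `I21.09`)
and exact for CPT, the standard claims practice. The shipped code lists
are small representative families per concept, deliberately mutually
disjoint (e.g. the old-MI history code `I25.2` belongs to the AMI concept
and is excluded from the generic-CAD prefixes), and fully overridable
from YAML. They make no claim of matching any production phenotype's
lists, which are not public in citable form.

The era rule — ICD-9-CM diagnoses may not be dated on/after 2015-10-01 —
is a hard structural invariant enforced at load time.

## The synthetic cohort generator

The generator emulates the *conditions* of a claims-validation study, not
any real population:

* Latent truth per patient: independent Bernoulli draws for each event
  type (AMI 0.20, PCI 0.15, CABG 0.08), chronic CAD (0.35), the 11
  enrichment factors (age from a Normal(66, 12) truncated to 40–95; the
  others at prevalences of 0.03–0.25 typical of an at-risk adult claims
  population), and three exclusions (GI bleed 0.02, bleeding disorder
  0.01, aspirin allergy 0.01). Independence is assumed because no joint
  distribution is available to fit, and it is what keeps the expected PPV
  in closed form.
* Event dates are uniform over the 2006-01-01 .. 2017-04-01 observation
  window, so most events are "distant" — exactly the prevalent-case
  regime the phenotype must handle.
* Coding: a true event emits a claim at its event date with probability
  `code_sensitivity` = 0.85, facility-setting with probability 0.6, coded
  in the system of its era. A *coded* event additionally emits one
  ICD-10-era "history of X" re-mention claim with probability 0.5 — the
  mechanism by which a 2007 CABG can anchor a 2016 facility claim.
  Patients with no true event emit one spurious qualifying code in the
  ICD-10 era with probability `code_false_positive_rate` (the miscoded
  non-cardiology encounter). Exclusions are coded with sensitivity 0.5;
  aspirin allergy never emits a claim (verified bit-for-bit: the claims
  stream is identical whether the allergy prevalence is 0 or 1).
* Administrative flags (fully insured 0.25, contact info complete 0.95,
  do-not-contact 0.02) are drawn independently of all clinical truth, so
  the regulatory filter and record retrieval cannot bias the PPV.
* One seed, split into independent substreams (truth, dates, coding,
  clinical values, administrative), makes every run reproducible
  byte-for-byte.

**Not emulated:** enrollment gaps, billing sequences and costs,
comorbidity correlation structure, coding drift within an era,
facility-level clustering of retrieval success, and any geography or
seasonality. Passing tests therefore demonstrate correctness of the
*pipeline logic and statistics under known truth*, not performance of the
phenotype on real claims.

## Closed-form expected PPV

`expected_ppv(config)` computes P(record would confirm | patient flagged)
exactly, by enumerating the generator's mixture:

* Per event type, the event date is integrated over segments bounded by
  the ICD-10-era cutoff and the abstraction recency horizon. Within a
  segment a coded event is **claims-visible** (can yield a recent facility
  index claim) with probability `1 − (1 − f)(1 − r·f)` post-cutoff (own
  claim or re-mention; `f` facility fraction, `r` re-mention rate) and
  `r·f` pre-cutoff; it is **documented after review** unless it is
  distant *and* missed by the abstractor *and* unrecovered by both
  experts, probability `m(1 − d)²`.
* Event types combine by independence through the inclusion–exclusion
  identity P(≥1 visible ∧ ≥1 documented) = 1 − Π(no-vis) − Π(no-doc) +
  Π(neither).
* The false-positive branch adds `Π(1−p_event) · fp · f` to the flagged
  mass; exclusion terms multiply the numerator by P(no true exclusion)
  and the denominator by P(no *coded* exclusion).
* Enrichment prevalence cancels from the ratio entirely, because chart
  review confirms events and exclusions, not enrichment — a useful
  structural fact: enrichment coding errors cannot move the PPV.

`calibrate_false_positive_rate` inverts this function (Brent's method) to
set the false-positive rate so the expected PPV hits a target, 0.91 by
default — the realized value in the motivating study. The calibration is
a property of the closed form, never of any simulation outcome. A
50,000-patient simulation agrees with the closed form to well within the
0.01 tolerance asserted in the tests.

## Sampling and adjudication model

* **Index claim**: the most recent facility claim on/after 2015-10-01
  bearing an AMI/PCI/CABG code; date ties break on the lexicographically
  greatest claim id (any deterministic rule would do; this one is stable
  across file orderings). CAD-only patients are excluded from the
  validation frame by design, which is why "CAD only" is a
  *non-confirmation* category in the primary analysis and a confirmation
  in the sensitivity analysis.
* **Sample sizes**: the pipeline pins the two strata at n1 = 172 and
  n2 = 128 as in the motivating design. Note these are not
  `ceil(100/0.6) = 167` and `ceil(75/0.6) = 125`; how the original design
  inflated its request counts is not recoverable, so `required_requests`
  exposes an explicit inflation parameter instead of guessing.
* **Retrieval** is a single Bernoulli(0.617) per record, independent of
  truth (the five-outreach schedule is collapsed; only the final
  obtained/unobtainable status matters to the statistics). Unobtainable
  records leave the PPV denominator.
* **Abstraction** reads the latent truth, not the claims: documented
  events are the true events except that an event older than
  `horizon_days` = 730 is omitted with probability 0.08; chronic CAD and
  all exclusions (including aspirin allergy) are always documented.
* **Expert review**: all abstraction-non-confirmed records plus a random
  10 confirmed ones are reviewed. Each expert independently recovers each
  missed event with probability 0.9. Both-reverse flips the record; a
  split goes to conference, modelled as deterministic reclassification on
  the pooled findings (reproducible, and consistent with consensus being
  evidence-driven rather than a coin flip). Experts are symmetric and
  independent; no inter-rater correlation model is attempted. Confirmed
  records are never reversed downward — the error model only omits true
  events, it never fabricates them, so there is nothing for a downward
  reversal to act on.

The miss/recovery defaults reproduce the *scale* of the motivating
study's review dynamics (about 6 % of confirmed-at-truth records
initially missed, nearly all recovered on review); they are not fitted
quantities.

## Statistical choices

* Clopper–Pearson limits via beta quantiles; the brute-force
  tail-sum-inversion oracle lives only in the tests and the acceptance
  script, where the two agree to < 1e-9 for all k ≤ n ≤ 30.
* The ratio interval defaults to the Katz log method; the printed ratio
  intervals of the motivating study are treated as soft checks (agreement
  to ~2 decimals, not asserted), since that study does not name its
  method. Bootstrap percentile intervals agree with Katz to < 0.02 at the
  study's counts.
* Ratio orientation is fixed in the report schema as first-named over
  second-named group (AMI/PCI-CABG, male/female, ≥65/<65). The published
  table's stratum-ratio formula as printed evaluates to 1.004, while its
  printed value 0.996 corresponds to the AMI-over-PCI/CABG orientation;
  the report uses the orientation that reproduces the printed value.
* Display rounding is half-up to 3 decimals (1 decimal for percentages),
  matching the printed precision; all stored values are full precision.

## Problem sizes

The default test suite runs cohorts of 50–5,000 patients plus one
50,000-patient convergence check (a few seconds each); interval coverage
uses 10,000 binomial replicates; stratum-uniformity uses 10,000 draws on
a 20-patient pool. The acceptance script sizes its calibrated pipeline
run at 20,000 patients so the post-regulatory pool can fill the full
172 + 128 design, and its Monte-Carlo/closed-form comparison at 50,000
patients. All sizes are package choices made for statistical resolution.

## Known limitations

* Population-scale attrition counts of any real claims database are not
  reproducible from synthetic data and are out of scope; only the
  monotone structure of the attrition chain is asserted.
* The study design identifies PPV only: algorithm-negative patients are
  never sampled, so sensitivity, specificity and NPV are undefined here.
* Independence of truth components is a modelling convenience; real
  cardiac comorbidity is strongly correlated. A correlation structure
  would change subgroup compositions but not the validity of the
  estimators being tested.
* The conference-consensus model is deterministic; disagreement dynamics
  beyond "pooled evidence decides" are not modelled.
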