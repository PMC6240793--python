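import pandas as pd
import pytest

from phenoval.phenotype import (
    eligibility_results,
    enrichment_met,
    exclusion_flags,
    inclusion_flags,
    run_phenotype,
)
from phenoval.synth import GeneratorConfig, generate_cohort, truth_claims_eligible

from conftest import AS_OF, make_cohort


def one_patient(**kwargs):
    return make_cohort(demographics=[{"patient_id": "p1", **kwargs.pop("demo", {})}], **kwargs)


def test_distant_ami_still_counts_as_inclusion(registry):
    """Prevalent-case semantics: a 2007 event has no lookback limit."""
    cohort = one_patient(
        diagnoses=[{"patient_id": "p1", "claim_id": "c1", "service_date": "2007-03-10",
                    "code": "410.11", "code_system": "ICD9CM"}]
    )
    assert inclusion_flags(cohort, registry, AS_OF) == {"AMI"}


def test_no_qualifying_codes_empty_flags(registry):
    cohort = one_patient(
        diagnoses=[{"patient_id": "p1", "claim_id": "c1", "service_date": "2016-01-01", "code": "J45.40"}]
    )
    assert inclusion_flags(cohort, registry, AS_OF) == frozenset()


def test_any_claim_position_and_any_setting_count(registry):
    cohort = one_patient(
        diagnoses=[{"patient_id": "p1", "claim_id": "c1", "service_date": "2016-05-01",
                    "code": "I21.09", "position": 5, "setting": "professional"}]
    )
    assert inclusion_flags(cohort, registry, AS_OF) == {"AMI"}


def test_future_records_beyond_as_of_ignored(registry):
    cohort = one_patient(
        diagnoses=[{"patient_id": "p1", "claim_id": "c1", "service_date": "2016-05-01", "code": "I21.09"}]
    )
    assert inclusion_flags(cohort, registry, pd.Timestamp("2016-04-30")) == frozenset()


@pytest.mark.parametrize(
    "birth,expected",
    [("1952-04-01", True), ("1952-04-02", False)],  # exactly 65 vs one day short
)
def test_age_threshold_is_inclusive_at_65(registry, birth, expected):
    cohort = one_patient(demo={"birth_date": birth})
    met = enrichment_met(cohort, registry, AS_OF)
    assert ("age_ge_65" in met) is expected


def test_sbp_window_is_trailing_365_days(registry):
    recent = one_patient(
        demo={"birth_date": "1980-01-01"},
        vitals=[{"patient_id": "p1", "measure_date": "2016-06-01", "systolic_bp": 142.0}],
    )
    stale = one_patient(
        demo={"birth_date": "1980-01-01"},
        vitals=[{"patient_id": "p1", "measure_date": "2016-02-25", "systolic_bp": 142.0}],  # 400 days out
    )
    assert "sbp_ge_140_12mo" in enrichment_met(recent, registry, AS_OF)
    assert enrichment_met(stale, registry, AS_OF) == frozenset()


@pytest.mark.parametrize(
    "analyte,value,date,factor,expected",
    [
        ("creatinine", 1.5, "2010-01-01", "creatinine_ge_1_5", True),   # inclusive, no window
        ("creatinine", 1.49, "2016-06-01", "creatinine_ge_1_5", False),
        ("LDL", 130.0, "2016-12-01", "ldl_ge_130_12mo", True),          # inclusive, windowed
        ("LDL", 130.0, "2015-12-01", "ldl_ge_130_12mo", False),         # outside 365 days
    ],
)
def test_lab_thresholds(registry, analyte, value, date, factor, expected):
    cohort = one_patient(
        demo={"birth_date": "1980-01-01"},
        labs=[{"patient_id": "p1", "result_date": date, "analyte": analyte, "value": value}],
    )
    assert (factor in enrichment_met(cohort, registry, AS_OF)) is expected


@pytest.mark.parametrize("lvef,expected", [(49.0, True), (50.0, False)])
def test_lvef_threshold_is_strict(registry, lvef, expected):
    cohort = one_patient(
        demo={"birth_date": "1980-01-01"},
        vitals=[{"patient_id": "p1", "measure_date": "2012-01-01", "lvef_percent": lvef}],
    )
    assert ("lvef_lt_50" in enrichment_met(cohort, registry, AS_OF)) is expected


def test_gi_bleed_code_anywhere_in_history_excludes(registry):
    cohort = one_patient(
        diagnoses=[{"patient_id": "p1", "claim_id": "c1", "service_date": "2008-01-01",
                    "code": "578.9", "code_system": "ICD9CM"}]
    )
    assert exclusion_flags(cohort, registry, AS_OF) == {"gi_bleed"}


def test_aspirin_allergy_invisible_to_claims(registry):
    """A patient whose latent truth carries the allergy has no claim code
    for it, so the phenotype can never raise an exclusion."""
    config = GeneratorConfig(n_patients=50, seed=21, p_aspirin_allergy=1.0,
                             p_gi_bleed=0.0, p_bleeding_disorder=0.0)
    cohort, truth = generate_cohort(config)
    assert truth["true_aspirin_allergy"].all()
    frame = run_phenotype(cohort, registry, as_of=AS_OF)
    assert not frame[["excl_significant_bleeding", "excl_gi_bleed"]].any().any()


def _eligible(frame, pid="p1"):
    return bool(frame.loc[frame["patient_id"] == pid, "eligible"].iloc[0])


def test_composite_verdicts(registry):
    ami = {"patient_id": "p1", "claim_id": "c1", "service_date": "2016-01-01", "code": "I21.09"}
    gi = {"patient_id": "p1", "claim_id": "c2", "service_date": "2016-02-01", "code": "K92.1"}
    cad = {"patient_id": "p1", "claim_id": "c3", "service_date": "2016-03-01", "code": "I25.10"}
    old = {"birth_date": "1947-01-01"}  # age 70 at as_of
    young = {"birth_date": "1980-01-01"}

    # qualifying event + enrichment, no exclusion -> eligible
    assert _eligible(run_phenotype(one_patient(demo=old, diagnoses=[ami]), registry, AS_OF))
    # CAD alone without any enrichment factor -> not eligible
    assert not _eligible(run_phenotype(one_patient(demo=young, diagnoses=[cad]), registry, AS_OF))
    # exclusion code vetoes an otherwise eligible patient
    frame = run_phenotype(one_patient(demo=old, diagnoses=[ami, gi]), registry, AS_OF)
    assert not _eligible(frame)
    assert bool(frame["excl_gi_bleed"].iloc[0])


def test_monotonicity_of_eligibility(registry):
    """Adding qualifying/enrichment records never revokes eligibility;
    adding an exclusion record never grants it."""
    old = {"birth_date": "1947-01-01"}
    ami = {"patient_id": "p1", "claim_id": "c1", "service_date": "2016-01-01", "code": "I21.09"}
    extra_incl = {"patient_id": "p1", "claim_id": "c4", "service_date": "2016-04-01", "code": "Z95.1"}
    gi = {"patient_id": "p1", "claim_id": "c2", "service_date": "2016-02-01", "code": "K92.1"}

    base = run_phenotype(one_patient(demo=old, diagnoses=[ami]), registry, AS_OF)
    more = run_phenotype(one_patient(demo=old, diagnoses=[ami, extra_incl]), registry, AS_OF)
    assert _eligible(base) and _eligible(more)

    ineligible = run_phenotype(one_patient(demo=old, diagnoses=[ami, gi]), registry, AS_OF)
    still = run_phenotype(one_patient(demo=old, diagnoses=[ami, gi, extra_incl]), registry, AS_OF)
    assert not _eligible(ineligible) and not _eligible(still)


def test_result_invariant_to_record_order(registry):
    config = GeneratorConfig(n_patients=120, seed=8)
    cohort, _ = generate_cohort(config)
    frame_a = run_phenotype(cohort, registry, as_of=AS_OF)

    shuffled = cohort
    shuffled.diagnoses = cohort.diagnoses.sample(frac=1.0, random_state=0).reset_index(drop=True)
    shuffled.vitals = cohort.vitals.sample(frac=1.0, random_state=1).reset_index(drop=True)
    frame_b = run_phenotype(shuffled, registry, as_of=AS_OF)

    a = frame_a.sort_values("patient_id").reset_index(drop=True)
    b = frame_b.sort_values("patient_id").reset_index(drop=True)
    pd.testing.assert_frame_equal(a, b)


def test_perfect_coding_matches_truth_eligibility(registry):
    """Oracle equivalence: with every coding channel error-free the
    phenotype verdict equals the truth-derived verdict for all patients."""
    config = GeneratorConfig(
        n_patients=3000, seed=5, code_sensitivity=1.0, code_false_positive_rate=0.0,
        exclusion_code_sensitivity=1.0, enrichment_sensitivity=1.0, p_aspirin_allergy=0.0,
    )
    cohort, truth = generate_cohort(config)
    frame = run_phenotype(cohort, registry, as_of=config.end)
    merged = frame.merge(
        truth[["patient_id"]].assign(expected=truth_claims_eligible(truth).values),
        on="patient_id",
    )
    assert (merged["eligible"] == merged["expected"]).all()


def test_eligibility_results_consistency(registry):
    cohort, _ = generate_cohort(GeneratorConfig(n_patients=30, seed=14))
    frame = run_phenotype(cohort, registry, as_of=AS_OF)
    results = eligibility_results(frame)
    assert len(results) == 30
    for r in results:
        assert r.eligible == (bool(r.inclusion_flags) and bool(r.enrichment_met) and not r.exclusion_flags)
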