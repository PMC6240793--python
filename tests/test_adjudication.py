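import numpy as np
import pandas as pd
import pytest

from phenoval.adjudication import (
    CONFIRMED,
    NON_CONFIRMED,
    AbstractionErrorModel,
    FixtureError,
    classify_confirmation,
    expert_review,
    load_paper_fixture,
    outcome_accounting,
    replay_paper_counts,
    simulate_abstraction,
    simulate_retrieval,
)
from phenoval.synth import GeneratorConfig, generate_cohort, truth_claims_eligible

AS_OF = pd.Timestamp("2017-04-01")


def _truth_row(pid="p1", ami=None, pci=None, cabg=None, cad=False,
               allergy=False, gi=False, bd=False):
    return {
        "patient_id": pid,
        "true_ami": ami is not None, "ami_date": ami or "",
        "true_pci": pci is not None, "pci_date": pci or "",
        "true_cabg": cabg is not None, "cabg_date": cabg or "",
        "true_cad": cad,
        "enrichment_truth": "age_ge_65",
        "true_gi_bleed": gi, "true_bleeding_disorder": bd, "true_aspirin_allergy": allergy,
    }


# --- confirmation rules -------------------------------------------------------

@pytest.mark.parametrize(
    "events,exclusions,mode,status,category",
    [
        ({"AMI"}, set(), "primary", CONFIRMED, "none"),
        ({"CABG", "CAD"}, set(), "primary", CONFIRMED, "none"),
        ({"CAD"}, set(), "primary", NON_CONFIRMED, "cad_only"),
        ({"CAD"}, set(), "sensitivity", CONFIRMED, "none"),
        ({"AMI"}, {"gi_bleed"}, "primary", NON_CONFIRMED, "exclusion_present"),
        ({"AMI"}, {"aspirin_allergy"}, "sensitivity", NON_CONFIRMED, "exclusion_present"),
        (set(), set(), "primary", NON_CONFIRMED, "no_evidence"),
    ],
)
def test_classify_confirmation(events, exclusions, mode, status, category):
    assert classify_confirmation(events, exclusions, mode) == (status, category)


# --- retrieval ------------------------------------------------------------------

def test_retrieval_rate_extremes():
    pids = [f"p{i}" for i in range(50)]
    assert simulate_retrieval(pids, 1.0, seed=0).all()
    assert not simulate_retrieval(pids, 0.0, seed=0).any()


def test_retrieval_mean_matches_binomial_expectation():
    """1000 replicates of 300 requests at rate 0.617: mean within 3 SE of 185.1."""
    pids = [f"p{i}" for i in range(300)]
    totals = [simulate_retrieval(pids, 0.617, seed=s).sum() for s in range(1000)]
    mean = np.mean(totals)
    se = np.sqrt(300 * 0.617 * 0.383 / 1000)
    assert abs(mean - 185.1) < 3 * se


def test_retrieval_is_independent_of_truth():
    """Truth-eligibility prevalence among retrieved vs non-retrieved differs
    by less than 3 SE over pooled replicates."""
    cohort, truth = generate_cohort(GeneratorConfig(n_patients=2000, seed=23))
    eligible = truth_claims_eligible(truth).to_numpy()
    diffs, ses = [], []
    for s in range(50):
        got = simulate_retrieval(truth["patient_id"], 0.617, seed=1000 + s).to_numpy()
        p1, p0 = eligible[got].mean(), eligible[~got].mean()
        n1, n0 = got.sum(), (~got).sum()
        pooled = eligible.mean()
        diffs.append(p1 - p0)
        ses.append(np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n0)))
    grand = np.mean(diffs)
    grand_se = np.sqrt(np.mean(np.square(ses)) / len(ses))
    assert abs(grand) < 3 * grand_se


# --- abstraction ----------------------------------------------------------------

def test_recent_event_always_documented():
    truth = pd.DataFrame([_truth_row(ami="2016-05-01")])
    model = AbstractionErrorModel(miss_distant_event_prob=1.0, horizon_days=730)
    rec = simulate_abstraction(["p1"], truth, model, seed=0, as_of=AS_OF).iloc[0]
    assert "AMI" in rec["doc_events"]


def test_distant_event_missed_with_certain_miss_probability():
    truth = pd.DataFrame([_truth_row(cabg="2007-06-01")])
    model = AbstractionErrorModel(miss_distant_event_prob=1.0, horizon_days=730)
    rec = simulate_abstraction(["p1"], truth, model, seed=0, as_of=AS_OF).iloc[0]
    assert rec["doc_events"] == frozenset()
    assert rec["missed_events"] == {"CABG"}


def test_record_documents_aspirin_allergy_that_claims_cannot_see():
    truth = pd.DataFrame([_truth_row(ami="2016-05-01", allergy=True)])
    model = AbstractionErrorModel()
    rec = simulate_abstraction(["p1"], truth, model, seed=0, as_of=AS_OF).iloc[0]
    assert "aspirin_allergy" in rec["doc_exclusions"]


# --- expert review ---------------------------------------------------------------

def _review(truth_rows, model, seed=0):
    truth = pd.DataFrame(truth_rows)
    abstraction = simulate_abstraction(truth["patient_id"], truth, model, seed=seed, as_of=AS_OF)
    return abstraction, expert_review(abstraction, model, seed=seed)


def test_both_experts_recover_distant_event_and_reverse():
    model = AbstractionErrorModel(miss_distant_event_prob=1.0, expert_detect_prob=1.0)
    _, outcomes = _review([_truth_row(cabg="2007-06-01")], model)
    row = outcomes.iloc[0]
    assert row["abstractor_status"] == NON_CONFIRMED
    assert row["expert1_reverse"] and row["expert2_reverse"]
    assert row["final_status_primary"] == CONFIRMED


def test_unrecoverable_miss_stands_non_confirmed():
    model = AbstractionErrorModel(miss_distant_event_prob=1.0, expert_detect_prob=0.0)
    _, outcomes = _review([_truth_row(cabg="2007-06-01")], model)
    row = outcomes.iloc[0]
    assert not row["expert1_reverse"] and not row["expert2_reverse"]
    assert row["final_status_primary"] == NON_CONFIRMED
    assert row["nonconfirm_category"] == "no_evidence"


def test_confirmed_records_never_reversed_downward():
    model = AbstractionErrorModel(miss_distant_event_prob=0.0)
    _, outcomes = _review([_truth_row(pid=f"p{i}", ami="2016-05-01") for i in range(20)], model)
    assert (outcomes["final_status_primary"] == CONFIRMED).all()


def test_final_status_equals_reclassification_of_pooled_evidence():
    """Recomputation oracle: for every record, the final primary status must
    equal classify_confirmation applied to abstraction + expert recoveries."""
    model = AbstractionErrorModel(miss_distant_event_prob=0.7, expert_detect_prob=0.5)
    rows = [_truth_row(pid=f"p{i}", cabg="2007-06-01", cad=(i % 3 == 0)) for i in range(40)]
    abstraction, outcomes = _review(rows, model, seed=3)
    for (_, a), (_, o) in zip(abstraction.iterrows(), outcomes.iterrows()):
        evidence = set(a["doc_events"]) | ({"CAD"} if a["doc_cad"] else set())
        if o["expert1_reverse"] or o["expert2_reverse"]:
            # any reversal claim means at least one expert recovered something
            assert o["final_status_primary"] == CONFIRMED
        else:
            expected, _cat = classify_confirmation(evidence, a["doc_exclusions"], "primary")
            assert o["final_status_primary"] == expected


def test_sensitivity_confirmations_superset_of_primary():
    model = AbstractionErrorModel(miss_distant_event_prob=0.5, expert_detect_prob=0.3)
    rows = [
        _truth_row(pid=f"p{i}", cabg="2007-06-01" if i % 2 else None, cad=(i % 3 == 0), gi=(i % 7 == 0))
        for i in range(60)
    ]
    _, outcomes = _review(rows, model, seed=5)
    primary = outcomes["final_status_primary"] == CONFIRMED
    sens = outcomes["final_status_sensitivity"] == CONFIRMED
    assert (sens | ~primary).all()  # primary confirmed implies sensitivity confirmed


def test_accounting_identity_on_simulated_run():
    model = AbstractionErrorModel(miss_distant_event_prob=0.3, expert_detect_prob=0.6)
    rows = [
        _truth_row(pid=f"p{i}", ami="2016-01-01" if i % 2 else None,
                   cabg="2007-06-01" if i % 5 == 0 else None,
                   cad=(i % 3 == 0), gi=(i % 11 == 0), allergy=(i % 13 == 0))
        for i in range(80)
    ]
    _, outcomes = _review(rows, model, seed=9)
    acct = outcome_accounting(outcomes)
    assert (
        acct["primary_confirmed"]
        + acct["exclusion_present"] + acct["cad_only"] + acct["no_evidence"]
        == acct["reviewed_records"]
    )


# --- printed-count replay ----------------------------------------------------------

def test_replay_reproduces_final_confirmation_counts():
    replay = replay_paper_counts()
    assert replay.obtained == 185
    assert replay.primary_confirmed == 168
    assert replay.sensitivity_confirmed == 172
    assert sum(replay.nonconfirm_categories.values()) == 185 - 168
    assert replay.retrieval_rate == pytest.approx(0.617, abs=5e-4)


def test_replay_rejects_inconsistent_fixture():
    fx = load_paper_fixture()
    fx["nonconfirm_categories"]["no_evidence"] = 9  # breaks the arithmetic
    with pytest.raises(FixtureError, match="categories"):
        replay_paper_counts(fx)
    fx = load_paper_fixture()
    fx["split_cases"]["stand"] = 2
    with pytest.raises(FixtureError, match="split"):
        replay_paper_counts(fx)
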