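"""Simulated record retrieval, abstraction, and two-expert adjudication.

The chart review is the study's gold standard: an abstractor extracts the
documented cardiac events and exclusion conditions from each retrieved
record, and a record *confirms* eligibility when it documents AMI, PCI or
CABG and no exclusion.  Two blinded experts then re-review all
abstraction-non-confirmed records (plus a small random sample of
confirmed ones): if both independently flag a record for reversal it is
reversed; if exactly one does, the decision is settled in conference —
modelled here as deterministic reclassification on the experts' pooled
findings.

The dominant abstraction error in this setting is omission of events far
in the past (a bypass graft a decade ago may not surface in a recent
discharge summary), captured by :class:`AbstractionErrorModel`.
Exclusion conditions — including aspirin allergy, which claims can never
see — are always visible to the abstractor, because the medical record
reflects the latent truth.

:func:`replay_paper_counts` applies the same consensus arithmetic to a
packaged fixture of the published study's printed tallies, yielding the
primary (168/185) and sensitivity (172/185) numerators.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .registry import AMI, CABG, CAD, PCI

EVENTS = (AMI, PCI, CABG)
EXCLUSIONS = ("aspirin_allergy", "gi_bleed", "bleeding_disorder")

CONFIRMED = "confirmed"
NON_CONFIRMED = "non_confirmed"

CAT_EXCLUSION = "exclusion_present"
CAT_CAD_ONLY = "cad_only"
CAT_NO_EVIDENCE = "no_evidence"
CAT_NONE = "none"


@dataclass(frozen=True)
class AbstractionErrorModel:
    """How abstraction can deviate from truth, and how review recovers it.

    ``miss_distant_event_prob`` — probability the abstraction omits a true
    event dated more than ``horizon_days`` before the as-of date;
    ``expert_detect_prob`` — per-expert probability of recovering each
    missed event on manual review.
    """

    miss_distant_event_prob: float = 0.08
    horizon_days: int = 730
    expert_detect_prob: float = 0.9
    confirmed_review_sample: int = 10

    def __post_init__(self) -> None:
        for p in (self.miss_distant_event_prob, self.expert_detect_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class AbstractionRecord:
    patient_id: str
    retrieved: bool
    documented_events: frozenset[str] = frozenset()
    documented_exclusions: frozenset[str] = frozenset()
    record_context: str = "cardiology"


def classify_confirmation(
    documented_events, documented_exclusions, mode: str = "primary"
) -> tuple[str, str]:
    """Confirmation status and non-confirmation category for one record.

    Exclusion documented -> non-confirmed (both modes); else any of
    AMI/PCI/CABG -> confirmed; else CAD alone -> non-confirmed (CAD-only)
    in primary mode but confirmed in sensitivity mode; else no evidence.
    """
    if mode not in ("primary", "sensitivity"):
        raise ValueError(f"unknown mode {mode!r}")
    events = set(documented_events)
    if set(documented_exclusions):
        return NON_CONFIRMED, CAT_EXCLUSION
    if events & set(EVENTS):
        return CONFIRMED, CAT_NONE
    if CAD in events:
        if mode == "sensitivity":
            return CONFIRMED, CAT_NONE
        return NON_CONFIRMED, CAT_CAD_ONLY
    return NON_CONFIRMED, CAT_NO_EVIDENCE


def simulate_retrieval(patients, retrieval_rate: float, seed: int) -> pd.Series:
    """Independent Bernoulli(rate) per patient — retrieval never looks at truth."""
    if not 0 <= retrieval_rate <= 1:
        raise ValueError("retrieval_rate must lie in [0, 1]")
    patients = [str(p) for p in patients]
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    return pd.Series(rng.random(len(patients)) < retrieval_rate, index=pd.Index(patients, name="patient_id"))


def simulate_abstraction(
    retrieved_patients,
    truth: pd.DataFrame,
    error_model: AbstractionErrorModel,
    seed: int,
    as_of,
) -> pd.DataFrame:
    """Abstract each retrieved record against latent truth.

    Documented events are the true events, except that a true event dated
    before ``as_of - horizon_days`` is omitted with
    ``miss_distant_event_prob``; chronic CAD and all true exclusions are
    always documented.  Missed events are kept in latent ``miss_*``
    columns so that expert review can attempt to recover them.
    """
    as_of = pd.Timestamp(as_of)
    horizon = as_of - pd.Timedelta(days=error_model.horizon_days)
    t = truth.set_index("patient_id")
    pids = [str(p) for p in retrieved_patients]
    missing = [p for p in pids if p not in t.index]
    if missing:
        raise KeyError(f"truth missing for retrieved patient(s): {missing[:5]}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    rows = []
    for pid in pids:
        row = t.loc[pid]
        documented: set[str] = set()
        missed: set[str] = set()
        for event, flag_col, date_col in (
            (AMI, "true_ami", "ami_date"),
            (PCI, "true_pci", "pci_date"),
            (CABG, "true_cabg", "cabg_date"),
        ):
            if not bool(row[flag_col]):
                continue
            event_date = pd.Timestamp(row[date_col])
            distant = event_date < horizon
            if distant and rng.random() < error_model.miss_distant_event_prob:
                missed.add(event)
            else:
                documented.add(event)
        if bool(row["true_cad"]):
            documented.add(CAD)
        exclusions = {
            name
            for name, col in (
                ("aspirin_allergy", "true_aspirin_allergy"),
                ("gi_bleed", "true_gi_bleed"),
                ("bleeding_disorder", "true_bleeding_disorder"),
            )
            if bool(row[col])
        }
        context = "cardiology" if documented & ({CAD} | set(EVENTS)) else "non_cardiology"
        rows.append(
            {
                "patient_id": pid,
                "retrieved": True,
                "doc_events": frozenset(documented & set(EVENTS)),
                "doc_cad": CAD in documented,
                "doc_exclusions": frozenset(exclusions),
                "missed_events": frozenset(missed),
                "record_context": context,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "retrieved", "doc_events", "doc_cad",
            "doc_exclusions", "missed_events", "record_context",
        ],
    )


def _doc_set(rec) -> set[str]:
    events = set(rec["doc_events"])
    if rec["doc_cad"]:
        events.add(CAD)
    return events


def expert_review(
    abstraction: pd.DataFrame,
    error_model: AbstractionErrorModel,
    seed: int,
) -> pd.DataFrame:
    """Apply the two-expert consensus rules to every abstracted record.

    All abstraction-non-confirmed records plus a seeded random sample of
    confirmed records are reviewed.  Each expert independently recovers
    each missed event with ``expert_detect_prob``; both-reverse flips the
    record outright, a split goes to conference, which reclassifies on the
    pooled findings.  Confirmed records are never reversed downward.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    statuses = [
        classify_confirmation(_doc_set(rec), rec["doc_exclusions"], "primary")[0]
        for _, rec in abstraction.iterrows()
    ]
    confirmed_idx = [i for i, s in enumerate(statuses) if s == CONFIRMED]
    k = min(error_model.confirmed_review_sample, len(confirmed_idx))
    sampled_confirmed = set(
        rng.choice(confirmed_idx, size=k, replace=False).tolist() if k else []
    )

    out = []
    for i, (_, rec) in enumerate(abstraction.iterrows()):
        abstractor_status = statuses[i]
        docs = _doc_set(rec)
        exclusions = rec["doc_exclusions"]
        missed = set(rec["missed_events"])
        reviewed = abstractor_status == NON_CONFIRMED or i in sampled_confirmed

        expert_reverse = [False, False]
        recovered: list[set[str]] = [set(), set()]
        if reviewed:
            for e in range(2):
                recovered[e] = {ev for ev in sorted(missed) if rng.random() < error_model.expert_detect_prob}
                status_e = classify_confirmation(docs | recovered[e], exclusions, "primary")[0]
                expert_reverse[e] = status_e != abstractor_status

        conference = CAT_NONE
        if sum(expert_reverse) == 2 or sum(expert_reverse) == 1:
            evidence = docs | recovered[0] | recovered[1]
        else:
            evidence = docs
        if sum(expert_reverse) == 1:
            pooled_primary = classify_confirmation(evidence, exclusions, "primary")[0]
            pooled_sens = classify_confirmation(evidence, exclusions, "sensitivity")[0]
            if pooled_primary != abstractor_status:
                conference = "reverse"
            elif pooled_sens == CONFIRMED and pooled_primary == NON_CONFIRMED:
                conference = "reverse_if_cad_counts"
            else:
                conference = "stand"

        final_primary, category = classify_confirmation(evidence, exclusions, "primary")
        final_sens, _ = classify_confirmation(evidence, exclusions, "sensitivity")
        out.append(
            {
                "patient_id": rec["patient_id"],
                "abstractor_status": abstractor_status,
                "reviewed": reviewed,
                "expert1_reverse": expert_reverse[0],
                "expert2_reverse": expert_reverse[1],
                "conference_decision": conference,
                "final_status_primary": final_primary,
                "final_status_sensitivity": final_sens,
                "nonconfirm_category": category,
            }
        )
    return pd.DataFrame(out)


def outcome_accounting(outcomes: pd.DataFrame) -> dict[str, int]:
    """Tallies mirroring the published study's review bookkeeping."""
    cats = outcomes.loc[outcomes["final_status_primary"] == NON_CONFIRMED, "nonconfirm_category"]
    return {
        "reviewed_records": int(len(outcomes)),
        "abstractor_confirmed": int((outcomes["abstractor_status"] == CONFIRMED).sum()),
        "primary_confirmed": int((outcomes["final_status_primary"] == CONFIRMED).sum()),
        "sensitivity_confirmed": int((outcomes["final_status_sensitivity"] == CONFIRMED).sum()),
        CAT_EXCLUSION: int((cats == CAT_EXCLUSION).sum()),
        CAT_CAD_ONLY: int((cats == CAT_CAD_ONLY).sum()),
        CAT_NO_EVIDENCE: int((cats == CAT_NO_EVIDENCE).sum()),
    }


# ---------------------------------------------------------------------------
# replay of the published printed tallies
# ---------------------------------------------------------------------------

class FixtureError(ValueError):
    """The printed-count fixture is internally inconsistent."""


@dataclass(frozen=True)
class ReplayCounts:
    requested: int
    obtained: int
    abstractor_confirmed: int
    primary_confirmed: int
    sensitivity_confirmed: int
    nonconfirm_categories: dict
    strata: dict
    sex: dict
    age: dict

    @property
    def retrieval_rate(self) -> float:
        return self.obtained / self.requested


def load_paper_fixture() -> dict:
    """The packaged printed-count fixture as a dict."""
    with resources.files("phenoval.data").joinpath("review_counts.json").open("r") as fh:
        return json.load(fh)


def replay_paper_counts(fixture: dict | None = None) -> ReplayCounts:
    """Apply the consensus arithmetic to the printed tallies.

    primary numerator = abstractor-confirmed + dual reversals + conference
    reversals; sensitivity numerator additionally counts the dual and
    conference CAD-only cases.  Raises :class:`FixtureError` if any
    accounting identity fails.
    """
    fx = fixture if fixture is not None else load_paper_fixture()
    split = fx["split_cases"]
    if split["total"] != split["stand"] + split["reverse_to_confirmed"] + split["cad_only"]:
        raise FixtureError("split cases do not partition")
    if fx["abstractor_confirmed"] + fx["abstractor_non_confirmed"] != fx["obtained"]:
        raise FixtureError("abstractor statuses do not sum to records obtained")
    reviewed_nc = (
        fx["dual_reversals_to_confirmed"]
        + fx["dual_cad_only_reversals"]
        + fx["dual_verified_non_confirmed"]
        + split["total"]
    )
    if reviewed_nc != fx["abstractor_non_confirmed"]:
        raise FixtureError("expert dispositions do not cover the non-confirmed records")

    primary = (
        fx["abstractor_confirmed"]
        + fx["dual_reversals_to_confirmed"]
        + split["reverse_to_confirmed"]
    )
    sensitivity = primary + fx["dual_cad_only_reversals"] + split["cad_only"]

    cats = fx["nonconfirm_categories"]
    if sum(cats.values()) != fx["obtained"] - primary:
        raise FixtureError("non-confirmation categories do not sum to the final non-confirmed count")

    for name in ("strata", "sex", "age"):
        groups = fx[name]
        if sum(g["n"] for g in groups.values()) != fx["obtained"]:
            raise FixtureError(f"{name} denominators do not partition the obtained records")
        if sum(g["confirmed"] for g in groups.values()) != primary:
            raise FixtureError(f"{name} numerators do not sum to the primary numerator")

    return ReplayCounts(
        requested=fx["requested"],
        obtained=fx["obtained"],
        abstractor_confirmed=fx["abstractor_confirmed"],
        primary_confirmed=primary,
        sensitivity_confirmed=sensitivity,
        nonconfirm_categories=dict(cats),
        strata={k: dict(v) for k, v in fx["strata"].items()},
        sex={k: dict(v) for k, v in fx["sex"].items()},
        age={k: dict(v) for k, v in fx["age"].items()},
    )
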