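"""The trial-eligibility computable phenotype over claims.

A patient is study-eligible iff all three of the following hold at the
``as_of`` date:

1. **qualifying cardiac history** — at least one claim code for AMI, PCI,
   CABG, or chronic CAD/ischemic heart disease, in *any* claim position,
   any care setting, with no lookback limit (prevalent cases count);
2. **at least one of 11 risk-enrichment factors** — age >= 65 at as_of,
   creatinine >= 1.5 mg/dL (any time), prevalent diabetes, known
   three-vessel CAD, cerebrovascular disease, peripheral arterial disease,
   LVEF < 50 %, chronic heart failure, systolic BP >= 140 mmHg in the past
   12 months, LDL >= 130 mg/dL in the past 12 months, or current smoking;
3. **no claims-coded exclusion** — no history of significant bleeding or a
   GI-bleed condition.  (Aspirin allergy also excludes a patient from the
   trial but is not recorded in claims, so the phenotype can never see it.)

Thresholds are inclusive ("at least") except LVEF, which is strictly
below 50.  "Past 12 months" is the closed interval [as_of - 365 days,
as_of].
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cohort import ClaimsCohort
from .registry import (
    CEREBROVASCULAR,
    CodeSetRegistry,
    DIABETES,
    ENRICHMENT_FACTORS,
    EXCLUSION_CONCEPTS,
    HEART_FAILURE,
    INCLUSION_CONCEPTS,
    PAD,
    THREE_VESSEL_CAD,
)

PAST_12_MONTHS_DAYS = 365

_DIAGNOSIS_FACTORS = {
    "diabetes": DIABETES,
    "three_vessel_cad": THREE_VESSEL_CAD,
    "cerebrovascular_disease": CEREBROVASCULAR,
    "peripheral_arterial_disease": PAD,
    "heart_failure": HEART_FAILURE,
}


@dataclass(frozen=True)
class EligibilityResult:
    """Per-patient phenotype verdict with full reason codes."""

    patient_id: str
    eligible: bool
    inclusion_flags: frozenset[str]
    enrichment_met: frozenset[str]
    exclusion_flags: frozenset[str]
    as_of_date: pd.Timestamp

    def __post_init__(self) -> None:
        expected = bool(self.inclusion_flags) and bool(self.enrichment_met) and not self.exclusion_flags
        if self.eligible != expected:
            raise ValueError("eligible flag inconsistent with reason sets")


def _claims_long(cohort: ClaimsCohort, registry: CodeSetRegistry, as_of: pd.Timestamp, concepts) -> pd.DataFrame:
    """Concept hits across diagnoses and procedures dated on/before as_of."""
    frames = []
    dx = cohort.diagnoses
    if len(dx):
        frames.append(dx[dx["service_date"] <= as_of][["patient_id", "claim_id", "service_date", "code", "code_system", "setting"]])
    px = cohort.procedures
    if len(px):
        frames.append(px[px["service_date"] <= as_of][["patient_id", "claim_id", "service_date", "code", "code_system", "setting"]])
    if not frames:
        return pd.DataFrame(columns=["patient_id", "claim_id", "service_date", "code", "code_system", "setting", "concept"])
    claims = pd.concat(frames, ignore_index=True)
    return registry.match_claims(claims, concepts=concepts)


def _flag_frame(cohort: ClaimsCohort, registry: CodeSetRegistry, as_of: pd.Timestamp) -> pd.DataFrame:
    """One row per patient with boolean columns for every flag."""
    pids = cohort.demographics["patient_id"]
    out = pd.DataFrame({"patient_id": pids}).set_index("patient_id")

    concepts = set(INCLUSION_CONCEPTS) | set(EXCLUSION_CONCEPTS) | set(_DIAGNOSIS_FACTORS.values())
    hits = _claims_long(cohort, registry, as_of, concepts)
    if len(hits):
        pivot = (
            hits.drop_duplicates(["patient_id", "concept"])
            .assign(hit=True)
            .pivot(index="patient_id", columns="concept", values="hit")
            .reindex(out.index)
            .notna()
        )
    else:
        pivot = pd.DataFrame(index=out.index)

    def has_concept(concept: str) -> pd.Series:
        if concept in pivot.columns:
            return pivot[concept]
        return pd.Series(False, index=out.index)

    for concept in INCLUSION_CONCEPTS:
        out[f"incl_{concept}"] = has_concept(concept)
    for concept in EXCLUSION_CONCEPTS:
        out[f"excl_{concept}"] = has_concept(concept)

    # --- enrichment -------------------------------------------------------
    demo = cohort.demographics.set_index("patient_id")
    out["enr_age_ge_65"] = (demo["birth_date"] + pd.DateOffset(years=65)) <= as_of

    for factor, concept in _DIAGNOSIS_FACTORS.items():
        out[f"enr_{factor}"] = has_concept(concept)

    window_start = as_of - pd.Timedelta(days=PAST_12_MONTHS_DAYS)
    labs = cohort.labs
    labs = labs[labs["result_date"] <= as_of] if len(labs) else labs

    def lab_flag(analyte: str, threshold: float, windowed: bool) -> pd.Series:
        if not len(labs):
            return pd.Series(False, index=out.index)
        sel = labs[labs["analyte"] == analyte]
        if windowed:
            sel = sel[sel["result_date"] >= window_start]
        hit = sel[sel["value"] >= threshold]["patient_id"].unique()
        return out.index.to_series().isin(hit)

    out["enr_creatinine_ge_1_5"] = lab_flag("creatinine", 1.5, windowed=False)
    out["enr_ldl_ge_130_12mo"] = lab_flag("LDL", 130.0, windowed=True)

    vitals = cohort.vitals
    vitals = vitals[vitals["measure_date"] <= as_of] if len(vitals) else vitals
    if len(vitals):
        sbp = vitals[(vitals["measure_date"] >= window_start) & (vitals["systolic_bp"] >= 140)]
        out["enr_sbp_ge_140_12mo"] = out.index.to_series().isin(sbp["patient_id"].unique())
        lvef = vitals[vitals["lvef_percent"] < 50]
        out["enr_lvef_lt_50"] = out.index.to_series().isin(lvef["patient_id"].unique())
        smoke = vitals[vitals["smoking_current"].notna()].sort_values(["patient_id", "measure_date"], kind="stable")
        latest = smoke.groupby("patient_id")["smoking_current"].last()
        out["enr_current_smoker"] = out.index.to_series().map(latest).eq(True)
    else:
        out["enr_sbp_ge_140_12mo"] = False
        out["enr_lvef_lt_50"] = False
        out["enr_current_smoker"] = False

    return out.reset_index()


def run_phenotype(cohort: ClaimsCohort, registry: CodeSetRegistry, as_of=None) -> pd.DataFrame:
    """Classify every patient; returns one row per patient.

    Columns: ``patient_id``, per-flag booleans (``incl_*``, ``enr_*``,
    ``excl_*``), the composite ``eligible``, and ``as_of``.  Deterministic
    and invariant to record order within a patient.
    """
    as_of = pd.Timestamp(as_of) if as_of is not None else cohort.max_service_date()
    flags = _flag_frame(cohort, registry, as_of)
    incl_cols = [f"incl_{c}" for c in INCLUSION_CONCEPTS]
    enr_cols = [f"enr_{f}" for f in ENRICHMENT_FACTORS]
    excl_cols = [f"excl_{c}" for c in EXCLUSION_CONCEPTS]
    flags["eligible"] = (
        flags[incl_cols].any(axis=1) & flags[enr_cols].any(axis=1) & ~flags[excl_cols].any(axis=1)
    )
    flags["as_of"] = as_of
    return flags


def _single(cohort_or_history, registry, as_of) -> pd.Series:
    history = cohort_or_history
    if history.n_patients != 1:
        raise ValueError("patient_history must contain exactly one patient")
    row = run_phenotype(history, registry, as_of=as_of).iloc[0]
    return row


def inclusion_flags(patient_history: ClaimsCohort, registry: CodeSetRegistry, as_of) -> frozenset[str]:
    """Qualifying cardiac concepts evidenced at any position/setting/date <= as_of."""
    row = _single(patient_history, registry, as_of)
    return frozenset(c for c in INCLUSION_CONCEPTS if row[f"incl_{c}"])


def enrichment_met(patient_history: ClaimsCohort, registry: CodeSetRegistry, as_of) -> frozenset[str]:
    """Enrichment factors met at as_of (windowed factors use trailing 365 days)."""
    row = _single(patient_history, registry, as_of)
    return frozenset(f for f in ENRICHMENT_FACTORS if row[f"enr_{f}"])


def exclusion_flags(patient_history: ClaimsCohort, registry: CodeSetRegistry, as_of) -> frozenset[str]:
    """Claims-coded exclusions only; aspirin allergy can never appear here."""
    row = _single(patient_history, registry, as_of)
    return frozenset(c for c in EXCLUSION_CONCEPTS if row[f"excl_{c}"])


def eligibility_results(phenotype_frame: pd.DataFrame) -> list[EligibilityResult]:
    """Convert a run_phenotype frame into typed per-patient results."""
    out = []
    for _, row in phenotype_frame.iterrows():
        out.append(
            EligibilityResult(
                patient_id=row["patient_id"],
                eligible=bool(row["eligible"]),
                inclusion_flags=frozenset(c for c in INCLUSION_CONCEPTS if row[f"incl_{c}"]),
                enrichment_met=frozenset(f for f in ENRICHMENT_FACTORS if row[f"enr_{f}"]),
                exclusion_flags=frozenset(c for c in EXCLUSION_CONCEPTS if row[f"excl_{c}"]),
                as_of_date=row["as_of"],
            )
        )
    return out
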