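"""Synthetic longitudinal claims with known latent truth.

The generator emulates the source population of a claims-based
trial-eligibility validation study: patients accrue diagnosis/procedure
claims over a 2006-2017 window, qualifying cardiac events (AMI, PCI, CABG)
may lie in the distant past (prevalent cases), claims coding is imperfect
in both directions, and one exclusion condition (aspirin allergy) is by
construction invisible in claims.  Because the latent truth is returned
alongside the data, the realized positive predictive value of any
downstream phenotype is measurable — and :func:`expected_ppv` gives the
exact closed-form value implied by the generator's mixture, so the whole
pipeline can be validated against an analytic oracle.

Coding mechanisms
-----------------
* a true event emits a claim at the event date with probability
  ``code_sensitivity``; the claim is a facility claim with probability
  ``facility_fraction`` and uses the coding system of its era (ICD-9-CM
  before 2015-10-01, ICD-10-CM after);
* a coded event additionally emits one "history of X" re-mention claim in
  the ICD-10 era with probability ``history_mention_rate`` — this is what
  lets an event from, say, 2007 surface on a recent facility claim;
* a patient with *no* true cardiac event emits one spurious qualifying
  code in the ICD-10 era with probability ``code_false_positive_rate``
  (the miscoded non-cardiology-encounter mechanism);
* GI bleed and bleeding-disorder exclusions are coded with probability
  ``exclusion_code_sensitivity``; aspirin allergy never emits a claim.
"""

from __future__ import annotations

import datetime as dt
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.optimize import brentq

from .cohort import ICD10_ERA_START, ClaimsCohort
from .registry import AMI, CABG, CAD, ENRICHMENT_FACTORS, PCI

EVENT_TYPES = (AMI, PCI, CABG)

# era-appropriate representative codes emitted for each mechanism
_EVENT_DIAG_CODES = {AMI: ("410.01", "I21.09")}          # (ICD-9 era, ICD-10 era)
_EVENT_PROC_CODES = {PCI: "92928", CABG: "33533"}        # CPT, valid in both eras
_HISTORY_CODES = {AMI: "I25.2", PCI: "Z98.61", CABG: "Z95.1"}  # ICD-10 status codes
_CAD_CODES = ("414.01", "I25.10")
_ENRICH_DIAG_CODES = {
    "diabetes": ("250.00", "E11.9"),
    "cerebrovascular_disease": ("434.91", "I63.9"),
    "peripheral_arterial_disease": ("443.9", "I73.9"),
    "heart_failure": ("428.0", "I50.9"),
    "three_vessel_cad": ("414.4", "I25.84"),
}
_EXCLUSION_CODES = {
    "gi_bleed": ("578.9", "K92.2"),
    "bleeding_disorder": ("285.1", "D62"),
}


class GeneratorConfig(BaseModel):
    """All knobs of the synthetic cohort, with study-condition defaults.

    Prevalences describe an at-risk adult claims population; the event and
    exclusion mix is sized so that, after calibrating the false-positive
    rate (:func:`calibrate_false_positive_rate`), the claims-invisible
    exclusions contribute a few percent of flagged patients and the
    realized phenotype PPV lands near 0.91.
    """

    n_patients: int = Field(ge=0, default=1000)
    start: dt.date = dt.date(2006, 1, 1)
    end: dt.date = dt.date(2017, 4, 1)

    # latent truth prevalences
    p_ami: float = Field(ge=0, le=1, default=0.20)
    p_pci: float = Field(ge=0, le=1, default=0.15)
    p_cabg: float = Field(ge=0, le=1, default=0.08)
    p_cad: float = Field(ge=0, le=1, default=0.35)

    p_diabetes: float = Field(ge=0, le=1, default=0.25)
    p_cerebrovascular: float = Field(ge=0, le=1, default=0.12)
    p_pad: float = Field(ge=0, le=1, default=0.10)
    p_heart_failure: float = Field(ge=0, le=1, default=0.12)
    p_three_vessel: float = Field(ge=0, le=1, default=0.03)
    p_creatinine_high: float = Field(ge=0, le=1, default=0.05)
    p_lvef_low: float = Field(ge=0, le=1, default=0.08)
    p_sbp_high: float = Field(ge=0, le=1, default=0.25)
    p_ldl_high: float = Field(ge=0, le=1, default=0.15)
    p_smoker: float = Field(ge=0, le=1, default=0.15)
    age_mean: float = 66.0
    age_sd: float = 12.0

    p_gi_bleed: float = Field(ge=0, le=1, default=0.02)
    p_bleeding_disorder: float = Field(ge=0, le=1, default=0.01)
    p_aspirin_allergy: float = Field(ge=0, le=1, default=0.01)

    # coding behaviour
    code_sensitivity: float = Field(ge=0, le=1, default=0.85)
    code_false_positive_rate: float = Field(ge=0, le=1, default=0.02)
    exclusion_code_sensitivity: float = Field(ge=0, le=1, default=0.5)
    enrichment_sensitivity: float = Field(ge=0, le=1, default=0.95)
    history_mention_rate: float = Field(ge=0, le=1, default=0.5)
    facility_fraction: float = Field(ge=0, le=1, default=0.6)

    # administrative flags (independent of truth)
    p_fully_insured: float = Field(ge=0, le=1, default=0.25)
    p_contact_info: float = Field(ge=0, le=1, default=0.95)
    p_do_not_contact: float = Field(ge=0, le=1, default=0.02)

    retrieval_rate: float = Field(ge=0, le=1, default=0.617)
    seed: int = 0

    @model_validator(mode="after")
    def _check_window(self) -> "GeneratorConfig":
        if self.start >= self.end:
            raise ValueError("date_range start must precede end")
        return self

    def event_prevalence(self, event: str) -> float:
        return {AMI: self.p_ami, PCI: self.p_pci, CABG: self.p_cabg}[event]


def _streams(seed: int) -> dict[str, np.random.Generator]:
    """One independent substream per generator purpose."""
    names = ("truth", "dates", "coding", "clinical", "admin")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _day(d: dt.date) -> int:
    return (pd.Timestamp(d) - pd.Timestamp("1970-01-01")).days


def _dates_from_days(days: np.ndarray) -> pd.Series:
    return pd.Series(pd.to_datetime(days, unit="D", origin="unix"))


def generate_cohort(config: GeneratorConfig) -> tuple[ClaimsCohort, pd.DataFrame]:
    """Draw a cohort and its latent truth table, deterministically by seed.

    Returns ``(cohort, truth)`` where ``truth`` has one row per patient
    with the latent event flags/dates, enrichment-factor truth, and
    exclusion truth.  Aspirin allergy appears only in ``truth`` — no claim
    record ever encodes it.
    """
    n = config.n_patients
    rng = _streams(config.seed)
    t_rng, d_rng, c_rng, k_rng, a_rng = (
        rng["truth"], rng["dates"], rng["coding"], rng["clinical"], rng["admin"],
    )

    start_d, end_d = _day(config.start), _day(config.end)
    cutoff_d = max(_day(ICD10_ERA_START.date()), start_d)
    end_ts = pd.Timestamp(config.end)

    pids = np.array([f"P{i:06d}" for i in range(n)])

    # --- latent truth -----------------------------------------------------
    has_event = {e: t_rng.random(n) < config.event_prevalence(e) for e in EVENT_TYPES}
    event_day = {e: d_rng.integers(start_d, end_d + 1, size=n) for e in EVENT_TYPES}
    true_cad = t_rng.random(n) < config.p_cad
    cad_day = d_rng.integers(start_d, end_d + 1, size=n)

    age_years = np.clip(t_rng.normal(config.age_mean, config.age_sd, size=n), 40.0, 95.0)
    birth = end_ts - pd.to_timedelta(np.round(age_years * 365.25).astype(int), unit="D")
    age_ge_65 = (birth + pd.DateOffset(years=65)) <= end_ts

    enr_truth = {
        "age_ge_65": np.asarray(age_ge_65),
        "creatinine_ge_1_5": t_rng.random(n) < config.p_creatinine_high,
        "diabetes": t_rng.random(n) < config.p_diabetes,
        "three_vessel_cad": t_rng.random(n) < config.p_three_vessel,
        "cerebrovascular_disease": t_rng.random(n) < config.p_cerebrovascular,
        "peripheral_arterial_disease": t_rng.random(n) < config.p_pad,
        "lvef_lt_50": t_rng.random(n) < config.p_lvef_low,
        "heart_failure": t_rng.random(n) < config.p_heart_failure,
        "sbp_ge_140_12mo": t_rng.random(n) < config.p_sbp_high,
        "ldl_ge_130_12mo": t_rng.random(n) < config.p_ldl_high,
        "current_smoker": t_rng.random(n) < config.p_smoker,
    }

    true_gi = t_rng.random(n) < config.p_gi_bleed
    true_bd = t_rng.random(n) < config.p_bleeding_disorder
    true_allergy = t_rng.random(n) < config.p_aspirin_allergy

    # --- demographics -----------------------------------------------------
    sex = np.where(a_rng.random(n) < 0.62, "M", "F")
    region = a_rng.choice(
        ["Northeast", "South", "Midwest", "West"], size=n, p=[0.17, 0.31, 0.32, 0.20]
    )
    demo = pd.DataFrame(
        {
            "patient_id": pids,
            "birth_date": birth,
            "sex": sex,
            "region": region,
            "fully_insured": a_rng.random(n) < config.p_fully_insured,
            "contact_info_complete": a_rng.random(n) < config.p_contact_info,
            "do_not_contact": a_rng.random(n) < config.p_do_not_contact,
        }
    )

    claim_counter = np.zeros(n, dtype=int)

    def new_claim_ids(idx: np.ndarray) -> np.ndarray:
        nonlocal claim_counter
        out = np.array([f"{pids[i]}-{claim_counter[i]:03d}" for i in idx])
        claim_counter[idx] += 1
        return out

    dx_parts: list[pd.DataFrame] = []
    px_parts: list[pd.DataFrame] = []

    def add_dx(idx, days, codes, systems, settings, positions) -> None:
        if len(idx) == 0:
            return
        dx_parts.append(
            pd.DataFrame(
                {
                    "patient_id": pids[idx],
                    "claim_id": new_claim_ids(idx),
                    "service_date": _dates_from_days(np.asarray(days)).to_numpy(),
                    "code": codes,
                    "code_system": systems,
                    "position": positions,
                    "setting": settings,
                }
            )
        )

    def era_codes(days: np.ndarray, pair: tuple[str, str]) -> tuple[np.ndarray, np.ndarray]:
        post = np.asarray(days) >= cutoff_d
        return np.where(post, pair[1], pair[0]), np.where(post, "ICD10CM", "ICD9CM")

    def settings_draw(rng_, k) -> np.ndarray:
        return np.where(rng_.random(k) < config.facility_fraction, "facility", "professional")

    # --- qualifying event claims + history re-mentions ---------------------
    for event in EVENT_TYPES:
        coded = has_event[event] & (c_rng.random(n) < config.code_sensitivity)
        idx = np.flatnonzero(coded)
        days = event_day[event][idx]
        setting = settings_draw(c_rng, len(idx))
        if event == AMI:
            codes, systems = era_codes(days, _EVENT_DIAG_CODES[AMI])
            add_dx(idx, days, codes, systems, setting, c_rng.integers(1, 6, size=len(idx)))
        else:
            if len(idx):
                px_parts.append(
                    pd.DataFrame(
                        {
                            "patient_id": pids[idx],
                            "claim_id": new_claim_ids(idx),
                            "service_date": _dates_from_days(days).to_numpy(),
                            "code": _EVENT_PROC_CODES[event],
                            "code_system": "CPT",
                            "setting": setting,
                        }
                    )
                )
        # ICD-10-era history re-mention: the mechanism by which a distant
        # event can still anchor a recent facility claim
        mention = coded & (c_rng.random(n) < config.history_mention_rate)
        midx = np.flatnonzero(mention)
        lo = np.maximum(cutoff_d, np.minimum(event_day[event][midx] + 1, end_d))
        mdays = lo + np.floor(c_rng.random(len(midx)) * (end_d - lo + 1)).astype(int)
        add_dx(
            midx,
            mdays,
            np.repeat(_HISTORY_CODES[event], len(midx)),
            np.repeat("ICD10CM", len(midx)),
            settings_draw(c_rng, len(midx)),
            c_rng.integers(1, 6, size=len(midx)),
        )

    # --- false-positive qualifying codes on event-free patients ------------
    no_event = ~(has_event[AMI] | has_event[PCI] | has_event[CABG])
    fp = no_event & (c_rng.random(n) < config.code_false_positive_rate)
    fidx = np.flatnonzero(fp)
    fdays = c_rng.integers(cutoff_d, end_d + 1, size=len(fidx))
    fp_concept = c_rng.choice(len(EVENT_TYPES), size=len(fidx), p=[0.6, 0.25, 0.15])
    fp_code = np.array([_EVENT_DIAG_CODES[AMI][1], _HISTORY_CODES[PCI], _HISTORY_CODES[CABG]])[fp_concept]
    add_dx(
        fidx,
        fdays,
        fp_code,
        np.repeat("ICD10CM", len(fidx)),
        settings_draw(c_rng, len(fidx)),
        c_rng.integers(1, 6, size=len(fidx)),
    )

    # --- chronic CAD diagnoses ---------------------------------------------
    cad_coded = true_cad & (c_rng.random(n) < config.code_sensitivity)
    cidx = np.flatnonzero(cad_coded)
    cdays = cad_day[cidx]
    codes, systems = era_codes(cdays, _CAD_CODES)
    add_dx(cidx, cdays, codes, systems, settings_draw(c_rng, len(cidx)), c_rng.integers(1, 6, size=len(cidx)))

    # --- enrichment diagnoses ----------------------------------------------
    for factor, pair in _ENRICH_DIAG_CODES.items():
        coded = enr_truth[factor] & (c_rng.random(n) < config.enrichment_sensitivity)
        idx = np.flatnonzero(coded)
        days = d_rng.integers(start_d, end_d + 1, size=len(idx))
        codes, systems = era_codes(days, pair)
        add_dx(idx, days, codes, systems, settings_draw(c_rng, len(idx)), np.ones(len(idx), dtype=int))

    # --- exclusion diagnoses (aspirin allergy never emits) ------------------
    for name, flags in (("gi_bleed", true_gi), ("bleeding_disorder", true_bd)):
        coded = flags & (c_rng.random(n) < config.exclusion_code_sensitivity)
        idx = np.flatnonzero(coded)
        days = d_rng.integers(start_d, end_d + 1, size=len(idx))
        codes, systems = era_codes(days, _EXCLUSION_CODES[name])
        add_dx(idx, days, codes, systems, settings_draw(c_rng, len(idx)), np.ones(len(idx), dtype=int))

    # --- labs ----------------------------------------------------------------
    lab_parts: list[pd.DataFrame] = []

    def add_lab(idx, days, analyte, values) -> None:
        if len(idx) == 0:
            return
        lab_parts.append(
            pd.DataFrame(
                {
                    "patient_id": pids[idx],
                    "result_date": _dates_from_days(np.asarray(days)).to_numpy(),
                    "analyte": analyte,
                    "value": np.round(values, 1),
                    "units": "mg/dL",
                }
            )
        )

    hi = np.flatnonzero(enr_truth["creatinine_ge_1_5"])
    add_lab(hi, d_rng.integers(start_d, end_d + 1, size=len(hi)), "creatinine", 1.5 + 1.5 * k_rng.random(len(hi)))
    lo = np.flatnonzero(~enr_truth["creatinine_ge_1_5"] & (k_rng.random(n) < 0.7))
    add_lab(lo, d_rng.integers(start_d, end_d + 1, size=len(lo)), "creatinine", 0.6 + 0.7 * k_rng.random(len(lo)))

    recent_lo, recent_hi = end_d - 300, end_d - 30  # safely inside the 365-day window
    hi = np.flatnonzero(enr_truth["ldl_ge_130_12mo"])
    add_lab(hi, d_rng.integers(recent_lo, recent_hi + 1, size=len(hi)), "LDL", 130 + 90 * k_rng.random(len(hi)))
    lo = np.flatnonzero(~enr_truth["ldl_ge_130_12mo"] & (k_rng.random(n) < 0.7))
    add_lab(lo, d_rng.integers(start_d, end_d + 1, size=len(lo)), "LDL", 60 + 65 * k_rng.random(len(lo)))

    # --- vitals ---------------------------------------------------------------
    vital_parts: list[pd.DataFrame] = []

    def add_vital(idx, days, sbp=None, smoking=None, lvef=None) -> None:
        if len(idx) == 0:
            return
        vital_parts.append(
            pd.DataFrame(
                {
                    "patient_id": pids[idx],
                    "measure_date": _dates_from_days(np.asarray(days)).to_numpy(),
                    "systolic_bp": sbp if sbp is not None else np.nan,
                    "smoking_current": smoking if smoking is not None else pd.NA,
                    "lvef_percent": lvef if lvef is not None else np.nan,
                }
            )
        )

    hi = np.flatnonzero(enr_truth["sbp_ge_140_12mo"])
    add_vital(hi, d_rng.integers(recent_lo, recent_hi + 1, size=len(hi)), sbp=np.round(140 + 60 * k_rng.random(len(hi))))
    lo = np.flatnonzero(~enr_truth["sbp_ge_140_12mo"] & (k_rng.random(n) < 0.7))
    add_vital(lo, d_rng.integers(start_d, end_d + 1, size=len(lo)), sbp=np.round(95 + 40 * k_rng.random(len(lo))))

    low = np.flatnonzero(enr_truth["lvef_lt_50"])
    add_vital(low, d_rng.integers(start_d, end_d + 1, size=len(low)), lvef=np.round(20 + 29 * k_rng.random(len(low))))
    ok = np.flatnonzero(~enr_truth["lvef_lt_50"] & (k_rng.random(n) < 0.4))
    add_vital(ok, d_rng.integers(start_d, end_d + 1, size=len(ok)), lvef=np.round(50 + 20 * k_rng.random(len(ok))))

    smk = np.flatnonzero(enr_truth["current_smoker"])
    add_vital(smk, d_rng.integers(recent_lo, recent_hi + 1, size=len(smk)), smoking=True)
    non = np.flatnonzero(~enr_truth["current_smoker"] & (k_rng.random(n) < 0.5))
    add_vital(non, d_rng.integers(start_d, end_d + 1, size=len(non)), smoking=False)

    # --- assemble --------------------------------------------------------------
    def cat(parts: list[pd.DataFrame], columns: list[str]) -> pd.DataFrame:
        if not parts:
            return pd.DataFrame(columns=columns)
        return pd.concat(parts, ignore_index=True)

    from .cohort import DIAGNOSIS_COLUMNS, LAB_COLUMNS, PROCEDURE_COLUMNS, VITAL_COLUMNS

    cohort = ClaimsCohort(
        demographics=demo,
        diagnoses=cat(dx_parts, DIAGNOSIS_COLUMNS),
        procedures=cat(px_parts, PROCEDURE_COLUMNS),
        labs=cat(lab_parts, LAB_COLUMNS),
        vitals=cat(vital_parts, VITAL_COLUMNS),
    ).sort()

    enrichment_joined = [
        "|".join(f for f in ENRICHMENT_FACTORS if enr_truth[f][i]) for i in range(n)
    ]
    truth = pd.DataFrame(
        {
            "patient_id": pids,
            "true_ami": has_event[AMI],
            "ami_date": np.where(has_event[AMI], _dates_from_days(event_day[AMI]).dt.strftime("%Y-%m-%d"), ""),
            "true_pci": has_event[PCI],
            "pci_date": np.where(has_event[PCI], _dates_from_days(event_day[PCI]).dt.strftime("%Y-%m-%d"), ""),
            "true_cabg": has_event[CABG],
            "cabg_date": np.where(has_event[CABG], _dates_from_days(event_day[CABG]).dt.strftime("%Y-%m-%d"), ""),
            "true_cad": true_cad,
            "enrichment_truth": enrichment_joined,
            "true_gi_bleed": true_gi,
            "true_bleeding_disorder": true_bd,
            "true_aspirin_allergy": true_allergy,
        }
    )
    return cohort, truth


def truth_has_event(truth: pd.DataFrame) -> pd.Series:
    return truth["true_ami"] | truth["true_pci"] | truth["true_cabg"]


def truth_confirmable(truth: pd.DataFrame) -> pd.Series:
    """Would a complete medical record confirm this patient? (event present,
    no exclusion of any kind — aspirin allergy included, since the record
    sees what claims cannot)."""
    no_excl = ~(truth["true_gi_bleed"] | truth["true_bleeding_disorder"] | truth["true_aspirin_allergy"])
    return truth_has_event(truth) & no_excl


def truth_claims_eligible(truth: pd.DataFrame) -> pd.Series:
    """Truth-derived phenotype verdict under perfect claims coding:
    a qualifying cardiac history, at least one enrichment factor, and no
    claims-codable exclusion (aspirin allergy is invisible by design)."""
    inclusion = truth_has_event(truth) | truth["true_cad"]
    enriched = truth["enrichment_truth"].astype(str).str.len() > 0
    no_coded_excl = ~(truth["true_gi_bleed"] | truth["true_bleeding_disorder"])
    return inclusion & enriched & no_coded_excl


def write_cohort(cohort: ClaimsCohort, truth: pd.DataFrame, directory) -> dict:
    """CSV tables plus ``truth.csv``; byte-stable for a fixed seed."""
    from pathlib import Path

    from .cohort import write_cohort as _write_tables

    paths = _write_tables(cohort, directory)
    tpath = Path(directory) / "truth.csv"
    truth.to_csv(tpath, index=False, lineterminator="\n")
    paths["truth"] = tpath
    return paths


def read_truth(directory) -> pd.DataFrame:
    from pathlib import Path

    df = pd.read_csv(
        Path(directory) / "truth.csv",
        dtype={"patient_id": str},
        keep_default_na=False,
        converters={},
    )
    for col in ("true_ami", "true_pci", "true_cabg", "true_cad",
                "true_gi_bleed", "true_bleeding_disorder", "true_aspirin_allergy"):
        if df[col].dtype == object:
            df[col] = df[col].map({"True": True, "False": False}).astype(bool)
    return df


# ---------------------------------------------------------------------------
# closed-form expected PPV (the analytic oracle for the whole pipeline)
# ---------------------------------------------------------------------------

def expected_ppv(
    config: GeneratorConfig,
    error_model: Optional["object"] = None,
    as_of: Optional[dt.date] = None,
    mode: str = "primary",
) -> float:
    """Exact P(record would confirm | patient flagged) under the generator.

    Enumerates the finite mixture the generator draws from.  Per event
    type, the event date is integrated over segments bounded by the
    ICD-10-era cutoff and the abstraction recency horizon; within a
    segment, a coded event is *claims-visible* (i.e. can produce a recent
    facility index claim) via its event-date claim and/or its history
    re-mention, and is *documented in the final review* unless it is
    distant, missed by the abstractor, and unrecovered by both experts.
    Event types combine by independence; the false-positive branch and the
    exclusion terms multiply in.  Enrichment-factor prevalence cancels
    from the ratio because record review confirms events and exclusions,
    not enrichment.

    ``mode="sensitivity"`` additionally counts flagged patients whose
    record documents chronic CAD but no qualifying event.
    """
    from .adjudication import AbstractionErrorModel  # no import cycle: adjudication is leaf-ward

    em = error_model if error_model is not None else AbstractionErrorModel()
    as_of_d = _day(as_of or config.end)
    start_d, end_d = _day(config.start), _day(config.end)
    cutoff_d = max(_day(ICD10_ERA_START.date()), start_d)
    total = end_d - start_d + 1

    ff, r, s = config.facility_fraction, config.history_mention_rate, config.code_sensitivity
    # an event date on/after the cutoff can be visible through its own claim
    v_post = 1.0 - (1.0 - ff) * (1.0 - r * ff)
    v_pre = r * ff
    unrecovered = (1.0 - em.expert_detect_prob) ** 2
    horizon_d = as_of_d - em.horizon_days

    # date segments: [start, min(horizon, cutoff)), [.., max(..)), [.., end]
    bounds = sorted({start_d, min(max(horizon_d, start_d), end_d + 1), min(max(cutoff_d, start_d), end_d + 1), end_d + 1})
    segments = []  # (mass, visible_given_coded, p_not_documented_finally)
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b <= a:
            continue
        mass = (b - a) / total
        post = a >= cutoff_d
        distant = (b - 1) < horizon_d
        q = em.miss_distant_event_prob * unrecovered if distant else 0.0
        segments.append((mass, v_post if post else v_pre, q))

    p00s, p01s, p10s = [], [], []
    for event in EVENT_TYPES:
        p = config.event_prevalence(event)
        p11 = p10 = p01 = 0.0
        for mass, v, q in segments:
            vis = s * v
            p11 += p * mass * vis * (1 - q)
            p10 += p * mass * vis * q
            p01 += p * mass * (1 - vis) * (1 - q)
        p00 = 1.0 - p11 - p10 - p01
        p00s.append(p00)
        p01s.append(p01)
        p10s.append(p10)

    p_no_vis = float(np.prod([a + b for a, b in zip(p00s, p01s)]))
    p_no_doc = float(np.prod([a + b for a, b in zip(p00s, p10s)]))
    p_none = float(np.prod(p00s))
    p_vis = 1.0 - p_no_vis
    p_vis_doc = 1.0 - p_no_vis - p_no_doc + p_none
    p_vis_nodoc = p_no_doc - p_none

    p_no_event = float(
        np.prod([1.0 - config.event_prevalence(e) for e in EVENT_TYPES])
    )
    p_fp_flag = p_no_event * config.code_false_positive_rate * config.facility_fraction

    xs = config.exclusion_code_sensitivity
    no_coded_excl = (1.0 - config.p_gi_bleed * xs) * (1.0 - config.p_bleeding_disorder * xs)
    no_true_excl = (
        (1.0 - config.p_gi_bleed)
        * (1.0 - config.p_bleeding_disorder)
        * (1.0 - config.p_aspirin_allergy)
    )

    denom = (p_vis + p_fp_flag) * no_coded_excl
    if denom <= 0:
        raise ValueError("degenerate config: probability of a phenotype-positive patient is zero")
    numer = p_vis_doc * no_true_excl
    if mode == "sensitivity":
        numer += (p_vis_nodoc + p_fp_flag) * config.p_cad * no_true_excl
    elif mode != "primary":
        raise ValueError(f"unknown mode {mode!r}")
    return numer / denom


def calibrate_false_positive_rate(
    config: GeneratorConfig,
    target_ppv: float = 0.91,
    error_model=None,
) -> GeneratorConfig:
    """Solve for the false-positive coding rate that sets the closed-form
    expected PPV to ``target_ppv``, holding every other knob fixed."""
    def gap(fp: float) -> float:
        c = config.model_copy(update={"code_false_positive_rate": fp})
        return expected_ppv(c, error_model=error_model) - target_ppv

    hi_ppv = gap(0.0) + target_ppv
    if hi_ppv < target_ppv:
        raise ValueError(
            f"target PPV {target_ppv} unreachable: even with no false positives "
            f"the expected PPV is {hi_ppv:.4f} (invisible exclusions dominate)"
        )
    fp = brentq(gap, 0.0, 1.0, xtol=1e-12)
    return config.model_copy(update={"code_false_positive_rate": float(fp)})
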