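"""Index-claim selection and the two-stratum validation sample.

From the phenotype-positive population, only patients with a *facility*
claim bearing an AMI, PCI, or CABG code on/after the ICD-10-era cutoff
(2015-10-01) enter the validation frame — patients whose claims show CAD
alone are deliberately left out, to enrich the sample with
claims-measurable events.  Each retained patient is anchored by an index
claim: the most recent such facility claim (date ties broken by the
lexicographically greatest claim_id).

The chart-review sample is then drawn in two strata without replacement:
first n1 patients with an AMI code (regardless of PCI/CABG), then n2 with
a PCI or CABG code from those not already taken.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import ICD10_ERA_START, ClaimsCohort
from .registry import AMI, CABG, CodeSetRegistry, PCI

QUALIFYING_CONCEPTS = (AMI, PCI, CABG)


@dataclass(frozen=True)
class IndexClaim:
    patient_id: str
    claim_id: str
    service_date: pd.Timestamp
    qualifying_concepts: frozenset[str]
    setting: str = "facility"

    def __post_init__(self) -> None:
        if self.setting != "facility":
            raise ValueError("index claims are facility claims by definition")
        if self.service_date < ICD10_ERA_START:
            raise ValueError("index claim predates the ICD-10 era cutoff")
        if not self.qualifying_concepts or not set(self.qualifying_concepts) <= set(QUALIFYING_CONCEPTS):
            raise ValueError("qualifying_concepts must be a non-empty subset of {AMI, PCI, CABG}")


@dataclass
class SamplingFrame:
    """The two-stratum draw; stratum 2 never overlaps stratum 1."""

    stratum1: list[str]
    stratum2: list[str]
    seed: int
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if set(self.stratum1) & set(self.stratum2):
            raise ValueError("strata overlap")

    @property
    def patients(self) -> list[str]:
        return list(self.stratum1) + list(self.stratum2)

    def to_frame(self, index_claims: pd.DataFrame | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "patient_id": self.patients,
                "stratum": [1] * len(self.stratum1) + [2] * len(self.stratum2),
            }
        )
        if index_claims is not None:
            df = df.merge(index_claims, on="patient_id", how="left")
        return df


def select_index_claims(
    eligible_patients,
    cohort: ClaimsCohort,
    registry: CodeSetRegistry,
    cutoff=ICD10_ERA_START,
) -> pd.DataFrame:
    """One index claim per patient with a qualifying recent facility claim.

    Returns a DataFrame (patient_id, claim_id, service_date,
    qualifying_concepts, ami_flag, pci_cabg_flag); patients with no
    qualifying facility claim on/after ``cutoff`` — in particular CAD-only
    histories — are dropped.
    """
    cutoff = pd.Timestamp(cutoff)
    eligible = set(map(str, eligible_patients))
    frames = []
    if len(cohort.diagnoses):
        frames.append(cohort.diagnoses[["patient_id", "claim_id", "service_date", "code", "code_system", "setting"]])
    if len(cohort.procedures):
        frames.append(cohort.procedures[["patient_id", "claim_id", "service_date", "code", "code_system", "setting"]])
    empty = pd.DataFrame(
        columns=["patient_id", "claim_id", "service_date", "qualifying_concepts", "ami_flag", "pci_cabg_flag"]
    )
    if not frames:
        return empty
    claims = pd.concat(frames, ignore_index=True)
    claims = claims[
        claims["patient_id"].isin(eligible)
        & (claims["setting"] == "facility")
        & (claims["service_date"] >= cutoff)
    ]
    hits = registry.match_claims(claims, concepts=QUALIFYING_CONCEPTS)
    if not len(hits):
        return empty

    # patient-level stratum pools come from *all* qualifying recent claims
    pool = hits.groupby("patient_id")["concept"].agg(set)

    # concepts per claim, then the most recent claim (ties: greatest claim_id)
    per_claim = (
        hits.groupby(["patient_id", "claim_id", "service_date"])["concept"]
        .agg(lambda s: frozenset(s))
        .reset_index()
        .sort_values(["patient_id", "service_date", "claim_id"], kind="stable")
    )
    index_claims = per_claim.groupby("patient_id", as_index=False).last()
    index_claims = index_claims.rename(columns={"concept": "qualifying_concepts"})
    index_claims["ami_flag"] = index_claims["patient_id"].map(lambda p: AMI in pool[p])
    index_claims["pci_cabg_flag"] = index_claims["patient_id"].map(
        lambda p: bool({PCI, CABG} & pool[p])
    )
    return index_claims.reset_index(drop=True)


def apply_regulatory_filter(patients, flags: pd.DataFrame) -> list[str]:
    """Retain patients whose records may be requested.

    ``flags`` must carry boolean columns ``fully_insured``,
    ``contact_info_complete`` and ``do_not_contact`` indexed by (or with a
    column) ``patient_id``.  The filter is purely administrative and, by
    design, independent of any clinical truth.
    """
    required = ("fully_insured", "contact_info_complete", "do_not_contact")
    if "patient_id" in flags.columns:
        flags = flags.set_index("patient_id")
    missing = [c for c in required if c not in flags.columns]
    if missing:
        raise KeyError(f"regulatory flags missing column(s): {', '.join(missing)}")
    out = []
    for pid in map(str, patients):
        if pid not in flags.index:
            raise KeyError(f"no regulatory flags for patient {pid}")
        row = flags.loc[pid]
        if bool(row["fully_insured"]) and bool(row["contact_info_complete"]) and not bool(row["do_not_contact"]):
            out.append(pid)
    return out


def required_requests(target_records: int, retrieval_rate: float, inflation: float = 1.0) -> int:
    """Records to request so that ~``target_records`` are expected back:
    ceiling(target * inflation / retrieval_rate)."""
    if retrieval_rate <= 0 or retrieval_rate > 1:
        raise ValueError("retrieval_rate must be in (0, 1]")
    if target_records <= 0:
        raise ValueError("target_records must be positive")
    return math.ceil(target_records * inflation / retrieval_rate)


def draw_strata(index_patients: pd.DataFrame, n1: int, n2: int, seed: int) -> SamplingFrame:
    """Simple random samples without replacement: n1 from the AMI pool,
    then n2 from the PCI/CABG pool excluding stratum-1 patients.

    If a pool is smaller than requested, the whole pool is taken and a
    warning is recorded on the frame (and emitted).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    pool1 = index_patients.loc[index_patients["ami_flag"], "patient_id"].tolist()
    warn: list[str] = []

    def sample(pool: list[str], k: int, label: str) -> list[str]:
        pool = sorted(pool)  # order-independence of the input frame
        if k > len(pool):
            msg = f"{label}: requested {k} but only {len(pool)} candidates; taking all"
            warnings.warn(msg, stacklevel=2)
            warn.append(msg)
            k = len(pool)
        if k == 0:
            return []
        return [pool[i] for i in sorted(rng.choice(len(pool), size=k, replace=False))]

    s1 = sample(pool1, n1, "stratum1")
    taken = set(s1)
    pool2 = [
        p for p in index_patients.loc[index_patients["pci_cabg_flag"], "patient_id"] if p not in taken
    ]
    s2 = sample(pool2, n2, "stratum2")
    return SamplingFrame(stratum1=s1, stratum2=s2, seed=seed, warnings=warn)
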