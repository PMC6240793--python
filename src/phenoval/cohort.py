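"""Patient-level longitudinal claims tables and their CSV round trip.

The layout follows the common-data-model convention used by research
networks: one table each for demographics, diagnoses, procedures, labs and
vitals, keyed by ``patient_id``.  Tables are plain pandas DataFrames inside
a :class:`ClaimsCohort`; files are comma-delimited UTF-8 with a header row,
one table per file (``demographic.csv`` ... ``vital.csv``).

The single substantive rule enforced here is the US coding-era boundary:
a diagnosis (or ICD procedure) dated on or after 2015-10-01 must carry an
ICD-10-CM code, never ICD-9-CM.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd

#: first service date of the ICD-10-CM coding era in US claims
ICD10_ERA_START = pd.Timestamp("2015-10-01")

SEXES = ("M", "F")
REGIONS = ("Northeast", "South", "Midwest", "West")
SETTINGS = ("facility", "professional")
ANALYTES = ("creatinine", "LDL")

DEMOGRAPHIC_COLUMNS = ["patient_id", "birth_date", "sex", "region"]
#: administrative flags used by the record-request regulatory filter;
#: optional on input, always written by the synthetic generator
ADMIN_FLAG_COLUMNS = ["fully_insured", "contact_info_complete", "do_not_contact"]
DIAGNOSIS_COLUMNS = ["patient_id", "claim_id", "service_date", "code", "code_system", "position", "setting"]
PROCEDURE_COLUMNS = ["patient_id", "claim_id", "service_date", "code", "code_system", "setting"]
LAB_COLUMNS = ["patient_id", "result_date", "analyte", "value", "units"]
VITAL_COLUMNS = ["patient_id", "measure_date", "systolic_bp", "smoking_current", "lvef_percent"]

_DATE_COLUMNS = {
    "demographics": ["birth_date"],
    "diagnoses": ["service_date"],
    "procedures": ["service_date"],
    "labs": ["result_date"],
    "vitals": ["measure_date"],
}

_FILE_NAMES = {
    "demographics": "demographic.csv",
    "diagnoses": "diagnosis.csv",
    "procedures": "procedure.csv",
    "labs": "lab.csv",
    "vitals": "vital.csv",
}


class CohortError(ValueError):
    """Raised when a cohort violates a structural invariant at load time."""


@dataclass(frozen=True)
class Violation:
    """One invariant violation found by :func:`validate_cohort`."""

    table: str
    patient_id: str
    message: str

    def __str__(self) -> str:  # line-oriented text form
        return f"{self.table}\t{self.patient_id}\t{self.message}"


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __len__(self) -> int:
        return len(self.violations)

    def to_text(self) -> str:
        return "\n".join(str(v) for v in self.violations)

    def to_json(self) -> str:
        return json.dumps(
            [{"table": v.table, "patient_id": v.patient_id, "message": v.message} for v in self.violations],
            indent=2,
        )


def _empty(columns: list[str]) -> pd.DataFrame:
    return pd.DataFrame(columns=columns)


@dataclass
class ClaimsCohort:
    """Five claims tables plus helpers; the shared container of the package."""

    demographics: pd.DataFrame = field(default_factory=lambda: _empty(DEMOGRAPHIC_COLUMNS))
    diagnoses: pd.DataFrame = field(default_factory=lambda: _empty(DIAGNOSIS_COLUMNS))
    procedures: pd.DataFrame = field(default_factory=lambda: _empty(PROCEDURE_COLUMNS))
    labs: pd.DataFrame = field(default_factory=lambda: _empty(LAB_COLUMNS))
    vitals: pd.DataFrame = field(default_factory=lambda: _empty(VITAL_COLUMNS))

    def __post_init__(self) -> None:
        self._coerce()

    def _coerce(self) -> None:
        for f in fields(self):
            df = getattr(self, f.name).copy()
            for col in _DATE_COLUMNS[f.name]:
                if col in df.columns:
                    df[col] = pd.to_datetime(df[col], format="mixed", errors="raise")
            if "patient_id" in df.columns:
                df["patient_id"] = df["patient_id"].astype(str)
            # CSV round trip leaves mixed bool/empty columns as strings
            if "smoking_current" in df.columns and df["smoking_current"].dtype == object:
                df["smoking_current"] = df["smoking_current"].map(
                    {True: True, False: False, "True": True, "False": False}
                )
            setattr(self, f.name, df)

    @property
    def n_patients(self) -> int:
        return len(self.demographics)

    @property
    def patient_ids(self) -> pd.Index:
        return pd.Index(self.demographics["patient_id"])

    def max_service_date(self) -> pd.Timestamp:
        dates = []
        for name in ("diagnoses", "procedures", "labs", "vitals"):
            df = getattr(self, name)
            col = _DATE_COLUMNS[name][0]
            if len(df):
                dates.append(df[col].max())
        if not dates:
            raise CohortError("cohort has no dated records; pass as_of explicitly")
        return max(dates)

    def sort(self) -> "ClaimsCohort":
        """Sort every table by (patient_id, date, ...) in place; returns self."""
        self.demographics = self.demographics.sort_values("patient_id", kind="stable").reset_index(drop=True)
        self.diagnoses = self.diagnoses.sort_values(
            ["patient_id", "service_date", "claim_id", "position"], kind="stable"
        ).reset_index(drop=True)
        self.procedures = self.procedures.sort_values(
            ["patient_id", "service_date", "claim_id", "code"], kind="stable"
        ).reset_index(drop=True)
        self.labs = self.labs.sort_values(["patient_id", "result_date", "analyte"], kind="stable").reset_index(drop=True)
        self.vitals = self.vitals.sort_values(["patient_id", "measure_date"], kind="stable").reset_index(drop=True)
        return self

    def patient_history(self, patient_id: str) -> "ClaimsCohort":
        """Single-patient view (copies), for per-patient phenotype calls."""
        pid = str(patient_id)
        return ClaimsCohort(
            demographics=self.demographics[self.demographics["patient_id"] == pid],
            diagnoses=self.diagnoses[self.diagnoses["patient_id"] == pid],
            procedures=self.procedures[self.procedures["patient_id"] == pid],
            labs=self.labs[self.labs["patient_id"] == pid],
            vitals=self.vitals[self.vitals["patient_id"] == pid],
        )


def validate_cohort(cohort: ClaimsCohort) -> ValidationReport:
    """Check every structural invariant; violations are data, not exceptions."""
    v: list[Violation] = []
    demo = cohort.demographics

    dup = demo["patient_id"][demo["patient_id"].duplicated()]
    for pid in dup:
        v.append(Violation("demographic", str(pid), "duplicate patient_id"))
    for _, row in demo[~demo["sex"].isin(SEXES)].iterrows():
        v.append(Violation("demographic", row["patient_id"], f"invalid sex {row['sex']!r}"))
    for _, row in demo[~demo["region"].isin(REGIONS)].iterrows():
        v.append(Violation("demographic", row["patient_id"], f"invalid region {row['region']!r}"))

    known = set(demo["patient_id"])
    birth = demo.set_index("patient_id")["birth_date"]

    def check_claims(df: pd.DataFrame, table: str, date_col: str) -> None:
        for _, row in df[~df["patient_id"].isin(known)].iterrows():
            v.append(Violation(table, row["patient_id"], "orphan record: patient not in demographics"))
        present = df[df["patient_id"].isin(known)]
        if len(present):
            bd = present["patient_id"].map(birth)
            for _, row in present[present[date_col] < bd].iterrows():
                v.append(
                    Violation(table, row["patient_id"], f"{date_col} {row[date_col].date()} precedes birth_date")
                )

    check_claims(cohort.diagnoses, "diagnosis", "service_date")
    check_claims(cohort.procedures, "procedure", "service_date")
    check_claims(cohort.labs, "lab", "result_date")
    check_claims(cohort.vitals, "vital", "measure_date")

    dx = cohort.diagnoses
    bad_era = dx[(dx["service_date"] >= ICD10_ERA_START) & (dx["code_system"] == "ICD9CM")]
    for _, row in bad_era.iterrows():
        v.append(
            Violation(
                "diagnosis",
                row["patient_id"],
                f"ICD9CM code {row['code']} dated {row['service_date'].date()} in the ICD-10 era",
            )
        )
    for _, row in dx[dx["position"] < 1].iterrows():
        v.append(Violation("diagnosis", row["patient_id"], f"position {row['position']} < 1"))
    for _, row in dx[~dx["setting"].isin(SETTINGS)].iterrows():
        v.append(Violation("diagnosis", row["patient_id"], f"invalid setting {row['setting']!r}"))

    px = cohort.procedures
    bad_era_px = px[
        (px["service_date"] >= ICD10_ERA_START) & (px["code_system"] == "ICD9CM")
    ]
    for _, row in bad_era_px.iterrows():
        v.append(
            Violation(
                "procedure",
                row["patient_id"],
                f"ICD9CM procedure {row['code']} dated {row['service_date'].date()} in the ICD-10 era",
            )
        )

    lab = cohort.labs
    for _, row in lab[lab["value"] <= 0].iterrows():
        v.append(Violation("lab", row["patient_id"], f"non-positive {row['analyte']} value {row['value']}"))
    for _, row in lab[~lab["analyte"].isin(ANALYTES)].iterrows():
        v.append(Violation("lab", row["patient_id"], f"unknown analyte {row['analyte']!r}"))

    vt = cohort.vitals
    if len(vt):
        allnull = vt[["systolic_bp", "smoking_current", "lvef_percent"]].isna().all(axis=1)
        for _, row in vt[allnull].iterrows():
            v.append(Violation("vital", row["patient_id"], "vital record with no measurement"))
        lvef = vt["lvef_percent"]
        bad = vt[lvef.notna() & ((lvef <= 0) | (lvef > 100))]
        for _, row in bad.iterrows():
            v.append(Violation("vital", row["patient_id"], f"lvef_percent {row['lvef_percent']} outside (0, 100]"))
    return ValidationReport(v)


def write_cohort(cohort: ClaimsCohort, directory) -> dict[str, Path]:
    """Write the five CSV tables; dates as ISO-8601 calendar dates."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, fname in _FILE_NAMES.items():
        df = getattr(cohort, name).copy()
        for col in _DATE_COLUMNS[name]:
            if col in df.columns:
                df[col] = pd.to_datetime(df[col]).dt.strftime("%Y-%m-%d")
        path = directory / fname
        df.to_csv(path, index=False, lineterminator="\n")
        paths[name] = path
    return paths


def read_cohort(directory, strict: bool = True) -> ClaimsCohort:
    """Read the CSV tables back into a sorted, validated cohort.

    With ``strict`` (default) any invariant violation — orphan claims, an
    ICD-9 code in the ICD-10 era, malformed dates — raises
    :class:`CohortError`.  Pass ``strict=False`` to load anyway and inspect
    :func:`validate_cohort` yourself.
    """
    directory = Path(directory)
    tables: dict[str, pd.DataFrame] = {}
    for name, fname in _FILE_NAMES.items():
        path = directory / fname
        if not path.exists():
            raise CohortError(f"missing table file: {path}")
        df = pd.read_csv(path, dtype={"patient_id": str, "code": str, "claim_id": str})
        for col in _DATE_COLUMNS[name]:
            if col in df.columns:
                try:
                    df[col] = pd.to_datetime(df[col], format="%Y-%m-%d", errors="raise")
                except (ValueError, TypeError) as exc:
                    raise CohortError(f"malformed date in {fname} column {col}: {exc}") from exc
        tables[name] = df
    cohort = ClaimsCohort(**tables).sort()
    if strict:
        report = validate_cohort(cohort)
        if not report.ok:
            raise CohortError(
                f"cohort failed validation with {len(report)} violation(s):\n{report.to_text()}"
            )
    return cohort
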