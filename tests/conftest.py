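"""Shared fixtures: tiny handcrafted cohorts and one calibrated pipeline run."""

from __future__ import annotations

import pandas as pd
import pytest
from hypothesis import settings

from phenoval.cohort import ClaimsCohort
from phenoval.pipeline import default_pipeline_config, run_pipeline
from phenoval.registry import default_registry

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

AS_OF = pd.Timestamp("2017-04-01")


def make_cohort(
    demographics=None,
    diagnoses=None,
    procedures=None,
    labs=None,
    vitals=None,
) -> ClaimsCohort:
    """Build a cohort from row dicts, filling sensible defaults."""
    demo_defaults = {
        "birth_date": "1950-06-15",
        "sex": "M",
        "region": "South",
        "fully_insured": True,
        "contact_info_complete": True,
        "do_not_contact": False,
    }
    dx_defaults = {"code_system": "ICD10CM", "position": 1, "setting": "facility"}
    px_defaults = {"code_system": "CPT", "setting": "facility"}
    lab_defaults = {"units": "mg/dL"}
    vital_defaults = {"systolic_bp": None, "smoking_current": None, "lvef_percent": None}

    def rows(entries, defaults):
        return pd.DataFrame([{**defaults, **e} for e in entries]) if entries else None

    kwargs = {}
    for name, entries, defaults in (
        ("demographics", demographics, demo_defaults),
        ("diagnoses", diagnoses, dx_defaults),
        ("procedures", procedures, px_defaults),
        ("labs", labs, lab_defaults),
        ("vitals", vitals, vital_defaults),
    ):
        df = rows(entries, defaults)
        if df is not None:
            kwargs[name] = df
    return ClaimsCohort(**kwargs).sort()


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def calibrated_run(tmp_path_factory):
    """One full pipeline run under study conditions (expected PPV 0.91,
    5000 patients), shared across tests that only read its artifacts."""
    outdir = tmp_path_factory.mktemp("run")
    config = default_pipeline_config(seed=42, n_patients=5000)
    results = run_pipeline(config, outdir / "a")
    return config, results, outdir / "a"
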