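"""End-to-end orchestration: generate -> phenotype -> sample -> adjudicate -> report.

A run is fully determined by a :class:`PipelineConfig` (one seed governs
every stochastic stage through independent substreams) and leaves behind
a run directory with every intermediate artifact plus a ``manifest.json``
whose stage counts mirror the attrition chain of a records-validation
study: phenotype-positive >= recent-facility-claim frame >= post-regulatory
>= sampled >= retrieved.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import sampling as sampling_mod
from .adjudication import (
    AbstractionErrorModel,
    expert_review,
    outcome_accounting,
    replay_paper_counts,
    simulate_abstraction,
    simulate_retrieval,
)
from .cohort import ICD10_ERA_START, ClaimsCohort
from .phenotype import run_phenotype
from .registry import CodeSetRegistry, default_registry, load_codesets
from .synth import GeneratorConfig, calibrate_false_positive_rate, generate_cohort, write_cohort
from .valstats import ValidationResults, ValidationStudy

logger = logging.getLogger("phenoval")


class PipelineConfig(BaseModel):
    """Everything a reproducible validation run needs."""

    generator: GeneratorConfig = GeneratorConfig()
    codeset_path: Optional[str] = None
    as_of: Optional[dt.date] = None  # default: generator window end
    cutoff: dt.date = dt.date(2015, 10, 1)
    n1: int = Field(ge=0, default=172)
    n2: int = Field(ge=0, default=128)
    retrieval_rate: float = Field(ge=0, le=1, default=0.617)
    miss_distant_event_prob: float = Field(ge=0, le=1, default=0.08)
    horizon_days: int = Field(gt=0, default=730)
    expert_detect_prob: float = Field(ge=0, le=1, default=0.9)
    confirmed_review_sample: int = Field(ge=0, default=10)
    alpha: float = Field(gt=0, lt=1, default=0.05)
    seed: int = 0

    def error_model(self) -> AbstractionErrorModel:
        return AbstractionErrorModel(
            miss_distant_event_prob=self.miss_distant_event_prob,
            horizon_days=self.horizon_days,
            expert_detect_prob=self.expert_detect_prob,
            confirmed_review_sample=self.confirmed_review_sample,
        )

    def registry(self) -> CodeSetRegistry:
        if self.codeset_path:
            return load_codesets(self.codeset_path)
        return default_registry()


def default_pipeline_config(seed: int = 0, n_patients: int = 5000, target_ppv: float = 0.91) -> PipelineConfig:
    """Study-condition defaults with the generator's false-positive rate
    calibrated so the closed-form expected PPV equals ``target_ppv``."""
    config = PipelineConfig(seed=seed)
    gen = config.generator.model_copy(update={"n_patients": n_patients, "seed": seed})
    gen = calibrate_false_positive_rate(gen, target_ppv=target_ppv, error_model=config.error_model())
    return config.model_copy(update={"generator": gen})


def _stage_seeds(seed: int) -> dict[str, int]:
    words = np.random.SeedSequence(seed).generate_state(5, dtype=np.uint32)
    names = ("generate", "sample", "retrieve", "abstract", "review")
    return {n: int(w) % (2**31) for n, w in zip(names, words)}


def _age_band(birth: pd.Series, as_of: pd.Timestamp) -> pd.Series:
    return np.where((pd.to_datetime(birth) + pd.DateOffset(years=65)) <= as_of, "ge_65", "lt_65")


def adjudicate_sample(
    frame: pd.DataFrame,
    truth: pd.DataFrame,
    cohort: ClaimsCohort,
    config: PipelineConfig,
    as_of: pd.Timestamp,
    seeds: dict[str, int],
) -> pd.DataFrame:
    """Retrieval, abstraction and expert review for a sampled frame.

    Returns per-record outcomes for retrieved records only (unobtainable
    records leave the PPV denominator), with stratum/sex/age_band labels
    attached for subgroup estimation.
    """
    retrieved = simulate_retrieval(frame["patient_id"], config.retrieval_rate, seeds["retrieve"])
    got = [p for p in frame["patient_id"] if retrieved[p]]
    abstraction = simulate_abstraction(got, truth, config.error_model(), seeds["abstract"], as_of)
    outcomes = expert_review(abstraction, config.error_model(), seeds["review"])
    outcomes = outcomes.merge(frame[["patient_id", "stratum"]], on="patient_id", how="left")
    demo = cohort.demographics[["patient_id", "birth_date", "sex"]]
    outcomes = outcomes.merge(demo, on="patient_id", how="left")
    outcomes["age_band"] = _age_band(outcomes["birth_date"], as_of)
    return outcomes.drop(columns=["birth_date"])


def run_pipeline(config: PipelineConfig, outdir) -> ValidationResults:
    """Execute every stage, writing all artifacts under ``outdir``.

    ``outdir`` must not already contain a run (no silent overwrites).
    Identical config (same seed) reproduces identical artifacts.
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()):
        raise FileExistsError(f"refusing to overwrite existing run directory {outdir}")
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    registry = config.registry()
    timings: dict[str, float] = {}
    counts: dict[str, int] = {}

    def stage(name: str):
        logger.info("stage %s ...", name)
        return time.perf_counter()

    t = stage("generate")
    gen_config = config.generator.model_copy(update={"seed": seeds["generate"]})
    cohort, truth = generate_cohort(gen_config)
    write_cohort(cohort, truth, outdir / "cohort")
    counts["patients"] = cohort.n_patients
    timings["generate"] = time.perf_counter() - t

    as_of = pd.Timestamp(config.as_of) if config.as_of else pd.Timestamp(config.generator.end)

    t = stage("phenotype")
    eligibility = run_phenotype(cohort, registry, as_of=as_of)
    eligibility.to_csv(outdir / "eligibility.csv", index=False, lineterminator="\n")
    eligible = eligibility.loc[eligibility["eligible"], "patient_id"]
    counts["phenotype_positive"] = int(len(eligible))
    timings["phenotype"] = time.perf_counter() - t

    t = stage("sample")
    index_claims = sampling_mod.select_index_claims(eligible, cohort, registry, cutoff=config.cutoff)
    counts["recent_facility_claim"] = int(len(index_claims))
    retained = sampling_mod.apply_regulatory_filter(
        index_claims["patient_id"], cohort.demographics
    )
    counts["post_regulatory"] = len(retained)
    pool = index_claims[index_claims["patient_id"].isin(retained)]
    frame = sampling_mod.draw_strata(pool, config.n1, config.n2, seeds["sample"]).to_frame(pool)
    frame_out = frame.copy()
    frame_out["qualifying_concepts"] = frame_out["qualifying_concepts"].map(
        lambda s: "|".join(sorted(s)) if isinstance(s, frozenset) else s
    )
    frame_out.to_csv(outdir / "frame.csv", index=False, lineterminator="\n")
    counts["sampled"] = int(len(frame))
    timings["sample"] = time.perf_counter() - t

    t = stage("adjudicate")
    outcomes = adjudicate_sample(frame, truth, cohort, config, as_of, seeds)
    outcomes.to_csv(outdir / "outcomes.csv", index=False, lineterminator="\n")
    counts["retrieved"] = int(len(outcomes))
    timings["adjudicate"] = time.perf_counter() - t

    t = stage("report")
    results = ValidationStudy.from_outcomes(outcomes, requested=len(frame)).fit(alpha=config.alpha)
    results.extra["accounting"] = outcome_accounting(outcomes)
    results.save(outdir, stem="report")
    timings["report"] = time.perf_counter() - t

    for name, seconds in timings.items():
        logger.info("stage %s took %.3fs", name, seconds)
    config_json = config.model_dump_json()
    # timings stay in the log: the manifest must be byte-identical across
    # re-runs with the same seed
    manifest = {
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "seed": config.seed,
        "stage_seeds": seeds,
        "counts": counts,
        "accounting": results.extra["accounting"],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
    (outdir / "config.json").write_text(config_json + "\n", encoding="utf-8")
    logger.info("run complete: %s", outdir)
    return results


def replay_paper(outdir=None, alpha: float = 0.05) -> ValidationResults:
    """Build the validation report directly from the packaged printed
    tallies, bypassing simulation entirely."""
    replay = replay_paper_counts()
    results = ValidationStudy.from_counts(replay).fit(alpha=alpha)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        results.save(outdir, stem="report")
        manifest = {
            "mode": "replay",
            "counts": {"requested": replay.requested, "retrieved": replay.obtained},
            "nonconfirm_categories": replay.nonconfirm_categories,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
    return results


def measure_realized_ppv(
    cohort: ClaimsCohort,
    truth: pd.DataFrame,
    registry: CodeSetRegistry | None = None,
    error_model: AbstractionErrorModel | None = None,
    as_of=None,
    seed: int = 0,
    cutoff=ICD10_ERA_START,
    mode: str = "primary",
) -> tuple[int, int]:
    """Empirical PPV over *every* phenotype-flagged patient (no sampling,
    full retrieval) — the Monte-Carlo counterpart of the generator's
    closed-form :func:`phenoval.synth.expected_ppv`.  Returns (k, n).
    """
    registry = registry or default_registry()
    em = error_model or AbstractionErrorModel()
    as_of = pd.Timestamp(as_of) if as_of is not None else cohort.max_service_date()
    eligibility = run_phenotype(cohort, registry, as_of=as_of)
    eligible = eligibility.loc[eligibility["eligible"], "patient_id"]
    index_claims = sampling_mod.select_index_claims(eligible, cohort, registry, cutoff=cutoff)
    flagged = index_claims["patient_id"].tolist()
    if not flagged:
        return 0, 0
    ss = np.random.SeedSequence(seed).generate_state(2, dtype=np.uint32)
    abstraction = simulate_abstraction(flagged, truth, em, int(ss[0]) % 2**31, as_of)
    outcomes = expert_review(abstraction, em, int(ss[1]) % 2**31)
    col = "final_status_primary" if mode == "primary" else "final_status_sensitivity"
    k = int((outcomes[col] == "confirmed").sum())
    return k, len(flagged)
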