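"""PPV estimation with exact binomial intervals, and the validation report.

The estimand throughout is the positive predictive value of the claims
phenotype: k confirmed records over n records obtained, with exact
(Clopper-Pearson) confidence limits from beta-quantile inversion.  Ratios
of PPVs between subgroups use the Katz log method by default (normal
approximation on log(p1/p2)), with a parametric-bootstrap percentile
interval as an alternative.

The modelling surface follows the Model -> Results convention:
:class:`ValidationStudy` is built from review outcomes (or directly from
printed counts) and ``fit()`` returns a :class:`ValidationResults` object
carrying the full PPV table, the subgroup ratios, and a ``summary()``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .adjudication import CONFIRMED, ReplayCounts, replay_paper_counts


def round_half_up(x: float, digits: int = 3) -> float:
    """Display rounding matching the conventional printed precision."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def ppv(k: int, n: int) -> float:
    """Point estimate k/n."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    return k / n


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial confidence limits via beta quantiles.

    Lower limit is 0 when k = 0; upper limit is 1 when k = n (where the
    lower limit reduces to (alpha/2)**(1/n)).
    """
    if n <= 0 or not 0 <= k <= n:
        raise ValueError("need n > 0 and 0 <= k <= n")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


@dataclass(frozen=True)
class PPVResult:
    k: int
    n: int
    estimate: float
    ci_low: float
    ci_high: float
    alpha: float = 0.05
    method: str = "clopper_pearson"

    @classmethod
    def from_counts(cls, k: int, n: int, alpha: float = 0.05) -> "PPVResult":
        lo, hi = clopper_pearson(k, n, alpha)
        return cls(k=k, n=n, estimate=ppv(k, n), ci_low=lo, ci_high=hi, alpha=alpha)

    def __str__(self) -> str:
        return (
            f"{self.k}/{self.n} = {round_half_up(self.estimate)} "
            f"({round_half_up(self.ci_low)}, {round_half_up(self.ci_high)})"
        )


@dataclass(frozen=True)
class RatioResult:
    ratio: float
    ci_low: float
    ci_high: float
    alpha: float = 0.05
    method: str = "katz_log"


def ppv_ratio(
    k1: int,
    n1: int,
    k2: int,
    n2: int,
    alpha: float = 0.05,
    method: str = "katz_log",
    n_boot: int = 100_000,
    seed: int = 0,
) -> RatioResult:
    """Ratio of two PPVs, (k1/n1)/(k2/n2), with a confidence interval.

    ``katz_log``: normal approximation on the log ratio with
    SE = sqrt((n1-k1)/(k1*n1) + (n2-k2)/(k2*n2)).
    ``bootstrap``: parametric resampling of both binomials, percentile
    interval (degenerate draws with k2* = 0 are redrawn implicitly by
    conditioning on a positive denominator proportion).
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("denominators must be positive")
    if k2 == 0:
        raise ValueError("reference-group proportion is zero; ratio undefined")
    r = (k1 / n1) / (k2 / n2)
    if method == "katz_log":
        if k1 == 0:
            raise ValueError("katz_log requires k1 > 0")
        se = np.sqrt((n1 - k1) / (k1 * n1) + (n2 - k2) / (k2 * n2))
        z = stats.norm.ppf(1 - alpha / 2)
        return RatioResult(r, float(r * np.exp(-z * se)), float(r * np.exp(z * se)), alpha, method)
    if method == "bootstrap":
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        b1 = rng.binomial(n1, k1 / n1, size=n_boot) / n1
        b2 = rng.binomial(n2, k2 / n2, size=n_boot) / n2
        ok = b2 > 0
        draws = b1[ok] / b2[ok]
        lo, hi = np.quantile(draws, [alpha / 2, 1 - alpha / 2])
        return RatioResult(r, float(lo), float(hi), alpha, method)
    raise ValueError(f"unknown method {method!r}")


def subgroup_ppvs(
    outcomes: pd.DataFrame,
    grouping: str,
    status_col: str = "final_status_primary",
    alpha: float = 0.05,
) -> dict[str, PPVResult]:
    """One PPVResult per level of ``grouping``; levels partition the denominator."""
    if grouping not in outcomes.columns:
        raise KeyError(f"no grouping column {grouping!r}")
    out: dict[str, PPVResult] = {}
    for level, sub in outcomes.groupby(grouping, sort=True):
        if len(sub) == 0:
            raise ValueError(f"empty level {level!r}")
        k = int((sub[status_col] == CONFIRMED).sum())
        out[str(level)] = PPVResult.from_counts(k, len(sub), alpha)
    return out


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

_ROW_ORDER = [
    ("all_abstractor", "All patients - abstractor"),
    ("all_post_review", "All patients, after expert review (main result)"),
    ("all_sensitivity", "Sensitivity analysis: CAD-only counted confirmed"),
    ("stratum_ami", "AMI stratum (stratum 1)"),
    ("stratum_pci_cabg", "PCI/CABG stratum (stratum 2)"),
    ("age_lt_65", "Aged < 65 years"),
    ("age_ge_65", "Aged >= 65 years"),
    ("sex_female", "Female patients"),
    ("sex_male", "Male patients"),
]
_ROW_LABELS = dict(_ROW_ORDER)

#: ratio orientation is fixed by the report schema: first-named over second
_RATIO_DEFS = {
    "strata_ami_over_pci_cabg": ("stratum_ami", "stratum_pci_cabg"),
    "sex_male_over_female": ("sex_male", "sex_female"),
    "age_ge65_over_lt65": ("age_ge_65", "age_lt_65"),
}


@dataclass
class ValidationStudy:
    """PPV validation of a phenotype against chart review.

    Construct with :meth:`from_outcomes` (simulated or real per-record
    review outcomes) or :meth:`from_counts` (pre-tallied numerators and
    denominators, e.g. replayed printed tallies); then call :meth:`fit`.
    """

    counts: dict[str, tuple[int, int]]  # row key -> (k, n)
    requested: int | None = None

    @classmethod
    def from_counts(cls, replay: ReplayCounts) -> "ValidationStudy":
        n = replay.obtained
        counts = {
            "all_abstractor": (replay.abstractor_confirmed, n),
            "all_post_review": (replay.primary_confirmed, n),
            "all_sensitivity": (replay.sensitivity_confirmed, n),
            "stratum_ami": (replay.strata["ami"]["confirmed"], replay.strata["ami"]["n"]),
            "stratum_pci_cabg": (replay.strata["pci_cabg"]["confirmed"], replay.strata["pci_cabg"]["n"]),
            "age_lt_65": (replay.age["lt_65"]["confirmed"], replay.age["lt_65"]["n"]),
            "age_ge_65": (replay.age["ge_65"]["confirmed"], replay.age["ge_65"]["n"]),
            "sex_female": (replay.sex["female"]["confirmed"], replay.sex["female"]["n"]),
            "sex_male": (replay.sex["male"]["confirmed"], replay.sex["male"]["n"]),
        }
        return cls(counts=counts, requested=replay.requested)

    @classmethod
    def from_paper_fixture(cls) -> "ValidationStudy":
        return cls.from_counts(replay_paper_counts())

    @classmethod
    def from_outcomes(cls, outcomes: pd.DataFrame, requested: int | None = None) -> "ValidationStudy":
        """Build from per-record outcomes.

        Requires columns ``abstractor_status``, ``final_status_primary``,
        ``final_status_sensitivity``; subgroup rows appear when
        ``stratum`` (1/2), ``sex`` (M/F) and ``age_band`` (lt_65/ge_65)
        columns are present.
        """
        n = len(outcomes)
        if n == 0:
            raise ValueError("no review outcomes")
        counts = {
            "all_abstractor": (int((outcomes["abstractor_status"] == CONFIRMED).sum()), n),
            "all_post_review": (int((outcomes["final_status_primary"] == CONFIRMED).sum()), n),
            "all_sensitivity": (int((outcomes["final_status_sensitivity"] == CONFIRMED).sum()), n),
        }

        def add_group(col: str, mapping: dict) -> None:
            if col not in outcomes.columns:
                return
            for value, key in mapping.items():
                sub = outcomes[outcomes[col] == value]
                if len(sub):
                    counts[key] = (int((sub["final_status_primary"] == CONFIRMED).sum()), len(sub))

        add_group("stratum", {1: "stratum_ami", 2: "stratum_pci_cabg"})
        add_group("sex", {"F": "sex_female", "M": "sex_male"})
        add_group("age_band", {"lt_65": "age_lt_65", "ge_65": "age_ge_65"})
        return cls(counts=counts, requested=requested)

    def fit(self, alpha: float = 0.05, ratio_method: str = "katz_log") -> "ValidationResults":
        rows = {}
        for key, (k, n) in self.counts.items():
            rows[key] = PPVResult.from_counts(k, n, alpha)
        ratios = {}
        for name, (num_key, den_key) in _RATIO_DEFS.items():
            if num_key in rows and den_key in rows:
                k1, n1 = self.counts[num_key]
                k2, n2 = self.counts[den_key]
                if 0 < k1 and 0 < k2:
                    ratios[name] = ppv_ratio(k1, n1, k2, n2, alpha=alpha, method=ratio_method)
        return ValidationResults(model=self, rows=rows, ratios=ratios, alpha=alpha)


@dataclass
class ValidationResults:
    """Estimates, exact intervals, ratios, and presentation helpers."""

    model: ValidationStudy
    rows: dict[str, PPVResult]
    ratios: dict[str, RatioResult]
    alpha: float = 0.05
    extra: dict = field(default_factory=dict)

    @property
    def overall(self) -> PPVResult:
        return self.rows["all_post_review"]

    @property
    def retrieval_rate(self) -> float | None:
        if self.model.requested:
            return self.rows["all_post_review"].n / self.model.requested
        return None

    def table(self) -> pd.DataFrame:
        records = []
        for key, _label in _ROW_ORDER:
            if key not in self.rows:
                continue
            r = self.rows[key]
            records.append(
                {
                    "row": key,
                    "label": _ROW_LABELS[key],
                    "denominator": r.n,
                    "numerator": r.k,
                    "ppv": round_half_up(r.estimate),
                    "ci_low": round_half_up(r.ci_low),
                    "ci_high": round_half_up(r.ci_high),
                }
            )
        return pd.DataFrame(records)

    def ratio_table(self) -> pd.DataFrame:
        records = []
        for name, r in self.ratios.items():
            records.append(
                {
                    "ratio": name,
                    "estimate": round_half_up(r.ratio),
                    "ci_low": round_half_up(r.ci_low),
                    "ci_high": round_half_up(r.ci_high),
                    "method": r.method,
                }
            )
        return pd.DataFrame(records)

    def summary(self) -> str:
        lines = ["Phenotype validation: positive predictive values", "=" * 64]
        if self.retrieval_rate is not None:
            lines.append(
                f"Records: {self.overall.n} obtained of {self.model.requested} requested "
                f"(retrieval rate {round_half_up(100 * self.retrieval_rate, 1)}%)"
            )
        for key, label in _ROW_ORDER:
            if key in self.rows:
                lines.append(f"{label:<50s} {self.rows[key]}")
        if self.ratios:
            lines.append("-" * 64)
            for name, r in self.ratios.items():
                lines.append(
                    f"PPV ratio {name:<40s} {round_half_up(r.ratio)} "
                    f"({round_half_up(r.ci_low)}, {round_half_up(r.ci_high)})"
                )
        return "\n".join(lines)

    def to_json(self) -> str:
        payload = {
            "alpha": self.alpha,
            "requested": self.model.requested,
            "rows": {
                key: {
                    "numerator": r.k,
                    "denominator": r.n,
                    "ppv": r.estimate,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                }
                for key, r in self.rows.items()
            },
            "ratios": {
                name: {"estimate": r.ratio, "ci_low": r.ci_low, "ci_high": r.ci_high, "method": r.method}
                for name, r in self.ratios.items()
            },
        }
        return json.dumps(payload, indent=2)

    def save(self, directory, stem: str = "report") -> dict[str, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        csv_path = directory / f"{stem}.csv"
        json_path = directory / f"{stem}.json"
        self.table().to_csv(csv_path, index=False, lineterminator="\n")
        json_path.write_text(self.to_json() + "\n", encoding="utf-8")
        return {"csv": csv_path, "json": json_path}


def build_report(outcomes_or_fixture, requested: int | None = None, alpha: float = 0.05) -> ValidationResults:
    """Convenience: fit a :class:`ValidationStudy` from whatever you have.

    Accepts a per-record outcomes DataFrame, a :class:`ReplayCounts`, a
    raw fixture dict, or ``None`` for the packaged printed tallies.
    """
    if outcomes_or_fixture is None:
        study = ValidationStudy.from_paper_fixture()
    elif isinstance(outcomes_or_fixture, ReplayCounts):
        study = ValidationStudy.from_counts(outcomes_or_fixture)
    elif isinstance(outcomes_or_fixture, dict):
        study = ValidationStudy.from_counts(replay_paper_counts(outcomes_or_fixture))
    elif isinstance(outcomes_or_fixture, pd.DataFrame):
        study = ValidationStudy.from_outcomes(outcomes_or_fixture, requested=requested)
    else:
        raise TypeError(f"cannot build a report from {type(outcomes_or_fixture)!r}")
    return study.fit(alpha=alpha)
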