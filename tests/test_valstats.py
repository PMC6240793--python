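import json
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phenoval.adjudication import replay_paper_counts
from phenoval.valstats import (
    PPVResult,
    ValidationStudy,
    build_report,
    clopper_pearson,
    ppv,
    ppv_ratio,
    round_half_up,
    subgroup_ppvs,
)


# --- brute-force oracle: invert binomial tail sums by bisection ---------------

def _tail_ge(k: int, n: int, p: float) -> float:
    return sum(comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1))


def _tail_le(k: int, n: int, p: float) -> float:
    return sum(comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(0, k + 1))


def exact_interval_bruteforce(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    def bisect(f, target):
        lo, hi = 0.0, 1.0
        for _ in range(100):
            mid = (lo + hi) / 2
            if f(mid) < target:
                lo = mid
            else:
                hi = mid
        return (lo + hi) / 2

    lower = 0.0 if k == 0 else bisect(lambda p: _tail_ge(k, n, p), alpha / 2)
    upper = 1.0 if k == n else bisect(lambda p: -_tail_le(k, n, p), -alpha / 2)
    return lower, upper


# --- point estimates -----------------------------------------------------------

@pytest.mark.parametrize(
    "k,n,expected",
    [(168, 185, 0.908), (97, 107, 0.907), (0, 10, 0.0), (71, 78, 0.910)],
)
def test_ppv_point_estimates(k, n, expected):
    assert round_half_up(ppv(k, n)) == expected


def test_ppv_rejects_bad_counts():
    with pytest.raises(ValueError):
        ppv(1, 0)
    with pytest.raises(ValueError):
        ppv(5, 4)


# --- exact interval --------------------------------------------------------------

def test_clopper_pearson_matches_bruteforce_oracle_everywhere():
    for n in range(1, 31):
        for k in range(0, n + 1):
            lo, hi = clopper_pearson(k, n)
            blo, bhi = exact_interval_bruteforce(k, n)
            assert lo == pytest.approx(blo, abs=1e-9), (k, n)
            assert hi == pytest.approx(bhi, abs=1e-9), (k, n)


def test_boundary_cases_closed_form():
    lo, hi = clopper_pearson(20, 20, alpha=0.05)
    assert hi == 1.0
    assert lo == pytest.approx(0.025 ** (1 / 20), rel=1e-12)
    lo0, hi0 = clopper_pearson(0, 12)
    assert lo0 == 0.0
    assert hi0 == pytest.approx(1 - 0.025 ** (1 / 12), rel=1e-12)


@given(n=st.integers(1, 200), frac=st.floats(0.0, 1.0), alpha=st.floats(0.005, 0.2))
def test_interval_brackets_estimate(n, frac, alpha):
    k = round(frac * n)
    lo, hi = clopper_pearson(k, n, alpha)
    assert 0.0 <= lo <= k / n <= hi <= 1.0


def test_interval_width_shrinks_with_n_at_fixed_proportion():
    for frac in (0.5, 0.85, 0.95):
        widths = []
        for n in (20, 40, 80, 160, 320):
            k = int(round(frac * n))
            lo, hi = clopper_pearson(k, n)
            widths.append(hi - lo)
        assert all(a > b for a, b in zip(widths, widths[1:])), frac


@pytest.mark.parametrize("p", [0.5, 0.85, 0.95])
@pytest.mark.parametrize("n", [30, 185])
def test_exact_interval_coverage_at_least_nominal(p, n):
    """10,000 replicates; the exact interval is conservative by design."""
    rng = np.random.default_rng(2024)
    ks = rng.binomial(n, p, size=10_000)
    bounds = {k: clopper_pearson(k, n) for k in np.unique(ks)}
    covered = np.array([bounds[k][0] <= p <= bounds[k][1] for k in ks])
    assert covered.mean() >= 0.95


# --- PPV ratios ---------------------------------------------------------------------

def test_equal_groups_give_unit_ratio():
    r = ppv_ratio(50, 100, 50, 100)
    assert r.ratio == pytest.approx(1.0)
    assert r.ci_low <= 1.0 <= r.ci_high


@pytest.mark.parametrize(
    "k1,n1,k2,n2,expected",
    [
        (97, 107, 71, 78, 0.996),    # AMI stratum over PCI/CABG stratum
        (106, 115, 62, 70, 1.041),   # male over female
        (134, 150, 34, 35, 0.920),   # >=65 over <65
    ],
)
def test_ratio_point_estimates_from_printed_counts(k1, n1, k2, n2, expected):
    assert round_half_up(ppv_ratio(k1, n1, k2, n2).ratio) == expected


def test_katz_interval_close_to_parametric_bootstrap():
    katz = ppv_ratio(97, 107, 71, 78, method="katz_log")
    boot = ppv_ratio(97, 107, 71, 78, method="bootstrap", n_boot=100_000, seed=1)
    assert katz.ci_low == pytest.approx(boot.ci_low, abs=0.02)
    assert katz.ci_high == pytest.approx(boot.ci_high, abs=0.02)


def test_ratio_rejects_zero_reference():
    with pytest.raises(ValueError):
        ppv_ratio(5, 10, 0, 10)


# --- subgroup partition ----------------------------------------------------------------

def test_subgroup_numerators_sum_to_overall():
    rng = np.random.default_rng(7)
    n = 200
    outcomes = pd.DataFrame(
        {
            "final_status_primary": np.where(rng.random(n) < 0.9, "confirmed", "non_confirmed"),
            "bucket": rng.choice(["a", "b", "c"], size=n),
        }
    )
    per_level = subgroup_ppvs(outcomes, "bucket")
    assert sum(r.k for r in per_level.values()) == (outcomes["final_status_primary"] == "confirmed").sum()
    assert sum(r.n for r in per_level.values()) == n


def test_all_confirmed_gives_unit_estimates():
    outcomes = pd.DataFrame(
        {
            "abstractor_status": ["confirmed"] * 40,
            "final_status_primary": ["confirmed"] * 40,
            "final_status_sensitivity": ["confirmed"] * 40,
            "stratum": [1] * 25 + [2] * 15,
        }
    )
    results = ValidationStudy.from_outcomes(outcomes).fit()
    assert all(r.estimate == 1.0 for r in results.rows.values())


# --- full report against the printed table ------------------------------------------------

PRINTED_TABLE = {
    "all_abstractor": (158, 185, 0.854, 0.795, 0.902),
    "all_post_review": (168, 185, 0.908, 0.857, 0.946),
    "all_sensitivity": (172, 185, 0.930, 0.883, 0.962),
    "stratum_ami": (97, 107, 0.907, 0.835, 0.954),
    "stratum_pci_cabg": (71, 78, 0.910, 0.824, 0.963),
    "age_lt_65": (34, 35, 0.971, 0.851, 0.999),
    "age_ge_65": (134, 150, 0.893, 0.833, 0.938),
    "sex_female": (62, 70, 0.886, 0.787, 0.949),
    "sex_male": (106, 115, 0.922, 0.857, 0.964),
}


def test_report_reproduces_every_printed_row():
    results = ValidationStudy.from_paper_fixture().fit()
    for key, (k, n, est, lo, hi) in PRINTED_TABLE.items():
        r = results.rows[key]
        assert (r.k, r.n) == (k, n), key
        assert round_half_up(r.estimate) == est, key
        assert round_half_up(r.ci_low) == lo, key
        assert round_half_up(r.ci_high) == hi, key


def test_report_serialization_roundtrip(tmp_path):
    results = build_report(None)
    paths = results.save(tmp_path)
    table = pd.read_csv(paths["csv"])
    assert len(table) == 9
    doc = json.loads(paths["json"].read_text())
    assert doc["rows"]["all_post_review"]["numerator"] == 168
    assert "strata_ami_over_pci_cabg" in doc["ratios"]


def test_build_report_accepts_counts_and_fixture():
    a = build_report(replay_paper_counts())
    b = build_report(None)
    assert a.rows["all_post_review"].k == b.rows["all_post_review"].k == 168


def test_ppvresult_invariants():
    r = PPVResult.from_counts(0, 10)
    assert r.ci_low == 0.0
    r = PPVResult.from_counts(10, 10)
    assert r.ci_high == 1.0
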