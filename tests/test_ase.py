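"""Allelic-fraction estimation, imbalance tests and cohort bias."""

from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tilapia_gh.ase import (
    AlleleCountRecord,
    binomial_imbalance_test,
    call_individuals,
    cohort_bias_test,
    condition_comparison,
    maternal_fraction,
    read_allele_counts,
)
from tilapia_gh.errors import ValidationError
from tilapia_gh.simulate import DEFAULT_ASE_PRESETS, ScenarioConfig, simulate_allele_counts


def rec(mat, pat, ind="x", sex="male", condition="adult"):
    return AlleleCountRecord(ind, sex, condition, mat, pat)


def exact_two_sided_p(k: int, n: int, p: float = 0.5) -> float:
    """Tail-enumeration oracle: sum of all outcome probabilities not
    exceeding the observed outcome's probability."""
    pmf = [comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(n + 1)]
    obs = pmf[k]
    return min(1.0, sum(q for q in pmf if q <= obs * (1 + 1e-12)))


@pytest.mark.parametrize(
    "mat,pat,expected", [(871, 129, 0.871), (0, 100, 0.0), (50, 50, 0.5)]
)
def test_maternal_fraction(mat, pat, expected):
    assert maternal_fraction(rec(mat, pat)) == pytest.approx(expected)


def test_zero_total_rejected():
    with pytest.raises(ValidationError):
        rec(0, 0)


def test_balanced_counts_have_unit_p():
    call = binomial_imbalance_test(rec(5, 5))
    assert call.p_value == 1.0 and call.direction == "balanced"


def test_nine_one_split_exact_p():
    assert binomial_imbalance_test(rec(9, 1)).p_value == pytest.approx(0.021484375)


def test_extreme_counts_stay_finite():
    call = binomial_imbalance_test(rec(1000, 0))
    assert call.direction == "maternal-biased"
    assert 0 < call.p_value < 1e-250


def test_matches_tail_enumeration_for_all_small_totals():
    """Exhaustive agreement with the enumeration oracle, totals <= 12."""
    for n in range(1, 13):
        for k in range(n + 1):
            got = binomial_imbalance_test(rec(k, n - k)).p_value
            assert got == pytest.approx(exact_two_sided_p(k, n), rel=1e-9), (k, n)


@given(st.integers(min_value=0, max_value=400), st.integers(min_value=0, max_value=400))
@settings(max_examples=200, derandomize=True)
def test_allele_label_symmetry(mat, pat):
    """Swapping maternal/paternal maps f -> 1-f, keeps p, flips direction."""
    if mat + pat == 0:
        return
    a = binomial_imbalance_test(rec(mat, pat))
    b = binomial_imbalance_test(rec(pat, mat))
    assert a.maternal_fraction == pytest.approx(1 - b.maternal_fraction)
    assert a.p_value == pytest.approx(b.p_value)
    flip = {"maternal-biased": "paternal-biased",
            "paternal-biased": "maternal-biased", "balanced": "balanced"}
    assert a.direction == flip[b.direction]


def test_cohort_bias_on_male_preset_simulation():
    """Cohort mean maternal percentage recovers the adult-male preset."""
    df = simulate_allele_counts("male_adult", depth=2000, seed=0)
    fracs = df.mat_count / (df.mat_count + df.pat_count)
    res = cohort_bias_test(fracs, "male/adult")
    assert res.mean_maternal_pct == pytest.approx(87.10, abs=3.0)
    assert res.direction == "maternal-biased" and res.p_value < 0.05


def test_degenerate_balanced_cohort_flagged():
    res = cohort_bias_test([0.5, 0.5, 0.5])
    assert res.degenerate and res.direction == "balanced"
    assert res.mean_maternal_pct == 50.0


def test_single_individual_rejected():
    with pytest.raises(ValidationError):
        cohort_bias_test([0.9])


def test_identical_conditions_rarely_flagged():
    """Type-I: fed vs fasted cohorts simulated from one preset."""
    cfg = ScenarioConfig(
        seed=0,
        ase_presets={
            "fed": {"sex": "male", "condition": "fed",
                    "fractions": (0.90, 0.88, 0.86, 0.84, 0.82)},
            "fasted": {"sex": "male", "condition": "fasted",
                       "fractions": (0.90, 0.88, 0.86, 0.84, 0.82)},
        },
    )
    hits = 0
    reps = 300
    for s in range(reps):
        fed = simulate_allele_counts("fed", depth=500, seed=s, config=cfg)
        fasted = simulate_allele_counts("fasted", depth=500, seed=s, config=cfg)
        fa = fed.mat_count / (fed.mat_count + fed.pat_count)
        fb = fasted.mat_count / (fasted.mat_count + fasted.pat_count)
        hits += condition_comparison(fa, fb)["decision"] == "condition effect"
    assert hits / reps <= 0.10


def test_strong_condition_shift_detected():
    rng = np.random.default_rng(1)
    fed = 0.9 + rng.normal(0, 0.01, 5)
    fasted = 0.5 + rng.normal(0, 0.01, 5)
    assert condition_comparison(fed, fasted)["decision"] == "condition effect"


def test_empty_condition_group_rejected():
    with pytest.raises(ValidationError):
        condition_comparison([], [0.5, 0.6])


@pytest.mark.parametrize("depths", [(50, 500, 5000)])
def test_recovery_tightens_with_depth(depths):
    """Cohort-mean error shrinks as read depth grows."""
    target = 100 * np.mean(DEFAULT_ASE_PRESETS["female_adult"]["fractions"])
    errors = []
    for depth in depths:
        means = []
        for s in range(100):
            df = simulate_allele_counts("female_adult", depth=depth, rho=0.0, seed=s)
            means.append(100 * (df.mat_count / (df.mat_count + df.pat_count)).mean())
        errors.append(abs(np.mean(means) - target))
    assert errors[-1] < 0.5
    assert errors[-1] <= errors[0] + 0.2


def test_individual_calls_roundtrip_table(tmp_path, default_bundle):
    records = read_allele_counts(default_bundle.allele_counts_path)
    calls = call_individuals(records, bh=True)
    assert len(calls) == len(records)
    assert set(calls.columns) >= {"individual", "maternal_fraction", "p_value",
                                  "direction", "p_adjusted"}
    adult_males = calls[(calls.sex == "male") & (calls.condition == "adult")]
    assert (adult_males.direction == "maternal-biased").sum() == 5
    assert (adult_males.direction == "paternal-biased").sum() == 1
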