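"""Comparative-Ct quantification and inheritance-mode classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tilapia_gh.errors import DegenerateInputError, ValidationError
from tilapia_gh.expression import (
    classify_by_sex,
    classify_inheritance,
    delta_delta_ct,
    midparent_value,
    read_ct_table,
    summarize_groups,
)
from tilapia_gh.simulate import ScenarioConfig, simulate_ct_table


def make_ct_table(samples: dict) -> pd.DataFrame:
    """samples: sample -> (group, sex, {gene: [ct replicates]})"""
    rows = []
    for sample, (group, sex, genes) in samples.items():
        for gene, cts in genes.items():
            for rep, ct in enumerate(cts, 1):
                rows.append((sample, group, sex, "adult", gene, rep, ct))
    return pd.DataFrame(
        rows, columns=["sample", "group", "sex", "age_class", "gene", "replicate", "ct"]
    )


def test_closed_form_rq():
    """Target 2 cycles earlier than the calibrator at equal reference
    levels quadruples the relative quantity."""
    table = make_ct_table({
        "s": ("NB", "male", {"GH": [20.0], "ref": [15.0]}),
        "cal": ("BB", "male", {"GH": [22.0], "ref": [15.0]}),
    })
    rq = delta_delta_ct(table, calibrator_group="BB").set_index("sample")["rq"]
    assert rq["s"] == pytest.approx(4.0)
    assert rq["cal"] == pytest.approx(1.0)


def test_sample_equal_to_calibrator_has_unit_rq():
    table = make_ct_table({
        "only": ("BB", "male", {"GH": [21.0, 21.0], "ref": [17.0, 17.0]}),
    })
    assert delta_delta_ct(table, "BB")["rq"].iloc[0] == pytest.approx(1.0)


def test_triplicates_use_their_mean():
    table = make_ct_table({
        "s": ("NB", "male", {"GH": [20.1, 19.9, 20.0], "ref": [15.0, 15.0, 15.0]}),
        "cal": ("BB", "male", {"GH": [22.0], "ref": [15.0]}),
    })
    rq = delta_delta_ct(table, "BB").set_index("sample")["rq"]
    # dCt(s) = 20.0 - 15.0; ddCt = 5 - 7 = -2
    assert rq["s"] == pytest.approx(2.0 ** 2)


def test_missing_reference_gene_rejected():
    table = make_ct_table({"s": ("BB", "male", {"GH": [20.0]})})
    with pytest.raises(ValidationError):
        delta_delta_ct(table, "BB")


@given(st.floats(min_value=-3, max_value=3))
@settings(max_examples=50, derandomize=True)
def test_rq_invariant_to_per_sample_ct_shift(shift):
    """Adding a constant to one sample's target AND reference Ct leaves
    every RQ unchanged (the normalisation absorbs sample-loading shifts)."""
    base = {
        "s1": ("NB", "male", {"GH": [20.0, 20.2], "ref": [15.0, 15.1]}),
        "s2": ("NN", "male", {"GH": [22.0], "ref": [15.3]}),
        "cal": ("BB", "male", {"GH": [24.0], "ref": [15.2]}),
    }
    shifted = {
        "s1": ("NB", "male", {"GH": [c + shift for c in [20.0, 20.2]],
                              "ref": [c + shift for c in [15.0, 15.1]]}),
        "s2": base["s2"],
        "cal": base["cal"],
    }
    rq_a = delta_delta_ct(make_ct_table(base), "BB").set_index("sample")["rq"]
    rq_b = delta_delta_ct(make_ct_table(shifted), "BB").set_index("sample")["rq"]
    assert np.allclose(rq_a, rq_b)


@pytest.mark.parametrize(
    "nn,bb,expected", [(1.0, 1.0, 1.0), (378.95, 305.25, 342.10), (2.0, 0.5, 1.25)]
)
def test_midparent_value(nn, bb, expected):
    assert midparent_value(nn, bb) == pytest.approx(expected)


def test_midparent_requires_positive_means():
    with pytest.raises(ValidationError):
        midparent_value(-1.0, 2.0)


def test_overdominant_when_hybrid_exceeds_both_parents():
    rng = np.random.default_rng(2)
    call = classify_inheritance(
        rng.normal(12, 1, 6), rng.normal(4, 1, 6), rng.normal(1, 1, 6)
    )
    assert call.category == "overdominant" and call.nonadditive


def test_maternal_dominant_when_hybrid_matches_dam_only():
    rng = np.random.default_rng(3)
    call = classify_inheritance(
        rng.normal(6, 0.5, 6), rng.normal(6, 0.5, 6), rng.normal(1, 0.5, 6)
    )
    assert call.category == "maternal-dominant"


def test_null_cohorts_called_additive_at_nominal_rate():
    """Type-I rate of the MPV test stays below 0.10 under the null."""
    rng = np.random.default_rng(0)
    nonadditive = sum(
        classify_inheritance(rng.normal(10, 1, 5), rng.normal(10, 1, 5),
                             rng.normal(10, 1, 5)).category != "additive"
        for _ in range(400)
    )
    assert nonadditive / 400 <= 0.10


def test_parent_swap_mirrors_dominance_labels():
    rng = np.random.default_rng(4)
    h, m, p = rng.normal(6, 0.5, 6), rng.normal(6, 0.5, 6), rng.normal(1, 0.5, 6)
    fwd = classify_inheritance(h, m, p)
    rev = classify_inheritance(h, p, m)
    assert fwd.category == "maternal-dominant"
    assert rev.category == "paternal-dominant"
    assert fwd.mpv == rev.mpv


def test_zero_variance_cohort_is_degenerate():
    with pytest.raises(DegenerateInputError):
        classify_inheritance([5.0, 5.0, 5.0], [1.0, 1.2, 0.9], [0.5, 0.6, 0.4])


def test_default_scenario_hybrid_sits_above_mpv():
    """End-to-end: the generated Ct table yields an above-MPV
    nonadditive call in both sexes."""
    table = simulate_ct_table(ScenarioConfig(seed=5))
    rq = delta_delta_ct(table, "BB")
    calls = classify_by_sex(rq)
    for sex, call in calls.items():
        assert call.nonadditive
        hybrid_mean = rq[(rq.group == "NB") & (rq.sex == sex)]["rq"].mean()
        assert hybrid_mean > call.mpv


def test_group_summaries_carry_sd_and_n(default_bundle):
    rq = delta_delta_ct(read_ct_table(default_bundle.ct_table_path), "BB")
    summaries = summarize_groups(rq)
    assert {(s.group, s.sex) for s in summaries} == {
        (g, sx) for g in ("NN", "BB", "NB") for sx in ("male", "female")
    }
    for s in summaries:
        assert s.n == 5 and s.mean_rq > 0 and s.sd_rq >= 0
        assert s.sem_rq == pytest.approx(s.sd_rq / np.sqrt(5))
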