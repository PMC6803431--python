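"""Relative quantification of GH expression and inheritance-mode calls.

GH Ct values are normalised to the beta-actin reference gene with the
comparative-Ct (2^-ddCt) method, summarised per group x sex, and the
hybrid cohort is classified against the midparent value (MPV, the
arithmetic mean of the two parental cohort means): a hybrid that differs
from the MPV is nonadditive, refined to overdominant / underdominant /
maternal- or paternal-dominant by comparison with each parent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, ValidationError
from .stats import one_sample_t, welch_t

MATERNAL_GROUP = "NN"  # Nile tilapia dam
PATERNAL_GROUP = "BB"  # blue tilapia sire
HYBRID_GROUP = "NB"


@dataclass(frozen=True)
class RelativeExpression:
    sample: str
    group: str
    sex: str
    rq: float  # 2^-ddCt, dimensionless

    def __post_init__(self) -> None:
        if self.rq <= 0:
            raise ValidationError("RQ must be positive")


@dataclass(frozen=True)
class GroupExpressionSummary:
    group: str
    sex: str
    n: int
    mean_rq: float
    sd_rq: float

    @property
    def sem_rq(self) -> float:
        return self.sd_rq / np.sqrt(self.n)


@dataclass(frozen=True)
class InheritanceCall:
    """MPV-relative classification of hybrid expression."""

    category: str  # additive | predominant | below-mpv | maternal-dominant |
    #                paternal-dominant | overdominant | underdominant
    nonadditive: bool
    mpv: float
    p_values: dict = field(default_factory=dict)


def _mean_ct(df: pd.DataFrame, sample: str, gene: str) -> float:
    vals = df.loc[(df["sample"] == sample) & (df["gene"] == gene), "ct"]
    if vals.empty:
        raise ValidationError(f"sample {sample}: no Ct replicates for gene {gene!r}")
    if ((vals <= 0) | (vals >= 45)).any():
        raise ValidationError(f"sample {sample}: Ct outside (0, 45)")
    return float(vals.mean())


def delta_ct(ct_table: pd.DataFrame, sample: str,
             target: str = "GH", reference: str = "ref") -> float:
    """dCt = mean Ct(target) - mean Ct(reference) for one sample."""
    return _mean_ct(ct_table, sample, target) - _mean_ct(ct_table, sample, reference)


def delta_delta_ct(
    ct_table: pd.DataFrame,
    calibrator_group: str = PATERNAL_GROUP,
    target: str = "GH",
    reference: str = "ref",
) -> pd.DataFrame:
    """Per-sample relative quantities, 2^-ddCt.

    The calibrator dCt is the mean dCt over the calibrator group's
    samples (default: the lowest-expressing parental line, BB), so the
    calibrator group averages to RQ ~ 1. Returns a table with columns
    sample, group, sex, dct, rq.
    """
    meta = ct_table[["sample", "group", "sex"]].drop_duplicates("sample")
    if calibrator_group not in set(meta["group"]):
        raise ValidationError(f"calibrator group {calibrator_group!r} absent from table")
    dcts = {s: delta_ct(ct_table, s, target, reference) for s in meta["sample"]}
    cal_samples = meta.loc[meta["group"] == calibrator_group, "sample"]
    cal_dct = float(np.mean([dcts[s] for s in cal_samples]))
    out = meta.copy()
    out["dct"] = out["sample"].map(dcts)
    out["rq"] = 2.0 ** -(out["dct"] - cal_dct)
    return out.reset_index(drop=True)


def summarize_groups(rq_table: pd.DataFrame) -> list[GroupExpressionSummary]:
    """Mean/sd RQ per group x sex (sd requires n >= 2)."""
    out = []
    for (group, sex), sub in rq_table.groupby(["group", "sex"], sort=False):
        n = len(sub)
        if n < 2:
            raise ValidationError(f"group {group}/{sex}: need n >= 2 for a summary")
        out.append(GroupExpressionSummary(group, sex, n,
                                          float(sub["rq"].mean()),
                                          float(sub["rq"].std(ddof=1))))
    return out


def midparent_value(mean_maternal: float, mean_paternal: float) -> float:
    """Additive expectation for the hybrid: the parental-mean average."""
    if mean_maternal <= 0 or mean_paternal <= 0:
        raise ValidationError("parental means must be positive")
    return (mean_maternal + mean_paternal) / 2.0


def classify_inheritance(
    hybrid, maternal, paternal, alpha: float = 0.05
) -> InheritanceCall:
    """Classify hybrid expression relative to MPV and both parents.

    Stage 1: one-sample t of the hybrid RQs against the MPV point
    estimate; nonsignificant -> additive. Stage 2 refines a nonadditive
    call with Welch t tests against each parent: above/below both ->
    over/underdominant; indistinguishable from exactly one parent (with
    the parents themselves differing) -> that parent's dominance;
    otherwise the direction-only call (above-MPV nonadditive is the
    "predominant" pattern).
    """
    hybrid = np.asarray(hybrid, float)
    maternal = np.asarray(maternal, float)
    paternal = np.asarray(paternal, float)
    for name, arr in (("hybrid", hybrid), ("maternal", maternal), ("paternal", paternal)):
        if len(arr) < 2:
            raise ValidationError(f"{name} cohort needs n >= 2")
        if np.ptp(arr) == 0:
            raise DegenerateInputError(f"{name} cohort has zero variance")

    mpv = midparent_value(float(maternal.mean()), float(paternal.mean()))
    _, p_mpv = one_sample_t(hybrid, mpv)
    pvals = {"vs_mpv": p_mpv}
    if p_mpv >= alpha:
        return InheritanceCall("additive", False, mpv, pvals)

    above = bool(hybrid.mean() > mpv)
    _, p_mat = welch_t(hybrid, maternal)
    _, p_pat = welch_t(hybrid, paternal)
    _, p_parents = welch_t(maternal, paternal)
    pvals.update({"vs_maternal": p_mat, "vs_paternal": p_pat, "parents": p_parents})

    h, m, p = hybrid.mean(), maternal.mean(), paternal.mean()
    if p_mat < alpha and p_pat < alpha:
        if h > m and h > p:
            return InheritanceCall("overdominant", True, mpv, pvals)
        if h < m and h < p:
            return InheritanceCall("underdominant", True, mpv, pvals)
    if p_parents < alpha:
        if p_mat >= alpha and p_pat < alpha:
            return InheritanceCall("maternal-dominant", True, mpv, pvals)
        if p_pat >= alpha and p_mat < alpha:
            return InheritanceCall("paternal-dominant", True, mpv, pvals)
    return InheritanceCall("predominant" if above else "below-mpv", True, mpv, pvals)


def cohort_rqs(rq_table: pd.DataFrame, group: str, sex: str) -> np.ndarray:
    sub = rq_table[(rq_table["group"] == group) & (rq_table["sex"] == sex)]
    return sub["rq"].to_numpy()


def classify_by_sex(rq_table: pd.DataFrame, alpha: float = 0.05) -> dict[str, InheritanceCall]:
    """Inheritance call per sex from a per-sample RQ table."""
    calls = {}
    for sex in rq_table["sex"].unique():
        calls[str(sex)] = classify_inheritance(
            cohort_rqs(rq_table, HYBRID_GROUP, sex),
            cohort_rqs(rq_table, MATERNAL_GROUP, sex),
            cohort_rqs(rq_table, PATERNAL_GROUP, sex),
            alpha=alpha,
        )
    return calls


def read_ct_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "group", "sex", "gene", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"Ct table missing columns {sorted(missing)}")
    return df
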