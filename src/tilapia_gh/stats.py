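"""Shared statistical utilities: variance-homogeneity gating, one-way
ANOVA with Tukey HSD, and the t-test wrappers used across modules."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, ValidationError


@dataclass(frozen=True)
class HomogeneityResult:
    transformed: bool
    levene_p: float
    groups: list  # original or log10-transformed values


@dataclass(frozen=True)
class AnovaTukeyResult:
    omnibus_p: float
    f_statistic: float
    pairwise_p: dict  # (i, j) group-index pair -> Tukey-adjusted p
    significant: dict  # (i, j) -> bool at the supplied alpha


def check_homogeneity_and_transform(groups, alpha: float = 0.05) -> HomogeneityResult:
    """Levene's test (median-centred); on heterogeneity, log10-transform.

    Mirrors the analysis convention of gating parametric comparisons on
    variance homogeneity and stabilising with log10 when it fails.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValidationError("need >= 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValidationError("each group needs n >= 2")
    if all(np.ptp(g) == 0 for g in groups):
        # Levene is undefined on all-constant groups; nothing to transform.
        return HomogeneityResult(False, 1.0, groups)
    p = float(stats.levene(*groups, center="median").pvalue)
    if p < alpha:
        if any((g <= 0).any() for g in groups):
            raise ValidationError("log10 transform requires strictly positive values")
        return HomogeneityResult(True, p, [np.log10(g) for g in groups])
    return HomogeneityResult(False, p, groups)


def anova_tukey(groups, alpha: float = 0.05) -> AnovaTukeyResult:
    """One-way ANOVA omnibus F test plus Tukey HSD pairwise comparisons."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValidationError("ANOVA + Tukey requires >= 3 groups")
    if any(len(g) < 2 for g in groups):
        raise ValidationError("each group needs n >= 2")
    if all(np.ptp(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
        # identical constant groups: no variance anywhere, F is 0/0
        pairs = {(i, j): 1.0 for i in range(len(groups)) for j in range(i + 1, len(groups))}
        return AnovaTukeyResult(1.0, 0.0, pairs, {k: False for k in pairs})
    f, p = stats.f_oneway(*groups)
    hsd = stats.tukey_hsd(*groups)
    pairwise = {}
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            pairwise[(i, j)] = float(hsd.pvalue[i, j])
    sig = {k: v < alpha for k, v in pairwise.items()}
    return AnovaTukeyResult(float(p), float(f), pairwise, sig)


def welch_t(a, b) -> tuple[float, float]:
    """Welch two-sample t test; returns (statistic, two-sided p)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("Welch t needs n >= 2 per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise DegenerateInputError("both groups have zero variance")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def paired_t(a, b) -> tuple[float, float]:
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) != len(b):
        raise ValidationError("paired t needs equal-length samples")
    if len(a) < 2:
        raise ValidationError("paired t needs n >= 2")
    d = a - b
    if np.ptp(d) == 0:
        raise DegenerateInputError("zero-variance differences")
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def one_sample_t(values, popmean: float) -> tuple[float, float]:
    values = np.asarray(values, float)
    if len(values) < 2:
        raise ValidationError("one-sample t needs n >= 2")
    if np.ptp(values) == 0:
        raise DegenerateInputError("zero-variance sample")
    t, p = stats.ttest_1samp(values, popmean)
    return float(t), float(p)
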