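"""Cis/trans decomposition of regulatory divergence in the F1 hybrid.

Parental expression divergence A = log2(NN/BB) mixes cis and trans
effects; within the hybrid both alleles share one trans environment, so
the allelic divergence B = log2(maternal/paternal reads) isolates the
cis component and the trans component is the remainder A - B. When cis
and trans act in the same direction ({B>0 and A-B>0} or {B<0 and
A-B<0}) they are enhancing; opposite directions ({B>0 and A-B<0} or
{B<0 and A-B>0}) are compensating. An epsilon dead-zone (default 0.1
log2 units) adds the boundary categories conserved / cis-only /
trans-only, which the sign rules alone leave undefined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .ase import CohortBiasResult
from .errors import ValidationError
from .expression import GroupExpressionSummary, MATERNAL_GROUP, PATERNAL_GROUP

EXTENDED_CATEGORIES = frozenset({"conserved", "cis-only", "trans-only"})


@dataclass(frozen=True)
class CisTransResult:
    A: float  # log2 parental expression divergence
    B: float  # log2 hybrid allelic divergence (cis)
    trans: float  # A - B
    category: str
    extended: bool  # True when the category comes from the epsilon dead-zone

    def __post_init__(self) -> None:
        if self.trans != self.A - self.B:
            raise ValidationError("trans must equal A - B exactly")


def parental_divergence(mean_nn: float, mean_bb: float) -> float:
    """A = log2(NN/BB) from parental mean relative expression."""
    if mean_nn <= 0 or mean_bb <= 0:
        raise ValidationError("parental means must be positive")
    return math.log2(mean_nn / mean_bb)


def cis_effect(maternal_pct: float, paternal_pct: float) -> float:
    """B = log2(maternal/paternal allele share in the hybrid)."""
    if maternal_pct <= 0 or paternal_pct <= 0:
        raise ValidationError("allele percentages must be positive")
    return math.log2(maternal_pct / paternal_pct)


def classify(A: float, B: float, epsilon: float = 0.1) -> CisTransResult:
    """Sign-rule category for one gene x cohort, with epsilon dead-zone."""
    if not (np.isfinite(A) and np.isfinite(B)):
        raise ValidationError("A and B must be finite")
    if epsilon < 0:
        raise ValidationError("epsilon must be >= 0")
    trans = A - B
    small_b, small_t = abs(B) <= epsilon, abs(trans) <= epsilon
    if small_b and small_t:
        cat, ext = "conserved", True
    elif small_t:
        cat, ext = "cis-only", True
    elif small_b:
        cat, ext = "trans-only", True
    elif (B > 0) == (trans > 0):
        cat, ext = "enhancing", False
    else:
        cat, ext = "compensating", False
    return CisTransResult(A, B, trans, cat, ext)


def decompose(
    summaries: list[GroupExpressionSummary],
    cohort_ase: CohortBiasResult,
    sex: str,
    epsilon: float = 0.1,
) -> CisTransResult:
    """Chain A from the expression summaries and B from the cohort-mean
    allelic percentage for one sex, then classify."""
    by_group = {s.group: s for s in summaries if s.sex == sex}
    for g in (MATERNAL_GROUP, PATERNAL_GROUP):
        if g not in by_group:
            raise ValidationError(f"missing {g} expression summary for sex {sex!r}")
    A = parental_divergence(by_group[MATERNAL_GROUP].mean_rq,
                            by_group[PATERNAL_GROUP].mean_rq)
    m = cohort_ase.mean_maternal_pct
    B = cis_effect(m, 100.0 - m)
    return classify(A, B, epsilon)
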