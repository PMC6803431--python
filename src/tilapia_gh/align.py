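"""Global pairwise alignment (Needleman-Wunsch, linear gap penalty).

The parental GH cDNAs are equal-length substitutions-only sequences, so
any sane scoring scheme returns the ungapped alignment; the aligner is
nonetheless a full global aligner with a fixed, deterministic traceback
(tie-break preference: diagonal, then up (gap in B), then left (gap in A))
so downstream SNP coordinates never depend on library version or tie
ordering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

_ALLOWED = set("ACGTN")


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global alignment of two sequences; '-' marks gaps."""

    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValidationError("aligned rows differ in length")

    def columns(self):
        """Iterate (base_a, base_b) columns."""
        return zip(self.aligned_a, self.aligned_b)


def align_pair(
    seq_a: str,
    seq_b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> PairwiseAlignment:
    """Optimal global alignment of two nucleotide sequences.

    Parameters follow the usual linear-gap scheme (gap is the per-base
    penalty, a negative number). N is scored like any other symbol, so
    N/N is a match and N against a real base a mismatch.
    """
    a, b = seq_a.upper(), seq_b.upper()
    if not a or not b:
        raise ValidationError("cannot align an empty sequence")
    for name, s in (("A", a), ("B", b)):
        bad = set(s) - _ALLOWED
        if bad:
            raise ValidationError(f"sequence {name} contains non-ACGTN characters: {bad}")

    n, m = len(a), len(b)
    score = np.empty((n + 1, m + 1), dtype=float)
    score[0, :] = np.arange(m + 1) * gap
    score[:, 0] = np.arange(n + 1) * gap
    arr_a = np.frombuffer(a.encode(), dtype="S1")
    arr_b = np.frombuffer(b.encode(), dtype="S1")
    for i in range(1, n + 1):
        sub = np.where(arr_b == arr_a[i - 1], match, mismatch)
        row_prev = score[i - 1]
        row = score[i]
        for j in range(1, m + 1):
            row[j] = max(row_prev[j - 1] + sub[j - 1], row_prev[j] + gap, row[j - 1] + gap)

    # Traceback, diagonal > up > left on ties.
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            diag = score[i - 1, j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
            if score[i, j] == diag:
                out_a.append(a[i - 1])
                out_b.append(b[j - 1])
                i, j = i - 1, j - 1
                continue
        if i > 0 and score[i, j] == score[i - 1, j] + gap:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
            continue
        out_a.append("-")
        out_b.append(b[j - 1])
        j -= 1

    return PairwiseAlignment("".join(reversed(out_a)), "".join(reversed(out_b)),
                             float(score[n, m]))
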