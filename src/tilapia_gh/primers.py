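"""Primer pairs, amplicon sizes and SNP-coverage checks.

Primer sequences are carried as metadata in the orientation they are
synthesised (reverse primers are reverse-complement relative to the plus
strand); all coordinate arithmetic happens on plus-strand signed CDS
spans.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from .coords import signed_span_length, validate_coord
from .errors import ValidationError

_VALID_BASES = set("ACGT")


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse primer pair with inclusive signed CDS spans."""

    name: str
    forward_seq: str
    forward_span: tuple[int, int]
    reverse_seq: str
    reverse_span: tuple[int, int]
    annealing_temp_c: float = 60.0

    def __post_init__(self) -> None:
        for seq, span, role in (
            (self.forward_seq, self.forward_span, "forward"),
            (self.reverse_seq, self.reverse_span, "reverse"),
        ):
            start, end = span
            validate_coord(start)
            validate_coord(end)
            if not (start < end or (start == end and len(seq) == 1)):
                raise ValidationError(f"{self.name} {role}: span start must precede end")
            if set(seq.upper()) - _VALID_BASES:
                raise ValidationError(f"{self.name} {role}: non-ACGT base in primer")
            if len(seq) != signed_span_length(start, end):
                raise ValidationError(
                    f"{self.name} {role}: primer length {len(seq)} != span length "
                    f"{signed_span_length(start, end)}"
                )


def amplicon_size(pair: PrimerPair) -> int:
    """PCR product length: the inclusive span from the forward primer's
    5' end to the reverse primer's 3' end (plus-strand coordinates)."""
    f_start, f_end = pair.forward_span
    r_start, r_end = pair.reverse_span
    if not f_end < r_start:
        raise ValidationError(
            f"{pair.name}: forward span must lie entirely 5' of the reverse span"
        )
    return signed_span_length(f_start, r_end)


def site_in_amplicon(position: int, pair: PrimerPair) -> Optional[int]:
    """1-based offset of a SNP position within the pair's amplicon, or
    ``None`` when the site is outside it."""
    validate_coord(position)
    f_start = pair.forward_span[0]
    r_end = pair.reverse_span[1]
    if position < f_start or position > r_end:
        return None
    return signed_span_length(f_start, position)


# The study's primer set (design metadata for the GH and beta-actin assays).
RT_GH = PrimerPair(
    "rt-GH",
    "ATCAGGGCCAATCAGGATGA", (409, 428),
    "GTGCATGTCCTTCTTGAAGCAA", (537, 558),
)
RT_ACTB = PrimerPair(
    "rt-beta-actin",
    "CCACAGCCGAGAGGGAAAT", (605, 623),
    "CCATCTCCTGCTCGAAGTC", (664, 682),
)
PYR_GH = PrimerPair(
    "pyr-GH",
    "GAAGCAGAGAATTATCCTGACAC", (427, 449),
    "CAAGCCAGCAATTCATAAGTT", (519, 539),
)
CLONING_GH = PrimerPair(
    "GH",
    "CTGAGCCGCAAACAGAGCC", (-26, -8),
    "AAAACTTCTGATGTCACGATTACCA", (727, 751),
)

STUDY_PRIMERS: dict[str, PrimerPair] = {
    p.name: p for p in (CLONING_GH, RT_GH, RT_ACTB, PYR_GH)
}


def read_primer_table(path: str | Path) -> dict[str, PrimerPair]:
    """Read a primer TSV (name, seq, start, end, role[, tm]) into pairs."""
    df = pd.read_csv(path, sep="\t")
    pairs: dict[str, PrimerPair] = {}
    for name, sub in df.groupby("name", sort=False):
        roles = {r.role: r for r in sub.itertuples()}
        if not {"forward", "reverse"} <= roles.keys():
            raise ValidationError(f"primer {name}: need one forward and one reverse row")
        fwd, rev = roles["forward"], roles["reverse"]
        tm = float(getattr(fwd, "tm", 60.0))
        pairs[str(name)] = PrimerPair(
            str(name),
            fwd.seq, (int(fwd.start), int(fwd.end)),
            rev.seq, (int(rev.start), int(rev.end)),
            tm,
        )
    return pairs


def write_primer_table(pairs: dict[str, PrimerPair], path: str | Path) -> None:
    rows = []
    for p in pairs.values():
        rows.append((p.name, p.forward_seq, p.forward_span[0], p.forward_span[1],
                     "forward", p.annealing_temp_c))
        rows.append((p.name, p.reverse_seq, p.reverse_span[0], p.reverse_span[1],
                     "reverse", p.annealing_temp_c))
    pd.DataFrame(rows, columns=["name", "seq", "start", "end", "role", "tm"]).to_csv(
        path, sep="\t", index=False
    )
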