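"""Signed CDS coordinate arithmetic.

Positions on the GH cDNA are 1-based within the coding sequence; negative
positions count 5'-ward from the CDS start (-1 is the base immediately
upstream of +1). Position 0 does not exist. Spans are inclusive at both
ends. This zero-skipping convention reproduces every printed amplicon size
of the study's primer table, including the cloning pair whose forward
primer lies in the 5' UTR (-26 to -8, 777-bp product).
"""

from __future__ import annotations

from .errors import CoordinateError


def validate_coord(value: int) -> int:
    """Check a signed CDS coordinate; position 0 is undefined."""
    if not isinstance(value, (int,)) or isinstance(value, bool):
        raise CoordinateError(f"coordinate must be an integer, got {value!r}")
    if value == 0:
        raise CoordinateError("position 0 does not exist in signed CDS coordinates")
    return value


def signed_span_length(start: int, end: int) -> int:
    """Number of bases in the inclusive span [start, end].

    Same-sign spans count end - start + 1 positions; spans crossing the
    CDS start count end - start because position 0 is skipped.
    """
    validate_coord(start)
    validate_coord(end)
    if start > end:
        raise CoordinateError(f"reversed span: start {start} > end {end}")
    if (start > 0) == (end > 0):
        return end - start + 1
    return end - start


def next_coord(value: int) -> int:
    """The coordinate immediately 3' of ``value`` (skips 0)."""
    validate_coord(value)
    return 1 if value == -1 else value + 1


def signed_to_index(position: int, utr5_len: int) -> int:
    """Map a signed coordinate to a 0-based index in a sequence that
    starts ``utr5_len`` bases upstream of the CDS."""
    validate_coord(position)
    idx = utr5_len + position - 1 if position > 0 else utr5_len + position
    if idx < 0:
        raise CoordinateError(
            f"position {position} lies 5' of the sequence start (UTR length {utr5_len})"
        )
    return idx


def index_to_signed(index: int, utr5_len: int) -> int:
    """Inverse of :func:`signed_to_index`."""
    if index < 0:
        raise CoordinateError(f"negative sequence index {index}")
    offset = index - utr5_len
    return offset if offset < 0 else offset + 1
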