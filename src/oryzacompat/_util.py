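"""Small shared helpers."""

from __future__ import annotations

import math

DNA = frozenset("ACGT")
GAP = "-"
MISSING = "N"


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero.

    Python's built-in ``round`` uses banker's rounding; published percentage
    tables in this field conventionally round 0.5 up (62.5 -> 63).
    """
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def as_pairs(alignment) -> list[tuple[str, str]]:
    """Normalise an alignment argument to ``[(id, sequence), ...]``.

    Accepts a Biopython ``MultipleSeqAlignment``/iterable of ``SeqRecord``,
    an iterable of ``(id, seq)`` pairs, or a bare iterable of strings (ids are
    then ``seq0``, ``seq1``, ...). Sequences are upper-cased.
    """
    pairs: list[tuple[str, str]] = []
    for i, item in enumerate(alignment):
        if isinstance(item, str):
            pairs.append((f"seq{i}", item.upper()))
        elif isinstance(item, tuple) and len(item) == 2:
            pairs.append((str(item[0]), str(item[1]).upper()))
        else:  # SeqRecord-like
            pairs.append((str(item.id), str(item.seq).upper()))
    return pairs


def check_aligned(pairs: list[tuple[str, str]]) -> int:
    """Return the common aligned length, raising on ragged input."""
    if not pairs:
        raise ValueError("empty alignment")
    length = len(pairs[0][1])
    for name, seq in pairs:
        if len(seq) != length:
            raise ValueError(
                f"sequence {name!r} has length {len(seq)}, expected {length}"
            )
    return length
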