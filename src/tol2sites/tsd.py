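"""Target-site duplication (TSD) detection and summaries.

hAT-family transposases such as Tol2 duplicate an 8-bp target word on
integration, leaving identical copies on both sides of the element.  At
a sequenced insertion the duplication shows up as the longest overlap
between the suffix of the upstream (left) flank and the prefix of the
downstream (right) flank, both read on the target plus strand.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .errors import EmptyInputError, InvalidArgumentError

CANONICAL_TSD_LEN = 8


@dataclass(frozen=True)
class TsdCall:
    """Detected duplication at one insertion: sequence, length and
    whether it is the canonical 8-bp hAT signature."""

    tsd_seq: str
    tsd_len: int
    canonical: bool

    def __post_init__(self) -> None:
        assert len(self.tsd_seq) == self.tsd_len
        assert not self.canonical or self.tsd_len == CANONICAL_TSD_LEN


def detect_tsd(left_flank: str, right_flank: str, max_len: int = 12) -> TsdCall:
    """Longest duplication of length <= ``max_len`` shared by the flank pair.

    Returns the largest k such that the length-k suffix of
    ``left_flank`` equals the length-k prefix of ``right_flank``
    (k = 0, a blunt joint, is allowed).  ``max_len`` defaults to 12,
    deliberately above the canonical 8, so that over-long duplications
    are observed and classified rather than clipped.
    """
    if max_len < 0:
        raise InvalidArgumentError("max_len must be >= 0")
    left = left_flank.upper()
    right = right_flank.upper()
    if len(left) < max_len or len(right) < max_len:
        raise InvalidArgumentError(
            f"flanks must be at least max_len={max_len} bp (got {len(left)} and {len(right)})"
        )
    best = 0
    for k in range(1, max_len + 1):
        if left[-k:] == right[:k]:
            best = k
    seq = right[:best]
    return TsdCall(seq, best, best == CANONICAL_TSD_LEN)


def tsd_rate(calls: list[TsdCall]) -> tuple[float, dict[int, int]]:
    """Fraction of canonical 8-bp duplications and a length histogram."""
    if not calls:
        raise EmptyInputError("tsd_rate needs at least one call")
    frac = sum(c.canonical for c in calls) / len(calls)
    hist = dict(sorted(Counter(c.tsd_len for c in calls).items()))
    return frac, hist
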