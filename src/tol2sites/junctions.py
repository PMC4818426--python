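"""Junction-read parsing and mapping onto the circular target.

A junction record spans the boundary between a transposon end and the
flanking target DNA.  Processing is exact-match only: the terminal is
located by exact search (allowing 5' truncation of the terminal), and
the flank is anchored on the plasmid by exact search of its
element-proximal bases against the doubled sequence (circularity) and
its reverse complement.  Records that fail are classified, never
silently dropped: every input record ends up as part of a called event
or in exactly one reject category.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    ChimericJunctionError,
    DiscordantJunctionPairError,
    InvalidArgumentError,
    UnmappedFlankError,
    UnparseableJunctionError,
)
from .events import InsertionEvent
from .plasmid import TargetPlasmid, revcomp
from .tsd import detect_tsd

_JUNCTION_ALPHABET = set("ACGTN")


@dataclass(frozen=True)
class JunctionRecord:
    """One raw junction read awaiting parsing."""

    id: str
    sequence: str
    side: str = "unknown"  # left | right | unknown (informative only)
    experiment: str = "exp1"

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not self.sequence:
            raise InvalidArgumentError("junction sequence must be non-empty")
        if set(self.sequence) - _JUNCTION_ALPHABET:
            raise InvalidArgumentError("junction sequence restricted to A,C,G,T,N")

    @property
    def pair_id(self) -> str:
        return self.id.rsplit("|", 1)[0] if "|" in self.id else self.id


@dataclass(frozen=True)
class FlankMapping:
    """A target flank anchored on the plasmid.

    ``position`` is the plus-strand coordinate of the flank base
    adjacent to the transposon; ``strand`` the strand the flank read
    matched; ``proximal`` records which end of the flank string abuts
    the element ('end' for left junctions, 'start' for right).
    """

    junction_id: str
    position: int
    strand: str
    match_len: int
    ambiguous: bool
    flank: str = field(repr=False, default="")
    proximal: str = "start"


def parse_junction(record, ends, min_terminal_match: int = 14) -> tuple[str, str]:
    """Locate a transposon terminal in the record and return (side, flank).

    The terminal may be 5'-truncated down to ``min_terminal_match``
    exact bases.  A terminal found in forward orientation is followed by
    the flank, which is returned as-is; a terminal found as its reverse
    complement is preceded by the flank, which is returned
    reverse-complemented.  Finding both terminals raises
    ChimericJunctionError; finding neither, UnparseableJunctionError.
    """
    if min_terminal_match < 12:
        raise InvalidArgumentError("min_terminal_match must be >= 12")
    seq = record.sequence.upper()
    hits = {}
    for side, terminal in (("left", ends.left_terminal), ("right", ends.right_terminal)):
        terminal = terminal.upper()
        if len(terminal) < min_terminal_match:
            raise InvalidArgumentError("terminal shorter than min_terminal_match")
        hit = _find_terminal(seq, terminal, min_terminal_match)
        if hit is not None:
            hits[side] = hit
    if not hits:
        raise UnparseableJunctionError(
            f"{record.id}: no terminal with >= {min_terminal_match} exact bases"
        )
    if len(hits) == 2:
        raise ChimericJunctionError(f"{record.id}: both terminals present")
    (side, (form, i, k)), = hits.items()
    flank = seq[i + k :] if form == "fwd" else revcomp(seq[:i])
    return side, flank


def _find_terminal(seq: str, terminal: str, min_match: int):
    """Longest exact occurrence of the terminal's outer end (or its
    reverse complement) within ``seq``; None if below ``min_match``."""
    for k in range(len(terminal), min_match - 1, -1):
        i = seq.find(terminal[-k:])  # forward: flank follows the terminal 3' end
        if i != -1:
            return ("fwd", i, k)
        i = seq.find(revcomp(terminal[-k:]))  # revcomp: flank precedes it
        if i != -1:
            return ("rc", i, k)
    return None


def map_flank(
    flank: str,
    plasmid: TargetPlasmid,
    min_anchor: int = 16,
    proximal: str = "start",
    junction_id: str = "",
) -> FlankMapping:
    """Anchor a flank on the circular plasmid by exact substring search.

    The anchor is the ``min_anchor`` flank bases nearest the transposon
    (the start of the flank string for right junctions, the end for
    left junctions).  The anchor is searched in the doubled plasmid
    sequence and its reverse complement; a unique hit yields the
    mapping, multiple hits set ``ambiguous`` and report the
    lowest-coordinate one, no hit raises UnmappedFlankError.
    """
    if proximal not in ("start", "end"):
        raise InvalidArgumentError("proximal must be 'start' or 'end'")
    flank = flank.upper()
    a = min_anchor
    if a < 1 or a > len(plasmid):
        raise InvalidArgumentError("min_anchor must be in [1, plasmid length]")
    if len(flank) < a:
        raise InvalidArgumentError("flank shorter than min_anchor")
    anchor = flank[:a] if proximal == "start" else flank[-a:]
    if "N" in anchor:
        raise UnmappedFlankError(f"{junction_id}: anchor contains N")

    L = len(plasmid)
    doubled = plasmid.doubled
    palindrome = revcomp(anchor) == anchor
    hits: list[tuple[int, str, int]] = []  # (proximal position, strand, hit start)
    for s in _find_all(doubled, anchor, L):
        pos = s % L if proximal == "start" else (s + a - 1) % L
        hits.append((pos, "+", s))
    if not palindrome:
        for s in _find_all(doubled, revcomp(anchor), L):
            pos = (s + a - 1) % L if proximal == "start" else s % L
            hits.append((pos, "-", s))
    if not hits:
        raise UnmappedFlankError(f"{junction_id}: anchor has no exact hit on the target")
    hits.sort(key=lambda h: (h[0], h[1]))
    pos, strand, _ = hits[0]
    ambiguous = len(hits) > 1 or palindrome
    return FlankMapping(
        junction_id=junction_id,
        position=pos,
        strand=strand,
        match_len=_extended_match(flank, plasmid, pos, strand, proximal),
        ambiguous=ambiguous,
        flank=flank,
        proximal=proximal,
    )


def _find_all(haystack: str, needle: str, limit: int) -> list[int]:
    """Start offsets < limit of every occurrence of needle in haystack."""
    out, i = [], haystack.find(needle)
    while i != -1 and i < limit:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def _extended_match(flank: str, plasmid: TargetPlasmid, pos: int, strand: str, proximal: str) -> int:
    """Contiguous matching bases from the proximal end of the flank."""
    n = min(len(flank), len(plasmid))
    flank = flank[-n:] if proximal == "end" else flank[:n]
    if strand == "+":
        window = plasmid.fetch(pos, n) if proximal == "start" else plasmid.fetch(pos - n + 1, n)
    else:
        window = (
            revcomp(plasmid.fetch(pos - n + 1, n))
            if proximal == "start"
            else revcomp(plasmid.fetch(pos, n))
        )
    if proximal == "start":
        pairs = zip(flank, window)
    else:
        pairs = zip(reversed(flank), reversed(window))
    m = 0
    for x, y in pairs:
        if x != y:
            break
        m += 1
    return m


def call_insertion(
    left: FlankMapping,
    right: FlankMapping,
    plasmid: TargetPlasmid,
    max_tsd: int = 12,
    experiment: str = "exp1",
    event_id: str | None = None,
) -> InsertionEvent:
    """Combine a left/right flank-mapping pair into one insertion event.

    Orientation follows the strand pair ('+','+' -> '+'; '-','-' ->
    '-'); the duplication length is fixed by the mapped positions and
    must be reproduced by the sequence overlap of the two plus-strand
    flanks for the event to be canonical.  Strand-discordant pairs, or
    pairs whose positions imply a duplication longer than ``max_tsd``,
    raise DiscordantJunctionPairError.
    """
    L = len(plasmid)
    if left.strand != right.strand:
        raise DiscordantJunctionPairError(
            f"{left.junction_id}/{right.junction_id}: flanks on opposite strands"
        )
    orientation = left.strand
    if orientation == "+":
        up, down = left, right
        up_flank, down_flank = left.flank, right.flank
    else:
        up, down = right, left
        up_flank, down_flank = revcomp(right.flank), revcomp(left.flank)
    k_pos = (up.position - down.position + 1) % L
    if k_pos > max_tsd:
        raise DiscordantJunctionPairError(
            f"{left.junction_id}/{right.junction_id}: positions imply a "
            f"{k_pos}-bp duplication (> max_tsd={max_tsd})"
        )
    seq_call = detect_tsd(up_flank, down_flank, max_len=max_tsd)
    tsd_seq = plasmid.fetch(down.position, k_pos)
    canonical = k_pos == 8 and seq_call.tsd_len >= k_pos
    return InsertionEvent(
        event_id=event_id or left.junction_id.rsplit("|", 1)[0],
        position=down.position,
        orientation=orientation,
        tsd_seq=tsd_seq,
        tsd_len=k_pos,
        canonical=canonical,
        experiment=experiment,
    )


def process_junctions(
    records: Sequence[JunctionRecord],
    plasmid: TargetPlasmid,
    ends,
    min_terminal_match: int = 14,
    min_anchor: int = 16,
    max_tsd: int = 12,
) -> tuple[list[InsertionEvent], list[tuple[str, str]], Counter]:
    """Parse, map and pair a batch of junction records.

    Returns (events, rejects, accounting): ``rejects`` holds
    (record id, reason) with reasons in {unparseable, chimeric,
    unmapped, ambiguous, discordant, unpaired}; ``accounting`` counts
    records per outcome and satisfies
    ``accounting.total() == len(records)``.
    """
    mapped: dict[str, dict[str, FlankMapping]] = {}
    meta: dict[str, JunctionRecord] = {}
    rejects: list[tuple[str, str]] = []
    rejected_pairs: set[str] = set()

    for rec in records:
        meta[rec.pair_id] = rec
        try:
            side, flank = parse_junction(rec, ends, min_terminal_match)
            m = map_flank(
                flank,
                plasmid,
                min_anchor=min_anchor,
                proximal="end" if side == "left" else "start",
                junction_id=rec.id,
            )
        except UnparseableJunctionError:
            rejects.append((rec.id, "unparseable"))
            rejected_pairs.add(rec.pair_id)
            continue
        except ChimericJunctionError:
            rejects.append((rec.id, "chimeric"))
            rejected_pairs.add(rec.pair_id)
            continue
        except (UnmappedFlankError, InvalidArgumentError):
            rejects.append((rec.id, "unmapped"))
            rejected_pairs.add(rec.pair_id)
            continue
        if m.ambiguous:
            rejects.append((rec.id, "ambiguous"))
            rejected_pairs.add(rec.pair_id)
            continue
        mapped.setdefault(rec.pair_id, {})[side] = m

    events: list[InsertionEvent] = []
    for pair_id, sides in mapped.items():
        if pair_id in rejected_pairs or len(sides) != 2:
            for m in sides.values():
                rejects.append((m.junction_id, "unpaired"))
            continue
        try:
            events.append(
                call_insertion(
                    sides["left"], sides["right"], plasmid, max_tsd=max_tsd,
                    experiment=meta[pair_id].experiment, event_id=pair_id,
                )
            )
        except DiscordantJunctionPairError:
            for m in sides.values():
                rejects.append((m.junction_id, "discordant"))

    accounting = Counter(reason for _, reason in rejects)
    accounting["called"] = 2 * len(events)
    return events, rejects, accounting


# ---------------------------------------------------------------------------
# FASTA I/O for junction records
# ---------------------------------------------------------------------------


def write_junctions_fasta(records: Iterable[JunctionRecord], path: str | Path) -> None:
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.id, description=f"side={r.side} experiment={r.experiment}")
        for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


def read_junctions_fasta(path: str | Path) -> list[JunctionRecord]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = dict(
            kv.split("=", 1) for kv in rec.description.split()[1:] if "=" in kv
        )
        out.append(
            JunctionRecord(
                rec.id,
                str(rec.seq),
                side=fields.get("side", "unknown"),
                experiment=fields.get("experiment", "exp1"),
            )
        )
    return out
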