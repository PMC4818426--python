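"""Insertion events and their tab-separated on-disk representation."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

EVENT_COLUMNS = ["event_id", "position", "orientation", "tsd_seq", "tsd_len", "canonical", "experiment"]


@dataclass(frozen=True)
class InsertionEvent:
    """One mapped integration of the transposon into the target.

    ``position`` is the 0-based plasmid coordinate of the first base of
    the duplicated target word (the insertion point itself when the
    duplication length is zero).  ``orientation`` '+' means the left
    transposon arm abuts the lower-coordinate flank.
    """

    event_id: str
    position: int
    orientation: str
    tsd_seq: str
    tsd_len: int
    canonical: bool
    experiment: str = "exp1"

    def __post_init__(self) -> None:
        assert self.orientation in "+-"
        assert len(self.tsd_seq) == self.tsd_len


def events_to_frame(events: list[InsertionEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [[e.event_id, e.position, e.orientation, e.tsd_seq, e.tsd_len, e.canonical, e.experiment]
         for e in events],
        columns=EVENT_COLUMNS,
    )


def write_events(events: list[InsertionEvent], path: str | Path) -> None:
    events_to_frame(events).to_csv(path, sep="\t", index=False)


def read_events(path: str | Path) -> list[InsertionEvent]:
    df = pd.read_csv(path, sep="\t", dtype={"tsd_seq": str}, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        out.append(
            InsertionEvent(
                event_id=str(row.event_id),
                position=int(row.position),
                orientation=str(row.orientation),
                tsd_seq=str(row.tsd_seq) if row.tsd_seq else "",
                tsd_len=int(row.tsd_len),
                canonical=bool(row.canonical) if not isinstance(row.canonical, str)
                else row.canonical.lower() == "true",
                experiment=str(row.experiment),
            )
        )
    return out
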