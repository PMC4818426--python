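#!/usr/bin/env python
"""Map junction reads back onto the circular target.

Each read is split into transposon terminal + target flank, the flank
is anchored by exact search on the doubled plasmid sequence, and left/
right pairs are combined into insertion events.  Every input record is
accounted for: called, or rejected with a reason.

Reads scratch/run from 01; writes events_called.tsv, rejects.tsv.
"""

from pathlib import Path

import pandas as pd

from tol2sites import TransposonEnds, process_junctions, write_events
from tol2sites.junctions import read_junctions_fasta
from tol2sites.plasmid import read_fasta, read_gff3

RUN = Path(__file__).resolve().parent.parent / "scratch" / "run"


def main() -> None:
    target = read_fasta(RUN / "target.fa")
    target.features = read_gff3(RUN / "target.gff3", len(target))
    records = read_junctions_fasta(RUN / "junctions.fasta")
    events, rejects, accounting = process_junctions(records, target, TransposonEnds())

    write_events(events, RUN / "events_called.tsv")
    pd.DataFrame(rejects, columns=["record_id", "reason"]).to_csv(
        RUN / "rejects.tsv", sep="\t", index=False
    )

    print(f"records in: {len(records)}")
    for reason, n in sorted(accounting.items()):
        print(f"  {reason}: {n}")
    print(f"events called: {len(events)} "
          f"(conservation: {sum(accounting.values())} == {len(records)})")


if __name__ == "__main__":
    main()
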