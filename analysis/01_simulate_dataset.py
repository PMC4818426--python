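#!/usr/bin/env python
"""Generate the synthetic study dataset: a 4-kb circular target plasmid
with a 64 %-AT SV40 polyA segment, four independent integration
experiments of 125 biased insertions each, and the paired junction
reads the mapping stages consume.

Writes scratch/run/{target.fa,target.gff3,target.bed,events_truth.tsv,junctions.fasta}.
"""

from pathlib import Path

from tol2sites import (
    BiasModel, TransposonEnds, emit_junction_reads, make_target_plasmid,
    simulate_experiments, write_events,
)
from tol2sites.junctions import write_junctions_fasta
from tol2sites.pipeline import DEFAULT_FEATURE_SPEC, stage_seed
from tol2sites.plasmid import write_bed, write_fasta, write_gff3

SEED = 42
OUT = Path(__file__).resolve().parent.parent / "scratch" / "run"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    target = make_target_plasmid(
        4000, [tuple(r) for r in DEFAULT_FEATURE_SPEC], seed=stage_seed(SEED, "plasmid")
    )
    write_fasta(target, OUT / "target.fa")
    write_gff3(target, OUT / "target.gff3")
    write_bed(target, OUT / "target.bed")

    bias = BiasModel()  # beta_at=8, window=51, tsd_fidelity=0.86
    events = simulate_experiments(target, 125, 4, bias, stage_seed(SEED, "events"))
    write_events(events, OUT / "events_truth.tsv")
    reads = emit_junction_reads(events, target, TransposonEnds(), flank_len=24)
    write_junctions_fasta(reads, OUT / "junctions.fasta")

    print(f"target plasmid: {len(target)} bp, {len(target.features)} features")
    print(f"simulated {len(events)} events across 4 experiments "
          f"-> {len(reads)} junction records")
    print(f"run data in {OUT}")


if __name__ == "__main__":
    main()
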