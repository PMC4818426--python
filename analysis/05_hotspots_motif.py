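#!/usr/bin/env python
"""Hotspots, integration-site motif and AT context.

Hotspots are positions recovered in more than one experiment (any
orientation) or in both orientations within one experiment.  The motif
is the 14-position base-count matrix over canonical insertion sites
(3 bp context + 8-bp duplicated word + 3 bp context); on an unpatterned
synthetic target its consensus is expected to be near-degenerate, while
the AT contrast (site windows vs plasmid background) captures the
generator's AT preference.

Writes results/hotspots.bed, results/motif_counts.tsv, results/consensus.txt.
"""

from pathlib import Path

from tol2sites import (
    REFERENCE_CONSENSUS, at_enrichment, build_motif, call_hotspots, read_events,
)
from tol2sites.stats import write_hotspots_bed
from tol2sites.plasmid import read_fasta, read_gff3

ROOT = Path(__file__).resolve().parent.parent / "results"
RUN = Path(__file__).resolve().parent.parent / "scratch" / "run"


def main() -> None:
    target = read_fasta(RUN / "target.fa")
    target.features = read_gff3(RUN / "target.gff3", len(target))
    events = read_events(RUN / "events_called.tsv")

    hotspots = call_hotspots(events)
    write_hotspots_bed(hotspots, target.name, ROOT / "hotspots.bed")
    by_rule = {}
    for h in hotspots:
        by_rule[h.rule_fired] = by_rule.get(h.rule_fired, 0) + 1
    print(f"hotspots: {len(hotspots)} ({by_rule})")

    motif = build_motif(events, target)
    motif.to_frame().to_csv(ROOT / "motif_counts.tsv", sep="\t")
    (ROOT / "consensus.txt").write_text(motif.consensus + "\n")
    print(f"motif: n_sites = {motif.n_sites}, skipped (non-canonical) = {motif.n_skipped}")
    print(f"  consensus:  {motif.consensus}")
    print(f"  soft:       {motif.soft_consensus}")
    print(f"  reference:  {REFERENCE_CONSENSUS}")

    site_at, background_at, per_feature = at_enrichment(events, target, window=51)
    print(f"AT context: site windows {site_at:.3f} vs background {background_at:.3f}")
    for name, at in per_feature.items():
        print(f"  {name}: {at:.3f}")


if __name__ == "__main__":
    main()
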