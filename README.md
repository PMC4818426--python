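# tol2sites

Analysis of **Tol2 transposon integration sites** on a circular plasmid
target: from transposon–target junction sequences to mapped insertion
events, target-site-duplication (TSD) calls, a Monte Carlo test of
integration bias over annotated features, insertion "hotspots", and the
integration-site consensus motif.

Tol2 is a *hAT*-superfamily DNA transposon widely used for vertebrate
transgenesis (most prominently in zebrafish). Transposase-mediated
integration leaves a diagnostic signature: an **8-bp duplication of the
target word** flanking the inserted element. In an in vitro target-joining
assay, insertions into an ampicillin-resistant target plasmid are recovered
as Kan⁺ colonies, both junctions are sequenced, and the insertion map is
tested for non-randomness — Tol2 prefers AT-rich sequence such as an SV40
polyA segment (AT content 64 %).

The package is written for people analysing such junction data (or
emulating it): it includes a seeded **synthetic-data generator** so the
entire pipeline is testable end to end without archived raw reads.

## The statistics at the core

**TSD detection.** For an insertion with upstream flank *u* and downstream
flank *d* (both on the target plus strand), the duplication length is the
largest *k* ≤ 12 with suffix_k(*u*) = prefix_k(*d*); a call is *canonical*
iff *k* = 8 with identical copies.

**Feature-occupancy Monte Carlo test.** With disjoint features of lengths
ℓ₁…ℓ_m (plus an explicit "unannotated" remainder so Σp_i = 1), the null is
count vector **C** ~ Multinomial(n, p), p_i = ℓ_i / Σℓ. Significance is
empirical over 10,000 simulated draws with the add-one correction

    p_greater(i) = (1 + #{sims with C_i ≥ observed_i}) / (1 + n_sims)

and symmetrically for p_less. An exact full-enumeration tail
(`exact_multinomial_tail`) serves as an independent oracle on tiny
instances.

**Hotspots.** A position is a hotspot iff events there are recovered in ≥ 2
distinct experiments (any orientations), or in both orientations within a
single experiment.

**Motif.** Over canonical events, base counts of the 14-mer (3 bp context +
8-bp duplicated word + 3 bp context) on the insertion strand, reduced to an
IUPAC consensus and compared against the previously reported weak consensus
`TNA(C/G)TTATAA(G/C)TNA`.

## Worked example

One command runs the synthetic demonstration end to end:

```bash
tol2sites demo --outdir demo_run --seed 42
```

or step by step via the numbered drivers:

```bash
python analysis/01_simulate_dataset.py   # target + 4x125 events + junction reads
python analysis/02_map_junctions.py      # parse, map, pair -> called events
python analysis/03_tsd_rates.py          # TSD worked example + canonical rate
python analysis/04_feature_bias.py       # occupancy + Monte Carlo test
python analysis/05_hotspots_motif.py     # hotspots, motif, AT context
python analysis/06_assay_metrics.py      # colony-ratio and founder arithmetic
```

With the default seed (42) the run prints:

```
records in: 1000
events called: 500 (conservation: 1000 == 1000)
synthetic run (n = 500): canonical fraction 0.844 (configured fidelity 0.86)

   feature  observed  expected  p_greater   p_less
sv40_polyA       118      50.0   0.000100 1.000000
      ampR       109     125.0   0.957104 0.052495
       ori        60      75.0   0.974603 0.033397
  backbone       213     250.0   0.999500 0.000600

hotspots: 36 ({'multi-experiment': 30, 'bidirectional-within-experiment': 6})
AT context: site windows 0.566 vs background 0.514
```

Reading: all 1000 junction records are accounted for and every simulated
event is recovered; the canonical-TSD fraction (0.844) sits within
sampling error of the generator's fidelity (0.86); the AT-rich SV40 polyA
segment captures 118 insertions against a length-proportional expectation
of 50 (p_greater = 1/10001, the resolution floor of the corrected test —
i.e. < 0.0001); and insertion sites sit in AT-richer context (0.566) than
the plasmid background (0.514). The motif consensus on this unpatterned
random target is degenerate (`NNNNNNNNNNNNNN`), as it should be — a
sequence preference only emerges when one is planted (see the motif tests).

The TSD worked example runs on eight published germline insertion sites
cloned from transgenic zebrafish; every flank pair yields an 8-bp
duplication (e.g. site 1: `CAAGCAAC`).

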