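# Methods

## Coordinate conventions

All coordinates are 0-based, half-open and reduced mod the plasmid length
L; features may wrap the origin (`end <= start`), with length
`(end − start) mod L` (L itself for a full-circle feature). The *insertion
position* of an event is the coordinate of the first base of the 8-bp
target word that becomes duplicated; for a blunt (0-bp) joint it is the
insertion point itself. Orientation `+` means the transposon left arm
abuts the lower-coordinate flank. In flat files, wrapped features are
written with `end > L` (GFF3 gets `Is_circular=true`), the common
convention for circular replicons, and reduced mod L on read.

## Synthetic-data generator

The generator emulates the statistical structure of an in vitro plasmid
target-joining assay: insertions into a circular target with a preference
for AT-rich sequence, both orientations, 8-bp duplications with imperfect
canonical fidelity, and several independent experiments.

**Target plasmid.** `make_target_plasmid` tiles features in order from
position 0; each feature's sequence is a seeded permutation containing
exactly `round(AT · len)` A/T bases, so realized AT content matches its
target up to rounding (the default layout includes a 10 %-of-length
segment at AT 0.64, emulating an SV40 polyA region, over a 50 %-AT
backbone).

**Position bias.** Per-position sampling weight
`w(p) ∝ exp(beta_at · AT(p))`, where `AT(p)` is the AT fraction of the
circular window (default 51 bp, odd so it is centred) around p, optionally
multiplied by a 14-position log-odds motif term. `beta_at = 0` with no
motif gives the uniform model — exactly the null the Monte Carlo test
simulates. The default `beta_at = 8` is a calibration choice (no
generative bias model is reported for the observed preference); it yields
roughly a 3-fold per-position weight ratio between 64 %-AT and 50 %-AT
sequence and a clearly non-random map at a few hundred events. The window
of 51 bp is the same scale used for AT-context summaries.

**TSD fidelity.** With probability `tsd_fidelity` (default 0.86, the
observed in vitro canonical rate) an event duplicates the 8-mer starting
at its position; otherwise the duplication length is drawn uniformly from
{0..7, 9, 10} (the structure of non-canonical junctions is not reported;
this choice makes them countable at every length without inventing
mismatch structure). Duplication copies are always identical — the
generator does not model mismatched copies or sequencing error.

**Junction reads.** Each event emits two records, `terminal + flank`
(left and right arm; terminals default to the outermost 20 bp of each
arm, which are also the miniTol2 PCR primer sequences, arms 261/192 bp).
The flank is written reading away from the element: for `+` events the
left flank is the plus-strand window ending with the duplicated word and
the right flank the window beginning with it; for `−` events the arms
swap junctions and the flanks are reverse complements of the opposite
windows. This is a package-defined read layout (real LM-PCR reads vary in
primer placement and strand); the parser accepts the terminal in either
orientation, so externally produced records in either sense parse the
same way. Flanks default to 24 bp (≥ 12 is required so the TSD search
window is always covered) and wrap the origin without truncation.

## Junction processing

Exact matching throughout — on plasmid-scale targets exact 16-bp anchors
are effectively unique, and avoiding mismatch alignment keeps the mapping
auditable. The terminal may be 5'-truncated down to `min_terminal_match`
(default 14: the two arms share their first 12 bp, so 14 is the smallest
comfortable discriminating length). Flanks are anchored by their
`min_anchor` (default 16) element-proximal bases against the doubled
plasmid sequence and its reverse complement; multiple hits (or a
palindromic anchor) are flagged ambiguous, reported with the
lowest-coordinate hit, and excluded from all statistics. Anchors
containing N cannot match and are rejected.

Pairing: the duplication length is fixed by the two mapped positions,
`k = (pos_up − pos_down + 1) mod L`, and must be reproduced by the
sequence overlap of the plus-strand flanks for the event to be canonical;
strand-discordant pairs or `k > max_tsd` (default 12) raise a discordant
error. Every record is accounted for in exactly one outcome — called,
unparseable, chimeric, unmapped, ambiguous, discordant, or unpaired (a
record whose mate was itself rejected or absent) — and batch totals are
reported, since real junction datasets routinely lose a substantial
minority of reads between sequencing and mapping.

## Occupancy statistics

`feature_occupancy` requires disjoint features and adds an explicit
`unannotated` pseudo-feature for uncovered length, so the
length-proportional multinomial is proper (probabilities sum to 1).
Boundary events belong to the following feature (half-open intervals).

`monte_carlo_bias_test` draws `n_sims` (default 10,000) multinomial
vectors and reports both one-sided empirical p-values per feature with
the add-one correction `(1 + hits)/(1 + n_sims)`, so p ∈ (0, 1] and the
smallest reportable value at 10,000 draws is 1/10001 ≈ 0.0001. Both
sides are reported rather than folded into a two-sided value, leaving the
directional reading to the analyst. `exact_multinomial_tail` enumerates
all count vectors (feasible for n ≤ 12, ≤ 4 features) as an independent
oracle; tests additionally cross-check the enumeration against the
closed-form binomial marginal.

**Null calibration.** The empirical p-value is discrete: with n = 75
events over four equal features the focal count is Binomial(75, ¼),
whose largest atom is ≈ 0.106, so the p-value lattice has steps of that
size and the Kolmogorov–Smirnov distance of even a perfectly calibrated
p-value sample from the *continuous* uniform has a deterministic floor
near 0.1 (and KS sampling noise alone has median 0.83/√R ≈ 0.059 at
R = 200 replicates). Calibration is therefore verified against the exact
discrete null — a chi-square goodness-of-fit of replicate null counts
against the Binomial(75, ¼) marginal, and the MC-vs-enumeration bound
above — rather than by a small-sample KS distance to U(0,1).

## Hotspots

A hotspot is an exact position (first TSD base) with events from ≥ 2
experiments, or from both orientations within one experiment — repeated
recovery that position-level uniform chance makes unlikely, orientation
serving as an independence witness within an experiment. A `tolerance`
parameter (default 0) optionally groups positions within ±k bp before
applying the rules (grouping is linear in coordinates; groups do not
merge across the origin). Results are invariant to event order and to
experiment relabeling.

## Motif and AT context

The motif accumulates base counts of the 14-mer centred on the duplicated
word (3 + 8 + 3), reverse-complemented for `−` events, over canonical
events only (others are counted as skipped — a non-8-bp duplication has
no well-defined 14-mer frame). Consensus per column: the top base if its
frequency ≥ 0.8; a two-base IUPAC code if the top two jointly reach 0.8
and each ≥ 0.25; else N. A lowercase "soft" consensus marks columns whose
top base reaches the 0.5 majority threshold, as a diagnostic.
`iupac_compatible` checks column-wise set inclusion against the reference
consensus `TNASTTATAASTNA`. AT context compares the mean AT fraction of
51-bp windows centred on insertion positions with the whole-plasmid AT
fraction, plus per-feature AT content.

## Assay arithmetic

`integration_ratio` = (Kan⁺/kan_plated_fraction)/(Amp⁺/amp_plated_fraction);
plated fractions are explicit because the dilution accounting behind a
reported ratio is rarely printed. Germline frequency is rounded half-up
to integer percent (matching how founder tables are printed); category
mosaicism is the unweighted mean over founders (a weighting by clutch
size is not recoverable from printed summaries).

## Pipeline and reproducibility

Every randomized stage derives its seed as
`seed XOR crc32(stage_tag) mod (2³¹ − 1)`, so stages re-run in isolation
reproduce their output and identical configs give byte-identical
summaries. The demo configuration uses a 4,000-bp target, 4 experiments
× 125 events, fidelity 0.86, 10,000 Monte Carlo draws — sizes at which
the full pipeline and test suite run in seconds while keeping binomial
standard errors small relative to the tested tolerances.

## What the synthetic data does and does not show

The generator reproduces: AT-biased, orientation-symmetric insertion on a
circular target; imperfect canonical-TSD fidelity at the observed rate;
multi-experiment structure. It does not model: sequencing or PCR error,
chimeric molecules, mismatched duplication copies, recovery bias between
colonies, target-site sequence specificity beyond the optional motif
term, or chromatin/flexibility effects. Passing round-trip tests
therefore demonstrates the pipeline's correctness on clean junctions and
the statistics' calibration under the stated models — not robustness to
noisy real-world reads, which exact-match anchoring would route to the
reject categories rather than miscall.

## Known limitations

- Exact matching only; a single sequencing error in an anchor rejects the
  record (by design, surfaced in the accounting).
- Hotspot grouping with tolerance > 0 does not merge across the origin.
- The motif consensus rule is frequency-threshold based, not
  information-theoretic; counts are exported for logo tools.
- `exact_multinomial_tail` is deliberately limited to tiny instances.
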