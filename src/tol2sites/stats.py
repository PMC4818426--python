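"""Feature-occupancy statistics, hotspots and the integration-site motif.

The central test asks whether insertions distribute over the plasmid's
annotated features in proportion to feature length.  Under that null
the per-feature counts are multinomial with p_i = length_i / L_total;
significance is assessed empirically by Monte Carlo simulation of the
multinomial (the procedure the assay's field uses), with an exact
enumeration of small instances serving as an independent oracle.
"""

from __future__ import annotations

import itertools
import math
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    AmbiguousAnnotationError,
    EmptyInputError,
    InvalidArgumentError,
    UnsupportedSizeError,
)
from .events import InsertionEvent
from .plasmid import TargetPlasmid, at_fraction, revcomp

#: Previously reported weak integration-site consensus (3 bp of context,
#: the 8-bp duplicated word, 3 bp of context); S = C or G.
REFERENCE_CONSENSUS = "TNASTTATAASTNA"

MOTIF_FLANK = 3
MOTIF_WIDTH = 2 * MOTIF_FLANK + 8  # 14

_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S", frozenset("AT"): "W",
    frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D", frozenset("ACT"): "H", frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}
_IUPAC_SETS = {v: set(k) for k, v in _IUPAC.items()}


# ---------------------------------------------------------------------------
# Occupancy
# ---------------------------------------------------------------------------


@dataclass
class OccupancyTable:
    """Observed insertion counts per (disjoint) feature."""

    names: list[str]
    lengths: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=int)
        self.counts = np.asarray(self.counts, dtype=int)
        if np.any(self.lengths < 1):
            raise InvalidArgumentError("feature lengths must be >= 1")
        if np.any(self.counts < 0):
            raise InvalidArgumentError("counts must be >= 0")

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    @property
    def probabilities(self) -> np.ndarray:
        return self.lengths / self.lengths.sum()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"feature": self.names, "length": self.lengths, "observed": self.counts})


def feature_occupancy(events: list[InsertionEvent], plasmid: TargetPlasmid) -> OccupancyTable:
    """Count events per feature; uncovered plasmid length becomes an
    explicit "unannotated" feature so the multinomial is proper.

    Feature intervals are half-open, so an event at a feature's end
    coordinate belongs to the following feature.  Overlapping features
    raise AmbiguousAnnotationError (the length-proportional probability
    model requires a disjoint partition).
    """
    L = len(plasmid)
    owner = np.full(L, -1, dtype=int)
    for idx, f in enumerate(plasmid.features):
        cells = f.positions(L)
        if np.any(owner[cells] != -1):
            raise AmbiguousAnnotationError(f"feature {f.name} overlaps another feature")
        owner[cells] = idx

    names = [f.name for f in plasmid.features]
    lengths = [f.length(L) for f in plasmid.features]
    uncovered = int(np.sum(owner == -1))
    unannotated_idx = None
    if uncovered:
        unannotated_idx = len(names)
        names = names + ["unannotated"]
        lengths = lengths + [uncovered]

    counts = np.zeros(len(names), dtype=int)
    for ev in events:
        idx = owner[ev.position % L]
        counts[idx if idx != -1 else unannotated_idx] += 1
    return OccupancyTable(names, np.array(lengths), counts)


# ---------------------------------------------------------------------------
# Monte Carlo bias test and its exact small-instance oracle
# ---------------------------------------------------------------------------


@dataclass
class MonteCarloResult:
    """Per-feature empirical one-sided p-values with simulation metadata.

    p_greater (p_less) is the add-one-corrected fraction of simulated
    multinomial draws whose count for the feature is >= (<=) the
    observed count, so p is always in (0, 1].
    """

    names: list[str]
    observed: np.ndarray
    expected: np.ndarray
    p_greater: np.ndarray
    p_less: np.ndarray
    n_sims: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.names,
                "observed": self.observed,
                "expected": self.expected,
                "p_greater": self.p_greater,
                "p_less": self.p_less,
            }
        )

    def p_for(self, name: str) -> tuple[float, float]:
        i = self.names.index(name)
        return float(self.p_greater[i]), float(self.p_less[i])


def monte_carlo_bias_test(
    occupancy: OccupancyTable, n_sims: int = 10_000, seed: int = 0
) -> MonteCarloResult:
    """Empirical test of length-proportional occupancy.

    Draws ``n_sims`` multinomial vectors of ``n_total`` counts with
    p_i = length_i / total length and reports, per feature, how often
    the simulated count is at least (at most) the observed one, with
    the add-one correction (1 + hits) / (1 + n_sims).
    """
    if n_sims < 1:
        raise InvalidArgumentError("n_sims must be >= 1")
    n = occupancy.n_total
    if n == 0:
        raise EmptyInputError("occupancy table has no observations")
    rng = np.random.default_rng(seed)
    p = occupancy.probabilities
    sims = rng.multinomial(n, p, size=n_sims)
    obs = occupancy.counts
    p_greater = (1 + (sims >= obs).sum(axis=0)) / (1 + n_sims)
    p_less = (1 + (sims <= obs).sum(axis=0)) / (1 + n_sims)
    return MonteCarloResult(
        names=list(occupancy.names),
        observed=obs.copy(),
        expected=n * p,
        p_greater=p_greater,
        p_less=p_less,
        n_sims=n_sims,
        seed=seed,
    )


def exact_multinomial_tail(occupancy: OccupancyTable, feature: str) -> float:
    """Exact P(count_feature >= observed) under the length-proportional
    multinomial, by full enumeration of count vectors.

    Only feasible for tiny instances (n_total <= 12, <= 4 features);
    exists as an independent oracle for the Monte Carlo test.
    """
    n = occupancy.n_total
    k = len(occupancy.names)
    if n > 12 or k > 4:
        raise UnsupportedSizeError("exact enumeration limited to n_total <= 12 and <= 4 features")
    if feature not in occupancy.names:
        raise InvalidArgumentError(f"unknown feature {feature!r}")
    f = occupancy.names.index(feature)
    obs = int(occupancy.counts[f])
    p = occupancy.probabilities
    total = 0.0
    for cuts in itertools.combinations(range(n + k - 1), k - 1):
        counts = np.diff([-1, *cuts, n + k - 1]) - 1
        if counts[f] < obs:
            continue
        coef = math.factorial(n)
        for c in counts:
            coef //= math.factorial(int(c))
        total += coef * float(np.prod(p**counts))
    return min(total, 1.0)


# ---------------------------------------------------------------------------
# Hotspots
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Hotspot:
    """An insertion position supported by independent recovery: seen in
    more than one experiment, or in both orientations within one."""

    position: int
    supporting: tuple[tuple[str, str], ...]  # (experiment, orientation)
    rule_fired: str  # multi-experiment | bidirectional-within-experiment


def call_hotspots(events: list[InsertionEvent], tolerance: int = 0) -> list[Hotspot]:
    """Positions qualifying as hotspots, sorted by coordinate.

    A location is a hotspot iff events there occur in >= 2 distinct
    experiments (any orientations) or, within a single experiment, in
    both orientations.  With ``tolerance`` > 0, positions within
    ``tolerance`` bp of each other are grouped into one location
    (reported at the group's lowest coordinate).
    """
    if tolerance < 0:
        raise InvalidArgumentError("tolerance must be >= 0")
    by_pos: dict[int, list[InsertionEvent]] = defaultdict(list)
    for ev in events:
        by_pos[ev.position].append(ev)

    groups: list[tuple[int, list[InsertionEvent]]] = []
    if tolerance == 0:
        groups = [(pos, evs) for pos, evs in sorted(by_pos.items())]
    else:
        current: list[int] = []
        for pos in sorted(by_pos):
            if current and pos - current[-1] > tolerance:
                groups.append((current[0], [e for p in current for e in by_pos[p]]))
                current = []
            current.append(pos)
        if current:
            groups.append((current[0], [e for p in current for e in by_pos[p]]))

    hotspots = []
    for pos, evs in groups:
        if len(evs) < 2:
            continue
        experiments = {e.experiment for e in evs}
        rule = None
        if len(experiments) >= 2:
            rule = "multi-experiment"
        else:
            orientations = {e.orientation for e in evs}
            if orientations == {"+", "-"}:
                rule = "bidirectional-within-experiment"
        if rule is None:
            continue
        support = tuple(sorted((e.experiment, e.orientation) for e in evs))
        hotspots.append(Hotspot(pos, support, rule))
    return hotspots


def write_hotspots_bed(hotspots: list[Hotspot], plasmid_name: str, path) -> None:
    lines = [
        f"{plasmid_name}\t{h.position}\t{h.position + 1}\thotspot_{h.rule_fired}\t{len(h.supporting)}\t."
        for h in hotspots
    ]
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# Integration-site motif
# ---------------------------------------------------------------------------


@dataclass
class Motif:
    """Base counts over the 14-position integration site (3 bp of
    upstream context, the 8-bp duplicated word, 3 bp downstream)."""

    counts: np.ndarray  # 4 x 14, rows A,C,G,T
    consensus: str
    soft_consensus: str
    n_sites: int
    n_skipped: int = 0

    def to_frame(self) -> pd.DataFrame:
        cols = [f"pos{i - MOTIF_FLANK}" for i in range(MOTIF_WIDTH)]
        return pd.DataFrame(self.counts, index=list("ACGT"), columns=cols)


def build_motif(
    events: list[InsertionEvent],
    plasmid: TargetPlasmid,
    majority_threshold: float = 0.5,
    strong_threshold: float = 0.8,
) -> Motif:
    """Position-frequency matrix and IUPAC consensus of insertion sites.

    For each event with a canonical 8-bp duplication the 14-mer centred
    on the duplicated word is extracted on the event's reported strand;
    events without a canonical duplication are skipped (counted).  The
    consensus reports a base when its column frequency reaches
    ``strong_threshold``, a two-base IUPAC code when the top two bases
    jointly reach it and each exceeds 0.25, and N otherwise; a
    lowercase "soft" consensus additionally marks columns whose top
    base reaches ``majority_threshold``.
    """
    counts = np.zeros((4, MOTIF_WIDTH), dtype=int)
    row = {b: i for i, b in enumerate("ACGT")}
    n_sites = n_skipped = 0
    for ev in events:
        if not ev.canonical or ev.tsd_len != 8:
            n_skipped += 1
            continue
        word = plasmid.fetch(ev.position - MOTIF_FLANK, MOTIF_WIDTH)
        if ev.orientation == "-":
            word = revcomp(word)
        for j, b in enumerate(word):
            counts[row[b], j] += 1
        n_sites += 1

    consensus = []
    soft = []
    for j in range(MOTIF_WIDTH):
        col = counts[:, j]
        tot = col.sum()
        if tot == 0:
            consensus.append("N")
            soft.append("n")
            continue
        freq = col / tot
        order = np.argsort(freq)[::-1]
        top, second = order[0], order[1]
        if freq[top] >= strong_threshold:
            consensus.append("ACGT"[top])
        elif freq[top] + freq[second] >= strong_threshold and freq[top] >= 0.25 and freq[second] >= 0.25:
            consensus.append(_IUPAC[frozenset("ACGT"[top] + "ACGT"[second])])
        else:
            consensus.append("N")
        soft.append("ACGT"[top].lower() if freq[top] >= majority_threshold else "n")
    return Motif(counts, "".join(consensus), "".join(soft), n_sites, n_skipped)


def iupac_compatible(consensus: str, pattern: str) -> bool:
    """True if every consensus column is a refinement of the pattern
    column (its IUPAC base set is a subset; N matches anything)."""
    if len(consensus) != len(pattern):
        return False
    return all(
        _IUPAC_SETS[c.upper()] <= _IUPAC_SETS[p.upper()] or p.upper() == "N"
        for c, p in zip(consensus, pattern)
    )


# ---------------------------------------------------------------------------
# AT enrichment
# ---------------------------------------------------------------------------


def at_enrichment(
    events: list[InsertionEvent], plasmid: TargetPlasmid, window: int = 51
) -> tuple[float, float, dict[str, float]]:
    """AT context of insertion sites versus the plasmid background.

    Returns (mean AT fraction of the windows centred on insertion
    positions, whole-plasmid AT fraction, per-feature AT fractions).
    """
    if window < 1 or window % 2 == 0:
        raise InvalidArgumentError("window must be an odd integer >= 1")
    half = window // 2
    site_at = (
        float(np.mean([at_fraction(plasmid.fetch(ev.position - half, window)) for ev in events]))
        if events
        else float("nan")
    )
    per_feature = {
        f.name: at_fraction(plasmid.feature_sequence(f)) for f in plasmid.features
    }
    return site_at, plasmid.at_fraction(), per_feature
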