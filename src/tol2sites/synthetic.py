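"""Synthetic target plasmids, biased insertion events and junction reads.

The generator reproduces the statistical structure the downstream
analysis assumes: insertion positions drawn over a circular plasmid
with an exponential preference for locally AT-rich sequence, both
insertion orientations, 8-bp target-site duplication with a
configurable canonical-duplication fidelity, and multiple independent
experiments for hotspot calling.

The default fidelity of 0.86 matches the in vitro observation that
86 % of sequenced Tol2 insertions carry the canonical 8-bp hAT
duplication; the bias strength ``beta_at`` is a calibration choice (no
generative model is reported for the observed AT preference).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import InvalidArgumentError
from .events import InsertionEvent
from .junctions import JunctionRecord
from .plasmid import Feature, TargetPlasmid, revcomp
from .tsd import CANONICAL_TSD_LEN

#: Outermost bases of the Tol2 arms (also the miniTol2 PCR primers).
LEFT_TERMINAL = "CAGAGGTGTAAAGTACTTGA"
RIGHT_TERMINAL = "CAGAGGTGTAAAAAGTACTC"
LEFT_ARM_LEN = 261
RIGHT_ARM_LEN = 192

#: Lengths a perturbed (non-canonical) duplication may take.
NONCANONICAL_TSD_LENGTHS = tuple(list(range(0, 8)) + [9, 10])


@dataclass(frozen=True)
class TransposonEnds:
    """The outermost arm sequences used to recognise junction reads."""

    left_terminal: str = LEFT_TERMINAL
    right_terminal: str = RIGHT_TERMINAL
    left_arm_len: int = LEFT_ARM_LEN
    right_arm_len: int = RIGHT_ARM_LEN

    def __post_init__(self) -> None:
        if self.left_terminal == self.right_terminal:
            raise InvalidArgumentError("left and right terminals must be distinct")


@dataclass(frozen=True)
class BiasModel:
    """Insertion-position bias: per-position weight
    w(p) ∝ exp(beta_at · AT-fraction of the window centred on p),
    optionally multiplied by a 14-position motif term.

    ``beta_at = 0`` with no motif weights gives the uniform model.
    ``tsd_fidelity`` is the probability an event carries the canonical
    8-bp duplication; otherwise its duplication length is drawn
    uniformly from {0..7, 9, 10}.
    """

    beta_at: float = 8.0
    window: int = 51
    motif_weights: np.ndarray | None = None  # 4 x 14 log-weights (A,C,G,T rows)
    tsd_fidelity: float = 0.86

    def __post_init__(self) -> None:
        if self.beta_at < 0:
            raise InvalidArgumentError("beta_at must be >= 0")
        if self.window < 1 or self.window % 2 == 0:
            raise InvalidArgumentError("window must be an odd integer >= 1")
        if not 0.0 <= self.tsd_fidelity <= 1.0:
            raise InvalidArgumentError("tsd_fidelity must be in [0, 1]")
        if self.motif_weights is not None and np.asarray(self.motif_weights).shape != (4, 14):
            raise InvalidArgumentError("motif_weights must be a 4 x 14 matrix")

    def position_weights(self, plasmid: TargetPlasmid) -> np.ndarray:
        """Normalized per-position sampling weights over [0, L)."""
        L = len(plasmid)
        log_w = self.beta_at * plasmid.local_at(self.window)
        if self.motif_weights is not None:
            w = np.asarray(self.motif_weights, dtype=float)
            base_idx = np.frombuffer(plasmid.sequence.encode(), dtype=np.uint8)
            lut = np.zeros(256, dtype=int)
            for i, b in enumerate("ACGT"):
                lut[ord(b)] = i
            rows = lut[base_idx]
            score = np.zeros(L)
            for j in range(14):
                score += w[np.roll(rows, 3 - j), :][:, j]
            log_w = log_w + score
        log_w -= log_w.max()
        weights = np.exp(log_w)
        total = weights.sum()
        if not np.isfinite(total) or total <= 0:
            raise InvalidArgumentError("degenerate bias model: weights do not normalize")
        return weights / total


def make_target_plasmid(
    length: int,
    feature_spec: Sequence[tuple[str, float, float]],
    seed: int,
    name: str = "synthetic_target",
) -> TargetPlasmid:
    """Build a circular plasmid whose features tile the sequence in order.

    ``feature_spec`` rows are (name, fraction of plasmid length,
    target AT fraction).  Each feature's sequence is a seeded random
    permutation containing exactly round(AT · len) A/T bases, so the
    realized AT fraction matches the target to within rounding; any
    length not covered by the spec is filled, unannotated, at AT 0.5.
    """
    if length < 100:
        raise InvalidArgumentError("plasmid length must be >= 100 bp")
    fracs = [f for _, f, _ in feature_spec]
    if any(f <= 0 for f in fracs):
        raise InvalidArgumentError("feature fractions must be positive")
    if sum(fracs) > 1.0 + 1e-9:
        raise InvalidArgumentError("feature fractions must sum to <= 1")
    for _, _, at in feature_spec:
        if not 0.0 <= at <= 1.0:
            raise InvalidArgumentError("AT fractions must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    pieces: list[str] = []
    features: list[Feature] = []
    cursor = 0
    for fname, frac, at in feature_spec:
        n = int(round(frac * length))
        n = min(n, length - cursor)
        pieces.append(_random_sequence(rng, n, at))
        features.append(Feature(fname, cursor, (cursor + n) % length))
        cursor += n
    if cursor < length:
        pieces.append(_random_sequence(rng, length - cursor, 0.5))
    return TargetPlasmid(name, "".join(pieces), features)


def _random_sequence(rng: np.random.Generator, n: int, at: float) -> str:
    if n == 0:
        return ""
    n_at = int(round(at * n))
    bases = np.concatenate(
        [
            rng.choice(np.array(["A", "T"]), size=n_at),
            rng.choice(np.array(["C", "G"]), size=n - n_at),
        ]
    )
    rng.shuffle(bases)
    return "".join(bases)


def simulate_insertions(
    plasmid: TargetPlasmid,
    n: int,
    bias: BiasModel,
    seed: int,
    experiment: str = "exp1",
) -> list[InsertionEvent]:
    """Draw ``n`` independent insertion events under the bias model.

    Positions are sampled from the normalized per-position weights,
    orientation is Bernoulli(1/2), and the duplicated word is the
    plasmid 8-mer starting at the position (canonical, probability
    ``tsd_fidelity``) or a perturbed-length duplication otherwise.
    """
    if n < 0:
        raise InvalidArgumentError("number of events must be >= 0")
    if n == 0:
        return []
    rng = np.random.default_rng(seed)
    weights = bias.position_weights(plasmid)
    positions = rng.choice(len(plasmid), size=n, p=weights)
    orientations = rng.choice(np.array(["+", "-"]), size=n)
    canonical = rng.random(n) < bias.tsd_fidelity
    perturbed = rng.choice(np.array(NONCANONICAL_TSD_LENGTHS), size=n)

    events = []
    for i in range(n):
        k = CANONICAL_TSD_LEN if canonical[i] else int(perturbed[i])
        pos = int(positions[i])
        events.append(
            InsertionEvent(
                event_id=f"{experiment}:e{i:05d}",
                position=pos,
                orientation=str(orientations[i]),
                tsd_seq=plasmid.fetch(pos, k),
                tsd_len=k,
                canonical=k == CANONICAL_TSD_LEN,
                experiment=experiment,
            )
        )
    return events


def simulate_experiments(
    plasmid: TargetPlasmid,
    n_per_experiment: int,
    n_experiments: int,
    bias: BiasModel,
    seed: int,
) -> list[InsertionEvent]:
    """Independent replicate experiments (labels exp1..expK) for hotspot calling."""
    rng = np.random.default_rng(seed)
    events: list[InsertionEvent] = []
    for k in range(n_experiments):
        sub = int(rng.integers(0, 2**31 - 1))
        events.extend(simulate_insertions(plasmid, n_per_experiment, bias, sub, f"exp{k + 1}"))
    return events


def emit_junction_reads(
    events: Sequence[InsertionEvent],
    plasmid: TargetPlasmid,
    ends: TransposonEnds | None = None,
    flank_len: int = 24,
) -> list[JunctionRecord]:
    """Two junction records per event: terminal sequence + target flank.

    Records are laid out as the stored terminal followed by the
    adjacent target flank read away from the element.  For a '+'
    event (left arm at the lower coordinate) the left-junction flank is
    the plus-strand window ending with the duplicated word and the
    right-junction flank the plus-strand window beginning with it; for
    a '-' event the arms swap junctions, so the flanks are the reverse
    complements of the opposite windows.  Flanks wrap the circular
    origin without truncation.
    """
    ends = ends or TransposonEnds()
    if flank_len < 12:
        raise InvalidArgumentError(
            "flank_len must be >= 12 bp (shorter flanks cannot span the TSD search window)"
        )
    records = []
    for ev in events:
        up = plasmid.fetch(ev.position + ev.tsd_len - flank_len, flank_len)
        down = plasmid.fetch(ev.position, flank_len)
        if ev.orientation == "+":
            left_flank, right_flank = up, down
        else:
            left_flank, right_flank = revcomp(down), revcomp(up)
        records.append(
            JunctionRecord(f"{ev.event_id}|L", ends.left_terminal + left_flank,
                           side="left", experiment=ev.experiment)
        )
        records.append(
            JunctionRecord(f"{ev.event_id}|R", ends.right_terminal + right_flank,
                           side="right", experiment=ev.experiment)
        )
    return records
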