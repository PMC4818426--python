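"""Circular target plasmid: sequence, features and standard-format I/O.

All coordinates in this package are 0-based, half-open and reduced
modulo the plasmid length ``L``.  A feature whose ``end`` is <= its
``start`` wraps across the origin; its length is ``(end - start) mod L``
(``L`` itself when start == end, i.e. the whole circle).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InvalidArgumentError

_ALPHABET = set("ACGT")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (N allowed)."""
    return seq.translate(_COMPLEMENT)[::-1]


def at_fraction(seq: str) -> float:
    """Fraction of A/T bases in ``seq``."""
    if not seq:
        return 0.0
    return (seq.count("A") + seq.count("T")) / len(seq)


@dataclass(frozen=True)
class Feature:
    """An annotated interval on the circular plasmid.

    ``start`` is 0-based inclusive, ``end`` 0-based exclusive; ``end``
    less than or equal to ``start`` denotes a feature wrapping the
    origin. ``strand`` is '+', '-' or '.'.
    """

    name: str
    start: int
    end: int
    strand: str = "."

    def length(self, plasmid_length: int) -> int:
        n = (self.end - self.start) % plasmid_length
        return n if n > 0 else plasmid_length

    def positions(self, plasmid_length: int) -> np.ndarray:
        """All plasmid coordinates the feature covers, in order."""
        return (self.start + np.arange(self.length(plasmid_length))) % plasmid_length

    def contains(self, pos: int, plasmid_length: int) -> bool:
        off = (pos - self.start) % plasmid_length
        return off < self.length(plasmid_length)


@dataclass
class TargetPlasmid:
    """A circular DNA target with an ordered list of annotated features."""

    name: str
    sequence: str
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise InvalidArgumentError("plasmid sequence must be non-empty")
        if set(self.sequence) - _ALPHABET:
            bad = sorted(set(self.sequence) - _ALPHABET)
            raise InvalidArgumentError(f"plasmid sequence contains non-ACGT symbols: {bad}")
        names = [f.name for f in self.features]
        if len(names) != len(set(names)):
            raise InvalidArgumentError("feature names must be unique within a plasmid")
        L = len(self.sequence)
        self.features = [
            Feature(f.name, f.start % L, f.end % L, f.strand) for f in self.features
        ]

    def __len__(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, length: int) -> str:
        """Circular subsequence of ``length`` bp starting at ``start`` (mod L)."""
        if length < 0:
            raise InvalidArgumentError("fetch length must be >= 0")
        L = len(self.sequence)
        if length > L:
            raise InvalidArgumentError("fetch length exceeds plasmid length")
        start %= L
        if start + length <= L:
            return self.sequence[start : start + length]
        return self.sequence[start:] + self.sequence[: start + length - L]

    @property
    def doubled(self) -> str:
        """Plasmid sequence concatenated with itself (circular search)."""
        return self.sequence + self.sequence

    def feature_sequence(self, feature: Feature) -> str:
        return self.fetch(feature.start, feature.length(len(self)))

    def at_fraction(self) -> float:
        return at_fraction(self.sequence)

    def local_at(self, window: int) -> np.ndarray:
        """Per-position AT fraction of the circular window centred on each base.

        ``window`` must be odd so the window is symmetric.
        """
        if window < 1 or window % 2 == 0:
            raise InvalidArgumentError("window must be an odd integer >= 1")
        L = len(self.sequence)
        window = min(window, L if L % 2 == 1 else L - 1)
        is_at = np.frombuffer(self.sequence.encode(), dtype=np.uint8)
        is_at = ((is_at == ord("A")) | (is_at == ord("T"))).astype(float)
        half = window // 2
        padded = np.concatenate([is_at[L - half :], is_at, is_at[:half]]) if half else is_at
        kernel = np.ones(window) / window
        return np.convolve(padded, kernel, mode="valid")


# ---------------------------------------------------------------------------
# File formats.  Wrapped (origin-spanning) features are serialized with an
# end coordinate beyond L, the common flat-file convention for circular
# replicons, and reduced mod L on read.
# ---------------------------------------------------------------------------


def write_fasta(plasmid: TargetPlasmid, path: str | Path) -> None:
    rec = SeqRecord(Seq(plasmid.sequence), id=plasmid.name, description="circular")
    SeqIO.write([rec], str(path), "fasta")


def read_fasta(path: str | Path, features: list[Feature] | None = None) -> TargetPlasmid:
    rec = next(SeqIO.parse(str(path), "fasta"))
    return TargetPlasmid(rec.id, str(rec.seq).upper(), list(features or []))


def write_gff3(plasmid: TargetPlasmid, path: str | Path) -> None:
    L = len(plasmid)
    lines = ["##gff-version 3", f"##sequence-region {plasmid.name} 1 {L}"]
    lines.append(
        "\t".join(
            [plasmid.name, "tol2sites", "region", "1", str(L), ".", "+", ".",
             f"ID={plasmid.name};Is_circular=true"]
        )
    )
    for f in plasmid.features:
        end = f.end if f.end > f.start else f.end + L
        lines.append(
            "\t".join(
                [plasmid.name, "tol2sites", "sequence_feature", str(f.start + 1),
                 str(end), ".", f.strand if f.strand in "+-" else ".", ".",
                 f"ID={f.name};Name={f.name}"]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path, plasmid_length: int) -> list[Feature]:
    feats = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 9 or cols[2] == "region":
            continue
        attrs = dict(kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv)
        name = attrs.get("Name", attrs.get("ID", cols[2]))
        start = (int(cols[3]) - 1) % plasmid_length
        end = int(cols[4]) % plasmid_length
        strand = cols[6] if cols[6] in "+-" else "."
        feats.append(Feature(name, start, end, strand))
    return feats


def write_bed(plasmid: TargetPlasmid, path: str | Path) -> None:
    L = len(plasmid)
    lines = []
    for f in plasmid.features:
        end = f.end if f.end > f.start else f.end + L
        strand = f.strand if f.strand in "+-" else "."
        lines.append(f"{plasmid.name}\t{f.start}\t{end}\t{f.name}\t0\t{strand}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_bed(path: str | Path, plasmid_length: int) -> list[Feature]:
    feats = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith(("#", "track", "browser")):
            continue
        cols = line.split("\t")
        name = cols[3] if len(cols) > 3 else f"feature_{len(feats)}"
        strand = cols[5] if len(cols) > 5 and cols[5] in "+-" else "."
        feats.append(
            Feature(name, int(cols[1]) % plasmid_length, int(cols[2]) % plasmid_length, strand)
        )
    return feats
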