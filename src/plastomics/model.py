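"""Core data model: circular plastome sequences, gene features, intervals.

All internal coordinates are 0-based half-open on a circular axis.  GenBank
I/O (see :mod:`plastomics.io`) converts to and from 1-based inclusive
coordinates at the boundary, so every downstream module works in a single
coordinate convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
VALID_BASES = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(seq: str) -> str:
    """Complement without reversal."""
    return seq.translate(_COMPLEMENT)


def normalize_seq(seq: str) -> str:
    """Uppercase, U->T, and collapse non-ACGTN ambiguity codes to N.

    A warning is logged when ambiguity codes are replaced.
    """
    s = seq.upper().replace("U", "T")
    if not set(s) <= VALID_BASES:
        bad = sorted(set(s) - VALID_BASES)
        log.warning("mapping ambiguity codes %s to N", "".join(bad))
        s = "".join(c if c in VALID_BASES else "N" for c in s)
    return s


@dataclass(frozen=True)
class Interval:
    """0-based half-open interval on a circle; ``wrap`` means start > end
    and the segment crosses the origin."""

    start: int
    end: int
    wrap: bool = False

    def length(self, genome_length: int) -> int:
        """Modular length; a wrap interval with start == end is the full circle."""
        n = (self.end - self.start) % genome_length
        if n == 0:
            return genome_length if self.wrap else 0
        return n

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < 0:
            raise ValueError("negative coordinate in interval")
        if not self.wrap and self.end < self.start:
            raise ValueError(
                f"non-wrapping interval with end < start: [{self.start},{self.end})"
            )

    def contains(self, pos: int, genome_length: int) -> bool:
        pos %= genome_length
        if self.wrap:
            return pos >= self.start or pos < self.end
        return self.start <= pos < self.end


def interval_length(iv: Interval, genome_length: int) -> int:
    """Modular length of a circular interval; a wrap interval with
    start == end denotes the full circle."""
    n = (iv.end - iv.start) % genome_length
    if n == 0:
        return genome_length if iv.wrap else 0
    return n


def make_interval(start: int, end: int, genome_length: int) -> Interval:
    """Build an interval, reducing coordinates mod genome length and
    setting the wrap flag automatically."""
    start %= genome_length
    end %= genome_length
    return Interval(start, end, wrap=start > end)


@dataclass
class GeneFeature:
    """A gene with one or more exons on a circular genome.

    ``exons`` are ordered [start, end) intervals in transcription order;
    individual exons may wrap the origin.  ``kind`` is one of
    {"CDS", "tRNA", "rRNA", "other"}.
    """

    name: str
    kind: str
    exons: list[Interval]
    strand: str = "+"

    KINDS = ("CDS", "tRNA", "rRNA", "other")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"feature {self.name!r} has no exons")

    @property
    def start(self) -> int:
        return min(e.start for e in self.exons)

    def intron_count(self) -> int:
        return len(self.exons) - 1

    def span(self, genome_length: int) -> Interval:
        """Smallest interval covering all exons (assumes the feature does
        not span more than half the circle, true for real plastome genes)."""
        if len(self.exons) == 1:
            return self.exons[0]
        # anchor on the first exon and take the modular hull
        a = self.exons[0].start
        lo, hi = 0, 0
        for e in self.exons:
            s = (e.start - a) % genome_length
            t = s + interval_length(e, genome_length)
            lo = min(lo, s)
            hi = max(hi, t)
        return make_interval(a + lo, a + hi, genome_length)

    def length(self, genome_length: int) -> int:
        return sum(interval_length(e, genome_length) for e in self.exons)


@dataclass
class QuadripartitePartition:
    """LSC / IRb / SSC / IRa partition of a circular plastome."""

    lsc: Interval
    irb: Interval
    ssc: Interval
    ira: Interval
    genome_length: int

    def regions(self) -> dict[str, Interval]:
        return {"LSC": self.lsc, "IRb": self.irb, "SSC": self.ssc, "IRa": self.ira}

    def region_of(self, pos: int) -> str:
        for name, iv in self.regions().items():
            if iv.contains(pos, self.genome_length):
                return name
        raise ValueError(f"position {pos} not covered by partition")

    def lengths(self) -> dict[str, int]:
        return {
            name: interval_length(iv, self.genome_length)
            for name, iv in self.regions().items()
        }

    def validate(self) -> None:
        total = sum(self.lengths().values())
        if total != self.genome_length:
            raise ValueError(
                f"partition covers {total} bp of a {self.genome_length} bp genome"
            )
        if interval_length(self.ira, self.genome_length) != interval_length(
            self.irb, self.genome_length
        ):
            raise ValueError("IR copies differ in length")


@dataclass
class Plastome:
    """A circular plastome: sequence, features, optional partition."""

    id: str
    seq: str
    circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)
    partition: Optional[QuadripartitePartition] = None
    description: str = ""

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError("empty sequence")
        self.seq = normalize_seq(self.seq)
        self.features.sort(key=lambda f: f.start)

    def __len__(self) -> int:
        return len(self.seq)

    def slice(self, iv: Interval) -> str:
        """Extract the interval's sequence, wrapping the origin if needed."""
        n = len(self.seq)
        if interval_length(iv, n) == n:
            return self.seq[iv.start :] + self.seq[: iv.start]
        if iv.wrap:
            return self.seq[iv.start :] + self.seq[: iv.end]
        return self.seq[iv.start : iv.end]

    def feature_seq(self, feat: GeneFeature) -> str:
        """Concatenated exon sequence in coding orientation."""
        s = "".join(self.slice(e) for e in feat.exons)
        return revcomp(s) if feat.strand == "-" else s

    def rotated(self, offset: int) -> "Plastome":
        """Return a copy rotated so that old coordinate ``offset`` becomes 0."""
        n = len(self.seq)
        offset %= n
        seq = self.seq[offset:] + self.seq[:offset]
        feats = []
        for f in self.features:
            exons = [
                make_interval(e.start - offset, e.end - offset, n) for e in f.exons
            ]
            feats.append(GeneFeature(f.name, f.kind, exons, f.strand))
        return Plastome(self.id, seq, self.circular, feats, None, self.description)


def circular_slice(plastome: Plastome, iv: Interval) -> str:
    """Functional alias for :meth:`Plastome.slice`."""
    return plastome.slice(iv)
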