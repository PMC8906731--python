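"""Interval arithmetic, coverage tracks, and peak AUC quantification.

All coordinates are 0-based, half-open (BED convention). A "track" is
per-base coverage over each chromosome, either raw counts or a normalized
density; AUC over an interval is the plain sum of per-base values, so it is
additive over any partition of the interval. Bases outside a track's stored
extent contribute zero rather than raising.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic span ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: [{self.start}, {self.end})")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class TagAlignment:
    """A single aligned sequencing tag (read) with its strand."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")


@dataclass
class Peak:
    """A called binding site: an interval plus summit and signal areas.

    ``auc`` is the area under the signal curve over the interval (signal*bp);
    ``background_auc`` is the same quantity measured on the matched
    background (whole-cell extract) track. The summit defaults to the
    interval midpoint when the caller has none.
    """

    interval: GenomicInterval
    summit: int | None = None
    auc: float = 0.0
    background_auc: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        if self.summit is None:
            self.summit = self.interval.midpoint
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(
                f"summit {self.summit} outside [{self.interval.start}, {self.interval.end})"
            )
        if self.auc < 0 or self.background_auc < 0:
            raise ValueError("auc and background_auc must be >= 0")

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass
class SignalTrack:
    """Dense per-base coverage vectors keyed by chromosome.

    Suitable for toy genomes up to tens of Mb; bedGraph input is expanded
    to per-base on load. ``total_mapped_reads`` is only required when a
    normalized (rpm/bp) quantity is requested.
    """

    data: dict[str, np.ndarray] = field(default_factory=dict)
    total_mapped_reads: int | None = None

    def chrom_values(self, chrom: str) -> np.ndarray:
        return self.data.get(chrom, np.zeros(0))

    def values(self, interval: GenomicInterval) -> np.ndarray:
        """Per-base values over the interval; out-of-bounds bases are 0."""
        out = np.zeros(interval.width, dtype=float)
        vec = self.data.get(interval.chrom)
        if vec is None:
            return out
        lo = max(interval.start, 0)
        hi = min(interval.end, len(vec))
        if hi > lo:
            out[lo - interval.start : hi - interval.start] = vec[lo:hi]
        return out

    def auc(self, interval: GenomicInterval) -> float:
        return peak_auc(self, interval)


def extend_reads(
    reads: list[TagAlignment], extension_bp: int = 200
) -> list[GenomicInterval]:
    """Extend each read by ``extension_bp`` in its 3' direction.

    This is the usual fragment-length surrogate for single-end ChIP tags:
    a plus-strand read grows past its end, a minus-strand read grows past
    its start (clipped at 0). Records with an unknown strand are rejected
    with a warning rather than raising.
    """
    if extension_bp < 0:
        raise ValueError("extension_bp must be >= 0")
    out: list[GenomicInterval] = []
    for read in reads:
        if read.strand == "+":
            out.append(GenomicInterval(read.chrom, read.start, read.end + extension_bp))
        elif read.strand == "-":
            out.append(
                GenomicInterval(read.chrom, max(read.start - extension_bp, 0), read.end)
            )
        else:  # only reachable for records built outside TagAlignment validation
            logger.warning("skipping read with unknown strand %r on %s", read.strand, read.chrom)
    return out


def read_density(
    reads: list[TagAlignment],
    region: GenomicInterval,
    total_mapped: int,
    extension_bp: int = 200,
) -> float:
    """Normalized read density over a region, in rpm/bp.

    Reads are 3'-extended, per-base coverage is averaged over the region,
    and the result is divided by millions of mapped reads:
    mean coverage / (total_mapped / 1e6).
    """
    if total_mapped <= 0:
        raise ValueError(f"total_mapped must be > 0 for normalization, got {total_mapped}")
    overlap = 0
    for iv in extend_reads(reads, extension_bp):
        overlap += iv.overlap_bp(region)
    coverage = overlap / region.width
    return coverage / (total_mapped / 1e6)


def reads_to_track(
    reads: list[TagAlignment],
    chrom_lengths: dict[str, int],
    extension_bp: int = 200,
    total_mapped: int | None = None,
) -> SignalTrack:
    """Pile extended reads into a dense coverage track."""
    data = {c: np.zeros(n, dtype=float) for c, n in chrom_lengths.items()}
    for iv in extend_reads(reads, extension_bp):
        vec = data.get(iv.chrom)
        if vec is None:
            continue
        lo = min(iv.start, len(vec))
        hi = min(iv.end, len(vec))
        if hi > lo:
            vec[lo:hi] += 1.0
    return SignalTrack(data=data, total_mapped_reads=total_mapped)


def peak_auc(track: SignalTrack, interval: GenomicInterval) -> float:
    """Sum of per-base track values over the interval (signal*bp)."""
    vec = track.data.get(interval.chrom)
    if vec is None:
        return 0.0
    lo = max(interval.start, 0)
    hi = min(interval.end, len(vec))
    if hi <= lo:
        return 0.0
    return float(vec[lo:hi].sum())


def background_subtracted_auc(peak: Peak) -> float:
    """Background (whole-cell extract) subtracted AUC, floored at zero.

    Negative occupancy is not meaningful, so the difference is clipped.
    """
    return max(peak.auc - peak.background_auc, 0.0)
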