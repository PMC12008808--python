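"""Core data model for single-molecule chromatin fibers and genomic annotations.

All coordinates are 0-based, half-open (BED convention) on the reference.
A :class:`Fiber` is one sequenced chromatin molecule carrying the features
called on it upstream: m6A events (MTase-stenciled accessible adenines),
MTase-protected footprints ("nucleosomes", which may also be bound-protein
footprints), MTase-sensitive patches (MSPs), and per-site CpG methylation
calls. The package consumes these features; it does not call them from raw
kinetics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np

logger = logging.getLogger("dichrom")

__all__ = [
    "DichromError",
    "ConfigError",
    "FiberValidationError",
    "FiberTableParseError",
    "FormatError",
    "GenomicInterval",
    "SatClass",
    "SatelliteAnnotation",
    "Fiber",
    "DensityTrack",
]


class DichromError(Exception):
    """Base class for package errors."""


class ConfigError(DichromError):
    """Invalid configuration or parameters."""


class FiberValidationError(DichromError):
    """A fiber violates the data-model invariants."""


class FiberTableParseError(DichromError):
    """Malformed fiber-table input; message names the offending row."""


class FormatError(DichromError):
    """A file is not in the expected format (e.g. BAM without MM/ML tags)."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    strand: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise FiberValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in (None, "+", "-", "."):
            raise FiberValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlap(self, other: "GenomicInterval") -> int:
        """Overlap length in bp (0 if disjoint or different chrom)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def intersects(self, other: "GenomicInterval") -> bool:
        return self.overlap(other) > 0


class SatClass(str, Enum):
    """Satellite annotation classes used to stratify fibers and motif scans."""

    ACTIVE_HOR = "active_hor"
    INACTIVE_HOR = "inactive_hor"
    DIVERGENT_MONOMERIC = "divergent_monomeric"
    OTHER_SATELLITE = "other_satellite"
    NON_SATELLITE = "non_satellite"


@dataclass(frozen=True)
class SatelliteAnnotation:
    interval: GenomicInterval
    sat_class: SatClass


def _check_sorted_nonoverlapping(
    intervals: Sequence[GenomicInterval], kind: str, fiber_id: str
) -> None:
    for a, b in zip(intervals, intervals[1:]):
        if b.start < a.end:
            raise FiberValidationError(
                f"fiber {fiber_id}: overlapping {kind} intervals "
                f"[{a.start},{a.end}) and [{b.start},{b.end})"
            )


@dataclass
class Fiber:
    """One sequenced chromatin molecule and its called features.

    ``m6a_positions`` is a strictly increasing int array of reference
    positions. ``nucleosomes`` and ``msps`` are sorted, internally
    non-overlapping interval lists. ``cpg_calls`` maps reference position of
    the CpG (C of the CG dinucleotide, plus strand) to a boolean methylation
    call; sites without a confident call are simply absent.
    """

    fiber_id: str
    interval: GenomicInterval
    m6a_positions: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    nucleosomes: list[GenomicInterval] = field(default_factory=list)
    msps: list[GenomicInterval] = field(default_factory=list)
    cpg_calls: dict[int, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.m6a_positions = np.asarray(self.m6a_positions, dtype=np.int64)
        self.validate()

    def validate(self) -> None:
        iv = self.interval
        pos = self.m6a_positions
        if pos.size:
            dedup = np.unique(pos)
            if dedup.size != pos.size:
                logger.warning(
                    "fiber %s: %d duplicate m6A positions removed",
                    self.fiber_id, pos.size - dedup.size,
                )
                self.m6a_positions = pos = dedup
            elif np.any(np.diff(pos) <= 0):
                self.m6a_positions = pos = np.unique(pos)
            if pos[0] < iv.start or pos[-1] >= iv.end:
                raise FiberValidationError(
                    f"fiber {self.fiber_id}: m6A position outside span "
                    f"[{iv.start},{iv.end})"
                )
        for kind, feats in (("nucleosome", self.nucleosomes), ("msp", self.msps)):
            feats.sort(key=lambda f: (f.start, f.end))
            _check_sorted_nonoverlapping(feats, kind, self.fiber_id)
            for f in feats:
                if f.start < iv.start or f.end > iv.end or f.chrom != iv.chrom:
                    raise FiberValidationError(
                        f"fiber {self.fiber_id}: {kind} [{f.start},{f.end}) "
                        f"outside span {iv.chrom}:[{iv.start},{iv.end})"
                    )
        for p in self.cpg_calls:
            if p < iv.start or p >= iv.end:
                raise FiberValidationError(
                    f"fiber {self.fiber_id}: CpG call at {p} outside span"
                )

    # -- convenience -------------------------------------------------------
    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    def spans(self, region: GenomicInterval) -> bool:
        return self.interval.contains(region)

    def copy(self) -> "Fiber":
        return Fiber(
            fiber_id=self.fiber_id,
            interval=self.interval,
            m6a_positions=self.m6a_positions.copy(),
            nucleosomes=list(self.nucleosomes),
            msps=list(self.msps),
            cpg_calls=dict(self.cpg_calls),
        )


@dataclass
class DensityTrack:
    """Per-bp feature count, molecule coverage and density over a region.

    density = feature_count / coverage where coverage > 0, NaN elsewhere.
    """

    chrom: str
    start: int
    feature_count: np.ndarray
    coverage: np.ndarray

    def __post_init__(self) -> None:
        self.feature_count = np.asarray(self.feature_count, dtype=np.int64)
        self.coverage = np.asarray(self.coverage, dtype=np.int64)
        if self.feature_count.shape != self.coverage.shape:
            raise ConfigError("feature_count and coverage must be same length")
        if np.any(self.feature_count > self.coverage):
            raise FiberValidationError("feature_count exceeds coverage")

    @property
    def end(self) -> int:
        return self.start + self.coverage.size

    @property
    def density(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            d = self.feature_count / self.coverage.astype(float)
        d[self.coverage == 0] = np.nan
        return d


def sort_fibers(fibers: Iterable[Fiber]) -> list[Fiber]:
    """Canonical fiber ordering: (chrom, start, end, fiber_id)."""
    return sorted(
        fibers, key=lambda f: (f.chrom, f.start, f.end, f.fiber_id)
    )


def subset_overlapping(
    fibers: Iterable[Fiber], region: GenomicInterval
) -> list[Fiber]:
    return [f for f in fibers if f.interval.intersects(region)]


def replace_interval(fiber: Fiber, interval: GenomicInterval) -> Fiber:
    out = fiber.copy()
    out.interval = interval
    out.validate()
    return out
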