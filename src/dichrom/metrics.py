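"""Per-fiber dichromatin metrics.

Di-nucleosome / large-accessible-patch classification (strict >210 bp and
>150 bp cutoffs), regional per-fiber summaries, patch-spacing statistics
(observed consecutive start-to-start distances vs the density-based
expected spacing), per-core patch-count estimates, and the interval-span
occupancy fraction used for point-centromere (CCAN) footprints.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .model import DichromError, Fiber, GenomicInterval

DINUC_CUTOFF = 210
LARGE_MSP_CUTOFF = 150


@dataclass
class FiberDichromatinSummary:
    fiber_id: str
    region: str
    n_nucleosomes: int
    pct_dinucleosome: float  # NaN when no nucleosomes
    n_msps: int
    pct_large_msp: float     # NaN when no MSPs
    n_large_msps_in_region: int


@dataclass
class SpacingResult:
    observed: np.ndarray       # consecutive start-to-start distances, bp
    expected: float            # sequenced_bases / n_contained (NaN if none)
    n_msps_contained: int
    sequenced_bases: int


def classify_features(
    fiber: Fiber,
    dinuc_cutoff: int = DINUC_CUTOFF,
    msp_cutoff: int = LARGE_MSP_CUTOFF,
    region: Optional[GenomicInterval] = None,
    region_label: str = "all",
) -> FiberDichromatinSummary:
    """Classify one fiber's footprints (strictly greater-than cutoffs).

    A footprint is di-nucleosomal iff its length > ``dinuc_cutoff``; an MSP
    is a large (accessible chromatin) patch iff length > ``msp_cutoff``.
    Percentages are per fiber; with a zero denominator they are NaN.
    When ``region`` is given only features fully inside it are counted.
    """
    nucs = fiber.nucleosomes
    msps = fiber.msps
    if region is not None:
        nucs = [n for n in nucs if region.contains(n)]
        msps = [m for m in msps if region.contains(m)]
    n_di = sum(1 for n in nucs if len(n) > dinuc_cutoff)
    n_large = sum(1 for m in msps if len(m) > msp_cutoff)
    return FiberDichromatinSummary(
        fiber_id=fiber.fiber_id,
        region=region_label,
        n_nucleosomes=len(nucs),
        pct_dinucleosome=100.0 * n_di / len(nucs) if nucs else float("nan"),
        n_msps=len(msps),
        pct_large_msp=100.0 * n_large / len(msps) if msps else float("nan"),
        n_large_msps_in_region=n_large,
    )


def regional_summaries(
    fibers: Iterable[Fiber],
    regions: Sequence[GenomicInterval],
    dinuc_cutoff: int = DINUC_CUTOFF,
    msp_cutoff: int = LARGE_MSP_CUTOFF,
) -> pd.DataFrame:
    """Per-fiber dichromatin summaries with fibers assigned to the region
    holding >= 50% of their span (ties to the leftmost region; fibers
    reaching no region get the label "unassigned")."""
    labels = [r.name or f"{r.chrom}:{r.start}-{r.end}" for r in regions]
    rows = []
    for f in fibers:
        best, best_ov = None, 0
        for r, lab in zip(regions, labels):
            ov = f.interval.overlap(r)
            if ov > best_ov:
                best, best_ov = (r, lab), ov
        if best is not None and best_ov * 2 >= len(f.interval):
            region, label = best
        else:
            region, label = None, "unassigned"
        s = classify_features(
            f, dinuc_cutoff, msp_cutoff, region=region,
            region_label=label,
        )
        rows.append(vars(s))
    return pd.DataFrame(rows)


def patch_spacing(
    fibers: Iterable[Fiber],
    region: GenomicInterval,
    msp_cutoff: int = LARGE_MSP_CUTOFF,
) -> SpacingResult:
    """Observed vs expected spacing of large accessible patches in a core.

    Observed: distances between start positions of consecutive large MSPs
    on the same fiber, both fully contained in the region. Expected: total
    sequenced bases in the region divided by the number of contained large
    MSPs (algebraically the density-based expected distance).
    """
    observed: list[int] = []
    n_contained = 0
    sequenced = 0
    for f in fibers:
        ov = f.interval.overlap(region)
        if ov == 0:
            continue
        sequenced += ov
        contained = [
            m for m in f.msps if len(m) > msp_cutoff and region.contains(m)
        ]
        n_contained += len(contained)
        starts = [m.start for m in contained]
        observed.extend(b - a for a, b in zip(starts, starts[1:]))
    expected = sequenced / n_contained if n_contained else float("nan")
    return SpacingResult(
        np.asarray(observed, dtype=np.int64), expected, n_contained, sequenced
    )


def estimate_patch_count(
    fibers: Iterable[Fiber],
    region: GenomicInterval,
    msp_cutoff: int = LARGE_MSP_CUTOFF,
) -> float:
    """Expected number of accessible patches a full-length traversal of the
    region would carry: (contained large MSPs / sequenced bases) x length."""
    sp = patch_spacing(fibers, region, msp_cutoff)
    if sp.sequenced_bases == 0:
        raise DichromError("no sequenced bases overlap the region")
    return sp.n_msps_contained / sp.sequenced_bases * len(region)


def interval_span_fraction(
    fibers: Iterable[Fiber],
    target: GenomicInterval,
    min_span_fraction: float = 0.9,
) -> float:
    """Fraction of target-spanning fibers carrying one protected footprint
    that covers at least ``min_span_fraction`` of the target.

    This is the single-molecule occupancy statistic for point-centromere
    (CDE I-III / CCAN) footprints; NaN when no fiber spans the target.
    """
    n_span = 0
    n_occ = 0
    need = min_span_fraction * len(target)
    for f in fibers:
        if not f.spans(target):
            continue
        n_span += 1
        if any(n.overlap(target) >= need for n in f.nucleosomes):
            n_occ += 1
    return n_occ / n_span if n_span else float("nan")


def footprint_size_distribution(
    fibers: Iterable[Fiber],
    region: Optional[GenomicInterval] = None,
    bins: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray, pd.Series]:
    """Histogram and summary quantiles of protected-footprint lengths.

    Footprints overlapping ``region`` (any overlap) are counted; returns
    ``(counts, bin_edges, quantiles)`` where quantiles holds the 5/25/50/
    75/95th percentiles and the count.
    """
    lengths = []
    for f in fibers:
        for n in f.nucleosomes:
            if region is None or n.intersects(region):
                lengths.append(len(n))
    lengths = np.asarray(lengths, dtype=np.int64)
    if bins is None:
        bins = np.arange(0, 1001, 10)
    counts, edges = np.histogram(lengths, bins=bins)
    if lengths.size:
        q = np.percentile(lengths, [5, 25, 50, 75, 95])
    else:
        q = np.full(5, np.nan)
    quant = pd.Series(
        {"q05": q[0], "q25": q[1], "median": q[2], "q75": q[3], "q95": q[4],
         "n": lengths.size}
    )
    return counts, edges, quant
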