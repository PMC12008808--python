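"""Per-bp track aggregation and a naive fallback fiber segmenter.

Aggregate tracks follow the convention of counting total feature
occurrences across all molecules at a bp and dividing by the molecule
coverage at that bp; bps with zero coverage are undefined (NaN).
"""

from __future__ import annotations

from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .model import (
    DensityTrack,
    Fiber,
    FiberValidationError,
    GenomicInterval,
)

Feature = Literal["m6a", "nucleosome", "msp"]


def segment_fiber_naive(
    fiber: Fiber, min_footprint: int = 85, min_msp: int = 85
) -> Fiber:
    """Naive run-length segmentation of a fiber from its m6A events alone.

    Maximal m6A-free runs of length >= ``min_footprint`` become protected
    footprints; the complementary runs (where consecutive m6A events are
    never more than ``min_footprint`` apart) of length >= ``min_msp`` become
    MSPs. This is a documented fallback for fibers whose production
    segmentation is unavailable; it is deliberately simple and makes no
    attempt to mimic an HMM-based segmenter.
    """
    if fiber.nucleosomes or fiber.msps:
        raise FiberValidationError(
            f"fiber {fiber.fiber_id} already has footprints; refusing to overwrite"
        )
    start, end = fiber.start, fiber.end
    pos = fiber.m6a_positions
    # m6A-free runs: before first event, between events, after last event
    bounds = np.concatenate(([start - 1], pos, [end]))
    out = fiber.copy()
    nucs: list[GenomicInterval] = []
    gaps: list[tuple[int, int]] = []  # all m6A-free runs (possibly empty)
    for a, b in zip(bounds[:-1], bounds[1:]):
        gaps.append((int(a) + 1, int(b)))
    for lo, hi in gaps:
        if hi - lo >= min_footprint:
            nucs.append(GenomicInterval(fiber.chrom, lo, hi))
    # complement of footprints within the span
    msps: list[GenomicInterval] = []
    cursor = start
    for n in nucs:
        if n.start - cursor >= min_msp:
            msps.append(GenomicInterval(fiber.chrom, cursor, n.start))
        cursor = n.end
    if end - cursor >= min_msp:
        msps.append(GenomicInterval(fiber.chrom, cursor, end))
    out.nucleosomes = nucs
    out.msps = msps
    out.validate()
    return out


def aggregate_density_track(
    fibers: Iterable[Fiber], feature: Feature, region: GenomicInterval
) -> DensityTrack:
    """Per-bp density of a fiber feature over a region.

    feature_count(bp) = number of fibers whose chosen feature covers the bp
    (for m6a: an event at the bp); coverage(bp) = number of fibers spanning
    the bp. An empty fiber list yields an all-undefined track.
    """
    n = len(region)
    count = np.zeros(n + 1, dtype=np.int64)
    cov = np.zeros(n + 1, dtype=np.int64)
    for f in fibers:
        lo = max(f.start, region.start) - region.start
        hi = min(f.end, region.end) - region.start
        if hi <= lo:
            continue
        cov[lo] += 1
        cov[hi] -= 1
        if feature == "m6a":
            p = f.m6a_positions
            p = p[(p >= region.start) & (p < region.end)] - region.start
            count[p] += 1
            count[p + 1] -= 1
        else:
            feats = f.nucleosomes if feature == "nucleosome" else f.msps
            for iv in feats:
                a = max(iv.start, region.start) - region.start
                b = min(iv.end, region.end) - region.start
                if b > a:
                    count[a] += 1
                    count[b] -= 1
    return DensityTrack(
        region.chrom,
        region.start,
        np.cumsum(count[:-1]),
        np.cumsum(cov[:-1]),
    )


def aggregate_methylation(
    fibers: Iterable[Fiber], region: GenomicInterval
) -> pd.DataFrame:
    """Per-site CpG methylation table over a region.

    Columns: position, n_called, n_methylated, fraction. Sites called on no
    fiber are omitted.
    """
    called: dict[int, int] = {}
    meth: dict[int, int] = {}
    for f in fibers:
        for p, v in f.cpg_calls.items():
            if region.start <= p < region.end:
                called[p] = called.get(p, 0) + 1
                if v:
                    meth[p] = meth.get(p, 0) + 1
    positions = sorted(called)
    n_called = np.array([called[p] for p in positions], dtype=np.int64)
    n_meth = np.array([meth.get(p, 0) for p in positions], dtype=np.int64)
    return pd.DataFrame(
        {
            "position": np.asarray(positions, dtype=np.int64),
            "n_called": n_called,
            "n_methylated": n_meth,
            "fraction": n_meth / n_called if len(positions) else np.empty(0),
        }
    )
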