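"""Chromatin repeat lengths from per-fiber Fourier periodograms.

Each fiber's m6A pattern is binarized per bp (event = 1), a standard
one-sided periodogram (rectangular window, unit sample spacing, no
detrending by default) estimates its spectral density, densities are
interpolated onto a common 1 bp repeat-length grid and combined as the
per-gridpoint median, and the dominant chromatin repeat length is read off
the aggregated spectrum's maximum within the analysis band (120-300 bp by
default, which covers satellite units of 155-340 bp and nucleosome repeat
lengths of 170-193 bp).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import signal as _signal

from .model import DichromError, Fiber, GenomicInterval

logger = logging.getLogger("dichrom")

MIN_PERIOD = 120
MAX_PERIOD = 300
MIN_EVENTS = 10


@dataclass
class BinaryFiberVector:
    fiber_id: str
    origin: int            # reference position of values[0]
    values: np.ndarray     # uint8 0/1 per bp


@dataclass
class SpectralDensity:
    """Spectral density on a decreasing repeat-length grid (bp)."""

    repeat_lengths: np.ndarray
    densities: np.ndarray
    n_fibers: int = 1


def binarize_m6a(
    fiber: Fiber, region: Optional[GenomicInterval] = None
) -> BinaryFiberVector:
    """Per-bp 0/1 vector over the fiber (optionally clipped to a region)."""
    lo, hi = fiber.start, fiber.end
    if region is not None:
        lo, hi = max(lo, region.start), min(hi, region.end)
        if hi <= lo:
            raise DichromError(
                f"fiber {fiber.fiber_id} does not overlap the region"
            )
    values = np.zeros(hi - lo, dtype=np.uint8)
    p = fiber.m6a_positions
    p = p[(p >= lo) & (p < hi)]
    values[p - lo] = 1
    return BinaryFiberVector(fiber.fiber_id, lo, values)


def fiber_periodogram(
    vec: BinaryFiberVector,
    min_period: int = MIN_PERIOD,
    max_period: int = MAX_PERIOD,
    min_events: int = MIN_EVENTS,
    detrend: bool = False,
) -> Optional[SpectralDensity]:
    """One fiber's periodogram restricted to the repeat-length band.

    Returns None (with a logged reason) for fibers shorter than twice the
    maximum period or with fewer than ``min_events`` events.
    """
    x = vec.values
    if x.size < 2 * max_period:
        logger.debug("fiber %s skipped: length %d < %d",
                     vec.fiber_id, x.size, 2 * max_period)
        return None
    if int(x.sum()) < min_events:
        logger.debug("fiber %s skipped: %d events < %d",
                     vec.fiber_id, int(x.sum()), min_events)
        return None
    freqs, dens = _signal.periodogram(
        x.astype(float),
        fs=1.0,
        window="boxcar",
        detrend="constant" if detrend else False,
        scaling="density",
    )
    keep = (freqs > 0) & (1.0 / np.maximum(freqs, 1e-300) >= min_period) & (
        1.0 / np.maximum(freqs, 1e-300) <= max_period
    )
    rl = 1.0 / freqs[keep]
    return SpectralDensity(rl, dens[keep], n_fibers=1)


def aggregate_spectra(
    spectra: Sequence[SpectralDensity],
    min_period: int = MIN_PERIOD,
    max_period: int = MAX_PERIOD,
) -> SpectralDensity:
    """Median spectral density on a common 1 bp repeat-length grid.

    Per-fiber densities (whose raw frequency grids depend on fiber length)
    are linearly interpolated onto integer repeat lengths before taking the
    per-gridpoint median across fibers.
    """
    if not spectra:
        raise DichromError("no spectra to aggregate")
    grid = np.arange(min_period, max_period + 1, dtype=float)
    rows = np.empty((len(spectra), grid.size))
    for i, sp in enumerate(spectra):
        # repeat_lengths are decreasing; np.interp wants increasing x
        rows[i] = np.interp(grid, sp.repeat_lengths[::-1], sp.densities[::-1])
    med = np.median(rows, axis=0)
    return SpectralDensity(grid[::-1], med[::-1], n_fibers=len(spectra))


def peak_repeat_length(
    spec: SpectralDensity, n_peaks: int = 1
) -> list[tuple[float, float]]:
    """Repeat lengths of the largest local maxima (global maximum first,
    ties broken toward the shorter repeat length)."""
    if spec.repeat_lengths.size == 0:
        raise DichromError("empty spectrum")
    # work on an increasing repeat-length axis
    rl = spec.repeat_lengths[::-1]
    d = spec.densities[::-1]
    if np.allclose(d, d[0]):
        logger.warning("flat spectrum: peak is degenerate")
        return [(float(rl[0]), float(d[0]))]
    maxima = [
        i for i in range(d.size)
        if (i == 0 or d[i] >= d[i - 1]) and (i == d.size - 1 or d[i] > d[i + 1])
    ]
    # sort by density (desc) then repeat length (asc): shorter wins ties
    maxima.sort(key=lambda i: (-d[i], rl[i]))
    return [(float(rl[i]), float(d[i])) for i in maxima[:n_peaks]]


def region_spectrum(
    fibers: Iterable[Fiber],
    region: Optional[GenomicInterval] = None,
    min_period: int = MIN_PERIOD,
    max_period: int = MAX_PERIOD,
    min_events: int = MIN_EVENTS,
    detrend: bool = False,
) -> SpectralDensity:
    """Aggregated median spectrum of all accepted fibers in a region."""
    spectra = []
    n_skipped = 0
    for f in fibers:
        if region is not None and not f.interval.intersects(region):
            continue
        sp = fiber_periodogram(
            binarize_m6a(f, region), min_period, max_period, min_events, detrend
        )
        if sp is None:
            n_skipped += 1
        else:
            spectra.append(sp)
    if n_skipped:
        logger.info("region_spectrum: skipped %d fibers", n_skipped)
    return aggregate_spectra(spectra, min_period, max_period)
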