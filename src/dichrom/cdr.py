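"""Centromere-core (CDR) calling from aggregate CpG methylation.

The core of a satellite array is located as a hypo-CpG-methylated dip:
alpha-satellite annotations are gap-merged and length-filtered, mean CpG
methylation is computed in sliding windows (1190 bp, 170 bp step), windows
below the array's 35th percentile are selected, contiguous selected
windows form candidates, and candidates are kept when they are at least
15 kb long, have a mean window methylation below the 20th percentile, and
avoid the terminal 70 kb of the array (15 kb for the chrY-style variant).

Candidate boundaries use a per-bp consensus rule: a base belongs to a
candidate only if every site-bearing window covering it passed the
35th-percentile cut. Because windows advance by one step, this quantizes
candidate edges to the step grid instead of letting a single passing
window drag the boundary a full window width outward.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    DichromError,
    GenomicInterval,
    SatClass,
    SatelliteAnnotation,
)

logger = logging.getLogger("dichrom")


@dataclass
class CdrParams:
    """Windowing and filter parameters for core calling (defaults are the
    published procedure; ``terminal_exclusion`` drops to 15 kb for arrays
    whose termini sit close to the core, the chrY-style variant)."""

    merge_gap: int = 25
    min_array: int = 100_000
    window_size: int = 1190
    step: int = 170
    window_percentile: float = 35.0
    merged_percentile: float = 20.0
    min_cdr_length: int = 15_000
    terminal_exclusion: int = 70_000

    def __post_init__(self) -> None:
        if self.window_size < self.step:
            raise DichromError("window_size must be >= step")
        for p in (self.window_percentile, self.merged_percentile):
            if not 0 < p < 100:
                raise DichromError("percentiles must lie in (0, 100)")


@dataclass
class MethylationWindow:
    interval: GenomicInterval
    mean_fraction: float
    n_sites: int


@dataclass
class CdrCall:
    interval: GenomicInterval
    mean_window_fraction: float
    array_id: str
    passed_filters: dict[str, bool] = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return all(self.passed_filters.values())


def merge_satellite_arrays(
    annotations: Sequence[SatelliteAnnotation],
    params: CdrParams,
    sat_class: SatClass = SatClass.ACTIVE_HOR,
) -> list[GenomicInterval]:
    """Gap-merge annotations of one satellite class and keep long stretches.

    Intervals of the class separated by strictly less than ``merge_gap`` bp
    are merged; merged stretches shorter than ``min_array`` are dropped.
    """
    per_chrom: dict[str, list[GenomicInterval]] = {}
    for ann in annotations:
        if ann.sat_class is sat_class:
            per_chrom.setdefault(ann.interval.chrom, []).append(ann.interval)
    merged: list[GenomicInterval] = []
    for chrom in sorted(per_chrom):
        ivs = sorted(per_chrom[chrom], key=lambda x: (x.start, x.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start - cur_e < params.merge_gap:
                cur_e = max(cur_e, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_s, cur_e))
    return [iv for iv in merged if len(iv) >= params.min_array]


def window_methylation(
    array: GenomicInterval,
    meth_table: pd.DataFrame,
    params: CdrParams,
) -> list[MethylationWindow]:
    """Sliding mean CpG methylation in windows across one merged array.

    ``meth_table`` needs columns ``position`` and ``fraction`` (as produced
    by :func:`dichrom.tracks.aggregate_methylation` or read from a
    bedGraph). Windows start at the array start and advance by ``step``;
    the last window lies fully inside the array.
    """
    if len(array) < params.window_size:
        logger.warning("array %s shorter than one window", array)
        return []
    pos = np.asarray(meth_table["position"], dtype=np.int64)
    frac = np.asarray(meth_table["fraction"], dtype=float)
    order = np.argsort(pos)
    pos, frac = pos[order], frac[order]
    csum = np.concatenate(([0.0], np.cumsum(frac)))

    starts = np.arange(array.start, array.end - params.window_size + 1, params.step)
    lo = np.searchsorted(pos, starts, side="left")
    hi = np.searchsorted(pos, starts + params.window_size, side="left")
    n = hi - lo
    out = []
    with np.errstate(invalid="ignore"):
        means = np.where(n > 0, (csum[hi] - csum[lo]) / np.maximum(n, 1), np.nan)
    for s, m, k in zip(starts, means, n):
        out.append(MethylationWindow(
            GenomicInterval(array.chrom, int(s), int(s) + params.window_size),
            float(m) if k > 0 else float("nan"),
            int(k),
        ))
    return out


def call_cdrs(
    windows: Sequence[MethylationWindow],
    params: CdrParams,
    array: GenomicInterval,
) -> list[CdrCall]:
    """Call core candidates from one array's methylation windows.

    Returns every candidate with its three filter outcomes recorded
    (length, percentile, terminal); the final calls are those whose
    ``passed`` is True. Zero-site windows are ignored (they neither select
    nor veto). All-siteless windows raise, naming the array.
    """
    scored = [w for w in windows if w.n_sites > 0]
    if not scored:
        raise DichromError(f"array {array.chrom}:{array.start}-{array.end}: "
                           "no methylation window contains a CpG site")
    means = np.array([w.mean_fraction for w in scored])
    p_win = np.percentile(means, params.window_percentile)
    p_merged = np.percentile(means, params.merged_percentile)
    # strict "below"; the epsilon keeps float rounding of tied window means
    # (e.g. a perfectly uniform array) from breaking ties arbitrarily
    eps = 1e-9
    selected = means < p_win - eps

    # per-bp consensus: base in candidate <=> covered and never vetoed
    n = len(array)
    covered = np.zeros(n + 1, dtype=np.int32)
    vetoed = np.zeros(n + 1, dtype=np.int32)
    for w, sel in zip(scored, selected):
        a, b = w.interval.start - array.start, w.interval.end - array.start
        covered[a] += 1
        covered[b] -= 1
        if not sel:
            vetoed[a] += 1
            vetoed[b] -= 1
    mask = (np.cumsum(covered[:-1]) > 0) & (np.cumsum(vetoed[:-1]) == 0)

    edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    runs = edges.reshape(-1, 2)

    array_id = f"{array.chrom}:{array.start}-{array.end}"
    term = params.terminal_exclusion
    calls: list[CdrCall] = []
    for a, b in runs:
        iv = GenomicInterval(array.chrom, array.start + int(a), array.start + int(b))
        members = [
            w.mean_fraction
            for w, sel in zip(scored, selected)
            if sel and w.interval.intersects(iv)
        ]
        cand_mean = float(np.mean(members)) if members else float("nan")
        in_terminal = (
            iv.start < array.start + term or iv.end > array.end - term
        )
        calls.append(CdrCall(
            iv,
            cand_mean,
            array_id,
            {
                "length": len(iv) >= params.min_cdr_length,
                "percentile": bool(cand_mean < p_merged - eps),
                "terminal": not in_terminal,
            },
        ))
    return calls


def call_cdrs_on_arrays(
    annotations: Sequence[SatelliteAnnotation],
    meth_table: pd.DataFrame,
    params: Optional[CdrParams] = None,
    core_bed: Optional[Sequence[GenomicInterval]] = None,
) -> tuple[list[CdrCall], list[CdrCall]]:
    """End-to-end core calling: merge arrays, window, call, filter.

    When ``core_bed`` is given (externally defined cores, e.g. CENP-A
    CUT&RUN enriched regions), methylation-based calling is bypassed and
    the provided intervals are returned as pre-passed calls.

    Returns ``(final_calls, all_candidates)``.
    """
    params = params or CdrParams()
    if core_bed is not None:
        calls = [
            CdrCall(iv, float("nan"), "external",
                    {"length": True, "percentile": True, "terminal": True})
            for iv in core_bed
        ]
        return calls, calls
    candidates: list[CdrCall] = []
    for array in merge_satellite_arrays(annotations, params):
        windows = window_methylation(array, meth_table, params)
        if not windows:
            continue
        candidates.extend(call_cdrs(windows, params, array))
    final = [c for c in candidates if c.passed]
    return final, candidates


def audit_table(candidates: Sequence[CdrCall]) -> pd.DataFrame:
    """Per-candidate filter outcomes, for the audit TSV."""
    return pd.DataFrame([
        {
            "chrom": c.interval.chrom,
            "start": c.interval.start,
            "end": c.interval.end,
            "array": c.array_id,
            "mean_window_fraction": c.mean_window_fraction,
            "pass_length": c.passed_filters.get("length"),
            "pass_percentile": c.passed_filters.get("percentile"),
            "pass_terminal": c.passed_filters.get("terminal"),
            "final": c.passed,
        }
        for c in candidates
    ])
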