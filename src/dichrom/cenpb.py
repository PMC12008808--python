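"""CENP-B box discovery and single-molecule footprint scoring.

The 17 bp CENP-B box consensus (NTTCGNNNNANNCGGGN) is scanned on both
strands under IUPAC semantics and matches are kept when the matched 17-mer
contains exactly two CG dinucleotides. Every molecule fully covering a box
is stratified by its CpG methylation state at those two CpGs (0, 1 or 2
methylated; molecules with an uncalled box CpG are excluded from strata),
its m6A pattern around the box center is collapsed into 10 bp-smoothed
frequency profiles per stratum, and occupancy is quantified by a footprint
score: flank m6A frequency (offsets -35..-27 and +22..+27) divided by core
frequency (offsets -7..+1, pseudocounted). Score distributions come from
repeated 10% subsampling of the stratum. Higher scores indicate greater
CENP-B occupancy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .model import (
    ConfigError,
    DichromError,
    Fiber,
    GenomicInterval,
)

CENPB_MOTIF = "NTTCGNNNNANNCGGGN"
MOTIF_CENTER_OFFSET = 8   # 9th base of the motif, in motif orientation
PROFILE_HALFWIDTH = 50
FLANK_OFFSETS = np.concatenate([np.arange(-35, -26), np.arange(22, 28)])
CORE_OFFSETS = np.arange(-7, 2)

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMP = str.maketrans("ACGTN", "TGCAN")


@dataclass
class CenpBSite:
    interval: GenomicInterval           # width 17 on the reference
    strand: str
    center: int                         # reference position of the 9th base
    cpg_positions: tuple[int, int]      # reference starts of the 2 CGs
    region: str = ""


@dataclass
class BoxFiberObservation:
    site_id: int
    fiber_id: str
    mcpg_state: Optional[int]           # 0/1/2, None = a box CpG uncalled
    m6a_window: np.ndarray              # binary, motif orientation


@dataclass
class FootprintScore:
    stratum: str
    score: float
    n_fibers: int
    distribution: np.ndarray = field(default_factory=lambda: np.empty(0))


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _match_mask(seq_codes: np.ndarray, pattern: str, max_mismatches: int) -> np.ndarray:
    """Positions i where seq[i:i+len(pattern)] matches with <= k mismatches."""
    L = len(pattern)
    n = seq_codes.size - L + 1
    if n <= 0:
        return np.zeros(0, dtype=bool)
    mism = np.zeros(n, dtype=np.int16)
    for j, c in enumerate(pattern):
        allowed = _IUPAC.get(c)
        if allowed is None:
            raise ConfigError(f"non-IUPAC character {c!r} in motif")
        if allowed == "ACGT":
            continue
        col = seq_codes[j: j + n]
        ok = np.zeros(n, dtype=bool)
        for b in allowed:
            ok |= col == ord(b)
        mism += ~ok
    return mism <= max_mismatches


def scan_cenpb_boxes(
    seq: str,
    regions: Optional[Sequence[GenomicInterval]] = None,
    chrom: str = "ref",
    motif: str = CENPB_MOTIF,
    max_mismatches: int = 0,
    require_cpgs: int = 2,
) -> list[CenpBSite]:
    """Scan a reference sequence for CENP-B boxes on both strands.

    Matches are reported in reference coordinates; minus-strand matches get
    strand "-" with the center mapped through the strand. Only matches
    whose 17-mer contains exactly ``require_cpgs`` CG dinucleotides are
    kept (CG content is strand-symmetric).
    """
    seq = seq.upper()
    L = len(motif)
    regions = regions or [GenomicInterval(chrom, 0, len(seq))]
    sites: list[CenpBSite] = []
    for reg in regions:
        sub = seq[reg.start: reg.end]
        codes = np.frombuffer(sub.encode(), dtype=np.uint8)
        fwd = np.flatnonzero(_match_mask(codes, motif, max_mismatches))
        rc_codes = np.frombuffer(_revcomp(sub).encode(), dtype=np.uint8)
        rev = np.flatnonzero(_match_mask(rc_codes, motif, max_mismatches))
        hits = [(int(i), "+") for i in fwd] + [
            (len(sub) - L - int(i), "-") for i in rev
        ]
        for off, strand in sorted(hits):
            s = reg.start + off
            mer = seq[s: s + L]
            cgs = tuple(
                s + j for j in range(L - 1) if mer[j: j + 2] == "CG"
            )
            if len(cgs) != require_cpgs:
                continue
            center = s + MOTIF_CENTER_OFFSET if strand == "+" else (
                s + L - 1 - MOTIF_CENTER_OFFSET
            )
            sites.append(CenpBSite(
                GenomicInterval(reg.chrom, s, s + L, strand=strand),
                strand, center, cgs,
                region=reg.name or "",
            ))
    return sites


def observe_boxes(
    fibers: Iterable[Fiber],
    sites: Sequence[CenpBSite],
    profile_halfwidth: int = PROFILE_HALFWIDTH,
) -> list[BoxFiberObservation]:
    """One observation per (site, fiber fully spanning center +/- halfwidth).

    The binary m6A window is reported in motif orientation (minus-strand
    windows are position-flipped), so profile offsets always run 5' to 3'
    along the motif. The mCpG state is the number of methylated calls among
    the box's two CpGs when both are called, else None.
    """
    out: list[BoxFiberObservation] = []
    w = 2 * profile_halfwidth + 1
    for f in fibers:
        pos = f.m6a_positions
        for si, site in enumerate(sites):
            lo = site.center - profile_halfwidth
            hi = site.center + profile_halfwidth + 1
            if not (f.start <= lo and hi <= f.end and f.chrom == site.interval.chrom):
                continue
            window = np.zeros(w, dtype=np.uint8)
            p = pos[(pos >= lo) & (pos < hi)]
            window[p - lo] = 1
            if site.strand == "-":
                window = window[::-1]
            p1, p2 = site.cpg_positions
            if p1 in f.cpg_calls and p2 in f.cpg_calls:
                state: Optional[int] = int(f.cpg_calls[p1]) + int(f.cpg_calls[p2])
            else:
                state = None
            out.append(BoxFiberObservation(si, f.fiber_id, state, window))
    return out


def aggregate_profile(
    observations: Sequence[BoxFiberObservation], smooth: int = 10
) -> np.ndarray:
    """Mean m6A frequency per offset, then a rolling mean of width
    ``smooth`` (window [-5, +4] for width 10, truncated at the ends)."""
    if not observations:
        raise DichromError("empty stratum")
    mat = np.stack([o.m6a_window for o in observations]).astype(float)
    return _rolling_mean(mat.mean(axis=0), smooth)


def _rolling_mean(x: np.ndarray, width: int) -> np.ndarray:
    n = x.size
    half_lo = width // 2           # left reach: 5 for width 10
    half_hi = width - half_lo - 1  # right reach: 4
    csum = np.concatenate(([0.0], np.cumsum(x)))
    lo = np.clip(np.arange(n) - half_lo, 0, n)
    hi = np.clip(np.arange(n) + half_hi + 1, 0, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def footprint_score(
    profile: np.ndarray,
    pseudocount: float = 1e-3,
    halfwidth: int = PROFILE_HALFWIDTH,
) -> float:
    """Flank / core ratio of the smoothed m6A frequency profile.

    Flank = mean over offsets -35..-27 and +22..+27; core = mean over
    offsets -7..+1 (inclusive, relative to the motif center at index
    ``halfwidth``); the pseudocount keeps fully protected cores finite.
    """
    if profile.size < 2 * halfwidth + 1:
        raise DichromError("profile does not cover the required offsets")
    flank = float(np.mean(profile[FLANK_OFFSETS + halfwidth]))
    core = float(np.mean(profile[CORE_OFFSETS + halfwidth]))
    return flank / (core + pseudocount)


def score_distribution(
    observations: Sequence[BoxFiberObservation],
    stratum: str = "",
    subsample_fraction: float = 0.10,
    n_subsamples: int = 1000,
    seed: int = 0,
    pseudocount: float = 1e-3,
    smooth: int = 10,
) -> FootprintScore:
    """Footprint-score distribution from repeated subsampling.

    Each of ``n_subsamples`` draws takes ceil(fraction x n) observations
    without replacement, collapses them to a smoothed profile and scores
    it. The full-stratum score and the distribution are returned;
    reproducible from ``seed``.
    """
    n = len(observations)
    k = math.ceil(subsample_fraction * n)
    if k < 5:
        raise DichromError(
            f"stratum too small: {n} observations give subsamples of {k} < 5"
        )
    mat = np.stack([o.m6a_window for o in observations]).astype(float)
    halfwidth = (mat.shape[1] - 1) // 2
    rng = np.random.default_rng(seed)
    scores = np.empty(n_subsamples)
    for i in range(n_subsamples):
        idx = rng.choice(n, size=k, replace=False)
        prof = _rolling_mean(mat[idx].mean(axis=0), smooth)
        scores[i] = footprint_score(prof, pseudocount, halfwidth)
    full = footprint_score(
        _rolling_mean(mat.mean(axis=0), smooth), pseudocount, halfwidth
    )
    return FootprintScore(stratum, full, n, scores)


def stratify(
    observations: Iterable[BoxFiberObservation],
) -> dict[int, list[BoxFiberObservation]]:
    """Group observations by mCpG state (0/1/2); uncalled are dropped."""
    strata: dict[int, list[BoxFiberObservation]] = {0: [], 1: [], 2: []}
    for o in observations:
        if o.mcpg_state is not None:
            strata[o.mcpg_state].append(o)
    return strata


def nucleosome_edge_positioning(
    fibers: Iterable[Fiber],
    sites: Sequence[CenpBSite],
    halfwidth: int = 500,
) -> dict[int, dict[str, np.ndarray]]:
    """Percentage histograms of closest nucleosome edges around boxes.

    For each (site, fiber spanning center +/- halfwidth), the boundary of
    the nearest fully-upstream nucleosome closest to the center and
    likewise downstream are recorded as offsets in motif orientation. A
    footprint covering the center itself contributes to neither side.
    Returns, per mCpG stratum, "upstream" and "downstream" arrays of
    length 2*halfwidth+1 (percent of observations per offset).
    """
    counts: dict[int, dict[str, np.ndarray]] = {
        s: {"upstream": np.zeros(2 * halfwidth + 1),
            "downstream": np.zeros(2 * halfwidth + 1)}
        for s in (0, 1, 2)
    }
    totals: dict[int, dict[str, int]] = {
        s: {"upstream": 0, "downstream": 0} for s in (0, 1, 2)
    }
    for f in fibers:
        for site in sites:
            c = site.center
            if not (f.start <= c - halfwidth and c + halfwidth + 1 <= f.end):
                continue
            p1, p2 = site.cpg_positions
            if p1 not in f.cpg_calls or p2 not in f.cpg_calls:
                continue
            state = int(f.cpg_calls[p1]) + int(f.cpg_calls[p2])
            left = [n for n in f.nucleosomes if n.end <= c]
            right = [n for n in f.nucleosomes if n.start > c]
            up_off = down_off = None
            if left:
                up_off = max(n.end for n in left) - c      # <= 0
            if right:
                down_off = min(n.start for n in right) - c  # > 0
            if site.strand == "-":
                up_off, down_off = (
                    None if down_off is None else -down_off,
                    None if up_off is None else -up_off,
                )
            for key, off in (("upstream", up_off), ("downstream", down_off)):
                if off is not None and -halfwidth <= off <= halfwidth:
                    counts[state][key][off + halfwidth] += 1
                    totals[state][key] += 1
    for s in counts:
        for key in counts[s]:
            t = totals[s][key]
            if t:
                counts[s][key] = 100.0 * counts[s][key] / t
    return counts
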