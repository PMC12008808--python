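"""Readers and writers for the formats the pipeline touches.

Fiber-table TSV (versioned, documented below), modified-base BAM (MM/ML),
BED/BED4/BED6, bedGraph, and FASTA. BigWig output is supported when pyBigWig
is importable but is never required.

Fiber-table schema (``#dichrom_fiber_table v1``), tab-separated::

    fiber_id  chrom  start  end  m6a  nucleosomes  msps  cpg

``m6a`` is a comma list of reference positions; ``nucleosomes`` and ``msps``
are comma lists of ``start-end`` half-open intervals; ``cpg`` is a comma
list of ``pos:0|1`` methylation calls. Empty lists are written as ``.``.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .model import (
    Fiber,
    FiberTableParseError,
    FiberValidationError,
    FormatError,
    GenomicInterval,
    SatClass,
    SatelliteAnnotation,
    sort_fibers,
)

logger = logging.getLogger("dichrom")

FIBER_TABLE_MAGIC = "#dichrom_fiber_table"
FIBER_TABLE_VERSION = "v1"
_COLUMNS = ["fiber_id", "chrom", "start", "end", "m6a", "nucleosomes", "msps", "cpg"]

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# fiber table
# ---------------------------------------------------------------------------

def _fmt_list(values: Iterable[str]) -> str:
    joined = ",".join(values)
    return joined if joined else "."


def _fiber_to_row(f: Fiber) -> list[str]:
    return [
        f.fiber_id,
        f.chrom,
        str(f.start),
        str(f.end),
        _fmt_list(str(p) for p in f.m6a_positions),
        _fmt_list(f"{n.start}-{n.end}" for n in f.nucleosomes),
        _fmt_list(f"{m.start}-{m.end}" for m in f.msps),
        _fmt_list(
            f"{p}:{int(v)}" for p, v in sorted(f.cpg_calls.items())
        ),
    ]


def write_fiber_table(fibers: Iterable[Fiber], path: PathLike) -> None:
    fibers = sort_fibers(fibers)
    with open(path, "w") as fh:
        fh.write(f"{FIBER_TABLE_MAGIC} {FIBER_TABLE_VERSION}\n")
        fh.write("\t".join(_COLUMNS) + "\n")
        for f in fibers:
            fh.write("\t".join(_fiber_to_row(f)) + "\n")


def _parse_int(tok: str, row: int, what: str) -> int:
    try:
        return int(tok)
    except ValueError as exc:
        raise FiberTableParseError(
            f"row {row}: malformed {what} {tok!r}"
        ) from exc


def _parse_intervals(
    tok: str, chrom: str, row: int, what: str
) -> list[GenomicInterval]:
    if tok == ".":
        return []
    out = []
    for item in tok.split(","):
        try:
            s, e = item.split("-")
            iv = GenomicInterval(chrom, int(s), int(e))
        except (ValueError, FiberValidationError) as exc:
            raise FiberTableParseError(
                f"row {row}: malformed {what} interval {item!r}: {exc}"
            ) from exc
        out.append(iv)
    return out


def read_fiber_table(path: PathLike, schema: str = FIBER_TABLE_VERSION) -> list[Fiber]:
    """Read and validate a fiber table; invalid rows raise naming the row."""
    fibers: list[Fiber] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith(FIBER_TABLE_MAGIC):
            raise FormatError(f"{path}: missing fiber-table header line")
        version = header.split()[-1]
        if version != schema:
            raise FormatError(
                f"{path}: schema {version} does not match requested {schema}"
            )
        colnames = fh.readline().rstrip("\n").split("\t")
        if colnames != _COLUMNS:
            raise FormatError(f"{path}: unexpected columns {colnames}")
        for rownum, line in enumerate(fh, start=3):
            line = line.rstrip("\n")
            if not line:
                continue
            toks = line.split("\t")
            if len(toks) != len(_COLUMNS):
                raise FiberTableParseError(
                    f"row {rownum}: expected {len(_COLUMNS)} columns, got {len(toks)}"
                )
            fid, chrom = toks[0], toks[1]
            start = _parse_int(toks[2], rownum, "start")
            end = _parse_int(toks[3], rownum, "end")
            try:
                interval = GenomicInterval(chrom, start, end)
            except FiberValidationError as exc:
                raise FiberTableParseError(f"row {rownum}: {exc}") from exc
            if toks[4] == ".":
                m6a = np.empty(0, dtype=np.int64)
            else:
                try:
                    m6a = np.array([int(x) for x in toks[4].split(",")], dtype=np.int64)
                except ValueError as exc:
                    raise FiberTableParseError(
                        f"row {rownum}: malformed m6A list"
                    ) from exc
            nucs = _parse_intervals(toks[5], chrom, rownum, "nucleosome")
            msps = _parse_intervals(toks[6], chrom, rownum, "msp")
            cpg: dict[int, bool] = {}
            if toks[7] != ".":
                for item in toks[7].split(","):
                    try:
                        p, v = item.split(":")
                        cpg[int(p)] = bool(int(v))
                    except ValueError as exc:
                        raise FiberTableParseError(
                            f"row {rownum}: malformed CpG call {item!r}"
                        ) from exc
            try:
                fibers.append(
                    Fiber(fid, interval, np.sort(m6a), nucs, msps, cpg)
                )
            except FiberValidationError as exc:
                raise FiberValidationError(f"row {rownum}: {exc}") from exc
    return fibers


# ---------------------------------------------------------------------------
# modified-base BAM
# ---------------------------------------------------------------------------

def read_modbam(
    path: PathLike,
    m6a_prob_threshold: float = 0.8,
    cpg_prob_threshold: float = 0.8,
    region: Optional[GenomicInterval] = None,
) -> list[Fiber]:
    """Read fibers from a coordinate-sorted BAM with MM/ML modification tags.

    m6A calls (``A+a``) and 5mC calls (``C+m``) whose scaled probability
    (ML/255) is >= the respective threshold become events; positions are
    lifted to reference coordinates through the alignment (insertions are
    skipped, deletions emit nothing). If per-read footprint tags (``ns/nl``
    nucleosome starts/lengths, ``as/al`` MSP starts/lengths, query
    coordinates) are present they are lifted too; otherwise footprint lists
    are left empty. Unmapped reads are skipped with a logged count.
    """
    import pysam

    fibers: list[Fiber] = []
    n_unmapped = 0
    with pysam.AlignmentFile(str(path), "rb") as bam:
        if region is not None:
            it = bam.fetch(region.chrom, region.start, region.end)
        else:
            it = bam.fetch(until_eof=True)
        for aln in it:
            if aln.is_unmapped:
                n_unmapped += 1
                continue
            fibers.append(
                _fiber_from_alignment(aln, m6a_prob_threshold, cpg_prob_threshold)
            )
    if n_unmapped:
        logger.info("read_modbam: skipped %d unmapped reads", n_unmapped)
    return fibers


def _fiber_from_alignment(aln, m6a_thresh: float, cpg_thresh: float) -> Fiber:
    mods = aln.modified_bases  # query coords in aligned orientation
    if mods is None or len(mods) == 0:
        raise FormatError(f"read {aln.query_name}: missing MM/ML tags")
    # query->reference map over aligned bases only
    q2r: dict[int, int] = {
        q: r for q, r in aln.get_aligned_pairs(matches_only=True)
    }
    m6a_ref: list[int] = []
    cpg: dict[int, bool] = {}
    for (base, _strand, mod), calls in mods.items():
        if base == "A" and mod == "a":
            for qpos, qual in calls:
                if qual / 255.0 >= m6a_thresh and qpos in q2r:
                    m6a_ref.append(q2r[qpos])
        elif base == "C" and mod == "m":
            for qpos, qual in calls:
                if qpos not in q2r:
                    continue
                rpos = q2r[qpos]
                # reverse-strand CpG calls land on the G; report the C
                if aln.is_reverse:
                    rpos -= 1
                if rpos >= aln.reference_start:
                    cpg[rpos] = qual / 255.0 >= cpg_thresh
    interval = GenomicInterval(
        aln.reference_name, aln.reference_start, aln.reference_end
    )

    def _lift_intervals(starts_tag: str, lens_tag: str) -> list[GenomicInterval]:
        if not (aln.has_tag(starts_tag) and aln.has_tag(lens_tag)):
            return []
        out = []
        for s, ln in zip(aln.get_tag(starts_tag), aln.get_tag(lens_tag)):
            lo = _nearest_ref(q2r, s)
            hi = _nearest_ref(q2r, s + ln - 1)
            if lo is not None and hi is not None and hi + 1 > lo:
                out.append(GenomicInterval(interval.chrom, lo, hi + 1))
        return _drop_overlaps(out)

    nucs = _lift_intervals("ns", "nl")
    msps = _lift_intervals("as", "al")
    m6a = np.unique(np.asarray(m6a_ref, dtype=np.int64))
    m6a = m6a[(m6a >= interval.start) & (m6a < interval.end)]
    return Fiber(aln.query_name, interval, m6a, nucs, msps, cpg)


def _nearest_ref(q2r: dict[int, int], qpos: int) -> Optional[int]:
    for q in (qpos, qpos - 1, qpos + 1, qpos - 2, qpos + 2):
        if q in q2r:
            return q2r[q]
    return None


def _drop_overlaps(ivs: list[GenomicInterval]) -> list[GenomicInterval]:
    ivs = sorted(ivs, key=lambda x: (x.start, x.end))
    out: list[GenomicInterval] = []
    for iv in ivs:
        if out and iv.start < out[-1].end:
            continue
        out.append(iv)
    return out


# ---------------------------------------------------------------------------
# BED / bedGraph / FASTA
# ---------------------------------------------------------------------------

def read_bed(path: PathLike) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            toks = line.split("\t")
            name = toks[3] if len(toks) > 3 else None
            strand = toks[5] if len(toks) > 5 else None
            out.append(
                GenomicInterval(toks[0], int(toks[1]), int(toks[2]), name, strand)
            )
    return out


def read_satellite_bed(path: PathLike) -> list[SatelliteAnnotation]:
    """BED4 with the satellite class in column 4."""
    anns = []
    for iv in read_bed(path):
        if iv.name is None:
            raise FormatError(f"{path}: satellite BED needs a class in column 4")
        anns.append(SatelliteAnnotation(iv, SatClass(iv.name)))
    return anns


def write_bed(intervals: Sequence[GenomicInterval], path: PathLike) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.strand is not None:
                cols += [iv.name or ".", "0", iv.strand or "."]
            fh.write("\t".join(cols) + "\n")


def write_bedgraph(
    chrom: str, start: int, values: np.ndarray, path: PathLike
) -> None:
    """Write a per-bp value array as run-length-collapsed bedGraph (NaN skipped)."""
    values = np.asarray(values, dtype=float)
    with open(path, "w") as fh:
        run_start = None
        run_val = None
        for i, v in enumerate(values):
            if run_val is not None and (np.isnan(v) or v != run_val):
                fh.write(f"{chrom}\t{start + run_start}\t{start + i}\t{run_val:g}\n")
                run_start, run_val = None, None
            if run_val is None and not np.isnan(v):
                run_start, run_val = i, v
        if run_val is not None:
            fh.write(
                f"{chrom}\t{start + run_start}\t{start + values.size}\t{run_val:g}\n"
            )


def write_bigwig(
    chrom: str, start: int, values: np.ndarray, chrom_len: int, path: PathLike
) -> bool:
    """Best-effort bigWig export; returns False when pyBigWig is absent."""
    try:
        import pyBigWig
    except ImportError:
        logger.info("pyBigWig not installed; skipping bigWig output %s", path)
        return False
    bw = pyBigWig.open(str(path), "w")
    bw.addHeader([(chrom, chrom_len)])
    vals = np.asarray(values, dtype=float)
    ok = ~np.isnan(vals)
    idx = np.flatnonzero(ok)
    bw.addEntries(
        chrom, (start + idx).tolist(), values=vals[idx].tolist(), span=1
    )
    bw.close()
    return True


def read_fasta(path: PathLike) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: PathLike, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def validate_fiber_table(path: PathLike) -> int:
    """Validate a fiber table, returning the number of fibers (raises on error)."""
    return len(read_fiber_table(path))
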