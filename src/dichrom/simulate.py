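"""Synthetic Fiber-seq fixture generator with known ground truth.

Emits a reference built from a tandem alpha-satellite-like monomer array
flanked by non-satellite sequence, plants a hypo-CpG-methylated core (CDR)
inside the array, and simulates single chromatin fibers carrying:

* nucleosome footprints phased one per monomer inside the core (with a
  configurable fraction replaced by di-nucleosome-sized footprints) and
  unphased arrays at the euchromatic spacing elsewhere;
* large MTase-sensitive patches (accessible chromatin patches) placed as a
  per-fiber overdispersed (Gamma-mixed Poisson) point process;
* CENP-B boxes (exact consensus instances punctuating alternating
  monomers) whose occupancy probability depends on the molecule's CpG
  methylation state at the box's two CpG dinucleotides — occupied boxes get
  a protein-sized protected footprint with exposed flanking linkers;
* m6A events stenciled onto A/T bases of all unprotected DNA.

Everything is reproducible from one master seed via spawned child seeds,
so the reference and the fibers can be regenerated independently.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .model import (
    ConfigError,
    Fiber,
    GenomicInterval,
    SatClass,
    SatelliteAnnotation,
)
from . import io as dio

CENPB_MOTIF = "NTTCGNNNNANNCGGGN"
_BASES = np.array(list("ACGT"))
# alpha satellite is A/T rich; keeps linker A/T fraction well above 25%
_BASE_PROBS = np.array([0.3, 0.2, 0.2, 0.3])


@dataclass
class FixtureConfig:
    """Generative parameters of a synthetic centromere fixture.

    Lengths in bp, rates per kb, probabilities in [0, 1].
    """

    monomer_length: int = 170
    n_monomers: int = 0          # array_length = n_monomers * monomer_length
    flank_length: int = 20_000
    cdr_offset: Optional[int] = None   # from array start; None = no core
    cdr_length: int = 20_000
    cdr_meth: float = 0.05
    background_meth: float = 0.85
    cpg_dropout: float = 0.05
    euchromatic_spacing: int = 190
    nucleosome_len: int = 147
    nucleosome_phase_offset: int = 10  # footprint start within each monomer
    phase_core_nucleosomes: bool = True  # False: random phase inside the core
    dinucleosome_rate_core: float = 0.5
    dinuc_len_range: tuple[int, int] = (211, 300)
    msp_rate_core: float = 0.11
    msp_rate_flank: float = 0.02
    msp_cluster_factor: float = 2.0
    msp_len_range: tuple[int, int] = (151, 800)
    cenpb_spacing: int = 2             # monomers between consecutive boxes
    cenpb_offset_in_monomer: int = 60
    p_occupy_given_mcpg: dict[int, float] = field(
        default_factory=lambda: {0: 0.8, 1: 0.1, 2: 0.05}
    )
    cenpb_footprint_len: int = 60
    cenpb_linker: int = 25             # cleared accessible DNA on each side
    m6a_density_accessible: float = 0.4
    fiber_length: int = 15_000
    n_fibers: int = 300
    fiber_region: Optional[tuple[int, int]] = None  # restrict sampled spans
    chrom: str = "synth1"
    seed: int = 0

    # -- derived -----------------------------------------------------------
    @property
    def array_length(self) -> int:
        return self.n_monomers * self.monomer_length

    @property
    def reference_length(self) -> int:
        return self.array_length + 2 * self.flank_length

    def validate(self) -> None:
        probs = [
            self.cdr_meth, self.background_meth, self.cpg_dropout,
            self.m6a_density_accessible, *self.p_occupy_given_mcpg.values(),
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ConfigError("all probabilities must be in [0, 1]")
        if self.monomer_length < 50:
            raise ConfigError("monomer_length must be >= 50")
        if self.n_monomers > 0 and self.array_length < self.monomer_length:
            raise ConfigError("array shorter than one monomer")
        if self.cdr_offset is not None:
            if self.n_monomers == 0:
                raise ConfigError("a core requires a satellite array")
            if self.cdr_offset < 0 or (
                self.cdr_offset + self.cdr_length > self.array_length
            ):
                raise ConfigError("core must lie within the satellite array")
        if self.n_monomers > 0 and self.fiber_length < 2 * self.monomer_length:
            raise ConfigError("fiber_length must be >= 2 monomers")
        if self.msp_cluster_factor < 1.0:
            raise ConfigError("msp_cluster_factor must be >= 1")
        if self.fiber_length > self.reference_length:
            raise ConfigError("fiber_length exceeds reference length")

    # -- presets -----------------------------------------------------------
    @classmethod
    def core(cls, seed: int = 7, **kw) -> "FixtureConfig":
        """Centromere-core fixture: the core spans the whole array, every
        fiber lies inside it, nucleosomes phased one per monomer."""
        n_mon = kw.pop("n_monomers", 353)  # ~60 kb array
        cfg = cls(
            n_monomers=n_mon,
            flank_length=2_000,
            cdr_offset=0,
            cdr_length=n_mon * kw.get("monomer_length", 170),
            seed=seed,
            **kw,
        )
        cfg.fiber_region = (cfg.flank_length, cfg.flank_length + cfg.array_length)
        cfg.validate()
        return cfg

    @classmethod
    def euchromatic(cls, seed: int = 7, **kw) -> "FixtureConfig":
        """Euchromatic fixture: no satellite array, unphased nucleosome
        arrays at the default 190 bp spacing."""
        cfg = cls(n_monomers=0, flank_length=30_000, cdr_offset=None,
                  seed=seed, **kw)
        cfg.validate()
        return cfg

    @classmethod
    def cdr_calling(cls, seed: int = 0, **kw) -> "FixtureConfig":
        """Core-calling fixture: 300 kb array with a planted hypomethylated
        dip (default 20 kb) centered, far from both termini."""
        n_mon = kw.pop("n_monomers", 1765)  # ~300 kb
        cdr_length = kw.pop("cdr_length", 20_000)
        had_region = "fiber_region" in kw
        cfg = cls(n_monomers=n_mon, cdr_length=cdr_length, seed=seed, **kw)
        if cfg.cdr_offset is None:
            cfg.cdr_offset = (cfg.array_length - cdr_length) // 2
        if not had_region:
            cfg.fiber_region = (
                cfg.flank_length, cfg.flank_length + cfg.array_length
            )
        cfg.validate()
        return cfg

    @classmethod
    def cenpb_strata(cls, seed: int = 7, **kw) -> "FixtureConfig":
        """CENP-B scoring fixture: a core with intermediate CpG methylation
        (0.5) so boxes populate all three mCpG states, and unphased
        nucleosome arrays so the flank/core score contrast reflects box
        occupancy rather than array phasing."""
        kw.setdefault("cdr_meth", 0.5)
        kw.setdefault("n_fibers", 400)
        kw.setdefault("phase_core_nucleosomes", False)
        return cls.core(seed=seed, **kw)

    @classmethod
    def spacing(cls, cluster_factor: float, seed: int = 11, **kw) -> "FixtureConfig":
        """Patch-spacing fixture: dense, short accessible patches so that
        fiber-edge truncation of observed gaps is negligible relative to
        the mean gap."""
        kw.setdefault("msp_rate_core", 3.0)
        kw.setdefault("msp_len_range", (151, 180))
        kw.setdefault("fiber_length", 40_000)
        kw.setdefault("n_fibers", 150)
        return cls.core(seed=seed, msp_cluster_factor=cluster_factor, **kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["dinuc_len_range"] = list(self.dinuc_len_range)
        d["msp_len_range"] = list(self.msp_len_range)
        d["fiber_region"] = list(self.fiber_region) if self.fiber_region else None
        d["p_occupy_given_mcpg"] = {
            str(k): v for k, v in self.p_occupy_given_mcpg.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FixtureConfig":
        d = dict(d)
        d["p_occupy_given_mcpg"] = {
            int(k): float(v) for k, v in d["p_occupy_given_mcpg"].items()
        }
        d["dinuc_len_range"] = tuple(d["dinuc_len_range"])
        d["msp_len_range"] = tuple(d["msp_len_range"])
        if d.get("fiber_region"):
            d["fiber_region"] = tuple(d["fiber_region"])
        return cls(**d)


@dataclass
class PlantedBox:
    interval: GenomicInterval
    strand: str
    center: int
    cpg_positions: tuple[int, int]


@dataclass
class ReferenceBundle:
    config: FixtureConfig
    chrom: str
    seq: str
    annotations: list[SatelliteAnnotation]
    boxes: list[PlantedBox]
    cdr: Optional[GenomicInterval]
    array: Optional[GenomicInterval]
    at_mask: np.ndarray
    cg_sites: np.ndarray

    def expected_methylation(self) -> pd.DataFrame:
        """Bulk (infinite-coverage) per-CpG methylation fractions — the
        analog of a deep aggregate methylation track."""
        cfg = self.config
        frac = np.full(self.cg_sites.size, cfg.background_meth)
        if self.cdr is not None:
            inside = (self.cg_sites >= self.cdr.start) & (
                self.cg_sites < self.cdr.end
            )
            frac[inside] = cfg.cdr_meth
        return pd.DataFrame({"position": self.cg_sites, "fraction": frac})


@dataclass
class TruthSet:
    cdr: Optional[GenomicInterval]
    core_spacing: int
    flank_spacing: int
    fiber_msp_multiplier: dict[str, float]
    box_observations: pd.DataFrame  # box_id, fiber_id, mcpg_true, mcpg_called, occupied

    def to_json(self) -> dict:
        return {
            "cdr": None if self.cdr is None else {
                "chrom": self.cdr.chrom, "start": self.cdr.start, "end": self.cdr.end
            },
            "core_spacing": self.core_spacing,
            "flank_spacing": self.flank_spacing,
            "fiber_msp_multiplier": self.fiber_msp_multiplier,
            "box_observations": self.box_observations.to_dict(orient="list"),
        }


# ---------------------------------------------------------------------------
# reference
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.choice(4, size=n, p=_BASE_PROBS)]


def _fill_motif(rng: np.random.Generator) -> str:
    """One exact-consensus box instance; N positions drawn from {A,T} so the
    17-mer keeps exactly its two fixed CpG dinucleotides."""
    out = []
    for c in CENPB_MOTIF:
        out.append("AT"[rng.integers(2)] if c == "N" else c)
    return "".join(out)


def _contains_motif(seq: str) -> bool:
    import re

    pat = re.compile(CENPB_MOTIF.replace("N", "[ACGT]"))
    rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    return bool(pat.search(seq) or pat.search(rc))


def make_reference(config: FixtureConfig) -> ReferenceBundle:
    config.validate()
    ref_ss, _ = np.random.SeedSequence(config.seed).spawn(2)
    rng = np.random.default_rng(ref_ss)

    monomer = None
    if config.n_monomers > 0:
        for _ in range(100):
            cand = "".join(_random_seq(rng, config.monomer_length))
            # the tandem context must carry no accidental consensus match
            if not _contains_motif(cand + cand):
                monomer = cand
                break
        if monomer is None:  # pragma: no cover
            raise ConfigError("could not draw a motif-free monomer")

    flank_l = "".join(_random_seq(rng, config.flank_length))
    flank_r = "".join(_random_seq(rng, config.flank_length))

    boxes: list[PlantedBox] = []
    array_start = config.flank_length
    array_parts: list[str] = []
    off = config.cenpb_offset_in_monomer
    for k in range(config.n_monomers):
        m = monomer
        if config.cenpb_spacing > 0 and k % config.cenpb_spacing == 0:
            inst = _fill_motif(rng)
            m = monomer[:off] + inst + monomer[off + 17:]
            s = array_start + k * config.monomer_length + off
            iv = GenomicInterval(config.chrom, s, s + 17, strand="+")
            cg = tuple(s + i for i in range(16) if inst[i: i + 2] == "CG")
            assert len(cg) == 2
            boxes.append(PlantedBox(iv, "+", s + 8, cg))  # 9th base, offset +8
        array_parts.append(m)
    seq = flank_l + "".join(array_parts) + flank_r

    anns: list[SatelliteAnnotation] = []
    array_iv = None
    if config.flank_length > 0:
        anns.append(SatelliteAnnotation(
            GenomicInterval(config.chrom, 0, config.flank_length),
            SatClass.NON_SATELLITE))
    if config.n_monomers > 0:
        array_iv = GenomicInterval(
            config.chrom, array_start, array_start + config.array_length
        )
        anns.append(SatelliteAnnotation(array_iv, SatClass.ACTIVE_HOR))
    if config.flank_length > 0:
        anns.append(SatelliteAnnotation(
            GenomicInterval(config.chrom, len(seq) - config.flank_length, len(seq)),
            SatClass.NON_SATELLITE))

    cdr = None
    if config.cdr_offset is not None:
        cdr = GenomicInterval(
            config.chrom,
            array_start + config.cdr_offset,
            array_start + config.cdr_offset + config.cdr_length,
            name="planted_core",
        )

    arr = np.frombuffer(seq.encode(), dtype="S1")
    at_mask = (arr == b"A") | (arr == b"T")
    is_c = arr == b"C"
    is_g = arr == b"G"
    cg_sites = np.flatnonzero(is_c[:-1] & is_g[1:])
    return ReferenceBundle(
        config, config.chrom, seq, anns, boxes, cdr, array_iv, at_mask, cg_sites
    )


# ---------------------------------------------------------------------------
# fibers
# ---------------------------------------------------------------------------

def _gamma_multiplier(rng: np.random.Generator, factor: float) -> float:
    """Mean-1 Gamma multiplier with variance factor-1 (factor 1 -> exactly 1)."""
    if factor <= 1.0:
        return 1.0
    var = factor - 1.0
    return float(rng.gamma(shape=1.0 / var, scale=var))


def _core_segments(
    span: tuple[int, int], cdr: Optional[GenomicInterval]
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Split a fiber span into (core, non-core) segments."""
    s, e = span
    if cdr is None or cdr.end <= s or cdr.start >= e:
        return [], [(s, e)]
    cs, ce = max(s, cdr.start), min(e, cdr.end)
    non = []
    if s < cs:
        non.append((s, cs))
    if ce < e:
        non.append((ce, e))
    return [(cs, ce)], non


def simulate_fibers(
    config: FixtureConfig, bundle: ReferenceBundle
) -> tuple[list[Fiber], TruthSet]:
    config.validate()
    _, fiber_ss = np.random.SeedSequence(config.seed).spawn(2)
    children = fiber_ss.spawn(config.n_fibers)

    cdr = bundle.cdr
    mon_len = config.monomer_length
    array_start = bundle.array.start if bundle.array else 0
    lo, hi = config.fiber_region or (0, len(bundle.seq))
    if hi - lo < config.fiber_length:
        raise ConfigError("fiber_region shorter than fiber_length")

    fibers: list[Fiber] = []
    multipliers: dict[str, float] = {}
    box_rows: list[tuple] = []

    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        fid = f"fiber_{i:05d}"
        start = int(rng.integers(lo, hi - config.fiber_length + 1))
        end = start + config.fiber_length
        span = GenomicInterval(config.chrom, start, end)

        # --- CpG methylation (true state, then dropout to calls) ----------
        sites = bundle.cg_sites
        sites = sites[(sites >= start) & (sites < end - 1)]
        rate = np.full(sites.size, config.background_meth)
        if cdr is not None:
            rate[(sites >= cdr.start) & (sites < cdr.end)] = config.cdr_meth
        meth_true = rng.random(sites.size) < rate
        dropped = rng.random(sites.size) < config.cpg_dropout
        cpg_true = dict(zip(sites.tolist(), meth_true.tolist()))
        cpg_calls = {
            int(p): bool(v)
            for p, v, d in zip(sites, meth_true, dropped)
            if not d
        }

        # --- nucleosome arrays --------------------------------------------
        core_segs, other_segs = _core_segments((start, end), cdr)
        if not config.phase_core_nucleosomes:
            other_segs = sorted(core_segs + other_segs)
            core_segs = []
        nucs: list[tuple[int, int]] = []
        for cs, ce in core_segs:
            k0 = max(0, (cs - array_start) // mon_len)
            mono_starts = array_start + mon_len * np.arange(
                k0, (ce - array_start) // mon_len + 1
            )
            cand = [
                (int(m + config.nucleosome_phase_offset),
                 int(m + config.nucleosome_phase_offset + config.nucleosome_len))
                for m in mono_starts
            ]
            cand = [(a, b) for a, b in cand if a >= cs and b <= ce]
            j = 0
            while j < len(cand):
                a, b = cand[j]
                if (
                    j + 1 < len(cand)
                    and rng.random() < config.dinucleosome_rate_core
                ):
                    ln = int(rng.integers(config.dinuc_len_range[0],
                                          config.dinuc_len_range[1] + 1))
                    if a + ln <= ce:
                        nucs.append((a, a + ln))
                        j += 2
                        continue
                nucs.append((a, b))
                j += 1
        for cs, ce in other_segs:
            phase = int(rng.integers(0, config.euchromatic_spacing))
            p = cs + phase
            while p + config.nucleosome_len <= ce:
                nucs.append((p, p + config.nucleosome_len))
                p += config.euchromatic_spacing

        # --- accessible patches (large MSPs) ------------------------------
        mult = _gamma_multiplier(rng, config.msp_cluster_factor)
        multipliers[fid] = mult
        msps: list[tuple[int, int]] = []
        for segs, rate_kb in ((core_segs, config.msp_rate_core),
                              (other_segs, config.msp_rate_flank)):
            for cs, ce in segs:
                n = rng.poisson(rate_kb * mult * (ce - cs) / 1000.0)
                if n == 0:
                    continue
                starts = np.sort(rng.integers(cs, ce, size=n))
                for s0 in starts:
                    ln = int(rng.integers(config.msp_len_range[0],
                                          config.msp_len_range[1] + 1))
                    e0 = min(int(s0) + ln, ce)
                    if e0 - s0 >= config.msp_len_range[0] and all(
                        e0 <= a or s0 >= b for a, b in msps
                    ):
                        msps.append((int(s0), e0))
        nucs = _subtract_regions(nucs, msps)

        # --- CENP-B occupancy ----------------------------------------------
        half = config.cenpb_footprint_len // 2
        clear = half + config.cenpb_linker
        for bi, box in enumerate(bundle.boxes):
            c = box.center
            if c - clear < start or c + clear > end:
                continue
            p1, p2 = box.cpg_positions
            state_true = int(cpg_true.get(p1, False)) + int(cpg_true.get(p2, False))
            if p1 in cpg_calls and p2 in cpg_calls:
                state_called: Optional[int] = int(cpg_calls[p1]) + int(cpg_calls[p2])
            else:
                state_called = None
            p_occ = config.p_occupy_given_mcpg.get(state_true, 0.0)
            occupied = bool(rng.random() < p_occ)
            box_rows.append((bi, fid, state_true, state_called, occupied))
            if occupied:
                # clear nucleosomes around the box; the protein footprint
                # sits inside accessible DNA (patches are left untouched:
                # bound-protein footprints live within patches)
                nucs = _subtract_regions(nucs, [(c - clear, c + clear)])
                nucs.append((c - half, c - half + config.cenpb_footprint_len))
        nucs.sort()
        msps.sort()

        # --- m6A stenciling -------------------------------------------------
        protected = np.zeros(config.fiber_length, dtype=bool)
        for a, b in nucs:
            protected[a - start: b - start] = True
        accessible = bundle.at_mask[start:end] & ~protected
        cand = np.flatnonzero(accessible)
        events = cand[rng.random(cand.size) < config.m6a_density_accessible]
        fibers.append(Fiber(
            fid,
            span,
            (events + start).astype(np.int64),
            [GenomicInterval(config.chrom, a, b) for a, b in nucs],
            [GenomicInterval(config.chrom, a, b) for a, b in msps],
            cpg_calls,
        ))

    truth = TruthSet(
        cdr=cdr,
        core_spacing=mon_len,
        flank_spacing=config.euchromatic_spacing,
        fiber_msp_multiplier=multipliers,
        box_observations=pd.DataFrame(
            box_rows,
            columns=["box_id", "fiber_id", "mcpg_true", "mcpg_called", "occupied"],
        ),
    )
    return fibers, truth


def _subtract_regions(
    intervals: list[tuple[int, int]], cut: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Drop intervals that overlap any cut region (no trimming)."""
    if not cut:
        return sorted(intervals)
    out = []
    for a, b in sorted(intervals):
        if any(a < ce and cs < b for cs, ce in cut):
            continue
        out.append((a, b))
    return out


# ---------------------------------------------------------------------------
# fixture emission
# ---------------------------------------------------------------------------

def emit_fixture(config: FixtureConfig, outdir: str | Path, force: bool = False) -> Path:
    """Write reference, annotations, fibers, bulk methylation, truth and a
    manifest to ``outdir``. Refuses a non-empty directory unless forced."""
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise ConfigError(f"{outdir} is not empty (use force=True)")
    outdir.mkdir(parents=True, exist_ok=True)

    bundle = make_reference(config)
    fibers, truth = simulate_fibers(config, bundle)

    dio.write_fasta({bundle.chrom: bundle.seq}, outdir / "reference.fa")
    with open(outdir / "satellites.bed", "w") as fh:
        for ann in bundle.annotations:
            iv = ann.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{ann.sat_class.value}\n")
    dio.write_bed(
        [b.interval for b in bundle.boxes], outdir / "cenpb_boxes.bed"
    )
    if bundle.cdr is not None:
        dio.write_bed([bundle.cdr], outdir / "truth_cdr.bed")
    dio.write_fiber_table(fibers, outdir / "fibers.tsv")
    bundle.expected_methylation().to_csv(
        outdir / "bulk_methylation.tsv", sep="\t", index=False
    )
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth.to_json(), fh, indent=1)
    cfg = config.to_dict()
    manifest = {
        "config": cfg,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(
            yaml.safe_dump(cfg, sort_keys=True).encode()
        ).hexdigest(),
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return outdir
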