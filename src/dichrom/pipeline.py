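"""End-to-end orchestration: simulate (optional) -> cdr -> metrics ->
spectra -> cenpb, with a provenance manifest and per-stage outputs."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import cdr as _cdr
from . import cenpb as _cenpb
from . import io as dio
from . import metrics as _metrics
from . import simulate as _sim
from . import spectra as _spectra
from . import tracks as _tracks
from .model import ConfigError, GenomicInterval

logger = logging.getLogger("dichrom")


@dataclass
class RunConfig:
    outdir: str = "dichrom_out"
    seed: int = 0
    # inputs; when simulate is set they are generated instead
    simulate: Optional[dict] = None       # FixtureConfig fields
    fibers: Optional[str] = None
    reference: Optional[str] = None
    satellites: Optional[str] = None
    methylation: Optional[str] = None     # per-site TSV (position, fraction)
    core_bed: Optional[str] = None
    cdr_params: dict = field(default_factory=dict)
    dinuc_cutoff: int = _metrics.DINUC_CUTOFF
    msp_cutoff: int = _metrics.LARGE_MSP_CUTOFF
    min_period: int = _spectra.MIN_PERIOD
    max_period: int = _spectra.MAX_PERIOD
    subsample_fraction: float = 0.10
    n_subsamples: int = 1000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def validate(self) -> None:
        if self.simulate is None:
            if self.fibers is None:
                raise ConfigError("config needs either simulate: or fibers:")
            if self.satellites is None and self.core_bed is None:
                raise ConfigError(
                    "config needs a satellite BED or a core BED"
                )
            for p in (self.fibers, self.reference, self.satellites,
                      self.methylation, self.core_bed):
                if p is not None and not Path(p).exists():
                    raise ConfigError(f"input does not exist: {p}")


def run_all(config: RunConfig) -> Path:
    """Run every stage; partial outputs are preserved on stage failure."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        # ------------------------------------------------------------ inputs
        if config.simulate is not None:
            stage = "simulate"
            fix = dict(config.simulate)
            fix.setdefault("seed", config.seed)
            fcfg = _sim.FixtureConfig.from_dict({
                **_sim.FixtureConfig().to_dict(), **fix
            })
            fixdir = out / "fixture"
            _sim.emit_fixture(fcfg, fixdir, force=True)
            bundle = _sim.make_reference(fcfg)
            fibers, _ = _sim.simulate_fibers(fcfg, bundle)
            seq = bundle.seq
            annotations = bundle.annotations
            meth = bundle.expected_methylation()
            core_bed = None
        else:
            stage = "load"
            fibers = dio.read_fiber_table(config.fibers)
            seq = None
            if config.reference:
                seq = next(iter(dio.read_fasta(config.reference).values()))
            annotations = (
                dio.read_satellite_bed(config.satellites)
                if config.satellites else []
            )
            core_bed = dio.read_bed(config.core_bed) if config.core_bed else None
            if config.methylation:
                meth = pd.read_csv(config.methylation, sep="\t")
            else:
                region = _fiber_hull(fibers)
                meth = _tracks.aggregate_methylation(fibers, region)

        # ---------------------------------------------------------------- cdr
        stage = "cdr"
        params = _cdr.CdrParams(**config.cdr_params)
        calls, candidates = _cdr.call_cdrs_on_arrays(
            annotations, meth, params, core_bed=core_bed
        )
        dio.write_bed([c.interval for c in calls], out / "cdr.bed")
        _cdr.audit_table(candidates).to_csv(
            out / "cdr_audit.tsv", sep="\t", index=False
        )

        # ------------------------------------------------------------ metrics
        stage = "metrics"
        regions = [c.interval for c in calls] or [_fiber_hull(fibers)]
        summaries = _metrics.regional_summaries(
            fibers, regions, config.dinuc_cutoff, config.msp_cutoff
        )
        summaries.to_csv(out / "dichromatin_summaries.tsv", sep="\t", index=False)
        spacing_rows = []
        for r in regions:
            sp = _metrics.patch_spacing(fibers, r, config.msp_cutoff)
            spacing_rows.append({
                "region": f"{r.chrom}:{r.start}-{r.end}",
                "expected": sp.expected,
                "n_contained": sp.n_msps_contained,
                "sequenced_bases": sp.sequenced_bases,
                "median_observed": float(np.median(sp.observed))
                if sp.observed.size else None,
                "patch_count_estimate": sp.n_msps_contained
                / sp.sequenced_bases * len(r) if sp.sequenced_bases else None,
            })
        with open(out / "patch_spacing.json", "w") as fh:
            json.dump(spacing_rows, fh, indent=1)

        # ------------------------------------------------------------ spectra
        stage = "spectra"
        rows = []
        for r in regions:
            try:
                agg = _spectra.region_spectrum(
                    fibers, r, config.min_period, config.max_period
                )
            except Exception:
                continue
            peak = _spectra.peak_repeat_length(agg)[0]
            for rl, d in zip(agg.repeat_lengths, agg.densities):
                rows.append({
                    "region": f"{r.chrom}:{r.start}-{r.end}",
                    "repeat_length": rl, "median_density": d,
                    "n_fibers": agg.n_fibers, "peak": peak[0],
                })
        pd.DataFrame(rows).to_csv(out / "spectra.tsv", sep="\t", index=False)

        # -------------------------------------------------------------- cenpb
        stage = "cenpb"
        if seq is not None:
            sites = _cenpb.scan_cenpb_boxes(
                seq, [a.interval for a in annotations] or None,
                chrom=fibers[0].chrom if fibers else "ref",
            )
            dio.write_bed([s.interval for s in sites], out / "cenpb_sites.bed")
            obs = _cenpb.observe_boxes(fibers, sites)
            strata = _cenpb.stratify(obs)
            dist = {}
            for state, group in strata.items():
                try:
                    fs = _cenpb.score_distribution(
                        group, stratum=f"mcpg_{state}",
                        subsample_fraction=config.subsample_fraction,
                        n_subsamples=config.n_subsamples,
                        seed=config.seed + state,
                    )
                except Exception as exc:
                    logger.info("stratum %s skipped: %s", state, exc)
                    continue
                dist[f"mcpg_{state}"] = {
                    "score": fs.score, "n": fs.n_fibers,
                    "median_subsample": float(np.median(fs.distribution)),
                }
            with open(out / "cenpb_scores.json", "w") as fh:
                json.dump(dist, fh, indent=1)

        # ----------------------------------------------------------- manifest
        stage = "manifest"
        cfg_dict = vars(config).copy()
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "config": cfg_dict,
            "config_sha256": hashlib.sha256(
                yaml.safe_dump(cfg_dict, sort_keys=True, default_flow_style=True)
                .encode()
            ).hexdigest(),
            "outputs": sorted(
                p.name for p in out.iterdir() if p.is_file()
            ),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
    except Exception as exc:
        raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
    return out


def _fiber_hull(fibers) -> GenomicInterval:
    chrom = fibers[0].chrom
    return GenomicInterval(
        chrom,
        min(f.start for f in fibers if f.chrom == chrom),
        max(f.end for f in fibers if f.chrom == chrom),
    )
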