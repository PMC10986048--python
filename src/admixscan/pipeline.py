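"""End-to-end wiring of the two headline analyses.

``run_introgression_pipeline``: D statistic -> windowed f_d -> ancestry
window fractions -> top-ancestry overlap -> introgression BED.

``run_selection_pipeline``: PBS windows -> top-quantile threshold ->
exclusion of introgression regions -> merged sweeps -> optional GWAS
LD-block overlap.

Every output file starts with a comment header carrying the package
version, a hash of the effective configuration and the seed, so reruns are
auditable and byte-reproducible.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ancestry import (
    ancestry_window_fractions,
    naive_paint,
    read_ancestry_tsv,
    top_bottom_ancestry,
    write_ancestry_tsv,
)
from .introgression import QuartetSpec, call_introgression_regions, d_statistic, fd_windows
from .pbs import call_sweeps, overlap_with_ld_blocks, pbs_windows
from .regions import GenomeLayout, RegionSet, make_windows
from .vcf import read_vcf

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths plus every tunable default of the window scans."""

    vcf: str
    popmap: str
    ancestry_tsv: str | None = None  # None -> run the naive painter
    ld_blocks_bed: str | None = None
    introgression_bed: str | None = None  # selection stage input, if precomputed
    quartet: dict = field(
        default_factory=lambda: {"p1": "EU", "p2": "B", "p3": "AS", "outgroup": "O"}
    )
    pbs_pops: dict = field(
        default_factory=lambda: {"target": "B", "control": "EU", "outgroup": "AS"}
    )
    window_size: int = 50_000
    pbs_step: int = 2_000
    block_size: int = 5_000_000
    fd_min_sites: int = 100
    min_sites: int = 10
    fd_quantile: float = 0.05
    ancestry_tail: float = 0.05
    pbs_top_quantile: float = 0.05
    outgroup_max_derived: float = 0.1
    log_base: float = float(np.e)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _header(cfg: PipelineConfig) -> list[str]:
    return [
        f"admixscan={__version__}",
        f"config_hash={cfg.config_hash}",
        f"seed={cfg.seed}",
    ]


def _write_table(df: pd.DataFrame, path: Path, cfg: PipelineConfig) -> None:
    with open(path, "w") as fh:
        for line in _header(cfg):
            fh.write(f"#{line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def _load(cfg: PipelineConfig):
    for attr in ("vcf", "popmap"):
        p = getattr(cfg, attr)
        if not Path(p).exists():
            raise FileNotFoundError(f"{attr} file not found: {p}")
    gm = read_vcf(cfg.vcf, cfg.popmap)
    if gm.layout is None:
        raise ValueError("VCF lacks contig headers; cannot build windows")
    return gm


def run_introgression_pipeline(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Run D -> f_d -> ancestry windows -> overlap; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gm = _load(cfg)
    layout = gm.layout
    windows = make_windows(layout, cfg.window_size, cfg.window_size)
    quartet = QuartetSpec(**cfg.quartet)

    def stage(name, fn, *a, **kw):
        try:
            return fn(*a, **kw)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    dres = stage("dstat", d_statistic, gm, quartet, cfg.block_size,
                 cfg.outgroup_max_derived)
    fd = stage("fd", fd_windows, gm, quartet, windows, cfg.fd_min_sites,
               cfg.outgroup_max_derived)
    if cfg.ancestry_tsv:
        am = read_ancestry_tsv(cfg.ancestry_tsv)
    else:
        am = stage("paint", naive_paint, gm, quartet.p2, quartet.p1, quartet.p3,
                   cfg.window_size)
    wt = stage("ancestry_windows", ancestry_window_fractions, am, windows)
    high_as, high_eu = stage("ancestry_tails", top_bottom_ancestry, wt,
                             cfg.ancestry_tail)
    called = stage("call_introgression", call_introgression_regions, fd, high_as,
                   cfg.fd_quantile)

    dstat_path = outdir / "dstat.json"
    with open(dstat_path, "w") as fh:
        json.dump(
            {
                "meta": dict(x.split("=") for x in _header(cfg)),
                "d": dres.d,
                "z": None if np.isnan(dres.z) else dres.z,
                "n_blocks": dres.n_blocks,
                "n_sites": dres.n_sites,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    _write_table(fd, outdir / "fd.tsv", cfg)
    write_ancestry_tsv(am, outdir / "ancestry.tsv")
    _write_table(wt, outdir / "ancestry_windows.tsv", cfg)
    high_as.to_bed(outdir / "ancestry_high_as.bed", header=_header(cfg))
    high_eu.to_bed(outdir / "ancestry_high_eu.bed", header=_header(cfg))
    called.to_bed(outdir / "introgression.bed", header=_header(cfg))
    manifest = {
        "d": dres.d,
        "z": None if np.isnan(dres.z) else dres.z,
        "n_introgression_regions": len(called),
        "introgression_bp": called.covered_bp,
        "outputs": sorted(p.name for p in outdir.iterdir()),
    }
    log.info("introgression pipeline done: %s", manifest)
    return manifest


def run_selection_pipeline(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Run PBS -> threshold -> introgression exclusion -> sweeps -> LD
    overlap; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gm = _load(cfg)
    layout = gm.layout
    windows = make_windows(layout, cfg.window_size, cfg.pbs_step)
    pbs = pbs_windows(
        gm,
        windows,
        min_sites=cfg.min_sites,
        log_base=cfg.log_base,
        **cfg.pbs_pops,
    )
    if cfg.introgression_bed:
        introgressed = RegionSet.from_bed(cfg.introgression_bed)
    else:
        introgressed = RegionSet()
        log.info("no introgression BED supplied; excluding nothing")
    result = call_sweeps(pbs, introgressed, cfg.pbs_top_quantile, layout)

    _write_table(pbs, outdir / "pbs.tsv", cfg)
    with open(outdir / "threshold.json", "w") as fh:
        json.dump(
            {
                "meta": dict(x.split("=") for x in _header(cfg)),
                "threshold": result.threshold,
                "genome_fraction": result.genome_fraction,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    result.regions.to_bed(outdir / "sweeps.bed", header=_header(cfg))
    manifest = {
        "threshold": result.threshold,
        "n_sweep_regions": len(result.regions),
        "sweep_bp": result.regions.covered_bp,
        "genome_fraction": result.genome_fraction,
    }
    if cfg.ld_blocks_bed:
        core = overlap_with_ld_blocks(
            result.regions, RegionSet.from_bed(cfg.ld_blocks_bed)
        )
        core.to_bed(outdir / "core_regions.bed", header=_header(cfg))
        manifest["n_core_regions"] = len(core)
        manifest["core_bp"] = core.covered_bp
    else:
        log.info("no LD-block BED supplied; core-region stage skipped")
    manifest["outputs"] = sorted(p.name for p in outdir.iterdir())
    log.info("selection pipeline done: %s", manifest)
    return manifest
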