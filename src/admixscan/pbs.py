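"""Population branch statistic selection scan.

Pairwise windowed Weir-Cockerham Fst values are transformed into branch
lengths T = -log(1 - Fst) and combined as

    PBS = (T_BY + T_BO - T_YO) / 2

where B is the target (the scanned breed), Y the control population it
recently diverged from, and O the more distant reference.  A large PBS
marks allele-frequency change private to the target branch.  Negative
window Fst (common under weak differentiation) gives a negative branch
term and is deliberately retained, so PBS can go below zero; Fst is only
clamped away from 1 to keep T finite.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .regions import GenomeLayout, Region, RegionSet, genome_fraction, merge_regions
from .stats import fst_site_components, window_sums
from .vcf import GenotypeMatrix

FST_CLAMP = 1.0 - 1e-12


def _branch_length(fst: np.ndarray, log_base: float) -> np.ndarray:
    t = -np.log(1.0 - np.minimum(fst, FST_CLAMP))
    if log_base != np.e:
        t = t / np.log(log_base)
    return t


def pbs_windows(
    gm: GenotypeMatrix,
    windows: list[Region],
    target: str = "B",
    control: str = "EU",
    outgroup: str = "AS",
    min_sites: int = 10,
    log_base: float = np.e,
) -> pd.DataFrame:
    """Windowed PBS from ratio-of-sums W&C Fst of the three pairs.

    Windows with fewer than ``min_sites`` usable sites in any pair are
    missing.  ``log_base`` switches the branch-length logarithm (natural
    log by default).
    """
    if len({target, control, outgroup}) != 3:
        raise ValueError("target, control and outgroup must be distinct")
    pairs = {
        "by": (target, control),
        "bo": (target, outgroup),
        "yo": (control, outgroup),
    }
    cols = []
    for a, b in pairs.values():
        num, den, usable = fst_site_components(gm, a, b)
        cols += [num, den, usable.astype(float)]
    sums = window_sums(gm.chrom, gm.pos0, np.column_stack(cols), windows)
    fst = {}
    n_sites = {}
    for i, key in enumerate(pairs):
        num_s, den_s, n_s = sums[:, 3 * i], sums[:, 3 * i + 1], sums[:, 3 * i + 2]
        with np.errstate(invalid="ignore", divide="ignore"):
            fst[key] = np.where(den_s != 0, num_s / np.where(den_s != 0, den_s, 1), np.nan)
        n_sites[key] = n_s.astype(int)
    ok = np.ones(len(windows), dtype=bool)
    for key in pairs:
        ok &= (n_sites[key] >= min_sites) & ~np.isnan(fst[key])
    t = {k: np.where(ok, _branch_length(np.nan_to_num(fst[k]), log_base), np.nan) for k in pairs}
    pbs = (t["by"] + t["bo"] - t["yo"]) / 2.0
    return pd.DataFrame(
        {
            "chrom": [w.chrom for w in windows],
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
            "n_sites": np.minimum.reduce([n_sites[k] for k in pairs]),
            "fst_by": np.where(ok, fst["by"], np.nan),
            "fst_bo": np.where(ok, fst["bo"], np.nan),
            "fst_yo": np.where(ok, fst["yo"], np.nan),
            "t_by": t["by"],
            "t_bo": t["bo"],
            "t_yo": t["yo"],
            "pbs": pbs,
        }
    )


@dataclass(frozen=True)
class SweepCallResult:
    threshold: float
    regions: RegionSet
    genome_fraction: float | None  # None when no layout was supplied


def call_sweeps(
    pbs: pd.DataFrame,
    introgressed: RegionSet,
    top_quantile: float = 0.05,
    layout: GenomeLayout | None = None,
) -> SweepCallResult:
    """Top-PBS windows, minus any window touching an introgression region,
    merged into sweep candidates.

    The threshold is the empirical (1 - top_quantile) quantile of
    non-missing PBS; windows with PBS >= threshold pass (ties pass).  Any
    bp of overlap with ``introgressed`` disqualifies a window.
    """
    if not 0.0 < top_quantile <= 1.0:
        raise ValueError("top_quantile must lie in (0, 1]")
    vals = pbs["pbs"].to_numpy()
    ok = ~np.isnan(vals)
    if not ok.any():
        raise ValueError("no windows with defined PBS")
    threshold = float(np.quantile(vals[ok], 1.0 - top_quantile))
    intro = introgressed.merge(0)
    kept: list[Region] = []
    for i in np.flatnonzero(ok & (vals >= threshold)):
        w = Region(pbs["chrom"].iat[i], int(pbs["start"].iat[i]), int(pbs["end"].iat[i]))
        if not any(w.overlaps(r) for r in intro):
            kept.append(w)
    regions = merge_regions(kept, 0).retag("sweep")
    frac = genome_fraction(regions, layout) if layout is not None else None
    return SweepCallResult(threshold=threshold, regions=regions, genome_fraction=frac)


def overlap_with_ld_blocks(sweeps: RegionSet, ld_blocks: RegionSet) -> RegionSet:
    """Exact intersection of sweep regions with GWAS LD blocks (tag
    ``core``): the trait-associated sweep cores."""
    return sweeps.intersect(ld_blocks).retag("core")
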