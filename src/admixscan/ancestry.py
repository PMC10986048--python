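"""Local-ancestry labels for an admixed target, summarised in 50-kb windows.

A production local-ancestry tool (e.g. a mosaic-copying model) is consumed
as a site x haplotype 0/1 label TSV; for self-contained runs a deliberately
naive painter is provided that assigns each target haplotype, per fixed-bp
chunk, to the reference panel containing its nearest (minimum Hamming
distance) haplotype.  Labels: 0 = European panel, 1 = Asian panel,
-1 = unassigned (exact distance tie).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .regions import Region, RegionSet, merge_regions
from .vcf import GenotypeMatrix

UNASSIGNED = np.int8(-1)


@dataclass
class AncestryMatrix:
    """Per-site, per-target-haplotype ancestry labels aligned to a site list."""

    sites: pd.DataFrame  # chrom, pos (1-based)
    labels: np.ndarray  # int8 (n_sites, n_haplotypes) in {0, 1, -1}
    hap_ids: list[str]

    def __post_init__(self) -> None:
        if self.labels.shape != (len(self.sites), len(self.hap_ids)):
            raise ValueError("label matrix shape does not match sites/haplotypes")


def naive_paint(
    gm: GenotypeMatrix,
    target: str = "B",
    panel_eu: str = "EU",
    panel_as: str = "AS",
    chunk: int = 50_000,
) -> AncestryMatrix:
    """Chunk-wise nearest-panel-haplotype painter (ties -> unassigned).

    Missing alleles count as mismatches; the generator emits none.
    """
    for panel in (panel_eu, panel_as):
        if not gm.samples_of(panel):
            raise ValueError(f"empty reference panel {panel!r}")
    t_cols = gm.hap_columns(target)
    hap_ids = []
    for s in gm.samples_of(target):
        hap_ids += [f"{s}.0", f"{s}.1"]
    labels = np.full((gm.n_sites, len(t_cols)), UNASSIGNED, dtype=np.int8)
    chrom = gm.chrom
    pos0 = gm.pos0
    H = gm.haplotypes
    eu_cols = gm.hap_columns(panel_eu)
    as_cols = gm.hap_columns(panel_as)
    for c in pd.unique(chrom):
        cmask = chrom == c
        cpos = pos0[cmask]
        cidx = np.flatnonzero(cmask)
        n_chunks = math.ceil((cpos.max() + 1) / chunk) if len(cpos) else 0
        for k in range(n_chunks):
            in_chunk = (cpos >= k * chunk) & (cpos < (k + 1) * chunk)
            if not in_chunk.any():
                continue
            rows = cidx[in_chunk]
            T = H[np.ix_(rows, t_cols)].astype(np.float32)
            dist = {}
            for name, cols in (("eu", eu_cols), ("as", as_cols)):
                P = H[np.ix_(rows, cols)].astype(np.float32)
                # Hamming distance over 0/1 alleles via two inner products
                dist[name] = (T.T @ (1.0 - P) + (1.0 - T).T @ P).min(axis=1)
            lab = np.where(
                dist["eu"] < dist["as"], 0, np.where(dist["as"] < dist["eu"], 1, -1)
            ).astype(np.int8)
            labels[rows] = lab[None, :]
    return AncestryMatrix(
        sites=gm.sites[["chrom", "pos"]].reset_index(drop=True),
        labels=labels,
        hap_ids=hap_ids,
    )


def ancestry_window_fractions(
    am: AncestryMatrix, windows: list[Region]
) -> pd.DataFrame:
    """Per-window fraction of assigned (site x haplotype) cells labelled
    Asian (1); unassigned cells enter neither numerator nor denominator.
    Windows must be non-overlapping; all-unassigned windows are NaN.
    """
    for a, b in zip(windows, windows[1:]):
        if a.overlaps(b):
            raise ValueError("ancestry windows must be non-overlapping")
    chrom = am.sites["chrom"].to_numpy()
    pos0 = am.sites["pos"].to_numpy() - 1
    n_as = (am.labels == 1).sum(axis=1).astype(float)
    n_assigned = (am.labels >= 0).sum(axis=1).astype(float)
    from .stats import window_sums

    sums = window_sums(chrom, pos0, np.column_stack([n_as, n_assigned]), windows)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(sums[:, 1] > 0, sums[:, 0] / np.maximum(sums[:, 1], 1), np.nan)
    return pd.DataFrame(
        {
            "chrom": [w.chrom for w in windows],
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
            "n_cells": sums[:, 1].astype(int),
            "frac_as": frac,
        }
    )


def top_bottom_ancestry(
    wt: pd.DataFrame, tail: float = 0.05
) -> tuple[RegionSet, RegionSet]:
    """Call the top/bottom ``tail`` of the empirical window-fraction
    distribution: (high-Asian-ancestry set, high-European-ancestry set).

    Each tail takes ceil(tail * n_nonmissing) windows before merging; ties
    are broken by genomic order (earlier window wins).
    """
    if not 0.0 < tail <= 0.5:
        raise ValueError("tail must lie in (0, 0.5]")
    vals = wt["frac_as"].to_numpy()
    idx = np.flatnonzero(~np.isnan(vals))
    if len(idx) == 0:
        raise ValueError("no windows with assigned ancestry")
    k = int(np.ceil(tail * len(idx)))

    def take(order: np.ndarray, tag: str) -> RegionSet:
        chosen = sorted(order[:k])
        regs = [
            Region(wt["chrom"].iat[i], int(wt["start"].iat[i]), int(wt["end"].iat[i]))
            for i in chosen
        ]
        return merge_regions(regs, 0).retag(tag)

    top_order = idx[np.argsort(-vals[idx], kind="stable")]
    bot_order = idx[np.argsort(vals[idx], kind="stable")]
    return take(top_order, "high_AS"), take(bot_order, "high_EU")


# ---------------------------------------------------------------------- I/O

def write_ancestry_tsv(am: AncestryMatrix, path: str | Path) -> None:
    df = pd.DataFrame(am.labels, columns=am.hap_ids)
    df.insert(0, "pos", am.sites["pos"].to_numpy())
    df.insert(0, "chrom", am.sites["chrom"].to_numpy())
    df.to_csv(path, sep="\t", index=False)


def read_ancestry_tsv(path: str | Path) -> AncestryMatrix:
    df = pd.read_csv(path, sep="\t", comment="#")
    hap_ids = [c for c in df.columns if c not in ("chrom", "pos")]
    return AncestryMatrix(
        sites=df[["chrom", "pos"]].copy(),
        labels=df[hap_ids].to_numpy(dtype=np.int8),
        hap_ids=hap_ids,
    )
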