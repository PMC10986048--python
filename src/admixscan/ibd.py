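"""Identity-by-descent sharing contrast between two competing ancestor panels.

The genome is cut into fixed-size bins (default 10 kb).  For each bin and
each ancestor panel, nIBD = cIBD / tIBD where cIBD counts the target x
panel sample pairs with any IBD segment overlapping the bin (a pair counts
once per bin, however many haplotype combinations match) and tIBD is the
total number of such pairs.  rIBD = nIBD(EU) - nIBD(AS) contrasts European
against Asian sharing, and ZrIBD standardises rIBD over all genome bins.

Segments normally come from an external IBD caller's interval table; a
naive exact-identity scanner over phased haplotypes is provided so the
stage runs self-contained on simulated cohorts.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .regions import GenomeLayout, Region, RegionSet, merge_regions
from .vcf import GenotypeMatrix

IBD_COLUMNS = ["sample1", "sample2", "chrom", "start", "end"]


@dataclass
class IBDSegmentSet:
    """Sample-pair intervals declared identical by descent (0-based
    half-open)."""

    segments: pd.DataFrame  # sample1, sample2, chrom, start, end
    pop1: str
    pop2: str

    def __post_init__(self) -> None:
        seg = self.segments
        missing = [c for c in IBD_COLUMNS if c not in seg.columns]
        if missing:
            raise ValueError(f"IBD table lacks columns {missing}")
        if len(seg) and not (seg["start"] < seg["end"]).all():
            raise ValueError("IBD segments need start < end")
        if len(seg) and (seg["sample1"] == seg["sample2"]).any():
            raise ValueError("IBD segment pairs a sample with itself")

    def __len__(self) -> int:
        return len(self.segments)


def naive_ibd(
    gm: GenotypeMatrix,
    pop_a: str,
    pop_b: str,
    min_len: int = 100_000,
) -> IBDSegmentSet:
    """Maximal exact-identity runs between cross-population haplotype pairs.

    A run spans from its first to its last identical site (half-open at
    last+1) and is reported per sample pair (union over the four haplotype
    combinations) when at least ``min_len`` bp long.  Requires phase in
    both populations; missing alleles break runs.
    """
    for pop in (pop_a, pop_b):
        if not gm.all_phased(pop):
            raise ValueError(f"population {pop!r} is not fully phased")
    rows: list[dict] = []
    chrom_arr = gm.chrom
    pos0 = gm.pos0
    H = gm.haplotypes
    idx_a = gm.sample_indices(pop_a)
    idx_b = gm.sample_indices(pop_b)
    for c in pd.unique(chrom_arr):
        cmask = chrom_arr == c
        cpos = pos0[cmask]
        Hc = H[cmask]
        for ia in idx_a:
            sa = gm.samples[ia]
            for ib in idx_b:
                sb = gm.samples[ib]
                pair_regs: list[Region] = []
                for ha in (2 * ia, 2 * ia + 1):
                    a_col = Hc[:, ha]
                    for hb in (2 * ib, 2 * ib + 1):
                        b_col = Hc[:, hb]
                        eq = (a_col == b_col) & (a_col >= 0)
                        if not eq.any():
                            continue
                        # run-length extraction on the boolean identity track
                        d = np.diff(eq.astype(np.int8))
                        starts = np.flatnonzero(d == 1) + 1
                        ends = np.flatnonzero(d == -1) + 1
                        if eq[0]:
                            starts = np.r_[0, starts]
                        if eq[-1]:
                            ends = np.r_[ends, len(eq)]
                        lo = cpos[starts]
                        hi = cpos[ends - 1] + 1
                        keep = hi - lo >= min_len
                        pair_regs.extend(
                            Region(str(c), int(a), int(b))
                            for a, b in zip(lo[keep], hi[keep])
                        )
                for r in merge_regions(pair_regs, 0):
                    rows.append(
                        {
                            "sample1": sa,
                            "sample2": sb,
                            "chrom": r.chrom,
                            "start": r.start,
                            "end": r.end,
                        }
                    )
    seg = pd.DataFrame(rows, columns=IBD_COLUMNS)
    return IBDSegmentSet(seg, pop_a, pop_b)


def _bin_pair_counts(
    segments: pd.DataFrame, layout: GenomeLayout, bin_size: int
) -> dict[str, np.ndarray]:
    """Per-chromosome cIBD: number of distinct sample pairs with any
    segment overlapping each bin."""
    counts = {
        chrom: np.zeros(-(-length // bin_size), dtype=np.int64)
        for chrom, length in layout.items()
    }
    if not len(segments):
        return counts
    for (s1, s2, chrom), grp in segments.groupby(
        ["sample1", "sample2", "chrom"], sort=False
    ):
        n_bins = len(counts[chrom])
        diff = np.zeros(n_bins + 1, dtype=np.int64)
        # a segment touches every bin it overlaps by >= 1 bp; bin intervals
        # of distinct segments can collide even when the segments do not,
        # so dedup per pair happens on bin indices
        bin_ivals = [
            (int(a) // bin_size, min(-(-int(b) // bin_size), n_bins))
            for a, b in zip(grp["start"], grp["end"])
        ]
        bin_ivals.sort()
        cur_lo, cur_hi = bin_ivals[0]
        merged_ivals = []
        for lo, hi in bin_ivals[1:]:
            if lo <= cur_hi:
                cur_hi = max(cur_hi, hi)
            else:
                merged_ivals.append((cur_lo, cur_hi))
                cur_lo, cur_hi = lo, hi
        merged_ivals.append((cur_lo, cur_hi))
        for lo, hi in merged_ivals:
            diff[lo] += 1
            diff[hi] -= 1
        counts[chrom] += np.cumsum(diff[:-1])
    return counts


def ribd_bins(
    segs_eu: IBDSegmentSet,
    segs_as: IBDSegmentSet,
    n_b: int,
    n_eu: int,
    n_as: int,
    layout: GenomeLayout,
    bin_size: int = 10_000,
) -> pd.DataFrame:
    """Genome bins with nIBD toward each panel, rIBD and genome-wide ZrIBD.

    ZrIBD standardises rIBD by the mean and s.d. over *all* genome bins
    (zero-sharing bins included).  Raises when the genome has no bins or
    the rIBD distribution is degenerate (s.d. zero, e.g. no segments).
    """
    if layout.total_bp == 0 or bin_size <= 0:
        raise ValueError("need a non-empty layout and positive bin size")
    c_eu = _bin_pair_counts(segs_eu.segments, layout, bin_size)
    c_as = _bin_pair_counts(segs_as.segments, layout, bin_size)
    frames = []
    for chrom, length in layout.items():
        n_bins = -(-length // bin_size)
        starts = np.arange(n_bins) * bin_size
        ends = np.minimum(starts + bin_size, length)
        nibd_eu = c_eu[chrom] / (n_b * n_eu)
        nibd_as = c_as[chrom] / (n_b * n_as)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": ends,
                    "cibd_eu": c_eu[chrom],
                    "cibd_as": c_as[chrom],
                    "nibd_eu": nibd_eu,
                    "nibd_as": nibd_as,
                    "ribd": nibd_eu - nibd_as,
                }
            )
        )
    bins = pd.concat(frames, ignore_index=True)
    if bins.empty:
        raise ValueError("genome produced zero bins")
    mu = bins["ribd"].mean()
    sd = bins["ribd"].std(ddof=0)
    if sd == 0:
        raise ValueError("rIBD distribution is constant; ZrIBD undefined")
    bins["zribd"] = (bins["ribd"] - mu) / sd
    bins.attrs["tibd_eu"] = n_b * n_eu
    bins.attrs["tibd_as"] = n_b * n_as
    return bins


def call_yorkshire_like(
    bins: pd.DataFrame,
    ancestry_high_eu: RegionSet,
    z_sd: float = 2.0,
    nibd_min: float = 0.80,
) -> RegionSet:
    """Bins with ZrIBD > ``z_sd`` and nIBD(EU) > ``nibd_min``, kept only
    inside the high-European-ancestry windows, merged with gap 0."""
    passing = bins[(bins["zribd"] > z_sd) & (bins["nibd_eu"] > nibd_min)]
    regs = [
        Region(r.chrom, int(r.start), int(r.end))
        for r in passing.itertuples(index=False)
    ]
    return (
        merge_regions(regs, 0)
        .intersect(ancestry_high_eu)
        .merge(0)
        .retag("yorkshire_like")
    )


# ---------------------------------------------------------------------- I/O

def read_ibd_tsv(
    path: str | Path, pop1: str, pop2: str, one_based: bool = False
) -> IBDSegmentSet:
    """Read ``sample1 sample2 chrom start end`` (0-based half-open, or
    1-based inclusive with ``one_based=True``)."""
    seg = pd.read_csv(path, sep="\t", comment="#")
    if one_based:
        seg = seg.assign(start=seg["start"] - 1)
    return IBDSegmentSet(seg[IBD_COLUMNS].copy(), pop1, pop2)


def write_ibd_tsv(segs: IBDSegmentSet, path: str | Path) -> None:
    segs.segments.to_csv(path, sep="\t", index=False)
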