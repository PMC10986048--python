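"""ABBA-BABA tests: genome-wide D with block-jackknife Z and windowed f_d.

Sign conventions (deliberately different between the two statistics, each
following the tool lineage it reproduces):

* ``d_statistic`` uses the qpDstat orientation
  D = sum (p1 - p2)(p3 - pO) / sum (p1 + p2 - 2 p1 p2) p3' ... i.e.
  (BABA - ABBA) / (BABA + ABBA): gene flow between P2 and P3 drives D (and
  its jackknife Z) negative, gene flow between P1 and P3 drives it
  positive.
* ``fd_windows`` uses the windowed admixture-fraction estimator's
  orientation, D_window = (ABBA - BABA) / (ABBA + BABA), so P3-into-P2
  introgression gives positive window D and a meaningful f_d in (0, 1].
  Windows with D_window < 0, or with D_window > 0 but raw f_d > 1, are
  clamped to zero; windows below the site minimum are missing.

Derived alleles are polarised by the outgroup: the outgroup major allele is
ancestral, and sites where the outgroup's derived frequency exceeds a
threshold (or is missing) are excluded.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .regions import Region, RegionSet, make_windows, merge_regions
from .stats import hap_freq, window_sums
from .vcf import GenotypeMatrix


@dataclass(frozen=True)
class QuartetSpec:
    """Role assignment ((P1, P2), P3, O) for the four-taxon tests."""

    p1: str
    p2: str
    p3: str
    outgroup: str

    def __post_init__(self) -> None:
        roles = (self.p1, self.p2, self.p3, self.outgroup)
        if len(set(roles)) != 4:
            raise ValueError(f"quartet roles must be four distinct populations: {roles}")


@dataclass(frozen=True)
class DResult:
    d: float
    z: float  # NaN when jackknife variance is zero
    n_blocks: int
    n_sites: int


def polarized_frequencies(
    gm: GenotypeMatrix,
    q: QuartetSpec,
    outgroup_max_derived: float = 0.1,
    min_alleles: int = 2,
):
    """Per-site derived-allele frequencies (p1, p2, p3, pO) after outgroup
    polarisation, plus the retained-site mask.

    Ancestral is the outgroup major allele; sites are dropped when any
    population has fewer than ``min_alleles`` called haplotypes or the
    outgroup derived frequency exceeds ``outgroup_max_derived``.
    """
    freqs = {}
    ok = np.ones(gm.n_sites, dtype=bool)
    for pop in (q.p1, q.p2, q.p3, q.outgroup):
        f, n = hap_freq(gm, pop)
        freqs[pop] = f
        ok &= n >= min_alleles
    p_o_alt = freqs[q.outgroup]
    flip = p_o_alt > 0.5  # ALT is ancestral there; derived = REF
    out = {}
    for pop in (q.p1, q.p2, q.p3, q.outgroup):
        out[pop] = np.where(flip, 1.0 - freqs[pop], freqs[pop])
    ok &= np.nan_to_num(out[q.outgroup], nan=1.0) <= outgroup_max_derived
    return out[q.p1], out[q.p2], out[q.p3], out[q.outgroup], ok


def _pattern_sums(p1, p2, p3, po):
    abba = (1 - p1) * p2 * p3 * (1 - po)
    baba = p1 * (1 - p2) * p3 * (1 - po)
    return abba, baba


def d_statistic(
    gm: GenotypeMatrix,
    q: QuartetSpec,
    block_size: int = 5_000_000,
    outgroup_max_derived: float = 0.1,
    min_alleles: int = 2,
) -> DResult:
    """Genome-wide D with a weighted block-jackknife Z score.

    Blocks are contiguous ``block_size``-bp tiles; blocks without
    informative sites are dropped, and at least two non-empty blocks are
    required for the jackknife variance.  Equal blocks give variance zero;
    Z is then reported missing (NaN) with a warning rather than inflated.
    """
    p1, p2, p3, po, ok = polarized_frequencies(
        gm, q, outgroup_max_derived, min_alleles
    )
    abba, baba = _pattern_sums(p1, p2, p3, po)
    num = np.where(ok, baba - abba, 0.0)
    den = np.where(ok, baba + abba, 0.0)
    num = np.nan_to_num(num)
    den = np.nan_to_num(den)
    informative = ok & (den > 0)

    if gm.layout is None:
        raise ValueError("genotype matrix lacks a genome layout for blocking")
    blocks = make_windows(gm.layout, block_size, block_size)
    sums = window_sums(
        gm.chrom,
        gm.pos0,
        np.column_stack([num, den, informative.astype(float)]),
        blocks,
    )
    m = sums[:, 2]
    keep = m > 0
    if keep.sum() < 2:
        raise ValueError("fewer than 2 non-empty jackknife blocks")
    num_b, den_b, m_b = sums[keep, 0], sums[keep, 1], sums[keep, 2]
    num_tot, den_tot, n_tot = num_b.sum(), den_b.sum(), m_b.sum()
    if den_tot == 0:
        raise ValueError("no informative ABBA/BABA sites")
    d_hat = num_tot / den_tot

    # weighted delete-one-block jackknife (Busing et al. 1999)
    d_minus = (num_tot - num_b) / (den_tot - den_b)
    h = n_tot / m_b
    n_blocks = len(m_b)
    theta_jack = n_blocks * d_hat - np.sum((1.0 - m_b / n_tot) * d_minus)
    tau = h * d_hat - (h - 1.0) * d_minus
    var = np.sum((tau - theta_jack) ** 2 / (h - 1.0)) / n_blocks
    if var <= 0:
        warnings.warn("jackknife variance is zero; Z reported as missing")
        z = float("nan")
    else:
        z = d_hat / np.sqrt(var)
    return DResult(d=float(d_hat), z=float(z), n_blocks=n_blocks, n_sites=int(n_tot))


def fd_windows(
    gm: GenotypeMatrix,
    q: QuartetSpec,
    windows: list[Region],
    min_sites: int = 100,
    outgroup_max_derived: float = 0.1,
    min_alleles: int = 2,
) -> pd.DataFrame:
    """Windowed f_d with the dynamic-donor denominator.

    Per site the donor P_D is whichever of P2/P3 has the higher derived
    frequency; f_d = S(P1,P2,P3,O) / S(P1,P_D,P_D,O) with
    S = sum(ABBA - BABA).  Returns columns chrom,start,end,n_sites,d,fd;
    ``fd`` is NaN when the window has fewer than ``min_sites`` retained
    sites, else clamped into [0, 1] by the rules above.
    """
    p1, p2, p3, po, ok = polarized_frequencies(
        gm, q, outgroup_max_derived, min_alleles
    )
    abba, baba = _pattern_sums(p1, p2, p3, po)
    pd_ = np.maximum(p2, p3)
    abba_d = (1 - p1) * pd_ * pd_ * (1 - po)
    baba_d = p1 * (1 - pd_) * pd_ * (1 - po)
    cols = np.column_stack(
        [
            np.nan_to_num(np.where(ok, abba - baba, 0.0)),
            np.nan_to_num(np.where(ok, abba + baba, 0.0)),
            np.nan_to_num(np.where(ok, abba_d - baba_d, 0.0)),
            ok.astype(float),
        ]
    )
    sums = window_sums(gm.chrom, gm.pos0, cols, windows)
    n_sites = sums[:, 3].astype(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        d_win = np.where(sums[:, 1] > 0, sums[:, 0] / sums[:, 1], 0.0)
        fd_raw = np.where(sums[:, 2] != 0, sums[:, 0] / sums[:, 2], 0.0)
    # the >1 clamp tolerates float error: complete replacement makes the
    # numerator and denominator analytically equal, so raw f_d sits at 1
    # up to summation order
    eps = 1e-9
    fd_raw = np.where(np.abs(fd_raw - 1.0) <= eps, 1.0, fd_raw)
    fd = np.where((d_win < 0) | (fd_raw > 1.0) | (fd_raw < 0.0), 0.0, fd_raw)
    fd = np.where(n_sites >= min_sites, fd, np.nan)
    d_win = np.where(n_sites >= min_sites, d_win, np.nan)
    return pd.DataFrame(
        {
            "chrom": [w.chrom for w in windows],
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
            "n_sites": n_sites,
            "d": d_win,
            "fd": fd,
        }
    )


def call_introgression_regions(
    fd: pd.DataFrame,
    ancestry_top: RegionSet,
    fd_quantile: float = 0.05,
) -> RegionSet:
    """Candidate introgression = top-f_d windows intersected with the
    high-donor-ancestry windows.

    The top ``fd_quantile`` of non-missing f_d windows (count-based,
    ceil(q n); ties broken by genomic order, earlier window wins) are merged
    with gap 0, intersected with ``ancestry_top`` and tagged
    ``introgressed``.
    """
    if not 0.0 < fd_quantile <= 1.0:
        raise ValueError("fd_quantile must lie in (0, 1]")
    vals = fd["fd"].to_numpy()
    ok = ~np.isnan(vals)
    if not ok.any():
        raise ValueError("all f_d windows are missing")
    idx = np.flatnonzero(ok)
    k = int(np.ceil(fd_quantile * len(idx)))
    order = idx[np.argsort(-vals[idx], kind="stable")][:k]
    top = [
        Region(fd["chrom"].iat[i], int(fd["start"].iat[i]), int(fd["end"].iat[i]))
        for i in sorted(order)
    ]
    merged = merge_regions(top, 0)
    return merged.intersect(ancestry_top).merge(0).retag("introgressed")
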