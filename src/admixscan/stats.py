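"""Per-site allele frequencies and windowed pairwise statistics.

Two distance statistics live here:

* Weir & Cockerham (1984) Fst, combined per window as a ratio of sums
  (sum of the among-population variance component a over sum of a+b+c),
  the "weighted" estimator VCFtools reports.  Negative estimates are kept.
* d_xy, the mean number of differences between haplotypes drawn one from
  each population, computed per site from allele frequencies
  (p_x (1-p_y) + (1-p_x) p_y), which equals the exact all-pairs haplotype
  enumeration under per-site pairwise deletion of missing alleles.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .regions import Region
from .vcf import GenotypeMatrix


# ------------------------------------------------------------- frequencies

def site_frequencies(
    gm: GenotypeMatrix, pops: list[str] | tuple[str, ...], min_alleles: int = 2
) -> pd.DataFrame:
    """Per-site ALT counts and called-allele counts per population.

    Adds one usability flag per population (called alleles >= min_alleles)
    and a combined ``usable`` flag requiring every requested population.
    """
    known = set(gm.populations)
    for pop in pops:
        if pop not in known:
            raise KeyError(f"unknown population {pop!r}; matrix has {sorted(known)}")
    out = {"chrom": gm.chrom, "pos": gm.sites["pos"].to_numpy()}
    usable = np.ones(gm.n_sites, dtype=bool)
    for pop in pops:
        h = gm.haps(pop)
        called = (h >= 0).sum(axis=1)
        alt = np.where(h > 0, h, 0).sum(axis=1)
        out[f"alt_{pop}"] = alt
        out[f"called_{pop}"] = called
        ok = called >= min_alleles
        out[f"usable_{pop}"] = ok
        usable &= ok
    out["usable"] = usable
    return pd.DataFrame(out)


def hap_freq(gm: GenotypeMatrix, pop: str) -> tuple[np.ndarray, np.ndarray]:
    """(ALT haplotype frequency, called haplotype count) per site."""
    h = gm.haps(pop)
    called = (h >= 0).sum(axis=1)
    alt = np.where(h > 0, h, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(called > 0, alt / np.maximum(called, 1), np.nan)
    return freq, called


# ----------------------------------------------------------------- windows

def window_sums(
    chrom: np.ndarray,
    pos0: np.ndarray,
    values: np.ndarray,
    windows: list[Region],
) -> np.ndarray:
    """Sum per-site ``values`` (n_sites, k) over possibly-sliding windows.

    Sites must be sorted by (chrom, pos).  Uses prefix sums per chromosome,
    so overlapping windows cost O(log n) each.
    """
    values = np.atleast_2d(values.T).T  # ensure 2-D (n_sites, k)
    result = np.zeros((len(windows), values.shape[1]))
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for c in pd.unique(chrom):
        m = chrom == c
        p = pos0[m]
        csum = np.vstack(
            [np.zeros(values.shape[1]), np.cumsum(values[m], axis=0)]
        )
        by_chrom[str(c)] = (p, csum)
    for i, w in enumerate(windows):
        if w.chrom not in by_chrom:
            continue
        p, csum = by_chrom[w.chrom]
        lo = np.searchsorted(p, w.start, side="left")
        hi = np.searchsorted(p, w.end, side="left")
        result[i] = csum[hi] - csum[lo]
    return result


# --------------------------------------------------------------------- Fst

def wc_fst_components(
    n1: np.ndarray, p1: np.ndarray, h1: np.ndarray,
    n2: np.ndarray, p2: np.ndarray, h2: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir & Cockerham (1984) per-site variance components for two
    populations of diploids.

    Parameters are per-population: n (called diploid count), p (ALT allele
    frequency) and h (observed heterozygote frequency).  Returns the
    among-population component ``a``, between-individual ``b`` and
    within-individual ``c``.  Requires n >= 2 in both populations.
    """
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0) / (nbar - 1.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1 - pbar) - s2 * (r - 1.0) / r - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
    )
    c = hbar / 2.0
    return a, b, c


def _diploid_summary(gm: GenotypeMatrix, pop: str):
    dosage, called = gm.diploid(pop)
    n = called.sum(axis=1).astype(float)
    alt = np.where(called, dosage, 0).sum(axis=1)
    het = (np.where(called, dosage, -9) == 1).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / np.maximum(2.0 * n, 1.0), np.nan)
        h = np.where(n > 0, het / np.maximum(n, 1.0), np.nan)
    return n, p, h


def fst_site_components(
    gm: GenotypeMatrix, pop_a: str, pop_b: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (a, a+b+c, usable) arrays for a population pair; sites with
    fewer than 2 called diploids in either population are unusable and
    contribute zero."""
    if pop_a == pop_b:
        raise ValueError("Fst requires two distinct populations")
    n1, p1, h1 = _diploid_summary(gm, pop_a)
    n2, p2, h2 = _diploid_summary(gm, pop_b)
    usable = (n1 >= 2) & (n2 >= 2)
    a, b, c = wc_fst_components(n1, p1, h1, n2, p2, h2)
    num = np.where(usable, a, 0.0)
    den = np.where(usable, a + b + c, 0.0)
    num = np.nan_to_num(num)
    den = np.nan_to_num(den)
    return num, den, usable


def fst_weir_cockerham(
    gm: GenotypeMatrix,
    pop_a: str,
    pop_b: str,
    windows: list[Region],
    min_sites: int = 10,
) -> pd.DataFrame:
    """Windowed W&C Fst by ratio of sums; windows with fewer than
    ``min_sites`` usable sites report NaN."""
    num, den, usable = fst_site_components(gm, pop_a, pop_b)
    sums = window_sums(
        gm.chrom, gm.pos0, np.column_stack([num, den, usable.astype(float)]), windows
    )
    n_sites = sums[:, 2].astype(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(
            (n_sites >= min_sites) & (sums[:, 1] != 0.0),
            sums[:, 0] / np.where(sums[:, 1] != 0.0, sums[:, 1], 1.0),
            np.nan,
        )
    return pd.DataFrame(
        {
            "chrom": [w.chrom for w in windows],
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
            "n_sites": n_sites,
            "fst": fst,
        }
    )


# --------------------------------------------------------------------- dxy

def dxy(
    gm: GenotypeMatrix,
    pop_x: str,
    pop_y: str,
    windows: list[Region],
    denominator: str = "per_used_site",
    min_sites: int = 10,
    min_alleles: int = 2,
) -> pd.DataFrame:
    """Windowed mean cross-population haplotype difference.

    ``denominator`` is ``per_used_site`` (average over usable sites) or
    ``per_bp`` (divide by window length).
    """
    if denominator not in ("per_used_site", "per_bp"):
        raise ValueError("denominator must be 'per_used_site' or 'per_bp'")
    px, nx = hap_freq(gm, pop_x)
    py, ny = hap_freq(gm, pop_y)
    usable = (nx >= min_alleles) & (ny >= min_alleles)
    d = np.where(usable, px * (1 - py) + (1 - px) * py, 0.0)
    d = np.nan_to_num(d)
    sums = window_sums(
        gm.chrom, gm.pos0, np.column_stack([d, usable.astype(float)]), windows
    )
    n_sites = sums[:, 1].astype(int)
    value = np.full(len(windows), np.nan)
    ok = n_sites >= max(min_sites, 1)
    if denominator == "per_used_site":
        value[ok] = sums[ok, 0] / n_sites[ok]
    else:
        lengths = np.array([w.length for w in windows], dtype=float)
        value[ok] = sums[ok, 0] / lengths[ok]
    return pd.DataFrame(
        {
            "chrom": [w.chrom for w in windows],
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
            "n_sites": n_sites,
            "dxy": value,
        }
    )


def dxy_preference_fraction(
    dxy_b_vs_as: pd.DataFrame, dxy_b_vs_eu: pd.DataFrame
) -> float:
    """Fraction of windows where the target is closer to the Asian ancestor
    than to the European one (ties count as not-lower); windows missing in
    either table are excluded from the denominator."""
    key = ["chrom", "start", "end"]
    if not dxy_b_vs_as[key].equals(dxy_b_vs_eu[key]):
        raise ValueError("window lists differ between the two dxy tables")
    a = dxy_b_vs_as["dxy"].to_numpy()
    e = dxy_b_vs_eu["dxy"].to_numpy()
    ok = ~np.isnan(a) & ~np.isnan(e)
    if not ok.any():
        raise ValueError("no windows with dxy defined in both tables")
    return float(np.mean(a[ok] < e[ok]))
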