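"""Independent brute-force oracles used across the suite.

Every function here recomputes a quantity by direct enumeration (per-base
boolean arrays, per-haplotype double loops, scalar single-site formulas),
deliberately sharing no code with the library paths it checks.
"""
from __future__ import annotations

import numpy as np


def region_bool(regions, length: int, chrom: str) -> np.ndarray:
    """Per-base membership array for one chromosome."""
    out = np.zeros(length, dtype=bool)
    for r in regions:
        if r.chrom == chrom:
            out[r.start : r.end] = True
    return out


def dxy_pairs(hx: np.ndarray, hy: np.ndarray) -> float:
    """Mean per-site differences over all cross-population haplotype pairs,
    summed over sites; missing alleles excluded pairwise per site."""
    n_sites = hx.shape[0]
    acc = 0.0
    for s in range(n_sites):
        diffs = 0
        pairs = 0
        for i in range(hx.shape[1]):
            if hx[s, i] < 0:
                continue
            for j in range(hy.shape[1]):
                if hy[s, j] < 0:
                    continue
                pairs += 1
                diffs += int(hx[s, i] != hy[s, j])
        if pairs:
            acc += diffs / pairs
    return acc


def wc_single_site(gt_a: list[int], gt_b: list[int]):
    """Scalar Weir & Cockerham (1984) components for one site and two
    populations of diploid ALT dosages (missing coded -1)."""
    ga = [g for g in gt_a if g >= 0]
    gb = [g for g in gt_b if g >= 0]
    n1, n2 = len(ga), len(gb)
    if n1 < 2 or n2 < 2:
        return None
    p1 = sum(ga) / (2 * n1)
    p2 = sum(gb) / (2 * n2)
    h1 = sum(1 for g in ga if g == 1) / n1
    h2 = sum(1 for g in gb if g == 1) / n2
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c


def fd_window_recompute(p1, p2, p3, po, keep):
    """Window f_d and D from per-site pattern sums, scalar loop."""
    num = den_d = den_fd = 0.0
    for k in range(len(p1)):
        if not keep[k]:
            continue
        abba = (1 - p1[k]) * p2[k] * p3[k] * (1 - po[k])
        baba = p1[k] * (1 - p2[k]) * p3[k] * (1 - po[k])
        pdon = max(p2[k], p3[k])
        abba_d = (1 - p1[k]) * pdon * pdon * (1 - po[k])
        baba_d = p1[k] * (1 - pdon) * pdon * (1 - po[k])
        num += abba - baba
        den_d += abba + baba
        den_fd += abba_d - baba_d
    d = num / den_d if den_d > 0 else 0.0
    fd = num / den_fd if den_fd != 0 else 0.0
    if d < 0 or fd > 1 or fd < 0:
        fd = 0.0
    return d, fd


def ibd_bin_pair_counts(segments, n_bins: int, bin_size: int, chrom: str):
    """Per-bin distinct-pair counts by per-base overlap testing."""
    counts = np.zeros(n_bins, dtype=int)
    pairs = {}
    for row in segments.itertuples(index=False):
        if row.chrom != chrom:
            continue
        pairs.setdefault((row.sample1, row.sample2), []).append((row.start, row.end))
    for b in range(n_bins):
        lo, hi = b * bin_size, (b + 1) * bin_size
        for segs in pairs.values():
            if any(s < hi and lo < e for s, e in segs):
                counts[b] += 1
    return counts
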