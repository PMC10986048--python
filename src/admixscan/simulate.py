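"""Seeded synthetic cohorts with planted introgression, sweeps and IBD tracts.

The generator emulates the study design the scans assume: a target breed B
descended mostly from a European ancestor panel (EU), an Asian ancestor
panel (AS), and a distant outgroup (O) that carries the ancestral allele at
nearly every site.

Model
-----
Per site, an ancestral derived-allele frequency p is drawn uniform on
(0.05, 0.95).  Each ingroup population's frequency is drawn from a
Balding-Nichols beta with mean p and its drift parameter F; the outgroup's
derived frequency is drawn from a Balding-Nichols beta with a small mean
(near-monomorphic ancestral carrier), so outgroup polarisation of "derived"
is well defined.  Haplotypes are sampled binomially per site and phased
trivially.  Sites are independent (no background LD); linkage signal exists
only inside planted tracts, where haplotype copying creates perfect local
haplotype structure — exactly what the window scans need to detect.

Planted structure (each with a truth table):

* introgression tracts: a fraction ``f`` of B haplotypes is replaced by
  copies of randomly chosen AS haplotypes;
* sweep tracts: B's frequency is shifted by ``delta`` toward the locally
  major allele (clipped to [0, 1]) before haplotype sampling;
* IBD tracts: a founder haplotype (taken from the first designated EU
  sample) is written onto both haplotypes of every designated B sample and
  onto haplotype 0 of every designated EU sample, so each designated
  B x EU pair is identical by descent across the tract.

All randomness flows from ``SimConfig.seed``; the same config yields
byte-identical VCF output.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genetrees import GeneTreeRecord
from .regions import GenomeLayout, Region, RegionSet, intersect_regions
from .vcf import GenotypeMatrix, write_popmap, write_vcf

POPS = ("B", "EU", "AS", "O")


@dataclass(frozen=True)
class IntrogressionTract:
    region: Region
    fraction: float  # fraction of B haplotypes replaced by AS copies

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("introgression fraction must lie in [0, 1]")


@dataclass(frozen=True)
class SweepTract:
    region: Region
    delta: float  # frequency shift toward the locally major allele in B

    def __post_init__(self) -> None:
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError("sweep delta must lie in [0, 1]")


@dataclass(frozen=True)
class IBDTract:
    """Planted haplotype sharing between B and EU samples.

    ``pairs`` are (B sample index, EU sample index) tuples; every sample
    appearing in any pair receives the tract's founder haplotype.
    """

    region: Region
    pairs: tuple[tuple[int, int], ...]


@dataclass
class SimConfig:
    layout: GenomeLayout
    snp_density: float = 0.005  # sites per bp (5 per kb, a scaled-down WGS density)
    n_samples: dict[str, int] = field(
        default_factory=lambda: {"B": 20, "EU": 20, "AS": 20, "O": 6}
    )
    # moderate breed drift for the target and its European ancestor, deeper
    # drift for the Asian lineage, reproducing the study system's Fst
    # ordering (target closer to the European than to the Asian ancestor)
    drift: dict[str, float] = field(
        default_factory=lambda: {"B": 0.1, "EU": 0.1, "AS": 0.3, "O": 0.5}
    )
    outgroup_ancestral_freq: float = 0.02
    introgression_tracts: tuple[IntrogressionTract, ...] = ()
    sweep_tracts: tuple[SweepTract, ...] = ()
    ibd_tracts: tuple[IBDTract, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        for pop in POPS:
            if pop not in self.n_samples or pop not in self.drift:
                raise ValueError(f"population {pop} missing from config")
            if not 0.0 < self.drift[pop] < 1.0:
                raise ValueError(f"drift F for {pop} must lie in (0, 1)")
        for tract in (
            *self.introgression_tracts,
            *self.sweep_tracts,
            *self.ibd_tracts,
        ):
            if tract.region.end > self.layout.length_of(tract.region.chrom):
                raise ValueError(f"tract {tract.region} outside genome layout")
        sweep = RegionSet(t.region for t in self.sweep_tracts)
        intro = RegionSet(t.region for t in self.introgression_tracts)
        if len(intersect_regions(sweep, intro)):
            raise ValueError(
                "sweep and introgression tracts overlap; the pipeline treats "
                "them as exclusive"
            )


@dataclass
class TruthTables:
    introgression: RegionSet
    sweeps: RegionSet
    ibd_segments: pd.DataFrame  # sample1, sample2, chrom, start, end
    ancestral_allele: np.ndarray  # per site, 0 = REF is ancestral


def _balding_nichols(rng: np.random.Generator, mean: np.ndarray | float, f: float,
                     size: int) -> np.ndarray:
    mean = np.broadcast_to(np.asarray(mean, dtype=float), (size,))
    scale = (1.0 - f) / f
    return rng.beta(np.maximum(mean * scale, 1e-12),
                    np.maximum((1.0 - mean) * scale, 1e-12))


def simulate_cohort(cfg: SimConfig) -> tuple[GenotypeMatrix, TruthTables]:
    """Draw a phased cohort and its truth tables from a single seed."""
    rng = np.random.default_rng(cfg.seed)
    sample_names = {
        pop: [f"{pop}_{i:02d}" for i in range(cfg.n_samples[pop])] for pop in POPS
    }

    chrom_frames: list[pd.DataFrame] = []
    chrom_blocks: list[np.ndarray] = []
    ibd_rows: list[dict] = []

    for chrom, length in cfg.layout.items():
        n_sites = int(round(cfg.snp_density * length))
        pos0 = np.sort(rng.choice(length, size=n_sites, replace=False))
        p_anc = rng.uniform(0.05, 0.95, n_sites)

        freqs: dict[str, np.ndarray] = {}
        for pop in POPS:
            if pop == "O":
                freqs[pop] = _balding_nichols(
                    rng, cfg.outgroup_ancestral_freq, cfg.drift["O"], n_sites
                )
            else:
                freqs[pop] = _balding_nichols(rng, p_anc, cfg.drift[pop], n_sites)

        # sweeps act on B's frequency before haplotype sampling
        for tract in cfg.sweep_tracts:
            if tract.region.chrom != chrom:
                continue
            mask = (pos0 >= tract.region.start) & (pos0 < tract.region.end)
            p_b = freqs["B"][mask]
            shift = np.where(p_b >= 0.5, tract.delta, -tract.delta)
            freqs["B"][mask] = np.clip(p_b + shift, 0.0, 1.0)

        haps: dict[str, np.ndarray] = {}
        for pop in POPS:
            n_hap = 2 * cfg.n_samples[pop]
            haps[pop] = (
                rng.random((n_sites, n_hap)) < freqs[pop][:, None]
            ).astype(np.int8)

        for tract in cfg.introgression_tracts:
            if tract.region.chrom != chrom:
                continue
            mask = np.flatnonzero(
                (pos0 >= tract.region.start) & (pos0 < tract.region.end)
            )
            n_hap_b = haps["B"].shape[1]
            k = int(round(tract.fraction * n_hap_b))
            recipients = rng.choice(n_hap_b, size=k, replace=False)
            # distinct donor lineages while the donor panel lasts: keeps the
            # copied set's allele frequency matched to the donor panel's
            n_donor = haps["AS"].shape[1]
            if k <= n_donor:
                donors = rng.permutation(n_donor)[:k]
            else:
                donors = rng.integers(0, n_donor, size=k)
            haps["B"][np.ix_(mask, recipients)] = haps["AS"][np.ix_(mask, donors)]

        for tract in cfg.ibd_tracts:
            if tract.region.chrom != chrom:
                continue
            mask = np.flatnonzero(
                (pos0 >= tract.region.start) & (pos0 < tract.region.end)
            )
            b_idx = sorted({b for b, _ in tract.pairs})
            eu_idx = sorted({e for _, e in tract.pairs})
            founder = haps["EU"][mask, 2 * eu_idx[0]].copy()
            for e in eu_idx:
                haps["EU"][mask, 2 * e] = founder
            for b in b_idx:
                haps["B"][mask, 2 * b] = founder
                haps["B"][mask, 2 * b + 1] = founder
            for b, e in tract.pairs:
                ibd_rows.append(
                    {
                        "sample1": sample_names["B"][b],
                        "sample2": sample_names["EU"][e],
                        "chrom": chrom,
                        "start": tract.region.start,
                        "end": tract.region.end,
                    }
                )

        ref = np.full(n_sites, "A")
        alt = np.full(n_sites, "G")
        chrom_frames.append(
            pd.DataFrame(
                {"chrom": chrom, "pos": pos0 + 1, "ref": ref, "alt": alt}
            )
        )
        chrom_blocks.append(np.hstack([haps[pop] for pop in POPS]))

    sites = pd.concat(chrom_frames, ignore_index=True)
    haplotypes = np.vstack(chrom_blocks)
    samples = [s for pop in POPS for s in sample_names[pop]]
    sample_pops = {s: pop for pop in POPS for s in sample_names[pop]}

    gm = GenotypeMatrix(
        sites=sites,
        haplotypes=haplotypes,
        samples=samples,
        sample_pops=sample_pops,
        phased=np.ones(len(samples), dtype=bool),
        layout=cfg.layout,
    )
    truth = TruthTables(
        introgression=RegionSet(
            Region(t.region.chrom, t.region.start, t.region.end, "introgression_truth")
            for t in cfg.introgression_tracts
        ),
        sweeps=RegionSet(
            Region(t.region.chrom, t.region.start, t.region.end, "sweep_truth")
            for t in cfg.sweep_tracts
        ),
        ibd_segments=pd.DataFrame(
            ibd_rows, columns=["sample1", "sample2", "chrom", "start", "end"]
        ),
        ancestral_allele=np.zeros(len(sites), dtype=np.int8),
    )
    return gm, truth


def write_cohort(
    gm: GenotypeMatrix, truth: TruthTables, outdir: str | Path, seed: int | None = None
) -> dict[str, Path]:
    """Write VCF, popmap, truth BEDs and the IBD truth TSV to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "cohort.vcf",
        "popmap": outdir / "popmap.tsv",
        "introgression_bed": outdir / "introgression.bed",
        "sweep_bed": outdir / "sweep.bed",
        "ibd_tsv": outdir / "ibd_truth.tsv",
    }
    header = [] if seed is None else [f"admixscan_seed={seed}"]
    write_vcf(gm, paths["vcf"], header_lines=header)
    write_popmap(gm.sample_pops, paths["popmap"])
    truth.introgression.to_bed(paths["introgression_bed"])
    truth.sweeps.to_bed(paths["sweep_bed"])
    truth.ibd_segments.to_csv(paths["ibd_tsv"], sep="\t", index=False)
    return paths


# ------------------------------------------------------------- gene trees

def msc_topology_probs(t: float) -> np.ndarray:
    """Multispecies-coalescent topology law for an internal branch of ``t``
    coalescent units: (P(I), P(II), P(III))."""
    if t < 0:
        raise ValueError("internal branch length must be >= 0")
    minor = np.exp(-t) / 3.0
    return np.array([1.0 - 2.0 * minor, minor, minor])


_NEWICKS = {
    "I": "(((B,EU),AS),O);",
    "II": "(((B,AS),EU),O);",
    "III": "(((EU,AS),B),O);",
}


def simulate_gene_trees(
    n_genes: int,
    internal_branch_t: float,
    seed: int | None = None,
    n_snps: int = 100,
) -> list[GeneTreeRecord]:
    """Draw gene trees from the MSC topology law (outgroup attached basally).

    Branch lengths carry no information here; ``n_snps`` is attached so the
    records pass the census SNP filter unchanged.
    """
    probs = msc_topology_probs(internal_branch_t)
    rng = np.random.default_rng(seed)
    draws = rng.choice(3, size=n_genes, p=probs)
    classes = np.array(["I", "II", "III"])[draws]
    return [
        GeneTreeRecord(f"gene{i:06d}", _NEWICKS[c], n_snps, topology=str(c))
        for i, c in enumerate(classes)
    ]
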