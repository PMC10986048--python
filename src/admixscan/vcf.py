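"""Biallelic-SNP genotype container and VCF / population-map I/O.

The in-memory substrate of every statistic is a haplotype matrix: one int8
column per haplotype (two per diploid sample), values 0 (REF), 1 (ALT) or
-1 (missing).  Positions are stored 1-based as in VCF; ``pos0`` exposes the
0-based coordinate used by all region logic.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .regions import GenomeLayout, Region

log = logging.getLogger(__name__)

MISSING = np.int8(-1)


@dataclass
class GenotypeMatrix:
    """Phased (or phase-agnostic) biallelic genotypes with population labels.

    Attributes
    ----------
    sites : DataFrame with columns chrom, pos (1-based), ref, alt,
        sorted by (chrom, pos), positions strictly increasing per chromosome.
    haplotypes : int8 array (n_sites, 2 * n_samples); columns 2i, 2i+1 are
        the two haplotypes of sample i.
    samples : sample identifiers, order matching the haplotype columns.
    sample_pops : sample -> population label (e.g. B, EU, AS, O).
    phased : per-sample flag; True when every called genotype was phased.
    layout : optional chromosome lengths (populated from VCF contig headers
        or by the simulator).
    """

    sites: pd.DataFrame
    haplotypes: np.ndarray
    samples: list[str]
    sample_pops: dict[str, str]
    phased: np.ndarray
    layout: GenomeLayout | None = None
    n_dropped_records: int = 0

    def __post_init__(self) -> None:
        if self.haplotypes.shape != (len(self.sites), 2 * len(self.samples)):
            raise ValueError("haplotype matrix shape does not match sites/samples")
        missing = [s for s in self.samples if s not in self.sample_pops]
        if missing:
            raise ValueError(f"samples missing from population map: {missing}")
        for chrom, grp in self.sites.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing or grp["pos"].duplicated().any():
                raise ValueError(f"positions not strictly increasing on {chrom}")

    # ------------------------------------------------------------- indexing
    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def populations(self) -> list[str]:
        return sorted(set(self.sample_pops.values()))

    @property
    def pos0(self) -> np.ndarray:
        return self.sites["pos"].to_numpy() - 1

    @property
    def chrom(self) -> np.ndarray:
        return self.sites["chrom"].to_numpy()

    def samples_of(self, pop: str) -> list[str]:
        out = [s for s in self.samples if self.sample_pops[s] == pop]
        if not out:
            raise KeyError(f"no samples in population {pop!r}")
        return out

    def sample_indices(self, pop: str) -> np.ndarray:
        names = set(self.samples_of(pop))
        return np.array([i for i, s in enumerate(self.samples) if s in names])

    def hap_columns(self, pop: str) -> np.ndarray:
        idx = self.sample_indices(pop)
        return np.sort(np.concatenate([2 * idx, 2 * idx + 1]))

    def haps(self, pop: str) -> np.ndarray:
        """(n_sites, n_hap) haplotype view for one population."""
        return self.haplotypes[:, self.hap_columns(pop)]

    def diploid(self, pop: str) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (alt dosage, called mask) per sample for one population.

        A genotype is called only when both haplotypes are non-missing.
        """
        idx = self.sample_indices(pop)
        h0 = self.haplotypes[:, 2 * idx]
        h1 = self.haplotypes[:, 2 * idx + 1]
        called = (h0 >= 0) & (h1 >= 0)
        dosage = np.where(called, h0 + h1, -1).astype(np.int8)
        return dosage, called

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            sites=self.sites.loc[mask].reset_index(drop=True),
            haplotypes=self.haplotypes[mask],
            samples=list(self.samples),
            sample_pops=dict(self.sample_pops),
            phased=self.phased.copy(),
            layout=self.layout,
        )

    def site_mask_in(self, region: Region) -> np.ndarray:
        pos0 = self.pos0
        return (
            (self.chrom == region.chrom)
            & (pos0 >= region.start)
            & (pos0 < region.end)
        )

    def all_phased(self, pop: str | None = None) -> bool:
        if pop is None:
            return bool(self.phased.all())
        return bool(self.phased[self.sample_indices(pop)].all())


# ---------------------------------------------------------------------- I/O

def read_popmap(path: str | Path) -> dict[str, str]:
    """Read a two-column ``sample<TAB>population`` file."""
    popmap: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{ln}: expected 'sample<TAB>population'")
            popmap[parts[0]] = parts[1]
    if not popmap:
        raise ValueError(f"population map {path} is empty")
    return popmap


def read_vcf(path: str | Path, popmap: str | Path | dict[str, str]) -> GenotypeMatrix:
    """Load biallelic SNPs from a VCF with GT fields.

    Multi-allelic and non-SNP records are dropped (count kept on the returned
    matrix and logged).  Every VCF sample must appear in the population map.
    """
    from cyvcf2 import VCF

    pops = popmap if isinstance(popmap, dict) else read_popmap(popmap)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF has no samples")
    unmapped = [s for s in samples if s not in pops]
    if unmapped:
        raise ValueError(f"samples in VCF but absent from population map: {unmapped}")

    layout = None
    if vcf.seqnames and vcf.seqlens:
        layout = GenomeLayout(tuple(vcf.seqnames), tuple(vcf.seqlens))

    chroms: list[str] = []
    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    hap_rows: list[np.ndarray] = []
    phased = np.ones(len(samples), dtype=bool)
    n_dropped = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_dropped += 1
            continue
        gts = np.asarray(var.genotypes, dtype=np.int64)  # (n_samples, 3)
        row = np.empty(2 * len(samples), dtype=np.int8)
        row[0::2] = gts[:, 0]
        row[1::2] = gts[:, 1]
        row[row < 0] = MISSING
        called = (gts[:, 0] >= 0) & (gts[:, 1] >= 0)
        phased &= (gts[:, 2] == 1) | ~called
        chroms.append(var.CHROM)
        positions.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        hap_rows.append(row)
    if n_dropped:
        log.info("read_vcf: dropped %d multi-allelic/non-SNP records", n_dropped)

    sites = pd.DataFrame(
        {"chrom": chroms, "pos": positions, "ref": refs, "alt": alts}
    )
    haps = (
        np.vstack(hap_rows)
        if hap_rows
        else np.empty((0, 2 * len(samples)), dtype=np.int8)
    )
    return GenotypeMatrix(
        sites=sites,
        haplotypes=haps,
        samples=samples,
        sample_pops={s: pops[s] for s in samples},
        phased=phased,
        layout=layout,
        n_dropped_records=n_dropped,
    )


def write_vcf(gm: GenotypeMatrix, path: str | Path, header_lines: list[str] = ()) -> None:
    """Write the matrix as an uncompressed VCFv4.2 with GT-only records."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=admixscan\n")
        for line in header_lines:
            fh.write(f"##{line}\n")
        if gm.layout is not None:
            for chrom, length in gm.layout.items():
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        sep = np.where(gm.phased, "|", "/")
        sites = gm.sites
        H = gm.haplotypes
        for i in range(gm.n_sites):
            row = sites.iloc[i]
            gts = []
            for j in range(gm.n_samples):
                a, b = H[i, 2 * j], H[i, 2 * j + 1]
                sa = "." if a < 0 else str(int(a))
                sb = "." if b < 0 else str(int(b))
                gts.append(f"{sa}{sep[j]}{sb}")
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def write_popmap(sample_pops: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s, p in sample_pops.items():
            fh.write(f"{s}\t{p}\n")
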