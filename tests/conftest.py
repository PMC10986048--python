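import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from admixscan import (
    GenomeLayout,
    GenotypeMatrix,
    IBDTract,
    IntrogressionTract,
    Region,
    SimConfig,
    SweepTract,
    simulate_cohort,
)


def make_gm(
    haps_by_pop: dict[str, np.ndarray],
    positions: np.ndarray | None = None,
    chrom: str = "chr1",
    layout: GenomeLayout | None = None,
) -> GenotypeMatrix:
    """Hand-built genotype matrix: one chromosome, haplotype columns per
    population, default positions 1, 2, 3, ..."""
    n_sites = next(iter(haps_by_pop.values())).shape[0]
    if positions is None:
        positions = np.arange(1, n_sites + 1)
    samples, pops, cols = [], {}, []
    for pop, H in haps_by_pop.items():
        assert H.shape[1] % 2 == 0
        for i in range(H.shape[1] // 2):
            name = f"{pop}_{i}"
            samples.append(name)
            pops[name] = pop
        cols.append(H.astype(np.int8))
    sites = pd.DataFrame(
        {"chrom": chrom, "pos": positions, "ref": "A", "alt": "G"}
    )
    return GenotypeMatrix(
        sites=sites,
        haplotypes=np.hstack(cols),
        samples=samples,
        sample_pops=pops,
        phased=np.ones(len(samples), dtype=bool),
        layout=layout,
    )


SMALL_LAYOUT = GenomeLayout(("chr1", "chr2"), (5_000_000, 5_000_000))
TWIN_LAYOUT = GenomeLayout(("chr1", "chr2"), (10_000_000, 10_000_000))


def introgression_tracts(n_per_chrom=5, length=200_000, spacing=1_800_000,
                         offset=500_000, fraction=0.8):
    tracts = []
    for chrom in ("chr1", "chr2"):
        for i in range(n_per_chrom):
            s = offset + i * spacing
            tracts.append(IntrogressionTract(Region(chrom, s, s + length), fraction))
    return tuple(tracts)


@pytest.fixture(scope="session")
def neutral_cohort():
    """Tract-free cohort at the generator defaults (session-cached)."""
    cfg = SimConfig(layout=SMALL_LAYOUT, seed=11)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def introgressed_cohort():
    """10% of the genome as f=0.8 Asian-into-target tracts."""
    cfg = SimConfig(
        layout=TWIN_LAYOUT,
        seed=7,
        introgression_tracts=introgression_tracts(),
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def sweep_cohort():
    """Planted delta=0.4 sweeps plus disjoint introgression tracts."""
    sweeps = tuple(
        SweepTract(Region("chr1", 3_000_000 + i * 2_500_000, 3_100_000 + i * 2_500_000), 0.4)
        for i in range(3)
    ) + tuple(
        SweepTract(Region("chr2", 3_000_000 + i * 2_500_000, 3_100_000 + i * 2_500_000), 0.4)
        for i in range(2)
    )
    intro = tuple(
        IntrogressionTract(Region("chr2", 500_000 + i * 700_000, 700_000 + i * 700_000), 0.8)
        for i in range(2)
    )
    cfg = SimConfig(
        layout=TWIN_LAYOUT, seed=13, sweep_tracts=sweeps, introgression_tracts=intro
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def ibd_cohort():
    """Planted founder-haplotype sharing between all target and EU samples
    over four 200-kb tracts."""
    pairs = tuple((b, e) for b in range(20) for e in range(20))
    tracts = tuple(
        IBDTract(Region(chrom, s, s + 200_000), pairs)
        for chrom, s in (
            ("chr1", 1_000_000),
            ("chr1", 6_000_000),
            ("chr2", 2_500_000),
            ("chr2", 7_500_000),
        )
    )
    cfg = SimConfig(layout=TWIN_LAYOUT, seed=19, ibd_tracts=tracts)
    return simulate_cohort(cfg)
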