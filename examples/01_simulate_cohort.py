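"""Simulate an admixed cohort with planted introgression and write it out.

The cohort emulates a developed breed (B) with a European ancestor panel
(EU), an Asian ancestor panel (AS) and an outgroup (O) that carries the
ancestral allele almost everywhere.  One 400-kb tract of B haplotypes is
replaced (80% of haplotypes) by Asian donor copies.
"""
from pathlib import Path

from admixscan import (
    GenomeLayout,
    IntrogressionTract,
    Region,
    SimConfig,
    simulate_cohort,
    write_cohort,
)

cfg = SimConfig(
    layout=GenomeLayout(("chr1",), (5_000_000,)),
    seed=1,
    introgression_tracts=(
        IntrogressionTract(Region("chr1", 2_000_000, 2_400_000), 0.8),
    ),
)
gm, truth = simulate_cohort(cfg)
outdir = Path("scratch/example_cohort")
paths = write_cohort(gm, truth, outdir, seed=cfg.seed)

print(f"simulated {gm.n_sites} SNPs for {gm.n_samples} samples "
      f"({', '.join(sorted(set(gm.sample_pops.values())))})")
print(f"planted introgression: {truth.introgression.covered_bp:,} bp")
for name, p in paths.items():
    print(f"  {name}: {p}")
# The VCF + popmap feed every downstream scan; the truth BEDs let you
# score any region-calling method against the planted tracts.
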