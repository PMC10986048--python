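# Methods

## Setting and notation

Four populations: a target breed B, its European ancestor panel EU, its
Asian ancestor panel AS, and an outgroup O used only to polarise alleles.
All statistics operate on biallelic SNPs; all intervals are 0-based
half-open (VCF positions are converted on read). Windows are anchored at
position 0 of each chromosome; full-size windows are emitted while they
fit, plus one truncated terminal window so that a step equal to the size
tiles each chromosome exactly.

## The synthetic cohort model

The generator is a per-site Balding–Nichols model, chosen over a full
coalescent because its closed-form frequency moments make the estimators'
expectations checkable by direct numerical integration, and every
statistic in the package is frequency-based.

Per site: an ancestral derived-allele frequency p ~ Uniform(0.05, 0.95);
each ingroup population's frequency is Beta-distributed with mean p and
drift parameter F (variance F·p(1−p)); haplotypes are sampled binomially
and phased trivially. The outgroup's derived frequency is drawn from a
Balding–Nichols beta with small mean (default 0.02, F_O = 0.5): a
near-monomorphic ancestral carrier, mirroring the role a distant outgroup
plays in polarisation. Sites where the outgroup's derived frequency
exceeds 0.1 (configurable) are excluded from the ABBA-BABA statistics.

Default drift: F_B = F_EU = 0.1, F_AS = 0.3. These were fixed once, to
reproduce the study system's qualitative structure — the target is closer
to its European ancestor (windowed Weir–Cockerham Fst ≈ 0.10 at these
defaults) than to the deeper-diverged Asian lineage (≈ 0.18), the same
ordering and scale reported for real European/Asian pig contrasts. Default
density 5 SNPs/kb and 20 diploids per ingroup population (6 outgroup) are
a scaled-down stand-in for WGS cohorts.

Sites are independent: there is no background linkage disequilibrium.
Linkage exists only inside planted tracts, where haplotype copying creates
perfect local haplotype structure. This is deliberate — the window scans
(f_d, rIBD, PBS) need tract-level signal, not genome-wide LD realism — but
it means passing tests say nothing about the behaviour of these statistics
under realistic recombination, background selection, or LD between scan
windows.

Planted structure, each emitted with a truth table:

* **Introgression tract** (Region, fraction f): round(f · n_hap) target
  haplotypes, chosen at random, are replaced by copies of donor
  haplotypes. Donors are drawn *without* replacement while the panel
  lasts, so the copied set's allele frequencies match the donor panel's;
  at f = 1 with equal panel sizes the tract frequencies match exactly and
  the f_d estimator's denominator equals its numerator.
* **Sweep tract** (Region, δ): the target's frequency is shifted by δ
  toward the locally major allele and clipped to [0, 1] before haplotype
  sampling. Sweep and introgression tracts may not overlap (the pipeline
  treats the two region classes as exclusive, so overlapping truth would
  be unscorable); the generator rejects such configs.
* **IBD tract** (Region, sample pairs): one founder haplotype (the first
  designated EU sample's) is written onto both haplotypes of every
  designated B sample and onto haplotype 0 of every designated EU sample.
  Every designated pair is then exactly IBD across the tract, the planted
  region is founder-homozygous in the target (as a strongly
  European-derived region would be), and the tract lands in the bottom
  tail of the Asian-ancestry window distribution, which the region-calling
  filter requires.

All randomness flows from the single config seed; identical configs give
byte-identical VCFs.

## Sign conventions (deliberately two)

The genome-wide D statistic follows the qpDstat orientation:
per site, numerator (p1 − p2)·p3·(1 − pO) — i.e. BABA − ABBA — so gene
flow between P2 (the target) and P3 (the Asian donor) drives D and its Z
*negative*, and P1–P3 flow drives it positive. The windowed f_d machinery
follows the orientation of the windowed admixture-fraction literature:
window D = (ABBA − BABA)/(ABBA + BABA), so the same P3→P2 introgression
gives *positive* window D and an f_d in (0, 1]. The two conventions differ
by sign on purpose: each matches the tool lineage practitioners know, and
the f_d clamping rules (below) are only coherent in the second.

## Per-statistic choices

**D and the jackknife.** Frequency-weighted site patterns (population
frequencies, not sampled haplotypes) reduce variance and match
population-mode D tools. Z comes from a weighted delete-one-block
jackknife (Busing-style, blocks weighted by informative-site counts) over
contiguous blocks, default 5 Mb, configurable; small test genomes use
proportionally smaller blocks to keep ≥ 20 blocks. Fewer than two
non-empty blocks is an error; zero jackknife variance (all blocks equal)
reports Z as missing with a warning, never a silently huge value.

**f_d.** Dynamic donor: per site the donor P_D is whichever of P2/P3 has
the higher derived frequency. Windows are non-overlapping 50 kb by
default (a step is configurable); a window needs ≥ 100 retained sites
("retained" = passing the polarisation and min-allele filters), else its
f_d is missing. Clamps: window D < 0 → 0; raw f_d > 1 (possible only
through float noise, tolerated at 1 ± 1e−9) or < 0 → 0. Reported f_d is
therefore always in [0, 1].

**Fst.** Weir & Cockerham (1984) two-population diploid variance
components, combined per window as Σa / Σ(a+b+c) (the "weighted"
ratio-of-sums VCFtools reports). Negative estimates are retained. Sites
need ≥ 2 called diploids per population.

**d_xy.** Per site p_x(1−p_y) + (1−p_x)p_y from called-haplotype
frequencies, which equals all-pairs haplotype enumeration exactly under
per-site pairwise deletion. The window denominator defaults to
per-used-site (a per-bp mode is provided); with the per-site denominator
the preference fraction (share of windows where d_xy(B,AS) < d_xy(B,EU),
ties counting as not-lower) is insensitive to site density.

**Local ancestry.** The naive painter assigns each target haplotype, per
50-kb chunk, to the panel containing its minimum-Hamming-distance
haplotype; exact ties are unassigned, missing alleles count as
mismatches. It is a deliberately simple stand-in exercising the window
machinery — it ignores switch errors, admixture LD and panel phasing
quality — and any external tool's per-site 0/1 label matrix can be
supplied as TSV instead. Window fractions average over assigned
(site × haplotype) cells, reading "frequencies of ancestries averaged per
window" at the allele level; unassigned cells leave both numerator and
denominator. Tail calling takes ⌈tail · n⌉ windows per side, ties broken
by genomic order (earlier window wins) for determinism.

**rIBD.** cIBD counts *sample pairs* (once per bin regardless of how many
haplotype combinations match), making nIBD = cIBD/tIBD ≤ 1 with
tIBD = n_B · n_other pairwise comparisons. A segment touches every bin it
overlaps by ≥ 1 bp. ZrIBD standardises over all genome bins including
zero-sharing bins; a degenerate (constant) rIBD distribution is an error,
not a silent zero. The naive IBD scanner reports maximal exact-identity
runs ≥ 100 kb between cross-population haplotype pairs — real IBD callers
tolerate genotyping error and use LD models; this one exists so the stage
runs self-contained on simulated data, where planted tracts are exact
copies and chance 100-kb identity is vanishingly rare.

**PBS.** T = −ln(1 − Fst) with Fst clamped at 1 − 1e−12 (T stays finite);
natural log by default with the base configurable. Negative window Fst
gives negative T and can give negative PBS — retained, matching the
negative minima such scans report. A window is missing unless all three
pairs have ≥ 10 usable sites. The sweep threshold is the empirical
(1 − q) quantile of non-missing PBS with ≥ comparisons (ties pass);
"coincides with introgression" means any bp of overlap (strictest
reading, fraction configurable); passing windows merge with gap 0 and the
merged set's genome fraction is reported — which is how a top-5% window
cut can cover more than 5% of the genome once overlapping sliding windows
merge.

**Gene trees.** Classification is purely topological: the single
informative split of the unrooted quartet determines the ingroup cherry;
polytomies are unresolved and excluded from all counts. Genes with ≤ 10
SNPs are removed (boundary: 11 kept). The ILS null calibrates
t̂ = −ln((3/2)(1 − concordance)) — requiring concordance in (1/3, 1) —
and draws replicate censuses multinomially from the MSC topology law
(P(concordant) = 1 − (2/3)e^(−t), each minor class (1/3)e^(−t));
materialising newick strings per replicate would change nothing but the
runtime. Both a one-sample t-test of the simulated III/II ratios against
the observed ratio and a two-sided empirical tail probability are
reported; the empirical p is the defensible one (the t-test conflates
Monte-Carlo error with sampling error) and both appear in the output.

## Scan tails on simulated cohorts

The candidate-calling defaults mirror the field's top-5% conventions
(f_d quantile 0.05, ancestry tails 0.05, PBS top 0.05), and all are
config-exposed. A counting argument fixes how they are used on cohorts
with known truth: a top-q cut can recover at most q/c of a planted
fraction c, so when a simulated cohort carries admixture on 10% of its
genome the introgression scan's f_d quantile and ancestry tail are set to
0.10 — the known simulated fraction — rather than the 5% default. This is
a property of quantile thresholds, not a tuned number; the acceptance
script states the fraction it simulates and matches the tails to it.

## Numerical and degenerate-input behaviour

Missing genotypes are never imputed; each statistic defines its own
site-inclusion rule (min called alleles, min diploids, polarisation
filter). Windows below their site minimum are NaN and excluded from
quantiles. Merging tags regions with the union of constituent tags.
Quantile thresholds use numpy's default (linear interpolation) empirical
quantile. The pipeline stamps every output with the package version, a
config hash and the seed; reruns are byte-identical.

## Known limitations

* No background LD, recombination maps, or sequencing error in the
  generator; power estimates from it are optimistic.
* The naive painter and naive IBD scanner are exercise harnesses for the
  window logic, not replacements for production LAI/IBD tools.
* d_xy's window size and denominator, the f_d candidate cutoff, and the
  jackknife block size have no single canonical value in the scan
  literature; all are exposed in config with the defaults above.
* The ILS test conditions on the point-calibrated t̂ and ignores
  uncertainty in the concordance estimate; at census sizes in the tens of
  thousands that uncertainty is negligible.
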