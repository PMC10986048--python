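import numpy as np
import pytest

from admixscan import (
    GenomeLayout,
    QuartetSpec,
    Region,
    RegionSet,
    call_introgression_regions,
    d_statistic,
    fd_windows,
    make_windows,
)
from admixscan.introgression import polarized_frequencies
from conftest import make_gm
from oracles import fd_window_recompute

Q = QuartetSpec("EU", "B", "AS", "O")
LAY = GenomeLayout(("chr1",), (1_000,))


def pattern_gm(patterns, layout=LAY, n_hap=4):
    """Build a matrix from site patterns: each pattern is (p1,p2,p3,o)
    allele values; populations are monomorphic per site.  Sites are spread
    evenly over the chromosome so block jackknifing sees several blocks."""
    arr = np.array(patterns)
    length = layout.chrom_lengths[0]
    positions = np.linspace(1, length, num=len(arr), dtype=int)
    positions = np.maximum.accumulate(positions)  # strictly increasing guard
    if len(np.unique(positions)) != len(positions):
        positions = np.arange(1, len(arr) + 1)
    H = {
        "EU": np.repeat(arr[:, [0]], n_hap, axis=1),
        "B": np.repeat(arr[:, [1]], n_hap, axis=1),
        "AS": np.repeat(arr[:, [2]], n_hap, axis=1),
        "O": np.repeat(arr[:, [3]], n_hap, axis=1),
    }
    return make_gm(H, positions=positions, layout=layout)


BABA = (1, 0, 1, 0)
ABBA = (0, 1, 1, 0)


class TestDStatistic:
    def test_quartet_roles_distinct(self):
        with pytest.raises(ValueError):
            QuartetSpec("B", "B", "AS", "O")

    def test_pure_baba_gives_plus_one(self):
        gm = pattern_gm([BABA] * 100)
        res = d_statistic(gm, Q, block_size=500)
        assert res.d == pytest.approx(1.0)

    def test_pure_abba_gives_minus_one(self):
        gm = pattern_gm([ABBA] * 100)
        res = d_statistic(gm, Q, block_size=500)
        assert res.d == pytest.approx(-1.0)

    def test_balanced_patterns_give_zero(self):
        gm = pattern_gm([ABBA, BABA] * 50)
        res = d_statistic(gm, Q, block_size=500)
        assert res.d == pytest.approx(0.0)

    def test_swapping_p1_p2_flips_sign(self, neutral_cohort):
        gm, _ = neutral_cohort
        a = d_statistic(gm, Q, block_size=1_000_000)
        b = d_statistic(gm, QuartetSpec("B", "EU", "AS", "O"), block_size=1_000_000)
        assert a.d == pytest.approx(-b.d)
        assert a.z == pytest.approx(-b.z)

    def test_sample_order_within_population_irrelevant(self, neutral_cohort):
        gm, _ = neutral_cohort
        a = d_statistic(gm, Q, block_size=1_000_000)
        rng = np.random.default_rng(0)
        perm_samples = list(gm.samples)
        # shuffle B samples among themselves by permuting their hap columns
        b_idx = gm.sample_indices("B")
        perm = rng.permutation(b_idx)
        H = gm.haplotypes.copy()
        for src, dst in zip(b_idx, perm):
            H[:, 2 * dst : 2 * dst + 2] = gm.haplotypes[:, 2 * src : 2 * src + 2]
        import dataclasses

        gm2 = dataclasses.replace(gm, haplotypes=H)
        b = d_statistic(gm2, Q, block_size=1_000_000)
        assert a.d == pytest.approx(b.d)

    def test_identical_blocks_flag_missing_z(self):
        gm = pattern_gm([ABBA, BABA] * 50)
        with pytest.warns(UserWarning, match="variance"):
            res = d_statistic(gm, Q, block_size=100)
        assert np.isnan(res.z)

    def test_single_block_rejected(self):
        gm = pattern_gm([ABBA] * 10)
        with pytest.raises(ValueError, match="blocks"):
            d_statistic(gm, Q, block_size=10_000)

    def test_outgroup_polymorphic_sites_excluded(self):
        # outgroup derived frequency 0.5 > 0.1 threshold -> excluded
        H = {
            "EU": np.zeros((40, 4), int),
            "B": np.ones((40, 4), int),
            "AS": np.ones((40, 4), int),
            "O": np.tile([0, 0, 1, 1], (40, 1)),
        }
        gm = make_gm(H, layout=LAY)
        _, _, _, _, keep = polarized_frequencies(gm, Q)
        assert not keep.any()


class TestFdWindows:
    def test_negative_window_d_clamped_to_zero(self):
        # BABA-dominant window: Martin-orientation D < 0 -> f_d := 0
        gm = pattern_gm([BABA] * 150, layout=LAY)
        win = [Region("chr1", 0, 1_000)]
        t = fd_windows(gm, Q, win, min_sites=100)
        assert t["d"].iloc[0] < 0
        assert t["fd"].iloc[0] == 0.0

    def test_below_min_sites_missing(self):
        gm = pattern_gm([ABBA] * 99, layout=LAY)
        t = fd_windows(gm, Q, [Region("chr1", 0, 1_000)], min_sites=100)
        assert np.isnan(t["fd"].iloc[0])
        t2 = fd_windows(gm, Q, [Region("chr1", 0, 1_000)], min_sites=99)
        assert not np.isnan(t2["fd"].iloc[0])

    def test_reported_fd_in_unit_interval(self, introgressed_cohort):
        gm, _ = introgressed_cohort
        wins = make_windows(gm.layout, 50_000, 50_000)
        t = fd_windows(gm, Q, wins)
        vals = t["fd"].dropna()
        assert ((vals >= 0) & (vals <= 1)).all()

    def test_matches_per_site_pattern_recompute(self, introgressed_cohort):
        """Window f_d equals a scalar recomputation from the per-site
        polarised frequencies."""
        gm, _ = introgressed_cohort
        wins = make_windows(gm.layout, 50_000, 50_000)[:60]
        t = fd_windows(gm, Q, wins, min_sites=1)
        p1, p2, p3, po, ok = polarized_frequencies(gm, Q)
        chrom, pos0 = gm.chrom, gm.pos0
        for i, w in enumerate(wins):
            m = (chrom == w.chrom) & (pos0 >= w.start) & (pos0 < w.end)
            if not m.any():
                continue
            d, fd = fd_window_recompute(p1[m], p2[m], p3[m], po[m], ok[m])
            assert t["d"].iloc[i] == pytest.approx(d)
            assert t["fd"].iloc[i] == pytest.approx(fd)

    def test_full_replacement_window_fd_near_one(self):
        """A window whose target haplotypes were all replaced by donor
        copies estimates an admixture fraction close to 1."""
        from admixscan import IntrogressionTract, SimConfig, simulate_cohort

        lay = GenomeLayout(("chr1",), (1_000_000,))
        tract = IntrogressionTract(Region("chr1", 400_000, 600_000), 1.0)
        cfg = SimConfig(layout=lay, seed=17, introgression_tracts=(tract,))
        gm, _ = simulate_cohort(cfg)
        wins = [Region("chr1", 450_000, 500_000), Region("chr1", 500_000, 550_000)]
        t = fd_windows(gm, Q, wins)
        assert (t["fd"] > 0.85).all()


class TestCallIntrogression:
    def fd_table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "chrom": ["chr1"] * 10,
                "start": np.arange(10) * 100,
                "end": (np.arange(10) + 1) * 100,
                "n_sites": 200,
                "d": 0.1,
                "fd": [0.9, 0.8, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, np.nan, 0.1],
            }
        )

    def test_empty_ancestry_top_gives_empty(self):
        out = call_introgression_regions(self.fd_table(), RegionSet(), 0.2)
        assert len(out) == 0

    def test_quantile_one_whole_genome_keeps_all_non_missing(self):
        whole = RegionSet([Region("chr1", 0, 1_000)])
        out = call_introgression_regions(self.fd_table(), whole, 1.0)
        # nine non-missing windows merge into [0,800) and [900,1000)
        assert [(r.start, r.end) for r in out] == [(0, 800), (900, 1_000)]

    def test_top_quantile_selects_highest_fd(self):
        whole = RegionSet([Region("chr1", 0, 1_000)])
        # ceil(0.2 * 9 non-missing) = 2 windows: the 0.9 and 0.8 ones
        out = call_introgression_regions(self.fd_table(), whole, 0.2)
        assert [(r.start, r.end) for r in out] == [(0, 200)]

    def test_all_missing_rejected(self):
        t = self.fd_table().assign(fd=np.nan)
        with pytest.raises(ValueError):
            call_introgression_regions(t, RegionSet(), 0.1)
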