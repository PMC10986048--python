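import numpy as np
import pytest

from admixscan import (
    GenomeLayout,
    IntrogressionTract,
    Region,
    SimConfig,
    dxy,
    dxy_preference_fraction,
    fst_weir_cockerham,
    make_windows,
    simulate_cohort,
    site_frequencies,
)
from conftest import make_gm
from oracles import dxy_pairs, wc_single_site

WIN1 = [Region("chr1", 0, 10_000)]


class TestSiteFrequencies:
    def test_counts_and_flags(self):
        # 2 diploid B samples: 0/0 and 0/1 -> alt 1 of 4 called
        H = {"B": np.array([[0, 0, 0, 1]]), "EU": np.array([[-1, -1, -1, -1]])}
        sf = site_frequencies(make_gm(H), ["B", "EU"])
        assert sf["alt_B"].iloc[0] == 1 and sf["called_B"].iloc[0] == 4
        assert not sf["usable_EU"].iloc[0]
        assert not sf["usable"].iloc[0]

    def test_unknown_population_rejected(self):
        H = {"B": np.zeros((2, 4), dtype=int)}
        with pytest.raises(KeyError):
            site_frequencies(make_gm(H), ["B", "XX"])

    @pytest.mark.parametrize("seed", range(3))
    def test_random_matrix_matches_loop(self, seed):
        rng = np.random.default_rng(seed)
        H = {"B": rng.choice([-1, 0, 1], size=(50, 8), p=[0.1, 0.5, 0.4])}
        sf = site_frequencies(make_gm(H), ["B"])
        for s in range(50):
            row = H["B"][s]
            assert sf["alt_B"].iloc[s] == (row == 1).sum()
            assert sf["called_B"].iloc[s] == (row >= 0).sum()


class TestFst:
    def test_identical_pools_near_zero(self):
        rng = np.random.default_rng(0)
        freqs = rng.uniform(0.05, 0.95, 1_000)
        pool = (rng.random((1_000, 200)) < freqs[:, None]).astype(int)
        gm = make_gm({"B": pool[:, :100], "EU": pool[:, 100:]})
        fst = fst_weir_cockerham(gm, "B", "EU", WIN1, min_sites=1)["fst"].iloc[0]
        assert abs(fst) < 0.02

    def test_fixed_difference_gives_one(self):
        gm = make_gm({"B": np.zeros((20, 8), int), "EU": np.ones((20, 8), int)})
        fst = fst_weir_cockerham(gm, "B", "EU", WIN1, min_sites=1)["fst"].iloc[0]
        assert fst == pytest.approx(1.0)

    def test_same_population_rejected(self):
        gm = make_gm({"B": np.zeros((5, 4), int)})
        with pytest.raises(ValueError):
            fst_weir_cockerham(gm, "B", "B", WIN1)

    def test_window_without_sites_missing(self):
        gm = make_gm({"B": np.zeros((5, 4), int), "EU": np.ones((5, 4), int)})
        far = [Region("chr1", 100_000, 200_000)]
        assert np.isnan(fst_weir_cockerham(gm, "B", "EU", far)["fst"].iloc[0])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_scalar_site_oracle(self, seed):
        """Ratio-of-sums W&C Fst equals the independently coded single-site
        components combined the same way, on random 8-sample matrices with
        missing data."""
        rng = np.random.default_rng(200 + seed)
        H = {
            "B": rng.choice([-1, 0, 1], size=(40, 8), p=[0.05, 0.5, 0.45]),
            "EU": rng.choice([-1, 0, 1], size=(40, 8), p=[0.05, 0.3, 0.65]),
        }
        gm = make_gm(H)
        got = fst_weir_cockerham(gm, "B", "EU", WIN1, min_sites=1)["fst"].iloc[0]
        num = den = 0.0
        for s in range(40):
            def dosages(pop):
                out = []
                for i in range(4):
                    a, b = H[pop][s, 2 * i], H[pop][s, 2 * i + 1]
                    out.append(a + b if a >= 0 and b >= 0 else -1)
                return out
            comp = wc_single_site(dosages("B"), dosages("EU"))
            if comp is None:
                continue
            a, b, c = comp
            num += a
            den += a + b + c
        assert got == pytest.approx(num / den)


class TestDxy:
    def test_identical_monomorphic_zero(self):
        gm = make_gm({"B": np.zeros((10, 4), int), "EU": np.zeros((10, 4), int)})
        assert dxy(gm, "B", "EU", WIN1, min_sites=1)["dxy"].iloc[0] == 0.0

    def test_fixed_opposite_single_site(self):
        gm = make_gm({"B": np.zeros((1, 4), int), "EU": np.ones((1, 4), int)})
        assert dxy(gm, "B", "EU", WIN1, min_sites=1)["dxy"].iloc[0] == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_all_pairs_enumeration(self, seed):
        rng = np.random.default_rng(300 + seed)
        H = {
            "B": rng.choice([-1, 0, 1], size=(30, 6), p=[0.1, 0.4, 0.5]),
            "EU": rng.choice([-1, 0, 1], size=(30, 8), p=[0.1, 0.6, 0.3]),
        }
        gm = make_gm(H)
        table = dxy(gm, "B", "EU", WIN1, min_sites=1, min_alleles=1)
        expect = dxy_pairs(H["B"], H["EU"]) / table["n_sites"].iloc[0]
        assert table["dxy"].iloc[0] == pytest.approx(expect)

    def test_symmetry_exact(self):
        rng = np.random.default_rng(4)
        H = {"B": rng.integers(0, 2, (50, 8)), "EU": rng.integers(0, 2, (50, 6))}
        gm = make_gm(H)
        a = dxy(gm, "B", "EU", WIN1, min_sites=1)["dxy"].iloc[0]
        b = dxy(gm, "EU", "B", WIN1, min_sites=1)["dxy"].iloc[0]
        assert a == b

    def test_per_bp_denominator(self):
        gm = make_gm({"B": np.zeros((1, 4), int), "EU": np.ones((1, 4), int)})
        t = dxy(gm, "B", "EU", WIN1, denominator="per_bp", min_sites=1)
        assert t["dxy"].iloc[0] == pytest.approx(1.0 / 10_000)

    def test_bad_denominator_rejected(self):
        gm = make_gm({"B": np.zeros((1, 4), int), "EU": np.ones((1, 4), int)})
        with pytest.raises(ValueError):
            dxy(gm, "B", "EU", WIN1, denominator="bogus")


class TestDxyPreference:
    def test_all_windows_favouring_donor(self):
        import pandas as pd

        w = pd.DataFrame({"chrom": "c", "start": [0, 10], "end": [10, 20]})
        a = w.assign(dxy=[0.1, 0.2])
        e = w.assign(dxy=[0.3, 0.4])
        assert dxy_preference_fraction(a, e) == 1.0

    def test_ties_count_as_not_lower(self):
        import pandas as pd

        w = pd.DataFrame({"chrom": "c", "start": [0], "end": [10]})
        assert dxy_preference_fraction(w.assign(dxy=[0.3]), w.assign(dxy=[0.3])) == 0.0

    def test_mismatched_windows_rejected(self):
        import pandas as pd

        a = pd.DataFrame({"chrom": "c", "start": [0], "end": [10], "dxy": [0.1]})
        b = pd.DataFrame({"chrom": "c", "start": [5], "end": [15], "dxy": [0.1]})
        with pytest.raises(ValueError):
            dxy_preference_fraction(a, b)

    def test_symmetric_null_near_half_and_introgression_raises_it(self):
        """With equal EU/AS drift the preference fraction sits near 0.5;
        planting Asian tracts on the same seed pushes it up."""
        lay = GenomeLayout(("chr1",), (5_000_000,))
        drift = {"B": 0.1, "EU": 0.2, "AS": 0.2, "O": 0.5}
        tracts = tuple(
            IntrogressionTract(Region("chr1", 250_000 + i * 1_000_000, 450_000 + i * 1_000_000), 0.8)
            for i in range(5)
        )
        windows = make_windows(lay, 50_000, 50_000)

        def pref(cfg):
            gm, _ = simulate_cohort(cfg)
            a = dxy(gm, "B", "AS", windows)
            e = dxy(gm, "B", "EU", windows)
            return dxy_preference_fraction(a, e)

        null = pref(SimConfig(layout=lay, drift=drift, seed=33))
        admixed = pref(SimConfig(layout=lay, drift=drift, seed=33,
                                 introgression_tracts=tracts))
        assert abs(null - 0.5) < 0.1
        assert admixed > null
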