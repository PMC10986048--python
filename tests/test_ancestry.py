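import numpy as np
import pandas as pd
import pytest

from admixscan import (
    GenomeLayout,
    Region,
    ancestry_window_fractions,
    naive_paint,
    top_bottom_ancestry,
)
from admixscan.ancestry import AncestryMatrix, read_ancestry_tsv, write_ancestry_tsv
from conftest import make_gm


def label_matrix(labels, chrom="chr1"):
    labels = np.asarray(labels, dtype=np.int8)
    sites = pd.DataFrame(
        {"chrom": chrom, "pos": np.arange(1, labels.shape[0] + 1)}
    )
    ids = [f"h{i}" for i in range(labels.shape[1])]
    return AncestryMatrix(sites=sites, labels=labels, hap_ids=ids)


class TestNaivePaint:
    def test_copied_haplotype_labelled_donor(self):
        rng = np.random.default_rng(0)
        n_sites = 100
        eu = rng.integers(0, 2, (n_sites, 8))
        as_ = rng.integers(0, 2, (n_sites, 8))
        b = np.column_stack([as_[:, 0], as_[:, 3], eu[:, 1], eu[:, 2]])
        gm = make_gm({"B": b, "EU": eu, "AS": as_})
        am = naive_paint(gm, "B", "EU", "AS", chunk=1_000)
        assert (am.labels[:, 0] == 1).all()
        assert (am.labels[:, 1] == 1).all()
        assert (am.labels[:, 2] == 0).all()
        assert (am.labels[:, 3] == 0).all()

    def test_equidistant_chunk_unassigned(self):
        # panels are single-haplotype mirror images; target differs from
        # each at exactly one site
        eu = np.array([[0], [0], [1], [1]])
        as_ = np.array([[1], [1], [0], [0]])
        b = np.array([[1], [0], [1], [0]])
        gm = make_gm({"B": np.repeat(b, 2, axis=1), "EU": np.repeat(eu, 2, axis=1),
                      "AS": np.repeat(as_, 2, axis=1)})
        am = naive_paint(gm, "B", "EU", "AS", chunk=1_000)
        assert (am.labels == -1).all()

    def test_empty_panel_rejected(self):
        gm = make_gm({"B": np.zeros((4, 2), int), "EU": np.zeros((4, 2), int),
                      "AS": np.zeros((4, 2), int)})
        with pytest.raises(KeyError):
            naive_paint(gm, "B", "EU", "XX")

    def test_panel_order_equivariance(self):
        rng = np.random.default_rng(5)
        eu = rng.integers(0, 2, (60, 10))
        as_ = rng.integers(0, 2, (60, 10))
        b = rng.integers(0, 2, (60, 6))
        gm1 = make_gm({"B": b, "EU": eu, "AS": as_})
        perm = rng.permutation(10)
        gm2 = make_gm({"B": b, "EU": eu[:, perm], "AS": as_[:, perm]})
        am1 = naive_paint(gm1, "B", "EU", "AS", chunk=1_000)
        am2 = naive_paint(gm2, "B", "EU", "AS", chunk=1_000)
        assert (am1.labels == am2.labels).all()

    def test_tract_sites_recovered(self, introgressed_cohort):
        """Painting the f=0.8 cohort labels nearly all truly donated
        haplotype cells Asian inside the tracts."""
        gm, truth = introgressed_cohort
        am = naive_paint(gm, "B", "EU", "AS")
        # donated haplotypes are exact AS copies; check the aggregate rate
        chrom, pos0 = gm.chrom, gm.pos0
        rates = []
        for r in truth.introgression:
            m = (chrom == r.chrom) & (pos0 >= r.start) & (pos0 < r.end)
            frac_as = (am.labels[m] == 1).mean()
            rates.append(frac_as)
        # 80% of haplotypes are verbatim donor copies; the painter should
        # label at least those
        assert np.mean(rates) > 0.75


class TestWindowFractions:
    def test_all_donor_cells(self):
        am = label_matrix(np.ones((10, 4)))
        wt = ancestry_window_fractions(am, [Region("chr1", 0, 100)])
        assert wt["frac_as"].iloc[0] == 1.0

    def test_half_and_half(self):
        labels = np.column_stack([np.ones((10, 2)), np.zeros((10, 2))])
        am = label_matrix(labels)
        wt = ancestry_window_fractions(am, [Region("chr1", 0, 100)])
        assert wt["frac_as"].iloc[0] == 0.5

    def test_unassigned_cells_excluded(self):
        labels = np.array([[1, -1], [0, -1]])
        am = label_matrix(labels)
        wt = ancestry_window_fractions(am, [Region("chr1", 0, 100)])
        assert wt["frac_as"].iloc[0] == 0.5
        assert wt["n_cells"].iloc[0] == 2

    def test_all_unassigned_window_missing(self):
        am = label_matrix(np.full((5, 2), -1))
        wt = ancestry_window_fractions(am, [Region("chr1", 0, 100)])
        assert np.isnan(wt["frac_as"].iloc[0])

    def test_overlapping_windows_rejected(self):
        am = label_matrix(np.ones((5, 2)))
        with pytest.raises(ValueError):
            ancestry_window_fractions(
                am, [Region("chr1", 0, 100), Region("chr1", 50, 150)]
            )

    @pytest.mark.parametrize("seed", range(3))
    def test_random_labels_match_cell_count_loop(self, seed):
        rng = np.random.default_rng(400 + seed)
        labels = rng.choice([-1, 0, 1], size=(200, 6), p=[0.2, 0.4, 0.4])
        am = label_matrix(labels)
        windows = [Region("chr1", i * 50, (i + 1) * 50) for i in range(4)]
        wt = ancestry_window_fractions(am, windows)
        pos0 = np.arange(200)
        for i, w in enumerate(windows):
            cells = labels[(pos0 >= w.start) & (pos0 < w.end)]
            n1 = int((cells == 1).sum())
            n_assigned = int((cells >= 0).sum())
            assert wt["n_cells"].iloc[i] == n_assigned
            if n_assigned:
                assert wt["frac_as"].iloc[i] == pytest.approx(n1 / n_assigned)


class TestTopBottom:
    def window_table(self, fracs):
        n = len(fracs)
        return pd.DataFrame(
            {
                "chrom": "chr1",
                "start": np.arange(n) * 100,
                "end": (np.arange(n) + 1) * 100,
                "n_cells": 10,
                "frac_as": fracs,
            }
        )

    def test_ranked_fractions_take_extremes(self):
        wt = self.window_table(np.arange(1, 101) / 100.0)
        high_as, high_eu = top_bottom_ancestry(wt, 0.05)
        assert [(r.start, r.end) for r in high_as] == [(9_500, 10_000)]
        assert [(r.start, r.end) for r in high_eu] == [(0, 500)]

    def test_constant_fractions_use_genomic_order_ties(self):
        wt = self.window_table(np.full(100, 0.5))
        high_as, high_eu = top_bottom_ancestry(wt, 0.05)
        # both tails take the first five windows by the earlier-window rule
        assert [(r.start, r.end) for r in high_as] == [(0, 500)]
        assert [(r.start, r.end) for r in high_eu] == [(0, 500)]

    def test_tail_bounds_enforced(self):
        wt = self.window_table(np.arange(10) / 10.0)
        for bad in (0.0, 0.6, -0.1):
            with pytest.raises(ValueError):
                top_bottom_ancestry(wt, bad)

    def test_tails_disjoint_for_nonconstant(self):
        rng = np.random.default_rng(9)
        wt = self.window_table(rng.uniform(size=200))
        high_as, high_eu = top_bottom_ancestry(wt, 0.1)
        assert high_as.overlap_bp(high_eu) == 0


def test_ancestry_tsv_round_trip(tmp_path):
    rng = np.random.default_rng(2)
    labels = rng.choice([-1, 0, 1], size=(30, 4))
    am = label_matrix(labels)
    path = tmp_path / "anc.tsv"
    write_ancestry_tsv(am, path)
    back = read_ancestry_tsv(path)
    assert (back.labels == am.labels).all()
    assert back.hap_ids == am.hap_ids
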