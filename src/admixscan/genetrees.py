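"""Four-taxon gene-tree topology census and the ILS coalescent null test.

For a quartet {B, EU, AS, O} rooted by the outgroup O, every binary tree
reduces to one of three ingroup topologies:

* class I   — ((B, EU), AS): concordant with the species tree,
* class II  — ((B, AS), EU): the Asian-sharing discordant class,
* class III — ((EU, AS), B): the other discordant class.

Under incomplete lineage sorting alone with an internal branch of t
coalescent units, P(I) = 1 - (2/3) e^(-t) and the discordant classes each
occur with probability (1/3) e^(-t), so II and III are expected equal.  An
excess of class II over III is the hybridisation signal; the census is
tested first for II = III (chi-square) and then for the ratio III/II
against a census simulated under the pure-ILS law calibrated from the
observed concordance.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
from scipy import stats

DEFAULT_LABELS = ("B", "EU", "AS", "O")
TOPOLOGY_CLASSES = ("I", "II", "III")


@dataclass(frozen=True)
class GeneTreeRecord:
    gene_id: str
    newick: str
    n_snps: int
    topology: str | None = None  # "I" | "II" | "III" | "unresolved"


@dataclass(frozen=True)
class TopologyCensus:
    n_i: int
    n_ii: int
    n_iii: int
    n_unresolved: int = 0

    @property
    def total(self) -> int:
        """Resolved trees only; unresolved are excluded from all tests."""
        return self.n_i + self.n_ii + self.n_iii

    @property
    def concordance(self) -> float:
        return self.n_i / self.total


def classify_tree(
    newick: str,
    labels: Sequence[str] = DEFAULT_LABELS,
    outgroup: str = "O",
) -> str:
    """Assign a 4-taxon newick to topology class I/II/III or ``unresolved``.

    Classification is purely topological (branch lengths, rotations and the
    newick rooting are ignored): the single informative split of the
    unrooted quartet determines the ingroup cherry.
    """
    ingroup = [x for x in labels if x != outgroup]
    tree = dendropy.Tree.get(data=newick, schema="newick")
    leaves = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    if leaves != sorted(labels):
        raise ValueError(
            f"tree taxa {leaves} do not match expected labels {sorted(labels)}"
        )
    cherries = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        comp = frozenset(labels) - side
        for part in (side, comp):
            if len(part) == 2 and outgroup not in part:
                cherries.add(part)
    if len(cherries) != 1:
        return "unresolved"
    cherry = next(iter(cherries))
    a, b, c = ingroup
    mapping = {
        frozenset((a, b)): "I",
        frozenset((a, c)): "II",
        frozenset((b, c)): "III",
    }
    return mapping[cherry]


def classify_records(
    records: Iterable[GeneTreeRecord],
    labels: Sequence[str] = DEFAULT_LABELS,
    outgroup: str = "O",
) -> list[GeneTreeRecord]:
    return [
        replace(r, topology=classify_tree(r.newick, labels, outgroup))
        for r in records
    ]


def filter_genes(
    records: Iterable[GeneTreeRecord], min_snps: int = 11
) -> list[GeneTreeRecord]:
    """Drop genes with fewer than ``min_snps`` SNPs (default keeps > 10)."""
    return [r for r in records if r.n_snps >= min_snps]


def census(records: Iterable[GeneTreeRecord]) -> TopologyCensus:
    counts = {"I": 0, "II": 0, "III": 0, "unresolved": 0}
    for r in records:
        if r.topology is None:
            raise ValueError(f"gene {r.gene_id}: topology not classified yet")
        counts[r.topology] += 1
    return TopologyCensus(counts["I"], counts["II"], counts["III"], counts["unresolved"])


def minor_topology_equality_test(c: TopologyCensus) -> tuple[float, float]:
    """1-df chi-square goodness of fit of (n_II, n_III) against equality."""
    if c.n_ii + c.n_iii == 0:
        raise ValueError("no discordant trees: cannot test II vs III")
    chi2, p = stats.chisquare([c.n_ii, c.n_iii])
    return float(chi2), float(p)


@dataclass(frozen=True)
class IlsRatioTestResult:
    observed_ratio: float
    t_hat: float
    simulated_ratios: np.ndarray
    p_t: float
    p_empirical: float


def ils_ratio_test(
    c: TopologyCensus, n_reps: int = 1000, seed: int | None = None
) -> IlsRatioTestResult:
    """Test the observed III/II ratio against a pure-ILS multispecies
    coalescent null.

    The internal branch is calibrated from the observed concordance,
    t_hat = -ln((3/2) (1 - n_I/total)); ``n_reps`` censuses of ``total``
    genes are then drawn from the MSC topology law at t_hat and the III/II
    ratio recorded per replicate.  Reported are a one-sample t-test of the
    simulated ratios against the observed constant and a two-sided
    empirical tail probability.
    """
    from .simulate import msc_topology_probs

    total = c.total
    conc = c.concordance
    if not (1 / 3 < conc < 1):
        raise ValueError(
            f"concordance {conc:.3f} outside (1/3, 1): no valid ILS calibration"
        )
    if c.n_ii == 0:
        raise ValueError("n_II = 0: observed ratio undefined")
    t_hat = -np.log(1.5 * (1.0 - conc))
    probs = msc_topology_probs(t_hat)
    rng = np.random.default_rng(seed)
    sims = rng.multinomial(total, probs, size=n_reps)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = sims[:, 2] / sims[:, 1]
    ratios = ratios[np.isfinite(ratios)]
    observed = c.n_iii / c.n_ii
    t_res = stats.ttest_1samp(ratios, observed)
    lo = float(np.mean(ratios <= observed))
    hi = float(np.mean(ratios >= observed))
    p_emp = min(1.0, 2.0 * min(lo, hi))
    return IlsRatioTestResult(
        observed_ratio=float(observed),
        t_hat=float(t_hat),
        simulated_ratios=ratios,
        p_t=float(t_res.pvalue),
        p_empirical=p_emp,
    )


# ---------------------------------------------------------------------- I/O

def read_gene_trees(
    newick_path: str | Path, snp_counts_path: str | Path | None = None
) -> list[GeneTreeRecord]:
    """Read one newick per line (optionally ``id<TAB>newick``) plus an
    optional ``gene<TAB>n_snps`` TSV."""
    counts: dict[str, int] = {}
    if snp_counts_path is not None:
        with open(snp_counts_path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                gene, n = line.split("\t")[:2]
                counts[gene] = int(n)
    records = []
    with open(newick_path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "\t" in line:
                gene_id, nwk = line.split("\t", 1)
            else:
                gene_id, nwk = f"gene{i:06d}", line
            # without a SNP-count table every gene passes the SNP filter
            n_snps = counts.get(gene_id, 0) if snp_counts_path is not None else 10**9
            records.append(GeneTreeRecord(gene_id, nwk, n_snps))
    return records


def write_gene_trees(records: Iterable[GeneTreeRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.gene_id}\t{r.newick}\n")
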