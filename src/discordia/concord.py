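"""Quartet concordance around species-tree branches and positional
stratification of topology frequencies.

Under the multispecies coalescent an internal species-tree branch of length
T coalescent units yields the species-tree quartet resolution with
probability 1 - (2/3)exp(-T) and each alternative with probability
(1/3)exp(-T); a zero-length branch gives the random one-third expectation.
Observed quartet frequencies around each internal branch are compared with
that baseline, a small-scale exhaustive quartet-score estimator recovers the
species tree from gene trees, and window topologies are stratified into five
folded telomere-to-centromere bins per chromosome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations, product
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._phylo import Node, Tree, _adjacency, quartet_pairing

__all__ = [
    "FocalBranch",
    "QuartetFrequencies",
    "focal_branches",
    "quartet_frequencies",
    "msc_quartet_expectation",
    "quartet_score_species_tree",
    "enumerate_unrooted_topologies",
    "fold_position",
    "regional_topology_frequencies",
]


@dataclass(frozen=True)
class FocalBranch:
    """An internal species-tree edge with its four neighbouring leaf groups.

    ``groups`` is ordered so the species tree pairs (g1, g2) | (g3, g4);
    the three quartet resolutions are t1 = g1g2|g3g4 (species tree),
    t2 = g1g3|g2g4, t3 = g1g4|g2g3.
    """

    branch_id: str
    groups: tuple[frozenset[str], frozenset[str], frozenset[str], frozenset[str]]

    def __post_init__(self):
        leaves = frozenset().union(*self.groups)
        if sum(len(g) for g in self.groups) != len(leaves):
            raise ValueError("neighbour groups must partition the leaf set")


@dataclass(frozen=True)
class QuartetFrequencies:
    t1: float
    t2: float
    t3: float
    n_trees: int

    def __post_init__(self):
        if self.n_trees and abs(self.t1 + self.t2 + self.t3 - 1.0) > 1e-9:
            raise ValueError("quartet frequencies must sum to 1")


def focal_branches(species_tree: Tree) -> list[FocalBranch]:
    """Enumerate the internal edges of the (unrooted view of the) species
    tree, each with its four neighbouring leaf groups."""
    adj = _adjacency(species_tree)
    internal = [i for i, nb in adj.nbrs.items() if len(nb) >= 3]
    out = []
    seen = set()
    for u in internal:
        for v in adj.nbrs[u]:
            if v not in internal or (v, u) in seen:
                continue
            seen.add((u, v))
            side_u = [adj.side(x, blocked=u) for x in adj.nbrs[u] if x != v]
            side_v = [adj.side(x, blocked=v) for x in adj.nbrs[v] if x != u]
            if len(side_u) != 2 or len(side_v) != 2:
                raise ValueError("species tree must be binary")
            side_u.sort(key=lambda s: min(s))
            side_v.sort(key=lambda s: min(s))
            g1, g2 = side_u
            g3, g4 = side_v
            if min(min(g3), min(g4)) < min(min(g1), min(g2)):
                g1, g2, g3, g4 = g3, g4, g1, g2
            bid = "|".join(
                ",".join(sorted(g)) for g in (g1, g2, g3, g4)
            )
            out.append(FocalBranch(bid, (g1, g2, g3, g4)))
    out.sort(key=lambda b: b.branch_id)
    return out


def quartet_frequencies(
    gene_trees: Iterable[Tree], branch: FocalBranch
) -> QuartetFrequencies:
    """Frequencies of the three quartet resolutions around a focal branch.

    For each gene tree, every quartet formed by one leaf per neighbour group
    is tallied and the per-tree proportions are averaged; averaging across
    trees weights each gene tree equally regardless of clade size.
    Unresolved quartets are split equally over the three resolutions. Gene
    trees missing a whole neighbour group are skipped.
    """
    totals = np.zeros(3)
    n_used = 0
    for tree in gene_trees:
        taxa = tree.taxon_set()
        present = [sorted(g & taxa) for g in branch.groups]
        if any(not g for g in present):
            continue
        splits = tree.splits()
        tree_counts = np.zeros(3)
        n_q = 0
        for a, b, c, d in product(*present):
            pairing = quartet_pairing(splits, a, b, c, d)
            if pairing is None:
                tree_counts += 1.0 / 3.0
            else:
                tree_counts[pairing] += 1.0
            n_q += 1
        totals += tree_counts / n_q
        n_used += 1
    if n_used == 0:
        return QuartetFrequencies(math.nan, math.nan, math.nan, 0)
    freq = totals / n_used
    return QuartetFrequencies(float(freq[0]), float(freq[1]), float(freq[2]), n_used)


def msc_quartet_expectation(t: float) -> tuple[float, float, float]:
    """MSC quartet-resolution probabilities for an internal branch of length
    ``t`` coalescent units: (1 - (2/3)e^-t, (1/3)e^-t, (1/3)e^-t)."""
    if t < 0:
        raise ValueError("branch length must be >= 0")
    disc = math.exp(-t) / 3.0
    return (1.0 - 2.0 * disc, disc, disc)


# ---------------------------------------------------------------------------
# Exhaustive quartet-score species-tree estimation
# ---------------------------------------------------------------------------


def enumerate_unrooted_topologies(taxa: Sequence[str]) -> list[Tree]:
    """All (2n-5)!! unrooted binary topologies on ``taxa`` (n >= 3)."""
    taxa = sorted(taxa)
    if len(taxa) < 3:
        raise ValueError("need at least 3 taxa")

    base = Tree(Node(None, None, [Node(t) for t in taxa[:3]]))
    trees = [base]
    for label in taxa[3:]:
        nxt: list[Tree] = []
        for t in trees:
            edges = _edge_count(t)
            for e in range(edges):
                nxt.append(_insert_on_edge(t, e, label))
        trees = nxt
    return trees


def _edge_count(tree: Tree) -> int:
    return sum(1 for n in tree.root.walk() if n is not tree.root)


def _insert_on_edge(tree: Tree, edge_index: int, label: str) -> Tree:
    new = tree.copy()
    idx = [-1]

    def rec(parent: Node) -> bool:
        for i, child in enumerate(parent.children):
            idx[0] += 1
            if idx[0] == edge_index:
                mid = Node(None, None, [child, Node(label)])
                parent.children[i] = mid
                return True
            if rec(child):
                return True
        return False

    rec(new.root)
    return new


def quartet_score_species_tree(
    gene_trees: Sequence[Tree],
    taxa: Optional[Sequence[str]] = None,
    max_exhaustive: int = 8,
) -> tuple[Tree, float, list[str]]:
    """Exhaustive quartet-score species-tree estimate.

    Scores every unrooted candidate topology by the total number of induced
    quartet topologies it shares with the gene trees and returns the argmax
    (plus its score and the canonical ids of any tied candidates; ties are
    broken by canonical-id order). Intended for small taxon sets — an
    exhaustive substitute for summary methods' heuristics.
    """
    gene_trees = list(gene_trees)
    if taxa is None:
        taxa = sorted(frozenset().union(*(t.taxon_set() for t in gene_trees)))
    taxa = sorted(taxa)
    if len(taxa) > max_exhaustive:
        raise ValueError(
            f"{len(taxa)} taxa exceeds the exhaustive-search limit "
            f"{max_exhaustive}; import an externally estimated species tree"
        )
    quartets = list(combinations(taxa, 4))
    qindex = {q: i for i, q in enumerate(quartets)}
    counts = np.zeros((len(quartets), 3))
    for tree in gene_trees:
        present = tree.taxon_set()
        splits = tree.splits()
        for q in quartets:
            if not set(q) <= present:
                continue
            pairing = quartet_pairing(splits, *q)
            if pairing is not None:
                counts[qindex[q], pairing] += 1

    best_score = -1.0
    best: list[tuple[str, Tree]] = []
    for cand in enumerate_unrooted_topologies(taxa):
        splits = cand.splits()
        score = 0.0
        for q in quartets:
            pairing = quartet_pairing(splits, *q)
            if pairing is not None:
                score += counts[qindex[q], pairing]
        if score > best_score + 1e-9:
            best_score = score
            best = [(cand.canonical_id(), cand)]
        elif abs(score - best_score) <= 1e-9:
            best.append((cand.canonical_id(), cand))
    best.sort(key=lambda x: x[0])
    ties = [cid for cid, _ in best]
    return best[0][1], float(best_score), ties


# ---------------------------------------------------------------------------
# Folded positional stratification
# ---------------------------------------------------------------------------


def fold_position(pos: int, chrom_length: int, n_bins: int = 5) -> int:
    """Bin a chromosome position into folded telomere-to-middle fifths.

    The chromosome is folded in half so both ends map together: with
    r = min(pos, L-1-pos) / (L/2), bin ``n_bins`` is telomere-proximal
    (r near 0) and bin 1 is the chromosome middle. Positions exactly on a
    bin boundary go to the more telomere-proximal bin. Mirrored positions
    (pos and L-1-pos) always map to the same bin.
    """
    if not 0 <= pos < chrom_length:
        raise ValueError(f"position {pos} outside [0, {chrom_length})")
    m = min(pos, chrom_length - 1 - pos)
    if m == 0:
        return n_bins
    # r * n_bins = 2 * n_bins * m / L, exactly in integer arithmetic
    k = -((-2 * n_bins * m) // chrom_length)  # ceil
    return max(1, n_bins - int(k) + 1)


def regional_topology_frequencies(
    windows: pd.DataFrame,
    chrom_lengths: dict[str, int],
    min_trees_per_chrom: int = 20,
    n_bins: int = 5,
) -> tuple[pd.DataFrame, float, float, list[str]]:
    """Topology frequencies per folded chromosomal bin, with a chi-square
    homogeneity test across bins.

    ``windows`` needs columns chrom, start, end, topology (one row per
    window-based gene tree); window midpoints are binned. Chromosomes
    contributing fewer than ``min_trees_per_chrom`` trees are excluded.
    Returns (per-bin table, chi2 statistic, p-value, excluded chromosomes);
    empty bins appear with zero counts but do not contribute degrees of
    freedom.
    """
    required = {"chrom", "start", "end", "topology"}
    if not required <= set(windows.columns):
        raise ValueError(f"windows table needs columns {sorted(required)}")
    counts_per_chrom = windows["chrom"].value_counts()
    excluded = sorted(
        c for c in counts_per_chrom.index if counts_per_chrom[c] < min_trees_per_chrom
    )
    kept = windows[~windows["chrom"].isin(excluded)].copy()
    if kept.empty:
        empty = pd.DataFrame(columns=["bin", "topology", "count", "frequency"])
        return empty, math.nan, math.nan, excluded

    mids = ((kept["start"] + kept["end"]) // 2).to_numpy()
    bins = np.array(
        [
            fold_position(int(m), int(chrom_lengths[c]), n_bins)
            for m, c in zip(mids, kept["chrom"])
        ]
    )
    kept["bin"] = bins

    table = (
        kept.groupby(["bin", "topology"]).size().unstack(fill_value=0)
        .reindex(range(1, n_bins + 1), fill_value=0)
    )
    long = table.stack().rename("count").reset_index()
    long.columns = ["bin", "topology", "count"]
    totals = long.groupby("bin")["count"].transform("sum")
    long["frequency"] = np.where(totals > 0, long["count"] / totals, 0.0)

    observed = table.to_numpy(dtype=float)
    nonempty = observed.sum(axis=1) > 0
    observed = observed[nonempty]
    if observed.shape[0] < 2 or observed.shape[1] < 2:
        return long, 0.0, 1.0, excluded
    # drop all-zero topology columns (cannot happen after grouping, kept safe)
    observed = observed[:, observed.sum(axis=0) > 0]
    chi2, p, _, _ = stats.chi2_contingency(observed)
    return long, float(chi2), float(p), excluded
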