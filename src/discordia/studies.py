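"""Self-contained simulation studies exercising the full pipeline.

Each routine generates its own data with the package's coalescent simulator
under fixed study conditions, runs the relevant analysis stage, and returns
the measured quantity — Monte-Carlo agreement with the MSC closed form,
type-I error calibration and power of the D statistic, D_FOIL direction
recovery, neighbor-joining recovery on additive matrices, pattern-counter
equivalence with brute-force enumeration, and detection of a planted
positional introgression signal.
"""

from __future__ import annotations

import math
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from ._phylo import Node, Tree
from .concord import (
    focal_branches,
    fold_position,
    msc_quartet_expectation,
    quartet_frequencies,
    regional_topology_frequencies,
)
from .dfoil import PATTERN_NAMES, count_patterns5, dfoil_stats
from .dstat import count_patterns4, jackknife_z, patterson_d
from .simcoal import (
    IntrogressionEvent,
    SimConfig,
    SpeciesTreeModel,
    sample_gene_tree,
    simulate_windows,
)
from .treebuild import DistanceMatrix, canonical_topology, nj_tree
from .winio import AlignmentWindow, SnpMatrix, extract_biallelic_sites

TRIO_TREE = "(((P1:1.0,P2:1.0):0.5,P3:1.5):2.0,O:3.5);"
DFOIL_TREE = "(((P1:0.5,P2:0.5):1.0,(P3:1.0,P4:1.0):0.5):1.5,O:3.0);"


# ---------------------------------------------------------------------------
# Quartet-frequency agreement with the MSC closed form
# ---------------------------------------------------------------------------


def quartet_oracle_agreement(
    t_values: Sequence[float] = (0.0, 0.5, 1.0, 2.0),
    n_trees: int = 10_000,
    seed: int = 0,
) -> list[dict]:
    """Observed vs expected quartet frequencies around a focal branch of
    length T, from ``n_trees`` simulated gene trees per T.

    The species tree is (((A,B):T,C):8,D): the deeper internal branch is
    effectively infinite so the focal branch alone governs discordance.
    """
    rng = np.random.default_rng(seed)
    out = []
    for t_len in t_values:
        model = SpeciesTreeModel.from_newick(
            f"(((A:1,B:1):{t_len},C:{1 + t_len}):8,D:{9 + t_len});"
        )
        trees = [sample_gene_tree(model, rng=rng) for _ in range(n_trees)]
        branch = next(
            b
            for b in focal_branches(model.tree)
            if {frozenset("A"), frozenset("B")} <= set(b.groups)
        )
        qf = quartet_frequencies(trees, branch)
        expected = msc_quartet_expectation(t_len)
        se1 = math.sqrt(expected[0] * (1 - expected[0]) / n_trees)
        se2 = math.sqrt(expected[1] * (1 - expected[1]) / n_trees)
        out.append(
            {
                "T": t_len,
                "observed": (qf.t1, qf.t2, qf.t3),
                "expected": expected,
                "se": (se1, se2, se2),
                "n": n_trees,
            }
        )
    return out


# ---------------------------------------------------------------------------
# D statistic: calibration and power
# ---------------------------------------------------------------------------


def d_type_i_error(
    n_replicates: int = 100,
    n_windows: int = 1_300,
    window_length: int = 25,
    mutation_scale: float = 0.005,
    seed: int = 0,
) -> tuple[float, int]:
    """Fraction of ILS-only replicate datasets whose trio D rejects at
    p < 0.05 (should be ~0.05); ~2,000 SNPs per dataset.

    Many short loci keep each jackknife block an aggregate of dozens of
    independent genealogies, which the block-jackknife variance needs; a
    residual excess over 5% (~0.065) is inherent to reading the 20-block
    jackknife Z against the normal tail.
    """
    model = SpeciesTreeModel.from_newick(TRIO_TREE)
    rej = 0
    for i in range(n_replicates):
        cfg = SimConfig(
            n_windows=n_windows,
            window_length=window_length,
            mutation_scale=mutation_scale,
            seed=seed * 100_003 + i,
        )
        ds = simulate_windows(cfg, model)
        snps = extract_biallelic_sites(ds.windows, outgroup="O")
        _, p, _, flag = jackknife_z(snps, "P1", "P2", "P3", "O")
        if flag == "ok" and p < 0.05:
            rej += 1
    return rej / n_replicates, n_replicates


def d_power(
    gamma: float = 0.3,
    n_replicates: int = 20,
    n_windows: int = 5_000,
    window_length: int = 100,
    mutation_scale: float = 0.01,
    event_time: float = 0.2,
    seed: int = 0,
) -> tuple[float, int]:
    """Fraction of replicates where a recent P3 -> P1 pulse yields D > 0
    with p < 0.05 (counts polarized so the recipient sits in the P2 slot)."""
    model = SpeciesTreeModel.from_newick(TRIO_TREE)
    ev = IntrogressionEvent("P3", "P1", event_time, gamma)
    hits = 0
    for i in range(n_replicates):
        cfg = SimConfig(
            n_windows=n_windows,
            window_length=window_length,
            mutation_scale=mutation_scale,
            seed=seed * 100_019 + i,
        )
        ds = simulate_windows(cfg, model, [ev])
        snps = extract_biallelic_sites(ds.windows, outgroup="O")
        counts = count_patterns4(snps, "P2", "P1", "P3", "O")
        d = patterson_d(counts)
        _, p, _, flag = jackknife_z(snps, "P2", "P1", "P3", "O")
        if flag == "ok" and d > 0 and p < 0.05:
            hits += 1
    return hits / n_replicates, n_replicates


# ---------------------------------------------------------------------------
# D_FOIL direction recovery
# ---------------------------------------------------------------------------

DIRECTION_CONFIGS = (("P3", "P1"), ("P1", "P3"), ("P4", "P2"), ("P2", "P4"))


def dfoil_direction_recovery(
    n_replicates: int = 15,
    n_windows: int = 5_000,
    window_length: int = 150,
    mutation_scale: float = 0.04,
    gamma: float = 0.3,
    event_time: float = 0.05,
    alpha: float = 0.01,
    seed: int = 0,
    configs: Sequence[tuple[str, str]] = DIRECTION_CONFIGS,
) -> dict:
    """Classify a planted pulse for each donor/recipient configuration.

    Sites are thinned to at most one per window so the per-component
    chi-square sees approximately independent draws. Returns per-config
    modal calls plus the overall per-replicate accuracy.
    """
    model = SpeciesTreeModel.from_newick(DFOIL_TREE)
    results = {}
    n_correct = 0
    n_total = 0
    for k, (donor, recipient) in enumerate(configs):
        ev = IntrogressionEvent(donor, recipient, event_time, gamma)
        truth = f"{donor}=>{recipient}"
        calls = []
        for i in range(n_replicates):
            cfg = SimConfig(
                n_windows=n_windows,
                window_length=window_length,
                mutation_scale=mutation_scale,
                seed=seed * 100_043 + k * 1_009 + i,
            )
            ds = simulate_windows(cfg, model, [ev])
            snps = extract_biallelic_sites(
                ds.windows, outgroup="O", thin=window_length
            )
            res = dfoil_stats(
                count_patterns5(snps, "P1", "P2", "P3", "P4", "O"), alpha=alpha
            )
            calls.append(res.classification)
        modal = max(set(calls), key=calls.count)
        results[truth] = {
            "modal_call": modal,
            "calls": calls,
            "correct": modal == truth,
        }
        n_correct += sum(c == truth for c in calls)
        n_total += len(calls)
    results["accuracy"] = n_correct / n_total
    results["n"] = n_total
    return results


# ---------------------------------------------------------------------------
# Brute-force pattern-counter equivalence
# ---------------------------------------------------------------------------


def _brute4(cols: list[str]) -> tuple[int, int, int, int]:
    abba = baba = bbaa = used = 0
    for c in cols:
        if "N" in c or len(set(c)) != 2:
            continue
        used += 1
        d = tuple(x != c[3] for x in c[:3])
        abba += d == (False, True, True)
        baba += d == (True, False, True)
        bbaa += d == (True, True, False)
    return abba, baba, bbaa, used


def _brute5(cols: list[str]) -> dict[str, int]:
    counts = {name: 0 for name in PATTERN_NAMES}
    for c in cols:
        if "N" in c or len(set(c)) != 2:
            continue
        name = "".join("B" if c[i] != c[4] else "A" for i in range(4))
        counts[name] += 1
    return counts


def _random_matrix(rng: np.random.Generator, n_taxa: int) -> tuple[SnpMatrix, list[str]]:
    n_sites = int(rng.integers(0, 51))
    alphabet = np.frombuffer(b"ACGTN", dtype="S1")
    taxa = [f"T{i}" for i in range(n_taxa)]
    alleles = alphabet[rng.integers(0, 5, size=(n_taxa, n_sites))]
    cols = [
        "".join(alleles[i, j].decode() for i in range(n_taxa))
        for j in range(n_sites)
    ]
    snps = SnpMatrix(
        taxa, alleles, np.array(["c"] * n_sites), np.arange(n_sites)
    )
    return snps, cols


def pattern_oracle_equivalence(n_cases: int = 1_000, seed: int = 0) -> tuple[float, int]:
    """Fraction of random matrices (<= 50 sites) on which the vectorized 4-
    and 5-taxon pattern counters equal independent per-site enumeration."""
    rng = np.random.default_rng(seed)
    ok = 0
    half = n_cases // 2
    for i in range(n_cases):
        if i < half:
            snps, cols = _random_matrix(rng, 4)
            c = count_patterns4(snps, "T0", "T1", "T2", "T3")
            ok += (c.n_abba, c.n_baba, c.n_bbaa, c.n_sites_used) == _brute4(cols)
        else:
            snps, cols = _random_matrix(rng, 5)
            c = count_patterns5(snps, "T0", "T1", "T2", "T3", "T4")
            expected = _brute5(cols)
            ok += all(c[name] == expected[name] for name in PATTERN_NAMES)
    return ok / n_cases, n_cases


# ---------------------------------------------------------------------------
# Neighbor-joining recovery on additive matrices
# ---------------------------------------------------------------------------


def random_additive_tree(
    labels: Sequence[str],
    rng: np.random.Generator,
    min_bl: float = 0.02,
    max_bl: float = 0.5,
) -> tuple[Tree, list[str], np.ndarray]:
    """Random unrooted binary topology with uniform branch lengths and its
    exact path-distance matrix (tree-additive by construction)."""
    labels = list(labels)
    root = Node(None, None, [Node(lab) for lab in labels[:3]])
    tree = Tree(root)
    for lab in labels[3:]:
        edges = [
            (parent, i)
            for parent in tree.root.walk()
            for i in range(len(parent.children))
        ]
        parent, i = edges[rng.integers(len(edges))]
        old = parent.children[i]
        parent.children[i] = Node(None, None, [old, Node(lab)])
    for node in tree.root.walk():
        if node is not tree.root:
            node.length = float(rng.uniform(min_bl, max_bl))

    idx = {lab: i for i, lab in enumerate(labels)}
    dist = np.zeros((len(labels), len(labels)))

    def depths(node: Node, acc: float) -> dict[str, float]:
        if node.is_leaf:
            return {node.label: acc}
        out: dict[str, float] = {}
        for c in node.children:
            out.update(depths(c, acc + c.length))
        return out

    def fill(node: Node) -> None:
        for c in node.children:
            fill(c)
        subs = [depths(c, c.length) for c in node.children]
        for a, b in combinations(range(len(subs)), 2):
            for la, da in subs[a].items():
                for lb, db in subs[b].items():
                    dist[idx[la], idx[lb]] = dist[idx[lb], idx[la]] = da + db

    fill(tree.root)
    return tree, labels, dist


def nj_recovery_rate(
    n_cases: int = 500, max_taxa: int = 8, seed: int = 0
) -> tuple[float, int]:
    """Fraction of random tree-additive matrices whose NJ tree matches the
    generating topology exactly."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_cases):
        n_taxa = int(rng.integers(4, max_taxa + 1))
        labels = [f"t{i}" for i in range(n_taxa)]
        tree, labels, dist = random_additive_tree(labels, rng)
        dm = DistanceMatrix(labels, dist, np.full(dist.shape, "ok", dtype=object))
        hits += canonical_topology(nj_tree(dm)) == canonical_topology(tree)
    return hits / n_cases, n_cases


# ---------------------------------------------------------------------------
# Window/filter contracts
# ---------------------------------------------------------------------------


def window_filter_contracts() -> dict[str, int | bool]:
    """Deterministic checks of the stated windowing and filter rules."""
    from .winio import filter_windows, make_windows

    seq = ("ACGT" * 9000)[:35_000]
    wins = make_windows({"A": seq, "B": seq, "C": seq}, window_size=10_000)

    boundary = AlignmentWindow({"A": "A" * 150, "B": "A" * 150}, "c", 0, 150)
    short = AlignmentWindow({"A": "A" * 200, "B": "A" * 100 + "-" * 100}, "c", 0, 200)
    missing_col = AlignmentWindow(
        {t: s for t, s in zip("ABCD", ["A", "C", "C", "N"])}, "c", 0, 1
    )
    snps_strict = extract_biallelic_sites([missing_col], outgroup="D", max_missing=0.2)
    return {
        "windows_from_35kb": len(wins),
        "boundary_150_retained": filter_windows([boundary], min_len=150) == [boundary],
        "short_window_removed": filter_windows([short], min_len=150) == [],
        "missing_quarter_site_dropped": snps_strict.n_sites == 0,
    }


# ---------------------------------------------------------------------------
# Regional stratification with a planted positional signal
# ---------------------------------------------------------------------------


def regional_signal_detection(
    n_windows: int = 1_000,
    window_length: int = 100,
    gamma: float = 0.5,
    seed: int = 0,
) -> tuple[float, float, int]:
    """Plant gamma gene flow only in the two telomere-proximal bins of one
    folded chromosome and test topology-frequency homogeneity across bins.

    Returns (chi2, p, n_windows). True gene-tree topologies are used so the
    test isolates the positional signal from inference noise.
    """
    rng = np.random.default_rng(seed)
    model = SpeciesTreeModel.from_newick("(((A:1,B:1):1,C:2):8,D:10);")
    ev = IntrogressionEvent("C", "A", 0.2, gamma)
    length = n_windows * window_length
    rows = []
    for i in range(n_windows):
        start, end = i * window_length, (i + 1) * window_length
        b = fold_position((start + end) // 2, length)
        events = [ev] if b >= 4 else []
        tree = sample_gene_tree(model, events, rng=rng)
        rows.append(("chr1", start, end, canonical_topology(tree)))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "topology"])
    _, chi2, p, _ = regional_topology_frequencies(
        df, {"chr1": length}, min_trees_per_chrom=20
    )
    return chi2, p, n_windows


def fold_mirror_agreement(n_positions: int = 10_000, seed: int = 0) -> tuple[float, int]:
    """Fraction of random (position, length) draws where a position and its
    mirror land in the same folded bin (must be 1.0)."""
    rng = np.random.default_rng(seed)
    ok = 0
    for _ in range(n_positions):
        length = int(rng.integers(2, 10**7))
        pos = int(rng.integers(0, length))
        ok += fold_position(pos, length) == fold_position(length - 1 - pos, length)
    return ok / n_positions, n_positions
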