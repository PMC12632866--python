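"""Per-window gene-tree inference and topology bookkeeping.

Gene trees are built from Jukes-Cantor distances with neighbor-joining — a
deterministic, self-contained estimator adequate for topology-level
discordance analysis; externally inferred newick trees can be imported to
bypass this stage entirely. Includes column-bootstrap support, outgroup
rooting, order-invariant canonical topology identifiers, a strain-monophyly
filter and topology counting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from ._phylo import Node, Tree
from .winio import AlignmentWindow

__all__ = [
    "WindowRejected",
    "JCDistance",
    "DistanceMatrix",
    "jc69_distance",
    "jc_distance_matrix",
    "nj_tree",
    "bootstrap_support",
    "root_by_outgroup",
    "canonical_topology",
    "monophyly_filter",
    "count_topologies",
]

SATURATION_P = 0.75


class WindowRejected(ValueError):
    """A window that cannot yield a usable gene tree (with the reason)."""


@dataclass(frozen=True)
class JCDistance:
    """A pairwise JC69 distance with its diagnostic state.

    ``status`` is ``ok``, ``saturated`` (mismatch fraction >= 0.75) or
    ``undefined`` (no comparable sites); ``d`` is NaN unless ``ok``."""

    d: float
    p: float
    n_sites: int
    status: str

    @property
    def usable(self) -> bool:
        return self.status == "ok"


def jc69_distance(seq_a: str, seq_b: str) -> JCDistance:
    """JC69 distance d = -(3/4) ln(1 - (4/3) p) over pairwise-comparable sites.

    Sites with a gap or missing character in either sequence are excluded
    pairwise.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned to equal length")
    a = np.frombuffer(seq_a.upper().encode(), dtype="S1")
    b = np.frombuffer(seq_b.upper().encode(), dtype="S1")
    bad = np.isin(a, [b"N", b"-", b"?"]) | np.isin(b, [b"N", b"-", b"?"])
    comparable = ~bad
    n = int(comparable.sum())
    if n == 0:
        return JCDistance(math.nan, math.nan, 0, "undefined")
    p = float((a[comparable] != b[comparable]).mean())
    if p >= SATURATION_P:
        return JCDistance(math.nan, p, n, "saturated")
    d = -0.75 * math.log(1.0 - (4.0 / 3.0) * p)
    return JCDistance(d, p, n, "ok")


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray  # substitutions/site; NaN where unusable
    status: np.ndarray  # object array of per-pair status strings

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("diagonal must be zero")
        finite = self.d[~np.isnan(self.d)]
        if (finite < 0).any():
            raise ValueError("distances must be non-negative")
        if not np.array_equal(
            np.nan_to_num(self.d, nan=-1.0), np.nan_to_num(self.d.T, nan=-1.0)
        ):
            raise ValueError("distance matrix must be symmetric")

    def usable(self) -> bool:
        return not np.isnan(self.d).any()


def jc_distance_matrix(window: AlignmentWindow | dict[str, str]) -> DistanceMatrix:
    seqs = window.sequences if isinstance(window, AlignmentWindow) else window
    taxa = list(seqs)
    n = len(taxa)
    d = np.zeros((n, n))
    status = np.full((n, n), "ok", dtype=object)
    for i, j in combinations(range(n), 2):
        jc = jc69_distance(seqs[taxa[i]], seqs[taxa[j]])
        d[i, j] = d[j, i] = jc.d if jc.usable else math.nan
        status[i, j] = status[j, i] = jc.status
    return DistanceMatrix(taxa, d, status)


# ---------------------------------------------------------------------------
# Neighbor-joining
# ---------------------------------------------------------------------------


def nj_tree(dm: DistanceMatrix) -> Tree:
    """Standard neighbor-joining (Q-criterion agglomeration).

    Ties in Q are broken by the lowest (i, j) index pair in the current
    agglomeration order and negative branch lengths are clamped to zero, so
    results are reproducible. Returns an unrooted tree (trifurcating root
    node). Raises :class:`WindowRejected` on saturated/undefined distances.
    """
    if len(dm.taxa) < 3:
        raise ValueError("neighbor-joining needs at least 3 taxa")
    if not dm.usable():
        bad = [
            (dm.taxa[i], dm.taxa[j], dm.status[i, j])
            for i, j in zip(*np.nonzero(np.isnan(dm.d)))
            if i < j
        ]
        raise WindowRejected(f"unusable distances: {bad}")

    nodes: list[Node] = [Node(t) for t in dm.taxa]
    d = dm.d.copy()
    active = list(range(len(dm.taxa)))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index tie-break: scan in row-major order
        best = (np.inf, -1, -1)
        for ai in range(m):
            for aj in range(ai + 1, m):
                if q[ai, aj] < best[0] - 1e-12:
                    best = (q[ai, aj], ai, aj)
        _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = d[i, j]
        vi = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        vj = dij - vi
        vi, vj = max(vi, 0.0), max(vj, 0.0)
        parent = Node(None)
        nodes[i].length = vi
        nodes[j].length = vj
        parent.add(nodes[i])
        parent.add(nodes[j])
        new_d = 0.5 * (d[i, active] + d[j, active] - dij)
        k = i  # reuse slot i for the new node
        d[k, active] = new_d
        d[active, k] = new_d
        d[k, k] = 0.0
        nodes[k] = parent
        active.remove(j)

    # final three-way join
    i, j, k = active
    root = Node(None)
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    for idx, ln in ((i, li), (j, lj), (k, lk)):
        nodes[idx].length = max(ln, 0.0)
        root.add(nodes[idx])
    return Tree(root)


def nj_from_window(window: AlignmentWindow | dict[str, str]) -> Tree:
    return nj_tree(jc_distance_matrix(window))


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------


def bootstrap_support(
    window: AlignmentWindow | dict[str, str],
    b: int = 100,
    rng: Optional[np.random.Generator] = None,
) -> Tree:
    """NJ tree with internal branches annotated by bootstrap percentages.

    Alignment columns are resampled with replacement ``b`` times; each
    internal branch of the full-data tree is labelled with the percentage of
    successful replicates containing the same bipartition. Replicates whose
    resampled distances are unusable are skipped (the denominator is the
    number of successful replicates).
    """
    if b < 1:
        raise ValueError("bootstrap replicate count must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    seqs = window.sequences if isinstance(window, AlignmentWindow) else window
    base = nj_from_window(seqs)
    length = len(next(iter(seqs.values())))
    names = list(seqs)
    arrs = {t: np.frombuffer(seqs[t].encode(), dtype="S1") for t in names}

    counts: dict[frozenset[str], int] = {}
    n_ok = 0
    all_taxa = base.taxon_set()
    for _ in range(b):
        cols = rng.integers(0, length, size=length)
        resampled = {t: arrs[t][cols].tobytes().decode() for t in names}
        try:
            rep = nj_from_window(resampled)
        except WindowRejected:
            continue
        n_ok += 1
        for s in rep.splits():
            key = min(s, frozenset(all_taxa - s), key=sorted)
            counts[key] = counts.get(key, 0) + 1

    def annotate(n: Node, below: frozenset[str]) -> None:
        if n.is_leaf:
            return
        if n is not base.root and 1 < len(below) < len(all_taxa) - 1:
            key = min(below, frozenset(all_taxa - below), key=sorted)
            pct = 100.0 * counts.get(key, 0) / max(n_ok, 1)
            n.label = f"{pct:.0f}"

    def rec(n: Node) -> frozenset[str]:
        if n.is_leaf:
            return frozenset((n.label,))
        below = frozenset().union(*(rec(c) for c in n.children))
        annotate(n, below)
        return below

    rec(base.root)
    return base


# ---------------------------------------------------------------------------
# Rooting, canonical ids, filters, counting
# ---------------------------------------------------------------------------


def root_by_outgroup(tree: Tree, outgroup: Iterable[str] | str) -> Tree:
    """Root on the branch separating the outgroup from the ingroup."""
    return tree.rooted_by_outgroup(outgroup)


def canonical_topology(
    tree: Tree, restrict_to: Optional[Iterable[str]] = None, rooted: bool = False
) -> str:
    """Order-invariant topology identifier, optionally on an induced subset."""
    return tree.canonical_id(restrict_to=restrict_to, rooted=rooted)


def monophyly_filter(
    trees: Iterable[Tree],
    clade_taxa: Iterable[str],
    outgroup: Optional[str | Iterable[str]] = None,
) -> list[Tree]:
    """Keep trees in which ``clade_taxa`` form a clade.

    Trees missing any of the clade taxa (or the outgroup) are rejected. With
    an outgroup the test is performed under outgroup rooting; without one,
    the unrooted bipartition is tested.
    """
    clade = frozenset(clade_taxa)
    og = (
        None
        if outgroup is None
        else (frozenset((outgroup,)) if isinstance(outgroup, str) else frozenset(outgroup))
    )
    kept = []
    for t in trees:
        taxa = t.taxon_set()
        if not clade <= taxa or (og is not None and not og <= taxa):
            continue
        if clade == taxa:
            kept.append(t)
            continue
        if og is not None:
            try:
                rooted = t.rooted_by_outgroup(og)
            except ValueError:
                continue
            if clade in rooted.clades():
                kept.append(t)
        else:
            for s in t.splits():
                if s == clade or taxa - s == clade:
                    kept.append(t)
                    break
    return kept


def count_topologies(
    trees: Iterable[Tree],
    restrict_to: Optional[Iterable[str]] = None,
    rooted: bool = False,
) -> pd.DataFrame:
    """Tally canonical topology identifiers.

    Degenerate identifiers (induced subsets with < 3 taxa) are excluded from
    the frequency denominator. Rows are ordered by descending count, then by
    identifier.
    """
    ids = []
    for t in trees:
        cid = canonical_topology(t, restrict_to=restrict_to, rooted=rooted)
        if not cid.startswith("degenerate"):
            ids.append(cid)
    if not ids:
        return pd.DataFrame(columns=["canonical_id", "count", "frequency"])
    ser = pd.Series(ids).value_counts()
    df = pd.DataFrame(
        {"canonical_id": ser.index, "count": ser.to_numpy(dtype=int)}
    )
    df = df.sort_values(
        ["count", "canonical_id"], ascending=[False, True], ignore_index=True
    )
    df["frequency"] = df["count"] / df["count"].sum()
    return df
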