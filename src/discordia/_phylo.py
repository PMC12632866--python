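"""Lightweight rooted-tree structure shared by the simulator and analysis stages.

Trees are stored as plain ``Node`` objects (children lists, optional branch
lengths). Newick text is parsed through dendropy and converted; everything
that runs once per window or once per gene tree (splits, quartet induction,
canonical identifiers, re-rooting) operates on this structure directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

__all__ = [
    "Node",
    "Tree",
    "parse_newick",
    "read_newick_trees",
]


@dataclass
class Node:
    label: Optional[str] = None
    length: Optional[float] = None
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add(self, child: "Node") -> "Node":
        self.children.append(child)
        return child

    def walk(self) -> Iterator["Node"]:
        """Pre-order traversal."""
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))


class Tree:
    """A rooted tree over uniquely labelled leaves.

    Unrooted semantics (bipartitions, canonical topology ids) are obtained by
    ignoring root placement, so the same object serves both views.
    """

    def __init__(self, root: Node):
        self.root = root

    # ------------------------------------------------------------------ basics

    def leaves(self) -> list[Node]:
        return [n for n in self.root.walk() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        labels = [n.label for n in self.leaves()]
        if any(l is None for l in labels):
            raise ValueError("tree has unlabelled leaves")
        return labels  # type: ignore[return-value]

    def taxon_set(self) -> frozenset[str]:
        return frozenset(self.leaf_labels())

    def copy(self) -> "Tree":
        def rec(n: Node) -> Node:
            return Node(n.label, n.length, [rec(c) for c in n.children])

        return Tree(rec(self.root))

    # ------------------------------------------------------------------ newick

    def to_newick(self, lengths: bool = True, precision: int = 6) -> str:
        def rec(n: Node) -> str:
            if n.is_leaf:
                s = n.label or ""
            else:
                s = "(" + ",".join(rec(c) for c in n.children) + ")"
                if n.label:
                    s += n.label
            if lengths and n.length is not None:
                s += f":{n.length:.{precision}g}"
            return s

        return rec(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tree({self.to_newick(lengths=False)})"

    # ------------------------------------------------------------- bipartitions

    def splits(self) -> list[frozenset[str]]:
        """Non-trivial unrooted bipartitions, each reported as one side.

        The side returned is the leaf set under the corresponding node; the
        root's own edge is excluded (it is not an internal edge of the
        unrooted tree).
        """
        all_taxa = self.taxon_set()
        out: list[frozenset[str]] = []

        def rec(n: Node) -> frozenset[str]:
            if n.is_leaf:
                return frozenset((n.label,))  # type: ignore[arg-type]
            below = frozenset().union(*(rec(c) for c in n.children))
            if n is not self.root and 1 < len(below) < len(all_taxa) - 1:
                out.append(below)
            return below

        rec(self.root)
        # A child of a bifurcating root duplicates the split of its sibling
        # subtree; deduplicate as unordered bipartitions.
        seen: set[frozenset[str]] = set()
        uniq = []
        for s in out:
            key = min(s, frozenset(all_taxa - s), key=sorted)
            if key not in seen:
                seen.add(key)
                uniq.append(s)
        return uniq

    def clades(self) -> list[frozenset[str]]:
        """Leaf sets of all internal nodes below the root (rooted view)."""
        out: list[frozenset[str]] = []

        def rec(n: Node) -> frozenset[str]:
            if n.is_leaf:
                return frozenset((n.label,))  # type: ignore[arg-type]
            below = frozenset().union(*(rec(c) for c in n.children))
            out.append(below)
            return below

        rec(self.root)
        return out

    # ---------------------------------------------------------------- pruning

    def pruned_to(self, taxa: Iterable[str]) -> "Tree":
        """Induced subtree on ``taxa``; unifurcations suppressed (lengths added)."""
        keep = set(taxa)
        missing = keep - self.taxon_set()
        if missing:
            raise KeyError(f"taxa not in tree: {sorted(missing)}")

        def rec(n: Node) -> Optional[Node]:
            if n.is_leaf:
                if n.label in keep:
                    return Node(n.label, n.length)
                return None
            kids = [k for k in (rec(c) for c in n.children) if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                child = kids[0]
                if child.length is not None and n.length is not None:
                    child.length += n.length
                elif n.length is not None and child.length is None:
                    child.length = n.length
                return child
            return Node(n.label, n.length, kids)

        new_root = rec(self.root)
        if new_root is None:
            raise ValueError("pruning removed every leaf")
        return Tree(new_root)

    # ---------------------------------------------------------------- rooting

    def rooted_by_outgroup(self, outgroup: Iterable[str] | str) -> "Tree":
        """Re-root so the outgroup taxa form one child clade of the root.

        Raises ``ValueError`` if the outgroup is not separable (no unrooted
        edge has exactly the outgroup on one side).
        """
        if isinstance(outgroup, str):
            og = frozenset((outgroup,))
        else:
            og = frozenset(outgroup)
        taxa = self.taxon_set()
        if not og or not og <= taxa:
            raise KeyError(f"outgroup {sorted(og)} not a subset of tree taxa")
        if og == taxa:
            raise ValueError("outgroup cannot be the whole leaf set")

        adj = _adjacency(self)
        # find the edge (u, v) with exactly the outgroup below v when cut
        for (u, v), length in adj.edges.items():
            side = adj.side(v, u)
            if side == og:
                return adj.reroot_on_edge(u, v, length)
        raise ValueError(f"outgroup {sorted(og)} is not a clade on any rooting")

    # ------------------------------------------------------------- canonical id

    def canonical_id(
        self, restrict_to: Optional[Iterable[str]] = None, rooted: bool = False
    ) -> str:
        """Order-invariant topology identifier (branch lengths ignored).

        For the unrooted view the tree is deterministically anchored at its
        lexicographically smallest leaf, so any rooting of the same topology
        yields the same string. Subsets with fewer than 3 taxa collapse to a
        single degenerate identifier.
        """
        taxa = self.taxon_set() if restrict_to is None else frozenset(restrict_to)
        if restrict_to is not None and not taxa <= self.taxon_set():
            raise KeyError("restrict_to contains taxa absent from tree")
        if len(taxa) < 3:
            return "degenerate(" + ",".join(sorted(taxa)) + ")"
        sub = self.pruned_to(taxa) if taxa != self.taxon_set() else self

        if rooted:
            return _canon_rooted(sub.root)

        anchor = min(taxa)
        adj = _adjacency(sub)
        nbr = adj.neighbours(anchor_label=anchor)
        parts = sorted(adj.canon(n, exclude=nbr.anchor_node) for n in nbr.others)
        return "(" + ",".join([anchor] + parts) + ");"


def _canon_rooted(n: Node) -> str:
    if n.is_leaf:
        return n.label or ""
    return "(" + ",".join(sorted(_canon_rooted(c) for c in n.children)) + ")"


# --------------------------------------------------------------------------
# Undirected adjacency view used for re-rooting and unrooted canonical forms.
# --------------------------------------------------------------------------


class _Adjacency:
    def __init__(self) -> None:
        self.nbrs: dict[int, list[int]] = {}
        self.edges: dict[tuple[int, int], Optional[float]] = {}
        self.labels: dict[int, Optional[str]] = {}

    def add_edge(self, a: int, b: int, length: Optional[float]) -> None:
        self.nbrs.setdefault(a, []).append(b)
        self.nbrs.setdefault(b, []).append(a)
        self.edges[(a, b)] = length
        self.edges[(b, a)] = length

    def side(self, start: int, blocked: int) -> frozenset[str]:
        """Leaf labels reachable from ``start`` without crossing ``blocked``."""
        seen = {blocked, start}
        stack = [start]
        labels = []
        while stack:
            x = stack.pop()
            if self.labels[x] is not None and len(self.nbrs[x]) == 1:
                labels.append(self.labels[x])
            for y in self.nbrs[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return frozenset(labels)  # type: ignore[arg-type]

    def _build(self, node_id: int, parent: int, length: Optional[float]) -> Node:
        n = Node(self.labels[node_id], length)
        for y in self.nbrs[node_id]:
            if y != parent:
                n.add(self._build(y, node_id, self.edges[(node_id, y)]))
        return n

    def reroot_on_edge(self, u: int, v: int, length: Optional[float]) -> Tree:
        half = None if length is None else length / 2.0
        root = Node(None, None)
        root.add(self._build(v, u, half))
        root.add(self._build(u, v, half))
        # orient outgroup side first for readability; caller sorted by search
        root.children.sort(key=lambda c: sorted(_leaf_labels_of(c)))
        tree = Tree(root)
        _suppress_unifurcations(tree.root)
        return tree

    class _Anchor:
        def __init__(self, anchor_node: int, others: list[int]):
            self.anchor_node = anchor_node
            self.others = others

    def neighbours(self, anchor_label: str) -> "._Anchor":  # type: ignore[name-defined]
        leaf = next(
            i
            for i, lab in self.labels.items()
            if lab == anchor_label and len(self.nbrs[i]) == 1
        )
        hub = self.nbrs[leaf][0]
        others = [y for y in self.nbrs[hub] if y != leaf]
        anch = _Adjacency._Anchor(leaf, others)
        anch.anchor_node = hub  # canonical recursion excludes the hub's anchor side
        anch.others = others
        anch.hub = hub
        return anch

    def canon(self, node_id: int, exclude: int) -> str:
        # exclude is the hub; recurse away from it
        return self._canon_from(node_id, parent=exclude)

    def _canon_from(self, node_id: int, parent: int) -> str:
        kids = [y for y in self.nbrs[node_id] if y != parent]
        if not kids:
            return self.labels[node_id] or ""
        return "(" + ",".join(sorted(self._canon_from(y, node_id) for y in kids)) + ")"


def _leaf_labels_of(n: Node) -> list[str]:
    return [x.label or "" for x in n.walk() if x.is_leaf]


def _suppress_unifurcations(root: Node) -> None:
    for n in list(root.walk()):
        changed = True
        while changed:
            changed = False
            for i, c in enumerate(list(n.children)):
                if not c.is_leaf and len(c.children) == 1:
                    g = c.children[0]
                    if g.length is not None and c.length is not None:
                        g.length += c.length
                    elif g.length is None:
                        g.length = c.length
                    n.children[i] = g
                    changed = True


def _adjacency(tree: Tree) -> _Adjacency:
    adj = _Adjacency()
    counter = [0]
    ids: dict[int, int] = {}

    def nid(node: Node) -> int:
        key = id(node)
        if key not in ids:
            ids[key] = counter[0]
            adj.labels[counter[0]] = node.label
            adj.nbrs.setdefault(counter[0], [])
            counter[0] += 1
        return ids[key]

    root = tree.root
    stack = [root]
    while stack:
        n = stack.pop()
        for c in n.children:
            adj.add_edge(nid(n), nid(c), c.length)
            stack.append(c)
    # splice out the root if it is a bifurcation (unrooted view)
    rid = ids[id(root)]
    if len(root.children) == 2 and root.label is None:
        a, b = (nid(c) for c in root.children)
        la = adj.edges[(rid, a)]
        lb = adj.edges[(rid, b)]
        total = None if (la is None or lb is None) else la + lb
        adj.nbrs[a].remove(rid)
        adj.nbrs[b].remove(rid)
        del adj.nbrs[rid]
        for key in ((rid, a), (a, rid), (rid, b), (b, rid)):
            adj.edges.pop(key, None)
        adj.add_edge(a, b, total)
    return adj


# ---------------------------------------------------------------------- parsing


def parse_newick(text: str) -> Tree:
    """Parse one newick string (via dendropy) into a :class:`Tree`."""
    import dendropy

    dtree = dendropy.Tree.get(
        data=text, schema="newick", preserve_underscores=True
    )
    return _from_dendropy(dtree)


def read_newick_trees(path) -> list[Tree]:
    """Read a file with one newick tree per line."""
    import dendropy

    tl = dendropy.TreeList.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
    return [_from_dendropy(t) for t in tl]


def _from_dendropy(dtree) -> Tree:
    def rec(dnode) -> Node:
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        n = Node(label, dnode.edge.length)
        for c in dnode.child_nodes():
            n.add(rec(c))
        return n

    return Tree(rec(dtree.seed_node))


def quartet_pairing(
    splits: list[frozenset[str]], a: str, b: str, c: str, d: str
) -> Optional[int]:
    """Which pairing of {a,b,c,d} a split set supports.

    Returns 0 for ab|cd, 1 for ac|bd, 2 for ad|bc, or None when no split
    separates the quartet (unresolved).
    """
    for s in splits:
        ina, inb, inc, ind = a in s, b in s, c in s, d in s
        k = ina + inb + inc + ind
        if k == 2:
            if ina and inb:
                return 0
            if inc and ind:
                return 0
            if ina and inc:
                return 1
            if inb and ind:
                return 1
            return 2
        if k == 1 or k == 3:
            continue
    return None
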