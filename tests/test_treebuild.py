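"""Distance estimation, neighbor-joining, bootstrap, rooting, topology
bookkeeping — including the additive-matrix recovery property."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_additive_tree
from discordia._phylo import parse_newick
from discordia.simcoal import SimConfig, SpeciesTreeModel, simulate_windows
from discordia.treebuild import (
    DistanceMatrix,
    WindowRejected,
    bootstrap_support,
    canonical_topology,
    count_topologies,
    jc69_distance,
    jc_distance_matrix,
    monophyly_filter,
    nj_from_window,
    nj_tree,
    root_by_outgroup,
)


class TestJC69:
    def test_identical_sequences_zero(self):
        est = jc69_distance("ACGTACGT", "ACGTACGT")
        assert est.usable and est.d == 0.0

    def test_quarter_mismatch_closed_form(self):
        # p = 0.25 -> d = -(3/4) ln(1 - 1/3) = 0.75 * ln(3/2)
        est = jc69_distance("AAAA", "AAAC")
        assert est.p == 0.25
        assert est.d == pytest.approx(-0.75 * math.log(2.0 / 3.0))
        assert est.d == pytest.approx(0.3040988, abs=1e-6)

    def test_saturation_flag(self):
        est = jc69_distance("AAAAA", "CCCCA")  # p = 0.8
        assert est.status == "saturated" and not est.usable

    def test_no_comparable_sites_undefined(self):
        est = jc69_distance("NNN", "ACG")
        assert est.status == "undefined"

    def test_pairwise_deletion(self):
        est = jc69_distance("ACGTN", "ACG-A")
        assert est.n_sites == 3 and est.d == 0.0

    def test_monotone_in_p(self):
        ds = []
        for k in range(0, 7):
            seq_b = "C" * k + "A" * (10 - k)
            ds.append(jc69_distance("A" * 10, seq_b).d)
        assert all(b > a for a, b in zip(ds, ds[1:]))

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            jc69_distance("ACG", "AC")


class TestNeighborJoining:
    def test_four_taxon_additive_split(self):
        taxa = ["A", "B", "C", "D"]
        d = np.array(
            [
                [0.0, 0.2, 0.3, 0.3],
                [0.2, 0.0, 0.3, 0.3],
                [0.3, 0.3, 0.0, 0.2],
                [0.3, 0.3, 0.2, 0.0],
            ]
        )
        dm = DistanceMatrix(taxa, d, np.full((4, 4), "ok", dtype=object))
        t = nj_tree(dm)
        assert canonical_topology(t) == canonical_topology(parse_newick("((A,B),(C,D));"))

    def test_three_taxa_star(self):
        dm = DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0, 0.1, 0.2], [0.1, 0, 0.3], [0.2, 0.3, 0]]),
            np.full((3, 3), "ok", dtype=object),
        )
        t = nj_tree(dm)
        assert t.taxon_set() == frozenset("ABC")

    def test_taxon_order_invariance(self, rng):
        tree, labels, dist = random_additive_tree("ABCDEF", rng)
        cid = canonical_topology(tree)
        for _ in range(3):
            perm = rng.permutation(len(labels))
            taxa_p = [labels[i] for i in perm]
            d_p = dist[np.ix_(perm, perm)]
            dm = DistanceMatrix(taxa_p, d_p, np.full(d_p.shape, "ok", dtype=object))
            assert canonical_topology(nj_tree(dm)) == cid

    def test_saturated_pair_rejects_window(self):
        seqs = {"A": "AAAAA", "B": "CCCCC", "C": "AAAAC"}
        with pytest.raises(WindowRejected):
            nj_from_window(seqs)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        n_taxa=st.integers(min_value=4, max_value=8),
        seed=st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_additive_recovery_property(self, n_taxa, seed):
        """NJ exactly recovers the generating topology of any tree-additive
        distance matrix."""
        rng = np.random.default_rng(seed)
        labels = [f"t{i}" for i in range(n_taxa)]
        tree, labels, dist = random_additive_tree(labels, rng)
        dm = DistanceMatrix(labels, dist, np.full(dist.shape, "ok", dtype=object))
        assert canonical_topology(nj_tree(dm)) == canonical_topology(tree)

    def test_agrees_with_skbio_on_random_matrix(self, rng):
        skbio = pytest.importorskip("skbio")
        tree, labels, dist = random_additive_tree("ABCDEFG", rng)
        noisy = dist + rng.uniform(0, 0.005, dist.shape)
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy, 0.0)
        dm = DistanceMatrix(labels, noisy, np.full(noisy.shape, "ok", dtype=object))
        ours = canonical_topology(nj_tree(dm))
        sk_tree = skbio.tree.nj(skbio.DistanceMatrix(noisy, ids=labels))
        theirs = canonical_topology(parse_newick(str(sk_tree)))
        assert ours == theirs


class TestBootstrap:
    def test_perfect_signal_full_support(self, rng):
        # strongly supported AB|CD split from repeated site patterns
        seqs = {
            "A": "A" * 70 + "C" * 10,
            "B": "A" * 70 + "C" * 10,
            "C": "A" * 70 + "G" * 10,
            "D": "A" * 70 + "G" * 10,
        }
        t = bootstrap_support(seqs, b=50, rng=rng)
        supports = [
            float(n.label)
            for n in t.root.walk()
            if not n.is_leaf and n.label is not None
        ]
        assert supports and all(s == 100.0 for s in supports)

    def test_supports_within_range(self, rng, quartet_model):
        ds = simulate_windows(
            SimConfig(n_windows=3, window_length=300, mutation_scale=0.05, seed=9),
            quartet_model,
        )
        for w in ds.windows:
            t = bootstrap_support(w, b=30, rng=rng)
            for n in t.root.walk():
                if not n.is_leaf and n.label is not None:
                    assert 0.0 <= float(n.label) <= 100.0

    def test_zero_replicates_rejected(self, rng):
        with pytest.raises(ValueError):
            bootstrap_support({"A": "AC", "B": "AC", "C": "AC"}, b=0, rng=rng)

    def test_long_branch_high_support(self, rng):
        model = SpeciesTreeModel.from_newick("(((A:1,B:1):5,C:6):5,D:11);")
        ds = simulate_windows(
            SimConfig(n_windows=8, window_length=2000, mutation_scale=0.02, seed=11),
            model,
        )
        key = frozenset("AB")
        supports = []
        for w in ds.windows:
            t = bootstrap_support(w, b=40, rng=rng)
            for n in t.root.walk():
                below = frozenset(x.label for x in n.walk() if x.is_leaf)
                if below == key and n.label is not None:
                    supports.append(float(n.label))
        assert supports and np.median(supports) >= 95.0


class TestRootingAndTopology:
    def test_root_example(self):
        t = parse_newick("((A,B),(C,O));")
        rooted = root_by_outgroup(t, "O")
        assert rooted.root.children[0].is_leaf or rooted.root.children[1].is_leaf

    def test_monophyly_filter_keeps_and_drops(self):
        keep = parse_newick("((((S1,S2),(S3,S4)),X),O);")
        drop = parse_newick("((((S1,X),(S3,S4)),S2),O);")
        missing = parse_newick("(((S1,S2),S3),O);")
        out = monophyly_filter(
            [keep, drop, missing], ["S1", "S2", "S3", "S4"], outgroup="O"
        )
        assert out == [keep]

    def test_monophyly_filter_empty_input(self):
        assert monophyly_filter([], ["A", "B"]) == []

    def test_count_topologies_frequencies(self):
        trees = (
            [parse_newick("((A,B),(C,D));")] * 6
            + [parse_newick("((A,C),(B,D));")] * 3
            + [parse_newick("((A,D),(B,C));")] * 1
        )
        df = count_topologies(trees)
        assert list(df["count"]) == [6, 3, 1]
        assert list(df["frequency"]) == [0.6, 0.3, 0.1]

    def test_count_topologies_order_invariant(self, rng):
        trees = [parse_newick("((A,B),(C,D));")] * 2 + [
            parse_newick("((A,C),(B,D));")
        ]
        df1 = count_topologies(trees)
        df2 = count_topologies(trees[::-1])
        assert df1.equals(df2)

    def test_pipeline_recovers_true_gene_trees(self, rng):
        """With informative windows, NJ trees match the true gene trees."""
        model = SpeciesTreeModel.from_newick("(((A:1,B:1):2,C:3):2,D:5);")
        ds = simulate_windows(
            SimConfig(n_windows=50, window_length=5000, mutation_scale=0.05, seed=21),
            model,
        )
        hits = 0
        for w, true_t in zip(ds.windows, ds.true_gene_trees):
            est = nj_from_window(w)
            hits += canonical_topology(est) == canonical_topology(true_t)
        assert hits / len(ds.windows) >= 0.9
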