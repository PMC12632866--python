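"""Quartet concordance, the MSC baseline, species-tree estimation and the
folded regional stratification."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from discordia._phylo import parse_newick
from discordia.concord import (
    enumerate_unrooted_topologies,
    focal_branches,
    fold_position,
    msc_quartet_expectation,
    quartet_frequencies,
    quartet_score_species_tree,
    regional_topology_frequencies,
)
from discordia.simcoal import (
    IntrogressionEvent,
    SimConfig,
    SpeciesTreeModel,
    sample_gene_tree,
)
from discordia.treebuild import canonical_topology


class TestMscExpectation:
    def test_zero_branch_gives_one_third(self):
        assert msc_quartet_expectation(0.0) == (
            pytest.approx(1 / 3),
            pytest.approx(1 / 3),
            pytest.approx(1 / 3),
        )

    def test_long_branch_limit(self):
        p = msc_quartet_expectation(50.0)
        assert p[0] == pytest.approx(1.0) and p[1] == pytest.approx(0.0)

    def test_closed_form_point(self):
        t = -math.log(0.3)
        assert msc_quartet_expectation(t) == (
            pytest.approx(0.8),
            pytest.approx(0.1),
            pytest.approx(0.1),
        )

    def test_sums_to_one(self):
        for t in (0.0, 0.3, 1.7, 9.0):
            assert sum(msc_quartet_expectation(t)) == pytest.approx(1.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            msc_quartet_expectation(-0.1)


class TestQuartetFrequencies:
    def test_identical_trees_give_unity(self):
        st_tree = parse_newick("((A,B),(C,D));")
        br = focal_branches(st_tree)[0]
        qf = quartet_frequencies([parse_newick("((A,B),(C,D));")] * 10, br)
        assert (qf.t1, qf.t2, qf.t3) == (1.0, 0.0, 0.0)

    def test_mixed_trees_proportions(self):
        st_tree = parse_newick("((A,B),(C,D));")
        br = focal_branches(st_tree)[0]
        trees = (
            [parse_newick("((A,B),(C,D));")] * 6
            + [parse_newick("((A,C),(B,D));")] * 3
            + [parse_newick("((A,D),(B,C));")] * 1
        )
        qf = quartet_frequencies(trees, br)
        assert (qf.t1, qf.t2, qf.t3) == (
            pytest.approx(0.6),
            pytest.approx(0.3),
            pytest.approx(0.1),
        )

    def test_tree_missing_group_skipped(self):
        st_tree = parse_newick("((A,B),(C,D));")
        br = focal_branches(st_tree)[0]
        qf = quartet_frequencies(
            [parse_newick("((A,B),(C,D));"), parse_newick("((A,B),(C,X));")], br
        )
        assert qf.n_trees == 1

    def test_zero_length_branch_randomizes(self, rng):
        model = SpeciesTreeModel.from_newick("(((A:1,B:1):0.0,C:1.0):8,D:9.0);")
        trees = [sample_gene_tree(model, rng=rng) for _ in range(4000)]
        br = next(
            b
            for b in focal_branches(model.tree)
            if {frozenset("A"), frozenset("B")} <= set(b.groups)
        )
        qf = quartet_frequencies(trees, br)
        se = math.sqrt((1 / 3) * (2 / 3) / 4000)
        for f in (qf.t1, qf.t2, qf.t3):
            assert abs(f - 1 / 3) < 3 * se

    def test_msc_oracle_agreement_along_t(self, rng):
        """Observed quartet frequencies track 1-(2/3)e^-T (3 Monte-Carlo SE)."""
        n = 4000
        for t_len in (0.5, 2.0):
            model = SpeciesTreeModel.from_newick(
                f"(((A:1,B:1):{t_len},C:{1 + t_len}):8,D:{9 + t_len});"
            )
            trees = [sample_gene_tree(model, rng=rng) for _ in range(n)]
            br = next(
                b
                for b in focal_branches(model.tree)
                if {frozenset("A"), frozenset("B")} <= set(b.groups)
            )
            qf = quartet_frequencies(trees, br)
            exp = msc_quartet_expectation(t_len)
            se = math.sqrt(exp[0] * (1 - exp[0]) / n)
            assert abs(qf.t1 - exp[0]) < 3 * se


class TestSpeciesTreeEstimation:
    def test_unanimous_trees_score(self):
        trees = [parse_newick("((A,B),(C,D));")] * 7
        est, score, ties = quartet_score_species_tree(trees, "ABCD")
        assert canonical_topology(est) == canonical_topology(trees[0])
        assert score == 7  # C(4,4) = 1 quartet per tree

    def test_majority_quartet_wins(self):
        trees = [parse_newick("((A,B),(C,D));")] * 7 + [
            parse_newick("((A,C),(B,D));")
        ] * 3
        est, score, _ = quartet_score_species_tree(trees, "ABCD")
        assert canonical_topology(est) == canonical_topology(
            parse_newick("((A,B),(C,D));")
        )
        assert score == 7

    def test_topology_enumeration_counts(self):
        assert len(enumerate_unrooted_topologies("ABCD")) == 3
        assert len(enumerate_unrooted_topologies("ABCDE")) == 15
        assert len(enumerate_unrooted_topologies("ABCDEF")) == 105

    def test_matches_per_quartet_majority_vote_on_quartets(self, rng):
        # on 4-taxon problems the estimator is exactly majority voting
        for seed in range(5):
            r = np.random.default_rng(seed)
            choices = [
                "((A,B),(C,D));", "((A,C),(B,D));", "((A,D),(B,C));"
            ]
            picks = r.integers(0, 3, size=11)
            counts = np.bincount(picks, minlength=3)
            if (counts == counts.max()).sum() > 1:
                continue  # tied majorities are broken by id order, not votes
            trees = [parse_newick(choices[i]) for i in picks]
            est, _, _ = quartet_score_species_tree(trees, "ABCD")
            majority = choices[counts.argmax()]
            assert canonical_topology(est) == canonical_topology(
                parse_newick(majority)
            )

    def test_recovers_species_tree_from_simulation(self, rng):
        model = SpeciesTreeModel.from_newick(
            "((((A:1,B:1):2,C:3):2,(D:2,E:2):3):3,F:8);"
        )
        trees = [sample_gene_tree(model, rng=rng) for _ in range(500)]
        est, _, ties = quartet_score_species_tree(trees)
        assert len(ties) == 1
        assert canonical_topology(est) == canonical_topology(model.tree)

    def test_too_many_taxa_advises_import(self):
        with pytest.raises(ValueError, match="exhaustive"):
            quartet_score_species_tree([], [f"t{i}" for i in range(9)])


class TestFoldPosition:
    @pytest.mark.parametrize("pos,expected", [(5, 5), (94, 5), (50, 1), (0, 5), (99, 5)])
    def test_examples_length_100(self, pos, expected):
        assert fold_position(pos, 100) == expected

    def test_boundary_goes_telomere_proximal(self):
        # L=100: r = 0.2 exactly at m=10 -> still bin 5
        assert fold_position(10, 100) == 5
        assert fold_position(11, 100) == 4

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fold_position(100, 100)

    @settings(max_examples=300, derandomize=True, deadline=None)
    @given(
        length=st.integers(min_value=2, max_value=10**8),
        frac=st.floats(min_value=0.0, max_value=1.0, exclude_max=True),
    )
    def test_mirror_invariance(self, length, frac):
        pos = int(frac * length)
        pos = min(pos, length - 1)
        assert fold_position(pos, length) == fold_position(length - 1 - pos, length)

    def test_bins_partition(self):
        L = 1000
        bins = {fold_position(p, L) for p in range(L)}
        assert bins == {1, 2, 3, 4, 5}


class TestRegional:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "topology"])

    def test_sparse_chromosome_excluded(self):
        rows = [("chr1", i * 10, (i + 1) * 10, "t1") for i in range(19)]
        rows += [("chr2", i * 10, (i + 1) * 10, "t1") for i in range(25)]
        table, chi2, p, excluded = regional_topology_frequencies(
            self._frame(rows), {"chr1": 190, "chr2": 250}
        )
        assert excluded == ["chr1"]
        assert table["count"].sum() == 25

    def test_uniform_topology_homogeneous(self):
        rows = [("chr1", i * 10, (i + 1) * 10, "t1") for i in range(40)]
        _, chi2, p, _ = regional_topology_frequencies(
            self._frame(rows), {"chr1": 400}
        )
        assert p == 1.0

    def test_planted_positional_signal_detected(self, rng):
        """Bin-dependent introgression produces a significant homogeneity
        test: telomere-proximal windows get gamma = 0.5 gene flow."""
        model = SpeciesTreeModel.from_newick("(((A:1,B:1):1,C:2):8,D:10);")
        ev = IntrogressionEvent(donor="C", recipient="A", time=0.2, proportion=0.5)
        L, W = 100_000, 100  # 1000 windows on one chromosome
        rows = []
        for i in range(1000):
            start, end = i * W, (i + 1) * W
            b = fold_position((start + end) // 2, L)
            events = [ev] if b >= 4 else []
            t = sample_gene_tree(model, events, rng=rng)
            rows.append(("chr1", start, end, canonical_topology(t)))
        _, chi2, p, _ = regional_topology_frequencies(
            self._frame(rows), {"chr1": L}, min_trees_per_chrom=20
        )
        assert p < 0.01
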