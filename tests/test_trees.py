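"""Distances, neighbor joining, parsimony, RF distance, monophyly."""

import itertools
import math

import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare

from phylostrip.alignment import Alignment
from phylostrip.trees import (
    DistanceMatrix,
    TreeError,
    distance_matrix,
    fitch_length,
    is_monophyletic,
    leaf_labels,
    mp_best_trees,
    neighbor_joining,
    read_newick,
    rf_distance,
    write_newick,
    _enumerate_unrooted,
)


def nt(seqs: dict):
    return Alignment(taxa=tuple(seqs), sequences=tuple(seqs.values()))


def random_binary_tree(rng, n):
    """Random unrooted binary tree with exponential branch lengths."""
    taxa = [f"t{i+1}" for i in range(n)]
    tree = dendropy.Tree.get(data=f"({taxa[0]},{taxa[1]},{taxa[2]});", schema="newick")
    for label in taxa[3:]:
        edges = [e for e in tree.preorder_edge_iter() if e.head_node.parent_node]
        edge = edges[rng.integers(len(edges))]
        # split the edge and hang the new leaf
        old_head = edge.head_node
        parent = old_head.parent_node
        parent.remove_child(old_head)
        mid = parent.new_child()
        mid.add_child(old_head)
        leaf = mid.new_child(taxon=tree.taxon_namespace.new_taxon(label=label))
    for edge in tree.preorder_edge_iter():
        if edge.head_node.parent_node:
            edge.length = float(rng.uniform(0.05, 1.0))
    return tree


def path_distance_matrix(tree):
    """Additive distances from leaf-to-leaf path lengths (dendropy route)."""
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    n = len(labels)
    d = np.zeros((n, n))
    tx = {t.label: t for t in tree.taxon_namespace}
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = pdm.patristic_distance(tx[labels[i]], tx[labels[j]])
    return DistanceMatrix(
        taxa=tuple(labels), matrix=d, infinite=np.zeros((n, n), dtype=bool)
    )


class TestDistances:
    def test_identical_zero(self):
        dm = distance_matrix(nt({"a": "ACGT", "b": "ACGT"}))
        assert dm.value("a", "b") == 0.0

    def test_p_and_jc_closed_form(self):
        a = nt({"a": "AAAA", "b": "AAAT"})
        assert distance_matrix(a, "p").value("a", "b") == pytest.approx(0.25)
        expected = -0.75 * math.log(1 - 4 * 0.25 / 3)
        assert distance_matrix(a, "jc").value("a", "b") == pytest.approx(expected)

    def test_saturated_pair_flagged_infinite(self):
        a = nt({"a": "AAAA", "b": "CCCG"})
        dm = distance_matrix(a, "jc")
        assert math.isinf(dm.value("a", "b")) and dm.infinite.any()

    def test_gapped_columns_skipped(self):
        a = nt({"a": "A-GT", "b": "ACGA"})
        assert distance_matrix(a, "p").value("a", "b") == pytest.approx(1 / 3)

    def test_no_comparable_columns_error(self):
        a = nt({"a": "A---", "b": "-CGT"})
        with pytest.raises(Exception, match="a.*b|b.*a"):
            distance_matrix(a)


class TestNeighborJoining:
    def test_three_taxa_unique_topology(self):
        dm = distance_matrix(nt({"a": "AAAA", "b": "AAAT", "c": "ATTT"}))
        tree = neighbor_joining(dm)
        assert leaf_labels(tree) == {"a", "b", "c"}

    def test_recovers_additive_tree_exactly(self, rng):
        tree = random_binary_tree(rng, 5)
        dm = path_distance_matrix(tree)
        inferred = neighbor_joining(dm)
        assert rf_distance(inferred, tree) == 0
        # branch lengths are recovered too on additive input
        pdm_in = {  # leaf-pair path lengths of the inferred tree
            frozenset((a, b)): dm.value(a, b)
            for a, b in itertools.combinations(dm.taxa, 2)
        }
        out = path_distance_matrix(inferred)
        for a, b in itertools.combinations(dm.taxa, 2):
            assert out.value(a, b) == pytest.approx(pdm_in[frozenset((a, b))], abs=1e-9)

    def test_additive_property_many_trees(self, rng):
        for n in (6, 9, 12):
            for _ in range(5):
                tree = random_binary_tree(rng, n)
                assert rf_distance(neighbor_joining(path_distance_matrix(tree)), tree) == 0

    def test_label_order_invariance(self, rng):
        tree = random_binary_tree(rng, 6)
        dm = path_distance_matrix(tree)
        perm = list(rng.permutation(len(dm.taxa)))
        dm2 = DistanceMatrix(
            taxa=tuple(dm.taxa[i] for i in perm),
            matrix=dm.matrix[np.ix_(perm, perm)],
            infinite=dm.infinite[np.ix_(perm, perm)],
        )
        assert rf_distance(neighbor_joining(dm), neighbor_joining(dm2)) == 0

    def test_infinite_entry_rejected(self):
        a = nt({"a": "AAAA", "b": "CCCG", "c": "ACGT"})
        with pytest.raises(TreeError, match="filter"):
            neighbor_joining(distance_matrix(a, "jc"))


class TestFitch:
    def test_single_change(self):
        tree = read_newick("((a,b),(c,d));")
        a = nt({"a": "A", "b": "A", "c": "T", "d": "T"})
        assert fitch_length(tree, a) == 1

    def test_two_changes_vs_enumeration(self):
        tree = read_newick("((a,b),(c,d));")
        a = nt({"a": "A", "b": "T", "c": "A", "d": "T"})
        assert fitch_length(tree, a) == 2

    def test_constant_and_missing_zero_cost(self):
        tree = read_newick("((a,b),(c,d));")
        assert fitch_length(tree, nt({"a": "A", "b": "A", "c": "A", "d": "A"})) == 0
        assert fitch_length(tree, nt({"a": "A", "b": "-", "c": "?", "d": "A"})) == 0

    def test_rerooting_invariance(self, rng, random_nt_alignment):
        a = random_nt_alignment(rng, 6, 40)
        tree = random_binary_tree(rng, 6)
        score = fitch_length(tree, a)
        for edge in list(tree.preorder_edge_iter())[3:6]:
            t2 = tree.clone(depth=1)
            e2 = list(t2.preorder_edge_iter())[
                list(tree.preorder_edge_iter()).index(edge)
            ]
            t2.reroot_at_edge(e2)
            assert fitch_length(t2, a) == score

    def test_star_tree_attains_lower_bound(self):
        # on a star the Hartigan cost is n - max state count per column
        tree = read_newick("(a,b,c,d,e);")
        a = nt({"a": "A", "b": "A", "c": "G", "d": "C", "e": "C"})
        assert fitch_length(tree, a) == 3

    def test_exhaustive_state_enumeration_oracle(self, rng, random_nt_alignment):
        """Independent oracle: minimize over all internal-state assignments."""
        for n in (4, 5, 6):
            a = random_nt_alignment(rng, n, 12, p_gap=0.1)
            tree = random_binary_tree(rng, n)
            internal = [
                nd for nd in tree.postorder_node_iter() if not nd.is_leaf()
            ]
            total = 0
            for col in range(1, a.length + 1):
                leaf_state = {t: a.sequence(t)[col - 1] for t in a.taxa}
                best = None
                for assign in itertools.product("ACGT", repeat=len(internal)):
                    states = dict(zip(internal, assign))
                    cost = 0
                    for nd in tree.postorder_node_iter():
                        if nd.parent_node is None:
                            continue
                        s = (
                            leaf_state[nd.taxon.label]
                            if nd.is_leaf()
                            else states[nd]
                        )
                        if s not in "ACGT":
                            continue  # missing leaf: no cost on its edge
                        if s != states[nd.parent_node]:
                            cost += 1
                    best = cost if best is None else min(best, cost)
                total += best
            assert fitch_length(tree, a) == total

    def test_leaf_mismatch_rejected(self):
        tree = read_newick("((a,b),(c,d));")
        with pytest.raises(TreeError):
            fitch_length(tree, nt({"a": "A", "b": "A", "c": "A", "x": "A"}))


class TestMpBestTrees:
    def test_topology_counts(self):
        assert len(_enumerate_unrooted(list("abcd"))) == 3
        assert len(_enumerate_unrooted(list("abcde"))) == 15
        assert len(_enumerate_unrooted(list("abcdef"))) == 105

    def test_perfect_signal_single_tree(self):
        a = nt({"a": "AAAA", "b": "AAAT", "c": "TTTA", "d": "TTTT"})
        best = mp_best_trees(a)
        assert len(best) == 1
        assert rf_distance(best[0], read_newick("((a,b),(c,d));")) == 0

    def test_best_score_matches_independent_minimum(self, rng, random_nt_alignment):
        a = random_nt_alignment(rng, 6, 30)
        best = mp_best_trees(a)
        best_score = fitch_length(best[0], a)
        # independent pass: score every topology via newick reconstruction
        scores = []
        for tup in _enumerate_unrooted(list(a.taxa)):
            def render(x):
                if isinstance(x, tuple):
                    return "(" + ",".join(render(c) for c in x) + ")"
                return x
            t = read_newick(render(tup) + ";")
            scores.append(fitch_length(t, a))
        assert best_score == min(scores)
        assert len(best) == scores.count(min(scores))

    def test_too_many_taxa_advises_nj(self, rng, random_nt_alignment):
        a = random_nt_alignment(rng, 11, 10)
        with pytest.raises(TreeError, match="neighbor"):
            mp_best_trees(a)


class TestRfDistance:
    def test_identical_zero(self, rng):
        t = random_binary_tree(rng, 7)
        assert rf_distance(t, t.clone(depth=1)) == 0

    def test_four_taxon_alternatives(self):
        t1 = read_newick("((a,b),(c,d));")
        t2 = read_newick("((a,c),(b,d));")
        assert rf_distance(t1, t2) == 2

    def test_max_on_opposed_caterpillars(self):
        n = 8
        t1 = read_newick("(((((((t1,t2),t3),t4),t5),t6),t7),t8);")
        t2 = read_newick("(((((((t1,t8),t6),t4),t2),t5),t3),t7);")
        assert rf_distance(t1, t2) == 2 * (n - 3)

    def test_metric_properties(self, rng):
        trees = [random_binary_tree(rng, 8) for _ in range(4)]
        for t1, t2 in itertools.combinations(trees, 2):
            d12 = rf_distance(t1, t2)
            assert d12 == rf_distance(t2, t1) >= 0
        for t1, t2, t3 in itertools.permutations(trees, 3):
            assert rf_distance(t1, t3) <= rf_distance(t1, t2) + rf_distance(t2, t3)

    def test_agrees_with_dendropy(self, rng):
        for _ in range(10):
            ns = dendropy.TaxonNamespace()
            t1 = dendropy.Tree.get(
                data=write_newick(random_binary_tree(rng, 9)) + "\n",
                schema="newick", taxon_namespace=ns,
            )
            t2 = dendropy.Tree.get(
                data=write_newick(random_binary_tree(rng, 9)) + "\n",
                schema="newick", taxon_namespace=ns,
            )
            t1.encode_bipartitions(); t2.encode_bipartitions()
            assert rf_distance(t1, t2) == treecompare.symmetric_difference(t1, t2)

    def test_leaf_mismatch_rejected(self):
        with pytest.raises(TreeError):
            rf_distance(read_newick("((a,b),(c,d));"), read_newick("((a,b),(c,e));"))


class TestMonophyly:
    def test_singleton_true(self):
        assert is_monophyletic(read_newick("((a,b),(c,d));"), {"a"})

    def test_complement_symmetry(self, rng):
        t = random_binary_tree(rng, 7)
        leaves = leaf_labels(t)
        for _ in range(10):
            k = int(rng.integers(1, 6))
            sub = set(rng.choice(sorted(leaves), size=k, replace=False))
            assert is_monophyletic(t, sub) == is_monophyletic(t, leaves - sub)

    def test_split_enumeration(self):
        t = read_newick("((a,b),(c,d));")
        assert is_monophyletic(t, {"a", "b"})
        assert not is_monophyletic(t, {"a", "c"})

    def test_improper_subset_rejected(self):
        t = read_newick("((a,b),(c,d));")
        with pytest.raises(TreeError):
            is_monophyletic(t, {"a", "b", "c", "d"})
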