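"""Lightweight tree inference and comparison harness.

Trees are :class:`dendropy.Tree` objects; Newick I/O goes through
dendropy.  Inference is deliberately small-scale and exact: neighbor
joining with deterministic lexicographic tie-breaking, and maximum
parsimony by exhaustive enumeration of unrooted topologies (up to 10
taxa).  Parsimony lengths use Hartigan's generalization of the Fitch
algorithm, which is exact on multifurcating trees — the same statistic
the slow-fast rate proxy implies on a polytomic background tree.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import dendropy
import numpy as np

from .alignment import Alignment, AlignmentError


class TreeError(ValueError):
    pass


def read_newick(source: str) -> dendropy.Tree:
    """Parse a Newick string (or file contents) into an unrooted tree."""
    return dendropy.Tree.get(data=source, schema="newick")


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def leaf_labels(tree: dendropy.Tree) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in tree.leaf_node_iter())


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric taxon distance matrix with saturation flags."""

    taxa: tuple[str, ...]
    matrix: np.ndarray          # (n, n) float, inf where saturated
    infinite: np.ndarray        # (n, n) bool

    def value(self, t1: str, t2: str) -> float:
        i, j = self.taxa.index(t1), self.taxa.index(t2)
        return float(self.matrix[i, j])


def distance_matrix(a: Alignment, model: str = "p") -> DistanceMatrix:
    """Pairwise distances: ``p`` (mismatch fraction) or ``jc`` correction.

    Comparisons use only columns where both taxa carry counted states;
    under ``jc``, p >= 3/4 is flagged infinite.  A pair with no
    comparable column at all is an error.
    """
    if a.n_taxa < 2:
        raise AlignmentError("distance matrix requires >= 2 taxa")
    if model not in ("p", "jc"):
        raise ValueError(f"unknown distance model {model!r}")
    counted = sorted(a.counted_states())
    arr = a.to_array()
    ok = np.isin(arr, [s.encode("ascii") for s in counted])
    n = a.n_taxa
    d = np.zeros((n, n))
    inf = np.zeros((n, n), dtype=bool)
    for i, j in itertools.combinations(range(n), 2):
        both = ok[i] & ok[j]
        m = int(both.sum())
        if m == 0:
            raise AlignmentError(
                f"no comparable columns between {a.taxa[i]!r} and {a.taxa[j]!r}"
            )
        p = float((arr[i, both] != arr[j, both]).sum()) / m
        if model == "p":
            val = p
        elif p >= 0.75:
            val, inf[i, j] = np.inf, True
            inf[j, i] = True
        else:
            val = -0.75 * np.log(1.0 - 4.0 * p / 3.0)
        d[i, j] = d[j, i] = val
    return DistanceMatrix(taxa=a.taxa, matrix=d, infinite=inf)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Ties on the Q criterion are broken by the lexicographic order of the
    smallest original taxon label in each cluster; negative branch
    lengths are clamped to zero.
    """
    if dm.infinite.any():
        raise TreeError(
            "distance matrix contains saturated (infinite) entries; "
            "filter the alignment or use p-distances"
        )
    n0 = len(dm.taxa)
    if n0 < 3:
        raise TreeError("neighbor joining requires >= 3 taxa")
    ns = dendropy.TaxonNamespace()
    nodes = []
    reps = []  # lexicographic representative label per active cluster
    for t in dm.taxa:
        leaf = dendropy.Node(taxon=ns.new_taxon(label=t))
        nodes.append(leaf)
        reps.append(t)
    d = dm.matrix.astype(float).copy()
    active = list(range(n0))
    lengths: dict[dendropy.Node, float] = {}

    while len(active) > 2:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for ai, aj in itertools.combinations(range(m), 2):
            q = (m - 2) * sub[ai, aj] - r[ai] - r[aj]
            pair_key = tuple(sorted((reps[active[ai]], reps[active[aj]])))
            key = (q, pair_key)
            if best is None or key < best[0]:
                best = (key, ai, aj)
        _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        lengths[nodes[i]] = max(li, 0.0)
        lengths[nodes[j]] = max(lj, 0.0)
        # distances from the new cluster to every other active cluster
        d = np.pad(d, ((0, 1), (0, 1)))
        for ak in range(m):
            if ak in (ai, aj):
                continue
            k = active[ak]
            d[-1, k] = d[k, -1] = 0.5 * (sub[ai, ak] + sub[aj, ak] - dij)
        nodes.append(parent)
        reps.append(min(reps[i], reps[j]))
        active = [k for k in active if k not in (i, j)] + [d.shape[0] - 1]

    i, j = active
    root = dendropy.Node()
    root.add_child(nodes[i])
    root.add_child(nodes[j])
    half = max(d[i, j], 0.0) / 2
    lengths[nodes[i]] = half
    lengths[nodes[j]] = half
    tree = dendropy.Tree(taxon_namespace=ns, seed_node=root)
    for node, ln in lengths.items():
        node.edge.length = ln
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# parsimony
# ---------------------------------------------------------------------------

def _state_masks(a: Alignment) -> tuple[dict[str, np.ndarray], int]:
    """Per-taxon bitmask arrays over columns; missing = all states."""
    states = sorted(a.counted_states())
    if len(states) > 30:
        raise AlignmentError("too many states for bitmask parsimony")
    bit = {s: 1 << i for i, s in enumerate(states)}
    full = (1 << len(states)) - 1
    masks = {}
    for t, seq in zip(a.taxa, a.sequences):
        masks[t] = np.array(
            [bit.get(c, full) for c in seq], dtype=np.int64
        )
    return masks, len(states)


def fitch_length(tree: dendropy.Tree, a: Alignment) -> int:
    """Minimum number of state changes of *a* on *tree* (all columns).

    Uses Hartigan's bottom-up algorithm, exact for multifurcations.
    Gaps/missing/ambiguities contribute the universal state set and
    hence no cost; the score is invariant under re-rooting.
    """
    labels = leaf_labels(tree)
    if labels != frozenset(a.taxa):
        raise TreeError(
            f"tree leaves and alignment taxa differ: {sorted(labels ^ set(a.taxa))}"
        )
    masks, n_states = _state_masks(a)
    cost = np.zeros(a.length, dtype=np.int64)
    node_mask: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node_mask[node] = masks[node.taxon.label]
            continue
        children = [node_mask[c] for c in node.child_nodes()]
        votes = np.zeros((n_states, a.length), dtype=np.int64)
        for cm in children:
            for s in range(n_states):
                votes[s] += (cm >> s) & 1
        vmax = votes.max(axis=0)
        upper = np.zeros(a.length, dtype=np.int64)
        for s in range(n_states):
            upper |= ((votes[s] == vmax).astype(np.int64)) << s
        cost += len(children) - vmax
        node_mask[node] = upper
    return int(cost.sum())


def _enumerate_unrooted(taxa: list[str]):
    """Yield every unrooted binary topology over *taxa* as nested tuples.

    Stepwise addition: each new taxon attaches to every edge of every
    partial tree, giving the (2n-5)!! distinct topologies.
    """
    if len(taxa) < 3:
        raise TreeError("need >= 3 taxa")
    base = (taxa[0], taxa[1], taxa[2])  # the unique 3-leaf star

    def edges(sub, path):
        # enumerate attachment points: every leaf or internal tuple
        for i, child in enumerate(sub):
            yield path + (i,)
            if isinstance(child, tuple):
                yield from edges(child, path + (i,))

    def attach(sub, path, leaf):
        i, rest = path[0], path[1:]
        new_child = attach(sub[i], rest, leaf) if rest else (sub[i], leaf)
        return sub[:i] + (new_child,) + sub[i + 1 :]

    trees = [base]
    for leaf in taxa[3:]:
        nxt = []
        for t in trees:
            for path in edges(t, ()):
                nxt.append(attach(t, path, leaf))
        trees = nxt
    return trees


def _tuple_to_newick(t) -> str:
    def render(x):
        return "(" + ",".join(render(c) for c in x) + ")" if isinstance(x, tuple) else x

    return render(t) + ";"


def mp_best_trees(a: Alignment, max_taxa: int = 10) -> list[dendropy.Tree]:
    """All maximum parsimony topologies by exhaustive enumeration.

    Exact and deterministic; refuses more than *max_taxa* taxa, where
    the (2n-5)!! topology count becomes impractical — use
    :func:`neighbor_joining` instead.
    """
    if a.n_taxa > max_taxa:
        raise TreeError(
            f"{a.n_taxa} taxa exceed the exhaustive-search limit "
            f"({max_taxa}); use neighbor joining"
        )
    ns = dendropy.TaxonNamespace([dendropy.Taxon(label=t) for t in a.taxa])
    best_score = None
    best: list[dendropy.Tree] = []
    for tup in _enumerate_unrooted(list(a.taxa)):
        tree = dendropy.Tree.get(
            data=_tuple_to_newick(tup), schema="newick", taxon_namespace=ns
        )
        score = fitch_length(tree, a)
        if best_score is None or score < best_score:
            best_score, best = score, [tree]
        elif score == best_score:
            best.append(tree)
    return best


# ---------------------------------------------------------------------------
# topology comparison
# ---------------------------------------------------------------------------

def _splits(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions, each normalized to the side that
    contains the lexicographically smallest leaf label."""
    all_leaves = leaf_labels(tree)
    anchor = min(all_leaves)
    out: set[frozenset[str]] = set()
    for node in tree.postorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if min(len(below), len(all_leaves) - len(below)) >= 2:
            side = below if anchor in below else all_leaves - below
            out.add(frozenset(side))
    return out


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Robinson-Foulds distance: symmetric difference of non-trivial
    unrooted bipartitions."""
    l1, l2 = leaf_labels(t1), leaf_labels(t2)
    if l1 != l2:
        raise TreeError(f"leaf sets differ: {sorted(l1 ^ l2)}")
    return len(_splits(t1) ^ _splits(t2))


def is_monophyletic(tree: dendropy.Tree, taxa) -> bool:
    """True iff some edge of the unrooted tree splits *taxa* from the rest."""
    taxa = frozenset(taxa)
    leaves = leaf_labels(tree)
    if not taxa or not taxa < leaves:
        raise TreeError("taxa must be a non-empty proper subset of the leaves")
    k = len(taxa)
    if k == 1 or k == len(leaves) - 1:
        return True  # a terminal edge realizes every (near-)trivial split
    anchor = min(leaves)
    side = taxa if anchor in taxa else leaves - taxa
    return frozenset(side) in _splits(tree)
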