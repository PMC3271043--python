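"""Nonstationary sequence simulation and the long-branch-attraction bench.

Sites evolve independently on a rooted tree under a Tamura (1992)
substitution process whose equilibrium GC content theta and
transition/transversion ratio kappa can change from branch to branch —
a branch-wise nonhomogeneous, nonstationary model.  A lineage whose
branches carry a low theta drifts toward an AT-rich composition the way
obligate endosymbiont genomes do, and when two unrelated lineages share
both long branches and a low theta, distance and parsimony methods tend
to pull them together: the compositional flavour of long-branch
attraction.  The fixtures here reproduce that regime in miniature so
the site filters and recodings can be benchmarked on data where the
true topology is known.

T92 rate matrix (states A, C, G, T): equilibrium frequencies
pi_A = pi_T = (1 - theta)/2, pi_G = pi_C = theta/2; transitions
(A<->G, C<->T) are scaled by kappa; the matrix is normalized to one
expected substitution per site per unit branch length.  Transition
probabilities are computed by matrix exponential, exact to machine
precision, so branch lengths compose (Chapman-Kolmogorov).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.linalg import expm

from .alignment import NUCLEOTIDE, Alignment
from .filters import (
    TaxonGroupSet,
    atgc_filter,
    default_thresholds,
    exclude_codon_positions,
    slowfast_rates,
    slowfast_series,
)
from .recoding import recode_ry
from .trees import (
    distance_matrix,
    is_monophyletic,
    leaf_labels,
    mp_best_trees,
    neighbor_joining,
    read_newick,
    rf_distance,
)

_BASES = np.array([b"A", b"C", b"G", b"T"])


@dataclass(frozen=True)
class BranchModel:
    """Default branch parameters; per-edge overrides live on the tree.

    theta_root draws the root sequence i.i.d. with GC content
    theta_root; each edge then uses its own ``edge.theta`` /
    ``edge.kappa`` attribute if set, falling back to the defaults here.
    """

    theta_root: float = 0.5
    theta: float = 0.5
    kappa: float = 2.0

    def __post_init__(self):
        for th in (self.theta_root, self.theta):
            if not 0.0 < th < 1.0:
                raise ValueError(f"theta must be in (0, 1), got {th}")
        if self.kappa <= 0:
            raise ValueError(f"kappa must be > 0, got {self.kappa}")


def t92_rate_matrix(theta: float, kappa: float) -> np.ndarray:
    """Normalized T92 generator over (A, C, G, T)."""
    if not 0.0 < theta < 1.0:
        raise ValueError(f"theta must be in (0, 1), got {theta}")
    if kappa <= 0:
        raise ValueError(f"kappa must be > 0, got {kappa}")
    pi = np.array([(1 - theta) / 2, theta / 2, theta / 2, (1 - theta) / 2])
    q = np.zeros((4, 4))
    transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            q[i, j] = pi[j] * (kappa if (i, j) in transitions else 1.0)
        q[i, i] = -q[i].sum()
    mu = -(pi * np.diag(q)).sum()
    return q / mu


def t92_transition_probs(theta: float, kappa: float, t: float) -> np.ndarray:
    """P(t) = exp(Q t); rows sum to one."""
    if t < 0:
        raise ValueError("branch length must be >= 0")
    return expm(t92_rate_matrix(theta, kappa) * t)


def _root_frequencies(theta_root: float) -> np.ndarray:
    return np.array(
        [(1 - theta_root) / 2, theta_root / 2, theta_root / 2, (1 - theta_root) / 2]
    )


def simulate_alignment(
    tree: dendropy.Tree,
    model: BranchModel,
    n_sites: int,
    seed: int,
    site_rate_multipliers: np.ndarray | None = None,
    codon_rates: tuple[float, float, float] | None = None,
) -> Alignment:
    """Evolve *n_sites* i.i.d. sites down *tree* under the branch-wise model.

    Edge attributes ``theta`` / ``kappa`` override the model defaults;
    ``edge.length`` is expected substitutions per site.  With
    ``codon_rates`` the per-position rate pattern (r1, r2, r3) is tiled
    over codons and the output is codon-framed (n_sites must be a
    multiple of 3).  Deterministic for a given seed.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if codon_rates is not None:
        if site_rate_multipliers is not None:
            raise ValueError("give either codon_rates or site_rate_multipliers")
        if n_sites % 3:
            raise ValueError("codon_rates requires n_sites divisible by 3")
        site_rate_multipliers = np.tile(np.asarray(codon_rates, float), n_sites // 3)
    if site_rate_multipliers is not None and len(site_rate_multipliers) != n_sites:
        raise ValueError("site_rate_multipliers length must equal n_sites")

    rng = np.random.default_rng(seed)
    root = tree.seed_node
    states = {root: rng.choice(4, size=n_sites, p=_root_frequencies(model.theta_root))}
    pcache: dict[tuple, np.ndarray] = {}

    def probs(theta, kappa, t):
        key = (round(theta, 12), round(kappa, 12), round(t, 12))
        if key not in pcache:
            pcache[key] = t92_transition_probs(theta, kappa, t)
        return pcache[key]

    for node in tree.preorder_node_iter():
        if node is root:
            continue
        edge = node.edge
        t = edge.length or 0.0
        theta = getattr(edge, "theta", model.theta)
        kappa = getattr(edge, "kappa", model.kappa)
        parent = states[node.parent_node]
        child = np.empty(n_sites, dtype=np.int64)
        if site_rate_multipliers is None:
            groups = [(1.0, np.arange(n_sites))]
        else:
            groups = [
                (m, np.nonzero(site_rate_multipliers == m)[0])
                for m in np.unique(site_rate_multipliers)
            ]
        for mult, idx in groups:
            if t * mult == 0.0:
                child[idx] = parent[idx]
                continue
            p = probs(theta, kappa, t * mult)
            u = rng.random(len(idx))
            cum = np.cumsum(p, axis=1)
            child[idx] = (u[:, None] > cum[parent[idx]]).sum(axis=1)
        states[node] = child

    taxa, seqs = [], []
    for leaf in tree.leaf_node_iter():
        taxa.append(leaf.taxon.label)
        seqs.append(_BASES[states[leaf]].tobytes().decode("ascii"))
    return Alignment(
        taxa=tuple(taxa),
        sequences=tuple(seqs),
        alphabet=NUCLEOTIDE,
        codon_frame=codon_rates is not None,
    )


# ---------------------------------------------------------------------------
# LBA fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LbaFixture:
    """A known-truth four-taxon scenario for the rescue benchmark.

    The true topology is ((A,B),(C,D)); the designated "attracted pair"
    is the non-sister pair (A, C), which carries the long and/or
    AT-shifted branches depending on style.
    """

    style: str
    tree: dendropy.Tree = field(compare=False)
    model: BranchModel
    attracted_pair: tuple[str, str]
    true_newick: str
    n_sites: int
    replicates: int
    base_seed: int
    codon_rates: tuple[float, float, float] | None = None


@dataclass(frozen=True)
class LbaExperimentResult:
    """Per-transform topology-recovery frequencies over replicates."""

    fixture_style: str
    inference: str
    replicates: int
    base_seed: int
    frequencies: dict[str, dict[str, float]]

    def to_json(self) -> str:
        return json.dumps(
            {
                "fixture": self.fixture_style,
                "inference": self.inference,
                "replicates": self.replicates,
                "base_seed": self.base_seed,
                "frequencies": self.frequencies,
            },
            indent=2,
            sort_keys=True,
        )


_TRUE_NEWICK = "((A,B),(C,D));"


def make_lba_fixture(
    style: str,
    n_sites: int = 5000,
    replicates: int = 100,
    base_seed: int = 0,
    long_length: float = 0.4,
    short_length: float = 0.1,
    internal_length: float = 0.1,
    moderate_length: float = 0.3,
    theta_bias: float = 0.2,
    theta_background: float = 0.5,
    kappa: float = 2.0,
    codon_rates: tuple[float, float, float] | None = None,
) -> LbaFixture:
    """Build a seeded four-taxon fixture in one of three styles.

    ``felsenstein``: taxa A and C get long terminal branches, uniform
    base composition — classic rate-driven attraction.
    ``compositional``: A and C get moderate branches but a low
    equilibrium GC (theta_bias), the others stay near-stationary —
    purely composition-driven convergence.
    ``combined``: long branches *and* low theta on A and C, the regime
    of fast-evolving AT-rich endosymbiont genomes.

    The default long-branch length (0.4 expected substitutions/site,
    four times the background) keeps the combined fixture in the regime
    where the attraction is driven by compositional convergence rather
    than by outright saturation: at these lengths the same tree with
    uniform composition is recovered correctly, so any artifact present
    is attributable to the AT shift — the component site filtering can
    actually remove.  Far longer branches put parsimony in the
    classical Felsenstein zone where no site treatment helps.
    """
    if style not in ("felsenstein", "compositional", "combined"):
        raise ValueError(f"unknown fixture style {style!r}")
    model = BranchModel(
        theta_root=theta_background, theta=theta_background, kappa=kappa
    )
    tree = read_newick(_TRUE_NEWICK)
    tree.is_rooted = True
    tip_edges = {lf.taxon.label: lf.edge for lf in tree.leaf_node_iter()}
    for node in tree.seed_node.child_nodes():
        node.edge.length = internal_length / 2  # root sits mid-internal-edge
    for label in ("B", "D"):
        tip_edges[label].length = short_length
    pair_length = long_length if style in ("felsenstein", "combined") else moderate_length
    for label in ("A", "C"):
        e = tip_edges[label]
        e.length = pair_length
        if style in ("compositional", "combined"):
            e.theta = theta_bias
    return LbaFixture(
        style=style,
        tree=tree,
        model=model,
        attracted_pair=("A", "C"),
        true_newick=_TRUE_NEWICK,
        n_sites=n_sites,
        replicates=replicates,
        base_seed=base_seed,
        codon_rates=codon_rates,
    )


_K_TRANSFORMS = {f"atgc_k{k}": k for k in range(11)}


def _apply_transform(aln: Alignment, name: str, fixture: LbaFixture):
    if name == "none":
        return aln
    if name == "ry":
        return recode_ry(aln, scope="all")
    if name == "ry12":
        return recode_ry(aln, scope="first_second")
    if name == "third_excluded":
        return exclude_codon_positions(aln, keep={1, 2})
    if name in _K_TRANSFORMS:
        return atgc_filter(aln, _K_TRANSFORMS[name])
    if name == "slowfast":
        # the only unambiguous a priori groups a 4-taxon fixture offers
        # are the true cherries; drop the fastest rate class
        groups = TaxonGroupSet(groups=(("left", ("A", "B")), ("right", ("C", "D"))))
        rates = slowfast_rates(aln, groups)
        thr = default_thresholds(rates)
        if not thr:
            return aln
        return slowfast_series(aln, rates, thresholds=[thr[0]])[0]
    raise ValueError(f"unknown transform {name!r}")


def _infer(aln: Alignment, inference: str) -> list:
    if inference == "mp":
        return mp_best_trees(aln)
    if inference == "nj":
        return [neighbor_joining(distance_matrix(aln, model="p"))]
    raise ValueError(f"unknown inference {inference!r}")


def lba_experiment(
    fixture: LbaFixture,
    transforms: list[str],
    inference: str = "mp",
    replicates: int | None = None,
    seed: int | None = None,
) -> LbaExperimentResult:
    """Run the rescue benchmark: simulate, transform, infer, score.

    Per transform, records the fraction of replicates in which (a) the
    true topology is the unique optimum and (b) every optimal tree
    groups the attracted pair.  Replicate r uses seed base_seed + r, so
    the whole table is reproducible from (fixture, seed).
    """
    replicates = replicates if replicates is not None else fixture.replicates
    base = seed if seed is not None else fixture.base_seed
    true_tree = read_newick(fixture.true_newick)
    pair = set(fixture.attracted_pair)
    hits = {t: {"true_topology": 0, "attracted_pair": 0} for t in transforms}
    for r in range(replicates):
        aln = simulate_alignment(
            fixture.tree,
            fixture.model,
            fixture.n_sites,
            seed=base + r,
            codon_rates=fixture.codon_rates,
        )
        for name in transforms:
            sub = _apply_transform(aln, name, fixture)
            trees = _infer(sub, inference)
            if len(trees) == 1 and rf_distance(trees[0], true_tree) == 0:
                hits[name]["true_topology"] += 1
            if trees and all(is_monophyletic(t, pair) for t in trees):
                hits[name]["attracted_pair"] += 1
    freqs = {
        name: {k: v / replicates for k, v in d.items()} for name, d in hits.items()
    }
    return LbaExperimentResult(
        fixture_style=fixture.style,
        inference=inference,
        replicates=replicates,
        base_seed=base,
        frequencies=freqs,
    )


# ---------------------------------------------------------------------------
# annotated-Newick input
# ---------------------------------------------------------------------------

def read_annotated_tree(source: str) -> dendropy.Tree:
    """Parse Newick whose comments carry per-branch parameters.

    Comments of the form ``[&theta=0.2,kappa=4]`` after a node set that
    node's incoming-edge parameters, e.g.
    ``((A:1.0[&theta=0.2],B:0.1),(C:1.0[&theta=0.2],D:0.1));``.
    """
    tree = dendropy.Tree.get(
        data=source, schema="newick", extract_comment_metadata=False
    )
    for node in tree.preorder_node_iter():
        for comment in node.comments:
            body = comment.lstrip("&")
            for item in body.split(","):
                if "=" not in item:
                    continue
                key, _, val = item.partition("=")
                key = key.strip()
                if key in ("theta", "kappa"):
                    setattr(node.edge, key, float(val))
    return tree
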