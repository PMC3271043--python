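import numpy as np
import pytest

from phylostrip.alignment import Alignment

BASES = "ACGT"


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_nt_alignment():
    """Factory for random nucleotide alignments with gaps/ambiguities."""

    def make(rng, n_taxa, n_cols, p_gap=0.05, p_ambig=0.03, codon_frame=False):
        symbols = np.array(list("ACGT"))
        mat = symbols[rng.integers(0, 4, size=(n_taxa, n_cols))]
        gaps = rng.random((n_taxa, n_cols)) < p_gap
        mat[gaps] = "-"
        amb = rng.random((n_taxa, n_cols)) < p_ambig
        mat[amb] = np.array(list("NRYSW"))[rng.integers(0, 5, size=int(amb.sum()))]
        return Alignment(
            taxa=tuple(f"t{i+1}" for i in range(n_taxa)),
            sequences=tuple("".join(row) for row in mat),
            codon_frame=codon_frame,
        )

    return make


@pytest.fixture
def random_aa_alignment():
    def make(rng, n_taxa, n_cols):
        symbols = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        mat = symbols[rng.integers(0, 20, size=(n_taxa, n_cols))]
        gaps = rng.random((n_taxa, n_cols)) < 0.05
        mat[gaps] = "-"
        return Alignment(
            taxa=tuple(f"t{i+1}" for i in range(n_taxa)),
            sequences=tuple("".join(row) for row in mat),
            alphabet="amino",
        )

    return make


def brute_force_site_classes(aln, counted):
    """Naive per-column recount, independent of site_summary's internals."""
    classes = []
    for j in range(aln.length):
        col = [s[j] for s in aln.sequences if s[j] in counted]
        distinct = set(col)
        if len(distinct) < 2:
            classes.append("constant")
        elif len([s for s in distinct if col.count(s) >= 2]) >= 2:
            classes.append("parsimony-informative")
        else:
            classes.append("variable-uninformative")
    return classes
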