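"""Site-exclusion filters for compositionally biased matrices.

Three treatments:

* third-codon-position removal (``exclude_codon_positions``);
* the AT/GC compositional filter: drop every column in which both the
  A/T and the G/C state categories are observed, so that all remaining
  substitutions are within-category transversions (A<->T or G<->C) —
  exactly the substitution class that convergent AT enrichment cannot
  generate.  A relaxation series re-admits columns whose minority
  category is carried by at most ``k`` taxa, k = 0..10 by default;
* the slow-fast procedure: assign each column a substitution-rate proxy
  from user-declared, a priori monophyletic taxon groups (the minimum
  change count on a tree that is a polytomy everywhere outside the
  groups), then strip the fastest rate classes stepwise.

AT/GC category membership: A, T and the IUPAC code W (= A/T) count as
A/T; G, C and S (= G/C) count as G/C; gaps, missing and every other
ambiguity are uncategorized and can never trigger removal.  Exceptions
in the relaxed rule are counted as minority-category taxa, whichever
taxa they are, which makes k = 0 coincide exactly with the strict rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .alignment import NUCLEOTIDE, Alignment, AlignmentError

_AT = frozenset(b"ATW")
_GC = frozenset(b"GCS")


@dataclass(frozen=True)
class AtGcColumnProfile:
    """Category counts for one column: n_AT + n_GC + n_other = n_taxa."""

    n_at: int
    n_gc: int
    n_other: int


@dataclass(frozen=True)
class TaxonGroupSet:
    """Named, pairwise-disjoint groups of taxon labels."""

    groups: tuple[tuple[str, tuple[str, ...]], ...]

    def __post_init__(self):
        seen: set[str] = set()
        for name, members in self.groups:
            if not members:
                raise ValueError(f"group {name!r} is empty")
            if seen & set(members):
                raise ValueError(f"group {name!r} overlaps another group")
            seen |= set(members)

    @classmethod
    def from_file(cls, path) -> "TaxonGroupSet":
        """Parse a group file, one ``name: taxon1 taxon2 ...`` per line."""
        groups = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, _, rest = line.partition(":")
            groups.append((name.strip(), tuple(rest.split())))
        return cls(groups=tuple(groups))

    def validate_against(self, a: Alignment) -> None:
        taxa = set(a.taxa)
        for name, members in self.groups:
            absent = sorted(set(members) - taxa)
            if absent:
                raise AlignmentError(
                    f"group {name!r} names taxa absent from the alignment: {absent}"
                )


@dataclass(frozen=True)
class SiteRateTable:
    """Per-column integer rate proxies from a slow-fast group set."""

    rates: tuple[int, ...]
    provenance: str

    @property
    def max_rate(self) -> int:
        return max(self.rates)


# ---------------------------------------------------------------------------
# codon positions
# ---------------------------------------------------------------------------

def exclude_codon_positions(a: Alignment, keep=frozenset({1, 2})) -> Alignment:
    """Keep only the requested within-codon positions (1-based in codon)."""
    if a.alphabet != NUCLEOTIDE:
        raise AlignmentError("codon-position exclusion requires nucleotide data")
    if not a.codon_frame:
        raise AlignmentError("codon-position exclusion requires codon_frame")
    keep = frozenset(keep)
    if not keep <= {1, 2, 3} or not keep:
        raise ValueError("keep must be a non-empty subset of {1, 2, 3}")
    cols = [c for c in range(1, a.length + 1) if ((c - 1) % 3) + 1 in keep]
    return a.take_columns(cols, codon_frame=(keep == {1, 2, 3}))


# ---------------------------------------------------------------------------
# AT/GC filter
# ---------------------------------------------------------------------------

def _category_counts(a: Alignment) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-column (n_AT, n_GC) over the whole matrix."""
    arr = a.to_array()
    at = np.isin(arr, [b"A", b"T", b"W"]).sum(axis=0)
    gc = np.isin(arr, [b"G", b"C", b"S"]).sum(axis=0)
    return at, gc


def atgc_profile(a: Alignment, column: int) -> AtGcColumnProfile:
    """Category counts for one column (1-based)."""
    if a.alphabet != NUCLEOTIDE:
        raise AlignmentError("AT/GC profiling requires nucleotide data")
    col = a.column(column).encode("ascii")
    n_at = sum(1 for c in col if c in _AT)
    n_gc = sum(1 for c in col if c in _GC)
    return AtGcColumnProfile(n_at=n_at, n_gc=n_gc, n_other=len(col) - n_at - n_gc)


def atgc_retained_columns(a: Alignment, k: int = 0) -> list[int]:
    """1-based indices of columns retained under a k-taxon exception.

    A column survives iff its minority category is carried by at most
    *k* taxa, i.e. ``min(n_AT, n_GC) <= k``; k = 0 is the strict rule
    removing every column containing both categories.
    """
    if a.alphabet != NUCLEOTIDE:
        raise AlignmentError("AT/GC filtering requires nucleotide data")
    if k < 0:
        raise ValueError("k must be >= 0")
    at, gc = _category_counts(a)
    keep = np.minimum(at, gc) <= k
    return [int(i) + 1 for i in np.nonzero(keep)[0]]


def atgc_filter(a: Alignment, k: int = 0) -> Alignment:
    """Apply the AT/GC compositional filter with *k* taxon exceptions."""
    return a.take_columns(atgc_retained_columns(a, k))


def atgc_series(a: Alignment, k_max: int = 10) -> list[Alignment]:
    """The relaxation series: one matrix per k = 0..k_max (11 by default).

    Retained column sets are nested in k, so matrix lengths are
    monotonically non-decreasing along the series.
    """
    return [atgc_filter(a, k) for k in range(k_max + 1)]


# ---------------------------------------------------------------------------
# slow-fast
# ---------------------------------------------------------------------------

def slowfast_rates(a: Alignment, groups: TaxonGroupSet) -> SiteRateTable:
    """Per-column rate proxies from a priori monophyletic groups.

    rate(col) = sum over groups of (distinct counted states among the
    group's taxa at col - 1, floored at 0).  Gaps/missing/ambiguities do
    not count, and taxa outside every group are ignored.  This is the
    minimum parsimony change count on the tree in which each group is a
    resolved clade hanging off one big polytomy.
    """
    groups.validate_against(a)
    counted = a.counted_states()
    counted_b = {s.encode("ascii") for s in counted}
    arr = a.to_array()
    index = {t: i for i, t in enumerate(a.taxa)}
    rates = np.zeros(a.length, dtype=int)
    for _, members in groups.groups:
        rows = arr[[index[t] for t in members], :]
        for j in range(a.length):
            states = {c.tobytes() for c in rows[:, j]} & counted_b
            if len(states) > 1:
                rates[j] += len(states) - 1
    return SiteRateTable(
        rates=tuple(int(r) for r in rates),
        provenance=";".join(name for name, _ in groups.groups),
    )


def default_thresholds(rates: SiteRateTable) -> list[int]:
    """Every integer threshold from max(rate) - 1 down to 0."""
    return list(range(rates.max_rate - 1, -1, -1))


def slowfast_series(
    a: Alignment,
    rates: SiteRateTable,
    thresholds: list[int] | None = None,
) -> list[Alignment]:
    """Strip the fastest sites stepwise: matrix i keeps rate <= thresholds[i].

    Thresholds must be strictly descending non-negative integers; the
    default schedule emits every integer threshold below the maximum
    observed rate, so the series is nested by construction.  An empty
    matrix is emitted with a warning rather than an error.
    """
    if len(rates.rates) != a.length:
        raise AlignmentError("rate table does not match alignment length")
    if thresholds is None:
        thresholds = default_thresholds(rates)
    if any(t < 0 for t in thresholds) or any(
        later >= earlier for earlier, later in zip(thresholds, thresholds[1:])
    ):
        raise ValueError("thresholds must be strictly descending and >= 0")
    r = np.asarray(rates.rates)
    out = []
    for t in thresholds:
        cols = [int(i) + 1 for i in np.nonzero(r <= t)[0]]
        if not cols:
            warnings.warn(f"slow-fast threshold {t} leaves an empty matrix")
        out.append(a.take_columns(cols))
    return out
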