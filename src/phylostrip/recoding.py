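"""Character-state recoding.

Two families of transforms that discard the substitution classes most
prone to saturation and compositional convergence:

* RY recoding of nucleotides (purine R = A/G, pyrimidine Y = C/T),
  optionally restricted to first+second codon positions with third
  positions removed;
* amino acid recoding into Dayhoff-style groups (``dayhoff6``,
  ``dayhoff4``, ``hp``), shipped as a plain-text scheme table so users
  can add their own.

Group target symbols are the first-listed residue of each group, keeping
recoded files human-readable and NEXUS-declarable.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .alignment import AMINO, NUCLEOTIDE, Alignment, AlignmentError, recoded

_AA20 = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class RecodingScheme:
    """A total mapping from an amino acid alphabet onto group symbols."""

    name: str
    groups: tuple[tuple[str, tuple[str, ...]], ...]  # (target, members)
    to_missing: frozenset[str]

    def __post_init__(self):
        seen: set[str] = set()
        targets = [t for t, _ in self.groups]
        if len(set(targets)) != len(targets):
            raise ValueError(f"{self.name}: duplicate target symbols")
        for _, members in self.groups:
            if seen & set(members):
                raise ValueError(f"{self.name}: groups are not disjoint")
            seen |= set(members)
        covered = seen | self.to_missing
        if covered != _AA20:
            raise ValueError(
                f"{self.name}: groups + missing must partition the 20 residues; "
                f"off by {sorted(covered ^ _AA20)}"
            )

    def mapping(self) -> dict[str, str]:
        m = {res: target for target, members in self.groups for res in members}
        for res in self.to_missing:
            m[res] = "?"
        return m


def load_schemes(path: str | Path | None = None) -> dict[str, RecodingScheme]:
    """Parse the scheme table (shipped file by default)."""
    if path is None:
        text = (
            resources.files("phylostrip") / "data" / "recoding_schemes.txt"
        ).read_text()
    else:
        text = Path(path).read_text()
    raw: dict[str, dict] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        name, members = fields[0], fields[1:]
        entry = raw.setdefault(name, {"groups": [], "missing": set()})
        if members[0] == "?":
            entry["missing"].update(members[1:])
        else:
            entry["groups"].append((members[0], tuple(members)))
    return {
        name: RecodingScheme(
            name=name,
            groups=tuple(e["groups"]),
            to_missing=frozenset(e["missing"]),
        )
        for name, e in raw.items()
    }


SCHEMES = load_schemes()

# RY map: within-class IUPAC codes pass through, anything straddling the
# purine/pyrimidine boundary carries no class information and goes missing.
_RY_MAP = {
    "A": "R", "G": "R", "R": "R",
    "C": "Y", "T": "Y", "Y": "Y",
    "-": "-", "?": "?",
}


def recode_ry(a: Alignment, scope: str = "all") -> Alignment:
    """RY-recode a nucleotide alignment.

    ``scope="all"`` recodes every column; ``scope="first_second"``
    additionally removes third codon positions (the two treatments are
    applied as a pair), so the output has 2/3 of the input columns.
    """
    if a.alphabet != NUCLEOTIDE:
        raise AlignmentError("RY recoding requires a nucleotide alignment")
    if scope not in ("all", "first_second"):
        raise ValueError(f"unknown scope {scope!r}")
    if scope == "first_second":
        if not a.codon_frame:
            raise AlignmentError("scope='first_second' requires codon_frame")
        src = a.take_columns(
            [c for c in range(1, a.length + 1) if c % 3 != 0]
        )
        name = "ry12"
    else:
        src = a
        name = "ry"
    seqs = tuple(
        "".join(_RY_MAP.get(c, "?") for c in s) for s in src.sequences
    )
    return Alignment(
        taxa=src.taxa,
        sequences=seqs,
        alphabet=recoded(name),
        partitions=src.partitions,
    )


def recode_aa(a: Alignment, scheme: str | RecodingScheme) -> Alignment:
    """Recode an amino acid alignment under a named Dayhoff-style scheme."""
    if a.alphabet != AMINO:
        raise AlignmentError("amino acid recoding requires an amino alignment")
    if isinstance(scheme, str):
        try:
            scheme = SCHEMES[scheme]
        except KeyError:
            raise ValueError(
                f"unknown scheme {scheme!r}; available: {sorted(SCHEMES)}"
            ) from None
    table = scheme.mapping()
    table.update({"-": "-", "?": "?", "X": "?", "*": "?"})
    unknown = sorted({c for s in a.sequences for c in s if c not in table})
    if unknown:
        raise AlignmentError(f"unknown residue character(s): {unknown}")
    seqs = tuple("".join(table[c] for c in s) for s in a.sequences)
    return Alignment(
        taxa=a.taxa,
        sequences=seqs,
        alphabet=recoded(scheme.name),
        partitions=a.partitions,
    )
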