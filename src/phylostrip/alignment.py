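"""Alignment container, I/O, translation, concatenation and site statistics.

The central object is :class:`Alignment`, a taxa-by-columns character matrix
tagged with an alphabet (``nucleotide``, ``amino`` or ``recoded(<scheme>)``),
an optional codon frame, and a 1-based gene-partition map.  Everything
downstream (recoding, site filtering, simulation output, tree inference)
consumes and produces this type.

Counting conventions: gap ``-``, missing ``?``, nucleotide ambiguity codes
and amino ``X``/``*`` are "uncounted" for all site and composition
statistics; ``-`` and ``?`` are preserved as distinct symbols on round trip.
User-facing column coordinates are 1-based inclusive, as in NEXUS charsets.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Nexus import Nexus
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NUCLEOTIDE = "nucleotide"
AMINO = "amino"

_NT_COUNTED = set("ACGT")
_AA_COUNTED = set("ACDEFGHIKLMNPQRSTVWY")
_IUPAC_NT = set("ACGTUNRYSWKMBDHV")
_GAPLIKE = set("-?.")


def recoded(scheme: str) -> str:
    """Alphabet tag for a matrix recoded under *scheme*."""
    return f"recoded({scheme})"


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class Alignment:
    """Immutable multiple sequence alignment.

    Parameters
    ----------
    taxa : tuple of str
        Unique taxon labels, row order of ``sequences``.
    sequences : tuple of str
        One uppercase character string per taxon, all equal length.
    alphabet : str
        ``nucleotide``, ``amino`` or ``recoded(<scheme>)``.
    codon_frame : bool
        Columns come in consecutive codon triplets starting at column 1.
    partitions : tuple of (name, first, last)
        1-based inclusive, contiguous, non-overlapping gene intervals
        tiling ``[1, length]``.
    """

    taxa: tuple[str, ...]
    sequences: tuple[str, ...]
    alphabet: str = NUCLEOTIDE
    codon_frame: bool = False
    partitions: tuple[tuple[str, int, int], ...] = field(default=())

    def __post_init__(self):
        if len(self.taxa) != len(self.sequences):
            raise AlignmentError("taxa and sequences differ in number")
        if not self.taxa:
            raise AlignmentError("alignment has no taxa")
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if list(self.taxa).count(t) > 1})
            raise AlignmentError(f"duplicate taxon labels: {dupes}")
        length = len(self.sequences[0])
        for label, seq in zip(self.taxa, self.sequences):
            if len(seq) != length:
                raise AlignmentError(
                    f"length mismatch for taxon {label!r}: "
                    f"{len(seq)} != {length}"
                )
        if not self.partitions and length:
            object.__setattr__(self, "partitions", (("all", 1, length),))
        self._check_partitions(length)
        if self.codon_frame:
            if length % 3:
                raise AlignmentError("codon_frame set but length not divisible by 3")
            for name, first, last in self.partitions:
                if (last - first + 1) % 3:
                    raise AlignmentError(
                        f"codon_frame set but partition {name!r} length "
                        "not divisible by 3"
                    )

    def _check_partitions(self, length: int) -> None:
        if length == 0:
            if self.partitions:
                raise AlignmentError("zero-length alignment cannot have partitions")
            return
        expected = 1
        for name, first, last in self.partitions:
            if first != expected or last < first:
                raise AlignmentError(
                    f"partition {name!r} [{first},{last}] does not tile the matrix"
                )
            expected = last + 1
        if expected != length + 1:
            raise AlignmentError("partitions do not cover the full alignment")

    # -- basic accessors -------------------------------------------------

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def sequence(self, taxon: str) -> str:
        return self.sequences[self.taxa.index(taxon)]

    def column(self, col: int) -> str:
        """Column *col* (1-based) as a string over taxa in row order."""
        return "".join(seq[col - 1] for seq in self.sequences)

    def to_array(self) -> np.ndarray:
        """Matrix as a (n_taxa, length) array of single-byte strings."""
        return np.frombuffer(
            "".join(self.sequences).encode("ascii"), dtype="S1"
        ).reshape(self.n_taxa, self.length)

    # -- column subsetting ----------------------------------------------

    def take_columns(
        self,
        columns,
        codon_frame: bool = False,
        alphabet: str | None = None,
    ) -> "Alignment":
        """New alignment keeping 1-based *columns* in the given order.

        The partition map is rescaled: each gene keeps the count of its
        surviving columns; genes losing every column are dropped.
        """
        cols = list(columns)
        if any(c < 1 or c > self.length for c in cols):
            raise AlignmentError("column index out of range")
        idx = [c - 1 for c in cols]
        seqs = tuple("".join(s[i] for i in idx) for s in self.sequences)
        parts = []
        pos = 1
        for name, first, last in self.partitions:
            kept = sum(1 for c in cols if first <= c <= last)
            if kept:
                parts.append((name, pos, pos + kept - 1))
                pos += kept
        return Alignment(
            taxa=self.taxa,
            sequences=seqs,
            alphabet=alphabet or self.alphabet,
            codon_frame=codon_frame,
            partitions=tuple(parts),
        )

    def counted_states(self) -> frozenset[str]:
        """States that count toward site/composition statistics."""
        if self.alphabet == NUCLEOTIDE:
            return frozenset(_NT_COUNTED)
        if self.alphabet == AMINO:
            return frozenset(_AA_COUNTED)
        observed = set("".join(self.sequences))
        return frozenset(observed - _GAPLIKE - {"X", "N", "*"})


@dataclass(frozen=True)
class SiteSummary:
    """Per-column site classification and totals."""

    classes: tuple[str, ...]  # constant | variable-uninformative | parsimony-informative
    n_constant: int
    n_variable: int            # variable-uninformative + parsimony-informative
    n_informative: int
    state_counts: tuple[dict, ...]


@dataclass(frozen=True)
class TaxonCompositionTable:
    """Per-taxon GC fraction; taxa with no unambiguous base map to None."""

    gc: dict[str, float | None]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _detect_alphabet(seqs) -> str:
    chars = [c for s in seqs for c in s if c not in _GAPLIKE]
    if not chars:
        return NUCLEOTIDE
    n_nt = sum(1 for c in chars if c in _IUPAC_NT)
    return NUCLEOTIDE if n_nt / len(chars) >= 0.9 else AMINO


def _from_records(records, fmt: str) -> Alignment:
    taxa, seqs = [], []
    for rec in records:
        taxa.append(rec.id)
        seqs.append(str(rec.seq).upper())
    if not taxa:
        raise AlignmentError(f"no sequences found in {fmt} input")
    if len(set(taxa)) != len(taxa):
        raise AlignmentError("duplicate taxon labels in input")
    length = len(seqs[0])
    for i, (t, s) in enumerate(zip(taxa, seqs)):
        if len(s) != length:
            raise AlignmentError(
                f"length mismatch for taxon {t!r} (record {i + 1}): "
                f"{len(s)} != {length}"
            )
    alphabet = _detect_alphabet(seqs)
    if alphabet == NUCLEOTIDE:
        seqs = [s.replace("U", "T") for s in seqs]
    return Alignment(taxa=tuple(taxa), sequences=tuple(seqs), alphabet=alphabet)


def read_alignment(path, format: str = "fasta") -> Alignment:
    """Read a FASTA, relaxed-PHYLIP or NEXUS alignment.

    The alphabet is auto-detected (>= 90% of non-gap characters in the
    IUPAC nucleotide set means nucleotide, else amino); ``U`` is
    normalized to ``T`` in nucleotide data.
    """
    path = Path(path)
    if format == "fasta":
        return _from_records(SeqIO.parse(path, "fasta"), format)
    if format == "phylip":
        return _from_records(SeqIO.parse(path, "phylip-relaxed"), format)
    if format == "nexus":
        nex = Nexus.Nexus(str(path))
        records = [
            SeqRecord(Seq(str(nex.matrix[t])), id=str(t)) for t in nex.taxlabels
        ]
        aln = _from_records(records, format)
        # honour an explicit datatype over heuristics
        dt = (nex.datatype or "").lower()
        if dt == "protein":
            aln = replace(aln, alphabet=AMINO)
        elif dt == "dna":
            aln = replace(aln, alphabet=NUCLEOTIDE)
        return aln
    raise ValueError(f"unknown format {format!r}")


def _nexus_text(a: Alignment) -> str:
    if a.alphabet == NUCLEOTIDE:
        fmt = "datatype=dna missing=? gap=-"
    elif a.alphabet == AMINO:
        fmt = "datatype=protein missing=? gap=-"
    else:
        symbols = "".join(sorted(a.counted_states()))
        fmt = f'datatype=standard symbols="{symbols}" missing=? gap=-'
    width = max(len(t) for t in a.taxa) + 2
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"  DIMENSIONS NTAX={a.n_taxa} NCHAR={a.length};",
        f"  FORMAT {fmt};",
        "  MATRIX",
    ]
    for t, s in zip(a.taxa, a.sequences):
        label = f"'{t}'" if any(ch.isspace() for ch in t) else t
        lines.append(f"    {label.ljust(width)}{s}")
    lines += ["  ;", "END;", ""]
    return "\n".join(lines)


def write_alignment(a: Alignment, path, format: str = "fasta") -> None:
    """Write *a*; recoded alphabets require NEXUS (symbol declaration)."""
    path = Path(path)
    if format == "nexus":
        path.write_text(_nexus_text(a))
        return
    if a.alphabet not in (NUCLEOTIDE, AMINO):
        raise AlignmentError(
            f"{format} has no symbol declaration; write recoded data as NEXUS"
        )
    records = [SeqRecord(Seq(s), id=t, description="") for t, s in zip(a.taxa, a.sequences)]
    fmt = "phylip-relaxed" if format == "phylip" else format
    with open(path, "w") as fh:
        SeqIO.write(records, fh, fmt)


def write_partition_file(a: Alignment, path) -> None:
    """RAxML-style plain-text partition map, one ``gene = first-last`` per line."""
    with open(path, "w") as fh:
        for name, first, last in a.partitions:
            fh.write(f"{name} = {first}-{last}\n")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

_TABLE1 = CodonTable.unambiguous_dna_by_id[1]


def translate_cds(a: Alignment) -> Alignment:
    """Translate a codon-framed nucleotide alignment (genetic code 1).

    Codons containing any gap or ambiguity become ``X``; stop codons are
    translated as ``*`` and their total count raised as a warning.
    """
    if a.alphabet != NUCLEOTIDE:
        raise AlignmentError("translate_cds requires a nucleotide alignment")
    if not a.codon_frame:
        raise AlignmentError("translate_cds requires codon_frame")
    fwd = _TABLE1.forward_table
    stops = set(_TABLE1.stop_codons)
    n_stop = 0
    out = []
    for seq in a.sequences:
        aa = []
        for i in range(0, len(seq), 3):
            codon = seq[i : i + 3]
            if any(c not in "ACGT" for c in codon):
                aa.append("X")
            elif codon in stops:
                aa.append("*")
                n_stop += 1
            else:
                aa.append(fwd[codon])
        out.append("".join(aa))
    if n_stop:
        warnings.warn(f"{n_stop} internal stop codon(s) translated as '*'")
    parts = tuple(
        (name, (first - 1) // 3 + 1, last // 3) for name, first, last in a.partitions
    )
    return Alignment(
        taxa=a.taxa, sequences=tuple(out), alphabet=AMINO, partitions=parts
    )


def concatenate(parts: list[Alignment], names: list[str] | None = None) -> Alignment:
    """Concatenate gene alignments over an identical taxon set.

    Taxa are re-ordered to the first part's order; no missing data is
    permitted (a taxon absent from any part is an error).
    """
    if not parts:
        raise AlignmentError("nothing to concatenate")
    ref = parts[0]
    ref_set = set(ref.taxa)
    for i, p in enumerate(parts[1:], start=2):
        if set(p.taxa) != ref_set:
            missing = sorted(ref_set ^ set(p.taxa))
            raise AlignmentError(
                f"taxon sets differ between part 1 and part {i}: {missing}"
            )
        if p.alphabet != ref.alphabet:
            raise AlignmentError("alphabet mismatch between parts")
        if p.codon_frame != ref.codon_frame:
            raise AlignmentError("codon_frame must be all-or-none across parts")
    if names is None:
        names = []
        for i, p in enumerate(parts, start=1):
            if len(p.partitions) == 1 and p.partitions[0][0] == "all":
                names.append(f"gene{i}")
            else:
                names.append(None)
    seqs = []
    for t in ref.taxa:
        seqs.append("".join(p.sequence(t) for p in parts))
    partitions = []
    offset = 0
    for p, nm in zip(parts, names):
        if nm is not None:
            partitions.append((nm, offset + 1, offset + p.length))
        else:
            for g, first, last in p.partitions:
                partitions.append((g, offset + first, offset + last))
        offset += p.length
    return Alignment(
        taxa=ref.taxa,
        sequences=tuple(seqs),
        alphabet=ref.alphabet,
        codon_frame=ref.codon_frame,
        partitions=tuple(partitions),
    )


def site_summary(a: Alignment) -> SiteSummary:
    """Classify every column as constant / variable-uninformative /
    parsimony-informative.

    A column is parsimony-informative iff at least two distinct counted
    states each occur in at least two taxa; variable iff at least two
    distinct counted states occur at all.  Gaps, missing and ambiguity
    codes never count; all-gap columns are constant.
    """
    counted = a.counted_states()
    arr = a.to_array()
    classes = []
    state_counts = []
    for j in range(a.length):
        col = arr[:, j]
        vals, counts = np.unique(col, return_counts=True)
        cc = {
            v.decode(): int(n)
            for v, n in zip(vals, counts)
            if v.decode() in counted
        }
        state_counts.append(cc)
        if len(cc) < 2:
            classes.append("constant")
        elif sum(1 for n in cc.values() if n >= 2) >= 2:
            classes.append("parsimony-informative")
        else:
            classes.append("variable-uninformative")
    n_inf = classes.count("parsimony-informative")
    n_var = n_inf + classes.count("variable-uninformative")
    return SiteSummary(
        classes=tuple(classes),
        n_constant=classes.count("constant"),
        n_variable=n_var,
        n_informative=n_inf,
        state_counts=tuple(state_counts),
    )


def taxon_gc_content(a: Alignment, columns=None) -> TaxonCompositionTable:
    """Per-taxon GC fraction, ``(#G + #C) / (#A + #C + #G + #T)``.

    Only unambiguous bases enter the denominator; a taxon with none in
    the selected columns is reported as None (undefined).
    """
    if a.alphabet != NUCLEOTIDE:
        raise AlignmentError("GC content requires a nucleotide alignment")
    if columns is not None:
        idx = [c - 1 for c in columns]
    else:
        idx = range(a.length)
    gc: dict[str, float | None] = {}
    for t, seq in zip(a.taxa, a.sequences):
        n_gc = n_all = 0
        for i in idx:
            c = seq[i]
            if c in "ACGT":
                n_all += 1
                if c in "GC":
                    n_gc += 1
        gc[t] = (n_gc / n_all) if n_all else None
    return TaxonCompositionTable(gc=gc)
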