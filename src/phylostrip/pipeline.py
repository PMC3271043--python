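"""Declarative pipeline: read -> concatenate -> transform chain -> reports.

A config (YAML) names the input alignments, an ordered list of stages
and an output directory; the chain is type-checked against alphabet
transitions before any stage runs, every emitted matrix is accompanied
by a JSON report (site-class counts, per-taxon GC where applicable,
retained column indices for filters, and a provenance hash of
config+seed), and outputs are a pure function of (inputs, config,
seed): the run directory is stamped with the provenance hash rather
than a timestamp, so a rerun reproduces byte-identical files instead of
clobbering different ones.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import filters, recoding
from .alignment import (
    AMINO,
    NUCLEOTIDE,
    Alignment,
    AlignmentError,
    concatenate,
    read_alignment,
    site_summary,
    taxon_gc_content,
    translate_cds,
    write_alignment,
    write_partition_file,
)

log = logging.getLogger("phylostrip")

# stage name -> (required input alphabet, needs codon frame, output alphabet)
_STAGE_TYPES = {
    "translate": (NUCLEOTIDE, True, AMINO),
    "drop-third": (NUCLEOTIDE, True, NUCLEOTIDE),
    "ry": (NUCLEOTIDE, False, "recoded(ry)"),
    "ry12": (NUCLEOTIDE, True, "recoded(ry12)"),
    "dayhoff6": (AMINO, False, "recoded(dayhoff6)"),
    "dayhoff4": (AMINO, False, "recoded(dayhoff4)"),
    "hp": (AMINO, False, "recoded(hp)"),
    "atgc-filter": (NUCLEOTIDE, False, NUCLEOTIDE),
    "slowfast": (None, False, None),  # alphabet-preserving
    "stats": (None, False, None),
}


@dataclass(frozen=True)
class PipelineConfig:
    """Inputs, ordered transformation chain and output options."""

    inputs: tuple[str, ...]
    format: str = "fasta"
    codon_frame: bool = False
    stages: tuple[dict, ...] = ()
    output_dir: str = "phylostrip_out"
    out_format: str = "fasta"
    seed: int = 0
    group_file: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["inputs"] = tuple(raw["inputs"])
        raw["stages"] = tuple(raw.get("stages", ()))
        return cls(**raw)

    def provenance_hash(self) -> str:
        blob = json.dumps(
            {
                "inputs": list(self.inputs),
                "format": self.format,
                "codon_frame": self.codon_frame,
                "stages": list(self.stages),
                "out_format": self.out_format,
                "seed": self.seed,
                "group_file": self.group_file,
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def check_stage_chain(config: PipelineConfig) -> str:
    """Type-check alphabet transitions; returns the final alphabet.

    Raises before any computation if a stage cannot accept its
    predecessor's output (e.g. dayhoff6 on nucleotide data without a
    prior translate).
    """
    alphabet = NUCLEOTIDE  # inputs are sequence files; amino detected at read
    framed = config.codon_frame
    for stage in config.stages:
        op = stage["op"]
        if op not in _STAGE_TYPES:
            raise ValueError(f"unknown stage {op!r}")
        need_alpha, need_frame, out_alpha = _STAGE_TYPES[op]
        if need_alpha is not None and alphabet != need_alpha:
            raise AlignmentError(
                f"stage {op!r} requires {need_alpha} input but the chain "
                f"produces {alphabet} at this point"
            )
        if need_frame and not framed:
            raise AlignmentError(f"stage {op!r} requires codon-framed input")
        if out_alpha is not None:
            alphabet = out_alpha
        if op == "drop-third":
            framed = set(stage.get("keep", [1, 2])) == {1, 2, 3}
        elif op != "stats":  # column filters and recodings break the frame
            framed = False
    return alphabet


def _apply_stage(aln: Alignment, stage: dict, config: PipelineConfig):
    """Run one stage; returns (alignment, report-extras)."""
    op = stage["op"]
    extras: dict = {}
    if op == "stats":
        return aln, extras
    if op == "translate":
        return translate_cds(aln), extras
    if op == "drop-third":
        keep = frozenset(stage.get("keep", (1, 2)))
        return filters.exclude_codon_positions(aln, keep=keep), extras
    if op == "ry":
        return recoding.recode_ry(aln, scope="all"), extras
    if op == "ry12":
        return recoding.recode_ry(aln, scope="first_second"), extras
    if op in ("dayhoff6", "dayhoff4", "hp"):
        return recoding.recode_aa(aln, op), extras
    if op == "atgc-filter":
        k = int(stage.get("k", 0))
        retained = filters.atgc_retained_columns(aln, k)
        extras["retained_columns"] = retained
        return aln.take_columns(retained), extras
    if op == "slowfast":
        if config.group_file is None:
            raise AlignmentError("slowfast stage requires a group_file")
        groups = filters.TaxonGroupSet.from_file(config.group_file)
        rates = filters.slowfast_rates(aln, groups)
        thr = stage.get("threshold")
        if thr is None:
            sched = filters.default_thresholds(rates)
            thr = sched[0] if sched else rates.max_rate
        cols = [i + 1 for i, r in enumerate(rates.rates) if r <= thr]
        extras["retained_columns"] = cols
        extras["threshold"] = thr
        return aln.take_columns(cols), extras
    raise ValueError(f"unknown stage {op!r}")


def matrix_report(aln: Alignment, config: PipelineConfig, **extras) -> dict:
    summary = site_summary(aln)
    report = {
        "n_taxa": aln.n_taxa,
        "length": aln.length,
        "alphabet": aln.alphabet,
        "sites": {
            "constant": summary.n_constant,
            "variable": summary.n_variable,
            "parsimony_informative": summary.n_informative,
        },
        "provenance": config.provenance_hash(),
    }
    if aln.alphabet == NUCLEOTIDE:
        report["taxon_gc"] = taxon_gc_content(aln).gc
    report.update(extras)
    return report


def _emit(aln: Alignment, name: str, outdir: Path, config: PipelineConfig, extras):
    fmt = config.out_format
    if aln.alphabet not in (NUCLEOTIDE, AMINO):
        fmt = "nexus"  # recoded alphabets need a symbol declaration
    ext = {"fasta": "fasta", "phylip": "phy", "nexus": "nex"}[fmt]
    mpath = outdir / f"{name}.{ext}"
    write_alignment(aln, mpath, format=fmt)
    write_partition_file(aln, outdir / f"{name}.partitions.txt")
    rpath = outdir / f"{name}.report.json"
    rpath.write_text(json.dumps(matrix_report(aln, config, **extras), indent=2, sort_keys=True))
    return mpath


def _read_inputs(config: PipelineConfig) -> Alignment:
    parts = []
    for p in config.inputs:
        aln = read_alignment(p, format=config.format)
        if config.codon_frame:
            aln = Alignment(
                taxa=aln.taxa,
                sequences=aln.sequences,
                alphabet=aln.alphabet,
                codon_frame=True,
            )
        parts.append(aln)
    if len(parts) == 1:
        return parts[0]
    names = [Path(p).stem for p in config.inputs]
    return concatenate(parts, names=names)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured chain; returns the final matrix report."""
    check_stage_chain(config)  # pre-flight, before any computation
    aln = _read_inputs(config)
    log.info("input: %d taxa x %d columns (%s)", aln.n_taxa, aln.length, aln.alphabet)
    outdir = Path(config.output_dir) / f"run-{config.provenance_hash()}"
    outdir.mkdir(parents=True, exist_ok=True)
    extras: dict = {}
    taxa_before = set(aln.taxa)
    for stage in config.stages:
        aln, extras = _apply_stage(aln, stage, config)
        assert set(aln.taxa) == taxa_before, "stage changed the taxon set"
        log.info(
            "stage %-12s -> %d taxa x %d columns (%s)",
            stage["op"], aln.n_taxa, aln.length, aln.alphabet,
        )
    _emit(aln, "final", outdir, config, extras)
    report = matrix_report(aln, config, **extras)
    (outdir / "run.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def make_matrix_series(config: PipelineConfig, k_max: int = 10) -> dict:
    """Emit the full family of derived matrices from one codon-framed input.

    Family: nucleotide full, third positions removed, RY, RY12, the
    AT/GC relaxation series k = 0..k_max, the translated amino acid
    matrix and its dayhoff6/dayhoff4/hp recodings, plus the slow-fast
    series when a group file is configured.  Returns the manifest.
    """
    aln = _read_inputs(config)
    if aln.alphabet != NUCLEOTIDE or not aln.codon_frame:
        raise AlignmentError("matrix-series requires codon-framed nucleotide input")
    outdir = Path(config.output_dir) / f"series-{config.provenance_hash()}"
    outdir.mkdir(parents=True, exist_ok=True)

    products: list[tuple[str, Alignment, dict]] = [("nt_full", aln, {})]
    products.append(("nt_pos12", filters.exclude_codon_positions(aln, keep={1, 2}), {}))
    products.append(("ry", recoding.recode_ry(aln, scope="all"), {}))
    products.append(("ry12", recoding.recode_ry(aln, scope="first_second"), {}))
    for k in range(k_max + 1):
        cols = filters.atgc_retained_columns(aln, k)
        products.append(
            (f"atgc_k{k}", aln.take_columns(cols), {"retained_columns": cols, "k": k})
        )
    aa = translate_cds(aln)
    products.append(("aa", aa, {}))
    for scheme in ("dayhoff6", "dayhoff4", "hp"):
        products.append((scheme, recoding.recode_aa(aa, scheme), {}))
    if config.group_file is not None:
        groups = filters.TaxonGroupSet.from_file(config.group_file)
        rates = filters.slowfast_rates(aln, groups)
        for thr, mat in zip(
            filters.default_thresholds(rates), filters.slowfast_series(aln, rates)
        ):
            products.append((f"sf_t{thr}", mat, {"threshold": thr}))
    else:
        log.warning("no group file configured; slow-fast series skipped")

    manifest = {"provenance": config.provenance_hash(), "matrices": []}
    for name, mat, extras in products:
        if mat.length == 0:
            log.warning("matrix %s is empty; not written", name)
            continue
        path = _emit(mat, name, outdir, config, extras)
        digest = hashlib.sha256(path.read_bytes()).hexdigest()[:16]
        manifest["matrices"].append(
            {
                "name": name,
                "path": str(path),
                "n_taxa": mat.n_taxa,
                "length": mat.length,
                "alphabet": mat.alphabet,
                "sha256": digest,
            }
        )
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
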