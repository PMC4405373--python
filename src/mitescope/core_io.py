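"""Shared sequence/annotation containers and standard-format readers and writers.

Conventions used throughout the package:

* all in-memory coordinates are 0-based half-open;
* GFF-like annotation files are 1-based inclusive and converted on read/write;
* element tables are BED-compatible (0-based half-open) TSV with attribute columns;
* DNA is uppercase over the alphabet ``{A, C, G, T, N}``; ``N`` is a legal residue
  but never matches any base in comparisons performed by the analysis modules.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

DNA_ALPHABET = frozenset("ACGTN")
FASTA_LINE_WIDTH = 60

_ELEMENT_TABLE_COLUMNS = (
    "chrom",
    "chromStart",
    "chromEnd",
    "name",
    "family",
    "tsd",
    "tir_length",
    "tir_mismatches",
    "intact",
)


class ParseError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class GenomeSequence:
    """A named DNA contig."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("contig id must be non-empty")
        if not self.residues:
            raise ValueError(f"contig {self.id!r}: empty sequence")
        bad = set(self.residues) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"contig {self.id!r}: illegal residues {sorted(bad)!r}; "
                "allowed alphabet is A/C/G/T/N"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene; CDS coordinates are 0-based half-open."""

    gene_id: str
    contig_id: str
    strand: str
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: strand must be '+' or '-'")
        if not (0 <= self.cds_start < self.cds_end):
            raise ValueError(
                f"gene {self.gene_id!r}: invalid CDS interval "
                f"[{self.cds_start}, {self.cds_end})"
            )


@dataclass
class PipelineConfig:
    """Tunable parameters of the discovery/analysis pipeline.

    Defaults mirror the detection rules of the source workflow: TIR 5-60 bp with at
    most one mismatch, TSD 2-20 bp, element body < 1500 bp, families at >= 90%
    identity with >= 3 members, remnant mining at identity >= 0.90 and consensus
    coverage >= 0.80, 300 bp gene flanks and 0.02-wide divergence histogram bins.
    """

    tir_min: int = 5
    tir_max: int = 60
    tsd_min: int = 2
    tsd_max: int = 20
    max_element_len: int = 1500
    max_tir_mismatch: int = 1
    family_identity: float = 0.90
    min_family_size: int = 3
    remnant_identity: float = 0.90
    remnant_coverage: float = 0.80
    flank_bp: int = 300
    histogram_bin: float = 0.02
    rng_seed: int = 20150421
    # clustering guards beyond the headline thresholds (see docs/methods.md)
    min_edge_coverage: float = 0.60
    min_edge_columns: int = 30
    max_candidate_n: int = 2

    def __post_init__(self) -> None:
        for name in ("family_identity", "remnant_identity", "remnant_coverage",
                     "min_edge_coverage"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 1 <= self.tir_min <= self.tir_max:
            raise ValueError("require 1 <= tir_min <= tir_max")
        if not 1 <= self.tsd_min <= self.tsd_max:
            raise ValueError("require 1 <= tsd_min <= tsd_max")
        if self.max_element_len <= 2 * self.tir_min:
            raise ValueError("max_element_len must exceed twice tir_min")
        if self.max_tir_mismatch < 0:
            raise ValueError("max_tir_mismatch must be >= 0")
        if self.histogram_bin <= 0:
            raise ValueError("histogram_bin must be positive")

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a (multi-line) FASTA file into validated :class:`GenomeSequence` records.

    Residues are uppercased; any character outside ``A/C/G/T/N`` raises
    :class:`ParseError` naming the offending line.
    """
    path = Path(path)
    records: list[GenomeSequence] = []
    seen: set[str] = set()
    header: str | None = None
    chunks: list[str] = []
    header_line = 0

    def _flush(line_no: int) -> None:
        nonlocal header, chunks
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise ParseError(f"{path}:{header_line}: record {header!r} has no sequence")
        records.append(GenomeSequence(id=header, residues=seq))
        header, chunks = None, []

    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush(line_no)
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise ParseError(f"{path}:{line_no}: empty FASTA header")
                if name in seen:
                    raise ParseError(f"{path}:{line_no}: duplicate sequence id {name!r}")
                seen.add(name)
                header = name
                header_line = line_no
            else:
                if header is None:
                    raise ParseError(
                        f"{path}:{line_no}: sequence data before any FASTA header"
                    )
                chunk = line.upper()
                bad = set(chunk) - DNA_ALPHABET
                if bad:
                    raise ParseError(
                        f"{path}:{line_no}: illegal sequence character(s) "
                        f"{sorted(bad)!r}"
                    )
                chunks.append(chunk)
        _flush(line_no=-1)
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[GenomeSequence] | Iterable[tuple[str, str]],
                path: str | Path, width: int = FASTA_LINE_WIDTH) -> None:
    """Write records (GenomeSequence or (id, seq) tuples) as wrapped FASTA."""
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, GenomeSequence):
                name, seq = rec.id, rec.residues
            else:
                name, seq = rec
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Gene annotations (GFF-like, 1-based inclusive on disk)
# ---------------------------------------------------------------------------

def read_gene_annotations(path: str | Path,
                          genome: Sequence[GenomeSequence] | None = None
                          ) -> list[GeneModel]:
    """Read a GFF-like TSV of CDS records.

    Expected columns: ``contig source type start end score strand frame [attrs]``
    with 1-based inclusive coordinates; they are converted to the package's
    0-based half-open convention.  If *genome* is given, coordinates are bounds-
    checked against contig lengths and unknown contigs rejected.
    """
    path = Path(path)
    lengths = {g.id: len(g) for g in genome} if genome is not None else None
    genes: list[GeneModel] = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise ParseError(
                    f"{path}:{line_no}: expected >= 8 tab-separated fields, "
                    f"got {len(fields)}"
                )
            contig, _source, ftype, start_s, end_s, _score, strand, _frame = fields[:8]
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{line_no}: non-integer coordinate") from exc
            if start1 < 1 or start1 > end1:
                raise ParseError(
                    f"{path}:{line_no}: invalid 1-based interval {start1}..{end1}"
                )
            if lengths is not None:
                if contig not in lengths:
                    raise ParseError(f"{path}:{line_no}: unknown contig {contig!r}")
                if end1 > lengths[contig]:
                    raise ParseError(
                        f"{path}:{line_no}: end {end1} exceeds contig "
                        f"{contig!r} length {lengths[contig]}"
                    )
            gene_id = _attr_gene_id(fields[8] if len(fields) > 8 else "",
                                    default=f"{ftype}_{line_no}")
            genes.append(GeneModel(gene_id=gene_id, contig_id=contig, strand=strand,
                                   cds_start=start1 - 1, cds_end=end1))
    return genes


def _attr_gene_id(attrs: str, default: str) -> str:
    for token in attrs.replace(";", " ").split():
        if token.startswith("ID="):
            return token[3:]
        if token.startswith("gene_id="):
            return token[8:]
    return attrs.strip() or default


def write_gene_annotations(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write genes back out in the GFF-like 1-based inclusive dialect."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                f"{g.contig_id}\tmitescope\tCDS\t{g.cds_start + 1}\t{g.cds_end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# Element tables (BED-compatible TSV)
# ---------------------------------------------------------------------------

def write_element_table(elements: Iterable, path: str | Path) -> None:
    """Serialize located elements as a BED-compatible TSV with attribute columns.

    Elements may be any objects carrying ``contig/start/end`` plus optional
    ``family``, ``tsd``, ``tir_length``, ``tir_mismatches`` and ``intact``
    attributes; missing attributes are written as ``.``.
    """
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_ELEMENT_TABLE_COLUMNS) + "\n")
        for i, el in enumerate(elements):
            contig = getattr(el, "contig", None) or getattr(el, "contig_id")
            start, end = el.start, el.end
            row = [
                contig,
                str(start),
                str(end),
                getattr(el, "name", None) or f"element_{i + 1}",
                _opt(getattr(el, "family", None)),
                _opt(getattr(el, "tsd", None)),
                _opt(getattr(el, "tir_length", None)),
                _opt(getattr(el, "tir_mismatches", None)),
                _opt(int(el.intact) if getattr(el, "intact", None) is not None else None),
            ]
            fh.write("\t".join(row) + "\n")


def _opt(value) -> str:
    return "." if value in (None, "") else str(value)


@dataclass(frozen=True)
class ElementRecord:
    """A row of an element table, as read back from disk."""

    contig: str
    start: int
    end: int
    name: str
    family: str | None = None
    tsd: str | None = None
    tir_length: int | None = None
    tir_mismatches: int | None = None
    intact: bool | None = None


def read_element_table(path: str | Path) -> list[ElementRecord]:
    """Read a table produced by :func:`write_element_table` (lossless round-trip)."""
    path = Path(path)
    rows: list[ElementRecord] = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != len(_ELEMENT_TABLE_COLUMNS):
                raise ParseError(
                    f"{path}:{line_no}: expected {len(_ELEMENT_TABLE_COLUMNS)} "
                    f"columns, got {len(f)}"
                )
            rows.append(ElementRecord(
                contig=f[0], start=int(f[1]), end=int(f[2]), name=f[3],
                family=None if f[4] == "." else f[4],
                tsd=None if f[5] == "." else f[5],
                tir_length=None if f[6] == "." else int(f[6]),
                tir_mismatches=None if f[7] == "." else int(f[7]),
                intact=None if f[8] == "." else bool(int(f[8])),
            ))
    return rows
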