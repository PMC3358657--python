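"""Readers and writers for the pipeline's on-disk formats.

Coordinate contract shared by every module in this package: all in-memory
coordinates are 0-based, half-open ``[start, end)``.  SAM's 1-based POS is
converted on read; BED is passed through unchanged (it is already 0-based
half-open).  Alignments are treated as ungapped blocks whose length equals
the query length — profiles are built on single-exon genes from short
reads, so spliced/indel CIGARs are rejected (and counted) rather than
interpreted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")


class ParseError(ValueError):
    """Malformed input file; ``line`` is the 1-based offending line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = f"{path}:{line}: " if line is not None else (f"{path}: " if path else "")
        super().__init__(f"{loc}{message}")
        self.path = path
        self.line = line


@dataclass(frozen=True)
class Genome:
    """A reference genome: chromosome name -> uppercase A/C/G/T/N string."""

    sequences: Mapping[str, str]

    def __post_init__(self):
        for name, seq in self.sequences.items():
            if not name:
                raise ValueError("empty chromosome name")
            bad = set(seq) - _VALID_BASES
            if bad:
                raise ValueError(
                    f"chromosome {name!r} contains illegal characters {sorted(bad)}"
                )

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences


@dataclass(frozen=True)
class GeneModel:
    """A single-exon gene interval, 0-based half-open, with strand."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    single_exon: bool = True

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ExperimentMeta:
    """One sequencing experiment: producing lab, platform, assay, read length."""

    experiment_id: str
    lab: str
    platform: str = "Illumina"
    assay: str = "RNA"
    read_length: int = 50
    alignment_path: str | None = None

    def __post_init__(self):
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")


@dataclass(frozen=True)
class AlignedRead:
    """A uniquely mapped read, reduced to an ungapped genomic block."""

    chrom: str
    start: int
    length: int
    strand: str = "+"
    unique: bool = True

    def __post_init__(self):
        if self.start < 0 or self.length < 1:
            raise ValueError("invalid read coordinates")

    @property
    def end(self) -> int:
        return self.start + self.length


def read_fasta(path) -> Genome:
    """Parse a FASTA file into a :class:`Genome`.

    Sequences are uppercased and line breaks removed.  Duplicate headers,
    headerless sequence, and characters outside A/C/G/T/N raise
    :class:`ParseError` naming the offending line.
    """
    sequences: dict[str, list[str]] = {}
    current: str | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise ParseError("empty FASTA header", path, lineno)
                if name in sequences:
                    raise ParseError(f"duplicate FASTA header {name!r}", path, lineno)
                sequences[name] = []
                current = name
            else:
                if current is None:
                    raise ParseError("sequence before first header", path, lineno)
                chunk = line.upper()
                bad = set(chunk) - _VALID_BASES
                if bad:
                    raise ParseError(
                        f"illegal sequence characters {sorted(bad)}", path, lineno
                    )
                sequences[current].append(chunk)
    return Genome({name: "".join(parts) for name, parts in sequences.items()})


def write_fasta(genome: Genome, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_bed(path) -> list[GeneModel]:
    """Parse a BED6 file of single-exon genes (0-based half-open, native BED)."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(
                    f"expected 6 BED columns, found {len(fields)}", path, lineno
                )
            chrom, start_s, end_s, name, _score, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError("non-integer coordinates", path, lineno) from None
            if start >= end:
                raise ParseError(
                    f"empty or inverted interval [{start}, {end})", path, lineno
                )
            if strand not in ("+", "-"):
                raise ParseError(f"unknown strand symbol {strand!r}", path, lineno)
            genes.append(GeneModel(name, chrom, start, end, strand, single_exon=True))
    return genes


def write_bed(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


# CIGAR ops compatible with the ungapped-block model: M, =, X.
_BLOCK_OPS = {0, 7, 8}  # pysam numeric codes for M, =, X


def read_alignments(
    path,
    meta: ExperimentMeta | None = None,
    genome: Genome | None = None,
    *,
    return_stats: bool = False,
):
    """Read uniquely mapped reads from a SAM file.

    Unmapped records are dropped.  A record is non-unique when its NH tag
    reports more than one hit, or when the same read name appears in more
    than one mapped record; non-unique reads are excluded entirely,
    matching the convention of discarding multi-mappers before coverage.
    Records whose CIGAR contains anything but M/=/X (indels, splices,
    clips) are rejected and counted.  SAM's 1-based POS becomes a 0-based
    start; the block length is the query sequence length.
    """
    stats = {
        "records": 0,
        "unmapped": 0,
        "multimapper": 0,
        "cigar_rejected": 0,
        "kept": 0,
    }
    mapped: list[tuple[str, str, int, int, str]] = []  # (name, chrom, start, len, strand)
    name_hits: dict[str, int] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            stats["records"] += 1
            if rec.is_unmapped:
                stats["unmapped"] += 1
                continue
            if rec.cigartuples and any(op not in _BLOCK_OPS for op, _ in rec.cigartuples):
                stats["cigar_rejected"] += 1
                continue
            nh = rec.get_tag("NH") if rec.has_tag("NH") else None
            if nh is not None and nh > 1:
                stats["multimapper"] += 1
                name_hits[rec.query_name] = name_hits.get(rec.query_name, 0) + 2
                continue
            length = rec.query_length or rec.infer_query_length() or 0
            if length < 1:
                stats["cigar_rejected"] += 1
                continue
            name_hits[rec.query_name] = name_hits.get(rec.query_name, 0) + 1
            strand = "-" if rec.is_reverse else "+"
            mapped.append(
                (rec.query_name, rec.reference_name, rec.reference_start, length, strand)
            )
    reads: list[AlignedRead] = []
    for name, chrom, start, length, strand in mapped:
        if name_hits[name] > 1:
            stats["multimapper"] += 1
            continue
        if genome is not None:
            if chrom not in genome:
                raise ValueError(f"read {name}: unknown chromosome {chrom!r}")
            if start + length > genome.length(chrom):
                raise ValueError(
                    f"read {name}: interval [{start}, {start + length}) exceeds "
                    f"{chrom} length {genome.length(chrom)}"
                )
        reads.append(AlignedRead(chrom, start, length, strand))
    stats["kept"] = len(reads)
    if stats["cigar_rejected"]:
        logger.warning(
            "%s: rejected %d records with non-block CIGAR ops", path,
            stats["cigar_rejected"],
        )
    if return_stats:
        return reads, stats
    return reads


def write_bedgraph(values: Sequence[float], chrom: str, path, *, header: str | None = None) -> None:
    """Write per-position values as a BedGraph track.

    Runs of equal adjacent values are collapsed into single half-open
    intervals.  ``values[i]`` is the value at 0-based position ``i``.
    """
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        n = len(values)
        i = 0
        while i < n:
            j = i + 1
            while j < n and values[j] == values[i]:
                j += 1
            fh.write(f"{chrom}\t{i}\t{j}\t{values[i]:g}\n")
            i = j


_META_COLUMNS = ["experiment_id", "lab", "platform", "assay", "read_length", "alignment_path"]


def read_metadata(path, *, resolve_paths: bool = False) -> list[ExperimentMeta]:
    """Read the experiment metadata TSV (header: experiment_id, lab, platform,
    assay, read_length, alignment_path).

    With ``resolve_paths``, relative alignment paths are resolved against
    the metadata file's directory.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = set(_META_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"metadata missing columns {sorted(missing)}", path)
    base = Path(path).parent

    def _resolve(p):
        if not resolve_paths or p is None or Path(p).is_absolute():
            return p
        return str(base / p)

    metas = [
        ExperimentMeta(
            experiment_id=row.experiment_id,
            lab=row.lab,
            platform=row.platform,
            assay=row.assay,
            read_length=int(row.read_length),
            alignment_path=_resolve(row.alignment_path),
        )
        for row in df.itertuples()
    ]
    ids = [m.experiment_id for m in metas]
    if len(set(ids)) != len(ids):
        raise ParseError("duplicate experiment_id in metadata", path)
    return metas


def write_metadata(metas: Iterable[ExperimentMeta], path) -> None:
    df = pd.DataFrame(
        [
            {
                "experiment_id": m.experiment_id,
                "lab": m.lab,
                "platform": m.platform,
                "assay": m.assay,
                "read_length": m.read_length,
                "alignment_path": m.alignment_path,
            }
            for m in metas
        ],
        columns=_META_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)
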