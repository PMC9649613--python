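"""Readers and writers for every external format the pipeline touches.

All genomic intervals are 0-based half-open throughout the package: rMATS
``*_0base`` columns are 0-based starts, end columns are exclusive, and BED
peaks follow the BED convention.  ``NA`` and empty fields map to missing;
any other non-numeric token is an error (fail loudly on dialect drift).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """A file does not match the declared dialect (e.g. missing column)."""


class ParseError(ValueError):
    """A field inside an otherwise well-formed file failed to parse."""


EVENT_TYPES = ("SE", "A3SS", "A5SS", "MXE", "RI")

#: Per-type coordinate column names, in the order they are stored in
#: :attr:`RmatsRow.coords`.
COORD_COLUMNS: dict[str, tuple[str, ...]] = {
    "SE": (
        "exonStart_0base", "exonEnd",
        "upstreamES", "upstreamEE",
        "downstreamES", "downstreamEE",
    ),
    "A3SS": (
        "longExonStart_0base", "longExonEnd",
        "shortES", "shortEE",
        "flankingES", "flankingEE",
    ),
    "A5SS": (
        "longExonStart_0base", "longExonEnd",
        "shortES", "shortEE",
        "flankingES", "flankingEE",
    ),
    "MXE": (
        "1stExonStart_0base", "1stExonEnd",
        "2ndExonStart_0base", "2ndExonEnd",
        "upstreamES", "upstreamEE",
        "downstreamES", "downstreamEE",
    ),
    "RI": (
        "riExonStart_0base", "riExonEnd",
        "upstreamES", "upstreamEE",
        "downstreamES", "downstreamEE",
    ),
}

SHARED_COLUMNS = (
    "ID", "GeneID", "geneSymbol", "chr", "strand",
    "IJC_SAMPLE_1", "SJC_SAMPLE_1", "IJC_SAMPLE_2", "SJC_SAMPLE_2",
    "IncFormLen", "SkipFormLen", "PValue", "FDR",
    "IncLevel1", "IncLevel2", "IncLevelDifference",
)


@dataclass
class RmatsRow:
    """One line of an rMATS junction-count (JC) output table."""

    event_type: str
    event_id: str
    gene_id: str
    gene_symbol: str
    chrom: str
    strand: str
    coords: tuple[int, ...]
    ijc_s1: list[int]
    sjc_s1: list[int]
    ijc_s2: list[int]
    sjc_s2: list[int]
    inc_form_len: int
    skip_form_len: int
    pvalue: float | None
    fdr: float | None
    inc_level_1: list[float | None]
    inc_level_2: list[float | None]
    inc_level_difference: float | None

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        if len(self.coords) != len(COORD_COLUMNS[self.event_type]):
            raise ValueError(
                f"{self.event_type} expects "
                f"{len(COORD_COLUMNS[self.event_type])} coordinates, "
                f"got {len(self.coords)}"
            )
        if any(c < 0 for c in self.coords):
            raise ValueError("negative coordinate")
        for s, e in zip(self.coords[::2], self.coords[1::2]):
            if not s < e:
                raise ValueError(f"interval start {s} not below end {e}")
        if self.inc_form_len <= 0 or self.skip_form_len <= 0:
            raise ValueError("form lengths must be positive")
        if len(self.ijc_s1) != len(self.sjc_s1) or len(self.ijc_s2) != len(self.sjc_s2):
            raise ValueError("replicate list lengths differ within a group")
        if len(self.inc_level_1) != len(self.ijc_s1) or len(self.inc_level_2) != len(self.ijc_s2):
            raise ValueError("inclusion-level list length differs from count lists")


@dataclass
class PeakRecord:
    """One eCLIP peak (BED 0-based half-open) with its signal statistics."""

    chrom: str
    start: int
    end: int
    rbp_name: str
    cell_line: str
    strand: str
    log2_fold_change: float
    neg_log10_p: float

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ParseError(f"negative coordinate {self.start}")
        if not self.start < self.end:
            raise ParseError(f"peak start {self.start} not below end {self.end}")


@dataclass
class PeakSchema:
    """Column layout of a BED-like peak file (0-based column indices).

    eCLIP narrowPeak dialects vary in where they put the signal columns,
    so the mapping is explicit configuration rather than a guess.
    """

    lfc_col: int = 6
    p_col: int = 7
    name_col: int = 3
    strand_col: int = 5


@dataclass
class GeneCounts:
    """Gene-level read counts across samples, with the transcript length."""

    gene_id: str
    length_bp: int
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError("gene length must be positive")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative count")


# ---------------------------------------------------------------------------
# field-level parsing helpers


def _parse_float_or_missing(token: str, line_no: int, col: str) -> float | None:
    token = token.strip()
    if token in ("NA", ""):
        return None
    try:
        return float(token)
    except ValueError:
        raise ParseError(f"line {line_no}: column {col}: not a number: {token!r}")


def _parse_int_list(token: str, line_no: int, col: str) -> list[int]:
    out = []
    for part in str(token).split(","):
        part = part.strip()
        try:
            value = int(part)
        except ValueError:
            raise ParseError(
                f"line {line_no}: column {col}: count field not an integer: {part!r}"
            )
        if value < 0:
            raise ParseError(f"line {line_no}: column {col}: negative count {value}")
        out.append(value)
    return out


def _parse_level_list(token: str, line_no: int, col: str) -> list[float | None]:
    return [
        _parse_float_or_missing(part, line_no, col)
        for part in str(token).split(",")
    ]


# ---------------------------------------------------------------------------
# rMATS tables


def read_rmats_table(path: str | Path, event_type: str) -> list[RmatsRow]:
    """Read one per-type rMATS JC table into :class:`RmatsRow` records.

    Coordinates are kept exactly as printed (no shifting); comma-separated
    replicate fields are split into lists; literal ``NA`` maps to missing.
    """
    if event_type not in EVENT_TYPES:
        raise ValueError(f"unknown event type {event_type!r}")
    coord_cols = COORD_COLUMNS[event_type]
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file (no header)")
        index = {name: i for i, name in enumerate(header)}
        for col in (*SHARED_COLUMNS, *coord_cols):
            if col not in index:
                raise FormatError(f"{path}: missing mandatory column {col!r}")
        rows: list[RmatsRow] = []
        for line_no, fields in enumerate(reader, start=2):
            if not fields or (len(fields) == 1 and not fields[0].strip()):
                continue

            def get(col: str) -> str:
                return fields[index[col]]

            try:
                coords = tuple(int(get(c)) for c in coord_cols)
            except ValueError:
                raise ParseError(f"line {line_no}: non-integer coordinate")
            rows.append(
                RmatsRow(
                    event_type=event_type,
                    event_id=get("ID"),
                    gene_id=get("GeneID").strip('"'),
                    gene_symbol=get("geneSymbol").strip('"'),
                    chrom=get("chr"),
                    strand=get("strand"),
                    coords=coords,
                    ijc_s1=_parse_int_list(get("IJC_SAMPLE_1"), line_no, "IJC_SAMPLE_1"),
                    sjc_s1=_parse_int_list(get("SJC_SAMPLE_1"), line_no, "SJC_SAMPLE_1"),
                    ijc_s2=_parse_int_list(get("IJC_SAMPLE_2"), line_no, "IJC_SAMPLE_2"),
                    sjc_s2=_parse_int_list(get("SJC_SAMPLE_2"), line_no, "SJC_SAMPLE_2"),
                    inc_form_len=int(get("IncFormLen")),
                    skip_form_len=int(get("SkipFormLen")),
                    pvalue=_parse_float_or_missing(get("PValue"), line_no, "PValue"),
                    fdr=_parse_float_or_missing(get("FDR"), line_no, "FDR"),
                    inc_level_1=_parse_level_list(get("IncLevel1"), line_no, "IncLevel1"),
                    inc_level_2=_parse_level_list(get("IncLevel2"), line_no, "IncLevel2"),
                    inc_level_difference=_parse_float_or_missing(
                        get("IncLevelDifference"), line_no, "IncLevelDifference"
                    ),
                )
            )
    return rows


def _fmt_level(value: float | None) -> str:
    return "NA" if value is None else f"{value:.3f}"


def _fmt_stat(value: float | None) -> str:
    return "NA" if value is None else repr(float(value))


def write_rmats_table(rows: Sequence[RmatsRow], path: str | Path, event_type: str) -> None:
    """Write records back out in the rMATS JC dialect (round-trip partner)."""
    coord_cols = COORD_COLUMNS[event_type]
    header = (
        ["ID", "GeneID", "geneSymbol", "chr", "strand"]
        + list(coord_cols)
        + [
            "ID.1",  # rMATS repeats the ID before the count block
            "IJC_SAMPLE_1", "SJC_SAMPLE_1", "IJC_SAMPLE_2", "SJC_SAMPLE_2",
            "IncFormLen", "SkipFormLen", "PValue", "FDR",
            "IncLevel1", "IncLevel2", "IncLevelDifference",
        ]
    )
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        for row in rows:
            if row.event_type != event_type:
                raise ValueError("row event type does not match table type")
            writer.writerow(
                [row.event_id, f'"{row.gene_id}"', f'"{row.gene_symbol}"',
                 row.chrom, row.strand]
                + list(row.coords)
                + [
                    row.event_id,
                    ",".join(str(c) for c in row.ijc_s1),
                    ",".join(str(c) for c in row.sjc_s1),
                    ",".join(str(c) for c in row.ijc_s2),
                    ",".join(str(c) for c in row.sjc_s2),
                    row.inc_form_len, row.skip_form_len,
                    _fmt_stat(row.pvalue), _fmt_stat(row.fdr),
                    ",".join(_fmt_level(v) for v in row.inc_level_1),
                    ",".join(_fmt_level(v) for v in row.inc_level_2),
                    _fmt_level(row.inc_level_difference),
                ]
            )


# ---------------------------------------------------------------------------
# peaks


def read_peaks(
    path: str | Path,
    schema: PeakSchema | None = None,
    rbp_name: str | None = None,
    cell_line: str = "",
) -> list[PeakRecord]:
    """Read a BED6+ peak file; coordinates are 0-based half-open.

    ``rbp_name`` overrides the name column (manifest-driven naming); when
    absent the name column supplies it.
    """
    schema = schema or PeakSchema()
    peaks: list[PeakRecord] = []
    with open(path, newline="") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            for col in (schema.lfc_col, schema.p_col):
                if col >= len(fields):
                    raise FormatError(
                        f"{path}: line {line_no}: schema column {col} out of range "
                        f"({len(fields)} fields)"
                    )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(f"line {line_no}: non-integer coordinate")
            if start < 0:
                raise ParseError(f"line {line_no}: negative coordinate {start}")
            name = fields[schema.name_col] if schema.name_col < len(fields) else "."
            strand = fields[schema.strand_col] if schema.strand_col < len(fields) else "."
            lfc = _parse_float_or_missing(fields[schema.lfc_col], line_no, "log2FC")
            p = _parse_float_or_missing(fields[schema.p_col], line_no, "-log10P")
            if lfc is None or p is None:
                raise ParseError(f"line {line_no}: missing signal value")
            peaks.append(
                PeakRecord(
                    chrom=fields[0], start=start, end=end,
                    rbp_name=rbp_name if rbp_name is not None else name,
                    cell_line=cell_line, strand=strand,
                    log2_fold_change=lfc, neg_log10_p=p,
                )
            )
    return peaks


def write_peaks(peaks: Iterable[PeakRecord], path: str | Path) -> None:
    """Write peaks as BED6+2 (name, score=0, strand, log2FC, -log10P)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for p in peaks:
            writer.writerow(
                [p.chrom, p.start, p.end, p.rbp_name, 0, p.strand,
                 repr(float(p.log2_fold_change)), repr(float(p.neg_log10_p))]
            )


def read_peak_manifest(path: str | Path) -> pd.DataFrame:
    """Manifest table with columns ``file``, ``rbp_name``, ``cell_line``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("file", "rbp_name", "cell_line"):
        if col not in df.columns:
            raise FormatError(f"{path}: manifest missing column {col!r}")
    return df


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into ``{contig: uppercase sequence}``.

    The contig name is the header token before the first whitespace.
    Duplicate contig names and empty sequences are errors.
    """
    genome: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in genome:
            raise FormatError(f"{path}: duplicate contig name {record.id!r}")
        seq = str(record.seq).upper()
        if not seq:
            raise FormatError(f"{path}: empty sequence for contig {record.id!r}")
        genome[record.id] = seq
    return genome


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# gene counts and annotation boundaries


def read_gene_counts(path: str | Path) -> pd.DataFrame:
    """Gene count table: gene_id, length, one integer column per sample.

    Returns a DataFrame indexed by gene_id with a ``length`` column followed
    by the sample columns.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "length" not in df.columns:
        raise FormatError(f"{path}: missing mandatory column 'length'")
    if (df["length"] <= 0).any():
        raise ParseError(f"{path}: non-positive gene length")
    return df


def write_gene_counts(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def gene_counts_records(df: pd.DataFrame) -> list[GeneCounts]:
    """Explode a counts DataFrame into per-gene :class:`GeneCounts` records."""
    samples = [c for c in df.columns if c != "length"]
    return [
        GeneCounts(
            gene_id=str(gene),
            length_bp=int(row["length"]),
            counts={s: int(row[s]) for s in samples},
        )
        for gene, row in df.iterrows()
    ]


def read_boundary_set(path: str | Path) -> set[tuple[str, int]]:
    """Annotation exon-boundary list: tab-separated chrom, pos, side, strand.

    The returned set keys on (chrom, pos); side/strand columns are carried in
    the file for provenance but splice-site novelty is positional.
    """
    boundaries: set[tuple[str, int]] = set()
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("chrom\t"):
            raise FormatError(f"{path}: missing boundary header")
        for line_no, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            try:
                boundaries.add((fields[0], int(fields[1])))
            except (IndexError, ValueError):
                raise ParseError(f"line {line_no}: malformed boundary line")
    return boundaries


def write_boundary_set(
    boundaries: Iterable[tuple[str, int, str, str]], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["chrom", "pos", "side", "strand"])
        for row in sorted(boundaries):
            writer.writerow(row)
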