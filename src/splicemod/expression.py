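"""Gene-expression normalization (RPKM) and novel-exon consequence math.

RPKM = counts * 1e9 / (gene length in bp * total mapped reads in the
sample); the depth denominator defaults to the sum of assigned gene
counts per sample.  The consequence arithmetic captures what inserting a
novel exon does to a transcript: amplicon length across the flanking
primers grows by the exon length, the reading frame shifts unless the
exon length is a multiple of 3, and in-frame stop codons can be counted
when the exon sequence and incoming frame are known.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneCounts

logger = logging.getLogger(__name__)

STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass
class ExpressionRecord:
    gene_id: str
    rpkm: dict[str, float]
    log2_ratio: dict[str, float] = field(default_factory=dict)


@dataclass
class NovelExonConsequence:
    exon_length_nt: int
    frameshift: bool
    stop_codons_in_frame: int | None
    excluded_amplicon_bp: int
    included_amplicon_bp: int


def rpkm(
    counts: GeneCounts, total_mapped: Mapping[str, int]
) -> ExpressionRecord:
    """Reads per kilobase of transcript per million mapped reads."""
    values: dict[str, float] = {}
    for sample, c in counts.counts.items():
        total = total_mapped[sample]
        if total <= 0:
            raise ValueError(f"sample {sample}: zero total mapped reads")
        values[sample] = c * 1e9 / (counts.length_bp * total)
    return ExpressionRecord(gene_id=counts.gene_id, rpkm=values)


def rpkm_table(
    counts: pd.DataFrame, total_mapped: Mapping[str, int] | None = None
) -> pd.DataFrame:
    """Vectorized RPKM over a gene x sample count table with a ``length``
    column.  When ``total_mapped`` is omitted, per-sample assigned-read
    sums serve as the depth denominator."""
    samples = [c for c in counts.columns if c != "length"]
    mat = counts[samples].to_numpy(dtype=float)
    lengths = counts["length"].to_numpy(dtype=float)
    if total_mapped is None:
        totals = mat.sum(axis=0)
    else:
        totals = np.array([total_mapped[s] for s in samples], dtype=float)
    if np.any(totals <= 0):
        raise ValueError("zero total mapped reads in a sample")
    values = mat * 1e9 / (lengths[:, None] * totals[None, :])
    return pd.DataFrame(values, index=counts.index, columns=samples)


def log2_ratio_table(
    rpkm_df: pd.DataFrame,
    comparisons: Mapping[str, tuple[Sequence[str], Sequence[str]]],
) -> pd.DataFrame:
    """Per-gene log2(mean RPKM treated / mean RPKM vehicle) per comparison.

    The ratio is defined only when both group means are positive; other
    cells are NaN.
    """
    out = {}
    for label, (treated, vehicle) in comparisons.items():
        num = rpkm_df[list(treated)].mean(axis=1)
        den = rpkm_df[list(vehicle)].mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(
                (num > 0) & (den > 0), np.log2(num / den), np.nan
            )
        out[label] = pd.Series(ratio, index=rpkm_df.index)
    return pd.DataFrame(out)


def consistent_direction_genes(
    ratios: pd.DataFrame,
) -> tuple[set[str], set[str]]:
    """Genes whose log2 ratio carries the same strict sign in every
    comparison column: (consistently up, consistently down).  Genes with a
    missing ratio are excluded with a warning."""
    missing = ratios.index[ratios.isna().any(axis=1)]
    for gene in missing:
        logger.warning("gene %s missing a log2 ratio; excluded", gene)
    clean = ratios.dropna()
    up = set(clean.index[(clean > 0).all(axis=1)].astype(str))
    down = set(clean.index[(clean < 0).all(axis=1)].astype(str))
    return up, down


def count_inframe_stops(sequence: str, frame_offset: int = 0) -> int:
    """Stop codons in the reading frame entering the exon.

    ``frame_offset`` is the number of bases carried over from the upstream
    exon into the first codon, so complete codons start at index
    ``(3 - frame_offset) % 3``.  Codons spanning the exon junctions are
    not evaluated.
    """
    if frame_offset not in (0, 1, 2):
        raise ValueError("frame offset must be 0, 1 or 2")
    seq = sequence.upper()
    start = (3 - frame_offset) % 3
    return sum(
        1
        for i in range(start, len(seq) - 2, 3)
        if seq[i : i + 3] in STOP_CODONS
    )


def novel_exon_consequence(
    exon_length_nt: int,
    excluded_amplicon_bp: int,
    exon_sequence: str | None = None,
    upstream_frame_offset: int | None = None,
) -> NovelExonConsequence:
    """Transcript-level consequence of inserting a novel exon.

    The included-isoform amplicon equals the excluded-isoform amplicon
    plus the exon length; the exon induces a frameshift iff its length is
    not a multiple of 3.  In-frame stop codons are counted only when both
    the exon sequence and the incoming reading frame are supplied.
    """
    if exon_length_nt <= 0 or excluded_amplicon_bp <= 0:
        raise ValueError("lengths must be positive")
    if exon_sequence is not None and len(exon_sequence) != exon_length_nt:
        raise ValueError(
            f"sequence length {len(exon_sequence)} does not match "
            f"exon length {exon_length_nt}"
        )
    stops = None
    if exon_sequence is not None and upstream_frame_offset is not None:
        stops = count_inframe_stops(exon_sequence, upstream_frame_offset)
    return NovelExonConsequence(
        exon_length_nt=exon_length_nt,
        frameshift=exon_length_nt % 3 != 0,
        stop_codons_in_frame=stops,
        excluded_amplicon_bp=excluded_amplicon_bp,
        included_amplicon_bp=excluded_amplicon_bp + exon_length_nt,
    )
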