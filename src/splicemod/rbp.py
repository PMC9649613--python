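"""eCLIP-based RNA-binding-protein enrichment at splicing events.

A peak is significant when -log10(P) >= 3 and log2(fold change) >= 3
(both inclusive).  An event's region runs from the upstream exon start to
the downstream exon end; an event is "bound" by an RBP when that region
overlaps a significant peak by at least one base.  Enrichment of a
foreground event set against the coverage-passing background is an
upper-tail hypergeometric test; rescued-vs-unrescued binding contrasts use
a two-sided Fisher exact test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree
from scipy.stats import fisher_exact, hypergeom

from .events import SpliceEvent, _norm_chrom
from .io_formats import PeakRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EventRegion:
    """Genomic span tested for peak overlap (0-based half-open)."""

    key: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"region start {self.start} not below end {self.end}")


def event_region(event: SpliceEvent) -> EventRegion:
    start, end = event.region
    return EventRegion(
        key=event.key, chrom=event.chrom, strand=event.strand, start=start, end=end
    )


@dataclass
class RBPEnrichmentRecord:
    rbp_name: str
    N: int        # background events
    K: int        # background events bound
    n: int        # foreground events
    k_bound: int  # foreground events bound
    fold_enrichment: float
    pvalue: float


def filter_peaks(
    peaks: Iterable[PeakRecord],
    min_neg_log10_p: float = 3.0,
    min_log2fc: float = 3.0,
) -> list[PeakRecord]:
    """Keep significant peaks (both thresholds inclusive)."""
    return [
        p
        for p in peaks
        if p.neg_log10_p >= min_neg_log10_p and p.log2_fold_change >= min_log2fc
    ]


def events_bound(
    regions: Sequence[EventRegion],
    peaks: Sequence[PeakRecord],
    stranded: bool = False,
) -> set[str]:
    """Keys of regions overlapping >= 1 bp with >= 1 peak.

    An event counts once regardless of how many peaks hit it.  Strand-aware
    matching is off by default (peaks are intersected by coordinate only).
    """
    trees: dict[str | tuple[str, str], IntervalTree] = {}
    for p in peaks:
        chrom_key = (
            (_norm_chrom(p.chrom), p.strand) if stranded else _norm_chrom(p.chrom)
        )
        trees.setdefault(chrom_key, IntervalTree()).addi(p.start, p.end)
    bound: set[str] = set()
    for region in regions:
        chrom_key = (
            (_norm_chrom(region.chrom), region.strand)
            if stranded
            else _norm_chrom(region.chrom)
        )
        tree = trees.get(chrom_key)
        if tree is not None and tree.overlap(region.start, region.end):
            bound.add(region.key)
    return bound


def rbp_enrichment(
    foreground_keys: set[str],
    background_keys: set[str],
    bound_by_rbp: Mapping[str, set[str]],
) -> list[RBPEnrichmentRecord]:
    """Hypergeometric over-representation of RBP binding in the foreground.

    Per RBP with K background-bound events: P = P(X >= k | N, K, n) with
    N background events, n foreground events and k foreground-bound events;
    fold enrichment = (k/n) / (K/N).  RBPs binding no background event are
    omitted.
    """
    if not background_keys:
        raise ValueError("background must be nonempty")
    if not foreground_keys <= background_keys:
        raise ValueError("foreground must be a subset of the background")
    N = len(background_keys)
    n = len(foreground_keys)
    records = []
    for rbp in sorted(bound_by_rbp):
        bound = bound_by_rbp[rbp]
        K = len(bound & background_keys)
        if K == 0:
            continue
        k = len(bound & foreground_keys)
        p = float(hypergeom.sf(k - 1, N, K, n))
        fold = (k / n) / (K / N) if n else float("nan")
        records.append(
            RBPEnrichmentRecord(
                rbp_name=rbp, N=N, K=K, n=n, k_bound=k,
                fold_enrichment=fold, pvalue=p,
            )
        )
    records.sort(key=lambda r: (r.pvalue, r.rbp_name))
    return records


@dataclass
class BindingContrast:
    """Fisher contrast of RBP binding between two disjoint event classes."""

    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    pvalue: float


def rescued_vs_unrescued_binding(
    rescued: set[str], unrescued: set[str], bound: set[str]
) -> BindingContrast:
    """Two-sided Fisher exact test of binding in rescued vs unrescued events.

    Table rows are (rescued, unrescued), columns (bound, unbound).  An
    empty class yields P = 1 with a warning.
    """
    if rescued & unrescued:
        raise ValueError("rescued and unrescued sets must be disjoint")
    a = len(bound & rescued)
    b = len(rescued) - a
    c = len(bound & unrescued)
    d = len(unrescued) - c
    table = ((a, b), (c, d))
    if not rescued or not unrescued:
        logger.warning("empty event class in binding contrast; P reported as 1")
        return BindingContrast(table=table, odds_ratio=float("nan"), pvalue=1.0)
    odds, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return BindingContrast(table=table, odds_ratio=float(odds), pvalue=float(p))


def export_enrichments(records: Sequence[RBPEnrichmentRecord], path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["rbp", "N", "K", "n", "k", "fold_enrichment", "pvalue"])
        for r in records:
            writer.writerow(
                [r.rbp_name, r.N, r.K, r.n, r.k_bound,
                 f"{r.fold_enrichment:.6g}", f"{r.pvalue:.6g}"]
            )
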