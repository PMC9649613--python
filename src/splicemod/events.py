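"""Canonical splicing-event model, PSI recomputation and filtering.

An event is identified by a key that is a pure function of its type,
chromosome, strand and coordinate tuple, so the identical exon junction
found in separate rMATS analyses maps to the identical key.  Sign
convention for the inclusion-level difference (group 1 mean PSI minus
group 2 mean PSI): a negative value means the exon is *included* in the
target (group 2) condition, a positive value means it is *excluded*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree
from statsmodels.stats.multitest import multipletests

from .io_formats import COORD_COLUMNS, EVENT_TYPES, RmatsRow

logger = logging.getLogger(__name__)

INCLUDED = "included"
EXCLUDED = "excluded"


@dataclass(frozen=True)
class SpliceEvent:
    """One alternative-splicing event with its genomic anatomy."""

    event_type: str
    gene_id: str
    gene_symbol: str
    chrom: str
    strand: str
    coords: tuple[int, ...]
    novel_ss: bool = False

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        expected = len(COORD_COLUMNS[self.event_type])
        if len(self.coords) != expected:
            raise ValueError(
                f"{self.event_type} coordinate tuple must have {expected} "
                f"entries, got {len(self.coords)}"
            )

    @property
    def key(self) -> str:
        return event_key(self)

    @property
    def target_exon(self) -> tuple[int, int]:
        """The exon whose inclusion the PSI refers to (first exon for MXE,
        long exon for A3SS/A5SS, retained region for RI)."""
        return (self.coords[0], self.coords[1])

    @property
    def region(self) -> tuple[int, int]:
        """Full genomic span of the event (upstream exon start to downstream
        exon end, i.e. the min/max over all exon coordinates)."""
        return (min(self.coords), max(self.coords))


def event_key(event: SpliceEvent) -> str:
    """Deterministic canonical key: ``type|chrom|strand|c1-c2-...``."""
    coords = "-".join(str(c) for c in event.coords)
    return f"{event.event_type}|{event.chrom}|{event.strand}|{coords}"


@dataclass
class EventQuant:
    """Per-sample quantification and comparison statistics for one event."""

    event: SpliceEvent
    ijc1: tuple[int, ...]
    sjc1: tuple[int, ...]
    ijc2: tuple[int, ...]
    sjc2: tuple[int, ...]
    inc_levels_1: tuple[float | None, ...]
    inc_levels_2: tuple[float | None, ...]
    inc_form_len: int
    skip_form_len: int
    pvalue: float | None
    fdr: float | None
    inc_level_difference: float | None

    @property
    def key(self) -> str:
        return self.event.key

    @property
    def sample_totals(self) -> tuple[int, ...]:
        """Total junction support (IJC+SJC) per sample, both groups."""
        return tuple(i + s for i, s in zip(self.ijc1, self.sjc1)) + tuple(
            i + s for i, s in zip(self.ijc2, self.sjc2)
        )

    @property
    def direction(self) -> str | None:
        """Included-in-target for negative differences, excluded for positive."""
        if self.inc_level_difference is None:
            return None
        return INCLUDED if self.inc_level_difference < 0 else EXCLUDED


@dataclass
class ComparisonSet:
    """All events quantified in one two-group comparison."""

    label: str
    group1_name: str
    group2_name: str
    events: dict[str, EventQuant] = field(default_factory=dict)

    def add(self, quant: EventQuant) -> None:
        key = quant.key
        if key in self.events:
            raise ValueError(f"duplicate event key {key} in {self.label}")
        self.events[key] = quant

    def __len__(self) -> int:
        return len(self.events)

    def keys(self) -> set[str]:
        return set(self.events)

    def subset(self, keys: Iterable[str]) -> "ComparisonSet":
        keep = set(keys)
        return replace(
            self, events={k: q for k, q in self.events.items() if k in keep}
        )


def quant_from_row(
    row: RmatsRow, boundary_set: set[tuple[str, int]] | None = None
) -> EventQuant:
    """Build an :class:`EventQuant` from a parsed rMATS row.

    When an annotation boundary set is given, the event is flagged novel if
    either target-exon splice site is absent from it.
    """
    event = SpliceEvent(
        event_type=row.event_type,
        gene_id=row.gene_id,
        gene_symbol=row.gene_symbol,
        chrom=row.chrom,
        strand=row.strand,
        coords=row.coords,
    )
    if boundary_set is not None:
        event = replace(event, novel_ss=is_novel(event, boundary_set))
    return EventQuant(
        event=event,
        ijc1=tuple(row.ijc_s1),
        sjc1=tuple(row.sjc_s1),
        ijc2=tuple(row.ijc_s2),
        sjc2=tuple(row.sjc_s2),
        inc_levels_1=tuple(row.inc_level_1),
        inc_levels_2=tuple(row.inc_level_2),
        inc_form_len=row.inc_form_len,
        skip_form_len=row.skip_form_len,
        pvalue=row.pvalue,
        fdr=row.fdr,
        inc_level_difference=row.inc_level_difference,
    )


def comparison_from_rows(
    rows: Iterable[RmatsRow],
    label: str,
    group1_name: str,
    group2_name: str,
    boundary_set: set[tuple[str, int]] | None = None,
) -> ComparisonSet:
    cs = ComparisonSet(label=label, group1_name=group1_name, group2_name=group2_name)
    for row in rows:
        cs.add(quant_from_row(row, boundary_set))
    return cs


def is_novel(event: SpliceEvent, boundary_set: set[tuple[str, int]]) -> bool:
    """An event is novel when a target-exon splice site is unannotated."""
    start, end = event.target_exon
    return (event.chrom, start) not in boundary_set or (
        event.chrom, end
    ) not in boundary_set


# ---------------------------------------------------------------------------
# PSI


def compute_psi(
    ijc: int, sjc: int, inc_form_len: int, skip_form_len: int
) -> float | None:
    """Length-normalized percent-spliced-in from junction counts.

    PSI = (IJC/IncFormLen) / (IJC/IncFormLen + SJC/SkipFormLen); missing
    (None) when no junction read supports either form.
    """
    if ijc < 0 or sjc < 0:
        raise ValueError("junction counts must be non-negative")
    if inc_form_len <= 0 or skip_form_len <= 0:
        raise ValueError("form lengths must be positive")
    if ijc + sjc == 0:
        return None
    inc = ijc / inc_form_len
    skip = sjc / skip_form_len
    return inc / (inc + skip)


# ---------------------------------------------------------------------------
# filters


def coverage_filter(cs: ComparisonSet, min_count: int = 10) -> ComparisonSet:
    """Keep events with at least ``min_count`` junction reads (IJC+SJC) in
    *every* sample of both groups."""
    kept = {
        key: q
        for key, q in cs.events.items()
        if all(t >= min_count for t in q.sample_totals)
    }
    return replace(cs, events=kept)


def significant_events(
    cs: ComparisonSet,
    fdr_max: float = 0.05,
    min_abs_delta: float = 0.1,
) -> ComparisonSet:
    """Keep events with FDR strictly below ``fdr_max`` and |ΔPSI| strictly
    above ``min_abs_delta``.  Events with a missing FDR or difference are
    skipped with a logged warning."""
    kept: dict[str, EventQuant] = {}
    for key, q in cs.events.items():
        if q.fdr is None or q.inc_level_difference is None:
            logger.warning(
                "%s: event %s missing FDR or inclusion difference; skipped",
                cs.label, key,
            )
            continue
        if q.fdr < fdr_max and abs(q.inc_level_difference) > min_abs_delta:
            kept[key] = q
    return replace(cs, events=kept)


def shared_events(a: ComparisonSet, b: ComparisonSet, direction: str) -> set[str]:
    """Keys significant in both comparisons with the stated direction in both."""
    if direction not in (INCLUDED, EXCLUDED):
        raise ValueError(f"direction must be {INCLUDED!r} or {EXCLUDED!r}")
    return {
        key
        for key, q in a.events.items()
        if q.direction == direction
        and key in b.events
        and b.events[key].direction == direction
    }


def overlap_with_intervals(
    events: Sequence[SpliceEvent],
    intervals: Sequence[tuple[str, int, int]],
) -> set[str]:
    """Keys whose target exon overlaps >= 1 bp with any query interval.

    Chromosome naming is normalized across the "chr1"/"1" styles; strand is
    ignored (coordinate overlap only).
    """
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in intervals:
        trees.setdefault(_norm_chrom(chrom), IntervalTree()).addi(start, end)
    hits: set[str] = set()
    for event in events:
        chrom = _norm_chrom(event.chrom)
        tree = trees.get(chrom)
        if tree is None:
            if trees:
                logger.warning(
                    "chromosome %s absent from query intervals; "
                    "event %s counted as non-overlapping",
                    event.chrom, event.key,
                )
            continue
        start, end = event.target_exon
        if tree.overlap(start, end):
            hits.add(event.key)
    return hits


def _norm_chrom(chrom: str) -> str:
    return chrom[3:] if chrom.startswith("chr") else chrom


def recompute_bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted P values (validation utility)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("P values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def export_significant(cs: ComparisonSet, path) -> None:
    """Tab-separated export: key, type, direction, fdr, delta, novel flag."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["key", "event_type", "direction", "fdr", "inc_level_difference", "novel_ss"]
        )
        for key in sorted(cs.events):
            q = cs.events[key]
            writer.writerow(
                [key, q.event.event_type, q.direction, q.fdr,
                 q.inc_level_difference, int(q.event.novel_ss)]
            )
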