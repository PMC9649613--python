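"""Splice-site window extraction and k-mer enrichment.

For each cassette (SE) event the foreground windows straddle the target
exon's 3' splice site (exon start boundary) and 5' splice site (exon end
boundary); the background windows are the corresponding 3' splice site of
the upstream exon and 5' splice site of the downstream exon.  A window
spans ``flank`` bases on each side of the boundary and is reported on the
sense strand, so the splice-site grammar reads left-to-right regardless of
genomic strand.  Enrichment per k-mer is a two-sided Fisher exact test of
pooled foreground vs background occurrence counts.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from scipy.stats import fisher_exact

from .events import SpliceEvent

logger = logging.getLogger(__name__)

THREE_PRIME = "three_prime"
FIVE_PRIME = "five_prime"
FOREGROUND = "foreground"
BACKGROUND = "background"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifWindowConfig:
    """Window geometry: ``flank`` bases each side of a splice-site boundary,
    analysed at the given k-mer sizes.  The default 5-base flank yields a
    10-nt window, the tightest that still fits an 8-mer."""

    flank: int = 5
    k_sizes: tuple[int, ...] = (4, 6, 8)

    def __post_init__(self) -> None:
        if self.flank < 1:
            raise ValueError("flank must be at least 1")
        if not self.k_sizes:
            raise ValueError("at least one k-mer size required")
        if 2 * self.flank < max(self.k_sizes):
            raise ValueError(
                f"window of {2 * self.flank} nt cannot hold a "
                f"{max(self.k_sizes)}-mer"
            )


@dataclass(frozen=True)
class SpliceSiteWindow:
    key: str
    site: str          # three_prime | five_prime
    role: str          # foreground | background
    sequence: str

    def __post_init__(self) -> None:
        if set(self.sequence) - set("ACGTN"):
            raise ValueError(f"non-nucleotide characters in {self.sequence!r}")


@dataclass
class KmerEnrichmentRecord:
    kmer: str
    site: str
    fg_count: int
    fg_total: int
    bg_count: int
    bg_total: int
    odds_ratio: float
    pvalue: float

    @property
    def relative_frequency_fg(self) -> float:
        return self.fg_count / self.fg_total

    @property
    def relative_frequency_bg(self) -> float:
        return self.bg_count / self.bg_total


def _window(genome_seq: str, boundary: int, strand: str, flank: int) -> str | None:
    lo, hi = boundary - flank, boundary + flank
    if lo < 0 or hi > len(genome_seq):
        return None
    seq = genome_seq[lo:hi].upper()
    return reverse_complement(seq) if strand == "-" else seq


def _site_boundaries(event: SpliceEvent) -> dict[tuple[str, str], int]:
    """Genomic boundary position per (site, role) for a cassette exon.

    On the plus strand the 3'SS of an exon sits at its start coordinate and
    the 5'SS at its end; on the minus strand the two swap.  rMATS upstream/
    downstream exons are transcript-oriented, so on the minus strand the
    upstream exon lies at higher genomic coordinates.
    """
    ts, te = event.coords[0], event.coords[1]
    us, ue = event.coords[2], event.coords[3]
    ds, de = event.coords[4], event.coords[5]
    if event.strand == "-":
        return {
            (THREE_PRIME, FOREGROUND): te,
            (FIVE_PRIME, FOREGROUND): ts,
            (THREE_PRIME, BACKGROUND): ue,   # upstream exon's 3'SS
            (FIVE_PRIME, BACKGROUND): ds,    # downstream exon's 5'SS
        }
    return {
        (THREE_PRIME, FOREGROUND): ts,
        (FIVE_PRIME, FOREGROUND): te,
        (THREE_PRIME, BACKGROUND): us,
        (FIVE_PRIME, BACKGROUND): de,
    }


def extract_windows(
    events: Sequence[SpliceEvent],
    genome: Mapping[str, str],
    cfg: MotifWindowConfig = MotifWindowConfig(),
    event_types: tuple[str, ...] = ("SE",),
) -> list[SpliceSiteWindow]:
    """Extract sense-strand splice-site windows for cassette-exon geometries.

    Events whose windows run off a contig end are skipped with a warning;
    a contig absent from the genome is an error.
    """
    windows: list[SpliceSiteWindow] = []
    for event in events:
        if event.event_type not in event_types:
            continue
        if event.chrom not in genome:
            raise KeyError(f"contig {event.chrom!r} absent from genome")
        seq = genome[event.chrom]
        boundaries = _site_boundaries(event)
        extracted = {
            site_role: _window(seq, boundary, event.strand, cfg.flank)
            for site_role, boundary in boundaries.items()
        }
        if any(w is None for w in extracted.values()):
            logger.warning(
                "event %s: window extends beyond contig %s; skipped",
                event.key, event.chrom,
            )
            continue
        for (site, role), w in extracted.items():
            windows.append(
                SpliceSiteWindow(key=event.key, site=site, role=role, sequence=w)
            )
    return windows


def count_kmers(
    windows: Iterable[SpliceSiteWindow] | Iterable[str], k: int
) -> tuple[Counter, int]:
    """Pooled overlapping k-mer occurrence counts across windows.

    k-mers containing N are not counted.  Returns (counts, total counted).
    """
    counts: Counter = Counter()
    total = 0
    for w in windows:
        seq = w if isinstance(w, str) else w.sequence
        if k > len(seq):
            raise ValueError(f"k={k} exceeds window length {len(seq)}")
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            counts[kmer] += 1
            total += 1
    return counts, total


def kmer_enrichment(
    fg_counts: Mapping[str, int],
    fg_total: int,
    bg_counts: Mapping[str, int],
    bg_total: int,
    site: str = "",
) -> list[KmerEnrichmentRecord]:
    """Two-sided Fisher exact test per k-mer, foreground vs background.

    The 2x2 table is [[fg_count, fg_total-fg_count], [bg_count,
    bg_total-bg_count]]; the odds ratio uses a +0.5 continuity correction
    when any cell is zero.  Records are sorted by ascending P then
    descending foreground frequency.
    """
    if fg_total <= 0 or bg_total <= 0:
        raise ValueError("totals must be positive")
    records = []
    for kmer in set(fg_counts) | set(bg_counts):
        a = fg_counts.get(kmer, 0)
        c = bg_counts.get(kmer, 0)
        if a == 0 and c == 0:
            continue
        b = fg_total - a
        d = bg_total - c
        _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
        if min(a, b, c, d) == 0:
            odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        else:
            odds = (a * d) / (b * c)
        records.append(
            KmerEnrichmentRecord(
                kmer=kmer, site=site,
                fg_count=a, fg_total=fg_total,
                bg_count=c, bg_total=bg_total,
                odds_ratio=float(odds), pvalue=float(p),
            )
        )
    records.sort(key=lambda r: (r.pvalue, -r.relative_frequency_fg, r.kmer))
    return records


def site_enrichments(
    windows: Sequence[SpliceSiteWindow],
    cfg: MotifWindowConfig = MotifWindowConfig(),
) -> dict[tuple[str, int], list[KmerEnrichmentRecord]]:
    """Run the full k-mer analysis: per splice site and k-mer size, compare
    foreground windows against background windows."""
    out: dict[tuple[str, int], list[KmerEnrichmentRecord]] = {}
    for site in (THREE_PRIME, FIVE_PRIME):
        fg = [w for w in windows if w.site == site and w.role == FOREGROUND]
        bg = [w for w in windows if w.site == site and w.role == BACKGROUND]
        for k in cfg.k_sizes:
            fg_counts, fg_total = count_kmers(fg, k)
            bg_counts, bg_total = count_kmers(bg, k)
            if fg_total == 0 or bg_total == 0:
                out[(site, k)] = []
                continue
            out[(site, k)] = kmer_enrichment(
                fg_counts, fg_total, bg_counts, bg_total, site=site
            )
    return out


def export_enrichments(
    enrichments: Mapping[tuple[str, int], Sequence[KmerEnrichmentRecord]], path
) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["kmer", "k", "site", "fg_freq", "bg_freq", "odds_ratio", "pvalue"]
        )
        for (site, k), records in enrichments.items():
            for r in records:
                writer.writerow(
                    [r.kmer, k, site,
                     f"{r.relative_frequency_fg:.6g}",
                     f"{r.relative_frequency_bg:.6g}",
                     f"{r.odds_ratio:.6g}", f"{r.pvalue:.6g}"]
                )
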