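"""Quantification of drug-induced reversal ("rescue") of disease splicing.

For every significant disease event (Ctrl-DMSO vs HD-DMSO) detected with
more than ``min_reads`` junction reads in every single sample of both the
vehicle and the drug comparison, the absolute deviation of the HD group
mean PSI from the Ctrl-DMSO group mean PSI is computed under vehicle and
under drug.  An event is rescued when the drug-arm deviation drops
strictly below the 0.1 corridor.  The population-level shift between the
two deviation samples is tested with the two-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import fmean
from typing import Sequence

from scipy.stats import ranksums

from .events import ComparisonSet, EventQuant, EXCLUDED, INCLUDED


@dataclass
class RescueRecord:
    key: str
    direction_in_hd: str
    psi_ctrl_dmso: float
    psi_hd_dmso: float
    psi_hd_drug: float
    abs_diff_dmso: float
    abs_diff_drug: float
    rescued: bool


@dataclass
class RescueSummary:
    n_events: int
    mean_abs_diff_dmso: float
    mean_abs_diff_drug: float
    percent_reduction: float
    rescued_fraction: float
    n_rescued: int
    n_still_included: int
    n_still_excluded: int
    ranksum_statistic: float
    ranksum_p: float


@dataclass
class OverlapReport:
    intersection: set[str]
    jaccard: float
    n_a: int
    n_b: int


def _group_mean_psi(levels: Sequence[float | None]) -> float | None:
    values = [v for v in levels if v is not None]
    return fmean(values) if values else None


def _detected_everywhere(quant: EventQuant, min_reads: int) -> bool:
    return all(t > min_reads for t in quant.sample_totals)


def rescue_records(
    hd_events: ComparisonSet,
    dmso_comparison: ComparisonSet,
    drug_comparison: ComparisonSet,
    rescue_threshold: float = 0.1,
    min_reads: int = 10,
) -> tuple[list[RescueRecord], int]:
    """Build one record per qualifying disease event.

    ``hd_events`` is the significance-called Ctrl-DMSO vs HD-DMSO set;
    ``dmso_comparison`` and ``drug_comparison`` are the full (unfiltered)
    Ctrl-DMSO vs HD-DMSO and Ctrl-DMSO vs HD-drug comparisons supplying the
    per-sample inclusion levels.  Events not detected with strictly more
    than ``min_reads`` junction reads in every sample of both comparisons
    are excluded; the second return value counts them.
    """
    if not dmso_comparison.events or not drug_comparison.events:
        raise ValueError("a condition group is entirely missing")
    records: list[RescueRecord] = []
    n_excluded = 0
    for key in sorted(hd_events.events):
        dmso = dmso_comparison.events.get(key)
        drug = drug_comparison.events.get(key)
        if dmso is None or drug is None:
            n_excluded += 1
            continue
        if not (
            _detected_everywhere(dmso, min_reads)
            and _detected_everywhere(drug, min_reads)
        ):
            n_excluded += 1
            continue
        psi_ctrl = _group_mean_psi(dmso.inc_levels_1)
        psi_hd_dmso = _group_mean_psi(dmso.inc_levels_2)
        psi_hd_drug = _group_mean_psi(drug.inc_levels_2)
        if psi_ctrl is None or psi_hd_dmso is None or psi_hd_drug is None:
            n_excluded += 1
            continue
        abs_dmso = abs(psi_ctrl - psi_hd_dmso)
        abs_drug = abs(psi_ctrl - psi_hd_drug)
        direction = INCLUDED if psi_ctrl - psi_hd_dmso < 0 else EXCLUDED
        records.append(
            RescueRecord(
                key=key,
                direction_in_hd=direction,
                psi_ctrl_dmso=psi_ctrl,
                psi_hd_dmso=psi_hd_dmso,
                psi_hd_drug=psi_hd_drug,
                abs_diff_dmso=abs_dmso,
                abs_diff_drug=abs_drug,
                rescued=abs_drug < rescue_threshold,
            )
        )
    return records, n_excluded


def rescue_summary(records: Sequence[RescueRecord]) -> RescueSummary:
    """Population summary: mean deviations, percent reduction, rescued
    fraction, the pie-chart partition and the rank-sum shift test."""
    if not records:
        raise ValueError("no rescue records")
    dmso = [r.abs_diff_dmso for r in records]
    drug = [r.abs_diff_drug for r in records]
    mean_dmso = fmean(dmso)
    mean_drug = fmean(drug)
    percent_reduction = (
        100.0 * (1.0 - mean_drug / mean_dmso) if mean_dmso > 0 else 0.0
    )
    rescued = [r for r in records if r.rescued]
    # direction of unrescued events re-read from the drug arm: negative
    # Ctrl-minus-HD-drug deviation means the exon is still included in HD
    still_included = sum(
        1
        for r in records
        if not r.rescued and r.psi_ctrl_dmso - r.psi_hd_drug < 0
    )
    still_excluded = len(records) - len(rescued) - still_included
    stat, p = ranksums(dmso, drug)
    return RescueSummary(
        n_events=len(records),
        mean_abs_diff_dmso=mean_dmso,
        mean_abs_diff_drug=mean_drug,
        percent_reduction=percent_reduction,
        rescued_fraction=len(rescued) / len(records),
        n_rescued=len(rescued),
        n_still_included=still_included,
        n_still_excluded=still_excluded,
        ranksum_statistic=float(stat),
        ranksum_p=float(p),
    )


def drug_targets_disease_events(
    hd_keys: set[str], drug_keys: set[str]
) -> OverlapReport:
    """Overlap of disease-associated and directly drug-responsive events."""
    intersection = hd_keys & drug_keys
    union = hd_keys | drug_keys
    return OverlapReport(
        intersection=intersection,
        jaccard=len(intersection) / len(union) if union else 0.0,
        n_a=len(hd_keys),
        n_b=len(drug_keys),
    )


def export_records(records: Sequence[RescueRecord], path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["key", "direction", "abs_diff_dmso", "abs_diff_drug", "rescued"]
        )
        for r in records:
            writer.writerow(
                [r.key, r.direction_in_hd,
                 f"{r.abs_diff_dmso:.6g}", f"{r.abs_diff_drug:.6g}",
                 int(r.rescued)]
            )
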