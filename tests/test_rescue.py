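"""Rescue record arithmetic, summary statistics and invariants."""

import dataclasses

import numpy as np
import pytest

from splicemod import rescue
from splicemod.events import ComparisonSet, EventQuant
from splicemod.rescue import RescueRecord
from tests.test_events import make_event


def quant(event, psi1, psi2, counts=50):
    n1, n2 = len(psi1), len(psi2)
    return EventQuant(
        event=event,
        ijc1=(counts,) * n1, sjc1=(counts,) * n1,
        ijc2=(counts,) * n2, sjc2=(counts,) * n2,
        inc_levels_1=tuple(psi1), inc_levels_2=tuple(psi2),
        inc_form_len=2, skip_form_len=1,
        pvalue=0.001, fdr=0.001,
        inc_level_difference=float(np.mean(psi1) - np.mean(psi2)),
    )


def build_inputs(events_psi, counts=50):
    """events_psi: list of (start, ctrl, hd_dmso, hd_drug) group-mean PSI.

    Returns (hd_significant, dmso_comparison, drug_comparison) with three
    samples per group at exactly the given PSI (no noise).
    """
    hd = ComparisonSet(label="hd", group1_name="Ctrl_DMSO", group2_name="HD_DMSO")
    dmso = ComparisonSet(label="dmso", group1_name="Ctrl_DMSO", group2_name="HD_DMSO")
    drug = ComparisonSet(label="drug", group1_name="Ctrl_DMSO", group2_name="HD_Drug")
    for start, ctrl, hd_dmso, hd_drug in events_psi:
        event = make_event(start, start + 100)
        dmso.add(quant(event, (ctrl,) * 3, (hd_dmso,) * 3, counts))
        drug.add(quant(event, (ctrl,) * 3, (hd_drug,) * 3, counts))
        hd.add(quant(event, (ctrl,) * 3, (hd_dmso,) * 3, counts))
    return hd, dmso, drug


class TestRescueRecords:
    def test_hand_arithmetic(self):
        hd, dmso, drug = build_inputs([(100, 0.8, 0.5, 0.75)])
        (rec,), n_excluded = rescue.rescue_records(hd, dmso, drug)
        assert n_excluded == 0
        assert rec.abs_diff_dmso == pytest.approx(0.3)
        assert rec.abs_diff_drug == pytest.approx(0.05)
        assert rec.rescued
        assert rec.direction_in_hd == "excluded"  # PSI lower in HD

    def test_threshold_is_strict(self):
        hd, dmso, drug = build_inputs([(100, 0.8, 0.5, 0.70)])  # diff exactly 0.10
        (rec,), _ = rescue.rescue_records(hd, dmso, drug)
        assert rec.abs_diff_drug == pytest.approx(0.1)
        assert not rec.rescued

    def test_perfect_reversal_rescued(self):
        hd, dmso, drug = build_inputs([(100, 0.8, 0.5, 0.8)])
        (rec,), _ = rescue.rescue_records(hd, dmso, drug)
        assert rec.abs_diff_drug == 0.0
        assert rec.rescued

    def test_detection_rule_excludes_low_count_events(self):
        # 5+5 = 10 reads per sample: "> 10" is strict, so the event drops out
        hd, dmso, drug = build_inputs([(100, 0.8, 0.5, 0.8)], counts=5)
        records, n_excluded = rescue.rescue_records(hd, dmso, drug)
        assert records == [] and n_excluded == 1

    def test_empty_condition_group_is_error(self):
        hd, dmso, _ = build_inputs([(100, 0.8, 0.5, 0.8)])
        empty = ComparisonSet(label="drug", group1_name="a", group2_name="b")
        with pytest.raises(ValueError):
            rescue.rescue_records(hd, dmso, empty)

    def test_monotone_moving_drug_psi_toward_ctrl_never_unrescues(self):
        base = (100, 0.8, 0.4, 0.72)
        hd, dmso, drug = build_inputs([base])
        (rec,), _ = rescue.rescue_records(hd, dmso, drug)
        assert rec.rescued
        for closer in (0.74, 0.78, 0.8):
            hd2, dmso2, drug2 = build_inputs([(100, 0.8, 0.4, closer)])
            (rec2,), _ = rescue.rescue_records(hd2, dmso2, drug2)
            assert rec2.rescued


class TestRescueSummary:
    def _records(self, pairs):
        return [
            RescueRecord(
                key=f"e{i}", direction_in_hd="included",
                psi_ctrl_dmso=0.5, psi_hd_dmso=0.5 + d1, psi_hd_drug=0.5 + d2,
                abs_diff_dmso=abs(d1), abs_diff_drug=abs(d2),
                rescued=abs(d2) < 0.1,
            )
            for i, (d1, d2) in enumerate(pairs)
        ]

    def test_no_change_under_drug_is_null(self):
        records = self._records([(0.3, 0.3), (0.2, 0.2), (0.4, 0.4)])
        s = rescue.rescue_summary(records)
        assert s.percent_reduction == pytest.approx(0.0)
        assert s.ranksum_p > 0.5

    def test_hand_computed_percent_reduction(self):
        records = self._records([(0.4, 0.3), (0.5, 0.375), (0.3, 0.225)])
        s = rescue.rescue_summary(records)
        assert s.mean_abs_diff_dmso == pytest.approx(0.4)
        assert s.mean_abs_diff_drug == pytest.approx(0.3)
        assert s.percent_reduction == pytest.approx(25.0)

    def test_partition_counts_sum_to_total(self):
        records = self._records([(0.3, 0.01), (0.3, 0.25), (-0.3, -0.2), (0.2, 0.15)])
        s = rescue.rescue_summary(records)
        assert s.n_rescued + s.n_still_included + s.n_still_excluded == s.n_events
        assert s.n_rescued == 1
        assert s.n_still_included == 2  # psi_hd_drug above ctrl
        assert s.n_still_excluded == 1

    def test_summary_invariant_to_event_order(self):
        records = self._records([(0.4, 0.1), (0.3, 0.05), (0.25, 0.2)])
        a = rescue.rescue_summary(records)
        b = rescue.rescue_summary(list(reversed(records)))
        assert a == dataclasses.replace(b)

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            rescue.rescue_summary([])

    def test_inert_drug_rescues_only_events_already_in_corridor(self):
        pairs = [(0.05, 0.05), (0.3, 0.3), (0.08, 0.08), (0.15, 0.15)]
        s = rescue.rescue_summary(self._records(pairs))
        assert s.n_rescued == sum(1 for d1, _ in pairs if abs(d1) < 0.1)


class TestOverlapReport:
    def test_disjoint_sets_have_jaccard_zero(self):
        report = rescue.drug_targets_disease_events({"a"}, {"b"})
        assert report.jaccard == 0.0 and report.intersection == set()

    def test_identical_sets_have_jaccard_one(self):
        report = rescue.drug_targets_disease_events({"a", "b"}, {"a", "b"})
        assert report.jaccard == 1.0

    def test_fixture_overlap_matches_truth_scan(self, fixture_bundle, pipeline_result):
        for cell in fixture_bundle.config.cell_types:
            hd_truth = fixture_bundle.significant[f"{cell}/Ctrl_DMSO_vs_HD_DMSO"]
            drug_truth = set()
            for contrast in (
                "Ctrl_DMSO_vs_Ctrl_Drug", "HD_DMSO_vs_HD_Drug",
            ):
                drug_truth |= fixture_bundle.significant[f"{cell}/{contrast}"]
            report = rescue.drug_targets_disease_events(hd_truth, drug_truth)
            summary = pipeline_result.summary["drug_vs_disease_overlap"][cell]
            assert summary["n_overlap"] == len(report.intersection)
            assert summary["jaccard"] == pytest.approx(report.jaccard, abs=1e-4)


class TestFixtureRescue:
    def test_truth_rescued_events_are_exactly_those_flagged(
        self, fixture_bundle, pipeline_result
    ):
        """On noiseless-enough fixture data the pipeline's rescued set equals
        the generator's planted rescued set, restricted to events that
        qualified for rescue analysis."""
        for cell, records in pipeline_result.rescue_records.items():
            flagged = {r.key for r in records if r.rescued}
            qualifying = {r.key for r in records}
            expected = fixture_bundle.rescued_keys & qualifying
            assert flagged == expected
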