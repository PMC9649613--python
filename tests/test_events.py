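"""Event model, PSI recomputation, coverage/significance filters."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from splicemod import events as ev
from splicemod.events import ComparisonSet, EventQuant, SpliceEvent


def make_event(start=100, end=200, strand="+", chrom="chr1", event_type="SE"):
    if event_type == "SE":
        coords = (start, end, start - 60, start - 20, end + 20, end + 60)
    else:
        raise NotImplementedError
    return SpliceEvent(
        event_type=event_type, gene_id="G", gene_symbol="S",
        chrom=chrom, strand=strand, coords=coords,
    )


def make_quant(
    event=None, ijc1=(20, 20), sjc1=(20, 20), ijc2=(20, 20), sjc2=(20, 20),
    fdr=0.01, delta=-0.3,
):
    event = event or make_event()
    return EventQuant(
        event=event,
        ijc1=tuple(ijc1), sjc1=tuple(sjc1), ijc2=tuple(ijc2), sjc2=tuple(sjc2),
        inc_levels_1=(0.5,) * len(ijc1), inc_levels_2=(0.5,) * len(ijc2),
        inc_form_len=2, skip_form_len=1,
        pvalue=0.001, fdr=fdr, inc_level_difference=delta,
    )


class TestComputePsi:
    @pytest.mark.parametrize(
        "ijc,sjc,ifl,sfl,expected",
        [
            (0, 25, 2, 1, 0.0),
            (25, 0, 2, 1, 1.0),
            (30, 10, 2, 1, 0.6),  # (30/2) / ((30/2) + (10/1))
        ],
    )
    def test_length_normalized_formula(self, ijc, sjc, ifl, sfl, expected):
        assert ev.compute_psi(ijc, sjc, ifl, sfl) == pytest.approx(expected)

    def test_no_reads_is_missing(self):
        assert ev.compute_psi(0, 0, 2, 1) is None

    @pytest.mark.parametrize("bad", [(-1, 5, 2, 1), (5, 5, 0, 1), (5, 5, 2, -2)])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            ev.compute_psi(*bad)

    @settings(max_examples=50, derandomize=True)
    @given(ijc=st.integers(0, 500), sjc=st.integers(0, 500))
    def test_psi_stays_in_unit_interval(self, ijc, sjc):
        psi = ev.compute_psi(ijc, sjc, 2, 1)
        assert psi is None or 0.0 <= psi <= 1.0


class TestEventKey:
    def test_same_coordinates_same_key(self):
        assert make_event().key == make_event().key

    def test_one_base_shift_changes_key(self):
        assert make_event(100, 200).key != make_event(101, 200).key

    def test_random_events_have_distinct_idempotent_keys(self):
        rng = np.random.default_rng(1)
        events = []
        seen_coords = set()
        while len(events) < 100:
            s = int(rng.integers(100, 10_000))
            e = s + int(rng.integers(50, 300))
            if (s, e) in seen_coords:
                continue
            seen_coords.add((s, e))
            events.append(make_event(s, e, strand="+-"[int(rng.integers(2))]))
        keys = {e_.key for e_ in events}
        assert len(keys) == 100
        assert all(ev.event_key(e_) == e_.key for e_ in events)

    def test_wrong_coordinate_arity_rejected(self):
        with pytest.raises(ValueError):
            SpliceEvent(
                event_type="MXE", gene_id="G", gene_symbol="S",
                chrom="chr1", strand="+", coords=(1, 2, 3, 4),
            )


class TestCoverageFilter:
    def _comparison(self, quants):
        cs = ComparisonSet(label="t", group1_name="a", group2_name="b")
        for q in quants:
            cs.add(q)
        return cs

    def test_boundary_total_ten_retained(self):
        q = make_quant(ijc1=(5,), sjc1=(5,), ijc2=(4,), sjc2=(6,))
        assert len(ev.coverage_filter(self._comparison([q]))) == 1

    def test_single_failing_sample_drops_event(self):
        q = make_quant(ijc1=(4, 25), sjc1=(5, 25), ijc2=(25, 25), sjc2=(25, 25))
        assert len(ev.coverage_filter(self._comparison([q]))) == 0

    def test_matches_brute_force_scan_and_is_idempotent(self):
        rng = np.random.default_rng(0)
        quants = []
        for i in range(20):
            counts = rng.integers(0, 20, size=(4, 2))
            quants.append(
                make_quant(
                    event=make_event(1000 + 500 * i, 1200 + 500 * i),
                    ijc1=counts[0], sjc1=counts[1], ijc2=counts[2], sjc2=counts[3],
                )
            )
        cs = self._comparison(quants)
        kept = ev.coverage_filter(cs)
        expected = {
            q.key
            for q in quants
            if all(
                int(i_) + int(s_) >= 10
                for i_, s_ in list(zip(q.ijc1, q.sjc1)) + list(zip(q.ijc2, q.sjc2))
            )
        }
        assert kept.keys() == expected
        assert ev.coverage_filter(kept).keys() == expected


class TestSignificance:
    def _one(self, fdr, delta):
        cs = ComparisonSet(label="t", group1_name="a", group2_name="b")
        cs.add(make_quant(fdr=fdr, delta=delta))
        return ev.significant_events(cs)

    def test_passing_event_labeled_included_in_target(self):
        out = self._one(0.049, -0.11)
        assert len(out) == 1
        (q,) = out.events.values()
        assert q.direction == "included"

    @pytest.mark.parametrize("fdr,delta", [(0.05, 0.5), (0.01, 0.1), (0.01, -0.1)])
    def test_threshold_boundaries_are_strict(self, fdr, delta):
        assert len(self._one(fdr, delta)) == 0

    def test_missing_statistics_skip_with_warning(self, caplog):
        cs = ComparisonSet(label="t", group1_name="a", group2_name="b")
        cs.add(make_quant(fdr=None, delta=-0.5))
        with caplog.at_level("WARNING"):
            out = ev.significant_events(cs)
        assert len(out) == 0
        assert "missing" in caplog.text

    def test_filters_commute_on_retained_set(self):
        rng = np.random.default_rng(3)
        cs = ComparisonSet(label="t", group1_name="a", group2_name="b")
        for i in range(30):
            counts = rng.integers(0, 25, size=(4, 3))
            cs.add(
                make_quant(
                    event=make_event(1000 + 500 * i, 1200 + 500 * i),
                    ijc1=counts[0], sjc1=counts[1], ijc2=counts[2], sjc2=counts[3],
                    fdr=float(rng.uniform(0, 0.1)),
                    delta=float(rng.uniform(-0.4, 0.4)),
                )
            )
        a = ev.significant_events(ev.coverage_filter(cs))
        b = ev.coverage_filter(ev.significant_events(cs))
        assert a.keys() == b.keys()
        # idempotence
        assert ev.significant_events(a).keys() == a.keys()


class TestSharedEvents:
    def _cs(self, specs):
        cs = ComparisonSet(label="t", group1_name="a", group2_name="b")
        for start, delta in specs:
            cs.add(make_quant(event=make_event(start, start + 100), delta=delta))
        return cs

    def test_disjoint_sets_share_nothing(self):
        a = self._cs([(100, -0.3)])
        b = self._cs([(5000, -0.3)])
        assert ev.shared_events(a, b, "included") == set()

    def test_identical_event_same_direction_shared(self):
        a = self._cs([(100, -0.3)])
        b = self._cs([(100, -0.2)])
        assert ev.shared_events(a, b, "included") == a.keys()
        assert ev.shared_events(a, b, "excluded") == set()

    def test_planted_overlap_counted_exactly(self):
        shared = [(1000 + 500 * i, -0.3) for i in range(7)]
        a = self._cs(shared + [(90_000, -0.3), (95_000, 0.3)])
        b = self._cs(shared + [(80_000, -0.3)])
        assert len(ev.shared_events(a, b, "included")) == 7


class TestIntervalOverlap:
    def test_one_base_overlap_counts(self):
        e = make_event(100, 200)
        assert ev.overlap_with_intervals([e], [("chr1", 199, 250)]) == {e.key}

    def test_half_open_adjacency_does_not_count(self):
        e = make_event(100, 200)
        assert ev.overlap_with_intervals([e], [("chr1", 200, 300)]) == set()

    def test_chr_prefix_styles_are_reconciled(self):
        e = make_event(100, 200, chrom="chr1")
        assert ev.overlap_with_intervals([e], [("1", 150, 160)]) == {e.key}

    def test_matches_quadratic_brute_force(self):
        rng = np.random.default_rng(7)
        events = [
            make_event(int(s), int(s) + int(rng.integers(50, 200)))
            for s in rng.integers(100, 5000, size=30)
        ]
        intervals = [
            ("chr1", int(s), int(s) + int(rng.integers(20, 400)))
            for s in rng.integers(100, 5000, size=10)
        ]
        expected = {
            e.key
            for e in events
            if any(
                e.target_exon[0] < iv[2] and iv[1] < e.target_exon[1]
                for iv in intervals
            )
        }
        assert ev.overlap_with_intervals(events, intervals) == expected


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert ev.recompute_bh_fdr([0.01]) == pytest.approx([0.01])

    def test_hand_computed_ladder(self):
        # m=4: adjusted = min over j>=i of p_(j)*m/j = 0.04 for every rank
        assert ev.recompute_bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    def test_equal_inputs_equal_outputs(self):
        out = ev.recompute_bh_fdr([0.2] * 5)
        assert np.allclose(out, 0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ev.recompute_bh_fdr([0.5, 1.5])

    @settings(max_examples=30, derandomize=True)
    @given(
        ps=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40)
    )
    def test_adjusted_values_monotone_in_sorted_p(self, ps):
        adj = ev.recompute_bh_fdr(ps)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert np.all((adj >= np.array(ps) - 1e-12) & (adj <= 1 + 1e-12))
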