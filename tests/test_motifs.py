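"""Splice-site window extraction and k-mer enrichment statistics."""

from math import comb

import numpy as np
import pytest

from splicemod import motifs
from splicemod.motifs import (
    BACKGROUND, FIVE_PRIME, FOREGROUND, THREE_PRIME,
    MotifWindowConfig, SpliceSiteWindow, reverse_complement,
)
from tests.test_events import make_event


def fisher_two_sided_enum(a, b, c, d):
    """Exact two-sided Fisher P by hypergeometric tail enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    denom = comb(r1 + r2, c1)
    p_obs = comb(r1, a) * comb(r2, c) / denom
    total = 0.0
    for aa in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = comb(r1, aa) * comb(r2, c1 - aa) / denom
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(1.0, total)


def _toy_genome(length=400, seed=0):
    rng = np.random.default_rng(seed)
    return {"chr1": "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))}


class TestWindowExtraction:
    def test_plus_strand_windows_straddle_exon_boundaries(self):
        genome = _toy_genome()
        event = make_event(100, 160)  # flanks at [40,80) and [180,220)
        windows = {
            (w.site, w.role): w.sequence
            for w in motifs.extract_windows([event], genome)
        }
        seq = genome["chr1"]
        assert windows[(THREE_PRIME, FOREGROUND)] == seq[95:105]
        assert windows[(FIVE_PRIME, FOREGROUND)] == seq[155:165]
        assert windows[(THREE_PRIME, BACKGROUND)] == seq[35:45]
        assert windows[(FIVE_PRIME, BACKGROUND)] == seq[215:225]

    def test_minus_strand_windows_are_reverse_complements(self):
        genome = _toy_genome()
        plus = {
            (w.site, w.role): w.sequence
            for w in motifs.extract_windows([make_event(100, 160, strand="+")], genome)
        }
        # the transcript-upstream exon of a minus-strand event sits at higher
        # genomic coordinates, so the flanking exons swap roles
        minus_event = make_event(100, 160, strand="-")
        minus = {
            (w.site, w.role): w.sequence
            for w in motifs.extract_windows([minus_event], genome)
        }
        assert minus[(THREE_PRIME, FOREGROUND)] == reverse_complement(
            plus[(FIVE_PRIME, FOREGROUND)]
        )
        assert minus[(FIVE_PRIME, FOREGROUND)] == reverse_complement(
            plus[(THREE_PRIME, FOREGROUND)]
        )

    def test_window_off_contig_start_skips_event_with_warning(self, caplog):
        genome = {"chr1": "ACGTACGTACGTACGTACGT"}
        event = make_event(62, 70)  # upstream exon at [2,42) -> bg window off end
        event = event.__class__(**{**event.__dict__, "coords": (8, 14, 2, 5, 16, 19)})
        with caplog.at_level("WARNING"):
            windows = motifs.extract_windows([event], genome)
        assert windows == []
        assert "skipped" in caplog.text

    def test_missing_contig_is_error(self):
        with pytest.raises(KeyError):
            motifs.extract_windows([make_event(100, 160)], {"chr2": "A" * 300})

    def test_config_rejects_window_smaller_than_kmer(self):
        with pytest.raises(ValueError):
            MotifWindowConfig(flank=3, k_sizes=(4, 8))


class TestKmerCounting:
    def test_overlapping_count_is_length_minus_k_plus_one(self):
        counts, total = motifs.count_kmers(["ACGTACGTAC"], 8)
        assert total == 3
        assert counts == {"ACGTACGT": 1, "CGTACGTA": 1, "GTACGTAC": 1}

    def test_single_kmer_window(self):
        counts, total = motifs.count_kmers(["AAAA"], 4)
        assert counts == {"AAAA": 1} and total == 1

    def test_n_containing_kmers_excluded(self):
        counts, total = motifs.count_kmers(["AANTT"], 2)
        assert counts == {"AA": 1, "TT": 1} and total == 2

    def test_totals_match_naive_scan_on_random_windows(self):
        rng = np.random.default_rng(2)
        windows = [
            "".join("ACGTN"[i] for i in rng.choice(5, size=10, p=[0.24] * 4 + [0.04]))
            for _ in range(100)
        ]
        for k in (4, 6, 8):
            counts, total = motifs.count_kmers(windows, k)
            naive = sum(
                1
                for w in windows
                for i in range(len(w) - k + 1)
                if "N" not in w[i : i + k]
            )
            assert total == naive == sum(counts.values())


class TestEnrichment:
    def test_identical_foreground_background_is_null(self):
        counts = {"ACGT": 5, "TTTT": 3}
        records = motifs.kmer_enrichment(counts, 8, counts, 8)
        assert all(r.pvalue == pytest.approx(1.0) for r in records)
        assert all(r.odds_ratio == pytest.approx(1.0) for r in records)

    def test_fisher_matches_tail_enumeration(self):
        records = motifs.kmer_enrichment({"AAAA": 8}, 100, {"AAAA": 1}, 400)
        rec = next(r for r in records if r.kmer == "AAAA")
        assert rec.pvalue == pytest.approx(fisher_two_sided_enum(8, 92, 1, 399), rel=1e-6)

    def test_zero_cell_gets_continuity_corrected_odds(self):
        (rec,) = motifs.kmer_enrichment({"AAAA": 4}, 10, {}, 10)
        assert rec.odds_ratio == pytest.approx((4.5 * 10.5) / (6.5 * 0.5))

    def test_relative_frequencies_sum_to_one_per_side(self):
        rng = np.random.default_rng(3)
        windows = [
            "".join("ACGT"[i] for i in rng.integers(0, 4, size=10)) for _ in range(50)
        ]
        counts, total = motifs.count_kmers(windows, 4)
        assert sum(c / total for c in counts.values()) == pytest.approx(1.0)

    def test_planted_motif_tops_ranking(self):
        rng = np.random.default_rng(4)
        motif = "AGAGTAAG"
        fg = []
        for _ in range(50):
            w = "".join("ACGT"[i] for i in rng.integers(0, 4, size=10))
            fg.append(w[0] + motif + w[9])
        bg = ["".join("ACGT"[i] for i in rng.integers(0, 4, size=10)) for _ in range(50)]
        fgc, fgt = motifs.count_kmers(fg, 8)
        bgc, bgt = motifs.count_kmers(bg, 8)
        records = motifs.kmer_enrichment(fgc, fgt, bgc, bgt)
        assert records[0].kmer == motif
        assert records[0].pvalue < 1e-10

    def test_strand_symmetry_of_enrichment(self):
        """Reverse-complementing the genome and flipping strands leaves
        every enrichment record invariant."""
        genome = _toy_genome(seed=9)
        events = [make_event(100, 160), make_event(240, 300)]
        flipped_genome = {"chr1": reverse_complement(genome["chr1"])}
        L = len(genome["chr1"])
        flipped_events = []
        for e in events:
            # mirror every exon; the transcript-upstream exon of the flipped
            # minus-strand event is the mirror of the original upstream exon
            ts, te = L - e.coords[1], L - e.coords[0]
            us, ue = L - e.coords[3], L - e.coords[2]
            ds, de = L - e.coords[5], L - e.coords[4]
            flipped_events.append(
                e.__class__(**{**e.__dict__, "strand": "-",
                               "coords": (ts, te, us, ue, ds, de)})
            )
        w_plus = motifs.extract_windows(events, genome)
        w_minus = motifs.extract_windows(flipped_events, flipped_genome)
        for k in (4, 6, 8):
            for site in (THREE_PRIME, FIVE_PRIME):
                for role in (FOREGROUND, BACKGROUND):
                    a, _ = motifs.count_kmers(
                        [w for w in w_plus if w.site == site and w.role == role], k
                    )
                    b, _ = motifs.count_kmers(
                        [w for w in w_minus if w.site == site and w.role == role], k
                    )
                    assert a == b
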