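"""Scanner correctness: mismatch accounting, exhaustiveness, strand symmetry,
12/23 pairing and breakpoint annotation."""

import numpy as np
import pytest

from ragdelscan import rss_scanner as rs
from ragdelscan import synthetic_data as sd
from conftest import random_dna


def naive_scan(seq, max_h=3, max_n=6, require_cac=True):
    """Independent oracle: enumerate every (heptamer, spacer, nonamer)
    window on both strands with explicit loops."""
    found = set()
    for strand, s in (("+", seq), ("-", rs.reverse_complement(seq))):
        L = len(s)
        for cls, spacers in rs.SPACER_CLASSES.items():
            for sp in spacers:
                for i in range(L - (16 + sp) + 1):
                    hept = s[i : i + 7]
                    non = s[i + 7 + sp : i + 16 + sp]
                    if "N" in hept or "N" in non or "N" in s[i + 7 : i + 7 + sp]:
                        continue
                    if require_cac and not hept.startswith("CAC"):
                        continue
                    hm = sum(a != b for a, b in zip(hept, rs.HEPTAMER_CONSENSUS))
                    nm = sum(a != b for a, b in zip(non, rs.NONAMER_CONSENSUS))
                    if hm <= max_h and nm <= max_n:
                        pos = i if strand == "+" else L - i - 7
                        found.add((pos, strand, cls, sp, hm, nm))
    return found


def as_tuples(candidates):
    return {
        (c.heptamer_start, c.strand, c.spacer_class, c.spacer_len,
         c.heptamer_mismatches, c.nonamer_mismatches)
        for c in candidates
    }


class TestMismatchCount:
    @pytest.mark.parametrize(
        "observed,consensus,expected",
        [
            ("CACAGTG", "CACAGTG", 0),
            ("CACTCTG", "CACAGTG", 2),     # hotspot heptamer vs consensus
            ("ACAGAATTG", "ACAAAAACC", 4),  # hotspot nonamer vs consensus
            ("CCAGGACAT", "ACAAAAACC", 6),  # the most diverged breakpoint nonamer
            ("CACTGCA", "CACAGTG", 3),      # the most diverged breakpoint heptamer
        ],
    )
    def test_examples(self, observed, consensus, expected):
        assert rs.mismatch_count(observed, consensus) == expected

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            rs.mismatch_count("CAC", "CACAGTG")


class TestScan:
    def test_embedded_23_rss_recovered(self, rng):
        hep, sp, non = sd.HOTSPOT_MOTIF
        spacer = random_dna(rng, sp)
        bg = random_dna(rng, 200)
        seq = bg[:90] + hep + spacer + non + bg[90:]
        hits = [
            c for c in rs.scan(seq)
            if c.heptamer_start == 90 and c.strand == "+" and c.spacer_len == 23
        ]
        assert len(hits) == 1
        assert hits[0].spacer_class == 23
        assert hits[0].heptamer_mismatches == 2
        assert hits[0].nonamer_mismatches == 4
        assert hits[0].total_score == 2 * 2 + 4

    def test_poly_a_yields_nothing(self):
        assert rs.scan("A" * 500) == []

    def test_minus_strand_consensus(self, rng):
        motif = rs.HEPTAMER_CONSENSUS + random_dna(rng, 12) + rs.NONAMER_CONSENSUS
        bg = random_dna(rng, 300)
        seq = bg[:150] + rs.reverse_complement(motif) + bg[150:]
        exact = [c for c in rs.scan(seq, 12) if c.heptamer_mismatches == 0
                 and c.nonamer_mismatches == 0]
        assert len(exact) == 1
        c = exact[0]
        assert c.strand == "-"
        # minus-strand heptamer occupies the rightmost 7 bp of the motif
        assert c.heptamer_start == 150 + 12 + 9
        assert rs.reverse_complement(seq[c.heptamer_start:c.heptamer_start + 7]) \
            == rs.HEPTAMER_CONSENSUS

    def test_invalid_characters_raise(self):
        with pytest.raises(ValueError):
            rs.scan("ACGTX" * 20)

    def test_n_windows_skipped(self, rng):
        seq = random_dna(rng, 100) + "N" * 5 + random_dna(rng, 100)
        for c in rs.scan(seq):
            lo, hi = c.span
            assert "N" not in seq[lo:hi]

    def test_matches_naive_enumeration(self, rng):
        for _ in range(15):
            seq = random_dna(rng, 800)
            assert as_tuples(rs.scan(seq)) == naive_scan(seq)

    def test_matches_naive_without_cac_anchor(self, rng):
        seq = random_dna(rng, 400)
        got = as_tuples(rs.scan(seq, require_cac=False, max_heptamer_mm=2, max_nonamer_mm=4))
        assert got == naive_scan(seq, max_h=2, max_n=4, require_cac=False)

    def test_strand_symmetry(self, rng):
        for _ in range(10):
            seq = random_dna(rng, 600)
            fwd = as_tuples(rs.scan(seq))
            rev = rs.scan(rs.reverse_complement(seq))
            L = len(seq)
            mirrored = {
                (L - c.heptamer_start - 7, "-" if c.strand == "+" else "+",
                 c.spacer_class, c.spacer_len,
                 c.heptamer_mismatches, c.nonamer_mismatches)
                for c in rev
            }
            assert fwd == mirrored

    def test_threshold_monotonicity(self, rng):
        seq = random_dna(rng, 1000)
        tight = as_tuples(rs.scan(seq, max_heptamer_mm=1, max_nonamer_mm=3))
        loose = as_tuples(rs.scan(seq, max_heptamer_mm=3, max_nonamer_mm=6))
        assert tight <= loose

    def test_sorted_by_score_then_position(self, rng):
        cands = rs.scan(random_dna(rng, 1500))
        keys = [(c.total_score, c.heptamer_start) for c in cands]
        assert keys == sorted(keys)

    def test_recovers_embedded_locus_motifs(self, desk_locus):
        """Every embedded truth motif is found with its true Hamming distances."""
        seq = desk_locus.sequence
        for site in [desk_locus.hotspot_rss, *desk_locus.distal_rss_sites]:
            lo = max(0, site.cleavage_edge - 60)
            hi = site.cleavage_edge + 60
            cands = rs.scan(seq[lo:hi])
            match = [
                c for c in cands
                if c.heptamer_start + lo == site.position
                and c.strand == site.strand
                and c.spacer_len == site.spacer_len
            ]
            assert len(match) == 1, site.label
            c = match[0]
            assert c.heptamer_mismatches == rs.mismatch_count(
                site.heptamer, rs.HEPTAMER_CONSENSUS)
            assert c.nonamer_mismatches == rs.mismatch_count(
                site.nonamer, rs.NONAMER_CONSENSUS)


class TestPairRSS:
    def _candidates(self, desk_locus):
        seq = desk_locus.sequence
        out = {}
        for site in [desk_locus.hotspot_rss, *desk_locus.distal_rss_sites]:
            lo = site.cleavage_edge - 60
            cands = rs.scan(seq[lo : site.cleavage_edge + 60])
            hit = [
                type(c)(**{**c.__dict__, "heptamer_start": c.heptamer_start + lo})
                for c in cands
                if c.heptamer_start + lo == site.position and c.strand == site.strand
                and c.spacer_len == site.spacer_len
            ]
            out[site.label] = hit[0]
        return out

    def test_hotspot_pairs_with_every_distal_site(self, desk_locus):
        cands = self._candidates(desk_locus)
        hotspot = cands.pop("HOTSPOT")
        pairs = rs.pair_rss([hotspot], list(cands.values()))
        assert len(pairs) == len(cands)
        for p in pairs:
            assert {p.proximal.spacer_class, p.distal.spacer_class} == {12, 23}
            start, end = p.predicted_deletion
            assert start == hotspot.cleavage_edge
            assert end in {c.cleavage_edge for c in cands.values()}

    def test_same_class_pairs_rejected(self, desk_locus):
        cands = self._candidates(desk_locus)
        distal = [v for k, v in cands.items() if k != "HOTSPOT"]
        assert rs.pair_rss(distal, distal) == []

    def test_empty_input(self, desk_locus):
        cands = self._candidates(desk_locus)
        assert rs.pair_rss([], list(cands.values())) == []

    def test_wrong_orientation_rejected(self, rng):
        """Two RSSs whose heptamers point away from the segment cannot delete it."""
        plus = rs.CandidateRSS("seq", 100, "+", 23, 23, "CACAGTG", "ACAAAAACC", 0, 0, 0)
        minus_left = rs.CandidateRSS("seq", 20, "-", 12, 12, "CACAGTG", "ACAAAAACC", 0, 0, 0)
        # minus-strand site left of the plus-strand site: heptamers face outward
        assert rs.pair_rss([plus], [minus_left]) == []


class TestAnnotateBreakpoints:
    def test_breakpoint_at_heptamer_edge(self, desk_locus):
        site = desk_locus.hotspot_rss
        lo = site.cleavage_edge - 60
        cands = rs.scan(desk_locus.sequence[lo : site.cleavage_edge + 60])
        shifted = [
            type(c)(**{**c.__dict__, "heptamer_start": c.heptamer_start + lo})
            for c in cands
        ]
        bp = site.cleavage_edge
        best = rs.annotate_breakpoints(shifted, [bp])[bp]
        assert best is not None
        # the winner is the lowest-score candidate within the window,
        # ties broken by distance then leftmost position
        in_range = [c for c in shifted if abs(c.cleavage_edge - bp) <= 50]
        expected = min(
            in_range,
            key=lambda c: (c.total_score, abs(c.cleavage_edge - bp), c.heptamer_start),
        )
        assert best == expected
        # the embedded hotspot motif itself is among the annotated candidates
        assert any(
            c.cleavage_edge == bp and c.strand == site.strand for c in in_range)

    def test_distant_breakpoint_maps_to_none(self, rng):
        c = rs.CandidateRSS("seq", 500, "+", 12, 12, "CACAGTG", "ACAAAAACC", 0, 0, 0)
        assert rs.annotate_breakpoints([c], [100], window=50) == {100: None}

    def test_equal_score_tie_breaks_leftmost(self):
        left = rs.CandidateRSS("seq", 90, "+", 12, 12, "CACAGTG", "ACAAAAACC", 0, 0, 0)
        right = rs.CandidateRSS("seq", 110, "+", 12, 12, "CACAGTG", "ACAAAAACC", 0, 0, 0)
        best = rs.annotate_breakpoints([right, left], [100])[100]
        assert best is left
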