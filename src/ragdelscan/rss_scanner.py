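"""Detection, scoring and 12/23 pairing of (cryptic) recombination signal sequences.

A recombination signal sequence (RSS) is a conserved heptamer (consensus
``CACAGTG``) and nonamer (consensus ``ACAAAAACC``) separated by a poorly
conserved spacer of 12±1 bp (a "12-RSS") or 23±1 bp (a "23-RSS").  The RAG
recombinase nicks at the heptamer/coding-flank border and, per the 12/23
rule, recombines only RSS pairs with unlike spacer classes.  Near-consensus
"cryptic" RSSs outside the antigen-receptor loci can support illegitimate
recombination; when two such sites face each other across a chromosomal
segment, recombination deletes the intervening DNA.

This module scans arbitrary DNA for candidate RSSs on both strands, scores
them by mismatches from consensus (heptamer mismatches weighted double,
because cleavage occurs at the heptamer), pairs candidates under the 12/23
rule in deletion-forming orientation, and maps observed breakpoints to
their nearest candidate.

Coordinates are 0-based half-open on the plus strand throughout.  A
minus-strand candidate's ``heptamer_start`` is the plus-strand offset of
the 7-mer window whose reverse complement is the heptamer in reading
orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

__all__ = [
    "HEPTAMER_CONSENSUS",
    "NONAMER_CONSENSUS",
    "SPACER_CLASSES",
    "CandidateRSS",
    "RSSPair",
    "mismatch_count",
    "reverse_complement",
    "scan",
    "pair_rss",
    "annotate_breakpoints",
]

HEPTAMER_CONSENSUS = "CACAGTG"
NONAMER_CONSENSUS = "ACAAAAACC"

#: Tolerated spacer lengths per class: exactly ±1 bp around 12 and 23.
SPACER_CLASSES: Mapping[int, Tuple[int, ...]] = {12: (11, 12, 13), 23: (22, 23, 24)}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def mismatch_count(observed: str, consensus: str) -> int:
    """Position-wise Hamming distance between two equal-length k-mers."""
    if len(observed) != len(consensus):
        raise ValueError(
            f"length mismatch: observed {len(observed)} vs consensus {len(consensus)}"
        )
    return sum(a != b for a, b in zip(observed, consensus))


@dataclass(frozen=True)
class CandidateRSS:
    """A located heptamer/spacer/nonamer match.

    ``heptamer_seq`` and ``nonamer_seq`` are given in reading orientation
    (i.e. already reverse-complemented for minus-strand candidates).
    """

    contig: str
    heptamer_start: int
    strand: str
    spacer_class: int
    spacer_len: int
    heptamer_seq: str
    nonamer_seq: str
    heptamer_mismatches: int
    nonamer_mismatches: int
    total_score: int

    @property
    def cleavage_edge(self) -> int:
        """Plus-strand position of the heptamer/coding-flank border.

        For a plus-strand RSS the coding flank lies to the left of the
        heptamer; for a minus-strand RSS it lies to the right.
        """
        return self.heptamer_start if self.strand == "+" else self.heptamer_start + 7

    @property
    def span(self) -> Tuple[int, int]:
        """Plus-strand half-open interval occupied by the full motif."""
        if self.strand == "+":
            return (self.heptamer_start, self.heptamer_start + 16 + self.spacer_len)
        return (self.heptamer_start - self.spacer_len - 9, self.heptamer_start + 7)


@dataclass(frozen=True)
class RSSPair:
    """A 12/23-compatible RSS pair in deletion-forming orientation."""

    proximal: CandidateRSS
    distal: CandidateRSS
    orientation_valid: bool
    predicted_deletion: Tuple[int, int]

    @property
    def combined_score(self) -> int:
        return self.proximal.total_score + self.distal.total_score


def _validate_alphabet(seq: str) -> None:
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains non-ACGTN characters: {sorted(bad)!r}")


def _find_anchors(seq: str) -> List[int]:
    """All positions where the heptamer's obligate CAC prefix occurs."""
    out = []
    i = seq.find("CAC")
    while i != -1:
        out.append(i)
        i = seq.find("CAC", i + 1)
    return out


def scan(
    sequence: str,
    spacer_class: int | str = "both",
    max_heptamer_mm: int = 3,
    max_nonamer_mm: int = 6,
    require_cac: bool = True,
    contig: str = "seq",
    heptamer_weight: int = 2,
    nonamer_weight: int = 1,
) -> List[CandidateRSS]:
    """Exhaustively scan both strands for candidate RSSs.

    Every (heptamer, spacer length, nonamer) window on either strand whose
    mismatch counts fall within the thresholds is returned, sorted
    ascending by total score then by position.  Windows containing ``N``
    are skipped; other non-ACGT characters raise.

    The default thresholds (heptamer ≤ 3 mismatches with an obligate CAC,
    nonamer ≤ 6) are the loosest needed to admit every functional cryptic
    RSS documented at breakpoints of this locus class, with zero margin.
    """
    seq = sequence.upper()
    _validate_alphabet(seq)
    if spacer_class == "both":
        classes: Tuple[int, ...] = (12, 23)
    elif spacer_class in SPACER_CLASSES:
        classes = (int(spacer_class),)
    else:
        raise ValueError(f"spacer_class must be 12, 23 or 'both', got {spacer_class!r}")
    min_spacer = min(s for c in classes for s in SPACER_CLASSES[c])
    if len(seq) < 7 + min_spacer + 9:
        raise ValueError("sequence shorter than the minimal RSS window")

    results: List[CandidateRSS] = []
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        L = len(s)
        positions: Iterable[int] = _find_anchors(s) if require_cac else range(L - 6)
        for i in positions:
            hept = s[i : i + 7]
            if len(hept) < 7 or "N" in hept:
                continue
            hm = mismatch_count(hept, HEPTAMER_CONSENSUS)
            if hm > max_heptamer_mm:
                continue
            if require_cac and not hept.startswith("CAC"):
                continue
            for cls in classes:
                for spacer in SPACER_CLASSES[cls]:
                    n0 = i + 7 + spacer
                    non = s[n0 : n0 + 9]
                    if len(non) < 9 or "N" in non or "N" in s[i + 7 : n0]:
                        continue
                    nm = mismatch_count(non, NONAMER_CONSENSUS)
                    if nm > max_nonamer_mm:
                        continue
                    h_start = i if strand == "+" else L - i - 7
                    results.append(
                        CandidateRSS(
                            contig=contig,
                            heptamer_start=h_start,
                            strand=strand,
                            spacer_class=cls,
                            spacer_len=spacer,
                            heptamer_seq=hept,
                            nonamer_seq=non,
                            heptamer_mismatches=hm,
                            nonamer_mismatches=nm,
                            total_score=heptamer_weight * hm + nonamer_weight * nm,
                        )
                    )
    results.sort(
        key=lambda c: (c.total_score, c.heptamer_start, c.strand, c.spacer_len)
    )
    return results


def pair_rss(
    proximal: Sequence[CandidateRSS], distal: Sequence[CandidateRSS]
) -> List[RSSPair]:
    """Pair candidates under the 12/23 rule in deletion-forming orientation.

    A pair is valid iff the spacer classes differ and the two heptamers
    flank the would-be-deleted segment: the left-hand RSS must lie on the
    plus strand and the right-hand RSS on the minus strand, so that both
    nonamers point into the deleted DNA and the coding flanks are retained.
    The predicted deletion runs between the two heptamer cleavage edges.
    """
    pairs: List[RSSPair] = []
    for p in proximal:
        for d in distal:
            if p.spacer_class == d.spacer_class:
                continue
            left, right = (p, d) if p.cleavage_edge <= d.cleavage_edge else (d, p)
            if left.strand != "+" or right.strand != "-":
                continue
            if left.cleavage_edge >= right.cleavage_edge:
                continue
            pairs.append(
                RSSPair(
                    proximal=p,
                    distal=d,
                    orientation_valid=True,
                    predicted_deletion=(left.cleavage_edge, right.cleavage_edge),
                )
            )
    pairs.sort(
        key=lambda pr: (
            pr.combined_score,
            pr.predicted_deletion,
            pr.proximal.heptamer_start,
        )
    )
    return pairs


def annotate_breakpoints(
    candidates: Sequence[CandidateRSS],
    breakpoints: Sequence[int],
    window: int = 50,
) -> Dict[int, Optional[CandidateRSS]]:
    """Map each breakpoint to the best candidate RSS within ``window`` bp.

    "Best" is lowest total score; ties break by distance from the
    candidate's cleavage edge, then by leftmost heptamer position.
    Breakpoints with no candidate in range map to ``None`` — a breakpoint
    genuinely lacking a flanking RSS is a legitimate observation.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    out: Dict[int, Optional[CandidateRSS]] = {}
    for bp in breakpoints:
        best: Optional[CandidateRSS] = None
        best_key: Optional[Tuple[int, int, int]] = None
        for c in candidates:
            dist = abs(c.cleavage_edge - bp)
            if dist > window:
                continue
            key = (c.total_score, dist, c.heptamer_start)
            if best_key is None or key < best_key:
                best, best_key = c, key
        out[bp] = best
    return out
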