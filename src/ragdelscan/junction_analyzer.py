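"""Decomposition and clustering of deletion-spanning junction sequences.

A junction read spans a deletion: it begins in the retained proximal flank
and ends in the retained distal flank.  Between the two anchors there may
be non-templated nucleotides (TdT-added "N-nucleotides", the signature of
a RAG/NHEJ coding joint) or microhomology (short identity shared by both
flanks, which makes the exact cut position ambiguous).

``decompose`` splits a junction against its two reference flanks by greedy
maximal prefix/suffix matching.  When the maximal prefix and suffix
matches overlap, the overlap is reported as microhomology with the
canonical split at the proximal-most position and an empty insertion.
Breakpoint positions from many junctions are grouped into deletion types
by single-linkage clustering, and the minimal window holding a given
fraction of breakpoints quantifies hotspot tightness.

Conventions: ``proximal_break`` is the 0-based offset into the proximal
reference of the first base NOT retained; ``distal_break`` the offset into
the distal reference of the first base retained.  The junction's leading
bases align with the start of the proximal reference, and its trailing
bases with the end of the distal reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from typing import Dict, List, Optional, Sequence, Tuple

__all__ = [
    "JunctionCall",
    "BreakpointCluster",
    "decompose",
    "cluster_breakpoints",
    "hotspot_window",
    "classify_deletion",
    "count_unique_junctions",
    "roman_label",
]

_ROMAN = [
    (1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"),
    (90, "XC"), (50, "L"), (40, "XL"), (10, "X"), (9, "IX"),
    (5, "V"), (4, "IV"), (1, "I"),
]


def roman_label(n: int) -> str:
    """Deletion-type style roman numeral label (1 -> 'I', 8 -> 'VIII')."""
    if n <= 0:
        raise ValueError("label index must be positive")
    out = []
    for value, sym in _ROMAN:
        while n >= value:
            out.append(sym)
            n -= value
    return "".join(out)


@dataclass(frozen=True)
class JunctionCall:
    """Decomposition of one junction sequence.

    ``status`` is "ok" for a resolved call and "unrelated" when neither or
    only one junction end anchors in its reference (e.g. a co-amplified
    unrelated sequence); unresolved fields are then None/empty.
    """

    proximal_break: Optional[int]
    distal_break: Optional[int]
    inserted_nt: str
    microhomology_len: int
    microhomology_seq: str
    junction_id: Optional[str] = None
    sample_id: Optional[str] = None
    status: str = "ok"

    def reconstruct(self, proximal_ref: str, distal_ref: str) -> str:
        if self.status != "ok":
            raise ValueError("cannot reconstruct an unrelated junction")
        return (
            proximal_ref[: self.proximal_break]
            + self.inserted_nt
            + distal_ref[self.distal_break :]
        )


def _common_prefix_len(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[i] == b[i]:
        i += 1
    return i


def _common_suffix_len(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[-1 - i] == b[-1 - i]:
        i += 1
    return i


def decompose(
    junction: str,
    proximal_ref: str,
    distal_ref: str,
    min_anchor: int = 10,
    junction_id: Optional[str] = None,
    sample_id: Optional[str] = None,
) -> JunctionCall:
    """Split a junction into breakpoints, inserted nucleotides and microhomology.

    The proximal break is the length of the longest junction prefix that
    matches the start of ``proximal_ref``; the distal flank is matched
    analogously as the longest common suffix with ``distal_ref``.  The
    unexplained middle is the non-templated insertion.  If the two maximal
    matches overlap, the overlap is microhomology: the insertion is empty
    and the split is placed at the proximal-most consistent position.

    Each anchor must comprise at least ``min_anchor`` exact bases,
    otherwise the call is returned with status "unrelated".
    """
    junction = junction.upper()
    proximal_ref = proximal_ref.upper()
    distal_ref = distal_ref.upper()
    if len(junction) < 2:
        raise ValueError("junction must be at least 2 nt")
    if not proximal_ref or not distal_ref:
        raise ValueError("references must be non-empty")
    if min_anchor < 1:
        raise ValueError("min_anchor must be >= 1")

    p = _common_prefix_len(junction, proximal_ref)
    s = _common_suffix_len(junction, distal_ref)
    if p < min_anchor or s < min_anchor:
        return JunctionCall(
            proximal_break=None,
            distal_break=None,
            inserted_nt="",
            microhomology_len=0,
            microhomology_seq="",
            junction_id=junction_id,
            sample_id=sample_id,
            status="unrelated",
        )

    j = len(junction)
    if p + s <= j:
        call = JunctionCall(
            proximal_break=p,
            distal_break=len(distal_ref) - s,
            inserted_nt=junction[p : j - s],
            microhomology_len=0,
            microhomology_seq="",
            junction_id=junction_id,
            sample_id=sample_id,
        )
    else:
        overlap = p + s - j
        split = j - s  # proximal-most split: overlap assigned to the distal flank
        call = JunctionCall(
            proximal_break=split,
            distal_break=len(distal_ref) - s,
            inserted_nt="",
            microhomology_len=overlap,
            microhomology_seq=junction[split : split + overlap],
            junction_id=junction_id,
            sample_id=sample_id,
        )
    assert call.reconstruct(proximal_ref, distal_ref) == junction
    return call


@dataclass(frozen=True)
class BreakpointCluster:
    cluster_id: str
    representative: int
    members: Tuple[int, ...]
    tolerance: int


def cluster_breakpoints(
    positions: Sequence[int], tolerance: int = 10
) -> List[BreakpointCluster]:
    """Single-linkage clustering of breakpoint positions.

    Two positions join the same cluster when chained by gaps of at most
    ``tolerance`` bp.  Clusters are labelled I, II, ... in genomic order;
    the representative is the (lower) median member.
    """
    if not positions:
        raise ValueError("positions must be non-empty")
    srt = sorted(positions)
    groups: List[List[int]] = [[srt[0]]]
    for pos in srt[1:]:
        if pos - groups[-1][-1] <= tolerance:
            groups[-1].append(pos)
        else:
            groups.append([pos])
    return [
        BreakpointCluster(
            cluster_id=roman_label(i + 1),
            representative=g[(len(g) - 1) // 2],
            members=tuple(g),
            tolerance=tolerance,
        )
        for i, g in enumerate(groups)
    ]


def hotspot_window(
    positions: Sequence[int], fraction: float
) -> Tuple[int, Tuple[int, int]]:
    """Minimal inclusive window containing at least ``fraction`` of positions.

    Returns ``(length_bp, (start, end))`` with both ends inclusive and
    length counted in bp (a single position has length 1).  Ties break to
    the leftmost start.
    """
    if not positions:
        raise ValueError("positions must be non-empty")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    srt = sorted(positions)
    k = ceil(fraction * len(srt))
    best_len, best_iv = None, None
    for i in range(len(srt) - k + 1):
        start, end = srt[i], srt[i + k - 1]
        length = end - start + 1
        if best_len is None or length < best_len:
            best_len, best_iv = length, (start, end)
    return best_len, best_iv


def classify_deletion(
    breakpoint: int,
    catalog: Sequence[BreakpointCluster],
    tolerance: int = 50,
) -> str:
    """Assign a breakpoint to the nearest catalogued deletion type.

    Returns the cluster label when the nearest representative is within
    ``tolerance`` bp, else "novel" (e.g. a breakpoint falling kilobases
    outside the known hotspot).  Equidistant ties take the lower-position
    cluster's label.
    """
    if not catalog:
        raise ValueError("catalog must be non-empty")
    best = min(catalog, key=lambda c: (abs(c.representative - breakpoint), c.representative))
    if abs(best.representative - breakpoint) <= tolerance:
        return best.cluster_id
    return "novel"


def count_unique_junctions(calls: Sequence[JunctionCall]) -> Dict[str, int]:
    """Number of distinct junctions per sample.

    Uniqueness is keyed on (proximal_break, distal_break, inserted_nt):
    two deletions with identical breakpoints but different non-templated
    insertions arose independently and count separately.  Calls with
    status != "ok" are ignored.
    """
    seen: Dict[str, set] = {}
    for call in calls:
        if call.status != "ok":
            continue
        sid = call.sample_id if call.sample_id is not None else ""
        seen.setdefault(sid, set()).add(
            (call.proximal_break, call.distal_break, call.inserted_nt)
        )
    return {sid: len(keys) for sid, keys in seen.items()}
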