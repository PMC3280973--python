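"""Synthetic locus, deletion-event, cohort and Ct-table generator.

The generator emulates the study system behind this package: a two-exon
tumour-suppressor gene on the minus strand of a ~600 kb locus whose last
exon carries a 23-RSS recombination hotspot, with eight cryptic 12-class
RSS sites downstream at distances spanning 101-557 kb.  Illegitimate
RAG-mediated recombination between the hotspot and a distal site deletes
the intervening DNA and leaves a coding joint carrying 0-10 random
non-templated (TdT) nucleotides.  Deletions arise independently in
multiple subclones of a leukemia sample; a bulk copy-number assay (MLPA)
only detects clones above ~30% clonal fraction, while breakpoint-spanning
PCR detects far smaller subclones.

Everything is scalable: ``scale_factor`` shrinks all genomic distances so
that whole-cohort simulations run at desk scale, and every stochastic
choice flows from a single seed.  Embedded motifs use the cryptic RSS
sequences documented at this locus class's breakpoints, so the scanner's
mismatch accounting can be validated against known truth.

Ground truth (motif coordinates, true breakpoints, insertions, clonal
fractions) is carried on every object for parameter-recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .rss_scanner import (
    HEPTAMER_CONSENSUS,
    NONAMER_CONSENSUS,
    mismatch_count,
    reverse_complement,
    scan,
)

__all__ = [
    "EmbeddedRSS",
    "LocusModel",
    "DeletionEvent",
    "CohortRecord",
    "SimulatorConfig",
    "PAPER_DISTAL_DISTANCES_BP",
    "DISTAL_SITE_MOTIFS",
    "HOTSPOT_MOTIF",
    "simulate_locus",
    "simulate_deletion",
    "simulate_cohort",
    "apply_detection",
    "simulate_ct_tables",
    "cohort_to_frame",
    "cohort_junction_records",
    "event_truth_frame",
    "locus_rss_bed",
    "locus_deletion_bed",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

#: Deletion sizes at paper scale.  Only the range endpoints (101 and 557 kb)
#: are documented; the six intermediate sizes are a fixed generator choice.
PAPER_DISTAL_DISTANCES_BP: Mapping[str, int] = {
    "I": 101_000,
    "II": 152_000,
    "III": 203_000,
    "IV": 268_000,
    "V": 330_000,
    "VI": 412_000,
    "VII": 489_000,
    "VIII": 557_000,
}

#: Cryptic RSS motifs (heptamer, spacer length, nonamer) embedded at each
#: distal site, as documented at the corresponding breakpoints.  No RSS was
#: recovered at the type-II breakpoint in the source data, so site II
#: carries the optimal consensus instead (synthetic stand-in).
DISTAL_SITE_MOTIFS: Mapping[str, Tuple[str, int, str]] = {
    "I": ("CACAGTA", 12, "CCAGGACAT"),
    "II": (HEPTAMER_CONSENSUS, 12, NONAMER_CONSENSUS),
    "III": ("CACAATG", 13, "ACTGAAATG"),
    "IV": ("CACAGCT", 12, "ACATTTTCA"),
    "V": ("CACTGCA", 12, "GCAATAACC"),
    "VI": ("CACAGAG", 13, "ACAATATAG"),
    "VII": ("CACTGTG", 12, "ATATATTCT"),
    "VIII": (HEPTAMER_CONSENSUS, 12, "ACAATTAAT"),
}

#: The 23-class hotspot motif inside the gene's last exon.
HOTSPOT_MOTIF: Tuple[str, int, str] = ("CACTCTG", 23, "ACAGAATTG")

#: Empirical deletion-type usage (type III ~half of mapped cases; V and
#: VIII next; the remaining five types uniform over the residual mass).
EMPIRICAL_SITE_WEIGHTS: Mapping[str, float] = {
    "I": 0.038, "II": 0.038, "III": 0.49, "IV": 0.038,
    "V": 0.15, "VI": 0.038, "VII": 0.038, "VIII": 0.17,
}

DEFAULT_SUBGROUP_SIZES: Mapping[str, int] = {
    "hyperdiploid": 160,
    "etv6_runx1": 142,
    "bcr_abl1": 23,
    "mll": 17,
    "other": 180,
    "unknown": 200,
}

#: Per-subgroup clonal (bulk-detectable) deletion prevalence.
DEFAULT_CLONAL_RATES: Mapping[str, float] = {
    "hyperdiploid": 0.031,
    "etv6_runx1": 0.190,
    "bcr_abl1": 0.261,
    "mll": 0.0,
    "other": 0.072,
    "unknown": 0.070,
}


@dataclass(frozen=True)
class EmbeddedRSS:
    """Ground truth for one embedded RSS motif.

    ``position`` is the plus-strand offset of the heptamer 7-mer window;
    ``heptamer``/``nonamer`` are given in reading orientation (for a
    minus-strand site the plus-strand substring is their reverse
    complement).
    """

    position: int
    strand: str
    heptamer: str
    spacer_len: int
    nonamer: str
    label: str
    spacer_seq: str = ""

    def __post_init__(self) -> None:
        if self.spacer_len not in (11, 12, 13, 22, 23, 24):
            raise ValueError(f"spacer length {self.spacer_len} outside 12±1/23±1")
        if not self.heptamer.startswith("CAC"):
            raise ValueError("heptamer must begin with CAC in reading orientation")

    @property
    def spacer_class(self) -> int:
        return 12 if self.spacer_len <= 13 else 23

    @property
    def cleavage_edge(self) -> int:
        return self.position if self.strand == "+" else self.position + 7


@dataclass
class LocusModel:
    locus_length: int
    gene_interval: Tuple[int, int]
    exon2_interval: Tuple[int, int]
    hotspot_rss: EmbeddedRSS
    distal_rss_sites: List[EmbeddedRSS]
    sequence: str
    scale_factor: float
    gene_strand: str = "-"
    contig: str = "locus"

    def distal_by_label(self, label: str) -> EmbeddedRSS:
        for site in self.distal_rss_sites:
            if site.label == label:
                return site
        raise KeyError(label)

    def deletion_size(self, label: str) -> int:
        return self.distal_by_label(label).cleavage_edge - self.hotspot_rss.cleavage_edge


@dataclass
class DeletionEvent:
    """One simulated recombination event with full ground truth."""

    proximal_rss: EmbeddedRSS
    distal_rss: EmbeddedRSS
    deleted_interval: Tuple[int, int]
    inserted_nt: str
    junction_sequence: str
    junction_flank: int
    clone_id: Optional[str] = None
    clonal_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.proximal_rss.spacer_class == self.distal_rss.spacer_class:
            raise ValueError("12/23 rule violated: spacer classes are equal")
        if not 0 < self.clonal_fraction <= 1:
            raise ValueError("clonal fraction must be in (0, 1]")

    @property
    def deletion_type(self) -> str:
        return self.distal_rss.label

    @property
    def size(self) -> int:
        return self.deleted_interval[1] - self.deleted_interval[0]

    def flanking_references(
        self, locus: LocusModel, extra: int = 20
    ) -> Tuple[str, str]:
        """Reference flanks for junction decomposition.

        The proximal reference starts where the junction does and extends
        ``extra`` bp past the true breakpoint; the distal reference starts
        ``extra`` bp before its breakpoint and ends with the junction.
        """
        b_p, b_d = self.deleted_interval
        f = self.junction_flank
        prox = locus.sequence[b_p - f : b_p + extra]
        dist = locus.sequence[b_d - extra : b_d + f]
        return prox, dist


@dataclass
class CohortRecord:
    sample_id: str
    lineage: str  # "BCP-ALL", "T-ALL" or "normal"
    subgroup: str
    clones: List[DeletionEvent] = field(default_factory=list)
    timepoint: str = "diagnosis"

    def __post_init__(self) -> None:
        total = sum(c.clonal_fraction for c in self.clones)
        if total > 1.0 + 1e-9:
            raise ValueError(f"clonal fractions sum to {total:.3f} > 1")


@dataclass
class SimulatorConfig:
    """All knobs of the generator; defaults are the study conditions."""

    seed: int = 0
    n_samples: Dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SUBGROUP_SIZES)
    )
    deletion_prob: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLONAL_RATES)
    )
    n_tall: int = 109
    n_normal: int = 26
    subclonal_prob: float = 0.18
    #: extra independent deletions in a bulk-positive sample (0..3, so up
    #: to 4 unique deletions per sample)
    extra_clone_probs: Tuple[float, ...] = (0.73, 0.17, 0.07, 0.03)
    #: number of subclones in a bulk-negative subclonal carrier (1..)
    subclonal_clone_probs: Tuple[float, ...] = (0.8, 0.2)
    insertion_len_range: Tuple[int, int] = (1, 10)
    non_extendable_insertions: bool = True
    site_weights: Optional[Dict[str, float]] = None  # None = empirical usage
    mlpa_detect_fraction: float = 0.30
    pcr_detect_fraction: float = 0.01
    scale_factor: float = 1.0
    junction_flank: int = 60
    #: telomeric-breakpoint scatter: a core_fraction of breakpoints fall in
    #: a core_bp stretch inside a region_bp window around the hotspot edge
    breakpoint_core_bp: int = 10
    breakpoint_region_bp: int = 33
    breakpoint_core_fraction: float = 0.75
    distal_jitter_bp: int = 4
    ct_noise_sd: float = 0.1

    def validate(self) -> List[str]:
        problems = []
        for name, p in self.deletion_prob.items():
            if not 0 <= p <= 1:
                problems.append(f"deletion_prob[{name}]={p} outside [0,1]")
        if not 0 <= self.subclonal_prob <= 1:
            problems.append(f"subclonal_prob={self.subclonal_prob} outside [0,1]")
        if self.mlpa_detect_fraction <= self.pcr_detect_fraction:
            problems.append(
                "mlpa_detect_fraction must exceed pcr_detect_fraction "
                f"({self.mlpa_detect_fraction} <= {self.pcr_detect_fraction})"
            )
        if self.scale_factor <= 0:
            problems.append(f"scale_factor={self.scale_factor} must be positive")
        if self.ct_noise_sd < 0:
            problems.append(f"ct_noise_sd={self.ct_noise_sd} must be non-negative")
        lo, hi = self.insertion_len_range
        if lo < 0 or hi < lo or hi > 10:
            problems.append(f"insertion_len_range={self.insertion_len_range} outside 0..10")
        if self.breakpoint_core_bp > self.breakpoint_region_bp:
            problems.append("breakpoint_core_bp exceeds breakpoint_region_bp")
        return problems

    def require_valid(self) -> None:
        problems = self.validate()
        if problems:
            raise ValueError("; ".join(problems))


def _rng_stream(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, stream])


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


# ---------------------------------------------------------------------------
# Locus


def minimal_feasible_scale() -> float:
    """Smallest scale at which distal sites neither overlap each other nor
    the hotspot motif (with a 20 bp guard band)."""
    dists = sorted(PAPER_DISTAL_DISTANCES_BP.values())
    min_gap = min(b - a for a, b in zip(dists, dists[1:]))
    motif_footprint = 7 + 24 + 9 + 20
    return max(motif_footprint / min_gap, 200 / dists[0])


def simulate_locus(
    config: SimulatorConfig, rng: Optional[np.random.Generator] = None
) -> LocusModel:
    """Build the synthetic locus: background + embedded RSS motifs.

    The background is rejection-sampled i.i.d. uniform ACGT until it
    contains no spurious zero-mismatch RSS candidate, so exact-consensus
    truth is unambiguous while near-consensus noise (realistic) remains.
    Identical config and seed give a byte-identical sequence.
    """
    config.require_valid()
    scale = config.scale_factor
    min_scale = minimal_feasible_scale()
    if scale < min_scale:
        raise ValueError(
            f"scale_factor {scale} too small: distal RSS sites would overlap; "
            f"minimal feasible scale is {min_scale:.5f}"
        )
    if rng is None:
        rng = _rng_stream(config.seed, 0)

    distances = {
        label: int(round(d * scale)) for label, d in PAPER_DISTAL_DISTANCES_BP.items()
    }
    pad = 300
    gene_len = max(600, int(round(30_000 * scale)))
    gene = (pad, pad + gene_len)
    exon2 = (gene[1] - 200, gene[1])
    h = gene[1] - 150  # hotspot heptamer start, inside exon 2
    locus_length = h + max(distances.values()) + 300

    hep, spacer_len, non = HOTSPOT_MOTIF
    # exact-consensus embedded sites are the only allowed 0-mismatch hits
    for attempt in range(20):
        spacers: Dict[str, str] = {"HOTSPOT": _random_bases(rng, spacer_len)}
        seq = list(_random_bases(rng, locus_length))
        seq[h : h + 7] = hep
        seq[h + 7 : h + 7 + spacer_len] = spacers["HOTSPOT"]
        seq[h + 7 + spacer_len : h + 16 + spacer_len] = non

        distal_sites: List[EmbeddedRSS] = []
        for label in sorted(distances, key=distances.get):
            d_hep, d_spacer, d_non = DISTAL_SITE_MOTIFS[label]
            spacer_seq = _random_bases(rng, d_spacer)
            spacers[label] = spacer_seq
            g = h + distances[label] - 7  # heptamer window start (minus strand)
            plus = reverse_complement(d_hep + spacer_seq + d_non)
            start = g - d_spacer - 9
            seq[start : g + 7] = plus
            distal_sites.append(
                EmbeddedRSS(
                    position=g,
                    strand="-",
                    heptamer=d_hep,
                    spacer_len=d_spacer,
                    nonamer=d_non,
                    label=label,
                    spacer_seq=spacer_seq,
                )
            )
        sequence = "".join(seq)

        hotspot = EmbeddedRSS(
            position=h,
            strand="+",
            heptamer=hep,
            spacer_len=spacer_len,
            nonamer=non,
            label="HOTSPOT",
            spacer_seq=spacers["HOTSPOT"],
        )
        exact = scan(sequence, "both", max_heptamer_mm=0, max_nonamer_mm=0)
        intended = {
            (s.position, s.strand)
            for s in [hotspot, *distal_sites]
            if mismatch_count(s.heptamer, HEPTAMER_CONSENSUS) == 0
            and mismatch_count(s.nonamer, NONAMER_CONSENSUS) == 0
        }
        if all((c.heptamer_start, c.strand) in intended for c in exact):
            break
    else:  # pragma: no cover - p(spurious consensus RSS) is ~1e-3 per draw
        raise RuntimeError("could not sample a clean background in 20 attempts")

    return LocusModel(
        locus_length=locus_length,
        gene_interval=gene,
        exon2_interval=exon2,
        hotspot_rss=hotspot,
        distal_rss_sites=distal_sites,
        sequence=sequence,
        scale_factor=scale,
    )


def locus_rss_bed(locus: LocusModel) -> pd.DataFrame:
    """Truth BED (0-based half-open) of every embedded RSS motif."""
    rows = []
    for site in [locus.hotspot_rss, *locus.distal_rss_sites]:
        if site.strand == "+":
            start = site.position
            end = site.position + 16 + site.spacer_len
        else:
            start = site.position - site.spacer_len - 9
            end = site.position + 7
        rows.append(
            {
                "chrom": locus.contig,
                "start": start,
                "end": end,
                "name": f"RSS_{site.label}",
                "score": site.spacer_class,
                "strand": site.strand,
            }
        )
    return pd.DataFrame(rows)


def locus_deletion_bed(locus: LocusModel) -> pd.DataFrame:
    """Truth BED of the nominal deleted segment for every deletion type."""
    h = locus.hotspot_rss.cleavage_edge
    rows = [
        {
            "chrom": locus.contig,
            "start": h,
            "end": site.cleavage_edge,
            "name": f"DEL_{site.label}",
            "score": site.cleavage_edge - h,
            "strand": "+",
        }
        for site in locus.distal_rss_sites
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Deletion events


def _draw_site(
    locus: LocusModel,
    rng: np.random.Generator,
    site_weights: Optional[Mapping[str, float]],
) -> EmbeddedRSS:
    labels = [s.label for s in locus.distal_rss_sites]
    if site_weights is None:
        weights = np.array([EMPIRICAL_SITE_WEIGHTS[l] for l in labels], dtype=float)
    else:
        weights = np.array([site_weights.get(l, 0.0) for l in labels], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("site weights sum to zero")
    idx = rng.choice(len(labels), p=weights / weights.sum())
    return locus.distal_rss_sites[int(idx)]


def _draw_proximal_break(
    locus: LocusModel, rng: np.random.Generator, config: SimulatorConfig
) -> int:
    """Telomeric breakpoint with hotspot scatter.

    A ``breakpoint_core_fraction`` of breakpoints fall uniformly in a
    ``breakpoint_core_bp`` stretch centred on the hotspot cleavage edge;
    the rest fall uniformly in the remainder of a ``breakpoint_region_bp``
    window around it.
    """
    h = locus.hotspot_rss.cleavage_edge
    core = config.breakpoint_core_bp
    region = config.breakpoint_region_bp
    core_lo = h - (core - 1) // 2
    region_lo = h - (region - 1) // 2
    if region <= core or rng.random() < config.breakpoint_core_fraction:
        return int(rng.integers(core_lo, core_lo + core))
    outside = [
        p
        for p in range(region_lo, region_lo + region)
        if not core_lo <= p < core_lo + core
    ]
    return int(outside[rng.integers(0, len(outside))])


def simulate_deletion(
    locus: LocusModel,
    rng: np.random.Generator,
    config: Optional[SimulatorConfig] = None,
    clone_id: Optional[str] = None,
    clonal_fraction: float = 1.0,
) -> DeletionEvent:
    """Draw one RAG-type deletion joining the 23-RSS hotspot to a 12-class site.

    The junction is proximal flank + TdT insertion + distal flank; the
    insertion is drawn from the configured length distribution with random
    bases, rejection-sampled so it cannot be extended into either flank
    when ``non_extendable_insertions`` is set (which makes the generating
    decomposition unique).
    """
    if config is None:
        config = SimulatorConfig(scale_factor=locus.scale_factor)
    if not locus.distal_rss_sites:
        raise ValueError("locus has no distal 12-class RSS site to pair with")
    site = _draw_site(locus, rng, config.site_weights)
    b_p = _draw_proximal_break(locus, rng, config)
    jit = config.distal_jitter_bp
    b_d = site.cleavage_edge + (int(rng.integers(-jit, jit + 1)) if jit else 0)

    lo, hi = config.insertion_len_range
    ins_len = int(rng.integers(lo, hi + 1))
    seq = locus.sequence
    for _ in range(100):
        ins = _random_bases(rng, ins_len)
        if not config.non_extendable_insertions or ins_len == 0:
            break
        if ins[0] != seq[b_p] and ins[-1] != seq[b_d - 1]:
            break
    f = config.junction_flank
    junction = seq[b_p - f : b_p] + ins + seq[b_d : b_d + f]
    return DeletionEvent(
        proximal_rss=locus.hotspot_rss,
        distal_rss=site,
        deleted_interval=(b_p, b_d),
        inserted_nt=ins,
        junction_sequence=junction,
        junction_flank=f,
        clone_id=clone_id,
        clonal_fraction=clonal_fraction,
    )


# ---------------------------------------------------------------------------
# Cohort


def _choice(rng: np.random.Generator, probs: Sequence[float]) -> int:
    p = np.asarray(probs, dtype=float)
    return int(rng.choice(len(p), p=p / p.sum()))


def _subclone_fractions(
    rng: np.random.Generator, k: int, config: SimulatorConfig
) -> List[float]:
    """Fractions for k subclones, all below the bulk detection limit.

    The total subclonal mass is drawn between twice the PCR detection
    limit and 90% of the bulk limit, then split among the subclones plus a
    residual normal compartment by a symmetric Dirichlet.
    """
    mass = rng.uniform(2 * config.pcr_detect_fraction, 0.9 * config.mlpa_detect_fraction)
    weights = rng.dirichlet(np.ones(k + 1))
    return [float(mass * w) for w in weights[:k]]


def simulate_cohort(
    config: SimulatorConfig, locus: Optional[LocusModel] = None
) -> List[CohortRecord]:
    """Simulate the full multiclonal cohort.

    Per subgroup, each sample carries a bulk-detectable (major clone)
    deletion with the configured clonal prevalence; bulk-positive samples
    may carry additional independent subclonal deletions, and
    bulk-negative samples carry purely subclonal deletions with
    probability ``subclonal_prob``.  T-lineage and normal samples carry no
    deletions.  Identical config ⇒ identical cohort.
    """
    config.require_valid()
    if not any(config.n_samples.values()) and config.n_tall == 0 and config.n_normal == 0:
        raise ValueError("cohort is empty: all group sizes are zero")
    if locus is None:
        locus = simulate_locus(config)
    rng = _rng_stream(config.seed, 1)

    records: List[CohortRecord] = []
    for subgroup in sorted(config.n_samples):
        p_clonal = config.deletion_prob.get(subgroup, 0.0)
        for i in range(config.n_samples[subgroup]):
            sample_id = f"BCP_{subgroup}_{i:04d}"
            clones: List[DeletionEvent] = []
            if rng.random() < p_clonal:
                major_frac = float(rng.uniform(0.35, 0.95))
                n_extra = _choice(rng, config.extra_clone_probs)
                sub_fracs = (
                    _subclone_fractions(rng, n_extra, config) if n_extra else []
                )
                # rescale if the major clone leaves too little room
                room = 1.0 - major_frac
                total_sub = sum(sub_fracs)
                if total_sub > room and total_sub > 0:
                    sub_fracs = [f * room / total_sub * 0.99 for f in sub_fracs]
                fracs = [major_frac, *sub_fracs]
            elif rng.random() < config.subclonal_prob:
                k = 1 + _choice(rng, config.subclonal_clone_probs)
                fracs = _subclone_fractions(rng, k, config)
            else:
                fracs = []
            for j, frac in enumerate(fracs):
                clones.append(
                    simulate_deletion(
                        locus,
                        rng,
                        config,
                        clone_id=f"{sample_id}.c{j}",
                        clonal_fraction=max(frac, 1e-6),
                    )
                )
            records.append(CohortRecord(sample_id, "BCP-ALL", subgroup, clones))
    for i in range(config.n_tall):
        records.append(CohortRecord(f"TALL_{i:04d}", "T-ALL", "NA", []))
    for i in range(config.n_normal):
        records.append(CohortRecord(f"NBM_{i:04d}", "normal", "NA", []))
    return records


def apply_detection(
    record: CohortRecord, config: SimulatorConfig
) -> Dict[str, str]:
    """Detection label per clone: MLPA+ / PCR-only / undetected.

    Monotone in clonal fraction: a clone at or above the bulk (MLPA)
    detection fraction is MLPA+, one at or above the PCR limit but below
    the bulk limit is PCR-only, anything smaller is undetected.
    """
    labels = {}
    for clone in record.clones:
        if clone.clonal_fraction >= config.mlpa_detect_fraction:
            labels[clone.clone_id] = "MLPA+"
        elif clone.clonal_fraction >= config.pcr_detect_fraction:
            labels[clone.clone_id] = "PCR-only"
        else:
            labels[clone.clone_id] = "undetected"
    return labels


def cohort_to_frame(
    records: Sequence[CohortRecord], config: Optional[SimulatorConfig] = None
) -> pd.DataFrame:
    """Long-format cohort table, one row per clone (or per clone-free sample)."""
    rows = []
    for rec in records:
        if not rec.clones:
            rows.append(
                {
                    "sample_id": rec.sample_id,
                    "lineage": rec.lineage,
                    "subgroup": rec.subgroup,
                    "timepoint": rec.timepoint,
                    "clone_id": "",
                    "deletion_type": "none",
                    "clonal_fraction": 0.0,
                }
            )
            continue
        labels = apply_detection(rec, config) if config is not None else {}
        for clone in rec.clones:
            row = {
                "sample_id": rec.sample_id,
                "lineage": rec.lineage,
                "subgroup": rec.subgroup,
                "timepoint": rec.timepoint,
                "clone_id": clone.clone_id,
                "deletion_type": clone.deletion_type,
                "clonal_fraction": clone.clonal_fraction,
            }
            if labels:
                row["detection"] = labels[clone.clone_id]
            rows.append(row)
    return pd.DataFrame(rows)


def cohort_junction_records(
    records: Sequence[CohortRecord],
) -> List[Tuple[str, str]]:
    """(id, sequence) pairs for a junction FASTA, one record per clone."""
    out = []
    for rec in records:
        for clone in rec.clones:
            out.append(
                (
                    f"{clone.clone_id}|{clone.deletion_type}",
                    clone.junction_sequence,
                )
            )
    return out


def event_truth_frame(records: Sequence[CohortRecord]) -> pd.DataFrame:
    """Ground-truth table of every simulated deletion event."""
    rows = []
    for rec in records:
        for clone in rec.clones:
            rows.append(
                {
                    "sample_id": rec.sample_id,
                    "clone_id": clone.clone_id,
                    "deletion_type": clone.deletion_type,
                    "proximal_break": clone.deleted_interval[0],
                    "distal_break": clone.deleted_interval[1],
                    "inserted_nt": clone.inserted_nt,
                    "clonal_fraction": clone.clonal_fraction,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Ct tables

CHIP_CELL_LINES: Mapping[str, Tuple[str, ...]] = {
    "BCP-ALL": ("RS4;11", "Nalm6", "CCRF-SB"),
    "T-ALL": ("HSB2", "Jurkat", "KARPAS45"),
}

CHIP_REGIONS: Tuple[str, ...] = ("-1kb_prom", "prox_prom", "exon2", "3UTR")

#: True percent recovery per (antibody, region, lineage).  The chromatin
#: landscape these emulate: promoter-proximal H3K4me3 in both lineages,
#: gene-body H3K4me3 near the breakpoint hotspot only in B-lineage cells,
#: and promoter H3K9/14Ac higher in B-lineage cells.  Magnitudes are the
#: generator's own choice (plausible percent-of-input values); only the
#: contrasts matter downstream.
CHIP_TRUE_RECOVERY: Mapping[Tuple[str, str, str], float] = {
    ("H3K4me3", "-1kb_prom", "BCP-ALL"): 1.0,
    ("H3K4me3", "-1kb_prom", "T-ALL"): 1.0,
    ("H3K4me3", "prox_prom", "BCP-ALL"): 20.0,
    ("H3K4me3", "prox_prom", "T-ALL"): 18.0,
    ("H3K4me3", "exon2", "BCP-ALL"): 8.0,
    ("H3K4me3", "exon2", "T-ALL"): 0.8,
    ("H3K4me3", "3UTR", "BCP-ALL"): 1.5,
    ("H3K4me3", "3UTR", "T-ALL"): 0.5,
    ("H3K9/14Ac", "-1kb_prom", "BCP-ALL"): 1.0,
    ("H3K9/14Ac", "-1kb_prom", "T-ALL"): 1.0,
    ("H3K9/14Ac", "prox_prom", "BCP-ALL"): 12.0,
    ("H3K9/14Ac", "prox_prom", "T-ALL"): 4.0,
    ("H3K9/14Ac", "exon2", "BCP-ALL"): 2.0,
    ("H3K9/14Ac", "exon2", "T-ALL"): 2.0,
    ("H3K9/14Ac", "3UTR", "BCP-ALL"): 1.0,
    ("H3K9/14Ac", "3UTR", "T-ALL"): 1.0,
}

#: True expression fold changes relative to the calibrator line (Nalm6).
EXPRESSION_TRUE_FOLD: Mapping[str, float] = {
    "Nalm6": 1.0,
    "RS4;11": 1.3,
    "CCRF-SB": 0.7,
    "HSB2": 0.6,
    "Jurkat": 1.1,
    "KARPAS45": 0.9,
}

CT_INPUT_BASE = 28.0
CT_REFERENCE_BASE = 22.0
CT_TARGET_CALIBRATOR = 24.0
INPUT_DILUTION = 0.01


def simulate_ct_tables(
    config: SimulatorConfig,
    rng: Optional[np.random.Generator] = None,
    n_chip_replicates: int = 2,
    n_expr_replicates: int = 6,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Emit ChIP and expression Ct tables consistent with the true ratios.

    Ct values are derived by inverting the percent-recovery and ddCt
    formulas from the true enrichment/fold-change tables, then perturbed
    with Gaussian noise of ``config.ct_noise_sd`` cycles.  At sigma = 0
    the quantification module recovers the truth to machine precision.
    """
    if config.ct_noise_sd < 0:
        raise ValueError("ct_noise_sd must be non-negative")
    if rng is None:
        rng = _rng_stream(config.seed, 2)
    sd = config.ct_noise_sd

    chip_rows = []
    for lineage, lines in CHIP_CELL_LINES.items():
        for cell_line in lines:
            for antibody in ("H3K4me3", "H3K9/14Ac"):
                for region in CHIP_REGIONS:
                    recovery = CHIP_TRUE_RECOVERY[(antibody, region, lineage)]
                    ct_chip_true = CT_INPUT_BASE - np.log2(
                        recovery / 100.0 / INPUT_DILUTION
                    )
                    for rep in range(1, n_chip_replicates + 1):
                        for role, ct_true in (
                            ("input", CT_INPUT_BASE),
                            ("chip", ct_chip_true),
                        ):
                            chip_rows.append(
                                {
                                    "sample_id": cell_line,
                                    "lineage": lineage,
                                    "antibody": antibody,
                                    "region": region,
                                    "role": role,
                                    "replicate": rep,
                                    "ct": float(ct_true + rng.normal(0, sd) if sd else ct_true),
                                    "dilution": INPUT_DILUTION,
                                }
                            )

    expr_rows = []
    for lineage, lines in CHIP_CELL_LINES.items():
        for cell_line in lines:
            fold = EXPRESSION_TRUE_FOLD[cell_line]
            ct_target_true = CT_TARGET_CALIBRATOR - np.log2(fold)
            role = "calibrator" if cell_line == "Nalm6" else "unknown"
            for rep in range(1, n_expr_replicates + 1):
                for target, ct_true in (
                    ("BTG1", ct_target_true),
                    ("HPRT", CT_REFERENCE_BASE),
                ):
                    expr_rows.append(
                        {
                            "sample_id": cell_line,
                            "lineage": lineage,
                            "target": target,
                            "role": role,
                            "replicate": rep,
                            "ct": float(ct_true + rng.normal(0, sd) if sd else ct_true),
                        }
                    )
    return pd.DataFrame(chip_rows), pd.DataFrame(expr_rows)
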