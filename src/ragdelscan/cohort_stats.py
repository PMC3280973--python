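"""Cohort enrichment statistics: 2x2 contingency tables per cytogenetic subgroup.

Deletion prevalence is compared between sample groups (lineage, or one
cytogenetic subgroup versus the rest) with a Pearson chi-square test
WITHOUT continuity correction, falling back to Fisher's exact test when
any expected cell count is below 5.  Both choices mirror the conventions
of standard clinical-statistics packages; P-values are two-sided and
reported unadjusted.

Also provides the subclonal-screening summary (bulk-assay-positive versus
PCR-only detections per group) and deletion-type frequency tallies.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyTable",
    "TestResult",
    "chi_square_2x2",
    "fisher_exact_2x2",
    "test_table",
    "build_tables",
    "samples_from_cohort",
    "subclonal_summary",
    "deletion_type_frequencies",
    "load_reference_counts",
    "reference_cohort_pvalues",
]


@dataclass
class ContingencyTable:
    """2x2 counts: rows = group yes/no, columns = deletion +/-.

    ``a``/``b`` are deletion-positive/negative counts in the group of
    interest, ``c``/``d`` the same outside it.
    """

    a: int
    b: int
    c: int
    d: int
    group_label: str = ""
    test_used: str = "auto"

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def expected(self) -> np.ndarray:
        n = self.total
        if n == 0:
            raise ValueError("empty table")
        rows = np.array([self.a + self.b, self.c + self.d], dtype=float)
        cols = np.array([self.a + self.c, self.b + self.d], dtype=float)
        return np.outer(rows, cols) / n

    def choose_test(self) -> str:
        """Chi-square unless any expected count < 5 (small-sample rule)."""
        return "fisher" if self.expected().min() < 5 else "chi_square"


@dataclass(frozen=True)
class TestResult:
    statistic: Optional[float]
    p_value: float
    df: Optional[int]
    test_used: str
    group_label: str = ""


def chi_square_2x2(t: ContingencyTable) -> TestResult:
    """Pearson chi-square without continuity correction, df = 1, two-sided.

    Equivalent to the closed form N(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)).
    Raises when a margin is zero (the statistic is undefined; use Fisher).
    """
    margins = (t.a + t.b, t.c + t.d, t.a + t.c, t.b + t.d)
    if min(margins) == 0:
        raise ValueError("zero margin: chi-square undefined, use fisher_exact_2x2")
    stat, p, df, _ = stats.chi2_contingency(
        [[t.a, t.b], [t.c, t.d]], correction=False
    )
    return TestResult(float(stat), float(p), int(df), "chi_square", t.group_label)


def fisher_exact_2x2(t: ContingencyTable, method: str = "min_likelihood") -> TestResult:
    """Fisher's exact test, two-sided.

    Default is the minimum-likelihood method (sum of hypergeometric
    probabilities of all margin-fixed tables no more probable than the
    observed one, the common statistical-package default).  ``method=
    "doubling"`` doubles the smaller one-sided tail instead, capped at 1.
    """
    if t.total == 0:
        raise ValueError("all-zero table")
    if method == "min_likelihood":
        _, p = stats.fisher_exact([[t.a, t.b], [t.c, t.d]], alternative="two-sided")
    elif method == "doubling":
        _, less = stats.fisher_exact([[t.a, t.b], [t.c, t.d]], alternative="less")
        _, greater = stats.fisher_exact([[t.a, t.b], [t.c, t.d]], alternative="greater")
        p = min(1.0, 2.0 * min(less, greater))
    else:
        raise ValueError(f"unknown method {method!r}")
    return TestResult(None, float(p), None, "fisher", t.group_label)


def test_table(t: ContingencyTable) -> TestResult:
    """Run the test recorded on the table ('auto' applies the small-sample rule)."""
    choice = t.test_used if t.test_used != "auto" else t.choose_test()
    if choice == "chi_square":
        return chi_square_2x2(t)
    if choice == "fisher":
        return fisher_exact_2x2(t)
    raise ValueError(f"unknown test {choice!r}")


# ---------------------------------------------------------------------------
# Cohort-table construction


def samples_from_cohort(
    cohort: pd.DataFrame,
    mlpa_detect_fraction: float = 0.30,
    pcr_detect_fraction: float = 0.01,
) -> pd.DataFrame:
    """Collapse a per-clone cohort table to one row per sample.

    Expects the simulator's long format (``sample_id lineage subgroup
    timepoint clone_id deletion_type clonal_fraction``; clone-free samples
    carry a single row with deletion_type "none").  Adds boolean columns
    ``mlpa_positive`` (any clone at or above the bulk-assay detection
    fraction) and ``pcr_positive`` (any clone detectable at all).
    """
    required = {"sample_id", "lineage", "subgroup", "clonal_fraction", "deletion_type"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    df = cohort.copy()
    df["_has_del"] = df["deletion_type"].astype(str) != "none"
    frac = df["clonal_fraction"].astype(float).where(df["_has_del"], 0.0)
    df["_mlpa"] = frac >= mlpa_detect_fraction
    df["_pcr"] = frac >= pcr_detect_fraction
    out = (
        df.groupby("sample_id", sort=True)
        .agg(
            lineage=("lineage", "first"),
            subgroup=("subgroup", "first"),
            n_deletions=("_has_del", "sum"),
            mlpa_positive=("_mlpa", "any"),
            pcr_positive=("_pcr", "any"),
        )
        .reset_index()
    )
    return out


def build_tables(
    samples: pd.DataFrame,
    group_col: str = "subgroup",
    status_col: str = "mlpa_positive",
    missing_values: Sequence[str] = ("unknown", "NA", ""),
) -> List[ContingencyTable]:
    """One yes/no table per group value, versus all other informative samples.

    Samples whose ``group_col`` value is missing (by convention "unknown",
    "NA" or empty) are excluded from every table, which is why the yes+no
    totals need not add up to the full cohort.  ``test_used`` is left on
    "auto" so the small-sample rule decides at test time.
    """
    if group_col not in samples.columns or status_col not in samples.columns:
        raise ValueError(f"unknown column: need {group_col!r} and {status_col!r}")
    known = samples[~samples[group_col].astype(str).isin(list(missing_values))]
    tables = []
    for value in sorted(known[group_col].astype(str).unique()):
        in_group = known[group_col].astype(str) == value
        pos = known[status_col].astype(bool)
        tables.append(
            ContingencyTable(
                a=int((in_group & pos).sum()),
                b=int((in_group & ~pos).sum()),
                c=int((~in_group & pos).sum()),
                d=int((~in_group & ~pos).sum()),
                group_label=value,
            )
        )
    return tables


def subclonal_summary(
    samples: pd.DataFrame,
    junction_counts: Optional[Dict[str, int]] = None,
    by: str = "lineage",
) -> pd.DataFrame:
    """Detection-channel summary per group.

    For each group: number of samples, bulk-assay (MLPA) positives,
    PCR-only positives (deletion detectable by breakpoint-spanning PCR but
    below the bulk detection limit), the PCR-only fraction among
    MLPA-negative samples, and — when per-sample unique-junction counts
    are supplied — the number of multi-deletion samples (>= 2 unique
    junctions).
    """
    if "mlpa_positive" not in samples.columns or "pcr_positive" not in samples.columns:
        raise ValueError("samples must carry detection labels (run samples_from_cohort)")
    rows = []
    for value, grp in samples.groupby(by, sort=True):
        mlpa_pos = int(grp["mlpa_positive"].sum())
        pcr_only = int((~grp["mlpa_positive"] & grp["pcr_positive"]).sum())
        mlpa_neg = len(grp) - mlpa_pos
        multi = 0
        if junction_counts is not None:
            multi = sum(
                1 for sid in grp["sample_id"] if junction_counts.get(sid, 0) >= 2
            )
        rows.append(
            {
                by: value,
                "n_samples": len(grp),
                "mlpa_positive": mlpa_pos,
                "pcr_only": pcr_only,
                "mlpa_negative": mlpa_neg,
                "pcr_only_fraction": pcr_only / mlpa_neg if mlpa_neg else 0.0,
                "multi_deletion_samples": multi,
            }
        )
    return pd.DataFrame(rows)


def deletion_type_frequencies(labels: Sequence[str]) -> pd.DataFrame:
    """Proportion of each deletion type among classified cases.

    Proportions are taken over labels other than "novel"/"unmapped", which
    are reported separately with proportion NaN.
    """
    counts: Dict[str, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    classified = sum(v for k, v in counts.items() if k not in ("novel", "unmapped"))
    rows = []
    for lab in sorted(counts):
        sep = lab in ("novel", "unmapped")
        rows.append(
            {
                "deletion_type": lab,
                "count": counts[lab],
                "proportion": (counts[lab] / classified) if (classified and not sep) else float("nan"),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Published reference counts

_REFERENCE_COUNTS = "reference_cohort_counts.tsv"


def load_reference_counts() -> pd.DataFrame:
    """Published MLPA screening counts for the pediatric ALL reference cohort.

    One row per comparison: deletion-positive/negative counts inside and
    outside each group, and the test reported for it (chi-square without
    continuity correction except Fisher's exact for the small MLL group).
    """
    with resources.files("ragdelscan.data").joinpath(_REFERENCE_COUNTS).open() as fh:
        return pd.read_csv(fh, sep="\t")


def reference_cohort_pvalues() -> pd.DataFrame:
    """Recompute the enrichment P-values from the packaged reference counts."""
    counts = load_reference_counts()
    rows = []
    for rec in counts.itertuples(index=False):
        table = ContingencyTable(
            a=int(rec.group_pos),
            b=int(rec.group_neg),
            c=int(rec.rest_pos),
            d=int(rec.rest_neg),
            group_label=str(rec.comparison),
            test_used=str(rec.test),
        )
        res = test_table(table)
        rows.append(
            {
                "comparison": rec.comparison,
                "test": res.test_used,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "p_rounded": round(res.p_value, 3),
                "n": table.total,
            }
        )
    return pd.DataFrame(rows)
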