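"""ChIP enrichment (percent recovery) and relative expression (2^-ddCt) from Ct tables.

ChIP-qPCR enrichment is expressed as percent recovery of input chromatin,

    recovery% = input_dilution_factor * 2^(Ct_input - Ct_ChIP) * 100,

and relative expression by the ddCt method,

    fold = 2^-[(Ct_target,s - Ct_ref,s) - (Ct_target,cal - Ct_ref,cal)],

so the calibrator sample maps to 1.0 exactly.  Replicate Ct values are
averaged per (sample, target) before either formula is applied; no
amplification-efficiency calibration is attempted.  Group comparisons
(e.g. recovery in B-lineage versus T-lineage cell lines) use the
classical equal-variance two-sample t-test; Welch's correction is
available behind a flag.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "QPCRMeasurement",
    "ChIPSample",
    "pct_recovery",
    "recovery_table",
    "delta_delta_ct",
    "fold_changes",
    "compare_groups",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QPCRMeasurement:
    sample_id: str
    target: str
    role: str  # "unknown" or "calibrator"
    ct: float
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.ct <= 0:
            raise ValueError("Ct must be positive")


@dataclass(frozen=True)
class ChIPSample:
    sample_id: str
    antibody: str
    region: str
    ct_chip: float
    ct_input: float
    input_dilution_factor: float

    def __post_init__(self) -> None:
        if self.input_dilution_factor <= 0:
            raise ValueError("input dilution factor must be positive")


def pct_recovery(
    ct_input: float, ct_chip: float, input_dilution_factor: float
) -> float:
    """Percent of input chromatin recovered in the ChIP fraction.

    Strictly increasing in (Ct_input - Ct_ChIP) and linear in the dilution
    factor.  Values above 100% are possible and logged as suspicious.
    """
    if input_dilution_factor <= 0:
        raise ValueError("input dilution factor must be positive")
    if not (math.isfinite(ct_input) and math.isfinite(ct_chip)):
        raise ValueError("Ct values must be finite")
    rec = input_dilution_factor * 2.0 ** (ct_input - ct_chip) * 100.0
    if rec > 100.0:
        logger.warning(
            "recovery %.1f%% exceeds 100%% — check dilution factor or Ct assignment",
            rec,
        )
    return rec


def recovery_table(chip: pd.DataFrame) -> pd.DataFrame:
    """Percent recovery per (sample, antibody, region, replicate).

    Expects long format with columns ``sample_id antibody region role ct
    dilution``; role is "chip" or "input".  Rows lacking either role raise.
    """
    needed = {"sample_id", "antibody", "region", "role", "ct", "dilution"}
    missing = needed - set(chip.columns)
    if missing:
        raise ValueError(f"ChIP table missing columns: {sorted(missing)}")
    keys = ["sample_id", "antibody", "region"]
    if "replicate" in chip.columns:
        keys.append("replicate")
    rows = []
    for key, grp in chip.groupby(keys, sort=True):
        roles = grp.set_index("role")
        if "chip" not in roles.index or "input" not in roles.index:
            raise ValueError(f"group {key} lacks a chip or input Ct")
        ct_chip = float(grp.loc[grp["role"] == "chip", "ct"].mean())
        ct_input = float(grp.loc[grp["role"] == "input", "ct"].mean())
        dilution = float(grp.loc[grp["role"] == "input", "dilution"].iloc[0])
        rec = pct_recovery(ct_input, ct_chip, dilution)
        rows.append(dict(zip(keys, key)) | {"pct_recovery": rec})
    return pd.DataFrame(rows)


def delta_delta_ct(
    ct_target: float, ct_reference: float, ct_target_cal: float, ct_reference_cal: float
) -> float:
    """Fold change of one sample relative to the calibrator, 2^-ddCt."""
    ddct = (ct_target - ct_reference) - (ct_target_cal - ct_reference_cal)
    return 2.0 ** (-ddct)


def fold_changes(
    expr: pd.DataFrame,
    target: str,
    reference: str,
    calibrator: str,
) -> pd.Series:
    """Per-sample fold change of ``target`` versus ``reference`` gene.

    Replicate Cts are averaged per (sample, gene) first.  Every sample
    must carry the reference gene; the calibrator sample must be present
    and returns exactly 1.0.
    """
    needed = {"sample_id", "target", "ct"}
    missing = needed - set(expr.columns)
    if missing:
        raise ValueError(f"expression table missing columns: {sorted(missing)}")
    mean_ct = expr.groupby(["sample_id", "target"])["ct"].mean().unstack()
    for gene in (target, reference):
        if gene not in mean_ct.columns:
            raise ValueError(f"gene {gene!r} absent from table")
    if calibrator not in mean_ct.index:
        raise ValueError(f"calibrator sample {calibrator!r} absent from table")
    if mean_ct[reference].isna().any():
        bad = mean_ct.index[mean_ct[reference].isna()].tolist()
        raise ValueError(f"missing reference Ct for samples {bad}")
    dct = mean_ct[target] - mean_ct[reference]
    folds = 2.0 ** (-(dct - dct.loc[calibrator]))
    folds.name = "fold_change"
    return folds


def compare_groups(
    group_a: Sequence[float],
    group_b: Sequence[float],
    equal_var: bool = True,
    alpha: float = 0.05,
) -> Tuple[float, float, bool]:
    """Two-sample t-test between measurement groups.

    Classical equal-variance Student's t by default (df = nA + nB - 2);
    ``equal_var=False`` gives Welch's test.  Returns (t, two-sided P,
    significant-at-alpha).  Two degenerate identical constant groups give
    t = 0, P = 1 by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0, False
        return math.copysign(math.inf, a.mean() - b.mean()), 0.0, True
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p), bool(p < alpha)
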