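"""Input-normalized co-IP densitometry: binding folds versus a reference.

A densitometry table holds one row per (condition, replicate) with the
immunoprecipitate (IP) band intensity and the corresponding input band
intensity, in the same arbitrary densitometric units.  Quantification is

1. per-row normalization, ratio = ip_intensity / input_intensity, which
   cancels expression-level differences between lanes;
2. fold versus the reference condition: every row's ratio is divided by the
   *mean* ratio of the reference condition, so the reference mean fold is
   exactly 1.00 AU by construction and a standard error is defined per
   condition;
3. an unpaired pooled-variance two-sided Student's t-test of each condition's
   folds against the reference's folds, with significance stars from a
   configurable threshold map.

Folds are invariant to rescaling all intensities by a common positive
constant, and the estimator is exact on noise-free tables.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "REQUIRED_COLUMNS",
    "DEFAULT_STAR_MAP",
    "BindingResult",
    "read_table",
    "normalize_to_input",
    "fold_vs_reference",
    "quantify",
    "significance_stars",
]

REQUIRED_COLUMNS = ("condition", "replicate", "ip_intensity", "input_intensity")

# (p threshold, stars), most stringent first; drawn from common figure-legend
# conventions (*: P < 0.01, ***: P < 0.001).  Passed explicitly where a
# different legend convention is wanted.
DEFAULT_STAR_MAP: tuple[tuple[float, str], ...] = ((0.001, "***"), (0.01, "*"))


@dataclasses.dataclass
class BindingResult:
    """Per-condition binding summary in arbitrary units (reference = 1.00)."""

    summary: pd.DataFrame  # condition, n, mean_fold, sem_fold, p_value, stars
    folds: pd.DataFrame  # the input table plus ratio and fold columns
    reference: str


def significance_stars(p: float, star_map=DEFAULT_STAR_MAP) -> str:
    if not np.isfinite(p):
        return ""
    for threshold, stars in sorted(star_map):
        if p < threshold:
            return stars
    return ""


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"table is missing columns {missing}")
    if (table["input_intensity"] <= 0).any():
        raise ValueError("input intensities must be positive")
    if (table["ip_intensity"] <= 0).any():
        raise ValueError("IP intensities must be positive")
    counts = table.groupby("condition").size()
    few = counts[counts < 2]
    if not few.empty:
        raise ValueError(f"conditions with fewer than 2 replicates: {list(few.index)}")
    return table


def read_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a densitometry CSV."""
    return _validate(pd.read_csv(path))


def normalize_to_input(table: pd.DataFrame) -> pd.DataFrame:
    """Append the per-row IP/input ratio as a ``ratio`` column."""
    table = _validate(table).copy()
    table["ratio"] = table["ip_intensity"] / table["input_intensity"]
    return table


def fold_vs_reference(
    table: pd.DataFrame,
    reference: str = "WT",
    star_map=DEFAULT_STAR_MAP,
) -> BindingResult:
    """Fold change versus the reference condition with group statistics.

    ``table`` must carry the ``ratio`` column from :func:`normalize_to_input`.
    The reference's p-value is reported as NaN (a condition cannot be tested
    against itself).
    """
    if "ratio" not in table.columns:
        table = normalize_to_input(table)
    conditions = table["condition"].unique()
    if reference not in conditions:
        raise ValueError(f"reference condition {reference!r} not present")
    table = table.copy()
    ref_mean_ratio = table.loc[table["condition"] == reference, "ratio"].mean()
    table["fold"] = table["ratio"] / ref_mean_ratio
    ref_folds = table.loc[table["condition"] == reference, "fold"].to_numpy()

    rows = []
    for label in conditions:
        folds = table.loc[table["condition"] == label, "fold"].to_numpy()
        if label == reference:
            p = math.nan
        else:
            _, p = stats.ttest_ind(folds, ref_folds, equal_var=True)
        rows.append(
            {
                "condition": label,
                "n": folds.size,
                "mean_fold": float(folds.mean()),
                "sem_fold": float(folds.std(ddof=1) / math.sqrt(folds.size)),
                "p_value": float(p),
                "stars": significance_stars(p, star_map),
            }
        )
    return BindingResult(summary=pd.DataFrame(rows), folds=table, reference=reference)


def quantify(
    table: pd.DataFrame, reference: str = "WT", star_map=DEFAULT_STAR_MAP
) -> BindingResult:
    """Normalize to input and compute folds versus the reference in one call."""
    return fold_vs_reference(normalize_to_input(table), reference, star_map)
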