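"""Arrayed siRNA screen statistics.

Normalization of per-well reporter-positive percentages to the control
condition, replicate-level Student's t-tests, hit calling at a fold and
p-value threshold, combinatorial-screen enumeration and comparison to the
most potent single hit, viability gating, agonist blunting calls, and qPCR
relative expression by the 2^-ddCt method.

Tests are run on the raw replicate percentages, not on normalized folds:
dividing each replicate by a noisy control mean would distort the test.
"""

from __future__ import annotations

import itertools
import logging
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("fatebarrier.screen")

__all__ = [
    "read_plate",
    "normalize_and_test",
    "call_hits",
    "enumerate_combinations",
    "compare_to_best_single",
    "blunting_calls",
    "viability_gate",
    "fold_change",
    "ddct_fold",
]

MAX_COMBINATION_ITEMS = 20


def read_plate(path: str | Path) -> pd.DataFrame:
    """Read a screen plate TSV (condition, replicate, percent_positive
    [, cells])."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    need = {"condition", "replicate", "percent_positive"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"plate table missing columns: {sorted(missing)}")
    return df


def normalize_and_test(
    plate: pd.DataFrame,
    control: str = "siControl",
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-condition fold vs control and two-tailed unpaired t-test.

    fold = mean(condition) / mean(control); p from Student's (equal
    variance) t-test of raw replicate values against the control replicates
    (Welch with ``equal_var=False``).  Single-replicate conditions get their
    fold with p = NaN.  Optional ``cells`` column yields a
    ``viability_ratio`` column (mean cells / control mean cells).
    """
    if control not in set(plate["condition"]):
        raise ValueError(f"control condition {control!r} not in plate")
    ctrl = plate.loc[plate["condition"] == control, "percent_positive"].to_numpy(float)
    if len(ctrl) < 2:
        raise ValueError("control needs >= 2 replicates")
    ctrl_mean = float(ctrl.mean())
    if ctrl_mean == 0:
        raise ValueError("control mean is zero; cannot normalize")
    has_cells = "cells" in plate.columns
    ctrl_cells = (
        float(plate.loc[plate["condition"] == control, "cells"].mean()) if has_cells else None
    )
    rows = []
    for cond, sub in plate.groupby("condition", sort=True):
        vals = sub["percent_positive"].to_numpy(float)
        fold = float(vals.mean()) / ctrl_mean
        if cond == control:
            p = 1.0
        elif len(vals) < 2:
            p = np.nan
            logger.info("condition %s has a single replicate: p reported NA", cond)
        else:
            p = float(stats.ttest_ind(vals, ctrl, equal_var=equal_var).pvalue)
        row = {
            "condition": cond,
            "n_replicates": len(vals),
            "mean_percent": float(vals.mean()),
            "fold": fold,
            "p_value": p,
        }
        if has_cells:
            row["viability_ratio"] = (
                float(sub["cells"].mean()) / ctrl_cells if ctrl_cells else np.nan
            )
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["control"] = control
    out.attrs["control_mean"] = ctrl_mean
    return out


def call_hits(
    hit_table: pd.DataFrame,
    fold_min: float = 1.25,
    alpha: float = 0.05,
    direction: Literal["increase", "decrease"] = "increase",
) -> pd.DataFrame:
    """Flag hits: fold strictly > fold_min (or < 1/fold_min for
    ``decrease``) AND p < alpha.  Returns the table with a ``hit`` column.

    No multiple-testing correction is applied to the hit criterion (the
    per-condition p < alpha rule); a BH-adjusted ``padj_bh`` column is
    emitted for reference.
    """
    if direction not in ("increase", "decrease"):
        raise ValueError(f"unknown direction {direction!r}")
    out = hit_table.copy()
    fold = out["fold"].to_numpy(float)
    p = out["p_value"].to_numpy(float)
    passes_fold = fold > fold_min if direction == "increase" else fold < 1.0 / fold_min
    out["hit"] = passes_fold & (p < alpha) & ~np.isnan(p)
    finite = ~np.isnan(p)
    padj = np.full(len(out), np.nan)
    if finite.any():
        from statsmodels.stats.multitest import multipletests

        padj[finite] = multipletests(p[finite], method="fdr_bh")[1]
    out["padj_bh"] = padj
    return out


def enumerate_combinations(items: Sequence[str], min_size: int = 1) -> list[tuple[str, ...]]:
    """All subsets of ``items`` of size >= min_size, ordered by size then
    lexicographically.  For n validated hits and min_size 1 the count is
    2^n - 1 (255 for n = 8)."""
    n = len(items)
    if not (1 <= n <= MAX_COMBINATION_ITEMS):
        raise ValueError(f"need 1 <= n <= {MAX_COMBINATION_ITEMS} items, got {n}")
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    out: list[tuple[str, ...]] = []
    for k in range(min_size, n + 1):
        out.extend(itertools.combinations(sorted(items), k))
    return out


def compare_to_best_single(
    plate: pd.DataFrame,
    singles: Sequence[str],
    combinations: Sequence[str] | None = None,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Compare each combination condition to the most potent single hit.

    The best single is the condition among ``singles`` with the highest mean
    percent-positive.  Each other condition (or the explicit
    ``combinations`` list) is t-tested against the best single's replicates;
    it is flagged when p < alpha AND its mean exceeds the best single's.
    """
    means = plate.groupby("condition")["percent_positive"].mean()
    missing = [s for s in singles if s not in means.index]
    if missing:
        raise ValueError(f"single conditions absent from plate: {missing}")
    best = max(singles, key=lambda s: means[s])
    best_vals = plate.loc[plate["condition"] == best, "percent_positive"].to_numpy(float)
    if len(best_vals) < 2:
        raise ValueError(f"best single {best!r} has < 2 replicates")
    conds = (
        [c for c in means.index if c not in set(singles)]
        if combinations is None
        else list(combinations)
    )
    rows = []
    for cond in conds:
        vals = plate.loc[plate["condition"] == cond, "percent_positive"].to_numpy(float)
        if len(vals) < 2:
            p = np.nan
        elif np.array_equal(np.sort(vals), np.sort(best_vals)) and vals.std() == 0 and best_vals.std() == 0:
            p = 1.0
        else:
            p = float(stats.ttest_ind(vals, best_vals, equal_var=equal_var).pvalue)
        rows.append(
            {
                "condition": cond,
                "mean_percent": float(vals.mean()) if len(vals) else np.nan,
                "best_single": best,
                "best_single_mean": float(best_vals.mean()),
                "fold_vs_best_single": float(vals.mean()) / float(best_vals.mean()),
                "p_value": p,
                "exceeds_best_single": bool(
                    len(vals)
                    and vals.mean() > best_vals.mean()
                    and not np.isnan(p)
                    and p < alpha
                ),
            }
        )
    return pd.DataFrame(rows)


def blunting_calls(
    hit_table: pd.DataFrame,
    reference_condition: str,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Flag conditions that blunt the reference response.

    A condition is *blunted* iff its mean percent-positive is <= threshold x
    the reference condition's mean (a 50% reduction at the default).
    """
    ref_rows = hit_table[hit_table["condition"] == reference_condition]
    if len(ref_rows) == 0:
        raise ValueError(f"reference condition {reference_condition!r} absent")
    ref_mean = float(ref_rows["mean_percent"].iloc[0])
    out = hit_table.copy()
    out["blunted"] = out["mean_percent"] <= threshold * ref_mean
    out.loc[out["condition"] == reference_condition, "blunted"] = False
    return out


def viability_gate(hit_table: pd.DataFrame, min_cells_frac: float = 0.7) -> pd.DataFrame:
    """Flag conditions passing the viability gate: mean cell count >=
    ``min_cells_frac`` of the control's (requires a ``viability_ratio``
    column from :func:`normalize_and_test`)."""
    if "viability_ratio" not in hit_table.columns:
        raise ValueError("hit table has no viability_ratio column (no cells data)")
    out = hit_table.copy()
    out["viable"] = out["viability_ratio"] >= min_cells_frac
    return out


def fold_change(a_percent: float, b_percent: float) -> float:
    """Ratio b/a of two percentages (e.g. 5 -> 16 % gives 3.2)."""
    if a_percent <= 0 or b_percent <= 0:
        raise ValueError("percentages must be > 0")
    return b_percent / a_percent


def ddct_fold(
    ct_target_treated: float,
    ct_ref_treated: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative expression by the 2^-ddCt method.

    ddCt = (Ct_target - Ct_reference)_treated - (Ct_target - Ct_reference)_control;
    returns 2^-ddCt.
    """
    for v in (ct_target_treated, ct_ref_treated, ct_target_ctrl, ct_ref_ctrl):
        if v <= 0:
            raise ValueError("Ct values must be > 0")
    ddct = (ct_target_treated - ct_ref_treated) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct))
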