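"""Chromatin-state stratified binding and pairwise co-occupancy.

Classifies each transcription factor's binding sites as lying in open or
closed chromatin (overlap with an ATAC-derived open-region set) and computes
the pairwise co-occupancy matrix M[a][b] = fraction of a's peaks overlapped
by at least one peak of b.  M is in general not symmetric, because the
fraction is relative to the row factor's peak count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .intervals_core import IntervalSet, intersect, merge_intervals

logger = logging.getLogger("fatebarrier.landscape")

__all__ = ["StateClassification", "CooccupancyMatrix", "classify_by_state", "cooccupancy"]


@dataclass
class StateClassification:
    """Per-peak open/closed call for one factor's peak set."""

    tf_name: str
    states: pd.Series  # "open"/"closed" per peak, aligned to the sorted peak table
    n_open: int
    n_closed: int

    @property
    def total(self) -> int:
        return self.n_open + self.n_closed

    @property
    def frac_open(self) -> float | None:
        """Fraction open, or None (reported as NA) for an empty peak set."""
        return self.n_open / self.total if self.total else None

    @property
    def frac_closed(self) -> float | None:
        return 1.0 - self.frac_open if self.total else None

    def summary_row(self) -> dict:
        fo = self.frac_open
        return {
            "tf": self.tf_name,
            "n_open": self.n_open,
            "n_closed": self.n_closed,
            # fractions reported to 0.1%
            "frac_open": round(fo, 3) if fo is not None else "NA",
            "frac_closed": round(1 - fo, 3) if fo is not None else "NA",
        }


@dataclass
class CooccupancyMatrix:
    """Row-normalized co-occupancy fractions with audit counts."""

    tf_names: list[str]
    matrix: pd.DataFrame  # fractions, rows = a, cols = b
    counts: pd.DataFrame  # numerators (co-occupied peak counts)
    totals: pd.Series  # row denominators (a peak counts in stratum)
    stratum: str = "all"

    def to_frame(self) -> pd.DataFrame:
        out = self.matrix.copy()
        out.insert(0, "stratum", self.stratum)
        return out


def classify_by_state(
    peaks: IntervalSet,
    open_regions: IntervalSet,
    min_overlap_bp: int = 1,
    tf_name: str = "TF",
) -> StateClassification:
    """Call each peak open iff it overlaps the open-region set by >= ``min_overlap_bp``.

    ``open_regions`` is merged internally if not already merged.
    """
    if not open_regions.merged_flag:
        open_regions = merge_intervals(open_regions)
    peaks = peaks if peaks.sorted_flag else peaks.sort()
    if len(peaks) == 0:
        return StateClassification(tf_name, pd.Series(dtype=str), 0, 0)
    rep = intersect(peaks, open_regions, min_overlap_bp=min_overlap_bp)
    states = pd.Series(np.where(rep["overlapped"], "open", "closed"))
    n_open = int(rep["overlapped"].sum())
    return StateClassification(tf_name, states, n_open, len(peaks) - n_open)


def cooccupancy(
    peak_sets: Mapping[str, IntervalSet],
    min_overlap_bp: int = 1,
    stratum: Mapping[str, StateClassification] | None = None,
    stratum_state: str = "open",
    partner_same_stratum: bool = False,
) -> CooccupancyMatrix:
    """Pairwise co-occupancy matrix over named peak sets.

    M[a][b] is the fraction of a's peaks (restricted to ``stratum_state``
    peaks when ``stratum`` classifications are given) overlapped by >= 1 peak
    of b.  By default the partner set b is taken in full; with
    ``partner_same_stratum`` b is restricted to the same stratum.
    """
    names = list(peak_sets)
    if len(names) < 2:
        raise ValueError("need at least two peak sets for co-occupancy")
    if stratum is not None:
        missing = [t for t in names if t not in stratum]
        if missing:
            raise ValueError(f"no state classification for: {missing}")

    def _subset(tf: str) -> IntervalSet:
        s = peak_sets[tf] if peak_sets[tf].sorted_flag else peak_sets[tf].sort()
        if stratum is None:
            return s
        mask = (stratum[tf].states == stratum_state).to_numpy()
        sub = IntervalSet(df=s.df[mask].reset_index(drop=True), sorted_flag=True)
        return sub

    row_sets = {t: _subset(t) for t in names}
    col_sets = row_sets if partner_same_stratum else {
        t: (peak_sets[t] if peak_sets[t].sorted_flag else peak_sets[t].sort())
        for t in names
    }

    frac = pd.DataFrame(np.nan, index=names, columns=names, dtype=float)
    counts = pd.DataFrame(0, index=names, columns=names, dtype=int)
    totals = pd.Series({t: len(row_sets[t]) for t in names}, dtype=int)
    for a in names:
        na = len(row_sets[a])
        for b in names:
            if na == 0:
                continue
            if a == b:
                counts.loc[a, b] = na
                frac.loc[a, b] = 1.0
                continue
            rep = intersect(row_sets[a], col_sets[b], min_overlap_bp=min_overlap_bp)
            k = int(rep["overlapped"].sum())
            counts.loc[a, b] = k
            frac.loc[a, b] = k / na
    strat_label = "all" if stratum is None else stratum_state
    return CooccupancyMatrix(names, frac, counts, totals, stratum=strat_label)
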