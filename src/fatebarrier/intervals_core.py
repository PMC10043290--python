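"""Genomic-interval data model and overlap machinery.

All coordinates are BED-style: 0-based, half-open ``[start, end)``.  The
central container, :class:`IntervalSet`, wraps a :class:`pandas.DataFrame`
with one row per peak and is the atom every downstream stage (chromatin-state
classification, co-occupancy, annotation, domain calling) operates on.

Supported text formats are BED3, BED6 and the 10-column ENCODE narrowPeak
produced by MACS2-style peak callers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("fatebarrier.intervals")

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "PeakFormatError",
    "read_peaks",
    "write_bed",
    "merge_intervals",
    "consolidate_replicates",
    "intersect",
]

#: Column order of the internal peak table.
PEAK_COLUMNS = [
    "chrom",
    "start",
    "end",
    "name",
    "score",
    "strand",
    "signal",
    "neg_log10_p",
    "neg_log10_q",
    "summit_offset",
]

VALID_STRANDS = {"+", "-", "."}


class PeakFormatError(ValueError):
    """Raised when a peak file line cannot be parsed."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic span."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class IntervalSet:
    """An ordered collection of peak records.

    ``df`` holds one row per record with :data:`PEAK_COLUMNS`.  ``sorted_flag``
    asserts per-chromosome non-decreasing starts; ``merged_flag`` additionally
    asserts that no two same-chromosome records overlap or abut.
    """

    df: pd.DataFrame = field(default_factory=lambda: _empty_frame())
    sorted_flag: bool = False
    merged_flag: bool = False

    def __post_init__(self) -> None:
        missing = [c for c in PEAK_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"peak table missing columns: {missing}")
        bad = self.df["start"] >= self.df["end"]
        if bool(bad.any()):
            row = self.df[bad].iloc[0]
            raise ValueError(
                f"record {row['chrom']}:{row['start']}-{row['end']} has start >= end"
            )

    # -- construction ------------------------------------------------------

    @classmethod
    def from_intervals(
        cls,
        intervals: Iterable[tuple],
        names: Sequence[str] | None = None,
    ) -> "IntervalSet":
        """Build from ``(chrom, start, end[, strand])`` tuples."""
        rows = []
        for i, t in enumerate(intervals):
            chrom, start, end = t[0], int(t[1]), int(t[2])
            strand = t[3] if len(t) > 3 else "."
            name = names[i] if names is not None else f"iv{i}"
            rows.append((chrom, start, end, name, 0.0, strand, 0.0, 0.0, 0.0, np.nan))
        df = pd.DataFrame(rows, columns=PEAK_COLUMNS) if rows else _empty_frame()
        return cls(df=df).sort()

    # -- basic protocol ----------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        for row in self.df.itertuples(index=False):
            yield GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand)

    @property
    def total_span(self) -> int:
        """Sum of record lengths (not deduplicated)."""
        return int((self.df["end"] - self.df["start"]).sum())

    def chromosomes(self) -> list[str]:
        return sorted(self.df["chrom"].unique())

    def sort(self) -> "IntervalSet":
        """Return a copy sorted by (chrom, start, end)."""
        df = self.df.sort_values(
            ["chrom", "start", "end"], kind="mergesort"
        ).reset_index(drop=True)
        return IntervalSet(df=df, sorted_flag=True, merged_flag=self.merged_flag)

    def intervals(self) -> list[tuple[str, int, int]]:
        return list(zip(self.df["chrom"], self.df["start"].astype(int), self.df["end"].astype(int)))


def _empty_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=str),
            "start": pd.Series(dtype=np.int64),
            "end": pd.Series(dtype=np.int64),
            "name": pd.Series(dtype=str),
            "score": pd.Series(dtype=float),
            "strand": pd.Series(dtype=str),
            "signal": pd.Series(dtype=float),
            "neg_log10_p": pd.Series(dtype=float),
            "neg_log10_q": pd.Series(dtype=float),
            "summit_offset": pd.Series(dtype=float),
        }
    )


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_FORMAT_MIN_COLS = {"BED3": 3, "BED6": 6, "narrowPeak": 10}


def _parse_int(token: str, line_no: int, what: str) -> int:
    try:
        return int(token)
    except ValueError:
        raise PeakFormatError(f"line {line_no}: non-integer {what} {token!r}") from None


def read_peaks(path: str | Path, format: str = "narrowPeak") -> IntervalSet:
    """Read a BED3/BED6/narrowPeak file into a sorted :class:`IntervalSet`.

    Missing optional columns are filled with neutral defaults (score 0,
    strand '.', summit unset).  Lines starting with ``#``, ``track`` or
    ``browser`` are skipped.

    Raises
    ------
    PeakFormatError
        On malformed coordinates (non-integer or start >= end), naming the
        offending line number.
    ValueError
        On an unknown format token.
    """
    if format not in _FORMAT_MIN_COLS:
        raise ValueError(
            f"unknown format {format!r}; expected one of {sorted(_FORMAT_MIN_COLS)}"
        )
    min_cols = _FORMAT_MIN_COLS[format]
    rows = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < min_cols:
                raise PeakFormatError(
                    f"line {line_no}: expected >= {min_cols} columns for "
                    f"{format}, got {len(fields)}"
                )
            chrom = fields[0]
            start = _parse_int(fields[1], line_no, "start")
            end = _parse_int(fields[2], line_no, "end")
            if start < 0 or start >= end:
                raise PeakFormatError(
                    f"line {line_no}: invalid coordinates {start}-{end} "
                    "(require 0 <= start < end)"
                )
            name = fields[3] if len(fields) > 3 and fields[3] else f"peak{line_no}"
            score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            strand = fields[5] if len(fields) > 5 and fields[5] in VALID_STRANDS else "."
            signal = p = q = 0.0
            summit: float = np.nan
            if format == "narrowPeak":
                signal = float(fields[6]) if fields[6] != "." else 0.0
                p = float(fields[7]) if fields[7] != "." else 0.0
                q = float(fields[8]) if fields[8] != "." else 0.0
                s = _parse_int(fields[9], line_no, "summit")
                if s >= 0:
                    if s >= end - start:
                        raise PeakFormatError(
                            f"line {line_no}: summit offset {s} outside peak of "
                            f"length {end - start}"
                        )
                    summit = float(s)
            rows.append((chrom, start, end, name, score, strand, signal, p, q, summit))
    df = pd.DataFrame(rows, columns=PEAK_COLUMNS) if rows else _empty_frame()
    return IntervalSet(df=df).sort()


def write_bed(s: IntervalSet, path: str | Path, header: str | None = None) -> None:
    """Write an interval set as BED6 with an optional ``#`` provenance header."""
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for row in s.df.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{int(row.start)}\t{int(row.end)}\t"
                f"{row.name}\t{row.score:g}\t{row.strand}\n"
            )


# ---------------------------------------------------------------------------
# Merge / consolidate
# ---------------------------------------------------------------------------


def merge_intervals(s: IntervalSet, gap: int = 0) -> IntervalSet:
    """Union records that overlap or lie within ``gap`` bp of each other.

    Sweep-line over per-chromosome sorted starts; idempotent and
    order-invariant.  The output carries synthetic names and neutral scores.
    """
    if gap < 0:
        raise ValueError(f"gap must be >= 0, got {gap}")
    if len(s) == 0:
        return IntervalSet(df=_empty_frame(), sorted_flag=True, merged_flag=True)
    df = s.df.sort_values(["chrom", "start", "end"], kind="mergesort")
    out_rows = []
    for chrom, sub in df.groupby("chrom", sort=True):
        starts = sub["start"].to_numpy(dtype=np.int64)
        ends = sub["end"].to_numpy(dtype=np.int64)
        cur_s, cur_e = starts[0], ends[0]
        for st, en in zip(starts[1:], ends[1:]):
            if st <= cur_e + gap:
                cur_e = max(cur_e, en)
            else:
                out_rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = st, en
        out_rows.append((chrom, cur_s, cur_e))
    out = IntervalSet.from_intervals(out_rows, names=[f"m{i}" for i in range(len(out_rows))])
    out.merged_flag = True
    return out


def consolidate_replicates(
    reps: Sequence[IntervalSet],
    mode: Literal["union_merge", "intersection"] = "union_merge",
) -> IntervalSet:
    """Consolidate replicate peak sets into a single peak set per factor.

    ``union_merge`` (default) merges the concatenation of all replicates —
    peaks merged across samples.  ``intersection`` keeps only the parts of
    the merged union that are covered by at least one peak in *every*
    replicate, i.e. reproducibility filtering.
    """
    if len(reps) == 0:
        raise ValueError("need at least one replicate")
    if mode not in ("union_merge", "intersection"):
        raise ValueError(f"unknown mode {mode!r}")
    concat = IntervalSet(
        df=pd.concat([r.df for r in reps], ignore_index=True)
        if any(len(r) for r in reps)
        else _empty_frame()
    )
    union = merge_intervals(concat.sort(), gap=0)
    if mode == "union_merge":
        return union
    # Intersection of coverage: clip the union down to bp covered in every
    # replicate, via per-replicate merged coverage.
    merged_reps = [merge_intervals(r, gap=0) for r in reps]
    pieces = union
    for mr in merged_reps:
        pieces = _coverage_intersection(pieces, mr)
    pieces.merged_flag = True
    return pieces


def _coverage_intersection(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """bp-wise intersection of two merged interval sets."""
    out: list[tuple[str, int, int]] = []
    b_by_chrom = {c: sub for c, sub in b.df.groupby("chrom")}
    for chrom, sub in a.df.groupby("chrom", sort=True):
        if chrom not in b_by_chrom:
            continue
        bs = b_by_chrom[chrom]["start"].to_numpy(np.int64)
        be = b_by_chrom[chrom]["end"].to_numpy(np.int64)
        for st, en in zip(sub["start"].to_numpy(np.int64), sub["end"].to_numpy(np.int64)):
            lo = int(np.searchsorted(be, st, side="right"))
            hi = int(np.searchsorted(bs, en, side="left"))
            for j in range(lo, hi):
                o_s, o_e = max(st, bs[j]), min(en, be[j])
                if o_s < o_e:
                    out.append((chrom, int(o_s), int(o_e)))
    res = IntervalSet.from_intervals(out, names=[f"i{i}" for i in range(len(out))])
    return res


# ---------------------------------------------------------------------------
# Intersection / pairing report
# ---------------------------------------------------------------------------


def intersect(
    a: IntervalSet,
    b: IntervalSet,
    min_overlap_bp: int = 1,
    min_overlap_frac: float = 0.0,
    auto_sort: bool = True,
) -> pd.DataFrame:
    """Per-``a``-record overlap report against ``b``.

    A record of ``a`` is *overlapped* iff some record of ``b`` shares at least
    ``min_overlap_bp`` bp AND at least ``min_overlap_frac`` of the a-record's
    length.  The report has one row per a-record (in a's sorted order) with
    columns ``overlapped`` (bool), ``best_partner`` (positional index into
    b's sorted table, -1 if none) and ``overlap_bp`` (bp with best partner).

    Best partner is the b-record with the largest overlap; ties broken by
    smaller b start.  The call is not symmetric: swap the arguments for the
    converse report.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    if not (0.0 <= min_overlap_frac <= 1.0):
        raise ValueError("min_overlap_frac must lie in [0, 1]")
    if not a.sorted_flag or not b.sorted_flag:
        if not auto_sort:
            raise ValueError("inputs must be sorted (or pass auto_sort=True)")
        logger.info("intersect: auto-sorting unsorted input")
    a = a if a.sorted_flag else a.sort()
    b = b if b.sorted_flag else b.sort()

    n = len(a)
    overlapped = np.zeros(n, dtype=bool)
    best_partner = np.full(n, -1, dtype=np.int64)
    overlap_bp = np.zeros(n, dtype=np.int64)

    # positional index of b rows per chromosome
    b_pos = np.arange(len(b))
    b_groups: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, sub in b.df.groupby("chrom"):
        idx = b_pos[b.df["chrom"].to_numpy() == chrom]
        bs = sub["start"].to_numpy(np.int64)
        be = sub["end"].to_numpy(np.int64)
        b_groups[chrom] = (bs, be, np.maximum.accumulate(be), idx)

    a_chrom = a.df["chrom"].to_numpy()
    a_start = a.df["start"].to_numpy(np.int64)
    a_end = a.df["end"].to_numpy(np.int64)
    for i in range(n):
        grp = b_groups.get(a_chrom[i])
        if grp is None:
            continue
        bs, be, be_cummax, idx = grp
        st, en = a_start[i], a_end[i]
        lo = int(np.searchsorted(be_cummax, st, side="right"))
        hi = int(np.searchsorted(bs, en, side="left"))
        if lo >= hi:
            continue
        ov = np.minimum(en, be[lo:hi]) - np.maximum(st, bs[lo:hi])
        ov = np.where(ov > 0, ov, 0)
        j = int(np.argmax(ov))  # argmax returns first max -> smallest start tie-break
        best = int(ov[j])
        if best <= 0:
            continue
        alen = en - st
        if best >= min_overlap_bp and best >= min_overlap_frac * alen:
            overlapped[i] = True
            best_partner[i] = idx[lo + j]
            overlap_bp[i] = best
    return pd.DataFrame(
        {
            "chrom": a_chrom,
            "start": a_start,
            "end": a_end,
            "name": a.df["name"].to_numpy(),
            "overlapped": overlapped,
            "best_partner": best_partner,
            "overlap_bp": overlap_bp,
        }
    )
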