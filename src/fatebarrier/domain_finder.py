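"""Pseudobulk accessibility and differential-accessibility domain calling.

From a per-cell fragment table and a barcode-to-cluster assignment, builds a
regions x cluster-groups pseudobulk count matrix, normalizes to fragments
per million per kb, and calls *domain 1* regions (open in the reference
group, closed in the target group) and *domain 2* regions (the converse).
A call requires both the open/closed signal pattern and a
Benjamini-Hochberg-adjusted two-proportion test at the chosen FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals_core import IntervalSet

logger = logging.getLogger("fatebarrier.domains")

__all__ = [
    "FragmentTable",
    "AccessibilityMatrix",
    "read_fragments",
    "read_clusters",
    "pseudobulk",
    "call_domains",
    "domain_summary",
    "binding_density_in_domains",
    "tss_differential_accessibility",
]

HISTOGRAM_BINS = [0, 200, 400, 600, 800, 1000, np.inf]


@dataclass
class FragmentTable:
    """Fragments (chrom, start, end, barcode) plus barcode->cluster labels.

    Fragments whose barcode has no cluster label are excluded with a logged
    count.
    """

    df: pd.DataFrame
    clusters: pd.Series  # index barcode -> cluster id

    def __post_init__(self) -> None:
        need = {"chrom", "start", "end", "barcode"}
        if not need.issubset(self.df.columns):
            raise ValueError(f"fragment table needs columns {sorted(need)}")
        if bool((self.df["start"] >= self.df["end"]).any()):
            raise ValueError("fragment with start >= end")
        labeled = self.df["barcode"].isin(self.clusters.index)
        n_drop = int((~labeled).sum())
        if n_drop:
            logger.info("excluding %d fragments with unlabeled barcodes", n_drop)
            self.df = self.df[labeled].reset_index(drop=True)

    def cluster_of(self) -> pd.Series:
        return self.df["barcode"].map(self.clusters)


@dataclass
class AccessibilityMatrix:
    """Pseudobulk counts C[region, group] with per-group depths.

    ``normalized`` is fragments per million per kb:
    N[r, g] = C[r, g] * 1e6 / (D[g] * length_kb(r)).
    """

    regions: IntervalSet
    counts: pd.DataFrame  # index region position, columns group names
    depths: pd.Series  # total fragments per group

    @property
    def normalized(self) -> pd.DataFrame:
        length_kb = (
            (self.regions.df["end"] - self.regions.df["start"]).to_numpy(float) / 1000.0
        )
        n = self.counts.to_numpy(float) * 1e6
        n /= self.depths.to_numpy(float)[None, :]
        n /= length_kb[:, None]
        return pd.DataFrame(n, index=self.counts.index, columns=self.counts.columns)


def read_fragments(path: str | Path) -> pd.DataFrame:
    """Read a 4+ column fragments TSV (chrom, start, end, barcode); plain or
    gzipped, with or without header."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :4]
    df.columns = ["chrom", "start", "end", "barcode"]
    if df.iloc[0]["chrom"] == "chrom":  # header row present
        df = df.iloc[1:].reset_index(drop=True)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def read_clusters(path: str | Path) -> pd.Series:
    """Read a 2-column barcode -> cluster TSV."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if str(df.iloc[0, 0]) in ("barcode", "cell"):
        df = df.iloc[1:].reset_index(drop=True)
    s = pd.Series(df.iloc[:, 1].astype(str).to_numpy(), index=df.iloc[:, 0].astype(str))
    s.name = "cluster"
    return s


def pseudobulk(
    frags: FragmentTable,
    regions: IntervalSet,
    groups: Mapping[str, Sequence],
) -> AccessibilityMatrix:
    """Count fragments per region per cluster group.

    A fragment counts once in every region it overlaps by >= 1 bp (regions
    are expected merged, hence non-overlapping); every fragment of a group
    contributes to that group's depth whether or not it falls in a region.
    Groups must be disjoint cluster-id sets and nonempty in cells.
    """
    seen: set = set()
    for gname, cl in groups.items():
        cl = set(cl)
        if cl & seen:
            raise ValueError(f"cluster groups are not disjoint at group {gname!r}")
        seen |= cl
        if not any(c in cl for c in frags.clusters.to_numpy()):
            raise ValueError(f"group {gname!r} has no cells")
    regions = regions if regions.sorted_flag else regions.sort()
    rdf = regions.df
    cluster_per_frag = frags.cluster_of()
    counts = np.zeros((len(rdf), len(groups)), dtype=np.int64)
    depths = {}
    for gi, (gname, cl) in enumerate(groups.items()):
        sub = frags.df[cluster_per_frag.isin(set(cl)).to_numpy()]
        depths[gname] = len(sub)
        for chrom, csub in sub.groupby("chrom"):
            rmask = (rdf["chrom"] == chrom).to_numpy()
            if not rmask.any():
                continue
            r_start = rdf.loc[rmask, "start"].to_numpy(np.int64)
            r_end = rdf.loc[rmask, "end"].to_numpy(np.int64)
            fs = np.sort(csub["start"].to_numpy(np.int64))
            fe = np.sort(csub["end"].to_numpy(np.int64))
            # overlap >= 1 bp  <=>  frag.start < r.end  and  frag.end > r.start
            n_before_end = np.searchsorted(fs, r_end, side="left")
            n_ending_before = np.searchsorted(fe, r_start, side="right")
            counts[rmask, gi] = n_before_end - n_ending_before
    cdf = pd.DataFrame(counts, columns=list(groups))
    return AccessibilityMatrix(regions, cdf, pd.Series(depths, dtype=np.int64))


def _two_proportion_p(x1, n1, x2, n2) -> np.ndarray:
    """Vectorized two-sided two-proportion z-test (pooled SE)."""
    x1 = np.asarray(x1, float)
    x2 = np.asarray(x2, float)
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, (p1 - p2) / se, 0.0)
    return 2.0 * stats.norm.sf(np.abs(z))


def default_taus(mat: AccessibilityMatrix, groups: Sequence[str]) -> tuple[float, float]:
    """(tau_open, tau_closed) = (2x, 0.5x) the median of nonzero normalized
    signal across the given groups."""
    n = mat.normalized[list(groups)].to_numpy().ravel()
    nz = n[n > 0]
    med = float(np.median(nz)) if nz.size else 1.0
    return 2.0 * med, 0.5 * med


def call_domains(
    mat: AccessibilityMatrix,
    ref_group: str,
    tgt_group: str,
    tau_open: float | None = None,
    tau_closed: float | None = None,
    alpha: float = 0.05,
    merge_gap: int = 0,
) -> pd.DataFrame:
    """Call domain-1 / domain-2 regions between two pseudobulk groups.

    A region is *open* in a group iff its normalized signal >= ``tau_open``
    and *closed* iff <= ``tau_closed`` (in between: buffer zone, no call).
    domain1 = open(ref) and closed(tgt); domain2 = the converse.  Calls also
    require BH-adjusted two-proportion q <= ``alpha``.  Adjacent same-class
    calls within ``merge_gap`` bp are merged (q of a merged call = min q).

    Returns a DataFrame (chrom, start, end, domain_class, n_ref, n_tgt,
    p_value, q_value) sorted by position; exactly antisymmetric under
    swapping ref and tgt (domain1 <-> domain2).
    """
    if tau_open is None or tau_closed is None:
        t_open, t_closed = default_taus(mat, [ref_group, tgt_group])
        tau_open = t_open if tau_open is None else tau_open
        tau_closed = t_closed if tau_closed is None else tau_closed
    if tau_closed >= tau_open:
        raise ValueError("tau_closed must be < tau_open")
    norm = mat.normalized
    n_ref = norm[ref_group].to_numpy()
    n_tgt = norm[tgt_group].to_numpy()
    x_ref = mat.counts[ref_group].to_numpy()
    x_tgt = mat.counts[tgt_group].to_numpy()
    p = _two_proportion_p(x_ref, int(mat.depths[ref_group]), x_tgt, int(mat.depths[tgt_group]))
    q = multipletests(p, method="fdr_bh")[1]
    d1 = (n_ref >= tau_open) & (n_tgt <= tau_closed)
    d2 = (n_tgt >= tau_open) & (n_ref <= tau_closed)
    called = (d1 | d2) & (q <= alpha)
    rdf = mat.regions.df
    out = pd.DataFrame(
        {
            "chrom": rdf["chrom"].to_numpy()[called],
            "start": rdf["start"].to_numpy(np.int64)[called],
            "end": rdf["end"].to_numpy(np.int64)[called],
            "domain_class": np.where(d1[called], "domain1", "domain2"),
            "n_ref": n_ref[called],
            "n_tgt": n_tgt[called],
            "p_value": p[called],
            "q_value": q[called],
        }
    ).sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    if merge_gap >= 0 and len(out) > 1:
        out = _merge_adjacent_calls(out, merge_gap)
    return out


def _merge_adjacent_calls(calls: pd.DataFrame, gap: int) -> pd.DataFrame:
    rows = []
    for (chrom, cls), sub in calls.groupby(["chrom", "domain_class"], sort=True):
        sub = sub.sort_values("start")
        cur = None
        for r in sub.itertuples(index=False):
            if cur is not None and r.start <= cur["end"] + gap:
                cur["end"] = max(cur["end"], r.end)
                cur["q_value"] = min(cur["q_value"], r.q_value)
                cur["p_value"] = min(cur["p_value"], r.p_value)
            else:
                if cur is not None:
                    rows.append(cur)
                cur = {
                    "chrom": chrom,
                    "start": int(r.start),
                    "end": int(r.end),
                    "domain_class": cls,
                    "n_ref": r.n_ref,
                    "n_tgt": r.n_tgt,
                    "p_value": r.p_value,
                    "q_value": r.q_value,
                }
        if cur is not None:
            rows.append(cur)
    return (
        pd.DataFrame(rows)
        .sort_values(["chrom", "start"], kind="mergesort")
        .reset_index(drop=True)
    )


def domain_summary(calls: pd.DataFrame) -> dict:
    """Per-class region counts, total spans, length histogram and
    per-chromosome counts.  Histogram bins default to
    [0, 200), [200, 400), ..., [1000, inf) bp."""
    out: dict = {}
    for cls in ("domain1", "domain2"):
        sub = calls[calls["domain_class"] == cls] if len(calls) else calls
        lengths = (
            (sub["end"] - sub["start"]).to_numpy(np.int64) if len(sub) else np.array([], int)
        )
        hist, _ = np.histogram(lengths, bins=HISTOGRAM_BINS)
        per_chrom = (
            sub.groupby("chrom").size().to_dict() if len(sub) else {}
        )
        out[cls] = {
            "n_regions": int(len(sub)),
            "total_span_bp": int(lengths.sum()),
            "length_histogram": {
                f"[{int(lo)},{'inf' if np.isinf(hi) else int(hi)})": int(c)
                for lo, hi, c in zip(HISTOGRAM_BINS[:-1], HISTOGRAM_BINS[1:], hist)
            },
            "per_chromosome": per_chrom,
        }
    return out


def binding_density_in_domains(
    calls: pd.DataFrame, peak_sets: Mapping[str, IntervalSet]
) -> pd.DataFrame:
    """Per-factor binding density (peaks per Mbp) in each domain class.

    A peak counts for a class if it overlaps any region of that class by
    >= 1 bp; density = count * 1e6 / class span (NA when the span is 0).
    """
    from .intervals_core import intersect

    rows = []
    for cls in ("domain1", "domain2"):
        sub = calls[calls["domain_class"] == cls] if len(calls) else calls.iloc[0:0]
        span = int((sub["end"] - sub["start"]).sum()) if len(sub) else 0
        cls_set = IntervalSet.from_intervals(
            list(zip(sub["chrom"], sub["start"], sub["end"]))
        )
        for tf, peaks in peak_sets.items():
            if span == 0 or len(peaks) == 0:
                n_olap = 0
            else:
                rep = intersect(peaks if peaks.sorted_flag else peaks.sort(), cls_set)
                n_olap = int(rep["overlapped"].sum())
            rows.append(
                {
                    "domain_class": cls,
                    "tf": tf,
                    "n_peaks": n_olap,
                    "span_bp": span,
                    "peaks_per_mbp": (n_olap * 1e6 / span) if span else np.nan,
                }
            )
    return pd.DataFrame(rows)


def tss_differential_accessibility(
    mat: AccessibilityMatrix,
    ref_group: str,
    tgt_group: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Gene-level differential accessibility over core-promoter regions.

    The matrix regions must be promoter windows named by gene_id (duplicate
    gene_ids have their counts summed).  Two-proportion test per gene with
    BH correction; ``called`` genes have q <= alpha, with direction
    "more_accessible_in_target" or "more_accessible_in_reference".  Sorted
    by q ascending.
    """
    gene_ids = mat.regions.df["name"].to_numpy()
    df = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "x_ref": mat.counts[ref_group].to_numpy(),
            "x_tgt": mat.counts[tgt_group].to_numpy(),
        }
    )
    agg = df.groupby("gene_id", sort=True).sum()
    n_ref, n_tgt = int(mat.depths[ref_group]), int(mat.depths[tgt_group])
    p = _two_proportion_p(agg["x_ref"], n_ref, agg["x_tgt"], n_tgt)
    q = multipletests(p, method="fdr_bh")[1]
    rate_ref = agg["x_ref"].to_numpy() / n_ref
    rate_tgt = agg["x_tgt"].to_numpy() / n_tgt
    out = pd.DataFrame(
        {
            "gene_id": agg.index,
            "x_ref": agg["x_ref"].to_numpy(),
            "x_tgt": agg["x_tgt"].to_numpy(),
            "p_value": p,
            "q_value": q,
            "called": q <= alpha,
            "direction": np.where(
                rate_tgt > rate_ref,
                "more_accessible_in_target",
                np.where(
                    rate_tgt < rate_ref, "more_accessible_in_reference", "unchanged"
                ),
            ),
        }
    )
    return out.sort_values(["q_value", "gene_id"], kind="mergesort").reset_index(drop=True)
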