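"""Gene models, core-promoter windows and peak-to-feature annotation.

The core-promoter window is the strand-aware interval from 1 kb upstream to
0.1 kb downstream of a gene's TSS.  Peaks are assigned to exactly one
feature by their midpoint (summit when available) with priority
core_promoter > exon > intron > TTS_flank > intergenic.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .intervals_core import GenomicInterval, IntervalSet, intersect

logger = logging.getLogger("fatebarrier.annotation")

__all__ = [
    "GeneModel",
    "FeatureAssignment",
    "read_gtf",
    "write_gtf",
    "core_promoter_window",
    "promoter_windows_set",
    "annotate_peaks",
    "promoter_bound_genes",
]

FEATURES = ["core_promoter", "exon", "intron", "TTS_flank", "intergenic"]
TTS_FLANK_BP = 1000


@dataclass
class GeneModel:
    """Minimal gene model: id, strand, TSS/TES, exon spans.

    ``tss`` is the transcription start in genome coordinates, so on the minus
    strand tss > tes.  Exons are 0-based half-open and lie within the gene
    body.
    """

    gene_id: str
    gene_name: str
    chrom: str
    strand: str  # "+" or "-"
    tss: int
    tes: int
    exons: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.strand == "+" and not self.tss < self.tes:
            raise ValueError(f"gene {self.gene_id}: + strand requires tss < tes")
        if self.strand == "-" and not self.tss > self.tes:
            raise ValueError(f"gene {self.gene_id}: - strand requires tss > tes")

    @property
    def body_start(self) -> int:
        return min(self.tss, self.tes)

    @property
    def body_end(self) -> int:
        return max(self.tss, self.tes)


@dataclass
class FeatureAssignment:
    peak_name: str
    feature: str
    gene_id: str  # "none" for intergenic
    distance_to_tss: float  # signed bp; NaN for intergenic


# ---------------------------------------------------------------------------
# GTF I/O — gene and exon rows, 1-based closed converted to 0-based half-open
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def _parse_attrs(s: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(s))


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Read gene models from GTF (``gene`` rows; ``exon`` rows when present).

    When no ``gene`` rows exist, gene extents are derived from the span of
    each gene's transcripts/exons.
    """
    genes: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                continue
            chrom, _src, feature, start1, end1, _score, strand, _frame, attrs = f[:9]
            if feature not in ("gene", "exon", "transcript"):
                continue
            a = _parse_attrs(attrs)
            gid = a.get("gene_id")
            if gid is None:
                continue
            start0, end0 = int(start1) - 1, int(end1)  # to 0-based half-open
            g = genes.get(gid)
            if g is None:
                g = {
                    "gene_name": a.get("gene_name", gid),
                    "chrom": chrom,
                    "strand": strand,
                    "lo": None,
                    "hi": None,
                    "has_gene_row": False,
                    "exons": [],
                }
                genes[gid] = g
                order.append(gid)
            if feature == "gene":
                g["lo"], g["hi"] = start0, end0
                g["has_gene_row"] = True
            elif feature == "exon":
                g["exons"].append((start0, end0))
                if not g["has_gene_row"]:
                    g["lo"] = start0 if g["lo"] is None else min(g["lo"], start0)
                    g["hi"] = end0 if g["hi"] is None else max(g["hi"], end0)
            else:  # transcript
                if not g["has_gene_row"]:
                    g["lo"] = start0 if g["lo"] is None else min(g["lo"], start0)
                    g["hi"] = end0 if g["hi"] is None else max(g["hi"], end0)
    models = []
    for gid in order:
        g = genes[gid]
        if g["lo"] is None:
            logger.warning("gene %s has no coordinates; skipped", gid)
            continue
        tss, tes = (g["lo"], g["hi"]) if g["strand"] == "+" else (g["hi"], g["lo"])
        exons = [
            GenomicInterval(g["chrom"], s, e, g["strand"]) for s, e in sorted(g["exons"])
        ]
        models.append(
            GeneModel(gid, g["gene_name"], g["chrom"], g["strand"], tss, tes, exons)
        )
    return models


def write_gtf(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene + exon rows (1-based closed coordinates)."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.gene_name}";'
            fh.write(
                f"{g.chrom}\tfatebarrier\tgene\t{g.body_start + 1}\t{g.body_end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            for ex in g.exons:
                fh.write(
                    f"{g.chrom}\tfatebarrier\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{g.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# Core-promoter windows
# ---------------------------------------------------------------------------


def core_promoter_window(
    g: GeneModel, upstream: int = 1000, downstream: int = 100
) -> GenomicInterval:
    """Strand-aware promoter window around the TSS, clipped at position 0.

    On the + strand the window is [tss - upstream, tss + downstream); on the
    - strand it is mirrored about the TSS: [tss - downstream, tss + upstream).
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("upstream/downstream must be >= 0")
    if upstream == 0 and downstream == 0:
        raise ValueError("upstream and downstream cannot both be 0")
    if g.strand == "+":
        start, end = g.tss - upstream, g.tss + downstream
    else:
        start, end = g.tss - downstream, g.tss + upstream
    start = max(0, start)
    if start >= end:
        raise ValueError(f"gene {g.gene_id}: promoter window empty after clipping")
    return GenomicInterval(g.chrom, start, end, g.strand)


def promoter_windows_set(
    genes: Sequence[GeneModel], upstream: int = 1000, downstream: int = 100
) -> IntervalSet:
    """Core-promoter windows as an IntervalSet named by gene_id."""
    ivs, names = [], []
    for g in genes:
        w = core_promoter_window(g, upstream, downstream)
        ivs.append((w.chrom, w.start, w.end, g.strand))
        names.append(g.gene_id)
    return IntervalSet.from_intervals(ivs, names=names)


# ---------------------------------------------------------------------------
# Feature annotation
# ---------------------------------------------------------------------------


def _midpoints(peaks: IntervalSet) -> np.ndarray:
    """Peak midpoints; summit position when set."""
    start = peaks.df["start"].to_numpy(np.int64)
    end = peaks.df["end"].to_numpy(np.int64)
    mid = (start + end) // 2
    summit = peaks.df["summit_offset"].to_numpy(float)
    has = ~np.isnan(summit)
    mid[has] = start[has] + summit[has].astype(np.int64)
    return mid


def annotate_peaks(
    peaks: IntervalSet,
    genes: Sequence[GeneModel],
    upstream: int = 1000,
    downstream: int = 100,
) -> tuple[list[FeatureAssignment], pd.DataFrame]:
    """Assign each peak to one feature by its midpoint.

    Priority: core_promoter > exon > intron > TTS_flank (TES +/- 1 kb) >
    intergenic.  A midpoint inside several genes' windows goes to the gene
    with the nearest TSS (ties by lexicographically smaller gene_id).

    Returns the per-peak assignments and a feature-distribution summary with
    counts and percentages (a partition of the peak count).
    """
    peaks = peaks if peaks.sorted_flag else peaks.sort()
    mids = _midpoints(peaks)
    chroms = peaks.df["chrom"].to_numpy()
    names = peaks.df["name"].to_numpy()

    genes_by_chrom: dict[str, list[GeneModel]] = {}
    promoters: dict[str, GenomicInterval] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)
        promoters[g.gene_id] = core_promoter_window(g, upstream, downstream)

    assignments: list[FeatureAssignment] = []
    for pname, chrom, mid in zip(names, chroms, mids):
        cands: list[tuple[int, str, str, int]] = []  # (priority, gene_id, feature, |dist|)
        for g in genes_by_chrom.get(chrom, []):
            dist = int(mid - g.tss) if g.strand == "+" else int(g.tss - mid)
            w = promoters[g.gene_id]
            if w.start <= mid < w.end:
                cands.append((0, g.gene_id, "core_promoter", abs(dist)))
                continue
            if g.body_start <= mid < g.body_end:
                in_exon = any(ex.start <= mid < ex.end for ex in g.exons)
                feat = "exon" if in_exon else "intron"
                cands.append((1 if in_exon else 2, g.gene_id, feat, abs(dist)))
                continue
            tes = g.tes
            if tes - TTS_FLANK_BP <= mid < tes + TTS_FLANK_BP:
                cands.append((3, g.gene_id, "TTS_flank", abs(dist)))
        if not cands:
            assignments.append(FeatureAssignment(pname, "intergenic", "none", float("nan")))
            continue
        # best priority first; among those, nearest TSS, then smaller gene_id
        cands.sort(key=lambda c: (c[0], c[3], c[1]))
        _prio, gid, feat, _ = cands[0]
        g = next(x for x in genes_by_chrom[chrom] if x.gene_id == gid)
        signed = int(mid - g.tss) if g.strand == "+" else int(g.tss - mid)
        assignments.append(FeatureAssignment(pname, feat, gid, float(signed)))

    counts = {f: 0 for f in FEATURES}
    for a in assignments:
        counts[a.feature] += 1
    total = max(1, len(assignments))
    summary = pd.DataFrame(
        {
            "feature": FEATURES,
            "count": [counts[f] for f in FEATURES],
            "percent": [100.0 * counts[f] / total for f in FEATURES],
        }
    )
    return assignments, summary


def promoter_bound_genes(
    peak_sets: dict[str, IntervalSet],
    genes: Sequence[GeneModel],
    upstream: int = 1000,
    downstream: int = 100,
    min_overlap_bp: int = 1,
) -> pd.DataFrame:
    """Per-gene promoter-binding flags for each factor.

    A gene is flagged for factor t iff >= 1 peak of t overlaps the gene's
    core-promoter window by >= ``min_overlap_bp`` (half-open semantics: a
    peak starting exactly at the window end does not bind).  Duplicated
    gene_ids keep the first model (warning logged).

    Returns a DataFrame indexed by gene_id with one boolean column per
    factor plus ``bound_any``.
    """
    seen: dict[str, GeneModel] = {}
    for g in genes:
        if g.gene_id in seen:
            logger.warning("duplicated gene_id %s: keeping first", g.gene_id)
            continue
        seen[g.gene_id] = g
    uniq = list(seen.values())
    windows = promoter_windows_set(uniq, upstream, downstream)
    out = pd.DataFrame(index=[g.gene_id for g in uniq])
    out.index.name = "gene_id"
    win_names = windows.df["name"].to_numpy()
    for tf, peaks in peak_sets.items():
        rep = intersect(windows, peaks, min_overlap_bp=min_overlap_bp)
        flags = pd.Series(rep["overlapped"].to_numpy(), index=win_names)
        out[tf] = flags.reindex(out.index).fillna(False).astype(bool)
    out["bound_any"] = out.any(axis=1) if len(peak_sets) else False
    return out
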