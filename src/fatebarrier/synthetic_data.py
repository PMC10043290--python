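"""Synthetic multi-omics fixtures with planted ground truth.

Generates every input the pipeline consumes — toy genome FASTA + GTF,
per-factor replicate narrowPeak files, open-chromatin BED, region sequences
with planted motif occurrences, single-cell fragment tables with planted
differentially-accessible domains, DE tables with planted promoter-binding
structure, and screen plate tables — together with a machine-readable truth
bundle, so each analysis stage has a parameter-recovery test.

Planted quantities are *realized* quantities: open/closed placement, binding
flags and motif occurrence counts are written exactly (estimation noise then
lives downstream, where it belongs), while fragment counts and replicate
percentages are sampled from the stated noise models.

Seeding: a single master seed expands into per-generator child seeds through
``numpy`` ``SeedSequence(master, spawn_key=(k,))`` with a fixed index per
generator, so regenerating one input never perturbs the others.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel, write_gtf
from .intervals_core import GenomicInterval, IntervalSet, merge_intervals, write_bed

logger = logging.getLogger("fatebarrier.synthetic")

__all__ = [
    "child_rng",
    "make_genome",
    "make_open_regions",
    "make_peaks",
    "make_motif_regions",
    "make_fragments",
    "make_de_table",
    "make_screen_plate",
    "make_combination_plate",
    "make_agonist_plate",
    "simulate",
]

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Fixed per-generator spawn indices for the master-seed expansion.
GENERATOR_KEYS = {
    "genome": 0,
    "open_regions": 1,
    "peaks": 2,
    "motifs": 3,
    "fragments": 4,
    "de": 5,
    "screen": 6,
    "combo": 7,
    "agonist": 8,
}

#: Default per-factor open-chromatin fractions, mirroring the binding
#: landscape of the four barrier factors (JUNB/ZNF207 mostly open, ATF7IP/SP7
#: mostly closed).
DEFAULT_OPEN_FRACTIONS = {"ATF7IP": 0.21, "JUNB": 0.78, "SP7": 0.03, "ZNF207": 0.94}

#: Default planted co-occupancy: fraction of the row factor's peaks whose
#: centers are duplicated into the column factor's peak set.
DEFAULT_COOCCUPANCY = {
    ("ATF7IP", "JUNB"): 0.50,
    ("ZNF207", "JUNB"): 0.97,
    ("SP7", "ATF7IP"): 0.70,
}


def child_rng(master_seed: int, generator: str) -> np.random.Generator:
    """Deterministic child RNG for a named generator."""
    if generator not in GENERATOR_KEYS:
        raise ValueError(f"unknown generator {generator!r}")
    ss = np.random.SeedSequence(master_seed, spawn_key=(GENERATOR_KEYS[generator],))
    return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# Genome + gene models
# ---------------------------------------------------------------------------


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(BASES, size=length, p=p).tobytes().decode("ascii")


def _place_nonoverlapping(
    rng: np.random.Generator,
    chrom_sizes: Mapping[str, int],
    lengths: Sequence[int],
    max_tries: int = 200,
    margin: int = 0,
    forbidden: list[tuple[str, int, int]] | None = None,
) -> list[tuple[str, int, int]]:
    """Place intervals of the given lengths uniformly without mutual overlap
    (rejection sampling)."""
    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    placed: list[tuple[str, int, int]] = list(forbidden or [])
    out: list[tuple[str, int, int]] = []
    for L in lengths:
        ok = False
        for _ in range(max_tries):
            ci = int(rng.choice(len(chroms), p=sizes / sizes.sum()))
            chrom = chroms[ci]
            hi = chrom_sizes[chrom] - L
            if hi <= 0:
                continue
            start = int(rng.integers(0, hi))
            end = start + L
            clash = any(
                c == chrom and start < e + margin and end > s - margin
                for c, s, e in placed
            )
            if not clash:
                placed.append((chrom, start, end))
                out.append((chrom, start, end))
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"could not place interval of length {L} after {max_tries} tries"
            )
    return out


def make_genome(
    n_chrom: int = 2,
    chrom_length: int = 1_000_000,
    gc: float = 0.5,
    n_genes: int = 200,
    gene_length_range: tuple[int, int] = (2_000, 10_000),
    seed: int = 0,
) -> tuple[dict[str, str], list[GeneModel]]:
    """Toy genome: i.i.d. sequence at the stated GC plus non-overlapping
    gene models (uniform placement, Bernoulli(0.5) strand, 2-4 exons)."""
    if chrom_length < 10_000:
        raise ValueError("chromosome length must be >= 10 kb")
    rng = child_rng(seed, "genome")
    seqs = {
        f"chr{i + 1}": _random_sequence(rng, chrom_length, gc) for i in range(n_chrom)
    }
    # genes occupy jittered slots so dense layouts stay feasible; 1.2 kb
    # margins keep promoter windows inside the chromosome and off neighbors
    margin = 1_200
    per_chrom = [n_genes // n_chrom + (1 if i < n_genes % n_chrom else 0) for i in range(n_chrom)]
    spans = []
    for ci, (chrom, nk) in enumerate(zip(seqs, per_chrom)):
        if nk == 0:
            continue
        slot = chrom_length // nk
        if slot < gene_length_range[0] + 2 * margin:
            raise ValueError("too many genes for the chromosome length")
        for k in range(nk):
            lo = k * slot + margin
            L = int(rng.integers(gene_length_range[0], gene_length_range[1] + 1))
            L = min(L, slot - 2 * margin)
            start = int(rng.integers(lo, lo + slot - 2 * margin - L + 1))
            spans.append((chrom, start, start + L))
    genes = []
    for gi, (chrom, start, end) in enumerate(spans):
        strand = "+" if rng.random() < 0.5 else "-"
        tss, tes = (start, end) if strand == "+" else (end, start)
        n_ex = int(rng.integers(2, 5))
        cuts = np.sort(rng.choice(np.arange(start + 50, end - 50), size=2 * (n_ex - 1), replace=False))
        bounds = [start, *cuts.tolist(), end]
        exons = [
            GenomicInterval(chrom, bounds[2 * k], bounds[2 * k + 1], strand)
            for k in range(n_ex)
        ]
        gid = f"gene{gi + 1:04d}"
        genes.append(GeneModel(gid, gid.upper(), chrom, strand, tss, tes, exons))
    return seqs, genes


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Open regions + TF peaks
# ---------------------------------------------------------------------------


def make_open_regions(
    chrom_sizes: Mapping[str, int],
    n_regions: int = 300,
    region_length: int = 1_000,
    seed: int = 0,
) -> IntervalSet:
    """Non-overlapping open-chromatin regions of fixed length, uniformly
    placed and merged."""
    rng = child_rng(seed, "open_regions")
    spans = _place_nonoverlapping(
        rng, chrom_sizes, [region_length] * n_regions, margin=200
    )
    return merge_intervals(IntervalSet.from_intervals(spans))


def make_tiled_open_regions(
    chrom_sizes: Mapping[str, int],
    region_length: int = 10_000,
    spacing: int = 40_000,
    offset: int = 5_000,
) -> IntervalSet:
    """Deterministic regular tiling of open regions (one region of
    ``region_length`` every ``spacing`` bp).  Used for sparse-coordinate
    recovery scenarios where chance peak overlap must stay negligible."""
    spans = []
    for chrom, size in chrom_sizes.items():
        start = offset
        while start + region_length < size:
            spans.append((chrom, start, start + region_length))
            start += spacing
    s = IntervalSet.from_intervals(spans, names=[f"open{i}" for i in range(len(spans))])
    s.merged_flag = True
    return s


@dataclass
class PeakTruth:
    """Planted binding landscape for one factor."""

    true_peaks: IntervalSet
    replicates: list[IntervalSet]
    n_open: int
    n_closed: int


def make_peaks(
    chrom_sizes: Mapping[str, int],
    open_regions: IntervalSet,
    n_peaks: Mapping[str, int] | int = 5_000,
    open_fractions: Mapping[str, float] | None = None,
    cooccupancy: Mapping[tuple[str, str], float] | None = None,
    peak_length_lognorm: tuple[float, float] = (np.log(300.0), 0.25),
    n_replicates: int = 2,
    reproducibility: float = 0.85,
    boundary_jitter: int = 10,
    seed: int = 0,
) -> dict[str, PeakTruth]:
    """Plant per-factor peak sets with exact open/closed proportions and
    pairwise co-occupancy.

    Exactly ``round(open_fraction * n)`` of each factor's own peaks are
    placed fully inside open regions, the rest fully outside (the realized
    open count is the recorded truth).  Co-occupancy rho[a][b] duplicates
    exactly ``round(rho * n_a)`` of a's peak centers into b's set.
    Reproducibility: exactly ``round(reproducibility * n)`` true peaks
    appear in every replicate; each remaining peak appears in exactly one
    randomly chosen replicate.  Replicate peaks carry +/-
    ``boundary_jitter`` bp edge noise.
    """
    open_fractions = dict(DEFAULT_OPEN_FRACTIONS if open_fractions is None else open_fractions)
    cooccupancy = dict(DEFAULT_COOCCUPANCY if cooccupancy is None else cooccupancy)
    tfs = list(open_fractions)
    if isinstance(n_peaks, int):
        n_peaks = {t: n_peaks for t in tfs}
    rng = child_rng(seed, "peaks")

    odf = open_regions.df
    o_by_chrom = {
        c: (sub["start"].to_numpy(np.int64), sub["end"].to_numpy(np.int64))
        for c, sub in odf.groupby("chrom")
    }
    o_lens = (odf["end"] - odf["start"]).to_numpy(np.int64)
    o_chroms = odf["chrom"].to_numpy()
    o_starts = odf["start"].to_numpy(np.int64)

    def _in_open(chrom: str, start: int, end: int) -> bool:
        if chrom not in o_by_chrom:
            return False
        os_, oe_ = o_by_chrom[chrom]
        i = int(np.searchsorted(oe_, start, side="right"))
        return i < len(os_) and os_[i] < end

    o_cum = np.cumsum(o_lens / o_lens.sum()) if len(o_lens) else np.array([])

    def _draw_length() -> int:
        return max(50, int(rng.lognormal(*peak_length_lognorm)))

    def _place_open() -> tuple[str, int, int]:
        # choose an open region weighted by length, place the peak inside it
        ri = int(np.searchsorted(o_cum, rng.random()))
        L = _draw_length()
        if L >= o_lens[ri]:
            L = max(50, int(o_lens[ri]) - 2)
        start = int(o_starts[ri] + rng.integers(0, o_lens[ri] - L))
        return o_chroms[ri], start, start + L

    chrom_names = list(chrom_sizes)
    chrom_cum = np.cumsum(
        np.array([chrom_sizes[c] for c in chrom_names], dtype=float)
    )
    chrom_cum /= chrom_cum[-1]

    def _place_closed() -> tuple[str, int, int]:
        for _ in range(500):
            ci = int(np.searchsorted(chrom_cum, rng.random()))
            chrom = chrom_names[ci]
            L = _draw_length()
            start = int(rng.integers(0, chrom_sizes[chrom] - L))
            if not _in_open(chrom, start, start + L):
                return chrom, start, start + L
        raise RuntimeError("failed to place closed peak")

    planted: dict[str, list[tuple[str, int, int]]] = {}
    for tf in tfs:
        n = n_peaks[tf]
        k_open = int(round(open_fractions[tf] * n))
        spans = [_place_open() for _ in range(k_open)]
        spans += [_place_closed() for _ in range(n - k_open)]
        planted[tf] = spans

    # co-occupancy duplication: copies of a's peaks go into b's set
    for (a, b), rho in cooccupancy.items():
        if a not in planted or b not in planted:
            raise ValueError(f"co-occupancy names unknown factor: {(a, b)}")
        n_a = len(planted[a])
        k = int(round(rho * n_a))
        idx = rng.choice(n_a, size=k, replace=False)
        for i in idx:
            chrom, s, e = planted[a][i]
            c = (s + e) // 2
            L = _draw_length()
            ns = max(0, c - L // 2)
            planted[b].append((chrom, ns, ns + L))

    out: dict[str, PeakTruth] = {}
    for tf in tfs:
        spans = planted[tf]
        true_set = IntervalSet.from_intervals(
            spans, names=[f"{tf}_p{i}" for i in range(len(spans))]
        )
        n_open = sum(1 for c, s, e in spans if _in_open(c, s, e))
        # exactly round(reproducibility * n) peaks shared by all replicates;
        # the rest each land in one randomly chosen replicate
        n = len(spans)
        perm = rng.permutation(n)
        n_shared = int(round(reproducibility * n))
        shared = set(perm[:n_shared].tolist())
        solo_rep = {int(i): int(rng.integers(n_replicates)) for i in perm[n_shared:]}
        reps = []
        for r in range(n_replicates):
            rep_spans = []
            for i, (chrom, s, e) in enumerate(spans):
                if i not in shared and solo_rep.get(i) != r:
                    continue
                js = s + int(rng.integers(-boundary_jitter, boundary_jitter + 1))
                je = e + int(rng.integers(-boundary_jitter, boundary_jitter + 1))
                js = max(0, js)
                if je - js < 20:
                    je = js + 20
                rep_spans.append((chrom, js, je))
            reps.append(
                IntervalSet.from_intervals(
                    rep_spans, names=[f"{tf}_r{r}_p{i}" for i in range(len(rep_spans))]
                )
            )
        out[tf] = PeakTruth(true_set, reps, n_open, len(spans) - n_open)
    return out


# ---------------------------------------------------------------------------
# Motif-planted region sequences
# ---------------------------------------------------------------------------

_RC = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_RC)[::-1]


def count_occurrences(seq: str, consensus: str) -> int:
    """Overlapping occurrences of a consensus site on both strands."""
    pats = {consensus, _revcomp(consensus)}
    n = 0
    for p in pats:
        n += len(re.findall(f"(?={re.escape(p)})", seq))
    return n


def _clean_sequence(rng: np.random.Generator, length: int, gc: float, consensus: str) -> str:
    """Random sequence guaranteed free of the consensus on either strand."""
    for _ in range(200):
        s = _random_sequence(rng, length, gc)
        if count_occurrences(s, consensus) == 0:
            return s
        # resample only the offending windows, then re-check
        w = len(consensus)
        for pat in (consensus, _revcomp(consensus)):
            while pat in s:
                i = s.index(pat)
                s = s[:i] + _random_sequence(rng, w, gc) + s[i + w :]
        if count_occurrences(s, consensus) == 0:
            return s
    raise RuntimeError("could not generate consensus-free sequence")


def _plant(rng, seq: str, consensus: str, k: int) -> str:
    """Write exactly k non-overlapping occurrences into a consensus-free
    sequence, verifying the realized count."""
    w = len(consensus)
    for _ in range(200):
        offs = np.sort(rng.choice(len(seq) - w + 1, size=k, replace=False))
        if k > 1 and np.any(np.diff(offs) < w + 1):
            continue
        chars = list(seq)
        for o in offs:
            strand_flip = rng.random() < 0.5
            site = _revcomp(consensus) if strand_flip else consensus
            chars[o : o + w] = site
        out = "".join(chars)
        if count_occurrences(out, consensus) == k:
            return out
    raise RuntimeError("could not plant requested motif count")


def make_motif_regions(
    n_regions: int,
    region_length: int,
    consensus: str,
    carrier_fraction: float | None = None,
    density_per_kb: float | None = None,
    gc: float = 0.5,
    seed: int = 0,
    name_prefix: str = "r",
) -> tuple[list[tuple[str, str]], dict]:
    """Region sequences with planted motif occurrences.

    Exactly one of ``carrier_fraction`` (exactly that fraction of regions
    carries one occurrence, the rest carry none) or ``density_per_kb``
    (every region carries exactly ``round(density * length_kb)``
    occurrences) must be given.  Non-carrier sequence is guaranteed free of
    consensus matches on both strands, so the planted numbers are the
    realized, recoverable truth.
    """
    if (carrier_fraction is None) == (density_per_kb is None):
        raise ValueError("give exactly one of carrier_fraction / density_per_kb")
    rng = child_rng(seed, "motifs")
    regions = []
    total_occ = 0
    carriers = 0
    if carrier_fraction is not None:
        n_carry = int(round(carrier_fraction * n_regions))
        for i in range(n_regions):
            s = _clean_sequence(rng, region_length, gc, consensus)
            if i < n_carry:
                s = _plant(rng, s, consensus, 1)
                total_occ += 1
                carriers += 1
            regions.append((f"{name_prefix}{i}", s))
        # shuffle region order so carriers are not positional
        order = rng.permutation(n_regions)
        regions = [regions[j] for j in order]
    else:
        # distribute round(density * total_kb) occurrences over the regions
        total = int(round(density_per_kb * n_regions * region_length / 1000.0))
        per_region = np.full(n_regions, total // n_regions, dtype=int)
        extra = total - int(per_region.sum())
        if extra:
            per_region[rng.choice(n_regions, size=extra, replace=False)] += 1
        for i in range(n_regions):
            s = _clean_sequence(rng, region_length, gc, consensus)
            k = int(per_region[i])
            if k > 0:
                s = _plant(rng, s, consensus, k)
            total_occ += k
            carriers += int(k > 0)
            regions.append((f"{name_prefix}{i}", s))
    truth = {
        "consensus": consensus,
        "n_regions": n_regions,
        "region_length": region_length,
        "n_carriers": carriers,
        "total_occurrences": total_occ,
        "density_per_kb": 1000.0 * total_occ / (n_regions * region_length),
    }
    return regions, truth


# ---------------------------------------------------------------------------
# Fragments with planted DA domains
# ---------------------------------------------------------------------------


@dataclass
class FragmentTruth:
    regions: IntervalSet
    domain1: IntervalSet
    domain2: IntervalSet
    clusters: pd.Series  # barcode -> cluster
    domain1_span: int
    domain2_span: int


def make_fragments(
    chrom_sizes: Mapping[str, int],
    n_regions: int = 500,
    region_length: int = 500,
    n_domain1: int = 100,
    n_domain2: int = 60,
    rate_ratio: float = 10.0,
    open_count: float = 1_600.0,
    n_cells: int = 3_000,
    cluster_fractions: Mapping[str, float] | None = None,
    target_cluster: str = "2",
    fragment_length: int = 100,
    background_frac: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, FragmentTruth]:
    """Fragment table with planted domain-1/domain-2 accessibility.

    ``open_count`` is the expected pseudobulk fragment count of an *open*
    region summed over all cells; closed regions get
    ``open_count/rate_ratio`` and background (non-domain) regions the
    geometric mean of the two, so they sit in the buffer zone between the
    open and closed thresholds.  The default depth is set so that the
    closed-state Poisson noise in the smallest cluster group (13% of cells)
    stays well clear of the buffer thresholds.
    Domain-1 regions are open in every cluster except ``target_cluster`` and
    closed there; domain-2 regions the converse.  ``background_frac`` of all
    fragments fall outside any region (depth-only).  Cluster sizes default
    to 13% of cells in the target cluster (cluster "2") and the rest split
    evenly across clusters 1, 3..7.
    """
    if rate_ratio <= 1:
        raise ValueError("rate_ratio must be > 1")
    rng = child_rng(seed, "fragments")
    if cluster_fractions is None:
        others = [c for c in "1345678"[:6]]
        cluster_fractions = {target_cluster: 0.13}
        for c in others:
            cluster_fractions[c] = 0.87 / len(others)
    cells: list[tuple[str, str]] = []
    names = list(cluster_fractions)
    counts = np.floor(np.array([cluster_fractions[c] for c in names]) * n_cells).astype(int)
    counts[0] += n_cells - counts.sum()
    for cname, k in zip(names, counts):
        if k <= 0:
            raise ValueError(f"cluster {cname} has zero cells")
        cells += [(f"BC{cname}_{i:05d}", cname) for i in range(k)]
    clusters = pd.Series({bc: cl for bc, cl in cells}, name="cluster")

    spans = _place_nonoverlapping(
        child_rng(seed, "open_regions"),
        chrom_sizes,
        [region_length] * n_regions,
        margin=200,
    )
    regions = IntervalSet.from_intervals(spans, names=[f"reg{i}" for i in range(n_regions)])
    # class assignment by shuffled index
    order = rng.permutation(n_regions)
    d1_idx = set(order[:n_domain1].tolist())
    d2_idx = set(order[n_domain1 : n_domain1 + n_domain2].tolist())

    closed_count = open_count / rate_ratio
    # background regions sit at 0.4x the open rate: the derived thresholds
    # (2x / 0.5x the median signal) then fall at 0.8x and 0.2x the open
    # rate, leaving a 2-fold margin over the closed rate at ratio 10
    buffer_count = 0.4 * open_count

    cluster_names = names
    n_cells_per = dict(zip(names, counts))
    chrom_parts: list[np.ndarray] = []
    start_parts: list[np.ndarray] = []
    bc_parts: list[np.ndarray] = []
    for ri, (chrom, s, e) in enumerate(spans):
        for cl in cluster_names:
            if ri in d1_idx:
                mean = closed_count if cl == target_cluster else open_count
            elif ri in d2_idx:
                mean = open_count if cl == target_cluster else closed_count
            else:
                mean = buffer_count
            # per-cluster expected count scales with the cluster's cell share
            lam = mean * n_cells_per[cl] / n_cells
            k = int(rng.poisson(lam))
            if k == 0:
                continue
            starts = rng.integers(s, max(s + 1, e - fragment_length), size=k)
            bcs = rng.choice(n_cells_per[cl], size=k)
            chrom_parts.append(np.full(k, chrom, dtype=object))
            start_parts.append(starts.astype(np.int64))
            bc_parts.append(
                np.array([f"BC{cl}_{b:05d}" for b in bcs], dtype=object)
            )
    frag_rows: list[tuple[str, int, int, str]] = []
    # depth-only background fragments outside regions
    n_in = int(sum(len(a) for a in start_parts))
    n_bg = int(background_frac / (1 - background_frac) * n_in)
    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    occupied = {c: (sub["start"].to_numpy(), sub["end"].to_numpy()) for c, sub in regions.df.groupby("chrom")}
    cell_arr = np.array([bc for bc, _ in cells], dtype=object)
    ci_all = rng.choice(len(chroms), size=n_bg, p=sizes / sizes.sum())
    bc_all = rng.integers(len(cell_arr), size=n_bg)
    for ci in range(len(chroms)):
        chrom = chroms[ci]
        sel = ci_all == ci
        k = int(sel.sum())
        if k == 0:
            continue
        st = rng.integers(0, chrom_sizes[chrom] - fragment_length, size=k)
        os_, oe_ = occupied.get(chrom, (np.array([]), np.array([])))
        if len(os_):
            i = np.searchsorted(oe_, st, side="right")
            in_region = (i < len(os_)) & (os_[np.minimum(i, len(os_) - 1)] < st + fragment_length)
            st = st[~in_region]  # drop would-be in-region draws
        bcs = cell_arr[bc_all[sel][: len(st)]]
        chrom_parts.append(np.full(len(st), chrom, dtype=object))
        start_parts.append(st.astype(np.int64))
        bc_parts.append(bcs)
    frags = pd.DataFrame(
        {
            "chrom": np.concatenate(chrom_parts) if chrom_parts else np.array([], object),
            "start": np.concatenate(start_parts) if start_parts else np.array([], np.int64),
        }
    )
    frags["end"] = frags["start"] + fragment_length
    frags["barcode"] = np.concatenate(bc_parts) if bc_parts else np.array([], object)
    if frag_rows:
        frags = pd.concat(
            [frags, pd.DataFrame(frag_rows, columns=["chrom", "start", "end", "barcode"])],
            ignore_index=True,
        )
    chrom_codes = np.searchsorted(np.array(sorted(chrom_sizes)), frags["chrom"].to_numpy())
    order2 = np.lexsort((frags["start"].to_numpy(), chrom_codes))
    frags = frags.iloc[order2].reset_index(drop=True)

    def _subset(idx: set) -> IntervalSet:
        sel = [spans[i] for i in sorted(idx)]
        return IntervalSet.from_intervals(sel, names=[f"d{i}" for i in range(len(sel))])

    d1, d2 = _subset(d1_idx), _subset(d2_idx)
    truth = FragmentTruth(
        regions, d1, d2, clusters, d1.total_span, d2.total_span
    )
    return frags, truth


# ---------------------------------------------------------------------------
# DE table + promoter-binding flags
# ---------------------------------------------------------------------------


def make_de_table(
    n_genes: int = 5_000,
    n_down: int = 501,
    n_up: int = 235,
    n_bound_down: int = 348,
    n_bound_up: int = 112,
    p_bound_null: float = 0.30,
    tf_fractions: Mapping[str, float] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """DE table plus per-gene promoter-binding flags with exact planted counts.

    Exactly ``n_down``/``n_up`` genes get BH-adjusted p < 0.05 with
    negative/positive log2 fold-changes; exactly ``n_bound_down`` of the
    down genes and ``n_bound_up`` of the up genes are flagged
    promoter-bound.  Per-factor flags among bound genes are planted at
    ``tf_fractions`` (default JUNB 0.97, ZNF207 0.60, ATF7IP 0.55, SP7
    0.30), exact within the bound DE subset.
    """
    if n_down + n_up > n_genes:
        raise ValueError("n_down + n_up exceeds n_genes")
    if n_bound_down > n_down or n_bound_up > n_up:
        raise ValueError("bound counts exceed DE counts")
    tf_fractions = dict(
        {"ATF7IP": 0.55, "JUNB": 0.97, "SP7": 0.30, "ZNF207": 0.60}
        if tf_fractions is None
        else tf_fractions
    )
    rng = child_rng(seed, "de")
    gene_ids = [f"g{i + 1:05d}" for i in range(n_genes)]
    labels = np.array(["down"] * n_down + ["up"] * n_up + ["ns"] * (n_genes - n_down - n_up))
    rng.shuffle(labels)
    lfc = np.where(
        labels == "down",
        -(0.3 + np.abs(rng.normal(1.2, 0.6, n_genes))),
        np.where(
            labels == "up",
            0.3 + np.abs(rng.normal(1.0, 0.5, n_genes)),
            rng.normal(0.0, 0.15, n_genes),
        ),
    )
    lfc[(labels == "ns") & (lfc == 0.0)] = 0.01
    padj = np.where(
        labels == "ns",
        rng.uniform(0.05, 1.0, n_genes),
        10.0 ** rng.uniform(-8.0, np.log10(0.049), n_genes),
    )
    pval = padj * rng.uniform(0.05, 1.0, n_genes)
    de = pd.DataFrame(
        {"gene_id": gene_ids, "log2fc": lfc, "pvalue": pval, "padj": padj}
    )

    bound = np.zeros(n_genes, dtype=bool)
    down_idx = np.nonzero(labels == "down")[0]
    up_idx = np.nonzero(labels == "up")[0]
    ns_idx = np.nonzero(labels == "ns")[0]
    bound[rng.choice(down_idx, size=n_bound_down, replace=False)] = True
    bound[rng.choice(up_idx, size=n_bound_up, replace=False)] = True
    k_null = int(round(p_bound_null * len(ns_idx)))
    bound[rng.choice(ns_idx, size=k_null, replace=False)] = True

    flags = pd.DataFrame(index=pd.Index(gene_ids, name="gene_id"))
    bound_de_idx = np.nonzero(bound & (labels != "ns"))[0]
    bound_ns_idx = np.nonzero(bound & (labels == "ns"))[0]
    for tf, frac in tf_fractions.items():
        col = np.zeros(n_genes, dtype=bool)
        k_de = int(round(frac * len(bound_de_idx)))
        col[rng.choice(bound_de_idx, size=k_de, replace=False)] = True
        k_ns = int(round(frac * len(bound_ns_idx)))
        if k_ns:
            col[rng.choice(bound_ns_idx, size=k_ns, replace=False)] = True
        flags[tf] = col
    # bound_any is the planted bound vector itself (a bound gene may carry
    # no individual factor attribution), keeping the planted counts exact
    flags["bound_any"] = bound
    truth = {
        "n_de": n_down + n_up,
        "n_down": n_down,
        "n_up": n_up,
        "n_bound_de": n_bound_down + n_bound_up,
        "n_bound_down": n_bound_down,
        "n_bound_up": n_bound_up,
        "tf_fractions": tf_fractions,
    }
    return de, flags, truth


# ---------------------------------------------------------------------------
# Screen plates
# ---------------------------------------------------------------------------


def make_screen_plate(
    n_conditions: int = 1_435,
    n_hits: int = 69,
    control_mean: float = 6.0,
    hit_fold_range: tuple[float, float] = (1.4, 3.8),
    replicate_sigma: float = 0.5,
    n_replicates: int = 4,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Arrayed screen plate: a control at ``control_mean`` percent positive,
    ``n_hits`` conditions with planted fold effects and the rest null.
    Replicates are Normal(mean, sigma) truncated to [0, 100]."""
    rng = child_rng(seed, "screen")
    rows = []

    def add(cond: str, mean: float, cells: float = 1000.0) -> None:
        for r in range(n_replicates):
            v = float(np.clip(rng.normal(mean, replicate_sigma), 0.0, 100.0))
            rows.append((cond, r + 1, v, cells))

    add("siControl", control_mean)
    hit_ids = []
    folds = rng.uniform(*hit_fold_range, size=n_hits)
    for i in range(n_conditions - 1):
        cond = f"siTF{i + 1:04d}"
        if i < n_hits:
            add(cond, control_mean * folds[i])
            hit_ids.append(cond)
        else:
            add(cond, control_mean * float(rng.normal(1.0, 0.02)))
    plate = pd.DataFrame(rows, columns=["condition", "replicate", "percent_positive", "cells"])
    return plate, {"hit_conditions": sorted(hit_ids), "n_hits": n_hits}


def make_combination_plate(
    singles: Sequence[str] = (
        "siAtf7ip",
        "siFoxa1",
        "siHexim2",
        "siJunb",
        "siSmarca5",
        "siSox15",
        "siSp7",
        "siZfp207",
    ),
    best_single_mean: float = 24.0,
    control_mean: float = 6.0,
    n_super: int = 4,
    super_mean: float = 36.0,
    replicate_sigma: float = 1.0,
    n_replicates: int = 4,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Combinatorial screen: all 2^n - 1 subsets of the validated singles,
    with exactly ``n_super`` planted combinations more potent than the best
    single (which is the first listed single)."""
    from .screen_stats import enumerate_combinations

    rng = child_rng(seed, "combo")
    combos = enumerate_combinations(list(singles), min_size=1)
    rows = []

    def add(cond: str, mean: float) -> None:
        for r in range(n_replicates):
            v = float(np.clip(rng.normal(mean, replicate_sigma), 0.0, 100.0))
            rows.append((cond, r + 1, v, 1000.0))

    add("siControl", control_mean)
    single_means = {s: best_single_mean if s == singles[0] else rng.uniform(8.0, 18.0) for s in singles}
    multi = [c for c in combos if len(c) > 1]
    super_idx = set(rng.choice(len(multi), size=n_super, replace=False).tolist())
    super_names = []
    for c in combos:
        name = "+".join(c)
        if len(c) == 1:
            add(name, float(single_means[c[0]]))
        else:
            j = multi.index(c)
            if j in super_idx:
                add(name, float(rng.normal(super_mean, 1.0)))
                super_names.append(name)
            else:
                add(name, float(rng.uniform(10.0, best_single_mean - 4.0)))
    plate = pd.DataFrame(rows, columns=["condition", "replicate", "percent_positive", "cells"])
    truth = {
        "best_single": singles[0],
        "super_combinations": sorted(super_names),
        "n_super": n_super,
        "n_combinations": len(combos),
    }
    return plate, truth


def make_agonist_plate(
    n_conditions: int = 200,
    n_blunted: int = 61,
    n_blunted_low_viability: int = 52,
    reference_mean: float = 40.0,
    replicate_sigma: float = 1.0,
    n_replicates: int = 4,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Agonist screen plate: conditions tested in the induced-reprogramming
    assay against a reference condition (siAJSZ); ``n_blunted`` planted to
    reduce the response by > 50%, of which ``n_blunted_low_viability`` also
    fail the viability gate."""
    if n_blunted_low_viability > n_blunted:
        raise ValueError("more low-viability blunted than blunted")
    rng = child_rng(seed, "agonist")
    rows = []

    def add(cond: str, mean: float, cells: float) -> None:
        for r in range(n_replicates):
            v = float(np.clip(rng.normal(mean, replicate_sigma), 0.0, 100.0))
            rows.append((cond, r + 1, v, cells))

    add("siControl", reference_mean, 1000.0)  # control = reference response level
    blunted_ids, low_via_ids = [], []
    for i in range(n_conditions):
        cond = f"siCand{i + 1:03d}"
        if i < n_blunted:
            mean = float(rng.uniform(2.0, 0.45 * reference_mean))
            cells = 300.0 if i < n_blunted_low_viability else 1000.0
            blunted_ids.append(cond)
            if i < n_blunted_low_viability:
                low_via_ids.append(cond)
        else:
            mean = float(rng.uniform(0.75 * reference_mean, 1.1 * reference_mean))
            cells = 1000.0
        add(cond, mean, cells)
    plate = pd.DataFrame(rows, columns=["condition", "replicate", "percent_positive", "cells"])
    truth = {
        "n_blunted": n_blunted,
        "blunted_conditions": sorted(blunted_ids),
        "n_blunted_low_viability": n_blunted_low_viability,
        "low_viability_conditions": sorted(low_via_ids),
    }
    return plate, truth


# ---------------------------------------------------------------------------
# One-call fixture bundle
# ---------------------------------------------------------------------------


def simulate(out_dir: str | Path, seed: int = 0, config: dict | None = None) -> dict:
    """Generate the full default fixture bundle into ``out_dir``.

    Writes genome.fa, genes.gtf, open_regions.bed, per-factor replicate
    narrowPeak files, fragments.tsv + clusters.tsv, de_table.tsv +
    bound_flags.tsv, screen/combination/agonist plate TSVs, and truth.json.
    Returns the truth dictionary.  Bit-exact for a given (config, seed).
    """
    cfg = {
        "n_chrom": 2,
        "chrom_length": 1_000_000,
        "gc": 0.5,
        "n_genes": 200,
        "n_peaks": 5_000,
        "n_open_regions": 300,
        "open_region_length": 1_000,
    }
    cfg.update(config or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    seqs, genes = make_genome(
        n_chrom=cfg["n_chrom"],
        chrom_length=cfg["chrom_length"],
        gc=cfg["gc"],
        n_genes=cfg["n_genes"],
        seed=seed,
    )
    write_gtf(genes, out / "genes.gtf")
    sizes = {c: len(s) for c, s in seqs.items()}

    open_regions = make_open_regions(
        sizes, cfg["n_open_regions"], cfg["open_region_length"], seed=seed
    )
    write_bed(open_regions, out / "open_regions.bed", header="synthetic open chromatin")

    peaks = make_peaks(sizes, open_regions, n_peaks=cfg["n_peaks"], seed=seed)
    peak_files: dict[str, list[str]] = {}
    for tf, pt in peaks.items():
        files = []
        for ri, rep in enumerate(pt.replicates):
            p = out / f"{tf}_rep{ri + 1}.narrowPeak"
            _write_narrowpeak(rep, p)
            files.append(p.name)
        peak_files[tf] = files

    frags, frag_truth = make_fragments(sizes, seed=seed)
    # plant one AP-1 site at each domain-1 region center and one MEF2 site
    # at each domain-2 center so the motif stage sees differential structure
    ap1, mef2 = "TGACTCA", "CTAAAAATAG"
    mut = {c: list(s) for c, s in seqs.items()}
    for dset, site in ((frag_truth.domain1, ap1), (frag_truth.domain2, mef2)):
        for row in dset.df.itertuples(index=False):
            c = (int(row.start) + int(row.end)) // 2
            mut[row.chrom][c : c + len(site)] = site
    seqs = {c: "".join(chars) for c, chars in mut.items()}
    write_fasta(seqs, out / "genome.fa")
    frags.to_csv(out / "fragments.tsv", sep="\t", header=False, index=False)
    frag_truth.clusters.rename_axis("barcode").reset_index().to_csv(
        out / "clusters.tsv", sep="\t", header=False, index=False
    )
    write_bed(frag_truth.regions, out / "atac_regions.bed", header="synthetic pseudobulk regions")
    write_bed(frag_truth.domain1, out / "truth_domain1.bed", header="planted domain1")
    write_bed(frag_truth.domain2, out / "truth_domain2.bed", header="planted domain2")

    de, flags, de_truth = make_de_table(seed=seed)
    de.to_csv(out / "de_table.tsv", sep="\t", index=False)
    flags.reset_index().to_csv(out / "bound_flags.tsv", sep="\t", index=False)

    plate, screen_truth = make_screen_plate(seed=seed)
    plate.to_csv(out / "screen_plate.tsv", sep="\t", index=False)
    combo, combo_truth = make_combination_plate(seed=seed)
    combo.to_csv(out / "combination_plate.tsv", sep="\t", index=False)
    agonist, agonist_truth = make_agonist_plate(seed=seed)
    agonist.to_csv(out / "agonist_plate.tsv", sep="\t", index=False)

    truth = {
        "seed": seed,
        "config": cfg,
        "chrom_sizes": sizes,
        "peaks": {
            tf: {
                "n_true": len(pt.true_peaks),
                "n_open": pt.n_open,
                "n_closed": pt.n_closed,
                "replicate_files": peak_files[tf],
            }
            for tf, pt in peaks.items()
        },
        "cooccupancy": {f"{a}->{b}": r for (a, b), r in DEFAULT_COOCCUPANCY.items()},
        "fragments": {
            "domain1_span": frag_truth.domain1_span,
            "domain2_span": frag_truth.domain2_span,
            "n_domain1": len(frag_truth.domain1),
            "n_domain2": len(frag_truth.domain2),
            "target_cluster": "2",
            "cluster_sizes": frag_truth.clusters.value_counts().to_dict(),
        },
        "de": de_truth,
        "screen": screen_truth,
        "combination": combo_truth,
        "agonist": agonist_truth,
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return truth


def _write_narrowpeak(s: IntervalSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for row in s.df.itertuples(index=False):
            L = int(row.end) - int(row.start)
            fh.write(
                f"{row.chrom}\t{int(row.start)}\t{int(row.end)}\t{row.name}\t0\t.\t"
                f"1.0\t2.0\t1.0\t{L // 2}\n"
            )
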