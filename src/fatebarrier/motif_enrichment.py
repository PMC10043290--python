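"""PWM scanning and motif enrichment against a scrambled background.

Log-odds scanning of region sequences on both strands, with the score
threshold calibrated so that the per-window false-positive rate under the
background base composition does not exceed a target (default 1e-4), via
exact convolution of the per-column score distribution (discretized for wide
matrices).  Enrichment of a target region set over a background set is
reported as a fraction-of-regions fold with an upper-tail binomial p-value,
plus hit densities in hits/kb; differential enrichment between two region
sets compares densities with a two-proportion z-test.

The background sets are dinucleotide- (default) or mononucleotide-preserving
per-region shuffles (Altschul–Erickson Euler-path algorithm).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs
from scipy import stats
from statsmodels.stats.proportion import proportions_ztest

logger = logging.getLogger("fatebarrier.motifs")

__all__ = [
    "PWM",
    "MotifHitSet",
    "EnrichmentResult",
    "read_jaspar",
    "scan",
    "scramble_background",
    "enrichment",
    "differential_enrichment",
    "BUNDLED_CONSENSI",
]

BASES = "ACGT"
_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

UNIFORM_BG = np.array([0.25, 0.25, 0.25, 0.25])

#: Consensus sites for the motifs this analysis reports on (AP-1 element
#: TGACTCA plus reprogramming-factor motifs), used to build default PWMs
#: when no JASPAR matrices are supplied.
BUNDLED_CONSENSI = {
    "AP1": "TGACTCA",
    "MEF2C": "CTAAAAATAG",
    "TBX5": "AGGTGTGA",
    "ASCL1": "CAGCTG",
    "KLF4": "GGGGTGGGG",
    "cMYC": "CACGTG",
    "STAT": "TTCCCGGAA",
}


@dataclass
class PWM:
    """Position probability matrix with background frequencies.

    ``matrix`` is W x 4 (A, C, G, T) of probabilities summing to 1 per row;
    ``background`` a length-4 composition.  Log-odds scores are
    log2((p + pc*q) / q) column-wise, with pseudocount ``pc`` applied at
    scoring time so zero-probability cells stay finite.
    """

    name: str
    matrix: np.ndarray
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BG.copy())
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4 or self.matrix.shape[0] == 0:
            raise ValueError("PWM matrix must be W x 4 with W >= 1")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"PWM {self.name}: rows must sum to 1")
        if (self.matrix < 0).any():
            raise ValueError(f"PWM {self.name}: negative probabilities")
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return int(self.matrix.shape[0])

    def log_odds(self) -> np.ndarray:
        """W x 4 log2 odds scores with pseudocount regularization."""
        p = (self.matrix + self.pseudocount * self.background) / (1.0 + self.pseudocount)
        return np.log2(p / self.background)

    @classmethod
    def from_consensus(
        cls,
        name: str,
        consensus: str,
        background: np.ndarray | None = None,
        match_prob: float = 0.97,
    ) -> "PWM":
        """Sharp PWM from a consensus site: ``match_prob`` on the consensus
        base, the remainder split over the other three."""
        bg = UNIFORM_BG.copy() if background is None else np.asarray(background, float)
        w = len(consensus)
        m = np.full((w, 4), (1.0 - match_prob) / 3.0)
        for i, b in enumerate(consensus.upper()):
            m[i, BASES.index(b)] = match_prob
        return cls(name, m, bg)

    @classmethod
    def from_counts(
        cls,
        name: str,
        counts: np.ndarray,
        background: np.ndarray | None = None,
        pseudocount: float = 0.8,
    ) -> "PWM":
        """JASPAR-style count matrix to probabilities, with the pseudocount
        split across bases by the background composition."""
        bg = UNIFORM_BG.copy() if background is None else np.asarray(background, float)
        counts = np.asarray(counts, dtype=float)
        totals = counts.sum(axis=1, keepdims=True)
        m = (counts + pseudocount * bg) / (totals + pseudocount)
        return cls(name, m, bg)

    # -- threshold calibration --------------------------------------------

    def score_distribution(self, decimals: int = 9) -> tuple[np.ndarray, np.ndarray]:
        """Distribution of window scores under the background model.

        Column-by-column convolution merging equal (rounded) score sums;
        exact at ``decimals`` = 9 for short matrices, discretized at coarser
        rounding for wide ones.  Returns (sorted scores, probabilities).
        """
        scores = self.log_odds()
        dist: dict[float, float] = {0.0: 1.0}
        for i in range(self.width):
            new: dict[float, float] = {}
            col = scores[i]
            for s, p in dist.items():
                for b in range(4):
                    k = round(s + col[b], decimals)
                    new[k] = new.get(k, 0.0) + p * self.background[b]
            dist = new
        keys = np.array(sorted(dist))
        probs = np.array([dist[k] for k in keys])
        return keys, probs

    def threshold_for_fpr(self, fpr: float = 1e-4) -> float:
        """Smallest score whose per-window upper-tail probability under the
        background model is <= ``fpr`` (max score if none qualifies)."""
        decimals = 9 if self.width <= 12 else 3
        keys, probs = self.score_distribution(decimals=decimals)
        tail = np.cumsum(probs[::-1])[::-1]  # tail[i] = P(score >= keys[i])
        ok = tail <= fpr
        # tiny epsilon guards against rounding direction in the DP merge
        if not ok.any():
            return float(keys[-1]) - 1e-9
        return float(keys[ok.argmax()]) - 1e-9


def read_jaspar(path: str | Path, background: np.ndarray | None = None) -> list[PWM]:
    """Read JASPAR-format count matrices into PWMs (pseudocount 0.8)."""
    out = []
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            counts = np.column_stack([m.counts[b] for b in BASES])
            out.append(PWM.from_counts(m.name or m.matrix_id, counts, background))
    if not out:
        raise ValueError(f"no motifs parsed from {path}")
    return out


def write_jaspar(pwms: Sequence[PWM], path: str | Path, scale: int = 100) -> None:
    """Write PWMs as JASPAR count matrices (probabilities scaled to counts)."""
    with open(path, "w") as fh:
        for p in pwms:
            fh.write(f">{p.name} {p.name}\n")
            counts = np.rint(p.matrix * scale).astype(int)
            for bi, b in enumerate(BASES):
                row = " ".join(f"{c:6d}" for c in counts[:, bi])
                fh.write(f"{b} [{row} ]\n")


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------


@dataclass
class MotifHitSet:
    """Scan result: hits table plus scan bookkeeping.

    ``hits`` has columns (region_id, offset, strand, score); offsets are the
    leftmost base of the matching window on the forward coordinate system,
    for both strands.  ``n_windows`` counts all scanned windows (both
    strands, N-containing windows excluded); ``total_bp`` is the summed
    region length.
    """

    motif_name: str
    hits: pd.DataFrame
    score_threshold: float
    n_windows: int
    total_bp: int
    n_regions: int

    @property
    def regions_with_hit(self) -> set:
        return set(self.hits["region_id"].unique())

    @property
    def density_per_kb(self) -> float:
        return 1000.0 * len(self.hits) / self.total_bp if self.total_bp else 0.0


def _window_scores(codes: np.ndarray, smat: np.ndarray) -> np.ndarray:
    """Score every window; windows containing N get -inf."""
    w = smat.shape[0]
    nwin = codes.size - w + 1
    if nwin <= 0:
        return np.empty(0)
    padded = np.vstack([smat.T, np.full((1, w), -np.inf)])  # row 4 = N
    total = np.zeros(nwin)
    for i in range(w):
        total += padded[codes[i : i + nwin], i]
    return total


def scan(
    seq_regions: Sequence[tuple[str, str]],
    pwm: PWM,
    score_threshold: float | None = None,
    fpr: float = 1e-4,
) -> MotifHitSet:
    """Scan regions with a PWM on both strands.

    ``score_threshold`` overrides the default policy (smallest score with
    per-window background false-positive rate <= ``fpr``).  Regions shorter
    than the motif yield no hits; windows containing N are skipped.
    """
    if pwm.width == 0:
        raise ValueError("empty PWM")
    thr = pwm.threshold_for_fpr(fpr) if score_threshold is None else float(score_threshold)
    smat = pwm.log_odds()
    smat_rc = smat[::-1, ::-1]  # reverse-complement scoring matrix
    w = pwm.width
    rows = []
    n_windows = 0
    total_bp = 0
    for rid, seq in seq_regions:
        codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        total_bp += codes.size
        if codes.size < w:
            continue
        for strand, mat in (("+", smat), ("-", smat_rc)):
            sc = _window_scores(codes, mat)
            n_windows += int(np.isfinite(sc).sum())
            hit_at = np.nonzero(sc >= thr)[0]
            for o in hit_at:
                rows.append((rid, int(o), strand, float(sc[o])))
    hits = pd.DataFrame(rows, columns=["region_id", "offset", "strand", "score"])
    return MotifHitSet(pwm.name, hits, thr, n_windows, total_bp, len(seq_regions))


# ---------------------------------------------------------------------------
# Scrambled background
# ---------------------------------------------------------------------------


def _dinuc_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Altschul–Erickson shuffle preserving the exact dinucleotide multiset.

    Builds the dinucleotide transition multigraph, draws a random
    last-edge tree rooted at the terminal character (rejection sampling for
    connectivity), shuffles the remaining out-edges and walks the Euler path.
    """
    if len(seq) < 3 or len(set(seq)) == 1:
        return seq
    chars = list(seq)
    verts = sorted(set(chars))
    out_edges: dict[str, list[str]] = {v: [] for v in verts}
    for a, b in zip(chars, chars[1:]):
        out_edges[a].append(b)
    last = chars[-1]
    non_terminal = [v for v in verts if v != last]

    for _attempt in range(1000):
        last_edge = {}
        ok = True
        for v in non_terminal:
            if not out_edges[v]:
                ok = False
                break
            last_edge[v] = out_edges[v][rng.integers(len(out_edges[v]))]
        if not ok:
            break
        # connectivity: from every non-terminal vertex, following chosen
        # last edges must reach the terminal vertex
        def reaches(v: str) -> bool:
            seen = set()
            while v != last:
                if v in seen or v not in last_edge:
                    return False
                seen.add(v)
                v = last_edge[v]
            return True

        if all(reaches(v) for v in non_terminal):
            lists = {}
            for v in verts:
                edges = list(out_edges[v])
                if v in last_edge:
                    edges.remove(last_edge[v])
                perm = rng.permutation(len(edges))
                edges = [edges[i] for i in perm]
                if v in last_edge:
                    edges.append(last_edge[v])
                lists[v] = edges
            out = [chars[0]]
            pos = {v: 0 for v in verts}
            v = chars[0]
            for _ in range(len(chars) - 1):
                nxt = lists[v][pos[v]]
                pos[v] += 1
                out.append(nxt)
                v = nxt
            return "".join(out)
    logger.warning("dinucleotide shuffle failed to connect; returning input")
    return seq


def scramble_background(
    seq_regions: Sequence[tuple[str, str]],
    mode: Literal["dinucleotide", "mononucleotide"] = "dinucleotide",
    n_shuffles: int = 1,
    seed: int | None = None,
) -> list[tuple[str, str]]:
    """Per-region shuffles preserving length and base composition.

    ``dinucleotide`` (default) preserves the exact dinucleotide multiset;
    regions shorter than 2 bp fall back to mononucleotide with a logged
    notice.  Deterministic given ``seed``.
    """
    if mode not in ("dinucleotide", "mononucleotide"):
        raise ValueError(f"unknown shuffle mode {mode!r}")
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n_shuffles):
        for rid, seq in seq_regions:
            m = mode
            if m == "dinucleotide" and len(seq) < 2:
                logger.info("region %s shorter than 2 bp: mononucleotide fallback", rid)
                m = "mononucleotide"
            if m == "mononucleotide":
                arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
                shuf = arr[rng.permutation(arr.size)].tobytes().decode("ascii")
            else:
                shuf = _dinuc_shuffle(seq, rng)
            out.append((f"{rid}|shuf{k}", shuf))
    return out


# ---------------------------------------------------------------------------
# Enrichment statistics
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentResult:
    motif_name: str
    n_target: int
    k_target: int  # target regions with >= 1 hit
    f_target: float
    f_background: float
    fold: float
    p_value: float
    density_target: float  # hits/kb
    density_background: float
    background_floored: bool = False

    def as_dict(self) -> dict:
        return {
            "motif": self.motif_name,
            "n_target": self.n_target,
            "k_target": self.k_target,
            "f_target": self.f_target,
            "f_background": self.f_background,
            "fold": self.fold,
            "p_value": self.p_value,
            "density_target": self.density_target,
            "density_background": self.density_background,
        }


def enrichment(target: MotifHitSet, background: MotifHitSet) -> EnrichmentResult:
    """Fraction-of-regions fold enrichment of target over background.

    fold = f_t / f_b where f is the fraction of regions with >= 1 hit; f_b
    is floored at 1/(2*N_b + 1) when zero (flagged).  p is the upper-tail
    binomial P(X >= k_t | n_t, f_b).  Densities (hits/kb over all scanned
    bp) are reported alongside.
    """
    if target.motif_name != background.motif_name:
        raise ValueError("target and background scanned with different motifs")
    if target.n_regions == 0:
        raise ValueError("zero target regions")
    if background.n_regions == 0:
        raise ValueError("zero background regions")
    k_t = len(target.regions_with_hit)
    n_t = target.n_regions
    f_t = k_t / n_t
    f_b = len(background.regions_with_hit) / background.n_regions
    floored = False
    if f_b == 0.0:
        f_b = 1.0 / (2 * background.n_regions + 1)
        floored = True
        logger.info("background fraction floored to %g for %s", f_b, target.motif_name)
    fold = f_t / f_b
    p = float(stats.binom.sf(k_t - 1, n_t, f_b))  # P(X >= k_t)
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return EnrichmentResult(
        target.motif_name,
        n_t,
        k_t,
        f_t,
        f_b,
        fold,
        p,
        target.density_per_kb,
        background.density_per_kb,
        floored,
    )


def differential_enrichment(
    set1: Sequence[tuple[str, str]],
    set2: Sequence[tuple[str, str]],
    pwms: Sequence[PWM],
    fpr: float = 1e-4,
) -> pd.DataFrame:
    """Per-motif density comparison between two region sets.

    Densities are hits/kb in each set; ratio = density1/density2 (NA if no
    hits anywhere, inf if only set2 is empty of hits); p from a
    two-proportion z-test on hit counts over scanned windows.  Sorted by
    |log2 ratio| descending (NA rows last).
    """
    if not set1 or not set2:
        raise ValueError("both region sets must be nonempty")
    rows = []
    for pwm in pwms:
        h1 = scan(set1, pwm, fpr=fpr)
        h2 = scan(set2, pwm, fpr=fpr)
        k1, k2 = len(h1.hits), len(h2.hits)
        d1, d2 = h1.density_per_kb, h2.density_per_kb
        if k1 == 0 and k2 == 0:
            ratio, log2r, p = np.nan, np.nan, np.nan
        else:
            ratio = d1 / d2 if d2 > 0 else np.inf
            log2r = np.log2(ratio) if np.isfinite(ratio) and ratio > 0 else np.inf
            _z, p = proportions_ztest([k1, k2], [h1.n_windows, h2.n_windows])
        rows.append(
            {
                "motif": pwm.name,
                "hits1": k1,
                "hits2": k2,
                "density1": d1,
                "density2": d2,
                "ratio": ratio,
                "log2_ratio": log2r,
                "p_value": p,
            }
        )
    df = pd.DataFrame(rows)
    order = df["log2_ratio"].abs().fillna(-np.inf)
    return df.loc[order.sort_values(ascending=False, kind="mergesort").index].reset_index(
        drop=True
    )
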