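"""Interval model, file parsing, merging and intersection.

The derived expectations come from per-bp boolean-mask and quadratic
all-pairs oracles, which stay independent of the sweep-line implementation.
"""

from __future__ import annotations

import numpy as np
import pytest

from fatebarrier.intervals_core import (
    GenomicInterval,
    IntervalSet,
    PeakFormatError,
    consolidate_replicates,
    intersect,
    merge_intervals,
    read_peaks,
    write_bed,
)

# ---------------------------------------------------------------------- I/O


def test_read_peaks_formats_and_defaults(tmp_path):
    p = tmp_path / "a.bed"
    p.write_text("chr1\t100\t200\n")
    s = read_peaks(p, format="BED3")
    assert len(s) == 1
    row = s.df.iloc[0]
    assert (row["chrom"], row["start"], row["end"]) == ("chr1", 100, 200)
    assert row["score"] == 0.0 and row["strand"] == "." and np.isnan(row["summit_offset"])

    empty = tmp_path / "empty.bed"
    empty.write_text("")
    assert len(read_peaks(empty, format="BED3")) == 0


def test_read_narrowpeak_matches_hand_parsed_fixture(tmp_path):
    # 10-column narrowPeak line, parsed by hand: summit offset 50, q 3.1
    p = tmp_path / "a.narrowPeak"
    p.write_text(
        "# header\n"
        "chr2\t1000\t1500\tpk1\t250\t+\t8.5\t12.0\t3.1\t50\n"
        "chr1\t10\t110\tpk2\t100\t-\t4.0\t6.0\t2.0\t-1\n"
    )
    s = read_peaks(p, format="narrowPeak")
    assert len(s) == 2
    assert s.sorted_flag
    # sorted: chr1 first
    r1, r2 = s.df.iloc[0], s.df.iloc[1]
    assert r1["chrom"] == "chr1" and r1["strand"] == "-" and np.isnan(r1["summit_offset"])
    assert r2["name"] == "pk1" and r2["summit_offset"] == 50 and r2["neg_log10_q"] == 3.1
    assert r2["signal"] == 8.5


@pytest.mark.parametrize(
    "line,err",
    [
        ("chr1\t100\n", "columns"),
        ("chr1\tx\t200\n", "non-integer"),
        ("chr1\t200\t100\n", "invalid coordinates"),
    ],
)
def test_read_peaks_errors_name_line(tmp_path, line, err):
    p = tmp_path / "bad.bed"
    p.write_text("chr1\t0\t5\n" + line)
    with pytest.raises(PeakFormatError, match="line 2") as exc:
        read_peaks(p, format="BED3")
    assert err in str(exc.value)


def test_unknown_format_token_rejected(tmp_path):
    p = tmp_path / "a.bed"
    p.write_text("chr1\t0\t5\n")
    with pytest.raises(ValueError, match="unknown format"):
        read_peaks(p, format="BED4")


def test_write_read_roundtrip(tmp_path):
    s = IntervalSet.from_intervals([("chr1", 5, 50, "+"), ("chr2", 0, 9)])
    path = tmp_path / "x.bed"
    write_bed(s, path, header="provenance")
    assert path.read_text().startswith("# provenance")
    back = read_peaks(path, format="BED6")
    assert back.intervals() == s.intervals()


# ------------------------------------------------------------------- model


def test_interval_invariants():
    iv = GenomicInterval("chr1", 10, 25)
    assert iv.length == 15
    with pytest.raises(ValueError):
        GenomicInterval("chr1", 25, 25)
    with pytest.raises(ValueError):
        GenomicInterval("chr1", -1, 5)


def test_total_span_invariant_under_sorting():
    s = IntervalSet.from_intervals([("chr2", 0, 7), ("chr1", 3, 10), ("chr1", 0, 4)])
    assert s.total_span == 7 + 7 + 4
    assert s.sort().total_span == s.total_span


# ------------------------------------------------------------------- merge


def _mask_merge_oracle(intervals, gap, chrom_len=100_000):
    """Per-bp boolean mask oracle for merge (gap handled by dilation)."""
    mask = np.zeros(chrom_len + gap + 2, dtype=bool)
    for _c, s, e in intervals:
        mask[s : e + gap] = True  # right-dilate by gap, then contract
    out = []
    in_run = False
    for i, v in enumerate(mask):
        if v and not in_run:
            start, in_run = i, True
        elif not v and in_run:
            out.append((start, i))
            in_run = False
    return [(s, e - gap) for s, e in out]


def test_merge_trivial_cases():
    s = IntervalSet.from_intervals([("chr1", 0, 10), ("chr1", 5, 15)])
    assert merge_intervals(s).intervals() == [("chr1", 0, 15)]
    s2 = IntervalSet.from_intervals([("chr1", 0, 10), ("chr1", 20, 30)])
    assert len(merge_intervals(s2)) == 2
    with pytest.raises(ValueError):
        merge_intervals(s, gap=-1)


@pytest.mark.parametrize("gap", [0, 7])
def test_merge_matches_per_bp_mask_oracle(gap):
    rng = np.random.default_rng(11)
    starts = rng.integers(0, 99_000, size=1_000)
    lengths = rng.integers(1, 900, size=1_000)
    ivs = [("chrT", int(s), int(s + l)) for s, l in zip(starts, lengths)]
    got = merge_intervals(IntervalSet.from_intervals(ivs), gap=gap).intervals()
    expected = [("chrT", s, e) for s, e in _mask_merge_oracle(ivs, gap)]
    assert got == expected


def test_merge_idempotent_and_order_invariant():
    rng = np.random.default_rng(5)
    ivs = [
        ("chr1" if i % 2 else "chr2", int(s), int(s + l))
        for i, (s, l) in enumerate(
            zip(rng.integers(0, 50_000, 300), rng.integers(1, 400, 300))
        )
    ]
    m1 = merge_intervals(IntervalSet.from_intervals(ivs))
    assert merge_intervals(m1).intervals() == m1.intervals()
    shuffled = [ivs[i] for i in rng.permutation(len(ivs))]
    assert merge_intervals(IntervalSet.from_intervals(shuffled)).intervals() == m1.intervals()
    assert m1.merged_flag
    assert m1.total_span <= IntervalSet.from_intervals(ivs).total_span


# ------------------------------------------------------- replicate handling


def test_consolidate_modes_trivial():
    a = IntervalSet.from_intervals([("chr1", 0, 10)])
    b = IntervalSet.from_intervals([("chr1", 5, 15)])
    assert consolidate_replicates([a, b], "union_merge").intervals() == [("chr1", 0, 15)]
    assert consolidate_replicates([a, b], "intersection").intervals() == [("chr1", 5, 10)]
    with pytest.raises(ValueError):
        consolidate_replicates([], "union_merge")
    with pytest.raises(ValueError):
        consolidate_replicates([a], "bogus")


def test_union_span_dominates_intersection_span():
    rng = np.random.default_rng(3)
    reps = []
    for _ in range(3):
        ivs = [
            ("chrX", int(s), int(s + l))
            for s, l in zip(rng.integers(0, 80_000, 150), rng.integers(10, 500, 150))
        ]
        reps.append(IntervalSet.from_intervals(ivs))
    u = consolidate_replicates(reps, "union_merge")
    i = consolidate_replicates(reps, "intersection")
    assert u.total_span >= i.total_span


def test_replicate_intersection_recovers_planted_reproducibility():
    """Two replicates sharing exactly 70% of 5,000 planted peaks: the
    intersection count comes back near 3,500."""
    from fatebarrier.synthetic_data import make_peaks, make_tiled_open_regions

    sizes = {"chr1": 200_000_000}
    opens = make_tiled_open_regions(sizes, region_length=5_000, spacing=40_000)
    pk = make_peaks(
        sizes,
        opens,
        n_peaks=5_000,
        open_fractions={"TF1": 0.5},
        cooccupancy={},
        reproducibility=0.70,
        seed=21,
    )["TF1"]
    inter = consolidate_replicates(pk.replicates, "intersection")
    assert abs(len(inter) - 3_500) < 150


# --------------------------------------------------------------- intersect


def test_intersect_trivial_and_chromosome_mismatch():
    a = IntervalSet.from_intervals([("chr1", 100, 200)])
    b = IntervalSet.from_intervals([("chr1", 150, 160)])
    rep = intersect(a, b)
    assert bool(rep["overlapped"].iloc[0]) and rep["overlap_bp"].iloc[0] == 10
    rep2 = intersect(a, IntervalSet.from_intervals([("chr2", 100, 200)]))
    assert not rep2["overlapped"].any()
    with pytest.raises(ValueError):
        intersect(a, b, min_overlap_frac=1.5)


def test_intersect_fraction_threshold():
    a = IntervalSet.from_intervals([("chr1", 0, 100)])
    b = IntervalSet.from_intervals([("chr1", 90, 200)])
    assert intersect(a, b, min_overlap_frac=0.05)["overlapped"].iloc[0]
    assert not intersect(a, b, min_overlap_frac=0.2)["overlapped"].iloc[0]


def test_intersect_matches_quadratic_oracle():
    """2,000 random a-records against 2,000 b-records on two chromosomes:
    overlap flags, best partners and overlap bp all equal the O(n^2) scan."""
    rng = np.random.default_rng(17)

    def rand_set(n):
        ivs = [
            ("chr1" if c else "chr2", int(s), int(s + l))
            for c, s, l in zip(
                rng.integers(0, 2, n),
                rng.integers(0, 990_000, n),
                rng.integers(1, 5_000, n),
            )
        ]
        return IntervalSet.from_intervals(ivs)

    a, b = rand_set(2_000), rand_set(2_000)
    rep = intersect(a, b, min_overlap_bp=1)

    b_chrom = b.df["chrom"].to_numpy()
    b_start = b.df["start"].to_numpy()
    b_end = b.df["end"].to_numpy()
    for i, arow in enumerate(a.df.itertuples(index=False)):
        ov = np.minimum(arow.end, b_end) - np.maximum(arow.start, b_start)
        ov[b_chrom != arow.chrom] = 0
        ov = np.maximum(ov, 0)
        best_ov = int(ov.max(initial=0))
        assert bool(rep["overlapped"].iloc[i]) == (best_ov > 0)
        assert rep["overlap_bp"].iloc[i] == best_ov
        if best_ov > 0:
            # ties: smallest b start; b is sorted, argmax returns first max
            assert rep["best_partner"].iloc[i] == int(np.argmax(ov))
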