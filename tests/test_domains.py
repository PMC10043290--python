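"""Pseudobulk accessibility and differential-accessibility domain calling."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from fatebarrier.domain_finder import (
    AccessibilityMatrix,
    FragmentTable,
    binding_density_in_domains,
    call_domains,
    domain_summary,
    pseudobulk,
    tss_differential_accessibility,
)
from fatebarrier.intervals_core import IntervalSet
from fatebarrier.synthetic_data import make_fragments


def _table(frag_rows, cluster_map):
    df = pd.DataFrame(frag_rows, columns=["chrom", "start", "end", "barcode"])
    return FragmentTable(df, pd.Series(cluster_map))


def _matrix(counts: dict, depths: dict, region_length=1_000) -> AccessibilityMatrix:
    n = len(next(iter(counts.values())))
    regions = IntervalSet.from_intervals(
        [("chr1", i * 10_000, i * 10_000 + region_length) for i in range(n)],
        names=[f"reg{i}" for i in range(n)],
    )
    return AccessibilityMatrix(regions, pd.DataFrame(counts), pd.Series(depths))


# ---------------------------------------------------------------- pseudobulk


def test_pseudobulk_counts_and_depth():
    t = _table(
        [("chr1", 100, 150, "bcA"), ("chr1", 5_000, 5_100, "bcA")],
        {"bcA": "g"},
    )
    regions = IntervalSet.from_intervals([("chr1", 0, 1_000)])
    mat = pseudobulk(t, regions, {"G": ["g"]})
    assert mat.counts.iloc[0, 0] == 1  # second fragment is depth-only
    assert mat.depths["G"] == 2


def test_pseudobulk_group_validation():
    t = _table([("chr1", 0, 10, "b1")], {"b1": "1"})
    regions = IntervalSet.from_intervals([("chr1", 0, 1_000)])
    with pytest.raises(ValueError, match="no cells"):
        pseudobulk(t, regions, {"G": ["9"]})
    with pytest.raises(ValueError, match="disjoint"):
        pseudobulk(t, regions, {"A": ["1"], "B": ["1"]})


def test_pseudobulk_unlabeled_barcodes_excluded():
    t = _table(
        [("chr1", 0, 50, "known"), ("chr1", 0, 50, "unknown")],
        {"known": "1"},
    )
    assert len(t.df) == 1


def test_pseudobulk_poisson_counts_recover_planted_rates():
    """Counts per region match the planted Poisson rates within 3 sigma for
    nearly all regions."""
    rng = np.random.default_rng(6)
    lam = 50.0
    rows = []
    n_regions = 100
    for ri in range(n_regions):
        k = rng.poisson(lam)
        for j in range(k):
            s = ri * 10_000 + int(rng.integers(0, 900))
            rows.append(("chr1", s, s + 50, "bc0"))
    t = _table(rows, {"bc0": "1"})
    regions = IntervalSet.from_intervals(
        [("chr1", i * 10_000, i * 10_000 + 1_000) for i in range(n_regions)]
    )
    mat = pseudobulk(t, regions, {"G": ["1"]})
    c = mat.counts["G"].to_numpy()
    within = np.abs(c - lam) <= 3 * np.sqrt(lam)
    assert within.mean() >= 0.97


def test_normalization_invariant_under_depth_scaling():
    mat = _matrix({"a": [10, 20], "b": [5, 10]}, {"a": 1_000, "b": 500})
    n1 = mat.normalized
    mat2 = _matrix({"a": [20, 40], "b": [5, 10]}, {"a": 2_000, "b": 500})
    pd.testing.assert_frame_equal(n1, mat2.normalized)


# ------------------------------------------------------------- domain calls


def test_call_domains_forced_pattern_and_no_call():
    counts = {"ref": [5_000, 1_000, 30], "tgt": [30, 1_000, 5_000]}
    mat = _matrix(counts, {"ref": 100_000, "tgt": 100_000})
    calls = call_domains(mat, "ref", "tgt", tau_open=20_000, tau_closed=5_000)
    by_start = {int(r.start): r.domain_class for r in calls.itertuples(index=False)}
    assert by_start == {0: "domain1", 20_000: "domain2"}
    with pytest.raises(ValueError):
        call_domains(mat, "ref", "tgt", tau_open=1.0, tau_closed=2.0)


def test_call_domains_antisymmetric_under_group_swap():
    rng = np.random.default_rng(12)
    counts = {
        "ref": rng.poisson(200, 50).tolist(),
        "tgt": rng.poisson(200, 50).tolist(),
    }
    counts["ref"][:10] = [2_000] * 10
    counts["tgt"][:10] = [20] * 10
    counts["tgt"][10:16] = [2_000] * 6
    counts["ref"][10:16] = [20] * 6
    mat = _matrix(counts, {"ref": 200_000, "tgt": 200_000})
    fwd = call_domains(mat, "ref", "tgt")
    rev = call_domains(mat, "tgt", "ref")
    swap = {"domain1": "domain2", "domain2": "domain1"}
    assert list(fwd["start"]) == list(rev["start"])
    assert [swap[c] for c in fwd["domain_class"]] == list(rev["domain_class"])


def test_null_false_call_rate_controlled():
    """Both groups drawn from one Poisson rate field over 200 simulated
    genomes: called fraction stays within 0.05 + 2 Monte-Carlo SE."""
    rng = np.random.default_rng(99)
    n_regions, n_sims = 50, 200
    frac_called = []
    for _ in range(n_sims):
        lam = rng.uniform(50, 500, n_regions)
        counts = {"ref": rng.poisson(lam), "tgt": rng.poisson(lam)}
        mat = _matrix({k: v.tolist() for k, v in counts.items()}, {"ref": 50_000, "tgt": 50_000})
        calls = call_domains(mat, "ref", "tgt", alpha=0.05, merge_gap=-1)
        frac_called.append(len(calls) / n_regions)
    mean = float(np.mean(frac_called))
    mc_se = float(np.std(frac_called) / np.sqrt(n_sims))
    assert mean <= 0.05 + 2 * mc_se + 1e-9


def test_planted_domain_recovery_span_and_jaccard():
    """Planted domains at rate ratio 10 and high depth: per-class spans
    within +/-5% and bp Jaccard >= 0.95."""
    sizes = {"chr1": 1_000_000, "chr2": 1_000_000}
    frags, truth = make_fragments(sizes, n_regions=300, n_domain1=60, n_domain2=40, seed=77)
    table = FragmentTable(frags, truth.clusters)
    groups = {"ref": list("134567"), "tgt": ["2"]}
    mat = pseudobulk(table, truth.regions, groups)
    calls = call_domains(mat, "ref", "tgt")

    def _bp_set(df_or_set):
        out = set()
        if isinstance(df_or_set, IntervalSet):
            it = df_or_set.df.itertuples(index=False)
        else:
            it = df_or_set.itertuples(index=False)
        for r in it:
            out |= {(r.chrom, p) for p in range(int(r.start), int(r.end))}
        return out

    for cls, planted in (("domain1", truth.domain1), ("domain2", truth.domain2)):
        got = calls[calls["domain_class"] == cls]
        span = int((got["end"] - got["start"]).sum())
        assert span == pytest.approx(planted.total_span, rel=0.05)
        a, b = _bp_set(got), _bp_set(planted)
        jaccard = len(a & b) / len(a | b)
        assert jaccard >= 0.95


# ------------------------------------------------------- summaries/densities


def test_domain_summary_arithmetic_and_empty():
    calls = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1"],
            "start": [0, 1_000],
            "end": [600, 1_400],
            "domain_class": ["domain1", "domain1"],
            "n_ref": [1, 1],
            "n_tgt": [0, 0],
            "p_value": [0.0, 0.0],
            "q_value": [0.0, 0.0],
        }
    )
    s = domain_summary(calls)
    assert s["domain1"]["n_regions"] == 2
    assert s["domain1"]["total_span_bp"] == 1_000
    assert s["domain1"]["length_histogram"]["[400,600)"] == 1
    assert s["domain2"]["n_regions"] == 0
    empty = domain_summary(calls.iloc[0:0])
    assert empty["domain1"]["total_span_bp"] == 0


def test_binding_density_arithmetic():
    calls = pd.DataFrame(
        {
            "chrom": ["chr1"],
            "start": [0],
            "end": [1_000],
            "domain_class": ["domain1"],
            "n_ref": [1.0],
            "n_tgt": [0.0],
            "p_value": [0.0],
            "q_value": [0.0],
        }
    )
    inside = IntervalSet.from_intervals([("chr1", 100, 200)])
    outside = IntervalSet.from_intervals([("chr1", 5_000, 5_100)])
    dens = binding_density_in_domains(calls, {"IN": inside, "OUT": outside})
    d = {(r["domain_class"], r["tf"]): r for _, r in dens.iterrows()}
    assert d[("domain1", "IN")]["peaks_per_mbp"] == pytest.approx(1_000.0)
    assert d[("domain1", "OUT")]["peaks_per_mbp"] == 0.0
    assert np.isnan(d[("domain2", "IN")]["peaks_per_mbp"])  # span 0 -> NA


# -------------------------------------------------------------- TSS-level DA


def test_tss_da_exact_two_proportion_oracle():
    """Counts 0/10,000 vs 100/10,000: called with direction toward the
    target, p matching a directly computed pooled two-proportion z-test."""
    regions = IntervalSet.from_intervals(
        [("chr1", 0, 1_000), ("chr1", 10_000, 11_000)], names=["gA", "gB"]
    )
    mat = AccessibilityMatrix(
        regions,
        pd.DataFrame({"ref": [0, 50], "tgt": [100, 50]}),
        pd.Series({"ref": 10_000, "tgt": 10_000}),
    )
    out = tss_differential_accessibility(mat, "ref", "tgt")
    row = out[out["gene_id"] == "gA"].iloc[0]
    assert row["called"] and row["direction"] == "more_accessible_in_target"
    from scipy.stats import norm

    p1, p2, n = 0.0, 0.01, 10_000
    pooled = (0 + 100) / (2 * n)
    z = (p1 - p2) / np.sqrt(pooled * (1 - pooled) * (2 / n))
    assert row["p_value"] == pytest.approx(2 * norm.sf(abs(z)), rel=1e-9)
    unchanged = out[out["gene_id"] == "gB"].iloc[0]
    assert not unchanged["called"]


def test_tss_da_duplicate_gene_ids_summed_and_planted_recovery():
    rng = np.random.default_rng(15)
    n_genes, n_da = 500, 50
    depth = 2_000_000
    base = rng.poisson(400, n_genes)
    tgt = base.copy()
    tgt[:n_da] = base[:n_da] * 8  # large planted effect
    regions = IntervalSet.from_intervals(
        [("chr1", i * 5_000, i * 5_000 + 1_100) for i in range(n_genes)],
        names=[f"g{i:04d}" for i in range(n_genes)],
    )
    mat = AccessibilityMatrix(
        regions,
        pd.DataFrame({"ref": base, "tgt": tgt}),
        pd.Series({"ref": depth, "tgt": depth}),
    )
    out = tss_differential_accessibility(mat, "ref", "tgt", alpha=0.05)
    called = set(out[out["called"]]["gene_id"])
    planted = {f"g{i:04d}" for i in range(n_da)}
    assert len(called & planted) >= 45
    false_calls = called - planted
    assert len(false_calls) <= 0.05 * n_genes
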