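"""Arrayed siRNA screen statistics: normalization, hit calling,
combinatorics, blunting/viability gating and qPCR fold-changes."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fatebarrier.screen_stats import (
    blunting_calls,
    call_hits,
    compare_to_best_single,
    ddct_fold,
    enumerate_combinations,
    fold_change,
    normalize_and_test,
    viability_gate,
)
from fatebarrier.synthetic_data import make_agonist_plate, make_screen_plate


def _plate(condition_values: dict, control="siControl", cells=None):
    rows = []
    for cond, vals in condition_values.items():
        for r, v in enumerate(vals):
            row = {"condition": cond, "replicate": r + 1, "percent_positive": v}
            if cells is not None:
                row["cells"] = cells.get(cond, 1_000)
            rows.append(row)
    return pd.DataFrame(rows)


# ------------------------------------------------------------- normalization


def test_fold_and_p_against_control():
    plate = _plate({"siControl": [6, 6, 6, 6], "siX": [36, 36, 36, 36]})
    ht = normalize_and_test(plate)
    x = ht.set_index("condition")
    assert x.loc["siX", "fold"] == pytest.approx(6.0)
    assert x.loc["siControl", "fold"] == 1.0
    # identical replicates to control -> fold 1, p = 1
    plate2 = _plate({"siControl": [5, 6, 7, 6], "siSame": [5, 6, 7, 6]})
    x2 = normalize_and_test(plate2).set_index("condition")
    assert x2.loc["siSame", "fold"] == pytest.approx(1.0)
    assert x2.loc["siSame", "p_value"] == pytest.approx(1.0)


def test_normalize_matches_scipy_student_t():
    ctrl, cond = [5.1, 6.4, 5.8, 6.0], [7.2, 8.1, 7.5, 7.9]
    plate = _plate({"siControl": ctrl, "siY": cond})
    ht = normalize_and_test(plate).set_index("condition")
    expected = stats.ttest_ind(cond, ctrl, equal_var=True).pvalue
    assert ht.loc["siY", "p_value"] == pytest.approx(expected, rel=1e-12)


def test_normalize_edge_cases():
    with pytest.raises(ValueError, match="control"):
        normalize_and_test(_plate({"siX": [1, 2]}))
    with pytest.raises(ValueError, match="zero"):
        normalize_and_test(_plate({"siControl": [0, 0], "siX": [1, 2]}))
    ht = normalize_and_test(_plate({"siControl": [5, 6], "siSingle": [9]}))
    row = ht.set_index("condition").loc["siSingle"]
    assert row["fold"] == pytest.approx(9 / 5.5) and np.isnan(row["p_value"])


def test_null_type_one_error_calibrated():
    """10,000 null simulations at n = 4 per group: the plate statistic
    (two-tailed equal-variance t) rejects at p < 0.05 at rate 0.05 +/- 0.006."""
    rng = np.random.default_rng(20)
    a = rng.normal(10.0, 2.0, size=(10_000, 4))
    b = rng.normal(10.0, 2.0, size=(10_000, 4))
    p = stats.ttest_ind(a, b, axis=1, equal_var=True).pvalue
    rate = float((p < 0.05).mean())
    assert abs(rate - 0.05) <= 0.006


# --------------------------------------------------------------- hit calling


def test_call_hits_strict_thresholds():
    ht = pd.DataFrame(
        {
            "condition": ["a", "b", "c"],
            "fold": [1.30, 1.25, 2.0],
            "p_value": [0.01, 0.001, 0.2],
        }
    )
    out = call_hits(ht)
    assert list(out["hit"]) == [True, False, False]  # strict > and strict <
    dec = call_hits(
        pd.DataFrame({"condition": ["d"], "fold": [0.5], "p_value": [0.01]}),
        direction="decrease",
    )
    assert bool(dec["hit"].iloc[0])


def test_call_hits_monotone_in_thresholds():
    rng = np.random.default_rng(14)
    ht = pd.DataFrame(
        {
            "condition": [f"c{i}" for i in range(50)],
            "fold": rng.uniform(0.8, 2.5, 50),
            "p_value": rng.uniform(0, 0.2, 50),
        }
    )
    base = set(call_hits(ht, fold_min=1.25, alpha=0.05).query("hit")["condition"])
    stricter_fold = set(call_hits(ht, fold_min=1.5, alpha=0.05).query("hit")["condition"])
    stricter_alpha = set(call_hits(ht, fold_min=1.25, alpha=0.01).query("hit")["condition"])
    assert stricter_fold <= base and stricter_alpha <= base


def test_screen_recovers_planted_hits():
    """1,435-condition plate with 69 planted strong effects: the >1.25-fold,
    p < 0.05 filter returns exactly the planted set."""
    plate, truth = make_screen_plate(seed=8)
    hits = call_hits(normalize_and_test(plate))
    called = set(hits.query("hit")["condition"])
    assert called == set(truth["hit_conditions"])
    assert len(called) == 69


# ------------------------------------------------------------- combinatorics


@pytest.mark.parametrize("n", range(1, 13))
def test_enumerate_combinations_count(n):
    items = [f"s{i}" for i in range(n)]
    assert len(enumerate_combinations(items)) == 2**n - 1


def test_enumerate_combinations_order_and_guards():
    out = enumerate_combinations(["c", "a", "b"])
    assert out == [
        ("a",), ("b",), ("c",),
        ("a", "b"), ("a", "c"), ("b", "c"),
        ("a", "b", "c"),
    ]
    assert len(enumerate_combinations([f"s{i}" for i in range(8)])) == 255
    assert len(enumerate_combinations(["x"])) == 1
    with pytest.raises(ValueError):
        enumerate_combinations([f"s{i}" for i in range(21)])


def test_compare_to_best_single():
    plate = _plate(
        {
            "siA": [24, 25, 23, 24],
            "siB": [12, 13, 11, 12],
            "combo1": [36, 35, 37, 36],
            "combo2": [24, 25, 23, 24],
        }
    )
    out = compare_to_best_single(plate, singles=["siA", "siB"]).set_index("condition")
    assert out.loc["combo1", "best_single"] == "siA"
    assert bool(out.loc["combo1", "exceeds_best_single"])
    assert not bool(out.loc["combo2", "exceeds_best_single"])
    assert out.loc["combo2", "p_value"] == pytest.approx(1.0)
    with pytest.raises(ValueError, match="absent"):
        compare_to_best_single(plate, singles=["siZ"])


def test_combination_screen_recovers_planted_super_combinations():
    from fatebarrier.synthetic_data import make_combination_plate

    plate, truth = make_combination_plate(seed=19)
    plate = plate[plate["condition"] != "siControl"]
    singles = [c for c in plate["condition"].unique() if "+" not in c]
    out = compare_to_best_single(plate, singles=singles)
    flagged = set(out.query("exceeds_best_single")["condition"])
    assert flagged == set(truth["super_combinations"])
    assert len(flagged) == 4


# -------------------------------------------------- blunting and viability


def test_blunting_and_viability_gates():
    ht = pd.DataFrame(
        {
            "condition": ["siControl", "blunted", "kept", "toxic"],
            "mean_percent": [40.0, 18.0, 35.0, 10.0],
            "fold": [1.0, 0.45, 0.875, 0.25],
            "p_value": [1.0, 0.01, 0.5, 0.01],
            "viability_ratio": [1.0, 0.95, 1.0, 0.3],
        }
    )
    out = viability_gate(blunting_calls(ht, "siControl"))
    x = out.set_index("condition")
    assert bool(x.loc["blunted", "blunted"]) and bool(x.loc["blunted", "viable"])
    assert not bool(x.loc["kept", "blunted"])
    assert bool(x.loc["toxic", "blunted"]) and not bool(x.loc["toxic", "viable"])
    with pytest.raises(ValueError, match="absent"):
        blunting_calls(ht, "missing")


def test_agonist_plate_blunting_recount():
    """61 of 200 planted blunting conditions are recovered by an independent
    row-by-row recount."""
    plate, truth = make_agonist_plate(seed=23)
    ht = normalize_and_test(plate)
    out = viability_gate(blunting_calls(ht, "siControl"))
    called = set(out.query("blunted")["condition"])
    assert called == set(truth["blunted_conditions"])
    # brute-force recount straight off the plate means
    ref = plate[plate["condition"] == "siControl"]["percent_positive"].mean()
    manual = {
        c
        for c, sub in plate.groupby("condition")
        if c != "siControl" and sub["percent_positive"].mean() <= 0.5 * ref
    }
    assert called == manual
    viable_blunted = out.query("blunted and viable")
    assert len(viable_blunted) == truth["n_blunted"] - truth["n_blunted_low_viability"]


# ------------------------------------------------------------ fold changes


def test_fold_change_examples():
    assert fold_change(5, 16) == pytest.approx(3.2)
    assert fold_change(6, 36) == pytest.approx(6.0)
    with pytest.raises(ValueError):
        fold_change(0, 5)


def test_ddct_fold():
    assert ddct_fold(20, 20, 20, 20) == pytest.approx(1.0)
    assert ddct_fold(20, 18, 22, 18) == pytest.approx(4.0)
    with pytest.raises(ValueError):
        ddct_fold(-1, 20, 20, 20)
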