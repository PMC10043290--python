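"""Differential expression x promoter binding integration.

Consumes a differential-expression table (gene, log2FC, p, BH-adjusted p)
and the per-gene promoter-binding flags, producing the DE/bound overlap
(Venn counts), the down/up breakdown among bound DE genes, per-factor
promoter contributions, and top-quantile candidate gene lists.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

logger = logging.getLogger("fatebarrier.integration")

__all__ = [
    "IntegrationResult",
    "read_de_table",
    "filter_de",
    "integrate",
    "select_candidates",
]


@dataclass
class IntegrationResult:
    """Venn counts and fractions of the DE x promoter-bound overlap."""

    n_de: int
    n_de_down: int
    n_de_up: int
    n_bound_de: int
    n_bound_down: int
    n_bound_up: int
    per_tf_contribution: dict[str, float]  # fraction of bound DE genes with that TF
    bound_de_genes: pd.DataFrame  # DE rows restricted to bound genes

    @property
    def frac_bound(self) -> float:
        return self.n_bound_de / self.n_de if self.n_de else float("nan")

    @property
    def frac_down_among_bound(self) -> float:
        return self.n_bound_down / self.n_bound_de if self.n_bound_de else float("nan")

    def venn(self) -> dict:
        return {
            "n_de": self.n_de,
            "n_de_down": self.n_de_down,
            "n_de_up": self.n_de_up,
            "n_bound_de": self.n_bound_de,
            "n_bound_down": self.n_bound_down,
            "n_bound_up": self.n_bound_up,
            "frac_bound": self.frac_bound,
            "frac_down_among_bound": self.frac_down_among_bound,
        }


def _norm_gene(s: pd.Series) -> pd.Series:
    return s.astype(str).str.strip().str.upper()


def read_de_table(path: str | Path) -> pd.DataFrame:
    """Read a DE TSV with header columns (gene_id, log2fc, pvalue, padj).

    Common aliases (log2FoldChange, p_value, FDR...) are accepted.
    """
    df = pd.read_csv(path, sep="\t")
    alias = {
        "gene": "gene_id",
        "log2foldchange": "log2fc",
        "lfc": "log2fc",
        "p_value": "pvalue",
        "p": "pvalue",
        "fdr": "padj",
        "qvalue": "padj",
        "adj_p": "padj",
    }
    df.columns = [alias.get(c.lower(), c.lower()) for c in df.columns]
    need = {"gene_id", "log2fc", "padj"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        raise ValueError("duplicate gene_id in DE table")
    viol = int((df.get("pvalue", df["padj"]) > df["padj"]).sum())
    if viol:
        logger.warning("%d rows with padj < pvalue (input trusted)", viol)
    return df


def filter_de(t: pd.DataFrame, alpha: float = 0.05, lfc_min: float = 0.0) -> pd.DataFrame:
    """Keep genes with padj < alpha (strict) and |log2fc| >= lfc_min.

    Adds a ``direction`` column ("down"/"up" by sign of log2fc); genes with
    log2fc exactly 0 are excluded with a logged notice.
    """
    if "padj" not in t.columns:
        raise ValueError("DE table has no padj column")
    zero = t["log2fc"] == 0
    if bool(zero.any()):
        logger.info("excluding %d genes with log2fc == 0", int(zero.sum()))
    kept = t[(t["padj"] < alpha) & (t["log2fc"].abs() >= lfc_min) & ~zero].copy()
    kept["direction"] = np.where(kept["log2fc"] < 0, "down", "up")
    return kept.reset_index(drop=True)


def integrate(de: pd.DataFrame, bound: pd.DataFrame) -> IntegrationResult:
    """Intersect a filtered DE table with per-gene promoter-binding flags.

    ``bound`` is the table from ``annotation.promoter_bound_genes`` (indexed
    by gene_id with per-TF boolean columns and ``bound_any``).  Gene
    identifiers are matched exactly after whitespace/case normalization; DE
    genes absent from the bound table count as unbound (logged).
    """
    if len(de) == 0:
        raise ValueError("zero DE genes")
    if "direction" not in de.columns:
        raise ValueError("DE table must be filtered first (no direction column)")
    de = de.copy()
    de["_g"] = _norm_gene(de["gene_id"])
    bidx = pd.Index(_norm_gene(pd.Series(bound.index.astype(str))))
    tf_cols = [c for c in bound.columns if c != "bound_any"]
    b = bound.copy()
    b.index = bidx
    b = b[~b.index.duplicated(keep="first")]
    n_missing = int((~de["_g"].isin(b.index)).sum())
    if n_missing:
        logger.info("%d DE genes absent from bound table: treated unbound", n_missing)
    flags = b.reindex(de["_g"]).infer_objects(copy=False).fillna(False).astype(bool)
    de_bound_mask = flags["bound_any"].to_numpy() if "bound_any" in flags else flags[tf_cols].any(axis=1).to_numpy()
    down = (de["direction"] == "down").to_numpy()
    n_de = len(de)
    n_down = int(down.sum())
    n_bound = int(de_bound_mask.sum())
    n_bound_down = int((de_bound_mask & down).sum())
    per_tf = {}
    for tf in tf_cols:
        per_tf[tf] = (
            float(flags[tf].to_numpy()[de_bound_mask].sum() / n_bound) if n_bound else float("nan")
        )
    bound_rows = de[de_bound_mask].drop(columns=["_g"]).reset_index(drop=True)
    return IntegrationResult(
        n_de=n_de,
        n_de_down=n_down,
        n_de_up=n_de - n_down,
        n_bound_de=n_bound,
        n_bound_down=n_bound_down,
        n_bound_up=n_bound - n_bound_down,
        per_tf_contribution=per_tf,
        bound_de_genes=bound_rows,
    )


def select_candidates(
    de_bound: pd.DataFrame,
    direction: Literal["down", "up"],
    quantile: float = 0.25,
    rank_by: Literal["log2fc", "padj"] = "log2fc",
) -> pd.DataFrame:
    """Top-quantile candidate genes among the bound + DE subset.

    Keeps ceil(quantile * n) genes of the requested direction, the most
    extreme first (most negative log2fc for "down", most positive for "up";
    or smallest padj).  Ties at the cut are broken by smaller padj then
    gene_id, making the selection invariant to input row order.
    """
    if not (0.0 < quantile <= 1.0):
        raise ValueError("quantile must lie in (0, 1]")
    if direction not in ("down", "up"):
        raise ValueError(f"unknown direction {direction!r}")
    sub = de_bound[de_bound["direction"] == direction].copy()
    if len(sub) == 0:
        raise ValueError(f"no genes with direction {direction!r}")
    k = math.ceil(quantile * len(sub))
    if rank_by == "log2fc":
        key = sub["log2fc"] if direction == "down" else -sub["log2fc"]
    elif rank_by == "padj":
        key = sub["padj"]
    else:
        raise ValueError(f"unknown rank_by {rank_by!r}")
    sub = sub.assign(_key=key.to_numpy())
    sub = sub.sort_values(
        ["_key", "padj", "gene_id"], kind="mergesort"
    ).drop(columns="_key")
    return sub.head(k).reset_index(drop=True)
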