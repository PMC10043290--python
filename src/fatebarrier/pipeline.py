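"""Config-driven orchestration of the full analysis.

Runs the stages landscape -> annotation -> motifs -> domains -> integration
-> screen over a directory of input files (typically the synthetic fixture
bundle from :mod:`fatebarrier.synthetic_data`), writing per-stage TSV/BED
outputs, a manifest with parameters and input checksums, and one summary
JSON holding the headline numbers.  Deterministic given inputs and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from importlib import metadata as _metadata
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation as ann
from . import binding_landscape as bl
from . import de_integration as dei
from . import domain_finder as dom
from . import motif_enrichment as me
from . import screen_stats as ss
from .intervals_core import IntervalSet, consolidate_replicates, read_peaks, write_bed

logger = logging.getLogger("fatebarrier.pipeline")

__all__ = ["PipelineError", "default_config", "load_config", "run_pipeline"]

ALL_STAGES = ["peaks", "landscape", "annotation", "motifs", "domains", "integration", "screen"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the offending input."""

    def __init__(self, stage: str, msg: str):
        super().__init__(f"stage {stage!r} failed: {msg}")
        self.stage = stage


def default_config(fixture_dir: str | Path, seed: int = 0) -> dict:
    """Config pointing at a fixture bundle laid out by
    :func:`fatebarrier.synthetic_data.simulate`."""
    d = Path(fixture_dir)
    tfs = ["ATF7IP", "JUNB", "SP7", "ZNF207"]
    return {
        "seed": seed,
        "stages": {s: True for s in ALL_STAGES},
        "inputs": {
            "peak_replicates": {
                tf: [str(d / f"{tf}_rep1.narrowPeak"), str(d / f"{tf}_rep2.narrowPeak")]
                for tf in tfs
            },
            "open_regions": str(d / "open_regions.bed"),
            "genome_fasta": str(d / "genome.fa"),
            "gtf": str(d / "genes.gtf"),
            "fragments": str(d / "fragments.tsv"),
            "clusters": str(d / "clusters.tsv"),
            "atac_regions": str(d / "atac_regions.bed"),
            "de_table": str(d / "de_table.tsv"),
            "bound_flags": str(d / "bound_flags.tsv"),
            "screen_plate": str(d / "screen_plate.tsv"),
            "combination_plate": str(d / "combination_plate.tsv"),
            "agonist_plate": str(d / "agonist_plate.tsv"),
        },
        "params": {
            "consolidate_mode": "union_merge",
            "promoter_upstream": 1000,
            "promoter_downstream": 100,
            "min_overlap_bp": 1,
            "ref_groups": ["1", "3", "4", "5", "6", "7"],
            "tgt_groups": ["2"],
            "alpha": 0.05,
            "de_alpha": 0.05,
            "candidate_quantile": 0.25,
            "fold_min": 1.25,
            "blunting_threshold": 0.5,
            "viability_min": 0.7,
            "motif_fpr": 1e-4,
        },
    }


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "inputs" not in cfg:
        raise ValueError("pipeline config must be a mapping with an 'inputs' section")
    return cfg


def _validate(cfg: dict) -> None:
    """Fail fast: every enabled stage's inputs must resolve."""
    stages = cfg.get("stages", {s: True for s in ALL_STAGES})
    inputs = cfg["inputs"]
    need = {
        "peaks": ["peak_replicates"],
        "landscape": ["peak_replicates", "open_regions"],
        "annotation": ["peak_replicates", "gtf"],
        "motifs": ["genome_fasta"],
        "domains": ["fragments", "clusters", "atac_regions"],
        "integration": ["de_table", "bound_flags"],
        "screen": ["screen_plate"],
    }
    for stage, keys in need.items():
        if not stages.get(stage, False):
            continue
        for k in keys:
            v = inputs.get(k)
            if v is None:
                raise ValueError(f"stage {stage!r}: missing input {k!r}")
            paths = (
                [p for reps in v.values() for p in reps] if isinstance(v, dict) else [v]
            )
            for p in paths:
                if not Path(p).exists():
                    raise ValueError(f"stage {stage!r}: input file not found: {p}")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: dict, out_dir: str | Path) -> dict:
    """Execute the enabled stages; returns the summary dictionary.

    Stage order: peaks -> landscape -> annotation -> domains -> motifs ->
    integration -> screen (motifs runs after domains so differential motif
    analysis can use the fresh domain calls; with domains disabled it falls
    back to ``domain1_bed``/``domain2_bed`` inputs when given).  Writes
    per-stage outputs plus ``summary.json`` and ``manifest.json`` into
    ``out_dir``.  On stage failure raises :class:`PipelineError`, leaving a
    ``<stage>.partial`` marker next to any partial outputs.
    """
    _validate(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = cfg.get("stages", {s: True for s in ALL_STAGES})
    params = cfg.get("params", {})
    inputs = cfg["inputs"]
    seed = int(cfg.get("seed", 0))
    summary: dict = {"seed": seed}

    state: dict = {"consolidated": {}, "classifications": {}, "domain_calls": None}

    def _peaks():
        mode = params.get("consolidate_mode", "union_merge")
        counts = {}
        for tf, rep_paths in inputs["peak_replicates"].items():
            reps = [read_peaks(p, format="narrowPeak") for p in rep_paths]
            cons = consolidate_replicates(reps, mode=mode)
            state["consolidated"][tf] = cons
            counts[tf] = len(cons)
            write_bed(cons, out / f"peaks_{tf}.bed", header=f"{tf} consolidated ({mode})")
        summary["peak_counts"] = counts

    def _landscape():
        consolidated = state["consolidated"]
        open_regions = read_peaks(inputs["open_regions"], format="BED3")
        mob = int(params.get("min_overlap_bp", 1))
        state_rows = []
        for tf, peaks in consolidated.items():
            c = bl.classify_by_state(peaks, open_regions, min_overlap_bp=mob, tf_name=tf)
            state["classifications"][tf] = c
            state_rows.append(c.summary_row())
        pd.DataFrame(state_rows).to_csv(out / "state_classification.tsv", sep="\t", index=False)
        mat_all = bl.cooccupancy(consolidated, min_overlap_bp=mob)
        mat_open = bl.cooccupancy(
            consolidated, min_overlap_bp=mob, stratum=state["classifications"],
            stratum_state="open",
        )
        mat_all.to_frame().to_csv(out / "cooccupancy_all.tsv", sep="\t")
        mat_open.to_frame().to_csv(out / "cooccupancy_open.tsv", sep="\t")
        summary["state_fractions"] = {
            r["tf"]: {"frac_open": r["frac_open"], "n_open": r["n_open"], "n_closed": r["n_closed"]}
            for r in state_rows
        }
        summary["cooccupancy_all"] = _round_matrix(mat_all.matrix)
        summary["cooccupancy_open"] = _round_matrix(mat_open.matrix)

    def _annotation():
        consolidated = state["consolidated"]
        genes = ann.read_gtf(inputs["gtf"])
        up = int(params.get("promoter_upstream", 1000))
        down = int(params.get("promoter_downstream", 100))
        dist = {}
        for tf, peaks in consolidated.items():
            _a, summ = ann.annotate_peaks(peaks, genes, upstream=up, downstream=down)
            summ.to_csv(out / f"feature_distribution_{tf}.tsv", sep="\t", index=False)
            dist[tf] = {
                row["feature"]: round(float(row["percent"]), 1) for _i, row in summ.iterrows()
            }
        bound = ann.promoter_bound_genes(consolidated, genes, upstream=up, downstream=down)
        bound.reset_index().to_csv(out / "promoter_bound_genes.tsv", sep="\t", index=False)
        summary["feature_distribution"] = dist
        summary["n_promoter_bound_any"] = int(bound["bound_any"].sum())

    def _domains():
        frag_df = dom.read_fragments(inputs["fragments"])
        clusters = dom.read_clusters(inputs["clusters"])
        table = dom.FragmentTable(frag_df, clusters)
        regions = read_peaks(inputs["atac_regions"], format="BED3")
        ref = [str(g) for g in params.get("ref_groups", ["1", "3", "4", "5", "6", "7"])]
        tgt = [str(g) for g in params.get("tgt_groups", ["2"])]
        mat = dom.pseudobulk(table, regions, {"ref": ref, "tgt": tgt})
        calls = dom.call_domains(mat, "ref", "tgt", alpha=float(params.get("alpha", 0.05)))
        state["domain_calls"] = calls
        calls.to_csv(out / "domain_calls.tsv", sep="\t", index=False)
        summ = dom.domain_summary(calls)
        if state["consolidated"]:
            dens = dom.binding_density_in_domains(calls, state["consolidated"])
            dens.to_csv(out / "domain_binding_density.tsv", sep="\t", index=False)
            summary["domain_binding_density"] = {
                f"{r['domain_class']}:{r['tf']}": None
                if not np.isfinite(r["peaks_per_mbp"])
                else round(float(r["peaks_per_mbp"]), 2)
                for _i, r in dens.iterrows()
            }
        summary["domain_spans_bp"] = {
            cls: summ[cls]["total_span_bp"] for cls in ("domain1", "domain2")
        }
        summary["domain_counts"] = {
            cls: summ[cls]["n_regions"] for cls in ("domain1", "domain2")
        }
        summary["domain_length_histogram"] = {
            cls: summ[cls]["length_histogram"] for cls in ("domain1", "domain2")
        }
        summary["cluster_cell_fractions"] = {
            str(k): round(float(v) / len(clusters), 4)
            for k, v in clusters.value_counts().sort_index().items()
        }

    def _motifs():
        from pyfaidx import Fasta

        fa = Fasta(inputs["genome_fasta"])
        pwms = [
            me.PWM.from_consensus("AP1", me.BUNDLED_CONSENSI["AP1"]),
            me.PWM.from_consensus("MEF2C", me.BUNDLED_CONSENSI["MEF2C"]),
        ]
        fpr = float(params.get("motif_fpr", 1e-4))

        def _extract(bed_path):
            regions = read_peaks(bed_path, format="BED3")
            return [
                (str(r.name), str(fa[r.chrom][int(r.start) : int(r.end)]).upper())
                for r in regions.df.itertuples(index=False)
            ]

        calls = state["domain_calls"]
        if calls is not None and len(calls):
            d1 = calls[calls["domain_class"] == "domain1"]
            d2 = calls[calls["domain_class"] == "domain2"]
            seqs1 = [
                (f"d1_{i}", str(fa[r.chrom][int(r.start) : int(r.end)]).upper())
                for i, r in enumerate(d1.itertuples(index=False))
            ]
            seqs2 = [
                (f"d2_{i}", str(fa[r.chrom][int(r.start) : int(r.end)]).upper())
                for i, r in enumerate(d2.itertuples(index=False))
            ]
        elif inputs.get("domain1_bed") and inputs.get("domain2_bed"):
            seqs1, seqs2 = _extract(inputs["domain1_bed"]), _extract(inputs["domain2_bed"])
        else:
            logger.info("[motifs] no domain regions available; stage skipped")
            return
        if not seqs1 or not seqs2:
            logger.info("[motifs] empty domain sequence set; stage skipped")
            return
        diff = me.differential_enrichment(seqs1, seqs2, pwms, fpr=fpr)
        diff.to_csv(out / "differential_motifs.tsv", sep="\t", index=False)
        summary["differential_motifs"] = {
            r["motif"]: {
                "density1": round(float(r["density1"]), 4),
                "density2": round(float(r["density2"]), 4),
                "ratio": None if not np.isfinite(r["ratio"]) else round(float(r["ratio"]), 4),
            }
            for _i, r in diff.iterrows()
        }
        bg = me.scramble_background(seqs1, mode="dinucleotide", seed=seed)
        t_hits = me.scan(seqs1, pwms[0], fpr=fpr)
        b_hits = me.scan(bg, pwms[0], fpr=fpr)
        enr = me.enrichment(t_hits, b_hits)
        summary["ap1_enrichment_vs_scramble"] = {
            "fold": round(enr.fold, 4),
            "p_value": float(f"{enr.p_value:.4g}"),
            "density_per_kb": round(enr.density_target, 4),
        }

    def _integration():
        de_raw = dei.read_de_table(inputs["de_table"])
        bound = pd.read_csv(inputs["bound_flags"], sep="\t", index_col=0).astype(bool)
        de = dei.filter_de(de_raw, alpha=float(params.get("de_alpha", 0.05)))
        res = dei.integrate(de, bound)
        q = float(params.get("candidate_quantile", 0.25))
        cand_down = dei.select_candidates(res.bound_de_genes, "down", quantile=q)
        cand_up = dei.select_candidates(res.bound_de_genes, "up", quantile=q)
        cand_down.to_csv(out / "candidates_down.tsv", sep="\t", index=False)
        cand_up.to_csv(out / "candidates_up.tsv", sep="\t", index=False)
        with open(out / "venn_counts.json", "w") as fh:
            json.dump(res.venn(), fh, indent=2, sort_keys=True)
        summary["integration"] = res.venn()
        summary["integration"]["per_tf_contribution"] = {
            k: round(v, 4) for k, v in sorted(res.per_tf_contribution.items())
        }
        summary["n_candidates_down"] = len(cand_down)
        summary["n_candidates_up"] = len(cand_up)

    def _screen():
        plate = ss.read_plate(inputs["screen_plate"])
        ht = ss.normalize_and_test(plate, control="siControl")
        hits = ss.call_hits(
            ht,
            fold_min=float(params.get("fold_min", 1.25)),
            alpha=float(params.get("alpha", 0.05)),
        )
        hits.to_csv(out / "screen_hits.tsv", sep="\t", index=False)
        summary["n_screen_hits"] = int(hits["hit"].sum())
        if inputs.get("combination_plate") and Path(inputs["combination_plate"]).exists():
            combo = ss.read_plate(inputs["combination_plate"])
            singles = [
                c for c in combo["condition"].unique() if "+" not in c and c != "siControl"
            ]
            cmp_df = ss.compare_to_best_single(
                combo[combo["condition"] != "siControl"], singles
            )
            cmp_df.to_csv(out / "combination_vs_best_single.tsv", sep="\t", index=False)
            summary["n_combinations_beyond_best_single"] = int(
                cmp_df["exceeds_best_single"].sum()
            )
        if inputs.get("agonist_plate") and Path(inputs["agonist_plate"]).exists():
            ag = ss.read_plate(inputs["agonist_plate"])
            agt = ss.normalize_and_test(ag, control="siControl")
            blunt = ss.blunting_calls(
                agt, "siControl", threshold=float(params.get("blunting_threshold", 0.5))
            )
            blunt = ss.viability_gate(
                blunt, min_cells_frac=float(params.get("viability_min", 0.7))
            )
            blunt.to_csv(out / "agonist_blunting.tsv", sep="\t", index=False)
            summary["n_blunting"] = int(blunt["blunted"].sum())
            summary["n_blunting_viable"] = int((blunt["blunted"] & blunt["viable"]).sum())

    order = [
        ("peaks", _peaks),
        ("landscape", _landscape),
        ("annotation", _annotation),
        ("domains", _domains),
        ("motifs", _motifs),
        ("integration", _integration),
        ("screen", _screen),
    ]
    for name, fn in order:
        if not stages.get(name, False):
            continue
        marker = out / f"{name}.partial"
        marker.touch()
        logger.info("[%s] running", name)
        try:
            fn()
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(name, str(exc)) from exc
        marker.unlink(missing_ok=True)

    manifest = {
        "package_version": _pkg_version(),
        "parameters": params,
        "stages": {s: bool(stages.get(s, False)) for s in ALL_STAGES},
        "seed": seed,
        "input_checksums": {
            k: (_sha256(v) if isinstance(v, str) and Path(v).exists() else None)
            for k, v in inputs.items()
            if not isinstance(v, dict)
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def _round_matrix(m: pd.DataFrame) -> dict:
    return {
        a: {b: (None if pd.isna(m.loc[a, b]) else round(float(m.loc[a, b]), 4)) for b in m.columns}
        for a in m.index
    }


def _pkg_version() -> str:
    try:
        return _metadata.version("fatebarrier")
    except _metadata.PackageNotFoundError:
        return "unknown"
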