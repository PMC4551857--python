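"""End-to-end orchestration: simulate/load → co-expression → network → DE → enrichment.

The pipeline is driven by a single YAML/JSON config; stages run in
dependency order, files are the only interface between stages, and a
machine-readable JSON report aggregates per-stage summaries together with
the config hash and seed. Observed statistics (medians, counts, graph
metrics) are seed-independent; only null distributions and p-values vary
with the seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from neurocoex import coexpression, enrichment, network, rankprod, synthetic_data
from neurocoex.expression_io import ExpressionMatrix, read_matrix_tsv, write_matrix_tsv
from neurocoex.gene_sets import AnnotationTable, GeneSetCollection, read_gmt, write_gmt

__all__ = ["run_pipeline", "load_config"]

logger = logging.getLogger("neurocoex.pipeline")

DEFAULTS = {
    "n_resamples": 10_000,
    "threshold": 0.9,
    "n_networks": 10_000,
    "n_permutations": 100,
    "alpha": 0.05,
    "m": 21,
}


def load_config(source) -> dict:
    """Load a pipeline config from a YAML/JSON file path or pass a dict through."""
    if isinstance(source, dict):
        return dict(source)
    with open(source) as fh:
        return yaml.safe_load(fh)


def _config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(canon).hexdigest()[:16]


def run_pipeline(config, out_dir=None) -> dict:
    """Execute the configured stages and return the aggregated report.

    Raises ``RuntimeError`` naming the failing stage on error; outputs of
    completed stages are retained on disk.
    """
    config = load_config(config)
    seed = int(config.get("seed", 0))
    out = Path(out_dir or config.get("out_dir", "neurocoex_out"))
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config_hash": _config_hash(config),
        "seed": seed,
        "stages": {},
    }
    state: dict = {}
    stage_fns = [
        ("simulate", _stage_simulate),
        ("inputs", _stage_inputs),
        ("coexpr", _stage_coexpr),
        ("network", _stage_network),
        ("rankprod", _stage_rankprod),
        ("enrich", _stage_enrich),
    ]
    for name, fn in stage_fns:
        if name not in config:
            continue
        t0 = time.perf_counter()
        logger.info("stage %s: starting", name)
        try:
            summary = fn(config[name] or {}, state, seed, out)
        except Exception as exc:
            _write_report(report, out)
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        report["stages"][name] = summary
        # timings go to the log, not the report, so reruns are byte-identical
        logger.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
    _write_report(report, out)
    return report


def _write_report(report: dict, out: Path) -> None:
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)


def _stage_simulate(cfg: dict, state: dict, seed: int, out: Path) -> dict:
    sc = synthetic_data.SyntheticConfig(
        n_genes=int(cfg.get("n_genes", 2000)),
        n_samples=int(cfg.get("n_samples", 100)),
        modules=[tuple(m) for m in cfg.get("modules", [])],
        set_labels={
            k: tuple(v) if isinstance(v, list) and v and v[0] == "background" else v
            for k, v in (cfg.get("set_labels") or {}).items()
        },
        de_spec=cfg.get("de_spec"),
        seed=int(cfg.get("seed", seed)),  # data seed may be pinned separately
    )
    summary: dict = {}
    if sc.modules or not sc.de_spec:
        em, truth = synthetic_data.generate_module_matrix(sc)
        state["matrix"] = em
        state["sets"] = {k: frozenset(v) for k, v in truth["sets"].items()}
        write_matrix_tsv(em, out / "matrix.tsv")
        if state["sets"]:
            write_gmt(
                GeneSetCollection(state["sets"], frozenset(em.gene_ids)),
                out / "sets.gmt",
            )
        with open(out / "truth.json", "w") as fh:
            json.dump(truth, fh)
        summary["n_genes"] = em.n_genes
        summary["n_samples"] = em.n_samples
        summary["sets"] = {k: len(v) for k, v in state["sets"].items()}
    if sc.de_spec:
        case, ctrl, de_truth = synthetic_data.generate_de_experiment(sc)
        state["case"], state["control"] = case, ctrl
        state["de_truth"] = de_truth
        state.setdefault("de_sets", {k: frozenset(v) for k, v in de_truth["sets"].items()})
        write_matrix_tsv(case, out / "case.tsv")
        write_matrix_tsv(ctrl, out / "control.tsv")
        with open(out / "de_truth.json", "w") as fh:
            json.dump(de_truth, fh)
        summary["n_planted_up"] = len(de_truth["planted_up"])
    return summary


def _stage_inputs(cfg: dict, state: dict, seed: int, out: Path) -> dict:
    if "matrix" in cfg:
        state["matrix"] = ExpressionMatrix(read_matrix_tsv(cfg["matrix"]))
    if "sets" in cfg:
        state["sets"] = dict(read_gmt(cfg["sets"]).sets)
    if "case" in cfg:
        state["case"] = ExpressionMatrix(read_matrix_tsv(cfg["case"]))
    if "control" in cfg:
        state["control"] = ExpressionMatrix(read_matrix_tsv(cfg["control"]))
    if "annotation" in cfg:
        state["annotation"] = AnnotationTable.read_tsv(cfg["annotation"])
    return {k: True for k in cfg}


def _stage_coexpr(cfg: dict, state: dict, seed: int, out: Path) -> dict:
    cm = state.get("correlation")
    if cm is None:
        cm = coexpression.correlation_matrix(
            state["matrix"], log2=bool(cfg.get("log2", False))
        )
        state["correlation"] = cm
    sets = state["sets"]
    pairs = cfg.get("pairs") or [[name, None] for name in sets]
    n_res = int(cfg.get("n_resamples", DEFAULTS["n_resamples"]))
    results = {}
    for a, b in pairs:
        res = coexpression.set_coexpression_test(
            cm,
            sets[a],
            sets[b] if b else None,
            n_resamples=n_res,
            seed=seed,
        )
        key = a if b is None else f"{a}-{b}"
        results[key] = {
            "observed_median": res.observed_median,
            "z_score": res.z_score,
            "p_empirical": res.p_empirical,
            "n_resamples": res.n_resamples,
        }
    return {"pairs": results}


def _stage_network(cfg: dict, state: dict, seed: int, out: Path) -> dict:
    cm = state.get("correlation")
    if cm is None:
        cm = coexpression.correlation_matrix(state["matrix"])
        state["correlation"] = cm
    focal = state["sets"][cfg.get("set", next(iter(state["sets"])))]
    thr = float(cfg.get("threshold", DEFAULTS["threshold"]))
    n_net = int(cfg.get("n_networks", DEFAULTS["n_networks"]))
    thresholds = cfg.get("thresholds") or [thr]
    sweep = network.threshold_sweep(
        cm, sorted(thresholds), focal, n_networks=n_net, seed=seed
    )
    pd.DataFrame(sweep).to_csv(out / "clustering_sweep.tsv", sep="\t", index=False)
    g_inc = network.build_threshold_graph(cm, thr, focal, scope="incident")
    summary: dict = {"sweep": sweep}
    if g_inc.number_of_edges() > 0:
        try:
            comp = network.edge_composition_test(g_inc, focal)
            summary["edge_composition"] = {
                "n_within": comp.n_within,
                "n_incident": comp.n_incident,
                "expected_fraction": comp.expected_fraction,
                "chi_square": comp.chi_square,
                "p_value": comp.p_value,
            }
        except ValueError as exc:  # e.g. every incident node is focal
            summary["edge_composition"] = {"unavailable": str(exc)}
        edges = [(a, b, d["r"]) for a, b, d in g_inc.edges(data=True)]
        pd.DataFrame(edges, columns=["node1", "node2", "correlation"]).to_csv(
            out / "edges.tsv", sep="\t", index=False
        )
    return summary


def _stage_rankprod(cfg: dict, state: dict, seed: int, out: Path) -> dict:
    res = rankprod.permutation_pvalues(
        state["case"],
        state["control"],
        n_permutations=int(cfg.get("n_permutations", DEFAULTS["n_permutations"])),
        seed=seed,
    )
    alpha = float(cfg.get("alpha", DEFAULTS["alpha"]))
    hits = res.significant_up(alpha)
    state["hits"] = hits
    res.table.to_csv(out / "rankprod.tsv", sep="\t", index_label="gene_id")
    return {
        "n_genes": len(res.table),
        "n_permutations": res.n_permutations,
        "alpha": alpha,
        "n_significant_up": len(hits),
    }


def _stage_enrich(cfg: dict, state: dict, seed: int, out: Path) -> dict:
    annot = state.get("annotation")
    if annot is None:
        # derive an annotation table from the labelled sets of the DE design
        sets = state.get("de_sets") or state["sets"]
        background = state["case"].gene_ids if "case" in state else state["matrix"].gene_ids
        pairs = [(g, name) for name, genes in sets.items() for g in genes]
        annot = AnnotationTable.from_pairs(background, pairs)
        state["annotation"] = annot
    hits = state.get("hits") or cfg.get("hits")
    results = enrichment.mc_enrichment(
        hits,
        annot,
        n_resamples=int(cfg.get("n_resamples", DEFAULTS["n_resamples"])),
        seed=seed,
        m=cfg.get("m"),
    )
    table = enrichment.enrichment_table(results)
    table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    return {"categories": table.to_dict(orient="records")}
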