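"""End-to-end orchestration: simulate/load -> preprocess -> detectors ->
consensus -> networks, with a reproducible run manifest.

A run is configured by a plain dict (usually parsed from YAML, see
``consenseq run-all --help``); every output table lands under the run
directory and the manifest records the seed, a hash of the resolved
configuration, per-stage gene counts and the output inventory, so two runs
with the same configuration and seed produce byte-identical outputs and the
same manifest hash.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .consensus import (ConsensusConfig, apply_gates, calibrate_lfc_threshold,
                        overlap_summary, vote)
from .detectors import combine_results, run_detectors
from .dispersion import estimate_dispersions
from .network import (annotate_first_de, build_subnetwork, classify_common_targets,
                      extract_crosstalk, load_edges, merge_networks, write_edge_table,
                      write_graphml, write_node_table)
from .preprocess import (ValidationError, experiment_samples, filter_low_expression,
                         lfc_vs_control, read_counts, read_sample_sheet, write_counts,
                         write_lfc, write_sample_sheet)
from .simulate import SimConfig, simulate_dual_experiment, simulate_edge_table, write_truth

log = logging.getLogger(__name__)

__all__ = ["DEFAULT_CONFIG", "run_pipeline", "make_report", "StageError", "config_hash"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "consenseq_run",
    "counts": None,
    "sample_sheet": None,
    "edges": None,
    "simulate": {"n_genes": 500, "frac_de": 0.1, "n_edges": 1500, "shared_de_frac": 0.25},
    "experiments": {
        "SB": {"alpha": 0.05, "lam": 0.5, "k_min_tools": 3, "control_gene": None},
        "SU": {"alpha": 0.01, "lam": 0.7, "k_min_tools": 3, "control_gene": None},
    },
    "preprocess": {"min_cpm": 1.0, "pseudocount": 0.5, "filter_mode": "mean"},
    "detectors": {"use_adjusted": True, "spline_df": 3, "poly_degree": 2, "impulse_maxiter": 300},
    "network": {"min_score": 400},
}


def _merge_dict(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge_dict(out[k], v)
        else:
            out[k] = v
    return out


def resolve_config(config: dict | None, seed: int | None = None,
                   outdir: str | None = None) -> dict:
    cfg = _merge_dict(DEFAULT_CONFIG, config or {})
    if seed is not None:
        cfg["seed"] = int(seed)
    if outdir is not None:
        cfg["outdir"] = str(outdir)
    return cfg


def config_hash(cfg: dict) -> str:
    """Hash of the analytic configuration (the output location is excluded,
    so runs into different directories compare equal)."""
    cfg = {k: v for k, v in cfg.items() if k != "outdir"}
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _validate(cfg: dict) -> dict[str, ConsensusConfig]:
    out = {}
    for exp, c in cfg["experiments"].items():
        out[exp] = ConsensusConfig(alpha=c.get("alpha", 0.05), lam=c.get("lam", 0.5),
                                   k_min_tools=c.get("k_min_tools", 3),
                                   control_gene=c.get("control_gene"),
                                   use_adjusted=cfg["detectors"].get("use_adjusted", True))
    for key in ("counts", "sample_sheet", "edges"):
        if cfg.get(key) is not None and not Path(cfg[key]).exists():
            raise ValidationError(f"configured {key} path does not exist: {cfg[key]}")
    return out


def run_pipeline(config: dict | None = None, seed: int | None = None,
                 outdir: str | None = None) -> dict:
    """Run the full analysis; returns the manifest dict (also written to
    ``<outdir>/manifest.json``)."""
    cfg = resolve_config(config, seed, outdir)
    gates_cfg = _validate(cfg)  # validation errors raised before any stage runs
    out = Path(cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": cfg["seed"],
                      "config_hash": config_hash(cfg), "stages": {}, "outputs": []}

    def emit(name: str):
        manifest["outputs"].append(name)
        return out / name

    stage = "inputs"
    try:
        if cfg["counts"] is None:
            sim_cfg = dict(cfg["simulate"])
            n_edges = sim_cfg.pop("n_edges", 1500)
            shared = sim_cfg.pop("shared_de_frac", 0.25)
            sc = SimConfig(seed=cfg["seed"], **sim_cfg)
            matrix, sheet, truth = simulate_dual_experiment(sc, shared_de_frac=shared)
            edges = simulate_edge_table(list(matrix.gene_ids), n_edges,
                                        rng=np.random.default_rng(cfg["seed"] + 7919))
            write_counts(matrix, emit("inputs_counts.tsv"))
            write_sample_sheet(sheet, emit("inputs_samples.tsv"))
            write_truth(truth, emit("inputs_truth.tsv"))
            edges.to_csv(emit("inputs_edges.tsv"), sep="\t", index=False)
        else:
            matrix = read_counts(cfg["counts"])
            sheet = read_sample_sheet(cfg["sample_sheet"])
            edges = load_edges(cfg["edges"], cfg["network"]["min_score"]) if cfg["edges"] else None
        sheet.validate_against(matrix)
        if cfg["counts"] is None:
            edges = load_edges(out / "inputs_edges.tsv", cfg["network"]["min_score"])
        manifest["stages"]["n_genes_input"] = int(matrix.counts.shape[0])
        manifest["stages"]["n_samples"] = int(matrix.counts.shape[1])

        consensus_genes: dict[str, set] = {}
        lfc_tables: dict[str, pd.DataFrame] = {}
        nets = {}
        for exp, gate in gates_cfg.items():
            stage = f"preprocess[{exp}]"
            if exp not in sheet.treated_arms():
                raise ValidationError(f"experiment {exp!r} has no samples in the sheet")
            sheet.validate_design(exp)
            pp = cfg["preprocess"]
            filt = filter_low_expression(matrix, sheet, pp["min_cpm"], treatment=exp,
                                         mode=pp["filter_mode"])
            lfc = lfc_vs_control(filt, sheet, exp, pseudocount=pp["pseudocount"])
            lfc_tables[exp] = lfc
            write_lfc(lfc, emit(f"lfc_{exp}.tsv"), lam=gate.lam)
            manifest["stages"][f"n_genes_filtered_{exp}"] = int(filt.counts.shape[0])

            stage = f"detect[{exp}]"
            disp = estimate_dispersions(filt, sheet, samples=experiment_samples(sheet, exp))
            det = cfg["detectors"]
            results = run_detectors(filt, sheet, exp, disp,
                                    spline_df=det["spline_df"], poly_degree=det["poly_degree"],
                                    pseudocount=cfg["preprocess"]["pseudocount"],
                                    impulse_maxiter=det["impulse_maxiter"])
            for name, tab in results.items():
                tab.to_csv(emit(f"detector_{name}_{exp}.tsv"), sep="\t")
            combine_results(results).to_csv(emit(f"detectors_combined_{exp}.tsv"), sep="\t")

            stage = f"consensus[{exp}]"
            if gate.control_gene:
                lam, note = calibrate_lfc_threshold(lfc, gate.control_gene)
                log.info("%s: %s", exp, note)
                gate.lam = lam
                manifest["stages"][f"lam_calibrated_{exp}"] = lam
            sets = apply_gates(results, lfc, gate)
            for name, s in sets.items():
                manifest["stages"][f"n_candidates_{name}_{exp}"] = len(s)
            calls = vote(sets, gate.k_min_tools, lfc, gate.lam)
            calls.to_csv(emit(f"consensus_{exp}.tsv"), sep="\t", index=False)
            overlap_summary(sets).to_csv(emit(f"overlap_{exp}.tsv"), sep="\t", index=False)
            consensus_genes[exp] = set(calls["gene_id"])
            manifest["stages"][f"n_consensus_{exp}"] = len(consensus_genes[exp])

            stage = f"network[{exp}]"
            if edges is not None and consensus_genes[exp]:
                net = build_subnetwork(consensus_genes[exp], edges)
                annotate_first_de(net, lfc, gate.lam, experiment=exp)
                write_graphml(net, emit(f"network_{exp}.graphml"))
                write_node_table(net, emit(f"network_{exp}_nodes.tsv"))
                nets[exp] = net
                manifest["stages"][f"n_network_nodes_{exp}"] = net.number_of_nodes()

        stage = "crosstalk"
        exps = list(gates_cfg)
        if len(exps) == 2 and all(e in nets for e in exps):
            a, b = exps
            merged = merge_networks(nets[a], nets[b])
            write_graphml(merged, emit("network_merged.graphml"))
            shared = consensus_genes[a] & consensus_genes[b]
            manifest["stages"]["n_common_targets"] = len(shared)
            cross = extract_crosstalk(merged, shared)
            write_graphml(cross, emit("network_crosstalk.graphml"))
            write_node_table(cross, emit("network_crosstalk_nodes.tsv"))
            write_edge_table(cross, emit("network_crosstalk_edges.tsv"))
            cls = classify_common_targets(shared, lfc_tables[a], lfc_tables[b],
                                          gates_cfg[a].lam, gates_cfg[b].lam, labels=(a, b))
            cls.to_csv(emit("common_targets_classification.tsv"), sep="\t", index=False)
            if len(cls):
                counts = cls["classification"].value_counts()
                manifest["stages"]["n_synergistic"] = int(counts.get("synergistic", 0))
                manifest["stages"]["n_antagonistic"] = int(counts.get("antagonistic", 0))
            manifest["stages"]["n_crosstalk_nodes"] = cross.number_of_nodes()
    except ValidationError:
        raise
    except Exception as e:  # mark the failed stage, keep partial outputs
        (out / f"failed_{stage.replace('[', '_').replace(']', '')}.marker").write_text(str(e))
        raise StageError(stage, e) from e

    body = json.dumps(manifest, sort_keys=True, indent=2, default=str)
    manifest["manifest_hash"] = hashlib.sha256(body.encode()).hexdigest()[:16]
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=2, default=str))
    return manifest


def make_report(run_dir) -> dict:
    """Summary tables for a completed run.

    Writes, per experiment, a heatmap-ready LFC matrix of the consensus
    genes sorted for maximal downregulation at the earliest timepoint
    (most negative LFC first, ties broken by gene id), and a combined
    matrix for the common targets.
    """
    run = Path(run_dir)
    manifest_path = run / "manifest.json"
    if not manifest_path.exists():
        raise ValidationError(f"no manifest.json under {run}; incomplete run")
    manifest = json.loads(manifest_path.read_text())
    outputs = {}
    common = None
    if (run / "common_targets_classification.tsv").exists():
        common = pd.read_csv(run / "common_targets_classification.tsv", sep="\t")
    exps = sorted({p.stem.split("_")[1] for p in run.glob("consensus_*.tsv")})
    lfc_cache = {}
    for exp in exps:
        cons = pd.read_csv(run / f"consensus_{exp}.tsv", sep="\t")
        lfc = pd.read_csv(run / f"lfc_{exp}.tsv", sep="\t", index_col=0)
        lfc = lfc[[c for c in lfc.columns if c.startswith("lfc_")]]
        lfc_cache[exp] = lfc
        mat = lfc.loc[[g for g in cons["gene_id"] if g in lfc.index]]
        if len(mat) and len(mat.columns):
            # most negative LFC at the earliest timepoint first; ties by gene id
            mat = mat.sort_index(kind="mergesort").sort_values(mat.columns[0], kind="mergesort")
        path = run / f"heatmap_{exp}.tsv"
        mat.rename_axis("gene_id").to_csv(path, sep="\t")
        outputs[f"heatmap_{exp}"] = path
    if common is not None and len(exps) == 2 and len(common):
        a, b = exps
        genes = sorted(set(common["gene_id"]))
        mat = pd.concat([lfc_cache[a].loc[genes].add_suffix(f"_{a}"),
                         lfc_cache[b].loc[genes].add_suffix(f"_{b}")], axis=1)
        first = mat.columns[0]
        mat = mat.sort_index(kind="mergesort").sort_values(first, kind="mergesort")
        path = run / "heatmap_common.tsv"
        mat.rename_axis("gene_id").to_csv(path, sep="\t")
        outputs["heatmap_common"] = path
    elif len(exps) == 2:
        path = run / "heatmap_common.tsv"
        pd.DataFrame(columns=["gene_id"]).to_csv(path, sep="\t", index=False)
        outputs["heatmap_common"] = path
    outputs["manifest"] = manifest_path
    return outputs
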