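"""End-to-end orchestration: simulate -> preprocess -> per-time split ->
transition metrics -> markers / TF pairs / cluster matching / LR deltas.

A single flat configuration drives every stage; the resolved configuration
is written next to the outputs and re-running with the same configuration
and seed reproduces byte-identical CSVs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import lr as lr_mod
from . import markers as markers_mod
from . import similarity as sim_mod
from . import tfpairs as tfpairs_mod
from . import transition as transition_mod
from .matrix_io import (
    CellAnnotation,
    GeneAnnotation,
    read_cell_annotation,
    read_count_matrix,
    read_gene_annotation,
    write_cell_annotation,
    write_count_matrix,
    write_gene_annotation,
)
from .preprocess import filter_cells, filter_genes, normalize
from .simulate import (
    ConditionPairConfig,
    SimulationConfig,
    simulate_condition_pair,
    simulate_time_course,
)

log = logging.getLogger("sctip")

#: defaults mirror the thresholds of the upstream study
DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "outdir": "sctip_out",
    "simulate": True,
    "input_matrix": None,
    "input_matrix_format": "mtx",
    "cell_annotation": None,
    "gene_annotation": None,
    "time_order": None,
    # simulation
    "cells_per_time": 200,
    "n_time_points": 5,
    "transition_time_index": 2,
    # QC / normalization
    "min_genes": 500,
    "min_cells": 10,
    "umi_sd": 2.0,
    "size_factor": 10000.0,
    # markers
    "min_pct": 0.2,
    "logfc_threshold": 0.2,
    "block_logfc": 0.58,
    "q_threshold": 0.05,
    "tf_p_threshold": 0.05,
    # transition metrics
    "signed_cell_corr": False,
    "equalize_cells": None,
    # cluster matching
    "signature_cap": 100,
    # LR communication
    "n_perm": 1000,
    "lr_alpha": 0.05,
    "lr_threshold": 0.4,
    "top_n": 20,
    "lr_fold": 3.0,
    "lr_cells_per_condition": 400,
    # stage toggles
    "run_transition": True,
    "run_markers": True,
    "run_tf_pairs": True,
    "run_match_clusters": True,
    "run_lr": True,
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def resolve_config(overrides: dict[str, Any] | None = None) -> dict[str, Any]:
    cfg = dict(DEFAULT_CONFIG)
    for key, value in (overrides or {}).items():
        if key not in DEFAULT_CONFIG:
            raise KeyError(f"unknown configuration key {key!r}")
        if value is not None or DEFAULT_CONFIG[key] is None:
            cfg[key] = value
    return cfg


def load_config_file(path: str) -> dict[str, Any]:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("configuration file must hold a flat mapping")
    return data


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, index=False, float_format="%.12g")


def run_pipeline(config: dict[str, Any]) -> dict[str, Any]:
    """Execute all enabled stages; returns (and writes) the run manifest."""
    cfg = resolve_config(config)
    outdir = cfg["outdir"]
    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "resolved_config.yaml"), "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)

    seed_seq = np.random.SeedSequence(cfg["seed"])
    child = {
        name: int(s.generate_state(1)[0])
        for name, s in zip(
            ("simulate", "lr_data", "lr_perm_a", "lr_perm_b", "split"),
            seed_seq.spawn(5),
        )
    }

    manifest: dict[str, Any] = {
        "seed": cfg["seed"],
        "stages": {},
        "outputs": {},
    }

    def _record(stage: str, started: float, *paths: str) -> None:
        manifest["stages"][stage] = {
            "seconds": round(time.perf_counter() - started, 3),
            "outputs": list(paths),
        }
        for p in paths:
            manifest["outputs"][os.path.relpath(p, outdir)] = _sha256(p)

    # ---- input ---------------------------------------------------------
    t0 = time.perf_counter()
    try:
        if cfg["simulate"]:
            sim_cfg = SimulationConfig(
                n_time_points=cfg["n_time_points"],
                transition_index=cfg["transition_time_index"],
                cells_per_time=cfg["cells_per_time"],
                seed=child["simulate"],
            )
            cm, cells, genes, truth = simulate_time_course(sim_cfg)
            data_dir = os.path.join(outdir, "simulated")
            write_count_matrix(cm, data_dir, format="mtx")
            write_cell_annotation(cells, os.path.join(data_dir, "cells.tsv"))
            write_gene_annotation(genes, os.path.join(data_dir, "genes_annotation.tsv"))
            with open(os.path.join(data_dir, "truth.json"), "w") as fh:
                json.dump(truth.to_dict(), fh, indent=2, sort_keys=True)
            paths = [
                os.path.join(data_dir, f)
                for f in ("matrix.mtx", "genes.tsv", "barcodes.tsv",
                          "cells.tsv", "genes_annotation.tsv", "truth.json")
            ]
        else:
            for key in ("input_matrix", "cell_annotation"):
                if not cfg[key]:
                    raise FileNotFoundError(
                        f"configuration key {key!r} required when simulate is off"
                    )
            cm = read_count_matrix(cfg["input_matrix"], cfg["input_matrix_format"])
            cells = read_cell_annotation(cfg["cell_annotation"], cfg["time_order"])
            genes = (
                read_gene_annotation(cfg["gene_annotation"])
                if cfg["gene_annotation"]
                else None
            )
            truth = None
            paths = []
        cells.require_covers(cm.cell_ids)
    except Exception as exc:
        raise PipelineError("input", str(exc)) from exc
    _record("input", t0, *paths)
    log.info("[input] %d genes x %d cells", cm.n_genes, cm.n_cells)

    # ---- preprocess ----------------------------------------------------
    t0 = time.perf_counter()
    # the synthetic panel is far smaller than a transcriptome, so the
    # study-scale complexity threshold would empty it; cap it at half the
    # panel for simulated runs and record the effective value
    min_genes = cfg["min_genes"]
    if cfg["simulate"]:
        min_genes = min(min_genes, cm.n_genes // 2)
    manifest["effective_min_genes"] = min_genes
    try:
        cm_f, cell_report = filter_cells(cm, min_genes, cfg["umi_sd"])
        cm_f, gene_report = filter_genes(cm_f, genes, cfg["min_cells"])
        nm = normalize(cm_f, cfg["size_factor"])
        report_path = os.path.join(outdir, "filter_report.json")
        with open(report_path, "w") as fh:
            json.dump(
                {"cells": cell_report.to_dict(), "genes": gene_report.to_dict()},
                fh, indent=2, sort_keys=True,
            )
        filtered_dir = os.path.join(outdir, "filtered")
        write_count_matrix(cm_f, filtered_dir, format="mtx")
    except Exception as exc:
        raise PipelineError("preprocess", str(exc)) from exc
    _record("preprocess", t0, report_path,
            *(os.path.join(filtered_dir, f)
              for f in ("matrix.mtx", "genes.tsv", "barcodes.tsv")))
    log.info("[preprocess] kept %d genes x %d cells", nm.n_genes, nm.n_cells)

    # ---- per-time split ------------------------------------------------
    time_of_cell = cells.column("time_point")
    nm_by_time = {}
    for t in cells.time_levels:
        ids = [c for c in nm.cell_ids if time_of_cell[c] == t]
        if len(ids) >= 2:
            nm_by_time[t] = nm.subset_cells(ids)

    # ---- transition metrics --------------------------------------------
    if cfg["run_transition"]:
        t0 = time.perf_counter()
        try:
            series = transition_mod.transition_index(
                nm_by_time, signed_cell_corr=cfg["signed_cell_corr"]
            )
            series_path = os.path.join(outdir, "transition_series.csv")
            series.to_csv(series_path)
            trend = transition_mod.correlation_trend_summary(series)
            trend_path = os.path.join(outdir, "transition_trend.json")
            with open(trend_path, "w") as fh:
                json.dump(trend, fh, indent=2, sort_keys=True)
        except Exception as exc:
            raise PipelineError("transition", str(exc)) from exc
        _record("transition", t0, series_path, trend_path)
        log.info("[transition] peak I_C at %s", series.argmax_ic())

    # ---- markers -------------------------------------------------------
    if cfg["run_markers"] or cfg["run_match_clusters"]:
        t0 = time.perf_counter()
        try:
            marker_table = markers_mod.find_markers(
                nm,
                time_of_cell,
                mode="one_vs_rest",
                min_pct=cfg["min_pct"],
                logfc_threshold=cfg["logfc_threshold"],
                q_threshold=cfg["q_threshold"],
            )
            markers_path = os.path.join(outdir, "markers.csv")
            _write_csv(marker_table, markers_path)
        except Exception as exc:
            raise PipelineError("markers", str(exc)) from exc
        _record("markers", t0, markers_path)

    # ---- stage TFs and pair products -----------------------------------
    if cfg["run_tf_pairs"]:
        t0 = time.perf_counter()
        try:
            if genes is None:
                raise ValueError("TF stage requires a gene annotation")
            tf_genes = [g for g in genes.flagged("is_tf") if g in nm.gene_ids]
            first, last = cells.time_levels[0], cells.time_levels[-1]
            early, late = markers_mod.select_stage_tfs(
                nm_by_time[first], nm_by_time[last], tf_genes,
                p_threshold=cfg["tf_p_threshold"],
            )
            if not early or not late:
                raise ValueError("no stage-specific TFs found")
            scores = tfpairs_mod.tf_pair_products(nm_by_time, sorted(early), sorted(late))
            summary = tfpairs_mod.bifurcation_summary(scores)
            pair_summary = tfpairs_mod.pair_summaries(scores)
            tf_path = os.path.join(outdir, "tf_pair_summary.csv")
            tf_time_path = os.path.join(outdir, "tf_bifurcation.csv")
            _write_csv(pair_summary, tf_path)
            _write_csv(summary, tf_time_path)
        except Exception as exc:
            raise PipelineError("tf_pairs", str(exc)) from exc
        _record("tf_pairs", t0, tf_path, tf_time_path)

    # ---- cluster matching (split-half self-consistency) ----------------
    if cfg["run_match_clusters"]:
        t0 = time.perf_counter()
        try:
            rng = np.random.default_rng(child["split"])
            order = rng.permutation(nm.n_cells)
            half = nm.n_cells // 2
            ids_a = [nm.cell_ids[i] for i in sorted(order[:half])]
            ids_b = [nm.cell_ids[i] for i in sorted(order[half:])]
            sets = []
            for ids in (ids_a, ids_b):
                tbl = markers_mod.find_markers(
                    nm.subset_cells(ids),
                    time_of_cell,
                    mode="one_vs_rest",
                    min_pct=cfg["min_pct"],
                    logfc_threshold=cfg["logfc_threshold"],
                    q_threshold=cfg["q_threshold"],
                )
                sets.append(sim_mod.signature_sets(tbl, cap=cfg["signature_cap"]))
            mat, best = sim_mod.similarity_matrix(sets[0], sets[1])
            match_path = os.path.join(outdir, "cluster_similarity.csv")
            mat.rename_axis("cluster").reset_index().to_csv(
                match_path, index=False, float_format="%.12g"
            )
            best_path = os.path.join(outdir, "cluster_best_matches.json")
            with open(best_path, "w") as fh:
                json.dump(best, fh, indent=2, sort_keys=True)
        except Exception as exc:
            raise PipelineError("match_clusters", str(exc)) from exc
        _record("match_clusters", t0, match_path, best_path)

    # ---- LR communication ---------------------------------------------
    if cfg["run_lr"]:
        t0 = time.perf_counter()
        try:
            pair_cfg = ConditionPairConfig(
                cells_per_condition=cfg["lr_cells_per_condition"],
                ligand_folds={"lig_00": cfg["lr_fold"]},
                seed=child["lr_data"],
            )
            lr_cm, lr_cells, lr_genes = simulate_condition_pair(pair_cfg)
            lr_nm = normalize(lr_cm, cfg["size_factor"])
            cond = lr_cells.column("condition")
            clus = lr_cells.column("cluster")
            tables = {}
            for label, perm_seed in (
                (pair_cfg.conditions[0], child["lr_perm_a"]),
                (pair_cfg.conditions[1], child["lr_perm_b"]),
            ):
                ids = [c for c in lr_nm.cell_ids if cond[c] == label]
                sub = lr_nm.subset_cells(ids)
                sig = lr_mod.lr_significance(
                    sub, clus, pair_cfg.lr_pairs(),
                    n_perm=cfg["n_perm"], seed=perm_seed,
                )
                tables[label] = lr_mod.rank_and_select(
                    sig, alpha=cfg["lr_alpha"], top_n=cfg["top_n"]
                )
            delta = lr_mod.classify_delta(
                tables[pair_cfg.conditions[0]],
                tables[pair_cfg.conditions[1]],
                threshold=cfg["lr_threshold"],
                label_a=pair_cfg.conditions[0],
                label_b=pair_cfg.conditions[1],
            )
            lr_path = os.path.join(outdir, "lr_delta.csv")
            _write_csv(delta, lr_path)
        except Exception as exc:
            raise PipelineError("lr", str(exc)) from exc
        _record("lr", t0, lr_path)

    manifest_path = os.path.join(outdir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
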