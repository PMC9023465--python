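"""End-to-end pipeline: simulate/load -> QC -> SIT -> downstream.

Stages exchange TSV/JSON only, so each stage can be rerun standalone and
non-Python consumers can pick up intermediate results. A run manifest
records the config snapshot, input digests, seed, per-stage cell/gene
counts and quartile cutpoints; identical manifest inputs reproduce
identical outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .io import (GeneSet, normalize, read_10x_triplet,
                 read_gene_annotation, read_gmt)
from .qc import filter_cells, filter_genes_protein_coding, gate_epithelial
from .sit import SitParams, run_sit
from .downstream import (default_survival_panel, stratify_bcl2_mcl1,
                         survival_correlation_screen, wilcoxon_de)
from .simulate import SimConfig, simulate_tumor, standin_cellcycle_sets

logger = logging.getLogger(__name__)

__all__ = ["ConfigError", "PipelineError", "load_config", "run_pipeline"]


class ConfigError(ValueError):
    """The run configuration violates the schema (exit code 2)."""


class PipelineError(RuntimeError):
    """A stage failed on the data (exit code 1)."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage}: {message}")


_QC_DEFAULTS = {"max_mito_frac": 0.25, "min_genes": 100,
                "protein_coding": True, "gate_epithelial": True}
_SIT_DEFAULTS = {"n_bins": 25, "n_ctrl_per_gene": 100,
                 "weight_exponent": 0.25, "per_sample": False}
_DOWNSTREAM_DEFAULTS = {"de": True, "screen": True, "stratify": True,
                        "min_pct": 0.30, "fdr_cut": 0.05,
                        "r_threshold": 0.4, "fdr_threshold": 0.05,
                        "mcl1_positive_quartiles": "upper"}


def load_config(path: str | Path) -> dict:
    """Load and validate a YAML run config; raises ConfigError naming the
    offending fields."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a mapping")
    problems: list[str] = []
    if "input" not in cfg or not isinstance(cfg.get("input"), dict):
        problems.append("input (mapping) is required")
    else:
        inp = cfg["input"]
        if ("simulate" in inp) == ("triplet_dir" in inp):
            problems.append("input: exactly one of 'simulate' or 'triplet_dir' required")
    sit = cfg.get("sit", {})
    if not isinstance(sit, dict):
        problems.append("sit must be a mapping")
    else:
        cc = sit.get("cellcycle_gmt")
        simulated = isinstance(cfg.get("input"), dict) and "simulate" in cfg["input"]
        if cc is None and not simulated:
            problems.append("sit.cellcycle_gmt: required when input is not simulated "
                            "(path to a GMT with the K, R and WP cell-cycle sets)")
    if "seed" in cfg and not isinstance(cfg["seed"], int):
        problems.append("seed must be an integer")
    if problems:
        raise ConfigError("; ".join(problems))
    cfg.setdefault("seed", 0)
    cfg["qc"] = {**_QC_DEFAULTS, **cfg.get("qc", {})}
    cfg["sit"] = {**_SIT_DEFAULTS, **cfg.get("sit", {})}
    cfg["downstream"] = {**_DOWNSTREAM_DEFAULTS, **cfg.get("downstream", {})}
    return cfg


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _load_cellcycle(sit_cfg: dict, simulated: bool) -> dict[str, GeneSet]:
    cc = sit_cfg.get("cellcycle_gmt")
    if cc is None:
        if not simulated:
            raise ConfigError("sit.cellcycle_gmt required for non-simulated input")
        return standin_cellcycle_sets()
    paths = cc if isinstance(cc, list) else [cc]
    sets: dict[str, GeneSet] = {}
    for p in paths:
        for gs in read_gmt(p):
            sets[gs.name] = gs
    missing = [k for k in ("K", "R", "WP") if k not in sets]
    if missing:
        raise ConfigError(
            f"sit.cellcycle_gmt: sets named {missing} not found (GMT set names "
            "must be K, R and WP)"
        )
    return sets


def run_pipeline(config_path: str | Path, out_dir: str | Path | None = None) -> dict:
    """Execute the full pipeline described by a YAML config.

    Writes sit_scores.tsv, de.tsv, screen.tsv, stratification.tsv, qc.json
    and manifest.json under the output directory, and returns the manifest.
    On a stage failure, outputs of completed stages and a manifest marking
    the failed stage are left behind.
    """
    config_path = Path(config_path)
    cfg = load_config(config_path)
    out = Path(out_dir or cfg.get("out_dir", "senindex_out"))
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "tool": "senindex",
        "version": __version__,
        "config": cfg,
        "config_digest": _digest(config_path),
        "seed": cfg["seed"],
        "started": datetime.now(timezone.utc).isoformat(),
        "stages": {},
        "outputs": {},
        "input_digests": {},
    }

    def finish(stage_failed: str | None = None) -> dict:
        manifest["finished"] = datetime.now(timezone.utc).isoformat()
        if stage_failed:
            manifest["failed_stage"] = stage_failed
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        return manifest

    stage = "input"
    try:
        simulated = "simulate" in cfg["input"]
        if simulated:
            sim_kwargs = dict(cfg["input"]["simulate"] or {})
            sim_kwargs.setdefault("seed", cfg["seed"])
            sim_cfg = SimConfig(**sim_kwargs)
            cm, truth = simulate_tumor(sim_cfg)
            truth_path = out / "truth.tsv"
            truth.truth_frame().assign(cell_id=cm.cell_ids).to_csv(
                truth_path, sep="\t", index=False
            )
            manifest["outputs"]["truth.tsv"] = _digest(truth_path)
            manifest["stages"]["input"] = {
                "mode": "simulate", "config": dataclasses.asdict(sim_cfg)
            }
        else:
            tdir = Path(cfg["input"]["triplet_dir"])
            cm = read_10x_triplet(tdir)
            for f in sorted(tdir.iterdir()):
                if f.is_file():
                    manifest["input_digests"][f.name] = _digest(f)
            ann = cfg["input"].get("annotation")
            if ann:
                table = read_gene_annotation(ann)
                common = cm.gene_ids.intersection(table.index)
                cm.genes.loc[common, "biotype"] = table.loc[common, "biotype"]
                cm.genes.loc[common, "is_mito"] = table.loc[common, "is_mito"]
                manifest["input_digests"]["annotation"] = _digest(Path(ann))
            manifest["stages"]["input"] = {
                "mode": "triplet", "dir": str(tdir),
                "n_cells": cm.n_cells, "n_genes": cm.n_genes,
            }

        stage = "qc"
        qcc = cfg["qc"]
        raw = cm
        cm, rep_cells = filter_cells(cm, qcc["max_mito_frac"], qcc["min_genes"])
        if qcc["protein_coding"]:
            cm = filter_genes_protein_coding(cm)
        nm = normalize(cm)
        if qcc["gate_epithelial"]:
            nm, rep_gate = gate_epithelial(nm)
        else:
            rep_gate = None
        qc_summary = {
            "cells": rep_cells.to_dict(),
            "gating": rep_gate.to_dict() if rep_gate else None,
            "n_genes_before": raw.n_genes,
            "n_genes_after": nm.n_genes,
        }
        with open(out / "qc.json", "w") as fh:
            json.dump(qc_summary, fh, indent=2)
        manifest["outputs"]["qc.json"] = _digest(out / "qc.json")
        manifest["stages"]["qc"] = qc_summary

        stage = "sit"
        sitc = cfg["sit"]
        cellcycle = _load_cellcycle(sitc, simulated)
        params = SitParams(
            seed=cfg["seed"], n_bins=sitc["n_bins"],
            n_ctrl_per_gene=sitc["n_ctrl_per_gene"],
            weight_exponent=sitc["weight_exponent"],
            per_sample=sitc["per_sample"],
        )
        table, audit = run_sit(nm, cellcycle, params)
        scores_path = out / "sit_scores.tsv"
        _write_tsv(table.rename_axis("cell_id").reset_index(), scores_path)
        with open(out / "sit_audit.json", "w") as fh:
            json.dump(audit, fh, indent=2)
        manifest["outputs"]["sit_scores.tsv"] = _digest(scores_path)
        manifest["outputs"]["sit_audit.json"] = _digest(out / "sit_audit.json")
        manifest["stages"]["sit"] = {
            "n_cells": int(nm.n_cells),
            "n_senescent": audit["n_senescent"],
            "quartile_cutpoints": audit.get("quartile_cutpoints"),
        }

        stage = "downstream"
        dsc = cfg["downstream"]
        labels = table["sit_label"].to_numpy()
        if dsc["de"]:
            de = wilcoxon_de(nm, labels, dsc["min_pct"], dsc["fdr_cut"])
            _write_tsv(de, out / "de.tsv")
            manifest["outputs"]["de.tsv"] = _digest(out / "de.tsv")
        if dsc["screen"]:
            screen = survival_correlation_screen(
                nm, table, default_survival_panel(),
                dsc["r_threshold"], dsc["fdr_threshold"],
            )
            _write_tsv(screen, out / "screen.tsv")
            manifest["outputs"]["screen.tsv"] = _digest(out / "screen.tsv")
        if dsc["stratify"]:
            strat = stratify_bcl2_mcl1(
                nm, labels, mcl1_positive_quartiles=dsc["mcl1_positive_quartiles"]
            )
            _write_tsv(strat, out / "stratification.tsv")
            manifest["outputs"]["stratification.tsv"] = _digest(out / "stratification.tsv")
        manifest["stages"]["downstream"] = {k: bool(dsc[k]) for k in ("de", "screen", "stratify")}
    except ConfigError:
        finish(stage)
        raise
    except Exception as exc:
        finish(stage)
        raise PipelineError(stage, str(exc)) from exc

    return finish()
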