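"""End-to-end `simulate -> estimate -> diff -> phenotype` orchestration.

A single YAML/JSON config drives the run; one global seed fans out to
per-stage seeds by fixed offsets so stages are independently reproducible.
All tabular outputs are TSV with a header row and floats at 6 significant
digits; a manifest (config hash, package version, per-stage output
checksums, timestamps, warnings) is written at the end of the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import ExpressionMatrix
from .errors import ConfigError, InputError
from .estimator import FluxEstimator, metabolite_change
from .differential import differential_flux, flux_zscore
from .network import FactorGraph, central_metabolism_fixture, load_network, parse_gene_map
from .phenotype import cluster_stage_distribution, knn_cluster, ssgsea_scores, \
    top_principal_components, tsne_embed
from .simulate import make_two_group_study

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"
_STAGE_SEED_OFFSETS = {"simulate": 101, "estimate": 202, "diff": 303, "phenotype": 404}


@dataclass
class RunConfig:
    seed: int = 42
    output_dir: str = "fluxcentral_run"
    module_table: str | None = None
    gene_map: str | None = None
    expression: str | None = None
    metadata: str | None = None
    simulate: dict = field(default_factory=lambda: {
        "enabled": True, "n_per_group": 60, "perturbed_modules": {},
        "noise_sd": 0.1, "genes_per_module": 3, "slack_sd": 0.0,
    })
    estimate: dict = field(default_factory=lambda: {
        "lambda_scale": 1.0, "hidden_sizes": [8, 4], "epochs": 100,
        "learning_rate": 0.008, "ta_mode": "metabolic_total",
        "convergence_tol": 1e-4, "patience": 10,
    })
    differential: dict = field(default_factory=lambda: {"enabled": True})
    phenotype: dict = field(default_factory=lambda: {
        "enabled": True, "zscore": True, "n_components": 12,
        "k_neighbors": 20, "resolution": 0.8, "perplexity": 30.0,
        "gene_sets": None,
    })

    def stage_seed(self, stage: str) -> int:
        return (int(self.seed) + _STAGE_SEED_OFFSETS[stage]) % (2**31 - 1)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_SCHEMA = {
    "seed": int, "output_dir": str, "module_table": (str, type(None)),
    "gene_map": (str, type(None)), "expression": (str, type(None)),
    "metadata": (str, type(None)), "simulate": dict, "estimate": dict,
    "differential": dict, "phenotype": dict,
}
_SECTION_KEYS = {
    "simulate": {"enabled", "n_per_group", "perturbed_modules", "noise_sd",
                 "genes_per_module", "slack_sd"},
    "estimate": {"lambda_scale", "hidden_sizes", "epochs", "learning_rate",
                 "ta_mode", "convergence_tol", "patience"},
    "differential": {"enabled"},
    "phenotype": {"enabled", "zscore", "n_components", "k_neighbors",
                  "resolution", "perplexity", "gene_sets"},
}


def validate_config(path_or_dict) -> RunConfig:
    """Parse and validate a config; raises :class:`ConfigError` with the full error list."""
    if isinstance(path_or_dict, dict):
        raw = path_or_dict
    else:
        path = Path(path_or_dict)
        try:
            raw = yaml.safe_load(path.read_text())
        except yaml.YAMLError as exc:
            raise ConfigError([f"cannot parse {path}: {exc}"]) from exc
        if not isinstance(raw, dict):
            raise ConfigError([f"{path}: top level must be a mapping"])

    errors: list[str] = []
    for key in raw:
        if key not in _SCHEMA:
            errors.append(f"unknown key {key!r}")
    for key, typ in _SCHEMA.items():
        if key in raw and raw[key] is not None and not isinstance(raw[key], typ):
            errors.append(f"key {key!r}: expected {typ}, got {type(raw[key]).__name__}")
    for section, allowed in _SECTION_KEYS.items():
        for key in (raw.get(section) or {}):
            if key not in allowed:
                errors.append(f"unknown key {section}.{key!r}")

    defaults = RunConfig()
    merged = {}
    for f in dataclasses.fields(RunConfig):
        if f.name in _SECTION_KEYS:
            base = dict(getattr(defaults, f.name))
            base.update(raw.get(f.name) or {})
            merged[f.name] = base
        elif f.name in raw:
            merged[f.name] = raw[f.name]

    est = merged.get("estimate", defaults.estimate)
    if est.get("lambda_scale", 1.0) < 0:
        errors.append("estimate.lambda_scale must be non-negative")
    if est.get("epochs", 1) < 0:
        errors.append("estimate.epochs must be non-negative")
    if est.get("learning_rate", 1.0) <= 0:
        errors.append("estimate.learning_rate must be positive")
    sim = merged.get("simulate", defaults.simulate)
    if sim.get("n_per_group", 1) <= 0:
        errors.append("simulate.n_per_group must be positive")
    for mid, fold in (sim.get("perturbed_modules") or {}).items():
        if not isinstance(fold, (int, float)) or fold <= 0:
            errors.append(f"simulate.perturbed_modules[{mid!r}] must be a positive number")
    if sim.get("noise_sd", 0) < 0:
        errors.append("simulate.noise_sd must be non-negative")
    if not sim.get("enabled", True) and not merged.get("expression"):
        errors.append("expression path required when the simulate stage is disabled")

    if errors:
        raise ConfigError(errors)
    return RunConfig(**merged)


@dataclass
class RunManifest:
    config_hash: str
    package_version: str
    stages: dict
    started: str
    finished: str
    warnings: list
    failed_stage: str | None = None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def run_pipeline(config: RunConfig) -> RunManifest:
    """Run the enabled stages in order, writing each stage's outputs before the next.

    Returns the manifest; on stage failure the manifest (with the failed
    stage flagged and partial outputs recorded) is still written before
    the exception propagates.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    config_hash = hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True).encode()
    ).hexdigest()
    stages: dict[str, dict] = {}
    warn_log: list[str] = []
    failed: str | None = None

    if not config.simulate.get("enabled", True) and not config.expression:
        raise InputError("expression path required when the simulate stage is disabled")

    def record(stage: str, outputs: list[Path]):
        stages[stage] = {"outputs": {p.name: _sha256(p) for p in outputs}}

    try:
        # -- network -----------------------------------------------------
        stage = "network"
        if config.module_table and config.gene_map:
            graph = load_network(config.module_table, config.gene_map)
        else:
            graph = central_metabolism_fixture()
        graph_path = out / "graph.json"
        graph.to_json(graph_path)
        record(stage, [graph_path])

        # -- simulate / load ----------------------------------------------
        stage = "simulate"
        if config.simulate.get("enabled", True):
            sim = config.simulate
            dataset = make_two_group_study(
                graph, n_per_group=int(sim["n_per_group"]),
                perturbed_modules=list((sim.get("perturbed_modules") or {}).items()),
                seed=config.stage_seed("simulate"),
                genes_per_module=int(sim["genes_per_module"]),
                noise_sd=float(sim["noise_sd"]), slack_sd=float(sim.get("slack_sd", 0.0)),
            )
            expr = dataset.expression
            expr_path, meta_path = out / "expression.tsv", out / "metadata.tsv"
            truth_path, params_path = out / "true_flux.tsv", out / "sim_parameters.json"
            expr.to_tsv(expr_path, meta_path)
            _write_tsv(dataset.true_flux, truth_path)
            params_path.write_text(json.dumps({
                "seed": config.stage_seed("simulate"),
                "n_per_group": sim["n_per_group"], "noise_sd": sim["noise_sd"],
                "genes_per_module": sim["genes_per_module"],
                "perturbed_modules": sim.get("perturbed_modules") or {},
            }, indent=1) + "\n")
            record(stage, [expr_path, meta_path, truth_path, params_path])
        else:
            expr = ExpressionMatrix.from_tsv(config.expression, config.metadata)
            stages[stage] = {"outputs": {}, "skipped": True}

        # -- estimate ------------------------------------------------------
        stage = "estimate"
        e = config.estimate
        est = FluxEstimator(
            graph=graph, hidden_sizes=tuple(e["hidden_sizes"]),
            lambda_scale=float(e["lambda_scale"]), ta_mode=str(e["ta_mode"]),
            epochs=int(e["epochs"]), learning_rate=float(e["learning_rate"]),
            convergence_tol=float(e["convergence_tol"]), patience=int(e["patience"]),
            random_state=config.stage_seed("estimate"),
        ).fit(expr)
        flux = est.flux_
        balance = metabolite_change(flux, graph)
        flux_path, bal_path = out / "flux.tsv", out / "balance.tsv"
        trace_path = out / "loss_trace.csv"
        model_path, sidecar_path = out / "model.npz", out / "model.json"
        _write_tsv(flux, flux_path)
        _write_tsv(balance, bal_path)
        est.loss_trace_.to_csv(trace_path, float_format=FLOAT_FORMAT)
        np.savez(model_path, **{
            f"{mid}/{key}": arr
            for mid, params in est.params_.items() for key, arr in params.items()
        })
        sidecar_path.write_text(json.dumps({
            "hidden_sizes": list(e["hidden_sizes"]), "lambda_scale": e["lambda_scale"],
            "ta_mode": e["ta_mode"], "epochs_run": est.n_epochs_,
            "converged": est.converged_, "seed": config.stage_seed("estimate"),
            "negative_fraction": est.negative_fraction_,
        }, indent=1) + "\n")
        record(stage, [flux_path, bal_path, trace_path, sidecar_path])

        meta = expr.metadata

        # -- differential --------------------------------------------------
        stage = "diff"
        if config.differential.get("enabled", True) and meta is not None \
                and "status" in meta.columns and meta["status"].nunique() > 1:
            labels = meta["status"]
            diff_flux = differential_flux(flux, labels)
            diff_bal = differential_flux(balance, labels)
            z = flux_zscore(flux.loc[labels == "tumor"], flux.loc[labels == "normal"])
            paths = [out / "differential_flux.tsv", out / "differential_balance.tsv",
                     out / "flux_zscore.tsv"]
            for df, p in zip((diff_flux, diff_bal, z), paths):
                _write_tsv(df, p)
            record(stage, paths)
        else:
            stages[stage] = {"outputs": {}, "skipped": True}

        # -- phenotype -----------------------------------------------------
        stage = "phenotype"
        if config.phenotype.get("enabled", True):
            ph = config.phenotype
            profile = flux
            if ph.get("zscore", True) and meta is not None and "status" in meta.columns \
                    and (meta["status"] == "normal").sum() >= 2:
                profile = flux_zscore(flux.loc[meta["status"] == "tumor"],
                                      flux.loc[meta["status"] == "normal"])
            n_comp = min(int(ph["n_components"]), min(profile.shape))
            pcs = top_principal_components(profile, n_comp)
            labels = knn_cluster(
                pcs, k_neighbors=min(int(ph["k_neighbors"]), profile.shape[0] - 1),
                resolution=float(ph["resolution"]), seed=config.stage_seed("phenotype"),
            )
            report = cluster_stage_distribution(
                labels, meta if meta is not None else pd.DataFrame(index=profile.index)
            )
            paths = [out / "pca_scores.tsv", out / "clusters.tsv"]
            _write_tsv(pcs, paths[0])
            labels.to_frame().to_csv(paths[1], sep="\t")
            report_path = out / "cluster_report.json"
            report_path.write_text(json.dumps({
                "n_clusters": report.n_clusters,
                "stage_chi2_p": report.stage_chi2_p,
                "composition": {
                    str(k): {"/".join(map(str, col)) if isinstance(col, tuple) else str(col): int(v)
                             for col, v in row.items()}
                    for k, row in report.composition.to_dict("index").items()
                },
            }, indent=1, default=str) + "\n")
            paths.append(report_path)
            if profile.shape[0] > 3 * float(ph["perplexity"]):
                emb = tsne_embed(profile, seed=config.stage_seed("phenotype"),
                                 perplexity=float(ph["perplexity"]))
                tsne_path = out / "tsne.tsv"
                _write_tsv(emb.coordinates, tsne_path)
                paths.append(tsne_path)
            else:
                warn_log.append("too few samples for t-SNE at the configured perplexity; skipped")
            if ph.get("gene_sets"):
                sets = {k: list(v) for k, v in parse_gene_map(ph["gene_sets"]).items()}
                scores = ssgsea_scores(expr, sets)
                es_path = out / "enrichment_scores.tsv"
                _write_tsv(scores, es_path)
                paths.append(es_path)
            record(stage, paths)
        else:
            stages[stage] = {"outputs": {}, "skipped": True}
    except Exception:
        failed = stage
        raise
    finally:
        manifest = RunManifest(
            config_hash=config_hash, package_version=__version__, stages=stages,
            started=started, finished=time.strftime("%Y-%m-%dT%H:%M:%S"),
            warnings=warn_log, failed_stage=failed,
        )
        manifest.to_json(out / "manifest.json")
    return manifest
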