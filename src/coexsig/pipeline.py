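"""Configuration-driven orchestration of the full workflow.

A run is described by one YAML (or dict) configuration naming the input
files, the stages to execute, and the stage parameters; every intermediate
artifact is written to the output directory and a JSON manifest records
inputs, configuration hash, seed, outputs and timings, so a run is
reproducible and auditable from a single file.

Stage order: io -> qc -> preprocess -> network -> modules -> association ->
comparison -> classify.  Stages not requested (or whose inputs are not
configured) are skipped.
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

from . import io as eio
from .association import eigengene_trait_association, select_disease_modules
from .classify import (
    ReferenceSignature,
    SignatureParams,
    classify_variant,
    detect_modules,
)
from .comparison import (
    cross_dataset_overlap,
    gene_set_enrichment,
    module_preservation,
    preservation_to_frame,
    read_gmt,
)
from .modules import ModuleAssignment, export_top_connections, hub_genes, module_eigengenes
from .network import (
    adjacency_from_correlation,
    drop_zero_variance_genes,
    pairwise_correlation,
    pick_soft_threshold,
)
from .preprocess import (
    differential_expression,
    normalize_to_family_control,
    remove_covariates,
    write_de_results,
)
from .synthetic import SyntheticConfig, generate_dataset

log = logging.getLogger("coexsig")

ALL_STAGES = (
    "io", "qc", "preprocess", "network", "modules", "association",
    "comparison", "classify",
)

_KNOWN_KEYS = {
    "expression", "metadata", "orientation", "gene_sets", "ortholog_map",
    "second_expression", "second_assignment", "signature", "stages", "seed",
    "outdir", "qc", "preprocess", "network", "modules", "association",
    "comparison", "classify",
}
_KNOWN_SUBKEYS = {
    "qc": {"z_cut"},
    "preprocess": {"covariates", "family_normalize", "differential_expression",
                   "fdr_cut", "lfc_cut", "covariates_before_family_norm"},
    "network": {"power", "sign_mode", "target_r2"},
    "modules": {"min_module_size", "cut_height", "merge_cut", "top_connections"},
    "association": {"alpha"},
    "comparison": {"n_permutations", "universe_policy"},
    "classify": {"mode", "alpha", "z_threshold", "variant_label"},
}


class PipelineConfigError(ValueError):
    """The pipeline configuration is invalid."""


def load_config(path) -> dict:
    with open(path) as fh:
        try:
            config = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise PipelineConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(config, dict):
        raise PipelineConfigError(f"{path}: configuration must be a mapping")
    return config


def validate_config(config: dict) -> None:
    unknown = set(config) - _KNOWN_KEYS
    if unknown:
        raise PipelineConfigError(f"unknown configuration keys: {sorted(unknown)}")
    for section, allowed in _KNOWN_SUBKEYS.items():
        sub = config.get(section, {})
        if sub is None:
            continue
        if not isinstance(sub, dict):
            raise PipelineConfigError(f"section {section!r} must be a mapping")
        bad = set(sub) - allowed
        if bad:
            raise PipelineConfigError(
                f"unknown keys in section {section!r}: {sorted(bad)}"
            )
    stages = config.get("stages", list(ALL_STAGES))
    bad = set(stages) - set(ALL_STAGES)
    if bad:
        raise PipelineConfigError(f"unknown stages: {sorted(bad)}")
    if "expression" not in config:
        raise PipelineConfigError("configuration must name an 'expression' input")
    if "association" in stages and "metadata" not in config:
        raise PipelineConfigError(
            "the association stage requires a 'metadata' input"
        )


def default_config() -> dict:
    """Full-defaults configuration template (for `coexsig init-config`)."""
    return {
        "expression": "expression.tsv",
        "metadata": "metadata.tsv",
        "orientation": "genes_in_rows",
        "stages": list(ALL_STAGES[:6]),
        "seed": 0,
        "outdir": "coexsig_out",
        "qc": {"z_cut": -2.5},
        "preprocess": {"covariates": [], "family_normalize": False,
                       "differential_expression": False,
                       "fdr_cut": 0.05, "lfc_cut": 0.3},
        "network": {"power": None, "sign_mode": "unsigned", "target_r2": 0.8},
        "modules": {"min_module_size": 30, "cut_height": None,
                    "merge_cut": 0.25, "top_connections": 1000},
        "association": {"alpha": 0.05},
    }


def _config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_pipeline(config: dict, outdir: str | Path | None = None) -> dict:
    """Execute the configured stages and return the run manifest."""
    validate_config(config)
    outdir = Path(outdir or config.get("outdir", "coexsig_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(config.get("stages", ALL_STAGES[:6]))
    seed = int(config.get("seed", 0))
    manifest: dict = {
        "config_hash": _config_hash(config),
        "seed": seed,
        "inputs": {k: str(config[k]) for k in
                   ("expression", "metadata", "gene_sets", "ortholog_map",
                    "second_expression", "signature") if k in config},
        "stages": stages,
        "outputs": [],
        "timings": {},
    }

    def _emit(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        manifest["outputs"].append(str(path))

    t0 = time.time()
    expr = eio.read_expression(
        config["expression"], config.get("orientation", "genes_in_rows")
    )
    meta = None
    if "metadata" in config:
        meta = eio.read_metadata(config["metadata"])
        eio.validate_metadata(meta, expr)
    manifest["timings"]["io"] = round(time.time() - t0, 3)
    log.info("loaded %d genes x %d samples", *expr.shape)

    if "qc" in stages:
        t0 = time.time()
        z_cut = (config.get("qc") or {}).get("z_cut", -2.5)
        outliers = eio.detect_outlier_samples(expr, z_cut=z_cut)
        if outliers:
            log.warning("excluding outlier sample(s): %s", outliers)
            expr = expr.drop(columns=outliers)
            if meta is not None:
                meta = meta.drop(index=outliers)
        _emit("outliers.json", lambda p: Path(p).write_text(json.dumps(outliers)))
        manifest["timings"]["qc"] = round(time.time() - t0, 3)

    if "preprocess" in stages:
        t0 = time.time()
        pp = config.get("preprocess") or {}
        covs = list(pp.get("covariates", []))
        if pp.get("covariates_before_family_norm", False) and covs:
            expr = remove_covariates(expr, meta, covs)
            covs = []
        if pp.get("family_normalize", False):
            expr, meta = normalize_to_family_control(expr, meta)
        if covs:
            expr = remove_covariates(expr, meta, covs)
        if pp.get("differential_expression", False):
            de = differential_expression(
                expr, meta,
                fdr_cut=pp.get("fdr_cut", 0.05), lfc_cut=pp.get("lfc_cut", 0.3),
            )
            _emit("differential_expression.tsv", lambda p: write_de_results(de, p))
        _emit("preprocessed_expression.tsv", lambda p: eio.write_expression(expr, p))
        manifest["timings"]["preprocess"] = round(time.time() - t0, 3)

    assignment = eigengenes = tom = adj = None
    net = config.get("network") or {}
    mod = config.get("modules") or {}
    params = SignatureParams(
        power=net.get("power"),
        sign_mode=net.get("sign_mode", "unsigned"),
        target_r2=net.get("target_r2", 0.8),
        min_module_size=mod.get("min_module_size", 30),
        cut_height=mod.get("cut_height"),
        merge_cut=mod.get("merge_cut", 0.25),
    )
    if "network" in stages or "modules" in stages:
        t0 = time.time()
        expr = drop_zero_variance_genes(expr)
        cor = pairwise_correlation(expr)
        if params.power is None:
            from .network import choose_power
            power, report = choose_power(
                cor, n_samples=expr.shape[1],
                target_r2=params.target_r2, sign_mode=params.sign_mode,
            )
            if report is not None:
                _emit("soft_threshold.tsv",
                      lambda p: report.to_frame().to_csv(p, sep="\t", index=False))
        else:
            power = params.power
        adj = adjacency_from_correlation(cor, power, params.sign_mode)
        manifest["power"] = float(power)
        manifest["timings"]["network"] = round(time.time() - t0, 3)

    if "modules" in stages:
        t0 = time.time()
        from .network import topological_overlap
        from .modules import cluster_genes, cut_tree_dynamic, merge_close_modules
        tom = topological_overlap(adj)
        tree = cluster_genes(1.0 - tom)
        assignment = cut_tree_dynamic(
            tree, expr.index,
            min_module_size=params.min_module_size, cut_height=params.cut_height,
        )
        if assignment.module_labels:
            assignment = merge_close_modules(expr, assignment, params.merge_cut)
        _emit("modules.tsv", lambda p: assignment.to_tsv(p))
        _emit("modules.gmt", lambda p: assignment.to_gmt(p))
        if assignment.module_labels:
            eigengenes = module_eigengenes(expr, assignment)
            _emit("eigengenes.tsv",
                  lambda p: eigengenes.values.to_csv(p, sep="\t", index_label="module"))
            hubs = hub_genes(adj, expr, assignment, eigengenes)
            hub_frame = pd.concat(
                {label: frame for label, frame in hubs.items()}, names=["module", "gene_id"]
            )
            _emit("hub_genes.tsv", lambda p: hub_frame.to_csv(p, sep="\t"))
            n_edges = mod.get("top_connections", 1000)
            largest = assignment.sizes().idxmax()
            edges = export_top_connections(tom, assignment, largest, n_edges)
            _emit("top_connections.tsv",
                  lambda p: edges.to_csv(p, sep="\t", index=False))
        manifest["timings"]["modules"] = round(time.time() - t0, 3)

    if "association" in stages and eigengenes is not None:
        t0 = time.time()
        alpha = (config.get("association") or {}).get("alpha", 0.05)
        assoc = eigengene_trait_association(eigengenes, meta)
        assoc = assoc.join(assignment.sizes().rename("size"))
        _emit("module_trait.tsv",
              lambda p: assoc.to_csv(p, sep="\t", index_label="module"))
        selected = select_disease_modules(assoc, alpha=alpha)
        manifest["disease_modules"] = selected
        manifest["timings"]["association"] = round(time.time() - t0, 3)

    if "comparison" in stages:
        t0 = time.time()
        comp = config.get("comparison") or {}
        if "gene_sets" in config and assignment is not None:
            sets = read_gmt(config["gene_sets"])
            enr = gene_set_enrichment(
                assignment, sets,
                universe_policy=comp.get("universe_policy", "all_genes"),
            )
            _emit("enrichment.tsv", lambda p: enr.to_csv(p, sep="\t", index=False))
        if "second_expression" in config and assignment is not None:
            expr_b = eio.read_expression(config["second_expression"])
            pres = module_preservation(
                expr, expr_b, assignment,
                n_permutations=comp.get("n_permutations", 100), seed=seed,
            )
            _emit("preservation.tsv",
                  lambda p: preservation_to_frame(pres).to_csv(p, sep="\t"))
            if "second_assignment" in config and "ortholog_map" in config:
                labels_b = pd.read_csv(
                    config["second_assignment"], sep="\t", index_col=0
                ).iloc[:, 0]
                omap = pd.read_csv(config["ortholog_map"], sep="\t")
                pmat, fdr, counts = cross_dataset_overlap(
                    assignment, ModuleAssignment(labels=labels_b), omap
                )
                _emit("cross_overlap_p.tsv", lambda p: pmat.to_csv(p, sep="\t"))
                _emit("cross_overlap_fdr.tsv", lambda p: fdr.to_csv(p, sep="\t"))
        manifest["timings"]["comparison"] = round(time.time() - t0, 3)

    if "classify" in stages and "signature" in config:
        t0 = time.time()
        cl = config.get("classify") or {}
        signature = ReferenceSignature.from_json(config["signature"])
        # classification does its own family normalization, so it always
        # starts from the raw input files
        raw_expr = eio.read_expression(
            config["expression"], config.get("orientation", "genes_in_rows")
        )
        raw_meta = eio.read_metadata(config["metadata"])
        call = classify_variant(
            raw_expr,
            raw_meta,
            signature,
            mode=cl.get("mode"),
            alpha=cl.get("alpha", 0.05),
            z_threshold=cl.get("z_threshold", 2.0),
            variant_label=cl.get("variant_label", "candidate"),
        )
        _emit("pathogenicity_call.json", lambda p: call.to_json(p))
        manifest["call"] = call.call
        manifest["timings"]["classify"] = round(time.time() - t0, 3)

    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest


def simulate_to_files(config: dict, outdir: str | Path) -> dict:
    """Generate a synthetic cohort and write it as pipeline-ready files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    known = {f.name for f in SyntheticConfig.__dataclass_fields__.values()}
    bad = set(config) - known
    if bad:
        raise PipelineConfigError(f"unknown synthetic-data keys: {sorted(bad)}")
    syn = SyntheticConfig(**config)
    expr, meta, truth = generate_dataset(syn)
    eio.write_expression(expr, outdir / "expression.tsv")
    eio.write_metadata(meta, outdir / "metadata.tsv")
    truth.to_json(outdir / "truth.json")
    return {
        "outputs": [str(outdir / n) for n in
                    ("expression.tsv", "metadata.tsv", "truth.json")],
        "seed": syn.seed,
    }
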