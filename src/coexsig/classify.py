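"""Disease-signature derivation and single-patient classification.

This is the diagnostic endpoint of the workflow: given a reference cohort
of affected and control samples, derive the disease transcriptional
signature (the disease-associated co-expression modules); given a candidate
variant carrier's expression data, test whether their profile is associated
with that signature.

Two classification modes are provided, because standard network analysis
does not define module construction from a single normalized sample:

``module_overlap``
    For patient datasets with enough effective samples (>= 8 after family
    normalization): build co-expression modules in the patient data and
    hypergeometric-test every patient module against each signature module
    over the shared gene universe.

``deviation_set`` (default for singletons)
    Family-normalize, form the patient's deviation gene set — genes whose
    normalized value exceeds a robust z threshold (median/MAD of the
    normalized control samples) — and hypergeometric-test that set against
    the signature modules.

In both modes the decision statistic is the minimum BH-adjusted p across
signature modules, and the call is ``supported`` iff it falls below alpha.
The call expresses evidence of signature association only; it is not a
clinical variant classification.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .association import eigengene_trait_association, select_disease_modules
from .comparison import hypergeometric_overlap
from .modules import (
    ModuleAssignment,
    cluster_genes,
    cut_tree_dynamic,
    merge_close_modules,
    module_eigengenes,
)
from .network import (
    adjacency_from_correlation,
    choose_power,
    drop_zero_variance_genes,
    pairwise_correlation,
    topological_overlap,
)
from .preprocess import normalize_to_family_control, remove_covariates

__all__ = ["SignatureParams", "ReferenceSignature", "PathogenicityCall",
           "derive_signature", "classify_variant", "detect_modules"]


@dataclass(frozen=True)
class SignatureParams:
    """Network / module / association parameters for signature derivation."""

    power: float | None = None          # None = pick by scale-free fit
    sign_mode: str = "unsigned"
    target_r2: float = 0.8
    min_module_size: int = 30
    cut_height: float | None = None     # None = 0.99 x max merge height
    merge_cut: float = 0.25
    alpha: float = 0.05
    covariates: tuple[str, ...] = ()


@dataclass
class ReferenceSignature:
    """Disease-associated module gene sets plus their derivation provenance."""

    modules: dict[str, set[str]]        # display name -> gene set
    universe: set[str]
    provenance: dict

    def __post_init__(self):
        for name, genes in self.modules.items():
            stray = set(genes) - self.universe
            if stray:
                raise ValueError(
                    f"signature module {name!r} has genes outside its universe: "
                    f"{sorted(stray)[:5]}"
                )

    def to_json(self, path) -> None:
        payload = {
            "modules": {k: sorted(v) for k, v in self.modules.items()},
            "universe": sorted(self.universe),
            "provenance": self.provenance,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ReferenceSignature":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            modules={k: set(v) for k, v in payload["modules"].items()},
            universe=set(payload["universe"]),
            provenance=payload.get("provenance", {}),
        )


@dataclass
class PathogenicityCall:
    """Outcome of testing one candidate profile against a signature."""

    variant: str
    best_module_p: float                # minimum raw p across signature modules
    adjusted_p: float                   # minimum BH-adjusted p (decision statistic)
    call: str                           # "supported" | "not_supported"
    alpha: float
    mode: str
    per_module_p: dict[str, float] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


# ---------------------------------------------------------------------------
# Module detection sub-pipeline (shared by derivation and overlap mode)
# ---------------------------------------------------------------------------

def detect_modules(
    expr: pd.DataFrame, params: SignatureParams
) -> tuple[ModuleAssignment, pd.DataFrame, float]:
    """Correlation -> adjacency -> TOM -> clustering -> tree cut -> merge.

    Returns the merged module assignment, the TOM, and the power used.
    """
    expr = drop_zero_variance_genes(expr)
    cor = pairwise_correlation(expr)
    if params.power is None:
        power, _ = choose_power(
            cor, n_samples=expr.shape[1],
            target_r2=params.target_r2, sign_mode=params.sign_mode,
        )
    else:
        power = params.power
    adj = adjacency_from_correlation(cor, power, params.sign_mode)
    tom = topological_overlap(adj)
    tree = cluster_genes(1.0 - tom)
    assignment = cut_tree_dynamic(
        tree, expr.index,
        min_module_size=params.min_module_size,
        cut_height=params.cut_height,
    )
    if assignment.module_labels:
        assignment = merge_close_modules(expr, assignment, params.merge_cut)
    return assignment, tom, power


def derive_signature(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    params: SignatureParams = SignatureParams(),
    name_prefix: str = "Mod",
) -> ReferenceSignature:
    """Derive the disease signature from a reference cohort.

    Runs covariate removal (if requested), network construction, module
    detection, eigengene computation and eigengene-trait association; the
    signature is the set of disease-associated modules with the full
    derivation parameters recorded.
    """
    meta = meta.loc[expr.columns]
    n_cases = int((meta["status"] == 1).sum())
    n_ctrl = int((meta["status"] == 0).sum())
    if n_cases < 2 or n_ctrl < 2:
        raise ValueError(
            f"signature derivation needs >= 2 cases and >= 2 controls "
            f"(got {n_cases} and {n_ctrl})"
        )
    if params.covariates:
        expr = remove_covariates(expr, meta, list(params.covariates))
    assignment, _, power = detect_modules(expr, params)
    modules: dict[str, set[str]] = {}
    assoc_table = None
    if assignment.module_labels:
        eg = module_eigengenes(expr, assignment)
        assoc = eigengene_trait_association(eg, meta)
        selected = select_disease_modules(assoc, alpha=params.alpha)
        assoc_table = assoc.reset_index().to_dict("records")
        for label in selected:
            modules[f"{name_prefix}{label:02d}"] = set(assignment.genes(label))
    provenance = {
        "power": float(power),
        "sign_mode": params.sign_mode,
        "min_module_size": params.min_module_size,
        "merge_cut": params.merge_cut,
        "alpha": params.alpha,
        "n_cases": n_cases,
        "n_controls": n_ctrl,
        "n_genes": int(expr.shape[0]),
        "association": assoc_table,
    }
    return ReferenceSignature(
        modules=modules, universe=set(expr.index), provenance=provenance
    )


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def _deviation_set(
    normalized: pd.DataFrame,
    meta: pd.DataFrame,
    z_threshold: float,
) -> set[str]:
    """Genes whose affected normalized value robustly deviates from controls.

    The control spread per gene is the MAD (scaled to be consistent with a
    normal SD) of the normalized control samples; with several affected
    samples their median profile is used.
    """
    affected = normalized.loc[:, (meta["status"] == 1).to_numpy()]
    controls = normalized.loc[:, (meta["status"] == 0).to_numpy()]
    if affected.shape[1] == 0:
        raise ValueError("no affected sample in the patient dataset")
    if controls.shape[1] < 2:
        raise ValueError(
            f"deviation-set mode needs >= 2 normalized control samples, "
            f"got {controls.shape[1]}"
        )
    profile = affected.median(axis=1)
    center = controls.median(axis=1)
    mad = (controls.sub(center, axis=0)).abs().median(axis=1) * 1.4826
    mad = mad.replace(0, np.nan)
    z = (profile - center) / mad
    return set(z.index[z.abs() > z_threshold])


def classify_variant(
    patient_expr: pd.DataFrame,
    patient_meta: pd.DataFrame,
    signature: ReferenceSignature,
    mode: str | None = None,
    alpha: float = 0.05,
    z_threshold: float = 2.0,
    variant_label: str = "candidate",
    module_params: SignatureParams = SignatureParams(min_module_size=10),
) -> PathogenicityCall:
    """Test a candidate patient's profile against a reference signature.

    The patient dataset must be family-normalizable (one control per
    family).  ``mode`` defaults to ``deviation_set`` when fewer than 8
    effective (post-normalization) samples remain, else ``module_overlap``.
    """
    if not signature.modules:
        raise ValueError("reference signature contains no modules")
    patient_meta = patient_meta.loc[patient_expr.columns]
    normalized, norm_meta = normalize_to_family_control(patient_expr, patient_meta)
    if mode is None:
        mode = "module_overlap" if normalized.shape[1] >= 8 else "deviation_set"
    if mode not in ("module_overlap", "deviation_set"):
        raise ValueError(f"unknown mode {mode!r}")

    universe = signature.universe & set(patient_expr.index)
    if not universe:
        raise ValueError("patient genes do not intersect the signature universe")
    sig_modules = {
        name: set(genes) & universe for name, genes in signature.modules.items()
    }

    if mode == "deviation_set":
        dev = _deviation_set(normalized, norm_meta, z_threshold) & universe
        if not dev:
            warnings.warn("empty deviation set; calling not_supported with p = 1")
            return PathogenicityCall(
                variant=variant_label, best_module_p=1.0, adjusted_p=1.0,
                call="not_supported", alpha=alpha, mode=mode,
                per_module_p={name: 1.0 for name in sig_modules},
                metadata={"deviation_set_size": 0, "universe_size": len(universe)},
            )
        per_module = {
            name: hypergeometric_overlap(dev, genes, universe).p
            for name, genes in sig_modules.items()
        }
        extra = {"deviation_set_size": len(dev), "universe_size": len(universe),
                 "z_threshold": z_threshold}
    else:
        assignment, _, _ = detect_modules(normalized, module_params)
        if not assignment.module_labels:
            warnings.warn("no modules detected in patient data; not_supported, p = 1")
            return PathogenicityCall(
                variant=variant_label, best_module_p=1.0, adjusted_p=1.0,
                call="not_supported", alpha=alpha, mode=mode,
                per_module_p={name: 1.0 for name in sig_modules},
                metadata={"n_patient_modules": 0, "universe_size": len(universe)},
            )
        # BH across the full patient-module x signature-module test matrix
        all_p = []
        per_module = {name: 1.0 for name in sig_modules}
        for name, genes in sig_modules.items():
            for label in assignment.module_labels:
                members = set(assignment.genes(label)) & universe
                if not members:
                    continue
                p = hypergeometric_overlap(members, genes, universe).p
                all_p.append(p)
                per_module[name] = min(per_module[name], p)
        extra = {
            "n_patient_modules": len(assignment.module_labels),
            "universe_size": len(universe),
        }
        if all_p:
            _, adj_all, _, _ = multipletests(np.array(all_p), method="fdr_bh")
            best_p = float(min(all_p))
            adjusted = float(adj_all.min())
        else:
            best_p = adjusted = 1.0
        return PathogenicityCall(
            variant=variant_label, best_module_p=best_p, adjusted_p=adjusted,
            call="supported" if adjusted < alpha else "not_supported",
            alpha=alpha, mode=mode,
            per_module_p={n: float(p) for n, p in per_module.items()},
            metadata=extra,
        )

    names = list(per_module)
    raw = np.array([per_module[n] for n in names])
    _, adj, _, _ = multipletests(raw, method="fdr_bh")
    best_p = float(raw.min())
    adjusted = float(adj.min())
    return PathogenicityCall(
        variant=variant_label,
        best_module_p=best_p,
        adjusted_p=adjusted,
        call="supported" if adjusted < alpha else "not_supported",
        alpha=alpha,
        mode=mode,
        per_module_p={n: float(p) for n, p in per_module.items()},
        metadata=extra,
    )
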