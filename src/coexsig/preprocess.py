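"""Covariate removal, family-control normalization and differential expression.

Covariate removal is plain per-gene ordinary-least-squares residualization
(categorical covariates one-hot encoded with one level dropped); the grand
mean of each gene is added back so the output stays on the input scale.
Family-control normalization subtracts, per gene, the expression of the one
designated unaffected control of each family — the within-family baseline —
cancelling family-specific background exactly.  Differential expression is a
per-gene Welch two-sample t-test on log-scale values with Benjamini–Hochberg
FDR control and the conventional joint threshold on FDR and |log2 fold
change|.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "remove_covariates",
    "normalize_to_family_control",
    "differential_expression",
    "write_de_results",
]


def _design_matrix(meta: pd.DataFrame, covariate_names: list[str]) -> pd.DataFrame:
    """Intercept + one-hot-encoded covariates; raises on rank deficiency."""
    cols = {"__intercept__": np.ones(len(meta))}
    for name in covariate_names:
        if name not in meta.columns:
            raise ValueError(f"covariate {name!r} not present in metadata")
        col = meta[name]
        if pd.api.types.is_numeric_dtype(col):
            cols[name] = col.to_numpy(dtype=float)
        else:
            dummies = pd.get_dummies(col.astype(str), prefix=name, drop_first=True)
            for c in dummies.columns:
                cols[c] = dummies[c].to_numpy(dtype=float)
    design = pd.DataFrame(cols, index=meta.index)
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        # identify offending columns: those whose removal restores full rank
        collinear = []
        x = design.to_numpy()
        for j, name in enumerate(design.columns):
            reduced = np.delete(x, j, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                collinear.append(name)
        raise ValueError(f"design matrix is rank-deficient; collinear columns: {collinear}")
    return design


def remove_covariates(
    expr: pd.DataFrame, meta: pd.DataFrame, covariate_names: list[str]
) -> pd.DataFrame:
    """Regress named covariates out of every gene, keeping the grand mean.

    The trait of interest must never be passed here; only nuisance
    covariates (batch, family, age, ...) are removed.
    """
    if not covariate_names:
        return expr.copy()
    meta = meta.loc[expr.columns]
    design = _design_matrix(meta, list(covariate_names))
    x = design.to_numpy(dtype=float)
    y = expr.to_numpy(dtype=float).T            # samples x genes
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    out = resid.T + expr.to_numpy().mean(axis=1, keepdims=True)
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


def normalize_to_family_control(
    expr: pd.DataFrame, meta: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Subtract each family's control column from its other members.

    Every family must contain exactly one sample flagged as its baseline
    control: the sample with ``family_control == 1`` where that metadata
    column exists, else the sample with ``status == 0``.  The control
    columns themselves (identically zero after subtraction) are dropped.
    Returns the normalized matrix and the metadata restricted to the
    remaining samples.
    """
    meta = meta.loc[expr.columns]
    if "family_id" not in meta.columns:
        raise ValueError("family normalization requires a 'family_id' metadata column")
    bad = []
    control_of: dict[str, str] = {}
    flag = "family_control" if "family_control" in meta.columns else "status"
    for fam, members in meta.groupby("family_id"):
        if flag == "family_control":
            controls = members.index[members["family_control"] == 1]
        else:
            controls = members.index[members["status"] == 0]
        if len(controls) != 1:
            bad.append(f"{fam} ({len(controls)} controls)")
        else:
            control_of[fam] = controls[0]
    if bad:
        raise ValueError(
            "each family must have exactly one control sample; offending families: "
            + ", ".join(bad)
        )
    keep = [s for s in expr.columns if s != control_of[meta.loc[s, "family_id"]]]
    out = expr[keep].copy()
    for s in keep:
        out[s] = expr[s] - expr[control_of[meta.loc[s, "family_id"]]]
    return out, meta.loc[keep]


def differential_expression(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    fdr_cut: float = 0.05,
    lfc_cut: float = 0.3,
) -> pd.DataFrame:
    """Per-gene Welch t-test of affected vs control with BH-FDR.

    ``expr`` is assumed log-scale, so the group-mean difference is a log2
    fold change directly.  Returns a DataFrame with columns ``log2fc``,
    ``p``, ``fdr`` and ``passes`` where ``passes`` means
    ``fdr < fdr_cut and |log2fc| > lfc_cut``.
    """
    meta = meta.loc[expr.columns]
    cases = expr.loc[:, (meta["status"] == 1).to_numpy()]
    ctrls = expr.loc[:, (meta["status"] == 0).to_numpy()]
    if cases.shape[1] < 2 or ctrls.shape[1] < 2:
        raise ValueError(
            f"need >= 2 samples per group (got {cases.shape[1]} affected, "
            f"{ctrls.shape[1]} control)"
        )
    log2fc = cases.mean(axis=1) - ctrls.mean(axis=1)
    t, p = stats.ttest_ind(
        cases.to_numpy(), ctrls.to_numpy(), axis=1, equal_var=False
    )
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance-in-both-groups genes
    _, fdr, _, _ = multipletests(p, method="fdr_bh")
    out = pd.DataFrame(
        {"log2fc": log2fc, "p": p, "fdr": fdr}, index=expr.index
    )
    out["passes"] = (out["fdr"] < fdr_cut) & (out["log2fc"].abs() > lfc_cut)
    return out


def write_de_results(de: pd.DataFrame, path) -> None:
    de.to_csv(path, sep="\t", index_label="gene_id")
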