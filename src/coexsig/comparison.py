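"""Cross-dataset module comparison: overlap, preservation, enrichment.

Module membership between two networks (possibly from different species,
linked by a one-to-one ortholog map) is compared with the exact upper-tail
hypergeometric test over a stated gene universe.  Module preservation asks
whether a reference module's density (mean within-module adjacency) and
connectivity pattern recur in an independent test dataset, expressed as
permutation z-scores against random same-size gene sets.  Gene-set
over-representation against user-supplied GMT collections uses the same
hypergeometric machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .modules import ModuleAssignment
from .network import adjacency_from_correlation, pairwise_correlation

__all__ = [
    "OverlapResult",
    "PreservationResult",
    "read_gmt",
    "write_gmt",
    "hypergeometric_overlap",
    "cross_dataset_overlap",
    "module_preservation",
    "preservation_to_frame",
    "gene_set_enrichment",
]


@dataclass(frozen=True)
class OverlapResult:
    """Hypergeometric membership overlap of two gene sets in a universe."""

    set_a_size: int
    set_b_size: int
    universe_size: int
    overlap: int
    p: float


@dataclass(frozen=True)
class PreservationResult:
    """Permutation z-scores for one reference module in a test dataset."""

    module: int
    z_density: float
    z_connectivity: float
    z_summary: float
    n_permutations: int
    seed: int


# ---------------------------------------------------------------------------
# GMT gene-set collections
# ---------------------------------------------------------------------------

def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT file (set name, description, member genes per line)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(parts[2:])
    return sets


def write_gmt(sets: dict[str, set[str]], path, description: str = "gene set") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write(f"{name}\t{description}\t" + "\t".join(sorted(genes)) + "\n")


# ---------------------------------------------------------------------------
# Hypergeometric overlap
# ---------------------------------------------------------------------------

def hypergeometric_overlap(set_a, set_b, universe) -> OverlapResult:
    """Exact upper-tail probability of at least the observed overlap.

    ``p = P(X >= overlap)`` for X hypergeometric with ``|universe|`` items,
    ``|A|`` marked, ``|B|`` drawn; evaluated via the survival function in
    log-stable form.
    """
    universe = set(universe)
    set_a, set_b = set(set_a), set(set_b)
    if not universe:
        raise ValueError("universe must be non-empty")
    stray_a = set_a - universe
    stray_b = set_b - universe
    if stray_a or stray_b:
        raise ValueError(
            f"sets must be subsets of the universe; offenders: "
            f"A-side {sorted(stray_a)[:5]}, B-side {sorted(stray_b)[:5]}"
        )
    n = len(universe)
    overlap = len(set_a & set_b)
    # P(X >= k) = sf(k - 1); sf at k-1 <= -1 is exactly 1
    p = float(stats.hypergeom.sf(overlap - 1, n, len(set_a), len(set_b)))
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return OverlapResult(
        set_a_size=len(set_a),
        set_b_size=len(set_b),
        universe_size=n,
        overlap=overlap,
        p=p,
    )


def cross_dataset_overlap(
    assignment_a: ModuleAssignment,
    assignment_b: ModuleAssignment,
    ortholog_map: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """All pairwise module-membership overlaps across an ortholog map.

    The universe is the set of genes present in BOTH datasets through the
    one-to-one ortholog map; each module's membership is intersected with
    that universe before testing, and the unassigned pools are excluded.

    Returns ``(p, fdr, overlap_counts)`` DataFrames with A-modules as rows
    and B-modules as columns; ``fdr`` is BH-adjusted across the whole
    matrix.
    """
    if ortholog_map.shape[1] != 2:
        raise ValueError("ortholog map must have exactly two columns")
    a_col, b_col = ortholog_map.columns[:2]
    if ortholog_map[a_col].duplicated().any() or ortholog_map[b_col].duplicated().any():
        raise ValueError("ortholog map must be one-to-one (duplicate ids found)")
    genes_a = set(assignment_a.labels.index)
    genes_b = set(assignment_b.labels.index)
    mapped = ortholog_map[
        ortholog_map[a_col].isin(genes_a) & ortholog_map[b_col].isin(genes_b)
    ]
    if mapped.empty:
        raise ValueError("ortholog map shares no genes with both datasets")
    a_to_b = dict(zip(mapped[a_col], mapped[b_col]))
    universe = set(a_to_b.values())          # universe expressed in B's id space
    mods_a = assignment_a.module_labels
    mods_b = assignment_b.module_labels
    if not mods_a or not mods_b:
        raise ValueError("both assignments must contain at least one module")
    p = pd.DataFrame(index=mods_a, columns=mods_b, dtype=float)
    counts = pd.DataFrame(index=mods_a, columns=mods_b, dtype=int)
    for ma in mods_a:
        image_a = {a_to_b[g] for g in assignment_a.genes(ma) if g in a_to_b}
        for mb in mods_b:
            members_b = set(assignment_b.genes(mb)) & universe
            res = hypergeometric_overlap(image_a, members_b, universe)
            p.loc[ma, mb] = res.p
            counts.loc[ma, mb] = res.overlap
    flat = p.to_numpy().ravel()
    _, fdr_flat, _, _ = multipletests(flat, method="fdr_bh")
    fdr = pd.DataFrame(fdr_flat.reshape(p.shape), index=p.index, columns=p.columns)
    return p, fdr, counts


# ---------------------------------------------------------------------------
# Module preservation
# ---------------------------------------------------------------------------

def _preservation_stats(
    expr_ref: pd.DataFrame,
    expr_test: pd.DataFrame,
    genes: list[str],
    power: float,
    sign_mode: str,
) -> tuple[float, float]:
    """(density in test data, ref/test intramodular-connectivity correlation)."""
    adj_t = adjacency_from_correlation(
        pairwise_correlation(expr_test.loc[genes]), power, sign_mode
    ).values.to_numpy()
    np.fill_diagonal(adj_t, 0.0)
    m = len(genes)
    density = adj_t.sum() / (m * (m - 1))
    adj_r = adjacency_from_correlation(
        pairwise_correlation(expr_ref.loc[genes]), power, sign_mode
    ).values.to_numpy()
    np.fill_diagonal(adj_r, 0.0)
    k_ref = adj_r.sum(axis=1)
    k_test = adj_t.sum(axis=1)
    if k_ref.std() == 0 or k_test.std() == 0:
        cor_k = 0.0
    else:
        cor_k = float(np.corrcoef(k_ref, k_test)[0, 1])
    return float(density), cor_k


def module_preservation(
    expr_ref: pd.DataFrame,
    expr_test: pd.DataFrame,
    assignment_ref: ModuleAssignment,
    n_permutations: int = 100,
    seed: int = 0,
    power: float = 6.0,
    sign_mode: str = "unsigned",
) -> list[PreservationResult]:
    """Permutation z-scores of module density and connectivity preservation.

    For each reference module, the observed statistics are the mean
    within-module adjacency in the TEST data and the correlation between
    intramodular connectivity computed in reference vs test data.  The null
    distribution comes from ``n_permutations`` random gene sets of the same
    size drawn from the genes shared by both matrices.  ``z_summary`` is
    the mean of the two z-scores.
    """
    if n_permutations < 20:
        raise ValueError(f"n_permutations must be >= 20, got {n_permutations}")
    shared = expr_ref.index.intersection(expr_test.index)
    if len(shared) < 30:
        raise ValueError(
            f"need >= 30 genes shared between reference and test data, got {len(shared)}"
        )
    rng = np.random.default_rng(seed)
    shared_list = list(shared)
    results = []
    for label in assignment_ref.module_labels:
        genes = [g for g in assignment_ref.genes(label) if g in set(shared)]
        if len(genes) < 3:
            warnings.warn(f"module {label} has < 3 shared genes; skipped")
            continue
        obs_density, obs_cork = _preservation_stats(
            expr_ref, expr_test, genes, power, sign_mode
        )
        null_density = np.empty(n_permutations)
        null_cork = np.empty(n_permutations)
        for b in range(n_permutations):
            rand_genes = list(rng.choice(shared_list, size=len(genes), replace=False))
            null_density[b], null_cork[b] = _preservation_stats(
                expr_ref, expr_test, rand_genes, power, sign_mode
            )
        z_density = _z(obs_density, null_density)
        z_connectivity = _z(obs_cork, null_cork)
        results.append(
            PreservationResult(
                module=label,
                z_density=z_density,
                z_connectivity=z_connectivity,
                z_summary=(z_density + z_connectivity) / 2.0,
                n_permutations=n_permutations,
                seed=seed,
            )
        )
    return results


def _z(observed: float, null: np.ndarray) -> float:
    sd = null.std(ddof=1)
    # a numerically degenerate null (e.g. identical ref/test data, where every
    # permutation scores exactly alike) carries no evidence either way
    if sd <= 1e-8 * max(1.0, abs(float(null.mean()))):
        return 0.0
    return float((observed - null.mean()) / sd)


def preservation_to_frame(results: list[PreservationResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results]).set_index("module")


# ---------------------------------------------------------------------------
# Gene-set over-representation
# ---------------------------------------------------------------------------

def gene_set_enrichment(
    assignment: ModuleAssignment,
    sets: dict[str, set[str]],
    universe_policy: str = "all_genes",
) -> pd.DataFrame:
    """Hypergeometric over-representation of each gene set in each module.

    ``universe_policy`` picks the background: every gene of the source
    matrix (``all_genes``) or only module-assigned genes
    (``assigned_genes``).  Sets are intersected with the universe; empty
    intersections are dropped with a warning.  BH correction is applied
    across sets within each module; rows are sorted by p within module, so
    the head of each module's block is its "top sets" view.
    """
    if universe_policy == "all_genes":
        universe = set(assignment.labels.index)
    elif universe_policy == "assigned_genes":
        universe = set(assignment.labels.index[assignment.labels > 0])
    else:
        raise ValueError(f"unknown universe_policy {universe_policy!r}")
    usable = {}
    for name, genes in sets.items():
        inter = set(genes) & universe
        if not inter:
            warnings.warn(f"gene set {name!r} has no genes in the universe; dropped")
            continue
        usable[name] = inter
    if not usable:
        raise ValueError("no gene set intersects the universe")
    rows = []
    for label in assignment.module_labels:
        members = set(assignment.genes(label)) & universe
        ps = []
        for name, genes in usable.items():
            res = hypergeometric_overlap(members, genes, universe)
            ps.append((name, res))
        _, fdr, _, _ = multipletests([r.p for _, r in ps], method="fdr_bh")
        for (name, res), q in zip(ps, fdr):
            rows.append(
                {
                    "module": label,
                    "gene_set": name,
                    "overlap": res.overlap,
                    "set_size": res.set_b_size,
                    "module_size": res.set_a_size,
                    "universe_size": res.universe_size,
                    "p": res.p,
                    "fdr": q,
                }
            )
    out = pd.DataFrame(rows)
    return out.sort_values(["module", "p"], kind="stable").reset_index(drop=True)
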