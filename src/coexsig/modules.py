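"""Module detection: clustering, tree cutting, eigengenes, merging, hubs.

Genes are clustered by average-linkage hierarchical clustering of the
topological-overlap dissimilarity (1 - TOM).  Modules are branches of the
dendrogram below a static cut height with at least ``min_module_size``
leaves (the deterministic "tree" variant of dynamic tree cut); genes in
smaller branches stay unassigned (label 0).  Each module is summarized by
its eigengene — the first principal component of the standardized member
submatrix — and modules whose eigengenes are nearly collinear are merged.
Hub genes are ranked by intramodular connectivity (kIM, summed adjacency to
same-module genes) and by module membership (kME, correlation with the
eigengene).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .network import Adjacency

__all__ = [
    "ModuleAssignment",
    "Eigengenes",
    "cluster_genes",
    "cut_tree_dynamic",
    "module_eigengenes",
    "merge_close_modules",
    "hub_genes",
    "export_top_connections",
]


@dataclass
class ModuleAssignment:
    """Partition of genes into labeled modules; label 0 = unassigned pool."""

    labels: pd.Series                       # gene_id -> int label
    label_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        self.labels = self.labels.astype(int)
        if (self.labels < 0).any():
            raise ValueError("module labels must be nonnegative")
        if self.labels.index.duplicated().any():
            raise ValueError("duplicate gene ids in module assignment")

    @property
    def module_labels(self) -> list[int]:
        """Sorted labels of proper modules (excludes the unassigned pool)."""
        return sorted(set(self.labels.unique()) - {0})

    def genes(self, label: int) -> list[str]:
        return self.labels.index[self.labels == label].tolist()

    def sizes(self) -> pd.Series:
        return self.labels[self.labels > 0].value_counts().sort_index()

    def name_of(self, label: int) -> str:
        return self.label_names.get(label, f"M{label:02d}")

    def to_tsv(self, path) -> None:
        self.labels.rename("module").to_csv(path, sep="\t", index_label="gene_id")

    def to_gmt(self, path, description: str = "coexpression module") -> None:
        with open(path, "w") as fh:
            for label in self.module_labels:
                genes = "\t".join(self.genes(label))
                fh.write(f"{self.name_of(label)}\t{description}\t{genes}\n")


@dataclass
class Eigengenes:
    """Per-module, per-sample first-PC summary profiles, unit variance."""

    values: pd.DataFrame                    # module label (rows) x samples (cols)
    variance_explained: pd.Series           # module label -> fraction in [0, 1]

    def vector(self, label: int) -> pd.Series:
        return self.values.loc[label]


# ---------------------------------------------------------------------------
# Clustering and tree cut
# ---------------------------------------------------------------------------

def cluster_genes(dissimilarity: pd.DataFrame) -> np.ndarray:
    """Average-linkage hierarchical clustering of a gene dissimilarity matrix.

    Returns a scipy linkage matrix (merge tree with heights).
    """
    d = dissimilarity.to_numpy()
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("dissimilarity must be a symmetric square matrix")
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return linkage(squareform(d, checks=False), method="average")


def cut_tree_dynamic(
    tree: np.ndarray,
    gene_ids: pd.Index,
    min_module_size: int = 30,
    cut_height: float | None = None,
) -> ModuleAssignment:
    """Static-height tree cut with a minimum branch size.

    All merges above ``cut_height`` (default 0.99 x the tallest merge) are
    cut; each remaining branch with at least ``min_module_size`` leaves
    becomes a module.  Labels are assigned by decreasing module size (ties
    broken by the lowest member gene index); smaller branches get label 0.
    """
    if min_module_size < 2:
        raise ValueError(f"min_module_size must be >= 2, got {min_module_size}")
    max_height = float(tree[:, 2].max()) if len(tree) else 0.0
    if cut_height is None:
        cut_height = 0.99 * max_height
    if cut_height <= 0:
        raw = np.arange(1, len(gene_ids) + 1)      # every leaf its own branch
    else:
        raw = fcluster(tree, t=cut_height, criterion="distance")
    labels = pd.Series(0, index=gene_ids, dtype=int)
    branches = []
    for branch_id in np.unique(raw):
        members = np.where(raw == branch_id)[0]
        if members.size >= min_module_size:
            branches.append((members.size, members[0], members))
    branches.sort(key=lambda t: (-t[0], t[1]))
    for new_label, (_, _, members) in enumerate(branches, start=1):
        labels.iloc[members] = new_label
    return ModuleAssignment(labels=labels)


# ---------------------------------------------------------------------------
# Eigengenes
# ---------------------------------------------------------------------------

def _first_pc(sub: np.ndarray) -> tuple[np.ndarray, float]:
    """First principal component scores of a standardized genes x samples block."""
    u, s, vt = np.linalg.svd(sub, full_matrices=False)
    scores = vt[0]
    var_explained = float(s[0] ** 2 / (s**2).sum())
    return scores, var_explained


def module_eigengenes(expr: pd.DataFrame, assignment: ModuleAssignment) -> Eigengenes:
    """First principal component per module, unit variance, mean-oriented.

    Member genes are standardized (mean 0, variance 1) before the PC is
    taken, so every gene contributes on equal footing.  The eigengene is
    oriented to correlate nonnegatively with the module's mean expression
    profile; an exact-zero tie is broken toward positive correlation with
    the first member gene.
    """
    if expr.shape[1] < 3:
        raise ValueError(f"eigengenes need >= 3 samples, got {expr.shape[1]}")
    rows, ve = {}, {}
    for label in assignment.module_labels:
        genes = assignment.genes(label)
        if len(genes) < 2:
            raise ValueError(f"module {label} has fewer than 2 genes")
        sub = expr.loc[genes].to_numpy(dtype=float)
        mu = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, ddof=1, keepdims=True)
        if (sd == 0).any():
            sd = np.where(sd == 0, 1.0, sd)
        z = (sub - mu) / sd
        scores, var_explained = _first_pc(z)
        scores = scores - scores.mean()
        scores = scores / scores.std(ddof=1)
        mean_profile = z.mean(axis=0)
        orient = np.dot(scores, mean_profile)
        if orient == 0:
            orient = np.dot(scores, z[0])
        if orient < 0:
            scores = -scores
        rows[label] = scores
        ve[label] = var_explained
    values = pd.DataFrame.from_dict(rows, orient="index")
    values.columns = expr.columns
    return Eigengenes(values=values, variance_explained=pd.Series(ve))


# ---------------------------------------------------------------------------
# Module merging
# ---------------------------------------------------------------------------

def merge_close_modules(
    expr: pd.DataFrame,
    assignment: ModuleAssignment,
    eigengene_dissimilarity_cut: float = 0.25,
) -> ModuleAssignment:
    """Merge module pairs whose eigengene dissimilarity 1 - cor is below cut.

    The closest qualifying pair is merged first and eigengenes recomputed
    after every merge, until no pair qualifies.  Final labels are renumbered
    by decreasing size.
    """
    labels = assignment.labels.copy()
    while True:
        current = ModuleAssignment(labels=labels)
        mods = current.module_labels
        if len(mods) < 2:
            break
        eg = module_eigengenes(expr, current)
        e = eg.values.loc[mods].to_numpy()
        cor = np.corrcoef(e)
        best, best_diss = None, eigengene_dissimilarity_cut
        for i in range(len(mods)):
            for j in range(i + 1, len(mods)):
                diss = 1.0 - cor[i, j]
                if diss < best_diss:
                    best, best_diss = (mods[i], mods[j]), diss
        if best is None:
            break
        keep, absorb = best
        labels[labels == absorb] = keep
    merged = ModuleAssignment(labels=labels)
    # renumber by decreasing size, ties by lowest member position
    order = sorted(
        merged.module_labels,
        key=lambda m: (-len(merged.genes(m)), merged.labels.index.get_loc(merged.genes(m)[0])),
    )
    remap = {old: new for new, old in enumerate(order, start=1)}
    new_labels = merged.labels.map(lambda v: remap.get(v, 0))
    return ModuleAssignment(labels=new_labels)


# ---------------------------------------------------------------------------
# Hub genes and top connections
# ---------------------------------------------------------------------------

def hub_genes(
    adj: Adjacency,
    expr: pd.DataFrame,
    assignment: ModuleAssignment,
    eigengenes: Eigengenes,
) -> dict[int, pd.DataFrame]:
    """Per-module hub rankings by kIM and kME.

    kIM_i = summed adjacency of gene i to the other genes of its module;
    kME_i = Pearson correlation of gene i's profile with its module
    eigengene.  Returns, per module label, a DataFrame indexed by gene with
    columns ``kIM``, ``kME``, ``rank_kIM``, ``rank_kME`` (rank 1 = top hub;
    ties broken by gene order in the expression matrix).
    """
    report: dict[int, pd.DataFrame] = {}
    a = adj.values
    for label in assignment.module_labels:
        genes = assignment.genes(label)
        sub = a.loc[genes, genes].to_numpy().copy()
        np.fill_diagonal(sub, 0.0)
        kim = pd.Series(sub.sum(axis=1), index=genes)
        eg = eigengenes.vector(label).to_numpy()
        x = expr.loc[genes].to_numpy()
        xc = x - x.mean(axis=1, keepdims=True)
        ec = eg - eg.mean()
        denom = np.linalg.norm(xc, axis=1) * np.linalg.norm(ec)
        with np.errstate(divide="ignore", invalid="ignore"):
            kme = np.where(denom > 0, xc @ ec / denom, 0.0)
        kme = pd.Series(kme, index=genes)
        pos = {g: i for i, g in enumerate(genes)}
        rank_kim = sorted(genes, key=lambda g: (-kim[g], pos[g]))
        rank_kme = sorted(genes, key=lambda g: (-kme[g], pos[g]))
        frame = pd.DataFrame({"kIM": kim, "kME": kme})
        frame["rank_kIM"] = pd.Series({g: r + 1 for r, g in enumerate(rank_kim)})
        frame["rank_kME"] = pd.Series({g: r + 1 for r, g in enumerate(rank_kme)})
        report[label] = frame
    return report


def export_top_connections(
    tom: pd.DataFrame,
    assignment: ModuleAssignment,
    label: int,
    n_edges: int = 1000,
) -> pd.DataFrame:
    """Strongest intramodular TOM edges of one module.

    Returns up to ``n_edges`` gene pairs (each once, first index < second)
    sorted by decreasing TOM weight, ties broken by gene-pair position, with
    each node's degree within the exported subgraph.
    """
    if n_edges < 1:
        raise ValueError(f"n_edges must be >= 1, got {n_edges}")
    genes = assignment.genes(label)
    if not genes:
        raise ValueError(f"module {label} does not exist or is empty")
    sub = tom.loc[genes, genes].to_numpy()
    edges = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            edges.append((sub[i, j], i, j))
    edges.sort(key=lambda e: (-e[0], e[1], e[2]))
    edges = edges[:n_edges]
    out = pd.DataFrame(
        {
            "gene_a": [genes[i] for _, i, _ in edges],
            "gene_b": [genes[j] for _, _, j in edges],
            "weight": [w for w, _, _ in edges],
        }
    )
    degree = pd.concat([out["gene_a"], out["gene_b"]]).value_counts()
    out["degree_a"] = out["gene_a"].map(degree)
    out["degree_b"] = out["gene_b"].map(degree)
    return out
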