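"""Reading, writing and quality control of expression matrices.

Conventions
-----------
An *expression matrix* is a :class:`pandas.DataFrame` with genes as the row
index and samples as the columns, holding real values (log-scale expression,
microarray intensities, or counts).  *Sample metadata* is a DataFrame indexed
by ``sample_id`` with at least a binary ``status`` column (0 = control,
1 = affected) and an optional ``family_id`` column; any further columns are
treated as covariates.  *Gene lengths* are a Series of positive integers
(base pairs) indexed by gene id.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "read_expression",
    "write_expression",
    "read_metadata",
    "write_metadata",
    "read_gene_lengths",
    "validate_expression",
    "validate_metadata",
    "counts_to_log_rpkm",
    "detect_outlier_samples",
]


class FormatError(ValueError):
    """An input table violates the expected format."""


# ---------------------------------------------------------------------------
# Readers / writers (TSV)
# ---------------------------------------------------------------------------

def read_expression(path, orientation: str = "genes_in_rows") -> pd.DataFrame:
    """Read a tab-separated expression table into genes x samples orientation.

    Parameters
    ----------
    path
        TSV file with a header row and the gene (or sample) identifiers in
        the first column.
    orientation
        ``"genes_in_rows"`` if rows are genes, ``"samples_in_rows"`` if the
        table is transposed on disk.  The returned frame is always
        genes x samples.
    """
    if orientation not in ("genes_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if orientation == "samples_in_rows":
        df = df.T
    df.index = pd.Index(df.index.astype(str))
    df.columns = pd.Index(df.columns.astype(str))
    df.index.name = None
    df.columns.name = None
    validate_expression(df, source=str(path))
    return df.astype(float)


def write_expression(expr: pd.DataFrame, path) -> None:
    """Write a genes x samples matrix as TSV (gene ids in the first column)."""
    expr.to_csv(path, sep="\t", index_label="gene_id")


def read_metadata(path) -> pd.DataFrame:
    """Read a sample metadata TSV (columns: sample_id, status, family_id, ...)."""
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in meta.columns:
        raise FormatError(f"{path}: metadata must have a 'sample_id' column")
    meta = meta.set_index("sample_id")
    validate_metadata(meta)
    return meta


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


def read_gene_lengths(path) -> pd.Series:
    """Read a two-column TSV (gene_id, length_bp) into a Series of ints."""
    tab = pd.read_csv(path, sep="\t", dtype={0: str})
    if tab.shape[1] != 2:
        raise FormatError(f"{path}: expected exactly two columns (gene_id, length_bp)")
    lengths = pd.Series(tab.iloc[:, 1].to_numpy(), index=tab.iloc[:, 0].astype(str))
    if lengths.index.duplicated().any():
        dups = lengths.index[lengths.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate gene ids in length table: {dups}")
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0].tolist()
        raise FormatError(f"non-positive gene lengths for: {bad}")
    return lengths.astype(int)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_expression(expr: pd.DataFrame, source: str = "expression matrix") -> None:
    """Check uniqueness of ids and that every cell is numeric and finite."""
    if expr.index.duplicated().any():
        dups = expr.index[expr.index.duplicated()].unique().tolist()
        raise FormatError(f"{source}: duplicate gene ids: {dups}")
    if expr.columns.duplicated().any():
        dups = expr.columns[expr.columns.duplicated()].unique().tolist()
        raise FormatError(f"{source}: duplicate sample ids: {dups}")
    values = expr.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        numeric = expr.apply(pd.to_numeric, errors="coerce")
        bad = numeric.isna() & expr.notna()
        if bad.to_numpy().any():
            g, s = np.argwhere(bad.to_numpy())[0]
            raise FormatError(
                f"{source}: non-numeric cell at gene {expr.index[g]!r}, "
                f"sample {expr.columns[s]!r}: {expr.iat[g, s]!r}"
            )
    if pd.isna(values.astype(float)).any():
        raise FormatError(f"{source}: missing values present")


def validate_metadata(meta: pd.DataFrame, expr: pd.DataFrame | None = None) -> None:
    if "status" not in meta.columns:
        raise FormatError("metadata must have a 'status' column")
    status = set(pd.unique(meta["status"]))
    if not status <= {0, 1}:
        raise FormatError(f"status must be binary 0/1; found {sorted(status)}")
    if meta.index.duplicated().any():
        raise FormatError("duplicate sample ids in metadata")
    if expr is not None and set(meta.index) != set(expr.columns):
        missing = sorted(set(expr.columns) - set(meta.index))
        extra = sorted(set(meta.index) - set(expr.columns))
        raise FormatError(
            f"metadata/expression sample mismatch (missing: {missing}, extra: {extra})"
        )


# ---------------------------------------------------------------------------
# Counts -> log2 RPKM
# ---------------------------------------------------------------------------

def counts_to_log_rpkm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Convert a raw count matrix to log2(RPKM + 1).

    RPKM (reads per kilobase per million mapped reads) for gene *g* in
    sample *s* is ``counts[g, s] / ((length_bp[g] / 1e3) * (libsize[s] / 1e6))``
    where ``libsize`` is the per-sample column total.  The +1 pseudocount
    anchors zero counts at exactly 0 on the log scale.
    """
    missing = counts.index.difference(lengths.index)
    if len(missing) > 0:
        raise ValueError(f"no gene length for: {missing.tolist()}")
    libsize = counts.sum(axis=0)
    if (libsize <= 0).any():
        bad = libsize.index[libsize <= 0].tolist()
        raise ValueError(f"zero library size for sample(s): {bad}")
    kb = lengths.reindex(counts.index).to_numpy(dtype=float)[:, None] / 1e3
    per_million = libsize.to_numpy(dtype=float)[None, :] / 1e6
    rpkm = counts.to_numpy(dtype=float) / (kb * per_million)
    return pd.DataFrame(np.log2(rpkm + 1.0), index=counts.index, columns=counts.columns)


# ---------------------------------------------------------------------------
# Sample outlier detection
# ---------------------------------------------------------------------------

def detect_outlier_samples(expr: pd.DataFrame, z_cut: float = -2.5) -> list[str]:
    """Flag samples with anomalously low mean inter-sample correlation.

    For each sample the mean Pearson correlation with every other sample is
    computed; samples whose standardized (z-scored) mean correlation falls
    below ``z_cut`` are removed and the procedure repeats on the remainder
    until no sample is flagged.  Returns the flagged sample ids in the order
    of removal.
    """
    if expr.shape[1] < 4:
        raise ValueError(
            f"outlier detection needs at least 4 samples, got {expr.shape[1]} "
            "(mean inter-sample correlation is not meaningful below that)"
        )
    flagged: list[str] = []
    current = expr
    while current.shape[1] >= 4:
        cor = np.corrcoef(current.to_numpy(), rowvar=False)
        np.fill_diagonal(cor, np.nan)
        mean_cor = np.nanmean(cor, axis=0)
        sd = mean_cor.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            break
        z = (mean_cor - mean_cor.mean()) / sd
        below = np.where(z < z_cut)[0]
        if below.size == 0:
            break
        worst = below[np.argmin(z[below])]
        flagged.append(str(current.columns[worst]))
        current = current.drop(columns=current.columns[worst])
    return flagged
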