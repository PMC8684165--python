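"""Weighted co-expression network construction.

The network over genes is built in three steps: Pearson correlation of
expression profiles, soft thresholding of the correlations into an adjacency
(``|r|^beta`` unsigned, ``((1 + r)/2)^beta`` signed), and the topological
overlap measure (TOM), which augments direct adjacency with shared-neighbor
weight.  The soft-threshold power beta is chosen as the smallest candidate
whose connectivity distribution fits a scale-free (power-law) form with
signed R^2 at or above a target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Adjacency",
    "SoftThresholdReport",
    "drop_zero_variance_genes",
    "pairwise_correlation",
    "adjacency_from_correlation",
    "pick_soft_threshold",
    "default_power",
    "choose_power",
    "topological_overlap",
]

DEFAULT_POWERS = tuple(range(1, 21))


@dataclass
class Adjacency:
    """Soft-thresholded network adjacency: symmetric, in [0, 1], unit diagonal."""

    values: pd.DataFrame
    power: float
    sign_mode: str = "unsigned"

    def __post_init__(self):
        a = self.values.to_numpy()
        if a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.allclose(a, a.T, atol=1e-12):
            raise ValueError("adjacency must be symmetric")
        if not np.allclose(np.diag(a), 1.0):
            raise ValueError("adjacency diagonal must be 1")
        if a.min() < -1e-12 or a.max() > 1 + 1e-12:
            raise ValueError("adjacency entries must lie in [0, 1]")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index


@dataclass
class SoftThresholdReport:
    powers: list[float]
    fit_r2: list[float]              # signed scale-free fit index per power
    mean_connectivity: list[float]
    chosen_power: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "power": self.powers,
                "fit_r2": self.fit_r2,
                "mean_connectivity": self.mean_connectivity,
                "chosen": [p == self.chosen_power for p in self.powers],
            }
        )


def drop_zero_variance_genes(expr: pd.DataFrame) -> pd.DataFrame:
    """Remove genes with zero sample variance, warning with their ids."""
    var = expr.to_numpy().var(axis=1)
    zero = var == 0
    if zero.any():
        dropped = expr.index[zero].tolist()
        warnings.warn(
            f"dropping {len(dropped)} zero-variance gene(s) before correlation: "
            f"{dropped[:10]}{'...' if len(dropped) > 10 else ''}"
        )
        expr = expr.loc[~zero]
    return expr


def pairwise_correlation(expr: pd.DataFrame) -> pd.DataFrame:
    """Gene x gene Pearson correlation matrix."""
    if expr.shape[1] < 3:
        raise ValueError(f"need >= 3 samples for correlation, got {expr.shape[1]}")
    var = expr.to_numpy().var(axis=1)
    if (var == 0).any():
        bad = expr.index[var == 0].tolist()
        raise ValueError(
            f"zero-variance gene(s) present (drop them first with "
            f"drop_zero_variance_genes): {bad[:10]}"
        )
    cor = np.corrcoef(expr.to_numpy())
    cor = np.clip(cor, -1.0, 1.0)
    np.fill_diagonal(cor, 1.0)
    return pd.DataFrame(cor, index=expr.index, columns=expr.index)


def adjacency_from_correlation(
    cor: pd.DataFrame, power: float, sign_mode: str = "unsigned"
) -> Adjacency:
    """Raise correlations to the soft-threshold power.

    unsigned: ``a = |r|^power``; signed: ``a = ((1 + r) / 2)^power``.
    """
    if power <= 0:
        raise ValueError(f"power must be positive, got {power}")
    if sign_mode not in ("unsigned", "signed"):
        raise ValueError(f"sign_mode must be 'unsigned' or 'signed', got {sign_mode!r}")
    r = cor.to_numpy()
    if sign_mode == "unsigned":
        a = np.abs(r) ** power
    else:
        a = ((1.0 + r) / 2.0) ** power
    np.fill_diagonal(a, 1.0)
    return Adjacency(
        values=pd.DataFrame(a, index=cor.index, columns=cor.columns),
        power=power,
        sign_mode=sign_mode,
    )


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of log10(freq) ~ log10(mean k) over equal-width bins of k.

    Positive-slope fits (anti-scale-free) are reported with a negative sign,
    following the standard signed scale-free topology fit index.
    """
    k = k[k > 0]
    if k.size == 0 or np.ptp(k) == 0:
        raise ValueError("degenerate connectivity distribution: all equal or zero")
    # equal-width discretization of k (the standard scale-free fit index)
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    edges[-1] *= 1 + 1e-12
    idx = np.digitize(k, edges) - 1
    xs, ys = [], []
    for b in range(n_bins):
        members = k[idx == b]
        if members.size == 0:
            continue
        xs.append(np.log10(members.mean()))
        ys.append(np.log10(members.size / k.size))
    if len(xs) < 3:
        raise ValueError("too few populated connectivity bins for a scale-free fit")
    xs, ys = np.asarray(xs), np.asarray(ys)
    slope, intercept = np.polyfit(xs, ys, 1)
    pred = slope * xs + intercept
    ss_res = ((ys - pred) ** 2).sum()
    ss_tot = ((ys - ys.mean()) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return -r2 if slope > 0 else r2


def pick_soft_threshold(
    cor: pd.DataFrame,
    powers: tuple[float, ...] = DEFAULT_POWERS,
    target_r2: float = 0.8,
    sign_mode: str = "unsigned",
    n_bins: int = 10,
) -> SoftThresholdReport:
    """Choose the soft-threshold power by the scale-free topology criterion.

    The chosen power is the smallest candidate whose signed fit R^2 reaches
    ``target_r2``; if none does, the candidate maximizing the fit.
    """
    if cor.shape[0] < 30:
        raise ValueError(
            f"soft-threshold selection needs >= 30 genes for a meaningful "
            f"connectivity histogram, got {cor.shape[0]}"
        )
    r = cor.to_numpy()
    fits, mean_k = [], []
    for p in powers:
        if sign_mode == "unsigned":
            a = np.abs(r) ** p
        else:
            a = ((1.0 + r) / 2.0) ** p
        np.fill_diagonal(a, 0.0)
        k = a.sum(axis=1)
        fits.append(_scale_free_fit(k, n_bins=n_bins))
        mean_k.append(float(k.mean()))
    fits_arr = np.asarray(fits)
    reaching = np.where(fits_arr >= target_r2)[0]
    chosen = powers[reaching[0]] if reaching.size else powers[int(np.argmax(fits_arr))]
    return SoftThresholdReport(
        powers=list(powers), fit_r2=fits, mean_connectivity=mean_k, chosen_power=chosen
    )


def default_power(n_samples: int, sign_mode: str = "unsigned") -> float:
    """Sample-size-based fallback soft-threshold power.

    The conventional defaults used when the scale-free fit does not yield a
    usable power: unsigned networks 9 / 8 / 7 / 6 for < 20, < 30, < 40 and
    >= 40 samples respectively; signed networks double these.
    """
    if n_samples < 20:
        p = 9
    elif n_samples < 30:
        p = 8
    elif n_samples < 40:
        p = 7
    else:
        p = 6
    return 2 * p if sign_mode == "signed" else p


def choose_power(
    cor: pd.DataFrame,
    n_samples: int,
    powers: tuple[float, ...] = DEFAULT_POWERS,
    target_r2: float = 0.8,
    sign_mode: str = "unsigned",
    min_mean_connectivity: float = 1.0,
) -> tuple[float, SoftThresholdReport | None]:
    """Scale-free power choice with a degenerate-network guard.

    Applies :func:`pick_soft_threshold`; if the chosen power leaves the
    network with mean connectivity below ``min_mean_connectivity`` (high
    powers annihilate the adjacency, after which no module can survive a
    static-height tree cut), falls back to the sample-size default power.
    """
    try:
        report = pick_soft_threshold(
            cor, powers=powers, target_r2=target_r2, sign_mode=sign_mode
        )
    except ValueError:
        return default_power(n_samples, sign_mode), None
    idx = report.powers.index(report.chosen_power)
    if report.mean_connectivity[idx] < min_mean_connectivity:
        return default_power(n_samples, sign_mode), report
    return report.chosen_power, report


def topological_overlap(adj: Adjacency) -> pd.DataFrame:
    """Topological overlap matrix.

    ``TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` for i != j, with
    ``l_ij = sum_u a_iu a_uj`` over u distinct from i and j and
    ``k_i = sum_u a_iu`` over u != i; diagonal 1.  Dissimilarity for
    clustering is ``1 - TOM``.
    """
    a = adj.values.to_numpy().copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    # full product counts u == i and u == j terms; remove them
    l = a @ a                      # l[i, j] includes no u==i or u==j term since diag 0
    min_k = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (l + a) / (min_k + 1.0 - a)
    tom = np.where(min_k + 1.0 - a > 0, tom, 0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(tom, index=adj.gene_ids, columns=adj.gene_ids)
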