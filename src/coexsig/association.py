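"""Module eigengene / disease-status association.

Each module eigengene is correlated with the binary disease trait
(point-biserial Pearson correlation, trait coded 0/1) and tested with the
standard correlation t-test, ``t = r * sqrt((n - 2) / (1 - r^2))`` on
``n - 2`` degrees of freedom.  Modules below the significance threshold,
ordered by increasing p, are the disease-associated candidates.  No
multiple-testing correction is applied at selection time; BH-adjusted
values are reported alongside for transparency.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .modules import Eigengenes

__all__ = ["eigengene_trait_association", "select_disease_modules"]


def eigengene_trait_association(
    eigengenes: Eigengenes, meta: pd.DataFrame
) -> pd.DataFrame:
    """Correlate every module eigengene with disease status.

    Returns a DataFrame indexed by module label with columns ``r``, ``p``,
    ``fdr`` (BH across modules) and ``n``.
    """
    samples = eigengenes.values.columns
    missing = [s for s in samples if s not in meta.index]
    if missing:
        raise ValueError(f"status missing for sample(s): {missing}")
    status = meta.loc[samples, "status"].to_numpy(dtype=float)
    n = len(samples)
    if n < 4:
        raise ValueError(f"association needs >= 4 samples, got {n}")
    if status.min() == status.max():
        raise ValueError("both status groups must be non-empty")
    rows = []
    for label in eigengenes.values.index:
        e = eigengenes.values.loc[label].to_numpy(dtype=float)
        r = float(np.corrcoef(e, status)[0, 1])
        r = float(np.clip(r, -1.0, 1.0))
        if abs(r) == 1.0:
            p = 0.0
        else:
            t = r * np.sqrt((n - 2) / (1.0 - r**2))
            p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
        rows.append((label, r, p, n))
    out = pd.DataFrame(rows, columns=["module", "r", "p", "n"]).set_index("module")
    _, fdr, _, _ = multipletests(out["p"].to_numpy(), method="fdr_bh")
    out["fdr"] = fdr
    return out


def select_disease_modules(results: pd.DataFrame, alpha: float = 0.05) -> list[int]:
    """Module labels with p < alpha, ordered by increasing p.

    The unassigned pool (label 0) is never selectable.
    """
    if results.empty:
        raise ValueError("no module-trait results to select from")
    hits = results[(results["p"] < alpha) & (results.index != 0)]
    return hits.sort_values("p").index.tolist()
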