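"""Synthetic expression cohorts with planted co-expression module structure.

The generator emulates the statistical structure of a small-cohort
transcriptomic study of a monogenic neurodegenerative disease: groups of
co-regulated genes driven by shared latent factors, a disease effect loaded
onto one or more of those factors, per-family background offsets, and a
paired cross-species dataset linked through an ortholog map.  Every dataset
carries its ground truth so downstream network, association and
classification stages can be tested against known structure.

Model
-----
For gene *g* in sample *s*::

    x[g, s] = u_g * f_{m(g)}(s) + b_{g, fam(s)} + eps[g, s]

where ``m(g)`` is the planted module of *g* (non-members have no factor
term), ``f_m`` are per-sample standard-normal latent factors, loadings
``u_g ~ Normal(loading_mean, loading_sd)`` truncated to (0, 1],
``b`` are per-(gene, family) offsets ``~ Normal(0, family_offsets_sd^2)``
and ``eps ~ Normal(0, noise_sd^2)``.  In affected samples the factors of
``disease_modules`` are shifted by ``disease_effect`` (in factor SD units),
so the disease signal lives at the module-eigengene level rather than in
individual genes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SyntheticConfig", "SyntheticTruth", "generate_dataset", "generate_ortholog_pair"]


class ConfigurationError(ValueError):
    """A synthetic-data configuration violates an invariant."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic cohort.

    Defaults describe a desk-scale cohort: 1000 genes of which three
    100-gene modules are co-regulated, one module carrying a 1.5-SD disease
    shift, balanced cases/controls, and moderate gene-level noise.
    """

    n_genes: int = 1000
    n_samples: int = 30
    module_sizes: tuple[int, ...] = (100, 100, 100)
    loading_mean: float = 0.8
    loading_sd: float = 0.1
    disease_modules: tuple[int, ...] = ()
    disease_effect: float = 0.0
    n_cases: int = 0
    n_families: int = 0          # 0 = every sample its own family, no offsets drawn
    family_offsets_sd: float = 0.0
    family_factor_corr: float = 0.0   # within-family correlation of module factors
    noise_sd: float = 0.6
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "module_sizes", tuple(int(s) for s in self.module_sizes))
        object.__setattr__(self, "disease_modules", tuple(int(m) for m in self.disease_modules))
        self.validate()

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be positive")
        if self.n_samples <= 0:
            raise ConfigurationError("n_samples must be positive")
        if any(s <= 0 for s in self.module_sizes):
            raise ConfigurationError("module_sizes must all be positive")
        if sum(self.module_sizes) > self.n_genes:
            raise ConfigurationError(
                f"sum(module_sizes)={sum(self.module_sizes)} exceeds n_genes={self.n_genes}"
            )
        if not (0 < self.loading_mean <= 1):
            raise ConfigurationError("loading_mean must lie in (0, 1]")
        if self.loading_sd < 0:
            raise ConfigurationError("loading_sd must be nonnegative")
        if self.n_cases > self.n_samples:
            raise ConfigurationError(f"n_cases={self.n_cases} exceeds n_samples={self.n_samples}")
        if any(m >= len(self.module_sizes) or m < 0 for m in self.disease_modules):
            raise ConfigurationError(
                f"disease_modules {self.disease_modules} index outside "
                f"0..{len(self.module_sizes) - 1}"
            )
        if self.family_offsets_sd < 0:
            raise ConfigurationError("family_offsets_sd must be nonnegative")
        if not (0 <= self.family_factor_corr < 1):
            raise ConfigurationError("family_factor_corr must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")


@dataclass
class SyntheticTruth:
    """Planted structure behind a generated dataset."""

    assignment: pd.Series            # gene_id -> module label (1-based; 0 = background)
    factors: pd.DataFrame            # module label (rows) x sample (cols) latent values
    case_labels: pd.Series           # sample_id -> 0/1
    family_ids: pd.Series            # sample_id -> family label
    seed: int

    def module_genes(self, label: int) -> list[str]:
        return self.assignment.index[self.assignment == label].tolist()

    def to_json(self, path) -> None:
        payload = {
            "assignment": self.assignment.to_dict(),
            "factors": {str(k): v for k, v in self.factors.T.to_dict("list").items()},
            "case_labels": self.case_labels.to_dict(),
            "family_ids": self.family_ids.to_dict(),
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def _truncated_loadings(rng: np.random.Generator, n: int, mean: float, sd: float) -> np.ndarray:
    """Draw Normal(mean, sd) loadings, redrawing until all fall in (0, 1]."""
    if sd == 0:
        return np.full(n, mean)
    out = rng.normal(mean, sd, size=n)
    bad = (out <= 0) | (out > 1)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out <= 0) | (out > 1)
    return out


def generate_dataset(
    config: SyntheticConfig,
    gene_prefix: str = "G",
    sample_prefix: str = "S",
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate one expression cohort from the latent-factor model.

    Returns
    -------
    (expression, metadata, truth)
        ``expression`` is genes x samples; ``metadata`` is indexed by sample
        id with columns ``status`` and ``family_id``; ``truth`` records the
        planted assignment, factors, labels and seed.  Bit-reproducible from
        ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_mod = len(config.module_sizes)

    gene_ids = [f"{gene_prefix}{i:05d}" for i in range(config.n_genes)]
    sample_ids = [f"{sample_prefix}{j:03d}" for j in range(config.n_samples)]

    # gene -> module (first modules' genes in order, remainder background)
    assignment = np.zeros(config.n_genes, dtype=int)
    pos = 0
    for m, size in enumerate(config.module_sizes, start=1):
        assignment[pos:pos + size] = m
        pos += size

    # case/control labels: first n_cases samples are affected
    status = np.zeros(config.n_samples, dtype=int)
    status[: config.n_cases] = 1

    # family structure: round-robin over families, or singleton families
    if config.n_families > 0:
        fam = np.array([f"F{j % config.n_families:02d}" for j in range(config.n_samples)])
    else:
        fam = np.array([f"F{j:03d}" for j in range(config.n_samples)])
    families = pd.unique(fam)

    factors = rng.standard_normal((n_mod, config.n_samples))
    if config.family_factor_corr > 0:
        # equicorrelated within family: f = sqrt(rho)*g_family + sqrt(1-rho)*e_sample,
        # keeping unit marginal variance.  Models family-shared baseline module
        # activity (shared genetics/environment/processing batch) — the
        # component that family-control normalization is meant to cancel.
        rho = config.family_factor_corr
        fam_factors = rng.standard_normal((n_mod, len(families)))
        fam_index = {f: i for i, f in enumerate(families)}
        shared = fam_factors[:, [fam_index[f] for f in fam]]
        factors = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * factors
    for m in config.disease_modules:
        factors[m, status == 1] += config.disease_effect

    loadings = _truncated_loadings(
        rng, config.n_genes, config.loading_mean, config.loading_sd
    )

    x = rng.normal(0.0, config.noise_sd, size=(config.n_genes, config.n_samples))
    member = assignment > 0
    x[member] += loadings[member, None] * factors[assignment[member] - 1]

    if config.family_offsets_sd > 0:
        offsets = rng.normal(
            0.0, config.family_offsets_sd, size=(config.n_genes, len(families))
        )
        fam_index = {f: i for i, f in enumerate(families)}
        x += offsets[:, [fam_index[f] for f in fam]]

    expr = pd.DataFrame(x, index=gene_ids, columns=sample_ids)
    meta = pd.DataFrame(
        {"status": status, "family_id": fam}, index=pd.Index(sample_ids, name="sample_id")
    )
    if config.n_families > 0:
        # flag one unaffected member per family as its baseline control
        control_flag = np.zeros(config.n_samples, dtype=int)
        for f in families:
            members = np.where(fam == f)[0]
            unaffected = members[status[members] == 0]
            if unaffected.size > 0:
                control_flag[unaffected[0]] = 1
        meta["family_control"] = control_flag
    truth = SyntheticTruth(
        assignment=pd.Series(assignment, index=gene_ids),
        factors=pd.DataFrame(factors, index=range(1, n_mod + 1), columns=sample_ids),
        case_labels=pd.Series(status, index=sample_ids),
        family_ids=pd.Series(fam, index=sample_ids),
        seed=config.seed,
    )
    return expr, meta, truth


def generate_ortholog_pair(
    config_a: SyntheticConfig,
    config_b: SyntheticConfig,
    shared_modules: list[tuple[int, int]] = (),
    map_fraction: float = 1.0,
    seed: int = 0,
):
    """Generate two cohorts linked by a one-to-one ortholog map.

    For each ``(module_in_a, module_in_b)`` pair in ``shared_modules`` the
    member genes of A's module are mapped onto the member genes of B's
    paired module, covering at least ``map_fraction`` of the smaller module.
    Background (and unshared-module) genes are mapped uniformly at random at
    the same fraction, so a null pair still has a realistic ortholog table.

    Returns ``(dataset_a, dataset_b, ortholog_map, (truth_a, truth_b))``
    where each dataset is an ``(expression, metadata, truth-free)`` pair of
    frames and the map is a two-column DataFrame (gene_a, gene_b).
    """
    if not (0 < map_fraction <= 1):
        raise ConfigurationError(f"map_fraction must lie in (0, 1], got {map_fraction}")
    for ma, mb in shared_modules:
        if ma >= len(config_a.module_sizes) or mb >= len(config_b.module_sizes):
            raise ConfigurationError(
                f"shared module pair ({ma}, {mb}) indexes outside the module lists"
            )

    expr_a, meta_a, truth_a = generate_dataset(config_a, gene_prefix="A")
    expr_b, meta_b, truth_b = generate_dataset(config_b, gene_prefix="B")

    rng = np.random.default_rng(seed)
    pairs: list[tuple[str, str]] = []
    used_a: set[str] = set()
    used_b: set[str] = set()

    for ma, mb in shared_modules:
        genes_a = truth_a.module_genes(ma + 1)
        genes_b = truth_b.module_genes(mb + 1)
        n_map = max(1, int(np.ceil(map_fraction * min(len(genes_a), len(genes_b)))))
        pick_a = list(rng.choice(genes_a, size=n_map, replace=False))
        pick_b = list(rng.choice(genes_b, size=n_map, replace=False))
        pairs.extend(zip(pick_a, pick_b))
        used_a.update(pick_a)
        used_b.update(pick_b)

    rest_a = [g for g in expr_a.index if g not in used_a]
    rest_b = [g for g in expr_b.index if g not in used_b]
    n_rest = int(np.floor(map_fraction * min(len(rest_a), len(rest_b))))
    if n_rest > 0:
        pick_a = list(rng.choice(rest_a, size=n_rest, replace=False))
        pick_b = list(rng.choice(rest_b, size=n_rest, replace=False))
        pairs.extend(zip(pick_a, pick_b))

    ortholog_map = pd.DataFrame(pairs, columns=["gene_a", "gene_b"])
    return (expr_a, meta_a), (expr_b, meta_b), ortholog_map, (truth_a, truth_b)
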