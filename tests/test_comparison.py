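"""Hypergeometric overlap, cross-dataset comparison, preservation, enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import coexsig as cx
from coexsig.modules import ModuleAssignment


def hypergeom_sum_oracle(n, a, b, k):
    """P(X >= k) by direct summation of the hypergeometric pmf."""
    total = 0.0
    for x in range(k, min(a, b) + 1):
        total += math.comb(a, x) * math.comb(n - a, b - x) / math.comb(n, b)
    return total


class TestHypergeometricOverlap:
    def test_saturated_set(self):
        universe = {f"g{i}" for i in range(10)}
        res = cx.hypergeometric_overlap(universe, set(list(universe)[:3]), universe)
        assert res.overlap == 3
        assert res.p == pytest.approx(1.0)

    def test_zero_overlap_has_p_one(self):
        universe = {f"g{i}" for i in range(20)}
        res = cx.hypergeometric_overlap(
            {f"g{i}" for i in range(5)}, {f"g{i}" for i in range(10, 15)}, universe
        )
        assert res.overlap == 0 and res.p == 1.0

    def test_matches_summation_oracle(self):
        universe = {f"g{i}" for i in range(100)}
        a = {f"g{i}" for i in range(10)}
        b = {f"g{i}" for i in range(5, 15)}
        res = cx.hypergeometric_overlap(a, b, universe)
        assert res.overlap == 5
        assert res.p == pytest.approx(hypergeom_sum_oracle(100, 10, 10, 5), abs=1e-12)

    def test_exhaustive_enumeration_small_universe(self):
        # enumerate every possible draw of |B| items from a 12-item universe
        n, a_size, b_size = 12, 5, 4
        universe = [f"g{i}" for i in range(n)]
        a = set(universe[:a_size])
        tail_counts = {}
        n_draws = 0
        for draw in itertools.combinations(universe, b_size):
            k = len(a & set(draw))
            tail_counts[k] = tail_counts.get(k, 0) + 1
            n_draws += 1
        for k in range(0, min(a_size, b_size) + 1):
            enumerated = sum(v for kk, v in tail_counts.items() if kk >= k) / n_draws
            b = set(universe[a_size - k:a_size - k + b_size]) if k else set(
                universe[a_size:a_size + b_size]
            )
            res = cx.hypergeometric_overlap(a, b, set(universe))
            assert res.overlap == k
            assert res.p == pytest.approx(enumerated, abs=1e-12)

    def test_monotone_in_overlap(self):
        universe = {f"g{i}" for i in range(50)}
        a = {f"g{i}" for i in range(10)}
        ps = []
        for k in range(0, 9):
            b = {f"g{i}" for i in range(10 - k, 20 - k)}
            res = cx.hypergeometric_overlap(a, b, universe)
            assert res.overlap == k
            ps.append(res.p)
        assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))

    def test_stray_genes_and_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            cx.hypergeometric_overlap({"x"}, {"y"}, set())
        with pytest.raises(ValueError, match="offenders"):
            cx.hypergeometric_overlap({"x"}, {"g0"}, {"g0", "g1"})


class TestCrossDatasetOverlap:
    @staticmethod
    def _pair(shared, seed_a, seed_b, map_seed):
        cfg_a = cx.SyntheticConfig(n_genes=400, module_sizes=(60, 60), n_samples=30,
                                   seed=seed_a)
        cfg_b = cx.SyntheticConfig(n_genes=400, module_sizes=(60, 60), n_samples=30,
                                   seed=seed_b)
        return cx.generate_ortholog_pair(cfg_a, cfg_b, shared_modules=shared,
                                         map_fraction=1.0, seed=map_seed)

    def test_planted_shared_module_attains_minimum_p(self):
        (ea, _), (eb, _), omap, (ta, tb) = self._pair([(0, 0)], 9, 10009, 9)
        aa = ModuleAssignment(labels=ta.assignment)
        ab = ModuleAssignment(labels=tb.assignment)
        p, fdr, counts = cx.cross_dataset_overlap(aa, ab, omap)
        assert p.stack().idxmin() == (1, 1)
        assert p.loc[1, 1] < 1e-6

    def test_symmetry_under_dataset_swap(self):
        (ea, _), (eb, _), omap, (ta, tb) = self._pair([(0, 1)], 3, 4, 5)
        aa = ModuleAssignment(labels=ta.assignment)
        ab = ModuleAssignment(labels=tb.assignment)
        p_ab, _, _ = cx.cross_dataset_overlap(aa, ab, omap)
        swapped = omap.rename(columns={"gene_a": "gene_b", "gene_b": "gene_a"})
        p_ba, _, _ = cx.cross_dataset_overlap(ab, aa, swapped[["gene_a", "gene_b"]])
        assert np.allclose(p_ab.to_numpy(), p_ba.to_numpy().T, atol=1e-12)

    def test_duplicate_map_entries_rejected(self):
        (_, _), (_, _), omap, (ta, tb) = self._pair([], 1, 2, 3)
        dup = pd.concat([omap, omap.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match="one-to-one"):
            cx.cross_dataset_overlap(
                ModuleAssignment(labels=ta.assignment),
                ModuleAssignment(labels=tb.assignment), dup,
            )

    def test_disjoint_map_rejected(self):
        (_, _), (_, _), _, (ta, tb) = self._pair([], 1, 2, 3)
        bogus = pd.DataFrame({"gene_a": ["nope1"], "gene_b": ["nope2"]})
        with pytest.raises(ValueError, match="no genes"):
            cx.cross_dataset_overlap(
                ModuleAssignment(labels=ta.assignment),
                ModuleAssignment(labels=tb.assignment), bogus,
            )


class TestModulePreservation:
    def test_self_preservation_beats_shuffled(self):
        cfg = cx.SyntheticConfig(n_genes=200, module_sizes=(60,), n_samples=30, seed=2)
        expr, _, truth = cx.generate_dataset(cfg)
        assign = ModuleAssignment(labels=truth.assignment)
        rng = np.random.default_rng(0)
        wins = 0
        for trial in range(5):
            z_self = cx.module_preservation(
                expr, expr, assign, n_permutations=50, seed=trial
            )[0].z_summary
            shuffled = expr.copy()
            shuffled.iloc[:] = rng.permutation(expr.to_numpy().ravel()).reshape(expr.shape)
            z_perm = cx.module_preservation(
                expr, shuffled, assign, n_permutations=50, seed=trial
            )[0].z_summary
            wins += z_self > z_perm
        assert wins == 5

    def test_permutation_floor_enforced(self):
        cfg = cx.SyntheticConfig(n_genes=100, module_sizes=(40,), n_samples=20, seed=2)
        expr, _, truth = cx.generate_dataset(cfg)
        with pytest.raises(ValueError, match="n_permutations"):
            cx.module_preservation(expr, expr,
                                   ModuleAssignment(labels=truth.assignment),
                                   n_permutations=10)

    def test_summary_is_mean_of_components(self):
        cfg = cx.SyntheticConfig(n_genes=150, module_sizes=(50,), n_samples=25, seed=4)
        expr, _, truth = cx.generate_dataset(cfg)
        other, _, _ = cx.generate_dataset(
            cx.SyntheticConfig(n_genes=150, module_sizes=(2,), n_samples=25, seed=99)
        )
        res = cx.module_preservation(expr, other,
                                     ModuleAssignment(labels=truth.assignment),
                                     n_permutations=30, seed=1)[0]
        assert res.z_summary == pytest.approx((res.z_density + res.z_connectivity) / 2)


class TestGeneSetEnrichment:
    def _assignment(self):
        labels = pd.Series(0, index=[f"g{i}" for i in range(200)])
        labels.iloc[:50] = 1
        labels.iloc[50:80] = 2
        return ModuleAssignment(labels=labels)

    def test_self_set_is_most_enriched(self):
        assign = self._assignment()
        sets = {
            "self": set(assign.genes(1)),
            "random": {f"g{i}" for i in range(100, 140)},
        }
        res = cx.gene_set_enrichment(assign, sets)
        mod1 = res[res["module"] == 1]
        assert mod1.iloc[0]["gene_set"] == "self"
        assert mod1.iloc[0]["p"] < 1e-20

    def test_disjoint_set_p_one(self):
        assign = self._assignment()
        sets = {"disjoint": {f"g{i}" for i in range(150, 190)}}
        res = cx.gene_set_enrichment(assign, sets)
        assert (res[res["module"] == 1]["p"] == 1.0).all()

    def test_matches_summation_oracle(self, rng):
        universe = [f"g{i}" for i in range(500)]
        labels = pd.Series(0, index=universe)
        labels.iloc[:50] = 1
        assign = ModuleAssignment(labels=labels)
        gene_set = set(universe[30:50]) | set(universe[100:120])  # 20 in, 20 out
        res = cx.gene_set_enrichment(assign, {"s": gene_set})
        row = res[(res["module"] == 1) & (res["gene_set"] == "s")].iloc[0]
        assert row["overlap"] == 20
        assert row["p"] == pytest.approx(hypergeom_sum_oracle(500, 50, 40, 20),
                                         rel=1e-9)

    def test_set_outside_universe_dropped(self):
        assign = self._assignment()
        with pytest.warns(UserWarning, match="dropped"):
            res = cx.gene_set_enrichment(
                assign, {"alien": {"xx1", "xx2"}, "ok": set(assign.genes(2))}
            )
        assert set(res["gene_set"]) == {"ok"}

    def test_gmt_round_trip(self, tmp_path):
        sets = {"setA": {"g1", "g2"}, "setB": {"g3"}}
        path = tmp_path / "sets.gmt"
        cx.write_gmt(sets, path)
        assert cx.read_gmt(path) == sets
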