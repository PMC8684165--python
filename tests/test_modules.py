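"""Dendrogram, tree cut, eigengenes, module merging, hubs, edge export."""

import numpy as np
import pandas as pd
import pytest

import coexsig as cx
from coexsig.modules import ModuleAssignment


def _diss_frame(d):
    ids = [f"g{i}" for i in range(d.shape[0])]
    return pd.DataFrame(d, index=ids, columns=ids)


def average_linkage_oracle(d):
    """Naive average-linkage agglomeration; returns sorted merge heights."""
    clusters = {i: [i] for i in range(d.shape[0])}
    heights = []
    while len(clusters) > 1:
        best = None
        for a in clusters:
            for b in clusters:
                if a >= b:
                    continue
                h = np.mean([d[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or h < best[0]:
                    best = (h, a, b)
        h, a, b = best
        heights.append(h)
        clusters[a] = clusters[a] + clusters.pop(b)
    return sorted(heights)


class TestClustering:
    def test_two_block_structure(self):
        d = np.ones((6, 6))
        d[:3, :3] = 0.0
        d[3:, 3:] = 0.0
        np.fill_diagonal(d, 0.0)
        tree = cx.cluster_genes(_diss_frame(d))
        heights = tree[:, 2]
        assert heights[-1] == pytest.approx(1.0)
        assert np.allclose(heights[:-1], 0.0)

    def test_matches_average_linkage_oracle(self, rng):
        d = rng.uniform(0.1, 1.0, size=(5, 5))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        tree = cx.cluster_genes(_diss_frame(d))
        assert np.allclose(sorted(tree[:, 2]), average_linkage_oracle(d), atol=1e-12)

    def test_permutation_equivariant_heights(self, rng):
        d = rng.uniform(0.1, 1.0, size=(8, 8))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        perm = rng.permutation(8)
        t1 = cx.cluster_genes(_diss_frame(d))
        t2 = cx.cluster_genes(_diss_frame(d[np.ix_(perm, perm)]))
        assert np.allclose(sorted(t1[:, 2]), sorted(t2[:, 2]), atol=1e-12)

    def test_asymmetric_input_rejected(self, rng):
        d = rng.uniform(size=(4, 4))
        with pytest.raises(ValueError, match="symmetric"):
            cx.cluster_genes(_diss_frame(d))


class TestTreeCut:
    def test_planted_modules_recovered(self):
        from sklearn.metrics import adjusted_rand_score
        cfg = cx.SyntheticConfig(
            n_genes=800, module_sizes=(100, 100, 100), loading_mean=0.8,
            noise_sd=0.6, n_samples=50, seed=11,
        )
        expr, _, truth = cx.generate_dataset(cfg)
        # fixed conventional power isolates the cut from power selection
        assignment, _, _ = cx.detect_modules(expr, cx.SignatureParams(power=6))
        members = truth.assignment.index[truth.assignment > 0]
        ari = adjusted_rand_score(
            truth.assignment[members], assignment.labels[members]
        )
        assert ari >= 0.9

    def test_oversized_min_module_leaves_all_unassigned(self, rng):
        d = rng.uniform(0.1, 1.0, size=(10, 10))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        tree = cx.cluster_genes(_diss_frame(d))
        out = cx.cut_tree_dynamic(tree, _diss_frame(d).index, min_module_size=11)
        assert (out.labels == 0).all()

    def test_zero_cut_height_leaves_all_unassigned(self, rng):
        d = rng.uniform(0.1, 1.0, size=(10, 10))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        tree = cx.cluster_genes(_diss_frame(d))
        out = cx.cut_tree_dynamic(tree, _diss_frame(d).index,
                                  min_module_size=2, cut_height=0.0)
        assert (out.labels == 0).all()

    def test_min_module_size_floor(self, rng):
        d = np.zeros((4, 4))
        tree = cx.cluster_genes(_diss_frame(d))
        with pytest.raises(ValueError, match="min_module_size"):
            cx.cut_tree_dynamic(tree, _diss_frame(d).index, min_module_size=1)

    def test_partition_covers_all_genes(self):
        cfg = cx.SyntheticConfig(n_genes=300, module_sizes=(60, 60),
                                 n_samples=30, seed=1)
        expr, _, _ = cx.generate_dataset(cfg)
        assignment, _, _ = cx.detect_modules(expr, cx.SignatureParams())
        assert assignment.sizes().sum() + (assignment.labels == 0).sum() == 300


class TestEigengenes:
    def test_rank_one_module(self, rng):
        v = rng.standard_normal(12)
        expr = pd.DataFrame(
            [2 * v + 1, 0.5 * v, v], index=["a", "b", "c"],
            columns=[f"s{i}" for i in range(12)],
        )
        assignment = ModuleAssignment(labels=pd.Series([1, 1, 1], index=expr.index))
        eg = cx.module_eigengenes(expr, assignment)
        assert eg.variance_explained[1] == pytest.approx(1.0)
        vz = (v - v.mean()) / v.std(ddof=1)
        assert np.allclose(eg.vector(1).to_numpy(), vz, atol=1e-8)

    def test_anticorrelated_pair_orientation(self, rng):
        v = rng.standard_normal(10)
        expr = pd.DataFrame([v, -v], index=["a", "b"],
                            columns=[f"s{i}" for i in range(10)])
        assignment = ModuleAssignment(labels=pd.Series([1, 1], index=expr.index))
        eg = cx.module_eigengenes(expr, assignment)
        assert eg.variance_explained[1] == pytest.approx(1.0)
        # mean profile vanishes; tie broken toward the first member gene
        assert np.corrcoef(eg.vector(1), v)[0, 1] > 0

    def test_matches_svd_oracle(self, rng):
        expr = pd.DataFrame(
            rng.standard_normal((10, 15)),
            index=[f"g{i}" for i in range(10)],
            columns=[f"s{i}" for i in range(15)],
        )
        assignment = ModuleAssignment(labels=pd.Series(1, index=expr.index))
        eg = cx.module_eigengenes(expr, assignment)
        z = expr.to_numpy()
        z = (z - z.mean(axis=1, keepdims=True)) / z.std(axis=1, ddof=1, keepdims=True)
        _, s, vt = np.linalg.svd(z, full_matrices=False)
        oracle = vt[0] - vt[0].mean()
        oracle /= oracle.std(ddof=1)
        got = eg.vector(1).to_numpy()
        assert np.allclose(got, oracle, atol=1e-8) or np.allclose(got, -oracle, atol=1e-8)
        assert eg.variance_explained[1] == pytest.approx(s[0] ** 2 / (s**2).sum())

    def test_singleton_module_rejected(self, rng):
        expr = pd.DataFrame(rng.standard_normal((3, 6)),
                            index=["a", "b", "c"],
                            columns=[f"s{i}" for i in range(6)])
        assignment = ModuleAssignment(labels=pd.Series([1, 2, 2], index=expr.index))
        with pytest.raises(ValueError, match="module 1"):
            cx.module_eigengenes(expr, assignment)


class TestMergeModules:
    def test_artificially_split_module_remerged(self, small_cohort):
        expr, _, truth = small_cohort
        labels = truth.assignment.copy()
        members = labels.index[labels == 1]
        labels.loc[members[:25]] = 3          # split planted module 1 in two
        merged = cx.merge_close_modules(expr, ModuleAssignment(labels=labels),
                                        eigengene_dissimilarity_cut=0.25)
        half_a = set(members[:25])
        half_b = set(members[25:])
        lab_of = merged.labels
        assert len({lab_of[g] for g in half_a} | {lab_of[g] for g in half_b}) == 1

    def test_zero_cut_is_noop(self, small_cohort):
        expr, _, truth = small_cohort
        assignment = ModuleAssignment(labels=truth.assignment)
        merged = cx.merge_close_modules(expr, assignment,
                                        eigengene_dissimilarity_cut=0.0)
        # same partition (labels may be renumbered)
        assert (
            pd.crosstab(assignment.labels, merged.labels).astype(bool).sum().max() == 1
        )

    def test_independent_modules_not_merged(self, small_cohort):
        expr, _, truth = small_cohort
        assignment = ModuleAssignment(labels=truth.assignment)
        merged = cx.merge_close_modules(expr, assignment)
        assert len(merged.module_labels) == len(assignment.module_labels)


class TestHubsAndEdges:
    def test_identical_genes_all_kme_one(self, rng):
        v = rng.standard_normal(10)
        expr = pd.DataFrame([v, v, v], index=["a", "b", "c"],
                            columns=[f"s{i}" for i in range(10)])
        labels = ModuleAssignment(labels=pd.Series(1, index=expr.index))
        adj = cx.adjacency_from_correlation(cx.pairwise_correlation(expr), 6)
        eg = cx.module_eigengenes(expr, labels)
        report = cx.hub_genes(adj, expr, labels, eg)[1]
        assert np.allclose(report["kME"], 1.0)
        assert list(report.sort_values("rank_kME").index) == ["a", "b", "c"]

    def test_kim_matches_loop_oracle(self, small_cohort):
        expr, _, truth = small_cohort
        labels = ModuleAssignment(labels=truth.assignment)
        adj = cx.adjacency_from_correlation(cx.pairwise_correlation(expr), 6)
        eg = cx.module_eigengenes(expr, labels)
        report = cx.hub_genes(adj, expr, labels, eg)
        genes = labels.genes(1)
        a = adj.values
        for g in genes[:10]:
            oracle = sum(a.loc[g, h] for h in genes if h != g)
            assert report[1].loc[g, "kIM"] == pytest.approx(oracle, abs=1e-10)

    def test_top_connections_sorted_and_clipped(self):
        tom = pd.DataFrame(
            [[1.0, 0.9, 0.2], [0.9, 1.0, 0.5], [0.2, 0.5, 1.0]],
            index=["a", "b", "c"], columns=["a", "b", "c"],
        )
        labels = ModuleAssignment(labels=pd.Series(1, index=tom.index))
        top2 = cx.export_top_connections(tom, labels, 1, n_edges=2)
        assert list(zip(top2["gene_a"], top2["gene_b"])) == [("a", "b"), ("b", "c")]
        everything = cx.export_top_connections(tom, labels, 1, n_edges=99)
        assert len(everything) == 3
        with pytest.raises(ValueError, match="n_edges"):
            cx.export_top_connections(tom, labels, 1, n_edges=0)

    def test_tie_breaking_deterministic(self):
        tom = pd.DataFrame(0.5, index=["a", "b", "c"], columns=["a", "b", "c"])
        np.fill_diagonal(tom.values, 1.0)
        labels = ModuleAssignment(labels=pd.Series(1, index=tom.index))
        edges = cx.export_top_connections(tom, labels, 1, n_edges=3)
        assert list(zip(edges["gene_a"], edges["gene_b"])) == [
            ("a", "b"), ("a", "c"), ("b", "c")
        ]
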