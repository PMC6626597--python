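import numpy as np
import pandas as pd
import pytest

from comodnet.detection import (
    GREY,
    ModulePartition,
    assign_colors,
    average_linkage,
    dynamic_tree_cut,
    eigengene_dissimilarity,
    merge_close_modules,
    module_eigengene,
)
from comodnet.expression import ExpressionMatrix
from comodnet.network import build_network, tom_dissimilarity
from comodnet.simulate import default_spec, simulate_expression, DEFAULT_EFFECTS


def upgma_reference(dissim):
    """Naive O(n^3) UPGMA: returns the sorted list of merge heights."""
    d = {frozenset([i]): None for i in range(dissim.shape[0])}
    clusters = [frozenset([i]) for i in range(dissim.shape[0])]
    heights = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                pairs = [(i, j) for i in clusters[a] for j in clusters[b]]
                avg = float(np.mean([dissim[i, j] for i, j in pairs]))
                if best is None or avg < best[0]:
                    best = (avg, a, b)
        avg, a, b = best
        heights.append(avg)
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append(merged)
    del d
    return sorted(heights)


def block_dissim(rng, sizes, within=0.1, between=0.9, jitter=0.01):
    """Symmetric dissimilarity with tight diagonal blocks."""
    n = sum(sizes)
    d = np.full((n, n), between)
    start = 0
    for size in sizes:
        d[start : start + size, start : start + size] = within
        start += size
    noise = rng.uniform(-jitter, jitter, size=(n, n))
    d = d + (noise + noise.T) / 2
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 1.0)


class TestAverageLinkage:
    def test_three_point_hand_computation(self):
        d = np.array([[0.0, 0.1, 0.8], [0.1, 0.0, 0.8], [0.8, 0.8, 0.0]])
        dendro = average_linkage(d, gene_ids=["A", "B", "C"])
        tree = dendro.linkage
        assert {int(tree[0, 0]), int(tree[0, 1])} == {0, 1}
        assert tree[0, 2] == pytest.approx(0.1)
        assert tree[1, 2] == pytest.approx(0.8)

    def test_identical_genes_merge_at_zero(self):
        d = np.array([[0.0, 0.0, 0.5], [0.0, 0.0, 0.5], [0.5, 0.5, 0.0]])
        dendro = average_linkage(d)
        assert dendro.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_matches_naive_upgma_reference(self, rng):
        raw = rng.uniform(0.05, 1.0, size=(15, 15))
        d = (raw + raw.T) / 2
        np.fill_diagonal(d, 0.0)
        dendro = average_linkage(d)
        np.testing.assert_allclose(
            np.sort(dendro.heights), upgma_reference(d), atol=1e-10
        )

    def test_heights_nondecreasing(self, small_bundle):
        expr = small_bundle.expr.subset_genes(small_bundle.expr.gene_ids[:120])
        net = build_network(expr)
        dendro = average_linkage(tom_dissimilarity(net.tom))
        assert (np.diff(dendro.heights) >= -1e-12).all()

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            average_linkage(np.array([[0.0, 0.2], [0.5, 0.0]]))


class TestDynamicTreeCut:
    def test_two_planted_blocks_recovered(self, rng):
        d = block_dissim(rng, [40, 35])
        part = dynamic_tree_cut(average_linkage(d), min_module_size=30)
        assert part.n_modules == 2
        labels = part.assignment.to_numpy()
        assert len(set(labels[:40])) == 1
        assert len(set(labels[40:])) == 1
        assert labels[0] != labels[-1]
        assert (labels != GREY).all()

    def test_noise_genes_left_grey(self, rng):
        n_block, n_noise = 40, 12
        n = n_block + n_noise
        d = np.full((n, n), 0.95)
        d[:n_block, :n_block] = 0.1
        noise = rng.uniform(0, 0.04, size=(n, n))
        d = d + (noise + noise.T) / 2
        np.fill_diagonal(d, 0.0)
        part = dynamic_tree_cut(average_linkage(d), min_module_size=30)
        assert part.n_modules == 1
        labels = part.assignment.to_numpy()
        assert (labels[:n_block] != GREY).all()
        assert (labels[n_block:] == GREY).all()

    def test_block_below_min_size_is_grey(self, rng):
        d = block_dissim(rng, [40, 20])
        part = dynamic_tree_cut(average_linkage(d), min_module_size=30)
        labels = part.assignment.to_numpy()
        assert part.n_modules == 1
        assert (labels[40:] == GREY).all()

    def test_min_module_size_validation(self, rng):
        d = block_dissim(rng, [40])
        with pytest.raises(ValueError, match="min_module_size"):
            dynamic_tree_cut(average_linkage(d), min_module_size=1)
        with pytest.raises(ValueError, match="fewer"):
            dynamic_tree_cut(average_linkage(d), min_module_size=50)


class TestModuleEigengene:
    @staticmethod
    def z(values):
        values = np.asarray(values, dtype=float)
        return (values - values.mean(axis=1, keepdims=True)) / values.std(
            axis=1, ddof=1, keepdims=True
        )

    def test_single_gene_module_matches_profile(self, rng):
        values = rng.standard_normal((1, 12))
        expr = ExpressionMatrix(pd.DataFrame(values, index=["g0"]))
        part = ModulePartition(pd.Series(["M1"], index=["g0"]))
        eig = module_eigengene(expr, part)
        me = eig.eigengenes.loc["M1"].to_numpy()
        assert np.corrcoef(me, values[0])[0, 1] == pytest.approx(1.0)
        assert eig.variance_explained["M1"] == pytest.approx(1.0)

    def test_two_identical_genes(self, rng):
        row = rng.standard_normal(10)
        expr = ExpressionMatrix(pd.DataFrame([row, row], index=["a", "b"]))
        part = ModulePartition(pd.Series(["M1", "M1"], index=["a", "b"]))
        eig = module_eigengene(expr, part)
        assert eig.variance_explained["M1"] == pytest.approx(1.0)

    def test_matches_eigendecomposition_reference(self, rng):
        """Eigengene equals the top eigenvector of Z'Z (up to sign) and
        variance explained equals lambda_1 / trace."""
        values = rng.standard_normal((20, 14))
        genes = [f"g{i}" for i in range(20)]
        expr = ExpressionMatrix(pd.DataFrame(values, index=genes))
        part = ModulePartition(pd.Series(["M1"] * 20, index=genes))
        eig = module_eigengene(expr, part)
        zmat = self.z(values)
        lam, vec = np.linalg.eigh(zmat.T @ zmat)
        ref = vec[:, -1]
        me = eig.eigengenes.loc["M1"].to_numpy()
        assert abs(float(np.dot(me, ref))) == pytest.approx(1.0, abs=1e-8)
        assert eig.variance_explained["M1"] == pytest.approx(
            lam[-1] / lam.sum(), abs=1e-10
        )

    def test_sign_aligned_with_module_mean(self, small_bundle):
        part = ModulePartition(small_bundle.truth.copy())
        eig = module_eigengene(small_bundle.expr, part)
        for label in part.labels:
            zmat = self.z(small_bundle.expr.data.loc[part.members(label)].to_numpy())
            me = eig.eigengenes.loc[label].to_numpy()
            assert np.corrcoef(me, zmat.mean(axis=0))[0, 1] >= 0

    def test_variance_explained_is_mean_squared_correlation(self, rng):
        """First-PC optimality: the eigengene maximizes the mean squared
        gene correlation, which equals its variance explained."""
        values = rng.standard_normal((15, 10))
        genes = [f"g{i}" for i in range(15)]
        expr = ExpressionMatrix(pd.DataFrame(values, index=genes))
        part = ModulePartition(pd.Series(["M1"] * 15, index=genes))
        eig = module_eigengene(expr, part)
        me = eig.eigengenes.loc["M1"].to_numpy()
        cors_me = [np.corrcoef(values[i], me)[0, 1] ** 2 for i in range(15)]
        assert np.mean(cors_me) == pytest.approx(
            eig.variance_explained["M1"], abs=1e-10
        )
        for _ in range(20):
            u = rng.standard_normal(10)
            cors_u = [np.corrcoef(values[i], u)[0, 1] ** 2 for i in range(15)]
            assert np.mean(cors_u) <= np.mean(cors_me) + 1e-12

    def test_zero_variance_module_named(self):
        expr = ExpressionMatrix(
            pd.DataFrame([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]], index=["flat", "ok"])
        )
        part = ModulePartition(pd.Series(["M1", "M1"], index=["flat", "ok"]))
        with pytest.raises(ValueError, match="M1"):
            module_eigengene(expr, part)


class TestMergeCloseModules:
    def test_shared_factor_modules_merge(self):
        spec = default_spec(
            seed=11,
            module_sizes=(50, 50, 40),
            factor_assignment=(0, 0, 1),
            within_factor_r=0.9,
            effects=DEFAULT_EFFECTS[:2],
            n_background=0,
        )
        bundle = simulate_expression(spec)
        part = ModulePartition(bundle.truth.copy())
        merged, eig = merge_close_modules(bundle.expr, part, cut_height=0.25)
        assert merged.n_modules == 2
        labels = merged.assignment.to_numpy()
        assert len(set(labels[:100])) == 1
        assert labels[0] != labels[-1]

    def test_distant_eigengenes_left_alone(self, small_bundle):
        part = ModulePartition(small_bundle.truth.copy())
        merged, eig = merge_close_modules(small_bundle.expr, part, cut_height=0.25)
        assert merged.n_modules == part.n_modules
        d = eigengene_dissimilarity(eig).to_numpy()
        off = ~np.eye(d.shape[0], dtype=bool)
        assert (d[off] >= 0.25).all()

    def test_final_eigengenes_separated_by_cut_height(self, small_bundle):
        part = ModulePartition(small_bundle.truth.copy())
        for cut in (0.25, 0.6):
            merged, eig = merge_close_modules(small_bundle.expr, part, cut_height=cut)
            if merged.n_modules > 1:
                d = eigengene_dissimilarity(eig).to_numpy()
                off = ~np.eye(d.shape[0], dtype=bool)
                assert d[off].min() >= cut - 1e-9

    def test_cut_height_validation(self, small_bundle):
        part = ModulePartition(small_bundle.truth.copy())
        with pytest.raises(ValueError, match="cut_height"):
            merge_close_modules(small_bundle.expr, part, cut_height=0.0)
        with pytest.raises(ValueError, match="cut_height"):
            merge_close_modules(small_bundle.expr, part, cut_height=1.5)


class TestAssignColors:
    def test_size_ranked_color_names(self):
        labels = ["A"] * 40 + ["B"] * 60 + [GREY] * 5
        genes = [f"g{i}" for i in range(len(labels))]
        part = ModulePartition(pd.Series(labels, index=genes))
        colored = assign_colors(part)
        sizes = colored.module_sizes()
        assert sizes["turquoise"] == 60
        assert sizes["blue"] == 40
        assert (colored.assignment.iloc[-5:] == GREY).all()

    def test_size_ties_break_by_first_gene_id(self):
        labels = ["B"] * 30 + ["A"] * 30
        genes = [f"g{i:02d}" for i in range(60)]
        part = ModulePartition(pd.Series(labels, index=genes))
        colored = assign_colors(part)
        # module "B" holds g00..g29, the lexicographically first gene
        assert colored.assignment["g00"] == "turquoise"
        assert colored.assignment["g59"] == "blue"
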