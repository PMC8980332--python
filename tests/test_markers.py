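"""Cell QC, normalisation, rank-sum testing, and marker selection."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from crmscan.markers import (
    EmptyResultError,
    ExpressionMatrix,
    find_markers,
    normalize,
    passing_markers,
    qc_filter_cells,
    rank_sum_test,
    select_tfs,
)
from crmscan.simulate import ExpressionSpec, make_expression


def small_matrix(columns, mito=("mt-0",)):
    """columns: dict cell -> list of counts over genes g0..g{n-1}, mt-0."""
    genes = [f"g{i}" for i in range(len(next(iter(columns.values()))) - 1)] + ["mt-0"]
    cells = list(columns)
    counts = np.array([columns[c] for c in cells]).T
    return ExpressionMatrix(
        genes=genes,
        cells=cells,
        counts=counts,
        cluster_of={c: "X" for c in cells},
        mito_genes=frozenset(mito),
    )


class TestQcFilter:
    def _matrix_with_detected(self, n_detected, n_genes=1200, mito_counts=0):
        counts = np.zeros((n_genes + 1, 1), dtype=int)
        counts[:n_detected, 0] = 10
        counts[n_genes, 0] = mito_counts  # the mito gene
        genes = [f"g{i}" for i in range(n_genes)] + ["mt-0"]
        return ExpressionMatrix(
            genes=genes,
            cells=["c0"],
            counts=counts,
            cluster_of={"c0": "X"},
            mito_genes=frozenset(["mt-0"]),
        )

    def test_exactly_900_genes_removed(self):
        with pytest.raises(EmptyResultError):
            qc_filter_cells(self._matrix_with_detected(900))

    def test_901_genes_kept(self):
        out = qc_filter_cells(self._matrix_with_detected(901))
        assert out.n_cells == 1

    def test_exactly_20_pct_mito_removed(self):
        # 950 genes x 10 counts = 9500; mito 2375 -> exactly 20% of 11875
        mat = self._matrix_with_detected(950, mito_counts=2375)
        assert mat.counts[:, 0].sum() * 0.2 == 2375
        with pytest.raises(EmptyResultError):
            qc_filter_cells(mat)

    def test_under_both_bounds_kept(self):
        mat = self._matrix_with_detected(950, mito_counts=500)
        assert qc_filter_cells(mat).n_cells == 1

    def test_25_pct_mito_removed(self):
        mat = self._matrix_with_detected(950, mito_counts=9500 // 3 + 1)
        with pytest.raises(EmptyResultError):
            qc_filter_cells(mat)


class TestNormalize:
    def test_zero_count_maps_to_zero(self):
        mat = small_matrix({"c0": [0, 3, 7, 1]})
        _, norm = normalize(mat)
        assert norm[0, 0] == 0.0

    def test_count_equal_to_total(self):
        mat = small_matrix({"c0": [5, 0, 0, 0]})
        _, norm = normalize(mat)
        assert norm[0, 0] == pytest.approx(math.log(1 + 1e4), abs=1e-6)
        assert math.log(1 + 1e4) == pytest.approx(9.2104, abs=1e-4)

    def test_depth_invariance(self):
        a = small_matrix({"c0": [1, 2, 3, 4]})
        b = small_matrix({"c0": [2, 4, 6, 8]})
        _, na = normalize(a)
        _, nb = normalize(b)
        assert np.allclose(na, nb)

    def test_zero_total_cell_dropped_with_warning(self):
        mat = small_matrix({"c0": [1, 2, 3, 4], "c1": [0, 0, 0, 0]})
        with pytest.warns(UserWarning):
            out, norm = normalize(mat)
        assert out.n_cells == 1 and norm.shape[1] == 1


def brute_exact_ranksum(a, b):
    """Exhaustive enumeration over all C(n, |a|) group assignments."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    na, n = len(a), len(pooled)
    w_obs = ranks[:na].sum()
    mean = na * (n + 1) / 2
    dev = abs(w_obs - mean)
    extreme = total = 0
    for combo in itertools.combinations(range(n), na):
        w = ranks[list(combo)].sum()
        total += 1
        if abs(w - mean) >= dev - 1e-12:
            extreme += 1
    return extreme / total


class TestRankSum:
    def test_canonical_exact_case(self):
        # {1,2,3} vs {4,5,6}: 2 of the 20 arrangements are as extreme
        assert rank_sum_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        assert rank_sum_test([2, 2, 2], [2, 2, 2]) == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        na = int(rng.integers(2, 5))
        nb = int(rng.integers(2, 7 - na + 4))
        # integer draws force ties into the enumeration as well
        a = rng.integers(0, 6, size=na).astype(float)
        b = rng.integers(0, 6, size=nb).astype(float)
        assert rank_sum_test(a, b) == pytest.approx(brute_exact_ranksum(a, b))

    @pytest.mark.parametrize("seed", range(10))
    def test_normal_approximation_near_exact(self, seed):
        rng = np.random.default_rng(100 + seed)
        a = rng.normal(0.0, 1.0, size=20)
        b = rng.normal(0.3, 1.0, size=20)
        exact = rank_sum_test(a, b, exact_max_n=50)
        approx = rank_sum_test(a, b, exact_max_n=0)
        assert approx == pytest.approx(exact, rel=0.10)


@pytest.fixture(scope="module")
def planted_mat():
    spec = ExpressionSpec(
        n_genes=200,
        cluster_cells=(("MG", 100), ("Rest", 300)),
        planted_markers=(("hot16", "MG", 16.0), ("warm25", "MG", 2.5)),
    )
    mat, _ = make_expression(spec, seed=5)
    return mat


class TestFindMarkers:
    def test_sixteen_fold_marker_passes(self, planted_mat):
        results = find_markers(planted_mat, "MG")
        by_gene = {r.gene_id: r for r in results}
        hot = by_gene["hot16"]
        assert hot.log2fc > 2 and hot.p_value < 1e-10 and hot.passes
        assert hot.log2fc == pytest.approx(4.0, abs=0.8)

    def test_two_point_five_fold_fails_fc_filter(self, planted_mat):
        results = find_markers(planted_mat, "MG")
        warm = {r.gene_id: r for r in results}["warm25"]
        assert warm.p_value < 0.05  # significant ...
        assert warm.log2fc < 2 and not warm.passes  # ... but under the FC cut

    def test_low_pct_gene_excluded(self, planted_mat):
        mat = ExpressionMatrix(
            genes=list(planted_mat.genes),
            cells=list(planted_mat.cells),
            counts=planted_mat.counts.copy(),
            cluster_of=dict(planted_mat.cluster_of),
            mito_genes=planted_mat.mito_genes,
        )
        gi = mat.genes.index("gene0000")
        row = np.zeros(mat.n_cells, dtype=mat.counts.dtype)
        row[:: 10] = 1  # ~10% of cells in both groups
        mat.counts[gi] = row
        results = find_markers(mat, "MG")
        assert "gene0000" not in {r.gene_id for r in results}

    def test_degenerate_cluster_rejected(self, planted_mat):
        with pytest.raises(ValueError):
            find_markers(planted_mat, "NotACluster")


class TestSelectTfs:
    def _mk(self, gene, passes=True):
        from crmscan.markers import MarkerResult

        return MarkerResult(gene, "MG", 3.0, 1e-6, 1e-5, 0.9, 0.1, passes=passes)

    def test_intersection_preserves_order(self):
        markers = [self._mk(g) for g in ["a", "b", "c", "d", "e"]]
        panel = select_tfs(markers, ["d", "b"])
        assert [r.gene_id for r in panel] == ["b", "d"]
        assert all(r.is_tf for r in panel)

    def test_failing_markers_not_selected(self):
        markers = [self._mk("a", passes=False)]
        with pytest.warns(UserWarning):
            assert select_tfs(markers, ["a"]) == []

    def test_disjoint_sets_warn_empty(self):
        with pytest.warns(UserWarning):
            assert select_tfs([self._mk("a")], ["z"]) == []

    def test_duplicate_tf_ids_deduplicated(self):
        panel = select_tfs([self._mk("a")], ["a", "a", "a"])
        assert [r.gene_id for r in panel] == ["a"]


class TestParameterRecovery:
    def test_planted_marker_recall_and_false_pass_rate(self):
        planted = tuple((f"mk{i:02d}", "MG", 16.0) for i in range(20))
        spec = ExpressionSpec(
            n_genes=500,
            cluster_cells=(("MG", 100), ("Rest", 300)),
            planted_markers=planted,
        )
        mat, truth = make_expression(spec, seed=11)
        results = find_markers(mat, "MG")
        passed = {r.gene_id for r in results if r.passes}
        planted_names = set(truth.gene_id)
        recall = len(passed & planted_names) / len(planted_names)
        false_pass = len(passed - planted_names) / (len(mat.genes) - len(planted_names))
        assert recall >= 0.95
        assert false_pass <= 0.05

    def test_label_permutation_null_calibrated(self):
        spec = ExpressionSpec(
            n_genes=400, cluster_cells=(("MG", 100), ("Rest", 300))
        )
        mat, _ = make_expression(spec, seed=21)
        rng = np.random.default_rng(22)
        labels = np.array([mat.cluster_of[c] for c in mat.cells])
        rng.shuffle(labels)
        mat.cluster_of = dict(zip(mat.cells, labels))
        results = find_markers(mat, "MG")
        frac = np.mean([r.p_value < 0.05 for r in results])
        n = len(results)
        half_width = 2.576 * math.sqrt(0.05 * 0.95 / n)
        assert abs(frac - 0.05) <= half_width + 1e-12
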