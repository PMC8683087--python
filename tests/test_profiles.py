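"""QC filtering, pseudobulk profiles, expressed-gene calling, markers, dotplots."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from urchin_atlas import (
    GeneSetPanel,
    ParameterError,
    SimConfig,
    call_expressed,
    cluster_profile,
    dotplot_table,
    filter_qc,
    find_markers,
    rank_sum_test,
    simulate_atlas,
)
from urchin_atlas.core_io import AtlasError
from conftest import make_matrix


def annotate(cells, clusters, subclusters=None):
    ann = pd.DataFrame({"cell_id": cells, "cluster": clusters})
    if subclusters is not None:
        ann["subcluster"] = subclusters
    return ann


class TestQC:
    def test_gene_in_two_cells_removed(self):
        # detected in exactly 2 of 4 cells -> below the strict 3-cell cut
        m = make_matrix([[1, 1, 0, 0], [1, 1, 1, 1]])
        out = filter_qc(m, min_cells=3, min_genes=0)
        assert out.gene_ids == ["g1"]

    def test_cell_at_exactly_min_genes_retained(self):
        n = 250
        arr = np.ones((n, 2), dtype=int)
        arr[200:, 0] = 0  # cell0 detects exactly 200 genes
        arr[210:, 1] = 0
        m = make_matrix(arr)
        out = filter_qc(m, min_cells=0, min_genes=200)
        assert out.cell_ids == ["cell0", "cell1"]
        out = filter_qc(m, min_cells=0, min_genes=201)
        assert out.cell_ids == ["cell1"]

    def test_clean_matrix_unchanged_and_idempotent(self, small_atlas):
        m, _, _ = small_atlas
        once = filter_qc(m, min_genes=20)
        twice = filter_qc(once, min_genes=20)
        assert once == twice

    def test_all_cells_removed_warns_not_raises(self, caplog):
        m = make_matrix([[1, 1, 1]])
        with caplog.at_level("WARNING", logger="urchin_atlas"):
            out = filter_qc(m, min_cells=3, min_genes=5)
        assert out.n_cells == 0


class TestClusterProfile:
    def test_single_cell_cpm(self):
        m = make_matrix([[3], [1]], genes=["g1", "g2"], cells=["a"])
        prof = cluster_profile(m, annotate(["a"], ["c1"]))
        assert prof.mean_cpm.loc["c1"].tolist() == [750000.0, 250000.0]

    def test_duplicated_cell_idempotent(self):
        m1 = make_matrix([[3], [1]], cells=["a"])
        m2 = make_matrix([[3, 3], [1, 1]], cells=["a", "b"])
        p1 = cluster_profile(m1, annotate(["a"], ["c1"]))
        p2 = cluster_profile(m2, annotate(["a", "b"], ["c1", "c1"]))
        assert np.allclose(p1.mean_cpm.values, p2.mean_cpm.values)

    def test_rows_sum_to_one_million(self, small_atlas):
        m, ann, _ = small_atlas
        prof = cluster_profile(m, ann)
        assert np.allclose(prof.mean_cpm.sum(axis=1), 1e6, rtol=1e-9)
        assert ((prof.pct_expressing >= 0) & (prof.pct_expressing <= 1)).all().all()

    def test_unannotated_cell_listed(self):
        m = make_matrix([[1, 2]], cells=["a", "b"])
        with pytest.raises(AtlasError, match="b"):
            cluster_profile(m, annotate(["a"], ["c1"]))

    def test_profile_tracks_generator_truth(self):
        """Pseudobulk CPM agrees with the planted expectations at depth."""
        cfg = SimConfig(n_clusters=4, cells_per_cluster=500, n_genes=100,
                        baseline_mean=50.0, nb_dispersion=10.0,
                        markers_per_cluster=0, panel_size=0, seed=7)
        m, ann, truth = simulate_atlas(cfg)
        prof = cluster_profile(m, ann)
        t = truth.cluster_means
        mask = t >= 50
        rel = ((prof.mean_cpm[mask] - t[mask]).abs() / t[mask]).stack()
        assert (rel < 0.10).mean() >= 0.99
        assert rel.median() < 0.05


class TestCallExpressed:
    def make_profile(self, cpm_rows, clusters, genes):
        cpm = pd.DataFrame(cpm_rows, index=clusters, columns=genes)
        from urchin_atlas import ClusterProfile
        return ClusterProfile(cpm, cpm * 0, pd.Series(1, index=clusters))

    def test_strictly_greater_than_threshold(self):
        p = self.make_profile([[3.0, 3.01, 0.0]], ["c1"], ["g1", "g2", "g3"])
        ex = call_expressed(p, threshold_tpm=3.0)
        assert ex["c1"] == {"g2"}
        assert ex.anywhere() == {"g2"}

    def test_raising_threshold_monotone(self, small_atlas):
        m, ann, _ = small_atlas
        prof = cluster_profile(m, ann)
        lo, hi = call_expressed(prof, 3.0), call_expressed(prof, 30.0)
        for c in prof.clusters:
            assert hi[c] <= lo[c]


def brute_force_rank_sum_p(x, y):
    """Oracle: exact two-sided permutation p for the rank-sum statistic."""
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    n1, n = len(x), len(combined)
    mu = n1 * (n + 1) / 2
    obs = abs(ranks[:n1].sum() - mu)
    hits = total = 0
    for idx in itertools.combinations(range(n), n1):
        total += 1
        if abs(sum(ranks[i] for i in idx) - mu) >= obs - 1e-9:
            hits += 1
    return hits / total


class TestRankSum:
    @pytest.mark.parametrize("n1,n2,seed", [(3, 3, 0), (4, 7, 1), (6, 6, 2),
                                            (10, 10, 3), (5, 9, 4)])
    def test_exact_matches_brute_force(self, n1, n2, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 4, n1).astype(float)  # heavy ties
        y = rng.integers(0, 4, n2).astype(float)
        assert rank_sum_test(x, y) == pytest.approx(brute_force_rank_sum_p(x, y))

    def test_normal_approx_close_to_exact(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=11)  # just above the exact-enumeration cutoff
        y = rng.normal(size=8)
        approx = rank_sum_test(x, y)
        exact = brute_force_rank_sum_p(x, y)
        assert approx == pytest.approx(exact, abs=0.03)

    def test_identical_samples_p_one(self):
        assert rank_sum_test(np.ones(5), np.ones(7)) == 1.0


class TestFindMarkers:
    def test_planted_marker_detected(self):
        cfg = SimConfig(n_clusters=3, cells_per_cluster=500, n_genes=200,
                        markers_per_cluster=1, marker_log2fc=4.0,
                        branch_sd=0.3, gene_mean_sigma=0.5, seed=11,
                        panel_size=0)
        m, ann, truth = simulate_atlas(cfg)
        gene, cluster = next(iter(truth.marker_of.items()))
        table = find_markers(m, ann, cluster)
        row = table[table["gene_id"] == gene].iloc[0]
        assert row["log2_fc"] > 2.0
        assert row["p_adj"] < 0.01

    def test_min_pct_filter_excludes_rare_gene(self):
        # g0 detected in 0.5% of cells in both groups, min_pct=0.01
        arr = np.zeros((2, 400), dtype=int)
        arr[0, 0] = 1    # 1/200 in cluster A
        arr[0, 200] = 1  # 1/200 in cluster B
        arr[1, :] = 1
        m = make_matrix(arr)
        ann = annotate(m.cell_ids, ["A"] * 200 + ["B"] * 200)
        table = find_markers(m, ann, "A", min_pct=0.01)
        assert "g0" not in set(table["gene_id"])

    def test_no_signal_gene(self):
        arr = np.ones((1, 20), dtype=int)
        m = make_matrix(arr)
        ann = annotate(m.cell_ids, ["A"] * 10 + ["B"] * 10)
        table = find_markers(m, ann, "A")
        row = table.iloc[0]
        assert row["p"] == 1.0 and row["log2_fc"] == 0.0

    def test_tiny_cluster_rejected(self):
        m = make_matrix(np.ones((3, 5), dtype=int))
        ann = annotate(m.cell_ids, ["A"] * 2 + ["B"] * 3)
        with pytest.raises(ParameterError):
            find_markers(m, ann, "A")

    def test_padj_bounds(self, small_atlas):
        m, ann, _ = small_atlas
        table = find_markers(m, ann, "c1")
        assert (table["p_adj"] >= table["p"]).all()
        assert table["p_adj"].between(0, 1).all()


class TestDotplot:
    def make_profile(self, cpm_rows, clusters, genes):
        from urchin_atlas import ClusterProfile
        cpm = pd.DataFrame(cpm_rows, index=clusters, columns=genes)
        return ClusterProfile(cpm, cpm * 0 + 0.5, pd.Series(1, index=clusters))

    def test_uniform_gene_z_zero(self):
        p = self.make_profile([[10.0], [10.0], [10.0]], ["a", "b", "c"], ["g"])
        tab = dotplot_table(p, GeneSetPanel("x", {"g"}))
        assert (tab["z"] == 0).all()

    def test_two_cluster_contrast(self):
        p = self.make_profile([[100.0], [0.0]], ["a", "b"], ["g"])
        tab = dotplot_table(p, GeneSetPanel("x", {"g"}))
        assert tab["z"].tolist() == pytest.approx(
            [1 / math.sqrt(2), -1 / math.sqrt(2)]
        )

    def test_all_genes_missing_empty(self, caplog):
        p = self.make_profile([[1.0], [2.0]], ["a", "b"], ["g"])
        with caplog.at_level("WARNING", logger="urchin_atlas"):
            tab = dotplot_table(p, GeneSetPanel("x", {"absent"}))
        assert tab.empty
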