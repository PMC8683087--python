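"""Independent-swap null, panel counting, chi-squared, and the full test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from urchin_atlas import (
    ContingencyTable2x2,
    GeneSetPanel,
    IntegrityError,
    ParameterError,
    chi_squared_2x2,
    coexpression_power_config,
    coexpression_test,
    extract_subfamily_matrix,
    independent_swap,
    panel_expressed_count,
    simulate_atlas,
)
from urchin_atlas.core_io import AtlasError
from conftest import make_matrix


def swap_invariants(before, after):
    assert before.sum() == pytest.approx(after.sum())
    assert np.array_equal((before > 0).sum(axis=1), (after > 0).sum(axis=1))
    assert np.array_equal((before > 0).sum(axis=0), (after > 0).sum(axis=0))
    for r in range(before.shape[0]):
        assert sorted(before[r][before[r] > 0]) == sorted(after[r][after[r] > 0])


class TestIndependentSwap:
    def test_checkerboard_two_state_space(self):
        # a 2x2 checkerboard has exactly two states; every attempt samples the
        # full quartet, so n swaps land on the start (n even) or flip (n odd)
        a = np.array([[5.0, 0.0], [0.0, 7.0]])
        flipped = np.array([[0.0, 5.0], [7.0, 0.0]])
        for n in range(6):
            out = independent_swap(a, n_iter=n, seed=n)
            assert np.array_equal(out, flipped if n % 2 else a)

    def test_all_nonzero_fixed_point(self):
        m = np.arange(1.0, 13.0).reshape(3, 4)
        assert np.array_equal(independent_swap(m, n_iter=5000, seed=0), m)

    @pytest.mark.parametrize("seed", range(5))
    def test_conservation_laws(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.poisson(0.7, size=(20, 30)).astype(float)
        out = independent_swap(m, n_iter=10_000, seed=seed + 100)
        swap_invariants(m, out)

    def test_zero_iterations_identity(self):
        rng = np.random.default_rng(1)
        m = rng.poisson(1.0, size=(5, 5)).astype(float)
        assert np.array_equal(independent_swap(m, n_iter=0, seed=3), m)

    def test_seed_reproducible(self):
        rng = np.random.default_rng(2)
        m = rng.poisson(0.5, size=(15, 15)).astype(float)
        a = independent_swap(m, n_iter=3000, seed=11)
        b = independent_swap(m, n_iter=3000, seed=11)
        assert np.array_equal(a, b)

    def test_successful_mode_conserves(self):
        rng = np.random.default_rng(3)
        m = rng.poisson(0.5, size=(15, 20)).astype(float)
        out = independent_swap(m, n_iter=200, seed=4, count_successful=True)
        swap_invariants(m, out)

    def test_parameter_errors(self):
        with pytest.raises(ParameterError):
            independent_swap(np.ones((1, 5)), n_iter=10)
        with pytest.raises(ParameterError):
            independent_swap(np.ones((3, 3)), n_iter=-1)
        with pytest.raises(IntegrityError):
            independent_swap(np.array([[1.0, -1.0], [0.0, 1.0]]), n_iter=1)


class TestPanelCount:
    def test_absent_genes_count_zero(self):
        m = make_matrix([[1, 0], [0, 1]])
        assert panel_expressed_count(m, GeneSetPanel("p", {"zz", "yy"})) == 0

    def test_any_cell_rule(self):
        m = make_matrix([[1, 0], [0, 0], [2, 3]])
        panel = GeneSetPanel("p", {"g0", "g1", "g2"})
        assert panel_expressed_count(m, panel) == 2

    def test_mean_threshold_rule(self):
        m = make_matrix([[8, 0], [2, 2], [0, 1], [9, 9]])
        panel = GeneSetPanel("p", {"g0", "g1", "g2", "g3"})
        # means: 4, 2, 0.5, 9 -> strictly above 3: g0 and g3
        assert panel_expressed_count(m, panel, rule="mean_gt_thr", threshold=3) == 2


class TestChiSquared:
    def test_diagonal_table_yates(self):
        chi2, p = chi_squared_2x2(ContingencyTable2x2(10, 0, 0, 10))
        assert chi2 == pytest.approx(16.2)
        assert p == pytest.approx(stats.chi2.sf(16.2, 1))

    def test_equal_rows_null(self):
        chi2, p = chi_squared_2x2(ContingencyTable2x2(5, 5, 5, 5))
        assert (chi2, p) == (0.0, 1.0)

    def test_degenerate_margin(self):
        assert chi_squared_2x2(ContingencyTable2x2(0, 0, 3, 4)) == (0.0, 1.0)

    def test_negative_rejected(self):
        with pytest.raises(IntegrityError):
            ContingencyTable2x2(-1, 2, 3, 4)

    @pytest.mark.parametrize("continuity", [True, False])
    def test_matches_reference_implementation(self, continuity):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b, c, d = rng.integers(1, 40, size=4)
            chi2, p = chi_squared_2x2(ContingencyTable2x2(a, b, c, d), continuity)
            ref_chi2, ref_p, _, _ = stats.chi2_contingency(
                [[a, b], [c, d]], correction=continuity
            )
            assert chi2 == pytest.approx(ref_chi2, abs=1e-10)
            assert p == pytest.approx(ref_p, abs=1e-10)

    def test_uncorrected_equals_z_squared(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a, b, c, d = rng.integers(1, 30, size=4)
            chi2, _ = chi_squared_2x2(ContingencyTable2x2(a, b, c, d), False)
            p1, p2 = a / (a + b), c / (c + d)
            pool = (a + c) / (a + b + c + d)
            z = (p1 - p2) / np.sqrt(pool * (1 - pool) * (1 / (a + b) + 1 / (c + d)))
            assert chi2 == pytest.approx(z**2)


class TestExtractSubfamily:
    def test_column_subset(self, small_atlas):
        m, ann, _ = small_atlas
        fam = extract_subfamily_matrix(m, ann, "c6")
        expected = set(ann.loc[ann["cluster"] == "c6", "cell_id"])
        assert set(fam.cell_ids) == expected

    def test_silent_genes_dropped(self):
        m = make_matrix([[1, 0, 5], [0, 0, 9], [0, 0, 0]])
        ann = pd.DataFrame({"cell_id": m.cell_ids,
                            "cluster": ["fam", "fam", "other"]})
        fam = extract_subfamily_matrix(m, ann, "fam")
        assert fam.gene_ids == ["g0"] and fam.n_cells == 2

    def test_empty_family(self, small_atlas):
        m, ann, _ = small_atlas
        with pytest.raises(AtlasError):
            extract_subfamily_matrix(m, ann, "nope")


class TestCoexpressionTest:
    def test_ubiquitous_panel_is_null_fixed_point(self):
        """Panel genes present in every cell can never swap: chi2=0, p=1."""
        rng = np.random.default_rng(5)
        arr = rng.poisson(0.4, size=(10, 12))
        arr[:3, :] += 1  # panel rows occupy every cell
        m = make_matrix(arr)
        ann = pd.DataFrame({
            "cell_id": m.cell_ids,
            "cluster": ["fam"] * 12,
            "subcluster": ["fam.s1"] * 4 + ["fam.s2"] * 8,
        })
        panel = GeneSetPanel("p", {"g0", "g1", "g2"})
        res = coexpression_test(m, ann, "fam", "fam.s1", panel,
                                n_swap_iters=2000, n_replicates=20, seed=0)
        assert res.k_obs == 3
        assert all(c == 3 for c in res.per_replicate_counts)
        assert res.chi2 == 0.0 and res.p == 1.0

    def test_planted_panel_detected_scaled_down(self):
        """Scaled-down run (10k successful swaps, 50 replicates) finds the panel."""
        m, ann, truth = simulate_atlas(coexpression_power_config(5))
        res = coexpression_test(
            m, ann, truth.panel_cluster, truth.target_subcluster,
            truth.panel_genes, n_swap_iters=10_000, n_replicates=50,
            seed=5, count_successful=True,
        )
        assert res.p < 0.05
        assert res.p_empirical <= 0.02
        assert abs(res.k_rand_rounded - res.k_rand_mean) <= 0.5

    def test_result_table_margins(self, small_atlas):
        m, ann, truth = small_atlas
        res = coexpression_test(m, ann, truth.panel_cluster,
                                truth.target_subcluster, truth.panel_genes,
                                n_swap_iters=500, n_replicates=5, seed=1)
        t = res.table
        assert t.a + t.b == res.G and t.c + t.d == res.G
        assert 0 <= res.p_empirical <= 1

    def test_target_outside_family_rejected(self, small_atlas):
        m, ann, truth = small_atlas
        with pytest.raises(AtlasError):
            coexpression_test(m, ann, "c1", truth.target_subcluster,
                              truth.panel_genes, n_swap_iters=10,
                              n_replicates=2, seed=0)
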