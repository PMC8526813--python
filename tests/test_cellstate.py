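"""Per-cell associate counting, state calls, markers, metastasis contrast
and the developmental-potential score."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stromascope import (ExpressionMatrix, classify_state, count_associates,
                         dev_potential, find_markers, metastasis_contrast,
                         potential_vs_activity)
from stromascope.formats import SC_LOGNORM


def _sc(values, genes=None, cells=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cells = cells or [f"c{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=cells),
                            SC_LOGNORM)


def _assoc(roles: dict) -> pd.DataFrame:
    df = pd.DataFrame({"role": pd.Series(roles)})
    df.index.name = "gene"
    return df


class TestCountAssociates:
    def test_all_zero_cell_counts_zero(self):
        m = _sc(np.zeros((4, 3)))
        counts = count_associates(m, _assoc({"g0": "ligand", "g1": "receptor"}))
        assert (counts[["n_ligands", "n_receptors", "n_total"]] == 0).all().all()

    def test_full_expression_counts_role_sizes(self):
        m = _sc(np.ones((4, 2)))
        roles = {"g0": "ligand", "g1": "ligand", "g2": "receptor",
                 "g3": "both"}
        counts = count_associates(m, _assoc(roles))
        assert (counts["n_ligands"] == 3).all()       # both counts as ligand
        assert (counts["n_receptors"] == 2).all()     # and as receptor
        assert (counts["n_total"] == 4).all()         # but once in the total

    def test_random_sparse_matches_bruteforce_scan(self):
        rng = np.random.default_rng(0)
        vals = rng.random((12, 30)) * (rng.random((12, 30)) < 0.3)
        roles = {f"g{i}": ("ligand" if i % 2 else "receptor")
                 for i in range(8)}
        counts = count_associates(_sc(vals), _assoc(roles))
        for j in range(30):
            expected = sum(vals[i, j] > 0 for i in range(8))
            assert counts["n_total"].iloc[j] == expected

    def test_empty_intersection_rejected(self):
        m = _sc(np.ones((2, 2)))
        with pytest.raises(ValueError, match="no associate gene"):
            count_associates(m, _assoc({"absent": "ligand"}))


class TestStateClassification:
    @pytest.mark.parametrize("count,expected", [
        (0, "inactive"), (1, "inactive"),
        (2, "intermediate"), (3, "intermediate"),
        (5, "intermediate"),
        (6, "active"), (10, "active"),
    ])
    def test_strict_default_cutoffs(self, count, expected):
        s = classify_state(pd.Series([count]), active_min=5, inactive_max=2)
        assert s.iloc[0] == expected

    def test_states_partition_cells(self):
        rng = np.random.default_rng(1)
        counts = pd.Series(rng.integers(0, 12, size=200))
        states = classify_state(counts)
        assert states.isin(["active", "inactive", "intermediate"]).all()
        assert len(states) == 200

    def test_inverted_cutoffs_rejected(self):
        with pytest.raises(ValueError, match="inactive_max"):
            classify_state(pd.Series([1]), active_min=2, inactive_max=5)


class TestMarkers:
    def _states(self, n_active, n_inactive):
        return pd.Series(["active"] * n_active + ["inactive"] * n_inactive,
                         index=[f"c{j}" for j in range(n_active + n_inactive)])

    def test_identical_distributions_no_markers(self):
        rng = np.random.default_rng(2)
        block = rng.random((10, 25))
        m = _sc(np.hstack([block, block]))
        res = find_markers(m, self._states(25, 25))
        assert res["marker"].sum() == 0

    def test_active_only_gene_is_marker(self):
        rng = np.random.default_rng(3)
        vals = rng.random((5, 100)) + 0.1
        vals[0, 50:] = 0.0  # gene g0 silent in inactive cells
        res = find_markers(_sc(vals), self._states(50, 50))
        assert bool(res.loc["g0", "marker"])

    def test_matches_independent_ranksum_oracle(self):
        """Planted shifts: the marker p-values equal a per-gene scipy
        rank-sum computed independently, after identical BH adjustment."""
        rng = np.random.default_rng(4)
        vals = np.abs(rng.normal(1, 0.5, size=(20, 60)))
        vals[:5, :30] += 1.5  # upregulated in active cells
        states = self._states(30, 30)
        res = find_markers(_sc(vals), states)
        from statsmodels.stats.multitest import multipletests
        pvals = [stats.mannwhitneyu(vals[i, :30], vals[i, 30:],
                                    alternative="two-sided").pvalue
                 for i in range(20)]
        padj = multipletests(pvals, method="fdr_bh")[1]
        np.testing.assert_allclose(res["p"].to_numpy(), pvals, rtol=1e-10)
        np.testing.assert_allclose(res["p_adj"].to_numpy(), padj, rtol=1e-10)
        assert set(res.index[res["marker"]]) >= {f"g{i}" for i in range(5)}

    def test_shuffled_labels_false_positive_control(self):
        rng = np.random.default_rng(5)
        vals = np.abs(rng.normal(1, 0.5, size=(200, 80)))
        states = self._states(40, 40)
        shuffled = pd.Series(rng.permutation(states.to_numpy()),
                             index=states.index)
        res = find_markers(_sc(vals), shuffled)
        assert res["marker"].sum() <= 5  # BH at 5% over a global null

    def test_low_detection_genes_untested(self):
        vals = np.zeros((3, 400))
        vals[0] = 1.0
        vals[1, 0] = vals[1, 200] = 1.0  # 0.5% in each state -> skipped
        vals[2, ::2] = 1.0
        res = find_markers(_sc(vals), self._states(200, 200))
        assert "g1" not in res.index

    def test_missing_state_rejected(self):
        m = _sc(np.ones((3, 6)))
        with pytest.raises(ValueError, match="at least 3"):
            find_markers(m, pd.Series(["active"] * 6,
                                      index=[f"c{j}" for j in range(6)]))


class TestMetastasisContrast:
    def _setup(self, shift):
        rng = np.random.default_rng(6)
        n = 60
        counts = pd.DataFrame({
            "n_total": np.concatenate([
                rng.integers(0, 6, n), rng.integers(0, 6, n) + shift])},
            index=[f"c{j}" for j in range(2 * n)])
        ann = pd.DataFrame({
            "tumour_id": ["t1"] * 30 + ["t2"] * 30 + ["t3"] * 30 + ["t4"] * 30,
            "metastasis": [False] * n + [True] * n,
        }, index=counts.index)
        return counts, ann

    def test_identical_distributions_nonsignificant(self):
        counts, ann = self._setup(0)
        res = metastasis_contrast(counts, ann)
        assert abs(res["difference"]) < 0.5
        assert res["p_value"] > 0.05

    def test_planted_shift_detected_with_direction(self):
        counts, ann = self._setup(3)
        res = metastasis_contrast(counts, ann)
        assert res["difference"] > 2
        assert res["p_value"] < 0.001
        per = res["per_tumour_means"]
        assert set(per["tumour_id"]) == {"t1", "t2", "t3", "t4"}

    def test_single_class_rejected(self):
        counts, ann = self._setup(0)
        ann["metastasis"] = True
        with pytest.raises(ValueError, match="non-metastatic"):
            metastasis_contrast(counts, ann)


class TestDevPotential:
    def test_nested_expression_chain_monotone(self):
        """Cells expressing nested supersets of genes: potential strictly
        increases along the chain."""
        n_cells, n_genes = 12, 15
        vals = np.zeros((n_genes, n_cells))
        for j in range(n_cells):
            vals[:j + 2, j] = 1.0 + 0.05 * j  # nested sets, graded level
        pot = dev_potential(_sc(vals), top_k=n_genes)
        assert (np.diff(pot.to_numpy()) > 0).all()

    def test_degenerate_uniform_expression_rank_scaled_counts(self):
        """With binary uniform expression and top_k = all genes, the score
        reduces to the rank-rescaled detected-gene count."""
        rng = np.random.default_rng(7)
        vals = (rng.random((20, 15)) < np.linspace(0.2, 0.9, 15)).astype(float)
        m = _sc(vals)
        pot = dev_potential(m, top_k=20)
        gene_counts = (vals > 0).sum(axis=0)
        rho = stats.spearmanr(pot, gene_counts).statistic
        assert rho > 0.95

    def test_constant_gene_counts_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            dev_potential(_sc(np.ones((5, 12))))

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError, match="10 cells"):
            dev_potential(_sc(np.eye(8)))

    def test_bounded_and_rank_invariant(self):
        rng = np.random.default_rng(8)
        vals = np.abs(rng.normal(0, 1, size=(30, 40))) * \
            (rng.random((30, 40)) < 0.5)
        pot = dev_potential(_sc(vals), top_k=10)
        assert ((pot >= 0) & (pot <= 1)).all()
        assert pot.min() == 0.0 and pot.max() == 1.0


class TestPotentialVsActivity:
    def test_identity_gives_r_one(self):
        idx = [f"c{j}" for j in range(20)]
        x = pd.Series(np.arange(20, dtype=float), index=idx)
        counts = pd.DataFrame({"n_total": np.arange(20)}, index=idx)
        res = potential_vs_activity(x, counts)
        assert res["r"] == pytest.approx(1.0)
        assert set(res["by_count_bin"].index) == {"<2", "2-5", ">5"}

    def test_independent_inputs_near_zero(self):
        rng = np.random.default_rng(9)
        idx = [f"c{j}" for j in range(300)]
        pot = pd.Series(rng.random(300), index=idx)
        counts = pd.DataFrame({"n_total": rng.integers(0, 10, 300)}, index=idx)
        res = potential_vs_activity(pot, counts)
        assert abs(res["r"]) < 0.15

    def test_bin_summary_partitions_cells(self):
        idx = [f"c{j}" for j in range(30)]
        pot = pd.Series(np.linspace(0, 1, 30), index=idx)
        counts = pd.DataFrame({"n_total": list(range(10)) * 3}, index=idx)
        res = potential_vs_activity(pot, counts)
        assert res["by_count_bin"]["count"].sum() == 30
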