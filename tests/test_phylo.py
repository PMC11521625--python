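"""Phylogenetic covariance, lambda machinery and GLS allometry."""

import numpy as np
import pandas as pd
import pytest

from allomorph.io import read_newick
from allomorph.phylo import (
    PhylogeneticAllometry,
    bm_covariance,
    estimate_lambda,
    lambda_transform,
    pgls_fit,
    prune_tree,
    rescale_tree,
)
from allomorph.allometry import ShapeAllometry
from allomorph.simulate import (
    simulate_evolutionary_dataset,
    simulate_tree,
)

THREE_TIP = "((A:1,B:1):1,C:2);"


class TestPrune:
    def test_path_length_conservation(self):
        tree = read_newick(THREE_TIP)
        pruned = prune_tree(tree, ["A", "C"])
        assert set(pruned.tip_names) == {"A", "C"}
        d = pruned.root_distances()
        assert d["A"] == pytest.approx(2.0)
        assert d["C"] == pytest.approx(2.0)

    def test_keep_all_is_identity(self):
        tree = read_newick(THREE_TIP)
        pruned = prune_tree(tree, ["A", "B", "C"])
        assert set(pruned.tip_names) == {"A", "B", "C"}
        assert pruned.root_distances() == tree.root_distances()

    def test_unknown_tip_listed_in_error(self):
        tree = read_newick(THREE_TIP)
        with pytest.raises(ValueError, match="ghost"):
            prune_tree(tree, ["A", "ghost"])

    def test_subset_count_from_219_tip_tree(self):
        tree = simulate_tree(219, seed=5)
        keep = sorted(tree.tip_names)[:57]
        pruned = prune_tree(tree, keep)
        assert pruned.n_tips == 57
        # depths preserved for kept tips
        before = tree.root_distances()
        after = pruned.root_distances()
        for name in keep[:5]:
            assert after[name] == pytest.approx(before[name], abs=1e-12)


class TestBMCovariance:
    def test_star_tree_identity(self):
        cov = bm_covariance(read_newick("(A:1,B:1,C:1,D:1);"))
        np.testing.assert_allclose(cov.matrix, np.eye(4), atol=1e-12)

    def test_three_tip_example(self):
        cov = bm_covariance(read_newick(THREE_TIP))
        order = cov.tip_order
        m = pd.DataFrame(cov.matrix, index=order, columns=order)
        assert m.loc["A", "A"] == pytest.approx(2.0)
        assert m.loc["A", "B"] == pytest.approx(1.0)
        assert m.loc["A", "C"] == pytest.approx(0.0)
        assert m.loc["C", "C"] == pytest.approx(2.0)

    def test_matches_path_enumeration_oracle(self):
        """Each entry equals the summed edge lengths from root to the MRCA,
        found by explicitly intersecting root-to-tip node paths."""
        tree = simulate_tree(10, seed=11)
        cov = bm_covariance(tree)

        dtree = tree.tree
        paths = {}
        for leaf in dtree.leaf_node_iter():
            node, path = leaf, []
            while node is not None:
                path.append(node)
                node = node.parent_node
            paths[leaf.taxon.label] = list(reversed(path))
        oracle = np.zeros_like(cov.matrix)
        for i, a in enumerate(cov.tip_order):
            for j, b in enumerate(cov.tip_order):
                shared = 0.0
                for na, nb in zip(paths[a], paths[b]):
                    if na is not nb:
                        break
                    if na.parent_node is not None:
                        shared += na.edge.length
                oracle[i, j] = shared
        np.testing.assert_allclose(cov.matrix, oracle, atol=1e-12)


class TestLambdaTransform:
    def test_identity_at_one(self):
        cov = bm_covariance(read_newick(THREE_TIP))
        np.testing.assert_allclose(lambda_transform(cov, 1.0).matrix, cov.matrix)

    def test_star_structure_at_zero(self):
        cov = bm_covariance(read_newick(THREE_TIP))
        out = lambda_transform(cov, 0.0).matrix
        np.testing.assert_allclose(out, np.diag(np.diag(cov.matrix)))

    def test_half_scales_offdiagonals_only(self):
        cov = bm_covariance(read_newick(THREE_TIP))
        out = lambda_transform(cov, 0.5)
        m = pd.DataFrame(out.matrix, index=out.tip_order, columns=out.tip_order)
        assert m.loc["A", "B"] == pytest.approx(0.5)
        assert m.loc["A", "A"] == pytest.approx(2.0)

    def test_out_of_range_rejected(self):
        cov = bm_covariance(read_newick(THREE_TIP))
        with pytest.raises(ValueError):
            lambda_transform(cov, 1.2)


class TestRescaleTree:
    @pytest.mark.parametrize("lam", [0.0, 0.37, 1.0])
    def test_covariance_commutes_with_branch_rescaling(self, lam):
        tree = simulate_tree(12, seed=2)
        direct = lambda_transform(bm_covariance(tree), lam)
        via_tree = bm_covariance(rescale_tree(tree, lam))
        np.testing.assert_allclose(via_tree.matrix, direct.matrix, atol=1e-10)

    def test_unit_lambda_preserves_newick_lengths(self):
        tree = read_newick(THREE_TIP)
        out = rescale_tree(tree, 1.0)
        assert out.root_distances() == tree.root_distances()


class TestEstimateLambda:
    def test_grid_oracle_single_column(self):
        """Bounded search agrees with a dense grid over an independently
        coded GLS profile likelihood (slogdet + explicit GLS mean)."""
        tree = simulate_tree(6, seed=4)
        cov = bm_covariance(tree)
        rng = np.random.default_rng(8)
        chol = np.linalg.cholesky(cov.matrix + 1e-9 * np.eye(6))
        y = (chol @ rng.standard_normal(6))[:, None]

        def oracle_ll(lam):
            c = cov.matrix * lam
            np.fill_diagonal(c, np.diag(cov.matrix))
            s = len(c)
            sign, logdet = np.linalg.slogdet(c)
            ci = np.linalg.inv(c)
            one = np.ones(s)
            mu = (one @ ci @ y[:, 0]) / (one @ ci @ one)
            r = y[:, 0] - mu
            sigma2 = (r @ ci @ r) / s
            return -0.5 * (s * np.log(2 * np.pi * sigma2) + logdet + s)

        grid = np.linspace(0, 1, 10001)
        lls = [oracle_ll(g) for g in grid]
        lam_grid = grid[int(np.argmax(lls))]

        est = estimate_lambda(y, tree)
        assert est.lam == pytest.approx(lam_grid, abs=2e-4)
        assert est.log_likelihood >= max(est.log_likelihood_bounds) - 1e-9

    def test_optimum_at_least_as_likely_as_bounds(self):
        tree = simulate_tree(16, seed=9)
        scores = np.random.default_rng(3).standard_normal((16, 4))
        est = estimate_lambda(scores, tree)
        assert est.log_likelihood >= est.log_likelihood_bounds[0] - 1e-9
        assert est.log_likelihood >= est.log_likelihood_bounds[1] - 1e-9
        assert 0.0 <= est.lam <= 1.0

    def test_recovery_at_bounds_small(self):
        """Brownian data pulls lambda-hat up; iid noise pulls it to zero."""
        tree = simulate_tree(48, seed=1)
        cov = bm_covariance(tree)
        chol = np.linalg.cholesky(cov.matrix + 1e-9 * np.eye(48))
        rng = np.random.default_rng(10)
        bm_hats, iid_hats = [], []
        for _ in range(5):
            bm_scores = chol @ rng.standard_normal((48, 5))
            iid_scores = rng.standard_normal((48, 5))
            bm_hats.append(estimate_lambda(bm_scores, tree, cov=cov).lam)
            iid_hats.append(estimate_lambda(iid_scores, tree, cov=cov).lam)
        assert np.mean(bm_hats) >= 0.85
        assert np.mean(iid_hats) <= 0.15


class TestPGLS:
    def test_star_tree_equals_ols(self):
        star = read_newick("(" + ",".join(f"t{i}:1" for i in range(12)) + ");")
        rng = np.random.default_rng(6)
        lcs = rng.uniform(0, 3, 12)
        y = np.outer(lcs, rng.normal(size=6)) + 0.05 * rng.normal(size=(12, 6))
        species = [f"t{i}" for i in range(12)]
        model = PhylogeneticAllometry(y, star, lcs=lcs, species=species, lam=1.0)
        gls = model.fit(permutations=9, seed=0)
        ols = ShapeAllometry(y, lcs).fit(permutations=9, seed=0)
        np.testing.assert_allclose(gls.coefficients, ols.coefficients, atol=1e-10)
        np.testing.assert_allclose(
            gls.anova.table[["Df", "SS", "Rsq", "F"]].to_numpy(float),
            ols.anova.table[["Df", "SS", "Rsq", "F"]].to_numpy(float),
            atol=1e-8,
            equal_nan=True,
        )

    def test_coefficients_match_gls_oracle(self):
        tree = simulate_tree(15, seed=3)
        rng = np.random.default_rng(1)
        species = sorted(tree.tip_names)
        lcs = rng.uniform(0, 3, 15)
        y = rng.normal(size=(15, 4))
        fit = PhylogeneticAllometry(y, tree, lcs=lcs, species=species, lam=1.0).fit(
            permutations=1, seed=0
        )
        c = bm_covariance(tree).matrix
        ci = np.linalg.inv(c)
        x = np.column_stack([np.ones(15), lcs])
        beta_oracle = np.linalg.solve(x.T @ ci @ x, x.T @ ci @ y)
        np.testing.assert_allclose(fit.coefficients, beta_oracle, atol=1e-10)

    def test_single_term_type2_equals_sequential(self):
        tree = simulate_tree(10, seed=7)
        data, _ = simulate_evolutionary_dataset(
            tree, slope=np.random.default_rng(0).normal(size=9), seed=2
        )
        fit = pgls_fit(data, tree, lam=1.0, permutations=19, seed=4)
        tab = fit.anova.table.set_index("term")
        # single-term: SS(model) + SS(res) = SS(total)
        assert tab.loc["LCS", "SS"] + tab.loc["residuals", "SS"] == pytest.approx(
            tab.loc["total", "SS"], rel=1e-9
        )

    def test_missing_species_is_hard_error(self):
        tree = simulate_tree(8, seed=1)
        y = np.zeros((3, 6))
        with pytest.raises(ValueError, match="missing from tree"):
            PhylogeneticAllometry(
                y, tree, lcs=np.r_[0.0, 1.0, 2.0], species=["x1", "x2", "x3"]
            )

    def test_two_group_slope_recovery(self):
        """Planted group slopes are recovered by the GLS interaction model."""
        tree = simulate_tree(64, seed=21)
        rng = np.random.default_rng(2)
        p = 6
        slope_a = rng.normal(size=p)
        slope_b = slope_a + 0.5 * rng.normal(size=p)
        data, _ = simulate_evolutionary_dataset(
            tree, slope_a, sigma_bm=0.01, seed=3,
            group_sizes={"ga": 32, "gb": 32},
        )
        mask_b = (data.specimens["group"] == "gb").to_numpy()
        y = data.flat.copy()
        y[mask_b] += np.outer(
            data.log_centroid_size[mask_b], slope_b - slope_a
        )
        fit = PhylogeneticAllometry(
            y,
            tree,
            lcs=data.log_centroid_size,
            species=list(data.specimens["species"]),
            groups=data.specimens["group"].to_numpy(),
            lam=1.0,
        ).fit(permutations=9, seed=5)
        # coefficient rows: intercept, LCS, group, LCS:group
        est_a = fit.coefficients[1]
        est_b = fit.coefficients[1] + fit.coefficients[3]
        assert np.linalg.norm(est_a - slope_a) < 0.05
        assert np.linalg.norm(est_b - slope_b) < 0.05
        tab = fit.anova.table.set_index("term")
        assert list(tab.index) == ["LCS", "group", "LCS:group", "residuals", "total"]
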