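"""Broken stick, PERMANOVA, disparity, z-scores, PGLS."""

import numpy as np
import pandas as pd
import pytest

import osteomorph as om
from osteomorph.pipeline import read_tree_from_string
from osteomorph.stats import (AliasedTermError, DisparityIndices, _gls_loglik,
                              _lambda_cov, pgls_fit, permanova)
from osteomorph.trees import phylo_covariance


class TestBrokenStick:
    def test_closed_form_small_cases(self):
        # p=3, proportions (0.7, 0.2, 0.1); b = (0.6111, 0.2778, 0.1111)
        assert om.broken_stick(np.array([0.7, 0.2, 0.1])) == 1
        assert om.broken_stick(np.array([0.99, 0.01])) == 1
        assert om.broken_stick(np.ones(4) / 4) == 0

    @pytest.mark.parametrize("p", [2, 5, 17, 50])
    def test_matches_brute_force_enumeration(self, p):
        rng = np.random.default_rng(p)
        eig = np.sort(rng.exponential(1.0, p))[::-1]
        props = eig / eig.sum()
        b = [sum(1.0 / i for i in range(k, p + 1)) / p for k in range(1, p + 1)]
        expected = 0
        for k in range(p):
            if props[k] > b[k]:
                expected += 1
            else:
                break
        assert om.broken_stick(eig) == expected

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            om.broken_stick(np.zeros(3))
        with pytest.raises(ValueError):
            om.broken_stick(np.array([1.0]))

    def test_retain_axes_skips_exclusions(self):
        eig = np.array([5.0, 2.0, 1.0, 0.2, 0.1])
        base = om.retain_axes(eig)
        excl = om.retain_axes(eig, excluded_pcs=[2])
        assert 1 not in excl
        assert len(excl) == len(base)


class TestZscore:
    def test_standardization(self):
        rng = np.random.default_rng(0)
        X = rng.normal(5, 3, (40, 4))
        Z = om.zscore(X)
        assert np.abs(Z.mean(axis=0)).max() < 1e-12
        np.testing.assert_allclose(Z.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (20, 3))
        np.testing.assert_allclose(om.zscore(X), om.zscore(X * 7.5 - 3.0),
                                   atol=1e-10)

    def test_constant_axis_dropped_single_row_rejected(self):
        X = np.column_stack([np.arange(10.0), np.ones(10)])
        with pytest.warns(UserWarning, match="constant"):
            Z = om.zscore(X)
        assert Z.shape == (10, 1)
        with pytest.raises(ValueError):
            om.zscore(np.ones((1, 3)))


class TestPermanova:
    @pytest.fixture(scope="class")
    def toy(self):
        rng = np.random.default_rng(42)
        n = 24
        design = pd.DataFrame({
            "strategy": np.repeat(["pelvic", "transfer"], n // 2),
            "sex": np.tile(np.repeat(["female", "male"], n // 4), 2),
            "species": np.repeat([f"sp{i}" for i in range(6)], 4),
            "standard_length": rng.uniform(25, 45, n).round(3),
        })
        scores = rng.standard_normal((n, 4))
        scores[design.strategy == "pelvic", 0] += 1.5
        return scores, design

    def test_type_i_decomposition_exact(self, toy):
        scores, design = toy
        tab = permanova(scores, design, n_perm=99, seed=0)
        total = sum(tab.ss.values()) + tab.residual_ss
        assert total == pytest.approx(tab.total_ss, rel=1e-12)
        assert all(0 <= v <= 1 for v in tab.r2.values())
        assert tab.df["species"] == 4  # 6 species, strategy nested

    def test_seed_reproducible(self, toy):
        scores, design = toy
        a = permanova(scores, design, n_perm=199, seed=5)
        b = permanova(scores, design, n_perm=199, seed=5)
        assert a.p == b.p

    def test_p_floor_and_bounds(self, toy):
        scores, design = toy
        strong = scores.copy()
        strong[design.strategy == "pelvic"] += 100
        tab = permanova(strong, design, terms=["strategy"], n_perm=9999, seed=1)
        assert tab.p["strategy"] == pytest.approx(1 / 10000)
        for p in tab.p.values():
            assert 1 / 10000 <= p <= 1

    def test_null_term_r2_near_zero(self):
        rng = np.random.default_rng(3)
        design = pd.DataFrame({"strategy": rng.permutation(
            np.repeat(["a", "b"], 15))})
        scores = rng.standard_normal((30, 3))
        tab = permanova(scores, design, terms=["strategy"], n_perm=499, seed=2)
        assert tab.r2["strategy"] < 0.15
        assert tab.p["strategy"] > 0.01

    def test_aliased_order_refused(self, toy):
        scores, design = toy
        with pytest.raises(AliasedTermError, match="strategy"):
            permanova(scores, design, terms=["species", "strategy"],
                      n_perm=49, seed=0)

    def test_matches_vegan_adonis2(self, toy, tmp_path):
        """Independent oracle: R vegan's adonis2 on the same data."""
        import shutil
        import subprocess
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        scores, design = toy
        df = pd.concat([design, pd.DataFrame(scores, columns=list("wxyz"))],
                       axis=1)
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        rfile = tmp_path / "oracle.R"
        rfile.write_text(f"""
suppressMessages(library(vegan))
d <- read.csv("{csv}")
Y <- as.matrix(d[, c("w","x","y","z")])
res <- adonis2(Y ~ strategy + sex + species + standard_length, data=d,
               permutations=99, method="euclidean", by="terms")
write.csv(data.frame(ss=res$SumOfSqs, f=res$F), "{tmp_path}/out.csv")
""")
        subprocess.run(["Rscript", str(rfile)], check=True,
                       capture_output=True)
        out = pd.read_csv(tmp_path / "out.csv")
        tab = permanova(scores, design,
                        terms=["strategy", "sex", "species", "standard_length"],
                        n_perm=49, seed=0)
        for i, t in enumerate(tab.terms):
            assert tab.ss[t] == pytest.approx(out.ss[i], rel=1e-8)
            assert tab.f[t] == pytest.approx(out.f[i], rel=1e-8)
        assert tab.residual_ss == pytest.approx(out.ss[4], rel=1e-8)


class TestDisparity:
    def test_unit_square_closed_form(self):
        sq = np.array([[0.0, 0], [1, 0], [1, 1], [0, 1]])
        ind = om.disparity_indices(sq, ["g"] * 4, n_boot=0)
        assert ind.ranges["g"] == 2.0
        assert ind.hull["g"] == 4.0  # perimeter

    def test_unit_cube_closed_form(self):
        corners = np.array([[x, y, z] for x in (0, 1) for y in (0, 1)
                            for z in (0, 1)], dtype=float)
        ind = om.disparity_indices(corners, ["g"] * 8, n_boot=0)
        assert ind.ranges["g"] == 3.0
        assert ind.hull["g"] == 6.0  # surface area

    def test_degenerate_coplanar_affine_span(self):
        sq = np.array([[0.0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]])
        ind = om.disparity_indices(sq, ["g"] * 4, n_boot=0)
        assert ind.hull_dim["g"] == 2
        assert ind.hull["g"] == pytest.approx(4.0)

    def test_bootstrap_median_bounded_by_full_sample(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((40, 3))
        ind = om.disparity_indices(X, ["g"] * 40, n_boot=500, seed=1)
        assert np.median(ind.boot_ranges["g"]) <= ind.ranges["g"]
        assert ind.boot_ranges["g"].max() <= ind.ranges["g"] + 1e-12

    def test_ttests_identical_and_shifted(self):
        rng = np.random.default_rng(2)
        base = rng.normal(10, 1, 5000)
        ind = DisparityIndices(
            groups=["a", "b", "c"], ranges={}, hull={},
            boot_ranges={"a": base, "b": base.copy(),
                         "c": base + 2 * base.std()},
            boot_hull={})
        table = om.disparity_ttests(ind, "ranges")
        assert len(table) == 3  # Bonferroni factor 3
        ab = table[(table.group_a == "a") & (table.group_b == "b")].iloc[0]
        assert abs(ab.t) < 1e-9 and ab.p_bonferroni == 1.0
        ac = table[(table.group_a == "a") & (table.group_b == "c")].iloc[0]
        assert ac.p_bonferroni < 0.001


class TestPGLS:
    @pytest.fixture(scope="class")
    def tree_cov(self):
        tree = read_tree_from_string(om.default_tree_newick())
        return phylo_covariance(tree)

    def test_star_tree_equals_ols(self):
        star = read_tree_from_string(
            "(A:1,B:1,C:1,D:1,E:1,F:1,G:1,H:1);")
        C, taxa = phylo_covariance(star)
        rng = np.random.default_rng(0)
        y = rng.standard_normal(8)
        X = np.column_stack([np.ones(8), rng.uniform(0, 1, 8)])
        beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
        for lam in (0.0, 0.37, 1.0):
            ll, beta, *_ = _gls_loglik(y, X, _lambda_cov(C, lam))
            np.testing.assert_allclose(beta, beta_ols, atol=1e-8)

    def test_lambda_zero_fit_is_ols_for_ultrametric(self, tree_cov):
        C, taxa = tree_cov
        rng = np.random.default_rng(1)
        y = rng.standard_normal(8)
        X = np.column_stack([np.ones(8), rng.uniform(0, 1, 8)])
        _, beta, *_ = _gls_loglik(y, X, _lambda_cov(C, 0.0))
        beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(beta, beta_ols, atol=1e-8)

    def test_optimizer_sanity(self, tree_cov):
        C, taxa = tree_cov
        rng = np.random.default_rng(2)
        L = np.linalg.cholesky(C + 1e-12 * np.eye(8))
        y = L @ rng.standard_normal(8)
        X = np.column_stack([np.ones(8), rng.uniform(25, 45, 8)])
        fit = pgls_fit(y, X, C, lambda_policy="ml")
        ll_hat = _gls_loglik(y, X, _lambda_cov(C, fit.lambda_ml), reml=True)[0]
        for lam in (0.0, 1.0):
            assert ll_hat >= _gls_loglik(y, X, _lambda_cov(C, lam),
                                         reml=True)[0] - 1e-9

    def test_policy_resets_lambda_to_one(self, tree_cov):
        C, taxa = tree_cov
        rng = np.random.default_rng(3)
        L = np.linalg.cholesky(C + 1e-12 * np.eye(8))
        y = L @ rng.standard_normal(8)          # true lambda = 1
        X = np.column_stack([np.ones(8), rng.uniform(25, 45, 8)])
        fit = pgls_fit(y, X, C, lambda_policy="reset-to-1")
        if fit.lrt_p_vs_1 > 0.05:
            assert fit.lambda_used == 1.0
        assert 0 <= fit.lambda_ml <= 1

    def test_matches_nlme_gls_at_fixed_lambda(self, tree_cov, tmp_path):
        """Independent oracle: ape corPagel + nlme gls, ML, fixed lambda."""
        import shutil
        import subprocess
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        C, taxa = tree_cov
        rng = np.random.default_rng(3)
        L = np.linalg.cholesky(C + 1e-10 * np.eye(8))
        y = L @ rng.standard_normal(8) * 0.8
        x = rng.uniform(25, 45, 8)
        strat = np.array([0, 0, 0, 0, 0, 1, 1, 1], float)
        X = np.column_stack([np.ones(8), strat, x])
        pd.DataFrame(dict(species=taxa, y=y, sl=x, strat=strat)).to_csv(
            tmp_path / "d.csv", index=False)
        (tmp_path / "t.nwk").write_text(om.default_tree_newick())
        rfile = tmp_path / "oracle.R"
        rfile.write_text(f"""
suppressMessages({{library(ape); library(nlme)}})
tr <- read.tree("{tmp_path}/t.nwk")
d <- read.csv("{tmp_path}/d.csv"); rownames(d) <- d$species
out <- NULL
for (lam in c(0, 0.5, 1)) {{
  fit <- gls(y ~ strat + sl, data=d,
             correlation=corPagel(lam, tr, form=~species, fixed=TRUE),
             method="ML")
  out <- rbind(out, c(lam, logLik(fit), coef(fit)))
}}
write.csv(as.data.frame(out), "{tmp_path}/out.csv", row.names=FALSE)
""")
        subprocess.run(["Rscript", str(rfile)], check=True,
                       capture_output=True)
        out = pd.read_csv(tmp_path / "out.csv")
        for i, lam in enumerate((0.0, 0.5, 1.0)):
            ll, beta, *_ = _gls_loglik(y, X, _lambda_cov(C, lam))
            assert ll == pytest.approx(out.iloc[i, 1], abs=1e-6)
            np.testing.assert_allclose(beta, out.iloc[i, 2:5].to_numpy(),
                                       atol=1e-6)

    def test_pgls_wrapper_shapes(self, tree_cov):
        C, taxa = tree_cov
        rng = np.random.default_rng(4)
        df = pd.DataFrame(
            {"PC1": rng.standard_normal(8), "PC2": rng.standard_normal(8),
             "strategy_pelvic": [0, 0, 0, 0, 0, 1, 1, 1],
             "standard_length": rng.uniform(25, 45, 8)},
            index=taxa)
        from osteomorph.stats import pgls
        res = pgls(df, C, taxa, response_cols=["PC1", "PC2"])
        frame = res.to_frame()
        assert set(frame.model) == {"PC1", "PC2"}
        assert ((0 <= frame.lambda_ml) & (frame.lambda_ml <= 1)).all()
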