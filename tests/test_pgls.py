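import numpy as np
import pytest

import longsel as ls
from longsel.pgls import gls_fit_dense
from longsel.scoring import MutationRates, ScoredColumn


def random_instance(rng, n=8):
    """A random valid PGLS problem on a random ultrametric tree."""
    tree = ls.simulate_tree(n, 1.0, int(rng.integers(1 << 30)))
    species = sorted(tree.tip_labels())
    cov = ls.brownian_covariance(tree, species, 1.0)
    y = rng.normal(size=n)
    X = rng.normal(size=(n, 2))
    return y, X, cov


class TestBrownianCovariance:
    def test_star_tree_is_diagonal(self, star_tree):
        cov = ls.brownian_covariance(star_tree, ["A", "B", "C", "D"], 1.0)
        np.testing.assert_allclose(cov.matrix, 2.0 * np.eye(4))

    def test_three_tip_values(self, three_tip_tree):
        cov = ls.brownian_covariance(three_tip_tree, ["A", "B", "C"], 1.0)
        expect = np.array([[2.0, 1.0, 0.0], [1.0, 2.0, 0.0], [0.0, 0.0, 2.0]])
        np.testing.assert_allclose(cov.matrix, expect)

    def test_prune_equals_submatrix(self, three_tip_tree):
        full = ls.brownian_covariance(three_tip_tree, ["A", "B", "C"], 1.0)
        pruned = ls.brownian_covariance(three_tip_tree, ["A", "B"], 1.0)
        np.testing.assert_allclose(pruned.matrix, full.matrix[:2, :2])

    def test_lambda_scales_off_diagonal_only(self, three_tip_tree):
        cov = ls.brownian_covariance(three_tip_tree, ["A", "B", "C"], 0.5)
        assert cov.matrix[0, 1] == pytest.approx(0.5)
        assert cov.matrix[0, 0] == pytest.approx(2.0)

    def test_unknown_species_rejected(self, three_tip_tree):
        with pytest.raises(ls.LongselError):
            ls.brownian_covariance(three_tip_tree, ["A", "Z"], 1.0)


class TestGlsFit:
    def test_identity_covariance_equals_ols(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        n = 12
        y = rng.normal(size=n)
        X = rng.normal(size=(n, 2))
        cov = ls.BrownianCovariance([f"s{i}" for i in range(n)], np.eye(n))
        fit = ls.gls_fit(y, X, cov)
        ref = sm.OLS(y, sm.add_constant(X)).fit()
        np.testing.assert_allclose(fit.coef, ref.params, atol=1e-12)
        np.testing.assert_allclose(fit.se, ref.bse, atol=1e-12)
        np.testing.assert_allclose(fit.pvalues, ref.pvalues, atol=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_whitened_matches_dense_inverse(self, seed):
        rng = np.random.default_rng(seed)
        y, X, cov = random_instance(rng)
        a = ls.gls_fit(y, X, cov)
        b = gls_fit_dense(y, X, cov)
        np.testing.assert_allclose(a.coef, b.coef, atol=1e-10)
        np.testing.assert_allclose(a.se, b.se, atol=1e-10)
        np.testing.assert_allclose(a.pvalues, b.pvalues, atol=1e-10)

    def test_matches_r_nlme_gls_brownian(self):
        """Frozen reference fit from R (ape + nlme, corBrownian)."""
        tree = ls.PhylogeneticTree.from_newick(
            "(((A:1,B:1):1,(C:1.5,D:1.5):0.5):1,(E:2.5,F:2.5):0.5);", "time"
        )
        y = np.array([0.1257302210933933, -0.1321048632913019,
                      0.6404226504432821, 0.10490011715303971,
                      -0.535669373161111, 0.36159505490948474])
        x1 = np.array([1.3040000451301372, 0.9470809631292422,
                       -0.7037352358069926, -1.2654214710460525,
                       -0.6232744625373522, 0.0413259793472436])
        x2 = np.array([-2.3250307746388343, -0.21879166393254573,
                       -1.2459109472530652, -0.7322673547034516,
                       -0.5442589828573099, -0.31630015636915454])
        cov = ls.brownian_covariance(tree, list("ABCDEF"), 1.0)
        fit = ls.gls_fit(y, np.column_stack([x1, x2]), cov)
        np.testing.assert_allclose(
            fit.coef,
            [-0.0691789269396676, -0.0581386300825928, -0.15419754499812],
            rtol=1e-9,
        )
        np.testing.assert_allclose(
            fit.se, [0.35199797531546, 0.248201965733123, 0.216928621361109],
            rtol=1e-9,
        )
        np.testing.assert_allclose(
            fit.pvalues,
            [0.856754030384757, 0.829875078927567, 0.528474505607092],
            rtol=1e-9,
        )

    def test_exact_linear_response_recovers_slope(self, star_tree):
        cov = ls.brownian_covariance(star_tree, ["A", "B", "C", "D"], 1.0)
        X = np.array([[1.0, 0.3], [2.0, -0.4], [3.0, 0.9], [4.0, 0.1]])
        y = 2.0 + 1.5 * X[:, 0] - 0.7 * X[:, 1]
        fit = ls.gls_fit(y, X, cov)
        np.testing.assert_allclose(fit.coef, [2.0, 1.5, -0.7], atol=1e-9)
        assert fit.degenerate
        assert fit.p_mls == 0.0

    def test_constant_response_is_flat(self, star_tree):
        cov = ls.brownian_covariance(star_tree, ["A", "B", "C", "D"], 1.0)
        X = np.arange(8.0).reshape(4, 2)
        fit = ls.gls_fit(np.full(4, 3.0), X, cov)
        assert fit.degenerate
        assert fit.b_mls == 0.0 and fit.p_mls == 1.0

    def test_collinear_design_flagged(self, star_tree):
        cov = ls.brownian_covariance(star_tree, ["A", "B", "C", "D"], 1.0)
        x = np.array([1.0, 2.0, 3.0, 4.0])
        fit = ls.gls_fit(np.array([0.1, 0.9, 0.2, 0.8]),
                         np.column_stack([x, 2 * x]), cov)
        assert fit.degenerate
        assert fit.p_mls == 1.0

    def test_lambda_zero_on_ultrametric_equals_ols(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        tree = ls.simulate_tree(8, 1.0, 7)
        species = sorted(tree.tip_labels())
        cov = ls.brownian_covariance(tree, species, 0.0)
        y = rng.normal(size=8)
        X = rng.normal(size=(8, 2))
        fit = ls.gls_fit(y, X, cov)
        ref = sm.OLS(y, sm.add_constant(X)).fit()
        np.testing.assert_allclose(fit.coef, ref.params, atol=1e-10)
        np.testing.assert_allclose(fit.pvalues, ref.pvalues, atol=1e-10)

    def test_nonpositive_definite_rejected(self):
        m = np.eye(4)
        m[0, 1] = m[1, 0] = 2.0  # eigenvalue -1: not a valid covariance
        cov = ls.BrownianCovariance(list("abcd"), m)
        with pytest.raises(ls.LongselError, match="positive definite"):
            ls.gls_fit(np.arange(4.0), np.ones((4, 2)), cov)


class TestFitColumn:
    def make_scored(self, scores, ref="human"):
        rec = ls.ColumnRecord("a", 0, {sp: "A" for sp in scores} | {ref: "A"},
                              "A", "fit")
        return ScoredColumn(rec, scores)

    def traits_tree(self, n=8, seed=2):
        tree = ls.simulate_tree(n, 1.0, seed)
        species = sorted(tree.tip_labels())
        rng = np.random.default_rng(seed)
        rows = {sp: (float(3 + 10 * rng.random()), float(100 + i))
                for i, sp in enumerate(species)}
        rows["human"] = (90.0, 6e4)
        # human is not in the tree: reference exclusion makes this irrelevant
        return ls.TraitTable.from_dict(rows, reference="human"), tree, species

    def test_reference_never_contributes(self):
        traits, tree, species = self.traits_tree()
        scores = {sp: float(i) for i, sp in enumerate(species)}
        scores["human"] = 99.0
        fit = ls.fit_column(self.make_scored(scores), traits, tree)
        assert fit.n == len(species)

    def test_constant_scores_degenerate(self):
        traits, tree, species = self.traits_tree()
        fit = ls.fit_column(
            self.make_scored({sp: 2.0 for sp in species}), traits, tree
        )
        assert fit.degenerate and fit.b_mls == 0.0 and fit.p_mls == 1.0

    def test_too_few_species_degenerate(self):
        traits, tree, species = self.traits_tree()
        fit = ls.fit_column(
            self.make_scored({sp: 1.0 for sp in species[:3]}), traits, tree
        )
        assert fit.degenerate and fit.n == 3

    def test_planted_slope_detected_on_star_tree(self):
        nwk = "(" + ",".join(f"t{i}:1" for i in range(12)) + ");"
        tree = ls.PhylogeneticTree.from_newick(nwk, "time")
        rng = np.random.default_rng(0)
        species = sorted(tree.tip_labels())
        mls = 10 ** rng.uniform(0.5, 2.0, size=12)
        traits = ls.TraitTable.from_dict(
            {sp: (float(m), 1000.0 * (1 + i)) for i, (sp, m) in
             enumerate(zip(species, mls))} | {"human": (90.0, 6e4)},
            reference="human",
        )
        scores = {
            sp: 3.0 * np.log10(traits.mls(sp)) + rng.normal(0, 0.05)
            for sp in species
        }
        fit = ls.fit_column(self.make_scored(scores), traits, tree)
        assert fit.b_mls > 0
        assert fit.p_mls < 0.05

    def test_pvalues_uniform_under_brownian_null(self):
        """True-null responses with tree-structured noise give uniform p."""
        from scipy.stats import kstest

        tree = ls.simulate_tree(15, 1.0, 4)
        species = sorted(tree.tip_labels())
        cov = ls.brownian_covariance(tree, species, 1.0)
        L = np.linalg.cholesky(cov.matrix)
        rng = np.random.default_rng(8)
        X = rng.normal(size=(15, 2))
        ps = [
            ls.gls_fit(L @ rng.normal(size=15), X, cov).p_mls
            for _ in range(2000)
        ]
        stat = kstest(ps, "uniform").statistic
        assert stat < 1.63 / np.sqrt(2000)
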