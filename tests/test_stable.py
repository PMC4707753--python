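"""Stable density, branch scaling and likelihood machinery.

The independent oracle for the numeric density is a direct oscillatory
quadrature of the characteristic-function inversion
(1/pi) * int_0^inf cos(x k) exp(-(s k)^alpha) dk, plus
scipy.stats.levy_stable as a second, externally implemented reference.
"""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import levy_stable, multivariate_normal

from stabletrees import (
    AugmentedState,
    StableParams,
    TimeTree,
    TraitTable,
    augmented_loglik,
    bm_marginal_loglik,
    branch_scale,
    gls_root_mean,
    stable_logpdf,
    stable_pdf,
)


pytestmark = pytest.mark.filterwarnings("ignore::scipy.integrate.IntegrationWarning")


def oracle_pdf(x, alpha, scale=1.0):
    """Characteristic-function inversion by adaptive oscillatory quadrature."""
    val, _ = quad(lambda k: math.exp(-((scale * k) ** alpha)), 0, 80.0 / scale,
                  weight="cos", wvar=abs(x), limit=4000, epsabs=1e-15, epsrel=1e-13)
    return val / math.pi


class TestStablePdf:
    def test_gaussian_closed_form(self):
        assert stable_pdf(0.0, 2.0, 1.0) == pytest.approx(1.0 / math.sqrt(4 * math.pi), rel=1e-12)
        # alpha=2 is Gaussian with variance 2*scale^2
        for x, s in [(0.7, 1.0), (2.0, 0.5), (-3.0, 2.0)]:
            expect = math.exp(-x * x / (4 * s * s)) / math.sqrt(4 * math.pi * s * s)
            assert stable_pdf(x, 2.0, s) == pytest.approx(expect, rel=1e-12)

    def test_cauchy_closed_form(self):
        assert stable_pdf(0.0, 1.0, 1.0) == pytest.approx(1.0 / math.pi, rel=1e-12)
        assert stable_pdf(3.0, 1.0, 2.0) == pytest.approx(2.0 / (math.pi * (4 + 9)), rel=1e-12)

    @pytest.mark.parametrize("alpha", [1.1, 1.5, 1.77, 1.95])
    @pytest.mark.parametrize("x", [0.0, 0.5, 3.0, 10.0, 29.0, 31.0, 50.0])
    def test_numeric_against_quadrature_oracle(self, alpha, x):
        assert stable_pdf(x, alpha, 1.0) == pytest.approx(oracle_pdf(x, alpha), rel=1e-6)

    @pytest.mark.parametrize("alpha,x", [(1.3, 0.7), (1.5, 3.0), (1.77, 12.0)])
    def test_against_scipy_levy_stable(self, alpha, x):
        # scipy's S1 parameterization with beta=0 shares our convention
        assert stable_pdf(x, alpha, 1.0) == pytest.approx(
            levy_stable.pdf(x, alpha, 0.0), rel=2e-5)

    @pytest.mark.parametrize("alpha", [1.1, 1.5, 1.77, 2.0])
    @pytest.mark.parametrize("scale", [0.1, 1.0, 10.0])
    def test_normalization(self, alpha, scale):
        val, _ = quad(lambda x: stable_pdf(x, alpha, scale), -np.inf, np.inf, limit=500)
        assert val == pytest.approx(1.0, abs=1e-4)

    def test_symmetry_exact(self):
        xs = np.array([0.0, 0.3, 1.7, 8.0, 40.0])
        for alpha in (1.2, 1.77, 2.0):
            assert np.array_equal(stable_pdf(xs, alpha, 1.0), stable_pdf(-xs, alpha, 1.0))

    def test_monotone_decreasing_in_abs_x(self):
        xs = np.linspace(0, 45, 400)
        for alpha in (1.1, 1.5, 1.9, 2.0):
            d = stable_pdf(xs, alpha, 1.0)
            assert np.all(np.diff(d) < 0)

    @pytest.mark.parametrize("alpha", [1.15, 1.6, 2.0])
    @pytest.mark.parametrize("scale", [0.25, 3.0])
    def test_scaling_law(self, alpha, scale):
        xs = np.array([0.0, 0.5, 2.0, 11.0])
        lhs = stable_pdf(xs, alpha, scale)
        rhs = stable_pdf(xs / scale, alpha, 1.0) / scale
        np.testing.assert_allclose(lhs, rhs, rtol=1e-9)

    def test_heavier_tails_with_smaller_alpha(self):
        # tail mass beyond 5*scale increases monotonically as alpha drops
        def tail(alpha):
            val, _ = quad(lambda x: stable_pdf(x, alpha, 1.0), 5.0, np.inf, limit=500)
            return val
        masses = [tail(a) for a in (2.0, 1.77, 1.5, 1.3, 1.1)]
        assert all(b > a for a, b in zip(masses, masses[1:]))

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            stable_pdf(0.0, 0.9, 1.0)
        with pytest.raises(ValueError):
            stable_pdf(0.0, 2.1, 1.0)
        with pytest.raises(ValueError):
            stable_pdf(0.0, 1.5, 0.0)


class TestBranchScale:
    @pytest.mark.parametrize("c,t,alpha,expect", [
        (2.0, 9.0, 2.0, 6.0),
        (1.0, 1.0, 1.37, 1.0),
        (1.0, 32.0, 1.25, 16.0),
    ])
    def test_values(self, c, t, alpha, expect):
        assert branch_scale(c, t, alpha) == pytest.approx(expect, rel=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError):
            branch_scale(1.0, 0.0, 1.5)
        with pytest.raises(ValueError):
            branch_scale(-1.0, 1.0, 1.5)


class TestAugmentedLoglik:
    def test_two_tip_star_gaussian(self, two_tip_star):
        aug = AugmentedState({0: 0.0})
        p = StableParams(2.0, 1.0, 0.0)
        zero = TraitTable({"A": 1.0, "B": 1.0})  # log10 = 0
        assert augmented_loglik(two_tip_star, zero, aug, p) == pytest.approx(
            2 * math.log(1 / math.sqrt(4 * math.pi)), abs=1e-12)
        pm1 = TraitTable({"A": 10.0, "B": 0.1})  # log10 = +1, -1
        assert augmented_loglik(two_tip_star, pm1, aug, p) == pytest.approx(
            2 * (math.log(1 / math.sqrt(4 * math.pi)) - 0.25), abs=1e-12)

    def test_five_tip_oracle_composition(self, five_tip_tree, five_tip_traits):
        alpha, c = 1.6, 0.8
        rng = np.random.default_rng(7)
        aug = AugmentedState({v: float(rng.normal()) for v in range(five_tip_tree.n_nodes)
                              if not five_tip_tree.is_tip[v]})
        p = StableParams(alpha, c, aug.node_values[0])
        got = augmented_loglik(five_tip_tree, five_tip_traits, aug, p)
        # independent oracle: per-edge quadrature densities summed by hand
        x = dict(aug.node_values)
        for l, w in five_tip_traits.working_values.items():
            x[five_tip_tree.labels.index(l)] = w
        expect = 0.0
        for ch in five_tip_tree.edge_child:
            t = five_tip_tree.duration[ch]
            dx = x[int(ch)] - x[int(five_tip_tree.parent[ch])]
            expect += math.log(oracle_pdf(dx, alpha, c * t ** (1 / alpha)))
        assert got == pytest.approx(expect, rel=1e-9, abs=1e-7)

    def test_missing_node_error(self, two_tip_star):
        traits = TraitTable({"A": 1.0, "B": 1.0})
        with pytest.raises(KeyError, match="0"):
            augmented_loglik(two_tip_star, traits, AugmentedState({}),
                             StableParams(2.0, 1.0, 0.0))

    def test_root_state_consistency_enforced(self, two_tip_star):
        traits = TraitTable({"A": 1.0, "B": 1.0})
        with pytest.raises(ValueError, match="root"):
            augmented_loglik(two_tip_star, traits, AugmentedState({0: 0.5}),
                             StableParams(2.0, 1.0, 0.0))


class TestBmMarginal:
    def test_two_tip_closed_form(self, two_tip_star):
        traits = TraitTable({"A": 1.0, "B": 1.0})
        assert bm_marginal_loglik(two_tip_star, traits, 1.0, 0.0) == pytest.approx(
            -math.log(2 * math.pi), abs=1e-12)

    def test_three_tip_dense_mvn_oracle(self, three_tip_tree):
        vals = {"A": 0.3, "B": -0.4, "C": 1.2}
        traits = TraitTable({k: 10.0 ** v for k, v in vals.items()})
        sigma2, root = 0.8, 0.2
        # dense covariance: sigma2 * shared root-to-tip path length
        cov = sigma2 * np.array([
            [1.7, 1.0, 0.0],
            [1.0, 2.3, 0.0],
            [0.0, 0.0, 2.5],
        ])
        expect = multivariate_normal(mean=root * np.ones(3), cov=cov).logpdf(
            [vals["A"], vals["B"], vals["C"]])
        got = bm_marginal_loglik(three_tip_tree, traits, sigma2, root)
        assert got == pytest.approx(expect, abs=1e-8)

    def test_gls_root_is_ml_root(self, three_tip_tree):
        vals = {"A": 0.3, "B": -0.4, "C": 1.2}
        traits = TraitTable({k: 10.0 ** v for k, v in vals.items()})
        cov = np.array([[1.7, 1.0, 0.0], [1.0, 2.3, 0.0], [0.0, 0.0, 2.5]])
        ci = np.linalg.inv(cov)
        one = np.ones(3)
        y = np.array([vals["A"], vals["B"], vals["C"]])
        expect = (one @ ci @ y) / (one @ ci @ one)
        assert gls_root_mean(three_tip_tree, traits) == pytest.approx(expect, abs=1e-10)
        # and it maximizes the BM marginal likelihood
        base = bm_marginal_loglik(three_tip_tree, traits, 0.7, expect)
        for dr in (-0.05, 0.05):
            assert bm_marginal_loglik(three_tip_tree, traits, 0.7, expect + dr) < base

    def test_augmented_marginalizes_to_pruning_at_alpha2(self, three_tip_tree):
        # integrate the single non-root internal node out of the
        # augmented likelihood by quadrature; sigma2 = 2 c^2
        vals = {"A": 0.3, "B": -0.4, "C": 1.2}
        traits = TraitTable({k: 10.0 ** v for k, v in vals.items()})
        c, root = 0.6, 0.1
        sigma2 = 2 * c * c
        tree = three_tip_tree
        inner = next(v for v in range(tree.n_nodes)
                     if not tree.is_tip[v] and v != tree.root)

        def joint(u):
            aug = AugmentedState({tree.root: root, inner: u})
            return math.exp(augmented_loglik(tree, traits, aug,
                                             StableParams(2.0, c, root)))

        val, _ = quad(joint, -8, 8, limit=300)
        assert math.log(val) == pytest.approx(
            bm_marginal_loglik(tree, traits, sigma2, root), abs=1e-4)

    def test_sigma2_domain(self, two_tip_star):
        traits = TraitTable({"A": 1.0, "B": 1.0})
        with pytest.raises(ValueError):
            bm_marginal_loglik(two_tip_star, traits, 0.0, 0.0)
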