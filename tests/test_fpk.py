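import numpy as np
import pytest
from scipy.stats import chisquare, norm

from divdensity import fpk, synthgen
from divdensity.treekit import DatedTree, make_trait_table

from conftest import bm_integrated_loglik, gaussian_potential_for_ou


class TestStationaryDensity:
    def test_flat_potential_uniform(self):
        g = fpk.TraitGrid(-2, 2, 41)
        land = fpk.stationary_density(g, fpk.PotentialCoefficients())
        assert np.allclose(land.density, 1 / 41)
        assert land.density.sum() == pytest.approx(1.0)

    def test_quadratic_well_peaks_at_center(self):
        g = fpk.TraitGrid(-2, 2, 41)
        land = fpk.stationary_density(g, fpk.PotentialCoefficients(b=3.0))
        assert land.peak == pytest.approx(0.0, abs=g.h / 2)
        assert np.allclose(land.density, land.density[::-1])

    def test_double_well_two_symmetric_peaks(self):
        # V(u) = u^4 - 2 u^2 has minima at u = +-1 on the standardized axis
        g = fpk.TraitGrid(-2, 2, 201)
        land = fpk.stationary_density(g, fpk.PotentialCoefficients(a=1.0, b=-2.0))
        assert land.multimodal
        assert len(land.peaks) == 2
        assert land.peaks[0] == pytest.approx(-land.peaks[1], abs=1e-9)
        # u = +-1 maps to x = +-4/3 on this grid (axis scale 3/4 per x unit)
        assert abs(land.peaks[1] - 4.0 / 3.0) <= g.h


class TestGenerator:
    def setup_method(self):
        self.grid = fpk.TraitGrid(-2, 2, 51)

    def test_rows_sum_to_zero(self):
        m = fpk.FPKModel(0.3, fpk.PotentialCoefficients(1.0, -0.5, 0.7), self.grid)
        Q = fpk.build_generator(m)
        assert np.abs(Q.sum(axis=1)).max() < 1e-12

    def test_flat_potential_symmetric_rates(self):
        m = fpk.FPKModel(0.5, fpk.PotentialCoefficients(), self.grid)
        Q = fpk.build_generator(m)
        k = 0.5 / (2 * self.grid.h**2)
        off = np.diag(Q, 1)
        assert np.allclose(off, k)
        assert np.allclose(np.diag(Q, -1), k)

    def test_stationary_density_is_left_null_vector(self):
        m = fpk.FPKModel(0.4, fpk.PotentialCoefficients(0.5, 1.0, -0.3), self.grid)
        Q = fpk.build_generator(m)
        pi = fpk.stationary_density(self.grid, m.potential).density
        assert np.abs(pi @ Q).max() < 1e-12


class TestBranchTransition:
    def test_zero_time_is_identity(self):
        g = fpk.TraitGrid(-1, 1, 21)
        m = fpk.FPKModel(0.2, fpk.PotentialCoefficients(), g)
        assert np.allclose(fpk.branch_transition(m, 0.0), np.eye(21), atol=1e-10)

    def test_rows_sum_to_one_nonnegative(self):
        g = fpk.TraitGrid(-1, 1, 31)
        m = fpk.FPKModel(0.2, fpk.PotentialCoefficients(0.2, 1.0, 0.5), g)
        P = fpk.branch_transition(m, 3.0)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-9)
        assert P.min() >= 0

    def test_long_time_converges_to_stationary(self):
        g = fpk.TraitGrid(-1, 1, 31)
        m = fpk.FPKModel(0.5, fpk.PotentialCoefficients(), g)
        P = fpk.branch_transition(m, 1e4)
        assert np.abs(P - 1.0 / 31).max() < 1e-6

    def test_moderate_time_matches_gaussian_kernel(self):
        g = fpk.TraitGrid(-5, 5, 201)
        m = fpk.FPKModel(0.5, fpk.PotentialCoefficients(), g)
        P = fpk.branch_transition(m, 2.0)  # variance 1, far from bounds
        i0 = g.nearest_cell(0.0)[0]
        mass = norm.pdf(g.points, 0.0, 1.0) * g.h
        assert np.abs(P[i0] - mass / mass.sum()).sum() < 0.01


class TestTreeLoglik:
    def test_matches_closed_form_bm(self, ten_tip_tree, bm_tip_data):
        sigma2, y, traits = bm_tip_data
        g = fpk.wide_grid(y, n_points=200)
        model = fpk.FPKModel(sigma2, fpk.PotentialCoefficients(), g)
        ll = fpk.tree_loglik(ten_tip_tree, traits, model, tip_mapping="linear")
        ll_bm = bm_integrated_loglik(y, ten_tip_tree.vcv().to_numpy(), sigma2,
                                     g.upper - g.lower)
        assert abs(ll - ll_bm) < 0.05

    def test_matches_closed_form_ou(self, ten_tip_tree):
        alpha, theta, sigma2 = 0.15, 0.2, 0.05
        rng = np.random.default_rng(11)
        C = ten_tip_tree.vcv().to_numpy()
        d = 2 * (ten_tip_tree.root_age - C)
        np.fill_diagonal(d, 0.0)
        V = sigma2 / (2 * alpha) * np.exp(-alpha * d)
        y = theta + np.linalg.cholesky(V) @ rng.standard_normal(10)
        traits = make_trait_table(ten_tip_tree.tip_labels, 10.0**y)
        g = fpk.wide_grid(y, n_points=200)
        model = fpk.FPKModel(
            sigma2, gaussian_potential_for_ou(g, sigma2, alpha, theta), g)
        ll = fpk.tree_loglik(ten_tip_tree, traits, model, tip_mapping="linear")
        ll_ou = fpk.ou_stationary_loglik(ten_tip_tree, traits, sigma2, alpha, theta)
        assert abs(ll - ll_ou) < 0.1

    def test_discretization_converges_with_refinement(self, ten_tip_tree,
                                                      bm_tip_data):
        sigma2, y, traits = bm_tip_data
        lls = []
        for n_points in (100, 200, 400):
            g = fpk.wide_grid(y, n_points=n_points)
            m = fpk.FPKModel(sigma2, fpk.PotentialCoefficients(), g)
            lls.append(fpk.tree_loglik(ten_tip_tree, traits, m,
                                       tip_mapping="linear"))
        assert abs(lls[2] - lls[1]) < abs(lls[1] - lls[0])

    def test_trait_outside_bounds_names_species(self, ten_tip_tree):
        traits = make_trait_table(ten_tip_tree.tip_labels,
                                  [1.0] * 9 + [1e6])
        model = fpk.FPKModel(0.1, fpk.PotentialCoefficients(),
                             fpk.default_grid(50))
        with pytest.raises(ValueError, match="sp0010"):
            fpk.tree_loglik(ten_tip_tree, traits, model)


@pytest.fixture(scope="module")
def dataset():
    tree = synthgen.simulate_bd_tree(60, 0.15, 0.05, seed=5, root_age=29.0)
    g = fpk.default_grid(64)
    true = fpk.FPKModel(0.06, fpk.PotentialCoefficients(0, 2.0, 4.6), g)
    traits = fpk.simulate_fpk(tree, true, seed=6)
    return tree, traits


@pytest.fixture(scope="module")
def all_fits(dataset):
    tree, traits = dataset
    return fpk.fit_all_models(tree, traits, n_points=48, n_starts=3, seed=7)


class TestFitModel:
    def test_aic_identity_and_weights(self, all_fits):
        for f in all_fits.values():
            assert f.aic == pytest.approx(2 * f.n_params - 2 * f.log_likelihood)
        assert fpk.aic_weights(all_fits).sum() == pytest.approx(1.0)

    def test_nesting_of_bounded_models(self, all_fits):
        lls = {k: f.log_likelihood for k, f in all_fits.items()}
        assert lls["BBMV4"] + 1e-4 >= lls["BBMV2"]
        assert lls["BBMV2"] + 1e-4 >= lls["BBMV1"]
        assert lls["BBMV1"] + 1e-4 >= lls["BBM"]

    def test_quartic_bounded_beats_flat_bounded_on_bm_data(self, ten_tip_tree,
                                                           bm_tip_data):
        _, _, traits = bm_tip_data
        g = fpk.default_grid(48)
        bbm = fpk.fit_model(ten_tip_tree, traits, "BBM", grid=g, n_starts=3)
        bbmv4 = fpk.fit_model(
            ten_tip_tree, traits, "BBMV4", grid=g, n_starts=3,
            extra_starts=[[np.log(bbm.mle_params["sigma2"]), 0, 0, 0]])
        assert bbmv4.log_likelihood + 1e-4 >= bbm.log_likelihood

    def test_param_counts(self, all_fits):
        expect = {"BM": 2, "OU": 3, "FPK": 4, "BBMV4": 4, "BBMV2": 3,
                  "BBMV1": 2, "BBM": 1}
        assert {k: f.n_params for k, f in all_fits.items()} == expect

    def test_unknown_model_rejected(self, dataset):
        tree, traits = dataset
        with pytest.raises(ValueError):
            fpk.fit_model(tree, traits, "EB")


class TestLandscapePeak:
    def test_symmetric_well_peaks_at_midpoint(self):
        g = fpk.default_grid(51)
        fit = fpk.FitResult("BBMV2", {"sigma2": 0.1, "b": 2.0, "c": 0.0},
                            -10, 3, 26, True, 1, grid=g)
        pk = fpk.landscape_peak(fit)
        assert pk["peak_log10"] == pytest.approx((g.lower + g.upper) / 2,
                                                 abs=g.h)

    def test_back_transform_to_meters(self):
        g = fpk.TraitGrid(-1.0969, -1.0969 + 1.0, 3)
        fit = fpk.FitResult("BBMV1", {"sigma2": 0.1, "c": 50.0}, -10, 2, 24,
                            True, 1, grid=g)
        pk = fpk.landscape_peak(fit)  # steep downhill potential: peak at lower bound
        assert pk["peak_log10"] == pytest.approx(-1.0969)
        assert pk["peak_m"] == pytest.approx(0.08, abs=0.0001)

    def test_flat_landscape_undefined(self):
        fit = fpk.FitResult("BBM", {"sigma2": 0.1}, -10, 1, 22, True, 1,
                            grid=fpk.default_grid(31))
        pk = fpk.landscape_peak(fit)
        assert not pk["defined"]

    def test_two_equal_maxima_flagged_multimodal(self):
        fit = fpk.FitResult("BBMV4", {"sigma2": 0.1, "a": 1.0, "b": -2.0,
                                      "c": 0.0}, -10, 4, 28, True, 1,
                            grid=fpk.TraitGrid(-2, 2, 201))
        pk = fpk.landscape_peak(fit)
        assert pk["multimodal"] and len(pk["peaks_log10"]) == 2


class TestRootStateDistribution:
    def test_short_tree_concentrates_at_tip(self):
        tree = DatedTree.from_newick("(A:0.0001);")
        traits = make_trait_table(["A"], [1.0])  # log10 = 0
        g = fpk.TraitGrid(-1, 1, 41)
        fit = fpk.FitResult("BBM", {"sigma2": 0.5}, 0, 1, 2, True, 1, grid=g)
        out = fpk.root_state_distribution(tree, traits, fit)
        assert out["mode"] == pytest.approx(0.0, abs=g.h)
        assert out["density"].max() > 0.95

    def test_symmetric_tips_give_symmetric_root(self):
        tree = DatedTree.from_newick("(A:1,B:1);")
        traits = make_trait_table(["A", "B"], [10.0**0.5, 10.0**-0.5])
        g = fpk.TraitGrid(-2, 2, 81)
        fit = fpk.FitResult("BBM", {"sigma2": 0.3}, 0, 1, 2, True, 1, grid=g)
        out = fpk.root_state_distribution(tree, traits, fit)
        assert np.allclose(out["density"], out["density"][::-1], atol=1e-9)
        lo, hi = out["interval"]
        assert lo == pytest.approx(-hi, abs=g.h)

    def test_bm_root_mode_matches_gls_estimate(self, ten_tip_tree, bm_tip_data):
        sigma2, y, traits = bm_tip_data
        g = fpk.wide_grid(y, n_points=200)
        fit = fpk.FitResult("BBM", {"sigma2": sigma2}, 0, 1, 2, True, 1,
                            grid=g, root_prior="flat")
        out = fpk.root_state_distribution(ten_tip_tree, traits, fit)
        C = ten_tip_tree.vcv().to_numpy()
        ones = np.ones(len(y))
        w = np.linalg.solve(C, ones)
        gls_root = float(y @ w) / float(ones @ w)
        assert abs(out["mode"] - gls_root) <= g.h


class TestSimulateFpk:
    def test_seed_determinism(self, ten_tip_tree):
        m = fpk.FPKModel(0.05, fpk.PotentialCoefficients(0, 2, 4.6),
                         fpk.default_grid(64))
        a = fpk.simulate_fpk(ten_tip_tree, m, seed=3)
        b = fpk.simulate_fpk(ten_tip_tree, m, seed=3)
        assert a.data.equals(b.data)

    def test_single_branch_variance_matches_bm(self):
        # flat potential, wide bounds: tip variance across replicates = s2 * t
        tree = DatedTree.from_newick("(A:4);")
        g = fpk.TraitGrid(-8, 8, 161)
        m = fpk.FPKModel(0.25, fpk.PotentialCoefficients(), g)
        tips = [
            fpk.simulate_fpk(tree, m, seed=s, root_state=0.0)
            .data.height_log10.iloc[0]
            for s in range(500)
        ]
        assert np.var(tips) == pytest.approx(0.25 * 4, rel=0.10)

    def test_long_branches_reach_stationary_distribution(self):
        # star tree with long branches: tips are iid draws from the landscape
        star = "(" + ",".join(f"t{i}:400" for i in range(400)) + ");"
        tree = DatedTree.from_newick(star)
        g = fpk.TraitGrid(-2, 2, 25)
        m = fpk.FPKModel(0.5, fpk.PotentialCoefficients(0, 3.0, 1.0), g)
        traits = fpk.simulate_fpk(tree, m, seed=9)
        pi = fpk.stationary_density(g, m.potential).density
        cells = g.nearest_cell(traits.data.height_log10.to_numpy())
        observed = np.bincount(cells, minlength=25)
        keep = pi * 400 >= 5  # chi-square validity
        obs = np.append(observed[keep], observed[~keep].sum())
        exp = np.append(pi[keep] * 400, pi[~keep].sum() * 400)
        stat, p = chisquare(obs, exp * obs.sum() / exp.sum())
        assert p > 0.01
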