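import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.stats import pearsonr

from divdensity import comparative, georange, synthgen
from divdensity.comparative import (
    backbone_tree,
    height_metric_sweep,
    pgls_fit,
    rate_density_decoupling,
    trait_distribution_summary,
)
from divdensity.treekit import make_trait_table, slice_clades


class TestBackbone:
    def test_collapse_at_cutoff_3(self, worked_tree):
        sl = slice_clades(worked_tree, 3)
        bb = backbone_tree(worked_tree, sl)
        assert bb.n_tips == 2
        # both clades' stems trace to the root: 2-tip backbone rooted at
        # (root age - cutoff) = 2
        assert bb.root_age == pytest.approx(2.0)
        assert sorted(bb.tip_labels) == sorted(c.clade_id for c in sl.clades)

    def test_collapse_at_cutoff_4_5(self, worked_tree):
        sl = slice_clades(worked_tree, 4.5)
        bb = backbone_tree(worked_tree, sl)
        assert bb.n_tips == 2
        assert bb.root_age == pytest.approx(0.5)

    def test_shared_path_lengths_preserved(self):
        t = synthgen.simulate_bd_tree(40, 0.25, 0.0, seed=3, root_age=20.0)
        cutoff = 6.0
        sl = slice_clades(t, cutoff)
        bb = backbone_tree(t, sl)
        C = bb.vcv()
        assert np.allclose(np.diag(C), t.root_age - cutoff, atol=1e-6)
        # covariance of two backbone tips equals the shared time from the
        # root to the MRCA of the original clades
        for ci in sl.clades[:3]:
            for cj in sl.clades[3:6]:
                mrca = t.tree.mrca(taxon_labels=[next(iter(ci.tip_set)),
                                                 next(iter(cj.tip_set))])
                assert C.loc[ci.clade_id, cj.clade_id] == pytest.approx(
                    t.root_age - mrca.age, abs=1e-6)

    def test_single_clade_rejected(self, worked_tree):
        sl = slice_clades(worked_tree, 1.5)
        with pytest.raises(ValueError):
            backbone_tree(worked_tree, sl)


@pytest.fixture(scope="module")
def data():
    tree = synthgen.simulate_bd_tree(30, 0.2, 0.0, seed=1, root_age=10.0)
    C = tree.vcv().to_numpy()
    rng = np.random.default_rng(3)
    x = rng.standard_normal(30)
    y = rng.standard_normal(30)
    return y, x, C


class TestPgls:
    def test_lambda_zero_equals_ols(self, data):
        y, x, C = data
        fit = pgls_fit(y, x, C, lambda_fixed=0.0)
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        assert fit.slope == pytest.approx(ols.params[1], abs=1e-8)
        assert fit.slope_se == pytest.approx(ols.bse[1], abs=1e-8)
        assert fit.p_value == pytest.approx(ols.pvalues[1], abs=1e-8)

    def test_lambda_one_equals_brownian_gls(self, data):
        y, x, C = data
        fit = pgls_fit(y, x, C, lambda_fixed=1.0)
        gls = sm.GLS(y, sm.add_constant(x), sigma=C).fit()
        assert fit.slope == pytest.approx(gls.params[1], abs=1e-10)
        assert fit.slope_se == pytest.approx(gls.bse[1], abs=1e-10)

    def test_star_phylogeny_lambda_irrelevant(self, data):
        y, x, _ = data
        star = np.eye(30) * 7.5
        est = pgls_fit(y, x, star)
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        assert est.slope == pytest.approx(ols.params[1], abs=1e-7)

    def test_ci_contains_slope(self, data):
        y, x, C = data
        fit = pgls_fit(y, x, C)
        lo, hi = fit.slope_ci95
        assert lo <= fit.slope <= hi
        assert 0.0 <= fit.lambda_ <= 1.0

    def test_slope_recovery_coverage(self):
        cover = 0
        for rep in range(100):
            tree = synthgen.simulate_bd_tree(50, 0.2, 0.0, seed=rep,
                                             root_age=10.0)
            C = tree.vcv().to_numpy()
            rng = np.random.default_rng(1000 + rep)
            L = np.linalg.cholesky(C)
            x = L @ rng.standard_normal(50)
            y = 2.0 * x + 0.5 * (L @ rng.standard_normal(50))
            lo, hi = pgls_fit(y, x, C).slope_ci95
            cover += lo <= 2.0 <= hi
        assert cover >= 90

    def test_too_few_clades_rejected(self):
        with pytest.raises(ValueError):
            pgls_fit([1, 2], [1, 2], np.eye(2))


class TestSweep:
    def test_single_tree_single_cutoff(self, small_coupled_bundle):
        b = small_coupled_bundle
        rec = georange.clean_occurrences(b.occurrences, b.region)
        res = height_metric_sweep(b.trees[:1], b.traits, metric="density",
                                  cutoffs=(8,), records=rec)
        assert len(res.fits) == 1
        assert res.summary.loc[0, "cutoff"] == 8

    def test_coupled_fixture_negative_density_slopes(self, small_coupled_bundle):
        b = small_coupled_bundle
        rec = georange.clean_occurrences(b.occurrences, b.region)
        res = height_metric_sweep(b.trees, b.traits, metric="density",
                                  cutoffs=(6, 9, 12), records=rec)
        assert (res.summary["median_slope"] < 0).all()

    def test_sweep_deterministic(self, small_coupled_bundle):
        b = small_coupled_bundle
        rec = georange.clean_occurrences(b.occurrences, b.region)
        r1 = height_metric_sweep(b.trees[:2], b.traits, metric="rate",
                                 cutoffs=(7, 10))
        r2 = height_metric_sweep(b.trees[:2], b.traits, metric="rate",
                                 cutoffs=(7, 10))
        assert r1.fits.to_csv(index=False) == r2.fits.to_csv(index=False)

    def test_density_requires_records(self, small_coupled_bundle):
        b = small_coupled_bundle
        with pytest.raises(ValueError):
            height_metric_sweep(b.trees, b.traits, metric="density")


class TestDecoupling:
    def test_perfect_correlation_limits(self):
        rng = np.random.default_rng(0)
        v = rng.standard_normal(20)
        r, _ = pearsonr(v, v)
        assert r == pytest.approx(1.0)
        r, _ = pearsonr(v, -v)
        assert r == pytest.approx(-1.0)

    def test_independent_metrics_rarely_significant(self):
        # 100 tree x cutoff cells of 30 independent rate/density pairs
        rng = np.random.default_rng(5)
        nonsig = 0
        for _ in range(100):
            r, p = pearsonr(rng.standard_normal(30), rng.standard_normal(30))
            nonsig += p >= 0.05
        assert nonsig >= 90

    def test_r_invariant_to_affine_rescaling(self, small_coupled_bundle):
        b = small_coupled_bundle
        rec = georange.clean_occurrences(b.occurrences, b.region)
        base = rate_density_decoupling(b.trees[:1], b.traits, rec,
                                       cutoffs=(7, 10))
        # rescaling either metric is an affine map; recompute via the cells
        assert np.all(base.cells["r"].between(-1, 1))
        assert 0.0 <= base.frac_nonsignificant <= 1.0

    def test_pipeline_decoupling_runs(self, small_coupled_bundle):
        b = small_coupled_bundle
        rec = georange.clean_occurrences(b.occurrences, b.region)
        res = rate_density_decoupling(b.trees[:2], b.traits, rec,
                                      cutoffs=(6, 9, 12))
        assert len(res.cells) == 6
        assert np.isfinite(res.mean_r)


class TestTraitDistribution:
    def test_symmetric_sample_zero_skew(self):
        tt = make_trait_table([f"s{i}" for i in range(30)],
                              10.0 ** np.tile([-1.0, 0.0, 1.0], 10))
        out = trait_distribution_summary(tt)
        assert out["skew"] == pytest.approx(0.0, abs=1e-12)

    def test_positive_skew_detected(self):
        vals = np.tile([0.0, 0.0, 0.0, 1.0], 10)
        tt = make_trait_table([f"s{i}" for i in range(40)], 10.0**vals)
        out = trait_distribution_summary(tt)
        assert out["skew"] > 0

    def test_constant_sample_undefined(self):
        tt = make_trait_table([f"s{i}" for i in range(10)], [2.0] * 10)
        out = trait_distribution_summary(tt)
        assert not out["defined"]

    def test_small_sample_rejected(self):
        tt = make_trait_table(list("abc"), [1, 2, 3])
        with pytest.raises(ValueError):
            trait_distribution_summary(tt)

    def test_type_one_error_calibration(self):
        # D'Agostino test on normal data rejects at roughly the nominal rate
        rng = np.random.default_rng(8)
        rejections = 0
        for _ in range(100):
            vals = 10.0 ** rng.standard_normal(1000)
            tt = make_trait_table([f"s{i}" for i in range(1000)], vals)
            rejections += trait_distribution_summary(tt)["p_value"] < 0.05
        assert 1 <= rejections <= 12
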