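import numpy as np
import pytest

from divdensity import fpk, synthgen
from divdensity.treekit import DatedTree, make_trait_table

#: five-tip worked tree used across slicing/backbone tests (root age 5)
WORKED_NEWICK = "((A:2,B:2):3,(C:4,(D:1,E:1):3):1);"


@pytest.fixture(scope="session")
def worked_tree() -> DatedTree:
    return DatedTree.from_newick(WORKED_NEWICK)


@pytest.fixture(scope="session")
def ten_tip_tree() -> DatedTree:
    """Seeded 10-tip pure-birth tree for the likelihood oracle tests."""
    return synthgen.simulate_bd_tree(10, 0.3, 0.0, seed=42)


@pytest.fixture(scope="session")
def bm_tip_data(ten_tip_tree):
    """Tips drawn from the exact Brownian tip distribution (root at 0)."""
    rng = np.random.default_rng(7)
    sigma2 = 0.04
    C = ten_tip_tree.vcv().to_numpy()
    y = np.linalg.cholesky(sigma2 * C) @ rng.standard_normal(ten_tip_tree.n_tips)
    traits = make_trait_table(ten_tip_tree.tip_labels, 10.0**y)
    return sigma2, y, traits


@pytest.fixture(scope="session")
def small_coupled_bundle():
    """Coupled-scenario synthetic bundle shared by integration tests."""
    cfg = synthgen.SynthConfig(seed=21, n_tips=120, n_posterior_trees=3)
    return synthgen.end_to_end_fixture("coupled", seed=21, config=cfg)


def bm_integrated_loglik(y, C, sigma2, interval_width):
    """Closed-form Brownian log-likelihood with the root state integrated
    against a uniform prior of the given width (the flat-landscape analogue
    of the grid models' stationary root prior)."""
    n = len(y)
    V = sigma2 * C
    ones = np.ones(n)
    Vi_ones = np.linalg.solve(V, ones)
    denom = float(ones @ Vi_ones)
    mu = float(y @ Vi_ones) / denom
    resid = y - mu
    Q0 = float(resid @ np.linalg.solve(V, resid))
    _, logdet = np.linalg.slogdet(V)
    return (-(n - 1) / 2 * np.log(2 * np.pi) - 0.5 * logdet - 0.5 * Q0
            - 0.5 * np.log(denom) - np.log(interval_width))


def gaussian_potential_for_ou(grid: fpk.TraitGrid, sigma2, alpha, theta):
    """Potential coefficients making the grid diffusion an OU process with
    the given parameters: V(x) = (alpha/sigma2) (x - theta)^2 expressed on
    the standardized axis."""
    mid = (grid.lower + grid.upper) / 2.0
    s = (grid.upper - grid.lower) / (2.0 * fpk.POTENTIAL_AXIS_HALFWIDTH)
    b = alpha / sigma2 * s**2
    c = 2.0 * alpha / sigma2 * s * (mid - theta)
    return fpk.PotentialCoefficients(0.0, b, c)
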