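"""Bounded macroevolutionary-landscape models of continuous-trait evolution.

The general model is a diffusion on a trait interval: a character x evolves
under random diffusion with rate sigma^2 plus a deterministic force pulling
it down the gradient of an evolutionary potential V(x),

    dX = -(sigma^2/2) V'(X) dt + sigma dW,

optionally with reflecting bounds.  The stationary distribution
pi(x) ∝ exp(-V(x)) is the *macroevolutionary landscape*: its peaks are trait
values favored over the clade's history.  V is a polynomial
a*u^4 + b*u^2 + c*u evaluated on the grid axis rescaled to [-1.5, 1.5]
(keeps coefficient magnitudes comparable across grids).  The model family:

    BM     flat landscape, no bounds        (2 params: sigma^2, root state)
    OU     Gaussian landscape, no bounds    (3 params: sigma^2, alpha, theta)
    FPK    quartic landscape, distant bounds (4 params)
    BBMV4  quartic landscape, reflecting bounds (4)
    BBMV2  quadratic landscape, bounds          (3)
    BBMV1  linear potential (directional trend), bounds (2)
    BBM    flat landscape, reflecting bounds     (1)

BM and OU are fitted in closed form / by 1-D profile likelihood on the
phylogenetic covariance matrix.  The grid models discretize the diffusion as
a birth-death chain on an evenly spaced grid with nearest-neighbour rates

    q(i -> i+-1) = sigma^2/(2 h^2) * exp(-(V_j - V_i)/2),

which satisfies detailed balance with pi_i ∝ exp(-V_i) exactly and recovers
the Fokker-Planck drift to O(h).  The generator is symmetrizable by
D = diag(pi^1/2), so branch propagation uses one symmetric-tridiagonal
eigendecomposition per likelihood evaluation.  Likelihoods are continuous
densities (grid mass divided by the cell width per tip), so grid-model and
closed-form log-likelihoods are directly comparable under AIC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh_tridiagonal
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import qmc

from .treekit import DatedTree, TraitTable

logger = logging.getLogger(__name__)

MODEL_NAMES = ("BM", "OU", "FPK", "BBMV4", "BBMV2", "BBMV1", "BBM")
GRID_MODELS = ("FPK", "BBMV4", "BBMV2", "BBMV1", "BBM")
#: active potential coefficients per grid model
_ACTIVE = {"FPK": "abc", "BBMV4": "abc", "BBMV2": "bc", "BBMV1": "c", "BBM": ""}
N_PARAMS = {"BM": 2, "OU": 3, "FPK": 4, "BBMV4": 4, "BBMV2": 3, "BBMV1": 2, "BBM": 1}

#: default trait bounds for height in log10 meters: 1 cm to 50 m
DEFAULT_BOUNDS = (np.log10(0.01), np.log10(50.0))
DEFAULT_N_POINTS = 100
#: half-width of the standardized axis on which the potential polynomial acts
POTENTIAL_AXIS_HALFWIDTH = 1.5
#: cap on V - min(V); cells above this carry stationary mass < 1e-26 and an
#: uncapped potential would amplify eigendecomposition round-off
V_CAP = 60.0


# ---------------------------------------------------------------------------
# Grid, potential, landscape
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraitGrid:
    """Evenly spaced trait grid on [lower, upper] (log10 m for height)."""

    lower: float
    upper: float
    n_points: int = DEFAULT_N_POINTS

    def __post_init__(self):
        if not self.lower < self.upper:
            raise ValueError("grid needs lower < upper")
        if self.n_points < 3:
            raise ValueError("grid needs at least 3 points")

    @property
    def points(self) -> np.ndarray:
        return np.linspace(self.lower, self.upper, self.n_points)

    @property
    def h(self) -> float:
        return (self.upper - self.lower) / (self.n_points - 1)

    @property
    def scaled_axis(self) -> np.ndarray:
        """Grid points mapped affinely onto [-1.5, 1.5]."""
        w = POTENTIAL_AXIS_HALFWIDTH
        return np.linspace(-w, w, self.n_points)

    def nearest_cell(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, float))
        if np.any(x < self.lower - 1e-12) or np.any(x > self.upper + 1e-12):
            raise ValueError("trait value outside grid bounds")
        return np.clip(np.rint((x - self.lower) / self.h).astype(int),
                       0, self.n_points - 1)


def default_grid(n_points: int = DEFAULT_N_POINTS) -> TraitGrid:
    return TraitGrid(DEFAULT_BOUNDS[0], DEFAULT_BOUNDS[1], n_points)


def wide_grid(trait_values, n_sd: float = 10.0,
              n_points: int = DEFAULT_N_POINTS) -> TraitGrid:
    """Grid with bounds ``n_sd`` trait standard deviations beyond the data
    range -- the 'effectively unbounded' setting used by FPK and BM checks."""
    x = np.asarray(trait_values, float)
    sd = float(np.std(x))
    if sd == 0:
        sd = max(abs(x[0]), 1.0) * 0.1
    return TraitGrid(float(x.min() - n_sd * sd), float(x.max() + n_sd * sd), n_points)


@dataclass(frozen=True)
class PotentialCoefficients:
    """V(u) = a u^4 + b u^2 + c u on the standardized axis u in [-1.5, 1.5]."""

    a: float = 0.0
    b: float = 0.0
    c: float = 0.0

    def evaluate(self, grid: TraitGrid) -> np.ndarray:
        u = grid.scaled_axis
        return self.a * u**4 + self.b * u**2 + self.c * u


@dataclass
class FPKModel:
    """A diffusion-with-potential trait model on a grid."""

    sigma2: float
    potential: PotentialCoefficients
    grid: TraitGrid
    bounded: bool = True

    def __post_init__(self):
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")


@dataclass
class MacroevoLandscape:
    """Stationary trait distribution ∝ exp(-V) on the grid."""

    grid: TraitGrid
    density: np.ndarray  # probability mass per grid point, sums to 1
    peak: float          # trait value (log10 m) of the maximum
    peaks: list = field(default_factory=list)
    multimodal: bool = False


def stationary_density(grid: TraitGrid, potential: PotentialCoefficients
                       ) -> MacroevoLandscape:
    """Normalized exp(-V) on the grid, with its peak(s)."""
    V = potential.evaluate(grid)
    w = np.exp(-(V - V.min()))  # shift avoids overflow
    density = w / w.sum()
    pts = grid.points
    top = density.max()
    peak_idx = np.flatnonzero(density >= top * (1 - 1e-9))
    peaks = [float(pts[i]) for i in peak_idx]
    return MacroevoLandscape(
        grid=grid,
        density=density,
        peak=peaks[0],
        peaks=peaks,
        multimodal=len(peaks) > 1,
    )


# ---------------------------------------------------------------------------
# Generator and branch propagation
# ---------------------------------------------------------------------------

def build_generator(model: FPKModel) -> np.ndarray:
    """Transition-rate matrix over grid cells (rows sum to 0, reflecting ends).

    Dense form, for inspection and small problems; likelihood evaluation uses
    the equivalent symmetric-tridiagonal factorization in :class:`_Propagator`.
    """
    V = model.potential.evaluate(model.grid)
    V = np.clip(V - V.min(), 0.0, V_CAP)
    n = model.grid.n_points
    k = model.sigma2 / (2.0 * model.grid.h**2)
    up = k * np.exp(-(V[1:] - V[:-1]) / 2.0)    # rate i -> i+1
    dn = k * np.exp(-(V[:-1] - V[1:]) / 2.0)    # rate i+1 -> i
    Q = np.zeros((n, n))
    Q[np.arange(n - 1), np.arange(1, n)] = up
    Q[np.arange(1, n), np.arange(n - 1)] = dn
    Q[np.arange(n), np.arange(n)] = -Q.sum(axis=1)
    return Q


class _Propagator:
    """exp(Q t) action via the detailed-balance symmetrization.

    With pi ∝ exp(-V) and W = diag(exp(-V/2)), S = W Q W^-1 is symmetric
    tridiagonal with constant off-diagonal sigma^2/(2h^2); its
    eigendecomposition gives exp(Qt) v = W^-1 U exp(L t) U' W v.
    """

    def __init__(self, model: FPKModel):
        V = model.potential.evaluate(model.grid)
        V = np.clip(V - V.min(), 0.0, V_CAP)
        n = model.grid.n_points
        k = model.sigma2 / (2.0 * model.grid.h**2)
        up = k * np.exp(-(V[1:] - V[:-1]) / 2.0)
        dn = k * np.exp(-(V[:-1] - V[1:]) / 2.0)
        diag = np.zeros(n)
        diag[:-1] -= up
        diag[1:] -= dn
        lam, U = eigh_tridiagonal(diag, np.full(n - 1, k))
        self.lam = np.minimum(lam, 0.0)  # generator spectrum is <= 0
        self.U = U
        self.W = np.exp(-V / 2.0)
        self.V = V
        self.model = model

    def propagate(self, v: np.ndarray, t: float) -> np.ndarray:
        """exp(Q t) @ v (conditional-likelihood direction, rate i->j in Q_ij)."""
        w = self.U.T @ (self.W * v)
        out = (self.U @ (np.exp(self.lam * t) * w)) / self.W
        return np.maximum(out, 0.0)

    def transition_row(self, i: int, t: float) -> np.ndarray:
        """Row i of exp(Q t): P(end cell | start cell i), normalized."""
        tmp = (self.U[i, :] * np.exp(self.lam * t)) @ self.U.T
        row = np.maximum(tmp * self.W / self.W[i], 0.0)
        s = row.sum()
        return row / s if s > 0 else np.full_like(row, 1.0 / len(row))

    def stationary_mass(self) -> np.ndarray:
        w = self.W**2  # exp(-V)
        return w / w.sum()


def branch_transition(model: FPKModel, t: float) -> np.ndarray:
    """Full transition-probability matrix exp(Q t); rows sum to 1."""
    if t < 0:
        raise ValueError("branch length must be >= 0")
    prop = _Propagator(model)
    n = model.grid.n_points
    E = np.exp(prop.lam * t)
    P = (prop.U * E) @ prop.U.T
    P = (P / prop.W[:, None]) * prop.W[None, :]
    P = np.maximum(P, 0.0)
    return P / P.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Pruning likelihood
# ---------------------------------------------------------------------------

class _TreeIndex:
    """Postorder edge list of a dated tree, cached for repeated pruning."""

    def __init__(self, tree: DatedTree):
        nodes = list(tree.tree.postorder_node_iter())
        self.node_pos = {id(nd): i for i, nd in enumerate(nodes)}
        self.nodes = nodes
        self.children = [
            [(self.node_pos[id(ch)], ch.edge.length) for ch in nd.child_nodes()]
            for nd in nodes
        ]
        self.is_leaf = [nd.is_leaf() for nd in nodes]
        self.labels = [DatedTree._label(nd) if nd.is_leaf() else None for nd in nodes]
        self.root_index = len(nodes) - 1
        self.n_tips = sum(self.is_leaf)


def _tip_vectors(index: _TreeIndex, traits: TraitTable, grid: TraitGrid,
                 tip_mapping: str = "nearest") -> dict[int, np.ndarray]:
    lookup = traits.as_series()
    vecs: dict[int, np.ndarray] = {}
    for i, leaf in enumerate(index.is_leaf):
        if not leaf:
            continue
        lab = index.labels[i]
        if lab not in lookup.index or pd.isna(lookup[lab]):
            raise ValueError(f"species {lab!r} has no trait value")
        x = float(lookup[lab])
        if not (grid.lower - 1e-12 <= x <= grid.upper + 1e-12):
            raise ValueError(
                f"trait of species {lab!r} ({x:.4g}) outside grid bounds "
                f"[{grid.lower:.4g}, {grid.upper:.4g}]"
            )
        v = np.zeros(grid.n_points)
        if tip_mapping == "nearest":
            v[grid.nearest_cell(x)[0]] = 1.0
        elif tip_mapping == "linear":
            f = (x - grid.lower) / grid.h
            lo = int(np.clip(np.floor(f), 0, grid.n_points - 2))
            frac = f - lo
            v[lo] = 1.0 - frac
            v[lo + 1] = frac
        else:
            raise ValueError(f"unknown tip mapping {tip_mapping!r}")
        vecs[i] = v
    return vecs


def _prune_loglik(index: _TreeIndex, tip_vecs: dict[int, np.ndarray],
                  prop: _Propagator, root_prior: np.ndarray,
                  return_root: bool = False):
    """Felsenstein pruning over the grid; returns a continuous-density logL."""
    partial: dict[int, np.ndarray] = {}
    log_scale = 0.0
    for i, leaf in enumerate(index.is_leaf):
        if leaf:
            partial[i] = tip_vecs[i]
            continue
        acc = np.ones(prop.model.grid.n_points)
        for child_pos, blen in index.children[i]:
            acc = acc * prop.propagate(partial.pop(child_pos), blen or 0.0)
        m = acc.max()
        if m <= 0 or not np.isfinite(m):
            return (-np.inf, None) if return_root else -np.inf
        log_scale += np.log(m)
        partial[i] = acc / m
    root_part = partial[index.root_index]
    like = float(root_prior @ root_part)
    if like <= 0:
        return (-np.inf, None) if return_root else -np.inf
    logL = np.log(like) + log_scale - index.n_tips * np.log(prop.model.grid.h)
    if return_root:
        post = root_prior * root_part
        return logL, post / post.sum()
    return logL


def tree_loglik(tree: DatedTree, traits: TraitTable, model: FPKModel,
                root_prior: str = "stationary",
                tip_mapping: str = "nearest") -> float:
    """Log-likelihood of tip traits under a grid diffusion model.

    The root state is integrated against the model's stationary density
    (``root_prior='stationary'``, the landscape interpretation) or a flat
    prior over the grid (``'flat'``).  Reported on the continuous-density
    scale, comparable with closed-form BM/OU likelihoods.
    """
    index = _TreeIndex(tree)
    tip_vecs = _tip_vectors(index, traits, model.grid, tip_mapping)
    prop = _Propagator(model)
    prior = _root_prior_vector(prop, root_prior)
    return _prune_loglik(index, tip_vecs, prop, prior)


def _root_prior_vector(prop: _Propagator, root_prior: str) -> np.ndarray:
    if root_prior == "stationary":
        return prop.stationary_mass()
    if root_prior == "flat":
        n = len(prop.W)
        return np.full(n, 1.0 / n)
    raise ValueError(f"unknown root prior {root_prior!r}")


# ---------------------------------------------------------------------------
# Closed-form BM and OU fits
# ---------------------------------------------------------------------------

def _gls_mean(y: np.ndarray, R: np.ndarray):
    """GLS mean and quadratic form under covariance proportional to R."""
    Ri = np.linalg.solve(R, np.ones_like(y))
    Ry = np.linalg.solve(R, y)
    denom = float(Ri.sum())
    mu = float(y @ Ri) / denom
    resid = y - mu
    Q0 = float(resid @ np.linalg.solve(R, resid))
    return mu, Q0, denom, Ry


def _bm_fit(tree: DatedTree, traits: TraitTable):
    labels = [l for l in tree.tip_labels]
    y = traits.height_log10(labels).to_numpy(float)
    C = tree.vcv(labels).to_numpy()
    n = len(y)
    mu, Q0, _, _ = _gls_mean(y, C)
    sigma2 = Q0 / n
    sign, logdetC = np.linalg.slogdet(C)
    logL = -0.5 * (n * np.log(2 * np.pi) + n * np.log(sigma2) + logdetC + n)
    return {"sigma2": sigma2, "z0": mu}, float(logL)


def _ou_R(C: np.ndarray, alpha: float, T: float) -> np.ndarray:
    """OU correlation structure (root fixed at theta), up to sigma^2/(2 alpha)."""
    d = 2.0 * (T - C)  # patristic distances (ultrametric)
    return np.exp(-alpha * d) * (1.0 - np.exp(-2.0 * alpha * C)) / (2.0 * alpha)


def _ou_fit(tree: DatedTree, traits: TraitTable):
    labels = tree.tip_labels
    y = traits.height_log10(labels).to_numpy(float)
    C = tree.vcv(labels).to_numpy()
    n = len(y)
    T = tree.root_age

    def neg_prof(log_alpha):
        alpha = np.exp(log_alpha)
        R = _ou_R(C, alpha, T)
        sign, logdetR = np.linalg.slogdet(R)
        if sign <= 0:
            return 1e10
        try:
            mu, Q0, _, _ = _gls_mean(y, R)
        except np.linalg.LinAlgError:
            return 1e10
        sigma2 = Q0 / n
        if sigma2 <= 0:
            return 1e10
        return 0.5 * (n * np.log(2 * np.pi) + n * np.log(sigma2) + logdetR + n)

    res = minimize_scalar(neg_prof, bounds=(np.log(1e-4 / T), np.log(50.0 / T)),
                          method="bounded",
                          options={"xatol": 1e-8})
    alpha = float(np.exp(res.x))
    R = _ou_R(C, alpha, T)
    mu, Q0, _, _ = _gls_mean(y, R)
    sigma2 = Q0 / n
    return {"sigma2": sigma2, "alpha": alpha, "theta": mu}, float(-res.fun)


def ou_stationary_loglik(tree: DatedTree, traits: TraitTable,
                         sigma2: float, alpha: float, theta: float) -> float:
    """Closed-form OU log-likelihood with the root drawn from the OU
    stationary distribution N(theta, sigma^2/(2 alpha)): tips are jointly
    Gaussian with mean theta and covariance sigma^2/(2 alpha) exp(-alpha d)."""
    labels = tree.tip_labels
    y = traits.height_log10(labels).to_numpy(float)
    C = tree.vcv(labels).to_numpy()
    d = 2.0 * (tree.root_age - C)
    np.fill_diagonal(d, 0.0)
    V = sigma2 / (2.0 * alpha) * np.exp(-alpha * d)
    n = len(y)
    sign, logdet = np.linalg.slogdet(V)
    resid = y - theta
    Q0 = float(resid @ np.linalg.solve(V, resid))
    return float(-0.5 * (n * np.log(2 * np.pi) + logdet + Q0))


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """One model fitted to one tree's tip traits."""

    model_name: str
    mle_params: dict
    log_likelihood: float
    n_params: int
    aic: float
    converged: bool
    n_starts_used: int
    grid: TraitGrid | None = None
    root_prior: str = "stationary"

    @property
    def model(self) -> FPKModel | None:
        if self.model_name not in GRID_MODELS:
            return None
        p = self.mle_params
        return FPKModel(
            sigma2=p["sigma2"],
            potential=PotentialCoefficients(
                p.get("a", 0.0), p.get("b", 0.0), p.get("c", 0.0)
            ),
            grid=self.grid,
            bounded=self.model_name != "FPK",
        )


def _grid_for_model(model_name: str, y: np.ndarray, grid: TraitGrid | None,
                    n_points: int) -> TraitGrid:
    if grid is not None:
        return grid
    if model_name == "FPK":
        return wide_grid(y, n_points=n_points)
    return default_grid(n_points)


def fit_model(tree: DatedTree, traits: TraitTable, model_name: str,
              grid: TraitGrid | None = None, n_points: int = DEFAULT_N_POINTS,
              n_starts: int = 5, seed: int = 0, root_prior: str = "stationary",
              tip_mapping: str = "nearest",
              extra_starts: list | None = None) -> FitResult:
    """Maximum-likelihood fit of one of the seven trait-evolution models.

    BM and OU use the phylogenetic covariance matrix (closed form / 1-D
    profile); grid models maximize the pruning likelihood over (log sigma^2,
    active potential coefficients) from ``n_starts`` Latin-hypercube starts.
    Grid bounds default to [log10(1 cm), log10(50 m)] for bounded models and
    to 10 trait SD beyond the data for FPK.  ``extra_starts`` (vectors in the
    same parameterization) allows warm-starting from a nested model's
    optimum.
    """
    if model_name not in MODEL_NAMES:
        raise ValueError(f"unknown model {model_name!r}; choose from {MODEL_NAMES}")
    labels = tree.tip_labels
    y = traits.height_log10(labels)
    if y.isna().any():
        missing = y.index[y.isna()].tolist()
        raise ValueError(f"species without traits: {missing}")
    y = y.to_numpy(float)
    if len(y) < 3:
        raise ValueError("need at least 3 tips with trait values")

    if model_name == "BM":
        params, logL = _bm_fit(tree, traits)
        k = N_PARAMS["BM"]
        return FitResult("BM", params, logL, k, 2 * k - 2 * logL, True, 1)
    if model_name == "OU":
        params, logL = _ou_fit(tree, traits)
        k = N_PARAMS["OU"]
        return FitResult("OU", params, logL, k, 2 * k - 2 * logL, True, 1)

    g = _grid_for_model(model_name, y, grid, n_points)
    active = _ACTIVE[model_name]
    index = _TreeIndex(tree)
    tip_vecs = _tip_vectors(index, traits, g, tip_mapping)

    # data-informed scale for sigma^2 starts: BM estimate on the tree
    bm_params, _ = _bm_fit(tree, traits)
    log_s2_center = np.log(max(bm_params["sigma2"], 1e-12))

    def unpack(theta):
        sigma2 = float(np.exp(theta[0]))
        coef = dict(zip(active, theta[1:]))
        pot = PotentialCoefficients(coef.get("a", 0.0), coef.get("b", 0.0),
                                    coef.get("c", 0.0))
        return FPKModel(sigma2=sigma2, potential=pot, grid=g,
                        bounded=model_name != "FPK")

    def nll(theta):
        try:
            prop = _Propagator(unpack(theta))
        except (ValueError, np.linalg.LinAlgError):
            return 1e10
        prior = _root_prior_vector(prop, root_prior)
        ll = _prune_loglik(index, tip_vecs, prop, prior)
        if not np.isfinite(ll):
            return 1e10
        return -ll

    dim = 1 + len(active)
    lo = np.array([log_s2_center - 5.0] + [-20.0] * len(active))
    hi = np.array([log_s2_center + 3.0] + [20.0] * len(active))
    rng = np.random.default_rng(seed)
    if dim == 1:
        starts = [np.array([log_s2_center + d]) for d in
                  np.linspace(-2, 2, n_starts)]
    else:
        sampler = qmc.LatinHypercube(d=dim, seed=rng)
        unit = sampler.random(n_starts)
        span_lo = np.array([log_s2_center - 3.0] + [-8.0] * len(active))
        span_hi = np.array([log_s2_center + 2.0] + [8.0] * len(active))
        starts = list(span_lo + unit * (span_hi - span_lo))
    for es in extra_starts or []:
        starts.append(np.asarray(es, float))

    best = None
    n_ok = 0
    for x0 in starts:
        res = minimize(nll, np.clip(x0, lo, hi), method="L-BFGS-B",
                       bounds=list(zip(lo, hi)),
                       options={"ftol": 1e-10, "gtol": 1e-7, "maxiter": 500})
        if np.isfinite(res.fun) and res.fun < 1e9:
            n_ok += 1
            if best is None or res.fun < best.fun:
                best = res
    converged = best is not None and n_ok > 0
    if best is None:
        logger.warning("all %d starts failed for %s", len(starts), model_name)
        return FitResult(model_name, {}, -np.inf, N_PARAMS[model_name], np.inf,
                         False, 0, grid=g, root_prior=root_prior)
    theta = best.x
    params = {"sigma2": float(np.exp(theta[0]))}
    params.update({k: float(v) for k, v in zip(active, theta[1:])})
    logL = float(-best.fun)
    k = N_PARAMS[model_name]
    return FitResult(model_name, params, logL, k, 2 * k - 2 * logL,
                     converged, n_ok, grid=g, root_prior=root_prior)


def fit_all_models(tree: DatedTree, traits: TraitTable,
                   model_names=MODEL_NAMES, n_points: int = DEFAULT_N_POINTS,
                   n_starts: int = 5, seed: int = 0,
                   root_prior: str = "stationary") -> dict[str, FitResult]:
    """Fit a set of models, warm-starting each bounded model from the optimum
    of the model nested inside it (guarantees the nesting chain
    logL(BBMV4) >= logL(BBMV2) >= logL(BBMV1) >= logL(BBM) up to optimizer
    tolerance)."""
    fits: dict[str, FitResult] = {}
    chain = {"BBMV1": "BBM", "BBMV2": "BBMV1", "BBMV4": "BBMV2"}
    shared_grid = default_grid(n_points)
    for name in model_names:
        extra = []
        parent = chain.get(name)
        if parent and parent in fits and fits[parent].converged:
            p = fits[parent].mle_params
            vec = [np.log(p["sigma2"])]
            vec += [p.get(coef, 0.0) for coef in _ACTIVE[name]]
            extra.append(vec)
        g = shared_grid if name in GRID_MODELS and name != "FPK" else None
        fits[name] = fit_model(tree, traits, name, grid=g, n_points=n_points,
                               n_starts=n_starts, seed=seed,
                               root_prior=root_prior, extra_starts=extra)
    return fits


def aic_weights(fits: dict[str, FitResult]) -> pd.Series:
    """Akaike weights over a set of fitted models (sum to 1)."""
    aics = pd.Series({k: f.aic for k, f in fits.items() if np.isfinite(f.aic)})
    d = aics - aics.min()
    w = np.exp(-d / 2.0)
    return w / w.sum()


# ---------------------------------------------------------------------------
# Landscape peak and root state
# ---------------------------------------------------------------------------

def landscape_peak(fit: FitResult) -> dict:
    """Peak of the fitted macroevolutionary landscape, in log10 m and meters.

    A flat fitted potential has no defined peak (every grid point ties);
    reported with ``defined=False``.
    """
    if fit.model_name not in GRID_MODELS:
        raise ValueError("landscape peak requires a grid-model fit")
    model = fit.model
    land = stationary_density(model.grid, model.potential)
    flat = land.density.max() - land.density.min() < 1e-12
    return {
        "defined": not flat,
        "peak_log10": None if flat else land.peak,
        "peak_m": None if flat else float(10.0 ** land.peak),
        "peaks_log10": [] if flat else land.peaks,
        "multimodal": land.multimodal and not flat,
    }


def root_state_distribution(tree: DatedTree, traits: TraitTable,
                            fit: FitResult, root_prior: str | None = None,
                            interval: float = 0.90) -> dict:
    """Posterior density of the root state on the grid plus a central
    credibility interval (cumulative mass 0.05-0.95 by default)."""
    if fit.model_name not in GRID_MODELS:
        raise ValueError("root distribution requires a grid-model fit")
    model = fit.model
    index = _TreeIndex(tree)
    tip_vecs = _tip_vectors(index, traits, model.grid)
    prop = _Propagator(model)
    prior = _root_prior_vector(prop, root_prior or fit.root_prior)
    logL, post = _prune_loglik(index, tip_vecs, prop, prior, return_root=True)
    pts = model.grid.points
    cum = np.cumsum(post)
    lo_q, hi_q = (1 - interval) / 2, 1 - (1 - interval) / 2
    lo = float(pts[int(np.searchsorted(cum, lo_q))])
    hi = float(pts[min(int(np.searchsorted(cum, hi_q)), len(pts) - 1)])
    mode = float(pts[int(np.argmax(post))])
    return {"grid": pts, "density": post, "mode": mode,
            "interval": (lo, hi), "log_likelihood": logL}


# ---------------------------------------------------------------------------
# Forward simulation
# ---------------------------------------------------------------------------

def simulate_fpk(tree: DatedTree, model: FPKModel, seed: int,
                 root_state: float | None = None) -> TraitTable:
    """Simulate tip traits under a grid diffusion model.

    The root state is drawn from the stationary density (or fixed), then each
    branch transitions between grid cells by sampling from exp(Q t) rows.
    Deterministic under ``seed``.
    """
    from .treekit import make_trait_table

    rng = np.random.default_rng(seed)
    prop = _Propagator(model)
    n = model.grid.n_points
    pts = model.grid.points
    if root_state is None:
        root_cell = int(rng.choice(n, p=prop.stationary_mass()))
    else:
        root_cell = int(model.grid.nearest_cell(root_state)[0])
    state: dict[int, int] = {}
    root = tree.tree.seed_node
    state[id(root)] = root_cell
    tip_states: dict[str, float] = {}
    for node in tree.tree.preorder_node_iter():
        if node is root:
            continue
        parent_cell = state[id(node.parent_node)]
        t = node.edge.length or 0.0
        if t == 0:
            cell = parent_cell
        else:
            row = prop.transition_row(parent_cell, t)
            cell = int(rng.choice(n, p=row))
        state[id(node)] = cell
        if node.is_leaf():
            tip_states[DatedTree._label(node)] = float(pts[cell])
    labels = list(tip_states)
    heights = [10.0 ** tip_states[l] for l in labels]
    return make_trait_table(labels, heights)
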