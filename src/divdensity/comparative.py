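"""Phylogenetic regressions of diversification metrics on clade trait medians.

For one tree and one time cutoff, the pipeline is: slice the tree into
unnamed clades; attach trait medians; (for density) pool the clades'
occurrence records into convex-hull areas; compute the diversification
metric per clade; collapse each clade to a single tip on the *backbone*
phylogeny connecting them; regress metric on median log10 height by
generalized least squares with Pagel's lambda residual covariance
(lambda estimated by profile maximum likelihood on [0, 1]).

Sweeps repeat this over a posterior set of trees and a range of cutoffs
(default 5-15 Ma, 1 Myr apart) and summarize the slope distribution per
cutoff.  Decoupling of the two diversification axes is measured as the
Pearson correlation between rate and density across clades, per tree and
cutoff, with the fraction of non-significant correlations reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize_scalar
from scipy.stats import pearsonr, skew, skewtest, spearmanr

from . import divmetrics, georange
from .treekit import CladeSlice, DatedTree, TraitTable, clade_summaries, slice_clades

logger = logging.getLogger(__name__)

DEFAULT_CUTOFFS = tuple(range(5, 16))  # 5..15 Ma, 1 Myr apart


# ---------------------------------------------------------------------------
# Backbone construction
# ---------------------------------------------------------------------------

def backbone_tree(tree: DatedTree, clade_slice: CladeSlice) -> DatedTree:
    """Collapse each sliced clade to one tip on the backbone phylogeny.

    Each clade becomes a tip (labelled by its clade id) hanging from the
    cutoff-crossing branch; branch lengths above the cut are preserved and
    the whole tree is shifted so backbone tips sit at age 0 (the regression
    covariance only uses shared path lengths, which the shift preserves).
    Singleton lineages are excluded, matching their exclusion from the
    regressions.  Requires >= 2 clades.
    """
    if clade_slice.n_clades < 2:
        raise ValueError("backbone needs at least 2 clades")
    cutoff = clade_slice.cutoff_age
    clade_by_node = {id(c._node): c for c in clade_slice.clades}

    def render(node):
        """Newick fragment for the surviving subtree rooted at ``node``
        (a node older than the cutoff), returned as (fragment, top_age);
        the parent measures the connecting edge as its own age minus
        top_age, which transparently suppresses unifurcations left by
        dropped singleton lineages."""
        parts = []
        for ch in node.child_nodes():
            if ch.age > cutoff:
                sub = render(ch)
                if sub is not None:
                    frag, top_age = sub
                    parts.append((frag, node.age - top_age))
            else:
                clade = clade_by_node.get(id(ch))
                if clade is not None:
                    parts.append((clade.clade_id, node.age - cutoff))
        if not parts:
            return None
        if len(parts) == 1:
            frag, blen = parts[0]
            return (frag, node.age - blen)
        inner = ",".join(f"{frag}:{blen:.17g}" for frag, blen in parts)
        return (f"({inner})", node.age)

    out = render(tree.tree.seed_node)
    if out is None:
        raise ValueError("no clades survive on the backbone")
    frag, _ = out
    if not frag.startswith("("):
        raise ValueError("backbone collapsed to a single tip")
    return DatedTree.from_newick(frag + ";")


# ---------------------------------------------------------------------------
# PGLS with Pagel's lambda
# ---------------------------------------------------------------------------

@dataclass
class PglsFit:
    """A lambda-model phylogenetic regression of y on x."""

    slope: float
    intercept: float
    lambda_: float
    slope_se: float
    slope_ci95: tuple[float, float]
    p_value: float
    n_clades: int
    log_likelihood: float

    @property
    def significant(self) -> bool:
        lo, hi = self.slope_ci95
        return lo > 0 or hi < 0


def _lambda_cov(C: np.ndarray, lam: float) -> np.ndarray:
    V = lam * C
    np.fill_diagonal(V, np.diag(C))
    return V


def _profile_nll(lam: float, y: np.ndarray, X: np.ndarray, C: np.ndarray) -> float:
    V = _lambda_cov(C, lam)
    n = len(y)
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return 1e10
    logdet = 2.0 * np.log(np.diag(L)).sum()
    Xs = np.linalg.solve(L, X)
    ys = np.linalg.solve(L, y)
    beta, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
    resid = ys - Xs @ beta
    s2 = float(resid @ resid) / n
    if s2 <= 0:
        return 1e10
    return 0.5 * (n * np.log(2 * np.pi) + n * np.log(s2) + logdet + n)


def pgls_fit(y, x, cov, lambda_fixed: float | None = None) -> PglsFit:
    """GLS regression of y on x with lambda-scaled phylogenetic covariance.

    ``cov`` is the Brownian covariance of the backbone (DataFrame or array,
    aligned with y and x).  lambda is estimated by profiling the ML over a
    101-point grid on [0, 1] followed by a local bounded refine; boundary
    optima are reported as exactly 0 or 1.  Coefficient standard errors and
    the 95% CI use a t distribution with n - 2 df.
    """
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    C = cov.to_numpy() if isinstance(cov, pd.DataFrame) else np.asarray(cov, float)
    n = len(y)
    if n < 3:
        raise ValueError("PGLS needs at least 3 clades")
    if C.shape != (n, n):
        raise ValueError("covariance shape does not match data")
    X = np.column_stack([np.ones(n), x])

    if lambda_fixed is not None:
        lam_hat = float(lambda_fixed)
    else:
        grid = np.linspace(0.0, 1.0, 101)
        nlls = [_profile_nll(l, y, X, C) for l in grid]
        i = int(np.argmin(nlls))
        lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, 100)]
        if hi > lo:
            res = minimize_scalar(_profile_nll, bounds=(lo, hi), method="bounded",
                                  args=(y, X, C), options={"xatol": 1e-6})
            lam_hat = float(res.x) if res.fun <= nlls[i] else float(grid[i])
        else:
            lam_hat = float(grid[i])
        if lam_hat < 1e-4:
            lam_hat = 0.0
        elif lam_hat > 1 - 1e-4:
            lam_hat = 1.0

    V = _lambda_cov(C, lam_hat)
    model = sm.GLS(y, X, sigma=V)
    fit = model.fit()
    ci = fit.conf_int(alpha=0.05)
    return PglsFit(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        lambda_=lam_hat,
        slope_se=float(fit.bse[1]),
        slope_ci95=(float(ci[1][0]), float(ci[1][1])),
        p_value=float(fit.pvalues[1]),
        n_clades=n,
        log_likelihood=float(-_profile_nll(lam_hat, y, X, C)),
    )


# ---------------------------------------------------------------------------
# Per-tree x cutoff metric table
# ---------------------------------------------------------------------------

def clade_metric_table(tree: DatedTree, cutoff: float, traits: TraitTable,
                       records: pd.DataFrame | None = None,
                       base: str = "e",
                       stem_age_mode: str = "stem") -> tuple[pd.DataFrame, CladeSlice]:
    """One row per usable clade: n, stem age, trait median, area, metrics.

    ``stem_age_mode='stem'`` uses the age of the crossing branch's parent
    node; ``'cutoff'`` uses the cutoff itself (sensitivity option).  Area and
    density columns are NaN when no records are supplied; clades with a
    degenerate hull get NaN density and are excluded from density regressions.
    """
    sl = slice_clades(tree, cutoff)
    clades = clade_summaries(sl, traits)
    rows = []
    for c in clades:
        t = c.stem_age if stem_age_mode == "stem" else cutoff
        row = {
            "clade_id": c.clade_id,
            "n": c.n,
            "stem_age": t,
            "median_height_log10": c.median_height_log10,
            "rate": divmetrics.net_diversification_rate(c.n, t, base=base),
            "area_km2": np.nan,
            "density": np.nan,
            "raw_ratio": np.nan,
            "log_ratio": np.nan,
            "log_log": np.nan,
        }
        if records is not None:
            est = georange.clade_range_area(c.tip_set, records, clade_id=c.clade_id)
            if est.ok:
                m = divmetrics.clade_metrics(c.clade_id, c.n, t, est.area_km2,
                                             base=base)
                row.update(area_km2=est.area_km2, density=m.density,
                           raw_ratio=m.raw_ratio, log_ratio=m.log_ratio,
                           log_log=m.log_log)
        rows.append(row)
    return pd.DataFrame(rows), sl


# ---------------------------------------------------------------------------
# Sweeps
# ---------------------------------------------------------------------------

@dataclass
class SweepResult:
    """PGLS fits per (tree, cutoff) plus per-cutoff slope summaries."""

    fits: pd.DataFrame      # tree_id, cutoff, slope, se, ci, lambda, p, n_clades
    summary: pd.DataFrame   # per cutoff: median slope, quartiles, frac significant
    metric: str
    skipped: list


def _summarize_sweep(fits: pd.DataFrame, metric: str, skipped) -> SweepResult:
    if len(fits) == 0:
        return SweepResult(fits, pd.DataFrame(), metric, skipped)
    grp = fits.groupby("cutoff")
    summary = pd.DataFrame({
        "n_fits": grp.size(),
        "median_slope": grp["slope"].median(),
        "q25_slope": grp["slope"].quantile(0.25),
        "q75_slope": grp["slope"].quantile(0.75),
        "frac_significant": grp["significant"].mean(),
        "frac_negative": grp.apply(
            lambda g: float((g["slope"] < 0).mean()), include_groups=False),
    }).reset_index()
    return SweepResult(fits, summary, metric, skipped)


def height_metric_sweep(trees, traits: TraitTable,
                        metric: str = "density",
                        cutoffs=DEFAULT_CUTOFFS,
                        records: pd.DataFrame | None = None,
                        base: str = "e",
                        stem_age_mode: str = "stem",
                        min_clades: int = 3) -> SweepResult:
    """PGLS of a diversification metric on clade median height, swept over
    posterior trees and time cutoffs.  Tree x cutoff cells with fewer than
    ``min_clades`` usable clades are skipped and logged."""
    if metric not in ("rate", "density", "raw_ratio", "log_ratio", "log_log"):
        raise ValueError(f"unknown metric {metric!r}")
    if metric != "rate" and records is None:
        raise ValueError("density metrics need occurrence records")
    rows, skipped = [], []
    for tree_id, tree in enumerate(trees):
        for cutoff in cutoffs:
            if not (0 < cutoff < tree.root_age):
                skipped.append((tree_id, cutoff, "cutoff outside tree depth"))
                continue
            table, sl = clade_metric_table(tree, cutoff, traits, records,
                                           base=base, stem_age_mode=stem_age_mode)
            usable = table.dropna(subset=[metric, "median_height_log10"])
            if len(usable) < min_clades:
                skipped.append((tree_id, cutoff, f"{len(usable)} usable clades"))
                continue
            bb = backbone_tree(tree, sl)
            C = bb.vcv(usable["clade_id"].tolist())
            fit = pgls_fit(usable[metric], usable["median_height_log10"], C)
            rows.append({
                "tree_id": tree_id, "cutoff": cutoff, "slope": fit.slope,
                "intercept": fit.intercept, "lambda": fit.lambda_,
                "slope_se": fit.slope_se, "ci_lo": fit.slope_ci95[0],
                "ci_hi": fit.slope_ci95[1], "p_value": fit.p_value,
                "n_clades": fit.n_clades, "significant": fit.significant,
            })
    if skipped:
        logger.info("sweep skipped %d tree x cutoff cells", len(skipped))
    return _summarize_sweep(pd.DataFrame(rows), metric, skipped)


@dataclass
class DecouplingResult:
    """Rate-density correlations per (tree, cutoff) and their summary."""

    cells: pd.DataFrame  # tree_id, cutoff, r, p_value, n_clades
    mean_r: float
    sd_r: float
    frac_nonsignificant: float


def rate_density_decoupling(trees, traits: TraitTable, records: pd.DataFrame,
                            cutoffs=DEFAULT_CUTOFFS, base: str = "e",
                            stem_age_mode: str = "stem",
                            method: str = "pearson",
                            min_clades: int = 3) -> DecouplingResult:
    """Correlation between diversification rate and density across clades,
    one coefficient per tree x cutoff; summarized as mean +- sd and the
    fraction of comparisons non-significant at the 5% level."""
    corr = pearsonr if method == "pearson" else spearmanr
    rows = []
    for tree_id, tree in enumerate(trees):
        for cutoff in cutoffs:
            if not (0 < cutoff < tree.root_age):
                continue
            table, _ = clade_metric_table(tree, cutoff, traits, records,
                                          base=base, stem_age_mode=stem_age_mode)
            usable = table.dropna(subset=["rate", "density"])
            if len(usable) < min_clades:
                continue
            r, p = corr(usable["rate"], usable["density"])
            rows.append({"tree_id": tree_id, "cutoff": cutoff, "r": float(r),
                         "p_value": float(p), "n_clades": len(usable)})
    cells = pd.DataFrame(rows)
    if len(cells) == 0:
        return DecouplingResult(cells, np.nan, np.nan, np.nan)
    return DecouplingResult(
        cells,
        mean_r=float(cells["r"].mean()),
        sd_r=float(cells["r"].std()),
        frac_nonsignificant=float((cells["p_value"] >= 0.05).mean()),
    )


# ---------------------------------------------------------------------------
# Trait distribution
# ---------------------------------------------------------------------------

def trait_distribution_summary(traits: TraitTable) -> dict:
    """Sample skewness of log10 height and the D'Agostino skewness test."""
    x = traits.data["height_log10"].to_numpy(float)
    if len(x) < 8:
        raise ValueError("D'Agostino skewness test needs n >= 8")
    if np.ptp(x) == 0:
        return {"skew": np.nan, "z": np.nan, "p_value": np.nan, "defined": False}
    z, p = skewtest(x)
    return {"skew": float(skew(x)), "z": float(z), "p_value": float(p),
            "defined": True}
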