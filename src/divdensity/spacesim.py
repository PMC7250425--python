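"""Spatially explicit individual-based simulator of migration and speciation.

Used to validate diversification-density metrics: individuals of an
initially monotypic clade live on a W x H grid of local communities with
carrying capacity K, reproduce, migrate between neighbouring cells, and
speciate; at the end the clade's richness n and occupied hull area A feed
the four candidate density metrics (log(n)/sqrt(A), n/A, log(n)/A,
log(n)/log(A)).  A metric that measures the spatial scale of diversification
should fall as migration speeds range expansion, fall as the available
landscape grows, rise with local carrying capacity, and not care how new
species are delimited (speciation mode).

Update rules (one concrete realization of the scheme; isolated here so
alternates can be swapped):

1. *Reproduction-regulation*: each occupied cell is refilled to exactly K
   offspring, species drawn multinomially in proportion to local abundance.
2. *Migration*: every individual independently moves with probability m to
   one of its 4 neighbour cells (uniform); moves off the edge are cancelled.
3. *Speciation*: each extant species independently speciates with
   probability s.  ``point_mutation``: the individuals of the species in one
   random occupied cell become a new species.  ``vicariance``: the species'
   occupied cells are split by a random axis-aligned line and one side
   becomes a new species.
4. Species with zero individuals are marked extinct (extinction is emergent;
   there is no separate extinction parameter).

Areas are convex hulls of occupied cell footprints (unit squares) in
squared cell lengths, computed with the same planar hull machinery as the
geographic range module; the raw occupied-cell count is also reported.

Default parameters put the community at its drift-invasion packing
equilibrium: dispersal slow enough that species ranges stay at one to a few
cells (where the two speciation modes carve indistinguishable daughters)
and runs long enough that richness has stopped climbing, so sweeps measure
equilibrium responses rather than transient expansion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from . import divmetrics
from .georange import hull_area_km2

logger = logging.getLogger(__name__)

SPECIATION_MODES = ("point_mutation", "vicariance")


@dataclass(frozen=True)
class SimParams:
    """Parameters of one simulation run."""

    width: int = 5
    height: int = 5
    carrying_capacity: int = 20
    migration_rate: float = 0.02
    speciation_rate: float = 0.1
    speciation_mode: str = "point_mutation"
    n_steps: int = 1500
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.migration_rate <= 1 and 0 <= self.speciation_rate <= 1):
            raise ValueError("rates must lie in [0, 1]")
        if min(self.width, self.height, self.carrying_capacity) < 1:
            raise ValueError("grid dimensions and K must be >= 1")
        if self.speciation_mode not in SPECIATION_MODES:
            raise ValueError(f"speciation_mode must be one of {SPECIATION_MODES}")


@dataclass
class SimResult:
    """Outcome of one run: richness, areas, metrics, and the species tree."""

    params: SimParams
    n_species: int                    # extant richness
    area: float                       # clade hull area, squared cell lengths
    cell_count_area: float            # number of occupied cells (option B area)
    metrics: dict                     # density, raw_ratio, log_ratio, log_log
    species_parent: list              # parent species id per species (-1 = root)
    species_extant: list
    occupied_cells: dict              # species id -> (k, 2) array of cells
    events: list = field(default_factory=list)
    extinct_run: bool = False


def _migrate_all(counts: np.ndarray, m: float, rng: np.random.Generator
                 ) -> np.ndarray:
    """Move Binomial(count, m) individuals per (species, cell) to uniform
    4-neighbours; off-grid moves are cancelled.  Count is conserved."""
    movers = rng.binomial(counts, m)
    stay = counts - movers
    north = rng.binomial(movers, 0.25)
    rem = movers - north
    south = rng.binomial(rem, 1.0 / 3.0)
    rem = rem - south
    east = rng.binomial(rem, 0.5)
    west = rem - east
    out = stay.astype(np.int64)
    # rows are axis 1 (y), columns axis 2 (x); edge movers bounce back
    out[:, :-1] += north[:, 1:]
    out[:, 0] += north[:, 0]
    out[:, 1:] += south[:, :-1]
    out[:, -1] += south[:, -1]
    out[:, :, 1:] += east[:, :, :-1]
    out[:, :, -1] += east[:, :, -1]
    out[:, :, :-1] += west[:, :, 1:]
    out[:, :, 0] += west[:, :, 0]
    return out


def run_simulation(params: SimParams) -> SimResult:
    """Run the simulator from a single ancestral species seeded with K
    individuals in the central cell.  Deterministic under ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    H, W, K = params.height, params.width, params.carrying_capacity
    counts = np.zeros((1, H, W), dtype=np.int64)  # rows = live species
    counts[0, H // 2, W // 2] = K
    row_ids = [0]          # row index -> species id in the registry
    parent = [-1]
    extinct = [False]
    events: list[dict] = []

    for step in range(params.n_steps):
        # 1. reproduction-regulation: refill each occupied cell to K
        totals = counts.sum(axis=0)
        n_sp = counts.shape[0]
        if n_sp == 1:
            counts[0][totals > 0] = K
        else:
            single = (counts > 0).sum(axis=0) == 1
            occupied_mask = totals > 0
            pure = single & occupied_mask
            if pure.any():
                sel = counts[:, pure]
                sel[sel > 0] = K
                counts[:, pure] = sel
            mixed = occupied_mask & ~single
            if mixed.any():
                cols = counts[:, mixed].T.astype(float)       # (cells, S)
                probs = cols / cols.sum(axis=1, keepdims=True)
                counts[:, mixed] = rng.multinomial(K, probs).T

        # 2. migration
        if params.migration_rate > 0:
            counts = _migrate_all(counts, params.migration_rate, rng)

        # 3. speciation
        speciate = rng.random(counts.shape[0]) < params.speciation_rate
        for row in np.nonzero(speciate)[0]:
            if not counts[row].any():
                continue
            cells = np.column_stack(np.nonzero(counts[row]))  # (k, 2) = (y, x)
            if len(cells) < 2:
                # speciation subdivides a range; a single-cell range cannot
                # subdivide (a "speciation" there would just relabel the
                # species), so 1-cell species skip the event in both modes
                continue
            new_grid = np.zeros((H, W), dtype=np.int64)
            if params.speciation_mode == "point_mutation":
                y, x = cells[rng.integers(len(cells))]
                new_grid[y, x] = counts[row, y, x]
                counts[row, y, x] = 0
            else:  # vicariance
                split = _vicariance_split(cells, rng)
                if split is None:
                    continue
                new_grid[split[:, 0], split[:, 1]] = counts[row, split[:, 0],
                                                            split[:, 1]]
                counts[row, split[:, 0], split[:, 1]] = 0
            counts = np.concatenate([counts, new_grid[None]], axis=0)
            parent.append(row_ids[row])
            extinct.append(False)
            row_ids.append(len(parent) - 1)
            events.append({"step": step, "event": "speciation",
                           "parent": parent[-1], "child": len(parent) - 1})

        # 4. extinction: drop empty rows, mark their species extinct
        alive = counts.reshape(counts.shape[0], -1).any(axis=1)
        if not alive.all():
            for row in np.nonzero(~alive)[0]:
                sp = row_ids[row]
                extinct[sp] = True
                events.append({"step": step, "event": "extinction",
                               "species": sp})
            counts = counts[alive]
            row_ids = [r for r, a in zip(row_ids, alive) if a]
        if counts.shape[0] == 0:
            logger.warning("all individuals extinct at step %d", step)
            return SimResult(params, 0, 0.0, 0.0, {}, parent, [False] * len(parent),
                             {}, events, extinct_run=True)

    extant = list(row_ids)
    occupied = {
        sp: np.column_stack(np.nonzero(counts[row]))
        for row, sp in enumerate(row_ids)
    }
    all_cells = np.column_stack(np.nonzero(counts.sum(axis=0)))
    # hull over occupied cell footprints (each cell a unit square, so the
    # four corners of every occupied cell enter the hull): a fully occupied
    # W x H grid then has area W*H, not (W-1)*(H-1) as center-point hulls
    # would give; coordinates in cell lengths (x=col, y=row)
    corners = np.concatenate([
        all_cells[:, ::-1] + off
        for off in ((-0.5, -0.5), (-0.5, 0.5), (0.5, -0.5), (0.5, 0.5))
    ]).astype(float)
    est = hull_area_km2(None, None, clade_id="clade", projected=corners)
    area = est.area_km2
    n = len(extant)
    metrics = {}
    if n >= 1 and area > 0:
        for variant, key in (("log_sqrt", "density"), ("raw_ratio", "raw_ratio"),
                             ("log_ratio", "log_ratio"), ("log_log", "log_log")):
            try:
                metrics[key] = divmetrics.diversification_density(n, area, variant)
            except ValueError:
                metrics[key] = np.nan
    return SimResult(
        params=params, n_species=n, area=float(area),
        cell_count_area=float(len(all_cells)), metrics=metrics,
        species_parent=parent, species_extant=[not e for e in extinct],
        occupied_cells=occupied, events=events,
    )


def _vicariance_split(cells: np.ndarray, rng: np.random.Generator):
    """Cells going to the daughter species: one side of a random axis-aligned
    split.  Tries a random axis first, then the other; None if the range
    cannot be split (single distinct coordinate on both axes)."""
    for axis in rng.permutation(2):
        vals = np.unique(cells[:, axis])
        if len(vals) < 2:
            continue
        thr = vals[rng.integers(len(vals) - 1)]  # split after thr
        side = cells[:, axis] <= thr
        if rng.random() < 0.5:
            side = ~side
        return cells[side]
    return None


# ---------------------------------------------------------------------------
# Metric validation sweeps
# ---------------------------------------------------------------------------

METRIC_KEYS = ("density", "raw_ratio", "log_ratio", "log_log")


def _run_level(base: SimParams, reps: int, seed: int, **overrides) -> pd.DataFrame:
    rows = []
    n_extinct = 0
    for rep in range(reps):
        p = SimParams(**{**_params_dict(base), **overrides,
                         "seed": seed + rep})
        res = run_simulation(p)
        if res.extinct_run or not res.metrics:
            n_extinct += 1
            continue
        rows.append({"n": res.n_species, "area": res.area, **res.metrics,
                     **overrides})
    df = pd.DataFrame(rows)
    df.attrs["n_excluded"] = n_extinct
    return df


def _params_dict(p: SimParams) -> dict:
    return {f: getattr(p, f) for f in
            ("width", "height", "carrying_capacity", "migration_rate",
             "speciation_rate", "speciation_mode", "n_steps", "seed")}


def metric_validation_experiment(
    base: SimParams | None = None,
    m_levels=(0.01, 0.05, 0.2, 0.5),
    k_levels=(5, 20, 80),
    dim_levels=((4, 4), (6, 6), (9, 9)),
    modes=SPECIATION_MODES,
    reps: int = 20,
    mode_reps: int = 250,
    seed: int = 0,
) -> dict:
    """Sweep each driver with the others held at ``base`` and correlate every
    metric with the driver (Spearman); speciation-mode sensitivity is the
    standardized mean difference of each metric between modes.

    Returns ``{"correlations": DataFrame(driver, metric, rho, p),
    "mode_smd": DataFrame(metric, smd), "runs": DataFrame}``; runs ending in
    total extinction are excluded and counted in ``runs.attrs``.
    """
    base = base or SimParams()
    frames = []
    corr_rows = []
    seed_step = 10_000

    sweeps = {
        "migration_rate": [{"migration_rate": v} for v in m_levels],
        "carrying_capacity": [{"carrying_capacity": v} for v in k_levels],
        "landscape_area": [{"width": w, "height": h} for w, h in dim_levels],
    }
    s = seed
    for driver, levels in sweeps.items():
        dfs = []
        for ov in levels:
            df = _run_level(base, reps, s, **ov)
            s += seed_step
            if driver == "landscape_area":
                df["driver_value"] = ov["width"] * ov["height"]
            else:
                df["driver_value"] = list(ov.values())[0]
            dfs.append(df)
        sweep_df = pd.concat(dfs, ignore_index=True)
        sweep_df["driver"] = driver
        frames.append(sweep_df)
        for metric in METRIC_KEYS:
            vals = sweep_df.dropna(subset=[metric])
            rho, p = spearmanr(vals["driver_value"], vals[metric])
            corr_rows.append({"driver": driver, "metric": metric,
                              "rho": float(rho), "p_value": float(p)})

    mode_frames = {}
    for mode in modes:
        mode_frames[mode] = _run_level(base, mode_reps, s,
                                       speciation_mode=mode)
        s += seed_step
    smd_rows = []
    for metric in METRIC_KEYS:
        a = mode_frames[modes[0]][metric].dropna().to_numpy()
        b = mode_frames[modes[1]][metric].dropna().to_numpy()
        pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
        smd = (a.mean() - b.mean()) / pooled if pooled > 0 else np.nan
        smd_rows.append({"metric": metric, "smd": float(smd),
                         "n_a": len(a), "n_b": len(b)})

    runs = pd.concat(frames, ignore_index=True)
    return {
        "correlations": pd.DataFrame(corr_rows),
        "mode_smd": pd.DataFrame(smd_rows),
        "runs": runs,
        "mode_runs": mode_frames,
    }


def species_tree_is_valid(result: SimResult) -> bool:
    """The species registry must be a rooted tree: species 0 is the single
    root and every other species' parent precedes it."""
    parents = result.species_parent
    if not parents or parents[0] != -1:
        return False
    return all(0 <= p < i for i, p in enumerate(parents[1:], start=1))
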