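"""Synthetic inputs with the statistical structure the analysis assumes.

Generates, from one root seed: a posterior-like set of dated ultrametric
trees (one birth-death topology, node ages jittered multiplicatively); log10
heights evolved under a bounded-landscape diffusion whose peak sits near the
short-stature end (so the synthetic height distribution is right-skewed on
the log scale, as in succulent-dominated clades); per-species occurrence
clouds whose spatial dispersion scales with height as base_km * height_m^gamma
(tall plants disperse farther, so short plants get tighter ranges); and
GBIF-style contaminant records (botanical-garden locality strings and
out-of-region points) for the cleaning filters to catch.

The ``coupled`` scenario (gamma > 0) builds in the mechanism under test --
short plants => smaller ranges => higher diversification density; the
``null`` scenario (gamma = 0) breaks the height-range link and is the
calibration fixture for false-positive rates.
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from shapely.geometry import box, Point, Polygon

from . import fpk
from .treekit import DatedTree, TraitTable, make_trait_table

KM_PER_DEGREE_LAT = 111.195  # spherical Earth, R = 6371 km


def default_region() -> Polygon:
    """Synthetic study region: a southern-African-like lon/lat box."""
    return box(12.0, -35.0, 40.0, -15.0)


@dataclass
class SynthConfig:
    """Generator settings; defaults are the study conditions emulated."""

    n_tips: int = 200
    birth_rate: float = 0.15          # Myr^-1
    death_rate: float = 0.05          # Myr^-1
    root_age: float = 29.0            # Myr; tree rescaled to this crown age
    n_posterior_trees: int = 100
    jitter_sd: float = 0.05           # lognormal sd on node ages
    # trait model: bounded landscape with its peak near 3 cm, close enough
    # to the 1 cm bound that simulated log10 heights come out right-skewed
    sigma2: float = 0.06              # (log10 m)^2 Myr^-1
    potential_a: float = 0.0
    potential_b: float = 2.0
    potential_c: float = 4.6
    grid_points: int = 100
    # range model
    mean_occurrences: int = 30        # Poisson mean per species (+3 floor)
    dispersion_base_km: float = 15.0
    gamma: float = 1.0                # dispersion ~ height_m^gamma
    dispersion_noise_sd: float = 0.4  # lognormal scatter on dispersion
    sigma_space_km: float = 60.0      # spatial BM rate for centroids, km/sqrt(Myr)
    garden_fraction: float = 0.05
    out_of_region_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if not self.birth_rate > self.death_rate >= 0:
            raise ValueError("need birth_rate > death_rate >= 0")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        for f in (self.garden_fraction, self.out_of_region_fraction):
            if not 0 <= f <= 1:
                raise ValueError("contamination fractions must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def simulate_bd_tree(n_tips: int, birth_rate: float, death_rate: float,
                     seed: int, root_age: float | None = None) -> DatedTree:
    """Constant-rate birth-death tree conditioned on ``n_tips`` extant
    species (extinct lineages pruned), optionally rescaled to a fixed crown
    age.  Tips are labelled sp0001..spN."""
    from dendropy.model import birthdeath

    rng = random.Random(seed)
    for attempt in range(20):
        try:
            tree = birthdeath.birth_death_tree(
                birth_rate=birth_rate, death_rate=death_rate,
                num_extant_tips=n_tips, rng=rng,
            )
            break
        except Exception:
            if attempt == 19:
                raise RuntimeError(
                    "birth-death simulation failed repeatedly; lower the "
                    "extinction fraction or tip count"
                )
    # the simulator stops exactly at the n-th speciation, leaving a
    # zero-length cherry; extend all pendant edges by the waiting time to
    # the next event so the present falls strictly between events
    t_extra = rng.expovariate(n_tips * (birth_rate + death_rate))
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"sp{i + 1:04d}"
        leaf.edge.length = (leaf.edge.length or 0.0) + t_extra
    dated = DatedTree.from_newick(
        tree.as_string(schema="newick", suppress_rooting=True)
    )
    if root_age is not None:
        factor = root_age / dated.root_age
        for edge in dated.tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= factor
        dated = DatedTree.from_newick(dated.as_newick())
    return dated


def _render_newick(tree: DatedTree, ages: dict) -> str:
    def rec(node):
        age = ages[id(node)]
        if node.is_leaf():
            return DatedTree._label(node), age
        parts = []
        for ch in node.child_nodes():
            frag, ch_age = rec(ch)
            parts.append(f"{frag}:{age - ch_age:.17g}")
        return "(" + ",".join(parts) + ")", age

    frag, _ = rec(tree.tree.seed_node)
    return frag + ";"


def make_posterior_set(tree: DatedTree, n: int, jitter_sd: float,
                       seed: int) -> list[DatedTree]:
    """Emulate a dating posterior: ``n`` copies of the tree with node ages
    jittered by lognormal(0, jitter_sd) factors, constrained so parents stay
    older than children and tips stay at the present.  Topology is kept
    fixed (topological uncertainty is irrelevant to the slicing machinery
    this feeds)."""
    if n < 1:
        raise ValueError("need n >= 1 trees")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        ages: dict = {}
        for node in tree.tree.preorder_node_iter():
            if node.is_leaf():
                ages[id(node)] = 0.0
                continue
            factor = float(rng.lognormal(0.0, jitter_sd)) if jitter_sd > 0 else 1.0
            new_age = node.age * factor
            parent = node.parent_node
            if parent is not None:
                new_age = min(new_age, ages[id(parent)] * 0.9999)
            ages[id(node)] = max(new_age, 1e-9)
        out.append(DatedTree.from_newick(_render_newick(tree, ages)))
    return out


# ---------------------------------------------------------------------------
# Traits
# ---------------------------------------------------------------------------

def trait_model(config: SynthConfig) -> fpk.FPKModel:
    return fpk.FPKModel(
        sigma2=config.sigma2,
        potential=fpk.PotentialCoefficients(
            config.potential_a, config.potential_b, config.potential_c
        ),
        grid=fpk.default_grid(config.grid_points),
        bounded=True,
    )


def simulate_traits(tree: DatedTree, config: SynthConfig, seed: int) -> TraitTable:
    return fpk.simulate_fpk(tree, trait_model(config), seed=seed)


# ---------------------------------------------------------------------------
# Occurrences
# ---------------------------------------------------------------------------

def _uniform_in_polygon(poly: Polygon, rng: np.random.Generator, n: int = 1
                        ) -> np.ndarray:
    minx, miny, maxx, maxy = poly.bounds
    pts = []
    while len(pts) < n:
        x = rng.uniform(minx, maxx)
        y = rng.uniform(miny, maxy)
        if poly.covers(Point(x, y)):
            pts.append((x, y))
    return np.array(pts)


def _species_centroids(tree: DatedTree, config: SynthConfig,
                       rng: np.random.Generator, region: Polygon) -> dict:
    """Centroids evolve as spatial Brownian motion along the tree, reflected
    into the region box: related species sit near each other, so clade range
    areas carry phylogenetic signal (dispersal-limited biogeography) instead
    of being a pure function of species count."""
    minx, miny, maxx, maxy = region.bounds
    root_xy = np.array([rng.uniform(minx, maxx), rng.uniform(miny, maxy)])
    pos = {id(tree.tree.seed_node): root_xy}
    centroids: dict = {}
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        t = max(node.edge.length or 0.0, 1e-9)
        p = pos[id(node.parent_node)]
        step_km = rng.normal(0.0, config.sigma_space_km * np.sqrt(t), 2)
        xy = p + np.array([
            step_km[0] / (KM_PER_DEGREE_LAT * max(np.cos(np.radians(p[1])), 0.1)),
            step_km[1] / KM_PER_DEGREE_LAT,
        ])
        for k, (lo, hi) in enumerate(((minx, maxx), (miny, maxy))):
            span = hi - lo
            v = (xy[k] - lo) % (2 * span)
            xy[k] = lo + (v if v <= span else 2 * span - v)
        pos[id(node)] = xy
        if node.is_leaf():
            centroids[DatedTree._label(node)] = xy
    return centroids


def simulate_occurrences(traits: TraitTable, config: SynthConfig, seed: int,
                         region: Polygon | None = None,
                         tree: DatedTree | None = None) -> pd.DataFrame:
    """Per-species occurrence clouds plus contaminant records.

    Species centroids evolve as spatial Brownian motion on ``tree``
    (uniform-random when no tree is given); each species then gets
    Poisson(mean)+3 bivariate-normal points with standard deviation
    base_km * height_m^gamma km (longitude scaled by cos(latitude));
    contaminants are appended per the configured fractions.
    """
    region = region or default_region()
    rng = np.random.default_rng(seed)
    if tree is not None:
        centroids = _species_centroids(tree, config, rng, region)
    else:
        pts = _uniform_in_polygon(region, rng, len(traits))
        centroids = {sp: pts[i] for i, sp in enumerate(traits.species)}
    rows = []
    for _, sp in traits.data.iterrows():
        centroid = centroids[sp["species"]]
        sd_km = (config.dispersion_base_km * sp["height_m"] ** config.gamma
                 * float(rng.lognormal(0.0, config.dispersion_noise_sd)))
        n_pts = int(rng.poisson(config.mean_occurrences)) + 3
        sd_lat = sd_km / KM_PER_DEGREE_LAT
        sd_lon = sd_km / (KM_PER_DEGREE_LAT *
                          max(np.cos(np.radians(centroid[1])), 0.1))
        lon = rng.normal(centroid[0], sd_lon, n_pts)
        lat = rng.normal(centroid[1], sd_lat, n_pts)
        lon = np.clip(lon, -179.9, 179.9)
        lat = np.clip(lat, -89.9, 89.9)
        for x, y in zip(lon, lat):
            rows.append({"species": sp["species"], "lon": float(x),
                         "lat": float(y), "locality_text": ""})
    clean = pd.DataFrame(rows)

    contaminants = []
    n_clean = len(clean)
    species = traits.data["species"].tolist()
    n_garden = int(round(config.garden_fraction * n_clean))
    for _ in range(n_garden):
        c = _uniform_in_polygon(region, rng)[0]
        contaminants.append({
            "species": species[rng.integers(len(species))],
            "lon": float(c[0]), "lat": float(c[1]),
            "locality_text": rng.choice([
                "Botanical Garden, cultivated",
                "garden escape near town",
                "Kirstenbosch botanical collection",
            ]),
        })
    n_out = int(round(config.out_of_region_fraction * n_clean))
    for _ in range(n_out):
        contaminants.append({
            "species": species[rng.integers(len(species))],
            "lon": float(rng.uniform(-10, 10)),
            "lat": float(rng.uniform(40, 60)),
            "locality_text": "",
        })
    if contaminants:
        clean = pd.concat([clean, pd.DataFrame(contaminants)], ignore_index=True)
    return clean


# ---------------------------------------------------------------------------
# End-to-end fixture
# ---------------------------------------------------------------------------

@dataclass
class Bundle:
    """A complete synthetic input set for the analysis pipeline."""

    trees: list
    traits: TraitTable
    occurrences: pd.DataFrame
    region: Polygon
    manifest: dict = field(default_factory=dict)


def end_to_end_fixture(scenario: str = "coupled", seed: int = 0,
                       config: SynthConfig | None = None) -> Bundle:
    """Build a full input bundle.

    ``coupled``: dispersion scales with height (gamma > 0) and the landscape
    peak sits near the short bound.  ``null``: gamma = 0, heights and range
    sizes are independent.
    """
    if scenario not in ("coupled", "null"):
        raise ValueError("scenario must be 'coupled' or 'null'")
    if config is None:
        config = SynthConfig(seed=seed)
    if scenario == "null":
        config = SynthConfig(**{**asdict(config), "gamma": 0.0,
                                "dispersion_base_km": 40.0})
    root = np.random.SeedSequence(config.seed)
    s_tree, s_post, s_trait, s_occ = [
        int(s.generate_state(1)[0] % (2**31 - 1)) for s in root.spawn(4)
    ]
    base_tree = simulate_bd_tree(config.n_tips, config.birth_rate,
                                 config.death_rate, s_tree, config.root_age)
    trees = make_posterior_set(base_tree, config.n_posterior_trees,
                               config.jitter_sd, s_post)
    traits = simulate_traits(base_tree, config, s_trait)
    region = default_region()
    occurrences = simulate_occurrences(traits, config, s_occ, region,
                                       tree=base_tree)
    manifest = {"scenario": scenario, "config": asdict(config)}
    return Bundle(trees=trees, traits=traits, occurrences=occurrences,
                  region=region, manifest=manifest)


def write_bundle(bundle: Bundle, outdir) -> dict:
    """Write trees (Newick), traits and occurrences (CSV), and a manifest
    JSON recording the generating parameters; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tree_dir = outdir / "trees"
    tree_dir.mkdir(exist_ok=True)
    paths = {"trees": []}
    for i, t in enumerate(bundle.trees):
        p = tree_dir / f"tree_{i:03d}.nwk"
        p.write_text(t.as_newick() + "\n")
        paths["trees"].append(str(p))
    traits_path = outdir / "traits.csv"
    bundle.traits.data[["species", "height_m"]].to_csv(traits_path, index=False)
    occ_path = outdir / "occurrences.csv"
    bundle.occurrences.to_csv(occ_path, index=False)
    region_path = outdir / "region.geojson"
    region_path.write_text(json.dumps({
        "type": "Feature", "properties": {},
        "geometry": bundle.region.__geo_interface__,
    }))
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(bundle.manifest, indent=2))
    paths.update(traits=str(traits_path), occurrences=str(occ_path),
                 region=str(region_path), manifest=str(manifest_path))
    return paths
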