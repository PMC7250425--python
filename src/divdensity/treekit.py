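"""Dated phylogenies: parsing, validation, time-slicing into unnamed clades.

Trees are rooted, ultrametric, with branch lengths in Myr.  Ages are
measured backward from the present, so every extant tip sits at age 0 and
the root carries the largest age.  The central operation is slicing a tree
at a time cutoff ``c``: every branch whose parent node is older than ``c``
and whose child node is at or below ``c`` defines one *unnamed clade* --
the set of extant tips descending from that branch.  Lineages crossing the
cutoff with a single surviving species are set aside as singletons.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: default relative tolerance (fraction of root age) for the ultrametricity check;
#: trees dated by rate smoothing are never exactly ultrametric.
DEFAULT_ULTRAMETRIC_RTOL = 1e-6


class TreeValidationError(ValueError):
    """Raised when a tree violates the dated-ultrametric contract."""


class TraitTableError(ValueError):
    """Raised for malformed trait tables (missing columns, bad heights)."""


# ---------------------------------------------------------------------------
# DatedTree
# ---------------------------------------------------------------------------

class DatedTree:
    """A rooted ultrametric phylogeny with node ages in Myr (tips at 0).

    Wraps a :class:`dendropy.Tree`; every node gets an ``age`` attribute
    computed top-down from branch lengths.  Tip labels must be unique.
    """

    def __init__(self, tree: dendropy.Tree, rtol: float = DEFAULT_ULTRAMETRIC_RTOL):
        self._tree = tree
        self._compute_ages(rtol)

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, newick_text: str, rtol: float = DEFAULT_ULTRAMETRIC_RTOL) -> "DatedTree":
        try:
            tree = dendropy.Tree.get(
                data=newick_text,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises assorted error types
            raise TreeValidationError(f"malformed Newick: {exc}") from exc
        return cls(tree, rtol=rtol)

    @classmethod
    def from_path(cls, path, rtol: float = DEFAULT_ULTRAMETRIC_RTOL) -> "DatedTree":
        with open(path) as fh:
            return cls.from_newick(fh.read(), rtol=rtol)

    def _compute_ages(self, rtol: float) -> None:
        self._tree.is_rooted = True
        root = self._tree.seed_node
        # depth = distance from root along branches
        depth = {root: 0.0}
        for node in self._tree.preorder_node_iter():
            if node is root:
                continue
            if node.edge.length is None:
                raise TreeValidationError(
                    f"branch above {self._label(node)!r} has no length"
                )
            depth[node] = depth[node.parent_node] + node.edge.length
        leaves = list(self._tree.leaf_node_iter())
        if not leaves:
            raise TreeValidationError("tree has no tips")
        root_age = max(depth[lf] for lf in leaves)
        if root_age <= 0:
            raise TreeValidationError("tree has zero depth")
        tol = rtol * root_age
        for lf in leaves:
            if abs(depth[lf] - root_age) > tol:
                raise TreeValidationError(
                    f"tree is not ultrametric: tip {self._label(lf)!r} sits at age "
                    f"{root_age - depth[lf]:.6g}, beyond tolerance {tol:.3g}"
                )
        for node in self._tree.preorder_node_iter():
            node.age = root_age - depth[node]
        for lf in leaves:
            lf.age = 0.0  # snap within-tolerance tips exactly to the present
        labels = [self._label(lf) for lf in leaves]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeValidationError(f"duplicate tip labels: {dupes}")
        self._root_age = root_age
        self._tip_labels = labels

    @staticmethod
    def _label(node) -> str:
        if node.taxon is not None:
            return node.taxon.label
        return node.label or "<unnamed>"

    # -- accessors ----------------------------------------------------------

    @property
    def tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def root_age(self) -> float:
        return self._root_age

    @property
    def tip_labels(self) -> list[str]:
        return list(self._tip_labels)

    @property
    def n_tips(self) -> int:
        return len(self._tip_labels)

    def as_newick(self) -> str:
        return self._tree.as_string(
            schema="newick", suppress_rooting=True,
            real_value_format_specifier=".17g",
        ).strip()

    def leaf_nodes(self):
        return self._tree.leaf_node_iter()

    def vcv(self, labels: Sequence[str] | None = None) -> pd.DataFrame:
        """Brownian phylogenetic covariance matrix.

        Entry (i, j) is the shared path length from the root down to the MRCA
        of tips i and j, i.e. root age minus MRCA age; diagonal entries equal
        the root age (total evolutionary time per tip).
        """
        labels = list(labels) if labels is not None else self.tip_labels
        pos = {l: i for i, l in enumerate(labels)}
        n = len(labels)
        C = np.zeros((n, n))
        np.fill_diagonal(C, self._root_age)
        # postorder sweep: tips of different child subtrees share time
        # root_age - node.age at their MRCA `node`
        tip_idx: dict = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                lab = self._label(node)
                tip_idx[node] = (
                    np.array([pos[lab]]) if lab in pos else np.empty(0, dtype=int)
                )
                continue
            groups = [tip_idx.pop(ch) for ch in node.child_nodes()]
            shared = self._root_age - node.age
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    if len(groups[i]) and len(groups[j]):
                        C[np.ix_(groups[i], groups[j])] = shared
                        C[np.ix_(groups[j], groups[i])] = shared
            tip_idx[node] = np.concatenate(groups) if groups else np.empty(0, int)
        found = {l for l in labels} & {self._label(lf) for lf in self._tree.leaf_node_iter()}
        missing = [l for l in labels if l not in found]
        if missing:
            raise KeyError(f"tips not in tree: {missing}")
        return pd.DataFrame(C, index=labels, columns=labels)


# ---------------------------------------------------------------------------
# Trait table
# ---------------------------------------------------------------------------

@dataclass
class TraitTable:
    """Species trait table: maximum vegetative height in meters and its log10.

    ``height_log10 = log10(height_m)`` exactly; heights must be positive.
    """

    data: pd.DataFrame  # columns: species, height_m, height_log10

    def __post_init__(self):
        req = {"species", "height_m", "height_log10"}
        if not req.issubset(self.data.columns):
            raise TraitTableError(f"trait table needs columns {sorted(req)}")

    @property
    def species(self) -> list[str]:
        return self.data["species"].tolist()

    def height_log10(self, species: Iterable[str]) -> pd.Series:
        sub = self.data.set_index("species")["height_log10"]
        return sub.reindex(list(species))

    def as_series(self) -> pd.Series:
        return self.data.set_index("species")["height_log10"]

    def __len__(self) -> int:
        return len(self.data)


def make_trait_table(species: Sequence[str], height_m: Sequence[float]) -> TraitTable:
    """Build a TraitTable from parallel vectors, validating positivity."""
    h = np.asarray(height_m, dtype=float)
    if np.any(~np.isfinite(h)) or np.any(h <= 0):
        bad = [s for s, v in zip(species, h) if not (np.isfinite(v) and v > 0)]
        raise TraitTableError(f"non-positive or non-finite heights for: {bad}")
    df = pd.DataFrame(
        {"species": list(species), "height_m": h, "height_log10": np.log10(h)}
    )
    return TraitTable(df)


def load_trait_table(csv) -> TraitTable:
    """Read a ``species,height_m`` CSV; rows with missing height are dropped
    with a warning (taxonomic compilations typically lose a species or two)."""
    if isinstance(csv, (str, bytes)) and "\n" in str(csv):
        df = pd.read_csv(io.StringIO(str(csv)), float_precision="round_trip")
    else:
        df = pd.read_csv(csv, float_precision="round_trip")
    if not {"species", "height_m"}.issubset(df.columns):
        raise TraitTableError("trait CSV must have columns species,height_m")
    n0 = len(df)
    df = df.dropna(subset=["height_m"]).copy()
    if len(df) < n0:
        logger.warning("dropped %d species with missing height", n0 - len(df))
    return make_trait_table(df["species"].tolist(), df["height_m"].to_numpy())


# ---------------------------------------------------------------------------
# Clade slicing
# ---------------------------------------------------------------------------

@dataclass
class CladeSummary:
    """An unnamed clade produced by a time-cutoff slice.

    ``n`` counts extant tips, ``stem_age`` is the age of the parent node of
    the branch crossing the cutoff, and ``median_height_log10`` (attached by
    :func:`clade_summaries`) is the trait median over the clade's tips.
    """

    clade_id: str
    tip_set: frozenset
    n: int
    stem_age: float
    cutoff_age: float
    median_height_log10: float | None = None
    n_trait_tips: int | None = None
    flagged: bool = False  # fewer than 2 trait-bearing tips
    _node: object = field(default=None, repr=False, compare=False)


@dataclass
class CladeSlice:
    """Result of slicing a tree at one cutoff: clades (>= 2 tips) + singletons."""

    cutoff_age: float
    clades: list[CladeSummary]
    singletons: list[str]

    @property
    def n_clades(self) -> int:
        return len(self.clades)

    @property
    def n_lineages(self) -> int:
        return len(self.clades) + len(self.singletons)


def slice_clades(tree: DatedTree, cutoff_age: float) -> CladeSlice:
    """Cut the tree at ``cutoff_age`` Ma and return the unnamed clades.

    A branch crosses the cut when ``parent.age > cutoff >= child.age``
    (half-open, so a node exactly at the cutoff falls below the cut).  Each
    crossing branch with >= 2 descendant tips yields a clade whose stem age is
    the parent node's age; single-tip lineages are returned as singletons.
    """
    if not (0 < cutoff_age < tree.root_age):
        raise ValueError(
            f"cutoff {cutoff_age} must lie strictly between 0 and the root age "
            f"{tree.root_age:.4g}"
        )
    clades: list[CladeSummary] = []
    singletons: list[str] = []
    idx = 0
    for node in tree.tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            continue
        if parent.age > cutoff_age >= node.age:
            tips = frozenset(
                DatedTree._label(lf) for lf in node.leaf_iter()
            ) if not node.is_leaf() else frozenset({DatedTree._label(node)})
            if len(tips) >= 2:
                clades.append(
                    CladeSummary(
                        clade_id=f"c{cutoff_age:g}_{idx:03d}",
                        tip_set=tips,
                        n=len(tips),
                        stem_age=parent.age,
                        cutoff_age=cutoff_age,
                        _node=node,
                    )
                )
                idx += 1
            else:
                singletons.append(next(iter(tips)))
    return CladeSlice(cutoff_age=cutoff_age, clades=clades, singletons=singletons)


def clade_summaries(clade_slice: CladeSlice, traits: TraitTable) -> list[CladeSummary]:
    """Attach the median log10 height over each clade's trait-bearing tips.

    Tips missing from the trait table are ignored inside the median; a clade
    left with < 2 trait-bearing tips keeps its species count but is flagged;
    a clade with none is dropped with a warning.
    """
    out: list[CladeSummary] = []
    lookup = traits.as_series()
    for clade in clade_slice.clades:
        vals = lookup.reindex(sorted(clade.tip_set)).dropna()
        if len(vals) == 0:
            logger.warning(
                "clade %s has no trait-bearing tips; dropped", clade.clade_id
            )
            continue
        clade.median_height_log10 = float(np.median(vals.to_numpy()))
        clade.n_trait_tips = int(len(vals))
        clade.flagged = len(vals) < 2
        out.append(clade)
    return out


def perturbed_tree_set_stats(
    trees: Sequence[DatedTree], cutoff: float
) -> dict:
    """Clade counts per tree at one cutoff, plus their median across trees."""
    if len(trees) == 0:
        raise ValueError("need at least one tree")
    counts = [slice_clades(t, cutoff).n_clades for t in trees]
    return {"counts": counts, "median": float(np.median(counts))}


def slice_to_frame(clade_slice: CladeSlice) -> pd.DataFrame:
    """Tabulate a slice for CSV export."""
    rows = [
        {
            "cutoff": clade_slice.cutoff_age,
            "clade_id": c.clade_id,
            "n": c.n,
            "stem_age": c.stem_age,
            "median_height_log10": c.median_height_log10,
            "tips": ";".join(sorted(c.tip_set)),
        }
        for c in clade_slice.clades
    ]
    return pd.DataFrame(
        rows,
        columns=["cutoff", "clade_id", "n", "stem_age", "median_height_log10", "tips"],
    )
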