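"""Core data containers shared by every module.

Unit convention: after ingest every coordinate in the package is a physical
position in micrometres (µm).  Voxel indices appear only at the file boundary
(:mod:`cmiwarp.io_formats`), where voxel index ``i`` along an axis maps to
physical position ``i * scale`` (0-based, origin at the voxel corner).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "VoxelScale",
    "SkeletonNode",
    "SkeletonTree",
    "Skeleton",
    "LandmarkSet",
    "ScoringTable",
    "SkeletonValidationError",
]


class SkeletonValidationError(ValueError):
    """A skeleton violates a structural invariant (connectivity, acyclicity)."""


@dataclass(frozen=True)
class VoxelScale:
    """Physical size of one voxel in µm along each axis.

    May be anisotropic; e.g. in vivo two-photon stacks are commonly
    (0.358, 0.358, 5.0) µm.
    """

    sx: float
    sy: float
    sz: float

    def __post_init__(self) -> None:
        arr = np.asarray([self.sx, self.sy, self.sz], dtype=float)
        if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
            raise ValueError(f"voxel scale must be finite and strictly positive, got {arr}")

    def as_array(self) -> np.ndarray:
        return np.array([self.sx, self.sy, self.sz], dtype=float)

    @property
    def voxel_volume_um3(self) -> float:
        return float(self.sx * self.sy * self.sz)


@dataclass
class SkeletonNode:
    """One skeleton node: a 3D point in µm with an optional vessel radius."""

    id: int
    position: np.ndarray  # shape (3,), µm
    radius: float | None = None
    attrs: dict = field(default_factory=dict)  # unknown file attributes, preserved on write

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"node {self.id}: position must be 3 finite coordinates")


@dataclass
class SkeletonTree:
    """One connected, acyclic tree of skeleton nodes."""

    id: int
    name: str
    nodes: dict[int, SkeletonNode]
    edges: set[tuple[int, int]]  # stored as sorted (min, max) node-id pairs

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def validate(self) -> None:
        for a, b in self.edges:
            for nid in (a, b):
                if nid not in self.nodes:
                    raise SkeletonValidationError(
                        f"tree {self.id!r}: edge ({a}, {b}) references missing node {nid}"
                    )
        g = self.graph()
        if len(self.nodes) > 0 and not nx.is_connected(g):
            comps = sorted(nx.connected_components(g), key=len, reverse=True)
            orphans = sorted(set().union(*comps[1:]))
            raise SkeletonValidationError(
                f"tree {self.id!r} is disconnected; orphan nodes: {orphans}"
            )
        if len(self.edges) >= len(self.nodes) and len(self.nodes) > 0:
            raise SkeletonValidationError(f"tree {self.id!r} contains a cycle")


@dataclass
class Skeleton:
    """A set of traced trees (e.g. the blood vessels of one imaging modality).

    Node ids are unique across the whole skeleton, so trees can be merged
    into one graph and junctions referenced by bare node id.
    """

    trees: list[SkeletonTree]
    dataset_name: str = ""
    voxel_scale: VoxelScale | None = None

    def validate(self) -> None:
        seen: set[int] = set()
        for tree in self.trees:
            dup = seen & set(tree.nodes)
            if dup:
                raise SkeletonValidationError(
                    f"node ids {sorted(dup)} appear in more than one tree"
                )
            seen |= set(tree.nodes)
            tree.validate()

    # -- convenience accessors -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return sum(len(t.nodes) for t in self.trees)

    def iter_nodes(self) -> Iterator[SkeletonNode]:
        for tree in self.trees:
            yield from tree.nodes.values()

    def node(self, node_id: int) -> SkeletonNode:
        for tree in self.trees:
            if node_id in tree.nodes:
                return tree.nodes[node_id]
        raise KeyError(f"node id {node_id} not in skeleton")

    def node_positions(self) -> dict[int, np.ndarray]:
        return {n.id: n.position for n in self.iter_nodes()}

    def graph(self) -> nx.Graph:
        """All trees merged into one undirected graph (a forest)."""
        g = nx.Graph()
        for tree in self.trees:
            g.add_nodes_from(tree.nodes)
            g.add_edges_from(tree.edges)
        return g

    def transform_positions(self, fn) -> "Skeleton":
        """Return a copy with every node position mapped through ``fn``.

        ``fn`` takes an (n, 3) array and returns an (n, 3) array; topology,
        radii and attributes are untouched.
        """
        new_trees = []
        for tree in self.trees:
            ids = list(tree.nodes)
            pts = np.array([tree.nodes[i].position for i in ids], dtype=float)
            warped = np.asarray(fn(pts.reshape(-1, 3)), dtype=float).reshape(-1, 3)
            nodes = {
                i: SkeletonNode(i, warped[j], tree.nodes[i].radius, dict(tree.nodes[i].attrs))
                for j, i in enumerate(ids)
            }
            new_trees.append(SkeletonTree(tree.id, tree.name, nodes, set(tree.edges)))
        return Skeleton(new_trees, self.dataset_name, self.voxel_scale)


@dataclass
class LandmarkSet:
    """Ordered pairs of corresponding points between two modality spaces.

    ``moving`` and ``fixed`` are (n, 3) µm coordinate arrays; row *i* of each
    is the same physical feature seen in the two spaces.  Only rows with
    ``active`` set take part in warp fitting.
    """

    names: list[str]
    moving: np.ndarray
    fixed: np.ndarray
    active: np.ndarray
    moving_name: str = "moving"
    fixed_name: str = "fixed"

    def __post_init__(self) -> None:
        self.moving = np.asarray(self.moving, dtype=float).reshape(-1, 3)
        self.fixed = np.asarray(self.fixed, dtype=float).reshape(-1, 3)
        self.active = np.asarray(self.active, dtype=bool).reshape(-1)
        n = len(self.names)
        if not (self.moving.shape[0] == self.fixed.shape[0] == self.active.shape[0] == n):
            raise ValueError("names, moving, fixed and active must have equal length")
        if len(set(self.names)) != n:
            dup = sorted({x for x in self.names if self.names.count(x) > 1})
            raise ValueError(f"duplicate landmark names: {dup}")
        if not (np.all(np.isfinite(self.moving)) and np.all(np.isfinite(self.fixed))):
            raise ValueError("landmark coordinates must be finite")

    def __len__(self) -> int:
        return len(self.names)

    @property
    def n_active(self) -> int:
        return int(self.active.sum())

    def active_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        return self.moving[self.active], self.fixed[self.active]

    def swapped(self) -> "LandmarkSet":
        """The same correspondences with moving and fixed spaces exchanged.

        Used to fit the reverse-direction warp; warps are always fitted per
        direction, never inverted numerically.
        """
        return LandmarkSet(
            list(self.names),
            self.fixed.copy(),
            self.moving.copy(),
            self.active.copy(),
            moving_name=self.fixed_name,
            fixed_name=self.moving_name,
        )

    def subset(self, mask: np.ndarray) -> "LandmarkSet":
        mask = np.asarray(mask, dtype=bool)
        return LandmarkSet(
            [n for n, m in zip(self.names, mask) if m],
            self.moving[mask],
            self.fixed[mask],
            self.active[mask],
            self.moving_name,
            self.fixed_name,
        )


#: Artefact flag columns used when a scoring table does not declare its own.
#: Nine are the named staining-artefact categories of the scoring scheme
#: ("undefined" collects poorly stained samples matching no defined type);
#: the remaining three are configurable placeholders.
DEFAULT_ARTEFACT_COLUMNS: tuple[str, ...] = (
    "sideways",
    "crack",
    "central",
    "bubble",
    "smoky",
    "patchy",
    "necrotic",
    "sandy",
    "wrinkled",
    "detached",
    "granular",
    "undefined",
)

#: Metadata columns recognised on scoring tables (all optional except
#: experiment_id).
SCORING_METADATA_COLUMNS: tuple[str, ...] = (
    "experiment_id",
    "experiment_start_date",
    "fixation_method",
    "fixative_formula",
    "staining_method",
    "anaesthetics",
    "culling_method",
    "use_of_dexamethasone",
    "use_of_cold_buffer",
    "mouse_line",
    "tissue_type",
    "slice_index",
    "thickness",
    "two_p_history",
)


@dataclass
class ScoringTable:
    """Per-sample binary artefact scores plus experiment metadata.

    ``data`` holds one row per sample.  Each artefact column is coerced to
    {0, 1}: 1 means the artefact is present in that sample.  ``experiment_id``
    groups samples prepared together, the unit for prevalence/penetrance.
    """

    data: pd.DataFrame
    artefact_columns: tuple[str, ...] = DEFAULT_ARTEFACT_COLUMNS

    def __post_init__(self) -> None:
        self.artefact_columns = tuple(self.artefact_columns)
        missing = [c for c in self.artefact_columns if c not in self.data.columns]
        if missing:
            raise ValueError(f"scoring table lacks artefact columns: {missing}")
        if "experiment_id" not in self.data.columns:
            raise ValueError("scoring table lacks an experiment_id column")
        flags = self.data[list(self.artefact_columns)]
        bad = ~flags.isin([0, 1]).all(axis=None)
        if bad:
            raise ValueError("artefact flags must be 0 or 1")
        exp = self.data["experiment_id"].astype(str)
        if (exp.str.strip() == "").any() or exp.isna().any():
            raise ValueError("every sample needs a non-empty experiment_id")
        if "thickness" in self.data.columns:
            th = pd.to_numeric(self.data["thickness"], errors="coerce")
            if (th.dropna() <= 0).any():
                raise ValueError("thickness must be > 0 where present")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_samples(self) -> int:
        return len(self.data)

    @property
    def n_experiments(self) -> int:
        return int(self.data["experiment_id"].nunique())

    def flags(self) -> pd.DataFrame:
        return self.data[list(self.artefact_columns)].astype(int)
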