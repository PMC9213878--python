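"""Synthetic vascular scenes and scoring tables.

Real inputs to the pipeline are manual tracings of cortical/olfactory-bulb
vasculature imaged by several modalities, hand-seeded landmark pairs, and
hand-scored artefact tables.  This module generates stand-ins with the same
statistical structure so that every stage of the package is testable without
any imaging data:

* :func:`generate_vessel_tree` grows a tortuous branching tree inside a
  ~(160 µm)³ box, the scale of a typical traced vasculature volume;
* a :class:`GroundTruthScene` equips the tree with one smooth, diffeomorphic
  deformation per imaging modality, landmark/tracing jitter levels and
  per-modality radius thresholds below which vessels are not resolvable;
* :func:`simulate_modality` renders the tree as one modality would see it —
  deformed, jittered, with thin branches pruned consistently across
  modalities (as unresolvable vessels are deleted from *all* datasets to
  keep them comparable) — together with a landmark set pairing that
  modality to the reference anatomy space;
* :func:`generate_scoring_table` draws Bernoulli artefact flags with
  optional per-experiment random effects and plausible metadata.

Everything is fully determined by the seeds passed in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cmiwarp.core import (
    LandmarkSet,
    ScoringTable,
    Skeleton,
    SkeletonNode,
    SkeletonTree,
    VoxelScale,
)

__all__ = [
    "AffineDeformation",
    "SmoothDeformation",
    "random_smooth_deformation",
    "generate_vessel_tree",
    "junction_node_ids",
    "prune_thin_branches",
    "GroundTruthScene",
    "simulate_modality",
    "simulate_scene",
    "scene_junction_table",
    "two_modality_scene",
    "default_scene",
    "generate_scoring_table",
    "DEFAULT_ARTEFACT_PROBS",
]


# --------------------------------------------------------------------------
# deformations
# --------------------------------------------------------------------------

@dataclass
class AffineDeformation:
    """x ↦ A·x + b.  The identity is ``AffineDeformation.identity()``."""

    matrix: np.ndarray
    offset: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        self.offset = np.asarray(self.offset, dtype=float).reshape(3)

    @classmethod
    def identity(cls) -> "AffineDeformation":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def scaling(cls, s: float | tuple[float, float, float]) -> "AffineDeformation":
        return cls(np.diag(np.broadcast_to(np.asarray(s, dtype=float), 3)), np.zeros(3))

    def __call__(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float).reshape(-1, 3)
        return pts @ self.matrix.T + self.offset


@dataclass
class SmoothDeformation:
    """Affine part plus a sum of Gaussian displacement bumps.

    x ↦ A·x + b + Σᵢ aᵢ · exp(−‖x − cᵢ‖² / (2 wᵢ²)).  With bump amplitudes
    ≤ ~10 % of the domain size and widths ≥ ~40 µm the map stays
    diffeomorphic (positive Jacobian determinant) while being genuinely
    nonrigid — the scale of realistic tissue deformation during sample
    preparation.
    """

    affine: AffineDeformation
    centers: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    amplitudes: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    widths: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float).reshape(-1, 3)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float).reshape(-1, 3)
        self.widths = np.asarray(self.widths, dtype=float).reshape(-1)
        if not (len(self.centers) == len(self.amplitudes) == len(self.widths)):
            raise ValueError("centers, amplitudes and widths must have equal length")
        if np.any(self.widths <= 0):
            raise ValueError("bump widths must be positive")

    def __call__(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float).reshape(-1, 3)
        out = self.affine(pts)
        for c, a, w in zip(self.centers, self.amplitudes, self.widths):
            d2 = np.sum((pts - c) ** 2, axis=1)
            out = out + a * np.exp(-d2 / (2.0 * w * w))[:, None]
        return out

    def min_jacobian_det(self, box_size: float, grid: int = 6, eps: float = 1e-3) -> float:
        """Smallest finite-difference Jacobian determinant on a probe grid;
        positive everywhere means the map is locally invertible."""
        ax = np.linspace(0, box_size, grid)
        pts = np.array(np.meshgrid(ax, ax, ax)).reshape(3, -1).T
        dets = np.empty(len(pts))
        for i, p in enumerate(pts):
            J = np.empty((3, 3))
            for k in range(3):
                dp = np.zeros(3)
                dp[k] = eps
                J[:, k] = (self(p + dp)[0] - self(p - dp)[0]) / (2 * eps)
            dets[i] = np.linalg.det(J)
        return float(dets.min())


def random_smooth_deformation(
    rng: np.random.Generator,
    box_size: float = 160.0,
    n_bumps: int = 4,
    max_amplitude: float | None = None,
    min_width: float = 40.0,
    scale_range: tuple[float, float] = (0.95, 1.05),
) -> SmoothDeformation:
    """Draw a random diffeomorphic deformation of the scene box.

    Default bump amplitudes stay below 10 % of the box size and widths at or
    above 40 µm, within what a 50–170-landmark warp can capture.
    """
    if max_amplitude is None:
        max_amplitude = 0.10 * box_size
    scales = rng.uniform(*scale_range, size=3)
    shear = rng.normal(0.0, 0.01, size=(3, 3))
    matrix = np.diag(scales) + shear - np.diag(np.diag(shear))
    offset = rng.uniform(-0.05 * box_size, 0.05 * box_size, size=3)
    centers = rng.uniform(0, box_size, size=(n_bumps, 3))
    direction = rng.standard_normal((n_bumps, 3))
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    amplitudes = direction * rng.uniform(0.2 * max_amplitude, max_amplitude, size=(n_bumps, 1))
    widths = rng.uniform(min_width, 1.8 * min_width, size=n_bumps)
    return SmoothDeformation(AffineDeformation(matrix, offset), centers, amplitudes, widths)


# --------------------------------------------------------------------------
# vessel-tree generation
# --------------------------------------------------------------------------

def _tortuous_walk(
    rng: np.random.Generator,
    start: np.ndarray,
    direction: np.ndarray,
    length: float,
    step: float,
    persistence: float,
    box_size: float,
) -> np.ndarray:
    """Persistent random walk confined to [0, box]³; returns the new points
    (excluding the start)."""
    pts = []
    pos = start.astype(float).copy()
    d = direction / np.linalg.norm(direction)
    travelled = 0.0
    while travelled < length:
        noise = rng.standard_normal(3)
        d = persistence * d + (1 - persistence) * noise
        d /= np.linalg.norm(d)
        nxt = pos + step * d
        for k in range(3):  # reflect at box faces
            if nxt[k] < 0 or nxt[k] > box_size:
                d[k] = -d[k]
                nxt[k] = np.clip(nxt[k], 0, box_size)
        pos = nxt
        pts.append(pos.copy())
        travelled += step
    return np.array(pts) if pts else np.zeros((0, 3))


def _branch_direction(rng: np.random.Generator, parent_dir: np.ndarray, angle: float) -> np.ndarray:
    """Rotate the parent direction by ``angle`` around a random perpendicular axis."""
    d = parent_dir / np.linalg.norm(parent_dir)
    perp = rng.standard_normal(3)
    perp -= perp.dot(d) * d
    perp /= np.linalg.norm(perp)
    return np.cos(angle) * d + np.sin(angle) * perp


def generate_vessel_tree(
    seed: int,
    box_size: float = 160.0,
    n_junctions: int = 10,
    radius_range: tuple[float, float] = (0.5, 4.0),
    step_um: float = 2.0,
    persistence: float = 0.62,
    branch_length_range: tuple[float, float] = (18.0, 45.0),
) -> Skeleton:
    """Grow a random tortuous vascular tree inside a (box_size µm)³ box.

    The tree is built breadth-first from a trunk: each finished branch either
    bifurcates (its end node becomes a degree-3 junction) while the junction
    budget lasts, or terminates as a free end.  The result is connected and
    acyclic with exactly ``n_junctions`` branching nodes.  Branch radii
    shrink monotonically from trunk to tips within ``radius_range``, so
    pruning by a radius threshold always removes whole subtrees.  Each node
    records its branch id in ``attrs['branch']``.  Polylines are persistent
    random walks, giving realistic tortuosity (arc length noticeably above
    chord length).
    """
    if n_junctions < 1:
        raise ValueError("need n_junctions >= 1")
    r_min, r_max = radius_range
    if not (0 < r_min <= r_max):
        raise ValueError(f"invalid radius range {radius_range}")
    rng = np.random.default_rng(seed)

    nodes: dict[int, SkeletonNode] = {}
    edges: set[tuple[int, int]] = set()
    next_id = 1

    def add_node(pos: np.ndarray, radius: float, branch: int) -> int:
        nonlocal next_id
        nid = next_id
        next_id += 1
        nodes[nid] = SkeletonNode(nid, np.clip(pos, 0, box_size), radius, {"branch": branch})
        return nid

    start = rng.uniform(0.2 * box_size, 0.8 * box_size, size=3)
    start[2] = 0.0  # trunk enters through a box face, like a penetrating vessel
    trunk_dir = np.array([0.0, 0.0, 1.0]) + 0.3 * rng.standard_normal(3)
    root_id = add_node(start, r_max, 0)

    # queue entries: (branch id, start node id, direction, radius)
    queue: list[tuple[int, int, np.ndarray, float]] = [(0, root_id, trunk_dir, r_max)]
    next_branch = 1
    junctions_made = 0
    junction_ids: list[int] = []

    while queue:
        branch, start_node, direction, radius = queue.pop(0)
        length = rng.uniform(*branch_length_range)
        pts = _tortuous_walk(rng, nodes[start_node].position, direction, length, step_um, persistence, box_size)
        prev = start_node
        for p in pts:
            nid = add_node(p, radius, branch)
            edges.add((min(prev, nid), max(prev, nid)))
            prev = nid
        end_dir = (
            nodes[prev].position - nodes[start_node].position
            if prev != start_node
            else direction
        )
        if np.linalg.norm(end_dir) == 0:
            end_dir = direction
        if junctions_made < n_junctions and len(pts) > 0:
            junctions_made += 1
            junction_ids.append(prev)
            for _ in range(2):
                angle = rng.uniform(np.deg2rad(25), np.deg2rad(65))
                child_dir = _branch_direction(rng, end_dir, angle)
                child_radius = max(r_min, radius * rng.uniform(0.60, 0.85))
                queue.append((next_branch, prev, child_dir, child_radius))
                next_branch += 1

    if junctions_made < n_junctions:
        raise ValueError(
            f"could only place {junctions_made} of {n_junctions} junctions; "
            "increase box_size or shorten branches"
        )
    tree = SkeletonTree(1, "synthetic-vessels", nodes, edges)
    skeleton = Skeleton([tree], dataset_name=f"synthetic-seed{seed}",
                        voxel_scale=VoxelScale(1.0, 1.0, 1.0))
    skeleton.validate()
    return skeleton


def junction_node_ids(skeleton: Skeleton) -> list[int]:
    """Node ids of degree ≥ 3 (vessel branch points)."""
    g = skeleton.graph()
    return sorted(n for n in g.nodes if g.degree(n) >= 3)


def prune_thin_branches(skeleton: Skeleton, radius_threshold: float) -> Skeleton:
    """Remove all nodes on branches thinner than ``radius_threshold`` µm.

    Radii shrink from trunk to tips in generated trees, so thresholding
    removes whole subtrees and the remainder stays connected.  Raises if
    nothing remains or no junction survives.
    """
    if radius_threshold <= 0:
        return skeleton
    trees = []
    for tree in skeleton.trees:
        keep = {
            i for i, n in tree.nodes.items() if n.radius is None or n.radius >= radius_threshold
        }
        if not keep:
            continue
        nodes = {i: tree.nodes[i] for i in keep}
        edges = {(a, b) for a, b in tree.edges if a in keep and b in keep}
        trees.append(SkeletonTree(tree.id, tree.name, nodes, edges))
    pruned = Skeleton(trees, skeleton.dataset_name, skeleton.voxel_scale)
    if pruned.n_nodes == 0:
        raise ValueError(
            f"radius threshold {radius_threshold} µm is above every vessel radius: "
            "nothing remains"
        )
    pruned.validate()
    if not junction_node_ids(pruned):
        raise ValueError(
            f"radius threshold {radius_threshold} µm pruned away every junction"
        )
    return pruned


# --------------------------------------------------------------------------
# ground-truth scenes
# --------------------------------------------------------------------------

@dataclass
class GroundTruthScene:
    """A base anatomy plus everything needed to render it per modality.

    ``base`` lives in the *reference* space.  For each modality name the
    scene holds a deformation (reference → modality coordinates), a landmark
    jitter σ (µm, applied per axis to both ends of each landmark pair), a
    tracing jitter σ (µm, applied per skeleton node), and the vessel radius
    (µm) below which the modality cannot resolve a vessel.  ``seed`` fully
    determines every simulated output.
    """

    base: Skeleton
    deformations: dict[str, AffineDeformation | SmoothDeformation]
    landmark_sigma: dict[str, float]
    tracing_sigma: dict[str, float]
    radius_threshold: dict[str, float]
    seed: int
    n_landmarks: int = 60
    junction_landmark_fraction: float = 0.7
    box_size: float = 160.0

    def __post_init__(self) -> None:
        mods = set(self.deformations)
        for name, d in (
            ("landmark_sigma", self.landmark_sigma),
            ("tracing_sigma", self.tracing_sigma),
            ("radius_threshold", self.radius_threshold),
        ):
            if set(d) != mods:
                raise ValueError(f"{name} keys {sorted(d)} do not match modalities {sorted(mods)}")

    @property
    def modalities(self) -> list[str]:
        return sorted(self.deformations)

    def validate_diffeomorphic(self, grid: int = 5) -> None:
        """Check every smooth deformation has positive Jacobian determinant
        on a probe grid over the scene box."""
        for m, d in self.deformations.items():
            if isinstance(d, SmoothDeformation):
                det = d.min_jacobian_det(self.box_size, grid=grid)
            else:
                det = float(np.linalg.det(d.matrix))
            if det <= 0:
                raise ValueError(f"deformation for {m!r} is not orientation-preserving (min det {det:.3g})")

    def _rng(self, modality: str, stream: int) -> np.random.Generator:
        idx = self.modalities.index(modality)
        return np.random.default_rng([self.seed, idx, stream])


def _effective_threshold(scene: GroundTruthScene) -> float:
    # Vessels unresolvable in ANY modality are deleted from all of them,
    # so the matched skeletons stay comparable.
    return max(scene.radius_threshold.values())


def simulate_modality(scene: GroundTruthScene, modality: str) -> tuple[Skeleton, LandmarkSet]:
    """Render the scene as one modality sees it.

    Returns the modality's skeleton (base pruned of thin vessels, deformed,
    with per-node tracing jitter; node ids preserved) and a landmark set
    whose *moving* points are in the modality space and *fixed* points in
    the reference space — exactly what :func:`cmiwarp.warping.fit_warp`
    needs to map this modality back into the reference frame.
    """
    if modality not in scene.deformations:
        raise KeyError(f"unknown modality {modality!r}; scene has {scene.modalities}")
    deform = scene.deformations[modality]
    pruned = prune_thin_branches(scene.base, _effective_threshold(scene))

    # skeleton: deform + tracing jitter (unit noise drawn unconditionally so
    # different sigmas reuse the same realization, scaled)
    rng_trace = scene._rng(modality, stream=1)
    noise = rng_trace.standard_normal((pruned.n_nodes, 3))
    sigma_t = scene.tracing_sigma[modality]

    ids = [n.id for n in pruned.iter_nodes()]
    id_index = {nid: i for i, nid in enumerate(ids)}

    skeleton = pruned.transform_positions(deform)
    for node in skeleton.iter_nodes():
        node.position = node.position + sigma_t * noise[id_index[node.id]]
    skeleton.dataset_name = f"{scene.base.dataset_name}:{modality}"

    # landmarks: junction-biased sample of base points
    rng_lm = scene._rng(modality, stream=2)
    junctions = junction_node_ids(pruned)
    others = [i for i in ids if i not in set(junctions)]
    n_j = min(len(junctions), int(round(scene.junction_landmark_fraction * scene.n_landmarks)))
    n_o = scene.n_landmarks - n_j
    if n_o > len(others):
        raise ValueError("scene skeleton too small for the requested number of landmarks")
    chosen = list(rng_lm.choice(junctions, size=n_j, replace=False)) + list(
        rng_lm.choice(others, size=n_o, replace=False)
    )
    base_pts = np.array([pruned.node(int(i)).position for i in chosen], dtype=float)
    sigma_l = scene.landmark_sigma[modality]
    noise_mv = rng_lm.standard_normal((len(chosen), 3))
    noise_fx = rng_lm.standard_normal((len(chosen), 3))
    moving = deform(base_pts) + sigma_l * noise_mv
    fixed = base_pts + sigma_l * noise_fx
    landmarks = LandmarkSet(
        [f"L{idx:03d}" for idx in range(len(chosen))],
        moving,
        fixed,
        np.ones(len(chosen), dtype=bool),
        moving_name=modality,
        fixed_name="reference",
    )
    return skeleton, landmarks


def scene_junction_table(scene: GroundTruthScene) -> dict[str, dict[str, int]]:
    """Matched-junction table for a simulated scene.

    Simulation preserves node ids across modalities, so each surviving
    junction maps to the same id everywhere — standing in for the manual
    cross-modality matching done on real tracings.
    """
    pruned = prune_thin_branches(scene.base, _effective_threshold(scene))
    table: dict[str, dict[str, int]] = {}
    for nid in junction_node_ids(pruned):
        table[f"J{nid:04d}"] = {m: nid for m in scene.modalities}
    return table


def simulate_scene(scene: GroundTruthScene) -> tuple[dict[str, Skeleton], dict[str, LandmarkSet]]:
    """Simulate every modality: returns ({modality: skeleton},
    {modality: landmarks-to-reference})."""
    skeletons, landmark_sets = {}, {}
    for m in scene.modalities:
        skeletons[m], landmark_sets[m] = simulate_modality(scene, m)
    return skeletons, landmark_sets


def two_modality_scene(
    seed: int,
    deformation: AffineDeformation | SmoothDeformation,
    landmark_sigma: float = 0.0,
    tracing_sigma: float = 0.0,
    n_junctions: int = 8,
    n_landmarks: int = 60,
    box_size: float = 160.0,
) -> GroundTruthScene:
    """A minimal scene: a reference modality (identity) and one moving
    modality under ``deformation`` with the given landmark jitter σ (µm).

    The workhorse for controlled recovery experiments: with an affine
    deformation and σ = 0 the pipeline error is pure discretization; raising
    σ isolates the effect of landmark-seeding noise on warping accuracy.
    """
    base = generate_vessel_tree(seed, box_size=box_size, n_junctions=n_junctions)
    return GroundTruthScene(
        base=base,
        deformations={"ref": AffineDeformation.identity(), "mov": deformation},
        landmark_sigma={"ref": 0.0, "mov": float(landmark_sigma)},
        tracing_sigma={"ref": 0.0, "mov": float(tracing_sigma)},
        radius_threshold={"ref": 0.0, "mov": 0.0},
        seed=seed,
        n_landmarks=n_landmarks,
        box_size=box_size,
    )


def default_scene(
    seed: int,
    n_junctions: int = 12,
    box_size: float = 160.0,
    n_landmarks: int = 60,
    landmark_sigma: dict[str, float] | None = None,
    tracing_sigma: float = 0.3,
) -> GroundTruthScene:
    """A three-modality scene shaped like a typical correlative experiment.

    Modalities ``2p`` (in vivo two-photon: strongest deformation relative to
    the embedded state, noisiest landmarks), ``sxrt`` (X-ray tomography:
    mild deformation, cannot resolve vessels thinner than ~1 µm radius) and
    ``sbem`` (block-face EM: the reference space, identity deformation).
    Bump amplitudes ≤ 10 % of the box and widths ≥ 40 µm keep deformations
    diffeomorphic and within reach of a ~60-landmark warp.
    """
    rng = np.random.default_rng([seed, 9000])
    base = generate_vessel_tree(seed, box_size=box_size, n_junctions=n_junctions)
    if landmark_sigma is None:
        landmark_sigma = {"2p": 2.0, "sxrt": 0.5, "sbem": 0.3}
    deformations = {
        "2p": random_smooth_deformation(rng, box_size, n_bumps=4, scale_range=(1.00, 1.08)),
        "sxrt": random_smooth_deformation(
            rng, box_size, n_bumps=3, max_amplitude=0.03 * box_size, scale_range=(0.98, 1.02)
        ),
        "sbem": AffineDeformation.identity(),
    }
    scene = GroundTruthScene(
        base=base,
        deformations=deformations,
        landmark_sigma=dict(landmark_sigma),
        tracing_sigma={m: tracing_sigma for m in deformations},
        radius_threshold={"2p": 0.0, "sxrt": 1.0, "sbem": 0.0},
        seed=seed,
        n_landmarks=n_landmarks,
        box_size=box_size,
    )
    scene.validate_diffeomorphic()
    return scene


# --------------------------------------------------------------------------
# scoring tables
# --------------------------------------------------------------------------

#: Default per-artefact Bernoulli probabilities for synthetic tables.  The
#: two dominant mechanical/staining artefacts (sideways, crack) jointly
#: affect ~60 % of samples, ~15 % of samples are uncategorisable
#: ("undefined"), and with independent flags ~20 % of samples carry no
#: artefact at all — the yield regime of a real thick-slice staining
#: pipeline.
DEFAULT_ARTEFACT_PROBS: dict[str, float] = {
    "sideways": 0.40,
    "crack": 0.36,
    "central": 0.08,
    "bubble": 0.05,
    "smoky": 0.06,
    "patchy": 0.05,
    "necrotic": 0.04,
    "sandy": 0.04,
    "wrinkled": 0.03,
    "detached": 0.03,
    "granular": 0.02,
    "undefined": 0.155,
}

_DEFAULT_METADATA_LEVELS: dict[str, tuple] = {
    "fixation_method": ("perfusion", "immersion"),
    "fixative_formula": ("PFA4", "PFA2_GA2.5", "PFA4_GA0.5"),
    "staining_method": ("1sRO", "2sRO"),
    "anaesthetics": ("isoflurane", "ketamine_xylazine"),
    "culling_method": ("perfusion", "decapitation"),
    "use_of_dexamethasone": (0, 1),
    "use_of_cold_buffer": (0, 1),
    "mouse_line": ("C57BL6", "Tbet-cre"),
    "tissue_type": ("first_slice", "deeper_slice", "whole_OB", "half_OB"),
    "thickness": (0.4, 0.6, 0.8, 1.0),
    "two_p_history": (0, 1),
}


def generate_scoring_table(
    seed: int,
    n_samples: int = 427,
    n_experiments: int = 30,
    artefact_probs: dict[str, float] | None = None,
    metadata_spec: dict[str, tuple] | None = None,
    experiment_sigma: float = 0.0,
) -> ScoringTable:
    """Draw a synthetic artefact scoring table.

    Samples are assigned to ``n_experiments`` experiments of (near-)equal
    size.  Each artefact flag is Bernoulli with the given probability; a
    positive ``experiment_sigma`` adds a per-experiment Gaussian shift on
    the logit scale, creating the batch-to-batch variability that makes
    prevalence and penetrance informative.  Metadata levels are drawn per
    experiment (the realistic granularity: a protocol variable is fixed
    within a batch) from ``metadata_spec`` or built-in defaults.
    """
    probs = dict(DEFAULT_ARTEFACT_PROBS if artefact_probs is None else artefact_probs)
    for name, p in probs.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"artefact probability {name}={p} outside [0, 1]")
    if n_samples < 1 or n_experiments < 1 or n_experiments > n_samples:
        raise ValueError("need 1 <= n_experiments <= n_samples")
    levels = dict(_DEFAULT_METADATA_LEVELS)
    if metadata_spec:
        for col, lv in metadata_spec.items():
            if not len(lv):
                raise ValueError(f"metadata column {col!r} has no levels")
            levels[col] = tuple(lv)

    rng = np.random.default_rng(seed)
    base, extra = divmod(n_samples, n_experiments)
    sizes = [base + (1 if e < extra else 0) for e in range(n_experiments)]
    experiment_ids = np.repeat([f"E{e + 1:03d}" for e in range(n_experiments)], sizes)

    df = pd.DataFrame({"sample_id": [f"S{i + 1:04d}" for i in range(n_samples)]})
    df["experiment_id"] = experiment_ids

    artefact_names = list(probs)
    shift = rng.normal(0.0, experiment_sigma, size=(n_experiments, len(artefact_names)))
    logit = lambda p: np.log(p / (1 - p))  # noqa: E731
    expit = lambda x: 1.0 / (1.0 + np.exp(-x))  # noqa: E731
    exp_index = np.repeat(np.arange(n_experiments), sizes)
    for j, name in enumerate(artefact_names):
        p = probs[name]
        if experiment_sigma > 0 and 0 < p < 1:
            per_sample_p = expit(logit(p) + shift[exp_index, j])
        else:
            per_sample_p = np.full(n_samples, p)
        df[name] = (rng.random(n_samples) < per_sample_p).astype(int)

    start = pd.Timestamp("2020-01-06")
    per_exp_meta = {}
    for col, lv in levels.items():
        per_exp_meta[col] = [lv[rng.integers(len(lv))] for _ in range(n_experiments)]
    df["experiment_start_date"] = [
        (start + pd.Timedelta(days=14 * int(e))).date().isoformat() for e in exp_index
    ]
    for col in levels:
        df[col] = [per_exp_meta[col][int(e)] for e in exp_index]
    df["slice_index"] = rng.integers(1, 5, size=n_samples)

    return ScoringTable(df, tuple(artefact_names))
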