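"""Warping-accuracy quantification from matched blood-vessel skeletons.

The procedure compares the *same* blood vessels traced independently in two
or three imaging modalities:

1. vessel branch points (junctions, nodes of degree ≥ 3) are matched across
   modalities by hand and supplied as a label ↔ node-id table;
2. freely ending tracings are trimmed back to the nearest matched junction,
   so every modality covers the same vessels to the same extent
   (:func:`trim_free_ends`);
3. each tracing is split into segments at the matched junctions
   (:func:`split_segments`);
4. per segment, the arc lengths in all modalities are averaged and divided
   by a 0.5 µm step to fix a shared number of interpolation points *n*
   (:func:`compute_step_count`), and each modality's polyline is resampled
   at equal arc-length fractions (:func:`resample_segment`), yielding *n*
   matched nodes per modality;
5. all modalities are warped into one reference space and, for every matched
   node and modality pair, the Euclidean distance between the paired points
   is recorded (:func:`matched_node_distances`);
6. the overall warping accuracy for a modality pair is the mean of all its
   matched-node distances (:func:`summarize_accuracy`); each point counts
   equally, so longer segments contribute more points.

:func:`warping_accuracy` runs steps 2–6 end to end.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from cmiwarp.core import Skeleton, SkeletonTree
from cmiwarp.warping import WarpField, fit_warp

__all__ = [
    "MatchedJunction",
    "SegmentMatch",
    "trim_free_ends",
    "split_segments",
    "compute_step_count",
    "resample_segment",
    "matched_node_distances",
    "summarize_accuracy",
    "warping_accuracy",
    "DEFAULT_STEP_UM",
    "SegmentTopologyError",
]

logger = logging.getLogger(__name__)

#: Interpolation step between matched nodes along a vessel segment (µm).
DEFAULT_STEP_UM = 0.5


class SegmentTopologyError(ValueError):
    """The skeleton/junction combination does not define unambiguous segments."""


@dataclass(frozen=True)
class MatchedJunction:
    """One vessel branch point identified in every modality.

    ``node_ids`` maps modality name → node id in that modality's skeleton.
    """

    label: str
    node_ids: dict[str, int] = field(hash=False)


def junctions_from_table(table: dict[str, dict[str, int]]) -> list[MatchedJunction]:
    """Build :class:`MatchedJunction` objects from a label → {modality: id} map."""
    return [MatchedJunction(label, dict(per_mod)) for label, per_mod in table.items()]


@dataclass
class SegmentMatch:
    """One vessel segment between two matched junctions, in every modality.

    ``polylines`` maps modality → ordered (k, 3) µm node positions running
    from junction ``labels[0]`` to ``labels[1]`` (labels are sorted
    lexicographically, applied identically in every modality, so pairing is
    never silently reversed).  After :meth:`resample`, ``points`` holds the
    *n* matched nodes per modality.
    """

    labels: tuple[str, str]
    polylines: dict[str, np.ndarray]
    n: int | None = None
    points: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def id(self) -> str:
        return f"{self.labels[0]}--{self.labels[1]}"

    def lengths(self) -> dict[str, float]:
        """Per-modality arc length in µm (sum of consecutive node distances)."""
        return {m: _arc_length(p) for m, p in self.polylines.items()}

    def resample(self, step: float = DEFAULT_STEP_UM) -> "SegmentMatch":
        """Fix the shared step count from the mean arc length and resample
        every modality's polyline to *n* matched points."""
        self.n = compute_step_count(list(self.lengths().values()), step)
        self.points = {m: resample_segment(p, self.n) for m, p in self.polylines.items()}
        return self


def _arc_length(polyline: np.ndarray) -> float:
    diffs = np.diff(np.asarray(polyline, dtype=float), axis=0)
    return float(np.linalg.norm(diffs, axis=1).sum())


# --------------------------------------------------------------------------
# trimming
# --------------------------------------------------------------------------

def trim_free_ends(skeleton: Skeleton, matched_node_ids: set[int]) -> Skeleton:
    """Remove freely ending tracings up to a matched junction.

    Leaves that are not matched junctions are deleted iteratively until every
    remaining leaf is matched; matched junctions and the paths between them
    are untouched.  A tree containing no matched junction disappears
    entirely.  A matched junction of degree < 3 is kept with a warning — the
    procedure tolerates it, but it suggests a mismatched table.
    """
    all_ids = {n.id for n in skeleton.iter_nodes()}
    missing = set(matched_node_ids) - all_ids
    if missing:
        raise KeyError(f"matched junction node ids absent from skeleton: {sorted(missing)}")

    g = skeleton.graph()
    for nid in matched_node_ids:
        if g.degree(nid) < 3:
            logger.warning(
                "matched junction node %d has degree %d (< 3) before trimming", nid, g.degree(nid)
            )
    protected = set(matched_node_ids)
    while True:
        removable = [n for n in g.nodes if g.degree(n) <= 1 and n not in protected]
        if not removable:
            break
        g.remove_nodes_from(removable)

    keep = set(g.nodes)
    trees = []
    for tree in skeleton.trees:
        nodes = {i: n for i, n in tree.nodes.items() if i in keep}
        if not nodes:
            continue
        edges = {(a, b) for a, b in tree.edges if a in keep and b in keep}
        trees.append(SkeletonTree(tree.id, tree.name, nodes, edges))
    trimmed = Skeleton(trees, skeleton.dataset_name, skeleton.voxel_scale)
    trimmed.validate()
    return trimmed


# --------------------------------------------------------------------------
# segment splitting
# --------------------------------------------------------------------------

def _walk_segments_one_modality(
    skeleton: Skeleton, junction_by_node: dict[int, str], modality: str
) -> dict[tuple[str, str], np.ndarray]:
    """Enumerate inter-junction paths in one modality.

    From each matched junction every incident edge is walked through
    non-junction nodes (which must be pass-through, degree 2) until another
    matched junction is reached.  Returns canonically ordered polylines keyed
    by the sorted junction-label pair.
    """
    g = skeleton.graph()
    positions = skeleton.node_positions()
    found: dict[tuple[str, str], np.ndarray] = {}
    for start, start_label in junction_by_node.items():
        if start not in g:
            raise KeyError(f"{modality}: junction node {start} not in skeleton")
        for first in g.neighbors(start):
            path = [start, first]
            prev, cur = start, first
            while cur not in junction_by_node:
                nxt = [n for n in g.neighbors(cur) if n != prev]
                if len(nxt) == 0:
                    # dangling chain: should not survive trimming
                    raise SegmentTopologyError(
                        f"{modality}: path from junction {start_label!r} ends freely at "
                        f"node {cur}; trim free ends before splitting"
                    )
                if len(nxt) > 1:
                    raise SegmentTopologyError(
                        f"{modality}: unmatched branching node {cur} (degree "
                        f"{g.degree(cur)}) between matched junctions; every junction on "
                        "the compared vessels must be matched"
                    )
                prev, cur = cur, nxt[0]
                path.append(cur)
            end_label = junction_by_node[cur]
            key = tuple(sorted((start_label, end_label)))
            if key[0] == key[1]:
                raise SegmentTopologyError(
                    f"{modality}: segment loops back to junction {start_label!r}"
                )
            if start_label > end_label:
                path = path[::-1]
            poly = np.array([positions[i] for i in path], dtype=float)
            if key in found:
                if found[key].shape != poly.shape or not np.allclose(found[key], poly):
                    raise SegmentTopologyError(
                        f"{modality}: multiple distinct paths between junctions "
                        f"{key[0]!r} and {key[1]!r}"
                    )
            else:
                found[key] = poly
    return found


def _dedupe_consecutive(poly: np.ndarray, context: str) -> np.ndarray:
    keep = np.ones(len(poly), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(poly, axis=0), axis=1) > 0
    if not keep.all():
        logger.warning("%s: collapsed %d duplicate consecutive nodes", context, int((~keep).sum()))
    return poly[keep]


def split_segments(
    skeletons: dict[str, Skeleton],
    junctions: list[MatchedJunction],
) -> list[SegmentMatch]:
    """Split trimmed skeletons into matched inter-junction segments.

    One :class:`SegmentMatch` is produced per junction pair connected by a
    single path in *every* modality.  Segments present in only a subset of
    modalities are reported (warning) and excluded, mirroring the rule that
    only vessels covered in all datasets are compared.
    """
    per_modality: dict[str, dict[tuple[str, str], np.ndarray]] = {}
    for modality, skeleton in skeletons.items():
        junction_by_node: dict[int, str] = {}
        for j in junctions:
            if modality not in j.node_ids:
                raise KeyError(f"junction {j.label!r} has no node id for modality {modality!r}")
            nid = j.node_ids[modality]
            if nid in junction_by_node:
                raise SegmentTopologyError(
                    f"{modality}: node {nid} assigned to junctions "
                    f"{junction_by_node[nid]!r} and {j.label!r}"
                )
            junction_by_node[nid] = j.label
        per_modality[modality] = _walk_segments_one_modality(skeleton, junction_by_node, modality)

    keys_per_modality = {m: set(d) for m, d in per_modality.items()}
    common = set.intersection(*keys_per_modality.values())
    for modality, keys in keys_per_modality.items():
        extra = keys - common
        if extra:
            logger.warning(
                "%d segment(s) present in %s but not all modalities were excluded: %s",
                len(extra), modality, sorted(extra),
            )

    segments = []
    for key in sorted(common):
        polylines = {
            m: _dedupe_consecutive(per_modality[m][key], f"{m}:{key[0]}--{key[1]}")
            for m in skeletons
        }
        segments.append(SegmentMatch(labels=key, polylines=polylines))
    return segments


# --------------------------------------------------------------------------
# resampling
# --------------------------------------------------------------------------

def compute_step_count(lengths: list[float], step: float = DEFAULT_STEP_UM) -> int:
    """Number of matched points for a segment.

    The arc lengths of the segment in all modalities are averaged and
    divided by the interpolation step (default 0.5 µm = 500 nm); the result
    is rounded half away from zero and clamped to ≥ 2 so every segment
    contributes at least its two junction endpoints.
    """
    lengths = [float(x) for x in lengths]
    if not lengths or any(x <= 0 for x in lengths):
        raise ValueError(f"segment arc lengths must be positive, got {lengths}")
    if step <= 0:
        raise ValueError(f"interpolation step must be positive, got {step}")
    raw = math.floor(np.mean(lengths) / step + 0.5)  # round half away from zero (lengths > 0)
    return max(int(raw), 2)


def resample_segment(polyline: np.ndarray, n: int) -> np.ndarray:
    """Resample a polyline to ``n`` points at equal arc-length fractions.

    Points sit at fractions i/(n−1), i = 0…n−1, of the total arc length, by
    linear interpolation along the polyline; the first and last points
    coincide exactly with the segment endpoints (the junctions).
    """
    if n < 2:
        raise ValueError(f"need n >= 2 resampled points, got {n}")
    poly = np.asarray(polyline, dtype=float).reshape(-1, 3)
    if poly.shape[0] < 2:
        raise ValueError("polyline needs at least 2 nodes")
    seg_len = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    total = seg_len.sum()
    if total <= 0:
        raise ValueError("zero-length polyline cannot be resampled")
    s = np.concatenate([[0.0], np.cumsum(seg_len)])
    targets = np.linspace(0.0, total, n)
    out = np.column_stack([np.interp(targets, s, poly[:, k]) for k in range(3)])
    out[0], out[-1] = poly[0], poly[-1]  # exact endpoints, no float drift
    return out


# --------------------------------------------------------------------------
# matched-node distances
# --------------------------------------------------------------------------

def matched_node_distances(
    segments: list[SegmentMatch],
    warps: dict[str, WarpField | None],
    reference: str,
) -> pd.DataFrame:
    """Distances between matched resampled nodes after warping into the
    reference space.

    ``warps[modality]`` maps that modality's coordinates into the reference
    space; the reference modality itself may map with ``None`` (identity).
    Returns one row per (segment, step, modality pair) with columns
    ``segment, step, pair, x, y, z, distance_um``; the tagged position is
    the midpoint of the two warped points in reference space, usable for
    spatial accuracy maps.
    """
    if reference not in warps:
        raise KeyError(f"no warp entry for reference modality {reference!r}")
    modalities = sorted(warps)
    rows: list[dict] = []
    for seg in segments:
        if not seg.points:
            seg.resample()
        counts = {m: seg.points[m].shape[0] for m in modalities if m in seg.points}
        missing = [m for m in modalities if m not in seg.points]
        if missing:
            raise KeyError(f"segment {seg.id}: no resampled points for {missing}")
        if len(set(counts.values())) != 1:
            raise ValueError(
                f"segment {seg.id}: modalities have mismatched point counts {counts}"
            )
        warped = {}
        for m in modalities:
            w = warps[m]
            warped[m] = seg.points[m] if w is None else w(seg.points[m])
        for i, a in enumerate(modalities):
            for b in modalities[i + 1 :]:
                delta = warped[a] - warped[b]
                dist = np.linalg.norm(delta, axis=1)
                mid = 0.5 * (warped[a] + warped[b])
                pair = f"{a}->{b}"
                for step in range(dist.shape[0]):
                    rows.append(
                        {
                            "segment": seg.id,
                            "step": step,
                            "pair": pair,
                            "x": mid[step, 0],
                            "y": mid[step, 1],
                            "z": mid[step, 2],
                            "distance_um": dist[step],
                        }
                    )
    return pd.DataFrame(rows, columns=["segment", "step", "pair", "x", "y", "z", "distance_um"])


def summarize_accuracy(
    records: pd.DataFrame,
    percentiles: tuple[float, ...] = (5, 25, 50, 75, 95),
    histogram_bins: int = 20,
) -> dict[str, dict]:
    """Per-modality-pair summary of matched-node distances.

    The overall warping accuracy of a pair is the mean over all its matched
    points (each point weighted equally, so longer segments contribute
    more); the range is (min, max).  Also returns percentiles and a
    histogram for distribution plots.
    """
    if records.empty:
        raise ValueError("no matched-node distance records to summarize")
    out: dict[str, dict] = {}
    for pair, grp in records.groupby("pair"):
        d = grp["distance_um"].to_numpy()
        counts, edges = np.histogram(d, bins=histogram_bins)
        out[str(pair)] = {
            "n_points": int(d.size),
            "n_segments": int(grp["segment"].nunique()),
            "mean_um": float(d.mean()),
            "min_um": float(d.min()),
            "max_um": float(d.max()),
            "percentiles_um": {str(p): float(np.percentile(d, p)) for p in percentiles},
            "histogram": {"counts": counts.tolist(), "bin_edges_um": edges.tolist()},
        }
    return out


# --------------------------------------------------------------------------
# end-to-end pipeline
# --------------------------------------------------------------------------

def warping_accuracy(
    skeletons: dict[str, Skeleton],
    junction_table: dict[str, dict[str, int]],
    landmarks: dict[str, "object"],
    reference: str,
    step: float = DEFAULT_STEP_UM,
) -> tuple[pd.DataFrame, dict[str, dict]]:
    """Run the full accuracy procedure: trim, split, resample, warp, measure.

    Parameters
    ----------
    skeletons
        Modality name → traced vessel skeleton (µm).
    junction_table
        Junction label → {modality: node id}; every junction must be present
        in every modality.
    landmarks
        Modality name → either a fitted :class:`WarpField` into the reference
        space, a :class:`~cmiwarp.core.LandmarkSet` (moving = that modality,
        fixed = reference; fitted here), or an explicit ``None`` meaning the
        modality is already in reference coordinates (always the case for the
        reference itself).  A modality missing from the mapping is an error.
    reference
        Modality whose space the comparison happens in.

    Returns
    -------
    (records, summary)
        The per-node distance records and the per-pair summary.
    """
    if reference not in skeletons:
        raise KeyError(f"reference modality {reference!r} has no skeleton")
    warps: dict[str, WarpField | None] = {}
    for modality in skeletons:
        if modality not in landmarks:
            raise KeyError(
                f"modality {modality!r} needs landmarks, a warp into {reference!r}, "
                "or an explicit None (already in reference coordinates)"
            )
        obj = landmarks[modality]
        if obj is None:
            warps[modality] = None
        elif isinstance(obj, WarpField):
            warps[modality] = obj
        else:
            warps[modality] = fit_warp(obj)

    junctions = junctions_from_table(junction_table)
    trimmed = {}
    for modality, skeleton in skeletons.items():
        ids = {j.node_ids[modality] for j in junctions}
        trimmed[modality] = trim_free_ends(skeleton, ids)
    segments = split_segments(trimmed, junctions)
    if not segments:
        raise SegmentTopologyError("no segments shared by all modalities")
    for seg in segments:
        seg.resample(step)
    records = matched_node_distances(segments, warps, reference)
    return records, summarize_accuracy(records)
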