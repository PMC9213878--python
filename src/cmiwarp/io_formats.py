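"""File readers and writers.

Formats supported:

* **Skeletons** — webKnossos NML-style XML.  Node positions are stored in
  voxel units in the file together with a ``<scale>`` element (µm per voxel);
  on read they are converted to physical µm as ``voxel_index * scale``
  (0-based, voxel origin at the voxel corner), and converted back on write,
  so read∘write is the identity to well below 1e-6 µm.
* **Landmark pairs** — CSV with canonical header
  ``name,active,mvg_x,mvg_y,mvg_z,fix_x,fix_y,fix_z``.  A BigWarp-compatible
  headerless 8-column export is auto-detected from the first cell of the
  first row.  Coordinates are taken to already be physical µm.
* **Scoring tables** — UTF-8 comma-separated CSV, one sample per row, binary
  artefact flags plus metadata columns.
* **Stacks** — multi-page grayscale TIFF, via :mod:`tifffile`.
"""

from __future__ import annotations

import csv
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from cmiwarp.core import (
    DEFAULT_ARTEFACT_COLUMNS,
    LandmarkSet,
    ScoringTable,
    Skeleton,
    SkeletonNode,
    SkeletonTree,
    VoxelScale,
)

__all__ = [
    "read_skeleton",
    "write_skeleton",
    "read_landmarks",
    "write_landmarks",
    "read_scoring_table",
    "write_scoring_table",
    "read_junction_table",
    "write_junction_table",
    "read_stack",
    "measure_embedded_volume",
]

_NODE_CORE_ATTRS = {"id", "x", "y", "z", "radius"}


class SkeletonParseError(ValueError):
    """Raised when skeleton XML cannot be interpreted; names the element."""


# --------------------------------------------------------------------------
# skeletons (NML-style XML)
# --------------------------------------------------------------------------

def read_skeleton(
    path: str | Path,
    voxel_scale_override: VoxelScale | None = None,
) -> Skeleton:
    """Read a skeleton from NML-style XML, converting positions to µm.

    Parameters
    ----------
    path
        XML file with a ``<things>`` root, a ``<parameters><scale .../>``
        element (µm per voxel) and one ``<thing>`` per tree.
    voxel_scale_override
        Use this scale instead of the file's ``<scale>`` element.  Required
        when the file carries none; also the escape hatch for exported files
        whose positions are already physical (pass a unit scale).

    Raises
    ------
    SkeletonParseError
        On malformed XML, a missing/invalid element, or a missing scale with
        no override.
    SkeletonValidationError
        If a tree is disconnected or cyclic.
    """
    path = Path(path)
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise SkeletonParseError(f"{path}: not well-formed XML: {exc}") from exc
    if root.tag != "things":
        raise SkeletonParseError(f"{path}: expected <things> root, found <{root.tag}>")

    scale = voxel_scale_override
    params = root.find("parameters")
    dataset_name = ""
    if params is not None:
        exp = params.find("experiment")
        if exp is not None:
            dataset_name = exp.get("name", "")
        scale_el = params.find("scale")
        if scale is None and scale_el is not None:
            try:
                scale = VoxelScale(
                    float(scale_el.get("x")), float(scale_el.get("y")), float(scale_el.get("z"))
                )
            except (TypeError, ValueError) as exc:
                raise SkeletonParseError(f"{path}: invalid <scale> element: {exc}") from exc
    if scale is None:
        raise SkeletonParseError(
            f"{path}: no <scale> element found and no voxel_scale_override given"
        )
    s = scale.as_array()

    trees: list[SkeletonTree] = []
    for thing in root.iter("thing"):
        try:
            tree_id = int(thing.get("id", len(trees) + 1))
        except ValueError as exc:
            raise SkeletonParseError(f"{path}: non-integer <thing> id") from exc
        name = thing.get("name", f"tree{tree_id}")
        nodes: dict[int, SkeletonNode] = {}
        nodes_el = thing.find("nodes")
        if nodes_el is not None:
            for node_el in nodes_el.iter("node"):
                try:
                    nid = int(node_el.get("id"))
                    vox = np.array(
                        [float(node_el.get(k)) for k in ("x", "y", "z")], dtype=float
                    )
                except (TypeError, ValueError) as exc:
                    raise SkeletonParseError(
                        f"{path}: <node> in tree {tree_id} lacks numeric id/x/y/z"
                    ) from exc
                radius_attr = node_el.get("radius")
                radius = float(radius_attr) if radius_attr is not None else None
                extra = {
                    k: v for k, v in node_el.attrib.items() if k not in _NODE_CORE_ATTRS
                }
                if nid in nodes:
                    raise SkeletonParseError(
                        f"{path}: duplicate node id {nid} in tree {tree_id}"
                    )
                nodes[nid] = SkeletonNode(nid, vox * s, radius, extra)
        edges: set[tuple[int, int]] = set()
        edges_el = thing.find("edges")
        if edges_el is not None:
            for edge_el in edges_el.iter("edge"):
                try:
                    a, b = int(edge_el.get("source")), int(edge_el.get("target"))
                except (TypeError, ValueError) as exc:
                    raise SkeletonParseError(
                        f"{path}: <edge> in tree {tree_id} lacks integer source/target"
                    ) from exc
                edges.add((min(a, b), max(a, b)))
        trees.append(SkeletonTree(tree_id, name, nodes, edges))

    skeleton = Skeleton(trees, dataset_name=dataset_name, voxel_scale=scale)
    skeleton.validate()
    return skeleton


def write_skeleton(skeleton: Skeleton, path: str | Path) -> None:
    """Write a skeleton as NML-style XML, converting µm back to voxel units.

    Requires ``skeleton.voxel_scale``.  Positions are written with 9
    significant digits after the point so a read/write round trip is the
    identity to far below 1e-6 µm; unknown node attributes are preserved.
    """
    if skeleton.voxel_scale is None:
        raise ValueError("cannot write a skeleton without a voxel scale")
    s = skeleton.voxel_scale.as_array()
    root = ET.Element("things")
    params = ET.SubElement(root, "parameters")
    ET.SubElement(params, "experiment", name=skeleton.dataset_name)
    ET.SubElement(
        params,
        "scale",
        x=repr(skeleton.voxel_scale.sx),
        y=repr(skeleton.voxel_scale.sy),
        z=repr(skeleton.voxel_scale.sz),
    )
    for tree in skeleton.trees:
        thing = ET.SubElement(root, "thing", id=str(tree.id), name=tree.name)
        nodes_el = ET.SubElement(thing, "nodes")
        for node in tree.nodes.values():
            vox = node.position / s
            attrs = {
                "id": str(node.id),
                "x": f"{vox[0]:.9f}",
                "y": f"{vox[1]:.9f}",
                "z": f"{vox[2]:.9f}",
            }
            if node.radius is not None:
                attrs["radius"] = repr(node.radius)
            attrs.update({k: str(v) for k, v in node.attrs.items()})
            ET.SubElement(nodes_el, "node", **attrs)
        edges_el = ET.SubElement(thing, "edges")
        for a, b in sorted(tree.edges):
            ET.SubElement(edges_el, "edge", source=str(a), target=str(b))
    ET.ElementTree(root).write(path, encoding="utf-8", xml_declaration=True)


# --------------------------------------------------------------------------
# landmark pairs (CSV)
# --------------------------------------------------------------------------

_CANONICAL_HEADER = ["name", "active", "mvg_x", "mvg_y", "mvg_z", "fix_x", "fix_y", "fix_z"]
_TRUTHY = {"1", "true", "yes", "t", "active"}
_FALSY = {"0", "false", "no", "f", "inactive"}


def _parse_active(value: str, row_number: int) -> bool:
    v = value.strip().strip('"').lower()
    if v in _TRUTHY:
        return True
    if v in _FALSY:
        return False
    raise ValueError(f"landmark row {row_number}: cannot interpret active flag {value!r}")


def read_landmarks(
    path: str | Path,
    moving_name: str = "moving",
    fixed_name: str = "fixed",
) -> LandmarkSet:
    """Read paired landmarks from CSV; coordinates are physical µm.

    The canonical dialect has the header
    ``name,active,mvg_x,mvg_y,mvg_z,fix_x,fix_y,fix_z``; a headerless
    BigWarp-style 8-column export (``"Pt-0","true",mx,my,mz,fx,fy,fz``) is
    auto-detected when the first cell is not the literal ``name``.
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        rows = [r for r in csv.reader(fh) if r and any(c.strip() for c in r)]
    if not rows:
        raise ValueError(f"{path}: empty landmark file")
    start = 0
    if rows[0][0].strip().strip('"').lower() == "name":
        if [c.strip().lower() for c in rows[0]] != _CANONICAL_HEADER:
            raise ValueError(
                f"{path}: unrecognised landmark header {rows[0]!r}; "
                f"expected {','.join(_CANONICAL_HEADER)}"
            )
        start = 1

    names: list[str] = []
    moving, fixed, active = [], [], []
    for idx, row in enumerate(rows[start:], start=start + 1):
        if len(row) != 8:
            raise ValueError(f"{path}: row {idx}: expected 8 columns, found {len(row)}")
        name = row[0].strip().strip('"')
        try:
            coords = [float(c.strip().strip('"')) for c in row[2:]]
        except ValueError as exc:
            raise ValueError(f"{path}: row {idx}: non-numeric coordinate: {exc}") from exc
        names.append(name)
        active.append(_parse_active(row[1], idx))
        moving.append(coords[:3])
        fixed.append(coords[3:])
    if len(set(names)) != len(names):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"{path}: duplicate landmark names: {dup}")
    return LandmarkSet(
        names,
        np.array(moving, dtype=float),
        np.array(fixed, dtype=float),
        np.array(active, dtype=bool),
        moving_name=moving_name,
        fixed_name=fixed_name,
    )


def write_landmarks(landmarks: LandmarkSet, path: str | Path) -> None:
    """Write a landmark set in the canonical CSV dialect."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CANONICAL_HEADER)
        for name, act, m, f in zip(
            landmarks.names, landmarks.active, landmarks.moving, landmarks.fixed
        ):
            writer.writerow(
                [name, "true" if act else "false"]
                + [repr(float(v)) for v in m]
                + [repr(float(v)) for v in f]
            )


# --------------------------------------------------------------------------
# scoring tables (CSV)
# --------------------------------------------------------------------------

def read_scoring_table(
    path: str | Path,
    artefact_columns: tuple[str, ...] | list[str] = DEFAULT_ARTEFACT_COLUMNS,
    blanks_as_absent: bool = False,
) -> ScoringTable:
    """Read an artefact scoring table from CSV.

    Each requested artefact column is coerced to {0, 1}.  Blank flags are an
    error unless ``blanks_as_absent`` is set, in which case they count as 0
    (absent); silent imputation otherwise hides data problems.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty scoring table") from exc
    if df.empty:
        raise ValueError(f"{path}: scoring table has a header but no rows")
    artefact_columns = tuple(artefact_columns)
    missing = [c for c in artefact_columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: requested artefact columns not in file: {missing}")
    for col in artefact_columns:
        vals = df[col]
        if vals.isna().any():
            if not blanks_as_absent:
                raise ValueError(
                    f"{path}: column {col!r} has blank flags; "
                    "pass blanks_as_absent=True to treat them as 0"
                )
            vals = vals.fillna(0)
        numeric = pd.to_numeric(vals, errors="coerce")
        if numeric.isna().any() or not numeric.isin([0, 1]).all():
            bad = sorted(set(vals[~numeric.isin([0, 1])].astype(str)))
            raise ValueError(f"{path}: column {col!r} has flags outside {{0, 1}}: {bad}")
        df[col] = numeric.astype(int)
    if "experiment_id" not in df.columns:
        raise ValueError(f"{path}: scoring table lacks an experiment_id column")
    exp = df["experiment_id"]
    empty = exp.isna() | (exp.astype(str).str.strip() == "")
    if empty.any():
        raise ValueError(
            f"{path}: rows {list(df.index[empty])} have a missing experiment_id"
        )
    return ScoringTable(df, artefact_columns)


def write_scoring_table(table: ScoringTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False)


# --------------------------------------------------------------------------
# junction correspondence tables (CSV: label,modality,node_id)
# --------------------------------------------------------------------------

def read_junction_table(path: str | Path) -> dict[str, dict[str, int]]:
    """Read a junction correspondence table: label → {modality: node_id}.

    Junction matching across modalities is manual input (branch points are
    matched by eye using vessel shape); this table records the result.
    """
    df = pd.read_csv(path)
    required = {"label", "modality", "node_id"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: junction table needs columns {sorted(required)}")
    out: dict[str, dict[str, int]] = {}
    for _, row in df.iterrows():
        label = str(row["label"])
        modality = str(row["modality"])
        entry = out.setdefault(label, {})
        if modality in entry:
            raise ValueError(f"{path}: duplicate entry for junction {label!r} in {modality!r}")
        entry[modality] = int(row["node_id"])
    return out


def write_junction_table(junctions: dict[str, dict[str, int]], path: str | Path) -> None:
    rows = [
        {"label": label, "modality": m, "node_id": nid}
        for label, per_mod in junctions.items()
        for m, nid in per_mod.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# --------------------------------------------------------------------------
# image stacks
# --------------------------------------------------------------------------

def read_stack(path: str | Path) -> np.ndarray:
    """Read a multi-page grayscale TIFF as a 3D (z, y, x) array."""
    arr = np.asarray(tifffile.imread(path))
    if arr.ndim == 2:
        arr = arr[None, :, :]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a grayscale stack, got shape {arr.shape}")
    return arr


def measure_embedded_volume(
    stack: np.ndarray,
    threshold: float,
    voxel_scale: VoxelScale,
    exclusion_mask: np.ndarray | None = None,
) -> float:
    """Tissue volume of an embedded sample from a thresholded 3D stack, in mm³.

    The volume is the number of voxels at or above ``threshold`` (tissue,
    excluding any voxels flagged in ``exclusion_mask`` — e.g. the space
    occupied by a crack) times the physical voxel volume.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError(f"stack must be 3D, got shape {stack.shape}")
    tissue = stack >= threshold
    if exclusion_mask is not None:
        exclusion_mask = np.asarray(exclusion_mask, dtype=bool)
        if exclusion_mask.shape != stack.shape:
            raise ValueError(
                f"exclusion mask shape {exclusion_mask.shape} "
                f"does not match stack shape {stack.shape}"
            )
        tissue &= ~exclusion_mask
    um3 = float(tissue.sum()) * voxel_scale.voxel_volume_um3
    return um3 * 1e-9  # µm³ → mm³
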