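"""Landmark-based nonrigid warp fields between modality coordinate spaces.

The warp is a 3D polyharmonic radial-basis interpolant, φ(r) = r, with an
affine + constant polynomial tail, fitted with zero smoothing so that every
active landmark pair is reproduced exactly (to solver tolerance).  This is
the thin-plate-spline-like behaviour of the interactive landmark tools whose
exports the package ingests, and the accuracy pipeline relies on landmarks
being interpolated, not approximated.

Two consequences worth knowing:

* any exactly-affine landmark relation is reproduced by the affine tail
  alone, over the whole domain;
* warps are direction specific — the reverse mapping is fitted from the
  swapped landmark pairs (:meth:`cmiwarp.core.LandmarkSet.swapped`), never
  obtained by numerical inversion.

The linear solve is :class:`scipy.interpolate.RBFInterpolator` (kernel
``"linear"``, polynomial degree 1, ``smoothing=0``), which assembles the
standard augmented symmetric system and shifts/scales the data internally
for conditioning.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import RBFInterpolator
from scipy.linalg import LinAlgError

from cmiwarp.core import LandmarkSet, Skeleton

__all__ = [
    "WarpField",
    "fit_warp",
    "apply_warp",
    "leave_one_out_error",
    "warp_to_json",
    "warp_from_json",
    "DegenerateLandmarkError",
]

logger = logging.getLogger(__name__)

BASIS_KIND = "polyharmonic1+affine"

#: Minimum number of active, non-coplanar pairs needed to determine the
#: affine tail (12 dof) together with the interpolation conditions.
MIN_LANDMARKS = 4


class DegenerateLandmarkError(ValueError):
    """Landmark configuration cannot determine a warp (too few, coplanar,
    or duplicated moving points)."""


def _check_configuration(moving: np.ndarray) -> None:
    if moving.shape[0] < MIN_LANDMARKS:
        raise DegenerateLandmarkError(
            f"need at least {MIN_LANDMARKS} active landmark pairs, got {moving.shape[0]}"
        )
    # exact duplicate moving points make the interpolation system singular
    rounded = np.round(moving / 1e-9).astype(np.int64)
    uniq, counts = np.unique(rounded, axis=0, return_counts=True)
    if (counts > 1).any():
        dup = uniq[counts > 1][0] * 1e-9
        raise DegenerateLandmarkError(
            f"duplicate moving landmark position near {tuple(dup)} µm"
        )
    centered = moving - moving.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[2] <= 1e-9 * max(sv[0], 1.0):
        raise DegenerateLandmarkError(
            "active moving landmarks are (near-)coplanar: their smallest "
            f"principal extent is {sv[2]:.3g} µm, which leaves the affine part "
            "of the warp undetermined out of plane"
        )


@dataclass
class WarpField:
    """A fitted smooth mapping from the moving space to the fixed space.

    Behaves like a fitted-model object: carries the source landmarks and a
    residual summary (the fitted displacement error at each active landmark,
    which for this exact interpolant is at numerical-noise level).  Call the
    instance, or :func:`apply_warp`, to map points.
    """

    landmarks: LandmarkSet
    basis: str = BASIS_KIND
    residual_max_um: float = field(default=np.nan)
    residual_mean_um: float = field(default=np.nan)
    _interpolator: RBFInterpolator | None = field(default=None, repr=False)
    _hull_lo: np.ndarray | None = field(default=None, repr=False)
    _hull_hi: np.ndarray | None = field(default=None, repr=False)

    @property
    def moving_name(self) -> str:
        return self.landmarks.moving_name

    @property
    def fixed_name(self) -> str:
        return self.landmarks.fixed_name

    def __call__(self, points: np.ndarray) -> np.ndarray:
        """Map (n, 3) µm points from moving space into fixed space."""
        if self._interpolator is None:
            raise RuntimeError("warp has not been fitted")
        pts = np.asarray(points, dtype=float)
        squeeze = pts.ndim == 1
        pts = pts.reshape(-1, 3)
        margin = 0.10 * np.maximum(self._hull_hi - self._hull_lo, 1.0)
        outside = (pts < self._hull_lo - margin) | (pts > self._hull_hi + margin)
        if outside.any():
            logger.warning(
                "%d of %d points lie well outside the landmark bounding box "
                "(%s→%s): the warp is extrapolating there",
                int(outside.any(axis=1).sum()),
                pts.shape[0],
                self.moving_name,
                self.fixed_name,
            )
        out = self._interpolator(pts)
        return out[0] if squeeze else out


def fit_warp(landmarks: LandmarkSet) -> WarpField:
    """Fit an exact-interpolation warp field to the active landmark pairs.

    Raises :class:`DegenerateLandmarkError` when fewer than 4 active pairs
    are available, the active moving points are coplanar, or moving points
    are duplicated.
    """
    moving, fixed = landmarks.active_pairs()
    _check_configuration(moving)
    try:
        interp = RBFInterpolator(moving, fixed, kernel="linear", degree=1, smoothing=0.0)
    except (LinAlgError, np.linalg.LinAlgError) as exc:
        raise DegenerateLandmarkError(
            f"singular interpolation system for {moving.shape[0]} landmarks: {exc}"
        ) from exc
    residuals = np.linalg.norm(interp(moving) - fixed, axis=1)
    return WarpField(
        landmarks=landmarks,
        basis=BASIS_KIND,
        residual_max_um=float(residuals.max()),
        residual_mean_um=float(residuals.mean()),
        _interpolator=interp,
        _hull_lo=moving.min(axis=0),
        _hull_hi=moving.max(axis=0),
    )


def apply_warp(warp: WarpField, target: np.ndarray | Skeleton):
    """Warp points or a whole skeleton into the fixed space.

    For a skeleton only node positions change; trees, edges, radii and
    attributes are preserved.
    """
    if isinstance(target, Skeleton):
        warped = target.transform_positions(warp)
        warped.dataset_name = (
            f"{target.dataset_name}@{warp.fixed_name}" if target.dataset_name else ""
        )
        return warped
    return warp(np.asarray(target, dtype=float))


def leave_one_out_error(landmarks: LandmarkSet) -> np.ndarray:
    """Leave-one-out displacement error (µm) for each active landmark.

    For each active pair *i* the warp is refitted on the remaining active
    pairs and evaluated at ``moving_i``; the returned value is the distance
    to ``fixed_i``.  A landmark whose error stands far above the rest is a
    likely seeding mistake.
    """
    active_idx = np.flatnonzero(landmarks.active)
    if active_idx.size < MIN_LANDMARKS + 1:
        raise DegenerateLandmarkError(
            f"leave-one-out needs at least {MIN_LANDMARKS + 1} active pairs, "
            f"got {active_idx.size}"
        )
    errors = np.empty(active_idx.size)
    for j, i in enumerate(active_idx):
        mask = np.ones(len(landmarks), dtype=bool)
        mask[i] = False
        try:
            warp = fit_warp(landmarks.subset(mask))
        except DegenerateLandmarkError as exc:
            raise DegenerateLandmarkError(
                f"degenerate landmark subset when leaving out index {i} "
                f"({landmarks.names[i]!r}): {exc}"
            ) from exc
        predicted = warp(landmarks.moving[i])
        errors[j] = float(np.linalg.norm(predicted - landmarks.fixed[i]))
    return errors


# --------------------------------------------------------------------------
# serialization
# --------------------------------------------------------------------------
# JSON schema (version 1):
# {
#   "format": "cmiwarp-warpfield", "version": 1,
#   "basis": "polyharmonic1+affine",
#   "moving_name": ..., "fixed_name": ...,
#   "landmarks": [{"name": ..., "active": ..., "moving": [x,y,z],
#                  "fixed": [x,y,z]}, ...],
#   "residual_max_um": ..., "residual_mean_um": ...
# }
# The basis coefficients are not stored: with zero smoothing the fit is a
# deterministic function of the landmarks, so loading refits and reproduces
# the identical mapping; storing the landmarks keeps the file auditable.


def warp_to_json(warp: WarpField, path: str | Path | None = None) -> dict:
    """Serialize a warp field to the documented JSON schema.

    Returns the document; also writes it to ``path`` when given.
    """
    lm = warp.landmarks
    doc = {
        "format": "cmiwarp-warpfield",
        "version": 1,
        "basis": warp.basis,
        "moving_name": lm.moving_name,
        "fixed_name": lm.fixed_name,
        "landmarks": [
            {
                "name": name,
                "active": bool(act),
                "moving": [float(v) for v in m],
                "fixed": [float(v) for v in f],
            }
            for name, act, m, f in zip(lm.names, lm.active, lm.moving, lm.fixed)
        ],
        "residual_max_um": warp.residual_max_um,
        "residual_mean_um": warp.residual_mean_um,
    }
    if path is not None:
        Path(path).write_text(json.dumps(doc, indent=1))
    return doc


def warp_from_json(source: str | Path | dict) -> WarpField:
    """Rebuild a warp field from its JSON document (file path or dict)."""
    if isinstance(source, (str, Path)):
        doc = json.loads(Path(source).read_text())
    else:
        doc = source
    if doc.get("format") != "cmiwarp-warpfield":
        raise ValueError("not a cmiwarp warp-field document")
    if doc.get("basis") != BASIS_KIND:
        raise ValueError(f"unsupported basis kind {doc.get('basis')!r}")
    entries = doc["landmarks"]
    landmarks = LandmarkSet(
        [e["name"] for e in entries],
        np.array([e["moving"] for e in entries], dtype=float),
        np.array([e["fixed"] for e in entries], dtype=float),
        np.array([e["active"] for e in entries], dtype=bool),
        moving_name=doc.get("moving_name", "moving"),
        fixed_name=doc.get("fixed_name", "fixed"),
    )
    return fit_warp(landmarks)
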