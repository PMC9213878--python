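"""Tissue volume change during sample preparation.

Heavy-metal staining, dehydration and resin embedding change tissue volume.
Paired warping landmarks mark the same features in the fresh-tissue (e.g.
in vivo two-photon) space and the structural (e.g. X-ray CT) space, so the
volume-change factor *r* can be read off inter-landmark distances:

* pick ``k`` landmarks at random in the fresh space and compute their
  distances to every other landmark;
* keep the ``top_m`` largest distances (long baselines average out local
  landmark error);
* for each kept pair form the ratio structural-distance / fresh-distance;
* *r* is the mean of those ratios, cubed (a linear shrink/swell factor
  taken to the third power is a volume factor).

The fresh volume is then the embedded (CT-measured) volume divided by *r*.

For an isotropic scaling by *s* every ratio equals *s* and *r* = *s*³
exactly, whatever the seed.  For anisotropic deformation *r* is a single
summary between min(s)³ and max(s)³; no anisotropy correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from cmiwarp.core import LandmarkSet

__all__ = [
    "VolumeRatioEstimate",
    "estimate_volume_ratio",
    "estimate_fresh_volume",
    "volume_trajectory",
]


@dataclass
class VolumeRatioEstimate:
    """Result of :func:`estimate_volume_ratio`.

    ``r`` is the volume-change factor (dimensionless; > 1 means the sample
    swelled from fresh to structural space).  ``ratios`` are the per-pair
    structural/fresh distance ratios that were averaged.
    """

    r: float
    ratios: np.ndarray
    k: int
    m: int
    seed: int | None
    mean_of_cubes: bool = False

    def __post_init__(self) -> None:
        if not self.r > 0:
            raise ValueError(f"volume ratio must be positive, got {self.r}")


def estimate_volume_ratio(
    landmarks: LandmarkSet,
    k: int = 20,
    top_m: int = 400,
    seed: int | None = None,
    mean_of_cubes: bool = False,
) -> VolumeRatioEstimate:
    """Estimate the volume-change factor *r* from paired landmarks.

    ``landmarks.moving`` is the fresh-tissue space (where the top distances
    are ranked) and ``landmarks.fixed`` the structural space.  ``k`` seed
    landmarks are drawn without replacement with a seeded RNG; unordered
    pairs are counted once even when both endpoints are seeds.

    ``mean_of_cubes`` switches to cubing each ratio before averaging — an
    alternative reading of "averaged ratio … cubed"; the default averages
    first and cubes the mean.  The two agree whenever the ratios are
    constant (any similarity transform).
    """
    moving, fixed = landmarks.active_pairs()
    n = moving.shape[0]
    if n < k + 1:
        raise ValueError(f"need at least k+1 = {k + 1} active landmarks, got {n}")
    rng = np.random.default_rng(seed)
    seeds = rng.choice(n, size=k, replace=False)

    pair_set: set[tuple[int, int]] = set()
    for i in seeds:
        for j in range(n):
            if j != i:
                pair_set.add((min(i, j), max(i, j)))
    pairs = np.array(sorted(pair_set), dtype=int)
    d_moving = np.linalg.norm(moving[pairs[:, 0]] - moving[pairs[:, 1]], axis=1)
    d_fixed = np.linalg.norm(fixed[pairs[:, 0]] - fixed[pairs[:, 1]], axis=1)

    order = np.argsort(-d_moving, kind="stable")
    m = min(top_m, order.size)
    top = order[:m]
    if np.any(d_moving[top] == 0):
        raise ValueError("zero fresh-space distance in the top pair set (duplicate landmarks?)")
    ratios = d_fixed[top] / d_moving[top]
    if mean_of_cubes:
        r = float(np.mean(ratios**3))
    else:
        r = float(np.mean(ratios) ** 3)
    return VolumeRatioEstimate(r=r, ratios=ratios, k=k, m=m, seed=seed,
                               mean_of_cubes=mean_of_cubes)


def estimate_fresh_volume(embedded_volume_mm3: float, r: float) -> float:
    """Fresh-tissue volume (mm³) from the embedded volume and the
    volume-change factor: embedded / r."""
    if not embedded_volume_mm3 > 0:
        raise ValueError(f"embedded volume must be positive, got {embedded_volume_mm3}")
    if not r > 0:
        raise ValueError(f"volume ratio must be positive, got {r}")
    return embedded_volume_mm3 / r


def volume_trajectory(
    group_volumes: "dict[str, list[float]] | list[list[float]]",
) -> tuple[list[float], list[float]]:
    """Mean volume per preparation step and step-to-step mean ratios.

    ``group_volumes`` is an ordered mapping (or list) of per-step volume
    lists, one entry per sample group measured after that step.  Returns
    ``(means, ratios)`` where ``ratios[t] = means[t+1] / means[t]``; a ratio
    of 1 marks no volume change across that step.
    """
    if isinstance(group_volumes, dict):
        steps = list(group_volumes.values())
    else:
        steps = list(group_volumes)
    if not steps:
        raise ValueError("no volume groups given")
    means = []
    for idx, vols in enumerate(steps):
        vols = np.asarray(vols, dtype=float)
        if vols.size == 0:
            raise ValueError(f"volume group {idx} is empty")
        means.append(float(vols.mean()))
    ratios = [means[t] / means[t - 1] for t in range(1, len(means))]
    return means, ratios
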