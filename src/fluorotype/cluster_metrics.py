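"""Cluster-geometry statistics for allele-discrimination plots.

Three quantities describe how well a platform separates genotype clusters in
the two-channel fluorescence plane, all anchored at the mean no-template
control (NTC) coordinate (x1, y1):

* **separation angle** alpha = arctan(dy/dx) between the X-axis and the line
  from the NTC centroid to a point (dx = signal_x - x1, dy = signal_y - y1) —
  implemented via atan2 so a vertical line (dx = 0) is well defined, and
  restricted to [0, pi/2] because genotyping signals sit in the first
  quadrant relative to the NTC.  A smaller A11 angle means better
  discrimination of the homozygote from the heterozygote cloud.
* **NTC distance** D = sqrt(dx^2 + dy^2), proportional to fluorescence gain.
* **compactness** S: the sample standard deviation (divisor n - 1) of member
  distances to the cluster centroid; smaller is tighter.

Angle and compactness comparisons are conventionally restricted to the A11
cluster; NTC distance uses all called clusters.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .allele_calling import NtcReference
from .plate_io import FluorescencePoint, GENOTYPE_LABELS

__all__ = [
    "UndefinedAngleError",
    "separation_angle",
    "separation_angles",
    "ntc_distance",
    "compactness",
    "summarize_clusters",
    "METRICS_COLUMNS",
]

METRICS_COLUMNS = (
    "assay_id",
    "platform_id",
    "label",
    "n",
    "centroid_x",
    "centroid_y",
    "mean_angle_rad",
    "mean_ntc_distance",
    "compactness",
)

_TINY = 1e-12


class UndefinedAngleError(ValueError):
    """The point coincides with the NTC centroid: no direction exists."""


def _deltas(point: FluorescencePoint | tuple[float, float], ntc: NtcReference):
    if isinstance(point, FluorescencePoint):
        x, y = point.signal_x, point.signal_y
    else:
        x, y = point
    return x - ntc.centroid[0], y - ntc.centroid[1]


def separation_angle(
    point: FluorescencePoint | tuple[float, float], ntc: NtcReference
) -> float:
    """Separation angle alpha (radians, in [0, pi/2]) of one point.

    Tiny negative deltas (|d| < 1e-12, numerical noise) are floored to zero
    before the angle is formed; the result is then clamped to [0, pi/2].
    For dx > 0 this reproduces the plain arctan(dy/dx) exactly.
    """
    dx, dy = _deltas(point, ntc)
    if abs(dx) < _TINY:
        dx = 0.0
    if abs(dy) < _TINY:
        dy = 0.0
    if dx == 0.0 and dy == 0.0:
        raise UndefinedAngleError("point coincides with the NTC centroid")
    alpha = math.atan2(dy, dx)
    return min(max(alpha, 0.0), math.pi / 2)


def separation_angles(xy: np.ndarray, ntc: NtcReference) -> np.ndarray:
    """Vectorized :func:`separation_angle` over an (n, 2) signal array."""
    delta = np.asarray(xy, dtype=float) - np.asarray(ntc.centroid)
    delta[np.abs(delta) < _TINY] = 0.0
    if np.any((delta[:, 0] == 0.0) & (delta[:, 1] == 0.0)):
        raise UndefinedAngleError("a point coincides with the NTC centroid")
    return np.clip(np.arctan2(delta[:, 1], delta[:, 0]), 0.0, math.pi / 2)


def ntc_distance(
    point: FluorescencePoint | tuple[float, float], ntc: NtcReference
) -> float:
    """Euclidean distance D from the NTC centroid to the point."""
    dx, dy = _deltas(point, ntc)
    return math.hypot(dx, dy)


def compactness(xy: Sequence[tuple[float, float]] | np.ndarray) -> float:
    """Cluster compactness S: sample SD of member-to-centroid distances.

    Undefined for fewer than two members (returns NaN, never 0 — a singleton
    carries no spread information).
    """
    arr = np.asarray(xy, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("expected an (n, 2) array of signals")
    if len(arr) < 2:
        return float("nan")
    centroid = arr.mean(axis=0)
    d = np.hypot(*(arr - centroid).T)
    return float(np.std(d, ddof=1))


def summarize_clusters(
    points: Sequence[FluorescencePoint],
    calls: pd.DataFrame,
    ntc_by_assay: Mapping[tuple[str, str], NtcReference],
    a11_only: bool = False,
) -> pd.DataFrame:
    """Per-(assay, platform, genotype label) cluster summaries.

    Joins calls onto points by (sample_id, assay_id, platform_id) and, for
    each called genotype cluster with at least one member, reports centroid,
    size, mean separation angle, mean NTC distance and compactness
    (compactness is NaN for singleton clusters).  ``a11_only=True`` restricts
    the output to the A11 cluster, the conventional basis for angle and
    compactness comparisons; NTC-distance comparisons use all clusters.

    Clusters with zero members are simply absent from the output.
    """
    pts = pd.DataFrame(
        {
            "sample_id": [p.sample_id for p in points],
            "assay_id": [p.assay_id for p in points],
            "platform_id": [p.platform_id for p in points],
            "signal_x": [p.signal_x for p in points],
            "signal_y": [p.signal_y for p in points],
            "is_ntc": [p.is_ntc for p in points],
        }
    )
    pts = pts[~pts["is_ntc"]]
    genotyped = calls[calls["label"].isin(GENOTYPE_LABELS)]
    merged = pts.merge(
        genotyped[["sample_id", "assay_id", "platform_id", "label"]],
        on=["sample_id", "assay_id", "platform_id"],
        how="inner",
    )
    rows = []
    for (assay_id, platform_id, label), grp in merged.groupby(
        ["assay_id", "platform_id", "label"], sort=True
    ):
        if a11_only and label != "A11":
            continue
        ntc = ntc_by_assay[(assay_id, platform_id)]
        xy = grp[["signal_x", "signal_y"]].to_numpy()
        angles = separation_angles(xy, ntc)
        delta = xy - np.asarray(ntc.centroid)
        dists = np.hypot(delta[:, 0], delta[:, 1])
        rows.append(
            {
                "assay_id": assay_id,
                "platform_id": platform_id,
                "label": label,
                "n": len(grp),
                "centroid_x": float(xy[:, 0].mean()),
                "centroid_y": float(xy[:, 1].mean()),
                "mean_angle_rad": float(angles.mean()),
                "mean_ntc_distance": float(dists.mean()),
                "compactness": compactness(xy),
            }
        )
    return pd.DataFrame(rows, columns=list(METRICS_COLUMNS))
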