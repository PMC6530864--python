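"""Genotype calling from two-channel endpoint fluorescence.

Commercial genotyping software auto-calls alleles with undocumented
proprietary logic; this module is a transparent replacement.  The caller is
anchored on the no-template controls of each assay x platform and proceeds in
three stages:

1. **FAILED** — wells whose signal is indistinguishable from the NTC cloud
   (within ``failed_radius_mult`` NTC spreads of the NTC centroid, with an
   absolute floor of ``ntc_floor_frac`` of the assay's 90th-percentile NTC
   distance; with only two NTC wells the spread estimate alone is far too
   variable to threshold on).
2. **INVALID** — amplified wells whose fluorescence is too low to classify:
   NTC distance below ``invalid_radius_frac`` of the 90th-percentile NTC
   distance of the amplified wells.
3. **Genotypes** — the remaining wells are clustered by k-means (k = 3) in
   (separation angle, log NTC distance) coordinates — angle is the field's own
   discrimination axis, so the caller is consistent with the reported
   metrics — with fixed initial centroids at 15/45/75 degrees on the observed
   median radius.  Clusters are labelled A11 / A12 / A22 in ascending mean
   angle; a cluster with fewer than two members (e.g. a heterozygote-free
   assay splitting a homozygote cloud) is merged into its angular neighbour.

Call quality is the posterior probability of the assigned cluster under an
isotropic Gaussian mixture fitted to the final clusters, so it lives in
[0, 1] and equals 1 in the noise-free limit.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .plate_io import CALL_COLUMNS, FluorescencePoint, GENOTYPE_LABELS

__all__ = [
    "NtcReference",
    "CallerParams",
    "ReferenceMissingError",
    "ntc_reference",
    "call_assay",
    "call_experiment",
    "call_rate_summary",
]

#: Initial k-means angles (radians): the idealized A11 / A12 / A22 geometry.
_INIT_ANGLES = (math.pi / 12, math.pi / 4, 5 * math.pi / 12)


class ReferenceMissingError(ValueError):
    """An assay x platform has no NTC wells to anchor the caller on."""


@dataclass(frozen=True)
class NtcReference:
    """No-template-control anchor of one assay x platform.

    ``centroid`` is the per-channel arithmetic mean of the NTC wells,
    ``spread`` the RMS distance of NTC wells from that centroid (0 for a
    single NTC).
    """

    centroid: tuple[float, float]
    spread: float
    n_ntc: int


@dataclass(frozen=True)
class CallerParams:
    """Tunable thresholds of the three-stage caller.

    failed_radius_mult : multiple of the NTC spread within which a well is
        FAILED (default 3.0).
    ntc_floor_frac : absolute floor on the FAILED radius, as a fraction of the
        assay's 90th-percentile NTC distance (default 0.05); guards against
        underestimated spread from few NTC wells.
    invalid_radius_frac : amplified wells closer to the NTC than this fraction
        of the amplified 90th-percentile NTC distance are INVALID (default 0.25).
    min_quality : genotype calls with posterior quality below this become
        INVALID (default 0.0, i.e. disabled).
    merge_gap_mult : adjacent clusters whose mean angles sit closer than this
        multiple of their pooled within-cluster angle SD are merge
        candidates (default 4.0).  A Gaussian cloud split in half leaves its
        halves about 2.7 pooled SDs apart, while genuine genotype clusters
        sit much further, so this rule undoes the spurious 3-way split
        k-means produces on heterozygote-free assays.
    max_merge_gap : absolute ceiling (radians) on any merge: clusters whose
        mean angles differ by more than this are never merged, whatever
        their spread (default pi/12, half the idealized 30-degree spacing
        between neighbouring genotype clusters).  Keeps very noisy genuine
        clusters intact.
    """

    failed_radius_mult: float = 3.0
    invalid_radius_frac: float = 0.25
    min_quality: float = 0.0
    ntc_floor_frac: float = 0.05
    merge_gap_mult: float = 4.0
    max_merge_gap: float = math.pi / 12
    k: int = 3

    def __post_init__(self) -> None:
        if self.failed_radius_mult <= 0:
            raise ValueError("failed_radius_mult must be positive")
        if not 0 < self.invalid_radius_frac < 1:
            raise ValueError("invalid_radius_frac must lie in (0, 1)")
        if not 0 <= self.min_quality <= 1:
            raise ValueError("min_quality must lie in [0, 1]")
        if not 0 < self.ntc_floor_frac < 1:
            raise ValueError("ntc_floor_frac must lie in (0, 1)")
        if self.merge_gap_mult < 0:
            raise ValueError("merge_gap_mult must be non-negative")
        if self.max_merge_gap < 0:
            raise ValueError("max_merge_gap must be non-negative")
        if self.k != 3:
            raise ValueError("the caller is defined for k = 3 genotype clusters")


def ntc_reference(points: Sequence[FluorescencePoint]) -> NtcReference:
    """Compute the NTC anchor from the ``is_ntc`` points of one assay x platform."""
    ntc = [(p.signal_x, p.signal_y) for p in points if p.is_ntc]
    if not ntc:
        raise ReferenceMissingError("no NTC wells present for this assay")
    arr = np.asarray(ntc, dtype=float)
    centroid = arr.mean(axis=0)
    spread = float(np.sqrt(np.mean(np.sum((arr - centroid) ** 2, axis=1))))
    return NtcReference(
        centroid=(float(centroid[0]), float(centroid[1])),
        spread=spread,
        n_ntc=len(ntc),
    )


def _merge_small_clusters(
    assign: np.ndarray, angles: np.ndarray, min_size: int = 2
) -> np.ndarray:
    """Merge clusters with < min_size members into the angular neighbour."""
    while True:
        ids = np.unique(assign)
        if len(ids) <= 1:
            return assign
        sizes = {c: int(np.sum(assign == c)) for c in ids}
        small = [c for c in ids if sizes[c] < min_size]
        if not small:
            return assign
        c = small[0]
        mean_angles = {k: float(np.mean(angles[assign == k])) for k in ids}
        neighbour = min(
            (k for k in ids if k != c),
            key=lambda k: abs(mean_angles[k] - mean_angles[c]),
        )
        assign[assign == c] = neighbour


def _merge_split_clusters(
    assign: np.ndarray, angles: np.ndarray, gap_mult: float, max_gap: float
) -> np.ndarray:
    """Merge angularly adjacent clusters that look like halves of one cloud.

    Two adjacent clusters are merged when the gap between their mean angles
    is below ``gap_mult`` times the pooled within-cluster angle SD and below
    the absolute ceiling ``max_gap``; the rule is scale-free (angles only)
    and repeats until stable.
    """
    while True:
        ids = sorted(
            np.unique(assign), key=lambda c: float(np.mean(angles[assign == c]))
        )
        if len(ids) <= 1:
            return assign
        merged = False
        for a, b in zip(ids, ids[1:]):
            ang_a, ang_b = angles[assign == a], angles[assign == b]
            gap = abs(float(np.mean(ang_b)) - float(np.mean(ang_a)))
            df = len(ang_a) + len(ang_b) - 2
            pooled_var = (
                np.sum((ang_a - ang_a.mean()) ** 2)
                + np.sum((ang_b - ang_b.mean()) ** 2)
            ) / max(df, 1)
            if gap < max_gap and gap < gap_mult * math.sqrt(float(pooled_var)):
                assign[assign == b] = a
                merged = True
                break
        if not merged:
            return assign


def _label_clusters(assign: np.ndarray, angles: np.ndarray) -> dict[int, str]:
    """Assign genotype labels to final clusters by ascending mean angle.

    With fewer than three clusters the label subset is chosen (order
    preserved) to minimize total distance of cluster mean angles from the
    idealized 15/45/75-degree geometry, so a two-cluster assay resolves to
    the two most plausible genotype classes.
    """
    ids = sorted(np.unique(assign), key=lambda c: float(np.mean(angles[assign == c])))
    canonical = dict(zip(GENOTYPE_LABELS, _INIT_ANGLES))
    best = None
    for combo in itertools.combinations(GENOTYPE_LABELS, len(ids)):
        cost = sum(
            abs(float(np.mean(angles[assign == c])) - canonical[label])
            for c, label in zip(ids, combo)
        )
        if best is None or cost < best[0]:
            best = (cost, combo)
    return dict(zip(ids, best[1]))


def _mixture_posteriors(
    xy: np.ndarray, assign: np.ndarray, scale: float
) -> np.ndarray:
    """Posterior of each point's own cluster under an isotropic Gaussian
    mixture fitted to the final clusters (weights = cluster proportions)."""
    ids = np.unique(assign)
    var_floor = max(1e-9 * scale, 1e-300) ** 2
    means, variances, weights = [], [], []
    for c in ids:
        member = xy[assign == c]
        mu = member.mean(axis=0)
        # per-dimension isotropic variance, floored so a degenerate
        # (noise-free) cluster still yields a proper density
        var = float(np.mean(np.sum((member - mu) ** 2, axis=1)) / 2.0)
        means.append(mu)
        variances.append(max(var, var_floor))
        weights.append(len(member) / len(xy))
    log_dens = np.empty((len(xy), len(ids)))
    for j, (mu, var, w) in enumerate(zip(means, variances, weights)):
        sq = np.sum((xy - mu) ** 2, axis=1)
        log_dens[:, j] = math.log(w) - math.log(2 * math.pi * var) - sq / (2 * var)
    log_dens -= log_dens.max(axis=1, keepdims=True)
    dens = np.exp(log_dens)
    post = dens / dens.sum(axis=1, keepdims=True)
    col = {c: j for j, c in enumerate(ids)}
    return post[np.arange(len(xy)), [col[c] for c in assign]]


def call_assay(
    points: Sequence[FluorescencePoint],
    ntc: NtcReference,
    params: CallerParams | None = None,
) -> pd.DataFrame:
    """Call genotypes for the points of one assay x platform.

    Returns a call table (columns :data:`~fluorotype.plate_io.CALL_COLUMNS`)
    with one row per input point, in input order.  NTC wells are labelled
    ``NTC``; quality is recorded only for genotype calls.  The procedure is
    deterministic and invariant to row order and to a common positive
    rescaling of all signals.
    """
    params = params or CallerParams()
    n = len(points)
    xy = np.array([(p.signal_x, p.signal_y) for p in points], dtype=float)
    is_ntc = np.array([p.is_ntc for p in points], dtype=bool)

    labels = np.full(n, "", dtype=object)
    quality = np.full(n, np.nan)
    labels[is_ntc] = "NTC"

    delta = xy - np.asarray(ntc.centroid)
    dist = np.hypot(delta[:, 0], delta[:, 1])

    sample = ~is_ntc
    # Stage 1: FAILED.  Proportional threshold with an absolute floor taken
    # from the overall signal scale of the assay.
    p90_all = float(np.percentile(dist[sample], 90)) if sample.any() else 0.0
    failed_radius = max(
        params.failed_radius_mult * ntc.spread, params.ntc_floor_frac * p90_all
    )
    failed = sample & (dist <= failed_radius)
    labels[failed] = "FAILED"

    # Stage 2: INVALID (weak amplification).
    amplified = sample & ~failed
    if amplified.any():
        p90_amp = float(np.percentile(dist[amplified], 90))
        invalid = amplified & (dist < params.invalid_radius_frac * p90_amp)
        labels[invalid] = "INVALID"
        amplified &= ~invalid

    idx = np.flatnonzero(amplified)
    if len(idx) < 3:
        # Too few amplified points to resolve clusters: assay is uncallable.
        labels[idx] = "INVALID"
    elif len(idx):
        angles = np.arctan2(delta[idx, 1], delta[idx, 0])
        log_r = np.log(dist[idx])
        feats = np.column_stack([angles, log_r])
        med_log_r = float(np.median(log_r))
        init = np.array([[a, med_log_r] for a in _INIT_ANGLES])
        km = KMeans(n_clusters=3, init=init, n_init=1, random_state=0)
        assign = km.fit_predict(feats)
        assign = _merge_small_clusters(assign, angles)
        assign = _merge_split_clusters(
            assign, angles, params.merge_gap_mult, params.max_merge_gap
        )
        assign = _merge_small_clusters(assign, angles)
        label_of = _label_clusters(assign, angles)
        post = _mixture_posteriors(xy[idx], assign, scale=max(p90_all, ntc.spread))
        for row, c, q in zip(idx, assign, post):
            if q < params.min_quality:
                labels[row] = "INVALID"
            else:
                labels[row] = label_of[c]
                quality[row] = float(min(max(q, 0.0), 1.0))

    return pd.DataFrame(
        {
            "sample_id": [p.sample_id for p in points],
            "assay_id": [p.assay_id for p in points],
            "platform_id": [p.platform_id for p in points],
            "label": labels,
            "quality": quality,
        },
        columns=list(CALL_COLUMNS),
    )


def call_experiment(
    points_by_platform: Mapping[str, Sequence[FluorescencePoint]],
    params: CallerParams | None = None,
) -> tuple[pd.DataFrame, dict[tuple[str, str], NtcReference]]:
    """Call every assay of every platform; returns the combined call table
    and the NTC references keyed by (assay_id, platform_id)."""
    tables = []
    refs: dict[tuple[str, str], NtcReference] = {}
    for platform_id, points in points_by_platform.items():
        by_assay: dict[str, list[FluorescencePoint]] = {}
        for p in points:
            by_assay.setdefault(p.assay_id, []).append(p)
        for assay_id, assay_points in by_assay.items():
            ref = ntc_reference(assay_points)
            refs[(assay_id, platform_id)] = ref
            tables.append(call_assay(assay_points, ref, params))
    calls = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame(
        columns=list(CALL_COLUMNS)
    )
    return calls, refs


def call_rate_summary(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-platform call-rate bookkeeping.

    ``failed_pct`` is FAILED / non-NTC wells, ``amplified_pct`` its
    complement; invalid wells count among the amplified, ``n_called`` are the
    wells that received a genotype.
    """
    if calls.empty:
        raise ValueError("empty call table")
    rows = []
    for platform_id, grp in calls.groupby("platform_id", sort=True):
        sample = grp[grp["label"] != "NTC"]
        n = len(sample)
        n_failed = int((sample["label"] == "FAILED").sum())
        n_invalid = int((sample["label"] == "INVALID").sum())
        n_called = int(sample["label"].isin(GENOTYPE_LABELS).sum())
        failed_pct = 100.0 * n_failed / n if n else float("nan")
        rows.append(
            {
                "platform_id": platform_id,
                "n_points": n,
                "n_failed": n_failed,
                "failed_pct": failed_pct,
                "amplified_pct": 100.0 - failed_pct,
                "n_invalid": n_invalid,
                "n_called": n_called,
            }
        )
    return pd.DataFrame(rows)
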