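"""Statistical comparison of genotyping platforms.

One-way fixed-effects ANOVA under a completely randomized design (each
successful amplification — or each cluster, depending on the replication
unit — is a replication), Fisher's LSD mean separation with compact letter
display, and pairwise genotype concordance between platforms.

Replication unit: call quality is naturally a per-point quantity (thousands
of residual degrees of freedom), while angle, compactness and NTC distance
are per-cluster quantities (one value per assay x platform cluster); both
units are supported and the defaults follow that convention.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .plate_io import GENOTYPE_LABELS

__all__ = [
    "AnovaTable",
    "LsdGrouping",
    "ConcordanceCell",
    "StatisticalError",
    "anova_crd",
    "lsd_letters",
    "concordance",
    "concordance_matrix",
    "compare_platforms",
]


class StatisticalError(ValueError):
    """A statistical precondition (group sizes, degrees of freedom) fails."""


@dataclass(frozen=True)
class AnovaTable:
    """One-way CRD ANOVA decomposition for a single metric."""

    metric: str
    df_between: int
    ss_between: float
    ms_between: float
    f_value: float
    p_value: float
    df_within: int
    ss_within: float
    ms_within: float
    grand_mean: float
    group_means: Mapping[str, float]
    group_sizes: Mapping[str, int]


@dataclass(frozen=True)
class LsdGrouping:
    """Fisher-LSD mean separation with a compact letter display.

    Two groups share a letter exactly when their mean difference does not
    exceed their pairwise LSD ``t(1 - alpha/2, df_within) *
    sqrt(MS_within * (1/n_i + 1/n_j))``.  Letters run from "a" downward in
    descending-mean order.  ``lsd_value`` is the representative LSD at the
    harmonic-mean group size; ``pairwise_lsd`` holds every pair's threshold.
    """

    metric: str
    alpha: float
    means: Mapping[str, float]
    letters: Mapping[str, str]
    lsd_value: float
    pairwise_lsd: Mapping[tuple[str, str], float] = field(default_factory=dict)


@dataclass(frozen=True)
class ConcordanceCell:
    """Agreement between two platforms over jointly genotyped cells."""

    platform_a: str
    platform_b: str
    n_joint: int
    n_agree: int

    @property
    def concordance(self) -> float | None:
        """Fraction agreeing, or None when no cell was genotyped by both."""
        if self.n_joint == 0:
            return None
        return self.n_agree / self.n_joint


def anova_crd(
    values: Sequence[float] | np.ndarray,
    groups: Sequence[str],
    metric: str = "",
) -> AnovaTable:
    """One-way fixed-effects ANOVA (completely randomized design).

    Requires at least two groups with at least two observations each.  When
    the within-group variance is exactly zero, F is 0 (p = 1) if the group
    means coincide and +inf (p = 0) otherwise.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups, dtype=object)
    if values.shape != groups.shape:
        raise ValueError("values and groups must have equal length")
    names = sorted(set(groups))
    if len(names) < 2:
        raise StatisticalError("ANOVA requires at least two groups")
    by_group = {name: values[groups == name] for name in names}
    for name, obs in by_group.items():
        if len(obs) < 2:
            raise StatisticalError(
                f"group {name!r} has fewer than two observations"
            )
    n_total = len(values)
    grand = float(values.mean())
    means = {name: float(obs.mean()) for name, obs in by_group.items()}
    sizes = {name: int(len(obs)) for name, obs in by_group.items()}
    ss_between = float(
        sum(sizes[name] * (means[name] - grand) ** 2 for name in names)
    )
    ss_within = float(
        sum(np.sum((by_group[name] - means[name]) ** 2) for name in names)
    )
    df_between = len(names) - 1
    df_within = n_total - len(names)
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0.0:
        if ss_between == 0.0:
            f_value, p_value = 0.0, 1.0
        else:
            f_value, p_value = float("inf"), 0.0
    else:
        f_value = ms_between / ms_within
        p_value = float(stats.f.sf(f_value, df_between, df_within))
    return AnovaTable(
        metric=metric,
        df_between=df_between,
        ss_between=ss_between,
        ms_between=ms_between,
        f_value=f_value,
        p_value=p_value,
        df_within=df_within,
        ss_within=ss_within,
        ms_within=ms_within,
        grand_mean=grand,
        group_means=means,
        group_sizes=sizes,
    )


def _maximal_cliques(names: Sequence[str], nonsig) -> list[tuple[str, ...]]:
    """Maximal mutually-nonsignificant subsets, by subset enumeration.

    Platform comparisons involve a handful of groups, so 2^k enumeration is
    exact and cheap; it guarantees the share-a-letter relation mirrors
    pairwise non-significance exactly.
    """
    if len(names) > 16:
        raise StatisticalError("letter display limited to 16 groups")
    cliques: list[tuple[str, ...]] = []
    for r in range(len(names), 0, -1):
        for combo in itertools.combinations(names, r):
            if any(set(combo) <= set(c) for c in cliques):
                continue
            if all(nonsig(a, b) for a, b in itertools.combinations(combo, 2)):
                cliques.append(combo)
    return cliques


def lsd_letters(anova: AnovaTable, alpha: float = 0.05) -> LsdGrouping:
    """Fisher's LSD mean separation with letters.

    Unequal group sizes use the per-pair LSD with (1/n_i + 1/n_j).  Letter
    sets are the maximal groups of mutually non-different means, lettered in
    descending order of their largest mean, so every group holds at least one
    letter and two groups share a letter iff their difference is within LSD.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if anova.df_within < 1:
        raise StatisticalError("LSD requires at least one residual df")
    t_crit = float(stats.t.ppf(1 - alpha / 2, anova.df_within))
    names = sorted(anova.group_means, key=anova.group_means.get, reverse=True)
    pairwise: dict[tuple[str, str], float] = {}
    for a, b in itertools.combinations(sorted(names), 2):
        lsd = t_crit * math.sqrt(
            anova.ms_within * (1 / anova.group_sizes[a] + 1 / anova.group_sizes[b])
        )
        pairwise[(a, b)] = pairwise[(b, a)] = lsd

    def nonsig(a: str, b: str) -> bool:
        return abs(anova.group_means[a] - anova.group_means[b]) <= pairwise[(a, b)]

    cliques = _maximal_cliques(names, nonsig)
    cliques.sort(key=lambda c: -max(anova.group_means[g] for g in c))
    letters = {name: "" for name in names}
    for letter, clique in zip("abcdefghijklmnop", cliques):
        for name in clique:
            letters[name] += letter

    k = len(names)
    n_harm = k / sum(1 / anova.group_sizes[g] for g in names)
    lsd_value = t_crit * math.sqrt(anova.ms_within * 2 / n_harm)
    return LsdGrouping(
        metric=anova.metric,
        alpha=alpha,
        means=dict(anova.group_means),
        letters=letters,
        lsd_value=lsd_value,
        pairwise_lsd=pairwise,
    )


def _genotyped(calls: pd.DataFrame) -> pd.DataFrame:
    return calls[calls["label"].isin(GENOTYPE_LABELS)]


def concordance(calls_a: pd.DataFrame, calls_b: pd.DataFrame) -> ConcordanceCell:
    """Genotype concordance between two platforms' call tables.

    Only sample x assay cells genotyped (A11/A12/A22) by *both* platforms
    enter the denominator; FAILED/INVALID/NTC cells are excluded entirely.
    Heterozygote-vs-homozygote mismatches count as discordant.
    """
    a = _genotyped(calls_a)
    b = _genotyped(calls_b)
    pid_a = a["platform_id"].iloc[0] if len(a) else "a"
    pid_b = b["platform_id"].iloc[0] if len(b) else "b"
    joint = a[["sample_id", "assay_id", "label"]].merge(
        b[["sample_id", "assay_id", "label"]],
        on=["sample_id", "assay_id"],
        suffixes=("_a", "_b"),
    )
    return ConcordanceCell(
        platform_a=str(pid_a),
        platform_b=str(pid_b),
        n_joint=len(joint),
        n_agree=int((joint["label_a"] == joint["label_b"]).sum()),
    )


def concordance_matrix(calls: pd.DataFrame) -> pd.DataFrame:
    """All pairwise concordances from a combined call table.

    Returns one row per unordered platform pair with n_joint, n_agree and
    concordance (NaN when undefined).
    """
    platforms = sorted(calls["platform_id"].unique())
    rows = []
    for a, b in itertools.combinations(platforms, 2):
        cell = concordance(
            calls[calls["platform_id"] == a], calls[calls["platform_id"] == b]
        )
        rows.append(
            {
                "platform_a": a,
                "platform_b": b,
                "n_joint": cell.n_joint,
                "n_agree": cell.n_agree,
                "concordance": (
                    float("nan") if cell.concordance is None else cell.concordance
                ),
            }
        )
    return pd.DataFrame(rows)


#: Default replication unit per metric: call quality is a per-point
#: observation; the geometric metrics are per-cluster observations.
DEFAULT_UNITS = {
    "call_quality": "per_point",
    "separation_angle": "per_cluster",
    "compactness": "per_cluster",
    "ntc_distance": "per_cluster",
}


def compare_platforms(
    summaries: pd.DataFrame,
    calls: pd.DataFrame,
    points: pd.DataFrame | None = None,
    ntc_by_assay: Mapping[tuple[str, str], object] | None = None,
    alpha: float = 0.05,
    units: Mapping[str, str] | None = None,
    a11_only: bool = True,
) -> dict[str, tuple[AnovaTable, LsdGrouping]]:
    """Run the four per-metric platform comparisons.

    ``summaries`` is the cluster-summary table (all labels); angle and
    compactness comparisons are restricted to the A11 cluster when
    ``a11_only`` (the conventional basis), NTC distance always uses all
    called clusters, and call quality uses the per-point qualities from
    ``calls``.  ``units`` may override the replication unit per metric
    ("per_point" requires *points* and *ntc_by_assay* for the geometric
    metrics).  Returns ``{metric: (AnovaTable, LsdGrouping)}``.
    """
    units = {**DEFAULT_UNITS, **(units or {})}
    results: dict[str, tuple[AnovaTable, LsdGrouping]] = {}

    genotyped = _genotyped(calls)
    quality = genotyped.dropna(subset=["quality"])
    anova = anova_crd(
        quality["quality"].to_numpy(),
        quality["platform_id"].to_numpy(),
        metric="call_quality",
    )
    results["call_quality"] = (anova, lsd_letters(anova, alpha))

    def per_point_values(column: str, restrict_a11: bool) -> pd.DataFrame:
        if points is None or ntc_by_assay is None:
            raise ValueError(
                "per_point geometric metrics require points and NTC references"
            )
        from .cluster_metrics import separation_angles

        merged = points[~points["is_ntc"]].merge(
            genotyped[["sample_id", "assay_id", "platform_id", "label"]],
            on=["sample_id", "assay_id", "platform_id"],
        )
        if restrict_a11:
            merged = merged[merged["label"] == "A11"]
        out = []
        for (assay_id, platform_id), grp in merged.groupby(
            ["assay_id", "platform_id"]
        ):
            ntc = ntc_by_assay[(assay_id, platform_id)]
            xy = grp[["signal_x", "signal_y"]].to_numpy()
            delta = xy - np.asarray(ntc.centroid)
            if column == "mean_angle_rad":
                vals = separation_angles(xy, ntc)
            else:
                vals = np.hypot(delta[:, 0], delta[:, 1])
            out.append(pd.DataFrame({"platform_id": platform_id, "value": vals}))
        return pd.concat(out, ignore_index=True)

    geo = [
        ("separation_angle", "mean_angle_rad", a11_only),
        ("compactness", "compactness", a11_only),
        ("ntc_distance", "mean_ntc_distance", False),
    ]
    for metric, column, restrict in geo:
        if units.get(metric) == "per_point" and metric != "compactness":
            table = per_point_values(column, restrict)
            vals, grp = table["value"].to_numpy(), table["platform_id"].to_numpy()
        else:
            rows = summaries[summaries["label"] == "A11"] if restrict else summaries
            rows = rows.dropna(subset=[column])
            vals = rows[column].to_numpy()
            grp = rows["platform_id"].to_numpy()
        anova = anova_crd(vals, grp, metric=metric)
        results[metric] = (anova, lsd_letters(anova, alpha))
    return results
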