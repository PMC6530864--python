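"""Synthetic two-channel fluorescence plate generator.

Endpoint-fluorescence genotyping experiments read two allele-specific reporter
channels per well after PCR; the three genotype classes appear as clusters in
the (signal_x, signal_y) plane: homozygote A11 near the X-axis, homozygote A22
near the Y-axis, and heterozygote A12 along the diagonal.  This module plants
that geometry explicitly so every downstream stage (calling, cluster metrics,
platform comparison) can be validated against known truth.

Model
-----
Each platform profile defines an NTC (no-template control) anchor and, per
genotype label, a centroid at polar coordinates ``(gain * r_label, angle_label)``
measured from the NTC center, with ``r_A11 = r_A22 = 1`` and ``r_A12 = 1/sqrt(2)``
by default (so the heterozygote's per-channel signal is comparable to a
homozygote's single active channel).  Called wells are isotropic-Gaussian
scatter around their centroid; wells that fail to amplify are drawn from the
NTC distribution; "invalid" wells amplify weakly, at a radius uniform between
twice the NTC noise and a quarter of the platform gain.

Genotype truth is a property of the DNA: the same sample x assay genotype is
shared by every platform, while amplification outcome (called / failed /
invalid) is drawn independently per platform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .plate_io import FluorescencePoint

__all__ = [
    "PlatformProfile",
    "SimConfig",
    "TruthRecord",
    "simulate_experiment",
    "default_three_platform_config",
    "write_truth",
    "read_truth",
    "load_sim_config",
]

OUTCOMES = ("called", "failed", "invalid")

#: Radial scale of each genotype centroid relative to the platform gain.
DEFAULT_HET_RADIUS = 1.0 / math.sqrt(2.0)


@dataclass(frozen=True)
class PlatformProfile:
    """Fluorescence geometry and failure behaviour of one genotyping chemistry.

    Parameters
    ----------
    gain
        Mean NTC-to-homozygote-centroid distance, in normalized fluorescence
        units.  This is the quantity the NTC-to-cluster distance metric
        recovers.
    angle_a11, angle_a12, angle_a22
        Planted separation angles (radians from the X-axis, measured at the
        NTC anchor) of the three genotype centroids.  A11 sits in (0, pi/4),
        A22 in (pi/4, pi/2), A12 on the diagonal by default.
    noise_sd
        Isotropic per-point fluorescence SD of called wells.
    fail_rate, invalid_rate
        Per-well probabilities of failed amplification and of weak "invalid"
        amplification.
    ntc_center, ntc_sd
        Mean and isotropic SD of the NTC signal distribution.
    """

    platform_id: str
    gain: float
    angle_a11: float
    angle_a22: float
    noise_sd: float
    fail_rate: float = 0.0
    invalid_rate: float = 0.0
    angle_a12: float = math.pi / 4
    ntc_center: tuple[float, float] = (0.0, 0.0)
    ntc_sd: float = 0.0

    def __post_init__(self) -> None:
        numeric = (
            self.gain,
            self.angle_a11,
            self.angle_a12,
            self.angle_a22,
            self.noise_sd,
            self.fail_rate,
            self.invalid_rate,
            *self.ntc_center,
            self.ntc_sd,
        )
        if not all(math.isfinite(v) for v in numeric):
            raise ValueError(f"{self.platform_id}: non-finite profile parameter")
        if self.gain <= 0:
            raise ValueError(f"{self.platform_id}: gain must be positive")
        if self.noise_sd < 0 or self.ntc_sd < 0:
            raise ValueError(f"{self.platform_id}: negative noise SD")
        if not 0 <= self.fail_rate <= 1 or not 0 <= self.invalid_rate <= 1:
            raise ValueError(f"{self.platform_id}: rates must lie in [0, 1]")
        if self.fail_rate + self.invalid_rate > 1:
            raise ValueError(
                f"{self.platform_id}: fail_rate + invalid_rate exceeds 1"
            )
        if not self.angle_a11 < self.angle_a12 < self.angle_a22:
            raise ValueError(
                f"{self.platform_id}: angles must satisfy a11 < a12 < a22"
            )
        if not (0 < self.angle_a11 and self.angle_a22 < math.pi / 2):
            raise ValueError(
                f"{self.platform_id}: genotype angles must lie in (0, pi/2)"
            )

    def angle_of(self, genotype: str) -> float:
        return {
            "A11": self.angle_a11,
            "A12": self.angle_a12,
            "A22": self.angle_a22,
        }[genotype]


@dataclass(frozen=True)
class SimConfig:
    """Layout and sampling parameters of a simulated experiment.

    Defaults emulate the study design the package targets: 94 samples plus
    2 NTC wells (one 96-well column block per assay on 384-well plates) by
    29 scorable assays, run on every platform profile.  ``maf`` is the
    allele-2 frequency; genotypes are drawn per sample x assay once and
    shared across platforms.
    """

    platforms: tuple[PlatformProfile, ...]
    n_samples: int = 94
    n_ntc: int = 2
    n_assays: int = 29
    maf: float = 0.5
    het_model: Literal["hardy_weinberg", "fixed_fraction"] = "hardy_weinberg"
    het_fraction: float = 0.05
    het_radius: float = DEFAULT_HET_RADIUS
    assay_angle_jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_assays < 1 or self.n_ntc < 0:
            raise ValueError("layout counts out of range")
        if not 0 < self.maf < 1:
            raise ValueError("maf must lie in (0, 1)")
        if self.het_model not in ("hardy_weinberg", "fixed_fraction"):
            raise ValueError(f"unknown het_model {self.het_model!r}")
        if not 0 <= self.het_fraction <= 1:
            raise ValueError("het_fraction must lie in [0, 1]")
        if self.het_radius <= 0:
            raise ValueError("het_radius must be positive")
        if self.assay_angle_jitter_sd < 0:
            raise ValueError("assay_angle_jitter_sd must be non-negative")
        if not self.platforms:
            raise ValueError("at least one platform profile required")
        ids = [p.platform_id for p in self.platforms]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate platform_id in config")

    @property
    def wells_per_assay(self) -> int:
        return self.n_samples + self.n_ntc

    @property
    def points_per_platform(self) -> int:
        return self.wells_per_assay * self.n_assays


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one sample x assay cell.

    ``true_genotype`` is platform-invariant (a property of the DNA);
    ``outcomes`` maps each platform_id to "called", "failed" or "invalid".
    """

    sample_id: str
    assay_id: str
    true_genotype: str
    outcomes: Mapping[str, str]


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _well_ids(n_wells: int, assay_index: int) -> list[str]:
    """384-well labels (rows A-P, columns 01-24), row-major, one 96-well
    block per assay, four assay blocks per plate.  Labels only; no
    coordinate math depends on them."""
    start = (assay_index % 4) * 96
    ids = []
    for k in range(start, start + n_wells):
        row, col = divmod(k, 24)
        ids.append(f"{chr(ord('A') + row)}{col + 1:02d}")
    return ids


def _genotype_probs(config: SimConfig) -> tuple[float, float, float]:
    p = config.maf
    if config.het_model == "hardy_weinberg":
        return ((1 - p) ** 2, 2 * p * (1 - p), p**2)
    h = config.het_fraction
    return ((1 - h) * (1 - p), h, (1 - h) * p)


def simulate_experiment(
    config: SimConfig,
) -> tuple[dict[str, list[FluorescencePoint]], list[TruthRecord]]:
    """Simulate one multi-platform genotyping experiment.

    Returns the per-platform point lists (keyed by platform_id, each of
    exactly ``(n_samples + n_ntc) * n_assays`` points) and the shared truth
    table.  All randomness flows from ``config.seed`` through one
    :class:`numpy.random.SeedSequence`; the per-platform streams are spawned
    deterministically from it, so the result is bit-reproducible.
    """
    root = np.random.SeedSequence(config.seed)
    truth_seq, jitter_seq, *platform_seqs = root.spawn(2 + len(config.platforms))
    truth_rng = np.random.default_rng(truth_seq)
    jitter_rng = np.random.default_rng(jitter_seq)

    sample_ids = [f"S{i + 1:03d}" for i in range(config.n_samples)]
    assay_ids = [f"SNP{j + 1:02d}" for j in range(config.n_assays)]

    probs = _genotype_probs(config)
    genotype_codes = truth_rng.choice(
        3, size=(config.n_assays, config.n_samples), p=probs
    )
    genotype_labels = np.array(["A11", "A12", "A22"])

    # Optional per-assay jitter of the centroid angles (default 0): one draw
    # per assay x platform, applied to all three genotype angles of that assay.
    jitter = jitter_rng.normal(
        0.0,
        config.assay_angle_jitter_sd,
        size=(len(config.platforms), config.n_assays),
    )
    if config.assay_angle_jitter_sd == 0:
        jitter[:] = 0.0

    # Per-platform outcome draws, per sample x assay.
    outcomes: dict[str, np.ndarray] = {}
    points: dict[str, list[FluorescencePoint]] = {}
    for p_idx, (profile, seq) in enumerate(zip(config.platforms, platform_seqs)):
        rng = np.random.default_rng(seq)
        if profile.invalid_rate > 0 and 2 * profile.ntc_sd >= 0.25 * profile.gain:
            raise ValueError(
                f"{profile.platform_id}: invalid-radius band is empty "
                "(2*ntc_sd >= 0.25*gain)"
            )
        u = rng.random(size=(config.n_assays, config.n_samples))
        out = np.full((config.n_assays, config.n_samples), "called", dtype=object)
        out[u < profile.fail_rate] = "failed"
        out[(u >= profile.fail_rate) & (u < profile.fail_rate + profile.invalid_rate)] = (
            "invalid"
        )
        outcomes[profile.platform_id] = out

        cx, cy = profile.ntc_center
        plate: list[FluorescencePoint] = []
        for j, assay_id in enumerate(assay_ids):
            wells = _well_ids(config.wells_per_assay, j)
            for i, sample_id in enumerate(sample_ids):
                genotype = genotype_labels[genotype_codes[j, i]]
                outcome = out[j, i]
                if outcome == "failed":
                    x, y = rng.normal((cx, cy), profile.ntc_sd)
                elif outcome == "invalid":
                    radius = rng.uniform(2 * profile.ntc_sd, 0.25 * profile.gain)
                    theta = profile.angle_of(genotype) + jitter[p_idx, j]
                    x = cx + radius * math.cos(theta)
                    y = cy + radius * math.sin(theta)
                else:
                    theta = profile.angle_of(genotype) + jitter[p_idx, j]
                    r = profile.gain * (
                        config.het_radius if genotype == "A12" else 1.0
                    )
                    mx = cx + r * math.cos(theta)
                    my = cy + r * math.sin(theta)
                    x, y = rng.normal((mx, my), profile.noise_sd)
                plate.append(
                    FluorescencePoint(
                        well_id=wells[i],
                        sample_id=sample_id,
                        assay_id=assay_id,
                        platform_id=profile.platform_id,
                        signal_x=float(x),
                        signal_y=float(y),
                    )
                )
            for k in range(config.n_ntc):
                x, y = rng.normal((cx, cy), profile.ntc_sd)
                plate.append(
                    FluorescencePoint(
                        well_id=wells[config.n_samples + k],
                        sample_id="NTC",
                        assay_id=assay_id,
                        platform_id=profile.platform_id,
                        signal_x=float(x),
                        signal_y=float(y),
                        is_ntc=True,
                    )
                )
        points[profile.platform_id] = plate

    truth = [
        TruthRecord(
            sample_id=sample_ids[i],
            assay_id=assay_ids[j],
            true_genotype=str(genotype_labels[genotype_codes[j, i]]),
            outcomes={
                profile.platform_id: str(outcomes[profile.platform_id][j, i])
                for profile in config.platforms
            },
        )
        for j in range(config.n_assays)
        for i in range(config.n_samples)
    ]
    return points, truth


def default_three_platform_config(seed: int = 0, **overrides) -> SimConfig:
    """The "paper-like" scenario: three platform chemistries on the standard
    94-sample + 2-NTC x 29-assay layout.

    The profiles encode the qualitative contrasts the platforms are known
    for: the rhAmp-style chemistry has by far the highest fluorescence gain
    (longest NTC-to-cluster distance), the TaqMan-style chemistry the most
    compact clusters but the widest A11 separation angle, and the KASP-style
    chemistry the lowest gain.  Failure and invalid rates follow the observed
    per-platform call-rate contrasts (TaqMan 7% / KASP 6.5% / rhAmp 3%
    unamplified; invalid calls concentrated on TaqMan).  The profiles are a
    deterministic function of nothing: the seed only drives sampling.

    A diversity panel of inbred wheat lines is almost fully homozygous, so
    the default heterozygote model is ``fixed_fraction`` with 5% A12.
    """
    profiles = (
        PlatformProfile(
            platform_id="rhAmp",
            gain=5.0,
            angle_a11=0.19,
            angle_a22=math.pi / 2 - 0.19,
            noise_sd=0.30,
            fail_rate=0.03,
            invalid_rate=7 / 2726,
            ntc_center=(0.2, 0.2),
            ntc_sd=0.02,
        ),
        PlatformProfile(
            platform_id="KASP",
            gain=1.5,
            angle_a11=0.19,
            angle_a22=math.pi / 2 - 0.19,
            noise_sd=0.075,
            fail_rate=0.065,
            invalid_rate=13 / 2726,
            ntc_center=(0.2, 0.2),
            ntc_sd=0.02,
        ),
        PlatformProfile(
            platform_id="TaqMan",
            gain=1.9,
            angle_a11=0.35,
            angle_a22=math.pi / 2 - 0.35,
            noise_sd=0.038,
            fail_rate=0.07,
            invalid_rate=57 / 2726,
            ntc_center=(0.2, 0.2),
            ntc_sd=0.02,
        ),
    )
    params = dict(
        platforms=profiles,
        n_samples=94,
        n_ntc=2,
        n_assays=29,
        maf=0.5,
        het_model="fixed_fraction",
        het_fraction=0.05,
        seed=seed,
    )
    params.update(overrides)
    return SimConfig(**params)


# ---------------------------------------------------------------------------
# Truth-table and config serialization
# ---------------------------------------------------------------------------

def truth_to_frame(truth: Sequence[TruthRecord]) -> pd.DataFrame:
    platform_ids = list(truth[0].outcomes) if truth else []
    data = {
        "sample_id": [t.sample_id for t in truth],
        "assay_id": [t.assay_id for t in truth],
        "true_genotype": [t.true_genotype for t in truth],
    }
    for pid in platform_ids:
        data[f"outcome_{pid}"] = [t.outcomes[pid] for t in truth]
    return pd.DataFrame(data)


def write_truth(truth: Sequence[TruthRecord], path: str | Path) -> None:
    """Write the truth table as CSV (one ``outcome_<platform>`` column each)."""
    truth_to_frame(truth).to_csv(path, index=False)


def read_truth(path: str | Path) -> list[TruthRecord]:
    frame = pd.read_csv(path, dtype=str)
    platform_ids = [
        c[len("outcome_"):] for c in frame.columns if c.startswith("outcome_")
    ]
    return [
        TruthRecord(
            sample_id=r["sample_id"],
            assay_id=r["assay_id"],
            true_genotype=r["true_genotype"],
            outcomes={pid: r[f"outcome_{pid}"] for pid in platform_ids},
        )
        for _, r in frame.iterrows()
    ]


def load_sim_config(path: str | Path) -> SimConfig:
    """Load a simulation config from a flat-key YAML file.

    Top-level keys are :class:`SimConfig` fields; ``platforms`` is a list of
    mappings, one :class:`PlatformProfile` block per platform.
    """
    with open(path) as handle:
        raw = yaml.safe_load(handle)
    if not isinstance(raw, dict) or "platforms" not in raw:
        raise ValueError(f"{path}: config must be a mapping with a 'platforms' list")
    profiles = tuple(
        PlatformProfile(
            **{
                **block,
                "ntc_center": tuple(block.get("ntc_center", (0.0, 0.0))),
            }
        )
        for block in raw.pop("platforms")
    )
    return SimConfig(platforms=profiles, **raw)
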