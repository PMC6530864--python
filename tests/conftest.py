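"""Shared fixtures: the full three-platform scenario is simulated and called
once per session and reused by the bookkeeping, caller and comparison tests."""

from __future__ import annotations

import math

import pandas as pd
import pytest

import fluorotype as ft
from fluorotype.synthetic_plates import truth_to_frame


@pytest.fixture(scope="session")
def paper_like_run():
    """Simulate + call the default three-platform experiment (seed 0).

    Returns a dict with config, per-platform points, truth records, the
    combined call table, NTC references and a truth table in long format
    (one row per sample x assay x platform with planted outcome).
    """
    config = ft.default_three_platform_config(seed=0)
    points, truth = ft.simulate_experiment(config)
    calls, refs = ft.call_experiment(points)
    tf = truth_to_frame(truth)
    long = tf.melt(
        id_vars=["sample_id", "assay_id", "true_genotype"],
        value_vars=[c for c in tf.columns if c.startswith("outcome_")],
        var_name="platform_id",
        value_name="outcome",
    )
    long["platform_id"] = long["platform_id"].str.replace(
        "outcome_", "", regex=False
    )
    return {
        "config": config,
        "points": points,
        "truth": truth,
        "calls": calls,
        "refs": refs,
        "truth_long": long,
    }


@pytest.fixture()
def zero_noise_run():
    """A noise- and dropout-free single-platform experiment: every called
    point sits exactly on its genotype centroid."""
    profile = ft.PlatformProfile(
        platform_id="Z",
        gain=3.0,
        angle_a11=0.2,
        angle_a22=math.pi / 2 - 0.2,
        noise_sd=0.0,
        ntc_sd=0.0,
        ntc_center=(0.5, 0.5),
    )
    config = ft.SimConfig(
        platforms=(profile,),
        n_samples=40,
        n_assays=2,
        seed=3,
        het_model="fixed_fraction",
        het_fraction=0.2,
    )
    points, truth = ft.simulate_experiment(config)
    calls, refs = ft.call_experiment(points)
    return {
        "config": config,
        "profile": profile,
        "points": points,
        "truth": truth,
        "calls": calls,
        "refs": refs,
    }


def merge_calls_with_truth(run: dict) -> pd.DataFrame:
    """Join a run's call table onto the planted truth, one row per well."""
    return run["calls"].merge(
        run["truth_long"], on=["sample_id", "assay_id", "platform_id"]
    )
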