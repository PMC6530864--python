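"""One-way CRD ANOVA, LSD letter display and concordance."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from statsmodels.formula.api import ols

import fluorotype as ft
from fluorotype.platform_comparison import StatisticalError


def _vals_groups(groups: dict):
    vals = np.concatenate([np.asarray(v, dtype=float) for v in groups.values()])
    labels = np.concatenate([[k] * len(v) for k, v in groups.items()])
    return vals, labels


class TestAnova:
    def test_textbook_two_group_example(self):
        """Groups {1,2,3} and {4,5,6}: SSB 13.5, SSW 4, F(1,4) = 13.5."""
        vals, grp = _vals_groups({"a": [1, 2, 3], "b": [4, 5, 6]})
        table = ft.anova_crd(vals, grp)
        assert table.ss_between == pytest.approx(13.5)
        assert table.ss_within == pytest.approx(4.0)
        assert table.f_value == pytest.approx(13.5)
        assert table.p_value == pytest.approx(0.0213116411, abs=1e-8)
        assert table.df_between == 1 and table.df_within == 4

    def test_identical_groups_null(self):
        vals, grp = _vals_groups({"a": [2.0, 3.0, 4.0], "b": [2.0, 3.0, 4.0]})
        table = ft.anova_crd(vals, grp)
        assert table.f_value == 0.0 and table.p_value == 1.0

    def test_zero_within_variance_unequal_means(self):
        vals, grp = _vals_groups({"a": [1.0, 1.0], "b": [2.0, 2.0]})
        table = ft.anova_crd(vals, grp)
        assert table.f_value == np.inf and table.p_value == 0.0

    def test_small_group_rejected_by_name(self):
        vals, grp = _vals_groups({"a": [1.0, 2.0], "tiny": [3.0]})
        with pytest.raises(StatisticalError, match="tiny"):
            ft.anova_crd(vals, grp)

    def test_matches_linear_model_oracle(self):
        """F and p agree with a statsmodels OLS fit to 1e-8 relative, and
        SS_total = SS_between + SS_within, on 50 random datasets."""
        rng = np.random.default_rng(11)
        for _ in range(50):
            k = int(rng.integers(2, 5))
            groups = {
                f"g{j}": rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 2.0),
                                    size=int(rng.integers(3, 30)))
                for j in range(k)
            }
            vals, grp = _vals_groups(groups)
            table = ft.anova_crd(vals, grp)
            frame = pd.DataFrame({"y": vals, "g": grp})
            fit = ols("y ~ C(g)", data=frame).fit()
            oracle = sm.stats.anova_lm(fit)
            assert table.f_value == pytest.approx(
                float(oracle["F"].iloc[0]), rel=1e-8
            )
            assert table.p_value == pytest.approx(
                float(oracle["PR(>F)"].iloc[0]), rel=1e-8, abs=1e-300
            )
            ss_total = float(np.sum((vals - vals.mean()) ** 2))
            assert table.ss_between + table.ss_within == pytest.approx(
                ss_total, rel=1e-9
            )

    def test_shift_and_scale_invariance(self):
        """Adding a constant changes no SS; scaling by c multiplies SS by c^2."""
        rng = np.random.default_rng(12)
        groups = {f"g{j}": rng.normal(j, 1.0, 15) for j in range(3)}
        vals, grp = _vals_groups(groups)
        base = ft.anova_crd(vals, grp)
        shifted = ft.anova_crd(vals + 100.0, grp)
        scaled = ft.anova_crd(vals * 3.0, grp)
        assert shifted.ss_between == pytest.approx(base.ss_between, rel=1e-9)
        assert shifted.ss_within == pytest.approx(base.ss_within, rel=1e-9)
        assert scaled.ss_between == pytest.approx(9 * base.ss_between, rel=1e-9)
        assert scaled.ss_within == pytest.approx(9 * base.ss_within, rel=1e-9)

    def test_type_i_error_rate(self):
        """Null rejection rate at alpha = 0.05 is 0.05 +/- 0.01 over 2,000
        seeded replicates (three equal-mean normal groups)."""
        rng = np.random.default_rng(13)
        grp = np.repeat(["a", "b", "c"], 20)
        reject = 0
        n_rep = 2000
        for _ in range(n_rep):
            table = ft.anova_crd(rng.normal(size=60), grp)
            reject += table.p_value < 0.05
        assert abs(reject / n_rep - 0.05) <= 0.01


class TestLsdLetters:
    def _anova(self, groups):
        vals, grp = _vals_groups(groups)
        return ft.anova_crd(vals, grp)

    def test_equal_means_share_one_letter(self):
        table = self._anova(
            {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0], "c": [1.0, 2.0, 3.0]}
        )
        grouping = ft.lsd_letters(table)
        assert set(grouping.letters.values()) == {"a"}

    def test_one_group_separates(self):
        """Means 10, 10.1, 20 with LSD ~ 0.5: the high mean gets its own
        letter and the close pair shares the other (brute-force all-pairs
        oracle: only |10.1 - 10| falls below the threshold)."""
        # ms_within chosen so the equal-n pairwise LSD is exactly 0.5
        from scipy import stats as sps

        t_crit = float(sps.t.ppf(0.975, 57))
        ms_within = (0.5 / t_crit) ** 2 / (2 / 20)
        table = ft.AnovaTable(
            metric="demo", df_between=2, ss_between=1.0, ms_between=0.5,
            f_value=1.0, p_value=0.5, df_within=57,
            ss_within=ms_within * 57, ms_within=ms_within, grand_mean=13.4,
            group_means={"low": 10.0, "mid": 10.1, "high": 20.0},
            group_sizes={"low": 20, "mid": 20, "high": 20},
        )
        grouping = ft.lsd_letters(table)
        assert grouping.lsd_value == pytest.approx(0.5)
        assert grouping.letters["high"] == "a"
        assert grouping.letters["low"] == grouping.letters["mid"] == "b"

    @pytest.mark.parametrize("seed", range(12))
    def test_letters_mirror_pairwise_significance(self, seed):
        """Sharing a letter is exactly equivalent to pairwise LSD
        non-significance, brute-forced over randomized mean sets with
        unequal group sizes."""
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 6))
        groups = {
            f"g{j}": rng.normal(rng.uniform(0, 3), 1.0, int(rng.integers(4, 25)))
            for j in range(k)
        }
        table = self._anova(groups)
        grouping = ft.lsd_letters(table, alpha=0.05)
        for a, b in itertools.combinations(groups, 2):
            diff = abs(table.group_means[a] - table.group_means[b])
            nonsig = diff <= grouping.pairwise_lsd[(a, b)]
            share = bool(set(grouping.letters[a]) & set(grouping.letters[b]))
            assert share == nonsig
        assert all(grouping.letters[g] for g in groups)  # every group lettered

    def test_letters_descend_from_a(self):
        rng = np.random.default_rng(15)
        groups = {"hi": 30 + rng.normal(0, 0.1, 10), "lo": rng.normal(0, 0.1, 10)}
        grouping = ft.lsd_letters(self._anova(groups))
        assert grouping.letters["hi"] == "a" and grouping.letters["lo"] == "b"


def _call_table(platform, cells):
    """cells: {(sample, assay): label}"""
    rows = [
        {
            "sample_id": s,
            "assay_id": a,
            "platform_id": platform,
            "label": lab,
            "quality": 0.9 if lab in ft.GENOTYPE_LABELS else np.nan,
        }
        for (s, a), lab in cells.items()
    ]
    return pd.DataFrame(rows)


class TestConcordance:
    def test_self_concordance_is_one(self):
        cells = {(f"S{i}", "SNP01"): ("A11", "A12", "A22")[i % 3] for i in range(9)}
        table = _call_table("P", cells)
        cell = ft.concordance(table, table)
        assert cell.concordance == 1.0
        assert cell.n_joint == 9

    def test_hand_counted_agreement(self):
        """10 jointly called cells, 9 matching: concordance 0.90."""
        cells_a = {(f"S{i}", "SNP01"): "A11" for i in range(10)}
        cells_b = dict(cells_a)
        cells_b[("S0", "SNP01")] = "A22"
        cell = ft.concordance(_call_table("A", cells_a), _call_table("B", cells_b))
        assert cell.n_joint == 10 and cell.n_agree == 9
        assert cell.concordance == pytest.approx(0.90)

    def test_failed_and_invalid_cells_excluded(self):
        """Cells not genotyped by both platforms enter neither numerator nor
        denominator."""
        cells_a = {("S1", "SNP01"): "A11", ("S2", "SNP01"): "FAILED",
                   ("S3", "SNP01"): "A12"}
        cells_b = {("S1", "SNP01"): "A11", ("S2", "SNP01"): "A11",
                   ("S3", "SNP01"): "INVALID"}
        cell = ft.concordance(_call_table("A", cells_a), _call_table("B", cells_b))
        assert cell.n_joint == 1 and cell.n_agree == 1

    def test_disjoint_assays_undefined(self):
        cells_a = {("S1", "SNP01"): "A11"}
        cells_b = {("S1", "SNP02"): "A11"}
        cell = ft.concordance(_call_table("A", cells_a), _call_table("B", cells_b))
        assert cell.n_joint == 0 and cell.concordance is None

    def test_symmetry(self):
        rng = np.random.default_rng(16)
        labels = list(ft.GENOTYPE_LABELS) + ["FAILED", "INVALID"]
        cells_a = {(f"S{i}", f"SNP{j}"): labels[rng.integers(len(labels))]
                   for i in range(20) for j in range(3)}
        cells_b = {key: labels[rng.integers(len(labels))] for key in cells_a}
        ab = ft.concordance(_call_table("A", cells_a), _call_table("B", cells_b))
        ba = ft.concordance(_call_table("B", cells_b), _call_table("A", cells_a))
        assert ab.concordance == ba.concordance
        assert ab.n_joint == ba.n_joint


def test_power_on_separated_planted_angles():
    """Two platforms with a planted A11 angle difference of 3 per-cluster
    noise SDs: the pipeline ANOVA rejects at alpha = 0.001 (spot check of the
    parameter-recovery property; the acceptance suite replicates it 200x)."""
    import math

    delta = 3 * (0.10 / 2.0) / np.sqrt(64 * 0.375)
    profiles = tuple(
        ft.PlatformProfile(
            platform_id=name, gain=2.0, angle_a11=0.20 + d,
            angle_a22=math.pi / 2 - 0.2, noise_sd=0.10,
            ntc_center=(0.1, 0.1), ntc_sd=0.01,
        )
        for name, d in (("A", 0.0), ("B", delta))
    )
    config = ft.SimConfig(
        platforms=profiles, n_samples=64, n_assays=20, seed=21,
        het_model="fixed_fraction", het_fraction=0.25,
    )
    points, _ = ft.simulate_experiment(config)
    calls, refs = ft.call_experiment(points)
    all_points = [p for pts in points.values() for p in pts]
    summaries = ft.summarize_clusters(all_points, calls, refs, a11_only=True)
    table = ft.anova_crd(
        summaries["mean_angle_rad"].to_numpy(), summaries["platform_id"].to_numpy()
    )
    assert table.p_value < 1e-3
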