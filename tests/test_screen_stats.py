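"""Nonparametric screen statistics, batch correction and effect scoring."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from zfscreen import (
    ScreenSimConfig,
    batch_correct,
    classify_compound,
    effect_score,
    hedges_g,
    make_screen_dataset,
    mann_whitney_u,
    mortality_and_effusion_rates,
    percentage_effect,
    relative_median_diff,
    run_screen,
    summarize_screen,
)
from zfscreen.screen_stats import round_half_up


def mwu_permutation_oracle(a, b):
    """Exact two-sided p by full enumeration of group assignments.

    p = P(U <= min tail) + P(U >= opposite tail) over all C(n+m, n)
    splits of the pooled tie-free sample.
    """
    pooled = np.concatenate([a, b])
    n1 = len(a)
    n1n2 = len(a) * len(b)

    def u_stat(sample, rest):
        return sum(x > y for x in sample for y in rest)

    u_obs = u_stat(a, b)
    lo, hi = min(u_obs, n1n2 - u_obs), max(u_obs, n1n2 - u_obs)
    count = 0
    total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        sel = np.zeros(len(pooled), dtype=bool)
        sel[list(comb)] = True
        u = u_stat(pooled[sel], pooled[~sel])
        if u <= lo or u >= hi:
            count += 1
        total += 1
    return count / total


class TestMannWhitney:
    def test_identical_multisets_p_one(self):
        _, p = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    def test_full_separation_three_vs_three(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)  # 2/20 splits as extreme

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(30):
            n1, n2 = rng.integers(2, 8, size=2)
            pooled = rng.normal(size=n1 + n2)
            a, b = pooled[:n1], pooled[n1:]
            _, p = mann_whitney_u(a, b)
            assert p == pytest.approx(mwu_permutation_oracle(a, b), abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1, 2])


class TestHedgesG:
    def test_equal_means_zero(self):
        assert hedges_g([1, 2, 3], [3, 2, 1]) == 0.0

    def test_antisymmetry(self):
        g = hedges_g([1, 2, 3], [2, 3, 4])
        assert hedges_g([2, 3, 4], [1, 2, 3]) == pytest.approx(-g)

    def test_direct_formula_oracle(self):
        # means 2 and 3, pooled SD 1, J = 1 - 3/(4*6 - 9) = 0.8
        assert hedges_g([1, 2, 3], [2, 3, 4]) == pytest.approx(-0.8, abs=1e-12)

    def test_zero_spread_is_an_error(self):
        with pytest.raises(ValueError, match="spread"):
            hedges_g([2, 2, 2], [2, 2, 2])


class TestMedianEffects:
    def test_relative_median_diff(self):
        assert relative_median_diff([12, 12, 12], [10, 10]) == pytest.approx(0.2)
        assert relative_median_diff([7], [7]) == 0.0
        assert relative_median_diff([5], [10]) == -0.5

    def test_zero_control_median_rejected(self):
        with pytest.raises(ValueError):
            relative_median_diff([1], [0])

    @pytest.mark.parametrize(
        "t,c,fc,pct", [(12, 10, 1.2, 20.0), (10, 10, 1.0, 0.0), (5, 10, 0.5, -50.0)]
    )
    def test_percentage_effect(self, t, c, fc, pct):
        got_fc, got_pct = percentage_effect([t], [c])
        assert got_fc == pytest.approx(fc)
        assert got_pct == pytest.approx(pct)


class TestEffectScore:
    def test_worked_example(self):
        # -log10(0.01) * 0.5 * 0.2 = 0.2
        assert effect_score(0.01, 0.5, 0.2) == pytest.approx(0.2)

    def test_p_one_gives_zero_and_masks(self):
        assert effect_score(1.0, 2.0, 0.5) == 0.0
        assert effect_score(1.0, 2.0, 0.5, alpha=0.999) is None

    def test_sign_follows_median_direction(self):
        assert effect_score(0.01, -0.5, -0.2) < 0
        assert effect_score(0.01, -0.5, 0.2) > 0

    def test_masked_when_not_significant(self):
        assert effect_score(0.2, 1.0, 1.0, alpha=0.05) is None
        assert effect_score(0.01, 1.0, 1.0, alpha=0.05) is not None

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            effect_score(0.0, 1.0, 1.0)


def _records(per_plate):
    """Build a minimal records table: {plate: {treatment: values}}."""
    rows = []
    for plate, groups in per_plate.items():
        for treatment, values in groups.items():
            for i, v in enumerate(values):
                rows.append(
                    {
                        "larva_id": f"{plate}_{treatment}_{i}",
                        "experiment_id": plate,
                        "treatment": treatment,
                        "replicate": 1,
                        "alive": True,
                        "effusion": False,
                        "metric": float(v),
                    }
                )
    return pd.DataFrame(rows)


class TestBatchCorrect:
    def test_stated_shift_rule(self):
        rec = _records(
            {
                "A": {"DMSO": [5, 5, 5], "drug": [8, 9]},
                "B": {"DMSO": [7, 7, 7], "drug": [1, 2]},
            }
        )
        out = batch_correct(rec, "metric")
        # global control median 6: plate A shifted +1, plate B -1
        assert out.loc[(out.experiment_id == "A") & (out.treatment == "drug"), "metric"].tolist() == [9, 10]
        assert out.loc[(out.experiment_id == "B") & (out.treatment == "drug"), "metric"].tolist() == [0, 1]

    def test_single_experiment_is_unchanged(self):
        rec = _records({"A": {"DMSO": [4, 5, 6], "drug": [7, 8]}})
        out = batch_correct(rec, "metric")
        assert out["metric"].tolist() == rec["metric"].tolist()

    def test_control_medians_align_and_differences_survive(self):
        rng = np.random.default_rng(0)
        plates = {}
        for plate, off in zip("ABC", (-2.0, 0.0, 3.0)):
            plates[plate] = {
                "DMSO": list(rng.normal(10 + off, 1, 15)),
                "drug": list(rng.normal(12 + off, 1, 10)),
            }
        rec = _records(plates)
        out = batch_correct(rec, "metric")
        ctrl = out[out.treatment == "DMSO"]
        global_median = ctrl["metric"].median()
        for _, sub in ctrl.groupby("experiment_id"):
            assert sub["metric"].median() == pytest.approx(global_median, abs=1e-12)
        for plate in "ABC":
            before = rec[rec.experiment_id == plate]["metric"].to_numpy()
            after = out[out.experiment_id == plate]["metric"].to_numpy()
            assert np.allclose(np.diff(before), np.diff(after), atol=1e-12)

    def test_experiment_without_controls_rejected(self):
        rec = _records({"A": {"DMSO": [5], "drug": [8]}, "B": {"drug": [1]}})
        with pytest.raises(ValueError, match="control"):
            batch_correct(rec, "metric")


class TestMortalityEffusion:
    def _rec(self, treatment, alive_flags, effusion_flags, replicate):
        return pd.DataFrame(
            {
                "larva_id": [f"{treatment}{replicate}_{i}" for i in range(len(alive_flags))],
                "treatment": treatment,
                "replicate": replicate,
                "alive": alive_flags,
                "effusion": effusion_flags,
            }
        )

    def test_mortality_is_mean_over_replicates(self):
        rec = pd.concat(
            [
                self._rec("drug", [False] + [True] * 9, [False] * 10, 1),
                self._rec("drug", [False] * 3 + [True] * 7, [False] * 10, 2),
            ]
        )
        out = mortality_and_effusion_rates(rec)
        assert out["mortality_rate_pct"].item() == pytest.approx(20.0)  # (10+30)/2

    def test_no_deaths_zero(self):
        rec = self._rec("drug", [True] * 10, [False] * 10, 1)
        assert mortality_and_effusion_rates(rec)["mortality_rate_pct"].item() == 0.0

    def test_effusion_percentage(self):
        rec = self._rec("drug", [True] * 18, [True] * 17 + [False], 1)
        out = mortality_and_effusion_rates(rec)
        assert round_half_up(out["effusion_pct"].item(), 1) == 94.4  # 17 of 18


def _results(rows):
    return pd.DataFrame(
        rows,
        columns=["treatment", "metric", "score", "significant"],
    )


class TestClassifyCompound:
    def test_nothing_significant(self):
        res = _results([("c", "ejection_fraction_pct", None, False)])
        assert classify_compound(res) == "No significant effect"

    def test_only_ef_significant_is_heart(self):
        res = _results(
            [
                ("c", "ejection_fraction_pct", -0.4, True),
                ("c", "isv_count", None, False),
            ]
        )
        assert classify_compound(res) == "ΔHeart"

    def test_largest_magnitude_wins(self):
        res = _results(
            [
                ("c", "ejection_fraction_pct", -0.3, True),
                ("c", "isv_median_area_px2", -0.8, True),
            ]
        )
        assert classify_compound(res) == "ΔVasculature"

    def test_tie_broken_by_family_order(self):
        res = _results(
            [
                ("c", "velocity_dark", 0.5, True),
                ("c", "heart_rate_bpm", -0.5, True),
            ]
        )
        assert classify_compound(res) == "ΔHeart"


class TestSummarizeScreen:
    def _screen(self, n=162, n_mr=7, n_ratio=17, n_size=33):
        """Screen of n compounds with engineered flag counts."""
        results = []
        records = []
        for i in range(n):
            tr = f"c{i:03d}"
            results.append(
                {
                    "treatment": tr,
                    "metric": "log_bright_dark_ratio",
                    "score": -0.5 if i < n_ratio else None,
                    "significant": i < n_ratio,
                }
            )
            results.append(
                {
                    "treatment": tr,
                    "metric": "body_length_um",
                    "score": -0.7 if i < n_size else None,
                    "significant": i < n_size,
                }
            )
            dead = 2 if i < n_mr else 0  # 2/10 dead -> 20% MR
            for rep in (1, 2):
                for k in range(10):
                    records.append(
                        {
                            "larva_id": f"{tr}_{rep}_{k}",
                            "treatment": tr,
                            "replicate": rep,
                            "alive": k >= dead,
                            "effusion": False,
                        }
                    )
        return pd.DataFrame(results), pd.DataFrame(records)

    def test_printed_percentages_from_counts(self):
        results, records = self._screen()
        summary = summarize_screen(results, records)
        assert summary["n_compounds"] == 162
        assert summary["mortality_over_threshold"]["count"] == 7
        assert summary["mortality_over_threshold"]["pct_of_compounds"] == 4.3
        ratio = summary["significant_per_metric"]["log_bright_dark_ratio"]
        assert ratio == {"count": 17, "pct_of_compounds": 10.5}
        size = summary["significant_per_metric"]["body_length_um"]
        assert size == {"count": 33, "pct_of_compounds": 20.4}

    def test_zero_flagged(self):
        results, records = self._screen(n=20, n_mr=0, n_ratio=0, n_size=0)
        summary = summarize_screen(results, records)
        assert summary["mortality_over_threshold"]["pct_of_compounds"] == 0.0

    def test_rounding_is_half_up(self):
        assert round_half_up(10.45, 1) == 10.5
        assert round_half_up(100 * 7 / 162, 1) == 4.3
        assert round_half_up(2.25, 1) == 2.3


class TestScreenCalibration:
    def test_null_screen_type_one_error(self):
        # all multipliers 1.0: significance rate must sit at alpha
        flagged = total = 0
        for seed in range(5):
            records, _ = make_screen_dataset(
                ScreenSimConfig(n_compounds=25, compounds_per_plate=5, seed=seed)
            )
            res = run_screen(records)
            flagged += int(res["significant"].sum())
            total += len(res)
        assert total >= 1000
        assert flagged / total == pytest.approx(0.05, abs=0.02)

    def test_power_for_doubled_heart_rate(self):
        hits = 0
        n_sims = 10
        for seed in range(n_sims):
            records, _ = make_screen_dataset(
                ScreenSimConfig(
                    n_compounds=1,
                    n_larvae_per_group=10,
                    n_replicates=1,
                    effects={"compound_001": {"heart_rate_bpm": 2.0}},
                    seed=seed,
                )
            )
            res = run_screen(records, metrics=["heart_rate_bpm"])
            hits += int(res["significant"].iloc[0])
        assert hits / n_sims >= 0.8
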