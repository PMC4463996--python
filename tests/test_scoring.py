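"""Intake summarisation and the HEIFA rubric: primitives, properties, oracle."""

import logging

import numpy as np
import pytest

from conftest import make_random_summary
from dietq.model import IntakeRecord, ParticipantProfile, ScoringConfig
from dietq.scoring import (
    moderation_score,
    prorated_quantity_score,
    score_record,
    summarize_intake,
    variety_score,
)


class TestPrimitives:
    @pytest.mark.parametrize(
        "serves, target, max_pts, expected",
        [(5.0, 5.0, 10.0, 10.0), (0.0, 5.0, 10.0, 0.0), (1.5, 5.0, 5.0, 1.5), (9.0, 5.0, 10.0, 10.0)],
    )
    def test_prorated_quantity(self, serves, target, max_pts, expected):
        assert prorated_quantity_score(serves, target, max_pts) == pytest.approx(expected)

    def test_prorated_rejects_negative_serves(self):
        with pytest.raises(ValueError):
            prorated_quantity_score(-1.0, 5.0, 10.0)

    @pytest.mark.parametrize(
        "value, expected",
        [(10.0, 10.0), (15.0, 0.0), (12.5, 5.0), (0.0, 10.0), (40.0, 0.0)],
    )
    def test_moderation_linear_between_cuts(self, value, expected):
        assert moderation_score(value, 10.0, 15.0, 10.0) == pytest.approx(expected)

    def test_moderation_requires_ordered_cuts(self):
        with pytest.raises(ValueError):
            moderation_score(5.0, 15.0, 10.0, 10.0)

    def test_variety_sums_and_caps(self):
        pts = {"a": 1.0, "b": 1.0, "c": 1.0, "d": 1.0, "e": 1.0}
        assert variety_score(["a", "b"], pts, 5.0) == 2.0
        assert variety_score(list(pts), pts, 5.0) == 5.0
        assert variety_score([], pts, 5.0) == 0.0

    def test_variety_ignores_unknown_subgroup_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING, logger="dietq"):
            got = variety_score(["a", "mystery"], {"a": 1.0}, 5.0)
        assert got == 1.0
        assert "mystery" in caplog.text


def _record(composition, amounts, sex="female", **over):
    fields = dict(
        profile=ParticipantProfile(
            participant_id="t", sex=sex, age=25, weight_kg=70.0, height_m=1.68
        ),
        amounts=amounts,
        ssb_ml_per_week=0.0,
        takeaway_per_week="0-1",
        water_ml_per_day=0.0,
    )
    fields.update(over)
    return IntakeRecord(**fields)


class TestSummarize:
    def test_serves_are_grams_over_serve_size(self, composition):
        s = summarize_intake(_record(composition, {"veg_carrot": 100.0}), composition)
        assert s.group_serves["vegetables"] == pytest.approx(100.0 / 75.0)

    def test_wholegrain_proportion_on_grams(self, composition):
        s = summarize_intake(
            _record(composition, {"grain_wholemeal_bread": 50.0, "grain_white_bread": 50.0}),
            composition,
        )
        assert s.wholegrain_prop == pytest.approx(0.5)

    def test_single_food_supplies_all_energy(self, composition):
        s = summarize_intake(_record(composition, {"grain_oats": 100.0}), composition)
        assert s.group_pct_e["grains"] == pytest.approx(100.0)

    def test_macronutrient_pct_e_sums_near_100(self, composition):
        amounts = {"grain_oats": 80.0, "meat_chicken": 150.0, "dairy_whole_milk": 300.0,
                   "disc_chocolate": 40.0, "alc_beer": 285.0}
        s = summarize_intake(_record(composition, amounts), composition)
        total = s.protein_pct_e + s.fat_pct_e + s.carb_pct_e + s.alcohol_pct_e
        assert total == pytest.approx(100.0, abs=2.0)

    def test_empty_record_flags_undefined_energy_without_nans(self, composition):
        s = summarize_intake(_record(composition, {}), composition)
        assert s.energy_defined is False
        assert s.sat_fat_pct_e == 0.0 and s.total_sugars_pct_e == 0.0
        assert not any(np.isnan(v) for v in s.group_pct_e.values())

    def test_linear_in_amounts(self, composition):
        a = summarize_intake(_record(composition, {"meat_fish": 100.0}), composition)
        b = summarize_intake(_record(composition, {"meat_fish": 250.0}), composition)
        assert b.sodium_mg_day == pytest.approx(2.5 * a.sodium_mg_day, rel=1e-12)
        assert b.group_serves["meat_alt"] == pytest.approx(2.5 * a.group_serves["meat_alt"], rel=1e-12)

    def test_water_proportion_of_total_beverages(self, composition):
        r = _record(
            composition, {"alc_beer": 500.0}, water_ml_per_day=500.0, ssb_ml_per_week=0.0
        )
        s = summarize_intake(r, composition)
        assert s.water_prop == pytest.approx(0.5)


def brute_force_rubric(summary, cfg: ScoringConfig) -> float:
    """Independent straight-line evaluation of the same rubric (test oracle)."""
    sex = summary.sex
    pts = 0.0
    # vegetables
    t = cfg.quantity_targets["vegetables"][sex]
    pts += 5.0 * min(summary.group_serves.get("vegetables", 0.0) / t, 1.0)
    pts += min(sum(1.0 for sg in summary.veg_subgroups if sg in cfg.veg_variety_points), 5.0)
    # fruit
    t = cfg.quantity_targets["fruit"][sex]
    pts += 5.0 * min(summary.group_serves.get("fruit", 0.0) / t, 1.0)
    pts += min(sum(1.0 for sg in summary.fruit_subgroups if sg in cfg.fruit_variety_points), 5.0)
    # grains
    t = cfg.quantity_targets["grains"][sex]
    pts += 5.0 * min(summary.group_serves.get("grains", 0.0) / t, 1.0)
    pts += 5.0 * min(summary.wholegrain_prop / 0.5, 1.0)
    # meat
    t = cfg.quantity_targets["meat_alt"][sex]
    pts += 10.0 * min(summary.group_serves.get("meat_alt", 0.0) / t, 1.0)
    # dairy
    t = cfg.quantity_targets["dairy_alt"][sex]
    pts += 5.0 * min(summary.group_serves.get("dairy_alt", 0.0) / t, 1.0)
    pts += 5.0 * min(summary.lowfat_prop / 0.5, 1.0)

    def mod(value, full, zero, mx):
        if not summary.energy_defined:
            return 0.0
        if value <= full:
            return mx
        if value >= zero:
            return 0.0
        return mx * (zero - value) / (zero - full)

    pts += mod(summary.discretionary_pct_e, 20.0, 60.0, 10.0)
    pts += mod(summary.sat_fat_pct_e, 10.0, 15.0, 10.0)
    pts += mod(summary.sodium_mg_day, 2300.0, 4600.0, 10.0)
    pts += mod(summary.total_sugars_pct_e, 15.0, 30.0, 10.0)
    pts += mod(summary.alcohol_g_day, 20.0, 40.0, 5.0)
    pts += 5.0 * min(summary.water_prop / 0.5, 1.0)
    return pts


class TestScoreRecord:
    def test_total_is_component_sum(self, config):
        rng = np.random.default_rng(7)
        score = score_record(make_random_summary(rng), config)
        assert score.total == pytest.approx(sum(score.components.values()), abs=1e-12)

    def test_matches_independent_rubric_on_random_summaries(self, config):
        rng = np.random.default_rng(42)
        for _ in range(100):
            s = make_random_summary(rng)
            assert score_record(s, config).total == pytest.approx(
                brute_force_rubric(s, config), abs=1e-9
            )

    def test_bounds_hold_under_fuzzing(self, config):
        rng = np.random.default_rng(3)
        for _ in range(500):
            score = score_record(make_random_summary(rng), config)
            assert 0.0 <= score.total <= 100.0
            for name, v in score.components.items():
                assert -1e-12 <= v <= config.component_max[name] + 1e-12

    def test_more_core_food_never_lowers_the_total(self, config):
        rng = np.random.default_rng(11)
        for _ in range(200):
            s = make_random_summary(rng)
            serves = dict(s.group_serves)
            serves["vegetables"] = serves["vegetables"] + 1.0
            bigger = s.model_copy(update={"group_serves": serves})
            assert score_record(bigger, config).total >= score_record(s, config).total - 1e-9

    def test_more_sodium_never_raises_the_total(self, config):
        rng = np.random.default_rng(12)
        for _ in range(200):
            s = make_random_summary(rng)
            saltier = s.model_copy(update={"sodium_mg_day": s.sodium_mg_day + 500.0})
            assert score_record(saltier, config).total <= score_record(s, config).total + 1e-9

    def test_zero_energy_scores_zero_on_moderation_and_flags(self, config, composition):
        s = summarize_intake(_record(composition, {}), composition)
        score = score_record(s, config)
        assert score.degenerate_energy
        for comp in ("discretionary", "fat", "sodium", "sugars", "alcohol"):
            assert score.components[comp] == 0.0
            assert score.met[comp] is False

    def test_order_of_input_rows_is_irrelevant(self, composition, config):
        amounts = {"veg_carrot": 80.0, "grain_oats": 60.0, "dairy_skim_milk": 250.0,
                   "disc_chips": 30.0}
        fwd = _record(composition, dict(amounts))
        rev = _record(composition, dict(reversed(list(amounts.items()))))
        a = score_record(summarize_intake(fwd, composition), config)
        b = score_record(summarize_intake(rev, composition), config)
        assert a.total == b.total
        assert a.components == b.components

    def test_subscores_sum_to_components(self, config):
        rng = np.random.default_rng(5)
        s = make_random_summary(rng)
        score = score_record(s, config)
        assert score.components["vegetables"] == pytest.approx(
            score.subscores["vegetables_quantity"] + score.subscores["vegetables_variety"]
        )
        assert score.components["grains"] == pytest.approx(
            score.subscores["grains_quantity"] + score.subscores["grains_wholegrain"]
        )
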