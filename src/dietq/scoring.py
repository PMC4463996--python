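"""Per-participant intake summaries and the 11-component modified HEIFA score.

The index rates a diet against the 2013 Australian Dietary Guidelines on a
0–100 scale. Five food-group components reward quantity (prorated serves/day
against sex-specific targets) plus, where applicable, variety (fruit,
vegetables), wholegrain proportion (grains) or low-fat proportion (dairy).
Five moderation components (discretionary energy, saturated fat, sodium,
total sugars, alcohol) score the maximum at or below a full-credit cut-off,
zero at or beyond a zero-credit cut-off, and linearly in between. Water is
scored on its proportion of total beverage volume.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .model import (
    BEVERAGE_GROUPS,
    CORE_GROUPS,
    EnergyFactors,
    FoodCompositionEntry,
    FoodGroup,
    IntakeRecord,
    ScoringConfig,
    UnknownFoodError,
    composition_index,
)

logger = logging.getLogger("dietq")

__all__ = [
    "IntakeSummary",
    "HEIFAScore",
    "summarize_intake",
    "prorated_quantity_score",
    "moderation_score",
    "variety_score",
    "score_record",
]

#: moderation component name → IntakeSummary attribute carrying its value
MODERATION_SOURCES: dict[str, tuple[str, str]] = {
    "discretionary": ("discretionary_pct_e", "discretionary_pct_e"),
    "fat": ("saturated_fat_pct_e", "sat_fat_pct_e"),
    "sodium": ("sodium_mg", "sodium_mg_day"),
    "sugars": ("total_sugars_pct_e", "total_sugars_pct_e"),
    "alcohol": ("alcohol_g", "alcohol_g_day"),
}


class IntakeSummary(BaseModel):
    """Derived per-participant quantities the scoring rubric consumes."""

    model_config = ConfigDict(frozen=True)

    participant_id: str = ""
    sex: str = "female"
    group_g: dict[str, float] = Field(default_factory=dict)
    group_serves: dict[str, float] = Field(default_factory=dict)
    group_pct_e: dict[str, float] = Field(default_factory=dict)
    wholegrain_prop: float = Field(default=0.0, ge=0, le=1)
    lowfat_prop: float = Field(default=0.0, ge=0, le=1)
    veg_subgroups: frozenset[str] = frozenset()
    fruit_subgroups: frozenset[str] = frozenset()
    sat_fat_pct_e: float = 0.0
    total_sugars_pct_e: float = 0.0
    sodium_mg_day: float = Field(default=0.0, ge=0)
    alcohol_g_day: float = Field(default=0.0, ge=0)
    alcohol_pct_e: float = 0.0
    discretionary_pct_e: float = 0.0
    protein_pct_e: float = 0.0
    fat_pct_e: float = 0.0
    carb_pct_e: float = 0.0
    mono_fat_pct_e: float = 0.0
    poly_fat_pct_e: float = 0.0
    starch_pct_e: float = 0.0
    fiber_g_day: float = Field(default=0.0, ge=0)
    water_prop: float = Field(default=0.0, ge=0, le=1)
    beverages_ml_day: float = Field(default=0.0, ge=0)
    ssb_ml_day: float = Field(default=0.0, ge=0)
    energy_kj_day: float = Field(default=0.0, ge=0)
    energy_kcal_day: float = Field(default=0.0, ge=0)
    #: False when total energy is zero, in which case %E fields are 0 by
    #: convention (flagged, never NaN) and moderation components score 0.
    energy_defined: bool = True


class HEIFAScore(BaseModel):
    """The 11 component scores, their sub-scores, met flags and the total."""

    model_config = ConfigDict(frozen=True)

    participant_id: str = ""
    components: dict[str, float]
    subscores: dict[str, float]
    met: dict[str, bool]
    total: float
    degenerate_energy: bool = False

    @model_validator(mode="after")
    def _additive(self) -> "HEIFAScore":
        s = sum(self.components.values())
        if abs(s - self.total) > 1e-9:
            raise ValueError(f"total {self.total} != component sum {s}")
        return self


def prorated_quantity_score(serves: float, target: float, max_points: float) -> float:
    """``max_points * min(serves/target, 1)`` — no penalty above the target."""
    if serves < 0:
        raise ValueError(f"negative serves: {serves}")
    if target <= 0:
        raise ValueError(f"non-positive target: {target}")
    return max_points * min(serves / target, 1.0)


def moderation_score(value: float, full_cut: float, zero_cut: float, max_points: float) -> float:
    """Full credit at/below ``full_cut``, zero at/beyond ``zero_cut``, linear between."""
    if not full_cut < zero_cut:
        raise ValueError(f"full_cut {full_cut} must be < zero_cut {zero_cut}")
    if value <= full_cut:
        return max_points
    if value >= zero_cut:
        return 0.0
    return max_points * (zero_cut - value) / (zero_cut - full_cut)


def variety_score(
    consumed_subgroups: Sequence[str] | frozenset[str],
    subgroup_points: Mapping[str, float],
    cap: float,
) -> float:
    """Sum of per-subgroup points over consumed subgroups, capped."""
    total = 0.0
    for sg in set(consumed_subgroups):
        if sg not in subgroup_points:
            logger.warning("variety_score: unknown subgroup %r ignored", sg)
            continue
        total += subgroup_points[sg]
    return min(total, cap)


def summarize_intake(
    record: IntakeRecord,
    composition: Sequence[FoodCompositionEntry] | Mapping[str, FoodCompositionEntry],
    factors: EnergyFactors | None = None,
) -> IntakeSummary:
    """Aggregate one record into group and nutrient summaries.

    All quantities are linear in the per-item amounts. Energy comes from the
    composition table's per-100 g energy column; the single-item SSB response
    contributes beverage volume only (it sits outside the FFQ nutrient
    engine). Zero total energy yields %E fields of 0 with
    ``energy_defined=False`` rather than NaN.
    """
    factors = factors or EnergyFactors()
    comp = composition_index(composition)

    group_g = {g.value: 0.0 for g in FoodGroup}
    group_e = {g.value: 0.0 for g in FoodGroup}
    group_serves = {g.value: 0.0 for g in CORE_GROUPS}
    subgroup_serves: dict[tuple[str, str], float] = {}
    energy = protein = fat = sat = mono = poly = carb = sugars = starch = 0.0
    fiber = sodium = alcohol = 0.0
    wholegrain_g = grains_g = lowfat_g = dairy_g = 0.0
    beverage_ml = 0.0
    water_item_ml = 0.0

    for fid, grams in record.amounts.items():
        if fid not in comp:
            raise UnknownFoodError(f"food_id not in composition table: {fid}")
        e = comp[fid]
        f = grams / 100.0
        group_g[e.group.value] += grams
        item_energy = f * e.energy_kj
        group_e[e.group.value] += item_energy
        energy += item_energy
        protein += f * e.protein_g
        fat += f * e.fat_g
        sat += f * e.sat_fat_g
        mono += f * e.mono_fat_g
        poly += f * e.poly_fat_g
        carb += f * e.carb_g
        sugars += f * e.sugars_g
        starch += f * e.starch_g
        fiber += f * e.fiber_g
        sodium += f * e.sodium_mg
        alcohol += f * e.alcohol_g
        if e.group in CORE_GROUPS:
            serves = grams / e.serve_size_g
            group_serves[e.group.value] += serves
            if e.subgroup:
                key = (e.group.value, e.subgroup)
                subgroup_serves[key] = subgroup_serves.get(key, 0.0) + serves
        if e.group is FoodGroup.grains:
            grains_g += grams
            if e.is_wholegrain:
                wholegrain_g += grams
        if e.group is FoodGroup.dairy_alt:
            dairy_g += grams
            if e.is_low_fat:
                lowfat_g += grams
        if e.group in BEVERAGE_GROUPS:
            ml = grams / e.density_g_per_ml
            beverage_ml += ml
            if e.group is FoodGroup.beverage_water:
                water_item_ml += ml

    ssb_ml_day = record.ssb_ml_per_week / 7.0
    beverage_ml += record.water_ml_per_day + ssb_ml_day
    water_ml = record.water_ml_per_day + water_item_ml

    energy_defined = energy > 0.0

    def pct_e(kj: float) -> float:
        return 100.0 * kj / energy if energy_defined else 0.0

    # variety: a subgroup counts once it supplies >= the configured minimum
    # serves per week (default 1); the threshold itself lives in the scoring
    # config, so here we record subgroups at >= 1 serve/week.
    veg_sub = frozenset(
        sg for (g, sg), s in subgroup_serves.items() if g == "vegetables" and s * 7.0 >= 1.0
    )
    fruit_sub = frozenset(
        sg for (g, sg), s in subgroup_serves.items() if g == "fruit" and s * 7.0 >= 1.0
    )

    return IntakeSummary(
        participant_id=record.profile.participant_id,
        sex=record.profile.sex,
        group_g=group_g,
        group_serves=group_serves,
        group_pct_e={g: pct_e(kj) for g, kj in group_e.items()},
        wholegrain_prop=wholegrain_g / grains_g if grains_g > 0 else 0.0,
        lowfat_prop=lowfat_g / dairy_g if dairy_g > 0 else 0.0,
        veg_subgroups=veg_sub,
        fruit_subgroups=fruit_sub,
        sat_fat_pct_e=pct_e(sat * factors.fat_kj_per_g),
        total_sugars_pct_e=pct_e(sugars * factors.carbohydrate_kj_per_g),
        sodium_mg_day=sodium,
        alcohol_g_day=alcohol,
        alcohol_pct_e=pct_e(alcohol * factors.alcohol_kj_per_g),
        discretionary_pct_e=pct_e(group_e["discretionary"]),
        protein_pct_e=pct_e(protein * factors.protein_kj_per_g),
        fat_pct_e=pct_e(fat * factors.fat_kj_per_g),
        carb_pct_e=pct_e(carb * factors.carbohydrate_kj_per_g),
        mono_fat_pct_e=pct_e(mono * factors.fat_kj_per_g),
        poly_fat_pct_e=pct_e(poly * factors.fat_kj_per_g),
        starch_pct_e=pct_e(starch * factors.carbohydrate_kj_per_g),
        fiber_g_day=fiber,
        water_prop=water_ml / beverage_ml if beverage_ml > 0 else 0.0,
        beverages_ml_day=beverage_ml,
        ssb_ml_day=ssb_ml_day,
        energy_kj_day=energy,
        energy_kcal_day=energy / factors.kj_per_kcal,
        energy_defined=energy_defined,
    )


def score_record(summary: IntakeSummary, config: ScoringConfig | None = None) -> HEIFAScore:
    """Apply the full rubric to one summary and return the 0–100 score."""
    config = config or ScoringConfig()
    sex = summary.sex
    components: dict[str, float] = {}
    subscores: dict[str, float] = {}
    met: dict[str, bool] = {}

    # five food-group components
    for comp_name, group in (
        ("vegetables", "vegetables"),
        ("fruit", "fruit"),
        ("grains", "grains"),
        ("meat_alt", "meat_alt"),
        ("dairy_alt", "dairy_alt"),
    ):
        serves = summary.group_serves.get(group, 0.0)
        target = config.target(comp_name, sex)
        q = prorated_quantity_score(serves, target, config.quantity_points[comp_name])
        subscores[f"{comp_name}_quantity"] = q
        met[comp_name] = serves >= target
        if comp_name == "vegetables":
            v = variety_score(summary.veg_subgroups, config.veg_variety_points, config.veg_variety_cap)
            subscores["vegetables_variety"] = v
            components[comp_name] = q + v
        elif comp_name == "fruit":
            v = variety_score(summary.fruit_subgroups, config.fruit_variety_points, config.fruit_variety_cap)
            subscores["fruit_variety"] = v
            components[comp_name] = q + v
        elif comp_name == "grains":
            wg = config.wholegrain_points * min(summary.wholegrain_prop / config.wholegrain_full_prop, 1.0)
            subscores["grains_wholegrain"] = wg
            components[comp_name] = q + wg
        elif comp_name == "dairy_alt":
            lf = config.lowfat_points * min(summary.lowfat_prop / config.lowfat_full_prop, 1.0)
            subscores["dairy_alt_lowfat"] = lf
            components[comp_name] = q + lf
        else:
            components[comp_name] = q

    # moderation components (zero on a degenerate zero-energy record)
    degenerate = not summary.energy_defined
    for comp_name, (cut_key, attr) in MODERATION_SOURCES.items():
        cuts = config.moderation[cut_key]
        value = getattr(summary, attr)
        if degenerate:
            components[comp_name] = 0.0
            met[comp_name] = False
        else:
            components[comp_name] = moderation_score(
                value, cuts.full_cut, cuts.zero_cut, config.component_max[comp_name]
            )
            met[comp_name] = value <= cuts.full_cut

    # water: proportion of total beverage volume
    components["water"] = config.component_max["water"] * min(
        summary.water_prop / config.water_full_prop, 1.0
    )
    met["water"] = summary.water_prop >= config.water_full_prop

    total = sum(components.values())
    return HEIFAScore(
        participant_id=summary.participant_id,
        components=components,
        subscores=subscores,
        met=met,
        total=total,
        degenerate_energy=degenerate,
    )
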