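"""Domain types, scoring configuration, and CSV/JSON readers and writers.

The package works from two tabular inputs:

* a *food composition table* — one row per FFQ item, carrying its food-group
  and variety-subgroup assignment, wholegrain/low-fat flags, the standard
  serve size in grams, and per-100 g energy and nutrients;
* a *cohort table* — one row per participant, with demographics, wide
  per-item ``g_<food_id>`` daily amounts, the single-item weekly
  sugar-sweetened-beverage (SSB) volume, daily plain-water volume and the
  ordinal takeaway-frequency category.

Both are plain comma-separated UTF-8 files with a header row and ``.``
decimals. Liquids are stored internally in grams; a per-item density
converts millilitre inputs.
"""

from __future__ import annotations

import json
import math
from enum import Enum
from pathlib import Path
from typing import Literal, Mapping, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "FoodGroup",
    "CORE_GROUPS",
    "BEVERAGE_GROUPS",
    "Sex",
    "TakeawayCategory",
    "TAKEAWAY_CATEGORIES",
    "TAKEAWAY_ORDINAL",
    "EnergyFactors",
    "FoodCompositionEntry",
    "ParticipantProfile",
    "IntakeRecord",
    "ModerationCuts",
    "ScoringConfig",
    "ReferenceValue",
    "ReferenceValues",
    "default_reference_values",
    "CompositionSchemaError",
    "RowValidationError",
    "UnknownFoodError",
    "ConfigError",
    "load_composition_table",
    "write_composition_table",
    "composition_index",
    "load_cohort",
    "write_cohort",
    "load_scoring_config",
    "load_reference_values",
]


class CompositionSchemaError(Exception):
    """The composition CSV header does not match the documented schema."""


class RowValidationError(Exception):
    """A row violates a type invariant (reported with its identifier)."""


class UnknownFoodError(Exception):
    """A cohort column references a food_id absent from the composition table."""


class ConfigError(Exception):
    """A configuration file violates a structural invariant."""


class FoodGroup(str, Enum):
    vegetables = "vegetables"
    fruit = "fruit"
    grains = "grains"
    meat_alt = "meat_alt"
    dairy_alt = "dairy_alt"
    discretionary = "discretionary"
    beverage_water = "beverage_water"
    beverage_ssb = "beverage_ssb"
    beverage_other = "beverage_other"
    alcohol_bev = "alcohol_bev"


CORE_GROUPS: tuple[FoodGroup, ...] = (
    FoodGroup.vegetables,
    FoodGroup.fruit,
    FoodGroup.grains,
    FoodGroup.meat_alt,
    FoodGroup.dairy_alt,
)

#: groups whose items count toward total beverage volume (plain water and the
#: single-item SSB response are carried on the record itself).
BEVERAGE_GROUPS: tuple[FoodGroup, ...] = (
    FoodGroup.beverage_water,
    FoodGroup.beverage_ssb,
    FoodGroup.beverage_other,
    FoodGroup.alcohol_bev,
)

Sex = Literal["male", "female"]

TakeawayCategory = Literal["0-1", "2-3", "4-5", "6+"]
TAKEAWAY_CATEGORIES: tuple[str, ...] = ("0-1", "2-3", "4-5", "6+")
TAKEAWAY_ORDINAL: dict[str, int] = {c: i for i, c in enumerate(TAKEAWAY_CATEGORIES)}


class EnergyFactors(BaseModel):
    """Metabolisable-energy conversion factors (kJ per gram) and kcal scale."""

    model_config = ConfigDict(frozen=True)

    protein_kj_per_g: float = 17.0
    fat_kj_per_g: float = 37.0
    carbohydrate_kj_per_g: float = 16.7
    alcohol_kj_per_g: float = 29.0
    kj_per_kcal: float = 4.184

    def energy_kj(self, protein_g: float, fat_g: float, carb_g: float, alcohol_g: float) -> float:
        return (
            self.protein_kj_per_g * protein_g
            + self.fat_kj_per_g * fat_g
            + self.carbohydrate_kj_per_g * carb_g
            + self.alcohol_kj_per_g * alcohol_g
        )


class FoodCompositionEntry(BaseModel):
    """One FFQ item: group/subgroup assignment, flags, serve size, per-100 g nutrients."""

    model_config = ConfigDict(frozen=True)

    food_id: str
    name: str
    group: FoodGroup
    subgroup: str = ""
    is_wholegrain: bool = False
    is_low_fat: bool = False
    serve_size_g: float = Field(gt=0)
    density_g_per_ml: float = Field(default=1.0, gt=0)
    # per 100 g
    energy_kj: float = Field(ge=0)
    protein_g: float = Field(default=0.0, ge=0)
    fat_g: float = Field(default=0.0, ge=0)
    sat_fat_g: float = Field(default=0.0, ge=0)
    mono_fat_g: float = Field(default=0.0, ge=0)
    poly_fat_g: float = Field(default=0.0, ge=0)
    carb_g: float = Field(default=0.0, ge=0)
    sugars_g: float = Field(default=0.0, ge=0)
    starch_g: float = Field(default=0.0, ge=0)
    fiber_g: float = Field(default=0.0, ge=0)
    sodium_mg: float = Field(default=0.0, ge=0)
    alcohol_g: float = Field(default=0.0, ge=0)

    @model_validator(mode="after")
    def _check_invariants(self) -> "FoodCompositionEntry":
        tol = 1e-6
        if self.sat_fat_g + self.mono_fat_g + self.poly_fat_g > self.fat_g + tol:
            raise ValueError(
                f"fat fractions exceed total fat "
                f"({self.sat_fat_g}+{self.mono_fat_g}+{self.poly_fat_g} > {self.fat_g})"
            )
        if self.sugars_g + self.starch_g > self.carb_g + tol:
            raise ValueError("sugars + starch exceed total carbohydrate")
        derived = EnergyFactors().energy_kj(self.protein_g, self.fat_g, self.carb_g, self.alcohol_g)
        # energy must agree with the macronutrient-derived value to 10 %
        # (near-zero-energy items such as water are exempt from the ratio test)
        if derived > 10.0 or self.energy_kj > 10.0:
            if not (0.9 * derived - tol <= self.energy_kj <= 1.1 * derived + tol):
                raise ValueError(
                    f"energy {self.energy_kj} kJ/100g outside 10% of "
                    f"macronutrient-derived {derived:.1f} kJ/100g"
                )
        return self


class ParticipantProfile(BaseModel):
    """Demographics needed for BMR and sex-specific targets; BMI is derived."""

    model_config = ConfigDict(frozen=True)

    participant_id: str
    sex: Sex
    age: int = Field(ge=18)
    weight_kg: float = Field(gt=0)
    height_m: float = Field(gt=0)

    @property
    def bmi(self) -> float:
        return self.weight_kg / self.height_m**2


class IntakeRecord(BaseModel):
    """One participant's daily FFQ amounts plus the behavioural single items."""

    profile: ParticipantProfile
    amounts: dict[str, float] = Field(default_factory=dict)
    ssb_ml_per_week: float = Field(default=0.0, ge=0)
    takeaway_per_week: Optional[TakeawayCategory] = None
    water_ml_per_day: float = Field(default=0.0, ge=0)
    complete: bool = True

    @model_validator(mode="after")
    def _nonneg_amounts(self) -> "IntakeRecord":
        for fid, g in self.amounts.items():
            if g < 0:
                raise ValueError(f"negative amount for {fid}: {g}")
        return self


class ModerationCuts(BaseModel):
    """Full-score / zero-score cut-off pair for a moderation nutrient."""

    model_config = ConfigDict(frozen=True)

    full_cut: float
    zero_cut: float

    @model_validator(mode="after")
    def _ordered(self) -> "ModerationCuts":
        if not self.full_cut < self.zero_cut:
            raise ValueError(f"full_cut {self.full_cut} must be < zero_cut {self.zero_cut}")
        return self


def _default_component_max() -> dict[str, float]:
    return {
        "vegetables": 10.0,
        "fruit": 10.0,
        "grains": 10.0,
        "meat_alt": 10.0,
        "dairy_alt": 10.0,
        "discretionary": 10.0,
        "fat": 10.0,
        "sodium": 10.0,
        "sugars": 10.0,
        "water": 5.0,
        "alcohol": 5.0,
    }


def _default_targets() -> dict[str, dict[str, float]]:
    # AGHE 2013 adult serves/day
    return {
        "vegetables": {"male": 6.0, "female": 5.0},
        "fruit": {"male": 2.0, "female": 2.0},
        "grains": {"male": 6.0, "female": 6.0},
        "meat_alt": {"male": 3.0, "female": 2.5},
        "dairy_alt": {"male": 2.5, "female": 2.5},
    }


def _default_moderation() -> dict[str, ModerationCuts]:
    return {
        "saturated_fat_pct_e": ModerationCuts(full_cut=10.0, zero_cut=15.0),
        "total_sugars_pct_e": ModerationCuts(full_cut=15.0, zero_cut=30.0),
        "sodium_mg": ModerationCuts(full_cut=2300.0, zero_cut=4600.0),
        "discretionary_pct_e": ModerationCuts(full_cut=20.0, zero_cut=60.0),
        "alcohol_g": ModerationCuts(full_cut=20.0, zero_cut=40.0),
    }


class ScoringConfig(BaseModel):
    """Parameters of the 11-component modified HEIFA rubric.

    Nine components (five food groups, discretionary foods, saturated fat,
    sodium, total sugars) are scored out of 10; water and alcohol out of 5;
    maxima must sum to 100. Quantity sub-scores are prorated against
    sex-specific serves/day targets; variety points reward distinct fruit and
    vegetable subgroups eaten at least once a week; wholegrain and low-fat
    sub-scores give full credit at a configurable proportion (default >50 %,
    the "mostly wholegrain" criterion); moderation nutrients score linearly
    between a full-credit and a zero-credit cut-off.
    """

    component_max: dict[str, float] = Field(default_factory=_default_component_max)
    quantity_targets: dict[str, dict[str, float]] = Field(default_factory=_default_targets)
    quantity_points: dict[str, float] = Field(
        default_factory=lambda: {
            "vegetables": 5.0,
            "fruit": 5.0,
            "grains": 5.0,
            "meat_alt": 10.0,
            "dairy_alt": 5.0,
        }
    )
    veg_variety_points: dict[str, float] = Field(
        default_factory=lambda: {
            "green_veg": 1.0,
            "orange_veg": 1.0,
            "legumes": 1.0,
            "starchy_veg": 1.0,
            "other_veg": 1.0,
        }
    )
    veg_variety_cap: float = 5.0
    fruit_variety_points: dict[str, float] = Field(
        default_factory=lambda: {
            "pome": 1.0,
            "citrus": 1.0,
            "berries": 1.0,
            "stone": 1.0,
            "tropical": 1.0,
        }
    )
    fruit_variety_cap: float = 5.0
    wholegrain_points: float = 5.0
    wholegrain_full_prop: float = Field(default=0.5, gt=0, le=1)
    lowfat_points: float = 5.0
    lowfat_full_prop: float = Field(default=0.5, gt=0, le=1)
    water_full_prop: float = Field(default=0.5, gt=0, le=1)
    variety_min_serves_per_week: float = Field(default=1.0, gt=0)
    moderation: dict[str, ModerationCuts] = Field(default_factory=_default_moderation)
    energy_factors: EnergyFactors = Field(default_factory=EnergyFactors)

    @model_validator(mode="after")
    def _structure(self) -> "ScoringConfig":
        total = sum(self.component_max.values())
        if abs(total - 100.0) > 1e-9:
            raise ValueError(f"component maxima sum to {total}, expected 100")
        for comp, by_sex in self.quantity_targets.items():
            for sex, t in by_sex.items():
                if t <= 0:
                    raise ValueError(f"non-positive target for {comp}/{sex}")
        for comp, split in (
            ("vegetables", self.quantity_points["vegetables"] + self.veg_variety_cap),
            ("fruit", self.quantity_points["fruit"] + self.fruit_variety_cap),
            ("grains", self.quantity_points["grains"] + self.wholegrain_points),
            ("dairy_alt", self.quantity_points["dairy_alt"] + self.lowfat_points),
            ("meat_alt", self.quantity_points["meat_alt"]),
        ):
            if abs(split - self.component_max[comp]) > 1e-9:
                raise ValueError(f"sub-scores for {comp} sum to {split}, expected {self.component_max[comp]}")
        required = {"saturated_fat_pct_e", "total_sugars_pct_e", "sodium_mg", "discretionary_pct_e", "alcohol_g"}
        missing = required - set(self.moderation)
        if missing:
            raise ValueError(f"moderation cuts missing: {sorted(missing)}")
        return self

    def target(self, component: str, sex: str) -> float:
        return self.quantity_targets[component][sex]


class ReferenceValue(BaseModel):
    model_config = ConfigDict(frozen=True)

    value: float
    unit: str = ""
    source: str


class ReferenceValues(BaseModel):
    """Read-only named constants for the comparison population."""

    model_config = ConfigDict(frozen=True)

    values: dict[str, ReferenceValue] = Field(default_factory=dict)

    def get(self, key: str) -> Optional[float]:
        rv = self.values.get(key)
        return None if rv is None else rv.value


def default_reference_values() -> ReferenceValues:
    """National survey (NNPAS 2011, ages 19-30) comparison constants.

    Carried as configuration constants only; never recomputed.
    """
    src_g = "NNPAS 2011-12, ages 19-30, mean intake (g/day)"
    src_pe = "NNPAS 2011-12, ages 19-30, mean % energy"
    vals = {
        "vegetables_g": (172.8, "g/day", src_g),
        "fruit_g": (109.5, "g/day", src_g),
        "grains_g": (171.5, "g/day", src_g),
        "meat_alt_g": (221.5, "g/day", src_g),
        "dairy_alt_g": (242.1, "g/day", src_g),
        "vegetables_pct_e": (7.5, "%E", src_pe),
        "fruit_pct_e": (3.1, "%E", src_pe),
        "grains_pct_e": (16.5, "%E", src_pe),
        "meat_alt_pct_e": (19.4, "%E", src_pe),
        "dairy_alt_pct_e": (9.9, "%E", src_pe),
        "ssb_ml_day": (309.4, "mL/day", src_g),
        "alcohol_g_day": (10.8, "g/day", src_g),
        "carb_pct_e": (45.3, "%E", src_pe),
        "total_sugars_pct_e": (19.8, "%E", src_pe),
        "starch_pct_e": (24.7, "%E", src_pe),
        "protein_pct_e": (18.1, "%E", src_pe),
        "fat_pct_e": (31.2, "%E", src_pe),
        "sat_fat_pct_e": (11.7, "%E", src_pe),
        "mono_fat_pct_e": (12.0, "%E", src_pe),
        "poly_fat_pct_e": (4.9, "%E", src_pe),
        "alcohol_pct_e": (2.8, "%E", src_pe),
        "fiber_g_day": (23.7, "g/day", src_g),
    }
    return ReferenceValues(
        values={k: ReferenceValue(value=v, unit=u, source=s) for k, (v, u, s) in vals.items()}
    )


# ---------------------------------------------------------------------------
# CSV / JSON I/O
# ---------------------------------------------------------------------------

COMPOSITION_COLUMNS: tuple[str, ...] = (
    "food_id",
    "name",
    "group",
    "subgroup",
    "is_wholegrain",
    "is_low_fat",
    "serve_size_g",
    "density_g_per_ml",
    "energy_kj",
    "protein_g",
    "fat_g",
    "sat_fat_g",
    "mono_fat_g",
    "poly_fat_g",
    "carb_g",
    "sugars_g",
    "starch_g",
    "fiber_g",
    "sodium_mg",
    "alcohol_g",
)

_COHORT_FIXED_COLUMNS: tuple[str, ...] = (
    "participant_id",
    "sex",
    "age",
    "weight_kg",
    "height_m",
    "ssb_ml_per_week",
    "takeaway_per_week",
    "water_ml_per_day",
)


def load_composition_table(path: str | Path) -> list[FoodCompositionEntry]:
    """Read and validate a food composition CSV.

    Raises :class:`CompositionSchemaError` naming any missing column and
    :class:`RowValidationError` (carrying the food_id) for invariant failures.
    """
    df = pd.read_csv(path, dtype={"food_id": str, "name": str, "subgroup": str})
    for col in COMPOSITION_COLUMNS:
        if col not in df.columns:
            raise CompositionSchemaError(f"missing column: {col}")
    entries: list[FoodCompositionEntry] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        fid = str(row["food_id"])
        if fid in seen:
            raise RowValidationError(f"{fid}: duplicate food_id")
        seen.add(fid)
        data = {c: row[c] for c in COMPOSITION_COLUMNS}
        data["subgroup"] = "" if pd.isna(row["subgroup"]) else str(row["subgroup"])
        data["is_wholegrain"] = bool(row["is_wholegrain"])
        data["is_low_fat"] = bool(row["is_low_fat"])
        try:
            entries.append(FoodCompositionEntry(**data))
        except ValueError as exc:
            raise RowValidationError(f"{fid}: {exc}") from exc
    return entries


def write_composition_table(entries: Sequence[FoodCompositionEntry], path: str | Path) -> None:
    rows = []
    for e in entries:
        d = e.model_dump()
        d["group"] = e.group.value
        rows.append({c: d[c] for c in COMPOSITION_COLUMNS})
    pd.DataFrame(rows, columns=list(COMPOSITION_COLUMNS)).to_csv(path, index=False)


def composition_index(
    composition: Sequence[FoodCompositionEntry] | Mapping[str, FoodCompositionEntry],
) -> dict[str, FoodCompositionEntry]:
    """food_id → entry lookup (accepts a list or an already-built mapping)."""
    if isinstance(composition, Mapping):
        return dict(composition)
    return {e.food_id: e for e in composition}


def load_cohort(
    path: str | Path, composition: Sequence[FoodCompositionEntry] | Mapping[str, FoodCompositionEntry]
) -> list[IntakeRecord]:
    """Read a cohort CSV (wide ``g_<food_id>`` amount columns).

    A record is marked ``complete=False`` when any behavioural/beverage field
    (takeaway category, water, SSB) is missing; missing demographics are a
    hard :class:`RowValidationError` because such a row can be neither
    screened nor scored. Unknown amount columns raise
    :class:`UnknownFoodError`; negative amounts raise
    :class:`RowValidationError`.
    """
    comp = composition_index(composition)
    df = pd.read_csv(path, dtype={"participant_id": str, "sex": str, "takeaway_per_week": str})
    for col in _COHORT_FIXED_COLUMNS:
        if col not in df.columns:
            raise CompositionSchemaError(f"missing column: {col}")
    amount_cols = [c for c in df.columns if c.startswith("g_")]
    for c in amount_cols:
        fid = c[2:]
        if fid not in comp:
            raise UnknownFoodError(f"unknown food_id in cohort table: {fid}")
    records: list[IntakeRecord] = []
    for _, row in df.iterrows():
        pid = str(row["participant_id"])
        for dem in ("sex", "age", "weight_kg", "height_m"):
            if pd.isna(row[dem]):
                raise RowValidationError(f"{pid}: missing demographic field {dem}")
        try:
            profile = ParticipantProfile(
                participant_id=pid,
                sex=str(row["sex"]),
                age=int(row["age"]),
                weight_kg=float(row["weight_kg"]),
                height_m=float(row["height_m"]),
            )
        except ValueError as exc:
            raise RowValidationError(f"{pid}: {exc}") from exc
        amounts: dict[str, float] = {}
        for c in amount_cols:
            v = row[c]
            if pd.isna(v):
                continue
            v = float(v)
            if v < 0:
                raise RowValidationError(f"{pid}: negative amount for {c[2:]}: {v}")
            if v > 0:
                amounts[c[2:]] = v
        takeaway = row["takeaway_per_week"]
        takeaway = None if (pd.isna(takeaway) or str(takeaway) == "") else str(takeaway)
        if takeaway is not None and takeaway not in TAKEAWAY_CATEGORIES:
            raise RowValidationError(f"{pid}: unknown takeaway category {takeaway!r}")
        complete = takeaway is not None
        water = row["water_ml_per_day"]
        ssb = row["ssb_ml_per_week"]
        if pd.isna(water) or pd.isna(ssb):
            complete = False
        try:
            records.append(
                IntakeRecord(
                    profile=profile,
                    amounts=amounts,
                    ssb_ml_per_week=0.0 if pd.isna(ssb) else float(ssb),
                    takeaway_per_week=takeaway,
                    water_ml_per_day=0.0 if pd.isna(water) else float(water),
                    complete=complete,
                )
            )
        except ValueError as exc:
            raise RowValidationError(f"{pid}: {exc}") from exc
    return records


def write_cohort(records: Sequence[IntakeRecord], path: str | Path) -> None:
    """Write records as a wide cohort CSV (round-trips with :func:`load_cohort`)."""
    food_ids = sorted({fid for r in records for fid in r.amounts})
    rows = []
    for r in records:
        row: dict[str, object] = {
            "participant_id": r.profile.participant_id,
            "sex": r.profile.sex,
            "age": r.profile.age,
            "weight_kg": repr(r.profile.weight_kg),
            "height_m": repr(r.profile.height_m),
            "ssb_ml_per_week": repr(r.ssb_ml_per_week),
            "takeaway_per_week": r.takeaway_per_week if r.takeaway_per_week is not None else "",
            "water_ml_per_day": repr(r.water_ml_per_day),
        }
        for fid in food_ids:
            row[f"g_{fid}"] = repr(r.amounts[fid]) if fid in r.amounts else ""
        rows.append(row)
    cols = list(_COHORT_FIXED_COLUMNS) + [f"g_{fid}" for fid in food_ids]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = dict(base)
    for k, v in override.items():
        if k in out and isinstance(out[k], dict) and isinstance(v, Mapping):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def load_scoring_config(path: str | Path | None = None) -> ScoringConfig:
    """Load a scoring configuration, applying defaults for absent fields.

    ``None`` (or an empty JSON object) yields the full default rubric.
    Structural violations — e.g. component maxima not summing to 100 —
    raise :class:`ConfigError`.
    """
    user: dict = {}
    if path is not None:
        with open(path) as fh:
            user = json.load(fh)
        if not isinstance(user, dict):
            raise ConfigError("scoring config must be a JSON object")
    defaults = ScoringConfig().model_dump()
    try:
        return ScoringConfig(**_deep_merge(defaults, user))
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def load_reference_values(path: str | Path | None = None) -> ReferenceValues:
    """Load reference constants from JSON; ``None`` yields the bundled defaults."""
    if path is None:
        return default_reference_values()
    with open(path) as fh:
        raw = json.load(fh)
    try:
        return ReferenceValues(
            values={k: ReferenceValue(**v) for k, v in raw.get("values", raw).items()}
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"bad reference values file: {exc}") from exc
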