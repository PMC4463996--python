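"""End-to-end orchestration: load → screen → score → analyze → report.

The pipeline is deterministic given fixed inputs and seed; every run writes
``screening.csv``, ``scores.csv``, the analysis tables and a plain-text run
log with ISO-8601 timestamps, input hashes and the seed. On any stage error
partial outputs are removed and a stage-tagged exception is raised.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .model import (
    FoodCompositionEntry,
    IntakeRecord,
    ReferenceValues,
    ScoringConfig,
    TAKEAWAY_ORDINAL,
    composition_index,
    load_cohort,
    load_composition_table,
    load_reference_values,
    load_scoring_config,
)
from .screening import apply_exclusions, screening_frame
from .scoring import score_record, summarize_intake
from .stats import (
    assign_quartiles,
    compare_genders,
    compare_to_reference,
    regress_behavior,
    tally_guidelines,
    trend_by_quartile,
)

__all__ = ["PipelineConfig", "PipelineError", "score_cohort", "analyze_cohort", "run_pipeline"]

COMPONENT_ORDER = (
    "vegetables",
    "fruit",
    "grains",
    "meat_alt",
    "dairy_alt",
    "discretionary",
    "fat",
    "sodium",
    "sugars",
    "water",
    "alcohol",
)

#: per-participant metric columns carried into the quartile and reference tables
_METRIC_COLUMNS = {
    "vegetables_g": lambda s: s.group_g["vegetables"],
    "fruit_g": lambda s: s.group_g["fruit"],
    "grains_g": lambda s: s.group_g["grains"],
    "meat_alt_g": lambda s: s.group_g["meat_alt"],
    "dairy_alt_g": lambda s: s.group_g["dairy_alt"],
    "discretionary_g": lambda s: s.group_g["discretionary"],
    "wholegrain_g": lambda s: s.wholegrain_prop * s.group_g["grains"],
    "lowfat_dairy_g": lambda s: s.lowfat_prop * s.group_g["dairy_alt"],
    "vegetables_pct_e": lambda s: s.group_pct_e["vegetables"],
    "fruit_pct_e": lambda s: s.group_pct_e["fruit"],
    "grains_pct_e": lambda s: s.group_pct_e["grains"],
    "meat_alt_pct_e": lambda s: s.group_pct_e["meat_alt"],
    "dairy_alt_pct_e": lambda s: s.group_pct_e["dairy_alt"],
    "discretionary_pct_e": lambda s: s.discretionary_pct_e,
    "protein_pct_e": lambda s: s.protein_pct_e,
    "fat_pct_e": lambda s: s.fat_pct_e,
    "sat_fat_pct_e": lambda s: s.sat_fat_pct_e,
    "mono_fat_pct_e": lambda s: s.mono_fat_pct_e,
    "poly_fat_pct_e": lambda s: s.poly_fat_pct_e,
    "carb_pct_e": lambda s: s.carb_pct_e,
    "total_sugars_pct_e": lambda s: s.total_sugars_pct_e,
    "starch_pct_e": lambda s: s.starch_pct_e,
    "alcohol_pct_e": lambda s: s.alcohol_pct_e,
    "alcohol_g_day": lambda s: s.alcohol_g_day,
    "sodium_mg_day": lambda s: s.sodium_mg_day,
    "fiber_g_day": lambda s: s.fiber_g_day,
    "ssb_ml_day": lambda s: s.ssb_ml_day,
    "energy_kj_day": lambda s: s.energy_kj_day,
    "energy_kcal_day": lambda s: s.energy_kcal_day,
}


class PipelineError(Exception):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"{stage} stage failed: {cause}")
        self.stage = stage
        self.cause = cause


class PipelineConfig(BaseModel):
    composition_path: str
    cohort_path: str
    scoring_config_path: Optional[str] = None
    reference_values_path: Optional[str] = None
    out_dir: str = "analysis"
    seed: int = 0
    t_test_equal_var: bool = False
    chi2_correction: bool = False


def score_cohort(
    records: Sequence[IntakeRecord],
    composition: Sequence[FoodCompositionEntry] | Mapping[str, FoodCompositionEntry],
    config: ScoringConfig | None = None,
) -> pd.DataFrame:
    """Summarize and score each record into one tidy row per participant."""
    config = config or ScoringConfig()
    comp = composition_index(composition)
    rows = []
    for record in records:
        summary = summarize_intake(record, comp, config.energy_factors)
        score = score_record(summary, config)
        row: dict[str, object] = {
            "participant_id": record.profile.participant_id,
            "sex": record.profile.sex,
            "total": score.total,
        }
        for comp_name in COMPONENT_ORDER:
            row[comp_name] = score.components[comp_name]
        for name, value in score.subscores.items():
            row[f"sub_{name}"] = value
        for comp_name in COMPONENT_ORDER:
            row[f"met_{comp_name}"] = score.met[comp_name]
        row["ssb_ml_per_week"] = record.ssb_ml_per_week
        row["takeaway_ordinal"] = (
            TAKEAWAY_ORDINAL[record.takeaway_per_week]
            if record.takeaway_per_week is not None
            else pd.NA
        )
        for metric, fn in _METRIC_COLUMNS.items():
            row[metric] = fn(summary)
        rows.append(row)
    return pd.DataFrame(rows)


def analyze_cohort(
    scores: pd.DataFrame,
    reference: ReferenceValues | None = None,
    t_test_equal_var: bool = False,
    chi2_correction: bool = False,
) -> dict[str, pd.DataFrame]:
    """All cohort tables from a scored frame.

    Returns the gender comparison (table1), core-food and noncore/nutrient
    reference comparisons (table2, table3, table5 schemas), quartile means
    with linear-trend p-values (table4), the guideline tally and the two
    behaviour regressions.
    """
    reference = reference or load_reference_values()
    quartile_map = assign_quartiles(
        list(zip(scores["participant_id"].astype(str), scores["total"].astype(float)))
    )
    scores = scores.copy()
    scores["quartile"] = [quartile_map[str(p)] for p in scores["participant_id"]]

    gender = compare_genders(
        scores,
        components=list(COMPONENT_ORDER),
        equal_var=t_test_equal_var,
        chi2_correction=chi2_correction,
    )
    tally = tally_guidelines(scores)

    trend_vars = [
        "total",
        "energy_kcal_day",
        "vegetables_g",
        "fruit_g",
        "grains_g",
        "wholegrain_g",
        "meat_alt_g",
        "dairy_alt_g",
        "lowfat_dairy_g",
        "discretionary_g",
        "ssb_ml_day",
        "fiber_g_day",
        "sodium_mg_day",
    ]
    q_rows = []
    for var in trend_vars:
        row: dict[str, object] = {"variable": var}
        for q in ("Q1", "Q2", "Q3", "Q4"):
            sub = scores.loc[scores["quartile"] == q, var].astype(float)
            row[f"{q}_mean"] = sub.mean()
            row[f"{q}_sd"] = sub.std(ddof=1)
        trend = trend_by_quartile(scores[var].astype(float), scores["quartile"])
        row["trend_slope"] = trend.slope
        row["trend_p"] = trend.p
        q_rows.append(row)
    quartile_table = pd.DataFrame(q_rows)

    reg = regress_behavior(scores)
    reg_table = pd.DataFrame(
        [
            {
                "predictor": name,
                "slope": r.slope,
                "intercept": r.intercept,
                "se": r.se,
                "t": r.t,
                "p": r.p,
                "n": r.n,
            }
            for name, r in reg.items()
        ]
    )

    reference_table = compare_to_reference(scores, reference)

    return {
        "table1_gender": gender,
        "table4_quartiles": quartile_table,
        "reference_comparison": reference_table,
        "guideline_tally": tally,
        "behavior_regression": reg_table,
        "quartile_assignment": scores[["participant_id", "quartile"]],
    }


def _hash_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full pipeline and return the artifact directory."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, df: pd.DataFrame) -> None:
        path = out_dir / name
        df.to_csv(path, index=False)
        written.append(path)

    try:
        try:
            composition = load_composition_table(config.composition_path)
            cohort = load_cohort(config.cohort_path, composition)
            scoring_config = load_scoring_config(config.scoring_config_path)
            reference = load_reference_values(config.reference_values_path)
        except Exception as exc:
            raise PipelineError("load", exc) from exc
        try:
            included, log = apply_exclusions(cohort, composition, scoring_config.energy_factors)
            emit("screening.csv", screening_frame(log))
        except Exception as exc:
            raise PipelineError("screen", exc) from exc
        try:
            scores = score_cohort(included, composition, scoring_config)
            emit("scores.csv", scores)
        except Exception as exc:
            raise PipelineError("score", exc) from exc
        try:
            tables = analyze_cohort(
                scores,
                reference,
                t_test_equal_var=config.t_test_equal_var,
                chi2_correction=config.chi2_correction,
            )
            for name, df in tables.items():
                emit(f"{name}.csv", df)
        except Exception as exc:
            raise PipelineError("analyze", exc) from exc
        log_lines = [
            f"{_dt.datetime.now(_dt.timezone.utc).isoformat()} dietq {__version__}",
            f"seed: {config.seed}",
            f"composition: {config.composition_path} sha256={_hash_file(config.composition_path)}",
            f"cohort: {config.cohort_path} sha256={_hash_file(config.cohort_path)}",
            f"participants: {len(cohort)} screened, {len(scores)} included",
            f"config: {json.dumps(config.model_dump(), sort_keys=True)}",
        ]
        (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
    except PipelineError:
        for path in written:
            path.unlink(missing_ok=True)
        raise
    return out_dir
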