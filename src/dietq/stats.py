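"""Cohort analytics on scored diets: quartiles, trends, gender contrasts,
guideline tallies, behaviour regressions and reference comparisons.

All tests are textbook procedures: a linear trend across score quartiles is
the slope t-test from OLS of the value on the quartile index 1–4 (which
handles unequal quartile sizes; the balanced orthogonal-polynomial contrast
is retained as a secondary route), gender differences use a two-sample
t test (Welch by default) and a Pearson chi-square on met-guideline
proportions, and behaviour associations are simple OLS regressions of the
total score on weekly SSB volume and on the ordinal takeaway category.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import ReferenceValues, TAKEAWAY_ORDINAL

__all__ = [
    "QUARTILES",
    "TrendResult",
    "RegressionResult",
    "assign_quartiles",
    "trend_by_quartile",
    "polynomial_linear_contrast",
    "compare_genders",
    "pearson_chi2_2x2",
    "tally_guidelines",
    "regress_behavior",
    "compare_to_reference",
]

QUARTILES = ("Q1", "Q2", "Q3", "Q4")


@dataclass(frozen=True)
class TrendResult:
    slope: float
    se: float
    t: float
    p: float
    n: int


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    se: float
    t: float
    p: float
    n: int


def assign_quartiles(scores: Sequence[tuple[str, float]] | Mapping[str, float]) -> dict[str, str]:
    """Rank-based split of totals into Q1 (lowest) … Q4 (highest).

    Sizes are as equal as n permits (lower quartiles absorb any remainder);
    ties are broken by stable input order, so the assignment is deterministic.
    """
    if isinstance(scores, Mapping):
        pairs = list(scores.items())
    else:
        pairs = list(scores)
    if len(pairs) < 4:
        raise ValueError(f"need at least 4 participants for quartiles, got {len(pairs)}")
    totals = np.asarray([t for _, t in pairs], dtype=float)
    order = np.argsort(totals, kind="stable")
    assignment: dict[str, str] = {}
    for qi, chunk in enumerate(np.array_split(order, 4)):
        for idx in chunk:
            assignment[pairs[int(idx)][0]] = QUARTILES[qi]
    return assignment


def _quartile_index(quartiles: Sequence[str]) -> np.ndarray:
    try:
        return np.asarray([QUARTILES.index(q) + 1 for q in quartiles], dtype=float)
    except ValueError as exc:
        raise ValueError(f"unknown quartile label: {exc}") from exc


def trend_by_quartile(values: Sequence[float], quartiles: Sequence[str]) -> TrendResult:
    """Linear trend of a per-participant value across the ordered quartiles.

    OLS of the value on the quartile index 1–4; slope, its SE, and the
    two-sided slope t-test. All four quartiles must be represented.
    """
    y = np.asarray(values, dtype=float)
    x = _quartile_index(quartiles)
    present = set(quartiles)
    missing = [q for q in QUARTILES if q not in present]
    if missing:
        raise ValueError(f"empty quartile group(s): {missing}")
    res = sps.linregress(x, y)
    return TrendResult(
        slope=float(res.slope),
        se=float(res.stderr),
        t=float(res.slope / res.stderr) if res.stderr > 0 else float("inf"),
        p=float(res.pvalue),
        n=len(y),
    )


def polynomial_linear_contrast(
    values: Sequence[float], quartiles: Sequence[str]
) -> tuple[float, float]:
    """Balanced linear polynomial contrast across the four groups.

    Returns the contrast estimate ``L = Σ c_j ȳ_j`` with coefficients
    (−3, −1, 1, 3) and its t statistic using the within-group mean square
    (one-way ANOVA error term). Intended for balanced designs; on balanced
    data the estimate is proportional to the OLS slope (L = 10·slope).
    """
    y = np.asarray(values, dtype=float)
    labels = np.asarray(quartiles)
    coeffs = np.array([-3.0, -1.0, 1.0, 3.0])
    means, ns, sse = [], [], 0.0
    for q in QUARTILES:
        g = y[labels == q]
        if g.size == 0:
            raise ValueError(f"empty quartile group: {q}")
        means.append(g.mean())
        ns.append(g.size)
        sse += float(((g - g.mean()) ** 2).sum())
    L = float(np.dot(coeffs, means))
    df = int(y.size - 4)
    mse = sse / df if df > 0 else float("nan")
    se = float(np.sqrt(mse * np.sum(coeffs**2 / np.asarray(ns))))
    t = L / se if se > 0 else float("inf")
    return L, t


def pearson_chi2_2x2(
    met_a: int, n_a: int, met_b: int, n_b: int, correction: bool = False
) -> tuple[float, float]:
    """Pearson chi-square on a met/not-met 2×2 table (no continuity
    correction by default). A zero margin (nobody or everybody met in both
    groups) returns (0.0, 1.0)."""
    table = np.array([[met_a, n_a - met_a], [met_b, n_b - met_b]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 0.0, 1.0
    res = sps.chi2_contingency(table, correction=correction)
    return float(res.statistic), float(res.pvalue)


def compare_genders(
    scores: pd.DataFrame,
    components: Sequence[str] | None = None,
    equal_var: bool = False,
    chi2_correction: bool = False,
) -> pd.DataFrame:
    """Per-component gender comparison table.

    ``scores`` holds one row per participant with a ``sex`` column, component
    score columns and matching ``met_<component>`` flag columns. For each
    component: mean (SD) and met n (%) by sex, a two-sample t test on the
    scores (Welch unless ``equal_var``) and a Pearson chi-square on the met
    proportions.
    """
    for sex in ("male", "female"):
        if (scores["sex"] == sex).sum() == 0:
            raise ValueError(f"no {sex} participants")
    if components is None:
        components = [c[4:] for c in scores.columns if c.startswith("met_")]
    male = scores[scores["sex"] == "male"]
    female = scores[scores["sex"] == "female"]
    rows = []
    for comp in components:
        m, f = male[comp].to_numpy(float), female[comp].to_numpy(float)
        met_m = int(male[f"met_{comp}"].sum())
        met_f = int(female[f"met_{comp}"].sum())
        if np.allclose(m.var(ddof=1) + f.var(ddof=1), 0.0) and np.isclose(m.mean(), f.mean()):
            t_stat, t_p = 0.0, 1.0
        else:
            t_res = sps.ttest_ind(m, f, equal_var=equal_var)
            t_stat, t_p = float(t_res.statistic), float(t_res.pvalue)
        chi2, chi2_p = pearson_chi2_2x2(met_m, len(m), met_f, len(f), correction=chi2_correction)
        rows.append(
            {
                "component": comp,
                "male_mean": m.mean(),
                "male_sd": m.std(ddof=1),
                "male_met_n": met_m,
                "male_met_pct": 100.0 * met_m / len(m),
                "female_mean": f.mean(),
                "female_sd": f.std(ddof=1),
                "female_met_n": met_f,
                "female_met_pct": 100.0 * met_f / len(f),
                "t_stat": t_stat,
                "t_p": t_p,
                "chi2": chi2,
                "chi2_p": chi2_p,
            }
        )
    return pd.DataFrame(rows)


def tally_guidelines(scores: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages meeting each guideline (from the met flags)."""
    met_cols = [c for c in scores.columns if c.startswith("met_")]
    n = len(scores)
    rows = []
    for c in met_cols:
        k = int(scores[c].sum())
        rows.append(
            {
                "component": c[4:],
                "n_met": k,
                "pct_met": round(100.0 * k / n, 1) if n else 0.0,
            }
        )
    return pd.DataFrame(rows)


def regress_behavior(scores: pd.DataFrame) -> dict[str, RegressionResult]:
    """Simple OLS of the total score on SSB volume and on takeaway category.

    ``scores`` needs columns ``total``, ``ssb_ml_per_week`` and either an
    ordinal ``takeaway_ordinal`` or a categorical ``takeaway_per_week``
    (coded 0–3). One predictor at a time; a constant predictor is an error.
    """
    y = scores["total"].to_numpy(float)
    out: dict[str, RegressionResult] = {}
    predictors: dict[str, np.ndarray] = {
        "ssb_ml_per_week": scores["ssb_ml_per_week"].to_numpy(float)
    }
    if "takeaway_ordinal" in scores.columns:
        predictors["takeaway"] = scores["takeaway_ordinal"].to_numpy(float)
    elif "takeaway_per_week" in scores.columns:
        predictors["takeaway"] = np.asarray(
            [TAKEAWAY_ORDINAL[c] for c in scores["takeaway_per_week"]], dtype=float
        )
    for name, x in predictors.items():
        if np.var(x) == 0:
            raise ValueError(f"constant predictor: {name}")
        res = sps.linregress(x, y)
        out[name] = RegressionResult(
            slope=float(res.slope),
            intercept=float(res.intercept),
            se=float(res.stderr),
            t=float(res.slope / res.stderr) if res.stderr > 0 else float("inf"),
            p=float(res.pvalue),
            n=len(y),
        )
    return out


def compare_to_reference(
    metrics: pd.DataFrame, reference: ReferenceValues
) -> pd.DataFrame:
    """Cohort mean (SD) next to each reference constant, no inferential test.

    ``metrics`` holds one numeric column per comparable quantity; reference
    keys without a matching column are skipped with a warning.
    """
    rows = []
    for key, rv in reference.values.items():
        if key not in metrics.columns:
            warnings.warn(f"no cohort column for reference key {key!r}; row omitted")
            continue
        col = metrics[key].to_numpy(float)
        rows.append(
            {
                "key": key,
                "cohort_mean": col.mean() if col.size else float("nan"),
                "cohort_sd": col.std(ddof=1) if col.size > 1 else float("nan"),
                "reference": rv.value,
                "difference": (col.mean() - rv.value) if col.size else float("nan"),
                "unit": rv.unit,
                "source": rv.source,
            }
        )
    if not rows:
        warnings.warn("empty reference comparison table")
        return pd.DataFrame(
            columns=["key", "cohort_mean", "cohort_sd", "reference", "difference", "unit", "source"]
        )
    return pd.DataFrame(rows)
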