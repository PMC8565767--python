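"""Counterfactual covariate decomposition of predicted fire probability.

The contribution of a covariate subset is isolated by predicting from the
full fitted model after replacing every *inactive* covariate with a null
value that eliminates its spatial (and temporal) variation:

- climate normals have no meaningful zero, so they are set to the training
  mean;
- housing density, cultivated fraction and the short-term climate
  deviations have a meaningful zero, so they are set to 0;
- the distance covariates are set to the training *maximum* (zero distance
  is where their influence is strongest, so the far limit is the null);
- years since fire has no stated null in the source framework; here it is
  removed by setting it to the training mean (an extension, flagged in the
  report output).

Sub-model mean-annual-probability maps are then correlated (Pearson) with
the observed mean annual fire frequency and with the full model's map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .features import (
    CLIMATE_COVARIATES,
    COVARIATES,
    HUMAN_COVARIATES,
    FireHistory,
)
from .gam import FittedGAM, predict_probability

__all__ = [
    "NULL_RULES",
    "STANDARD_SUBSETS",
    "SubsetSpec",
    "null_value",
    "predict_with_subset",
    "mean_annual_probability",
    "observed_mean_annual_probability",
    "correlate_maps",
    "decomposition_report",
]

#: how each covariate is nulled out when inactive
NULL_RULES = {
    "aet_normal": "training_mean",
    "cwd_normal": "training_mean",
    "aet_dev3": "zero",
    "cwd_dev3": "zero",
    "housing_density_25km": "zero",
    "cultivated_fraction": "zero",
    "dist_roads": "training_max",
    "dist_electrical": "training_max",
    "years_since_fire": "training_mean",  # extension: no stated null rule
}


@dataclass(frozen=True)
class SubsetSpec:
    """A named set of active covariates; everything else is nulled."""

    name: str
    active: tuple[str, ...]
    null_rules: dict = field(default_factory=lambda: dict(NULL_RULES))

    def __post_init__(self):
        unknown = set(self.active) - set(COVARIATES)
        if unknown:
            raise ValueError(f"unknown covariates in subset {self.name!r}: "
                             f"{sorted(unknown)}")


#: the standard report rows: full model, climate, climate normals only,
#: human activity, development, cultivation, and time-since-fire only
STANDARD_SUBSETS = (
    SubsetSpec("all", COVARIATES),
    SubsetSpec("climate", CLIMATE_COVARIATES),
    SubsetSpec("climate_normals", ("aet_normal", "cwd_normal")),
    SubsetSpec("human_activity", HUMAN_COVARIATES),
    SubsetSpec("development", ("housing_density_25km", "dist_roads",
                               "dist_electrical")),
    SubsetSpec("cultivation", ("cultivated_fraction",)),
    SubsetSpec("time_since_fire", ("years_since_fire",)),
)


def null_value(covariate: str, model: FittedGAM,
               null_rules: dict | None = None) -> float:
    """The value a covariate takes when its effect is eliminated."""
    rules = NULL_RULES if null_rules is None else null_rules
    if covariate not in rules:
        raise ValueError(f"no null rule defined for {covariate!r}; "
                         "specify one explicitly")
    rule = rules[covariate]
    if rule == "zero":
        return 0.0
    summary = model.training_summary.get(covariate)
    if summary is None:
        raise ValueError(f"model carries no training summary for "
                         f"{covariate!r}")
    if rule == "training_mean":
        return float(summary["mean"])
    if rule == "training_max":
        return float(summary["max"])
    raise ValueError(f"unknown null rule {rule!r}")


def predict_with_subset(
    model: FittedGAM, records: pd.DataFrame, subset: SubsetSpec
) -> np.ndarray:
    """Full-model predictions with inactive covariates held at their nulls.

    Active covariates pass through untouched, so the identity subset
    reproduces the full-model predictions exactly.
    """
    inactive = [t.name for t in model.terms if t.name not in subset.active]
    if not inactive:
        return predict_probability(model, records)
    counterfactual = records.copy()
    for name in inactive:
        counterfactual[name] = null_value(name, model, subset.null_rules)
    return predict_probability(model, counterfactual)


def mean_annual_probability(
    per_year: dict[int, np.ndarray], period: tuple[int, int]
) -> np.ndarray:
    """Per-pixel arithmetic mean of annual probability maps over a period."""
    lo, hi = period
    missing = [y for y in range(lo, hi + 1) if y not in per_year]
    if missing:
        raise ValueError(f"missing predictions for years {missing}")
    return np.mean([per_year[y] for y in range(lo, hi + 1)], axis=0)


def observed_mean_annual_probability(
    history: FireHistory, period: tuple[int, int]
) -> np.ndarray:
    """Observed burn frequency: burn years in period / years in period.

    The record may begin before the modeling window; only the requested
    period enters the ratio.
    """
    lo, hi = period
    if hi < lo:
        raise ValueError("empty period")
    if lo < history.record_start or hi > history.record_end:
        raise ValueError("period extends beyond the fire record")
    sel = history.burned[lo - history.record_start: hi - history.record_start + 1]
    return sel.sum(axis=0) / float(hi - lo + 1)


def correlate_maps(map_a: np.ndarray, map_b: np.ndarray):
    """Pearson correlation over the common valid (finite) pixels.

    Returns ``(r, p, df)`` with df = n - 2.  Zero-variance input is
    undefined and raises.
    """
    a = np.asarray(map_a, dtype=float).ravel()
    b = np.asarray(map_b, dtype=float).ravel()
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if len(a) < 3:
        raise ValueError("need at least 3 common valid pixels")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("Pearson correlation undefined for a zero-variance map")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p), len(a) - 2


def _subset_mean_map(model, records, subset, period, shape):
    """Mean-annual-probability raster for one subset over sampled pixels."""
    lo, hi = period
    in_period = records[(records["year"] >= lo) & (records["year"] <= hi)]
    probs = predict_with_subset(model, in_period, subset)
    grouped = pd.DataFrame({
        "row": in_period["row"].to_numpy(),
        "col": in_period["col"].to_numpy(),
        "p": probs,
    }).groupby(["row", "col"])["p"]
    n_years = hi - lo + 1
    counts = grouped.count()
    if (counts != n_years).any():
        raise ValueError("records do not cover every pixel-year in the period")
    mean_p = grouped.mean()
    out = np.full(shape, np.nan)
    idx = np.array(list(mean_p.index))
    out[idx[:, 0], idx[:, 1]] = mean_p.to_numpy()
    return out


def decomposition_report(
    model: FittedGAM,
    records: pd.DataFrame,
    history: FireHistory,
    period: tuple[int, int],
    shape: tuple[int, int],
    subsets=STANDARD_SUBSETS,
    observed_period: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Correlate each subset's mean-probability map with the observed burn
    frequency and with the full model's map.

    ``records`` must contain one row per pixel and year of ``period`` for
    the pixels over which the correlations are computed (by default the
    Poisson-disk-sampled training pixels; pass a table over all valid
    pixels for statewide maps).  ``observed_period`` may extend earlier
    than the modeling period when a longer record gives a more robust
    observed frequency; it defaults to ``period``.
    """
    if observed_period is None:
        observed_period = period
    observed = observed_mean_annual_probability(history, observed_period)
    subsets = list(subsets)
    maps = {s.name: _subset_mean_map(model, records, s, period, shape)
            for s in subsets}
    if "all" in maps:
        full_map = maps["all"]
    else:
        full_map = _subset_mean_map(model, records, SubsetSpec("all", COVARIATES),
                                    period, shape)
    rows = []
    for s in subsets:
        m = maps[s.name]
        r_obs, p_obs, df = correlate_maps(m, observed)
        r_full, p_full, _ = correlate_maps(m, full_map)
        rows.append({
            "subset": s.name,
            "active": "+".join(s.active),
            "r_observed": r_obs, "p_observed": p_obs,
            "r_full_model": r_full, "p_full_model": p_full,
            "df": df,
            "ysf_nulled_to_mean": "years_since_fire" not in s.active,
        })
    return pd.DataFrame(rows)
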