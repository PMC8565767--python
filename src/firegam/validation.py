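"""Spatiotemporal blocked cross-validation and skill metrics.

Predictive skill in novel conditions is measured with multidimensional
k-fold CV: years are partitioned into ``n_groups`` random temporal groups
and sampled pixels into ``n_groups`` random spatial groups.  Iteration i
holds out temporal group T_i and spatial group S_i jointly; the model is
trained on records with year not in T_i *and* pixel not in S_i, and scored
by ROC/AUC separately on three disjoint test cells:

- ``novel_locations``: pixel in S_i, year not in T_i
- ``novel_years``:     pixel not in S_i, year in T_i
- ``novel_both``:      pixel in S_i and year in T_i

Regional CV restricts both training and testing data to one region before
assigning spatial groups; leave-one-region-out trains on all other regions
and scores within the held-out region only.  Statewide and regional AUCs
on matched folds are compared with paired t-tests.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .gam import fit_binomial_gam, predict_probability

__all__ = [
    "NOVELTY_TYPES",
    "CVPlan",
    "CVResult",
    "PairedTTestResult",
    "roc_auc",
    "assign_cv_groups",
    "run_spatiotemporal_cv",
    "run_regional_cv",
    "run_leave_one_region_out",
    "paired_ttest",
]

logger = logging.getLogger(__name__)

NOVELTY_TYPES = ("novel_locations", "novel_years", "novel_both")


def roc_auc(labels, scores) -> float:
    """Probability that a random positive outranks a random negative,
    with ties counted one half (the Mann-Whitney convention)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("ROC/AUC undefined: only one class present")
    return float(roc_auc_score(labels, scores))


@dataclass
class CVPlan:
    """Random partition of years and pixels into n near-equal groups."""

    n_groups: int
    year_group: dict[int, int]
    pixel_group: dict[int, int]
    seed: int

    @property
    def years(self) -> list[int]:
        return sorted(self.year_group)

    @property
    def pixels(self) -> list[int]:
        return sorted(self.pixel_group)

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        yrs = pd.DataFrame(sorted(self.year_group.items()),
                           columns=["year", "temporal_group"])
        pix = pd.DataFrame(sorted(self.pixel_group.items()),
                           columns=["pixel_id", "spatial_group"])
        return yrs, pix


@dataclass
class CVResult:
    """Per-iteration AUC by novelty type, plus train/test sizes."""

    table: pd.DataFrame  # iteration, novelty, auc, n_train, n_test
    n_missing: int = 0
    meta: dict = field(default_factory=dict)

    def mean_auc(self) -> pd.Series:
        """Mean AUC per novelty type; missing iterations are dropped."""
        return self.table.dropna(subset=["auc"]).groupby("novelty")["auc"].mean()

    def aucs(self, novelty: str) -> np.ndarray:
        sub = self.table[self.table["novelty"] == novelty]
        return sub.sort_values("iteration")["auc"].to_numpy()


def assign_cv_groups(years, pixels, n_groups: int = 10, seed: int = 0) -> CVPlan:
    """Seeded random partition of years and pixels into ``n_groups`` groups
    whose sizes differ by at most one."""
    years = np.asarray(sorted(set(int(y) for y in years)))
    pixels = np.asarray(sorted(set(int(p) for p in pixels)))
    if len(years) < n_groups:
        raise ValueError(f"{len(years)} years cannot form {n_groups} groups")
    if len(pixels) < n_groups:
        raise ValueError(f"{len(pixels)} pixels cannot form {n_groups} groups")
    rng = np.random.default_rng(seed)

    def partition(items, rng):
        perm = rng.permutation(len(items))
        groups = {}
        for g, chunk in enumerate(np.array_split(perm, n_groups)):
            for idx in chunk:
                groups[int(items[idx])] = g
        return groups

    return CVPlan(
        n_groups=n_groups,
        year_group=partition(years, rng),
        pixel_group=partition(pixels, rng),
        seed=seed,
    )


def run_spatiotemporal_cv(
    records: pd.DataFrame,
    plan: CVPlan,
    term_specs,
    lambda_rule="gcv",
    full_grid: bool = False,
    score_fn=None,
) -> CVResult:
    """Blocked CV over paired (temporal, spatial) holdouts.

    By default iteration i pairs temporal group i with spatial group i
    (n_groups iterations); ``full_grid=True`` runs all n_groups^2 pairs.
    ``score_fn(train, test) -> scores`` may replace model fitting (e.g. to
    score with the generating model or an intercept-only baseline).
    """
    tg = records["year"].map(plan.year_group)
    sg = records["pixel_id"].map(plan.pixel_group)
    if tg.isna().any() or sg.isna().any():
        raise ValueError("plan does not cover all record years/pixels")
    pairs = (
        [(i, j) for i in range(plan.n_groups) for j in range(plan.n_groups)]
        if full_grid else [(i, i) for i in range(plan.n_groups)]
    )
    rows = []
    for it, (ti, sj) in enumerate(pairs):
        in_t = (tg == ti).to_numpy()
        in_s = (sg == sj).to_numpy()
        train = records[~in_t & ~in_s]
        if score_fn is None:
            if train["burned"].nunique() < 2:
                warnings.warn(f"iteration {it}: training fold has a single "
                              "class; AUCs recorded as missing", stacklevel=2)
                predict = None
            else:
                model = fit_binomial_gam(train, term_specs,
                                         lambda_rule=lambda_rule)
                predict = lambda test: predict_probability(model, test)  # noqa: E731
        else:
            predict = lambda test: score_fn(train, test)  # noqa: E731
        for novelty, mask in (
            ("novel_locations", in_s & ~in_t),
            ("novel_years", ~in_s & in_t),
            ("novel_both", in_s & in_t),
        ):
            test = records[mask]
            if predict is None or len(test) == 0 \
                    or test["burned"].nunique() < 2:
                if predict is not None:
                    warnings.warn(
                        f"iteration {it}, {novelty}: test cell has a single "
                        "class; AUC recorded as missing", stacklevel=2)
                auc = np.nan
            else:
                auc = roc_auc(test["burned"].to_numpy(), predict(test))
            rows.append({"iteration": it, "novelty": novelty, "auc": auc,
                         "n_train": len(train), "n_test": len(test)})
    table = pd.DataFrame(rows)
    return CVResult(table=table,
                    n_missing=int(table["auc"].isna().sum()),
                    meta={"full_grid": full_grid, "seed": plan.seed})


def run_regional_cv(
    records: pd.DataFrame,
    plan: CVPlan,
    term_specs,
    lambda_rule="gcv",
    region_col: str = "region_id",
) -> tuple[dict[int, CVResult], dict[int, str]]:
    """Independent spatiotemporal CV inside each region.

    Training and testing data are restricted to the region *before* spatial
    groups are assigned.  Temporal groups are shared with the statewide
    plan so regional and statewide folds are matched.  If a region contains
    every pixel of the plan its spatial groups are reused verbatim (a
    one-region landscape therefore reproduces the statewide CV exactly);
    otherwise its pixels are re-partitioned with a seed derived from the
    plan seed and the region id.  Regions whose data cannot support the CV
    (single class, too few pixels) are skipped with a logged reason.
    """
    results: dict[int, CVResult] = {}
    skipped: dict[int, str] = {}
    for region in sorted(records[region_col].unique()):
        sub = records[records[region_col] == region]
        reason = None
        if sub["burned"].nunique() < 2:
            reason = "single class (insufficient fires observed)"
        elif sub["pixel_id"].nunique() < plan.n_groups:
            reason = "fewer pixels than spatial groups"
        if reason:
            logger.warning("region %s skipped: %s", region, reason)
            skipped[int(region)] = reason
            continue
        pixels = sorted(sub["pixel_id"].unique())
        if set(pixels) == set(plan.pixel_group):
            region_plan = plan
        else:
            sub_seed = int((plan.seed * 1_000_003 + int(region) + 1) % 2**31)
            sub_plan = assign_cv_groups(plan.years, pixels,
                                        plan.n_groups, seed=sub_seed)
            region_plan = CVPlan(
                n_groups=plan.n_groups,
                year_group=dict(plan.year_group),  # matched temporal folds
                pixel_group=sub_plan.pixel_group,
                seed=sub_seed,
            )
        results[int(region)] = run_spatiotemporal_cv(
            sub, region_plan, term_specs, lambda_rule=lambda_rule)
    return results, skipped


def run_leave_one_region_out(
    records: pd.DataFrame,
    term_specs,
    lambda_rule="gcv",
    region_col: str = "region_id",
) -> pd.DataFrame:
    """Train on all regions but one; score AUC inside the held-out region.

    Returns one row per region (held-out AUC and sizes); regions whose
    held-out records carry a single class get a missing AUC.
    """
    regions = sorted(records[region_col].unique())
    if len(regions) < 2:
        raise ValueError("leave-one-region-out needs at least two regions")
    rows = []
    for region in regions:
        held = records[region_col] == region
        train = records[~held]
        test = records[held]
        if train["burned"].nunique() < 2:
            warnings.warn(f"training data excluding region {region} have a "
                          "single class; AUC recorded as missing",
                          stacklevel=2)
            rows.append({"region_id": region, "auc": np.nan,
                         "n_train": len(train), "n_test": len(test)})
            continue
        model = fit_binomial_gam(train, term_specs, lambda_rule=lambda_rule)
        if test["burned"].nunique() < 2:
            warnings.warn(f"region {region}: held-out records have a single "
                          "class; AUC recorded as missing", stacklevel=2)
            auc = np.nan
        else:
            auc = roc_auc(test["burned"].to_numpy(),
                          predict_probability(model, test))
        rows.append({"region_id": region, "auc": auc,
                     "n_train": len(train), "n_test": len(test)})
    return pd.DataFrame(rows)


@dataclass
class PairedTTestResult:
    t: float
    p: float
    df: int
    degenerate: bool = False


def paired_ttest(auc_a, auc_b) -> PairedTTestResult:
    """Two-sided paired t-test on per-iteration AUC differences.

    Zero-variance differences make the statistic degenerate; the result is
    flagged rather than raising (identical vectors give t=0, p=1)."""
    a = np.asarray(auc_a, dtype=float)
    b = np.asarray(auc_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("paired t-test needs equal-length 1-d vectors, n>=2")
    d = a - b
    df = len(d) - 1
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            return PairedTTestResult(t=0.0, p=1.0, df=df, degenerate=True)
        return PairedTTestResult(t=float(np.inf * np.sign(d.mean())),
                                 p=0.0, df=df, degenerate=True)
    t, p = stats.ttest_rel(a, b)
    return PairedTTestResult(t=float(t), p=float(p), df=df)
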