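"""Binomial GAM with penalized natural cubic regression splines.

The model for a binary burn indicator :math:`y_i` with covariates
:math:`x_{i1},\\dots,x_{ip}` is

.. math::

   \\mathrm{logit}\\, P(y_i = 1) = \\beta_0 + \\sum_j f_j(x_{ij}),

where each :math:`f_j` is a natural cubic regression spline with a small
basis (default dimension 5) and an integrated-squared-second-derivative
(curvature) penalty.  Fitting maximizes the Bernoulli log-likelihood minus
:math:`\\sum_j \\lambda_j \\beta_j^T S_j \\beta_j` by penalized iteratively
reweighted least squares (P-IRLS) with step halving, so the penalized
deviance is non-increasing across iterations.  The smoothing parameter is
chosen by generalized cross-validation over a log-spaced grid shared across
terms (a fixed value is also accepted), and each term reports its effective
degrees of freedom (EDF), the trace of its block of the influence matrix.

Basis details: knots sit at quantiles of the training covariate (always
including the min and max).  Each smooth is parameterized by its values at
the knots; the natural-spline second-derivative map gives both evaluation
between knots and the exact curvature penalty, whose null space is the
constants-plus-linears.  A sum-to-zero constraint over the training rows is
absorbed by reparameterization so each smooth is identifiable alongside the
intercept (a k-knot smooth therefore carries k-1 free coefficients).
Prediction outside the training range clamps the covariate to the range
rather than extrapolating the cubic.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.special import expit, logit
from scipy.stats import chi2

__all__ = [
    "SmoothTermSpec",
    "FittedTerm",
    "FittedGAM",
    "PerfectSeparationWarning",
    "build_spline_basis",
    "crs_design",
    "fit_binomial_gam",
    "fit_leave_one_year_out",
    "predict_probability",
    "predict_linear",
    "partial_effect",
    "coefficient_surface",
]

DEFAULT_BASIS_DIM = 5
DEFAULT_LAMBDA_GRID = np.logspace(-2.0, 6.0, 13)
MAX_PIRLS_ITER = 200
DEVIANCE_RTOL = 1e-8


class PerfectSeparationWarning(UserWarning):
    pass


@dataclass(frozen=True)
class SmoothTermSpec:
    """One smooth term: covariate name, basis dimension, basis type.

    ``basis="cr"`` is the penalized natural cubic regression spline (the
    default; ``basis_dim`` knots, curvature penalty).  ``basis="linear"``
    enters the raw covariate as a single unpenalized column, which reduces
    the term to ordinary logistic regression — useful for oracle checks.
    """

    name: str
    basis_dim: int = DEFAULT_BASIS_DIM
    basis: str = "cr"

    def __post_init__(self):
        if self.basis == "cr" and self.basis_dim < 3:
            raise ValueError(
                f"cubic regression spline needs basis_dim >= 3 "
                f"(got {self.basis_dim} for {self.name!r})")
        if self.basis not in ("cr", "linear"):
            raise ValueError(f"unknown basis {self.basis!r}")


# ---------------------------------------------------------------------------
# natural cubic regression spline basis
# ---------------------------------------------------------------------------

def _crs_matrices(knots: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Second-derivative map F and penalty S for a natural cubic spline
    parameterized by its values at the knots.

    With knot gaps h_j, the interior second derivatives delta satisfy
    B delta = D beta (tridiagonal B, banded D); F = B^-1 D maps knot values
    to second derivatives and S = D' B^-1 D is the exact curvature penalty
    integral, annihilating constants and linears.
    """
    k = len(knots)
    h = np.diff(knots)
    B = np.zeros((k - 2, k - 2))
    D = np.zeros((k - 2, k))
    for i in range(k - 2):
        B[i, i] = (h[i] + h[i + 1]) / 3.0
        if i + 1 < k - 2:
            B[i, i + 1] = h[i + 1] / 6.0
            B[i + 1, i] = h[i + 1] / 6.0
        D[i, i] = 1.0 / h[i]
        D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        D[i, i + 2] = 1.0 / h[i + 1]
    F = linalg.solve(B, D, assume_a="pos")
    S = D.T @ F
    S = (S + S.T) / 2.0
    return F, S


def crs_design(x: np.ndarray, knots: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Evaluate the k cardinal natural-spline basis functions at ``x``.

    Values outside the knot span are clamped to the boundary (constant
    extrapolation of the boundary value).
    """
    k = len(knots)
    x = np.clip(np.asarray(x, dtype=float), knots[0], knots[-1])
    j = np.clip(np.searchsorted(knots, x, side="right") - 1, 0, k - 2)
    h = knots[j + 1] - knots[j]
    lo, hi = knots[j], knots[j + 1]
    a_minus = (hi - x) / h
    a_plus = (x - lo) / h
    c_minus = ((hi - x) ** 3 / h - h * (hi - x)) / 6.0
    c_plus = ((x - lo) ** 3 / h - h * (x - lo)) / 6.0
    n = len(x)
    X = np.zeros((n, k))
    rows = np.arange(n)
    X[rows, j] += a_minus
    X[rows, j + 1] += a_plus
    # cubic parts load on the interior second derivatives via F
    C = np.zeros((n, k - 2))
    inner_lo = j - 1  # delta index of left knot (natural BC: delta_0 = 0)
    mask = inner_lo >= 0
    C[rows[mask], inner_lo[mask]] += c_minus[mask]
    inner_hi = j  # delta index of right knot
    mask = inner_hi <= k - 3
    C[rows[mask], inner_hi[mask]] += c_plus[mask]
    X += C @ F
    return X


def _quantile_knots(x: np.ndarray, k: int) -> np.ndarray:
    """k knots at evenly spaced quantiles of the *unique* covariate values
    (linear-interpolation quantile type), always including the observed min
    and max.  Using unique values keeps heavy atoms (e.g. a years-since-
    fire cap holding much of the mass) from collapsing knots together and
    keeps knots out of gaps in the support."""
    ux = np.unique(np.asarray(x, dtype=float))
    if len(ux) < k:
        raise ValueError("covariate has too few distinct values for the "
                         f"requested basis dimension {k}")
    knots = np.quantile(ux, np.linspace(0.0, 1.0, k))
    if len(np.unique(knots)) < k:
        raise ValueError("could not place strictly increasing quantile knots")
    return knots


@dataclass
class SplineBasis:
    """Design and penalty for one smooth, pre-constraint."""

    knots: np.ndarray
    F: np.ndarray
    S: np.ndarray  # curvature penalty on knot values

    def design(self, x: np.ndarray) -> np.ndarray:
        return crs_design(x, self.knots, self.F)


def build_spline_basis(
    x: np.ndarray, basis_dim: int = DEFAULT_BASIS_DIM,
    knots: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, SplineBasis]:
    """Cubic regression spline basis evaluated at ``x`` plus its curvature
    penalty matrix.

    Returns ``(X, S, basis)`` where ``X`` is (n, basis_dim), ``S`` the
    penalty whose quadratic form is the integrated squared second
    derivative, and ``basis`` the reusable evaluator.  Knots default to
    quantiles of ``x``; explicit knots must be strictly increasing.
    """
    if knots is None:
        knots = _quantile_knots(x, basis_dim)
    else:
        knots = np.asarray(knots, dtype=float)
        if (np.diff(knots) <= 0).any():
            raise ValueError("knots must be strictly increasing")
    F, S = _crs_matrices(knots)
    basis = SplineBasis(knots=knots, F=F, S=S)
    return basis.design(np.asarray(x, dtype=float)), S, basis


def _constraint_null_basis(colmeans: np.ndarray) -> np.ndarray:
    """Orthonormal basis Z of the sum-to-zero constraint m' beta = 0."""
    return linalg.null_space(colmeans[None, :])


# ---------------------------------------------------------------------------
# fitted-model containers
# ---------------------------------------------------------------------------

@dataclass
class FittedTerm:
    name: str
    basis: str
    knots: np.ndarray | None     # None for linear terms
    F: np.ndarray | None
    S_constrained: np.ndarray    # penalty in the constrained parameterization
    Z: np.ndarray | None         # constraint null-space map (k x k-1)
    colmeans: np.ndarray         # training column means of the raw basis
    coef: np.ndarray             # constrained coefficients
    lam: float
    edf: float
    cols: slice                  # columns in the full design matrix

    @property
    def n_coef(self) -> int:
        return len(self.coef)

    def raw_design(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.basis == "linear":
            return x[:, None]
        return crs_design(x, self.knots, self.F)

    def design(self, x: np.ndarray) -> np.ndarray:
        X = self.raw_design(x)
        if self.Z is None:
            return X
        return X @ self.Z

    def value(self, x: np.ndarray) -> np.ndarray:
        """Term contribution on the log-odds scale."""
        return self.design(x) @ self.coef


@dataclass
class FittedGAM:
    """A fitted penalized binomial additive model.

    Holds everything needed to reproduce predictions: intercept, per-term
    knots / constraint maps / coefficients / smoothing parameters / EDFs,
    the coefficient covariance (Bayesian, scale 1), and training covariate
    summaries (mean, min, max) used for clamping and counterfactual null
    values.
    """

    intercept: float
    terms: list[FittedTerm]
    cov: np.ndarray                      # (1+q, 1+q) coefficient covariance
    training_summary: dict[str, dict]    # name -> {mean, min, max}
    n_train: int
    deviance: float
    null_deviance: float
    edf_total: float
    converged: bool
    n_iter: int
    lambda_rule: str
    train_positive_fraction: float
    meta: dict = field(default_factory=dict)

    def term(self, name: str) -> FittedTerm:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(f"model has no smooth term {name!r}")

    @property
    def term_names(self) -> list[str]:
        return [t.name for t in self.terms]

    # -- serialization -----------------------------------------------------
    def to_json_dict(self) -> dict:
        def arr(a):
            return None if a is None else np.asarray(a).tolist()
        return {
            "intercept": self.intercept,
            "terms": [
                {
                    "name": t.name, "basis": t.basis, "knots": arr(t.knots),
                    "F": arr(t.F), "S_constrained": arr(t.S_constrained),
                    "Z": arr(t.Z), "colmeans": arr(t.colmeans),
                    "coef": arr(t.coef), "lam": t.lam, "edf": t.edf,
                    "cols": [t.cols.start, t.cols.stop],
                }
                for t in self.terms
            ],
            "cov": arr(self.cov),
            "training_summary": self.training_summary,
            "n_train": self.n_train,
            "deviance": self.deviance,
            "null_deviance": self.null_deviance,
            "edf_total": self.edf_total,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "lambda_rule": self.lambda_rule,
            "train_positive_fraction": self.train_positive_fraction,
            "meta": self.meta,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json_dict(cls, d: dict) -> "FittedGAM":
        def arr(a):
            return None if a is None else np.asarray(a, dtype=float)
        terms = [
            FittedTerm(
                name=t["name"], basis=t["basis"], knots=arr(t["knots"]),
                F=arr(t["F"]), S_constrained=arr(t["S_constrained"]),
                Z=arr(t["Z"]), colmeans=arr(t["colmeans"]),
                coef=arr(t["coef"]), lam=t["lam"], edf=t["edf"],
                cols=slice(*t["cols"]),
            )
            for t in d["terms"]
        ]
        return cls(
            intercept=d["intercept"], terms=terms, cov=arr(d["cov"]),
            training_summary=d["training_summary"], n_train=d["n_train"],
            deviance=d["deviance"], null_deviance=d["null_deviance"],
            edf_total=d["edf_total"], converged=d["converged"],
            n_iter=d["n_iter"], lambda_rule=d["lambda_rule"],
            train_positive_fraction=d["train_positive_fraction"],
            meta=d.get("meta", {}),
        )

    @classmethod
    def from_json(cls, path) -> "FittedGAM":
        with open(path) as fh:
            return cls.from_json_dict(json.load(fh))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _binomial_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.sum(y * np.log(mu) + (1 - y) * np.log1p(-mu)))


def _assemble_design(records: pd.DataFrame, term_specs):
    """Build the full design matrix [1 | centered term blocks] and per-term
    constrained penalty blocks from training data."""
    n = len(records)
    blocks = [np.ones((n, 1))]
    penalties = []   # (cols, S_constrained)
    terms = []
    col = 1
    for spec in term_specs:
        x = records[spec.name].to_numpy(dtype=float)
        n_unique = len(np.unique(x))
        if spec.basis == "cr" and n_unique < spec.basis_dim:
            # degrade rather than fail on degenerate covariates (common in
            # small regional subsets): shrink the basis, fall back to a
            # linear term, or drop a constant column entirely
            if n_unique >= 3:
                spec = SmoothTermSpec(spec.name, n_unique, "cr")
            elif n_unique == 2:
                spec = SmoothTermSpec(spec.name, basis="linear")
            else:
                warnings.warn(f"covariate {spec.name!r} is constant in the "
                              "training data; term dropped", stacklevel=3)
                continue
            warnings.warn(f"covariate {spec.name!r} has {n_unique} distinct "
                          f"values; basis reduced", stacklevel=3)
        if spec.basis == "linear":
            Xt = x[:, None]
            m = np.zeros(1)
            Z = None
            Sc = np.zeros((1, 1))
            knots = F = None
        else:
            Xraw, S, basis = build_spline_basis(x, spec.basis_dim)
            m = Xraw.mean(axis=0)
            Z = _constraint_null_basis(m)
            Xt = (Xraw - 0.0) @ Z  # constrained columns; sum exactly n*m'Z=0
            Sc = Z.T @ S @ Z
            knots, F = basis.knots, basis.F
        q = Xt.shape[1]
        cols = slice(col, col + q)
        blocks.append(Xt)
        penalties.append((cols, Sc))
        terms.append(FittedTerm(
            name=spec.name, basis=spec.basis, knots=knots, F=F,
            S_constrained=Sc, Z=Z, colmeans=m, coef=np.zeros(q),
            lam=0.0, edf=float(q), cols=cols,
        ))
        col += q
    return np.hstack(blocks), penalties, terms


def _penalty_matrix(p, penalties, lams) -> np.ndarray:
    S = np.zeros((p, p))
    for (cols, Sc), lam in zip(penalties, lams):
        S[cols, cols] += lam * Sc
    return S


def _pirls(X, y, S_lam, beta0=None, ridge=0.0):
    """Penalized IRLS with step halving; returns (beta, mu, pen_dev, n_iter,
    converged, XtWX_at_solution)."""
    n, p = X.shape
    if beta0 is None:
        beta = np.zeros(p)
        ybar = float(np.clip(y.mean(), 1e-6, 1 - 1e-6))
        beta[0] = logit(ybar)
    else:
        beta = beta0.copy()
    R = S_lam + ridge * np.eye(p)

    def pen_dev(b, mu):
        return _binomial_deviance(y, mu) + float(b @ R @ b)

    eta = X @ beta
    mu = expit(eta)
    current = pen_dev(beta, mu)
    XtWX = None
    converged = False
    it = 0
    for it in range(1, MAX_PIRLS_ITER + 1):
        w = np.clip(mu * (1 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        Xw = X * w[:, None]
        XtWX = X.T @ Xw
        rhs = Xw.T @ z
        try:
            beta_new = linalg.solve(XtWX + R, rhs, assume_a="pos")
        except linalg.LinAlgError:
            beta_new = linalg.lstsq(XtWX + R, rhs)[0]
        # step halving guarantees the penalized deviance never increases
        step = beta_new - beta
        t = 1.0
        for _ in range(30):
            cand = beta + t * step
            mu_c = expit(X @ cand)
            new = pen_dev(cand, mu_c)
            if np.isfinite(new) and new <= current + 1e-12:
                break
            t /= 2.0
        else:
            break
        beta = beta + t * step
        eta = X @ beta
        mu = expit(eta)
        new = pen_dev(beta, mu)
        if abs(current - new) < DEVIANCE_RTOL * (abs(new) + 0.1):
            current = new
            converged = True
            break
        current = new
    w = np.clip(mu * (1 - mu), 1e-10, None)
    XtWX = X.T @ (X * w[:, None])
    return beta, mu, current, it, converged, XtWX


def _edf(XtWX, S_lam, ridge=0.0):
    p = XtWX.shape[0]
    A = XtWX + S_lam + ridge * np.eye(p)
    try:
        H = linalg.solve(A, XtWX, assume_a="pos")
    except linalg.LinAlgError:
        H = linalg.lstsq(A, XtWX)[0]
    return np.diag(H)


def fit_binomial_gam(
    records: pd.DataFrame,
    term_specs,
    lambda_rule="gcv",
    lambda_grid: np.ndarray | None = None,
    exclude_year: int | None = None,
) -> FittedGAM:
    """Fit the penalized binomial additive model.

    Parameters
    ----------
    records
        Design table with a binary ``burned`` column and one column per
        term covariate.  Both classes must be present.
    term_specs
        Iterable of :class:`SmoothTermSpec` (may be empty for an
        intercept-only model).
    lambda_rule
        ``"gcv"`` (default): one smoothing parameter shared across terms,
        chosen by generalized cross-validation on a log-spaced grid;
        ``"gcv_perterm"``: one GCV pass per term, coordinate-wise over the
        same grid; a float: that fixed lambda for every term; a sequence:
        fixed per-term lambdas.
    exclude_year
        If given, rows with ``year == exclude_year`` are dropped before
        fitting (the leave-one-year-out training mode, where each year of
        interest is predicted by a model trained on all other years).
    """
    if exclude_year is not None:
        records = records[records["year"] != exclude_year]
    if len(records) == 0:
        raise ValueError("no training records")
    y = records["burned"].to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("training data contain a single class; "
                         "a binomial model cannot be fitted")
    term_specs = list(term_specs)
    X, penalties, terms = _assemble_design(records, term_specs)
    n, p = X.shape
    grid = DEFAULT_LAMBDA_GRID if lambda_grid is None else np.asarray(lambda_grid)

    def fit_at(lams, beta0=None):
        S_lam = _penalty_matrix(p, penalties, lams)
        return S_lam, _pirls(X, y, S_lam, beta0=beta0)

    n_terms = len(terms)
    rule_name = lambda_rule if isinstance(lambda_rule, str) else "fixed"
    if n_terms == 0 or all(t.basis == "linear" for t in terms):
        lams = np.zeros(n_terms)
        rule_name = "none"
    elif isinstance(lambda_rule, str) and lambda_rule in ("gcv", "gcv_perterm"):
        best = (np.inf, None)
        beta0 = None
        for lam in grid:
            lams = np.full(n_terms, lam)
            S_lam, (beta, mu, pdev, *_rest) = fit_at(lams, beta0)
            beta0 = beta
            XtWX = _rest[-1]
            tau = float(_edf(XtWX, S_lam).sum())
            dev = _binomial_deviance(y, mu)
            gcv = n * dev / (n - tau) ** 2
            if gcv < best[0]:
                best = (gcv, lams)
        lams = best[1]
        if lambda_rule == "gcv_perterm":
            # one coordinate-wise refinement sweep over the shared-grid optimum
            lams = lams.copy()
            for j in range(n_terms):
                best_j = (np.inf, lams[j])
                for lam in grid:
                    trial = lams.copy()
                    trial[j] = lam
                    S_lam, (beta, mu, pdev, *_rest) = fit_at(trial)
                    XtWX = _rest[-1]
                    tau = float(_edf(XtWX, S_lam).sum())
                    gcv = n * _binomial_deviance(y, mu) / (n - tau) ** 2
                    if gcv < best_j[0]:
                        best_j = (gcv, lam)
                lams[j] = best_j[1]
    elif isinstance(lambda_rule, str):
        raise ValueError(f"unknown lambda_rule {lambda_rule!r}")
    else:
        lams = np.broadcast_to(np.asarray(lambda_rule, dtype=float),
                               (n_terms,)).copy()

    S_lam, (beta, mu, pdev, n_iter, converged, XtWX) = fit_at(lams)

    ridge = 0.0
    if np.abs(beta).max() > 1e3 or not np.isfinite(beta).all():
        warnings.warn(
            "coefficients diverged (possible perfect separation); "
            "refitting with a small ridge penalty",
            PerfectSeparationWarning, stacklevel=2)
        ridge = 1e-4
        S_ridge = S_lam + ridge * np.eye(p)
        beta, mu, pdev, n_iter, converged, XtWX = _pirls(X, y, S_lam,
                                                         ridge=ridge)
        S_lam = S_ridge - ridge * np.eye(p)  # keep S_lam as pure penalty

    edf_diag = _edf(XtWX, S_lam, ridge=ridge)
    A = XtWX + S_lam + ridge * np.eye(p)
    try:
        cov = linalg.inv(A)
    except linalg.LinAlgError:
        cov = linalg.pinv(A)

    for t, lam in zip(terms, lams):
        t.coef = beta[t.cols]
        t.lam = float(lam)
        t.edf = float(edf_diag[t.cols].sum())

    summary = {}
    for name in dict.fromkeys(s.name for s in term_specs):
        xcol = records[name].to_numpy(dtype=float)
        summary[name] = {"mean": float(xcol.mean()),
                         "min": float(xcol.min()),
                         "max": float(xcol.max())}

    dev = _binomial_deviance(y, mu)
    ybar = float(y.mean())
    null_dev = _binomial_deviance(y, np.full_like(y, ybar))
    return FittedGAM(
        intercept=float(beta[0]),
        terms=terms,
        cov=cov,
        training_summary=summary,
        n_train=n,
        deviance=dev,
        null_deviance=null_dev,
        edf_total=float(edf_diag.sum()),
        converged=converged,
        n_iter=n_iter,
        lambda_rule=rule_name,
        train_positive_fraction=ybar,
        meta={"excluded_year": exclude_year, "ridge": ridge},
    )


def fit_leave_one_year_out(
    records: pd.DataFrame, term_specs, years=None, **kwargs
) -> dict[int, FittedGAM]:
    """One model per year of interest, trained on all other years."""
    if years is None:
        years = sorted(records["year"].unique())
    return {
        int(yy): fit_binomial_gam(records, term_specs,
                                  exclude_year=int(yy), **kwargs)
        for yy in years
    }


# ---------------------------------------------------------------------------
# prediction and interrogation
# ---------------------------------------------------------------------------

def _clamped(model: FittedGAM, name: str, x: np.ndarray) -> np.ndarray:
    s = model.training_summary[name]
    return np.clip(np.asarray(x, dtype=float), s["min"], s["max"])


def predict_linear(model: FittedGAM, records: pd.DataFrame) -> np.ndarray:
    """Linear predictor (log-odds); covariates clamped to training range."""
    eta = np.full(len(records), model.intercept)
    for t in model.terms:
        if t.name not in records.columns:
            raise KeyError(f"record table lacks model covariate {t.name!r}")
        x = _clamped(model, t.name, records[t.name].to_numpy(dtype=float))
        eta += t.value(x)
    return eta


def predict_probability(model: FittedGAM, records: pd.DataFrame) -> np.ndarray:
    """invlogit(intercept + sum of smooth contributions), in (0, 1)."""
    return expit(predict_linear(model, records))


def partial_effect(
    model: FittedGAM, term_name: str, x_grid: np.ndarray
) -> pd.DataFrame:
    """Centered smooth contribution of one term on the log-odds scale.

    Returns a frame with the evaluation grid, the effect, its pointwise
    standard error from the coefficient covariance, and a flag marking grid
    points outside the training span (evaluated under the clamping rule).
    """
    t = model.term(term_name)
    x_grid = np.asarray(x_grid, dtype=float)
    s = model.training_summary[term_name]
    out_of_range = (x_grid < s["min"]) | (x_grid > s["max"])
    C = t.design(_clamped(model, term_name, x_grid))
    eff = C @ t.coef
    Vt = model.cov[t.cols, t.cols]
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", C, Vt, C), 0.0))
    return pd.DataFrame({"x": x_grid, "effect": eff, "se": se,
                         "clamped": out_of_range})


def coefficient_surface(
    model: FittedGAM, term_name: str, covariate_raster: np.ndarray
) -> np.ndarray:
    """Per-pixel partial-effect (log-odds contribution) of one term.

    NaN cells in the input stay NaN in the output.
    """
    t = model.term(term_name)
    raster = np.asarray(covariate_raster, dtype=float)
    out = np.full(raster.shape, np.nan)
    ok = np.isfinite(raster)
    x = _clamped(model, term_name, raster[ok])
    out[ok] = t.value(x)
    return out


def term_significance(model: FittedGAM) -> pd.DataFrame:
    """Approximate Wald chi-squared test per smooth term.

    The statistic is coef' V^-1 coef on the term's coefficient block with
    the EDF (rounded up) as reference degrees of freedom.  These p-values
    are approximate — penalized estimation makes the reference distribution
    only an approximation — and are labeled accordingly.
    """
    rows = []
    for t in model.terms:
        Vt = model.cov[t.cols, t.cols]
        try:
            stat = float(t.coef @ linalg.solve(Vt, t.coef, assume_a="pos"))
        except linalg.LinAlgError:
            stat = float(t.coef @ linalg.pinv(Vt) @ t.coef)
        df = max(t.edf, 1e-6)
        rows.append({"term": t.name, "edf": t.edf, "ref_df": t.n_coef,
                     "chi_sq": stat,
                     "p_value_approx": float(chi2.sf(stat, df))})
    return pd.DataFrame(rows)
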