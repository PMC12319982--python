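"""Developmental trajectory models for microstate features.

Each feature (e.g. the duration of one microstate class) is regressed on
age, sex and retained-segment count with a Gaussian random intercept per
subject:

    y_ij = x_ij' b + u_i + e_ij,   u_i ~ N(0, s_u^2),  e_ij ~ N(0, s_e^2)

fitted by maximum likelihood: the marginal log-likelihood is profiled over
the variance ratio lambda = s_u^2 / s_e^2, with generalized-least-squares
fixed effects and the residual variance in closed form at each candidate
ratio.  Age enters linearly, with at most one added nonlinear term —
quadratic (raw months squared) or natural-log months.  The three candidate
age models are compared by BIC; a nonlinear model is adopted only with
strong support (the linear model's BIC exceeding it by at least 6 points),
and between two qualifying nonlinear models the lower BIC wins.  Predictor
importance is summarized by Cohen's f^2 from full-versus-reduced marginal
R^2, with the conventional 0.02 / 0.15 / 0.35 small/medium/large cutoffs.

Wald z statistics are used for fixed-effect p-values; BIC counts the fixed
effects plus the two variance parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io_ingest import FeatureTable, ValidationError

__all__ = [
    "ModelSpec",
    "TrajectoryFit",
    "design_matrix",
    "fit_random_intercept_lmm",
    "select_age_model",
    "effect_sizes",
    "f2_category",
]

AGE_MODELS = ("linear", "quadratic", "log")


@dataclass
class ModelSpec:
    """One candidate trajectory model for a (feature, class) response."""

    feature: str = "duration"
    class_label: str = "A"
    age_model: Literal["linear", "quadratic", "log"] = "linear"
    include_sex: bool = True
    include_segments: bool = True
    center_age: bool = False

    def __post_init__(self) -> None:
        if self.age_model not in AGE_MODELS:
            raise ValidationError(f"unknown age model {self.age_model!r}")

    @property
    def predictor_names(self) -> list[str]:
        names = ["intercept", "age"]
        if self.age_model == "quadratic":
            names.append("age_sq")
        elif self.age_model == "log":
            names.append("log_age")
        if self.include_sex:
            names.append("sex")
        if self.include_segments:
            names.append("segments")
        return names


@dataclass
class TrajectoryFit:
    """Fitted random-intercept mixed model."""

    spec: ModelSpec
    beta: pd.DataFrame  # index: predictor; columns: estimate, se, z, p
    sigma_u2: float
    sigma_e2: float
    loglik: float
    bic: float
    n_obs: int
    n_subjects: int
    n_params: int
    marginal_r2: float
    f2: dict[str, float] = field(default_factory=dict)
    boundary: bool = False  # sigma_u2 clamped at zero

    def __post_init__(self) -> None:
        if self.sigma_u2 < 0 or self.sigma_e2 <= 0:
            raise ValidationError("variance components out of range")


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------

def design_matrix(table: FeatureTable, spec: ModelSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Extract (X, y, groups) for one (feature, class) response.

    Rows are (subject, visit) observations of the chosen feature; ``groups``
    are integer subject codes for the random intercept.
    """
    df = table.df
    sub = df[(df["feature"] == spec.feature) & (df["class"] == spec.class_label)]
    if len(sub) == 0:
        raise ValidationError(
            f"no observations for feature={spec.feature!r} class={spec.class_label!r}"
        )
    age = sub["age_months"].astype(float).to_numpy()
    if spec.center_age:
        age = age - age.mean()
    cols = [np.ones(len(sub)), age]
    if spec.age_model == "quadratic":
        cols.append(age**2)
    elif spec.age_model == "log":
        raw = sub["age_months"].astype(float).to_numpy()
        cols.append(np.log(raw))
    if spec.include_sex:
        cols.append(sub["sex"].astype(float).to_numpy())
    if spec.include_segments:
        cols.append(sub["retained_segments"].astype(float).to_numpy())
    X = np.column_stack(cols)
    y = sub["value"].astype(float).to_numpy()
    groups = pd.Categorical(sub["subject"]).codes.astype(np.int64)
    return X, y, groups


# ---------------------------------------------------------------------------
# Profiled maximum likelihood
# ---------------------------------------------------------------------------

def _group_slices(groups: np.ndarray) -> list[np.ndarray]:
    order = np.argsort(groups, kind="stable")
    sorted_groups = groups[order]
    bounds = np.flatnonzero(np.diff(sorted_groups)) + 1
    return [order[s] for s in np.split(np.arange(len(groups)), bounds)]


def _profile_ml(X: np.ndarray, y: np.ndarray, idx: list[np.ndarray], lam: float):
    """GLS at variance ratio lam = s_u^2/s_e^2; returns (-2 profiled ll, parts).

    With Sigma_i = s_e^2 (I + lam J), (I + lam J)^{-1} = I - lam/(1+lam m) J,
    so the whittened cross-products reduce to per-group mean corrections.
    """
    N, p = X.shape
    XtX = np.zeros((p, p))
    Xty = np.zeros(p)
    yty = 0.0
    logdet = 0.0
    for rows in idx:
        m = len(rows)
        Xi, yi = X[rows], y[rows]
        c = lam / (1.0 + lam * m)
        xs, ys = Xi.sum(axis=0), yi.sum()
        XtX += Xi.T @ Xi - c * np.outer(xs, xs)
        Xty += Xi.T @ yi - c * xs * ys
        yty += yi @ yi - c * ys * ys
        logdet += np.log1p(lam * m)
    beta = np.linalg.solve(XtX, Xty)
    rss = yty - Xty @ beta  # whittened residual sum of squares
    rss = max(rss, 1e-300)
    sigma_e2 = rss / N
    ll = -0.5 * (N * np.log(2 * np.pi * sigma_e2) + logdet + N)
    return ll, beta, sigma_e2, XtX, logdet


def fit_random_intercept_lmm(table: FeatureTable, spec: ModelSpec) -> TrajectoryFit:
    """ML fit of a random-intercept linear mixed model.

    The marginal Gaussian likelihood (block covariance s_u^2 J + s_e^2 I
    per subject) is maximized by a 1-D search over the variance ratio, with
    GLS fixed effects and closed-form residual variance profiled out.  When
    the optimum sits at the boundary the random-intercept variance is
    clamped to zero (ordinary least squares) with a warning flag.  Standard
    errors are Wald, p-values normal-theory.
    """
    X, y, groups = design_matrix(table, spec)
    names = spec.predictor_names
    N, p = X.shape
    if len(np.unique(groups)) < 2:
        raise ValidationError("need >= 2 subjects")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # name the collinear columns via QR pivoting on the correlation structure
        _, R = np.linalg.qr(X)
        bad = [names[j] for j in range(p) if abs(R[j, j]) < 1e-8 * abs(R[0, 0])]
        raise ValidationError(f"rank-deficient design matrix; suspect columns: {bad or names}")
    idx = _group_slices(groups)

    def neg_ll(log_lam: float) -> float:
        return -_profile_ml(X, y, idx, np.exp(log_lam))[0]

    res = optimize.minimize_scalar(neg_ll, bounds=(-12.0, 12.0), method="bounded",
                                   options={"xatol": 1e-10})
    lam = float(np.exp(res.x))
    ll, beta, sigma_e2, XtX, _ = _profile_ml(X, y, idx, lam)
    ll0, beta0, sigma_e20, XtX0, _ = _profile_ml(X, y, idx, 0.0)
    boundary = False
    if ll0 >= ll:  # boundary optimum: no between-subject variance
        lam, ll, beta, sigma_e2, XtX = 0.0, ll0, beta0, sigma_e20, XtX0
        boundary = True
    sigma_u2 = lam * sigma_e2
    cov_beta = sigma_e2 * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov_beta))
    z = beta / se
    pvals = 2 * stats.norm.sf(np.abs(z))
    n_params = p + 2
    bic = -2.0 * ll + n_params * np.log(N)
    fitted_fixed = X @ beta
    var_fixed = float(np.var(fitted_fixed))
    marginal_r2 = var_fixed / (var_fixed + sigma_u2 + sigma_e2)
    beta_df = pd.DataFrame(
        {"estimate": beta, "se": se, "z": z, "p": pvals}, index=names
    )
    return TrajectoryFit(
        spec=spec,
        beta=beta_df,
        sigma_u2=float(sigma_u2),
        sigma_e2=float(sigma_e2),
        loglik=float(ll),
        bic=float(bic),
        n_obs=N,
        n_subjects=len(idx),
        n_params=n_params,
        marginal_r2=float(marginal_r2),
        boundary=boundary,
    )


# ---------------------------------------------------------------------------
# Model selection and effect sizes
# ---------------------------------------------------------------------------

@dataclass
class AgeModelSelection:
    selected: str
    bic: dict[str, float]
    delta: float
    fits: dict[str, TrajectoryFit]


def select_age_model(
    fits: dict[str, TrajectoryFit], delta: float = 6.0
) -> AgeModelSelection:
    """Choose among linear / linear+quadratic / linear+log age models by BIC.

    A nonlinear model is selected only if it beats the linear model's BIC by
    at least ``delta`` points (inclusive); if both nonlinear models qualify
    the lower BIC wins; otherwise the linear model is retained.
    """
    missing = set(AGE_MODELS) - set(fits)
    if missing:
        raise ValidationError(f"need fits for all of {AGE_MODELS}; missing {sorted(missing)}")
    n_obs = {m: fits[m].n_obs for m in AGE_MODELS}
    if len(set(n_obs.values())) != 1:
        raise ValidationError(f"fits computed on different observation sets: {n_obs}")
    bic = {m: fits[m].bic for m in AGE_MODELS}
    qualifying = [m for m in ("quadratic", "log") if bic["linear"] - bic[m] >= delta]
    if not qualifying:
        selected = "linear"
    else:
        selected = min(qualifying, key=lambda m: bic[m])
    return AgeModelSelection(selected=selected, bic=bic, delta=delta, fits=fits)


def f2_category(f2: float) -> str:
    """Cohen's f² magnitude label at the 0.02 / 0.15 / 0.35 cutoffs."""
    if f2 >= 0.35:
        return "large"
    if f2 >= 0.15:
        return "medium"
    if f2 >= 0.02:
        return "small"
    return "negligible"


def _drop_predictor(spec: ModelSpec, name: str) -> ModelSpec | None:
    if name == "sex":
        return ModelSpec(**{**spec.__dict__, "include_sex": False})
    if name == "segments":
        return ModelSpec(**{**spec.__dict__, "include_segments": False})
    if name in ("age_sq", "log_age"):
        return ModelSpec(**{**spec.__dict__, "age_model": "linear"})
    if name == "age":
        return None  # handled via a custom design below
    return None


def effect_sizes(table: FeatureTable, fit_full: TrajectoryFit) -> dict[str, float]:
    """Cohen's f² per predictor from full-vs-reduced marginal-R² refits.

    f² = (R²_full − R²_reduced) / (1 − R²_full), with marginal R² =
    var(Xβ̂) / (var(Xβ̂) + σ_u² + σ_e²).  Every reduced model keeps the
    random-intercept structure and observation set of the full model;
    dropping "age" removes the linear term while retaining any nonlinear
    term, mirroring per-coefficient effect sizes in trajectory tables.
    """
    r2_full = fit_full.marginal_r2
    if r2_full >= 1.0:
        raise ValidationError("degenerate fit: marginal R² = 1")
    spec = fit_full.spec
    out: dict[str, float] = {}
    for name in fit_full.beta.index:
        if name == "intercept":
            continue
        reduced_spec = _drop_predictor(spec, name)
        if reduced_spec is not None:
            fit_red = fit_random_intercept_lmm(table, reduced_spec)
        else:
            fit_red = _fit_without_column(table, spec, name)
        f2 = (r2_full - fit_red.marginal_r2) / (1.0 - r2_full)
        out[name] = float(max(f2, 0.0) if abs(f2) < 1e-12 else f2)
    fit_full.f2 = out
    return out


def _fit_without_column(table: FeatureTable, spec: ModelSpec, name: str) -> TrajectoryFit:
    """Refit with one design column removed (for terms without a spec flag)."""
    X, y, groups = design_matrix(table, spec)
    names = spec.predictor_names
    j = names.index(name)
    Xr = np.delete(X, j, axis=1)
    idx = _group_slices(groups)

    def neg_ll(log_lam: float) -> float:
        return -_profile_ml(Xr, y, idx, np.exp(log_lam))[0]

    res = optimize.minimize_scalar(neg_ll, bounds=(-12.0, 12.0), method="bounded",
                                   options={"xatol": 1e-10})
    lam = float(np.exp(res.x))
    ll, beta, sigma_e2, XtX, _ = _profile_ml(Xr, y, idx, lam)
    ll0, beta0, sigma_e20, XtX0, _ = _profile_ml(Xr, y, idx, 0.0)
    if ll0 >= ll:
        lam, ll, beta, sigma_e2, XtX = 0.0, ll0, beta0, sigma_e20, XtX0
    sigma_u2 = lam * sigma_e2
    fitted = Xr @ beta
    var_fixed = float(np.var(fitted))
    r2 = var_fixed / (var_fixed + sigma_u2 + sigma_e2)
    reduced_names = [n for n in names if n != name]
    cov_beta = sigma_e2 * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov_beta))
    return TrajectoryFit(
        spec=spec,
        beta=pd.DataFrame({"estimate": beta, "se": se, "z": beta / se,
                           "p": 2 * stats.norm.sf(np.abs(beta / se))}, index=reduced_names),
        sigma_u2=float(sigma_u2),
        sigma_e2=float(sigma_e2),
        loglik=float(ll),
        bic=float(-2 * ll + (Xr.shape[1] + 2) * np.log(len(y))),
        n_obs=len(y),
        n_subjects=len(idx),
        n_params=Xr.shape[1] + 2,
        marginal_r2=float(r2),
    )
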