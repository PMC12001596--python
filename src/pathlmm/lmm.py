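"""Gaussian linear mixed model with a single random intercept per individual.

The model for a response vector ``a`` (a pathway score column or a raw
metabolite) is

    a = beta_t + theta_d + u_i + eps,   u_i ~ N(0, sigma_u^2),
                                        eps ~ N(0, sigma_e^2) iid,

with categorical fixed effects for time and condition and one random
intercept per individual to absorb the correlation between repeated
measurements.  Fixed effects are tested by the likelihood ratio of the
full model against the model without that effect, referred to a
chi-square with df = (number of levels - 1).

Fitting is by maximum likelihood (not REML): likelihoods of models with
different fixed-effect structures are only comparable under ML.  For one
random intercept the likelihood can be profiled analytically down to a
one-dimensional function of the variance ratio lambda = sigma_u^2 /
sigma_e^2: given lambda, V is block diagonal with blocks I + lambda*J,
whose inverse and determinant are closed-form, so the GLS coefficients
and the residual variance maximize out exactly.  The remaining scalar
optimization is a coarse grid over log(lambda) (including the lambda = 0
boundary) refined by bounded Brent search — deterministic and fast.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

_LOG_LAMBDA_GRID = np.linspace(-12.0, 12.0, 25)
_LOGLIK_TOL = 1e-8


@dataclass
class MixedModelFit:
    fixed_effects: tuple[str, ...]
    coefficients: pd.Series
    re_variance: float           # Var(u_i)
    resid_variance: float        # sigma_e^2
    loglik: float                # ML log-likelihood
    n_params: int                # free parameters (fixed + 2 variances)
    converged: bool
    n_obs: int = 0
    dropped_factors: tuple[str, ...] = field(default_factory=tuple)


@dataclass
class LRTResult:
    stat: float
    df: int
    pvalue: float
    effect: str


def design_matrix(
    design: pd.DataFrame, fixed: tuple[str, ...] | list[str] | set[str]
) -> tuple[np.ndarray, list[str], list[str]]:
    """Treatment-coded design matrix: intercept + (levels-1) dummies per factor.

    Factors with a single observed level carry no information and are
    dropped with a warning; their names are returned so the caller can
    account for them.
    """
    cols: list[np.ndarray] = [np.ones(len(design))]
    names: list[str] = ["Intercept"]
    dropped: list[str] = []
    for factor in ("time", "condition"):
        if factor not in fixed:
            continue
        vals = design[factor]
        if isinstance(vals.dtype, pd.CategoricalDtype):
            levels = [l for l in vals.cat.categories if (vals == l).any()]
        else:
            levels = sorted(pd.unique(vals.astype(str)))
            vals = vals.astype(str)
        if len(levels) < 2:
            logger.warning("factor '%s' has a single level; dropped", factor)
            dropped.append(factor)
            continue
        for level in levels[1:]:
            cols.append((vals == level).to_numpy(dtype=float))
            names.append(f"{factor}[{level}]")
    X = np.column_stack(cols)
    return X, names, dropped


def _profile_loglik(
    lam: float,
    y: np.ndarray,
    X: np.ndarray,
    group_idx: np.ndarray,
    group_sizes: np.ndarray,
) -> tuple[float, np.ndarray, float, float]:
    """ML log-likelihood profiled over beta and sigma_e^2 at fixed lambda.

    Returns (loglik, beta_hat, sigma_e^2_hat, sigma_u^2_hat).
    """
    N, p = X.shape
    n_groups = group_sizes.shape[0]
    c = lam / (1.0 + lam * group_sizes)          # (n_groups,)

    # group sums of X columns and of y
    Sx = np.zeros((n_groups, p))
    np.add.at(Sx, group_idx, X)
    Sy = np.zeros(n_groups)
    np.add.at(Sy, group_idx, y)

    XtVX = X.T @ X - (Sx * c[:, None]).T @ Sx
    XtVy = X.T @ y - Sx.T @ (c * Sy)
    beta, *_ = np.linalg.lstsq(XtVX, XtVy, rcond=None)

    r = y - X @ beta
    Sr = np.zeros(n_groups)
    np.add.at(Sr, group_idx, r)
    rss_v = float(r @ r - c @ Sr**2)
    if rss_v <= 0:
        return -np.inf, beta, 0.0, 0.0
    sigma_e2 = rss_v / N
    logdet = float(np.sum(np.log1p(lam * group_sizes)))
    ll = -0.5 * (N * (np.log(2 * np.pi * sigma_e2) + 1.0) + logdet)
    return ll, beta, sigma_e2, lam * sigma_e2


def fit_lmm(
    a: np.ndarray | pd.Series,
    design: pd.DataFrame,
    fixed: tuple[str, ...] | list[str] | set[str] = ("time", "condition"),
) -> MixedModelFit:
    """ML fit of the random-intercept model for response ``a``.

    ``design`` must be row-aligned with ``a`` and carry ``individual``,
    ``time`` and ``condition`` columns.
    """
    y = np.asarray(a, dtype=float)
    if y.shape[0] != len(design):
        raise ValueError("response length does not match design rows")
    if design["individual"].nunique() < 2:
        raise ValueError("need at least 2 individuals")
    fixed = tuple(f for f in ("time", "condition") if f in set(fixed))

    X, names, dropped = design_matrix(design, fixed)

    groups, group_labels = pd.factorize(design["individual"])
    group_sizes = np.bincount(groups).astype(float)

    if float(np.var(y)) < 1e-300:
        # degenerate response: likelihood unbounded, nothing to test
        logger.warning("constant response; returning degenerate fit")
        return MixedModelFit(
            fixed_effects=fixed,
            coefficients=pd.Series(np.zeros(X.shape[1]), index=names),
            re_variance=0.0,
            resid_variance=0.0,
            loglik=np.nan,
            n_params=X.shape[1] + 2,
            converged=False,
            n_obs=y.shape[0],
            dropped_factors=tuple(dropped),
        )

    def neg_ll_logscale(t: float) -> float:
        return -_profile_loglik(np.exp(t), y, X, groups, group_sizes)[0]

    # boundary lambda = 0 plus a coarse grid over log(lambda), then refine
    ll0 = _profile_loglik(0.0, y, X, groups, group_sizes)[0]
    grid_ll = np.array([-neg_ll_logscale(t) for t in _LOG_LAMBDA_GRID])
    best = int(np.argmax(grid_ll))
    if grid_ll[best] <= ll0 + _LOGLIK_TOL:
        lam_hat, ll_hat = 0.0, ll0
    else:
        lo = _LOG_LAMBDA_GRID[max(best - 1, 0)]
        hi = _LOG_LAMBDA_GRID[min(best + 1, len(_LOG_LAMBDA_GRID) - 1)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = optimize.minimize_scalar(
                neg_ll_logscale, bounds=(lo, hi), method="bounded",
                options={"xatol": 1e-10},
            )
        lam_hat, ll_hat = float(np.exp(res.x)), -float(res.fun)
        if ll0 >= ll_hat:  # boundary still wins
            lam_hat, ll_hat = 0.0, ll0

    ll, beta, sigma_e2, sigma_u2 = _profile_loglik(
        lam_hat, y, X, groups, group_sizes
    )
    return MixedModelFit(
        fixed_effects=fixed,
        coefficients=pd.Series(beta, index=names),
        re_variance=sigma_u2,
        resid_variance=sigma_e2,
        loglik=ll,
        n_params=X.shape[1] + 2,
        converged=np.isfinite(ll),
        n_obs=y.shape[0],
        dropped_factors=tuple(dropped),
    )


def lrt_effect(
    a: np.ndarray | pd.Series,
    design: pd.DataFrame,
    full: tuple[str, ...] | list[str] | set[str],
    dropped: str,
) -> LRTResult:
    """Likelihood-ratio test of one fixed effect against the full model."""
    full = tuple(f for f in ("time", "condition") if f in set(full))
    if dropped not in full:
        raise ValueError(f"effect '{dropped}' not in full model {full}")
    restricted = tuple(f for f in full if f != dropped)

    fit_full = fit_lmm(a, design, full)
    fit_rest = fit_lmm(a, design, restricted)

    vals = design[dropped]
    if isinstance(vals.dtype, pd.CategoricalDtype):
        n_levels = sum((vals == l).any() for l in vals.cat.categories)
    else:
        n_levels = vals.nunique()
    df = int(n_levels) - 1

    if not (fit_full.converged and fit_rest.converged):
        logger.warning("unconverged fit in LRT for '%s'; p = NA", dropped)
        return LRTResult(np.nan, max(df, 0), np.nan, dropped)
    if df <= 0 or dropped in fit_full.dropped_factors:
        # the factor carried no information: full == restricted
        return LRTResult(0.0, 0, 1.0, dropped)

    stat = 2.0 * (fit_full.loglik - fit_rest.loglik)
    stat = max(stat, 0.0)  # clip optimizer-tolerance negatives
    pvalue = float(stats.chi2.sf(stat, df))
    return LRTResult(float(stat), df, pvalue, dropped)
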