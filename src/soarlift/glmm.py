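"""Mixed models linking soaring modes to uplift, with Nakagawa R-squared.

Two model families are provided:

* :func:`fit_binomial_glmm` — a logistic mixed model for soaring mode
  (circular or linear soaring = 1 vs gliding = 0) on thermal and orographic
  uplift velocity, with crossed random intercepts for bird identity and day
  of data collection.  Estimation is maximum likelihood with the Laplace
  approximation: for candidate variance components the fixed effects and
  the spherical random effects are jointly maximized by Newton iterations,
  and the profiled Laplace log-likelihood is optimized over the variance
  components.
* :func:`fit_gaussian_lmm` — a Gaussian mixed model comparing a flight
  parameter between the two soaring modes, with the same crossed random
  intercepts (fitted by REML via :mod:`statsmodels`).

Goodness of fit is summarized by the marginal and conditional R-squared of
Nakagawa & Schielzeth: the variance of the fixed-effect linear predictor
over the data, relative to the total of fixed, random-intercept and residual
variances (pi^2 / 3 on the logit scale).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .modes import CIRCULAR, GLIDING, LINEAR
from .raster import RasterGrid

__all__ = [
    "GLMMFit",
    "build_observations",
    "exclude_extreme_uplift",
    "fit_binomial_glmm",
    "fit_gaussian_lmm",
    "r2_nakagawa",
]

LOGIT_RESIDUAL_VARIANCE = math.pi ** 2 / 3


class SeparationError(RuntimeError):
    """The binomial response is degenerate or perfectly separable."""


@dataclass
class GLMMFit:
    """Fixed-effect table and variance components of a fitted mixed model."""

    terms: list[str]
    estimates: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    vc_bird: float
    vc_day: float
    loglik: float
    converged: bool
    n_obs: int
    distribution: str                 # "binomial" | "gaussian"
    var_fixed: float                  # variance of the fixed linear predictor
    sigma2_resid: float               # residual variance (pi^2/3 for logit)
    r2_marginal: float = field(default=float("nan"))
    r2_conditional: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        m, c = r2_nakagawa(self, _allow_unconverged=True)
        self.r2_marginal, self.r2_conditional = m, c

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"term": self.terms, "estimate": self.estimates,
                             "se": self.se, "z": self.z, "p": self.p})


# ----------------------------------------------------------------------
# observation table

def build_observations(labelled: pd.DataFrame, w0: RasterGrid,
                       w_star: RasterGrid) -> pd.DataFrame:
    """Annotate classified segments with uplift sampled at their centroids.

    Takes a classified segment table (``mode``, ``centroid_x``,
    ``centroid_y``, ``bird_id``, ``day``), drops excluded segments, and
    samples the orographic and thermal uplift rasters at each segment
    centroid by the nearest-cell rule.  The two rasters may differ in
    resolution; each is sampled on its own grid.
    """
    keep = labelled[labelled["mode"].isin([GLIDING, CIRCULAR, LINEAR])].copy()
    pts = keep[["centroid_x", "centroid_y"]].to_numpy(float)
    keep["orographic_uplift_ms"] = w0.sample(pts)
    keep["thermal_uplift_ms"] = w_star.sample(pts)
    return keep.reset_index(drop=True)


def exclude_extreme_uplift(table: pd.DataFrame, threshold_ms: float
                           ) -> tuple[pd.DataFrame, int]:
    """Drop observations whose orographic uplift exceeds ``threshold_ms``.

    Extreme orographic uplift values are rare, high-leverage points that can
    break GLMM convergence.  Returns the filtered table and the number of
    rows removed.
    """
    bad = table["orographic_uplift_ms"] > threshold_ms
    return table[~bad].reset_index(drop=True), int(bad.sum())


# ----------------------------------------------------------------------
# Laplace-approximated binomial GLMM

def _design(table: pd.DataFrame, fixed: list[str]):
    X = np.column_stack([np.ones(len(table))] +
                        [table[c].to_numpy(float) for c in fixed])
    bird = pd.Categorical(table["bird_id"]).codes
    day = pd.Categorical(table["day"]).codes
    return X, bird.astype(int), day.astype(int)


def _joint_mode(y, X, bird, day, sig_b, sig_d, max_iter=100, tol=1e-10):
    """Newton maximization of the penalized joint log-likelihood.

    Random effects are parametrized spherically, ``u = sigma * v`` with
    ``v ~ N(0, I)``, so the variance-zero boundary is regular.  Returns the
    joint mode, the penalized objective, and the blocks of the joint
    negative Hessian needed for the Laplace correction and the fixed-effect
    covariance.
    """
    n, p = X.shape
    nb, nd = bird.max() + 1, day.max() + 1
    q = nb + nd
    Zb = np.zeros((n, nb))
    Zb[np.arange(n), bird] = sig_b
    Zd = np.zeros((n, nd))
    Zd[np.arange(n), day] = sig_d
    C = np.column_stack([X, Zb, Zd])          # n x (p + q)
    delta = np.zeros(p + q)

    def objective(d):
        eta = C @ d
        return float(np.sum(y * eta - np.logaddexp(0, eta)) - 0.5 * d[p:] @ d[p:])

    f = objective(delta)
    for _ in range(max_iter):
        eta = C @ delta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        grad = C.T @ (y - mu)
        grad[p:] -= delta[p:]
        H = (C.T * w) @ C
        H[p:, p:] += np.eye(q)
        step = np.linalg.solve(H, grad)
        # step-halving keeps Newton ascending
        t = 1.0
        for _ in range(40):
            cand = delta + t * step
            fc = objective(cand)
            if fc >= f - 1e-12:
                break
            t /= 2
        delta, f_new = cand, fc
        if abs(f_new - f) < tol * (abs(f) + 1):
            f = f_new
            break
        f = f_new
    eta = C @ delta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1 - mu)
    H = (C.T * w) @ C
    H[p:, p:] += np.eye(q)
    return delta, f, H, C


def _joint_hessian(y, X, bird, day, sig_b, sig_d, beta, v):
    """Negative Hessian of the joint penalized log-likelihood at (beta, v)."""
    n, p = X.shape
    nb, nd = bird.max() + 1, day.max() + 1
    q = nb + nd
    Z = np.zeros((n, q))
    Z[np.arange(n), bird] = sig_b
    Z[np.arange(n), nb + day] = sig_d
    C = np.column_stack([X, Z])
    eta = X @ beta + Z @ v
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1 - mu)
    H = (C.T * w) @ C
    H[p:, p:] += np.eye(q)
    return H


def _laplace_profile_beta(y, X, bird, day, sig_b, sig_d):
    """Laplace log-likelihood with beta profiled at the joint mode."""
    p = X.shape[1]
    delta, f, H, _ = _joint_mode(y, X, bird, day, sig_b, sig_d)
    sign, logdet = np.linalg.slogdet(H[p:, p:])
    if sign <= 0:
        return -np.inf, delta, H
    return f - 0.5 * logdet, delta, H


def _laplace_loglik(y, X, bird, day, sig_b, sig_d, beta,
                    max_iter=100, tol=1e-11):
    """Laplace log-likelihood at fixed (variances, beta); only the spherical
    random effects are profiled, as in the Laplace stage of lme4's glmer."""
    n = X.shape[0]
    nb, nd = bird.max() + 1, day.max() + 1
    q = nb + nd
    Z = np.zeros((n, q))
    Z[np.arange(n), bird] = sig_b
    Z[np.arange(n), nb + day] = sig_d
    off = X @ beta
    v = np.zeros(q)

    def objective(vv):
        eta = off + Z @ vv
        return float(np.sum(y * eta - np.logaddexp(0, eta)) - 0.5 * vv @ vv)

    f = objective(v)
    for _ in range(max_iter):
        eta = off + Z @ v
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        grad = Z.T @ (y - mu) - v
        H = (Z.T * w) @ Z + np.eye(q)
        step = np.linalg.solve(H, grad)
        t = 1.0
        for _ in range(40):
            cand = v + t * step
            fc = objective(cand)
            if fc >= f - 1e-12:
                break
            t /= 2
        v, f_new = cand, fc
        if abs(f_new - f) < tol * (abs(f) + 1):
            f = f_new
            break
        f = f_new
    eta = off + Z @ v
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1 - mu)
    H = (Z.T * w) @ Z + np.eye(q)
    sign, logdet = np.linalg.slogdet(H)
    if sign <= 0:
        return -np.inf, v
    return f - 0.5 * logdet, v


def fit_binomial_glmm(table: pd.DataFrame, response_mode: str = "linear",
                      fixed: list[str] | None = None,
                      fix_variances: tuple[float, float] | None = None
                      ) -> GLMMFit:
    """Binomial GLMM of soaring mode on uplift with crossed random intercepts.

    ``response_mode`` selects which soaring mode is contrasted with gliding:
    ``"linear"`` fits linear soaring (1) vs gliding (0), ``"circular"``
    circular soaring vs gliding; the other soaring mode's rows are dropped.
    Fixed effects default to thermal and orographic uplift velocity; random
    intercepts are bird identity and day, crossed.  ``fix_variances`` pins
    the two random-intercept variances instead of estimating them (0, 0
    reduces the model to ordinary logistic regression).
    """
    if fixed is None:
        fixed = ["thermal_uplift_ms", "orographic_uplift_ms"]
    mode_of_interest = {"linear": LINEAR, "circular": CIRCULAR}[response_mode]
    sub = table[table["mode"].isin([GLIDING, mode_of_interest])]
    if sub.empty:
        raise SeparationError("no observations for this response")
    y = (sub["mode"] == mode_of_interest).to_numpy(float)
    if y.min() == y.max():
        raise SeparationError("response has a single class")
    X, bird, day = _design(sub, fixed)

    p = X.shape[1]
    if fix_variances is not None:
        sig = (math.sqrt(fix_variances[0]), math.sqrt(fix_variances[1]))
        ll, delta, H = _laplace_profile_beta(y, X, bird, day, *sig)
        beta = delta[:p]
        converged = np.isfinite(ll)
    else:
        # stage 1: cheap joint profiling of (beta, u) over the variances
        def neg0(params):
            ll, _, _ = _laplace_profile_beta(y, X, bird, day,
                                             abs(params[0]), abs(params[1]))
            return -ll

        res0 = optimize.minimize(neg0, x0=[0.5, 0.5], method="Nelder-Mead",
                                 options={"xatol": 1e-3, "fatol": 1e-6,
                                          "maxiter": 200})
        sig0 = (abs(res0.x[0]), abs(res0.x[1]))
        _, delta0, _ = _laplace_profile_beta(y, X, bird, day, *sig0)

        # stage 2: true Laplace ML — optimize (variances, beta) with only
        # the random effects profiled
        def neg(params):
            ll, _ = _laplace_loglik(y, X, bird, day, abs(params[0]),
                                    abs(params[1]), params[2:])
            return -ll

        x0 = np.concatenate([sig0, delta0[:p]])
        res = optimize.minimize(neg, x0=x0, method="Nelder-Mead",
                                options={"xatol": 1e-5, "fatol": 1e-9,
                                         "maxiter": 2000, "maxfev": 3000})
        sig = (abs(res.x[0]), abs(res.x[1]))
        beta = res.x[2:]
        converged = bool(res.success)
        ll, v = _laplace_loglik(y, X, bird, day, *sig, beta)
        H = _joint_hessian(y, X, bird, day, *sig, beta, v)
    if np.abs(beta).max() > 30:
        raise SeparationError("fixed effects diverged: likely complete separation")
    # fixed-effect covariance: Schur complement of the random-effect block
    A, B, E = H[:p, :p], H[:p, p:], H[p:, p:]
    cov = np.linalg.inv(A - B @ np.linalg.solve(E, B.T))
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pval = 2 * stats.norm.sf(np.abs(z))

    return GLMMFit(
        terms=["(Intercept)"] + fixed,
        estimates=beta, se=se, z=z, p=pval,
        vc_bird=sig[0] ** 2, vc_day=sig[1] ** 2,
        loglik=float(ll), converged=converged, n_obs=len(sub),
        distribution="binomial",
        var_fixed=float(np.var(X @ beta, ddof=1)) if len(sub) > 1 else 0.0,
        sigma2_resid=LOGIT_RESIDUAL_VARIANCE,
    )


# ----------------------------------------------------------------------
# Gaussian LMM for flight-parameter contrasts

def fit_gaussian_lmm(table: pd.DataFrame, parameter: str,
                     log_transform: bool = False) -> GLMMFit:
    """Gaussian LMM comparing a flight parameter between the soaring modes.

    Response is the flight parameter (log-transformed when requested, for
    right-skewed positive quantities such as AGL and ground speed); the
    fixed factor is the soaring mode (linear vs circular), with crossed
    random intercepts for bird and day, fitted by REML.  The reported
    contrast is the linear-soaring effect relative to circular soaring.
    """
    import statsmodels.formula.api as smf

    sub = table[table["mode"].isin([CIRCULAR, LINEAR])].copy()
    sub = sub.dropna(subset=[parameter])
    if sub["mode"].nunique() < 2:
        raise ValueError("both soaring modes must be present")
    resp = sub[parameter].to_numpy(float)
    if log_transform:
        if np.any(resp <= 0):
            raise ValueError("log transform requires a strictly positive parameter")
        resp = np.log(resp)
    data = pd.DataFrame({
        "resp": resp,
        "is_linear": (sub["mode"] == LINEAR).astype(float).to_numpy(),
        "bird_id": sub["bird_id"].astype(str).to_numpy(),
        "day": sub["day"].astype(str).to_numpy(),
        "grp": np.ones(len(sub)),
    })
    md = smf.mixedlm("resp ~ is_linear", data, groups="grp",
                     vc_formula={"bird": "0 + C(bird_id)", "day": "0 + C(day)"})
    fit = md.fit(reml=True, method=["lbfgs", "powell"])
    beta = fit.fe_params.to_numpy()
    se = fit.bse_fe.to_numpy()
    z = beta / se
    pval = 2 * stats.norm.sf(np.abs(z))
    vc = fit.vcomp
    names = list(md.exog_vc.names)
    vc_bird = float(vc[names.index("bird")])
    vc_day = float(vc[names.index("day")])
    Xb = fit.model.exog @ beta
    return GLMMFit(
        terms=["(Intercept)", "mode[linear]"],
        estimates=beta, se=se, z=z, p=pval,
        vc_bird=vc_bird, vc_day=vc_day,
        loglik=float(fit.llf), converged=bool(fit.converged), n_obs=len(sub),
        distribution="gaussian",
        var_fixed=float(np.var(Xb, ddof=1)) if len(sub) > 1 else 0.0,
        sigma2_resid=float(fit.scale),
    )


# ----------------------------------------------------------------------

def r2_nakagawa(fit: GLMMFit, _allow_unconverged: bool = False
                ) -> tuple[float, float]:
    """Marginal and conditional R-squared of a mixed model.

    Marginal R2 is the share of variance explained by the fixed effects
    alone; conditional R2 adds the random-intercept variances to the
    numerator.  The fixed-effect variance is the variance of the realized
    fixed linear predictor; the residual variance is the Gaussian residual
    variance or pi^2 / 3 on the logit scale.
    """
    if not fit.converged and not _allow_unconverged:
        raise ValueError("refusing to compute R2 for an unconverged fit")
    total = fit.var_fixed + fit.vc_bird + fit.vc_day + fit.sigma2_resid
    if total <= 0:
        return 0.0, 0.0
    marginal = fit.var_fixed / total
    conditional = (fit.var_fixed + fit.vc_bird + fit.vc_day) / total
    return float(marginal), float(conditional)
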