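"""Model fitting: the penalized-spline reference backend and the driver.

Every candidate model is fitted to the identical row set through a
pluggable backend.  A backend must either fit a spec or return a *failed*
FitRecord — it never raises through the driver, so one pathological model
cannot abort a run.

The reference backend fits penalized regression splines by iteratively
reweighted least squares (direct weighted least squares for gaussian),
with one smoothing parameter per penalty chosen by minimizing GCV,

    GCV(lambda) = n * D(lambda) / (n - gamma * edf(lambda))^2,

using the standard degrees-of-freedom inflation gamma = 1.4 that guards
against GCV's tendency to undersmooth (Kim & Gu's correction, also the
value commonly recommended for mgcv's GCV criterion),

where D is the deviance and edf = tr[(X'WX + sum_j lambda_j S_j)^{-1} X'WX]
is the effective number of parameters (intercept and parametric columns
count 1 each).  This edf, plus one for the gaussian scale, is the
parameter count fed to the information criteria.  The optimizer is
Nelder-Mead on log-lambda; the whole procedure is deterministic.

Families: gaussian (identity link), binomial (logit), poisson (log).
Random-effect terms are reserved in the contract but rejected by this
backend with a capability failure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, special

from .basis import DegenerateDataError, Design, build_design
from .formula import FitSpec, render_formula_string

__all__ = ["FitRecord", "PenalizedSplineBackend", "fit_all", "GamFit"]

_RHO_LIM = 15.0


# --------------------------------------------------------------------------
# exponential families (canonical links)

class _Gaussian:
    name = "gaussian"
    n_scale_params = 1

    @staticmethod
    def validate(y):
        return np.asarray(y, dtype=float)

    @staticmethod
    def linkinv(eta):
        return eta

    @staticmethod
    def deviance(y, mu):
        return float(((y - mu) ** 2).sum())

    @staticmethod
    def loglik(y, mu):
        n = len(y)
        rss = ((y - mu) ** 2).sum()
        if rss <= 0:
            raise FloatingPointError("zero residual variance: loglik unbounded")
        s2 = rss / n  # MLE scale
        return float(-0.5 * n * (math.log(2 * math.pi * s2) + 1.0))


class _Poisson:
    name = "poisson"
    n_scale_params = 0

    @staticmethod
    def validate(y):
        y = np.asarray(y, dtype=float)
        if (y < 0).any() or not np.allclose(y, np.round(y)):
            raise ValueError("poisson response must be non-negative integers")
        return y

    @staticmethod
    def linkinv(eta):
        return np.exp(np.clip(eta, -30.0, 30.0))

    @staticmethod
    def deviance(y, mu):
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(y > 0, y * np.log(y / mu), 0.0)
        return float(2.0 * (term - (y - mu)).sum())

    @staticmethod
    def loglik(y, mu):
        return float((y * np.log(mu) - mu - special.gammaln(y + 1.0)).sum())


class _Binomial:
    name = "binomial"
    n_scale_params = 0

    @staticmethod
    def validate(y):
        y = np.asarray(y, dtype=float)
        if ((y < 0) | (y > 1)).any():
            raise ValueError("binomial response must lie in [0, 1]")
        return y

    @staticmethod
    def linkinv(eta):
        return special.expit(eta)

    @staticmethod
    def deviance(y, mu):
        mu = np.clip(mu, 1e-10, 1 - 1e-10)
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
            t2 = np.where(y < 1, (1 - y) * np.log((1 - y) / (1 - mu)), 0.0)
        return float(2.0 * (t1 + t2).sum())

    @staticmethod
    def loglik(y, mu):
        mu = np.clip(mu, 1e-10, 1 - 1e-10)
        return float((y * np.log(mu) + (1 - y) * np.log(1 - mu)).sum())


_FAMILIES = {"gaussian": _Gaussian, "poisson": _Poisson, "binomial": _Binomial}


# --------------------------------------------------------------------------

@dataclass
class GamFit:
    """A fitted penalized-spline model; supports prediction on new data."""

    design: Design
    coef: np.ndarray
    family: str
    lambdas: np.ndarray

    def predict(self, data: pd.DataFrame, type: str = "response") -> np.ndarray:
        eta = self.design.matrix(data) @ self.coef
        if type == "link":
            return eta
        return _FAMILIES[self.family].linkinv(eta)


@dataclass
class FitRecord:
    """Per-model fit outcome."""

    model_id: str
    status: str                     # "ok" | "failed"
    formula: str = ""
    n_obs: int = 0
    loglik: float = math.nan
    n_params: float = math.nan      # effective dof (+ scale params)
    edf: float = math.nan           # effective dof alone
    deviance: float = math.nan
    null_deviance: float = math.nan
    deviance_explained: float = math.nan
    fitted: np.ndarray | None = None
    error_message: str = ""
    fit: GamFit | None = None
    lambdas: tuple = ()


def _solve_penalized(xtwx, xtwz, lambdas, penalties):
    a = xtwx.copy()
    for lam, s in zip(lambdas, penalties):
        a += lam * s
    try:
        c, low = linalg.cho_factor(a, check_finite=False)
    except linalg.LinAlgError:
        a = a + np.eye(len(a)) * (1e-8 * max(np.trace(a) / len(a), 1.0))
        c, low = linalg.cho_factor(a, check_finite=False)
    beta = linalg.cho_solve((c, low), xtwz, check_finite=False)
    edf = float(np.trace(linalg.cho_solve((c, low), xtwx, check_finite=False)))
    return beta, edf


def _pirls(X, y, penalties, lambdas, fam, max_iter=100, tol=1e-9):
    """Penalized IRLS to convergence at fixed smoothing parameters.

    Returns (beta, mu, edf, deviance).
    """
    n = len(y)
    if fam.name == "gaussian":
        xtwx = X.T @ X
        beta, edf = _solve_penalized(xtwx, X.T @ y, lambdas, penalties)
        mu = X @ beta
        return beta, mu, edf, fam.deviance(y, mu)

    mu = (y + y.mean()) / 2.0
    if fam.name == "binomial":
        mu = np.clip(mu, 0.01, 0.99)
        eta = np.log(mu / (1 - mu))
        var = lambda m: np.clip(m * (1 - m), 1e-10, None)
    else:  # poisson
        mu = np.clip(mu, 0.01, None)
        eta = np.log(mu)
        var = lambda m: np.clip(m, 1e-10, None)

    dev = fam.deviance(y, mu)
    beta = edf = None
    for _ in range(max_iter):
        w = var(mu)  # canonical link: w = V(mu)
        z = eta + (y - mu) / w
        sw = np.sqrt(w)
        xw = X * sw[:, None]
        beta, edf = _solve_penalized(xw.T @ xw, xw.T @ (sw * z),
                                     lambdas, penalties)
        eta = X @ beta
        mu = fam.linkinv(eta)
        dev_new = fam.deviance(y, mu)
        if abs(dev_new - dev) < tol * (abs(dev_new) + 0.1):
            dev = dev_new
            break
        dev = dev_new
    if beta is None or not np.isfinite(dev):
        raise FloatingPointError("PIRLS failed to produce a finite fit")
    return beta, mu, edf, dev


def _initial_log_lambdas(X, penalties):
    xtx_diag = np.einsum("ij,ij->j", X, X)
    out = []
    for s in penalties:
        active = np.diag(s) > 0
        num = xtx_diag[active].sum() if active.any() else xtx_diag.sum()
        den = max(np.trace(s), 1e-8)
        out.append(math.log(max(num / den, 1e-6)))
    return np.array(out)


_GCV_GAMMA = 1.4  # edf inflation guarding against GCV undersmoothing


def _select_lambdas(X, y, penalties, fam, gamma=_GCV_GAMMA):
    """Minimize GCV over log smoothing parameters (Nelder-Mead)."""
    n = len(y)
    m = len(penalties)
    if m == 0:
        return np.array([])

    if fam.name == "gaussian":
        # cache the Gram matrices: per-evaluation cost is then O(p^3)
        g = X.T @ X
        b = X.T @ y
        yty = float(y @ y)

        def edf_dev(lam):
            beta, edf = _solve_penalized(g, b, lam, penalties)
            rss = max(yty - 2.0 * float(beta @ b) + float(beta @ (g @ beta)),
                      1e-300)
            return edf, rss
    else:
        def edf_dev(lam):
            _, _, edf, dev = _pirls(X, y, penalties, lam, fam)
            return edf, dev

    def gcv(rho):
        lam = np.exp(np.clip(rho, -_RHO_LIM, _RHO_LIM))
        try:
            edf, dev = edf_dev(lam)
        except (linalg.LinAlgError, FloatingPointError):
            return np.inf
        denom = n - gamma * edf
        if denom < 0.5:
            return np.inf
        return n * max(dev, 1e-300) / denom ** 2

    rho0 = _initial_log_lambdas(X, penalties)
    res = optimize.minimize(gcv, rho0, method="Nelder-Mead",
                            options={"xatol": 1e-3, "fatol": 1e-7,
                                     "maxfev": 250 * m, "maxiter": 250 * m})
    best = np.clip(res.x, -_RHO_LIM, _RHO_LIM)
    return np.exp(best)


class PenalizedSplineBackend:
    """Reference backend: penalized B-spline GAM with GCV smoothing
    selection.  Deterministic: identical data and spec give identical
    records."""

    families = ("gaussian", "binomial", "poisson")
    supports_cyclic = True
    supports_tensor = True
    supports_by = True
    supports_random_terms = False

    def fit(self, spec: FitSpec, data: pd.DataFrame) -> FitRecord:
        model_id = spec.model.id
        formula = ""
        try:
            formula = render_formula_string(spec)
            if spec.family not in self.families:
                raise ValueError(f"family {spec.family!r} not supported "
                                 f"by the reference backend")
            if spec.random_terms:
                raise ValueError(
                    "random-effect terms are not supported by the reference "
                    "backend (capability: supports_random_terms=False)")
            fam = _FAMILIES[spec.family]
            y = fam.validate(data[spec.response].to_numpy())
            design = build_design(spec, data)
            X = design.X
            if X.shape[0] <= X.shape[1]:
                raise ValueError(
                    f"model {model_id!r}: more columns ({X.shape[1]}) than "
                    f"observations ({X.shape[0]})")
            lambdas = _select_lambdas(X, y, design.penalties, fam)
            beta, mu, edf, dev = _pirls(X, y, design.penalties, lambdas, fam)
            null_dev = fam.deviance(y, np.full_like(y, y.mean()))
            dev_expl = 1.0 - dev / null_dev if null_dev > 0 else 0.0
            ll = fam.loglik(y, mu)
            if not np.isfinite(ll):
                raise FloatingPointError("non-finite log-likelihood")
            return FitRecord(
                model_id=model_id, status="ok", formula=formula,
                n_obs=len(y), loglik=ll,
                n_params=edf + fam.n_scale_params, edf=edf,
                deviance=dev, null_deviance=null_dev,
                deviance_explained=float(np.clip(dev_expl, 0.0, 1.0)),
                fitted=mu,
                fit=GamFit(design=design, coef=beta, family=spec.family,
                           lambdas=lambdas),
                lambdas=tuple(np.round(lambdas, 12)))
        except Exception as exc:  # capture, never propagate
            return FitRecord(model_id=model_id, status="failed",
                             formula=formula, n_obs=len(data),
                             error_message=f"{type(exc).__name__}: {exc}")


def fit_all(fit_specs: list[FitSpec], data: pd.DataFrame,
            backend=None, parallel: bool = False,
            n_jobs: int = -1) -> list[FitRecord]:
    """Fit every candidate spec on the shared data.

    Individual failures become failed records; the returned list matches
    the input order, and parallel execution gives records identical to
    sequential execution (fits are independent and deterministic).
    """
    if backend is None:
        backend = PenalizedSplineBackend()
    if parallel:
        from joblib import Parallel, delayed
        records = Parallel(n_jobs=n_jobs)(
            delayed(backend.fit)(spec, data) for spec in fit_specs)
    else:
        records = [backend.fit(spec, data) for spec in fit_specs]
    n_obs = {r.n_obs for r in records if r.status == "ok"}
    if len(n_obs) > 1:  # pragma: no cover - defensive
        raise AssertionError("fits used differing row sets")
    return list(records)
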