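"""Subject-level model inversion.

Each candidate model is a perceptual filter (HGF or RW) paired with a
response likelihood (linear log-RT or raw-belief Gaussian observation).
Free parameters carry independent Gaussian priors on a transformed scale
(identity for volatilities and regression slopes, log for the noise
variance, logit for the RW learning rate).  Fitting maximises the log joint
log p(y | params) + log p(params) with a quasi-Newton optimizer from
multiple seeded restarts, and the log model evidence is obtained by
Laplace's approximation around the MAP:

    LME = log p(y, theta_MAP) + (d/2) log 2*pi - 1/2 log det(-H),

with H the Hessian of the log joint at the MAP (central finite
differences).  Trials without a valid response update beliefs (the input is
still observed) but contribute nothing to the likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import optimize

from .perceptual import (
    HGFParams,
    HGFTrajectory,
    InvalidTrajectoryError,
    RWParams,
    RWTrajectory,
    hgf_filter,
    rw_filter,
)
from .response import (
    LogRTParams,
    WaldParams,
    drift_from_beliefs,
    gauss_obs_loglik,
    logrt_loglik,
    logrt_predict,
    wald_logpdf,
)

__all__ = [
    "Prior",
    "PriorSpec",
    "FitResult",
    "default_priors",
    "fit_map",
    "laplace_evidence",
    "fit_wald",
    "fit_wald_cohort",
    "rmse",
    "InsufficientDataError",
    "NonConvergenceError",
]

_LOG2PI = math.log(2.0 * math.pi)

# Table-of-priors defaults: volatilities N(-4,1)/N(-2,1); baseline log-RT
# N(6.2146, 4); slopes N(0, 4); log noise variance N(1.0972, 0.6931); RW
# learning rate N(0, 1) on the logit scale.
_HGF_PRIORS = (
    ("omega2", -4.0, 1.0, "identity"),
    ("omega3", -2.0, 1.0, "identity"),
    ("beta0", 6.2146, 4.0, "identity"),
    ("beta_surprise", 0.0, 4.0, "identity"),
    ("beta_sig1", 0.0, 4.0, "identity"),
    ("beta_sig2", 0.0, 4.0, "identity"),
    ("beta_vol", 0.0, 4.0, "identity"),
    ("zeta", 1.0972, 0.6931, "log"),
)
_RW_PRIORS = (
    ("alpha", 0.0, 1.0, "logit"),
    ("zeta", 1.0972, 0.6931, "log"),
)


class InsufficientDataError(ValueError):
    """Too few valid trials to fit."""


class NonConvergenceError(RuntimeError):
    """All optimizer restarts failed; carries the best partial result."""

    def __init__(self, msg: str, best=None):
        super().__init__(msg)
        self.best = best


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x)) if x > -700 else 0.0


@dataclass(frozen=True)
class Prior:
    """Gaussian prior on one parameter in its estimation space."""

    name: str
    mean: float
    var: float
    transform: str = "identity"  # identity | log | logit

    def __post_init__(self) -> None:
        if self.var <= 0:
            raise ValueError(f"prior variance for {self.name} must be positive")
        if self.transform not in ("identity", "log", "logit"):
            raise ValueError(f"unknown transform {self.transform!r}")

    def to_native(self, x: float) -> float:
        if self.transform == "log":
            return math.exp(x)
        if self.transform == "logit":
            return _sigmoid(x)
        return x

    def to_estimation(self, value: float) -> float:
        if self.transform == "log":
            return math.log(value)
        if self.transform == "logit":
            return math.log(value / (1.0 - value))
        return value

    def logpdf(self, x: float) -> float:
        return -0.5 * (_LOG2PI + math.log(self.var) + (x - self.mean) ** 2 / self.var)


@dataclass(frozen=True)
class PriorSpec:
    """Ordered collection of parameter priors for one model."""

    priors: tuple[Prior, ...]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.priors)

    @property
    def d(self) -> int:
        return len(self.priors)

    def means(self) -> np.ndarray:
        return np.array([p.mean for p in self.priors])

    def log_prior(self, xi: np.ndarray) -> float:
        return float(sum(p.logpdf(x) for p, x in zip(self.priors, xi)))

    def to_native(self, xi: np.ndarray) -> dict[str, float]:
        return {p.name: p.to_native(x) for p, x in zip(self.priors, xi)}

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        return np.array(
            [rng.normal(p.mean, math.sqrt(p.var)) for p in self.priors]
        )

    def replace(self, **overrides: tuple[float, float]) -> "PriorSpec":
        """Return a spec with (mean, var) overridden for named parameters."""
        new = []
        for p in self.priors:
            if p.name in overrides:
                m, v = overrides[p.name]
                new.append(Prior(p.name, m, v, p.transform))
            else:
                new.append(p)
        return PriorSpec(tuple(new))


def default_priors(model: str) -> PriorSpec:
    """Default priors for ``'hgf'`` (log-RT pairing) or ``'rw'`` (Gaussian)."""
    table = {"hgf": _HGF_PRIORS, "rw": _RW_PRIORS}[model.lower()]
    return PriorSpec(tuple(Prior(*row) for row in table))


@dataclass
class FitResult:
    """MAP fit of one subject under one model."""

    model: str
    map_params: dict[str, float]
    xi_map: np.ndarray
    lme: float
    log_joint: float
    log_lik: float
    trajectory: object
    yhat: np.ndarray
    residuals: np.ndarray
    rmse: float
    n_valid: int
    n_restarts_used: int
    converged: bool
    lme_flagged: bool = False
    priors: PriorSpec | None = None
    cov_xi: np.ndarray | None = None  # Laplace posterior covariance (estimation space)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "map_params": self.map_params,
            "lme": self.lme,
            "log_joint": self.log_joint,
            "log_lik": self.log_lik,
            "rmse": self.rmse,
            "n_valid": self.n_valid,
            "n_restarts_used": self.n_restarts_used,
            "converged": self.converged,
            "lme_flagged": self.lme_flagged,
        }


def _model_loglik_and_pred(
    model: str, xi: np.ndarray, spec: PriorSpec, u: np.ndarray,
    y: np.ndarray, missing: np.ndarray,
):
    """(log-likelihood, trajectory, predictions) at estimation-space xi."""
    native = spec.to_native(xi)
    if model == "hgf":
        traj = hgf_filter(u, HGFParams(omega2=native["omega2"], omega3=native["omega3"]))
        p = LogRTParams(
            beta0=native["beta0"],
            beta_surprise=native["beta_surprise"],
            beta_sig1=native["beta_sig1"],
            beta_sig2=native["beta_sig2"],
            beta_vol=native["beta_vol"],
            zeta=native["zeta"],
        )
        yhat = logrt_predict(traj, u, p)
        ll = logrt_loglik(y, yhat, native["zeta"], missing)
    elif model == "rw":
        traj = rw_filter(u, RWParams(alpha=native["alpha"]))
        yhat = traj.v_pred
        ll = gauss_obs_loglik(y, traj, native["zeta"], missing)
    else:
        raise ValueError("model must be 'hgf' or 'rw'")
    return ll, traj, yhat


def fit_map(
    u_seq,
    y,
    model: str = "hgf",
    missing=None,
    priors: PriorSpec | None = None,
    n_restarts: int = 5,
    seed: int = 0,
    tol: float = 1e-9,
    maxiter: int = 500,
) -> FitResult:
    """MAP-fit a perceptual+response model to one subject's log-RT series.

    Parameters
    ----------
    u_seq : binary input sequence (1 = SR match).
    y : observed log reaction time (log-ms), aligned with ``u_seq``; entries
        on missing trials are ignored.
    model : ``'hgf'`` (HGF + linear log-RT) or ``'rw'`` (RW + Gaussian
        observation of the raw belief).
    missing : boolean mask of trials with no valid response.
    n_restarts : quasi-Newton restarts; the first starts at the prior mean,
        the rest at seeded prior draws.

    Trajectories that lose positive-definiteness score ``-inf`` and are
    rejected by the optimizer.
    """
    model = model.lower()
    u = np.asarray(u_seq)
    y = np.asarray(y, dtype=float)
    if u.shape != y.shape:
        raise ValueError("u_seq and y must be aligned")
    if missing is None:
        missing = ~np.isfinite(y)
    missing = np.asarray(missing, dtype=bool)
    spec = priors if priors is not None else default_priors(model)
    y = np.where(missing, 0.0, y)  # masked values never enter the likelihood

    def log_joint(xi: np.ndarray) -> float:
        try:
            ll, _, _ = _model_loglik_and_pred(model, xi, spec, u, y, missing)
        except (InvalidTrajectoryError, OverflowError, FloatingPointError):
            return -np.inf
        lj = ll + spec.log_prior(xi)
        return lj if np.isfinite(lj) else -np.inf

    def nll(xi: np.ndarray) -> float:
        v = log_joint(xi)
        return 1e12 if not np.isfinite(v) else -v

    rng = np.random.default_rng(seed)
    starts = [spec.means()] + [spec.sample(rng) for _ in range(n_restarts - 1)]
    best_xi, best_val, used, ok = None, np.inf, 0, False
    for x0 in starts:
        used += 1
        try:
            res = optimize.minimize(
                nll, x0, method="L-BFGS-B",
                # loose ftol/gtol stall at the start point on flat, noisy
                # surfaces; eps larger than sqrt(machine-eps) stabilises the
                # finite-difference gradient of the filtered likelihood
                options={"maxiter": maxiter, "ftol": tol, "gtol": 1e-7,
                         "eps": 1e-6},
            )
        except (ValueError, FloatingPointError):
            continue
        if np.isfinite(res.fun) and res.fun < best_val:
            best_val, best_xi, ok = res.fun, res.x, True
    if not ok or best_xi is None:
        raise NonConvergenceError("all restarts failed", best=None)

    xi = np.asarray(best_xi, dtype=float)
    ll, traj, yhat = _model_loglik_and_pred(model, xi, spec, u, y, missing)
    lj = ll + spec.log_prior(xi)
    H = _hessian_cfd(log_joint, xi)
    lme, flagged = laplace_evidence(log_joint, xi, hessian=H)
    try:
        cov = np.linalg.inv(-H)
        if np.any(np.diag(cov) <= 0):
            cov = None
    except np.linalg.LinAlgError:
        cov = None
    resid = np.where(missing, np.nan, y - yhat)
    valid = resid[~missing]
    fit_rmse = float(np.sqrt(np.mean(valid**2))) if valid.size else float("nan")
    return FitResult(
        model=model,
        map_params=spec.to_native(xi),
        xi_map=xi,
        lme=lme,
        log_joint=float(lj),
        log_lik=float(ll),
        trajectory=traj,
        yhat=yhat,
        residuals=resid,
        rmse=fit_rmse,
        n_valid=int((~missing).sum()),
        n_restarts_used=used,
        converged=True,
        lme_flagged=flagged,
        priors=spec,
        cov_xi=cov,
    )


def _hessian_cfd(f: Callable[[np.ndarray], float], x: np.ndarray,
                 h: float = 1e-3) -> np.ndarray:
    """Central-finite-difference Hessian with symmetrisation."""
    d = x.size
    steps = h * np.maximum(1.0, np.abs(x))
    H = np.empty((d, d))
    f0 = f(x)
    for i in range(d):
        ei = np.zeros(d); ei[i] = steps[i]
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / steps[i] ** 2
        for j in range(i + 1, d):
            ej = np.zeros(d); ej[j] = steps[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * steps[i] * steps[j])
    return 0.5 * (H + H.T)


def laplace_evidence(
    log_joint: Callable[[np.ndarray], float],
    xi_map: np.ndarray,
    h: float = 1e-3,
    hessian: np.ndarray | None = None,
) -> tuple[float, bool]:
    """Laplace approximation to the log model evidence at a MAP point.

    Returns ``(lme, flagged)``; ``flagged`` is True when the negative
    Hessian was not positive definite and a jittered or pseudo-determinant
    fallback was used.  With zero free parameters the LME is simply the log
    joint at the fixed values.
    """
    xi_map = np.atleast_1d(np.asarray(xi_map, dtype=float))
    d = xi_map.size
    lj = float(log_joint(xi_map))
    if d == 0:
        return lj, False
    H = hessian if hessian is not None else _hessian_cfd(log_joint, xi_map, h=h)
    negH = -H
    flagged = False
    sign, logdet = np.linalg.slogdet(negH)
    if sign <= 0:
        flagged = True
        jitter = 1e-6 * max(1.0, float(np.abs(np.diag(negH)).max()))
        sign, logdet = np.linalg.slogdet(negH + jitter * np.eye(d))
        if sign <= 0:
            # pseudo-determinant over the positive spectrum
            ev = np.linalg.eigvalsh(negH)
            pos = ev[ev > 1e-10]
            logdet = float(np.sum(np.log(pos))) if pos.size else 0.0
    return lj + 0.5 * d * _LOG2PI - 0.5 * float(logdet), flagged


def rmse(fit: FitResult) -> float:
    """Root-mean-square residual over non-missing trials."""
    return fit.rmse


# ---------------------------------------------------------------------------
# Wald response-model fitting (maximum likelihood, per subject)

def _wald_nll(theta, rt, traj, u, missing, model):
    v0, c = theta
    if v0 <= 0:
        return 1e12
    params = WaldParams(v0=v0, c=c)
    drift = drift_from_beliefs(traj, u, params, model=model)
    ok = ~missing
    lp = wald_logpdf(rt[ok], params, drift[ok])
    if not np.all(np.isfinite(lp)):
        return 1e12
    return -float(np.sum(lp))


def fit_wald(
    rt_s,
    traj,
    u_seq,
    model: str = "hgf",
    missing=None,
    init: tuple[float, float] = (6.0, 1.0),
) -> WaldParams:
    """Maximum-likelihood Wald response parameters (v0, c) for one subject.

    Reaction times are in seconds; trials flagged missing, non-finite, or at
    or below the 0.2-s non-decision offset are excluded.  Requires at least
    10 valid trials.  Optimisation starts from ``init`` (defaults 6 and 1).
    """
    rt = np.asarray(rt_s, dtype=float)
    u = np.asarray(u_seq)
    if missing is None:
        missing = np.zeros(rt.shape, dtype=bool)
    missing = np.asarray(missing, dtype=bool) | ~np.isfinite(rt)
    missing = missing | np.where(np.isfinite(rt), rt <= WaldParams().t0, True)
    if int((~missing).sum()) < 10:
        raise InsufficientDataError("fewer than 10 valid reaction times")
    rt = np.where(missing, 1.0, rt)
    res = optimize.minimize(
        _wald_nll, np.asarray(init, dtype=float),
        args=(rt, traj, u, missing, model.lower()),
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
    )
    v0, c = res.x
    return WaldParams(v0=float(max(v0, 0.2)), c=float(c))


def fit_wald_cohort(
    subjects: Sequence[tuple[np.ndarray, object, np.ndarray, np.ndarray]],
    model: str = "hgf",
    init: tuple[float, float] = (6.0, 1.0),
) -> tuple[WaldParams, list[WaldParams]]:
    """Group-then-subject Wald fitting.

    ``subjects`` is a sequence of ``(rt_s, trajectory, u_seq, missing)``
    tuples.  A first pass maximises the pooled likelihood across all
    subjects starting from ``init``; the group estimate then initialises
    each subject-wise fit.  Returns ``(group_params, per_subject_params)``.
    """
    def pooled_nll(theta):
        return sum(
            _wald_nll(theta, np.where(np.asarray(m, bool) | ~np.isfinite(rt), 1.0, rt),
                      tr, np.asarray(u), np.asarray(m, bool) | ~np.isfinite(rt)
                      | np.where(np.isfinite(rt), rt <= 0.2, True), model)
            for rt, tr, u, m in (
                (np.asarray(r, float), t, uu, mm) for r, t, uu, mm in subjects
            )
        )

    res = optimize.minimize(
        pooled_nll, np.asarray(init, dtype=float), method="Nelder-Mead",
        options={"xatol": 1e-5, "fatol": 1e-6, "maxiter": 1000},
    )
    group = WaldParams(v0=float(max(res.x[0], 0.2)), c=float(res.x[1]))
    per_subject = [
        fit_wald(rt, tr, u, model=model, missing=m, init=(group.v0, group.c))
        for rt, tr, u, m in subjects
    ]
    return group, per_subject
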