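"""Response models mapping beliefs onto reaction times.

Three observation models are provided:

* a linear model of log reaction time (natural log of RT in milliseconds)
  with Gaussian noise, driven by HGF trajectory quantities — used for model
  inversion and log model evidence;
* a plain Gaussian observation model whose per-trial mean is the raw RW
  belief — the literal continuous-response pairing for the RW model;
* a shifted Wald (inverse-Gaussian) first-passage-time model with
  belief-coupled drift — used to simulate and predict RT in seconds.

The Wald model treats a response as a one-boundary drift-diffusion process:
with threshold a and drift v, the passage time is Wald(mean a/v, shape a^2),
shifted by a non-decision offset t0.  The threshold is fixed at 1 (absorbing
the scale degeneracy) and t0 at 0.2 s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .perceptual import HGFTrajectory, RWTrajectory

__all__ = [
    "LogRTParams",
    "WaldParams",
    "logrt_predict",
    "logrt_loglik",
    "gauss_obs_loglik",
    "wald_pdf",
    "wald_logpdf",
    "wald_mean",
    "wald_var",
    "wald_sample",
    "drift_from_beliefs",
    "DRIFT_FLOOR",
]

#: Lower bound on drift to keep the Wald density proper for extreme beliefs.
DRIFT_FLOOR = 0.1

_LOG2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class LogRTParams:
    """Linear log-RT model: intercept, four belief regressors, noise.

    beta0 is baseline log-RT in log-milliseconds (prior mean 6.2146, i.e. a
    ~500 ms baseline); zeta is the Gaussian noise variance.
    """

    beta0: float = 6.2146
    beta_surprise: float = 0.0
    beta_sig1: float = 0.0
    beta_sig2: float = 0.0
    beta_vol: float = 0.0
    zeta: float = math.exp(1.0972)

    def __post_init__(self) -> None:
        if self.zeta <= 0:
            raise ValueError("zeta must be positive")


@dataclass(frozen=True)
class WaldParams:
    """Shifted-Wald response model parameters.

    v0: mean drift rate (1/s); c: belief-coupling coefficient; t0:
    non-decision offset (fixed 0.2 s); a: threshold (fixed 1).
    """

    v0: float = 6.0
    c: float = 1.0
    t0: float = 0.2
    a: float = 1.0

    def __post_init__(self) -> None:
        if self.v0 <= 0:
            raise ValueError("v0 must be positive")

    def with_(self, **kw) -> "WaldParams":
        return replace(self, **kw)


def _regressors(traj: HGFTrajectory, u_seq: np.ndarray) -> np.ndarray:
    """Design matrix columns: surprise, level-1 variance, level-2 prediction
    variance, exponentiated level-3 prediction."""
    u = np.asarray(u_seq)
    if len(traj) != u.size:
        raise ValueError("trajectory and input sequence lengths differ")
    mh1 = traj.muhat1
    surprise = np.where(u == 1, -np.log(mh1), -np.log(1.0 - mh1))
    return np.column_stack(
        [surprise, mh1 * (1.0 - mh1), traj.sigmahat2, np.exp(traj.muhat3)]
    )


def logrt_predict(traj: HGFTrajectory, u_seq, params: LogRTParams) -> np.ndarray:
    """Predicted log-RT (log-ms) per trial from an HGF trajectory.

    yhat = beta0 + beta_surprise*S + beta_sig1*muhat1(1-muhat1)
         + beta_sig2*sigmahat2 + beta_vol*exp(muhat3),
    with Shannon surprise S = -ln muhat1 on match trials, -ln(1-muhat1)
    on mismatch trials.  Defined on every trial, missing or not.
    """
    X = _regressors(traj, np.asarray(u_seq))
    slopes = np.array(
        [params.beta_surprise, params.beta_sig1, params.beta_sig2, params.beta_vol]
    )
    return params.beta0 + X @ slopes


def _gauss_loglik(y, yhat, zeta, missing) -> float:
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    ok = ~np.asarray(missing, dtype=bool)
    r = y[ok] - yhat[ok]
    n = r.size
    if n == 0:
        return 0.0
    with np.errstate(over="ignore"):  # huge residuals just mean -inf
        return float(-0.5 * n * (_LOG2PI + math.log(zeta))
                     - 0.5 * np.sum(r * r) / zeta)


def logrt_loglik(y, yhat, zeta: float, missing=None) -> float:
    """Gaussian log-likelihood of observed log-RT; missing trials add 0."""
    if zeta <= 0:
        raise ValueError("zeta must be positive")
    if missing is None:
        missing = np.zeros(np.asarray(y).shape, dtype=bool)
    return _gauss_loglik(y, yhat, zeta, missing)


def gauss_obs_loglik(y, rw_traj: RWTrajectory, zeta: float, missing=None) -> float:
    """Gaussian observation likelihood with per-trial mean = raw RW belief.

    This is the literal continuous-response pairing for the RW model: the
    prediction lives on the belief scale [0, 1] while y is log-RT, so the
    residuals carry the resulting scale mismatch (~5-6 on log-ms data).
    """
    if zeta <= 0:
        raise ValueError("zeta must be positive")
    if missing is None:
        missing = np.zeros(np.asarray(y).shape, dtype=bool)
    return _gauss_loglik(y, rw_traj.v_pred, zeta, missing)


def wald_logpdf(t, params: WaldParams, drift) -> np.ndarray:
    """Log-density of the shifted Wald; -inf at or below the offset t0."""
    t = np.asarray(t, dtype=float)
    v = np.asarray(drift, dtype=float)
    a, t0 = params.a, params.t0
    w = t - t0
    out = np.full(np.broadcast(t, v).shape, -np.inf)
    pos = w > 0
    wp = np.broadcast_to(w, out.shape)[pos]
    vp = np.broadcast_to(v, out.shape)[pos]
    out[pos] = (
        math.log(a)
        - 0.5 * (_LOG2PI + 3.0 * np.log(wp))
        - (a - vp * wp) ** 2 / (2.0 * wp)
    )
    return out


def wald_pdf(t, params: WaldParams, drift) -> np.ndarray:
    """Density of the shifted Wald first-passage-time distribution.

    f(t) = a / sqrt(2 pi w^3) * exp(-(a - v w)^2 / (2 w)),  w = t - t0,
    and 0 for t <= t0.
    """
    return np.exp(wald_logpdf(t, params, drift))


def wald_mean(params: WaldParams, drift) -> np.ndarray:
    """Analytic mean a/v + t0."""
    return params.a / np.asarray(drift, dtype=float) + params.t0


def wald_var(params: WaldParams, drift) -> np.ndarray:
    """Analytic variance a/v^3."""
    return params.a / np.asarray(drift, dtype=float) ** 3


def wald_sample(params: WaldParams, drift, seed=None) -> np.ndarray:
    """Draw shifted-Wald reaction times (seconds), one per drift value."""
    rng = np.random.default_rng(seed)
    v = np.atleast_1d(np.asarray(drift, dtype=float))
    if np.any(v <= 0):
        raise ValueError("drift must be positive")
    # Wald(threshold a, drift v) = inverse Gaussian(mean a/v, shape a^2)
    return rng.wald(params.a / v, params.a**2) + params.t0


def wald_cdf(t, params: WaldParams, drift) -> np.ndarray:
    """CDF of the shifted Wald (via scipy's inverse-Gaussian)."""
    v = np.asarray(drift, dtype=float)
    mu = params.a / v
    lam = params.a**2
    # scipy invgauss(mu=m, scale=s) has mean m*s and shape s
    return stats.invgauss.cdf(
        np.asarray(t, dtype=float) - params.t0, mu=mu / lam, scale=lam
    )


def drift_from_beliefs(
    traj,
    u_seq,
    params: WaldParams,
    model: str = "hgf",
) -> np.ndarray:
    """Per-trial drift rate from a belief trajectory.

    The belief aligned to the observed trial type is b[t] = p(observed
    outcome): muhat1 (HGF) or the prior RW belief v_pred on match trials,
    their complement on mismatch trials.  Drift couples that belief, and for
    the HGF also the centred level-3 volatility prediction, to the base
    rate:

        HGF: v_t = v0 + c * ((b - 0.5) - (muhat3 - mean(muhat3)))
        RW:  v_t = v0 + c * (b - 0.5)

    floored at 0.1 s^-1 so the Wald density stays proper.
    """
    u = np.asarray(u_seq)
    model = model.lower()
    if model == "hgf":
        b = np.where(u == 1, traj.muhat1, 1.0 - traj.muhat1)
        vol = traj.muhat3 - traj.muhat3.mean()
        v = params.v0 + params.c * ((b - 0.5) - vol)
    elif model == "rw":
        b = np.where(u == 1, traj.v_pred, 1.0 - traj.v_pred)
        v = params.v0 + params.c * (b - 0.5)
    else:
        raise ValueError("model must be 'hgf' or 'rw'")
    return np.maximum(v, DRIFT_FLOOR)
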