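"""Trial-wise belief updating: binary 3-level HGF and Rescorla-Wagner.

The hierarchical Gaussian filter (HGF) tracks three coupled states: x1, the
binary trial outcome (stimulus-response match vs mismatch); x2, the log-odds
tendency towards matching; and x3, the (log-scale) volatility of that
tendency.  x2 and x3 evolve as Gaussian random walks whose step variances
are set by the level above, so the effective learning rate at the outcome
level adapts to estimated volatility.  Tonic (trial-invariant) volatility at
levels 2 and 3 is parameterised as omega2 and omega3; the level-2/3 coupling
kappa is fixed at 1. The meta-volatility parameter often written theta is
represented here as exp(omega3).

The Rescorla-Wagner (RW) model is the fixed-learning-rate alternative:
v <- v + alpha * (u - v).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "HGFParams",
    "HGFTrajectory",
    "RWParams",
    "RWTrajectory",
    "InvalidTrajectoryError",
    "hgf_update",
    "hgf_filter",
    "rw_filter",
    "learning_rate",
]

#: Clipping bound on the level-1 prediction before it enters precisions.
_MUHAT1_EPS = 1e-8

_TRAJ_FIELDS = (
    "muhat1", "muhat2", "muhat3", "sigmahat2", "sigmahat3",
    "mu2", "sigma2", "mu3", "sigma3", "delta1", "delta2", "lr1",
)


class InvalidTrajectoryError(ValueError):
    """A parameter set produced a non-positive precision; reject it."""


@dataclass(frozen=True)
class HGFParams:
    """Binary HGF parameters.

    omega2, omega3
        Tonic log-volatility at levels 2 and 3.
    kappa
        Coupling strength between levels 2 and 3 (fixed at 1 by default).
    mu2_0, sigma2_0, mu3_0, sigma3_0
        Initial posterior means/variances; fixed, not estimated.
    """

    omega2: float = -4.0
    omega3: float = -2.0
    kappa: float = 1.0
    mu2_0: float = 0.0
    sigma2_0: float = 0.1
    mu3_0: float = 1.0
    sigma3_0: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma2_0 <= 0 or self.sigma3_0 <= 0:
            raise ValueError("initial variances must be positive")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")

    def initial_state(self) -> tuple[float, float, float, float]:
        return (self.mu2_0, self.sigma2_0, self.mu3_0, self.sigma3_0)


@dataclass(frozen=True)
class RWParams:
    """Rescorla-Wagner parameters: fixed learning rate and initial belief."""

    alpha: float
    v0: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0.0 <= self.v0 <= 1.0:
            raise ValueError("v0 must lie in [0, 1]")


class HGFTrajectory:
    """Per-trial HGF quantities as equal-length numpy arrays.

    Attributes muhat* / sigmahat* are pre-input predictions at each trial,
    mu* / sigma* are post-input posteriors, delta1/delta2 prediction errors,
    and lr1 the effective outcome-level learning rate.
    """

    def __init__(self, **arrays: np.ndarray) -> None:
        n = {len(v) for v in arrays.values()}
        if len(n) != 1:
            raise ValueError("all trajectory fields must share a length")
        for k in _TRAJ_FIELDS:
            setattr(self, k, np.asarray(arrays[k], dtype=float))

    def __len__(self) -> int:
        return len(self.muhat1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({k: getattr(self, k) for k in _TRAJ_FIELDS})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "HGFTrajectory":
        return cls(**{k: df[k].to_numpy() for k in _TRAJ_FIELDS})


@dataclass
class RWTrajectory:
    """Per-trial RW quantities: prior belief, prediction error, posterior."""

    v_pred: np.ndarray
    delta: np.ndarray
    v_post: np.ndarray

    def __len__(self) -> int:
        return len(self.v_pred)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"v_pred": self.v_pred, "delta": self.delta, "v_post": self.v_post}
        )


def hgf_update(
    state: tuple[float, float, float, float],
    u: int,
    params: HGFParams,
) -> tuple[tuple[float, float, float, float], dict[str, float]]:
    """One HGF step: predict from `state`, observe binary `u`, update.

    Returns the new ``(mu2, sigma2, mu3, sigma3)`` state and a record of
    every per-trial quantity.  Raises :class:`InvalidTrajectoryError` if the
    level-3 precision goes non-positive, which callers treat as an
    infinitely bad parameter set.
    """
    mu2, sigma2, mu3, sigma3 = state
    om2, om3, ka = params.omega2, params.omega3, params.kappa

    muhat2 = mu2
    muhat1 = 1.0 / (1.0 + math.exp(-muhat2))
    muhat1 = min(max(muhat1, _MUHAT1_EPS), 1.0 - _MUHAT1_EPS)
    muhat3 = mu3
    v2 = math.exp(ka * muhat3 + om2)     # level-2 random-walk step variance
    sigmahat2 = sigma2 + v2
    sigmahat3 = sigma3 + math.exp(om3)

    delta1 = u - muhat1
    pi2 = 1.0 / sigmahat2 + muhat1 * (1.0 - muhat1)
    mu2_new = muhat2 + delta1 / pi2
    sigma2_new = 1.0 / pi2

    w2 = v2 / sigmahat2
    delta2 = (sigma2_new + (mu2_new - muhat2) ** 2) / sigmahat2 - 1.0
    pi3 = 1.0 / sigmahat3 + (ka * ka / 2.0) * w2 * (w2 + (2.0 * w2 - 1.0) * delta2)
    if pi3 <= 0.0:
        raise InvalidTrajectoryError("non-positive level-3 precision")
    sigma3_new = 1.0 / pi3
    mu3_new = muhat3 + sigma3_new * (ka / 2.0) * w2 * delta2

    if delta1 != 0.0:
        lr1 = (1.0 / (1.0 + math.exp(-mu2_new)) - muhat1) / delta1
    else:
        lr1 = 0.0

    record = {
        "muhat1": muhat1, "muhat2": muhat2, "muhat3": muhat3,
        "sigmahat2": sigmahat2, "sigmahat3": sigmahat3,
        "mu2": mu2_new, "sigma2": sigma2_new,
        "mu3": mu3_new, "sigma3": sigma3_new,
        "delta1": delta1, "delta2": delta2, "lr1": lr1,
    }
    return (mu2_new, sigma2_new, mu3_new, sigma3_new), record


def hgf_filter(u_seq, params: HGFParams) -> HGFTrajectory:
    """Run the binary HGF over an input sequence.

    Predictions at trial t depend only on inputs before t (causal filter).
    """
    u = np.asarray(u_seq)
    if u.size == 0:
        raise ValueError("input sequence must be non-empty")
    if not np.isin(u, (0, 1)).all():
        raise ValueError("inputs must be binary")

    n = u.size
    out = {k: np.empty(n) for k in _TRAJ_FIELDS}
    state = params.initial_state()
    # inlined scalar loop: the recursion is inherently sequential
    for t in range(n):
        state, rec = hgf_update(state, int(u[t]), params)
        for k, val in rec.items():
            out[k][t] = val
    return HGFTrajectory(**out)


def rw_filter(u_seq, params: RWParams) -> RWTrajectory:
    """Rescorla-Wagner filter: v_post = v_pred + alpha * (u - v_pred)."""
    u = np.asarray(u_seq, dtype=float)
    if u.size == 0:
        raise ValueError("input sequence must be non-empty")
    if not np.isin(u, (0.0, 1.0)).all():
        raise ValueError("inputs must be binary")
    n = u.size
    v_pred = np.empty(n)
    v_post = np.empty(n)
    v = params.v0
    a = params.alpha
    for t in range(n):
        v_pred[t] = v
        v = v + a * (u[t] - v)
        v_post[t] = v
    return RWTrajectory(v_pred=v_pred, delta=u - v_pred, v_post=v_post)


def learning_rate(traj: HGFTrajectory) -> np.ndarray:
    """Effective outcome-level learning rate per trial.

    Defined as the fraction of the outcome prediction error absorbed into
    the next outcome prediction: (sigmoid(mu2) - muhat1) / delta1, and 0
    where delta1 = 0.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        lr = (1.0 / (1.0 + np.exp(-traj.mu2)) - traj.muhat1) / traj.delta1
    lr[traj.delta1 == 0.0] = 0.0
    return lr
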