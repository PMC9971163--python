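"""Model/Results front-end for subject-level fitting.

`BeliefLearningModel` pairs a perceptual filter (HGF or RW) with its
response likelihood and fits one subject's reaction-time series by MAP +
Laplace; `WaldDDMModel` fits the shifted-Wald drift-diffusion response
model by maximum likelihood and simulates predicted reaction times.  Both
follow the statsmodels convention: a Model is constructed from data,
``fit()`` returns a Results object carrying estimates, uncertainties and
diagnostics, and ``summary()`` renders a table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import inversion
from .inversion import FitResult, PriorSpec, default_priors, fit_wald
from .response import WaldParams, drift_from_beliefs, wald_mean, wald_sample

__all__ = [
    "BeliefLearningModel",
    "BeliefLearningResults",
    "WaldDDMModel",
    "WaldDDMResults",
]

_MS_LOG = "log-ms"


class BeliefLearningModel:
    """One subject's belief-learning model of log reaction time.

    Parameters
    ----------
    u : binary input sequence (1 = SR match, 0 = mismatch).
    y_logrt : observed log reaction time in log-milliseconds.
    missing : optional boolean mask of trials without a valid response;
        non-finite y entries are treated as missing regardless.
    perceptual : ``'hgf'`` (3-level volatility learner + linear log-RT
        response) or ``'rw'`` (fixed learning rate + Gaussian observation
        of the raw belief).
    priors : optional :class:`PriorSpec` overriding the defaults.
    """

    def __init__(self, u, y_logrt, missing=None, perceptual: str = "hgf",
                 priors: PriorSpec | None = None):
        self.u = np.asarray(u)
        self.y = np.asarray(y_logrt, dtype=float)
        self.missing = (
            ~np.isfinite(self.y) if missing is None
            else (np.asarray(missing, dtype=bool) | ~np.isfinite(self.y))
        )
        self.perceptual = perceptual.lower()
        self.priors = priors if priors is not None else default_priors(self.perceptual)

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, perceptual: str = "hgf",
                       rt_col: str = "rt_s", priors: PriorSpec | None = None):
        """Build from a trial table with RT in seconds; converts to log-ms."""
        rt = table[rt_col].to_numpy(dtype=float)
        missing = table["missing"].to_numpy(dtype=bool) if "missing" in table \
            else ~np.isfinite(rt)
        with np.errstate(invalid="ignore", divide="ignore"):
            y = np.log(rt * 1000.0)
        return cls(table["u"].to_numpy(), y, missing=missing,
                   perceptual=perceptual, priors=priors)

    def fit(self, n_restarts: int = 5, seed: int = 0, **opts) -> "BeliefLearningResults":
        res = inversion.fit_map(
            self.u, self.y, model=self.perceptual, missing=self.missing,
            priors=self.priors, n_restarts=n_restarts, seed=seed, **opts,
        )
        return BeliefLearningResults(self, res)


@dataclass
class BeliefLearningResults:
    """MAP estimates, Laplace evidence and diagnostics for one subject."""

    model: BeliefLearningModel
    fit: FitResult

    @property
    def params(self) -> dict[str, float]:
        return self.fit.map_params

    @property
    def lme(self) -> float:
        return self.fit.lme

    @property
    def rmse(self) -> float:
        return self.fit.rmse

    @property
    def trajectory(self):
        return self.fit.trajectory

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.fit.yhat

    @property
    def bse(self) -> dict[str, float] | None:
        """Posterior standard errors in estimation space (Laplace), or None."""
        if self.fit.cov_xi is None:
            return None
        sds = np.sqrt(np.diag(self.fit.cov_xi))
        return dict(zip(self.fit.priors.names, sds))

    def summary(self) -> pd.DataFrame:
        names = self.fit.priors.names
        bse = self.bse or {n: np.nan for n in names}
        tab = pd.DataFrame(
            {
                "param": names,
                "estimate": [self.fit.map_params[n] for n in names],
                "xi_map": self.fit.xi_map,
                "se_xi": [bse[n] for n in names],
                "prior_mean": [p.mean for p in self.fit.priors.priors],
                "transform": [p.transform for p in self.fit.priors.priors],
            }
        )
        tab.attrs["model"] = self.fit.model
        tab.attrs["lme"] = self.fit.lme
        tab.attrs["rmse"] = self.fit.rmse
        tab.attrs["n_valid"] = self.fit.n_valid
        return tab

    def __repr__(self) -> str:
        return (
            f"<BeliefLearningResults model={self.fit.model} "
            f"lme={self.fit.lme:.2f} rmse={self.fit.rmse:.3f}>"
        )


class WaldDDMModel:
    """Shifted-Wald drift-diffusion response model for one subject.

    Couples a fitted belief trajectory to reaction times in seconds; drift
    on each trial is the base rate plus the coupling coefficient times the
    aligned belief (minus, for the HGF, the centred volatility prediction).
    """

    def __init__(self, rt_s, trajectory, u, missing=None, perceptual: str = "hgf"):
        self.rt = np.asarray(rt_s, dtype=float)
        self.trajectory = trajectory
        self.u = np.asarray(u)
        self.missing = (
            ~np.isfinite(self.rt) if missing is None
            else (np.asarray(missing, dtype=bool) | ~np.isfinite(self.rt))
        )
        self.perceptual = perceptual.lower()

    def fit(self, init: tuple[float, float] = (6.0, 1.0)) -> "WaldDDMResults":
        params = fit_wald(self.rt, self.trajectory, self.u,
                          model=self.perceptual, missing=self.missing, init=init)
        return WaldDDMResults(self, params)


@dataclass
class WaldDDMResults:
    model: WaldDDMModel
    params: WaldParams

    @property
    def drift(self) -> np.ndarray:
        return drift_from_beliefs(self.model.trajectory, self.model.u,
                                  self.params, model=self.model.perceptual)

    @property
    def fittedvalues(self) -> np.ndarray:
        """Predicted mean RT per trial (seconds): a/v + t0."""
        return wald_mean(self.params, self.drift)

    def simulate(self, seed=None) -> np.ndarray:
        """Draw one simulated RT (seconds) per trial."""
        return wald_sample(self.params, self.drift, seed=seed)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "param": ["v0", "c", "t0", "a"],
                "estimate": [self.params.v0, self.params.c,
                             self.params.t0, self.params.a],
                "fixed": [False, False, True, True],
            }
        )

    def __repr__(self) -> str:
        return f"<WaldDDMResults v0={self.params.v0:.3f} c={self.params.c:.3f}>"
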