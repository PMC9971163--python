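"""Random-effects Bayesian model selection from per-subject log evidences.

Treats the model identity of each subject as a draw from a population
multinomial with Dirichlet-distributed frequencies r, and inverts the
hierarchical model by variational Bayes: posterior assignment
probabilities u_nk and Dirichlet concentrations alpha are iterated to a
fixed point.  From the Dirichlet posterior we report expected model
frequencies, exceedance probabilities (P(r_k > r_j for all j)), the
Bayesian omnibus risk (posterior probability that all models are equally
frequent), and protected exceedance probabilities that blend exceedance
with that null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import betaln, digamma, gammaln, logsumexp

__all__ = [
    "BMSResult",
    "vb_dirichlet",
    "exceedance_prob",
    "protected_xp",
    "bms",
    "lme_differences",
]


@dataclass
class BMSResult:
    """Posterior summary of random-effects model selection."""

    model_names: tuple[str, ...]
    alpha: np.ndarray            # Dirichlet concentrations
    expected_r: np.ndarray       # posterior expected model frequencies
    xp: np.ndarray               # exceedance probabilities
    pxp: np.ndarray              # protected exceedance probabilities
    bor: float                   # Bayesian omnibus risk
    u_nk: np.ndarray             # per-subject assignment probabilities
    free_energy: float           # variational free energy of the RFX model
    n_iter: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": self.model_names,
                "alpha": self.alpha,
                "expected_r": self.expected_r,
                "xp": self.xp,
                "pxp": self.pxp,
            }
        )

    def to_dict(self) -> dict:
        return {
            "model_names": list(self.model_names),
            "alpha": self.alpha.tolist(),
            "expected_r": self.expected_r.tolist(),
            "xp": self.xp.tolist(),
            "pxp": self.pxp.tolist(),
            "bor": self.bor,
            "free_energy": self.free_energy,
            "n_iter": self.n_iter,
        }


def _check_lme(lme: np.ndarray) -> np.ndarray:
    lme = np.asarray(lme, dtype=float)
    if lme.ndim != 2 or lme.shape[1] < 2:
        raise ValueError("LME matrix must be n_subjects x n_models, K >= 2")
    if not np.all(np.isfinite(lme)):
        raise ValueError("LME matrix must be finite")
    return lme


def vb_dirichlet(
    lme,
    alpha0: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 10_000,
    return_iters: bool = False,
):
    """Variational fixed point for the Dirichlet-multinomial RFX model.

    Iterates u_nk proportional to exp(lme_nk + psi(alpha_k) - psi(sum alpha))
    and alpha_k = alpha0 + sum_n u_nk until the sup-norm change in alpha
    falls below ``tol``.  Returns ``(alpha, u_nk)``.
    """
    lme = _check_lme(lme)
    n, K = lme.shape
    alpha = np.full(K, alpha0 + n / K)
    for it in range(max_iter):
        logu = lme + digamma(alpha) - digamma(alpha.sum())
        logu -= logsumexp(logu, axis=1, keepdims=True)
        u = np.exp(logu)
        alpha_new = alpha0 + u.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            return (alpha_new, u, it + 1) if return_iters else (alpha_new, u)
        alpha = alpha_new
    raise RuntimeError("VB Dirichlet iteration did not converge")


def exceedance_prob(alpha, n_samples: int = 1_000_000, seed: int = 0) -> np.ndarray:
    """P(model k is the most frequent) under Dirichlet(alpha).

    Analytic for two models via the Beta tail; Monte-Carlo with a fixed
    seed otherwise.
    """
    alpha = np.asarray(alpha, dtype=float)
    K = alpha.size
    if K == 2:
        xp1 = 1.0 - stats.beta.cdf(0.5, alpha[0], alpha[1])
        return np.array([xp1, 1.0 - xp1])
    rng = np.random.default_rng(seed)
    r = rng.dirichlet(alpha, size=n_samples)
    winners = np.argmax(r, axis=1)
    return np.bincount(winners, minlength=K) / n_samples


def _free_energy_rfx(lme: np.ndarray, alpha: np.ndarray, u: np.ndarray,
                     alpha0: float) -> float:
    """Variational free energy of the random-effects model at convergence."""
    n, K = lme.shape
    a0 = np.full(K, alpha0)
    asum = alpha.sum()
    Elogr = digamma(alpha) - digamma(asum)
    # E_q[log p(y, m | r)] + assignment entropy
    F = float(np.sum(u * (lme + Elogr)))
    with np.errstate(divide="ignore", invalid="ignore"):
        F -= float(np.nansum(u * np.where(u > 0, np.log(u), 0.0)))
    # E_q[log p(r)] - E_q[log q(r)]
    F += float(gammaln(a0.sum()) - gammaln(a0).sum() + ((a0 - 1.0) * Elogr).sum())
    F -= float(gammaln(asum) - gammaln(alpha).sum() + ((alpha - 1.0) * Elogr).sum())
    return F


def _free_energy_null(lme: np.ndarray) -> float:
    """Log evidence of the null: every model equally frequent (r = 1/K)."""
    n, K = lme.shape
    return float(np.sum(logsumexp(lme - np.log(K), axis=1)))


def protected_xp(
    lme,
    alpha,
    u,
    xp: np.ndarray,
    alpha0: float = 1.0,
) -> tuple[np.ndarray, float]:
    """Protected exceedance probabilities and Bayesian omnibus risk.

    BOR = 1 / (1 + exp(F1 - F0)) compares the free energy F1 of the
    random-effects model against the evidence F0 of the equal-frequency
    null; pxp_k = xp_k (1 - BOR) + BOR / K.
    """
    lme = _check_lme(lme)
    K = lme.shape[1]
    F1 = _free_energy_rfx(lme, np.asarray(alpha, float), np.asarray(u, float), alpha0)
    F0 = _free_energy_null(lme)
    bor = 1.0 / (1.0 + np.exp(F1 - F0))
    pxp = np.asarray(xp, float) * (1.0 - bor) + bor / K
    return pxp, float(bor)


def bms(
    lme,
    model_names=("hgf", "rw"),
    alpha0: float = 1.0,
    seed: int = 0,
) -> BMSResult:
    """Full random-effects model selection from an LME matrix."""
    lme = _check_lme(lme)
    alpha, u, n_iter = vb_dirichlet(lme, alpha0=alpha0, return_iters=True)
    xp = exceedance_prob(alpha, seed=seed)
    pxp, bor = protected_xp(lme, alpha, u, xp, alpha0=alpha0)
    F1 = _free_energy_rfx(lme, alpha, u, alpha0)
    return BMSResult(
        model_names=tuple(model_names),
        alpha=alpha,
        expected_r=alpha / alpha.sum(),
        xp=xp,
        pxp=pxp,
        bor=bor,
        u_nk=u,
        free_energy=F1,
        n_iter=n_iter,
    )


def lme_differences(lme) -> tuple[np.ndarray, int]:
    """Per-subject LME difference (model 1 - model 2) for a 2-model matrix.

    Returns the difference vector and the count of positive entries
    (subjects in which model 1 outperforms model 2).
    """
    lme = _check_lme(lme)
    if lme.shape[1] != 2:
        raise ValueError("LME differences are defined for exactly 2 models")
    d = lme[:, 0] - lme[:, 1]
    return d, int(np.sum(d > 0))
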