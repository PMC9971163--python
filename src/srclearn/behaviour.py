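"""Behavioural statistics for the SR-congruence task.

Implements the analysis battery applied to reaction times and model
trajectories: mismatch costs by probability context, the Friedman test with
Conover post-hocs and Kendall's W, the partial-eta-squared to Cohen's f
conversion used for power analysis, and volatility-by-context summaries
with a Greenhouse-Geisser-corrected repeated-measures ANOVA.

Mismatch cost is mean RT(match) - mean RT(mismatch) in milliseconds, so a
negative value means mismatching trials were slower (the classic cost).
Inferential tests on costs are restricted to the 0.3/0.5/0.7 contexts: in
the extreme contexts the rare trial type occurs only 8 times per subject,
too few for a stable cell mean.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "mismatch_cost",
    "friedman_test",
    "conover_posthoc",
    "cohens_f",
    "volatility_by_block",
    "FriedmanResult",
    "RMAnovaResult",
    "INFERENCE_CONTEXTS",
]

#: Contexts included in inferential tests on mismatch costs.
INFERENCE_CONTEXTS = (0.3, 0.5, 0.7)


@dataclass
class FriedmanResult:
    chi2: float
    df: int
    pvalue: float
    kendalls_w: float


@dataclass
class RMAnovaResult:
    """One-way repeated-measures ANOVA with sphericity correction."""

    F: float
    df_num: float            # Greenhouse-Geisser adjusted
    df_den: float
    pvalue: float            # GG-corrected
    gg_epsilon: float
    partial_eta_sq: float
    means: pd.DataFrame      # per (subject, context) cell means
    posthoc: pd.DataFrame    # Bonferroni-adjusted paired comparisons


def mismatch_cost(trials: pd.DataFrame, rt_col: str = "rt_s") -> pd.DataFrame:
    """Per subject-by-context mismatch cost in milliseconds.

    Missing trials are excluded; a (subject, context) cell lacking either
    trial type is omitted from the output rather than reported as zero.
    """
    df = trials.copy()
    if "missing" in df.columns:
        df = df[~df["missing"].astype(bool)]
    df = df[np.isfinite(df[rt_col])]
    rows = []
    for (sid, p), cell in df.groupby(["subject_id", "p_match"]):
        rt_match = cell.loc[cell["u"] == 1, rt_col]
        rt_mis = cell.loc[cell["u"] == 0, rt_col]
        if len(rt_match) == 0 or len(rt_mis) == 0:
            continue
        rows.append(
            {
                "subject_id": sid,
                "p_match": p,
                "cost_ms": 1000.0 * (rt_match.mean() - rt_mis.mean()),
                "n_match": len(rt_match),
                "n_mismatch": len(rt_mis),
            }
        )
    return pd.DataFrame(rows, columns=["subject_id", "p_match", "cost_ms",
                                       "n_match", "n_mismatch"])


def _rank_matrix(values: np.ndarray) -> np.ndarray:
    """Within-subject (row-wise) average ranks."""
    return np.apply_along_axis(stats.rankdata, 1, values)


def friedman_test(values) -> FriedmanResult:
    """Friedman rank test across k >= 3 repeated conditions.

    ``values`` is an n_subjects x k_conditions matrix with no missing
    entries.  Kendall's W is reported as chi2 / (n (k - 1)).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] < 3:
        raise ValueError("need a complete n x k matrix with k >= 3")
    if not np.all(np.isfinite(values)):
        raise ValueError("matrix must be complete (no missing values)")
    n, k = values.shape
    R = _rank_matrix(values)
    if np.allclose(R.var(axis=1), 0.0):   # no within-subject variation at all
        return FriedmanResult(chi2=0.0, df=k - 1, pvalue=1.0, kendalls_w=0.0)
    chi2, p = stats.friedmanchisquare(*values.T)
    return FriedmanResult(
        chi2=float(chi2), df=k - 1, pvalue=float(p),
        kendalls_w=float(chi2 / (n * (k - 1))),
    )


def conover_posthoc(values, labels=None) -> pd.DataFrame:
    """Conover's pairwise post-hoc comparisons after a Friedman test.

    Uses within-subject ranks: with column rank sums R_j, the statistic for
    a pair (i, j) is

        t = |R_i - R_j| / sqrt(2 n (A1 - B1) / ((n-1)(k-1))),

    where A1 is the sum of squared ranks and B1 = (1/n) sum_j R_j^2,
    referred to Student's t with (n-1)(k-1) degrees of freedom.  Both
    Bonferroni and Holm adjusted p-values are reported (capped at 1).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] < 3:
        raise ValueError("need a complete n x k matrix with k >= 3")
    if not np.all(np.isfinite(values)):
        raise ValueError("matrix must be complete (no missing values)")
    n, k = values.shape
    if labels is None:
        labels = [str(j) for j in range(k)]
    R = _rank_matrix(values)
    Rj = R.sum(axis=0)
    A1 = float(np.sum(R**2))
    B1 = float(np.sum(Rj**2)) / n
    df = (n - 1) * (k - 1)
    denom_sq = 2.0 * n * (A1 - B1) / df
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        if denom_sq <= 0:       # all columns identical: no rank variation
            t, p = 0.0, 1.0
        else:
            t = (Rj[i] - Rj[j]) / math.sqrt(denom_sq)
            p = 2.0 * stats.t.sf(abs(t), df)
        rows.append({"a": labels[i], "b": labels[j], "t_stat": t,
                     "df": df, "p_unadj": p})
    out = pd.DataFrame(rows)
    m = len(out)
    out["p_bonferroni"] = np.minimum(out["p_unadj"] * m, 1.0)
    order = np.argsort(out["p_unadj"].to_numpy())
    holm = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * out["p_unadj"].iloc[idx])
        holm[idx] = min(running, 1.0)
    out["p_holm"] = holm
    return out


def cohens_f(partial_eta_sq: float) -> float:
    """Convert partial eta-squared to Cohen's f: sqrt(eta2 / (1 - eta2))."""
    if not 0.0 <= partial_eta_sq < 1.0:
        raise ValueError("partial eta squared must lie in [0, 1)")
    return math.sqrt(partial_eta_sq / (1.0 - partial_eta_sq))


def volatility_by_block(
    trajectories: dict[str, "object"],
    schedules: pd.DataFrame,
    value: str = "mu3",
) -> RMAnovaResult:
    """Mean level-3 volatility per probability context, with rm-ANOVA.

    ``trajectories`` maps subject_id to an HGF trajectory aligned with that
    subject's rows of ``schedules`` (one row per trial, in trial order).
    Returns per-cell means, a one-way repeated-measures ANOVA across the
    five contexts with Greenhouse-Geisser correction, and paired t-tests
    Bonferroni-adjusted over all 10 context pairs.
    """
    import pingouin as pg

    cells = []
    for sid, traj in trajectories.items():
        sched = schedules[schedules["subject_id"] == sid].sort_values("trial")
        vals = np.asarray(getattr(traj, value))
        if len(vals) != len(sched):
            raise ValueError(f"trajectory/schedule length mismatch for {sid}")
        d = pd.DataFrame({"p_match": sched["p_match"].to_numpy(), value: vals})
        m = d.groupby("p_match")[value].mean()
        for p, v in m.items():
            cells.append({"subject_id": sid, "p_match": p, "mean_vol": v})
    means = pd.DataFrame(cells)

    aov = pg.rm_anova(
        data=means, dv="mean_vol", within="p_match", subject="subject_id",
        correction=True, detailed=True, effsize="np2",
    )
    row = aov.iloc[0]
    df1, df2 = float(row["DF"]), float(aov.iloc[1]["DF"])
    if "F" in aov.columns and np.isfinite(row.get("F", np.nan)):
        Fstat, np2 = float(row["F"]), float(row["np2"])
        eps = float(row.get("eps", 1.0))
        p_gg = row.get("p_GG_corr", np.nan)
        pval = float(p_gg) if np.isfinite(p_gg) else float(row["p_unc"])
    else:  # degenerate (e.g. constant input): no effect, no correction
        Fstat, np2, eps, pval = 0.0, 0.0, 1.0, 1.0

    contexts = sorted(means["p_match"].unique())
    wide = means.pivot(index="subject_id", columns="p_match", values="mean_vol")
    pairs = list(itertools.combinations(contexts, 2))
    ph_rows = []
    for a, b in pairs:
        diff = wide[a] - wide[b]
        if np.allclose(diff.std(ddof=1), 0.0):
            t, p = (0.0, 1.0) if np.allclose(diff.mean(), 0) else (np.inf, 0.0)
        else:
            t, p = stats.ttest_rel(wide[a], wide[b])
        ph_rows.append(
            {"a": a, "b": b, "mean_diff": float(diff.mean()),
             "se": float(diff.std(ddof=1) / np.sqrt(len(diff))),
             "t": float(t), "p_bonferroni": min(float(p) * len(pairs), 1.0)}
        )
    return RMAnovaResult(
        F=Fstat,
        df_num=df1 * eps,
        df_den=df2 * eps,
        pvalue=pval,
        gg_epsilon=eps,
        partial_eta_sq=np2,
        means=means,
        posthoc=pd.DataFrame(ph_rows),
    )
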