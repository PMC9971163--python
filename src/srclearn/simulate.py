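"""Synthetic cohorts for the SR-congruence task.

Generates complete per-subject trial tables with the statistical structure
the analysis pipeline assumes: the canonical 10-block/400-trial design,
trial-wise beliefs filtered by a generating perceptual model (HGF by
default, RW as an alternative), and reaction times drawn from the shifted
Wald drift-diffusion response model with belief-coupled drift.  Responses
slower than the task's 1-second window are recorded as missing, but their
binary input still updates beliefs, exactly as in the task.

Subject-level parameters are drawn around the analysis priors: omega2 ~
N(-4, 0.5^2), omega3 ~ N(-2, 0.5^2), drift base rate v0 ~ N(6, 0.5^2) and
coupling c ~ N(1, 0.25^2) truncated positive — heterogeneous but stable
cohorts.  Seeds are derived per subject with a counter-based scheme, so
adding subjects never perturbs earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import (
    DesignSequence,
    generate_trial_schedule,
    make_block_orders,
)
from .perceptual import HGFParams, RWParams, hgf_filter, rw_filter
from .response import WaldParams, drift_from_beliefs, wald_sample

__all__ = ["CohortSpec", "simulate_subject", "simulate_cohort", "ideal_observer",
           "RESPONSE_WINDOW_S"]

#: Responses beyond this window are not recorded.
RESPONSE_WINDOW_S = 1.0

TRIAL_TABLE_COLUMNS = [
    "subject_id", "trial", "block", "p_match", "u", "cue", "stimulus",
    "rt_s", "missing",
]


@dataclass(frozen=True)
class CohortSpec:
    """Generating conditions for a synthetic cohort."""

    n_subjects: int = 28
    seed: int = 0
    omega2_mean: float = -4.0
    omega2_sd: float = 0.5
    omega3_mean: float = -2.0
    omega3_sd: float = 0.5
    v0_mean: float = 6.0
    v0_sd: float = 0.5
    c_mean: float = 1.0
    c_sd: float = 0.25
    agent_model: str = "hgf"           # generating perceptual model
    rt_model: str = "wald"             # 'wald' or 'lognormal'
    lognormal_sigma: float = 0.15      # only for the log-normal alternative

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.agent_model not in ("hgf", "rw"):
            raise ValueError("agent_model must be 'hgf' or 'rw'")

    def subject_seed(self, i: int) -> int:
        """Counter-based per-subject seed; independent of cohort size."""
        ss = np.random.SeedSequence(self.seed, spawn_key=(i,))
        return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))

    def subject_params(self, i: int):
        rng = np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(i, 1))
        )
        if self.agent_model == "hgf":
            perceptual = HGFParams(
                omega2=rng.normal(self.omega2_mean, self.omega2_sd),
                omega3=rng.normal(self.omega3_mean, self.omega3_sd),
            )
        else:
            perceptual = RWParams(alpha=float(np.clip(rng.beta(3, 7), 0.01, 0.99)))
        v0 = max(rng.normal(self.v0_mean, self.v0_sd), 1.0)
        c = abs(rng.normal(self.c_mean, self.c_sd))
        return perceptual, WaldParams(v0=v0, c=c)


def simulate_subject(
    design: DesignSequence,
    perceptual_params,
    wald_params: WaldParams,
    subject_id: str = "S01",
    seed: int = 0,
    agent_model: str | None = None,
    rt_model: str = "wald",
    lognormal_sigma: float = 0.15,
) -> pd.DataFrame:
    """Simulate one subject's trial table.

    The schedule is generated under ``seed``, beliefs are filtered trial by
    trial with the generating perceptual model, drift couples the aligned
    belief (and, for the HGF, the volatility prediction) to the base rate,
    and RT is drawn from the shifted Wald.  RTs beyond the 1-s response
    window are recorded as missing (value removed); belief updates still
    see the input on those trials.
    """
    if agent_model is None:
        agent_model = "hgf" if isinstance(perceptual_params, HGFParams) else "rw"
    schedule = generate_trial_schedule(design, subject_id=subject_id, seed=seed)
    u = schedule["u"].to_numpy()
    if agent_model == "hgf":
        traj = hgf_filter(u, perceptual_params)
    else:
        traj = rw_filter(u, perceptual_params)
    drift = drift_from_beliefs(traj, u, wald_params, model=agent_model)
    rng_rt = np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(7,))
    )
    if rt_model == "wald":
        rt = rng_rt.wald(wald_params.a / drift, wald_params.a**2) + wald_params.t0
    elif rt_model == "lognormal":
        mean_rt = wald_params.a / drift + wald_params.t0
        rt = np.exp(rng_rt.normal(np.log(mean_rt), lognormal_sigma))
    else:
        raise ValueError("rt_model must be 'wald' or 'lognormal'")
    missing = rt > RESPONSE_WINDOW_S
    table = schedule.copy()
    table["rt_s"] = np.where(missing, np.nan, rt)
    table["missing"] = missing
    table.attrs["agent_model"] = agent_model
    table.attrs["params"] = {
        "perceptual": perceptual_params.__dict__,
        "wald": wald_params.__dict__,
    }
    return table


def simulate_cohort(spec: CohortSpec) -> list[pd.DataFrame]:
    """Simulate a full cohort; subjects alternate the two block orders."""
    order1, order2 = make_block_orders()
    tables = []
    for i in range(spec.n_subjects):
        design = order1 if i % 2 == 0 else order2
        perceptual, wald = spec.subject_params(i)
        tables.append(
            simulate_subject(
                design,
                perceptual,
                wald,
                subject_id=f"S{i + 1:02d}",
                seed=spec.subject_seed(i),
                agent_model=spec.agent_model,
                rt_model=spec.rt_model,
                lognormal_sigma=spec.lognormal_sigma,
            )
        )
    return tables


def ideal_observer(schedule: pd.DataFrame):
    """HGF trajectory at prior-mean parameters on a schedule's inputs.

    The reference trajectory for structural checks: omega2 = -4,
    omega3 = -2, default initial states.
    """
    return hgf_filter(schedule["u"].to_numpy(), HGFParams())
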