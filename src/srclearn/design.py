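"""Block structure and per-subject trial schedules for the SR-congruence task.

The task presents 400 trials in 10 blocks of 40.  Each block has a hidden
Bernoulli probability that the observed stimulus action matches the cued
response action, p(match) in {0.1, 0.3, 0.5, 0.7, 0.9}.  Each probability
context occurs twice, the first and last blocks are 0.5 contexts, and
consecutive blocks differ by at least 0.4 so context changes are salient.
Two counterbalanced block orders are used; the second is the first reversed.

Cue identity ("open" vs "close" action) is balanced 50:50 across the whole
schedule, so only the cue-relative congruence of the upcoming stimulus is
predictable, never the stimulus identity itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

P_LEVELS = (0.1, 0.3, 0.5, 0.7, 0.9)

#: Canonical first block order; the second order is its reverse.  Each of the
#: four non-0.5 contexts is visited once before any repeats, 0.5 bookends the
#: sequence, and all consecutive steps are >= 0.4.
CANONICAL_ORDER_1 = (0.5, 0.1, 0.7, 0.3, 0.9, 0.1, 0.7, 0.3, 0.9, 0.5)

MIN_STEP = 0.4

CUES = ("open", "close")

SCHEDULE_COLUMNS = ["subject_id", "trial", "block", "p_match", "u", "cue", "stimulus"]


class DesignError(ValueError):
    """A block sequence or schedule violates the task's design constraints."""


@dataclass(frozen=True)
class BlockSpec:
    """One block: hidden match probability and trial count."""

    p_match: float
    n_trials: int = 40

    def __post_init__(self) -> None:
        if not any(abs(self.p_match - p) < 1e-12 for p in P_LEVELS):
            raise DesignError(
                f"p_match must be one of {P_LEVELS}, got {self.p_match}"
            )
        if self.n_trials <= 0:
            raise DesignError("n_trials must be positive")

    @property
    def n_match(self) -> int:
        return int(round(self.p_match * self.n_trials))

    @property
    def n_mismatch(self) -> int:
        return self.n_trials - self.n_match


@dataclass(frozen=True)
class DesignSequence:
    """An ordered list of 10 blocks forming one counterbalancing order."""

    blocks: tuple[BlockSpec, ...]
    order_id: int = 1

    def __post_init__(self) -> None:
        validate_design(self)

    @property
    def p_sequence(self) -> tuple[float, ...]:
        return tuple(b.p_match for b in self.blocks)

    def reversed(self, order_id: int = 2) -> "DesignSequence":
        return DesignSequence(tuple(reversed(self.blocks)), order_id=order_id)


def validate_design(design: DesignSequence) -> None:
    ps = [b.p_match for b in design.blocks]
    if len(ps) != 10:
        raise DesignError(f"a design has 10 blocks, got {len(ps)}")
    for level in P_LEVELS:
        if sum(abs(p - level) < 1e-12 for p in ps) != 2:
            raise DesignError(f"context {level} must appear exactly twice")
    if abs(ps[0] - 0.5) > 1e-12 or abs(ps[-1] - 0.5) > 1e-12:
        raise DesignError("first and last blocks must be 0.5 contexts")
    steps = np.abs(np.diff(ps))
    if np.any(steps < MIN_STEP - 1e-12):
        raise DesignError(f"consecutive contexts must differ by >= {MIN_STEP}")


def make_block_orders(
    order_1: tuple[float, ...] = CANONICAL_ORDER_1,
    n_trials: int = 40,
) -> tuple[DesignSequence, DesignSequence]:
    """Return the canonical counterbalanced pair of block sequences.

    Deterministic: order 1 is the fixed canonical sequence (overridable),
    order 2 is its reverse.  Both are validated against every design
    constraint before being returned.
    """
    seq1 = DesignSequence(
        tuple(BlockSpec(p, n_trials) for p in order_1), order_id=1
    )
    return seq1, seq1.reversed()


def _balanced_cues(n: int, rng: np.random.Generator) -> np.ndarray:
    """Exactly half 'open', half 'close', in random order (n is even here)."""
    cues = np.array([CUES[0]] * (n // 2) + [CUES[1]] * (n - n // 2))
    rng.shuffle(cues)
    return cues


def generate_trial_schedule(
    design: DesignSequence,
    subject_id: str = "S01",
    seed: int = 0,
) -> pd.DataFrame:
    """Generate one subject's 400-trial schedule from a block design.

    Within each block the match/mismatch sequence is a uniformly random
    permutation of exactly ``round(p_match * n_trials)`` match trials under
    ``seed``.  Cues are balanced within every block-by-trial-type cell (all
    cell counts are even under the canonical design), which makes the cue
    ratio exactly 50:50 over the schedule and, because stimulus identity is
    cue on match trials and the other action on mismatch trials, the stimulus
    marginal exactly 50:50 as well.

    Returns a tidy DataFrame with columns ``subject_id, trial, block,
    p_match, u, cue, stimulus``; ``u`` is 1 on stimulus-response match
    trials, 0 on mismatch trials.
    """
    rng = np.random.default_rng(seed)
    rows: list[pd.DataFrame] = []
    trial0 = 0
    for b_idx, block in enumerate(design.blocks, start=1):
        u = np.zeros(block.n_trials, dtype=int)
        u[: block.n_match] = 1
        rng.shuffle(u)
        cue = np.empty(block.n_trials, dtype=object)
        for val in (1, 0):
            mask = u == val
            cue[mask] = _balanced_cues(int(mask.sum()), rng)
        other = {CUES[0]: CUES[1], CUES[1]: CUES[0]}
        stim = np.array([c if m else other[c] for c, m in zip(cue, u)])
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": subject_id,
                    "trial": np.arange(trial0 + 1, trial0 + block.n_trials + 1),
                    "block": b_idx,
                    "p_match": block.p_match,
                    "u": u,
                    "cue": cue,
                    "stimulus": stim,
                }
            )
        )
        trial0 += block.n_trials
    return pd.concat(rows, ignore_index=True)


def schedule_counts(schedule: pd.DataFrame) -> pd.DataFrame:
    """Tabulate match/mismatch trial counts per probability context."""
    if schedule.empty:
        return pd.DataFrame(columns=["p_match", "n_match", "n_mismatch"])
    g = schedule.groupby("p_match")["u"]
    out = pd.DataFrame(
        {
            "n_match": g.sum().astype(int),
            "n_mismatch": (g.count() - g.sum()).astype(int),
        }
    ).reset_index()
    return out
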