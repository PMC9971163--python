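"""CSV/JSON interchange for trial tables, trajectories and fit results.

Trial tables travel as plain CSV with RT in seconds; the log-ms conversion
used by the log-RT response model happens inside the model layer, never in
files.  Schema violations raise :class:`SchemaError` naming the offending
field.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "read_trial_table",
    "write_trial_table",
    "write_trajectory",
    "read_lme_table",
    "write_fit_result",
]

REQUIRED_COLUMNS = [
    "subject_id", "trial", "block", "p_match", "u", "cue", "stimulus",
    "rt_s", "missing",
]

RT_MAX_S = 10.0


class SchemaError(ValueError):
    """A trial table failed validation."""


def validate_trial_table(df: pd.DataFrame) -> pd.DataFrame:
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column: {col}")
    if not np.isin(df["u"].to_numpy(), (0, 1)).all():
        raise SchemaError("u: values must be binary (0/1)")
    df = df.copy()
    df["missing"] = df["missing"].astype(bool)
    rt = df["rt_s"].to_numpy(dtype=float)
    present = ~df["missing"].to_numpy()
    if np.any(~np.isfinite(rt[present])):
        raise SchemaError("rt_s: non-missing trials must have a finite RT")
    if np.any(rt[present] <= 0.0) or np.any(rt[present] > RT_MAX_S):
        raise SchemaError(f"rt_s: values must lie in (0, {RT_MAX_S}] seconds")
    return df


def read_trial_table(path) -> pd.DataFrame:
    """Read and validate a per-trial CSV table (RT in seconds)."""
    df = pd.read_csv(path)
    return validate_trial_table(df)


def write_trial_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def write_trajectory(traj, path) -> None:
    """One row per trial, trajectory fields as columns."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    traj.to_frame().to_csv(path, index=False)


def read_lme_table(path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a long CSV (subject_id, model, lme) into an LME matrix.

    Returns ``(matrix, subject_ids, model_names)`` with subjects as rows in
    first-appearance order and models as columns.
    """
    df = pd.read_csv(path)
    for col in ("subject_id", "model", "lme"):
        if col not in df.columns:
            raise SchemaError(f"missing required column: {col}")
    subjects = list(dict.fromkeys(df["subject_id"]))
    models = list(dict.fromkeys(df["model"]))
    wide = df.pivot(index="subject_id", columns="model", values="lme")
    wide = wide.loc[subjects, models]
    if wide.isna().any().any():
        raise SchemaError("lme: every subject needs an entry for every model")
    return wide.to_numpy(dtype=float), subjects, models


def write_fit_result(fit, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(fit.to_dict(), fh, indent=2)
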