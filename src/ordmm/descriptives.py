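"""Descriptive summaries of the long-format ordinal score table.

Complete-case by default: means, SDs and stage deltas use observed scores
only, since the descriptive surface precedes imputation in the pipeline;
pass an imputed dataset to summarise completed data instead.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import data as dio
from .data import N_SKILLS, N_CATEGORIES, STAGES


def category_proportions(df: pd.DataFrame, skill: int) -> pd.DataFrame:
    """Per-stage proportions of the four categories plus the missing share.

    Proportions are over all rows present at the stage, so the four category
    shares and the missing share sum to one.  Stages with no rows are
    returned with ``empty=True`` and zero shares rather than NaNs.
    """
    col = dio.skill_col(skill)
    out = []
    for t in STAGES:
        sub = df.loc[df["stage"] == t, col]
        n = len(sub)
        row: dict = {"stage": t, "n_rows": n, "empty": n == 0}
        if n == 0:
            for k in range(1, N_CATEGORIES + 1):
                row[f"p{k}"] = 0.0
            row["missing"] = 0.0
        else:
            for k in range(1, N_CATEGORIES + 1):
                row[f"p{k}"] = float((sub == k).sum()) / n
            row["missing"] = float(sub.isna().sum()) / n
        out.append(row)
    return pd.DataFrame(out)


def summary_table(df: pd.DataFrame) -> pd.DataFrame:
    """Mean, sample SD (n-1), counts and missing share per skill x stage,
    with stage deltas ``delta_next = mean(t+1) - mean(t)`` on observed scores."""
    rows = []
    for i in range(1, N_SKILLS + 1):
        col = dio.skill_col(i)
        means: dict[int, float] = {}
        for t in STAGES:
            sub = df.loc[df["stage"] == t, col]
            obs = sub.dropna().astype(float)
            n_obs = len(obs)
            mean = float(obs.mean()) if n_obs else np.nan
            sd = float(obs.std(ddof=1)) if n_obs > 1 else (0.0 if n_obs == 1 else np.nan)
            means[t] = mean
            rows.append(
                {
                    "skill": i,
                    "stage": t,
                    "mean": mean,
                    "sd": sd,
                    "n_observed": n_obs,
                    "missing_share": float(sub.isna().mean()) if len(sub) else np.nan,
                }
            )
        for t in STAGES:
            nxt = means.get(t + 1, np.nan)
            delta = nxt - means[t] if np.isfinite(means.get(t, np.nan)) else np.nan
            rows[-3 + t]["delta_next"] = delta
    return pd.DataFrame(rows)


def stage_deltas(summary: pd.DataFrame) -> pd.DataFrame:
    """Consecutive-stage mean differences per skill, from a summary_table frame."""
    out = []
    for i, grp in summary.groupby("skill"):
        g = grp.set_index("stage")["mean"]
        for t in STAGES[:-1]:
            if t in g.index and t + 1 in g.index:
                out.append({"skill": i, "from_stage": t, "to_stage": t + 1,
                            "delta": float(g[t + 1] - g[t])})
    return pd.DataFrame(out)
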