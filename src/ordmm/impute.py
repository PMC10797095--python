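"""Multiple imputation of missing ordinal scores by predictive mean matching.

Missing score cells are imputed m times on the wide (student x skill-stage)
score matrix with chained equations: each sweep regresses one incomplete
column on all other score columns plus cohort dummies, and replaces each
missing value with the observed outcome of a donor whose predicted mean is
closest to the target's prediction (type-1 matching: donors predicted with
the least-squares point estimate, targets with a posterior draw of the
coefficients).  Because donors are observed values, imputations always lie
on the ordinal support {1, 2, 3, 4}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import data as dio
from .data import N_SKILLS, STAGES


class RankDeficiencyError(ValueError):
    """Too few observed rows to fit the imputation regression; shrink the
    predictor set or pool columns."""


@dataclass(frozen=True)
class ImputationConfig:
    m: int = 5
    k_donors: int = 5
    n_cycles: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.m < 1 or self.k_donors < 1 or self.n_cycles < 1:
            raise ValueError("m, k_donors and n_cycles must all be >= 1")


@dataclass
class ImputedDataset:
    """One completed copy of the long table; ``provenance`` marks imputed cells."""

    dataset: pd.DataFrame
    index: int
    provenance: pd.DataFrame  # boolean, score columns only


def pmm_column(
    y_observed: np.ndarray,
    X_observed: np.ndarray,
    X_missing: np.ndarray,
    k_donors: int = 5,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Impute one column by predictive mean matching.

    Steps: least-squares fit of y on X over observed rows; a draw of the
    residual variance (scaled inverse chi-square) and of the coefficients
    from their approximate posterior; point-estimate predictions for
    observed rows and drawn-coefficient predictions for missing rows; for
    each missing row the k observed rows with nearest predictions form the
    donor pool (distance ties enlarge the pool) and a uniformly sampled
    donor's observed y is returned.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    y = np.asarray(y_observed, dtype=float)
    Xo = np.column_stack([np.ones(len(y)), np.asarray(X_observed, dtype=float)])
    Xm = np.column_stack([np.ones(len(X_missing)), np.asarray(X_missing, dtype=float)])
    n, p = Xo.shape
    if n < p + 1:
        raise RankDeficiencyError(
            f"{n} observed rows cannot support {p} regression parameters; "
            "reduce the predictor set"
        )
    if n < k_donors:
        raise RankDeficiencyError(f"fewer observed rows ({n}) than donors ({k_donors})")

    gram = Xo.T @ Xo
    # tiny ridge keeps collinear predictor sets (e.g. duplicated columns) workable
    gram += 1e-8 * np.eye(p) * max(1.0, np.trace(gram) / p)
    gram_inv = np.linalg.inv(gram)
    beta_hat = gram_inv @ (Xo.T @ y)
    resid = y - Xo @ beta_hat
    dof = max(n - p, 1)
    sigma2_draw = float(resid @ resid) / stats.chi2.rvs(dof, random_state=rng)
    L = np.linalg.cholesky(sigma2_draw * gram_inv + 1e-12 * np.eye(p))
    beta_draw = beta_hat + L @ rng.standard_normal(p)

    yhat_obs = Xo @ beta_hat           # donors: point estimates (type-1 matching)
    yhat_mis = Xm @ beta_draw          # targets: posterior draw

    out = np.empty(len(Xm))
    for j, pred in enumerate(yhat_mis):
        d = np.abs(yhat_obs - pred)
        if len(d) > k_donors:
            kth = np.partition(d, k_donors - 1)[k_donors - 1]
            pool = np.flatnonzero(d <= kth)      # ties enlarge the pool
        else:
            pool = np.arange(len(d))
        out[j] = y[pool[rng.integers(len(pool))]]
    return out


def _predictor_frame(wide: pd.DataFrame) -> pd.DataFrame:
    """Score columns plus 0/1 cohort dummies (first cohort as reference)."""
    score_cols = [c for c in wide.columns if c.startswith("sskill_")]
    X = wide[score_cols].astype(float).copy()
    dummies = pd.get_dummies(wide["cohort"], prefix="cohort", drop_first=True)
    for c in dummies.columns:
        X[c] = dummies[c].astype(float)
    return X


def multiple_impute(df: pd.DataFrame, config: ImputationConfig | None = None) -> list[ImputedDataset]:
    """Produce m completed copies of a validated long-format dataset.

    Targets are exactly the missing score cells of rows present in the
    table.  Wide cells with no underlying row (a student never assessed at a
    stage) are given working values so they can serve as predictors, but are
    never written back.  Observed cells are never modified.
    """
    config = config or ImputationConfig()
    wide = dio.to_wide_scores(df)
    score_cols = [c for c in wide.columns if c.startswith("sskill_")]
    score_mat = wide[score_cols].astype(float)
    observed = score_mat.notna()

    long_score_cols = [dio.skill_col(i) for i in range(1, N_SKILLS + 1)]
    provenance = df[long_score_cols].isna()

    if provenance.to_numpy().sum() == 0:
        return [ImputedDataset(df.copy(), j + 1, provenance.copy())
                for j in range(config.m)]

    incomplete = [c for c in score_cols if not observed[c].all()]
    for c in incomplete:
        if observed[c].sum() == 0:
            raise ValueError(f"column {c!r} has no observed values; cannot impute")

    master = np.random.SeedSequence(config.seed)
    copies: list[ImputedDataset] = []
    for j, child in enumerate(master.spawn(config.m), start=1):
        rng = np.random.default_rng(child)
        work = score_mat.copy()
        # initial fill: random draws from each column's observed values
        for c in incomplete:
            pool = work.loc[observed[c], c].to_numpy()
            miss = ~observed[c]
            work.loc[miss, c] = rng.choice(pool, size=int(miss.sum()), replace=True)

        for _ in range(config.n_cycles):
            for c in incomplete:
                X_all = _predictor_frame(wide.assign(**{col: work[col] for col in score_cols}))
                X_others = X_all.drop(columns=c)
                obs_mask = observed[c].to_numpy()
                y_obs = work.loc[observed[c], c].to_numpy()
                # keep the regression overdetermined on small donor pools by
                # restricting to the predictors most correlated with the target
                n_obs = int(obs_mask.sum())
                if n_obs < X_others.shape[1] + 2:
                    k = max(3, n_obs // 3)
                    with np.errstate(invalid="ignore", divide="ignore"):
                        corr = np.abs([
                            np.corrcoef(X_others.to_numpy()[obs_mask, j], y_obs)[0, 1]
                            for j in range(X_others.shape[1])
                        ])
                    corr = np.nan_to_num(corr)
                    keep = np.argsort(corr)[::-1][:k]
                    X_others = X_others.iloc[:, np.sort(keep)]
                Xo = X_others.to_numpy()
                imputed = pmm_column(
                    y_obs,
                    Xo[obs_mask],
                    Xo[~obs_mask],
                    k_donors=config.k_donors,
                    rng=rng,
                )
                work.loc[~observed[c], c] = imputed

        completed_wide = wide.copy()
        completed_wide[score_cols] = work
        completed = dio.fill_long_from_wide(completed_wide, df)
        copies.append(ImputedDataset(completed, j, provenance.copy()))
    return copies


def median_fill(df: pd.DataFrame) -> pd.DataFrame:
    """Baseline: fill every missing cell with its column's observed median score."""
    out = df.copy()
    for i in range(1, N_SKILLS + 1):
        col = dio.skill_col(i)
        med = out[col].dropna().astype(float).median()
        out.loc[out[col].isna(), col] = int(round(med)) if pd.notna(med) else pd.NA
    return out
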