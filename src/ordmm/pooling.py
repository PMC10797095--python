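"""Rubin's-rules pooling across imputed-dataset fits and post-hoc summaries.

Pooled point estimates are arithmetic means of per-imputation posterior
means; the total variance combines the average within-imputation posterior
variance W and the between-imputation variance B as W + (1 + 1/m) B.  The
between-only SE, sqrt((1 + 1/m) B), is reported alongside because published
multiple-imputation tables sometimes print only the between component (a
zero SE is only consistent with that convention); the statistically
complete total SE should be preferred for inference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .model import PosteriorFit


@dataclass
class PooledEstimate:
    pooled_mean: float
    within_var: float
    between_var: float
    m: int

    @property
    def total_se(self) -> float:
        return float(np.sqrt(self.within_var + (1 + 1 / self.m) * self.between_var))

    @property
    def between_only_se(self) -> float:
        return float(np.sqrt((1 + 1 / self.m) * self.between_var))

    @property
    def odds(self) -> float:
        return to_odds(self.pooled_mean)


def rubin_pool(means, variances) -> PooledEstimate:
    """Combine per-imputation posterior means and variances.

    With a single imputation the between-variance is zero (within-only);
    otherwise B is the sample variance (m-1 denominator) of the means.
    """
    means = np.asarray(means, dtype=float)
    variances = np.asarray(variances, dtype=float)
    if means.shape != variances.shape:
        raise ValueError("means and variances must have equal length")
    m = means.size
    if m < 1:
        raise ValueError("need at least one imputation")
    between = float(means.var(ddof=1)) if m > 1 else 0.0
    return PooledEstimate(
        pooled_mean=float(means.mean()),
        within_var=float(variances.mean()),
        between_var=between,
        m=m,
    )


def to_odds(logit_effect: float) -> float:
    """Multiplicative change in odds for a logit-scale effect: exp(x)."""
    if not np.isfinite(logit_effect):
        raise ValueError("logit effect must be finite")
    return float(np.exp(logit_effect))


@dataclass
class EffectRange:
    lower: float
    upper: float


def normal_range(mu: float, sigma: float, z: float = 1.96) -> EffectRange:
    """Central normal range mu +/- z*sigma (default ~95% of course effects)."""
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    return EffectRange(lower=mu - z * sigma, upper=mu + z * sigma)


def pool_parameter(fits: list[PosteriorFit], name: str) -> PooledEstimate:
    """Rubin-pool one named parameter across per-imputation fits."""
    means, variances = [], []
    for f in fits:
        row = f.param_summary(name)
        means.append(row["mean"])
        variances.append(row["sd"] ** 2)
    return rubin_pool(means, variances)


def course_effect_estimates(fits: list[PosteriorFit], shift_by_beta: bool = False) -> np.ndarray:
    """Per-course pooled posterior means of the course random effects u_c.

    ``fits`` are the per-imputation fits of one skill; they must share the
    course catalog.  With ``shift_by_beta`` the pooled mean course effect is
    added, centring the vector on the average-course effect instead of 0.
    """
    catalogs = {f.data.n_courses for f in fits}
    if len(catalogs) != 1:
        raise ValueError(f"fits disagree on course catalog size: {sorted(catalogs)}")
    C = catalogs.pop()
    pooled = np.array([
        pool_parameter(fits, f"u[{c + 1}]").pooled_mean for c in range(C)
    ])
    if shift_by_beta:
        pooled = pooled + pool_parameter(fits, "beta").pooled_mean
    return pooled


def cross_skill_correlation(u_matrix: np.ndarray) -> np.ndarray:
    """Pearson correlations of per-course effect estimates across skills.

    ``u_matrix`` is courses x skills.  Zero-variance columns yield NaN
    entries (flagged undefined) off the unit diagonal.
    """
    u = np.asarray(u_matrix, dtype=float)
    if u.shape[0] < 3:
        raise ValueError("need at least 3 courses for a correlation matrix")
    sd = u.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(u, rowvar=False)
    corr = np.asarray(corr)
    corr[np.eye(len(sd), dtype=bool)] = 1.0
    degenerate = sd == 0
    if degenerate.any():
        corr[degenerate, :] = np.nan
        corr[:, degenerate] = np.nan
        corr[np.eye(len(sd), dtype=bool)] = 1.0
    return corr


def effect_density(values, bandwidth: float | None = None,
                   n_grid: int = 512) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-kernel density of effect estimates on an explicit grid.

    Bandwidth defaults to Silverman's rule; all-equal inputs raise with a
    pointer to the explicit ``bandwidth`` argument.  The grid spans the data
    plus four bandwidths so the curve integrates to ~1 on the grid.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values for a density estimate")
    if values.std() == 0 and bandwidth is None:
        raise ValueError(
            "degenerate (all-equal) values: pass an explicit bandwidth")
    if bandwidth is None:
        kde = gaussian_kde(values, bw_method="silverman")
    else:
        sd = values.std(ddof=1)
        if sd == 0:
            # gaussian_kde factors the bandwidth by the data SD; emulate a
            # fixed-width kernel mixture directly for degenerate data
            grid = np.linspace(values[0] - 4 * bandwidth,
                               values[0] + 4 * bandwidth, n_grid)
            dens = np.exp(-0.5 * ((grid - values[0]) / bandwidth) ** 2)
            dens /= bandwidth * np.sqrt(2 * np.pi)
            return grid, dens
        kde = gaussian_kde(values, bw_method=bandwidth / sd)
    h = np.sqrt(kde.covariance[0, 0])
    grid = np.linspace(values.min() - 4 * h, values.max() + 4 * h, n_grid)
    return grid, kde(grid)


def pooled_effect_table(fits_by_skill: dict[int, list[PosteriorFit]]) -> pd.DataFrame:
    """Per-skill pooled effects: beta with both SE conventions, odds, and
    pooled random-effect SDs (one row per skill)."""
    rows = []
    for skill in sorted(fits_by_skill):
        fits = fits_by_skill[skill]
        beta = pool_parameter(fits, "beta")
        sc = pool_parameter(fits, "sigma_c")
        ss = pool_parameter(fits, "sigma_s")
        rng = normal_range(beta.pooled_mean, sc.pooled_mean)
        rows.append({
            "skill": skill,
            "beta": beta.pooled_mean,
            "between_only_se": beta.between_only_se,
            "total_se": beta.total_se,
            "odds": beta.odds,
            "sigma_c": sc.pooled_mean,
            "sigma_s": ss.pooled_mean,
            "effect_lower_95": rng.lower,
            "effect_upper_95": rng.upper,
            "max_rhat": max(f.max_rhat for f in fits),
        })
    return pd.DataFrame(rows)
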