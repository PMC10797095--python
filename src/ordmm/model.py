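"""Multiple-membership cumulative-logit mixed model, fitted by MCMC.

For skill ``i`` the model for student ``s`` at stage ``t`` is

    logit P(Y_st <= k) = alpha_k - eta_st,   k = 1..K-1
    eta_st = beta * N_st + sum_{c followed} u_c + theta_s

with ordered thresholds ``alpha``, a mean per-course effect ``beta``
multiplied by the cumulative course count ``N_st`` (membership dummies are
the unnormalised 0/1 indicators, not sum-to-one weights), course random
effects ``u_c ~ N(0, sigma_c)`` and student random effects
``theta_s ~ N(0, sigma_s)``.

Priors: improper flat on beta; half-t(3, 0, 2.5) on both standard
deviations; t(3, 0, 2.5) on each threshold subject to the ordering
constraint.  Sampling runs on an unconstrained parameterisation (first
threshold plus log-increments; log standard deviations; non-centred
course/student effects) with the package's NUTS engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, log_expit

from .data import ModelData, N_CATEGORIES
from .diagnostics import split_rhat
from .mcmc import nuts_sample


@dataclass(frozen=True)
class Priors:
    """Weakly-informative defaults mirroring common cumulative-logit practice."""

    sigma_df: float = 3.0
    sigma_scale: float = 2.5
    threshold_df: float = 3.0
    threshold_scale: float = 2.5

    def __post_init__(self):
        if self.sigma_scale <= 0 or self.threshold_scale <= 0:
            raise ValueError("prior scales must be positive")
        if self.sigma_df <= 0 or self.threshold_df <= 0:
            raise ValueError("prior degrees of freedom must be positive")


@dataclass(frozen=True)
class McmcConfig:
    """Chain layout; ``n_iter`` counts warm-up, so each chain retains
    ``n_iter - n_warmup`` draws."""

    n_chains: int = 4
    n_iter: int = 5000
    n_warmup: int = 1000
    target_accept: float = 0.8

    def __post_init__(self):
        if self.n_warmup >= self.n_iter:
            raise ValueError("n_warmup must be smaller than n_iter")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")

    @property
    def n_retained(self) -> int:
        return self.n_chains * (self.n_iter - self.n_warmup)

    @staticmethod
    def full_scale() -> "McmcConfig":
        """Full-scale preset: 4 chains x 5,000 iterations with 1,000 warm-up
        each, retaining 16,000 draws."""
        return McmcConfig(n_chains=4, n_iter=5000, n_warmup=1000)

    @staticmethod
    def desk() -> "McmcConfig":
        """Desk-scale preset for quick runs: 2 chains x 1,500 iterations."""
        return McmcConfig(n_chains=2, n_iter=1500, n_warmup=500)


@dataclass
class ModelParams:
    """One point in the constrained parameter space."""

    beta: float
    thresholds: np.ndarray    # (K-1,), strictly increasing
    sigma_c: float
    sigma_s: float
    u: np.ndarray             # (n_courses,)
    theta: np.ndarray         # (n_students,)


def _t_logpdf(x, df: float, scale: float):
    """Student-t log density, location 0."""
    c = (math.lgamma((df + 1) / 2) - math.lgamma(df / 2)
         - 0.5 * math.log(df * math.pi) - math.log(scale))
    return c - (df + 1) / 2 * np.log1p((np.asarray(x) / scale) ** 2 / df)


def _t_dlogpdf(x, df: float, scale: float):
    return -(df + 1) * np.asarray(x) / (df * scale**2 + np.asarray(x) ** 2)


def linear_predictor(beta: float, u: np.ndarray, theta: np.ndarray,
                     data: ModelData) -> np.ndarray:
    """Per-row linear combination ``eta = beta*N + sum(u over followed courses)
    + theta_student`` (logit units)."""
    return beta * data.counts + data.membership @ np.asarray(u, dtype=float) \
        + np.asarray(theta, dtype=float)[data.student_idx]


def category_probs(thresholds: np.ndarray, eta) -> np.ndarray:
    """Category probability vector(s) of length K from the cumulative logits.

    ``P(Y <= k) = expit(alpha_k - eta)``; positive ``eta`` shifts mass toward
    higher categories.  Raises on unordered thresholds.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if (np.diff(thresholds) <= 0).any():
        raise ValueError("thresholds must be strictly increasing")
    eta = np.asarray(eta, dtype=float)
    cum = expit(thresholds - eta[..., None])
    pad_shape = eta.shape + (1,)
    cum_full = np.concatenate(
        [np.zeros(pad_shape), cum, np.ones(pad_shape)], axis=-1)
    return np.diff(cum_full, axis=-1)


def _loglik_terms(thresholds: np.ndarray, eta: np.ndarray, y: np.ndarray):
    """Stable per-row log category probabilities and d(logp)/d(eta).

    Interior categories use log[sigmoid(a) - sigmoid(b)] =
    log sigmoid(a) + log sigmoid(-b) + log(1 - e^{b-a}), whose eta-gradient
    telescopes to sigmoid(b) - sigmoid(-a).
    """
    a1, a2, a3 = thresholds
    lp = np.empty_like(eta)
    deta = np.empty_like(eta)
    # per-threshold gradient accumulators (likelihood part)
    galpha = np.zeros(3)

    m = y == 1
    g1 = a1 - eta[m]
    lp[m] = log_expit(g1)
    s = expit(-g1)
    deta[m] = -s
    galpha[0] += s.sum()

    m = y == 4
    g3 = a3 - eta[m]
    lp[m] = log_expit(-g3)
    s = expit(g3)
    deta[m] = s
    galpha[2] -= s.sum()

    for k, (lo, hi) in ((2, (a1, a2)), (3, (a2, a3))):
        m = y == k
        if not m.any():
            continue
        b = lo - eta[m]
        a = hi - eta[m]
        d = hi - lo
        log_gap = np.log1p(-np.exp(-d))
        lp[m] = log_expit(a) + log_expit(-b) + log_gap
        r = 1.0 / np.expm1(d)
        sa = expit(-a)
        sb = expit(b)
        deta[m] = sb - sa
        galpha[k - 1] += (sa + r).sum()
        galpha[k - 2] += (-sb - r).sum()
    return lp, deta, galpha


def log_likelihood(params: ModelParams, data: ModelData) -> float:
    """Sum over rows of the log category probability of the observed score."""
    eta = linear_predictor(params.beta, params.u, params.theta, data)
    lp, _, _ = _loglik_terms(np.asarray(params.thresholds, dtype=float), eta, data.y)
    return float(lp.sum())


def log_prior(params: ModelParams, priors: Priors | None = None) -> float:
    """Joint log prior density on the constrained space (no Jacobians).

    Flat beta contributes zero; sigmas get half-t mass (``-inf`` outside the
    positive support); thresholds get t densities; u and theta get
    Normal(0, sigma) densities.
    """
    priors = priors or Priors()
    if params.sigma_c <= 0 or params.sigma_s <= 0:
        return -np.inf
    thr = np.asarray(params.thresholds, dtype=float)
    lp = float(_t_logpdf(thr, priors.threshold_df, priors.threshold_scale).sum())
    for s in (params.sigma_c, params.sigma_s):
        lp += math.log(2.0) + float(_t_logpdf(s, priors.sigma_df, priors.sigma_scale))
    for vec, s in ((params.u, params.sigma_c), (params.theta, params.sigma_s)):
        v = np.asarray(vec, dtype=float)
        lp += float(-0.5 * np.sum((v / s) ** 2) - v.size * (math.log(s)
                    + 0.5 * math.log(2 * math.pi)))
    return lp


@dataclass
class PosteriorFit:
    """MCMC output for one skill x one (imputed) dataset."""

    draws: dict                      # name -> array (chains, n_kept[, dim])
    summary: pd.DataFrame            # parameter, mean, sd, q2.5, q97.5, rhat
    config: McmcConfig
    data: ModelData
    skill: int
    imputation: int | None = None
    n_divergent: int = 0

    @property
    def max_rhat(self) -> float:
        return float(self.summary["rhat"].max())

    def param_summary(self, name: str) -> pd.Series:
        row = self.summary[self.summary["parameter"] == name]
        if row.empty:
            raise KeyError(name)
        return row.iloc[0]

    def credible_interval(self, name: str, level: float = 0.95) -> tuple[float, float]:
        lo = (1 - level) / 2
        flat = self._flat(name)
        return tuple(np.quantile(flat, [lo, 1 - lo]))

    def _flat(self, name: str) -> np.ndarray:
        if name in self.draws:
            return self.draws[name].reshape(-1)
        base, idx = name.rsplit("[", 1)
        return self.draws[base][..., int(idx[:-1]) - 1].reshape(-1)


def _make_logp_grad(data: ModelData, priors: Priors):
    """Build the unconstrained log-posterior-and-gradient closure.

    Row groups per outcome category, the membership matrix and its
    transpose are precomputed so each evaluation is a handful of
    vectorised operations; this is the sampler's hot path.

    The course count is centred internally (``eta`` uses ``N - mean(N)``
    and the sampled thresholds absorb ``beta * mean(N)``), a unit-Jacobian
    linear change of variables that removes the strong posterior ridge
    between ``beta`` and the thresholds; draws are mapped back on output.
    """
    y = data.y
    N = data.counts.astype(float)
    nbar = float(N.mean())
    Nc = N - nbar
    M = np.ascontiguousarray(data.membership)
    Mt = np.ascontiguousarray(M.T)
    sidx = data.student_idx
    C, S = data.n_courses, data.n_students
    tdf, tsc = priors.threshold_df, priors.threshold_scale
    sdf, ssc = priors.sigma_df, priors.sigma_scale
    i1, i2, i3, i4 = (np.flatnonzero(y == k) for k in (1, 2, 3, 4))
    n2, n3 = len(i2), len(i3)
    tvar_thr = tdf * tsc * tsc
    tvar_sig = sdf * ssc * ssc
    half = -(tdf + 1) / 2
    half_sig = -(sdf + 1) / 2

    def logp_grad(x: np.ndarray):
        # reject absurd log-scale excursions before they overflow/underflow exp()
        if max(x[2], x[3], x[4], x[5]) > 30.0 or min(x[2], x[3]) < -30.0:
            return -np.inf, np.zeros_like(x)
        beta = x[0]
        e2, e3 = math.exp(x[2]), math.exp(x[3])
        a1 = x[1]
        a2 = a1 + e2
        a3 = a2 + e3
        sigma_c, sigma_s = math.exp(x[4]), math.exp(x[5])
        z_u = x[6:6 + C]
        z_t = x[6 + C:6 + C + S]
        Mz = M @ z_u
        eta = beta * Nc + sigma_c * Mz + sigma_s * z_t[sidx]

        deta = np.empty_like(eta)
        logp = 0.0
        ga1 = ga2 = ga3 = 0.0

        # y == 1: log sigmoid(a1 - eta)
        g = a1 - eta[i1]
        s = expit(-g)
        logp += float(log_expit(g).sum())
        deta[i1] = -s
        ga1 += float(s.sum())
        # y == 4: log sigmoid(eta - a3)
        g = a3 - eta[i4]
        s = expit(g)
        logp += float(log_expit(-g).sum())
        deta[i4] = s
        ga3 -= float(s.sum())
        # y == 2: between a1 and a2 (gap e2 is row-constant)
        if n2:
            b = a1 - eta[i2]
            a = b + e2
            sa = expit(-a)
            sb = expit(b)
            r = 1.0 / math.expm1(e2) if e2 < 700.0 else 0.0
            logp += float(log_expit(a).sum() + log_expit(-b).sum()) \
                + n2 * math.log(-math.expm1(-e2))
            deta[i2] = sb - sa
            ga2 += float(sa.sum()) + n2 * r
            ga1 += -float(sb.sum()) - n2 * r
        # y == 3: between a2 and a3
        if n3:
            b = a2 - eta[i3]
            a = b + e3
            sa = expit(-a)
            sb = expit(b)
            r = 1.0 / math.expm1(e3) if e3 < 700.0 else 0.0
            logp += float(log_expit(a).sum() + log_expit(-b).sum()) \
                + n3 * math.log(-math.expm1(-e3))
            deta[i3] = sb - sa
            ga3 += float(sa.sum()) + n3 * r
            ga2 += -float(sb.sum()) - n3 * r

        # priors on the unconstrained target (Jacobians included); threshold
        # priors act on the reported thresholds alpha_k = a_k + beta * nbar
        shift = beta * nbar
        p1, p2, p3 = a1 + shift, a2 + shift, a3 + shift
        for a in (p1, p2, p3):
            logp += half * math.log1p(a * a / tvar_thr)
        logp += x[2] + x[3]
        logp += half_sig * math.log1p(sigma_c * sigma_c / tvar_sig) + x[4]
        logp += half_sig * math.log1p(sigma_s * sigma_s / tvar_sig) + x[5]
        zu_sq = float(z_u @ z_u)
        zt_sq = float(z_t @ z_t)
        logp += -0.5 * zu_sq - 0.5 * zt_sq

        dp1 = 2 * half * p1 / (tvar_thr + p1 * p1)
        dp2 = 2 * half * p2 / (tvar_thr + p2 * p2)
        dp3 = 2 * half * p3 / (tvar_thr + p3 * p3)
        ga1 += dp1
        ga2 += dp2
        ga3 += dp3

        grad = np.empty_like(x)
        grad[0] = float(deta @ Nc) + nbar * (dp1 + dp2 + dp3)
        grad[1] = ga1 + ga2 + ga3
        grad[2] = (ga2 + ga3) * e2 + 1.0
        grad[3] = ga3 * e3 + 1.0
        grad[4] = sigma_c * float(Mz @ deta) \
            + 2 * half_sig * sigma_c * sigma_c / (tvar_sig + sigma_c * sigma_c) + 1.0
        grad[5] = sigma_s * float(z_t[sidx] @ deta) \
            + 2 * half_sig * sigma_s * sigma_s / (tvar_sig + sigma_s * sigma_s) + 1.0
        grad[6:6 + C] = sigma_c * (Mt @ deta) - z_u
        grad[6 + C:] = sigma_s * np.bincount(sidx, weights=deta, minlength=S) - z_t
        return logp, grad

    logp_grad.nbar = nbar
    return logp_grad


def _initial_point(data: ModelData, rng: np.random.Generator) -> np.ndarray:
    """Empirical start: thresholds at the logits of the pooled cumulative
    score frequencies, small effects, moderate SDs, jittered per chain."""
    C, S = data.n_courses, data.n_students
    freq = np.array([(data.y <= k).mean() for k in range(1, N_CATEGORIES)])
    freq = np.clip(freq, 0.01, 0.99)
    freq = np.maximum.accumulate(freq + np.arange(3) * 1e-3)
    alpha0 = np.log(freq / (1 - freq))
    x = np.zeros(6 + C + S)
    x[1] = alpha0[0]
    x[2] = np.log(max(alpha0[1] - alpha0[0], 0.1))
    x[3] = np.log(max(alpha0[2] - alpha0[1], 0.1))
    x[4] = np.log(0.2)
    x[5] = np.log(0.3)
    x[:6] += 0.05 * rng.standard_normal(6)
    x[6:] = 0.1 * rng.standard_normal(C + S)
    return x


def constrain_draws(raw: np.ndarray, C: int, S: int, nbar: float = 0.0) -> dict:
    """Map unconstrained chain draws (chains, n, dim) to constrained blocks.

    ``nbar`` undoes the internal course-count centring: reported thresholds
    are the sampled ones plus ``beta * nbar``.
    """
    beta = raw[..., 0]
    a1 = raw[..., 1] + beta * nbar
    alpha2 = a1 + np.exp(raw[..., 2])
    alpha3 = alpha2 + np.exp(raw[..., 3])
    alpha = np.stack([a1, alpha2, alpha3], axis=-1)
    sigma_c = np.exp(raw[..., 4])
    sigma_s = np.exp(raw[..., 5])
    u = sigma_c[..., None] * raw[..., 6:6 + C]
    theta = sigma_s[..., None] * raw[..., 6 + C:6 + C + S]
    return {"beta": beta, "alpha": alpha, "sigma_c": sigma_c,
            "sigma_s": sigma_s, "u": u, "theta": theta}


def _summarise(draws: dict, C: int, S: int) -> pd.DataFrame:
    rows = []

    def add(name, arr):
        flat = arr.reshape(-1)
        rows.append({
            "parameter": name,
            "mean": float(flat.mean()),
            "sd": float(flat.std(ddof=1)),
            "q2.5": float(np.quantile(flat, 0.025)),
            "q97.5": float(np.quantile(flat, 0.975)),
            "rhat": split_rhat(arr),
        })

    add("beta", draws["beta"])
    for k in range(3):
        add(f"alpha[{k + 1}]", draws["alpha"][..., k])
    add("sigma_c", draws["sigma_c"])
    add("sigma_s", draws["sigma_s"])
    for c in range(C):
        add(f"u[{c + 1}]", draws["u"][..., c])
    for s in range(S):
        add(f"theta[{s + 1}]", draws["theta"][..., s])
    return pd.DataFrame(rows)


def fit(
    data: ModelData,
    priors: Priors | None = None,
    mcmc: McmcConfig | None = None,
    seed: int = 0,
    imputation: int | None = None,
) -> PosteriorFit:
    """Fit the model by NUTS and report per-parameter summaries and split
    R-hat for every parameter.

    Chains are seeded independently from ``seed``; a non-finite posterior at
    initialisation triggers re-jittered restarts (bounded) before failing.
    """
    if data.n_rows == 0:
        raise ValueError("cannot fit a model on empty data")
    priors = priors or Priors()
    mcmc = mcmc or McmcConfig()
    C, S = data.n_courses, data.n_students
    logp_grad = _make_logp_grad(data, priors)

    n_kept = mcmc.n_iter - mcmc.n_warmup
    raw = np.empty((mcmc.n_chains, n_kept, 6 + C + S))
    n_divergent = 0
    ss = np.random.SeedSequence(seed)
    for chain, child in enumerate(ss.spawn(mcmc.n_chains)):
        rng = np.random.default_rng(child)
        x0 = None
        for _ in range(10):
            cand = _initial_point(data, rng)
            if np.isfinite(logp_grad(cand)[0]):
                x0 = cand
                break
        if x0 is None:
            raise RuntimeError(
                "non-finite log posterior at initialisation after 10 attempts; "
                "check the data for empty categories or extreme counts")
        res = nuts_sample(logp_grad, x0, mcmc.n_warmup, n_kept, rng,
                          target_accept=mcmc.target_accept)
        raw[chain] = res.draws
        n_divergent += res.n_divergent

    draws = constrain_draws(raw, C, S, nbar=logp_grad.nbar)
    summary = _summarise(draws, C, S)
    return PosteriorFit(draws=draws, summary=summary, config=mcmc, data=data,
                        skill=data.skill, imputation=imputation,
                        n_divergent=n_divergent)
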