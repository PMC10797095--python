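"""Convergence diagnostics for multi-chain MCMC output.

Implements the rank-normalized split R-hat (bulk and folded variants, the
maximum reported), the standard between/within-chain variance-ratio
diagnostic computed on rank-normalized draws after splitting each chain in
half.  Values near 1 indicate mixing.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.special import ndtri


def _split_chains(draws: np.ndarray) -> np.ndarray:
    chains, n = draws.shape
    half = n // 2
    return np.concatenate([draws[:, :half], draws[:, n - half:]], axis=0)


def _rank_normalize(x: np.ndarray) -> np.ndarray:
    r = stats.rankdata(x, method="average").reshape(x.shape)
    return ndtri((r - 3.0 / 8) / (x.size + 1.0 / 4))


def _rhat_basic(seq: np.ndarray) -> float:
    m, n = seq.shape
    chain_means = seq.mean(axis=1)
    W = seq.var(axis=1, ddof=1).mean()
    B = n * chain_means.var(ddof=1)
    if W == 0:
        return 1.0
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def split_rhat(draws: np.ndarray) -> float:
    """Rank-normalized split R-hat of one scalar parameter.

    ``draws`` has shape (chains, n).  Each chain is split in half; ranks are
    taken over the pooled draws and mapped through the normal quantile
    function; the classic diagnostic is computed on the transformed draws
    and on their folded (|x - median|) counterpart, and the larger value is
    returned.  A constant parameter returns exactly 1.0 (nothing to mix) so
    degenerate blocks never propagate NaNs; callers may flag zero-variance
    parameters separately.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2:
        raise ValueError("draws must have shape (chains, n)")
    if draws.shape[0] < 2:
        raise ValueError("split R-hat needs at least 2 chains")
    if draws.shape[1] < 4:
        raise ValueError("need at least 4 draws per chain to split")
    if np.ptp(draws) == 0:
        return 1.0
    seq = _split_chains(draws)
    bulk = _rhat_basic(_rank_normalize(seq))
    folded = _rhat_basic(_rank_normalize(np.abs(seq - np.median(seq))))
    return max(bulk, folded)


def max_rhat(draw_blocks: dict) -> float:
    """Maximum split R-hat over every scalar parameter in a draws dict
    (arrays shaped (chains, n) or (chains, n, dim))."""
    worst = -np.inf
    for arr in draw_blocks.values():
        arr = np.asarray(arr)
        if arr.ndim == 2:
            worst = max(worst, split_rhat(arr))
        else:
            for j in range(arr.shape[-1]):
                worst = max(worst, split_rhat(arr[..., j]))
    return float(worst)
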