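"""Convergence diagnostics: split-chain potential scale reduction and ACF."""

from __future__ import annotations

import numpy as np

__all__ = ["gelman_rubin", "autocorrelation"]


def gelman_rubin(draws: np.ndarray) -> float:
    """Split-chain potential scale reduction factor (R-hat).

    ``draws`` is (chains, n) with at least 2 chains of >= 10 draws each.
    Each chain is split in half, and R-hat compares between- to within-
    sequence variance; values near 1 indicate the chains agree.
    """
    x = np.asarray(draws, dtype=float)
    if x.ndim != 2:
        raise ValueError("draws must be a (chains, draws) matrix")
    m, n = x.shape
    if m < 2:
        raise ValueError("R-hat needs at least 2 chains")
    if n < 10:
        raise ValueError("R-hat needs at least 10 draws per chain")
    half = n // 2
    seqs = np.concatenate([x[:, :half], x[:, n - half:]], axis=0)  # (2m, half)
    if np.ptp(seqs) == 0:
        return 1.0
    w = seqs.var(axis=1, ddof=1).mean()
    b_over_n = seqs.mean(axis=1).var(ddof=1)
    if w == 0:
        return np.inf
    var_plus = (half - 1) / half * w + b_over_n
    return float(np.sqrt(var_plus / w))


def gelman_rubin_all(draws: dict[str, np.ndarray]) -> dict[str, float]:
    """R-hat for every scalar in a dict of (chains, draws, ...) blocks."""
    out: dict[str, float] = {}
    for name, arr in draws.items():
        arr = np.asarray(arr)
        if arr.ndim == 2:
            out[name] = gelman_rubin(arr)
        else:
            flat = arr.reshape(arr.shape[0], arr.shape[1], -1)
            for idx in range(flat.shape[2]):
                out[f"{name}[{idx}]"] = gelman_rubin(flat[:, :, idx])
    return out


def autocorrelation(draws: np.ndarray, max_lag: int) -> np.ndarray:
    """Sample autocorrelation of a single chain at lags 0..max_lag.

    Standard biased estimator (normalised by the lag-0 autocovariance), so
    ``acf[0] == 1`` exactly.
    """
    x = np.asarray(draws, dtype=float).ravel()
    n = x.size
    if n <= max_lag:
        raise ValueError("need more draws than max_lag")
    z = x - x.mean()
    c0 = float(z @ z) / n
    if c0 == 0:
        raise ValueError("constant chain; autocorrelation undefined")
    acf = np.empty(max_lag + 1)
    for lag in range(max_lag + 1):
        acf[lag] = float(z[: n - lag] @ z[lag:]) / n / c0
    return acf
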