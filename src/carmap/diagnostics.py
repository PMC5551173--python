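"""Convergence diagnostics and posterior summaries.

Classic (non-split, non-rank-normalised) Brooks-Gelman-Rubin potential scale
reduction factor — the flavour contemporaneous with the WinBUGS-era
protocol this package mirrors — plus an autocorrelation-based effective
sample size with Geyer's initial-positive-sequence truncation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


def _as_matrix(chains, parameter: str | None):
    """Accept a ChainSet (+ parameter name) or a 1D/2D array of draws."""
    from .mcmc import ChainSet

    if isinstance(chains, ChainSet):
        if parameter is None:
            raise ValueError("a parameter name is required with a ChainSet")
        return chains.posterior_matrix(parameter)
    arr = np.asarray(chains, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.ndim != 2:
        raise ValueError("draws must be 1D (single chain) or 2D (chains x draws)")
    return arr


def gelman_rubin(chains, parameter: str | None = None, split: bool = False) -> float:
    """Potential scale reduction factor R-hat (>= ~1; near 1 at convergence).

    With ``split=True`` each chain is halved first (the modern split-R-hat
    variant); the default is the classic statistic.
    """
    x = _as_matrix(chains, parameter)
    if split:
        half = x.shape[1] // 2
        x = np.vstack([x[:, :half], x[:, half: 2 * half]])
    m, n = x.shape
    if m < 2:
        raise ValueError("R-hat requires at least two chains")
    if n < 10:
        raise ValueError("chains are too short for R-hat (need length >= 10)")
    w = x.var(axis=1, ddof=1).mean()
    b_over_n = x.mean(axis=1).var(ddof=1)
    if w == 0:
        return 1.0 if b_over_n == 0 else np.inf
    var_hat = (n - 1) / n * w + b_over_n
    return float(np.sqrt(var_hat / w))


def _ess_one(x: np.ndarray) -> float:
    n = x.size
    x = x - x.mean()
    var0 = np.dot(x, x) / n
    if var0 == 0 or n < 10:
        if var0 == 0:
            warnings.warn("constant chain: effective sample size floored at 1")
            return 1.0
        raise ValueError("chain too short for ESS (need length >= 10)")
    # autocovariance via FFT
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conjugate(f))[:n].real / n
    rho = acov / acov[0]
    # Geyer initial positive sequence: sum rho_{2k} + rho_{2k+1} while positive
    tau = -1.0
    k = 0
    while 2 * k + 1 < n:
        gamma = rho[2 * k] + rho[2 * k + 1]
        if gamma <= 0:
            break
        tau += 2.0 * gamma
        k += 1
    tau = max(tau, 1.0 / n)
    return float(max(n / tau, 1.0))


def effective_sample_size(chains, parameter: str | None = None) -> float:
    """Autocorrelation-based ESS (summed over chains), floored at 1.

    For an AR(1) chain with lag-1 correlation r the large-n value is
    n (1 - r) / (1 + r); iid draws give ESS ~ n.  A constant chain returns
    the floor value 1 with a warning.
    """
    x = _as_matrix(chains, parameter)
    return float(sum(_ess_one(row) for row in x))


def posterior_summary(chains, parameters: list[str] | None = None) -> pd.DataFrame:
    """Pooled posterior mean, sd (sample), and central 95% interval.

    ``chains`` is a ChainSet (all scalar parameters unless ``parameters``
    restricts them) or an array of draws for a single quantity.
    """
    from .mcmc import ChainSet

    if isinstance(chains, ChainSet):
        names = parameters if parameters is not None else chains.names
        rows = {name: chains.posterior(name) for name in names}
    else:
        rows = {"value": np.asarray(chains, dtype=float).ravel()}
    out = []
    for name, draws in rows.items():
        if draws.size == 0:
            raise ValueError(f"no post-burn-in draws for {name!r}")
        out.append(
            {
                "parameter": name,
                "mean": float(draws.mean()),
                "sd": float(draws.std(ddof=1)) if draws.size > 1 else 0.0,
                "q2.5": float(np.quantile(draws, 0.025)),
                "q97.5": float(np.quantile(draws, 0.975)),
            }
        )
    return pd.DataFrame(out).set_index("parameter")
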