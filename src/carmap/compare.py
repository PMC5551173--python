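"""Model comparison (DIC) and posterior effect extraction.

DIC is computed with the deviance focused at the latent level: the plug-in
deviance uses the posterior mean of the log relative risk eta itself (the
BUGS-era convention for hierarchical disease-mapping models), so

    p_D  = mean deviance - deviance(posterior mean eta),
    DIC  = mean deviance + p_D.

Lower DIC is better.  Also here: temporal (alpha_t) and seasonal (beta_q)
effect summaries, per-cell relative risks exp(eta), and the posterior
classification of per-area risk trajectories into increasing / decreasing /
persistently-high / no-trend classes.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .data import CountPanel, ExpectedCounts
from .diagnostics import posterior_summary
from .mcmc import ChainSet
from .model import ModelSpec, deviance as full_deviance


@dataclasses.dataclass(frozen=True)
class DicResult:
    dic: float
    mean_deviance: float
    p_d: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.p_d):
            raise ValueError("effective number of parameters is not finite")

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


def dic(
    chains: ChainSet,
    panel: CountPanel | np.ndarray,
    E: ExpectedCounts | np.ndarray,
    spec: ModelSpec | None = None,
) -> DicResult:
    """Deviance information criterion from a fitted chain set."""
    if chains.eta_mean is None:
        raise ValueError("chain set carries no posterior-mean latent field")
    counts = panel.counts if isinstance(panel, CountPanel) else np.asarray(panel)
    if counts.ndim == 1:
        counts = counts[:, None]
    e_vals = E.values if isinstance(E, ExpectedCounts) else np.asarray(E, float)
    if e_vals.ndim == 1:
        e_vals = e_vals[:, None]
    mean_dev = float(chains.posterior_deviance().mean())
    dev_at_mean = full_deviance(chains.eta_mean, counts, e_vals)
    p_d = mean_dev - dev_at_mean
    return DicResult(dic=mean_dev + p_d, mean_deviance=mean_dev, p_d=p_d)


def temporal_effect(chains: ChainSet) -> pd.DataFrame:
    """Posterior mean and 95% interval of the temporal trend alpha_t."""
    if not chains.spec.is_temporal:
        raise ValueError("temporal effect requires a spatio-temporal fit")
    names = [n for n in chains.names if n.startswith("alpha[")]
    if not names:
        raise ValueError("alpha was pinned in this fit; no temporal effect to report")
    table = posterior_summary(chains, names).reset_index()
    table["period"] = [int(n[6:-1]) for n in table["parameter"]]
    return table.sort_values("period").set_index("period").drop(columns="parameter")


def seasonal_effect(chains: ChainSet) -> pd.DataFrame:
    """Posterior summaries of beta_1..beta_3 plus exp-scale rate ratios.

    Rate ratios are relative to the reference trimester (the fourth,
    beta_4 = 0): exp(beta_q) multiplies the expected rate.
    """
    if not chains.spec.is_seasonal:
        raise ValueError("seasonal effect requires a quarterly fit")
    names = [n for n in chains.names if n.startswith("beta[")]
    table = posterior_summary(chains, names)
    rr = {
        name: float(np.exp(chains.posterior(name)).mean()) for name in names
    }
    table["rate_ratio"] = pd.Series(rr)
    table["rr_q2.5"] = [float(np.exp(np.quantile(chains.posterior(n), 0.025))) for n in names]
    table["rr_q97.5"] = [float(np.exp(np.quantile(chains.posterior(n), 0.975))) for n in names]
    return table


def relative_risks(chains: ChainSet) -> dict[str, np.ndarray]:
    """Per-cell posterior summaries of the relative risk exp(eta_it).

    Returns arrays of shape (n_areas, n_periods): posterior ``mean``,
    ``q2.5`` and ``q97.5``.
    """
    rr = np.exp(chains.eta_posterior_draws())
    return {
        "mean": rr.mean(axis=0),
        "q2.5": np.quantile(rr, 0.025, axis=0),
        "q97.5": np.quantile(rr, 0.975, axis=0),
    }


def classify_trends(
    rr_draws: np.ndarray,
    first_period_block,
    last_period_block,
    p_hi: float = 0.9,
) -> pd.DataFrame:
    """Classify each area's risk trajectory from posterior RR draws.

    Parameters
    ----------
    rr_draws
        Relative-risk draws, shape (n_draws, n_areas, n_periods).
    first_period_block, last_period_block
        Disjoint sequences of 0-based period indices (e.g. first year vs
        last year); an area's block-level RR per draw is the mean RR over
        the block's periods.
    p_hi
        Posterior-probability threshold (default 0.9).

    Rules, applied in order: ``increasing`` if P(RR_last > RR_first) >= p_hi;
    ``decreasing`` if P(RR_last < RR_first) >= p_hi; ``persistent_high``
    if P(RR > 1) >= p_hi in every block; otherwise ``none``.  Ties count
    toward neither direction, so identical blocks are ``none``.
    """
    rr_draws = np.asarray(rr_draws, dtype=float)
    if rr_draws.ndim != 3:
        raise ValueError("rr_draws must be (n_draws, n_areas, n_periods)")
    first = np.asarray(first_period_block, dtype=int)
    last = np.asarray(last_period_block, dtype=int)
    if np.intersect1d(first, last).size:
        raise ValueError("period blocks must not overlap")
    if not 0.5 < p_hi <= 1.0:
        raise ValueError("p_hi must be in (0.5, 1]")
    rr_first = rr_draws[:, :, first].mean(axis=2)  # (draws, areas)
    rr_last = rr_draws[:, :, last].mean(axis=2)
    p_inc = (rr_last > rr_first).mean(axis=0)
    p_dec = (rr_last < rr_first).mean(axis=0)
    p_high_first = (rr_first > 1.0).mean(axis=0)
    p_high_last = (rr_last > 1.0).mean(axis=0)
    p_high_min = np.minimum(p_high_first, p_high_last)
    labels = np.where(
        p_inc >= p_hi,
        "increasing",
        np.where(
            p_dec >= p_hi,
            "decreasing",
            np.where(p_high_min >= p_hi, "persistent_high", "none"),
        ),
    )
    return pd.DataFrame(
        {
            "label": labels,
            "p_increasing": p_inc,
            "p_high_first": p_high_first,
            "p_high_last": p_high_last,
        }
    )


def compare_models(results, labels: list[str] | None = None) -> pd.DataFrame:
    """DIC table over several fitted models, sorted ascending (best first).

    ``results`` is a sequence of :class:`~carmap.results.DiseaseMapResults`
    fitted to the *same* data.
    """
    rows = []
    ref_counts = None
    for k, res in enumerate(results):
        counts = res.model.panel.counts
        if ref_counts is None:
            ref_counts = counts
        elif counts.shape != ref_counts.shape or (counts != ref_counts).any():
            raise ValueError("models being compared were fitted to different data")
        d = res.dic()
        rows.append(
            {
                "model": labels[k] if labels else res.model.spec.variant,
                "dic": d.dic,
                "mean_deviance": d.mean_deviance,
                "p_d": d.p_d,
            }
        )
    return pd.DataFrame(rows).sort_values("dic").reset_index(drop=True)
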