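"""Results object returned by :meth:`DiseaseMapModel.fit`."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import compare as _compare
from .diagnostics import effective_sample_size, gelman_rubin, posterior_summary
from .mcmc import ChainSet


class DiseaseMapResults:
    """Posterior estimates, uncertainties and diagnostics of a fitted model.

    Thin façade over the stored :class:`~carmap.mcmc.ChainSet`: summaries are
    pooled post-burn-in draws, diagnostics are per-parameter R-hat / ESS, and
    the comparison/effect extraction functions of :mod:`carmap.compare` are
    exposed as methods.
    """

    def __init__(self, model, chains: ChainSet):
        self.model = model
        self.chains = chains

    # -- parameter summaries -------------------------------------------
    @property
    def params(self) -> pd.Series:
        """Posterior means of the scalar parameters."""
        return pd.Series(
            {name: float(self.chains.posterior(name).mean()) for name in self.chains.names}
        )

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        rows = {
            name: np.quantile(self.chains.posterior(name), [alpha / 2, 1 - alpha / 2])
            for name in self.chains.names
        }
        return pd.DataFrame(rows, index=["lower", "upper"]).T

    def rhat(self, parameter: str) -> float:
        return gelman_rubin(self.chains, parameter)

    def ess(self, parameter: str) -> float:
        return effective_sample_size(self.chains, parameter)

    def summary(self) -> pd.DataFrame:
        """Posterior mean, sd, 95% interval and, with >= 2 chains, R-hat/ESS."""
        table = posterior_summary(self.chains)
        if self.chains.n_chains >= 2:
            table["rhat"] = [self.rhat(n) for n in table.index]
            table["ess"] = [self.ess(n) for n in table.index]
        return table

    def __str__(self) -> str:
        spec = self.model.spec
        head = (
            f"{type(self).__name__}: variant={spec.variant}, "
            f"areas={spec.n_areas}, periods={spec.n_periods}, "
            f"chains={self.chains.n_chains} x {self.chains.n_iter} "
            f"(burn-in {self.chains.burn_in})"
        )
        with pd.option_context("display.float_format", "{:0.3f}".format):
            return head + "\n" + self.summary().to_string()

    # -- comparison / effects ------------------------------------------
    def dic(self) -> _compare.DicResult:
        return _compare.dic(
            self.chains, self.model.panel, self.model.exog_expected, self.model.spec
        )

    def temporal_effect(self) -> pd.DataFrame:
        return _compare.temporal_effect(self.chains)

    def seasonal_effect(self) -> pd.DataFrame:
        return _compare.seasonal_effect(self.chains)

    def relative_risks(self) -> dict[str, np.ndarray]:
        return _compare.relative_risks(self.chains)

    def classify_trends(
        self,
        first_period_block=None,
        last_period_block=None,
        p_hi: float = 0.9,
    ) -> pd.DataFrame:
        """Trend classes per area; defaults compare first vs last year."""
        T = self.model.spec.n_periods
        block = min(4, T // 2) if self.model.spec.is_seasonal else 1
        if first_period_block is None:
            first_period_block = list(range(block))
        if last_period_block is None:
            last_period_block = list(range(T - block, T))
        rr = np.exp(self.chains.eta_posterior_draws())
        return _compare.classify_trends(rr, first_period_block, last_period_block, p_hi)

    # -- persistence ----------------------------------------------------
    def save(self, outdir) -> None:
        """Write per-chain CSVs, the run manifest, and the summary table."""
        outdir = Path(outdir)
        self.chains.save(outdir)
        self.summary().to_csv(outdir / "summary.csv")

    # -- plotting (optional, line plots only) ---------------------------
    def plot_temporal_effect(self, ax=None):
        import matplotlib.pyplot as plt

        table = self.temporal_effect()
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(table.index, table["mean"], marker="o", color="C0")
        ax.fill_between(table.index, table["q2.5"], table["q97.5"], alpha=0.25)
        ax.axhline(0.0, color="grey", lw=0.8)
        ax.set_xlabel("period")
        ax.set_ylabel(r"temporal effect $\alpha_t$")
        return ax

    def plot_rr_trajectories(self, areas=None, ax=None):
        import matplotlib.pyplot as plt

        rr = self.relative_risks()["mean"]
        if areas is None:
            areas = np.argsort(rr.mean(axis=1))[-5:]
        if ax is None:
            _, ax = plt.subplots()
        for i in areas:
            ax.plot(np.arange(1, rr.shape[1] + 1), rr[i], label=f"area {i + 1}")
        ax.axhline(1.0, color="grey", lw=0.8)
        ax.set_xlabel("period")
        ax.set_ylabel("relative risk")
        ax.legend(fontsize="small")
        return ax
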