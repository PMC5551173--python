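import numpy as np
import pytest

from carmap.compare import (
    DicResult,
    classify_trends,
    compare_models,
    dic,
    relative_risks,
    seasonal_effect,
    temporal_effect,
)
from carmap.data import CountPanel, ExpectedCounts
from carmap.graphs import build_lattice_graph
from carmap.mcmc import ChainSet, McmcConfig
from carmap.model import DiseaseMapModel, ModelSpec, ParameterState, deviance
from carmap.simulate import generate_study, simulate_spatial, simulate_st


def _manual_chainset(spec, deviance_trace, eta_mean, names=("mu",)):
    n_iter = deviance_trace.shape[1]
    return ChainSet(
        names=list(names),
        draws=np.zeros((deviance_trace.shape[0], n_iter, len(names))),
        deviance=deviance_trace,
        burn_in=0,
        spec=spec,
        config=McmcConfig(n_chains=deviance_trace.shape[0], n_iter=n_iter, burn_in=0),
        eta_mean=eta_mean,
        eta_draws=None,
        accept_rates={},
    )


class TestDic:
    def test_constant_deviance_gives_zero_pd(self):
        spec = ModelSpec("spatial", 4, 1)
        counts = np.array([[2], [3], [1], [0]])
        E = np.full((4, 1), 1.5)
        eta_mean = np.full((4, 1), 0.2)
        d0 = deviance(eta_mean, counts, E)
        cs = _manual_chainset(spec, np.full((2, 50), d0), eta_mean)
        res = dic(cs, counts, E)
        assert res.p_d == pytest.approx(0.0, abs=1e-9)
        assert res.dic == pytest.approx(d0)

    def test_identity_holds_exactly(self, small_quarterly_fit):
        _, result = small_quarterly_fit
        d = result.dic()
        assert d.dic == pytest.approx(d.mean_deviance + d.p_d, rel=1e-12)

    def test_pd_counts_free_parameters_in_fixed_effects_model(self):
        """A Poisson model with only an intercept has p_D ~ 1."""
        g = build_lattice_graph(5, 5)
        counts = simulate_spatial(
            {"mu": 0.1, "sigma_phi": 0.0, "sigma_theta": 0.0},
            g, np.full(25, 40.0), seed=8,
        )
        model = DiseaseMapModel(
            counts, g, variant="spatial",
            expected=ExpectedCounts(np.full((25, 1), 40.0)),
            fixed={"sigma_phi": 0.0, "sigma_theta": 0.0},
        )
        res = model.fit(config=McmcConfig(n_chains=2, n_iter=3_000, burn_in=500, seed=8))
        assert res.dic().p_d == pytest.approx(1.0, abs=0.35)

    def test_invalid_pd_rejected(self):
        with pytest.raises(ValueError):
            DicResult(dic=np.nan, mean_deviance=np.nan, p_d=np.nan)


class TestTemporalEffect:
    def test_spatial_chains_rejected(self, conjugate_fit):
        with pytest.raises(ValueError):
            temporal_effect(conjugate_fit.chains)

    def test_summaries_sum_to_zero(self, small_quarterly_fit):
        _, result = small_quarterly_fit
        table = result.temporal_effect()
        assert len(table) == 12
        assert table["mean"].sum() == pytest.approx(0.0, abs=1e-9)

    def test_recovers_linear_trend(self):
        """A deterministic increasing alpha truth must come back monotone up
        to Monte-Carlo error (strongly rank-correlated with the truth)."""
        g = build_lattice_graph(5, 5)
        T = 6
        alpha_truth = np.linspace(-0.5, 0.5, T)
        alpha_truth -= alpha_truth.mean()
        truth = ParameterState.zeros(
            ModelSpec("st_annual", 25, T),
            rho=0.0, sigma_phi=0.0, sigma_theta=0.0, sigma_alpha=0.0,
        )
        truth.alpha = alpha_truth
        panel = simulate_st(truth, g, np.full(25, 15.0), n_periods=T, seed=2)
        model = DiseaseMapModel(
            panel, g, variant="st_annual",
            expected=ExpectedCounts(np.full((25, T), 15.0)),
        )
        res = model.fit(config=McmcConfig(n_chains=2, n_iter=2_500, burn_in=600, seed=2))
        est = res.temporal_effect()["mean"].to_numpy()
        corr = np.corrcoef(est, alpha_truth)[0, 1]
        assert corr > 0.95
        assert est[-1] > est[0] + 0.5


class TestSeasonalEffect:
    def test_nonseasonal_chains_rejected(self, conjugate_fit):
        with pytest.raises(ValueError):
            seasonal_effect(conjugate_fit.chains)

    def test_well_powered_recovery(self, small_quarterly_fit):
        study, result = small_quarterly_fit
        table = result.seasonal_effect()
        truth = study.truth.beta
        for k in range(3):
            row = table.loc[f"beta[{k + 1}]"]
            assert row["q2.5"] <= truth[k] <= row["q97.5"]
        # the large third-trimester effect is resolved away from zero
        assert table.loc["beta[3]", "q2.5"] > 0.0
        # rate ratios are on the exp scale relative to trimester 4
        assert table.loc["beta[3]", "rate_ratio"] == pytest.approx(
            np.exp(result.params["beta[3]"]), rel=0.05
        )

    def test_rate_ratio_arithmetic(self):
        assert np.exp(0.118) == pytest.approx(1.125, abs=0.002)


class TestRelativeRisks:
    def test_dimensions_and_null_truth(self, conjugate_fit):
        rr = relative_risks(conjugate_fit.chains)
        assert rr["mean"].shape == (4, 1)
        # all-zero latent truth: RR ~ exp(mu_hat) = 100/90
        assert np.allclose(rr["mean"], 100 / 90, rtol=0.05)

    def test_doubled_risk_area_recovered(self):
        g = build_lattice_graph(5, 5)
        theta = np.zeros((25, 1))
        theta[12, 0] = np.log(2.0)
        truth = ParameterState.zeros(ModelSpec("spatial", 25, 1))
        truth.theta = theta
        panel = simulate_spatial(truth, g, np.full(25, 30.0), seed=6)
        model = DiseaseMapModel(
            panel, g, variant="spatial",
            expected=ExpectedCounts(np.full((25, 1), 30.0)),
        )
        res = model.fit(config=McmcConfig(n_chains=2, n_iter=2_000, burn_in=500, seed=6))
        rr = res.relative_risks()
        assert rr["q2.5"][12, 0] <= 2.0 <= rr["q97.5"][12, 0]
        assert rr["mean"][12, 0] == pytest.approx(2.0, rel=0.25)


class TestClassifyTrends:
    def _draws(self, path_first, path_last, n_draws=400, noise=0.05, seed=0):
        rng = np.random.default_rng(seed)
        n_areas = len(path_first)
        rr = np.empty((n_draws, n_areas, 4))
        for a in range(n_areas):
            rr[:, a, :2] = path_first[a] * np.exp(rng.normal(0, noise, (n_draws, 2)))
            rr[:, a, 2:] = path_last[a] * np.exp(rng.normal(0, noise, (n_draws, 2)))
        return rr

    def test_construction_examples(self):
        rr = self._draws(
            path_first=[0.8, 2.0, 1.0, 1.0],
            path_last=[2.0, 0.8, 1.0, 2.0],
        )
        rr[:, 2, :] = 1.0  # exactly flat at the null
        labels = classify_trends(rr, [0, 1], [2, 3], p_hi=0.9)["label"]
        assert labels[0] == "increasing"
        assert labels[1] == "decreasing"
        assert labels[2] == "none"
        assert labels[3] == "increasing"

    def test_persistent_high(self):
        rr = self._draws(path_first=[2.0], path_last=[2.0])
        out = classify_trends(rr, [0, 1], [2, 3], p_hi=0.9)
        assert out["label"][0] == "persistent_high"
        assert out["p_high_first"][0] >= 0.9

    def test_flat_draws_are_none(self):
        rr = np.ones((100, 3, 4))
        labels = classify_trends(rr, [0, 1], [2, 3])["label"]
        assert (labels == "none").all()

    def test_overlapping_blocks_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            classify_trends(np.ones((10, 2, 4)), [0, 1], [1, 2])

    def test_invariant_to_draw_permutation(self):
        rr = self._draws(path_first=[0.9, 1.5], path_last=[1.8, 1.4], seed=3)
        out1 = classify_trends(rr, [0, 1], [2, 3])
        perm = np.random.default_rng(4).permutation(rr.shape[0])
        out2 = classify_trends(rr[perm], [0, 1], [2, 3])
        assert (out1["label"] == out2["label"]).all()
        assert np.allclose(out1["p_increasing"], out2["p_increasing"])


class TestCompareModels:
    def test_table_sorted_and_consistent(self, small_quarterly_fit):
        study, result = small_quarterly_fit
        other = DiseaseMapModel(
            study.panel, study.graph, variant="st_quarterly_rho0",
            expected=study.expected,
        ).fit(config=McmcConfig(n_chains=1, n_iter=1_200, burn_in=300, seed=11))
        table = compare_models([result, other])
        assert list(table.columns) == ["model", "dic", "mean_deviance", "p_d"]
        assert table["dic"].is_monotonic_increasing

    def test_mismatched_data_rejected(self, small_quarterly_fit, conjugate_fit):
        _, result = small_quarterly_fit
        with pytest.raises(ValueError, match="different data"):
            compare_models([result, conjugate_fit])


class TestPlots:
    def test_line_plots_render(self, small_quarterly_fit, tmp_path):
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        _, result = small_quarterly_fit
        ax = result.plot_temporal_effect()
        assert ax.get_xlabel() == "period"
        ax2 = result.plot_rr_trajectories(areas=[0, 5])
        assert len(ax2.get_lines()) >= 2
        fig = ax.get_figure()
        fig.savefig(tmp_path / "temporal.png")
        assert (tmp_path / "temporal.png").exists()
        plt.close("all")
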