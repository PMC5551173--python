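import numpy as np
import pytest

from carmap.data import CountPanel, ExpectedCounts
from carmap.graphs import build_lattice_graph
from carmap.model import (
    DiseaseMapModel,
    ModelSpec,
    ParameterState,
    linear_predictor,
    log_posterior,
    residual_field,
)


@pytest.fixture()
def g4():
    return build_lattice_graph(2, 2)


def _random_state(spec, seed, **scalars):
    rng = np.random.default_rng(seed)
    state = ParameterState.zeros(spec)
    state.phi = rng.normal(0, 0.3, size=(spec.n_areas, spec.n_periods))
    state.phi -= state.phi.mean(axis=0, keepdims=True)
    state.theta = rng.normal(0, 0.3, size=(spec.n_areas, spec.n_periods))
    alpha = rng.normal(0, 0.2, size=spec.n_periods)
    state.alpha = alpha - alpha.mean()
    state.beta = rng.normal(0, 0.2, size=3)
    state.sigma_phi = state.sigma_theta = 0.4
    state.sigma_alpha = 0.2
    state.rho = 0.5
    for key, val in scalars.items():
        setattr(state, key, val)
    return state


class TestLinearPredictor:
    def test_spatial_all_zero_effects_is_mu(self, g4):
        spec = ModelSpec("spatial", 4, 1)
        eta = linear_predictor(ParameterState.zeros(spec, mu=0.7), spec)
        assert np.allclose(eta, 0.7)

    def test_first_period_no_scaling_at_rho_zero(self):
        spec = ModelSpec("st_annual", 4, 3)
        state = _random_state(spec, 0, rho=0.0)
        eta = linear_predictor(state, spec)
        expected = state.mu + state.alpha[0] + state.phi[:, 0] + state.theta[:, 0]
        assert np.allclose(eta[:, 0], expected)

    def test_first_period_scale_factor(self):
        # (1 - 0.6^2)^(-1/2) = 1.25
        spec = ModelSpec("st_annual", 4, 3)
        state = _random_state(spec, 1, rho=0.6)
        eta = linear_predictor(state, spec)
        psi1 = state.phi[:, 0] + state.theta[:, 0]
        assert np.allclose(eta[:, 0] - state.mu - state.alpha[0], 1.25 * psi1)

    @pytest.mark.parametrize("variant", ["st_annual", "st_quarterly"])
    def test_autoregressive_recursion_identity(self, variant):
        """eta must satisfy the defining recursion: the residual after
        removing the fixed part is rho times the previous residual plus the
        current innovation."""
        spec = ModelSpec(variant, 4, 8)
        state = _random_state(spec, 2, rho=0.7)
        eta = linear_predictor(state, spec)
        beta4 = np.append(state.beta, 0.0)
        seas = beta4[spec.season - 1] if spec.is_seasonal else np.zeros(8)
        fixed = state.mu + state.alpha + seas
        resid = eta - fixed[None, :]
        psi = state.phi + state.theta
        for t in range(1, 8):
            assert np.allclose(resid[:, t], 0.7 * resid[:, t - 1] + psi[:, t])

    def test_seasonal_offsets_use_reference_category(self):
        spec = ModelSpec("st_quarterly", 4, 8)
        state = ParameterState.zeros(spec, beta=np.array([-0.1, 0.2, 0.3]))
        eta = linear_predictor(state, spec)
        # trimester 4 (periods 4, 8) carries no seasonal offset
        assert np.allclose(eta[:, 3], 0.0)
        assert np.allclose(eta[:, 7], 0.0)
        assert np.allclose(eta[:, 1], 0.2)

    def test_stationary_residual_variance(self):
        """With the first-period scaling, the prior variance of the residual
        field is constant in t (checked in closed form for iid theta only)."""
        spec = ModelSpec("st_annual", 4, 6)
        rng = np.random.default_rng(3)
        rho, s = 0.8, 0.5
        reps = 30_000
        var_t = np.zeros(6)
        psi = rng.normal(0, s, size=(reps, 6))
        r = np.empty_like(psi)
        r[:, 0] = psi[:, 0] / np.sqrt(1 - rho**2)
        for t in range(1, 6):
            r[:, t] = rho * r[:, t - 1] + psi[:, t]
        var_t = r.var(axis=0)
        assert np.allclose(var_t, s**2 / (1 - rho**2), rtol=0.05)

    def test_shape_mismatch_rejected(self):
        spec = ModelSpec("st_annual", 4, 3)
        state = ParameterState.zeros(ModelSpec("st_annual", 9, 3))
        with pytest.raises(ValueError, match="shape"):
            linear_predictor(state, spec)


class TestLogPosterior:
    def _inputs(self, g4, variant="spatial", T=1):
        spec = ModelSpec(variant, 4, T)
        rng = np.random.default_rng(7)
        counts = rng.integers(0, 6, size=(4, T))
        E = np.full((4, T), 2.0)
        return spec, CountPanel(counts, populations=[10] * 4), ExpectedCounts(E)

    def test_out_of_support_sigma_gives_minus_inf(self, g4):
        spec, panel, E = self._inputs(g4)
        state = _random_state(spec, 0, sigma_theta=1.5)
        assert log_posterior(state, panel, E, spec, g4) == -np.inf
        state = _random_state(spec, 0, sigma_theta=0.0)
        assert log_posterior(state, panel, E, spec, g4) == -np.inf

    def test_out_of_support_rho_gives_minus_inf(self, g4):
        spec = ModelSpec("st_annual", 4, 3)
        panel = CountPanel(np.ones((4, 3), int), populations=[10] * 4)
        E = ExpectedCounts(np.ones((4, 3)))
        state = _random_state(spec, 1, rho=1.0)
        assert log_posterior(state, panel, E, spec, g4) == -np.inf

    def test_poisson_score_maximum_at_log_ratio(self, g4):
        """With no random effects, the log posterior in mu is maximised at
        log(sum O / sum E) (the Poisson score equation)."""
        spec = ModelSpec(
            "spatial", 4, 1, fixed={"sigma_phi": 0.0, "sigma_theta": 0.0}
        )
        panel = CountPanel(np.array([[5], [3], [2], [0]]), populations=[10] * 4)
        E = ExpectedCounts(np.full((4, 1), 2.0))
        opt = np.log(10 / 8)

        def lp(mu):
            return log_posterior(
                ParameterState.zeros(spec, mu=mu), panel, E, spec, g4
            )

        eps = 1e-5
        grad = (lp(opt + eps) - lp(opt - eps)) / (2 * eps)
        assert grad == pytest.approx(0.0, abs=1e-6)
        assert lp(opt) > lp(opt + 0.3)
        assert lp(opt) > lp(opt - 0.3)

    def test_shift_invariance_phi_vs_mu(self, g4):
        """Adding a constant to phi while subtracting it from mu leaves the
        likelihood part unchanged; the ICAR term is shift-invariant, so the
        whole log posterior is unchanged (the flat direction the sum-to-zero
        constraint removes)."""
        spec, panel, E = self._inputs(g4)
        state = _random_state(spec, 5)
        shifted = state.copy()
        shifted.phi = state.phi + 0.37
        shifted.mu = state.mu - 0.37
        a = log_posterior(state, panel, E, spec, g4)
        b = log_posterior(shifted, panel, E, spec, g4)
        assert a == pytest.approx(b, rel=1e-12)

    def test_gradient_wrt_mu_matches_analytic(self, g4):
        spec, panel, E = self._inputs(g4)
        state = _random_state(spec, 8)
        eta = linear_predictor(state, spec)
        analytic = panel.counts.sum() - (E.values * np.exp(eta)).sum()
        eps = 1e-6

        def lp(mu):
            s = state.copy()
            s.mu = mu
            return log_posterior(s, panel, E, spec, g4)

        numeric = (lp(state.mu + eps) - lp(state.mu - eps)) / (2 * eps)
        assert numeric == pytest.approx(analytic, rel=1e-5)

    def test_gradient_wrt_beta_matches_analytic(self, g4):
        spec = ModelSpec("st_quarterly", 4, 8)
        rng = np.random.default_rng(9)
        panel = CountPanel(rng.integers(0, 5, size=(4, 8)), populations=[10] * 4)
        E = ExpectedCounts(np.full((4, 8), 1.5))
        state = _random_state(spec, 9, rho=0.4)
        eta = linear_predictor(state, spec)
        cols = np.flatnonzero(spec.season == 2)
        analytic = (
            panel.counts[:, cols].sum()
            - (E.values[:, cols] * np.exp(eta[:, cols])).sum()
            - state.beta[1] / 10_000.0
        )
        eps = 1e-6

        def lp(b2):
            s = state.copy()
            s.beta = state.beta.copy()
            s.beta[1] = b2
            return log_posterior(s, panel, E, spec, g4)

        numeric = (lp(state.beta[1] + eps) - lp(state.beta[1] - eps)) / (2 * eps)
        assert numeric == pytest.approx(analytic, rel=1e-4)


class TestModelSpec:
    def test_variant_validation(self):
        with pytest.raises(ValueError, match="variant"):
            ModelSpec("bym2", 4, 1)
        with pytest.raises(ValueError, match="single-period"):
            ModelSpec("spatial", 4, 3)
        with pytest.raises(ValueError, match="n_periods"):
            ModelSpec("st_annual", 4, 1)

    def test_rho0_variant_has_no_free_rho(self):
        assert not ModelSpec("st_quarterly_rho0", 4, 8).has_free_rho
        assert ModelSpec("st_quarterly", 4, 8).has_free_rho

    def test_season_map(self):
        spec = ModelSpec("st_quarterly", 4, 6)
        assert list(spec.season) == [1, 2, 3, 4, 1, 2]


class TestDiseaseMapModel:
    def test_graph_panel_mismatch(self, g4):
        panel = CountPanel(np.ones((9, 1), int), populations=[10] * 9)
        with pytest.raises(ValueError, match="areas"):
            DiseaseMapModel(panel, g4)

    def test_rho0_residual_has_no_time_coupling(self):
        spec = ModelSpec("st_quarterly_rho0", 4, 8)
        state = _random_state(spec, 11, rho=0.9)  # rho must be ignored
        resid = residual_field(state, spec)
        psi = state.phi + state.theta
        assert np.allclose(resid, psi)
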