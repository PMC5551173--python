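"""Model definitions: BYM spatial and autoregressive spatio-temporal variants.

Three Poisson log-linear relative-risk models for areal count panels:

``spatial``
    O_i ~ Poisson(E_i exp(eta_i)), eta_i = mu + phi_i + theta_i with phi an
    ICAR field and theta iid Gaussian (the BYM convolution model).

``st_annual``
    O_it ~ Poisson(E_it exp(eta_it)) with a first-order autoregression in
    time on the spatio-temporal residual:
    eta_i1 = mu + alpha_1 + (1 - rho^2)^(-1/2) (phi_i1 + theta_i1),
    eta_it = mu + alpha_t + rho (eta_i(t-1) - mu - alpha_(t-1))
             + phi_it + theta_it,
    where alpha_t is a random-walk temporal trend and each period has its
    own ICAR + iid fields.  The first-period scaling makes the residual
    field stationary in time.

``st_quarterly`` / ``st_quarterly_rho0``
    As ``st_annual`` plus seasonal fixed effects beta_q(t) (trimesters, with
    the fourth trimester as reference, beta_4 = 0).  The autoregression acts
    on the residual after removing the full fixed part mu + alpha_t +
    beta_q(t).  The ``_rho0`` variant pins rho = 0 (no space-time
    interaction); it exists to quantify, via DIC, what the autoregression
    buys.

Priors: mu flat; rho ~ U(-1, 1); sigma_alpha, sigma_phi, sigma_theta ~
U(0, 1) (on the standard-deviation scale); beta_k ~ N(0, 10,000).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
from scipy.special import gammaln

from .data import CountPanel, ExpectedCounts, expected_counts, season_of
from .graphs import AreaGraph, icar_quadform

VARIANTS = ("spatial", "st_annual", "st_quarterly", "st_quarterly_rho0")

BETA_PRIOR_VAR = 10_000.0
SIGMA_PRIOR_HIGH = 1.0


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    """Which model variant to fit, at what dimensions, with what is pinned.

    ``fixed`` maps parameter names (``sigma_phi``, ``sigma_theta``,
    ``sigma_alpha``, ``rho``) to pinned values; pinning a sigma to 0 removes
    the corresponding random-effect field entirely (used e.g. by the
    fixed-effects-only conjugacy checks).
    """

    variant: str
    n_areas: int
    n_periods: int
    fixed: Mapping[str, float] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if self.variant == "spatial" and self.n_periods != 1:
            raise ValueError("the spatial variant is single-period")
        if self.variant != "spatial" and self.n_periods < 2:
            raise ValueError("spatio-temporal variants need n_periods >= 2")
        object.__setattr__(self, "fixed", dict(self.fixed))

    @property
    def is_temporal(self) -> bool:
        return self.variant != "spatial"

    @property
    def is_seasonal(self) -> bool:
        return self.variant in ("st_quarterly", "st_quarterly_rho0")

    @property
    def has_free_rho(self) -> bool:
        return (
            self.is_temporal
            and self.variant != "st_quarterly_rho0"
            and "rho" not in self.fixed
        )

    @property
    def season(self) -> np.ndarray:
        """q(t) per period (1..4) for seasonal variants, else all 4 (beta off)."""
        if self.is_seasonal:
            return np.asarray(season_of(np.arange(1, self.n_periods + 1)))
        return np.full(self.n_periods, 4)

    def free_scalar_names(self) -> list[str]:
        names = ["mu"]
        if self.is_temporal:
            names += [f"alpha[{t}]" for t in range(1, self.n_periods + 1)]
        if self.is_seasonal:
            names += [f"beta[{k}]" for k in (1, 2, 3)]
        if self.is_temporal:
            names.append("rho")
        for s in ("sigma_phi", "sigma_theta"):
            names.append(s)
        if self.is_temporal:
            names.append("sigma_alpha")
        return names


@dataclasses.dataclass
class ParameterState:
    """One full set of model parameter values (used as MCMC state and as
    generative truth in simulation studies)."""

    mu: float = 0.0
    alpha: np.ndarray | None = None  # (n_periods,), sum-to-zero
    beta: np.ndarray | None = None  # (3,), trimesters 1..3; beta_4 = 0
    rho: float = 0.0
    phi: np.ndarray | None = None  # (n_areas, n_periods), columns sum-to-zero
    theta: np.ndarray | None = None  # (n_areas, n_periods)
    sigma_alpha: float = 0.0
    sigma_phi: float = 0.0
    sigma_theta: float = 0.0

    @classmethod
    def zeros(cls, spec: ModelSpec, **overrides) -> "ParameterState":
        state = cls(
            alpha=np.zeros(spec.n_periods),
            beta=np.zeros(3),
            phi=np.zeros((spec.n_areas, spec.n_periods)),
            theta=np.zeros((spec.n_areas, spec.n_periods)),
        )
        for key, val in overrides.items():
            setattr(state, key, np.asarray(val, float) if key in ("alpha", "beta", "phi", "theta") else float(val))
        return state

    def copy(self) -> "ParameterState":
        return ParameterState(
            mu=self.mu,
            alpha=None if self.alpha is None else self.alpha.copy(),
            beta=None if self.beta is None else self.beta.copy(),
            rho=self.rho,
            phi=None if self.phi is None else self.phi.copy(),
            theta=None if self.theta is None else self.theta.copy(),
            sigma_alpha=self.sigma_alpha,
            sigma_phi=self.sigma_phi,
            sigma_theta=self.sigma_theta,
        )

    def as_flat_dict(self) -> dict[str, float]:
        """Scalar view (fields excluded) for truth records and manifests."""
        out = {"mu": float(self.mu), "rho": float(self.rho),
               "sigma_alpha": float(self.sigma_alpha),
               "sigma_phi": float(self.sigma_phi),
               "sigma_theta": float(self.sigma_theta)}
        if self.beta is not None:
            for k in range(3):
                out[f"beta[{k + 1}]"] = float(self.beta[k])
        return out


def _fixed_part(state: ParameterState, spec: ModelSpec) -> np.ndarray:
    """mu + alpha_t + beta_q(t) per period (length n_periods)."""
    fixed = np.full(spec.n_periods, state.mu)
    if spec.is_temporal and state.alpha is not None:
        fixed = fixed + state.alpha
    if spec.is_seasonal and state.beta is not None:
        beta4 = np.append(state.beta, 0.0)
        fixed = fixed + beta4[spec.season - 1]
    return fixed


def residual_field(state: ParameterState, spec: ModelSpec) -> np.ndarray:
    """The spatio-temporal residual r_it = eta_it - (mu + alpha_t + beta_q(t)).

    r_i1 = (1 - rho^2)^(-1/2) (phi_i1 + theta_i1);
    r_it = rho r_i(t-1) + phi_it + theta_it.

    With this first-period scaling, the prior variance of r is constant in t
    (time-stationarity of the residual field).
    """
    psi = state.phi + state.theta
    if not spec.is_temporal:
        return psi
    rho = 0.0 if spec.variant == "st_quarterly_rho0" else float(state.rho)
    if not -1 < rho < 1:
        raise ValueError("|rho| must be < 1")
    r = np.empty_like(psi)
    r[:, 0] = psi[:, 0] / np.sqrt(1.0 - rho**2)
    for t in range(1, spec.n_periods):
        r[:, t] = rho * r[:, t - 1] + psi[:, t]
    return r


def linear_predictor(state: ParameterState, spec: ModelSpec) -> np.ndarray:
    """Log relative risk eta (n_areas x n_periods) assembled per variant."""
    if state.phi is None or state.theta is None:
        raise ValueError("state must carry phi and theta fields (use zeros if off)")
    if state.phi.shape != (spec.n_areas, spec.n_periods):
        raise ValueError(
            f"phi has shape {state.phi.shape}, expected "
            f"({spec.n_areas}, {spec.n_periods})"
        )
    return _fixed_part(state, spec)[None, :] + residual_field(state, spec)


def poisson_loglik(eta: np.ndarray, counts: np.ndarray, E: np.ndarray) -> float:
    """Poisson log likelihood up to the data-only constant (log O! and O log E)."""
    return float(np.sum(counts * eta) - np.sum(E * np.exp(eta)))


def deviance(eta: np.ndarray, counts: np.ndarray, E: np.ndarray) -> float:
    """Full deviance -2 log p(O | eta), constants included (DIC scale)."""
    lam_log = np.log(E) + eta
    return float(-2.0 * np.sum(counts * lam_log - E * np.exp(eta) - gammaln(counts + 1.0)))


def log_posterior(
    state: ParameterState,
    panel: CountPanel | np.ndarray,
    E: ExpectedCounts | np.ndarray,
    spec: ModelSpec,
    graph: AreaGraph,
) -> float:
    """Unnormalised log posterior of a full parameter state.

    Poisson likelihood (constants dropped) plus ICAR, iid-Gaussian, RW1 and
    beta-prior log densities, including the sigma-dependent rank terms needed
    for correct inference on the standard deviations.  States outside the
    prior support (sigmas outside (0, 1) unless pinned, |rho| >= 1) return
    -inf rather than raising, so samplers can reject uniformly.
    """
    counts = panel.counts if isinstance(panel, CountPanel) else np.asarray(panel)
    e_vals = E.values if isinstance(E, ExpectedCounts) else np.asarray(E, float)
    n, T = spec.n_areas, spec.n_periods

    use_phi = spec.fixed.get("sigma_phi", None) != 0.0
    use_theta = spec.fixed.get("sigma_theta", None) != 0.0
    use_alpha = spec.is_temporal and spec.fixed.get("sigma_alpha", None) != 0.0

    # support checks
    for name, use in (("sigma_phi", use_phi), ("sigma_theta", use_theta),
                      ("sigma_alpha", use_alpha)):
        if use and not 0.0 < getattr(state, name) < SIGMA_PRIOR_HIGH:
            return -np.inf
    rho = state.rho
    if spec.variant == "st_quarterly_rho0":
        rho = 0.0
    if spec.is_temporal and not -1.0 < rho < 1.0:
        return -np.inf

    eta = linear_predictor(state, spec)
    lp = poisson_loglik(eta, counts, e_vals)

    if use_phi:
        s2 = state.sigma_phi**2
        quad = sum(icar_quadform(state.phi[:, t], graph) for t in range(T))
        lp += -T * (n - 1) * np.log(state.sigma_phi) - quad / (2.0 * s2)
    if use_theta:
        s2 = state.sigma_theta**2
        lp += -n * T * np.log(state.sigma_theta) - np.sum(state.theta**2) / (2.0 * s2)
    if use_alpha:
        d = np.diff(state.alpha)
        lp += -(T - 1) * np.log(state.sigma_alpha) - np.sum(d**2) / (
            2.0 * state.sigma_alpha**2
        )
    if spec.is_seasonal:
        lp += -np.sum(state.beta**2) / (2.0 * BETA_PRIOR_VAR)
    return float(lp)


class DiseaseMapModel:
    """Areal relative-risk model bound to data, statsmodels-style.

    Parameters
    ----------
    panel
        Observed counts and populations.
    graph
        Areal adjacency.
    variant
        One of ``spatial``, ``st_annual``, ``st_quarterly``,
        ``st_quarterly_rho0``.
    expected
        Expected counts; computed by internal standardization of the panel
        when omitted.
    expected_mode
        ``global`` or ``per_period`` standardization (only used when
        ``expected`` is omitted).
    fixed
        Parameters pinned at fixed values (see :class:`ModelSpec`).

    ``fit()`` runs the Metropolis-within-Gibbs sampler and returns a
    :class:`~carmap.results.DiseaseMapResults`.
    """

    def __init__(
        self,
        panel: CountPanel,
        graph: AreaGraph,
        variant: str = "spatial",
        expected: ExpectedCounts | None = None,
        expected_mode: str = "global",
        fixed: Mapping[str, float] | None = None,
    ):
        if graph.n_areas != panel.n_areas:
            raise ValueError(
                f"graph has {graph.n_areas} areas but panel has {panel.n_areas}"
            )
        self.panel = panel
        self.graph = graph
        self.spec = ModelSpec(
            variant=variant,
            n_areas=panel.n_areas,
            n_periods=panel.n_periods,
            fixed=fixed or {},
        )
        self.exog_expected = (
            expected
            if expected is not None
            else expected_counts(panel.populations, panel, mode=expected_mode)
        )
        if self.exog_expected.shape != panel.counts.shape:
            raise ValueError("expected counts shape does not match the panel")

    @classmethod
    def from_files(
        cls, counts_path, populations_path, gal_path, variant="spatial", **kwargs
    ) -> "DiseaseMapModel":
        from pathlib import Path

        from .graphs import read_adjacency

        panel = CountPanel.read_csv(counts_path, populations_path)
        graph = read_adjacency(Path(gal_path).read_text())
        return cls(panel, graph, variant=variant, **kwargs)

    def log_posterior(self, state: ParameterState) -> float:
        return log_posterior(state, self.panel, self.exog_expected, self.spec, self.graph)

    def fit(self, config=None, **kwargs):
        from .mcmc import McmcConfig, fit as mcmc_fit
        from .results import DiseaseMapResults

        if config is None:
            config = McmcConfig(**kwargs)
        elif kwargs:
            config = dataclasses.replace(config, **kwargs)
        chains = mcmc_fit(self.spec, self.panel, self.exog_expected, self.graph, config)
        return DiseaseMapResults(self, chains)

    def __repr__(self) -> str:
        return (
            f"DiseaseMapModel(variant={self.spec.variant!r}, "
            f"n_areas={self.spec.n_areas}, n_periods={self.spec.n_periods})"
        )
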