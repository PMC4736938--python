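"""Independent oracles shared between the unit and acceptance suites.

These deliberately avoid the package's sampler code paths: the intercept
posterior is computed by dense quadrature, and parameter recovery generates
data straight from the estimation model's own definition.
"""

import numpy as np
from scipy.special import logsumexp

import icesurvey as isv
from icesurvey.detection import AvailabilityPrior, DetectionPrior
from icesurvey.estimation import MCMC_PRESETS, MCMCConfig
from icesurvey.survey import CountData, EffortSummary

TOY_COUNTS = np.array([40.0, 55.0, 38.0, 47.0])
TOY_A = 0.5
TOY_P = 0.94


def point_prior(p: float, species: str = "x") -> DetectionPrior:
    avail = AvailabilityPrior(
        species, mean=1.0, logit_sd=0.0, mu=np.inf, degenerate=True
    )
    return DetectionPrior(species, 1.0, 1.0, avail, np.array([p]))


def toy_fit(seed: int = 2):
    """Fit the 4-unit intercept-only toy problem with the package sampler."""
    g = isv.build_grid(2, 2)
    eff = EffortSummary("toy", np.full(4, TOY_A), np.zeros(4))
    counts = CountData(
        "x", C=TOY_COUNTS.astype(int), n=TOY_COUNTS.astype(int),
        surveyed=np.ones(4, bool),
    )
    return isv.fit_abundance_model(
        counts, eff, g, isv.ModelSpec(()), point_prior(TOY_P),
        MCMCConfig(500, 30_000, 3000, 10), seed=seed,
    )


def toy_intercept_posterior_mean() -> float:
    """Brute-force posterior mean of the intercept for the 4-unit toy:
    dense grid over (beta0, tau_eps), Gauss-Hermite over the unit-level
    noise, Gamma(1, 0.01) prior on tau_eps and a diffuse N(0, 1e4) prior on
    the level."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(61)
    weights = weights / weights.sum()
    b_grid = np.linspace(3.0, 6.5, 241)
    tau_grid = np.geomspace(0.2, 2000.0, 121)
    sigma = 1.0 / np.sqrt(tau_grid)
    c_off = 1.0 * TOY_A * TOY_P  # R_j = 1
    lp = np.zeros((b_grid.size, tau_grid.size))
    for Cj in TOY_COUNTS:
        z = b_grid[:, None, None] + sigma[None, :, None] * nodes[None, None, :]
        ll = Cj * (np.log(c_off) + z) - c_off * np.exp(z)
        lp += logsumexp(ll + np.log(weights)[None, None, :], axis=2)
    lp += -0.01 * tau_grid[None, :]  # Gamma(1, 0.01) prior, up to constants
    lp += np.log(np.gradient(np.log(tau_grid)) * tau_grid)[None, :]
    lp += -0.5 * 1e-4 * b_grid[:, None] ** 2
    post = np.exp(lp - lp.max())
    marg = post.sum(axis=1)
    return float(np.sum(b_grid * marg) / marg.sum())


def parameter_recovery_coverage(n_reps: int = 100, seed: int = 0) -> np.ndarray:
    """Generate data from the estimation model itself on a 100-unit grid
    with known coefficients and report, per coefficient, how many of the
    nominal-90% credible intervals cover the truth."""
    g = isv.build_grid(10, 10, n_nearshore_strata=1, n_offshore_strata=1)
    spec = isv.ModelSpec(("stratum",))
    X, _ = isv.build_design_matrix(g, spec)
    beta_true = np.array([3.9, 0.8])
    tau_eps_true = 10.0
    A_val, p_val = 0.3, 0.94
    eff = EffortSummary("r", np.full(g.n_units, A_val), np.zeros(g.n_units))
    prior = point_prior(p_val)
    covered = np.zeros(beta_true.size)
    for ss in np.random.SeedSequence(seed).spawn(n_reps):
        rng = np.random.default_rng(ss)
        nu = X @ beta_true + rng.normal(0, 1 / np.sqrt(tau_eps_true), g.n_units)
        C = rng.poisson(g.R * A_val * p_val * np.exp(nu))
        counts = CountData("x", C=C, n=C, surveyed=np.ones(g.n_units, bool))
        fit = isv.fit_abundance_model(
            counts, eff, g, spec, prior, MCMC_PRESETS["test"], seed=rng
        )
        lo = np.quantile(fit.draws.beta, 0.05, axis=0)
        hi = np.quantile(fit.draws.beta, 0.95, axis=0)
        covered += (lo <= beta_true) & (beta_true <= hi)
    return covered
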