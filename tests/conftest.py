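import numpy as np
import pytest

import icesurvey as isv


@pytest.fixture(scope="session")
def grid505():
    """The default 505-unit study grid."""
    return isv.default_grid()


@pytest.fixture(scope="session")
def grid3x3():
    return isv.build_grid(3, 3)


@pytest.fixture(scope="session")
def gen_model505(grid505):
    """Generation-side spatial effect model (intercept-restricted basis)."""
    return isv.build_rsr_basis(
        grid505, X=np.ones((grid505.n_units, 1)), m=50, tau_eta=5.0
    )


@pytest.fixture(scope="session")
def effort_b1(grid505):
    design = isv.design_catalogue(grid505)["B1"]
    return isv.compute_effort(design, grid505)


@pytest.fixture(scope="session")
def ringed_fit(grid505, gen_model505, effort_b1):
    """One end-to-end ringed-seal replicate fitted with the stratum model;
    reused by several diagnostics tests."""
    dens = isv.make_density_surface(
        grid505, isv.default_density_profile("ringed", grid505), 380_000, "ringed"
    )
    rng = np.random.default_rng(1234)
    intensity = isv.simulate_intensity(grid505, dens, gen_model505, seed=rng)
    pop = isv.draw_population(intensity, rng)
    counts = isv.simulate_counts(
        pop, effort_b1, isv.detection_truth_for("ringed"), rng
    )
    prior = isv.species_detection_prior("ringed", seed=7)
    fit = isv.fit_abundance_model(
        counts,
        effort_b1,
        grid505,
        isv.ModelSpec(("stratum",)),
        prior,
        isv.MCMC_PRESETS["short"],
        seed=rng,
    )
    return {"fit": fit, "pop": pop, "counts": counts, "intensity": intensity}
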