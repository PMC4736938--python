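"""Simulate one survey replicate: population realization, photographic
coverage and detected counts.

A ringed-seal population is drawn from the stochastic intensity surface
(smoothed strata densities x spatial random effects x lognormal noise),
the 8-flight evenly-spread design is intersected with the grid to get the
photographed proportion A_j of each unit, and in-photo detections are
thinned by coverage, availability (0.65) and thermal detection (0.94).
"""

import numpy as np

import icesurvey as isv

grid = isv.default_grid()
density = isv.make_density_surface(
    grid, isv.default_density_profile("ringed", grid), 380_000, "ringed"
)
gen_model = isv.build_rsr_basis(
    grid, X=np.ones((grid.n_units, 1)), m=50, tau_eta=5.0
)

rng = np.random.default_rng(42)
intensity = isv.simulate_intensity(grid, density, gen_model, seed=rng)
population = isv.draw_population(intensity, rng)
print(f"expected abundance sum lambda_j : {intensity.lam.sum():,.0f}")
print(f"realized abundance N            : {population.N:,}")

design = isv.design_catalogue(grid)["B1"]
effort = isv.compute_effort(design, grid)
print(f"surveyed units                  : {effort.n_surveyed} / {grid.n_units}")
print(f"mean photographed proportion    : {effort.A[effort.surveyed].mean():.4f}")

truth = isv.detection_truth_for("ringed")
counts = isv.simulate_counts(population, effort, truth, rng)
print(f"overall detectability p_js      : {truth.p:.3f}")
print(f"animals in photographed areas   : {counts.n.sum():,}")
print(f"detected in photographs         : {counts.C.sum():,}")

# Roughly A_j * p_js of each unit's animals end up as detections; the gap
# between N and sum(C) is what the estimation model must reconstruct.
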