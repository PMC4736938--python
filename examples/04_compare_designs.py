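"""Compare survey designs by replicate simulation.

Runs a small version of the design-evaluation loop: for each replicate a
new ringed-seal population is simulated, surveyed under two designs (4
vs 8 evenly-spread flights), and the stratum estimation model is fitted;
designs are scored by median proportional bias, median CV, RMSE and 90%
credible-interval coverage.  (The full study crosses 9 designs x up to 9
models x 100 replicates x 3 species.)
"""

import icesurvey as isv
from icesurvey.estimation import MCMC_PRESETS

config = isv.ExperimentConfig(
    species=("ringed",),
    designs=("A1", "B1"),
    models={"stratum": isv.ModelSpec(("stratum",)),
            "stratum + samp.dens": isv.ModelSpec(("stratum", "samp.dens"))},
    n_reps=4,
    mcmc=MCMC_PRESETS["test"],
)
summary, records = isv.run_experiment(config, seed=3)

cols = ["design_id", "model_label", "median_prop_bias", "median_cv",
        "rmse", "ci_coverage", "n_reps"]
print(summary[cols].to_string(index=False, float_format=lambda x: f"{x:.3f}"))

# With many replicates the 8-flight design (B1) shows lower CV and RMSE
# than the 4-flight design (A1); at this demonstration scale (4 replicates)
# the CV ordering is usually visible while RMSE remains noisy.
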