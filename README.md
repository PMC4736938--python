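# icesurvey

Simulation-based evaluation of instrument-based aerial survey designs for
ice-associated marine mammals (ringed seals, bearded seals and polar bears
on a large Arctic shelf sea).

Aerial surveys that pair infrared imagery with high-resolution photography
can cover huge, remote sea-ice regions, but they are expensive: before
flying, one wants to know how many flights, and which track layout, will
deliver an abundance estimate with acceptable bias and precision.
`icesurvey` answers this by simulation. It builds a gridded virtual
seascape, simulates spatially structured populations, "flies" candidate
transect designs over them with imperfect detection, estimates total
abundance with a hierarchical Bayesian spatial count model, and scores each
design x model combination against the known truth.

## The model

The study area is discretised into J = 505 survey units of 625 km²; unit
*j* has habitat (saltwater) proportion *R<sub>j</sub>* and habitat area
*a<sub>j</sub>* = 625 *R<sub>j</sub>*.

**Population generation.** Per-stratum densities *d<sub>j</sub>* (scaled so
totals match the expected population sizes: 380 000 ringed seals, 19 800
bearded seals, E(N) = 1000 polar bears) are smoothed with a row-stochastic
neighbourhood matrix **W** (self weight 2, rook-neighbour weight 1), and
expected abundance gets stochastic structure

&nbsp;&nbsp;&nbsp;&nbsp;λ<sub>j</sub> = a<sub>j</sub> exp( log d\*<sub>j</sub> + η<sub>j</sub> + ε<sub>j</sub> ),

with **η** from a reduced-rank (Moran basis) ICAR distribution with
precision τ<sub>η</sub> = 5 and ε<sub>j</sub> ~ N(0, 0.1). Realized
abundance is N<sub>j</sub> ~ Poisson(λ<sub>j</sub>).

**Surveys.** Each design flies 4, 8 or 12 tracks of ≈980 km; the
photographed swath is 470 m x 84%. Geometric intersection of the swath
with the grid gives the photographed proportion A<sub>j</sub>; detections
are C<sub>j</sub> ~ Binomial(n<sub>j</sub>, p<sub>js</sub>) with
n<sub>j</sub> ~ Binomial(N<sub>j</sub>, A<sub>j</sub>) (equivalently,
Poisson(A<sub>j</sub>λ<sub>j</sub>) thinning) and p<sub>js</sub> =
availability x thermal detection (0.48 / 0.65 / 1.0 x 0.94).

**Estimation.** Counts are modelled as a thinned Poisson process,
C<sub>j</sub> ~ Poisson(A<sub>j</sub> p<sub>js</sub> λ<sub>j</sub>) with
λ = **R** exp(**X**β + η + ε), an informative Monte-Carlo prior on
p<sub>js</sub> (Beta(71, 5) thermal detection x a per-species availability
prior), Gamma(1, 0.01) precision priors, and an optional reduced-rank ICAR
random effect. The posterior is sampled by adaptive Metropolis-within-Gibbs
and total abundance is summarised posterior-predictively. Designs are
scored by proportional bias, CV, RMSE and 90% credible-interval coverage
over replicates.

## Worked example

```bash
python examples/03_fit_abundance_model.py
```

```
detection prior mean 0.601 (generation used 0.611)
true N        : 400,852
N_hat         : 366,137
posterior SE  : 43,907  (CV 0.120)
90% interval  : [297,422, 437,091]
covered       : True
acceptance    : {'zeta': 0.353, 'beta_translation': 0.349, 'p': 0.121}
```

One ringed-seal population (~400 000 animals) was simulated, surveyed with
8 evenly-spread flights (~3000 detections in photographs), and fitted with
the stratum model. The posterior-predictive mean is within 9% of truth,
the CV is 12%, and the nominal-90% interval covers the true total — the
interval is deliberately conservative because estimation propagates more
detectability uncertainty than was used to generate the data.

The other examples build the scenario (`01`), walk through one survey
simulation (`02`), and run a small multi-design comparison (`04`).

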