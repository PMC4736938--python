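"""Build the synthetic study system: grid, density surfaces and designs.

The default scenario is a 27 x 20 lattice of 625 km^2 survey units with a
mainland band along the south, 12 survey strata (10 nearshore, 2 offshore),
stratum-patterned seal density surfaces scaled to expected totals of
380 000 ringed and 19 800 bearded seals, a smooth relative-use surface for
polar bears scaled to an expected 1000 animals, and nine transect designs
with 4, 8 or 12 flights of ~980 km each.
"""

import numpy as np

import icesurvey as isv

grid = isv.default_grid()
print(f"survey units            : {grid.n_units}")
print(f"cell area (km^2)        : {grid.cell_area:.0f}")
print(f"total habitat (km^2)    : {grid.a.sum():,.0f}")
print(f"strata                  : {', '.join(grid.strata_levels)}")

for species, total in [("ringed", 380_000), ("bearded", 19_800)]:
    surf = isv.make_density_surface(
        grid, isv.default_density_profile(species, grid), total, species
    )
    implied = (grid.a * surf.d).sum() / grid.a.sum()
    print(f"{species:8s} total {total:>7,} -> mean density {implied:.3f} km^-2")

rsf, bear_dens = isv.make_rsf_surface(grid, N_target=1000, seed=1)
print(f"polar bear E(N) = {(rsf.c * rsf.w).sum():.0f}, "
      f"mean density {(rsf.c * rsf.w).sum() / grid.a.sum():.4f} km^-2")

print("\ndesign  flights  coastal  total km")
for name, design in isv.design_catalogue(grid).items():
    print(f"{name:6s} {design.n_flights:8d} {design.n_coastal:8d} "
          f"{design.total_length:9.0f}")

# The totals above are the expected population sizes before survey thinning;
# the design table shows how flight effort is allocated between long
# transects and short coastal tracks.
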