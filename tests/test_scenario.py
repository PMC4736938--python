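"""Grid construction, strata, density surfaces, use surface and designs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import icesurvey as isv
from icesurvey.scenario import DESIGN_CATALOGUE


class TestGrid:
    def test_default_grid_dimensions(self, grid505):
        assert grid505.n_units == 505
        assert grid505.cell_area == 625.0
        assert np.all(grid505.R > 0) and np.all(grid505.R <= 1)
        np.testing.assert_allclose(grid505.a, 625.0 * grid505.R)

    def test_strata_partition(self, grid505):
        levels, counts = np.unique(grid505.stratum, return_counts=True)
        assert len(levels) == 12
        assert sum(lev.startswith("N") for lev in levels) == 10
        assert sum(lev.startswith("O") for lev in levels) == 2
        assert counts.min() > 0
        assert counts.sum() == grid505.n_units

    def test_single_cell_grid(self):
        g = isv.build_grid(1, 1, land_mask=np.array([[1.0]]))
        assert g.n_units == 1
        assert g.adjacency[0].size == 0
        assert g.R[0] == 1.0
        # all-water convention: distance to the southern lattice edge
        assert g.dist_land[0] == pytest.approx(12.5)

    def test_rook_adjacency_counts(self, grid3x3):
        degrees = np.array([nb.size for nb in grid3x3.adjacency])
        centre = np.nonzero(
            (grid3x3.row == 1) & (grid3x3.col == 1)
        )[0][0]
        assert degrees[centre] == 4
        corners = (np.isin(grid3x3.row, [0, 2])) & (np.isin(grid3x3.col, [0, 2]))
        assert np.all(degrees[corners] == 2)

    def test_adjacency_symmetric_irreflexive(self, grid505):
        for i, nb in enumerate(grid505.adjacency):
            assert i not in nb
            for j in nb:
                assert i in grid505.adjacency[j]

    def test_dist_land_nearest_land_cell(self, grid505):
        # first water row sits one half-cell from the mainland edge
        row1 = grid505.row == 1
        assert np.all(grid505.dist_land[row1] == pytest.approx(12.5))

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"nx": 0, "ny": 3},
            {"nx": 3, "ny": 3, "land_mask": np.ones((2, 2))},
            {"nx": 2, "ny": 2, "land_mask": np.full((2, 2), 1.5)},
            {"nx": 1, "ny": 1, "land_mask": np.zeros((1, 1))},
        ],
    )
    def test_build_grid_errors(self, kwargs):
        with pytest.raises(ValueError):
            isv.build_grid(**kwargs)


class TestDensitySurfaces:
    def test_default_totals_rescale_exactly(self, grid505):
        for sp, total in [("ringed", 380_000.0), ("bearded", 19_800.0)]:
            surf = isv.make_density_surface(
                grid505, isv.default_density_profile(sp, grid505), total, sp
            )
            assert abs((grid505.a * surf.d).sum() - total) / total < 1e-9
            assert np.all(surf.d >= 0)

    def test_uniform_profile_gives_constant_density(self, grid3x3):
        profile = {s: 1.0 for s in grid3x3.strata_levels}
        surf = isv.make_density_surface(grid3x3, profile, 100.0)
        np.testing.assert_allclose(surf.d, 100.0 / grid3x3.a.sum())

    def test_two_stratum_hand_solved_scaling(self):
        # two equal-area units in different strata, levels 2:1, target 3A
        # -> the scaling constant is exactly 1
        g = isv.build_grid(1, 2)
        assert len(g.strata_levels) == 2
        s0, s1 = g.stratum[0], g.stratum[1]
        surf = isv.make_density_surface(g, {s0: 2.0, s1: 1.0}, 3.0 * 625.0)
        np.testing.assert_allclose(surf.d, [2.0, 1.0])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        levels=st.lists(
            st.floats(0.01, 50.0, allow_nan=False), min_size=2, max_size=2
        ),
        target=st.floats(1.0, 1e6),
    )
    def test_rescaling_property(self, levels, target):
        g = isv.build_grid(1, 2)
        profile = dict(zip(g.strata_levels, levels))
        surf = isv.make_density_surface(g, profile, target)
        assert abs((g.a * surf.d).sum() - target) <= 1e-9 * target

    def test_density_profile_errors(self, grid3x3):
        profile = {s: 0.0 for s in grid3x3.strata_levels}
        with pytest.raises(ValueError):
            isv.make_density_surface(grid3x3, profile, 10.0)
        profile[grid3x3.strata_levels[0]] = -1.0
        with pytest.raises(ValueError):
            isv.make_density_surface(grid3x3, profile, 10.0)


class TestUseSurface:
    def test_scaled_to_expected_total(self, grid505):
        rsf, dens = isv.make_rsf_surface(grid505, N_target=1000, seed=3)
        assert abs((rsf.c * rsf.w).sum() - 1000.0) < 1e-9 * 1000.0
        assert np.all(rsf.w > 0)
        np.testing.assert_allclose(dens.d, rsf.c * rsf.w / 625.0)

    def test_constant_field_scaling(self, grid3x3):
        rsf, _ = isv.make_rsf_surface(grid3x3, N_target=90, seed=0, field_sd=0.0)
        np.testing.assert_allclose(rsf.w, 1.0)
        assert rsf.c == pytest.approx(90.0 / grid3x3.n_units)

    def test_doubling_w_halves_c(self, grid3x3):
        rsf, dens = isv.make_rsf_surface(grid3x3, N_target=50, seed=5)
        c2 = 50.0 / (2.0 * rsf.w).sum()
        assert c2 == pytest.approx(rsf.c / 2.0)
        np.testing.assert_allclose(c2 * (2 * rsf.w) / 625.0, dens.d)

    def test_seed_reproducibility(self, grid3x3):
        a, _ = isv.make_rsf_surface(grid3x3, seed=9)
        b, _ = isv.make_rsf_surface(grid3x3, seed=9)
        np.testing.assert_array_equal(a.w, b.w)

    def test_invalid_target(self, grid3x3):
        with pytest.raises(ValueError):
            isv.make_rsf_surface(grid3x3, N_target=0)


class TestFlightDesigns:
    def test_catalogue_configurations(self, grid505):
        cat = isv.design_catalogue(grid505)
        assert set(cat) == set(DESIGN_CATALOGUE)
        for name, (nf, nc) in DESIGN_CATALOGUE.items():
            d = cat[name]
            assert d.n_flights == nf and d.n_coastal == nc
            assert len(d.tracks) == nf
            lengths = d.track_lengths()
            assert np.all(np.abs(lengths - 980.0) <= 0.05 * 980.0)
            assert d.photo_swath == pytest.approx(0.470 * 0.84)

    def test_total_track_lengths(self, grid505):
        cat = isv.design_catalogue(grid505)
        assert cat["B1"].total_length == pytest.approx(7840.0, rel=0.01)
        assert cat["C1"].total_length == pytest.approx(11_760.0, rel=0.01)

    def test_even_leg_spacing_and_containment(self, grid505):
        d = isv.build_flight_design(grid505, n_flights=4, n_coastal=0)
        xs = sorted({x for t in d.tracks for x in t[:, 0]})
        gaps = np.diff(xs)
        np.testing.assert_allclose(gaps, gaps[0])
        xmin, ymin, xmax, ymax = grid505.bounds
        for t in d.tracks:
            assert t[:, 0].min() >= xmin and t[:, 0].max() <= xmax
            assert t[:, 1].min() >= ymin and t[:, 1].max() <= ymax

    def test_coastal_tracks_hug_the_shore(self, grid505):
        d = isv.build_flight_design(grid505, n_flights=8, n_coastal=4)
        coastal = d.tracks[4:]
        for t in coastal:
            assert t[:, 1].max() <= 100.0  # inside the nearshore band

    def test_invalid_coastal_count(self, grid505):
        with pytest.raises(ValueError):
            isv.build_flight_design(grid505, n_flights=4, n_coastal=4)
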