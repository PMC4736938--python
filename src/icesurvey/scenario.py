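"""Synthetic study system: lattice survey grid, species density surfaces and
flight-track designs.

The study system emulates a large (~3e5 km^2) Arctic shelf sea surveyed from
fixed-wing aircraft: a rectangular lattice of 625 km^2 survey units with a
land band along the southern edge, ice-seal density surfaces built from
per-stratum density levels (nearshore/offshore, with an alongshore gradient),
a smooth relative-probability-of-use surface for a sparse apex predator
(polar bears), and a catalogue of nine transect designs differing in the
number of flights (4/8/12) and in how much effort is concentrated near the
coast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SurveyGrid",
    "DensitySurface",
    "RSFSurface",
    "FlightDesign",
    "build_grid",
    "default_land_mask",
    "default_grid",
    "make_density_surface",
    "default_density_profile",
    "make_rsf_surface",
    "build_flight_design",
    "design_catalogue",
    "DESIGN_CATALOGUE",
]

#: default cell side (km); 25 km x 25 km = 625 km^2 units, the resolution of
#: commonly available sea-ice imagery
DEFAULT_CELL_SIZE = 25.0

#: default per-flight track length (km); consistent with the 900-1200 km
#: effective range of a Twin Otter with auxiliary fuel tank
DEFAULT_FLIGHT_LENGTH = 980.0

#: thermal imaging swath width (km) at 300 m survey altitude
THERMAL_SWATH = 0.470

#: fraction of the thermal swath covered by digital photographs
PHOTO_FRACTION = 0.84

#: design label -> (n_flights, n_coastal); the letter encodes the level of
#: effort, the digit the number of coastal flights (1 = none, 2 = two, ...)
DESIGN_CATALOGUE: dict[str, tuple[int, int]] = {
    "A1": (4, 0),
    "A2": (4, 2),
    "B1": (8, 0),
    "B2": (8, 2),
    "B3": (8, 4),
    "C1": (12, 0),
    "C2": (12, 2),
    "C3": (12, 4),
    "C4": (12, 6),
}


@dataclass
class SurveyGrid:
    """Lattice of habitat-bearing survey units.

    Only cells with a positive saltwater proportion are survey units; fully
    land cells are retained separately so that distance-to-land can be
    computed.  ``unit_id`` runs 1..J in row-major (south-to-north) order.
    """

    unit_id: np.ndarray          # (J,) int, 1..J
    row: np.ndarray              # (J,) lattice row index (northing direction)
    col: np.ndarray              # (J,) lattice column index (easting direction)
    centroid_x: np.ndarray       # (J,) km
    centroid_y: np.ndarray       # (J,) km
    cell_area: float             # km^2
    R: np.ndarray                # (J,) proportion saltwater habitat, in (0, 1]
    stratum: np.ndarray          # (J,) string labels
    dist_land: np.ndarray        # (J,) km to nearest fully-land cell
    adjacency: list[np.ndarray]  # rook neighbours, 0-based unit indices
    nx: int
    ny: int
    cell_size: float
    land_cells: np.ndarray       # (n_land, 2) (row, col) of fully-land cells

    @property
    def n_units(self) -> int:
        return self.unit_id.size

    @property
    def a(self) -> np.ndarray:
        """Effective habitat area per unit (km^2): cell_area * R_j."""
        return self.cell_area * self.R

    @property
    def northing(self) -> np.ndarray:
        return self.centroid_y

    @property
    def easting(self) -> np.ndarray:
        return self.centroid_x

    @property
    def strata_levels(self) -> np.ndarray:
        """Stratum labels in a stable (sorted) order."""
        return np.unique(self.stratum)

    def adjacency_matrix(self) -> np.ndarray:
        """Dense symmetric 0/1 rook adjacency among survey units."""
        J = self.n_units
        A = np.zeros((J, J))
        for i, nb in enumerate(self.adjacency):
            A[i, nb] = 1.0
        return A

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """Lattice bounding box (xmin, ymin, xmax, ymax) in km."""
        return (0.0, 0.0, self.nx * self.cell_size, self.ny * self.cell_size)


@dataclass
class DensitySurface:
    """Per-unit initial density (animals km^-2) for one species."""

    species: str
    d: np.ndarray  # (J,) animals km^-2
    provenance: str = ""


@dataclass
class RSFSurface:
    """Relative probability of use w_j, with scaling constant c such that
    sum_j c*w_j equals a target expected total abundance."""

    w: np.ndarray
    c: float
    N_target: float


@dataclass
class FlightDesign:
    """A set of flight tracks, each a planar polyline of ~equal length."""

    design_id: str
    n_flights: int
    n_coastal: int
    tracks: list[np.ndarray]  # each (k, 2) array of (x, y) km
    per_flight_length: float = DEFAULT_FLIGHT_LENGTH
    thermal_swath: float = THERMAL_SWATH
    photo_fraction: float = PHOTO_FRACTION

    @property
    def photo_swath(self) -> float:
        """Width of the photographed strip (km)."""
        return self.thermal_swath * self.photo_fraction

    def track_lengths(self) -> np.ndarray:
        return np.array([_polyline_length(t) for t in self.tracks])

    @property
    def total_length(self) -> float:
        return float(self.track_lengths().sum())


def _polyline_length(xy: np.ndarray) -> float:
    return float(np.sqrt(np.diff(xy[:, 0]) ** 2 + np.diff(xy[:, 1]) ** 2).sum())


def _point_to_cell_distance(px, py, row, col, s):
    """Distance from point(s) to the closed square of lattice cell (row, col)."""
    x0, x1 = col * s, (col + 1) * s
    y0, y1 = row * s, (row + 1) * s
    dx = np.maximum(np.maximum(x0 - px, px - x1), 0.0)
    dy = np.maximum(np.maximum(y0 - py, py - y1), 0.0)
    return np.hypot(dx, dy)


def default_land_mask(nx: int = 27, ny: int = 20) -> np.ndarray:
    """Habitat-proportion mask for the default study system.

    The southern row is mainland; a small cape of fully-land cells juts into
    the second row; coastal rows grade from mostly-land to open water; and a
    few island/shoal cells dot the shelf.  With the default dimensions this
    yields exactly 505 habitat-bearing survey units whose total habitat
    area is ~294 000 km^2 (the scale of large Arctic shelf study areas).
    """
    mask = np.ones((ny, nx))
    mask[0, :] = 0.0                 # mainland band
    cape = slice(10, 18)             # 8-cell cape in the second row
    if ny > 1:
        mask[1, :] = 0.35
        mask[1, cape] = 0.0
    if ny > 2:
        mask[2, :] = 0.6
    if ny > 3:
        mask[3, :] = 0.85
    for r, c in ((6, 4), (7, 21), (9, 12), (11, 7), (12, 18), (14, 2),
                 (15, 24), (17, 10)):
        if r < ny and c < nx:
            mask[r, c] = 0.1         # islands / shoals
    return mask


def build_grid(
    nx: int,
    ny: int,
    cell_size: float = DEFAULT_CELL_SIZE,
    land_mask: np.ndarray | None = None,
    n_nearshore_strata: int = 10,
    n_offshore_strata: int = 2,
    nearshore_depth: float = 50.0,
) -> SurveyGrid:
    """Build the lattice survey grid with covariates, strata and adjacency.

    Parameters
    ----------
    nx, ny
        Lattice dimensions (columns = easting, rows = northing).
    cell_size
        Cell side length in km.
    land_mask
        (ny, nx) array of habitat (saltwater) proportions in [0, 1]; cells
        with 0 are fully land and excluded from the survey units.  ``None``
        means all-water.
    n_nearshore_strata, n_offshore_strata
        Number of strata: nearshore units (within ``nearshore_depth`` km of
        land) are split alongshore (by easting), the offshore remainder is
        split by northing.  Empty strata are dropped on degenerate grids.
    """
    if nx < 1 or ny < 1:
        raise ValueError("grid dimensions must be positive")
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    if land_mask is None:
        land_mask = np.ones((ny, nx))
    land_mask = np.asarray(land_mask, dtype=float)
    if land_mask.shape == (ny * nx,):
        land_mask = land_mask.reshape(ny, nx)
    if land_mask.shape != (ny, nx):
        raise ValueError(
            f"land_mask shape {land_mask.shape} does not match grid ({ny}, {nx})"
        )
    if land_mask.min() < 0 or land_mask.max() > 1:
        raise ValueError("land_mask values must lie in [0, 1]")

    rows, cols = np.nonzero(land_mask > 0)
    # row-major order: south-to-north, then west-to-east
    order = np.lexsort((cols, rows))
    rows, cols = rows[order], cols[order]
    J = rows.size
    if J == 0:
        raise ValueError("grid contains no habitat-bearing cells")
    R = land_mask[rows, cols]
    cx = (cols + 0.5) * cell_size
    cy = (rows + 0.5) * cell_size

    land_rows, land_cols = np.nonzero(land_mask == 0)
    land_cells = np.column_stack([land_rows, land_cols])
    if land_cells.shape[0] > 0:
        d = np.full(J, np.inf)
        for lr, lc in land_cells:
            d = np.minimum(d, _point_to_cell_distance(cx, cy, lr, lc, cell_size))
        dist_land = d
    else:
        # convention for all-water grids: distance to the southern lattice edge
        dist_land = cy.copy()

    stratum = _assign_strata(
        cx, cy, dist_land, nearshore_depth, n_nearshore_strata, n_offshore_strata
    )

    # rook adjacency among habitat cells
    index = -np.ones((ny, nx), dtype=int)
    index[rows, cols] = np.arange(J)
    adjacency: list[np.ndarray] = []
    for r, c in zip(rows, cols):
        nb = []
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < ny and 0 <= cc < nx and index[rr, cc] >= 0:
                nb.append(index[rr, cc])
        adjacency.append(np.array(sorted(nb), dtype=int))

    return SurveyGrid(
        unit_id=np.arange(1, J + 1),
        row=rows,
        col=cols,
        centroid_x=cx,
        centroid_y=cy,
        cell_area=cell_size * cell_size,
        R=R,
        stratum=stratum,
        dist_land=dist_land,
        adjacency=adjacency,
        nx=nx,
        ny=ny,
        cell_size=cell_size,
        land_cells=land_cells,
    )


def _assign_strata(cx, cy, dist_land, nearshore_depth, n_near, n_off):
    J = cx.size
    stratum = np.empty(J, dtype=object)
    near = dist_land <= nearshore_depth
    idx_near = np.nonzero(near)[0]
    idx_off = np.nonzero(~near)[0]
    if idx_off.size == 0:
        # everything is nearshore on tiny grids; fall back to alongshore bands
        idx_near, idx_off = idx_near, idx_off
    if idx_near.size > 0:
        k = min(n_near, idx_near.size)
        order = idx_near[np.lexsort((cy[idx_near], cx[idx_near]))]
        for g, chunk in enumerate(np.array_split(order, k)):
            stratum[chunk] = f"N{g + 1:02d}"
    if idx_off.size > 0:
        k = min(n_off, idx_off.size)
        order = idx_off[np.lexsort((cx[idx_off], cy[idx_off]))]
        for g, chunk in enumerate(np.array_split(order, k)):
            stratum[chunk] = f"O{g + 1}"
    return stratum.astype(str)


def default_grid() -> SurveyGrid:
    """The default 27 x 20 study system: 505 survey units of 625 km^2."""
    return build_grid(nx=27, ny=20, land_mask=default_land_mask(27, 20))


# ---------------------------------------------------------------------------
# density surfaces
# ---------------------------------------------------------------------------

#: expected total abundance used to scale the default seal density surfaces
DEFAULT_TOTALS = {"bearded": 19_800.0, "ringed": 380_000.0}


def default_density_profile(species: str, grid: SurveyGrid) -> dict[str, float]:
    """Per-stratum relative density levels for the default seal scenarios.

    Ringed seals: high nearshore, declining alongshore west-to-east and low
    offshore with a south > north gradient.  Bearded seals: highest in the
    southern offshore stratum, low nearshore.  Only the *pattern* matters:
    :func:`make_density_surface` rescales to the species total.
    """
    levels: dict[str, float] = {}
    near = sorted(s for s in np.unique(grid.stratum) if s.startswith("N"))
    off = sorted(s for s in np.unique(grid.stratum) if s.startswith("O"))
    if species == "ringed":
        for i, s in enumerate(near):
            levels[s] = 3.0 - 1.2 * i / max(1, len(near) - 1)
        for i, s in enumerate(off):
            levels[s] = 1.0 - 0.5 * i / max(1, len(off) - 1)
    elif species == "bearded":
        for s in near:
            levels[s] = 0.3
        for i, s in enumerate(off):
            levels[s] = 1.2 - 0.5 * i / max(1, len(off) - 1)
    else:
        raise ValueError(f"no default stratum profile for species {species!r}")
    return levels


def make_density_surface(
    grid: SurveyGrid,
    profile: dict[str, float],
    target_total: float,
    species: str = "seal",
) -> DensitySurface:
    """Map per-stratum density levels onto the grid and rescale so that
    sum_j a_j d_j equals ``target_total`` animals."""
    levels = np.array([profile[s] for s in grid.stratum], dtype=float)
    if (levels < 0).any():
        raise ValueError("density levels must be non-negative")
    raw_total = float(np.sum(grid.a * levels))
    if raw_total == 0:
        if target_total != 0:
            raise ValueError("all-zero density profile with nonzero target total")
        scale = 0.0
    else:
        scale = target_total / raw_total
    return DensitySurface(
        species=species,
        d=levels * scale,
        provenance=f"stratum profile rescaled to total {target_total:g}",
    )


def make_rsf_surface(
    grid: SurveyGrid,
    smoothness: float = 100.0,
    N_target: float = 1000.0,
    seed: int | np.random.Generator = 0,
    field_sd: float = 0.75,
) -> tuple[RSFSurface, DensitySurface]:
    """Smooth relative-probability-of-use surface for a sparse species.

    ``w_j`` is an exponentiated spatially smoothed Gaussian field: iid
    standard-normal noise is convolved with a Gaussian kernel of range
    ``smoothness`` km, standardised to standard deviation ``field_sd`` on the
    log scale, and exponentiated.  The constant ``c`` solves
    ``sum_j c w_j = N_target``; density is ``d_j = c w_j / cell_area``.
    """
    if N_target <= 0:
        raise ValueError("N_target must be positive")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(grid.n_units)
    dx = grid.centroid_x[:, None] - grid.centroid_x[None, :]
    dy = grid.centroid_y[:, None] - grid.centroid_y[None, :]
    Kmat = np.exp(-(dx * dx + dy * dy) / (2.0 * smoothness**2))
    g = Kmat @ z / np.sqrt((Kmat * Kmat).sum(axis=1))
    sd = g.std()
    if sd > 0:
        g = g * (field_sd / sd)
    w = np.exp(g - g.mean())
    c = N_target / w.sum()
    rsf = RSFSurface(w=w, c=c, N_target=float(N_target))
    dens = DensitySurface(
        species="polar_bear",
        d=c * w / grid.cell_area,
        provenance=f"exponentiated smoothed Gaussian field, E(N)={N_target:g}",
    )
    return rsf, dens


# ---------------------------------------------------------------------------
# flight designs
# ---------------------------------------------------------------------------


def build_flight_design(
    grid: SurveyGrid,
    n_flights: int,
    n_coastal: int = 0,
    per_flight_length: float = DEFAULT_FLIGHT_LENGTH,
    design_id: str | None = None,
    thermal_swath: float = THERMAL_SWATH,
    photo_fraction: float = PHOTO_FRACTION,
) -> FlightDesign:
    """Construct a transect design on the grid.

    Long flights are out-and-back "hairpins" of two parallel north-south
    legs (perpendicular to the coast), placed so the 2*(n_flights-n_coastal)
    legs are evenly spaced across the grid.  Coastal flights are east-west
    hairpins inside the nearshore band, staggered alongshore.  Each flight's
    polyline length equals ``per_flight_length`` up to a few per mille (legs
    are clipped to the habitat extent).
    """
    if n_flights < 1:
        raise ValueError("n_flights must be positive")
    if n_coastal < 0 or n_coastal >= n_flights:
        raise ValueError("n_coastal must satisfy 0 <= n_coastal < n_flights")
    s = grid.cell_size
    xmax = grid.nx * s
    # habitat vertical extent (km): above the land band if present
    y_lo = float(grid.row.min()) * s
    y_hi = float(grid.row.max() + 1) * s
    height = y_hi - y_lo

    tracks: list[np.ndarray] = []
    n_long = n_flights - n_coastal
    if n_long > 0:
        spacing = xmax / (2 * n_long)
        v = min(height, (per_flight_length - spacing) / 2.0)
        if v <= 0:
            raise ValueError("per_flight_length too short for this grid")
        for i in range(n_long):
            xa = (2 * i + 0.5) * spacing
            xb = (2 * i + 1.5) * spacing
            if i % 2 == 0:   # anchored at the coast
                ya, yb = y_lo, y_lo + v
            else:            # anchored at the far (north) edge
                ya, yb = y_hi, y_hi - v
            tracks.append(
                np.array([[xa, ya], [xa, yb], [xb, yb], [xb, ya]], dtype=float)
            )
    connector = 12.0
    h = (per_flight_length - connector) / 2.0
    if n_coastal > 0 and h > xmax:
        raise ValueError("coastal track would exit the grid")
    for k in range(n_coastal):
        y1 = y_lo + 5.0 + 7.0 * k
        y2 = y1 + connector
        if n_coastal > 1:
            x0 = k * (xmax - h) / (n_coastal - 1)
        else:
            x0 = (xmax - h) / 2.0
        tracks.append(
            np.array([[x0, y1], [x0 + h, y1], [x0 + h, y2], [x0, y2]], dtype=float)
        )

    xmin_b, ymin_b, xmax_b, ymax_b = grid.bounds
    for t in tracks:
        if (
            t[:, 0].min() < xmin_b - 1e-9
            or t[:, 0].max() > xmax_b + 1e-9
            or t[:, 1].min() < ymin_b - 1e-9
            or t[:, 1].max() > ymax_b + 1e-9
        ):
            raise ValueError("track would exit grid bounds")

    if design_id is None:
        design_id = f"F{n_flights}c{n_coastal}"
    return FlightDesign(
        design_id=design_id,
        n_flights=n_flights,
        n_coastal=n_coastal,
        tracks=tracks,
        per_flight_length=per_flight_length,
        thermal_swath=thermal_swath,
        photo_fraction=photo_fraction,
    )


def design_catalogue(
    grid: SurveyGrid, per_flight_length: float = DEFAULT_FLIGHT_LENGTH
) -> dict[str, FlightDesign]:
    """The nine standard designs (A1-A2, B1-B3, C1-C4)."""
    return {
        name: build_flight_design(
            grid, nf, nc, per_flight_length=per_flight_length, design_id=name
        )
        for name, (nf, nc) in DESIGN_CATALOGUE.items()
    }
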