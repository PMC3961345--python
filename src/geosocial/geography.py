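"""Geographic substrate: rasters, great-circle distances, density-weighted sampling.

This module provides everything the mobility model needs to know about space:
a population raster (read from an ESRI ASCII grid or synthesized as a mixture
of Gaussian "cities"), haversine distances, population-weighted placement of
agents, jump-length laws (truncated power law, truncated normal, uniform) and
the density-weighted choice of a jump target at a given distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize

EARTH_RADIUS_KM = 6371.0
#: km per degree of latitude (and of longitude at the equator) on the sphere
KM_PER_DEG = 2.0 * math.pi * EARTH_RADIUS_KM / 360.0


class InputError(ValueError):
    """Invalid argument values (coordinates out of range, empty grids, ...)."""


class FormatError(ValueError):
    """Malformed input files."""


@dataclass(frozen=True)
class Location:
    """A point on the WGS84 sphere, decimal degrees."""

    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not (-90.0 <= self.lat <= 90.0):
            raise InputError(f"latitude {self.lat} outside [-90, 90]")
        if not (-180.0 <= self.lon <= 180.0):
            raise InputError(f"longitude {self.lon} outside [-180, 180]")


def great_circle_distance(a: Location, b: Location) -> float:
    """Haversine distance in km between two locations (sphere R = 6371 km)."""
    return float(
        haversine_km(
            np.asarray(a.lat), np.asarray(a.lon), np.asarray(b.lat), np.asarray(b.lon)
        )
    )


def haversine_km(lat1, lon1, lat2, lon2):
    """Vectorized haversine; arguments in decimal degrees, result in km."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


@dataclass
class PopulationGrid:
    """Georeferenced population counts on a regular lat/lon grid.

    Rows are ordered north -> south (raster convention): row 0 holds the
    northernmost cells.  ``xllcorner``/``yllcorner`` georeference the lower-left
    corner of the grid, as in the ESRI ASCII dialect.
    """

    xllcorner: float
    yllcorner: float
    cellsize: float
    counts: np.ndarray  # (n_rows, n_cols), float, >= 0
    nodata: float = -9999.0

    # cached flattened cell-center coordinates for vectorized queries
    _lats: np.ndarray = field(init=False, repr=False)
    _lons: np.ndarray = field(init=False, repr=False)
    _flat: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise InputError("counts must be a 2-D array")
        if np.any(self.counts < 0):
            raise FormatError("negative population counts")
        if self.total_population <= 0:
            raise FormatError("grid has zero total population")
        n_rows, n_cols = self.counts.shape
        # row 0 = northernmost band
        lat_centers = self.yllcorner + (np.arange(n_rows)[::-1] + 0.5) * self.cellsize
        lon_centers = self.xllcorner + (np.arange(n_cols) + 0.5) * self.cellsize
        glat, glon = np.meshgrid(lat_centers, lon_centers, indexing="ij")
        object.__setattr__(self, "_lats", glat.ravel())
        object.__setattr__(self, "_lons", glon.ravel())
        object.__setattr__(self, "_flat", self.counts.ravel())
        # precomputed trig for fast annulus queries (row 0 = north)
        object.__setattr__(self, "_lat_rad", np.radians(glat.ravel()))
        object.__setattr__(self, "_lon_rad", np.radians(glon.ravel()))
        object.__setattr__(self, "_cos_lat", np.cos(np.radians(glat.ravel())))
        object.__setattr__(self, "_row_lat_centers", lat_centers)
        object.__setattr__(
            self, "_density_max", float((self._flat / self._cos_lat).max())
        )

    @property
    def n_rows(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cols(self) -> int:
        return self.counts.shape[1]

    @property
    def total_population(self) -> float:
        return float(self.counts.sum())

    @property
    def lat_max(self) -> float:
        return self.yllcorner + self.n_rows * self.cellsize

    @property
    def lon_max(self) -> float:
        return self.xllcorner + self.n_cols * self.cellsize

    def contains(self, loc: Location) -> bool:
        return (
            self.yllcorner <= loc.lat <= self.lat_max
            and self.xllcorner <= loc.lon <= self.lon_max
        )

    def cell_of(self, loc: Location) -> tuple[int, int]:
        """(row, col) of the cell containing ``loc`` (row 0 = north)."""
        col = int((loc.lon - self.xllcorner) / self.cellsize)
        row_from_south = int((loc.lat - self.yllcorner) / self.cellsize)
        row = self.n_rows - 1 - row_from_south
        return (min(max(row, 0), self.n_rows - 1), min(max(col, 0), self.n_cols - 1))

    def cell_bounds(self, row: int, col: int) -> tuple[float, float, float, float]:
        """(lat_south, lat_north, lon_west, lon_east) of a cell."""
        lat_s = self.yllcorner + (self.n_rows - 1 - row) * self.cellsize
        lon_w = self.xllcorner + col * self.cellsize
        return lat_s, lat_s + self.cellsize, lon_w, lon_w + self.cellsize

    def jitter_in_cell(self, row: int, col: int, rng: np.random.Generator) -> Location:
        lat_s, lat_n, lon_w, lon_e = self.cell_bounds(row, col)
        return Location(
            lat=float(rng.uniform(lat_s, lat_n)), lon=float(rng.uniform(lon_w, lon_e))
        )


def read_population_raster(path) -> PopulationGrid:
    """Read an ESRI ASCII grid (.asc).  NODATA cells are mapped to 0 population."""
    with open(path) as fh:
        tokens = fh.read().split()
    header = {}
    i = 0
    expected = ["ncols", "nrows", "xllcorner", "yllcorner", "cellsize"]
    while i + 1 < len(tokens) and tokens[i].lower().lstrip("#") in expected + ["nodata_value"]:
        header[tokens[i].lower()] = float(tokens[i + 1])
        i += 2
    for key in expected:
        if key not in header:
            raise FormatError(f"missing header field {key!r}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    nodata = header.get("nodata_value", -9999.0)
    values = tokens[i:]
    if len(values) != nrows * ncols:
        raise FormatError(
            f"expected {nrows * ncols} cell values, found {len(values)}"
        )
    try:
        arr = np.array(values, dtype=float).reshape(nrows, ncols)
    except ValueError as exc:
        raise FormatError(f"non-numeric cell value: {exc}") from exc
    arr = np.where(arr == nodata, 0.0, arr)
    if np.any(arr < 0):
        raise FormatError("negative population counts in raster")
    return PopulationGrid(
        xllcorner=header["xllcorner"],
        yllcorner=header["yllcorner"],
        cellsize=header["cellsize"],
        counts=arr,
        nodata=nodata,
    )


def write_population_raster(path, grid: PopulationGrid) -> None:
    """Write the grid back out in the same ESRI ASCII dialect (exact round-trip)."""
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {float(grid.xllcorner)!r}\n")
        fh.write(f"yllcorner {float(grid.yllcorner)!r}\n")
        fh.write(f"cellsize {float(grid.cellsize)!r}\n")
        fh.write(f"NODATA_value {float(grid.nodata)!r}\n")
        for row in grid.counts:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def synth_population_grid(
    extent: tuple[float, float, float, float],
    n_cities: int = 3,
    city_weights: Sequence[float] | None = None,
    city_sd_km: float | Sequence[float] = 30.0,
    cellsize: float = 0.05,
    total_population: float = 1_000_000.0,
    seed: int | None = 0,
    city_centers: Sequence[tuple[float, float]] | None = None,
) -> PopulationGrid:
    """Synthesize a population raster as a mixture of isotropic Gaussian cities.

    ``extent`` is (lat_min, lat_max, lon_min, lon_max).  City centers are drawn
    uniformly in the interior unless given explicitly; each city holds a share
    of ``total_population`` proportional to its weight, spread as a 2-D Gaussian
    with standard deviation ``city_sd_km`` (per-city values allowed).
    Deterministic for a given seed.
    """
    lat_min, lat_max, lon_min, lon_max = extent
    if n_cities < 1:
        raise InputError("n_cities must be >= 1")
    if lat_max - lat_min < cellsize or lon_max - lon_min < cellsize:
        raise InputError("extent smaller than one cell")
    if city_weights is None:
        city_weights = [1.0] * n_cities
    city_weights = np.asarray(city_weights, dtype=float)
    if len(city_weights) != n_cities or np.any(city_weights <= 0):
        raise InputError("need one positive weight per city")
    sds = np.broadcast_to(np.asarray(city_sd_km, dtype=float), (n_cities,))
    rng = np.random.default_rng(seed)
    n_rows = int(round((lat_max - lat_min) / cellsize))
    n_cols = int(round((lon_max - lon_min) / cellsize))
    if city_centers is None:
        # keep centers off the border so most Gaussian mass stays on-grid
        pad_lat = 0.15 * (lat_max - lat_min)
        pad_lon = 0.15 * (lon_max - lon_min)
        city_centers = [
            (
                rng.uniform(lat_min + pad_lat, lat_max - pad_lat),
                rng.uniform(lon_min + pad_lon, lon_max - pad_lon),
            )
            for _ in range(n_cities)
        ]
    lat_centers = lat_min + (np.arange(n_rows)[::-1] + 0.5) * cellsize
    lon_centers = lon_min + (np.arange(n_cols) + 0.5) * cellsize
    glat, glon = np.meshgrid(lat_centers, lon_centers, indexing="ij")
    counts = np.zeros((n_rows, n_cols))
    shares = total_population * city_weights / city_weights.sum()
    for (clat, clon), sd, share in zip(city_centers, sds, shares):
        dx = (glon - clon) * KM_PER_DEG * math.cos(math.radians(clat))
        dy = (glat - clat) * KM_PER_DEG
        dens = np.exp(-(dx**2 + dy**2) / (2.0 * sd**2))
        s = dens.sum()
        if s > 0:
            counts += share * dens / s
    counts = np.round(counts, 6)
    return PopulationGrid(
        xllcorner=lon_min, yllcorner=lat_min, cellsize=cellsize, counts=counts
    )


def sample_initial_positions(
    grid: PopulationGrid, n: int, seed: int | np.random.Generator | None = 0
) -> list[Location]:
    """Draw agent home positions: cell ~ population, point uniform in cell."""
    if grid.total_population <= 0:
        raise InputError("grid has zero population")
    rng = np.random.default_rng(seed)
    if n == 0:
        return []
    probs = grid._flat / grid._flat.sum()
    idx = rng.choice(grid._flat.size, size=n, p=probs)
    rows, cols = np.unravel_index(idx, grid.counts.shape)
    return [grid.jitter_in_cell(r, c, rng) for r, c in zip(rows, cols)]


# --------------------------------------------------------------------------
# jump-length laws
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class JumpSpec:
    """Distribution of jump (displacement) lengths in km.

    ``powerlaw``: density proportional to r^(-exponent) truncated to
    [d_min, d_max]; the default exponent magnitude is 1.55, the value reported
    for human displacement lengths.  ``normal``: Gaussian(mean, sd) truncated
    below at d_min and above at d_max.  ``uniform``: flat on [d_min, d_max].
    """

    family: str = "powerlaw"
    exponent: float = 1.55
    d_min: float = 1.0
    d_max: float = 20000.0
    mean: float = 100.0
    sd: float = 50.0

    def __post_init__(self) -> None:
        if self.family not in ("powerlaw", "normal", "uniform"):
            raise InputError(f"unknown jump family {self.family!r}")
        if self.d_min <= 0 or self.d_max <= self.d_min:
            raise InputError("need 0 < d_min < d_max")

    def sample(self, rng: np.random.Generator, size=None) -> np.ndarray | float:
        u = rng.random(size)
        if self.family == "powerlaw":
            a = abs(self.exponent)
            if abs(a - 1.0) < 1e-12:
                x = self.d_min * (self.d_max / self.d_min) ** u
            else:
                g = 1.0 - a
                lo, hi = self.d_min**g, self.d_max**g
                x = (lo + u * (hi - lo)) ** (1.0 / g)
            return x
        if self.family == "uniform":
            return self.d_min + u * (self.d_max - self.d_min)
        # truncated normal via inverse CDF between the truncation quantiles
        from scipy.stats import norm

        lo = norm.cdf((self.d_min - self.mean) / self.sd) if self.sd > 0 else 0.0
        hi = norm.cdf((self.d_max - self.mean) / self.sd) if self.sd > 0 else 1.0
        if self.sd == 0:
            return np.full_like(np.asarray(u, dtype=float), self.mean) if size else self.mean
        return self.mean + self.sd * norm.ppf(lo + u * (hi - lo))

    def cdf(self, r) -> np.ndarray:
        """Analytic CDF (power-law and uniform families)."""
        r = np.asarray(np.clip(r, self.d_min, self.d_max), dtype=float)
        if self.family == "powerlaw":
            a = abs(self.exponent)
            if abs(a - 1.0) < 1e-12:
                return np.log(r / self.d_min) / np.log(self.d_max / self.d_min)
            g = 1.0 - a
            return (r**g - self.d_min**g) / (self.d_max**g - self.d_min**g)
        if self.family == "uniform":
            return (r - self.d_min) / (self.d_max - self.d_min)
        raise NotImplementedError("CDF implemented for powerlaw and uniform")


def sample_jump_length(spec: JumpSpec, rng: np.random.Generator, size=None):
    """Draw one (or ``size``) jump length(s) from ``spec``."""
    return spec.sample(rng, size=size)


def fit_truncated_powerlaw(
    samples: np.ndarray, d_min: float, d_max: float
) -> float:
    """Maximum-likelihood exponent magnitude of a doubly truncated power law.

    The density is C r^(-a) on [d_min, d_max]; the MLE maximizes
    n log C(a) - a sum(log r) over a, solved numerically.
    Returns the estimated magnitude a-hat (> 0).
    """
    x = np.asarray(samples, dtype=float)
    if np.any((x < d_min) | (x > d_max)):
        raise InputError("samples outside the truncation bounds")
    n = x.size
    slog = float(np.log(x).sum())

    def negloglik(a: float) -> float:
        if abs(a - 1.0) < 1e-9:
            logc = -math.log(math.log(d_max / d_min))
        else:
            g = 1.0 - a
            logc = math.log(abs(g) / abs(d_max**g - d_min**g))
        return -(n * logc - a * slog)

    res = optimize.minimize_scalar(negloglik, bounds=(0.01, 6.0), method="bounded")
    return float(res.x)


# --------------------------------------------------------------------------
# density-weighted jump targets
# --------------------------------------------------------------------------

def annulus_width(grid: PopulationGrid, origin: Location, r: float) -> float:
    """Annulus width: max(cell diagonal at the origin latitude, 0.05 r)."""
    diag = grid.cellsize * KM_PER_DEG * math.hypot(
        1.0, math.cos(math.radians(origin.lat))
    )
    return max(diag, 0.05 * r)


def _destination_points(origin: Location, r: float, thetas: np.ndarray):
    """Points at great-circle distance r from origin along bearings ``thetas``."""
    delta = r / EARTH_RADIUS_KM
    phi1 = math.radians(origin.lat)
    lam1 = math.radians(origin.lon)
    sin_phi2 = math.sin(phi1) * math.cos(delta) + math.cos(phi1) * math.sin(
        delta
    ) * np.cos(thetas)
    sin_phi2 = np.minimum(np.maximum(sin_phi2, -1.0), 1.0)
    phi2 = np.arcsin(sin_phi2)
    lam2 = lam1 + np.arctan2(
        np.sin(thetas) * math.sin(delta) * math.cos(phi1),
        math.cos(delta) - math.sin(phi1) * sin_phi2,
    )
    lam2 = (lam2 + math.pi) % (2.0 * math.pi) - math.pi
    return np.degrees(phi2), np.degrees(lam2)


def _density_at(grid: PopulationGrid, lats: np.ndarray, lons: np.ndarray) -> np.ndarray:
    """Population density (count per unit area) at points; 0 outside the grid."""
    inv = 1.0 / grid.cellsize
    cols = ((lons - grid.xllcorner) * inv).astype(int)
    rows_s = ((lats - grid.yllcorner) * inv).astype(int)
    inside = (
        (lats >= grid.yllcorner)
        & (lats <= grid.lat_max)
        & (lons >= grid.xllcorner)
        & (lons <= grid.lon_max)
    )
    cols = np.where(inside, np.minimum(cols, grid.n_cols - 1), 0)
    rows_s = np.where(inside, np.minimum(rows_s, grid.n_rows - 1), 0)
    counts = grid.counts[grid.n_rows - 1 - rows_s, cols]
    # cell area shrinks with cos(lat); density = count / area
    dens = counts / np.maximum(np.cos(np.radians(lats)), 1e-6)
    return np.where(inside, dens, 0.0)


def _density_at_scalar(grid: PopulationGrid, lat: float, lon: float) -> float:
    if not (
        grid.yllcorner <= lat <= grid.lat_max
        and grid.xllcorner <= lon <= grid.lon_max
    ):
        return 0.0
    col = min(int((lon - grid.xllcorner) / grid.cellsize), grid.n_cols - 1)
    row_s = min(int((lat - grid.yllcorner) / grid.cellsize), grid.n_rows - 1)
    c = grid.counts[grid.n_rows - 1 - row_s, col]
    return float(c) / max(math.cos(math.radians(lat)), 1e-6)


def sample_jump_target(
    grid: PopulationGrid,
    origin: Location,
    r: float,
    rng: np.random.Generator,
) -> Location | None:
    """Pick a destination at distance r in a density-weighted direction.

    The bearing is drawn with probability density proportional to the
    population density at the point of the circle of radius r around the
    origin (rejection sampling against the circle's density profile, so the
    bearing law is exact and continuous); the landing point is then jittered
    radially within the annulus [r - w/2, r + w/2] along the same bearing,
    avoiding both artificial zero distances and grid-quantized directions.
    Returns None when the whole circle carries no population (the caller's
    fallback policy applies).
    """
    if r <= 0:
        raise InputError("jump length must be positive")
    if not grid.contains(origin):
        raise InputError("origin outside grid extent")
    # fast path: rejection against the grid-wide density bound (agents mostly
    # sit in dense areas, where acceptance is high)
    for _ in range(4):
        t = rng.random(64) * 2.0 * math.pi
        plat, plon = _destination_points(origin, r, t)
        pw = _density_at(grid, plat, plon)
        acc = np.flatnonzero(rng.random(64) * grid._density_max < pw)
        if acc.size:
            return _radial_jitter(grid, origin, r, float(t[int(acc[0])]), rng)
    # slow path: scan the circle's density profile and bound locally
    cell_km = grid.cellsize * KM_PER_DEG
    n_scan = int(np.clip(2.0 * math.pi * r / cell_km, 64, 2048))
    thetas = np.linspace(0.0, 2.0 * math.pi, n_scan, endpoint=False)
    lats, lons = _destination_points(origin, r, thetas)
    w = _density_at(grid, lats, lons)
    wmax = float(w.max())
    if wmax <= 0.0:
        return None
    for _ in range(50):
        t = rng.random(64) * 2.0 * math.pi
        plat, plon = _destination_points(origin, r, t)
        pw = _density_at(grid, plat, plon)
        acc = np.flatnonzero(rng.random(64) * wmax < pw)
        if acc.size:
            return _radial_jitter(grid, origin, r, float(t[int(acc[0])]), rng)
    # pathological acceptance rate: fall back to the scanned profile
    cum = np.cumsum(w)
    i = int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))
    return _radial_jitter(grid, origin, r, float(thetas[i]), rng)


def _radial_jitter(
    grid: PopulationGrid,
    origin: Location,
    r: float,
    theta: float,
    rng: np.random.Generator,
) -> Location:
    """Perturb the landing distance within the annulus, staying on population."""
    w = annulus_width(grid, origin, r)
    radii = r + (rng.random(8) - 0.5) * w
    for ri in radii[radii > 0]:
        lat, lon = _destination_point_scalar(origin, float(ri), theta)
        if _density_at_scalar(grid, lat, lon) > 0:
            return Location(lat, lon)
    lat, lon = _destination_point_scalar(origin, r, theta)
    return Location(lat, lon)


def _destination_point_scalar(origin: Location, r: float, theta: float):
    delta = r / EARTH_RADIUS_KM
    phi1 = math.radians(origin.lat)
    sin_phi2 = math.sin(phi1) * math.cos(delta) + math.cos(phi1) * math.sin(
        delta
    ) * math.cos(theta)
    sin_phi2 = min(max(sin_phi2, -1.0), 1.0)
    phi2 = math.asin(sin_phi2)
    lam2 = math.radians(origin.lon) + math.atan2(
        math.sin(theta) * math.sin(delta) * math.cos(phi1),
        math.cos(delta) - math.sin(phi1) * sin_phi2,
    )
    lam2 = (lam2 + math.pi) % (2.0 * math.pi) - math.pi
    return math.degrees(phi2), math.degrees(lam2)


def nearest_populated_target(
    grid: PopulationGrid, origin: Location, r: float, rng: np.random.Generator
) -> Location:
    """Fallback: the populated cell whose center distance is closest to r."""
    d = haversine_km(origin.lat, origin.lon, grid._lats, grid._lons)
    pop = grid._flat > 0
    score = np.where(pop, np.abs(d - r), np.inf)
    idx = int(np.argmin(score))
    row, col = np.unravel_index(idx, grid.counts.shape)
    return grid.jitter_in_cell(int(row), int(col), rng)
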