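"""Geographic substrate: distances, rasters, placement, jump sampling."""

import math

import numpy as np
import pytest
from scipy import stats

from geosocial.geography import (
    EARTH_RADIUS_KM,
    FormatError,
    InputError,
    JumpSpec,
    Location,
    PopulationGrid,
    fit_truncated_powerlaw,
    great_circle_distance,
    nearest_populated_target,
    read_population_raster,
    sample_initial_positions,
    sample_jump_length,
    sample_jump_target,
    synth_population_grid,
    write_population_raster,
)


class TestGreatCircle:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ((10, 20), (10, 20), 0.0),
            ((0, 0), (0, 180), math.pi * EARTH_RADIUS_KM),  # antipodal on equator
            ((0, 0), (0, 1), 2 * math.pi * EARTH_RADIUS_KM / 360),  # one degree
        ],
    )
    def test_known_distances(self, a, b, expected):
        d = great_circle_distance(Location(*a), Location(*b))
        assert d == pytest.approx(expected, abs=1e-6)

    def test_is_a_metric_on_random_triples(self):
        rng = np.random.default_rng(0)
        pts = [
            Location(float(rng.uniform(-80, 80)), float(rng.uniform(-179, 179)))
            for _ in range(30)
        ]
        for a, b, c in zip(pts[:10], pts[10:20], pts[20:]):
            dab = great_circle_distance(a, b)
            dba = great_circle_distance(b, a)
            assert dab == pytest.approx(dba, rel=1e-12)  # symmetry
            assert dab >= 0
            dac = great_circle_distance(a, c)
            dbc = great_circle_distance(b, c)
            assert dab <= dac + dbc + 1e-9  # triangle inequality

    def test_coordinate_validation(self):
        with pytest.raises(InputError):
            Location(91.0, 0.0)
        with pytest.raises(InputError):
            Location(0.0, 181.0)


class TestRaster:
    def test_read_sums_and_header(self, tmp_path):
        p = tmp_path / "g.asc"
        p.write_text(
            "ncols 2\nnrows 2\nxllcorner 10\nyllcorner 40\ncellsize 0.5\n"
            "NODATA_value -9999\n5 5\n5 5\n"
        )
        g = read_population_raster(p)
        assert g.total_population == 20
        assert (g.n_rows, g.n_cols, g.cellsize) == (2, 2, 0.5)

    def test_nodata_cells_carry_zero_weight(self, tmp_path):
        p = tmp_path / "g.asc"
        p.write_text(
            "ncols 2\nnrows 1\nxllcorner 0\nyllcorner 0\ncellsize 1\n"
            "NODATA_value -1\n-1 7\n"
        )
        g = read_population_raster(p)
        assert g.total_population == 7
        assert g.counts[0, 0] == 0

    def test_value_count_mismatch_is_format_error(self, tmp_path):
        p = tmp_path / "g.asc"
        p.write_text(
            "ncols 2\nnrows 2\nxllcorner 0\nyllcorner 0\ncellsize 1\n"
            "NODATA_value -1\n1 2 3\n"
        )
        with pytest.raises(FormatError):
            read_population_raster(p)

    def test_round_trip_is_exact(self, tmp_path):
        g = synth_population_grid(
            (45.0, 47.0, 5.0, 7.0), n_cities=2, city_weights=[2, 1], seed=3
        )
        p = tmp_path / "rt.asc"
        write_population_raster(p, g)
        g2 = read_population_raster(p)
        np.testing.assert_array_equal(g.counts, g2.counts)
        assert (g.xllcorner, g.yllcorner, g.cellsize) == (
            g2.xllcorner, g2.yllcorner, g2.cellsize,
        )


class TestSyntheticGrid:
    def test_single_tight_city_peaks_at_center(self):
        g = synth_population_grid(
            (45.0, 47.0, 5.0, 7.0), n_cities=1, city_sd_km=2.0, seed=0,
            city_centers=[(46.0, 6.0)],
        )
        r, c = np.unravel_index(np.argmax(g.counts), g.counts.shape)
        peak = g.cell_bounds(int(r), int(c))
        assert peak[0] <= 46.0 <= peak[1] and peak[2] <= 6.0 <= peak[3]

    def test_two_city_mass_ratio(self):
        g = synth_population_grid(
            (40.0, 50.0, 0.0, 10.0), n_cities=2, city_weights=[3, 1],
            city_sd_km=20.0, seed=0, city_centers=[(43.0, 3.0), (47.0, 7.0)],
            cellsize=0.05,
        )
        lat = np.linspace(50.0 - 0.025, 40.0 + 0.025, g.n_rows)[:, None]
        lon = np.linspace(0.025, 9.975, g.n_cols)[None, :]
        # mass within 3 sd (~0.54 deg) of each center
        near1 = (np.abs(lat - 43.0) < 0.6) & (np.abs(lon - 3.0) < 0.8)
        near2 = (np.abs(lat - 47.0) < 0.6) & (np.abs(lon - 7.0) < 0.8)
        ratio = g.counts[near1].sum() / g.counts[near2].sum()
        assert ratio == pytest.approx(3.0, rel=0.05)

    def test_same_seed_identical(self):
        a = synth_population_grid((45, 47, 5, 7), n_cities=3, seed=9)
        b = synth_population_grid((45, 47, 5, 7), n_cities=3, seed=9)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_tiny_extent_rejected(self):
        with pytest.raises(InputError):
            synth_population_grid((45, 45.01, 5, 5.01), cellsize=0.5)


class TestInitialPositions:
    def test_degenerate_single_cell(self):
        counts = np.zeros((3, 3))
        counts[1, 1] = 10.0
        g = PopulationGrid(xllcorner=0, yllcorner=0, cellsize=1.0, counts=counts)
        pts = sample_initial_positions(g, 50, seed=0)
        for p in pts:
            assert 1.0 <= p.lat <= 2.0 and 1.0 <= p.lon <= 2.0

    def test_two_equal_cells_binomial(self):
        counts = np.array([[1.0, 1.0]])
        g = PopulationGrid(xllcorner=0, yllcorner=0, cellsize=1.0, counts=counts)
        n = 10_000
        pts = sample_initial_positions(g, n, seed=1)
        left = sum(1 for p in pts if p.lon < 1.0)
        sigma = math.sqrt(n * 0.25)
        assert abs(left - n / 2) < 3 * sigma

    def test_empirical_frequencies_match_weights(self):
        rng = np.random.default_rng(5)
        counts = rng.uniform(1, 10, size=(2, 5))
        g = PopulationGrid(xllcorner=0, yllcorner=0, cellsize=1.0, counts=counts)
        n = 1_000_000
        pts = sample_initial_positions(g, n, seed=2)
        freq = np.zeros((2, 5))
        for p in pts:
            freq[g.cell_of(p)] += 1
        tv = 0.5 * np.abs(freq / n - counts / counts.sum()).sum()
        assert tv < 0.01

    def test_zero_requests_and_zero_population(self):
        counts = np.array([[1.0]])
        g = PopulationGrid(xllcorner=0, yllcorner=0, cellsize=1.0, counts=counts)
        assert sample_initial_positions(g, 0, seed=0) == []
        with pytest.raises(FormatError):
            PopulationGrid(xllcorner=0, yllcorner=0, cellsize=1.0, counts=np.zeros((2, 2)))


class TestJumpLengths:
    def test_powerlaw_cdf_matches_analytic(self):
        spec = JumpSpec()
        rng = np.random.default_rng(0)
        x = np.sort(sample_jump_length(spec, rng, size=1_000_000))
        ecdf = np.arange(1, x.size + 1) / x.size
        assert np.max(np.abs(ecdf - spec.cdf(x))) < 0.005

    def test_uniform_family(self):
        spec = JumpSpec(family="uniform", d_min=10.0, d_max=50.0)
        rng = np.random.default_rng(1)
        x = sample_jump_length(spec, rng, size=20_000)
        assert x.min() >= 10.0 and x.max() <= 50.0
        assert stats.kstest(x, stats.uniform(10.0, 40.0).cdf).pvalue > 0.01

    def test_truncated_normal_respects_bounds(self):
        spec = JumpSpec(family="normal", d_min=1.0, d_max=100.0, mean=5.0, sd=10.0)
        rng = np.random.default_rng(2)
        x = spec.sample(rng, size=10_000)
        assert x.min() >= 1.0 and x.max() <= 100.0

    def test_mle_recovers_exponent_at_modest_n(self):
        spec = JumpSpec(exponent=2.1, d_min=1.0, d_max=500.0)
        rng = np.random.default_rng(3)
        x = spec.sample(rng, size=200_000)
        assert fit_truncated_powerlaw(x, 1.0, 500.0) == pytest.approx(2.1, abs=0.03)

    def test_invalid_specs_rejected(self):
        with pytest.raises(InputError):
            JumpSpec(d_min=0.0)
        with pytest.raises(InputError):
            JumpSpec(d_min=10.0, d_max=5.0)
        with pytest.raises(InputError):
            JumpSpec(family="cauchy")


@pytest.fixture(scope="module")
def uniform_grid():
    return PopulationGrid(
        xllcorner=0.0, yllcorner=40.0, cellsize=0.1, counts=np.ones((80, 80))
    )


class TestJumpTargets:

    def test_single_populated_annulus_cell_always_chosen(self):
        counts = np.zeros((9, 9))
        counts[4, 4] = 1.0  # origin cell (also populated so grid is valid)
        counts[4, 8] = 5.0  # the only cell near distance ~0.4 deg east
        g = PopulationGrid(xllcorner=0, yllcorner=0, cellsize=0.1, counts=counts)
        origin = Location(0.45, 0.45)
        r = great_circle_distance(origin, Location(0.45, 0.85))
        rng = np.random.default_rng(0)
        for _ in range(25):
            t = sample_jump_target(g, origin, r, rng)
            assert t is not None
            assert 0.8 <= t.lon <= 0.9

    def test_uniform_grid_gives_uniform_bearings(self, uniform_grid):
        origin = Location(44.0, 4.0)
        rng = np.random.default_rng(1)
        n = 100_000
        bearings = np.empty(n)
        for i in range(n):
            t = sample_jump_target(uniform_grid, origin, 50.0, rng)
            dy = t.lat - origin.lat
            dx = (t.lon - origin.lon) * math.cos(math.radians(origin.lat))
            bearings[i] = math.atan2(dy, dx) % (2 * math.pi)
        obs, _ = np.histogram(bearings, bins=12, range=(0, 2 * math.pi))
        assert stats.chisquare(obs).pvalue > 0.01

    def test_weighted_cells_selected_in_proportion(self):
        # two populated cells at the same distance east/west of the origin,
        # population ratio 9:1
        counts = np.zeros((3, 5))
        counts[1, 2] = 1.0  # origin cell
        counts[1, 0] = 9.0
        counts[1, 4] = 1.0
        g = PopulationGrid(xllcorner=0, yllcorner=0, cellsize=0.1, counts=counts)
        origin = Location(0.15, 0.25)
        r = great_circle_distance(origin, Location(0.15, 0.05))
        rng = np.random.default_rng(2)
        n = 5000
        hits_west = 0
        for _ in range(n):
            t = sample_jump_target(g, origin, r, rng)
            assert t is not None
            if t.lon < 0.25:
                hits_west += 1
        p = 0.9
        sigma = math.sqrt(n * p * (1 - p))
        assert abs(hits_west - n * p) < 3 * sigma

    def test_never_selects_empty_cell(self, uniform_grid):
        g = PopulationGrid(
            xllcorner=0.0,
            yllcorner=40.0,
            cellsize=0.1,
            counts=np.kron(np.indices((40, 40)).sum(axis=0) % 2, np.ones((2, 2))),
        )
        origin = Location(44.0, 4.0)
        rng = np.random.default_rng(3)
        for _ in range(300):
            r = float(rng.uniform(5, 200))
            t = sample_jump_target(g, origin, r, rng)
            if t is not None:
                row, col = g.cell_of(t)
                assert g.counts[row, col] > 0

    def test_origin_outside_grid_rejected(self, uniform_grid):
        with pytest.raises(InputError):
            sample_jump_target(
                uniform_grid, Location(10.0, 4.0), 50.0, np.random.default_rng(0)
            )

    def test_fallback_picks_nearest_populated(self):
        counts = np.zeros((3, 3))
        counts[0, 0] = 1.0
        g = PopulationGrid(xllcorner=0, yllcorner=0, cellsize=1.0, counts=counts)
        t = nearest_populated_target(g, Location(0.5, 0.5), 5000.0, np.random.default_rng(0))
        assert g.counts[g.cell_of(t)] > 0
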