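"""Deterministic synthetic worlds and planted-structure networks.

These generators produce test substrates with known ground truth: a Gaussian
multi-city world emulating heterogeneous national population density (a few
dominant cities over a sparse countryside, at the node counts of the smaller
country datasets), plus networks with a planted link-probability slope,
planted per-distance-scale reciprocity, and planted triangles at separated
distance scales, for exercising the statistics against construction oracles.
"""

from __future__ import annotations

import numpy as np

from .geography import (
    InputError,
    KM_PER_DEG,
    Location,
    haversine_km,
    sample_initial_positions,
    synth_population_grid,
)
from .network import DirectedGeoNetwork
from .tf_model import ModelParams, run_tf

FIXTURE_KINDS = (
    "gaussian_world",
    "planted_p1_slope",
    "planted_reciprocity",
    "planted_triangles",
    "tf_reference",
)

#: default synthetic world: a UK/Germany-scale country (~10 deg extent) with
#: three cities of population share 3:2:1 and 30 km spread
DEFAULT_WORLD = dict(
    extent=(45.0, 55.0, 0.0, 10.0),
    n_cities=3,
    city_weights=(3.0, 2.0, 1.0),
    city_sd_km=30.0,
    cellsize=0.1,
)


def gaussian_world(n_agents: int = 2000, seed: int = 0, **overrides):
    """(grid, positions): multi-city world plus density-sampled agent homes."""
    opts = {**DEFAULT_WORLD, **overrides}
    grid = synth_population_grid(seed=seed, **opts)
    positions = sample_initial_positions(grid, n_agents, seed=seed + 1)
    return grid, positions


def planted_p1_slope(
    n_agents: int = 1000,
    slope: float = 1.0,
    base_prob: float = 0.5,
    d0: float = 5.0,
    seed: int = 0,
):
    """Network whose link probability falls off as d^(-slope) by construction.

    Each unordered pair at distance d is linked independently with probability
    base_prob * (max(d, d0)/d0)^(-slope), so a log-log regression of the
    measured P1(d) recovers -slope.  Returns (net, slope).
    """
    rng = np.random.default_rng(seed)
    grid, positions = gaussian_world(n_agents, seed=seed)
    lat = np.array([p.lat for p in positions])
    lon = np.array([p.lon for p in positions])
    net = DirectedGeoNetwork({i: p for i, p in enumerate(positions)})
    iu, ju = np.triu_indices(n_agents, k=1)
    d = haversine_km(lat[iu], lon[iu], lat[ju], lon[ju])
    prob = base_prob * (np.maximum(d, d0) / d0) ** (-slope)
    hit = rng.random(iu.size) < prob
    for i, j in zip(iu[hit], ju[hit]):
        net.add_edge(int(i), int(j))
    return net, slope


def planted_reciprocity(
    reciprocity_by_scale: dict[float, float] | None = None,
    pairs_per_scale: int = 50,
    seed: int = 0,
):
    """Directed network with exact planted reciprocity at separated scales.

    ``reciprocity_by_scale`` maps a pair distance in km to the fraction of
    directed links at that distance whose reverse exists.  Pairs are laid out
    along the equator, far from each other, so each scale falls in its own
    distance bin.  Returns (net, the map actually planted).
    """
    if reciprocity_by_scale is None:
        reciprocity_by_scale = {10.0: 0.8, 1000.0: 0.2}
    net = DirectedGeoNetwork()
    nid = 0
    planted = {}
    base_lat = 0.0
    row = 0.0
    for dist_km, frac in reciprocity_by_scale.items():
        # n_recip mutual pairs contribute 2 reciprocated links each:
        # R = 2*n_recip / (2*n_recip + n_one_way)
        n_recip = round(frac * pairs_per_scale)
        dlon = dist_km / KM_PER_DEG
        for p in range(pairs_per_scale):
            a, b = nid, nid + 1
            nid += 2
            lon0 = (p * (dlon + 2.0)) % 300.0 - 150.0
            net.add_node(a, Location(base_lat + row, lon0))
            net.add_node(b, Location(base_lat + row, lon0 + dlon))
            net.add_edge(a, b)
            if p < n_recip:
                net.add_edge(b, a)
        # mutual pairs contribute 2 reciprocated directed links each
        planted[dist_km] = 2 * n_recip / (2 * n_recip + pairs_per_scale - n_recip)
        row += 2.0
    return net, planted


def planted_triangles(
    scales_km=(10.0, 1000.0),
    n_triangles: int = 5,
    n_open: int = 5,
    seed: int = 0,
):
    """Closed triangles and open triads planted at separated distance scales.

    At each scale, equilateral-ish triangles and open 2-paths are laid out in
    isolation, so C(d) is closed/(closed+open) at that scale's triad distance
    and zero elsewhere.  Returns (net, expected C per scale).
    """
    net = DirectedGeoNetwork()
    nid = 0
    expected = {}
    row = 0.0
    for scale in scales_km:
        dlon = scale / KM_PER_DEG
        lon = -150.0
        for t in range(n_triangles):
            a, b, c = nid, nid + 1, nid + 2
            nid += 3
            net.add_node(a, Location(row, lon))
            net.add_node(b, Location(row, lon + dlon))
            net.add_node(c, Location(row + dlon * 0.866, lon + dlon / 2.0))
            net.add_edge(a, b)
            net.add_edge(b, c)
            net.add_edge(a, c)
            lon += 3.0 * dlon + 1.0
        lon = -150.0  # open triads go on their own latitude band
        for t in range(n_open):
            a, b, c = nid, nid + 1, nid + 2
            nid += 3
            net.add_node(a, Location(row + 2.0, lon))
            net.add_node(b, Location(row + 2.0, lon + dlon))
            net.add_node(c, Location(row + 2.0, lon + 2.0 * dlon))
            net.add_edge(a, b)
            net.add_edge(b, c)
            lon += 4.0 * dlon + 1.0
        # per triangle: 3 closed triads; per open path: 1 open triad
        expected[scale] = 3.0 * n_triangles / (3.0 * n_triangles + n_open)
        row += 5.0
    return net, expected


def tf_reference(
    n_agents: int = 500,
    p_v: float = 0.4,
    p_c: float = 0.02,
    links_per_node: float = 3.0,
    seed: int = 0,
    **world_overrides,
):
    """A coupled-model run on a Gaussian world, for self-consistency tests.

    Returns (grid, positions, result) with L_target = links_per_node * N.
    """
    grid, positions = gaussian_world(n_agents, seed=seed, **world_overrides)
    params = ModelParams(
        p_v=p_v, p_c=p_c, L_target=int(links_per_node * n_agents)
    )
    result = run_tf(params, grid, positions, seed=seed + 17)
    return grid, positions, result


def make_fixture(kind: str, params: dict | None = None, seed: int = 0):
    """Dispatch by fixture kind; ``params`` are keyword overrides."""
    params = params or {}
    if kind == "gaussian_world":
        return gaussian_world(seed=seed, **params)
    if kind == "planted_p1_slope":
        return planted_p1_slope(seed=seed, **params)
    if kind == "planted_reciprocity":
        return planted_reciprocity(seed=seed, **params)
    if kind == "planted_triangles":
        return planted_triangles(seed=seed, **params)
    if kind == "tf_reference":
        return tf_reference(seed=seed, **params)
    raise InputError(f"unknown fixture kind {kind!r}; one of {FIXTURE_KINDS}")
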