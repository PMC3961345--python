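"""Shared fixtures: small worlds, tiny planted networks, brute-force oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from geosocial.fixtures import gaussian_world
from geosocial.geography import Location, great_circle_distance
from geosocial.network import DirectedGeoNetwork


@pytest.fixture(scope="session")
def small_world():
    """A 3-city Gaussian world with 300 agents (session-cached)."""
    return gaussian_world(300, seed=21)


@pytest.fixture(scope="session")
def medium_world():
    """A 3-city Gaussian world with 500 agents (session-cached)."""
    return gaussian_world(500, seed=11)


def random_geo_digraph(n: int, p_edge: float, seed: int) -> DirectedGeoNetwork:
    """A random directed network with positions scattered over ~1000 km."""
    rng = np.random.default_rng(seed)
    net = DirectedGeoNetwork()
    for i in range(n):
        net.add_node(i, Location(float(rng.uniform(40, 50)), float(rng.uniform(0, 12))))
    for u in range(n):
        for v in range(n):
            if u != v and rng.random() < p_edge:
                net.add_edge(u, v)
    return net


@pytest.fixture(
    scope="session",
    params=[(8, 0.3, 1), (20, 0.15, 2), (40, 0.08, 3), (60, 0.05, 4), (25, 0.5, 5)],
    ids=["n8", "n20", "n40", "n60", "n25dense"],
)
def small_random_net(request):
    n, p, seed = request.param
    return random_geo_digraph(n, p, seed)


# --------------------------------------------------------------------------
# brute-force oracles (independent of the metrics module implementation)
# --------------------------------------------------------------------------

def brute_pair_distances(net):
    """Unordered-pair distances, keyed in both orientations."""
    loc = net.locations
    ids = sorted(net.nodes(), key=repr)
    out = {}
    for a, b in itertools.combinations(ids, 2):
        d = great_circle_distance(loc[a], loc[b])
        out[(a, b)] = d
        out[(b, a)] = d
    return out


def brute_undirected_adj(net):
    adj = {i: set() for i in net.nodes()}
    for u, targets in net.out.items():
        for v in targets:
            adj[u].add(v)
            adj[v].add(u)
    return adj


def brute_triads(net):
    """All (center, leaf_i, leaf_k) triads of the symmetrized network."""
    adj = brute_undirected_adj(net)
    triads = []
    for j in net.nodes():
        nbrs = sorted(adj[j], key=repr)
        for i, k in itertools.combinations(nbrs, 2):
            triads.append((j, i, k, k in adj[i]))
    return triads


def brute_triangles(net):
    adj = brute_undirected_adj(net)
    ids = sorted(net.nodes(), key=repr)
    tris = []
    for a, b, c in itertools.combinations(ids, 3):
        if b in adj[a] and c in adj[a] and c in adj[b]:
            tris.append((a, b, c))
    return tris


def brute_overlap(net, i, j):
    adj = brute_undirected_adj(net)
    union = (adj[i] | adj[j]) - {i, j}
    if not union:
        return None
    return len(adj[i] & adj[j]) / len(union)
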