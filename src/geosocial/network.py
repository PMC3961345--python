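"""Directed network of geolocated agents.

A thin adjacency container tuned for the simulation loop: O(1) edge insertion
and membership, per-node out-/in-neighbor sets, symmetrized neighborhoods and
reciprocity tests.  Nodes carry :class:`~geosocial.geography.Location`s so the
distance-resolved statistics can be computed directly on the object.
"""

from __future__ import annotations

from typing import Hashable, Iterable, Iterator

import numpy as np

from .geography import InputError, Location


class DirectedGeoNetwork:
    """Directed graph over geolocated nodes; no self-loops, no duplicate edges."""

    def __init__(self, nodes: dict[Hashable, Location] | None = None):
        self.locations: dict[Hashable, Location] = dict(nodes or {})
        self.out: dict[Hashable, set] = {i: set() for i in self.locations}
        self.inn: dict[Hashable, set] = {i: set() for i in self.locations}
        self._n_edges = 0

    # -- construction ------------------------------------------------------
    def add_node(self, i: Hashable, loc: Location) -> None:
        if i not in self.locations:
            self.out[i] = set()
            self.inn[i] = set()
        self.locations[i] = loc

    def add_edge(self, u: Hashable, v: Hashable) -> bool:
        """Add the directed edge u->v; returns False if it already exists."""
        if u == v:
            raise InputError("self-loops are not allowed")
        if u not in self.locations or v not in self.locations:
            raise InputError(f"edge endpoints must be nodes: {u!r}->{v!r}")
        if v in self.out[u]:
            return False
        self.out[u].add(v)
        self.inn[v].add(u)
        self._n_edges += 1
        return True

    # -- queries -----------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.locations)

    @property
    def n_edges(self) -> int:
        return self._n_edges

    def nodes(self) -> Iterable[Hashable]:
        return self.locations.keys()

    def has_edge(self, u, v) -> bool:
        return u in self.out and v in self.out[u]

    def is_reciprocated(self, u, v) -> bool:
        return self.has_edge(u, v) and self.has_edge(v, u)

    def neighbors(self, i) -> set:
        """Symmetrized neighborhood Γ_i = out(i) ∪ in(i)."""
        return self.out[i] | self.inn[i]

    def degree(self, i) -> int:
        return len(self.out[i] | self.inn[i])

    def edges(self) -> Iterator[tuple[Hashable, Hashable]]:
        for u, targets in self.out.items():
            for v in targets:
                yield (u, v)

    def undirected_edges(self) -> Iterator[tuple[Hashable, Hashable]]:
        """Each connected pair once, regardless of direction(s)."""
        seen = set()
        for u, v in self.edges():
            key = (u, v) if repr(u) <= repr(v) else (v, u)
            if key not in seen:
                seen.add(key)
                yield key

    # -- conversions -------------------------------------------------------
    def coord_arrays(self, order: list | None = None):
        """(ids, lat array, lon array) in a fixed node order."""
        ids = list(self.locations) if order is None else order
        lat = np.array([self.locations[i].lat for i in ids])
        lon = np.array([self.locations[i].lon for i in ids])
        return ids, lat, lon

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        for i, loc in self.locations.items():
            g.add_node(i, lat=loc.lat, lon=loc.lon)
        g.add_edges_from(self.edges())
        return g

    def copy(self) -> "DirectedGeoNetwork":
        new = DirectedGeoNetwork(self.locations)
        for u, targets in self.out.items():
            new.out[u] = set(targets)
        for v, sources in self.inn.items():
            new.inn[v] = set(sources)
        new._n_edges = self._n_edges
        return new
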