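"""Distance-resolved and scalar geo-social network statistics.

All statistics are computed identically for empirical and simulated networks:
the link probability P1(d), the symmetrized degree distribution P(k), the
reciprocity R(d) of directed links, the social overlap J_f(d) (a modified
Jaccard index over neighbor sets), the distance-resolved triadic closure
probability C(d), the triangle-shape disparity distribution P(D) and scalar
summaries (connected-node count, mean local clustering, global C and R).

Distance-resolved curves are binned on logarithmic distance bins; empty bins
are marked undefined (NaN value, zero count) and excluded from averages.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .geography import InputError, haversine_km
from .network import DirectedGeoNetwork

#: floor applied to degenerate (near-zero) triangle edge lengths, km
D_MIN_FLOOR = 1e-6


@dataclass(frozen=True)
class DistanceBinning:
    """Log-spaced distance bins in km."""

    edges: np.ndarray  # strictly increasing, edges[0] > 0

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        if e.ndim != 1 or e.size < 2 or e[0] <= 0 or np.any(np.diff(e) <= 0):
            raise InputError("bin edges must be positive and strictly increasing")
        object.__setattr__(self, "edges", e)

    @classmethod
    def log_bins(cls, d_lo: float, d_hi: float, n_bins: int = 30) -> "DistanceBinning":
        return cls(np.geomspace(d_lo, d_hi, n_bins + 1))

    @property
    def n_bins(self) -> int:
        return self.edges.size - 1

    def assign(self, d) -> np.ndarray:
        """Bin index per distance; -1 for out-of-range."""
        d = np.asarray(d, dtype=float)
        idx = np.searchsorted(self.edges, d, side="right") - 1
        idx[(d < self.edges[0]) | (d > self.edges[-1])] = -1
        # the top edge is inclusive
        idx[d == self.edges[-1]] = self.n_bins - 1
        return idx

    def centers(self) -> np.ndarray:
        return np.sqrt(self.edges[:-1] * self.edges[1:])


@dataclass
class MetricCurve:
    """A distance-binned statistic: value and sample count per bin."""

    binning: DistanceBinning
    values: np.ndarray  # NaN where undefined
    counts: np.ndarray

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def weighted_mean(self) -> float:
        """Sample-count-weighted average over defined bins."""
        m = self.defined & (self.counts > 0)
        if not m.any():
            return float("nan")
        return float(np.average(self.values[m], weights=self.counts[m]))


def _ratio_curve(binning, numer, denom) -> MetricCurve:
    values = np.full(binning.n_bins, np.nan)
    mask = denom > 0
    values[mask] = numer[mask] / denom[mask]
    return MetricCurve(binning=binning, values=values, counts=denom.astype(int))


def _binned_ratio(binning, distances, weights) -> MetricCurve:
    """Per-bin mean of ``weights`` over samples at ``distances``."""
    numer = np.zeros(binning.n_bins)
    denom = np.zeros(binning.n_bins)
    if len(distances):
        b = binning.assign(np.asarray(distances, dtype=float))
        ok = b >= 0
        np.add.at(denom, b[ok], 1)
        np.add.at(numer, b[ok], np.asarray(weights, dtype=float)[ok])
    return _ratio_curve(binning, numer, denom)


def default_binning(net: DirectedGeoNetwork, n_bins: int = 30, seed: int = 0) -> DistanceBinning:
    """30 log bins from 1 km to the 99.9th percentile pairwise distance."""
    ids, lat, lon = net.coord_arrays()
    n = len(ids)
    rng = np.random.default_rng(seed)
    if n * (n - 1) // 2 <= 200_000:
        iu, ju = np.triu_indices(n, k=1)
    else:
        iu = rng.integers(0, n, size=200_000)
        ju = rng.integers(0, n, size=200_000)
        keep = iu != ju
        iu, ju = iu[keep], ju[keep]
    d = haversine_km(lat[iu], lon[iu], lat[ju], lon[ju])
    d_hi = float(np.percentile(d[d > 0], 99.9)) if np.any(d > 0) else 10.0
    return DistanceBinning.log_bins(1.0, max(d_hi, 2.0), n_bins)


def _pair_distance_matrix(net):
    ids, lat, lon = net.coord_arrays()
    index = {v: k for k, v in enumerate(ids)}
    return ids, index, lat, lon


def link_probability_curve(
    net: DirectedGeoNetwork,
    binning: DistanceBinning | None = None,
    pair_budget: int = 10_000_000,
    seed: int = 0,
    exact_threshold: int = 5000,
) -> MetricCurve:
    """P1(d): probability that a pair of users at distance d is connected.

    A pair counts as linked when either directed edge exists.  All unordered
    pairs are enumerated when N <= ``exact_threshold``; above that the curve is
    estimated from ``pair_budget`` uniformly sampled pairs.
    """
    if net.n_nodes < 2:
        raise InputError("need at least 2 nodes")
    ids, index, lat, lon = _pair_distance_matrix(net)
    n = len(ids)
    binning = binning or default_binning(net)
    linked_total = np.zeros(binning.n_bins)
    pair_total = np.zeros(binning.n_bins)
    if n <= exact_threshold:
        linked = set()
        for u, v in net.undirected_edges():
            a, b = index[u], index[v]
            linked.add((min(a, b), max(a, b)))
        chunk = 500
        for start in range(0, n, chunk):
            rows = np.arange(start, min(start + chunk, n))
            for i in rows:
                js = np.arange(i + 1, n)
                if js.size == 0:
                    continue
                d = haversine_km(lat[i], lon[i], lat[js], lon[js])
                b = binning.assign(d)
                ok = b >= 0
                np.add.at(pair_total, b[ok], 1)
                if net.neighbors(ids[i]):
                    is_linked = np.fromiter(
                        ((i, int(j)) in linked for j in js), bool, js.size
                    )
                    sel = ok & is_linked
                    np.add.at(linked_total, b[sel], 1)
    else:
        rng = np.random.default_rng(seed)
        batch = 1_000_000
        drawn = 0
        while drawn < pair_budget:
            m = min(batch, pair_budget - drawn)
            iu = rng.integers(0, n, size=m)
            ju = rng.integers(0, n, size=m)
            keep = iu != ju
            iu, ju = iu[keep], ju[keep]
            drawn += m
            d = haversine_km(lat[iu], lon[iu], lat[ju], lon[ju])
            b = binning.assign(d)
            ok = b >= 0
            np.add.at(pair_total, b[ok], 1)
            is_linked = np.fromiter(
                (
                    net.has_edge(ids[i], ids[j]) or net.has_edge(ids[j], ids[i])
                    for i, j in zip(iu, ju)
                ),
                bool,
                iu.size,
            )
            sel = ok & is_linked
            np.add.at(linked_total, b[sel], 1)
    return _ratio_curve(binning, linked_total, pair_total)


def degree_distribution(net: DirectedGeoNetwork, symmetrize: bool = True):
    """P(k) histogram as (k values, node counts); counts sum to N.

    With ``symmetrize`` (the default) mutual edges count once: k is the size
    of the union of in- and out-neighborhoods.
    """
    if symmetrize:
        degs = [len(net.neighbors(i)) for i in net.nodes()]
    else:
        degs = [len(net.out[i]) for i in net.nodes()]
    degs = np.asarray(degs, dtype=int)
    kmax = int(degs.max(initial=0))
    counts = np.bincount(degs, minlength=kmax + 1)
    return np.arange(kmax + 1), counts


def reciprocity_curve(net: DirectedGeoNetwork, binning: DistanceBinning | None = None) -> MetricCurve:
    """R(d): among directed links at distance d, the fraction reciprocated."""
    binning = binning or default_binning(net)
    loc = net.locations
    ds, flags = [], []
    for u, v in net.edges():
        ds.append(
            float(haversine_km(loc[u].lat, loc[u].lon, loc[v].lat, loc[v].lon))
        )
        flags.append(net.has_edge(v, u))
    return _binned_ratio(binning, ds, flags)


def social_overlap(net: DirectedGeoNetwork, i, j) -> float | None:
    """Modified Jaccard overlap of two connected users' friend sets.

    |Γ_i ∩ Γ_j| / |(Γ_i ∪ Γ_j) \\ {i, j}|: 1 when i and j share all their
    friends, 0 when they share none.  Returns None (undefined) when the
    denominator is empty.
    """
    gi, gj = net.neighbors(i), net.neighbors(j)
    if j not in gi and i not in gj:
        raise InputError(f"{i!r} and {j!r} are not connected")
    denom = (gi | gj) - {i, j}
    if not denom:
        return None
    return len(gi & gj) / len(denom)


def overlap_curve(net: DirectedGeoNetwork, binning: DistanceBinning | None = None) -> MetricCurve:
    """J_f(d): mean social overlap of connected pairs at distance d."""
    binning = binning or default_binning(net)
    loc = net.locations
    ds, ovs = [], []
    for u, v in net.undirected_edges():
        ov = social_overlap(net, u, v)
        if ov is None:
            continue
        ds.append(float(haversine_km(loc[u].lat, loc[u].lon, loc[v].lat, loc[v].lon)))
        ovs.append(ov)
    return _binned_ratio(binning, ds, ovs)


def triad_census(net: DirectedGeoNetwork, triad_distance: str = "mean"):
    """Per-triad records over the symmetrized network.

    Yields (center, leaf_i, leaf_k, triad distance, closed?) for every triad:
    a center j adjacent to two distinct leaves; closed when the leaves are
    also adjacent.  Triad distance is the mean (or max) of the two center-leaf
    distances.
    """
    if triad_distance not in ("mean", "max"):
        raise InputError("triad_distance must be 'mean' or 'max'")
    loc = net.locations
    adj = {i: net.neighbors(i) for i in net.nodes()}
    for j, nbrs in adj.items():
        nb = sorted(nbrs, key=repr)
        if len(nb) < 2:
            continue
        dj = {
            i: float(haversine_km(loc[j].lat, loc[j].lon, loc[i].lat, loc[i].lon))
            for i in nb
        }
        for i, k in itertools.combinations(nb, 2):
            d = (dj[i] + dj[k]) / 2.0 if triad_distance == "mean" else max(dj[i], dj[k])
            yield (j, i, k, d, k in adj[i])


def clustering_curve(
    net: DirectedGeoNetwork,
    binning: DistanceBinning | None = None,
    triad_distance: str = "mean",
) -> MetricCurve:
    """C(d): probability that a triad at distance d is closed.

    The sample-count-weighted average of this curve over its bins equals the
    global clustering coefficient N_closed / N_triads exactly.
    """
    binning = binning or default_binning(net)
    ds, flags = [], []
    for (_, _, _, d, is_closed) in triad_census(net, triad_distance):
        ds.append(d)
        flags.append(is_closed)
    return _binned_ratio(binning, ds, flags)


def triangles(net: DirectedGeoNetwork):
    """Unique triangles of the symmetrized network as node triples."""
    adj = {i: net.neighbors(i) for i in net.nodes()}
    order = {v: k for k, v in enumerate(sorted(adj, key=repr))}
    for u, v in net.undirected_edges():
        if order[u] > order[v]:
            u, v = v, u
        for w in adj[u] & adj[v]:
            if order[w] > order[v]:
                yield (u, v, w)


def triangle_disparity(d1: float, d2: float, d3: float) -> float:
    """Shape disparity of a triangle's three edge lengths.

    0 for an equilateral triangle; -> 1 when one edge is much shorter than the
    other two (two users co-located, the third far away).  Near-zero lengths
    are floored to keep the ratio defined.
    """
    ds = np.maximum([d1, d2, d3], D_MIN_FLOOR)
    return float((ds.max() - ds.min()) / ds.max())


def disparity_distribution(net: DirectedGeoNetwork, n_bins: int = 20):
    """P(D): normalized histogram of triangle disparities.

    Returns (bin edges on [0, 1], probabilities, triangle counts per bin).
    """
    loc = net.locations
    vals = []
    for (u, v, w) in triangles(net):
        d1 = float(haversine_km(loc[u].lat, loc[u].lon, loc[v].lat, loc[v].lon))
        d2 = float(haversine_km(loc[u].lat, loc[u].lon, loc[w].lat, loc[w].lon))
        d3 = float(haversine_km(loc[v].lat, loc[v].lon, loc[w].lat, loc[w].lon))
        vals.append(triangle_disparity(d1, d2, d3))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(vals, bins=edges)
    probs = counts / counts.sum() if counts.sum() > 0 else counts.astype(float)
    return edges, probs, counts


@dataclass
class ScalarSummary:
    n_connected: int  # nodes with symmetrized degree >= 1
    mean_local_clustering: float  # averaged over the connected nodes
    global_clustering: float  # closed triads / triads
    global_reciprocity: float  # reciprocated directed edges / directed edges


def local_clustering(net: DirectedGeoNetwork, i) -> float | None:
    """Closed triads centered on i / triads centered on i (None if degree < 2)."""
    nbrs = net.neighbors(i)
    k = len(nbrs)
    if k < 2:
        return None
    adj = {n: net.neighbors(n) for n in nbrs}
    closed = sum(1 for a, b in itertools.combinations(nbrs, 2) if b in adj[a])
    return closed / (k * (k - 1) / 2)


def scalar_summary(net: DirectedGeoNetwork) -> ScalarSummary:
    connected = [i for i in net.nodes() if net.degree(i) >= 1]
    locals_ = [local_clustering(net, i) or 0.0 for i in connected]
    n_tri = 0
    n_closed = 0
    for (*_, is_closed) in triad_census(net):
        n_tri += 1
        n_closed += int(is_closed)
    n_dir = net.n_edges
    n_recip = sum(1 for u, v in net.edges() if net.has_edge(v, u))
    return ScalarSummary(
        n_connected=len(connected),
        mean_local_clustering=float(np.mean(locals_)) if locals_ else 0.0,
        global_clustering=n_closed / n_tri if n_tri else 0.0,
        global_reciprocity=n_recip / n_dir if n_dir else 0.0,
    )
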