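"""Uncoupled baseline models.

Two nulls isolate the ingredients of the coupled model: the spatial S model
links pairs at random with a probability decaying as a power law of their
distance (geography, no structure), and the linking L model grows ties purely
through random links, co-visits at a common friend's place and reciprocation
(structure, no geography).  The jump-law variants re-run the full coupled
model with normal or uniform displacement lengths instead of the default
truncated power law.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .geography import InputError, JumpSpec, Location, haversine_km
from .network import DirectedGeoNetwork
from .tf_model import ModelParams, SimulationResult, run_tf

_RANDOM_LINK_RETRIES = 50


@dataclass(frozen=True)
class SModelParams:
    """Distance-kernel random linking: weight max(d, d0)^(-alpha)."""

    alpha: float = 0.7
    d0: float = 1.0
    L_target: int = 1000

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise InputError("alpha must be >= 0")
        if self.d0 <= 0:
            raise InputError("d0 must be > 0")


def run_s_model(
    positions: list[Location], params: SModelParams, seed: int | None = 0
) -> DirectedGeoNetwork:
    """Sample exactly L_target distinct directed edges, weight ~ d^(-alpha).

    Weighted sampling without replacement uses the Gumbel top-k trick, which is
    exact for distinct-item sampling with probabilities proportional to the
    weights.
    """
    n = len(positions)
    if n < 2:
        raise InputError("need at least 2 positions")
    if params.L_target > n * (n - 1):
        raise InputError("L_target exceeds the number of possible directed edges")
    rng = np.random.default_rng(seed)
    lat = np.array([p.lat for p in positions])
    lon = np.array([p.lon for p in positions])
    d = haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    w = np.maximum(d, params.d0) ** (-params.alpha)
    np.fill_diagonal(w, 0.0)
    flat = w.ravel()
    # Gumbel top-k: argmax of log w + Gumbel noise ~ weighted draw w/o replacement
    with np.errstate(divide="ignore"):
        keys = np.log(flat) + rng.gumbel(size=flat.size)
    top = np.argpartition(-keys, params.L_target)[: params.L_target]
    net = DirectedGeoNetwork({i: loc for i, loc in enumerate(positions)})
    for idx in top:
        u, v = divmod(int(idx), n)
        net.add_edge(u, v)
    assert net.n_edges == params.L_target
    return net


@dataclass(frozen=True)
class LModelParams:
    """Visit-driven closure with no geography.

    p_v    probability an agent visits a uniformly chosen out-neighbor per sweep
    p_c    probability an agent adds one random directed link per sweep
    p_enc  probability each missing directed edge between two co-visitors is created
    q      probability a host reciprocates a visitor's (one-way) link
    """

    p_v: float = 0.5
    p_c: float = 0.05
    p_enc: float = 1.0
    q: float = 1.0
    steps: int = 200

    def __post_init__(self) -> None:
        for name in ("p_v", "p_c", "p_enc", "q"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise InputError(f"{name}={v} outside [0, 1]")


class _LState:
    """Adjacency plus incrementally maintained triad/link tallies."""

    def __init__(self, n: int):
        self.n = n
        self.out = [set() for _ in range(n)]
        self.inn = [set() for _ in range(n)]
        self.adj = [set() for _ in range(n)]  # union neighborhoods
        self.deg = np.zeros(n, dtype=int)
        self.triads = 0
        self.closed = 0
        self.l_r = 0  # reciprocated directed links
        self.l_nr = 0  # non-reciprocated directed links

    def add_edge(self, u: int, v: int) -> bool:
        if u == v or v in self.out[u]:
            return False
        self.out[u].add(v)
        self.inn[v].add(u)
        if u in self.out[v]:
            # the reverse existed: one link moves from non- to reciprocated
            self.l_r += 2
            self.l_nr -= 1
        else:
            self.l_nr += 1
        if v not in self.adj[u]:
            # a new undirected relationship: update triad tallies
            common = self.adj[u] & self.adj[v]
            self.closed += 3 * len(common)
            self.triads += self.deg[u] + self.deg[v]
            self.adj[u].add(v)
            self.adj[v].add(u)
            self.deg[u] += 1
            self.deg[v] += 1
        return True

    @property
    def clustering(self) -> float:
        return self.closed / self.triads if self.triads else 0.0

    @property
    def reciprocity(self) -> float:
        tot = self.l_r + self.l_nr
        return self.l_r / tot if tot else 0.0


def run_l_model(
    n_agents: int,
    params: LModelParams,
    seed: int | None = 0,
    positions: list[Location] | None = None,
    log_events: bool = False,
):
    """Simulate the L model; returns (network, per-sweep series DataFrame).

    Per sweep: every agent independently visits a uniformly chosen out-neighbor
    with probability p_v (abstract co-presence at the host's place) and adds a
    random directed link with probability p_c; at sweep end every unordered
    pair of a host's visitors gains each missing directed edge with probability
    p_enc, and every visitor's one-way link to its host is reciprocated with
    probability q.  The series records C, R and the link count each sweep.
    """
    if n_agents < 3:
        raise InputError("need at least 3 agents")
    rng = np.random.default_rng(seed)
    st = _LState(n_agents)
    rows = []
    events = [] if log_events else None
    for step in range(1, params.steps + 1):
        u_visit = rng.random(n_agents)
        u_rand = rng.random(n_agents)
        hosts: dict[int, list[int]] = {}
        # visits (state at sweep start decides who can visit)
        for a in range(n_agents):
            if u_visit[a] < params.p_v and st.out[a]:
                targets = tuple(st.out[a])
                h = targets[rng.integers(len(targets))]
                hosts.setdefault(h, []).append(a)
        # random global links
        for a in range(n_agents):
            if u_rand[a] < params.p_c:
                for _ in range(_RANDOM_LINK_RETRIES):
                    b = int(rng.integers(n_agents))
                    if b == a or b in st.out[a]:
                        continue
                    st.add_edge(a, b)
                    if events is not None:
                        events.append(("random", a, b, step))
                    break
        # co-visit closure and reciprocation at sweep end
        for h, visitors in hosts.items():
            if len(visitors) > 1:
                for x in range(len(visitors)):
                    for y in range(x + 1, len(visitors)):
                        u, v = visitors[x], visitors[y]
                        if v not in st.out[u] and rng.random() < params.p_enc:
                            if st.add_edge(u, v) and events is not None:
                                events.append(("closure", u, v, step))
                        if u not in st.out[v] and rng.random() < params.p_enc:
                            if st.add_edge(v, u) and events is not None:
                                events.append(("closure", v, u, step))
            for v in visitors:
                if v not in st.out[h] and rng.random() < params.q:
                    if st.add_edge(h, v) and events is not None:
                        events.append(("reciprocation", h, v, step))
        rows.append(
            {
                "step": step,
                "C": st.clustering,
                "R": st.reciprocity,
                "links": st.l_r + st.l_nr,
            }
        )
    if positions is None:
        positions = [Location(0.0, 0.0)] * n_agents
    net = DirectedGeoNetwork({i: loc for i, loc in enumerate(positions)})
    for a in range(n_agents):
        for b in st.out[a]:
            net.add_edge(a, b)
    series = pd.DataFrame(rows)
    if log_events:
        return net, series, events
    return net, series


def degree_histogram(net_or_state) -> np.ndarray:
    """Union-degree histogram (counts per k) of an L-model network."""
    if isinstance(net_or_state, DirectedGeoNetwork):
        degs = np.array([net_or_state.degree(i) for i in net_or_state.nodes()])
    else:
        degs = net_or_state.deg
    return np.bincount(degs)


def run_tf_variant(
    params: ModelParams,
    jump: JumpSpec,
    grid,
    initial_positions,
    seed: int | None = 0,
    **kwargs,
) -> SimulationResult:
    """The coupled model with a substituted jump-length law (normal/uniform)."""
    return run_tf(replace(params, jump=jump), grid, initial_positions, seed, **kwargs)
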