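"""The coupled travel-and-friendship dynamics.

Agents live on a population raster.  At every activation a randomly chosen
agent first moves — visiting a random friend with probability ``p_v``, or
jumping a random distance (drawn from the jump-length law) in a direction
weighted by population density — and then forms ties: with probability ``p``
it links to everyone inside its local delta x delta km box, and independently
with probability ``p_c`` it links to one uniformly random agent anywhere.
The run stops when the directed-link count reaches the target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .geography import (
    InputError,
    JumpSpec,
    KM_PER_DEG,
    Location,
    PopulationGrid,
    nearest_populated_target,
    sample_jump_target,
)
from .network import DirectedGeoNetwork

_RANDOM_LINK_RETRIES = 50
_EMPTY_ANNULUS_REDRAWS = 10


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the coupled model.

    p_v      probability of visiting a friend in the travel stage
    p        probability of linking to all box-mates in the friendship stage
    p_c      probability of one random global link per activation
    delta_km side of the local neighborhood box, km
    jump     jump-length law for random travel
    L_target directed-link count at which the run stops
    """

    p_v: float = 0.3
    p: float = 0.1
    p_c: float = 0.01
    delta_km: float = 5.0
    jump: JumpSpec = field(default_factory=JumpSpec)
    L_target: int = 1000
    max_steps: int = 100_000
    visit_mode: str = "out"  # "out": visit people you follow; "symmetric": any tie
    per_neighbor_gate: bool = False  # True: Bernoulli(p) per box-mate

    def __post_init__(self) -> None:
        for name in ("p_v", "p", "p_c"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise InputError(f"{name}={v} outside [0, 1]")
        if self.delta_km <= 0:
            raise InputError("delta_km must be positive")
        if self.L_target < 1:
            raise InputError("L_target must be >= 1")
        if self.visit_mode not in ("out", "symmetric"):
            raise InputError(f"unknown visit_mode {self.visit_mode!r}")


@dataclass
class SimulationResult:
    net: DirectedGeoNetwork
    link_series: list[int]  # directed-edge count at the end of each time step
    steps: int
    seed: int | None
    completed: bool  # False when max_steps was hit before L_target
    trajectory: list[tuple[int, int, float, float]] | None = None  # (step, agent, lat, lon)
    creation_log: list[tuple[int, int, float]] | None = None  # (u, v, distance at creation)


def travel_stage(
    agent,
    params: ModelParams,
    grid: PopulationGrid,
    net: DirectedGeoNetwork,
    rng: np.random.Generator,
) -> Location:
    """Move one agent and return its new location (the network is not updated).

    With probability ``p_v`` and a non-empty friend set the agent relocates to
    the current position of a uniformly chosen friend; otherwise it jumps a
    sampled distance toward a density-weighted target.  If repeated jump draws
    land in empty annuli the populated cell nearest the drawn distance is used.
    """
    friends = net.out[agent] if params.visit_mode == "out" else net.neighbors(agent)
    here = net.locations[agent]
    if friends and rng.random() < params.p_v:
        chosen = tuple(friends)[rng.integers(len(friends))]
        return net.locations[chosen]
    r = 0.0
    for _ in range(_EMPTY_ANNULUS_REDRAWS):
        r = float(params.jump.sample(rng))
        target = sample_jump_target(grid, here, r, rng)
        if target is not None:
            return target
    return nearest_populated_target(grid, here, r, rng)


def box_mates(
    agent_idx: int,
    lat: np.ndarray,
    lon: np.ndarray,
    delta_km: float,
) -> np.ndarray:
    """Indices of agents inside the delta x delta km box centered on agent_idx.

    The box is axis-aligned in the local tangent plane: the longitude span is
    widened by 1/cos(lat) so the physical width stays delta km.
    """
    half_lat = 0.5 * delta_km / KM_PER_DEG
    coslat = max(math.cos(math.radians(lat[agent_idx])), 1e-6)
    half_lon = 0.5 * delta_km / (KM_PER_DEG * coslat)
    mask = (np.abs(lat - lat[agent_idx]) <= half_lat) & (
        np.abs(lon - lon[agent_idx]) <= half_lon
    )
    mask[agent_idx] = False
    return np.flatnonzero(mask)


def friendship_stage(
    agent,
    params: ModelParams,
    net: DirectedGeoNetwork,
    rng: np.random.Generator,
    lat: np.ndarray | None = None,
    lon: np.ndarray | None = None,
    ids: list | None = None,
    max_new: int | None = None,
) -> list[tuple]:
    """Run the linking stage for one agent; returns the edges created.

    One Bernoulli(p) draw gates linking to every box-mate at once (the spec's
    literal single-action reading; ``per_neighbor_gate`` switches to one draw
    per box-mate).  Independently one Bernoulli(p_c) draw gates a single random
    global link, redrawn while the sampled edge already exists (bounded
    retries).  ``max_new`` caps the number of edges added so a run can stop
    exactly at its link target.
    """
    if lat is None or lon is None or ids is None:
        ids, lat, lon = net.coord_arrays()
    if isinstance(agent, (int, np.integer)) and 0 <= agent < len(ids) and ids[int(agent)] == agent:
        idx = int(agent)
    else:
        idx = ids.index(agent)
    created: list[tuple] = []
    budget = math.inf if max_new is None else max_new

    if params.per_neighbor_gate:
        for j in box_mates(idx, lat, lon, params.delta_km):
            if len(created) >= budget:
                break
            if rng.random() < params.p and net.add_edge(agent, ids[j]):
                created.append((agent, ids[j]))
    elif rng.random() < params.p:
        for j in box_mates(idx, lat, lon, params.delta_km):
            if len(created) >= budget:
                break
            if net.add_edge(agent, ids[j]):
                created.append((agent, ids[j]))
    if len(created) < budget and rng.random() < params.p_c:
        n = len(ids)
        for _ in range(_RANDOM_LINK_RETRIES):
            j = int(rng.integers(n))
            other = ids[j]
            if other == agent or net.has_edge(agent, other):
                continue
            net.add_edge(agent, other)
            created.append((agent, other))
            break
    return created


def run_tf(
    params: ModelParams,
    grid: PopulationGrid,
    initial_positions: list[Location],
    seed: int | None = 0,
    log_trajectory: bool = False,
    log_creations: bool = False,
) -> SimulationResult:
    """Simulate the coupled model until ``L_target`` directed links exist.

    One time step is a sweep of N single-agent activations drawn uniformly
    with replacement.  The run is deterministic given the seed; it stops at the
    first activation where the edge count reaches ``L_target`` (the last batch
    of box links is truncated so the final count is exact) or, failing that,
    at ``max_steps`` with ``completed=False``.
    """
    n = len(initial_positions)
    if n < 2:
        raise InputError("need at least 2 agents")
    if params.L_target >= n * (n - 1):
        raise InputError("L_target must be < N(N-1)")
    rng = np.random.default_rng(seed)
    net = DirectedGeoNetwork({i: loc for i, loc in enumerate(initial_positions)})
    lat = np.array([p.lat for p in initial_positions])
    lon = np.array([p.lon for p in initial_positions])
    ids = list(range(n))
    series: list[int] = []
    trajectory: list[tuple[int, int, float, float]] | None = [] if log_trajectory else None
    creations: list[tuple[int, int, float]] | None = [] if log_creations else None

    step = 0
    done = False
    while not done and step < params.max_steps:
        step += 1
        agents = rng.integers(0, n, size=n)
        for a_ in agents:
            a = int(a_)
            loc = travel_stage(a, params, grid, net, rng)
            net.locations[a] = loc
            lat[a] = loc.lat
            lon[a] = loc.lon
            if trajectory is not None:
                trajectory.append((step, a, loc.lat, loc.lon))
            remaining = params.L_target - net.n_edges
            new_edges = friendship_stage(
                a, params, net, rng, lat=lat, lon=lon, ids=ids, max_new=remaining
            )
            if creations is not None:
                from .geography import haversine_km

                for (u, v) in new_edges:
                    d = float(haversine_km(lat[u], lon[u], lat[v], lon[v]))
                    creations.append((u, v, d))
            if net.n_edges >= params.L_target:
                done = True
                break
        series.append(net.n_edges)

    return SimulationResult(
        net=net,
        link_series=series,
        steps=step,
        seed=seed,
        completed=done,
        trajectory=trajectory,
        creation_log=creations,
    )


def with_jump(params: ModelParams, jump: JumpSpec) -> ModelParams:
    """Same parameters with a substituted jump-length law."""
    return replace(params, jump=jump)
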