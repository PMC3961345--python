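"""File formats and run configuration.

Everything on disk is diff-able text: TSV edge lists and location tables with
a single '#'-prefixed header line, CSV metric curves, ESRI ASCII rasters and
YAML configs.  Coordinates are printed at 6 decimals.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime

import numpy as np
import yaml

from .geography import FormatError, InputError, JumpSpec, Location
from .metrics import MetricCurve
from .network import DirectedGeoNetwork
from .tf_model import ModelParams

log = logging.getLogger("geosocial")


# --------------------------------------------------------------------------
# edge lists and location tables
# --------------------------------------------------------------------------

def write_edgelist(path, net: DirectedGeoNetwork, header_extra: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(f"# src\tdst{(' ' + header_extra).rstrip()}\n")
        for u, v in sorted(net.edges(), key=repr):
            fh.write(f"{u}\t{v}\n")


def read_edgelist(path) -> list[tuple[str, str]]:
    """Directed edges from a TSV; self-loops and duplicates are format errors."""
    edges: list[tuple[str, str]] = []
    seen = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"line {lineno}: expected 'src<TAB>dst'")
            u, v = parts
            if u == v:
                raise FormatError(f"line {lineno}: self-loop {u!r}")
            if (u, v) in seen:
                raise FormatError(f"line {lineno}: duplicate edge {u!r}->{v!r}")
            seen.add((u, v))
            edges.append((u, v))
    return edges


def write_positions(path, locations: dict, header_extra: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(f"# id\tlat\tlon{(' ' + header_extra).rstrip()}\n")
        for i in sorted(locations, key=repr):
            loc = locations[i]
            fh.write(f"{i}\t{loc.lat:.6f}\t{loc.lon:.6f}\n")


def read_positions(path) -> dict[str, Location]:
    out: dict[str, Location] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"line {lineno}: expected 'id<TAB>lat<TAB>lon'")
            try:
                out[parts[0]] = Location(lat=float(parts[1]), lon=float(parts[2]))
            except (ValueError, InputError) as exc:
                raise FormatError(f"line {lineno}: {exc}") from exc
    return out


def network_from_files(edge_path, positions_path) -> DirectedGeoNetwork:
    positions = read_positions(positions_path)
    net = DirectedGeoNetwork(positions)
    for u, v in read_edgelist(edge_path):
        if u not in positions or v not in positions:
            raise FormatError(f"edge endpoint {u!r}->{v!r} has no position")
        net.add_edge(u, v)
    return net


# --------------------------------------------------------------------------
# check-in records (SNAP location-based-service dialect)
# --------------------------------------------------------------------------

def load_checkins(path) -> tuple[dict[str, Location], int]:
    """Per-user last-known position from a check-in file.

    Rows are 'user<TAB>timestamp<TAB>lat<TAB>lon<TAB>location_id'; for every
    user the most recent record by timestamp wins (ties: last occurrence in
    the file).  Malformed rows are skipped and counted; returns
    (user -> Location, number of rows skipped).
    """
    latest: dict[str, tuple[datetime, int, Location]] = {}
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                skipped += 1
                continue
            user, stamp = parts[0], parts[1]
            try:
                ts = datetime.fromisoformat(stamp.replace("Z", "+00:00"))
                loc = Location(lat=float(parts[2]), lon=float(parts[3]))
            except (ValueError, InputError):
                skipped += 1
                continue
            prev = latest.get(user)
            if prev is None or (ts, lineno) >= (prev[0], prev[1]):
                latest[user] = (ts, lineno, loc)
    if not latest:
        raise FormatError("no valid check-in rows")
    if skipped:
        log.info("load_checkins: skipped %d malformed rows", skipped)
    return {u: rec[2] for u, rec in latest.items()}, skipped


# --------------------------------------------------------------------------
# metric curves
# --------------------------------------------------------------------------

def write_curve(path, curve: MetricCurve, header_extra: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(f"# bin_low,bin_high,value,n{(' ' + header_extra).rstrip()}\n")
        e = curve.binning.edges
        for i in range(curve.binning.n_bins):
            v = "" if np.isnan(curve.values[i]) else f"{curve.values[i]:.6g}"
            fh.write(f"{e[i]:.6g},{e[i + 1]:.6g},{v},{int(curve.counts[i])}\n")


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------

_JUMP_KEYS = {"family", "exponent", "d_min", "d_max", "mean", "sd"}
_PARAM_KEYS = {
    "p_v", "p", "p_c", "delta_km", "L_target", "max_steps",
    "visit_mode", "per_neighbor_gate",
}


@dataclass
class RunConfig:
    """Simulation settings as read from / written to YAML (lossless round-trip)."""

    params: ModelParams = field(default_factory=ModelParams)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = _PARAM_KEYS | {"jump", "seed"}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        jump_raw = raw.pop("jump", {})
        unknown = set(jump_raw) - _JUMP_KEYS
        if unknown:
            raise FormatError(f"unknown jump keys: {sorted(unknown)}")
        seed = raw.pop("seed", 0)
        params = ModelParams(jump=JumpSpec(**jump_raw), **raw)
        return cls(params=params, seed=seed)

    def to_yaml(self, path) -> None:
        data = asdict(self.params)
        data["jump"] = asdict(self.params.jump)
        data["seed"] = self.seed
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def digest(self) -> str:
        """Short config hash embedded in output headers."""
        data = asdict(self.params)
        data["seed"] = self.seed
        blob = yaml.safe_dump(data, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
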