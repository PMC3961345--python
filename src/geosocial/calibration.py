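"""Model-data discrepancy and parameter scans.

The discrepancy between a reference network and a model network is measured
over eight properties — P1(d), P(k), R(d), J_f(d), C(d), P(D), the number of
connected nodes and the mean local clustering — each scored with a symmetric
normalized absolute difference

    E_X = (1/n) * sum_i |a_i - b_i| / (|a_i| + |b_i|)

(0/0 terms contribute 0; scalars have n = 1), and Err is the unweighted mean
of the eight E_X.  The form is bounded in [0, 1] and scale-free, so
properties spanning different orders of magnitude contribute comparably.
Distribution properties are compared on the reference's binning.

The scan over (p_v, p_c) uses a Latin-square design: k levels of p_v on a
linear grid and k levels of p_c on a logarithmic grid, with each row and
column visited exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .geography import InputError, PopulationGrid, Location
from .metrics import (
    DistanceBinning,
    MetricCurve,
    clustering_curve,
    default_binning,
    degree_distribution,
    disparity_distribution,
    link_probability_curve,
    overlap_curve,
    reciprocity_curve,
    scalar_summary,
)
from .network import DirectedGeoNetwork
from .tf_model import ModelParams, run_tf

PROPERTY_NAMES = ("P1", "Pk", "Rd", "Jf", "Cd", "PD", "Nc", "local_C")


def compute_properties(
    net: DirectedGeoNetwork,
    binning: DistanceBinning | None = None,
    pair_budget: int = 2_000_000,
    seed: int = 0,
    disparity_bins: int = 20,
) -> dict:
    """The eight compared properties of one network."""
    binning = binning or default_binning(net)
    ks, counts = degree_distribution(net, symmetrize=True)
    summary = scalar_summary(net)
    _, pd_probs, _ = disparity_distribution(net, n_bins=disparity_bins)
    return {
        "P1": link_probability_curve(net, binning, pair_budget=pair_budget, seed=seed),
        "Pk": counts / counts.sum(),
        "Rd": reciprocity_curve(net, binning),
        "Jf": overlap_curve(net, binning),
        "Cd": clustering_curve(net, binning),
        "PD": pd_probs,
        "Nc": float(summary.n_connected),
        "local_C": summary.mean_local_clustering,
        "_binning": binning,
    }


def average_properties(props_list: list[dict]) -> dict:
    """Replica-mean of property dictionaries (per-bin, count-weighted for curves).

    Averaging the model's curves over replicas before scoring removes most of
    the replica sampling noise from the discrepancy, which would otherwise
    both blur the Err surface and bias it toward parameter regions that
    produce smoother curves.
    """
    out: dict = {}
    first = props_list[0]
    for name in PROPERTY_NAMES:
        vals = [p[name] for p in props_list]
        if isinstance(first[name], MetricCurve):
            v = np.array([np.where(c.defined, c.values, 0.0) for c in vals])
            n = np.array([c.counts for c in vals], dtype=float)
            tot = n.sum(axis=0)
            merged = np.full(tot.shape, np.nan)
            nz = tot > 0
            merged[nz] = (v * n).sum(axis=0)[nz] / tot[nz]
            out[name] = MetricCurve(
                binning=first[name].binning, values=merged, counts=tot.astype(int)
            )
        elif isinstance(first[name], np.ndarray):
            m = max(a.size for a in vals)
            out[name] = np.mean([np.pad(a, (0, m - a.size)) for a in vals], axis=0)
        else:
            out[name] = float(np.mean(vals))
    return out


def _symmetric_terms(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    denom = np.abs(a) + np.abs(b)
    out = np.zeros_like(denom)
    nz = denom > 0
    out[nz] = np.abs(a - b)[nz] / denom[nz]
    return out


def property_error(reference, model, min_count: int = 1) -> float:
    """E_X for one property (curve, histogram array, or scalar).

    Curve bins enter the sum when either side has at least ``min_count``
    samples there (an undefined side contributes 0); raising ``min_count``
    suppresses the sampling-noise floor of sparse tail bins during
    calibration.
    """
    if isinstance(reference, MetricCurve) and isinstance(model, MetricCurve):
        if reference.binning.n_bins != model.binning.n_bins:
            raise InputError("curves must share a binning")
        mask = (reference.defined & (reference.counts >= min_count)) | (
            model.defined & (model.counts >= min_count)
        )
        if not mask.any():
            raise InputError("no bin is defined on either side")
        a = np.where(reference.defined, reference.values, 0.0)[mask]
        b = np.where(model.defined, model.values, 0.0)[mask]
        return float(_symmetric_terms(a, b).mean())
    if isinstance(reference, np.ndarray) or isinstance(model, np.ndarray):
        a = np.asarray(reference, dtype=float)
        b = np.asarray(model, dtype=float)
        m = max(a.size, b.size)
        a = np.pad(a, (0, m - a.size))
        b = np.pad(b, (0, m - b.size))
        mask = (a != 0) | (b != 0)
        if not mask.any():
            raise InputError("both distributions are empty")
        return float(_symmetric_terms(a[mask], b[mask]).mean())
    a, b = float(reference), float(model)
    return float(_symmetric_terms(np.array([a]), np.array([b]))[0])


def total_err(
    reference_props: dict, model_props: dict, min_count: int = 1
) -> tuple[float, dict]:
    """Err = mean E_X over the eight properties; returns (Err, per-property)."""
    per = {}
    for name in PROPERTY_NAMES:
        if name not in reference_props or name not in model_props:
            raise InputError(f"missing property {name!r}")
        per[name] = property_error(
            reference_props[name], model_props[name], min_count=min_count
        )
    return float(np.mean(list(per.values()))), per


@dataclass(frozen=True)
class LatinSquareDesign:
    """k cells of a k x k (p_v, p_c) grid, one per row and column."""

    pv_levels: np.ndarray  # linear grid
    pc_levels: np.ndarray  # logarithmic grid
    cells: tuple  # ((row, col), ...) with rows=pv index, cols=pc index

    @classmethod
    def sample(
        cls,
        pv_range: tuple[float, float],
        pc_range: tuple[float, float],
        k: int,
        rng: np.random.Generator,
    ) -> "LatinSquareDesign":
        if k < 2:
            raise InputError("k must be >= 2")
        pv = np.linspace(pv_range[0], pv_range[1], k)
        pc = np.geomspace(pc_range[0], pc_range[1], k)
        perm = rng.permutation(k)
        return cls(pv_levels=pv, pc_levels=pc, cells=tuple((i, int(perm[i])) for i in range(k)))

    def params(self):
        for (i, j) in self.cells:
            yield (i, j, float(self.pv_levels[i]), float(self.pc_levels[j]))


@dataclass
class ScanResult:
    design: LatinSquareDesign
    table: pd.DataFrame  # one row per cell: pv_idx, pc_idx, p_v, p_c, err, E_X columns
    best_pv: float
    best_pc: float


def latin_square_scan(
    reference_net: DirectedGeoNetwork,
    grid: PopulationGrid,
    positions: list[Location],
    base_params: ModelParams,
    pv_range: tuple[float, float] = (0.05, 0.95),
    pc_range: tuple[float, float] = (1e-3, 0.5),
    k: int = 7,
    replicas: int = 3,
    seed: int | None = 0,
    pair_budget: int = 2_000_000,
    n_bins: int = 12,
    min_count: int = 5,
    refine: bool = True,
    max_refine_steps: int = 6,
) -> ScanResult:
    """Scan (p_v, p_c) over a Latin-square design against a reference network.

    Each design cell reruns the coupled model ``replicas`` times with distinct
    derived seeds, at the reference's link count; the replica-averaged
    properties are scored against the reference on its binning.  The
    comparison uses coarser distance bins than the plotting default and drops
    bins with fewer than ``min_count`` samples, which suppresses the
    sampling-noise floor that would otherwise mask the parameter signal.

    A Latin design visits each row and column once, so its resolution around
    the minimum is one grid step at best; with ``refine`` the scan then
    descends greedily on the full k x k grid from the Latin argmin (evaluating
    the four neighbors per step), mirroring the usual follow-up exploration
    along the lines crossing the minimum.
    """
    ss = np.random.SeedSequence(seed)
    design_rng = np.random.default_rng(ss.spawn(1)[0])
    design = LatinSquareDesign.sample(pv_range, pc_range, k, design_rng)
    binning = default_binning(reference_net, n_bins=n_bins)
    ref_props = compute_properties(reference_net, binning, pair_budget=pair_budget)
    l_target = reference_net.n_edges
    base_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
    cache: dict[tuple[int, int], dict] = {}

    def evaluate(i: int, j: int) -> dict:
        if (i, j) in cache:
            return cache[(i, j)]
        p_v = float(design.pv_levels[i])
        p_c = float(design.pc_levels[j])
        params = replace(base_params, p_v=p_v, p_c=p_c, L_target=l_target)
        reps = []
        for r in range(replicas):
            # common random numbers: every cell reuses the same replica seeds,
            # so shared sampling noise cancels in cell-to-cell comparisons
            child = np.random.SeedSequence((base_seed, r))
            res = run_tf(
                params, grid, positions,
                seed=int(child.generate_state(1)[0] % (2**31)),
            )
            reps.append(compute_properties(res.net, binning, pair_budget=pair_budget))
        err, per = total_err(ref_props, average_properties(reps), min_count=min_count)
        row = {"pv_idx": i, "pc_idx": j, "p_v": p_v, "p_c": p_c, "err": err}
        for name in PROPERTY_NAMES:
            row[f"E_{name}"] = per[name]
        cache[(i, j)] = row
        return row

    for (i, j) in design.cells:
        evaluate(i, j)
    best = min(cache.values(), key=lambda r: r["err"])
    if refine:
        cur = (best["pv_idx"], best["pc_idx"])
        for _ in range(max_refine_steps):
            i, j = cur
            neighbors = [
                (i + di, j + dj)
                for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1))
                if 0 <= i + di < k and 0 <= j + dj < k
            ]
            for cell in neighbors:
                evaluate(*cell)
            nxt = min(
                (cache[c] for c in neighbors + [cur]), key=lambda r: r["err"]
            )
            if (nxt["pv_idx"], nxt["pc_idx"]) == cur:
                break
            cur = (nxt["pv_idx"], nxt["pc_idx"])
        best = min(cache.values(), key=lambda r: r["err"])
    table = pd.DataFrame(list(cache.values()))
    return ScanResult(
        design=design, table=table, best_pv=float(best["p_v"]), best_pc=float(best["p_c"])
    )


def sensitivity_sweep(
    base_params: ModelParams,
    grid: PopulationGrid,
    positions: list[Location],
    param_name: str,
    values,
    replicas: int = 3,
    seed: int | None = 0,
    binning: DistanceBinning | None = None,
    pair_budget: int = 2_000_000,
):
    """Rerun the model varying one parameter; returns (curves, summary table).

    ``curves`` maps each swept value to the list of per-replica property
    dictionaries; the summary table holds per-value replica means of scalar
    digests (weighted-mean J_f and C(d), global reciprocity, connected nodes).
    """
    out: dict = {}
    rows = []
    for vi, value in enumerate(values):
        params = replace(base_params, **{param_name: value})
        reps = []
        for r, child in enumerate(
            np.random.SeedSequence(((seed or 0), vi)).spawn(replicas)
        ):
            res = run_tf(
                params, grid, positions, seed=int(child.generate_state(1)[0] % (2**31))
            )
            props = compute_properties(
                res.net, binning or default_binning(res.net), pair_budget=pair_budget
            )
            props["_summary"] = scalar_summary(res.net)
            reps.append(props)
        out[value] = reps
        rows.append(
            {
                param_name: value,
                "mean_Jf": float(np.mean([p["Jf"].weighted_mean() for p in reps])),
                "mean_Cd": float(np.mean([p["Cd"].weighted_mean() for p in reps])),
                "global_R": float(
                    np.mean([p["_summary"].global_reciprocity for p in reps])
                ),
                "Nc": float(np.mean([p["Nc"] for p in reps])),
            }
        )
    return out, pd.DataFrame(rows)
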