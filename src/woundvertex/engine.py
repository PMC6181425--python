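"""Time-stepping engine: overdamped dynamics and the closure loop.

Each step executes, in fixed order:

1. adhesion kinetics (unbind at k_off, bind at k_on; protrusive binding at
   the crawling wound edge),
2. edge refinement (subdivide > L_max, merge < L_min) and collapse of
   vanishing wound-border edges,
3. T1 neighbour exchanges on interior edges below L*,
4. motility-mode update (stochastic crawl->purse-string at k_p, or the
   curvature-gated variant),
5. motion: forward-Euler overdamped updates
   dx = (dt/mu) (F + f_p) for wound-edge vertices,
   dx = (dt/mu) (F + averaged self-propulsion) in the bulk,
   dr = (dt/mu) (spring + adhesion forces) for free substrate nodes,
   plus rotational diffusion of bulk polarity.

Randomness is split into independent per-subsystem streams (adhesion,
polarity, mode switching) derived from one root seed, so switching one
subsystem off does not shift another's draws.  Identical (state, params,
seed) give bitwise-identical trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import ModelParams
from .tissue import Tissue, MODE_BULK, MODE_CRAWL, MODE_PS, polygon_area, TopologyError
from .mechanics import (mechanical_forces, refine_edges,
                        collapse_short_border_edges, fuse_wound_fronts,
                        seal_small_loops, scan_t1)
from .adhesion import AdhesionUpdater
from .motility import (update_polarity, self_propulsion_forces,
                       crawl_directions, crawl_forces,
                       switch_modes_stochastic, switch_modes_curvature)

__all__ = ["Simulation", "Trajectory", "Snapshot", "SimulationUnstable",
           "run_to_closure", "wound_area", "sweep"]


class SimulationUnstable(RuntimeError):
    pass


def wound_area(tissue: Tissue) -> float:
    """Open wound area (um^2): shoelace area summed over the wound-border
    loops.  Zero once the wound has closed; raises on a broken border (a
    loop reduced below 3 vertices while carrying area)."""
    loops = tissue.wound_loops()
    if not loops:
        return 0.0
    if all(len(lp) < 3 for lp in loops):
        raise TopologyError("wound border loop is broken (< 3 vertices)")
    return tissue.wound_area()


@dataclass
class Snapshot:
    t: float
    x: np.ndarray
    cells: list
    mode: np.ndarray
    theta: np.ndarray
    adh_node: np.ndarray
    adh_rest: np.ndarray
    sub_u: np.ndarray | None
    wound_area: float
    border_vertices: np.ndarray
    centroids: np.ndarray

    def as_tissue(self) -> Tissue:
        t = Tissue(self.x, self.cells, mode=self.mode, theta=self.theta)
        t.adh_node = self.adh_node.copy()
        t.adh_rest = self.adh_rest.copy()
        return t


@dataclass
class Trajectory:
    params: ModelParams
    seed: int | None
    wound_center: np.ndarray
    substrate: object | None = None        # reference mesh; node u per snapshot
    times: list = field(default_factory=list)
    snapshots: list = field(default_factory=list)
    events: list = field(default_factory=list)
    area_times: list = field(default_factory=list)
    areas: list = field(default_factory=list)
    closure_time: float | None = None      # None => censored (no closure by t_max)

    @property
    def closed(self) -> bool:
        return self.closure_time is not None

    @property
    def n_cells(self) -> int:
        return len(self.snapshots[0].cells) if self.snapshots else 0

    def duration(self) -> float:
        if self.closure_time is not None:
            return self.closure_time
        return self.area_times[-1] if self.area_times else 0.0


class Simulation:
    """Mechanochemical wound-closure simulation on one tissue + substrate."""

    def __init__(self, tissue: Tissue, substrate, params: ModelParams,
                 seed: int | None = 0):
        self.tissue = tissue
        self.substrate = substrate
        self.params = params
        self.seed = seed
        ss = np.random.SeedSequence(seed)
        kids = ss.spawn(3)
        self.rng_adhesion = np.random.default_rng(kids[0])
        self.rng_polarity = np.random.default_rng(kids[1])
        self.rng_modes = np.random.default_rng(kids[2])
        self._adh = AdhesionUpdater()
        self.t = 0.0
        self._step_count = 0
        self.events: list = []
        loop = tissue.wound_loop()
        self.wound_center = (tissue.x[loop].mean(axis=0) if loop is not None
                             else tissue.x[tissue.topology.used].mean(axis=0))
        self.closed = wound_area(tissue) < params.A_close if loop is not None else True

    # ------------------------------------------------------------------
    def step(self) -> None:
        tissue, sub, p = self.tissue, self.substrate, self.params

        # 1 --- adhesion kinetics (protrusive binding needs crawl directions)
        if sub is not None:
            dirs = crawl_directions(tissue)
            self.events += self._adh.update(tissue, sub, p, self.rng_adhesion,
                                            crawl_dirs=dirs, t=self.t)

        # 2 --- edge refinement and border-edge collapse (one pass per step;
        #       refinement runs every step, so stragglers are caught next step)
        refine_edges(tissue, params=p, max_iter=1)
        for (a, b) in collapse_short_border_edges(tissue, p.L_min / 4.0):
            self.events.append({"kind": "collapse", "t": self.t,
                                "vertex": int(a), "node": int(b), "tension": 0.0})
        for (a, b) in fuse_wound_fronts(tissue, p.L_min):
            self.events.append({"kind": "fuse", "t": self.t,
                                "vertex": int(a), "node": int(b), "tension": 0.0})
        for size in seal_small_loops(tissue, p.A_close):
            self.events.append({"kind": "seal", "t": self.t,
                                "vertex": int(size), "node": -1, "tension": 0.0})

        # 3 --- T1 neighbour exchanges
        if p.t1_enabled:
            for key in scan_t1(tissue, p, sub):
                self.events.append({"kind": "t1", "t": self.t,
                                    "vertex": int(key[0]), "node": int(key[1]),
                                    "tension": 0.0})

        # 4 --- motility-mode update
        if p.curvature_sensing:
            self.events += switch_modes_curvature(tissue, p, t=self.t)
        else:
            self.events += switch_modes_stochastic(tissue, p, self.rng_modes,
                                                   t=self.t)

        # 5 --- overdamped motion.  The motion update is sub-stepped when a
        # vertex would move further than L_min in one Euler step (sharp
        # corners on distorted border cells produce transiently large elastic
        # forces); sub-stepping recomputes forces and converges to the same
        # overdamped dynamics.  Kinetics stay at cadence dt.
        dirs = crawl_directions(tissue)
        used = tissue.topology.used
        free = None if sub is None else ~sub.pinned
        clamp_ids, clamp_speed = self._contact_speed_caps()
        remaining = p.dt
        n_sub = 0
        Fn_adh = None   # time-averaged adhesion reaction on substrate nodes
        while remaining > 1e-12:
            F, F_nodes = mechanical_forces(tissue, sub, p)
            F += crawl_forces(tissue, p, dirs)
            F += self_propulsion_forces(tissue, p)
            v = F / p.mu
            if len(clamp_ids):
                sp = np.hypot(v[clamp_ids, 0], v[clamp_ids, 1])
                over = sp > clamp_speed
                if over.any():
                    scale = np.ones_like(sp)
                    scale[over] = clamp_speed[over] / sp[over]
                    v[clamp_ids] *= scale[:, None]
            vmax = float(np.max(np.hypot(v[used, 0], v[used, 1]))) if used.any() else 0.0
            dt_sub = remaining
            if vmax * dt_sub > p.L_min:
                dt_sub = max(p.L_min / vmax, remaining / 8.0)
            dt_sub = min(dt_sub, remaining)
            if n_sub >= 32:
                raise SimulationUnstable(
                    f"vertex speed {vmax:.3g} um/s keeps displacement above "
                    f"{p.L_min} um after 32 sub-steps; reduce dt")
            tissue.x[used] += dt_sub * v[used]
            if F_nodes is not None:
                w = dt_sub / p.dt
                Fn_adh = F_nodes * w if Fn_adh is None else Fn_adh + F_nodes * w
            remaining -= dt_sub
            n_sub += 1
        if sub is not None:
            # substrate nodes are slow (their relaxation time mu/k_s is
            # hundreds of seconds), so one update per step suffices
            from .substrate import substrate_forces
            Fn = substrate_forces(sub)
            if Fn_adh is not None:
                Fn += Fn_adh
            sub.r[free] += (p.dt / p.mu) * Fn[free]
        tissue.theta = update_polarity(tissue.theta, p.dt, p.D_r, self.rng_polarity)
        self.t += p.dt
        self._step_count += 1
        if self._step_count % 25 == 0:
            used = tissue.topology.used
            if used.sum() < 0.7 * len(tissue.x):
                tissue.compact()

        loops = tissue.wound_loops()
        if not loops or all(len(lp) < 3 for lp in loops) \
                or tissue.wound_area() < p.A_close:
            self.closed = True

    # ------------------------------------------------------------------
    def _contact_speed_caps(self, horizon: float = 4.0, frac: float = 0.45):
        """Speed caps keeping approaching wound fronts from interpenetrating.

        A wound-border vertex may move at most ``frac`` of its distance to
        the nearest border vertex that is >= 3 hops away along the loop, per
        step; both sides moving at most 45% of their separation can approach
        geometrically but never cross, and fusion merges them on contact.
        Returns (vertex ids, max speeds)."""
        from scipy.spatial import cKDTree
        tissue, p = self.tissue, self.params
        ids, caps = [], []
        for loop in tissue.wound_loops():
            n = len(loop)
            if n < 8:
                continue
            tree = cKDTree(tissue.x[loop])
            pairs = tree.query_pairs(horizon)
            dmin = np.full(n, np.inf)
            for (i, j) in pairs:
                hop = abs(i - j)
                hop = min(hop, n - hop)
                if hop < 3:
                    continue
                d = float(np.linalg.norm(tissue.x[loop[i]] - tissue.x[loop[j]]))
                dmin[i] = min(dmin[i], d)
                dmin[j] = min(dmin[j], d)
            close = np.isfinite(dmin)
            ids.extend(int(v) for v in loop[close])
            caps.extend(frac * dmin[close] / p.dt)
        return np.asarray(ids, dtype=np.int64), np.asarray(caps)

    # ------------------------------------------------------------------
    def snapshot(self) -> Snapshot:
        tissue = self.tissue
        return Snapshot(
            t=self.t,
            x=tissue.x.copy(),
            cells=[c.copy() for c in tissue.cells],
            mode=tissue.mode.copy(),
            theta=tissue.theta.copy(),
            adh_node=tissue.adh_node.copy(),
            adh_rest=tissue.adh_rest.copy(),
            sub_u=None if self.substrate is None else self.substrate.u.copy(),
            wound_area=self.tissue.wound_area(),
            border_vertices=tissue.wound_border_vertices().copy(),
            centroids=tissue.centroids().copy(),
        )

    def run(self, t_max: float | None = None,
            snapshot_every: float | None = None) -> Trajectory:
        """Step until wound closure or ``t_max``; record snapshots, the wound
        area series and the event log.  A run that hits ``t_max`` open is
        reported as censored (closure_time None), not an error."""
        p = self.params
        t_max = p.t_max if t_max is None else t_max
        cadence = p.snapshot_every if snapshot_every is None else snapshot_every
        traj = Trajectory(params=p, seed=self.seed,
                          wound_center=self.wound_center.copy(),
                          substrate=self.substrate)
        traj.snapshots.append(self.snapshot())
        traj.times.append(self.t)
        traj.area_times.append(self.t)
        traj.areas.append(self.tissue.wound_area())
        next_snap = self.t + cadence
        while not self.closed and self.t < t_max - 1e-9:
            self.step()
            traj.area_times.append(self.t)
            traj.areas.append(self.tissue.wound_area())
            if self.t >= next_snap - 1e-9 or self.closed:
                traj.snapshots.append(self.snapshot())
                traj.times.append(self.t)
                next_snap += cadence
        traj.events = self.events
        if self.closed:
            traj.closure_time = self.t
        return traj


def run_to_closure(tissue: Tissue, substrate, params: ModelParams,
                   seed: int | None = 0, t_max: float | None = None) -> Trajectory:
    """Convenience wrapper: build a Simulation and run it to closure."""
    return Simulation(tissue, substrate, params, seed=seed).run(t_max=t_max)


# --------------------------------------------------------------------------
# parameter sweeps
# --------------------------------------------------------------------------

def sweep(grid: dict, params: ModelParams, replicates: int = 5,
          base_seed: int = 0, kind: str = "voronoi",
          t_max: float | None = None) -> pd.DataFrame:
    """Run ``replicates`` stochastic closures for every combination in
    ``grid`` (param name -> list of values) and summarise closure time, mean
    substrate strain energy, guidance G and T1 rate (mean and sd over
    replicates)."""
    import itertools
    from .woundgen import initial_state
    from . import analysis

    names = list(grid.keys())
    rows = []
    combo_seeds = np.random.SeedSequence(base_seed).spawn(
        int(np.prod([len(grid[n]) for n in names]) or 1))
    for ic, values in enumerate(itertools.product(*(grid[n] for n in names))):
        combo = dict(zip(names, values))
        pr = params.replace(**combo)
        rep_seeds = combo_seeds[ic].spawn(replicates)
        metrics = {"closure_time": [], "mean_strain_energy": [], "G": [],
                   "t1_rate": []}
        for rs in rep_seeds:
            seed_int = int(rs.generate_state(1)[0] % (2 ** 31))
            tissue, sub = initial_state(pr, seed=seed_int, kind=kind)
            traj = run_to_closure(tissue, sub, pr, seed=seed_int, t_max=t_max)
            metrics["closure_time"].append(
                np.nan if traj.closure_time is None else traj.closure_time)
            metrics["mean_strain_energy"].append(analysis.mean_strain_energy(traj))
            metrics["G"].append(analysis.guidance(traj)[1])
            metrics["t1_rate"].append(analysis.t1_rate(traj))
        row = dict(combo)
        for k, v in metrics.items():
            row[f"{k}_mean"] = float(np.nanmean(v))
            row[f"{k}_sd"] = float(np.nanstd(v, ddof=1)) if replicates > 1 else 0.0
        row["replicates"] = replicates
        rows.append(row)
    return pd.DataFrame(rows)
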