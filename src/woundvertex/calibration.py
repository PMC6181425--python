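"""Single-cell calibration runs.

The protrusion force scale is anchored to the crawl speed of an isolated
cell with a fixed polarity vector: every boundary vertex is treated as a
leading-edge vertex with the same protrusion direction, adhesion kinetics
run as in the tissue, and the mean centroid speed over the run is reported.
"""

from __future__ import annotations

import math

import numpy as np

from .params import ModelParams
from .tissue import Tissue, MODE_CRAWL
from .mechanics import mechanical_forces, refine_edges
from .adhesion import AdhesionUpdater
from .motility import crawl_forces
from .substrate import build_substrate, substrate_forces

__all__ = ["make_single_cell", "single_cell_crawl_speed"]


def make_single_cell(params: ModelParams) -> Tissue:
    """One regular hexagonal cell of area A0, in crawl mode, edges refined."""
    s = math.sqrt(2.0 * params.A0 / (3.0 * math.sqrt(3.0)))
    ang = np.arange(6) * np.pi / 3.0
    pts = np.column_stack([s * np.cos(ang), s * np.sin(ang)])
    tissue = Tissue(pts, [np.arange(6)])
    tissue.mode[0] = MODE_CRAWL
    refine_edges(tissue, params=params)
    return tissue


def single_cell_crawl_speed(params: ModelParams, seed: int = 0,
                            duration: float = 3600.0,
                            direction=(1.0, 0.0)) -> float:
    """Mean crawl speed (um/hr) of a single cell with fixed polarity.

    The cell sits on a default substrate; all its vertices protrude along
    ``direction`` when unbound (finite lamellipodial reach) and bind/unbind
    with the default kinetics, protrusively biased forward.
    """
    p = params
    tissue = make_single_cell(p)
    vhat = np.asarray(direction, dtype=float)
    vhat = vhat / np.linalg.norm(vhat)
    span = p.v0 * 0.0 + 60.0  # substrate long enough for ~1 hr of crawling
    sub = build_substrate((-10.0, span, -12.0, 12.0), params=p, margin=8.0)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    updater = AdhesionUpdater()
    c0 = tissue.centroids()[0].copy()
    t = 0.0
    nsteps = int(round(duration / p.dt))
    free = ~sub.pinned
    for _ in range(nsteps):
        used_ids = np.where(tissue.topology.used)[0]
        dirs = {int(v): vhat for v in used_ids}
        updater.update(tissue, sub, p, rng, crawl_dirs=dirs, t=t)
        refine_edges(tissue, params=p, max_iter=1)
        used = tissue.topology.used
        dirs = {int(v): vhat for v in np.where(used)[0]}
        remaining = p.dt
        n_sub = 0
        while remaining > 1e-12 and n_sub < 32:
            F, F_nodes = mechanical_forces(tissue, sub, p)
            F += crawl_forces(tissue, p, dirs)
            v = F / p.mu
            vmax = float(np.max(np.hypot(v[used, 0], v[used, 1])))
            dt_sub = remaining
            if vmax * dt_sub > p.L_min:
                dt_sub = max(p.L_min / vmax, remaining / 16.0)
            dt_sub = min(dt_sub, remaining)
            tissue.x[used] += dt_sub * v[used]
            Fn = substrate_forces(sub)
            if F_nodes is not None:
                Fn += F_nodes
            sub.r[free] += (dt_sub / p.mu) * Fn[free]
            remaining -= dt_sub
            n_sub += 1
        t += p.dt
    c1 = tissue.centroids()[0]
    return float(np.linalg.norm(c1 - c0) / duration * 3600.0)
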