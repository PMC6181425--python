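"""Kinetic focal adhesions coupling cell vertices to substrate nodes.

Each cell vertex can carry at most one adhesion: a stiff spring of stiffness
k_f between the vertex and a substrate node, whose rest extension is the
vertex-node separation recorded at binding time.  Bound vertices detach with
rate k_off (optionally force-dependent via a two-pathway catch-bond law);
unbound vertices attach to the nearest substrate node with rate k_on.
Vertices on the wound border of crawling cells bind "protrusively": the
candidate node is the one nearest to the vertex displaced one lattice
spacing along the crawl direction, which biases new adhesions ahead of the
leading edge.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial import cKDTree

from .params import ModelParams
from .tissue import Tissue, MODE_CRAWL

__all__ = ["adhesion_energy", "adhesion_forces", "bond_tensions",
           "catch_bond_off_rate", "update_adhesion_states", "AdhesionUpdater"]


def adhesion_energy(tissue: Tissue, substrate, params: ModelParams) -> float:
    """Total focal-adhesion spring energy (nN um)."""
    bound = np.where(tissue.adh_node >= 0)[0]
    if len(bound) == 0:
        return 0.0
    sep = tissue.x[bound] - substrate.r[tissue.adh_node[bound]]
    L = np.hypot(sep[:, 0], sep[:, 1])
    return 0.5 * params.k_f * float(np.sum((L - tissue.adh_rest[bound]) ** 2))


def adhesion_forces(tissue: Tissue, substrate, params: ModelParams):
    """Equal-and-opposite spring forces: (force on vertices, force on nodes).

    The force vanishes when the current separation equals the separation
    recorded at binding; otherwise it has magnitude k_f * (|x - r| - rest)
    along the connector (attractive when stretched).
    """
    n = len(tissue.x)
    Fv = np.zeros((n, 2))
    Fn = np.zeros((substrate.n_nodes, 2))
    bound = np.where(tissue.adh_node >= 0)[0]
    if len(bound) == 0:
        return Fv, Fn
    nodes = tissue.adh_node[bound]
    sep = tissue.x[bound] - substrate.r[nodes]
    L = np.hypot(sep[:, 0], sep[:, 1])
    Lsafe = np.where(L > 0, L, 1.0)
    f = -params.k_f * (L - tissue.adh_rest[bound])  # < 0 when stretched: pulls back
    fvec = (f / Lsafe)[:, None] * sep
    Fv[bound] = fvec
    np.add.at(Fn, nodes, -fvec)
    return Fv, Fn


def bond_tensions(tissue: Tissue, substrate, params: ModelParams) -> np.ndarray:
    """Per-vertex bond tension magnitude k_f * |(|x-r| - rest)| (nN);
    zero for unbound vertices."""
    t = np.zeros(len(tissue.x))
    bound = np.where(tissue.adh_node >= 0)[0]
    if len(bound):
        sep = tissue.x[bound] - substrate.r[tissue.adh_node[bound]]
        L = np.hypot(sep[:, 0], sep[:, 1])
        t[bound] = params.k_f * np.abs(L - tissue.adh_rest[bound])
    return t


def catch_bond_off_rate(f, params: ModelParams):
    """Two-pathway unbinding rate as a function of bond tension (s^-1).

    k_off(f) = k0 exp(-f/f0) + k1 exp(catch_sign * f/f1).  With
    ``catch_sign = +1`` (default) the second pathway strengthens under load,
    so the lifetime first rises then falls with force — a catch bond.  With
    ``catch_sign = -1`` both pathways decay (pure slip weakening).  At f = 0
    the rate is k0 + k1 either way.  Negative tensions (compressed bonds) are
    clamped to zero with a warning.
    """
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        warnings.warn("negative bond tension clamped to 0", stacklevel=2)
        f = np.clip(f, 0.0, None)
    return params.k0 * np.exp(-f / params.f0) + params.k1 * np.exp(params.catch_sign * f / params.f1)


class AdhesionUpdater:
    """Stochastic bind/unbind update with a cached KD-tree over substrate
    nodes (rebuilt every ``tree_refresh`` calls; node displacements per step
    are tiny compared with the lattice spacing)."""

    def __init__(self, tree_refresh: int = 20):
        self.tree_refresh = tree_refresh
        self._tree = None
        self._count = 0

    def _get_tree(self, substrate) -> cKDTree:
        if self._tree is None or self._count % self.tree_refresh == 0:
            self._tree = cKDTree(substrate.r)
        self._count += 1
        return self._tree

    def update(self, tissue: Tissue, substrate, params: ModelParams,
               rng: np.random.Generator, crawl_dirs: dict | None = None,
               t: float = 0.0) -> list:
        """One kinetic step of duration params.dt.

        ``crawl_dirs`` maps wound-border vertex id -> unit crawl direction
        for vertices of crawl-mode cells (protrusive binding).  Returns the
        event list: dicts with keys kind/t/vertex/node/tension.
        """
        events = []
        dt = params.dt
        used = tissue.topology.used

        # states are read at the start of the step (simultaneous update): a
        # vertex that detaches now can rebind next step at the earliest, so
        # the stationary bound fraction is k_on/(k_on + k_off)
        unbound_start = np.where((tissue.adh_node < 0) & used)[0]

        # ---- unbinding ----
        bound = np.where((tissue.adh_node >= 0) & used)[0]
        if len(bound):
            if params.catch_bond:
                tension = bond_tensions(tissue, substrate, params)[bound]
                rates = catch_bond_off_rate(tension, params)
            else:
                tension = bond_tensions(tissue, substrate, params)[bound]
                rates = np.full(len(bound), params.k_off)
            p_off = np.minimum(rates * dt, 1.0)
            detach = bound[rng.random(len(bound)) < p_off]
            for v in detach:
                events.append({"kind": "unbind", "t": t, "vertex": int(v),
                               "node": int(tissue.adh_node[v]),
                               "tension": float(tension[np.searchsorted(bound, v)])})
            tissue.adh_node[detach] = -1
            # a fresh protrusion starts where the vertex let go
            tissue.prot_anchor[detach] = tissue.x[detach]

        # ---- binding ----
        unbound = unbound_start
        if len(unbound):
            p_on = min(params.k_on * dt, 1.0)
            binders = unbound[rng.random(len(unbound)) < p_on]
            if len(binders):
                query = tissue.x[binders].copy()
                if crawl_dirs:
                    for i, v in enumerate(binders):
                        d = crawl_dirs.get(int(v))
                        if d is not None:
                            query[i] = query[i] + params.protrusion_delta * d
                tree = self._get_tree(substrate)
                dist, nodes = tree.query(query)
                ok = dist <= params.capture_radius
                for v, node, good in zip(binders, nodes, ok):
                    if not good:
                        continue  # no node within the capture radius
                    tissue.adh_node[v] = node
                    tissue.adh_x0[v] = tissue.x[v]
                    tissue.adh_r0[v] = substrate.r[node]
                    tissue.adh_rest[v] = float(np.linalg.norm(tissue.x[v] - substrate.r[node]))
                    tissue.prot_anchor[v] = np.nan
                    events.append({"kind": "bind", "t": t, "vertex": int(v),
                                   "node": int(node), "tension": 0.0})
        return events


def update_adhesion_states(tissue: Tissue, substrate, params: ModelParams,
                           rng: np.random.Generator,
                           crawl_dirs: dict | None = None, t: float = 0.0) -> list:
    """One-shot adhesion kinetics update (builds a fresh KD-tree)."""
    return AdhesionUpdater(tree_refresh=1).update(tissue, substrate, params,
                                                  rng, crawl_dirs, t)
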