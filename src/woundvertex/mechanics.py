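"""Passive vertex-model mechanics: energies, analytic forces, edge
refinement and T1 neighbour exchanges.

The working energy per cell is the completed-square form

    E_i = K (A_i - A0)^2 + Gamma (P_i - P0)^2,

with P0 = -gamma / (2 Gamma) the preferred perimeter.  The expanded form
K (A - A0)^2 + Gamma P^2 + gamma P differs from it only by the constant
Gamma P0^2 per cell, so forces are identical.  Forces are the exact analytic
gradient -dE/dx assembled per polygon corner:

    dA/dx_v = ( y_next - y_prev, x_prev - x_next ) / 2
    dP/dx_v = unit(x_v - x_prev) + unit(x_v - x_next)
"""

from __future__ import annotations

import numpy as np

from .params import ModelParams, ConfigurationError
from .tissue import (Tissue, GeometryError, cross2, polygon_area,
                     polygon_perimeter, polygon_is_simple, MODE_PS)

__all__ = ["cell_energy", "shape_parameter", "tissue_mech_energy",
           "elastic_forces", "mechanical_forces", "refine_edges",
           "collapse_short_border_edges", "attempt_t1", "scan_t1"]


# --------------------------------------------------------------------------
# energies
# --------------------------------------------------------------------------

def cell_energy(pts: np.ndarray, params: ModelParams) -> float:
    """Mechanical energy of a single cell polygon (nN um)."""
    pts = np.asarray(pts, dtype=float)
    if len(pts) < 3:
        raise GeometryError("polygon needs at least 3 vertices")
    a = polygon_area(pts)
    if a <= 0:
        raise GeometryError(f"polygon area must be positive (CCW), got {a:.3g}")
    p = polygon_perimeter(pts)
    return params.K * (a - params.A0) ** 2 + params.Gamma * (p - params.P0) ** 2


def cell_energy_expanded(pts: np.ndarray, params: ModelParams) -> float:
    """Expanded energy form K(A-A0)^2 + Gamma P^2 + gamma P (for cross-checks)."""
    a = polygon_area(np.asarray(pts, dtype=float))
    p = polygon_perimeter(np.asarray(pts, dtype=float))
    return params.K * (a - params.A0) ** 2 + params.Gamma * p ** 2 + params.gamma * p


def shape_parameter(pts: np.ndarray) -> float:
    """Dimensionless shape index p = P / sqrt(A) of a polygon."""
    a = abs(polygon_area(np.asarray(pts, dtype=float)))
    if a == 0:
        raise GeometryError("zero-area polygon has undefined shape parameter")
    return polygon_perimeter(np.asarray(pts, dtype=float)) / np.sqrt(a)


def purse_string_edges(tissue: Tissue) -> list:
    """Wound-border edges owned by purse-string cells, as (u, v) pairs."""
    topo = tissue.topology
    out = []
    for key in tissue.wound_border_edges():
        corners = topo.edges.get(key)
        if corners and tissue.mode[topo.corner_cell[corners[0]]] == MODE_PS:
            out.append(key)
    return out


def tissue_mech_energy(tissue: Tissue, params: ModelParams,
                       substrate=None) -> float:
    """Total mechanical energy: cells + purse-string line tension
    (+ focal-adhesion springs when a substrate is given)."""
    A = tissue.areas()
    P = tissue.perimeters()
    e = float(np.sum(params.K * (A - params.A0) ** 2
                     + params.Gamma * (P - params.P0) ** 2))
    for (u, v) in purse_string_edges(tissue):
        e += params.gamma_ps * float(np.linalg.norm(tissue.x[v] - tissue.x[u]))
    if substrate is not None:
        from .adhesion import adhesion_energy
        e += adhesion_energy(tissue, substrate, params)
    return e


# --------------------------------------------------------------------------
# forces
# --------------------------------------------------------------------------

def elastic_forces(tissue: Tissue, params: ModelParams) -> np.ndarray:
    """-dE/dx of the cell area/perimeter energies, per vertex (nN)."""
    topo = tissue.topology
    x = tissue.x
    A = tissue.areas()
    P = tissue.perimeters()
    coefA = 2.0 * params.K * (A - params.A0)        # per cell
    coefP = 2.0 * params.Gamma * (P - params.P0)

    xv = x[topo.corner_v]
    xn = x[topo.corner_next]
    xp = x[topo.corner_prev]

    dA = 0.5 * np.column_stack([xn[:, 1] - xp[:, 1], xp[:, 0] - xn[:, 0]])
    ep = xv - xp
    en = xv - xn
    lp = np.hypot(ep[:, 0], ep[:, 1])
    ln = np.hypot(en[:, 0], en[:, 1])
    with np.errstate(invalid="ignore", divide="ignore"):
        dP = ep / np.where(lp > 0, lp, 1.0)[:, None] + en / np.where(ln > 0, ln, 1.0)[:, None]

    g = coefA[topo.corner_cell, None] * dA + coefP[topo.corner_cell, None] * dP
    n = len(x)
    fx = np.bincount(topo.corner_v, weights=-g[:, 0], minlength=n)
    fy = np.bincount(topo.corner_v, weights=-g[:, 1], minlength=n)
    return np.column_stack([fx, fy])


def mechanical_forces(tissue: Tissue, substrate, params: ModelParams):
    """Net mechanical force F = -dE_tot/dx on every vertex, plus the
    reaction forces on substrate nodes from the adhesion springs.

    E_tot = cell energies + purse-string line tension + adhesion springs.
    Returns ``(F_vertices, F_nodes)``; ``F_nodes`` is None without substrate.
    """
    from .motility import purse_string_forces
    F = elastic_forces(tissue, params) + purse_string_forces(tissue, params)
    F_nodes = None
    if substrate is not None:
        from .adhesion import adhesion_forces
        Fa, F_nodes = adhesion_forces(tissue, substrate, params)
        F = F + Fa
    return F, F_nodes


# --------------------------------------------------------------------------
# edge refinement
# --------------------------------------------------------------------------

def _edge_lengths(tissue: Tissue):
    keys = tissue.edge_array()
    if len(keys) == 0:
        return keys, np.empty(0)
    d = tissue.x[keys[:, 0]] - tissue.x[keys[:, 1]]
    return keys, np.hypot(d[:, 0], d[:, 1])


def _vertex_neighbors(tissue: Tissue) -> dict:
    return tissue.vertex_neighbors()


def _split_long_edges(tissue: Tissue, L_max: float) -> int:
    keys, lengths = _edge_lengths(tissue)
    idx = np.where(lengths > L_max)[0]
    if len(idx) == 0:
        return 0
    long_edges = [(int(keys[i, 0]), int(keys[i, 1])) for i in idx]
    topo = tissue.topology
    mids = tissue.add_vertices(0.5 * (tissue.x[[e[0] for e in long_edges]]
                                      + tissue.x[[e[1] for e in long_edges]]))
    inserts: dict = {}   # cell -> list of (position_after, new_vid)
    for (a, b), mid in zip(long_edges, mids):
        for k in topo.edges[(a, b)]:
            ci = int(topo.corner_cell[k])
            pos = k - int(topo.cell_ptr[ci])
            inserts.setdefault(ci, []).append((pos, int(mid)))
    for ci, ops in inserts.items():
        cell = list(tissue.cells[ci])
        for pos, vid in sorted(ops, reverse=True):
            cell.insert(pos + 1, vid)
        tissue.cells[ci] = np.asarray(cell, dtype=np.int64)
    tissue.invalidate_topology()
    return len(long_edges)


def _merge_short_edges(tissue: Tissue, L_min: float, max_rounds: int = 5) -> int:
    """Remove two-valent vertices on edges shorter than L_min.  Tri-cellular
    junction vertices are never removed.  Removals are batched per round
    (skipping vertices adjacent to an already-scheduled removal) so the
    topology is rebuilt once per round."""
    total = 0
    for _ in range(max_rounds):
        keys, lengths = _edge_lengths(tissue)
        if len(keys) == 0 or lengths.min() >= L_min:
            break
        nb = _vertex_neighbors(tissue)
        v_cells = tissue.vertex_cells()
        order = np.argsort(lengths)
        removable = []
        blocked: set = set()
        cell_hits: dict = {}
        for i in order:
            if lengths[i] >= L_min:
                break
            # among eligible endpoints prefer the more collinear one, so the
            # merge preserves the boundary shape (and its length)
            cand = []
            for v in keys[i]:
                if v in blocked:
                    continue
                cells_v = v_cells.get(v, [])
                if len(nb.get(v, ())) == 2 and all(
                        len(tissue.cells[ci]) - cell_hits.get(ci, 0) > 3
                        for ci in cells_v):
                    n1, n2 = (tissue.x[w] for w in nb[v])
                    chord = n2 - n1
                    nc = np.hypot(chord[0], chord[1])
                    dev = (abs(cross2(chord, tissue.x[v] - n1)) / nc
                           if nc > 0 else 0.0)
                    cand.append((dev, v, cells_v))
            if cand:
                _, v, cells_v = min(cand)
                removable.append(v)
                blocked.add(v)
                blocked.update(nb[v])
                for ci in cells_v:
                    cell_hits[ci] = cell_hits.get(ci, 0) + 1
        if not removable:
            break
        rem = set(removable)
        touched = {ci for v in removable for ci in v_cells[v]}
        for ci in touched:
            cell = tissue.cells[ci]
            tissue.cells[ci] = cell[~np.isin(cell, list(rem))]
        for v in removable:
            tissue.adh_node[v] = -1
        tissue.invalidate_topology()
        total += len(removable)
    return total


def refine_edges(tissue: Tissue, L_max: float | None = None,
                 L_min: float | None = None,
                 params: ModelParams | None = None, max_iter: int = 8) -> int:
    """Subdivide edges longer than L_max at their midpoint and merge away
    two-valent vertices on edges shorter than L_min.  Midpoint insertion
    preserves cell areas; an even edge-length distribution keeps focal
    adhesions evenly spread along cell boundaries.  Returns the number of
    topology operations performed."""
    if params is not None:
        L_max = params.L_max if L_max is None else L_max
        L_min = params.L_min if L_min is None else L_min
    if L_max is None or L_min is None:
        raise ConfigurationError("refine_edges needs L_max and L_min")
    if L_max <= 2.0 * L_min:
        raise ConfigurationError("refinement requires L_max > 2*L_min")
    # fast path: nothing to do (corner edges cover every edge)
    topo = tissue.topology
    d = tissue.x[topo.corner_v] - tissue.x[topo.corner_next]
    L = np.hypot(d[:, 0], d[:, 1])
    if len(L) and L.max() <= L_max and L.min() >= L_min:
        return 0
    total = 0
    for _ in range(max_iter):
        n = _split_long_edges(tissue, L_max)
        n += _merge_short_edges(tissue, L_min)
        total += n
        if n == 0:
            break
    return total


def collapse_short_border_edges(tissue: Tissue, threshold: float) -> list:
    """Collapse wound-border edges between two junction vertices that have
    shrunk below ``threshold`` (the contracted cable edge "shrinks to zero"),
    merging the endpoints at the edge midpoint and re-closing the border loop
    over the remaining vertices.  Returns the list of collapsed edges."""
    events = []
    guard = 0
    while guard < 50:
        guard += 1
        be = tissue.wound_border_edges()
        if not be:
            break
        short = []
        for (a, b) in be:
            L = float(np.linalg.norm(tissue.x[a] - tissue.x[b]))
            if L < threshold:
                short.append((a, b))
        if not short:
            break
        nb = _vertex_neighbors(tissue)
        v_cells = tissue.vertex_cells()
        target = None
        for (a, b) in short:
            if len(nb.get(a, ())) > 2 and len(nb.get(b, ())) > 2:
                target = (a, b)
                break
        if target is None:
            break
        a, b = target
        owner = None
        for ci in v_cells.get(a, []):
            if b in tissue.cells[ci]:
                owner = ci
        if owner is not None and len(tissue.cells[owner]) <= 3:
            break  # collapsing would degenerate the owning cell
        tissue.x[a] = 0.5 * (tissue.x[a] + tissue.x[b])
        for ci in list(v_cells.get(b, [])):
            cell = tissue.cells[ci]
            cell = np.where(cell == b, a, cell)
            keep = np.ones(len(cell), dtype=bool)
            for i in range(len(cell)):
                if cell[i] == cell[(i + 1) % len(cell)]:
                    keep[(i + 1) % len(cell)] = False
            tissue.cells[ci] = cell[keep]
        tissue.adh_node[a] = -1
        tissue.adh_node[b] = -1
        tissue.invalidate_topology()
        events.append((a, b))
    return events


def fuse_wound_fronts(tissue: Tissue, d_fuse: float) -> list:
    """Fuse pairs of wound-border vertices that have come into contact.

    Opposing wound fronts meet when closure is driven by crawling; two
    border vertices closer than ``d_fuse`` that are not near-neighbours
    along the loop and share no cell are merged at their midpoint, which
    pinches the wound loop in two.  Returns the list of fused pairs.
    """
    from scipy.spatial import cKDTree
    events = []
    for _ in range(10):
        loops = tissue.wound_loops()
        cand = None
        v_cells = tissue.vertex_cells()
        for loop in loops:
            n = len(loop)
            if n < 6:
                continue
            pos_in_loop = {int(v): i for i, v in enumerate(loop)}
            tree = cKDTree(tissue.x[loop])
            pairs = tree.query_pairs(d_fuse)
            best = None
            for (i, j) in pairs:
                hop = abs(i - j)
                hop = min(hop, n - hop)
                if hop < 3:
                    continue
                a, b = int(loop[i]), int(loop[j])
                if set(v_cells.get(a, ())) & set(v_cells.get(b, ())):
                    continue
                d = float(np.linalg.norm(tissue.x[a] - tissue.x[b]))
                if best is None or d < best[0]:
                    best = (d, a, b)
            if best is not None and (cand is None or best[0] < cand[0]):
                cand = best
        if cand is None:
            break
        _, a, b = cand
        tissue.x[a] = 0.5 * (tissue.x[a] + tissue.x[b])
        for ci in v_cells.get(b, []):
            cell = tissue.cells[ci]
            cell = np.where(cell == b, a, cell)
            keep = np.ones(len(cell), dtype=bool)
            for i in range(len(cell)):
                if cell[i] == cell[(i + 1) % len(cell)]:
                    keep[(i + 1) % len(cell)] = False
            tissue.cells[ci] = cell[keep]
        tissue.adh_node[a] = -1
        tissue.adh_node[b] = -1
        tissue.invalidate_topology()
        events.append((a, b))
    return events


def seal_small_loops(tissue: Tissue, A_close: float) -> list:
    """Seal residual wound loops whose area has dropped below the closure
    threshold: all vertices of such a loop are merged into one vertex at the
    loop centroid (the surrounding cells meet in a rosette).  Returns the
    list of sealed loop sizes."""
    events = []
    for _ in range(10):
        progress = False
        for target in tissue.wound_loops():
            area = abs(polygon_area(tissue.x[target])) if len(target) >= 3 else 0.0
            if len(target) >= 3 and area >= A_close:
                continue
            keep = int(target[0])
            rest = {int(v) for v in target[1:]}
            v_cells = tissue.vertex_cells()
            touched = {ci for v in target for ci in v_cells.get(int(v), [])}
            ok = True
            new_cells = {}
            for ci in touched:
                cell = tissue.cells[ci]
                cell = np.where(np.isin(cell, list(rest)), keep, cell)
                kp = np.ones(len(cell), dtype=bool)
                for i in range(len(cell)):
                    if cell[i] == cell[(i + 1) % len(cell)]:
                        kp[(i + 1) % len(cell)] = False
                cell = cell[kp]
                if len(cell) < 3 or len(np.unique(cell)) != len(cell):
                    ok = False   # sealing would pinch this cell; leave loop be
                    break
                new_cells[ci] = cell
            if not ok:
                continue
            tissue.x[keep] = tissue.x[target].mean(axis=0)
            for ci, cell in new_cells.items():
                tissue.cells[ci] = cell
            tissue.adh_node[keep] = -1
            for v in rest:
                tissue.adh_node[v] = -1
            tissue.invalidate_topology()
            events.append(len(target))
            progress = True
            break   # topology changed: re-derive the loops
        if not progress:
            break
    return events


# --------------------------------------------------------------------------
# T1 transitions
# --------------------------------------------------------------------------

def _local_energy(tissue: Tissue, cells_idx, verts, params: ModelParams,
                  substrate) -> float:
    e = 0.0
    for ci in cells_idx:
        pts = tissue.x[tissue.cells[ci]]
        a = polygon_area(pts)
        p = polygon_perimeter(pts)
        e += params.K * (a - params.A0) ** 2 + params.Gamma * (p - params.P0) ** 2
    if substrate is not None:
        for v in verts:
            node = tissue.adh_node[v]
            if node >= 0:
                sep = float(np.linalg.norm(tissue.x[v] - substrate.r[node]))
                e += 0.5 * params.k_f * (sep - tissue.adh_rest[v]) ** 2
    return e


def _replace_with_pair(cell: np.ndarray, old: int, pair) -> np.ndarray:
    i = int(np.where(cell == old)[0][0])
    return np.concatenate([cell[:i], np.asarray(pair, dtype=np.int64), cell[i + 1:]])


def _local_energy_grad(tissue: Tissue, cells_idx, verts, params: ModelParams,
                       substrate):
    """Local energy and its gradient with respect to the positions of
    ``verts`` (analytic)."""
    e = 0.0
    grad = np.zeros((len(verts), 2))
    vpos = {v: i for i, v in enumerate(verts)}
    for ci in cells_idx:
        cell = tissue.cells[ci]
        pts = tissue.x[cell]
        a_ = polygon_area(pts)
        p_ = polygon_perimeter(pts)
        e += params.K * (a_ - params.A0) ** 2 + params.Gamma * (p_ - params.P0) ** 2
        cA = 2.0 * params.K * (a_ - params.A0)
        cP = 2.0 * params.Gamma * (p_ - params.P0)
        n = len(cell)
        for i, v in enumerate(cell):
            j = vpos.get(int(v))
            if j is None:
                continue
            xp = tissue.x[cell[i - 1]]
            xn = tissue.x[cell[(i + 1) % n]]
            xv = tissue.x[v]
            dA = 0.5 * np.array([xn[1] - xp[1], xp[0] - xn[0]])
            ep_ = xv - xp
            en_ = xv - xn
            lp = np.hypot(*ep_)
            ln = np.hypot(*en_)
            dP = (ep_ / lp if lp > 0 else 0.0) + (en_ / ln if ln > 0 else 0.0)
            grad[j] += cA * dA + cP * dP
    if substrate is not None:
        for v in verts:
            node = tissue.adh_node[v]
            if node >= 0:
                sep = tissue.x[v] - substrate.r[node]
                L = float(np.hypot(*sep))
                e += 0.5 * params.k_f * (L - tissue.adh_rest[v]) ** 2
                if L > 0:
                    grad[vpos[v]] += params.k_f * (L - tissue.adh_rest[v]) * sep / L
    return e, grad


def _relax_pair(tissue: Tissue, cells_idx, a: int, b: int,
                params: ModelParams, substrate) -> float:
    """Locally minimise the energy of the affected cells over the positions
    of the junction pair (a, b); returns the minimised energy and leaves
    the optimal positions in place."""
    from scipy.optimize import minimize

    def fun(z):
        tissue.x[a] = z[:2]
        tissue.x[b] = z[2:]
        e, g = _local_energy_grad(tissue, cells_idx, (a, b), params, substrate)
        return e, g.ravel()

    z0 = np.concatenate([tissue.x[a], tissue.x[b]])
    res = minimize(fun, z0, jac=True, method="L-BFGS-B",
                   options={"maxiter": 60, "ftol": 1e-10, "gtol": 1e-6})
    tissue.x[a] = res.x[:2]
    tissue.x[b] = res.x[2:]
    return float(res.fun)


def attempt_t1(tissue: Tissue, edge, params: ModelParams,
               substrate=None, v_cells: dict | None = None) -> bool:
    """Attempt a T1 neighbour exchange on an interior edge below the
    threshold length L*.

    The edge is replaced by a perpendicular contact of the same length about
    the same midpoint, with the four surrounding cells reconnected, and the
    flip is kept only if it strictly lowers the total mechanical energy.
    Boundary edges, non-tri-valent junctions and edges at or above L* are
    never flipped.  Returns True iff the flip was applied.
    """
    a, b = int(edge[0]), int(edge[1])
    key = (a, b) if a < b else (b, a)
    topo = tissue.topology
    corners = topo.edges.get(key)
    if corners is None or len(corners) != 2:
        return False
    L = float(np.linalg.norm(tissue.x[b] - tissue.x[a]))
    if L >= params.L_star or L == 0.0:
        return False
    if v_cells is None:
        v_cells = tissue.vertex_cells()
    cells_a = v_cells.get(a, [])
    cells_b = v_cells.get(b, [])
    if len(cells_a) != 3 or len(cells_b) != 3:
        return False  # the perpendicular-contact rule needs tri-valent junctions
    shared = [ci for ci in cells_a if ci in cells_b]
    if len(shared) != 2:
        return False
    P, Q = shared
    R = [ci for ci in cells_a if ci not in shared][0]
    S = [ci for ci in cells_b if ci not in shared][0]
    if R == S:
        return False

    affected = [P, Q, R, S]
    old_x = {a: tissue.x[a].copy(), b: tissue.x[b].copy()}
    old_cells = {ci: tissue.cells[ci].copy() for ci in affected}
    # both topologies are compared at their locally relaxed junction
    # positions: the flip is kept only if the relaxed flipped state has
    # lower total mechanical energy than the relaxed unflipped state
    e_before = _relax_pair(tissue, affected, a, b, params, substrate)
    tissue.x[a] = old_x[a].copy()
    tissue.x[b] = old_x[b].copy()

    m = 0.5 * (tissue.x[a] + tissue.x[b])
    u = (tissue.x[b] - tissue.x[a]) / L
    nvec = np.array([-u[1], u[0]])

    def try_variant(xa_new, xb_new, order_R):
        tissue.x[a] = xa_new
        tissue.x[b] = xb_new
        for ci in affected:
            tissue.cells[ci] = old_cells[ci].copy()
        # P keeps one vertex of the pair, Q the other
        pa = tissue.cells[P]
        tissue.cells[P] = pa[pa != (b if order_R else a)]
        qa = tissue.cells[Q]
        tissue.cells[Q] = qa[qa != (a if order_R else b)]
        tissue.cells[R] = _replace_with_pair(old_cells[R], a,
                                             (a, b) if order_R else (b, a))
        tissue.cells[S] = _replace_with_pair(old_cells[S], b,
                                             (b, a) if order_R else (a, b))
        for ci in affected:
            pts = tissue.x[tissue.cells[ci]]
            if len(pts) < 3 or polygon_area(pts) <= 0 or not polygon_is_simple(pts):
                return None
        e = _relax_pair(tissue, affected, a, b, params, substrate)
        for ci in affected:   # the relaxed pair must keep the cells valid
            pts = tissue.x[tissue.cells[ci]]
            if polygon_area(pts) <= 0 or not polygon_is_simple(pts):
                return None
        return e

    best = None
    for xa_new, xb_new in ((m + 0.5 * L * nvec, m - 0.5 * L * nvec),
                           (m - 0.5 * L * nvec, m + 0.5 * L * nvec)):
        for order_R in (True, False):
            e_after = try_variant(xa_new, xb_new, order_R)
            if e_after is not None and (best is None or e_after < best[0]):
                best = (e_after, tissue.x[a].copy(), tissue.x[b].copy(), order_R)
            # roll back before next variant
            tissue.x[a] = old_x[a].copy()
            tissue.x[b] = old_x[b].copy()
            for ci in affected:
                tissue.cells[ci] = old_cells[ci].copy()

    if best is None or best[0] >= e_before:  # ties rejected: strict decrease only
        return False
    e_after, xa_new, xb_new, order_R = best
    tissue.x[a] = xa_new
    tissue.x[b] = xb_new
    pa = tissue.cells[P]
    tissue.cells[P] = pa[pa != (b if order_R else a)]
    qa = tissue.cells[Q]
    tissue.cells[Q] = qa[qa != (a if order_R else b)]
    tissue.cells[R] = _replace_with_pair(old_cells[R], a,
                                         (a, b) if order_R else (b, a))
    tissue.cells[S] = _replace_with_pair(old_cells[S], b,
                                         (b, a) if order_R else (a, b))
    tissue.invalidate_topology()
    return True


def scan_t1(tissue: Tissue, params: ModelParams, substrate=None) -> list:
    """Attempt T1 flips on every cell-cell interface shorter than L*.

    Edge refinement subdivides long interfaces, so the "cell edge" of the
    neighbour-exchange rule is the whole junction-to-junction interface (a
    chain of refined segments).  When an interface's total length drops
    below L*, its two-valent chain midpoints are merged away and the
    remaining junction-junction edge is offered to :func:`attempt_t1`.
    Returns the list of flipped edges.
    """
    from collections import Counter, defaultdict
    flipped = []
    guard = 0
    while guard < 20:
        guard += 1
        topo = tissue.topology
        iface: dict = defaultdict(list)
        for key, corners in topo.edges.items():
            if len(corners) == 2:
                c1 = int(topo.corner_cell[corners[0]])
                c2 = int(topo.corner_cell[corners[1]])
                iface[(min(c1, c2), max(c1, c2))].append(key)
        cands = []
        for pair, keys in iface.items():
            L = sum(float(np.linalg.norm(tissue.x[b] - tissue.x[a]))
                    for (a, b) in keys)
            if L < params.L_star:
                cands.append((L, pair, keys))
        cands.sort()
        applied = False
        for L, pair, keys in cands:
            deg = Counter(v for k in keys for v in k)
            ends = [v for v, c in deg.items() if c == 1]
            interior = [v for v, c in deg.items() if c == 2]
            if len(ends) != 2:
                continue
            nb = tissue.vertex_neighbors()
            v_cells = tissue.vertex_cells()
            if any(len(nb.get(v, ())) != 2 for v in interior):
                continue
            if any(len(tissue.cells[ci]) - 1 < 3
                   for v in interior for ci in v_cells.get(v, [])):
                continue
            if interior:
                rem = set(interior)
                touched = {ci for v in interior for ci in v_cells.get(v, [])}
                for ci in touched:
                    cell = tissue.cells[ci]
                    tissue.cells[ci] = cell[~np.isin(cell, list(rem))]
                for v in interior:
                    tissue.adh_node[v] = -1
                tissue.invalidate_topology()
            edge = (int(ends[0]), int(ends[1]))
            if attempt_t1(tissue, edge, params, substrate):
                flipped.append(edge)
                applied = True
                break  # topology changed; rescan
            if interior:
                applied = True   # midpoints merged; rescan the shortened list
                break
        if not applied:
            break
    return flipped
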