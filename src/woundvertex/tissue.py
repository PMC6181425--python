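"""Shared-vertex polygonal cell complex for the vertex model.

Cells are simple counter-clockwise polygons stored as cyclic lists of vertex
indices into one position array.  Interior edges are shared by exactly two
cells; edges on the outer tissue boundary or on the wound border belong to
one cell.  A lazily rebuilt topology cache provides the flat "corner" arrays
used to vectorise geometry and force evaluation, the edge incidence map, and
the boundary loops.  Because cells are oriented counter-clockwise, the outer
boundary loop has positive signed area when traversed through cell corners
while any wound (hole) loop has negative signed area; that sign is how the
two are told apart.

Per-cell state: motility mode (bulk / crawl / purse-string) and the polarity
angle used for bulk self-propulsion.  Per-vertex state: the focal-adhesion
record (substrate node id, anchors at binding time, rest extension), with
sigma_alpha = 1 iff the vertex is bound.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["Tissue", "Topology", "GeometryError", "TopologyError", "cross2",
           "MODE_BULK", "MODE_CRAWL", "MODE_PS", "polygon_area",
           "polygon_perimeter", "polygon_is_simple"]

MODE_BULK = 0
MODE_CRAWL = 1
MODE_PS = 2


class GeometryError(ValueError):
    pass


class TopologyError(ValueError):
    pass


def polygon_area(pts: np.ndarray) -> float:
    """Signed shoelace area of a closed polygon given as (n, 2) points."""
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polygon_perimeter(pts: np.ndarray) -> float:
    d = np.roll(pts, -1, axis=0) - pts
    return float(np.sum(np.hypot(d[:, 0], d[:, 1])))


def cross2(a, b):
    """z-component of the 2D cross product (works on (..., 2) arrays)."""
    return a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]


def _segments_intersect(p1, p2, p3, p4) -> bool:
    """Proper intersection test for open segments p1p2 and p3p4."""
    d1 = cross2(p4 - p3, p1 - p3)
    d2 = cross2(p4 - p3, p2 - p3)
    d3 = cross2(p2 - p1, p3 - p1)
    d4 = cross2(p2 - p1, p4 - p1)
    return ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0))


def polygon_is_simple(pts: np.ndarray) -> bool:
    """True if no two non-adjacent edges properly cross (vectorised O(n^2))."""
    n = len(pts)
    if n < 3:
        return False
    if n == 3:
        return True
    p1 = pts
    p2 = np.roll(pts, -1, axis=0)
    # segment pair (i, j): proper crossing test, broadcast over all pairs
    d1 = cross2(p2[None, :] - p1[None, :], p1[:, None] - p1[None, :])
    d2 = cross2(p2[None, :] - p1[None, :], p2[:, None] - p1[None, :])
    d3 = cross2(p2[:, None] - p1[:, None], p1[None, :] - p1[:, None])
    d4 = cross2(p2[:, None] - p1[:, None], p2[None, :] - p1[:, None])
    crossing = ((d1 > 0) != (d2 > 0)) & ((d3 > 0) != (d4 > 0))
    i = np.arange(n)
    adjacent = (np.abs(i[:, None] - i[None, :]) <= 1) | \
               (np.abs(i[:, None] - i[None, :]) == n - 1)
    return not bool((crossing & ~adjacent).any())


@dataclass
class Topology:
    """Flat corner arrays and edge/boundary structure for a cell list.

    ``corner_*`` arrays are ordered cell by cell, so per-cell reductions use
    ``np.add.reduceat`` at ``cell_ptr[:-1]``.
    """

    corner_cell: np.ndarray   # (nc,) cell index of each corner
    corner_v: np.ndarray      # (nc,) vertex id at each corner
    corner_next: np.ndarray   # (nc,) vertex id following in CCW order
    corner_prev: np.ndarray   # (nc,) vertex id preceding
    cell_ptr: np.ndarray      # (C+1,) offsets into corner arrays
    edges: dict               # (min,max) vertex pair -> list of corner indices
    boundary_loops: list      # list of vertex-id arrays, in traversal order
    outer_loop: int           # index into boundary_loops, -1 if none
    used: np.ndarray          # bool mask over vertex array

    @property
    def wound_loop_ids(self) -> list:
        return [i for i in range(len(self.boundary_loops)) if i != self.outer_loop]


def _build_topology(cells, x: np.ndarray) -> Topology:
    if not cells:
        empty = np.empty(0, dtype=np.int64)
        return Topology(empty, empty, empty, empty, np.zeros(1, dtype=np.int64),
                        {}, [], -1, np.zeros(len(x), dtype=bool))
    lens = np.asarray([len(c) for c in cells], dtype=np.int64)
    cell_ptr = np.concatenate([[0], np.cumsum(lens)])
    corner_v = np.concatenate(cells).astype(np.int64)
    idx = np.arange(cell_ptr[-1])
    nxt_i = idx + 1
    nxt_i[cell_ptr[1:] - 1] = cell_ptr[:-1]
    prv_i = idx - 1
    prv_i[cell_ptr[:-1]] = cell_ptr[1:] - 1
    corner_next = corner_v[nxt_i]
    corner_prev = corner_v[prv_i]
    corner_cell = np.repeat(np.arange(len(cells), dtype=np.int64), lens)

    # group corners by undirected edge
    M = np.int64(len(x) + 1)
    codes = np.minimum(corner_v, corner_next) * M + np.maximum(corner_v, corner_next)
    order = np.argsort(codes, kind="stable")
    sc = codes[order]
    starts = np.flatnonzero(np.r_[True, sc[1:] != sc[:-1]])
    counts = np.diff(np.r_[starts, len(sc)])
    edges: dict = {}
    olist = order.tolist()
    for s, c in zip(starts.tolist(), counts.tolist()):
        code = int(sc[s])
        edges[(code // int(M), code % int(M))] = olist[s:s + c]

    # boundary directed edges: v -> next where the undirected edge has one
    # cell.  A vertex can sit on two loops (a pinch point after wound-front
    # fusion), so loops are traced edge-wise, not vertex-wise.
    out_map: dict = {}
    n_bedges = 0
    for key, corners in edges.items():
        if len(corners) == 1:
            k = corners[0]
            u, v = int(corner_v[k]), int(corner_next[k])
            out_map.setdefault(u, []).append(v)
            n_bedges += 1
    loops = []
    used_edges: set = set()
    for start_u in list(out_map):
        for start_v in out_map[start_u]:
            if (start_u, start_v) in used_edges:
                continue
            loop = [start_u]
            used_edges.add((start_u, start_v))
            u, v = start_u, start_v
            guard = 0
            while v != start_u and guard <= n_bedges:
                guard += 1
                loop.append(v)
                nxts = [w for w in out_map.get(v, []) if (v, w) not in used_edges]
                if not nxts:
                    break  # open chain: malformed boundary, keep partial loop
                w = nxts[0]
                used_edges.add((v, w))
                u, v = v, w
            loops.append(np.asarray(loop, dtype=np.int64))

    outer = -1
    best = 0.0
    for i, loop in enumerate(loops):
        a = polygon_area(x[loop])
        if a > best:
            best, outer = a, i

    used = np.zeros(len(x), dtype=bool)
    used[corner_v] = True
    return Topology(corner_cell, corner_v, corner_next, corner_prev, cell_ptr,
                    edges, loops, outer, used)


class Tissue:
    """Vertex-model tissue: positions, cells, modes, polarity, adhesion state."""

    def __init__(self, x, cells, mode=None, theta=None):
        self.x = np.asarray(x, dtype=float).copy()
        self.cells = [np.asarray(c, dtype=np.int64).copy() for c in cells]
        n_cells = len(self.cells)
        self.mode = (np.zeros(n_cells, dtype=np.int8) if mode is None
                     else np.asarray(mode, dtype=np.int8).copy())
        self.theta = (np.zeros(n_cells, dtype=float) if theta is None
                      else np.asarray(theta, dtype=float).copy())
        n = len(self.x)
        self.adh_node = np.full(n, -1, dtype=np.int64)   # substrate node id, -1 unbound
        self.adh_rest = np.zeros(n, dtype=float)          # |x0 - r0| at binding
        self.adh_x0 = np.zeros((n, 2), dtype=float)       # vertex anchor at binding
        self.adh_r0 = np.zeros((n, 2), dtype=float)       # node anchor at binding
        self.prot_anchor = np.full((n, 2), np.nan)        # detach point: protrusion reach origin
        self._topo: Topology | None = None

    # --- topology cache -------------------------------------------------
    @property
    def topology(self) -> Topology:
        if self._topo is None:
            self._topo = _build_topology(self.cells, self.x)
        return self._topo

    def invalidate_topology(self) -> None:
        self._topo = None

    def add_vertex(self, pos) -> int:
        """Append a vertex (unbound); returns its id."""
        return int(self.add_vertices(np.asarray(pos, dtype=float)[None, :])[0])

    def add_vertices(self, pos: np.ndarray) -> np.ndarray:
        """Append a batch of vertices (unbound); returns their ids."""
        k = len(pos)
        n0 = len(self.x)
        self.x = np.vstack([self.x, np.asarray(pos, dtype=float)])
        self.adh_node = np.append(self.adh_node, np.full(k, -1, dtype=np.int64))
        self.adh_rest = np.append(self.adh_rest, np.zeros(k))
        self.adh_x0 = np.vstack([self.adh_x0, np.zeros((k, 2))])
        self.adh_r0 = np.vstack([self.adh_r0, np.zeros((k, 2))])
        self.prot_anchor = np.vstack([self.prot_anchor, np.asarray(pos, dtype=float)])
        self._topo = None
        return np.arange(n0, n0 + k, dtype=np.int64)

    def compact(self) -> np.ndarray:
        """Drop vertices no longer referenced by any cell, remapping ids.
        Returns the old ids of the kept vertices."""
        used = np.where(self.topology.used)[0]
        newid = np.full(len(self.x), -1, dtype=np.int64)
        newid[used] = np.arange(len(used))
        self.x = self.x[used].copy()
        self.adh_node = self.adh_node[used].copy()
        self.adh_rest = self.adh_rest[used].copy()
        self.adh_x0 = self.adh_x0[used].copy()
        self.adh_r0 = self.adh_r0[used].copy()
        self.prot_anchor = self.prot_anchor[used].copy()
        self.cells = [newid[c] for c in self.cells]
        self._topo = None
        return used

    def edge_array(self) -> np.ndarray:
        """(E, 2) array of undirected edges (cached per topology)."""
        topo = self.topology
        cached = getattr(topo, "_ea", None)
        if cached is None:
            if len(topo.corner_v) == 0:
                cached = np.empty((0, 2), dtype=np.int64)
            else:
                a = np.minimum(topo.corner_v, topo.corner_next)
                b = np.maximum(topo.corner_v, topo.corner_next)
                code = np.unique(a * np.int64(len(self.x) + 1) + b)
                cached = np.column_stack([code // (len(self.x) + 1),
                                          code % (len(self.x) + 1)])
            topo._ea = cached
        return cached

    def vertex_neighbors(self) -> dict:
        """Vertex id -> set of neighbouring vertex ids (cached per topology)."""
        topo = self.topology
        cached = getattr(topo, "_vn", None)
        if cached is None:
            cached = {}
            for (a, b) in topo.edges:
                cached.setdefault(a, set()).add(b)
                cached.setdefault(b, set()).add(a)
            topo._vn = cached
        return cached

    # --- geometry -------------------------------------------------------
    def areas(self) -> np.ndarray:
        t = self.topology
        xv = self.x[t.corner_v]
        xn = self.x[t.corner_next]
        cross = xv[:, 0] * xn[:, 1] - xn[:, 0] * xv[:, 1]
        return 0.5 * np.add.reduceat(cross, t.cell_ptr[:-1])

    def perimeters(self) -> np.ndarray:
        t = self.topology
        d = self.x[t.corner_next] - self.x[t.corner_v]
        return np.add.reduceat(np.hypot(d[:, 0], d[:, 1]), t.cell_ptr[:-1])

    def centroids(self) -> np.ndarray:
        """Area-weighted polygon centroids, (C, 2)."""
        t = self.topology
        xv = self.x[t.corner_v]
        xn = self.x[t.corner_next]
        cross = xv[:, 0] * xn[:, 1] - xn[:, 0] * xv[:, 1]
        cx = np.add.reduceat((xv[:, 0] + xn[:, 0]) * cross, t.cell_ptr[:-1])
        cy = np.add.reduceat((xv[:, 1] + xn[:, 1]) * cross, t.cell_ptr[:-1])
        a = 0.5 * np.add.reduceat(cross, t.cell_ptr[:-1])
        return np.column_stack([cx, cy]) / (6.0 * a[:, None])

    @property
    def sigma(self) -> np.ndarray:
        """Per-vertex adhesion state sigma_alpha in {0, 1}."""
        return (self.adh_node >= 0).astype(np.int8)

    # --- wound border ---------------------------------------------------
    def wound_loops(self) -> list:
        """Vertex-id loops of wound borders (holes), in traversal order."""
        t = self.topology
        return [t.boundary_loops[i] for i in t.wound_loop_ids]

    def wound_loop(self) -> np.ndarray | None:
        """The single wound-border loop, or None if the wound has closed."""
        loops = self.wound_loops()
        if not loops:
            return None
        if len(loops) == 1:
            return loops[0]
        return max(loops, key=lambda lp: abs(polygon_area(self.x[lp])))

    def wound_area(self) -> float:
        """Total open wound area: sum over wound loops (a crawling front
        that has fused across the gap leaves several loops).

        Hole loops are traversed clockwise through CCW cells, so an open
        gap has negative signed area; a positively-oriented "loop" marks a
        region where neighbouring fronts overlap (double-covered tissue,
        not open wound) and contributes zero."""
        total = 0.0
        for loop in self.wound_loops():
            if len(loop) >= 3:
                total += max(0.0, -polygon_area(self.x[loop]))
        return total

    def wound_border_vertices(self) -> np.ndarray:
        loops = self.wound_loops()
        if not loops:
            return np.empty(0, dtype=np.int64)
        return np.unique(np.concatenate(loops))

    def wound_border_edges(self) -> set:
        """Undirected (min,max) vertex pairs along all wound-border loops
        (cached per topology rebuild)."""
        topo = self.topology
        cached = getattr(topo, "_wbe", None)
        if cached is not None:
            return cached
        out = set()
        for loop in self.wound_loops():
            for i in range(len(loop)):
                a, b = int(loop[i]), int(loop[(i + 1) % len(loop)])
                out.add((a, b) if a < b else (b, a))
        topo._wbe = out
        return out

    def vertex_cells(self) -> dict:
        """Vertex id -> list of incident cell indices (cached per topology)."""
        topo = self.topology
        cached = getattr(topo, "_vc", None)
        if cached is not None:
            return cached
        vc: dict = {}
        for ci, cell in enumerate(self.cells):
            for v in cell.tolist():
                vc.setdefault(v, []).append(ci)
        topo._vc = vc
        return vc

    def border_cells(self) -> np.ndarray:
        """Indices of cells owning at least one wound-border edge."""
        t = self.topology
        be = self.wound_border_edges()
        cells = {int(t.corner_cell[t.edges[e][0]]) for e in be if e in t.edges}
        return np.asarray(sorted(cells), dtype=np.int64)

    def cell_border_run(self, ci: int) -> np.ndarray | None:
        """Contiguous run of wound-border vertices of cell ci, in the cell's
        CCW order.  Returns None if the cell has no wound-border edge; if the
        cell has several disjoint runs the longest is returned."""
        t = self.topology
        be = self.wound_border_edges()
        cell = self.cells[ci]
        n = len(cell)
        flags = np.zeros(n, dtype=bool)   # edge i: cell[i] -> cell[i+1]
        for i in range(n):
            a, b = int(cell[i]), int(cell[(i + 1) % n])
            key = (a, b) if a < b else (b, a)
            if key in be:
                flags[i] = True
        if not flags.any():
            return None
        if flags.all():
            return np.append(cell, cell[0])
        # find maximal runs of consecutive border edges (cyclic)
        runs = []
        i = 0
        while i < n:
            if flags[i] and not flags[i - 1]:
                j = i
                length = 0
                while flags[j % n]:
                    length += 1
                    j += 1
                runs.append((i, length))
            i += 1
        start, length = max(runs, key=lambda r: r[1])
        idx = [(start + k) % n for k in range(length + 1)]
        return cell[idx]

    # --- validation -----------------------------------------------------
    def validate(self, require_wound_loop: bool = False) -> None:
        """Check mesh invariants; raises GeometryError / TopologyError."""
        t = self.topology
        areas = self.areas()
        for ci, cell in enumerate(self.cells):
            if len(cell) < 3:
                raise GeometryError(f"cell {ci} has fewer than 3 vertices")
            if areas[ci] <= 0:
                raise GeometryError(f"cell {ci} has non-positive area {areas[ci]:.3g}")
            if not polygon_is_simple(self.x[cell]):
                raise GeometryError(f"cell {ci} is self-intersecting")
        for key, corners in t.edges.items():
            if len(corners) > 2:
                raise TopologyError(f"edge {key} shared by {len(corners)} cells")
        if require_wound_loop and not self.wound_loops():
            raise TopologyError("no wound-border loop present")

    # --- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "x": self.x.tolist(),
            "cells": [c.tolist() for c in self.cells],
            "mode": self.mode.tolist(),
            "theta": self.theta.tolist(),
            "adh_node": self.adh_node.tolist(),
            "adh_rest": self.adh_rest.tolist(),
            "adh_x0": self.adh_x0.tolist(),
            "adh_r0": self.adh_r0.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Tissue":
        t = cls(np.asarray(d["x"]), d["cells"],
                mode=np.asarray(d["mode"]), theta=np.asarray(d["theta"]))
        t.adh_node = np.asarray(d["adh_node"], dtype=np.int64)
        t.adh_rest = np.asarray(d["adh_rest"], dtype=float)
        t.adh_x0 = np.asarray(d["adh_x0"], dtype=float)
        t.adh_r0 = np.asarray(d["adh_r0"], dtype=float)
        return t

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load_json(cls, path) -> "Tissue":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def copy(self) -> "Tissue":
        t = Tissue(self.x, self.cells, self.mode, self.theta)
        t.adh_node = self.adh_node.copy()
        t.adh_rest = self.adh_rest.copy()
        t.adh_x0 = self.adh_x0.copy()
        t.adh_r0 = self.adh_r0.copy()
        t.prot_anchor = self.prot_anchor.copy()
        return t
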