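"""Initial-condition generation: tissues, wounds, pre-closure relaxation.

Tissues are built as Voronoi tessellations of seed points — a triangular
lattice of seeds yields a honeycomb of regular hexagons; random seeds with
Lloyd (centroidal) relaxation yield a disordered but even monolayer with
mean cell area ~ A0.  A wound is created by removing every cell that lies
totally or partially within the wound region, projecting the resulting
border vertices onto the target wound outline, relaxing the remaining cells
to an energy minimum with the border constrained to the outline, and setting
the border cells to crawl mode.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import Voronoi
import shapely
from shapely.geometry import Point, Polygon as ShapelyPolygon

from .params import ModelParams, ConfigurationError
from .tissue import Tissue, MODE_BULK, MODE_CRAWL, polygon_area
from .mechanics import elastic_forces, tissue_mech_energy

__all__ = ["WoundSpec", "generate_tissue", "make_wound", "relax_tissue",
           "relax_wounded_tissue", "initial_state"]


# --------------------------------------------------------------------------
# wound shapes
# --------------------------------------------------------------------------

@dataclass
class WoundSpec:
    """Target wound outline: circle, ellipse (fixed area, varying aspect), or
    a concave multi-lobed family R(phi) = R0 (1 + depth cos(m phi)) with R0
    chosen to fix the enclosed area."""

    shape: str = "circle"          # circle | ellipse | concave
    radius: float = 15.0           # um (circle)
    area: float | None = None      # um^2 (ellipse/concave; default pi*radius^2)
    aspect: float = 1.0            # ellipse major/minor axis ratio
    lobes: int = 3                 # concave lobe count m
    depth: float = 0.0             # concave lobe depth in [0, 0.6]
    center: tuple = (0.0, 0.0)

    def __post_init__(self):
        if self.shape not in ("circle", "ellipse", "concave"):
            raise ConfigurationError(f"unknown wound shape {self.shape!r}")
        if self.area is None:
            self.area = math.pi * self.radius ** 2
        if self.area < 0:
            raise ConfigurationError("wound area must be nonnegative")
        if self.aspect < 1.0:
            raise ConfigurationError("aspect ratio must be >= 1")
        if not 0.0 <= self.depth <= 0.6:
            raise ConfigurationError("concave lobe depth must be in [0, 0.6]")

    def boundary_points(self, n: int = 256) -> np.ndarray:
        """CCW sample of the wound outline, (n, 2)."""
        phi = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
        cx, cy = self.center
        if self.shape == "circle":
            r = math.sqrt(self.area / math.pi)
            return np.column_stack([cx + r * np.cos(phi), cy + r * np.sin(phi)])
        if self.shape == "ellipse":
            b = math.sqrt(self.area / (math.pi * self.aspect))
            a = self.aspect * b
            return np.column_stack([cx + a * np.cos(phi), cy + b * np.sin(phi)])
        if self.shape == "concave":
            r0 = math.sqrt(self.area / (math.pi * (1.0 + 0.5 * self.depth ** 2)))
            r = r0 * (1.0 + self.depth * np.cos(self.lobes * phi))
            return np.column_stack([cx + r * np.cos(phi), cy + r * np.sin(phi)])
        raise ConfigurationError(f"unknown wound shape {self.shape!r}")

    def polygon(self, n: int = 256) -> ShapelyPolygon:
        return ShapelyPolygon(self.boundary_points(n))

    @classmethod
    def from_dict(cls, d: dict) -> "WoundSpec":
        valid = {"shape", "radius", "area", "aspect", "lobes", "depth", "center"}
        unknown = set(d) - valid
        if unknown:
            raise ConfigurationError(f"unknown wound keys {sorted(unknown)}")
        d = dict(d)
        if "center" in d:
            d["center"] = tuple(d["center"])
        return cls(**d)


# --------------------------------------------------------------------------
# tissue generation
# --------------------------------------------------------------------------

def _cells_from_voronoi(seeds: np.ndarray, n_cells: int) -> Tissue:
    """Extract the ``n_cells`` Voronoi cells nearest the seed centroid as a
    shared-vertex tissue."""
    vor = Voronoi(seeds)
    center = seeds.mean(axis=0)
    order = np.argsort(np.linalg.norm(seeds - center, axis=1))
    chosen = []
    for i in order:
        region = vor.regions[vor.point_region[i]]
        if not region or -1 in region:
            continue
        chosen.append((i, region))
        if len(chosen) == n_cells:
            break
    if len(chosen) < n_cells:
        raise ConfigurationError("not enough interior Voronoi cells; add seeds")

    # merge near-duplicate Voronoi vertices, remap to compact ids
    coord_key: dict = {}
    remap: dict = {}
    pts: list = []
    for _, region in chosen:
        for vi in region:
            if vi in remap:
                continue
            key = (round(vor.vertices[vi][0], 6), round(vor.vertices[vi][1], 6))
            if key in coord_key:
                remap[vi] = coord_key[key]
            else:
                coord_key[key] = len(pts)
                remap[vi] = len(pts)
                pts.append(vor.vertices[vi])
    cells = []
    for i, region in chosen:
        ids = sorted({remap[vi] for vi in region})
        pts_arr = np.asarray([pts[j] for j in ids])
        ang = np.arctan2(pts_arr[:, 1] - seeds[i, 1], pts_arr[:, 0] - seeds[i, 0])
        cells.append(np.asarray(ids, dtype=np.int64)[np.argsort(ang)])
    tissue = Tissue(np.asarray(pts), cells)
    tissue.x -= tissue.centroids().mean(axis=0)  # recentre on the origin
    tissue.invalidate_topology()
    return tissue


def generate_tissue(n_cells: int, A0: float = 100.0,
                    rng: np.random.Generator | int | None = None,
                    kind: str = "voronoi", lloyd_iters: int = 5) -> Tissue:
    """Build an unwounded tissue of ~``n_cells`` cells with mean area ~ A0.

    ``kind='honeycomb'`` puts seeds on a triangular lattice (regular
    hexagonal cells, shape index ~3.722); ``kind='voronoi'`` draws random
    seeds and applies Lloyd relaxation, which monotonically evens out cell
    areas.  Identical seeds give identical tissues.
    """
    if n_cells < 7:
        raise ConfigurationError("need at least 7 cells to surround a wound")
    rng = np.random.default_rng(rng)
    n_total = int(math.ceil(n_cells * 2.2)) + 12
    if kind == "honeycomb":
        s = math.sqrt(2.0 * A0 / math.sqrt(3.0))
        R = math.sqrt(n_total * A0 / math.pi) + 2 * s
        dy = s * math.sqrt(3.0) / 2.0
        rows = int(R / dy) + 1
        cols = int(R / s) + 1
        seeds = []
        for j in range(-rows, rows + 1):
            for i in range(-cols, cols + 1):
                xx = i * s + (0.5 * s if j % 2 else 0.0)
                yy = j * dy
                if xx * xx + yy * yy <= R * R:
                    seeds.append((xx, yy))
        seeds = np.asarray(seeds)
    elif kind == "voronoi":
        R = math.sqrt(n_total * A0 / math.pi)
        rr = R * np.sqrt(rng.random(n_total))
        th = 2.0 * math.pi * rng.random(n_total)
        seeds = np.column_stack([rr * np.cos(th), rr * np.sin(th)])
        for _ in range(lloyd_iters):
            vor = Voronoi(seeds)
            new = seeds.copy()
            for i in range(len(seeds)):
                region = vor.regions[vor.point_region[i]]
                if not region or -1 in region:
                    continue
                poly = vor.vertices[region]
                if np.max(np.linalg.norm(poly, axis=1)) > 1.6 * R:
                    continue
                a = polygon_area(poly)
                if abs(a) < 1e-12:
                    continue
                new[i] = ShapelyPolygon(poly).centroid.coords[0]
            seeds = new
    else:
        raise ConfigurationError(f"unknown tissue kind {kind!r}")
    tissue = _cells_from_voronoi(seeds, n_cells)
    if tissue.areas().min() <= 0:  # fix any clockwise region ordering
        for ci, cell in enumerate(tissue.cells):
            if polygon_area(tissue.x[cell]) < 0:
                tissue.cells[ci] = cell[::-1].copy()
        tissue.invalidate_topology()
    tissue.validate()
    return tissue


# --------------------------------------------------------------------------
# relaxation
# --------------------------------------------------------------------------

def relax_tissue(tissue: Tissue, params: ModelParams, fixed=None,
                 gtol: float = 1e-3, maxiter: int = 2000) -> float:
    """Minimise the passive cell energies over vertex positions (in place);
    ``fixed`` vertex ids are held.  Returns the final energy."""
    used = np.where(tissue.topology.used)[0]
    fixed = set() if fixed is None else set(int(v) for v in fixed)
    free = np.asarray([v for v in used if v not in fixed], dtype=np.int64)
    if len(free) == 0:
        return tissue_mech_energy(tissue, params)

    def fun(z):
        tissue.x[free] = z.reshape(-1, 2)
        A = tissue.areas()
        P = tissue.perimeters()
        e = float(np.sum(params.K * (A - params.A0) ** 2
                         + params.Gamma * (P - params.P0) ** 2))
        g = -elastic_forces(tissue, params)[free]
        return e, g.ravel()

    res = minimize(fun, tissue.x[free].ravel(), jac=True, method="L-BFGS-B",
                   options={"maxiter": maxiter, "ftol": 1e-12, "gtol": gtol})
    tissue.x[free] = res.x.reshape(-1, 2)
    return float(res.fun)


def relax_wounded_tissue(tissue: Tissue, params: ModelParams,
                         spec: WoundSpec, rounds: int = 4,
                         gtol: float = 1e-3) -> float:
    """Relax a freshly wounded tissue to an energy minimum with all
    wound-border vertices constrained to the target wound outline.

    Alternates L-BFGS minimisation of the unconstrained vertices with
    projected-gradient sliding of the border vertices along the outline.
    Never increases the energy; on return the unconstrained force norms are
    below ``gtol`` (nN).  Returns the final energy.
    """
    ring = shapely.LineString(np.vstack([spec.boundary_points(512),
                                         spec.boundary_points(512)[:1]]))

    def project(pts):
        out = np.empty_like(pts)
        for i, p in enumerate(pts):
            q = ring.interpolate(ring.project(Point(p)))
            out[i] = (q.x, q.y)
        return out

    e = tissue_mech_energy(tissue, params)
    for _ in range(rounds):
        border = tissue.wound_border_vertices()
        tissue.x[border] = project(tissue.x[border])
        e = relax_tissue(tissue, params, fixed=border, gtol=gtol)
        # slide border vertices along the outline down the energy gradient
        eta = 2e-3  # um^2 / nN; backtracked below
        for _ in range(25):
            border = tissue.wound_border_vertices()
            F = elastic_forces(tissue, params)[border]
            old = tissue.x[border].copy()
            tissue.x[border] = project(old + eta * F)
            e_new = tissue_mech_energy(tissue, params)
            if e_new <= e:
                e = e_new
            else:
                tissue.x[border] = old
                eta *= 0.5
                if eta < 1e-6:
                    break
    border = tissue.wound_border_vertices()
    tissue.x[border] = project(tissue.x[border])
    e = relax_tissue(tissue, params, fixed=border, gtol=gtol)
    return e


# --------------------------------------------------------------------------
# wounding
# --------------------------------------------------------------------------

def make_wound(tissue: Tissue, spec: WoundSpec) -> Tissue:
    """Remove every cell lying totally or partially within the wound region,
    project the border vertices onto the target outline, and set the border
    cells to crawl mode.  Returns a new tissue; raises if the wound touches
    the outer tissue boundary."""
    if spec.area == 0:
        return tissue.copy()
    wound = spec.polygon()
    topo = tissue.topology
    if topo.outer_loop < 0:
        raise ConfigurationError("tissue has no outer boundary")
    outer = ShapelyPolygon(tissue.x[topo.boundary_loops[topo.outer_loop]])
    if not outer.buffer(-1e-6).contains(wound):
        raise ConfigurationError("wound region must lie strictly inside the tissue")

    keep = []
    for ci, cell in enumerate(tissue.cells):
        poly = ShapelyPolygon(tissue.x[cell])
        if poly.intersection(wound).area > 1e-9:
            continue
        keep.append(ci)
    if len(keep) == len(tissue.cells):
        out = tissue.copy()
        out.mode[:] = MODE_BULK
        return out
    if len(keep) < 3:
        raise ConfigurationError("wound removes nearly the whole tissue")

    out = Tissue(tissue.x, [tissue.cells[ci] for ci in keep],
                 mode=tissue.mode[keep], theta=tissue.theta[keep])
    loops = out.wound_loops()
    if not loops:
        raise ConfigurationError("wound removal produced no border loop")
    ring = shapely.LineString(np.vstack([spec.boundary_points(512),
                                         spec.boundary_points(512)[:1]]))
    for loop in loops:
        for v in loop:
            q = ring.interpolate(ring.project(Point(out.x[v])))
            out.x[v] = (q.x, q.y)
    out.invalidate_topology()
    out.mode[:] = MODE_BULK
    for ci in out.border_cells():
        out.mode[ci] = MODE_CRAWL
    return out


# --------------------------------------------------------------------------
# full pipeline
# --------------------------------------------------------------------------

def initial_state(params: ModelParams, seed: int | None = 0,
                  wound: WoundSpec | None = None, kind: str = "voronoi",
                  with_substrate: bool = True):
    """Generate -> relax -> wound -> constrained-relax -> substrate.

    Returns ``(tissue, substrate)``; ``substrate`` is None when
    ``with_substrate`` is False.
    """
    from .substrate import build_substrate
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    if wound is None:
        wound = WoundSpec(shape="circle" if params.wound_aspect == 1.0 else "ellipse",
                          radius=params.wound_radius,
                          aspect=params.wound_aspect)
    tissue = generate_tissue(params.n_cells, params.A0, rng, kind=kind)
    relax_tissue(tissue, params)
    from .mechanics import refine_edges
    refine_edges(tissue, params=params)
    tissue = make_wound(tissue, wound)
    relax_wounded_tissue(tissue, params, wound)
    # random initial polarity for bulk cells
    tissue.theta[:] = rng.uniform(-math.pi, math.pi, size=len(tissue.cells))
    sub = None
    if with_substrate:
        used = tissue.topology.used
        pts = tissue.x[used]
        extent = (pts[:, 0].min(), pts[:, 0].max(), pts[:, 1].min(), pts[:, 1].max())
        sub = build_substrate(extent, params=params)
    return tissue, sub
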