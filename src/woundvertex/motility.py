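"""Active cell motility: bulk self-propulsion, wound-edge crawling,
purse-string contractility, and motility-mode switching.

Bulk cells carry a unit polarity vector at angle theta_i undergoing
rotational diffusion (variance 2 D_r dt per step); the self-propulsion force
on a vertex is the average of mu v0 p_hat over its adjacent bulk cells.
Wound-border cells either crawl — a protrusion force f_p on their unbound
border vertices, directed along the bisector of the centroid-to-border-run-
endpoint rays ("contact inhibition of locomotion": the cell protrudes into
the free gap, not into its neighbours) — or carry a purse-string: an extra
line tension gamma_ps on their wound-border edges, modelling the
supracellular actomyosin cable.  Crawl cells convert to purse-string either
stochastically at rate k_p (irreversibly) or, in the curvature-sensing
variant, whenever the local border curvature exceeds a threshold.
"""

from __future__ import annotations

import numpy as np

from .params import ModelParams
from .tissue import Tissue, MODE_BULK, MODE_CRAWL, MODE_PS

__all__ = ["update_polarity", "self_propulsion_forces", "crawl_direction",
           "crawl_directions", "crawl_forces", "purse_string_forces",
           "switch_modes_stochastic", "switch_modes_curvature",
           "edge_curvature", "polarity_vectors"]


# --------------------------------------------------------------------------
# polarity and bulk self-propulsion
# --------------------------------------------------------------------------

def update_polarity(theta: np.ndarray, dt: float, D_r: float,
                    rng: np.random.Generator) -> np.ndarray:
    """One Euler step of rotational diffusion: theta += N(0, 2 D_r dt),
    wrapped to (-pi, pi]."""
    theta = np.asarray(theta, dtype=float)
    if D_r > 0:
        theta = theta + rng.normal(0.0, np.sqrt(2.0 * D_r * dt), size=theta.shape)
    return -np.mod(-theta + np.pi, 2.0 * np.pi) + np.pi


def polarity_vectors(theta: np.ndarray) -> np.ndarray:
    return np.column_stack([np.cos(theta), np.sin(theta)])


def self_propulsion_forces(tissue: Tissue, params: ModelParams) -> np.ndarray:
    """Averaged self-propulsion force per vertex (nN):
    (1/n_alpha) sum over adjacent *bulk* cells of mu v0 p_hat_i."""
    topo = tissue.topology
    n = len(tissue.x)
    F = np.zeros((n, 2))
    bulk_corner = tissue.mode[topo.corner_cell] == MODE_BULK
    if not bulk_corner.any() or params.v0 == 0:
        return F
    p = polarity_vectors(tissue.theta)[topo.corner_cell[bulk_corner]]
    verts = topo.corner_v[bulk_corner]
    fx = np.bincount(verts, weights=p[:, 0], minlength=n)
    fy = np.bincount(verts, weights=p[:, 1], minlength=n)
    counts = np.bincount(verts, minlength=n).astype(float)
    counts[counts == 0] = 1.0
    F[:, 0] = params.mu * params.v0 * fx / counts
    F[:, 1] = params.mu * params.v0 * fy / counts
    return F


# --------------------------------------------------------------------------
# crawling
# --------------------------------------------------------------------------

def crawl_direction(tissue: Tissue, ci: int,
                    centroid: np.ndarray | None = None) -> np.ndarray | None:
    """Unit protrusion direction of wound-border cell ci: the bisector of
    the angle subtended at the cell centroid by the two end vertices of the
    cell's contiguous wound-border run, oriented into the wound."""
    run = tissue.cell_border_run(ci)
    if run is None:
        return None
    c = tissue.centroids()[ci] if centroid is None else centroid
    e1, e2 = tissue.x[run[0]], tissue.x[run[-1]]
    mid = tissue.x[run].mean(axis=0)
    v1, v2 = e1 - c, e2 - c
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        v = mid - c
    else:
        v = v1 / n1 + v2 / n2
        if np.linalg.norm(v) < 1e-9:   # endpoints opposite: fall back to run midpoint
            v = mid - c
    nv = np.linalg.norm(v)
    if nv == 0:
        return None
    v = v / nv
    if np.dot(v, mid - c) < 0:
        v = -v
    return v


def crawl_directions(tissue: Tissue) -> dict:
    """Map wound-border vertex id -> unit crawl direction, averaged over the
    crawl-mode cells whose border run contains the vertex."""
    acc: dict = {}
    border = tissue.border_cells()
    if len(border) == 0:
        return {}
    cents = tissue.centroids()
    for ci in border:
        if tissue.mode[ci] != MODE_CRAWL:
            continue
        v = crawl_direction(tissue, int(ci), centroid=cents[ci])
        if v is None:
            continue
        run = tissue.cell_border_run(int(ci))
        for vid in run:
            acc.setdefault(int(vid), []).append(v)
    out = {}
    for vid, vecs in acc.items():
        s = np.sum(vecs, axis=0)
        ns = np.linalg.norm(s)
        if ns > 0:
            out[vid] = s / ns
    return out


def crawl_forces(tissue: Tissue, params: ModelParams,
                 dirs: dict | None = None) -> np.ndarray:
    """Protrusion force f_p (1 - sigma_alpha) v_hat on wound-border vertices
    of crawl-mode cells; bound vertices (sigma = 1) feel no protrusion.

    The lamellipodium has finite reach: attachment occurs by protruding into
    the nearest substrate node, so the force acts only until the vertex has
    advanced one node spacing (``protrusion_delta``) beyond the point where
    it detached; it then stalls until it rebinds.  A vertex with no recorded
    detach point (e.g. freshly created) starts its protrusion here.
    """
    F = np.zeros_like(tissue.x)
    if dirs is None:
        dirs = crawl_directions(tissue)
    sigma = tissue.sigma
    reach = params.protrusion_delta
    for vid, v in dirs.items():
        if sigma[vid] != 0:
            continue
        anchor = tissue.prot_anchor[vid]
        if np.isnan(anchor[0]):
            tissue.prot_anchor[vid] = anchor = tissue.x[vid]
        if float(np.dot(tissue.x[vid] - anchor, v)) < reach:
            F[vid] += params.f_p * v
    return F


# --------------------------------------------------------------------------
# purse-string
# --------------------------------------------------------------------------

def purse_string_forces(tissue: Tissue, params: ModelParams) -> np.ndarray:
    """Force from the extra line tension gamma_ps on wound-border edges of
    purse-string cells: gamma_ps times the sum of unit vectors along the
    adjacent cable edges, pointing away from each vertex."""
    from .mechanics import purse_string_edges
    F = np.zeros_like(tissue.x)
    for (u, v) in purse_string_edges(tissue):
        d = tissue.x[v] - tissue.x[u]
        L = np.hypot(d[0], d[1])
        if L == 0:
            continue
        d = d / L
        F[u] += params.gamma_ps * d
        F[v] -= params.gamma_ps * d
    return F


# --------------------------------------------------------------------------
# mode switching
# --------------------------------------------------------------------------

def switch_modes_stochastic(tissue: Tissue, params: ModelParams,
                            rng: np.random.Generator, t: float = 0.0) -> list:
    """Crawl-mode wound-border cells switch to purse-string with probability
    min(1, k_p dt); switching is irreversible.  Returns switch events."""
    events = []
    p = min(params.k_p * params.dt, 1.0)
    if p == 0:
        return events
    for ci in tissue.border_cells():
        if tissue.mode[ci] == MODE_CRAWL and rng.random() < p:
            tissue.mode[ci] = MODE_PS
            events.append({"kind": "mode_switch", "t": t, "cell": int(ci)})
    return events


def edge_curvature(tissue: Tissue, ci: int) -> float | None:
    """Signed curvature (um^-1) of cell ci's wound-border run: the inverse
    circumradius of the run's two end vertices and middle vertex, positive
    where the wound is convex (e.g. a shrinking circle), negative where it
    is concave.  Collinear points give zero; returns None if the cell has no
    border run."""
    run = tissue.cell_border_run(ci)
    if run is None:
        return None
    p1 = tissue.x[run[0]]
    p3 = tissue.x[run[-1]]
    p2 = tissue.x[run[len(run) // 2]] if len(run) > 2 else 0.5 * (p1 + p3)
    d1, d2 = p2 - p1, p3 - p2
    cross = d1[0] * d2[1] - d1[1] * d2[0]
    if abs(cross) < 1e-12:
        return 0.0
    # circumradius from |p1p2||p2p3||p1p3| / (2 |cross|)
    a = np.linalg.norm(d1)
    b = np.linalg.norm(d2)
    c = np.linalg.norm(p3 - p1)
    R = a * b * c / (2.0 * abs(cross))
    if R == 0:
        return 0.0
    # border loops (holes) are traversed clockwise; a convex wound makes the
    # run turn clockwise as well, i.e. negative cross product in cell order,
    # but runs are listed in the owning cell's CCW order which traverses the
    # hole loop: convex wound -> cross < 0 along the run
    return (1.0 if cross < 0 else -1.0) / R


def switch_modes_curvature(tissue: Tissue, params: ModelParams,
                           t: float = 0.0) -> list:
    """Curvature-gated (reversible) mode assignment: border cells whose local
    wound curvature exceeds kappa* contract by purse-string, the rest crawl."""
    events = []
    for ci in tissue.border_cells():
        if tissue.mode[ci] == MODE_BULK:
            continue
        kappa = edge_curvature(tissue, int(ci))
        if kappa is None:
            continue
        new = MODE_PS if kappa > params.kappa_star else MODE_CRAWL
        if new != tissue.mode[ci]:
            tissue.mode[ci] = new
            events.append({"kind": "mode_switch", "t": t, "cell": int(ci)})
    return events
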