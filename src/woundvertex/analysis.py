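"""Post-processing: traction reconstruction and collective-motion metrics.

Traction stresses are reconstructed the way traction-force microscopy on a
continuum gel would do it: substrate node displacements are interpolated to
a square grid, strains are taken by finite differences,
eps_kl = (d_k u_l + d_l u_k)/2, and the stress follows the isotropic linear
law for a thin sheet (plane stress) with the lattice values E_s, nu = 1/3:

    sigma_kl = (3/4) E_s eps_kl + (3/8) E_s delta_kl eps_mm.

The cell-applied traction balances the divergence of the sheet stress,
T_k = -h_s d_l sigma_kl, and the strain-energy density is
U = eps_kl sigma_kl / 2.  The plane-strain form of the constitutive law
(whose shear coefficient E/(1+nu) is identical but whose dilatational
coefficient is twice as large) is available as ``law="plane_strain"``; it
overestimates the dilatational stress of the spring lattice by a factor of
two and visibly degrades the agreement with the direct spring-force
readout.  An independent readout — the net spring force per
node divided by the area per node — serves as a cross-check of the continuum
pipeline.

Motion metrics: radial/azimuthal velocity and radial-traction kymographs,
the guidance parameter G (probability that a cell's centroid velocity points
within +-pi/2 of the wound centre), the effective friction
mu_eff = <F_r / v_r> under the first row of cells, T1 rates, the
velocity-velocity correlation function C_vv(r) and its decay length, the
purse-string coverage fraction of the wound perimeter, and local
curvature-velocity sampling of the advancing border.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import LinearNDInterpolator
from scipy.spatial import Delaunay

from .params import ModelParams
from .tissue import Tissue, cross2, MODE_PS, MODE_CRAWL
from .engine import Trajectory, Snapshot

__all__ = ["TractionField", "TractionCalculator", "traction_field",
           "traction_from_springs", "traction_cross_check",
           "mean_strain_energy", "substrate_spring_energy_series",
           "kymographs", "guidance", "effective_friction", "border_radial_load", "t1_rate",
           "velocity_correlation", "ps_coverage", "coverage_series",
           "curvature_velocity_scatter", "centroid_velocities"]

NU = 1.0 / 3.0  # triangular spring lattice Poisson ratio


# --------------------------------------------------------------------------
# traction reconstruction
# --------------------------------------------------------------------------

@dataclass
class TractionField:
    X: np.ndarray          # grid x coordinates (ny, nx)
    Y: np.ndarray
    u: np.ndarray          # displacements (ny, nx, 2), um
    eps: np.ndarray        # strain (ny, nx, 2, 2)
    sigma: np.ndarray      # stress (ny, nx, 2, 2), nN um^-2
    T: np.ndarray          # traction (ny, nx, 2), nN um^-2
    U: np.ndarray          # strain-energy density (ny, nx), nN um^-2 (per thickness)
    spacing: float


class TractionCalculator:
    """Reconstruct traction fields on a fixed square grid, reusing the
    Delaunay triangulation of the substrate reference nodes."""

    def __init__(self, substrate, spacing: float = 2.0):
        if spacing < substrate.spacing:
            warnings.warn("grid spacing below node spacing: aliasing likely",
                          stacklevel=2)
        self.sub = substrate
        self.spacing = float(spacing)
        self.tri = Delaunay(substrate.r_ref)
        r = substrate.r_ref
        xs = np.arange(r[:, 0].min(), r[:, 0].max() + 1e-9, spacing)
        ys = np.arange(r[:, 1].min(), r[:, 1].max() + 1e-9, spacing)
        self.X, self.Y = np.meshgrid(xs, ys)
        self._pts = np.column_stack([self.X.ravel(), self.Y.ravel()])

    def __call__(self, u_nodes: np.ndarray, E_s: float | None = None,
                 h_s: float | None = None,
                 law: str = "plane_stress") -> TractionField:
        E_s = self.sub.k_s * 2.0 / (math.sqrt(3.0) * self.sub.h_s) if E_s is None else E_s
        h_s = self.sub.h_s if h_s is None else h_s
        interp = LinearNDInterpolator(self.tri, u_nodes, fill_value=0.0)
        u = interp(self._pts).reshape(self.X.shape + (2,))
        h = self.spacing
        # eps_kl = (d_k u_l + d_l u_k) / 2; axis 0 is y, axis 1 is x
        dux_dy, dux_dx = np.gradient(u[..., 0], h)
        duy_dy, duy_dx = np.gradient(u[..., 1], h)
        eps = np.empty(self.X.shape + (2, 2))
        eps[..., 0, 0] = dux_dx
        eps[..., 1, 1] = duy_dy
        eps[..., 0, 1] = eps[..., 1, 0] = 0.5 * (dux_dy + duy_dx)
        if law == "plane_stress":
            lam = E_s * NU / (1.0 - NU ** 2)        # (3/8) E_s at nu = 1/3
        elif law == "plane_strain":
            lam = E_s * NU / ((1.0 + NU) * (1.0 - 2.0 * NU))
        else:
            raise ValueError(f"unknown constitutive law {law!r}")
        mu2 = E_s / (1.0 + NU)
        tr = eps[..., 0, 0] + eps[..., 1, 1]
        sigma = mu2 * eps
        sigma[..., 0, 0] += lam * tr
        sigma[..., 1, 1] += lam * tr
        dsxx_dy, dsxx_dx = np.gradient(sigma[..., 0, 0], h)
        dsxy_dy, dsxy_dx = np.gradient(sigma[..., 0, 1], h)
        dsyy_dy, dsyy_dx = np.gradient(sigma[..., 1, 1], h)
        # T_k = h_s d_l sigma_kl evaluated as the load the cells apply to the
        # gel: in static equilibrium the in-plane stress divergence balances
        # the applied surface traction, h d_l sigma_kl + t_k = 0, so the
        # cell-applied traction is minus the divergence of the sheet stress
        T = np.empty(self.X.shape + (2,))
        T[..., 0] = -h_s * (dsxx_dx + dsxy_dy)
        T[..., 1] = -h_s * (dsxy_dx + dsyy_dy)
        U = 0.5 * np.einsum("...kl,...kl->...", eps, sigma)
        return TractionField(self.X, self.Y, u, eps, sigma, T, U, self.spacing)


def traction_field(substrate, spacing: float = 2.0,
                   u_nodes: np.ndarray | None = None) -> TractionField:
    """One-shot traction reconstruction from a substrate snapshot."""
    calc = TractionCalculator(substrate, spacing)
    return calc(substrate.u if u_nodes is None else u_nodes)


def traction_from_springs(substrate, u_nodes: np.ndarray | None = None):
    """Direct traction readout: net spring force per node over the area per
    node (nN um^-2).  In quasi-static balance this equals minus the adhesion
    load, i.e. the traction the cells exert on the substrate.  Pinned
    boundary nodes carry the clamp reactions, not cell traction, and are
    reported as zero."""
    sub = substrate if u_nodes is None else _with_u(substrate, u_nodes)
    from .substrate import substrate_forces
    F = substrate_forces(sub)
    area_per_node = math.sqrt(3.0) / 2.0 * sub.spacing ** 2
    t = -F / area_per_node
    t[sub.pinned] = 0.0
    return t


def _with_u(substrate, u_nodes):
    s = substrate.copy()
    s.r = s.r_ref + u_nodes
    return s


def traction_cross_check(substrate, u_nodes: np.ndarray | None = None,
                         spacing: float = 2.0,
                         resolution: float | None = None) -> float:
    """Normalised RMS difference between the continuum-pipeline traction and
    the direct spring-force readout, both sampled on the same grid.

    The two readouts live on different native resolutions — the grid
    pipeline cannot represent wavelengths below ~2 grid spacings, while the
    spring readout resolves single-node point loads — so both fields are
    Gaussian-smoothed to a common ``resolution`` (um; default: twice the
    grid spacing) before comparing."""
    from scipy.ndimage import gaussian_filter
    calc = TractionCalculator(substrate, spacing)
    u = substrate.u if u_nodes is None else u_nodes
    tf = calc(u)
    t_nodes = traction_from_springs(substrate, u)
    interp = LinearNDInterpolator(calc.tri, t_nodes, fill_value=0.0)
    t_direct = interp(calc._pts).reshape(tf.T.shape)
    resolution = 2.0 * spacing if resolution is None else resolution
    sig = resolution / spacing
    T_grid = np.stack([gaussian_filter(tf.T[..., k], sig) for k in range(2)], -1)
    T_dir = np.stack([gaussian_filter(t_direct[..., k], sig) for k in range(2)], -1)
    num = np.sqrt(np.nanmean(np.sum((T_grid - T_dir) ** 2, axis=-1)))
    den = np.sqrt(np.nanmean(np.sum(T_dir ** 2, axis=-1)))
    return float(num / den) if den > 0 else 0.0


# --------------------------------------------------------------------------
# strain energy
# --------------------------------------------------------------------------

def mean_strain_energy(traj: Trajectory, spacing: float = 2.0,
                       every: int = 1) -> float:
    """Time-averaged total strain energy transmitted to the substrate
    (nN um): <SE> = (1/T) int dt int dA h_s U(x, y, t)."""
    if traj.substrate is None or len(traj.snapshots) < 1:
        return 0.0
    calc = TractionCalculator(traj.substrate, spacing)
    h_s = traj.substrate.h_s
    vals = []
    for snap in traj.snapshots[::every]:
        if snap.sub_u is None:
            continue
        tf = calc(snap.sub_u)
        vals.append(h_s * np.nansum(tf.U) * spacing ** 2)
    return float(np.mean(vals)) if vals else 0.0


def substrate_spring_energy_series(traj: Trajectory) -> np.ndarray:
    """Direct discrete substrate energy 0.5 k_s sum(dL^2) per snapshot."""
    from .substrate import substrate_energy
    out = []
    for snap in traj.snapshots:
        out.append(substrate_energy(_with_u(traj.substrate, snap.sub_u)))
    return np.asarray(out)


# --------------------------------------------------------------------------
# velocities and kymographs
# --------------------------------------------------------------------------

def centroid_velocities(traj: Trajectory, stride: int = 1):
    """Cell-centroid velocities over snapshot intervals.

    ``stride`` sets the differencing baseline in snapshots: a longer
    baseline averages out the displacement jitter that adhesion turnover
    puts on single intervals, leaving the coherent motion.  Returns a list
    of (t_mid, positions (C,2), velocities (C,2)) tuples."""
    out = []
    for s0, s1 in zip(traj.snapshots[:-stride], traj.snapshots[stride:]):
        dt = s1.t - s0.t
        if dt <= 0:
            continue
        v = (s1.centroids - s0.centroids) / dt
        out.append((0.5 * (s0.t + s1.t), 0.5 * (s0.centroids + s1.centroids), v))
    return out


def kymographs(traj: Trajectory, r_edges: np.ndarray | None = None,
               spacing: float = 2.0, traction_every: int = 1):
    """Radial kymographs about the initial wound centre.

    Returns a dict with r bin centres, snapshot-interval mid-times, and
    (nt, nr) maps ``v_r`` (cell radial velocity, positive toward the wound
    centre), ``v_theta_abs`` (azimuthal speed), and ``T_r`` (radial traction,
    positive outward).  Empty bins are NaN.
    """
    center = traj.wound_center
    if r_edges is None:
        pts = traj.snapshots[0].centroids
        rmax = np.max(np.linalg.norm(pts - center, axis=1))
        r_edges = np.arange(0.0, rmax + 5.0, 5.0)
    rc = 0.5 * (r_edges[:-1] + r_edges[1:])
    vels = centroid_velocities(traj)
    nt, nr = len(vels), len(rc)
    v_r = np.full((nt, nr), np.nan)
    v_t = np.full((nt, nr), np.nan)
    times = np.empty(nt)
    for it, (tm, pos, v) in enumerate(vels):
        times[it] = tm
        d = pos - center
        r = np.linalg.norm(d, axis=1)
        rhat = d / np.where(r > 0, r, 1.0)[:, None]
        that = np.column_stack([-rhat[:, 1], rhat[:, 0]])
        vr = -np.einsum("ij,ij->i", v, rhat)      # toward the centre positive
        vt = np.abs(np.einsum("ij,ij->i", v, that))
        idx = np.digitize(r, r_edges) - 1
        for ib in range(nr):
            m = idx == ib
            if m.any():
                v_r[it, ib] = vr[m].mean()
                v_t[it, ib] = vt[m].mean()
    T_r = None
    if traj.substrate is not None:
        calc = TractionCalculator(traj.substrate, spacing)
        snaps = traj.snapshots[::traction_every]
        T_r = np.full((len(snaps), nr), np.nan)
        t_times = np.empty(len(snaps))
        for it, snap in enumerate(snaps):
            t_times[it] = snap.t
            tf = calc(snap.sub_u)
            d = np.stack([tf.X - center[0], tf.Y - center[1]], axis=-1)
            r = np.linalg.norm(d, axis=-1)
            rhat = d / np.where(r > 0, r, 1.0)[..., None]
            tr = np.einsum("...k,...k->...", tf.T, rhat)   # outward positive
            idx = np.digitize(r.ravel(), r_edges) - 1
            trf = tr.ravel()
            for ib in range(nr):
                m = idx == ib
                if m.any():
                    T_r[it, ib] = np.nanmean(trf[m])
        return {"r": rc, "t": times, "v_r": v_r, "v_theta_abs": v_t,
                "T_r": T_r, "t_traction": t_times}
    return {"r": rc, "t": times, "v_r": v_r, "v_theta_abs": v_t, "T_r": None}


# --------------------------------------------------------------------------
# guidance, friction, T1 rate
# --------------------------------------------------------------------------

def guidance(traj: Trajectory, v_tol: float = 1e-9, stride: int = 2):
    """Angle samples between cell velocity and the direction to the wound
    centre, and the guidance G = P(|theta| < pi/2).  Zero-velocity samples
    (|v| < v_tol) are excluded."""
    center = traj.wound_center
    thetas = []
    for _, pos, v in centroid_velocities(traj, stride):
        d = center - pos
        nd = np.linalg.norm(d, axis=1)
        nv = np.linalg.norm(v, axis=1)
        ok = (nv > v_tol) & (nd > 0)
        if not ok.any():
            continue
        cosang = np.einsum("ij,ij->i", v[ok], d[ok]) / (nv[ok] * nd[ok])
        sinang = cross2(d[ok], v[ok]) / (nv[ok] * nd[ok])
        thetas.append(np.arctan2(sinang, cosang))
    if not thetas:
        return np.empty(0), np.nan
    theta = np.concatenate(thetas)
    G = float(np.mean(np.abs(theta) < 0.5 * np.pi))
    return theta, G


def _first_row_cells(snap: Snapshot) -> np.ndarray:
    border = set(int(v) for v in snap.border_vertices)
    out = [ci for ci, cell in enumerate(snap.cells)
           if any(int(v) in border for v in cell)]
    return np.asarray(out, dtype=np.int64)


def _first_row_radial_load(snap: Snapshot, sub, params, center):
    """Net radial force (outward positive, nN) that the first row of cells
    applies to the substrate through its adhesions, or None if no bonds."""
    first = _first_row_cells(snap)
    if len(first) == 0:
        return None
    verts = np.unique(np.concatenate([snap.cells[ci] for ci in first]))
    bound = verts[snap.adh_node[verts] >= 0]
    if len(bound) == 0:
        return None
    nodes = snap.adh_node[bound]
    rpos = sub.r_ref[nodes] + snap.sub_u[nodes]
    sep = snap.x[bound] - rpos
    L = np.hypot(sep[:, 0], sep[:, 1])
    Lsafe = np.where(L > 0, L, 1.0)
    f_on_node = (params.k_f * (L - snap.adh_rest[bound]) / Lsafe)[:, None] * sep
    d = rpos - center
    nd = np.linalg.norm(d, axis=1)
    rhat = d / np.where(nd > 0, nd, 1.0)[:, None]
    return float(np.sum(np.einsum("ij,ij->i", f_on_node, rhat)))


def border_radial_load(traj: Trajectory, params=None):
    """Time series of the net radial traction force the wound-edge cells
    apply to the substrate (outward positive).

    Crawling pulls the substrate outward under the leading edge (the cells
    haul themselves forward on anchors placed ahead); a purse-string drags
    the edge inward, so the sign of this force flips when the cable
    assembles.  Returns (times, F_r)."""
    p = params if params is not None else traj.params
    sub = traj.substrate
    ts, fr = [], []
    for snap in traj.snapshots:
        if snap.sub_u is None:
            continue
        F_r = _first_row_radial_load(snap, sub, p, traj.wound_center)
        if F_r is None:
            continue
        ts.append(snap.t)
        fr.append(F_r)
    return np.asarray(ts), np.asarray(fr)


def effective_friction(traj: Trajectory, params: ModelParams | None = None,
                       v_tol: float = 1e-4) -> float:
    """Effective friction mu_eff = <F_r / v_r> (nN s um^-1).

    F_r: net radial force the first row of cells (cells touching the wound
    border, recomputed per snapshot) exerts on the substrate through their
    adhesions, outward positive.  v_r: radial velocity of the wound border,
    outward positive.  Positive ratio = resistive drag (purse-string),
    negative = assistive (crawling).  Snapshots with |v_r| < v_tol um/s are
    skipped and the time average is a median (the ratio is heavy-tailed
    whenever the border velocity fluctuates through zero).
    """
    p = params if params is not None else traj.params
    sub = traj.substrate
    if sub is None:
        return np.nan
    center = traj.wound_center
    ratios = []
    for s0, s1 in zip(traj.snapshots[:-1], traj.snapshots[1:]):
        dt = s1.t - s0.t
        common = np.intersect1d(s0.border_vertices, s1.border_vertices)
        if dt <= 0 or len(common) < 3:
            continue
        r0 = np.linalg.norm(s0.x[common] - center, axis=1)
        r1 = np.linalg.norm(s1.x[common] - center, axis=1)
        v_r = float(np.mean(r1 - r0) / dt)
        if abs(v_r) < v_tol:
            continue
        F_r = _first_row_radial_load(s0, sub, p, center)
        if F_r is None:
            continue
        ratios.append(F_r / v_r)
    # the ratio distribution is heavy-tailed when the border velocity passes
    # near zero, so the time average is taken as a median
    return float(np.median(ratios)) if ratios else np.nan


def t1_rate(traj: Trajectory) -> float:
    """Neighbour exchanges per cell per hour over the closure.

    Counts interior T1 flips and wound-border edge collapses; a collapse is
    the boundary form of a neighbour exchange, in which a cell is squeezed
    off the leading edge and its two border neighbours gain adjacency."""
    n_t1 = sum(1 for e in traj.events if e.get("kind") in ("t1", "collapse"))
    dur_hr = traj.duration() / 3600.0
    n_cells = traj.n_cells
    if dur_hr <= 0 or n_cells == 0:
        return 0.0
    return n_t1 / (n_cells * dur_hr)


# --------------------------------------------------------------------------
# velocity correlation
# --------------------------------------------------------------------------

def velocity_correlation(traj: Trajectory, dr: float = 2.5,
                         t_frac: tuple = (0.1, 0.9), A0: float | None = None,
                         stride: int = 2, min_pairs: int = 20):
    """Velocity-velocity correlation C_vv(r) = <v(0).v(r)> / <v(0)^2> pooled
    over snapshot pairs inside the ``t_frac`` fraction of the run.

    Returns ``(r_centres, C, corr_len_diameters)``: the correlation length is
    the first radius where C_vv drops below 1/e, in units of the mean cell
    diameter sqrt(A0)."""
    A0 = traj.params.A0 if A0 is None else A0
    vels = centroid_velocities(traj, stride)
    if not vels:
        return np.empty(0), np.empty(0), np.nan
    t0, t1 = vels[0][0], vels[-1][0]
    lo = t0 + t_frac[0] * (t1 - t0)
    hi = t0 + t_frac[1] * (t1 - t0)
    num_acc: dict = {}
    cnt_acc: dict = {}
    denom = []
    for tm, pos, v in vels:
        if not (lo <= tm <= hi) or len(pos) < 20:
            continue
        denom.append(np.mean(np.einsum("ij,ij->i", v, v)))
        d = pos[:, None, :] - pos[None, :, :]
        r = np.sqrt(np.sum(d * d, axis=-1))
        dots = v @ v.T
        iu = np.triu_indices(len(pos), k=1)
        bins = np.floor(r[iu] / dr).astype(int)
        for b, val in zip(bins, dots[iu]):
            num_acc[b] = num_acc.get(b, 0.0) + val
            cnt_acc[b] = cnt_acc.get(b, 0) + 1
    if not denom:
        return np.empty(0), np.empty(0), np.nan
    den = float(np.mean(denom))
    nb = max(num_acc) + 1 if num_acc else 0
    r_centres = (np.arange(nb) + 0.5) * dr
    C = np.full(nb, np.nan)
    for b in range(nb):
        if cnt_acc.get(b, 0) > 0:
            C[b] = num_acc[b] / cnt_acc[b] / den
    corr_len = np.nan
    thresh = 1.0 / math.e
    prev = None
    for b in range(nb):
        if cnt_acc.get(b, 0) < min_pairs or not np.isfinite(C[b]):
            continue   # sparse bins (r below the centroid spacing) are noise
        if C[b] < thresh:
            if prev is not None:
                # linear interpolation between the last bin above 1/e and this one
                r_prev, c_prev = prev
                frac = (c_prev - thresh) / (c_prev - C[b])
                corr_len = (r_prev + frac * (r_centres[b] - r_prev)) / math.sqrt(A0)
            else:
                corr_len = r_centres[b] / math.sqrt(A0)
            break
        prev = (r_centres[b], C[b])
    return r_centres, C, corr_len


# --------------------------------------------------------------------------
# purse-string coverage and curvature-velocity
# --------------------------------------------------------------------------

def ps_coverage(tissue: Tissue) -> float:
    """Fraction of the wound-border length covered by purse-string cells.
    NaN once the wound has closed."""
    topo = tissue.topology
    be = tissue.wound_border_edges()
    if not be:
        return np.nan
    total = 0.0
    ps = 0.0
    for (u, v) in be:
        L = float(np.linalg.norm(tissue.x[v] - tissue.x[u]))
        total += L
        corners = topo.edges.get((u, v))
        if corners and tissue.mode[topo.corner_cell[corners[0]]] == MODE_PS:
            ps += L
    return ps / total if total > 0 else np.nan


def coverage_series(traj: Trajectory):
    """(times, coverage fraction) over the trajectory's snapshots."""
    t, c = [], []
    for snap in traj.snapshots:
        tis = snap.as_tissue()
        t.append(snap.t)
        c.append(ps_coverage(tis))
    return np.asarray(t), np.asarray(c)


def curvature_velocity_scatter(traj: Trajectory):
    """Per-border-cell samples of (signed local curvature, normal advance
    speed of the cell's border run) over consecutive snapshots, with the
    per-mode linear-fit slope.

    Returns a dict: kappa, speed, mode arrays plus ``slope`` per mode id.
    """
    from .motility import edge_curvature
    center = traj.wound_center
    kappas, speeds, modes = [], [], []
    prev = None
    for snap in traj.snapshots:
        tis = snap.as_tissue()
        info = {}
        for ci in tis.border_cells():
            run = tis.cell_border_run(int(ci))
            if run is None:
                continue
            mid = tis.x[run].mean(axis=0)
            kap = edge_curvature(tis, int(ci))
            info[int(ci)] = (mid, kap, int(tis.mode[ci]))
        if prev is not None:
            t0, info0 = prev
            dt = snap.t - t0
            for ci, (mid0, kap, mode) in info0.items():
                if ci not in info or dt <= 0 or kap is None:
                    continue
                mid1 = info[ci][0]
                inward = center - mid0
                n = np.linalg.norm(inward)
                if n == 0:
                    continue
                speed = float(np.dot(mid1 - mid0, inward / n)) / dt
                kappas.append(kap)
                speeds.append(speed)
                modes.append(mode)
        prev = (snap.t, info)
    kappas = np.asarray(kappas)
    speeds = np.asarray(speeds)
    modes = np.asarray(modes)
    slopes = {}
    for mode in np.unique(modes):
        m = modes == mode
        if m.sum() >= 5 and np.ptp(kappas[m]) > 0:
            slopes[int(mode)] = float(np.polyfit(kappas[m], speeds[m], 1)[0])
    return {"kappa": kappas, "speed": speeds, "mode": modes, "slope": slopes}
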