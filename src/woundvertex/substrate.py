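"""Elastic substrate: a triangular lattice of Hookean springs.

A triangular lattice of identical linear springs behaves, at long
wavelengths, as an isotropic linear-elastic sheet with Poisson's ratio
nu = 1/3 and Young's modulus E_s = 2 k_s / (sqrt(3) h_s), where k_s is the
spring constant and h_s the substrate thickness.  The mesh is built at a
prescribed node density, covers the tissue plus a margin, and its outermost
node ring is pinned (an attached gel far from the wound does not move).
Node motion is overdamped: free nodes move at velocity F/mu.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import minimize

from .params import ModelParams, ConfigurationError
from .tissue import GeometryError

__all__ = ["Substrate", "build_substrate", "substrate_forces",
           "substrate_energy", "measure_moduli"]


class Substrate:
    """Triangular spring mesh: positions, reference positions, springs."""

    def __init__(self, r_ref: np.ndarray, springs: np.ndarray, k_s: float,
                 h_s: float, pinned: np.ndarray, spacing: float):
        self.r_ref = np.asarray(r_ref, dtype=float).copy()
        self.r = self.r_ref.copy()
        self.springs = np.asarray(springs, dtype=np.int64)
        d = self.r_ref[self.springs[:, 1]] - self.r_ref[self.springs[:, 0]]
        self.rest = np.hypot(d[:, 0], d[:, 1])
        self.k_s = float(k_s)
        self.h_s = float(h_s)
        self.pinned = np.asarray(pinned, dtype=bool).copy()
        self.spacing = float(spacing)

    @property
    def n_nodes(self) -> int:
        return len(self.r_ref)

    @property
    def u(self) -> np.ndarray:
        """Displacement field r - r_ref, (M, 2)."""
        return self.r - self.r_ref

    def copy(self) -> "Substrate":
        s = Substrate(self.r_ref, self.springs, self.k_s, self.h_s,
                      self.pinned, self.spacing)
        s.r = self.r.copy()
        return s


def _triangular_lattice(xlim, ylim, a: float):
    """Node positions of a triangular lattice with spacing ``a`` covering the
    rectangle, one lattice vector along +x."""
    dy = a * math.sqrt(3.0) / 2.0
    nrows = int(math.ceil((ylim[1] - ylim[0]) / dy)) + 1
    ncols = int(math.ceil((xlim[1] - xlim[0]) / a)) + 2
    pts = []
    index = {}
    for j in range(nrows):
        x0 = xlim[0] + (0.5 * a if j % 2 else 0.0)
        for i in range(ncols):
            x = x0 + i * a
            if x > xlim[1] + 0.51 * a:
                continue
            index[(i, j)] = len(pts)
            pts.append((x, ylim[0] + j * dy))
    springs = []
    for (i, j), vid in index.items():
        for di, dj in ((1, 0), (0, 1), (1, 1)) if j % 2 else ((1, 0), (0, 1), (-1, 1)):
            nb = index.get((i + di, j + dj))
            if nb is not None:
                springs.append((vid, nb))
    return np.asarray(pts, dtype=float), np.asarray(springs, dtype=np.int64)


def build_substrate(extent, rho: float | None = None, E_s: float | None = None,
                    h_s: float | None = None, params: ModelParams | None = None,
                    margin: float | None = None, pin_boundary: bool = True) -> Substrate:
    """Build a pinned-boundary triangular spring mesh.

    ``extent`` is ``(xmin, xmax, ymin, ymax)`` of the region to cover (the
    tissue bounding box); the mesh extends ``margin`` further on every side
    and its boundary ring is pinned.  The spring constant follows from the
    target Young's modulus: k_s = sqrt(3) E_s h_s / 2.
    """
    if params is not None:
        rho = params.rho if rho is None else rho
        E_s = params.E_s if E_s is None else E_s
        h_s = params.h_s if h_s is None else h_s
        margin = params.substrate_margin if margin is None else margin
    margin = 20.0 if margin is None else margin
    if rho is None or rho <= 0 or h_s is None or h_s <= 0:
        raise ConfigurationError("substrate needs rho > 0 and h_s > 0")
    if E_s is None or E_s < 0:
        raise ConfigurationError("substrate needs E_s >= 0")
    a = math.sqrt(2.0 / (math.sqrt(3.0) * rho))
    xmin, xmax, ymin, ymax = extent
    pts, springs = _triangular_lattice((xmin - margin, xmax + margin),
                                       (ymin - margin, ymax + margin), a)
    k_s = math.sqrt(3.0) * E_s * h_s / 2.0
    pinned = np.zeros(len(pts), dtype=bool)
    if pin_boundary:
        eps = 1.01 * a
        pinned = ((pts[:, 0] < xmin - margin + eps) | (pts[:, 0] > xmax + margin - eps)
                  | (pts[:, 1] < ymin - margin + eps) | (pts[:, 1] > ymax + margin - eps))
    return Substrate(pts, springs, k_s, h_s, pinned, a)


def substrate_forces(sub: Substrate) -> np.ndarray:
    """Net Hookean spring force on every node (nN); zero at reference."""
    d = sub.r[sub.springs[:, 1]] - sub.r[sub.springs[:, 0]]
    L = np.hypot(d[:, 0], d[:, 1])
    if np.any(L == 0):
        raise GeometryError("coincident nodes on a substrate spring")
    f = sub.k_s * (L - sub.rest) / L   # tension / length
    fvec = f[:, None] * d
    n = sub.n_nodes
    fx = (np.bincount(sub.springs[:, 0], weights=fvec[:, 0], minlength=n)
          - np.bincount(sub.springs[:, 1], weights=fvec[:, 0], minlength=n))
    fy = (np.bincount(sub.springs[:, 0], weights=fvec[:, 1], minlength=n)
          - np.bincount(sub.springs[:, 1], weights=fvec[:, 1], minlength=n))
    return np.column_stack([fx, fy])


def substrate_energy(sub: Substrate) -> float:
    """Total spring energy 0.5 k_s sum (dL)^2 (nN um)."""
    d = sub.r[sub.springs[:, 1]] - sub.r[sub.springs[:, 0]]
    L = np.hypot(d[:, 0], d[:, 1])
    return 0.5 * sub.k_s * float(np.sum((L - sub.rest) ** 2))


def measure_moduli(E_s: float = 4.0, h_s: float = 5.0, rho: float = 0.6,
                   strain: float = 0.01, width: float = 180.0,
                   height: float = 36.0):
    """Uniaxial-stress test of the spring mesh: returns (E_eff, nu_eff).

    Two grip columns of nodes at the left/right ends are displaced apart by
    the prescribed axial strain; all other nodes (including the lateral
    boundaries, which are traction-free) relax to the energy minimum.
    E_eff is the axial force transmitted across the mid-section divided by
    the reference cross-section (height x h_s) and the strain; nu_eff is
    -transverse strain / axial strain measured in the middle third of the
    strip.  Both are evaluated away from the gripped ends, where the
    clamped lateral contraction would bias the result.  Strains above 5%
    leave the linear regime.
    """
    if strain > 0.05:
        import warnings
        warnings.warn("strain > 5%: nonlinear lattice response", stacklevel=2)
    sub = build_substrate((0.0, width, 0.0, height), rho=rho, E_s=E_s, h_s=h_s,
                          margin=0.0, pin_boundary=False)
    a = sub.spacing
    x = sub.r_ref[:, 0]
    left = x < 0.51 * a
    right = x > width - 0.51 * a
    grip = left | right
    disp = np.zeros_like(sub.r_ref)
    span = x[right].mean() - x[left].mean()
    disp[right, 0] = strain * span
    free = ~grip

    r0 = sub.r_ref + disp
    idx = np.where(free)[0]

    def fun(z):
        sub.r = r0.copy()
        sub.r[idx] = z.reshape(-1, 2)
        e = substrate_energy(sub)
        g = -substrate_forces(sub)[idx]
        return e, g.ravel()

    res = minimize(fun, r0[idx].ravel(), jac=True, method="L-BFGS-B",
                   options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10})
    sub.r = r0.copy()
    sub.r[idx] = res.x.reshape(-1, 2)

    # axial force transmitted across the mid-section x = width/2:
    # sum of x-components of spring tensions for springs crossing the plane
    xmid = width / 2.0 + 0.25 * a   # avoid slicing exactly through nodes
    ra, rb = sub.r[sub.springs[:, 0]], sub.r[sub.springs[:, 1]]
    xa = sub.r_ref[sub.springs[:, 0], 0]
    xb = sub.r_ref[sub.springs[:, 1], 0]
    crossing = ((xa < xmid) & (xb > xmid)) | ((xb < xmid) & (xa > xmid))
    d = rb - ra
    L = np.hypot(d[:, 0], d[:, 1])
    tension = sub.k_s * (L - sub.rest)
    # force transmitted in +x across the plane
    sign = np.where(xb > xa, 1.0, -1.0)
    axial = float(np.sum((tension * d[:, 0] / L * sign)[crossing]))

    y = sub.r_ref[:, 1]
    mid = (x > width / 3.0) & (x < 2.0 * width / 3.0)
    top = mid & (y > height - 0.6 * a)
    bot = mid & (y < 0.6 * a)
    width_ref = y[top].mean() - y[bot].mean()
    width_now = sub.r[top, 1].mean() - sub.r[bot, 1].mean()
    eps_t = (width_now - width_ref) / width_ref
    # a discrete strip of n node rows carries the load of n full lattice
    # rows, one row spacing each, not of the node-to-node span (n-1 rows)
    dy = a * math.sqrt(3.0) / 2.0
    n_rows = int(round(width_ref / dy)) + 1
    E_eff = axial / (n_rows * dy * h_s) / strain
    nu_eff = -eps_t / strain
    return E_eff, nu_eff
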