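"""Traction reconstruction and motion metrics on controlled inputs."""

import numpy as np
import pytest
from scipy.optimize import minimize

from woundvertex.params import ModelParams
from woundvertex.substrate import (build_substrate, substrate_forces,
                                   substrate_energy)
from woundvertex import analysis
from woundvertex.engine import Trajectory, Snapshot
from woundvertex.tissue import Tissue


# --------------------------------------------------------------------------
# synthetic substrate states
# --------------------------------------------------------------------------

@pytest.fixture(scope="module")
def flat_substrate():
    return build_substrate((0, 60, 0, 60), rho=0.6, E_s=4.0, h_s=5.0, margin=10.0)


@pytest.fixture(scope="module")
def ring_loaded_substrate():
    """Substrate relaxed under a smooth outward ring load (known traction)."""
    sub = build_substrate((0, 80, 0, 80), rho=0.6, E_s=4.0, h_s=5.0, margin=10.0)
    c = np.array([40.0, 40.0])
    d = sub.r_ref - c
    r = np.hypot(d[:, 0], d[:, 1])
    rhat = d / np.where(r > 0, r, 1)[:, None]
    apn = np.sqrt(3) / 2 * sub.spacing ** 2
    load = (0.05 * np.exp(-((r - 15) / 6.0) ** 2))[:, None] * rhat * apn
    idx = np.where(~sub.pinned)[0]

    def fun(z):
        sub.r = sub.r_ref.copy()
        sub.r[idx] = z.reshape(-1, 2)
        e = substrate_energy(sub) - np.sum(load[idx] * (sub.r[idx] - sub.r_ref[idx]))
        g = -(substrate_forces(sub)[idx] + load[idx])
        return e, g.ravel()

    res = minimize(fun, sub.r_ref[idx].ravel(), jac=True, method="L-BFGS-B",
                   options={"maxiter": 8000, "ftol": 1e-18, "gtol": 1e-10})
    sub.r = sub.r_ref.copy()
    sub.r[idx] = res.x.reshape(-1, 2)
    return sub, c, load / apn


class TestTractionField:
    def test_zero_displacement_gives_zero_fields(self, flat_substrate):
        tf = analysis.traction_field(flat_substrate)
        for f in (tf.u, tf.eps, tf.sigma, tf.T, tf.U):
            assert np.abs(np.nan_to_num(f)).max() == 0.0

    def test_uniform_strain_closed_form(self, flat_substrate):
        # manufactured u = (eps x, 0): eps_xx = eps, sigma per the plane-
        # stress law, traction = 0 (uniform stress)
        sub = flat_substrate
        eps0 = 1e-3
        u_nodes = np.column_stack([eps0 * sub.r_ref[:, 0],
                                   np.zeros(sub.n_nodes)])
        tf = analysis.traction_field(sub, u_nodes=u_nodes)
        interior = (slice(5, -5), slice(5, -5))
        E = 4.0
        sxx_expected = (0.75 * E + 0.375 * E) * eps0
        syy_expected = 0.375 * E * eps0
        assert np.allclose(tf.eps[interior][..., 0, 0], eps0, rtol=1e-6)
        assert np.allclose(tf.eps[interior][..., 1, 1], 0.0, atol=1e-9)
        assert np.allclose(tf.sigma[interior][..., 0, 0], sxx_expected, rtol=1e-6)
        assert np.allclose(tf.sigma[interior][..., 1, 1], syy_expected, rtol=1e-6)
        assert np.abs(tf.T[interior]).max() < 1e-10

    def test_linearity_in_displacement(self, ring_loaded_substrate):
        sub, _, _ = ring_loaded_substrate
        calc = analysis.TractionCalculator(sub, 2.0)
        t1 = calc(sub.u)
        t2 = calc(2.0 * sub.u)
        assert np.allclose(t2.eps, 2.0 * t1.eps)
        assert np.allclose(t2.T, 2.0 * t1.T)
        assert np.allclose(t2.U, 4.0 * t1.U)      # quadratic energy

    def test_smooth_field_cross_check_within_15_percent(self, ring_loaded_substrate):
        """On a smooth load the continuum pipeline and the direct per-node
        spring-force readout agree closely."""
        sub, _, _ = ring_loaded_substrate
        assert analysis.traction_cross_check(sub) < 0.15

    def test_net_traction_near_zero_for_balanced_load(self, ring_loaded_substrate):
        # the ring load is radially symmetric: net vector force ~ 0
        sub, _, _ = ring_loaded_substrate
        tf = analysis.traction_field(sub)
        net = np.nansum(tf.T.reshape(-1, 2), axis=0) * tf.spacing ** 2
        scale = np.nansum(np.abs(tf.T)) * tf.spacing ** 2
        # boundary pinning breaks the balance slightly; a few percent remains
        assert np.abs(net).max() < 0.05 * scale

    def test_strain_energy_matches_spring_energy_on_smooth_field(self, ring_loaded_substrate):
        """For a smooth deformation the grid integral of h_s U equals the
        discrete spring energy (continuum limit of the lattice)."""
        sub, _, _ = ring_loaded_substrate
        tf = analysis.traction_field(sub)
        grid_energy = np.nansum(tf.U) * tf.spacing ** 2 * sub.h_s
        spring = substrate_energy(sub)
        assert grid_energy == pytest.approx(spring, rel=0.10)

    def test_aliasing_warning_below_node_spacing(self, flat_substrate):
        with pytest.warns(UserWarning):
            analysis.TractionCalculator(flat_substrate, spacing=1.0)


# --------------------------------------------------------------------------
# synthetic trajectories for motion metrics
# --------------------------------------------------------------------------

def _toy_snapshot(t, centroids, border=(), x=None):
    n = len(centroids)
    x = centroids.copy() if x is None else x
    return Snapshot(t=t, x=x, cells=[np.array([i]) for i in range(n)],
                    mode=np.zeros(n, np.int8), theta=np.zeros(n),
                    adh_node=np.full(len(x), -1), adh_rest=np.zeros(len(x)),
                    sub_u=None, wound_area=0.0,
                    border_vertices=np.asarray(border, dtype=np.int64),
                    centroids=centroids.copy())


def _toy_traj(frames, dt=60.0, center=(0.0, 0.0)):
    traj = Trajectory(params=ModelParams(), seed=0,
                      wound_center=np.asarray(center, dtype=float))
    for i, c in enumerate(frames):
        traj.snapshots.append(_toy_snapshot(i * dt, c))
        traj.times.append(i * dt)
    return traj


def grid_positions(n=36, pitch=10.0):
    g = np.arange(n ** 0.5.__round__() if False else int(np.sqrt(n)))
    side = int(np.sqrt(n))
    xs, ys = np.meshgrid(np.arange(side), np.arange(side))
    pts = pitch * np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
    return pts - pts.mean(axis=0)


class TestGuidance:
    def test_all_inward_gives_one(self):
        pos = grid_positions(36)
        frames = [pos, pos * 0.99, pos * 0.98]
        traj = _toy_traj(frames)
        _, G = analysis.guidance(traj, stride=1)
        assert G == 1.0

    def test_isotropic_random_gives_half(self, rng):
        pos = grid_positions(400, pitch=10.0)
        frames = [pos]
        for _ in range(6):
            frames.append(frames[-1] + rng.normal(0, 0.5, pos.shape))
        traj = _toy_traj(frames)
        theta, G = analysis.guidance(traj, stride=1)
        assert G == pytest.approx(0.5, abs=4 * 0.5 / np.sqrt(len(theta)))


class TestKymographs:
    def test_radial_inward_motion_has_zero_azimuthal(self):
        pos = grid_positions(100, pitch=8.0)
        frames = [pos * (1 - 0.01 * k) for k in range(4)]
        traj = _toy_traj(frames)
        ky = analysis.kymographs(traj, r_edges=np.arange(0, 50, 10.0))
        assert np.nanmax(ky["v_theta_abs"]) < 1e-12
        assert np.nanmin(ky["v_r"]) >= 0.0    # toward the centre positive

    def test_rigid_rotation_is_purely_azimuthal(self):
        pos = grid_positions(100, pitch=8.0)
        w = 1e-3
        frames = []
        for k in range(4):
            a = w * k
            R = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
            frames.append(pos @ R.T)
        traj = _toy_traj(frames, dt=10.0)
        ky = analysis.kymographs(traj, r_edges=np.arange(0, 50, 10.0))
        assert np.nanmax(np.abs(ky["v_r"])) < 1e-4 * np.nanmax(ky["v_theta_abs"])
        # |v_theta| = omega r, with r the mean radius of the cells per bin
        edges = np.arange(0, 50, 10.0)
        rr = np.hypot(pos[:, 0], pos[:, 1])
        idx = np.digitize(rr, edges) - 1
        good = ~np.isnan(ky["v_theta_abs"][0])
        expected = np.array([rr[idx == b].mean() for b in range(len(edges) - 1)
                             if (idx == b).any()])
        assert np.allclose(ky["v_theta_abs"][0][good],
                           (w / 10.0) * expected, rtol=1e-2)


class TestVelocityCorrelation:
    def test_rigid_translation_fully_correlated(self):
        pos = grid_positions(100, pitch=10.0)
        frames = [pos + k * np.array([0.5, 0.2]) for k in range(6)]
        traj = _toy_traj(frames)
        r, C, _ = analysis.velocity_correlation(traj, dr=10.0, stride=1,
                                                min_pairs=1)
        good = ~np.isnan(C)
        assert np.allclose(C[good], 1.0)

    def test_independent_noise_decorrelates(self, rng):
        pos = grid_positions(400, pitch=10.0)
        frames = [pos]
        for _ in range(8):
            frames.append(frames[-1] + rng.normal(0, 0.5, pos.shape))
        traj = _toy_traj(frames)
        r, C, cl = analysis.velocity_correlation(traj, dr=10.0, stride=1)
        assert np.nanmax(np.abs(C[1:6])) < 0.15
        assert cl < 2.0


class TestCoverage:
    def test_all_crawl_zero_all_ps_one(self, voronoi60):
        from woundvertex.woundgen import make_wound, WoundSpec
        from woundvertex.tissue import MODE_PS
        w = make_wound(voronoi60, WoundSpec(radius=10.0))
        assert analysis.ps_coverage(w) == 0.0
        w.mode[w.border_cells()] = MODE_PS
        assert analysis.ps_coverage(w) == 1.0

    def test_closed_wound_reports_missing(self, voronoi60):
        assert np.isnan(analysis.ps_coverage(voronoi60))

    def test_stochastic_coverage_matches_markov_oracle(self, voronoi60, params):
        """On a static border, mean purse-string coverage after time t is
        1 - exp(-k_p t) (independent per-cell Poisson switching)."""
        from woundvertex.woundgen import make_wound, WoundSpec
        from woundvertex.motility import switch_modes_stochastic
        from woundvertex.params import HR
        p = params.replace(k_p=40.0 / HR)    # fast enough to resolve in 100 steps
        base = make_wound(voronoi60, WoundSpec(radius=10.0))
        nrep = 40
        nstep = 100
        cov = np.zeros((nrep, nstep))
        rng = np.random.default_rng(7)
        for rep in range(nrep):
            t = base.copy()
            for k in range(nstep):
                switch_modes_stochastic(t, p, rng)
                cov[rep, k] = analysis.ps_coverage(t)
        tgrid = (np.arange(nstep) + 1) * p.dt
        oracle = 1.0 - np.exp(-p.k_p * tgrid)
        mean = cov.mean(axis=0)
        assert np.abs(mean - oracle).max() < 0.08   # binomial noise at nrep=40


def test_t1_rate_zero_without_events():
    traj = _toy_traj([grid_positions(36)] * 3)
    assert analysis.t1_rate(traj) == 0.0
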