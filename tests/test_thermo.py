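import numpy as np
import pytest

from sparseffr import dynamics as dyn, thermo
from sparseffr.synthetic import double_well_force, double_well_potential
from .conftest import AnalyticForceField


BOUNDS = np.array([[-2.2, 2.2], [-1.6, 1.6]])


def dw_ff(barrier, curl, D):
    return AnalyticForceField(double_well_force(barrier, curl), D)


class TestLeastActionPath:
    def test_residence_at_minimum_costs_nothing(self):
        ff = dw_ff(0.25, 0.0, 0.05)
        # a short straight hop inside the flat bottom of one well
        p = thermo.least_action_path(ff, np.array([-1.0, 0.0]),
                                     np.array([-1.0, 0.05]), P=20)
        assert p.action < 0.2

    def test_descent_from_straight_line(self):
        ff = dw_ff(0.25, 0.3, 0.05)
        x_a, x_b = np.array([-1.0, 0.0]), np.array([1.0, 0.0])
        p = thermo.least_action_path(ff, x_a, x_b, P=30)
        T = p.total_time
        straight = np.linspace(0, 1, 30)[:, None] * (x_b - x_a) + x_a
        assert p.action <= thermo.path_action(ff, straight, T) + 1e-9

    def test_gradient_quasipotential_oracle(self):
        # Phi = (x^2-1)^2/4 embedded in 2D; Freidlin-Wentzell rate
        # functional gives uphill action dPhi / D
        b, D = 0.25, 0.05
        ff = dw_ff(b, 0.0, D)
        p = thermo.least_action_path(ff, np.array([-1.0, 0.0]),
                                     np.array([1.0, 0.0]), P=60,
                                     convention="fw")
        assert abs(p.action - b / D) <= 0.10 * (b / D)

    def test_half_convention_doubles_fw(self):
        ff = dw_ff(0.25, 0.0, 0.05)
        pf = thermo.least_action_path(ff, np.array([-1.0, 0.0]),
                                      np.array([1.0, 0.0]), P=40,
                                      convention="fw")
        pp = thermo.least_action_path(ff, np.array([-1.0, 0.0]),
                                      np.array([1.0, 0.0]), P=40,
                                      convention="half")
        assert abs(pp.action - 2 * pf.action) <= 0.05 * pp.action

    def test_identical_endpoints_rejected(self):
        ff = dw_ff(0.25, 0.0, 0.05)
        with pytest.raises(ValueError):
            thermo.least_action_path(ff, np.zeros(2), np.zeros(2))

    def test_uphill_path_traces_downhill_trajectory(self):
        # for gradient fields the optimal climb reverses the relaxation path
        b, D = 0.25, 0.0
        ff_det = dw_ff(b, 0.0, 0.05)
        p = thermo.least_action_path(ff_det, np.array([-1.0, 0.0]),
                                     np.array([1.0, 0.0]), P=40)
        # analytic relaxation path from the saddle is the x-axis
        assert np.abs(p.nodes[:, 1]).max() < 0.08


@pytest.fixture(scope="module")
def dw_equilibrium():
    b, D = 0.15, 0.08
    ff = dw_ff(b, 0.0, D)
    rng = np.random.default_rng(11)
    x0 = np.vstack([
        np.column_stack([rng.normal(-1, 0.2, 150), rng.normal(0, 0.3, 150)]),
        np.column_stack([rng.normal(1, 0.2, 150), rng.normal(0, 0.3, 150)]),
    ])
    ens = dyn.simulate(ff, x0, dt=2e-3, n_steps=40000, n_traj=300,
                       burn_in=4000, seed=11, bounds=BOUNDS)
    land = dyn.steady_state_landscape(ens, grid=96)
    return b, D, ff, x0, land


class TestBarriers:
    def test_barrier_matches_analytic_potential(self, dw_equilibrium):
        b, D, ff, x0, land = dw_equilibrium
        path = thermo.least_action_path(ff, np.array([-1.0, 0.0]),
                                        np.array([1.0, 0.0]), P=30)
        bar = thermo.barrier_heights(land, path)
        # U = Phi/D up to a constant, so the barrier is dPhi/D = b/D
        assert abs(bar["forward"] - b / D) <= 0.05 * (b / D) + 0.15
        assert abs(bar["forward"] - bar["backward"]) <= 0.3  # symmetry
        assert abs(bar["saddle"][0]) < 0.2

    def test_monotone_path_barrier_at_endpoint(self, dw_equilibrium):
        *_, land = dw_equilibrium
        # path from a well bottom straight up one side of the well
        nodes = np.column_stack([np.linspace(-1.0, -0.4, 10), np.zeros(10)])
        path = thermo.ActionPath(nodes, 1.0, 0.0)
        bar = thermo.barrier_heights(land, path)
        U_path = land.interp_U(nodes)
        assert abs(bar["forward"] - (U_path[-1] - U_path[0])) < 0.2


class TestMFPT:
    def test_source_equals_target(self):
        ff = dw_ff(0.25, 0.0, 0.05)
        m, sem, ok = thermo.mfpt(ff, np.array([1.0, 0.0]), np.array([1.0, 0.0]))
        assert m == 0.0 and ok

    def test_kramers_oracle(self):
        b, D = 0.25, 0.05  # Phi = (x^2-1)^2/4
        ff = dw_ff(b, 0.0, D)
        kram = 2 * np.pi / np.sqrt(8 * b * 4 * b) * np.exp(b / D)
        m, sem, ok = thermo.mfpt(ff, np.array([-1.0, 0.0]), np.array([1.0, 0.0]),
                                 dt=2e-3, n_traj=100, t_max=3 * kram,
                                 capture_radius=0.2, seed=12, bounds=BOUNDS)
        assert ok
        assert kram / 2 <= m <= kram * 2

    def test_unreliable_flag_when_horizon_too_short(self):
        b, D = 0.25, 0.02  # barrier 12.5 kT: essentially no crossings
        ff = dw_ff(b, 0.0, D)
        m, sem, ok = thermo.mfpt(ff, np.array([-1.0, 0.0]), np.array([1.0, 0.0]),
                                 dt=2e-3, n_traj=30, t_max=5.0,
                                 capture_radius=0.2, seed=13, bounds=BOUNDS)
        assert not ok and m <= 5.0


class TestFluxAndEPR:
    def test_equilibrium_accumulated_flux_small(self, dw_equilibrium):
        b, D, ff, x0, land = dw_equilibrium
        path = thermo.least_action_path(ff, np.array([-1.0, 0.0]),
                                        np.array([1.0, 0.0]), P=30)
        jhat = thermo.accumulated_flux(ff, land, path)
        # reference magnitude: int |F| p dl along the path
        mid = 0.5 * (path.nodes[:-1] + path.nodes[1:])
        dl = np.linalg.norm(np.diff(path.nodes, axis=0), axis=1)
        ref = float(np.sum(np.linalg.norm(ff(mid), axis=1)
                           * land.interp_p(mid) * dl))
        assert abs(jhat) <= 0.05 * ref + 1e-4

    def test_symmetric_endpoints_zero_log_term(self, dw_equilibrium):
        *_, land = dw_equilibrium
        ff = dw_ff(0.15, 0.0, 0.08)
        nodes = np.column_stack([np.linspace(-1, 1, 20), np.zeros(20)])
        path = thermo.ActionPath(nodes, 1.0, 0.0)
        jhat = thermo.accumulated_flux(ff, land, path)
        line = None  # log term vanishes for equal endpoint densities
        logp = land.interp_logp(np.array([[-1.0, 0.0], [1.0, 0.0]]))
        assert abs(logp[1] - logp[0]) < 0.2

    def test_epr_rotational_ou_closed_form(self, linear_ff):
        for w, D in [(1.0, 0.1), (2.0, 0.05)]:
            A = np.array([[-1.0, w], [-w, -1.0]])
            ff = linear_ff(A, D)
            rng = np.random.default_rng(14)
            x0 = rng.normal(0, np.sqrt(D), (300, 2))
            s = 6 * np.sqrt(D)
            epr = thermo.epr_trajectory(ff, x0, dt=1e-3, n_steps=40000,
                                        n_traj=300, burn_in=4000, seed=14,
                                        bounds=np.array([[-s, s], [-s, s]]))
            assert abs(epr - 2 * D * w**2) <= 0.10 * 2 * D * w**2

    def test_epr_grid_estimator_rotational_ou(self, linear_ff):
        w, D = 1.0, 0.1
        A = np.array([[-1.0, w], [-w, -1.0]])
        ff = linear_ff(A, D)
        rng = np.random.default_rng(15)
        x0 = rng.normal(0, np.sqrt(D), (400, 2))
        s = 6 * np.sqrt(D)
        ens = dyn.simulate(ff, x0, dt=2e-3, n_steps=30000, n_traj=400,
                           burn_in=3000, seed=15,
                           bounds=np.array([[-s, s], [-s, s]]))
        land = dyn.steady_state_landscape(ens, grid=96)
        epr = thermo.entropy_production_rate(ff, land)
        assert abs(epr - 2 * D * w**2) <= 0.10 * 2 * D * w**2

    def test_detailed_balance_epr_ratio(self):
        b, D = 0.15, 0.08
        rng = np.random.default_rng(16)
        x0 = np.vstack([
            np.column_stack([rng.normal(-1, 0.2, 150), rng.normal(0, 0.3, 150)]),
            np.column_stack([rng.normal(1, 0.2, 150), rng.normal(0, 0.3, 150)]),
        ])
        e0 = thermo.epr_trajectory(dw_ff(b, 0.0, D), x0, dt=1e-3, n_steps=40000,
                                   n_traj=200, burn_in=4000, seed=17, bounds=BOUNDS)
        ec = thermo.epr_trajectory(dw_ff(b, 0.5, D), x0, dt=1e-3, n_steps=40000,
                                   n_traj=200, burn_in=4000, seed=18, bounds=BOUNDS)
        assert ec > 0
        assert abs(e0) <= 1e-2 * ec


class TestDiffusionScan:
    def test_single_D_no_trends(self):
        ff = dw_ff(0.15, 0.5, 0.08)
        rng = np.random.default_rng(19)
        x0 = np.vstack([
            np.column_stack([rng.normal(-1, 0.2, 100), rng.normal(0, 0.3, 100)]),
            np.column_stack([rng.normal(1, 0.2, 100), rng.normal(0, 0.3, 100)]),
        ])
        summaries, trends = thermo.diffusion_scan(
            ff, [0.08], x0,
            sim_kwargs=dict(n_steps=20000, burn_in=2000, bounds=BOUNDS),
            mfpt_kwargs=dict(n_traj=60, t_max=120.0), seed=19)
        assert len(summaries) == 1 and trends == {}
        assert summaries[0].n_basins >= 2

    def test_determinism(self):
        ff = dw_ff(0.15, 0.5, 0.08)
        rng = np.random.default_rng(20)
        x0 = np.vstack([
            np.column_stack([rng.normal(-1, 0.2, 100), rng.normal(0, 0.3, 100)]),
            np.column_stack([rng.normal(1, 0.2, 100), rng.normal(0, 0.3, 100)]),
        ])
        kw = dict(sim_kwargs=dict(n_steps=15000, burn_in=2000, bounds=BOUNDS),
                  mfpt_kwargs=dict(n_traj=40, t_max=60.0), seed=21)
        s1, _ = thermo.diffusion_scan(ff, [0.1], x0, **kw)
        s2, _ = thermo.diffusion_scan(ff, [0.1], x0, **kw)
        assert s1[0].mfpt == s2[0].mfpt
        assert s1[0].epr == s2[0].epr
        assert s1[0].barrier_fwd == s2[0].barrier_fwd
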