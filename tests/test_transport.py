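"""Advection–dispersion operators and stiff integration."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.optimize import brentq
from scipy.special import erfc

import vasctx as vx
from vasctx import units
from vasctx.transport import AssembledTransport, element_incidence


class TestTaylorDispersion:
    def test_no_flow_limit(self):
        assert vx.taylor_dispersion(5.46e4, 0.0, 5.0) == 5.46e4

    def test_capillary_value_si(self):
        # D̃=9.1e−10 m²/s, u=160 µm/s, r=5 µm → ≈9.25e−10 m²/s
        d = vx.taylor_dispersion(
            units.cm2_per_min_to_um2_per_min(5.46e-4),
            units.um_per_s_to_um_per_min(160.0), 5.0)
        d_si = d * 1e-12 / 60.0
        assert d_si == pytest.approx(9.25e-10, rel=2e-3)

    def test_shear_term_quadratic_in_velocity(self):
        d0 = 5.46e4
        add1 = vx.taylor_dispersion(d0, 100.0, 5.0) - d0
        add2 = vx.taylor_dispersion(d0, 200.0, 5.0) - d0
        # subtraction of the large molecular part limits the precision
        assert add2 == pytest.approx(4 * add1, rel=1e-6)

    def test_never_below_molecular(self):
        u = np.linspace(0, 1e5, 13)
        d = vx.taylor_dispersion(5.46e4, u, 10.0)
        assert np.all(d >= 5.46e4)

    def test_nonpositive_diffusivity_rejected(self):
        with pytest.raises(ValueError):
            vx.taylor_dispersion(0.0, 10.0, 5.0)


class TestOperators:
    def test_two_node_advection_balance(self, single_vessel_domain):
        _, _, dom = single_vessel_domain
        spc = vx.glucose()
        LQ, LD = vx.assemble_operators(dom, spc)
        # single-element expansion at the first element: upwind is node 0
        c = np.zeros(dom.n_nodes)
        c[0] = 2.0
        q = np.abs(dom.flow[0])
        out = LQ @ c
        assert out[0] == pytest.approx(-q * 2.0)

    def test_uniform_field_kills_dispersion(self, single_vessel_domain):
        _, _, dom = single_vessel_domain
        _, LD = vx.assemble_operators(dom, vx.glucose())
        np.testing.assert_allclose(LD @ np.ones(dom.n_nodes), 0.0,
                                   atol=1e-6)

    def test_zero_column_sums(self, sampled_63):
        sol = vx.solve_flow(sampled_63)
        dom = vx.refine_edges(sampled_63, sol)
        LQ, LD = vx.assemble_operators(dom, vx.glucose())
        scale = np.abs(LQ).max()
        np.testing.assert_allclose(np.asarray(LQ.sum(axis=0)).ravel(), 0.0,
                                   atol=1e-12 * scale)
        np.testing.assert_allclose(np.asarray(LD.sum(axis=0)).ravel(), 0.0,
                                   atol=1e-9)

    def test_dispersion_laplacian_drives_downhill(self, single_vessel_domain):
        _, _, dom = single_vessel_domain
        _, LD = vx.assemble_operators(dom, vx.glucose())
        c = dom.coords[:, 0].copy()   # linear profile along the tube
        rate = -(LD @ c) / dom.node_volume
        # zero curvature inside; the low end relaxes up, the high end down
        lo = int(np.argmin(c))
        hi = int(np.argmax(c))
        interior = np.ones(dom.n_nodes, dtype=bool)
        interior[[lo, hi]] = False
        np.testing.assert_allclose(rate[interior], 0.0, atol=1e-6)
        assert rate[lo] > 0 and rate[hi] < 0

    def test_reorienting_element_leaves_operator_unchanged(
            self, single_vessel_domain):
        _, _, dom = single_vessel_domain
        LQ1, _ = vx.assemble_operators(dom, vx.glucose())
        import copy
        dom2 = copy.copy(dom)
        dom2.tail = dom.tail.copy()
        dom2.head = dom.head.copy()
        dom2.flow = dom.flow.copy()
        dom2.tail[3], dom2.head[3] = dom.head[3], dom.tail[3]
        dom2.flow[3] = -dom.flow[3]
        LQ2, _ = vx.assemble_operators(dom2, vx.glucose())
        np.testing.assert_allclose(LQ1.toarray(), LQ2.toarray(), rtol=1e-14)

    def test_modified_incidence_selects_upwind(self, single_vessel_domain):
        _, _, dom = single_vessel_domain
        Mo = vx.modified_incidence(dom).toarray()
        for e in range(dom.n_elements):
            up = dom.tail[e] if dom.flow[e] >= 0 else dom.head[e]
            assert Mo[e, up] == -1.0
            assert np.count_nonzero(Mo[e]) == 1


def _fd_oracle_rhs(dom, asm, name, target):
    """Independently coded dense upwind tank-in-series RHS (loops only)."""
    m = dom.n_nodes
    dq = asm.dq[name]
    qabs = np.abs(dom.flow)
    tail = np.where(dom.flow >= 0, dom.tail, dom.head)
    head = np.where(dom.flow >= 0, dom.head, dom.tail)
    inlet = set(np.flatnonzero(dom.role == "inlet").tolist())
    outlet = set(np.flatnonzero(dom.role == "outlet").tolist())
    V = dom.node_volume

    def rhs(t, c_free, cin):
        c = np.empty(m)
        free_idx = [i for i in range(m) if i not in inlet]
        c[free_idx] = c_free
        for i in inlet:
            c[i] = cin(t)
        dc = np.zeros(m)
        for e in range(len(qabs)):
            a, b = int(tail[e]), int(head[e])
            adv = qabs[e] * c[a]
            dc[b] += adv
            dc[a] -= adv
            disp = dq[e] * (c[a] - c[b])
            dc[b] += disp
            dc[a] -= disp
        for i in outlet:
            dc[i] -= qabs[[e for e in range(len(qabs))
                           if int(head[e]) == i][0]] * c[i]
        return np.array([dc[i] / V[i] for i in free_idx])

    return rhs


class TestIntegration:
    def test_quiescent_state_stays_constant(self):
        net = vx.single_vessel(230.0, 10.0, p_in=0.0, p_out=0.0)
        dom = vx.refine_edges(net, vx.solve_flow(net))
        tm = vx.TransportModel(species=[vx.glucose()], inlet_conc={},
                               initial_conc={"glucose": 2.0}, t_span=(0, 10))
        res = vx.integrate_transport(dom, tm)
        np.testing.assert_allclose(res.conc["glucose"], 2.0, atol=1e-6)

    def test_step_inlet_reaches_dirichlet_steady_state(
            self, single_vessel_domain):
        _, _, dom = single_vessel_domain
        tm = vx.TransportModel(species=[vx.glucose()],
                               inlet_conc={"glucose": 5.0},
                               t_span=(0, 10.0), rtol=1e-8, atol=1e-10)
        res = vx.integrate_transport(dom, tm)
        g = res.conc["glucose"]
        np.testing.assert_allclose(g[-1], 5.0, atol=1e-6)
        # advancing front: mean concentration grows monotonically
        # (up to the integrator's local error)
        means = g.mean(axis=1)
        assert np.all(np.diff(means) >= -1e-6)

    def test_matches_independent_fd_oracle(self, single_vessel_domain):
        _, _, dom = single_vessel_domain
        tm = vx.TransportModel(species=[vx.glucose()],
                               inlet_conc={"glucose": 5.0},
                               t_span=(0, 2.0), n_out=50,
                               rtol=1e-10, atol=1e-12)
        res = vx.integrate_transport(dom, tm)
        asm = res.diagnostics["assembled"]
        rhs = _fd_oracle_rhs(dom, asm, "glucose", 5.0)
        free = asm.free["glucose"]
        t_grid = res.time
        sol = solve_ivp(
            lambda t, y: rhs(t, y, lambda tt: asm.inlet_value("glucose", tt)),
            (t_grid[0], t_grid[-1]), np.zeros(int(free.sum())),
            method="BDF", t_eval=t_grid, rtol=1e-10, atol=1e-12)
        assert sol.success
        mine = res.conc["glucose"][:, free]
        np.testing.assert_allclose(mine, sol.y.T, atol=1e-8)

    def test_positivity(self, single_vessel_domain):
        _, _, dom = single_vessel_domain
        tm = vx.TransportModel(species=[vx.glucose()],
                               inlet_conc={"glucose": 5.0}, t_span=(0, 5.0))
        res = vx.integrate_transport(dom, tm)
        assert res.conc["glucose"].min() >= -tm.atol

    def test_mass_balance_along_trajectory(self, single_vessel_domain):
        _, _, dom = single_vessel_domain
        tm = vx.TransportModel(species=[vx.glucose()],
                               inlet_conc={"glucose": 5.0}, t_span=(0, 5.0))
        res = vx.integrate_transport(dom, tm)
        assert vx.mass_balance_residual(res, "glucose") < 1e-6


class TestSmoothstep:
    def test_endpoints_and_midpoint(self):
        assert vx.smoothstep(0.0) == 0.0
        assert vx.smoothstep(1.0) == 1.0
        assert vx.smoothstep(0.5) == 0.5
        assert vx.smoothstep(2.0) == 1.0  # clamped

    def test_hard_step_when_ramp_disabled(self, single_vessel_domain):
        _, _, dom = single_vessel_domain
        tm = vx.TransportModel(species=[vx.glucose()],
                               inlet_conc={"glucose": 5.0}, t_ramp=0.0,
                               t_span=(0, 1.0))
        asm = AssembledTransport.build(dom, tm)
        assert asm.inlet_value("glucose", 0.0) == 5.0


class TestCstrLimit:
    def test_single_tank_exponential(self):
        """A 1-element vessel is a single stirred tank: the outlet node obeys
        V dC/dt = (Q + D·A/h)(C_in − C), an exponential relaxation whose
        10–90% rise time is τ·ln 9."""
        net = vx.single_vessel(11.0, 10.0, q_in_nl_min=1.0)
        sol = vx.solve_flow(net)
        dom = vx.refine_edges(net, sol)
        assert dom.n_elements == 1
        tm = vx.TransportModel(species=[vx.glucose()],
                               inlet_conc={"glucose": 1.0},
                               t_ramp=0.0, t_span=(0, 0.2), n_out=400,
                               rtol=1e-10, atol=1e-12)
        res = vx.integrate_transport(dom, tm)
        out = np.flatnonzero(dom.role == "outlet")[0]
        q = np.abs(dom.flow[0])
        dq = (vx.taylor_dispersion(vx.glucose().diffusivity,
                                   dom.velocity[0], dom.radius[0])
              * dom.area[0] / dom.h[0])
        tau_min = dom.node_volume[out] / (q + dq)
        c = res.conc["glucose"][:, out]
        expected = 1.0 - np.exp(-res.time / tau_min)
        np.testing.assert_allclose(c, expected, atol=1e-6)
        tr = vx.rise_time(res.time_s, c)
        assert tr == pytest.approx(
            units.minutes_to_seconds(tau_min) * np.log(9.0), rel=0.01)


class TestAnalyticBreakthrough:
    def test_ogata_banks_midpoint_time(self):
        """Tanks-in-series vs the closed-form 1-D advection–dispersion
        breakthrough in a dispersion-dominated regime (element Pe < 2)."""
        net = vx.single_vessel(460.0, 10.0, q_in_nl_min=0.05)
        sol = vx.solve_flow(net)
        dom = vx.refine_edges(net, sol)
        u = np.abs(dom.velocity[0])
        d_eff = vx.taylor_dispersion(vx.glucose().diffusivity, u,
                                     dom.radius[0])
        assert u * dom.h[0] / d_eff < 2.0
        tm = vx.TransportModel(species=[vx.glucose()],
                               inlet_conc={"glucose": 1.0}, t_ramp=0.0,
                               t_span=(0, 30.0), n_out=600,
                               rtol=1e-8, atol=1e-10)
        res = vx.integrate_transport(dom, tm)
        x = 230.0  # midpoint observation point
        node = int(np.argmin(np.abs(dom.coords[:, 0] - x)))

        def ogata_banks(t_min):
            t = max(t_min, 1e-12)
            s = 2.0 * np.sqrt(d_eff * t)
            return 0.5 * (erfc((x - u * t) / s)
                          + np.exp(u * x / d_eff) * erfc((x + u * t) / s))

        t_mid_analytic = brentq(lambda t: ogata_banks(t) - 0.5, 1e-9, 30.0)
        c = res.conc["glucose"][:, node]
        i = int(np.argmax(c >= 0.5))
        f = (0.5 - c[i - 1]) / (c[i] - c[i - 1])
        t_mid_model = res.time[i - 1] + f * (res.time[i] - res.time[i - 1])
        assert t_mid_model == pytest.approx(t_mid_analytic, rel=0.05)


class TestTransitScaling:
    def test_pressure_drop_ratio_scales_transit_time(self):
        """Stokes linearity: ΔP 20 Pa vs 200 Pa gives a 10.00× transit
        ratio on a fixed geometry."""
        times = {}
        for dp in (20.0, 200.0):
            net = vx.sampled_network(
                vx.FixtureSpec(n_edges=63, seed=42, p_in=dp, p_out=0.0))
            sol = vx.solve_flow(net)
            times[dp] = vx.transit_time(net, sol)
        assert times[20.0] / times[200.0] == pytest.approx(10.00, abs=0.01)
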