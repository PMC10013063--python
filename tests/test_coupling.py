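"""Vessel–tissue exchange, cell kinetics and the coupled system."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import vasctx as vx
from vasctx.coupling import DEFAULT_KINETICS, STOICHIOMETRY


class TestExchangeRate:
    def test_equilibrium_gives_zero(self):
        assert vx.exchange_rate(3.0, 3.0, 10.0, 1.0) == 0.0

    def test_fed_state_glucose_import_rate(self):
        # Vm=10, Km=1.0, C_bv=5, C_cell=0 → 10·5/(1+5) = 8.333 M/min
        assert vx.exchange_rate(5.0, 0.0, 10.0, 1.0) == pytest.approx(
            8.333, abs=1e-3)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(0, 50), st.floats(0, 50),
           st.floats(0.01, 100), st.floats(0.01, 100))
    def test_antisymmetry(self, a, b, vm, km):
        fwd = vx.exchange_rate(a, b, vm, km)
        rev = vx.exchange_rate(b, a, vm, km)
        assert fwd == pytest.approx(-rev, abs=1e-12)

    def test_nonpositive_km_rejected(self):
        with pytest.raises(ValueError):
            vx.exchange_rate(5.0, 0.0, 10.0, 0.0)


class TestEnzymeRate:
    def test_half_saturation(self):
        # A = Km = 4.5 → Vm/2 = 0.005 M/min
        assert vx.enzyme_rate(4.5, 0.01, 4.5) == pytest.approx(0.005)

    def test_zero_substrate(self):
        assert vx.enzyme_rate(0.0, 0.01, 4.5) == 0.0

    def test_saturation_limit(self):
        assert vx.enzyme_rate(1e9, 0.01, 4.5) == pytest.approx(0.01, rel=1e-6)

    def test_negative_substrate_rejected(self):
        with pytest.raises(ValueError):
            vx.enzyme_rate(-1.0, 0.01, 4.5)


class TestModelConstruction:
    def test_stoichiometric_matrix(self, single_vessel_domain):
        _, _, dom = single_vessel_domain
        model = vx.build_glucose_lactate_model(dom)
        np.testing.assert_array_equal(
            model.stoichiometry, [[1, -1, 0], [0, 2, -1]])

    def test_default_kinetic_parameters(self, single_vessel_domain):
        _, _, dom = single_vessel_domain
        model = vx.build_glucose_lactate_model(dom)
        assert model.kinetics["T2"] == {"Vm": 10.0, "Km": 0.5}
        assert model.kinetics["T1"] == {"Vm": 10.0, "Km": 1.0}
        assert model.kinetics["E"] == {"Vm": 0.01, "Km": 4.5}

    def test_default_inlet_levels(self, single_vessel_domain):
        _, _, dom = single_vessel_domain
        model = vx.build_glucose_lactate_model(dom)
        assert model.transport.inlet_conc == {"glucose": 5.0, "lactate": 1.2}

    def test_missing_tissue_volumes_rejected(self, single_vessel_domain):
        import copy
        _, _, dom = single_vessel_domain
        dom2 = copy.copy(dom)
        dom2.tissue_volume = None
        with pytest.raises(ValueError, match="tissue"):
            vx.build_glucose_lactate_model(dom2)


class TestCoupledRhs:
    def test_global_equilibrium_is_fixed_point(self, single_vessel_domain):
        _, _, dom = single_vessel_domain
        net = dom.net
        # closed, uniform state with no enzyme: all derivatives vanish
        quiet = vx.single_vessel(230.0, 10.0, p_in=0.0, p_out=0.0)
        qdom = vx.refine_edges(quiet, vx.solve_flow(quiet))
        tm = vx.TransportModel(species=[vx.glucose(), vx.lactate()],
                               inlet_conc={},
                               initial_conc={"glucose": 3.0, "lactate": 1.0})
        kin = {"T1": {"Vm": 10.0, "Km": 1.0}, "E": {"Vm": 0.0, "Km": 4.5},
               "T2": {"Vm": 10.0, "Km": 0.5}}
        model = vx.CoupledModel(dom=qdom, transport=tm, kinetics=kin)
        m = qdom.n_nodes
        nt = model.tissue_nodes.size
        state = np.concatenate([np.full(m, 3.0), np.full(m, 1.0),
                                np.full(nt, 3.0), np.full(nt, 1.0)])
        d = vx.coupled_rhs(0.0, state, model)
        np.testing.assert_allclose(d, 0.0, atol=1e-9)

    def test_closed_system_carbon_conservation_rate(self, single_vessel_domain):
        """d/dt[Σ V(C_A + C_B/2)] = 0 for any state of a closed system."""
        quiet = vx.single_vessel(230.0, 10.0, p_in=0.0, p_out=0.0)
        qdom = vx.refine_edges(quiet, vx.solve_flow(quiet))
        tm = vx.TransportModel(species=[vx.glucose(), vx.lactate()],
                               inlet_conc={})
        model = vx.CoupledModel(dom=qdom, transport=tm)
        m = qdom.n_nodes
        tn = model.tissue_nodes
        nt = tn.size
        rng = np.random.default_rng(1)
        state = rng.uniform(0.1, 8.0, 2 * m + 2 * nt)
        d = vx.coupled_rhs(0.0, state, model)
        V = qdom.node_volume
        vc = qdom.tissue_volume[tn]
        rate = (V @ d[:m] + 0.5 * (V @ d[m:2 * m])
                + vc @ d[2 * m:2 * m + nt] + 0.5 * (vc @ d[2 * m + nt:]))
        scale = float(np.abs(V @ d[:m])) + 1.0
        assert abs(rate) < 1e-9 * scale


class TestIntegrateCoupled:
    def test_zero_transporters_decouple_to_pure_transport(
            self, single_vessel_domain):
        _, _, dom = single_vessel_domain
        kin = {"T1": {"Vm": 0.0, "Km": 1.0}, "E": {"Vm": 0.01, "Km": 4.5},
               "T2": {"Vm": 0.0, "Km": 0.5}}
        model = vx.build_glucose_lactate_model(dom, kinetics=kin,
                                               t_span=(0, 5.0),
                                               rtol=1e-8, atol=1e-10)
        res = vx.integrate_coupled(model)
        pure = vx.integrate_transport(dom, model.transport)
        np.testing.assert_allclose(res.conc["glucose"],
                                   pure.conc["glucose"], atol=1e-6)
        np.testing.assert_allclose(res.conc["lactate"],
                                   pure.conc["lactate"], atol=1e-6)

    def test_zero_enzyme_equilibrates_cell_with_vessel(
            self, single_vessel_domain):
        _, _, dom = single_vessel_domain
        kin = {"T1": {"Vm": 10.0, "Km": 1.0}, "E": {"Vm": 0.0, "Km": 4.5},
               "T2": {"Vm": 10.0, "Km": 0.5}}
        model = vx.build_glucose_lactate_model(dom, kinetics=kin,
                                               t_span=(0, 30.0))
        res = vx.integrate_coupled(model)
        tn = res.diagnostics["tissue_nodes"]
        a_bv = res.conc["glucose"][-1][tn]
        np.testing.assert_allclose(res.cell_conc["A"][-1], a_bv, atol=1e-3)

    def test_fed_state_event_ordering(self, single_vessel_domain):
        """Glucose step at the inlet: cell glucose rises first, cell lactate
        follows, and vessel lactate ends above its 1.2 mM basal level."""
        _, _, dom = single_vessel_domain
        model = vx.build_glucose_lactate_model(dom, t_span=(0, 30.0))
        res = vx.integrate_coupled(model)
        t = res.time_s
        a_cell = res.cell_conc["A"].mean(axis=1)
        b_cell = res.cell_conc["B"].mean(axis=1)

        def crossing(series, level):
            idx = np.flatnonzero(series >= level)
            return t[idx[0]] if idx.size else np.inf

        assert crossing(a_cell, 1.0) < crossing(b_cell, 1.0)
        tn = res.diagnostics["tissue_nodes"]
        downstream = tn[np.argmax(dom.path_distance_from_inlet()[tn])]
        assert res.conc["lactate"][-1, downstream] > 1.2

    def test_dose_monotonicity_of_net_uptake(self, single_vessel_domain):
        _, _, dom = single_vessel_domain
        totals = []
        for dose in (3.0, 10.0):
            model = vx.build_glucose_lactate_model(dom, glucose_in=dose,
                                                   t_span=(0, 10.0))
            totals.append(vx.net_exchange_totals(vx.integrate_coupled(model)))
        assert totals[1]["glucose_uptake"] > totals[0]["glucose_uptake"]
        assert totals[1]["lactate_release"] >= totals[0]["lactate_release"]


class TestConservation:
    def test_closed_system_carbon_drift(self, closed_coupled_result):
        tot = vx.carbon_total(closed_coupled_result)
        drift = (tot.max() - tot.min()) / tot[0]
        assert drift < 1e-8

    def test_exchange_bookkeeping_matches_cell_gain(self, single_vessel_domain):
        """With no enzyme, time-integrated uptake equals the final amount of
        glucose stored in the cells (mole bookkeeping across compartments)."""
        _, _, dom = single_vessel_domain
        kin = {"T1": {"Vm": 10.0, "Km": 1.0}, "E": {"Vm": 0.0, "Km": 4.5},
               "T2": {"Vm": 10.0, "Km": 0.5}}
        model = vx.build_glucose_lactate_model(dom, kinetics=kin,
                                               t_span=(0, 30.0), n_out=800,
                                               rtol=1e-8, atol=1e-10)
        res = vx.integrate_coupled(model)
        totals = vx.net_exchange_totals(res)
        tn = res.diagnostics["tissue_nodes"]
        vcell = dom.tissue_volume[tn]
        final_amount = float(vcell @ res.cell_conc["A"][-1])
        assert totals["glucose_uptake"] == pytest.approx(final_amount,
                                                         rel=1e-2)
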