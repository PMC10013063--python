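import numpy as np
import pytest

import vasctx as vx


@pytest.fixture(scope="session")
def single_vessel_domain():
    """A 230 µm, d=10 µm capillary at 3.76 nl/min, refined to 20 elements."""
    net = vx.single_vessel(230.0, 10.0, q_in_nl_min=3.76)
    sol = vx.solve_flow(net)
    dom = vx.refine_edges(net, sol)
    return net, sol, dom


@pytest.fixture(scope="session")
def diamond():
    net, expected = vx.diamond_loop()
    return net, expected, vx.solve_flow(net)


@pytest.fixture(scope="session")
def sampled_63():
    """63-segment random capillary tree (typical skeleton size)."""
    return vx.sampled_network(vx.FixtureSpec(n_edges=63, seed=42))


@pytest.fixture(scope="session")
def closed_coupled_result():
    """Closed-system glucose-lactate run: zero flow, no Dirichlet forcing."""
    net = vx.single_vessel(230.0, 10.0, p_in=0.0, p_out=0.0)
    dom = vx.refine_edges(net, vx.solve_flow(net))
    tm = vx.TransportModel(
        species=[vx.glucose(), vx.lactate()], inlet_conc={},
        initial_conc={"glucose": 5.0, "lactate": 1.2},
        t_span=(0.0, 60.0), rtol=1e-8, atol=1e-10)
    model = vx.CoupledModel(dom=dom, transport=tm)
    return vx.integrate_coupled(model)
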