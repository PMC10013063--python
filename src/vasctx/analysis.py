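"""Post-processing metrics: rise times, transit time, dimensionless groups,
net exchange totals and conservation diagnostics."""

from __future__ import annotations

import numpy as np

from . import units
from .discretize import DiscretizedDomain
from .flow import FlowSolution
from .network import VascularNetwork
from .transport import SimulationResult


def rise_time(t, c, lo: float = 0.10, hi: float = 0.90,
              ss_rel_tol: float = 1e-4):
    """10–90% rise time of a concentration series (units of ``t``).

    The steady-state value is the final sample, accepted only if the
    relative change over the last 5% of the span is below ``ss_rel_tol``.
    Crossings of lo·C_ss and hi·C_ss are located by linear interpolation.
    Returns ``None`` (missing) when no steady state is reached or the
    series never crosses the thresholds.
    """
    t = np.asarray(t, dtype=float)
    c = np.asarray(c, dtype=float)
    if t.size < 2:
        return None
    c_ss = c[-1]
    tail = c[t >= t[-1] - 0.05 * (t[-1] - t[0])]
    scale = max(abs(c_ss), 1e-300)
    if tail.size and (tail.max() - tail.min()) / scale > ss_rel_tol:
        return None
    if c_ss <= 0:
        return None

    def first_crossing(level):
        above = c >= level
        if above[0]:
            return t[0]
        idx = np.flatnonzero(above)
        if idx.size == 0:
            return None
        i = idx[0]
        # linear interpolation between samples i-1 and i
        f = (level - c[i - 1]) / (c[i] - c[i - 1])
        return t[i - 1] + f * (t[i] - t[i - 1])

    t_lo = first_crossing(lo * c_ss)
    t_hi = first_crossing(hi * c_ss)
    if t_lo is None or t_hi is None:
        return None
    return float(t_hi - t_lo)


def transit_time(dom_or_net, flow: FlowSolution) -> float:
    """Mean residence time (seconds): luminal volume / total inlet inflow.

    Accepts either a network or a discretized domain (the luminal volume
    is identical by construction).  Inflow is read off the solved flow at
    the inlet nodes, so the metric works for pressure- and flow-driven
    boundary conditions alike.
    """
    if isinstance(dom_or_net, DiscretizedDomain):
        net = dom_or_net.net
        volume = float(np.sum(dom_or_net.node_volume))
    else:
        net = dom_or_net
        volume = net.luminal_volume

    inflow = 0.0
    for e in range(net.n_edges):
        if net.role[net.tail[e]] == "inlet":
            inflow += flow.flow[e]
        elif net.role[net.head[e]] == "inlet":
            inflow -= flow.flow[e]
    if inflow <= 0:
        raise ValueError("no positive inlet inflow")
    return units.minutes_to_seconds(volume / inflow)


def peclet(u, l, d_mol):
    """Peclet number Pe = u·l/D̃ per branch (consistent units)."""
    d_mol = np.asarray(d_mol, dtype=float)
    if np.any(d_mol <= 0):
        raise ValueError("diffusivity must be positive")
    return np.abs(np.asarray(u, dtype=float)) * np.asarray(l, dtype=float) / d_mol


def schmidt(mu: float, rho: float, d_mol_m2_s: float) -> float:
    """Schmidt number Sc = ν/D̃ = (µ/ρ)/D̃ (SI inputs)."""
    if mu <= 0 or rho <= 0 or d_mol_m2_s <= 0:
        raise ValueError("all inputs must be positive")
    return (mu / rho) / d_mol_m2_s


def total_moles(result: SimulationResult, name: str) -> np.ndarray:
    """Σ_i V_i C_i(t) over vessel nodes (µm³·mM) for one species."""
    V = result.domain.node_volume
    return result.conc[name] @ V


def mass_balance_residual(result: SimulationResult, name: str) -> float:
    """Max relative defect of d/dt(Σ V C) = influx − outflux on the grid.

    Evaluates the semi-discrete identity at every saved state: the rate of
    change of the free-node vessel moles implied by the RHS operator must
    equal the net boundary flux (advective + dispersive at the forced
    inlet, advective at the outlets).  Pure-transport results only.
    """
    from .transport import transport_rhs

    asm = result.diagnostics["assembled"]
    dom, model = result.domain, asm.model
    m = dom.n_nodes
    names = [s.name for s in model.species]
    k = names.index(name)
    freemask = asm.free[name]
    worst = 0.0
    for j, tj in enumerate(result.time):
        c_full = np.concatenate([result.conc[nm][j] for nm in names])
        d = transport_rhs(tj, c_full, dom, model, _asm=asm)[k * m:(k + 1) * m]
        ck = result.conc[name][j]
        lhs = float(dom.node_volume[freemask] @ d[freemask])
        influx, outflux = asm.boundary_fluxes(name, tj, ck)
        scale = max(abs(influx), abs(outflux), 1e-12)
        worst = max(worst, abs(lhs - (influx - outflux)) / scale)
    return worst


def net_exchange_totals(result: SimulationResult) -> dict:
    """Time-integrated exchange fluxes of a coupled run (µm³·mM).

    Returns ``{"glucose_uptake": ..., "lactate_release": ...}``: the
    trapezoid-integrated Σ_i V_i^cell v_i over the output grid, positive
    for glucose moving into the tissue and lactate moving into the blood.
    """
    from .coupling import reaction_rates

    if result.cell_conc is None:
        raise ValueError("not a coupled result: no exchange fluxes to total")
    model = result.diagnostics["model"]
    tn = result.diagnostics["tissue_nodes"]
    vcell = model.dom.tissue_volume[tn]
    names = [s.name for s in model.transport.species]

    uptake = np.empty(result.time.size)
    release = np.empty(result.time.size)
    for j in range(result.time.size):
        a_bv = result.conc[names[0]][j][tn]
        b_bv = result.conc[names[1]][j][tn]
        v_t1, _, v_t2 = reaction_rates(model, a_bv, b_bv,
                                       result.cell_conc["A"][j],
                                       result.cell_conc["B"][j])
        uptake[j] = float(vcell @ v_t1)
        release[j] = float(vcell @ v_t2)
    return {
        "glucose_uptake": float(np.trapezoid(uptake, result.time)),
        "lactate_release": float(np.trapezoid(release, result.time)),
    }


def carbon_total(result: SimulationResult) -> np.ndarray:
    """Closed-system conserved quantity Σ V·(C_A + C_B/2) over time.

    Glucose (6 carbons) converts to two lactates (3 carbons each), so
    A + B/2 weighted by compartment volume is invariant when no mass
    crosses the network boundary.
    """
    model = result.diagnostics["model"]
    names = [s.name for s in model.transport.species]
    V = result.domain.node_volume
    tn = result.diagnostics["tissue_nodes"]
    vcell = model.dom.tissue_volume[tn]
    total = (result.conc[names[0]] @ V) + 0.5 * (result.conc[names[1]] @ V)
    total += (result.cell_conc["A"] @ vcell) + 0.5 * (result.cell_conc["B"] @ vcell)
    return total
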