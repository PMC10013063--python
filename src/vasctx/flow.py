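"""Steady Hagen–Poiseuille flow distribution on a vascular network.

Each vessel segment is a laminar Poiseuille conduit with conductance
G = π r⁴ / (8 µ l), so the edge flow is Q_e = G_e (p_tail − p_head) along
the stored orientation.  Mass conservation at every interior node closes
the system Mᵀ G M P = b: a weighted graph Laplacian acting on nodal
pressures, with prescribed boundary flows on the right-hand side and
prescribed boundary pressures eliminated into it.  The reduced system is
solved by SVD-based least squares (pseudoinverse), which also handles the
rank-deficient cases that arise with redundant anchors.

The linear (Stokes) regime assumed here requires Re < 1 in every segment;
:func:`reynolds_numbers` lets callers verify that after the fact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from . import units
from .network import (VascularNetwork, incidence_matrix, validate_network,
                      NetworkValidationError)

#: default blood viscosity, Pa·s (Newtonian approximation)
DEFAULT_MU = 0.004
#: default blood density, kg/m³
DEFAULT_RHO = 1000.0


@dataclass
class FlowSolution:
    """Solved pressure/flow field on a network.

    Attributes
    ----------
    pressure : (m,) nodal pressures, Pa.
    flow : (n,) edge volumetric flows, µm³/min, signed with the stored
        orientation (positive = tail → head).
    velocity : (n,) edge mean velocities Q/(πr²), µm/min.
    conductance : (n,) edge conductances, µm³/(min·Pa).
    residual : max interior node imbalance |div Q|, µm³/min.
    """

    pressure: np.ndarray
    flow: np.ndarray
    velocity: np.ndarray
    conductance: np.ndarray
    residual: float

    @property
    def flow_nl_min(self) -> np.ndarray:
        return units.um3_per_min_to_nl_per_min(self.flow)

    @property
    def velocity_um_s(self) -> np.ndarray:
        return units.um_per_min_to_um_per_s(self.velocity)

    def edge_velocity(self, convention: str = "mean") -> np.ndarray:
        """Velocity per edge (µm/min): ``mean`` Q/(πr²) or ``centerline`` 2Q/(πr²)."""
        if convention == "mean":
            return self.velocity
        if convention == "centerline":
            return 2.0 * self.velocity
        raise ValueError(f"unknown velocity convention {convention!r}")


def edge_conductance(r, l, mu: float) -> np.ndarray:
    """Hagen–Poiseuille conductance G = π r⁴ / (8 µ l).

    ``r``, ``l`` in µm, ``mu`` in Pa·s; result in canonical µm³/(min·Pa).
    """
    r = np.asarray(r, dtype=float)
    l = np.asarray(l, dtype=float)
    if np.any(r <= 0) or np.any(l <= 0) or mu <= 0:
        raise ValueError("radius, length and viscosity must be positive")
    return np.pi * r**4 / (8.0 * units.pa_s_to_pa_min(mu) * l)


def boundary_vector(net: VascularNetwork) -> np.ndarray:
    """Boundary flow vector q~ (µm³/min): −Q_in at inlet flow-BC nodes,
    +Q_out at outlet flow-BC nodes, 0 elsewhere.

    The sign convention matches the discrete accumulation −MᵀQ: fluid
    entering the network from outside shows up as a negative entry.
    """
    q = np.zeros(net.n_nodes)
    flow_nodes = np.flatnonzero(net.bc_kind == "flow")
    for i in flow_nodes:
        if net.role[i] == "inlet":
            q[i] = -net.bc_value[i]
        elif net.role[i] == "outlet":
            q[i] = +net.bc_value[i]
        else:
            raise NetworkValidationError(
                f"flow boundary condition on interior node {net.node_ids[i]!r}")
    if not np.any(net.bc_kind == "pressure"):
        # all-flow network: feasible only if boundary flows balance
        if abs(q.sum()) > 1e-9 * (np.abs(q).sum() + 1.0):
            raise NetworkValidationError(
                "flow boundary conditions do not sum to zero and no pressure "
                "anchor is present")
    return q


def inflow_for_velocity(net: VascularNetwork, v_um_s: float) -> float:
    """Inlet volumetric flow (µm³/min) realizing a mean inlet velocity.

    Uses the cross-section of the (single) edge attached to the inlet node:
    Q = v · π r².
    """
    inlets = np.flatnonzero(net.role == "inlet")
    if inlets.size != 1:
        raise ValueError("network must have exactly one inlet")
    e = [k for k in range(net.n_edges)
         if net.tail[k] == inlets[0] or net.head[k] == inlets[0]]
    area = net.area[e[0]]
    return units.um_per_s_to_um_per_min(v_um_s) * area


def solve_flow(net: VascularNetwork, mu: float = DEFAULT_MU) -> FlowSolution:
    """Solve the nodal-pressure system and back out edge flows/velocities.

    Pressure-BC nodes are eliminated: their columns of the Laplacian,
    scaled by the known pressures, move to the right-hand side, and their
    rows (whose boundary flow is the unknown reaction) are dropped.  The
    reduced system is solved with an SVD-based least-squares solve.
    """
    problems = validate_network(net)
    if problems:
        raise NetworkValidationError("; ".join(problems))

    m = net.n_nodes
    M = incidence_matrix(net)
    G = edge_conductance(net.radius, net.length, mu)
    L = (M.T @ sp.diags(G) @ M).tocsr()
    q = boundary_vector(net)

    known = net.bc_kind == "pressure"
    free = ~known
    p = np.zeros(m)
    p[known] = net.bc_value[known]

    # Mᵀ G M P = −q~ at every non-anchored node
    rhs = -q[free] - L[np.ix_(free, known)] @ p[known]
    A = L[np.ix_(free, free)].toarray()
    sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    p[free] = sol

    Q = G * (M @ p)
    u = Q / net.area

    div = flow_divergence(net, Q)
    interior = net.role == "interior"
    residual = float(np.max(np.abs(div[interior]))) if interior.any() else 0.0
    return FlowSolution(pressure=p, flow=Q, velocity=u, conductance=G,
                        residual=residual)


def flow_divergence(net: VascularNetwork, Q: np.ndarray) -> np.ndarray:
    """Net accumulation −MᵀQ per node (µm³/min).

    Interior entries vanish for a conservative flow field; boundary
    entries equal the boundary flows in the q~ sign convention (negative
    at inlets, positive at outlets).
    """
    M = incidence_matrix(net)
    return -(M.T @ np.asarray(Q, dtype=float))


def reynolds_numbers(sol: FlowSolution, net: VascularNetwork,
                     rho: float = DEFAULT_RHO, mu: float = DEFAULT_MU) -> np.ndarray:
    """Per-edge Reynolds number Re = ρ |u| d / µ (SI inputs ρ, µ)."""
    u_m_s = units.um_per_min_to_um_per_s(np.abs(sol.velocity)) / units.M_UM
    d_m = net.diameter / units.M_UM
    return rho * u_m_s * d_m / mu
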