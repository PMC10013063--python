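"""Graph advection–dispersion of solutes over the discretized domain.

The refined network is treated as a tank-in-series model: every refined
node is a well-mixed volume element, every element carries an advective
flux (upwind concentration × volumetric flow) and a dispersive flux
(volumetric dispersion coefficient D·A/h × concentration difference).
Axial dispersion is augmented by the Aris–Taylor shear contribution
u²r²/(48·D̃).  In matrix form the nodal mole balance reads

    V dC/dt = L_Q C − L_D C,

with L_Q = MᵀQM° the flow-weighted advection Laplacian (M° selecting the
upwind node of each flow-aligned element) and L_D = MᵀD_Q M the weighted
dispersion Laplacian.  Inlet nodes are Dirichlet-forced (optionally via a
smoothed step) and eliminated from the free state; outlet nodes carry a
pure advective sink with zero added dispersive boundary flux.  The stiff
system is integrated with BDF using the operators' sparsity pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.integrate import solve_ivp

from . import units
from .discretize import DiscretizedDomain

#: molecular diffusivity of glucose in blood plasma, cm²/min
GLUCOSE_D_CM2_MIN = 5.46e-4
#: molecular diffusivity of lactate in blood plasma, cm²/min
LACTATE_D_CM2_MIN = 7.71e-4


@dataclass(frozen=True)
class Species:
    """A transported solute with molecular diffusivity in µm²/min."""

    name: str
    diffusivity: float  # µm²/min

    def __post_init__(self):
        if not self.diffusivity > 0:
            raise ValueError("diffusivity must be positive")

    @classmethod
    def from_cm2_per_min(cls, name: str, d_cm2_min: float) -> "Species":
        return cls(name, units.cm2_per_min_to_um2_per_min(d_cm2_min))


def glucose() -> Species:
    return Species.from_cm2_per_min("glucose", GLUCOSE_D_CM2_MIN)


def lactate() -> Species:
    return Species.from_cm2_per_min("lactate", LACTATE_D_CM2_MIN)


@dataclass
class TransportModel:
    """Species, boundary/initial data and solver options for a transport run.

    ``inlet_conc`` maps species name → Dirichlet value (mM) applied at all
    inlet nodes; species absent from the map are not forced (their inlet
    node stays a free state — this is how closed/recirculating runs are
    set up).  ``initial_conc`` maps species name → scalar or per-node
    array (mM).  ``t_ramp`` (s) smooths the inlet step with
    s(x) = 3x² − 2x³; 0 disables smoothing.  ``t_span`` and the output
    grid are in seconds; tolerances are passed to the BDF integrator.
    """

    species: list[Species]
    inlet_conc: dict = field(default_factory=dict)
    initial_conc: dict = field(default_factory=dict)
    t_ramp: float = 0.1
    t_span: tuple = (0.0, 15.0)
    n_out: int = 200
    rtol: float = 1e-3
    atol: float = 1e-6
    velocity_convention: str = "mean"

    def __post_init__(self):
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ValueError("duplicate species names")
        for v in self.initial_conc.values():
            if np.any(np.asarray(v) < 0):
                raise ValueError("initial concentrations must be nonnegative")

    def species_by_name(self, name: str) -> Species:
        for s in self.species:
            if s.name == name:
                return s
        raise KeyError(name)


@dataclass
class SimulationResult:
    """Trajectories on the refined domain.

    ``time`` is the output grid in minutes (``time_s`` in seconds);
    ``conc[name]`` is an (n_times, n_nodes) array in mM including the
    Dirichlet-forced nodes; ``cell_conc`` is filled by coupled runs.
    """

    domain: DiscretizedDomain
    time: np.ndarray
    conc: dict
    cell_conc: dict | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def time_s(self) -> np.ndarray:
        return units.minutes_to_seconds(self.time)

    def series(self, name: str, node: int) -> np.ndarray:
        return self.conc[name][:, node]


def taylor_dispersion(d_mol, u, r):
    """Aris–Taylor effective axial dispersion D = D̃ + u²r²/(48·D̃).

    Canonical units: ``d_mol`` µm²/min, ``u`` µm/min, ``r`` µm.  The shear
    term is nonnegative, so D ≥ D̃ always.
    """
    d_mol = np.asarray(d_mol, dtype=float)
    if np.any(d_mol <= 0):
        raise ValueError("molecular diffusivity must be positive")
    u = np.asarray(u, dtype=float)
    r = np.asarray(r, dtype=float)
    return d_mol + (u * r) ** 2 / (48.0 * d_mol)


def _reoriented(dom: DiscretizedDomain):
    """Element tails/heads flipped so flows are nonnegative."""
    flip = dom.flow < 0
    tail = np.where(flip, dom.head, dom.tail)
    head = np.where(flip, dom.tail, dom.head)
    return tail, head, np.abs(dom.flow)


def element_incidence(dom: DiscretizedDomain) -> sp.csr_matrix:
    """Signed incidence of the refined graph (stored orientation)."""
    n, m = dom.n_elements, dom.n_nodes
    rows = np.repeat(np.arange(n), 2)
    cols = np.empty(2 * n, dtype=int)
    cols[0::2] = dom.tail
    cols[1::2] = dom.head
    data = np.tile([1.0, -1.0], n)
    return sp.csr_matrix((data, (rows, cols)), shape=(n, m))


def modified_incidence(dom: DiscretizedDomain) -> sp.csr_matrix:
    """Upwind selector M° (n×m): −1 at each element's upwind node.

    Elements are first reoriented along the local flow; zero-flow elements
    contribute an all-zero row (no advection).
    """
    tail, head, qabs = _reoriented(dom)
    n, m = dom.n_elements, dom.n_nodes
    rows, cols, data = [], [], []
    for e in range(n):
        if qabs[e] > 0:
            rows.append(e)
            cols.append(tail[e])
            data.append(-1.0)
    return sp.csr_matrix((data, (rows, cols)), shape=(n, m))


def assemble_operators(dom: DiscretizedDomain, species: Species,
                       velocity_convention: str = "mean"):
    """Sparse (L_Q, L_D) for one species on the refined domain.

    L_Q = MᵀQM° (advection, upwind), L_D = MᵀD_Q M (dispersion) with
    D_Q = diag(D·A/h) and D from the Aris–Taylor relation.  Both have zero
    column sums (interior mass conservation) and appear in the balance as
    V dC/dt = L_Q C − L_D C.
    """
    tail, head, qabs = _reoriented(dom)
    n, m = dom.n_elements, dom.n_nodes

    rows = np.repeat(np.arange(n), 2)
    cols = np.empty(2 * n, dtype=int)
    cols[0::2] = tail
    cols[1::2] = head
    data = np.tile([1.0, -1.0], n)
    Mr = sp.csr_matrix((data, (rows, cols)), shape=(n, m))
    Mo = sp.csr_matrix((-np.ones(n), (np.arange(n), tail)), shape=(n, m))
    LQ = (Mr.T @ sp.diags(qabs) @ Mo).tocsr()

    u = dom.velocity
    if velocity_convention == "centerline":
        u = 2.0 * u
    elif velocity_convention != "mean":
        raise ValueError(f"unknown velocity convention {velocity_convention!r}")
    D = taylor_dispersion(species.diffusivity, u, dom.radius)
    dq = D * dom.area / dom.h
    M = element_incidence(dom)
    LD = (M.T @ sp.diags(dq) @ M).tocsr()
    return LQ, LD


def smoothstep(x):
    """Cubic smoothed step s(x) = 3x² − 2x³ clamped to [0, 1]."""
    x = np.clip(x, 0.0, 1.0)
    return 3.0 * x**2 - 2.0 * x**3


@dataclass
class AssembledTransport:
    """Operators plus boundary bookkeeping for one transport problem.

    The RHS matrix per species is T = L_Q − L_D with an extra advective
    sink −Q on the diagonal of each outlet node; Dirichlet inlet nodes are
    eliminated from the free state and enter through the T[:, inlet]
    columns as a forcing term.
    """

    dom: DiscretizedDomain
    model: TransportModel
    T: dict                 # species name -> csr (m×m)
    volume: np.ndarray      # V^bv, µm³
    free: dict              # species name -> bool mask of free nodes
    dirichlet: dict         # species name -> (node indices, target mM)
    dq: dict = field(default_factory=dict)  # name -> D·A/h per element

    @classmethod
    def build(cls, dom: DiscretizedDomain, model: TransportModel):
        m = dom.n_nodes
        V = dom.node_volume
        if V is None or np.any(V <= 0):
            raise ValueError("domain must carry positive nodal volumes")

        tail, head, qabs = _reoriented(dom)
        outlet_sink = np.zeros(m)
        for e in range(dom.n_elements):
            if dom.role[head[e]] == "outlet":
                outlet_sink[head[e]] += qabs[e]

        T, free, diri, dqs = {}, {}, {}, {}
        inlets = np.flatnonzero(dom.role == "inlet")
        for spc in model.species:
            LQ, LD = assemble_operators(dom, spc, model.velocity_convention)
            Ts = (LQ - LD - sp.diags(outlet_sink)).tocsr()
            T[spc.name] = Ts
            u = dom.velocity
            if model.velocity_convention == "centerline":
                u = 2.0 * u
            dqs[spc.name] = (taylor_dispersion(spc.diffusivity, u, dom.radius)
                             * dom.area / dom.h)
            mask = np.ones(m, dtype=bool)
            if spc.name in model.inlet_conc:
                mask[inlets] = False
                diri[spc.name] = (inlets, float(model.inlet_conc[spc.name]))
            else:
                diri[spc.name] = (np.array([], dtype=int), 0.0)
            free[spc.name] = mask
        return cls(dom=dom, model=model, T=T, volume=V, free=free,
                   dirichlet=diri, dq=dqs)

    def inlet_value(self, name: str, t_min: float) -> float:
        """Dirichlet value C_in(t) (mM) at time t (minutes)."""
        _, target = self.dirichlet[name]
        ramp_min = units.seconds_to_minutes(self.model.t_ramp)
        if ramp_min <= 0:
            return target
        return target * float(smoothstep(t_min / ramp_min))

    def full_state(self, name: str, t_min: float, c_free: np.ndarray) -> np.ndarray:
        c = np.empty(self.dom.n_nodes)
        c[self.free[name]] = c_free
        nodes, _ = self.dirichlet[name]
        if nodes.size:
            c[nodes] = self.inlet_value(name, t_min)
        return c

    def initial_full(self, name: str) -> np.ndarray:
        c0 = self.model.initial_conc.get(name, 0.0)
        return np.broadcast_to(np.asarray(c0, dtype=float),
                               (self.dom.n_nodes,)).copy()

    def boundary_fluxes(self, name: str, t_min: float,
                        c_full: np.ndarray) -> tuple[float, float]:
        """(influx, outflux) across the free-state boundary (µm³·mM/min).

        Influx enters through elements leaving a Dirichlet-forced inlet
        node and has an advective part Q·C_in and a dispersive part
        (D·A/h)(C_in − C_neighbor); outflux is the advective sink Q·C at
        outlet nodes.  Together they balance d/dt of the free-node moles
        exactly (the operators' column sums vanish elsewhere).
        """
        tail, head, qabs = _reoriented(self.dom)
        nodes, _ = self.dirichlet[name]
        forced = set(int(i) for i in nodes)
        dq = self.dq[name]
        influx = outflux = 0.0
        for e in range(self.dom.n_elements):
            a, b = int(tail[e]), int(head[e])
            if a in forced:
                influx += (qabs[e] * c_full[a]
                           + dq[e] * (c_full[a] - c_full[b]))
            elif b in forced:
                influx += dq[e] * (c_full[b] - c_full[a]) - qabs[e] * c_full[a]
            if self.dom.role[b] == "outlet" and b not in forced:
                outflux += qabs[e] * c_full[b]
        return influx, outflux


def transport_rhs(t, c, dom: DiscretizedDomain, model: TransportModel,
                  _asm: AssembledTransport | None = None) -> np.ndarray:
    """Full-state time derivative (mM/min), all species stacked.

    ``c`` holds every refined node for each species in model order; inlet
    Dirichlet entries follow their forcing (their returned derivative is
    the ramp derivative).  ``t`` is in minutes.
    """
    asm = _asm or AssembledTransport.build(dom, model)
    m = dom.n_nodes
    c = np.asarray(c, dtype=float)
    if np.any(~np.isfinite(c)):
        raise FloatingPointError("NaN/inf in transport state")
    out = np.empty_like(c)
    ramp_min = units.seconds_to_minutes(model.t_ramp)
    for k, spc in enumerate(model.species):
        ck = c[k * m:(k + 1) * m]
        dck = (asm.T[spc.name] @ ck) / asm.volume
        nodes, target = asm.dirichlet[spc.name]
        if nodes.size:
            if ramp_min > 0 and t < ramp_min:
                x = t / ramp_min
                dck[nodes] = target * (6.0 * x - 6.0 * x**2) / ramp_min
            else:
                dck[nodes] = 0.0
        out[k * m:(k + 1) * m] = dck
    return out


def integrate_transport(dom: DiscretizedDomain,
                        model: TransportModel) -> SimulationResult:
    """Integrate the advection–dispersion system with BDF.

    Inlet Dirichlet nodes are eliminated from the ODE state; the sparsity
    pattern of the reduced operator is supplied to the solver.  Output is
    evaluated on ``model.n_out`` evenly spaced times over ``model.t_span``
    (seconds).
    """
    asm = AssembledTransport.build(dom, model)
    m = dom.n_nodes

    blocks, x0 = [], []
    for spc in model.species:
        mask = asm.free[spc.name]
        blocks.append(asm.T[spc.name][np.ix_(mask, mask)])
        full0 = asm.initial_full(spc.name)
        x0.append(full0[mask])
    x0 = np.concatenate(x0)
    sizes = [int(mask.sum()) for mask in
             (asm.free[s.name] for s in model.species)]
    offsets = np.concatenate([[0], np.cumsum(sizes)])

    def rhs(t, x):
        out = np.empty_like(x)
        for k, spc in enumerate(model.species):
            mask = asm.free[spc.name]
            xk = x[offsets[k]:offsets[k + 1]]
            r = asm.T[spc.name][np.ix_(mask, mask)] @ xk
            nodes, _ = asm.dirichlet[spc.name]
            if nodes.size:
                cin = asm.inlet_value(spc.name, t)
                r = r + asm.T[spc.name][np.ix_(mask, nodes)] @ np.full(
                    nodes.size, cin)
            out[offsets[k]:offsets[k + 1]] = r / asm.volume[mask]
        return out

    pattern = sp.block_diag(
        [b != 0 for b in blocks], format="csr").astype(float)

    t0, t1 = (units.seconds_to_minutes(t) for t in model.t_span)
    t_eval = np.linspace(t0, t1, model.n_out)
    sol = solve_ivp(rhs, (t0, t1), x0, method="BDF", t_eval=t_eval,
                    rtol=model.rtol, atol=model.atol, jac_sparsity=pattern)
    if not sol.success:
        raise RuntimeError(f"transport integration failed at t={sol.t[-1] if len(sol.t) else t0} min: "
                           f"{sol.message}")

    conc = {}
    for k, spc in enumerate(model.species):
        mask = asm.free[spc.name]
        arr = np.empty((len(sol.t), m))
        for j, tj in enumerate(sol.t):
            arr[j] = asm.full_state(spc.name, tj,
                                    sol.y[offsets[k]:offsets[k + 1], j])
        conc[spc.name] = arr
    return SimulationResult(domain=dom, time=sol.t, conc=conc,
                            diagnostics={"n_steps": sol.t.size,
                                         "nfev": sol.nfev,
                                         "assembled": asm})
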