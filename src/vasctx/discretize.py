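"""Refinement of vessel segments into cell-scale volume elements.

Each vessel segment is split into elements whose length h targets the
characteristic length c_l of a biological cell (default 11.5 µm, with an
admissible deviation δ = 2.5 µm), producing the tank-in-series domain on
which transport is solved.  Every refined node owns a volume equal to the
half-cylinder volumes of its adjacent elements; junction nodes merge the
half-cylinders of all adjoining branches into a single (spherical)
element, of which only the volume matters downstream.  Non-junction nodes
are paired with an annular tissue unit — a Krogh-type hollow cylinder of
wall thickness d_t/2 around the vessel — that holds the metabolizing cell
mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .flow import FlowSolution
from .network import VascularNetwork

#: characteristic element length: average biological cell diameter, µm
DEFAULT_CL = 11.5
#: admissible deviation of element length from c_l, µm
DEFAULT_DELTA = 2.5
#: default tissue-sleeve thickness parameter d_t, µm (outer diameter of the
#: annular unit is d_bv + d_t); derived from a 1020 µm³ beta-cell volume
DEFAULT_DT = 12.4


@dataclass
class DiscretizedDomain:
    """Refined tank-in-series domain built on top of a solved flow field.

    Nodes (size ``m``): refined graph nodes, the original network nodes
    plus interior subdivision points.  Elements (size ``n``): refined
    edges, each inheriting its parent segment's radius, flow and velocity.
    """

    net: VascularNetwork
    coords: np.ndarray          # (m, 3) µm
    is_junction: np.ndarray     # (m,) original nodes with degree >= 3
    role: np.ndarray            # (m,) inherited: inlet/outlet/interior
    parent_node: np.ndarray     # (m,) original node index or -1
    tail: np.ndarray            # (n,) refined node indices
    head: np.ndarray
    h: np.ndarray               # (n,) element lengths, µm
    radius: np.ndarray          # (n,) µm
    flow: np.ndarray            # (n,) µm³/min, signed with orientation
    velocity: np.ndarray        # (n,) µm/min (mean)
    parent_edge: np.ndarray     # (n,) original edge index
    h_exempt: np.ndarray        # (n,) True where the mesh bound cannot apply
    c_l: float = DEFAULT_CL
    delta: float = DEFAULT_DELTA
    node_volume: np.ndarray | None = None   # V^bv, µm³
    tissue_volume: np.ndarray | None = None  # V^cell, µm³

    @property
    def n_nodes(self) -> int:
        return len(self.coords)

    @property
    def n_elements(self) -> int:
        return len(self.h)

    @property
    def area(self) -> np.ndarray:
        """Element cross-sections π r² (µm²)."""
        return np.pi * self.radius**2

    def path_distance_from_inlet(self) -> np.ndarray:
        """Graph distance (µm) of every refined node from the inlet node."""
        import networkx as nx

        g = nx.Graph()
        for e in range(self.n_elements):
            g.add_edge(int(self.tail[e]), int(self.head[e]), weight=self.h[e])
        inlets = np.flatnonzero(self.role == "inlet")
        dist = nx.multi_source_dijkstra_path_length(g, set(map(int, inlets)))
        return np.array([dist[i] for i in range(self.n_nodes)])


def n_elements_for(l: float, c_l: float = DEFAULT_CL,
                   delta: float = DEFAULT_DELTA) -> tuple[int, bool]:
    """Element count for a parent segment of length ``l``.

    Returns ``(k, exempt)``.  The primary rule is k = round(l / c_l)
    (k ≥ 1, equal splitting).  When no integer split can land h inside the
    open interval (c_l − δ, c_l + δ) — segments shorter than c_l − δ, or
    lengths in the gap (c_l + δ, 2(c_l − δ)) — the edge is exempt from the
    bound and k is chosen to bring h closest to c_l.
    """
    def ok(k):
        h = l / k
        return (c_l - delta) < h < (c_l + delta) + 1e-12

    k = max(1, round(l / c_l))
    if ok(k):
        return k, False
    for kk in (k - 1, k + 1):
        if kk >= 1 and ok(kk):
            return kk, False
    if l <= c_l - delta:
        return 1, True
    candidates = [kk for kk in (max(1, k - 1), k, k + 1)]
    best = min(candidates, key=lambda kk: abs(l / kk - c_l))
    return best, True


def refine_edges(net: VascularNetwork, flow: FlowSolution,
                 c_l: float = DEFAULT_CL,
                 delta: float = DEFAULT_DELTA) -> DiscretizedDomain:
    """Split each vessel segment into k equal elements and build the domain.

    Elements inherit the parent's radius, flow and mean velocity; the
    refined graph keeps the parent orientation.  Nodal and tissue volumes
    are filled in by :func:`node_volumes` / :func:`tissue_volumes` (called
    here with defaults).
    """
    if not (c_l > 0 and 0 <= delta < c_l):
        raise ValueError("need c_l > 0 and 0 <= delta < c_l")

    m0 = net.n_nodes
    deg = net.degrees()
    coords = [net.coords[i] for i in range(m0)]
    parent_node = list(range(m0))
    tails, heads, hs, radii, flows, vels, parents, exempts = \
        [], [], [], [], [], [], [], []

    for e in range(net.n_edges):
        k, exempt = n_elements_for(net.length[e], c_l, delta)
        h = net.length[e] / k
        a, b = int(net.tail[e]), int(net.head[e])
        xa, xb = net.coords[a], net.coords[b]
        chain = [a]
        for j in range(1, k):
            coords.append(xa + (xb - xa) * (j / k))
            parent_node.append(-1)
            chain.append(len(coords) - 1)
        chain.append(b)
        for j in range(k):
            tails.append(chain[j])
            heads.append(chain[j + 1])
            hs.append(h)
            radii.append(net.radius[e])
            flows.append(flow.flow[e])
            vels.append(flow.velocity[e])
            parents.append(e)
            exempts.append(exempt)

    m = len(coords)
    role = np.full(m, "interior", dtype=object)
    is_junction = np.zeros(m, dtype=bool)
    for i in range(m0):
        role[i] = net.role[i]
        is_junction[i] = deg[i] >= 3
    role = role.astype(str)

    dom = DiscretizedDomain(
        net=net,
        coords=np.asarray(coords, dtype=float),
        is_junction=is_junction,
        role=role,
        parent_node=np.asarray(parent_node, dtype=int),
        tail=np.asarray(tails, dtype=int),
        head=np.asarray(heads, dtype=int),
        h=np.asarray(hs, dtype=float),
        radius=np.asarray(radii, dtype=float),
        flow=np.asarray(flows, dtype=float),
        velocity=np.asarray(vels, dtype=float),
        parent_edge=np.asarray(parents, dtype=int),
        h_exempt=np.asarray(exempts, dtype=bool),
        c_l=c_l, delta=delta,
    )
    dom.node_volume = node_volumes(dom)
    dom.tissue_volume = tissue_volumes(dom)
    return dom


def node_volumes(dom: DiscretizedDomain) -> np.ndarray:
    """Nodal luminal volumes V_i = ½ Σ_{adjacent elements} A h (µm³).

    At junction nodes the merged half-cylinder sum stands in for the
    spherical junction element.  Summing over all nodes recovers the total
    luminal volume Σ_e A_e h_e exactly.
    """
    V = np.zeros(dom.n_nodes)
    half = 0.5 * dom.area * dom.h
    np.add.at(V, dom.tail, half)
    np.add.at(V, dom.head, half)
    return V


def tissue_volumes(dom: DiscretizedDomain, d_t: float = DEFAULT_DT) -> np.ndarray:
    """Annular tissue-unit volumes V^cell per refined node (µm³).

    Each non-junction node owns the hollow-cylinder shell
    (π/4)[(d_bv + d_t)² − d_bv²] over its share of axial length (half of
    each adjacent element); junction nodes, where no vessel–tissue
    interaction is modeled, get 0.
    """
    if d_t < 0:
        raise ValueError("d_t must be nonnegative")
    d = 2.0 * dom.radius
    shell = (np.pi / 4.0) * ((d + d_t) ** 2 - d**2)  # per unit length, µm²
    V = np.zeros(dom.n_nodes)
    contrib = 0.5 * shell * dom.h
    np.add.at(V, dom.tail, contrib)
    np.add.at(V, dom.head, contrib)
    V[dom.is_junction] = 0.0
    return V
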