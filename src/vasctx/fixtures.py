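"""Synthetic vascular networks for testing and experimentation.

Generates the standard test geometries used throughout the package:
a single straight vessel, symmetric bifurcation trees, a hand-solvable
diamond loop, and randomly sampled capillary trees whose diameter and
length ranges (5–20 µm, 10–200 µm) emulate skeletonized capillary beds.
All generators return networks that pass :func:`vasctx.network.validate_network`
and are pure functions of their arguments (seed-reproducible).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import units
from .network import VascularNetwork, validate_network

#: defaults sitting inside typical capillary diameter/length distributions
DEFAULT_D_RANGE = (5.0, 20.0)
DEFAULT_L_RANGE = (10.0, 200.0)


@dataclass
class FixtureSpec:
    """Recipe for a sampled synthetic capillary network.

    ``n_edges`` vessel segments with diameters and lengths drawn uniformly
    from ``d_range`` / ``l_range`` (µm).  ``n_loops`` extra cross-edges
    turn the tree into a looped network.  The inlet is driven either by a
    pressure ``p_in`` (Pa) or, if ``q_in_nl_min`` is given, by a flow BC;
    all leaves are pressure-anchored outlets at ``p_out``.
    """

    kind: str = "sampled"
    n_edges: int = 63
    d_range: tuple = DEFAULT_D_RANGE
    l_range: tuple = DEFAULT_L_RANGE
    n_loops: int = 0
    seed: int = 0
    p_in: float = 60.0
    p_out: float = 0.0
    q_in_nl_min: float | None = None

    def __post_init__(self):
        if not (self.d_range[0] > 0 and self.l_range[0] > 0):
            raise ValueError("diameter/length ranges must be positive")


def _make_net(nodes_rows, edges_rows) -> VascularNetwork:
    nodes = pd.DataFrame(nodes_rows,
                         columns=["node_id", "x_um", "y_um", "z_um",
                                  "role", "bc_kind", "bc_value"])
    edges = pd.DataFrame(edges_rows,
                         columns=["edge_id", "tail", "head",
                                  "length_um", "diameter_um"])
    net = VascularNetwork.from_frames(nodes, edges, flow_unit="um3/min")
    problems = validate_network(net)
    if problems:  # pragma: no cover - generator bug guard
        raise AssertionError(f"generated invalid network: {problems}")
    return net


def single_vessel(l: float, d: float, *, p_in: float = 60.0, p_out: float = 0.0,
                  q_in_nl_min: float | None = None) -> VascularNetwork:
    """One straight capillary: node 1 (inlet) → node 2 (outlet).

    ``l``, ``d`` in µm.  By default both ends carry pressure BCs (Pa); if
    ``q_in_nl_min`` is given the inlet becomes a flow BC instead.
    """
    if not (l > 0 and d > 0):
        raise ValueError("length and diameter must be positive")
    if q_in_nl_min is not None:
        in_bc = ("flow", units.nl_per_min_to_um3_per_min(q_in_nl_min))
    else:
        in_bc = ("pressure", p_in)
    nodes = [
        (1, 0.0, 0.0, 0.0, "inlet", *in_bc),
        (2, l, 0.0, 0.0, "outlet", "pressure", p_out),
    ]
    edges = [(1, 1, 2, l, d)]
    return _make_net(nodes, edges)


def bifurcation_tree(depth: int, root_d: float = 10.0, child_ratio: float = 0.8,
                     seg_l: float = 50.0, *, p_in: float = 60.0,
                     p_out: float = 0.0) -> VascularNetwork:
    """Full binary tree: 1 inlet root segment, 2**depth outlet leaves.

    Child diameter = parent diameter × ``child_ratio``; every segment has
    length ``seg_l``.  Total edge count is 2**(depth+1) − 1.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not (0 < child_ratio <= 1):
        raise ValueError("child_ratio must be in (0, 1]")
    if not (root_d > 0 and seg_l > 0):
        raise ValueError("root_d and seg_l must be positive")

    nodes = [(0, 0.0, 0.0, 0.0, "inlet", "pressure", p_in)]
    edges = []
    next_node = 1
    # (node_id, level, diameter, x, y): frontier of open branch tips
    nodes.append((1, seg_l, 0.0, 0.0, "interior", "none", np.nan))
    edges.append((0, 0, 1, seg_l, root_d))
    frontier = [(1, 1, root_d, seg_l, 0.0)]
    next_node = 2
    eid = 1
    while frontier:
        nid, level, diam, x, y = frontier.pop(0)
        if level > depth:
            continue
        child_d = diam * child_ratio
        for dy in (-1.0, 1.0):
            cy = y + dy * seg_l / 2**level
            cid = next_node
            next_node += 1
            leaf = level == depth
            role = "outlet" if leaf else "interior"
            bc = ("pressure", p_out) if leaf else ("none", np.nan)
            nodes.append((cid, x + seg_l, cy, 0.0, role, *bc))
            edges.append((eid, nid, cid, seg_l, child_d))
            eid += 1
            if not leaf:
                frontier.append((cid, level + 1, child_d, x + seg_l, cy))
    return _make_net(nodes, edges)


def diamond_loop(conductances=(1.0, 2.0, 1.0, 2.0), *, q_in: float = 3.0,
                 p_out: float = 0.0, mu: float = 0.004, d: float = 10.0,
                 stub_factor: float = 100.0):
    """Hand-solvable diamond circuit A→B→D, A→C→D with inlet/outlet stubs.

    ``conductances = (g_AB, g_AC, g_BD, g_CD)`` in canonical µm³/(min·Pa);
    edge lengths are sized from the Hagen–Poiseuille law so each edge
    realizes its requested conductance at viscosity ``mu`` (Pa·s) and
    diameter ``d``.  Because boundary nodes must have degree 1, a high-
    conductance stub (``stub_factor`` × max g) feeds A and drains D; the
    returned expected solution accounts for the stubs exactly.

    Returns ``(net, expected)`` where ``expected`` holds the closed-form
    circuit solution: nodal pressures (Pa) and edge flows (µm³/min) keyed
    by node/edge id, for use as an independent oracle.
    """
    g = np.asarray(conductances, dtype=float)
    if g.shape != (4,) or np.any(g <= 0):
        raise ValueError("need 4 positive conductances")
    g_ab, g_ac, g_bd, g_cd = g
    g_stub = stub_factor * g.max()

    mu_c = units.pa_s_to_pa_min(mu)
    r = d / 2.0

    def length_for(gval):
        # invert G = π r⁴ / (8 µ l)
        return np.pi * r**4 / (8.0 * mu_c * gval)

    # closed-form series/parallel solve (independent of the matrix solver)
    r1 = 1.0 / g_ab + 1.0 / g_bd
    r2 = 1.0 / g_ac + 1.0 / g_cd
    r_par = 1.0 / (1.0 / r1 + 1.0 / r2)
    p_d = p_out + q_in / g_stub
    p_a = p_d + q_in * r_par
    q1 = (p_a - p_d) / r1
    q2 = (p_a - p_d) / r2
    p_b = p_a - q1 / g_ab
    p_c = p_a - q2 / g_ac
    p_in_node = p_a + q_in / g_stub

    expected = {
        "pressures": {"In": p_in_node, "A": p_a, "B": p_b, "C": p_c,
                      "D": p_d, "Out": p_out},
        "flows": {"In-A": q_in, "A-B": q1, "A-C": q2, "B-D": q1,
                  "C-D": q2, "D-Out": q_in},
        "conductances": {"In-A": g_stub, "A-B": g_ab, "A-C": g_ac,
                         "B-D": g_bd, "C-D": g_cd, "D-Out": g_stub},
    }

    nodes = [
        ("In", -50.0, 0.0, 0.0, "inlet", "flow", q_in),
        ("A", 0.0, 0.0, 0.0, "interior", "none", np.nan),
        ("B", 50.0, 25.0, 0.0, "interior", "none", np.nan),
        ("C", 50.0, -25.0, 0.0, "interior", "none", np.nan),
        ("D", 100.0, 0.0, 0.0, "interior", "none", np.nan),
        ("Out", 150.0, 0.0, 0.0, "outlet", "pressure", p_out),
    ]
    edges = [
        ("In-A", "In", "A", length_for(g_stub), d),
        ("A-B", "A", "B", length_for(g_ab), d),
        ("A-C", "A", "C", length_for(g_ac), d),
        ("B-D", "B", "D", length_for(g_bd), d),
        ("C-D", "C", "D", length_for(g_cd), d),
        ("D-Out", "D", "Out", length_for(g_stub), d),
    ]
    return _make_net(nodes, edges), expected


def sampled_network(spec: FixtureSpec) -> VascularNetwork:
    """Random capillary tree (plus optional loops) per a :class:`FixtureSpec`.

    A rooted random tree with exactly ``spec.n_edges`` segments is grown by
    attaching each new segment to a uniformly chosen existing attachment
    point; every leaf becomes a pressure-anchored outlet.  Fully
    reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n_tree = spec.n_edges - spec.n_loops
    if n_tree < 2:
        raise ValueError("need at least 2 tree edges")

    if spec.q_in_nl_min is not None:
        in_bc = ("flow", units.nl_per_min_to_um3_per_min(spec.q_in_nl_min))
    else:
        in_bc = ("pressure", spec.p_in)

    coords = {0: np.zeros(3)}
    # root inlet stub: node 0 (inlet) -> node 1
    parents = {1: 0}
    children: dict[int, list] = {0: [1], 1: []}
    edges = []

    def sample_edge():
        d = rng.uniform(*spec.d_range)
        l = rng.uniform(*spec.l_range)
        return l, d

    l, d = sample_edge()
    coords[1] = coords[0] + np.array([l, 0.0, 0.0])
    edges.append((0, 0, 1, l, d))
    # grow: attach to any non-root node with < 2 children (keeps degree <= 3)
    for eid in range(1, n_tree):
        candidates = [n for n, ch in children.items() if n != 0 and len(ch) < 2]
        parent = int(rng.choice(candidates))
        nid = len(coords)
        l, d = sample_edge()
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        coords[nid] = coords[parent] + l * direction
        children[parent].append(nid)
        children[nid] = []
        parents[nid] = parent
        edges.append((eid, parent, nid, l, d))

    # optional loop edges between distinct interior-ish nodes
    internal = [n for n, ch in children.items() if n != 0 and len(ch) >= 1]
    for k in range(spec.n_loops):
        if len(internal) < 2:
            break
        a, b = rng.choice(internal, size=2, replace=False)
        l, d = sample_edge()
        edges.append((n_tree + k, int(a), int(b), l, d))

    deg = {}
    for _, t, h, _, _ in edges:
        deg[t] = deg.get(t, 0) + 1
        deg[h] = deg.get(h, 0) + 1

    nodes = []
    for nid, xyz in coords.items():
        if nid == 0:
            nodes.append((0, *xyz, "inlet", *in_bc))
        elif deg[nid] == 1:
            nodes.append((nid, *xyz, "outlet", "pressure", spec.p_out))
        else:
            nodes.append((nid, *xyz, "interior", "none", np.nan))

    net = _make_net(nodes, edges)
    net.meta["fixture_spec"] = spec
    return net
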