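"""Vascular network data model, file I/O and graph operators.

A skeletonized capillary bed is represented as an oriented weighted graph:
nodes carry 3-D centerline coordinates (µm) plus a boundary role, edges are
vessel segments with a length and diameter (µm).  The stored edge
orientation is arbitrary but fixed; all signed quantities (incidence
matrix, flows) refer to it.

Boundary conditions live on nodes: a terminal node is an ``inlet`` or
``outlet`` and carries either a prescribed pressure (Pa) or a prescribed
volumetric flow (µm³/min internally; nl/min in files).  At least one node
must pin a pressure, otherwise the nodal-pressure system is only determined
up to an additive constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import units

ROLES = ("interior", "inlet", "outlet")
BC_KINDS = ("pressure", "flow", "none")

NODE_COLUMNS = ["node_id", "x_um", "y_um", "z_um", "role", "bc_kind", "bc_value"]
EDGE_COLUMNS = ["edge_id", "tail", "head", "length_um", "diameter_um"]


class NetworkFormatError(ValueError):
    """Raised when an input file does not have the expected columns/types."""


class NetworkValidationError(ValueError):
    """Raised when a structurally invalid network is used."""


@dataclass
class VascularNetwork:
    """Oriented weighted graph of vessel segments.

    Parameters
    ----------
    node_ids, edge_ids
        Unique identifiers (kept as read; ints or strings).
    coords
        (m, 3) nodal coordinates in µm.
    role, bc_kind
        Per-node strings from :data:`ROLES` / :data:`BC_KINDS`.
    bc_value
        Per-node boundary value in canonical units: Pa for pressure BCs,
        µm³/min for flow BCs, NaN where ``bc_kind == "none"``.
    tail, head
        Per-edge *indices* into the node arrays (stored orientation).
    length, diameter
        Per-edge segment length and diameter in µm.
    """

    node_ids: list
    coords: np.ndarray
    role: np.ndarray
    bc_kind: np.ndarray
    bc_value: np.ndarray
    edge_ids: list
    tail: np.ndarray
    head: np.ndarray
    length: np.ndarray
    diameter: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edge_ids)

    @property
    def radius(self) -> np.ndarray:
        """Per-edge luminal radius (µm)."""
        return self.diameter / 2.0

    @property
    def area(self) -> np.ndarray:
        """Per-edge luminal cross-section π r² (µm²)."""
        return np.pi * self.radius**2

    @property
    def luminal_volume(self) -> float:
        """Total luminal volume Σ_e π r_e² l_e (µm³)."""
        return float(np.sum(self.area * self.length))

    def node_index(self, node_id) -> int:
        return self._id_map()[node_id]

    def _id_map(self) -> dict:
        return {nid: i for i, nid in enumerate(self.node_ids)}

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        np.add.at(deg, self.tail, 1)
        np.add.at(deg, self.head, 1)
        return deg

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for i, nid in enumerate(self.node_ids):
            g.add_node(nid, index=i)
        for e in range(self.n_edges):
            g.add_edge(self.node_ids[self.tail[e]], self.node_ids[self.head[e]],
                       edge_id=self.edge_ids[e])
        return g

    # ---- construction -------------------------------------------------

    @classmethod
    def from_frames(cls, nodes: pd.DataFrame, edges: pd.DataFrame,
                    flow_unit: str = "um3/min") -> "VascularNetwork":
        """Build a network from node/edge tables (see ``NODE_COLUMNS``).

        ``flow_unit`` gives the unit of flow ``bc_value`` entries in the
        tables (``"nl/min"`` for files, ``"um3/min"`` for in-memory use).
        """
        for col in NODE_COLUMNS:
            if col not in nodes.columns:
                raise NetworkFormatError(f"nodes table missing column {col!r}")
        for col in EDGE_COLUMNS:
            if col not in edges.columns:
                raise NetworkFormatError(f"edges table missing column {col!r}")

        node_ids = list(nodes["node_id"])
        if len(set(node_ids)) != len(node_ids):
            raise NetworkValidationError("duplicate node ids")
        edge_ids = list(edges["edge_id"])
        if len(set(edge_ids)) != len(edge_ids):
            raise NetworkValidationError("duplicate edge ids")
        id_map = {nid: i for i, nid in enumerate(node_ids)}

        def to_index(col):
            idx = np.empty(len(edges), dtype=int)
            for k, v in enumerate(edges[col]):
                if v not in id_map:
                    raise NetworkValidationError(
                        f"edge references unknown node id {v!r}")
                idx[k] = id_map[v]
            return idx

        bc_kind = nodes["bc_kind"].fillna("none").astype(str).to_numpy()
        bc_value = pd.to_numeric(nodes["bc_value"], errors="coerce").to_numpy(float)
        if flow_unit == "nl/min":
            is_flow = bc_kind == "flow"
            bc_value = np.where(is_flow,
                                units.nl_per_min_to_um3_per_min(bc_value),
                                bc_value)
        elif flow_unit != "um3/min":
            raise ValueError(f"unknown flow unit {flow_unit!r}")

        net = cls(
            node_ids=node_ids,
            coords=nodes[["x_um", "y_um", "z_um"]].to_numpy(float),
            role=nodes["role"].astype(str).to_numpy(),
            bc_kind=bc_kind,
            bc_value=bc_value,
            edge_ids=edge_ids,
            tail=to_index("tail"),
            head=to_index("head"),
            length=edges["length_um"].to_numpy(float),
            diameter=edges["diameter_um"].to_numpy(float),
        )
        return net

    def to_frames(self, flow_unit: str = "um3/min") -> tuple[pd.DataFrame, pd.DataFrame]:
        bc_value = self.bc_value.copy()
        if flow_unit == "nl/min":
            is_flow = self.bc_kind == "flow"
            bc_value = np.where(is_flow,
                                units.um3_per_min_to_nl_per_min(bc_value),
                                bc_value)
        nodes = pd.DataFrame({
            "node_id": self.node_ids,
            "x_um": self.coords[:, 0],
            "y_um": self.coords[:, 1],
            "z_um": self.coords[:, 2],
            "role": self.role,
            "bc_kind": self.bc_kind,
            "bc_value": bc_value,
        })
        edges = pd.DataFrame({
            "edge_id": self.edge_ids,
            "tail": [self.node_ids[t] for t in self.tail],
            "head": [self.node_ids[h] for h in self.head],
            "length_um": self.length,
            "diameter_um": self.diameter,
        })
        return nodes, edges


# ---- file I/O ----------------------------------------------------------


def read_network(path) -> VascularNetwork:
    """Read a network from ``<path>/nodes.csv`` + ``<path>/edges.csv``.

    Flow boundary values in the files are in nl/min and are converted to
    the canonical µm³/min on read.  A ``<path>.graphml`` single file (or a
    path ending in ``.graphml``) is accepted as an alternate format.

    Raises
    ------
    NetworkFormatError
        for missing columns.
    NetworkValidationError
        for duplicate ids, dangling edge references or a disconnected graph.
    """
    import pathlib

    p = pathlib.Path(path)
    if p.suffix == ".graphml":
        net = _read_graphml(p)
    else:
        nodes_f, edges_f = p / "nodes.csv", p / "edges.csv"
        if not nodes_f.exists() or not edges_f.exists():
            raise NetworkFormatError(f"expected nodes.csv and edges.csv under {p}")
        net = VascularNetwork.from_frames(
            pd.read_csv(nodes_f), pd.read_csv(edges_f), flow_unit="nl/min")
    problems = validate_network(net)
    if problems:
        raise NetworkValidationError("; ".join(problems))
    return net


def write_network(net: VascularNetwork, path) -> None:
    """Write ``nodes.csv``/``edges.csv`` under ``path`` (flows in nl/min)."""
    import pathlib

    p = pathlib.Path(path)
    p.mkdir(parents=True, exist_ok=True)
    nodes, edges = net.to_frames(flow_unit="nl/min")
    nodes.to_csv(p / "nodes.csv", index=False)
    edges.to_csv(p / "edges.csv", index=False)


def _read_graphml(path) -> VascularNetwork:
    g = nx.read_graphml(path)
    nodes = pd.DataFrame([
        dict(node_id=n,
             x_um=d.get("x_um", 0.0), y_um=d.get("y_um", 0.0),
             z_um=d.get("z_um", 0.0),
             role=d.get("role", "interior"),
             bc_kind=d.get("bc_kind", "none"),
             bc_value=d.get("bc_value", float("nan")))
        for n, d in g.nodes(data=True)
    ])
    edges = pd.DataFrame([
        dict(edge_id=d.get("edge_id", k), tail=u, head=v,
             length_um=d["length_um"], diameter_um=d["diameter_um"])
        for k, (u, v, d) in enumerate(g.edges(data=True))
    ])
    return VascularNetwork.from_frames(nodes, edges, flow_unit="nl/min")


# ---- graph operators ---------------------------------------------------


def incidence_matrix(net: VascularNetwork) -> sp.csr_matrix:
    """Signed n×m incidence matrix M with M[e, tail]=+1, M[e, head]=−1.

    With this convention ``(M @ P)[e] = p_tail − p_head``, so M acts as the
    discrete (negative) gradient along the stored orientation and −Mᵀ as
    the discrete divergence.  Each row sums to zero.
    """
    n, m = net.n_edges, net.n_nodes
    rows = np.repeat(np.arange(n), 2)
    cols = np.empty(2 * n, dtype=int)
    cols[0::2] = net.tail
    cols[1::2] = net.head
    data = np.empty(2 * n)
    data[0::2] = 1.0
    data[1::2] = -1.0
    return sp.csr_matrix((data, (rows, cols)), shape=(n, m))


def validate_network(net: VascularNetwork) -> list[str]:
    """Check structural invariants; return a list of violations (empty = valid)."""
    problems: list[str] = []

    for e in range(net.n_edges):
        if not net.length[e] > 0:
            problems.append(f"edge {net.edge_ids[e]!r} has nonpositive length")
        if not net.diameter[e] > 0:
            problems.append(f"edge {net.edge_ids[e]!r} has nonpositive diameter")
        if net.tail[e] == net.head[e]:
            problems.append(f"edge {net.edge_ids[e]!r} is a self-loop")

    for r in set(net.role):
        if r not in ROLES:
            problems.append(f"unknown node role {r!r}")
    for k in set(net.bc_kind):
        if k not in BC_KINDS:
            problems.append(f"unknown bc_kind {k!r}")

    deg = net.degrees()
    inlets = np.flatnonzero(net.role == "inlet")
    outlets = np.flatnonzero(net.role == "outlet")
    if inlets.size == 0:
        problems.append("no inlet node")
    if outlets.size == 0:
        problems.append("no outlet node")
    for i in np.concatenate([inlets, outlets]):
        if deg[i] != 1:
            problems.append(
                f"boundary node {net.node_ids[i]!r} has degree {deg[i]} (expected 1)")
    for i in np.flatnonzero(net.role == "interior"):
        if net.bc_kind[i] != "none":
            problems.append(
                f"interior node {net.node_ids[i]!r} carries a boundary condition")
    for i in np.flatnonzero(np.isin(net.role, ("inlet", "outlet"))):
        if net.bc_kind[i] == "none":
            problems.append(
                f"boundary node {net.node_ids[i]!r} has no boundary condition")
        elif not np.isfinite(net.bc_value[i]):
            problems.append(
                f"boundary node {net.node_ids[i]!r} has no boundary value")

    if not np.any(net.bc_kind == "pressure"):
        problems.append("no pressure boundary condition (pressure level unpinned)")

    if net.n_nodes and not nx.is_connected(net.to_networkx()):
        problems.append("graph is disconnected")

    return problems


# ---- VTK export --------------------------------------------------------


def export_vtk(net: VascularNetwork, path, node_fields: dict | None = None,
               edge_fields: dict | None = None) -> None:
    """Write the network as VTK XML PolyData (.vtp) with line cells.

    ``node_fields`` become PointData arrays, ``edge_fields`` CellData
    arrays; array lengths must match the node/edge counts.
    """
    from .vtkio import write_polydata

    node_fields = node_fields or {}
    edge_fields = edge_fields or {}
    for name, arr in node_fields.items():
        if len(arr) != net.n_nodes:
            raise ValueError(f"node field {name!r} has length {len(arr)}, "
                             f"expected {net.n_nodes}")
    for name, arr in edge_fields.items():
        if len(arr) != net.n_edges:
            raise ValueError(f"edge field {name!r} has length {len(arr)}, "
                             f"expected {net.n_edges}")
    lines = np.column_stack([net.tail, net.head])
    write_polydata(path, net.coords, lines, point_data=node_fields,
                   cell_data=edge_fields)
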