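"""Minimal VTK XML PolyData (.vtp) writer and parse-back reader.

Only the subset needed for centerline networks is supported: points, line
cells (2-point polylines), and named float PointData / CellData arrays,
all ASCII-encoded.  Files open in ParaView and load with any standard VTK
reader.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET

import numpy as np


def _fmt(arr) -> str:
    return " ".join(repr(float(v)) for v in np.asarray(arr, dtype=float).ravel())


def write_polydata(path, points, lines, point_data=None, cell_data=None) -> None:
    """Write an ASCII .vtp file.

    Parameters
    ----------
    points : (m, 3) array of coordinates.
    lines : (n, 2) array of point-index pairs.
    point_data, cell_data : dicts of name → length-m / length-n float arrays.
    """
    points = np.asarray(points, dtype=float)
    lines = np.asarray(lines, dtype=int)
    point_data = point_data or {}
    cell_data = cell_data or {}

    def data_array(name, arr):
        return (f'<DataArray type="Float64" Name="{name}" '
                f'NumberOfComponents="1" format="ascii">{_fmt(arr)}</DataArray>')

    pd_xml = "".join(data_array(k, v) for k, v in point_data.items())
    cd_xml = "".join(data_array(k, v) for k, v in cell_data.items())
    connectivity = " ".join(str(i) for i in lines.ravel())
    offsets = " ".join(str(2 * (i + 1)) for i in range(len(lines)))

    xml = (
        '<?xml version="1.0"?>\n'
        '<VTKFile type="PolyData" version="1.0" byte_order="LittleEndian">'
        "<PolyData>"
        f'<Piece NumberOfPoints="{len(points)}" NumberOfVerts="0" '
        f'NumberOfLines="{len(lines)}" NumberOfStrips="0" NumberOfPolys="0">'
        f"<PointData>{pd_xml}</PointData>"
        f"<CellData>{cd_xml}</CellData>"
        "<Points>"
        f'<DataArray type="Float64" Name="Points" NumberOfComponents="3" '
        f'format="ascii">{_fmt(points)}</DataArray>'
        "</Points>"
        "<Lines>"
        f'<DataArray type="Int64" Name="connectivity" format="ascii">'
        f"{connectivity}</DataArray>"
        f'<DataArray type="Int64" Name="offsets" format="ascii">{offsets}</DataArray>'
        "</Lines>"
        "</Piece></PolyData></VTKFile>\n"
    )
    with open(path, "w") as fh:
        fh.write(xml)


def read_polydata(path):
    """Parse a .vtp written by :func:`write_polydata`.

    Returns ``(points, lines, point_data, cell_data)``.
    """
    root = ET.parse(path).getroot()
    piece = root.find("./PolyData/Piece")

    def parse(el, dtype=float):
        text = el.text or ""
        return np.array(text.split(), dtype=dtype)

    pts = parse(piece.find("./Points/DataArray")).reshape(-1, 3)
    conn = parse(piece.find("./Lines/DataArray[@Name='connectivity']"), int)
    lines = conn.reshape(-1, 2)
    point_data = {el.get("Name"): parse(el)
                  for el in piece.findall("./PointData/DataArray")}
    cell_data = {el.get("Name"): parse(el)
                 for el in piece.findall("./CellData/DataArray")}
    return pts, lines, point_data, cell_data
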