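"""Minimal ASCII VTU (VTK XML UnstructuredGrid) reader/writer.

Covers exactly what the pipeline emits: tetrahedral volume meshes and
triangle surface extractions with float/int point- and cell-data arrays,
loadable by ParaView. Only ASCII appended-free format is produced.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from typing import Mapping

import numpy as np

VTK_TETRA = 10
VTK_TRIANGLE = 5

_CELL_NNODES = {VTK_TETRA: 4, VTK_TRIANGLE: 3}


def _fmt_array(a: np.ndarray) -> str:
    a = np.asarray(a)
    if a.dtype.kind == "f":
        return "\n".join(" ".join(f"{x:.17g}" for x in row) for row in np.atleast_2d(a))
    return "\n".join(" ".join(str(int(x)) for x in row) for row in np.atleast_2d(a))


def _data_array(name: str, a: np.ndarray) -> ET.Element:
    a = np.asarray(a)
    if a.dtype.kind == "f":
        vtype = "Float64"
    else:
        vtype = "Int64"
    el = ET.Element("DataArray", type=vtype, Name=name, format="ascii")
    if a.ndim == 2 and a.shape[1] > 1:
        el.set("NumberOfComponents", str(a.shape[1]))
    el.text = "\n" + _fmt_array(a) + "\n"
    return el


def write_vtu(
    path,
    points: np.ndarray,
    cells: np.ndarray,
    cell_type: int = VTK_TETRA,
    point_data: Mapping[str, np.ndarray] | None = None,
    cell_data: Mapping[str, np.ndarray] | None = None,
) -> None:
    """Write one unstructured grid of homogeneous cell type to *path*."""
    points = np.asarray(points, dtype=float)
    cells = np.asarray(cells, dtype=np.int64)
    n_nodes_per_cell = _CELL_NNODES[cell_type]
    if cells.ndim != 2 or cells.shape[1] != n_nodes_per_cell:
        raise ValueError(f"cells must be (n, {n_nodes_per_cell}) for VTK type {cell_type}")

    root = ET.Element(
        "VTKFile", type="UnstructuredGrid", version="0.1", byte_order="LittleEndian"
    )
    grid = ET.SubElement(root, "UnstructuredGrid")
    piece = ET.SubElement(
        grid, "Piece", NumberOfPoints=str(len(points)), NumberOfCells=str(len(cells))
    )

    pts_el = ET.SubElement(piece, "Points")
    pts_el.append(_data_array("Points", points.reshape(-1, 3)))

    cells_el = ET.SubElement(piece, "Cells")
    cells_el.append(_data_array("connectivity", cells.reshape(len(cells), -1)))
    offsets = (np.arange(1, len(cells) + 1) * n_nodes_per_cell).reshape(-1, 1)
    cells_el.append(_data_array("offsets", offsets))
    cells_el.append(_data_array("types", np.full((len(cells), 1), cell_type)))

    pd_el = ET.SubElement(piece, "PointData")
    for name, arr in (point_data or {}).items():
        pd_el.append(_data_array(name, np.asarray(arr)))
    cd_el = ET.SubElement(piece, "CellData")
    for name, arr in (cell_data or {}).items():
        cd_el.append(_data_array(name, np.asarray(arr)))

    ET.ElementTree(root).write(path, xml_declaration=True, encoding="unicode")


def _parse_data_array(el: ET.Element) -> np.ndarray:
    kind = float if el.get("type", "").startswith("Float") else np.int64
    flat = np.array(el.text.split(), dtype=kind)
    ncomp = int(el.get("NumberOfComponents", "1"))
    return flat.reshape(-1, ncomp) if ncomp > 1 else flat


def read_vtu(path):
    """Read a VTU written by :func:`write_vtu`.

    Returns (points, cells, cell_type, point_data, cell_data).
    """
    piece = ET.parse(path).getroot().find("UnstructuredGrid").find("Piece")
    points = _parse_data_array(piece.find("Points").find("DataArray")).reshape(-1, 3)
    arrays = {el.get("Name"): el for el in piece.find("Cells").findall("DataArray")}
    types = np.atleast_1d(_parse_data_array(arrays["types"]).ravel())
    cell_type = int(types[0])
    if not np.all(types == cell_type):
        raise ValueError("mixed cell types are not supported")
    nn = _CELL_NNODES[cell_type]
    cells = _parse_data_array(arrays["connectivity"]).reshape(-1, nn)

    def collect(tag):
        sec = piece.find(tag)
        if sec is None:
            return {}
        return {el.get("Name"): _parse_data_array(el) for el in sec.findall("DataArray")}

    return points, cells, cell_type, collect("PointData"), collect("CellData")
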