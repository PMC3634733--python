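"""File I/O: STL/PLY surfaces, VTU/legacy-VTK volume meshes, Abaqus export.

Volume meshes travel as ASCII VTK unstructured grids (XML ``.vtu`` or
legacy ``.vtk``) with cell type 24 (quadratic tetrahedron): the tissue
region is a cell array named ``region`` and every node set is a 0/1 point
mask named ``set:<NAME>``.  Additional nodal fields (displacement, stress)
can be attached as point arrays.  The readers parse the same dialect the
writers emit.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np

from .errors import UserError, ValidationError
from .meshes import Region, SurfaceMesh, VolumeMesh

_SURFACE_EXTS = (".stl", ".ply")
_VOLUME_EXTS = (".vtu", ".vtk")


def read_surface(path: str | Path) -> SurfaceMesh:
    """Read a triangulated surface from STL or PLY."""
    import trimesh

    path = Path(path)
    if path.suffix.lower() not in _SURFACE_EXTS:
        raise UserError(
            f"unsupported surface format {path.suffix!r}; expected one of {_SURFACE_EXTS}"
        )
    if not path.exists():
        raise UserError(f"surface file not found: {path}")
    try:
        tm = trimesh.load(str(path), force="mesh", process=False)
    except Exception as exc:
        raise UserError(f"failed to parse {path}: {exc}") from exc
    mesh = SurfaceMesh(vertices=np.asarray(tm.vertices), triangles=np.asarray(tm.faces))
    mesh.validate()
    return mesh


def write_surface(surface: SurfaceMesh, path: str | Path) -> Path:
    """Write a surface as STL or PLY (ASCII)."""
    path = Path(path)
    if path.suffix.lower() not in _SURFACE_EXTS:
        raise UserError(
            f"unsupported surface format {path.suffix!r}; expected one of {_SURFACE_EXTS}"
        )
    tm = surface.as_trimesh()
    kind = path.suffix.lower().lstrip(".")
    if kind == "stl":
        data = tm.export(file_type="stl_ascii")
    else:
        data = tm.export(file_type="ply", encoding="ascii")
    mode = "wb" if isinstance(data, bytes) else "w"
    with open(path, mode) as fh:
        fh.write(data)
    return path


# --- VTU ---------------------------------------------------------------------

def _fmt(array: np.ndarray) -> str:
    a = np.asarray(array)
    if a.dtype.kind == "f":
        return " ".join(repr(float(v)) for v in a.ravel())
    return " ".join(str(int(v)) for v in a.ravel())


def write_volume(
    mesh: VolumeMesh,
    path: str | Path,
    point_data: dict[str, np.ndarray] | None = None,
    cell_data: dict[str, np.ndarray] | None = None,
) -> Path:
    """Write a TET10 mesh (plus optional fields) as ``.vtu`` or ``.vtk``."""
    path = Path(path)
    if path.suffix.lower() == ".vtu":
        return _write_vtu(mesh, path, point_data, cell_data)
    if path.suffix.lower() == ".vtk":
        return _write_vtk_legacy(mesh, path, point_data, cell_data)
    raise UserError(
        f"unsupported volume format {path.suffix!r}; expected one of {_VOLUME_EXTS}"
    )


def _point_arrays(mesh: VolumeMesh, point_data) -> dict[str, np.ndarray]:
    arrays: dict[str, np.ndarray] = {}
    for name, ids in sorted(mesh.node_sets.items()):
        mask = np.zeros(mesh.n_nodes, dtype=np.int64)
        mask[np.asarray(ids, dtype=np.int64)] = 1
        arrays[f"set:{name}"] = mask
    if point_data:
        for name, arr in point_data.items():
            arr = np.asarray(arr)
            if len(arr) != mesh.n_nodes:
                raise ValidationError(f"point array {name!r} length mismatch")
            arrays[name] = arr
    return arrays


def _write_vtu(mesh, path, point_data, cell_data) -> Path:
    arrays = _point_arrays(mesh, point_data)
    cells: dict[str, np.ndarray] = {"region": mesh.region}
    if cell_data:
        cells.update({k: np.asarray(v) for k, v in cell_data.items()})
    out = []
    out.append('<?xml version="1.0"?>')
    out.append('<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">')
    out.append(" <UnstructuredGrid>")
    out.append(f'  <Piece NumberOfPoints="{mesh.n_nodes}" NumberOfCells="{mesh.n_elements}">')
    out.append("   <Points>")
    out.append('    <DataArray type="Float64" NumberOfComponents="3" format="ascii">')
    out.append("     " + _fmt(mesh.nodes))
    out.append("    </DataArray>")
    out.append("   </Points>")
    out.append("   <Cells>")
    out.append('    <DataArray type="Int64" Name="connectivity" format="ascii">')
    out.append("     " + _fmt(mesh.elements))
    out.append("    </DataArray>")
    out.append('    <DataArray type="Int64" Name="offsets" format="ascii">')
    out.append("     " + _fmt(10 * np.arange(1, mesh.n_elements + 1)))
    out.append("    </DataArray>")
    out.append('    <DataArray type="UInt8" Name="types" format="ascii">')
    out.append("     " + _fmt(np.full(mesh.n_elements, 24)))
    out.append("    </DataArray>")
    out.append("   </Cells>")
    out.append("   <CellData>")
    for name, arr in cells.items():
        ncomp = 1 if arr.ndim == 1 else arr.shape[1]
        dtype = "Float64" if arr.dtype.kind == "f" else "Int64"
        out.append(
            f'    <DataArray type="{dtype}" Name="{name}" '
            f'NumberOfComponents="{ncomp}" format="ascii">'
        )
        out.append("     " + _fmt(arr))
        out.append("    </DataArray>")
    out.append("   </CellData>")
    out.append("   <PointData>")
    for name, arr in arrays.items():
        ncomp = 1 if arr.ndim == 1 else arr.shape[1]
        dtype = "Float64" if arr.dtype.kind == "f" else "Int64"
        out.append(
            f'    <DataArray type="{dtype}" Name="{name}" '
            f'NumberOfComponents="{ncomp}" format="ascii">'
        )
        out.append("     " + _fmt(arr))
        out.append("    </DataArray>")
    out.append("   </PointData>")
    out.append("  </Piece>")
    out.append(" </UnstructuredGrid>")
    out.append("</VTKFile>")
    path.write_text("\n".join(out))
    return path


def _write_vtk_legacy(mesh, path, point_data, cell_data) -> Path:
    arrays = _point_arrays(mesh, point_data)
    out = ["# vtk DataFile Version 3.0", "toothfea volume mesh", "ASCII",
           "DATASET UNSTRUCTURED_GRID", f"POINTS {mesh.n_nodes} double"]
    for p in mesh.nodes:
        out.append(f"{float(p[0])!r} {float(p[1])!r} {float(p[2])!r}")
    out.append(f"CELLS {mesh.n_elements} {mesh.n_elements * 11}")
    for e in mesh.elements:
        out.append("10 " + " ".join(str(int(v)) for v in e))
    out.append(f"CELL_TYPES {mesh.n_elements}")
    out.extend(["24"] * mesh.n_elements)
    out.append(f"CELL_DATA {mesh.n_elements}")
    out.append("SCALARS region int 1")
    out.append("LOOKUP_TABLE default")
    out.extend(str(int(r)) for r in mesh.region)
    out.append(f"POINT_DATA {mesh.n_nodes}")
    for name, arr in arrays.items():
        if arr.ndim == 1:
            kind = "double" if arr.dtype.kind == "f" else "int"
            out.append(f"SCALARS {name} {kind} 1")
            out.append("LOOKUP_TABLE default")
            out.extend(
                (repr(float(v)) if arr.dtype.kind == "f" else str(int(v))) for v in arr
            )
        else:
            out.append(f"VECTORS {name} double")
            for row in arr:
                out.append(" ".join(repr(float(v)) for v in row))
    path.write_text("\n".join(out) + "\n")
    return path


def read_volume(path: str | Path) -> tuple[VolumeMesh, dict[str, np.ndarray]]:
    """Read a TET10 mesh written by :func:`write_volume`.

    Returns the mesh (node sets reconstructed from ``set:`` masks) and a
    dict of the remaining point arrays.
    """
    path = Path(path)
    if not path.exists():
        raise UserError(f"volume file not found: {path}")
    if path.suffix.lower() == ".vtu":
        return _read_vtu(path)
    if path.suffix.lower() == ".vtk":
        return _read_vtk_legacy(path)
    raise UserError(
        f"unsupported volume format {path.suffix!r}; expected one of {_VOLUME_EXTS}"
    )


def _finish_mesh(nodes, elements, region, point_arrays) -> tuple[VolumeMesh, dict]:
    node_sets = {}
    extra = {}
    for name, arr in point_arrays.items():
        if name.startswith("set:"):
            node_sets[name[4:]] = np.flatnonzero(np.asarray(arr).astype(int))
        else:
            extra[name] = arr
    mesh = VolumeMesh(nodes=nodes, elements=elements, region=region, node_sets=node_sets)
    return mesh, extra


def _parse_array(text: str, dtype=float) -> np.ndarray:
    return np.array(text.split(), dtype=dtype)


def _read_vtu(path: Path) -> tuple[VolumeMesh, dict[str, np.ndarray]]:
    try:
        root = ET.parse(path).getroot()
        piece = root.find(".//Piece")
        pts = piece.find("Points/DataArray")
        nodes = _parse_array(pts.text).reshape(-1, 3)
        cells = {da.get("Name"): da for da in piece.find("Cells")}
        conn = _parse_array(cells["connectivity"].text, np.int64)
        types = _parse_array(cells["types"].text, np.int64)
        if not np.all(types == 24):
            raise UserError(f"{path}: expected only quadratic tetra (VTK type 24)")
        elements = conn.reshape(-1, 10)
        region = None
        for da in piece.find("CellData") or []:
            if da.get("Name") == "region":
                region = _parse_array(da.text, np.int64)
        if region is None:
            region = np.full(len(elements), int(Region.DENTINE))
        point_arrays = {}
        for da in piece.find("PointData") or []:
            ncomp = int(da.get("NumberOfComponents", "1"))
            if da.get("type") == "Float64":
                arr = _parse_array(da.text)
            else:
                arr = _parse_array(da.text, np.int64)
            point_arrays[da.get("Name")] = arr.reshape(-1, ncomp) if ncomp > 1 else arr
    except UserError:
        raise
    except Exception as exc:
        raise UserError(f"failed to parse VTU file {path}: {exc}") from exc
    return _finish_mesh(nodes, elements, region, point_arrays)


def _read_vtk_legacy(path: Path) -> tuple[VolumeMesh, dict[str, np.ndarray]]:
    try:
        lines = path.read_text().splitlines()
        i = 0

        def seek(prefix):
            nonlocal i
            while i < len(lines) and not lines[i].startswith(prefix):
                i += 1
            if i >= len(lines):
                raise UserError(f"{path}: missing {prefix} section")
            return lines[i]

        header = seek("POINTS").split()
        n_pts = int(header[1])
        i += 1
        nodes = np.array(
            [[float(v) for v in lines[i + k].split()] for k in range(n_pts)]
        )
        i += n_pts
        header = seek("CELLS").split()
        n_cells = int(header[1])
        i += 1
        elements = np.array(
            [[int(v) for v in lines[i + k].split()[1:]] for k in range(n_cells)],
            dtype=np.int64,
        )
        i += n_cells
        region = np.full(n_cells, int(Region.DENTINE))
        point_arrays: dict[str, np.ndarray] = {}
        while i < len(lines):
            line = lines[i]
            if line.startswith("SCALARS region"):
                i += 2
                region = np.array([int(lines[i + k]) for k in range(n_cells)])
                i += n_cells
            elif line.startswith("SCALARS "):
                name, kind = line.split()[1:3]
                i += 2
                conv = float if kind == "double" else int
                arr = np.array([conv(lines[i + k]) for k in range(n_pts)])
                point_arrays[name] = arr
                i += n_pts
            elif line.startswith("VECTORS "):
                name = line.split()[1]
                i += 1
                arr = np.array(
                    [[float(v) for v in lines[i + k].split()] for k in range(n_pts)]
                )
                point_arrays[name] = arr
                i += n_pts
            else:
                i += 1
    except UserError:
        raise
    except Exception as exc:
        raise UserError(f"failed to parse VTK file {path}: {exc}") from exc
    return _finish_mesh(nodes, elements, region, point_arrays)


# --- Abaqus export -----------------------------------------------------------

def write_abaqus_inp(
    mesh: VolumeMesh,
    path: str | Path,
    materials=None,
    nodal_forces: np.ndarray | None = None,
    constraints=None,
) -> Path:
    """Export the model in Abaqus INP dialect (C3D10) for cross-checking."""
    from .fem import default_materials

    materials = materials or default_materials()
    path = Path(path)
    out = ["*HEADING", "toothfea export", "*NODE"]
    for nid, p in enumerate(mesh.nodes, start=1):
        out.append(f"{nid}, {p[0]:.9g}, {p[1]:.9g}, {p[2]:.9g}")
    for r in np.unique(mesh.region):
        name = Region(r).name
        out.append(f"*ELEMENT, TYPE=C3D10, ELSET={name}")
        for eid in np.flatnonzero(mesh.region == r):
            conn = ", ".join(str(int(v) + 1) for v in mesh.elements[eid])
            out.append(f"{eid + 1}, {conn}")
    for r in np.unique(mesh.region):
        name = Region(r).name
        mat = materials[Region(r)]
        out.append(f"*SOLID SECTION, ELSET={name}, MATERIAL={name}")
        out.append(f"*MATERIAL, NAME={name}")
        out.append("*ELASTIC")
        out.append(f"{mat.E_mpa:.9g}, {mat.nu:.9g}")
    for set_name, ids in sorted(mesh.node_sets.items()):
        out.append(f"*NSET, NSET={set_name}")
        for chunk_start in range(0, len(ids), 8):
            out.append(", ".join(str(int(v) + 1) for v in ids[chunk_start:chunk_start + 8]))
    if constraints is not None:
        out.append("*BOUNDARY")
        for nid in sorted(constraints.fixed):
            for ax in sorted(constraints.fixed[nid]):
                dof = {"x": 1, "y": 2, "z": 3}[ax]
                out.append(f"{nid + 1}, {dof}, {dof}, 0.0")
    if nodal_forces is not None:
        out.append("*CLOAD")
        for nid in np.flatnonzero(np.abs(nodal_forces).sum(axis=1) > 0):
            for dof in range(3):
                if nodal_forces[nid, dof] != 0.0:
                    out.append(f"{nid + 1}, {dof + 1}, {nodal_forces[nid, dof]:.9g}")
    path.write_text("\n".join(out) + "\n")
    return path
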