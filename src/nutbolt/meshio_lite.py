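"""Minimal ASCII writers for Gmsh MSH 4.1 and VTK XML (VTU) files.

Only the subsets needed here are implemented: tagged triangle surfaces and
tagged quadratic-tet volume meshes for MSH; quadratic-tet meshes with point
and cell data for VTU.  Files are plain text so they remain diffable and
viewer-friendly.
"""

from __future__ import annotations

from typing import Dict, Optional

import numpy as np


# ---------------------------------------------------------------------------
# Gmsh MSH 4.1
# ---------------------------------------------------------------------------

def _msh_header():
    return "$MeshFormat\n4.1 0 8\n$EndMeshFormat\n"


def write_msh_surface(path, surfaces: Dict[str, "object"]) -> None:
    """Tagged triangulated surfaces (tag -> trimesh.Trimesh) as MSH 4.1."""
    names = list(surfaces.keys())
    offsets, all_verts = {}, []
    total = 0
    for tag in names:
        v = np.asarray(surfaces[tag].vertices, dtype=float)
        offsets[tag] = total
        total += len(v)
        all_verts.append(v)
    verts = np.concatenate(all_verts)
    with open(path, "w") as f:
        f.write(_msh_header())
        f.write("$PhysicalNames\n")
        f.write(f"{len(names)}\n")
        for k, tag in enumerate(names):
            f.write(f'2 {k + 1} "{tag}"\n')
        f.write("$EndPhysicalNames\n")
        f.write("$Entities\n")
        f.write(f"0 0 {len(names)} 0\n")
        for k, tag in enumerate(names):
            m = surfaces[tag]
            lo, hi = m.bounds
            f.write(f"{k + 1} {lo[0]} {lo[1]} {lo[2]} {hi[0]} {hi[1]} "
                    f"{hi[2]} 1 {k + 1} 0\n")
        f.write("$EndEntities\n")
        f.write("$Nodes\n")
        f.write(f"{len(names)} {total} 1 {total}\n")
        node_id = 1
        for k, tag in enumerate(names):
            v = surfaces[tag].vertices
            f.write(f"2 {k + 1} 0 {len(v)}\n")
            ids = np.arange(node_id, node_id + len(v))
            f.write("\n".join(str(i) for i in ids) + "\n")
            for p in v:
                f.write(f"{p[0]} {p[1]} {p[2]}\n")
            node_id += len(v)
        f.write("$EndNodes\n")
        f.write("$Elements\n")
        n_el = sum(len(surfaces[t].faces) for t in names)
        f.write(f"{len(names)} {n_el} 1 {n_el}\n")
        el_id = 1
        for k, tag in enumerate(names):
            faces = surfaces[tag].faces
            f.write(f"2 {k + 1} 2 {len(faces)}\n")
            off = offsets[tag] + 1
            for tri in faces:
                f.write(f"{el_id} {tri[0] + off} {tri[1] + off} "
                        f"{tri[2] + off}\n")
                el_id += 1
        f.write("$EndElements\n")


def write_msh_volume(path, mesh) -> None:
    """FluidMesh (quadratic tets + tagged boundary triangles) as MSH 4.1."""
    tags = sorted(set(mesh.boundary_tags))
    phys = {tag: k + 1 for k, tag in enumerate(tags)}
    vol_phys = len(tags) + 1
    with open(path, "w") as f:
        f.write(_msh_header())
        f.write("$PhysicalNames\n")
        f.write(f"{len(tags) + 1}\n")
        for tag, k in phys.items():
            f.write(f'2 {k} "{tag}"\n')
        f.write(f'3 {vol_phys} "fluid"\n')
        f.write("$EndPhysicalNames\n")
        lo = mesh.nodes.min(axis=0)
        hi = mesh.nodes.max(axis=0)
        f.write("$Entities\n")
        f.write(f"0 0 {len(tags)} 1\n")
        for tag, k in phys.items():
            f.write(f"{k} {lo[0]} {lo[1]} {lo[2]} {hi[0]} {hi[1]} {hi[2]} "
                    f"1 {k} 0\n")
        f.write(f"1 {lo[0]} {lo[1]} {lo[2]} {hi[0]} {hi[1]} {hi[2]} "
                f"1 {vol_phys} 0\n")
        f.write("$EndEntities\n")
        nn = len(mesh.nodes)
        f.write("$Nodes\n")
        f.write(f"1 {nn} 1 {nn}\n")
        f.write(f"3 1 0 {nn}\n")
        f.write("\n".join(str(i) for i in range(1, nn + 1)) + "\n")
        for p in mesh.nodes:
            f.write(f"{p[0]} {p[1]} {p[2]}\n")
        f.write("$EndNodes\n")
        # elements: per-tag triangle blocks (corner nodes) + tet10 block
        f.write("$Elements\n")
        n_tri = len(mesh.boundary_faces)
        n_tet = len(mesh.tets10)
        f.write(f"{len(tags) + 1} {n_tri + n_tet} 1 {n_tri + n_tet}\n")
        el = 1
        for tag, k in phys.items():
            sel = np.flatnonzero(mesh.boundary_tags == tag)
            f.write(f"2 {k} 2 {len(sel)}\n")
            for idx in sel:
                a, b, c = mesh.boundary_faces[idx] + 1
                f.write(f"{el} {a} {b} {c}\n")
                el += 1
        f.write(f"3 1 11 {n_tet}\n")   # type 11: 10-node tetrahedron
        # gmsh tet10 ordering matches VTK's except nodes 8<->9
        order = [0, 1, 2, 3, 4, 5, 6, 7, 9, 8]
        for row in mesh.tets10:
            ids = " ".join(str(row[j] + 1) for j in order)
            f.write(f"{el} {ids}\n")
            el += 1
        f.write("$EndElements\n")


# ---------------------------------------------------------------------------
# VTU (XML, ascii)
# ---------------------------------------------------------------------------

def write_vtu(path, mesh, point_data: Optional[Dict[str, np.ndarray]] = None,
              cell_data: Optional[Dict[str, np.ndarray]] = None) -> None:
    """FluidMesh as an ASCII .vtu (VTK quadratic tetrahedra, type 24)."""
    nodes = mesh.nodes
    cells = mesh.tets10
    nn, nc = len(nodes), len(cells)
    point_data = point_data or {}
    cell_data = cell_data or {}

    def arr(a, per_line=6):
        a = np.asarray(a)
        flat = a.reshape(len(a), -1)
        return "\n".join(" ".join(f"{x:.9g}" for x in row) for row in flat)

    with open(path, "w") as f:
        f.write('<?xml version="1.0"?>\n')
        f.write('<VTKFile type="UnstructuredGrid" version="0.1" '
                'byte_order="LittleEndian">\n<UnstructuredGrid>\n')
        f.write(f'<Piece NumberOfPoints="{nn}" NumberOfCells="{nc}">\n')
        f.write('<Points>\n<DataArray type="Float64" NumberOfComponents="3"'
                ' format="ascii">\n')
        f.write(arr(nodes))
        f.write('\n</DataArray>\n</Points>\n')
        f.write('<Cells>\n<DataArray type="Int64" Name="connectivity" '
                'format="ascii">\n')
        f.write("\n".join(" ".join(str(i) for i in row) for row in cells))
        f.write('\n</DataArray>\n<DataArray type="Int64" Name="offsets" '
                'format="ascii">\n')
        f.write("\n".join(str(10 * (i + 1)) for i in range(nc)))
        f.write('\n</DataArray>\n<DataArray type="UInt8" Name="types" '
                'format="ascii">\n')
        f.write("\n".join("24" for _ in range(nc)))
        f.write('\n</DataArray>\n</Cells>\n')
        f.write('<PointData>\n')
        for name, data in point_data.items():
            data = np.asarray(data)
            ncomp = 1 if data.ndim == 1 else data.shape[1]
            f.write(f'<DataArray type="Float64" Name="{name}" '
                    f'NumberOfComponents="{ncomp}" format="ascii">\n')
            f.write(arr(data.reshape(nn, -1)))
            f.write('\n</DataArray>\n')
        f.write('</PointData>\n<CellData>\n')
        for name, data in cell_data.items():
            data = np.asarray(data)
            ncomp = 1 if data.ndim == 1 else data.shape[1]
            f.write(f'<DataArray type="Float64" Name="{name}" '
                    f'NumberOfComponents="{ncomp}" format="ascii">\n')
            f.write(arr(data.reshape(nc, -1)))
            f.write('\n</DataArray>\n')
        f.write('</CellData>\n</Piece>\n</UnstructuredGrid>\n</VTKFile>\n')
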