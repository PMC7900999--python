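"""Mesh interchange: Gmsh MSH 2.2 ASCII read/write and legacy-VTK export.

Region and boundary tags travel as Gmsh physical groups with the canonical
names ``gray``, ``white``, ``S_g``, ``S_w``, ``SAS``, ``ventricle``; files
written by an external mesher are accepted as long as those names are
present.  Hierarchies are stored as one ``level_<l>.msh`` per level plus a
``hierarchy.yaml`` with the time discretization; the inter-level
prolongation maps are reconstructed geometrically on read (exact for nested
meshes).
"""

from __future__ import annotations

import os

import numpy as np
import yaml

from .geometry import (
    BOUNDARY_NAMES,
    REGION_NAMES,
    REQUIRED_TAGS,
    GeometryError,
    MeshHierarchy,
    SimplicialMesh,
    reconstruct_prolongation,
)

_NAME_TO_CODE = {name: code for code, name in {**REGION_NAMES, **BOUNDARY_NAMES}.items()}
_ELM_TRIANGLE, _ELM_TETRA, _ELM_LINE = 2, 4, 1


def write_msh(mesh: SimplicialMesh, path: str) -> None:
    d = mesh.dim
    cell_type = _ELM_TRIANGLE if d == 2 else _ELM_TETRA
    facet_type = _ELM_LINE if d == 2 else _ELM_TRIANGLE
    used = sorted(set(mesh.cell_regions.tolist()) | set(mesh.boundary_tags.tolist()))
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat", "$PhysicalNames", str(len(used))]
    for code in used:
        name = {**REGION_NAMES, **BOUNDARY_NAMES}.get(code, f"tag{code}")
        dim = d if code in REGION_NAMES or code == 0 else d - 1
        lines.append(f'{dim} {code} "{name}"')
    lines.append("$EndPhysicalNames")
    lines += ["$Nodes", str(mesh.n_vertices)]
    pts3 = np.zeros((mesh.n_vertices, 3))
    pts3[:, :d] = mesh.points
    for i, p in enumerate(pts3, start=1):
        lines.append(f"{i} {p[0]:.17g} {p[1]:.17g} {p[2]:.17g}")
    lines.append("$EndNodes")
    n_elem = mesh.n_cells + len(mesh.boundary_facets)
    lines += ["$Elements", str(n_elem)]
    eid = 1
    for facet, tag in zip(mesh.boundary_facets, mesh.boundary_tags):
        nodes = " ".join(str(v + 1) for v in facet)
        lines.append(f"{eid} {facet_type} 2 {tag} {tag} {nodes}")
        eid += 1
    for cell, reg in zip(mesh.cells, mesh.cell_regions):
        nodes = " ".join(str(v + 1) for v in cell)
        lines.append(f"{eid} {cell_type} 2 {reg} {reg} {nodes}")
        eid += 1
    lines.append("$EndElements")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_msh(path: str, validate: bool = True) -> SimplicialMesh:
    with open(path) as fh:
        tokens = fh.read().split("\n")
    sections: dict[str, list[str]] = {}
    cur = None
    for line in tokens:
        line = line.strip()
        if line.startswith("$End"):
            cur = None
        elif line.startswith("$"):
            cur = line[1:]
            sections[cur] = []
        elif cur is not None and line:
            sections[cur].append(line)

    phys: dict[int, str] = {}
    if "PhysicalNames" in sections:
        for line in sections["PhysicalNames"][1:]:
            parts = line.split(None, 2)
            phys[int(parts[1])] = parts[2].strip().strip('"')

    node_lines = sections["Nodes"][1:]
    pts = np.array([[float(x) for x in ln.split()[1:4]] for ln in node_lines])

    elems: dict[int, list] = {_ELM_LINE: [], _ELM_TRIANGLE: [], _ELM_TETRA: []}
    for line in sections["Elements"][1:]:
        parts = [int(x) for x in line.split()]
        etype, n_tags = parts[1], parts[2]
        if etype not in elems:
            raise GeometryError(f"unsupported element type {etype}")
        ptag = parts[3] if n_tags >= 1 else 0
        nodes = [v - 1 for v in parts[3 + n_tags:]]
        code = _NAME_TO_CODE.get(phys.get(ptag, ""), ptag)
        elems[etype].append((nodes, code))

    if elems[_ELM_TETRA]:
        d, vol, fac = 3, elems[_ELM_TETRA], elems[_ELM_TRIANGLE]
    else:
        d, vol, fac = 2, elems[_ELM_TRIANGLE], elems[_ELM_LINE]

    points = pts[:, :d]
    cell_arr = np.array([n for n, _ in vol], dtype=np.int64)
    reg_arr = np.array([c for _, c in vol], dtype=np.int64)
    if fac:
        bf = np.array([n for n, _ in fac], dtype=np.int64)
        bt = np.array([c for _, c in fac], dtype=np.int64)
    else:
        bf = np.empty((0, d), dtype=np.int64)
        bt = np.empty(0, dtype=np.int64)
    mesh = SimplicialMesh(points, cell_arr, reg_arr, bf, bt)
    if validate:
        validate_tags(mesh)
    return mesh


def validate_tags(mesh: SimplicialMesh) -> None:
    """Require the canonical parenchyma tags; error lists what is missing."""
    present = set()
    for name in ("gray", "white", "S_g", "S_w"):
        if mesh.region_mask(name).any():
            present.add(name)
    for code, name in ((5, "SAS"), (6, "ventricle")):
        if (mesh.boundary_tags == code).any():
            present.add(name)
    missing = [t for t in REQUIRED_TAGS if t not in present]
    if missing:
        raise GeometryError(
            "mesh is missing required tags: "
            + ", ".join(missing)
            + f" (required: {', '.join(REQUIRED_TAGS)})"
        )


def write_hierarchy(hierarchy: MeshHierarchy, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    for level in range(1, hierarchy.n_levels + 1):
        write_msh(hierarchy.mesh(level), os.path.join(out_dir, f"level_{level}.msh"))
    meta = {
        "n_levels": hierarchy.n_levels,
        "dt_base": float(hierarchy.dt_base),
        "T": float(hierarchy.T),
        "measure_scale": float(hierarchy.mesh(1).measure_scale),
        "format": "msh2.2",
    }
    with open(os.path.join(out_dir, "hierarchy.yaml"), "w") as fh:
        yaml.safe_dump(meta, fh)


def read_hierarchy(in_dir: str, validate: bool = True) -> MeshHierarchy:
    with open(os.path.join(in_dir, "hierarchy.yaml")) as fh:
        meta = yaml.safe_load(fh)
    meshes = [
        read_msh(os.path.join(in_dir, f"level_{l}.msh"), validate=validate)
        for l in range(1, meta["n_levels"] + 1)
    ]
    for m in meshes:
        m.measure_scale = float(meta.get("measure_scale", 1.0))
    prolongations = [
        reconstruct_prolongation(meshes[l], meshes[l + 1]) for l in range(len(meshes) - 1)
    ]
    return MeshHierarchy(meshes, prolongations, dt_base=meta["dt_base"], T=meta["T"])


def write_vtk(mesh: SimplicialMesh, path: str, nodal_data: dict | None = None) -> None:
    """Legacy-VTK ASCII export of a mesh with optional nodal fields."""
    d = mesh.dim
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ntracermc mesh\nASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_vertices} double\n")
        pts3 = np.zeros((mesh.n_vertices, 3))
        pts3[:, :d] = mesh.points
        for p in pts3:
            fh.write(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
        nloc = d + 1
        fh.write(f"CELLS {mesh.n_cells} {mesh.n_cells * (nloc + 1)}\n")
        for c in mesh.cells:
            fh.write(f"{nloc} " + " ".join(map(str, c)) + "\n")
        vtk_type = 5 if d == 2 else 10
        fh.write(f"CELL_TYPES {mesh.n_cells}\n")
        fh.write("\n".join([str(vtk_type)] * mesh.n_cells) + "\n")
        fh.write(f"CELL_DATA {mesh.n_cells}\nSCALARS region int 1\nLOOKUP_TABLE default\n")
        fh.write("\n".join(map(str, mesh.cell_regions)) + "\n")
        if nodal_data:
            fh.write(f"POINT_DATA {mesh.n_vertices}\n")
            for name, arr in nodal_data.items():
                arr = np.asarray(arr)
                if arr.ndim == 1:
                    fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    fh.write("\n".join(f"{v:.17g}" for v in arr) + "\n")
                else:
                    fh.write(f"VECTORS {name} double\n")
                    v3 = np.zeros((len(arr), 3))
                    v3[:, : arr.shape[1]] = arr
                    for v in v3:
                        fh.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
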