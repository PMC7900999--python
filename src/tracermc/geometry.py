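"""Synthetic surrogate brain geometry and nested mesh hierarchies.

The physical domain is an idealised parenchyma: a disk (2D) or ball (3D) of
radius ``outer_radius`` with a concentric ventricular hole of radius
``ventricle_radius``.  The outer shell of thickness ``gray_thickness`` is
tagged as gray matter, the remainder as white matter, and two small probe
subregions (one per tissue type) are tagged as unions of whole cells.  The
outer boundary is the SAS (pial) interface, the inner boundary the
ventricular interface.

Hierarchies are built by uniform red refinement (each triangle -> 4 children,
each tetrahedron -> 8), which makes every level an exact partition of its
parent cells: prolongation of coarse piecewise-linear functions is exact and
white-noise loads restrict exactly between levels.  Region and boundary tags
are assigned on the coarsest mesh and inherited, so the integration regions
and the polygonal/polyhedral domain are identical on every level.

A larger embedding box hierarchy is provided for Matern field sampling; field
values are transferred to parenchyma vertices through a barycentric lookup
table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree

from . import fem

# Region codes (cells)
GRAY, WHITE, S_G, S_W = 1, 2, 3, 4
# Boundary codes (facets)
SAS, VENTRICLE, BOX_BOUNDARY = 5, 6, 7

REGION_NAMES = {GRAY: "gray", WHITE: "white", S_G: "S_g", S_W: "S_w"}
BOUNDARY_NAMES = {SAS: "SAS", VENTRICLE: "ventricle", BOX_BOUNDARY: "box"}
REQUIRED_TAGS = ("gray", "white", "S_g", "S_w", "SAS", "ventricle")


class GeometryError(ValueError):
    """Raised when a geometry specification violates one of its invariants."""


@dataclass(frozen=True)
class GeometrySpec:
    """Parameters of the surrogate parenchyma and its embedding box.

    Lengths are in meters.  Defaults give a ~0.14 m-diameter domain matching
    the scale of a human brain, a 4 mm cortical (gray) shell and a 2 cm
    ventricular cavity; the 3D box margins reproduce a 0.16 x 0.21 x 0.17 m
    sampling box around the 0.14 m domain.
    """

    dimension: int = 2
    outer_radius: float = 0.07
    ventricle_radius: float = 0.02
    gray_thickness: float = 0.004
    probe_centers: tuple | None = None
    probe_radius: float = 0.0025
    box_margins: tuple | None = None
    n_levels: int = 1
    base_resolution: float = 0.01
    # 2D slab thickness: chosen so the 2D surrogate's tissue volume
    # (area x thickness = 1.4e-3 m^3) matches the 3D surrogate shell and
    # keeps the brain-to-CSF volume ratio ~10 of the conservation model
    slab_thickness: float = 0.1

    def __post_init__(self):
        if self.dimension not in (2, 3):
            raise GeometryError("dimension must be 2 or 3")
        if self.probe_centers is None:
            c_g = (0.0672, 0.0) if self.dimension == 2 else (0.0672, 0.0, 0.0)
            c_w = (-0.04, 0.0) if self.dimension == 2 else (-0.04, 0.0, 0.0)
            object.__setattr__(self, "probe_centers", (c_g, c_w))
        if self.box_margins is None:
            margins = (0.015, 0.015) if self.dimension == 2 else (0.01, 0.035, 0.015)
            object.__setattr__(self, "box_margins", margins)
        self.validate()

    @property
    def gray_inner_radius(self) -> float:
        return self.outer_radius - self.gray_thickness

    def validate(self) -> None:
        if self.n_levels < 1:
            raise GeometryError("n_levels must be >= 1")
        if not (0 < self.ventricle_radius < self.gray_inner_radius):
            raise GeometryError(
                "invariant violated: ventricle_radius < outer_radius - gray_thickness"
            )
        centers = np.atleast_2d(np.asarray(self.probe_centers, dtype=float))
        if centers.shape != (2, self.dimension):
            raise GeometryError("probe_centers must be two points of the stated dimension")
        radii = np.linalg.norm(centers, axis=1)
        for label, r in zip(("gray", "white"), radii):
            lo = r - self.probe_radius
            hi = r + self.probe_radius
            if not (self.ventricle_radius < lo and hi < self.outer_radius):
                raise GeometryError(
                    f"invariant violated: {label} probe ball not strictly inside the parenchyma"
                )
        if not (self.gray_inner_radius < radii[0] < self.outer_radius):
            raise GeometryError("invariant violated: first probe center must lie in the gray shell")
        if not (self.ventricle_radius < radii[1] < self.gray_inner_radius):
            raise GeometryError("invariant violated: second probe center must lie in the white core")

    def box_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        m = np.asarray(self.box_margins, dtype=float)
        half = self.outer_radius + m
        return -half, half


@dataclass
class SimplicialMesh:
    """A tagged simplicial mesh (triangles in 2D, tetrahedra in 3D)."""

    points: np.ndarray  # (n, d)
    cells: np.ndarray  # (m, d+1) vertex indices
    cell_regions: np.ndarray  # (m,) region codes (GRAY/WHITE/S_G/S_W, 0 for box)
    boundary_facets: np.ndarray  # (nb, d) vertex indices
    boundary_tags: np.ndarray  # (nb,) boundary codes
    # out-of-plane slab thickness (m) converting 2D areas to volumes, so the
    # 2D surrogate couples to the 3D CSF-volume bookkeeping; 1.0 in 3D
    measure_scale: float = 1.0

    @property
    def dim(self) -> int:
        return self.points.shape[1]

    @property
    def n_vertices(self) -> int:
        return self.points.shape[0]

    @property
    def n_cells(self) -> int:
        return self.cells.shape[0]

    def region_mask(self, name: str) -> np.ndarray:
        """Boolean cell mask for 'gray', 'white', 'S_g' or 'S_w'.

        Probe cells carry their own code but belong to their tissue type:
        gray = {GRAY, S_G}, white = {WHITE, S_W}.
        """
        r = self.cell_regions
        if name == "gray":
            return (r == GRAY) | (r == S_G)
        if name == "white":
            return (r == WHITE) | (r == S_W)
        if name == "S_g":
            return r == S_G
        if name == "S_w":
            return r == S_W
        raise KeyError(name)

    def region_volume(self, name: str) -> float:
        return float(fem.cell_volumes(self.points, self.cells)[self.region_mask(name)].sum())

    def volume(self) -> float:
        return float(fem.cell_volumes(self.points, self.cells).sum())

    def boundary_vertices(self, tag: int) -> np.ndarray:
        facets = self.boundary_facets[self.boundary_tags == tag]
        return np.unique(facets.ravel())


_EDGES_2D = np.array([[0, 1], [0, 2], [1, 2]])
_EDGES_3D = np.array([[0, 1], [0, 2], [0, 3], [1, 2], [1, 3], [2, 3]])


def _unique_edges(cells: np.ndarray, dim: int):
    loc = _EDGES_2D if dim == 2 else _EDGES_3D
    pairs = cells[:, loc]  # (m, ne, 2)
    pairs = np.sort(pairs.reshape(-1, 2), axis=1)
    uniq, inv = np.unique(pairs, axis=0, return_inverse=True)
    return uniq, inv.reshape(cells.shape[0], len(loc))


def refine(mesh: SimplicialMesh) -> tuple[SimplicialMesh, sp.csr_matrix]:
    """One uniform red refinement step.

    Returns the refined mesh and the prolongation matrix P (fine x coarse)
    interpolating coarse P1 functions exactly on the fine mesh.  Children of
    cell ``c`` occupy fine indices ``[c*2^d, (c+1)*2^d)`` so the parent of a
    fine cell is ``index // 2^d``.
    """
    d = mesh.dim
    n = mesh.n_vertices
    edges, cell_edge = _unique_edges(mesh.cells, d)
    mids = 0.5 * (mesh.points[edges[:, 0]] + mesh.points[edges[:, 1]])
    points = np.vstack([mesh.points, mids])
    mid_id = n + np.arange(len(edges))
    edge_lookup = {tuple(e): n + i for i, e in enumerate(map(tuple, edges))}

    c = mesh.cells
    m = cell_edge  # per-cell edge ids into `edges`
    if d == 2:
        m01, m02, m12 = (mid_id[m[:, k]] for k in range(3))
        v0, v1, v2 = c[:, 0], c[:, 1], c[:, 2]
        children = np.stack(
            [
                np.stack([v0, m01, m02], axis=1),
                np.stack([m01, v1, m12], axis=1),
                np.stack([m02, m12, v2], axis=1),
                np.stack([m01, m12, m02], axis=1),
            ],
            axis=1,
        ).reshape(-1, 3)
    else:
        m01, m02, m03, m12, m13, m23 = (mid_id[m[:, k]] for k in range(6))
        v0, v1, v2, v3 = c[:, 0], c[:, 1], c[:, 2], c[:, 3]
        tets = [
            (v0, m01, m02, m03),
            (m01, v1, m12, m13),
            (m02, m12, v2, m23),
            (m03, m13, m23, v3),
            # octahedron split along the m02-m13 diagonal (Bey's rule)
            (m01, m02, m03, m13),
            (m01, m02, m12, m13),
            (m02, m03, m13, m23),
            (m02, m12, m13, m23),
        ]
        children = np.stack([np.stack(t, axis=1) for t in tets], axis=1).reshape(-1, 4)

    n_child = 2**d
    regions = np.repeat(mesh.cell_regions, n_child)

    # refine boundary facets with tag inheritance
    bf = mesh.boundary_facets
    tags = mesh.boundary_tags
    if d == 2:
        bm = np.array(
            [edge_lookup[tuple(sorted((a, b)))] for a, b in bf], dtype=int
        ) if len(bf) else np.empty(0, dtype=int)
        new_bf = np.concatenate(
            [np.stack([bf[:, 0], bm], axis=1), np.stack([bm, bf[:, 1]], axis=1)]
        ) if len(bf) else bf.copy()
        new_tags = np.concatenate([tags, tags])
    else:
        def _mid(a, b):
            return edge_lookup[(min(a, b), max(a, b))]

        tris, new_tags_l = [], []
        for (a, b, cc), t in zip(bf, tags):
            mab, mac, mbc = _mid(a, b), _mid(a, cc), _mid(b, cc)
            tris += [(a, mab, mac), (mab, b, mbc), (mac, mbc, cc), (mab, mbc, mac)]
            new_tags_l += [t, t, t, t]
        new_bf = np.array(tris, dtype=int) if tris else bf.copy()
        new_tags = np.array(new_tags_l, dtype=int)

    rows = np.concatenate([np.arange(n), mid_id, mid_id])
    cols = np.concatenate([np.arange(n), edges[:, 0], edges[:, 1]])
    vals = np.concatenate([np.ones(n), np.full(2 * len(edges), 0.5)])
    P = sp.coo_matrix((vals, (rows, cols)), shape=(len(points), n)).tocsr()

    fine = SimplicialMesh(
        points, children.astype(np.int64), regions, new_bf, new_tags, mesh.measure_scale
    )
    return fine, P


@dataclass
class MeshHierarchy:
    """Nested meshes, level 1 = coarsest, with per-level time steps.

    ``dt(level)`` returns dt_base * 2^-level seconds; the horizon T must be
    divisible by the finest time step.
    """

    meshes: list  # of SimplicialMesh
    prolongations: list  # of csr, coarse -> fine, len n_levels-1
    dt_base: float = 900.0  # 15 min in seconds
    T: float = 86400.0  # one day
    spec: GeometrySpec | None = None

    def __post_init__(self):
        n_steps = self.T / self.dt(self.n_levels)
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise GeometryError("T must be divisible by every per-level time step")

    @property
    def n_levels(self) -> int:
        return len(self.meshes)

    def mesh(self, level: int) -> SimplicialMesh:
        return self.meshes[level - 1]

    def prolongation(self, level: int) -> sp.csr_matrix:
        """P mapping level ``level`` nodal values to level ``level+1``."""
        return self.prolongations[level - 1]

    def dt(self, level: int) -> float:
        return self.dt_base * 2.0 ** (-level)

    def cell_parents(self, level: int) -> np.ndarray:
        """Parent (level-1) cell index of each cell on ``level`` (>= 2)."""
        d = self.mesh(level).dim
        return np.arange(self.mesh(level).n_cells) // (2**d)


# ---------------------------------------------------------------------------
# surrogate parenchyma construction
# ---------------------------------------------------------------------------


def _radial_rings(spec: GeometrySpec) -> np.ndarray:
    h = spec.base_resolution
    n_white = max(1, round((spec.gray_inner_radius - spec.ventricle_radius) / h))
    n_gray = max(1, round(spec.gray_thickness / h))
    white = np.linspace(spec.ventricle_radius, spec.gray_inner_radius, n_white + 1)
    gray = np.linspace(spec.gray_inner_radius, spec.outer_radius, n_gray + 1)
    return np.concatenate([white, gray[1:]])


def _coarse_annulus(spec: GeometrySpec) -> SimplicialMesh:
    radii = _radial_rings(spec)
    r_mid = 0.5 * (spec.ventricle_radius + spec.outer_radius)
    nt = max(8, int(round(2 * np.pi * r_mid / spec.base_resolution)))
    theta = 2 * np.pi * np.arange(nt) / nt
    pts = np.concatenate(
        [np.stack([r * np.cos(theta), r * np.sin(theta)], axis=1) for r in radii]
    )
    cells = []
    for i in range(len(radii) - 1):
        a = i * nt + np.arange(nt)
        b = i * nt + (np.arange(nt) + 1) % nt
        c = a + nt
        dd = b + nt
        cells.append(np.stack([a, b, dd], axis=1))
        cells.append(np.stack([a, dd, c], axis=1))
    cells = np.concatenate(cells)
    # boundary facets
    inner = np.stack([np.arange(nt), (np.arange(nt) + 1) % nt], axis=1)
    off = (len(radii) - 1) * nt
    outer = off + inner
    bf = np.concatenate([inner, outer])
    tags = np.concatenate([np.full(nt, VENTRICLE), np.full(nt, SAS)])
    regions = _tag_regions(spec, pts, cells)
    return SimplicialMesh(
        pts, cells.astype(np.int64), regions, bf.astype(np.int64), tags, spec.slab_thickness
    )


def _icosahedron() -> tuple[np.ndarray, np.ndarray]:
    phi = (1 + np.sqrt(5)) / 2
    v = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    f = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ]
    )
    return v, f


def _subdivide_sphere(v: np.ndarray, f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    edges, cell_edge = _unique_edges(f, 3 - 1)  # faces are triangles: use 2D edge table
    mids = v[edges[:, 0]] + v[edges[:, 1]]
    mids /= np.linalg.norm(mids, axis=1, keepdims=True)
    n = len(v)
    vv = np.vstack([v, mids])
    mid = n + cell_edge
    m01, m02, m12 = mid[:, 0], mid[:, 1], mid[:, 2]
    a, b, c = f[:, 0], f[:, 1], f[:, 2]
    ff = np.concatenate(
        [
            np.stack([a, m01, m02], axis=1),
            np.stack([m01, b, m12], axis=1),
            np.stack([m02, m12, c], axis=1),
            np.stack([m01, m12, m02], axis=1),
        ]
    )
    return vv, ff


def _split_prism(g: np.ndarray) -> list[tuple[int, int, int, int]]:
    """Split a prism (bottom g[0:3], top g[3:6], g[i+3] above g[i]) into 3 tets.

    Quad diagonals are chosen through each quad's smallest global vertex id,
    which makes the decomposition conforming across neighbouring prisms.
    """
    g = list(g)
    k = int(np.argmin(g))
    if k >= 3:  # flip top/bottom so the smallest id is on the bottom
        g = g[3:] + g[:3]
        k -= 3
    # rotate so the smallest id is at local position 0
    rot = [k, (k + 1) % 3, (k + 2) % 3]
    g = [g[r] for r in rot] + [g[r + 3] for r in rot]
    if min(g[1], g[5]) < min(g[2], g[4]):
        return [(g[0], g[1], g[2], g[5]), (g[0], g[1], g[5], g[4]), (g[0], g[4], g[5], g[3])]
    return [(g[0], g[1], g[2], g[4]), (g[0], g[4], g[2], g[5]), (g[0], g[4], g[5], g[3])]


def _coarse_shell(spec: GeometrySpec) -> SimplicialMesh:
    radii = _radial_rings(spec)
    v, f = _icosahedron()
    # subdivide the sphere surface until edge length ~ base_resolution at mid radius
    r_mid = 0.5 * (spec.ventricle_radius + spec.outer_radius)
    while True:
        edge = np.linalg.norm(v[f[0, 0]] - v[f[0, 1]]) * r_mid
        if edge <= 1.6 * spec.base_resolution or len(v) > 3000:
            break
        v, f = _subdivide_sphere(v, f)
    ns = len(v)
    pts = np.concatenate([r * v for r in radii])
    cells = []
    for i in range(len(radii) - 1):
        for tri in f:
            bottom = (i * ns + tri).tolist()
            top = ((i + 1) * ns + tri).tolist()
            cells.extend(_split_prism(bottom + top))
    cells = np.array(cells, dtype=np.int64)
    off = (len(radii) - 1) * ns
    bf = np.concatenate([f, off + f])
    tags = np.concatenate([np.full(len(f), VENTRICLE), np.full(len(f), SAS)])
    regions = _tag_regions(spec, pts, cells)
    return SimplicialMesh(pts, cells, regions, bf.astype(np.int64), tags)


def _tag_regions(spec: GeometrySpec, pts: np.ndarray, cells: np.ndarray) -> np.ndarray:
    cent = pts[cells].mean(axis=1)
    # classify by mean vertex radius: vertices sit exactly on the radial
    # rings, so this is robust to the centroid of coarse curved-shell cells
    # being pulled inward by the chord
    r = np.linalg.norm(pts[cells], axis=2).mean(axis=1)
    regions = np.where(r >= spec.gray_inner_radius, GRAY, WHITE)
    centers = np.atleast_2d(np.asarray(spec.probe_centers, dtype=float))
    for center, code, base in zip(centers, (S_G, S_W), (GRAY, WHITE)):
        dist = np.linalg.norm(cent - center, axis=1)
        mask = (dist <= spec.probe_radius) & (regions == base)
        if not mask.any():  # fall back to the nearest cell of the right tissue
            cand = np.where(regions == base)[0]
            mask = np.zeros(len(cells), dtype=bool)
            mask[cand[np.argmin(dist[cand])]] = True
        regions[mask] = code
    return regions


def build_surrogate_hierarchy(
    spec: GeometrySpec,
    seed: int = 0,
    dt_base: float = 900.0,
    T: float = 86400.0,
) -> MeshHierarchy:
    """Build a nested hierarchy of surrogate parenchyma meshes.

    The construction is deterministic; ``seed`` is accepted for interface
    symmetry with the samplers and recorded nowhere else.
    """
    spec.validate()
    coarse = _coarse_annulus(spec) if spec.dimension == 2 else _coarse_shell(spec)
    meshes = [coarse]
    prolongations = []
    for _ in range(spec.n_levels - 1):
        fine, P = refine(meshes[-1])
        meshes.append(fine)
        prolongations.append(P)
    return MeshHierarchy(meshes, prolongations, dt_base=dt_base, T=T, spec=spec)


# ---------------------------------------------------------------------------
# embedding box
# ---------------------------------------------------------------------------


@dataclass
class BoxHierarchy:
    """Nested box meshes with barycentric transfer tables to the parenchyma.

    ``transfer[l-1]`` is a pair (cell_index, barycentric) mapping each
    parenchyma vertex of level ``l`` into its containing box cell on the box
    mesh of the same level.
    """

    meshes: list
    prolongations: list
    transfer: list  # [(cells (nv,), bary (nv, d+1)), ...]
    lo: np.ndarray
    hi: np.ndarray

    @property
    def n_levels(self) -> int:
        return len(self.meshes)

    def mesh(self, level: int) -> SimplicialMesh:
        return self.meshes[level - 1]

    def prolongation(self, level: int) -> sp.csr_matrix:
        return self.prolongations[level - 1]

    def restrict_to_parenchyma(self, level: int, nodal: np.ndarray) -> np.ndarray:
        cells_idx, bary = self.transfer[level - 1]
        verts = self.mesh(level).cells[cells_idx]
        return np.einsum("vi,vi->v", nodal[verts], bary)


def _coarse_box(spec: GeometrySpec) -> SimplicialMesh:
    lo, hi = spec.box_bounds()
    side = hi - lo
    h = spec.base_resolution
    n = np.maximum(2, np.round(side / h).astype(int))
    if spec.dimension == 2:
        nx, ny = n
        x = np.linspace(lo[0], hi[0], nx + 1)
        y = np.linspace(lo[1], hi[1], ny + 1)
        X, Y = np.meshgrid(x, y, indexing="ij")
        pts = np.stack([X.ravel(), Y.ravel()], axis=1)

        def vid(i, j):
            return i * (ny + 1) + j

        cells = []
        for i in range(nx):
            for j in range(ny):
                a, b = vid(i, j), vid(i + 1, j)
                c, d = vid(i, j + 1), vid(i + 1, j + 1)
                cells += [(a, b, d), (a, d, c)]
        cells = np.array(cells, dtype=np.int64)
        # boundary facets (tagged BOX_BOUNDARY; only the vertex set matters)
        bfs = []
        for i in range(nx):
            bfs += [(vid(i, 0), vid(i + 1, 0)), (vid(i, ny), vid(i + 1, ny))]
        for j in range(ny):
            bfs += [(vid(0, j), vid(0, j + 1)), (vid(nx, j), vid(nx, j + 1))]
        bf = np.array(bfs, dtype=np.int64)
    else:
        nx, ny, nz = n
        axes = [np.linspace(lo[k], hi[k], n[k] + 1) for k in range(3)]
        X, Y, Z = np.meshgrid(*axes, indexing="ij")
        pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

        def vid(i, j, k):
            return (i * (ny + 1) + j) * (nz + 1) + k

        # Kuhn subdivision of each hex into 6 tets: paths 0 -> (1,1,1)
        from itertools import permutations

        perms = list(permutations(range(3)))
        cells = []
        for i in range(nx):
            for j in range(ny):
                for k in range(nz):
                    base = np.array([i, j, k])
                    for perm in perms:
                        idx = [base.copy()]
                        cur = base.copy()
                        for ax in perm:
                            cur = cur.copy()
                            cur[ax] += 1
                            idx.append(cur)
                        cells.append(tuple(vid(*p) for p in idx))
        cells = np.array(cells, dtype=np.int64)
        # boundary facets: any tet face lying on the box surface
        bf = _boundary_faces_on_box(pts, cells, lo, hi)
    regions = np.zeros(len(cells), dtype=np.int64)
    tags = np.full(len(bf), BOX_BOUNDARY)
    return SimplicialMesh(pts, cells, regions, bf, tags)


def _boundary_faces_on_box(pts, cells, lo, hi) -> np.ndarray:
    faces = np.concatenate(
        [cells[:, [1, 2, 3]], cells[:, [0, 2, 3]], cells[:, [0, 1, 3]], cells[:, [0, 1, 2]]]
    )
    tol = 1e-12 * np.max(hi - lo)
    out = []
    for ax in range(3):
        for val in (lo[ax], hi[ax]):
            on = np.all(np.abs(pts[faces][:, :, ax] - val) < tol, axis=1)
            out.append(faces[on])
    return np.unique(np.sort(np.concatenate(out), axis=1), axis=0)


def boundary_vertices_of_box(mesh: SimplicialMesh, lo, hi) -> np.ndarray:
    tol = 1e-12 * float(np.max(hi - lo))
    on = np.zeros(mesh.n_vertices, dtype=bool)
    for ax in range(mesh.dim):
        on |= np.abs(mesh.points[:, ax] - lo[ax]) < tol
        on |= np.abs(mesh.points[:, ax] - hi[ax]) < tol
    return np.where(on)[0]


def locate_points(
    mesh: SimplicialMesh, query: np.ndarray, tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray]:
    """Find containing cell and barycentric coordinates for each query point."""
    d = mesh.dim
    cent = mesh.points[mesh.cells].mean(axis=1)
    tree = cKDTree(cent)
    nq = len(query)
    cells_out = np.full(nq, -1, dtype=np.int64)
    bary_out = np.zeros((nq, d + 1))
    A = np.ones((mesh.n_cells, d + 1, d + 1))
    A[:, 1:, :] = np.transpose(mesh.points[mesh.cells], (0, 2, 1))
    Ainv = np.linalg.inv(A)
    k = min(16, mesh.n_cells)
    _, nbrs = tree.query(query, k=k)
    nbrs = np.atleast_2d(nbrs)
    rhs = np.concatenate([np.ones((nq, 1)), query], axis=1)
    for col in range(nbrs.shape[1]):
        todo = cells_out < 0
        if not todo.any():
            break
        cand = nbrs[todo, col]
        lam = np.einsum("qij,qj->qi", Ainv[cand], rhs[todo])
        ok = np.all(lam >= -tol, axis=1)
        idx = np.where(todo)[0][ok]
        cells_out[idx] = cand[ok]
        bary_out[idx] = np.clip(lam[ok], 0.0, None)
    missing = np.where(cells_out < 0)[0]
    if len(missing):  # exhaustive fallback for stragglers
        for q in missing:
            lam = np.einsum("cij,j->ci", Ainv, rhs[q])
            ok = np.where(np.all(lam >= -tol, axis=1))[0]
            if len(ok) == 0:
                raise GeometryError("point outside mesh during location")
            cells_out[q] = ok[0]
            bary_out[q] = np.clip(lam[ok[0]], 0.0, None)
    bary_out /= bary_out.sum(axis=1, keepdims=True)
    return cells_out, bary_out


def build_embedding_box(
    hierarchy: MeshHierarchy,
    spec: GeometrySpec | None = None,
    correlation_length: float | None = None,
    refine_extra: int = 0,
) -> BoxHierarchy:
    """Build the nested box hierarchy and the vertex transfer tables.

    The box must strictly contain every parenchyma vertex; a margin smaller
    than the field correlation length triggers a truncation-error warning
    (the boundary effect of the sampling PDE decays exponentially with
    distance from the box boundary).
    """
    spec = spec or hierarchy.spec
    if spec is None:
        raise GeometryError("a GeometrySpec is required to size the box")
    lo, hi = spec.box_bounds()
    if correlation_length is not None and np.min(np.asarray(spec.box_margins)) < correlation_length:
        warnings.warn(
            "box margin smaller than the field correlation length; "
            "domain-truncation error may not be negligible",
            stacklevel=2,
        )
    coarse = _coarse_box(spec)
    # optionally refine the sampling box beyond the parenchyma resolution so
    # the coarsest level resolves the field (kappa * h <~ 1)
    for _ in range(refine_extra):
        coarse, _ = refine(coarse)
    meshes = [coarse]
    prolongations = []
    for _ in range(hierarchy.n_levels - 1):
        fine, P = refine(meshes[-1])
        meshes.append(fine)
        prolongations.append(P)
    transfer = []
    tol_geo = 1e-12 * float(np.max(hi - lo))
    for level in range(1, hierarchy.n_levels + 1):
        par = hierarchy.mesh(level)
        if np.any(par.points < lo + tol_geo) or np.any(par.points > hi - tol_geo):
            raise GeometryError("parenchyma vertex on or outside the embedding box boundary")
        cells_idx, bary = locate_points(meshes[level - 1], par.points)
        transfer.append((cells_idx, bary))
    return BoxHierarchy(meshes, prolongations, transfer, lo, hi)


def structured_box_hierarchy(
    lo, hi, n_cells_per_axis: int, n_levels: int, dimension: int = 2
) -> BoxHierarchy:
    """A standalone structured box hierarchy (no embedded parenchyma).

    Used for field diagnostics and covariance studies; the transfer table is
    empty, so samples carry box nodal values only.
    """
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)

    class _Spec:
        pass

    s = _Spec()
    s.dimension = dimension
    s.base_resolution = float(np.max(hi - lo)) / n_cells_per_axis
    s.box_bounds = lambda: (lo, hi)
    coarse = _coarse_box(s)
    meshes = [coarse]
    prolongations = []
    for _ in range(n_levels - 1):
        fine, P = refine(meshes[-1])
        meshes.append(fine)
        prolongations.append(P)
    return BoxHierarchy(meshes, prolongations, [], lo, hi)


# ---------------------------------------------------------------------------
# geometric reconstruction of hierarchy links (used by mesh IO)
# ---------------------------------------------------------------------------


def reconstruct_prolongation(coarse: SimplicialMesh, fine: SimplicialMesh) -> sp.csr_matrix:
    """Rebuild the coarse->fine interpolation matrix from geometry alone.

    Exact for nested meshes: each fine vertex lies in some coarse cell and its
    barycentric coordinates reproduce coarse P1 functions exactly.
    """
    cells_idx, bary = locate_points(coarse, fine.points)
    verts = coarse.cells[cells_idx]
    keep = bary > 1e-12
    rows = np.repeat(np.arange(fine.n_vertices), keep.sum(axis=1))
    cols = verts[keep]
    vals = bary[keep]
    return sp.coo_matrix(
        (vals, (rows, cols)), shape=(fine.n_vertices, coarse.n_vertices)
    ).tocsr()
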