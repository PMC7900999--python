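"""Piecewise-linear (P1) finite element kernels on simplicial meshes.

Dimension-generic (d = 2 triangles, d = 3 tetrahedra) vectorised assembly of
the standard operators used throughout the package: consistent and lumped
mass matrices, stiffness with a P1 diffusion coefficient, and the convection
operator for the weak form (div(v c), s) evaluated with vertex quadrature
(the quadrature that is consistent with mass lumping).
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp


def cell_volumes(points: np.ndarray, cells: np.ndarray) -> np.ndarray:
    """Signed-free volumes (areas in 2D) of each simplex."""
    d = points.shape[1]
    edges = points[cells[:, 1:]] - points[cells[:, :1]]  # (m, d, d)
    det = np.linalg.det(edges)
    fact = 2.0 if d == 2 else 6.0
    return np.abs(det) / fact


def shape_gradients(points: np.ndarray, cells: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Gradients of the d+1 barycentric basis functions per cell.

    Returns (grads, vols) with grads of shape (m, d+1, d): constant gradient
    of each P1 basis function on each cell.
    """
    d = points.shape[1]
    m = cells.shape[0]
    # Solve for gradients: [1 x_i] coefficients.  Build the (d+1)x(d+1)
    # system per cell: A^T lambda = e_i with A rows (1, x_i).
    A = np.ones((m, d + 1, d + 1))
    A[:, :, 1:] = points[cells]
    inv = np.linalg.inv(A)  # columns of inv give basis coefficients
    grads = np.transpose(inv[:, 1:, :], (0, 2, 1))  # (m, d+1, d)
    vols = cell_volumes(points, cells)
    return grads, vols


def _scatter(cells: np.ndarray, local: np.ndarray, n: int) -> sp.csr_matrix:
    """Assemble (m, d+1, d+1) local matrices into a global sparse matrix."""
    nloc = cells.shape[1]
    rows = np.repeat(cells, nloc, axis=1).ravel()
    cols = np.tile(cells, (1, nloc)).ravel()
    return sp.coo_matrix((local.ravel(), (rows, cols)), shape=(n, n)).tocsr()


def mass_matrix(points: np.ndarray, cells: np.ndarray) -> sp.csr_matrix:
    """Consistent P1 mass matrix M_ij = int phi_i phi_j."""
    d = points.shape[1]
    n = points.shape[0]
    vols = cell_volumes(points, cells)
    nloc = d + 1
    base = (np.ones((nloc, nloc)) + np.eye(nloc)) / ((nloc) * (nloc + 1))
    local = vols[:, None, None] * base[None]
    return _scatter(cells, local, n)


def lumped_mass(points: np.ndarray, cells: np.ndarray) -> np.ndarray:
    """Row-sum lumped mass matrix as a vector (equals V_e/(d+1) per vertex)."""
    d = points.shape[1]
    n = points.shape[0]
    vols = cell_volumes(points, cells)
    contrib = np.repeat(vols / (d + 1), d + 1)
    out = np.zeros(n)
    np.add.at(out, cells.ravel(), contrib)
    return out


def stiffness_matrix(
    points: np.ndarray,
    cells: np.ndarray,
    coeff: np.ndarray | float = 1.0,
) -> sp.csr_matrix:
    """Stiffness K_ij = int D grad phi_i . grad phi_j.

    ``coeff`` may be a scalar, a per-cell array, or a nodal (P1) array, which
    is reduced to its per-cell mean (midpoint-rule quadrature, second order).
    """
    n = points.shape[0]
    grads, vols = shape_gradients(points, cells)
    coeff = np.asarray(coeff, dtype=float)
    if coeff.ndim == 0:
        ce = float(coeff) * np.ones(len(cells))
    elif coeff.shape[0] == n:
        ce = coeff[cells].mean(axis=1)
    elif coeff.shape[0] == len(cells):
        ce = coeff
    else:  # pragma: no cover - defensive
        raise ValueError("coefficient shape matches neither nodes nor cells")
    local = (ce * vols)[:, None, None] * np.einsum("mid,mjd->mij", grads, grads)
    return _scatter(cells, local, n)


def convection_matrix(
    points: np.ndarray, cells: np.ndarray, v_nodal: np.ndarray
) -> sp.csr_matrix:
    """Convection operator N_ij for the weak term (div(v c), phi_i).

    Expands div(v c) = v . grad c + (div v) c with P1 velocity; the products
    against the test function are integrated with vertex quadrature:
    N_e[i, j] = V_e/(d+1) * (v_i . grad phi_j + div_e v delta_ij).
    """
    d = points.shape[1]
    n = points.shape[0]
    grads, vols = shape_gradients(points, cells)
    v_cells = v_nodal[cells]  # (m, d+1, d)
    # div v per cell: sum_i v_i . grad phi_i
    div = np.einsum("mid,mid->m", v_cells, grads)
    local = np.einsum("mid,mjd->mij", v_cells, grads)
    idx = np.arange(d + 1)
    local[:, idx, idx] += div[:, None]
    local *= (vols / (d + 1))[:, None, None]
    return _scatter(cells, local, n)


def region_integral_weights(
    points: np.ndarray, cells: np.ndarray, cell_mask: np.ndarray
) -> np.ndarray:
    """Vector w such that w @ c = int_region c dx exactly for P1 fields c."""
    d = points.shape[1]
    n = points.shape[0]
    vols = cell_volumes(points, cells[cell_mask])
    w = np.zeros(n)
    np.add.at(w, cells[cell_mask].ravel(), np.repeat(vols / (d + 1), d + 1))
    return w


def project_cellwise_to_nodes(
    points: np.ndarray, cells: np.ndarray, cell_values: np.ndarray
) -> np.ndarray:
    """Mass-lumped L2 projection of piecewise-constant data to nodal P1 data.

    ``cell_values`` has shape (m,) or (m, k); returns (n,) or (n, k).
    """
    d = points.shape[1]
    n = points.shape[0]
    vols = cell_volumes(points, cells)
    lump = lumped_mass(points, cells)
    vals = np.atleast_2d(cell_values.T).T  # (m, k)
    out = np.zeros((n, vals.shape[1]))
    w = vols / (d + 1)
    for j in range(vals.shape[1]):
        np.add.at(out[:, j], cells.ravel(), np.repeat(w * vals[:, j], d + 1))
    out /= lump[:, None]
    return out if cell_values.ndim > 1 else out[:, 0]
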