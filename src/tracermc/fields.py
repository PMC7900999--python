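"""Matern Gaussian random fields by the SPDE / white-noise method.

A Matern field with variance sigma^2, smoothness nu and correlation length
lambda has covariance

    C(r) = sigma^2 2^(1-nu)/Gamma(nu) (kappa r)^nu K_nu(kappa r),
    kappa = sqrt(8 nu)/lambda.

Samples are drawn by solving (I - kappa^-2 Lap)^k u = eta W' on an embedding
box with homogeneous Dirichlet conditions, where W' is spatial Gaussian white
noise and nu = 2k - d/2 must make k a positive integer.  The white-noise FEM
load is realised cell-locally from independent standard normals through the
Cholesky factor of each local mass matrix, so that Cov(b) equals the global
mass matrix exactly; on nested hierarchies the coarse load is the exact
restriction (prolongation transpose) of the fine one, which is what makes the
multilevel coupling exact.

The scaling eta = sigma kappa^(-d/2) (4 pi)^(d/4) sqrt(Gamma(nu+d/2)/Gamma(nu))
matches the free-space marginal variance of the SPDE solution to sigma^2; the
box solution is only approximately Matern near the boundary, with the error
decaying exponentially with distance from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.special import gamma as gamma_fn
from scipy.special import kv
from scipy.stats import gamma as gamma_dist
from scipy.stats import norm

from . import fem
from .geometry import BoxHierarchy, boundary_vertices_of_box


class FieldError(ValueError):
    pass


@dataclass(frozen=True)
class MaternSpec:
    """Matern covariance parameters plus derived SPDE quantities."""

    sigma2: float
    nu: float
    lam: float
    d: int

    def __post_init__(self):
        if min(self.sigma2, self.nu, self.lam) <= 0:
            raise FieldError("sigma2, nu and lam must all be positive")
        k = (self.nu + self.d / 2) / 2
        if abs(k - round(k)) > 1e-12 or round(k) < 1:
            raise FieldError(
                f"nu={self.nu} in d={self.d} gives non-integer SPDE solve count "
                f"k={(self.nu + self.d / 2) / 2}; adjust nu so that nu = 2k - d/2 "
                "with integer k (e.g. nu=3 in 2D, nu=2.5 in 3D)"
            )

    @property
    def kappa(self) -> float:
        return np.sqrt(8 * self.nu) / self.lam

    @property
    def spde_k(self) -> int:
        return int(round((self.nu + self.d / 2) / 2))

    @property
    def eta(self) -> float:
        return spde_scaling(self)


def spde_scaling(spec: MaternSpec) -> float:
    """White-noise scaling eta matching the free-space variance to sigma^2."""
    d, nu = spec.d, spec.nu
    return float(
        np.sqrt(spec.sigma2)
        * spec.kappa ** (-d / 2)
        * (4 * np.pi) ** (d / 4)
        * np.sqrt(gamma_fn(nu + d / 2) / gamma_fn(nu))
    )


def matern_covariance(r, spec: MaternSpec):
    """Matern covariance at separation(s) r >= 0; C(0) = sigma^2."""
    r = np.asarray(r, dtype=float)
    out = np.full(r.shape, spec.sigma2)
    pos = r > 0
    kr = spec.kappa * r[pos]
    out[pos] = spec.sigma2 * 2 ** (1 - spec.nu) / gamma_fn(spec.nu) * kr**spec.nu * kv(spec.nu, kr)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# white noise
# ---------------------------------------------------------------------------


def _unit_cholesky(d: int) -> np.ndarray:
    nloc = d + 1
    base = (np.ones((nloc, nloc)) + np.eye(nloc)) / (nloc * (nloc + 1))
    return np.linalg.cholesky(base)


@dataclass
class WhiteNoiseRealization:
    """Per-cell standard-normal draws on one box level, cell-major order.

    ``z`` has shape (n_cells, d+1).  Cells of a red-refined hierarchy are
    stored children-contiguously, so increasing cell index enumerates
    coarse-ancestor blocks first: assigning QMC coordinates in this order
    puts the leading (most important) dimensions on the largest spatial
    scales.
    """

    level: int
    z: np.ndarray

    @property
    def n_draws(self) -> int:
        return self.z.size


def white_noise_dimension(mesh) -> int:
    return mesh.n_cells * (mesh.dim + 1)


def sample_white_noise(mesh, level: int, rng: np.random.Generator) -> WhiteNoiseRealization:
    """Pseudo-random white-noise draws for one box mesh."""
    return WhiteNoiseRealization(level, rng.standard_normal((mesh.n_cells, mesh.dim + 1)))


def white_noise_from_uniforms(mesh, level: int, u: np.ndarray) -> WhiteNoiseRealization:
    """Map (scrambled) low-discrepancy coordinates to white-noise draws.

    Coordinates are converted by the inverse standard-normal CDF (which
    preserves the coordinate-wise low-discrepancy structure) and consumed in
    coarse-ancestor-first cell order.
    """
    need = white_noise_dimension(mesh)
    if u.size < need:
        raise FieldError(f"low-discrepancy point has {u.size} coordinates, need {need}")
    z = norm.ppf(np.clip(u[:need], 1e-15, 1 - 1e-15))
    return WhiteNoiseRealization(level, z.reshape(mesh.n_cells, mesh.dim + 1))


def white_noise_load(mesh, noise: WhiteNoiseRealization) -> np.ndarray:
    """Assemble the FEM load b with Cov(b) = mass matrix, exactly."""
    d = mesh.dim
    vols = fem.cell_volumes(mesh.points, mesh.cells)
    L = _unit_cholesky(d)
    local = np.sqrt(vols)[:, None] * (noise.z @ L.T)  # (m, d+1)
    b = np.zeros(mesh.n_vertices)
    np.add.at(b, mesh.cells.ravel(), local.ravel())
    return b


def couple_white_noise(b_fine: np.ndarray, prolongation: sp.csr_matrix) -> np.ndarray:
    """Coarse white-noise load as the exact restriction of the fine load."""
    return prolongation.T @ b_fine


# ---------------------------------------------------------------------------
# SPDE solves on the box hierarchy
# ---------------------------------------------------------------------------


@dataclass
class FieldSample:
    """One field realization: nodal values on a box level and the parenchyma
    restriction obtained through the barycentric transfer table."""

    level: int
    box_values: np.ndarray
    parenchyma_values: np.ndarray
    spec: MaternSpec


class BoxFieldSampler:
    """Samples Matern fields on a nested box hierarchy.

    Caches one sparse LU factorization of (M + kappa^-2 K) per level; the k
    Helmholtz solves per draw then reduce to back-substitutions.
    """

    def __init__(self, box: BoxHierarchy, spec: MaternSpec):
        self.box = box
        self.spec = spec
        self._ops: dict[int, tuple] = {}

    def _level_ops(self, level: int):
        if level not in self._ops:
            mesh = self.box.mesh(level)
            M = fem.mass_matrix(mesh.points, mesh.cells)
            K = fem.stiffness_matrix(mesh.points, mesh.cells)
            A = (M + self.spec.kappa**-2 * K).tocsr()
            bdry = boundary_vertices_of_box(mesh, self.box.lo, self.box.hi)
            free = np.setdiff1d(np.arange(mesh.n_vertices), bdry)
            lu = spla.splu(A[free][:, free].tocsc())
            self._ops[level] = (M, free, lu)
        return self._ops[level]

    def noise_dimension(self, level: int) -> int:
        return white_noise_dimension(self.box.mesh(level))

    def solve(self, level: int, load: np.ndarray) -> FieldSample:
        """Apply the k-fold Helmholtz solve to a white-noise load."""
        M, free, lu = self._level_ops(level)
        mesh = self.box.mesh(level)
        u = np.zeros(mesh.n_vertices)
        rhs = self.spec.eta * load
        for _ in range(self.spec.spde_k):
            u = np.zeros(mesh.n_vertices)
            u[free] = lu.solve(rhs[free])
            if not np.all(np.isfinite(u)):
                raise FieldError("SPDE solve produced non-finite values")
            rhs = M @ u
        if len(self.box.transfer) >= level:
            restricted = self.box.restrict_to_parenchyma(level, u)
        else:  # standalone box without an embedded domain
            restricted = None
        return FieldSample(level, u, restricted, self.spec)

    def sample(self, level: int, rng: np.random.Generator) -> FieldSample:
        noise = sample_white_noise(self.box.mesh(level), level, rng)
        return self.solve(level, white_noise_load(self.box.mesh(level), noise))

    def sample_coupled(
        self, level: int, rng: np.random.Generator
    ) -> tuple[FieldSample, FieldSample]:
        """One event, two levels: fine draw plus its exact coarse restriction."""
        if level < 2:
            raise FieldError("coupled sampling needs level >= 2")
        mesh_f = self.box.mesh(level)
        noise = sample_white_noise(mesh_f, level, rng)
        b_f = white_noise_load(mesh_f, noise)
        b_c = couple_white_noise(b_f, self.box.prolongation(level - 1))
        return self.solve(level, b_f), self.solve(level - 1, b_c)

    def sample_from_uniforms(self, level: int, u: np.ndarray) -> FieldSample:
        noise = white_noise_from_uniforms(self.box.mesh(level), level, u)
        return self.solve(level, white_noise_load(self.box.mesh(level), noise))


# ---------------------------------------------------------------------------
# copula transform
# ---------------------------------------------------------------------------


def gamma_copula_transform(values: np.ndarray, shape: float, scale: float) -> np.ndarray:
    """Monotone map F^-1(Phi(x)) from standard-normal to gamma marginals.

    ``values`` are point values of a standard (zero-mean, unit-variance)
    Gaussian field; the output is strictly positive with the same spatial
    dependence structure (rank correlation preserved).
    """
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise FieldError("non-finite input to copula transform")
    # isf(sf(.)) keeps full accuracy in both tails
    return gamma_dist.isf(norm.sf(values), shape, scale=scale)
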