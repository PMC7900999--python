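"""Binding of geometry, random fields, coefficients and transport into
samplers with the interfaces the Monte Carlo estimators expect.

A :class:`TransportSampler` owns a parenchyma hierarchy, its embedding-box
field samplers, the calibrated coefficient model (Model 1 glymphatic or
Model 2 capillary filtration) and the precomputed CSF drive.  It exposes

* ``sample_qoi(level, rng)`` — one functional vector Q_l,
* ``sample_pair(level, rng)`` — one coupled pair (Q_l, Q_(l-1)) sharing the
  scalar draws and the white-noise event (restricted exactly to the coarse
  level),
* ``sample_qoi_from_uniforms(level, u)`` — the QMC integrand H(u), with the
  scalar random inputs on the leading coordinates and the white-noise
  coordinates following in coarse-ancestor-first cell order.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import gamma as gamma_dist

from . import coefficients as co
from . import fields, transport
from .geometry import BoxHierarchy, MeshHierarchy, build_embedding_box


class TransportSampler:
    """Samples the tracer-transport output functionals on a mesh hierarchy."""

    def __init__(
        self,
        hierarchy: MeshHierarchy,
        model: str = "model2",
        diffusion: co.DiffusionParams | None = None,
        model1: co.Model1Params | None = None,
        model2: co.Model2Params | None = None,
        boundary: transport.BoundaryParams | None = None,
        tau: np.ndarray | None = None,
        box: BoxHierarchy | None = None,
        drive: transport.CsfDrive | None = None,
        drive_dt: float | None = None,
        calibration_samples: int = 64,
        box_refine_extra: int = 0,
    ):
        if model not in ("model1", "model2"):
            raise ValueError("model must be 'model1' or 'model2'")
        self.hierarchy = hierarchy
        self.model = model
        d = hierarchy.mesh(1).dim
        nu_default = 3.0 if d == 2 else 2.5
        self.diffusion = diffusion or co.DiffusionParams(nu=nu_default)
        self.model1 = model1 or co.Model1Params(nu_v=nu_default, lam_v=0.01 if d == 2 else 1.020e-3)
        self.model2 = model2 or co.Model2Params()
        self.boundary = boundary or transport.BoundaryParams()
        self.tau = tau if tau is not None else transport.default_tau_grid()
        self.box = box or build_embedding_box(
            hierarchy, correlation_length=self.diffusion.lam, refine_extra=box_refine_extra
        )

        self.diff_sampler = fields.BoxFieldSampler(self.box, self.diffusion.matern(d))
        finest = hierarchy.n_levels
        mesh_f = hierarchy.mesh(finest)
        if model == "model1":
            self.vel_sampler = fields.BoxFieldSampler(self.box, self.model1.matern(d))
            if self.model1.scaling_mode == "calibrated":
                self._m1_scale = co.calibrate_glymphatic_scale(
                    mesh_f, self.vel_sampler, finest, n_pilot=calibration_samples
                )
            else:
                self._m1_scale = co.glymphatic_scale(self.model1)
            self._n_stream = 1 if d == 2 else 3
        else:
            self.vel_sampler = None
            self._m2_scale = co.calibrate_model2_scale(mesh_f, self.model2)
            self._n_stream = 0

        self._weights = {}
        self.drive = drive or transport.precompute_csf_drive(
            hierarchy, *self.mean_coefficients(finest), self.boundary, dt_bar=drive_dt
        )

    # -- coefficients -------------------------------------------------------

    def mean_coefficients(self, level: int):
        """(D, v, r) with every random input replaced by its mean."""
        mesh = self.hierarchy.mesh(level)
        D = self.diffusion.D_gad
        if self.model == "model1":
            v = co.directional_velocity(mesh.points, self.model1, mesh.dim)
            r = 0.0
        else:
            vbar_mean = self.model2.gamma_shape * self._m2_scale
            v = vbar_mean * co.model2_profile(mesh.points, self.model2)
            r = self.model2.r
        return D, v, r

    def glymphatic_scale(self) -> float:
        return self._m1_scale

    def model2_gamma_scale(self) -> float:
        return self._m2_scale

    def realization(
        self, level: int, scalars: dict, field_values: list[np.ndarray]
    ) -> co.CoefficientRealization:
        """Assemble (D*, v, r) from scalar draws and parenchyma field values."""
        mesh = self.hierarchy.mesh(level)
        D = co.diffusion_field(field_values[0], self.diffusion)
        if self.model == "model1":
            stream = (
                field_values[1]
                if mesh.dim == 2
                else np.stack(field_values[1:4], axis=1)
            )
            v = co.model1_velocity(mesh, stream, scalars["U"], self.model1, self._m1_scale)
            r = 0.0
        else:
            v = co.model2_velocity(mesh, scalars["vbar"], self.model2)
            r = self.model2.r
        return co.CoefficientRealization(level, D, v, r, scalars)

    def _draw_scalars(self, u: np.ndarray) -> dict:
        if self.model == "model1":
            return {"U": float(u[0])}
        vbar = float(
            gamma_dist.ppf(
                np.clip(u[0], 1e-15, 1 - 1e-15),
                self.model2.gamma_shape,
                scale=self._m2_scale,
            )
        )
        return {"vbar": vbar}

    @property
    def n_scalars(self) -> int:
        return 1

    @property
    def n_fields(self) -> int:
        return 1 + self._n_stream

    def qmc_dimension(self, level: int) -> int:
        return self.n_scalars + self.n_fields * self.diff_sampler.noise_dimension(level)

    # -- sampling -----------------------------------------------------------

    def _field_samplers(self):
        return [self.diff_sampler] + [self.vel_sampler] * self._n_stream

    def sample_coefficients(self, level: int, rng: np.random.Generator):
        scalars = self._draw_scalars(rng.uniform(size=1))
        vals = [s.sample(level, rng).parenchyma_values for s in self._field_samplers()]
        return self.realization(level, scalars, vals)

    def sample_coefficients_pair(self, level: int, rng: np.random.Generator):
        """Coupled fine/coarse realizations from one event."""
        scalars = self._draw_scalars(rng.uniform(size=1))
        fine_vals, coarse_vals = [], []
        for s in self._field_samplers():
            f, c = s.sample_coupled(level, rng)
            fine_vals.append(f.parenchyma_values)
            coarse_vals.append(c.parenchyma_values)
        return (
            self.realization(level, scalars, fine_vals),
            self.realization(level - 1, scalars, coarse_vals),
        )

    def qoi(self, coeffs: co.CoefficientRealization) -> np.ndarray:
        level = coeffs.level
        mesh = self.hierarchy.mesh(level)
        sol = transport.solve_transport(
            mesh,
            self.hierarchy.dt(level),
            coeffs.D,
            coeffs.v,
            coeffs.r,
            self.drive,
            self.tau,
            self.boundary,
            level=level,
        )
        if level not in self._weights:
            self._weights[level] = transport.functional_weights(mesh)
        return (self._weights[level] @ sol.snapshots.T).ravel()

    def sample_qoi(self, level: int, rng: np.random.Generator) -> np.ndarray:
        return self.qoi(self.sample_coefficients(level, rng))

    def sample_pair(self, level: int, rng: np.random.Generator):
        """Coupled (Q_l, Q_(l-1)); level 1 returns (Q_1, 0)."""
        if level == 1:
            q = self.sample_qoi(1, rng)
            return q, np.zeros_like(q)
        cf, cc = self.sample_coefficients_pair(level, rng)
        return self.qoi(cf), self.qoi(cc)

    def sample_qoi_from_uniforms(self, level: int, u: np.ndarray) -> np.ndarray:
        """QMC integrand: scalars first, then per-field white-noise blocks."""
        u = np.asarray(u, dtype=float)
        need = self.qmc_dimension(level)
        if u.size < need:
            raise ValueError(f"QMC point has {u.size} coordinates, need {need}")
        scalars = self._draw_scalars(u[: self.n_scalars])
        block = self.diff_sampler.noise_dimension(level)
        vals = []
        off = self.n_scalars
        for s in self._field_samplers():
            vals.append(
                s.sample_from_uniforms(level, u[off : off + block]).parenchyma_values
            )
            off += block
        return self.qoi(self.realization(level, scalars, vals))

    def functional_names(self) -> list[str]:
        return [
            f"{name}(tau={int(t / 60)}min)"
            for name in transport.FUNCTIONAL_NAMES
            for t in self.tau
        ]
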