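"""Matern field sampling: covariance, white noise, coupling, copula."""

import numpy as np
import pytest
from scipy.stats import gamma as gamma_dist
from scipy.stats import normaltest

from tracermc import fem, fields
from tracermc.geometry import structured_box_hierarchy


@pytest.fixture(scope="module")
def resolved_box():
    """Standalone 2-level 2D box on which kappa*h is well below 1."""
    return structured_box_hierarchy([0, 0], [0.2, 0.2], 40, 2)


@pytest.fixture(scope="module")
def spec2d():
    return fields.MaternSpec(sigma2=1.0, nu=3.0, lam=0.04, d=2)


class TestCovarianceFunction:
    def test_zero_separation_gives_variance(self):
        spec = fields.MaternSpec(2.5, 3.0, 0.02, d=2)
        assert fields.matern_covariance(0.0, spec) == pytest.approx(2.5)

    def test_nu_half_reduces_to_exponential(self):
        spec = fields.MaternSpec(1.3, 0.5, 0.03, d=3)  # nu = 2k - d/2 with k = 1
        r = np.array([0.0, 0.01, 0.03, 0.1])
        want = 1.3 * np.exp(-spec.kappa * r)
        assert np.allclose(fields.matern_covariance(r, spec), want, rtol=1e-12)

    def test_kappa_from_smoothness_and_length(self):
        spec = fields.MaternSpec(1.0, 2.5, 0.01, d=3)
        assert spec.kappa == pytest.approx(np.sqrt(20) / 0.01)  # ~447.2 1/m
        assert spec.spde_k == 2

    def test_non_integer_solve_count_rejected(self):
        with pytest.raises(fields.FieldError, match="integer"):
            fields.MaternSpec(1.0, 2.5, 0.01, d=2)  # k = 1.75 in 2D


class TestSpdeScaling:
    def test_eta_proportional_to_sigma(self):
        a = fields.MaternSpec(1.0, 2.5, 0.01, d=3)
        b = fields.MaternSpec(4.0, 2.5, 0.01, d=3)
        assert b.eta == pytest.approx(2 * a.eta)

    def test_eta_vanishes_with_sigma(self):
        base = fields.spde_scaling(fields.MaternSpec(1.0, 3.0, 0.02, d=2))
        small = fields.spde_scaling(fields.MaternSpec(1e-12, 3.0, 0.02, d=2))
        assert small == pytest.approx(base * 1e-6)

    def test_marginal_variance_recovered_by_sampling(self, resolved_box, spec2d):
        # the eta closed form is exactly what makes interior point variance
        # equal sigma^2; checked against a Monte Carlo oracle
        sampler = fields.BoxFieldSampler(resolved_box, spec2d)
        rng = np.random.default_rng(11)
        m = resolved_box.mesh(2)
        interior = np.where(np.all((m.points > 0.07) & (m.points < 0.13), axis=1))[0][:80]
        n = 500
        vals = np.array([sampler.sample(2, rng).box_values[interior] for _ in range(n)])
        var = vals.var(axis=0, ddof=1).mean()
        se = np.sqrt(2.0 / n)  # relative SE of a chi^2 variance estimate
        assert abs(var - 1.0) < 3 * se + 0.05  # small residual FEM bias allowed


class TestWhiteNoise:
    def test_load_covariance_equals_mass_matrix(self, two_triangle_mesh):
        rng = np.random.default_rng(0)
        n = 20000
        B = np.array(
            [
                fields.white_noise_load(
                    two_triangle_mesh,
                    fields.sample_white_noise(two_triangle_mesh, 1, rng),
                )
                for _ in range(n)
            ]
        )
        emp = B.T @ B / n
        M = fem.mass_matrix(two_triangle_mesh.points, two_triangle_mesh.cells).toarray()
        assert np.abs(emp - M).max() < 4 * M.max() * np.sqrt(2.0 / n)
        assert np.abs(B.mean(axis=0)).max() < 4 * np.sqrt(M.max() / n)

    def test_zero_draws_give_zero_load(self, two_triangle_mesh):
        noise = fields.WhiteNoiseRealization(1, np.zeros((2, 3)))
        assert np.all(fields.white_noise_load(two_triangle_mesh, noise) == 0)

    def test_qmc_uniforms_map_through_inverse_normal_cdf(self, two_triangle_mesh):
        u = np.full(6, 0.5)
        noise = fields.white_noise_from_uniforms(two_triangle_mesh, 1, u)
        assert np.allclose(noise.z, 0.0)
        with pytest.raises(fields.FieldError, match="coordinates"):
            fields.white_noise_from_uniforms(two_triangle_mesh, 1, np.ones(3))


class TestCoupling:
    def test_restricted_load_preserves_total(self, resolved_box):
        # partition of unity: coarse load entries sum to the fine total
        rng = np.random.default_rng(2)
        mesh_f = resolved_box.mesh(2)
        b_f = fields.white_noise_load(
            mesh_f, fields.sample_white_noise(mesh_f, 2, rng)
        )
        b_c = fields.couple_white_noise(b_f, resolved_box.prolongation(1))
        assert b_c.sum() == pytest.approx(b_f.sum(), rel=1e-12)

    def test_coarse_load_covariance_is_coarse_mass(self):
        box = structured_box_hierarchy([0, 0], [1, 1], 2, 2)
        mesh_f = box.mesh(2)
        P = box.prolongation(1)
        rng = np.random.default_rng(3)
        n = 20000
        B = np.array(
            [
                fields.couple_white_noise(
                    fields.white_noise_load(
                        mesh_f, fields.sample_white_noise(mesh_f, 2, rng)
                    ),
                    P,
                )
                for _ in range(n)
            ]
        )
        emp = B.T @ B / n
        Mc = fem.mass_matrix(box.mesh(1).points, box.mesh(1).cells).toarray()
        assert np.abs(emp - Mc).max() < 4 * Mc.max() * np.sqrt(2.0 / n)

    def test_coupled_fields_decorrelate_slowly(self, resolved_box, spec2d):
        # fine/coarse samples from one event: E[u_f - u_c] ~ 0 and the
        # difference is much smaller than the field scale
        sampler = fields.BoxFieldSampler(resolved_box, spec2d)
        rng = np.random.default_rng(4)
        m = resolved_box.mesh(2)
        pt = int(np.argmin(np.linalg.norm(m.points - [0.1, 0.1], axis=1)))
        pt_c = int(
            np.argmin(np.linalg.norm(resolved_box.mesh(1).points - [0.1, 0.1], axis=1))
        )
        pairs = np.array(
            [
                (f.box_values[pt], c.box_values[pt_c])
                for f, c in (sampler.sample_coupled(2, rng) for _ in range(300))
            ]
        )
        diff = pairs[:, 0] - pairs[:, 1]
        assert abs(diff.mean()) < 3 * diff.std(ddof=1) / np.sqrt(len(diff))
        corr = np.corrcoef(pairs.T)[0, 1]
        assert corr > 0.9


class TestSpdeSolve:
    def test_zero_load_gives_zero_field(self, resolved_box, spec2d):
        sampler = fields.BoxFieldSampler(resolved_box, spec2d)
        out = sampler.solve(1, np.zeros(resolved_box.mesh(1).n_vertices))
        assert np.all(out.box_values == 0)

    def test_field_vanishes_on_box_boundary(self, resolved_box, spec2d):
        sampler = fields.BoxFieldSampler(resolved_box, spec2d)
        s = sampler.sample(1, np.random.default_rng(5))
        from tracermc.geometry import boundary_vertices_of_box

        bdry = boundary_vertices_of_box(
            resolved_box.mesh(1), resolved_box.lo, resolved_box.hi
        )
        assert np.all(s.box_values[bdry] == 0)

    def test_reproducible_given_seed(self, resolved_box, spec2d):
        sampler = fields.BoxFieldSampler(resolved_box, spec2d)
        a = sampler.sample(2, np.random.default_rng(9)).box_values
        b = sampler.sample(2, np.random.default_rng(9)).box_values
        assert np.array_equal(a, b)

    def test_covariance_recovery_at_multiple_separations(self, resolved_box, spec2d):
        # interior empirical covariances at separations {0, lam/2, lam, 2lam}
        # match the Matern form within Monte Carlo error
        sampler = fields.BoxFieldSampler(resolved_box, spec2d)
        rng = np.random.default_rng(6)
        m = resolved_box.mesh(2)
        lam = spec2d.lam
        x0 = np.array([0.08, 0.1])
        seps = [0.0, lam / 2, lam, 2 * lam]
        idx = [
            int(np.argmin(np.linalg.norm(m.points - (x0 + [s, 0.0]), axis=1)))
            for s in seps
        ]
        n = 600
        vals = np.array([sampler.sample(2, rng).box_values[idx] for _ in range(n)])
        for k, s in enumerate(seps):
            r = np.linalg.norm(m.points[idx[k]] - m.points[idx[0]])
            prod = vals[:, 0] * vals[:, k]
            emp = prod.mean()
            se = prod.std(ddof=1) / np.sqrt(n)
            want = fields.matern_covariance(r, spec2d)
            assert abs(emp - want) < 3 * se + 0.05, f"separation {s}"

    def test_point_values_are_gaussian(self, resolved_box, spec2d):
        sampler = fields.BoxFieldSampler(resolved_box, spec2d)
        rng = np.random.default_rng(7)
        m = resolved_box.mesh(1)
        pt = int(np.argmin(np.linalg.norm(m.points - [0.1, 0.1], axis=1)))
        vals = np.array([sampler.sample(1, rng).box_values[pt] for _ in range(400)])
        assert normaltest(vals).pvalue > 0.01


class TestGammaCopula:
    def test_zero_maps_to_gamma_median(self):
        shape, scale = 3.0, 0.75 * 1.2e-10 / 3
        out = fields.gamma_copula_transform(np.array([0.0]), shape, scale)
        assert out[0] == pytest.approx(gamma_dist.ppf(0.5, shape, scale=scale))

    def test_monotone_and_positive(self):
        x = np.linspace(-6, 6, 101)
        y = fields.gamma_copula_transform(x, 3.0, 2.0)
        assert np.all(np.diff(y) > 0)
        assert np.all(y > 0)

    def test_sample_mean_matches_gamma_mean(self):
        rng = np.random.default_rng(8)
        z = rng.standard_normal(200_000)
        y = fields.gamma_copula_transform(z, 3.0, 0.5)
        se = y.std(ddof=1) / np.sqrt(len(y))
        assert abs(y.mean() - 1.5) < 3 * se

    def test_non_finite_input_rejected(self):
        with pytest.raises(fields.FieldError):
            fields.gamma_copula_transform(np.array([np.nan]), 3.0, 1.0)
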