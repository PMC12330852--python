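"""Spherical-harmonics machinery: basis, fitting, zonal projection,
convolution, direction sets, apodised deltas and the ACC metric."""

import numpy as np
import pytest

from loresd import harmonics as shm


def rotation_matrix(axis, angle):
    axis = np.asarray(axis, float) / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


class TestBasis:
    def test_column_count_and_constant(self):
        dirs = shm.uniform_directions(10, seed=1)
        Y = shm.sh_basis_matrix(dirs, 8)
        assert Y.shape == (10, 45)
        Y0 = shm.sh_basis_matrix(np.array([[0.0, 0.0, 1.0]]), 0)
        assert Y0.shape == (1, 1)
        assert Y0[0, 0] == pytest.approx(1 / np.sqrt(4 * np.pi), abs=1e-14)

    def test_orthonormality_monte_carlo(self):
        # Gram matrix under Monte-Carlo quadrature on quasi-uniform points
        rng = np.random.default_rng(0)
        v = rng.normal(size=(5000, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        Y = shm.sh_basis_matrix(v, 4)
        gram = Y.T @ Y * 4 * np.pi / len(v)
        assert np.abs(gram - np.eye(gram.shape[0])).max() < 5e-2

    def test_input_validation(self):
        with pytest.raises(ValueError):
            shm.sh_basis_matrix(np.array([[0.0, 0.0, 2.0]]), 4)
        with pytest.raises(ValueError):
            shm.sh_basis_matrix(np.array([[0.0, 0.0, 1.0]]), 3)


class TestFitShellSH:
    def test_constant_amplitude(self):
        dirs = shm.uniform_directions(60, seed=2)
        c = shm.fit_shell_sh(np.full(60, 2.5), dirs, 0)
        assert c[0] == pytest.approx(2.5 * np.sqrt(4 * np.pi), rel=1e-12)

    def test_bandlimited_round_trip(self):
        rng = np.random.default_rng(3)
        coeffs = rng.normal(size=shm.n_coeffs(4))
        dirs = shm.uniform_directions(128, seed=4)
        amps = shm.sh_basis_matrix(dirs, 4) @ coeffs
        rec = shm.fit_shell_sh(amps, dirs, 4)
        np.testing.assert_allclose(rec, coeffs, atol=1e-10)

    def test_high_order_residual_is_projection_residual(self):
        # fitting an lmax=12 signal at lmax=8 leaves exactly the energy that
        # the orders-10,12 component has outside the lmax=8 span
        rng = np.random.default_rng(5)
        dirs = shm.uniform_directions(256, seed=6)
        Y12 = shm.sh_basis_matrix(dirs, 12)
        c12 = rng.normal(size=Y12.shape[1])
        amps = Y12 @ c12
        Y8 = shm.sh_basis_matrix(dirs, 8)
        fit = shm.fit_shell_sh(amps, dirs, 8)
        res = np.linalg.norm(amps - Y8 @ fit)
        # oracle: the low-order part is reproduced exactly, so the residual
        # equals that of fitting the high-order component alone
        high = Y12[:, 45:] @ c12[45:]
        res_oracle = np.linalg.norm(high - Y8 @ shm.fit_shell_sh(high, dirs, 8))
        assert res == pytest.approx(res_oracle, rel=1e-9)

    def test_underdetermined_raises(self):
        dirs = shm.uniform_directions(10, seed=7)
        with pytest.raises(ValueError, match="lmax"):
            shm.fit_shell_sh(np.ones(10), dirs, 8)


class TestZonalProjection:
    def test_constant_kernel(self):
        t = shm.gauss_legendre_nodes(32)
        h = shm.zonal_projection(np.ones_like(t), t, 8)
        assert h[0] == pytest.approx(np.sqrt(4 * np.pi), rel=1e-12)
        np.testing.assert_allclose(h[1:], 0, atol=1e-12)

    def test_cos_squared(self):
        t = shm.gauss_legendre_nodes(32)
        h = shm.zonal_projection(t**2, t, 8)
        assert abs(h[0]) > 0 and abs(h[1]) > 0
        np.testing.assert_allclose(h[2:], 0, atol=1e-12)

    def test_gaussian_kernel_vs_quadrature_oracle(self):
        # independent oracle: Gauss-Legendre quadrature of the kernel against
        # each Legendre polynomial
        b, lpar, lperp = 1.0, 2.2, 0.7
        t, w = np.polynomial.legendre.leggauss(80)
        k = np.exp(-b * lperp) * np.exp(-b * (lpar - lperp) * t**2)
        h = shm.zonal_projection(k, t, 8, weights=w)
        from scipy.special import eval_legendre
        for j, l in enumerate(range(0, 9, 2)):
            integral = np.sum(w * k * eval_legendre(l, t))
            oracle = 2 * np.pi * np.sqrt((2 * l + 1) / (4 * np.pi)) * integral
            assert h[j] == pytest.approx(oracle, abs=1e-8)

    def test_too_few_nodes(self):
        with pytest.raises(ValueError):
            shm.zonal_projection(np.ones(3), np.linspace(-1, 1, 3), 8)


class TestConvolution:
    def test_isotropic_kernel_gives_constant_shells(self):
        H = np.zeros((3, 5))
        H[:, 0] = [np.sqrt(4 * np.pi), 2.0, 1.0]
        p = shm.apodised_delta([0.0, 0.0, 1.0])
        S = shm.spherical_convolve_coeffs(H, p, 8)
        dirs = shm.uniform_directions(50, seed=8)
        Y = shm.sh_basis_matrix(dirs, 8)
        for row in S:
            amps = Y @ row
            assert np.ptp(amps) < 1e-12

    def test_delta_convolution_reproduces_kernel_profile(self):
        # convolving a true delta with a zonal Gaussian kernel must evaluate
        # to the kernel profile itself (band-limit error only)
        t, _ = np.polynomial.legendre.leggauss(64)
        b, lpar, lperp = 2.0, 2.0, 0.3
        k = np.exp(-b * lperp) * np.exp(-b * (lpar - lperp) * t**2)
        h = shm.zonal_projection(k, t, 8)
        # true delta along z: p_lm = Y_lm(z)
        p = shm.sh_basis_matrix(np.array([[0.0, 0.0, 1.0]]), 8)[0]
        S = shm.spherical_convolve_coeffs(h[None, :], p, 8)[0]
        alphas = np.linspace(0, np.pi, 25)
        dirs = np.column_stack([np.sin(alphas), np.zeros_like(alphas), np.cos(alphas)])
        amps = shm.sh_basis_matrix(dirs, 8) @ S
        expected = np.exp(-b * lperp) * np.exp(-b * (lpar - lperp) * np.cos(alphas) ** 2)
        band_limit_err = np.abs(
            shm.zonal_basis_matrix(np.cos(alphas), 8) @ h - expected).max()
        np.testing.assert_allclose(amps, expected, atol=2 * band_limit_err + 1e-9)

    def test_bilinearity(self):
        rng = np.random.default_rng(9)
        H1, H2 = rng.normal(size=(2, 3, 5))
        p1, p2 = rng.normal(size=(2, 45))
        a, b = 0.3, -1.7
        lhs = shm.spherical_convolve_coeffs(a * H1 + b * H2, p1, 8)
        rhs = a * shm.spherical_convolve_coeffs(H1, p1, 8) \
            + b * shm.spherical_convolve_coeffs(H2, p1, 8)
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)
        lhs = shm.spherical_convolve_coeffs(H1, a * p1 + b * p2, 8)
        rhs = a * shm.spherical_convolve_coeffs(H1, p1, 8) \
            + b * shm.spherical_convolve_coeffs(H1, p2, 8)
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_lmax_mismatch(self):
        with pytest.raises(ValueError):
            shm.spherical_convolve_coeffs(np.ones((3, 4)), np.ones(45), 8)


class TestDirections:
    def test_counts_and_norms(self):
        for n in (1, 5, 300):
            d = shm.uniform_directions(n, seed=0)
            assert d.shape == (n, 3)
            np.testing.assert_allclose(np.linalg.norm(d, axis=1), 1.0, atol=1e-10)

    def test_shipped_constraint_set(self):
        d = shm.constraint_directions(300)
        assert d.shape == (300, 3)
        np.testing.assert_allclose(np.linalg.norm(d, axis=1), 1.0, atol=1e-10)
        assert shm.minimum_angle(d) > 5.0

    def test_repulsion_quality_128(self):
        # independent oracle: plain projected-gradient repulsion from a
        # random start, antipodal pairs included
        rng = np.random.default_rng(42)
        x = rng.normal(size=(128, 3))
        x /= np.linalg.norm(x, axis=1, keepdims=True)
        for _ in range(400):
            diff = x[:, None, :] - x[None, :, :]
            dsum = x[:, None, :] + x[None, :, :]
            d2 = np.einsum("ijk,ijk->ij", diff, diff)
            s2 = np.einsum("ijk,ijk->ij", dsum, dsum)
            np.fill_diagonal(d2, np.inf)
            s2[s2 < 1e-12] = np.inf
            f = (diff / d2[..., None] ** 1.5).sum(1) + (dsum / s2[..., None] ** 1.5).sum(1)
            x += 0.01 * f / np.abs(f).max()
            x /= np.linalg.norm(x, axis=1, keepdims=True)
        oracle_angle = shm.minimum_angle(x)
        ours = shm.minimum_angle(shm.uniform_directions(128, seed=0))
        assert ours >= 0.8 * oracle_angle


class TestApodisedDelta:
    def test_peak_normalisation_and_nonnegativity(self):
        p = shm.apodised_delta([0.0, 0.0, 1.0])
        assert p[0] == pytest.approx(1 / np.sqrt(4 * np.pi), abs=1e-12)
        grid = shm.constraint_directions(300)
        amps = shm.sh_basis_matrix(grid, 8) @ p
        pole = shm.sh_basis_matrix(np.array([[0.0, 0.0, 1.0]]), 8) @ p
        assert pole[0] >= amps.max()
        dense = shm.uniform_directions(10000, seed=11)
        assert (shm.sh_basis_matrix(dense, 8) @ p).min() >= -1e-6

    def test_unit_integral(self):
        # spherical integral equals sqrt(4 pi) times the l=0 coefficient
        p = shm.apodised_delta([1.0, 1.0, 0.0])
        assert np.sqrt(4 * np.pi) * p[0] == pytest.approx(1.0, abs=1e-12)

    def test_rotation_equivariance(self):
        R = rotation_matrix([1, 2, 0.5], 1.1)
        mu = np.array([0.3, -0.5, 0.81])
        mu /= np.linalg.norm(mu)
        p1 = shm.apodised_delta(mu)
        p2 = shm.apodised_delta(R @ mu)
        dirs = shm.uniform_directions(500, seed=12)
        a1 = shm.sh_basis_matrix(dirs @ R.T, 8) @ p2
        a2 = shm.sh_basis_matrix(dirs, 8) @ p1
        np.testing.assert_allclose(a1, a2, atol=1e-10)

    def test_zero_vector_raises(self):
        with pytest.raises(ValueError):
            shm.apodised_delta([0.0, 0.0, 0.0])


class TestACC:
    def test_identity_and_sign(self):
        p = shm.apodised_delta([0.0, 0.0, 1.0])
        assert shm.acc(p, p) == pytest.approx(1.0, abs=1e-14)
        assert shm.acc(p, -p) == pytest.approx(-1.0, abs=1e-14)

    def test_invariant_to_isotropic_term_and_scale(self):
        p = shm.apodised_delta([0.0, 1.0, 0.0])
        q = p.copy()
        q[0] += 7.0
        assert shm.acc(p, 3.2 * q) == pytest.approx(1.0, abs=1e-14)

    def test_undefined_for_isotropic(self):
        iso = np.zeros(45)
        iso[0] = 1.0
        p = shm.apodised_delta([0.0, 0.0, 1.0])
        with pytest.raises(ValueError, match="undefined"):
            shm.acc(iso, p)

    def test_rotation_invariance_by_refit(self):
        # acc(u, v) must equal acc(Ru, Rv): rotate both by sampling amplitudes
        # on rotated directions and refitting coefficients
        u = shm.apodised_delta([0.0, 0.0, 1.0])
        v = shm.apodised_delta([np.sin(0.6), 0.0, np.cos(0.6)])
        R = rotation_matrix([0.2, 1.0, -0.3], 0.77)
        dirs = shm.uniform_directions(300, seed=13)
        Y = shm.sh_basis_matrix(dirs, 8)
        Yr = shm.sh_basis_matrix(dirs @ R, 8)
        u_rot = shm.fit_shell_sh(Yr @ u, dirs, 8)
        v_rot = shm.fit_shell_sh(Yr @ v, dirs, 8)
        assert shm.acc(u_rot, v_rot) == pytest.approx(shm.acc(u, v), abs=1e-6)

    def test_orthogonal_deltas_value_by_rotation_oracle(self):
        # value for two deltas 90 degrees apart, computed independently by
        # refitting the rotated amplitude samples of the same delta
        u = shm.apodised_delta([0.0, 0.0, 1.0])
        R = rotation_matrix([0.0, 1.0, 0.0], np.pi / 2)
        dirs = shm.uniform_directions(300, seed=14)
        Yr = shm.sh_basis_matrix(dirs @ R.T, 8)
        v_oracle = shm.fit_shell_sh(Yr @ u, dirs, 8)
        v = shm.apodised_delta([1.0, 0.0, 0.0])
        assert shm.acc(u, v) == pytest.approx(shm.acc(u, v_oracle), abs=1e-8)
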