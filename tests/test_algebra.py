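"""Unit tests for the spherical tensor algebra core."""

import math

import numpy as np
import pytest

from sphtensor.algebra import (
    RotationElement,
    S_MATRIX,
    SphericalTensor,
    cart_to_spherical_vec,
    cartesian_rank2_decompose,
    cartesian_rank2_recompose,
    cg_table,
    clebsch_gordan,
    normalized_product,
    product,
    solid_harmonic,
    spherical_harmonic,
    spherical_vec_to_cart,
    wigner_d,
)
from sphtensor.tensorial import angular_quadrature


# ---------------------------------------------------------------------------
# Clebsch-Gordan coefficients
# ---------------------------------------------------------------------------

class TestClebschGordan:
    @pytest.mark.parametrize("args,expected", [
        ((0, 0, 0, 0, 0, 0), 1.0),
        ((2, 1, 2, 1, 0, 0), 1.0),          # coupling with the rank-0 identity
        ((3, -2, 3, -2, 0, 0), 1.0),
        ((0, 0, 1, 1, 1, -1), 1.0 / math.sqrt(3.0)),
    ])
    def test_exact_values(self, args, expected):
        assert clebsch_gordan(*args) == pytest.approx(expected, abs=1e-14)

    def test_selection_rules(self):
        assert clebsch_gordan(1, 1, 1, 1, 1, 1) == 0.0      # m != m1+m2
        assert clebsch_gordan(3, 0, 1, 0, 1, 0) == 0.0      # triangle violation

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            clebsch_gordan(-1, 0, 0, 0, 0, 0)
        with pytest.raises(ValueError):
            clebsch_gordan(1, 2, 1, 0, 1, 0)

    def test_against_symbolic_oracle(self):
        """Exact agreement with sympy's symbolic CG for all j1, j2 <= 4."""
        from sympy.physics.quantum.cg import CG as symCG
        worst = 0.0
        for j1 in range(5):
            for j2 in range(5):
                for j in range(abs(j1 - j2), j1 + j2 + 1):
                    for m1 in range(-j1, j1 + 1):
                        for m2 in range(-j2, j2 + 1):
                            m = m1 + m2
                            if abs(m) > j:
                                continue
                            ref = float(symCG(j1, m1, j2, m2, j, m).doit())
                            got = clebsch_gordan(j, m, j1, m1, j2, m2)
                            worst = max(worst, abs(ref - got))
        assert worst < 1e-13

    def test_orthogonality_sums(self):
        """sum_{m1,m2} <j m|..><j' m'|..> = delta_jj' delta_mm'."""
        j1, j2 = 2, 1
        for j in range(abs(j1 - j2), j1 + j2 + 1):
            for jp in range(abs(j1 - j2), j1 + j2 + 1):
                t1, t2 = cg_table(j, j1, j2), cg_table(jp, j1, j2)
                G = np.einsum("abc,dbc->ad", t1, t2)
                expected = np.eye(2 * j + 1) if j == jp else \
                    np.zeros((2 * j + 1, 2 * jp + 1))
                np.testing.assert_allclose(G, expected, atol=1e-13)


# ---------------------------------------------------------------------------
# products
# ---------------------------------------------------------------------------

class TestProducts:
    def test_scalar_coupling_is_multiplication(self):
        a = SphericalTensor(0, [2.0 + 0j])
        b = SphericalTensor(0, [-1.5 + 0j])
        assert product(a, b, 0).u[0] == pytest.approx(-3.0)

    def test_rank0_coupling_is_inner_product(self, random_tensor):
        v, w = random_tensor(2), random_tensor(2)
        ip = sum((-1.0) ** m * v[m] * w[-m] for m in range(-2, 3))
        assert normalized_product(v, w, 0).u[0] == pytest.approx(ip, abs=1e-12)

    @pytest.mark.parametrize("j1,j2,j", [
        (1, 1, 0), (1, 1, 1), (1, 1, 2), (2, 1, 1), (2, 1, 2),
        (2, 1, 3), (3, 2, 1), (3, 3, 4), (2, 2, 2),
    ])
    def test_rotation_covariance(self, rng, random_tensor, j1, j2, j):
        """Coupling commutes with simultaneous rotation of both factors."""
        v, w = random_tensor(j1), random_tensor(j2)
        g = RotationElement.random(rng)
        lhs = product(
            SphericalTensor(j1, wigner_d(g, j1) @ v.u),
            SphericalTensor(j2, wigner_d(g, j2) @ w.u), j,
        ).u
        rhs = wigner_d(g, j) @ product(v, w, j).u
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    @pytest.mark.parametrize("j1,j2,j", [(1, 1, 0), (1, 1, 1), (2, 1, 2), (2, 2, 1)])
    def test_parity_law(self, random_tensor, j1, j2, j):
        """Even j+j1+j2 stays real-type, odd lands in the imaginary space."""
        p = product(random_tensor(j1), random_tensor(j2), j)
        assert p.imag_type == ((j + j1 + j2) % 2 == 1)
        assert p.check_realness(1e-12)

    def test_triangle_violation_raises(self, random_tensor):
        with pytest.raises(ValueError):
            product(random_tensor(1), random_tensor(1), 3)

    def test_normalized_product_odd_parity_raises(self, random_tensor):
        with pytest.raises(ValueError):
            normalized_product(random_tensor(1), random_tensor(1), 1)

    def test_normalized_product_definition(self, random_tensor):
        v, w = random_tensor(2), random_tensor(1)
        n = clebsch_gordan(1, 0, 2, 0, 1, 0)
        np.testing.assert_allclose(
            normalized_product(v, w, 1).u * n, product(v, w, 1).u, atol=1e-12
        )

    @pytest.mark.parametrize("j1,j2,j3", [
        (1, 1, 1), (1, 2, 1), (2, 1, 2), (2, 2, 2), (0, 2, 1), (2, 2, 1),
    ])
    def test_associativity_stretched(self, random_tensor, j1, j2, j3):
        """v o_l (w o_{j2+j3} y) = (v o_{j1+j2} w) o_l y at l = j1+j2+j3."""
        v, w, y = random_tensor(j1), random_tensor(j2), random_tensor(j3)
        l = j1 + j2 + j3
        lhs = product(v, product(w, y, j2 + j3), l).u
        rhs = product(product(v, w, j1 + j2), y, l).u
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    @pytest.mark.parametrize("j1,j2,j3", [(1, 3, 1), (1, 2, 1), (1, 4, 2), (2, 4, 1)])
    def test_associativity_contracting(self, random_tensor, j1, j2, j3):
        """v o_l (w o_{j2-j3} y) = (v o_{j2-j1} w) o_l y at l = j2-(j1+j3)."""
        l = j2 - (j1 + j3)
        assert l >= 0
        v, w, y = random_tensor(j1), random_tensor(j2), random_tensor(j3)
        lhs = product(v, product(w, y, j2 - j3), l).u
        rhs = product(product(v, w, j2 - j1), y, l).u
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    @pytest.mark.parametrize("j1,j2,j3", [(1, 3, 1), (1, 4, 2)])
    def test_associativity_swapped(self, random_tensor, j1, j2, j3):
        """v^{j2} o_l (w^{j1} o_{j1+j3} y^{j3}) = (v o_{j2-j1} w) o_l y."""
        l = j2 - (j1 + j3)
        assert l >= 0
        v, w, y = random_tensor(j2), random_tensor(j1), random_tensor(j3)
        lhs = product(v, product(w, y, j1 + j3), l).u
        rhs = product(product(w, v, j2 - j1), y, l).u
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)


# ---------------------------------------------------------------------------
# rotations / Wigner matrices
# ---------------------------------------------------------------------------

class TestWignerD:
    def test_rank0_is_identity(self, rng):
        g = RotationElement.random(rng)
        np.testing.assert_allclose(wigner_d(g, 0), [[1.0]])

    def test_rank1_closed_form(self, rng):
        """D^1 = S U_g S^+ with the Cartesian-to-spherical map."""
        for _ in range(5):
            g = RotationElement.random(rng)
            ref = S_MATRIX @ g.matrix @ np.conj(S_MATRIX).T
            np.testing.assert_allclose(wigner_d(g, 1), ref, atol=1e-13)

    @pytest.mark.parametrize("j", range(5))
    def test_unitarity(self, rng, j):
        g = RotationElement.random(rng)
        D = wigner_d(g, j)
        np.testing.assert_allclose(
            np.conj(D).T @ D, np.eye(2 * j + 1), atol=1e-12
        )

    @pytest.mark.parametrize("j", range(4))
    def test_homomorphism(self, rng, j):
        g1, g2 = RotationElement.random(rng), RotationElement.random(rng)
        np.testing.assert_allclose(
            wigner_d(g2.compose(g1), j),
            wigner_d(g2, j) @ wigner_d(g1, j), atol=1e-12,
        )

    def test_matrix_roundtrip_and_inverse(self, rng):
        g = RotationElement.random(rng)
        np.testing.assert_allclose(
            RotationElement.from_matrix(g.matrix).matrix, g.matrix, atol=1e-12
        )
        np.testing.assert_allclose(
            g.compose(g.inverse()).matrix, np.eye(3), atol=1e-12
        )

    def test_align_z(self, rng):
        n = rng.standard_normal(3)
        n /= np.linalg.norm(n)
        g = RotationElement.align_z_to(n)
        np.testing.assert_allclose(g.matrix @ [0, 0, 1.0], n, atol=1e-12)

    def test_improper_matrix_rejected(self):
        with pytest.raises(ValueError):
            RotationElement.from_matrix(np.diag([1.0, 1.0, -1.0]))


# ---------------------------------------------------------------------------
# Cartesian <-> spherical
# ---------------------------------------------------------------------------

class TestCartesianConversion:
    @pytest.mark.parametrize("r,expected", [
        ((0, 0, 1), (0, 1, 0)),
        ((1, 0, 0), (1 / math.sqrt(2), 0, -1 / math.sqrt(2))),
    ])
    def test_printed_vectors(self, r, expected):
        u = cart_to_spherical_vec(np.array(r, dtype=float))
        np.testing.assert_allclose(u.u, np.array(expected, dtype=complex),
                                   atol=1e-15)

    def test_roundtrip(self, rng):
        for _ in range(100):
            r = rng.standard_normal(3)
            np.testing.assert_allclose(
                spherical_vec_to_cart(cart_to_spherical_vec(r)), r, atol=1e-14
            )

    def test_identity_is_pure_trace(self):
        b0, b1, b2 = cartesian_rank2_decompose(np.eye(3))
        assert np.max(np.abs(b1.u)) < 1e-14
        assert np.max(np.abs(b2.u)) < 1e-14
        assert abs(b0.u[0]) > 0

    def test_antisymmetric_is_pure_rank1(self, rng):
        A = rng.standard_normal((3, 3))
        A = A - A.T
        b0, b1, b2 = cartesian_rank2_decompose(A)
        assert np.max(np.abs(b0.u)) < 1e-13
        assert np.max(np.abs(b2.u)) < 1e-13
        assert b1.imag_type and b1.check_realness(1e-12)

    def test_decompose_recompose_roundtrip(self, rng):
        for _ in range(10):
            T = rng.standard_normal((3, 3))
            T2 = cartesian_rank2_recompose(*cartesian_rank2_decompose(T))
            np.testing.assert_allclose(T2, T, atol=1e-12)


# ---------------------------------------------------------------------------
# spherical and solid harmonics
# ---------------------------------------------------------------------------

class TestHarmonics:
    def test_rank0_is_one(self, rng):
        s = rng.standard_normal(3)
        s /= np.linalg.norm(s)
        assert spherical_harmonic(0, s).u[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("j", range(5))
    def test_racah_normalization_quadrature(self, j):
        """Sphere quadrature of |Y^j_m|^2 equals 4 pi / (2j+1) per m."""
        pts, wts = angular_quadrature(2 * j + 2)
        from sphtensor.algebra import spherical_harmonic_components
        Y = spherical_harmonic_components(j, pts[:, 0], pts[:, 1], pts[:, 2])
        norms = np.einsum("mp,mp,p->m", np.conj(Y), Y, wts)
        np.testing.assert_allclose(
            np.real(norms), 4 * np.pi / (2 * j + 1), rtol=1e-12
        )

    @pytest.mark.parametrize("j", range(1, 5))
    def test_steering(self, rng, j):
        """Y^j(U_g s) = D_g^j Y^j(s)."""
        s = rng.standard_normal(3)
        s /= np.linalg.norm(s)
        g = RotationElement.random(rng)
        np.testing.assert_allclose(
            spherical_harmonic(j, g.matrix @ s).u,
            wigner_d(g, j) @ spherical_harmonic(j, s).u, atol=1e-12,
        )

    @pytest.mark.parametrize("j1,j2,j", [(1, 1, 2), (1, 2, 3), (2, 2, 2), (3, 2, 3)])
    def test_harmonic_coupling(self, rng, j1, j2, j):
        """Y^{j1} •_j Y^{j2} = Y^j pointwise on the sphere."""
        s = rng.standard_normal(3)
        s /= np.linalg.norm(s)
        lhs = normalized_product(
            spherical_harmonic(j1, s), spherical_harmonic(j2, s), j
        ).u
        np.testing.assert_allclose(lhs, spherical_harmonic(j, s).u, atol=1e-12)

    def test_realness(self, rng):
        s = rng.standard_normal(3)
        s /= np.linalg.norm(s)
        for j in range(5):
            assert spherical_harmonic(j, s).check_realness(1e-12)

    def test_zero_vector_raises(self):
        with pytest.raises(ValueError):
            spherical_harmonic(2, np.zeros(3))
        with pytest.raises(ValueError):
            spherical_harmonic(2, np.array([0.5, 0.0, 0.0]))

    @pytest.mark.parametrize("j", [1, 2, 3])
    def test_solid_harmonic_homogeneity(self, rng, j):
        """R^j(lambda r) = lambda^j R^j(r)."""
        r = rng.standard_normal(3)
        lam = rng.uniform(0.5, 2.0)
        np.testing.assert_allclose(
            solid_harmonic(j, lam * r).u, lam ** j * solid_harmonic(j, r).u,
            atol=1e-12,
        )

    def test_solid_harmonic_rank1_is_S(self, rng):
        r = rng.standard_normal(3)
        np.testing.assert_allclose(
            solid_harmonic(1, r).u, S_MATRIX @ r, atol=1e-13
        )

    def test_solid_harmonic_at_origin(self):
        assert solid_harmonic(0, np.zeros(3)).u[0] == 1.0
        assert np.all(solid_harmonic(2, np.zeros(3)).u == 0.0)

    def test_solid_harmonics_are_harmonic(self):
        """Each component of R^3 solves the Laplace equation (checked by
        high-order finite differences at random points)."""
        rng = np.random.default_rng(3)
        h = 1e-2
        # 4th-order central second-derivative stencil
        w = np.array([-1.0, 16.0, -30.0, 16.0, -1.0]) / (12.0 * h * h)
        offs = np.array([-2, -1, 0, 1, 2]) * h
        for _ in range(5):
            p = rng.uniform(-1, 1, 3)
            lap = np.zeros(7, dtype=complex)
            for axis in range(3):
                for wi, oi in zip(w, offs):
                    q = p.copy()
                    q[axis] += oi
                    lap += wi * solid_harmonic(3, q).u
            assert np.max(np.abs(lap)) < 1e-6


class TestSphericalTensorType:
    def test_component_count_enforced(self):
        with pytest.raises(ValueError):
            SphericalTensor(1, np.zeros(4))

    def test_random_tensor_satisfies_constraint(self, rng):
        for j in range(4):
            assert SphericalTensor.random(j, rng).check_realness(1e-12)
            assert SphericalTensor.random(j, rng, imag_type=True).check_realness(1e-12)

    def test_m_indexing(self, random_tensor):
        v = random_tensor(2)
        assert v[2] == v.u[0]
        assert v[-2] == v.u[4]
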