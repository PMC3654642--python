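"""Spherical tensor algebra: irreducible SO(3) tensors and their couplings.

A spherical tensor of rank ``j`` is an element of the carrier space of the
(2j+1)-dimensional irreducible unitary representation of the 3D rotation
group.  Components are indexed by the magnetic quantum number
``m = j, j-1, ..., -j`` (stored in that descending order) and obey the
realness constraint ``conj(u_m) = (-1)^m u_{-m}`` for "real-type" tensors.
Two tensors of ranks ``j1, j2`` couple through Clebsch-Gordan coefficients
into a tensor of any rank ``j`` with ``|j1-j2| <= j <= j1+j2``; this single
product subsumes the Kronecker- and epsilon-contractions of Cartesian
tensor calculus.

Conventions
-----------
* Condon-Shortley phases throughout.
* Spherical harmonics carry Racah (semi-Schmidt) normalization:
  ``int |Y^j_m|^2 dS = 4*pi/(2j+1)`` and ``Y^0 = 1``.
* The rank-1 tensor attached to a Cartesian vector ``r = (x, y, z)`` is
  ``u = S r = ((x-iy)/sqrt2, z, -(x+iy)/sqrt2)`` in ``m = +1, 0, -1`` order;
  the same matrix ``S`` links the Wigner matrix at rank 1 to the Cartesian
  rotation matrix, ``D^1_g = S U_g S^T*``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.special import sph_harm_y
from scipy.spatial.transform import Rotation as _ScipyRotation

__all__ = [
    "SphericalTensor",
    "RotationElement",
    "CGTable",
    "clebsch_gordan",
    "cg_table",
    "product",
    "normalized_product",
    "wigner_d",
    "wigner_small_d",
    "cart_to_spherical_vec",
    "spherical_vec_to_cart",
    "cartesian_rank2_decompose",
    "cartesian_rank2_recompose",
    "spherical_harmonic",
    "spherical_harmonic_components",
    "solid_harmonic",
    "S_MATRIX",
]

# Unitary change of basis from Cartesian 3-vectors to rank-1 spherical
# tensors, rows ordered m = +1, 0, -1.
_SQ2 = math.sqrt(2.0)
S_MATRIX = np.array(
    [
        [1.0 / _SQ2, -1j / _SQ2, 0.0],
        [0.0, 0.0, 1.0],
        [-1.0 / _SQ2, -1j / _SQ2, 0.0],
    ],
    dtype=complex,
)


def _check_rank(j: int) -> int:
    if not isinstance(j, (int, np.integer)) or j < 0:
        raise ValueError(f"rank must be a non-negative integer, got {j!r}")
    return int(j)


# ---------------------------------------------------------------------------
# Clebsch-Gordan coefficients (Racah's closed form, exact integer arithmetic)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _cg_exact(j: int, m: int, j1: int, m1: int, j2: int, m2: int) -> float:
    """Racah's single-sum closed form, evaluated with exact integers."""
    if m1 + m2 != m:
        return 0.0
    if not (abs(j1 - j2) <= j <= j1 + j2):
        return 0.0
    f = math.factorial
    # triangle coefficient and m-dependent factorials; all integers
    pref_num = (
        (2 * j + 1)
        * f(j1 + j2 - j) * f(j1 - j2 + j) * f(-j1 + j2 + j)
        * f(j + m) * f(j - m)
        * f(j1 + m1) * f(j1 - m1) * f(j2 + m2) * f(j2 - m2)
    )
    pref_den = f(j1 + j2 + j + 1)
    total = 0
    # Fraction-free: accumulate the alternating sum as a rational over a
    # common denominator is overkill; the integers stay modest for j <= 12.
    kmin = max(0, -(j - j2 + m1), -(j - j1 - m2))
    kmax = min(j1 + j2 - j, j1 - m1, j2 + m2)
    acc = 0.0
    for k in range(kmin, kmax + 1):
        den = (
            f(k) * f(j1 + j2 - j - k) * f(j1 - m1 - k) * f(j2 + m2 - k)
            * f(j - j2 + m1 + k) * f(j - j1 - m2 + k)
        )
        acc += (-1.0) ** k / den
    return math.sqrt(pref_num / pref_den) * acc + total


def clebsch_gordan(j: int, m: int, j1: int, m1: int, j2: int, m2: int) -> float:
    """Clebsch-Gordan coefficient ``<j m | j1 m1, j2 m2>`` (Condon-Shortley).

    Returns 0 when ``m != m1 + m2`` or the triangle inequality
    ``|j1-j2| <= j <= j1+j2`` fails.  Raises for invalid ranks or
    out-of-range magnetic numbers.
    """
    for jj, mm in ((j, m), (j1, m1), (j2, m2)):
        _check_rank(jj)
        if abs(mm) > jj:
            raise ValueError(f"|m|={abs(mm)} exceeds rank j={jj}")
    return _cg_exact(int(j), int(m), int(j1), int(m1), int(j2), int(m2))


@lru_cache(maxsize=None)
def cg_table(j: int, j1: int, j2: int) -> np.ndarray:
    """Dense CG array of shape (2j+1, 2j1+1, 2j2+1), m-descending indices.

    Entry ``[j-m, j1-m1, j2-m2]`` holds ``<j m | j1 m1, j2 m2>``.
    """
    j, j1, j2 = _check_rank(j), _check_rank(j1), _check_rank(j2)
    out = np.zeros((2 * j + 1, 2 * j1 + 1, 2 * j2 + 1))
    if not (abs(j1 - j2) <= j <= j1 + j2):
        return out
    for m1 in range(-j1, j1 + 1):
        for m2 in range(-j2, j2 + 1):
            m = m1 + m2
            if abs(m) <= j:
                out[j - m, j1 - m1, j2 - m2] = _cg_exact(j, m, j1, m1, j2, m2)
    out.setflags(write=False)
    return out


class CGTable:
    """Mutable-free cache of dense Clebsch-Gordan arrays keyed by (j, j1, j2)."""

    def __getitem__(self, key: tuple[int, int, int]) -> np.ndarray:
        return cg_table(*key)

    def coefficient(self, j: int, m: int, j1: int, m1: int, j2: int, m2: int) -> float:
        return clebsch_gordan(j, m, j1, m1, j2, m2)


# ---------------------------------------------------------------------------
# SphericalTensor
# ---------------------------------------------------------------------------

@dataclass
class SphericalTensor:
    """A rank-``j`` spherical tensor: 2j+1 complex components, m descending.

    ``imag_type=False`` marks real-type tensors (``conj(u_m) = (-1)^m u_-m``),
    ``imag_type=True`` the imaginary counterpart space with
    ``conj(w_m) = (-1)^(m+1) w_-m``.  The flag records which constraint the
    components are expected to satisfy; ``check_realness`` verifies it.
    """

    j: int
    u: np.ndarray
    imag_type: bool = False

    def __post_init__(self) -> None:
        self.j = _check_rank(self.j)
        self.u = np.asarray(self.u, dtype=complex)
        if self.u.shape != (2 * self.j + 1,):
            raise ValueError(
                f"rank-{self.j} tensor needs {2 * self.j + 1} components, "
                f"got shape {self.u.shape}"
            )

    def __getitem__(self, m: int) -> complex:
        """Component ``u_m`` by magnetic quantum number."""
        if abs(m) > self.j:
            raise IndexError(f"|m|={abs(m)} exceeds rank {self.j}")
        return self.u[self.j - m]

    def realness_residual(self) -> float:
        sign = -1.0 if self.imag_type else 1.0
        ms = np.arange(self.j, -self.j - 1, -1)
        return float(np.max(np.abs(
            np.conj(self.u) - sign * (-1.0) ** ms * self.u[::-1]
        )))

    def check_realness(self, tol: float = 1e-10) -> bool:
        return self.realness_residual() <= tol

    @classmethod
    def random(cls, j: int, rng: np.random.Generator,
               imag_type: bool = False) -> "SphericalTensor":
        """Random tensor satisfying the realness (or imaginariness) constraint."""
        j = _check_rank(j)
        u = np.empty(2 * j + 1, dtype=complex)
        for m in range(0, j + 1):
            re, im = rng.standard_normal(2)
            if m == 0:
                # m=0: real for real-type, purely imaginary for imag-type
                u[j] = 1j * re if imag_type else re
            else:
                v = re + 1j * im
                u[j - m] = v
                sign = (-1.0) ** (m + 1) if imag_type else (-1.0) ** m
                u[j + m] = sign * np.conj(v)
        return cls(j, u, imag_type=imag_type)

    def __add__(self, other: "SphericalTensor") -> "SphericalTensor":
        if self.j != other.j or self.imag_type != other.imag_type:
            raise ValueError("can only add tensors of equal rank and type")
        return SphericalTensor(self.j, self.u + other.u, self.imag_type)

    def __mul__(self, scalar: float) -> "SphericalTensor":
        return SphericalTensor(self.j, self.u * scalar, self.imag_type)

    __rmul__ = __mul__


# ---------------------------------------------------------------------------
# Products
# ---------------------------------------------------------------------------

def _couple(j: int, v: np.ndarray, j1: int, w: np.ndarray, j2: int) -> np.ndarray:
    """CG contraction of raw component arrays (m-descending)."""
    table = cg_table(j, j1, j2)
    return np.einsum("abc,b,c->a", table, v, w)


def product(v: SphericalTensor, w: SphericalTensor, j: int) -> SphericalTensor:
    """Spherical product ``v o_j w`` coupling ranks (j1, j2) -> j.

    The parity law fixes the output type: ``j + j1 + j2`` even keeps
    real-type inputs real-type, odd sends them to the imaginary space.
    """
    j = _check_rank(j)
    if not (abs(v.j - w.j) <= j <= v.j + w.j):
        raise ValueError(
            f"triangle inequality violated: |{v.j}-{w.j}| <= {j} <= {v.j}+{w.j}"
        )
    out = _couple(j, v.u, v.j, w.u, w.j)
    odd = (j + v.j + w.j) % 2 == 1
    imag_type = (v.imag_type ^ w.imag_type) ^ odd
    return SphericalTensor(j, out, imag_type=imag_type)


def normalized_product(v: SphericalTensor, w: SphericalTensor, j: int) -> SphericalTensor:
    """Normalized symmetric product ``v •_j w = (v o_j w) / <j0|j1 0, j2 0>``.

    Only defined for even ``j + j1 + j2`` (otherwise the normalizer is zero).
    At ``j = 0`` and equal ranks this is the standard inner product
    ``sum_m (-1)^m v_m w_{-m}``.
    """
    norm = clebsch_gordan(j, 0, v.j, 0, w.j, 0)
    if norm == 0.0:
        raise ValueError(
            f"•-product undefined for odd parity (j, j1, j2)=({j}, {v.j}, {w.j})"
        )
    res = product(v, w, j)
    return SphericalTensor(res.j, res.u / norm, res.imag_type)


# ---------------------------------------------------------------------------
# Rotations and Wigner-D matrices
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _small_d_prefactors(j: int):
    f = math.factorial
    ms = range(-j, j + 1)
    pref = {}
    for mp in ms:
        for m in ms:
            pref[(mp, m)] = math.sqrt(
                f(j + mp) * f(j - mp) * f(j + m) * f(j - m)
            )
    return pref


def wigner_small_d(j: int, beta: float) -> np.ndarray:
    """Wigner small-d matrix ``d^j_{m'm}(beta)``, indices m-descending."""
    j = _check_rank(j)
    pref = _small_d_prefactors(j)
    c = math.cos(beta / 2.0)
    s = math.sin(beta / 2.0)
    f = math.factorial
    d = np.zeros((2 * j + 1, 2 * j + 1))
    for mp in range(-j, j + 1):
        for m in range(-j, j + 1):
            kmin = max(0, m - mp)
            kmax = min(j + m, j - mp)
            acc = 0.0
            for k in range(kmin, kmax + 1):
                den = f(j + m - k) * f(k) * f(mp - m + k) * f(j - mp - k)
                term = (-1.0) ** (mp - m + k) / den
                acc += term * c ** (2 * j + m - mp - 2 * k) * s ** (mp - m + 2 * k)
            d[j - mp, j - m] = pref[(mp, m)] * acc
    return d


@dataclass(frozen=True)
class RotationElement:
    """A 3D rotation with ZYZ Euler angles and its representations.

    ``matrix`` is the Cartesian rotation matrix
    ``U_g = R_z(alpha) R_y(beta) R_z(gamma)``; ``wigner_d(j)`` the unitary
    (2j+1)x(2j+1) matrix representing the same rotation on rank-j tensors.
    """

    alpha: float
    beta: float
    gamma: float

    @property
    def matrix(self) -> np.ndarray:
        return _ScipyRotation.from_euler(
            "ZYZ", [self.alpha, self.beta, self.gamma]
        ).as_matrix()

    @classmethod
    def from_matrix(cls, U: np.ndarray) -> "RotationElement":
        U = np.asarray(U, dtype=float)
        if U.shape != (3, 3) or not np.allclose(U.T @ U, np.eye(3), atol=1e-8) \
                or np.linalg.det(U) < 0:
            raise ValueError("not a proper rotation matrix")
        import warnings
        with warnings.catch_warnings():
            # gimbal lock only makes the ZYZ factorization non-unique; any
            # representative yields the same rotation and Wigner matrices
            warnings.simplefilter("ignore", UserWarning)
            a, b, g = _ScipyRotation.from_matrix(U).as_euler("ZYZ")
        return cls(a, b, g)

    @classmethod
    def random(cls, rng: np.random.Generator) -> "RotationElement":
        return cls.from_matrix(_ScipyRotation.random(rng=rng).as_matrix())

    @classmethod
    def align_z_to(cls, n: np.ndarray) -> "RotationElement":
        """Rotation mapping the +z axis onto the unit vector ``n``."""
        n = np.asarray(n, dtype=float)
        nn = np.linalg.norm(n)
        if nn == 0:
            raise ValueError("zero vector has no direction")
        n = n / nn
        beta = math.acos(np.clip(n[2], -1.0, 1.0))
        alpha = math.atan2(n[1], n[0]) if (abs(n[0]) + abs(n[1])) > 0 else 0.0
        return cls(alpha, beta, 0.0)

    def compose(self, other: "RotationElement") -> "RotationElement":
        """Return self o other (apply ``other`` first)."""
        return RotationElement.from_matrix(self.matrix @ other.matrix)

    def inverse(self) -> "RotationElement":
        return RotationElement.from_matrix(self.matrix.T)

    def wigner_d(self, j: int) -> np.ndarray:
        return wigner_d(self, j)


def wigner_d(g: RotationElement, j: int) -> np.ndarray:
    """Wigner-D matrix of ``g`` at rank ``j`` in this package's conventions.

    Satisfies ``D^1 = S U_g S^T*`` (with the Cartesian-to-spherical map S),
    the homomorphism property, unitarity, and the harmonic steering identity
    ``Y^j(U_g s) = D^j_g Y^j(s)``.
    """
    j = _check_rank(j)
    if j == 0:
        return np.ones((1, 1), dtype=complex)
    d = wigner_small_d(j, g.beta)
    ms = np.arange(j, -j - 1, -1.0)
    # Components here carry m with the opposite sign of the bookkeeping used
    # for the standard (ascending-m) Condon-Shortley harmonics; relative to
    # the textbook assembly this transposes the small-d factor.  Pinned by
    # D^1 = S U_g S^+ and the steering identity Y^j(U_g s) = D^j Y^j(s).
    left = np.exp(-1j * ms * g.alpha)
    right = np.exp(-1j * ms * g.gamma)
    return left[:, None] * d.T * right[None, :]


# ---------------------------------------------------------------------------
# Cartesian <-> spherical conversions
# ---------------------------------------------------------------------------

def cart_to_spherical_vec(r: np.ndarray) -> SphericalTensor:
    """Map a Cartesian 3-vector to its rank-1 spherical tensor ``u = S r``."""
    r = np.asarray(r, dtype=float)
    if r.shape != (3,):
        raise ValueError("expected a 3-vector")
    return SphericalTensor(1, S_MATRIX @ r)


def spherical_vec_to_cart(u: SphericalTensor) -> np.ndarray:
    """Inverse of :func:`cart_to_spherical_vec`; exact by unitarity of S."""
    if u.j != 1:
        raise ValueError("expected a rank-1 tensor")
    r = np.conj(S_MATRIX).T @ u.u
    return np.real(r)


def cartesian_rank2_decompose(T: np.ndarray):
    """Decompose a real 3x3 tensor into spherical tensors of ranks 0, 1, 2.

    Rank 0 carries the trace, rank 1 the antisymmetric part, rank 2 the
    traceless symmetric part.  Computed through the CG sums acting on
    ``T^s = S T S^T*``.
    """
    T = np.asarray(T, dtype=float)
    if T.shape != (3, 3):
        raise ValueError("expected a 3x3 matrix")
    Ts = S_MATRIX @ T @ np.conj(S_MATRIX).T
    out = []
    for j in (0, 1, 2):
        b = np.zeros(2 * j + 1, dtype=complex)
        for m in range(j, -j - 1, -1):
            acc = 0.0 + 0.0j
            for m1 in range(1, -2, -1):
                m2 = m - m1
                if abs(m2) > 1:
                    continue
                acc += (
                    clebsch_gordan(j, m, 1, m1, 1, m2)
                    * (-1.0) ** m2
                    * Ts[1 - m1, 1 + m2]
                )
            b[j - m] = acc
        out.append(SphericalTensor(j, b, imag_type=(j == 1)))
    return tuple(out)


def cartesian_rank2_recompose(b0: SphericalTensor, b1: SphericalTensor,
                              b2: SphericalTensor) -> np.ndarray:
    """Rebuild the real 3x3 Cartesian tensor from its spherical parts."""
    if (b0.j, b1.j, b2.j) != (0, 1, 2):
        raise ValueError("expected ranks (0, 1, 2)")
    parts = {0: b0, 1: b1, 2: b2}
    Ts = np.zeros((3, 3), dtype=complex)
    for m1 in range(1, -2, -1):
        for m2 in range(1, -2, -1):
            acc = 0.0 + 0.0j
            for j in (0, 1, 2):
                m = m1 - m2
                if abs(m) > j:
                    continue
                acc += (
                    clebsch_gordan(j, m, 1, m1, 1, -m2)
                    * (-1.0) ** m2
                    * parts[j].u[j - m]
                )
            Ts[1 - m1, 1 - m2] = acc
    T = np.conj(S_MATRIX).T @ Ts @ S_MATRIX
    return np.real(T)


# ---------------------------------------------------------------------------
# Spherical and solid harmonics
# ---------------------------------------------------------------------------

def spherical_harmonic_components(j: int, x, y, z) -> np.ndarray:
    """Racah-normalized harmonic components on (arrays of) unit vectors.

    Returns an array of shape ``(2j+1,) + broadcast_shape`` with the
    component for ``m = j`` first.  Inputs need not be exactly unit length;
    they are normalized internally (zero vectors raise).
    """
    j = _check_rank(j)
    x, y, z = np.broadcast_arrays(*(np.asarray(a, dtype=float) for a in (x, y, z)))
    r = np.sqrt(x * x + y * y + z * z)
    if np.any(r == 0):
        raise ValueError("spherical harmonics are undefined at the zero vector")
    theta = np.arccos(np.clip(z / r, -1.0, 1.0))
    phi = np.arctan2(y, x)
    # scipy's sph_harm_y returns the orthonormal CS-phase harmonics for
    # m = -j..j; this package's m-descending storage together with its sign
    # convention for m makes that ascending slice the component array.
    ynm = sph_harm_y(j, np.arange(-j, j + 1), theta[..., None], phi[..., None])
    comps = np.moveaxis(ynm, -1, 0) * math.sqrt(4.0 * math.pi / (2 * j + 1))
    return np.ascontiguousarray(comps)


def spherical_harmonic(j: int, s: np.ndarray, tol: float = 1e-9) -> SphericalTensor:
    """Racah-normalized spherical harmonic ``Y^j(s)`` at a unit vector."""
    s = np.asarray(s, dtype=float)
    n = np.linalg.norm(s)
    if n == 0:
        raise ValueError("zero vector has no direction")
    if abs(n - 1.0) > tol:
        raise ValueError(f"|s| = {n} is not 1 within {tol}")
    comps = spherical_harmonic_components(j, *s)
    return SphericalTensor(j, comps)


def solid_harmonic(j: int, r: np.ndarray) -> SphericalTensor:
    """Solid harmonic ``R^j(r) = |r|^j Y^j(r/|r|)``; ``R^j(0) = 0`` for j >= 1."""
    j = _check_rank(j)
    r = np.asarray(r, dtype=float)
    n = np.linalg.norm(r)
    if n == 0:
        u = np.zeros(2 * j + 1, dtype=complex)
        if j == 0:
            u[0] = 1.0
        return SphericalTensor(j, u)
    comps = spherical_harmonic_components(j, *r) * n ** j
    return SphericalTensor(j, comps)
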