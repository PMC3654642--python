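"""Spherical tensor fields on voxel grids.

A rank-``j`` tensor field assigns a rank-``j`` spherical tensor to every
voxel of a 3D grid.  The grid is cubic with isotropic physical spacing and
a distinguished origin voxel (default: the floor-midpoint index), so that
voxel ``idx`` sits at the physical point ``(idx - origin) * spacing``.
Rotations act by resampling at ``U_g^T r`` followed by mixing the
components with the Wigner matrix ``D_g^j``; two fields combine either
voxel-wise (CG coupling per voxel) or by covariant convolution (one scalar
FFT convolution per component pair, CG-weighted).

The boundary model is periodic (torus), which makes translation covariance
of the convolution exact and lets spatial- and Fourier-domain paths agree
to round-off.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _dc_field

import numpy as np
from numpy.fft import fftn, ifftn
from scipy import ndimage

from sphtensor.algebra import (
    RotationElement,
    cg_table,
    clebsch_gordan,
    spherical_harmonic_components,
    wigner_d,
    _check_rank,
)

__all__ = [
    "SphericalTensorField",
    "coordinate_grids",
    "radius_grid",
    "gaussian_field",
    "harmonic_field",
    "solid_harmonic_field",
    "delta_field",
    "rotate_field",
    "pointwise_product",
    "convolve_fields",
    "convolve_fields_direct",
    "reflect_field",
    "reflection_matrix",
    "field_norm",
    "relative_error",
]


def default_origin(shape) -> tuple[int, int, int]:
    return tuple(int(n // 2) for n in shape)


@dataclass
class SphericalTensorField:
    """Voxel grid of rank-``j`` spherical tensors.

    ``data`` has shape ``(2j+1, nx, ny, nz)`` with the component for
    ``m = +j`` first.  ``imag_type`` marks fields valued in the imaginary
    space ``iV_j``.
    """

    j: int
    data: np.ndarray
    spacing: float = 1.0
    origin: tuple[int, int, int] | None = None
    imag_type: bool = False

    def __post_init__(self) -> None:
        self.j = _check_rank(self.j)
        self.data = np.asarray(self.data, dtype=complex)
        if self.data.ndim != 4 or self.data.shape[0] != 2 * self.j + 1:
            raise ValueError(
                f"rank-{self.j} field needs data of shape (2j+1, nx, ny, nz); "
                f"got {self.data.shape}"
            )
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.origin is None:
            self.origin = default_origin(self.grid_shape)
        else:
            self.origin = tuple(int(o) for o in self.origin)

    # -- geometry ----------------------------------------------------------
    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    @property
    def is_centered(self) -> bool:
        return self.origin == default_origin(self.grid_shape)

    def same_grid(self, other: "SphericalTensorField") -> bool:
        return (
            self.grid_shape == other.grid_shape
            and self.spacing == other.spacing
            and self.origin == other.origin
        )

    def coords(self):
        return coordinate_grids(self.grid_shape, self.spacing, self.origin)

    # -- component access --------------------------------------------------
    def component(self, m: int) -> np.ndarray:
        if abs(m) > self.j:
            raise IndexError(f"|m|={abs(m)} exceeds rank {self.j}")
        return self.data[self.j - m]

    def realness_residual(self) -> float:
        sign = -1.0 if self.imag_type else 1.0
        ms = np.arange(self.j, -self.j - 1, -1)
        flipped = self.data[::-1]
        signs = sign * (-1.0) ** ms
        return float(np.max(np.abs(np.conj(self.data) - signs[:, None, None, None] * flipped)))

    # -- constructors ------------------------------------------------------
    @classmethod
    def zeros(cls, j: int, shape, spacing: float = 1.0, origin=None,
              imag_type: bool = False) -> "SphericalTensorField":
        data = np.zeros((2 * _check_rank(j) + 1, *shape), dtype=complex)
        return cls(j, data, spacing, origin, imag_type)

    @classmethod
    def from_scalar(cls, arr: np.ndarray, spacing: float = 1.0,
                    origin=None) -> "SphericalTensorField":
        arr = np.asarray(arr)
        if arr.ndim != 3:
            raise ValueError("expected a 3D scalar array")
        return cls(0, arr[None].astype(complex), spacing, origin)

    def scalar(self) -> np.ndarray:
        """Real scalar values of a rank-0 real-type field."""
        if self.j != 0:
            raise ValueError("not a rank-0 field")
        return np.real(self.data[0])

    def copy(self) -> "SphericalTensorField":
        return SphericalTensorField(
            self.j, self.data.copy(), self.spacing, self.origin, self.imag_type
        )

    def __add__(self, other: "SphericalTensorField") -> "SphericalTensorField":
        if not self.same_grid(other) or self.j != other.j:
            raise ValueError("fields must share rank and grid")
        return SphericalTensorField(
            self.j, self.data + other.data, self.spacing, self.origin,
            self.imag_type and other.imag_type,
        )

    def __mul__(self, scalar) -> "SphericalTensorField":
        return SphericalTensorField(
            self.j, self.data * scalar, self.spacing, self.origin, self.imag_type
        )

    __rmul__ = __mul__


# ---------------------------------------------------------------------------
# grid helpers
# ---------------------------------------------------------------------------

def coordinate_grids(shape, spacing: float = 1.0, origin=None):
    """Physical coordinate arrays (X, Y, Z) for a voxel grid."""
    if origin is None:
        origin = default_origin(shape)
    axes = [
        (np.arange(n, dtype=float) - o) * spacing for n, o in zip(shape, origin)
    ]
    return np.meshgrid(*axes, indexing="ij", sparse=False)


def radius_grid(shape, spacing: float = 1.0, origin=None) -> np.ndarray:
    X, Y, Z = coordinate_grids(shape, spacing, origin)
    return np.sqrt(X * X + Y * Y + Z * Z)


def gaussian_field(shape, sigma: float, spacing: float = 1.0,
                   origin=None) -> SphericalTensorField:
    """Centered isotropic Gaussian ``exp(-r^2 / (2 sigma^2))`` as a scalar field."""
    r = radius_grid(shape, spacing, origin)
    return SphericalTensorField.from_scalar(
        np.exp(-(r ** 2) / (2.0 * sigma ** 2)), spacing, origin
    )


def harmonic_field(j: int, shape, spacing: float = 1.0,
                   origin=None) -> SphericalTensorField:
    """Direction field ``r -> Y^j(r/|r|)``; the origin voxel is zero-filled
    for ``j >= 1`` (``Y^0 = 1`` everywhere)."""
    j = _check_rank(j)
    X, Y, Z = coordinate_grids(shape, spacing, origin)
    r = np.sqrt(X * X + Y * Y + Z * Z)
    mask = r == 0
    Zs = np.where(mask, 1.0, Z)  # dummy direction at the origin
    comps = spherical_harmonic_components(j, X, Y, Zs)
    if j >= 1:
        comps[:, mask] = 0.0
    return SphericalTensorField(j, comps.astype(complex), spacing, origin)


def solid_harmonic_field(j: int, shape, spacing: float = 1.0,
                         origin=None) -> SphericalTensorField:
    """Field ``r -> R^j(r) = |r|^j Y^j(r/|r|)`` (zero at the origin, j >= 1)."""
    f = harmonic_field(j, shape, spacing, origin)
    r = radius_grid(shape, spacing, origin)
    f.data *= r[None] ** j
    return f


def delta_field(shape, spacing: float = 1.0, origin=None,
                at=None) -> SphericalTensorField:
    """Discrete delta: a single voxel of value ``1/spacing^3`` (unit mass)."""
    f = SphericalTensorField.zeros(0, shape, spacing, origin)
    idx = tuple(f.origin) if at is None else tuple(at)
    f.data[(0, *idx)] = 1.0 / spacing ** 3
    return f


# ---------------------------------------------------------------------------
# rotation
# ---------------------------------------------------------------------------

def rotate_field(f: SphericalTensorField, g: RotationElement,
                 mode: str = "nearest", order: int = 1) -> SphericalTensorField:
    """Rotate a tensor field about the grid origin: ``D_g^j f(U_g^T r)``.

    Values are resampled with trilinear interpolation by default (``order``
    selects the spline degree); ``mode`` selects the out-of-grid extension
    (any scipy.ndimage boundary mode).
    """
    if not f.is_centered:
        raise ValueError("rotation is defined about the centered origin only")
    U = g.matrix
    o = np.asarray(f.origin, dtype=float)
    matrix = U.T
    offset = o - matrix @ o
    resampled = np.empty_like(f.data)
    for c in range(f.data.shape[0]):
        re = ndimage.affine_transform(
            np.real(f.data[c]), matrix, offset=offset, order=order, mode=mode
        )
        im = ndimage.affine_transform(
            np.imag(f.data[c]), matrix, offset=offset, order=order, mode=mode
        )
        resampled[c] = re + 1j * im
    D = wigner_d(g, f.j)
    out = np.einsum("mn,n...->m...", D, resampled)
    return SphericalTensorField(f.j, out, f.spacing, f.origin, f.imag_type)


def reflection_matrix(plane: str, j: int) -> np.ndarray:
    """Representation of a coordinate-plane reflection on rank-j tensors.

    A reflection factors as inversion times a half-turn about the plane
    normal; inversion acts on rank-j harmonics as ``(-1)^j`` (parity of
    ``Y^j``), so ``D(sigma) = (-1)^j D^j(R_normal(pi))``.  With this action
    the harmonic fixpoint property extends to O(3):
    ``Y^j(U_sigma s) = D(sigma) Y^j(s)``.
    """
    axis = {"yz": 0, "xz": 1, "xy": 2}[plane]
    U_sigma = np.eye(3)
    U_sigma[axis, axis] = -1.0
    g_rot = RotationElement.from_matrix(-U_sigma)
    return (-1.0) ** j * wigner_d(g_rot, j)


def reflect_field(f: SphericalTensorField, plane: str) -> SphericalTensorField:
    """Reflection through a coordinate plane, acting on grid and components.

    ``(sigma f)(r) = D(sigma) f(U_sigma^T r)`` with the O(3) component
    action of :func:`reflection_matrix`.  The spatial flip is exact on the
    index torus for any origin.
    """
    axis = {"yz": 0, "xz": 1, "xy": 2}[plane]
    n = f.grid_shape[axis]
    o = f.origin[axis]
    # index map i -> (2o - i) mod n, exact for any origin on the torus
    idx = (2 * o - np.arange(n)) % n
    data = np.take(f.data, idx, axis=1 + axis)
    M = reflection_matrix(plane, f.j)
    data = np.einsum("mn,n...->m...", M, data)
    return SphericalTensorField(f.j, data, f.spacing, f.origin, f.imag_type)


# ---------------------------------------------------------------------------
# products
# ---------------------------------------------------------------------------

def _output_type(j: int, v: SphericalTensorField, w: SphericalTensorField) -> bool:
    odd = (j + v.j + w.j) % 2 == 1
    return (v.imag_type ^ w.imag_type) ^ odd


def pointwise_product(v: SphericalTensorField, w: SphericalTensorField, j: int,
                      normalized: bool = False) -> SphericalTensorField:
    """Voxel-wise spherical product ``(v o_j w)(r) = v(r) o_j w(r)``."""
    j = _check_rank(j)
    if not (abs(v.j - w.j) <= j <= v.j + w.j):
        raise ValueError("triangle inequality violated")
    if not v.same_grid(w):
        raise ValueError("fields must share grid geometry")
    table = cg_table(j, v.j, w.j)
    out = np.einsum("abc,b...,c...->a...", table, v.data, w.data)
    if normalized:
        norm = clebsch_gordan(j, 0, v.j, 0, w.j, 0)
        if norm == 0.0:
            raise ValueError("•-product undefined for odd parity")
        out /= norm
    return SphericalTensorField(j, out, v.spacing, v.origin, _output_type(j, v, w))


def _scalar_correlation_fft(v0_hat_conjflip, w_hat):
    return v0_hat_conjflip * w_hat


def convolve_fields(v: SphericalTensorField, w: SphericalTensorField, j: int,
                    normalized: bool = False,
                    kernel_arg: str = "r-r'") -> SphericalTensorField:
    """Covariant convolution of two tensor fields on the torus.

    With the default ``kernel_arg="r-r'"`` this is the ordinary convolution
    ``(v o~_j w)(r) = int v(r-r') o_j w(r') dr'``, under which the
    derivative-commutation property ``(grad^l v) o~ w = v o~ (grad^l w)``
    holds sign-free and convolving with a discrete delta is the identity.
    ``kernel_arg="r'-r"`` selects the correlation-style pairing
    ``int v(r'-r) o_j w(r') dr'`` instead; the two differ by a spatial flip
    of ``v``, and commutation then carries a factor ``(-1)^l``.  Both are
    translation covariant.  The result lives on ``w``'s grid.
    """
    j = _check_rank(j)
    if not (abs(v.j - w.j) <= j <= v.j + w.j):
        raise ValueError("triangle inequality violated")
    if v.grid_shape != w.grid_shape or v.spacing != w.spacing:
        raise ValueError("fields must share grid shape and spacing")
    if kernel_arg not in ("r'-r", "r-r'"):
        raise ValueError(f"unknown kernel_arg {kernel_arg!r}")

    # Move v's origin voxel to index 0 so index offsets equal physical offsets.
    shifts = tuple(-o for o in v.origin)
    v0 = np.roll(v.data, shifts, axis=(1, 2, 3))
    w_hat = np.stack([fftn(w.data[c]) for c in range(w.data.shape[0])])
    if kernel_arg == "r'-r":
        # correlation: FFT(out) = FFT(w) * conj(FFT(conj(v0)))
        v_hat = np.stack(
            [np.conj(fftn(np.conj(v0[c]))) for c in range(v0.shape[0])]
        )
    else:
        v_hat = np.stack([fftn(v0[c]) for c in range(v0.shape[0])])

    table = cg_table(j, v.j, w.j)
    out_hat = np.einsum("abc,b...,c...->a...", table, v_hat, w_hat)
    out = np.stack([ifftn(out_hat[c]) for c in range(out_hat.shape[0])])
    out *= v.spacing ** 3
    if normalized:
        norm = clebsch_gordan(j, 0, v.j, 0, w.j, 0)
        if norm == 0.0:
            raise ValueError("•-product undefined for odd parity")
        out /= norm
    # roll so that the output is indexed on w's grid (origin alignment)
    return SphericalTensorField(j, out, w.spacing, w.origin, _output_type(j, v, w))


def convolve_fields_direct(v: SphericalTensorField, w: SphericalTensorField,
                           j: int, normalized: bool = False,
                           kernel_arg: str = "r-r'") -> SphericalTensorField:
    """O(N^2) reference implementation of :func:`convolve_fields`.

    Independent of the FFT path; intended for small grids in tests.
    """
    j = _check_rank(j)
    shape = w.grid_shape
    out = SphericalTensorField.zeros(j, shape, w.spacing, w.origin,
                                     _output_type(j, v, w))
    table = cg_table(j, v.j, w.j)
    vo = np.asarray(v.origin)
    nidx = np.indices(shape).reshape(3, -1).T  # all voxel indices
    for r_flat in range(nidx.shape[0]):
        r = nidx[r_flat]
        if kernel_arg == "r'-r":
            sample = nidx - r + vo  # v at (r' - r)
        else:
            sample = r - nidx + vo  # v at (r - r')
        sample %= np.asarray(shape)
        vvals = v.data[:, sample[:, 0], sample[:, 1], sample[:, 2]]
        wvals = w.data[:, nidx[:, 0], nidx[:, 1], nidx[:, 2]]
        acc = np.einsum("abc,bn,cn->a", table, vvals, wvals)
        out.data[:, r[0], r[1], r[2]] = acc * v.spacing ** 3
    if normalized:
        out.data /= clebsch_gordan(j, 0, v.j, 0, w.j, 0)
    return out


# ---------------------------------------------------------------------------
# norms
# ---------------------------------------------------------------------------

def field_norm(f: SphericalTensorField) -> float:
    """Physical L2 norm over all components and voxels."""
    return float(np.sqrt(np.sum(np.abs(f.data) ** 2) * f.spacing ** 3))


def relative_error(a: SphericalTensorField, b: SphericalTensorField,
                   mask: np.ndarray | None = None) -> float:
    """Relative L2 error ||a - b|| / ||b|| (optionally within a voxel mask)."""
    da, db = a.data, b.data
    if mask is not None:
        da = da[:, mask]
        db = db[:, mask]
    denom = np.sqrt(np.sum(np.abs(db) ** 2))
    if denom == 0:
        return float(np.sqrt(np.sum(np.abs(da) ** 2)))
    return float(np.sqrt(np.sum(np.abs(da - db) ** 2)) / denom)
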