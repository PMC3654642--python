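"""Spherical derivative operators on tensor fields.

The spherical up-derivative raises field rank (T_l -> T_{l+1}) and the
down-derivative lowers it (T_l -> T_{l-1}); both are the normalized
coupling of the spherical gradient ``R^1(nabla)`` with the field and are
rotation covariant.  In the Fourier domain they act by pointwise
•-multiplication with ``i R^1(k)``.  Multiple derivatives of scalar fields
factor as ``nabla_i^n = nabla^{n-i} Delta^i``, which is the cheap route to
Gauss-Laguerre expansions.

Two discretizations are provided: central finite differences (order 2 or
4) and the exact spectral (FFT) derivative on the torus.  The Laplacian
comes in two flavours: the composition of the down- and up-stencils
(numerically stable under repeated application) and the naive 6-point
stencil kept for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.fft import fftn, ifftn, fftfreq

from sphtensor.algebra import S_MATRIX, cg_table, clebsch_gordan, _check_rank
from sphtensor.fields import SphericalTensorField

__all__ = [
    "DerivativeScheme",
    "up_derivative",
    "down_derivative",
    "fourier_derivative",
    "multi_derivative",
    "laplacian",
]


@dataclass(frozen=True)
class DerivativeScheme:
    """Discretization choices for the spherical derivatives.

    mode: "spatial" (central differences) or "fourier" (spectral, exact on
    band-limited torus fields).  fd_order: accuracy order of the central
    differences (2 or 4).  laplace_mode: "composed" chains the down- and
    up-derivative stencils; "naive6" is the classic 6-neighbour stencil.
    """

    mode: str = "spatial"
    fd_order: int = 4
    laplace_mode: str = "composed"

    def __post_init__(self) -> None:
        if self.mode not in ("spatial", "fourier"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.fd_order not in (2, 4):
            raise ValueError("fd_order must be 2 or 4")
        if self.laplace_mode not in ("composed", "naive6"):
            raise ValueError(f"unknown laplace_mode {self.laplace_mode!r}")


DEFAULT_SCHEME = DerivativeScheme()


def _axis_diff(arr: np.ndarray, axis: int, h: float, order: int) -> np.ndarray:
    """Periodic central difference along one axis."""
    if order == 2:
        return (np.roll(arr, -1, axis) - np.roll(arr, 1, axis)) / (2.0 * h)
    # 5-point 4th-order stencil (-1, 8, 0, -8, 1)/(12 h)
    return (
        -np.roll(arr, -2, axis)
        + 8.0 * np.roll(arr, -1, axis)
        - 8.0 * np.roll(arr, 1, axis)
        + np.roll(arr, 2, axis)
    ) / (12.0 * h)


def _gradient_spherical_spatial(arr: np.ndarray, h: float, order: int) -> np.ndarray:
    """Spherical components (m=+1,0,-1) of the gradient of one scalar array."""
    dx = _axis_diff(arr, 0, h, order)
    dy = _axis_diff(arr, 1, h, order)
    dz = _axis_diff(arr, 2, h, order)
    return np.einsum("mc,c...->m...", S_MATRIX, np.stack([dx, dy, dz]))


def _k_spherical(shape, spacing: float) -> np.ndarray:
    """Spherical components of the wave vector ``S k`` on the FFT grid."""
    ks = [2.0 * np.pi * fftfreq(n, d=spacing) for n in shape]
    KX, KY, KZ = np.meshgrid(*ks, indexing="ij")
    return np.einsum("mc,c...->m...", S_MATRIX, np.stack([KX, KY, KZ]))


def _couple_gradient(grad: np.ndarray, fdata: np.ndarray, l: int,
                     j_out: int) -> np.ndarray:
    """••-couple rank-1 gradient components with rank-l components -> rank j_out."""
    table = cg_table(j_out, 1, l)
    norm = clebsch_gordan(j_out, 0, 1, 0, l, 0)
    return np.einsum("abc,b...,c...->a...", table, grad, fdata) / norm


def _derivative(f: SphericalTensorField, direction: str,
                scheme: DerivativeScheme) -> SphericalTensorField:
    l = f.j
    if direction == "up":
        j_out = l + 1
    elif direction == "down":
        if l == 0:
            raise ValueError("down-derivative undefined for rank-0 fields")
        j_out = l - 1
    else:
        raise ValueError(f"unknown direction {direction!r}")

    if scheme.mode == "spatial":
        grads = np.stack([
            _gradient_spherical_spatial(f.data[c], f.spacing, scheme.fd_order)
            for c in range(2 * l + 1)
        ], axis=1)  # shape (3, 2l+1, nx, ny, nz)
        table = cg_table(j_out, 1, l)
        norm = clebsch_gordan(j_out, 0, 1, 0, l, 0)
        out = np.einsum("abc,bc...->a...", table, grads) / norm
    else:
        K = _k_spherical(f.grid_shape, f.spacing)
        fhat = np.stack([fftn(f.data[c]) for c in range(2 * l + 1)])
        out_hat = 1j * _couple_gradient(K, fhat, l, j_out)
        out = np.stack([ifftn(out_hat[c]) for c in range(j_out * 2 + 1)])
    # parity: derivative coupling (1, l) -> l±1 always has odd 1+l+j_out? No:
    # 1 + l + (l±1) is even, so the output stays in the input's type space.
    return SphericalTensorField(j_out, out, f.spacing, f.origin, f.imag_type)


def up_derivative(f: SphericalTensorField,
                  scheme: DerivativeScheme = DEFAULT_SCHEME) -> SphericalTensorField:
    """Spherical up-derivative ``R^1(nabla) •_{l+1} f``: rank l -> l+1."""
    return _derivative(f, "up", scheme)


def down_derivative(f: SphericalTensorField,
                    scheme: DerivativeScheme = DEFAULT_SCHEME) -> SphericalTensorField:
    """Spherical down-derivative ``R^1(nabla) •_{l-1} f``: rank l -> l-1."""
    return _derivative(f, "down", scheme)


def fourier_derivative(f: SphericalTensorField, direction: str = "up") -> SphericalTensorField:
    """Spectral spherical derivative: pointwise ``i R^1(k) •`` in k-space."""
    return _derivative(f, direction, DerivativeScheme(mode="fourier"))


def laplacian(f: SphericalTensorField,
              scheme: DerivativeScheme = DEFAULT_SCHEME) -> SphericalTensorField:
    """Laplace operator, applied component-wise.

    "composed" mode chains the scalar down- and up-derivative stencils
    (down o up on each component treated as a scalar field), which stays
    stable under repeated application; "naive6" is the standard 6-point
    stencil.  In "fourier" mode the exact symbol ``-|k|^2`` is used.
    """
    if scheme.mode == "fourier":
        ks = [2.0 * np.pi * fftfreq(n, d=f.spacing) for n in f.grid_shape]
        KX, KY, KZ = np.meshgrid(*ks, indexing="ij")
        k2 = KX ** 2 + KY ** 2 + KZ ** 2
        out = np.stack([
            ifftn(-k2 * fftn(f.data[c])) for c in range(f.data.shape[0])
        ])
        return SphericalTensorField(f.j, out, f.spacing, f.origin, f.imag_type)

    if scheme.laplace_mode == "naive6":
        h2 = f.spacing ** 2
        out = np.empty_like(f.data)
        for c in range(f.data.shape[0]):
            a = f.data[c]
            out[c] = (
                np.roll(a, 1, 0) + np.roll(a, -1, 0)
                + np.roll(a, 1, 1) + np.roll(a, -1, 1)
                + np.roll(a, 1, 2) + np.roll(a, -1, 2)
                - 6.0 * a
            ) / h2
        return SphericalTensorField(f.j, out, f.spacing, f.origin, f.imag_type)

    # composed: scalar down(up(.)) per component
    out = np.empty_like(f.data)
    for c in range(f.data.shape[0]):
        comp = SphericalTensorField(0, f.data[c][None], f.spacing, f.origin)
        res = down_derivative(up_derivative(comp, scheme), scheme)
        out[c] = res.data[0]
    return SphericalTensorField(f.j, out, f.spacing, f.origin, f.imag_type)


def multi_derivative(f: SphericalTensorField, n: int, i: int,
                     scheme: DerivativeScheme = DEFAULT_SCHEME) -> SphericalTensorField:
    """Multiple spherical derivative ``nabla_i^n = nabla^{n-i} Delta^i`` of a
    scalar field: rank 0 -> rank n-i.

    Only defined for scalar inputs; the factorization through the Laplacian
    does not generalize to tensor-valued fields.
    """
    if f.j != 0:
        raise ValueError("multiple spherical derivatives require a scalar field")
    if not (0 <= i <= n):
        raise ValueError(f"need n >= i >= 0, got n={n}, i={i}")
    out = f
    for _ in range(i):
        out = laplacian(out, scheme)
    for _ in range(n - i):
        out = up_derivative(out, scheme)
    return out
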