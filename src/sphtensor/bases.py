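"""Analytic kernel families with spherical-derivative ladders.

Two families of rotation-covariant kernels are provided, each computable
both in closed form and by iterated spherical derivatives of a single
isotropic seed:

* Gauss-Laguerre kernels ``L_n^j(r) exp(-r^2/2)`` with
  ``L_n^j(r) = R^{j-n}(r) L_n^{(j-n)+1/2}(r^2/2)`` (associated Laguerre
  polynomials).  The ladder identity
  ``L_n^j e^{-r^2/2} = ((-1)^j / (2^n n!)) nabla^{j-n} Delta^n e^{-r^2/2}``
  turns the projection of an image onto the whole family into ONE Gaussian
  convolution followed by cheap derivative chains.
* Gaussian-windowed spherical Bessel kernels
  ``B_s^j(r,k) = (-1)^j nabla^j [ j_0(kr) e^{-r^2/(2s)} ]`` with a closed
  form as a binomial sum over spherical Bessel functions ``j_i(kr)``.
  Superpositions of these kernels approximate Gaussian-windowed plane
  waves (Gabor functions) steerable to every orientation at once.

All ladder computations run on a sigma-scaled grid so the unit-width
identities apply verbatim; the scale enters only through the coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import eval_genlaguerre, spherical_jn

from sphtensor.algebra import spherical_harmonic, _check_rank
from sphtensor.fields import (
    SphericalTensorField,
    convolve_fields,
    coordinate_grids,
    gaussian_field,
    harmonic_field,
    radius_grid,
    solid_harmonic_field,
)
from sphtensor.derivatives import (
    DerivativeScheme,
    laplacian,
    multi_derivative,
    up_derivative,
)

__all__ = [
    "LaguerreKernelSpec",
    "BesselKernelSpec",
    "laguerre_kernel",
    "laguerre_ladder_kernel",
    "laguerre_expand",
    "bessel_kernel",
    "unwindowed_bessel_field",
    "gabor_alpha",
    "gabor_kernel",
    "gabor_exact",
]

_FOURIER = DerivativeScheme(mode="fourier")


@dataclass(frozen=True)
class LaguerreKernelSpec:
    """Gauss-Laguerre kernel indices: radial order ``n``, total order ``j``
    (the kernel has tensor rank ``j - n``), Gaussian width ``sigma`` in
    physical units."""

    n: int
    j: int
    sigma: float = 1.0

    def __post_init__(self) -> None:
        _check_rank(self.n), _check_rank(self.j)
        if self.j < self.n:
            raise ValueError(f"need j >= n, got j={self.j}, n={self.n}")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    @property
    def rank(self) -> int:
        return self.j - self.n


@dataclass(frozen=True)
class BesselKernelSpec:
    """Windowed Bessel kernel: rank ``j``, radial frequency ``k`` (radians
    per physical unit), Gaussian window variance ``s``."""

    j: int
    k: float
    s: float

    def __post_init__(self) -> None:
        _check_rank(self.j)
        if self.k <= 0 or self.s <= 0:
            raise ValueError("need k > 0 and s > 0")


def _ladder_prefactor(j: int, n: int) -> float:
    return (-1.0) ** j / (2.0 ** n * math.factorial(n))


# ---------------------------------------------------------------------------
# Gauss-Laguerre
# ---------------------------------------------------------------------------

def laguerre_kernel(spec: LaguerreKernelSpec, shape,
                    spacing: float = 1.0) -> SphericalTensorField:
    """Closed-form Gauss-Laguerre kernel ``L_n^j(r/sigma) e^{-r^2/2sigma^2}``.

    Returned on a centered grid with the given physical spacing; rank j-n.
    """
    scale = spacing / spec.sigma  # grid coordinates in sigma units
    r = radius_grid(shape, scale)
    Rf = solid_harmonic_field(spec.rank, shape, scale)
    lag = eval_genlaguerre(spec.n, spec.rank + 0.5, r ** 2 / 2.0)
    data = Rf.data * (lag * np.exp(-(r ** 2) / 2.0))[None]
    return SphericalTensorField(spec.rank, data, spacing)


def laguerre_ladder_kernel(spec: LaguerreKernelSpec, shape, spacing: float = 1.0,
                           scheme: DerivativeScheme = _FOURIER) -> SphericalTensorField:
    """Same kernel built by the derivative ladder from a sampled Gaussian."""
    scale = spacing / spec.sigma
    g = gaussian_field(shape, 1.0, spacing=scale)
    out = multi_derivative(g, spec.j, spec.n, scheme)
    out = SphericalTensorField(
        out.j, _ladder_prefactor(spec.j, spec.n) * out.data, spacing
    )
    return out


def laguerre_expand(image: SphericalTensorField, jmax: int, sigma: float,
                    scheme: DerivativeScheme = _FOURIER
                    ) -> dict[tuple[int, int], SphericalTensorField]:
    """Project a scalar image onto all Gauss-Laguerre kernels with j+n <= jmax.

    One Gaussian convolution (FFT) followed by iterated Laplacians and
    up-derivatives yields every coefficient field
    ``a_n^j = (L_n^j(./sigma) e^{-r^2/2sigma^2}) * image``
    (componentwise scalar convolutions, sigma-scaled units).  Returns a dict
    keyed by ``(j, n)``; each value is a rank ``j-n`` field.
    """
    if image.j != 0:
        raise ValueError("expansion defined for scalar images")
    jmax = _check_rank(jmax)
    scale = image.spacing / sigma
    work = SphericalTensorField(0, image.data, spacing=scale, origin=image.origin)
    g = gaussian_field(image.grid_shape, 1.0, spacing=scale, origin=image.origin)
    base = convolve_fields(g, work, 0)

    coeffs: dict[tuple[int, int], SphericalTensorField] = {}
    lap = base
    for n in range(0, jmax // 2 + 1):
        if n > 0:
            lap = laplacian(lap, scheme)
        chain = lap
        j = n
        while j + n <= jmax:
            coeffs[(j, n)] = SphericalTensorField(
                chain.j, _ladder_prefactor(j, n) * chain.data,
                image.spacing, image.origin,
            )
            chain = up_derivative(chain, scheme)
            j += 1
    return coeffs


# ---------------------------------------------------------------------------
# Gaussian-windowed Bessel kernels
# ---------------------------------------------------------------------------

def bessel_kernel(spec: BesselKernelSpec, shape, spacing: float = 1.0,
                  method: str = "closed",
                  scheme: DerivativeScheme = _FOURIER) -> SphericalTensorField:
    """Gaussian-windowed spherical Bessel kernel ``B_s^j(r, k)`` of rank j.

    ``method="closed"`` evaluates the binomial closed form
    ``Y^j(r) [sum_i C(j,i) (r/s)^{j-i} k^i j_i(kr)] e^{-r^2/2s}``;
    ``method="ladder"`` applies ``(-1)^j nabla^j`` to the sampled order-0
    kernel ``j_0(kr) e^{-r^2/2s}``.
    """
    j, k, s = spec.j, spec.k, spec.s
    if method == "ladder":
        r = radius_grid(shape, spacing)
        b0 = SphericalTensorField.from_scalar(
            spherical_jn(0, k * r) * np.exp(-(r ** 2) / (2.0 * s)), spacing
        )
        out = b0
        for _ in range(j):
            out = up_derivative(out, scheme)
        return SphericalTensorField(j, (-1.0) ** j * out.data, spacing)
    if method != "closed":
        raise ValueError(f"unknown method {method!r}")
    r = radius_grid(shape, spacing)
    radial = np.zeros_like(r)
    for i in range(j + 1):
        radial += (
            math.comb(j, i) * (r / s) ** (j - i) * k ** i * spherical_jn(i, k * r)
        )
    Yf = harmonic_field(j, shape, spacing)
    data = Yf.data * (radial * np.exp(-(r ** 2) / (2.0 * s)))[None]
    return SphericalTensorField(j, data, spacing)


def unwindowed_bessel_field(j: int, k: float, shape,
                            spacing: float = 1.0) -> SphericalTensorField:
    """``B^j(r, k) = Y^j(r) j_j(kr)``, the plane-wave radial basis."""
    r = radius_grid(shape, spacing)
    Yf = harmonic_field(j, shape, spacing)
    return SphericalTensorField(j, Yf.data * spherical_jn(j, k * r)[None], spacing)


# ---------------------------------------------------------------------------
# Gabor superposition
# ---------------------------------------------------------------------------

def gabor_exact(k_vec, s: float, shape, spacing: float = 1.0) -> np.ndarray:
    """The Gaussian-windowed plane wave ``e^{i k.r} e^{-r^2/2s}`` on the grid."""
    k_vec = np.asarray(k_vec, dtype=float)
    X, Y, Z = coordinate_grids(shape, spacing)
    phase = k_vec[0] * X + k_vec[1] * Y + k_vec[2] * Z
    r2 = X * X + Y * Y + Z * Z
    return np.exp(1j * phase) * np.exp(-r2 / (2.0 * s))


@lru_cache(maxsize=32)
def _gabor_alpha_cached(k: float, s: float, N: int, shape: tuple,
                        spacing: float) -> tuple:
    """Least-squares weights alpha_j(k) of the Bessel superposition.

    The magnitudes depend only on (k, s, N, grid): the fit is done with the
    wave vector along +z and reused for every direction by steering.
    """
    k_vec = np.array([0.0, 0.0, k])
    target = gabor_exact(k_vec, s, shape, spacing).ravel()
    cols = []
    zhat = np.array([0.0, 0.0, 1.0])
    for j in range(N + 1):
        Bj = bessel_kernel(BesselKernelSpec(j, k, s), shape, spacing)
        Yk = spherical_harmonic(j, zhat).u
        # scalar field B_s^j(r) •_0 Y^j(k_hat): inner-product contraction
        ms = np.arange(j, -j - 1, -1)
        proj = np.einsum("m,m...->...", (-1.0) ** ms * Yk[::-1], Bj.data)
        cols.append(((1j) ** j * proj).ravel())
    A = np.stack(cols, axis=1)
    # real weights: stack real and imaginary parts
    Ar = np.concatenate([np.real(A), np.imag(A)], axis=0)
    tr = np.concatenate([np.real(target), np.imag(target)])
    alpha, *_ = np.linalg.lstsq(Ar, tr, rcond=None)
    return tuple(float(a) for a in alpha)


def gabor_alpha(k: float, s: float, N: int, shape, spacing: float = 1.0) -> np.ndarray:
    return np.asarray(_gabor_alpha_cached(float(k), float(s), int(N),
                                          tuple(shape), float(spacing)))


def gabor_kernel(k_vec, s: float, N: int, shape,
                 spacing: float = 1.0) -> SphericalTensorField:
    """Band-limited Bessel superposition approximating the Gabor function.

    ``sum_{j<=N} i^j alpha_j(k) B_s^j(r,k) •_0 Y^j(k_hat)`` as a complex
    scalar field; ``k_vec = 0`` degenerates to the Gaussian window.
    """
    k_vec = np.asarray(k_vec, dtype=float)
    k = float(np.linalg.norm(k_vec))
    if k == 0:
        r = radius_grid(shape, spacing)
        return SphericalTensorField(
            0, np.exp(-(r ** 2) / (2.0 * s))[None].astype(complex), spacing
        )
    if N < 0:
        raise ValueError("band limit N must be >= 0")
    alpha = gabor_alpha(k, s, N, shape, spacing)
    khat = k_vec / k
    acc = np.zeros(shape, dtype=complex)
    for j in range(N + 1):
        Bj = bessel_kernel(BesselKernelSpec(j, k, s), shape, spacing)
        Yk = spherical_harmonic(j, khat).u
        ms = np.arange(j, -j - 1, -1)
        proj = np.einsum("m,m...->...", (-1.0) ** ms * Yk[::-1], Bj.data)
        acc += (1j) ** j * alpha[j] * proj
    return SphericalTensorField(0, acc[None], spacing)
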