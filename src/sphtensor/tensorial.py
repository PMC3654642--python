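"""Tensorial harmonic expansions of tensor-valued 3D images.

A rank-``l`` tensor field restricted to a sphere can be expanded in the
tensorial harmonics ``Z_km^j(s) = e_m^{j+k} o_l Y^j(s)`` — the natural
generalization of the scalar spherical-harmonic basis (to which it reduces
at ``l = 0``).  The index ``j`` is the angular frequency, ``k`` runs over
``-l..l`` (with ``j+k >= 0``), and ``m`` over ``-(j+k)..j+k``.  Rotating
the field multiplies the coefficient tensors ``a_k^j(r)`` from the left by
``D^{j+k}``, exactly as in the scalar case, which is what makes the
expansion useful for invariant features and steerable voting fields.

The angular basis is orthogonal; its Gram diagonal is computed here by
spherical quadrature from first principles rather than transcribed.
Radial structure is kept free: coefficients are sampled on concentric
shells (default: integer radii up to the inscribed sphere).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from numpy.polynomial.legendre import leggauss

from sphtensor.algebra import (
    RotationElement,
    cg_table,
    spherical_harmonic_components,
    _check_rank,
)
from sphtensor.fields import (
    SphericalTensorField,
    harmonic_field,
    radius_grid,
    rotate_field,
    reflect_field,
)

__all__ = [
    "TensorialHarmonicExpansion",
    "z_basis",
    "angular_quadrature",
    "z_basis_matrix",
    "expand_field",
    "reconstruct",
    "symmetrize",
]


def _valid_indices(l: int, J: int):
    """(j, k) pairs of the rank-l expansion up to band limit J."""
    for j in range(J + 1):
        for k in range(-l, l + 1):
            # the coupling (j+k) x j -> l must satisfy the triangle rule;
            # |k| <= l always holds, the lower bound excludes small j
            if j + k >= 0 and l <= 2 * j + k:
                yield j, k


def z_basis(j: int, k: int, m: int, l: int, s: np.ndarray):
    """Tensorial harmonic ``Z_km^j(s) = e_m^{j+k} o_l Y^j(s)`` as a rank-l
    component vector (complex ndarray of length 2l+1, m-descending)."""
    l = _check_rank(l)
    if j + k < 0 or abs(k) > l or abs(m) > j + k:
        raise ValueError(f"invalid tensorial-harmonic index (j={j}, k={k}, m={m})")
    Y = spherical_harmonic_components(j, *np.asarray(s, dtype=float))
    table = cg_table(l, j + k, j)  # [l-M, (j+k)-m1, j-m2]
    return table[:, (j + k) - m, :] @ Y


def angular_quadrature(order: int):
    """Product quadrature on S^2: Gauss-Legendre in cos(theta) x uniform
    azimuth.  Returns unit vectors (N, 3) and weights summing to 4*pi."""
    x, w = leggauss(order)
    phis = 2.0 * np.pi * np.arange(2 * order) / (2 * order)
    theta = np.arccos(x)
    st = np.sin(theta)
    pts = np.stack([
        np.outer(st, np.cos(phis)),
        np.outer(st, np.sin(phis)),
        np.outer(np.cos(theta), np.ones_like(phis)),
    ], axis=-1).reshape(-1, 3)
    wts = np.outer(w, np.full_like(phis, np.pi / order)).ravel()
    return pts, wts


def z_basis_matrix(l: int, J: int, pts: np.ndarray):
    """All tensorial harmonics evaluated at unit vectors ``pts``.

    Returns (index list of (j, k, m), complex array of shape
    (n_basis, 2l+1, n_pts)).
    """
    Ys = {j: spherical_harmonic_components(j, pts[:, 0], pts[:, 1], pts[:, 2])
          for j in range(J + 1)}
    idx = []
    mats = []
    for j, k in _valid_indices(l, J):
        table = cg_table(l, j + k, j)
        # Z for all m at once: [M, m, pts]
        block = np.einsum("abc,cp->abp", table, Ys[j])
        for m in range(j + k, -(j + k) - 1, -1):
            idx.append((j, k, m))
            mats.append(block[:, (j + k) - m, :])
    return idx, np.stack(mats)


@dataclass
class TensorialHarmonicExpansion:
    """Shell-sampled tensorial-harmonic coefficients of a rank-l field.

    ``coeffs[(j, k)]`` is a complex array of shape ``(2(j+k)+1, n_shells)``
    holding ``a_km^j(r_s)`` with m descending; ``radii`` the shell radii in
    physical units; ``gram[(j, k, m)]`` the quadrature Gram diagonal used
    in the projection.
    """

    l: int
    J: int
    radii: np.ndarray
    coeffs: dict
    gram: dict
    spacing: float = 1.0

    def coefficient(self, j: int, k: int, m: int) -> np.ndarray:
        return self.coeffs[(j, k)][(j + k) - m]

    def rotate(self, g: RotationElement) -> "TensorialHarmonicExpansion":
        """Coefficients of the rotated field: left-multiply by D^{j+k}."""
        from sphtensor.algebra import wigner_d
        new = {
            (j, k): wigner_d(g, j + k) @ a for (j, k), a in self.coeffs.items()
        }
        return TensorialHarmonicExpansion(
            self.l, self.J, self.radii, new, self.gram, self.spacing
        )


def _sample_on_shell(f: SphericalTensorField, radius_vox: float,
                     pts: np.ndarray) -> np.ndarray:
    """Cubic-spline samples of all components at ``radius * pts`` (voxel units)."""
    o = np.asarray(f.origin, dtype=float)
    coords = (radius_vox * pts + o).T  # (3, n_pts)
    out = np.empty((f.data.shape[0], pts.shape[0]), dtype=complex)
    for c in range(f.data.shape[0]):
        re = ndimage.map_coordinates(np.real(f.data[c]), coords, order=3)
        im = ndimage.map_coordinates(np.imag(f.data[c]), coords, order=3)
        out[c] = re + 1j * im
    return out


def expand_field(f: SphericalTensorField, J: int, radii=None,
                 quad_order: int | None = None) -> TensorialHarmonicExpansion:
    """Project a rank-l field onto tensorial harmonics, shell by shell.

    ``radii`` defaults to integer voxel radii up to the inscribed sphere.
    The per-shell projection divides by the numerically computed Gram
    diagonal, so it is exact for band-limited fields at sufficient
    quadrature order (default ``2J + 2``).
    """
    if not f.is_centered:
        raise ValueError("expansion requires the centered origin")
    J = _check_rank(J)
    if radii is None:
        rmax = min(f.grid_shape) // 2 - 1
        radii = np.arange(1.0, rmax + 1.0)
    radii = np.asarray(radii, dtype=float)
    order = quad_order if quad_order is not None else 2 * J + 2
    pts, wts = angular_quadrature(order)
    idx, Z = z_basis_matrix(f.j, J, pts)
    gram = {
        key: float(np.real(np.einsum("ap,ap,p->", np.conj(Z[i]), Z[i], wts)))
        for i, key in enumerate(idx)
    }
    coeffs = {
        (j, k): np.zeros((2 * (j + k) + 1, len(radii)), dtype=complex)
        for j, k in _valid_indices(f.j, J)
    }
    for si, r in enumerate(radii):
        vals = _sample_on_shell(f, r / f.spacing, pts)  # radius in voxels
        proj = np.einsum("nap,ap,p->n", np.conj(Z), vals, wts)
        for i, (j, k, m) in enumerate(idx):
            coeffs[(j, k)][(j + k) - m, si] = proj[i] / gram[(j, k, m)]
    return TensorialHarmonicExpansion(f.j, J, radii * f.spacing, coeffs, gram,
                                      f.spacing)


def reconstruct(exp: TensorialHarmonicExpansion, shape,
                spacing: float | None = None) -> SphericalTensorField:
    """Synthesize the field ``sum a_k^j(r) o_l Y^j(r_hat)`` on a voxel grid.

    Coefficients are linearly interpolated in radius; voxels outside the
    sampled radial range decay to zero.
    """
    spacing = exp.spacing if spacing is None else spacing
    l = exp.l
    out = SphericalTensorField.zeros(l, shape, spacing)
    r = radius_grid(shape, spacing)
    Ys = {j: harmonic_field(j, shape, spacing).data for j in range(exp.J + 1)}
    for (j, k), a in exp.coeffs.items():
        # radial interpolation of every m-component onto the voxel radii
        avox = np.stack([
            np.interp(r.ravel(), exp.radii, np.real(a[c]), left=0.0, right=0.0)
            + 1j * np.interp(r.ravel(), exp.radii, np.imag(a[c]), left=0.0, right=0.0)
            for c in range(a.shape[0])
        ]).reshape(a.shape[0], *shape)
        table = cg_table(l, j + k, j)
        out.data += np.einsum("abc,b...,c...->a...", table, avox, Ys[j])
    return out


def symmetrize(f: SphericalTensorField, symmetry: str,
               n_axial: int = 16) -> SphericalTensorField:
    """Project a field onto a symmetry class.

    ``axial``: average over ``n_axial`` rotations about z (exact for band
    limits below ``n_axial``); expansion terms with ``m != 0`` vanish.
    ``torsion_free``: axial average followed by the yz-reflection average;
    terms with ``k + l`` odd vanish.
    ``xy_reflection``: average with the xy-reflected field; for even-rank
    fields the odd-j terms vanish.
    """
    if symmetry == "axial":
        acc = f.data.copy()
        for i in range(1, n_axial):
            phi = 2.0 * np.pi * i / n_axial
            acc = acc + rotate_field(f, RotationElement(phi, 0.0, 0.0),
                                     order=3).data
        return SphericalTensorField(f.j, acc / n_axial, f.spacing, f.origin,
                                    f.imag_type)
    if symmetry == "torsion_free":
        fs = symmetrize(f, "axial", n_axial)
        refl = reflect_field(fs, "yz")
        return SphericalTensorField(f.j, 0.5 * (fs.data + refl.data),
                                    f.spacing, f.origin, f.imag_type)
    if symmetry == "xy_reflection":
        refl = reflect_field(f, "xy")
        return SphericalTensorField(f.j, 0.5 * (f.data + refl.data),
                                    f.spacing, f.origin, f.imag_type)
    raise ValueError(f"unknown symmetry {symmetry!r}")
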