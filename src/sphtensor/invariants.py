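"""Rotation-invariant descriptors, tensor voting, and trainable filters.

Three consumers of the spherical algebra live here:

* **Invariant descriptors.**  Second-order power-spectrum features
  ``c^j(k1,k2) = a^j(k1) •_0 a^j(k2)`` and third-order triple products
  ``(b^{j1} o_{j3} b^{j2}) o_0 b^{j3}`` with odd ``j1+j2+j3``.  Both are
  rotation invariant; only the odd-parity triple products change under
  reflections, so they can tell an object from its mirror image.
* **Tensor voting.**  Oriented evidence ``E^j(r) = m(r) Y^j(n(r))`` is
  convolved against the tensorial-harmonic decomposition of an
  axial-symmetric voting field, accumulating steered votes for every voxel
  in one pass of covariant convolutions — no orientation sampling.
* **Trainable Bessel voting filter.**  A covariant detector whose voting
  function is a band-limited expansion in Gaussian-windowed spherical
  Bessel kernels.  Local covariant descriptor fields are built from the
  image, combined linearly into vote-coefficient fields ``V^j(k_i)``, and
  collected with derivative chains plus ONE scalar convolution per
  frequency; the combination weights are fit by ridge least squares
  against a landmark target map.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _dc_field

import numpy as np
from scipy import ndimage

from sphtensor.algebra import (
    RotationElement,
    cg_table,
    clebsch_gordan,
    spherical_harmonic_components,
    _check_rank,
)
from sphtensor.fields import (
    SphericalTensorField,
    convolve_fields,
    harmonic_field,
    pointwise_product,
    radius_grid,
    rotate_field,
)
from sphtensor.derivatives import DerivativeScheme, down_derivative
from sphtensor.bases import BesselKernelSpec, bessel_kernel
from sphtensor.tensorial import expand_field, symmetrize

__all__ = [
    "power_spectrum_features",
    "triple_product_features",
    "VotingFieldSpec",
    "stick_voting_field",
    "project_voting_field",
    "tensor_voting",
    "tensor_voting_direct",
    "FilterModel",
    "train_filter",
    "apply_filter",
    "detect_peaks",
]

_FOURIER = DerivativeScheme(mode="fourier")


# ---------------------------------------------------------------------------
# invariant descriptors
# ---------------------------------------------------------------------------

def _inner0(a: np.ndarray, b: np.ndarray, j: int) -> np.ndarray:
    """Standard inner product ``a •_0 b = sum_m (-1)^m a_m b_{-m}``."""
    ms = np.arange(j, -j - 1, -1)
    return np.einsum("m...,m...->...", a, ((-1.0) ** ms)[
        (slice(None),) + (None,) * (b.ndim - 1)] * b[::-1])


def power_spectrum_features(a: dict) -> dict:
    """Second-order rotation invariants of expansion coefficients.

    ``a`` maps ``(j, k)`` (rank, frequency label) to component arrays of
    shape ``(2j+1, ...)``.  Returns ``{(j, k1, k2): c^j(k1, k2)}`` for all
    frequency pairs sharing a rank; the diagonal ``c^j(k, k)`` is the power
    spectrum ``||a^j(k)||^2``.
    """
    by_rank: dict[int, list] = {}
    for (j, k), arr in a.items():
        arr = np.asarray(arr, dtype=complex)
        if arr.shape[0] != 2 * j + 1:
            raise ValueError(f"coefficient for rank {j} has {arr.shape[0]} components")
        by_rank.setdefault(j, []).append((k, arr))
    out = {}
    for j, items in by_rank.items():
        for i1, (k1, a1) in enumerate(items):
            for (k2, a2) in items[i1:]:
                out[(j, k1, k2)] = _inner0(a1, a2, j)
    return out


def triple_product_features(b: dict, L: int) -> dict:
    """Third-order invariants ``(b^{j1} o_{j3} b^{j2}) o_0 b^{j3}``.

    ``b`` maps ``(j, label)`` — rank plus a frequency/radial label, as for
    the power spectrum — to component arrays ``(2j+1, ...)``.  Enumerates
    all entry triples with ``j1 + j2 + j3`` odd (the reflection-sensitive
    parity), the triangle rule, and every rank bounded by ``L``.  Returns
    ``{((j1, l1), (j2, l2), (j3, l3)): value}``; values are purely
    imaginary for real-type inputs (the odd coupling lands in the
    imaginary space) and flip sign under reflections, unlike the power
    spectrum.  The form is antisymmetric in its first two slots, so the
    triple of one entry with itself vanishes identically; such pairs are
    skipped, which is why informative triples need at least two coefficient
    sets per rank (e.g. two radial frequencies).
    """
    entries = sorted(b.keys(), key=str)
    out = {}
    for i1, e1 in enumerate(entries):
        j1 = e1[0]
        for e2 in entries[i1 + 1:]:  # e1 == e2 vanishes by antisymmetry
            j2 = e2[0]
            for e3 in entries:
                j3 = e3[0]
                if max(j1, j2, j3) > L or (j1 + j2 + j3) % 2 == 0:
                    continue
                if not (abs(j1 - j2) <= j3 <= j1 + j2):
                    continue
                t = cg_table(j3, j1, j2)
                mid = np.einsum("abc,b...,c...->a...", t,
                                np.asarray(b[e1], dtype=complex),
                                np.asarray(b[e2], dtype=complex))
                out[(e1, e2, e3)] = _inner0(
                    mid, np.asarray(b[e3], dtype=complex), j3
                )
    return out


# ---------------------------------------------------------------------------
# tensor voting
# ---------------------------------------------------------------------------

@dataclass
class VotingFieldSpec:
    """An axial-symmetric voting field of rank ``l`` tabulated on a grid.

    ``field`` holds the field steered along +z; ``band_limit`` the angular
    band used when projecting onto tensorial harmonics.
    """

    field: SphericalTensorField
    band_limit: int = 4

    def __post_init__(self) -> None:
        if not self.field.is_centered:
            raise ValueError("voting field must live on a centered grid")

    @property
    def rank(self) -> int:
        return self.field.j


def stick_voting_field(shape, sigma_r: float = 4.0, rank: int = 2,
                       spacing: float = 1.0) -> SphericalTensorField:
    """A Gaussian "stick" voting field: rank-2, axial and torsion-free.

    ``V(r) = exp(-r^2 / 2 sigma_r^2) Y^rank(z_hat)``-steered along the
    local direction; tabulated here along +z it is simply the outer
    Gaussian times the constant tensor ``Y^rank(z) = e_0``.
    """
    r = radius_grid(shape, spacing)
    prof = np.exp(-(r ** 2) / (2.0 * sigma_r ** 2))
    data = np.zeros((2 * rank + 1, *shape), dtype=complex)
    data[rank] = prof  # m = 0 component: Y^rank(z_hat) = e_0
    return SphericalTensorField(rank, data, spacing)


def project_voting_field(V: SphericalTensorField, J: int, radii=None,
                         symmetrize_first: bool = False) -> dict:
    """Tensorial-harmonic radial profiles ``a_k^j(r)`` of an axial field.

    Only ``m = 0`` coefficients survive axial symmetry; if the input is
    found non-axial it is symmetrized first (with a warning) when
    ``symmetrize_first`` is allowed, otherwise an error is raised.
    Returns ``{(j, k): (radii, profile)}``.
    """
    exp = expand_field(V, J, radii=radii)
    # residual mass in m != 0 relative to total
    tot, off = 0.0, 0.0
    for (j, k), a in exp.coeffs.items():
        p = np.abs(a) ** 2
        tot += float(p.sum())
        off += float(p.sum() - p[(j + k)].sum())
    if tot > 0 and off / tot > 1e-3:
        if not symmetrize_first:
            import warnings
            warnings.warn(
                "voting field is not axially symmetric; symmetrizing first"
            )
        Vs = symmetrize(V, "axial")
        exp = expand_field(Vs, J, radii=radii)
    return {
        (j, k): (exp.radii, a[(j + k)].copy())
        for (j, k), a in exp.coeffs.items()
    }


def _orientation_harmonic(m_img: np.ndarray, n_vec: np.ndarray, j: int) -> np.ndarray:
    """Evidence components ``m(r) Y^j(n(r))`` (zero where m == 0)."""
    mask = m_img > 0
    comps = np.zeros((2 * j + 1, *m_img.shape), dtype=complex)
    if not np.any(mask):
        return comps
    vals = spherical_harmonic_components(
        j, n_vec[0][mask], n_vec[1][mask], n_vec[2][mask]
    )
    comps[:, mask] = vals * m_img[mask]
    return comps


def tensor_voting(m_img: SphericalTensorField, n_vec: np.ndarray,
                  spec: VotingFieldSpec, J: int | None = None,
                  out_rank: int | None = None) -> SphericalTensorField:
    """Accumulate steered votes: ``U(r) = int V^{n(r')}(r - r') m(r') dr'``.

    ``m_img`` is the scalar evidence image, ``n_vec`` an array (3, nx, ny,
    nz) of unit orientation vectors defined wherever ``m > 0``.  The axial
    voting field of ``spec`` is decomposed once into tensorial harmonics;
    votes are then collected by one covariant convolution per (j, k) term.
    """
    if m_img.j != 0:
        raise ValueError("evidence image must be scalar")
    l = spec.rank
    if out_rank is not None and out_rank != l:
        raise ValueError(
            f"requested output rank {out_rank} != voting field rank {l}"
        )
    J = spec.band_limit if J is None else J
    profiles = project_voting_field(spec.field, J)
    shape = m_img.grid_shape
    m_arr = np.real(m_img.data[0])
    r = radius_grid(shape, m_img.spacing)
    out = SphericalTensorField.zeros(l, shape, m_img.spacing, m_img.origin)
    Yvox = {}
    for (j, k), (radii, prof) in profiles.items():
        if np.max(np.abs(prof)) == 0:
            continue
        # A_k^j(x) = a_k0^j(|x|) Y^j(x_hat), rank-j kernel field
        if j not in Yvox:
            Yvox[j] = harmonic_field(j, shape, m_img.spacing).data
        avox = (
            np.interp(r.ravel(), radii, np.real(prof), left=np.real(prof[0]), right=0.0)
            + 1j * np.interp(r.ravel(), radii, np.imag(prof), left=np.imag(prof[0]), right=0.0)
        ).reshape(shape)
        A = SphericalTensorField(j, Yvox[j] * avox[None], m_img.spacing,
                                 m_img.origin)
        E = SphericalTensorField(
            j + k, _orientation_harmonic(m_arr, n_vec, j + k),
            m_img.spacing, m_img.origin,
        )
        # kernel A sits in the second product slot: swap the CG coupling
        sign = (-1.0) ** ((j + k) + j - l)
        out.data += sign * convolve_fields(A, E, l).data
    return out


def tensor_voting_direct(m_img: SphericalTensorField, n_vec: np.ndarray,
                         spec: VotingFieldSpec) -> SphericalTensorField:
    """Brute-force reference: explicitly steer and add the voting field at
    every evidence voxel.  O(evidence voxels x grid); for small tests."""
    l = spec.rank
    shape = m_img.grid_shape
    m_arr = np.real(m_img.data[0])
    out = SphericalTensorField.zeros(l, shape, m_img.spacing, m_img.origin)
    idxs = np.argwhere(m_arr > 0)
    o = np.asarray(spec.field.origin)
    for idx in idxs:
        n = np.array([n_vec[0][tuple(idx)], n_vec[1][tuple(idx)],
                      n_vec[2][tuple(idx)]])
        g = RotationElement.align_z_to(n)
        Vn = rotate_field(spec.field, g, order=3)
        shift = idx - o
        out.data += m_arr[tuple(idx)] * np.roll(
            Vn.data, tuple(shift), axis=(1, 2, 3)
        ) * m_img.spacing ** 3
    return out


# ---------------------------------------------------------------------------
# trainable Bessel voting filter
# ---------------------------------------------------------------------------

def _bessel_coefficient_fields(image: SphericalTensorField, N: int,
                               k_list, s: float) -> dict:
    """Local covariant expansion coefficients ``a^j(k) = B_s^j * f``."""
    out = {}
    for k in k_list:
        for j in range(N + 1):
            ker = bessel_kernel(BesselKernelSpec(j, k, s), image.grid_shape,
                                image.spacing)
            out[(j, k)] = convolve_fields(ker, image, j)
    return out


def _descriptor_fields(image: SphericalTensorField, N: int, k_list,
                       s: float) -> list:
    """Dictionary of covariant rank-j descriptor fields.

    First-order entries are the Bessel coefficient fields themselves;
    second-order entries are their even-parity CG squares, which carry the
    orientation information a linear term cannot.  Returns a list of
    (label, rank, SphericalTensorField).
    """
    base = _bessel_coefficient_fields(image, N, k_list, s)
    feats = []
    for (j, k), f in sorted(base.items()):
        feats.append((f"a{j}(k{k})", j, f))
    keys = sorted(base.keys())
    for i1, (j1, k1) in enumerate(keys):
        for (j2, k2) in keys[i1:]:
            for j in range(abs(j1 - j2), min(j1 + j2, N) + 1):
                if (j1 + j2 + j) % 2 == 1:
                    continue  # keep real-type products only
                prod = pointwise_product(base[(j1, k1)], base[(j2, k2)], j)
                feats.append((f"a{j1}(k{k1})*a{j2}(k{k2})->{j}", j, prod))
    return feats


@dataclass
class FilterModel:
    """Trained covariant voting filter.

    ``weights[(label, rank, k)]`` are the real combination weights of the
    descriptor dictionary entries into the vote coefficients ``V^j(k)``;
    the saliency is ``sum_k B_s^0(k) * sum_j grad_j V^j(k)``.
    """

    N: int
    k_list: tuple
    s: float
    lam: float
    weights: dict
    feature_scale: dict

    def feature_keys(self):
        return list(self.weights.keys())

    def to_json(self) -> dict:
        return {
            "N": self.N,
            "k_list": list(self.k_list),
            "s": self.s,
            "lam": self.lam,
            "entries": [
                [label, rank, k, self.weights[(label, rank, k)],
                 self.feature_scale[(label, rank, k)]]
                for (label, rank, k) in self.weights
            ],
        }

    @classmethod
    def from_json(cls, obj: dict) -> "FilterModel":
        weights = {}
        scales = {}
        for label, rank, k, w, sc in obj["entries"]:
            weights[(label, int(rank), float(k))] = float(w)
            scales[(label, int(rank), float(k))] = float(sc)
        return cls(N=int(obj["N"]), k_list=tuple(obj["k_list"]),
                   s=float(obj["s"]), lam=float(obj["lam"]),
                   weights=weights, feature_scale=scales)


def _response_maps(image: SphericalTensorField, N: int, k_list,
                   s: float) -> dict:
    """Per-feature scalar response maps ``B_s^0(k) * grad_j d^j``.

    The rank-j descriptor is brought down to rank 0 by j down-derivatives
    and then convolved with the isotropic window kernel — the fast form of
    the voting collection.  Keys are (label, rank, k_outer).
    """
    feats = _descriptor_fields(image, N, k_list, s)
    down = {}
    for label, rank, f in feats:
        cur = f
        for _ in range(rank):
            cur = down_derivative(cur, _FOURIER)
        down[(label, rank)] = cur
    out = {}
    for k in k_list:
        b0 = bessel_kernel(BesselKernelSpec(0, k, s), image.grid_shape,
                           image.spacing)
        for (label, rank), f0 in down.items():
            resp = convolve_fields(b0, f0, 0)
            out[(label, rank, k)] = np.real(resp.data[0])
    return out


def _target_map(shape, landmarks, sigma_t: float = 2.0) -> np.ndarray:
    t = np.zeros(shape)
    if len(landmarks) == 0:
        return t
    idx = np.indices(shape)
    for p in landmarks:
        d2 = sum((idx[a] - p[a]) ** 2 for a in range(3))
        t += np.exp(-d2 / (2.0 * sigma_t ** 2))
    return t


def train_filter(images, landmark_sets, N: int = 2, k_list=(0.4, 0.8),
                 s: float = 16.0, lam: float = 1e-3,
                 sigma_t: float = 2.0) -> FilterModel:
    """Fit the voting filter by ridge regression against landmark maps.

    ``images`` are scalar fields, ``landmark_sets`` matching lists of voxel
    index triples.  The target is a unit-height Gaussian bump (width
    ``sigma_t``) at every landmark.  Raises if no landmarks are given.
    """
    if not images:
        raise ValueError("need at least one training image")
    if all(len(lm) == 0 for lm in landmark_sets):
        raise ValueError("need at least one landmark")
    rows_X, rows_t = [], []
    keys = None
    scales = None
    for img, lms in zip(images, landmark_sets):
        maps = _response_maps(img, N, k_list, s)
        if keys is None:
            keys = list(maps.keys())
            scales = {
                key: max(float(np.std(maps[key])), 1e-12) for key in keys
            }
        X = np.stack([maps[key].ravel() / scales[key] for key in keys], axis=1)
        rows_X.append(X)
        rows_t.append(_target_map(img.grid_shape, lms, sigma_t).ravel())
    X = np.concatenate(rows_X, axis=0)
    t = np.concatenate(rows_t)
    P = X.shape[1]
    A = X.T @ X + lam * np.eye(P)
    w = np.linalg.solve(A, X.T @ t)
    weights = {key: float(wi) for key, wi in zip(keys, w)}
    return FilterModel(N=N, k_list=tuple(k_list), s=s, lam=lam,
                       weights=weights, feature_scale=scales)


def apply_filter(model: FilterModel, image: SphericalTensorField) -> SphericalTensorField:
    """Saliency map of a trained filter on a new image."""
    maps = _response_maps(image, model.N, model.k_list, model.s)
    sal = np.zeros(image.grid_shape)
    for key, w in model.weights.items():
        sal += w * maps[key] / model.feature_scale[key]
    return SphericalTensorField.from_scalar(sal, image.spacing, image.origin)


def detect_peaks(saliency: SphericalTensorField, n_peaks: int,
                 min_distance: int = 4) -> np.ndarray:
    """Indices of the strongest local maxima (deterministic tie-break by
    lexicographic voxel index)."""
    arr = np.real(saliency.data[0])
    fp = np.ones((2 * min_distance + 1,) * 3, dtype=bool)
    local_max = arr == ndimage.maximum_filter(arr, footprint=fp, mode="wrap")
    cand = np.argwhere(local_max)
    vals = arr[local_max]
    # sort by value descending, then lexicographic index for determinism
    order = np.lexsort((cand[:, 2], cand[:, 1], cand[:, 0], -vals))
    return cand[order[:n_peaks]]
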