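# Methods

This note records the mathematical conventions, numerical choices and
known limitations of `sphtensor`, at the level of detail a maintainer or
a careful user needs. Everything quantitative stated here is computed by
the test suite or by `scripts/acceptance.py`; nothing is quoted from
elsewhere.

## Spherical tensors and conventions

A rank-*j* spherical tensor is an element of the (2j+1)-dimensional
carrier space of the irreducible unitary SO(3) representation of order
*j*. Components are stored with *m* descending from +j to −j and obey
the realness constraint `conj(u_m) = (−1)^m u_{−m}` ("real type"); the
complementary "imaginary type" obeys the same relation with an extra
sign. The package keeps the full complex component vector and asserts
the constraint rather than packing 2j+1 real numbers — clarity is worth
the factor of two in memory at the field sizes involved.

Fixed conventions, each pinned by a test:

* **Cartesian link.** `u = S r = ((x−iy)/√2, z, −(x+iy)/√2)` attaches a
  rank-1 tensor to a 3-vector; `S` is unitary and
  `D¹_g = S U_g S^†` links the Wigner matrix at rank 1 to the Cartesian
  rotation matrix.
* **Harmonics.** Racah (semi-Schmidt) normalization:
  `∫|Y^j_m|² dS = 4π/(2j+1)`, `Y⁰ ≡ 1`, Condon–Shortley phases. With the
  m-descending storage and the `S` above, the component array of `Y^j`
  equals the ascending-m slice of the standard orthonormal harmonics
  scaled by `sqrt(4π/(2j+1))`; the magnetic label is sign-flipped
  relative to textbook bookkeeping. Consequences verified numerically:
  `Y¹(s) = S s`, the coupling rule `Y^{j₁} •_j Y^{j₂} = Y^j`, and the
  steering rule `Y^j(U_g s) = D^j_g Y^j(s)`.
* **Wigner matrices.** Built from the explicit small-d sum over ZYZ
  Euler angles. Because of the flipped magnetic label, the assembly uses
  the transposed small-d factor and conjugated Euler phases relative to
  the textbook formula. Unitarity, the homomorphism property and the
  rank-1 closed form hold to 1e−12.
* **Clebsch–Gordan coefficients.** Racah's single-sum closed form in
  exact integer arithmetic (Python's arbitrary-precision factorials),
  cached as dense arrays per (j, j₁, j₂). Exact agreement (1e−13) with a
  symbolic oracle for all entries with j₁, j₂ ≤ 4 is part of the suite.
  Exact integers were preferred over log-factorial stabilization: at the
  ranks this package targets (j ≤ ~10) they are both faster and exact.

The product `∘_j` follows the CG contraction; its parity law (even
j+j₁+j₂ preserves real type, odd maps to imaginary type) and the three
associativity identities are asserted on random tensors. The normalized
variant `•_j` divides by `⟨j0|j₁0, j₂0⟩` and exists only for even
parity; at j = 0 it is the standard inner product.

## Fields, grids, and the convolution convention

Tensor fields live on cubic grids with isotropic spacing; voxel `idx`
sits at `(idx − origin)·spacing` with the origin defaulting to the
floor-midpoint index. The boundary model is periodic: FFT and spatial
paths then agree to round-off, and translation covariance of products
and convolutions is exact on the index torus. Rotation resamples at
`U_gᵀ r` (trilinear by default, spline order selectable) and multiplies
the component stack by `D^j_g`.

**Convolution indexing.** The covariant convolution is implemented as a
true convolution, `(v ∘̃_j w)(r) = ∫ v(r−r′) ∘_j w(r′) dr′`, with the
correlation-style variant (`v(r′−r)`) available as an option. The
choice is deliberate: under the true-convolution indexing the
derivative-commutation property `(∇^ℓ v) ∘̃ w = v ∘̃ (∇^ℓ w)` holds
sign-free (verified to 1e−15 spectrally), convolving with a unit-mass
delta is the identity, and the fast filter identity (one scalar
convolution per frequency after derivative chains) comes out without
rank-dependent signs. Under correlation indexing the commutation picks
up `(−1)^ℓ`. Both variants are validated against an O(N²) direct sum on
8³ grids.

## Spherical derivatives and discrete schemes

The up/down derivatives are `R¹(∇) •_{ℓ±1} f`. Two discretizations:

* **spatial**: central differences of order 2 or 4 (default 4, the
  5-point stencil (−1, 8, 0, −8, 1)/12h). The empirical convergence
  order on an analytic periodic function, measured over 16³/32³/64³, is
  4 (slope of log-error vs log-spacing; the acceptance script prints
  it).
* **fourier**: the exact symbol `i R¹(k)` on the torus; used wherever
  spectral accuracy matters (ladders, commutation tests).

The Laplacian comes as the composition `down ∘ up` of the
first-derivative stencils (default) or as the classic 6-point stencil.
`down ∘ up` equals the Laplacian only for scalar fields — the
associativity rules do not collapse the two couplings at rank ≥ 1, a
fact checked symbolically in the tests — so for tensor fields the
composed scheme is applied component-wise (the Laplacian is an isotropic
scalar operator). After two applications on a Gaussian, the composed
scheme's max-norm error against the analytic biharmonic is ~5× smaller
than the naive stencil's (the acceptance script reports the ratio);
the gap widens with further applications, which is what makes the
Laguerre ladder viable at higher radial orders.

Multiple derivatives of scalar fields factor as
`∇_i^n = ∇^{n−i} Δ^i`, acting in Fourier space as
`i^{n+i} |k|^{2i} R^{n−i}(k)`; both identities are tested.

## Analytic kernel families

**Gauss–Laguerre.** `L_n^j(r) = R^{j−n}(r) L_n^{(j−n)+1/2}(r²/2)` with
the associated Laguerre polynomials evaluated by scipy's recurrence.
The ladder identity used for fast projection is

    L_n^j(r) e^{−r²/2} = ((−1)^j / (2^n n!)) ∇^{j−n} Δ^n e^{−r²/2}.

The prefactor was *fit* numerically (least squares of ladder against
closed form) rather than transcribed, because printed sources are
ambiguous between this and its reciprocal; the fit reproduces
`(−1)^j/(2^n n!)` to 4+ digits at (j,n) up to (3,1). Projection of an
image onto the whole family with j+n ≤ 5 costs ONE Gaussian FFT
convolution followed by cheap derivative chains; on a 64³ head-like
phantom with σ = 6 voxels the ladder coefficients match explicit kernel
convolutions to relative L2 ≈ 4e−4 (worst pair). All ladders run on the
σ-scaled grid (spacing 1/σ) so the unit-width identities apply verbatim.

**Windowed Bessel / Gabor.** `B_s^0 = j₀(kr) e^{−r²/2s}` (s is the
window *variance*), `B_s^j := (−1)^j ∇^j B_s^0`, with the closed form
`Y^j(r̂) Σ_i C(j,i) (r/s)^{j−i} k^i j_i(kr) e^{−r²/2s}` verified against
the ladder to 1e−7. In the unwindowed limit
`∇^j j₀(kr) = (−k)^j Y^j j_j(kr)` — the sign is forced by
`∇ e^{−r²/2} = −R¹ e^{−r²/2}` and is asserted as measured.

The Gabor superposition `Σ_j i^j α_j(k) B_s^j •₀ Y^j(k̂)` approximates
the windowed plane wave with real weights α_j obtained by least squares
against the exact Gabor on the grid (no closed form is assumed). The
approximation has a genuine floor: the radial shape of `B_s^j` differs
from the exact expansion term `(2j+1) j_j(kr) e^{−r²/2s}` by relative
O(j/(k√s)), so for windows that actually decay on the grid the residual
plateaus around 0.1–0.35 rather than vanishing with the band limit. The
tests assert the monotone decrease with N and the measured level; users
needing exact windowed plane waves should synthesize them directly
(`gabor_exact`) and reserve the superposition for steerable filtering,
where the least-squares weights are exactly what the filter training
absorbs.

## Tensorial harmonics

Rank-ℓ fields expand as `f = Σ_{j,k} a_k^j(r) ∘_ℓ Y^j(r̂)` with
coefficients `a_k^j(r)` of rank j+k, j ≤ J, k = −ℓ…ℓ, subject to
j+k ≥ 0 *and* the coupling triangle ℓ ≤ 2j+k (the second bound excludes
degenerate basis elements that are identically zero). The angular basis
`Z_km^j = e_m^{j+k} ∘_ℓ Y^j` is orthogonal; its Gram diagonal is
computed by product quadrature (Gauss–Legendre in the polar angle ×
uniform azimuth, order 2J+2 by default) rather than transcribed. The
measured diagonal is m-independent and equals
`4π (2ℓ+1) / ((2j+1)(2(j+k)+1))` to 1e−10 — i.e. the commonly printed
normalization constant enters the orthogonality relation inverted.

Coefficients are sampled on concentric shells (default: integer voxel
radii up to the inscribed sphere) by cubic-spline interpolation;
reconstruction interpolates coefficients linearly in radius. Round-trip
error on band-limited rank-2 fields is < 1e−2 away from the innermost
shells, where the angular sampling of a Cartesian grid is genuinely
poor; shell radii below ~3 voxels should not be trusted at J ≥ 3.

**Symmetries.** Reflections act as `(−1)^j D^j(R_n(π))` (inversion ×
half-turn about the plane normal) — with this O(3) action the harmonic
fixpoint property extends to reflections exactly, which the tests pin on
odd grids where the spatial flip is lossless. Axial symmetrization
averages 16 z-rotations (exact for band limits ≤ 7 up to interpolation);
the torsion-free projection adds the yz-reflection average. The derived
selection rules (m ≠ 0 terms vanish after axial averaging; k+ℓ-odd terms
after the torsion-free projection; odd-j terms after xy-averaging of an
*axially symmetric* even-rank field — the xy rule needs axiality, since
the general coefficient rule is m-dependent) hold to the interpolation
noise floor (~1e−2 relative on resampled volumes, exact in synthesis).

## Invariant descriptors

Power-spectrum features `c^j(k₁,k₂) = a^j(k₁) •₀ a^j(k₂)` over all
frequency pairs per rank; the diagonal is `‖a^j(k)‖²`. Triple products
`(b^{j₁} ∘_{j₃} b^{j₂}) •₀ b^{j₃}` with j₁+j₂+j₃ odd are rotation
invariant, purely imaginary for real-type inputs, and flip sign under
reflections — they separate mirror images, which no second-order feature
can. The odd-parity coupling is antisymmetric in its first two slots, so
the triple of a coefficient set with itself vanishes identically;
informative features therefore require at least two labelled coefficient
sets per rank (e.g. two radial frequencies), and the API indexes
coefficients by (rank, label) pairs throughout.

## Tensor voting

The axial voting field is decomposed once into tensorial-harmonic radial
profiles (only m = 0 survives axiality); evidence images
`E^{j+k}(r) = m(r) Y^{j+k}(n(r))` are then convolved against the rank-j
kernel fields `a_k^j(|x|) Y^j(x̂)` — one covariant FFT convolution per
(j,k) term, instead of steering the field at every evidence voxel. The
fast path matches the brute-force steer-and-add oracle to < 1e−2
relative at 32³ with band limit 4. The default test field is a rank-2
Gaussian "stick" (axial and torsion-free); any axial field tabulated
along +z is accepted.

## Trainable Bessel voting filter

Detection is cast as covariant regression. Per frequency k and rank
j ≤ N, local coefficient fields `a^j(k) = B_s^j ∗ f` are computed; the
descriptor dictionary contains these plus their even-parity CG squares
(the second-order terms carry the orientation information a linear
covariant scalar filter cannot — such a filter is necessarily isotropic).
Each rank-j descriptor is brought to rank 0 by j down-derivatives and
convolved with the isotropic window kernel `B_s^0(k)` — the fast
collection form, equal (up to the absorbed (−1)^j) to the direct tensor
convolution by the commutation property, which a dedicated test checks
both ways. Ridge least squares fits the per-descriptor weights against a
target map of unit Gaussians (σ_t = 2 voxels) at the landmarks;
per-feature standard-deviation scaling keeps the normal equations well
conditioned, and the ridge parameter default 1e−2 was chosen once for
that conditioning. Saliency maps inherit covariance by construction
(rotating the input rotates the map, tested at 5e−2 on resampled
volumes); peak extraction uses a wrap-mode maximum filter with
lexicographic tie-breaking for determinism.

Study conditions for the detection benchmark: 64³ scenes, an asymmetric
five-Gaussian template (no symmetry plane), 10 training / 20 test
instances at uniform random orientations with ≥ 14-voxel separation,
6–10 distractor blobs, additive Gaussian noise at 2% of signal maximum,
two frequencies (0.4, 0.8 rad/voxel), window variance s = 16, band limit
N = 2. Under these conditions held-out recall at 2-voxel tolerance is
20/20 across the seeds exercised.

## Synthetic data

The phantom generator emulates the *geometry* of the target modalities:
Gaussian blob fields (cell nuclei), oriented tubes (neurites, root
cells), a pollen-like sphere with surface pores, and scenes of rotated
template copies. All randomness flows through one seeded generator;
identical specs are bit-identical, and every phantom ships exact ground
truth (positions, directions, rotation matrices). What the phantoms do
*not* emulate: realistic point-spread functions and anisotropic optics,
intensity inhomogeneity and shading, structured (non-Gaussian) noise,
crowding/occlusion, and anything resembling measured HARDI signal
profiles. Passing tests therefore demonstrate the correctness and
covariance of the machinery and detection under geometric nuisance, not
segmentation-grade performance on real acquisitions.

## Numerical choices and degenerate inputs

* Interpolation: trilinear default for rotation (cheap, adequate for
  covariance at 5e−2); cubic splines where accuracy matters (shell
  sampling, symmetrization, oracle steering). Error budgets in tests
  scale with grid size and are masked away from the box boundary and
  the origin voxel, where direction fields are undefined.
* The origin voxel of `Y^j`-type fields is zero-filled for j ≥ 1
  (`Y⁰ ≡ 1`); `R^j(0) = 0` for j ≥ 1 and `R⁰(0) = 1`.
* Anisotropic voxel spacing is rejected rather than silently
  mishandled; resample first.
* Down-derivatives of scalars, triangle violations, odd-parity
  normalized products, rank/grid mismatches and missing tensor sidecars
  raise immediately with descriptive messages.
* Problem sizes in tests and the acceptance script (8³ direct-sum
  oracles, 24³–48³ property checks, 64³ expansion and detection runs)
  were chosen so the full suite completes in a few minutes on one core
  while keeping every truncation-limited comparison inside its tolerance
  with margin.

## Known limitations

* Integer ranks only; no half-integer spin, no Cartesian tensors of
  rank ≥ 3.
* The periodic boundary model means kernels must decay within the box;
  kernels with heavy tails (high-order Laguerre, weakly windowed Bessel)
  lose accuracy near the boundary, visible as the truncation-limited
  comparisons above.
* The Gabor superposition is an approximation with a floor (see above),
  not an exact transform.
* The trainable filter's dictionary is second order; objects
  distinguishable only by third-order structure would need the triple
  products folded into the training features.
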