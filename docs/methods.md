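# Methods

This note records the model, the numerical conventions, and the design
choices made where the problem statement left the design open. It states no
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Quaternion representation

A location's quaternion is `q = a + bi + cj + dk` with Hamilton's basis
rules. Arrays of quaternions are stored as four parallel real planes
(structure of arrays), so the two complex planes of the Cayley–Dickson form
`α = a + bi`, `β = c + di` can be viewed without repacking — the layout that
the FFT path wants.

Rotations use unit quaternions `r = cos(θ/2) + sin(θ/2)·û` applied as the
sandwich `r q r⁻¹`. For unit `r` the inverse equals the conjugate and the
implementation uses `r*`: it avoids a division by the squared norm and is
exact to rounding for unit inputs (inputs more than `1e-8` from unit norm
are rejected). `r` and `−r` encode the same rotation; `RotationQuaternion`
canonicalizes to a non-negative real part so serialized rotations and
downstream checksums are reproducible. `rotation_between(u1, u2)` returns
the minimal rotation (angle `arccos(u1·u2)`, axis `u1 × u2`); for
antiparallel inputs the axis is ambiguous and is chosen deterministically
as the normalized cross of `u1` with the standard basis vector along which
`u1` has smallest magnitude.

Tolerances are module-level constants in `algebra.py`: `UNIT_ATOL = 1e-8`
for unit-norm preconditions, `STRICT_ATOL = 1e-12` for post-condition
accuracy.

## SVD model

The SVD model projects raw (unnormalized) counts onto the first four
singular vectors and splits depth (first coordinate, absolute value) from
direction (coordinates 2–4, unit-normalized). Sign conventions of an SVD
are arbitrary per component, which would make colors and serialized grids
run-dependent; each singular pair is therefore sign-fixed so the
largest-magnitude entry of the V column is positive (ties broken by lowest
index). Below 50 000 locations the exact LAPACK SVD is used; above, a
seeded randomized top-4 SVD (scikit-learn).

Degenerate cases:

- effective rank < 4 (e.g. fewer distinct expression profiles than 4): the
  model still runs — the missing projection coordinates are exactly zero —
  but a `RankWarning` suggests the gene model, since the vector directions
  are confined to a subspace. The bundled three-population simulation is
  itself rank 3 and is the canonical worked example, which is why rank
  deficiency is a warning rather than an error.
- effective rank < 2: every vector part would be zero; this raises.
- a location with `l_i = 0` (projection exactly on the first axis) gets
  vector part `(0, 0, 0)`; an all-zero location maps to the zero quaternion
  with a warning.

## Gene and gene-set models

The gene model takes three marker genes, optionally from a rank-`r`
truncated-SVD reconstruction of the count matrix (`recon_rank=0` uses the
expression values directly), and unit-normalizes the triple. Normalization
to unit length keeps the vector coefficients in `[-1, 1]`, matching the
bounded inputs the false-color sigmoid expects. Counts enter raw by
default, consistent with the SVD model's use of unnormalized counts; a
library-size normalization flag is available. The real part defaults to the
location's total library size, with the summed counts of the three genes as
an option. The gene-set model only assembles quaternions from
caller-supplied per-location scores; scoring itself (gene-set enrichment,
deconvolution proportions, ...) is deliberately out of scope.

## Grid construction

Locations are binned onto an R×C raster over the coordinate extent with
half-open uniform bins (last bin closed); x maps to columns and descending
y to increasing row index (image convention). Two locations landing in one
cell are averaged coefficient-wise and the vector part renormalized to unit
length, preserving the mapping invariant; last-write-wins would make the
grid order-dependent. Cells with no location are `(0, 0, 0, 0)` and flagged
empty.

Hole fill-in replaces empty cells *inside the convex hull of the observed
cells* with the mean of their non-empty 8-neighbours (vector part
renormalized), iterating until stable with a cap of 10 passes; each pass
reads only the previous pass's state, so the result is deterministic. Cells
outside the hull stay empty — the tissue boundary is preserved. If the
observed cells are degenerate (collinear), the bounding box stands in for
the hull. Observed cells are never modified by fill-in.

Grids serialize to a NumPy `.npz` container holding the four coefficient
planes, the occupancy mask, the bin edges and a frequency-domain flag; the
round trip is bit-faithful and byte-deterministic (checksummable).

## Quaternion Fourier transform

The forward transform splits the quaternion matrix into Cayley–Dickson
complex planes, applies two complex 2-D FFTs and reassembles
`F = Fα + Fβ·j`. Because `e^{-iθ}(α + βj) = e^{-iθ}α + (e^{-iθ}β)j`, this
equals the left-sided quaternion DFT with transform axis `i`,

```
F(u,v) = Σ_{m,n} exp(−i·2π(um/R + vn/C)) · Q(m,n),
```

with the exponential on the left of the quaternion product. Other QFT
conventions (right-sided, two-sided, axis ≠ i) exist in the literature and
are not offered. The forward transform is unnormalized; the inverse carries
`1/(RC)`. Occupancy flags are ignored by the transform — callers decide
whether to fill holes first. Correctness is established against a
brute-force O((RC)²) double-sum oracle, plus round-trip and Parseval
checks (`Σ||Q||² = (1/RC)·Σ||F||²`, which holds plane-wise for the complex
FFTs and hence for the quaternion norm).

## Spectral filtering

"Frequency components" are interpreted as *radial bands*: spectrum cells
are ranked by centred radial frequency `ρ(u,v) = √((u′/R)² + (v′/C)²)` and
grouped by distinct ρ (rounded at 1e-12). Low-pass zeroes the n distinct
highest bands, high-pass the n distinct lowest (DC is the lowest band).
Banding keeps conjugate-symmetric cell pairs together, so filtered fields
of real-valued inputs stay real; a per-cell counting mode is not
implemented. Requesting more bands than exist is an error.

## Convolution and biconvolution

All convolution is circular (FFT-native); no padding option is offered in
this version. Small kernels embed into grid-sized masks wrap-around-centred
at the origin, so the output stays aligned with the input (no half-kernel
shift). Real kernels commute with quaternions, so real-mask convolution is
an exact plane-wise complex FFT convolution. Following the model's
convention, `vector_only=True` (the default) convolves only the vector
field and passes the real (depth) plane through unchanged.

Quaternion masks do not commute, so a left and a right mask are used:
`ML ∗ X ∗ MR`, products taken in that order. The FFT path expands each mask
in Cayley–Dickson form and uses

```
(C1 + C2 j)(A + B j) = (C1 A − C2 conj(B)) + (C1 B + C2 conj(A)) j
(A + B j)(C1 + C2 j) = (A C1 − B conj(C2)) + (A C2 + B conj(C1)) j
```

term-by-term as complex FFT convolutions; it agrees with a triple-loop
spatial oracle to rounding. With `vector_only=True` the scalar plane the
biconvolution generates (vector-vector products have real parts) is
discarded and the input depth plane is passed through.

The rotation kernel pair for unit `r` has rows `(r, 0, r⁻¹)` on the left
and `(r⁻¹, 0, r)` on the right. Row sums are `3(r + r⁻¹) = 0` when
`θ = π`, so uniform fields are annihilated. For boundaries, the operator is
*direction-selective rather than magnitude-selective*: a verified property
of these kernels (asserted in the tests by construction of two-domain
fixtures) is that a boundary whose profiles differ only along the rotation
axis produces output confined to the axis direction, while a boundary
differing orthogonally produces output in the orthogonal plane. Measuring
the output component orthogonal to the axis therefore yields an edge
detector that ignores transitions along the axis — the sense in which
"changes in the direction of the rotation axis are ignored". The raw
output magnitude alone does not distinguish the two boundary types.

## Rotation analyses

The difference-length map is the per-cell Euclidean length of the vector
part of `Q − rotate(Q)`; real parts are ignored. It obeys the closed form
`2·|sin(θ/2)|·|v⊥|`, which the tests use as an analytic oracle. Note the
range is `[0, 2·max|v|]`: a unit vector orthogonal to the axis under a
half-turn yields 2 (the chord of a diameter), not 1.

Perturbation-rotation estimation averages each subset's unit vector parts
coefficient-wise and renormalizes (the chordal mean — appropriate for tight
direction clusters), then returns the minimal rotation between the two mean
directions. The dispersion diagnostic samples up to `n_pairs` control/
perturbed pairs without replacement (seeded), computes their pairwise
rotations, resolves each quaternion's sign toward the first sample (the
double cover makes averaging sign-sensitive), and reports
`1 − |mean quaternion|`: 0 when all pairwise rotations agree, growing with
angular noise. Subsets whose directions cancel (mean length < 1e-8) raise,
since no meaningful average direction exists.

## False-color rendering

Vector coefficients map through `s(x) = 1/(1 + e^{−2x})` to RGB — chosen so
that coefficients bounded in `[-1, 1]` use the sigmoid's near-linear range
and a zero coefficient is mid-gray. Depth maps to opacity by capping at the
`alpha_quantile` (default 0.9) quantile of the non-empty cells
(winsorizing, not discarding — discarding would punch holes in the image),
then `log(x − min + 1)` with the minimum over non-empty cells, then linear
rescale to `[0, 1]`. Zero-depth cells get alpha 0; cells at or above the
cap get alpha 1. Empty cells render as transparent neutral gray
`(0.5, 0.5, 0.5, 0)` — the RGB value is cosmetic since alpha is 0. If all
depths are equal the rescale is degenerate and opacity is set to 1 with a
warning. PNGs are 8-bit RGBA with values quantized by `round(255·v)`.

## Synthetic data

`simulate_fig1` generates the three-population worked example: 30 locations
× 5 genes, profiles `(0.5,0.2,0.1,0.1,0.1)`, `(0.1,0.1,0.1,0.2,0.5)`,
`(0.1,0.3,0.3,0.2,0.1)`, and within-population library sizes spanning a
1-to-10 range. The range is realized as ten equally spaced multiples of a
base depth (default 100, keeping all counts integral) — a modeling choice
consistent with the stated range. The default is noise-free, matching the
exact-collinearity property the SVD model demonstrates on it; rows within a
population are exact scalar multiples.

`simulate_domains` builds spatially structured fixtures (half-planes,
quadrants, disk-in-square) with one location per raster cell, a linear
depth ramp in raster order, and optional seeded multinomial sampling of
counts at each cell's depth. These fixtures emulate contiguous expression
domains with sharp boundaries; they do not emulate Visium-specific noise
(amplification bias, spatial bleed, irregular spot geometry, ~90% zero
fraction), so passing tests demonstrate correctness of the operators, not
robustness to real-data artifacts.

Problem sizes in the tests and the acceptance script (grids up to 12×12,
brute-force oracles up to 8×8) are chosen so the oracle comparisons — the
expensive O((RC)²) and triple-loop sums — stay exact-to-rounding while the
whole suite runs in seconds; the FFT implementations themselves are
size-independent.

## Known limitations

- Only a rank-3 slice (or three genes/sets) of the expression profile is
  represented; orthogonal biological signal is invisible to the mapping.
- Circular convolution wraps at grid edges; responses at opposite borders
  are artifacts of the wrap, not tissue structure.
- The spectral-filter band definition is one of several defensible readings
  of "top n frequency components"; per-cell counting is not offered.
- No correction is attempted for rotation/alignment mismatch between
  tissue coordinates and the array frame.
- Octonion extensions, 1-D (pseudotime) transforms, two-sided QFTs and
  registration via phase correlation are out of scope.
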