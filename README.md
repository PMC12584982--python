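# stquat

Quaternion models and hypercomplex Fourier analysis for spatial
transcriptomics (ST).

## The problem and the model

ST technologies (10x Visium/Visium HD, MERSCOPE, ...) measure gene
expression at spatially resolved tissue locations. Fourier-based image
analysis of such data is usually restricted to one gene or latent variable
at a time, because a real-valued 2-D matrix can carry only one feature per
location. `stquat` instead maps each location to a *quaternion*

```
q = a + b i + c j + d k,        i² = j² = k² = i j k = −1
```

whose real part `a` encodes sequencing depth (library size, a proxy for how
certain the relative expression profile is) and whose unit vector part
`(b, c, d)` encodes three transcriptomic features at once. Three mappings
are provided:

- **SVD model** — compute the SVD `X = U D Vᵀ` of the unnormalized count
  matrix, project onto the first four singular vectors, `P = U₄ D₄`, and set
  `qᵢ = (|pᵢ₁|, pᵢ₂/lᵢ, pᵢ₃/lᵢ, pᵢ₄/lᵢ)` with
  `lᵢ = √(pᵢ₂² + pᵢ₃² + pᵢ₄²)`. For raw counts, `|pᵢ₁|` tracks library
  size and the unit vector is the rank-3 relative expression profile.
- **Gene model** — the vector part is the (optionally reduced-rank
  reconstructed) expression of three chosen marker genes, unit-normalized.
- **Gene-set model** — the vector part is built from caller-supplied scores
  of three gene sets (or cell-type proportions).

Because relative profiles live on the unit sphere in R³, transitions
between transcriptomic states are 3-D rotations, represented by unit
quaternions `r = cos(θ/2) + sin(θ/2)·û` and applied as `r q r⁻¹`. On top of
this representation the package provides:

- quaternion grids rasterized from tissue coordinates (with hole fill-in),
- a 2-D quaternion-domain discrete Fourier transform via the
  Cayley–Dickson decomposition `q = (a + b i) + (c + d i) j` (two complex
  FFTs; equal to the left-sided quaternion DFT with axis `i`),
- low/high-pass spectral filtering on radial frequency bands,
- FFT convolution with real kernels (sharpen, edge) and *biconvolution*
  `ML ∗ X ∗ MR` with left/right quaternion mask matrices, including the
  axis-selective rotation-kernel edge detector,
- rotation analyses: difference-length maps, association probes, and
  perturbation-rotation estimation between location subsets,
- false-color RGBA rendering (vector part → RGB through a sigmoid, depth →
  opacity through a quantile-capped log rescale).

## Worked example

The bundled generator reproduces the canonical three-population
simulation: 30 locations × 5 genes, relative-abundance profiles
`(0.5, 0.2, 0.1, 0.1, 0.1)`, `(0.1, 0.1, 0.1, 0.2, 0.5)` and
`(0.1, 0.3, 0.3, 0.2, 0.1)`, library sizes spanning a 1-to-10 range within
each population:

```python
import numpy as np
from stquat import simulate_fig1, svd_model

counts = simulate_fig1()
print(counts.counts[0])           # [50 20 10 10 10]

loc = svd_model(counts)           # warns: effective rank 3 < 4
print(np.round(loc.q[0].coeffs(), 4))   # [47.5544 -0.9032 -0.4291 -0.    ]
print(np.round(loc.q[9].coeffs(), 4))   # [475.5441 -0.9032 -0.4291 -0.  ]

d = loc.depth[:10]
print(d.max() / d.min())          # 10.000000000000078
v = loc.q.vector()
print(v[0] @ v[1])                # 1.0        (same population: collinear)
print(v[0] @ v[10])               # -0.730738  (different population)
```

The real parts of locations 1 and 10 differ by exactly the 10× library-size
factor while their unit vectors coincide — each population lies on one line
through the origin of the projection space, so depth and relative profile
separate cleanly into the two quaternion parts.

The same objects feed the spatial pipeline:

```python
from stquat import build_grid, association_probe, convolve_real, KEDGE, to_rgba

grid = build_grid(loc.q, counts.coords, rows=3, cols=10, fill=False)
dmap = association_probe(grid, [1, 1, 1], np.pi)  # joint-association probe
img  = to_rgba(grid)                              # (3, 10, 4) RGBA in [0, 1]
edges = convolve_real(grid, KEDGE)                # edge-detection convolution
```

Everything is also scriptable from the shell:

```sh
stquat simulate fig1 --out counts.csv --coords-out xy.csv
stquat map counts.csv xy.csv --out grid.npz --rows 3 --cols 10
stquat render grid.npz --out grid.png
stquat filter grid.npz --out low.npz --mode lowpass --n 10
stquat convolve grid.npz --out edges.npz --kernel edge
stquat biconvolve grid.npz --out bic.npz --axis i --angle 180
stquat rotate grid.npz --out diff.csv --axis i+j --angle 180 --diff
```

## Layout

- `src/stquat/algebra.py` — Hamilton products, rotation quaternions
- `src/stquat/st_io.py` — MTX/CSV readers, grid rasterization + containers
- `src/stquat/mapping.py` — SVD / gene / gene-set quaternion models
- `src/stquat/qft.py` — Cayley–Dickson 2-D quaternion FFT
- `src/stquat/spectral.py` — filtering, kernels, convolution, biconvolution
- `src/stquat/rotation.py` — grid rotations, difference maps, estimates
- `src/stquat/falsecolor.py` — RGBA rendering, PNG output
- `src/stquat/synthetic.py` — simulation fixtures
- `src/stquat/cli.py` — `stquat` command-line tool
- `docs/methods.md` — modeling assumptions and numerical conventions
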