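# Methods

## The model and its assumptions

The tissue is idealized as a rectangle of length `l` (proximal–distal,
x) and width `h` (anterior–posterior, y) under spatially uniform shear,
with off-diagonal shear assumed zero so a single component `xx` carries
the kinematics. Three ingredients define the model:

1. **Decomposition.** The traceless tissue velocity gradient splits into
   cell-shape change and rearrangements, `ṽxx = d⟨Qxx⟩/dt + Rxx`, with
   `ṽxx = ½ ∂t(L−H)`, `L = log(l/l₀)`, `H = log(h/h₀)`.
2. **Rearrangement response.** `Rxx = λ qxx`: intercalation is driven
   by myosin anisotropy `q` at rate `λ` [h⁻¹].
3. **Constitutive law.** Deviatoric stress
   `σ̃ = 2K⟨Q⟩ + ζ q + 2μ d⟨Q⟩/dt` with elastic modulus `K`, active
   coefficient `ζ` (negative = AP-contractile) and viscosity `μ`. Free
   boundaries (`σ̃ = 0`) give
   `d⟨Qxx⟩/dt = −⟨Qxx⟩/τs − (ζ/2K)/τs · qxx(t)`, `τs = μ/K`.

Only the ratios `(τs, ζ/2K, λ)` are identifiable; `ζ/2μ = (ζ/2K)/τs`
is derived. The myosin schedule is piecewise linear — magnitude 1 on
`(t₀,t₁)`, linear ramp to 0 on `(t₁,t₂)`, zero after — with defaults
`t₀,t₁,t₂ = 4,5,6` h APF and right-continuous values at the
breakpoints (a measure-zero choice that cannot affect any integral).
The magnitude 1 is a normalization absorbed into `ζ` and `λ`.

The closed-form solution integrates the piecewise-constant/linear drive
against the exponential kernel exactly per segment, with the exponent
shifted (`e^{(t'−t)/τs}`) so small `τs` never overflows. `(L−H)(t)` is
evaluated by 24-point Gauss–Legendre quadrature per inter-timepoint
interval (split at the schedule breakpoints) on the closed-form
integrand; against the exact antiderivative this is accurate to machine
precision for these smooth segments. The independent ODE route
(`solve_Qxx_ode`) integrates segment-by-segment between breakpoints with
RK45 at user tolerance; the two routes agree to better than 1e−9
sup-norm over the physiological box (`τs ∈ [0.1,1]` h,
`ζ/2K ∈ [−0.14,−0.06]`, `Qxx0 ∈ [−0.1,0.1]`).

## Fitting

For fixed `τs`, `⟨Qxx⟩(t)` is affine in `ζ/2K` and `(L−H)(t)` affine in
`(ζ/2K, λ)`; the sensitivity curves are obtained by three forward
evaluations and the inner problem solved exactly by linear least
squares on the pooled residuals of both curves (equal weights by
default; per-block weights and a sequential mode — `ζ/2K` from the
elongation curve, then `λ` from the strain residual — are options).
`Qxx0` is pinned to the first measured elongation value. The outer
grid sweeps `τs` over 0.1–1 h (10 values by default); the full grid is
returned because the data constrain `λ` much more tightly than `τs`
(the fitted `λ` stays near its true value across the whole grid while
`ζ/2K` trades off against `τs`). The design matrix is well conditioned
at every grid point, so the SSE Hessian is positive definite and the
inner solve needs no iteration or starting values.

## Elongation tensor

Each triangle of the cell-center triangulation is compared with a
unit-area equilateral reference (one edge along +x): with `M` the
linear map from reference to observed triangle (orientation
normalized so `det M > 0`),

    Q = ½ log(M Mᵀ / det M).

Using the *left* Cauchy–Green tensor `MMᵀ` (lab frame) rather than
`MᵀM` (reference frame) is what makes the result independent of vertex
labeling and covariant under rotations (rotating the triangle by θ
rotates `(Qxx,Qxy)` by 2θ in nematic space). The log of the symmetric
unimodular 2×2 matrix is evaluated in closed form
(`|Q| = ½ arccosh(tr B/2)`, direction from the deviatoric part), which
is exact and vectorizes over all triangles.

Vertices where k ≥ 4 cells meet are fanned into k−2 triangles in
counterclockwise cell order (deterministic; such vertices are transient
T1 intermediates). Triangles are built only at interior vertices —
vertices touching a tissue-boundary edge are skipped to avoid
artificial hull anisotropy. Both `|⟨Q⟩|` and `⟨|Q|⟩` are reported
(they differ; `⟨|Q|⟩ ≥ |⟨Q⟩|` by convexity), and the triangle average
is unweighted by default with area weighting available.

**A finite-strain caveat.** Matrix logarithms are additive only for
commuting deformations: after an affine pure shear `s`, a triangle with
`qxy ≠ 0` changes its `Qxx` by `s` plus a second-order cross term
`O(s·q²)`. On an initially isotropic lattice the additivity is exact;
on disordered tissue the per-measurement bias is ≲1e−3 at the shears
the model produces, far below every tolerance used here, but it is the
reason the generator budgets its planted T1 swaps against *measured*
elongation rather than assuming exact additivity.

## Synthetic epithelium generator

The generator defines the study conditions; its defaults are fixed:

* **Meshes** — Voronoi tessellation of a hexagonal lattice (spacing 1)
  jittered by `disorder × 0.49 ×` Uniform(−1,1) per coordinate, with a
  3-site guard ring so every kept cell has a bounded polygon. At
  `disorder = 0` every cell is an exact regular hexagon. Default
  disorder 0.2–0.3 gives per-triangle anisotropy ⟨|Q|⟩ ≈ 0.05–0.1,
  comparable to a quiescent epithelium.
* **Tissue series** (default 200 cells, dt 0.25 h, 4–7 h APF) — per
  interval the mesh is sheared affinely by `½ Δ(L−H)` of the model
  solution, then T1 swaps (edge collapsed to its midpoint, re-opened
  perpendicular at the pre-collapse length between the flanking pair)
  are planted greedily until the *measured* mean elongation matches the
  model `⟨Qxx⟩`, so the shear excess carried by rearrangements
  realizes `Rxx = λ qxx` without any analytic shortcut. Candidate
  edges are scored by their measured elongation jump (a
  predictor–corrector loop internal to the generator); with `λ = 0` no
  swap is ever planted. Ground truth records every applied shear,
  imposed rearrangement rate and event.
* **Extrusions (T2)** shrink the cell over the two preceding frames and
  then contract its vertices to within 2% of the centroid, leaving no
  shared high-order vertex — so an extrusion never reads as a rosette.
  **Rosettes** are planted on single-frame copies by merging a
  threefold vertex with two edge-neighbors (≥5 incident cells),
  transient by construction.
* **Images** — membrane skeleton from all cell/cell and cell/exterior
  boundaries, Gaussian intensity ridge of ~2 px, shot (Poisson) plus
  read (Gaussian) noise with variance split evenly at the membrane;
  `snr` = membrane amplitude / total noise sd. Default 32 px per cell
  diameter. Labels are `cell_id + 1`, 0 on membrane and exterior.
* **Curves** — exact model solutions plus i.i.d. Gaussian noise
  (default study: sd 0.01, 13 timepoints over 4–7 h); `(L−H)(t₀)` is
  pinned to 0 because the first frame is the strain reference.
* **Polarity / coverage** — junctions within 30° of the AP axis get
  intensity `ratio` (default planted ratio 2, the observed 2-fold
  polarity), PD-aligned junctions 1, oblique ones a smooth `sin²`
  interpolation; multiplicative noise keeps class means unbiased.
  Surface profiles plant contiguous covered runs at `contrast ×`
  background (default 10×, 5% noise).

What the generator does **not** emulate: curved 3-D tissue geometry,
segmentation-error-correlated tracking noise, spatial gradients of
myosin or of intercalation, cell divisions, and image artifacts beyond
stationary shot/read noise. Passing closed-loop tests therefore
demonstrates correctness of the measurement chain and solver algebra
under the stated noise models, not robustness to every failure mode of
real microscopy.

## Kinematics and event detection

Derivatives use central differences with second-order one-sided stencils
at the series ends (`np.gradient`, `edge_order=2`). Because the same
operator acts on `(L−H)` and `⟨Qxx⟩`, the decomposition identity
`ṽxx − d⟨Qxx⟩/dt − Rxx = 0` holds exactly at every timepoint by
construction.

Event rules on tracked series: **T1** = an adjacency pair lost between
consecutive frames while the complementary pair of the same quartet is
gained; **T2** = a cell id disappearing whose area was non-increasing
(5% tolerance) over the preceding two frames — guarding against
tracking loss misread as extrusion; **rosette** = a vertex with ≥5
incident cells (a fourfold vertex is a T1 intermediate, not a rosette;
the threshold is configurable), the same incident set in consecutive
frames counted once. Detection is purely topological, so centroid
jitter at 2% of a cell diameter leaves recall at 1.0.

## Segmentation

The Shen–Castan smoother is the canonical ISEF: a separable symmetric
exponential `c·b^|n|`, `b = e^{−1/α}`, `c = (1−b)/(1+b)`, run as a
causal/anticausal recursive pair with steady-state initialization (so
constant images are exact fixed points) on a reflect-padded frame.
Ridge strength is the clipped negative minor eigenvalue of the Gaussian
Hessian at scale `σ` (γ-normalized by `σ²`). Watershed markers come
from regional minima after h-minima suppression at a fraction (default
0.08) of the ridge range; basins smaller than `min_cell_area_px`
(default 300 px at the default rendering resolution) are union-merged
into the neighbor behind their lowest ridge barrier and the transform
re-run with merged markers so watershed lines (label 0) are consistent.
Defaults were calibrated on the synthetic fixtures — the only ground
truth available — where all 100 planted cells are recovered at IoU 0.9
for snr ∈ {∞, 10, 5}. Evaluation uses greedy one-to-one IoU matching.

## Numerical and degenerate-input choices

* Zero-area triangles and non-positive cell polygons raise; triangle
  orientation is normalized before the tensor is formed.
* A mesh with no interior tricellular vertex yields an empty
  triangulation with a warning; averaging over it raises.
* Blank images segment to at most one region without error.
* Otsu thresholding requires bimodality: a constant profile returns 0%
  coverage, and an all-covered noisy profile (a unimodal histogram) is
  outside its domain — the explicit-threshold path covers those cases.
* Label-map reconstruction marks two cells adjacent when their labels
  touch after a 2 px label expansion, and finds tricellular vertices as
  clustered 2×2 blocks containing ≥3 distinct labels.
* Rasters are row-major, origin top-left, pixel centers at integer
  coordinates; mesh y increases downward so mesh and raster frames
  align without sign flips.
* All seeds are explicit arguments; no global random state is used
  anywhere.

## Problem sizes

Default study sizes — 200-cell series at dt 0.25 h over 4–7 h APF,
100-cell renders at 32 px/cell, 13-timepoint curves with 50 recovery
replicates — were chosen so each closed loop has enough statistics for
its stated tolerance (e.g. ~350 triangles make the per-T1 elongation
jump ~0.003, resolving a 0.1 h⁻¹ planted rate to a few percent) while a
full pipeline run stays in the seconds-to-a-minute range.

## Known limitations

* The T1-planting loop is greedy and measurement-guided; it matches the
  target rearrangement shear to ~1–3% per interval but does not model
  junction mechanics — the spatial pattern of intercalation is imposed,
  not emergent.
* Epithelial height enters only as an optional scalar; no 3-D shape.
* The continuum model is spatially uniform by assumption; no PDE
  version, and `K`, `μ`, `ζ` are not separately identifiable.
* Repeated surgery on the same neighborhood can produce invalid local
  geometry; such candidates are detected and rejected rather than
  relaxed mechanically.
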