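# Methods

## Model overview

The package simulates sprouting angiogenesis as discrete microvessel
networks — forests of line segments with active tips — growing through a
rectilinear hexahedral domain whose integration points carry two fields:
collagen density ρ (mg/mL) and an ellipsoidal fibril distribution (EFD), a
3×3 symmetric positive-definite tensor `P = Σ βᵢ nᵢ⊗nᵢ` whose eigenvalues
are the semiprincipal radii of the local fibril orientation distribution.
The fractional anisotropy

    FA = √½ · √((β₁−β₂)² + (β₂−β₃)² + (β₃−β₁)²) / √(β₁²+β₂²+β₃²)

(the population std of the radii over their rms) summarizes how aligned the
matrix is; FA is rotation- and scale-invariant, 0 at isotropy and → 1 in the
uniaxial limit.

Each time step, every active tip:

1. **interpolates** the local EFD and density from the 8 Gauss points of its
   cell (Log-Euclidean weighted mean for tensors, trilinear for scalars);
2. **samples** a contact-guidance direction θ from the (optionally
   pseudo-deformed) EFD by Monte-Carlo rejection;
3. **rotates** its orientation ψ toward θ about ψ×θ by the fraction α of
   their angle (α = 0 pure persistence, α = 1 pure guidance); the rotation
   satisfies angle(ψ_new, θ) = (1−α)·angle(ψ, θ) exactly;
4. **extends** by `rate(t) · ν(ρ, FA) · dt` along ψ_new.

Branches spawn stochastically on recently grown segments; tips arrest when
the local vessel volume fraction exceeds a threshold, and deactivate at the
domain boundary.

## Pseudo-deformation

A deformation gradient `F` maps the unit sphere through the net mapping
`Fⁿ = F·P⁰`. `Fⁿ` is generally non-symmetric, so the deformed distribution
is no longer an ellipsoid in tensor form. The left polar decomposition
`Fⁿ = Vⁿ Rⁿ` (computed via SVD, `Fⁿ = UΣWᵀ ⇒ Vⁿ = UΣUᵀ`, robust near
singularity) yields the pseudo-deformation `Fᵖ = Vⁿ`: the SPD stretch with
the rotation discarded. An older comparator, `B̂ = FⁿFⁿᵀ`, identifies the
same axes but squares the radii; it is provided as a diagnostic only.

**Why verification measures discretization, not model error.** The direction
distribution induced by mapping uniform sphere directions through a linear
map `A` has density ∝ det(A)⁻¹‖A⁻¹u‖⁻³, and `‖(Fⁿ)⁻¹u‖ = ‖(Vⁿ)⁻¹u‖` for all
u because the two maps differ only by a right rotation. The true- and
pseudo-deformed *continuum* distributions are therefore identical, and any
measured difference quantifies the discretization of the comparison
pipeline. The verification harness reports those differences under the
package's own quadrature so that the ellipsoidal approximation can be
trusted at the resolutions the simulations actually use.

### Verification harness

- Three initial EFD families — uniform `diag(1,1,1)`, uniaxial
  `diag(5,1,1)`, planar `diag(3,3,1)` — pre-rotated by the extrinsic
  composition `Rz(45°)·Ry(45°)·Rx(45°)` so loads never act along principal
  axes (radii configurable; the chosen values anchor the isotropic,
  transversely isotropic and planar FA regimes).
- Four load modes: uniaxial `diag(λ,1,1)` and biaxial `diag(λ,λ,1)` with
  λ ∈ [0.5, 1.5]; simple shear `I + κ e₁⊗e₂` and pure shear
  `diag(1+κ, 1/(1+κ), 1)` with κ ∈ [0, 0.5]; 11 evenly spaced sweep points
  per mode. Incompressibility is not imposed (standard kinematics for the
  stated parameter ranges).
- Source directions: the 10,242 vertices of a subdivision-level-5 icosphere.
- **GFA** is computed from the mapped surface radii `‖A s⁰ᵢ‖` with
  barycentric vertex-area quadrature weights (std/rms). The radius samples
  are smooth in the mesh, so the quadrature error sits near 10⁻⁶ — far
  below the 10⁻³ scale at which differences would be scientifically
  meaningful. Count-based facet histograms were rejected for this purpose:
  hard binning of ~10⁴ points carries O(n^-1/2) quantization noise near
  10⁻² in GFA at any binning resolution.
- **Fisher–Rao distance** `arccos Σ √(pᵢqᵢ)` (degrees) is computed between
  count-based facet histograms binned on a subdivision-level-2 icosphere
  (320 facets, ~32 points/facet). Finer binning mostly measures quantization
  (more facets than points at level 5 drives the distance toward 65° for
  identical distributions); coarser binning under-resolves sharp
  distributions. Measured maxima: ΔGFA ≈ 3.6·10⁻⁶ and ≈ 3.7° Fisher–Rao
  over the full sweep — both comfortably inside the ranges at which the
  ellipsoidal approximation is considered faithful (10⁻³ and 6°).

Facet histograms elsewhere in the package assign each direction to the
facet of maximum centroid dot product (ties → lowest index, a measure-zero
event) without area weighting; at level ≥ 2 the assignment-region solid
angles vary by only a few percent, and an area-corrected density accessor
exists for glyph rendering. Antipodal symmetrization is off for full-sphere
verification data and on for vessel-segment (axial) ODFs.

## Sampling and interpolation

Directions are sampled by drawing proposals uniformly in the bounding cube
`[−β₁, β₁]³` of the ellipsoid in its principal frame, accepting when
`Σ rᵢ²/βᵢ² < 1`, normalizing, and rotating into the global frame. For an
isotropic EFD the acceptance rate is the sphere/cube volume ratio π/6.
Uniform-in-volume sampling followed by normalization yields a directional
density ∝ ρ(u)³ (ρ(u) the ellipsoid radius along u) — *sharper* than the
radius profile itself. This ρ³ law is intentional: the sampler defines what
"probing the matrix" means in this model, and the chi-square and
density-oracle tests pin it down. The cube bound makes sampling from
extremely eccentric tensors (aspect ≳ 50) slow; physiologic EFDs (β₁/β₃ ≤ 10)
accept at ≥ 1% rates.

EFDs live at 8 Gauss points per cell (natural coordinates ±1/√3). A query
point's natural coordinates are rescaled by √3 and clamped to [−1, 1], so
standard trilinear shape functions `Nₖ = ⅛Π(1 + ξᵢcₖᵢ)` interpolate the
Gauss-point data as a shrunken virtual hexahedron. Tensors are averaged by
the Log-Euclidean weighted mean `exp(Σ wᵢ log Pᵢ)` — symmetric,
positive-definite, cheap, with eigenvalue bounds for commuting inputs; the
affine-invariant Karcher mean is available behind `mean="affine"` for
sensitivity checks (the two coincide for commuting inputs). Matrix logs of
the stored field are cached, so interpolation costs one batched 3×3
eigendecomposition per query set.

Legacy **vector mode** reproduces the older representation: one unit vector
per integration point, sampled from that point's EFD exactly once at
initialization and never re-sampled; interpolation is a normalized weighted
sum after flipping each vector into the hemisphere of the querying tip
(axial data), with a highest-weight fallback for perfectly cancelling
resultants.

## Growth rules and calibration

The velocity scale is a separable Lorentzian

    ν(ρ, FA) = a / [(1 + ((ρ−ρ₀)/b)²)(1 + ((FA−FA₀)/c)²)] + d

with defaults ρ₀ = 2.5 mg/mL, b = 0.7 mg/mL, FA₀ = 1, c = 0.8, d = 0.05.
The amplitude is rescaled at load time so that ν(3 mg/mL, FA_ref) = 1 with
FA_ref the anisotropy of the low-alignment reference matrix (radii
1.3/1.0/0.5, FA ≈ 0.41) — growth is expressed relative to unaligned
3 mg/mL collagen. The center placement makes ν strictly decreasing in
density over the physiologic 3–5 mg/mL range and increasing in FA over
[0, 1]; d sustains minimal non-negative growth. Because the amplitude
rescaling absorbs the density arm at 3 mg/mL, ν(3, FA) is independent of
(ρ₀, b): the density-response calibration does not perturb the 3 mg/mL
experiments. The width b = 0.7 mg/mL was calibrated once so that a
5 mg/mL interface slows transit strongly enough for densification to gate
invasion while alignment can still compensate — the regime the predictive
experiments probe. All six coefficients are config-exposed.

Two extension-rate rules are provided:

- **sigmoid** (default; culture and tumor scenarios): rate = d/dt of
  `A·logistic(k(t−t₀))` with A = 0.8 mm/tip, t₀ = 5 days, k = 1/day — peak
  extension ≈ 0.2 mm/day, within in-vitro ranges.
- **linear with arrest** (gradient scenario): ramp over the first 2 days to
  0.2 mm/day, zero once the local vessel volume fraction
  `(Σ length·πr²)/V_cell` exceeds `w_thresh`.

`w_thresh` defaults to 0.01. Note the seeded fragment packing already
reaches a volume fraction ≈ 0.003–0.035 in the seeding region (150
fragments/mm³ of median length 60 μm at 5 μm radius), so thresholds much
below 0.01 arrest growth at t = 0; the default sits a factor ~3–10 above
initial packing, allowing saturating but non-trivial growth.

The fibril weight defaults to α = 0.3, equal to the weight applied once to
each fragment orientation at seeding, and inside the regime where EFD-field
simulations polarize monotonically with matrix anisotropy while
out-polarizing vector-field simulations at high anisotropy. Time step
dt = 0.25 day with step length capped at half the smallest cell edge; θ is
sampled once per tip per step.

Branching: each tip carries an exponential lineage-growth threshold (mean
0.15 mm); crossing it spawns one branch at the start of the tip's newest
segment, directed at a zenith angle (truncated normal, 60° ± 15°) from the
parent axis with azimuth uniform on [0, 2π). The threshold distribution and
angles are stand-ins for unpublished measurements and are config-exposed.

## Scenarios (what the generator emulates)

- **uniform_culture**: 1 mm³ cube (0.1 mm cells; 0.05 mm refinement
  supported) of homogeneous collagen at anisotropy low/med/high —
  radii (1.3, 1, 0.5), (2.5, 1, 0.5), (5, 1, 0.5), major axis along x,
  anchoring the gradient ramp endpoints — and density 3 or 4 mg/mL.
- **gradient**: 1.8 × 2.0 × 0.5 mm strip; proximal/middle/distal regions of
  0.4/1.0/0.4 mm. β₁ ramps linearly 1.3→5.0 (positive) or 5.0→1.3
  (negative) across the middle at fixed β₂ = 1, β₃ = 0.5; flanks hold the
  adjacent end value; baseline is near-isotropic (1.05, 1.0, 0.95 — exact
  degeneracy avoided so eigenvectors stay well-posed). Fragments seed the
  proximal region; 12 days, linear-with-arrest rate rule.
- **tacs**: 1 × 1.68 × 0.6 mm domain along y: periphery (0.8 mm, seeded),
  80 μm interface (two 0.04 mm cell layers), tumor (0.8 mm). TACS-1 raises
  interface density to 5 mg/mL; TACS-2 aligns the interface EFD along x
  (radii 5, 1, 0.5); TACS-3 aligns it across the interface toward the tumor;
  combinations compose. The interface is refined only along y — finer z
  refinement in the source geometry served a finite-element mechanics solver
  that is outside this package's scope.

Fragment seeding: centers uniform in the seeding region; lengths log-normal
(median 60 μm, σ_log 0.5 — a documented stand-in for the measured
initial-length distribution, replaceable by any callable); orientations
drawn from `diag(1, 1, β₃ᵖ)` (isotropic in XY, polarized toward the plane
for β₃ᵖ < 1, default 0.5), then rotated once toward a sampled collagen
direction with weight 0.3; both ends become active tips.

What the generator does **not** emulate: matrix mechanics (tractions,
viscoelasticity, fluid flow) and the two-way feedback between vessel forces
and fibril reorientation; anastomosis; lumen formation; biochemical
signaling. Prescribed deformation-gradient fields can be applied to the EFD
maps (`apply_deformation_field`), but no forces are solved for. Passing
tests therefore demonstrate guidance-limited behavior, not
mechanics-coupled behavior.

## Replicates, determinism, outputs

Every stochastic draw flows through one seeded PCG64 engine in a fixed
order; identical seed + config replays a bit-identical segment table.
Replicate studies run seeds `base, base+1, …` and report per-seed metrics
with mean/sd and a manifest (family, variant, seeds, duration, config
hash). Segment tables export as CSV; networks and sphere glyphs as legacy
ASCII VTK polydata.

Morphometry: planar ODFs use 180 one-degree axial bins, length-weighted;
the ellipse axis ratio is `√(λ_max/λ_min)` of the 2×2 orientation structure
tensor of the binned masses (exact 1 for uniform histograms; capped at 50
for degenerate ones). Regional lengths use exact segment/box clipping, so
regional sums equal total length to 10⁻⁹ mm whenever regions tile the
domain.

## Problem sizes used by the shipped studies

The packaged studies run the verification sweep at its full printed size
(132 cases, 10,242 directions). The growth experiments run at desk scale:
cube cultures on 0.5 mm domains with 3 replicate seeds and no branching
(matching the comparison protocol), and the gradient and tumor-interface
scenarios at full printed geometry with 10 replicate seeds and dt = 0.25
day. Directional orderings, not absolute lengths, are the comparison
surface at these sizes; representative magnitudes appear in the README's
worked example.

## Known limitations

- The rejection sampler's cube bound is faithful to the published algorithm
  but inefficient for extreme eccentricities (see above).
- Count-based facet histograms are quantization-limited at ~10⁴ samples;
  the package deliberately computes verification GFA from radius samples
  instead (see the verification section for why this is the right oracle).
- A tip finishes its whole step inside the field of the cell where the step
  began (no sub-step re-interpolation across faces); with step length capped
  at half a cell edge the induced error is below the sampling noise.
- Region volumes assume axis-aligned boxes; non-rectilinear meshes and
  mesh import are out of scope.
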