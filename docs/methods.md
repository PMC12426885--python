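# Methods

This note documents the models implemented in `dtvtomo`, the parameter
choices that matter, what the synthetic data do and do not emulate, and
the numerical decisions taken where the design was open.

## Imaging model

A point-projection geometry with source-to-object distance `R1` (mm) and
propagation distance `R2` (mm) magnifies by `M = (R1+R2)/R1`. The
forward simulator works per projection in four steps:

1. **Contact image.** Beer–Lambert attenuation `exp(−∫μ dz)` with
   `μ = 4πβ/λ`, and projected phase `φ = −(2π/λ)∫δ dz`, both computed
   with the same discrete Joseph-type line integrator used for
   reconstruction (one shared discrete geometry; an optional 2×
   supersampled simulation grid avoids the inverse crime when wanted).
2. **Near-field propagation.** The transport-of-intensity expression
   `I = (contact/M²)(1 − (R2 λ/2πM) ∇⊥²φ)` with a 5-point Laplacian on
   the effective-pixel grid, reflective boundaries. Negative intensities
   (weak-object violations at strong edges) are clipped to zero with a
   logged count. A single effective wavelength is used throughout; no
   polychromatic weighting.
3. **System blur.** Gaussian convolution of width
   `σ = sqrt((1−1/M)²σ_s² + σ_d²/M²)` expressed in effective pixels,
   flux-conserving with reflective boundaries. All widths are the
   Gaussian width parameter; FWHM conversion (×2.3548) happens only
   where resolution is measured.
4. **Noise.** Poisson counts at `photons_per_pixel · M² · I`, so an
   empty beam averages `photons_per_pixel`; flats are the average of 16
   noisy flat frames; darks are zero (no dark current is modelled).
   Correction is `(I − dark)/(flat − dark)`.

Continuous scans evaluate the evolving phantom at each exposure
midpoint; no intra-exposure motion integration is performed, so motion
blur within one frame is not modelled.

A note on `M_opt = 1 + σ_d/σ_s`: this is **not** the minimiser of σ(M)
(that is `1 + (σ_d/σ_s)²`). It maximises phase-fringe contrast at fixed
system length — analytically, the figure of merit `(R2/M)/σ(M)²` peaks
exactly there, and the simulator's fringe amplitude reproduces the
interior optimum on a grid over `R2`.

## Phase retrieval

Single-distance homogeneous-object retrieval:
`φ = −½(δ/β) log|F⁻¹[F(I/I0) · H]|` with
`H = 1/((λR2/4πM)(δ/β)(u²+v²) + 1)`. The frequency convention is fixed
by self-consistency with the forward TIE model: `(u,v)` are *angular*
frequencies (`2π·fftfreq/pixel`) on the effective-pixel grid, and the
propagation distance enters as `R2/M`. Under this convention the filter
denominator equals `1 + (R2 δ/(M μ)) q²`, which is the exact linearised
inverse of the simulator; the round-trip test on a weak homogeneous blob
closes to 0.02 % RMS, and at `R2 = 0` the formula reduces exactly to
Beer–Lambert log inversion. Images are symmetrically padded to twice
their size before the FFT; intensities are clamped at 1e−6 before the
logarithm with a logged count of clamped pixels. The retrieved phase is
returned with the sign of a positive thickness measure (the negative of
the physical phase shift). δ/β is a configuration scalar; a CLI sweep
renders retrievals over a list of candidate ratios for visual/CNR
inspection, with no automatic selection rule.

## Tomographic operators

The reference geometry is 2D parallel-beam, one axial slice per rotation
plane; slice stacks are looped. The forward operator samples the image
on a rotated unit-spaced grid with bilinear interpolation (Joseph-type)
and scales by the voxel size; the backprojector scatters with the same
weights and is the exact numerical adjoint (inner-product tests close to
1e−16). Per-angle interpolation tables and, for fixed angle sets, an
assembled sparse system matrix are cached. FBP uses the band-limited
real-space ramp kernel (sampling |f| directly biases the DC region),
Hann-apodised by default, with the `π/(2 n_angles)` quadrature weight;
reconstruction is valid inside the inscribed circle and masked outside.
Objects are assumed to lie within the inscribed circle. Angles are
degrees externally, rotation is counter-clockwise about the grid centre,
and z is both the rotation axis and the height axis of the waterfront
analysis.

## Directional-TV reconstruction

The prior field is `ξ = ∇v / sqrt(‖∇v‖² + η²)` with forward-difference
gradients and Neumann boundaries — the identical discrete gradient used
in the functional and in the solver, so the dual and primal updates are
exact adjoints. The weight is `D_v = I − ξξᵀ`. PDHG solves

`min_{u≥0} ½‖Au − b‖² + α‖D_v∇u‖_{2,1}`

with duals for the data term (prox `(y+σr)/(1+σ)`) and for the weighted
gradient (projection onto the ball of radius √α), a non-negativity
projection as the primal prox, extrapolation θ = 1 and steps
`σ = τ = 0.99/L`.

Two scaling decisions are load-bearing:

- **√α folding.** The regulariser enters the stacked operator as
  `K = (A, √α D_v∇)` (so the dual ball has radius √α and
  `√α·‖√α D_v∇u‖ = α·dTV`). Without this, the projector's norm (~150 on
  a 128² slice) starves the gradient block and the prior is inert for
  any practical iteration count; with it, the blocks balance once α is
  of order `‖A‖²/‖∇‖²` and the prior acts within tens of iterations.
- **Normalised solver frame.** By default the solve runs on data scaled
  to unit maximum with a pixel-unit projector (ξ is invariant under the
  rescaling), making α portable across data scales. The defaults
  `α = 1e4` and `η = 0.2 ×` the 99.5th-percentile gradient magnitude of
  the reference were chosen on the synthetic study scene by inspecting
  the water-vs-air CNR — the same empirical procedure a practitioner
  uses on real data, where the published values for this regulariser
  class (α ≈ 5e−9, η ≈ 5e−11 on instrument-scale δ volumes) are
  likewise scene-specific. The study scene runs 100 iterations; the
  provenance default of 10 iterations with FBP warm start is kept as
  the `ReconConfig` default.

PDHG's primal objective is not pointwise monotone (it is a saddle-point
iteration); the solver guarantees a strong net decrease and raises a
step-size error if the objective grows five-fold within ten iterations.
The objective is sampled every `objective_every` iterations to keep the
per-iteration cost at two operator applications.

Behaviourally, the prior does two things the tests pin down: edges
present in the reference keep their position (half-maximum crossings
within one voxel) and their sharpness (ERF FWHM at or below the system
resolution — TV regularisation can sharpen a blurred but prior-aligned
edge), while features absent from the reference, like the moving water
level, are penalised isotropically and come out markedly blurrier.

## Alignment

Flyscan data have an unknown start angle; detector dead time dilates the
effective angular step; dropped frames shift the offset mid-scan. All
three are estimated by reconstructing candidates with FBP and minimising
the l2 distance to the reference volume, after mean subtraction and norm
scaling (decoupling alignment from grey-value drift), optionally within
a cylindrical mask. Offsets and step dilations injected alone are
recovered exactly on their grids, and a per-segment search absorbs a
mid-scan frame skip as a clean offset jump. When offset and dilation are
*jointly* unknown they couple through the scan midpoint (both shift the
mean applied angle) and the l2 objective can trade one against the
other; the coarse-to-fine `refine_alignment` therefore pivots the step
search at the scan midpoint with the mean rotation held fixed, and its
joint estimates carry an intrinsic uncertainty of roughly one grid step.

## Synthetic data: what it does and does not emulate

The phantom is a wood cylinder (δ, β defaults at an effective ~19 keV:
air ≈ 0, wood 4e−7/4e−10, water 5.2e−7/5.2e−10, i.e. δ/β = 1000 and the
grey-value ordering air < wood < water) pierced by non-overlapping axial
vessels whose geometry is drawn in physical coordinates from the seed,
so the same seed gives the same object at any grid resolution. Filling
follows Lucas–Washburn `h_i = k_i√(t − t0_i)` with `k_i ∝ 1/radius_i`;
rate-jump events emulate a joined vessel pair separating (geometrically,
a capsule-shaped joint cross-section below a separation height).
Filling relabels voxels strictly inside vessels, so every material
boundary of the dry state is preserved — the precondition for the
gradient-direction argument, which the shape-preserving image-pair
generator demonstrates quantitatively (raw Pearson correlation < 1,
gradient-direction correlation 1.000).

The study scene images one 128² axial slice at 10.4 µm effective pixels:
a 360 × 1 s static reference at 20 000 photons/pixel/frame and a
180 × 50 ms continuous dynamic scan at 1 000 (flux per unit time equal,
i.e. a 20× shorter exposure), against the laboratory geometry R1 = 320,
R2 = 140 mm, σ_s = 70, σ_d = 30 µm. Waterfront tracking runs on
(96, 48, 48) voxel timelines where classified volumes are the phantom's
δ maps plus Gaussian noise at one sixth of the water–air class gap,
standing in for reconstruction noise — tracking quality on real
reconstructions inherits whatever bias the reconstruction adds, which
this shortcut does not probe. Other honest gaps between the generator
and real data: no polychromatic spectrum or beam hardening, no detector
dark current or afterglow, no intra-exposure motion blur, no sample
drift or wobble, vessels are straight cylinders (no tortuosity), and
sub-resolution wood porosity is available only as an optional smooth
multiplicative texture on the wood optics. Passing tests therefore
demonstrate the correctness and qualitative behaviour of the method, not
instrument-level quantitative accuracy; the published grey-value
summaries in `reference_data.py` are carried as canonical inputs for the
CNR arithmetic, not as simulation targets.

## Degenerate inputs and tie-breaks

Vessel packing failures raise with the achieved count; empty angle
lists, geometry mismatches, non-positive clamp floors, flat alignment
objectives and all-NaN ratio profiles raise rather than defaulting.
Alignment ties break toward the smallest absolute offset. The waterfront
rule returns the vessel base when no water is found, the vessel top when
the ratio never stays below threshold, and treats windows truncated by
the vessel top as satisfied if all their existing samples are below
threshold; heights are measured from each vessel's lowest segmented
voxel. A droplet inside the persistence window postpones the front past
it — the strict reading of "drops below and remains below" — making the
estimate conservative from above.

## Known limitations

- 2D parallel-beam only; cone-beam weighting and true 3D regularisation
  are out of scope (slices are processed independently).
- The dTV solve at the study scale converges in the engineering sense
  (stable CNR, large net objective decrease) within ~100 iterations but
  is not iterated to high-precision optimality.
- α and η have no automatic selection rule, by design.
- Joint offset+step alignment is identifiable only up to the documented
  midpoint trade-off.
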