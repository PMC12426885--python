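# dtvtomo

Dynamic free-space-propagation (FSP) x-ray phase-contrast microtomography
with structure-based directional-TV regularisation — as a fully synthetic,
tested pipeline.

## The problem

Laboratory x-ray sources are orders of magnitude less brilliant than
synchrotrons, so dynamic micro-CT — imaging a process as it happens, e.g.
water rising by capillary action through the vessels of a wood skewer —
must reconstruct from seconds of noisy, undersampled projections. Two
ideas make that workable:

1. **Propagation-based phase contrast.** Letting the beam propagate a
   distance `R2` past a weakly absorbing object converts phase gradients
   into intensity fringes. In the near field the detected intensity obeys
   the transport-of-intensity relation

   `I = (I_contact / M²) · (1 − (R2 λ / 2π M) ∇⊥² φ)`,

   with magnification `M = (R1 + R2)/R1`. For Gaussian source width σ_s
   and detector PSF σ_d the total system blur is
   `σ = sqrt((1 − 1/M)² σ_s² + σ_d²/M²)`, and fringe contrast at fixed
   system length peaks at `M_opt = 1 + σ_d/σ_s`. A single-distance
   Paganin-type Fourier filter,
   `φ = −½ (δ/β) log |F⁻¹[ F(I/I0) / ((λ R2/4π M)(δ/β)(u²+v²) + 1) ]|`,
   inverts the propagation for a homogeneous object and strongly
   suppresses noise.

2. **A structure-based prior.** The process changes what is *inside*
   structures (air → water), not their shapes, so the normalised gradient
   *directions* of a high-quality reference volume `v` remain valid for
   every dynamic state. Each undersampled time point `u(t)` is
   reconstructed by

   `u(t) = argmin_{u ≥ 0} ½‖A u − b‖² + α · dTV(u, v)`,
   `dTV(u, v) = Σ ‖(I − ξξᵀ) ∇u‖₂`,  `ξ = ∇v / sqrt(‖∇v‖² + η²)`,

   solved with the primal-dual hybrid gradient (PDHG) method from a
   filtered-backprojection warm start. Gradients aligned with the
   reference's edges are free; gradients it cannot explain pay the full
   TV price.

No public dataset accompanies the method, so the package ships a
first-class synthetic generator: a wood-like cylinder with axial vessels
that fill with water as `h ∝ √t`, imaged by a simulator with TIE
propagation, Gaussian system blur and Poisson noise, plus the full
analysis chain (CNR, edge-response FWHM, per-vessel waterfront tracking
with the 0.1-ratio / 20-voxel persistence rule).

## Worked example

`python examples/dtv_vs_fbp.py` simulates a long reference scan of the
dry slice and one 9-second dynamic scan (180 × 50 ms frames under
continuous 20°/s rotation, 20× fewer photons per frame), then
reconstructs the *same* dynamic data three ways:

```
water-vs-air CNR of the three chains (same raw dynamic data):
  conventional (attenuation FBP)     CNR =  1.29
  analytical phase-retrieved FBP     CNR =  3.73
  dTV-regularised phase-retrieved    CNR =  4.99

system resolution (FWHM)             :   70.2 um
prior-aligned wood edge (dTV)        :   33.9 um
prior-absent waterline edge (dTV)    :   98.9 um
```

Phase retrieval and then the structure prior each raise the
contrast-to-noise ratio between water- and air-filled vessels, measured
as `CNR = (mean_water − mean_air) / ((sd_water + sd_air)/2)`. The edge
widths show the prior's trade-off: edges the reference knows stay at or
below the system resolution, while the moving water level — absent from
the reference — is penalised isotropically and blurs.

`python examples/waterfront_tracking.py` runs the 4D analysis: per-vessel
waterfront heights recover the programmed `√t` law (fitted exponent
0.506) and locate a programmed vessel-separation rate jump at its height
(378 µm detected vs 363 µm programmed, within three voxels).

## Layout

```
src/dtvtomo/
  geometry.py     system geometry, M_opt, system PSF width
  phantom.py      vessel phantom, filling schedules, shape-preserving pair
  simulate.py     TIE forward simulator (contact → propagation → blur → noise)
  retrieval.py    single-distance Paganin-type phase retrieval
  projector.py    matched Joseph projector/adjoint pair, FBP, power-method norm
  dtv.py          directional-TV prior and PDHG solver
  align.py        flyscan angular offset/step estimation
  metrics.py      CNR, gradient-direction correlation, ERF FWHM, histograms
  waterfront.py   water classification and per-vessel front tracking
  scenes.py       canonical end-to-end synthetic experiments
  config/io/pipeline/cli   run configuration, HDF5/TIFF I/O, stage runner
```

`docs/methods.md` documents the model, parameter choices and known
limitations.
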