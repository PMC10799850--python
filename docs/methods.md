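# Methods

This note records the models, numerical choices and validation conditions
behind `ritfm`, in the order the pipeline runs.

## Elastic model

The gel is treated as a linear, isotropic, **semi-infinite** elastic medium
with a free surface at `z = 0`.  Finite gel thickness (tens of µm in
practice) is neglected; thickness corrections are a known limitation, not a
goal.  The displacement response to a surface point force is the classical
Boussinesq–Cerruti solution.  With lateral offset `ρ = (x²+y²)^½`, depth
`z ≥ 0`, `r = (ρ²+z²)^½` and prefactor `C = (1+ν)/(2πE)`:

* lateral–lateral: `C [1/r + x²/r³ + (1−2ν)(1/(r+z) − x²/(r(r+z)²))]` (and
  the `y` analogue; the `xy` off-diagonals are symmetric),
* normal–normal: `C [z²/r³ + 2(1−ν)/r]`,
* shear–normal couplings carry the factor `(1−2ν)` and/or `z`, so they
  vanish identically at the surface for an incompressible gel (`ν = 0.5`).

This interior-point form is finite at `ρ = 0` for `z > 0` (the only
singularity is the load point itself) and reduces at `z = 0` to the familiar
2D TFM kernel, e.g. `G_zz = 3/(4πEρ)` at `ν = 0.5`.  Some published
statements of the tensor write `ρ` where the interior solution requires `r`;
we use the classical form because the alternative diverges on the axis
below the load, which is unphysical.

**Sign conventions.**  Package-wide, `x, y` are the lateral volume axes and
the third component of force/displacement is positive **toward the cell**
(upward).  The `z` argument of `greens_tensor` is depth below the surface.
Internally the classical depth-positive tensor is sign-mapped once
(`S G S`, `S = diag(1,1,−1)`); volumes store slices surface-first, so an
upward physical motion decreases the z index.

**Kernel sampling.**  The tensor is sampled on the full `(2n−1)²` lateral
offset grid per depth plane, so FFT convolution is an *exact* linear
convolution (verified against direct double summation at 1e−10).  The
singular surface cell is replaced by the analytic average of `G` over the
square grid cell (`⟨1/ρ⟩ = 4 ln(1+√2)/a`, `⟨x²/ρ³⟩ = 2 ln(1+√2)/a`; odd
terms vanish); for non-square cells a quarter-cell offset evaluation is the
fallback.  An optional truncation radius restricts each node's kernel
support to a local stencil; the default keeps the full long-range kernel,
because truncating the operator that generated the data demonstrably biases
the inversion (spurious normal traction, attenuated peaks).

## Traction inversion

The inverse problem `argmin_T ½‖u − G⊛T‖² + τ‖∇T‖₁` is solved globally with
**monotone FISTA**: gradient step, isotropic TV proximal map per traction
component (dual fast-gradient-projection, the "inner" iterations), and
acceptance of the candidate only if the objective does not increase.  All
solves start from zero (deconvolution stages warm start from the observed /
upsampled image, see below) and use no randomness.

**Non-dimensionalization.**  Step size and TV weight are only meaningful
relative to a scaling of the operator and data, and published values are
tied to unpublished internal scalings.  `ritfm` therefore fixes its own
frame once: the operator is scaled to unit spectral norm (power iteration,
deterministic) and the data to unit per-node RMS.  In this frame the default
parameters are step `α = 0.01`, TV weight `τ = 0.02`, 200 inner and 240
outer iterations — the standard settings for the traction problem — and
they transfer across grid sizes and moduli because both terms of the
objective are extensive in the node count.  A power-iteration safeguard
warns whenever `α` exceeds `1/L`.

**Measurement planes.**  Each traction vector is constrained by the
displacement vectors on the two grid planes nearest the surface (default),
evaluated at their actual depths; a `surface_only` switch evaluates the
kernel at `z = 0` instead.  A per-node local least-squares mode
(`local_patch_traction`, a 10×10×2 neighbourhood per node) is provided as a
regularization-free cross-check; it localizes isolated loads exactly but
underestimates extended patches, which is why the global TV solve is the
primary path.

**What TV regularization does to amplitudes.**  At the default `τ` the
converged solution suppresses displacement-noise-induced traction but also
shrinks genuine peaks (by roughly 30–50% for few-µm patches sensed from
1–2 µm deep planes).  Pattern geometry and force balance are preserved;
absolute peak values should be read as lower bounds unless `τ` is relaxed.

## Displacement tracking

Windowed 3D FFT cross-correlation with single-step upsampled-DFT subpixel
refinement (`skimage.registration.phase_cross_correlation`,
`normalization=None`), default upsample 100 (0.01 voxel).  Defaults follow
the instrument scale: 64³-voxel subsets (≈11.7 µm at 0.183 µm pitch) on an
11-voxel (≈2 µm) grid.  Windows are rejected when flat, mostly masked
(mask dilated by a window radius first), displaced beyond half the subset,
or below the peak-quality threshold; rejected nodes are infilled by linear
interpolation from valid neighbours and flagged, because the inversion
needs a complete grid.  Window estimates are unbiased to ≈0.03 voxel
(window-edge effects) with per-axis precision of a few nanometres on
noiseless phantoms; displacements approaching half the subset alias, so the
subset must exceed twice the largest expected shift.

Registration and tracking invariants tested: shift equivariance (to window
edge effects), ref/mov swap antisymmetry, exact recovery of integer shifts
by whole-volume correlation, and a 0.5–3 µm rigid-translation ladder
recovered with mean error <0.05 voxel and std <10 nm.

## High-pass filter

A zero-sum, even-symmetric kernel: a unit-sum Gaussian (`σ = √2` voxels)
minus the flat mean over an anisotropic support (half-windows 0.5 µm
lateral, 1 µm axial, converted to voxels by round-half-up).  Subtracting
the support mean makes the weights sum to zero exactly at any window
anisotropy, which the printed normalization constants of the usual
difference form do not guarantee; the functional intent — DC removal and a
bead-scale passband — is unchanged.  Boundary handling is reflect padding
to avoid edge darkening.  Measured on a bead-plus-smooth-background
phantom, the low-frequency band is suppressed by ≈29 dB while the bead peak
location is untouched.

## Synthetic data

The generator encodes the study conditions and is not tuned per experiment:

* **Beads**: 200-nm spheres at 3 beads/µm³, Poisson-sampled count, uniform
  subvoxel positions, rendered as Gaussians with σ from the stated tomogram
  resolution (161 nm lateral / 401 nm axial FWHM), floored at 0.75 voxel so
  the spots stay representable on the grid.  Rendered volumes are strictly
  band-limited (Nyquist planes zeroed) so Fourier translations compose
  exactly — subvoxel shift then unshift reproduces the volume to rounding.
* **Traction patterns**: contractile dipole, inward ring, normal-load patch
  (distal annulus up, proximal disc down) and rotational moment, all
  force-balanced by construction.  Patch width defaults to `σ = 2.5 µm`, a
  focal-adhesion-cluster scale; peak magnitude 100 Pa.
* **Forward warp**: continuum displacement from the elastic model evaluated
  at every z-plane depth, applied by tricubic interpolation with constant
  padding; the input volume is the relaxed (post-detachment) state.
* **Noise**: additive Gaussian on volumes, or direct displacement-space
  noise at the measured-accuracy scale (≈6 nm lateral / 15 nm axial).

What the phantoms do *not* emulate: optical artifacts (missing-cone
elongation, coherent speckle), bead aggregation, finite gel thickness and
gel nonlinearity.  Passing recovery tests therefore demonstrates the
correctness of the tracking/inversion chain, not robustness to every
instrument artifact.

## Validation conditions and problem sizes

Chosen once for the test battery, balancing statistical power against a
desktop-scale run:

* Tracking ladder: 128³ phantom, 64³ subsets on a 22-voxel grid, six
  translations (0.5–3 µm).
* Recovery ensemble: 20 seeded scenes, 32×96×96 voxels, 1.2-kPa gel,
  alternating dipole/ring at random orientation; tracked with 12³ subsets
  on a 4-voxel grid (upsample 20) and inverted at the default solver
  settings.  Acceptance: median pattern correlation >0.9 and net in-plane
  force <5% of gross.
* Sensitivity: noise-only displacement fields (6/6/15 nm) on a 1-kPa gel,
  24² grid at 2 µm; the reconstructed traction std defines shear/normal
  sensitivity, with the normal channel ≈3× less sensitive, as expected from
  the weaker depth coupling of `G_zz`.

## Dry mass

`c = (n − n_medium)/α` with `α = 0.185 mL/g`; negative concentrations are
clamped to zero (fraction logged).  Medium RI is a required input — it is
instrument- and buffer-specific.  Axial integration gives surface density
(1 g/mL·µm = 10³ fg/µm²); weight pressure `P = σg` with `g = 9.8 m/s²`
(1 fg/µm² → 10⁻⁶ kg/m²).  A 20.45 fg/µm² density weighs 2.0×10⁻⁴ Pa —
five-plus orders below 100-Pa-scale tractions, which is the quantitative
justification for ignoring gravity in the force balance.  Morphology uses a
0.02 g/mL support threshold by default (configurable); histogram binning is
Freedman–Diaconis.  Kymographs offer both max- and mean-reduction.

## Deconvolution

RI volume deconvolution reuses the TV-FISTA engine with a PSF convolution
operator (unit-sum PSF) in a two-stage multiscale schedule: 3× downsampled
solve (α = 0.003, τ = 0.003, 100/75 iterations), cubic upsampling, then a
full-resolution polish (α = 0.006, τ = 0.006, 50/25), with optional
non-negativity on the RI contrast.  Stages warm start from the observed /
upsampled image, so the schedule is a strict deterministic refinement; with
these conservative step sizes the improvement is modest and is largest when
structures are well resolved by the grid.

## Known limitations

* Half-space elasticity only; no finite-thickness or nonlinear corrections.
* Pure-translation tracking windows (no affine window deformation).
* TV amplitude shrinkage at the default weight (see above); no automatic
  `τ` selection — it is explicit configuration.
* Traction is reported on the tracking grid; no super-resolved output grid.
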