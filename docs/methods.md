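# Methods

This note records the physical model, the estimators, the numerical
choices and their rationale, and what the synthetic studies do and do not
demonstrate.

## Measurement principle

A positron-emitting pellet travels on a helix of radius `r_h` around the
object, inside a cylindrical PET detector.  Annihilation produces
back-to-back 511 keV photon pairs; a coincidence is a pair of crystal
hits defining a line of response (LOR).  For each LOR the expected count
ratio of a blank scan over a transmission scan equals
`exp(∫ µ dl)`, so the log-ratio sinogram is the Radon transform of the
attenuation map µ (cm⁻¹).  Reconstruction proceeds by single-slice
rebinning of the 3D data to 2D planes followed by filtered back
projection, plane by plane.

## Forward model

* **Decays** form a homogeneous Poisson process: the count is drawn once
  from `Poisson(activity × duration)` and times are uniform — equivalent
  to per-interval thinning, but vectorizable.
* **Pair directions** are isotropic; the pellet is a mathematical point
  at `source_position(t)`.
* **Detection**: both photons must intersect the crystal barrel within
  its axial extent; each intersection maps to the nearest crystal.  The
  pair survives with probability `efficiency² × exp(−τ)`, where τ is the
  optical depth along the photon path computed by an exact Siddon
  traversal of the voxel grid (µ in cm⁻¹ × intersection length in cm).
  Because attenuation factorizes along a line, one full-LOR integral
  equals the product of the two single-photon segments.
* **Not modeled** (by design): Compton scatter, random coincidences,
  dead time, positron range, photon acollinearity, depth of interaction,
  crystal energy response, and ¹⁸F decay over the scan (< 12% over
  20 min; an optional exponential flag could be added but the default
  ignores it).  Counts are therefore ideal-Poisson and the simulated
  maps are free of scatter bias; recovered µ values demonstrate the
  *reconstruction chain*, not a full physics validation.

## Phantoms

Voxelization uses the voxel-center rule (a voxel takes a material's µ iff
its center is inside the shape): simple, deterministic, convergent, and
consistent with the piecewise-constant grid the ray tracer assumes.
Material defaults at 511 keV: water 0.096 cm⁻¹ (literature reference),
air 0, soft tissue 0.0975, cortical bone 0.172, PTFE 0.191 cm⁻¹ (from
standard photon-attenuation tables at nominal densities); all are
overridable.  The 1 L bottle preset (90 mm × 157 mm, 999 mL) and the
insert layout (five air cavities of 5/8/9.5/12/16 mm on a 36 mm-radius
circle plus a 25 mm Teflon rod) are package presets — stated fixtures,
not measured geometry.

## Source tracking and separation

Per time bin, the pellet position is the point minimizing the summed
squared perpendicular distance to the bin's LORs (closed-form 3×3 normal
equations).  Emission contamination is handled by iteratively reweighted
least squares with Cauchy weights `1/(1+(r/c)²)`, `c = 10 mm`:
transmission LORs concentrate on a point and dominate after a few
iterations.  Two safeguards follow the fit:

* **Trust test** — a genuine lock has sharply concentrated residuals;
  bins lacking ≥ `min_events` residuals below `c`, or with a tight/loose
  inlier ratio under 0.5, are distrusted.
* **Neighbor propagation** — distrusted bins are re-solved starting from
  the nearest trusted bin's position and accepted only if well supported
  and within a plausible step.  This recovers intervals where the pellet
  sits near the axial edge of the FOV, where its geometric acceptance
  (and hence its event count) collapses while the emission background
  does not.

Remaining unresolved bins are bridged by linear interpolation.  An event
is classified transmission iff its LOR passes within
`2 × crystal pitch` (default) of the pellet position at its timestamp.
On the default desk-scale mixed scan this separates with ≈ 99%
accuracy against ground-truth tags; misclassification concentrates where
the pellet is nearly invisible (FOV edge) and on emission LORs that graze
the helix.

## Reconstruction

* **Binning**: transaxial projection to (radial offset s, azimuth ψ) with
  ψ ∈ [0, π); the radial lattice is symmetric about s = 0 (odd bin
  count).  **The radial bin width should be ≈ half the crystal pitch**:
  the discrete set of chord offsets a crystal ring can produce is itself
  quantized at that scale, and finer bins alias against it, leaving
  empty, interpolated bins that bias the profile.  Ring-pair stacks keep
  all pairs up to a configurable maximum ring difference.
* **SSRB**: counts from ring pair (r₁, r₂) are assigned to the plane at
  (r₁+r₂)/2; half-integer planes are kept, giving 2N−1 planes at half
  the ring spacing.  For objects uniform along z this is exact up to the
  oblique path-length factor 1/cos θ, which inflates the log-ratio by
  roughly 1–2% at the default geometry (visible as a ≈ +0.001 cm⁻¹
  offset on water); objects must span the axial FOV, otherwise oblique
  LORs exit the object and dilute the ratio.
* **Log-ratio**: the blank is scaled by the exposure ratio
  `(activity×duration)_trans / (…)_blank` before the ratio.  Default
  zero handling adds a pseudo-count of 0.5 to both raw counts — finite
  everywhere, with a known downward bias when per-bin transmission
  counts fall below ≈ 5 (configurations here keep object bins above
  that); the alternative `mask` policy interpolates empty bins radially.
* **FBP**: ramp filter in cycles/mm with Hann apodization up to
  0.9 × Nyquist by default (resolution-oriented runs use cutoff 1.0);
  zero-padded FFT filtering, bilinear-free 1D interpolation
  backprojection, scaling π/n_angles, output converted to cm⁻¹.
  Arc correction is omitted — at the configured crystal counts the
  chord-vs-arc radial distortion is below one bin across the imaging
  field.  Verified against the analytic disk transform and
  independently against `skimage.transform.iradon`.

## Study configurations and problem sizes

Desk-scale runs use a compact ring (radius 150 mm, 8 rings × 12 mm,
240 crystals/ring → 3.9 mm pitch) and a helix of radius 100 mm covering
the 96 mm axial FOV; these sizes keep a full chain run in tens of
seconds while preserving every algorithmic property of the full-size
system (the default `DetectorRing()` is whole-body scale and fully
configurable).  The water-bottle study uses 10⁷ transmission and
3×10⁷ blank decays; the insert study raises resolution (384 crystals →
2.5 mm pitch, 1.5 mm radial bins, 112 angles, Hann cutoff 1.0) and
exposures (2×10⁷ / 4×10⁷) because cavity recovery probes system
resolution — the plain desk ring emulates a coarser scanner than the
hardware under study and recovers only 12 mm.  The criterion itself
(cavity mask-mean below 50% of the water background) is held fixed
everywhere; with it, the 8 mm cavity is recovered and the 5 mm cavity is
not (contrast ratio ≈ 0.65).

## Coil-array evaluation

Channel sensitivities are quasi-static circular-loop fields (complete
elliptic integrals; the on-axis limit matches `a²/2(a²+z²)^{3/2}`), with
a smooth per-channel phase ramp.  K-space is centered, orthonormal-FFT;
channel noise is circular complex Gaussian with a Hermitian covariance
(`ρ^{|i−j|}` neighbor-decay model by default), added via Cholesky
factorization.

* **Pseudo-multiple-replica SNR**: per replica, fresh correlated noise is
  added, the data reconstructed and root-sum-of-squares combined;
  SNR = mean/std across replicas per pixel.  For complex noise of total
  variance σ² the magnitude-image noise is σ/√2, so the closed-form
  white-noise check is SNR = √2·|object|/σ.  Where there is no signal the
  magnitude statistics sit at the Rayleigh floor mean/std ≈ 1.91 — a
  property of magnitude combining, not a defect.
* **GRAPPA**: per-offset kernels (default 2 sampled ky × 5 kx taps,
  Tikhonov 10⁻⁴ trace-scaled) fit on a fully sampled ACS block and
  applied with periodic wrap in k-space.
* **g-factor**: `g = (σ_accelerated / σ_full) / √R`, both stds from
  pseudo replicas with noise on acquired samples only, weights calibrated
  once on noise-free ACS, map smoothed with a 3×3 mean filter.  G-maps
  default to a minimal 2×1 kernel with weak regularization: wider
  kernels average noise over many k-space samples ("noise apodization")
  and depress g far below the unaliasing-theory value (measured ≈ 0.67
  at R = 2 with the 2×5 kernel).  Even with the minimal kernel, GRAPPA's
  intrinsic smoothing leaves interior values up to ≈ 5% below 1 at
  R = 2; the g ≥ 1 property is therefore asserted within 3× the replica
  standard error.  Mean in-object g rises monotonically over R = 2, 3, 4
  on the 8-loop array (≈ 0.96, 1.04, 1.21).
* The comparison against a physical reference coil requires measured
  data; the analogous synthetic computation is the pixelwise
  `snr_ratio` of two simulated arrays.

## What passing tests show — and what they do not

The synthetic studies verify estimator correctness, unbiasedness of the
chain at adequate counts, count conservation, Poisson noise scaling, and
parameter recovery under the stated idealizations.  They do not validate
scatter/randoms handling, detector physics, hose/housing attenuation
(an optional annulus is off by default), or in vivo conditions; printed
per-voxel noise reflects desk-scale exposure, not clinical statistics.

## Reproducibility

Every simulation consumes an explicit seed; the pipeline derives
per-stage seeds from one master seed via `SeedSequence`, records them in
the provenance JSON together with the config hash and package version,
and identical configs reproduce all arrays bit for bit.
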