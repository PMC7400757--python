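# Methods

## Overview

`eloreta_npv` implements a source-space EEG instability analysis aimed at a
clinical prediction problem: in idiopathic normal pressure hydrocephalus
(iNPH), which patients will improve after CSF shunt surgery? The working
hypothesis is thermodynamic in flavour — cortex in a still-reversible disease
phase is *unstable*, showing larger temporal variance of its electrical
activity than cortex that has transitioned to an irreversible, stable phase.
The pipeline turns that idea into numbers in five steps:

1. **Preprocessing** — resting-state EEG (19-channel 10-20 montage, 500 Hz)
   is band-passed 0.53–120 Hz, re-referenced to the common average, and cut
   to a fixed-length epoch (500 s in the emulated protocol).
2. **Source reconstruction** — the eLORETA weighted minimum-norm inverse
   maps per-segment DFT sensor spectra to cortical current density on a
   voxel grid.
3. **NPV** — per voxel and frequency band, the normalized power variance
   (variance of band power divided by squared mean power) is computed in
   4.6-s windows stepped by 1.15 s and averaged over windows.
4. **Group statistics** — voxel-wise two-group ANOVA with max-statistic
   permutation correction across voxels, separately per band.
5. **Classification** — a one-predictor linear discriminant on log NPV at
   the extreme voxel/band, evaluated by leave-one-subject-out
   cross-validation (LOOCV).

## Forward model

The head is three concentric spherical shells — brain / skull / scalp with
radii 79 / 82 / 87 mm and conductivities 0.33 / 0.0042 / 0.33 S/m, the
conventional 3-shell values. The potential of a current dipole inside a
layered sphere is expanded in Legendre harmonics; per degree *n*, the two
radial-solution coefficients are propagated across shell boundaries by
continuity of potential and radial current density, with zero radial current
at the scalp. The series is truncated at 100 terms; with sources restricted
to ≤ 85% of the brain radius the truncated tail is below 1e-11 relative.
Source voxels sit on a regular Cartesian grid (25 mm default spacing, 81
voxels; tests also use 30 and 35 mm). Every gain column is mean-centered
over sensors so the leadfield is consistent with average-referenced data.

This is a deliberate desk-scale stand-in for a realistic MRI-based head
model: the algorithmic core (inverse, NPV, statistics, discriminant) is
agnostic to where the gain matrix comes from, and externally computed
leadfields can be imported through the HDF5 container.

## eLORETA

The weights solve the fixed point `W_j = (K_j' M K_j)^{1/2}` with
`M = (K W^{-1} K' + α·(tr C / N_s)·H)^+`, iterated from identity blocks until
the largest absolute weight change falls below 1e-6 (at most 100 iterations;
typically ~20). `H` is the average-reference centering operator, applied to
both leadfield and data. The matrix square root and SPD inverses use
eigendecompositions with an eigenvalue floor of 1e-12 times the largest
eigenvalue, and the sensor-space inverse is a pseudo-inverse, so rank
deficiency (centering removes one sensor dimension) never raises. The
leadfield is normalized internally by its RMS for conditioning; current
density is therefore in arbitrary units, which is irrelevant downstream
because NPV is scale-invariant and localization uses argmax power.

Regularization `α` is a dimensionless fraction of the mean sensor-covariance
trace: 0.05 by default for noisy data, ~1e-12 for noiseless localization
tests. eLORETA's defining property — zero localization error for noiseless
point sources — is verified exhaustively in the tests: every voxel of the
desk-scale model, all three orientations plus random mixtures, must localize
exactly (argmax of orientation-summed current-density power).

## Spectral decomposition and NPV

The elementary unit is the non-overlapping 1.15-s segment (575 samples at
500 Hz), chosen so that the 4.6-s NPV window is exactly 4 segments and the
1.15-s step exactly 1 segment. Per segment a plain (untapered) DFT is taken;
a Hann taper is available as an option. A DFT bin belongs to a band iff its
center frequency `k / 1.15 s` lies inside the closed band interval; with
0.8696 Hz bin spacing the beta band (13.5–29.5 Hz) holds bins 16–33. Bin 0
is never used. Band power at a voxel is the squared magnitude of current
density summed over the band's bins and over dipole orientations.

NPV of a window is the *population* variance of the 4 segment powers divided
by their squared mean — the squared coefficient of variation. The population
convention (divide by n) is the moment-ratio reading of the definition, and
with only 4 samples per window it differs materially from the sample
convention (divide by n−1), which is available as an option; the choice is
recorded in the map metadata. Window NPVs are averaged arithmetically over
the 431 sliding windows of a 500-s epoch (raw, untransformed averaging).
All-zero-power windows contribute NPV 0 rather than NaN, and are counted in
the log.

Properties relied on throughout: NPV is exactly invariant to global signal
rescaling (power scales quadratically in both numerator and squared-mean
denominator), is 0 iff power is constant within every window, and equals 1
in expectation for exponentially distributed power.

## Group statistics

Per voxel and band, a one-way two-group ANOVA F (df 1, n−2) compares
responders and non-responders; NPV enters raw (an option log-transforms it
first, since NPV is approximately chi-squared shaped). Power maps, when
compared as a negative control, are first subject-normalized (each subject's
map divided by its grand mean). Family-wise error across voxels is
controlled with the permutation distribution of the max-F over voxels,
separately per band — mirroring the emulated design, which could not pool
its band-wise null distributions. When `C(n, n1)` distinct relabelings fit
within the permutation budget the enumeration is exhaustive and p-values are
exact proportions; otherwise `n_perm` random relabelings are drawn and
`p = (1+b)/(1+n_perm)` avoids zero p-values.

The `extreme` (voxel, band) reported for predictor selection minimizes the
corrected p; ties — which are the rule under a strong effect, because every
sufficiently large F saturates the p-value at its resolution floor — are
broken by the larger observed F, then by voxel index and band order. Within
a band the corrected p is a monotone step function of F, so this refinement
just restores the full "most significant difference" ordering that the
p-value's discreteness hides.

## Discriminant

With one predictor, equal priors and pooled variance, the Fisher rule
reduces to a midpoint boundary: `score = w·ln(NPV) + intercept` with
`w = ±1` (positive when responders have the larger mean log NPV) and
`intercept = −w·(m₊+m₋)/2`. Natural log is the default and the base is
recorded in the model. Equal priors are kept despite unequal group sizes,
consistent with a unit-weight published rule of this form. LOOCV refits the
boundary for each held-out subject; predictor (voxel/band) selection happens
*outside* the CV loop by default, which mirrors the emulated analysis but
carries a known optimistic bias when the selection is data-driven — on null
cohorts, chance-level accuracy should be asserted at a fixed voxel, not at
the selected one.

## Synthetic cohorts

The generator produces the structure the analysis assumes, not biophysically
realistic iNPH pathology. Per subject it superposes through the shared
leadfield:

- **Effect sources** at the superomedial grid voxels (maximal z, then
  minimal |x| — the "high-convexity" stand-in, 3 midline voxels on the
  default grids): one beta carrier per subject (21.5 ± 1 Hz) modulated by
  one log-normal envelope redrawn every 1.15 s, expressed at each effect
  voxel with random orientation and phase. The envelope CV is the planted
  contrast: 0.8 for responders, 0.2 for non-responders. Sharing carrier and
  envelope across the effect voxels models a single coherent regional
  process; independent per-voxel envelopes would put the planted instability
  into the beat pattern of the leakage mixture and delocalize the effect.
- **Background**: 20 pink-noise (1/f power) dipoles at random voxels.
- **Occipital alpha**: a 10 Hz source at the most posterior voxel with a
  waxing-waning log-normal envelope (CV 0.5), the dominant eyes-closed
  rhythm.
- **Sensor noise**: white, 2 µV SD.

Dipole moments (beta 60, background 25, alpha 60 nA·m) put the simulated
scalp EEG around 10 µV RMS after average reference — the order of real
eyes-closed recordings. The log-normal envelope keeps power positive and has
closed-form CV control (`CV² = exp(σ²) − 1`); redrawing it at the 1.15-s
segment scale places the instability exactly at the resolution of the NPV
scheme. Subject seeds derive from the master seed, so cohorts are bitwise
reproducible.

What passing tests therefore show: the pipeline detects and localizes an
envelope-instability contrast of the assumed form through a known forward
model, with calibrated type-I error. What they cannot show: performance on
real patient EEG, with artifacts, individual head geometry, non-stationary
background, or effect sizes of clinical magnitude.

## Problem sizes and defaults

Test and demonstration runs use desk-scale settings chosen as the package's
own defaults: 27–81 voxel grids, 46–100-s recordings, 500 permutations, and
cohorts of 12–34 subjects. All scale linearly to the emulated protocol
(500-s epochs, thousands of voxels, 5000 permutations) through configuration
alone. Type-I calibration uses 200 null cohorts (8+8 subjects, equal
envelope CVs); planted-effect recovery uses 20 cohorts of 15 responders and
19 non-responders, matching the emulated cohort shape.

## Known limitations

- The spherical model's point-spread differs from a realistic BEM solution;
  localization claims transfer only qualitatively.
- With 19 sensors the inverse is heavily underdetermined; the planted-effect
  "extreme" voxel is occasionally (≈10% of cohorts) a grid neighbour or a
  deep voxel rather than the planted one — the F landscape is nearly flat
  across the point-spread plateau.
- EDF export quantizes to 16 bits against per-channel extrema and requires
  integer sampling rates and whole seconds of data.
- No artifact handling of any kind: inputs are assumed clean by contract.
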