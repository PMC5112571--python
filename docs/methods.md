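# Methods

This note records the models, parameter choices and numerical decisions
behind `cavimap`, and what the synthetic generators do and do not emulate.

## Cavitation-dose model

A passive cavitation detector records the acoustic emission of microbubbles
during each tone-burst pulse. Three spectral signatures are quantified from
the one-sided amplitude spectrum of each pulse, restricted to the
1.25–5.00 MHz analysis band (for excitation frequency f = 0.5 MHz this band
contains harmonics n·f for n = 3…10 and ultraharmonics (m/2)·f for odd
m = 5…19, and excludes the fundamental and its strong low-order components):

- **Harmonic level (dSCDh).** For each order n, the maximum spectral
  amplitude within a 20 kHz band centred on n·f is taken; the level is the
  time-domain RMS of a signal containing exactly those tones,
  `sqrt(Σ_n A_n²)/√2`. A single tone of amplitude A therefore yields
  A/√2, the RMS of a sinusoid.
- **Ultraharmonic level (dSCDu).** Identical, over the (m/2)·f bands.
- **Broadband level (dICD).** The spectrum is notched — 360 kHz total
  width around every harmonic and 100 kHz around every ultraharmonic — and
  the level is the RMS of the remaining band content, evaluated in the
  frequency domain via Parseval (`sqrt(Σ A_k²/2)` over retained bins).
  Inverse-transforming and taking the time-domain RMS would give the same
  number; the frequency-domain form is simpler and deterministic. With the
  default band plan the notches tile almost the whole analysis band,
  leaving fifteen 20 kHz islands (300 kHz in total) that sample the
  broadband floor.

Whole-sonication doses are plain sums of per-pulse levels (units:
volt·pulses; no absolute pressure calibration is attempted). When a
pre-injection control sonication is supplied, its mean per-pulse level is
subtracted from every pulse per channel and the result floored at zero
(negative cavitation is non-physical); the subtraction is per-pulse rather
than on the summed dose so that the floor acts before aggregation.

Numerical choices: a rectangular window over the full pulse (maximal
frequency resolution; leakage is negligible for ≥ 10 ms pulses and the
peak-picking filter is insensitive to it); a required frequency resolution
of ≤ 5 kHz so each 20 kHz search band holds ≥ 4 bins; a 1 mHz guard on
band-edge comparisons so bins on an exact edge classify deterministically.
All-zero pulses are valid input (zero spectrum, zero levels); non-finite
samples are rejected.

## Synthetic PCD generator

Each generated pulse is a sum of harmonic and ultraharmonic sinusoids at
configurable amplitudes plus white Gaussian noise of configurable RMS, with
phases drawn per component per pulse from a seeded PCG64 generator (random
phases avoid coherent artifacts across pulses; white noise is the simplest
broadband null with flat band occupancy). An optional sinusoidal envelope
across pulses emulates the breathing-rate periodicity seen when large
vessels sit in the focus. Pressure ramps scale the per-channel amplitudes
with built-in response shapes — `linear`, `plateau` (saturating, as stable
cavitation behaves at high pressure) and `threshold` (onset behaviour) —
over a strictly increasing pressure list, one deterministic sub-seed per
step. The generator does **not** simulate bubble dynamics
(Rayleigh–Plesset or FEM), transducer/skull transfer functions, or
frequency-dependent attenuation: passing tests demonstrate the
correctness of the quantification chain, not the realism of in-vivo
spectra.

## Relaxometry

The SPGR steady-state signal `S = M0 sin α (1−E1)/(1−E1 cos α)`,
`E1 = exp(−TR/T1)`, is linearized as `S/sin α = E1 · S/tan α + M0(1−E1)`
and fit per voxel by unweighted least squares across flip angles (the
standard DESPOT1 line fit; weighting schemes exist but the unweighted fit
is the classical method and unbiased at the SNRs considered). Voxels with
slope outside (0, 1), fitted T1 outside (1, 10000) ms, or a degenerate
design are flagged invalid and propagate as NaN — never as silent zeros.
R² of the line fit is returned as a per-voxel quality map.

Concentration maps use the fast-exchange relaxivity relation
`[Gd] = (1/T1 − 1/T1,0)/r1` with rates in s⁻¹ and r1 = 4 s⁻¹mM⁻¹
(gadodiamide). Negative concentrations — noise can push T1 above T1,0 —
are clamped to zero and counted.

Tissue segmentation thresholds pre-contrast T1 with half-open intervals
(lo, hi]: blood (1, 700] ms, white (700, 1170] ms, gray (1170, 1800] ms,
CSF (1800, 5000] ms. The exclusive lower bound prevents double assignment
at interval boundaries; values outside (1, 5000] ms are left unassigned.
Thresholds are configurable for per-subject recalibration.

## Opening volumetry and delivery

Enhancement is the voxelwise post/pre T1-weighted ratio, linearly rescaled
so the mean over an unsonicated deep-tissue reference ("thalamus") maps to
0 and the mean over an intravascular reference (ACA) maps to 1. The sham
cohort's enhancement is subtracted, the brain mask applied, and voxels
with residual normalized enhancement above a cutoff are counted inside the
ipsilateral VOI (default 10 × 10 × 32.5 mm³, centred on the planned
target); the mirror-image contralateral VOI's above-cutoff volume is
subtracted (aggregate, not voxelwise — the contralateral side estimates
the background rate) and the result floored at zero. The mid-sagittal
mirror plane is configuration (`x = 0` for the phantoms); registration to
a stereotactic frame is out of scope. An opening is *significant* when the
volume exceeds 80 mm³ (the sham-cohort mean + 3 SD); this total-volume
threshold is distinct from the voxelwise cutoff.

The voxelwise cutoff defaults to 0 (any residual enhancement). For
quantitative recovery at realistic noise the analysis workflows use a
cutoff of 0.7 on the normalized scale together with a connected-component
floor of 10 voxels (face connectivity): under the phantom's default
contrast the opened tissue sits at ≈ 1.3–1.6 normalized units while the
sham-subtracted noise floor at SNR 50 has σ ≈ 0.3–0.4, so 0.7 separates
the two, and isolated supra-cutoff noise voxels — spatially incoherent,
unlike a contiguous opening — are removed by the cluster floor. Both knobs
are explicit parameters.

Delivered Gd zeroes concentration voxels above the measured ACA
concentration (intravascular signal), applies the brain mask, and
integrates `[Gd]·V` (mol, with [Gd] in mol/L and V the voxel volume in
litres) over the ipsilateral minus the mirrored contralateral VOI — the
subtraction removes intrinsic parenchymal Gd retention. Efficiency is
100 × delivered / injected with a 1 mmol default injection. A uniform
0.05 mM over 300 mm³ yields 15 nmol and 0.0015 % by construction.

The per-tissue breakdown reports, for each class, the opened volume, its
share of the opening, its share of the sonicated region, and the opening
probability `|opened ∩ tissue| / |sonicated ∩ tissue|`; the gray:white
probability ratio is NaN-flagged when undefined (no opened voxels or no
white matter in the sonicated region).

## Brain phantom

The phantom is a nested-ellipsoid brain on a 96 × 96 × 64 grid at 1 mm
isotropic (desk-scale memory and runtime), mirror-symmetric about x = 0:
cortical gray shell, white interior, a mirrored pair of deep gray nuclei
standing in for the putamen/caudate targets, CSF ventricles, a z-oriented
blood vessel tube as the ACA reference, and a skull shell. Tissue T1,0
defaults (white 950, gray 1400, blood 400, CSF 3000 ms) sit inside their
segmentation intervals. Post-contrast T1 follows the forward relaxivity
model; the focal opening is an ellipsoid of uniform (default) or Gaussian
concentration with peak 0.07 mM — the highest focal concentration such
experiments report — on top of a 0.02 mM parenchymal retention background
(within the reported 0.01–0.02 mM range for unopened tissue; it also keeps
concentration noise away from the clamp-at-zero floor so the contralateral
subtraction stays unbiased) and a 0.5 mM intravascular concentration.

Rendered acquisitions: the 5-angle VFA series (TR 10 ms), T1-weighted
volumes at flip angle 8°/TR 8.5 ms, and a sham pair without focal uptake.
Noise is additive Gaussian on the magnitude (adequate approximation to
Rician at SNR ≥ 10) with σ = mean gray/white signal / SNR, default SNR 50.
Ground truth (voxelized opening volume, delivered nmol as concentration ×
volume over opening voxels, centre of mass, label maps) is computed by
direct voxel summation. The phantom does not emulate realistic
neuroanatomy, coil profiles, B1 inhomogeneity, partial-volume edges or
flow-related vessel brightening; recovery results demonstrate pipeline
correctness under the stated noise model, not in-vivo performance. Because
SPGR at these settings gives short-T1 blood only modest enhancement, the
vessel reference's normalized contrast is weaker than the flow-enhanced
ACA of real scans — one more reason the enhancement cutoff is exposed as a
parameter.

The targeting phantom is a spherical skull shell (default radii
30/34 mm) with a cylindrical opening of known axis placed at a known
offset from the planned focus; entry points, normals, incidence angles and
shift decompositions are available in closed form for validation.

## Targeting geometry

Surface normals are the normalized negative gradient of the Gaussian-
smoothed binary skull mask, trilinearly interpolated at the query point.
Smoothing σ defaults to 2.5 voxels: on voxelized spheres at 1 mm, σ = 1
leaves ~5° of lattice-anisotropy error in the gradient direction while
σ = 2.5 brings the full-pipeline incidence error under ~2°, still local
relative to a skull shell. Outer vs inner surfaces are distinguished by
labelling the background: components touching the volume border are
exterior, enclosed components are cavities; for open geometries (slab
phantoms) with no cavity, both faces border the exterior and the query
point selects the face. The beam entry point is the first
trajectory–skull crossing marching from the transducer side in
quarter-voxel steps with trilinear mask interpolation. Angles are
`arccos |u·v|` of unit vectors — absolute acute angles, since reported
incidence/refraction angles carry no sign convention.

The opening vector is the principal axis of the per-slice 2-D centres of
mass (slices along the third grid axis by convention, configurable),
oriented toward increasing slice index. Slices with cross-sectional area
below 0.9 × the median are dropped before the fit: the obliquely truncated
end slices of a tilted opening pull their centre of mass off the true axis
and otherwise bias the direction by several degrees. With fewer than two
nonempty slices the direction is flagged undefined; the centre of mass is
always reported.

## Statistics

Outcome–dose association uses ordinary least squares of the outcome
(opening volume, delivered nmol, or efficiency %) on the total cavitation
dose, reporting slope, intercept, R², the two-sided slope p-value and the
slope standard error, pooled and per subject (subjects with ≥ 3 usable
records). Sham and calibration records are excluded by default
(configurable). Group comparison is the two-sample pooled-variance
Student's t-test (not Welch — the classical test is the one this analysis
family reports), two-tailed, α = 0.05. No multiple-testing correction is
applied, matching the analysis surface this package reproduces.

## Problem sizes and determinism

Test and acceptance workloads are sized for interactive runs: 4096-sample
pulses at 12.8 MHz for spectral unit tests (the band plan is unchanged;
only the record length shrinks), full 10 ms/50 MHz pulses for the ramp
checks, 96 × 96 × 64 phantoms with 3 replicates for recovery estimates,
10⁴ voxels for the noisy-T1 median, 100 replicates for slope coverage and
2000 for the null rejection rate. Every stochastic step draws from an
explicit seed; fixed seeds give bit-identical phantoms and pulse trains.

## Known limitations

- Frequency-domain RMS assumes the filter definition above; a time-domain
  filtered-signal RMS would differ only through windowing.
- The delivered-Gd estimate inherits an irreducible fluctuation from VOI
  background noise (≈ 3 % SD at SNR 50 for a 30 nmol opening); replicate
  averaging is used where a tight estimate is needed.
- B1 inhomogeneity, registration error and brain extraction are out of
  scope; inputs are assumed co-registered with masks supplied.
- The enhancement cutoff and cluster floor are analysis parameters; the
  defaults documented here were chosen against the phantom's known
  contrast and noise model and should be recalibrated for other
  acquisition settings.
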