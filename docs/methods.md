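# Methods

This note documents the models, conventions and design choices behind
`canalqsm`, in the spirit of the methods documentation of packages such as
statsmodels or msprime: what is computed, under which assumptions, with which
defaults, and what the synthetic validation does and does not show.

## Signal model and conventions

All volumes are 3-D arrays indexed `(x, y, z)`; B₀ defaults to `+z` but is
carried as a unit vector in image axes, so oblique orientations only rotate
the kernel argument (`k_z → k·b̂₀`).  All spectral operations use the centered
FFT (DC at index `⌊N/2⌋` on each axis); every kernel is built on the same
centered grid — mixing centering conventions is the classic QSM bug, so the
convention is fixed package-wide and asserted in tests.

Field perturbations and susceptibilities are in ppm.  A relative field shift
`δ` (ppm) accumulates GRE phase

    φ = s · 2π f₀ TE · δ·10⁻⁶,      f₀ = (γ/2π) B₀,

with `γ/2π = 42.577 MHz/T`.  The sign `s` is a vendor convention; the package
default is `s = −1`, chosen so a paramagnetic inclusion shows *negative*
phase on its dipole lobes along B₀ — the appearance of cartilage canals in
ex vivo GRE data.  At 9.4 T and TE 15 ms, 1 ppm ↔ 37.7 rad.

## Phantom generator

The generator emulates an ex vivo epiphyseal-cartilage specimen filling the
field of view and is the package's study condition: a proton-signal tissue
volume threaded by thin paramagnetic cylinders ("canals").  Defaults:

| parameter | default | rationale |
|---|---|---|
| grid | 96³ voxels, 100 µm isotropic | the 9.4 T protocol resolution; 96³ keeps a full pipeline run in seconds |
| B₀, TE | 9.4 T, 15 ms | the ex vivo protocol |
| canal radius | 0.2 mm | mid-range of reported canal diameters (0.2–0.6 mm) |
| canal Δχ | +0.06 ppm | center of the reported +0.05…+0.07 ppm range |
| canal magnitude factor | 0.8 | canals are mildly dark in plain GRE; see below |
| tissue texture | multiplicative, relative SD 0.08, correlation length 1.6 mm | real cartilage is not uniform; a perfectly flat tissue makes the `x̄−4σ` segmentation rule degenerate (σ→0) |
| background field | low-order harmonic polynomial, ~0.3 ppm across the FOV | emulates external sources that SHARP must remove; harmonic by construction |
| noise | complex Gaussian, SD 0 or 0.05 of tissue signal (SNR 20) | noiseless for oracles, SNR 20 for robustness checks |

The forward model is the k-space dipole convolution `Δ̂B = D·χ̂` with
`D(k) = 1/3 − (k·b̂₀)²/K²` and `D(DC) = 0`: the absolute susceptibility
offset is unobservable, so all susceptibilities are relative to the tissue
mean.  The convolution is periodic (plain FFT); inclusions are therefore kept
at least 25 % of the FOV away from the lateral volume edges and the forward
model is validated only in the interior, where it matches the closed-form
infinite-cylinder fields (interior `Δχ(3cos²θ−1)/6`; exterior
`(Δχ/2)sin²θ (a/ρ)² cos2φ`) to within a few percent.

**Canal magnitude factor.**  The intrinsic GRE darkness of a canal is not a
quantity the source data constrain; what *is* constrained is the contrast
ordering — plain GRE depicts the canals with less definition than SWI, and
the splitting artifact is a *phase-mask* artifact.  A factor of 0.5 makes the
magnitude trough so deep that it swallows the phase-lobe darkening and no
method "splits"; 0.8 keeps the GRE contrast weakest, reproducing the observed
ordering (QSM-WI ≥ SWI ≥ GRE).  The value is a free generator parameter,
exposed in `PhantomSpec`.

Cylinders are infinite (they span the volume along their axis); there is no
vessel-lumen substructure, T2* decay, flow, or chemical shift.  Rasterization
antialiases inclusion surfaces by a linear partial-volume ramp one voxel
wide (exact binary occupancy is available via a flag).

## Segmentation

Box smoothing (default 7³, nearest-edge replication so edge means are not
depressed), threshold at `x̄ − 4σ` of the smoothed signal inside a coarse
seed ROI (inclusive `≥`, so exact-threshold voxels survive), then
six-connected erosion (default once).  The criterion for the optional second
erosion is operationalized as: erode again (max twice) if the eroded mask
still touches the volume boundary; the event is logged.  An externally
supplied (manual) mask can be substituted and is then only smoothed/eroded.
On a *noiseless* uniform phantom the rule is degenerate (σ = 0 ⇒ threshold =
x̄), which is why the demo pipeline defaults to the supplied-mask path for
synthetic data; the automatic path is validated on textured phantoms, where
it recovers ≥ 90 % of the true tissue support.

## SWI

The homodyne reference is the inverse transform of the centrally windowed
k-space; the window is separable ("per dimension"), of fractional width ½
(ex vivo default) or ¼, Hann-tapered by default (boxcar available).  The
window width is forced odd so it is symmetric about the DC index — an
asymmetric window imparts a spurious phase to the reference.  The filtered
phase `∠(original·conj(reference))` feeds a linear negative phase mask
(`m = (φ+π)/π` for `φ < 0`, else 1; positive polarity is the mirror image)
which multiplies the magnitude `mask_power` = 4 times.  Voxels where the
reference magnitude vanishes get phase 0 and are counted in the log.

## QSM

**Laplacian unwrapping** computes `∇²φ_true = cos φ ∇² sin φ − sin φ ∇² cos φ`
and inverts the Laplacian spectrally.  Both operators are realized in the
DCT-II basis (even-symmetric/Neumann boundaries) rather than the periodic
FFT: wrapped non-periodic fields (e.g. a background ramp) then unwrap cleanly
— a 6π wrapped ramp is recovered with interior slope error < 1 %, where the
periodic variant would return zero.  The inverse Laplacian's DC is undefined
and set to zero; the output is the true phase up to an additive harmonic
component, which SHARP removes next.

**SHARP.**  The spherical-mean-value operator `ρ = δ − S` (S a normalized
sphere, default diameter 9 voxels ⇒ 0.9 mm at 100 µm voxels) annihilates
harmonic functions.  The masked unwrapped phase is convolved with ρ, the
result restricted to the reliability mask (input mask eroded by the kernel
radius), and deconvolved in k-space where `|ρ̂| ≥` the truncation (0.5
default; components below it are zeroed — the convention of the reference
implementations; clamping is available as a flag).  Truncation 0.5 follows
the visualization-optimized processing; 0.05 (the reference-code default) is
used for quantitative recovery, where the heavy setting would bias canal
means.

**TKD.**  The local phase is converted to ppm and divided by the dipole
kernel with the inverse capped: `g = sign(1/D)·min(|1/D|, t)`.  The cap floor
is `min|1/D| = 3/2` (attained where `|D| = 2/3`, i.e. k ∥ B₀); for `t < 1.5`
the filter saturates to `±t` everywhere, which changes overall scaling but
not artifact structure.  On the magic-angle cone (`D = 0` exactly, a
measure-zero grid coincidence) the sign is taken from the high-|k·b̂₀| side
(negative).  `g(DC) = 0`; the output is the real part, zero-meaned over the
valid mask.  Defaults: t = 1.5 for visualization; t = 10 for quantitative
estimates, where the sweep has plateaued.  TKD underestimates systematically
(≈ 15 % at t = 10 on the fixture); no post-hoc underestimation correction is
applied.

## QSM-WI

Canal statistics (mean, population SD in ppm) are taken over a canal-only
ROI.  The weighting mask passes `χ ≤ mean − k_low·SD` (k_low = 2) at full
weight and ramps linearly to zero at `mean + k_high·SD`; the upper anchor is
this package's choice (k_high = 2 by default) — only the lower anchor is
externally specified, and the choice of upper anchor merely rescales mid-ramp
weights.  The mask multiplies the magnitude 4×.  The canal ROI matters: it
must be canal-core (the seeded, thresholded ROI below), because including
partial-volume edge voxels inflates the SD until `mean − 2·SD` falls below
the background level and the entire background lands mid-ramp.

## Analysis instruments

*Canal ROI*: voxels with `χ ≥ mean(seed) − 1·SD(seed)`, keeping only
26-connected components that intersect the seed.  The component retention is
a reproducible surrogate for an operator's manual exclusion of non-canal
areas; it is logged and does not claim to replicate the operator.  On the
fixture it overlaps the true canal support with Dice ≥ 0.5.

*Truncation sweep*: TKD re-run per t over a fixed ROI; records mean/SD,
64-bin histograms over [−0.1, +0.2] ppm (covering the expected canal range
with margin; values outside are clipped into the edge bins so counts conserve
the ROI size), and the background SD (streak energy) over the valid mask
outside the ROI.

*Slab projections*: the volume is partitioned into consecutive slabs along
the plane normal (axial ⊥ B₀ = z); per-pixel min or max; slab voxel count =
`round(thickness/voxel size)`, remainder slab kept and flagged.  Plane names
refer to the array axes with B₀ along +z.

*Splitting profile*: a line across the vessel image is smoothed with a
3-point mean and strict local minima deeper than `mean − 0.5·SD` of the
profile are counted — one minimum for a cleanly imaged vessel, two or more
for the split appearance.  Note a single-voxel notch is flattened by the
3-point mean by design; sub-voxel features are below the instrument's
resolution.

## Numerical choices and degenerate inputs

- FFT round-trip and Parseval are exact to < 1e−10 / 1e−8 relative error.
- Non-finite voxels are rejected at write time (count reported); empty ROIs,
  empty erosion results and masks smaller than the SHARP kernel are hard
  errors with actionable messages.
- Phase is rewrapped to (−π, π] on every read; phase stored in [0, 2π) is
  supported via an explicit dialect flag, never auto-detected.
- All generators are pure functions of their spec including the RNG seed;
  fixed seeds give bit-identical volumes.

## What the synthetic validation shows — and does not

The phantom suite demonstrates that the *processing chain* reproduces the
artifact physics: SWI splits a perpendicular canal along B₀ (two profile
minima), QSM and QSM-WI localize it correctly (one minimum, centered within
one voxel of the true axis), canal susceptibility estimates rise and plateau
with the TKD truncation while streaking grows, and a 0.06 ppm canal is
recovered within 20 % at t = 10 with ≤ 25 % spread across orientations.  It
does not validate performance on real tissue: actual specimens add B₁⁺
inhomogeneity, coil combination effects, non-harmonic chemical-shift
backgrounds, curved and branching vessels, sub-voxel lumina and T2*
decay, none of which the generator models.  Problem sizes (96³) were chosen
as the smallest grids that keep the canals several voxels thick with
generous guard bands; results were also exercised at 64³ in unit tests.
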