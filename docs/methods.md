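# Methods

`fidsnav` simulates a navigated multi-echo gradient-echo (GRE) brain
acquisition end to end and implements the estimation chain that makes
prospective motion correction (PMC) and retrospective field correction
possible from navigator data alone: a free-induction-decay (FID) readout
for per-channel zeroth-order field shifts and a two-hemisphere spherical
k-space navigator (SNAV) for rigid motion. This note records the models,
the parameters that matter, and the design choices taken where more than
one reasonable option existed.

## Coordinate and Fourier conventions

Axes follow head-first supine convention: x right–left, y
posteroanterior, z superoinferior. Rotations are **extrinsic, applied in
the order x → y → z** about the volume centre (`R = Rz Ry Rx`); angles in
degrees, translations in mm. This order is stated prominently because
nothing in the estimation chain works if producer and consumer disagree
on it.

Image coordinates are voxel centres in cm with index `n//2` at the
origin; k-space is in cycles/cm with the Cartesian grid at
`m/(N·Δ)`. The forward transform is `S(k) = Σ_x v(x) e^{-i2πk·x}`, so a
posed object obeys

```
F{posed}(k) = exp(-i 2π k·Δr) · F{ρ}(Rᵀ k)
```

— rotations rotate k-space, translations add a phase ramp. All
estimators are built on this identity, and the simulator honours it
exactly: off-grid (rotated) k-points are evaluated by **direct-summation
non-uniform DFT** over the masked voxels rather than by image-domain
regridding, so the Fourier identities hold to working precision and
estimator errors cannot be confounded with interpolation artifacts. A
single-precision fast path (fused polynomial sin/cos, absolute error
~4e-6, with BLAS accumulation) makes this affordable at desk scale; the
double-precision reference path remains the default for machine-precision
tests.

## Acquisition model

Protocol defaults: TR 51 ms; ten echoes at TE 3.28–45.40 ms; flip 15°
(a global scale only — steady-state and spin-history effects are not
modelled); one navigator (two TRs, one shell hemisphere each) every
eight imaging k-space lines, giving a motion-update rate of
`1/((8+2)·TR) = 1.96 Hz`; phase-encode ordering is linear so the scan
midpoint coincides with central k-space.

Each imaging sample is the exact Fourier value of the coil-weighted,
relaxation- and off-resonance-evolved phantom at the Cartesian k-point
remapped by the prospective transform (rotation of the sampled k-vector,
conjugate phase ramp for translation). Per-channel zeroth-order field
shifts enter as `exp(i2π·Δf₀·t)` across the readout with `t` measured
from excitation. Within-readout R2* decay uses the echo-centre TE (the
readout is under 1 ms; the approximation is far below the effects under
study). Fat voxels are modulated by the same six-peak spectrum the
mapping stage fits (below), so quantitative recovery is exact by
construction — deliberately: the package tests the *correction chain*,
not spectral-model mismatch.

The coil-weighted phantom is posed as a whole (sensitivities ride along
with the head). Real receive profiles are fixed in the scanner frame;
motion-induced sensitivity change is a known residual-error source in
PMC and is intentionally out of scope here.

Prospective correction is emulated with a controller callback. Each
completed navigator is processed with a configurable latency (default
22 ms); the FOV for each imaging TR uses the latest estimate available
10 ms (margin time) before that TR, so an estimate first applies to the
TR after its navigator. Controller failures hold the last value. Feeding
the controller ground-truth poses reproduces the static acquisition
line by line to machine precision — the hard upper bound on achievable
correction, asserted in the tests.

## Navigator signals

The FID is the k = 0 readout: 64 points at 10 μs dwell starting 200 μs
after excitation. In this model a rigid pose moves all voxel attributes
together, so the FID is exactly pose-invariant and a uniform field shift
is exactly a phase ramp — field and motion estimation decouple, which the
tests assert directly.

The SNAV samples a spherical shell (default radius 0.4 cycles/cm — not a
published value; chosen so that shell features are well resolved by the
head-sized object, and configurable) as two mirrored hemispheres of 8
latitude rings × 60 uniform longitudes (960 points). Sixty longitudes
rather than a sparser ring are used because the squared-magnitude signal
along a ring is nearly band-limited at the object radius and the lookup
table resamples rings in longitude; 60 samples leave headroom so that
FFT-based circular fractional shifts (exact for band-limited rings) do
not alias. A single nominal sample time (3 ms) carries the navigator's
B0 phase, matching the single zeroth-order correction applied per
navigator; intra-navigator phase evolution is deliberately not modelled.

## Estimation chain

Per navigator, in fixed order:

1. **Field**: each channel's FID is divided pointwise by the reference
   FID (the eighth navigator of the scan; estimates before it are 0 Hz
   by definition). The ratio cancels static phase — including the
   eddy-current-like static per-channel offsets the simulator can
   inject — and object evolution. The first 15 points are discarded,
   the remaining phase unwrapped and fitted by least squares;
   `Δf₀ = slope/2π`. Reference samples with zero magnitude are excluded;
   fewer than 8 usable points invalidates the estimate.
2. **SNAV phase correction**: multiply channel c by
   `exp(-i2π·Δf₀,c·t_nav)`; magnitudes untouched.
3. **Rotation**: argmin over a lookup table of expected channel-combined
   (root-sum-of-squares) shell magnitudes for rotations in [-6°, 6°] at
   0.25°. The table interpolates the measured baseline grid — 13 × 13
   trajectory rotations about kx, ky at 1° — bilinearly across (θx, θy)
   and by periodic longitude resampling for θz ("simulation by
   interpolation"); measured nodes reproduce their baselines exactly.
   Search is coarse-to-fine (1° exhaustive, then ±1° at 0.25°), verified
   in tests to equal the exhaustive 49³ argmin on noiseless data. Ties
   break toward smaller total rotation, then lexicographically; an
   argmin on the ±6° boundary sets an out-of-range flag. Baseline
   trajectory rotation composes as `Rx(θx)·Ry(θy)·Rz(θz)`, the transpose
   of the head rotation, so grid angles map to head angles by negation.
4. **Translation**: the complex baseline is interpolated at the
   estimated rotation (bilinear in (θx, θy), longitude-resampled in θz)
   and the channel-combined phase difference — unwrapped along each
   ring with ring-to-ring continuity — is fitted by weighted least
   squares (magnitude-squared weights, plus an intercept absorbing any
   residual global phase) to `Δφ = -2π k·Δr`. Sign convention: a +x
   object shift yields +tx. A weighted RMS phase residual above 0.5 rad
   flags the estimate low-confidence; the controller then holds the
   last good value.

The channel combination for rotation matching (RSS) and the
interpolated-complex-baseline reference for translation are package
choices, isolated behind single functions.

## Retrospective B0 correction and reconstruction

Each raw line is corrected per channel with
`S·exp(-i2π·Δf₀,coil·t)` using the estimate from the nearest navigator
in time; `t = TE + (sample − centre)·dwell`. This is an exact group
action on k-space (identity, inverse, composition at machine precision —
tested). Reconstruction is the centred inverse FFT per channel and echo;
magnitude combines by root-sum-of-squares, phase by conjugate-sensitivity
weighting with the known simulated profiles (a stand-in for calibrated
sensitivities, which are out of scope).

## Quantitative mapping

Voxel signal model, with the six-peak fat spectrum (relative amplitudes
0.087/0.693/0.128/0.004/0.039/0.048 at −3.80/−3.40/−2.60/−1.94/−0.39/
+0.60 ppm, 127.7 MHz centre frequency; configurable):

```
S(TE) = (W + F·Σₚ aₚ e^{i2πfₚTE}) · e^{i2πψTE} · e^{-R2*·TE}
```

**FF** comes from complex fitting of the first five echoes (all
TE < 10 ms): all masked voxels are fitted simultaneously by vectorised
variable projection (W, F ≥ 0 solve a linear subproblem; ψ, R2* ≥ 0 take
damped Gauss–Newton steps). The ψ landscape is multimodal — the dominant
fat peak aliases the naive two-echo phase estimate for fat-rich
voxels — so a coarse VARPRO grid over ±600 Hz seeds two refinements (best
basin, and best basin at least 100 Hz away, the swapped water–fat
assignment); the lower final cost wins. FF = F/(W+F) with 0/0 → 0;
voxels whose residual exceeds 1e-3 of the signal norm fall back to a
magnitude-ratio FF and are flagged NaN in the residual map.

**R2*** is then fitted to the magnitude of the same model over all ten
echoes with FF fixed (and ψ reused from the complex stage, where it is
magnitude-irrelevant): a weighted log-linear solve — the closed-form
mono-exponential fit when FF = 0 — followed by vectorised Gauss–Newton
refinement on the magnitude residuals.

## Phantom, trajectories, and noise

The digital head is a stack of nested ellipsoids on a 64 × 64 × 48 grid
at 2 mm (≈12.8 cm FOV): a scalp-fat rim (FF 0.9, R2* 40 s⁻¹), a signal
void for skull, a GM-like shell (15 s⁻¹), a WM-like core (20 s⁻¹),
off-centre iron-rich nuclei (50 s⁻¹) breaking rotational symmetry, and a
frontal off-resonance wedge (+12 Hz). Parameter maps are smoothed by a
1-voxel Gaussian so shell magnitudes vary smoothly with rotation — the
property the 1° baseline grid interpolation needs. Everything is a pure
function of (config, seed).

Motion trajectories are scripted (none / drift / steps / mixed);
amplitudes above the ±6° detectable range warn rather than fail. Field
trajectories couple to motion per channel:
`Δf₀[t,c] = coupling · g_c · |rotation(t)|` with gains `g_c ~ U(-1,1)`
drawn once per seed — reproducing the observation that shifts differ
strongly between channels without modelling susceptibility physics. The
magnitude distribution of real per-channel shifts is not characterised
anywhere authoritative; the default coupling of 1.5 Hz/deg yields
shifts of a few Hz for moderate motion, the range over which the late
echoes (TE ≈ 30–45 ms) accumulate ~1 rad of phase error.

Noise, when requested, is a single complex receiver noise level per
channel applied to every raw sample, parameterised by the reconstructed
image SNR (`fidsnav.noise`). Because k = 0 navigator samples integrate
the whole volume, their per-sample SNR is orders of magnitude above the
image SNR (~10⁴ vs 50 at the default phantom) — which is precisely why
FID phase fitting over a 0.49 ms window can resolve sub-0.1 Hz shifts
at ordinary imaging SNR, and why a hypothetical per-sample SNR of 50 on
the FID itself could not (the phase-slope Cramér–Rao bound is then
several Hz).

## The four-arm experiment

`run_experiment` mirrors the study design at desk scale: a static
reference acquisition, then (1) a no-motion repetition, (2) motion
without correction, (3) motion with PMC, reconstructed (4) with and
without retrospective B0 correction — arms 3 and 4 share one
acquisition, as prospective correction happens during the scan and the
field correction afterwards. All motion arms share the same trajectories.
Outputs are echo-wise SSIM/NRMSE tables against the reference, FF/R2*
mean-absolute-error tables, and midpoint-referenced RMS motion scores
(total displacement `‖Δt‖ + 2R·sin(Δθ/2)`, R = 64 mm head radius,
configurable; the exact published formula for this score is not
reproduced anywhere accessible, so the chord form is adopted and
documented). NRMSE is normalised by the reference intensity range within
the mask (switchable in principle; recorded here because range
normalisation is sensitive to low-spatial-frequency intensity changes).

The default experiment grid is 32 × 32 × 24 at 4 mm — the same physical
head in coarser voxels — with 8 channels, mixed drift+step motion up to
3°/2 mm starting after a quiet lead-in (25% of the scan, safely after
the eighth-navigator reference), and 1.5 Hz/deg field coupling. These
sizes keep a full four-arm run with per-voxel map fitting in the
minutes range; the estimator-recovery studies run on the full 64-scale
phantom. Simulation uses the single-precision path for the experiment
and the recovery studies, double precision wherever a test asserts
machine-precision identities.

## What passing does and does not show

The simulation is noiseless by default, the fat spectrum and coil
profiles are known exactly, the phantom is rigid, and navigators see the
same forward model as the imaging readout. Passing therefore shows that
the estimation chain, the prospective-update contract, and the
correction algebra are implemented correctly and that the corrections
recover image and map fidelity under the modelled physics. It does not
show robustness to spin-history effects, nonrigid motion (ears, jaw),
motion-induced coil-sensitivity change, higher-order spatial field
perturbations, eddy-current dynamics beyond a static per-channel phase,
or flow — all deliberately outside the model. Rotations beyond ±6° are
flagged, not recovered, matching the detectable range of the
baseline-grid design.
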