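# fidsnav

Simulation and estimation toolkit for navigator-based prospective motion
correction (PMC) of multi-echo gradient-echo (GRE) brain MRI, with
channel-wise retrospective B0 correction and downstream R2* / fat-fraction
(FF) mapping.

Quantitative GRE applications — R2* relaxometry, fat–water separation,
susceptibility-weighted methods — are acutely motion sensitive, and at the
long echo times they require, motion-induced *field* fluctuations corrupt
images even when the head pose is tracked perfectly. This package
implements, on a fully simulated acquisition of a digital head phantom,
the navigator design that addresses both at once: every eight k-space
lines, a two-TR navigator acquires a 64-point FID (k = 0 readout) followed
by a spherical k-space shell (SNAV) per hemisphere. It is written for MRI
methods researchers who want a controlled, fully inspectable testbed for
this estimation chain — every physical quantity in the simulation has
known ground truth.

The physics rests on two Fourier identities for a rigid pose
`(R, Δr)` of the object ρ:

```
F{posed}(k) = exp(-i 2π k·Δr) · F{ρ}(Rᵀ k)
```

so rotation rotates the shell signal's magnitude pattern on the sphere
(matched against a lookup table of pre-rotated baselines, [-6°, 6°] at
0.25°) and translation adds a phase ramp (fitted by weighted least
squares after unwrapping); and for a spatially uniform field shift Δf₀

```
S_corr(k) = S(k) · exp(-i 2π Δf₀,coil · t),   t = time after excitation
```

estimated per receive channel from the phase slope of the FID against a
reference navigator, applied forward (to correct navigators and raw
k-space lines) or in reverse (by the simulator, to corrupt them). The
acquisition loop emulates the real-time contract: estimates become
available after a processing latency and steer the field of view of
subsequent TRs; a controller fed ground truth reproduces a static scan to
machine precision.

## Worked example

Estimate a pose from a single simulated navigator:

```python
import numpy as np
from fidsnav import (ProtocolConfig, RigidTransform, acquire_baselines,
                     build_lookup_table, estimate_rotation, estimate_translation,
                     make_coil_profiles, make_phantom, make_snav_trajectory,
                     simulate_snav, scan_timing)
from fidsnav.estimation import combine_channels_magnitude

phantom = make_phantom(grid_shape=(32, 32, 24), voxel_size_mm=(4, 4, 4))
coils = make_coil_profiles(8, phantom, seed=0)
protocol = ProtocolConfig(grid_shape=phantom.grid_shape,
                          voxel_size_mm=phantom.voxel_size_mm)
trajectory = make_snav_trajectory()

baselines = acquire_baselines(phantom, coils, protocol, trajectory,
                              dtype=np.complex64)
lookup = build_lookup_table(baselines)

true_pose = RigidTransform(rot_deg=(2.0, -3.0, 1.5), trans_mm=(1.2, -0.8, 0.5))
snav = simulate_snav(phantom, coils, true_pose, trajectory=trajectory,
                     dtype=np.complex64)
rot, residual, out_of_range = estimate_rotation(
    combine_channels_magnitude(snav), lookup)
trans, phase_residual, _ = estimate_translation(snav, baselines, trajectory, rot)
print(f"estimated rotation (deg): {np.round(rot, 2)}")
print(f"estimated translation (mm): {np.round(trans, 3)}")

timing = scan_timing(ProtocolConfig(), base_scan_s=607, reference_scan_s=17,
                     dummy_s=7)
print(f"navigator rate: {timing['nav_update_frequency_hz']:.2f} Hz, "
      f"added time {timing['added_time_mmss']}, "
      f"overhead {100 * timing['relative_increase']:.1f}%")
```

prints

```
estimated rotation (deg): [ 2.  -3.   1.5]
estimated translation (mm): [ 1.2 -0.8  0.5]
navigator rate: 1.96 Hz, added time 2:32, overhead 29.0%
```

The rotation lands on the 0.25° lookup grid at the true pose; the
translation is recovered to well under 0.05 mm; and interleaving a 2-TR
navigator every 8 imaging TRs of a 51 ms-TR protocol yields a 1.96 Hz
update rate at a 29% scan-time overhead (navigation plus reference scan
and dummy time on a 10:07 base scan).

The four-arm experiment — static reference, no-motion repeat, motion
uncorrected, motion + PMC reconstructed with and without B0
correction — runs from the command line:

```
fidsnav experiment --seed 0 --out report/
```

writing echo-wise SSIM/NRMSE tables, FF and R2* mean-absolute-error
tables, and RMS motion scores. On the default moderate-motion scenario
the orderings mirror what matters clinically: PMC alone restores
early-echo image quality, while the late echoes and the R2* map need the
additional field correction (e.g. R2* MAE ≈ 1.10 s⁻¹ uncorrected →
0.40 s⁻¹ with PMC → 0.17 s⁻¹ with PMC + B0 correction at seed 0).

`fidsnav timing`, `fidsnav phantom` and `fidsnav motion` expose the
timing arithmetic, phantom NIfTI export and trajectory CSV generation.

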