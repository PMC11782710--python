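"""Motion scoring and image/map quality metrics.

The RMS motion score summarises a trajectory as the root-mean-square over
time of total head displacement relative to the pose at the scan midpoint
(which coincides with central k-space under linear phase-encode
ordering).  Total displacement maps rotation onto a head-sized sphere:

    d(t) = ||delta_translation|| + 2 R sin(delta_angle / 2),  R = 64 mm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity

from .phantom import MotionTrajectory
from .transforms import relative_transform


@dataclass
class MotionScore:
    rms_mm: float
    displacement_mm: np.ndarray  # per-timepoint total displacement
    reference_index: int


def rms_motion_score(traj: MotionTrajectory, head_radius_mm: float = 64.0) -> MotionScore:
    """Midpoint-referenced RMS of total displacement (mm)."""
    n = len(traj.transforms)
    if n < 2:
        raise ValueError("need at least 2 timepoints")
    ref_idx = n // 2
    ref = traj.transforms[ref_idx]
    disp = np.empty(n)
    for i, t in enumerate(traj.transforms):
        if np.array_equal(t.params, ref.params):
            disp[i] = 0.0  # exact zero for identical poses
            continue
        rel = relative_transform(t, ref)
        dtrans = float(np.linalg.norm(rel.trans_mm))
        dang = np.radians(rel.rotation_angle_deg())
        disp[i] = dtrans + 2.0 * head_radius_mm * np.sin(dang / 2.0)
    return MotionScore(float(np.sqrt(np.mean(disp**2))), disp, ref_idx)


def image_metrics(test_volume: np.ndarray, ref_volume: np.ndarray,
                  mask: np.ndarray) -> dict:
    """Masked SSIM and NRMSE of magnitude volumes.

    Volumes are normalised by the reference maximum within the mask; SSIM
    uses standard parameters (the per-voxel SSIM map is averaged over the
    mask) and NRMSE divides the masked RMS error by the reference
    intensity range within the mask.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask")
    if test_volume.shape != ref_volume.shape:
        raise ValueError("shape mismatch")
    ref = np.abs(np.asarray(ref_volume, dtype=float))
    tst = np.abs(np.asarray(test_volume, dtype=float))
    scale = ref[mask].max()
    if scale <= 0:
        raise ValueError("reference volume is empty")
    ref = ref / scale
    tst = tst / scale
    _, ssim_map = structural_similarity(
        ref, tst, data_range=1.0, full=True
    )
    ssim = float(ssim_map[mask].mean())
    err = tst[mask] - ref[mask]
    rng = ref[mask].max() - ref[mask].min()
    nrmse = float(np.sqrt(np.mean(err**2)) / rng) if rng > 0 else np.inf
    return {"ssim": ssim, "nrmse": nrmse}


def map_error(test_map: np.ndarray, ref_map: np.ndarray, mask: np.ndarray) -> float:
    """Mean absolute error over the mask."""
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask")
    if test_map.shape != ref_map.shape:
        raise ValueError("shape mismatch")
    return float(np.mean(np.abs(np.asarray(test_map)[mask]
                                - np.asarray(ref_map)[mask])))
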