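"""Spherical k-space navigator trajectory and FID/SNAV signal simulation.

A navigator event couples a 64-point FID (a pure k = 0 readout whose phase
slope over time measures the spatially uniform, per-channel field offset)
with a spherical-shell k-space readout (SNAV) acquired as two hemispheres.
Under rigid head motion the shell signal magnitude rotates on the sphere
while translation only adds a phase ramp — so magnitude matching recovers
rotation and phase differences recover translation.

The reference scan acquires FIDSNAV baselines with the *trajectory*
rotated about kx and ky over [-6, 6] deg in 1 deg steps; the lookup-table
estimator later interpolates these in the latitude-longitude plane.
Baseline trajectory rotation uses ``Rx(tx) @ Ry(ty)`` applied to the shell
points, and a rotation about kz is a pure longitude shift — together these
compose to the transpose of the extrinsic x->y->z head rotation, which is
what a moving head presents to a fixed navigator trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fourier import nudft_sample
from .phantom import CoilProfileSet, PhantomVolume
from .protocol import ProtocolConfig
from .transforms import RigidTransform, rotation_matrix


@dataclass
class NavTrajectory:
    """Two-hemisphere spherical-shell sampling pattern.

    Points are organised as rings: for each hemisphere, ``n_latitudes``
    rings of ``n_longitudes`` uniformly spaced longitudes.  Ring structure
    is what makes longitude resampling (kz-rotation simulation) exact.
    """

    shell_radius: float  # cycles/cm
    points: np.ndarray  # (n_points, 3) kx, ky, kz in cycles/cm
    hemisphere: np.ndarray  # (n_points,) +1 upper / -1 lower
    latitude_deg: np.ndarray
    longitude_deg: np.ndarray
    n_latitudes: int
    n_longitudes: int

    def __post_init__(self) -> None:
        r = np.linalg.norm(self.points, axis=1)
        if not np.allclose(r, self.shell_radius, rtol=1e-9):
            raise ValueError("all points must lie on the shell")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def ring_view(self, values: np.ndarray) -> np.ndarray:
        """Reshape per-point values to (..., 2 * n_latitudes, n_longitudes)."""
        return np.asarray(values).reshape(
            *np.asarray(values).shape[:-1], 2 * self.n_latitudes, self.n_longitudes
        )

    def rotated_points(self, rot_deg_x: float, rot_deg_y: float) -> np.ndarray:
        """Shell points under the baseline-scan rotation Rx(tx) @ Ry(ty)."""
        R = rotation_matrix((rot_deg_x, 0.0, 0.0)) @ rotation_matrix(
            (0.0, rot_deg_y, 0.0)
        )
        return self.points @ R.T


@dataclass
class FidSnavRecord:
    """One navigator event: per-channel FID + per-channel shell samples."""

    fid: np.ndarray  # (n_channels, fid_points)
    snav: np.ndarray  # (n_channels, n_points)
    trajectory: NavTrajectory
    time_s: float = 0.0

    def __post_init__(self) -> None:
        if self.snav.shape[-1] != self.trajectory.n_points:
            raise ValueError("snav length must match trajectory")


@dataclass
class BaselineSet:
    """Pre-rotated FIDSNAV baselines over (theta_x, theta_y) in 1 deg steps."""

    angles_deg: np.ndarray  # 1D grid, e.g. -6..6
    records: dict  # (int tx, int ty) -> FidSnavRecord
    reference_fid: np.ndarray
    trajectory: NavTrajectory

    def __post_init__(self) -> None:
        n = len(self.angles_deg)
        if len(self.records) != n * n:
            raise ValueError(f"baseline grid incomplete: {len(self.records)} != {n*n}")

    def record(self, tx: float, ty: float) -> FidSnavRecord:
        return self.records[(int(round(tx)), int(round(ty)))]


def make_snav_trajectory(
    shell_radius: float = 0.4,
    n_latitudes: int = 8,
    n_longitudes: int = 60,
) -> NavTrajectory:
    """Deterministic ring sampling of the two-hemisphere shell.

    Latitude rings sit at ``90 * (i + 0.5) / n_latitudes`` degrees above and
    below the kx-ky plane (mirrored hemispheres, so the point set is
    symmetric under kz -> -kz); longitudes are uniform within each ring.
    """
    if shell_radius <= 0:
        raise ValueError("shell_radius must be positive")
    lats = 90.0 * (np.arange(n_latitudes) + 0.5) / n_latitudes
    lons = 360.0 * np.arange(n_longitudes) / n_longitudes
    pts, hemi, lat_l, lon_l = [], [], [], []
    for sign in (+1.0, -1.0):
        for lat in lats:
            cl, sl = np.cos(np.radians(lat)), np.sin(np.radians(lat))
            for lon in lons:
                pts.append(
                    (
                        shell_radius * cl * np.cos(np.radians(lon)),
                        shell_radius * cl * np.sin(np.radians(lon)),
                        sign * shell_radius * sl,
                    )
                )
                hemi.append(sign)
                lat_l.append(lat)
                lon_l.append(lon)
    return NavTrajectory(
        shell_radius,
        np.asarray(pts),
        np.asarray(hemi),
        np.asarray(lat_l),
        np.asarray(lon_l),
        n_latitudes,
        n_longitudes,
    )


def _masked_channel_weights(
    phantom: PhantomVolume, coils: CoilProfileSet
) -> np.ndarray:
    """(N_masked, n_channels) coil-weighted proton density."""
    pd = phantom.proton_density[phantom.mask]
    sens = np.stack(
        [coils.sensitivities[c][phantom.mask] for c in range(coils.n_channels)],
        axis=1,
    )
    return pd[:, None] * sens


def simulate_fid(
    phantom: PhantomVolume,
    coils: CoilProfileSet,
    transform: RigidTransform = RigidTransform(),
    df0_per_channel=None,
    protocol: ProtocolConfig | None = None,
    phase_offset_rad=None,
) -> np.ndarray:
    """Per-channel FID: the k = 0 readout of the evolving coil-weighted head.

    FID_c(t_n) = sum_x PD C_c exp(i 2 pi (df0_c + offres(x)) t_n) exp(-R2* t_n)

    with t_n = start offset + n * dwell.  A rigid pose moves all voxel
    attributes together, so the k = 0 sum — and hence the field estimate —
    is invariant to motion; ``df0_c`` enters as a pure per-channel phase
    ramp.  ``phase_offset_rad`` adds a static per-channel phase (an
    eddy-current stand-in that FID normalisation must absorb).
    """
    protocol = protocol or ProtocolConfig(
        grid_shape=phantom.grid_shape, voxel_size_mm=phantom.voxel_size_mm
    )
    _ = transform.matrix  # validates finiteness; FID is pose-invariant
    tn = protocol.fid_times_s()  # (T,)
    offres = phantom.offres_map[phantom.mask]
    r2s = phantom.r2star_map[phantom.mask]
    evol = np.exp(np.outer(2j * np.pi * offres - r2s, tn))  # (N, T)
    w = _masked_channel_weights(phantom, coils)  # (N, C)
    fid = w.T @ evol  # (C, T)
    if df0_per_channel is not None:
        df0 = np.asarray(df0_per_channel, dtype=float)
        fid = fid * np.exp(2j * np.pi * df0[:, None] * tn[None, :])
    if phase_offset_rad is not None:
        fid = fid * np.exp(1j * np.asarray(phase_offset_rad, float))[:, None]
    return fid


def simulate_snav(
    phantom: PhantomVolume,
    coils: CoilProfileSet,
    transform: RigidTransform = RigidTransform(),
    df0_per_channel=None,
    trajectory: NavTrajectory | None = None,
    nav_time_s: float = 3.0e-3,
    dtype=np.complex128,
    kpoints=None,
) -> np.ndarray:
    """Per-channel shell samples of the posed, coil-weighted phantom.

    S_c(k) = F{PD C_c}(R^T k) exp(-i 2 pi k . dr) exp(i 2 pi df0_c t_nav)

    Magnitude is therefore invariant to translation and to df0.  A single
    nominal sample time is used per navigator, matching the estimator's
    single zeroth-order phase correction.  ``kpoints`` overrides the
    trajectory's nominal points (used for baseline scans with rotated
    trajectories).
    """
    if trajectory is None:
        trajectory = make_snav_trajectory()
    pts = trajectory.points if kpoints is None else np.asarray(kpoints)
    R = transform.matrix
    dr_cm = np.asarray(transform.trans_mm) / 10.0
    sample_pts = pts @ R  # row-wise R^T @ k
    w = _masked_channel_weights(phantom, coils)  # (N, C)
    snav = nudft_sample(sample_pts, phantom.masked_coords_cm(), w, dtype=dtype).T
    ramp = np.exp(-2j * np.pi * (pts @ dr_cm))
    snav = snav * ramp[None, :]
    if df0_per_channel is not None:
        df0 = np.asarray(df0_per_channel, dtype=float)
        snav = snav * np.exp(2j * np.pi * df0 * nav_time_s)[:, None]
    return snav


def acquire_baselines(
    phantom: PhantomVolume,
    coils: CoilProfileSet,
    protocol: ProtocolConfig | None = None,
    trajectory: NavTrajectory | None = None,
    angle_range_deg: float = 6.0,
    angle_step_deg: float = 1.0,
    dtype=np.complex128,
) -> BaselineSet:
    """Reference scan: static-phantom FIDSNAVs with pre-rotated trajectories.

    Covers (theta_x, theta_y) in [-range, range] at ``angle_step_deg``
    (13 x 13 = 169 records by default).  The (0, 0) entry is the unrotated
    baseline and its FID is the reference FID.
    """
    protocol = protocol or ProtocolConfig(
        grid_shape=phantom.grid_shape, voxel_size_mm=phantom.voxel_size_mm
    )
    if trajectory is None:
        trajectory = make_snav_trajectory()
    n = int(round(2 * angle_range_deg / angle_step_deg)) + 1
    angles = -angle_range_deg + angle_step_deg * np.arange(n)
    fid = simulate_fid(phantom, coils, protocol=protocol)
    records: dict = {}
    for tx in angles:
        for ty in angles:
            pts = trajectory.rotated_points(tx, ty)
            snav = simulate_snav(
                phantom, coils, trajectory=trajectory, dtype=dtype, kpoints=pts
            )
            records[(int(round(tx)), int(round(ty)))] = FidSnavRecord(
                fid=fid, snav=snav, trajectory=trajectory
            )
    return BaselineSet(angles, records, fid, trajectory)
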