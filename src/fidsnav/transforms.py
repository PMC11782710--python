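"""Rigid-body transforms for head pose and k-space geometry.

Coordinate convention (head-first supine): x = right-left, y =
posteroanterior, z = superoinferior.  Rotations are extrinsic, applied in
the order x -> y -> z about the volume centre, i.e. the rotation matrix is

    R = Rz(theta_z) @ Ry(theta_y) @ Rx(theta_x)

Under a rigid pose the object ``rho`` becomes ``rho(R^T (x - dr))`` and its
Fourier transform obeys

    F{posed}(k) = exp(-i 2 pi k . dr) * F{rho}(R^T k),

which is the identity every estimator in this package relies on: rotations
rotate k-space, translations add a linear phase ramp.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation


@dataclass(frozen=True)
class RigidTransform:
    """Six-parameter rigid motion state: rotations in degrees, translations in mm."""

    rot_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    trans_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        r = np.asarray(self.rot_deg, dtype=float)
        t = np.asarray(self.trans_mm, dtype=float)
        if r.shape != (3,) or t.shape != (3,):
            raise ValueError("rot_deg and trans_mm must each have 3 components")
        if not (np.all(np.isfinite(r)) and np.all(np.isfinite(t))):
            raise ValueError("transform parameters must be finite")
        object.__setattr__(self, "rot_deg", tuple(float(v) for v in r))
        object.__setattr__(self, "trans_mm", tuple(float(v) for v in t))

    @property
    def matrix(self) -> np.ndarray:
        """3x3 rotation matrix, extrinsic x -> y -> z."""
        # scipy lowercase seq = extrinsic axes in application order
        return Rotation.from_euler("xyz", self.rot_deg, degrees=True).as_matrix()

    @property
    def is_identity(self) -> bool:
        return all(v == 0.0 for v in self.rot_deg) and all(
            v == 0.0 for v in self.trans_mm
        )

    @property
    def params(self) -> np.ndarray:
        """(6,) vector [theta_x, theta_y, theta_z, tx, ty, tz] (deg, mm)."""
        return np.array(self.rot_deg + self.trans_mm, dtype=float)

    @classmethod
    def from_params(cls, p) -> "RigidTransform":
        p = np.asarray(p, dtype=float)
        return cls(tuple(p[:3]), tuple(p[3:6]))

    def inverse(self) -> "RigidTransform":
        rinv = Rotation.from_euler("xyz", self.rot_deg, degrees=True).inv()
        ang = rinv.as_euler("xyz", degrees=True)
        t = -(rinv.as_matrix() @ np.asarray(self.trans_mm))
        return RigidTransform(tuple(ang), tuple(t))

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Composition self∘other: apply ``other`` first, then ``self``."""
        ra = Rotation.from_euler("xyz", self.rot_deg, degrees=True)
        rb = Rotation.from_euler("xyz", other.rot_deg, degrees=True)
        rc = ra * rb
        t = ra.as_matrix() @ np.asarray(other.trans_mm) + np.asarray(self.trans_mm)
        return RigidTransform(tuple(rc.as_euler("xyz", degrees=True)), tuple(t))

    def rotation_angle_deg(self) -> float:
        """Magnitude of the net rotation (axis-angle angle, degrees)."""
        return float(
            np.degrees(
                Rotation.from_euler("xyz", self.rot_deg, degrees=True).magnitude()
            )
        )


IDENTITY = RigidTransform()


def relative_transform(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """Transform taking pose ``b`` to pose ``a`` (a composed with b^-1)."""
    return a.compose(b.inverse())


def rotation_matrix(rot_deg) -> np.ndarray:
    """Extrinsic x->y->z rotation matrix from three angles in degrees."""
    return Rotation.from_euler("xyz", rot_deg, degrees=True).as_matrix()
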