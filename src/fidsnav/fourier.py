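"""Fourier machinery shared by the acquisition and navigator simulators.

Conventions
-----------
Image-space coordinates are voxel centres in cm relative to the volume
centre (index ``n//2`` of each axis sits at the origin).  k-space
coordinates are in cycles/cm; the Cartesian grid carries integer indices
``m in [-n//2, n//2)`` mapped to ``k = m / (n * voxel_cm)``.  The forward
transform is

    S(k) = sum_x v(x) * exp(-i 2 pi k . x)

so on-grid sampling reduces to ``fftshift(fftn(ifftshift(v)))`` and the
image is recovered with the matching inverse.  Off-grid (rotated) k-points
are evaluated by an exact direct-summation non-uniform DFT over the masked
voxels — no gridding interpolation, so the rigid-motion Fourier identities
hold to machine precision.
"""

from __future__ import annotations

import numpy as np


def cartesian_kgrid_cycles_per_cm(grid_shape, voxel_size_mm):
    """1D k-axes (cycles/cm), centred: index n//2 corresponds to k = 0."""
    axes = []
    for n, d in zip(grid_shape, voxel_size_mm):
        m = np.arange(n) - n // 2
        axes.append(m / (n * d / 10.0))
    return tuple(axes)


def fft_forward(volume: np.ndarray) -> np.ndarray:
    """Centred forward FFT: S(k) = sum_x v(x) exp(-i2pi k.x)."""
    return np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(volume)))


def fft_inverse(kspace: np.ndarray) -> np.ndarray:
    """Inverse of :func:`fft_forward`."""
    return np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(kspace)))


def nudft_sample(
    kpoints_cycles_per_cm: np.ndarray,
    coords_cm: np.ndarray,
    values: np.ndarray,
    dtype: np.dtype = np.complex128,
) -> np.ndarray:
    """Exact non-uniform DFT: S[m, j] = sum_n exp(-i2pi k_m . x_n) v[n, j].

    Parameters
    ----------
    kpoints_cycles_per_cm : (M, 3) sample locations.
    coords_cm : (N, 3) voxel coordinates.
    values : (N,) or (N, J) complex voxel amplitudes; J independent
        weightings (e.g. channel x echo) share one phase matrix.
    dtype : complex64 for speed or complex128 for precision.

    The O(M N) cost is deliberate: at desk-scale grids a BLAS matmul beats
    any gridding scheme and is exact.
    """
    k = np.ascontiguousarray(kpoints_cycles_per_cm, dtype=np.float64)
    x = np.ascontiguousarray(coords_cm, dtype=np.float64)
    if k.ndim != 2 or k.shape[1] != 3:
        raise ValueError("kpoints must be (M, 3)")
    if np.dtype(dtype) == np.complex64:
        from ._fast_nudft import nudft_c64

        return nudft_c64(k, x, values)
    phase = k @ x.T  # (M, N) in cycles
    kern = np.exp(-2j * np.pi * phase)
    v = np.asarray(values)
    squeeze = v.ndim == 1
    if squeeze:
        v = v[:, None]
    out = kern @ v.astype(kern.dtype)
    return out[:, 0] if squeeze else out
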