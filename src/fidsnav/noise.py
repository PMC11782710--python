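"""Receiver-noise model shared by tests and the acceptance script.

A single complex thermal noise level per channel applies to every raw
sample — imaging readout, FID and shell navigator alike.  The level is
parameterised by the reconstructed image SNR: with an N-voxel inverse
FFT, voxel noise is sigma_k / sqrt(N), so

    sigma_k = mean masked voxel amplitude * sqrt(N) / SNR_image.

The k = 0 navigator samples sum the whole volume, so their per-sample
SNR is orders of magnitude above the image SNR — the asymmetry that
makes FID-based field estimation precise at ordinary imaging SNR.
"""

from __future__ import annotations

import numpy as np

from .phantom import CoilProfileSet, PhantomVolume


def sample_noise_std(phantom: PhantomVolume, coils: CoilProfileSet,
                     image_snr: float) -> np.ndarray:
    """Per-channel complex-sample noise std for a target image SNR."""
    if image_snr <= 0:
        raise ValueError("image_snr must be positive")
    n_vox = float(np.prod(phantom.grid_shape))
    m = phantom.mask
    sig = np.array([
        np.mean(np.abs(phantom.proton_density[m]
                       * coils.sensitivities[c][m]))
        for c in range(coils.n_channels)
    ])
    return sig * np.sqrt(n_vox) / image_snr


def add_complex_noise(samples: np.ndarray, sigma_per_channel: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """Add circular complex Gaussian noise; ``samples`` is (C, ...)."""
    sigma = np.asarray(sigma_per_channel, dtype=float)
    shape = samples.shape
    noise = (rng.standard_normal(shape) + 1j * rng.standard_normal(shape))
    sigma = sigma.reshape((shape[0],) + (1,) * (len(shape) - 1))
    return samples + sigma * noise / np.sqrt(2)
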