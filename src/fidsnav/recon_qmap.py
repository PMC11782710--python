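"""Combined surface for reconstruction and quantitative mapping.

Re-exports the retrospective B0 correction / reconstruction operations
(:mod:`fidsnav.recon`) and the FF / R2* fitting operations
(:mod:`fidsnav.qmap`) under one import path.
"""

from .qmap import (  # noqa: F401
    FAT_REL_AMPLITUDES,
    FAT_SHIFTS_PPM,
    QMaps,
    fat_modulation,
    fat_peak_freqs_hz,
    fit_ff,
    fit_r2star,
)
from .recon import ReconVolumeSet, b0_correct_line, reconstruct  # noqa: F401
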