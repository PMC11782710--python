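"""Acquisition protocol parameters.

Defaults follow a 3 T 10-echo multi-echo GRE protocol for multiparametric
mapping with interleaved FID + spherical-navigator (FIDSNAV) events: TR
51 ms, TEs 3.28-45.40 ms, flip 15 deg, one 2-TR navigator (two hemispheres)
every eight imaging k-space lines, FOV updates computed 10 ms ahead of
each TR, 64-point FIDs at 10 us dwell with the first 15 points discarded,
and the eighth navigator serving as the FID phase reference.
"""

from __future__ import annotations

from dataclasses import dataclass


DEFAULT_TE_MS = (3.28, 4.72, 6.22, 7.72, 9.49, 16.75, 23.90, 31.10, 38.16, 45.40)


@dataclass
class ProtocolConfig:
    tr_ms: float = 51.0
    te_ms: tuple[float, ...] = DEFAULT_TE_MS
    flip_deg: float = 15.0
    nav_every_n_lines: int = 8
    nav_trs_per_navigator: int = 2
    margin_time_ms: float = 10.0
    fid_points: int = 64
    fid_dwell_us: float = 10.0
    fid_discard_points: int = 15
    nav_reference_index: int = 8  # 1-based: the eighth navigator
    grid_shape: tuple[int, int, int] = (64, 64, 48)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    # simulation details not printed on a scanner card
    fid_start_us: float = 200.0      # FID start after RF excitation
    snav_time_ms: float = 3.0        # nominal SNAV sample time after RF
    readout_dwell_us: float = 10.0   # imaging readout sample spacing
    controller_latency_ms: float = 22.0  # navigator processing time

    def __post_init__(self) -> None:
        te = tuple(float(t) for t in self.te_ms)
        if any(b <= a for a, b in zip(te, te[1:])):
            raise ValueError("te_ms must be strictly increasing")
        if any(t >= self.tr_ms for t in te):
            raise ValueError("all TE must be shorter than TR")
        if self.nav_every_n_lines < 1:
            raise ValueError("nav_every_n_lines must be >= 1")
        self.te_ms = te

    @property
    def n_echoes(self) -> int:
        return len(self.te_ms)

    @property
    def te_s(self):
        import numpy as np

        return np.asarray(self.te_ms) / 1e3

    def fid_times_s(self):
        """Sample times of the FID readout, seconds after RF excitation."""
        import numpy as np

        return (self.fid_start_us + np.arange(self.fid_points) * self.fid_dwell_us) / 1e6
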