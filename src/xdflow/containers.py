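"""In-memory containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class AcquisitionTable:
    """Per-readout raw data: the single source every reconstruction re-bins.

    One row per TR: one (ky, kz) phase-encode sample of one velocity-encoding
    echo, across all coils, plus the Butterfly-style navigator readouts and
    physiologic stamps.

    Attributes
    ----------
    kspace : (n, n_coil) complex
        The acquired k-space sample per coil (kx collapsed: planar object).
    ky, kz : (n,) int
        Phase-encode indices on the FFT-shifted grid (DC at N//2).
    echo : (n,) int
        Velocity-encoding echo index (0 = flow-compensated reference).
    time_ms : (n,) float
        Acquisition timestamp.
    cardiac_phase : (n,) float in [0, 1)
        Normalized cardiac phase stamp from the (simulated) trigger system.
    navigator : (n, n_coil, n_axes, n_k) complex
        Per-TR navigator: the central k-space line along each spatial axis.
    attrs : dict
        grid, TR_ms, venc, heart_rate, voxel_size_mm, resp_rate, seed, ...
    """

    kspace: np.ndarray
    ky: np.ndarray
    kz: np.ndarray
    echo: np.ndarray
    time_ms: np.ndarray
    cardiac_phase: np.ndarray
    navigator: np.ndarray
    attrs: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.ky)
        for name in ("kspace", "kz", "echo", "time_ms", "cardiac_phase", "navigator"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"length mismatch in field '{name}'")

    @property
    def n_readouts(self) -> int:
        return len(self.ky)

    @property
    def n_coils(self) -> int:
        return self.kspace.shape[1]

    @property
    def grid(self) -> tuple[int, int]:
        return tuple(int(g) for g in self.attrs["grid"])


@dataclass
class XDImage:
    """Complex image set over (extra dims) x (y, z) with bin metadata.

    ``data`` has shape ``(N_t, N_c, N_r, Ny, Nz)`` for a single echo, or an
    extra leading echo axis when several echoes are stacked by the caller.
    ``bins`` records the bin centers/widths used by the reconstruction so
    downstream quantification knows the frame timing and phase centers.
    """

    data: np.ndarray
    bins: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    @property
    def n_t(self) -> int:
        return self.data.shape[-5]

    @property
    def n_c(self) -> int:
        return self.data.shape[-4]

    @property
    def n_r(self) -> int:
        return self.data.shape[-3]
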