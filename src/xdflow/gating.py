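"""Soft-gating / binning weights and k-space bin consolidation.

Every readout is assigned to cells of the (t, c, r, f) discretization with a
Hanning-window weight per resolved dimension (1 at the bin center, 0 at the
adjacent bin center, cos^2 partition of unity in between), multiplied by an
exponential motion down-weight when respiration is suppressed rather than
resolved.  Repeated samples of the same (ky, kz, bin) cell are consolidated
into a single weighted average: value = sum(w^2 y) / sum(w^2), weight =
sqrt(sum(w^2)), which leaves the weighted least-squares data term (up to an
m-independent constant) and its minimizer unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import AcquisitionTable
from .physio import PhysioSignals

#: samples whose composed weight falls below this are dropped from the bin
ZERO_WEIGHT_THRESHOLD = 1e-6


@dataclass
class GatingParams:
    """Exponential motion down-weighting: w_d = exp(-alpha*(d-beta)) for
    d > beta, else 1.  Defaults follow the soft-gating literature."""

    alpha: float = 1.0
    beta: float = 0.25

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")


@dataclass
class BinSpec:
    """Discretization of the extra (t, c, r, f) dimensions.

    mode is a convenience label; the behavior is fully determined by the
    numeric fields and policies:

    - ``conventional``: N_t = 1, N_r = 1, respiratory soft-gating on.
    - ``R1``: few temporal bins, many cardiac phases, soft-gating on.
    - ``R2``: respiratory-resolved (N_r > 1, respiratory_policy='resolved').
    - ``R3``: ~2-s temporal bins, few cardiac phases, single echo
      reconstructed with other echoes down-weighted by ``echo_downweight``.
    """

    mode: str = "conventional"
    n_t: int = 1
    t_window_ms: float | None = None       # half-window T_t; None -> span/n_t
    n_c: int = 1
    n_r: int = 1
    echo_policy: str = "all_echoes"        # or "single_echo_with_downweight"
    echo_downweight: float = 0.5
    respiratory_policy: str = "soft_gated"  # or "resolved"
    cyclic: bool = True

    def __post_init__(self):
        if min(self.n_t, self.n_c, self.n_r) < 1:
            raise ValueError("bin counts must be >= 1")
        if not (0.0 < self.echo_downweight <= 1.0):
            raise ValueError("echo_downweight must be in (0, 1]")
        if self.respiratory_policy not in ("soft_gated", "resolved"):
            raise ValueError(f"unknown respiratory_policy {self.respiratory_policy!r}")
        if self.echo_policy not in ("all_echoes", "single_echo_with_downweight"):
            raise ValueError(f"unknown echo_policy {self.echo_policy!r}")

    @classmethod
    def for_mode(cls, mode: str, **kw) -> "BinSpec":
        presets = {
            "conventional": dict(n_t=1, n_c=20, n_r=1, respiratory_policy="soft_gated"),
            "R1": dict(n_t=3, n_c=20, n_r=1, respiratory_policy="soft_gated"),
            "R2": dict(n_t=1, n_c=20, n_r=4, respiratory_policy="resolved"),
            "R3": dict(n_t=30, n_c=5, n_r=1, respiratory_policy="soft_gated",
                       echo_policy="single_echo_with_downweight"),
        }
        if mode not in presets:
            raise ValueError(f"unknown mode {mode!r}")
        cfg = presets[mode] | kw
        return cls(mode=mode, **cfg)


@dataclass
class WeightedBinnedData:
    """Consolidated weighted k-space samples, one row per unique
    (t, c, r, f, ky, kz) cell."""

    bin_t: np.ndarray      # (m,) int
    bin_c: np.ndarray      # (m,) int
    bin_r: np.ndarray      # (m,) int
    echo: np.ndarray       # (m,) int
    ky: np.ndarray         # (m,) int
    kz: np.ndarray         # (m,) int
    values: np.ndarray     # (m, n_coil) complex
    weights: np.ndarray    # (m,) float
    spec: BinSpec = field(default_factory=BinSpec)
    t_centers_ms: np.ndarray = field(default_factory=lambda: np.zeros(1))
    t_window_ms: float = 1.0
    attrs: dict = field(default_factory=dict)

    @property
    def grid(self) -> tuple[int, int]:
        return tuple(int(g) for g in self.attrs["grid"])

    @property
    def n_echoes(self) -> int:
        return int(self.echo.max()) + 1 if len(self.echo) else 1

    def occupancy(self) -> np.ndarray:
        """Sample counts per (t, c, r) bin for the first echo."""
        counts = np.zeros((self.spec.n_t, self.spec.n_c, self.spec.n_r), dtype=int)
        sel = self.echo == self.echo.min() if len(self.echo) else slice(0)
        np.add.at(counts, (self.bin_t[sel], self.bin_c[sel], self.bin_r[sel]), 1)
        return counts


def weight_temporal(t_ms, t0_ms, t_window_ms):
    """Hanning temporal bin weight: 1 at the bin center t0, 0 at offset T_t."""
    delta = (np.asarray(t0_ms, dtype=float) - np.asarray(t_ms, dtype=float)) / t_window_ms
    return np.where(np.abs(delta) <= 1.0, 0.5 + 0.5 * np.cos(np.pi * delta), 0.0)


def _phase_weight(phase, bin_index, n_bins, cyclic=True):
    x = np.asarray(phase, dtype=float) * n_bins
    delta = np.asarray(bin_index, dtype=float) - x
    if cyclic:
        delta = (delta + n_bins / 2.0) % n_bins - n_bins / 2.0
    return np.where(np.abs(delta) <= 1.0, 0.5 + 0.5 * np.cos(np.pi * delta), 0.0)


def weight_cardiac(c, c0, n_c, cyclic=True):
    """Hanning cardiac bin weight; bin c0 is centered at phase c0/N_c.
    The phase distance is cyclic by default (cardiac phase is periodic)."""
    return _phase_weight(c, c0, n_c, cyclic)


def weight_respiratory(r, r0, n_r, cyclic=True):
    """Hanning respiratory bin weight, mirroring the cardiac weight."""
    return _phase_weight(r, r0, n_r, cyclic)


def weight_motion(d, params: GatingParams = GatingParams()):
    """Exponential soft-gating weight from the centered motion signal d."""
    d = np.asarray(d, dtype=float)
    return np.where(d > params.beta, np.exp(-params.alpha * (d - params.beta)), 1.0)


def compose_weight(w_t, w_c, w_r, w_d):
    """Composite bin weight: the product of the four factors."""
    return np.asarray(w_t) * np.asarray(w_c) * np.asarray(w_r) * np.asarray(w_d)


def temporal_bin_centers(
    n_t: int, t_start_ms: float, t_end_ms: float, t_window_ms: float | None = None
) -> tuple[np.ndarray, float]:
    """Uniform temporal bin centers over [t_start, t_end]; the default
    half-window equals the bin spacing so adjacent windows overlap at half
    height (cos^2 partition of unity)."""
    span = t_end_ms - t_start_ms
    spacing = span / n_t
    centers = t_start_ms + (np.arange(n_t) + 0.5) * spacing
    return centers, float(t_window_ms if t_window_ms is not None else spacing)


def _dim_candidates_linear(t, centers, t_window):
    """Candidate temporal bins (at most 2) per sample with their weights."""
    n_t = len(centers)
    if n_t == 1:
        return [(np.zeros(len(t), dtype=int), np.ones(len(t)))]
    spacing = centers[1] - centers[0]
    j = np.floor((t - centers[0]) / spacing).astype(int)
    out = []
    for jj in (j, j + 1):
        jj = np.clip(jj, 0, n_t - 1)
        out.append((jj, weight_temporal(t, centers[jj], t_window)))
    return out


def _dim_candidates_cyclic(phase, n_bins, cyclic, weight_fn):
    """Candidate phase bins (at most 2) per sample with their weights."""
    if n_bins == 1:
        return [(np.zeros(len(phase), dtype=int), np.ones(len(phase)))]
    x = np.asarray(phase) * n_bins
    j = np.floor(x).astype(int)
    out = []
    for jj in (j, j + 1):
        jj = jj % n_bins if cyclic else np.clip(jj, 0, n_bins - 1)
        out.append((jj, weight_fn(phase, jj, n_bins, cyclic)))
    return out


def bin_and_consolidate(
    table: AcquisitionTable,
    signals: PhysioSignals,
    spec: BinSpec,
    params: GatingParams = GatingParams(),
) -> WeightedBinnedData:
    """Assign every readout to its (t, c, r, f) bins and consolidate.

    Repeated samples of a cell are replaced by their weighted average with
    weights w^2, and the cell weight becomes sqrt(sum w^2).  Samples whose
    composed weight is below ``ZERO_WEIGHT_THRESHOLD`` are dropped.
    """
    n = table.n_readouts
    if len(signals.c) != n:
        raise ValueError("physio signals do not cover every readout")

    t = np.asarray(table.time_ms, dtype=float)
    t_centers, t_window = temporal_bin_centers(
        spec.n_t, t.min(), t.max() + float(table.attrs.get("TR_ms", 0.0)),
        spec.t_window_ms,
    )

    if spec.respiratory_policy == "soft_gated":
        w_d = weight_motion(signals.d, params)
        r_cands = [(np.zeros(n, dtype=int), np.ones(n))]
    else:  # resolved: Hanning respiratory weights, no motion down-weighting
        w_d = np.ones(n)
        r_cands = _dim_candidates_cyclic(signals.r, spec.n_r, spec.cyclic,
                                         weight_respiratory)

    t_cands = _dim_candidates_linear(t, t_centers, t_window)
    c_cands = _dim_candidates_cyclic(signals.c, spec.n_c, spec.cyclic, weight_cardiac)

    echo = np.asarray(table.echo, dtype=int)
    if spec.echo_policy == "single_echo_with_downweight":
        echo_out = np.zeros(n, dtype=int)
        w_echo = np.where(echo == 0, 1.0, spec.echo_downweight)
        n_echo_out = 1
    else:
        echo_out = echo
        w_echo = np.ones(n)
        n_echo_out = int(echo.max()) + 1 if n else 1

    rows_idx, rows_t, rows_c, rows_r, rows_w = [], [], [], [], []
    base_w = w_d * w_echo
    idx = np.arange(n)
    for jt, wt in t_cands:
        for jc, wc in c_cands:
            for jr, wr in r_cands:
                w = wt * wc * wr * base_w
                keep = w >= ZERO_WEIGHT_THRESHOLD
                rows_idx.append(idx[keep])
                rows_t.append(jt[keep])
                rows_c.append(jc[keep])
                rows_r.append(jr[keep])
                rows_w.append(w[keep])

    sample = np.concatenate(rows_idx)
    bt = np.concatenate(rows_t)
    bc = np.concatenate(rows_c)
    br = np.concatenate(rows_r)
    w = np.concatenate(rows_w)

    ny, nz = table.grid
    ky = np.asarray(table.ky, dtype=np.int64)[sample]
    kz = np.asarray(table.kz, dtype=np.int64)[sample]
    fe = echo_out[sample]
    key = ((((bt * spec.n_c + bc) * spec.n_r + br) * n_echo_out + fe) * ny + ky) * nz + kz
    uniq, inv = np.unique(key, return_inverse=True)
    m = len(uniq)

    sw2 = np.bincount(inv, weights=w * w, minlength=m)
    n_coil = table.n_coils
    values = np.zeros((m, n_coil), dtype=complex)
    y = table.kspace[sample]                     # (rows, n_coil)
    w2 = (w * w)[:, None]
    np.add.at(values, inv, w2 * y)
    values /= sw2[:, None]

    kz_u = uniq % nz
    rest = uniq // nz
    ky_u = rest % ny
    rest //= ny
    fe_u = rest % n_echo_out
    rest //= n_echo_out
    br_u = rest % spec.n_r
    rest //= spec.n_r
    bc_u = rest % spec.n_c
    bt_u = rest // spec.n_c

    return WeightedBinnedData(
        bin_t=bt_u.astype(int), bin_c=bc_u.astype(int), bin_r=br_u.astype(int),
        echo=fe_u.astype(int), ky=ky_u.astype(int), kz=kz_u.astype(int),
        values=values, weights=np.sqrt(sw2),
        spec=spec, t_centers_ms=t_centers, t_window_ms=t_window,
        attrs=dict(table.attrs),
    )
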