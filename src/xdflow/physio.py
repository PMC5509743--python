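"""Physiologic signal extraction from intrinsic (Butterfly-style) navigators.

The velocity-encoding gradients replay the same central k-space lines every
TR, so they double as motion navigators at no time cost.  The processing
chain implemented here:

1. per-coil, per-axis rigid displacement from a linear-phase fit of the
   navigator against a reference readout (Fourier shift theorem);
2. zero-phase low-pass at 95% of the measured heart rate (removes cardiac
   motion and high-frequency noise) and high-pass at 0.1 Hz (removes drift,
   e.g. from contrast arrival);
3. correlation-based coil clustering to a single displacement vector d0[n];
4. norm + normalization by its standard deviation -> d1[n];
5. histogram centering on the most-occupied motion state -> d[n];
6. optional respiratory trigger detection and phase assignment r[n].

Cardiac phase c[n] is taken from the acquisition table's trigger stamps,
not extracted from the navigators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .containers import AcquisitionTable


@dataclass
class PhysioSignals:
    """Motion and phase signals, one entry per TR."""

    d0: np.ndarray            # (n, 3) displacement vector, pixels
    d1: np.ndarray            # (n,) normalized motion magnitude, std = 1
    d_ref: float              # histogram-mode center
    d: np.ndarray             # (n,) centered motion, d1 - d_ref
    c: np.ndarray             # (n,) cardiac phase in [0, 1)
    r: np.ndarray             # (n,) respiratory phase in [0, 1)
    resp_triggers: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    heart_rate: float = 0.0   # bpm
    resp_rate: float = 0.0    # bpm
    motion_free: bool = False


def navigator_displacement(
    nav: np.ndarray, reference: np.ndarray, grid: tuple[int, ...]
) -> np.ndarray:
    """Per-coil, per-axis displacement (pixels) from a linear-phase fit.

    A rigid shift by D pixels multiplies the k-space line along that axis by
    exp(i 2 pi k D / N).  The slope of the phase of nav * conj(reference) is
    estimated with the magnitude-weighted lag-one phase-difference estimator
    (robust to phase wrapping for multi-pixel shifts).

    Parameters
    ----------
    nav : (..., n_coil, n_axes, n_k) complex
    reference : (n_coil, n_axes, n_k) complex
    grid : axis lengths (N per axis), used to scale slope to pixels.

    Returns
    -------
    (..., n_coil, n_axes) float displacement in pixels.  TRs whose reference
    line is identically zero are returned as NaN (flagged invalid).
    """
    ref_mag = np.abs(reference)
    if np.all(ref_mag == 0):
        raise ValueError("zero-magnitude reference navigator")
    p = nav * np.conj(reference)            # phase = -2 pi k D / N
    q = p[..., 1:] * np.conj(p[..., :-1])   # lag-one phase increments
    # |q| magnitude-weights each increment's contribution to the mean slope
    slope = np.angle(np.sum(q, axis=-1) + 0j)
    n_axes = reference.shape[-2]
    scale = np.asarray([grid[a] / (2.0 * np.pi) for a in range(n_axes)])
    disp = -slope * scale                   # forward-FFT sign convention
    dead = np.all(ref_mag == 0, axis=-1)    # (n_coil, n_axes)
    if np.any(dead):
        disp = np.where(dead, np.nan, disp)
    return disp


def _sos_filter(signal, fs, cutoff_hz, btype, order=4, stop_db=30.0):
    """Zero-phase IIR filter: Chebyshev-II, so the named cutoff is a true
    stopband edge (>= stop_db attenuation there, doubled by the
    forward-backward pass) with a maximally flat passband."""
    nyq = fs / 2.0
    wn = cutoff_hz / nyq
    if btype == "low" and wn >= 1.0:
        return np.asarray(signal, dtype=float).copy()
    wn = min(max(wn, 1e-6), 0.999999)
    sos = sps.cheby2(order, stop_db, wn, btype=btype, output="sos")
    return sps.sosfiltfilt(sos, signal, axis=-1)


def lowpass_cardiac(signal, fs: float, heart_rate: float, order: int = 4):
    """Zero-phase low-pass at 95% of the heart-rate frequency (removes the
    cardiac component and high-frequency noise). heart_rate in bpm."""
    return _sos_filter(signal, fs, 0.95 * heart_rate / 60.0, "low", order)


def highpass_drift(signal, fs: float, cutoff_hz: float = 0.1, order: int = 4):
    """Zero-phase high-pass removing slow drifts (default cutoff 0.1 Hz).

    Butterworth rather than Chebyshev-II: drift removal needs an exact DC
    null, not a sharp transition."""
    nyq = fs / 2.0
    wn = min(max(cutoff_hz / nyq, 1e-6), 0.999999)
    sos = sps.butter(order, wn, btype="high", output="sos")
    return sps.sosfiltfilt(sos, signal, axis=-1)


def resp_bandlimit(d, fs: float, resp_rate: float, order: int = 4):
    """Low-pass the centered motion at 95% of the respiratory rate (bpm)."""
    return _sos_filter(d, fs, 0.95 * resp_rate / 60.0, "low", order)


def coil_cluster(signals: np.ndarray, threshold: float = 0.9) -> np.ndarray:
    """Consolidate per-coil 1-D signals into one by correlation clustering.

    Coils are grouped by |pairwise correlation| >= threshold (connected
    components); the largest group wins, members are sign-aligned to the
    group's seed (highest mean |correlation|) and averaged.  If no pair
    correlates, falls back to the single coil with the highest mean absolute
    correlation and warns.

    Parameters
    ----------
    signals : (n_coil, n) real array.
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    n_coil = signals.shape[0]
    if n_coil == 1:
        return signals[0].copy()
    sd = signals.std(axis=1)
    ok = sd > 0
    corr = np.zeros((n_coil, n_coil))
    if ok.sum() >= 2:
        c = np.corrcoef(signals[ok])
        idx = np.flatnonzero(ok)
        corr[np.ix_(idx, idx)] = c
    np.fill_diagonal(corr, 1.0)

    adj = (np.abs(corr) >= threshold) & ok[:, None] & ok[None, :]
    np.fill_diagonal(adj, False)
    # connected components by BFS
    unvisited = set(np.flatnonzero(ok))
    best_group: list[int] = []
    while unvisited:
        seed = unvisited.pop()
        group, frontier = {seed}, [seed]
        while frontier:
            cur = frontier.pop()
            for nb in np.flatnonzero(adj[cur]):
                if nb in unvisited:
                    unvisited.discard(int(nb))
                    group.add(int(nb))
                    frontier.append(int(nb))
        if len(group) > len(best_group):
            best_group = sorted(group)

    if len(best_group) < 2:
        mean_abs = np.abs(corr).sum(axis=1) - 1.0
        best = int(np.argmax(np.where(ok, mean_abs, -np.inf)))
        warnings.warn("no coil cluster above threshold; using best single coil")
        return signals[best].copy()

    sub = np.abs(corr[np.ix_(best_group, best_group)]).mean(axis=1)
    seed = best_group[int(np.argmax(sub))]
    signs = np.sign(corr[seed, best_group])
    signs[signs == 0] = 1.0
    return np.mean(signs[:, None] * signals[best_group], axis=0)


def normalize_motion(d0: np.ndarray) -> tuple[np.ndarray, bool]:
    """Normalized motion magnitude d1[n] = ||d0[n]|| / std(||d0||).

    Returns (d1, motion_free); a zero standard deviation (no motion at all)
    yields d1 = 0 with the motion-free flag set, so downstream soft-gating
    treats every sample as uncorrupted.
    """
    norm = np.linalg.norm(np.atleast_2d(d0), axis=-1)
    s = norm.std()
    if s == 0:
        return np.zeros_like(norm), True
    return norm / s, False


def center_motion(d1: np.ndarray, n_bins: int = 64) -> tuple[np.ndarray, float]:
    """Center motion on the most-occupied histogram bin: d = d1 - d_ref.

    Ties between equally populated bins resolve toward the smaller d1 value.
    """
    d1 = np.asarray(d1, dtype=float)
    counts, edges = np.histogram(d1, bins=n_bins)
    mode = int(np.argmax(counts))           # first max -> smaller center
    d_ref = 0.5 * (edges[mode] + edges[mode + 1])
    return d1 - d_ref, float(d_ref)


def estimate_resp_rate(d: np.ndarray, fs: float) -> float:
    """Respiratory rate estimate (bpm) from the autocorrelation peak.

    Autocorrelation is used rather than the FFT peak because the motion
    magnitude is a rectified quantity (it is a norm): rectification injects
    a strong second harmonic, but the true period still dominates the
    autocorrelation as long as the breathing waveform is asymmetric.
    """
    d = np.asarray(d, dtype=float)
    d = d - d.mean()
    n = len(d)
    if n < 4 or np.all(d == 0):
        return 0.0
    ac = sps.correlate(d, d, mode="full")[n - 1:]
    lo = max(1, int(fs * 60.0 / 120.0))     # 120 breaths/min upper bound
    hi = min(n - 1, int(fs * 60.0 / 3.0))   # 3 breaths/min lower bound
    if hi <= lo:
        return 0.0
    period = lo + int(np.argmax(ac[lo:hi]))
    return float(60.0 * fs / period)


def detect_resp_triggers(
    d: np.ndarray, fs: float, resp_rate: float | None = None, polarity: str = "max"
) -> np.ndarray:
    """Respiratory trigger indices: peaks of d with minimum separation half
    the estimated respiratory period.  ``polarity='min'`` triggers on troughs."""
    d = np.asarray(d, dtype=float)
    if polarity == "min":
        d = -d
    if resp_rate is None:
        resp_rate = estimate_resp_rate(d, fs)
    if resp_rate <= 0:
        return np.array([], dtype=int)
    min_sep = max(1, int(round(0.5 * fs * 60.0 / resp_rate)))
    prominence = 0.5 * d.std() if d.std() > 0 else None
    peaks, _ = sps.find_peaks(d, distance=min_sep, prominence=prominence)
    # drop peaks in the zero-phase filters' edge-transient zones
    guard = min_sep // 2
    peaks = peaks[(peaks >= guard) & (peaks < len(d) - guard)]
    return peaks.astype(int)


def resp_phase(n_samples: int, triggers: np.ndarray) -> np.ndarray:
    """Respiratory phase r[n] in [0, 1): linear position between enclosing
    triggers (r = 0 at a trigger, 0.5 midway); extrapolated periodically
    before the first and after the last trigger."""
    triggers = np.asarray(triggers, dtype=float)
    if len(triggers) < 2:
        return np.zeros(n_samples)
    idx = np.arange(n_samples, dtype=float)
    r = np.empty(n_samples)
    periods = np.diff(triggers)
    before = idx < triggers[0]
    r[before] = ((idx[before] - triggers[0]) / periods[0]) % 1.0
    after = idx >= triggers[-1]
    r[after] = ((idx[after] - triggers[-1]) / periods[-1]) % 1.0
    mid = ~before & ~after
    seg = np.searchsorted(triggers, idx[mid], side="right") - 1
    r[mid] = (idx[mid] - triggers[seg]) / periods[seg]
    return np.clip(r, 0.0, np.nextafter(1.0, 0.0))


def extract_physio(
    table: AcquisitionTable,
    cluster_threshold: float = 0.9,
    resolve_respiration: bool = True,
    trigger_polarity: str = "max",
    filter_order: int = 4,
) -> PhysioSignals:
    """Full navigator-to-signals pipeline on an acquisition table."""
    fs = 1000.0 / float(table.attrs["TR_ms"])
    heart_rate = float(table.attrs.get("heart_rate", 60.0))
    grid = table.grid
    nav = table.navigator
    ref = nav[0]

    disp = navigator_displacement(nav, ref, grid)   # (n, n_coil, n_axes)
    disp = np.nan_to_num(disp, nan=0.0)
    filt = lowpass_cardiac(disp.T, fs, heart_rate, filter_order)  # (axes, coil, n)
    filt = highpass_drift(filt, fs, order=filter_order)

    n_axes = filt.shape[0]
    d0 = np.zeros((table.n_readouts, 3))
    for ax in range(min(n_axes, 3)):
        d0[:, ax] = coil_cluster(filt[ax], threshold=cluster_threshold)

    d1, motion_free = normalize_motion(d0)
    d, d_ref = center_motion(d1)

    resp_rate = estimate_resp_rate(d, fs) if not motion_free else 0.0
    triggers = np.array([], dtype=int)
    r = np.zeros(table.n_readouts)
    if resolve_respiration and not motion_free and resp_rate > 0:
        triggers = detect_resp_triggers(d, fs, resp_rate, polarity=trigger_polarity)
        r = resp_phase(table.n_readouts, triggers)

    return PhysioSignals(
        d0=d0, d1=d1, d_ref=d_ref, d=d,
        c=np.asarray(table.cardiac_phase, dtype=float),
        r=r, resp_triggers=triggers,
        heart_rate=heart_rate, resp_rate=resp_rate,
        motion_free=motion_free,
    )
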