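"""Weighted compressed-sensing reconstruction over the (t, c, r) bins.

Solves, per velocity-encoding echo,

    argmin_m  1/2 || W (A m - y) ||_2^2
              + lambda_x ||Psi m||_1 + lambda_t ||D_t m||_1
              + lambda_c ||D_c m||_1 + lambda_r ||D_r m||_1

where A applies coil sensitivities, a unitary 2-D FFT and the per-bin
sampling pattern, W holds the soft-gating weights, Psi is the orthonormal
Daubechies-4 wavelet transform of each spatial slice and D_* are first-order
finite differences along the extra dimensions (cyclic along the cardiac
dimension by default, since cardiac phase is periodic).

The solver is ADMM with one split variable per active regularizer; each
z-update is a complex soft-threshold, and the x-update is solved with
conjugate gradients on the (Hermitian positive-definite) normal equations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

from .containers import AcquisitionTable, XDImage
from .gating import WeightedBinnedData


# ------------------------------------------------------------- config

@dataclass
class ReconConfig:
    lambda_x: float = 1e-5
    lambda_t: float = 0.01
    lambda_c: float = 0.01
    lambda_r: float = 0.01
    admm_rho: float = 0.1
    max_iters: int = 30
    cg_iters: int = 10
    tolerance: float = 1e-5
    wavelet: str = "db4"
    wavelet_levels: int = 3
    n_virtual_coils: int = 6
    cyclic_cardiac: bool = True

    def __post_init__(self):
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


@dataclass
class SensitivityMaps:
    """Per-(virtual-)coil complex sensitivity maps over the grid."""

    maps: np.ndarray                      # (n_coil, ny, nz)
    calib_size: int = 24
    eigenvalues: np.ndarray | None = None

    @property
    def n_coils(self) -> int:
        return self.maps.shape[0]


# ----------------------------------------------------- FFT helpers

def fft2c(x: np.ndarray) -> np.ndarray:
    """Unitary, centered 2-D FFT over the trailing two axes."""
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(x, axes=(-2, -1)), norm="ortho"),
        axes=(-2, -1))


def ifft2c(x: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(x, axes=(-2, -1)), norm="ortho"),
        axes=(-2, -1))


# ----------------------------------------------------- calibration

def project_calibration(
    table: AcquisitionTable, echo: int = 0, calib_size: int = 24
) -> np.ndarray:
    """Average the entire acquisition of one echo into a single k-space
    volume and cut out the central calibration region.

    The VDRad center oversampling guarantees coverage; an uncovered
    calibration point raises an error naming the missing extent.
    """
    ny, nz = table.grid
    cs = min(calib_size, ny, nz)
    sel = np.asarray(table.echo) == echo
    acc = np.zeros((table.n_coils, ny, nz), dtype=complex)
    cnt = np.zeros((ny, nz))
    ky = np.asarray(table.ky)[sel]
    kz = np.asarray(table.kz)[sel]
    np.add.at(acc.transpose(1, 2, 0), (ky, kz), table.kspace[sel])
    np.add.at(cnt, (ky, kz), 1.0)
    y0, z0 = ny // 2 - cs // 2, nz // 2 - cs // 2
    region_cnt = cnt[y0:y0 + cs, z0:z0 + cs]
    if np.any(region_cnt == 0):
        miss = np.argwhere(region_cnt == 0)
        raise ValueError(
            f"calibration region {cs}x{cs} not fully covered; "
            f"{len(miss)} missing samples, first at offset {tuple(miss[0])}")
    calib = acc[:, y0:y0 + cs, z0:z0 + cs] / region_cnt
    return calib


def espirit_maps(
    calib: np.ndarray,
    grid: tuple[int, int],
    kernel: int = 6,
    sv_threshold: float = 0.02,
    crop: float = 0.8,
) -> SensitivityMaps:
    """ESPIRiT-style sensitivity maps from a calibration k-space region.

    Builds the block-Hankel calibration matrix from sliding k-space
    patches, keeps the right-singular kernels above ``sv_threshold`` of the
    largest singular value, transforms them to image space and takes the
    per-voxel dominant eigenvector of G G^H.  Voxels whose top eigenvalue
    falls below ``crop`` are zeroed.  The per-voxel phase is referenced to
    coil 0, making the output deterministic.
    """
    n_coil, cs_y, cs_z = calib.shape
    ny, nz = grid
    k = min(kernel, cs_y, cs_z)

    # block-Hankel calibration matrix
    wy, wz = cs_y - k + 1, cs_z - k + 1
    rows = np.empty((wy * wz, k * k * n_coil), dtype=complex)
    idx = 0
    for iy in range(wy):
        for iz in range(wz):
            rows[idx] = calib[:, iy:iy + k, iz:iz + k].ravel()
            idx += 1
    _, s, vh = np.linalg.svd(rows, full_matrices=False)
    n_kern = max(1, int(np.sum(s >= sv_threshold * s[0])))
    kernels = vh[:n_kern].conj().reshape(n_kern, n_coil, k, k)

    # kernels -> image-space per-voxel operators
    pad = np.zeros((n_kern, n_coil, ny, nz), dtype=complex)
    y0, z0 = ny // 2 - k // 2, nz // 2 - k // 2
    pad[:, :, y0:y0 + k, z0:z0 + k] = kernels[:, :, ::-1, ::-1].conj()
    kerimg = fft2c(pad) * np.sqrt(ny * nz) / np.sqrt(k * k)

    g = kerimg.transpose(2, 3, 1, 0)               # (ny, nz, n_coil, n_kern)
    gram = g @ g.conj().transpose(0, 1, 3, 2)      # (ny, nz, n_coil, n_coil)
    evals, evecs = np.linalg.eigh(gram)
    top = evals[..., -1]
    vec = evecs[..., -1]                           # (ny, nz, n_coil)
    ref = vec[..., 0]
    phase = np.where(np.abs(ref) > 0, ref / np.maximum(np.abs(ref), 1e-30), 1.0)
    vec = vec * np.conj(phase)[..., None]
    vec = vec * (top >= crop)[..., None]
    maps = vec.transpose(2, 0, 1)
    return SensitivityMaps(maps=maps, calib_size=cs_y, eigenvalues=top)


def lowres_maps(calib: np.ndarray, grid: tuple[int, int]) -> SensitivityMaps:
    """Fallback: low-resolution ratio maps (apodized calibration / RSS)."""
    n_coil, cs_y, cs_z = calib.shape
    ny, nz = grid
    win = np.outer(np.hanning(cs_y), np.hanning(cs_z))
    pad = np.zeros((n_coil, ny, nz), dtype=complex)
    y0, z0 = ny // 2 - cs_y // 2, nz // 2 - cs_z // 2
    pad[:, y0:y0 + cs_y, z0:z0 + cs_z] = calib * win
    imgs = ifft2c(pad)
    rss = np.sqrt(np.sum(np.abs(imgs) ** 2, axis=0))
    rss = np.maximum(rss, 1e-12 * rss.max())
    return SensitivityMaps(maps=imgs / rss, calib_size=cs_y)


def calibrate_sensitivities(
    table: AcquisitionTable,
    calib_size: int = 24,
    kernel: int = 6,
    method: str = "espirit",
    **kw,
) -> SensitivityMaps:
    """Sensitivity maps from the acquisition itself (single set, reused by
    every reconstruction of the same dataset).

    ``method='auto'`` runs the eigen-decomposition calibration and falls
    back to low-resolution ratio maps if it degenerates (tiny calibration
    regions cannot support the kernel statistics).
    """
    calib = project_calibration(table, echo=0, calib_size=calib_size)
    cs = calib.shape[-1]
    k = min(kernel, max(3, cs // 3))
    if method in ("espirit", "auto"):
        maps = espirit_maps(calib, table.grid, kernel=k, **kw)
        support = np.mean(np.abs(maps.maps).sum(axis=0) > 0)
        if support >= 0.05 or method == "espirit":
            return maps
        return lowres_maps(calib, table.grid)
    if method == "lowres":
        return lowres_maps(calib, table.grid)
    raise ValueError(f"unknown calibration method {method!r}")


# ----------------------------------------------------- coil compression

def fit_coil_compressor(data: np.ndarray, n_virtual: int) -> tuple[np.ndarray, float]:
    """SVD coil-compression matrix fitted on (n_samples, n_coil) data.

    Returns (compressor (n_coil, n_virtual), retained energy fraction).
    """
    _, s, vh = np.linalg.svd(np.asarray(data), full_matrices=False)
    nv = min(n_virtual, len(s))
    energy = float(np.sum(s[:nv] ** 2) / np.sum(s ** 2))
    return vh[:nv].conj().T, energy


def coil_compress(table: AcquisitionTable, n_virtual: int) -> tuple[AcquisitionTable, float]:
    """Globally compress a raw table to ``n_virtual`` virtual coils."""
    comp, energy = fit_coil_compressor(table.kspace, n_virtual)
    nav = table.navigator
    nav_c = np.tensordot(nav, comp, axes=([1], [0])).transpose(0, 3, 1, 2)
    out = AcquisitionTable(
        kspace=table.kspace @ comp,
        ky=table.ky, kz=table.kz, echo=table.echo, time_ms=table.time_ms,
        cardiac_phase=table.cardiac_phase, navigator=nav_c,
        attrs=dict(table.attrs),
    )
    return out, energy


# ----------------------------------------------------- linear operators

class BinnedOperator:
    """A and A^H for one echo of a weighted binned dataset.

    The image is m[(t, c, r, y, z)]; per occupied bin the forward model is
    sample = F(S m)[ky, kz] and W holds the per-sample weights.
    """

    def __init__(self, binned: WeightedBinnedData, maps: np.ndarray, echo: int = 0):
        self.maps = maps
        self.spec = binned.spec
        self.grid = binned.grid
        self.shape = (self.spec.n_t, self.spec.n_c, self.spec.n_r) + self.grid
        sel = binned.echo == echo
        if not np.any(sel):
            raise ValueError(f"no samples for echo {echo}")
        bt, bc, br = binned.bin_t[sel], binned.bin_c[sel], binned.bin_r[sel]
        bins = (bt * self.spec.n_c + bc) * self.spec.n_r + br
        order = np.argsort(bins, kind="stable")
        self._bins = []
        ky, kz = binned.ky[sel][order], binned.kz[sel][order]
        w = binned.weights[sel][order]
        y = binned.values[sel][order]
        bins = bins[order]
        for b in np.unique(bins):
            s = bins == b
            t0, rem = divmod(int(b), self.spec.n_c * self.spec.n_r)
            c0, r0 = divmod(rem, self.spec.n_r)
            self._bins.append(dict(
                t=t0, c=c0, r=r0, ky=ky[s], kz=kz[s], w=w[s], y=y[s]))
        if all(np.all(b["w"] == 0) for b in self._bins):
            raise ValueError("all sample weights are zero")

    # plain A and A^H ------------------------------------------------------
    def forward(self, m: np.ndarray) -> list[np.ndarray]:
        """Per-bin predicted samples, each (n_samples, n_coil)."""
        out = []
        for b in self._bins:
            k = fft2c(self.maps * m[b["t"], b["c"], b["r"]][None])
            out.append(k[:, b["ky"], b["kz"]].T)
        return out

    def adjoint(self, ys: list[np.ndarray]) -> np.ndarray:
        m = np.zeros(self.shape, dtype=complex)
        for b, yb in zip(self._bins, ys):
            k = np.zeros((self.maps.shape[0],) + self.grid, dtype=complex)
            k[:, b["ky"], b["kz"]] = yb.T
            m[b["t"], b["c"], b["r"]] = np.sum(np.conj(self.maps) * ifft2c(k), axis=0)
        return m

    # weighted normal operator --------------------------------------------
    def normal_weighted(self, m: np.ndarray) -> np.ndarray:
        """A^H W^2 A m."""
        out = np.zeros(self.shape, dtype=complex)
        for b in self._bins:
            k = fft2c(self.maps * m[b["t"], b["c"], b["r"]][None])
            kk = np.zeros_like(k)
            kk[:, b["ky"], b["kz"]] = k[:, b["ky"], b["kz"]] * (b["w"] ** 2)[None, :]
            out[b["t"], b["c"], b["r"]] += np.sum(np.conj(self.maps) * ifft2c(kk), axis=0)
        return out

    def rhs_weighted(self) -> np.ndarray:
        """A^H W^2 y."""
        return self.adjoint([b["y"] * (b["w"] ** 2)[:, None] for b in self._bins])

    def data_objective(self, m: np.ndarray) -> float:
        """1/2 || W (A m - y) ||^2."""
        total = 0.0
        for b, pred in zip(self._bins, self.forward(m)):
            total += 0.5 * np.sum((b["w"][:, None] * np.abs(pred - b["y"])) ** 2)
        return float(total)


class WaveletTransform:
    """Orthonormal 2-D Daubechies wavelet transform of each spatial slice."""

    def __init__(self, shape, wavelet="db4", levels=3):
        self.shape = shape
        self.wavelet = wavelet
        ny, nz = shape[-2:]
        self.levels = min(levels, pywt.dwtn_max_level((ny, nz), wavelet))
        probe = pywt.wavedec2(np.zeros((ny, nz)), wavelet,
                              mode="periodization", level=self.levels)
        _, self._slices = pywt.coeffs_to_array(probe)

    def forward(self, m: np.ndarray) -> np.ndarray:
        flat = m.reshape(-1, *m.shape[-2:])
        out = np.empty_like(flat)
        for i, sl in enumerate(flat):
            coeffs = pywt.wavedec2(sl, self.wavelet, mode="periodization",
                                   level=self.levels)
            out[i], _ = pywt.coeffs_to_array(coeffs)
        return out.reshape(m.shape)

    def adjoint(self, w: np.ndarray) -> np.ndarray:
        flat = w.reshape(-1, *w.shape[-2:])
        out = np.empty_like(flat)
        for i, sl in enumerate(flat):
            coeffs = pywt.array_to_coeffs(sl, self._slices, output_format="wavedec2")
            out[i] = pywt.waverec2(coeffs, self.wavelet, mode="periodization")
        return out.reshape(w.shape)


class FiniteDifference:
    """First-order finite difference along one extra dimension.

    Cyclic: D m = roll(m, -1) - m.  Acyclic: forward difference with a
    replicated edge (the last difference is zero), so D of a constant
    array is exactly zero in both variants.
    """

    def __init__(self, axis: int, cyclic: bool):
        self.axis = axis
        self.cyclic = cyclic

    def forward(self, m: np.ndarray) -> np.ndarray:
        d = np.roll(m, -1, axis=self.axis) - m
        if not self.cyclic:
            idx = [slice(None)] * m.ndim
            idx[self.axis] = slice(-1, None)
            d[tuple(idx)] = 0.0
        return d

    def adjoint(self, d: np.ndarray) -> np.ndarray:
        if self.cyclic:
            return np.roll(d, 1, axis=self.axis) - d
        dd = d.copy()
        idx = [slice(None)] * d.ndim
        idx[self.axis] = slice(-1, None)
        dd[tuple(idx)] = 0.0
        return np.roll(dd, 1, axis=self.axis) - dd


def soft_threshold(x: np.ndarray, tau: float) -> np.ndarray:
    mag = np.abs(x)
    scale = np.maximum(mag - tau, 0.0) / np.maximum(mag, 1e-30)
    return x * scale


def _cg(apply_op, b, x0, n_iters, tol=1e-9):
    """Conjugate gradients for a Hermitian positive-definite complex system."""
    x = x0.copy()
    r = b - apply_op(x)
    p = r.copy()
    rs = np.vdot(r, r).real
    b_norm = np.linalg.norm(b)
    for _ in range(n_iters):
        if np.sqrt(rs) <= tol * max(b_norm, 1e-30):
            break
        ap = apply_op(p)
        alpha = rs / max(np.vdot(p, ap).real, 1e-300)
        x += alpha * p
        r -= alpha * ap
        rs_new = np.vdot(r, r).real
        p = r + (rs_new / max(rs, 1e-300)) * p
        rs = rs_new
    return x


def solve(
    binned: WeightedBinnedData,
    maps: SensitivityMaps | np.ndarray,
    config: ReconConfig = ReconConfig(),
    echoes: list[int] | None = None,
    verbose: bool = False,
) -> XDImage:
    """ADMM reconstruction; returns an XDImage with shape
    (n_echo, n_t, n_c, n_r, ny, nz) and a per-echo convergence log in
    ``provenance['log']``."""
    smaps = maps.maps if isinstance(maps, SensitivityMaps) else np.asarray(maps)
    if smaps.shape[-2:] != binned.grid:
        raise ValueError("sensitivity maps do not cover the reconstruction grid")
    if echoes is None:
        echoes = sorted(int(e) for e in np.unique(binned.echo))
    spec = binned.spec
    out = np.zeros((len(echoes), spec.n_t, spec.n_c, spec.n_r) + binned.grid,
                   dtype=complex)
    logs = []
    for i, e in enumerate(echoes):
        op = BinnedOperator(binned, smaps, echo=e)
        out[i], log = _solve_single(op, config, verbose)
        logs.append(log)
    return XDImage(
        data=out,
        bins=dict(
            t_centers_ms=np.asarray(binned.t_centers_ms),
            t_window_ms=binned.t_window_ms,
            n_c=spec.n_c, n_r=spec.n_r, echoes=list(echoes),
        ),
        provenance=dict(mode=spec.mode, log=logs, attrs=dict(binned.attrs)),
    )


def _regularizers(op: BinnedOperator, config: ReconConfig):
    regs = []
    if config.lambda_x > 0:
        regs.append((config.lambda_x,
                     WaveletTransform(op.shape, config.wavelet, config.wavelet_levels)))
    for lam, axis, cyclic in (
        (config.lambda_t, 0, False),
        (config.lambda_c, 1, config.cyclic_cardiac),
        (config.lambda_r, 2, False),
    ):
        if lam > 0 and op.shape[axis] > 1:
            regs.append((lam, FiniteDifference(axis, cyclic)))
    return regs


def objective(op: BinnedOperator, config: ReconConfig, m: np.ndarray) -> float:
    """Full objective value: weighted data term plus l1 penalties."""
    val = op.data_objective(m)
    for lam, T in _regularizers(op, config):
        val += lam * float(np.sum(np.abs(T.forward(m))))
    return val


def _solve_single(op: BinnedOperator, config: ReconConfig, verbose=False):
    rhs = op.rhs_weighted()
    scale = np.abs(rhs).max()
    if scale == 0:
        raise ValueError("zero right-hand side: no usable data")
    regs = _regularizers(op, config)
    rho = config.admm_rho

    # data rescaled to unit adjoint peak so lambda defaults transfer
    for b in op._bins:
        b["y"] = b["y"] / scale
    rhs = rhs / scale

    if not regs:
        m = _cg(op.normal_weighted, rhs, np.zeros_like(rhs),
                n_iters=max(config.max_iters * config.cg_iters, 50), tol=1e-12)
        for b in op._bins:
            b["y"] = b["y"] * scale
        return m * scale, dict(iters=0, objective=[])

    m = rhs.copy()
    zs = [T.forward(m) for _, T in regs]
    us = [np.zeros_like(z) for z in zs]
    log = []

    def normal(x):
        acc = op.normal_weighted(x)
        for _, T in regs:
            acc = acc + rho * T.adjoint(T.forward(x))
        return acc

    for it in range(config.max_iters):
        b = rhs.copy()
        for (_, T), z, u in zip(regs, zs, us):
            b += rho * T.adjoint(z - u)
        m_new = _cg(normal, b, m, config.cg_iters)
        if not np.all(np.isfinite(m_new)):
            raise RuntimeError(f"NaN/Inf in ADMM iterate at iteration {it}")
        primal = dual = 0.0
        for j, (lam, T) in enumerate(regs):
            tm = T.forward(m_new)
            z_old = zs[j]
            zs[j] = soft_threshold(tm + us[j], lam / rho)
            us[j] = us[j] + tm - zs[j]
            primal += float(np.linalg.norm(tm - zs[j]) ** 2)
            dual += float((rho * np.linalg.norm(zs[j] - z_old)) ** 2)
        obj = objective(op, config, m_new)
        log.append(obj)
        if verbose:
            print(f"  admm iter {it:3d}  objective {obj:.6e}")
        scale_ref = max(np.linalg.norm(m_new), 1e-30)
        m = m_new
        # stop on joint primal/dual residual stationarity
        if np.sqrt(primal) < config.tolerance * scale_ref \
                and np.sqrt(dual) < config.tolerance * rho * scale_ref:
            break

    for b in op._bins:
        b["y"] = b["y"] * scale
    return m * scale, dict(iters=len(log), objective=log)
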