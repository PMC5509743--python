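"""Velocity decoding, background-phase correction, and ROI flow metrics.

Velocities are decoded from the per-echo phase differences: a voxel moving
at the velocity-encoding limit (VENC) along an encoding direction acquires
a phase of pi relative to the flow-compensated reference echo.  Residual
background phase (eddy currents, uncompensated moments) is modeled as a
third-order spatial polynomial fitted over static tissue and subtracted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phantom import encoding_matrix


@dataclass
class VelocityField:
    """Per-voxel 3-vector velocity (cm/s) over the extra dims x grid."""

    v: np.ndarray                 # (3, n_t, n_c, n_r, ny, nz)
    venc: float
    matrix: np.ndarray            # (n_e, 4) encoding matrix
    magnitude: np.ndarray | None = None
    aliased: np.ndarray | None = None
    bins: dict = field(default_factory=dict)


@dataclass
class FlowResult:
    """ROI flow summaries: net flow per (t, c, r) in mL/s."""

    flow_ml_s: np.ndarray         # (n_t, n_c, n_r)
    mean_flow_l_min: float        # cycle-averaged, overall
    peak_speed_cm_s: float
    roi_area_cm2: float


def decode_velocity(
    echo_images: np.ndarray,
    venc: float,
    matrix: np.ndarray | None = None,
    bins: dict | None = None,
) -> VelocityField:
    """Least-squares velocity decode from multi-echo complex images.

    ``echo_images`` has shape (n_e, ..., ny, nz).  Phases are measured
    relative to echo 0 (anatomical/background phase cancels), then the
    velocity components solve  (M_e - M_0)[:, 1:] v = phase * venc / pi.
    The full encoding matrix (background column included) must be rank 4.
    """
    echo_images = np.asarray(echo_images)
    n_e = echo_images.shape[0]
    m = encoding_matrix(n_e) if matrix is None else np.asarray(matrix, dtype=float)
    if n_e < 4 or np.linalg.matrix_rank(m) < 4:
        raise ValueError(
            "velocity decoding needs >= 4 echoes with a rank-4 encoding matrix")
    phases = np.angle(echo_images * np.conj(echo_images[0:1]))
    diff = (m - m[0])[:, 1:]                    # (n_e, 3), background dropped
    pinv = np.linalg.pinv(diff)                 # (3, n_e)
    v = np.tensordot(pinv, phases, axes=1) * (venc / np.pi)
    mag = np.mean(np.abs(echo_images), axis=0)
    aliased = np.any(np.abs(v) > venc, axis=0)
    return VelocityField(v=v, venc=venc, matrix=m, magnitude=mag,
                         aliased=aliased, bins=dict(bins or {}))


def _poly_design(ny: int, nz: int, order: int = 3) -> np.ndarray:
    y = (np.arange(ny) - ny / 2) / ny
    z = (np.arange(nz) - nz / 2) / nz
    yy, zz = np.meshgrid(y, z, indexing="ij")
    cols = [yy ** i * zz ** j
            for i in range(order + 1) for j in range(order + 1 - i)]
    return np.stack([c.ravel() for c in cols], axis=1)   # (ny*nz, n_coef)


def background_correct(
    field: VelocityField, static_mask: np.ndarray, order: int = 3
) -> VelocityField:
    """Subtract a third-order polynomial background fitted on static tissue.

    The fit uses the time/phase-averaged velocity (background phase is
    stationary); the same surface is subtracted from every bin.
    """
    ny, nz = field.v.shape[-2:]
    design = _poly_design(ny, nz, order)
    n_coef = design.shape[1]
    sel = np.asarray(static_mask, dtype=bool).ravel()
    if sel.sum() < n_coef:
        raise ValueError(
            f"static mask has {int(sel.sum())} voxels; >= {n_coef} required "
            f"for an order-{order} fit")
    a = design[sel]
    v_out = field.v.copy()
    extra_axes = tuple(range(1, field.v.ndim - 2))
    for comp in range(3):
        mean_v = field.v[comp].mean(axis=tuple(range(field.v[comp].ndim - 2)))
        coef, *_ = np.linalg.lstsq(a, mean_v.ravel()[sel], rcond=None)
        surface = (design @ coef).reshape(ny, nz)
        v_out[comp] = field.v[comp] - surface
    return VelocityField(v=v_out, venc=field.venc, matrix=field.matrix,
                         magnitude=field.magnitude,
                         aliased=np.any(np.abs(v_out) > field.venc, axis=0),
                         bins=field.bins)


def roi_flow(
    field: VelocityField,
    roi: np.ndarray,
    pixel_area_mm2: float,
    component: int = 0,
) -> FlowResult:
    """Net flow through an in-plane ROI (plane normal = component axis).

    flow(t, c, r) = sum_ROI v_normal * pixel_area, in mL/s
    (cm/s * cm^2 = mL/s); mean flow is the all-bin average in L/min.
    """
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("empty flow ROI")
    area_cm2 = pixel_area_mm2 / 100.0
    v = field.v[component]                       # (n_t, n_c, n_r, ny, nz)
    flow = v[..., roi].sum(axis=-1) * area_cm2
    speed = np.abs(field.v[:, ..., roi]).max() if roi.any() else 0.0
    return FlowResult(
        flow_ml_s=flow,
        mean_flow_l_min=float(flow.mean() * 60.0 / 1000.0),
        peak_speed_cm_s=float(speed),
        roi_area_cm2=float(roi.sum() * area_cm2),
    )


def velocity_noise_std(
    field: VelocityField, static_mask: np.ndarray, cardiac_phase: float = 0.75
) -> np.ndarray:
    """Per-component velocity standard deviation over static tissue at the
    cardiac bin nearest the given normalized phase (default 0.75)."""
    static_mask = np.asarray(static_mask, dtype=bool)
    n_c = field.v.shape[2]
    c_bin = int(round(cardiac_phase * n_c)) % n_c   # bin centers at c0/N_c
    v = field.v[:, :, c_bin]                        # (3, n_t, n_r, ny, nz)
    vals = v[..., static_mask]
    return vals.reshape(3, -1).std(axis=1)
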