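"""Readers/writers: HDF5 raw container, NIfTI images, CSV curves, configs.

The raw container is a minimal HDF5 layout (not full ISMRMRD): complex
datasets are stored as paired ``<name>/real`` + ``<name>/imag`` float
arrays, scalars/metadata as root attributes.  Every writer round-trips
losslessly; readers validate the schema and raise ``SchemaError`` naming
the first missing dataset.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import yaml

from .containers import AcquisitionTable, XDImage
from .gating import BinSpec, WeightedBinnedData
from .physio import PhysioSignals

SCHEMA_VERSION = 1


class SchemaError(ValueError):
    """A container is missing required datasets or has inconsistent shapes."""


def _write_complex(group: h5py.Group, name: str, data: np.ndarray) -> None:
    g = group.create_group(name)
    g.create_dataset("real", data=np.ascontiguousarray(data.real))
    g.create_dataset("imag", data=np.ascontiguousarray(data.imag))


def _read_complex(group: h5py.Group, name: str) -> np.ndarray:
    if name not in group:
        raise SchemaError(f"missing dataset '{name}'")
    g = group[name]
    return np.asarray(g["real"]) + 1j * np.asarray(g["imag"])


RAW_DATASETS = ("kspace", "ky", "kz", "echo", "time_ms", "cardiac_phase",
                "navigator")


def write_raw(table: AcquisitionTable, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["container"] = "xdflow-raw"
        _write_complex(f, "kspace", table.kspace)
        _write_complex(f, "navigator", table.navigator)
        for name in ("ky", "kz", "echo", "time_ms", "cardiac_phase"):
            f.create_dataset(name, data=getattr(table, name))
        for k, v in table.attrs.items():
            f.attrs[k] = v


def read_raw(path) -> AcquisitionTable:
    with h5py.File(path, "r") as f:
        for name in RAW_DATASETS:
            if name not in f:
                raise SchemaError(f"missing dataset '{name}'")
        table = AcquisitionTable(
            kspace=_read_complex(f, "kspace"),
            ky=np.asarray(f["ky"]), kz=np.asarray(f["kz"]),
            echo=np.asarray(f["echo"]), time_ms=np.asarray(f["time_ms"]),
            cardiac_phase=np.asarray(f["cardiac_phase"]),
            navigator=_read_complex(f, "navigator"),
            attrs={k: (v.tolist() if isinstance(v, np.ndarray) else v)
                   for k, v in f.attrs.items()
                   if k not in ("schema_version", "container")},
        )
    if "grid" not in table.attrs:
        raise SchemaError("missing attribute 'grid'")
    return table


def write_physio(signals: PhysioSignals, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["container"] = "xdflow-physio"
        for name in ("d0", "d1", "d", "c", "r", "resp_triggers"):
            f.create_dataset(name, data=getattr(signals, name))
        f.attrs["d_ref"] = signals.d_ref
        f.attrs["heart_rate"] = signals.heart_rate
        f.attrs["resp_rate"] = signals.resp_rate
        f.attrs["motion_free"] = signals.motion_free


def read_physio(path) -> PhysioSignals:
    with h5py.File(path, "r") as f:
        for name in ("d0", "d1", "d", "c", "r"):
            if name not in f:
                raise SchemaError(f"missing dataset '{name}'")
        return PhysioSignals(
            d0=np.asarray(f["d0"]), d1=np.asarray(f["d1"]),
            d_ref=float(f.attrs["d_ref"]), d=np.asarray(f["d"]),
            c=np.asarray(f["c"]), r=np.asarray(f["r"]),
            resp_triggers=np.asarray(f["resp_triggers"]),
            heart_rate=float(f.attrs["heart_rate"]),
            resp_rate=float(f.attrs["resp_rate"]),
            motion_free=bool(f.attrs["motion_free"]),
        )


def write_binned(binned: WeightedBinnedData, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["container"] = "xdflow-binned"
        for name in ("bin_t", "bin_c", "bin_r", "echo", "ky", "kz", "weights"):
            f.create_dataset(name, data=getattr(binned, name))
        _write_complex(f, "values", binned.values)
        f.create_dataset("t_centers_ms", data=binned.t_centers_ms)
        f.attrs["t_window_ms"] = binned.t_window_ms
        f.attrs["spec"] = json.dumps(vars(binned.spec))
        f.attrs["table_attrs"] = json.dumps(binned.attrs)


def read_binned(path) -> WeightedBinnedData:
    with h5py.File(path, "r") as f:
        for name in ("bin_t", "bin_c", "bin_r", "echo", "ky", "kz",
                     "weights", "values"):
            if name not in f:
                raise SchemaError(f"missing dataset '{name}'")
        return WeightedBinnedData(
            bin_t=np.asarray(f["bin_t"]), bin_c=np.asarray(f["bin_c"]),
            bin_r=np.asarray(f["bin_r"]), echo=np.asarray(f["echo"]),
            ky=np.asarray(f["ky"]), kz=np.asarray(f["kz"]),
            values=_read_complex(f, "values"),
            weights=np.asarray(f["weights"]),
            spec=BinSpec(**json.loads(f.attrs["spec"])),
            t_centers_ms=np.asarray(f["t_centers_ms"]),
            t_window_ms=float(f.attrs["t_window_ms"]),
            attrs=json.loads(f.attrs["table_attrs"]),
        )


def write_xdimage(image: XDImage, path, voxel_size_mm: float = 1.0) -> None:
    """Magnitude NIfTI with extra dims packed into dim 4 plus a JSON
    sidecar declaring the packing order (NIfTI has no native 6-D
    semantics)."""
    path = Path(path)
    data = image.data
    packed = np.moveaxis(np.abs(data).reshape(-1, *data.shape[-2:]), 0, -1)
    affine = np.diag([voxel_size_mm, voxel_size_mm, voxel_size_mm, 1.0])
    nib.save(nib.Nifti1Image(np.ascontiguousarray(packed), affine), str(path))
    sidecar = {
        "axis_order": ["y", "z", "packed(echo,t,c,r)"],
        "shape": list(data.shape),
        "bins": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                 for k, v in image.bins.items()},
        "mode": image.provenance.get("mode", ""),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def write_flow_csv(flow_ml_s: np.ndarray, path, n_c: int | None = None) -> None:
    """Flow curve CSV: one row per (t, c, r) bin with the flow in mL/s."""
    arr = np.asarray(flow_ml_s)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["bin_t", "bin_c", "bin_r", "flow_ml_s"])
        for (it, ic, ir), val in np.ndenumerate(np.atleast_3d(arr)):
            w.writerow([it, ic, ir, f"{val:.6g}"])


KNOWN_CONFIG_SECTIONS = {
    "schema_version", "seed", "output_dir", "phantom", "sampling",
    "gating", "recon", "quantification", "modes",
}


def load_run_config(path) -> dict:
    """Load and validate a YAML run configuration; unknown top-level keys
    are rejected so typos fail loudly."""
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(cfg) - KNOWN_CONFIG_SECTIONS
    if unknown:
        raise SchemaError(f"unknown config keys: {sorted(unknown)}")
    cfg.setdefault("schema_version", SCHEMA_VERSION)
    cfg.setdefault("seed", 0)
    return cfg


def save_run_config(cfg: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))
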