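"""Readers and writers for stacks, calibration tables and result maps.

Two stack dialects are supported and round-trip tested:

* multi-page TIFF + JSON sidecar: frames interleaved (on, off) per delay in
  schedule order; the sidecar (same path with ``.json`` appended) holds the
  tau schedule, frame order, pixel size and scalar metadata;
* a single HDF5 container: ``tau``, ``on``, ``off`` datasets, attributes for
  pixel size and scalar metadata, and a ``truth/`` group preserving embedded
  synthetic ground-truth arrays.

Calibration tables go to CSV (h_nm, t1_us_mean, t1_us_sd, replicates) with a
JSON sidecar carrying the full configuration and seed; T1 and force maps go
to HDF5 with CSV summaries.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .fitting import T1Map, WidefieldStack
from .force_mapping import ForceMap, PixelClass
from .spin_bath import CalibrationTable

__all__ = [
    "StackFormatError",
    "write_stack_tiff",
    "read_stack_tiff",
    "write_stack_hdf5",
    "read_stack_hdf5",
    "write_stack",
    "read_stack",
    "write_calibration",
    "read_calibration",
    "write_t1_map",
    "read_t1_map",
    "write_force_map",
    "save_force_png",
]


class StackFormatError(ValueError):
    """Raised when a stack file or its metadata is malformed."""


def _json_safe(obj):
    if isinstance(obj, dict):
        return {k: _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return None  # arrays are not stored in JSON sidecars
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    return obj


def write_stack_tiff(stack: WidefieldStack, path) -> Path:
    """Write a stack as multi-page TIFF (+ JSON sidecar at ``<path>.json``)."""
    path = Path(path)
    n = stack.tau.size
    frames = np.empty((2 * n,) + stack.shape, dtype=np.float32)
    frames[0::2] = stack.on
    frames[1::2] = stack.off
    tifffile.imwrite(path, frames)
    sidecar = {
        "tau_us": stack.tau.tolist(),
        "frame_order": "on_off_interleaved",
        "pixel_size_nm": stack.pixel_size_nm,
        "metadata": {k: _json_safe(v) for k, v in stack.metadata.items()
                     if not isinstance(v, np.ndarray)},
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_stack_tiff(path) -> WidefieldStack:
    path = Path(path)
    sidecar_path = Path(str(path) + ".json")
    if not sidecar_path.exists():
        raise StackFormatError(f"missing JSON sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    for key in ("tau_us", "frame_order", "pixel_size_nm"):
        if key not in sidecar:
            raise StackFormatError(f"sidecar lacks required key {key!r}")
    if sidecar["frame_order"] != "on_off_interleaved":
        raise StackFormatError(f"unknown frame order {sidecar['frame_order']!r}")
    frames = tifffile.imread(path)
    tau = np.asarray(sidecar["tau_us"], dtype=float)
    if frames.shape[0] != 2 * tau.size:
        raise StackFormatError(
            f"{frames.shape[0]} frames do not match {tau.size} delays x 2 states"
        )
    return WidefieldStack(
        tau=tau,
        on=frames[0::2].astype(float),
        off=frames[1::2].astype(float),
        pixel_size_nm=float(sidecar["pixel_size_nm"]),
        metadata=sidecar.get("metadata", {}),
    )


def write_stack_hdf5(stack: WidefieldStack, path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("tau_us", data=stack.tau)
        f.create_dataset("on", data=stack.on, compression="gzip")
        f.create_dataset("off", data=stack.off, compression="gzip")
        f.attrs["pixel_size_nm"] = stack.pixel_size_nm
        scalars = {k: _json_safe(v) for k, v in stack.metadata.items()
                   if not isinstance(v, np.ndarray)}
        f.attrs["metadata_json"] = json.dumps(scalars)
        truth = f.create_group("truth")
        for k, v in stack.metadata.items():
            if isinstance(v, np.ndarray):
                truth.create_dataset(k, data=v)
    return path


def read_stack_hdf5(path) -> WidefieldStack:
    path = Path(path)
    with h5py.File(path, "r") as f:
        if "tau_us" not in f or "on" not in f or "off" not in f:
            raise StackFormatError(f"{path} lacks tau_us/on/off datasets")
        tau = f["tau_us"][...]
        on = f["on"][...]
        off = f["off"][...]
        meta = json.loads(f.attrs.get("metadata_json", "{}"))
        if "truth" in f:
            for k in f["truth"]:
                meta[k] = f["truth"][k][...]
        return WidefieldStack(tau=tau, on=on, off=off,
                              pixel_size_nm=float(f.attrs["pixel_size_nm"]),
                              metadata=meta)


def write_stack(stack: WidefieldStack, path) -> Path:
    """Dispatch on extension: ``.h5``/``.hdf5`` or ``.tif``/``.tiff``."""
    suffix = Path(path).suffix.lower()
    if suffix in (".h5", ".hdf5"):
        return write_stack_hdf5(stack, path)
    if suffix in (".tif", ".tiff"):
        return write_stack_tiff(stack, path)
    raise StackFormatError(f"unsupported stack extension {suffix!r}")


def read_stack(path) -> WidefieldStack:
    suffix = Path(path).suffix.lower()
    if suffix in (".h5", ".hdf5"):
        return read_stack_hdf5(path)
    if suffix in (".tif", ".tiff"):
        return read_stack_tiff(path)
    raise StackFormatError(f"unsupported stack extension {suffix!r}")


def write_calibration(table: CalibrationTable, csv_path, extra_sidecar: dict | None = None) -> Path:
    csv_path = Path(csv_path)
    df = pd.DataFrame(
        {
            "h_nm": table.h_nm,
            "t1_us_mean": table.t1_us_mean,
            "t1_us_sd": table.t1_us_sd,
            "replicates": table.replicates,
        }
    )
    df.to_csv(csv_path, index=False)
    sidecar = {"metadata": _json_safe(table.metadata)}
    if extra_sidecar:
        sidecar.update(_json_safe(extra_sidecar))
    Path(csv_path.with_suffix(".json")).write_text(json.dumps(sidecar, indent=1))
    return csv_path


def read_calibration(csv_path) -> CalibrationTable:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    meta = {}
    sidecar = csv_path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text()).get("metadata", {}) or {}
    return CalibrationTable(
        h_nm=df["h_nm"].to_numpy(),
        t1_us_mean=df["t1_us_mean"].to_numpy(),
        t1_us_sd=df["t1_us_sd"].to_numpy(),
        replicates=int(df["replicates"].iloc[0]),
        metadata=meta,
    )


def write_t1_map(t1map: T1Map, path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        for name in ("t1", "b", "a", "c", "residual_norm"):
            f.create_dataset(name, data=getattr(t1map, name))
        f.create_dataset("converged", data=t1map.converged)
        f.attrs["binning"] = t1map.binning
        f.attrs["pixel_size_nm"] = t1map.pixel_size_nm
        f.attrs["metadata_json"] = json.dumps(_json_safe(t1map.metadata))
    return path


def read_t1_map(path) -> T1Map:
    with h5py.File(path, "r") as f:
        return T1Map(
            t1=f["t1"][...], b=f["b"][...], a=f["a"][...], c=f["c"][...],
            residual_norm=f["residual_norm"][...], converged=f["converged"][...].astype(bool),
            binning=int(f.attrs["binning"]), pixel_size_nm=float(f.attrs["pixel_size_nm"]),
            metadata=json.loads(f.attrs.get("metadata_json", "{}")),
        )


def write_force_map(fmap: ForceMap, path, csv_summary_path=None) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("extension_nm", data=fmap.extension_nm)
        f.create_dataset("force_pn", data=fmap.force_pn)
        f.create_dataset("pixel_class", data=fmap.pixel_class)
        f.create_dataset("clamped", data=fmap.clamped)
        f.attrs["pixel_size_nm"] = fmap.pixel_size_nm
        f.attrs["class_legend"] = json.dumps({c.name.lower(): int(c) for c in PixelClass})
        f.attrs["provenance_json"] = json.dumps(_json_safe(fmap.provenance))
    if csv_summary_path is not None:
        counts = fmap.class_counts()
        pd.DataFrame(
            {"pixel_class": list(counts), "n_pixels": list(counts.values())}
        ).to_csv(csv_summary_path, index=False)
    return path


def save_force_png(fmap: ForceMap, path, dpi: int = 150):
    """Optional rendering hook: force map as a PNG heatmap."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    extent_um = np.array([0, fmap.shape[1], fmap.shape[0], 0]) * fmap.pixel_size_nm / 1000
    im = ax.imshow(fmap.force_pn, extent=extent_um, cmap="magma")
    fig.colorbar(im, ax=ax, label="force (pN)")
    ax.set_xlabel("x (um)")
    ax.set_ylabel("y (um)")
    fig.tight_layout()
    fig.savefig(path, dpi=dpi)
    plt.close(fig)
    return Path(path)
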