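"""File I/O: HDF5 containers for stacks / truth fields / reconstructions,
TIFF import/export, and convergence-history CSV.

HDF5 containers carry a ``format_version`` attribute and a fixed attribute
schema; readers validate the schema and raise :class:`SchemaError` naming the
first missing field.  Float payloads round-trip bitwise.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .containers import ComplexField, MeasurementStack, ReconResult

__all__ = [
    "SchemaError",
    "write_stack",
    "read_stack",
    "write_field",
    "read_field",
    "write_recon",
    "read_recon",
    "export_stack_tiff",
    "import_stack_tiff",
    "export_recon_tiff",
    "write_history_csv",
    "read_history_csv",
]

FORMAT_VERSION = 1

_STACK_ATTRS = ("wavelength_um", "z_um", "pitch_um", "sigma", "grid_shape",
                "crop_shape", "crop_offset")


class SchemaError(ValueError):
    """A container file is missing a required attribute or is inconsistent."""


def _require(attrs, name: str, path) -> object:
    if name not in attrs:
        raise SchemaError(f"{path}: missing required attribute {name!r}")
    return attrs[name]


def write_stack(path, stack: MeasurementStack, modulations=None) -> None:
    """Write a MeasurementStack (and optionally the K modulation phase maps)."""
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["kind"] = "measurement_stack"
        dset = f.create_dataset("intensities", data=stack.intensities)
        for name in ("wavelength_um", "z_um", "pitch_um"):
            f.attrs[name] = getattr(stack, name)
        f.attrs["sigma"] = stack.sigma
        f.attrs["grid_shape"] = stack.grid_shape
        f.attrs["crop_shape"] = stack.crop_shape
        f.attrs["crop_offset"] = stack.crop_offset
        if stack.truth_hash is not None:
            f.attrs["truth_hash"] = stack.truth_hash
        if stack.weights is not None:
            f.create_dataset("weights", data=stack.weights)
        if modulations is not None:
            f.create_dataset(
                "modulation_phases", data=np.stack([m.phase for m in modulations])
            )
        del dset


def read_stack(path):
    """Read a stack; returns (MeasurementStack, modulation phase array or None)."""
    with h5py.File(path, "r") as f:
        for name in _STACK_ATTRS:
            _require(f.attrs, name, path)
        if "intensities" not in f:
            raise SchemaError(f"{path}: missing dataset 'intensities'")
        sigma = tuple(int(v) for v in f.attrs["sigma"])
        crop_shape = tuple(int(v) for v in f.attrs["crop_shape"])
        intensities = f["intensities"][()]
        expected = (crop_shape[0] // sigma[0], crop_shape[1] // sigma[1])
        if intensities.shape[1:] != expected:
            raise SchemaError(
                f"{path}: intensity shape {intensities.shape[1:]} inconsistent "
                f"with crop_shape {crop_shape} and sigma {sigma}"
            )
        stack = MeasurementStack(
            intensities=intensities,
            wavelength_um=float(f.attrs["wavelength_um"]),
            z_um=float(f.attrs["z_um"]),
            pitch_um=float(f.attrs["pitch_um"]),
            sigma=sigma,
            grid_shape=tuple(int(v) for v in f.attrs["grid_shape"]),
            crop_shape=crop_shape,
            crop_offset=tuple(int(v) for v in f.attrs["crop_offset"]),
            weights=f["weights"][()] if "weights" in f else None,
            truth_hash=str(f.attrs["truth_hash"]) if "truth_hash" in f.attrs else None,
        )
        mods = f["modulation_phases"][()] if "modulation_phases" in f else None
    return stack, mods


def write_field(path, fld: ComplexField) -> None:
    """Write a complex field (e.g. the ground truth) to HDF5."""
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["kind"] = "complex_field"
        f.attrs["pitch_um"] = fld.pitch
        f.attrs["wavelength_um"] = fld.wavelength
        f.create_dataset("real", data=fld.values.real)
        f.create_dataset("imag", data=fld.values.imag)


def read_field(path) -> ComplexField:
    with h5py.File(path, "r") as f:
        _require(f.attrs, "pitch_um", path)
        _require(f.attrs, "wavelength_um", path)
        if "real" not in f or "imag" not in f:
            raise SchemaError(f"{path}: missing dataset 'real'/'imag'")
        values = f["real"][()] + 1j * f["imag"][()]
        return ComplexField(
            values, pitch=float(f.attrs["pitch_um"]), wavelength=float(f.attrs["wavelength_um"])
        )


def write_recon(path, result: ReconResult) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["kind"] = "reconstruction"
        f.attrs["gamma_used"] = result.gamma_used
        f.attrs["pitch_um"] = result.x_hat.pitch
        f.attrs["wavelength_um"] = result.x_hat.wavelength
        f.attrs["config_json"] = json.dumps(result.config)
        f.create_dataset("real", data=result.x_hat.values.real)
        f.create_dataset("imag", data=result.x_hat.values.imag)
        hist = f.create_group("history")
        for col in result.history.columns:
            hist.create_dataset(str(col), data=result.history[col].to_numpy())


def read_recon(path) -> ReconResult:
    with h5py.File(path, "r") as f:
        for name in ("gamma_used", "pitch_um", "wavelength_um", "config_json"):
            _require(f.attrs, name, path)
        values = f["real"][()] + 1j * f["imag"][()]
        x_hat = ComplexField(
            values, pitch=float(f.attrs["pitch_um"]), wavelength=float(f.attrs["wavelength_um"])
        )
        history = pd.DataFrame({name: ds[()] for name, ds in f["history"].items()})
        if "iter" in history.columns:
            history = history.sort_values("iter").reset_index(drop=True)
            history["iter"] = history["iter"].astype(int)
        return ReconResult(
            x_hat=x_hat,
            history=history,
            gamma_used=float(f.attrs["gamma_used"]),
            config=json.loads(f.attrs["config_json"]),
        )


# -- TIFF directory format -------------------------------------------------

def export_stack_tiff(directory, stack: MeasurementStack, modulations=None) -> None:
    """16-bit TIFF per measurement plus a YAML sidecar with the metadata and
    the intensity scale (intensities are stored as value/scale * 65535)."""
    import tifffile

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scale = float(stack.intensities.max()) or 1.0
    for k in range(stack.K):
        img = np.round(stack.intensities[k] / scale * 65535.0).astype(np.uint16)
        tifffile.imwrite(directory / f"measurement_{k:03d}.tif", img)
    if modulations is not None:
        for k, m in enumerate(modulations):
            tifffile.imwrite(
                directory / f"modulation_{k:03d}.tif", m.phase.astype(np.float32)
            )
    meta = {
        "format_version": FORMAT_VERSION,
        "K": int(stack.K),
        "intensity_scale": scale,
        "wavelength_um": float(stack.wavelength_um),
        "z_um": float(stack.z_um),
        "pitch_um": float(stack.pitch_um),
        "sigma": list(stack.sigma),
        "grid_shape": list(stack.grid_shape),
        "crop_shape": list(stack.crop_shape),
        "crop_offset": list(stack.crop_offset),
    }
    with open(directory / "stack.yaml", "w") as fh:
        yaml.safe_dump(meta, fh)


def import_stack_tiff(directory) -> MeasurementStack:
    import tifffile

    directory = Path(directory)
    sidecar = directory / "stack.yaml"
    if not sidecar.exists():
        raise SchemaError(f"{directory}: missing sidecar stack.yaml")
    with open(sidecar) as fh:
        meta = yaml.safe_load(fh)
    for name in ("K", "intensity_scale") + tuple(_STACK_ATTRS):
        _require(meta, name, sidecar)
    imgs = [
        tifffile.imread(directory / f"measurement_{k:03d}.tif").astype(np.float64)
        for k in range(int(meta["K"]))
    ]
    intensities = np.stack(imgs) / 65535.0 * float(meta["intensity_scale"])
    return MeasurementStack(
        intensities=intensities,
        wavelength_um=float(meta["wavelength_um"]),
        z_um=float(meta["z_um"]),
        pitch_um=float(meta["pitch_um"]),
        sigma=tuple(meta["sigma"]),
        grid_shape=tuple(meta["grid_shape"]),
        crop_shape=tuple(meta["crop_shape"]),
        crop_offset=tuple(meta["crop_offset"]),
    )


def export_recon_tiff(directory, result: ReconResult) -> None:
    """Amplitude and phase of the estimate as 32-bit float TIFFs, plus the
    convergence history as CSV."""
    import tifffile

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        directory / "amplitude.tif", np.abs(result.x_hat.values).astype(np.float32)
    )
    tifffile.imwrite(
        directory / "phase.tif", np.angle(result.x_hat.values).astype(np.float32)
    )
    write_history_csv(directory / "history.csv", result.history)


def write_history_csv(path, history: pd.DataFrame) -> None:
    """Convergence history CSV; floats printed with repr round-trip precision."""
    history.to_csv(path, index=False, float_format="%.17g")


def read_history_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")
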