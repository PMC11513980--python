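"""Readers, writers, and provenance.

Hyperspectral frame series live in HDF5 (``frames[t, y, x']`` plus
exposure/galvo/stage/timestamp metadata); multi-page TIFF stacks are
accepted for input with a YAML metadata sidecar (vendor cameras emit
TIFF).  Spectra and phase tables are CSV, calibration models YAML, RGB
composites PNG.  Every file carries a provenance block (config hash,
seed, software version) so a run can be reproduced from its outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .errors import SchemaError
from .types import CalibrationModel, FrameSeries, Spectrum

__all__ = [
    "make_provenance",
    "config_hash",
    "write_frame_series",
    "read_frame_series",
    "write_spectra_csv",
    "read_spectra_csv",
    "save_calibration",
    "load_calibration",
    "write_phase_table_csv",
    "write_rgb_png",
    "read_reference_peaks",
]

_SERIES_FIELDS = ("exposure", "galvo_y", "stage_y", "timestamps")


def config_hash(config: dict) -> str:
    """Stable hash of a configuration mapping (order-independent)."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def make_provenance(config: dict, seed=None) -> dict:
    return {
        "software": f"opmraman {__version__}",
        "config_hash": config_hash(config),
        "seed": seed,
        "config": config,
    }


def write_frame_series(path, series: FrameSeries, provenance=None):
    """Write a frame series to HDF5 (deterministic layout)."""
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("frames", data=np.asarray(series.frames),
                         track_times=False)
        f.create_dataset("stage_y", data=series.stage_y, track_times=False)
        f.create_dataset("timestamps", data=series.timestamps,
                         track_times=False)
        f.attrs["exposure"] = series.exposure
        f.attrs["galvo_y"] = series.galvo_y
        if provenance:
            f.attrs["provenance"] = json.dumps(provenance, default=str)
    return path


def read_frame_series(path) -> FrameSeries:
    """Read a frame series from HDF5 or a TIFF stack with YAML sidecar.

    Raises :class:`SchemaError` naming the first missing field.
    """
    import h5py

    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            if "frames" not in f:
                raise SchemaError("missing dataset 'frames'")
            for key in ("exposure", "galvo_y"):
                if key not in f.attrs:
                    raise SchemaError(f"missing attribute '{key}'")
            frames = f["frames"][...]
            n = len(frames)
            stage = f["stage_y"][...] if "stage_y" in f else np.zeros(n)
            ts = (f["timestamps"][...] if "timestamps" in f
                  else float(f.attrs["exposure"]) * np.arange(n))
            return FrameSeries(frames, exposure=float(f.attrs["exposure"]),
                               galvo_y=float(f.attrs["galvo_y"]),
                               stage_y=stage, timestamps=ts)
    # TIFF stack + sidecar
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    sidecar = path.with_suffix(path.suffix + ".yaml")
    if not sidecar.exists():
        raise SchemaError(f"missing metadata sidecar '{sidecar.name}'")
    meta = yaml.safe_load(sidecar.read_text())
    for key in ("exposure", "galvo_y"):
        if key not in meta:
            raise SchemaError(f"missing metadata field '{key}'")
    n = len(frames)
    return FrameSeries(
        frames, exposure=float(meta["exposure"]),
        galvo_y=float(meta["galvo_y"]),
        stage_y=np.asarray(meta.get("stage_y", np.zeros(n)), dtype=float),
        timestamps=np.asarray(
            meta.get("timestamps", float(meta["exposure"]) * np.arange(n)),
            dtype=float),
    )


def _provenance_header(provenance):
    if not provenance:
        return ""
    slim = {k: v for k, v in provenance.items() if k != "config"}
    return "".join(f"# {k}: {v}\n" for k, v in slim.items())


def write_spectra_csv(path, spectra, provenance=None):
    """Spectra as CSV columns (shift_cm1, intensity_0.., [label_i])."""
    path = Path(path)
    if isinstance(spectra, Spectrum):
        spectra = [spectra]
    data = {"shift_cm1": spectra[0].shifts}
    labels = []
    for i, sp in enumerate(spectra):
        data[f"intensity_{i}"] = sp.intensities
        labels.append(sp.label or "")
    df = pd.DataFrame(data)
    with open(path, "w") as fh:
        fh.write(_provenance_header(provenance))
        if any(labels):
            fh.write("# labels: " + ",".join(labels) + "\n")
        df.to_csv(fh, index=False)
    return path


def read_spectra_csv(path):
    path = Path(path)
    labels = []
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("# labels:"):
                labels = line.split(":", 1)[1].strip().split(",")
    df = pd.read_csv(path, comment="#")
    shifts = df["shift_cm1"].to_numpy()
    out = []
    for i, col in enumerate(c for c in df.columns if c.startswith("intensity")):
        lab = labels[i] if i < len(labels) and labels[i] else None
        out.append(Spectrum(shifts, df[col].to_numpy(), label=lab))
    return out


def save_calibration(path, model: CalibrationModel, provenance=None):
    doc = {
        "lambda_ref": float(model.lambda_ref),
        "dispersion": float(model.dispersion),
        "galvo_gain": float(model.galvo_gain),
        "tilt_shift_prefactor": float(model.tilt_shift_prefactor),
        "y_ref": float(model.y_ref),
        "x_ref": float(model.x_ref),
        "galvo_ref": float(model.galvo_ref),
        "excitation_nm": float(model.excitation_nm),
        "provenance": json.loads(json.dumps(
            {**model.provenance, **(provenance or {})}, default=float)),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))
    return Path(path)


def load_calibration(path) -> CalibrationModel:
    doc = yaml.safe_load(Path(path).read_text())
    prov = doc.pop("provenance", {}) or {}
    return CalibrationModel(**doc, provenance=prov)


def write_phase_table_csv(path, table, provenance=None):
    df = pd.DataFrame(table.to_records())
    with open(path, "w") as fh:
        fh.write(_provenance_header(provenance))
        df.to_csv(fh, index=False)
    return Path(path)


def write_rgb_png(path, rgb):
    """RGB float image in [0, 1] -> 8-bit PNG."""
    import imageio.v3 as iio

    arr = np.clip(np.asarray(rgb, dtype=float), 0.0, 1.0)
    iio.imwrite(Path(path), (255.0 * arr + 0.5).astype(np.uint8))
    return Path(path)


def read_reference_peaks(path):
    """CSV with columns (compound, shift_cm1) -> list of tuples."""
    df = pd.read_csv(path, comment="#")
    for col in ("compound", "shift_cm1"):
        if col not in df.columns:
            raise SchemaError(f"reference peak table missing column '{col}'")
    return [(str(r.compound), float(r.shift_cm1)) for r in df.itertuples()]
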