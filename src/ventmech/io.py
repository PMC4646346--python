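"""File I/O: NIfTI volumes, CSV recordings, study tables.

Conventions: voxel indices are 0-based with (i, j) in-slice and k the
slice index; all computation happens in index space, the NIfTI affine
only carries the voxel spacing.  CSVs are comma-separated, period
decimal, UTF-8, header required.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import FormatError, SamplingError, SchemaError
from .imaging import VentilationImage
from .mechanics import PressureFlowRecording

RECORDING_COLUMNS = ["time_s", "Pao_cmH2O", "Pes_cmH2O", "Qao_L_per_s"]

__all__ = [
    "read_image", "write_image", "read_recording", "write_recording",
    "read_study_table", "write_study_table", "RECORDING_COLUMNS",
]


def write_image(image: VentilationImage, path) -> None:
    affine = np.diag(list(image.spacing) + [1.0])
    nib.save(nib.Nifti1Image(image.intensities.astype(np.float32), affine), str(path))


def read_image(path) -> VentilationImage:
    """Load a NIfTI magnitude volume; negative intensities are rejected."""
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
    except Exception as exc:  # nibabel raises a zoo of classes
        raise FormatError(f"could not read NIfTI file {path}: {exc}") from exc
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D volume, got ndim={data.ndim}")
    if np.any(data < 0):
        raise ValueError(f"{path}: magnitude volume contains negative intensities")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VentilationImage(data, spacing)


def write_recording(recording: PressureFlowRecording, path) -> None:
    pd.DataFrame({
        "time_s": recording.time_s,
        "Pao_cmH2O": recording.pao,
        "Pes_cmH2O": recording.pes,
        "Qao_L_per_s": recording.qao,
    }).to_csv(path, index=False)


def read_recording(path, jitter_tol: float = 1e-6) -> PressureFlowRecording:
    """Load a pressure-flow CSV; the time axis must be uniform (max
    jitter below ``jitter_tol`` seconds) so the sampling rate can be
    inferred exactly."""
    df = pd.read_csv(path)
    missing = [c for c in RECORDING_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise SamplingError(f"{path}: need at least two samples")
    dt = np.diff(t)
    if dt.min() <= 0 or (dt.max() - dt.min()) > jitter_tol:
        raise SamplingError(f"{path}: time axis is not uniformly sampled")
    fs = 1.0 / float(np.mean(dt))
    return PressureFlowRecording(
        t,
        df["Pao_cmH2O"].to_numpy(dtype=float),
        df["Pes_cmH2O"].to_numpy(dtype=float),
        df["Qao_L_per_s"].to_numpy(dtype=float),
        fs,
    )


def write_study_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_study_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "pc20_censored" in df.columns:
        df["pc20_censored"] = df["pc20_censored"].astype(bool)
    return df
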