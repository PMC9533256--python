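"""Field and result export: CSV, NIfTI, JSON provenance."""

from __future__ import annotations

import json
import platform
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .solver import ThermalField

FLOAT_FMT = "%.6g"


def field_to_csv(field: ThermalField, path: str | Path) -> None:
    """Axisymmetric field as (r_mm, z_mm, T_C) triplets."""
    if field.mode != "axisymmetric":
        raise ValueError("CSV export is for axisymmetric fields; use NIfTI for 3-D")
    r, z = field.axes
    R, Z = np.meshgrid(r, z, indexing="ij")
    df = pd.DataFrame({"r_mm": R.ravel(), "z_mm": Z.ravel(),
                       "T_C": field.temperature.ravel()})
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def field_from_csv(path: str | Path) -> ThermalField:
    df = pd.read_csv(path)
    r = np.unique(df["r_mm"].to_numpy())
    z = np.unique(df["z_mm"].to_numpy())
    T = df["T_C"].to_numpy().reshape(len(r), len(z))
    return ThermalField(mode="axisymmetric", axes=(r, z), temperature=T)


def field_to_nifti(field: ThermalField, path: str | Path) -> None:
    """Voxel field as NIfTI (temperature in degC as float data)."""
    if field.mode != "cartesian3d":
        raise ValueError("NIfTI export is for cartesian3d fields")
    x, y, z = field.axes
    # NIfTI wants a uniform grid; fields on graded grids are resampled to the
    # finest spacing would be huge, so store node coords in the sidecar and
    # use the mean spacing in the affine.
    affine = np.diag([float(np.mean(np.diff(x))), float(np.mean(np.diff(y))),
                      float(np.mean(np.diff(z))), 1.0])
    affine[:3, 3] = (x[0], y[0], z[0])
    nib.save(nib.Nifti1Image(field.temperature.astype(np.float32), affine),
             str(path))
    sidecar = {"time_s": field.time, "x_mm": x.tolist(), "y_mm": y.tolist(),
               "z_mm": z.tolist()}
    p = Path(path)
    p.with_suffix(p.suffix + ".json").write_text(json.dumps(sidecar))


def write_provenance(path: str | Path, config, extra: dict | None = None) -> None:
    """Log parameters, seed and run diagnostics as JSON."""
    from . import __version__
    record = {"braincool_version": __version__,
              "python": platform.python_version(),
              "config": config.to_dict() if hasattr(config, "to_dict")
              else asdict(config)}
    if extra:
        record.update(extra)
    Path(path).write_text(json.dumps(record, indent=2, default=str))
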