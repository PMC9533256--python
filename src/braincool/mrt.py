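"""MR-thermometry (MRT) stack emulation and postprocessing.

Clinical intracranial cooling is monitored by MR thermometry: voxelwise
temperature maps (2 x 2 x 5 mm voxels, ~7.8 s per acquisition) with a
susceptibility artifact that makes voxels within ~3 mm of the probe axis
unreliable.  This module

* synthesizes such stacks from model temperature fields (resampling onto
  the acquisition grid + additive Gaussian noise, seeded), and
* reproduces the clinical postprocessing chain: per-axial-slice 2-D
  Gaussian filtering (sigma = 0.8 acquisition voxels) followed by order-3
  spline interpolation to a final in-plane voxel size of 0.5 x 0.5 mm
  (slices stay 5 mm),

so that model and "clinical" data can be compared like for like without any
patient data.  Downstream statistics (radial temperature profiles with
standard errors, cooled-area time series) mirror the clinical analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import AlreadyProcessedError, GeometryError
from .solver import ThermalField

ACQ_VOXEL = (2.0, 2.0, 5.0)       # mm, acquisition geometry
FRAME_INTERVAL = 7.8              # s
ARTIFACT_RADIUS = 3.0             # mm around the probe axis
PROCESSED_INPLANE = 0.5           # mm, after spline interpolation
GAUSSIAN_SIGMA = 0.8              # acquisition voxels, in-plane


@dataclass
class ThermometryStack:
    """Time series of voxel temperature frames.

    ``frames`` has shape (n_times, nx, ny, n_slices) in degC; ``x``/``y`` are
    in-plane voxel-center coordinates (mm, probe axis near the origin) and
    ``slice_z`` the axial slice positions.  ``artifact_mask`` flags in-plane
    voxels within ``artifact_radius`` of the probe axis as unreliable.
    """

    frames: np.ndarray
    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    slice_z: np.ndarray
    probe_axis: tuple[float, float] = (0.0, 0.0)
    artifact_radius: float = ARTIFACT_RADIUS
    processed: bool = False
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        nt, nx, ny, ns = self.frames.shape
        if (len(self.times), len(self.x), len(self.y), len(self.slice_z)) \
                != (nt, nx, ny, ns):
            raise GeometryError("frame shape inconsistent with axes")

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        dz = float(self.slice_z[1] - self.slice_z[0]) if len(self.slice_z) > 1 \
            else ACQ_VOXEL[2]
        return (float(self.x[1] - self.x[0]), float(self.y[1] - self.y[0]), dz)

    @property
    def artifact_mask(self) -> np.ndarray:
        """In-plane boolean mask (nx, ny): True where unreliable."""
        X, Y = np.meshgrid(self.x - self.probe_axis[0],
                           self.y - self.probe_axis[1], indexing="ij")
        return np.hypot(X, Y) <= self.artifact_radius + 1e-9

    def min_temperature_centroid(self) -> tuple[float, float]:
        """In-plane position of the coldest voxel of the final frame (center
        slice) — the default probe-centroid estimate."""
        ns = self.frames.shape[3]
        img = self.frames[-1, :, :, ns // 2]
        i, j = np.unravel_index(np.argmin(img), img.shape)
        return float(self.x[i]), float(self.y[j])


@dataclass
class RadialProfile:
    """Mean temperature and standard error vs in-plane distance from the
    probe, at one time point."""

    distances: np.ndarray
    mean: np.ndarray
    se: np.ndarray
    n_voxels: np.ndarray
    time: float

    @property
    def missing(self) -> np.ndarray:
        """Distances where every intersecting voxel was artifact-masked."""
        return self.n_voxels == 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time, "distance_mm": self.distances,
                             "mean_C": self.mean, "se_C": self.se,
                             "n_voxels": self.n_voxels})


def synthesize_stack(fields: list[ThermalField], noise_sd: float = 0.0,
                     seed: int | None = None, in_plane_extent: float = 64.0,
                     voxel_size: tuple[float, float, float] = ACQ_VOXEL,
                     n_slices: int = 3,
                     artifact_radius: float = ARTIFACT_RADIUS) -> ThermometryStack:
    """Emulate an MRT acquisition of the given model fields.

    Each field is resampled (linear) onto the acquisition voxel grid centered
    on the probe axis; i.i.d. Gaussian noise of ``noise_sd`` degC is added per
    voxel.  Deterministic for a fixed seed.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if not fields:
        raise ValueError("need at least one field")
    ref = fields[0]
    for f in fields[1:]:
        if f.mode != ref.mode or len(f.axes) != len(ref.axes) or any(
                len(a) != len(b) or not np.allclose(a, b)
                for a, b in zip(f.axes, ref.axes)):
            raise GeometryError("all fields must share one grid geometry")

    vx, vy, vz = voxel_size
    nx = max(2, int(round(in_plane_extent / vx)))
    ny = max(2, int(round(in_plane_extent / vy)))
    x = (np.arange(nx) - (nx - 1) / 2.0) * vx
    y = (np.arange(ny) - (ny - 1) / 2.0) * vy
    slice_z = (np.arange(n_slices) - (n_slices - 1) / 2.0) * vz

    rng = np.random.default_rng(seed)
    X, Y = np.meshgrid(x, y, indexing="ij")
    rr = np.hypot(X, Y)
    frames = np.empty((len(fields), nx, ny, n_slices))
    for ti, f in enumerate(fields):
        interp = f.interpolator()
        for si, z0 in enumerate(slice_z):
            if f.mode == "axisymmetric":
                pts = np.column_stack([rr.ravel(), np.full(rr.size, z0)])
            else:
                pts = np.column_stack([X.ravel(), Y.ravel(),
                                       np.full(X.size, z0)])
            frames[ti, :, :, si] = interp(pts).reshape(nx, ny)
        if noise_sd > 0:
            frames[ti] += rng.normal(0.0, noise_sd, frames[ti].shape)

    times = np.array([f.time for f in fields], dtype=float)
    return ThermometryStack(frames=frames, times=times, x=x, y=y,
                            slice_z=slice_z, artifact_radius=artifact_radius,
                            meta={"noise_sd": noise_sd, "seed": seed})


def postprocess_stack(stack: ThermometryStack,
                      sigma_voxels: float = GAUSSIAN_SIGMA,
                      target_inplane: float = PROCESSED_INPLANE) -> ThermometryStack:
    """Clinical postprocessing: per-slice 2-D Gaussian filter then order-3
    spline resampling of the in-plane axes to ``target_inplane`` mm.

    Every frame and slice is processed identically.  Calling this on an
    already-processed stack raises, so data can never be silently
    double-filtered.
    """
    if stack.processed:
        raise AlreadyProcessedError("stack has already been postprocessed")
    vx, vy, _ = stack.voxel_size
    fx, fy = vx / target_inplane, vy / target_inplane
    nt, nx, ny, ns = stack.frames.shape
    out = np.empty((nt, int(round(nx * fx)), int(round(ny * fy)), ns))
    for ti in range(nt):
        for si in range(ns):
            img = ndimage.gaussian_filter(stack.frames[ti, :, :, si],
                                          sigma=sigma_voxels, mode="nearest")
            out[ti, :, :, si] = ndimage.zoom(img, (fx, fy), order=3,
                                             mode="nearest", grid_mode=True)
    # grid_mode zoom keeps the physical cell extents; new voxel centers are
    # offset half an old voxel plus half a new one from the old first center
    x_new = stack.x[0] - vx / 2 + (np.arange(out.shape[1]) + 0.5) * target_inplane
    y_new = stack.y[0] - vy / 2 + (np.arange(out.shape[2]) + 0.5) * target_inplane
    return ThermometryStack(frames=out, times=stack.times.copy(),
                            x=x_new, y=y_new, slice_z=stack.slice_z.copy(),
                            probe_axis=stack.probe_axis,
                            artifact_radius=stack.artifact_radius,
                            processed=True, meta=dict(stack.meta))


def radial_profile(stack: ThermometryStack,
                   centroid: tuple[float, float] | None = None,
                   distances: np.ndarray | None = None,
                   frame: int = -1, bin_width: float = 0.5,
                   slices: str = "all") -> RadialProfile:
    """Mean and standard error of temperature on concentric circles.

    Voxels whose in-plane center lies within ``bin_width/2`` of each distance
    intersect that circle; artifact voxels (within the artifact radius of the
    probe axis) are excluded.  ``centroid`` defaults to the coldest voxel of
    the final frame.
    """
    if distances is None:
        distances = np.arange(3.5, 20.0 + 1e-9, 0.5)
    distances = np.asarray(distances, dtype=float)
    if np.any(distances <= stack.artifact_radius):
        raise ValueError("distances must exceed the artifact radius "
                         f"({stack.artifact_radius} mm)")
    cx, cy = centroid if centroid is not None else stack.min_temperature_centroid()
    X, Y = np.meshgrid(stack.x - cx, stack.y - cy, indexing="ij")
    dist = np.hypot(X, Y)
    reliable = ~stack.artifact_mask
    img = stack.frames[frame]
    if slices == "center":
        img = img[:, :, img.shape[2] // 2][:, :, None]

    mean = np.full(distances.shape, np.nan)
    se = np.full(distances.shape, np.nan)
    n = np.zeros(distances.shape, dtype=int)
    for i, d in enumerate(distances):
        ring = (np.abs(dist - d) <= bin_width / 2) & reliable
        vals = img[ring, :].ravel()
        n[i] = vals.size
        if vals.size:
            mean[i] = vals.mean()
            se[i] = vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else 0.0
    return RadialProfile(distances=distances, mean=mean, se=se, n_voxels=n,
                         time=float(stack.times[frame]))


def _infill_artifact(img: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Replace masked voxels by their nearest reliable voxel (the first
    reliable annulus, radially, for a centered circular mask)."""
    if not mask.any():
        return img
    _, (ii, jj) = ndimage.distance_transform_edt(mask, return_indices=True)
    out = img.copy()
    out[mask] = img[ii[mask], jj[mask]]
    return out


def cooled_area_timeseries(stack: ThermometryStack,
                           thresholds: dict[str, float] | None = None
                           ) -> pd.DataFrame:
    """Per-frame in-plane area (mm^2) below each threshold, center slice.

    The artifact core is infilled from the surrounding reliable voxels before
    thresholding.  Returns a long-format DataFrame
    (time_s, stratum, threshold_C, area_mm2).
    """
    if not stack.processed:
        raise ValueError("cooled_area_timeseries expects a postprocessed stack")
    from .votc import THRESHOLDS
    thresholds = thresholds or THRESHOLDS
    vx, vy, _ = stack.voxel_size
    mask = stack.artifact_mask
    ns = stack.frames.shape[3]
    rows = []
    for ti, t in enumerate(stack.times):
        img = _infill_artifact(stack.frames[ti, :, :, ns // 2], mask)
        for name, thr in thresholds.items():
            rows.append({"time_s": float(t), "stratum": name,
                         "threshold_C": thr,
                         "area_mm2": float((img < thr).sum() * vx * vy)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# NIfTI I/O (temperature as float data; times and geometry in a JSON sidecar)

def save_stack(stack: ThermometryStack, path: str | Path) -> None:
    path = Path(path)
    vx, vy, vz = stack.voxel_size
    affine = np.diag([vx, vy, vz, 1.0])
    affine[:3, 3] = (stack.x[0], stack.y[0], stack.slice_z[0])
    data = np.moveaxis(stack.frames, 0, -1)  # (x, y, z, t)
    nib.save(nib.Nifti1Image(data.astype(np.float32), affine), str(path))
    sidecar = {"times_s": stack.times.tolist(),
               "probe_axis_mm": list(stack.probe_axis),
               "artifact_radius_mm": stack.artifact_radius,
               "processed": stack.processed, "meta": stack.meta}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_stack(path: str | Path) -> ThermometryStack:
    path = Path(path)
    img = nib.load(str(path))
    data = np.moveaxis(np.asarray(img.dataobj, dtype=float), -1, 0)
    affine = img.affine
    nx, ny, ns = data.shape[1:]
    x = affine[0, 3] + np.arange(nx) * affine[0, 0]
    y = affine[1, 3] + np.arange(ny) * affine[1, 1]
    z = affine[2, 3] + np.arange(ns) * affine[2, 2]
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return ThermometryStack(frames=data, times=np.asarray(sidecar["times_s"]),
                            x=x, y=y, slice_z=z,
                            probe_axis=tuple(sidecar["probe_axis_mm"]),
                            artifact_radius=sidecar["artifact_radius_mm"],
                            processed=sidecar["processed"],
                            meta=sidecar.get("meta", {}))
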