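"""NIfTI / YAML / CSV input–output and cross-grid mask resampling.

Volumes are written as NIfTI-1 with a diagonal affine built from the
voxel spacing (shared world origin at voxel (0,0,0)); the semantic
role is stored in the header ``descrip`` field.  Time series are 4-D
NIfTI files with a YAML sidecar carrying the acquisition schedule.
Real-data deformable registration is out of scope here: phantom
modalities share one world frame by construction, so nearest-neighbour
resampling between grids is sufficient (plug an external registration
in front of :func:`resample_mask` for real data).
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .core import AcquisitionSchedule, LobarMaskSet, TimeSeries4D, VOLUME_ROLES, VoxelGrid3D

__all__ = [
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_timeseries",
    "write_timeseries",
    "read_schedule",
    "write_schedule",
    "resample_mask",
]


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def write_volume(vol: VoxelGrid3D, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(vol.values, dtype=np.float64), _affine(vol.spacing))
    img.header["descrip"] = vol.role.encode()
    nib.save(img, str(path))


def read_volume(path: str | Path, role: str | None = None) -> VoxelGrid3D:
    """Read a 3-D NIfTI volume; errors on any other dimensionality."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got ndim={data.ndim}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if role is None:
        descrip = img.header["descrip"].tobytes().split(b"\x00")[0].decode(errors="ignore")
        role = descrip if descrip in VOLUME_ROLES else "hpx_signal"
    return VoxelGrid3D(values=data, spacing=spacing, role=role)


def write_mask(masks: LobarMaskSet, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(masks.labels, dtype=np.int16), _affine(masks.spacing))
    nib.save(img, str(path))


def read_mask(path: str | Path) -> LobarMaskSet:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D label volume, got ndim={data.ndim}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LobarMaskSet(labels=np.asarray(np.rint(data), dtype=np.int16), spacing=spacing)


def write_schedule(schedule: AcquisitionSchedule, path: str | Path) -> None:
    payload = {
        "n_volumes": int(schedule.n_volumes),
        "volume_times": [float(t) for t in schedule.volume_times],
        "pulses_per_volume": int(schedule.pulses_per_volume),
        "slice_time_offsets": (
            None if schedule.slice_time_offsets is None else [float(t) for t in schedule.slice_time_offsets]
        ),
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_schedule(path: str | Path) -> AcquisitionSchedule:
    payload = yaml.safe_load(Path(path).read_text())
    offsets = payload.get("slice_time_offsets")
    return AcquisitionSchedule(
        n_volumes=int(payload["n_volumes"]),
        volume_times=np.asarray(payload["volume_times"], dtype=float),
        pulses_per_volume=int(payload["pulses_per_volume"]),
        slice_time_offsets=None if offsets is None else np.asarray(offsets, dtype=float),
    )


def write_timeseries(ts: TimeSeries4D, nii_path: str | Path, schedule_path: str | Path | None = None) -> None:
    img = nib.Nifti1Image(ts.as_array().astype(np.float64), _affine(ts.spacing))
    img.header["descrip"] = b"hpx_signal"
    nib.save(img, str(nii_path))
    if schedule_path is not None:
        write_schedule(ts.schedule, schedule_path)


def read_timeseries(nii_path: str | Path, schedule_path: str | Path) -> TimeSeries4D:
    img = nib.load(str(nii_path))
    data = np.asarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"{nii_path}: expected a 4-D time series, got ndim={data.ndim}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    schedule = read_schedule(schedule_path)
    volumes = [
        VoxelGrid3D(values=data[..., k], spacing=spacing, role="hpx_signal") for k in range(data.shape[-1])
    ]
    return TimeSeries4D(volumes=volumes, schedule=schedule)


def resample_mask(masks: LobarMaskSet, target_shape, target_spacing) -> LobarMaskSet:
    """Nearest-neighbour label resampling to a target grid.

    Both grids share the phantom world frame (origin at the centre of
    voxel (0,0,0), world = index x spacing).  Labels are carried over
    unchanged — nearest neighbour can never invent a label — and every
    lobe must survive the resampling or an error advises a finer grid.
    """
    target_shape = tuple(int(n) for n in target_shape)
    target_spacing = tuple(float(s) for s in target_spacing)
    idx = []
    for ax in range(3):
        world = np.arange(target_shape[ax]) * target_spacing[ax]
        src = np.rint(world / masks.spacing[ax]).astype(int)
        idx.append(np.clip(src, 0, masks.shape[ax] - 1))
    labels = masks.labels[np.ix_(idx[0], idx[1], idx[2])]
    out = LobarMaskSet(labels=labels, spacing=target_spacing)
    for name, n in out.lobe_voxel_counts().items():
        if n == 0:
            raise ValueError(
                f"lobe {name} vanished when resampling to grid {target_shape} at "
                f"{target_spacing} mm; choose a finer target grid"
            )
    return out
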