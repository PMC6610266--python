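"""Core in-memory containers shared by every pipeline stage.

Axis convention (stated once, used everywhere): volumes are indexed
``(x, y, z)`` with 0-based voxel indices, x running patient-left to
patient-right, y posterior to anterior, z inferior to superior.  The
anterior–posterior coil gradient therefore runs along axis 1.  Voxel
spacing is in millimetres; world coordinates are ``index * spacing``
with a shared origin at the centre of voxel (0, 0, 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Canonical lobe order: right upper/middle/lower, left upper/lower.
LOBE_NAMES: tuple[str, ...] = ("RUL", "RML", "RLL", "LUL", "LLL")

#: Integer label carried by each lobe in a label volume (0 = background).
LOBE_LABELS: dict[str, int] = {name: i + 1 for i, name in enumerate(LOBE_NAMES)}

#: Recognised semantic roles a scalar volume can carry.
VOLUME_ROLES = ("HU", "hpx_signal", "spect_counts", "ventilation_fraction", "alpha_deg")


@dataclass
class VoxelGrid3D:
    """A scalar 3-D volume with voxel spacing and a semantic role tag.

    Parameters
    ----------
    values
        3-D float array of voxel values.
    spacing
        Voxel spacing in mm, one value per axis.
    role
        One of :data:`VOLUME_ROLES`; documents what the values mean
        (Hounsfield units, hyperpolarized signal, SPECT counts, ...).
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    role: str = "hpx_signal"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"VoxelGrid3D requires a 3-D array, got ndim={self.values.ndim}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("VoxelGrid3D values must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        if self.role not in VOLUME_ROLES:
            raise ValueError(f"unknown volume role {self.role!r}; expected one of {VOLUME_ROLES}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_grid(self, other: "VoxelGrid3D | LobarMaskSet") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)


@dataclass
class LobarMaskSet:
    """Five-lobe integer label volume (0 background, 1..5 = RUL..LLL)."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    lobe_names: tuple[str, ...] = LOBE_NAMES

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("LobarMaskSet labels must be a 3-D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("LobarMaskSet labels must be integer-valued")
        extra = set(np.unique(self.labels)) - set(range(len(self.lobe_names) + 1))
        if extra:
            raise ValueError(f"unexpected labels {sorted(extra)} in mask volume")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def lobe_mask(self, lobe: str) -> np.ndarray:
        """Boolean mask of one lobe by name."""
        if lobe not in self.lobe_names:
            raise KeyError(f"unknown lobe {lobe!r}; expected one of {self.lobe_names}")
        return self.labels == LOBE_LABELS[lobe]

    def lung_mask(self) -> np.ndarray:
        """Union of the five lobes (whole lung, no trachea)."""
        return self.labels > 0

    def lobe_voxel_counts(self) -> dict[str, int]:
        return {name: int(np.count_nonzero(self.labels == LOBE_LABELS[name])) for name in self.lobe_names}

    def validate_nonempty(self) -> None:
        for name, n in self.lobe_voxel_counts().items():
            if n == 0:
                raise ValueError(f"lobe {name} is empty")


@dataclass
class AcquisitionSchedule:
    """Timing and RF-pulse bookkeeping for a breath-hold time series.

    The default emulates an 8-volume acquisition spread over a ~20 s
    breath-hold with 8 spiral interleaves per volume: each voxel sees
    ``pulses_per_volume`` RF excitations per volume and volume k is
    acquired at elapsed time ``volume_times[k-1]`` (t=0 at the first).
    Equally spaced volumes with a constant pulse count collapse the
    flip-angle and T1 decay into a single exponential rate, so such a
    schedule cannot separate the two (see ``decay_fit``).
    """

    n_volumes: int = 8
    volume_times: np.ndarray = field(default_factory=lambda: 2.5 * np.arange(8.0))
    pulses_per_volume: int = 8
    slice_time_offsets: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.volume_times = np.asarray(self.volume_times, dtype=float)
        if self.n_volumes < 1:
            raise ValueError("n_volumes must be >= 1")
        if self.volume_times.shape != (self.n_volumes,):
            raise ValueError(
                f"volume_times must have length n_volumes={self.n_volumes}, got {self.volume_times.shape}"
            )
        if np.any(np.diff(self.volume_times) <= 0):
            raise ValueError("volume_times must be strictly increasing")
        if self.pulses_per_volume < 1:
            raise ValueError("pulses_per_volume must be >= 1")
        if self.slice_time_offsets is not None:
            self.slice_time_offsets = np.asarray(self.slice_time_offsets, dtype=float)

    @property
    def is_uniform(self) -> bool:
        """True when volumes are equally spaced in time."""
        if self.n_volumes < 3:
            return True
        dt = np.diff(self.volume_times)
        return bool(np.allclose(dt, dt[0]))

    def pulse_counts(self) -> np.ndarray:
        """Cumulative RF pulses a voxel has experienced before each volume."""
        return self.pulses_per_volume * np.arange(self.n_volumes)

    @classmethod
    def uniform(cls, n_volumes: int = 8, dt: float = 2.5, pulses_per_volume: int = 8) -> "AcquisitionSchedule":
        return cls(n_volumes=n_volumes, volume_times=dt * np.arange(n_volumes), pulses_per_volume=pulses_per_volume)

    @classmethod
    def nonuniform(cls, volume_times: Sequence[float], pulses_per_volume: int = 8) -> "AcquisitionSchedule":
        times = np.asarray(volume_times, dtype=float)
        return cls(n_volumes=len(times), volume_times=times, pulses_per_volume=pulses_per_volume)

    @classmethod
    def identifiable_design(cls, pulses_per_volume: int = 8) -> "AcquisitionSchedule":
        """Non-uniform 8-volume schedule designed to separate α from T1.

        A burst of rapid early volumes (decay dominated by RF
        depletion) followed by sparse late volumes (decay dominated by
        T1) breaks the single-exponential collapse of the uniform
        schedule while staying inside a ~22 s breath-hold.
        """
        return cls.nonuniform([0.0, 1.0, 2.0, 3.0, 4.0, 10.0, 16.0, 22.0], pulses_per_volume)


@dataclass
class TimeSeries4D:
    """Ordered hyperpolarized-signal volumes plus their acquisition schedule."""

    volumes: list[VoxelGrid3D]
    schedule: AcquisitionSchedule

    def __post_init__(self) -> None:
        if len(self.volumes) != self.schedule.n_volumes:
            raise ValueError(
                f"{len(self.volumes)} volumes but schedule declares {self.schedule.n_volumes}"
            )
        first = self.volumes[0]
        for v in self.volumes[1:]:
            if not first.same_grid(v):
                raise ValueError("all volumes in a TimeSeries4D must share one grid")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.volumes[0].shape

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.volumes[0].spacing

    def as_array(self) -> np.ndarray:
        """Stack to a 4-D array with the volume index last (x, y, z, t)."""
        return np.stack([v.values for v in self.volumes], axis=-1)


@dataclass
class SignalCurve:
    """A regional signal–time curve (lobar mean signal per volume)."""

    values: np.ndarray
    schedule: AcquisitionSchedule
    region_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.schedule.n_volumes,):
            raise ValueError("curve length must match schedule.n_volumes")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("curve values must be finite")
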