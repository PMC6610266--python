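"""Forward model of hyperpolarized-gas signal decay during a breath-hold.

Hyperpolarized magnetization is a non-renewable pool: every RF pulse
reads out a fraction sin(α) and leaves cos(α) of the longitudinal
magnetization, while T1 relaxation destroys polarization continuously.
For a voxel that has experienced n_k = P·(k−1) pulses before volume k
(P pulses per volume) acquired at elapsed time t_k, the expected
signal is

    S_k = S0 · sin(α) · cos(α)^(P·(k−1)) · exp(−t_k / T1)

with S0 proportional to the local gas density (ventilation).  Gas
wash-in/washout dynamics are not modelled: the series covers a single
breath-hold only.
"""

from __future__ import annotations

import numpy as np

from .core import AcquisitionSchedule, TimeSeries4D, VoxelGrid3D

__all__ = ["hpx_signal_model", "decay_factors", "simulate_hpx_timeseries"]


def _check_params(alpha_deg, T1_s) -> None:
    # 90 deg is admitted as the degenerate single-shot readout
    # (sin 90 = 1, all magnetization consumed by the first pulse)
    alpha = np.asarray(alpha_deg, dtype=float)
    if np.any(alpha <= 0.0) or np.any(alpha > 90.0):
        raise ValueError("flip angle must lie in (0, 90] degrees")
    if np.any(np.asarray(T1_s, dtype=float) <= 0.0):
        raise ValueError("T1 must be positive")


def hpx_signal_model(
    S0: float,
    alpha_deg: float,
    T1_s: float,
    schedule: AcquisitionSchedule,
    k: int,
) -> float:
    """Expected noiseless signal of volume ``k`` (1-based).

    Strictly decreasing in k for any α in (0°, 90°) and finite T1.
    """
    if not 1 <= k <= schedule.n_volumes:
        raise ValueError(f"volume index k={k} outside 1..{schedule.n_volumes}")
    if S0 < 0:
        raise ValueError("S0 must be >= 0")
    _check_params(alpha_deg, T1_s)
    a = np.deg2rad(alpha_deg)
    n_pulses = schedule.pulse_counts()[k - 1]
    t = schedule.volume_times[k - 1]
    return float(S0 * np.sin(a) * np.cos(a) ** n_pulses * np.exp(-t / T1_s))


def decay_factors(alpha_deg, T1_s, schedule: AcquisitionSchedule) -> np.ndarray:
    """Per-volume decay factors sin(α)·cos(α)^(P(k−1))·exp(−t_k/T1).

    ``alpha_deg`` and ``T1_s`` may be scalars or arrays (broadcast
    against each other); the volume axis is appended last.
    """
    _check_params(alpha_deg, T1_s)
    a = np.deg2rad(np.asarray(alpha_deg, dtype=float))[..., None]
    T1 = np.asarray(T1_s, dtype=float)[..., None]
    n_pulses = schedule.pulse_counts()
    t = schedule.volume_times
    return np.sin(a) * np.cos(a) ** n_pulses * np.exp(-t / T1)


def simulate_hpx_timeseries(
    vent: VoxelGrid3D,
    alpha_map: VoxelGrid3D,
    T1_s,
    schedule: AcquisitionSchedule,
    noise_sd: float = 0.0,
    seed: int = 0,
    signal_scale: float = 1.0,
) -> TimeSeries4D:
    """Simulate the breath-hold time series voxel by voxel.

    Each voxel's noiseless course is the depletion model evaluated at
    its own flip angle (and T1, if a map is given) with
    S0 = signal_scale x ventilation; zero-mean Gaussian noise of sd
    ``noise_sd`` is added to every voxel of every volume.  Negative
    noisy values are kept (no magnitude/Rician bias is modelled).
    """
    if not vent.same_grid(alpha_map):
        raise ValueError("ventilation and flip-angle maps must share one grid")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    T1_arr = np.asarray(T1_s, dtype=float)
    if T1_arr.ndim not in (0, 3):
        raise ValueError("T1 must be a scalar or a 3-D map")
    if T1_arr.ndim == 3 and T1_arr.shape != vent.shape:
        raise ValueError("T1 map must share the ventilation grid")

    # inert-gas voxels (alpha undefined outside the coil model) are fine:
    # the alpha map covers the whole grid by construction
    factors = decay_factors(alpha_map.values, T1_arr, schedule)  # (x,y,z,t)
    S0 = signal_scale * vent.values[..., None]
    signal = S0 * factors
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sd, signal.shape)

    volumes = [
        VoxelGrid3D(values=signal[..., k], spacing=vent.spacing, role="hpx_signal")
        for k in range(schedule.n_volumes)
    ]
    return TimeSeries4D(volumes=volumes, schedule=schedule)
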