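"""Lobar scoring formulas: CT emphysema, HPX ventilation, SPECT V/Q.

Four scores per subject x lobe:

* **CT-%emphysema** — 100 x (lobe voxels with HU strictly below
  −950) / (lobe voxel count); the standard low-attenuation-area
  emphysema index.
* **relative %ventilation** — a lobe's share of the total lung signal,
  100 x Σ(signal in lobe) / Σ(signal in all five lobes).  Normalising
  by the total lung *signal* (rather than lung volume) makes the five
  lobar percentages sum to exactly 100, which is the stated constraint
  of the score; the same formula serves HPX signal and SPECT counts.
* **absolute %ventilation (defect)** — 100 x fraction of lobe voxels
  whose decay-corrected signal falls strictly below 5% of a whole-lung
  reference level.  Higher = more defect.  The reference defaults to
  the 99th percentile of lung-voxel signal (a robust maximum,
  insensitive to hot pixels); mean and max are available as options.
* **SPECT lobar %** — the relative formula applied to count volumes
  with masks nearest-neighbour-resampled to the SPECT grid.

Whole lung means the union of the five lobes (no trachea).  All
threshold comparisons are strict (<).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import LOBE_NAMES, LobarMaskSet, VoxelGrid3D

__all__ = [
    "emphysema_pct",
    "relative_ventilation_pct",
    "absolute_ventilation_defect_pct",
    "spect_lobar_pct",
    "build_score_table",
    "WHOLE_LUNG",
]

WHOLE_LUNG = "WL"

_REFERENCE_MODES = ("p99", "mean", "max")


def _check_grids(vol: VoxelGrid3D, masks: LobarMaskSet) -> None:
    if vol.shape != masks.shape:
        raise ValueError(f"volume grid {vol.shape} does not match mask grid {masks.shape}")


def emphysema_pct(ct: VoxelGrid3D, masks: LobarMaskSet, threshold_hu: float = -950.0) -> pd.Series:
    """Percentage of voxels below the attenuation threshold, per lobe.

    Returns a Series over RUL..LLL plus a whole-lung row.
    """
    _check_grids(ct, masks)
    masks.validate_nonempty()
    low = ct.values < threshold_hu
    out = {}
    for name in LOBE_NAMES:
        m = masks.lobe_mask(name)
        out[name] = 100.0 * np.count_nonzero(low & m) / np.count_nonzero(m)
    lung = masks.lung_mask()
    out[WHOLE_LUNG] = 100.0 * np.count_nonzero(low & lung) / np.count_nonzero(lung)
    return pd.Series(out, name="ct_emphysema_pct")


def relative_ventilation_pct(signal: VoxelGrid3D, masks: LobarMaskSet) -> pd.Series:
    """Each lobe's share of the total lung signal, summing to 100.

    Works for decay-corrected HPX signal and for SPECT counts alike.
    """
    _check_grids(signal, masks)
    masks.validate_nonempty()
    lung = masks.lung_mask()
    if np.any(signal.values[lung] < 0):
        raise ValueError("relative ventilation requires nonnegative signal inside the lungs")
    sums = np.array([signal.values[masks.lobe_mask(name)].sum() for name in LOBE_NAMES])
    total = sums.sum()
    if total <= 0:
        raise ValueError("total lung signal is zero; relative percentages are undefined")
    out = pd.Series(100.0 * sums / total, index=list(LOBE_NAMES), name="rel_vent_pct")
    out[WHOLE_LUNG] = 100.0
    return out


def absolute_ventilation_defect_pct(
    signal: VoxelGrid3D,
    masks: LobarMaskSet,
    frac: float = 0.05,
    reference: str = "p99",
) -> pd.Series:
    """Percentage of voxels below ``frac`` of the whole-lung signal level.

    ``reference`` selects the whole-lung level the 5% threshold is
    taken from: ``p99`` (default, robust maximum), ``mean`` or ``max``
    of lung-voxel signal.
    """
    _check_grids(signal, masks)
    masks.validate_nonempty()
    if reference not in _REFERENCE_MODES:
        raise ValueError(f"reference must be one of {_REFERENCE_MODES}")
    if not 0 < frac < 1:
        raise ValueError("frac must lie in (0, 1)")
    lung = masks.lung_mask()
    vals = signal.values[lung]
    if np.all(vals == 0):
        raise ValueError("all-zero signal volume; defect score undefined")
    if reference == "p99":
        level = float(np.percentile(vals, 99))
    elif reference == "mean":
        level = float(vals.mean())
    else:
        level = float(vals.max())
    threshold = frac * level
    below = signal.values < threshold
    out = {}
    for name in LOBE_NAMES:
        m = masks.lobe_mask(name)
        out[name] = 100.0 * np.count_nonzero(below & m) / np.count_nonzero(m)
    out[WHOLE_LUNG] = 100.0 * np.count_nonzero(below & lung) / np.count_nonzero(lung)
    return pd.Series(out, name="abs_vent_pct")


def spect_lobar_pct(spect: VoxelGrid3D, masks: LobarMaskSet) -> pd.Series:
    """Relative lobar percentage of a SPECT count volume.

    The masks must already live on the SPECT grid (use
    ``io.resample_mask`` with nearest-neighbour labels).
    """
    return relative_ventilation_pct(spect, masks).rename("spect_pct")


def build_score_table(
    subject_id: str,
    masks: LobarMaskSet,
    ct: VoxelGrid3D | None = None,
    hpx_corrected: VoxelGrid3D | None = None,
    spect_v: VoxelGrid3D | None = None,
    spect_q: VoxelGrid3D | None = None,
    spect_masks: LobarMaskSet | None = None,
    threshold_hu: float = -950.0,
    frac: float = 0.05,
    reference: str = "p99",
) -> pd.DataFrame:
    """Assemble the per-subject lobar score table.

    Rows: one per lobe plus a whole-lung row (lobe = ``WL``).  Missing
    modalities leave their columns as NaN, mirroring subjects that were
    not scanned with a modality.
    """
    idx = pd.MultiIndex.from_product([[subject_id], list(LOBE_NAMES) + [WHOLE_LUNG]], names=["subject_id", "lobe"])
    table = pd.DataFrame(
        index=idx,
        columns=["ct_emphysema_pct", "hpx_rel_vent_pct", "hpx_abs_vent_pct", "spect_vent_pct", "spect_perf_pct"],
        dtype=float,
    )

    def _fill(col: str, series: pd.Series) -> None:
        for lobe, v in series.items():
            table.loc[(subject_id, lobe), col] = v

    if ct is not None:
        _fill("ct_emphysema_pct", emphysema_pct(ct, masks, threshold_hu))
    if hpx_corrected is not None:
        _fill("hpx_rel_vent_pct", relative_ventilation_pct(hpx_corrected, masks))
        _fill("hpx_abs_vent_pct", absolute_ventilation_defect_pct(hpx_corrected, masks, frac, reference))
    sm = spect_masks if spect_masks is not None else masks
    if spect_v is not None:
        _fill("spect_vent_pct", spect_lobar_pct(spect_v, sm))
    if spect_q is not None:
        _fill("spect_perf_pct", spect_lobar_pct(spect_q, sm))
    return table
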