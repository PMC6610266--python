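"""Digital thorax phantom with known ground truth.

Generates synthetic "subjects" for the lobar ventilation pipeline: a
five-lobe lung geometry (two half-ellipsoid lungs cut by oblique
surfaces into 3 right + 2 left lobes), a CT-like attenuation volume
with spatially clustered emphysema below the −950 HU scoring
threshold, smooth ventilation/perfusion maps with clustered lobar
defects, an anterior–posterior coil flip-angle gradient, and
SPECT-like count volumes (Gaussian blur to ~10 mm resolution at ~4 mm
pixels, Poisson counts).

Everything is deterministic under ``PhantomSpec.random_seed``:
independent random streams are derived from the seed with fixed
sub-keys, so e.g. regenerating the ventilation map alone reproduces it
bit-identically.  Emphysema and ventilation-defect voxels are selected
by thresholding the *same* smooth cluster field at per-lobe quantiles,
so structural and functional lesions co-locate the way emphysematous
destruction and ventilation loss do in diseased lungs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import LOBE_NAMES, LobarMaskSet, VoxelGrid3D

# rng sub-keys: one stream per stochastic ingredient
_KEY_CLUSTER = 0
_KEY_HU = 1
_KEY_VENT_BASE = 2
_KEY_VENT_DEFECT = 3
_KEY_PERF_BASE = 4
_KEY_PERF_DEFECT = 5
_KEY_SPECT_V = 6
_KEY_SPECT_Q = 7

_DEFAULT_GEOMETRY = {
    # fractional-coordinate ellipsoids; x runs patient-left -> patient-right
    "left_center": (0.30, 0.50, 0.45),
    "right_center": (0.70, 0.50, 0.45),
    "semi_axes": (0.17, 0.30, 0.38),
    # oblique fissures: iso-surfaces of z - slope*(y - cy) at volume quantiles
    "oblique_slope": 0.4,
    "right_lobe_fracs": (0.35, 0.25, 0.40),  # RUL, RML, RLL volume shares
    "left_lobe_fracs": (0.55, 0.45),  # LUL, LLL volume shares
}


@dataclass
class PhantomSpec:
    """Parameters of one synthetic subject.

    HU distributions straddle the −950 HU emphysema threshold:
    parenchyma N(−850, 40) vs emphysema N(−980, 15), so the seeded
    per-lobe emphysema fractions are recoverable by threshold scoring.
    ``coil_ap_ratio`` is the anterior-to-posterior *signal* ratio
    sin(α_max)/sin(α_min) of the coil profile (the default 2 emulates
    a surface-coil flip-angle inhomogeneity of up to a factor of 2).
    """

    grid_shape: tuple[int, int, int] = (64, 64, 48)
    voxel_spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)
    lobe_geometry_params: dict = field(default_factory=lambda: dict(_DEFAULT_GEOMETRY))
    emphysema_fraction_per_lobe: tuple[float, ...] = (0.05, 0.05, 0.25, 0.05, 0.20)
    ventilation_defect_fraction_per_lobe: tuple[float, ...] = (0.05, 0.05, 0.30, 0.05, 0.25)
    perfusion_defect_fraction_per_lobe: tuple[float, ...] | None = None
    parenchyma_hu_mean: float = -850.0
    parenchyma_hu_sd: float = 40.0
    emphysema_hu_mean: float = -980.0
    emphysema_hu_sd: float = 15.0
    coil_ap_ratio: float = 2.0
    nominal_alpha: float = 10.0  # degrees
    T1_seconds: float = 20.0
    noise_sd: float = 0.002  # additive image noise, a.u. (free parameter)
    spect_resolution_fwhm: float = 10.0  # mm
    spect_pixel: float = 4.0  # mm
    spect_total_counts: float = 1.0e6
    cluster_sigma_vox: float = 2.0  # smoothing of the lesion cluster field
    random_seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        if len(self.grid_shape) != 3 or any(n <= 0 for n in self.grid_shape):
            raise ValueError(f"grid_shape must be three positive integers, got {self.grid_shape}")
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel_spacing must be positive")
        for name in ("emphysema_fraction_per_lobe", "ventilation_defect_fraction_per_lobe"):
            fr = tuple(float(v) for v in getattr(self, name))
            if len(fr) != 5 or any(not (0.0 <= v <= 1.0) for v in fr):
                raise ValueError(f"{name} must be 5 values in [0, 1], got {fr}")
            setattr(self, name, fr)
        if self.perfusion_defect_fraction_per_lobe is not None:
            fr = tuple(float(v) for v in self.perfusion_defect_fraction_per_lobe)
            if len(fr) != 5 or any(not (0.0 <= v <= 1.0) for v in fr):
                raise ValueError("perfusion_defect_fraction_per_lobe must be 5 values in [0, 1]")
            self.perfusion_defect_fraction_per_lobe = fr
        if not self.emphysema_hu_mean < -950.0:
            raise ValueError("emphysema_hu_mean must lie below the -950 HU threshold")
        if not self.parenchyma_hu_mean > -950.0:
            raise ValueError("parenchyma_hu_mean must lie above the -950 HU threshold")
        if self.coil_ap_ratio < 1.0:
            raise ValueError("coil_ap_ratio must be >= 1")
        if not (0.0 < self.nominal_alpha < 90.0):
            raise ValueError("nominal_alpha must be in (0, 90) degrees")
        if self.T1_seconds <= 0:
            raise ValueError("T1_seconds must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.spect_resolution_fwhm <= 0 or self.spect_pixel <= 0:
            raise ValueError("SPECT resolution and pixel size must be positive")
        self.random_seed = int(self.random_seed)

    def rng(self, key: int) -> np.random.Generator:
        """Independent generator for one stochastic ingredient."""
        return np.random.default_rng([self.random_seed, key])


def _fractional_coords(shape: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    axes = [np.arange(n) / max(n - 1, 1) for n in shape]
    return np.meshgrid(*axes, indexing="ij")


def generate_lobe_masks(spec: PhantomSpec) -> LobarMaskSet:
    """Two ellipsoid lungs split into 3 right + 2 left lobes.

    Fissures are iso-surfaces of the oblique coordinate
    ``z - slope*(y - cy)`` placed at within-lung volume quantiles, so
    the lobar volume shares follow the geometry parameters exactly
    (up to voxelisation).  Pure geometry: no randomness.
    """
    geo = {**_DEFAULT_GEOMETRY, **spec.lobe_geometry_params}
    x, y, z = _fractional_coords(spec.grid_shape)
    labels = np.zeros(spec.grid_shape, dtype=np.int16)

    def _lung(center):
        cx, cy, cz = center
        ax, ay, az = geo["semi_axes"]
        return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0

    right = _lung(geo["right_center"])
    left = _lung(geo["left_center"])
    slope = geo["oblique_slope"]

    def _split(mask, center_y, fracs, lobe_labels):
        """Assign labels bottom-up by quantiles of the oblique coordinate."""
        u = z[mask] - slope * (y[mask] - center_y)
        # fracs are listed upper->lower; cut from the bottom of the lung up
        shares = np.array(fracs[::-1], dtype=float)
        cuts = np.quantile(u, np.cumsum(shares)[:-1] / shares.sum())
        bins = np.digitize(u, cuts)  # 0 = most inferior block
        out = np.zeros(u.shape, dtype=np.int16)
        for b, lab in enumerate(lobe_labels[::-1]):
            out[bins == b] = lab
        labels[mask] = out

    _split(right, geo["right_center"][1], geo["right_lobe_fracs"], [1, 2, 3])  # RUL, RML, RLL
    _split(left, geo["left_center"][1], geo["left_lobe_fracs"], [4, 5])  # LUL, LLL

    masks = LobarMaskSet(labels=labels, spacing=spec.voxel_spacing)
    for name, n in masks.lobe_voxel_counts().items():
        if n == 0:
            raise ValueError(f"degenerate geometry: lobe {name} has zero voxels")
    return masks


def _cluster_field(spec: PhantomSpec) -> np.ndarray:
    """Smooth Gaussian random field shared by emphysema and defect placement."""
    noise = spec.rng(_KEY_CLUSTER).standard_normal(spec.grid_shape)
    return ndimage.gaussian_filter(noise, sigma=spec.cluster_sigma_vox)


def _select_clustered(field: np.ndarray, lobe: np.ndarray, fraction: float) -> np.ndarray:
    """Top-`fraction` of the cluster field within one lobe (exact count)."""
    sel = np.zeros(field.shape, dtype=bool)
    if fraction <= 0.0:
        return sel
    vals = field[lobe]
    if fraction >= 1.0:
        sel[lobe] = True
        return sel
    thr = np.quantile(vals, 1.0 - fraction)
    sel[lobe] = vals >= thr
    return sel


def generate_ct_volume(spec: PhantomSpec, masks: LobarMaskSet) -> VoxelGrid3D:
    """CT attenuation: clustered emphysema vs parenchyma HU inside lungs."""
    if masks.shape != spec.grid_shape:
        raise ValueError("masks are not on the spec grid")
    cluster = _cluster_field(spec)
    rng = spec.rng(_KEY_HU)
    hu = rng.normal(30.0, 15.0, spec.grid_shape)  # soft tissue background
    np.clip(hu, -150.0, None, out=hu)
    lung = masks.lung_mask()
    hu[lung] = rng.normal(spec.parenchyma_hu_mean, spec.parenchyma_hu_sd, int(lung.sum()))
    for name, frac in zip(LOBE_NAMES, spec.emphysema_fraction_per_lobe):
        sel = _select_clustered(cluster, masks.lobe_mask(name), frac)
        n = int(sel.sum())
        if n:
            hu[sel] = rng.normal(spec.emphysema_hu_mean, spec.emphysema_hu_sd, n)
    return VoxelGrid3D(values=hu, spacing=spec.voxel_spacing, role="HU")


def _defect_map(spec: PhantomSpec, masks: LobarMaskSet, fractions, base_key: int, defect_key: int) -> np.ndarray:
    base_rng = spec.rng(base_key)
    smooth = ndimage.gaussian_filter(base_rng.standard_normal(spec.grid_shape), sigma=3.0)
    lung = masks.lung_mask()
    sd = smooth[lung].std()
    vent = np.zeros(spec.grid_shape)
    vent[lung] = np.clip(0.75 + 0.15 * smooth[lung] / max(sd, 1e-12), 0.5, 1.0)
    cluster = _cluster_field(spec)
    defect_rng = spec.rng(defect_key)
    for name, frac in zip(LOBE_NAMES, fractions):
        sel = _select_clustered(cluster, masks.lobe_mask(name), frac)
        n = int(sel.sum())
        if n:
            vent[sel] = defect_rng.uniform(0.0, 0.02, n)
    return vent


def generate_ventilation_map(spec: PhantomSpec, masks: LobarMaskSet) -> VoxelGrid3D:
    """Smooth fractional ventilation in [0, 1] with clustered lobar defects.

    Healthy parenchyma sits in [0.5, 1]; defect voxels (co-located with
    the emphysema clusters) are near zero; outside the lungs the map
    is exactly zero.
    """
    if masks.shape != spec.grid_shape:
        raise ValueError("masks are not on the spec grid")
    vent = _defect_map(spec, masks, spec.ventilation_defect_fraction_per_lobe, _KEY_VENT_BASE, _KEY_VENT_DEFECT)
    return VoxelGrid3D(values=vent, spacing=spec.voxel_spacing, role="ventilation_fraction")


def generate_perfusion_map(spec: PhantomSpec, masks: LobarMaskSet) -> VoxelGrid3D:
    """Perfusion analogue of the ventilation map (its own noise stream)."""
    fr = spec.perfusion_defect_fraction_per_lobe or spec.ventilation_defect_fraction_per_lobe
    perf = _defect_map(spec, masks, fr, _KEY_PERF_BASE, _KEY_PERF_DEFECT)
    return VoxelGrid3D(values=perf, spacing=spec.voxel_spacing, role="ventilation_fraction")


def generate_coil_alpha_map(spec: PhantomSpec) -> VoxelGrid3D:
    """Anterior–posterior flip-angle gradient of a surface coil.

    The map is log-linear in sin(α) along y (posterior -> anterior),
    constructed so sin(α_anterior)/sin(α_posterior) equals
    ``coil_ap_ratio`` exactly and the geometric mean of sin(α) is
    sin(nominal_alpha).  A ratio of 1 gives a constant map.
    """
    if spec.coil_ap_ratio < 1.0:
        raise ValueError("coil_ap_ratio must be >= 1")
    ny = spec.grid_shape[1]
    yn = np.arange(ny) / max(ny - 1, 1)  # 0 = posterior, 1 = anterior
    gain = spec.coil_ap_ratio ** (yn - 0.5)
    sin_alpha = np.sin(np.deg2rad(spec.nominal_alpha)) * gain
    if sin_alpha.max() >= np.sin(np.deg2rad(89.0)):
        raise ValueError("coil_ap_ratio too large for nominal_alpha: sin(alpha) would exceed sin(89 deg)")
    alpha_deg = np.rad2deg(np.arcsin(sin_alpha))
    values = np.broadcast_to(alpha_deg[None, :, None], spec.grid_shape).copy()
    return VoxelGrid3D(values=values, spacing=spec.voxel_spacing, role="alpha_deg")


def blur_and_resample(vol: VoxelGrid3D, spec: PhantomSpec) -> VoxelGrid3D:
    """Blur to the SPECT point-spread FWHM and resample to the SPECT grid.

    The spatial integral (sum x voxel volume) is conserved: the blur
    uses zero padding (the maps are compactly supported inside the
    grid) and the linear resampling is renormalised to the input
    integral.
    """
    if np.any(vol.values < 0):
        raise ValueError("SPECT simulation requires a nonnegative input map")
    sigma_mm = spec.spect_resolution_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sigma_vox = [sigma_mm / s for s in vol.spacing]
    blurred = ndimage.gaussian_filter(vol.values.astype(float), sigma=sigma_vox, mode="constant")
    zoom = [s / spec.spect_pixel for s in vol.spacing]
    out = ndimage.zoom(blurred, zoom, order=1, mode="grid-constant", grid_mode=True)
    np.clip(out, 0.0, None, out=out)
    integral_in = blurred.sum() * vol.voxel_volume_mm3
    integral_out = out.sum() * spec.spect_pixel**3
    if integral_out > 0:
        out *= integral_in / integral_out
    return VoxelGrid3D(values=out, spacing=(spec.spect_pixel,) * 3, role="spect_counts")


def _spect_expected(mapvol: VoxelGrid3D, spec: PhantomSpec) -> VoxelGrid3D:
    low = blur_and_resample(mapvol, spec)
    total = low.values.sum()
    if total > 0:
        low.values *= spec.spect_total_counts / total
    return low


def generate_spect_pair(
    vent: VoxelGrid3D, perf: VoxelGrid3D, spec: PhantomSpec
) -> tuple[VoxelGrid3D, VoxelGrid3D]:
    """SPECT-like ventilation and perfusion count volumes.

    Each map is blurred to ``spect_resolution_fwhm``, resampled to the
    isotropic ``spect_pixel`` grid, scaled to ``spect_total_counts``
    expected counts, and degraded with Poisson noise.
    """
    out = []
    for mapvol, key in ((vent, _KEY_SPECT_V), (perf, _KEY_SPECT_Q)):
        expected = _spect_expected(mapvol, spec)
        counts = spec.rng(key).poisson(expected.values).astype(float)
        out.append(VoxelGrid3D(values=counts, spacing=expected.spacing, role="spect_counts"))
    return out[0], out[1]


@dataclass
class PhantomSubject:
    """All per-subject phantom volumes plus the seeded ground truth."""

    spec: PhantomSpec
    masks: LobarMaskSet
    ct: VoxelGrid3D
    ventilation: VoxelGrid3D
    perfusion: VoxelGrid3D
    alpha_map: VoxelGrid3D
    spect_v: VoxelGrid3D
    spect_q: VoxelGrid3D


def generate_subject(spec: PhantomSpec) -> PhantomSubject:
    """Generate every modality for one subject from one seed."""
    masks = generate_lobe_masks(spec)
    ct = generate_ct_volume(spec, masks)
    vent = generate_ventilation_map(spec, masks)
    perf = generate_perfusion_map(spec, masks)
    alpha = generate_coil_alpha_map(spec)
    spect_v, spect_q = generate_spect_pair(vent, perf, spec)
    return PhantomSubject(spec, masks, ct, vent, perf, alpha, spect_v, spect_q)


# Lobar weighting of disease severity: lower lobes carry more emphysema,
# mimicking the lower-lobe predominance seen on the example CT maps.
_SEVERITY_WEIGHTS = {"RUL": 0.50, "RML": 0.60, "RLL": 1.00, "LUL": 0.55, "LLL": 0.95}


def generate_cohort(
    n_subjects: int,
    base_spec: PhantomSpec | None = None,
    seed: int = 0,
) -> tuple[list[PhantomSpec], pd.DataFrame]:
    """Seeded cohort of phantom specs plus lung-function covariates.

    Subject severity ramps across the cohort; per-lobe emphysema
    fractions are severity x lobe weight (+ noise) and ventilation
    defect fractions are a noisy increasing function of emphysema, so
    structural damage drives ventilation loss by construction.  The
    FEV1-like covariates are a noisy decreasing function of the
    subject's mean defect burden — synthetic stand-ins that let the
    whole-lung lung-function regressions run, not spirometry models.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    base = base_spec or PhantomSpec()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_subjects + 1)
    cov_rng = np.random.default_rng(children[-1])
    severities = np.linspace(0.15, 0.85, n_subjects)
    specs: list[PhantomSpec] = []
    rows = []
    for i, (sev, child) in enumerate(zip(severities, children[:-1])):
        rng = np.random.default_rng(child)
        emph = np.clip(
            [sev * _SEVERITY_WEIGHTS[lobe] + rng.normal(0, 0.03) for lobe in LOBE_NAMES], 0.0, 0.95
        )
        defect = np.clip(1.15 * emph + rng.normal(0, 0.03, 5), 0.0, 0.97)
        perf_defect = np.clip(defect + rng.normal(0, 0.02, 5), 0.0, 0.97)
        spec = dataclasses.replace(
            base,
            emphysema_fraction_per_lobe=tuple(emph),
            ventilation_defect_fraction_per_lobe=tuple(defect),
            perfusion_defect_fraction_per_lobe=tuple(perf_defect),
            random_seed=int(child.generate_state(1)[0] % 2**31),
        )
        specs.append(spec)
        mean_defect = float(np.mean(defect))
        rows.append(
            {
                "subject_id": f"S{i + 1:02d}",
                "fev1_pct_pred": float(np.clip(95.0 - 75.0 * mean_defect + cov_rng.normal(0, 4.0), 10.0, 120.0)),
                "fev1_fvc_pct": float(np.clip(88.0 - 55.0 * mean_defect + cov_rng.normal(0, 4.0), 20.0, 100.0)),
                "severity": float(sev),
            }
        )
    return specs, pd.DataFrame(rows).set_index("subject_id")
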