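# Methods

## The signal model

Hyperpolarized xenon-129 carries a non-renewable magnetization pool:
each RF excitation reads out a fraction sin(α) of the longitudinal
magnetization and leaves cos(α) behind, while T1 relaxation destroys
polarization continuously during the breath-hold.  For a voxel that
has experienced P·(k−1) pulses before volume k (P pulses per volume,
one per spiral interleave) acquired at elapsed time t_k, the expected
signal is

    S_k = S0 · sin(α) · cos(α)^(P·(k−1)) · exp(−t_k / T1)

with S0 proportional to the local gas density, i.e. to ventilation.
This is the standard depletion model for hyperpolarized gas imaging.
Assumptions: a single breath-hold (no wash-in/washout gas dynamics),
slice excitations idealized as simultaneous (per-slice time offsets
are carried in the schedule type but default to zero), additive
zero-mean Gaussian noise on real-valued images (no Rician magnitude
bias), and no inter-slice RF cross-talk.

## Identifiability of (S0, α, T1)

With volumes equally spaced by Δt and a constant P, the model
collapses to a two-parameter geometric decay A·r^(k−1) with
A = S0·sin α and r = cos(α)^P·e^(−Δt/T1): α and T1 are confounded and
only the combined per-volume rate λ = P·ln sec α + Δt/T1 is
observable.  Any schedule whose volume times are *not* affine in the
volume index restores a rank-3 Jacobian, and three volumes then
suffice for three unknowns.

`check_identifiability` evaluates the analytic Jacobian at nominal
parameters (S0 = 1, α = 8°, T1 = 25 s), scales each column by its
parameter so the condition number is unit-free, and flags
non-identifiability above a cutoff of 1e8.  The two regimes are
separated by many orders of magnitude — a usable non-uniform schedule
sits at a condition number of 10–10⁴, the uniform collapse at ~1e16 —
so the cutoff's exact placement is uncritical.

`AcquisitionSchedule.identifiable_design()` (volume times 0, 1, 2, 3,
4, 10, 16, 22 s at P = 8) is the package's canonical well-conditioned
schedule: an early burst in which decay is dominated by RF depletion,
followed by late gaps dominated by T1.  It was chosen by comparing
Jacobian condition numbers of candidate 8-volume breath-hold
schedules; near-uniform perturbations of the 2.5 s schedule are
technically identifiable but so ill-conditioned that T1 estimates at
realistic noise are useless.

## Fitting and correction

`fit_decay_model` runs bounded trust-region least squares
(scipy `least_squares`, TRF) with deterministic initialization
α = 8°, T1 = 25 s, S0 = first value / model factor, bounds
α ∈ (0.1°, 89°), T1 ∈ (1, 200) s, tolerances 1e-12.  R² is
1 − SS_res/SS_tot about the curve mean, and is invariant under
positive rescaling of the curve.  Under a non-identifiable schedule
the solver still converges to a point on the (α, T1) ridge; the result
is flagged, and the combined rate λ (reported as
`decay_rate_per_volume`) remains exact.

Lobar curves are the **mean** (not sum) of voxel signal per volume —
invariant to lobe size, directly comparable across lobes.

`correct_timeseries` divides each voxel's course by the full modelled
decay factor sin(α)·cos(α)^(P(k−1))·e^(−t_k/T1) of its region and
averages the corrected volumes, so in the noiseless identifiable case
the output equals the underlying S0 map (scale × ventilation) exactly,
and with noise the averaging suppresses it by √n_volumes.  Two
granularities exist: per-lobe (default, matching lobar analysis) and
per-bin, which bins lung voxels by first-volume intensity deciles and
fits each bin — a spatial flip-angle correction that flattens a
factor-of-2 anterior–posterior coil gradient to within 2% without
noise-dominated voxel-wise fits.

## Scoring

* CT-%emphysema: 100 × (lobe voxels strictly below −950 HU) / lobe
  voxel count.
* Relative %ventilation: 100 × lobe signal sum / total lung signal
  sum.  The denominator is the total **signal** (not lung volume) so
  the five lobar percentages sum to exactly 100, which is the score's
  defining constraint; the same formula serves HPX and SPECT.
* Absolute %ventilation (defect): 100 × fraction of lobe voxels
  strictly below 5% of a whole-lung reference level.  The reference is
  the 99th percentile of lung-voxel signal by default (a robust
  maximum, insensitive to hot pixels); `mean` and `max` are options.
* Whole lung = union of the five lobes; all inequalities strict.

The absolute score is named "%ventilation" by imaging convention but
has defect semantics (higher = worse); the table column
`hpx_abs_vent_pct` keeps the conventional name with the defect
direction documented here.

## The digital thorax phantom

What it emulates: two half-ellipsoid lungs split by oblique planar
fissures into 3 right + 2 left lobes at fixed volume shares; CT
attenuation with Gaussian parenchyma N(−850, 40) HU and emphysema
N(−980, 15) HU straddling the −950 HU cut; emphysema and ventilation
defects placed by thresholding one shared smooth Gaussian random
field at per-lobe quantiles, so lesions are spatially clustered and
structurally/functionally co-located; a smooth ventilation map in
[0.5, 1] with defect voxels near zero; a log-linear
anterior–posterior coil profile with sin(α) ratio exactly
`coil_ap_ratio` (default 2) about a nominal 10° flip angle; SPECT
volumes blurred to 10 mm FWHM, resampled to 4 mm isotropic pixels
with the spatial integral conserved, scaled to 1e6 expected counts
and Poisson-degraded.

What it does not emulate: real airway/vascular anatomy, deformable
breathing motion, registration error between modalities (all grids
share one world frame), CT scanner physics, SPECT scatter/attenuation,
Rician noise, gas-exchange signal, and wash-in/washout dynamics.
Passing tests therefore demonstrate the correctness of the
quantification chain under known ground truth — not robustness to the
registration and physics confounds of patient data.

Cohort generation ramps a severity scalar across subjects; per-lobe
emphysema fractions are severity × lobe weight (lower lobes weighted
heaviest) plus noise, ventilation-defect fractions are a noisy
increasing function of emphysema (slope 1.15), and perfusion defects
track ventilation defects.  FEV1-like covariates are a noisy
decreasing function of mean defect burden — synthetic stand-ins that
exercise the whole-lung lung-function regressions, not spirometry
models.

Key free parameters (units, default, why):

| parameter | default | rationale |
|---|---|---|
| grid_shape / voxel_spacing | 64×64×48 @ 4 mm | desk-scale volumes with ≥1500 voxels per lobe |
| parenchyma / emphysema HU | −850±40 / −980±15 | places the −950 cut between modes with slight overlap |
| coil_ap_ratio | 2 | surface-coil anterior–posterior signal inhomogeneity of a factor of 2 |
| nominal_alpha / T1 | 10° / 20 s | typical hyperpolarized-gas breath-hold acquisition values |
| noise_sd | 0.002 a.u. | ~2% of a unit-ventilation first-volume signal (sin 10° ≈ 0.17 × vent ≈ 0.8); a free parameter, not a measured value |
| spect FWHM / pixel / counts | 10 mm / 4 mm / 1e6 | clinical SPECT resolution and pixel regime; count level giving visible but not dominant Poisson noise |
| cluster_sigma_vox | 2 voxels | ~8 mm lesion correlation length, coherent at CT and SPECT scales |

## Numerical choices

* Random streams: every stochastic ingredient (cluster field, HU
  draw, ventilation base/defect, perfusion, SPECT Poisson) derives its
  own generator from `(random_seed, sub-key)`, so any single volume is
  reproducible in isolation; cohorts spawn child seeds via
  `SeedSequence`.
* Lesion selection by within-lobe quantile thresholding makes the
  realized lesion fraction exact to one voxel.
* Mask resampling is nearest-neighbour on shared world coordinates
  (origin at voxel (0,0,0) centre, world = index × spacing); labels
  can only be copied, never interpolated, and a lobe that vanishes at
  a coarse target raises rather than silently dropping a region.
* The corrected ventilation map is floored at zero before scoring:
  simulation deliberately leaves Gaussian noise unclipped, while the
  relative-share formula requires nonnegative signal.
* Degenerate inputs (all-zero curves, empty lobes, zero-variance
  statistics inputs) raise errors naming the offending region rather
  than propagating NaNs.

## Statistics

Pearson r with the two-sided t-transform p-value and Fisher-z 95% CI;
OLS slope/intercept with slope SE and two-sided p.  Pooled lobar
regressions treat lobes of all subjects as independent observations —
plain OLS, ignoring within-subject clustering, as is conventional for
these scatter-plot comparisons; this understates p-value uncertainty
and is a documented limitation, not corrected with mixed models.
Per-subject correlations use the five lobar points (n = 5).  Subjects
missing a modality are excluded per-analysis; any pairing with fewer
than three complete pairs is reported as `not_computable`.

## Problem sizes

Tests and the acceptance script run phantoms at 48×48×36 (and
32×32×24 for unit tests) with 12-subject cohorts, 100-replicate R²
studies and 200-curve bias studies — sizes at which every documented
property is already stable; the generator scales to larger grids
unchanged.

## Known limitations

* The uniform 2.5 s schedule — the realistic breath-hold protocol —
  cannot separate α from T1; only the combined decay and S0·sin α are
  estimable, and the relative ventilation shares are insensitive to
  the split.  Absolute S0 recovery requires a non-uniform schedule.
* The per-bin flip-angle correction assumes signal intensity is
  monotone in α at fixed ventilation, which holds for a smooth coil
  profile and homogeneous ventilation but degrades where ventilation
  defects and coil gradient interact.
* Phantom lobar geometry is parametric, not anatomical; fissure
  placement is by volume quantiles of an oblique coordinate.
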