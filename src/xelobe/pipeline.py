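"""Top-level pipeline: simulate -> fit -> correct -> score -> compare.

Runs a phantom cohort end to end and writes every artifact plus a
manifest that suffices to reproduce the run byte-identically (config,
seed, library versions).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .compare_stats import run_cohort_comparison
from .core import AcquisitionSchedule
from .decay_fit import correct_timeseries_binned, correct_timeseries_lobar
from .hpx_sim import simulate_hpx_timeseries
from .lobar_scores import build_score_table
from .phantom import PhantomSpec, generate_cohort, generate_subject

logger = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "n_subjects",
    "seed",
    "phantom",
    "schedule",
    "scoring",
    "correction",
    "n_bins",
    "signal_scale",
    "include_spect",
    "write_volumes",
    "log_level",
}


@dataclass
class PipelineConfig:
    """Validated configuration of one cohort run."""

    n_subjects: int = 3
    seed: int = 0
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    schedule: AcquisitionSchedule = field(default_factory=AcquisitionSchedule)
    scoring: dict = field(default_factory=lambda: {"threshold_hu": -950.0, "frac": 0.05, "reference": "p99"})
    correction: str = "lobe"  # or "bins"
    n_bins: int = 10
    signal_scale: float = 1.0
    include_spect: bool = True
    write_volumes: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.correction not in ("lobe", "bins"):
            raise ValueError("correction must be 'lobe' or 'bins'")
        extra = set(self.scoring) - {"threshold_hu", "frac", "reference"}
        if extra:
            raise ValueError(f"unknown scoring keys: {sorted(extra)}")

    @classmethod
    def from_dict(cls, cfg: dict) -> "PipelineConfig":
        unknown = set(cfg) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(cfg)
        if "phantom" in kwargs:
            kwargs["phantom"] = PhantomSpec(**kwargs["phantom"])
        if "schedule" in kwargs:
            sched = dict(kwargs["schedule"])
            if "volume_times" in sched:
                sched["volume_times"] = np.asarray(sched["volume_times"], dtype=float)
                sched.setdefault("n_volumes", len(sched["volume_times"]))
            kwargs["schedule"] = AcquisitionSchedule(**sched)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["phantom"] = dataclasses.asdict(self.phantom)
        d["schedule"] = {
            "n_volumes": self.schedule.n_volumes,
            "volume_times": [float(t) for t in self.schedule.volume_times],
            "pulses_per_volume": self.schedule.pulses_per_volume,
        }
        return json.loads(json.dumps(d, default=lambda o: list(o) if isinstance(o, (tuple, np.ndarray)) else str(o)))


def process_subject(
    subject_id: str,
    spec: PhantomSpec,
    config: PipelineConfig,
    outdir: Path | None = None,
) -> pd.DataFrame:
    """Simulate one subject and score every modality."""
    subject = generate_subject(spec)
    ts = simulate_hpx_timeseries(
        subject.ventilation,
        subject.alpha_map,
        spec.T1_seconds,
        config.schedule,
        noise_sd=spec.noise_sd,
        seed=spec.random_seed,
        signal_scale=config.signal_scale,
    )
    if config.correction == "bins":
        corrected, _ = correct_timeseries_binned(ts, subject.masks, n_bins=config.n_bins)
    else:
        corrected, _ = correct_timeseries_lobar(ts, subject.masks)
    # noise is unclipped in simulation; scoring requires nonnegative signal,
    # so negative noise excursions (defect voxels) are floored at zero here
    corrected.values = np.clip(corrected.values, 0.0, None)

    spect_v = spect_q = spect_masks = None
    if config.include_spect:
        spect_v, spect_q = subject.spect_v, subject.spect_q
        spect_masks = io.resample_mask(subject.masks, spect_v.shape, spect_v.spacing)

    table = build_score_table(
        subject_id,
        subject.masks,
        ct=subject.ct,
        hpx_corrected=corrected,
        spect_v=spect_v,
        spect_q=spect_q,
        spect_masks=spect_masks,
        **config.scoring,
    )
    if outdir is not None and config.write_volumes:
        sdir = outdir / subject_id
        sdir.mkdir(parents=True, exist_ok=True)
        io.write_volume(subject.ct, sdir / "ct.nii.gz")
        io.write_mask(subject.masks, sdir / "lobe_masks.nii.gz")
        io.write_volume(subject.ventilation, sdir / "ventilation.nii.gz")
        io.write_volume(subject.alpha_map, sdir / "alpha_map.nii.gz")
        io.write_timeseries(ts, sdir / "hpx_timeseries.nii.gz", sdir / "schedule.yaml")
        io.write_volume(corrected, sdir / "hpx_corrected.nii.gz")
        if spect_v is not None:
            io.write_volume(spect_v, sdir / "spect_v.nii.gz")
            io.write_volume(spect_q, sdir / "spect_q.nii.gz")
    return table


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run the full cohort pipeline and write all artifacts.

    Returns the comparison report dict (with the cohort score table
    added under ``"scores"``).  Any stage failure raises with the
    subject and stage named.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    specs, covariates = generate_cohort(config.n_subjects, config.phantom, seed=config.seed)
    tables = []
    for i, spec in enumerate(specs):
        sid = f"S{i + 1:02d}"
        try:
            tables.append(process_subject(sid, spec, config, outdir))
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise RuntimeError(f"pipeline failed for subject {sid} (simulate/fit/score): {exc}") from exc
    scores = pd.concat(tables)

    try:
        report = run_cohort_comparison(scores, covariates)
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"pipeline failed in the compare stage: {exc}") from exc

    scores.to_csv(outdir / "scores.csv")
    covariates.to_csv(outdir / "covariates.csv")
    report["per_subject"].to_csv(outdir / "per_subject_correlations.csv", index=False)
    report["pooled"].to_csv(outdir / "pooled_regressions.csv", index=False)
    report["whole_lung"].to_csv(outdir / "whole_lung_regressions.csv", index=False)
    (outdir / "summary.txt").write_text(report["summary"] + "\n")

    manifest = {
        "xelobe_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "n_subjects": config.n_subjects,
        "outputs": sorted(p.name for p in outdir.iterdir() if p.is_file()),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    report["scores"] = scores
    report["covariates"] = covariates
    return report
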