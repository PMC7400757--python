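"""End-to-end study orchestration.

Runs the full replication in order — simulate (or load) a cohort, build (or
load) the forward model, fit the eLORETA filter, compute band-power time
courses and per-subject NPV maps, compare groups with the permutation-
corrected voxel-wise ANOVA (plus the plain eLORETA band-power comparison as
a negative control), and evaluate the one-predictor discriminant at the
extreme voxel/band with leave-one-subject-out cross-validation.

Every stage writes its artifact to the output directory; outputs are pure
functions of (inputs, config, seed), so re-running a configuration
reproduces the same files. Stage timings go to the logfile only, keeping the
exported artifacts byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .discriminant import export_scores_csv, fit_discriminant, loocv
from .forward_model import (
    SphericalModelSpec, build_spherical_leadfield, read_leadfield, write_leadfield,
)
from .group_stats import (
    SubjectMapSet, export_statmap_csv, permutation_correct, statmap_metadata,
    subject_normalize,
)
from .inverse_eloreta import SpatialFilter, compute_filter, compute_weights
from .io_eeg import (
    EEGRecording, apply_average_reference, apply_bandpass, read_edf,
    select_epoch, standard_1020_montage,
)
from .npv_core import npv_map
from .spectral_power import (
    BandDefinition, DEFAULT_BANDS, band_power_timecourse, segment_recording,
)
from .synthetic_cohort import CohortConfig, generate_cohort, write_cohort

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Complete configuration of one study run."""

    out_dir: str
    # forward model: either a file to import or a spherical spec to build
    leadfield_path: str | None = None
    model_spec: SphericalModelSpec = field(default_factory=SphericalModelSpec)
    # cohort: either synthetic settings or a directory of EDFs with labels
    cohort: dict | None = None          # CohortConfig kwargs minus leadfield
    edf_dir: str | None = None
    labels_path: str | None = None      # JSON list of subject group labels
    # analysis parameters
    epoch_duration: float | None = None  # None -> whole recording
    bandpass: tuple[float, float] = (0.53, 120.0)
    segment_len: float = 1.15
    window_len: float = 4.6
    step: float = 1.15
    alpha: float = 0.05
    n_perm: int = 5000
    seed: int = 0
    variance: str = "population"
    taper: str | None = None
    write_edfs: bool = False            # also dump the synthetic cohort as EDF

    def validate(self) -> None:
        if (self.cohort is None) == (self.edf_dir is None):
            raise ValueError("provide exactly one of cohort settings or an EDF directory")
        for p in (self.leadfield_path, self.edf_dir, self.labels_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured path does not exist: {p}")
        if self.edf_dir is not None and self.labels_path is None:
            raise ValueError("EDF input requires a labels file")


@dataclass
class RunReport:
    """Summary of one complete run; every number is also in an artifact file."""

    parameters: dict
    n_subjects: int
    npv_summary: dict
    extreme: dict
    control_extreme: dict
    cv: dict
    version: str
    timing: dict


def _mean_band_power_maps(
    filt: SpatialFilter,
    recordings: list[EEGRecording],
    cfg: RunConfig,
    bands: tuple[BandDefinition, ...],
) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject NPV maps and mean-power maps, stacked (S, V, B)."""
    npv_stack, pow_stack = [], []
    for i, rec in enumerate(recordings):
        segs = segment_recording(rec, cfg.segment_len)
        series = band_power_timecourse(
            filt, segs, bands, fs=rec.fs, taper=cfg.taper
        )
        nm = npv_map(series, cfg.window_len, cfg.step,
                     subject_id=f"subject_{i:03d}", variance=cfg.variance)
        npv_stack.append(nm.npv)
        pow_stack.append(series.power.mean(axis=2))
    return np.stack(npv_stack), np.stack(pow_stack)


def run_study(config: RunConfig, bands: tuple[BandDefinition, ...] = DEFAULT_BANDS) -> RunReport:
    """Execute all stages; artifacts land in ``config.out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timing: dict[str, float] = {}
    stage = "startup"

    def tick(name: str) -> None:
        nonlocal stage
        timing[name] = time.perf_counter()
        stage = name

    try:
        tick("forward")
        if config.leadfield_path is not None:
            lf = read_leadfield(config.leadfield_path)
        else:
            lf = build_spherical_leadfield(config.model_spec, standard_1020_montage())
            write_leadfield(lf, out / "leadfield.h5")

        tick("cohort")
        if config.cohort is not None:
            ccfg = CohortConfig(leadfield=lf, seed=config.seed, **config.cohort)
            recordings, truth = generate_cohort(ccfg)
            labels = list(truth.labels)
            if config.write_edfs:
                write_cohort(recordings, truth, out / "cohort")
            with open(out / "truth.json", "w") as fh:
                json.dump({
                    "labels": labels,
                    "effect_voxels": list(truth.effect_voxels),
                    "effect_band": truth.effect_band,
                }, fh, indent=2)
        else:
            with open(config.labels_path) as fh:
                labels = json.load(fh)
            montage = lf.montage
            paths = sorted(Path(config.edf_dir).glob("*.edf"))
            if len(paths) != len(labels):
                raise ValueError(
                    f"{len(paths)} EDF files but {len(labels)} labels"
                )
            recordings = [read_edf(p, montage) for p in paths]

        tick("preprocess")
        prepped = []
        for rec in recordings:
            hi = min(config.bandpass[1], 0.99 * rec.fs / 2)
            rec = apply_bandpass(rec, config.bandpass[0], hi)
            rec = apply_average_reference(rec)
            if config.epoch_duration is not None:
                rec = select_epoch(rec, config.epoch_duration)
            prepped.append(rec)

        tick("inverse")
        W = compute_weights(lf, alpha=config.alpha)
        filt = compute_filter(lf, W)

        tick("npv")
        npv_maps, power_maps = _mean_band_power_maps(filt, prepped, config, bands)
        band_names = tuple(b.name for b in bands)
        np.savez(out / "subject_maps.npz",
                 npv=npv_maps, power=power_maps, labels=np.array(labels))
        with open(out / "npv_meta.json", "w") as fh:
            json.dump({
                "variance": config.variance, "window_len_s": config.window_len,
                "step_s": config.step, "segment_len_s": config.segment_len,
                "taper": config.taper, "bands": list(band_names),
            }, fh, indent=2)

        tick("stats")
        npv_set = SubjectMapSet(npv_maps, tuple(labels), "npv", band_names)
        sm = permutation_correct(npv_set, n_perm=config.n_perm, seed=config.seed)
        export_statmap_csv(sm, lf.voxel_coords, band_names, out / "statmap_npv.csv")
        with open(out / "statmap_npv.json", "w") as fh:
            json.dump(statmap_metadata(sm), fh, indent=2)
        # negative control: plain eLORETA band power, subject-normalized
        pow_set = subject_normalize(
            SubjectMapSet(power_maps, tuple(labels), "power", band_names)
        )
        sm_pow = permutation_correct(pow_set, n_perm=config.n_perm, seed=config.seed)
        export_statmap_csv(sm_pow, lf.voxel_coords, band_names,
                           out / "statmap_power.csv")
        with open(out / "statmap_power.json", "w") as fh:
            json.dump(statmap_metadata(sm_pow), fh, indent=2)

        tick("classify")
        v_ext, b_ext, p_ext = sm.extreme
        x = np.log(npv_maps[:, v_ext, b_ext])
        cv = loocv(x, labels)
        model = fit_discriminant(x, labels, voxel_id=v_ext, band=band_names[b_ext])
        cv_payload = {
            **cv.as_dict(),
            "voxel_id": v_ext, "band": band_names[b_ext],
            "weight": model.weight, "intercept": model.intercept,
        }
        with open(out / "cv_report.json", "w") as fh:
            json.dump(cv_payload, fh, indent=2)
        export_scores_csv(cv, x, labels, out / "subject_scores.csv")

        tick("report")
        report = RunReport(
            parameters={
                "segment_len": config.segment_len, "window_len": config.window_len,
                "step": config.step, "alpha": config.alpha,
                "n_perm": config.n_perm, "seed": config.seed,
                "variance": config.variance, "taper": config.taper,
                "bands": list(band_names), "model_tag": lf.model_tag,
            },
            n_subjects=len(labels),
            npv_summary={
                "mean_npv_responder": float(
                    npv_maps[[l == "responder" for l in labels]].mean()
                ),
                "mean_npv_nonresponder": float(
                    npv_maps[[l == "nonresponder" for l in labels]].mean()
                ),
            },
            extreme=statmap_metadata(sm),
            control_extreme=statmap_metadata(sm_pow),
            cv=cv_payload,
            version=__version__,
            timing={},  # filled below; logged, not exported
        )
        t_keys = list(timing)
        durations = {
            k: (timing[t_keys[i + 1]] if i + 1 < len(t_keys) else time.perf_counter())
            - timing[k]
            for i, k in enumerate(t_keys)
        }
        report.timing = durations
        for name, dt in durations.items():
            logger.info("stage %-10s %.2f s", name, dt)
        payload = dataclasses.asdict(report)
        payload.pop("timing")  # keep report.json byte-reproducible
        with open(out / "report.json", "w") as fh:
            json.dump(payload, fh, indent=2)
        return report
    except Exception as exc:
        (out / "FAILED").write_text(f"{stage}: {exc}\n")
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc)) from exc
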