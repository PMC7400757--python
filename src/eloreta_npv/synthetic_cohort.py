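"""Synthetic EEG cohorts with a controlled beta-envelope instability effect.

Patient EEG is simulated with the statistical structure the analysis is
designed to detect. Each subject's scalp recording superposes, through a
shared forward model:

* **effect sources** — one coherent beta-band process (carrier ~21.5 Hz,
  jittered per subject) expressed at the designated "high-convexity" voxels
  (superomedial grid surface by default), amplitude-modulated by a log-normal
  envelope redrawn every 1.15 s. The envelope's CV is the planted group
  contrast: responders get an unstable envelope (CV 0.8 by default),
  non-responders a stable one (CV 0.2) — NPV is exactly a CV^2 statistic, so
  this is the quantity the pipeline should recover;
* **background sources** — pink-noise (1/f power) dipoles at random voxels;
* an **occipital alpha source** — a 10 Hz oscillation with a waxing-waning
  envelope at the most posterior voxel, the dominant rhythm of eyes-closed
  resting EEG;
* white **sensor noise**.

The log-normal envelope keeps power positive and has an analytically
controllable CV (CV^2 = exp(sigma^2) - 1). The envelope is redrawn at the
1.15-s segment scale so the planted instability lives exactly at the
resolution of the 4.6-s / 1.15-s NPV scheme. Everything is deterministic
given the master seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .forward_model import Leadfield
from .io_eeg import EEGRecording
from .spectral_power import BandDefinition, DEFAULT_BANDS

logger = logging.getLogger(__name__)

#: nA*m -> microvolt conversion against gain in V/(A*m)
_MOMENT_SCALE = 1e-3

RESPONDER = "responder"
NONRESPONDER = "nonresponder"


@dataclass
class CohortConfig:
    """Study conditions of one simulated cohort.

    Dipole moments are in nA*m; the defaults put the simulated scalp EEG
    around 10 uV RMS after average reference, with a clearly visible but not
    dominant beta source — the order of eyes-closed clinical recordings.
    """

    leadfield: Leadfield
    n_responders: int = 15
    n_nonresponders: int = 19
    duration: float = 100.0          # seconds, up to 500
    fs: float = 500.0
    effect_voxels: tuple[int, ...] | None = None   # None -> superomedial default
    effect_band: BandDefinition = DEFAULT_BANDS[3]  # beta 13.5-29.5 Hz
    envelope_cv_responder: float = 0.8
    envelope_cv_nonresponder: float = 0.2
    background_sources: int = 20
    sensor_noise_sd: float = 2.0     # microvolts
    seed: int = 0
    # source strengths (nA*m) and carrier parameters
    beta_moment: float = 60.0
    background_moment: float = 25.0
    alpha_moment: float = 60.0
    alpha_envelope_cv: float = 0.5
    carrier_hz: float = 21.5
    carrier_jitter_hz: float = 1.0
    envelope_step: float = 1.15      # seconds

    def __post_init__(self) -> None:
        if self.n_responders < 2 or self.n_nonresponders < 2:
            raise ValueError("need at least 2 subjects per group")
        if not (0 < self.duration <= 500):
            raise ValueError("duration must be in (0, 500] seconds")
        if self.envelope_cv_responder < 0 or self.envelope_cv_nonresponder < 0:
            raise ValueError("envelope CVs must be non-negative")
        if self.effect_voxels is not None:
            nv = self.leadfield.n_voxels
            bad = [v for v in self.effect_voxels if not (0 <= v < nv)]
            if bad:
                raise ValueError(f"effect voxel(s) not in leadfield: {bad}")

    def resolved_effect_voxels(self) -> tuple[int, ...]:
        if self.effect_voxels is not None:
            return tuple(self.effect_voxels)
        return default_effect_voxels(self.leadfield)


@dataclass
class CohortTruth:
    """Ground truth of a generated cohort, for recovery tests."""

    labels: tuple[str, ...]
    effect_voxels: tuple[int, ...]
    effect_band: str
    realized_envelope_cv: tuple[float, ...]  # per subject, across effect sources


def default_effect_voxels(lf: Leadfield, tol: float = 1e-6) -> tuple[int, ...]:
    """Voxels nearest the superomedial surface: maximal z, then minimal |x|."""
    coords = lf.voxel_coords
    zmax = coords[:, 2].max()
    top = np.flatnonzero(coords[:, 2] >= zmax - tol)
    ax = np.abs(coords[top, 0])
    keep = top[ax <= ax.min() + tol]
    return tuple(int(v) for v in np.sort(keep))


def occipital_voxel(lf: Leadfield) -> int:
    """Most posterior voxel (minimal y; ties to the midline, then inferior)."""
    coords = lf.voxel_coords
    order = np.lexsort((np.abs(coords[:, 2]), np.abs(coords[:, 0]), coords[:, 1]))
    return int(order[0])


def _lognormal_envelope(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Mean-1 log-normal draws with target coefficient of variation."""
    if cv == 0:
        return np.ones(n)
    s2 = np.log1p(cv**2)
    return rng.lognormal(mean=-0.5 * s2, sigma=np.sqrt(s2), size=n)


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-RMS noise with 1/f power spectrum."""
    n_bins = n // 2 + 1
    spec = rng.normal(size=n_bins) + 1j * rng.normal(size=n_bins)
    f = np.arange(n_bins, dtype=float)
    f[0] = np.inf  # kill DC
    spec *= f**-0.5
    x = np.fft.irfft(spec, n=n)
    return x / x.std()


def _random_orientation(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _project(lf: Leadfield, voxel: int, orient: np.ndarray, wave: np.ndarray) -> np.ndarray:
    """Scalp contribution (uV) of a source time course (nA*m) at one voxel."""
    if lf.n_orient == 3:
        pattern = lf.gain[:, voxel, :] @ orient
    else:
        pattern = lf.gain[:, voxel, 0]
    return np.outer(pattern, wave) * _MOMENT_SCALE


def _simulate(
    config: CohortConfig, group: str, rng: np.random.Generator
) -> tuple[np.ndarray, float]:
    lf = config.leadfield
    n = int(round(config.duration * config.fs))
    t = np.arange(n) / config.fs
    seg_samples = int(round(config.envelope_step * config.fs))
    n_env = -(-n // seg_samples)  # ceil
    reps = np.minimum(
        np.full(n_env, seg_samples), n - seg_samples * np.arange(n_env)
    )

    cv = (config.envelope_cv_responder if group == RESPONDER
          else config.envelope_cv_nonresponder)
    data = np.zeros((lf.n_sensors, n))
    realized = []

    # one coherent regional process: a single carrier (jittered per subject)
    # and a single envelope drive all effect voxels; orientation and phase
    # vary per voxel. Incoherent per-voxel envelopes would plant instability
    # into the beat pattern of the mixture and delocalize the effect.
    effect = config.resolved_effect_voxels()
    if effect:
        env_vals = _lognormal_envelope(rng, cv, n_env)
        realized.append(float(env_vals.std() / env_vals.mean()))
        env = np.repeat(env_vals, reps)
        f_c = config.carrier_hz + rng.normal(0.0, config.carrier_jitter_hz)
        for v in effect:
            phase = rng.uniform(0, 2 * np.pi)
            wave = config.beta_moment * env * np.sin(2 * np.pi * f_c * t + phase)
            data += _project(lf, v, _random_orientation(rng), wave)

    for _ in range(config.background_sources):
        v = int(rng.integers(lf.n_voxels))
        wave = config.background_moment * _pink_noise(rng, n)
        data += _project(lf, v, _random_orientation(rng), wave)

    if config.alpha_moment > 0:
        env = np.repeat(
            _lognormal_envelope(rng, config.alpha_envelope_cv, n_env), reps
        )
        phase = rng.uniform(0, 2 * np.pi)
        wave = config.alpha_moment * env * np.sin(2 * np.pi * 10.0 * t + phase)
        data += _project(lf, occipital_voxel(lf), _random_orientation(rng), wave)

    if config.sensor_noise_sd > 0:
        data += rng.normal(0.0, config.sensor_noise_sd, size=data.shape)

    mean_cv = float(np.mean(realized)) if realized else 0.0
    return data, mean_cv


def generate_subject(
    config: CohortConfig, group: str, subject_seed: int
) -> EEGRecording:
    """One synthetic subject; deterministic given (config, group, seed)."""
    if group not in (RESPONDER, NONRESPONDER):
        raise ValueError(f"unknown group: {group!r}")
    rng = np.random.default_rng(subject_seed)
    data, _ = _simulate(config, group, rng)
    return EEGRecording(
        data=data, fs=config.fs,
        channel_labels=tuple(config.leadfield.montage.labels),
        reference="recording",
    )


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[EEGRecording], CohortTruth]:
    """Full cohort (responders first) from independent per-subject seeds."""
    n_total = config.n_responders + config.n_nonresponders
    seed_rng = np.random.default_rng(config.seed)
    subject_seeds = seed_rng.integers(0, 2**31 - 1, size=n_total)
    labels = (RESPONDER,) * config.n_responders + (NONRESPONDER,) * config.n_nonresponders

    recs, realized = [], []
    for lbl, s in zip(labels, subject_seeds):
        rng = np.random.default_rng(int(s))
        data, cv = _simulate(config, lbl, rng)
        recs.append(EEGRecording(
            data=data, fs=config.fs,
            channel_labels=tuple(config.leadfield.montage.labels),
            reference="recording",
        ))
        realized.append(cv)
    truth = CohortTruth(
        labels=labels,
        effect_voxels=config.resolved_effect_voxels(),
        effect_band=config.effect_band.name,
        realized_envelope_cv=tuple(realized),
    )
    return recs, truth


def write_cohort(
    recordings: list[EEGRecording], truth: CohortTruth, out_dir: str | Path
) -> None:
    """Write subjects as EDF files plus a ground-truth JSON."""
    from .io_eeg import write_edf

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, rec in enumerate(recordings):
        write_edf(rec, out / f"subject_{i:03d}.edf")
    with open(out / "truth.json", "w") as fh:
        json.dump({
            "labels": list(truth.labels),
            "effect_voxels": list(truth.effect_voxels),
            "effect_band": truth.effect_band,
            "realized_envelope_cv": list(truth.realized_envelope_cv),
        }, fh, indent=2)
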