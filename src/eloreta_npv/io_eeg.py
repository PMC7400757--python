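"""Resting-state EEG input/output and preprocessing.

Recordings are carried as channels x samples matrices in microvolts, with an
ordered 10-20 montage and a reference tag. Preprocessing mirrors a standard
clinical resting-state protocol: a 0.53-120 Hz band-pass, re-referencing to
the common average (required by the inverse model's centering), and selection
of a fixed-length analysis epoch (500 s by default).

EDF (European Data Format) is used as the on-disk container. Reading goes
through :func:`mne.io.read_raw_edf`; a minimal EDF writer is provided here
because no writer is available among the runtime dependencies. A small header
probe guards against per-channel sampling-rate mismatches, which would
otherwise be hidden by the reader's implicit resampling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal as sps

logger = logging.getLogger(__name__)

#: The 19 standard 10-20 electrode labels (older T3/T4/T5/T6 temporal names).
TEN_TWENTY_LABELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T3", "T4", "T5", "T6", "Fz", "Cz", "Pz",
)


class ChannelNotFoundError(ValueError):
    """A requested montage channel is absent from the file."""


class SamplingRateMismatchError(ValueError):
    """Channels of one recording carry different sampling rates."""


class InsufficientDataError(ValueError):
    """The recording is shorter than the requested epoch."""


# ---------------------------------------------------------------------------
# Montage
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Montage:
    """Ordered scalp electrode set with unit-sphere positions.

    Positions live on the unit sphere in head coordinates: +x right,
    +y anterior, +z superior. They are scaled to the scalp radius by the
    forward model.
    """

    labels: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 3), unit norm

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if len(self.labels) != pos.shape[0]:
            raise ValueError("montage labels and positions disagree in length")
        if len(set(lbl.strip().lower() for lbl in self.labels)) != len(self.labels):
            raise ValueError("montage labels must be unique")
        norms = np.linalg.norm(pos, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("montage positions must have unit norm")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        key = label.strip().lower()
        for i, lbl in enumerate(self.labels):
            if lbl.strip().lower() == key:
                return i
        raise ChannelNotFoundError(f"channel not found: {label}")


def _slerp(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Midpoint of the great-circle arc between two unit vectors."""
    m = a + b
    return m / np.linalg.norm(m)


def standard_1020_montage() -> Montage:
    """Idealized 19-channel 10-20 montage on the unit sphere.

    Electrodes are placed by the classical 10-20 arc construction on an ideal
    sphere: the vertex Cz at the pole, the midline and temporal rows at 36 and
    72 degrees of inclination, and the intermediate frontal/parietal
    electrodes midway along the great circles joining their neighbours (the
    rule that defines them on a real head).
    """
    d36, d72, d18, d54 = map(np.deg2rad, (36.0, 72.0, 18.0, 54.0))

    def pol(incl: float, azim: float) -> np.ndarray:
        # azimuth measured from +y (anterior) toward +x (right)
        return np.array([
            np.sin(incl) * np.sin(azim),
            np.sin(incl) * np.cos(azim),
            np.cos(incl),
        ])

    pos = {
        "Cz": np.array([0.0, 0.0, 1.0]),
        "Fz": pol(d36, 0.0),
        "Pz": pol(d36, np.pi),
        "C3": pol(d36, -np.pi / 2),
        "C4": pol(d36, np.pi / 2),
        "Fp1": pol(d72, -d18),
        "Fp2": pol(d72, d18),
        "F7": pol(d72, -d54),
        "F8": pol(d72, d54),
        "T3": pol(d72, -np.pi / 2),
        "T4": pol(d72, np.pi / 2),
        "T5": pol(d72, -np.pi + d54),
        "T6": pol(d72, np.pi - d54),
        "O1": pol(d72, -np.pi + d18),
        "O2": pol(d72, np.pi - d18),
    }
    pos["F3"] = _slerp(pos["F7"], pos["Fz"])
    pos["F4"] = _slerp(pos["F8"], pos["Fz"])
    pos["P3"] = _slerp(pos["T5"], pos["Pz"])
    pos["P4"] = _slerp(pos["T6"], pos["Pz"])
    return Montage(TEN_TWENTY_LABELS, np.array([pos[l] for l in TEN_TWENTY_LABELS]))


def read_montage(path: str | Path) -> Montage:
    """Read a montage from a CSV table with columns label,x,y,z."""
    import pandas as pd

    df = pd.read_csv(path)
    cols = {c.strip().lower(): c for c in df.columns}
    labels = tuple(str(v).strip() for v in df[cols["label"]])
    xyz = df[[cols["x"], cols["y"], cols["z"]]].to_numpy(dtype=float)
    xyz = xyz / np.linalg.norm(xyz, axis=1, keepdims=True)
    return Montage(labels, xyz)


def write_montage(montage: Montage, path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame({
        "label": montage.labels,
        "x": montage.positions[:, 0],
        "y": montage.positions[:, 1],
        "z": montage.positions[:, 2],
    }).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Recording container
# ---------------------------------------------------------------------------

@dataclass
class EEGRecording:
    """Multi-channel EEG: channels x samples in microvolts."""

    data: np.ndarray            # (n_channels, n_samples), float64, microvolts
    fs: float                   # sampling rate, Hz
    channel_labels: tuple[str, ...]
    reference: str = "recording"  # {"recording", "average"}

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("channel label count must match data rows")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("EEG data must be finite")
        if self.reference not in ("recording", "average"):
            raise ValueError(f"unknown reference tag: {self.reference!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs


# ---------------------------------------------------------------------------
# EDF read / write
# ---------------------------------------------------------------------------

def _probe_edf_header(path: Path) -> tuple[list[str], list[float]]:
    """Return per-signal labels and sampling rates from a raw EDF header."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise ValueError(f"not an EDF file (truncated header): {path}")
        record_dur = float(head[244:252].decode("ascii").strip() or "1")
        ns = int(head[252:256].decode("ascii").strip())
        sig = fh.read(256 * ns)
    labels = [sig[16 * i:16 * (i + 1)].decode("ascii").strip() for i in range(ns)]
    off = ns * (16 + 80 + 8 * 5 + 80)
    n_per_rec = [
        int(sig[off + 8 * i: off + 8 * (i + 1)].decode("ascii").strip())
        for i in range(ns)
    ]
    rates = [n / record_dur for n in n_per_rec]
    return labels, rates


def read_edf(path: str | Path, montage: Montage) -> EEGRecording:
    """Read an EDF/EDF+ recording and reorder channels to the montage.

    Channel matching is case-insensitive and whitespace-trimmed. All matched
    channels must share one sampling rate; mismatches raise rather than being
    silently resampled.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    file_labels, file_rates = _probe_edf_header(path)
    norm = [lbl.strip().lower() for lbl in file_labels]
    picks: list[int] = []
    for want in montage.labels:
        key = want.strip().lower()
        if key not in norm:
            raise ChannelNotFoundError(f"channel not found: {want}")
        picks.append(norm.index(key))
    rates = {file_rates[i] for i in picks}
    if len(rates) > 1:
        raise SamplingRateMismatchError(
            f"channels carry different sampling rates: {sorted(rates)} Hz"
        )

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    raw_norm = [c.strip().lower() for c in raw.ch_names]
    order = [raw_norm.index(lbl.strip().lower()) for lbl in montage.labels]
    data_uv = raw.get_data()[order] * 1e6  # mne returns volts
    return EEGRecording(
        data=data_uv,
        fs=float(rates.pop()),
        channel_labels=tuple(montage.labels),
        reference="recording",
    )


def _fmt8(x: float) -> bytes:
    """Format a float into EDF's fixed 8-character ASCII field."""
    for spec in ("%8g", "%8.3g", "%8.2g", "%8.1g"):
        s = (spec % x).strip()
        if len(s) <= 8:
            return s.ljust(8).encode("ascii")
    raise ValueError(f"cannot format {x} into 8 chars")


def write_edf(rec: EEGRecording, path: str | Path) -> None:
    """Write a recording as plain EDF with 1-s data records.

    Requires an integer sampling rate and a whole number of seconds of data
    (both hold throughout this pipeline); amplitudes are quantized to the
    16-bit digital range against per-channel physical extrema.
    """
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    fs = int(round(fs))
    n_rec, rem = divmod(rec.n_samples, fs)
    if rem:
        raise ValueError("EDF export requires a whole number of seconds of data")

    nch = rec.n_channels
    pmins, pmaxs, digital = [], [], []
    for ch in rec.data:
        lo, hi = float(ch.min()), float(ch.max())
        if hi - lo < 1e-12:
            lo, hi = lo - 1.0, hi + 1.0
        # store the 8-char-rounded extrema, then quantize against the stored
        # values so that read(write(x)) differs from x only by quantization
        lo = float(_fmt8(lo).decode())
        hi = float(_fmt8(hi).decode())
        pmins.append(lo)
        pmaxs.append(hi)
        d = np.round((ch - lo) / (hi - lo) * 65535.0 - 32768.0)
        digital.append(np.clip(d, -32768, 32767).astype("<i2"))

    hdr = b"".join([
        b"0".ljust(8),
        b"X X X X".ljust(80),
        b"Startdate X X X X".ljust(80),
        b"01.01.00", b"00.00.00",
        str(256 * (nch + 1)).ljust(8).encode(),
        b"".ljust(44),
        str(n_rec).ljust(8).encode(),
        b"1".ljust(8),
        str(nch).ljust(4).encode(),
        b"".join(lbl[:16].ljust(16).encode() for lbl in rec.channel_labels),
        b"".join(b"".ljust(80) for _ in range(nch)),
        b"".join(b"uV".ljust(8) for _ in range(nch)),
        b"".join(_fmt8(v) for v in pmins),
        b"".join(_fmt8(v) for v in pmaxs),
        b"".join(b"-32768".ljust(8) for _ in range(nch)),
        b"".join(b"32767".ljust(8) for _ in range(nch)),
        b"".join(b"".ljust(80) for _ in range(nch)),
        b"".join(str(fs).ljust(8).encode() for _ in range(nch)),
        b"".join(b"".ljust(32) for _ in range(nch)),
    ])
    assert len(hdr) == 256 * (nch + 1)

    with open(path, "wb") as fh:
        fh.write(hdr)
        # one record = fs consecutive samples of every channel
        block = np.stack(digital)  # (nch, n_samples)
        for r in range(n_rec):
            fh.write(block[:, r * fs:(r + 1) * fs].tobytes())


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def apply_bandpass(rec: EEGRecording, lo: float = 0.53, hi: float = 120.0) -> EEGRecording:
    """Zero-phase Butterworth band-pass (4th order, forward-backward).

    The passband defaults to the acquisition filter of the clinical protocol
    (0.53-120 Hz); zero-phase filtering avoids distorting the power-envelope
    dynamics that the NPV statistic measures downstream.
    """
    if not (0 < lo < hi):
        raise ValueError(f"invalid band: {lo}-{hi} Hz")
    if hi >= rec.fs / 2:
        raise ValueError(
            f"invalid band: upper edge {hi} Hz must lie below Nyquist ({rec.fs / 2} Hz)"
        )
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=rec.fs, output="sos")
    out = sps.sosfiltfilt(sos, rec.data, axis=1)
    return replace(rec, data=out)


def apply_average_reference(rec: EEGRecording) -> EEGRecording:
    """Re-reference to the common average (idempotent linear projector)."""
    if rec.reference == "average":
        return rec
    out = rec.data - rec.data.mean(axis=0, keepdims=True)
    return replace(rec, data=out, reference="average")


def select_epoch(rec: EEGRecording, duration: float = 500.0) -> EEGRecording:
    """Keep the first ``duration`` seconds of the recording.

    Inputs are assumed artifact-free; epoch selection is positional only.
    """
    n_keep = int(round(duration * rec.fs))
    if n_keep > rec.n_samples:
        raise InsufficientDataError(
            f"insufficient data: need {duration} s "
            f"({n_keep} samples), have {rec.duration:.3f} s"
        )
    return replace(rec, data=rec.data[:, :n_keep].copy())
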