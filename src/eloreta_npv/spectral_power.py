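"""Segmentation, DFT sensor spectra, and cortical band-power time courses.

The recording is cut into consecutive non-overlapping 1.15-s segments — the
elementary time step of the NPV scheme (a 4.6-s NPV window is exactly 4
segments, the 1.15-s step exactly 1). Each segment's per-channel discrete
Fourier transform is pushed through the eLORETA spatial filter, and cortical
band power at a voxel is the squared magnitude of current density summed
over orientations and over the DFT bins whose center frequency falls inside
the band. With 1.15-s segments the bin spacing is 1/1.15 ~ 0.8696 Hz.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .inverse_eloreta import SpatialFilter
from .io_eeg import EEGRecording, InsufficientDataError

logger = logging.getLogger(__name__)

DEFAULT_SEGMENT_LEN = 1.15  # seconds


@dataclass(frozen=True)
class BandDefinition:
    """Closed frequency interval [lo, hi] in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi):
            raise ValueError(f"invalid band {self.name}: {self.lo}-{self.hi} Hz")


#: The five canonical bands of the analysis (half-Hz edge convention).
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.5, 4.0),
    BandDefinition("theta", 4.5, 7.0),
    BandDefinition("alpha", 7.5, 13.0),
    BandDefinition("beta", 13.5, 29.5),
    BandDefinition("gamma", 30.0, 59.5),
)


@dataclass
class BandPowerSeries:
    """Cortical power time courses: voxels x bands x segments."""

    power: np.ndarray               # (n_voxels, n_bands, n_segments), >= 0
    segment_len: float              # seconds
    fs: float
    band_defs: tuple[BandDefinition, ...]

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        if self.power.ndim != 3:
            raise ValueError("power must be voxels x bands x segments")
        if self.power.shape[1] != len(self.band_defs):
            raise ValueError("band axis disagrees with band definitions")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")

    @property
    def n_voxels(self) -> int:
        return self.power.shape[0]

    @property
    def n_segments(self) -> int:
        return self.power.shape[2]


def segment_recording(
    rec: EEGRecording, segment_len: float = DEFAULT_SEGMENT_LEN
) -> np.ndarray:
    """Cut into consecutive non-overlapping segments.

    Returns an (n_segments, n_channels, n_samples_per_segment) array with
    ``round(segment_len * fs)`` samples per segment; the trailing remainder
    is discarded.
    """
    n_per = int(round(segment_len * rec.fs))
    if n_per < 2:
        raise ValueError("segment too short for the sampling rate")
    n_seg = rec.n_samples // n_per
    if n_seg < 1:
        raise InsufficientDataError(
            f"recording ({rec.duration:.3f} s) shorter than one "
            f"{segment_len} s segment"
        )
    trimmed = rec.data[:, : n_seg * n_per]
    return np.transpose(
        trimmed.reshape(rec.n_channels, n_seg, n_per), (1, 0, 2)
    ).copy()


def dft_spectra(segments: np.ndarray, taper: str | None = None) -> np.ndarray:
    """Unnormalized forward DFT per channel (one-sided, real input).

    ``segments`` is (..., n_channels, n_samples); returns complex
    coefficients (..., n_channels, n_bins) with bin k centered at
    ``k / segment_len`` Hz. By default no taper is applied; ``taper="hann"``
    multiplies each segment by a Hann window first.
    """
    segments = np.asarray(segments, dtype=float)
    if not np.all(np.isfinite(segments)):
        raise ValueError("segments must be finite")
    if taper is None:
        x = segments
    elif taper == "hann":
        x = segments * np.hanning(segments.shape[-1])
    else:
        raise ValueError(f"unknown taper: {taper!r}")
    return np.fft.rfft(x, axis=-1)


def band_bins(band: BandDefinition, segment_len: float, n_samples: int) -> np.ndarray:
    """Indices of DFT bins whose center ``k/segment_len`` lies in [lo, hi], k >= 1."""
    n_bins = n_samples // 2 + 1
    k = np.arange(1, n_bins)
    freqs = k / segment_len
    return k[(freqs >= band.lo - 1e-12) & (freqs <= band.hi + 1e-12)]


def band_power_timecourse(
    T: SpatialFilter,
    segments: np.ndarray,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    fs: float | None = None,
    segment_len: float | None = None,
    taper: str | None = None,
) -> BandPowerSeries:
    """Per-voxel, per-band cortical power for every segment.

    For each segment and band, the sensor DFT coefficients of the band's bins
    are mapped through the spatial filter and the squared magnitudes are
    summed over bins and orientations. Bin 0 (DC) is never included.
    """
    segments = np.asarray(segments, dtype=float)
    n_seg, n_ch, n_per = segments.shape
    if n_ch != T.n_sensors:
        raise ValueError(
            f"filter expects {T.n_sensors} sensors, segments have {n_ch} channels"
        )
    if segment_len is None:
        if fs is None:
            raise ValueError("provide segment_len or fs")
        segment_len = n_per / fs
    if fs is None:
        fs = n_per / segment_len

    spectra = dft_spectra(segments, taper=taper)  # (n_seg, n_ch, n_bins)
    Tmat = T.filter.reshape(-1, T.n_sensors)      # (V * orient, sensors)

    power = np.empty((T.n_voxels, len(bands), n_seg))
    for b, band in enumerate(bands):
        bins = band_bins(band, segment_len, n_per)
        if bins.size == 0:
            raise ValueError(
                f"band {band.name} ({band.lo}-{band.hi} Hz) contains no DFT bins "
                f"at segment length {segment_len} s"
            )
        X = spectra[:, :, bins]                            # (n_seg, n_ch, n_b)
        X = np.moveaxis(X, 1, 0).reshape(n_ch, -1)         # (n_ch, n_seg * n_b)
        J = Tmat @ X                                       # (V*orient, n_seg * n_b)
        p = np.abs(J) ** 2
        p = p.reshape(T.n_voxels, T.n_orient, n_seg, bins.size)
        power[:, b, :] = p.sum(axis=(1, 3))
    return BandPowerSeries(
        power=power, segment_len=float(segment_len), fs=float(fs),
        band_defs=tuple(bands),
    )


def export_band_power_csv(series: BandPowerSeries, path) -> None:
    """Write the power time courses as tidy CSV (voxel_id, band, segment_index, power)."""
    import pandas as pd

    V, B, S = series.power.shape
    vox, band, seg = np.meshgrid(
        np.arange(V), np.arange(B), np.arange(S), indexing="ij"
    )
    pd.DataFrame({
        "voxel_id": vox.ravel(),
        "band": np.array([bd.name for bd in series.band_defs])[band.ravel()],
        "segment_index": seg.ravel(),
        "power": series.power.ravel(),
    }).to_csv(path, index=False)
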