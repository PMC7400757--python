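"""Normalized power variance (NPV) — the instability statistic.

NPV of a band-power time course within a window is the variance of power
divided by the squared mean power: the squared coefficient of variation, a
dimensionless index that is 0 for a perfectly stationary envelope and grows
with envelope variability (it equals 1 for exponentially distributed power).
Per subject, NPV is computed in sliding 4.6-s windows advanced in 1.15-s
steps over the whole epoch and averaged across windows (moving-average
scheme), yielding one stationary NPV value per voxel and band.

Variance is the population moment (divide by n): the statistic is a moment
ratio, and with only 4 power samples per window the n vs n-1 choice is
material. The sample-variance convention is available as an option and the
choice is recorded in the map's metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .spectral_power import BandPowerSeries

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_LEN = 4.6   # seconds
DEFAULT_STEP = 1.15        # seconds


@dataclass
class NPVMap:
    """Per-subject NPV values: voxels x bands (dimensionless)."""

    npv: np.ndarray            # (n_voxels, n_bands), >= 0
    n_windows: int
    window_len: float          # seconds
    step: float                # seconds
    subject_id: str = ""
    variance: str = "population"  # {"population", "sample"}

    def __post_init__(self) -> None:
        self.npv = np.asarray(self.npv, dtype=float)
        if np.any(self.npv < 0):
            raise ValueError("NPV must be non-negative")


def npv_window(p: np.ndarray, variance: str = "population") -> float:
    """NPV of one window of power samples: var(p) / mean(p)^2.

    All-zero windows return 0 by convention (a silent source is maximally
    stable, and NaNs would poison subject averages).
    """
    p = np.asarray(p, dtype=float)
    if p.size < 2:
        raise ValueError("NPV needs at least 2 power samples")
    if not np.all(np.isfinite(p)):
        raise ValueError("power samples must be finite")
    if np.any(p < 0):
        raise ValueError("negative power sample (power is a squared magnitude)")
    m = p.mean()
    if m == 0.0:
        return 0.0
    ddof = 0 if variance == "population" else 1
    return float(p.var(ddof=ddof) / m**2)


def npv_map(
    series: BandPowerSeries,
    window_len: float = DEFAULT_WINDOW_LEN,
    step: float = DEFAULT_STEP,
    subject_id: str = "",
    variance: str = "population",
) -> NPVMap:
    """Sliding-window NPV averaged over windows, per voxel and band.

    ``window_len`` and ``step`` must be integer multiples of the series'
    segment length (default 4.6 s windows / 1.15 s steps over 1.15 s
    segments: 4-segment windows advanced by 1 segment).
    """
    if variance not in ("population", "sample"):
        raise ValueError(f"unknown variance convention: {variance!r}")
    seg = series.segment_len
    w = window_len / seg
    s = step / seg
    if abs(w - round(w)) > 1e-9 or abs(s - round(s)) > 1e-9:
        raise ValueError(
            "window_len and step must be integer multiples of the segment length"
        )
    w, s = int(round(w)), int(round(s))
    if w < 2:
        raise ValueError("window must span at least 2 segments")
    n_seg = series.n_segments
    if n_seg < w:
        raise ValueError(
            f"only {n_seg} segments available but the window needs {w}"
        )

    # (V, B, n_windows, w) view over the segment axis
    wins = np.lib.stride_tricks.sliding_window_view(series.power, w, axis=2)[:, :, ::s]
    n_windows = wins.shape[2]
    m = wins.mean(axis=3)
    ddof = 0 if variance == "population" else 1
    v = wins.var(axis=3, ddof=ddof)
    with np.errstate(divide="ignore", invalid="ignore"):
        npv_w = np.where(m > 0, v / m**2, 0.0)
    n_silent = int((m == 0).sum())
    if n_silent:
        logger.info("npv_map: %d all-zero-power windows contributed NPV 0", n_silent)
    return NPVMap(
        npv=npv_w.mean(axis=2),
        n_windows=n_windows,
        window_len=float(window_len),
        step=float(step),
        subject_id=subject_id,
        variance=variance,
    )


def export_npv_csv(
    nmap: NPVMap,
    band_names: list[str],
    voxel_coords: np.ndarray,
    path,
) -> None:
    """Tidy CSV export: subject_id, voxel_id, x, y, z, band, npv."""
    import pandas as pd

    V, B = nmap.npv.shape
    vox, band = np.meshgrid(np.arange(V), np.arange(B), indexing="ij")
    coords = np.asarray(voxel_coords, dtype=float)
    pd.DataFrame({
        "subject_id": nmap.subject_id,
        "voxel_id": vox.ravel(),
        "x": coords[vox.ravel(), 0],
        "y": coords[vox.ravel(), 1],
        "z": coords[vox.ravel(), 2],
        "band": np.array(band_names)[band.ravel()],
        "npv": nmap.npv.ravel(),
    }).to_csv(path, index=False)


def npv_metadata(nmap: NPVMap, segment_len: float, taper: str | None = None) -> dict:
    """JSON-ready provenance for an NPV map."""
    return {
        "window_len_s": nmap.window_len,
        "step_s": nmap.step,
        "n_windows": nmap.n_windows,
        "variance": nmap.variance,
        "segment_len_s": segment_len,
        "taper": taper,
    }
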