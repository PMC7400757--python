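"""Voxel-wise two-group comparison with permutation max-statistic correction.

Subject maps (NPV or subject-normalized eLORETA power) are compared between
shunt responders and non-responders by one-way ANOVA at every voxel and band
(F with 1 and n1+n2-2 degrees of freedom). Family-wise error across voxels
is controlled per band with the permutation distribution of the maximum F
over voxels under random relabeling of subjects; following the study design
the correction runs across voxels within each band, not across bands (the
NPV null distributions differ per band). When the number of distinct
relabelings is small the enumeration is exhaustive and the p-values exact;
otherwise Monte Carlo relabelings are drawn and the (1+b)/(1+n) estimator
avoids zero p-values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np

logger = logging.getLogger(__name__)

RESPONDER = "responder"
NONRESPONDER = "nonresponder"


@dataclass
class SubjectMapSet:
    """Per-subject voxel x band maps with group labels."""

    maps: np.ndarray        # (n_subjects, n_voxels, n_bands)
    labels: tuple[str, ...]  # each in {responder, nonresponder}
    map_kind: str           # {"npv", "power"}
    band_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 3:
            raise ValueError("maps must be subjects x voxels x bands")
        if len(self.labels) != self.maps.shape[0]:
            raise ValueError("one label per subject required")
        bad = set(self.labels) - {RESPONDER, NONRESPONDER}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        for grp in (RESPONDER, NONRESPONDER):
            if self.labels.count(grp) < 2:
                raise ValueError(f"need at least 2 subjects in group {grp!r}")
        if self.map_kind not in ("npv", "power"):
            raise ValueError(f"unknown map kind: {self.map_kind!r}")

    @property
    def group_mask(self) -> np.ndarray:
        """Boolean mask, True for responders."""
        return np.array([lbl == RESPONDER for lbl in self.labels])


@dataclass
class StatMap:
    """Voxel x band F map with permutation-corrected p-values."""

    F: np.ndarray
    logF: np.ndarray
    p_corrected: np.ndarray
    n_permutations: int
    seed: int | None
    extreme: tuple[int, int, float]  # (voxel, band, p)
    exhaustive: bool = False


def subject_normalize(maps: SubjectMapSet) -> SubjectMapSet:
    """Divide each subject's map by its own grand mean (power maps only).

    Removes global per-subject scale so power maps are comparable across
    subjects; after normalization every subject's mean over voxels and bands
    is 1. NPV maps are dimensionless already and are not normalized.
    """
    if maps.map_kind != "power":
        raise ValueError("subject_normalize applies to power maps only")
    means = maps.maps.mean(axis=(1, 2), keepdims=True)
    if np.any(means == 0):
        raise ValueError("subject with an all-zero map cannot be normalized")
    return SubjectMapSet(
        maps=maps.maps / means, labels=maps.labels,
        map_kind=maps.map_kind, band_names=maps.band_names,
    )


def _f_stat(maps: np.ndarray, mask1: np.ndarray) -> np.ndarray:
    """One-way two-group ANOVA F per voxel/band; maps is (S, V, B).

    ``mask1`` may be one mask (S,) or a stack (P, S); the result then has a
    leading permutation axis.
    """
    maps2 = maps.reshape(maps.shape[0], -1)          # (S, VB)
    squeeze = mask1.ndim == 1
    M = np.atleast_2d(mask1).astype(float)           # (P, S)
    n = maps2.shape[0]
    n1 = M.sum(axis=1)                               # (P,)
    n2 = n - n1
    tot = maps2.sum(axis=0)                          # (VB,)
    ss_tot = (maps2**2).sum(axis=0) - tot**2 / n     # (VB,)
    s1 = M @ maps2                                   # (P, VB)
    m1 = s1 / n1[:, None]
    m2 = (tot[None, :] - s1) / n2[:, None]
    gm = tot[None, :] / n
    ssb = n1[:, None] * (m1 - gm) ** 2 + n2[:, None] * (m2 - gm) ** 2
    ssw = np.maximum(ss_tot[None, :] - ssb, 0.0)
    msw = ssw / (n - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(msw > 0, ssb / msw, np.where(ssb > 0, np.inf, 0.0))
    F = F.reshape((M.shape[0],) + maps.shape[1:])
    return F[0] if squeeze else F


def f_ratio_map(maps: SubjectMapSet) -> StatMap:
    """Observed F (and ln F) per voxel/band; p-values left empty (NaN)."""
    F = _f_stat(maps.maps, maps.group_mask)
    if np.any(np.isinf(F)):
        warnings.warn(
            "zero within-group variance with nonzero between-group difference; "
            "F reported as +inf",
            RuntimeWarning,
        )
    with np.errstate(divide="ignore"):
        logF = np.where(F > 0, np.log(np.where(F > 0, F, 1.0)), -np.inf)
    p = np.full_like(F, np.nan)
    return StatMap(F=F, logF=logF, p_corrected=p, n_permutations=0,
                   seed=None, extreme=(0, 0, np.nan))


def _relabelings(n: int, n1: int, n_perm: int, seed) -> tuple[np.ndarray, bool]:
    """Group-1 masks for the null: exhaustive if cheap, else Monte Carlo."""
    n_distinct = comb(n, n1)
    if n_distinct <= n_perm:
        M = np.zeros((n_distinct, n), dtype=bool)
        for i, idx in enumerate(combinations(range(n), n1)):
            M[i, list(idx)] = True
        return M, True
    rng = np.random.default_rng(seed)
    M = np.zeros((n_perm, n), dtype=bool)
    for i in range(n_perm):
        M[i, rng.choice(n, size=n1, replace=False)] = True
    return M, False


def permutation_correct(
    maps: SubjectMapSet,
    n_perm: int = 5000,
    seed: int | None = 0,
    log_transform: bool = False,
    across_bands: bool = False,
    chunk: int = 1000,
) -> StatMap:
    """Max-statistic permutation correction of the voxel-wise ANOVA.

    For each band independently (unless ``across_bands``), the null
    distribution of the maximum F over voxels under subject relabeling gives
    p_corrected(v) = (1 + #{perm max-F >= F_obs(v)}) / (1 + n_perm), or the
    exact proportion when all relabelings are enumerated. ``log_transform``
    runs the ANOVA on ln(maps) instead (NPV is roughly chi-squared shaped);
    the correction itself is invariant to monotone per-voxel rescalings
    shared by all subjects. ``extreme`` is the (voxel, band) of the smallest
    corrected p; ties (the corrected p saturates at its resolution floor for
    every sufficiently large F) are broken by the larger observed F, then by
    lowest voxel index and band order.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    data = maps.maps
    if log_transform:
        if np.any(data <= 0):
            raise ValueError("log transform requires strictly positive maps")
        data = np.log(data)
        maps = SubjectMapSet(data, maps.labels, maps.map_kind, maps.band_names)

    obs = f_ratio_map(maps)
    mask_obs = maps.group_mask
    n = data.shape[0]
    n1 = int(mask_obs.sum())

    M, exhaustive = _relabelings(n, n1, n_perm, seed)
    n_total = M.shape[0]
    # permutation max-F per band, accumulated in chunks
    n_bands = data.shape[2]
    max_axis = (1, 2) if across_bands else (1,)
    max_f = np.empty((n_total, 1 if across_bands else n_bands))
    for lo in range(0, n_total, chunk):
        Fp = _f_stat(data, M[lo:lo + chunk])          # (p, V, B)
        mf = Fp.max(axis=max_axis)
        max_f[lo:lo + chunk] = mf.reshape(mf.shape[0], -1)

    # count permutations whose max-F reaches each observed F
    Fo = obs.F  # (V, B)
    if across_bands:
        ge = max_f[:, None, None, 0] >= Fo[None, :, :]
    else:
        ge = max_f[:, None, :] >= Fo[None, :, :]
    count = ge.sum(axis=0)
    if exhaustive:
        p = count / n_total
    else:
        p = (1.0 + count) / (1.0 + n_total)
    p = np.clip(p, 0.0, 1.0)

    # tie-break: smallest p, then largest F, then lowest voxel index / band
    cand = np.argwhere(p == p.min())
    v_ext, b_ext = min(
        ((int(v), int(b)) for v, b in cand),
        key=lambda vb: (-Fo[vb], vb[0], vb[1]),
    )
    extreme = (v_ext, b_ext, float(p[v_ext, b_ext]))
    return StatMap(
        F=obs.F, logF=obs.logF, p_corrected=p,
        n_permutations=n_total, seed=seed, extreme=extreme,
        exhaustive=exhaustive,
    )


def export_statmap_csv(
    sm: StatMap, voxel_coords: np.ndarray, band_names: tuple[str, ...], path
) -> None:
    """Tidy CSV: voxel_id, x, y, z, band, F, logF, p_corrected."""
    import pandas as pd

    V, B = sm.F.shape
    vox, band = np.meshgrid(np.arange(V), np.arange(B), indexing="ij")
    coords = np.asarray(voxel_coords, dtype=float)
    pd.DataFrame({
        "voxel_id": vox.ravel(),
        "x": coords[vox.ravel(), 0],
        "y": coords[vox.ravel(), 1],
        "z": coords[vox.ravel(), 2],
        "band": np.array(band_names)[band.ravel()],
        "F": sm.F.ravel(),
        "logF": sm.logF.ravel(),
        "p_corrected": sm.p_corrected.ravel(),
    }).to_csv(path, index=False)


def statmap_metadata(sm: StatMap) -> dict:
    return {
        "n_permutations": sm.n_permutations,
        "seed": sm.seed,
        "exhaustive": sm.exhaustive,
        "extreme_voxel": sm.extreme[0],
        "extreme_band": sm.extreme[1],
        "extreme_p": sm.extreme[2],
    }
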