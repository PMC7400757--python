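"""Three-shell spherical-head EEG forward model.

The leadfield maps a unit current dipole at each source voxel (3 orthogonal
orientations) to average-referenced potentials at the scalp electrodes. The
head is modelled as three concentric conducting shells (brain, skull, scalp);
the potential of a dipole inside a layered sphere is computed with the
classical Legendre-series expansion, propagating the per-degree harmonic
coefficients across shell boundaries (continuity of potential and of radial
current) and imposing zero radial current at the scalp surface.

Geometry is desk-scale deliberately: a regular voxel grid inside the brain
shell stands in for a realistic MRI-based cortical solution space. All
downstream algorithms (inverse, power, NPV, statistics) are agnostic to the
head model given any gain matrix, and an import path for externally computed
leadfields is provided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_eeg import Montage

logger = logging.getLogger(__name__)


class LeadfieldFormatError(ValueError):
    """A leadfield file is structurally inconsistent."""


@dataclass(frozen=True)
class SphericalModelSpec:
    """Three-shell concentric sphere head geometry.

    Radii are ordered innermost to outermost (brain, skull, scalp) in mm;
    conductivities in S/m use the conventional 3-shell values with a
    low-conducting skull. Source voxels fill a regular grid restricted to
    85% of the brain radius (dipoles too close to a conductivity boundary
    make the series expansion slow to converge and are physiologically
    implausible for cortical grey matter anyway).
    """

    shell_radii_mm: tuple[float, float, float] = (79.0, 82.0, 87.0)
    shell_conductivities: tuple[float, float, float] = (0.33, 0.0042, 0.33)
    grid_spacing_mm: float = 25.0
    max_source_radius_fraction: float = 0.85

    def __post_init__(self) -> None:
        r = self.shell_radii_mm
        if not (0 < r[0] < r[1] < r[2]):
            raise ValueError("shell radii must increase brain -> skull -> scalp")
        if any(c <= 0 for c in self.shell_conductivities):
            raise ValueError("conductivities must be positive")
        if self.grid_spacing_mm <= 0:
            raise ValueError("grid spacing must be positive")


@dataclass
class Leadfield:
    """Forward gain: sensors x voxels x orientations, with voxel coordinates."""

    gain: np.ndarray          # (n_sensors, n_voxels, n_orient), orient in {1, 3}
    voxel_coords: np.ndarray  # (n_voxels, 3), mm
    montage: Montage
    model_tag: str = ""

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=float)
        self.voxel_coords = np.asarray(self.voxel_coords, dtype=float)
        if self.gain.ndim != 3:
            raise LeadfieldFormatError("gain must be sensors x voxels x orientations")
        if self.gain.shape[2] not in (1, 3):
            raise LeadfieldFormatError(
                f"unsupported orientation count: {self.gain.shape[2]}"
            )
        if self.gain.shape[0] != self.montage.n_channels:
            raise LeadfieldFormatError(
                f"gain has {self.gain.shape[0]} sensor rows but montage has "
                f"{self.montage.n_channels} labels"
            )
        if self.gain.shape[1] != self.voxel_coords.shape[0]:
            raise LeadfieldFormatError("gain voxel axis disagrees with coordinates")
        if self.gain.shape[1] < 2:
            raise LeadfieldFormatError("leadfield needs at least 2 voxels")
        if not np.all(np.isfinite(self.gain)):
            raise LeadfieldFormatError("gain entries must be finite")
        col_norm = np.linalg.norm(self.gain, axis=0)
        if np.any(col_norm == 0):
            raise LeadfieldFormatError("leadfield contains an all-zero gain column")

    @property
    def n_sensors(self) -> int:
        return self.gain.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.gain.shape[1]

    @property
    def n_orient(self) -> int:
        return self.gain.shape[2]


# ---------------------------------------------------------------------------
# Layered-sphere potential
# ---------------------------------------------------------------------------

def _scalp_transfer(n_terms: int, radii_m: np.ndarray, sigmas: np.ndarray) -> np.ndarray:
    """Scalp-surface harmonic transfer coefficients T_n, n = 1..n_terms.

    For each Legendre degree n the potential in shell j is
    A_j r^n + B_j r^-(n+1). The dipole's primary field fixes the inner B; the
    inner A and all outer coefficients follow from continuity of V and of
    sigma dV/dr at each interface plus zero radial current at the outer
    surface. T_n is the scalp-surface potential produced by a unit inner
    source coefficient (B_1 = 1).
    """
    L = len(radii_m)
    T = np.empty(n_terms)
    R = radii_m[-1]
    for i, n in enumerate(range(1, n_terms + 1)):
        # coefficients in layer j as linear functions of the unknown inner A:
        # (A_j, B_j) = u_j * A1 + v_j, with B_1 = 1 the source term
        u = np.array([1.0, 0.0])
        v = np.array([0.0, 1.0])
        for j in range(L - 1):
            a = radii_m[j]
            s1, s2 = sigmas[j], sigmas[j + 1]
            # continuity of V and of sigma * dV/dr at radius a
            mat = np.array([
                [a**n, a**-(n + 1)],
                [s2 * n * a**(n - 1), -s2 * (n + 1) * a**-(n + 2)],
            ])
            rhs_u = np.array([
                u[0] * a**n + u[1] * a**-(n + 1),
                s1 * (u[0] * n * a**(n - 1) - u[1] * (n + 1) * a**-(n + 2)),
            ])
            rhs_v = np.array([
                v[0] * a**n + v[1] * a**-(n + 1),
                s1 * (v[0] * n * a**(n - 1) - v[1] * (n + 1) * a**-(n + 2)),
            ])
            u = np.linalg.solve(mat, rhs_u)
            v = np.linalg.solve(mat, rhs_v)
        # insulating exterior: dV/dr = 0 at the scalp surface
        cu = u[0] * n * R**(n - 1) - u[1] * (n + 1) * R**-(n + 2)
        cv = v[0] * n * R**(n - 1) - v[1] * (n + 1) * R**-(n + 2)
        A1 = -cv / cu
        aL = u[0] * A1 + v[0]
        bL = u[1] * A1 + v[1]
        T[i] = aL * R**n + bL * R**-(n + 1)
    return T


def _legendre_p_and_dp(x: np.ndarray, n_max: int) -> tuple[np.ndarray, np.ndarray]:
    """P_n(x) and P_n'(x) for n = 1..n_max via stable recurrences."""
    x = np.asarray(x, dtype=float)
    P = np.empty((n_max + 1,) + x.shape)
    dP = np.empty_like(P)
    P[0], P[1] = 1.0, x
    dP[0], dP[1] = 0.0, 1.0
    for n in range(2, n_max + 1):
        P[n] = ((2 * n - 1) * x * P[n - 1] - (n - 1) * P[n - 2]) / n
        dP[n] = dP[n - 2] + (2 * n - 1) * P[n - 1]
    return P[1:], dP[1:]


def dipole_potentials(
    electrodes_m: np.ndarray,
    dipole_pos_m: np.ndarray,
    spec: SphericalModelSpec,
    n_terms: int = 100,
) -> np.ndarray:
    """Potentials (V) at scalp electrodes for the 3 unit dipoles (A*m) at one voxel.

    Returns an (n_electrodes, 3) matrix: column k is the potential field of a
    unit dipole along axis k. Potentials are referenced to infinity; the
    caller removes the mean for average-reference compatibility.
    """
    radii = np.asarray(spec.shell_radii_mm, float) * 1e-3
    sig = np.asarray(spec.shell_conductivities, float)
    T = _scalp_transfer(n_terms, radii, sig)

    f = np.linalg.norm(dipole_pos_m)
    r0_hat = dipole_pos_m / f if f > 1e-12 else np.array([0.0, 0.0, 1.0])
    e_norm = np.linalg.norm(electrodes_m, axis=1)
    e_hat = electrodes_m / e_norm[:, None]
    cosg = np.clip(e_hat @ r0_hat, -1.0, 1.0)

    ns = np.arange(1, n_terms + 1, dtype=float)
    with np.errstate(divide="ignore"):
        f_pow = np.where(ns == 1, 1.0, f ** (ns - 1))  # f^(n-1), 0^0 := 1
    g = T * f_pow / (4.0 * np.pi * sig[0])  # per-degree source-to-scalp factor

    P, dP = _legendre_p_and_dp(cosg, n_terms)  # (n_terms, n_elec)
    rad_series = (g * ns) @ P        # sum_n g_n * n * P_n(cos gamma)
    tan_series = g @ dP              # sum_n g_n * P_n'(cos gamma)

    # V = rad_series * (q . r0_hat) + tan_series * (q . (e_hat - cosg * r0_hat))
    tvec = e_hat - cosg[:, None] * r0_hat[None, :]
    out = rad_series[:, None] * r0_hat[None, :] + tan_series[:, None] * tvec
    return out


def _make_grid(spec: SphericalModelSpec) -> np.ndarray:
    """Regular voxel grid (mm) inside the allowed source sphere."""
    r_max = spec.max_source_radius_fraction * spec.shell_radii_mm[0]
    h = spec.grid_spacing_mm
    k = int(np.floor(r_max / h))
    axis = np.arange(-k, k + 1) * h
    X, Y, Z = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    keep = np.linalg.norm(pts, axis=1) <= r_max + 1e-9
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("grid: excluded %d points outside the source sphere", n_dropped)
    return pts[keep]


def build_spherical_leadfield(
    spec: SphericalModelSpec,
    montage: Montage,
    n_terms: int = 100,
) -> Leadfield:
    """Analytic 3-shell leadfield on a regular grid, average-referenced.

    Each gain column is the scalp field of a unit dipole (A*m) along one of
    the 3 Cartesian axes at one grid voxel, with the mean over sensors
    removed so that the gain is compatible with average-referenced data.
    """
    coords = _make_grid(spec)
    if coords.shape[0] < 2:
        raise ValueError("voxel grid is empty or degenerate; decrease spacing")
    elec = montage.positions * (spec.shell_radii_mm[2] * 1e-3)
    gain = np.empty((montage.n_channels, coords.shape[0], 3))
    for v, pos in enumerate(coords):
        gain[:, v, :] = dipole_potentials(elec, pos * 1e-3, spec, n_terms)
    gain -= gain.mean(axis=0, keepdims=True)
    tag = (
        f"sphere3({spec.shell_radii_mm[0]:g}/{spec.shell_radii_mm[1]:g}/"
        f"{spec.shell_radii_mm[2]:g}mm,h={spec.grid_spacing_mm:g}mm)"
    )
    return Leadfield(gain=gain, voxel_coords=coords, montage=montage, model_tag=tag)


# ---------------------------------------------------------------------------
# Leadfield container I/O (HDF5 named arrays)
# ---------------------------------------------------------------------------

def write_leadfield(lf: Leadfield, path) -> None:
    """Write a leadfield to an HDF5 container with named arrays."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("gain", data=lf.gain)
        f.create_dataset("coords", data=lf.voxel_coords)
        f.create_dataset("labels", data=np.array(lf.montage.labels, dtype="S"))
        f.create_dataset("positions", data=lf.montage.positions)
        f.attrs["model_tag"] = lf.model_tag


def read_leadfield(path) -> Leadfield:
    """Read a leadfield container written by :func:`write_leadfield`."""
    import h5py

    with h5py.File(path, "r") as f:
        gain = f["gain"][()]
        coords = f["coords"][()]
        labels = tuple(s.decode() for s in f["labels"][()])
        positions = f["positions"][()]
        tag = str(f.attrs.get("model_tag", ""))
    if gain.ndim != 3 or gain.shape[2] not in (1, 3):
        raise LeadfieldFormatError(
            f"unsupported orientation count: {gain.shape[2] if gain.ndim == 3 else '?'}"
        )
    if gain.shape[0] != len(labels):
        raise LeadfieldFormatError(
            f"gain has {gain.shape[0]} sensor rows but {len(labels)} montage labels"
        )
    montage = Montage(labels, positions)
    return Leadfield(gain=gain, voxel_coords=coords, montage=montage, model_tag=tag)
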