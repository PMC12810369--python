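"""Monolayer structural observables: tilt, O-O spacing, density and potential.

Covers the slab-resolved observables used to characterise how adsorbed ions
reorganize a carboxylate monolayer: per-ligand chain tilt angles, intra- and
intermolecular carboxylate O-O distances, species number-density profiles
along z, and the electrostatic potential obtained by double integration of
the charge-density profile (Poisson's equation in slab geometry, field and
potential both zero at z = 0). A sign change of the potential inside the ion
layer flags charge inversion (overcharging by the divalent counterions).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .binding import _smooth
from .constants import EPS0, EPS_WATER, KJ_PER_MOL_E_TO_VOLT
from .trajectory import SimBox, Trajectory

__all__ = [
    "TiltResult",
    "OORDFResult",
    "DensityProfile",
    "PotentialProfile",
    "tilt_angles",
    "oo_rdf_peaks",
    "density_profile",
    "electrostatic_potential",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# tilt


@dataclass
class TiltResult:
    """Per-ligand chain tilt angles vs the surface normal, degrees in [0, 90]."""

    angles: np.ndarray
    mean: float
    std: float
    n_skipped: int = 0


def _chain_axis(coords: np.ndarray, mode: str) -> np.ndarray | None:
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < 2:
        raise ValueError("chains need at least two atoms")
    if mode == "endpoints":
        v = coords[-1] - coords[0]
    else:  # principal axis of the centered atom cloud (robust to kinks)
        centered = coords - coords.mean(axis=0)
        _, s, vt = np.linalg.svd(centered, full_matrices=False)
        if s[0] < 1e-12:
            return None
        v = vt[0]
    n = np.linalg.norm(v)
    return None if n < 1e-12 else v / n


def tilt_angles(chains, axis_mode: str = "principal") -> TiltResult:
    """Tilt angle of each ligand chain relative to +z, folded to [0, 90] deg.

    ``chains`` is a sequence of (n_atoms, 3) coordinate arrays, one per
    ligand. ``axis_mode`` selects the chain-axis definition: ``"principal"``
    (least-squares line through all atoms, default) or ``"endpoints"``
    (first-to-last atom vector). Degenerate chains (all atoms coincident)
    are skipped with a warning.
    """
    angles = []
    skipped = 0
    for ci, coords in enumerate(chains):
        v = _chain_axis(coords, axis_mode)
        if v is None:
            log.warning("chain %d is degenerate (coincident atoms); skipped", ci)
            skipped += 1
            continue
        cosang = abs(float(v[2]))
        angles.append(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))
    if not angles:
        raise ValueError("no usable chains")
    arr = np.array(angles)
    return TiltResult(arr, float(arr.mean()), float(arr.std(ddof=0)), skipped)


# ---------------------------------------------------------------------------
# carboxylate O-O structure


@dataclass
class OORDFResult:
    """Intramolecular O-O distance plus the intermolecular O-O RDF."""

    intra_mean: float
    r_centers: np.ndarray | None
    g: np.ndarray | None
    second_peak_r: float | None


def oo_rdf_peaks(
    o_positions: np.ndarray,
    box: SimBox | None = None,
    r_max: float = 1.0,
    dr: float = 0.005,
    smoothing: int = 5,
) -> OORDFResult:
    """Carboxylate oxygen structure from (n_frames, n_ligands, 2, 3) coords.

    The intramolecular distance averages |O1 - O2| per ligand and frame; the
    intermolecular RDF histograms all O-O pairs excluding same-ligand pairs,
    and the position of its *second* peak (after centered moving-average
    smoothing) characterises the neighbour carboxylate spacing. A single
    ligand yields the intra distance only.
    """
    pos = np.asarray(o_positions, dtype=float)
    if pos.ndim == 3:
        pos = pos[None]
    n_frames, n_lig = pos.shape[0], pos.shape[1]
    intra = np.linalg.norm(pos[:, :, 0, :] - pos[:, :, 1, :], axis=-1)
    intra_mean = float(intra.mean())
    if n_lig < 2:
        log.warning("single ligand: intermolecular O-O RDF unavailable")
        return OORDFResult(intra_mean, None, None, None)
    edges = np.arange(0.0, r_max + dr, dr)
    counts = np.zeros(edges.size - 1)
    flat = pos.reshape(n_frames, n_lig * 2, 3)
    ligand_of = np.repeat(np.arange(n_lig), 2)
    same = ligand_of[:, None] == ligand_of[None, :]
    for fi in range(n_frames):
        drv = flat[fi][:, None, :] - flat[fi][None, :, :]
        if box is not None:
            drv = box.minimum_image(drv)
        d = np.sqrt(np.einsum("ijk,ijk->ij", drv, drv))
        d[same] = np.inf
        iu = np.triu_indices(d.shape[0], k=1)
        counts += np.histogram(d[iu][d[iu] < r_max], bins=edges)[0]
    r_centers = 0.5 * (edges[:-1] + edges[1:])
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    g = counts / np.maximum(shell, 1e-30) / max(counts.sum(), 1.0)  # shape only
    gs = _smooth(g, smoothing)
    from scipy.signal import argrelextrema

    peaks = [int(p) for p in argrelextrema(gs, np.greater_equal, order=2)[0]
             if gs[p] > 1e-12]
    dedup = []
    for p in peaks:
        if not dedup or p - dedup[-1] > 2:
            dedup.append(p)
    second = float(r_centers[dedup[1]]) if len(dedup) >= 2 else None
    return OORDFResult(intra_mean, r_centers, g, second)


# ---------------------------------------------------------------------------
# density and potential profiles


@dataclass
class DensityProfile:
    """Species-resolved number density along z (nm^-3) on a common grid."""

    z_centers: np.ndarray
    number_density: dict[str, np.ndarray]
    area: float
    dz: float
    n_frames: int

    def charge_density(self, charges: dict[str, float]) -> np.ndarray:
        """Charge density e/nm^3 from per-species charges."""
        rho = np.zeros_like(self.z_centers)
        for sp, dens in self.number_density.items():
            rho += charges.get(sp, 0.0) * dens
        return rho

    def particle_count(self, species: str) -> float:
        """Integral of a species density (particles; exact by construction)."""
        return float(self.number_density[species].sum() * self.area * self.dz)


def density_profile(traj: Trajectory, species: list[str], dz: float = 0.02) -> DensityProfile:
    """Per-species z histograms normalized by bin volume and frame count."""
    if dz <= 0:
        raise ValueError("dz must be > 0")
    edges = np.arange(0.0, traj.box.lz + dz, dz)
    centers = 0.5 * (edges[:-1] + edges[1:])
    area = traj.box.lx * traj.box.ly
    dens: dict[str, np.ndarray] = {}
    for sp in species:
        idx = traj.atom_indices(sp)
        z = np.clip(traj.frames[:, idx, 2].ravel(), 0.0, traj.box.lz - 1e-12)
        hist = np.histogram(z, bins=edges)[0].astype(float)
        dens[sp] = hist / (area * dz * traj.n_frames)
    return DensityProfile(centers, dens, area, dz, traj.n_frames)


@dataclass
class PotentialProfile:
    """Electrostatic potential from Poisson double integration, psi(0) = 0."""

    z: np.ndarray
    field: np.ndarray            # kJ mol^-1 e^-1 nm^-1
    psi: np.ndarray              # kJ mol^-1 e^-1
    psi_volts: np.ndarray
    eps_r: float
    total_charge_per_area: float
    charge_inversion: bool


def electrostatic_potential(
    z: np.ndarray,
    charge_density: np.ndarray,
    eps_r: float = EPS_WATER,
) -> PotentialProfile:
    """Integrate rho(z) (e/nm^3) twice for the slab electrostatic potential.

    E(z) = (1/eps0 eps_r) * int_0^z rho dz'   (field zero at z = 0)
    psi(z) = -int_0^z E dz'                   (potential zero at z = 0)

    using trapezoidal cumulative integration. ``charge_inversion`` flags a
    sign change of psi away from z = 0, the signature of overcharging by
    adsorbed multivalent counterions. The net charge per area is logged.
    """
    z = np.asarray(z, dtype=float)
    rho = np.asarray(charge_density, dtype=float)
    if z.shape != rho.shape:
        raise ValueError("z and charge_density must have equal shape")
    sigma = float(np.trapezoid(rho, z))
    log.info("total charge per area: %.6g e/nm^2", sigma)
    E = cumulative_trapezoid(rho, z, initial=0.0) / (EPS0 * eps_r)
    psi = -cumulative_trapezoid(E, z, initial=0.0)
    tol = 1e-9 * max(1.0, float(np.max(np.abs(psi))))
    signs = np.sign(psi[np.abs(psi) > tol])
    inversion = bool(signs.size and np.any(signs[:-1] * signs[1:] < 0))
    return PotentialProfile(z, E, psi, psi * KJ_PER_MOL_E_TO_VOLT, eps_r,
                            sigma, inversion)
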