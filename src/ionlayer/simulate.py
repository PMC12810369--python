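"""Overdamped Langevin (Brownian) dynamics of ions above a carboxylate lattice.

This is a reduced, implicit-solvent surrogate of the full explicit-solvent MD:
ions move by Euler-Maruyama Brownian dynamics in the nonbonded field of the
(static) carboxylate headgroups, with the solvent entering only through the
friction coefficient and a relative dielectric constant that screens the
Coulomb interaction. It supports equilibrium runs, constant-rate pulls of a
single ion along z, and umbrella-sampling windows on the z reaction
coordinate.

Units: nm, ps, kJ/mol, e, K, u (atomic mass unit). With masses in u and the
friction rate gamma in 1/ps, the friction coefficient is zeta = m*gamma (u/ps)
and the diffusion constant D = k_B T / zeta (nm^2/ps).

The z axis is bounded by reflecting walls at 0 and lz; x and y are periodic
with minimum-image interactions truncated at a plain cutoff (no Ewald sums —
this engine is a test harness for the analysis pipeline, not an MD package).

Note on ECC vs dielectric screening: the electronic continuum correction
scales *charges* (a property of the force field); the relative dielectric
``eps_r`` screens the *medium* in lieu of explicit water. Both may be active
simultaneously without double counting — explicit-solvent MD would use the
ECC alone with eps_r = 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .constants import EPS_WATER, K_COULOMB, KB, MOLAR_MASS
from .forcefield import ForceFieldSet, IonParams
from .monolayer import Headgroup
from .trajectory import SimBox, Trajectory

__all__ = [
    "System",
    "PullProtocol",
    "PullRecord",
    "UmbrellaWindow",
    "simulate_langevin",
    "run_constant_pull",
    "run_umbrella_windows",
    "DEFAULT_HEADGROUP_PARAMS",
]

log = logging.getLogger(__name__)

#: Generic carboxylate-atom LJ parameters (CHARMM-like carbonyl C / carboxylate
#: O magnitudes) and the default -0.5 e per oxygen charge assignment.
DEFAULT_HEADGROUP_PARAMS = {
    "C": IonParams("C", 0.0, 0.29288, 0.200),
    "O1": IonParams("O1", -0.5, 0.50208, 0.170),
    "O2": IonParams("O2", -0.5, 0.50208, 0.170),
}

_ATOM_MASS = {"C": 12.011, "O1": 15.999, "O2": 15.999, **MOLAR_MASS}


@dataclass
class System:
    """Mobile ions + static headgroup atoms ready for Brownian dynamics.

    Headgroup atoms are immobile (the infinite-stiffness limit of the lattice
    tether); mobile particles may carry an optional harmonic tether to a fixed
    anchor, which doubles as the external potential for calibration runs.
    """

    box: SimBox
    mobile_pos: np.ndarray          # (n_mobile, 3)
    mobile_labels: list[str]
    q_mobile: np.ndarray
    eps_mobile: np.ndarray
    rminh_mobile: np.ndarray
    mass_mobile: np.ndarray
    static_pos: np.ndarray          # (n_static, 3); may be empty
    static_labels: list[str]
    q_static: np.ndarray
    eps_static: np.ndarray
    rminh_static: np.ndarray
    coulomb_constant: float = K_COULOMB / EPS_WATER
    cutoff: float = 1.2
    tether_anchor: np.ndarray | None = None
    tether_k: float = 0.0
    metadata: dict = field(default_factory=dict)

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_components(
        cls,
        headgroups: list[Headgroup],
        ion_counts: dict[str, int],
        ff: ForceFieldSet,
        box: SimBox,
        eps_r: float = EPS_WATER,
        cutoff: float = 1.2,
        scale_headgroup_charges: bool = False,
        headgroup_params: dict[str, IonParams] | None = None,
        seed: int = 0,
        z_range: tuple[float, float] | None = None,
    ) -> "System":
        """Assemble a monolayer + ions system.

        Ion charges carry the force field's ECC factor; headgroup charges are
        scaled too only if ``scale_headgroup_charges`` (recorded in metadata).
        Ions start uniformly at random in ``z_range`` (default: above the
        headgroup plane).
        """
        hg_params = headgroup_params or DEFAULT_HEADGROUP_PARAMS
        f = ff.ecc_factor
        s_pos, s_lab, s_q, s_eps, s_rh = [], [], [], [], []
        for hg in headgroups:
            for name, pos in (("C", hg.c_pos), ("O1", hg.o1_pos), ("O2", hg.o2_pos)):
                p = hg_params[name]
                q = hg.charge_assignment.get(name, p.Q)
                s_pos.append(pos)
                s_lab.append(name)
                s_q.append(q * (f if scale_headgroup_charges else 1.0))
                s_eps.append(p.epsilon)
                s_rh.append(p.rmin_half)
        rng = np.random.default_rng(seed)
        z_top = max((p[2] for p in s_pos), default=0.0)
        z_lo, z_hi = z_range or (z_top + 0.25, box.lz - 0.25)
        m_pos, m_lab, m_q, m_eps, m_rh, m_mass = [], [], [], [], [], []
        for species, count in ion_counts.items():
            p = ff[species]
            for _ in range(count):
                m_pos.append([rng.uniform(0, box.lx), rng.uniform(0, box.ly),
                              rng.uniform(z_lo, z_hi)])
                m_lab.append(species)
                m_q.append(f * p.Q)
                m_eps.append(p.epsilon)
                m_rh.append(p.rmin_half)
                m_mass.append(_ATOM_MASS.get(species, 40.0))
        return cls(
            box=box,
            mobile_pos=np.array(m_pos, dtype=float).reshape(-1, 3),
            mobile_labels=m_lab,
            q_mobile=np.array(m_q), eps_mobile=np.array(m_eps),
            rminh_mobile=np.array(m_rh), mass_mobile=np.array(m_mass),
            static_pos=np.array(s_pos, dtype=float).reshape(-1, 3),
            static_labels=s_lab,
            q_static=np.array(s_q), eps_static=np.array(s_eps),
            rminh_static=np.array(s_rh),
            coulomb_constant=K_COULOMB / eps_r,
            cutoff=cutoff,
            metadata={
                "forcefield": ff.name,
                "ecc_factor": f,
                "ecc_on_headgroups": scale_headgroup_charges,
                "eps_r": eps_r,
                "combining_rule": ff.combining_rule,
                "seed": seed,
            },
        )

    @classmethod
    def ideal(cls, positions: np.ndarray, box: SimBox, mass: float = 40.0,
              label: str = "Ca2+") -> "System":
        """Non-interacting particles (zero charge, zero LJ) for calibration."""
        pos = np.asarray(positions, dtype=float).reshape(-1, 3)
        n = pos.shape[0]
        zeros = np.zeros(n)
        return cls(
            box=box, mobile_pos=pos.copy(), mobile_labels=[label] * n,
            q_mobile=zeros.copy(), eps_mobile=zeros.copy(),
            rminh_mobile=np.full(n, 0.1), mass_mobile=np.full(n, mass),
            static_pos=np.empty((0, 3)), static_labels=[],
            q_static=np.empty(0), eps_static=np.empty(0), rminh_static=np.empty(0),
        )

    # -- derived quantities --------------------------------------------------

    @property
    def n_mobile(self) -> int:
        return self.mobile_pos.shape[0]

    @property
    def n_static(self) -> int:
        return self.static_pos.shape[0]

    def with_tether(self, anchor: np.ndarray, k: float) -> "System":
        """Attach a harmonic tether U = k/2 |x - anchor|^2 to every mobile atom."""
        import copy

        new = copy.deepcopy(self)
        new.tether_anchor = np.asarray(anchor, dtype=float).reshape(-1, 3)
        if new.tether_anchor.shape[0] == 1:
            new.tether_anchor = np.repeat(new.tether_anchor, self.n_mobile, axis=0)
        new.tether_k = float(k)
        return new

    def _interacting(self) -> bool:
        return bool(
            self.n_static
            or self.n_mobile > 1
            and (np.any(self.q_mobile != 0) or np.any(self.eps_mobile != 0))
        )

    def forces(self, pos: np.ndarray) -> np.ndarray:
        """Total force on each mobile particle at positions ``pos`` (kJ/mol/nm)."""
        F = np.zeros_like(pos)
        if self._interacting():
            all_pos = (
                np.concatenate([pos, self.static_pos]) if self.n_static else pos
            )
            all_q = np.concatenate([self.q_mobile, self.q_static])
            all_eps = np.concatenate([self.eps_mobile, self.eps_static])
            all_rh = np.concatenate([self.rminh_mobile, self.rminh_static])
            dr = self.box.minimum_image(pos[:, None, :] - all_pos[None, :, :])
            r2 = np.einsum("ijk,ijk->ij", dr, dr)
            n = self.n_mobile
            r2[np.arange(n), np.arange(n)] = np.inf  # self-pairs
            mask = r2 <= self.cutoff**2
            # avoid double-counting mobile-mobile pairs? no: force on i sums
            # over all j, each ordered pair contributes once to i.
            r2 = np.where(mask, r2, np.inf)
            r = np.sqrt(r2)
            eps_ij = np.sqrt(self.eps_mobile[:, None] * all_eps[None, :])
            rmin_ij = self.rminh_mobile[:, None] + all_rh[None, :]
            qq = self.q_mobile[:, None] * all_q[None, :]
            x6 = (rmin_ij / r) ** 6
            fmag = 12.0 * eps_ij * (x6 * x6 - x6) / r + self.coulomb_constant * qq / r2
            with np.errstate(invalid="ignore"):
                F += np.einsum("ij,ijk->ik", np.where(mask, fmag / r, 0.0), dr)
        if self.tether_anchor is not None and self.tether_k > 0:
            F += -self.tether_k * (pos - self.tether_anchor)
        return F

    def trajectory_labels(self) -> list[str]:
        return list(self.static_labels) + list(self.mobile_labels)


def _reflect_z(z: np.ndarray, lz: float) -> np.ndarray:
    """Reflect coordinates into [0, lz] (handles multiple crossings)."""
    period = 2.0 * lz
    z = np.mod(z, period)
    return np.where(z > lz, period - z, z)


def _check_timestep(system: System, dt: float, friction: float, extra_k: float = 0.0) -> None:
    """Heuristic stability check: dt must be small vs zeta/k of the stiffest spring."""
    k_max = max(system.tether_k or 0.0, extra_k)
    if k_max <= 0:
        return
    zeta_min = float(np.min(system.mass_mobile)) * friction
    if dt > 0.2 * zeta_min / k_max:
        log.warning(
            "dt=%g ps exceeds 0.2*zeta/k=%g ps for the stiffest spring; "
            "overdamped integration may be inaccurate", dt, 0.2 * zeta_min / k_max
        )


def simulate_langevin(
    system: System,
    n_steps: int,
    dt: float = 0.01,
    T: float = 300.0,
    friction: float = 1.0,
    seed: int = 0,
    out_every: int = 100,
    wrap: bool = True,
    _bias=None,
) -> Trajectory:
    """Euler-Maruyama Brownian dynamics; reproducible from ``seed``.

    ``friction`` is the rate gamma in 1/ps; each particle's friction
    coefficient is m*gamma and its diffusion constant k_B T/(m*gamma).
    ``wrap=False`` leaves coordinates unwrapped (for MSD analysis); z-walls
    still reflect. ``_bias`` is an internal hook: callable(step, pos) -> force
    array added to the physical forces.

    Raises RuntimeError if any coordinate exceeds 10x the box (divergence).
    """
    _check_timestep(system, dt, friction)
    rng = np.random.default_rng(seed)
    pos = system.mobile_pos.copy()
    zeta = (system.mass_mobile * friction)[:, None]
    kT = KB * T
    noise_amp = np.sqrt(2.0 * kT * dt / zeta)
    frames = [np.concatenate([system.static_pos, pos]) if system.n_static else pos.copy()]
    limit = 10.0 * max(system.box.lx, system.box.ly, system.box.lz)
    for step in range(1, n_steps + 1):
        F = system.forces(pos if wrap else system.box.wrap(pos))
        if _bias is not None:
            F = F + _bias(step - 1, pos)
        pos = pos + F / zeta * dt + noise_amp * rng.standard_normal(pos.shape)
        if not np.all(np.isfinite(pos)) or np.any(np.abs(pos) > limit):
            finite = np.isfinite(pos).all(axis=1)
            bad = int(np.argmax(~finite | np.any(np.abs(pos) > limit, axis=1)))
            raise RuntimeError(
                f"Brownian dynamics diverged at step {step}: particle {bad} at "
                f"{pos[bad]} exceeds 10x the box; reduce dt or check parameters"
            )
        pos[:, 2] = _reflect_z(pos[:, 2], system.box.lz)
        if wrap:
            pos = system.box.wrap(pos)
        if step % out_every == 0:
            frames.append(
                np.concatenate([system.static_pos, pos]) if system.n_static else pos.copy()
            )
    prov = {
        "engine": "overdamped-langevin",
        "n_steps": n_steps, "dt_ps": dt, "T_K": T,
        "friction_per_ps": friction, "seed": seed,
        **system.metadata,
    }
    return Trajectory(np.stack(frames), system.trajectory_labels(), system.box,
                      dt_out=dt * out_every, provenance=prov)


# ---------------------------------------------------------------------------
# constant-rate pulling


@dataclass(frozen=True)
class PullProtocol:
    """Constant-rate harmonic pull along the z reaction coordinate.

    The reaction coordinate is the z component of the vector from the
    monolayer center of mass to the target ion. Defaults echo the reference
    protocol: k = 5000 kJ/mol/nm^2 at 2e-5 nm/ps.
    """

    k_pull: float = 5000.0
    rate: float = 2e-5
    target_ion: int = 0

    def __post_init__(self) -> None:
        if self.k_pull <= 0:
            raise ValueError("k_pull must be > 0")
        if self.rate < 0:
            raise ValueError("pull rate must be >= 0")


@dataclass
class PullRecord:
    """Force-vs-time output of a constant-rate pull.

    ``force`` is the force the ion exerts on the moving restraint along +z,
    k_pull*(z_ion - z_center), in kJ mol^-1 nm^-1: a bound (lagging) ion gives
    a negative, attractive dip. ``center_z`` is the absolute restraint center.
    """

    time: np.ndarray
    center_z: np.ndarray
    force: np.ndarray
    ion_id: int = 0
    protocol: PullProtocol | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if self.time.size > 1 and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")


def run_constant_pull(
    system: System,
    protocol: PullProtocol,
    n_steps: int,
    dt: float = 0.01,
    T: float = 300.0,
    friction: float = 1.0,
    seed: int = 0,
    out_every: int = 100,
) -> PullRecord:
    """Pull one ion away from the monolayer with a moving harmonic restraint."""
    if not 0 <= protocol.target_ion < system.n_mobile:
        raise IndexError(f"target ion {protocol.target_ion} out of range")
    _check_timestep(system, dt, friction, extra_k=protocol.k_pull)
    i = protocol.target_ion
    z_ref = float(system.static_pos[:, 2].mean()) if system.n_static else 0.0
    c0 = float(system.mobile_pos[i, 2]) - z_ref
    times, centers, forces = [], [], []

    def bias(step: int, pos: np.ndarray) -> np.ndarray:
        c = z_ref + c0 + protocol.rate * (step * dt)
        F = np.zeros_like(pos)
        F[i, 2] = -protocol.k_pull * (pos[i, 2] - c)
        return F

    # integrate manually to record the spring force at output times
    rng = np.random.default_rng(seed)
    pos = system.mobile_pos.copy()
    zeta = (system.mass_mobile * friction)[:, None]
    noise_amp = np.sqrt(2.0 * KB * T * dt / zeta)
    limit = 10.0 * max(system.box.lx, system.box.ly, system.box.lz)
    for step in range(n_steps + 1):
        c = z_ref + c0 + protocol.rate * (step * dt)
        if step % out_every == 0:
            times.append(step * dt)
            centers.append(c)
            forces.append(protocol.k_pull * (pos[i, 2] - c))
        if step == n_steps:
            break
        F = system.forces(pos) + bias(step, pos)
        pos = pos + F / zeta * dt + noise_amp * rng.standard_normal(pos.shape)
        if not np.all(np.isfinite(pos)) or np.any(np.abs(pos) > limit):
            raise RuntimeError(f"pull simulation diverged at step {step}")
        pos[:, 2] = _reflect_z(pos[:, 2], system.box.lz)
        pos = system.box.wrap(pos)
    return PullRecord(np.array(times), np.array(centers), np.array(forces),
                      ion_id=i, protocol=protocol)


# ---------------------------------------------------------------------------
# umbrella sampling


@dataclass
class UmbrellaWindow:
    """Samples of the z reaction coordinate under a harmonic bias."""

    center: float
    k_umb: float
    samples: np.ndarray
    T: float = 300.0

    def __post_init__(self) -> None:
        if self.k_umb <= 0:
            raise ValueError("k_umb must be > 0")
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.samples.size < 1:
            raise ValueError(f"umbrella window at {self.center} has no samples")


def run_umbrella_windows(
    system: System,
    centers,
    k_umb: float = 5000.0,
    n_steps: int = 5000,
    dt: float = 0.002,
    T: float = 300.0,
    friction: float = 1.0,
    seed: int = 0,
    out_every: int = 10,
    burn_in: float = 0.2,
    target_ion: int = 0,
    overlap_warn: float = 0.01,
) -> list[UmbrellaWindow]:
    """One biased Brownian run per center; samples recorded after burn-in.

    ``burn_in`` is the discarded fraction of each run. Adjacent windows whose
    sample histograms overlap by less than ``overlap_warn`` (fractional
    overlap of min/max ranges) trigger a warning — WHAM needs overlap.
    """
    centers = np.asarray(centers, dtype=float)
    if centers.size and np.any(np.diff(centers) <= 0):
        raise ValueError("umbrella centers must be strictly increasing")
    if n_steps * (1.0 - burn_in) < out_every:
        raise ValueError("no samples would remain after burn-in")
    _check_timestep(system, dt, friction, extra_k=k_umb)
    z_ref = float(system.static_pos[:, 2].mean()) if system.n_static else 0.0
    windows: list[UmbrellaWindow] = []
    i = target_ion
    burn_steps = int(burn_in * n_steps)
    for wi, c in enumerate(centers):
        rng = np.random.default_rng(np.random.SeedSequence([seed, wi]))
        pos = system.mobile_pos.copy()
        pos[i, 2] = np.clip(z_ref + c, 1e-3, system.box.lz - 1e-3)
        zeta = (system.mass_mobile * friction)[:, None]
        noise_amp = np.sqrt(2.0 * KB * T * dt / zeta)
        samples = []
        for step in range(1, n_steps + 1):
            F = system.forces(pos)
            F[i, 2] += -k_umb * (pos[i, 2] - z_ref - c)
            pos = pos + F / zeta * dt + noise_amp * rng.standard_normal(pos.shape)
            pos[:, 2] = _reflect_z(pos[:, 2], system.box.lz)
            pos = system.box.wrap(pos)
            if step > burn_steps and step % out_every == 0:
                samples.append(pos[i, 2] - z_ref)
        windows.append(UmbrellaWindow(center=float(c), k_umb=k_umb,
                                      samples=np.array(samples), T=T))
    for a, b in zip(windows, windows[1:]):
        lo = max(a.samples.min(), b.samples.min())
        hi = min(a.samples.max(), b.samples.max())
        span = max(np.ptp(a.samples), np.ptp(b.samples), 1e-12)
        if (hi - lo) / span < overlap_warn:
            log.warning("umbrella windows at %.3f and %.3f nm barely overlap",
                        a.center, b.center)
    return windows
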