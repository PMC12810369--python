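"""Nonbonded force-field parameters for alkaline-earth and monovalent ions.

The interaction model is the standard 12-6 Lennard-Jones plus Coulomb
potential,

    U(r) = eps_ij [ (Rmin_ij / r)^12 - 2 (Rmin_ij / r)^6 ]
           + k_C * f * Q_i * Q_j / r,

with ``eps_ij`` the LJ well depth (kJ/mol), ``Rmin_ij`` the separation at the
LJ minimum (nm), ``Q`` point charges in elementary-charge units, ``k_C`` the
Coulomb constant in MD units and ``f`` an optional electronic continuum
correction (ECC) factor that scales charges by 1/sqrt(eps_el) to account for
electronic polarization of the solvent in a mean-field way.

Three named parameter sets for Mg2+/Ca2+/Sr2+/Ba2+ (plus CHARMM monovalent
Na+/Cl-) ship as YAML tables under ``data/forcefields``; user tables in the
same schema load through :func:`load_forcefield`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import yaml

from .constants import K_COULOMB

__all__ = [
    "IonParams",
    "ForceFieldSet",
    "PairInteraction",
    "make_pair_params",
    "pair_energy",
    "pair_force",
    "apply_ecc",
    "ecc_factor_from_dielectric",
    "load_forcefield",
    "save_forcefield",
    "builtin_forcefield",
    "BUILTIN_FORCEFIELDS",
]

BUILTIN_FORCEFIELDS = ("li_tip3p", "mamatkulov", "mendes")

SIXTH_ROOT_OF_TWO = 2.0 ** (1.0 / 6.0)


@dataclass(frozen=True)
class IonParams:
    """Single-species nonbonded parameters.

    Parameters
    ----------
    species : str
        Label such as ``"Mg2+"`` or ``"Cl-"``.
    Q : float
        Point charge in elementary-charge units.
    epsilon : float
        LJ well depth, kJ/mol (>= 0).
    rmin_half : float
        Half the LJ minimum distance R_min/2, nm (> 0).
    """

    species: str
    Q: float
    epsilon: float
    rmin_half: float

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError(f"{self.species}: epsilon must be >= 0")
        if self.rmin_half <= 0:
            raise ValueError(f"{self.species}: rmin_half must be > 0")
        if abs(self.Q) > 2:
            raise ValueError(f"{self.species}: |Q| > 2 e not supported")

    @property
    def sigma(self) -> float:
        """LJ sigma in nm: R_min / 2^(1/6)."""
        return 2.0 * self.rmin_half / SIXTH_ROOT_OF_TWO


@dataclass
class ForceFieldSet:
    """Named collection of :class:`IonParams` with optional ECC scaling.

    ``ecc_factor`` is the charge-scaling factor f = 1/sqrt(eps_el); f = 1
    means no scaling. ``combining_rule`` records the mixing convention
    (only Lorentz-Berthelot is implemented: arithmetic R_min, geometric
    epsilon, the CHARMM convention).
    """

    name: str
    params: dict[str, IonParams]
    water_model_tag: str = ""
    ecc_factor: float = 1.0
    combining_rule: str = "lorentz-berthelot"
    provenance_notes: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.ecc_factor <= 1:
            raise ValueError("ecc_factor must lie in (0, 1]")

    def __getitem__(self, species: str) -> IonParams:
        try:
            return self.params[species]
        except KeyError:
            raise KeyError(
                f"species {species!r} not in force field {self.name!r}; "
                f"available: {sorted(self.params)}"
            ) from None

    def __contains__(self, species: str) -> bool:
        return species in self.params

    def with_ecc(self, f: float = 0.80) -> "ForceFieldSet":
        """Return a copy with ECC charge scaling factor ``f`` recorded."""
        if not 0 < f <= 1:
            raise ValueError("ECC factor must lie in (0, 1]")
        return replace(self, ecc_factor=f)

    def pair(self, species_a: str, species_b: str) -> "PairInteraction":
        """Combined pair parameters for two species, ECC factor applied."""
        return make_pair_params(self[species_a], self[species_b], self.ecc_factor)


@dataclass(frozen=True)
class PairInteraction:
    """Combined pair parameters ready for energy/force evaluation."""

    eps_ij: float
    rmin_ij: float
    qq_scaled: float  # f * Q_i * Q_j in e^2
    coulomb_constant: float = K_COULOMB

    def __post_init__(self) -> None:
        if self.eps_ij < 0:
            raise ValueError("eps_ij must be >= 0")
        if self.rmin_ij <= 0:
            raise ValueError("rmin_ij must be > 0")


def make_pair_params(a: IonParams, b: IonParams, f: float = 1.0,
                     coulomb_constant: float = K_COULOMB) -> PairInteraction:
    """Lorentz-Berthelot combination of two species' parameters.

    eps_ij = sqrt(eps_a eps_b); Rmin_ij = (Rmin_a + Rmin_b)/2;
    qq_scaled = f * Q_a * Q_b. The ECC factor applies once to the charge
    *product* (equivalently f' = sqrt(f) per charge); pass f = f_charge**2
    if both charges were pre-scaled individually.
    """
    rmin_ij = a.rmin_half + b.rmin_half
    if rmin_ij <= 0:
        raise ValueError("combined rmin must be positive")
    return PairInteraction(
        eps_ij=math.sqrt(a.epsilon * b.epsilon),
        rmin_ij=rmin_ij,
        qq_scaled=f * a.Q * b.Q,
        coulomb_constant=coulomb_constant,
    )


def pair_energy(r, p: PairInteraction):
    """12-6 LJ + Coulomb energy at separation ``r`` (nm), kJ/mol.

    Accepts scalar or ndarray ``r``; all entries must be > 0.
    """
    import numpy as np

    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr <= 0):
        raise ValueError("pair separation must be > 0")
    x6 = (p.rmin_ij / r_arr) ** 6
    u = p.eps_ij * (x6 * x6 - 2.0 * x6) + p.coulomb_constant * p.qq_scaled / r_arr
    return u if u.ndim else float(u)


def pair_force(r, p: PairInteraction):
    """Radial force -dU/dr at ``r`` (nm), kJ mol^-1 nm^-1; positive = repulsive."""
    import numpy as np

    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr <= 0):
        raise ValueError("pair separation must be > 0")
    x6 = (p.rmin_ij / r_arr) ** 6
    # dU/dr = eps*(-12 x^12 + 12 x^6)/r - kC qq / r^2 ; force = -dU/dr
    f = 12.0 * p.eps_ij * (x6 * x6 - x6) / r_arr \
        + p.coulomb_constant * p.qq_scaled / r_arr**2
    return f if f.ndim else float(f)


def apply_ecc(Q: float, f: float) -> float:
    """Scale a point charge by the ECC factor f = 1/sqrt(eps_el)."""
    if not 0 < f <= 1:
        raise ValueError("ECC factor must lie in (0, 1]")
    return f * Q


def ecc_factor_from_dielectric(eps_el: float) -> float:
    """ECC factor from the electronic dielectric constant: f = 1/sqrt(eps_el)."""
    if eps_el < 1:
        raise ValueError("electronic dielectric constant must be >= 1")
    return 1.0 / math.sqrt(eps_el)


# ---------------------------------------------------------------------------
# serialization


def _set_to_dict(ff: ForceFieldSet) -> dict:
    return {
        "name": ff.name,
        "water_model_tag": ff.water_model_tag,
        "ecc_factor": ff.ecc_factor,
        "combining_rule": ff.combining_rule,
        "provenance_notes": ff.provenance_notes,
        "params": [
            {
                "species": p.species,
                "Q": p.Q,
                "epsilon_kJmol": p.epsilon,
                "rmin_half_nm": p.rmin_half,
            }
            for p in ff.params.values()
        ],
    }


def save_forcefield(ff: ForceFieldSet, path) -> None:
    """Write a force-field set as a YAML table."""
    Path(path).write_text(yaml.safe_dump(_set_to_dict(ff), sort_keys=False))


def _set_from_dict(d: dict) -> ForceFieldSet:
    params = {
        row["species"]: IonParams(
            species=row["species"],
            Q=float(row["Q"]),
            epsilon=float(row["epsilon_kJmol"]),
            rmin_half=float(row["rmin_half_nm"]),
        )
        for row in d["params"]
    }
    return ForceFieldSet(
        name=d["name"],
        params=params,
        water_model_tag=d.get("water_model_tag", ""),
        ecc_factor=float(d.get("ecc_factor", 1.0)),
        combining_rule=d.get("combining_rule", "lorentz-berthelot"),
        provenance_notes=d.get("provenance_notes", ""),
    )


def load_forcefield(path) -> ForceFieldSet:
    """Load a YAML force-field table written by :func:`save_forcefield`."""
    return _set_from_dict(yaml.safe_load(Path(path).read_text()))


def builtin_forcefield(name: str, ecc: bool = False, ecc_f: float = 0.80) -> ForceFieldSet:
    """Load one of the shipped parameter sets by name.

    Parameters
    ----------
    name : {"li_tip3p", "mamatkulov", "mendes"}
    ecc : bool
        Apply ECC charge scaling with factor ``ecc_f`` (default 0.80).
    """
    if name not in BUILTIN_FORCEFIELDS:
        raise KeyError(f"unknown force field {name!r}; choose from {BUILTIN_FORCEFIELDS}")
    ref = resources.files("ionlayer.data.forcefields").joinpath(f"{name}.yaml")
    ff = _set_from_dict(yaml.safe_load(ref.read_text()))
    return ff.with_ecc(ecc_f) if ecc else ff
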