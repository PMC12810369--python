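"""Idealized deprotonated-MUA monolayer geometry.

Thiol self-assembled monolayers on Au(111) adopt the (sqrt3 x sqrt3)R30
triangular adsorption lattice; an nx x ny array of sulfur sites carries one
deprotonated 11-mercaptoundecanoic-acid (MUA) ligand each. Only the
carboxylate headgroup (one C, two O) is represented geometrically — the alkyl
chain is not simulated — so each ligand contributes a rigid COO- unit placed
at a configurable height above its lattice site.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "LatticeSpec",
    "Headgroup",
    "build_lattice",
    "build_headgroups",
    "DEFAULT_SPACING_NM",
    "DEFAULT_OO_DISTANCE_NM",
    "default_scenario",
]

#: sqrt(3) x the Au(111) lattice constant — the standard thiol-lattice spacing.
DEFAULT_SPACING_NM = 0.497

#: Intramolecular carboxylate O-O distance (2.2 A).
DEFAULT_OO_DISTANCE_NM = 0.22


@dataclass(frozen=True)
class LatticeSpec:
    """Triangular-lattice dimensions: ``nx`` columns x ``ny`` rows."""

    nx: int
    ny: int
    spacing: float = DEFAULT_SPACING_NM
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1:
            raise ValueError("lattice dimensions must be >= 1")
        if self.spacing <= 0:
            raise ValueError("lattice spacing must be > 0")

    @property
    def n_sites(self) -> int:
        return self.nx * self.ny


@dataclass
class Headgroup:
    """Rigid carboxylate headgroup: C plus two O, net charge -1 e."""

    ligand_id: int
    c_pos: np.ndarray
    o1_pos: np.ndarray
    o2_pos: np.ndarray
    charge_assignment: dict[str, float] = field(
        default_factory=lambda: {"C": 0.0, "O1": -0.5, "O2": -0.5}
    )

    @property
    def oo_distance(self) -> float:
        return float(np.linalg.norm(self.o1_pos - self.o2_pos))

    @property
    def total_charge(self) -> float:
        return sum(self.charge_assignment.values())


def build_lattice(spec: LatticeSpec) -> np.ndarray:
    """Sulfur-site xy positions on a triangular lattice, row-major order.

    Rows are offset by half a spacing and separated by spacing*sqrt(3)/2, so
    every interior site has six nearest neighbours at exactly ``spec.spacing``.

    Returns an (nx*ny, 2) array in nm.
    """
    a = spec.spacing
    row_height = a * math.sqrt(3.0) / 2.0
    ox, oy = spec.origin
    sites = np.empty((spec.n_sites, 2))
    k = 0
    for j in range(spec.ny):
        x_off = (j % 2) * a / 2.0
        for i in range(spec.nx):
            sites[k, 0] = ox + i * a + x_off
            sites[k, 1] = oy + j * row_height
            k += 1
    return sites


def build_headgroups(
    lattice: np.ndarray,
    height: float = 0.0,
    oo_distance: float = DEFAULT_OO_DISTANCE_NM,
    seed: int | None = 0,
    charge_assignment: dict[str, float] | None = None,
) -> list[Headgroup]:
    """Place one rigid carboxylate headgroup above each lattice site.

    The carbon sits at (x, y, height); the two oxygens are symmetric about the
    carbon, separated by ``oo_distance`` along a random in-plane azimuth drawn
    from ``seed`` (same seed -> identical geometry).
    """
    if oo_distance <= 0:
        raise ValueError("oo_distance must be > 0")
    rng = np.random.default_rng(seed)
    charges = charge_assignment or {"C": 0.0, "O1": -0.5, "O2": -0.5}
    half = oo_distance / 2.0
    groups: list[Headgroup] = []
    for lid, (x, y) in enumerate(np.asarray(lattice, dtype=float)):
        phi = rng.uniform(0.0, 2.0 * math.pi)
        d = np.array([math.cos(phi) * half, math.sin(phi) * half, 0.0])
        c = np.array([x, y, height])
        groups.append(
            Headgroup(
                ligand_id=lid,
                c_pos=c,
                o1_pos=c + d,
                o2_pos=c - d,
                charge_assignment=dict(charges),
            )
        )
    return groups


def default_scenario() -> dict:
    """Default ion composition mirroring the reference monolayer system.

    154 ligands (14 x 11), 100 divalent cations, 54 Na+, 100 Cl- in a
    6.06 x 5.20 x 7.00 nm box footprint.
    """
    return {
        "lattice": {"nx": 14, "ny": 11, "spacing": DEFAULT_SPACING_NM},
        "box": {"lx": 6.06, "ly": 5.20, "lz": 7.00},
        "ions": {"divalent": 100, "Na+": 54, "Cl-": 100},
        "divalent_species": "Ca2+",
        "temperature_K": 300.0,
    }


def save_scenario(scenario: dict, path) -> None:
    from pathlib import Path

    Path(path).write_text(yaml.safe_dump(scenario, sort_keys=False))


def load_scenario(path) -> dict:
    from pathlib import Path

    return yaml.safe_load(Path(path).read_text())
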