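"""Trajectory and simulation-box containers shared across the package."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SimBox", "Trajectory"]


@dataclass(frozen=True)
class SimBox:
    """Periodic slab box: x and y periodic, z bounded by walls at 0 and lz."""

    lx: float
    ly: float
    lz: float
    periodic: tuple[bool, bool, bool] = (True, True, False)

    def __post_init__(self) -> None:
        if min(self.lx, self.ly, self.lz) <= 0:
            raise ValueError("box lengths must be > 0")

    @property
    def lengths(self) -> np.ndarray:
        return np.array([self.lx, self.ly, self.lz])

    @property
    def volume(self) -> float:
        return self.lx * self.ly * self.lz

    def minimum_image(self, dr: np.ndarray) -> np.ndarray:
        """Apply the minimum-image convention along the periodic axes.

        ``dr`` is an (..., 3) displacement array; returns a new array.
        """
        dr = np.array(dr, dtype=float, copy=True)
        for ax, (per, L) in enumerate(zip(self.periodic, self.lengths)):
            if per:
                dr[..., ax] -= L * np.round(dr[..., ax] / L)
        return dr

    def wrap(self, pos: np.ndarray) -> np.ndarray:
        """Wrap positions into the box along periodic axes only."""
        pos = np.array(pos, dtype=float, copy=True)
        for ax, (per, L) in enumerate(zip(self.periodic, self.lengths)):
            if per:
                pos[..., ax] %= L
        return pos


@dataclass
class Trajectory:
    """Time-ordered coordinate frames for a fixed set of labeled particles.

    ``frames`` has shape (n_frames, n_atoms, 3) in nm; ``labels`` gives one
    species string per atom; ``dt_out`` is the output interval in ps.
    """

    frames: np.ndarray
    labels: list[str]
    box: SimBox
    dt_out: float = 1.0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame")
        if len(self.labels) != self.frames.shape[1]:
            raise ValueError("one species label per atom required")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt_out

    def atom_indices(self, species) -> np.ndarray:
        """Indices of atoms whose label is ``species`` (str or collection)."""
        wanted = {species} if isinstance(species, str) else set(species)
        return np.array([i for i, s in enumerate(self.labels) if s in wanted], dtype=int)
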