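"""Readers and writers for GRO / XYZ coordinates and XVG-dialect series.

Internal units are nm and ps everywhere. XYZ files are assumed to be in
Angstrom on input (the common convention) and converted; pass
``xyz_in_angstrom=False`` to override. GRO velocities are ignored on read and
omitted on write.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .trajectory import SimBox, Trajectory

__all__ = [
    "SeriesRecord",
    "read_coordinates",
    "write_coordinates",
    "read_series",
    "write_series",
]

log = logging.getLogger(__name__)

# species label <-> GRO residue/atom naming
_SPECIES_TO_NAME = {
    "Mg2+": "MG", "Ca2+": "CA", "Sr2+": "SR", "Ba2+": "BA",
    "Na+": "NA", "Cl-": "CL", "C": "C", "O1": "O1", "O2": "O2",
}
_NAME_TO_SPECIES = {v: k for k, v in _SPECIES_TO_NAME.items()}
_HEADGROUP_ATOMS = {"C", "O1", "O2"}


class TrajectoryParseError(ValueError):
    """Raised when a coordinate or series file cannot be parsed."""


def _label_to_names(label: str) -> tuple[str, str]:
    """Map a species label to (resname, atomname) for GRO output."""
    if label in _HEADGROUP_ATOMS:
        return "MUA", label
    name = _SPECIES_TO_NAME.get(label)
    if name is None:
        raise TrajectoryParseError(f"unknown species label {label!r}")
    return name, name


def _name_to_label(resname: str, atomname: str) -> str:
    if resname == "MUA":
        if atomname not in _HEADGROUP_ATOMS:
            raise TrajectoryParseError(f"unknown MUA atom name {atomname!r}")
        return atomname
    label = _NAME_TO_SPECIES.get(atomname.upper())
    if label is None:
        raise TrajectoryParseError(f"unknown atom label {atomname!r}")
    return label


# ---------------------------------------------------------------------------
# GRO


def _write_gro(traj: Trajectory, path: Path) -> None:
    lines: list[str] = []
    for fi in range(traj.n_frames):
        t = fi * traj.dt_out
        lines.append(f"ionlayer trajectory, t= {t:.3f} ps (frame {fi}, times in ps)")
        lines.append(f"{traj.n_atoms:5d}")
        for ai, label in enumerate(traj.labels):
            resname, atomname = _label_to_names(label)
            x, y, z = traj.frames[fi, ai]
            resid = (ai % 99999) + 1
            atomid = (ai % 99999) + 1
            lines.append(
                f"{resid:5d}{resname:<5s}{atomname:>5s}{atomid:5d}"
                f"{x:8.3f}{y:8.3f}{z:8.3f}"
            )
        lines.append(f"{traj.box.lx:10.5f}{traj.box.ly:10.5f}{traj.box.lz:10.5f}")
    path.write_text("\n".join(lines) + "\n")


def _read_gro(path: Path) -> Trajectory:
    raw = path.read_text().splitlines()
    frames: list[np.ndarray] = []
    labels: list[str] = []
    box: SimBox | None = None
    i = 0
    frame_idx = 0
    while i < len(raw):
        if not raw[i].strip():
            i += 1
            continue
        if i + 1 >= len(raw):
            raise TrajectoryParseError(f"truncated frame {frame_idx} in {path}")
        try:
            n_atoms = int(raw[i + 1].strip())
        except ValueError as exc:
            raise TrajectoryParseError(
                f"bad atom count in frame {frame_idx} of {path}: {raw[i+1]!r}"
            ) from exc
        if i + 2 + n_atoms >= len(raw):
            raise TrajectoryParseError(f"truncated frame {frame_idx} in {path}")
        coords = np.empty((n_atoms, 3))
        frame_labels: list[str] = []
        for k in range(n_atoms):
            line = raw[i + 2 + k]
            try:
                resname = line[5:10].strip()
                atomname = line[10:15].strip()
                coords[k] = [float(line[20:28]), float(line[28:36]), float(line[36:44])]
            except (ValueError, IndexError) as exc:
                raise TrajectoryParseError(
                    f"unparseable atom line {k} in frame {frame_idx} of {path}"
                ) from exc
            frame_labels.append(_name_to_label(resname, atomname))
        box_fields = raw[i + 2 + n_atoms].split()
        box = SimBox(float(box_fields[0]), float(box_fields[1]), float(box_fields[2]))
        if frame_idx == 0:
            labels = frame_labels
        elif frame_labels != labels:
            raise TrajectoryParseError(f"atom labels change at frame {frame_idx}")
        frames.append(coords)
        i += 3 + n_atoms
        frame_idx += 1
    if not frames:
        raise TrajectoryParseError(f"no frames found in {path}")
    log.info("read %d frames x %d atoms from %s", len(frames), len(labels), path)
    return Trajectory(np.stack(frames), labels, box)


# ---------------------------------------------------------------------------
# XYZ


def _write_xyz(traj: Trajectory, path: Path) -> None:
    lines: list[str] = []
    for fi in range(traj.n_frames):
        lines.append(str(traj.n_atoms))
        lines.append(f"ionlayer frame {fi}, t= {fi * traj.dt_out:.3f} ps, coords in Angstrom")
        for ai, label in enumerate(traj.labels):
            _, atomname = _label_to_names(label)
            x, y, z = traj.frames[fi, ai] * 10.0  # nm -> Angstrom
            lines.append(f"{atomname:<4s} {x:12.6f} {y:12.6f} {z:12.6f}")
    path.write_text("\n".join(lines) + "\n")


def _read_xyz(path: Path, box: SimBox | None, in_angstrom: bool) -> Trajectory:
    raw = path.read_text().splitlines()
    frames: list[np.ndarray] = []
    labels: list[str] = []
    i = 0
    frame_idx = 0
    scale = 0.1 if in_angstrom else 1.0
    while i < len(raw):
        if not raw[i].strip():
            i += 1
            continue
        try:
            n_atoms = int(raw[i].strip())
        except ValueError as exc:
            raise TrajectoryParseError(
                f"bad atom count at line {i + 1} of {path}"
            ) from exc
        if i + 2 + n_atoms > len(raw):
            raise TrajectoryParseError(f"truncated frame {frame_idx} in {path}")
        coords = np.empty((n_atoms, 3))
        frame_labels = []
        for k in range(n_atoms):
            parts = raw[i + 2 + k].split()
            if len(parts) < 4:
                raise TrajectoryParseError(
                    f"unparseable atom line {k} in frame {frame_idx} of {path}"
                )
            name = parts[0]
            frame_labels.append(
                name if name in _HEADGROUP_ATOMS else _name_to_label("", name)
            )
            coords[k] = [float(v) * scale for v in parts[1:4]]
        if frame_idx == 0:
            labels = frame_labels
        elif frame_labels != labels:
            raise TrajectoryParseError(f"atom labels change at frame {frame_idx}")
        frames.append(coords)
        i += 2 + n_atoms
        frame_idx += 1
    if not frames:
        raise TrajectoryParseError(f"no frames found in {path}")
    if in_angstrom:
        log.info("XYZ input assumed Angstrom; converted to nm")
    if box is None:
        span = np.stack(frames).reshape(-1, 3).max(axis=0)
        box = SimBox(*np.maximum(span, 1e-9))
    return Trajectory(np.stack(frames), labels, box)


# ---------------------------------------------------------------------------
# public API


def read_coordinates(path, format: str | None = None, box: SimBox | None = None,
                     xyz_in_angstrom: bool = True) -> Trajectory:
    """Load a (possibly multi-frame) GRO or XYZ coordinate file.

    ``format`` defaults to the file suffix. XYZ has no box record, so an
    explicit ``box`` may be supplied (otherwise a bounding box is inferred).
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    fmt = (format or p.suffix.lstrip(".")).lower()
    if fmt == "gro":
        return _read_gro(p)
    if fmt == "xyz":
        return _read_xyz(p, box, xyz_in_angstrom)
    raise ValueError(f"unsupported coordinate format {fmt!r}")


def write_coordinates(traj: Trajectory, path, format: str | None = None) -> None:
    """Write a trajectory as multi-frame GRO or XYZ."""
    p = Path(path)
    fmt = (format or p.suffix.lstrip(".")).lower()
    if traj.n_frames < 1:
        raise ValueError("refusing to write an empty trajectory")
    if fmt == "gro":
        _write_gro(traj, p)
    elif fmt == "xyz":
        _write_xyz(traj, p)
    else:
        raise ValueError(f"unsupported coordinate format {fmt!r}")


# ---------------------------------------------------------------------------
# two-column series (XVG dialect)


@dataclass
class SeriesRecord:
    """Two-column numeric series (e.g. time vs pull force) with header comments."""

    x: np.ndarray
    y: np.ndarray
    metadata: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have equal length")
        if self.x.size and np.any(np.diff(self.x) < 0):
            raise ValueError("abscissa must be monotone non-decreasing")

    def __len__(self) -> int:
        return self.x.size


def read_series(path) -> SeriesRecord:
    """Read a two-column XVG-dialect file ('#' and '@' lines are comments)."""
    p = Path(path)
    xs, ys, meta = [], [], []
    n_comment = 0
    for lineno, line in enumerate(p.read_text().splitlines(), start=1):
        s = line.strip()
        if not s:
            continue
        if s.startswith(("#", "@")):
            meta.append(s)
            n_comment += 1
            continue
        parts = s.split()
        try:
            xs.append(float(parts[0]))
            ys.append(float(parts[1]))
        except (ValueError, IndexError) as exc:
            raise TrajectoryParseError(
                f"non-numeric data at line {lineno} of {p}: {line!r}"
            ) from exc
    if not xs:
        raise TrajectoryParseError(f"no data rows in {p} ({n_comment} comment lines)")
    log.info("read %d rows (%d comments) from %s", len(xs), n_comment, p)
    return SeriesRecord(np.array(xs), np.array(ys), meta)


def write_series(record: SeriesRecord, path, xlabel: str = "x", ylabel: str = "y") -> None:
    """Write a series in the XVG dialect (comments preserved as '#' lines)."""
    p = Path(path)
    lines = [f"# ionlayer series: {xlabel} vs {ylabel} (times in ps, frame 0 = t 0)"]
    lines += [m if m.startswith(("#", "@")) else f"# {m}" for m in record.metadata]
    lines += [f"{xv:.8g} {yv:.8g}" for xv, yv in zip(record.x, record.y)]
    p.write_text("\n".join(lines) + "\n")
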