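"""Ion-carboxylate binding analysis: RDFs, distance cutoffs, binding motifs.

Divalent cations at a carboxylate monolayer bind as contact ion pairs —
bidentate (B, both carboxylate oxygens coordinate) or monodentate (M, one
oxygen) — or as solvent-shared ion pairs (indirect, I, one intervening water
layer). All classification here is done on the carboxylate-carbon-to-ion
distance, the observable the C-ion radial distribution function resolves:
successive RDF peaks correspond to B, M and I coordination, and the minima
between them define the distance-band cutoffs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import argrelextrema

from .trajectory import SimBox, Trajectory

__all__ = [
    "RDFResult",
    "CutoffScheme",
    "MotifAssignment",
    "BindingStats",
    "compute_rdf",
    "derive_cutoffs",
    "classify_frame",
    "classify_trajectory",
    "binding_statistics",
    "bound_count_series",
]

log = logging.getLogger(__name__)

DIVALENT_SPECIES = ("Mg2+", "Ca2+", "Sr2+", "Ba2+")


# ---------------------------------------------------------------------------
# RDF


@dataclass
class RDFResult:
    """Radial distribution function g(r) and running coordination number n(r)."""

    r_centers: np.ndarray
    g: np.ndarray
    coordination: np.ndarray
    pair_spec: tuple[str, str]
    n_frames: int

    def __post_init__(self) -> None:
        if np.any(self.g < 0):
            raise ValueError("g(r) must be non-negative")
        if np.any(np.diff(self.coordination) < -1e-12):
            raise ValueError("coordination number must be non-decreasing")


def _pair_distances(pos_a: np.ndarray, pos_b: np.ndarray, box: SimBox | None,
                    exclude_pairs: set[tuple[int, int]] | None = None) -> np.ndarray:
    """All A-B distances with minimum image along periodic axes."""
    dr = pos_a[:, None, :] - pos_b[None, :, :]
    if box is not None:
        dr = box.minimum_image(dr)
    d = np.sqrt(np.einsum("ijk,ijk->ij", dr, dr))
    if exclude_pairs:
        for i, j in exclude_pairs:
            d[i, j] = np.inf
    return d


def compute_rdf(
    traj: Trajectory,
    group_a,
    group_b,
    r_max: float = 1.0,
    dr: float = 0.002,
) -> RDFResult:
    """Slab-normalized g(r) between two species groups.

    ``group_a``/``group_b`` are species labels (str or collection) or explicit
    index arrays. Distances use the minimum image along the periodic x/y axes;
    the reference density for normalization is N_B / V with V the full box
    volume, and shells are the isotropic 4*pi*r^2*dr volumes — near the z
    walls g(r) therefore dips below 1 even for an ideal gas. The running
    coordination number n(r) is the exact cumulative pair count per A particle
    (not a shell re-integration), so it matches brute-force counting.
    """
    idx_a = traj.atom_indices(group_a) if isinstance(group_a, (str, list, tuple, set)) \
        else np.asarray(group_a, dtype=int)
    idx_b = traj.atom_indices(group_b) if isinstance(group_b, (str, list, tuple, set)) \
        else np.asarray(group_b, dtype=int)
    if idx_a.size == 0 or idx_b.size == 0:
        raise ValueError("RDF groups must be non-empty")
    if r_max > min(traj.box.lx, traj.box.ly) / 2:
        raise ValueError("r_max must not exceed half the smallest periodic box length")
    edges = np.arange(0.0, r_max + dr, dr)
    counts = np.zeros(edges.size - 1)
    shared = set(idx_a) & set(idx_b)
    for fi in range(traj.n_frames):
        d = _pair_distances(traj.frames[fi, idx_a], traj.frames[fi, idx_b], traj.box)
        if shared:
            for ia, a in enumerate(idx_a):
                jb = np.where(idx_b == a)[0]
                if jb.size:
                    d[ia, jb[0]] = np.inf
        counts += np.histogram(d[d < r_max], bins=edges)[0]
    r_centers = 0.5 * (edges[:-1] + edges[1:])
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    n_b_eff = idx_b.size - (1 if shared else 0)
    rho_b = n_b_eff / traj.box.volume
    norm = traj.n_frames * idx_a.size * rho_b * shell_vol
    g = counts / norm
    coordination = np.cumsum(counts) / (traj.n_frames * idx_a.size)
    spec_a = group_a if isinstance(group_a, str) else "groupA"
    spec_b = group_b if isinstance(group_b, str) else "groupB"
    return RDFResult(r_centers, g, coordination, (spec_a, spec_b), traj.n_frames)


# ---------------------------------------------------------------------------
# cutoffs


@dataclass(frozen=True)
class CutoffScheme:
    """Distance bands on the carboxylate-C-to-ion separation (nm).

    (0, bidentate_max]      -> bidentate direct contact (B)
    (bidentate_max, direct_max] -> monodentate direct contact (M)
    (direct_max, total_max] -> indirect / solvent-shared contact (I)
    ``indirect_split`` (optional) marks an internal dip splitting the indirect
    band into doubly vs singly hydrogen-bonded subtypes (seen for Mg2+).
    """

    bidentate_max: float
    direct_max: float
    total_max: float
    indirect_split: float | None = None
    source: str = "manual"

    def __post_init__(self) -> None:
        if not 0 < self.bidentate_max < self.direct_max < self.total_max:
            raise ValueError(
                "cutoffs must satisfy 0 < bidentate_max < direct_max < total_max"
            )
        if self.indirect_split is not None and not (
            self.direct_max < self.indirect_split < self.total_max
        ):
            raise ValueError("indirect_split must lie inside (direct_max, total_max)")


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y.astype(float)
    if window % 2 == 0:
        window += 1
    pad = window // 2
    ypad = np.pad(y.astype(float), pad, mode="edge")
    kernel = np.ones(window) / window
    return np.convolve(ypad, kernel, mode="valid")


def derive_cutoffs(rdf: RDFResult, smoothing: int = 5) -> CutoffScheme:
    """Locate band cutoffs at the local minima between successive RDF peaks.

    The first and second peaks define the bidentate and monodentate direct
    bands; any further peaks form the indirect region, whose terminating
    minimum sets ``total_max``. Two indirect peaks (an internal dip) yield
    ``indirect_split``. Ties break to the first qualifying extremum.

    Raises ValueError when fewer than two peaks are resolvable (supply manual
    cutoffs in that case).
    """
    g = _smooth(rdf.g, smoothing)
    r = rdf.r_centers
    maxima = argrelextrema(g, np.greater_equal, order=2)[0]
    # deduplicate plateaus and discard zero-height artifacts
    peaks = []
    for m in maxima:
        if g[m] <= 1e-12:
            continue
        if peaks and m - peaks[-1] <= 2 and abs(g[m] - g[peaks[-1]]) < 1e-12:
            continue
        peaks.append(int(m))
    if len(peaks) < 2:
        raise ValueError(
            "fewer than two resolvable RDF peaks; supply a manual CutoffScheme"
        )
    minima = [int(m) for m in argrelextrema(g, np.less_equal, order=2)[0]]

    def first_min_after(peak_idx: int, before: int | None = None) -> int | None:
        for m in minima:
            if m > peak_idx and (before is None or m < before):
                return m
        return None

    p1, p2 = peaks[0], peaks[1]
    m1 = first_min_after(p1, before=p2)
    if m1 is None:
        raise ValueError("no minimum between the first two RDF peaks")
    p3 = peaks[2] if len(peaks) > 2 else None
    m2 = first_min_after(p2, before=p3)
    if m2 is None:
        raise ValueError("no minimum terminating the second RDF peak")
    indirect_split = None
    if p3 is not None:
        p4 = peaks[3] if len(peaks) > 3 else None
        if p4 is not None:
            ms = first_min_after(p3, before=p4)
            m3 = first_min_after(p4)
            indirect_split = float(r[ms]) if ms is not None else None
        else:
            m3 = first_min_after(p3)
        total_idx = m3 if m3 is not None else g.size - 1
    else:
        # no resolvable indirect peak: close the total band where g decays
        tail = np.where(g[m2:] <= 0.05 * g[p2])[0]
        total_idx = m2 + int(tail[0]) if tail.size else g.size - 1
    return CutoffScheme(
        bidentate_max=float(r[m1]),
        direct_max=float(r[m2]),
        total_max=float(r[total_idx]),
        indirect_split=indirect_split,
        source="derived",
    )


# ---------------------------------------------------------------------------
# motif classification

_CATEGORY_ORDER = {"B": 0, "M": 1, "I": 2}


def _category(types: set[str]) -> str:
    if not types:
        return "unbound"
    return "+".join(sorted(types, key=_CATEGORY_ORDER.__getitem__))


@dataclass
class MotifAssignment:
    """Per-ion contact map for one frame.

    ``contacts[i]`` maps ligand index -> contact type ('B', 'M' or 'I') for
    ion i; ``categories[i]`` is the sorted union such as 'B+M+I' or
    'unbound'; ``counts[i]`` holds the ligand tallies with bidentate <=
    direct <= total guaranteed.
    """

    contacts: list[dict[int, str]]
    categories: list[str]
    counts: list[dict[str, int]]
    cutoffs: CutoffScheme

    @property
    def n_ions(self) -> int:
        return len(self.contacts)

    @property
    def n_bound(self) -> int:
        return sum(c != "unbound" for c in self.categories)


def classify_frame(
    ion_pos: np.ndarray,
    headgroup_pos: np.ndarray,
    cutoffs: CutoffScheme,
    box: SimBox | None = None,
) -> MotifAssignment:
    """Assign a binding motif to every ion from its C-ion distances.

    ``headgroup_pos`` holds the carboxylate carbon position of each ligand.
    Per ligand-ion pair the distance maps to B, M or I by the cutoff bands;
    the per-ion category is the sorted union over its contacted ligands.
    """
    ion_pos = np.asarray(ion_pos, dtype=float).reshape(-1, 3)
    headgroup_pos = np.asarray(headgroup_pos, dtype=float).reshape(-1, 3)
    d = _pair_distances(ion_pos, headgroup_pos, box)
    contacts: list[dict[int, str]] = []
    categories: list[str] = []
    counts: list[dict[str, int]] = []
    for i in range(ion_pos.shape[0]):
        cmap: dict[int, str] = {}
        di = d[i]
        for lig in np.where(di <= cutoffs.total_max)[0]:
            dist = di[lig]
            if dist <= cutoffs.bidentate_max:
                cmap[int(lig)] = "B"
            elif dist <= cutoffs.direct_max:
                cmap[int(lig)] = "M"
            else:
                cmap[int(lig)] = "I"
        types = set(cmap.values())
        n_b = sum(1 for t in cmap.values() if t == "B")
        n_direct = sum(1 for t in cmap.values() if t in ("B", "M"))
        contacts.append(cmap)
        categories.append(_category(types))
        counts.append({"bidentate": n_b, "direct": n_direct, "total": len(cmap)})
    return MotifAssignment(contacts, categories, counts, cutoffs)


def classify_trajectory(
    traj: Trajectory,
    cutoffs: CutoffScheme,
    ion_species=DIVALENT_SPECIES,
    headgroup_label: str = "C",
) -> list[MotifAssignment]:
    """Classify every frame of a trajectory (divalent ions vs carboxylate C)."""
    idx_ion = traj.atom_indices(ion_species)
    idx_hg = traj.atom_indices(headgroup_label)
    if idx_ion.size == 0 or idx_hg.size == 0:
        raise ValueError("trajectory lacks ions or headgroup carbons")
    return [
        classify_frame(traj.frames[fi, idx_ion], traj.frames[fi, idx_hg],
                       cutoffs, traj.box)
        for fi in range(traj.n_frames)
    ]


# ---------------------------------------------------------------------------
# statistics


@dataclass
class BindingStats:
    """Time-averaged binding statistics in the ligands-per-ion convention.

    ``ligands_per_ion['bidentate']`` averages the number of bidentate-bound
    ligands over (frame, ion) pairs with at least one bidentate contact;
    'direct' and 'total' condition analogously on >=1 direct (B or M) and
    >=1 contact of any type.
    """

    mean_bound: float
    std_bound: float
    ligands_per_ion: dict[str, float]
    motif_histogram: dict[str, float]
    n_frames: int
    n_ions: int


def binding_statistics(assignments: list[MotifAssignment]) -> BindingStats:
    """Aggregate per-frame motif assignments into mean binding statistics."""
    if not assignments:
        raise ValueError("need at least one classified frame")
    n_ions = assignments[0].n_ions
    bound_counts = np.array([a.n_bound for a in assignments], dtype=float)
    sums = {"bidentate": 0.0, "direct": 0.0, "total": 0.0}
    nobs = {"bidentate": 0, "direct": 0, "total": 0}
    hist: dict[str, float] = {}
    for a in assignments:
        frame_hist: dict[str, int] = {}
        for cat, cnt in zip(a.categories, a.counts):
            frame_hist[cat] = frame_hist.get(cat, 0) + 1
            if cnt["bidentate"] >= 1:
                sums["bidentate"] += cnt["bidentate"]
                nobs["bidentate"] += 1
            if cnt["direct"] >= 1:
                sums["direct"] += cnt["direct"]
                nobs["direct"] += 1
            if cnt["total"] >= 1:
                sums["total"] += cnt["total"]
                nobs["total"] += 1
        for cat, n in frame_hist.items():
            hist[cat] = hist.get(cat, 0.0) + n
    hist = {cat: n / len(assignments) for cat, n in hist.items()}
    ligands = {
        key: (sums[key] / nobs[key]) if nobs[key] else 0.0 for key in sums
    }
    return BindingStats(
        mean_bound=float(bound_counts.mean()),
        std_bound=float(bound_counts.std(ddof=0)),
        ligands_per_ion=ligands,
        motif_histogram=hist,
        n_frames=len(assignments),
        n_ions=n_ions,
    )


def bound_count_series(
    traj_or_assignments,
    cutoffs: CutoffScheme | None = None,
    window: int = 100,
    threshold: float = 1.0,
    ion_species=DIVALENT_SPECIES,
) -> tuple[np.ndarray, bool, dict]:
    """Per-frame bound-ion count and a convergence verdict.

    The series is converged when the means of the two halves of the final
    ``window`` frames differ by less than ``threshold`` ions (default one
    ion, the typical equilibrium standard deviation of the bound count).
    Returns (counts, converged, details).
    """
    if isinstance(traj_or_assignments, Trajectory):
        if cutoffs is None:
            raise ValueError("cutoffs required when passing a trajectory")
        assignments = classify_trajectory(traj_or_assignments, cutoffs,
                                          ion_species=ion_species)
        counts = np.array([a.n_bound for a in assignments], dtype=float)
    else:
        counts = np.asarray(traj_or_assignments, dtype=float)
    if window >= counts.size:
        raise ValueError("window must be shorter than the series")
    tail = counts[-window:]
    half = window // 2
    delta = abs(tail[:half].mean() - tail[half:].mean())
    converged = bool(delta < threshold)
    details = {
        "halves_delta": float(delta),
        "threshold": threshold,
        "tail_mean": float(tail.mean()),
        "tail_std": float(tail.std(ddof=0)),
    }
    return counts, converged, details
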