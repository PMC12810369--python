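"""Binding-strength estimators: adhesion forces, WHAM PMFs, Langmuir isotherm.

Three complementary routes to the strength of divalent-ion binding at a
carboxylate monolayer:

* **Adhesion force curves** (site-specific): a bound ion is pulled off the
  surface at constant rate; the adhesion force is the depth of the attractive
  dip in the bin-averaged force-distance curve relative to the large-distance
  plateau, and a tip-footprint average mimics what an AFM cantilever reads.
* **Umbrella-sampling PMF** (site-specific): biased windows along the z
  reaction coordinate are unbiased by the weighted histogram analysis method
  (WHAM) into a potential of mean force; the binding free energy is the depth
  of the interior minimum below the large-distance plateau (anchored to 0),
  with Bayesian-bootstrap (Dirichlet window-reweighting) uncertainties.
* **Langmuir isotherm** (collective): the equilibrium partition between bound
  and unbound ions gives K0 = q_e/(q_m - q_e) * C_0/C_e and
  dG0 = -R T ln K0.

AFM adhesion forces convert to free energies either as dG = N_A * F_AD * L
(L the length of the binding group) or through the Friddle equilibrium-limit
estimator dG = N_A * F_eq^2 / (2 k_cantilever); the two coincide exactly when
L = F_eq / (2 k).

The estimators are exposed both as functions and as model classes
(:class:`AdhesionForceModel`, :class:`UmbrellaPMF`, :class:`LangmuirIsotherm`)
whose ``fit()`` returns a result object with a ``summary()`` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .binding import CutoffScheme, classify_trajectory, DIVALENT_SPECIES
from .constants import KB, KJ_PER_MOL_NM_TO_PN, MOLAR_MASS, N_AVOGADRO, R_GAS
from .simulate import PullProtocol, PullRecord, UmbrellaWindow
from .trajectory import Trajectory

__all__ = [
    "PullRecord", "PullProtocol", "UmbrellaWindow",
    "AdhesionResult", "PMFCurve", "BindingDG", "LangmuirInputs",
    "LangmuirResult", "AFMRecord", "TipAverage",
    "extract_adhesion", "tip_average", "wham_pmf", "pmf_binding_dG",
    "estimate_langmuir_inputs", "langmuir_dG", "afm_force_to_dG", "friddle_dG",
    "AdhesionForceModel", "UmbrellaPMF", "LangmuirIsotherm",
]


# ---------------------------------------------------------------------------
# adhesion force extraction


@dataclass
class AdhesionResult:
    """Bin-averaged force curve and the extracted adhesion force (nN)."""

    binned_distance: np.ndarray
    binned_mean_force: np.ndarray
    plateau_force: float
    adhesion_force: float
    bin_size: int

    def summary(self) -> str:
        return (
            "Adhesion force extraction\n"
            f"  bins               : {self.binned_mean_force.size} x {self.bin_size} points\n"
            f"  plateau force      : {self.plateau_force:+.4f} nN\n"
            f"  extremal bin force : {self.binned_mean_force.min():+.4f} nN\n"
            f"  adhesion force     : {self.adhesion_force:.4f} nN"
        )


def extract_adhesion(
    pull,
    bin_size: int = 500,
    plateau_fraction: float = 0.2,
    force_unit: str = "kJ/mol/nm",
) -> AdhesionResult:
    """Bin-average a pull force trace and extract the adhesion force.

    ``pull`` is a :class:`PullRecord` or an (x, force) tuple of arrays. Forces
    are converted to nN (``force_unit`` is ``"kJ/mol/nm"``, ``"pN"`` or
    ``"nN"``). Non-overlapping bins of ``bin_size`` consecutive points are
    averaged; the plateau is the mean of the final ``plateau_fraction`` of
    bins and the adhesion force the absolute gap between the most negative
    (attractive) bin mean and that plateau.
    """
    if isinstance(pull, PullRecord):
        x, f = pull.center_z, pull.force
    else:
        x, f = np.asarray(pull[0], dtype=float), np.asarray(pull[1], dtype=float)
    scale = {"kJ/mol/nm": KJ_PER_MOL_NM_TO_PN * 1e-3, "pN": 1e-3, "nN": 1.0}[force_unit]
    f = f * scale
    if f.size < 2 * bin_size:
        raise ValueError(
            f"record of {f.size} points is too short for bin_size={bin_size} "
            "(need at least two bins)"
        )
    n_bins = f.size // bin_size
    fb = f[: n_bins * bin_size].reshape(n_bins, bin_size).mean(axis=1)
    xb = x[: n_bins * bin_size].reshape(n_bins, bin_size).mean(axis=1)
    n_plateau = max(1, int(round(plateau_fraction * n_bins)))
    plateau = float(fb[-n_plateau:].mean())
    adhesion = abs(float(fb.min()) - plateau)
    return AdhesionResult(xb, fb, plateau, adhesion, bin_size)


@dataclass
class TipAverage:
    """Footprint-averaged adhesion force (nN)."""

    mean: float
    std: float
    n_ions: int
    indices: list[int]

    def summary(self) -> str:
        return (
            f"Tip-averaged adhesion force: {self.mean:.4f} +/- {self.std:.4f} nN "
            f"({self.n_ions} ions in footprint)"
        )


def tip_average(
    results: list[AdhesionResult],
    ion_positions: np.ndarray,
    footprint: float = 2.4,
    center: tuple[float, float] | None = None,
) -> TipAverage:
    """Mean and sample std of adhesion forces over ions inside a square tip
    footprint (side ``footprint`` nm) centered on ``center`` (default: the
    centroid of the supplied positions)."""
    pos = np.asarray(ion_positions, dtype=float)[:, :2]
    if len(results) != pos.shape[0]:
        raise ValueError("one adhesion result per ion position required")
    cx, cy = center if center is not None else pos.mean(axis=0)
    half = footprint / 2.0
    inside = np.where(
        (np.abs(pos[:, 0] - cx) <= half) & (np.abs(pos[:, 1] - cy) <= half)
    )[0]
    if inside.size == 0:
        raise ValueError("no ions inside the tip footprint")
    vals = np.array([results[i].adhesion_force for i in inside])
    std = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return TipAverage(float(vals.mean()), std, int(inside.size), [int(i) for i in inside])


class AdhesionForceModel:
    """Adhesion-force estimator over one or many pull records.

    ``fit()`` returns the :class:`AdhesionResult` for a single record, or a
    (list-of-results, :class:`TipAverage`) pair when several records plus ion
    positions are given.
    """

    def __init__(self, records, bin_size: int = 500, plateau_fraction: float = 0.2,
                 force_unit: str = "kJ/mol/nm"):
        self.records = records
        self.bin_size = bin_size
        self.plateau_fraction = plateau_fraction
        self.force_unit = force_unit

    def fit(self, ion_positions=None, footprint: float = 2.4, center=None):
        if isinstance(self.records, (PullRecord, tuple)):
            return extract_adhesion(self.records, self.bin_size,
                                    self.plateau_fraction, self.force_unit)
        results = [
            extract_adhesion(r, self.bin_size, self.plateau_fraction, self.force_unit)
            for r in self.records
        ]
        if ion_positions is None:
            return results
        return results, tip_average(results, ion_positions, footprint, center)


# ---------------------------------------------------------------------------
# WHAM


@dataclass
class PMFCurve:
    """Potential of mean force with the large-distance plateau anchored to 0."""

    z: np.ndarray
    free_energy: np.ndarray
    bootstrap_std: np.ndarray
    n_bootstrap: int
    T: float
    window_meta: list[dict] = field(default_factory=list)

    def summary(self) -> str:
        dg = pmf_binding_dG(self)
        lines = [
            "WHAM potential of mean force",
            f"  windows     : {len(self.window_meta)}",
            f"  grid        : {self.z.size} bins over [{self.z[0]:.3f}, {self.z[-1]:.3f}] nm",
            f"  bootstraps  : {self.n_bootstrap}",
            f"  minimum     : {self.free_energy.min():+.3f} kJ/mol at "
            f"{self.z[int(np.argmin(self.free_energy))]:.3f} nm",
            f"  binding dG  : {dg.dG:.3f} kJ/mol"
            + ("" if dg.bound else " (no interior minimum: unbound)"),
        ]
        return "\n".join(lines)


def _wham_solve(n_kb: np.ndarray, N_k: np.ndarray, u_kb: np.ndarray,
                kT: float, tol: float, max_iter: int,
                f0: np.ndarray | None = None, return_f: bool = False):
    """Self-consistent WHAM in log space. Returns free energy per bin (kJ/mol),
    unanchored; empty bins come back as +inf. ``f0`` warm-starts the window
    shifts (used by the bootstrap)."""
    K, B = n_kb.shape
    log_Nk = np.log(N_k)
    tot_b = n_kb.sum(axis=0)
    log_nb = np.full(B, -np.inf)
    log_nb[tot_b > 0] = np.log(tot_b[tot_b > 0])
    f_k = np.zeros(K) if f0 is None else f0.copy()

    # The self-consistent WHAM equations are the stationary point of a convex
    # log-likelihood in the window shifts; minimize it directly (fast), then
    # polish with fixed-point sweeps to the requested self-consistency tol.
    from scipy.optimize import minimize

    M_b = tot_b
    u_red = u_kb / kT

    def objective(x):
        w = log_Nk[:, None] + x[:, None] - u_red       # (K, B)
        den = logsumexp(w, axis=0)
        obj = float(np.sum(M_b * den) - np.sum(N_k * x))
        soft = np.exp(w - den[None, :])
        grad = soft @ M_b - N_k
        return obj, grad

    res = minimize(objective, f_k / kT, jac=True, method="L-BFGS-B",
                   options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-10})
    f_k = res.x * kT
    f_k -= f_k[0]
    for _ in range(max_iter):
        log_den = logsumexp(log_Nk[:, None] + (f_k[:, None] - u_kb) / kT, axis=0)
        log_P = log_nb - log_den
        f_new = -kT * logsumexp(log_P[None, :] - u_kb / kT, axis=1)
        f_new -= f_new[0]
        if np.max(np.abs(f_new - f_k)) < tol:
            f_k = f_new
            break
        f_k = f_new
    log_den = logsumexp(log_Nk[:, None] + (f_k[:, None] - u_kb) / kT, axis=0)
    log_P = log_nb - log_den
    with np.errstate(invalid="ignore"):
        F = np.where(np.isfinite(log_P), -kT * log_P, np.inf)
    return (F, f_k) if return_f else F


def wham_pmf(
    windows: list[UmbrellaWindow],
    bin_width: float = 0.02,
    tol: float = 1e-8,
    max_iter: int = 100000,
    n_bootstrap: int = 200,
    seed: int = 0,
    plateau_fraction: float = 0.1,
) -> PMFCurve:
    """Combine umbrella windows into a PMF by self-consistent WHAM.

    The harmonic biases u_k(z) = k_umb/2 (z - c_k)^2 are unbiased iteratively
    to tolerance ``tol`` on the window free-energy shifts. The PMF is anchored
    so the mean over the final ``plateau_fraction`` of the grid is zero.
    Uncertainties are the per-bin std over ``n_bootstrap`` Bayesian bootstrap
    replicates (Dirichlet(1,...,1) weights across windows).

    Raises ValueError when adjacent windows do not overlap (naming the gap).
    """
    if not windows:
        raise ValueError("need at least one umbrella window")
    ordered = sorted(windows, key=lambda w: w.center)
    for a, b in zip(ordered, ordered[1:]):
        if a.samples.max() < b.samples.min():
            raise ValueError(
                f"umbrella windows at {a.center:.4f} and {b.center:.4f} nm do "
                f"not overlap ({a.samples.max():.4f} < {b.samples.min():.4f}); "
                "add intermediate windows"
            )
    T = ordered[0].T
    kT = KB * T
    lo = min(w.samples.min() for w in ordered)
    hi = max(w.samples.max() for w in ordered)
    edges = np.arange(lo, hi + bin_width, bin_width)
    if edges.size < 3:
        edges = np.linspace(lo, hi + 1e-9, 3)
    centers = 0.5 * (edges[:-1] + edges[1:])
    K, B = len(ordered), centers.size
    n_kb = np.stack([np.histogram(w.samples, bins=edges)[0] for w in ordered]).astype(float)
    N_k = n_kb.sum(axis=1)
    u_kb = np.stack([0.5 * w.k_umb * (centers - w.center) ** 2 for w in ordered])

    def anchored(F: np.ndarray) -> np.ndarray:
        ok = np.isfinite(F)
        n_pl = max(1, int(round(plateau_fraction * B)))
        plateau_idx = np.where(ok)[0][-n_pl:]
        return F - F[plateau_idx].mean()

    F_raw, f_hat = _wham_solve(n_kb, N_k, u_kb, kT, tol, max_iter, return_f=True)
    F = anchored(F_raw)
    rng = np.random.default_rng(seed)
    boots = np.empty((n_bootstrap, B))
    for b in range(n_bootstrap):
        w = rng.dirichlet(np.ones(K)) * K
        boots[b] = anchored(
            _wham_solve(n_kb * w[:, None], N_k * w, u_kb, kT, tol, max_iter, f0=f_hat)
        )
    import warnings

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        std = np.nanstd(np.where(np.isfinite(boots), boots, np.nan), axis=0)
    meta = [{"center": w.center, "k_umb": w.k_umb, "n_samples": int(n)}
            for w, n in zip(ordered, N_k)]
    return PMFCurve(centers, F, std, n_bootstrap, T, meta)


@dataclass
class BindingDG:
    """Binding free energy read off a PMF."""

    dG: float
    dG_per_ligand: float
    z_min: float
    bound: bool
    per_ligand_divisor: float


def pmf_binding_dG(pmf: PMFCurve, per_ligand_divisor: float = 1.0,
                   plateau_fraction: float = 0.1) -> BindingDG:
    """dG = |interior minimum - plateau| (plateau is 0 by anchoring).

    The minimum is searched outside the final ``plateau_fraction`` of the
    grid; a PMF with no interior minimum below the plateau is reported as
    unbound (dG = 0, ``bound=False``).
    """
    if per_ligand_divisor <= 0:
        raise ValueError("per_ligand_divisor must be > 0")
    ok = np.isfinite(pmf.free_energy)
    n_pl = max(1, int(round(plateau_fraction * pmf.z.size)))
    interior = np.where(ok)[0][:-n_pl] if np.count_nonzero(ok) > n_pl else np.where(ok)[0]
    if interior.size == 0:
        return BindingDG(0.0, 0.0, float("nan"), False, per_ligand_divisor)
    imin = interior[int(np.argmin(pmf.free_energy[interior]))]
    fmin = float(pmf.free_energy[imin])
    if fmin >= 0.0:
        return BindingDG(0.0, 0.0, float(pmf.z[imin]), False, per_ligand_divisor)
    dG = abs(fmin)
    return BindingDG(dG, dG / per_ligand_divisor, float(pmf.z[imin]), True,
                     per_ligand_divisor)


class UmbrellaPMF:
    """WHAM model over a set of umbrella windows; ``fit()`` -> :class:`PMFCurve`."""

    def __init__(self, windows: list[UmbrellaWindow], bin_width: float = 0.02,
                 tol: float = 1e-8, plateau_fraction: float = 0.1):
        self.windows = windows
        self.bin_width = bin_width
        self.tol = tol
        self.plateau_fraction = plateau_fraction

    def fit(self, n_bootstrap: int = 200, seed: int = 0) -> PMFCurve:
        return wham_pmf(self.windows, self.bin_width, self.tol,
                        n_bootstrap=n_bootstrap, seed=seed,
                        plateau_fraction=self.plateau_fraction)


# ---------------------------------------------------------------------------
# Langmuir isotherm


@dataclass
class LangmuirInputs:
    """Equilibrium occupancy inputs estimated from a trajectory."""

    q_e: float                 # mean bound ions over the analysis window
    q_m: float                 # maximum capacity (total divalent count by default)
    C_e: float                 # mol/L unbound
    bound_series: np.ndarray
    infinite_K: bool = False


def estimate_langmuir_inputs(
    traj: Trajectory,
    cutoffs: CutoffScheme,
    n_divalent_total: int | None = None,
    solution_volume_L: float | None = None,
    window: float = 0.5,
    ion_species=DIVALENT_SPECIES,
    q_m_mode: str = "ions",
    n_sites: int | None = None,
    z_slab: tuple[float, float] | None = None,
) -> LangmuirInputs:
    """Estimate (q_e, q_m, C_e) from the final ``window`` fraction of frames.

    An ion is bound when any carboxylate carbon lies within ``total_max``.
    ``solution_volume_L`` defaults to the box cross-section times the slab
    height above the headgroup plane (``z_slab`` overrides the bounds, nm).
    ``q_m_mode="ions"`` takes the maximum capacity as the total divalent ion
    count; ``"sites"`` uses ``n_sites`` (the ligand count).
    """
    if not 0 < window <= 1:
        raise ValueError("window must be a fraction in (0, 1]")
    idx_ion = traj.atom_indices(ion_species)
    n_div = n_divalent_total if n_divalent_total is not None else idx_ion.size
    if n_div < 1:
        raise ValueError("no divalent ions in trajectory")
    assignments = classify_trajectory(traj, cutoffs, ion_species=ion_species)
    bound = np.array([a.n_bound for a in assignments], dtype=float)
    n_tail = max(1, int(round(window * bound.size)))
    tail = bound[-n_tail:]
    q_e = float(tail.mean())
    if q_m_mode == "sites":
        if n_sites is None:
            raise ValueError("q_m_mode='sites' requires n_sites")
        q_m = float(n_sites)
    else:
        q_m = float(n_div)
    if solution_volume_L is None:
        idx_hg = traj.atom_indices("C")
        z0 = float(traj.frames[0, idx_hg, 2].mean()) if idx_hg.size else 0.0
        z_lo, z_hi = z_slab if z_slab is not None else (z0, traj.box.lz)
        solution_volume_L = traj.box.lx * traj.box.ly * (z_hi - z_lo) * 1e-24
    unbound_mean = float((n_div - tail).mean())
    C_e = unbound_mean / (N_AVOGADRO * solution_volume_L)
    return LangmuirInputs(q_e, q_m, C_e, bound, infinite_K=unbound_mean == 0.0)


@dataclass
class LangmuirResult:
    """Langmuir equilibrium constant and standard binding free energy."""

    q_e: float
    q_m: float
    C_e: float
    C_0: float
    K_0: float
    dG0: float
    T: float
    R: float = R_GAS

    def q_mg_per_g(self, species: str, absorbent_mass_g: float) -> tuple[float, float]:
        """(q_e, q_m) re-expressed in mg of ion per g of absorbent."""
        m = MOLAR_MASS[species]
        to_mg = m * 1e3 / N_AVOGADRO
        return self.q_e * to_mg / absorbent_mass_g, self.q_m * to_mg / absorbent_mass_g

    def summary(self) -> str:
        return (
            "Langmuir isotherm binding free energy\n"
            f"  q_e / q_m : {self.q_e:.3f} / {self.q_m:.3f} ions\n"
            f"  C_e       : {self.C_e:.6g} mol/L (C_0 = {self.C_0:g} mol/L)\n"
            f"  K_0       : {self.K_0:.6g}\n"
            f"  dG0       : {self.dG0:+.3f} kJ/mol at T = {self.T:g} K"
        )


def langmuir_dG(q_e: float, q_m: float, C_e: float, C_0: float = 1.0,
                T: float = 300.0) -> LangmuirResult:
    """K_0 = q_e/(q_m - q_e) * C_0/C_e and dG0 = -R T ln K_0."""
    if not 0 <= q_e < q_m:
        raise ValueError(
            f"need 0 <= q_e < q_m, got q_e={q_e}, q_m={q_m} "
            "(all ions bound implies an infinite equilibrium constant)"
        )
    if C_e <= 0:
        raise ValueError("C_e must be > 0 (no unbound ions implies infinite K_0)")
    if q_e == 0:
        raise ValueError("q_e = 0: no bound ions, K_0 = 0 and dG0 diverges")
    K_0 = q_e / (q_m - q_e) * C_0 / C_e
    dG0 = -R_GAS * T * math.log(K_0)
    return LangmuirResult(q_e, q_m, C_e, C_0, K_0, dG0, T)


class LangmuirIsotherm:
    """Langmuir-isotherm binding model; ``fit()`` -> :class:`LangmuirResult`."""

    def __init__(self, q_e: float, q_m: float, C_e: float, C_0: float = 1.0,
                 T: float = 300.0):
        self.q_e, self.q_m, self.C_e, self.C_0, self.T = q_e, q_m, C_e, C_0, T

    @classmethod
    def from_trajectory(cls, traj: Trajectory, cutoffs: CutoffScheme,
                        C_0: float = 1.0, T: float = 300.0,
                        **kwargs) -> "LangmuirIsotherm":
        inp = estimate_langmuir_inputs(traj, cutoffs, **kwargs)
        if inp.infinite_K:
            raise ValueError(
                "every divalent ion is bound in the analysis window: C_e = 0 "
                "and the Langmuir equilibrium constant diverges"
            )
        obj = cls(inp.q_e, inp.q_m, inp.C_e, C_0, T)
        obj.inputs = inp
        return obj

    def fit(self) -> LangmuirResult:
        return langmuir_dG(self.q_e, self.q_m, self.C_e, self.C_0, self.T)


# ---------------------------------------------------------------------------
# AFM conversions


@dataclass
class AFMRecord:
    """AFM adhesion force converted to a binding free energy."""

    F_AD: float                  # pN
    L: float                     # nm
    dG_bind: float               # kJ/mol
    dG_per_group: float | None = None
    tip_coverage: float | None = None
    T: float = 300.0

    @property
    def dG_in_kT(self) -> float:
        """Dimensionless view dG / (k_B T)."""
        return self.dG_bind / (KB * self.T)

    def summary(self) -> str:
        s = (
            "AFM force -> binding free energy\n"
            f"  F_AD    : {self.F_AD:g} pN, L = {self.L:g} nm\n"
            f"  dG_bind : {self.dG_bind:.3f} kJ/mol ({self.dG_in_kT:.2f} kT)"
        )
        if self.dG_per_group is not None:
            s += f"\n  per carboxylate group ({self.tip_coverage:g}): {self.dG_per_group:.3f} kJ/mol"
        return s


def afm_force_to_dG(F_AD: float, L: float, per_group: float | None = None,
                    T: float = 300.0) -> AFMRecord:
    """dG_bind = N_A * F_AD * L in kJ/mol (F_AD in pN, L in nm).

    ``per_group`` is the carboxylate-group coverage of the AFM tip; when
    given, the per-group free energy dG_bind / per_group is also reported.
    """
    if F_AD < 0:
        raise ValueError("adhesion force must be >= 0")
    if L <= 0:
        raise ValueError("interaction length must be > 0")
    dG = N_AVOGADRO * (F_AD * 1e-12) * (L * 1e-9) / 1e3
    per = dG / per_group if per_group else None
    return AFMRecord(F_AD, L, dG, per, per_group, T)


def friddle_dG(F_eq: float, k_cantilever: float) -> float:
    """Equilibrium-limit estimator dG = N_A * F_eq^2 / (2 k_cantilever).

    ``F_eq`` in pN (equal to the adhesion force in the loading-rate-
    independent regime), ``k_cantilever`` in N/m; returns kJ/mol.
    """
    if k_cantilever <= 0:
        raise ValueError("cantilever spring constant must be > 0")
    return N_AVOGADRO * (F_eq * 1e-12) ** 2 / (2.0 * k_cantilever) / 1e3
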