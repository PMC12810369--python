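# Methods

## System and scope

The package models the aqueous interface of a deprotonated
carboxylate-terminated alkanethiol monolayer (MUA-like) exposed to divalent
alkaline-earth cations, with Na⁺/Cl⁻ as supporting electrolyte. The reference
geometry is 154 ligands on a 14 × 11 triangular lattice — the (√3×√3)R30°
thiol adsorption lattice on Au(111), spacing 0.497 nm (√3 × the Au lattice
constant; the standard literature value, adopted here as an assumption and
configurable). Each ligand is reduced to its carboxylate headgroup: a carbon
at a configurable height above its lattice site and two oxygens 0.22 nm apart
(the intramolecular carboxylate O–O distance), each carrying −0.5 e by
default so the monolayer carries −1 e per deprotonated ligand. Alkyl chains
and the gold substrate are not represented; chains appear only as inputs to
the tilt-angle analysis.

## Nonbonded model

All ion–ion and ion–headgroup interactions use the 12-6 Lennard-Jones plus
Coulomb potential with Lorentz–Berthelot combining rules (arithmetic R_min,
geometric ε — the CHARMM convention; recorded per parameter set and
overridable). The Coulomb constant is fixed at 138.935458 kJ·mol⁻¹·nm·e⁻²;
units are GROMACS-style (nm, ps, kJ/mol, e, K, u) throughout.

The electronic continuum correction (ECC) scales ionic charges by
f = 1/√ε_el, default 0.80 when enabled. It applies to ion charges only by
default; scaling the headgroup charges too is available behind
`scale_headgroup_charges` and recorded in system metadata, since the
convention is genuinely ambiguous for surface charges.

Three parameter sets ship as YAML tables, each tagged with its provenance:
the Li et al. "compromise" TIP3P set (parametrized to hydration free energies
and coordination numbers), the Mamatkulov–Schwierz set (additionally activity
derivatives and water residence times), and the Mendes de Oliveira et al. ECC
set for Mg²⁺/Ca²⁺ (neutron-scattering structure factors; intended for use
with f = 0.80, which its table declares). Numeric values are best-effort
transcriptions from the cited primary sources; the tables are data, not
results — no test or reported number depends on their exact values — and
user-supplied tables in the same schema are first-class.

## Reduced Brownian simulator

Dynamics are overdamped Langevin (Euler–Maruyama):

x_{t+dt} = x_t + F/(mγ) dt + √(2 k_B T dt/(mγ)) ξ

with per-species mass m (u) and friction rate γ (1/ps, default 1), i.e.
friction coefficient ζ = mγ and diffusion constant D = k_B T/ζ. The solvent
is implicit: a relative dielectric ε_r = 78.5 divides the Coulomb constant.
This screening is distinct from ECC charge scaling (electronic polarization)
and the two are deliberately not merged; explicit-solvent MD would use ECC
with ε_r = 1, the implicit-solvent surrogate needs both.

Boundary conditions are a periodic slab: minimum image in x and y, reflecting
walls at z = 0 and z = l_z. Interactions use a plain cutoff, default 1.2 nm,
with no Ewald summation — the simulator is a controlled test harness for the
analysis pipeline, not an MD engine, and all of its statistical guarantees
are checked against closed forms (Einstein relation, equipartition variance,
Boltzmann histograms) rather than against real-water dynamics.

Headgroup atoms are immobile. The physical picture is a stiff harmonic
restraint of the lattice (50,000 kJ/mol/nm² on the anchoring atoms); in
overdamped integration such a spring would force dt below ~10⁻⁴ ps, so the
default is the infinite-stiffness limit and a finite per-atom tether
(`tether_k`) is available when mobility matters. The tether machinery doubles
as the external harmonic potential used in calibration runs.

Timestep guidance: dt should satisfy dt ≲ 0.2 ζ/k for the stiffest active
spring k; a warning is logged otherwise, and any non-finite or >10×-box
coordinate aborts the run with a diagnostic. The Euler–Maruyama stationary
variance in a harmonic well is k_BT/k · 2/(2 − k dt/ζ), so k dt/ζ ≤ 0.05
keeps the discretization bias of sampled variances below ~2.5%; calibration
tests use k dt/ζ ≈ 0.02.

Constant-rate pulls restrain the z component of the ion position relative to
the monolayer center of mass, with the restraint center moving as
c(t) = c₀ + v t (defaults k = 5000 kJ/mol/nm², v = 2×10⁻⁵ nm/ps). The
recorded force is the force the ion exerts on the moving restraint along +z,
k(z_ion − c): a bound, lagging ion produces a negative (attractive) dip,
which is the sign convention the adhesion extraction assumes. Umbrella
windows apply a static harmonic bias at each center, discard a configurable
burn-in (default 20%), and warn when adjacent windows' sample ranges barely
overlap.

## Synthetic ground-truth generator

Parameter-recovery tests need trajectories whose binding labels are known
exactly. Each ion owns a private cluster of carboxylate-carbon "slots", one
per contact type (B, M, I), on a grid with 4×total_max pitch so clusters
never interact. Per frame the ion is in a motif state — a subset of {B, M, I}
or "unbound" — and slots of active types sit at distances drawn uniformly
from the central 90% of the corresponding cutoff band (inactive slots are
parked at 1.4×total_max; unbound ions sit in bulk, 2.5×total_max above their
cluster). States switch by resampling from the target distribution with
probability 1 − exp(−r·dt) per frame (default exchange rate r = 0.05/ps),
so the stationary law equals the target by construction and empirical
fractions converge by the law of large numbers.

What this emulates: prescribed stationary motif mixtures, bound fractions and
exchange kinetics, i.e. exactly the statistical structure the classifiers and
the Langmuir estimator consume. What it does not emulate: realistic pair
correlations, solvation structure, cooperative binding, or forces — so
passing recovery tests certifies the *analysis* pipeline, not the realism of
any force field.

## Binding analysis

RDFs between group centers use minimum image in x/y, isotropic 4πr²dr shell
volumes and the N_B/V reference density of the full box; near the z walls an
ideal gas therefore reads below 1 (documented; the coordination number n(r)
is an exact cumulative pair count and free of this convention). Cutoff
derivation smooths g(r) with a centered moving average (5 bins) and places
cutoffs at the first local minimum after each of the first two peaks
(bidentate and direct bands); additional peaks form the indirect region, with
its terminating minimum as total_max and, when two indirect peaks exist, the
internal dip as `indirect_split`. Fewer than two peaks is an error asking for
manual cutoffs. With exactly two peaks the total band closes where g decays
to 5% of the second peak.

Classification maps each carboxylate-C–ion distance to B, M or I by the
bands; a per-ion category is the sorted union over ligands ("B+M+I" etc.).
Distances to the carboxylate carbon — the observable the C–ion RDF resolves —
define the bands; an oxygen-coordination cross-check is intentionally out of
the core path. The ligands-per-ion statistics condition on ions having at
least one contact of the respective tier (≥1 B for the bidentate column,
≥1 direct for direct, ≥1 any for total), so bidentate ≤ direct ≤ total holds
per ion by construction. Bound-count convergence uses the final window of the
series: converged when the two half-window means differ by less than one ion,
an operationalization of the equilibrium bound-count standard deviation of
about one ion.

## Free-energy estimators

*Adhesion.* Non-overlapping bins of 500 consecutive force points are
averaged; the plateau is the mean of the final 20% of bins and the adhesion
force |min(bin means) − plateau|, reported in nN. The estimate is exactly
invariant under constant force offsets. Tip averaging takes mean ± sample
standard deviation over ions whose starting x/y lie in a centered square
footprint (default 2.4 nm).

*WHAM.* Histogram WHAM on a common grid (default 0.02 nm bins; recovery
tests use 0.005 nm since the discretization error grows with k_umb·Δz²).
The self-consistent equations are solved by minimizing the equivalent convex
log-likelihood in the window shifts (L-BFGS with analytic gradient), then
polished by fixed-point sweeps to max|Δf| < 10⁻⁸ kJ/mol. The PMF is anchored
so the final 10% of the grid averages zero. Uncertainties are Bayesian
bootstrap: Dirichlet(1,…,1) weights across windows, each replicate re-solved
warm-started from the full-data solution (200 replicates by default, seeded).
Binding ΔG is the depth of the interior minimum below the plateau; a PMF with
no interior minimum below zero is reported unbound with ΔG = 0 and a flag.

*Langmuir.* q_e is the time-mean bound count over the final window (default:
last half) of frames, with "bound" meaning any carboxylate carbon within
total_max — the broadest reading, since excluding the indirect band is not
clearly warranted; q_m defaults to the total divalent ion count (the
monolayer has more sites than ions in the reference composition), with
q_m = site count available behind `q_m_mode="sites"`. C_e is the mean unbound
count over N_A × solution volume, the volume defaulting to box cross-section
× slab height above the headgroup plane (configurable — the convention is
not standardized). Capacities enter the isotherm as dimensionless counts; an
mg-per-g view is provided for reporting only. All-ions-bound yields C_e = 0
and is flagged as an infinite equilibrium constant rather than silently
clipped.

*AFM conversions.* ΔG_bind = N_A·F_AD·L per mole. The printed form of this
conversion is typographically ambiguous about k_BT; the worked number
78.4 pN × 3.32 Å → 15.7 kJ/mol fixes the per-mole convention adopted here,
and a dimensionless ΔG/k_BT view is retained on the result object. The
Friddle equilibrium-limit estimator is ΔG = N_A·F_eq²/(2k_cantilever); the
two agree identically when L = F_eq/(2k), which the tests assert numerically.

## Structure analysis

Tilt angles use the principal axis of the chain atom cloud (robust to kinks;
the first-to-last-atom vector is available as `axis_mode="endpoints"`),
folded to [0°, 90°] against +z. The carboxylate O–O analysis reports the
mean intramolecular distance and an intermolecular O–O RDF (same-ligand pairs
excluded) whose second-peak position tracks neighbour-carboxylate spacing.
Density profiles are per-species z histograms normalized by bin volume and
frame count (particle counts are conserved exactly by construction). The
electrostatic potential integrates the charge density twice by the
trapezoidal rule, E(0) = ψ(0) = 0, with ε_r = 78.5 default and ε_r = 1
available for vacuum-referenced profiles; a sign change of ψ flags charge
inversion. The parallel-plate capacitor closed form and a Gauss's-law
neutrality check validate the integration.

## Problem sizes and test design

The reference composition (100 divalent + 54 Na⁺ + 100 Cl⁻ over 154 ligands
in a 6.06 × 5.20 × 7.00 nm box) is the default scenario file; tests and the
acceptance script run reduced systems — 10–50 ions, 10³–10⁵ steps, 10³–10⁴
synthetic frames, 16 analytic umbrella windows of 2×10⁴ samples — chosen so
each statistical assertion has ≥2 standard errors of headroom at its stated
tolerance. Quantities reproduced exactly (the AFM conversions, the lattice
count, closed-form identities) are asserted to printed precision; stochastic
recoveries use the tolerances stated above, with fixed seeds for
reproducibility.

## Known limitations

- Absolute binding free energies, PMF depths and Table-style motif counts of
  the real interfacial system require large-scale explicit-solvent MD and are
  out of scope; the package validates estimator correctness, not force-field
  realism.
- No explicit water: hydrogen-bond-based indirect-binding subtypes can only
  be distinguished geometrically (via `indirect_split`), not by H-bond
  counting.
- No Ewald electrostatics; long-range effects beyond the cutoff are absent
  from the toy dynamics.
- GRO/XYZ/XVG-dialect text formats only; binary trajectory formats
  (XTC/TRR/DCD) are future work.
- Shipped force-field tables are transcriptions; verify against the original
  publications before production use.
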