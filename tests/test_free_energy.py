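"""Adhesion extraction, WHAM PMFs, Langmuir isotherm and AFM conversions."""

import math

import numpy as np
import pytest

from ionlayer import (
    CutoffScheme,
    LangmuirIsotherm,
    UmbrellaPMF,
    UmbrellaWindow,
    afm_force_to_dG,
    extract_adhesion,
    friddle_dG,
    generate_labeled_trajectory,
    langmuir_dG,
    pmf_binding_dG,
    tip_average,
    wham_pmf,
)
from ionlayer.constants import KB, R_GAS

kT300 = KB * 300.0


# ---------------------------------------------------------------------------
# adhesion


def _dip_trace(n=10_000, depth=-1.50, sigma=0.1, seed=0, offset=0.0):
    """Force trace in nN: Gaussian-shaped dip plus white noise."""
    rng = np.random.default_rng(seed)
    x = np.linspace(0.0, 5.0, n)
    # dip wide relative to the 500-point bin so bin averaging preserves depth
    force = depth * np.exp(-0.5 * ((x - 1.375) / 0.6) ** 2) + offset
    return x, force + rng.normal(0, sigma, n)


class TestAdhesion:
    def test_zero_trace_zero_adhesion(self):
        x = np.linspace(0, 1, 2000)
        res = extract_adhesion((x, np.zeros_like(x)), bin_size=100, force_unit="nN")
        assert res.adhesion_force == 0.0

    def test_recovers_synthetic_dip(self):
        """-1.50 nN dip under sigma = 0.1 nN noise recovered to +/-0.05 nN."""
        x, f = _dip_trace()
        res = extract_adhesion((x, f), bin_size=500, force_unit="nN")
        assert res.adhesion_force == pytest.approx(1.50, abs=0.05)

    def test_offset_invariance(self):
        x, f = _dip_trace(seed=1)
        a = extract_adhesion((x, f), bin_size=500, force_unit="nN").adhesion_force
        b = extract_adhesion((x, f + 0.7), bin_size=500, force_unit="nN").adhesion_force
        assert b == pytest.approx(a, abs=1e-12)

    def test_bin_size_self_consistency(self):
        """bin_size 1 vs 500 agree within one noise sigma."""
        x, f = _dip_trace(seed=2)
        a = extract_adhesion((x, f), bin_size=1, force_unit="nN").adhesion_force
        b = extract_adhesion((x, f), bin_size=500, force_unit="nN").adhesion_force
        assert abs(a - b) < 0.5  # raw-point extremum picks up noise peaks ~ 5 sigma
        # and with negligible noise they coincide
        x, f = _dip_trace(sigma=1e-6, seed=3)
        a = extract_adhesion((x, f), bin_size=1, force_unit="nN").adhesion_force
        b = extract_adhesion((x, f), bin_size=500, force_unit="nN").adhesion_force
        assert abs(a - b) < 0.02

    def test_short_record_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            extract_adhesion((np.arange(100.0), np.zeros(100)), bin_size=500)


class TestTipAverage:
    def _mk(self, adhesion):
        x = np.linspace(0, 1, 200)
        return extract_adhesion((x, np.full(200, -adhesion)), bin_size=10,
                                plateau_fraction=1e-9, force_unit="nN")

    def test_single_ion(self):
        res = [self._mk(1.2)]
        out = tip_average(res, np.array([[0.0, 0.0]]), footprint=2.4)
        assert out.mean == pytest.approx(res[0].adhesion_force)
        assert out.std == 0.0

    def test_three_ions_hand_formula(self):
        # constant traces have adhesion |min - plateau| = 0; build dips instead
        results = []
        for depth in (1.0, 2.0, 3.0):
            x, f = _dip_trace(n=2000, depth=-depth, sigma=0.0)
            results.append(extract_adhesion((x, f), bin_size=100, force_unit="nN"))
        pos = np.zeros((3, 2))
        out = tip_average(results, pos, footprint=1.0)
        assert out.mean == pytest.approx(2.0, rel=0.01)
        assert out.std == pytest.approx(1.0, rel=0.01)  # sample std of {1,2,3}

    def test_footprint_filter_matches_brute_force(self):
        rng = np.random.default_rng(5)
        depths = rng.uniform(0.5, 3.0, 12)
        results = []
        for d in depths:
            x, f = _dip_trace(n=2000, depth=-d, sigma=0.0)
            results.append(extract_adhesion((x, f), bin_size=100, force_unit="nN"))
        pos = rng.uniform(-3, 3, size=(12, 2))
        out = tip_average(results, pos, footprint=2.4, center=(0.0, 0.0))
        keep = [i for i in range(12) if abs(pos[i, 0]) <= 1.2 and abs(pos[i, 1]) <= 1.2]
        expect = np.array([results[i].adhesion_force for i in keep])
        assert sorted(out.indices) == sorted(keep)
        assert out.mean == pytest.approx(expect.mean())

    def test_empty_footprint_rejected(self):
        res = [self._mk(1.0)]
        with pytest.raises(ValueError, match="footprint"):
            tip_average(res, np.array([[50.0, 50.0]]), footprint=1.0, center=(0, 0))


# ---------------------------------------------------------------------------
# WHAM


def _analytic_windows(a=50.0, z0=1.0, k_umb=1000.0, n=20_000, seed=0,
                      centers=np.arange(0.3, 1.81, 0.1)):
    """Exact Gaussian samples from a quadratic landscape + harmonic bias."""
    rng = np.random.default_rng(seed)
    windows = []
    for c in centers:
        k_tot = a + k_umb
        mean = (a * z0 + k_umb * c) / k_tot
        windows.append(
            UmbrellaWindow(float(c), k_umb,
                           rng.normal(mean, math.sqrt(kT300 / k_tot), n), T=300.0)
        )
    return windows


class TestWham:
    def test_flat_landscape_flat_pmf(self):
        rng = np.random.default_rng(1)
        windows = [
            UmbrellaWindow(c, 200.0, rng.normal(c, math.sqrt(kT300 / 200.0), 20_000))
            for c in np.arange(0.5, 1.51, 0.1)
        ]
        pmf = wham_pmf(windows, bin_width=0.01, n_bootstrap=30, seed=0)
        sel = (pmf.z >= 0.5) & (pmf.z <= 1.5) & np.isfinite(pmf.free_energy)
        spread = pmf.free_energy[sel].max() - pmf.free_energy[sel].min()
        assert spread < 5 * np.nanmax(pmf.bootstrap_std[sel]) + 0.2

    def test_quadratic_landscape_recovery(self):
        """Recovered PMF matches 0.5 a (z - z0)^2 within 0.5 kJ/mol and 5%
        curvature over the window-sampled range."""
        a, z0 = 50.0, 1.0
        windows = _analytic_windows(a=a, z0=z0)
        pmf = wham_pmf(windows, bin_width=0.005, n_bootstrap=20, seed=0)
        target = 0.5 * a * (pmf.z - z0) ** 2
        sel = (pmf.z >= 0.3) & (pmf.z <= 1.8) & np.isfinite(pmf.free_energy)
        offset = (pmf.free_energy[sel] - target[sel]).mean()
        assert np.abs(pmf.free_energy[sel] - target[sel] - offset).max() < 0.5
        curv = 2.0 * np.polyfit(pmf.z[sel], pmf.free_energy[sel], 2)[0]
        assert curv == pytest.approx(a, rel=0.05)

    def test_single_unbiased_window_is_boltzmann_inversion(self):
        """With negligible bias the PMF equals -kT ln(histogram) + const."""
        rng = np.random.default_rng(2)
        samples = rng.normal(1.0, 0.1, 50_000)
        w = UmbrellaWindow(1.0, 1e-9, samples, T=300.0)
        pmf = wham_pmf([w], bin_width=0.02, n_bootstrap=0)
        hist, edges = np.histogram(samples, bins=np.arange(samples.min(),
                                                           samples.max() + 0.02, 0.02))
        ref = -kT300 * np.log(np.where(hist > 0, hist, np.nan))
        sel = np.isfinite(pmf.free_energy) & np.isfinite(ref[: pmf.z.size])
        diff = pmf.free_energy[sel] - ref[: pmf.z.size][sel]
        assert np.ptp(diff) < 1e-8  # constant offset only

    def test_non_overlapping_windows_error_names_gap(self):
        rng = np.random.default_rng(3)
        w1 = UmbrellaWindow(0.3, 5000.0, rng.normal(0.3, 0.01, 100))
        w2 = UmbrellaWindow(1.5, 5000.0, rng.normal(1.5, 0.01, 100))
        with pytest.raises(ValueError, match="0.3.*1.5"):
            wham_pmf([w1, w2])

    def test_model_interface(self):
        windows = _analytic_windows(n=2000)
        pmf = UmbrellaPMF(windows, bin_width=0.01).fit(n_bootstrap=10, seed=1)
        assert "WHAM" in pmf.summary()
        assert pmf.n_bootstrap == 10


class TestPmfBindingDG:
    def _pmf(self, values, z=None):
        from ionlayer.free_energy import PMFCurve

        z = z if z is not None else np.linspace(0.2, 2.0, len(values))
        return PMFCurve(z, np.asarray(values, dtype=float),
                        np.zeros(len(values)), 0, 300.0)

    def test_depth_of_minimum(self):
        z = np.linspace(0.2, 2.0, 100)
        vals = 50.0 * (np.exp(-((z - 0.6) ** 2) / 0.02) * -1.0)
        dg = pmf_binding_dG(self._pmf(vals, z))
        assert dg.dG == pytest.approx(50.0, rel=1e-6)
        assert dg.z_min == pytest.approx(0.6, abs=0.02)

    def test_per_ligand_division(self):
        z = np.linspace(0.2, 2.0, 100)
        vals = -44.0 * np.exp(-((z - 0.6) ** 2) / 0.02)
        dg = pmf_binding_dG(self._pmf(vals, z), per_ligand_divisor=4.4)
        assert dg.dG_per_ligand == pytest.approx(dg.dG / 4.4)

    def test_monotone_decay_flags_unbound(self):
        z = np.linspace(0.2, 2.0, 100)
        vals = 30.0 * np.exp(-3 * (z - 0.2))  # decays to plateau ~ 0 from above
        dg = pmf_binding_dG(self._pmf(vals, z))
        assert not dg.bound and dg.dG == 0.0


# ---------------------------------------------------------------------------
# Langmuir


class TestLangmuir:
    def test_symmetric_point_gives_zero(self):
        res = langmuir_dG(q_e=50.0, q_m=100.0, C_e=1.0, C_0=1.0, T=300.0)
        assert res.K_0 == pytest.approx(1.0)
        assert res.dG0 == pytest.approx(0.0, abs=1e-12)

    def test_direct_formula_oracle(self):
        res = langmuir_dG(90.0, 100.0, 0.065, T=300.0)
        K = (90.0 / 10.0) * (1.0 / 0.065)
        assert res.K_0 == pytest.approx(K, rel=1e-14)
        assert res.dG0 == pytest.approx(-R_GAS * 300.0 * math.log(K), rel=1e-14)

    def test_c0_doubling_shifts_by_rt_ln2(self):
        a = langmuir_dG(30.0, 100.0, 0.2, C_0=1.0, T=300.0)
        b = langmuir_dG(30.0, 100.0, 0.2, C_0=2.0, T=300.0)
        assert b.dG0 - a.dG0 == pytest.approx(-R_GAS * 300.0 * math.log(2.0), rel=1e-12)

    def test_antisymmetry_under_occupancy_swap(self):
        """(q_e, q_m-q_e) swap with C_e <-> C_0 inverts K_0 and flips dG0."""
        rng = np.random.default_rng(8)
        for _ in range(25):
            q_m = rng.uniform(10, 200)
            q_e = rng.uniform(0.1, 0.9) * q_m
            C_e = rng.uniform(1e-3, 2.0)
            C_0 = rng.uniform(1e-3, 2.0)
            fwd = langmuir_dG(q_e, q_m, C_e, C_0)
            rev = langmuir_dG(q_m - q_e, q_m, C_0, C_e)
            assert rev.K_0 == pytest.approx(1.0 / fwd.K_0, rel=1e-10)
            assert rev.dG0 == pytest.approx(-fwd.dG0, rel=1e-10, abs=1e-10)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            langmuir_dG(100.0, 100.0, 0.1)
        with pytest.raises(ValueError):
            langmuir_dG(10.0, 100.0, 0.0)

    def test_recovers_generator_bound_fraction(self, default_cutoffs):
        """Generator with 60% bound states yields q_e within 0.02 n."""
        n_ions = 50
        lt = generate_labeled_trajectory(
            n_ions, 3000,
            {"B": 0.2, "M": 0.2, "I": 0.2, "unbound": 0.4},
            cutoffs=default_cutoffs, seed=21,
        )
        model = LangmuirIsotherm.from_trajectory(
            lt.trajectory, default_cutoffs, window=1.0
        )
        assert model.q_e == pytest.approx(0.6 * n_ions, abs=0.02 * n_ions)
        res = model.fit()
        # dG0 matches the direct formula evaluation exactly
        K = model.q_e / (model.q_m - model.q_e) * model.C_0 / model.C_e
        assert res.dG0 == pytest.approx(-R_GAS * 300.0 * math.log(K), rel=1e-14)

    def test_hand_arithmetic_inputs(self, default_cutoffs):
        """90 of 100 ions bound in 1.5e-22 L -> q_e = 90, C_e by hand."""
        from ionlayer import estimate_langmuir_inputs

        lt = generate_labeled_trajectory(
            100, 20, {"B": 1.0}, cutoffs=default_cutoffs, seed=1
        )
        # relabel 10 ions as permanently unbound by moving them far away
        traj = lt.trajectory
        idx_ion = traj.atom_indices("Ca2+")[:10]
        traj.frames[:, idx_ion, 2] = traj.box.lz - 0.05
        inp = estimate_langmuir_inputs(
            traj, default_cutoffs, solution_volume_L=1.5e-22, window=1.0
        )
        assert inp.q_e == 90.0
        assert inp.C_e == pytest.approx(10.0 / (6.02214076e23 * 1.5e-22), rel=1e-12)

    def test_all_bound_flags_infinite_K(self, default_cutoffs):
        lt = generate_labeled_trajectory(10, 5, {"B": 1.0},
                                         cutoffs=default_cutoffs, seed=2)
        from ionlayer import estimate_langmuir_inputs

        inp = estimate_langmuir_inputs(lt.trajectory, default_cutoffs)
        assert inp.infinite_K
        with pytest.raises(ValueError, match="diverges"):
            LangmuirIsotherm.from_trajectory(lt.trajectory, default_cutoffs)


# ---------------------------------------------------------------------------
# AFM conversions


class TestAFM:
    def test_printed_worked_example(self):
        """78.4 pN x 3.32 A converts to 15.7 kJ/mol."""
        assert afm_force_to_dG(78.4, 0.332).dG_bind == pytest.approx(15.7, abs=0.05)

    def test_zero_force(self):
        assert afm_force_to_dG(0.0, 0.22).dG_bind == 0.0

    def test_unit_conversion_oracle(self):
        got = afm_force_to_dG(100.0, 0.22).dG_bind
        expect = 6.02214076e23 * (100e-12) * (0.22e-9) / 1e3
        assert got == pytest.approx(expect, rel=1e-14)

    def test_per_group_coverage(self):
        rec = afm_force_to_dG(78.4, 0.22, per_group=20)
        assert rec.dG_per_group == pytest.approx(rec.dG_bind / 20)

    def test_friddle_printed_comparison(self):
        """78.4 pN with k = 0.09 N/m gives 20.6 kJ/mol."""
        assert friddle_dG(78.4, 0.09) == pytest.approx(20.6, abs=0.05)

    def test_friddle_zero_force(self):
        assert friddle_dG(0.0, 0.1) == 0.0

    def test_friddle_unit_oracle(self):
        got = friddle_dG(100.0, 0.10)
        expect = 6.02214076e23 * (1e-10) ** 2 / 0.2 / 1e3
        assert got == pytest.approx(expect, rel=1e-14)

    def test_estimators_agree_at_matched_length(self):
        """F L == F^2/(2k) when L = F/(2k): algebraic identity, numerically."""
        F, k = 123.4, 0.07  # pN, N/m
        L_nm = (F * 1e-12) / (2 * k) * 1e9
        assert afm_force_to_dG(F, L_nm).dG_bind == pytest.approx(
            friddle_dG(F, k), rel=1e-12
        )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            afm_force_to_dG(-1.0, 0.22)
        with pytest.raises(ValueError):
            afm_force_to_dG(1.0, 0.0)
        with pytest.raises(ValueError):
            friddle_dG(10.0, 0.0)
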