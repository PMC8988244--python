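"""MBAR, PMF reconstruction, FEP averaging, I*, and error rules."""

import math
import warnings

import numpy as np
import pytest

from dimerfe.pmf import (
    DisconnectedSamplingError,
    FreeEnergyEstimate,
    PMFProfile,
    UmbrellaWindow,
    convergence_error,
    dg_dist_a,
    fep_cost,
    i_star,
    integrated_autocorrelation_time,
    load_windows,
    mbar_bootstrap,
    mbar_solve,
    pmf_from_windows,
    read_colvar,
    write_colvar,
)
from dimerfe.synthetic import (
    harmonic_potential,
    make_double_well,
    sample_potential,
    sample_umbrella_windows,
    tabulated_potential,
    true_free_energy,
    true_i_star,
)
from dimerfe.thermo import ThermoContext


class TestMbar:
    def test_single_window(self, thermo):
        w = UmbrellaWindow(0.0, 5.0, np.array([0.1, -0.2, 0.3]))
        assert np.array_equal(mbar_solve([w], thermo), [0.0])

    def test_two_harmonic_windows_match_gaussian_closed_form(self, thermo):
        # underlying V = x^2/2, biases k_b = 5 at centers 0 and 1:
        # f2 - f1 = beta * (k0 kb / (k0+kb)) c^2 / 2 exactly
        pot = harmonic_potential(1.0, 0.0, (-6.0, 6.0))
        windows = sample_umbrella_windows(pot, [0.0, 1.0], 5.0, 1500, thermo, seed=4)
        exact = 0.5 * (1.0 * 5.0 / 6.0) * 1.0**2 / thermo.kT
        value, sigma = mbar_bootstrap(windows, lambda ws, f: f[1], thermo, n_boot=25)
        assert value == pytest.approx(exact, abs=3 * sigma + 1e-6)

    def test_double_well_gap_matches_quadrature(self, thermo):
        pot = make_double_well()
        centers = np.linspace(2.0, 10.0, 17)
        windows = sample_umbrella_windows(pot, centers, 8.0, 300, thermo, seed=9)

        def well_gap_from_pmf(ws, f):
            prof = pmf_from_windows(ws, f, thermo=thermo)
            g, v = prof.grid[prof.occupied], prof.values[prof.occupied]
            beta = thermo.beta

            def well_fe(lo, hi):
                m = (g >= lo) & (g <= hi)
                return -thermo.kT * np.log(np.trapezoid(np.exp(-beta * v[m]), g[m]))

            return well_fe(2.0, 6.1) - well_fe(6.1, 10.0)

        value, sigma = mbar_bootstrap(windows, well_gap_from_pmf, thermo, n_boot=20)
        beta = thermo.beta
        x = np.linspace(2.0, 10.0, 8001)
        vx = pot(x)

        def true_fe(lo, hi):
            m = (x >= lo) & (x <= hi)
            return -thermo.kT * np.log(np.trapezoid(np.exp(-beta * vx[m]), x[m]))

        exact = true_fe(2.0, 6.1) - true_fe(6.1, 10.0)
        # allowance for histogram discretization on top of the bootstrap band
        assert value == pytest.approx(exact, abs=3 * sigma + 0.1)

    def test_disconnected_windows_raise(self, thermo):
        w1 = UmbrellaWindow(0.0, 1000.0, np.linspace(-0.05, 0.05, 50))
        w2 = UmbrellaWindow(100.0, 1000.0, np.linspace(99.95, 100.05, 50))
        with pytest.raises(DisconnectedSamplingError):
            mbar_solve([w1, w2], thermo)

    def test_weak_overlap_warns(self, thermo):
        w1 = UmbrellaWindow(0.0, 10.0, np.linspace(-0.5, 0.52, 80))
        w2 = UmbrellaWindow(1.0, 10.0, np.concatenate([[0.5], np.linspace(1.0, 1.5, 79)]))
        with pytest.warns(UserWarning, match="share only"):
            mbar_solve([w1, w2], thermo)

    def test_unbiased_window_reduces_mbar_to_fep(self, thermo):
        # f of a biased window relative to an unbiased one equals the FEP
        # cost of its bias evaluated on the unbiased samples
        pot = harmonic_potential(2.0, 0.0, (-5.0, 5.0))
        rng = np.random.default_rng(11)
        x0 = sample_potential(pot, 4000, thermo, rng=rng)
        bias = UmbrellaWindow(0.3, 4.0, np.array([0.0]))
        x1 = sample_potential(pot, 4000, thermo,
                              bias=bias.bias_energy, rng=rng)
        w0 = UmbrellaWindow(0.0, 0.0, x0)
        w1 = UmbrellaWindow(0.3, 4.0, x1)
        f = mbar_solve([w0, w1], thermo)
        fep = fep_cost(bias.bias_energy(x0), thermo, rng=rng)
        assert f[1] * thermo.kT == pytest.approx(fep.value, abs=3 * fep.stat_error + 0.02)


class TestPmfReconstruction:
    def test_flat_potential_gives_flat_pmf(self, thermo):
        flat = tabulated_potential([0.0, 10.0], [0.0, 0.0])
        windows = sample_umbrella_windows(flat, np.linspace(1, 9, 9), 2.0, 600,
                                          thermo, seed=21)
        prof = pmf_from_windows(windows, thermo=thermo)
        inner = (prof.grid > 1.0) & (prof.grid < 9.0) & prof.occupied
        assert np.nanmax(prof.values[inner]) < 0.25

    def test_double_well_shape_and_pointwise_agreement(self, thermo):
        pot = make_double_well()
        centers = np.linspace(2.0, 10.0, 17)
        windows = sample_umbrella_windows(pot, centers, 8.0, 300, thermo, seed=13)
        prof = pmf_from_windows(windows, thermo=thermo, n_boot=15)
        g, v = prof.grid[prof.occupied], prof.values[prof.occupied]
        s = prof.uncertainties[prof.occupied]
        # two minima near 4 and 8 with the barrier top inside 5.2-7.0
        left = g < 6.1
        assert abs(g[left][np.argmin(v[left])] - 4.0) < 0.5
        assert abs(g[~left][np.argmin(v[~left])] - 8.0) < 0.5
        mid = (g > 4.5) & (g < 9.0)
        barrier_pos = g[mid][np.argmax(v[mid])]
        assert 5.2 <= barrier_pos <= 7.0
        # pointwise agreement with the generator (min-zero aligned),
        # within 3 sigma plus a binning allowance
        ref = pot(g)
        ref = ref - ref.min()
        core = (g > 2.5) & (g < 9.5)
        assert np.all(np.abs(v - ref)[core] <= 3 * s[core] + 0.15)

    def test_bin_width_stability(self, thermo):
        pot = make_double_well()
        centers = np.linspace(2.5, 9.5, 13)
        windows = sample_umbrella_windows(pot, centers, 8.0, 250, thermo, seed=5)
        f = mbar_solve(windows, thermo)
        coarse = pmf_from_windows(windows, f, thermo=thermo, n_boot=15)
        lo, hi = coarse.grid[0], coarse.grid[-1]
        half = np.linspace(lo, hi, 2 * (len(coarse.grid)) + 1)
        fine = pmf_from_windows(windows, f, grid=half, thermo=thermo)
        vals_interp = np.interp(
            coarse.grid[coarse.occupied],
            fine.grid[fine.occupied], fine.values[fine.occupied],
        )
        diff = np.abs(vals_interp - coarse.values[coarse.occupied])
        tol = np.maximum(coarse.uncertainties[coarse.occupied], 0.02) + 0.1
        assert np.all(diff <= 3 * tol)

    def test_reference_window_choice_is_immaterial(self, thermo):
        pot = make_double_well()
        windows = sample_umbrella_windows(pot, np.linspace(3, 9, 7), 8.0, 200,
                                          thermo, seed=2)
        prof_a = pmf_from_windows(windows, thermo=thermo)
        reordered = windows[::-1]
        prof_b = pmf_from_windows(reordered, thermo=thermo, grid=None)
        vb = np.interp(prof_a.grid[prof_a.occupied],
                       prof_b.grid[prof_b.occupied], prof_b.values[prof_b.occupied])
        assert np.allclose(prof_a.values[prof_a.occupied], vb, atol=1e-6)


class TestFep:
    def test_zero_restraint_costs_nothing(self, thermo):
        est = fep_cost(np.zeros(100), thermo)
        assert est.value == 0.0
        assert est.stat_error == 0.0

    def test_gaussian_ratio_closed_form(self, thermo, rng):
        # V = x^2/2, u = x^2/2: dG = (kT/2) ln 2
        pot = harmonic_potential(1.0, 0.0, (-6.0, 6.0))
        x = sample_potential(pot, 5000, thermo, rng=rng)
        est = fep_cost(0.5 * x**2, thermo, rng=rng)
        exact = 0.5 * thermo.kT * math.log(2.0)
        assert est.value == pytest.approx(exact, abs=3 * est.stat_error + 1e-3)

    def test_staged_imposition_is_path_independent(self, thermo, rng):
        # imposing u1 then u2 equals imposing u1+u2 at once
        pot = harmonic_potential(1.5, 0.0, (-6.0, 6.0))
        u1 = lambda x: 0.4 * x**2
        u2 = lambda x: 0.3 * (x - 0.2) ** 2
        x0 = sample_potential(pot, 6000, thermo, rng=rng)
        stage1 = fep_cost(u1(x0), thermo, rng=rng)
        x1 = sample_potential(pot, 6000, thermo, bias=u1, rng=rng)
        stage2 = fep_cost(u2(x1), thermo, rng=rng)
        x0b = sample_potential(pot, 6000, thermo, rng=rng)
        single = fep_cost(u1(x0b) + u2(x0b), thermo, rng=rng)
        sigma = math.hypot(stage1.stat_error, stage2.stat_error, single.stat_error)
        assert stage1.value + stage2.value == pytest.approx(
            single.value, abs=3 * sigma + 1e-3
        )
        exact = true_free_energy(pot, lambda x: u1(x) + u2(x), thermo)
        assert single.value == pytest.approx(exact, abs=3 * single.stat_error + 1e-3)

    def test_too_few_or_infinite_samples_rejected(self, thermo):
        with pytest.raises(ValueError):
            fep_cost(np.array([1.0]), thermo)
        with pytest.raises(ValueError):
            fep_cost(np.full(10, np.inf), thermo)


class TestIStar:
    def test_flat_pmf_over_unit_range(self, thermo):
        grid = np.linspace(0.0, 1.0, 11)
        prof = PMFProfile(grid, np.full(11, 2.5), np.zeros(11))
        assert i_star(prof, 1.0, thermo, r_min=0.0) == pytest.approx(1.0)

    def test_square_well_piecewise_closed_form(self, thermo):
        dx = 5e-4
        grid = np.arange(0.0, 3.0 + dx / 2, dx)
        w = np.where((grid >= 1.0) & (grid <= 2.0), -5.0, 0.0)
        prof = PMFProfile(grid, w, np.zeros_like(w))
        expected = math.exp(5.0 / thermo.kT) + 2.0
        assert i_star(prof, 3.0, thermo, r_min=0.0) == pytest.approx(expected, rel=1e-3)

    def test_gaussian_well_matches_adaptive_quadrature(self, thermo):
        pot = tabulated_potential(
            np.linspace(0, 10, 6001),
            3.0 - 3.0 * np.exp(-0.5 * ((np.linspace(0, 10, 6001) - 3.0) / 0.7) ** 2),
        )
        grid = np.linspace(0.0, 10.0, 6001)
        prof = PMFProfile(grid, pot(grid), np.zeros_like(grid))
        est = i_star(prof, 10.0, thermo, r_min=0.0)
        exact = true_i_star(pot, 10.0, thermo)
        assert est == pytest.approx(exact, rel=1e-3)

    def test_monotone_in_well_depth(self, thermo):
        grid = np.linspace(0.0, 5.0, 501)
        shallow = PMFProfile(grid, -2.0 * np.exp(-((grid - 2) ** 2)), np.zeros_like(grid))
        deep = PMFProfile(grid, -4.0 * np.exp(-((grid - 2) ** 2)), np.zeros_like(grid))
        assert i_star(deep, 5.0, thermo, r_min=0.0) > i_star(shallow, 5.0, thermo, r_min=0.0)

    def test_anchor_outside_grid_rejected(self, thermo):
        grid = np.linspace(0.0, 1.0, 11)
        prof = PMFProfile(grid, np.zeros(11), np.zeros(11))
        with pytest.raises(ValueError):
            i_star(prof, 2.0, thermo)


class TestDistPlusAngleTerm:
    def test_unit_argument_gives_zero(self, thermo):
        # c0 * S* * I* = 1  <=>  S* I* = v0
        assert dg_dist_a(1.0, thermo.standard_volume, thermo) == pytest.approx(0.0)

    def test_log_identity(self, thermo):
        base = dg_dist_a(100.0, 5.0, thermo)
        boosted = dg_dist_a(100.0 * math.exp(1.0 / thermo.kT), 5.0, thermo)
        assert base - boosted == pytest.approx(1.0, abs=1e-10)

    def test_monotone_decreasing(self, thermo):
        assert dg_dist_a(200.0, 5.0, thermo) < dg_dist_a(100.0, 5.0, thermo)
        assert dg_dist_a(100.0, 10.0, thermo) < dg_dist_a(100.0, 5.0, thermo)

    def test_reference_magnitude(self, thermo):
        # S* ~ 5.45 A^2 with I* ~ 4.40e3 A at 1 M: about -1.59 kcal/mol
        val = dg_dist_a(4.40e3, 5.45, thermo)
        expected = -thermo.kT * math.log(5.45 * 4.40e3 / thermo.standard_volume)
        assert val == pytest.approx(expected)
        assert val == pytest.approx(-1.59, abs=0.02)


class TestErrorRules:
    def test_reported_error_is_the_larger_source(self):
        est = FreeEnergyEstimate(1.0, stat_error=0.3, sys_error=0.1)
        assert est.error == 0.3
        est = FreeEnergyEstimate(1.0, stat_error=0.1, sys_error=0.4)
        assert est.error == 0.4

    def _fep_estimator(self, thermo):
        def estimator(ws):
            u = 0.5 * 2.0 * ws[0].samples**2
            return fep_cost(u, thermo, n_boot=20)
        return estimator

    def test_stationary_series_converges(self, thermo):
        pot = harmonic_potential(1.0, 0.0, (-6.0, 6.0))
        est_small = convergence_error(
            [UmbrellaWindow(0.0, 0.0, sample_potential(pot, 400, thermo, rng=1))],
            self._fep_estimator(thermo),
        )
        est_large = convergence_error(
            [UmbrellaWindow(0.0, 0.0, sample_potential(pot, 40000, thermo, rng=1))],
            self._fep_estimator(thermo),
        )
        assert est_large.sys_error < est_small.sys_error + 0.02
        assert est_large.sys_error < 0.05

    def test_drifting_series_dominates_report(self, thermo):
        pot = harmonic_potential(1.0, 0.0, (-6.0, 6.0))
        x = sample_potential(pot, 4000, thermo, rng=3)
        drift = x + np.linspace(0.0, 2.5, x.size)  # deliberate non-stationarity
        est = convergence_error(
            [UmbrellaWindow(0.0, 0.0, drift)], self._fep_estimator(thermo)
        )
        assert est.sys_error > est.stat_error
        assert est.error == est.sys_error

    def test_needs_enough_fractions(self, thermo):
        w = UmbrellaWindow(0.0, 0.0, np.random.default_rng(0).normal(size=100))
        with pytest.raises(ValueError):
            convergence_error([w], self._fep_estimator(thermo), fractions=(0.5, 1.0))

    def test_autocorrelation_time_of_iid_series_is_near_one(self, rng):
        tau = integrated_autocorrelation_time(rng.normal(size=4000))
        assert tau < 1.5


def test_colvar_round_trip_and_manifest(tmp_path, thermo):
    values = np.linspace(3.0, 4.0, 25)
    write_colvar(tmp_path / "w0.colvar", values)
    assert np.allclose(read_colvar(tmp_path / "w0.colvar"), values, atol=1e-7)
    (tmp_path / "windows.json").write_text(
        '{"windows": [{"file": "w0.colvar", "center": 3.5, "k": 10.0}]}'
    )
    windows = load_windows(tmp_path / "windows.json")
    assert len(windows) == 1
    assert windows[0].center == 3.5
    assert windows[0].n == 25
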