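"""Dissolution–elimination PK model: closed forms, conservation, limits, recovery."""

import math

import numpy as np
import pytest

from crystaldepot import pk
from crystaldepot.pk import (CrystalDepot, PKParameters, ZincSolubilityModel,
                             bolus_time_above_threshold, complete_dissolution_time,
                             fit_dissolution_params, interval_extension_on_dose_doubling,
                             simulate_bolus, simulate_crystal_depot,
                             steady_state_concentration, time_above_threshold,
                             zinc_adjusted_solubility)


class TestBolus:
    def test_closed_form(self, default_params):
        t = np.array([0.0, default_params.t_half, 3 * default_params.t_half])
        prof = simulate_bolus(1.0, default_params, t)
        assert prof.Ct[0] == 1.0
        assert prof.Ct[1] == pytest.approx(0.5, rel=1e-12)
        assert prof.Ct[2] == pytest.approx(0.125, rel=1e-12)

    def test_time_above_threshold_closed_form(self, default_params):
        """10x-threshold bolus stays efficacious for ln(10)/k."""
        thr = default_params.C_threshold
        expected = math.log(10.0) / default_params.k
        assert bolus_time_above_threshold(10 * thr, default_params, thr) == \
            pytest.approx(expected, rel=1e-12)
        # interpolated measure on a grid agrees within 1%
        t = np.linspace(0, 200, 801)
        prof = simulate_bolus(10 * thr, default_params, t)
        assert time_above_threshold(prof, thr) == pytest.approx(expected, rel=0.01)

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            PKParameters(k=0.0, h=1.0, V=4.5, Cs=0.1)

    def test_threshold_above_peak_gives_zero(self, default_params):
        prof = simulate_bolus(0.005, default_params, np.linspace(0, 10, 11))
        assert time_above_threshold(prof, 0.01) == 0.0


class TestDoseDoubling:
    @pytest.mark.parametrize("t_half", [8.0, 9.5, 11.0])
    def test_extension_is_one_half_life(self, t_half):
        """Doubling a bolus dose buys exactly one elimination half-life."""
        params = PKParameters.from_half_life(t_half, h=1.0, V=4.5, Cs=0.1,
                                             C_threshold=0.01)
        ext = interval_extension_on_dose_doubling(params, 0.1)
        assert ext == pytest.approx(t_half, rel=1e-12)

    @pytest.mark.parametrize("mult", [2.0, 5.0, 50.0])
    def test_dose_independent(self, default_params, mult):
        thr = default_params.C_threshold
        ext = interval_extension_on_dose_doubling(default_params, mult * thr)
        assert ext == pytest.approx(default_params.t_half, rel=1e-12)

    def test_subthreshold_dose_rejected(self, default_params):
        with pytest.raises(ValueError):
            interval_extension_on_dose_doubling(default_params, 0.001)


class TestDepotSimulation:
    def test_no_driving_force(self, lamellar_depot, day_grid):
        params = PKParameters.from_half_life(9.5, h=0.5, V=4.5, Cs=0.0)
        prof = simulate_crystal_depot(lamellar_depot, params, day_grid)
        assert np.all(prof.Ct == 0.0)
        assert np.all(prof.M == lamellar_depot.M0)

    @pytest.mark.parametrize("geometry", ["lamellar", "isometric"])
    def test_mass_conservation(self, default_params, day_grid, geometry):
        depot = CrystalDepot(M0=5.0, A0=2.0, geometry_mode=geometry)
        prof = simulate_crystal_depot(depot, default_params, day_grid)
        assert prof.mass_balance_residual() < 1e-6
        assert np.all(np.diff(prof.M) <= 1e-12)

    def test_mass_conservation_through_exhaustion(self, default_params):
        """Balance holds across the M = 0 event and the washout tail."""
        depot = CrystalDepot(M0=0.05, A0=2.0, geometry_mode="isometric")
        t = np.linspace(0, 60, 301)
        prof = simulate_crystal_depot(depot, default_params, t)
        assert prof.M[-1] == 0.0
        assert prof.mass_balance_residual() < 1e-6

    def test_concentration_capped_at_solubility(self, default_params, day_grid):
        depot = CrystalDepot(M0=50.0, A0=50.0)
        prof = simulate_crystal_depot(depot, default_params, day_grid)
        assert np.all(prof.Ct <= default_params.Cs * (1 + 1e-9))

    def test_bolus_limit(self, default_params):
        """Fast transfer with dose << Cs·V collapses to the bolus closed form."""
        fast = PKParameters(k=default_params.k, h=5e4, V=4.5, Cs=10.0)
        depot = CrystalDepot(M0=0.5, A0=2.0)
        t = np.linspace(0, 60, 241)
        prof = simulate_crystal_depot(depot, fast, t)
        bol = simulate_bolus(depot.M0 / fast.V, fast, t)
        gap = np.max(np.abs(prof.Ct[1:] - bol.Ct[1:]))
        assert gap < 0.01 * bol.Ct.max()

    def test_steady_state_fixed_point(self, default_params):
        """Inexhaustible constant-area depot settles at Cs·q/(q+k), q = A·h/V."""
        depot = CrystalDepot(M0=1e6, A0=2.0)
        t = np.linspace(0, 300, 301)
        prof = simulate_crystal_depot(depot, default_params, t)
        target = steady_state_concentration(depot.A0, default_params)
        assert prof.Ct[-1] == pytest.approx(target, rel=1e-4)

    def test_depot_outlasts_equal_dose_bolus(self, default_params, lamellar_depot):
        """Crystal retention lengthens the efficacious window vs a bolus."""
        t = np.linspace(0, 500, 2001)
        prof = simulate_crystal_depot(lamellar_depot, default_params, t)
        tat_depot = time_above_threshold(prof, default_params.C_threshold)
        tat_bolus = bolus_time_above_threshold(
            lamellar_depot.M0 / default_params.V, default_params,
            default_params.C_threshold)
        assert tat_depot > tat_bolus

    def test_grid_refinement_stability(self, default_params, lamellar_depot):
        coarse = simulate_crystal_depot(lamellar_depot, default_params,
                                        np.linspace(0, 200, 201))
        fine = simulate_crystal_depot(lamellar_depot, default_params,
                                      np.linspace(0, 200, 2001))
        thr = default_params.C_threshold
        assert time_above_threshold(coarse, thr) == \
            pytest.approx(time_above_threshold(fine, thr), rel=0.01)

    def test_bad_grid_rejected(self, default_params, lamellar_depot):
        with pytest.raises(ValueError):
            simulate_crystal_depot(lamellar_depot, default_params,
                                   np.array([1.0, 2.0]))


class TestZinc:
    def test_limits(self):
        model = ZincSolubilityModel(Cs0=0.08, K_zn=100.0)
        assert zinc_adjusted_solubility(model, 0.0) == 0.08
        assert zinc_adjusted_solubility(model, 100.0) == pytest.approx(0.04)
        with pytest.raises(ValueError):
            zinc_adjusted_solubility(model, -1.0)

    def test_strictly_decreasing(self):
        model = ZincSolubilityModel(Cs0=0.08, K_zn=100.0)
        vals = [zinc_adjusted_solubility(model, z) for z in np.linspace(0, 400, 50)]
        assert np.all(np.diff(vals) < 0)

    def test_dissolution_time_increases_along_zinc_gradient(
            self, default_params, lamellar_depot):
        """Complete-dissolution time is strictly increasing over the assay's
        zinc grid under the hyperbolic solubility model."""
        model = ZincSolubilityModel(Cs0=0.08, K_zn=100.0)
        times = [complete_dissolution_time(lamellar_depot, default_params,
                                           zinc_mM=zn, zinc_model=model,
                                           sink=True, t_max=1e5).time
                 for zn in (20, 60, 100, 150, 200, 250, 300)]
        assert np.all(np.diff(times) > 0)


class TestCompleteDissolution:
    def test_lamellar_sink_linear_in_mass(self, default_params):
        """Constant-thickness sink dissolution: doubling M0 at fixed A0 doubles
        the completion time."""
        t1 = complete_dissolution_time(CrystalDepot(M0=5.0, A0=2.0),
                                       default_params, sink=True, t_max=1e5)
        t2 = complete_dissolution_time(CrystalDepot(M0=10.0, A0=2.0),
                                       default_params, sink=True, t_max=1e5)
        assert not t1.censored and not t2.censored
        assert t2.time == pytest.approx(2 * t1.time, rel=1e-6)

    def test_halving_solubility_slows_dissolution(self, lamellar_depot, default_params):
        lo = PKParameters(k=default_params.k, h=default_params.h,
                          V=default_params.V, Cs=default_params.Cs / 2)
        t_hi = complete_dissolution_time(lamellar_depot, default_params,
                                         sink=True, t_max=1e5).time
        t_lo = complete_dissolution_time(lamellar_depot, lo, sink=True,
                                         t_max=1e5).time
        assert t_lo > t_hi

    def test_lamellar_tail_slower_than_isometric(self, default_params):
        """At equal M0, A0 the lamellar depot (area ∝ M, exponential tail) takes
        longer to finish than the isometric one (area ∝ M^(2/3), finite-time)."""
        iso = complete_dissolution_time(
            CrystalDepot(M0=5.0, A0=2.0, geometry_mode="isometric"),
            default_params, sink=True, t_max=1e5)
        lam = complete_dissolution_time(
            CrystalDepot(M0=5.0, A0=2.0, geometry_mode="lamellar"),
            default_params, sink=True, t_max=1e5)
        assert lam.time > iso.time

    def test_censoring(self, lamellar_depot, default_params):
        res = complete_dissolution_time(lamellar_depot, default_params,
                                        sink=True, t_max=10.0)
        assert res.censored and res.time == 10.0

    def test_requires_positive_solubility(self, lamellar_depot):
        params = PKParameters(k=0.073, h=0.5, V=4.5, Cs=0.0)
        with pytest.raises(ValueError):
            complete_dissolution_time(lamellar_depot, params)


class TestParameterRecovery:
    def test_noiseless_recovery_within_1pct(self, default_params, lamellar_depot):
        t = np.linspace(0, 120, 121)
        obs = simulate_crystal_depot(lamellar_depot, default_params, t).Ct
        Cs_hat, h_hat = fit_dissolution_params(t, obs, lamellar_depot,
                                               default_params.k, default_params.V,
                                               Cs0=0.05, h0=0.9)
        assert Cs_hat == pytest.approx(default_params.Cs, rel=0.01)
        assert h_hat == pytest.approx(default_params.h, rel=0.01)

    def test_noisy_recovery_within_10pct(self, default_params, lamellar_depot):
        t = np.linspace(0, 120, 121)
        clean = simulate_crystal_depot(lamellar_depot, default_params, t).Ct
        rng = np.random.default_rng(7)
        noisy = clean * (1.0 + 0.05 * rng.standard_normal(clean.shape))
        Cs_hat, h_hat = fit_dissolution_params(t, noisy, lamellar_depot,
                                               default_params.k, default_params.V,
                                               Cs0=0.05, h0=0.9)
        assert Cs_hat == pytest.approx(default_params.Cs, rel=0.10)
        assert h_hat == pytest.approx(default_params.h, rel=0.10)


class TestScenarioIO:
    def test_default_scenario_runs(self):
        cfg = pk.load_scenario(None)
        profile, summary = pk.run_scenario(cfg)
        assert summary["mass_balance_residual"] < 1e-6
        assert summary["peak_Ct"] > cfg["pk"]["threshold"]

    def test_yaml_override(self, tmp_path):
        path = tmp_path / "scenario.yaml"
        path.write_text("pk:\n  t_half_days: 8.0\nt_end_days: 30\nn_points: 61\n")
        cfg = pk.load_scenario(str(path))
        assert cfg["pk"]["t_half_days"] == 8.0
        assert cfg["t_end_days"] == 30
        assert cfg["pk"]["h"] == pk.DEFAULT_SCENARIO["pk"]["h"]
        profile, _ = pk.run_scenario(cfg)
        assert len(profile.t) == 61
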