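"""DynG calibration, conductance retrieval chain, and pipeline."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from dyng import (
    DynGFit,
    EnvironmentState,
    LeafSample,
    PipelineOptions,
    SurfaceProperties,
    estimate_pipeline,
    fit_dyng,
    gsw_from_gtw,
    gsw_full_energy_balance,
    gsw_ig_only,
    gsw_sr1,
    gtw_from_ig,
    scenario_environment,
    sensitivity_analysis,
    simulate_reference_set,
    solve_surface_temperature,
    transpiration,
    moist_air_state,
    saturation_vapor_pressure,
)
from dyng.scenarios import wind_step_scenario
from dyng.ebalance import AL_SURFACE


def make_fit(slope):
    return DynGFit(slope=slope, intercept=0.0, r2=1.0, n_points=3)


class TestFitDyng:
    def test_exact_line_through_origin(self):
        g = np.array([0.1, 0.2, 0.3])
        fit = fit_dyng(np.c_[g, 2.0 * g])
        assert fit.slope == pytest.approx(2.0)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.n_points == 3

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(100):
            x = rng.uniform(0.05, 0.5, size=rng.integers(3, 8))
            y = 3.0 * x + rng.normal(0, 0.1, size=x.size)
            fit = fit_dyng(np.c_[x, y])
            oracle = np.linalg.lstsq(x[:, None], y, rcond=None)[0][0]
            assert abs(fit.slope - oracle) < 1e-10
            fit_i = fit_dyng(np.c_[x, y], through_origin=False)
            A = np.c_[x, np.ones_like(x)]
            sl, ic = np.linalg.lstsq(A, y, rcond=None)[0]
            assert abs(fit_i.slope - sl) < 1e-10
            assert abs(fit_i.intercept - ic) < 1e-10

    def test_flagged_point_dropped_with_warning(self):
        pts = [(0.1, 0.3), (0.2, 0.6), (0.3, np.nan)]
        with pytest.warns(UserWarning, match="three"):
            fit = fit_dyng(pts)
        assert fit.n_points == 2 and fit.valid

    def test_all_points_invalid_flags_fit(self):
        fit = fit_dyng([(0.1, 0.3), (0.2, 0.6)], valid=[False, False])
        assert not fit.valid and np.isnan(fit.slope)


class TestRetrievalChain:
    def test_gtw_boundary_layer_limit(self):
        fit = make_fit(3.0)
        assert gtw_from_ig(1e12, fit, 0.5) == pytest.approx(0.5, rel=1e-6)

    def test_gtw_series_resistor_oracle(self):
        # Ig = DynG * g_surf reads back the surface conductance; adding the
        # boundary layer in series gives the two-resistor total.
        fit = make_fit(2.5)
        g_surf, g_bw = 0.2, 0.6
        expected = 1.0 / (1.0 / g_surf + 1.0 / g_bw)
        assert gtw_from_ig(fit.slope * g_surf, fit, g_bw) == pytest.approx(
            expected, rel=1e-12)

    def test_gtw_zero_index_returns_zero(self):
        assert gtw_from_ig(0.0, make_fit(3.0), 0.5) == 0.0

    def test_gsw_sr0_is_single_face_series_inversion(self):
        g_tw, g_bw = 0.2, 0.6
        expected = 1.0 / (1.0 / g_tw - 1.0 / g_bw)
        assert gsw_from_gtw(g_tw, g_bw, SR=0.0) == pytest.approx(
            expected, rel=1e-12)

    def test_gsw_inverts_two_face_forward_partition(self, rng):
        """Eqn-style inversion recovers the g_sw that generated g_tw when
        the flux is partitioned across faces by SR."""
        for _ in range(200):
            g_sw = rng.uniform(0.02, 1.0)
            g_bw = rng.uniform(0.2, 2.0)
            sr = rng.uniform(0.0, 3.0)
            top, bot = g_sw * sr / (sr + 1), g_sw / (sr + 1)
            g_tw = sum(g * g_bw / (g + g_bw) for g in (top, bot) if g > 0)
            if g_tw >= g_bw:   # outside the retrieval's precondition
                continue
            assert gsw_from_gtw(g_tw, g_bw, SR=sr) == pytest.approx(
                g_sw, rel=1e-9)

    def test_sr1_reduction_identity(self, rng):
        """Two-step retrieval at SR=1 equals the closed form, everywhere."""
        ig = rng.uniform(0.05, 3.0, 1000)
        dyng = rng.uniform(0.5, 6.0, 1000)
        g_bw = rng.uniform(0.1, 2.0, 1000)
        for i in range(1000):
            fit = make_fit(dyng[i])
            a = gsw_from_gtw(gtw_from_ig(ig[i], fit, g_bw[i]), g_bw[i], SR=1.0)
            b = gsw_sr1(ig[i], fit, g_bw[i])
            assert abs(a / b - 1.0) < 1e-10

    def test_sr1_algebraic_limits(self):
        fit = make_fit(3.0)
        assert gsw_sr1(0.0, fit, 0.5) == 0.0
        assert gsw_sr1(1e15, fit, 0.5) == pytest.approx(1.0, rel=1e-9)

    def test_gsw_never_exceeds_twice_gbw(self, rng):
        ig = rng.uniform(0.01, 50.0, 500)
        fit = make_fit(2.0)
        g = gsw_sr1(ig, fit, 0.4)
        assert np.all(g < 0.8)

    def test_sr_sweep_has_small_effect_at_paper_scale(self):
        fit = make_fit(3.0)
        g_tw = gtw_from_ig(1.0, fit, 0.5)
        vals = [gsw_from_gtw(g_tw, 0.5, SR=s) for s in
                np.linspace(0.5, 1.5, 11)]
        assert (max(vals) - min(vals)) / np.median(vals) < 0.10

    def test_total_above_boundary_layer_rejected(self):
        with pytest.raises(ValueError, match="boundary-layer"):
            gsw_from_gtw(0.7, 0.5, SR=1.0)

    def test_ceiling_mode_preserves_series(self):
        assert gsw_from_gtw(0.7, 0.5, SR=1.0, clip_ceiling=True) == 1.0


class TestIgOnlyBaseline:
    def test_identity(self):
        assert gsw_ig_only(0.0) == 0.0
        assert gsw_ig_only(1.37) == 1.37

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            gsw_ig_only(-0.1)


class TestFullEnergyBalanceInversion:
    SURF = SurfaceProperties(alpha_sw=0.96, eps_top=0.97, eps_bottom=0.97)

    @pytest.mark.parametrize("g_sw", [0.05, 0.2, 0.5])
    def test_round_trip(self, g_sw):
        env = EnvironmentState(time=0, T_air=293.15, RH_air=0.4, wind=0.4,
                               PPFD=300.0)
        leaf = LeafSample(id="l", role="real", surface=self.SURF,
                          g_sw_true=g_sw, SR=1.0)
        T = solve_surface_temperature(leaf, env, 0.5)
        assert gsw_full_energy_balance(T, env, 0.5, self.SURF) == (
            pytest.approx(g_sw, rel=0.005))

    def test_dry_leaf_limit(self):
        env = EnvironmentState(time=0, T_air=293.15, RH_air=0.4, wind=0.4,
                               PPFD=300.0)
        dry = LeafSample(id="d", role="dry", surface=self.SURF)
        T = solve_surface_temperature(dry, env, 0.5)
        assert gsw_full_energy_balance(T, env, 0.5, self.SURF) < 1e-3

    def test_impossibly_cold_leaf_rejected(self):
        env = EnvironmentState(time=0, T_air=293.15, RH_air=0.4, wind=0.4,
                               PPFD=0.0)
        with pytest.raises(ValueError, match="colder"):
            gsw_full_energy_balance(273.15, env, 0.5, self.SURF)

    def test_deterministic(self):
        env = EnvironmentState(time=0, T_air=293.15, RH_air=0.4, wind=0.4,
                               PPFD=300.0)
        a = gsw_full_energy_balance(292.0, env, 0.5, self.SURF)
        b = gsw_full_energy_balance(292.0, env, 0.5, self.SURF)
        assert a == b


class TestTranspiration:
    def test_closed_stomata(self, env20):
        assert transpiration(0.0, 0.5, 292.0, env20) == 0.0

    def test_infinite_boundary_layer_limit(self, env20):
        air = moist_air_state(env20)
        g_sw, T_leaf = 0.3, 292.0
        expected = 0.018 * g_sw * (saturation_vapor_pressure(T_leaf)
                                   - air.e_a) / env20.P_atm
        assert transpiration(g_sw, 1e9, T_leaf, env20) == pytest.approx(
            expected, rel=1e-6)

    def test_hand_series_case(self, env20):
        air = moist_air_state(env20)
        g_tot = 0.3 * 0.6 / 0.9
        expected = 0.018 * g_tot * (saturation_vapor_pressure(292.0)
                                    - air.e_a) / env20.P_atm
        assert transpiration(0.3, 0.6, 292.0, env20) == pytest.approx(expected)

    def test_condensing_returns_zero(self):
        env = EnvironmentState(time=0, T_air=293.15, RH_air=1.0, wind=0.4)
        assert transpiration(0.3, 0.6, 290.0, env) == 0.0


class TestSensitivity:
    @given(ig=st.floats(0.2, 3.0), dyng=st.floats(0.5, 6.0),
           gbw=st.floats(0.1, 2.0))
    def test_gbw_perturbation_bounds(self, ig, dyng, gbw):
        tab = sensitivity_analysis(ig, dyng, gbw)
        up = tab[(tab.parameter == "g_bw") & (tab.perturbation == 0.5)]
        down = tab[(tab.parameter == "g_bw") & (tab.perturbation == -0.5)]
        assert 0 < float(up.rel_change.iloc[0]) < 0.5
        assert abs(float(down.rel_change.iloc[0])) > float(up.rel_change.iloc[0])

    def test_sr_sweep_weaker_than_gbw_sweep(self):
        tab = sensitivity_analysis(1.0, 3.0, 0.5)
        sr_max = tab[tab.parameter == "SR"].rel_change.abs().max()
        gbw_max = tab[tab.parameter == "g_bw"].rel_change.abs().max()
        assert sr_max < gbw_max


class TestPipeline:
    def run(self, samples, steps, targets, seed=0, dt=5.0,
            methods=("dyng",)):
        series = simulate_reference_set(samples, steps, sampling_dt=dt,
                                        seed=seed)
        env = scenario_environment(steps, dt)
        return estimate_pipeline(
            series, env, samples,
            PipelineOptions(methods=methods, target_ids=targets))

    def test_noise_free_recovery_within_two_percent(self, al_samples):
        res = self.run(al_samples, wind_step_scenario(60.0, noise_sd=0.0), ("target",))
        steady = res[res.time_s % 60 > 40]
        assert np.all(np.abs(steady.g_sw / 0.31 - 1.0) < 0.02)

    def test_ig_only_unstable_across_wind_steps(self, al_samples):
        res = self.run(al_samples, wind_step_scenario(60.0, noise_sd=0.0), ("target",),
                       methods=("dyng", "ig_only"))
        ig = res[(res.method == "ig_only") & (res.time_s % 60 > 40)]
        means = ig.groupby(ig.time_s // 60)["g_sw"].mean().to_numpy()
        assert (means.max() - means.min()) / means.min() > 0.20
        assert np.all(np.diff(means) < 0)

    def test_real_leaf_sr1_recovery(self, al_samples):
        leaf = LeafSample(id="leaf", role="real",
                          surface=SurfaceProperties(0.96, 0.97, 0.97),
                          g_sw_true=0.25, SR=1.0)
        res = self.run(al_samples + [leaf],
                       wind_step_scenario(60.0, noise_sd=0.0), ("leaf",))
        steady = res[res.time_s % 60 > 40]
        assert np.all(np.abs(steady.g_sw / 0.25 - 1.0) < 0.02)

    def test_reference_permutation_invariance(self, al_samples):
        res_a = self.run(al_samples, wind_step_scenario(60.0, noise_sd=0.0),
                         ("target",))
        shuffled = [al_samples[i] for i in (5, 2, 0, 4, 1, 3)]
        res_b = self.run(shuffled, wind_step_scenario(60.0, noise_sd=0.0),
                         ("target",))
        np.testing.assert_allclose(res_a.g_sw.to_numpy(),
                                   res_b.g_sw.to_numpy(), rtol=1e-12)

    def test_empty_series_rejected(self, al_samples):
        from dyng import TemperatureSeries
        series = TemperatureSeries(times=np.array([]), object_ids=[],
                                   temperatures=np.empty((0, 0)))
        with pytest.raises(ValueError, match="empty"):
            estimate_pipeline(series, [], al_samples, PipelineOptions())

    def test_missing_roles_listed(self, al_samples):
        steps = wind_step_scenario(30.0)
        series = simulate_reference_set(al_samples, steps, sampling_dt=5.0)
        env = scenario_environment(steps, 5.0)
        with pytest.raises(ValueError, match="porous references"):
            estimate_pipeline(series, env, al_samples,
                              PipelineOptions(target_ids=("target", "low")))
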