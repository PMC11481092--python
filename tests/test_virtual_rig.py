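"""Virtual-rig kinetics: limits, oracles, conservation and calibration."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from flowopt import virtual_rig as vr
from flowopt.virtual_rig import (CatalystState, DeactivationSchedule,
                                 KineticParams, Measurement, NoiseModel,
                                 StreamComposition, advance_catalyst,
                                 measure, simulate_step1, simulate_step2,
                                 simulate_telescoped)

FRESH = CatalystState()


def _cond1(T1=120.0, Q1=0.5, C1=0.05):
    return {"T1": T1, "Q1": Q1, "C1": C1}


class TestStep1:
    def test_vanishing_residence_time_passes_feed_through(self, paper_params,
                                                          osat_preset):
        out = simulate_step1(_cond1(Q1=1e9), FRESH, paper_params, osat_preset)
        assert out.c_aminophenol == pytest.approx(0.0, abs=1e-9)
        assert out.c_nitrophenol == pytest.approx(0.05)

    def test_dead_catalyst_gives_zero_conversion(self, paper_params,
                                                 osat_preset):
        dead = CatalystState(activity=0.0)
        out = simulate_step1(_cond1(), dead, paper_params, osat_preset)
        assert out.c_aminophenol == 0.0

    def test_nonpositive_flow_rejected(self, paper_params, osat_preset):
        with pytest.raises(vr.RigError, match="Q1"):
            simulate_step1(_cond1(Q1=0.0), FRESH, paper_params, osat_preset)

    def test_calibrated_grid_max_is_65pct_at_corner(self, paper_params,
                                                    osat_preset, step1_space):
        y, conds = vr.step1_yield_grid(paper_params, osat_preset,
                                       step1_space, n=41)
        assert y.max() == pytest.approx(0.65, abs=0.005)
        best = step1_space.as_dict(conds[int(np.argmax(y))])
        assert best["Q1"] == pytest.approx(step1_space.lower[1])
        assert best["T1"] == pytest.approx(step1_space.upper[0])

    def test_yield_monotone_in_each_variable(self, paper_params, osat_preset,
                                             step1_space):
        # nondecreasing in T1 and tau1 (i.e. 1/Q1), nonincreasing in C1
        y, _ = vr.step1_yield_grid(paper_params, osat_preset, step1_space,
                                   n=21)
        g = y.reshape(21, 21, 21)  # axes T1, Q1, C1
        assert np.all(np.diff(g, axis=0) >= -1e-12)
        assert np.all(np.diff(g, axis=1) <= 1e-12)
        assert np.all(np.diff(g, axis=2) <= 1e-12)


class TestStep2:
    def test_no_acylating_agent_means_no_product(self, paper_params,
                                                 osat_preset):
        feed = vr.pure_aminophenol_feed(0.02, paper_params)
        out = simulate_step2(feed, {"T2": 90.0, "tau2": 5.0, "equiv": 0.0},
                             paper_params, osat_preset)
        assert out.c_acetaminophen == 0.0
        assert out.c_aminophenol == pytest.approx(0.02)

    def test_zero_residence_time_is_identity(self, paper_params, osat_preset):
        feed = vr.pure_aminophenol_feed(0.02, paper_params)
        out = simulate_step2(feed, {"T2": 90.0, "tau2": 0.0, "equiv": 2.0},
                             paper_params, osat_preset)
        assert out.c_aminophenol == pytest.approx(0.02)
        assert out.c_acetaminophen == 0.0

    def test_negative_feed_rejected(self, paper_params, osat_preset):
        with pytest.raises(vr.RigError):
            StreamComposition(c_aminophenol=-0.01)

    def test_matches_second_order_closed_form(self, paper_params,
                                              osat_preset):
        # with hydrolysis and double acylation off, A + B -> C is classic
        # second-order kinetics with unequal initial concentrations
        rng = np.random.default_rng(42)
        p = vr.KineticParams(A1=1.0, Ea1=50e3, K_inh=0.0, A2=2e6, Ea2=30e3,
                             k_h=0.0, Ea_h=0.0, k_da=0.0, C_w0=0.0)
        for _ in range(20):
            a0, b0 = rng.uniform(0.01, 0.1, size=2)
            if abs(a0 - b0) < 1e-3:
                b0 += 5e-3
            T2 = rng.uniform(30.0, 100.0)
            tau = rng.uniform(0.5, 10.0)
            k2 = float(vr.amidation_rate_constant(T2, p))
            feed = StreamComposition(c_aminophenol=a0, liquid_flow=0.5)
            out = simulate_step2(feed, {"T2": T2, "tau2": tau,
                                        "equiv": b0 / a0}, p, osat_preset)
            expo = np.exp((b0 - a0) * k2 * tau)
            a_t = a0 * (b0 - a0) / (b0 * expo - a0)
            assert out.c_aminophenol == pytest.approx(a_t, abs=1e-6)

    def test_yield_monotone_in_equivalents(self, paper_params, osat_preset,
                                           step2_space, im_feed):
        y, _ = vr.step2_yield_grid(paper_params, osat_preset, step2_space,
                                   im_feed, n=13)
        g = y.reshape(13, 13, 13)  # axes T2, tau2, equiv
        assert np.all(np.diff(g, axis=2) >= -1e-10)

    def test_double_acylation_byproduct_stays_below_half_percent(
            self, paper_params, osat_preset, im_feed):
        out = simulate_step2(im_feed, {"T2": 100.0, "tau2": 5.0, "equiv": 3.0},
                             paper_params, osat_preset)
        assert out.c_diacylated / im_feed.c_aminophenol < 0.005

    def test_adaptive_integrator_vs_fine_fixed_step_reference(
            self, paper_params, osat_preset):
        rng = np.random.default_rng(7)
        for _ in range(10):
            feed = StreamComposition(
                c_aminophenol=rng.uniform(0.005, 0.05),
                c_water=rng.uniform(0.0, 0.1), liquid_flow=0.5)
            cond = {"T2": rng.uniform(30, 100), "tau2": rng.uniform(0.5, 10),
                    "equiv": rng.uniform(1, 3)}
            out = simulate_step2(feed, cond, paper_params, osat_preset)
            y0 = np.array([[feed.c_aminophenol,
                            cond["equiv"] * feed.c_aminophenol, 0.0, 0.0,
                            feed.c_water, 0.0]])
            k2 = np.atleast_1d(vr.amidation_rate_constant(cond["T2"],
                                                          paper_params))
            kh = np.atleast_1d(vr.hydrolysis_rate_constant(cond["T2"],
                                                           paper_params))
            ref = vr._rk4_batch(y0, k2, kh, paper_params.k_da,
                                np.array([cond["tau2"]]), n_steps=9000)[0]
            got = [out.c_aminophenol, out.c_anhydride, out.c_acetaminophen,
                   out.c_diacylated, out.c_water, out.c_acetic_acid]
            np.testing.assert_allclose(got, ref, atol=1e-5)


class TestTelescoped:
    def test_starved_anhydride_limit(self, paper_params, tel_preset):
        cond = {"T1": 150.0, "T2": 100.0, "Q1": 0.1, "ratio": 1e6}
        out1, out2 = simulate_telescoped(cond, FRESH, paper_params,
                                         tel_preset)
        y = vr.overall_yield(out2, tel_preset, cond["Q1"])
        assert y < 0.01
        # step 1 still converts normally
        assert out1.c_aminophenol > 0.9 * tel_preset.stock_conc_1

    def test_phenolic_core_conserved_across_both_steps(self, paper_params,
                                                       tel_preset, tel_space):
        rng = np.random.default_rng(11)
        U = rng.uniform(size=(100, 4))
        for u in U:
            cond = tel_space.as_dict(tel_space.from_unit(u))
            out1, out2 = simulate_telescoped(cond, FRESH, paper_params,
                                             tel_preset)
            c1 = tel_preset.stock_conc_1
            assert out1.c_nitrophenol + out1.c_aminophenol == pytest.approx(
                c1, rel=1e-6)
            f1 = out1.liquid_flow / out2.liquid_flow
            assert out2.phenolic_total == pytest.approx(c1 * f1, rel=1e-6)

    def test_concentrations_nonnegative_on_random_draws(self, paper_params,
                                                        tel_preset):
        # batch path: 10,000 random in-bounds step-2 systems stay >= 0
        rng = np.random.default_rng(3)
        N = 10_000
        y0 = np.zeros((N, 6))
        y0[:, 0] = rng.uniform(0.0, 0.05, N)
        y0[:, 1] = rng.uniform(0.0, 0.15, N)
        y0[:, 4] = rng.uniform(0.0, 0.1, N)
        T2 = rng.uniform(30, 100, N)
        tau = rng.uniform(0.0, 14.0, N)
        yT = vr._rk4_batch(y0, vr.amidation_rate_constant(T2, paper_params),
                           vr.hydrolysis_rate_constant(T2, paper_params),
                           paper_params.k_da, tau, n_steps=900)
        assert yT.min() >= 0.0
        # reference path: the raw adaptive integrator never goes negative
        for i in range(20):
            sol = solve_ivp(vr._rhs, (0, tau[i]), y0[i],
                            args=(float(vr.amidation_rate_constant(
                                T2[i], paper_params)),
                                float(vr.hydrolysis_rate_constant(
                                    T2[i], paper_params)),
                                paper_params.k_da),
                            method="LSODA", rtol=1e-7, atol=1e-9)
            assert sol.y.min() > -1e-8

    def test_calibrated_grid_max_is_85pct(self, paper_params, tel_preset,
                                          tel_space):
        y, _ = vr.telescoped_yield_grid(paper_params, tel_preset, tel_space,
                                        n=15)
        assert y.max() == pytest.approx(0.85, abs=0.005)


class TestMeasurement:
    def test_noiseless_identity(self):
        rng = np.random.default_rng(0)
        m = measure((0.4, 0.8), NoiseModel(sigma_abs=0.0, p_fault=0.0), rng)
        assert (m.yield_step1, m.yield_step2) == (0.4, 0.8)
        assert not m.blank_flag

    def test_always_faulty_separator_gives_blanks(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            m = measure((0.5, 0.9), NoiseModel(sigma_abs=0.0, p_fault=1.0),
                        rng)
            assert m.blank_flag and m.yield_step2 <= 0.02

    def test_noise_law_monte_carlo(self):
        rng = np.random.default_rng(123)
        noise = NoiseModel(sigma_abs=0.01, p_fault=0.0)
        ys = [measure((None, 0.5), noise, rng).yield_step2
              for _ in range(10_000)]
        assert 0.009 <= np.std(ys) <= 0.011


class TestCatalyst:
    def test_zero_elapsed_no_events_is_identity(self):
        s = CatalystState(activity=0.8, time_on_stream=5.0)
        assert advance_catalyst(s, 0.0) == s

    def test_standard_campaign_loses_under_five_percent(self):
        s = CatalystState()
        sched = DeactivationSchedule()
        # 14 standard experiments at the default 2 h each
        for _ in range(14):
            s = advance_catalyst(s, sched.experiment_duration_h, sched)
        assert 1.0 - s.activity < 0.05

    def test_shutdown_recovers_five_percent_relative(self):
        s = CatalystState(activity=0.90)
        sched = DeactivationSchedule(k_slow=0.0)
        out = advance_catalyst(s, 0.0, sched, events=("shutdown",))
        assert out.activity == pytest.approx(0.945)
        assert out.shutdowns == 1

    def test_failure_event_drops_activity(self):
        s = CatalystState(activity=1.0)
        sched = DeactivationSchedule(k_slow=0.0, drop_frac=0.3)
        out = advance_catalyst(s, 0.0, sched, events=("failure",))
        assert out.activity == pytest.approx(0.7)

    def test_recovery_capped_at_full_activity(self):
        s = CatalystState(activity=0.99)
        out = advance_catalyst(s, 0.0, DeactivationSchedule(k_slow=0.0),
                               events=("shutdown",))
        assert out.activity == 1.0


class TestCalibrate:
    def test_trivial_zero_targets_with_dead_kinetics(self, osat_preset,
                                                     tel_preset, step1_space,
                                                     step2_space, tel_space):
        p0 = KineticParams(A1=0.0, Ea1=50e3, K_inh=0.0, A2=0.0, Ea2=30e3,
                           k_h=0.0, Ea_h=0.0, k_da=0.0, C_w0=0.0)
        res = vr.calibrate(p0, osat_preset, tel_preset,
                           {"step1": 0.0, "step2_im": 0.0, "telescoped": 0.0},
                           step1_space, step2_space, tel_space,
                           n_grid=5, n_grid_tel=5)
        assert res.params == p0
        assert all(abs(r) <= 0.005 for r in res.residuals.values())

    def test_recovers_targets_from_perturbed_start(self, paper_params,
                                                   osat_preset, tel_preset,
                                                   step1_space, step2_space,
                                                   tel_space):
        from dataclasses import replace
        p0 = replace(paper_params, A1=paper_params.A1 * 3.0,
                     A2=paper_params.A2 * 0.3)
        res = vr.calibrate(p0, osat_preset, tel_preset,
                           {"step1": 0.65, "step2_im": 0.97},
                           step1_space, step2_space, tel_space, n_grid=15)
        assert res.achieved["step1"] == pytest.approx(0.65, abs=0.005)
        assert res.achieved["step2_im"] == pytest.approx(0.97, abs=0.005)

    def test_infeasible_target_reports_residuals(self, paper_params,
                                                 osat_preset, tel_preset,
                                                 step1_space, step2_space,
                                                 tel_space):
        with pytest.raises(vr.CalibrationError) as err:
            vr.calibrate(paper_params, osat_preset, tel_preset,
                         {"step1": 2.0}, step1_space, step2_space, tel_space,
                         n_grid=9)
        assert err.value.residuals

    def test_pure_reservoir_optimum_at_high_equivalents(self, paper_params,
                                                        osat_preset,
                                                        step2_space):
        feed = vr.pure_aminophenol_feed(0.01625, paper_params)
        y, conds = vr.step2_yield_grid(paper_params, osat_preset,
                                      step2_space, feed, n=21)
        assert y.max() >= 0.965
        best = step2_space.as_dict(conds[int(np.argmax(y))])
        assert best["equiv"] > 2.0
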