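"""Augmented plant assembly and LQG synthesis."""

import numpy as np
import pytest
from scipy import linalg

import visuotrack as vt
from visuotrack.plant import STATE_LABELS, closed_loop, stationary_output_variance
from visuotrack.statespace import SynthesisError


class TestSubsystemFilters:
    def test_perturbation_filter_corner_and_dc(self, constants):
        F = vt.build_perturbation_filter(constants)
        wc = 2 * np.pi * constants.pert_cutoff
        dc = vt.frequency_response(F, [1e-6]).siso()[0]
        corner = vt.frequency_response(F, [wc]).siso()[0]
        assert abs(abs(dc) - 1.0) < 1e-6
        assert abs(abs(corner) - 1.0 / np.sqrt(2)) < 1e-9

    def test_perturbation_filter_stationary_variance(self, constants):
        # white noise of intensity q through the filter: var = q * wc / 2
        F = vt.build_perturbation_filter(constants)
        q = 0.37
        wc = 2 * np.pi * constants.pert_cutoff
        # intensity q enters the state equation as B q B'
        P = vt.solve_lyapunov(F.A, q * F.B @ F.B.T)
        var = (F.C @ P @ F.C.T)[0, 0]
        assert abs(var - q * wc / 2.0) < 1e-9 * max(1.0, var)

    def test_noise_filter_critical_damping(self):
        N = vt.build_noise_filter(8.9)
        poles = np.sort(N.poles().real)
        assert np.allclose(N.poles().imag, 0.0, atol=1e-9)
        assert np.allclose(poles, [-8.9, -8.9], atol=1e-6)

    def test_noise_filter_half_gain_at_corner(self):
        # double real pole: |H(a)| = 1/(1+1) = 1/2 of DC gain
        N = vt.build_noise_filter(5.0)
        h = vt.frequency_response(N, [5.0]).siso()[0]
        assert abs(abs(h) - 0.5) < 1e-9

    def test_noise_filter_step_has_no_overshoot(self):
        N = vt.build_noise_filter(3.0)
        d = vt.discretize_zoh(N, 0.001)
        y = vt.simulate(d, np.ones((8000, 1)))[:, 0]
        assert y.max() <= 1.0 + 1e-9
        assert np.all(np.diff(y) >= -1e-12)

    def test_diff_filter_gain(self):
        D = vt.build_diff_filter(100.0)
        h1 = vt.frequency_response(D, [1.0]).siso()[0]
        assert abs(abs(h1) - 1.0) / 1.0 < 0.01          # gain ~ omega below corner
        hdc = vt.frequency_response(D, [1e-8]).siso()[0]
        assert abs(hdc) < 1e-6                            # kills constants
        ha = vt.frequency_response(D, [100.0]).siso()[0]
        assert abs(abs(ha) - 100.0 / np.sqrt(2)) < 1e-6

    def test_invalid_corners_raise(self):
        with pytest.raises(ValueError):
            vt.build_noise_filter(0.0)
        with pytest.raises(ValueError):
            vt.build_diff_filter(-1.0)


class TestAssemblePlant:
    def test_nine_states_with_expected_layout(self, constants, young_mean_params):
        plant = vt.assemble_plant(constants, young_mean_params)
        assert plant.sys.n_states == 9
        assert plant.sys.state_labels == STATE_LABELS
        assert [l for l in STATE_LABELS if l.startswith("delay")] == [
            "delay1", "delay2", "delay3", "delay4"
        ]

    def test_error_integrates_filtered_perturbation(self, constants,
                                                    young_mean_params):
        """With no control and no noise, e is the running integral of the
        filtered perturbation (numerical quadrature oracle)."""
        plant = vt.assemble_plant(constants, young_mean_params)
        dt = 0.001
        dsys = vt.discretize_zoh(plant.sys, dt)
        rng = np.random.default_rng(1)
        n = 3000
        U = np.zeros((n, 3))
        U[:, 1] = rng.standard_normal(n)  # white w only
        Y = vt.simulate(dsys, U)
        e = Y[:, 2]  # z_e output = e
        # exact quadrature oracle: between samples the filter state is
        # x(s) = exp(-wc s) x_k + (1 - exp(-wc s)) w_k, whose step integral
        # has a closed form; e accumulates those integrals
        wc = 2 * np.pi * constants.pert_cutoff
        a = np.exp(-wc * dt)
        g = (1.0 - a) / wc
        x = 0.0
        e_quad = np.empty(n)
        acc = 0.0
        for k in range(n):
            e_quad[k] = acc
            w = U[k, 1]
            acc += x * g + w * (dt - g)
            x = a * x + (1.0 - a) * w
        assert np.max(np.abs(e - e_quad)) < 1e-8

    def test_vanishing_delay_measurement_tracks_error(self, constants,
                                                      young_mean_params):
        plant = vt.assemble_plant(
            constants, young_mean_params.replace(latency_tau=1e-4)
        )
        dsys = vt.discretize_zoh(plant.sys, 0.001)
        U = np.zeros((2000, 3))
        U[:, 0] = 1.0  # ramp e via constant u_ideal
        Y = vt.simulate(dsys, U)
        # y (output 0) lags e (output 2) by at most ~tau on a unit-slope ramp
        assert np.max(np.abs(Y[200:, 0] - Y[200:, 2])) < 1e-3


class TestDesignLqg:
    def test_controller_dimensions(self, young_controller):
        plant, ctrl = young_controller
        assert ctrl.sys.n_states == 9
        assert ctrl.kalman_gain.shape == (9, 1)
        assert ctrl.lqr_gain.shape == (1, 9)

    def test_separation_principle(self, constants, young_controller):
        """Closed-loop eigenvalues = LQR eigenvalues union estimator
        eigenvalues -- the defining LQG structure."""
        plant, ctrl = young_controller
        A = plant.sys.A
        Bu = plant.sys.B[:, [0]]
        Cy = plant.sys.C[[0], :]
        eig_lqr = linalg.eigvals(A - Bu @ ctrl.lqr_gain)
        eig_est = linalg.eigvals(A - ctrl.kalman_gain @ Cy)
        cl = closed_loop(plant, ctrl)
        eig_cl = np.sort_complex(linalg.eigvals(cl.sys.A))
        both = np.sort_complex(np.concatenate([eig_lqr, eig_est]))
        assert np.max(np.abs(eig_cl - both) / (1.0 + np.abs(both))) < 1e-6

    def test_doubling_rho_shrinks_physical_gains(self, constants,
                                                 young_mean_params):
        """Higher effort cost -> smaller LQR gain elements on the physical
        (non-effort-filter) states."""
        gains = []
        for mult in (1.0, 2.0, 4.0):
            p = young_mean_params.replace(rho=young_mean_params.rho * mult)
            ctrl = vt.design_lqg(vt.assemble_plant(constants, p))
            gains.append(np.linalg.norm(ctrl.lqr_gain[0, :8]))
        assert gains[0] > gains[1] > gains[2]

    def test_more_noise_slows_kalman_timescale(self, constants,
                                               young_mean_params):
        def slowest(p):
            plant = vt.assemble_plant(constants, p)
            ctrl = vt.design_lqg(plant)
            ev = linalg.eigvals(
                plant.sys.A - ctrl.kalman_gain @ plant.sys.C[[0], :]
            )
            return np.max(ev.real)

        base = slowest(young_mean_params)
        noisy = slowest(
            young_mean_params.replace(
                noise_intensity=10 * young_mean_params.noise_intensity
            )
        )
        assert noisy > base  # closer to the imaginary axis

    def test_huge_rho_suppresses_control(self, constants, young_mean_params):
        p = young_mean_params.replace(rho=100.0)
        plant = vt.assemble_plant(constants, p)
        ctrl = vt.design_lqg(plant)
        assert abs(ctrl.lqr_gain[0, 0]) < 0.01
        H, _ = vt.predicted_response(plant, ctrl, np.array([1.0, 5.0]))
        assert np.all(np.abs(H.siso()) < 0.2)


class TestPredictedResponse:
    def test_dc_perturbation_rejection(self, young_controller):
        plant, ctrl = young_controller
        H, _ = vt.predicted_response(plant, ctrl, np.array([0.01]))
        h = H.siso()[0]
        assert abs(abs(h) - 1.0) < 0.01
        assert abs(abs(np.degrees(np.angle(h))) - 180.0) < 2.0

    def test_low_pass_subject_response(self, young_controller):
        plant, ctrl = young_controller
        H, _ = vt.predicted_response(plant, ctrl, np.array([1.0, 30.0]))
        mags = np.abs(H.siso())
        assert mags[1] < mags[0]

    def test_zero_noise_spectrum_is_perturbation_only(self, constants,
                                                      young_mean_params):
        p = young_mean_params.replace(noise_intensity=0.0)
        plant = vt.assemble_plant(constants, p)
        ctrl = vt.design_lqg(plant)
        om = np.logspace(-1, 1, 15)
        _, S = vt.predicted_response(plant, ctrl, om)
        cl = closed_loop(plant, ctrl)
        fr = vt.frequency_response(cl.sys, om)
        H_wu = fr.values[:, cl.output_index["u"], cl.input_index["w"]]
        np.testing.assert_allclose(
            S, np.abs(H_wu) ** 2 * constants.pert_white_intensity, rtol=1e-10
        )

    @pytest.mark.parametrize(
        "param", ["noise_intensity", "noise_bandwidth", "rho"]
    )
    def test_increased_noise_slows_response(self, constants,
                                            young_mean_params, param):
        """Raising any noise-related parameter weakly lowers |H_ud| across
        the responsive band (5-20 rad/s): the slowing-without-latency-change
        mechanism.  (Above ~20 rad/s, where |H| < 0.05, a higher noise
        intensity can raise the magnitude by a percent or two.)"""
        om = np.linspace(5.0, 20.0, 12)
        plant = vt.assemble_plant(constants, young_mean_params)
        H0, _ = vt.predicted_response(plant, vt.design_lqg(plant), om)
        p = young_mean_params.replace(
            **{param: getattr(young_mean_params, param) * 4.0}
        )
        plant4 = vt.assemble_plant(constants, p)
        H4, _ = vt.predicted_response(plant4, vt.design_lqg(plant4), om)
        assert np.all(np.abs(H4.siso()) <= np.abs(H0.siso()) * (1 + 1e-9))


class TestImpliedRmsError:
    def test_zero_noise_zero_perturbation(self, constants, young_mean_params):
        p = young_mean_params.replace(noise_intensity=0.0)
        plant = vt.assemble_plant(constants, p)
        ctrl = vt.design_lqg(plant)
        d = np.zeros(3000)
        assert vt.implied_rms_error(plant, ctrl, d, constants) == 0.0

    def test_noise_only_matches_monte_carlo(self, constants,
                                            young_mean_params):
        """Stationary Lyapunov noise contribution vs a 600-s noise-driven
        closed-loop simulation."""
        plant = vt.assemble_plant(constants, young_mean_params)
        ctrl = vt.design_lqg(plant)
        d = np.zeros(1000)
        pred = vt.implied_rms_error(plant, ctrl, d, constants)
        cl = closed_loop(plant, ctrl)
        dsys = vt.discretize_zoh(cl.sys, constants.dt)
        rng = np.random.default_rng(42)
        n = 60000
        U = np.zeros((n, cl.sys.n_inputs))
        U[:, cl.input_index["n_w"]] = rng.standard_normal(n) * np.sqrt(
            young_mean_params.noise_intensity * constants.sample_rate
        )
        e = vt.simulate(dsys, U)[:, cl.output_index["e"]]
        mc = float(np.sqrt(np.mean(e[2000:] ** 2)))
        assert abs(pred - mc) / mc < 0.10

    def test_ratio_near_one_on_synthetic_trial(self, constants,
                                               young_mean_params,
                                               young_trials):
        plant = vt.assemble_plant(constants, young_mean_params)
        ctrl = vt.design_lqg(plant)
        ratios = []
        for tr in young_trials[2:6]:
            pred = vt.implied_rms_error(plant, ctrl, tr.d, constants)
            obs = float(np.sqrt(np.mean(tr.e ** 2)))
            ratios.append(pred / obs)
        assert 0.8 < np.mean(ratios) < 1.25
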