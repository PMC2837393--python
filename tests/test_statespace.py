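"""Linear-systems toolbox: interconnection, delay, Riccati/Lyapunov, HSVs."""

import numpy as np
import pytest
from scipy import linalg

import visuotrack as vt
from visuotrack.statespace import DimensionError, SynthesisError

from conftest import rand_stable_system


def first_order(a, b=1.0, c=1.0):
    return vt.StateSpaceModel([[-a]], [[b]], [[c]], [[0.0]])


def care_hamiltonian_oracle(A, B, Q, R):
    """Stabilizing CARE solution from the stable invariant subspace of the
    Hamiltonian matrix (independent of scipy's solver path)."""
    A, B, Q, R = map(np.atleast_2d, (A, B, Q, R))
    n = A.shape[0]
    H = np.block([[A, -B @ linalg.inv(R) @ B.T], [-Q, -A.T]])
    w, V = linalg.eig(H)
    sel = w.real < 0
    assert sel.sum() == n
    V1 = V[:n, sel]
    V2 = V[n:, sel]
    return np.real(V2 @ linalg.inv(V1))


class TestSeries:
    def test_identity_preserves_response(self):
        S = first_order(1.0, 2.0, 3.0)
        cascade = vt.series(vt.identity_system(1), S)
        om = np.logspace(-1, 1, 20)
        np.testing.assert_allclose(
            vt.frequency_response(cascade, om).siso(),
            vt.frequency_response(S, om).siso(),
            rtol=1e-12,
        )

    def test_product_of_transfer_functions(self):
        s1, s2 = first_order(1.0), first_order(2.0)
        casc = vt.series(s1, s2)
        h = vt.frequency_response(casc, [1.0]).siso()[0]
        expected = (1.0 / (1j + 1.0)) * (1.0 / (1j + 2.0))
        assert abs(h - expected) < 1e-12

    def test_state_dimension_adds(self):
        two = vt.series(first_order(1.0), first_order(1.0))
        assert vt.series(first_order(3.0), two).n_states == 3

    def test_port_mismatch_raises(self):
        wide = vt.StateSpaceModel(
            [[-1.0]], [[1.0, 0.0]], [[1.0]], [[0.0, 0.0]]
        )
        with pytest.raises(DimensionError):
            vt.series(first_order(1.0), wide)  # 1 output into 2 inputs


class TestFeedbackLoop:
    def test_integrator_with_gain_places_pole(self):
        integ = vt.StateSpaceModel([[0.0]], [[1.0]], [[1.0]], [[0.0]])
        gain = vt.StateSpaceModel(
            np.zeros((0, 0)), np.zeros((0, 1)), np.zeros((1, 0)), [[3.0]]
        )
        cl = vt.feedback_loop(integ, gain, sign=-1)
        assert np.allclose(cl.poles(), [-3.0])
        h = vt.frequency_response(cl, [1.0]).siso()[0]
        assert abs(h - 1.0 / (1j + 3.0)) < 1e-12

    def test_zero_controller_is_open_loop(self):
        P = first_order(2.0)
        zero = vt.StateSpaceModel(
            np.zeros((0, 0)), np.zeros((0, 1)), np.zeros((1, 0)), [[0.0]]
        )
        cl = vt.feedback_loop(P, zero)
        om = np.logspace(-1, 1, 10)
        np.testing.assert_allclose(
            vt.frequency_response(cl, om).siso(),
            vt.frequency_response(P, om).siso(),
            rtol=1e-12,
        )

    def test_nine_plus_nine_states(self, young_controller):
        plant, ctrl = young_controller
        cl = vt.closed_loop(plant, ctrl)
        assert cl.sys.n_states == 18

    def test_frequency_response_composition(self):
        """Closed-loop response equals the loop-algebra composition."""
        rng = np.random.default_rng(5)
        P = rand_stable_system(rng, 3)
        C = rand_stable_system(rng, 2)
        cl = vt.feedback_loop(P, C, sign=-1)
        om = np.linspace(0.1, 20.0, 50)
        hp = vt.frequency_response(P, om).siso()
        hc = vt.frequency_response(C, om).siso()
        hcl = vt.frequency_response(cl, om).siso()
        np.testing.assert_allclose(hcl, hp / (1.0 + hp * hc), rtol=1e-8)


class TestPadeDelay:
    def test_zero_delay_is_identity(self):
        sys = vt.pade_delay(0.0, 4)
        assert sys.n_states == 0
        assert sys.D[0, 0] == 1.0

    @pytest.mark.parametrize("omega", [0.1, 1.0, 10.0])
    def test_all_pass_magnitude(self, omega):
        sys = vt.pade_delay(0.25, 4)
        h = vt.frequency_response(sys, [omega]).siso()[0]
        assert abs(abs(h) - 1.0) < 1e-9

    def test_phase_matches_exact_delay(self):
        # exact delay phase at omega=4 is -omega*tau = -1.0 rad
        sys = vt.pade_delay(0.25, 4)
        h = vt.frequency_response(sys, [4.0]).siso()[0]
        assert abs(np.angle(h) - (-1.0)) < 1e-3

    def test_state_count_and_negative_tau(self):
        assert vt.pade_delay(0.1, 4).n_states == 4
        with pytest.raises(ValueError):
            vt.pade_delay(-0.1, 4)


class TestSolveCare:
    def test_scalar_closed_form(self):
        # A=0,B=1,Q=1,R=1: -P^2+1=0 -> P=1
        P = vt.solve_care([[0.0]], [[1.0]], [[1.0]], [[1.0]])
        assert abs(P[0, 0] - 1.0) < 1e-10

    def test_zero_q_stable_a_gives_zero(self):
        P = vt.solve_care([[-2.0]], [[1.0]], [[0.0]], [[1.0]])
        assert abs(P[0, 0]) < 1e-12

    def test_matches_hamiltonian_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            n = 3
            A = rng.standard_normal((n, n))
            B = rng.standard_normal((n, 1))
            C = rng.standard_normal((1, n))
            Q = C.T @ C + 0.1 * np.eye(n)
            R = np.array([[1.0 + rng.random()]])
            P = vt.solve_care(A, B, Q, R)
            P_ref = care_hamiltonian_oracle(A, B, Q, R)
            np.testing.assert_allclose(P, P_ref, rtol=1e-6, atol=1e-8)

    def test_indefinite_r_rejected(self):
        with pytest.raises(SynthesisError):
            vt.solve_care([[0.0]], [[1.0]], [[1.0]], [[-1.0]])

    def test_residual_bound_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(2, 6))
            A = rng.standard_normal((n, n))
            B = rng.standard_normal((n, 2))
            C = rng.standard_normal((2, n))
            Q = C.T @ C
            R = np.eye(2) * (0.5 + rng.random())
            P = vt.solve_care(A, B, Q, R)  # raises if residual bound violated
            assert np.min(linalg.eigvalsh(P)) > -1e-8


class TestSolveLyapunov:
    def test_scalar_closed_form(self):
        # -2P + 2 = 0 -> P = 1
        P = vt.solve_lyapunov([[-1.0]], [[2.0]])
        assert abs(P[0, 0] - 1.0) < 1e-12

    def test_zero_q_gives_zero(self):
        P = vt.solve_lyapunov([[-1.0, 0.3], [0.0, -2.0]], np.zeros((2, 2)))
        assert np.max(np.abs(P)) < 1e-12

    def test_matches_kronecker_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            n = 4
            A = rng.standard_normal((n, n)) - 3.0 * np.eye(n)
            G = rng.standard_normal((n, n))
            Q = G @ G.T
            P = vt.solve_lyapunov(A, Q)
            # vec(AP + PA') = (I (x) A + A (x) I) vec(P) = -vec(Q)
            M = np.kron(np.eye(n), A) + np.kron(A, np.eye(n))
            P_ref = linalg.solve(M, -Q.reshape(-1)).reshape(n, n)
            np.testing.assert_allclose(P, P_ref, rtol=1e-8, atol=1e-10)

    def test_unstable_a_rejected(self):
        with pytest.raises(SynthesisError):
            vt.solve_lyapunov([[0.1]], [[1.0]])


class TestBalancedHsv:
    def test_first_order_closed_form(self):
        # Wc = b^2/2a, Wo = c^2/2a -> sigma = |bc| / 2a; a=1,b=2,c=3 -> 3
        sys = first_order(1.0, 2.0, 3.0)
        hsv = vt.balanced_hsv(sys)
        assert hsv.shape == (1,)
        assert abs(hsv[0] - 3.0) < 1e-10

    def test_similarity_invariance(self):
        rng = np.random.default_rng(9)
        sys = rand_stable_system(rng, 2)
        T = np.diag([10.0, 0.1])
        sys_t = vt.StateSpaceModel(
            linalg.inv(T) @ sys.A @ T, linalg.inv(T) @ sys.B, sys.C @ T, sys.D
        )
        np.testing.assert_allclose(
            vt.balanced_hsv(sys), vt.balanced_hsv(sys_t), rtol=1e-8
        )

    def test_weakly_coupled_modes_match_per_mode_values(self):
        # two well-separated first-order modes in parallel: each HSV close
        # to its isolated closed form
        m1 = first_order(0.5, 1.0, 1.0)   # sigma = 1/(2*0.5) = 1.0
        m2 = first_order(50.0, 1.0, 1.0)  # sigma = 1/100
        sys = vt.parallel_sum(m1, m2)
        hsv = vt.balanced_hsv(sys)
        assert abs(hsv[0] - 1.0) / 1.0 < 0.05
        assert abs(hsv[1] - 0.01) / 0.01 < 0.05

    def test_descending_and_invariant_on_random_systems(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            n = int(rng.integers(2, 7))
            sys = rand_stable_system(rng, n)
            hsv = vt.balanced_hsv(sys)
            assert hsv.shape == (n,)
            assert np.all(np.diff(hsv) <= 1e-12)
            assert np.all(hsv >= 0)
            M = rng.standard_normal((n, n)) + n * np.eye(n)
            sys_t = vt.StateSpaceModel(
                linalg.solve(M, sys.A @ M), linalg.solve(M, sys.B),
                sys.C @ M, sys.D,
            )
            np.testing.assert_allclose(
                hsv, vt.balanced_hsv(sys_t), rtol=1e-6, atol=1e-12
            )

    def test_unstable_rejected(self):
        with pytest.raises(SynthesisError):
            vt.balanced_hsv(first_order(-1.0))


class TestFrequencyResponse:
    def test_static_gain(self):
        sys = vt.StateSpaceModel(
            np.zeros((0, 0)), np.zeros((0, 1)), np.zeros((1, 0)), [[2.5]]
        )
        fr = vt.frequency_response(sys, [0.1, 1.0, 10.0])
        np.testing.assert_allclose(fr.siso(), 2.5)

    def test_first_order_lag_closed_form(self):
        h = vt.frequency_response(first_order(1.0), [1.0]).siso()[0]
        assert abs(abs(h) - 1.0 / np.sqrt(2.0)) < 1e-12
        assert abs(np.degrees(np.angle(h)) - (-45.0)) < 1e-9

    def test_integrator_closed_form(self):
        integ = vt.StateSpaceModel([[0.0]], [[1.0]], [[1.0]], [[0.0]])
        h = vt.frequency_response(integ, [0.1]).siso()[0]
        assert abs(abs(h) - 10.0) < 1e-9
        assert abs(np.degrees(np.angle(h)) - (-90.0)) < 1e-9

    def test_marginal_pole_on_grid_raises(self):
        osc = vt.StateSpaceModel(
            [[0.0, 1.0], [-4.0, 0.0]], [[0.0], [1.0]], [[1.0, 0.0]], [[0.0]]
        )
        with pytest.raises(SynthesisError, match="2"):
            vt.frequency_response(osc, [1.0, 2.0, 3.0])


class TestDiscretizeSimulate:
    def test_zero_input_zero_output(self):
        d = vt.discretize_zoh(first_order(1.0), 0.01)
        y = vt.simulate(d, np.zeros((100, 1)))
        assert np.all(y == 0)

    def test_first_order_step_response(self):
        d = vt.discretize_zoh(first_order(1.0), 0.01)
        y = vt.simulate(d, np.ones((101, 1)))
        assert abs(y[100, 0] - (1.0 - np.exp(-1.0))) < 1e-6

    def test_integrator_ramp_exact(self):
        integ = vt.StateSpaceModel([[0.0]], [[1.0]], [[1.0]], [[0.0]])
        d = vt.discretize_zoh(integ, 0.01)
        y = vt.simulate(d, np.ones((1001, 1)))
        assert abs(y[1000, 0] - 10.0) < 1e-8

    def test_zoh_matches_expm_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            sys = rand_stable_system(rng, 3, m=2, p=2)
            dt = 0.05
            d = vt.discretize_zoh(sys, dt)
            Ad_ref = linalg.expm(sys.A * dt)
            Bd_ref = linalg.solve(
                sys.A, (Ad_ref - np.eye(3)) @ sys.B
            )
            np.testing.assert_allclose(d.A, Ad_ref, rtol=1e-10)
            np.testing.assert_allclose(d.B, Bd_ref, rtol=1e-8, atol=1e-12)


class TestSerialization:
    def test_json_round_trip(self):
        sys = first_order(2.0, 3.0, 4.0)
        back = vt.StateSpaceModel.from_json(sys.to_json())
        np.testing.assert_array_equal(sys.A, back.A)
        np.testing.assert_array_equal(sys.D, back.D)
        assert sys.state_labels == back.state_labels
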