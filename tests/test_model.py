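"""Unit tests for the E-I rate model: transfer function, weights, integrator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eigamma.model import (
    ConnectionGains,
    ExternalInput,
    ModelSpec,
    PopulationParams,
    apply_discontinuity,
    effective_weights,
    sigmoid_response,
    sigmoid_slope,
    simulate,
)


class TestSigmoid:
    @pytest.mark.parametrize("m,theta", [(1.0, 5.0), (1.0, 20.0), (0.5, 2.0), (3.0, 0.5)])
    def test_zero_drive_gives_zero(self, m, theta):
        assert sigmoid_response(0.0, PopulationParams(m, theta)) == pytest.approx(0.0, abs=1e-15)

    @pytest.mark.parametrize("m,theta", [(1.0, 5.0), (2.0, 3.0)])
    def test_value_at_threshold(self, m, theta):
        # symmetry point of the logistic: 0.5 minus the lower offset
        expected = 0.5 - 1.0 / (1.0 + np.exp(m * theta))
        assert sigmoid_response(theta, PopulationParams(m, theta)) == pytest.approx(expected)

    def test_closed_form_value(self):
        # m=1, theta=5, drive=10: expit(5) - expit(-5), frozen from
        # high-precision evaluation of the closed form
        got = sigmoid_response(10.0, PopulationParams(1.0, 5.0))
        assert got == pytest.approx(0.9866142981514304, rel=1e-12)

    def test_rejects_nonfinite_drive(self):
        pop = PopulationParams(1.0, 5.0)
        for bad in (np.nan, np.inf, -np.inf):
            with pytest.raises(ValueError):
                sigmoid_response(bad, pop)

    def test_strictly_increasing_and_positive_slope(self):
        pop = PopulationParams(1.0, 5.0)
        # drives restricted to where the slope is above double-precision
        # underflow so the finite-difference check is meaningful
        rng = np.random.default_rng(7)
        x = np.sort(rng.uniform(-15, 25, 100))
        y = sigmoid_response(x, pop)
        assert np.all(np.diff(y) > 0)
        # finite differences agree in sign with the analytic derivative
        fd = (sigmoid_response(x + 1e-6, pop) - sigmoid_response(x - 1e-6, pop)) / 2e-6
        assert np.all(fd > 0)
        assert np.allclose(fd, sigmoid_slope(x, pop), rtol=1e-4, atol=1e-10)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(-60, 60), st.floats(-60, 60))
    def test_bounded_by_sigmoid_range(self, a, b):
        pop = PopulationParams(1.0, 5.0)
        lo = pop.lower_offset
        for v in (a, b):
            assert lo - 1e-12 <= sigmoid_response(v, pop) <= 1 + lo + 1e-12

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            PopulationParams(gain=0.0, threshold=5.0)
        with pytest.raises(ValueError):
            PopulationParams(gain=1.0, threshold=-1.0)


class TestWeights:
    def test_zero_lateral_gains_identity(self):
        g = ConnectionGains(Wee=16, Wei=26, Wie=20, Wii=1)
        w = effective_weights(g)
        assert (w.wee, w.wei, w.wie, w.wii) == (16, 26, 20, 1)

    def test_default_spec_effective_weights(self):
        w = ModelSpec.default().weights
        assert (w.wee, w.wei, w.wie, w.wii) == (16.0, 26.0, 20.0, 1.0)

    def test_base_plus_lateral_sum(self):
        g = ConnectionGains(Wee=10, Wei=20, Wie=15, Wii=0.5,
                            WeELR=6, WeILR=6, WiELR=5, WiILR=0.5)
        w = effective_weights(g)
        assert (w.wee, w.wei, w.wie, w.wii) == (16, 26, 20, 1)

    def test_negative_gain_rejected(self):
        with pytest.raises(ValueError):
            ConnectionGains(Wee=-1, Wei=26, Wie=20, Wii=1)


class TestApplyDiscontinuity:
    def test_identity_scale(self, default_spec):
        assert apply_discontinuity(default_spec, "wee", 1.0).weights == default_spec.weights

    @pytest.mark.parametrize("scale,expected", [(0.9, 14.4), (0.8, 12.8)])
    def test_wee_reduction(self, default_spec, scale, expected):
        assert apply_discontinuity(default_spec, "wee", scale).weights.wee == pytest.approx(expected)

    def test_original_untouched(self, default_spec):
        apply_discontinuity(default_spec, "wee", 0.5)
        assert default_spec.weights.wee == 16.0

    def test_lateral_gain_reduced_first(self):
        d = ModelSpec.default()
        spec = ModelSpec(
            e_params=d.e_params, i_params=d.i_params, taus=d.taus,
            gains=ConnectionGains(Wee=10, Wei=26, Wie=20, Wii=1, WeELR=6),
        )
        out = apply_discontinuity(spec, "wee", 0.9)  # remove 1.6 of 16
        assert out.gains.WeELR == pytest.approx(4.4)
        assert out.gains.Wee == pytest.approx(10.0)
        # large reduction exhausts the lateral gain (clamped at zero)
        out2 = apply_discontinuity(spec, "wee", 0.2)  # remove 12.8
        assert out2.gains.WeELR == 0.0
        assert out2.gains.Wee == pytest.approx(10.0 - (12.8 - 6.0))

    def test_errors(self, default_spec):
        with pytest.raises(ValueError):
            apply_discontinuity(default_spec, "wxx", 0.9)
        with pytest.raises(ValueError):
            apply_discontinuity(default_spec, "wee", 1.2)
        with pytest.raises(ValueError):
            apply_discontinuity(default_spec, "wee", -0.1)


class TestSimulate:
    def test_zero_input_origin_invariant(self, default_spec):
        traj = simulate(default_spec, ExternalInput(0.0, 0.0), 500.0)
        assert np.all(traj.E == 0.0) and np.all(traj.I == 0.0)

    def test_bounded_by_sigmoid_range(self, default_spec):
        rng = np.random.default_rng(11)
        lo_e = default_spec.e_params.lower_offset
        lo_i = default_spec.i_params.lower_offset
        for _ in range(5):
            inp = ExternalInput(rng.uniform(0, 10), rng.uniform(0, 20))
            traj = simulate(default_spec, inp, 1000.0)
            assert traj.E.min() >= lo_e - 1e-9 and traj.E.max() <= 1 + lo_e + 1e-9
            assert traj.I.min() >= lo_i - 1e-9 and traj.I.max() <= 1 + lo_i + 1e-9

    def test_integrator_convergence_on_probe_grid(self, default_spec):
        """RK4 at dt and dt/2 agree to <1e-4 sup-norm over the final 500 ms
        across a 5x5 (iE, iI) probe grid."""
        from eigamma.model import integrate_grid

        gE, gI = np.meshgrid(np.linspace(0, 10, 5), np.linspace(0, 20, 5))
        t1, E1, _ = integrate_grid(default_spec, gE.ravel(), gI.ravel(), 1500.0, 0.05)
        t2, E2, _ = integrate_grid(default_spec, gE.ravel(), gI.ravel(), 1500.0, 0.025)
        keep1 = t1 >= 1000.0
        keep2 = t2 >= 1000.0
        diff = np.abs(E1[keep1] - E2[keep2][::2])
        assert diff.max() < 1e-4

    def test_gamma_range_oscillation_at_operating_point(self, op_trajectory):
        tail = op_trajectory.E[op_trajectory.times >= 4000.0]
        assert tail.max() - tail.min() > 0.05  # sustained, large cycle
        x = tail - tail.mean()
        up = np.flatnonzero((x[:-1] < 0) & (x[1:] >= 0))
        freq = 1000.0 / (np.mean(np.diff(up)) * op_trajectory.dt)
        assert 20.0 < freq < 100.0

    def test_wee_reduction_collapses_amplitude(self, default_spec, op_input):
        def amp(spec):
            traj = simulate(spec, op_input, 2000.0)
            tail = traj.E[traj.times >= 500.0]
            return tail.max() - tail.min()

        a0 = amp(default_spec)
        a8 = amp(apply_discontinuity(default_spec, "wee", 0.8))
        assert a8 < 0.1 * a0

    def test_preconditions(self, default_spec):
        inp = ExternalInput(3.0, 7.5)
        with pytest.raises(ValueError):
            simulate(default_spec, inp, 2000.0, dt=1.0)  # dt > tau_i/50
        with pytest.raises(ValueError):
            simulate(default_spec, inp, 50.0)  # duration < 10*tau_e
        with pytest.raises(ValueError):
            simulate(default_spec, inp, 2000.0, initial_state=(2.0, 0.0))
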