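"""Phase-plane analysis tests: fixed points, nullclines, regimes, metrics."""

import numpy as np
import pytest

from conftest import random_input, random_spec
from eigamma.model import (
    ConnectionGains,
    ExternalInput,
    ModelSpec,
    Trajectory,
    apply_discontinuity,
)
from eigamma.dynamics import (
    MultipleFixedPointsError,
    classify_regime,
    find_fixed_points,
    input_plane_map,
    nullclines,
    oscillation_metrics,
    scan_fixed_points,
    steady_residual,
    weight_perturbation_experiment,
)


def bistable_spec() -> ModelSpec:
    """Strong E self-excitation with no E-I coupling: three steady states."""
    d = ModelSpec.default()
    return ModelSpec(
        e_params=d.e_params, i_params=d.i_params, taus=d.taus,
        gains=ConnectionGains(Wee=16, Wei=1e-6, Wie=0, Wii=0),
    )


class TestFixedPoints:
    def test_origin_root_at_zero_input(self, default_spec):
        fps = find_fixed_points(default_spec, ExternalInput(0.0, 0.0))
        d = min(np.hypot(f.E, f.I) for f in fps)
        assert d < 1e-9

    def test_matches_bruteforce_oracle_on_random_specs(self):
        rng = np.random.default_rng(42)
        for _ in range(12):
            spec = random_spec(rng)
            inp = random_input(rng)
            newton = sorted((f.E, f.I) for f in find_fixed_points(spec, inp))
            brute = sorted(scan_fixed_points(spec, inp, resolution=2000))
            assert len(newton) == len(brute)
            for (e1, i1), (e2, i2) in zip(newton, brute):
                assert abs(e1 - e2) < 1e-5 and abs(i1 - i2) < 1e-5

    def test_residual_bound_at_roots(self, default_spec, op_input):
        for f in find_fixed_points(default_spec, op_input):
            rE, rI = steady_residual(default_spec, op_input, f.E, f.I)
            assert abs(rE) < 1e-9 and abs(rI) < 1e-9

    def test_operating_point_is_unstable_focus(self, default_spec, op_input):
        fps = find_fixed_points(default_spec, op_input)
        assert len(fps) == 1
        fp = fps[0]
        assert fp.stability == "unstable_focus"
        assert np.all(fp.eigenvalues.real > 0)
        assert np.any(np.abs(fp.eigenvalues.imag) > 0)

    def test_bistable_spec_has_three_roots(self):
        fps = find_fixed_points(bistable_spec(), ExternalInput(0.0, 0.0))
        assert len(fps) == 3


class TestNullclines:
    def test_pass_through_origin_at_zero_input(self, default_spec):
        grid = np.linspace(-0.005, 0.9, 300)
        ns = nullclines(default_spec, ExternalInput(0.0, 0.0), grid)
        for curve in (ns.e_nullcline, ns.i_nullcline):
            d = np.min(np.hypot(curve[:, 0], curve[:, 1]))
            assert d < 1e-2  # origin lies on the sampled curve

    def test_points_satisfy_steady_state(self, default_spec, op_input):
        grid = np.linspace(0.0, 0.95, 200)
        ns = nullclines(default_spec, op_input, grid)
        for E, I in ns.e_nullcline:
            rE, _ = steady_residual(default_spec, op_input, E, I)
            assert abs(rE) < 1e-9
        for E, I in ns.i_nullcline:
            _, rI = steady_residual(default_spec, op_input, E, I)
            assert abs(rI) < 1e-9

    def test_intersection_matches_fixed_point(self, default_spec, op_input):
        fp = find_fixed_points(default_spec, op_input)[0]
        ns = nullclines(default_spec, op_input, np.array([fp.E]))
        assert abs(ns.e_nullcline[0, 1] - fp.I) < 1e-6
        assert abs(ns.i_nullcline[0, 1] - fp.I) < 1e-6

    def test_wee_scaling_leaves_i_nullcline_invariant(self, default_spec, op_input):
        grid = np.linspace(0.0, 0.9, 100)
        base = nullclines(default_spec, op_input, grid)
        for scale in (0.9, 0.8):
            pert = nullclines(apply_discontinuity(default_spec, "wee", scale), op_input, grid)
            np.testing.assert_array_equal(pert.i_nullcline, base.i_nullcline)
            assert np.max(np.abs(pert.e_nullcline[:, 1] - base.e_nullcline[:, 1])) > 1e-3

    def test_wii_scaling_leaves_e_nullcline_invariant(self, default_spec, op_input):
        grid = np.linspace(0.0, 0.9, 100)
        base = nullclines(default_spec, op_input, grid)
        pert = nullclines(apply_discontinuity(default_spec, "wii", 0.8), op_input, grid)
        np.testing.assert_array_equal(pert.e_nullcline, base.e_nullcline)
        assert np.max(np.abs(pert.i_nullcline[:, 1] - base.i_nullcline[:, 1])) > 1e-6


class TestOscillationMetrics:
    def test_constant_trajectory(self):
        t = np.arange(0, 3000.0, 0.5)
        traj = Trajectory(times=t, E=np.full_like(t, 0.3), I=np.full_like(t, 0.1), dt=0.5)
        m = oscillation_metrics(traj)
        assert m.amplitude == 0.0 and m.peak_frequency == 0.0 and not m.sustained

    def test_pure_sinusoid_frequency(self):
        t = np.arange(0, 3000.0, 0.5)
        traj = Trajectory(times=t, E=0.1 * np.sin(2 * np.pi * 50e-3 * t),
                          I=np.zeros_like(t), dt=0.5)
        m = oscillation_metrics(traj)
        bin_hz = 1000.0 / (3000.0 - 500.0)
        assert abs(m.peak_frequency - 50.0) < bin_hz
        assert abs(m.psd_peak_frequency - 50.0) <= bin_hz
        assert m.sustained
        assert m.amplitude == pytest.approx(0.2, rel=1e-2)

    def test_zero_crossing_agrees_with_periodogram(self, op_trajectory):
        m = oscillation_metrics(op_trajectory, transient_ms=500.0)
        bin_hz = 1000.0 / 4500.0
        assert m.sustained
        assert abs(m.peak_frequency - m.psd_peak_frequency) <= 2 * bin_hz

    def test_too_short_trajectory_rejected(self):
        t = np.arange(0, 1000.0, 0.5)
        traj = Trajectory(times=t, E=np.zeros_like(t), I=np.zeros_like(t), dt=0.5)
        with pytest.raises(ValueError):
            oscillation_metrics(traj, transient_ms=500.0)


class TestRegime:
    def test_operating_point_regime(self, default_spec, op_input):
        lab = classify_regime(default_spec, op_input)
        assert lab.oscillatory and lab.e_sublinear and lab.i_superlinear

    def test_saturated_input_not_oscillatory(self, default_spec):
        lab = classify_regime(default_spec, ExternalInput(100.0, 100.0))
        assert not lab.oscillatory

    def test_multiple_fixed_points_refused(self):
        with pytest.raises(MultipleFixedPointsError):
            classify_regime(bistable_spec(), ExternalInput(0.0, 0.0))


class TestInputPlaneMap:
    def test_single_zero_cell(self, default_spec):
        m = input_plane_map(default_spec, np.array([0.0]), np.array([0.0]),
                            duration=2000.0)
        assert m.E_map.shape == (1, 1)
        assert m.E_map[0, 0] == 0.0 and m.I_map[0, 0] == 0.0
        assert not m.sustained_map[0, 0]
        assert m.amplitude_map[0, 0] < 1e-3

    def test_axes_validated(self, default_spec):
        with pytest.raises(ValueError):
            input_plane_map(default_spec, np.array([1.0, 0.5]), np.array([0.0, 1.0]))


class TestPerturbation:
    def test_identity_scale_matches_unperturbed(self, default_spec, op_input):
        res = weight_perturbation_experiment(default_spec, "wee", [1.0], op_input,
                                             duration=3000.0)
        assert res[0].fixed_point_shift == 0.0
        assert res[0].metrics.sustained
        assert res[0].scale == 1.0
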